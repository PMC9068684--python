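import math
import random
import warnings
from fractions import Fraction

import numpy as np
import pytest

from genomealg.perm import (
    AlgebraElement,
    Permutation,
    coset_canonical,
    dihedral_group,
)
from genomealg.genome_algebra import cloud_count, reduced_irreps, symmetry_element
from genomealg.likelihood_mle import (
    full_group_partial_traces,
    likelihood,
    likelihood_full_group,
    mle,
    path_probability,
    spectral_decompose,
)
from genomealg.markov_oracle import (
    cloud_markov_matrix,
    oracle_likelihood,
    oracle_path_probability,
)
from genomealg.rearrangement_model import build_model


def random_perm(n, rng):
    imgs = list(range(1, n + 1))
    rng.shuffle(imgs)
    return Permutation(imgs)


@pytest.fixture(scope="module")
def sd5(adjacent5):
    return spectral_decompose(adjacent5[0])


@pytest.fixture(scope="module")
def sd6(adjacent6):
    return spectral_decompose(adjacent6[0])


class TestSpectralDecomposition:
    def test_trivial_partition_eigenvalue_one(self, sd6):
        b = sd6.blocks[0]
        assert b.partition == (6,)
        assert b.eigenvalues[0] == pytest.approx(1.0, abs=1e-12)
        assert len(b.eigenvalues) == 1

    def test_term_count_bound_n6(self, sd6):
        assert sd6.term_count <= 8

    def test_projections_idempotent_orthogonal(self, sd6):
        for b in sd6.blocks:
            total = np.zeros((b.k, b.k))
            for i, p in enumerate(b.projections):
                assert np.allclose(p @ p, p, atol=1e-10)
                total += p
                for j, q in enumerate(b.projections):
                    if i != j:
                        assert np.allclose(p @ q, 0, atol=1e-10)
            assert np.allclose(total, np.eye(b.k), atol=1e-10)

    def test_eigenvalues_in_unit_interval(self, sd5, sd6):
        for sd in (sd5, sd6):
            for b in sd.blocks:
                for lam in b.eigenvalues:
                    assert -1 - 1e-9 <= lam <= 1 + 1e-9


class TestPathProbability:
    def test_alpha0(self, adjacent6, sd6):
        ms = adjacent6[0]
        assert path_probability(ms, sd6, Permutation.identity(6), 0) == pytest.approx(1.0)
        for d in list(ms.z.elements)[:4]:
            assert path_probability(ms, sd6, d, 0) == pytest.approx(1.0)
        assert path_probability(ms, sd6, Permutation.parse("(1 2)", 6), 0) == pytest.approx(
            0.0, abs=1e-10
        )

    @pytest.mark.parametrize("fixture", ["adjacent5", "adjacent6", "inversions6"])
    def test_oracle_equivalence(self, fixture, request):
        ms, _ = request.getfixturevalue(fixture)
        sd = spectral_decompose(ms)
        cm = cloud_markov_matrix(ms)
        rng = random.Random(fixture)
        for _ in range(10):
            sigma = random_perm(ms.n, rng)
            for k in range(9):
                assert path_probability(ms, sd, sigma, k) == pytest.approx(
                    oracle_path_probability(cm, sigma, k), abs=1e-10
                )

    def test_conservation(self, adjacent6, sd6):
        ms = adjacent6[0]
        cm = cloud_markov_matrix(ms)
        for k in range(6):
            total = sum(path_probability(ms, sd6, rep, k) for rep in cm.basis)
            assert total == pytest.approx(1.0, abs=1e-10)

    def test_class_invariance(self, adjacent6, sd6):
        ms = adjacent6[0]
        rng = random.Random(42)
        sigma = random_perm(6, rng)
        base = [path_probability(ms, sd6, sigma, k) for k in range(5)]
        for _ in range(5):
            d1 = rng.choice(ms.z.elements)
            d2 = rng.choice(ms.z.elements)
            member = d1 * sigma * d2
            inv_member = d1 * sigma.inverse() * d2
            for k in range(5):
                assert path_probability(ms, sd6, member, k) == pytest.approx(
                    base[k], abs=1e-9
                )
                assert path_probability(ms, sd6, inv_member, k) == pytest.approx(
                    base[k], abs=1e-9
                )


class TestLikelihood:
    def test_l0_identity(self, adjacent6, sd6):
        ms = adjacent6[0]
        assert likelihood(ms, sd6, Permutation.identity(6), 0.0) == pytest.approx(1.0)

    def test_matches_poisson_series(self, adjacent5, sd5):
        ms, _ = adjacent5
        cm = cloud_markov_matrix(ms)
        rng = random.Random(7)
        for _ in range(10):
            sigma = random_perm(5, rng)
            t = rng.uniform(0.0, 10.0)
            assert likelihood(ms, sd5, sigma, t) == pytest.approx(
                oracle_likelihood(cm, sigma, t), abs=1e-8
            )

    def test_large_t_limit(self, adjacent6, sd6):
        ms = adjacent6[0]
        k = cloud_count(6, ms.z)
        for s in ["(1 2)", "(1 3 5)", "(2 4 6)"]:
            sigma = Permutation.parse(s, 6)
            assert likelihood(ms, sd6, sigma, 800.0) == pytest.approx(1.0 / k, abs=1e-9)

    def test_inverse_symmetry(self, adjacent6, sd6):
        ms = adjacent6[0]
        rng = random.Random(3)
        for _ in range(5):
            sigma = random_perm(6, rng)
            for t in (0.5, 2.0, 7.0):
                assert likelihood(ms, sd6, sigma, t) == pytest.approx(
                    likelihood(ms, sd6, sigma.inverse(), t), abs=1e-9
                )


class TestFullGroupRoute:
    def test_agreement_n5(self, adjacent5, sd5):
        ms, _ = adjacent5
        rng = random.Random(99)
        for _ in range(20):
            sigma = random_perm(5, rng)
            t = rng.uniform(0.0, 8.0)
            assert likelihood_full_group(ms, sigma, t) == pytest.approx(
                likelihood(ms, sd5, sigma, t), abs=1e-8
            )

    def test_knocked_out_traces_vanish(self, adjacent5, sd5):
        ms, _ = adjacent5
        reduced_eigs = {
            b.partition: set(b.eigenvalues) for b in sd5.blocks
        }
        rng = random.Random(5)
        for _ in range(5):
            sigma = random_perm(5, rng)
            for p, lam, trace in full_group_partial_traces(ms, sigma):
                kept = reduced_eigs.get(p, set())
                if not any(abs(lam - mu) < 1e-8 for mu in kept):
                    assert abs(trace) <= 1e-10

    def test_beta_coefficient_identity(self, adjacent4):
        # coefficient of e in sigma^{-1} s^k equals the enumerated beta_k
        from _oracles import brute_force_beta

        ms, _ = adjacent4
        s = AlgebraElement(4, dict(ms.expanded))
        rng = random.Random(1)
        for k in range(5):
            sk = s**k
            for _ in range(4):
                sigma = random_perm(4, rng)
                coeff = (
                    AlgebraElement.from_permutation(sigma.inverse()) * sk
                ).coefficient(Permutation.identity(4))
                assert coeff == brute_force_beta(ms, sigma, k)


class TestMLE:
    def test_identity_target(self, adjacent6, sd6):
        ms = adjacent6[0]
        res = mle(ms, sd6, Permutation.identity(6))
        assert res.mle_time == 0.0
        assert res.max_likelihood == pytest.approx(1.0)
        assert not res.unrelated

    def test_adjacent_swap_target_has_finite_mle(self, adjacent6, sd6):
        ms = adjacent6[0]
        res = mle(ms, sd6, Permutation.parse("(1 2)", 6))
        assert res.mle_time is not None and res.mle_time > 0
        assert res.max_likelihood > res.asymptote

    def test_class_members_agree(self, adjacent6, sd6):
        ms = adjacent6[0]
        rng = random.Random(21)
        sigma = Permutation.parse("(1 3)(2 5)", 6)
        base = mle(ms, sd6, sigma)
        for _ in range(3):
            d1, d2 = rng.choice(ms.z.elements), rng.choice(ms.z.elements)
            for member in (d1 * sigma * d2, d1 * sigma.inverse() * d2):
                res = mle(ms, sd6, member)
                assert res.mle_time == pytest.approx(base.mle_time, abs=1e-5)
                assert res.max_likelihood == pytest.approx(
                    base.max_likelihood, abs=1e-9
                )

    def test_no_finite_mle_exists_n6(self, adjacent6, sd6):
        ms = adjacent6[0]
        cm = cloud_markov_matrix(ms)
        none_cases = [rep for rep in cm.basis if mle(ms, sd6, rep).mle_time is None]
        assert none_cases
        res = mle(ms, sd6, none_cases[0])
        assert np.all(res.l_grid <= res.asymptote * (1 + 1e-9))
        assert res.asymptote == pytest.approx(1.0 / 60)

    def test_distance_symmetry(self, adjacent6, sd6):
        # distance(g -> h) equals distance(h -> g) for reversible models
        ms = adjacent6[0]
        g = Permutation.parse("(1 2 4)", 6)
        h = Permutation.parse("(2 6)(3 5)", 6)
        r1 = mle(ms, sd6, g * h.inverse())
        r2 = mle(ms, sd6, h * g.inverse())
        if r1.mle_time is None:
            assert r2.mle_time is None
        else:
            assert r1.mle_time == pytest.approx(r2.mle_time, abs=1e-5)

    def test_unrelated_under_non_generating_model(self):
        n = 5
        z = dihedral_group(n)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ms = build_model(
                n, z, [(Permutation.identity(n), Fraction(1))]
            )
        sd = spectral_decompose(ms)
        res = mle(ms, sd, Permutation.parse("(1 3)(2 4)", n))
        assert res.unrelated
        assert res.mle_time is None
        assert res.max_likelihood == 0.0
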