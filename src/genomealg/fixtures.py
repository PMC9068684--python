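"""Deterministic fixture models and sample genomes for tests and demos."""

from __future__ import annotations

import warnings
from fractions import Fraction

import numpy as np

from .perm import Permutation, coset_canonical, dihedral_group
from .rearrangement_model import (
    DuplicateCloudActionError,
    ModelSpec,
    build_model,
)

__all__ = ["fixture_model", "sample_genomes"]


def fixture_model(kind: str, n: int, seed: int = 0, n_genomes: int = 5):
    """Build a named fixture model plus ``n_genomes`` sample genome clouds.

    ``adjacent-swaps``: the single orbit of (1 2) under dihedral symmetry.
    ``small-inversions``: two-region and three-region inversions, realized
    as the dihedral orbits of (1 2) (weight 2/3) and (1 3) (weight 1/3);
    at N=5 the two orbits have the same cloud action (complementary
    rearrangements), so the deduplicated single-type model is built and
    the merge is logged.
    """
    z = dihedral_group(n)
    if kind == "adjacent-swaps":
        base = [(Permutation.from_cycles([(1, 2)], n), Fraction(1))]
        ms = build_model(n, z, base, enforce_reversibility=True)
    elif kind == "small-inversions":
        if n < 4:
            raise ValueError("small-inversions needs N >= 4")
        base = [
            (Permutation.from_cycles([(1, 2)], n), Fraction(2, 3)),
            (Permutation.from_cycles([(1, 3)], n), Fraction(1, 3)),
        ]
        try:
            ms = build_model(n, z, base, enforce_reversibility=True)
        except DuplicateCloudActionError:
            warnings.warn(
                f"N={n}: 2- and 3-region inversions have the same cloud "
                f"action; merging into a single type",
                stacklevel=2,
            )
            ms = build_model(n, z, base[:1], enforce_reversibility=True)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")

    genomes = sample_genomes(ms, n_genomes, seed)
    return ms, genomes


def sample_genomes(ms: ModelSpec, count: int, seed: int) -> list[Permutation]:
    """Canonical cloud representatives of uniformly random permutations."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(count):
        images = rng.permutation(ms.n) + 1
        out.append(coset_canonical(Permutation(images), ms.z))
    return out
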