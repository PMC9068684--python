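"""Rearrangement models: symmetry closure, reversibility, redundancy checks.

A model is specified by base rearrangement *types* (a permutation plus a
positive weight).  Each type is expanded into its conjugation orbit under
the symmetry subgroup (condition M1), optionally unioned with the orbit
of its inverse (condition M2).  A type's weight is split uniformly over
the distinct permutations of its orbit and the whole model is then
normalized to a probability distribution.

Two base types with the same cloud action (equal ``z a z``) are rejected:
silently merging complementary rearrangements would double-count them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np

from .perm import AlgebraElement, Permutation, SymmetrySubgroup, generates_full_group
from .genome_algebra import ReducedIrrep, symmetry_element
from .sn_irreps import algebra_rep

__all__ = [
    "ModelSpec",
    "ModelElement",
    "DuplicateCloudActionError",
    "build_model",
    "model_element",
    "reduced_model_matrices",
]


class DuplicateCloudActionError(ValueError):
    """Two base rearrangements act identically on every genome cloud.

    Under the symmetry subgroup a rearrangement and its complement can
    coincide as actions (e.g. 2-region and 3-region inversions at N=5);
    including both would silently skew the weights, so this is an error
    and the caller must deduplicate deliberately.
    """


@dataclass
class ModelSpec:
    """A validated rearrangement model ``(M, w)`` with its symmetry subgroup."""

    n: int
    z: SymmetrySubgroup
    base: list[tuple[Permutation, Fraction]]
    expanded: dict[Permutation, Fraction]
    cloud_weights: dict[Permutation, Fraction]
    reversible: bool
    generates: bool
    warnings: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.expanded)

    def weight(self, a: Permutation) -> Fraction:
        return self.expanded.get(a, Fraction(0))


@dataclass(frozen=True)
class ModelElement:
    """The model element s = sum w(a) a and its cloud form s~ = z s."""

    s: AlgebraElement
    s_tilde: AlgebraElement


def _cloud_action(a: Permutation, z: SymmetrySubgroup) -> AlgebraElement:
    """The exact element ``z a z`` characterizing the action of cloud ``za``."""
    ze = symmetry_element(z)
    return ze * a * ze


def _conjugation_orbit(a: Permutation, z: SymmetrySubgroup) -> set[Permutation]:
    return {d * a * d.inverse() for d in z.elements}


def build_model(
    n: int,
    z: SymmetrySubgroup,
    base: Sequence[tuple[Permutation, Fraction | int | float | str]],
    enforce_reversibility: bool = True,
) -> ModelSpec:
    """Expand base rearrangement types into a full (M1/M2-closed) model."""
    if z.degree != n:
        raise ValueError("symmetry subgroup degree mismatch")
    if not base:
        raise ValueError("model needs at least one base rearrangement")

    notes: list[str] = []
    parsed: list[tuple[Permutation, Fraction]] = []
    for a, w in base:
        if a.degree != n:
            raise ValueError(f"base rearrangement degree mismatch: {a}")
        w = Fraction(w)
        if w <= 0:
            raise ValueError(f"weight must be positive, got {w} for {a}")
        parsed.append((a, w))

    # reject base types with identical cloud actions (exact comparison)
    actions = [_cloud_action(a, z) for a, _ in parsed]
    for i in range(len(actions)):
        for j in range(i + 1, len(actions)):
            if actions[i] == actions[j]:
                raise DuplicateCloudActionError(
                    f"base rearrangements {parsed[i][0]} and {parsed[j][0]} have "
                    f"the same cloud action z*a*z; complementary rearrangements "
                    f"must not both be included"
                )

    for a, _ in parsed:
        if a in z:
            msg = (
                f"base rearrangement {a} lies in the symmetry subgroup: its "
                f"cloud action is the identity (pure self-loop weight)"
            )
            notes.append(msg)
            warnings.warn(msg, stacklevel=2)

    expanded: dict[Permutation, Fraction] = {}
    cloud_weights: dict[Permutation, Fraction] = {}
    for a, w in parsed:
        orbit = _conjugation_orbit(a, z)
        if enforce_reversibility:
            orbit |= {x.inverse() for x in orbit}
        share = w / len(orbit)
        for x in orbit:
            expanded[x] = expanded.get(x, Fraction(0)) + share
        cloud_weights[a] = w

    total = sum(expanded.values(), Fraction(0))
    expanded = {a: w / total for a, w in expanded.items()}
    cloud_weights = {a: w / total for a, w in cloud_weights.items()}

    # M1 closure sanity check (exact)
    for a, w in expanded.items():
        for d in z.elements:
            conj = d * a * d.inverse()
            if expanded.get(conj) != w:
                raise AssertionError("M1 closure violated after expansion")

    reversible = all(
        expanded.get(a.inverse()) == w for a, w in expanded.items()
    )
    if enforce_reversibility and not reversible:
        raise AssertionError("M2 closure violated after expansion")

    gens = list(expanded) + list(z.generators)
    generates = generates_full_group(gens, n)
    if not generates:
        msg = (
            "model and symmetry subgroup do not generate the full symmetric "
            "group; unreachable genomes are unrelated under the model"
        )
        notes.append(msg)
        warnings.warn(msg, stacklevel=2)

    return ModelSpec(
        n=n,
        z=z,
        base=parsed,
        expanded=expanded,
        cloud_weights=cloud_weights,
        reversible=reversible,
        generates=generates,
        warnings=notes,
    )


def model_element(ms: ModelSpec) -> ModelElement:
    """Exact model element and its cloud counterpart ``z s``."""
    s = AlgebraElement(ms.n, dict(ms.expanded))
    s_tilde = symmetry_element(ms.z) * s
    return ModelElement(s=s, s_tilde=s_tilde)


def reduced_model_matrices(
    ms: ModelSpec, rps: Sequence[ReducedIrrep]
) -> list[tuple[ReducedIrrep, np.ndarray]]:
    """Symmetric k_p x k_p matrices ``Q_p^T rho_p(s) Q_p`` for each k_p > 0.

    Requires a reversible model (M2); otherwise the matrices need not be
    diagonalisable by a real orthogonal change of basis.
    """
    if not ms.reversible:
        raise ValueError(
            "model is not reversible (M2); rebuild with enforce_reversibility=True"
        )
    s = AlgebraElement(ms.n, dict(ms.expanded))
    out = []
    for rp in rps:
        if rp.k == 0:
            continue
        full = algebra_rep(rp.partition, s)
        reduced = rp.q.T @ full @ rp.q
        if not np.allclose(reduced, reduced.T, atol=1e-10):
            raise ArithmeticError(
                f"reduced model matrix for {rp.partition} is not symmetric"
            )
        reduced = 0.5 * (reduced + reduced.T)
        out.append((rp, reduced))
    return out
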