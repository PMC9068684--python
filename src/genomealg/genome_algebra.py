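"""The symmetry element z, its irrep projections, and the reduced representations.

For a symmetry subgroup ``Z`` of S_N, the symmetry element
``z = (1/|Z|) sum_{d in Z} d`` is an idempotent whose irrep image
``rho_p(z)`` has spectrum contained in {0, 1}.  An orthonormal basis
``Q_p`` of the 1-eigenspace (dimension ``k_p``) defines the reduced
representation ``rho_p^A(tau) = Q_p^T rho_p(tau) Q_p`` of the genome
algebra ``A = z C[S_N]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .perm import AlgebraElement, Permutation, SymmetrySubgroup
from .sn_irreps import Partition, algebra_rep, irrep, partitions

__all__ = [
    "symmetry_element",
    "symmetry_projection",
    "ReducedIrrep",
    "reduced_irrep",
    "reduced_irreps",
    "reduced_rep_matrix",
    "regular_character_A",
    "cloud_count",
    "class_algebra_dimension",
    "dimension_table",
]

_EIGTOL = 1e-9


def symmetry_element(z: SymmetrySubgroup) -> AlgebraElement:
    """The idempotent ``(1/|Z|) sum_{d in Z} d`` with exact coefficients."""
    w = Fraction(1, z.order)
    return AlgebraElement(z.degree, {d: w for d in z.elements})


def symmetry_projection(partition: Partition, z: SymmetrySubgroup) -> np.ndarray:
    """``rho_p(z)``: the average of the irrep matrices over the subgroup.

    Symmetric and idempotent; eigenvalues are 0/1 up to numerical noise.
    """
    rep = irrep(tuple(partition))
    if rep.n != z.degree:
        raise ValueError("degree mismatch")
    proj = np.zeros((rep.dimension, rep.dimension))
    for d in z.elements:
        proj += rep.matrix(d)
    proj /= z.order
    return proj


@dataclass(frozen=True)
class ReducedIrrep:
    """Projection data defining one reduced irrep of the genome algebra."""

    partition: Partition
    dimension: int  # D_p of the parent irrep
    k: int          # multiplicity of eigenvalue 1 of rho_p(z)
    q: np.ndarray = field(repr=False)  # D_p x k_p, orthonormal columns


def reduced_irrep(partition: Partition, z: SymmetrySubgroup) -> ReducedIrrep:
    """Extract the eigenvalue-1 eigenspace of ``rho_p(z)``.

    The trace-derived multiplicity and the eigen-count must agree; a
    mismatch signals a broken irrep and raises.
    """
    partition = tuple(partition)
    proj = symmetry_projection(partition, z)
    dim = proj.shape[0]
    eigvals, eigvecs = np.linalg.eigh(proj)
    if np.any(np.minimum(np.abs(eigvals), np.abs(eigvals - 1.0)) > _EIGTOL):
        raise ArithmeticError(
            f"projection spectrum not within {_EIGTOL} of {{0,1}} for {partition}"
        )
    k_trace = int(round(np.trace(proj)))
    selected = eigvecs[:, eigvals > 0.5]
    if selected.shape[1] != k_trace:
        raise ArithmeticError(
            f"eigen-count {selected.shape[1]} != trace multiplicity {k_trace}"
        )
    if k_trace:
        # re-orthonormalize for safety; basis freedom is benign downstream
        q, _ = np.linalg.qr(selected)
    else:
        q = np.zeros((dim, 0))
    q.setflags(write=False)
    return ReducedIrrep(partition=partition, dimension=dim, k=k_trace, q=q)


def reduced_irreps(z: SymmetrySubgroup) -> list[ReducedIrrep]:
    """Reduced irreps for every partition of N, in partition order."""
    return [reduced_irrep(p, z) for p in partitions(z.degree)]


def reduced_rep_matrix(rp: ReducedIrrep, tau: AlgebraElement | Permutation) -> np.ndarray:
    """``Q_p^T rho_p(tau) Q_p`` — the k_p x k_p reduced representation.

    Only the z-side behaviour of ``tau`` is represented: the map factors
    through ``z tau z``, so arguments are implicitly premultiplied by z.
    """
    if isinstance(tau, Permutation):
        tau = AlgebraElement.from_permutation(tau)
    full = algebra_rep(rp.partition, tau)
    return rp.q.T @ full @ rp.q


def cloud_count(n: int, z: SymmetrySubgroup) -> int:
    """K = N!/|Z|, the number of distinct permutation clouds."""
    k, rem = divmod(math.factorial(n), z.order)
    assert rem == 0, "|Z| must divide N!"
    return k


def regular_character_A(sigma: Permutation, z: SymmetrySubgroup,
                        rps: list[ReducedIrrep] | None = None) -> float:
    """Regular character of the genome algebra at the cloud of ``sigma``.

    Computed two ways and cross-asserted: the exact case split
    (K if sigma in Z else 0) and the sum over reduced irrep traces.
    """
    k = cloud_count(sigma.degree, z)
    exact = float(k) if sigma in z else 0.0
    if rps is None:
        rps = reduced_irreps(z)
    spectral = sum(
        rp.dimension * float(np.trace(reduced_rep_matrix(rp, sigma)))
        for rp in rps
        if rp.k > 0
    )
    if abs(spectral - exact) > 1e-8 * max(1.0, k):
        raise ArithmeticError(
            f"regular character mismatch: exact {exact}, spectral {spectral}"
        )
    return exact


def _centralizer_order(cycle_type: tuple[int, ...]) -> int:
    counts: dict[int, int] = {}
    for length in cycle_type:
        counts[length] = counts.get(length, 0) + 1
    out = 1
    for length, mult in counts.items():
        out *= length**mult * math.factorial(mult)
    return out


def class_algebra_dimension(n: int, z: SymmetrySubgroup) -> int:
    """Number of double cosets ``[g]_D = {z1 g z2}`` via Burnside's lemma.

    ``z1 g z2 = g`` iff ``g z2 g^{-1} = z1^{-1}``, so the fixed-point count
    for the pair (z1, z2) is the centralizer order when z2 and z1^{-1}
    share a cycle type, and zero otherwise.
    """
    if n > 8:
        raise ValueError("double-coset count limited to N <= 8")
    total = 0
    types = [(d.inverse().cycle_type(), d.cycle_type()) for d in z.elements]
    for inv_type1, _ in types:
        for _, type2 in types:
            if inv_type1 == type2:
                total += _centralizer_order(type2)
    dim, rem = divmod(total, z.order**2)
    assert rem == 0
    return dim


def dimension_table(z: SymmetrySubgroup) -> list[tuple[Partition, int, int]]:
    """Rows ``(partition, D_p, k_p)`` in partition order."""
    return [(rp.partition, rp.dimension, rp.k) for rp in reduced_irreps(z)]
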