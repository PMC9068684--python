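"""Brute-force reference route: the cloud Markov chain on genome space.

The regular representation of the model element on the genome algebra is
a K x K column-stochastic matrix over the K = N!/|Z| genome clouds; its
k-th power read out at (cloud(sigma), reference) gives the same path
probabilities as the spectral route and is used as the oracle in tests.
Entries are accumulated exactly in rational arithmetic.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .perm import Permutation, SymmetrySubgroup, coset_canonical
from .rearrangement_model import ModelSpec

__all__ = [
    "CloudMarkovMatrix",
    "cloud_markov_matrix",
    "oracle_path_probability",
    "oracle_likelihood",
    "full_group_markov_matrix",
]


@dataclass
class CloudMarkovMatrix:
    """Cloud basis (reference first, then lex order) and transition matrix."""

    basis: list[Permutation]
    matrix_exact: list[list[Fraction]] = field(repr=False)
    matrix: np.ndarray = field(repr=False)
    index: dict[Permutation, int] = field(repr=False)
    z: "SymmetrySubgroup" = field(repr=False, default=None)

    @property
    def size(self) -> int:
        return len(self.basis)

    def cloud_index(self, sigma: Permutation) -> int:
        return self.index[coset_canonical(sigma, self.z)]


def _enumerate_clouds(ms: ModelSpec):
    n = ms.n
    reps: set[Permutation] = set()
    cloud_of: dict[Permutation, Permutation] = {}
    for images in itertools.permutations(range(1, n + 1)):
        sigma = Permutation(images)
        rep = coset_canonical(sigma, ms.z)
        cloud_of[sigma] = rep
        reps.add(rep)
    ref = coset_canonical(Permutation.identity(n), ms.z)
    basis = [ref] + sorted(reps - {ref})
    index = {rep: i for i, rep in enumerate(basis)}
    return basis, index, cloud_of


def cloud_markov_matrix(ms: ModelSpec) -> CloudMarkovMatrix:
    """Build the K x K cloud transition matrix by direct coset counting.

    Column j holds the one-event distribution out of cloud j: expanding
    ``s z sigma_j`` term by term, each permutation ``a d sigma_j`` lands in
    some cloud i and contributes ``w(a)/|Z|`` to entry (i, j).
    """
    k = math.factorial(ms.n) // ms.z.order
    if ms.n > 8:
        raise ValueError(f"cloud enumeration limited to N <= 8 (K would be {k})")
    basis, index, cloud_of = _enumerate_clouds(ms)
    zorder = ms.z.order
    exact = [[Fraction(0)] * k for _ in range(k)]
    for a, w in ms.expanded.items():
        share = w / zorder
        for d in ms.z.elements:
            ad = a * d
            for j, rep in enumerate(basis):
                target = cloud_of[ad * rep]
                exact[index[target]][j] += share
    dense = np.array([[float(x) for x in row] for row in exact])
    return CloudMarkovMatrix(
        basis=basis, matrix_exact=exact, matrix=dense, index=index, z=ms.z
    )


def oracle_path_probability(cm: CloudMarkovMatrix, sigma: Permutation, k: int) -> float:
    """Entry (cloud(sigma), reference) of the k-th matrix power."""
    if k < 0:
        raise ValueError("k must be >= 0")
    v = np.zeros(cm.size)
    v[0] = 1.0
    for _ in range(k):
        v = cm.matrix @ v
    return float(v[cm.cloud_index(sigma)])


def _poisson_truncation(t: float, tol: float = 1e-12) -> int:
    """Smallest k* with Poisson(t) tail mass beyond k* below tol."""
    if t == 0:
        return 0
    term = math.exp(-t)
    cum = term
    k = 0
    while 1.0 - cum > tol:
        k += 1
        term *= t / k
        cum += term
        if k > 100_000:  # pragma: no cover - safety valve
            break
    return k


def oracle_likelihood(cm: CloudMarkovMatrix, sigma: Permutation, t: float) -> float:
    """Truncated Poisson series sum_k alpha_k e^{-T} T^k / k!."""
    if t < 0:
        raise ValueError("T must be >= 0")
    kmax = _poisson_truncation(t)
    idx = cm.cloud_index(sigma)
    v = np.zeros(cm.size)
    v[0] = 1.0
    weight = math.exp(-t)
    total = weight * v[idx]
    for k in range(1, kmax + 1):
        v = cm.matrix @ v
        weight *= t / k
        total += weight * v[idx]
    return float(total)


def full_group_markov_matrix(ms: ModelSpec) -> tuple[list[Permutation], np.ndarray]:
    """The N! x N! permutation-level chain; entry (i,j) = w(sigma_i sigma_j^{-1})."""
    if ms.n > 5:
        raise ValueError("full-group matrix limited to N <= 5")
    perms = [Permutation(im) for im in itertools.permutations(range(1, ms.n + 1))]
    index = {p: i for i, p in enumerate(perms)}
    size = len(perms)
    mat = np.zeros((size, size))
    for j, pj in enumerate(perms):
        for a, w in ms.expanded.items():
            mat[index[a * pj], j] = float(w)
    return perms, mat
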