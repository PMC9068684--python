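"""Irreducible representations of S_N in Young's orthogonal form.

Partitions are enumerated in reverse-lexicographic order, which is the
canonical index for every per-partition array in the package.  Standard
Young tableaux are ordered by last-letter order so that the generator
matrices are reproducible bit-for-bit.  Representation matrices for an
arbitrary permutation are obtained by decomposing it into adjacent
transpositions (bubble sort of the one-line form) and multiplying the
generator matrices.
"""

from __future__ import annotations

import math
from functools import lru_cache
from typing import Sequence

import numpy as np

from .perm import AlgebraElement, Permutation

__all__ = [
    "Partition",
    "partitions",
    "hook_dimension",
    "standard_tableaux",
    "Irrep",
    "irrep",
    "irrep_matrix",
    "algebra_rep",
    "character",
]

Partition = tuple[int, ...]


def _validate_partition(p: Sequence[int]) -> Partition:
    p = tuple(int(x) for x in p)
    if not p or any(x <= 0 for x in p):
        raise ValueError(f"invalid partition {p}")
    if any(a < b for a, b in zip(p, p[1:])):
        raise ValueError(f"parts must be weakly decreasing: {p}")
    return p


def partitions(n: int) -> list[Partition]:
    """All partitions of ``n`` in reverse-lexicographic order, ``(n)`` first."""
    if n < 1:
        raise ValueError("n must be >= 1")

    def gen(remaining: int, cap: int):
        if remaining == 0:
            yield ()
            return
        for first in range(min(cap, remaining), 0, -1):
            for rest in gen(remaining - first, first):
                yield (first,) + rest

    return list(gen(n, n))


def hook_dimension(p: Sequence[int]) -> int:
    """Dimension of the irrep for partition ``p`` via the hook-length formula."""
    p = _validate_partition(p)
    n = sum(p)
    conj = [sum(1 for part in p if part > c) for c in range(p[0])]
    hooks = 1
    for r, row_len in enumerate(p):
        for c in range(row_len):
            hooks *= (row_len - c) + (conj[c] - r) - 1
    dim, rem = divmod(math.factorial(n), hooks)
    assert rem == 0
    return dim


def standard_tableaux(p: Sequence[int]) -> list[tuple[tuple[int, int], ...]]:
    """Standard Young tableaux of shape ``p`` in last-letter order.

    Each tableau is encoded as a tuple of ``(row, col)`` cells (0-based),
    indexed by entry value: element ``m-1`` of the tuple is the cell
    containing ``m``.
    """
    p = _validate_partition(p)
    n = sum(p)

    def build(filled: list[tuple[int, int]], row_fill: list[int]):
        if len(filled) == n:
            yield tuple(filled)
            return
        for r, row_len in enumerate(p):
            # next entry may extend any row whose length is behind the row above
            if row_fill[r] < row_len and (r == 0 or row_fill[r] < row_fill[r - 1]):
                row_fill[r] += 1
                filled.append((r, row_fill[r] - 1))
                yield from build(filled, row_fill)
                filled.pop()
                row_fill[r] -= 1

    tabs = list(build([], [0] * len(p)))
    # last-letter order: compare row sequences of the largest entries first
    tabs.sort(key=lambda t: tuple(t[m][0] for m in range(n - 1, -1, -1)))
    return tabs


class Irrep:
    """Young's orthogonal representation for one partition of N."""

    def __init__(self, partition: Sequence[int]):
        self.partition = _validate_partition(partition)
        self.n = sum(self.partition)
        self.tableaux = standard_tableaux(self.partition)
        self.dimension = len(self.tableaux)
        assert self.dimension == hook_dimension(self.partition)
        self.generator_matrices = self._build_generators()
        self._cache: dict[Permutation, np.ndarray] = {}
        self._cache_bound = 50_000

    def _build_generators(self) -> list[np.ndarray]:
        """Orthogonal involutions for the adjacent transpositions (i, i+1)."""
        dim = self.dimension
        index = {t: j for j, t in enumerate(self.tableaux)}
        gens = []
        for i in range(1, self.n):  # transposition (i, i+1)
            m = np.zeros((dim, dim))
            for j, tab in enumerate(self.tableaux):
                r1, c1 = tab[i - 1]
                r2, c2 = tab[i]
                # signed axial distance from the cell of i to the cell of i+1
                d = (c2 - r2) - (c1 - r1)
                m[j, j] = 1.0 / d
                swapped = list(tab)
                swapped[i - 1], swapped[i] = swapped[i], swapped[i - 1]
                other = index.get(tuple(swapped))
                if other is not None:
                    m[j, other] = math.sqrt(1.0 - 1.0 / d**2)
            gens.append(m)
        return gens

    def matrix(self, sigma: Permutation) -> np.ndarray:
        if sigma.degree != self.n:
            raise ValueError("permutation degree does not match partition size")
        cached = self._cache.get(sigma)
        if cached is not None:
            return cached
        word = _adjacent_word(sigma)
        m = np.eye(self.dimension)
        for i in word:
            m = m @ self.generator_matrices[i - 1]
        if len(self._cache) >= self._cache_bound:
            self._cache.clear()
        self._cache[sigma] = m
        m.setflags(write=False)
        return m


@lru_cache(maxsize=None)
def irrep(partition: Partition) -> Irrep:
    return Irrep(partition)


def _adjacent_word(sigma: Permutation) -> list[int]:
    """Indices i so that sigma = s_{i_1} s_{i_2} ... s_{i_m} (adjacent swaps).

    Bubble-sorting the one-line form by swapping positions (j, j+1)
    multiplies sigma on the right by s_j; reversing the recorded swaps
    yields a left-to-right word for sigma itself.
    """
    imgs = list(sigma.images)
    swaps: list[int] = []
    changed = True
    while changed:
        changed = False
        for j in range(len(imgs) - 1):
            if imgs[j] > imgs[j + 1]:
                imgs[j], imgs[j + 1] = imgs[j + 1], imgs[j]
                swaps.append(j + 1)
                changed = True
    return swaps[::-1]


def irrep_matrix(partition: Sequence[int], sigma: Permutation) -> np.ndarray:
    """Orthogonal matrix of ``sigma`` in the irrep indexed by ``partition``."""
    return irrep(_validate_partition(partition)).matrix(sigma)


def algebra_rep(partition: Sequence[int], tau: AlgebraElement) -> np.ndarray:
    """Linear extension of the irrep to a group-algebra element."""
    rep = irrep(_validate_partition(partition))
    if tau.degree != rep.n:
        raise ValueError("degree mismatch")
    out = np.zeros((rep.dimension, rep.dimension))
    for perm, coeff in tau.terms.items():
        out += float(coeff) * rep.matrix(perm)
    return out


def character(partition: Sequence[int], arg: Permutation | AlgebraElement) -> float:
    if isinstance(arg, Permutation):
        return float(np.trace(irrep_matrix(partition, arg)))
    return float(np.trace(algebra_rep(partition, arg)))
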