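"""Permutations of {1..N}, symmetry subgroups, cosets and sparse group-algebra elements.

Conventions used throughout the package:

* permutations are 1-based: ``images[i-1] = sigma(i)`` means region ``i``
  sits in position ``sigma(i)``;
* composition is function composition, ``(p * q)(i) = p(q(i))``, so a
  rearrangement ``a`` acts on a genome ``sigma`` by left multiplication
  ``a * sigma``;
* group-algebra coefficients are kept as exact :class:`~fractions.Fraction`
  values whenever the inputs are rational.
"""

from __future__ import annotations

import itertools
import math
import re
from fractions import Fraction
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "Permutation",
    "SymmetrySubgroup",
    "AlgebraElement",
    "compose",
    "dihedral_group",
    "rotation_group",
    "reflection_group",
    "trivial_group",
    "subgroup_closure",
    "coset_canonical",
    "double_coset_canonical",
    "double_coset_equal",
    "generates_full_group",
]

_CYCLE_RE = re.compile(r"\(([^()]*)\)")


class Permutation:
    """An immutable bijection of ``{1, ..., N}`` in one-line notation."""

    __slots__ = ("images",)

    def __init__(self, images: Sequence[int]):
        imgs = tuple(int(i) for i in images)
        n = len(imgs)
        if sorted(imgs) != list(range(1, n + 1)):
            raise ValueError(f"not a bijection of 1..{n}: {imgs}")
        object.__setattr__(self, "images", imgs)

    # -- construction ---------------------------------------------------
    @classmethod
    def identity(cls, n: int) -> "Permutation":
        return cls(range(1, n + 1))

    @classmethod
    def from_cycles(cls, cycles: Iterable[Sequence[int]], n: int) -> "Permutation":
        images = list(range(1, n + 1))
        for cyc in cycles:
            cyc = [int(c) for c in cyc]
            if any(c < 1 or c > n for c in cyc):
                raise ValueError(f"cycle entry out of range 1..{n}: {cyc}")
            if len(set(cyc)) != len(cyc):
                raise ValueError(f"repeated entry in cycle {cyc}")
            for a, b in zip(cyc, cyc[1:] + cyc[:1]):
                images[a - 1] = b
        # the per-cycle assignment can only break bijectivity if cycles overlap
        if sorted(images) != list(range(1, n + 1)):
            raise ValueError("overlapping cycles")
        return cls(images)

    @classmethod
    def parse(cls, text: str, n: int | None = None) -> "Permutation":
        """Parse one-line (``"2 1 3"``) or cycle (``"(1 2)(3 4)"``) notation.

        For cycle notation the degree ``n`` defaults to the largest moved
        point; for one-line notation ``n`` is implied by the entry count.
        """
        text = text.strip()
        if text.startswith("("):
            body = text.replace(",", " ")
            cycles = []
            leftover = _CYCLE_RE.sub("", body).strip()
            if leftover:
                raise ValueError(f"malformed cycle notation: {text!r}")
            for grp in _CYCLE_RE.findall(body):
                entries = [int(t) for t in grp.split()]
                if entries:
                    cycles.append(entries)
            if n is None:
                n = max((max(c) for c in cycles), default=1)
            return cls.from_cycles(cycles, n)
        if text in ("e", "()"):
            if n is None:
                raise ValueError("degree required to parse the identity")
            return cls.identity(n)
        entries = [int(t) for t in text.replace(",", " ").split()]
        if n is not None and len(entries) != n:
            raise ValueError(f"expected {n} entries, got {len(entries)}")
        return cls(entries)

    # -- group structure ------------------------------------------------
    @property
    def degree(self) -> int:
        return len(self.images)

    def __call__(self, i: int) -> int:
        return self.images[i - 1]

    def __mul__(self, other: "Permutation") -> "Permutation":
        if self.degree != other.degree:
            raise ValueError(
                f"degree mismatch: {self.degree} vs {other.degree}"
            )
        oi = other.images
        si = self.images
        return Permutation([si[j - 1] for j in oi])

    def inverse(self) -> "Permutation":
        inv = [0] * self.degree
        for i, j in enumerate(self.images, start=1):
            inv[j - 1] = i
        return Permutation(inv)

    def is_identity(self) -> bool:
        return all(j == i for i, j in enumerate(self.images, start=1))

    def cycles(self, include_fixed: bool = False) -> list[tuple[int, ...]]:
        seen = [False] * self.degree
        out = []
        for start in range(1, self.degree + 1):
            if seen[start - 1]:
                continue
            cyc = [start]
            seen[start - 1] = True
            j = self(start)
            while j != start:
                cyc.append(j)
                seen[j - 1] = True
                j = self(j)
            if len(cyc) > 1 or include_fixed:
                out.append(tuple(cyc))
        return out

    def cycle_type(self) -> tuple[int, ...]:
        lens = sorted((len(c) for c in self.cycles(include_fixed=True)), reverse=True)
        return tuple(lens)

    # -- formatting -----------------------------------------------------
    def one_line(self) -> str:
        return " ".join(str(i) for i in self.images)

    def __str__(self) -> str:
        cyc = self.cycles()
        if not cyc:
            return "e"
        return "".join("(" + " ".join(map(str, c)) + ")" for c in cyc)

    def __repr__(self) -> str:
        return f"Permutation([{self.one_line()}])"

    # -- ordering / hashing ---------------------------------------------
    def __eq__(self, other) -> bool:
        return isinstance(other, Permutation) and self.images == other.images

    def __lt__(self, other: "Permutation") -> bool:
        return self.images < other.images

    def __le__(self, other: "Permutation") -> bool:
        return self.images <= other.images

    def __hash__(self) -> int:
        return hash(self.images)


def compose(p: Permutation, q: Permutation) -> Permutation:
    """Function composition ``(p o q)(i) = p(q(i))``."""
    return p * q


class SymmetrySubgroup:
    """A subgroup of S_N given by generators, with its full element list."""

    def __init__(self, degree: int, generators: Sequence[Permutation], name: str = ""):
        self.degree = degree
        self.generators = tuple(generators)
        for g in self.generators:
            if g.degree != degree:
                raise ValueError("generator degree mismatch")
        self.elements = _closure(degree, self.generators)
        self._element_set = frozenset(self.elements)
        self.name = name

    @property
    def order(self) -> int:
        return len(self.elements)

    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self) -> Iterator[Permutation]:
        return iter(self.elements)

    def __contains__(self, sigma: Permutation) -> bool:
        return sigma in self._element_set

    def __repr__(self) -> str:
        label = self.name or "subgroup"
        return f"<{label} of S_{self.degree}, order {self.order}>"


def _closure(degree: int, generators: Sequence[Permutation]) -> tuple[Permutation, ...]:
    e = Permutation.identity(degree)
    seen = {e}
    frontier = [e]
    while frontier:
        nxt = []
        for x in frontier:
            for g in generators:
                y = g * x
                if y not in seen:
                    seen.add(y)
                    nxt.append(y)
        frontier = nxt
    return tuple(sorted(seen))


def rotation_permutation(n: int) -> Permutation:
    """The single-step rotation r = (1 2 ... N)."""
    return Permutation.from_cycles([list(range(1, n + 1))], n)


def reflection_permutation(n: int) -> Permutation:
    """The position-reversal reflection f(i) = N + 1 - i."""
    return Permutation([n + 1 - i for i in range(1, n + 1)])


def dihedral_group(n: int) -> SymmetrySubgroup:
    """The 2N-element dihedral group generated by rotation and reflection."""
    if n < 3:
        raise ValueError("dihedral symmetry needs N >= 3")
    z = SymmetrySubgroup(
        n, [rotation_permutation(n), reflection_permutation(n)], name=f"D_{n}"
    )
    assert z.order == 2 * n
    return z


def rotation_group(n: int) -> SymmetrySubgroup:
    """The cyclic rotation subgroup of order N."""
    return SymmetrySubgroup(n, [rotation_permutation(n)], name=f"C_{n}")


def reflection_group(n: int) -> SymmetrySubgroup:
    """The two-element subgroup {e, f} for a single reflection."""
    return SymmetrySubgroup(n, [reflection_permutation(n)], name="{e,f}")


def trivial_group(n: int) -> SymmetrySubgroup:
    return SymmetrySubgroup(n, [], name="{e}")


def subgroup_closure(n: int, generators: Sequence[Permutation]) -> SymmetrySubgroup:
    """Closure of an arbitrary generating set; ``[]`` gives the trivial group."""
    return SymmetrySubgroup(n, generators)


def coset_canonical(sigma: Permutation, z: SymmetrySubgroup) -> Permutation:
    """Lexicographically smallest element of the right coset ``{d sigma : d in Z}``."""
    if sigma.degree != z.degree:
        raise ValueError("degree mismatch")
    return min(d * sigma for d in z.elements)


def double_coset_canonical(sigma: Permutation, z: SymmetrySubgroup) -> Permutation:
    """Lex-min element of the double coset ``{z1 sigma z2}``."""
    return min(min(d1 * sigma * d2 for d2 in z.elements) for d1 in z.elements)


def double_coset_equal(sigma: Permutation, tau: Permutation, z: SymmetrySubgroup) -> bool:
    """True iff ``tau = z1 sigma z2`` for some ``z1, z2 in Z``."""
    if sigma.degree != tau.degree:
        raise ValueError("degree mismatch")
    sigma_inv = sigma.inverse()
    # tau = z1 sigma z2  <=>  sigma^{-1} z1^{-1} tau in Z for some z1
    return any(sigma_inv * d * tau in z for d in z.elements)


def generates_full_group(gens: Sequence[Permutation], n: int) -> bool:
    """True iff the closure of ``gens`` is all of S_N (order count)."""
    if any(g.degree != n for g in gens):
        raise ValueError("generator degree mismatch")
    if n > 9:
        raise ValueError("order-count check limited to N <= 9")
    return len(_closure(n, tuple(gens))) == math.factorial(n)


class AlgebraElement:
    """A sparse formal linear combination of permutations of fixed degree.

    The product is the bilinear extension of group multiplication.  Zero
    coefficients are dropped eagerly so equality of elements is equality
    of the stored term maps.
    """

    __slots__ = ("degree", "terms")

    def __init__(self, degree: int, terms: Mapping[Permutation, Fraction | float] | None = None):
        self.degree = degree
        clean: dict[Permutation, Fraction | float] = {}
        if terms:
            for perm, coeff in terms.items():
                if perm.degree != degree:
                    raise ValueError("term degree mismatch")
                if coeff != 0:
                    clean[perm] = coeff
        self.terms = clean

    @classmethod
    def from_permutation(cls, perm: Permutation, coeff: Fraction | float = Fraction(1)) -> "AlgebraElement":
        return cls(perm.degree, {perm: coeff})

    @classmethod
    def uniform(cls, perms: Iterable[Permutation], degree: int) -> "AlgebraElement":
        perms = list(perms)
        w = Fraction(1, len(perms))
        return cls(degree, {p: w for p in perms})

    def coefficient(self, perm: Permutation) -> Fraction | float:
        return self.terms.get(perm, Fraction(0))

    def coefficient_sum(self):
        return sum(self.terms.values(), Fraction(0))

    def support(self) -> set[Permutation]:
        return set(self.terms)

    # -- linear structure ------------------------------------------------
    def __add__(self, other: "AlgebraElement") -> "AlgebraElement":
        if self.degree != other.degree:
            raise ValueError("degree mismatch")
        out = dict(self.terms)
        for perm, coeff in other.terms.items():
            out[perm] = out.get(perm, 0) + coeff
        return AlgebraElement(self.degree, out)

    def __sub__(self, other: "AlgebraElement") -> "AlgebraElement":
        return self + (-1) * other

    def __rmul__(self, scalar) -> "AlgebraElement":
        return AlgebraElement(
            self.degree, {perm: scalar * coeff for perm, coeff in self.terms.items()}
        )

    # -- algebra product -------------------------------------------------
    def __mul__(self, other) -> "AlgebraElement":
        if isinstance(other, Permutation):
            other = AlgebraElement.from_permutation(other)
        if not isinstance(other, AlgebraElement):
            return NotImplemented
        if self.degree != other.degree:
            raise ValueError("degree mismatch")
        out: dict[Permutation, Fraction | float] = {}
        for p, cp in self.terms.items():
            for q, cq in other.terms.items():
                pq = p * q
                out[pq] = out.get(pq, 0) + cp * cq
        return AlgebraElement(self.degree, out)

    def __pow__(self, k: int) -> "AlgebraElement":
        if k < 0:
            raise ValueError("negative powers are not defined in the algebra")
        result = AlgebraElement.from_permutation(Permutation.identity(self.degree))
        base = self
        while k:
            if k & 1:
                result = result * base
            k >>= 1
            if k:
                base = base * base
        return result

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, AlgebraElement)
            and self.degree == other.degree
            and self.terms == other.terms
        )

    def __hash__(self):
        return hash((self.degree, frozenset(self.terms.items())))

    def __repr__(self) -> str:
        if not self.terms:
            return "0"
        bits = [f"{coeff}*{perm}" for perm, coeff in sorted(self.terms.items())]
        return " + ".join(bits)
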