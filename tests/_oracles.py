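"""Independent brute-force oracles shared by the test modules.

These enumerate rearrangement sequences directly and never touch the
spectral or Markov-matrix code paths they are used to validate.
"""

import itertools
from fractions import Fraction

from genomealg.perm import Permutation


def brute_force_beta(ms, sigma, k):
    """Exact beta_k by enumerating all |M|^k rearrangement sequences."""
    total = Fraction(0)
    items = list(ms.expanded.items())
    for seq in itertools.product(items, repeat=k):
        prod = Permutation.identity(ms.n)
        w = Fraction(1)
        for a, wa in seq:
            prod = a * prod
            w *= wa
        if prod == sigma:
            total += w
    return total


def brute_force_alpha(ms, sigma, k):
    """alpha_k = sum of beta_k over the coset of sigma."""
    return sum(
        (brute_force_beta(ms, d * sigma, k) for d in ms.z.elements), Fraction(0)
    )
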