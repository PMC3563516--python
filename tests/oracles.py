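"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths they verify: the folding oracle
enumerates every legal secondary structure recursively and scores it with
the model's energy definition; the count-test oracle sums the conditional
mass function with exact rational arithmetic.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

from bovmir.folding import INF, MIN_LOOP, pair_energy, structure_energy


def enumerate_structures(seq: str):
    """Yield every pseudoknot-free pair set legal under the model."""
    n = len(seq)

    def rec(positions):
        if not positions:
            yield frozenset()
            return
        i = positions[0]
        rest = positions[1:]
        for sub in rec(rest):  # i unpaired
            yield sub
        for j in rest:
            if j - i - 1 < MIN_LOOP or pair_energy(seq[i], seq[j]) >= INF / 2:
                continue
            inside = tuple(k for k in rest if i < k < j)
            outside = tuple(k for k in rest if k > j)
            for sub_in in rec(inside):
                for sub_out in rec(outside):
                    yield sub_in | sub_out | {(i, j)}

    yield from rec(tuple(range(n)))


def brute_force_mfe(seq: str) -> float:
    """Minimum of the model energy over all structures (open chain = 0)."""
    best = 0.0
    for pairs in enumerate_structures(seq):
        if not pairs:
            continue
        energy = structure_energy(seq, set(pairs))
        if energy < best:
            best = energy
    return best


def exact_conditional_pmf(k: int, x: int, n1: int, n2: int) -> Fraction:
    """p(k | x) of the conditional count distribution, exactly."""
    r = Fraction(n2, n1)
    return r**k * comb(x + k, k) / (1 + r) ** (x + k + 1)


def exact_two_sided_p(x: int, y: int, n1: int, n2: int) -> Fraction:
    """Two-sided p = 2*min(C, D) capped at 1, in exact arithmetic."""
    c = sum(exact_conditional_pmf(k, x, n1, n2) for k in range(y + 1))
    d = 1 - (c - exact_conditional_pmf(y, x, n1, n2))
    return min(Fraction(1), 2 * min(c, d))
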