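"""Independent brute-force oracles used by the tests.

Exact rational hypergeometric upper tail by direct enumeration of the
probability mass function from binomial coefficients, and a naive
one-read-at-a-time weighted counter.  Both are deliberately written
without reference to the package's implementations.
"""

from fractions import Fraction
from math import comb


def hypergeom_upper_tail_exact(k: int, size_a: int, size_b: int, n: int) -> Fraction:
    """P(X >= k), X = |draw of size_b from n, intersected with size_a|."""
    total = comb(n, size_b)
    acc = Fraction(0)
    for x in range(k, min(size_a, size_b) + 1):
        acc += Fraction(comb(size_a, x) * comb(n - size_a, size_b - x), total)
    return acc


def naive_weighted_counts(records) -> dict:
    """One read at a time: (transcript, sample) -> accumulated weight.

    ``records`` is an iterable of (read_id, sample_id, candidate_list).
    """
    acc: dict = {}
    for _read, sample, cands in records:
        w = Fraction(1, len(cands))
        for t in cands:
            acc[(t, sample)] = acc.get((t, sample), Fraction(0)) + w
    return acc
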