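"""Pairwise overlap of aligned gene sets.

For two treatment-effect gene sets drawn from a common background of
expressed genes: overlap size, direction concordance (both up, both down,
oppositely regulated), the representation factor

    RF = k * N / (|A| * |B|)

(observed overlap over the overlap expected under independence), and the
upper-tail hypergeometric probability of an overlap at least as large
(equivalently a one-sided Fisher exact test).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom


def representation_factor(k: int, size_a: int, size_b: int, n: int) -> float:
    """Observed over expected overlap; 0 when either set is empty."""
    if n == 0:
        raise ValueError("background size N must be positive")
    if n < max(size_a, size_b):
        raise ValueError("background smaller than a set")
    if size_a == 0 or size_b == 0:
        return 0.0
    return k * n / (size_a * size_b)


def hypergeometric_tail(k: int, size_a: int, size_b: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N=n, K=size_a, draws=size_b)."""
    if not (0 <= k <= min(size_a, size_b) <= n):
        raise ValueError(
            f"inconsistent sizes: k={k}, |A|={size_a}, |B|={size_b}, N={n}"
        )
    return float(hypergeom.sf(k - 1, n, size_a, size_b))


@dataclass(frozen=True)
class OverlapResult:
    """Overlap statistics for one effect pair (e.g. aging vs CR)."""

    name_a: str
    name_b: str
    background_size: int
    size_a: int
    size_b: int
    overlap: int
    both_up: int
    both_down: int
    opposite: int
    representation_factor: float
    p_value: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def compare_alignments(
    a: pd.DataFrame,
    b: pd.DataFrame,
    background: list[str],
    name_a: str = "A",
    name_b: str = "B",
) -> OverlapResult:
    """Compare two per-gene alignment tables (columns aligned, direction).

    ``background`` is the universe of genes that could have been aligned
    in both analyses (genes passing the expression filter in both); both
    aligned sets must be subsets of it.
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background")
    set_a = set(a.index[a["aligned"]]) & bg
    set_b = set(b.index[b["aligned"]]) & bg
    if len(set_a) != int(a["aligned"].sum()) or len(set_b) != int(b["aligned"].sum()):
        raise ValueError("aligned genes fall outside the background universe")

    common = sorted(set_a & set_b)
    dir_a = a.loc[common, "direction"]
    dir_b = b.loc[common, "direction"]
    both_up = int(((dir_a == "up") & (dir_b == "up")).sum())
    both_down = int(((dir_a == "down") & (dir_b == "down")).sum())
    opposite = len(common) - both_up - both_down

    k, na, nb, n = len(common), len(set_a), len(set_b), len(bg)
    return OverlapResult(
        name_a=name_a,
        name_b=name_b,
        background_size=n,
        size_a=na,
        size_b=nb,
        overlap=k,
        both_up=both_up,
        both_down=both_down,
        opposite=opposite,
        representation_factor=representation_factor(k, na, nb, n),
        p_value=hypergeometric_tail(k, na, nb, n),
    )
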