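"""Local gene-set enrichment over user-supplied GMT annotations.

One-sided Fisher exact enrichment of a query gene set against a
background, per term.  The default "modified" Fisher follows the EASE
convention: the observed overlap is decremented by one before taking the
upper tail, a conservative penalty against single-gene overlaps (an
overlap of 0 or 1 always yields p = 1).  No multiple-testing correction
by default; Benjamini-Hochberg adjusted p-values are available behind a
flag.
"""

from __future__ import annotations

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


def enrich(
    query: set[str] | list[str],
    background: list[str],
    library: dict[str, set[str]],
    alpha: float = 0.01,
    ease: bool = True,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Per-term one-sided (modified) Fisher enrichment.

    library maps term id -> member genes; members are intersected with
    the background before testing.  Returns a table sorted by ascending
    p (ties by term id) with columns overlap, set_size, query_size,
    background_size, p_value, enriched (p < alpha) and optionally
    p_adjusted.
    """
    bg = set(background)
    q = set(query)
    if not q <= bg:
        outside = sorted(q - bg)[:5]
        raise ValueError(f"query genes outside background: {outside}")
    n = len(bg)
    nq = len(q)
    rows = []
    for term, members in library.items():
        in_bg = set(members) & bg
        k = len(in_bg & q)
        k_eff = max(k - 1, 0) if ease else k
        # P(X >= k_eff), X ~ Hypergeom(N=n, K=|term in bg|, draws=|query|)
        p = float(hypergeom.sf(k_eff - 1, n, len(in_bg), nq)) if len(in_bg) else 1.0
        rows.append(
            {
                "term": term,
                "overlap": k,
                "set_size": len(in_bg),
                "query_size": nq,
                "background_size": n,
                "p_value": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows).sort_values(
        ["p_value", "term"], kind="stable", ignore_index=True
    )
    if bh_adjust and len(out):
        out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["enriched"] = out["p_value"] < alpha
    return out


def top_terms(res: pd.DataFrame, n: int = 10) -> pd.DataFrame:
    """First n rows of the p-sorted enrichment table (all rows when fewer)."""
    ordered = res.sort_values(["p_value", "term"], kind="stable", ignore_index=True)
    return ordered.head(n)
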