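"""Fold-change profile clustering.

Genes aligned to any condition PC are assembled into a profile matrix of
per-muscle log2 fold changes (columns ordered muscle-major, then
contrast) and clustered agglomeratively on Euclidean distances between
those changes.  The tree is cut to k clusters (default 8); ``select_k``
picks k by maximizing the mean silhouette width over tree cuts.

Default linkage is Ward's minimum-variance criterion, the standard
pairing for Euclidean profile clustering: complete and average linkage
are also supported but are sensitive to single outlier profiles, which
inflate the silhouette at large k by splitting off near-singleton
clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.metrics import silhouette_score

from .synthetic import MUSCLES


def build_profiles(
    lfc: dict[str, pd.DataFrame],
    alignments: list[pd.DataFrame],
) -> pd.DataFrame:
    """Profile matrix for the union of aligned genes.

    lfc maps contrast name -> genes x muscles LFC table; alignments are
    per-comparison alignment tables (column "aligned").  Rows are the
    union of aligned genes across all comparisons; columns are a
    (muscle, contrast) MultiIndex, muscle-major.  A gene aligned anywhere
    must have every LFC column available.
    """
    union: set[str] = set()
    for ga in alignments:
        union |= set(ga.index[ga["aligned"]])
    genes = sorted(union)

    contrasts = list(lfc)
    muscles = [m for m in MUSCLES if all(m in t.columns for t in lfc.values())]
    if not muscles:
        raise ValueError("no muscle column common to all LFC tables")
    cols = pd.MultiIndex.from_tuples(
        [(m, c) for m in muscles for c in contrasts], names=["muscle", "contrast"]
    )
    out = pd.DataFrame(index=genes, columns=cols, dtype=float)
    for c, table in lfc.items():
        missing = union - set(table.index)
        if missing:
            raise ValueError(
                f"LFC table {c!r} lacks aligned gene(s): {sorted(missing)[:5]}"
            )
        for m in muscles:
            out[(m, c)] = table.loc[genes, m].to_numpy()
    out.index.name = "gene_id"
    return out


@dataclass(frozen=True)
class ClusterAssignment:
    labels: pd.Series  # gene -> cluster id in 1..k
    linkage_name: str
    k: int
    merge_tree: np.ndarray = field(repr=False)  # scipy linkage matrix

    def to_newick(self) -> str:
        """Merge tree in nested-parenthesis (Newick) form with heights."""
        tree = hierarchy.to_tree(self.merge_tree)
        leaves = list(self.labels.index)

        def rec(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{leaves[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return rec(tree, tree.dist) + ";"


def _check_profiles(p: pd.DataFrame) -> np.ndarray:
    arr = p.to_numpy(dtype=float)
    if arr.size == 0:
        raise ValueError("empty profile matrix")
    if not np.isfinite(arr).all():
        raise ValueError("profile matrix has non-finite values")
    return arr


def hcluster(
    p: pd.DataFrame, linkage: str = "ward", k: int = 8
) -> ClusterAssignment:
    """Agglomerative clustering on Euclidean distances, cut to exactly k.

    Cluster ids are relabeled 1..k in order of first appearance along the
    input row order, so the assignment is deterministic given the input.
    """
    arr = _check_profiles(p)
    n = arr.shape[0]
    if k < 2 or k > n:
        raise ValueError(f"k={k} out of range 2..{n}")
    z = hierarchy.linkage(arr, method=linkage, metric="euclidean")
    raw = hierarchy.fcluster(z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, c in enumerate(raw):
        if c not in relabel:
            relabel[c] = len(relabel) + 1
        labels[i] = relabel[c]
    return ClusterAssignment(
        labels=pd.Series(labels, index=p.index, name="cluster"),
        linkage_name=linkage,
        k=int(labels.max()),
        merge_tree=z,
    )


def select_k(
    p: pd.DataFrame,
    k_range: range = range(2, 13),
    linkage: str = "ward",
) -> int:
    """Number of clusters maximizing mean silhouette width over tree cuts;
    ties go to the smallest k.  Degenerate all-identical input returns
    min(k_range) with a warning."""
    arr = _check_profiles(p)
    ks = [k for k in k_range if 2 <= k <= arr.shape[0] - 1]
    if not ks:
        raise ValueError("k_range has no feasible value for this matrix")
    if np.allclose(arr, arr[0]):
        warnings.warn("all profiles identical; returning min(k_range)", stacklevel=2)
        return min(ks)
    z = hierarchy.linkage(arr, method=linkage, metric="euclidean")
    best_k, best_s = None, -np.inf
    for k in ks:
        labels = hierarchy.fcluster(z, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        s = silhouette_score(arr, labels, metric="euclidean")
        if s > best_s + 1e-12:
            best_k, best_s = k, s
    if best_k is None:
        warnings.warn("no cut produced >= 2 clusters", stacklevel=2)
        return min(ks)
    return best_k


def cluster_summary(
    ca: ClusterAssignment, p: pd.DataFrame, zero_tol: float = 0.1
) -> pd.DataFrame:
    """Per-cluster mean profile plus an aggregated sign per contrast.

    The sign per contrast is the sign of the cross-muscle mean of the
    cluster's mean LFC, set to 0 when its magnitude is within
    ``zero_tol``.  Returns one row per cluster with columns
    ("size", ""), the (muscle, contrast) means, and ("sign", contrast).
    """
    rows = []
    contrasts = list(p.columns.get_level_values("contrast").unique())
    for cid in range(1, ca.k + 1):
        members = p.loc[ca.labels[ca.labels == cid].index]
        mean = members.mean(axis=0)
        row: dict = {("size", ""): len(members)}
        row.update({col: mean[col] for col in p.columns})
        for c in contrasts:
            v = float(mean.xs(c, level="contrast").mean())
            row[("sign", c)] = 0 if abs(v) <= zero_tol else int(np.sign(v))
        rows.append(row)
    out = pd.DataFrame(rows, index=pd.RangeIndex(1, ca.k + 1, name="cluster"))
    out.columns = pd.MultiIndex.from_tuples(out.columns)
    return out
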