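"""Gene-principal-component alignment: the pipeline's core statistic.

For a pairwise comparison of two treatment groups across all four muscles,
the log2(TPM + 1) gene x sample matrix is mean-centered (rows, columns,
or both), decomposed by PCA, and the "condition PC" is identified as the
component whose sample coordinates separate the two groups consistently
in every muscle (the separation score is the minimum across muscles of
the absolute standardized mean difference, Cohen's d, of the coordinates).
Because a handful of dominant components capture inter-muscle expression
differences, the condition PC typically lands at rank 3 or 4.

Each gene is then scored against the oriented condition PC:

* projection — inner product of the gene's centered sample profile with
  the unit PC coordinate vector,
* z — the projection standardized over all genes,
* r — Pearson correlation of the gene profile with the PC coordinates.

A gene is "aligned" when |z| >= 1.96 and |r| >= 0.4; its direction is up
(higher in group B) or down according to the sign of the projection.

The module exposes both the individual operations and a statsmodels-style
``PCAlignment`` model whose ``fit()`` returns ``PCAlignmentResults``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import MUSCLES, StudyDesign
from . import quantify

Z_THRESHOLD = 1.96
R_THRESHOLD = 0.4
LOG_PSEUDO = 1.0


def center(logexpr: pd.DataFrame, mode: str = "both") -> pd.DataFrame:
    """Mean-center a genes x samples matrix.

    mode "gene" subtracts row means, "sample" subtracts column means,
    "both" subtracts row means then column means (double centering; both
    row and column means end at zero, and the operation is idempotent).
    """
    if logexpr.isna().any().any():
        raise ValueError("matrix contains missing values")
    x = logexpr.astype(float)
    if float(x.to_numpy().std()) == 0.0:
        warnings.warn("centering a constant matrix", stacklevel=2)
    if mode == "gene":
        return x.sub(x.mean(axis=1), axis=0)
    if mode == "sample":
        return x.sub(x.mean(axis=0), axis=1)
    if mode == "both":
        x = x.sub(x.mean(axis=1), axis=0)
        return x.sub(x.mean(axis=0), axis=1)
    raise ValueError(f"unknown centering mode {mode!r}")


@dataclass(frozen=True)
class PCModel:
    """PCA of a centered genes x samples matrix.

    coordinates: samples x components, unit-norm columns (directions in
    sample space); gene_directions: genes x components, unit-norm columns;
    variance_fractions: fraction of total variance per component,
    nonincreasing.  Component sign fixed so the largest-magnitude sample
    coordinate is positive.
    """

    coordinates: pd.DataFrame
    gene_directions: pd.DataFrame
    variance_fractions: pd.Series
    singular_values: pd.Series

    @property
    def n_components(self) -> int:
        return self.coordinates.shape[1]


def fit_pca(x: pd.DataFrame) -> PCModel:
    """PCA via singular value decomposition of the centered matrix."""
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 genes and 2 samples")
    arr = x.to_numpy(dtype=float)
    u, s, vt = np.linalg.svd(arr, full_matrices=False)
    if not np.any(s > 0):
        raise ValueError("rank-0 input matrix")
    # deterministic sign: largest |coordinate| entry positive, per component
    for k in range(len(s)):
        i = int(np.argmax(np.abs(vt[k])))
        if vt[k, i] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    labels = [f"PC{k + 1}" for k in range(len(s))]
    total = float((s**2).sum())
    return PCModel(
        coordinates=pd.DataFrame(vt.T, index=x.columns, columns=labels),
        gene_directions=pd.DataFrame(u, index=x.index, columns=labels),
        variance_fractions=pd.Series(s**2 / total, index=labels),
        singular_values=pd.Series(s, index=labels),
    )


@dataclass(frozen=True)
class ConditionPC:
    """The PC chosen to represent a between-group treatment effect."""

    comparison: tuple[str, str]  # (groupA, groupB)
    pc_index: int  # 1-based
    orientation: int  # +1/-1; positive coordinate => higher in groupB
    separation_scores: pd.Series  # per searched PC: min-over-muscles |d|
    low_confidence: bool

    @property
    def label(self) -> str:
        return f"PC{self.pc_index}"

    def oriented_coordinates(self, model: PCModel) -> pd.Series:
        return self.orientation * model.coordinates[self.label]


def _cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    diff = b.mean() - a.mean()
    if pooled == 0:
        return 0.0 if diff == 0 else np.sign(diff) * np.inf
    return float(diff / pooled)


def find_condition_pc(
    model: PCModel,
    design: StudyDesign,
    comparison: tuple[str, str],
    search_depth: int = 6,
) -> ConditionPC:
    """Pick the PC whose coordinates separate the two groups in every
    muscle: argmax over the first ``search_depth`` PCs of
    min-over-muscles |Cohen's d|; ties go to the smaller index.

    Orientation is set so group B's mean coordinate exceeds group A's.
    A run where no PC reaches separation 1 is flagged low-confidence.
    """
    group_a, group_b = comparison
    depth = min(search_depth, model.n_components)
    muscles = [m for m in MUSCLES if m in set(design.table["muscle"])]
    scores = {}
    for k in range(1, depth + 1):
        coord = model.coordinates[f"PC{k}"]
        per_muscle = []
        for m in muscles:
            ids_a = [s for s in design.samples_of(group_a, m) if s in coord.index]
            ids_b = [s for s in design.samples_of(group_b, m) if s in coord.index]
            if not ids_a or not ids_b:
                raise ValueError(f"muscle {m!r} lacks samples for {comparison}")
            per_muscle.append(
                abs(_cohens_d(coord[ids_a].to_numpy(), coord[ids_b].to_numpy()))
            )
        scores[f"PC{k}"] = min(per_muscle)
    scores = pd.Series(scores)
    best = int(np.argmax(scores.to_numpy())) + 1  # ties -> smaller index

    coord = model.coordinates[f"PC{best}"]
    ids_a = [s for s in design.samples_of(group_a) if s in coord.index]
    ids_b = [s for s in design.samples_of(group_b) if s in coord.index]
    orientation = 1 if coord[ids_b].mean() >= coord[ids_a].mean() else -1
    return ConditionPC(
        comparison=(group_a, group_b),
        pc_index=best,
        orientation=orientation,
        separation_scores=scores,
        low_confidence=bool(scores.max() < 1.0),
    )


def align_genes(
    x: pd.DataFrame,
    model: PCModel,
    cpc: ConditionPC,
    z_threshold: float = Z_THRESHOLD,
    r_threshold: float = R_THRESHOLD,
) -> pd.DataFrame:
    """Score every gene against the oriented condition PC.

    Returns a DataFrame indexed by gene with columns projection, z, r,
    aligned (bool) and direction ("up"/"down"/"none"; up = higher in
    group B).  Zero-variance genes get r = 0 and are never aligned.
    """
    if list(x.columns) != list(model.coordinates.index):
        x = x[model.coordinates.index]
    v = cpc.oriented_coordinates(model).to_numpy()
    arr = x.to_numpy(dtype=float)

    proj = arr @ v
    sd = proj.std()
    z = (proj - proj.mean()) / sd if sd > 0 else np.zeros_like(proj)

    gc = arr - arr.mean(axis=1, keepdims=True)
    vc = v - v.mean()
    denom = np.linalg.norm(gc, axis=1) * np.linalg.norm(vc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, gc @ vc / denom, 0.0)

    aligned = (np.abs(z) >= z_threshold) & (np.abs(r) >= r_threshold)
    direction = np.where(aligned, np.where(proj > 0, "up", "down"), "none")
    return pd.DataFrame(
        {
            "projection": proj,
            "z": z,
            "r": r,
            "aligned": aligned,
            "direction": direction,
        },
        index=x.index,
    )


@dataclass(frozen=True)
class AlignmentSummary:
    n_aligned: int
    n_up: int
    n_down: int
    variance_fraction: float


def alignment_summary(
    ga: pd.DataFrame, model: PCModel, cpc: ConditionPC
) -> AlignmentSummary:
    """Counts of aligned/up/down genes plus the condition PC's variance
    fraction (the numbers annotated on each comparison's PC panel)."""
    n_up = int((ga["direction"] == "up").sum())
    n_down = int((ga["direction"] == "down").sum())
    return AlignmentSummary(
        n_aligned=int(ga["aligned"].sum()),
        n_up=n_up,
        n_down=n_down,
        variance_fraction=float(model.variance_fractions[cpc.label]),
    )


class PCAlignment:
    """Model: gene-PC alignment for one two-group comparison.

    Parameters
    ----------
    log_expr : genes x samples log2(TPM + pseudo) matrix covering exactly
        the samples of the two compared groups (all muscles).
    design : StudyDesign restricted to (or at least covering) those samples.
    comparison : (groupA, groupB); orientation "up" means higher in groupB.
    center_mode : "gene", "sample" or "both" (default).

    Examples
    --------
    >>> res = PCAlignment(logtpm, design, ("30mCON", "30mCR")).fit()
    >>> res.condition_pc.pc_index, res.summary_stats.n_aligned
    """

    def __init__(
        self,
        log_expr: pd.DataFrame,
        design: StudyDesign,
        comparison: tuple[str, str],
        center_mode: str = "both",
    ) -> None:
        sub = design.subset(comparison)
        missing = set(sub.sample_ids) - set(log_expr.columns)
        if missing:
            raise ValueError(f"samples missing from matrix: {sorted(missing)[:5]}")
        self.log_expr = log_expr[sub.sample_ids]
        self.design = sub
        self.comparison = tuple(comparison)
        self.center_mode = center_mode

    @classmethod
    def from_counts(
        cls,
        counts: pd.DataFrame,
        design: StudyDesign,
        comparison: tuple[str, str],
        lengths: pd.Series,
        min_cpm: float = 1.0,
        pseudo: float = LOG_PSEUDO,
        center_mode: str = "both",
    ) -> "PCAlignment":
        """Build from a gene-level count matrix: restrict to the two
        groups, apply the minimum-replicate CPM expression filter, convert
        to TPM with the given per-gene lengths and log2(TPM + pseudo)."""
        sub = design.subset(comparison)
        filtered, _ = quantify.filter_expressed(counts, sub, min_cpm=min_cpm)
        logtpm = np.log2(quantify.tpm(filtered, lengths) + pseudo)
        return cls(logtpm, sub, comparison, center_mode=center_mode)

    def fit(
        self,
        search_depth: int = 6,
        z_threshold: float = Z_THRESHOLD,
        r_threshold: float = R_THRESHOLD,
    ) -> "PCAlignmentResults":
        centered = center(self.log_expr, self.center_mode)
        model = fit_pca(centered)
        cpc = find_condition_pc(model, self.design, self.comparison, search_depth)
        ga = align_genes(centered, model, cpc, z_threshold, r_threshold)
        return PCAlignmentResults(self, centered, model, cpc, ga)


@dataclass(frozen=True)
class PCAlignmentResults:
    """Fitted alignment: PCA model, condition-PC choice, per-gene table."""

    model_spec: PCAlignment = field(repr=False)
    centered: pd.DataFrame = field(repr=False)
    pc_model: PCModel = field(repr=False)
    condition_pc: ConditionPC = field(repr=False)
    alignment: pd.DataFrame = field(repr=False)

    @property
    def summary_stats(self) -> AlignmentSummary:
        return alignment_summary(self.alignment, self.pc_model, self.condition_pc)

    @property
    def aligned_genes(self) -> list[str]:
        return list(self.alignment.index[self.alignment["aligned"]])

    def summary(self) -> str:
        a, b = self.condition_pc.comparison
        st = self.summary_stats
        scores = self.condition_pc.separation_scores
        lines = [
            "Gene-PC alignment",
            "=" * 54,
            f"Comparison:          {a} vs {b} (up = higher in {b})",
            f"Genes x samples:     {self.centered.shape[0]} x {self.centered.shape[1]}",
            f"Condition PC:        {self.condition_pc.label}"
            + ("  [low confidence]" if self.condition_pc.low_confidence else ""),
            f"Variance fraction:   {st.variance_fraction:.3f}",
            f"Aligned genes:       {st.n_aligned} ({st.n_up} up, {st.n_down} down)",
            "",
            "Separation (min over muscles |Cohen's d|):",
        ]
        for label, val in scores.items():
            mark = "  <-- selected" if label == self.condition_pc.label else ""
            lines.append(f"  {label:<5} {val:8.3f}{mark}")
        return "\n".join(lines)
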