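"""Transcript quantification arithmetic.

Weighted multi-mapping read assignment (a read compatible with n
transcripts contributes 1/n to each), TPM computation

    t_i = (c_i / l_i) / sum_j (c_j / l_j) * 1e6,

gene-level aggregation by summation, CPM, the minimum-replicate CPM
expression filter, and pseudo-counted mean-CPM log2 fold changes.

Matrices are pandas DataFrames oriented features x samples.  Fractional
counts from 1/n splitting are kept as reals throughout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic import MUSCLES, StudyDesign


def _candidate_lists(records: pd.DataFrame) -> pd.Series:
    """transcripts column as lists (accepts comma-joined strings or lists)."""
    col = records["transcripts"]
    if len(col) and isinstance(col.iloc[0], str):
        return col.str.split(",")
    return col.apply(list)


def count_weighted(records: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Weighted read assignment: each read splits weight 1 evenly across
    its candidate transcripts (1 for unique reads, 1/n for multi-mappers).

    Parameters
    ----------
    records : DataFrame with columns read_id, sample_id, transcripts
        (comma-separated transcript ids or lists thereof).
    annotation : DataFrame with transcript_id, gene_id, length.

    Returns a transcripts x samples count matrix covering every annotated
    transcript; per-sample column sums equal the read counts exactly.
    """
    known = set(annotation["transcript_id"])
    cands = _candidate_lists(records)
    n = cands.str.len()
    if (n == 0).any():
        bad = records.loc[n == 0, "read_id"].iloc[0]
        raise ValueError(f"read {bad!r} has an empty candidate set")

    flat = records[["read_id", "sample_id"]].copy()
    flat["weight"] = 1.0 / n
    flat["transcript_id"] = cands
    flat = flat.explode("transcript_id", ignore_index=True)
    unknown = ~flat["transcript_id"].isin(known)
    if unknown.any():
        row = flat.loc[unknown].iloc[0]
        raise ValueError(
            f"read {row['read_id']!r} maps to unknown transcript "
            f"{row['transcript_id']!r}"
        )

    mat = (
        flat.pivot_table(
            index="transcript_id",
            columns="sample_id",
            values="weight",
            aggfunc="sum",
            fill_value=0.0,
        )
        .reindex(annotation["transcript_id"], fill_value=0.0)
    )
    mat.index.name = "transcript_id"
    mat.columns.name = None
    return mat


def tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million: length-normalized rates rescaled so every
    sample column sums to 1e6.

    ``lengths`` is indexed by feature id (transcript or gene); an all-zero
    sample column has no defined normalization and raises.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])[:5]
        raise ValueError(f"features missing a length: {missing}")
    if (lengths <= 0).any():
        raise ValueError("lengths must be positive")
    rate = counts.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    zero = denom[denom == 0]
    if len(zero):
        raise ValueError(f"all-zero sample column(s): {list(zero.index)}")
    return rate.div(denom, axis=1) * 1e6


def gene_lengths(annotation: pd.DataFrame) -> pd.Series:
    """Per-gene effective length: mean of the gene's transcript lengths."""
    return annotation.groupby("gene_id")["length"].mean()


def aggregate_genes(x: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Sum transcript-level values (counts or TPM) over each parent gene.

    TPM columns keep their 1e6 total since genes partition transcripts.
    """
    mapping = annotation.set_index("transcript_id")["gene_id"]
    unknown = set(x.index) - set(mapping.index)
    if unknown:
        raise ValueError(f"transcripts absent from annotation: {sorted(unknown)[:5]}")
    out = x.groupby(mapping.reindex(x.index)).sum()
    out.index.name = "gene_id"
    return out


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million: count / library size * 1e6 per sample."""
    lib = counts.sum(axis=0)
    zero = lib[lib == 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    return counts.div(lib, axis=1) * 1e6


def filter_expressed(
    counts: pd.DataFrame,
    design: StudyDesign,
    min_cpm: float = 1.0,
    min_samples: int | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Expression filter: keep a gene iff its CPM reaches ``min_cpm`` in at
    least m samples, m being the smallest group size in the design subset
    under analysis (overridable via ``min_samples``).

    CPM is computed on the unfiltered library (column sums of the full
    matrix).  Returns (filtered counts, kept gene ids).
    """
    if len(design.table) == 0:
        raise ValueError("empty design")
    missing = set(design.sample_ids) - set(counts.columns)
    if missing:
        raise ValueError(f"design samples absent from counts: {sorted(missing)[:5]}")
    sub = counts[design.sample_ids]
    m = design.min_group_size() if min_samples is None else int(min_samples)
    n_ok = (cpm(sub) >= min_cpm).sum(axis=1)
    keep = n_ok >= m
    return sub.loc[keep], list(sub.index[keep])


def _tmm_like_factors(counts: pd.DataFrame, trim: float = 0.3) -> pd.Series:
    """Trimmed-mean normalization factors relative to the gene-wise
    geometric-mean reference (simplified TMM; no weighting)."""
    logc = np.log2(counts.where(counts > 0))
    ref = logc.mean(axis=1)
    factors = {}
    for s in counts.columns:
        ratios = (logc[s] - ref).dropna().sort_values()
        k = int(len(ratios) * trim)
        core = ratios.iloc[k : len(ratios) - k] if len(ratios) > 2 * k else ratios
        factors[s] = float(2 ** core.mean()) if len(core) else 1.0
    f = pd.Series(factors)
    return f / np.exp(np.log(f).mean())  # geometric mean 1


def log_fold_change(
    counts: pd.DataFrame,
    design: StudyDesign,
    contrast: tuple[str, str],
    per_muscle: bool = True,
    pseudo: float = 1.0,
    normalization: str = "library",
) -> pd.DataFrame:
    """Pseudo-counted mean-CPM log2 fold change, groupB over groupA.

    LFC = log2((mean CPM_B + pseudo) / (mean CPM_A + pseudo)), computed
    within each muscle (columns = muscles) or pooled (single column
    "all").  ``normalization`` "library" uses plain CPM; "tmm" divides
    library sizes by trimmed-mean scaling factors first.
    """
    group_a, group_b = contrast
    if normalization == "library":
        expr = cpm(counts)
    elif normalization == "tmm":
        expr = cpm(counts) / _tmm_like_factors(counts)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")

    def one(a_ids: list[str], b_ids: list[str], label: str) -> pd.Series:
        if not a_ids or not b_ids:
            raise ValueError(f"contrast {contrast} has an empty group in {label!r}")
        mean_a = expr[a_ids].mean(axis=1)
        mean_b = expr[b_ids].mean(axis=1)
        return np.log2((mean_b + pseudo) / (mean_a + pseudo))

    cols = {}
    if per_muscle:
        present = set(design.table["muscle"])
        for m in [m for m in MUSCLES if m in present]:
            cols[m] = one(
                [s for s in design.samples_of(group_a, m) if s in expr.columns],
                [s for s in design.samples_of(group_b, m) if s in expr.columns],
                m,
            )
    else:
        cols["all"] = one(
            [s for s in design.samples_of(group_a) if s in expr.columns],
            [s for s in design.samples_of(group_b) if s in expr.columns],
            "all",
        )
    out = pd.DataFrame(cols)
    out.index.name = "gene_id"
    return out
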