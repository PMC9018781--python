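"""File I/O: counts (TSV or MatrixMarket), study designs, transcript
annotations, alignment-record streams and GMT gene-set libraries.

All text readers are gzip-transparent (pandas infers compression from
the ``.gz`` suffix) and validate schemas strictly: duplicated ids,
non-numeric cells and design/matrix mismatches raise descriptive errors.
MatrixMarket matrices use ``<stem>.mtx`` plus ``<stem>.mtx.rows`` /
``<stem>.mtx.cols`` sidecar files with one id per line.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .synthetic import StudyDesign


def _open_text(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_counts(path: str | Path) -> pd.DataFrame:
    """Counts matrix, features x samples.  TSV (first column = feature id)
    or MatrixMarket with .rows/.cols sidecars."""
    path = Path(path)
    if ".mtx" in path.suffixes or path.suffix == ".mtx":
        mat = scipy.io.mmread(path)
        rows = Path(str(path) + ".rows").read_text().split()
        cols = Path(str(path) + ".cols").read_text().split()
        df = pd.DataFrame(
            np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat),
            index=rows,
            columns=cols,
        )
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = sorted(set(df.index[df.index.duplicated()]))[:5]
        raise ValueError(f"duplicated feature ids: {dup}")
    if df.columns.duplicated().any():
        raise ValueError("duplicated sample ids in counts header")
    try:
        df = df.astype(float)
    except ValueError as e:
        raise ValueError(f"non-numeric cell in counts matrix: {e}") from e
    if (df.to_numpy() < 0).any():
        raise ValueError("negative entries in counts matrix")
    return df


def write_counts(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    if ".mtx" in path.suffixes or path.suffix == ".mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.csr_matrix(df.to_numpy()))
        Path(str(path) + ".rows").write_text("\n".join(map(str, df.index)) + "\n")
        Path(str(path) + ".cols").write_text("\n".join(map(str, df.columns)) + "\n")
    else:
        df.to_csv(path, sep="\t")


def read_design(path: str | Path, counts: pd.DataFrame | None = None) -> StudyDesign:
    """Study design CSV (sample_id, muscle, group, replicate); when a
    counts matrix is given, every design sample must be a column."""
    design = StudyDesign(pd.read_csv(path))
    if counts is not None:
        missing = set(design.sample_ids) - set(counts.columns)
        if missing:
            raise ValueError(
                f"design references samples absent from counts: {sorted(missing)[:5]}"
            )
    return design


def write_design(design: StudyDesign, path: str | Path) -> None:
    design.table.to_csv(path, index=False)


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Transcript annotation TSV: transcript_id, gene_id, length."""
    ann = pd.read_csv(path, sep="\t")
    required = {"transcript_id", "gene_id", "length"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"annotation missing columns {sorted(missing)}")
    if ann["transcript_id"].duplicated().any():
        raise ValueError("duplicated transcript ids in annotation")
    if (ann["length"] <= 0).any():
        raise ValueError("non-positive transcript length in annotation")
    return ann


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    ann.to_csv(path, sep="\t", index=False)


def read_alignment_records(path: str | Path) -> pd.DataFrame:
    """Alignment records TSV: read_id TAB sample_id TAB comma-separated
    candidate transcript ids."""
    rec = pd.read_csv(
        path, sep="\t", names=["read_id", "sample_id", "transcripts"], dtype=str
    )
    if rec.isna().any().any():
        raise ValueError("malformed alignment record line (missing field)")
    return rec


def write_alignment_records(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, sep="\t", header=False, index=False)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene-set file: term TAB description TAB gene1 TAB gene2 ...

    Returns term id -> member set; duplicate terms and empty member
    lists raise."""
    library: dict[str, set[str]] = {}
    with _open_text(Path(path)) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {ln}: need term, description, >=1 gene")
            term, _desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ValueError(f"GMT line {ln}: term {term!r} has no members")
            if term in library:
                raise ValueError(f"GMT line {ln}: duplicate term {term!r}")
            library[term] = set(genes)
    return library


def write_gmt(library: dict[str, set[str]], path: str | Path) -> None:
    with _open_text(Path(path), "wt") as fh:
        for term, genes in library.items():
            fh.write("\t".join([term, term] + sorted(genes)) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    with _open_text(Path(path)) as fh:
        return [line.strip() for line in fh if line.strip()]
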