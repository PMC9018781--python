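"""End-to-end workflow: simulate (or load) counts, quantify, filter,
align each pairwise comparison, overlap the effect signatures, cluster
fold-change profiles and (optionally) run gene-set enrichment.

``RunConfig`` carries every stage parameter with the study's defaults
(alignment thresholds z = 1.96 and r = 0.4, 1-CPM expression filter,
enrichment alpha 0.01, eight clusters) and round-trips losslessly through
YAML.  ``run_pipeline`` writes all artifacts plus a machine-readable
summary JSON into a run directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as _cluster
from . import enrich as _enrich
from . import io as _io
from . import quantify, setcompare
from .pcalign import PCAlignment
from .synthetic import (
    SimParams,
    default_archetypes,
    default_design,
    generate_annotation,
    simulate_counts,
)

logger = logging.getLogger("pcsig")

#: comparison name -> (groupA, groupB); "up" means higher in groupB
DEFAULT_COMPARISONS: dict[str, tuple[str, str]] = {
    "aging": ("10mCON", "30mCON"),
    "cr": ("30mCON", "30mCR"),
    "rm": ("30mCON", "30mRM"),
    "cr_vs_rm": ("30mCR", "30mRM"),
}

#: effect pairs compared in the overlap stage
DEFAULT_OVERLAP_PAIRS: list[tuple[str, str]] = [
    ("aging", "cr"),
    ("aging", "rm"),
    ("cr", "rm"),
]

#: contrasts whose per-muscle fold changes form the clustering profiles
#: (all four displayed comparisons, incl. RM-over-CR)
DEFAULT_PROFILE_CONTRASTS: list[str] = ["aging", "cr", "rm", "cr_vs_rm"]


class ConfigError(ValueError):
    """Invalid or unknown configuration."""


@dataclass(frozen=True)
class RunConfig:
    """All pipeline parameters; defaults follow the study throughout."""

    # inputs ("simulate" or paths to counts/design/annotation)
    counts_path: str | None = None
    design_path: str | None = None
    annotation_path: str | None = None
    gmt_path: str | None = None
    simulate: bool = True
    sim: SimParams = field(default_factory=SimParams)
    # alignment thresholds
    z_threshold: float = 1.96
    r_threshold: float = 0.4
    search_depth: int = 6
    center_mode: str = "both"
    log_pseudo: float = 1.0
    # expression filter / fold changes
    min_cpm: float = 1.0
    filter_scope: str = "per_comparison"  # or "all_groups"
    lfc_pseudo: float = 1.0
    normalization: str = "library"
    # clustering
    linkage: str = "ward"
    n_clusters: int = 8
    run_select_k: bool = True
    k_min: int = 2
    k_max: int = 12
    # enrichment
    alpha: float = 0.01
    ease: bool = True
    comparisons: dict[str, tuple[str, str]] = field(
        default_factory=lambda: dict(DEFAULT_COMPARISONS)
    )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = dataclasses.asdict(self.sim)
        d["comparisons"] = {k: list(v) for k, v in self.comparisons.items()}
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        if "sim" in data and not isinstance(data["sim"], SimParams):
            sim_known = {f.name for f in dataclasses.fields(SimParams)}
            sim_unknown = set(data["sim"]) - sim_known
            if sim_unknown:
                raise ConfigError(f"unknown sim key(s): {sorted(sim_unknown)}")
            sim = dict(data["sim"])
            for key in ("transcripts_per_gene", "length_range"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            data["sim"] = SimParams(**sim)
        if "comparisons" in data:
            data["comparisons"] = {
                k: tuple(v) for k, v in data["comparisons"].items()
            }
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(data)


class StageFailure(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _load_inputs(cfg: RunConfig, outdir: Path):
    if cfg.simulate:
        design = default_design()
        annotation = generate_annotation(cfg.sim)
        counts, truth = simulate_counts(
            design, annotation, default_archetypes(), cfg.sim
        )
        _io.write_design(design, outdir / "design.csv")
        _io.write_annotation(annotation, outdir / "annotation.tsv")
        _io.write_counts(counts, outdir / "gene_counts.tsv")
        truth.to_csv(outdir / "truth.tsv", sep="\t")
        return design, annotation, counts, truth
    if not (cfg.counts_path and cfg.design_path and cfg.annotation_path):
        raise ConfigError(
            "simulate=false requires counts_path, design_path and annotation_path"
        )
    counts = _io.read_counts(cfg.counts_path)
    design = _io.read_design(cfg.design_path, counts)
    annotation = _io.read_annotation(cfg.annotation_path)
    return design, annotation, counts, None


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> dict:
    """Run every stage, writing artifacts under ``outdir``.

    Returns the summary dict (also written as summary.json).  Any stage
    failure raises StageFailure naming the stage; artifacts written by
    earlier stages are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"parameters": cfg.to_dict(), "stages": {}}
    stage = "setup"

    def tic(name: str) -> float:
        nonlocal stage
        stage = name
        logger.info("stage %s started", name)
        return time.perf_counter()

    def toc(name: str, t0: float, info: dict | None = None) -> None:
        dt = time.perf_counter() - t0
        logger.info("stage %s done in %.2fs %s", name, dt, info or {})
        if info is not None:
            summary["stages"][name] = info

    try:
        t0 = tic("inputs")
        design, annotation, counts, truth = _load_inputs(cfg, outdir)
        toc(
            "inputs",
            t0,
            {"n_genes": int(counts.shape[0]), "n_samples": int(counts.shape[1])},
        )

        t0 = tic("align")
        lengths = quantify.gene_lengths(annotation)
        results = {}
        kept: dict[str, list[str]] = {}
        align_info: dict = {}
        for name, (ga_group, gb_group) in cfg.comparisons.items():
            sub = design.subset((ga_group, gb_group))
            if cfg.filter_scope == "all_groups":
                filtered, kept_genes = quantify.filter_expressed(
                    counts, design, min_cpm=cfg.min_cpm
                )
                filtered = filtered[sub.sample_ids]
            else:
                filtered, kept_genes = quantify.filter_expressed(
                    counts, sub, min_cpm=cfg.min_cpm
                )
            logtpm = np.log2(quantify.tpm(filtered, lengths) + cfg.log_pseudo)
            model = PCAlignment(
                logtpm, sub, (ga_group, gb_group), center_mode=cfg.center_mode
            )
            res = model.fit(
                search_depth=cfg.search_depth,
                z_threshold=cfg.z_threshold,
                r_threshold=cfg.r_threshold,
            )
            results[name] = res
            kept[name] = kept_genes
            res.alignment.to_csv(outdir / f"alignment_{name}.tsv", sep="\t")
            res.pc_model.coordinates.to_csv(
                outdir / f"pc_coordinates_{name}.tsv", sep="\t"
            )
            st = res.summary_stats
            align_info[name] = {
                "pc_index": res.condition_pc.pc_index,
                "orientation": res.condition_pc.orientation,
                "low_confidence": res.condition_pc.low_confidence,
                "variance_fraction": st.variance_fraction,
                "n_kept_genes": len(kept_genes),
                "n_aligned": st.n_aligned,
                "n_up": st.n_up,
                "n_down": st.n_down,
                "separation_scores": {
                    k: float(v)
                    for k, v in res.condition_pc.separation_scores.items()
                },
            }
            (outdir / f"condition_pc_{name}.json").write_text(
                json.dumps(align_info[name], indent=2)
            )
        toc("align", t0, align_info)

        t0 = tic("compare")
        overlaps = {}
        for a, b in DEFAULT_OVERLAP_PAIRS:
            if a not in results or b not in results:
                continue
            background = sorted(set(kept[a]) & set(kept[b]))
            res = setcompare.compare_alignments(
                results[a].alignment.loc[
                    results[a].alignment.index.intersection(background)
                ],
                results[b].alignment.loc[
                    results[b].alignment.index.intersection(background)
                ],
                background,
                name_a=a,
                name_b=b,
            )
            overlaps[f"{a}_vs_{b}"] = res.to_dict()
        (outdir / "overlaps.json").write_text(json.dumps(overlaps, indent=2))
        toc("compare", t0, overlaps)

        t0 = tic("cluster")
        contrast_names = [c for c in DEFAULT_PROFILE_CONTRASTS if c in cfg.comparisons]
        union_kept = sorted(set().union(*(kept[c] for c in contrast_names)))
        counts_union = counts.loc[union_kept]
        lfc = {
            c: quantify.log_fold_change(
                counts_union,
                design,
                cfg.comparisons[c],
                per_muscle=True,
                pseudo=cfg.lfc_pseudo,
                normalization=cfg.normalization,
            )
            for c in contrast_names
        }
        profiles = _cluster.build_profiles(
            lfc, [results[c].alignment for c in cfg.comparisons]
        )
        cluster_info: dict = {"n_profile_genes": int(profiles.shape[0])}
        if profiles.shape[0] >= max(cfg.n_clusters, cfg.k_min + 1):
            assignment = _cluster.hcluster(
                profiles, linkage=cfg.linkage, k=cfg.n_clusters
            )
            assignment.labels.to_csv(outdir / "clusters.tsv", sep="\t")
            (outdir / "merge_tree.nwk").write_text(assignment.to_newick() + "\n")
            summary_table = _cluster.cluster_summary(assignment, profiles)
            summary_table.to_csv(outdir / "cluster_summary.tsv", sep="\t")
            cluster_info["k"] = assignment.k
            if cfg.run_select_k:
                cluster_info["selected_k"] = _cluster.select_k(
                    profiles,
                    k_range=range(cfg.k_min, cfg.k_max + 1),
                    linkage=cfg.linkage,
                )
        profiles.to_csv(outdir / "lfc_profiles.tsv", sep="\t")
        toc("cluster", t0, cluster_info)

        if cfg.gmt_path:
            t0 = tic("enrich")
            library = _io.read_gmt(cfg.gmt_path)
            enrich_info = {}
            for a, b in DEFAULT_OVERLAP_PAIRS:
                if a not in results or b not in results:
                    continue
                background = sorted(set(kept[a]) & set(kept[b]))
                query = sorted(
                    set(results[a].aligned_genes)
                    & set(results[b].aligned_genes)
                    & set(background)
                )
                if not query:
                    continue
                table = _enrich.enrich(
                    query, background, library, alpha=cfg.alpha, ease=cfg.ease
                )
                table.to_csv(outdir / f"enrichment_{a}_vs_{b}.tsv", sep="\t", index=False)
                enrich_info[f"{a}_vs_{b}"] = int(table["enriched"].sum())
            toc("enrich", t0, enrich_info)

        if truth is not None:
            summary["stages"]["truth_available"] = True
    except (ConfigError, StageFailure):
        raise
    except Exception as e:  # noqa: BLE001 - name the failing stage
        raise StageFailure(stage, e) from e

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
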