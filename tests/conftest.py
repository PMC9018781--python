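import numpy as np
import pandas as pd
import pytest

from pcsig import (
    PCAlignment,
    SimParams,
    default_archetypes,
    default_design,
    generate_annotation,
    simulate_counts,
)
from pcsig import quantify
from pcsig import cluster as cluster_mod
from pcsig.pipeline import DEFAULT_COMPARISONS, DEFAULT_PROFILE_CONTRASTS


@pytest.fixture(scope="session")
def tiny_annotation() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transcript_id": ["T1", "T2", "T3", "T4", "T5"],
            "gene_id": ["G1", "G1", "G2", "G2", "G3"],
            "length": [1000, 2000, 500, 1500, 800],
        }
    )


@pytest.fixture(scope="session")
def small_study():
    """A fast 40-gene synthetic study with planted effects."""
    params = SimParams(n_genes=40, seed=7)
    design = default_design()
    annotation = generate_annotation(params)
    counts, truth = simulate_counts(design, annotation, default_archetypes(), params)
    return params, design, annotation, counts, truth


@pytest.fixture(scope="session")
def default_run():
    """Full default-scale study (2,000 genes, 10% affected, magnitude 1,
    NB dispersion 0.05, 4 muscles x 6 replicates, fixed seed) run through
    filtering and PC alignment of every comparison, with the fold-change
    profile matrix of all aligned genes.  Shared across recovery tests."""
    params = SimParams(seed=1)
    design = default_design()
    annotation = generate_annotation(params)
    counts, truth = simulate_counts(design, annotation, default_archetypes(), params)
    lengths = quantify.gene_lengths(annotation)
    results, kept = {}, {}
    for name, comp in DEFAULT_COMPARISONS.items():
        sub = design.subset(comp)
        filtered, kept_genes = quantify.filter_expressed(counts, sub)
        logtpm = np.log2(quantify.tpm(filtered, lengths) + 1)
        results[name] = PCAlignment(logtpm, sub, comp).fit()
        kept[name] = kept_genes
    union_kept = sorted(set().union(*kept.values()))
    lfc = {
        c: quantify.log_fold_change(
            counts.loc[union_kept], design, DEFAULT_COMPARISONS[c]
        )
        for c in DEFAULT_PROFILE_CONTRASTS
    }
    profiles = cluster_mod.build_profiles(lfc, [r.alignment for r in results.values()])
    return {
        "params": params,
        "design": design,
        "counts": counts,
        "truth": truth,
        "results": results,
        "kept": kept,
        "profiles": profiles,
    }
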