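"""Synthetic multi-muscle RNA-seq study generator with planted structure.

Emulates the design of a four-muscle mouse aging study: four muscles
(SOL, TA, TRI, GAS) x four treatment groups (10-month controls, 30-month
controls, 30-month calorie-restricted, 30-month rapamycin-treated) x six
replicates.  Genes carry

* per-gene log-normal baselines (expression dynamic range),
* shared inter-muscle expression axes (so that the top principal
  components of the expression matrix separate muscles, pushing any
  treatment-effect component to lower rank), and
* planted treatment-effect "archetypes": signed log2 effects on the three
  biological contrasts aging (30mCON vs 10mCON), CR (30mCR vs 30mCON) and
  RM (30mRM vs 30mCON).

Counts are negative-binomial with variance mu + phi * mu**2 (gamma-Poisson
mixture; Poisson when phi = 0).  Everything is deterministic given
``SimParams.seed``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MUSCLES = ("SOL", "TA", "TRI", "GAS")
GROUPS = ("10mCON", "30mCON", "30mCR", "30mRM")
CONTRASTS = ("aging", "cr", "rm")

#: log2 group mean offset = sum of the contrast effects active in the group,
#: relative to the 10-month control baseline.
GROUP_ACTIVE_CONTRASTS: dict[str, tuple[str, ...]] = {
    "10mCON": (),
    "30mCON": ("aging",),
    "30mCR": ("aging", "cr"),
    "30mRM": ("aging", "rm"),
}


@dataclass(frozen=True)
class EffectArchetype:
    """A planted pattern of signed effects across the three contrasts."""

    name: str
    signs: dict[str, int]  # contrast -> {-1, 0, +1}
    magnitude: float = 1.0  # log2 units

    def __post_init__(self) -> None:
        if set(self.signs) != set(CONTRASTS):
            raise ValueError(f"signs must cover contrasts {CONTRASTS}")
        if any(s not in (-1, 0, 1) for s in self.signs.values()):
            raise ValueError("signs must be in {-1, 0, +1}")
        if self.magnitude <= 0:
            raise ValueError("magnitude must be positive")
        if all(s == 0 for s in self.signs.values()):
            raise ValueError("archetype needs at least one nonzero sign")

    @property
    def sign_vector(self) -> tuple[int, int, int]:
        return tuple(self.signs[c] for c in CONTRASTS)


def default_archetypes(magnitude: float = 1.0) -> list[EffectArchetype]:
    """The eight effect archetypes mirroring the qualitative fold-change
    cluster patterns of the study: e.g. genes increased with age, further
    increased by CR and suppressed by RM, and its mirror image; common
    CR/RM suppression of age-induced genes; CR-only and RM-only effects;
    pure aging effects; and concordant CR/RM induction.
    """
    table = [
        ("age-up_cr-up_rm-down", {"aging": +1, "cr": +1, "rm": -1}),
        ("age-down_cr-down_rm-up", {"aging": -1, "cr": -1, "rm": +1}),
        ("age-up_cr-down_rm-down", {"aging": +1, "cr": -1, "rm": -1}),
        ("cr-up", {"aging": 0, "cr": +1, "rm": 0}),
        ("rm-down", {"aging": 0, "cr": 0, "rm": -1}),
        ("age-up", {"aging": +1, "cr": 0, "rm": 0}),
        ("age-down", {"aging": -1, "cr": 0, "rm": 0}),
        ("cr-up_rm-up", {"aging": 0, "cr": +1, "rm": +1}),
    ]
    return [EffectArchetype(name, signs, magnitude) for name, signs in table]


@dataclass(frozen=True)
class StudyDesign:
    """Sample sheet: one row per sample with muscle, group and replicate."""

    table: pd.DataFrame  # columns: sample_id, muscle, group, replicate

    def __post_init__(self) -> None:
        required = {"sample_id", "muscle", "group", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"design table missing columns {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            dup = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample ids: {sorted(set(dup))}")
        bad_m = set(self.table["muscle"]) - set(MUSCLES)
        if bad_m:
            raise ValueError(f"unknown muscles: {sorted(bad_m)}")
        bad_g = set(self.table["group"]) - set(GROUPS)
        if bad_g:
            raise ValueError(f"unknown groups: {sorted(bad_g)}")
        cell_sizes = self.table.groupby(["muscle", "group"], observed=True).size()
        if (cell_sizes < 2).any():
            raise ValueError("every (muscle, group) cell needs >= 2 replicates")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def subset(self, groups: tuple[str, ...] | list[str]) -> "StudyDesign":
        """Restrict to the given treatment groups (all muscles kept)."""
        sub = self.table[self.table["group"].isin(groups)].reset_index(drop=True)
        return StudyDesign(sub)

    def samples_of(self, group: str, muscle: str | None = None) -> list[str]:
        t = self.table
        mask = t["group"] == group
        if muscle is not None:
            mask &= t["muscle"] == muscle
        return list(t.loc[mask, "sample_id"])

    def min_group_size(self) -> int:
        return int(self.table.groupby("group", observed=True).size().min())


def default_design(n_replicates: int = 6) -> StudyDesign:
    """The study layout: 4 muscles x 4 groups x ``n_replicates`` samples."""
    rows = [
        {
            "sample_id": f"{m}_{g}_r{r}",
            "muscle": m,
            "group": g,
            "replicate": r,
        }
        for m in MUSCLES
        for g in GROUPS
        for r in range(1, n_replicates + 1)
    ]
    return StudyDesign(pd.DataFrame(rows))


@dataclass(frozen=True)
class SimParams:
    """Knobs of the generator.

    baseline_mean is the median per-gene expected count; per-gene baselines
    are log-normal around it with spread ``baseline_log2_sd`` (bulk RNA-seq
    spans several orders of magnitude).  ``nb_dispersion`` is phi in
    var = mu + phi mu^2.  ``muscle_axis_count`` shared log2-offset axes
    separate the muscles; their per-gene loadings have SD
    ``muscle_axis_sd``.  ``affected_fraction`` of genes get an archetype,
    with per-gene magnitude jitter SD ``magnitude_jitter_sd``.
    """

    n_genes: int = 2000
    transcripts_per_gene: tuple[int, int] = (1, 3)
    length_range: tuple[int, int] = (300, 3000)
    baseline_mean: float = 100.0
    baseline_log2_sd: float = 1.5
    nb_dispersion: float = 0.05
    muscle_axis_count: int = 3
    muscle_axis_sd: float = 0.3
    affected_fraction: float = 0.10
    magnitude_jitter_sd: float = 0.25
    multimap_rate: float = 0.10
    reads_per_sample: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("affected_fraction", "multimap_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        lo, hi = self.length_range
        if lo <= 0 or hi < lo:
            raise ValueError(f"invalid length_range {self.length_range}")
        lo, hi = self.transcripts_per_gene
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid transcripts_per_gene {self.transcripts_per_gene}")

    def replace(self, **kw) -> "SimParams":
        return dataclasses.replace(self, **kw)


def _rng(params: SimParams, stream: int) -> np.random.Generator:
    # independent substream per generator stage, all rooted at params.seed
    return np.random.default_rng(np.random.SeedSequence([params.seed, stream]))


def generate_annotation(params: SimParams) -> pd.DataFrame:
    """Transcript table: transcript_id, gene_id, length (nt).

    Each gene gets a uniform 1..k transcripts with lengths uniform in
    ``length_range``.  Deterministic under the seed.
    """
    rng = _rng(params, 0)
    genes = [f"g{i:05d}" for i in range(1, params.n_genes + 1)]
    lo_t, hi_t = params.transcripts_per_gene
    n_tx = rng.integers(lo_t, hi_t + 1, size=params.n_genes)
    lo_l, hi_l = params.length_range
    rows = []
    for gene, k in zip(genes, n_tx):
        lengths = rng.integers(lo_l, hi_l + 1, size=k)
        for j in range(k):
            rows.append((f"{gene}.t{j + 1}", gene, int(lengths[j])))
    return pd.DataFrame(rows, columns=["transcript_id", "gene_id", "length"])


def _muscle_scores(n_axes: int, rng: np.random.Generator) -> np.ndarray:
    """Per-axis muscle score vectors, mean 0 / variance 1 across muscles.

    The first three axes are orthogonal Helmert-style contrasts of the four
    muscles; further axes (if requested) are random centered vectors.
    """
    helmert = np.array(
        [
            [1.0, -1.0, 0.0, 0.0],
            [1.0, 1.0, -2.0, 0.0],
            [1.0, 1.0, 1.0, -3.0],
        ]
    )
    scores = []
    for a in range(n_axes):
        if a < 3:
            v = helmert[a]
        else:
            v = rng.normal(size=4)
            v = v - v.mean()
        v = v / v.std()
        scores.append(v)
    return np.asarray(scores)  # (n_axes, 4)


def simulate_counts(
    design: StudyDesign,
    annotation: pd.DataFrame,
    archetypes: list[EffectArchetype],
    params: SimParams,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a gene-level count matrix plus its ground truth.

    Gene mean in sample s: baseline_g * 2**(muscle offset + sum of planted
    contrast effects active in s's group); counts NB(mu, phi).  Returns
    (counts genes x samples, truth table).  The truth table has one row per
    gene: archetype ("null" for unaffected genes), the true log2 fold
    change per contrast, and the per-muscle baseline log2 offsets.
    """
    genes = list(pd.unique(annotation["gene_id"]))
    if len(genes) != params.n_genes:
        raise ValueError(
            f"annotation has {len(genes)} genes but params.n_genes={params.n_genes}"
        )
    samples = design.sample_ids
    rng = _rng(params, 1)

    baseline = params.baseline_mean * np.exp2(
        rng.normal(0.0, params.baseline_log2_sd, size=len(genes))
    )

    loadings = rng.normal(
        0.0, params.muscle_axis_sd, size=(len(genes), params.muscle_axis_count)
    )
    scores = _muscle_scores(params.muscle_axis_count, rng)
    muscle_offset = loadings @ scores  # genes x 4, log2 units
    muscle_offset = pd.DataFrame(muscle_offset, index=genes, columns=list(MUSCLES))

    n_affected = int(round(params.affected_fraction * len(genes)))
    affected_idx = rng.choice(len(genes), size=n_affected, replace=False)
    which = rng.integers(0, len(archetypes), size=n_affected)
    jitter = rng.normal(0.0, params.magnitude_jitter_sd, size=n_affected)

    lfc = pd.DataFrame(0.0, index=genes, columns=list(CONTRASTS))
    arch_name = pd.Series("null", index=genes, name="archetype")
    for gi, ai, jt in zip(affected_idx, which, jitter):
        arch = archetypes[ai]
        mag = max(arch.magnitude + jt, 0.05)
        arch_name.iloc[gi] = arch.name
        for c in CONTRASTS:
            lfc.iloc[gi, lfc.columns.get_loc(c)] = arch.signs[c] * mag

    mu = np.empty((len(genes), len(samples)))
    for j, (_, row) in enumerate(design.table.iterrows()):
        log2_shift = muscle_offset[row["muscle"]].to_numpy().copy()
        for c in GROUP_ACTIVE_CONTRASTS[row["group"]]:
            log2_shift += lfc[c].to_numpy()
        mu[:, j] = baseline * np.exp2(log2_shift)

    if params.reads_per_sample is not None:
        mu *= params.reads_per_sample / mu.sum(axis=0, keepdims=True)

    phi = params.nb_dispersion
    if phi == 0:
        counts = rng.poisson(mu)
    else:
        lam = rng.gamma(shape=1.0 / phi, scale=phi * mu)
        counts = rng.poisson(lam)

    counts = pd.DataFrame(counts, index=genes, columns=samples)
    counts.index.name = "gene_id"
    truth = pd.concat(
        [
            arch_name,
            lfc.add_prefix("lfc_"),
            muscle_offset.add_prefix("offset_"),
        ],
        axis=1,
    )
    truth.index.name = "gene_id"
    return counts, truth


def emit_alignment_records(
    gene_counts: pd.DataFrame,
    annotation: pd.DataFrame,
    params: SimParams,
) -> pd.DataFrame:
    """Expand gene counts into per-read alignment records.

    Each read lists its true transcript (uniform among the gene's
    transcripts); with probability ``multimap_rate`` it additionally lists
    1..3 decoys drawn from the remaining transcripts of the true gene plus
    the transcripts of one random other gene, exercising both within-gene
    and between-gene weight splitting downstream.  Record count per sample
    equals the sample's (integer) count total.

    Returns a DataFrame with columns read_id, sample_id, transcripts
    (comma-separated transcript ids).
    """
    rng = _rng(params, 2)
    tx_of_gene: dict[str, list[str]] = {
        g: list(sub["transcript_id"]) for g, sub in annotation.groupby("gene_id")
    }
    unknown = set(gene_counts.index) - set(tx_of_gene)
    if unknown:
        raise ValueError(f"genes missing from annotation: {sorted(unknown)[:5]}")
    genes = list(gene_counts.index)

    rows: list[tuple[str, str, str]] = []
    for sample in gene_counts.columns:
        col = gene_counts[sample].to_numpy()
        col = np.rint(col).astype(int)
        read_no = 0
        for g, c in zip(genes, col):
            txs = tx_of_gene[g]
            for _ in range(int(c)):
                read_no += 1
                true_tx = txs[rng.integers(0, len(txs))]
                cands = {true_tx}
                if params.multimap_rate > 0 and rng.random() < params.multimap_rate:
                    decoy_gene = g
                    while decoy_gene == g and len(genes) > 1:
                        decoy_gene = genes[rng.integers(0, len(genes))]
                    pool = [t for t in txs if t != true_tx] + tx_of_gene[decoy_gene]
                    pool = [t for t in pool if t not in cands]
                    n_extra = int(rng.integers(1, 4))  # total candidates 2..4
                    if pool:
                        take = rng.choice(
                            len(pool), size=min(n_extra, len(pool)), replace=False
                        )
                        cands.update(pool[i] for i in take)
                rows.append(
                    (f"{sample}:r{read_no}", sample, ",".join(sorted(cands)))
                )
    return pd.DataFrame(rows, columns=["read_id", "sample_id", "transcripts"])
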