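"""Synthetic microarray-like data with planted gene-set effects.

The generator emulates two-group log2 expression cohorts of the kind the
pipeline analyses: per-gene Gaussian log2 intensities with gene-specific
baselines and variances, an additive group effect concentrated in designated
("planted") gene sets, per-gene/per-sample detection p-values from a simple
two-component model, and annotation quirks (duplicate symbols, multi-mapped
probes, sex-chromosome genes) that exercise the preprocessing filters.

A separate paired-condition generator produces two per-gene log2
fold-change vectors whose expected Pearson correlation is available in
closed form, for testing cross-condition concordance:

    fcA = s + uA + eA,  fcB = s + uB + eB,
    s ~ N(0, shared_sd^2), u ~ N(0, private_sd^2), e ~ N(0, noise_sd^2)
    =>  E[r] = shared_sd^2 / (shared_sd^2 + private_sd^2 + noise_sd^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionDataset, GeneSetCollection

__all__ = [
    "DetectionNoise",
    "SimulationConfig",
    "PairedConditionConfig",
    "simulate_gene_sets",
    "simulate_dataset",
    "simulate_paired_conditions",
]

CONTROL_LABEL = "control"
CONDITION_LABEL = "condition"


def gene_ids(n_genes: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n_genes + 1)]


@dataclass(frozen=True)
class DetectionNoise:
    """Two-component detection p-value model.

    Expressed genes draw Beta(a, b) p-values; the defaults put ~99.7% of
    their per-sample p-values below 0.01 so a reliably expressed gene passes
    the "detected in every sample of a group" rule, as on real arrays.  A
    ``silent_fraction`` of genes is unexpressed and draws Uniform(0, 1)
    p-values in every sample, so the presence filter has something to remove.
    """

    a: float = 0.05
    b: float = 200.0
    silent_fraction: float = 0.1


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions for one two-group cohort.

    Defaults mirror the study conditions the pipeline is exercised under:
    ~2,000 genes, two groups of 10 samples, RMA-like log2 baselines in
    [4, 12] with per-gene SDs in [0.2, 0.8], 200 candidate sets of which 10
    carry an additive 1.0 log2-unit shift in the condition group.
    """

    n_genes: int = 2000
    n_samples_per_group: tuple[int, int] = (10, 10)
    baseline_mean_range: tuple[float, float] = (4.0, 12.0)
    gene_sd_range: tuple[float, float] = (0.2, 0.8)
    n_sets: int = 200
    set_size_range: tuple[int, int] = (10, 40)
    n_planted_sets: int = 10
    delta: float = 1.0
    frac_affected_in_set: float = 1.0
    detection_noise: DetectionNoise = field(default_factory=DetectionNoise)
    sex_chrom_fraction: float = 0.05
    multimap_fraction: float = 0.05
    duplicate_symbol_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_sets < 1:
            raise ValueError("counts must be >= 1")
        if min(self.n_samples_per_group) < 1:
            raise ValueError("each group needs >= 1 sample")
        for frac in (self.frac_affected_in_set, self.sex_chrom_fraction,
                     self.multimap_fraction, self.duplicate_symbol_fraction,
                     self.detection_noise.silent_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if not math.isfinite(self.delta):
            raise ValueError("delta must be finite")
        lo, hi = self.set_size_range
        if not (2 <= lo <= hi <= self.n_genes):
            raise ValueError("set_size_range must lie within [2, n_genes]")


@dataclass(frozen=True)
class PairedConditionConfig:
    """Generative model for two correlated per-gene log2FC vectors."""

    n_genes: int = 10_000
    shared_sd: float = 0.5
    private_sd: float = 0.3
    noise_sd: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shared_sd, self.private_sd, self.noise_sd) < 0:
            raise ValueError("SDs must be >= 0")
        if self.shared_sd + self.private_sd <= 0 and self.noise_sd <= 0:
            raise ValueError("degenerate configuration: all SDs are zero")

    @property
    def expected_correlation(self) -> float:
        tot = self.shared_sd**2 + self.private_sd**2 + self.noise_sd**2
        return self.shared_sd**2 / tot

    @classmethod
    def from_expected_correlation(
        cls, r: float, n_genes: int = 10_000, total_sd: float = 1.0, seed: int = 0
    ) -> "PairedConditionConfig":
        """Choose SDs so the expected Pearson correlation equals ``r``.

        The non-shared variance is split equally between the private effect
        and estimation noise; the total per-vector SD is ``total_sd``.
        """
        if not 0.0 <= r < 1.0:
            raise ValueError("r must lie in [0, 1)")
        shared = math.sqrt(r) * total_sd
        rest = math.sqrt((1.0 - r) / 2.0) * total_sd
        return cls(n_genes=n_genes, shared_sd=shared, private_sd=rest, noise_sd=rest, seed=seed)


def simulate_gene_sets(
    n_genes: int,
    n_sets: int,
    set_size_range: tuple[int, int],
    seed: int = 0,
    genes: list[str] | None = None,
) -> GeneSetCollection:
    """Sample ``n_sets`` gene sets with sizes uniform on ``set_size_range``.

    Members are drawn without replacement within a set; overlap between sets
    is allowed.  Deterministic under ``seed``.
    """
    lo, hi = set_size_range
    if not (1 <= lo <= hi):
        raise ValueError(f"infeasible set_size_range {set_size_range}")
    if genes is None:
        genes = gene_ids(n_genes)
    if hi > len(genes):
        raise ValueError(f"set_size_range max {hi} exceeds n_genes {len(genes)}")
    rng = np.random.default_rng(seed)
    gene_arr = np.asarray(genes)
    sets: dict[str, tuple[str, ...]] = {}
    for i in range(1, n_sets + 1):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(gene_arr, size=size, replace=False)
        sets[f"SET_{i:04d}"] = tuple(members)
    return GeneSetCollection(sets, {name: "simulated" for name in sets})


def simulate_dataset(
    cfg: SimulationConfig,
    sets: GeneSetCollection,
    planted: list[str] | None = None,
) -> tuple[ExpressionDataset, list[str]]:
    """Generate a two-group cohort with planted effects in gene sets.

    Expression follows ``x(g, s) = baseline(g) + effect(g) * 1[s in
    condition] + eps`` with ``eps ~ N(0, sd(g))``; ``effect(g)`` equals
    ``cfg.delta`` for the affected fraction of each planted set's members and
    0 elsewhere.  ``planted`` names the affected sets explicitly (so several
    cohorts can share the same biology); by default ``cfg.n_planted_sets``
    sets are drawn at random.  Returns the dataset (with detection p-values,
    annotations and groups attached) and the planted set names.
    """
    if cfg.n_planted_sets > len(sets):
        raise ValueError(
            f"n_planted_sets={cfg.n_planted_sets} exceeds available sets ({len(sets)})"
        )
    if planted is not None:
        unknown = [s for s in planted if s not in sets.names]
        if unknown:
            raise ValueError(f"planted sets not in collection: {unknown}")
    rng = np.random.default_rng(cfg.seed)
    genes = gene_ids(cfg.n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    n1, n2 = cfg.n_samples_per_group
    samples = [f"ctrl_{i:02d}" for i in range(1, n1 + 1)] + [
        f"cond_{i:02d}" for i in range(1, n2 + 1)
    ]

    baseline = rng.uniform(*cfg.baseline_mean_range, size=cfg.n_genes)
    sd = rng.uniform(*cfg.gene_sd_range, size=cfg.n_genes)

    if planted is None:
        planted = [str(s) for s in rng.choice(np.asarray(sets.names), size=cfg.n_planted_sets, replace=False)]
    else:
        planted = list(planted)
    effect = np.zeros(cfg.n_genes)
    for name in planted:
        members = [g for g in sets.members(name) if g in gene_index]
        k = int(math.ceil(cfg.frac_affected_in_set * len(members)))
        chosen = rng.choice(np.asarray(members), size=k, replace=False) if k else []
        for g in chosen:
            effect[gene_index[g]] = cfg.delta

    is_cond = np.array([s.startswith("cond_") for s in samples])
    mean = baseline[:, None] + np.outer(effect, is_cond.astype(float))
    values = mean + rng.normal(size=(cfg.n_genes, len(samples))) * sd[:, None]
    values_df = pd.DataFrame(values, index=genes, columns=samples)

    # detection p-values: expressed ~ Beta(a, b); silent genes ~ Uniform(0, 1)
    dn = cfg.detection_noise
    silent = rng.random(cfg.n_genes) < dn.silent_fraction
    dp = rng.beta(dn.a, dn.b, size=(cfg.n_genes, len(samples)))
    dp[silent] = rng.random(size=(int(silent.sum()), len(samples)))
    dp_df = pd.DataFrame(np.clip(dp, 0.0, 1.0), index=genes, columns=samples)

    # annotations: symbols with planted duplicates, multi-mapped flags, X/Y labels
    symbols = np.array([f"SYM{i:05d}" for i in range(1, cfg.n_genes + 1)], dtype=object)
    n_dup = int(round(cfg.duplicate_symbol_fraction * cfg.n_genes))
    if n_dup:
        dup_rows = rng.choice(cfg.n_genes, size=n_dup, replace=False)
        donors = rng.choice(np.setdiff1d(np.arange(cfg.n_genes), dup_rows), size=n_dup)
        symbols[dup_rows] = symbols[donors]
    autosomes = rng.choice([str(c) for c in range(1, 20)], size=cfg.n_genes)
    chrom = autosomes.astype(object)
    n_sex = int(round(cfg.sex_chrom_fraction * cfg.n_genes))
    if n_sex:
        sex_rows = rng.choice(cfg.n_genes, size=n_sex, replace=False)
        chrom[sex_rows] = rng.choice(["X", "Y"], size=n_sex)
    multimap = (rng.random(cfg.n_genes) < cfg.multimap_fraction).astype(int)
    ann = pd.DataFrame(
        {"symbol": symbols, "chromosome": chrom, "multi_mapped": multimap}, index=genes
    )

    groups = pd.Series(
        [CONTROL_LABEL] * n1 + [CONDITION_LABEL] * n2, index=samples
    )
    ds = ExpressionDataset(
        values_df,
        detection_p=dp_df,
        annotations=ann,
        groups=groups,
        condition=CONDITION_LABEL,
        provenance=[f"simulate_dataset(seed={cfg.seed}, delta={cfg.delta})"],
    )
    return ds, planted


def simulate_paired_conditions(cfg: PairedConditionConfig) -> pd.DataFrame:
    """Generate two correlated per-gene log2FC vectors (columns ``fc_a``, ``fc_b``)."""
    if cfg.n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    if cfg.shared_sd == 0 and cfg.private_sd == 0 and cfg.noise_sd == 0:
        raise ValueError("degenerate configuration: all SDs are zero")
    rng = np.random.default_rng(cfg.seed)
    s = rng.normal(0.0, cfg.shared_sd, size=cfg.n_genes) if cfg.shared_sd else np.zeros(cfg.n_genes)
    draw = lambda sd: rng.normal(0.0, sd, size=cfg.n_genes) if sd else np.zeros(cfg.n_genes)
    fc_a = s + draw(cfg.private_sd) + draw(cfg.noise_sd)
    fc_b = s + draw(cfg.private_sd) + draw(cfg.noise_sd)
    return pd.DataFrame({"fc_a": fc_a, "fc_b": fc_b}, index=gene_ids(cfg.n_genes))
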