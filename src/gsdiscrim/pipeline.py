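"""Composition of the stages into the three study workflows.

1. **Derivation** — on a knockdown-vs-control dataset: preprocess, moderated
   differential statistics with permutation FDR, joint FC/FDR deregulation
   calls, and Fisher enrichment of the down-regulated genes; sets enriched at
   adjusted p < 0.05 among the down-regulated genes become the "mediated"
   candidate list.
2. **Cohort validation** — on one or more disease/control cohorts: score all
   sets per sample, find sets up-regulated in the condition group, test the
   overlap with the candidate list (cumulative hypergeometric over the sets
   scored in both analyses), order the overlapped sets for heatmaps, and
   classify samples by a designated principal component of the overlapped
   sets' scores (Welch t, ROC AUC, random-set resampling null).
3. **Cross-condition check** — two datasets sharing a gene universe are each
   run through differential analysis (a more permissive FDR preset for small
   in-vivo designs) and compared by log2FC Pearson concordance and the
   commonly deregulated gene list.

Each workflow exists as an in-memory function over datasets and as a
file-based runner driven by a YAML config (used by the CLI), whose outputs
carry a provenance header (package version, config hash, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .containers import ConcordanceResult, ExpressionDataset, GeneSetCollection, OverlapTestResult, ResamplingResult
from .de import DifferentialResult, differential_table
from .enrichment import fisher_enrichment
from .faime import SetScoreMatrix, faime_scores
from .classify import DiscriminationReport, discrimination_report, pc_separation_test, resample_random_sets, roc_auc
from .preprocess import preprocess
from .setstats import cluster_order, logfc_concordance, overlap_hypergeometric, set_group_test, upregulated_sets
from . import io as gio

logger = logging.getLogger(__name__)

__all__ = [
    "PRESETS",
    "DerivationResult",
    "CohortReport",
    "CohortValidation",
    "CrossConditionResult",
    "derive_candidate_sets",
    "validate_cohorts",
    "cross_condition",
    "run_derivation",
    "run_cohort_validation",
    "run_cross_condition",
]

# deregulation-call presets: cell-line derivation vs small in-vivo designs
PRESETS = {
    "cells": {"fc_threshold": 1.3, "q_threshold": 0.01},
    "mouse": {"fc_threshold": 1.3, "q_threshold": 0.10},
}


@dataclass
class DerivationResult:
    differential: DifferentialResult
    enrichment_up: pd.DataFrame
    enrichment_down: pd.DataFrame
    candidate_sets: list[str]


@dataclass
class CohortReport:
    up_sets: list[str]
    overlap: OverlapTestResult
    mediated_sets: list[str]
    heatmap_set_order: list[str]
    heatmap_sample_order: list[str]
    discrimination: DiscriminationReport | None
    pc_t: float | None
    pc_p: float | None
    pc_auc: float | None


@dataclass
class CohortValidation:
    per_cohort: dict[str, CohortReport]
    resampling: ResamplingResult | None


@dataclass
class CrossConditionResult:
    differential_a: DifferentialResult
    differential_b: DifferentialResult
    concordance: ConcordanceResult
    heatmap_gene_order: list[str]


def derive_candidate_sets(
    dataset: ExpressionDataset,
    sets: GeneSetCollection,
    fc_threshold: float = 1.3,
    q_threshold: float = 0.01,
    n_perm: int | str = 1000,
    seed: int | None = None,
    s0: float | str = "auto",
    alpha_adj: float = 0.05,
    min_overlap_genes: int = 3,
) -> DerivationResult:
    """Derivation workflow on an (already preprocessed) knockdown dataset.

    The candidate ("mediated") list contains the sets enriched among the
    down-regulated genes at BH-adjusted p < ``alpha_adj``.  The enrichment
    universe is the genes surviving preprocessing, i.e. all genes in
    ``dataset``.
    """
    diff = differential_table(
        dataset, s0=s0, n_perm=n_perm, seed=seed,
        fc_threshold=fc_threshold, q_threshold=q_threshold,
    )
    universe = dataset.genes

    def _enrich(genes: list[str]) -> pd.DataFrame:
        if not genes:
            return pd.DataFrame(columns=["k", "K", "n", "N", "p", "p_adj"])
        return fisher_enrichment(genes, universe, sets, min_overlap_genes=min_overlap_genes)

    enr_up = _enrich(diff.up_genes)
    enr_down = _enrich(diff.down_genes)
    candidates = list(enr_down.index[enr_down["p_adj"] < alpha_adj]) if len(enr_down) else []
    logger.info(
        "derivation: %d up / %d down genes; %d candidate set(s) at p_adj < %g",
        len(diff.up_genes), len(diff.down_genes), len(candidates), alpha_adj,
    )
    return DerivationResult(diff, enr_up, enr_down, candidates)


def validate_cohorts(
    cohorts: dict[str, ExpressionDataset],
    sets: GeneSetCollection,
    candidate_sets: list[str],
    alpha: float = 0.05,
    alternative: str = "two_sided",
    component: int = 2,
    B: int = 1000,
    seed: int | None = None,
    min_set_genes: int = 5,
    max_set_genes: int = 500,
    weight_scheme: str = "exp-rank",
    use_overlap: bool = True,
    standardize: bool = True,
) -> CohortValidation:
    """Cohort-validation workflow for one or more disease/control cohorts.

    Per cohort: FAIME scores for every admissible set, directional Welch
    tests for "up in condition" sets, cumulative hypergeometric overlap with
    the candidate list (universe = sets scored in both analyses), heatmap
    leaf orders on the overlapped sets, and PC-level classification on the
    overlapped sets (or on the full candidate list if ``use_overlap`` is
    False).  A joint resampling null compares the mean designated-component
    AUC across cohorts against random set lists of the same size.
    """
    if not candidate_sets:
        raise ValueError("candidate set list is empty")
    per_cohort: dict[str, CohortReport] = {}
    scored: dict[str, SetScoreMatrix] = {}
    class_lists: dict[str, list[str]] = {}
    for name, ds in cohorts.items():
        scores = faime_scores(ds, sets, min_set_genes, max_set_genes, weight_scheme)
        scored[name] = scores
        tests = set_group_test(scores, alternative=alternative)
        up = upregulated_sets(tests, alpha=alpha)
        universe = [s for s in scores.set_names if s in tests.index]
        cand_in_universe = [s for s in candidate_sets if s in universe]
        overlap = overlap_hypergeometric(cand_in_universe, up, universe)
        mediated = [s for s in candidate_sets if s in overlap.overlap_names]
        class_list = mediated if use_overlap else cand_in_universe
        class_lists[name] = class_list

        if len(class_list) >= 2:
            sub = scores.restrict(class_list)
            set_order = cluster_order(sub.scores, axis="rows") if len(class_list) >= 2 else class_list
            sample_order = cluster_order(sub.scores, axis="columns")
            report = discrimination_report(scores, class_list, component=component, standardize=standardize)
            col = f"PC{component}"
            if col in report.pc_tests.index:
                pc_t = float(report.pc_tests.loc[col, "t"])
                pc_p = float(report.pc_tests.loc[col, "p"])
                pc_auc = float(report.aucs[col])
            else:
                pc_t = pc_p = pc_auc = None
        else:
            logger.warning("cohort %r: empty/degenerate overlap (%d set(s)); classification skipped",
                           name, len(class_list))
            set_order, sample_order = list(class_list), list(scores.samples)
            report, pc_t, pc_p, pc_auc = None, None, None, None
        per_cohort[name] = CohortReport(
            up_sets=up, overlap=overlap, mediated_sets=mediated,
            heatmap_set_order=set_order, heatmap_sample_order=sample_order,
            discrimination=report, pc_t=pc_t, pc_p=pc_p, pc_auc=pc_auc,
        )

    # joint resampling over all cohorts on a shared classification list
    shared = class_lists[next(iter(class_lists))]
    usable = all(len(lst) >= 2 for lst in class_lists.values())
    resampling = None
    if usable:
        # use the first cohort's list intersected with every cohort's scored sets
        common = [s for s in shared if all(s in sc.set_names for sc in scored.values())]
        if len(common) >= 2:
            resampling = resample_random_sets(
                list(scored.values()), common, B=B, component=component,
                seed=seed, standardize=standardize,
            )
    if resampling is None:
        logger.warning("resampling skipped: classification list too small")
    return CohortValidation(per_cohort=per_cohort, resampling=resampling)


def cross_condition(
    dataset_a: ExpressionDataset,
    dataset_b: ExpressionDataset,
    fc_threshold: float = 1.3,
    q_threshold: float = 0.10,
    n_perm: int | str = 1000,
    seed: int | None = None,
    s0: float | str = "auto",
) -> CrossConditionResult:
    """Cross-condition concordance between two comparisons sharing genes."""
    shared = dataset_a.values.index.intersection(dataset_b.values.index)
    if len(shared) == 0:
        raise ValueError("datasets share no genes")
    da = differential_table(dataset_a, s0=s0, n_perm=n_perm, seed=seed,
                            fc_threshold=fc_threshold, q_threshold=q_threshold)
    db = differential_table(dataset_b, s0=s0, n_perm=n_perm, seed=seed,
                            fc_threshold=fc_threshold, q_threshold=q_threshold)
    conc = logfc_concordance(
        da.table["mean_diff"], db.table["mean_diff"],
        calls_a=da.table["call"], calls_b=db.table["call"],
    )
    common = list(conc.common_deregulated)
    if len(common) >= 2:
        order = cluster_order(dataset_a.values.loc[common], axis="rows")
    else:
        order = common
    return CrossConditionResult(da, db, conc, order)


# ---------------------------------------------------------------------------
# file-based runners (YAML config -> output directory)
# ---------------------------------------------------------------------------


def _load_config(config: str | Path | dict) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(config)
    return cfg


def _config_hash(cfg: dict) -> str:
    # output location excluded so the hash identifies the analysis, not where it lands
    hashable = {k: v for k, v in cfg.items() if k != "output_dir"}
    return hashlib.sha256(json.dumps(hashable, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _provenance(cfg: dict) -> list[str]:
    return [
        f"gsdiscrim {__version__}",
        f"config_hash {_config_hash(cfg)}",
        f"seed {cfg.get('seed', 0)}",
    ]


def _load_dataset(block: dict) -> ExpressionDataset:
    ds = gio.read_expression_matrix(
        block["expression"], scale=block.get("scale", "log2"),
        offset=float(block.get("offset", 0.0)),
    )
    if block.get("detection"):
        ds = gio.read_detection_matrix(block["detection"], ds)
    if block.get("annotations"):
        ds = gio.read_annotations(block["annotations"], ds)
    ds = gio.read_sample_groups(block["groups"], ds, condition=block.get("condition"))
    return preprocess(
        ds,
        detection_alpha=float(block.get("detection_alpha", 0.01)),
        skip_detection=bool(block.get("skip_detection", ds.detection_p is None)),
    )


def run_derivation(config: str | Path | dict) -> DerivationResult:
    """File-based derivation workflow: read inputs, run, write result tables."""
    cfg = _load_config(config)
    out = Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    header = _provenance(cfg)
    preset = PRESETS[cfg.get("preset", "cells")]
    ds = _load_dataset(cfg["derivation"])
    sets = gio.read_gmt(cfg["gene_sets"])
    result = derive_candidate_sets(
        ds, sets,
        fc_threshold=float(cfg.get("fc_threshold", preset["fc_threshold"])),
        q_threshold=float(cfg.get("q_threshold", preset["q_threshold"])),
        n_perm=cfg.get("n_perm", 1000),
        seed=int(cfg.get("seed", 0)),
        alpha_adj=float(cfg.get("alpha_adj", 0.05)),
    )
    gio.write_results_table(result.differential.table, out / "differential.tsv", header)
    if len(result.enrichment_down):
        gio.write_results_table(result.enrichment_down, out / "enrichment_down.tsv", header)
    if len(result.enrichment_up):
        gio.write_results_table(result.enrichment_up, out / "enrichment_up.tsv", header)
    (out / "candidate_sets.txt").write_text(
        "".join(f"{s}\n" for s in result.candidate_sets), encoding="utf-8"
    )
    return result


def run_cohort_validation(config: str | Path | dict) -> CohortValidation:
    """File-based cohort validation: per-cohort overlap + classification + resampling."""
    cfg = _load_config(config)
    out = Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    header = _provenance(cfg)
    sets = gio.read_gmt(cfg["gene_sets"])
    candidates = [
        line.strip() for line in Path(cfg["candidate_sets"]).read_text().splitlines() if line.strip()
    ]
    cohorts = {name: _load_dataset(block) for name, block in cfg["cohorts"].items()}
    result = validate_cohorts(
        cohorts, sets, candidates,
        alpha=float(cfg.get("alpha", 0.05)),
        component=int(cfg.get("component", 2)),
        B=int(cfg.get("resample", 1000)),
        seed=int(cfg.get("seed", 0)),
        use_overlap=bool(cfg.get("use_overlap", True)),
    )
    rows = []
    for name, rep in result.per_cohort.items():
        rows.append({
            "cohort": name,
            "n_up_sets": len(rep.up_sets),
            "overlap_k": rep.overlap.overlap,
            "overlap_p": rep.overlap.p,
            "universe": rep.overlap.universe_size,
            "pc_t": rep.pc_t, "pc_p": rep.pc_p, "pc_auc": rep.pc_auc,
        })
    gio.write_results_table(pd.DataFrame(rows).set_index("cohort"), out / "cohort_summary.tsv", header)
    if result.resampling is not None:
        res = result.resampling
        gio.write_results_table(
            pd.DataFrame({"null_auc": res.null_aucs}), out / "resampling_null.tsv", header
        )
        summary = pd.DataFrame([{
            "B": res.B, "candidate_size": res.candidate_size,
            "observed_mean_auc": res.observed, "p_right": res.p_right,
        }], index=pd.Index(["resampling"], name="record"))
        gio.write_results_table(summary, out / "resampling_summary.tsv", header)
    return result


def run_cross_condition(config: str | Path | dict) -> CrossConditionResult:
    """File-based cross-condition workflow (more permissive in-vivo FDR preset)."""
    cfg = _load_config(config)
    out = Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    header = _provenance(cfg)
    preset = PRESETS[cfg.get("preset", "mouse")]
    ds_a = _load_dataset(cfg["condition_a"])
    ds_b = _load_dataset(cfg["condition_b"])
    result = cross_condition(
        ds_a, ds_b,
        fc_threshold=float(cfg.get("fc_threshold", preset["fc_threshold"])),
        q_threshold=float(cfg.get("q_threshold", preset["q_threshold"])),
        n_perm=cfg.get("n_perm", 1000),
        seed=int(cfg.get("seed", 0)),
    )
    conc = result.concordance
    summary = pd.DataFrame([{
        "r": conc.r, "p": conc.p, "n_genes": conc.n_genes,
        "n_common_deregulated": len(conc.common_deregulated),
    }], index=pd.Index(["concordance"], name="record"))
    gio.write_results_table(summary, out / "concordance.tsv", header)
    if conc.common_deregulated:
        (out / "common_deregulated.txt").write_text(
            "".join(f"{g}\n" for g in result.heatmap_gene_order), encoding="utf-8"
        )
    return result
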