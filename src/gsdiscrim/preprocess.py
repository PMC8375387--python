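"""Gene-level filtering and scale normalization before differential analysis.

Three rules are applied to a summarized expression matrix before testing:

* a detection ("presence") filter keeping genes whose detection p-value is
  below a threshold in *every* sample of at least one group;
* annotation filters removing multi-mapped probes and genes on the sex
  chromosomes (to avoid sex-driven confounding), then collapsing duplicate
  symbols to the highest-mean-expression row so each symbol is measured once;
* an optional log2 transform for matrices supplied on linear scale.

All filters act on genes only: samples and group labels are never altered,
and each filter is idempotent.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np

from .containers import ExpressionDataset

logger = logging.getLogger(__name__)

__all__ = ["log2_transform", "apply_detection_filter", "apply_annotation_filters", "preprocess"]

_SEX_CHROMOSOMES = {"x", "y", "chrx", "chry"}


def log2_transform(dataset: ExpressionDataset, offset: float = 0.0) -> ExpressionDataset:
    """Return a copy with ``value <- log2(value + offset)``.

    Input values must be non-negative (linear intensities); a negative cell
    is reported with its coordinates.
    """
    if offset < 0:
        raise ValueError("offset must be non-negative")
    arr = dataset.values.to_numpy(dtype=float)
    if (arr < 0).any():
        g, s = np.argwhere(arr < 0)[0]
        raise ValueError(
            f"negative value at gene {dataset.values.index[g]!r}, "
            f"sample {dataset.values.columns[s]!r}: {arr[g, s]}"
        )
    transformed = np.log2(arr + offset)
    if not np.isfinite(transformed).all():
        g, s = np.argwhere(~np.isfinite(transformed))[0]
        raise ValueError(
            f"log2 transform produced a non-finite value at gene "
            f"{dataset.values.index[g]!r}, sample {dataset.values.columns[s]!r} "
            f"(zero input with offset 0?)"
        )
    values = dataset.values.copy()
    values.loc[:, :] = transformed
    return replace(
        dataset,
        values=values,
        provenance=[*dataset.provenance, f"log2_transform(offset={offset})"],
    )


def apply_detection_filter(dataset: ExpressionDataset, alpha: float = 0.01) -> ExpressionDataset:
    """Keep genes detected (p < ``alpha``) in every sample of at least one group."""
    if dataset.detection_p is None:
        raise ValueError(
            "no detection p-values attached; disable this filter explicitly "
            "(skip_detection) rather than omitting the matrix"
        )
    ctrl, cond = dataset.group_samples()
    dp = dataset.detection_p
    ok = (dp[ctrl] < alpha).all(axis=1) | (dp[cond] < alpha).all(axis=1)
    kept = list(dataset.values.index[ok])
    removed = int((~ok).sum())
    logger.info("detection filter (alpha=%g): removed %d of %d genes", alpha, removed, len(ok))
    return dataset.subset_genes(kept, note=f"apply_detection_filter(alpha={alpha}): removed {removed}")


def apply_annotation_filters(dataset: ExpressionDataset) -> ExpressionDataset:
    """Drop multi-mapped and sex-chromosome genes; collapse duplicate symbols.

    Among rows sharing a symbol only the row with the highest mean expression
    is retained, leaving a matrix with unique symbols.
    """
    if dataset.annotations is None:
        raise ValueError("no annotations attached")
    ann = dataset.annotations
    missing = [g for g in dataset.values.index if g not in ann.index]
    if missing:
        raise ValueError(f"annotation missing for gene(s): {missing[:5]}")
    ann = ann.loc[dataset.values.index]

    keep = (ann["multi_mapped"].astype(int) == 0) & (
        ~ann["chromosome"].astype(str).str.lower().isin(_SEX_CHROMOSOMES)
    )
    n_multi = int((ann["multi_mapped"].astype(int) != 0).sum())
    n_sex = int(ann["chromosome"].astype(str).str.lower().isin(_SEX_CHROMOSOMES).sum())
    kept_genes = dataset.values.index[keep.to_numpy()]

    # collapse duplicate symbols: keep the highest-mean-expression row
    means = dataset.values.loc[kept_genes].mean(axis=1)
    symbols = ann.loc[kept_genes, "symbol"]
    winners: list[str] = []
    best_for_symbol: dict[str, tuple[float, str]] = {}
    for g in kept_genes:
        sym = symbols[g]
        m = float(means[g])
        cur = best_for_symbol.get(sym)
        if cur is None or m > cur[0]:
            if cur is not None:
                logger.info("collapsing symbol %r: keeping %r (mean %.4g) over %r", sym, g, m, cur[1])
            best_for_symbol[sym] = (m, g)
    winner_set = {g for _, g in best_for_symbol.values()}
    winners = [g for g in kept_genes if g in winner_set]
    n_collapsed = len(kept_genes) - len(winners)
    logger.info(
        "annotation filters: removed %d multi-mapped, %d sex-chromosome, collapsed %d duplicate rows",
        n_multi, n_sex, n_collapsed,
    )
    return dataset.subset_genes(
        winners,
        note=f"apply_annotation_filters: multi={n_multi}, sex={n_sex}, collapsed={n_collapsed}",
    )


def preprocess(
    dataset: ExpressionDataset,
    detection_alpha: float = 0.01,
    skip_detection: bool = False,
) -> ExpressionDataset:
    """Standard filter sequence: detection filter then annotation filters."""
    out = dataset
    if not skip_detection:
        out = apply_detection_filter(out, alpha=detection_alpha)
    if out.annotations is not None:
        out = apply_annotation_filters(out)
    return out
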