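"""Moderated two-group differential expression with permutation FDR.

The per-gene statistic is the classic moderated difference

    d(g) = (mean2(g) - mean1(g)) / (s(g) + s0)

where ``s(g)`` is the pooled two-sample scatter
``sqrt([SS1 + SS2] / (n1 + n2 - 2) * (1/n1 + 1/n2))`` and ``s0`` is an
exchangeability constant stabilizing d for low-variance genes (with s0 = 0,
d is exactly the pooled-variance two-sample t statistic).  ``s0 = "auto"``
selects the constant minimizing the coefficient of variation of the spread
of d across genes binned by s quantiles.

False discovery rates come from permuting group labels: for each gene,
q(g) = median over permutations of #{|d_perm| >= |d_obs(g)|} divided by
#{|d_obs| >= |d_obs(g)|}, capped at 1 and made monotone non-increasing in
|d| by cumulative-minimum smoothing.  Small designs can enumerate all label
assignments exhaustively.

A gene is called deregulated when both gates pass strictly: linear
fold-change magnitude > fc_threshold and q < q_threshold, with direction
given by the sign of the condition-minus-control mean difference.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionDataset

logger = logging.getLogger(__name__)

__all__ = [
    "sam_statistics",
    "tusher_s0",
    "estimate_fdr_permutation",
    "fold_change",
    "call_deregulated",
    "differential_table",
    "DifferentialResult",
]

EXHAUSTIVE_LIMIT = 10_000


@dataclass
class DifferentialResult:
    """Per-gene differential table plus ordered up/down gene lists."""

    table: pd.DataFrame  # columns: d, s, mean_diff, fc, q, call
    up_genes: list[str]
    down_genes: list[str]
    s0: float


def _group_arrays(dataset: ExpressionDataset) -> tuple[np.ndarray, np.ndarray]:
    ctrl, cond = dataset.group_samples()
    X1 = dataset.values[ctrl].to_numpy(dtype=float)
    X2 = dataset.values[cond].to_numpy(dtype=float)
    return X1, X2


def _d_and_s(X1: np.ndarray, X2: np.ndarray, s0: float) -> tuple[np.ndarray, np.ndarray]:
    n1, n2 = X1.shape[1], X2.shape[1]
    m1 = X1.mean(axis=1)
    m2 = X2.mean(axis=1)
    ss = ((X1 - m1[:, None]) ** 2).sum(axis=1) + ((X2 - m2[:, None]) ** 2).sum(axis=1)
    s = np.sqrt(ss / (n1 + n2 - 2) * (1.0 / n1 + 1.0 / n2))
    denom = s + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(denom > 0, (m2 - m1) / denom, 0.0)
    return d, s


def tusher_s0(diff: np.ndarray, s: np.ndarray) -> float:
    """Select the exchangeability constant minimizing the CV of d's spread.

    Candidates are the percentiles of s (0, 5, ..., 100).  For each
    candidate, genes are binned by s quantiles and the median absolute
    deviation of d within each bin is computed; the candidate minimizing the
    coefficient of variation of those MADs is chosen.
    """
    n = len(s)
    if n < 20:
        return float(np.percentile(s, 50))
    n_bins = min(100, max(2, n // 20))
    quantile_edges = np.quantile(s, np.linspace(0, 1, n_bins + 1))
    bins = np.clip(np.searchsorted(quantile_edges, s, side="right") - 1, 0, n_bins - 1)
    candidates = np.percentile(s, np.arange(0, 101, 5))
    best_s0, best_cv = float(candidates[0]), np.inf
    for s0 in candidates:
        d_alpha = diff / (s + s0) if s0 > 0 or (s > 0).all() else None
        if d_alpha is None:
            continue
        mads = np.array([
            np.median(np.abs(d_alpha[bins == b] - np.median(d_alpha[bins == b])))
            for b in range(n_bins) if (bins == b).any()
        ])
        mean = mads.mean()
        if mean <= 0:
            continue
        cv = mads.std() / mean
        if cv < best_cv:
            best_cv, best_s0 = cv, float(s0)
    logger.info("tusher_s0 selected s0=%.6g (cv=%.4g)", best_s0, best_cv)
    return best_s0


def sam_statistics(
    dataset: ExpressionDataset, s0: float | str = "auto"
) -> tuple[pd.Series, pd.Series, float]:
    """Compute the moderated statistic d and pooled scatter s per gene.

    Returns ``(d, s, s0_used)``.  ``s0="auto"`` triggers data-driven
    selection; the chosen value is logged and returned.
    """
    X1, X2 = _group_arrays(dataset)
    _, s = _d_and_s(X1, X2, 0.0)
    m1, m2 = X1.mean(axis=1), X2.mean(axis=1)
    diff = m2 - m1
    if s0 == "auto":
        s0_used = tusher_s0(diff, s)
    else:
        s0_used = float(s0)
        if s0_used < 0:
            raise ValueError("s0 must be >= 0")
        if s0_used == 0 and not (s > 0).any():
            raise ValueError("all genes have zero variance; s0=0 is degenerate")
    d, _ = _d_and_s(X1, X2, s0_used)
    genes = dataset.values.index
    return pd.Series(d, index=genes, name="d"), pd.Series(s, index=genes, name="s"), s0_used


def _assignments(n: int, n1: int, n_perm: int | str, seed: int | None):
    """Yield index arrays selecting the permuted 'group1' samples."""
    if n_perm == "exhaustive":
        total = math.comb(n, n1)
        if total > EXHAUSTIVE_LIMIT:
            raise ValueError(
                f"exhaustive enumeration infeasible: C({n},{n1}) = {total} > {EXHAUSTIVE_LIMIT}"
            )
        logger.info("exhaustive permutation: enumerating %d label assignments", total)
        for combo in itertools.combinations(range(n), n1):
            yield np.asarray(combo)
    else:
        n_perm = int(n_perm)
        if n_perm <= 0:
            raise ValueError("n_perm must be positive")
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            yield rng.permutation(n)[:n1]


def estimate_fdr_permutation(
    dataset: ExpressionDataset,
    d_observed: pd.Series,
    s0: float,
    n_perm: int | str = 1000,
    seed: int | None = None,
) -> pd.Series:
    """Permutation-based q-values for the observed moderated statistics.

    For each gene, q = median over label permutations of the number of
    permuted |d| values at least as extreme as the gene's observed |d|,
    divided by the number of observed |d| values at least that extreme;
    capped at 1 and made monotone non-increasing in |d|.
    """
    X1, X2 = _group_arrays(dataset)
    n1 = X1.shape[1]
    X = np.hstack([X1, X2])
    n = X.shape[1]
    all_idx = np.arange(n)

    d_obs = d_observed.reindex(dataset.values.index).to_numpy(dtype=float)
    abs_obs = np.abs(d_obs)
    order = np.argsort(abs_obs, kind="stable")
    sorted_abs = abs_obs[order]
    # observed count of |d_obs| >= |d_obs(g)|
    cnt_obs = len(abs_obs) - np.searchsorted(sorted_abs, abs_obs, side="left")

    perm_counts = []
    for idx1 in _assignments(n, n1, n_perm, seed):
        mask = np.zeros(n, dtype=bool)
        mask[idx1] = True
        P1, P2 = X[:, mask], X[:, ~mask]
        d_perm, _ = _d_and_s(P1, P2, s0)
        sp = np.sort(np.abs(d_perm))
        perm_counts.append(len(sp) - np.searchsorted(sp, abs_obs, side="left"))
    counts = np.vstack(perm_counts)
    med = np.median(counts, axis=0)
    q = np.minimum(med / np.maximum(cnt_obs, 1), 1.0)

    # cumulative-minimum smoothing: monotone non-increasing in |d|
    desc = np.argsort(-abs_obs, kind="stable")
    q_desc = q[desc]
    q_desc = np.minimum.accumulate(q_desc[::-1])[::-1]
    q_mono = np.empty_like(q)
    q_mono[desc] = q_desc
    return pd.Series(q_mono, index=dataset.values.index, name="q")


def fold_change(dataset: ExpressionDataset) -> pd.DataFrame:
    """Per-gene log2 mean difference (condition - control) and linear FC magnitude."""
    X1, X2 = _group_arrays(dataset)
    mean_diff = X2.mean(axis=1) - X1.mean(axis=1)
    fc = 2.0 ** np.abs(mean_diff)
    return pd.DataFrame({"mean_diff": mean_diff, "fc": fc}, index=dataset.values.index)


def call_deregulated(
    table: pd.DataFrame, fc_threshold: float = 1.3, q_threshold: float = 0.01
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Apply the joint FC/FDR gates and return (table, up_genes, down_genes).

    ``call = up`` iff mean_diff > 0, fc > fc_threshold (strict) and
    q < q_threshold (strict); ``down`` symmetric.  Gene lists are ordered by
    decreasing |d|.
    """
    if not fc_threshold > 1:
        raise ValueError("fc_threshold must exceed 1")
    if not 0 < q_threshold < 1:
        raise ValueError("q_threshold must lie in (0, 1)")
    t = table.copy()
    passing = (t["fc"] > fc_threshold) & (t["q"] < q_threshold)
    call = np.where(~passing, "none", np.where(t["mean_diff"] > 0, "up", "down"))
    call[(t["mean_diff"] == 0)] = "none"
    t["call"] = call
    by_strength = t.reindex(t["d"].abs().sort_values(ascending=False).index)
    up = list(by_strength.index[by_strength["call"] == "up"])
    down = list(by_strength.index[by_strength["call"] == "down"])
    return t, up, down


def differential_table(
    dataset: ExpressionDataset,
    s0: float | str = "auto",
    n_perm: int | str = 1000,
    seed: int | None = None,
    fc_threshold: float = 1.3,
    q_threshold: float = 0.01,
) -> DifferentialResult:
    """Full differential workflow: statistic, permutation FDR, FC, calls."""
    d, s, s0_used = sam_statistics(dataset, s0=s0)
    q = estimate_fdr_permutation(dataset, d, s0_used, n_perm=n_perm, seed=seed)
    fc = fold_change(dataset)
    table = pd.concat([d, s, fc, q], axis=1)
    table, up, down = call_deregulated(table, fc_threshold, q_threshold)
    return DifferentialResult(table=table, up_genes=up, down_genes=down, s0=s0_used)
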