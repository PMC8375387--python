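"""Set-level statistics: group tests, list overlap, clustering order, concordance.

* ``set_group_test`` — Welch t-test per gene set comparing condition vs
  control single-sample scores; the "up-regulated in condition" list is the
  directional post-filter (positive direction and p below alpha).
* ``overlap_hypergeometric`` — cumulative hypergeometric tail probability
  that two set-name lists drawn from a common universe share at least the
  observed number of names.
* ``cluster_order`` — deterministic average-linkage/Euclidean leaf order on
  row-z-scored matrices, for heatmap rendering.
* ``logfc_concordance`` — Pearson correlation between two per-gene log2FC
  vectors on their shared genes, plus the commonly deregulated gene list.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import hypergeom

from .containers import ConcordanceResult, OverlapTestResult
from .faime import SetScoreMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "set_group_test",
    "upregulated_sets",
    "overlap_hypergeometric",
    "cluster_order",
    "logfc_concordance",
]


def set_group_test(
    scores: SetScoreMatrix, alternative: str = "two_sided"
) -> pd.DataFrame:
    """Welch t-test of condition vs control scores for each set.

    Returns a per-set table with columns ``t, p, direction`` (direction =
    sign of condition mean minus control mean).  Sets with zero variance in
    both groups are untestable and excluded with a warning.
    """
    if alternative not in ("two_sided", "greater"):
        raise ValueError("alternative must be 'two_sided' or 'greater'")
    ctrl, cond = scores.group_samples()
    if len(ctrl) < 2 or len(cond) < 2:
        raise ValueError("each group needs >= 2 samples")
    A = scores.scores[cond].to_numpy(dtype=float)  # condition
    B = scores.scores[ctrl].to_numpy(dtype=float)  # control
    var_a = A.var(axis=1, ddof=1)
    var_b = B.var(axis=1, ddof=1)
    testable = (var_a > 0) | (var_b > 0)
    if not testable.all():
        bad = list(np.asarray(scores.set_names)[~testable])
        logger.warning("excluding %d untestable zero-variance set(s): %s", len(bad), bad[:5])
    alt = "two-sided" if alternative == "two_sided" else "greater"
    res = stats.ttest_ind(A[testable], B[testable], axis=1, equal_var=False, alternative=alt)
    direction = np.sign(A[testable].mean(axis=1) - B[testable].mean(axis=1))
    return pd.DataFrame(
        {"t": res.statistic, "p": res.pvalue, "direction": direction},
        index=pd.Index(np.asarray(scores.set_names)[testable], name="set"),
    )


def upregulated_sets(test_table: pd.DataFrame, alpha: float = 0.05) -> list[str]:
    """Sets up-regulated in the condition group: direction > 0 and p < alpha."""
    mask = (test_table["direction"] > 0) & (test_table["p"] < alpha)
    return list(test_table.index[mask])


def overlap_hypergeometric(
    list_a: Iterable[str], list_b: Iterable[str], universe: Iterable[str]
) -> OverlapTestResult:
    """Cumulative hypergeometric test for the overlap of two name lists.

    ``p = P[X >= k]`` where X counts shared names when lists of the observed
    sizes are drawn at random from the universe.
    """
    uni = set(universe)
    a, b = set(list_a), set(list_b)
    bad = sorted((a | b) - uni)
    if bad:
        raise ValueError(f"lists not contained in universe; offending names: {bad[:10]}")
    N, K, n = len(uni), len(a), len(b)
    shared = sorted(a & b)
    k = len(shared)
    p = float(np.clip(hypergeom.sf(k - 1, N, K, n), 0.0, 1.0))
    return OverlapTestResult(
        universe_size=N, list_a_size=K, list_b_size=n,
        overlap=k, p=p, overlap_names=tuple(shared),
    )


def _zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    arr = matrix.to_numpy(dtype=float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=0, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        logger.warning("%d constant row(s) z-scored to zeros", int(flat.sum()))
    sd = np.where(sd == 0, 1.0, sd)
    return pd.DataFrame((arr - mu) / sd, index=matrix.index, columns=matrix.columns)


def cluster_order(matrix: pd.DataFrame, axis: str = "columns") -> list:
    """Leaf order from average-linkage hierarchical clustering for heatmaps.

    Rows are z-scored first (heatmaps show row-relative regulation); the
    requested axis is then clustered with Euclidean distance.  Ties break by
    input index, so the order is deterministic.
    """
    if axis not in ("rows", "columns"):
        raise ValueError("axis must be 'rows' or 'columns'")
    z = _zscore_rows(matrix)
    data = z.to_numpy() if axis == "rows" else z.to_numpy().T
    labels = list(matrix.index) if axis == "rows" else list(matrix.columns)
    if data.shape[0] < 2:
        raise ValueError("need at least 2 items on the clustered axis")
    Z = linkage(data, method="average", metric="euclidean")
    return [labels[i] for i in leaves_list(Z)]


def logfc_concordance(
    fc_a: pd.Series,
    fc_b: pd.Series,
    calls_a: pd.Series | None = None,
    calls_b: pd.Series | None = None,
) -> ConcordanceResult:
    """Pearson concordance of two log2FC vectors on their shared genes.

    When deregulation calls are supplied, ``common_deregulated`` collects
    genes called up in both or down in both analyses.
    """
    shared = fc_a.index.intersection(fc_b.index)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared genes, found {len(shared)}")
    x = fc_a.loc[shared].to_numpy(dtype=float)
    y = fc_b.loc[shared].to_numpy(dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in a fold-change vector")
    res = stats.pearsonr(x, y)
    common: tuple[str, ...] = ()
    if calls_a is not None and calls_b is not None:
        ca = calls_a.reindex(shared)
        cb = calls_b.reindex(shared)
        both = ((ca == "up") & (cb == "up")) | ((ca == "down") & (cb == "down"))
        common = tuple(shared[both.fillna(False)])
    return ConcordanceResult(
        r=float(res.statistic), p=float(res.pvalue), n_genes=int(len(shared)),
        common_deregulated=common,
    )
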