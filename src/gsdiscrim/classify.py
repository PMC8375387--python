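"""PC-level cohort classification of gene-set scores and its resampling null.

The set x sample score matrix (restricted to a candidate set list) is
decomposed by PCA across samples; a designated principal component (default
the second) is tested for group separation (Welch t) and scored by ROC AUC,
where AUC is the Mann-Whitney pair probability that a condition sample's
coordinate exceeds a control sample's (ties count one half).

Because a principal component's sign is arbitrary, every component is
oriented deterministically so the condition-group mean coordinate is >= the
control-group mean (ties resolved by making the largest loading positive).
The same orientation is applied to the random-set null draws, so observed
and null AUCs are directly comparable.

Significance of the candidate list is assessed by drawing B random set
lists of the same size, recomputing the designated-component AUC per cohort,
and comparing the observed mean-across-cohorts AUC with the null draws via
the add-one right-tail estimator ``p = (1 + #{null >= obs}) / (B + 1)``.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .containers import DiscriminationReport, PCAResult, ResamplingResult
from .faime import SetScoreMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "pca_transform",
    "pc_separation_test",
    "roc_auc",
    "resample_random_sets",
    "discrimination_report",
]


def _standardized_sample_matrix(scores: SetScoreMatrix, standardize: bool) -> np.ndarray:
    """Samples x sets matrix, optionally z-scoring each set across samples."""
    X = scores.scores.to_numpy(dtype=float).T
    if standardize:
        mu = X.mean(axis=0, keepdims=True)
        sd = X.std(axis=0, ddof=1, keepdims=True)
        if (sd == 0).any():
            logger.warning("%d constant set(s) standardized to zeros", int((sd == 0).sum()))
        sd = np.where(sd == 0, 1.0, sd)
        X = (X - mu) / sd
    return X


def _condition_mask(scores: SetScoreMatrix) -> np.ndarray:
    ctrl, cond = scores.group_samples()
    cond_set = set(cond)
    return np.array([s in cond_set for s in scores.samples])


def _orient(coords: np.ndarray, loadings: np.ndarray, cond_mask: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    """Flip component signs so condition mean >= control mean (tie: largest loading positive)."""
    coords = coords.copy()
    loadings = loadings.copy()
    for j in range(coords.shape[1]):
        flip = False
        if cond_mask is not None:
            diff = coords[cond_mask, j].mean() - coords[~cond_mask, j].mean()
        else:
            diff = 0.0
        if diff < 0:
            flip = True
        elif diff == 0:
            lead = loadings[j, np.argmax(np.abs(loadings[j]))]
            flip = lead < 0
        if flip:
            coords[:, j] *= -1
            loadings[j] *= -1
    return coords, loadings


def pca_transform(
    scores: SetScoreMatrix,
    restrict: Sequence[str] | None = None,
    standardize: bool = True,
) -> PCAResult:
    """PCA of set scores across samples with a deterministic sign convention.

    ``standardize`` z-scores each set across samples first (correlation-mode
    PCA; sets have heterogeneous scales).  All ``min(n_samples, n_sets)``
    components are returned.
    """
    if restrict is not None:
        scores = scores.restrict(restrict)
    n_sets, n_samples = scores.scores.shape
    if n_sets < 2:
        raise ValueError("PCA requires at least 2 sets")
    if n_samples < 3:
        raise ValueError("PCA requires at least 3 samples")
    X = _standardized_sample_matrix(scores, standardize)
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float((S**2).sum())
    evr = (S**2) / total if total > 0 else np.zeros_like(S)
    coords = U * S
    cond_mask = _condition_mask(scores) if scores.groups is not None else None
    coords, Vt = _orient(coords, Vt, cond_mask)
    comp_names = [f"PC{i+1}" for i in range(len(S))]
    return PCAResult(
        coordinates=pd.DataFrame(coords, index=scores.samples, columns=comp_names),
        explained_variance_ratio=evr,
        components=pd.DataFrame(Vt, index=comp_names, columns=scores.set_names),
    )


def pc_separation_test(
    pca: PCAResult, scores: SetScoreMatrix, component: int = 2
) -> tuple[float, float]:
    """Welch two-sided t-test of the chosen component's coordinates between groups."""
    col = f"PC{component}"
    if col not in pca.coordinates.columns:
        raise ValueError(f"component {component} not available (have {pca.coordinates.shape[1]})")
    ctrl, cond = scores.group_samples()
    a = pca.coordinates.loc[cond, col].to_numpy()
    b = pca.coordinates.loc[ctrl, col].to_numpy()
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("zero variance in both groups on this component")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def _pair_auc(values: np.ndarray, cond_mask: np.ndarray) -> float:
    """Mann-Whitney AUC: P(condition > control) with ties counted 1/2."""
    n_cond = int(cond_mask.sum())
    n_ctrl = int((~cond_mask).sum())
    r = rankdata(values)
    return float((r[cond_mask].sum() - n_cond * (n_cond + 1) / 2) / (n_cond * n_ctrl))


def roc_auc(
    values: pd.Series | np.ndarray,
    groups: pd.Series,
    condition: str,
) -> tuple[float, pd.DataFrame]:
    """AUC and ROC points for a per-sample scalar against two-class labels."""
    if isinstance(values, pd.Series):
        groups = groups.reindex(values.index)
        v = values.to_numpy(dtype=float)
    else:
        v = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    cond_mask = labels == condition
    if cond_mask.all() or (~cond_mask).all():
        raise ValueError("both classes must be present")
    auc = _pair_auc(v, cond_mask)
    fpr, tpr, thr = roc_curve(cond_mask.astype(int), v)
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return auc, roc


def _component_auc(Xsub: np.ndarray, component: int, cond_mask: np.ndarray) -> float:
    """Oriented designated-component AUC for a samples x sets submatrix."""
    Xc = Xsub - Xsub.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    if component > len(S):
        raise ValueError(f"component {component} not available for {Xsub.shape[1]} sets")
    c = U[:, component - 1] * S[component - 1]
    diff = c[cond_mask].mean() - c[~cond_mask].mean()
    if diff < 0:
        c = -c
    elif diff == 0 and Vt[component - 1, np.argmax(np.abs(Vt[component - 1]))] < 0:
        c = -c
    return _pair_auc(c, cond_mask)


def resample_random_sets(
    cohorts: Sequence[SetScoreMatrix],
    candidate_sets: Sequence[str],
    B: int = 1000,
    component: int = 2,
    seed: int | None = None,
    standardize: bool = True,
) -> ResamplingResult:
    """Random-gene-set null for the candidate list's mean cohort AUC.

    Each draw picks ``len(candidate_sets)`` set names uniformly without
    replacement from the sets scored in every cohort, recomputes the
    designated-component AUC in each cohort, and records the mean across
    cohorts.  ``p_right = (1 + #{null >= observed}) / (B + 1)``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    candidate = list(candidate_sets)
    if len(candidate) < 2:
        raise ValueError("need at least 2 candidate sets")
    available = set(cohorts[0].set_names)
    for c in cohorts[1:]:
        available &= set(c.set_names)
    missing = [s for s in candidate if s not in available]
    if missing:
        raise ValueError(f"candidate sets not scored in every cohort: {missing[:5]}")
    pool = sorted(available)
    k = len(candidate)
    if k > len(pool):
        raise ValueError(f"candidate size {k} exceeds available sets ({len(pool)})")

    states = []
    for c in cohorts:
        X = _standardized_sample_matrix(c, standardize)
        cond_mask = _condition_mask(c)
        col = {name: i for i, name in enumerate(c.set_names)}
        states.append((X, cond_mask, col))

    def mean_auc(names: Sequence[str]) -> float:
        total = 0.0
        for X, cond_mask, col in states:
            idx = np.array([col[n] for n in names])
            total += _component_auc(X[:, idx], component, cond_mask)
        return total / len(states)

    observed = mean_auc(candidate)
    rng = np.random.default_rng(seed)
    pool_arr = np.asarray(pool)
    null = np.empty(B)
    for b in range(B):
        draw = pool_arr[rng.choice(len(pool_arr), size=k, replace=False)]
        null[b] = mean_auc(draw)
    p_right = (1 + int((null >= observed).sum())) / (B + 1)
    return ResamplingResult(B=B, candidate_size=k, observed=observed,
                            null_aucs=null, p_right=p_right)


def discrimination_report(
    scores: SetScoreMatrix,
    candidate_sets: Sequence[str] | None = None,
    component: int = 2,
    standardize: bool = True,
) -> DiscriminationReport:
    """PCA + per-component Welch tests and AUCs for one cohort."""
    sub = scores.restrict(candidate_sets) if candidate_sets is not None else scores
    pca = pca_transform(sub, standardize=standardize)
    cond_mask = _condition_mask(sub)
    rows = {}
    aucs = {}
    for j, col in enumerate(pca.coordinates.columns, start=1):
        c = pca.coordinates[col].to_numpy()
        a, b = c[cond_mask], c[~cond_mask]
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            t = p = np.nan
        else:
            res = stats.ttest_ind(a, b, equal_var=False)
            t, p = float(res.statistic), float(res.pvalue)
        rows[col] = {"t": t, "p": p}
        aucs[col] = _pair_auc(c, cond_mask)
    return DiscriminationReport(
        pca=pca,
        pc_tests=pd.DataFrame(rows).T,
        aucs=pd.Series(aucs, name="auc"),
        component=component,
    )
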