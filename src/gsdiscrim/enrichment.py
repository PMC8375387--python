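"""Over-representation analysis of a gene list against a gene-set collection.

For each set, the one-sided Fisher / cumulative hypergeometric tail
``P[X >= k]`` is computed for the 2x2 table (list x set) within a declared
gene universe, and Benjamini-Hochberg adjustment is applied across the sets
actually tested (after a minimum-overlap filter).  Only enrichment (not
depletion) is tested.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .containers import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = ["bh_adjust", "fisher_enrichment"]


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, output in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return p_adj


def fisher_enrichment(
    gene_list: Iterable[str],
    universe: Iterable[str],
    sets: GeneSetCollection,
    min_overlap_genes: int = 3,
) -> pd.DataFrame:
    """One-sided Fisher enrichment of ``gene_list`` in each set, BH-corrected.

    Each set is intersected with the universe first; sets whose intersection
    has fewer than ``min_overlap_genes`` members are excluded from testing
    (and from the BH family).  Returns a table sorted by raw p ascending
    with columns ``k, K, n, N, p, p_adj``.
    """
    genes = set(gene_list)
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    outside = sorted(genes - uni)
    if outside:
        raise ValueError(f"gene list not contained in universe; offending genes: {outside[:10]}")
    N, n = len(uni), len(genes)

    rows = []
    skipped = 0
    for name in sets.names:
        members = sets[name] & uni
        K = len(members)
        if K < min_overlap_genes:
            skipped += 1
            continue
        k = len(members & genes)
        rows.append((name, k, K))
    if skipped:
        logger.info("fisher_enrichment: %d set(s) below min_overlap_genes=%d excluded",
                    skipped, min_overlap_genes)
    if not rows:
        return pd.DataFrame(columns=["k", "K", "n", "N", "p", "p_adj"])

    names = [r[0] for r in rows]
    k_arr = np.array([r[1] for r in rows])
    K_arr = np.array([r[2] for r in rows])
    # P[X >= k] for X ~ Hypergeom(N, K, n)
    p = hypergeom.sf(k_arr - 1, N, K_arr, n)
    p = np.clip(p, 0.0, 1.0)
    table = pd.DataFrame(
        {"k": k_arr, "K": K_arr, "n": n, "N": N, "p": p, "p_adj": bh_adjust(p)},
        index=pd.Index(names, name="set"),
    )
    return table.sort_values("p", kind="stable")
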