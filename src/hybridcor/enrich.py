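"""Functional-category distribution tables and hypergeometric enrichment.

Overrepresentation of a selected gene set against a background (by default
the differential set) is tested with the upper tail of the hypergeometric
distribution: with N annotated background genes, K of them in the category,
and n annotated query genes, p = P(X >= k).  The tail is summed in log space
for numerical stability at small p.  Genes may belong to several categories;
they count in every one, so distribution percentages need not sum to 100.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .diffexpr import adjust_fdr
from .io import DataError, logger


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise DataError(f"inconsistent counts N={N}, K={K}, n={n}")
    if not 0 <= k <= min(K, n):
        raise DataError(f"k={k} outside support [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    support = np.arange(k, min(K, n) + 1)
    if support.size == 0:
        return 1.0
    logp = stats.hypergeom.logpmf(support, N, K, n)
    return float(min(1.0, np.exp(logsumexp(logp))))


def enrich_categories(
    categories: dict, background: set, query: set, include_empty: bool = False
) -> pd.DataFrame:
    """One record per category: N, K, n, k, upper-tail p and BH q.

    The universe is the *annotated* background (background genes in at least
    one category); query genes outside the background are logged and dropped.
    """
    stray = query - background
    if stray:
        logger.warning("%d query genes outside the background were dropped", len(stray))
        query = query & background
    annotated = {g for members in categories.values() for g in members}
    bg = background & annotated
    if not bg:
        raise DataError("no background gene is annotated to any category")
    qu = query & annotated
    N, n = len(bg), len(qu)
    rows = []
    for name, members in categories.items():
        K = len(members & bg)
        k = len(members & qu)
        if K == 0 or (k == 0 and not include_empty):
            continue
        rows.append((name, N, K, n, k, hypergeom_upper_tail(N, K, n, k)))
    out = pd.DataFrame(rows, columns=["category", "N", "K", "n", "k", "p"]).set_index("category")
    if len(out):
        out["q"] = adjust_fdr(out["p"].to_numpy())
    else:
        out["q"] = pd.Series(dtype=float)
    logger.info("enrichment: %d categories tested (N=%d, n=%d)", len(out), N, n)
    return out


def category_table(
    categories: dict, background: set, query_sets: dict[str, set]
) -> pd.DataFrame:
    """Distribution table: per category and per labelled gene set, the member
    count and its percentage of that set's annotated genes."""
    annotated = {g for members in categories.values() for g in members}
    sets = {"background": background & annotated}
    for label, genes in query_sets.items():
        sets[label] = genes & background & annotated
    rows = []
    for name, members in categories.items():
        row = {"category": name}
        for label, genes in sets.items():
            count = len(members & genes)
            row[f"n_{label}"] = count
            row[f"pct_{label}"] = (
                round(100.0 * count / len(genes), 1) if genes else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("category")
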