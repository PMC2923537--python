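"""Mid-parent expression, heterosis, and gene-trait correlation statistics.

For each hybrid the predictor is L, the average log2 expression of a gene in
the hybrid's two parental lines.  Correlations of L with hybrid performance
(PY, PD) and mid-parent heterosis (HY, HD) are tested with a t-test on n - 2
degrees of freedom, BH-FDR adjusted, and interval-estimated with the
bias-corrected accelerated (BCa) bootstrap.  The trait-trait correlation is
tested by Monte Carlo permutation.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import adjust_fdr
from .io import DataError, FactorialDesign, TraitTable, logger

TRAITS = ("PY", "HY", "PD", "HD")


def compute_midparent(line_means: pd.DataFrame, design: FactorialDesign) -> pd.DataFrame:
    """Probe x hybrid matrix L = (flint-parent mean + dent-parent mean) / 2."""
    cols = {}
    for hybrid, p1, p2 in design.parent_pairs():
        for parent in (p1, p2):
            if parent not in line_means.columns:
                raise DataError(f"hybrid {hybrid!r}: parent {parent!r} missing from line means")
        cols[hybrid] = (line_means[p1].to_numpy() + line_means[p2].to_numpy()) / 2.0
    return pd.DataFrame(cols, index=line_means.index)


def compute_heterosis(
    traits: TraitTable, line_perse: pd.DataFrame, design: FactorialDesign
) -> pd.DataFrame:
    """Mid-parent heterosis per hybrid: H = F1 value - mean(parent per-se
    values), on the absolute trait scale (Mg/ha for HY, percent for HD)."""
    rows = {}
    for hybrid, p1, p2 in design.parent_pairs():
        for parent in (p1, p2):
            if parent not in line_perse.index:
                raise DataError(f"hybrid {hybrid!r}: per-se values missing for {parent!r}")
        mid_y = (line_perse.at[p1, "yield_perse"] + line_perse.at[p2, "yield_perse"]) / 2.0
        mid_d = (line_perse.at[p1, "gdmc_perse"] + line_perse.at[p2, "gdmc_perse"]) / 2.0
        rows[hybrid] = (
            traits.table.at[hybrid, "PY"] - mid_y,
            traits.table.at[hybrid, "PD"] - mid_d,
        )
    return pd.DataFrame.from_dict(rows, orient="index", columns=["HY", "HD"]).rename_axis(
        "hybrid_id"
    )


# ---------------------------------------------------------------------------
# correlation + t-test
# ---------------------------------------------------------------------------

def correlate_trait(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Pearson r with t = r sqrt(n-2)/sqrt(1-r^2) and its two-sided p on
    n - 2 df.  Returns (nan, nan, nan) for a constant vector so one degenerate
    probe cannot kill a batch."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise DataError(f"correlation needs n >= 3 hybrids, got {n}")
    if x.std() == 0 or y.std() == 0:
        return math.nan, math.nan, math.nan
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if 1.0 - abs(r) < 1e-12:  # numerically exact collinearity
        r = math.copysign(1.0, r)
    if abs(r) == 1.0:
        return r, math.copysign(math.inf, r), 0.0
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, t, min(p, 1.0)


def correlate_matrix(L: pd.DataFrame, trait: pd.Series) -> pd.DataFrame:
    """Vectorised correlate_trait over the rows of L against one trait.

    Returns a frame with r, t, p, q (BH over the defined rows)."""
    y = trait.loc[L.columns].to_numpy(dtype=float)
    n = y.size
    if n < 3:
        raise DataError(f"correlation needs n >= 3 hybrids, got {n}")
    x = L.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = math.sqrt((yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ yc) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    defined = (sx > 0) & (sy > 0)
    r[~defined] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * math.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    p = np.where(np.abs(r) == 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), n - 2))
    p = np.minimum(p, 1.0)
    q = np.full_like(p, np.nan)
    q[defined] = adjust_fdr(p[defined])
    return pd.DataFrame({"r": r, "t": t, "p": p, "q": q}, index=L.index)


def correlation_records(
    L: pd.DataFrame, traits: pd.DataFrame, trait_names=TRAITS
) -> pd.DataFrame:
    """Wide per-probe table with r_X, t_X, p_X, q_X for each requested trait."""
    parts = []
    for name in trait_names:
        if name not in traits.columns:
            continue
        sub = correlate_matrix(L, traits[name])
        parts.append(sub.add_suffix(f"_{name}"))
    out = pd.concat(parts, axis=1)
    logger.info("correlations: %d probes x %d traits over %d hybrids",
                len(out), len(parts), L.shape[1])
    return out


# ---------------------------------------------------------------------------
# BCa bootstrap
# ---------------------------------------------------------------------------

def _pearson_rows(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    xc = xs - xs.mean(axis=1, keepdims=True)
    yc = ys - ys.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        return (xc * yc).sum(axis=1) / denom


def bca_ci(
    x: np.ndarray,
    y: np.ndarray,
    B: int = 10000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """BCa bootstrap interval for the Pearson correlation of paired data.

    Pairs are resampled with replacement; the bias correction z0 uses
    half-weight for resample statistics tied with the estimate, and the
    acceleration a is the jackknife skewness
    a = sum(m - th_i)^3 / (6 [sum(m - th_i)^2]^{3/2}).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4:
        raise DataError(f"BCa bootstrap needs n >= 4 pairs, got {n}")
    theta_hat, _, _ = correlate_trait(x, y)
    if math.isnan(theta_hat):
        raise DataError("BCa bootstrap: constant input vector")

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    theta_star = _pearson_rows(x[idx], y[idx])
    theta_star = theta_star[np.isfinite(theta_star)]
    if theta_star.size == 0 or np.ptp(theta_star) == 0:
        logger.info("degenerate bootstrap distribution; returning point interval")
        return theta_hat, theta_hat

    B_eff = theta_star.size
    prop = ((theta_star < theta_hat).sum() + 0.5 * (theta_star == theta_hat).sum()) / B_eff
    prop = min(max(prop, 0.5 / B_eff), 1.0 - 0.5 / B_eff)
    z0 = stats.norm.ppf(prop)

    # jackknife acceleration
    sx, sy, sxx, syy, sxy = x.sum(), y.sum(), (x**2).sum(), (y**2).sum(), (x * y).sum()
    m = n - 1
    mx = (sx - x) / m
    my = (sy - y) / m
    vx = (sxx - x**2) / m - mx**2
    vy = (syy - y**2) / m - my**2
    cxy = (sxy - x * y) / m - mx * my
    with np.errstate(divide="ignore", invalid="ignore"):
        theta_i = cxy / np.sqrt(vx * vy)
    theta_i = theta_i[np.isfinite(theta_i)]
    dev = theta_i.mean() - theta_i
    denom = (dev**2).sum() ** 1.5
    a = 0.0 if denom == 0 else (dev**3).sum() / (6.0 * denom)

    alpha = (1.0 - level) / 2.0
    lo_hi = []
    for z_a in (stats.norm.ppf(alpha), stats.norm.ppf(1.0 - alpha)):
        adj = z0 + (z0 + z_a) / (1.0 - a * (z0 + z_a))
        lo_hi.append(float(np.quantile(theta_star, stats.norm.cdf(adj))))
    return lo_hi[0], lo_hi[1]


# ---------------------------------------------------------------------------
# trait-trait permutation test
# ---------------------------------------------------------------------------

def trait_permutation_test(
    y1: np.ndarray, y2: np.ndarray, n_perm: int = 9999, seed: int = 0
) -> tuple[float, float]:
    """Two-sided Monte Carlo permutation test of the Pearson correlation.

    p = (1 + #{|r_perm| >= |r_obs|}) / (n_perm + 1); the minimum attainable p
    is therefore 1/(n_perm + 1).  Returns (r_obs, p)."""
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    if y1.size != y2.size or y1.size < 3:
        raise DataError("permutation test needs equal-length vectors with n >= 3")
    if y1.std() == 0 or y2.std() == 0:
        raise DataError("permutation test: constant vector")
    r_obs, _, _ = correlate_trait(y1, y2)
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(y2, (n_perm, 1)), axis=1)
    r_perm = _pearson_rows(np.tile(y1, (n_perm, 1)), perms)
    p = (1.0 + (np.abs(r_perm) >= abs(r_obs)).sum()) / (n_perm + 1.0)
    return r_obs, float(p)
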