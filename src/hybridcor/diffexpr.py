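"""Differential-expression screen across parental inbred lines.

The screen mirrors a classic microarray workflow: a reliability threshold set
from spike-in control probes (mean + 3 sd of all spike-in intensities), a
fold-change prefilter (ratio > 1.3, i.e. |delta log2 line means| >
log2(1.3)), an empirical-Bayes moderated F-test of equal line means with
BH-FDR control at 0.01, nested pairwise (per line pair) moderated tests, and
a final fold-change / mean-intensity (> 8.0 log2) filter.

The moderated test shrinks each probe's residual variance s^2 (d residual df)
toward a prior (d0, s0^2) estimated across probes by moment matching of
log s^2 via digamma/trigamma inversion; the posterior variance is
s~^2 = (d0 s0^2 + d s^2) / (d0 + d) and the F statistic gains d0 denominator
degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .io import DataError, ExpressionMatrix, FactorialDesign, logger


@dataclass(frozen=True)
class PriorEstimate:
    """Empirical-Bayes variance prior: d0 prior df (may be +inf), s0sq prior
    variance on the log2 scale."""

    d0: float
    s0sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0 and self.s0sq > 0):
            raise ValueError(f"invalid prior d0={self.d0}, s0sq={self.s0sq}")


# ---------------------------------------------------------------------------
# reliability threshold
# ---------------------------------------------------------------------------

def reliability_threshold(spikein_values: np.ndarray) -> float:
    """Mean + 3 * sample sd (divisor n-1) of all spike-in intensities."""
    v = np.asarray(spikein_values, dtype=float).ravel()
    if v.size < 2:
        raise DataError("reliability threshold needs >= 2 spike-in values")
    return float(v.mean() + 3.0 * v.std(ddof=1))


# ---------------------------------------------------------------------------
# moderated F-test
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on 1/trigamma, monotone)."""
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_prior(s2: np.ndarray, df: float) -> PriorEstimate:
    """Moment-matching fit of a scaled inverse-chi-square prior to observed
    residual variances s2 with ``df`` degrees of freedom each."""
    s2 = np.asarray(s2, dtype=float)
    pos = s2[s2 > 0]
    if pos.size == 0:
        logger.warning("all residual variances are zero; falling back to d0=inf")
        return PriorEstimate(d0=math.inf, s0sq=1e-8)
    z = np.log(pos)
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0 or pos.size < 2:
        logger.info("no excess log-variance dispersion; using d0=inf")
        return PriorEstimate(d0=math.inf, s0sq=float(np.exp(emean)))
    half_d0 = _trigamma_inverse(evar)
    d0 = 2.0 * half_d0
    s0sq = float(np.exp(emean + special.digamma(half_d0) - math.log(half_d0)))
    return PriorEstimate(d0=d0, s0sq=s0sq)


def _anova_pieces(values: np.ndarray, line_idx: np.ndarray, n_lines: int):
    """Per-probe one-way ANOVA pieces for groups given by line_idx."""
    counts = np.bincount(line_idx, minlength=n_lines).astype(float)
    n = values.shape[1]
    sums = np.zeros((values.shape[0], n_lines))
    np.add.at(sums.T, line_idx, values.T)
    means = sums / counts
    grand = values.mean(axis=1)
    ss_between = ((means - grand[:, None]) ** 2 * counts).sum(axis=1)
    fitted = means[:, line_idx]
    ss_resid = ((values - fitted) ** 2).sum(axis=1)
    df_b = n_lines - 1
    df_r = n - n_lines
    return means, counts, ss_between, ss_resid, df_b, df_r


def moderated_f_test(
    values: pd.DataFrame, sample_lines: pd.Series
) -> tuple[PriorEstimate, pd.DataFrame]:
    """Empirical-Bayes moderated one-way F-test of equal line means.

    ``values``: probe x sample log2 matrix; ``sample_lines``: line_id per
    sample column.  Returns the estimated prior and a per-probe frame with
    F, p, s2, s2_post and the line means.
    """
    lines, line_idx = np.unique(np.asarray(sample_lines), return_inverse=True)
    k = len(lines)
    if k < 2:
        raise DataError("moderated F-test needs >= 2 lines")
    counts = np.bincount(line_idx)
    if counts.min() < 2:
        raise DataError(
            "every line needs >= 2 replicates for a per-probe residual variance; "
            f"line {lines[counts.argmin()]!r} has {counts.min()}"
        )
    x = values.to_numpy(dtype=float)
    means, cnts, ssb, ssr, df_b, df_r = _anova_pieces(x, line_idx, k)
    s2 = ssr / df_r
    prior = estimate_prior(s2, df_r)
    s2_post = _posterior_var(s2, df_r, prior)
    f = (ssb / df_b) / s2_post
    p = _f_pvalue(f, df_b, df_r + prior.d0)
    out = pd.DataFrame({"F": f, "p": p, "s2": s2, "s2_post": s2_post}, index=values.index)
    means_df = pd.DataFrame(means, index=values.index, columns=lines)
    out = pd.concat([out, means_df.add_prefix("mean:")], axis=1)
    return prior, out


def _posterior_var(s2: np.ndarray, df: float, prior: PriorEstimate) -> np.ndarray:
    if math.isinf(prior.d0):
        return np.full_like(np.asarray(s2, dtype=float), prior.s0sq)
    return (prior.d0 * prior.s0sq + df * s2) / (prior.d0 + df)


def _f_pvalue(f: np.ndarray, df1: float, df2: float) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    if math.isinf(df2):
        return stats.chi2.sf(f * df1, df1)
    return stats.f.sf(f, df1, df2)


def nested_pair_tests(
    line_means: pd.DataFrame,
    s2_post: np.ndarray,
    df_total: float,
    rep_counts: pd.Series,
    pairs: list[tuple[str, str, str]],
) -> dict[str, pd.DataFrame]:
    """Moderated pairwise tests for each (hybrid, flint parent, dent parent).

    The squared moderated t of the pair contrast is referred to
    F(1, d0 + d); q is BH-adjusted across probes within each pair.
    Returns per-hybrid frames with delta (log2 fc), p and q.
    """
    out = {}
    for hybrid, p1, p2 in pairs:
        for parent in (p1, p2):
            if parent not in line_means.columns:
                raise DataError(f"hybrid {hybrid!r}: parent line {parent!r} absent from matrix")
        delta = line_means[p1].to_numpy() - line_means[p2].to_numpy()
        scale = 1.0 / rep_counts[p1] + 1.0 / rep_counts[p2]
        t2 = delta**2 / (s2_post * scale)
        p = _f_pvalue(t2, 1.0, df_total)
        q = multipletests(p, method="fdr_bh")[1]
        out[hybrid] = pd.DataFrame(
            {"delta": delta, "p": p, "q": q}, index=line_means.index
        )
    return out


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

def adjust_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# the full screen
# ---------------------------------------------------------------------------

@dataclass
class DEScreen:
    """Result of the differential-expression screen."""

    table: pd.DataFrame          # per gene probe: F, p, q, flags, fold change, intensity
    prior: PriorEstimate
    threshold: float             # spike-in reliability threshold (log2)
    spikein_min_q: float         # smallest adjusted p among spike-in probes
    nested: dict                 # hybrid_id -> per-probe pairwise frame
    df_total: float              # denominator df of the moderated tests

    @property
    def de_ids(self) -> pd.Index:
        return self.table.index[self.table["de_pass"]]


def select_differential(
    expr: ExpressionMatrix,
    cfg: PipelineConfig,
    design: FactorialDesign | None = None,
) -> DEScreen:
    """Run the full screen; spike-ins are tested alongside the gene probes
    (their smallest adjusted p is reported as a calibration diagnostic) but
    never enter the differential set."""
    threshold = reliability_threshold(expr.spikein_values())
    prior, mod = moderated_f_test(expr.values, expr.sample_lines())
    mean_cols = [c for c in mod.columns if c.startswith("mean:")]
    line_means = mod[mean_cols].rename(columns=lambda c: c[5:])

    spikein = expr.is_spikein().to_numpy()
    reliable = (line_means.to_numpy() > threshold).sum(axis=1) >= cfg.min_lines
    max_fc = line_means.max(axis=1).to_numpy() - line_means.min(axis=1).to_numpy()
    fc_pass = max_fc > math.log2(cfg.fc_min)
    if cfg.intensity_summary == "mean":
        intensity = line_means.mean(axis=1).to_numpy()
    else:
        intensity = line_means.max(axis=1).to_numpy()
    intensity_pass = intensity > cfg.intensity_min

    # multiplicity is controlled within the tested family: gene probes passing
    # the reliability (and, by default, fold-change) prefilters, plus all
    # spike-ins, which ride along as negative controls
    tested = reliable.copy()
    if cfg.prefilter_fc:
        tested &= fc_pass
    tested |= spikein
    q = np.full(len(mod), np.nan)
    q[tested] = adjust_fdr(mod["p"].to_numpy()[tested])
    sig = np.zeros(len(mod), dtype=bool)
    sig[tested] = q[tested] <= cfg.fdr_de

    de_pass = reliable & fc_pass & sig & intensity_pass & ~spikein
    table = pd.DataFrame(
        {
            "F": mod["F"],
            "p": mod["p"],
            "q": q,
            "max_abs_log2fc": max_fc,
            "mean_intensity": intensity,
            "reliable": reliable,
            "fc_pass": fc_pass,
            "intensity_pass": intensity_pass,
            "sig_pass": sig,
            "de_pass": de_pass,
            "is_spikein": spikein,
        },
        index=expr.probe_ids,
    )

    spike_q = q[spikein]
    spikein_min_q = float(np.nanmin(spike_q)) if np.isfinite(spike_q).any() else math.nan

    rep_counts = expr.sample_lines().value_counts()
    df_r = expr.values.shape[1] - line_means.shape[1]
    nested = {}
    if design is not None:
        nested = nested_pair_tests(
            line_means, mod["s2_post"].to_numpy(), df_r + prior.d0, rep_counts,
            design.parent_pairs(),
        )
    logger.info(
        "DE screen: threshold=%.3f, prior d0=%.2f s0sq=%.4f, %d/%d probes differential, "
        "min spike-in q=%.3g",
        threshold, prior.d0, prior.s0sq, int(de_pass.sum()), len(table), spikein_min_q,
    )
    return DEScreen(
        table=table, prior=prior, threshold=threshold,
        spikein_min_q=spikein_min_q, nested=nested, df_total=df_r + prior.d0,
    )


def per_hybrid_de_counts(
    screen: DEScreen, design: FactorialDesign, cfg: PipelineConfig
) -> pd.DataFrame:
    """Per hybrid: differential probes whose parental pair is itself
    significant (nested q <= fdr_de) with pairwise fold change > fc_min.
    Adds the mean over hybrids and its percentage of all gene probes."""
    if not screen.nested:
        raise DataError("nested pairwise tests missing; rerun select_differential with a design")
    de = screen.table["de_pass"]
    n_genes = int((~screen.table["is_spikein"]).sum())
    rows = []
    for hybrid, _, _ in design.parent_pairs():
        sub = screen.nested[hybrid]
        hit = de & (sub["q"] <= cfg.fdr_de) & (sub["delta"].abs() > math.log2(cfg.fc_min))
        rows.append((hybrid, int(hit.sum())))
    out = pd.DataFrame(rows, columns=["hybrid_id", "n_de"]).set_index("hybrid_id")
    out.attrs["mean_de"] = float(out["n_de"].mean())
    out.attrs["mean_de_percent"] = percent(out["n_de"].mean(), n_genes)
    return out


def percent(count: float, total: float, ndigits: int = 1) -> float:
    """Share of ``count`` in ``total`` as a percentage rounded to ndigits."""
    if total <= 0:
        raise DataError("percent: total must be positive")
    return round(100.0 * count / total, ndigits)
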