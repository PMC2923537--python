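"""Line-resampling cross-validation of gene-ranking stability.

Each round samples 3 of the flint and 5 of the dent parental lines without
replacement; the estimation set is the 15 hybrids whose parents were both
sampled.  Gene-trait correlations are recomputed on the estimation set and
genes ranked by smallest p (ties by |r| descending, then probe id).  Two
overlap summaries are reported: the mean per-round overlap of the top-k list
with the full-data top-k, and the overlap of the top-k by selection frequency
across rounds with the full-data top-k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .correlate import correlate_matrix
from .io import DataError, FactorialDesign, logger


@dataclass
class CVResult:
    rounds: list          # per round: dict(lines, hybrids, top)
    top_full: list        # full-data top-k probe ids
    overlaps: np.ndarray  # per-round |top(round) & top(full)|
    frequencies: pd.Series  # per gene: rounds in which it entered the top-k
    k: int

    @property
    def mean_overlap(self) -> float:
        return float(self.overlaps.mean())


def rank_genes(stats: pd.DataFrame, k: int | None = None) -> list:
    """Order probes by (p asc, |r| desc, probe id); optionally truncate to k."""
    tab = stats.loc[sorted(stats.index)]  # id order first; stable sort keeps it for ties
    tab = tab.assign(_absr=tab["r"].abs()).sort_values(
        by=["p", "_absr"], ascending=[True, False], kind="mergesort"
    )
    order = list(tab.index)
    return order if k is None else order[:k]


def run_crossvalidation(
    L: pd.DataFrame,
    design: FactorialDesign,
    trait: pd.Series,
    cfg: PipelineConfig,
    seed: int = 0,
    n_flint_sample: int = 3,
    n_dent_sample: int = 5,
) -> CVResult:
    """Run cfg.cv_rounds rounds for one trait; deterministic given seed."""
    k = cfg.cv_top
    if k > len(L):
        raise DataError(f"cv_top={k} exceeds candidate gene count {len(L)}")
    flint = sorted(design.table["flint_parent"].unique())
    dent = sorted(design.table["dent_parent"].unique())
    if n_flint_sample > len(flint) or n_dent_sample > len(dent):
        raise DataError("cannot sample more lines than the design contains")

    full_stats = correlate_matrix(L, trait)
    top_full = rank_genes(full_stats.dropna(subset=["p"]), k)
    top_full_set = set(top_full)

    rng = np.random.default_rng(seed)
    freq = pd.Series(0, index=L.index, dtype=int)
    rounds, overlaps = [], np.zeros(cfg.cv_rounds)
    for rnd in range(cfg.cv_rounds):
        fl = sorted(rng.choice(flint, size=n_flint_sample, replace=False))
        dn = sorted(rng.choice(dent, size=n_dent_sample, replace=False))
        sub = design.table[
            design.table["flint_parent"].isin(fl) & design.table["dent_parent"].isin(dn)
        ]
        hybrids = list(sub["hybrid_id"])
        stats = correlate_matrix(L[hybrids], trait.loc[hybrids])
        top = rank_genes(stats.dropna(subset=["p"]), k)
        freq[top] += 1
        overlaps[rnd] = len(top_full_set.intersection(top))
        rounds.append({"lines": fl + dn, "hybrids": hybrids, "top": top})

    result = CVResult(rounds=rounds, top_full=top_full, overlaps=overlaps,
                      frequencies=freq, k=k)
    logger.info("cross-validation: %d rounds, k=%d, mean overlap %.1f",
                cfg.cv_rounds, k, result.mean_overlap)
    return result


def overlap_metrics(cv: CVResult, full_stats: pd.DataFrame | None = None) -> dict:
    """(a) mean per-round top-k overlap with the full-data top-k and (b) the
    overlap of the frequency-ranked top-k with the full-data top-k."""
    rank_in_full = {pid: i for i, pid in enumerate(cv.top_full)}
    by_freq = sorted(
        cv.frequencies.index,
        key=lambda pid: (-cv.frequencies[pid], rank_in_full.get(pid, len(rank_in_full)), pid),
    )[: cv.k]
    freq_overlap = len(set(by_freq) & set(cv.top_full))
    return {
        "mean_overlap": cv.mean_overlap,
        "frequency_rank_overlap": freq_overlap,
        "k": cv.k,
    }
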