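"""Two-step correlation selection of trait-associated gene sets.

Step 1 takes every gene whose mid-parent expression correlates with the
trait at p < alpha_step1 (grain yield: PY or HY; grain dry matter content:
PD only, since heterosis for dry matter content is negligible in maize).
Step 2 iterates over the remaining genes significant at p < alpha_step2 and
adds any whose mid-parent profile is co-expressed (signed Pearson r >
r_coexpr) with a gene already in the set, repeating until a fixpoint.  The
update is synchronous: a candidate is certified only against the set from the
previous iteration, so the result does not depend on processing order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .io import DataError, logger

TRAIT_COLUMNS = {"yield": ("PY", "HY"), "gdmc": ("PD",)}


@dataclass
class SelectionResult:
    """A selected gene set with per-gene provenance."""

    trait: str                 # 'yield' or 'gdmc'
    members: pd.DataFrame      # probe_id idx: step, iteration, r, p, sign, certifier, r_coexpr
    n_iterations: int
    alpha_step1: float
    alpha_step2: float
    r_coexpr: float

    @property
    def ids(self) -> pd.Index:
        return self.members.index

    @property
    def step1_ids(self) -> pd.Index:
        return self.members.index[self.members["step"] == 1]

    def summary(self) -> dict:
        n1 = int((self.members["step"] == 1).sum())
        n2 = int((self.members["step"] == 2).sum())
        n_pos = int((self.members["sign"] == "P").sum())
        n_neg = int((self.members["sign"] == "N").sum())
        return {
            "trait": self.trait,
            "n_step1": n1,
            "n_step2": n2,
            "n_total": n1 + n2,
            "n_positive": n_pos,
            "n_negative": n_neg,
            "n_iterations": self.n_iterations,
        }


def _best_trait_stat(correlations: pd.DataFrame, trait: str, on: str) -> pd.DataFrame:
    """Per probe: the smallest trait p (raw or q per config) and the r of the
    trait correlation with the largest |r|, over the trait's statistic set."""
    cols = TRAIT_COLUMNS[trait]
    stat = "p" if on == "raw" else "q"
    ps = np.column_stack([correlations[f"{stat}_{c}"].to_numpy(dtype=float) for c in cols])
    rs = np.column_stack([correlations[f"r_{c}"].to_numpy(dtype=float) for c in cols])
    with np.errstate(invalid="ignore"):
        best_p = np.nanmin(ps, axis=1) if ps.shape[1] > 1 else ps[:, 0]
    absr = np.abs(rs)
    absr[np.isnan(absr)] = -1.0
    pick = absr.argmax(axis=1)
    best_r = rs[np.arange(len(rs)), pick]
    return pd.DataFrame({"p": best_p, "r": best_r}, index=correlations.index)


def select_trait_genes(
    correlations: pd.DataFrame,
    L: pd.DataFrame,
    trait: str,
    cfg: PipelineConfig,
) -> SelectionResult:
    """Run the two-step selection for 'yield' or 'gdmc'.

    ``correlations`` is the wide per-probe table from
    :func:`hybridcor.correlate.correlation_records`, restricted to the
    candidate probes (the differential set); ``L`` holds their mid-parent
    profiles for the co-expression gate.
    """
    if trait not in TRAIT_COLUMNS:
        raise DataError(f"unknown trait {trait!r}; expected 'yield' or 'gdmc'")
    stats_ = _best_trait_stat(correlations, trait, cfg.threshold_on)
    defined = stats_["p"].notna()
    stats_ = stats_[defined]

    in_set = stats_["p"] < cfg.alpha_step1
    pool = (stats_["p"] < cfg.alpha_step2) & ~in_set

    records: dict[str, tuple] = {
        pid: (1, 0, stats_.at[pid, "r"], stats_.at[pid, "p"], "", np.nan)
        for pid in stats_.index[in_set]
    }

    # co-expression on the mid-parent profiles of pool + members
    active = stats_.index[in_set | pool]
    Lx = L.loc[active].to_numpy(dtype=float)
    Lc = Lx - Lx.mean(axis=1, keepdims=True)
    norms = np.sqrt((Lc**2).sum(axis=1))
    norms[norms == 0] = np.nan
    Ln = Lc / norms[:, None]
    pos = {pid: i for i, pid in enumerate(active)}

    member_ids = list(records)
    iteration = 0
    while True:
        pool_ids = [pid for pid in stats_.index[pool] if pid not in records]
        if not pool_ids or not member_ids:
            break
        iteration += 1
        member_rows = Ln[[pos[pid] for pid in member_ids]]
        cand_rows = Ln[[pos[pid] for pid in pool_ids]]
        rmat = cand_rows @ member_rows.T            # signed Pearson r
        best = np.nanargmax(rmat, axis=1) if rmat.size else np.array([], dtype=int)
        added = []
        for ci, pid in enumerate(pool_ids):
            r_best = rmat[ci, best[ci]]
            if r_best > cfg.r_coexpr:
                certifier = member_ids[best[ci]]
                records[pid] = (
                    2, iteration, stats_.at[pid, "r"], stats_.at[pid, "p"],
                    certifier, float(r_best),
                )
                added.append(pid)
        if not added:
            break  # this sweep certified nothing: fixpoint reached
        member_ids = list(records)

    members = pd.DataFrame.from_dict(
        records, orient="index",
        columns=["step", "iteration", "r", "p", "certifier", "r_coexpr"],
    ).rename_axis("probe_id")
    members["sign"] = np.where(members["r"] >= 0, "P", "N")
    result = SelectionResult(
        trait=trait, members=members, n_iterations=iteration,
        alpha_step1=cfg.alpha_step1, alpha_step2=cfg.alpha_step2, r_coexpr=cfg.r_coexpr,
    )
    logger.info("two-step selection (%s): %s", trait, result.summary())
    return result


def verify_fixpoint(
    result: SelectionResult, correlations: pd.DataFrame, L: pd.DataFrame, cfg: PipelineConfig
) -> bool:
    """Exhaustive check that no outside probe satisfies both Step-2 gates."""
    stats_ = _best_trait_stat(correlations, result.trait, cfg.threshold_on)
    outside = [
        pid for pid in stats_.index
        if pid not in result.ids and stats_.at[pid, "p"] < cfg.alpha_step2
    ]
    if not outside or len(result.ids) == 0:
        return True
    def norm_rows(ids):
        M = L.loc[ids].to_numpy(dtype=float)
        Mc = M - M.mean(axis=1, keepdims=True)
        n = np.sqrt((Mc**2).sum(axis=1))
        n[n == 0] = np.nan
        return Mc / n[:, None]
    rmat = norm_rows(outside) @ norm_rows(result.ids).T
    return bool(np.nanmax(rmat, initial=-np.inf) <= cfg.r_coexpr)


# ---------------------------------------------------------------------------
# trait interaction
# ---------------------------------------------------------------------------

def interaction_genes(
    s_yield: SelectionResult, s_gdmc: SelectionResult
) -> pd.DataFrame:
    """Genes in both trait sets, flagged when their correlations carry
    opposite signs for the two traits."""
    shared = s_yield.ids.intersection(s_gdmc.ids)
    out = pd.DataFrame(
        {
            "sign_yield": s_yield.members.loc[shared, "sign"],
            "sign_gdmc": s_gdmc.members.loc[shared, "sign"],
            "step_yield": s_yield.members.loc[shared, "step"],
            "step_gdmc": s_gdmc.members.loc[shared, "step"],
        }
    ).rename_axis("probe_id")
    out["opposite_sign"] = out["sign_yield"] != out["sign_gdmc"]
    out.attrs["n_overlap"] = len(out)
    out.attrs["n_opposite"] = int(out["opposite_sign"].sum())
    out.attrs["n_step1_both"] = int(((out["step_yield"] == 1) & (out["step_gdmc"] == 1)).sum())
    logger.info(
        "interaction set: %d shared genes, %d with opposite sign",
        len(out), out.attrs["n_opposite"],
    )
    return out


def set_composition(n_step1: int, n_step2: int) -> int:
    """Total set size from the step breakdown (Step 1 and Step 2 are disjoint)."""
    if n_step1 < 0 or n_step2 < 0:
        raise DataError("step counts must be non-negative")
    return n_step1 + n_step2
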