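#!/usr/bin/env python
"""Gene-trait correlations of mid-parent expression.

Computes L (the mid-parent average log2 expression per hybrid) for every
differential gene, recomputes mid-parent heterosis from the per-se line
values, correlates L with PY, HY, PD and HD (t-test on n - 2 = 96 df, BH
FDR), attaches 95% BCa bootstrap intervals to the strongest yield genes, and
runs the 9,999-sample Monte Carlo permutation test of r(PY, PD).
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from hybridcor import (
    PipelineConfig,
    bca_ci,
    compute_heterosis,
    compute_midparent,
    correlation_records,
    read_design,
    read_expression,
    read_traits,
    trait_permutation_test,
)

DATA = Path("scratch/analysis_data")
RESULTS = Path("results")


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-ci", type=int, default=10, help="genes given BCa intervals")
    args = ap.parse_args()
    cfg = PipelineConfig()

    expr = read_expression(DATA / "expression.tsv", DATA / "samples.tsv", DATA / "probes.tsv")
    design = read_design(DATA / "design.tsv")
    traits = read_traits(DATA / "traits.tsv", DATA / "line_perse.tsv")
    de = pd.read_csv(DATA / "de_results.tsv", sep="\t", index_col=0)
    de_ids = de.index[de["de_pass"].astype(bool)]

    L = compute_midparent(expr.line_means().loc[de_ids], design)
    het = compute_heterosis(traits, traits.line_perse, design)
    trait_frame = traits.table.copy()
    trait_frame[["HY", "HD"]] = het[["HY", "HD"]]

    records = correlation_records(L, trait_frame)
    records.rename_axis("probe_id").to_csv(
        DATA / "correlations.tsv", sep="\t", float_format="%.6g"
    )

    r_obs, p_perm = trait_permutation_test(
        trait_frame["PY"].to_numpy(), trait_frame["PD"].to_numpy(),
        n_perm=cfg.n_perm, seed=args.seed,
    )

    top = records.nsmallest(args.n_ci, "p_PY").copy()
    cis = [
        bca_ci(L.loc[pid].to_numpy(), trait_frame["PY"].to_numpy(),
               B=cfg.n_boot, seed=args.seed + i)
        for i, pid in enumerate(top.index)
    ]
    top[["ci95_low", "ci95_high"]] = cis
    cols = ["r_PY", "p_PY", "q_PY", "ci95_low", "ci95_high", "r_HY", "p_HY"]
    top[cols].rename_axis("probe_id").to_csv(
        RESULTS / "top_yield_correlations.tsv", sep="\t", float_format="%.4g"
    )

    n_sig = int(((records["p_PY"] < 0.01) | (records["p_HY"] < 0.01)).sum())
    summary = {
        "n_candidates": len(records),
        "n_sig_yield_p01": n_sig,
        "r_py_pd": round(r_obs, 4),
        "perm_p_py_pd": p_perm,
    }
    (RESULTS / "correlation_summary.json").write_text(json.dumps(summary, indent=2))
    print(f"{len(records)} differential genes correlated over {L.shape[1]} hybrids")
    print(f"{n_sig} genes with p < 0.01 for PY or HY")
    print(f"r(PY, PD) = {summary['r_py_pd']}, permutation p = {p_perm} "
          f"({cfg.n_perm} Monte Carlo samples)")
    print(f"top yield genes with BCa intervals -> {RESULTS}/top_yield_correlations.tsv")


if __name__ == "__main__":
    main()
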