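"""End-to-end orchestration: simulate -> DE screen -> correlate -> select ->
cross-validate -> enrich, reproducible from one seed.

A single global seed is expanded into per-stage substreams with
``numpy.random.SeedSequence(seed).spawn()`` in a fixed stage order, so each
stage is individually reproducible and inserting work into one stage cannot
shift the randomness of another.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import correlate, crossval, diffexpr, enrich, io, select, simulate
from .config import PipelineConfig, load_config
from .io import logger

STAGES = ("simulate", "de_filter", "correlate", "select", "crossval", "enrich")


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(STAGES, children)
    }


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(
    config: PipelineConfig | str | Path | None,
    outdir: str | Path,
    seed: int = 1,
    gen_cfg: simulate.GeneratorConfig | None = None,
    calibrate_reps: int = 50,
    ci_genes: int = 0,
) -> dict:
    """Run the whole pipeline on a synthetic study and write all outputs.

    ``ci_genes`` > 0 additionally computes BCa intervals for that many of the
    strongest selected genes per trait (the bootstrap dominates runtime).
    Returns the run manifest (also written as ``manifest.json``).
    """
    cfg = config if isinstance(config, PipelineConfig) else load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(seed)
    manifest: dict = {"seed": seed, "stage_seeds": seeds, "config": cfg.__dict__, "stages": []}

    def record(name: str, t0: float, outputs: dict[str, Path], counts: dict) -> None:
        manifest["stages"].append(
            {
                "name": name,
                "seconds": round(time.time() - t0, 3),
                "outputs": {str(p.name): _digest(p) for p in outputs.values()},
                "counts": counts,
            }
        )

    # ---- simulate ---------------------------------------------------------
    t0 = time.time()
    gcfg = gen_cfg or simulate.GeneratorConfig()
    if gcfg.trait_coupling is None:
        kappa = simulate.calibrate_trait_coupling(
            gcfg, target_r=gcfg.target_trait_corr, n_reps=calibrate_reps,
            seed=seeds["simulate"],
        )
        gcfg = gcfg.with_(trait_coupling=kappa)
    gcfg = gcfg.with_(seed=seeds["simulate"])
    expr, design, traits, truth = simulate.generate_dataset(gcfg)
    paths = {
        "matrix": outdir / "expression.tsv",
        "samples": outdir / "samples.tsv",
        "probes": outdir / "probes.tsv",
        "design": outdir / "design.tsv",
        "traits": outdir / "traits.tsv",
        "perse": outdir / "line_perse.tsv",
        "truth": outdir / "truth.tsv",
    }
    io.write_expression(expr, paths["matrix"], paths["samples"], paths["probes"])
    io.write_design(design, paths["design"])
    io.write_traits(traits, paths["traits"], paths["perse"])
    truth.to_table().to_csv(paths["truth"], sep="\t", index=False)
    record("simulate", t0, paths, {
        "probes": len(expr.probe_ids), "samples": len(expr.sample_ids),
        "hybrids": len(design), "kappa": round(truth.kappa, 4),
        "realized_r_py_pd": round(truth.realized_r_py_pd, 4),
    })

    # ---- differential expression -----------------------------------------
    t0 = time.time()
    screen = diffexpr.select_differential(expr, cfg, design)
    de_path = outdir / "de_results.tsv"
    screen.table.rename_axis("probe_id").to_csv(de_path, sep="\t", float_format="%.6g")
    counts_tab = diffexpr.per_hybrid_de_counts(screen, design, cfg)
    counts_path = outdir / "per_hybrid_de_counts.tsv"
    counts_tab.to_csv(counts_path, sep="\t")
    record("de_filter", t0, {"de": de_path, "counts": counts_path}, {
        "n_de": int(screen.table["de_pass"].sum()),
        "threshold": round(screen.threshold, 3),
        "spikein_min_q": round(screen.spikein_min_q, 4),
        "mean_de_per_hybrid": counts_tab.attrs["mean_de"],
        "mean_de_percent": counts_tab.attrs["mean_de_percent"],
    })

    # ---- correlations -----------------------------------------------------
    t0 = time.time()
    line_means = expr.line_means()
    L = correlate.compute_midparent(line_means.loc[screen.de_ids], design)
    het = correlate.compute_heterosis(traits, traits.line_perse, design)
    trait_frame = traits.table.copy()
    trait_frame[["HY", "HD"]] = het[["HY", "HD"]]
    records = correlate.correlation_records(L, trait_frame)
    r_pypd, p_pypd = correlate.trait_permutation_test(
        trait_frame["PY"].to_numpy(), trait_frame["PD"].to_numpy(),
        n_perm=cfg.n_perm, seed=seeds["correlate"],
    )
    corr_path = outdir / "correlations.tsv"
    records.rename_axis("probe_id").to_csv(corr_path, sep="\t", float_format="%.6g")
    record("correlate", t0, {"corr": corr_path}, {
        "n_candidates": len(records),
        "r_py_pd": round(r_pypd, 4), "perm_p_py_pd": p_pypd,
    })

    # ---- two-step selection ----------------------------------------------
    t0 = time.time()
    s_yield = select.select_trait_genes(records, L, "yield", cfg)
    s_gdmc = select.select_trait_genes(records, L, "gdmc", cfg)
    inter = select.interaction_genes(s_yield, s_gdmc)
    sel_paths = {}
    for res in (s_yield, s_gdmc):
        members = res.members.copy()
        if ci_genes > 0 and len(members):
            members[["ci_low", "ci_high"]] = np.nan
            strongest = members.sort_values("p").index[:ci_genes]
            trait_col = "PY" if res.trait == "yield" else "PD"
            for i, pid in enumerate(strongest):
                lo, hi = correlate.bca_ci(
                    L.loc[pid].to_numpy(), trait_frame[trait_col].to_numpy(),
                    B=cfg.n_boot, seed=seeds["select"] + i,
                )
                members.loc[pid, ["ci_low", "ci_high"]] = (lo, hi)
        path = outdir / f"selection_{res.trait}.tsv"
        members.to_csv(path, sep="\t", float_format="%.6g")
        sel_paths[res.trait] = path
    inter_path = outdir / "interaction.tsv"
    inter.to_csv(inter_path, sep="\t")
    sel_paths["interaction"] = inter_path
    record("select", t0, sel_paths, {
        "yield": s_yield.summary(), "gdmc": s_gdmc.summary(),
        "n_overlap": inter.attrs["n_overlap"], "n_opposite": inter.attrs["n_opposite"],
    })

    # ---- cross-validation -------------------------------------------------
    t0 = time.time()
    if len(L) == 0:
        logger.warning("no differential candidates; cross-validation skipped")
        record("crossval", t0, {}, {"skipped": "no candidates"})
    else:
        cv_cfg = cfg
        if cfg.cv_top > len(L):
            cv_cfg = cfg.with_(cv_top=max(1, len(L) // 2))
            logger.warning("cv_top=%d exceeds %d candidates; using %d",
                           cfg.cv_top, len(L), cv_cfg.cv_top)
        cv = crossval.run_crossvalidation(
            L, design, trait_frame["PY"], cv_cfg, seed=seeds["crossval"]
        )
        metrics = crossval.overlap_metrics(cv)
        cv_path = outdir / "cv_overlaps.tsv"
        pd.DataFrame({"round": np.arange(len(cv.overlaps)), "overlap": cv.overlaps}).to_csv(
            cv_path, sep="\t", index=False
        )
        freq_path = outdir / "cv_frequencies.tsv"
        cv.frequencies.rename("n_rounds_in_top").rename_axis("probe_id").to_csv(
            freq_path, sep="\t"
        )
        record("crossval", t0, {"overlaps": cv_path, "freq": freq_path}, metrics)

    # ---- enrichment -------------------------------------------------------
    t0 = time.time()
    gene_ids = list(expr.probes.index[expr.probes["is_spikein"] == 0])
    cats = simulate.synthetic_categories(truth, gene_ids, seed=seeds["enrich"])
    gmt_path = outdir / "categories.gmt"
    io.write_gmt(cats, gmt_path)
    background = set(screen.de_ids)
    outputs = {"gmt": gmt_path}
    n_tested = 0
    if background:
        enr = enrich.enrich_categories(cats, background, set(s_yield.ids))
        n_tested = len(enr)
        enr_path = outdir / "enrichment_yield.tsv"
        enr.to_csv(enr_path, sep="\t", float_format="%.4g")
        dist = enrich.category_table(
            cats, background, {"yield": set(s_yield.ids), "gdmc": set(s_gdmc.ids)}
        )
        dist_path = outdir / "category_table.tsv"
        dist.to_csv(dist_path, sep="\t")
        outputs |= {"enrichment": enr_path, "table": dist_path}
    else:
        logger.warning("empty differential background; enrichment skipped")
    record("enrich", t0, outputs, {"n_categories": len(cats), "n_tested": n_tested})

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    logger.info("pipeline complete: %d stages -> %s", len(manifest["stages"]), outdir)
    return manifest
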