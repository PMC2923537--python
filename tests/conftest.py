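import numpy as np
import pandas as pd
import pytest

from hybridcor import (
    GeneratorConfig,
    PipelineConfig,
    generate_dataset,
    select_differential,
)
from hybridcor.correlate import (
    compute_heterosis,
    compute_midparent,
    correlation_records,
)


@pytest.fixture(scope="session")
def pcfg():
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_cfg():
    """A scaled-down factorial study: same design (7 x 14, 98 hybrids), fewer
    probes so the whole pipeline runs in well under a second."""
    return GeneratorConfig(
        n_probes=1500,
        n_modules=4,
        n_modules_yield=1,
        n_modules_gdmc=1,
        n_causal_yield=20,
        n_causal_gdmc=15,
        n_causal_shared=5,
        seed=1,
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return generate_dataset(small_cfg)


def pipeline_products(expr, design, traits, pcfg):
    """DE screen -> candidate mid-parent profiles -> correlation records,
    with heterosis recomputed from the per-se line values."""
    screen = select_differential(expr, pcfg, design)
    line_means = expr.line_means()
    L = compute_midparent(line_means.loc[screen.de_ids], design)
    het = compute_heterosis(traits, traits.line_perse, design)
    trait_frame = traits.table.copy()
    trait_frame[["HY", "HD"]] = het[["HY", "HD"]]
    records = correlation_records(L, trait_frame)
    return screen, L, trait_frame, records


@pytest.fixture(scope="session")
def small_products(small_dataset, pcfg):
    expr, design, traits, _ = small_dataset
    return pipeline_products(expr, design, traits, pcfg)


def toy_expression(effect_rows: dict, n_spike: int = 3, reps: int = 2,
                   lines=("F1", "F2", "D01"), sigma: float = 0.0, seed: int = 0):
    """Build a tiny ExpressionMatrix from per-line mean levels.

    ``effect_rows`` maps probe_id -> per-line mean intensity (same order as
    ``lines``); spike-in probes sit at 5.0.
    """
    from hybridcor.io import ExpressionMatrix

    rng = np.random.default_rng(seed)
    groups = ["flint" if l.startswith("F") else "dent" for l in lines]
    sample_ids, line_ids, grp, rep = [], [], [], []
    for line, g in zip(lines, groups):
        for k in range(reps):
            sample_ids.append(f"{line}_r{k + 1}")
            line_ids.append(line)
            grp.append(g)
            rep.append(k + 1)
    probe_ids = list(effect_rows) + [f"SPIKE{i}" for i in range(n_spike)]
    rows = []
    for pid in effect_rows:
        base = np.repeat(effect_rows[pid], reps).astype(float)
        rows.append(base + sigma * rng.normal(size=base.size))
    for _ in range(n_spike):
        rows.append(5.0 + 0.01 * rng.normal(size=len(sample_ids)))
    values = pd.DataFrame(rows, index=probe_ids, columns=sample_ids)
    samples = pd.DataFrame(
        {"sample_id": sample_ids, "line_id": line_ids, "group": grp, "replicate": rep}
    ).set_index("sample_id")
    probes = pd.DataFrame(
        {"probe_id": probe_ids,
         "is_spikein": [0] * len(effect_rows) + [1] * n_spike}
    ).set_index("probe_id")
    return ExpressionMatrix(values=values, samples=samples, probes=probes)
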