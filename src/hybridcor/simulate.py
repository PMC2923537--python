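"""Synthetic factorial studies: expression, design, phenotypes and ground truth.

The generator emulates a flint x dent factorial of maize inbreds: 7 flint and
14 dent parents, 98 hybrids, probe-level log2 intensities with spike-in
control probes, gene-wise residual variances drawn from a scaled
inverse-chi-square prior, co-expression modules driven by latent per-line
factors, and causal genes whose mid-parent expression carries a target
correlation with hybrid grain yield (PY) and grain dry matter content (PD).

Trait model.  Each parental line carries latent general-combining-ability
scores.  The yield core of hybrid (i, j) is c_Y = (phi_i + delta_j)/sqrt(2)
with unit population variance; PY = py_mean + py_scale * (c_Y + sigma_e * e).
PD is built the same way from a second set of line scores that share a latent
component with the yield scores with coefficient -kappa, so the population
correlation r(PY, PD) equals -kappa / (1 + sigma_e^2).  sigma_e is solved
analytically so a fully loaded causal gene reaches the target gene-trait
correlation rho; kappa is set by :func:`calibrate_trait_coupling`.

Causal genes load their per-line expression effects on the same latent line
scores (loading ``causal_loading`` plus an idiosyncratic per-line component
``causal_noise``), which induces corr(L, trait) = rho by construction.  Genes
causal for both traits load on the difference of the yield and dry-matter
line scores and therefore correlate with the two traits with opposite signs.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .config import ConfigError
from .io import ExpressionMatrix, FactorialDesign, TraitTable, logger


@dataclass(frozen=True)
class GeneratorConfig:
    n_flint: int = 7
    n_dent: int = 14
    n_probes: int = 5000
    n_spikein: int = 100
    n_replicates: int = 3
    frac_variable: float = 0.3
    n_modules: int = 10
    module_size: int = 15
    n_modules_yield: int = 2       # modules whose latent aligns with yield
    n_modules_gdmc: int = 1        # modules whose latent aligns with GDMC
    module_align: float = 0.5      # alignment coefficient of those latents
    module_loading: float = 1.2    # latent loading of module members (log2 units)
    module_noise: float = 0.25     # idiosyncratic per-line sd of module members
    n_causal_yield: int = 40
    n_causal_gdmc: int = 30
    n_causal_shared: int = 10
    causal_corr_target: float = 0.6   # rho: population corr(L, trait) of causal genes
    causal_loading: float = 0.6       # latent loading of causal genes (log2 units)
    causal_noise: float = 0.35        # idiosyncratic per-line sd of causal genes
    trait_coupling: float | None = None  # kappa; None -> analytic value for target below
    target_trait_corr: float = -0.410    # default calibration target for r(PY, PD)
    baseline_mean: float = 9.0
    baseline_sd: float = 1.5
    spikein_mean: float = 5.0
    spikein_sd: float = 0.5
    d0_true: float = 4.0
    s0sq_true: float = 0.05
    line_effect_sd: float = 0.5    # per-line sd of generic variable genes
    py_mean: float = 10.0          # Mg/ha
    py_scale: float = 1.0
    pd_mean: float = 72.0          # percent dry matter
    pd_scale: float = 1.5
    perse_yield_mean: float = 5.0
    perse_gdmc_mean: float = 72.0
    perse_gca_loading: float = 0.6
    perse_noise_sd: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        def chk(cond: bool, name: str, msg: str) -> None:
            if not cond:
                raise ConfigError(f"{name}: {msg} (got {getattr(self, name)!r})")

        for name in (
            "n_flint", "n_dent", "n_probes", "n_spikein", "n_replicates",
            "module_size",
        ):
            chk(int(getattr(self, name)) >= 1, name, "must be a positive count")
        for name in (
            "n_modules", "n_modules_yield", "n_modules_gdmc",
            "n_causal_yield", "n_causal_gdmc", "n_causal_shared",
        ):
            chk(int(getattr(self, name)) >= 0, name, "must be a non-negative count")
        chk(self.n_replicates >= 2, "n_replicates", "needs >= 2 for residual df")
        chk(0 <= self.frac_variable < 1, "frac_variable", "must lie in [0, 1)")
        chk(0 < self.causal_corr_target < 1, "causal_corr_target", "must lie in (0, 1)")
        chk(
            self.n_causal_shared <= min(self.n_causal_yield, self.n_causal_gdmc),
            "n_causal_shared",
            "cannot exceed min(n_causal_yield, n_causal_gdmc)",
        )
        chk(
            self.n_modules_yield + self.n_modules_gdmc <= self.n_modules,
            "n_modules_yield",
            "aligned modules cannot exceed n_modules",
        )
        chk(self.d0_true > 0 and self.s0sq_true > 0, "d0_true", "variance prior must be positive")
        chk(0 < self.module_align < 1, "module_align", "must lie in (0, 1)")
        if self.trait_coupling is not None:
            chk(abs(self.trait_coupling) < 1, "trait_coupling", "must lie in (-1, 1)")
        n_var = round(self.frac_variable * self.n_probes)
        needed = self.n_distinct_causal + self.n_modules * self.module_size
        chk(
            needed <= n_var,
            "frac_variable",
            f"variable-gene budget {n_var} smaller than causal+module genes {needed}",
        )
        # sigma_e^2 must be attainable for the requested rho
        _ = noise_for_target(self)

    @property
    def n_distinct_causal(self) -> int:
        return self.n_causal_yield + self.n_causal_gdmc - self.n_causal_shared

    @property
    def n_hybrids(self) -> int:
        return self.n_flint * self.n_dent

    def with_(self, **kw) -> "GeneratorConfig":
        return replace(self, **kw)


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic study."""

    causal: pd.DataFrame      # probe_id, trait, sign_yield, sign_gdmc
    modules: pd.DataFrame     # probe_id, module_id, aligned
    sigma2: pd.Series         # true residual variance per probe
    d0_true: float
    s0sq_true: float
    kappa: float
    sigma_e2: float
    realized_r_py_pd: float

    def causal_ids(self, trait: str) -> list[str]:
        """Causal probe ids for 'yield' or 'gdmc' (shared genes count for both)."""
        sel = self.causal["trait"].isin([trait, "both"])
        return list(self.causal.loc[sel, "probe_id"])

    def to_table(self) -> pd.DataFrame:
        """Flat per-probe truth table (probe_id, role, trait, sign, module_id)."""
        rows = []
        for rec in self.causal.itertuples(index=False):
            sign = rec.sign_yield if rec.trait != "gdmc" else rec.sign_gdmc
            rows.append((rec.probe_id, "causal", rec.trait, sign, ""))
        for rec in self.modules.itertuples(index=False):
            rows.append((rec.probe_id, "module", rec.aligned, "", rec.module_id))
        return pd.DataFrame(rows, columns=["probe_id", "role", "trait", "sign", "module_id"])


# ---------------------------------------------------------------------------
# derived noise scales
# ---------------------------------------------------------------------------

def _mean_residual_variance(cfg: GeneratorConfig) -> float:
    d0, s0 = cfg.d0_true, cfg.s0sq_true
    if d0 > 2:
        return d0 * s0 / (d0 - 2)
    return d0 * s0 / stats.chi2.ppf(0.5, d0)  # median for heavy-tailed priors


def noise_for_target(cfg: GeneratorConfig) -> float:
    """Trait noise variance sigma_e^2 that makes a fully loaded causal gene
    reach corr(L, trait) = causal_corr_target."""
    lam, tau = cfg.causal_loading, cfg.causal_noise
    var_l = (lam**2 + tau**2) / 2 + _mean_residual_variance(cfg) / (2 * cfg.n_replicates)
    cov = lam / math.sqrt(2)
    rho_max = cov / math.sqrt(var_l)
    rho = cfg.causal_corr_target
    if rho >= rho_max:
        raise ConfigError(
            f"causal_corr_target: {rho} unattainable; max {rho_max:.3f} at "
            f"causal_loading={lam}, causal_noise={tau}"
        )
    return (cov / (math.sqrt(var_l) * rho)) ** 2 - 1.0


def _default_kappa(cfg: GeneratorConfig) -> float:
    sigma_e2 = noise_for_target(cfg)
    kappa = -cfg.target_trait_corr * (1 + sigma_e2)
    if abs(kappa) >= 1:
        raise ConfigError(
            f"target_trait_corr: {cfg.target_trait_corr} needs |kappa| >= 1; achievable "
            f"|r(PY,PD)| < {1 / (1 + sigma_e2):.3f} at the current noise settings"
        )
    return kappa


# ---------------------------------------------------------------------------
# latent line scores and traits
# ---------------------------------------------------------------------------

def _trait_block(cfg: GeneratorConfig, rng: np.random.Generator, kappa: float) -> dict:
    """Draw latent line scores and hybrid traits; returns everything the
    expression model needs to tie causal genes to the phenotypes."""
    nf, nd = cfg.n_flint, cfg.n_dent
    a = math.sqrt(abs(kappa))
    sk = 1.0 if kappa >= 0 else -1.0
    b = math.sqrt(1 - a * a)

    f_shared, f_y, f_d = rng.normal(size=(3, nf))
    d_shared, d_y, d_d = rng.normal(size=(3, nd))
    phi_y = a * f_shared + b * f_y
    phi_d = -sk * a * f_shared + b * f_d
    delta_y = a * d_shared + b * d_y
    delta_d = -sk * a * d_shared + b * d_d

    c_y = (phi_y[:, None] + delta_y[None, :]) / math.sqrt(2)   # nf x nd
    c_d = (phi_d[:, None] + delta_d[None, :]) / math.sqrt(2)

    sigma_e2 = noise_for_target(cfg)
    se = math.sqrt(sigma_e2)
    t_y = c_y + se * rng.normal(size=c_y.shape)
    t_d = c_d + se * rng.normal(size=c_d.shape)

    py = cfg.py_mean + cfg.py_scale * t_y
    pdm = cfg.pd_mean + cfg.pd_scale * t_d

    perse_y = np.concatenate([
        cfg.perse_yield_mean + cfg.perse_gca_loading * phi_y,
        cfg.perse_yield_mean + cfg.perse_gca_loading * delta_y,
    ]) + cfg.perse_noise_sd * rng.normal(size=nf + nd)
    perse_d = np.concatenate([
        cfg.perse_gdmc_mean + cfg.perse_gca_loading * phi_d,
        cfg.perse_gdmc_mean + cfg.perse_gca_loading * delta_d,
    ]) + cfg.perse_noise_sd * rng.normal(size=nf + nd)

    hy = py - (perse_y[:nf, None] + perse_y[None, nf:]) / 2
    hd = pdm - (perse_d[:nf, None] + perse_d[None, nf:]) / 2

    r = float(np.corrcoef(py.ravel(), pdm.ravel())[0, 1])
    return dict(
        phi_y=phi_y, phi_d=phi_d, delta_y=delta_y, delta_d=delta_d,
        py=py, pd=pdm, hy=hy, hd=hd, perse_y=perse_y, perse_d=perse_d,
        sigma_e2=sigma_e2, realized_r=r,
    )


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------

def generate_dataset(
    cfg: GeneratorConfig,
) -> tuple[ExpressionMatrix, FactorialDesign, TraitTable, SyntheticTruth]:
    """Generate one complete synthetic study, reproducible from cfg.seed."""
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    kappa = cfg.trait_coupling if cfg.trait_coupling is not None else _default_kappa(cfg)

    nf, nd, rpl = cfg.n_flint, cfg.n_dent, cfg.n_replicates
    flint = [f"F{i + 1}" for i in range(nf)]
    dent = [f"D{j + 1:02d}" for j in range(nd)]
    lines = flint + dent
    n_lines = len(lines)

    tb = _trait_block(cfg, rng, kappa)

    # ---- probe bookkeeping ------------------------------------------------
    n_g, n_s = cfg.n_probes, cfg.n_spikein
    gene_ids = [f"MZG{i + 1:05d}" for i in range(n_g)]
    spike_ids = [f"MZS{i + 1:03d}" for i in range(n_s)]
    probe_ids = gene_ids + spike_ids

    n_yield_only = cfg.n_causal_yield - cfg.n_causal_shared
    n_gdmc_only = cfg.n_causal_gdmc - cfg.n_causal_shared
    n_causal = cfg.n_distinct_causal
    n_module_genes = cfg.n_modules * cfg.module_size
    n_var = round(cfg.frac_variable * n_g)

    lam, tau = cfg.causal_loading, cfg.causal_noise
    effects = np.zeros((n_g, n_lines))

    # causal genes -----------------------------------------------------------
    signs = rng.choice([-1.0, 1.0], size=n_causal)
    gca_y = np.concatenate([tb["phi_y"], tb["delta_y"]])
    gca_d = np.concatenate([tb["phi_d"], tb["delta_d"]])
    # genes causal for both traits load on the (yield - gdmc) direction, so the
    # two trait correlations come out with opposite signs
    gca_shared = (gca_y - gca_d) / math.sqrt(2 + 2 * kappa)
    causal_rows = []
    for idx in range(n_causal):
        s = signs[idx]
        if idx < n_yield_only:
            base, trait = gca_y, "yield"
            sy, sg = ("P" if s > 0 else "N"), ""
        elif idx < n_yield_only + n_gdmc_only:
            base, trait = gca_d, "gdmc"
            sy, sg = "", ("P" if s > 0 else "N")
        else:
            base, trait = gca_shared, "both"
            sy, sg = ("P" if s > 0 else "N"), ("N" if s > 0 else "P")
        effects[idx] = s * (lam * base + tau * rng.normal(size=n_lines))
        causal_rows.append((gene_ids[idx], trait, sy, sg))
    causal = pd.DataFrame(causal_rows, columns=["probe_id", "trait", "sign_yield", "sign_gdmc"])

    # module genes -----------------------------------------------------------
    lam_m, tau_m, c = cfg.module_loading, cfg.module_noise, cfg.module_align
    module_rows = []
    pos = n_causal
    for m in range(cfg.n_modules):
        latent = rng.normal(size=n_lines)
        if m < cfg.n_modules_yield:
            latent = c * gca_y + math.sqrt(1 - c * c) * latent
            aligned = "yield"
        elif m < cfg.n_modules_yield + cfg.n_modules_gdmc:
            latent = c * gca_d + math.sqrt(1 - c * c) * latent
            aligned = "gdmc"
        else:
            aligned = "none"
        for _ in range(cfg.module_size):
            effects[pos] = lam_m * latent + tau_m * rng.normal(size=n_lines)
            module_rows.append((gene_ids[pos], f"M{m + 1:02d}", aligned))
            pos += 1
    modules = pd.DataFrame(module_rows, columns=["probe_id", "module_id", "aligned"])

    # generic variable genes -------------------------------------------------
    n_generic = n_var - pos
    if n_generic > 0:
        effects[pos:pos + n_generic] = rng.normal(
            scale=cfg.line_effect_sd, size=(n_generic, n_lines)
        )

    # ---- expression matrix -------------------------------------------------
    mu = np.concatenate([
        rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=n_g),
        rng.normal(cfg.spikein_mean, cfg.spikein_sd, size=n_s),
    ])
    n_probes_all = n_g + n_s
    sigma2 = cfg.s0sq_true * cfg.d0_true / rng.chisquare(cfg.d0_true, size=n_probes_all)

    all_effects = np.vstack([effects, np.zeros((n_s, n_lines))])
    line_idx = np.repeat(np.arange(n_lines), rpl)
    noise = rng.normal(size=(n_probes_all, n_lines * rpl)) * np.sqrt(sigma2)[:, None]
    x = mu[:, None] + all_effects[:, line_idx] + noise

    sample_ids = [f"{lines[l]}_r{k + 1}" for l in range(n_lines) for k in range(rpl)]
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "line_id": [lines[l] for l in line_idx],
            "group": ["flint" if l < nf else "dent" for l in line_idx],
            "replicate": [k + 1 for _ in range(n_lines) for k in range(rpl)],
        }
    ).set_index("sample_id")
    probes = pd.DataFrame(
        {"probe_id": probe_ids, "is_spikein": [0] * n_g + [1] * n_s}
    ).set_index("probe_id")
    expr = ExpressionMatrix(
        values=pd.DataFrame(x, index=pd.Index(probe_ids, name="probe_id"), columns=sample_ids),
        samples=samples,
        probes=probes,
    )

    # ---- design and traits -------------------------------------------------
    design = FactorialDesign(pd.DataFrame(
        [(f"{f}x{d}", f, d) for f in flint for d in dent],
        columns=["hybrid_id", "flint_parent", "dent_parent"],
    ))
    hybrid_ids = design.hybrid_ids
    trait_table = pd.DataFrame(
        {
            "PY": tb["py"].ravel(),
            "PD": tb["pd"].ravel(),
            "HY": tb["hy"].ravel(),
            "HD": tb["hd"].ravel(),
        },
        index=pd.Index(hybrid_ids, name="hybrid_id"),
    )
    line_perse = pd.DataFrame(
        {"yield_perse": tb["perse_y"], "gdmc_perse": tb["perse_d"]},
        index=pd.Index(lines, name="line_id"),
    )
    traits = TraitTable(table=trait_table, line_perse=line_perse)

    truth = SyntheticTruth(
        causal=causal,
        modules=modules,
        sigma2=pd.Series(sigma2, index=probe_ids),
        d0_true=cfg.d0_true,
        s0sq_true=cfg.s0sq_true,
        kappa=kappa,
        sigma_e2=tb["sigma_e2"],
        realized_r_py_pd=tb["realized_r"],
    )
    logger.info(
        "generated dataset: %d probes x %d samples, %d hybrids, kappa=%.3f, r(PY,PD)=%.3f",
        n_probes_all, len(sample_ids), len(design), kappa, tb["realized_r"],
    )
    return expr, design, traits, truth


# ---------------------------------------------------------------------------
# trait-coupling calibration
# ---------------------------------------------------------------------------

def calibrate_trait_coupling(
    cfg: GeneratorConfig,
    target_r: float = -0.410,
    n_reps: int = 200,
    seed: int = 0,
    tol: float = 0.01,
    max_iter: int = 6,
) -> float:
    """Find kappa so the mean realized r(PY, PD) over seeded replicates hits
    ``target_r``.  Deterministic given ``seed``; proportional updates from the
    analytic starting point -target * (1 + sigma_e^2)."""
    if not -1 < target_r < 1:
        raise ConfigError(f"target_r={target_r} outside (-1, 1)")
    if target_r == 0:
        return 0.0
    sigma_e2 = noise_for_target(cfg)
    r_max = 0.99 / (1 + sigma_e2)
    if abs(target_r) > r_max:
        raise ConfigError(
            f"target_r={target_r} unattainable; achievable range is "
            f"({-r_max:.3f}, {r_max:.3f}) at the current noise settings"
        )

    def mean_r(kappa: float, it: int) -> float:
        rs = np.empty(n_reps)
        for rep in range(n_reps):
            rng = np.random.default_rng([seed % (2**31), it, rep])
            rs[rep] = _trait_block(cfg, rng, kappa)["realized_r"]
        return float(rs.mean())

    kappa = -target_r * (1 + sigma_e2)
    for it in range(max_iter):
        realized = mean_r(kappa, it)
        if abs(realized - target_r) <= tol:
            break
        if realized == 0:
            kappa = min(0.99, kappa + 0.1 * math.copysign(1, -target_r))
            continue
        kappa = kappa * target_r / realized
        kappa = math.copysign(min(abs(kappa), 0.99), kappa)
    logger.info("calibrated kappa=%.4f for target r=%.3f (realized %.4f)", kappa, target_r, realized)
    return kappa


# ---------------------------------------------------------------------------
# synthetic functional categories
# ---------------------------------------------------------------------------

def synthetic_categories(
    truth: SyntheticTruth,
    gene_ids: list[str],
    n_random: int = 8,
    random_size: int = 60,
    seed: int = 0,
) -> dict:
    """A synthetic category map: one category per co-expression module plus
    random categories drawn from all gene-oriented probes.  Stands in for a
    curated functional catalogue; memberships may overlap."""
    rng = np.random.default_rng(seed)
    cats: dict = {}
    for module_id, sub in truth.modules.groupby("module_id"):
        cats[f"MODULE_{module_id}"] = set(sub["probe_id"])
    for trait in ("yield", "gdmc", "both"):
        ids = set(truth.causal.loc[truth.causal["trait"] == trait, "probe_id"])
        if ids:
            cats[f"CAUSAL_{trait.upper()}"] = ids
    for i in range(n_random):
        size = min(random_size, len(gene_ids))
        cats[f"RANDOM_{i + 1:02d}"] = set(rng.choice(gene_ids, size=size, replace=False))
    return cats
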