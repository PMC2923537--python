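# Methods

## The synthetic factorial study

The generator (`hybridcor.simulate`) emulates a transcriptome–phenotype
study on a flint x dent factorial: expression of 21 parental inbreds in
seedlings, field traits of their 98 F1 hybrids. It exists because the
analysis needs data with known ground truth; its defaults are the study
conditions every test and the acceptance computation run under.

### Trait model

Each parental line carries latent combining-ability (GCA) scores. For
flint line i and dent line j,

    c_Y(i,j) = (phi_i + delta_j) / sqrt(2)

is the yield core of the hybrid, with unit population variance, and

    PY = py_mean + py_scale * (c_Y + sigma_e * e_ij),

e_ij iid N(0,1). Dry matter content is built identically from a second set
of line scores that share a latent component with the yield scores: with
a = sqrt(kappa), the dry-matter line score loads -a on the shared factor
where the yield score loads +a, so the population correlation of the trait
cores is exactly -kappa and

    r(PY, PD) = -kappa / (1 + sigma_e^2).

Mid-parent heterosis is generated structurally: per-se line values are
emitted (loading 0.6 on the line's GCA score plus noise, sd 0.4) and
HY = PY - mid-parent per-se, so `compute_heterosis` can reproduce the
emitted HY exactly from its inputs.

### Expression model

A probe's sample value is mu_g + effect_g(line) + eps, eps ~ N(0, sigma_g^2)
with sigma_g^2 ~ d0 * s0^2 / chi^2(d0) (defaults d0 = 4, s0^2 = 0.05, the
regime the moderated F-test is designed for). Baselines are N(9.0, 1.5^2)
log2 units; spike-ins sit at N(5.0, 0.5^2) with no line effects. A fraction
`frac_variable` = 0.3 of the 5000 gene probes carries line effects:

* **Causal genes** (40 yield, 30 dry matter, 10 shared between the two)
  load their line effects on the trait GCA scores: effect = s * (lambda *
  score + tau * u_line) with loading lambda = 0.6, idiosyncratic sd
  tau = 0.35 and sign s. This makes corr(L, trait) analytic; the trait noise
  sigma_e is solved so that a fully loaded causal gene reaches the target
  rho (`causal_corr_target`, default 0.6):

      sigma_e^2 = (lambda / (sqrt(2) * sd_L * rho))^2 - 1,
      sd_L^2 = (lambda^2 + tau^2)/2 + E[sigma_g^2]/(2 * n_replicates).

  Shared causal genes load on the normalized difference of the yield and
  dry-matter scores, which gives them opposite-sign correlations with the
  two traits of magnitude rho * sqrt((1+kappa)/2).
* **Module genes** (10 modules of 15) share a latent per-line factor with
  loading 1.2 and idiosyncratic sd 0.25, giving expected pairwise mid-parent
  correlations of ~0.94 (> the 0.9 co-expression gate). Two module latents
  are partially aligned with the yield score and one with the dry-matter
  score (coefficient 0.5), so their members hover around the Step-2
  significance gate — this is what exercises the co-expression expansion.
* Remaining variable genes get iid N(0, 0.5^2) line effects (differential
  but trait-neutral); all other genes and all spike-ins are flat.

### Calibration of the trait coupling

`calibrate_trait_coupling` finds kappa such that the *mean realized* sample
correlation over seeded replicates hits the target (default -0.410). The
analytic inverse kappa = -target * (1 + sigma_e^2) is only a starting point:
with 98 hybrids generated from 21 line scores the effective sample size is
small and |r| attenuates by roughly 7%, so the procedure refines kappa with
proportional updates against simulated replicate means (deterministic given
its seed). Targets beyond the attainable range (|r| < 0.99/(1+sigma_e^2))
raise an error naming that range.

A single 98-hybrid realization scatters around the target with sd ~0.13;
only the mean over many seeds is calibrated. The same applies to per-seed
causal-gene correlations and hence to Step 2: in some realizations no
module member clears both Step-2 gates, in others dozens do.

### What the generator does not emulate

Two-channel loop-design hybridization, normalization, dye and spatial
artifacts, field-plot error structure, probe cross-hybridization, and any
gene-gene regulatory structure beyond linear latent factors. Passing tests
show the *procedures* behave as specified under a factorial GCA world with
Gaussian noise — not that real maize data satisfy these assumptions.

## Analysis procedures

**Reliability and filters.** Threshold = mean + 3 * sample sd (n−1 divisor)
of all spike-in intensities; a probe is reliable when >= `min_lines` (default
1) line means exceed it — the weakest reading of "reliably expressed", since
the source procedure does not fix the count. Fold change is compared on the
log2 scale (|delta line means| > log2 1.3). The intensity filter uses the
probe's mean over line means (configurable to max). The fold-change
prefilter is applied before the F-test by default (`prefilter_fc`); the BH
family is then the prefiltered gene probes plus all spike-ins, whose
smallest adjusted p is reported as the negative-control calibration of the
FDR cutoff. Note a consequence: tightening `fc_min` changes the BH family,
so DE-set monotonicity in `fc_min` is only guaranteed with the prefilter
off.

**Moderated F-test.** Per probe, a one-way model on line means; residual
variance s^2 with d = n − k df. The prior (d0, s0^2) is fitted by moment
matching of log s^2 (digamma/trigamma inversion, Newton on the trigamma
inverse); if the log-variances show no excess dispersion the prior df is
+infinity and every probe uses the common variance (logged). Posterior
variance (d0 s0^2 + d s^2)/(d0 + d); F on (k−1, d0+d) df, chi-square limit
when d0 is infinite. Nested pairwise tests square the moderated t of a line
pair contrast, F(1, d0+d), BH-adjusted per pair across probes.

**Correlation records.** Pearson r, t on n−2 df; constant vectors yield
flagged NaN records rather than exceptions. |r| within 1e-12 of 1 is snapped
to ±1 with p = 0. BCa intervals resample hybrids (pairs), use half-weight
ties in the bias term z0, jackknife acceleration, and clip the z0 proportion
to [0.5/B, 1−0.5/B]; a degenerate bootstrap returns the point interval.
Correlations are computed for differential probes only (configurable), the
set the selection operates on.

**Two-step selection.** Thresholds apply to raw p by default
(`threshold_on: fdr` switches to BH q; the source is ambiguous between the
two readings). The Step-2 candidate pool is fixed up front (p < 0.01, not in
Step 1); each sweep certifies candidates only against the previous sweep's
set (synchronous update), which makes the result independent of processing
order; the iteration stops at the first sweep that adds nothing. The
co-expression gate is signed r > 0.9 between mid-parent profiles. Signs P/N
come from the trait correlation with the largest |r| (yield: PY vs HY).

**Cross-validation.** Each round samples 3 flint and 5 dent lines without
replacement; the estimation set is the 15 hybrids among them. Genes are
ranked by p, ties by |r| descending, then probe id (fully specified for
reproducibility). Two overlap variants are reported: mean
per-round top-k overlap with the full-data top-k, and the overlap of the
top-k by selection frequency across rounds. Because estimation sets are
subsets of the same realized data, the null (no causal genes) overlap
exceeds the k^2/G random-ranking expectation; the hypergeometric null is
therefore a property of the overlap statistic under random rankings, which
the tests check directly.

**Enrichment.** Upper-tail hypergeometric p summed in log space; the
universe is the annotated differential background (configurable); genes
count in every category they belong to; one-sided overrepresentation only.

## Numerical and design choices

* Heterosis is absolute (F1 minus mid-parent), not percent of mid-parent.
* HD is computed and reported but never used for selection (dry-matter
  heterosis is negligible in maize).
* Effect sizes are parameterized by the target correlation rho rather than
  raw slopes, so power statements are design-independent.
* The replicate structure (3 per line) is a modeling device to make the
  moderated F-test estimable; per-line replication of the original loop
  design is not inferred.
* Pipeline seeds: one global seed expanded via `SeedSequence.spawn` in fixed
  stage order, so each stage is individually reproducible.
* Problem sizes in the test suite: recovery simulations average over 8–10
  seeds; BCa coverage uses 500 datasets with B = 2000 resamples; the
  calibration check uses 200 seeds. The acceptance script simulates 200
  studies at the full default scale.

## Known limitations

* The generator's GCA world has no specific combining ability beyond iid
  hybrid noise, no genotype x environment structure, and traits are exact
  linear functions of latent scores.
* With 15-hybrid estimation sets, per-round correlation estimates have
  sd ~0.29, so cross-validation top-k overlap at rho = 0.6 sits well below
  what a larger estimation set would give; the tests assert separation from
  the null rather than a high absolute overlap.
* BH-FDR within a fold-change-prefiltered family is conditional on the
  prefilter; no attempt is made to control FDR marginally.
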