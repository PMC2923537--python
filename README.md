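# hybridcor

Correlating parental seedling transcriptomes with hybrid field performance in
a factorial maize cross.

## The problem

In European maize breeding, F1 hybrids between the flint and dent heterotic
groups dominate production, and early maturity (indexed by grain dry matter
content) competes with grain yield. A natural question is which genes,
measured cheaply in seedlings of the *parental inbred lines*, carry
information about the field performance of their hybrids. This package
implements that analysis for a 7 flint x 14 dent factorial (98 hybrids):

1. **Differential expression screen.** Probes are reliable when a line-mean
   log2 intensity exceeds the spike-in threshold (mean + 3 sd of all spike-in
   control intensities). Differential genes pass a fold-change prefilter
   (> 1.3 between some pair of lines), an empirical-Bayes **moderated
   F-test** across the 21 lines at BH-FDR 0.01, and a mean-intensity filter
   (> 8.0 log2). The moderated test shrinks per-gene residual variances s²
   (d df) toward a prior (d0, s0²) fitted across genes, using the posterior
   variance s̃² = (d0·s0² + d·s²)/(d0 + d) and F referred to F(k−1, d0+d).
   Nested pairwise tests count, per hybrid, the genes differential between
   its two parents.
2. **Gene–trait correlation.** For each hybrid, L is the mid-parent average
   log2 expression of a gene in its two parents. Pearson r(L, PY), r(L, HY),
   r(L, PD), r(L, HD) — hybrid performance and mid-parent heterosis for grain
   yield (Mg ha⁻¹) and grain dry matter content (%) — are tested with
   t = r√(n−2)/√(1−r²) on n−2 = 96 df, BH-adjusted, with 95% **BCa
   bootstrap** intervals (10,000 resamples). The trait–trait correlation
   r(PY, PD) is tested by Monte Carlo permutation (9,999 samples).
3. **Two-step selection.** Step 1 takes genes with p < 10⁻⁴ (yield: PY or
   HY; dry matter content: PD only). Step 2 iteratively adds genes with
   p < 0.01 whose mid-parent profile is co-expressed (r > 0.9) with a
   current member, to a fixpoint. Genes in both trait sets with opposite
   correlation signs mark the yield / dry-matter interaction.
4. **Stability cross-validation.** 100 rounds resample 3 flint and 5 dent
   lines; correlations are re-ranked on the 15 hybrids among them and the
   top-200 lists compared with the full-data top-200.
5. **Enrichment.** Category distribution tables and one-sided hypergeometric
   overrepresentation tests against the differential background.

Matched expression-plus-field-phenotype data for such designs are rarely
public, so the package ships a fully specified **synthetic-study generator**
with known ground truth: latent per-line combining-ability scores drive both the traits
and the causal genes' expression, gene variances follow a scaled
inverse-chi-square prior, co-expression modules share latent line factors,
and a calibrated coupling coefficient reproduces the observed
r(PY, PD) = −0.410. Every stage is tested against this truth.

## Worked example

The analysis is organised as numbered drivers over the library:

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_differential_expression.py
python analysis/03_trait_correlations.py
python analysis/04_two_step_selection.py
python analysis/05_cross_validation.py
python analysis/06_enrichment.py
```

Output of the run above (small tables land in `results/`, bulky
intermediates in `scratch/`):

```
calibrated kappa = 0.9003 targeting r(PY,PD) = -0.410
study: 5100 probes x 63 samples, 98 hybrids; realized r(PY,PD) = -0.5519
reliability threshold: 6.794 (log2)
1090 of 5000 gene probes differential (prior d0 = 4.101, s0sq = 0.05033)
most significant spike-in q = 0.0238 (negative-control calibration of the FDR cutoff)
mean DE genes per hybrid: 413.1 = 8.3% of the array
r(PY, PD) = -0.5519, permutation p = 0.0001 (9999 Monte Carlo samples)
yield set S: 67 genes in Step 1 + 0 in Step 2 = 67 (55.2% positively correlated)
dry-matter set T: 66 + 0 = 66
interaction: 56 shared genes, 56 with opposite sign
recovered 31/31 candidate causal yield genes and 24/24 causal dry-matter genes
mean per-round overlap with the full-data top-200: 75.9 of 200
frequency-ranked top-200 overlap: 142 of 200
```

Reading this: the generator's variance prior (d0 = 4, s0² = 0.05) is
recovered almost exactly by the moderated test; spike-in negative controls
sit just above the 0.01 FDR cutoff, as they should; every causal gene that
survived the differential screen is found by the two-step selection; and all
56 genes shared between the two trait sets correlate with opposite signs —
the built-in yield / dry-matter antagonism. The realized r(PY, PD) of a
single 98-hybrid study scatters widely around the calibrated target (here
−0.55; the 200-seed mean is −0.41), and Step 2's co-expression expansion
varies by realization — in this seed no additional gene qualified, in
others it adds 2–28 (see `docs/methods.md`).

Equivalently, `hybridcor.run_all(config, outdir, seed)` executes all stages
on one seed and writes a digest manifest; the same functions accept
user-supplied expression/design/trait files via `hybridcor.read_expression`
and friends.

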