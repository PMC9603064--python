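# Methods

## The models and their assumptions

All three analyses operate on a balanced, complete, replicated factorial
layout of relative expression: temperature × tissue × gene × block, values
treated as opaque positive reals on the scale the ΔΔCt method produces.
Balance is a hard requirement, not a preference: the closed-form sums of
squares, the stratum degrees of freedom, and the identity
interaction SS = r·Σλ² all assume it. Unbalanced input is rejected with an
error rather than imputed.

**ΔΔCt quantification.** Relative expression is 2^−ΔΔCt with
ΔΔCt = (Ct_target − Ct_reference)_sample − (Ct_target − Ct_reference)_calibrator.
This assumes perfect (100%) amplification efficiency for both target and
reference; efficiency-corrected (Pfaffl-type) quantification is out of
scope. The method is exactly multiplicative: a shift of one cycle is a
factor of two, and f(ΔΔCt₁+ΔΔCt₂) = f(ΔΔCt₁)·f(ΔΔCt₂).

**Split-split-plot ANOVA.** Fixed treatment and block effects, three
independent Gaussian error strata (main plot = block × temperature,
subplot = block × temperature × tissue, sub-subplot = observation).
Estimation is the classical balanced-design decomposition — group-mean sums
of squares with subtraction — not REML; with balance the two coincide for
this model, and the closed form is exact, fast, and has no convergence
state. Block × treatment interactions beyond the three defined strata are
pooled into those strata (the standard convention that yields exactly three
error rows). Blocks are reported without an F ratio. Denominators:
temperature ÷ main-plot error; tissue and temperature × tissue ÷ split-plot
error; gene and every gene-containing interaction ÷ sub-subplot error.

**AMMI.** Cell means per temperature; main effects as level means minus the
grand mean; SVD of the doubly-centered residual matrix. Sums of squares are
expressed on the replicate-observation scale (means-based SS × r), which
keeps the within-cell error stratum at g·e·(r−1) df and makes the total SS
the ordinary corrected total. Each of the first two axes (default,
configurable) is F-tested with Gollob df (g + e − 1 − 2n) against the
pooled error mean square; later axes pool into a residual row. The Gollob
test is known to be liberal under the null — the leading axis of a pure
noise matrix captures more than its nominal share of SS — so its p-values
should be read as screening, not exact, inference. The test suite
quantifies this: the empirical 95% critical value of the IPCA1 F statistic
under a simulated null exceeds the nominal F quantile, and a test
calibrated against its own empirical null rejects at 5% within binomial
bounds.

**GGE.** Tissue-centered (environment-centered, unscaled) SVD of the cell
means: subtracting each tissue's mean removes μ + β_e and leaves genotype
plus interaction, which is what the biplot is meant to display. Gene scores
sum to zero on every axis as a direct consequence. Three axes are retained
for distances from the biplot origin; all plane geometry (angles, hull,
projections) uses the first two, since the biplot views are 2-D.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `n_axes` (AMMI) | 2 | axes tested individually; matches standard practice of interpreting IPCA1–2 |
| `partition` (GGE) | `symmetric` (f = 0.5) | singular values split evenly between gene and tissue scores; inner products, hence all rank-based readings, are independent of f |
| retained GGE axes | 3 | distance-from-center uses 3 axes; geometry is planar |
| p-value display floor | 1e-7 | reporting convention only; full precision kept in sidecar files |
| significance stars | ** p<0.01, * p<0.05 | reporting convention |

The symmetric partition default is also empirically the right one for
comparing against the published turbot score table: the per-axis norms of
its gene-score and tissue-score columns agree (e.g. both 1.156 on axis 1 at
14 °C), which is the signature of f = 0.5.

## The synthetic-data generator

`simulate_two_way` draws from the AMMI data-generating process itself
(additive effects + planted low-rank multiplicative interaction + i.i.d.
Gaussian cell noise); `simulate_ssp` draws the full split-split-plot layout
with the three error strata placed at the correct sharing level (main-plot
draws shared within block × temperature, subplot draws within
block × temperature × tissue, residual per observation).

Defaults reproduce the study conditions: 4 genes × 10 tissues ×
5 temperatures × 3 blocks, grand mean ≈ 1.7 relative units, and effect and
noise magnitudes chosen so each ANOVA source's expected SS sits at the
order of magnitude of the study's printed variance decomposition
(temperature spread ≈ 0.31, tissue ≈ 0.67, gene ≈ 0.55, interaction arrays
0.6–0.9; error-strata s.d. (σ_f, σ_g, σ) = (0.12, 0.10, 0.49), the last
matching the printed sub-subplot error MS ≈ 0.24; two-way interaction
singular values (5.7, 3.6) on the cell-mean scale, matching the
intermediate-stress AMMI axis SS). Planted score vectors are
orthonormalized internally (Gram–Schmidt within the zero-sum subspace) so
the planted decomposition is a valid SVD; fixed-effect arrays must sum to
zero over every index (tolerance 1e-10) or the spec is rejected.

Gaussian noise is the default because every estimator here is
least-squares/SVD based; a lognormal (multiplicative) option exists because
expression is non-negative, with the caveat that the ANOVA expectations
then hold on the log scale. Gaussian draws can produce negative values; the
analyses accept them and the generator warns.

What the generator does **not** emulate: Ct-level qPCR noise and
amplification curves, inter-gene correlation of measurement error within a
sample, heteroscedasticity across tissues (high-expressing tissues plausibly
noisier), and non-Gaussian tails. Passing tests therefore demonstrate
correctness of the estimators under their own model assumptions and
robustness of rank outputs under moderate Gaussian noise — not robustness
to every failure mode of real qPCR data.

## Numerical choices

* SVD sign indeterminacy is fixed by orienting each axis so the
  largest-magnitude tissue score is positive; signs are a convention and
  never compared to external score tables.
* Singular values below 1e-12 of the leading one are truncated to exact
  zeros so degenerate (additive or rank-deficient) data produce exact-zero
  scores instead of numerical dust.
* F ratios with a zero denominator MS (possible on noise-free synthetic
  data) are reported as NaN rather than raising.
* Which-won-where ties (equal winner projections) break by gene label
  order — arbitrary and documented; collinear gene scores fall back to two
  half-plane sectors with the extreme genes as winners.
* Zero-length tissue vectors make pairwise angles undefined; they are
  flagged on the result, not raised.
* An all-equal mean matrix is a valid degenerate GGE result (all scores
  zero), not an error; a zero average-tissue vector, by contrast, makes the
  mean-vs-stability axis undefined and is an error.
* CSV reads use round-trip float parsing so write → read → write is
  bit-identical.

## Design choices that were genuinely open

* **Ideal-point definition.** The comprehensive ranking uses the ideal
  point on the average-tissue axis at the maximum observed gene projection
  with zero instability, and ranks by Euclidean distance to it. This
  follows the concentric-circles reading of the biplot; a weighted
  mean/stability index would be an alternative, and the two can differ at
  rank level in near-ties.
* **Printed-score geometry.** Rank-based biplot outputs recomputed from the
  published score table reproduce 14 of the 15 published orderings exactly.
  The exception is ranks 3–4 of the 28 °C stability ordering, where the two
  genes' instabilities differ by ~2% (1.759 vs 1.793) — a near-tie that the
  published narrative does not resolve (it names only the top two). We
  report our computed order and flag the discrepancy rather than
  special-casing it.
* **Problem sizes in the test suite.** Oracle cross-checks run on
  2×3×2-factor designs over 100 random draws (large enough to exercise
  every SS term, small enough for loop-based oracles), and the IPCA1 null
  calibration uses 600 simulated 4×10×3 null tables split into calibration
  and evaluation halves. These sizes are the package's own choice of a
  thorough-but-quick default check.

## Known limitations

* Unbalanced or missing-cell designs are rejected; a mixed-model (REML)
  path would be needed to support them.
* Gollob df make the IPCA tests liberal (see above); no
  cross-validation-based axis selection is provided.
* Amplification-efficiency correction is not implemented.
* The replicate-level dataset of the motivating study is not
  redistributable with the package, so full-data reproduction of its grand
  means and AMMI tables requires the user to supply
  `data/appendix_a.csv`; everything derivable from the printed summary
  tables is checked without it.
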