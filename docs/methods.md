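# Methods

## The perturbation statistic

The individual differential network treats the control cohort's Spearman
correlation matrix as a fixed reference and measures the displacement a
single added respondent produces in each entry.  For edge (i, j) with
reference correlation `r = SCC_n(i,j)` over n controls,

    Z(i,j) = ΔSCC(i,j) / ((1 − r²) / (n − 1)),
    ΔSCC = SCC_{n+1} − SCC_n.

Assumptions worth stating explicitly:

* **The perturbed matrix is recomputed from raw data.**  Adding one
  respondent changes every rank, so there is no exact O(1) update for a
  rank correlation; `SCC_{n+1}` is always rebuilt from the n + 1 raw rows.
  Correctness over speed — at p = 17 and n in the hundreds each rebuild is
  about a millisecond.
* **Ties get average ranks**, the standard Spearman convention.
* **The denominator is the ratio form `(1 − r²)/(n − 1)`**, not its square
  root.  The scale of a single-observation displacement of a correlation is
  of order `(1 − r²)/(n − 1)`, which makes the ratio form a studentization
  of ΔSCC against that influence scale.  A `formula="sqrt"` switch exposes
  the square-root variant for sensitivity analysis; it is not the default.
  Empirically (see the null-calibration test) the default statistic is
  conservative: null patients exceed the Bonferroni threshold on at least
  one edge in ~2–3% of cases at a nominal 5% family level.
* **p-values use the standard normal two-sided tail** of Z, Bonferroni-
  corrected over m = 136 edges per patient.  m is a named parameter; the
  family is per patient.  The |Z| cutoff at α = 0.05 is 3.56228.
* **Degenerate edges** with r = ±1 exactly have a zero denominator; they
  are flagged non-evaluable (NaN z, never significant) rather than clamped,
  so downstream prevalence counts are explicit about exclusions.
* A patient profile must be complete; profiles with missing features are
  excluded with a warning, never imputed.

## Subtyping pipeline parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.05 | per-patient family significance level |
| `m_edges` | 136 | Bonferroni family size (all unique edges of 17 features) |
| `min_count` | 14 | patients in which an edge must be significant to be kept |
| `min_fraction` | unset | alternative prevalence threshold; stricter of the two applies |
| `k_range` | 1–8 | candidate cluster counts for the elbow rule |
| `max_iter` | 40 | Lloyd iterations per K-means run |
| `restarts` | 10 | K-means restarts; best within-cluster SS kept |

The elbow is automated as the interior k maximizing the discrete second
difference of the WSS curve (ties broken toward smaller k); the curve is
returned so a human can override the choice, since scree-plot reading is
traditionally visual.  Restarts guard against bad initializations; Lloyd
iterations are capped at 40 to match the clustering protocol this pipeline
standardizes.  Cluster labels are renumbered so cluster 1 has the lowest
mean NSSI severity, making "Group 1 / Group 2" semantics stable across
seeds.  Clustering uses the Z-standardized (population SD) selected
columns; the group comparison afterwards uses the raw, unstandardized
per-patient Z-scores, so reported means are on the perturbation scale.

Validation is resubstitution accuracy of a Fisher linear discriminant —
the field-standard check for this pipeline, reported with the caveat that
resubstitution overstates out-of-sample accuracy; stratified k-fold
cross-validation is available via `cv_folds`.

## Group statistics

Welch's unequal-variance t (Satterthwaite df) rather than the pooled-SD t:
recomputing the published comparison table from its printed group summary
statistics matches the printed t column under Welch but not under the
pooled form.  Cohen's d uses the classic pooled SD without the small-sample
(Hedges) correction, which reproduces four printed table cells exactly at 2
decimal places; the remaining rows agree to within one unit in the last
printed decimal, the residual being rounding of the printed 2-dp inputs.
Quantiles use linear interpolation between order statistics; group-mean
95% CIs use the normal 1.96 multiplier (groups are large).

## Questionnaire scoring

Reverse scoring reflects a code about its range midpoint, `(lo + hi) − x`,
an involution.  The Zung standard score is `round(sum × 1.25)` under
**round-half-up** (recorded in output metadata; plain "rounded" is
ambiguous and banker's rounding would differ on .5 sums).  NSSI frequency
categories {0, 1, 2–4, ≥5 episodes} are coded 0–3 and severities
{none..extremely severe} 0–4 — monotone integer codes bounding the total
severity at 16 × 3 × 4 = 192.  A type with frequency 0 contributes nothing
regardless of its severity code.  The 16th, open-ended self-harm type is
scored identically to the 15 listed types.  NEO-FFI and FES-CV item keys
are copyrighted, so item→dimension maps and reverse lists are user
configuration; the bundled NEO/FES specs are synthetic layouts for testing
only (block dimensions, regular reverse spacing) and say so in their
docstrings.

## Synthetic cohort generator

The generator emulates the statistical structure the method assumes, not
any particular clinical sample:

* **Controls**: latent multivariate normal with a chosen positive-definite
  base correlation matrix, mapped through strictly monotone affine
  marginals to scale-typical locations (Zung ≈ N(45–48, 10), NEO dimensions
  ≈ N(36, 7), FES dimensions ≈ N(5, 2)).  Monotone transforms preserve
  latent ranks exactly, so the Spearman structure is the Gaussian-copula
  value `(6/π) asin(r/2)` in closed form.
* **Patients**: a control-like latent draw displaced discordantly on each
  target edge (one coordinate up, the other down by the displacement, in
  latent SD units).  A single observation can only *shift* a sample
  correlation, so the planted quantity is the displacement; the achieved
  ΔSCC is measured by brute-force recomputation of both Spearman matrices
  and recorded as ground truth — no generator-internal approximation is
  trusted by tests.
* **Severity**: `baseline + coupling × Σ|achieved ΔSCC| + N(0, noise)`,
  truncated to the instrument's [0, 192] support and rounded.

Default scenario: 300 controls; subgroup 1 = 70 patients perturbing four
feature-disjoint edges at displacement 2.5, subgroup 2 = 50 patients
perturbing four other disjoint edges at displacement 3.5; base correlation
0.6 on the eight planted pairs (block-diagonal, hence positive definite)
and 0 elsewhere; severity baseline 5, coupling 1200, noise SD 6.  The sizes
keep the pipeline comfortably in the n ≫ p regime while running in under a
second; a maximally discordant single point at n = 300 can shift a Spearman
correlation by only ≈ 0.01–0.02, and the Bonferroni threshold at r = 0.6
requires |ΔSCC| ≳ 0.0076, so displacements were calibrated once by
simulation (2.5 gives ≈ 95% per-edge significance, 3.5 near 100%) and then
frozen.  The two subgroups' different displacements make subgroup 2 the
higher-perturbation, higher-severity group; coupling 1200 puts mean
severities around 70 and 78 — moderate on the 0–192 scale — with the noise
SD small enough that the severity difference is reliably detectable at
these group sizes.

What the generator does **not** emulate, and hence what passing tests do
not show about real questionnaire data: integer/ordinal marginals and the
heavy tying they produce, skewed score distributions, the dense background
correlation structure of real psychometric batteries, missing data, and
any demographic covariates.  One visible consequence: because each
subgroup's patients perturb all four of their edges together, the selected
columns are strongly collinear (VIFs far above 3), unlike the near-
independent edges reported on real data — the VIF check is exercised as a
reporting tool, not reproduced as a finding.

## Numerical and degenerate-input choices

* Spearman matrices are computed as Pearson correlations of average ranks,
  symmetrized and clipped to [−1, 1]; constant features raise by name.
* Standardization uses the population SD so standardized columns have SD
  exactly 1; a constant selected column raises by edge name.
* VIF on perfectly collinear columns reports `inf` with a flag instead of
  raising; VIF regressions use centered least squares.
* K-means is seeded and deterministic given `(seed, restarts, max_iter)`;
  WSS is nonincreasing in k by best-of-restarts construction.
* The elbow rule needs at least 3 candidate k values; ties in the second
  difference resolve toward the smaller k.
* CLI runs write a metadata JSON (seed, α, m, tie policy, formula variant,
  package version) sufficient to reproduce the run; failed runs remove
  partial outputs.

## Known limitations

* The normal reference for Z is an approximation; its accuracy degrades at
  small n and extreme reference correlations.  The implementation is
  conservative under the null in simulation, but no exact finite-n
  distribution is claimed.
* Prevalence selection with a fixed `min_count` has a different stringency
  at different cohort sizes; both count and fraction thresholds are exposed
  for that reason.
* Resubstitution accuracy is an optimistic validation metric and is
  reported as such.
* Published cluster counts, edge identities, and accuracies from real
  cohorts depend on non-public raw data; this package reproduces the
  arithmetic that is recomputable from printed summaries and demonstrates
  the pipeline's recovery properties on synthetic ground truth.
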