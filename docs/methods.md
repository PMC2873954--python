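# Methods

## The measurement model

A two-color aCGH experiment co-hybridizes sheared genomic DNA of the
platform species and of a heterologous species to an array of PCR-product
probes (~500 bp). For feature *f* on array *a* the quantity of interest is
the oriented log ratio M = log2(heterologous/platform). The package's
working model, which the synthetic generator implements and the analysis
assumes, is

    M_fa = mu_f + kinetic_f + eps_fa

- `mu_f = beta0 + beta_id * %ID_f` — the mean structure on percent
  identity. Divergence reduces heterologous hybridization, so beta_id > 0
  and diverged features have M < 0 (the platform-biased direction).
- `kinetic_f` — a per-feature constant across arrays: the deviation from
  the %ID regression line caused by sequence properties of the probe/sample
  pair. It is the sum of standardized-covariate effects
  (`beta_gc*z_GC + beta_align*z_align + beta_id_gc*z_ID*z_GC`) and a random
  component with SD `sd_kinetic(%ID)`, non-increasing in %ID. It is a
  property of the sequence pair, hence constant across technical
  replicates.
- `eps_fa` — per-observation technical noise with SD `sd_technical(%ID)`.

On the raw scale each array adds a dye-orientation sign (half the arrays
are dye-swapped), an additive dye bias, and a smooth cubic trend in the
average log intensity A; channel intensities are reconstructed as
`2^(A ± M/2)` plus additive background. These are nuisance structure that
preprocessing must remove.

## Generator defaults (the simulated study conditions)

- 18,000 usable features (reference studies use 10,000), 8 dye-swapped
  arrays, ~1000 conserved anchor features at >= 95 %ID.
- Two species profiles: *close* (mixture mode ~97 %ID, 1% missing
  orthologs) and *distant* (modes ~96.5/91/83 %ID, long tail to ~73 %ID, 5%
  missing orthologs), emulating contrasts a few versus 10–15 My diverged.
- beta0 = −10, beta_id = 0.10 per %ID (M = 0 at 100 %ID, −2 at 80 %ID,
  i.e. four-fold reduction; the slope is of the magnitude observed on
  cDNA platforms). Covariates: beta_gc = 0.12, beta_align = 0.05,
  beta_id_gc = −0.06 on standardized covariates — GC stabilizes weak
  duplexes, more so at higher divergence, hence the negative interaction.
- `sd_technical(%ID) = 0.30 + 0.012*(100−%ID)` per observation;
  `sd_kinetic(%ID) = 0.04 + 0.012*(95−%ID)+`. Both grow with divergence;
  with 8 arrays this places the point where kinetics variation overtakes
  technical error in the low-90s %ID.
- Dye bias 0.3, cubic intensity-trend amplitude 0.3, background 100 ± 20
  fluorescence units, 5% of observations forced below the quality filter.
- Missing-ortholog features carry a `NoHit` sentinel in annotations and
  hybridize at the floor of 60 %ID.
- Average log intensity A ~ N(12, 1) is drawn independently per feature and
  per array: genomic DNA gives roughly uniform copy number per feature, so
  intensity variation is mostly spot/labeling noise, which is
  array-specific. (This also means residual trend-removal errors average
  out over replicate arrays instead of acting as a per-feature offset.)

What the generator does **not** emulate: print-tip/spatial artifacts,
actual nucleotide sequences, paralog cross-hybridization, saturation, and
the heavy-tailed intensity distributions of real scanners. Passing tests
therefore validate the statistical machinery under a clean but realistic
noise model, not robustness to every artifact of physical arrays.

## Preprocessing

Quality filter: an observation is usable iff both channels' foreground is
at or above background + 2 SD(background) (SD taken per array and channel
across features) and its flag is non-negative. Background correction
subtracts background and replaces non-positive results by half the
smallest positive corrected value on that array/channel ("minimum" rule).
Normalization fits a robust loess (span 0.25, degree 1, 3 robustness
iterations) of M on A **using conserved features only**, subtracts the
interpolated curve from all features, and removes the conserved-set median
(anchor-set location centering — this makes the conserved-median-zero
contract exact rather than approximate). Dye-swapped arrays are negated.
Features usable on >= 2 arrays are flagged analyzed. The span default of
0.25 was chosen because a degree-1 smoother at wider spans leaves a
noticeable fraction of a cubic trend in place; with ~1000 anchors, a 0.25
span still averages ~250 points per window.

## Divergence calling

Per-feature means and unbiased variances over usable cells feed an
empirical-Bayes step: the variance prior (d0, s0²) is estimated by matching
the first two moments of log s² to the scaled-F sampling model, with the
trigamma inverse computed by Newton iterations (tolerance 1e-8). The
posterior variance is `(d0*s0² + d*s²)/(d0 + d)` with d = n−1, and the
moderated t has d0 + d degrees of freedom. When the observed dispersion of
log s² does not exceed the chi-square expectation, d0 is infinite and
s0² = exp(mean(log s² − psi(d/2) + log(d/2))) — the bias-corrected moment
estimate; for exactly degenerate inputs (all s² identical) the common value
itself is used, as the sampling model is then contradicted. The
implementation is cross-checked against Bioconductor limma's `squeezeVar`
in the test suite. Two-sided p-values are BH-adjusted, and a feature is
called diverged at alpha iff q < alpha **and** mean M < 0; nondirectional
significance flags are emitted alongside. Features failing filters are
reported with NA statistics, never dropped from output files.

## Calibration

- **Detection curve**: features sorted by %ID, fraction diverged in a
  moving window of 51 features (window center = mean %ID of the window),
  lowess-smoothed (span 0.3). Features with no BLAST hit are excluded from
  all calibration fits (their %ID is undefined) and counted separately.
- **ID-50**: binomial-logit GLM of the per-feature diverged indicator on
  %ID (IRLS, tolerance 1e-10); ID-50 = −intercept/slope. If the fitted
  probability never crosses 0.5 on [60, 100] the estimate is flagged
  out-of-range with its side; complete separation yields the boundary
  midpoint with a `separation` status. A windowed-proportion fit is the
  obvious alternative; the per-feature binomial GLM was chosen because it
  uses each observation exactly once.
- **Kinetics regression**: OLS of mean M on %ID crossed with GC, probe
  length and percent alignment. With `standardized=True` all variables are
  z-scored first and the per-covariate effect as a function of %ID is
  `beta_cov + beta_%ID:cov * z(%ID)`.
- **Variance partition**: technical = mean per-feature SE of the fitted
  mean (sqrt(s2_post/n)); kinetic = median absolute residual of the
  M ~ %ID regression divided by 0.6745 (the 0.75 normal quantile, making
  the estimator consistent for a normal SD). Default geometry: sliding
  windows of 301 features (wider than the detection window for a stable
  median); explicit %ID bins are also supported and are used for crossover
  location, where 5-%ID bins give a stable robust scale per bin. Note the
  measured kinetic curve necessarily contains the sampling error of the
  fitted mean, and the moderated technical curve is pulled toward the
  pooled prior; the design-implied reference curves in `cghdiv.studies`
  model both effects when checking crossover recovery against planted
  truth.
- **Replication power**: every k-combination of arrays (capped at 70,
  seeded sampling beyond that; at 8 arrays all 28/70/28/1 combinations for
  k = 2/4/6/8 are retained) is re-analyzed end-to-end and averaged.

## Homology and GO

Top-hit selection minimizes e-value with ties broken by larger bit score,
then input order; hits above e-value 1e-14 are discarded and such queries
report `NoHit`. Percent alignment = 100 * alignment length / probe length,
deliberately allowed above 100 (insertions inflate alignments). Multiple
HSPs are not merged. GO annotations are closed under DAG ancestry
(true-path rule) before testing. Representation uses the hypergeometric
distribution with the observed count included in both tails; p-values are
reported uncorrected with a 0.01 flag threshold (a BH option exists but is
off by default, matching the convention of reporting uncorrected GO
p-values). The universe is the set of analyzed features' genes with at
least one annotation; a gene enters a diverged or four-fold set if **any**
of its features qualifies, and the four-fold rule is strict
(mean M < −log2(4)).

## Numerical and design notes

- All randomness flows through `numpy.random.default_rng` seeded from the
  config; identical configs produce byte-identical outputs, including
  written files (floats are serialized with shortest round-trip repr and
  parsed with round-trip precision).
- The multi-array survival threshold defaults to 2; the quality filter
  requires both channels to pass; flags follow the GenePix convention
  (negative = bad).
- The logistic ID-50 shift-equivariance, BH step-up, and hypergeometric
  tails are each verified against brute-force oracles in the test suite;
  parameter recovery (slope, detection midpoint, crossover, interaction
  sign) is verified against the generator's planted truth on
  10,000-feature studies.
- Reference study sizes (10,000 features for calibration studies, 4,000
  for the null and normalization studies, 3,000 x 3 species for the
  intersection study) keep full-suite runs fast while leaving Monte-Carlo
  error well inside the asserted tolerances.

## Known limitations

- The linear M–%ID relationship is assumed throughout; real data deviate
  from linearity below ~75 %ID, which is neither simulated nor modeled.
- The kinetic estimator cannot separate kinetics variation from the
  sampling error of the fitted mean where the two are comparable; crossover
  locations are only sharply identified when the kinetic scale changes
  quickly with %ID.
- The toy GO DAG (33 terms) exercises propagation and testing logic; it is
  not a faithful ontology. Real analyses should supply their own edge list
  and annotations.
- Paralog cross-hybridization, spatial artifacts and between-array
  normalization are out of scope.
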