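# Methods notes

This note records the models implemented in `seasonomics`, the choices
made where the design was genuinely open, and what the synthetic
cohort does and does not emulate.

## Seasonal model

For one analyte with observations \(y_i\) at day-of-year \(d_i \in
[1, 365]\) from subject \(s(i)\):

\[ y_i = \beta_0 + x_i^\top\gamma + b_{s(i)} + f(d_i) + \varepsilon_i \]

- \(x_i\): covariates; IR/IS status (indicator) and BMI by default,
  age and BMI for the group-specific fits of the interval test (group
  is constant within a group and is dropped there).
- \(f\): cyclic cubic regression spline on the circle of period 365,
  parameterized by its values at K = 10 evenly spaced knots over
  [1, 366). The value/second-derivative construction guarantees the
  function and its first two derivatives match at day 1 and day 366,
  and the roughness penalty \(\int f''^2\) is the exact quadratic form
  \(\beta^\top D^\top B^{-1} D\,\beta\) with the constant function as
  its null space. The smooth is sum-to-zero constrained over the
  observed rows so the intercept is identified.
- \(b_s\): subject random intercepts, implemented as ridge-penalized
  subject indicators — the penalized-regression representation of a
  Gaussian random intercept with \(\lambda_b = \sigma^2/\sigma_b^2\).
- Fitting minimizes \(\|y - X\beta\|^2 + \lambda\,\beta_s^\top S
  \beta_s + \lambda_b \|b\|^2\). \((\lambda, \lambda_b)\) are chosen
  by GCV, \(n\,\mathrm{RSS}/(n - \mathrm{EDF})^2\), over log-spaced
  grids (30 points \(10^{-4}..10^6\) for \(\lambda\); 5 points
  \(10^{-2}..10^2\) for \(\lambda_b\); the penalty matrix is rescaled
  to unit spectral norm so the grid spans "unpenalized" to "flat").
  GCV keeps the whole procedure deterministic: no REML iteration, no
  convergence tolerance beyond linear algebra.
- Uncertainty: \(\mathrm{Var}(\hat\beta) = \hat\sigma^2 (X^\top X +
  P)^{-1}\); the 95% band of the annual curve is fit ± 1.96 × the
  propagated SD, with covariates held at their sample means and the
  subject block at zero.

Degenerate inputs: missing values are dropped per analyte; analytes
with fewer than `n_basis + n_covariates + 2` observations are reported
as *not fitted* rather than raising; days outside [1, 365] are
validation errors (calendar dates should be mapped with
`cohort.day_of_year`, which clamps leap day 366 to 365).

### Seasonality test

The seasonality call compares the model with and without the smooth by
the deviance difference \((\mathrm{RSS}_0 - \mathrm{RSS}_1) /
\hat\sigma_1^2\) against \(\chi^2_{df}\) with \(df = \max(1,
\mathrm{round}(\mathrm{EDF}_{smooth}))\). A subtlety mattered here: if
the test is evaluated at the GCV-selected fit, adaptive smoothing
biases it — simulation showed type-I error ≈ 0.15 at nominal 0.05,
because the selected EDF and the deviance difference are strongly
coupled. The test therefore uses the *unpenalized*-smooth fit, whose
smooth EDF is exactly its dimension (K − 1 = 9), reducing the formula
to the classical likelihood ratio test between nested linear models.
Measured on 500 simulated null analytes the empirical type-I error is
≈ 0.05, and power at per-observation SNR 3 (and even SNR 1) with 480
observations is ≈ 1. The smoothed fit is still what is reported and
clustered; only the test statistic comes from the unpenalized fit.
Across analytes the selection rule thresholds raw p ≤ 0.05 (no
multiplicity adjustment); `fit_table(adjust=True)` adds a BH column
for users who want it.

## Pattern discovery

Clustering operates on fitted annual curves evaluated on days 1..365
and z-scored per feature — curve space rather than raw spline
coefficients, which are basis-dependent. Fuzzy C-means follows the
Bezdek alternating scheme (membership update \(u_{ij} = 1/\sum_l
(d_{ij}/d_{il})^{2/(m-1)}\), centroid update as \(u^m\)-weighted mean)
to an objective change < 1e-9 or 1000 iterations, keeping the best of
10 seeded restarts; the objective is non-increasing across iterations.
Defaults: fuzzifier m = 2; k scanned over 2..10 (silhouette is
undefined at k = 1, so the scan starts at 2); silhouette computed on
hardened (argmax) labels with Euclidean distance; a partition that
hardens to a single label scores −1. Membership projection evaluates
the same membership formula against frozen centroids; a curve exactly
on a centroid gets a unit vector. Curves with zero variance across
days cannot be standardized and are excluded with a log message.

## Interval-wise group differences

The year is discretized to T grid points (T = 365 for full fidelity;
T = 52, weekly, is the desk-scale default that keeps B = 1000-style
permutation runs tractable — the grid is explicit in all outputs).
Per-interval areas use the trapezoid rule over the unit interval.
Pointwise SEs propagate the full coefficient covariance of each group
fit. Design choices:

- **Permutation unit.** Group is a subject-level attribute with
  repeated measures, so the default permutes subject-to-label
  assignments (all of a subject's visits move together); per-sample
  permutation is available via `unit="sample"` for literal label
  shuffling.
- **Directionality.** The pooled exceedance count is one-sided in the
  observed statistic's direction, combined with the adjusted-p < α/2
  threshold — the only reading under which the α/2 rule gives two-sided
  control at α.
- **Zero p-values** are kept exactly as the count produces them (no
  pseudo-count), preserving the printed formula; with B = 200 and
  T = 52 the smallest attainable p is 1/10200.
- **BH scope.** Adjustment is per feature across its T − 1 intervals.
- **Classification.** "Global" = every interval significant,
  "partial" = at least one but not all, "none" otherwise; contiguous
  significant intervals are merged into day ranges, including across
  the day 365 → 1 wrap (a wrapped range is reported with start > end).
- Group fits use a coarser λ grid (12 points) than the headline
  seasonal fits; with 2(B+1) refits per feature this cuts runtime ~2.5×
  with no visible effect on the curves.

Measured operating characteristics (test suite): on null features the
statistic pool and observed statistics are exchangeable; a 90-day
injected window with effect 2× the noise SD (40 subjects × 12 visits,
T = 52, B = 200) is recovered with Jaccard ≥ 0.5 in ≥ 80% of
replicates, typically 0.6–0.9 — spline smoothing blurs the window edges
by roughly one smoothing bandwidth, which bounds the attainable
Jaccard.

## Richness

Chao1 uses singleton/doubleton counts: bias-corrected
\(S_{obs} + F_1(F_1-1)/(2(F_2+1))\) by default (defined at \(F_2 = 0\));
classic \(S_{obs} + F_1^2/(2F_2)\) switchable, with the bias-corrected
form as its \(F_2 = 0\) fallback. The estimator is delegated to
scikit-bio and pinned by exact hand-computed values in the tests.
Counts are aggregated to genus/family/order/class/phylum by summing
within lineage groups (taxa missing from the map bucket to
"unclassified"; totals are conserved). No rarefaction is applied before
estimation. The winter-vs-summer summary contrasts the fitted annual
richness curve between days {1..60, 335..365} and days {152..244}.

## Synthetic cohort

The generator emulates the study design, not its molecular content:

- Visits: each subject gets `n_years × visits_per_year` visits with
  day-of-year i.i.d. uniform on {1..365} (collections were spread
  roughly evenly over the year); desk-scale default 40 subjects × 3
  years × quarterly; `full_cohort()` gives the 105-subject, 4-year
  scale. IR fraction defaults to 0.5 (the characterized subset of the
  cohort was 35 IR / 31 IS); BMI ~ N(28, 4²), age uniform 25–75.
- Archetypes: von-Mises-shaped bumps on the circle, centers day 115
  (late April) and day 350 (December, hence a trough in March–July),
  concentration set so FWHM ≈ 120 days; each standardized to mean 0,
  SD 1 over the year so `amplitude/noise_sd` is the per-observation
  SNR. A two-bump variant models twice-a-year analytes.
- Analytes: subject baseline N(0, subject_sd²) + amplitude ×
  archetype(day − jitter) + optional BMI slope + group effect
  (IR only, raised-cosine ramped inside a day window, 15-day ramps) +
  N(0, noise_sd²). Defaults noise_sd = subject_sd = 1, seasonal
  amplitude 3, differential effect 2, phase jitter ±10 days. The
  cohort paper states no per-ome noise magnitudes, so these are free
  parameters chosen once as a realistic desk-scale regime and
  documented here, not calibrated to any dataset.
- Taxon counts: per-visit multinomial over a geometric base-abundance
  profile; the number of taxa present follows a smooth annual cycle
  whose deep-winter level is `winter_richness_boost` × the mid-summer
  level (default 1.5; 120 taxa, 8000 reads, summer presence fraction
  0.45). Lineages nest taxa 3-to-1 into families and onward to 5 phyla.

What passing tests on this generator show — and what they do not: the
pipeline recovers the structure the generator encodes (two patterns,
differential windows, winter richness) under Gaussian noise, balanced
design and uniform sampling. Real cohort data add heteroscedastic and
heavy-tailed noise, ome-specific missingness, uneven visit spacing,
batch structure and compositional microbiome effects, none of which
the generator models; results on it validate the machinery, not any
biological claim.

## Numerical conventions

- All randomness flows from explicit integer seeds via numpy
  Generators; same seed ⇒ bit-identical outputs, including pipeline
  output checksums.
- Day coordinates are 1-based inclusive in [1, 365] everywhere.
- Fuzzy C-means convergence 1e-9 on the objective; penalized solves
  via Cholesky with an exact `lstsq` fallback at zero penalty; ties in
  silhouette argmax resolve to the smallest k.
- Desk-scale problem sizes used throughout the tests (40 × 12 visits,
  T = 52, B = 200, 10 restarts) are the package's default operating
  point; the full-fidelity settings (T = 365, B = 1000) are plain
  configuration changes.

## Known limitations

- The seasonal model is Gaussian with random intercepts only — no
  random slopes, non-Gaussian families or tensor smooths; microbiome
  values entering the interval test are assumed normalized upstream.
- GCV rather than REML for smoothing selection; a reference
  mixed-model smoother would differ in the selected λ, though not
  materially in the fitted curves at these data sizes.
- The silhouette criterion cannot score k = 1, so "no structure" shows
  up as a low maximal silhouette rather than a chosen k of 1.
- Permutation p-values are granular at 1/(B(T−1)); interval calls at
  the α/2 threshold inherit that granularity.
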