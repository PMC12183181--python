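# Methods

This note documents the models and procedures `fcpipe` implements, the
defaults and why they were chosen, what the synthetic cohorts do and do not
emulate, and the numerical decisions a maintainer would want to know.

## Cohort model and synthetic data

The package targets three-group, multi-site resting-state designs: two
depression subtypes split by anxiety severity (HAD with HAMA > 14, LAD with
HAMA < 14) and healthy controls, scanned at several sites. The synthetic
generator (`fcpipe.synthetic`) emulates this structure so the inference chain
can be validated by parameter recovery:

- **Signals.** Each subject's ROI series is a stationary Gaussian AR(1)
  process `x_t = φ x_{t−1} + √(1−φ²) L ε_t`, with `L` the Cholesky factor of
  the group correlation matrix, so the stationary cross-ROI correlation
  equals the target exactly and each ROI's lag-1 autocorrelation equals φ
  (default 0.4, a typical value for 2-s sampling; in [0, 1)). Default
  T = 240 volumes at TR = 2 s, so after discarding 10 volumes a scan of 230
  volumes remains and the 100-s/2-s window scheme yields 181 windows. The
  AR(1) process is the minimal temporal model that makes the windowed-CV
  statistic nondegenerate; no generative model is claimed beyond that.
- **Group effects.** Static effects add a delta to the target correlation of
  named edges in a named group (nearest-PD eigenvalue clipping at 1e−6 with a
  warning if a combination of deltas breaks positive definiteness; deltas
  that push |r| ≥ 1 are rejected). Dynamic effects alternate an edge's
  correlation between base ± delta in 50-s blocks, inflating windowed-r
  variability without moving its long-run mean.
- **Site effects.** At the signal level, a per-site scalar gain
  (log-normal, SD `site_scale_sd`) and offset (normal, SD `site_shift_sd`).
  Because Pearson correlation is invariant to per-column affine maps, these
  deliberately do **not** leak into FC features; they are detectable in
  signal variance and exercise the IO/preprocessing contract. For
  harmonization tests a feature-level injector follows the ComBat
  location–scale model exactly: `y = signal + shift_site,v + scale_site,v · noise`.
- **Phenotypes.** Age ~ N(33.5, 11) clipped to [18, 65], sex Bernoulli(½),
  education ~ N(11.2, 3.5) clipped to [3, 22], mean FD ~ |N(0.10, 0.045)|
  (so a realistic minority of subjects exceeds the 0.2-mm exclusion
  threshold). HAMD and HAMA are truncated normals with the published group
  means/SDs (HAD 20.47 ± 3.04 / 25.52 ± 5.39; LAD 20.16 ± 4.92 /
  10.78 ± 2.93); control values are not published and are set to screened
  levels (1.6 ± 1.5 / 4.0 ± 2.5). Truncation enforces HAMA > 14 for every
  HAD subject and < 14 for every LAD subject, so group labels are consistent
  with the defining threshold by construction. Clinical scores are drawn
  independently of the demographic covariates; real symptom scales
  correlate with age and education, which these cohorts do not emulate.

What passing tests on these cohorts show: the pipeline recovers effects of
the planted kind at the planted scale under Gaussian, stationary (or
block-switching) signals with exchangeable subjects. What they do not show:
robustness to hemodynamic nonlinearity, non-Gaussian noise, motion artifact
structure beyond a scalar FD covariate, or atlas/extraction error — none of
which the generator models.

## Preprocessing

Fixed stage order: drop initial volumes (default 10) → linear detrend →
nuisance regression (intercept always included; a generic T×K regressor
matrix, e.g. Friston-24 + WM + CSF, supplied by the caller) → band-pass.
The band-pass is a second-order Butterworth applied forward–backward
(`sosfiltfilt`), the de facto resting-state standard: zero phase, passband
(0.01–0.1 Hz) amplitudes preserved within 5%, ≥ 90% amplitude attenuation at
twice the upper cutoff. Subjects with mean FD strictly greater than 0.2 mm
are excluded ("larger than" read strictly: exactly 0.2 is kept).

## Connectivity

Edges are ordered row-major over the strict upper triangle, matching
`np.triu_indices`. Static FC clips r into [−1+1e−7, 1−1e−7] before `atanh`,
so perfect correlations map to ≈ ±8.4 rather than ±∞. Zero-variance ROIs
produce NaN at their edges and are reported, never silently zeroed.

Sliding windows: `window_samples = floor(window_s / TR)` (≥ 3),
`step_samples = max(1, round(step_s / TR))`, half-open 0-based ranges, no
truncated trailing window. The 100-s default respects the rule that the
window must cover one period of the slowest passband frequency (1/0.01 Hz).
The dynamic statistic is `CV = SD_{n−1}(r_w) / max(|mean(r_w)|, 1e−6)`,
computed on raw windowed r by default (a `use_fisher_z` switch enables
z-domain CV for sensitivity analyses). The absolute value and the 1e−6 floor
handle near-zero-mean edges, where a raw CV is sign-ambiguous and unbounded;
floored edges are flagged in the result metadata, and edges with fewer than
two valid windows are missing. Note the CV of a near-zero-mean edge is
dominated by the denominator and is reported but scientifically
uninterpretable — downstream users should respect the flags.

## ComBat harmonization

Parametric empirical-Bayes ComBat (location–scale model
`y_ijv = α_v + x_j'β_v + γ_iv + δ_iv ε_ijv`): features are standardized by
the covariate-adjusted OLS fit (site indicators + covariates, full-rank
required), per-site location/scale estimates are shrunk toward normal /
inverse-gamma empirical priors with moment-matched hyperparameters, and the
conditional posterior modes are found by the standard fixed-point iteration
(tolerance 1e−4), matching the canonical reference implementation — verified
to < 1e−6 maximum absolute difference on a frozen fixture
(`tests/data/combat_fixture.csv` and the reference output alongside it).
Static and dynamic features are harmonized separately (each kind has its own
scale). Sex enters as a single 0/1 indicator; continuous covariates are
passed unstandardized (the linear model is scale-equivariant). Features with
missing values are excluded from fitting and passed through with a warning;
unseen site labels are rejected rather than extrapolated.

One preservation subtlety: harmonization maps every site's residual scale to
the *pooled* scale, which is the only scale identifiable from the data. Under
a planted multiplicative noise effect the per-feature covariate correlation
therefore moves relative to the (unobservable) pre-site benchmark by an
amount that does not shrink with n; the package's preservation checks bound
the per-feature maximum change only for location-type site effects and use
the mean absolute change (< 0.05) when scale effects are planted.

## Edgewise inference

One-way fixed-effects ANOVA per edge (vectorized sums of squares; df
(g−1, N−g); features constant across all subjects get F = 0, p = 1 and a
flag), Benjamini–Hochberg step-up FDR (field default; the
Benjamini–Yekutieli variant is out of scope), and pooled-variance two-sided
post-hoc t-tests restricted to FDR-significant edges (Welch behind a flag).
Post-hoc results include a qualitative pattern label (`HAD<HC, HAD<LAD,
LAD~HC`-style) derived from which pairs pass the uncorrected α = 0.05.
Group covariates are deliberately **not** included in the edgewise ANOVA —
they are handled upstream by ComBat; this mirrors the analysis protocol the
package implements and is worth knowing when comparing to ANCOVA-style
pipelines. Static and dynamic features form separate FDR families.

Summary-statistic operations (chi-square from counts without continuity
correction; ANOVA reconstructed from means/SDs/ns; pooled t from summaries)
reproduce published demographic tables from their printed values: sex
chi-square p = 0.9238, age ANOVA p = 0.4962, education ANOVA p = 0.7450,
HAMD t-test p = 0.6616 — all within rounding of the printed 0.923 / 0.497 /
0.749 / 0.655 (the t-test is the loosest because both group SDs enter
rounded).

## Clinical association

The symptom coupling score is HAMD/HAMA (requires HAMA > 0). Edge–symptom
association uses partial correlation: Pearson on the residuals of both
variables after OLS on [intercept | age, sex, education, FD], with
p from `t = r√(df/(1−r²))`, df = n − 2 − K. Edge–edge association is plain
per-group Pearson (no covariates), two-sided. Edge selection is an explicit
input to the association functions, decoupling selection from correlation.

## Validation design and problem sizes

The acceptance script and tests use cohorts scaled to single-CPU runs while
keeping the statistical regime of interest: null calibration uses 20
replicate cohorts of 3 × 30 subjects, 50 ROIs (1,225 edges), T = 240;
recovery plants Δr = 0.3 at 15 of 1,225 edges with n = 40/group. A pilot at
seed 0 gave recall 1.00 and precision 1.00; the CI gates are recall ≥ 0.8
and precision ≥ 0.6, set below the pilot to absorb seed-to-seed variation in
a 15-edge count without masking a real regression. Null calibration for the
rejection rate uses static-z features (the cheapest fully-pipelined feature
kind); measured rate ≈ 0.050 and mean BH false-discovery proportion ≈ 0.001
across the 20 replicates.

## Known limitations

- ROI series in, ROI series out: no volume-level processing (slice timing,
  realignment, normalization, atlas extraction) — upstream tools own those.
- Rectangular windows and CV only; no tapering, state clustering or HMM
  summaries of dynamic FC.
- Parametric EB ComBat only (no nonparametric, longitudinal or GAM
  variants).
- The pipeline's clinical stage reports associations for all post-hoc
  significant edges; causal or mediation claims are out of scope.
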