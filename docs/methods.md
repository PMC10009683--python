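# Methods

## The percussion entropy index

The index quantifies directional coupling between two per-beat series of
a pulse pressure signal: peak-to-peak intervals (PPI, ms) and waveform
amplitudes (WA, arbitrary pressure units). Each series of length N is
reduced to N−1 binary fluctuation directions; a tie (equal successive
values) codes as 0, the same branch as a decrease. The percussion rate
`PR_s^m` is the fraction of positions at which an m-long binary window of
the PPI pattern equals, element-wise, the WA pattern window shifted by s
beats, the window count being n−m−s+1 with n = N−1. The index is

    PEI(m, S) = ln( Σ_{s=1..S} PR_s^m / Σ_{s=1..S} PR_s^{m+1} ),

with defaults m = 2 and S = 1 (a single one-beat shift; general S sums
over s = 1..S). `PR_s^{m+1}` is obtained by substituting m → m+1 in the
rate formula, so its window count is n−(m+1)−s+1; any other upper limit
would index windows past the end of the binary series.

Interpretation anchors: if the WA pattern is an exact lag-s copy of the
PPI pattern, both rates are 1 and PEI = 0; if the two patterns are
independent fair coins, an m-window matches with probability 2^−m, so
PEI → ln 2 ≈ 0.693. A zero rate sum (patterns that never match, e.g.
strictly antiparallel series) makes the log-ratio undefined and raises a
typed error rather than returning ±∞: it marks a degenerate recording of
the kind an HRV protocol would discard, and silent infinities would
poison downstream cohort statistics. No health interpretation is encoded:
the literature is not consistent about the direction of the health–PEI
mapping at the signal level, so the package computes the formula and
leaves interpretation to the analyst. Cohort tables carry PEI × 100
("percent" display scale); the raw value is always retained.

The vectorized rate (stride-tricks window comparison) is verified in the
test suite against an exhaustive triple-loop enumeration, exactly, across
series lengths 10–699, m = 1..3, s = 1..2; a deliberately naive
implementation (`percussion_rate_naive`) ships in the package for
independent verification.

## Synthetic data

No raw recordings are distributed, so two generators stand in for them.

**Signal level.** `gen_ppi_wa` draws PPI as a Gaussian random walk around
800 ms (step SD 8 ms, clipped per step to the physiological range
400–1500 ms) and builds WA so that its direction pattern copies the PPI
pattern at the given lag with probability `rho` per position, otherwise
an independent fair coin; step magnitudes are uniform on [0.5, 2] with a
positivity guard that preserves the intended direction. `rho` therefore
interpolates the index between its two limits: PEI = 0 at `rho = 1`
exactly, and PEI near ln 2 at `rho = 0`. `gen_waveform` renders one
compact raised-cosine pulse per beat, centred exactly on a sample with
half-width 40% of the smaller neighbouring interval, so pulses never
overlap, the rendered peak amplitude equals the beat's WA exactly and
peak spacing realises the PPI series to within half a sample;
`extract_peaks` (minimum-separation local-maximum detection) closes the
round trip. `calibrate_coupling` inverts the monotone map
rho → E[PEI] by bisection on a common-random-number Monte-Carlo estimate
(200 simulations per evaluation; the bisection stops when the estimated
mean is within a quarter of the 0.02 tolerance of the target, leaving
headroom for the estimator's own error).

A single 700-beat series estimates the index with sampling SD ≈ 0.065,
so tests of the independence limit assert the mean over replicates, not
a lone draw.

**Cohort level.** The statistics path does not route through waveforms
(there is no credible mapping from supplement intake to signal-level
coupling); `gen_cohort` instead draws per-subject PEI-percent values
directly as

    y_igt = μ_gt + u_i + e_igt,   u_i ~ N(0, ρσ²),  e_igt ~ N(0, (1−ρ)σ²),

a complete two-group (20 control, 10 experimental) × four-timepoint
design with exchangeable within-subject correlation ρ (`within_corr`).
The default cell means μ_gt are the trial's reported per-timepoint
reference means for controls (56.800, 60.750, 62.500, 64.970) with group
differences (−1.075, +1.910, +3.935, +4.040) added for the experimental
arm. The variance anchor is the reported between-subjects error mean
square 23.662: `error_sd²` is defined as the *targeted between-subjects
error MS*, and the per-observation variance is derived as
σ² = error_sd²/(1 + 3ρ) so that E[error MS] = error_sd² holds for any ρ.
The default ρ = 0.107 is the value that puts the within-subject residual
SD at 4.0, which keeps simulated pairwise-contrast standard errors
(≈ 1.1) inside the range the trial's pairwise table prints
(0.829–1.505). The trial reports no within-subject covariance matrix, so
exchangeable is the minimal assumption; its unequal printed SEs hint at
an unstructured covariance, and the suite accordingly accepts externally
supplied contrast diff/SE pairs without claiming the two routes coincide.

What the generator does *not* emulate: respiration and baroreflex
dynamics, reactive-hyperemia physiology, measurement dropout, any
pharmacological action of the supplement, or a covariance structure
richer than exchangeable. Passing tests therefore demonstrate the
correctness of the algorithms and the internal consistency of the
inference pipeline under the stated model — not the physiological
validity of the index on real recordings.

## Statistics

All procedures assume the complete mixed design; incomplete subjects
raise an error rather than being dropped silently.

- **Between-subjects table** — one-way Type-III ANOVA on subject means,
  scaled by the number of timepoints; with two groups the Type-III group
  SS is 4·(n₁n₂/N)(m̄₁−m̄₂)² and the intercept SS uses the effect-coded
  (unweighted) grand mean. Partial η² = SS/(SS+SS_error).
- **Multivariate within-subject tests** — TIME and TIME × GROUP are
  tested on the q = 3 successive difference variables in the
  effect-coded two-group GLM. Roy's largest root is the top eigenvalue
  λ of H·E⁻¹; its F transform λ(df_err−q+1)/q on (q, df_err−q+1) df is
  exact here because both hypotheses have a single degree of freedom
  (in general it is an upper-bound test and is labelled as such).
  Partial η² for Roy is λ/(1+λ).
- **Estimated marginal means** — cell means are arithmetic; time margins
  average the two group cell means unweighted (the convention of the
  legacy software family for unequal groups), with subject-weighted
  margins available as an option.
- **Pairwise time contrasts** — differences of unweighted time margins
  with standard errors from pooled within-group difference scores,
  df = N−2 = 28, Bonferroni family k = 6 (the 4-choose-2 distinct
  pairs): p_adj = min(1, k·p) and simultaneous CI
  diff ± t_{1−α/(2k), df}·se. At df = 28, k = 6 the multiplier is
  t ≈ 2.839, the value that reproduces the trial's printed CIs from its
  printed diffs and SEs.
- **Per-timepoint estimates** — OLS of PEI on the group indicator with
  control as reference: intercept = control mean, B = group difference,
  pooled-variance SEs at df = N−2, η² = t²/(t²+df).
- **Screens** — the KS normality test uses sample-estimated parameters
  with the asymptotic Kolmogorov p (the legacy one-sample dialect;
  Lilliefors behind `--ks lilliefors`); Levene is mean-centred by
  default (`--levene-center median` gives Brown–Forsythe); Mann–Whitney
  uses exact enumeration when untied and n₁n₂ ≤ 400, else the tie- and
  continuity-corrected normal approximation.

Sphericity-corrected univariate within-subject tables and the
Pillai/Wilks/Hotelling statistics are out of scope (the analysis reports
the multivariate route with Roy's root only), as are mixed-effects/REML
fits and missing-data handling.

## Verification of the published arithmetic

The printed inference inputs (pairwise mean differences and SEs,
between-subjects sums of squares, per-timepoint coefficients) ship as a
versioned in-package fixture; `verify_paper_tables` recomputes every
p-value, CI bound, F and effect size from them. Matching tolerances are
printed precision (half a unit in the third decimal) widened by the
propagated half-ULP of the inputs' own rounding: p and F to 5·10⁻⁴,
effect sizes to 10⁻³, CI bounds to 2.5·10⁻³ (a CI bound multiplies the
rounded SE by ≈ 2.84, so its reproducible precision from 3-d.p. inputs
is ≈ 2·10⁻³).

## Numerical and design notes

- Degenerate ANOVA input (zero between-subject variance) yields a report
  flagged `degenerate` with inference fields empty, rather than raising:
  all-constant data is a representable, if pathological, dataset.
- All generators take integer seeds into `numpy` Generators; identical
  seeds give bit-identical output, and derived child seeds come from
  `SeedSequence` so independent stages decouple.
- Pipeline runs write cohort CSV, JSON report, rendered Markdown tables
  and a verification checklist; timings and seeds go to the run log only,
  keeping the report files byte-identical across reruns of one config.
- Rendered tables round p-values to 3 decimals; report objects keep full
  precision.
- Simulation sizes in tests (e.g. 1200 null cohorts for the type-I-error
  check, 300 recovery cohorts, 100-replicate coupling grids) were chosen
  so Monte-Carlo error is small against each assertion's band while the
  suite stays quick to run routinely.

## Known limitations

- The cohort generator reproduces means and one variance anchor, not a
  full covariance structure; simulated pairwise SEs are homogeneous
  across pairs where the trial's printed SEs are not.
- The between-subjects intercept SS printed by the trial is not
  consistent with its own cell means (its Group SS and error MS are);
  verification treats the printed SS as inputs and checks the arithmetic
  built on them.
- The index's window statistics are exact but the signal-level generator
  is stylised (unimodal pulses, Gaussian interval walk); it validates
  algorithms, not physiology.
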