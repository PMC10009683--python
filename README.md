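# hrvtrial

Percussion-entropy heart-rate-variability analysis and the full
mixed-design repeated-measures inference pipeline for a two-group,
four-month intervention trial, with a synthetic-data generator in place of
raw cuff-pressure recordings.

## The problem

Heart-rate variability (HRV) indexes cardiovascular autonomic regulation;
non-linear HRV statistics are used to screen young adults for early
cardiovascular risk and to measure the effect of interventions (here, a
daily carotenoid-containing supplement over three months). This package is
for biostatisticians and physiological-signal researchers who need:

- the **percussion entropy index (PEI)**, a cross-entropy-style statistic
  of the coupling between per-beat **peak-to-peak intervals** (PPI, ms)
  and **waveform amplitudes** (WA) of a pulse pressure signal, and
- the complete inference pipeline for a **mixed design** — one
  between-subjects factor (control, n = 20, vs experimental, n = 10)
  crossed with four monthly measurements (T1–T4) — including Roy's
  largest root multivariate tests, Bonferroni-adjusted estimated marginal
  mean contrasts and per-timepoint parameter estimates.

## The statistic

Both per-beat series are reduced to binary fluctuation directions
(1 = increase, 0 = decrease-or-tie):

    a_i = [PPI(i+1) > PPI(i)],   b_i = [WA(i+1) > WA(i)],   i = 1..N-1.

The *percussion rate* at embedding dimension m and shift s is the
fraction of exactly matching windows

    PR_s^m = (1 / (n-m-s+1)) * sum_i [ a(i..i+m-1) == b(i+s..i+s+m-1) ],

with n = N - 1, and the index is the log-ratio across dimensions

    PEI(m, S) = ln( sum_{s=1..S} PR_s^m / sum_{s=1..S} PR_s^{m+1} ),

computed at the study values m = 2, S = 1. Perfectly coupled series give
PEI = 0; independent fair-coin fluctuations give PR^2 -> 1/4,
PR^3 -> 1/8, hence PEI -> ln 2 ≈ 0.693. Cohort-level PEI values are
reported on the percent scale (PEI × 100).

The inference side implements the one-sample Kolmogorov–Smirnov normality
screen (legacy estimated-parameter dialect, Lilliefors behind a flag), the
Mann–Whitney–Wilcoxon test (exact enumeration for small untied samples),
Levene's variance-homogeneity test, a Type-III between-subjects table,
Roy's largest root (largest eigenvalue of H·E⁻¹ on the three
within-subject difference variables, with its exact-F transform),
unweighted estimated marginal means, Bonferroni pairwise contrasts with
simultaneous CIs, and per-timepoint OLS parameter estimates with
η² = t²/(t²+df).

## Worked example

```python
from hrvtrial import *

# signal level: a 700-beat series whose WA direction copies the PPI
# direction at lag 1 with probability 0.6
series = gen_ppi_wa(CouplingSpec(rho=0.6, lag=1, n_beats=700, seed=42))
print(pei(series.ppi, series.wa).to_dict())

# cohort level: 20 + 10 subjects, four monthly measurements
cohort = gen_cohort(CohortSpec(seed=42))
report = mixed_rm_anova(cohort)
group = next(r for r in report.between_table if r.source == "Group")
print(group.F, group.p, group.partial_eta_sq)
for roy in report.roy_tests:
    print(roy.effect, roy.F, roy.p)
```

prints (rounded)

```
{'pr_m': [0.5997], 'pr_m1': [0.4612], 'pei': 0.2626, 'pei_percent': 26.26, 'm': 2, 'S': 1, 'n': 699}
Group   F = 6.255   p = 0.019   partial eta^2 = 0.183
TIME           F = 71.329  p < 0.001
TIME x GROUP   F = 5.047   p = 0.007
```

The PEI of 0.263 sits between the perfect-coupling limit (0) and the
independence limit (ln 2 ≈ 0.693), as expected for 60% directional
coupling. In the simulated cohort the supplemented group's PEI rises
faster over the four months than the control group's, which the
TIME × GROUP multivariate test detects.

The same pipeline is available from a shell:

```sh
hrvtrial generate --seed 1 --out cohort.csv
hrvtrial analyze cohort.csv --emm-weighting unweighted
hrvtrial verify
hrvtrial run-all --seed 1 --out-dir runs/demo
```

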