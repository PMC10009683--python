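"""Percussion-entropy HRV index and the mixed repeated-measures trial pipeline.

This module implements, in the order the analysis runs:

1.  **Percussion entropy index (PEI)** — a non-linear heart-rate-variability
    statistic computed from two paired per-beat series recorded by a
    cuff-type pulse sensor: peak-to-peak intervals (PPI, ms) and waveform
    amplitudes (WA, pressure units).  Both series are reduced to binary
    up/down fluctuation sequences; the *percussion rate* ``PR_s^m`` is the
    fraction of positions where an ``m``-long fluctuation pattern of PPI
    exactly matches the WA pattern shifted by ``s`` beats, and

        PEI(m, S) = ln( sum_s PR_s^m / sum_s PR_s^{m+1} )

    Perfectly coupled series give PEI = 0; independent fair-coin
    fluctuations give PEI -> ln 2.

2.  **Synthetic data generation** — paired PPI/WA series with a tunable
    directional-coupling probability ``rho`` (and an optional rendered
    pulse waveform with a peak extractor), plus a two-group x four-month
    cohort of per-subject PEI values (percent scale) with a prescribed
    group-by-time mean structure and between/within-subject variance.

3.  **Statistics suite** — the inference pipeline for a mixed design
    (one between-subjects group factor, four monthly measurements):
    one-sample Kolmogorov–Smirnov normality screen, Mann–Whitney–Wilcoxon
    baseline comparison, Levene's variance-homogeneity test, mixed-design
    repeated-measures ANOVA with Roy's-largest-root multivariate tests for
    TIME and TIME x GROUP, estimated marginal means, Bonferroni pairwise
    contrasts with simultaneous CIs, and per-timepoint parameter estimates.

4.  **Pipeline orchestration** — a config-driven run
    (generate -> PEI -> analyze -> verify) plus verification of the
    published inference arithmetic from its printed inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sp_signal
from scipy import special as sp_special
from scipy import stats as sp_stats

logger = logging.getLogger("hrvtrial")

#: canonical timepoint labels, first measurement to three-month follow-up
TIMEPOINTS = ("T1", "T2", "T3", "T4")
#: group labels; "control" is the reference level everywhere
GROUPS = ("control", "experimental")

__all__ = [
    "TIMEPOINTS",
    "GROUPS",
    "InvalidInputError",
    "UndefinedIndexError",
    "DegenerateSampleError",
    "ExtractionError",
    "CalibrationError",
    "PulsePairSeries",
    "PEIParams",
    "PEIResult",
    "binarize",
    "percussion_rate",
    "percussion_rate_naive",
    "pei",
    "pei_from_csv",
    "CouplingSpec",
    "CohortSpec",
    "gen_ppi_wa",
    "gen_waveform",
    "extract_peaks",
    "calibrate_coupling",
    "gen_cohort",
    "validate_cohort",
    "ks_normality",
    "mann_whitney",
    "levene",
    "estimated_marginal_means",
    "bonferroni_pairwise",
    "per_time_glm",
    "between_effects_table",
    "roy_multivariate_tests",
    "mixed_rm_anova",
    "PairwiseContrast",
    "BetweenSubjectsRow",
    "TimepointGLMRow",
    "RoyTest",
    "RMAnovaReport",
    "PRINTED_TABLES",
    "verify_paper_tables",
    "RunConfig",
    "run_pipeline",
]


# --------------------------------------------------------------------------
# Errors
# --------------------------------------------------------------------------


class InvalidInputError(ValueError):
    """Input violates a precondition (length, range, completeness)."""


class UndefinedIndexError(ArithmeticError):
    """PEI is undefined: a percussion-rate sum is zero (degenerate coupling)."""


class DegenerateSampleError(ValueError):
    """A sample has no variance where variance is required."""


class ExtractionError(RuntimeError):
    """Peak extraction failed to find enough resolvable pulses."""


class CalibrationError(RuntimeError):
    """Requested coupling target is outside the attainable range."""


# ==========================================================================
# Section 1 — Percussion entropy index
# ==========================================================================


@dataclass(frozen=True)
class PulsePairSeries:
    """Paired per-beat series: peak-to-peak intervals and waveform amplitudes.

    Parameters
    ----------
    ppi : sequence of float
        Peak-to-peak intervals in milliseconds, one per beat transition,
        all strictly positive.
    wa : sequence of float
        Waveform (pulse) amplitudes in arbitrary pressure units, same
        length as ``ppi``.
    """

    ppi: np.ndarray
    wa: np.ndarray

    def __init__(self, ppi: Sequence[float], wa: Sequence[float]) -> None:
        ppi_arr = np.asarray(ppi, dtype=float)
        wa_arr = np.asarray(wa, dtype=float)
        if ppi_arr.ndim != 1 or wa_arr.ndim != 1:
            raise InvalidInputError("ppi and wa must be one-dimensional")
        if ppi_arr.shape != wa_arr.shape:
            raise InvalidInputError(
                f"length mismatch: {ppi_arr.size} PPI vs {wa_arr.size} WA"
            )
        if ppi_arr.size and not np.all(ppi_arr > 0):
            raise InvalidInputError("all PPI values must be strictly positive")
        object.__setattr__(self, "ppi", ppi_arr)
        object.__setattr__(self, "wa", wa_arr)

    @property
    def n(self) -> int:
        return int(self.ppi.size)


@dataclass(frozen=True)
class PEIParams:
    """Embedding dimension ``m`` and maximum shift ``S`` for the index.

    The study values are ``m = 2`` and ``S = 1`` (only the one-beat shift
    is used); ``S > 1`` sums percussion rates over shifts ``s = 1..S``.
    """

    m: int = 2
    S: int = 1

    def __post_init__(self) -> None:
        if self.m < 1 or self.S < 1:
            raise InvalidInputError("require m >= 1 and S >= 1")


@dataclass(frozen=True)
class PEIResult:
    """Percussion rates at dimensions m and m+1 and the resulting index.

    ``pei_percent`` is ``pei * 100``, the display scale used for cohort
    summaries; the raw natural-log value is always retained.
    """

    pr_m_by_s: tuple[float, ...]
    pr_m1_by_s: tuple[float, ...]
    pei: float
    pei_percent: float
    params: PEIParams
    n: int  # binary-series length used as n in the rate formula

    def to_dict(self) -> dict:
        return {
            "pr_m": list(self.pr_m_by_s),
            "pr_m1": list(self.pr_m1_by_s),
            "pei": self.pei,
            "pei_percent": self.pei_percent,
            "m": self.params.m,
            "S": self.params.S,
            "n": self.n,
        }


def binarize(series: Sequence[float]) -> np.ndarray:
    """Map a numeric series to its 0/1 fluctuation directions.

    Element ``i`` is 1 iff ``series[i+1] > series[i]``; ties and decreases
    map to 0.  The output has length ``N - 1``.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise InvalidInputError("series must be one-dimensional with length >= 2")
    return (x[1:] > x[:-1]).astype(np.int8)


def _check_binary(a: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(a)
    if arr.ndim != 1:
        raise InvalidInputError(f"{name} must be one-dimensional")
    if arr.size and not np.isin(arr, (0, 1)).all():
        raise InvalidInputError(f"{name} must contain only 0s and 1s")
    return arr.astype(np.int8)


def percussion_rate(a: Sequence[int], b: Sequence[int], m: int, s: int) -> float:
    """Fraction of aligned m-windows of ``a`` matching the s-shifted windows of ``b``.

    Over ``i = 1..n-m-s+1`` (1-based), window ``a(i..i+m-1)`` is compared
    element-wise with ``b(i+s..i+s+m-1)``; the rate is the match count
    divided by the number of windows.
    """
    a_arr = _check_binary(a, "a")
    b_arr = _check_binary(b, "b")
    if a_arr.size != b_arr.size:
        raise InvalidInputError("a and b must have the same length")
    n = a_arr.size
    if m < 1 or s < 1:
        raise InvalidInputError("require m >= 1 and s >= 1")
    n_windows = n - m - s + 1
    if n_windows < 1:
        raise InvalidInputError(
            f"no windows: n={n}, m={m}, s={s} gives n-m-s+1={n_windows}"
        )
    wa_view = sliding_window_view(a_arr, m)[:n_windows]
    wb_view = sliding_window_view(b_arr, m)[s : s + n_windows]
    matches = (wa_view == wb_view).all(axis=1)
    return float(matches.sum() / n_windows)


def percussion_rate_naive(a: Sequence[int], b: Sequence[int], m: int, s: int) -> float:
    """Deliberately naive triple-loop percussion rate, kept for verification.

    Enumerates every window pair and compares element by element; slow but
    transparently faithful to the definition.
    """
    a_arr = _check_binary(a, "a")
    b_arr = _check_binary(b, "b")
    if a_arr.size != b_arr.size:
        raise InvalidInputError("a and b must have the same length")
    n = a_arr.size
    n_windows = n - m - s + 1
    if n_windows < 1:
        raise InvalidInputError("no windows for the given n, m, s")
    count = 0
    for i in range(n_windows):  # 0-based start of the a-window
        match = True
        for j in range(m):
            if a_arr[i + j] != b_arr[i + s + j]:
                match = False
                break
        if match:
            count += 1
    return count / n_windows


def pei(
    ppi: Sequence[float],
    wa: Sequence[float],
    params: PEIParams = PEIParams(),
) -> PEIResult:
    """Percussion entropy index of a paired PPI/WA recording.

    Binarizes both series, computes percussion rates at dimensions ``m``
    and ``m + 1`` for each shift ``s = 1..S``, and returns
    ``ln(sum_s PR_s^m / sum_s PR_s^{m+1})``.

    Raises
    ------
    UndefinedIndexError
        If either rate sum is zero — the fluctuation patterns never match
        (or never extend a match), which the study design treats as a
        failed measurement.
    """
    series = ppi if isinstance(ppi, PulsePairSeries) else PulsePairSeries(ppi, wa)
    a = binarize(series.ppi)
    b = binarize(series.wa)
    n = a.size
    min_len = params.m + 1 + params.S  # need >= 1 window at dimension m+1, shift S
    if n < min_len:
        raise InvalidInputError(
            f"binary series length {n} too short for m={params.m}, S={params.S}"
        )
    pr_m = tuple(percussion_rate(a, b, params.m, s) for s in range(1, params.S + 1))
    pr_m1 = tuple(percussion_rate(a, b, params.m + 1, s) for s in range(1, params.S + 1))
    num, den = sum(pr_m), sum(pr_m1)
    if num == 0.0 or den == 0.0:
        raise UndefinedIndexError(
            "percussion-rate sum is zero; PEI undefined for uncoupled input"
        )
    value = math.log(num / den)
    return PEIResult(pr_m, pr_m1, value, 100.0 * value, params, n)


def pei_from_csv(path: str | Path, params: PEIParams = PEIParams()) -> PEIResult:
    """Compute PEI from a two-column CSV with header ``ppi_ms,wa``."""
    df = pd.read_csv(path)
    if not {"ppi_ms", "wa"}.issubset(df.columns):
        raise InvalidInputError("CSV must have columns 'ppi_ms' and 'wa'")
    return pei(df["ppi_ms"].to_numpy(), df["wa"].to_numpy(), params)


# ==========================================================================
# Section 2 — Synthetic data generation
# ==========================================================================

# PPI base dynamics: bounded Gaussian random walk around a resting pulse.
_PPI_BASE_MS = 800.0
_PPI_STEP_SD_MS = 8.0
_PPI_BOUNDS_MS = (400.0, 1500.0)
_WA_BASE = 100.0
_WA_STEP_RANGE = (0.5, 2.0)


@dataclass(frozen=True)
class CouplingSpec:
    """Controls the directional coupling between synthetic PPI and WA.

    ``rho`` is the probability that the WA fluctuation direction copies
    the PPI direction at the aligned (lag) position; otherwise the WA
    direction is an independent fair coin.  ``rho = 1`` with ``lag = s``
    makes every percussion pattern match (PEI = 0); ``rho = 0`` gives
    independent fluctuations (PEI -> ln 2 for long series).
    """

    rho: float
    lag: int = 1
    n_beats: int = 700
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho <= 1.0):
            raise InvalidInputError(f"rho must lie in [0, 1], got {self.rho}")
        if self.lag < 0:
            raise InvalidInputError("lag must be non-negative")
        if self.n_beats < 10:
            raise InvalidInputError("n_beats must be >= 10")


def _bounded_walk(rng: np.random.Generator, n: int) -> np.ndarray:
    """Gaussian random walk around the base interval, clipped per step."""
    lo, hi = _PPI_BOUNDS_MS
    out = np.empty(n)
    x = _PPI_BASE_MS
    steps = rng.normal(0.0, _PPI_STEP_SD_MS, size=n)
    for i in range(n):
        x = min(hi, max(lo, x + steps[i]))
        out[i] = x
    return out


def gen_ppi_wa(spec: CouplingSpec) -> PulsePairSeries:
    """Generate a paired PPI/WA series with the requested coupling.

    The PPI series is a bounded random walk; its binary fluctuation
    pattern ``a`` seeds the WA direction pattern ``b`` via
    ``b[i + lag] = a[i]`` with probability ``rho`` (independent coin
    otherwise), and the WA values are then built to realise ``b`` exactly
    with strictly monotone steps, staying positive.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_beats
    ppi = _bounded_walk(rng, n)
    a = binarize(ppi)
    m = n - 1  # binary-series length
    b = rng.integers(0, 2, size=m).astype(np.int8)
    if spec.lag < m:
        copy_mask = rng.random(m - spec.lag) < spec.rho
        idx = np.nonzero(copy_mask)[0]
        b[idx + spec.lag] = a[idx]
    mags = rng.uniform(*_WA_STEP_RANGE, size=m)
    wa = np.empty(n)
    wa[0] = _WA_BASE
    for i in range(m):
        step = mags[i]
        if b[i] == 1:
            wa[i + 1] = wa[i] + step
        else:
            # keep amplitudes positive while preserving a strict decrease
            if wa[i] - step <= 1.0:
                step = 0.25 * wa[i]
            wa[i + 1] = wa[i] - step
    return PulsePairSeries(ppi, wa)


def gen_waveform(
    spec: CouplingSpec, fs: float = 500.0
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Render a sampled pulse-like signal realising a PPI/WA series.

    One peak is rendered per beat (``n_beats`` peaks, so ``n_beats - 1``
    successive intervals).  Each beat is a compact raised-cosine bump
    centred exactly on a sample, with half-width 40% of the smaller
    neighbouring interval so adjacent pulses never overlap: the signal
    value at each peak sample equals the beat's WA exactly.

    Returns
    -------
    t, x, truth
        Time axis (s), signal, and a ground-truth dict with keys
        ``peak_idx``, ``peak_t_sec``, ``ppi_ms`` (the n_beats - 1 intended
        inter-peak intervals) and ``wa`` (per-beat amplitudes).
    """
    if fs < 50.0:
        raise InvalidInputError("sampling rate must be >= 50 Hz")
    series = gen_ppi_wa(spec)
    gaps_s = series.ppi[1:] / 1000.0  # interval ending at beat k, k = 2..n
    peak_t = np.concatenate([[0.1], 0.1 + np.cumsum(gaps_s)])
    peak_idx = np.round(peak_t * fs).astype(int)
    if np.diff(peak_idx).min() < 4:
        raise InvalidInputError("sampling rate too low to resolve successive beats")
    amp = series.wa
    n_samp = peak_idx[-1] + int(0.2 * fs) + 1
    x = np.zeros(n_samp)
    gaps = np.diff(peak_idx)
    for k, idx in enumerate(peak_idx):
        left = gaps[k - 1] if k > 0 else gaps[0]
        right = gaps[k] if k < gaps.size else gaps[-1]
        h = max(2, int(0.4 * min(left, right)))
        j = np.arange(max(0, idx - h + 1), min(n_samp, idx + h))
        x[j] += amp[k] * 0.5 * (1.0 + np.cos(np.pi * (j - idx) / h))
    t = np.arange(n_samp) / fs
    truth = {
        "peak_idx": peak_idx,
        "peak_t_sec": peak_idx / fs,
        "ppi_ms": series.ppi[1:],
        "wa": amp,
    }
    return t, x, truth


def extract_peaks(x: Sequence[float], fs: float) -> PulsePairSeries:
    """Detect pulse peaks and return successive intervals and amplitudes.

    Local maxima are required to exceed 5% of the signal maximum and be
    separated by at least 200 ms (a physiological upper bound of
    300 beats/min).
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ExtractionError("signal too short")
    peak_max = arr.max()
    if peak_max <= 0:
        raise ExtractionError("no positive excursion in signal")
    idx, _ = sp_signal.find_peaks(
        arr, height=0.05 * peak_max, distance=max(1, int(0.2 * fs))
    )
    if idx.size < 2:
        raise ExtractionError(f"found {idx.size} peaks; need at least 2")
    ppi_ms = np.diff(idx) / fs * 1000.0
    return PulsePairSeries(ppi_ms, arr[idx][1:])


def _mean_pei(rho: float, n_beats: int, seeds: np.ndarray) -> float:
    vals = []
    for sd in seeds:
        series = gen_ppi_wa(CouplingSpec(rho=rho, lag=1, n_beats=n_beats, seed=int(sd)))
        vals.append(pei(series.ppi, series.wa).pei)
    return float(np.mean(vals))


def calibrate_coupling(
    target_pei: float,
    n_beats: int = 700,
    seed: int = 0,
    tol: float = 0.02,
    n_sims: int = 200,
) -> float:
    """Invert the monotone map rho -> E[PEI] by bisection.

    Uses common random numbers (the same simulation seeds at every rho)
    so the estimated mean is monotone non-increasing in rho.  The
    bisection stops once the estimated mean is within ``tol / 4`` of the
    target, leaving headroom for the Monte-Carlo error of the estimate
    itself so fresh simulations at the returned rho land within ``tol``.
    """
    seeds = np.random.SeedSequence(seed).generate_state(n_sims) % (2**31)
    hi_val = _mean_pei(0.0, n_beats, seeds)  # ~ ln 2
    lo_val = _mean_pei(1.0, n_beats, seeds)  # exactly 0
    if not (lo_val - tol <= target_pei <= hi_val + tol):
        raise CalibrationError(
            f"target {target_pei:.3f} outside attainable range "
            f"[{lo_val:.3f}, {hi_val:.3f}]"
        )
    lo_rho, hi_rho = 0.0, 1.0  # pei decreasing in rho
    for _ in range(30):
        mid = 0.5 * (lo_rho + hi_rho)
        val = _mean_pei(mid, n_beats, seeds)
        if abs(val - target_pei) <= 0.25 * tol:
            return mid
        if val > target_pei:
            lo_rho = mid
        else:
            hi_rho = mid
    return 0.5 * (lo_rho + hi_rho)


# -- cohort generation ------------------------------------------------------

#: group-by-time mean PEI (percent scale) of the study cohort: the control
#: row is the per-timepoint reference mean, the experimental row adds the
#: reported group difference at each timepoint.
DEFAULT_CELL_MEANS = {
    "control": (56.800, 60.750, 62.500, 64.970),
    "experimental": (55.725, 62.660, 66.435, 69.010),
}
#: between-subjects error mean square the generator is anchored to
DEFAULT_ERROR_MS = 23.662


@dataclass(frozen=True)
class CohortSpec:
    """Two-group, four-timepoint cohort with a prescribed mean structure.

    ``error_sd`` squared is the *between-subjects error mean square* the
    generator targets (the subject-to-subject variance anchor, default
    sqrt(23.662)); ``within_corr`` is the exchangeable correlation of a
    subject's repeated measures.  The implied per-observation variance is
    ``error_sd**2 / (1 + 3 * within_corr)``, split into a subject random
    intercept (fraction ``within_corr``) and an i.i.d. residual.  The
    default correlation 0.107 puts the within-subject residual SD at 4.0,
    which keeps simulated pairwise-contrast standard errors in the range
    the study reports.
    """

    n_control: int = 20
    n_experimental: int = 10
    cell_means: dict = field(
        default_factory=lambda: {g: DEFAULT_CELL_MEANS[g] for g in GROUPS}
    )
    error_sd: float = math.sqrt(DEFAULT_ERROR_MS)
    within_corr: float = 0.107
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_experimental < 1:
            raise InvalidInputError("group sizes must be positive")
        if self.error_sd < 0:
            raise InvalidInputError("error_sd must be non-negative")
        if not (0.0 <= self.within_corr < 1.0):
            raise InvalidInputError("within_corr must lie in [0, 1)")
        for g in GROUPS:
            mus = np.asarray(self.cell_means[g], dtype=float)
            if mus.shape != (4,) or not np.all(np.isfinite(mus)):
                raise InvalidInputError(f"cell_means[{g!r}] must be 4 finite values")


def gen_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a complete long-format cohort (one row per subject-timepoint).

    Each observation is ``cell_mean + subject_intercept + residual`` with
    variance components as described on :class:`CohortSpec`; the expected
    between-subjects error mean square equals ``spec.error_sd ** 2``.
    """
    rng = np.random.default_rng(spec.seed)
    sigma2_obs = spec.error_sd**2 / (1.0 + 3.0 * spec.within_corr)
    sd_u = math.sqrt(spec.within_corr * sigma2_obs)
    sd_e = math.sqrt((1.0 - spec.within_corr) * sigma2_obs)
    rows = []
    for group, n_g, prefix in (
        ("control", spec.n_control, "C"),
        ("experimental", spec.n_experimental, "E"),
    ):
        mus = np.asarray(spec.cell_means[group], dtype=float)
        for i in range(n_g):
            u = rng.normal(0.0, sd_u) if sd_u > 0 else 0.0
            eps = rng.normal(0.0, sd_e, size=4) if sd_e > 0 else np.zeros(4)
            for t_idx, tp in enumerate(TIMEPOINTS):
                rows.append(
                    (f"{prefix}{i + 1:02d}", group, tp, mus[t_idx] + u + eps[t_idx])
                )
    return pd.DataFrame(rows, columns=["subject_id", "group", "timepoint", "pei_percent"])


def validate_cohort(data: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format cohort contract; return a cleaned copy.

    Every subject must have exactly one record per timepoint (complete
    design — listwise deletion is never applied silently) and both groups
    must contain at least two subjects.
    """
    required = {"subject_id", "group", "timepoint", "pei_percent"}
    if not required.issubset(data.columns):
        raise InvalidInputError(f"cohort must have columns {sorted(required)}")
    df = data.copy()
    bad_groups = set(df["group"]) - set(GROUPS)
    if bad_groups:
        raise InvalidInputError(f"unknown group labels: {sorted(bad_groups)}")
    bad_tp = set(df["timepoint"]) - set(TIMEPOINTS)
    if bad_tp:
        raise InvalidInputError(f"unknown timepoints: {sorted(bad_tp)}")
    counts = df.groupby("subject_id")["timepoint"].agg(["count", "nunique"])
    if not ((counts["count"] == 4) & (counts["nunique"] == 4)).all():
        bad = counts.index[(counts["count"] != 4) | (counts["nunique"] != 4)].tolist()
        raise InvalidInputError(f"incomplete subjects (need all 4 timepoints): {bad}")
    sizes = df.drop_duplicates("subject_id").groupby("group").size()
    for g in GROUPS:
        if sizes.get(g, 0) < 2:
            raise InvalidInputError(f"group {g!r} needs >= 2 subjects")
    return df


# ==========================================================================
# Section 3 — Statistics suite
# ==========================================================================


def ks_normality(x: Sequence[float], method: str = "legacy") -> tuple[float, float]:
    """One-sample Kolmogorov–Smirnov normality screen.

    ``method='legacy'`` compares against a normal with mean and SD
    estimated from the sample and takes the p-value from the asymptotic
    Kolmogorov distribution, the dialect of the classic one-sample KS as
    printed by legacy statistical packages.  ``method='lilliefors'``
    applies the correction appropriate for estimated parameters.
    """
    arr = np.asarray(x, dtype=float)
    if arr.size < 4:
        raise InvalidInputError("need at least 4 observations")
    sd = arr.std(ddof=1)
    if sd == 0:
        raise DegenerateSampleError("sample has zero variance")
    if method == "legacy":
        d = sp_stats.kstest(arr, "norm", args=(arr.mean(), sd)).statistic
        p = float(sp_special.kolmogorov(math.sqrt(arr.size) * d))
        return float(d), min(1.0, p)
    if method == "lilliefors":
        from statsmodels.stats.diagnostic import lilliefors

        d, p = lilliefors(arr, dist="norm")
        return float(d), float(p)
    raise InvalidInputError(f"unknown KS method {method!r}")


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann–Whitney–Wilcoxon two-sample test (two-sided).

    Uses exact enumeration when there are no ties and ``n_x * n_y <= 400``,
    otherwise the normal approximation with midrank tie correction and
    continuity correction.  Returns ``(U of x, p)``.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise InvalidInputError("samples must be non-empty")
    combined = np.concatenate([xa, ya])
    has_ties = np.unique(combined).size < combined.size
    exact = (not has_ties) and xa.size * ya.size <= 400
    res = sp_stats.mannwhitneyu(
        xa, ya, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


def levene(groups: Sequence[Sequence[float]], center: str = "mean") -> tuple[float, float]:
    """Levene's test of equality of error variance across groups.

    The mean-centred variant (one-way ANOVA on absolute deviations from
    the group mean) is the default; ``center='median'`` gives the
    Brown–Forsythe robust variant.
    """
    if len(groups) < 2:
        raise InvalidInputError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise InvalidInputError("every group needs at least 2 observations")
    if center not in ("mean", "median"):
        raise InvalidInputError(f"unknown centering {center!r}")
    res = sp_stats.levene(*arrays, center=center)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class PairwiseContrast:
    """One Bonferroni-adjusted pairwise comparison of time-margin means."""

    pair: tuple[str, str]
    diff: float
    se: float
    df: int
    k: int
    t: float
    p_adj: float
    ci_low: float
    ci_high: float

    def to_dict(self) -> dict:
        return {
            "I": self.pair[0],
            "J": self.pair[1],
            "diff": self.diff,
            "se": self.se,
            "df": self.df,
            "k": self.k,
            "t": self.t,
            "p_adj": self.p_adj,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        }


@dataclass(frozen=True)
class BetweenSubjectsRow:
    """One row of the Type-III between-subjects effects table."""

    source: str
    ss: float
    df: int
    ms: float
    F: float | None
    p: float | None
    partial_eta_sq: float | None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class TimepointGLMRow:
    """Per-timepoint parameter estimates (control group as reference)."""

    timepoint: str
    intercept: float
    se_intercept: float
    p_intercept: float
    B: float
    se_B: float
    t: float
    p: float
    eta_sq: float
    df: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class RoyTest:
    """Roy's-largest-root multivariate test for one within-subject effect.

    ``F`` is the exact upper-bound transformation
    ``lambda * (df_err - q + df_h) / q`` with ``q`` difference variables;
    for a single-df hypothesis this F is exact.
    """

    effect: str
    largest_root: float
    F: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def bonferroni_pairwise(
    diff: float,
    se: float,
    df: int,
    k: int,
    alpha: float = 0.05,
    pair: tuple[str, str] = ("I", "J"),
) -> PairwiseContrast:
    """Bonferroni-adjusted t contrast with a simultaneous confidence interval.

    ``p_adj = min(1, k * P(|T_df| >= |diff/se|))`` and the CI is
    ``diff ± t_{1-alpha/(2k), df} * se``.
    """
    if se <= 0:
        raise InvalidInputError("se must be positive")
    if df < 1 or k < 1:
        raise InvalidInputError("require df >= 1 and k >= 1")
    t = diff / se
    p_adj = min(1.0, k * 2.0 * float(sp_stats.t.sf(abs(t), df)))
    crit = float(sp_stats.t.ppf(1.0 - alpha / (2.0 * k), df))
    return PairwiseContrast(
        pair=tuple(pair),
        diff=diff,
        se=se,
        df=df,
        k=k,
        t=t,
        p_adj=p_adj,
        ci_low=diff - crit * se,
        ci_high=diff + crit * se,
    )


def between_effects_table(
    effects: dict[str, tuple[float, int]], ss_error: float, df_error: int
) -> list[BetweenSubjectsRow]:
    """Assemble a Type-III between-subjects table from sums of squares.

    ``effects`` maps source name to ``(SS, df)``; F uses the shared error
    mean square and partial eta squared is ``SS / (SS + SS_error)``.
    """
    if df_error < 1 or any(df < 1 for _, df in effects.values()):
        raise InvalidInputError("degrees of freedom must be positive")
    if ss_error < 0 or any(ss < 0 for ss, _ in effects.values()):
        raise InvalidInputError("sums of squares must be non-negative")
    if ss_error == 0:
        raise DegenerateSampleError("zero error sum of squares")
    ms_error = ss_error / df_error
    rows = []
    for name, (ss, df) in effects.items():
        ms = ss / df
        F = ms / ms_error
        p = float(sp_stats.f.sf(F, df, df_error))
        rows.append(
            BetweenSubjectsRow(name, ss, df, ms, F, p, ss / (ss + ss_error))
        )
    rows.append(
        BetweenSubjectsRow("Error", ss_error, df_error, ms_error, None, None, None)
    )
    return rows


def per_time_glm(data: pd.DataFrame, timepoint: str) -> TimepointGLMRow:
    """OLS of PEI on the group indicator at one timepoint.

    With the control group as reference: intercept = control mean,
    ``B`` = experimental minus control mean, SEs from the pooled residual
    variance with ``df = N - 2``, and ``eta_sq = t^2 / (t^2 + df)``.
    """
    sub = data[data["timepoint"] == timepoint]
    ctrl = sub.loc[sub["group"] == "control", "pei_percent"].to_numpy(float)
    expt = sub.loc[sub["group"] == "experimental", "pei_percent"].to_numpy(float)
    if ctrl.size < 2 or expt.size < 2:
        raise InvalidInputError(f"both groups needed at timepoint {timepoint}")
    n1, n2 = ctrl.size, expt.size
    df = n1 + n2 - 2
    s2 = ((n1 - 1) * ctrl.var(ddof=1) + (n2 - 1) * expt.var(ddof=1)) / df
    B = expt.mean() - ctrl.mean()
    se_B = math.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
    if se_B == 0:
        t = 0.0
        p = 1.0
    else:
        t = B / se_B
        p = 2.0 * float(sp_stats.t.sf(abs(t), df))
    se_int = math.sqrt(s2 / n1) if s2 > 0 else 0.0
    p_int = (
        2.0 * float(sp_stats.t.sf(abs(ctrl.mean() / se_int), df)) if se_int > 0 else 0.0
    )
    return TimepointGLMRow(
        timepoint=timepoint,
        intercept=ctrl.mean(),
        se_intercept=se_int,
        p_intercept=p_int,
        B=B,
        se_B=se_B,
        t=t,
        p=p,
        eta_sq=t * t / (t * t + df),
        df=df,
    )


def estimated_marginal_means(
    data: pd.DataFrame, weighting: str = "unweighted"
) -> dict:
    """Cell and margin means of PEI.

    Cell means are arithmetic means per group x timepoint.  Time margins
    average the two group cell means *unweighted* by default (the
    convention for unequal groups in the software the tables follow);
    ``weighting='weighted'`` pools over subjects instead.
    """
    if weighting not in ("unweighted", "weighted"):
        raise InvalidInputError(f"unknown weighting {weighting!r}")
    cells = (
        data.groupby(["group", "timepoint"], sort=False)["pei_percent"]
        .mean()
        .unstack("timepoint")
    )
    for g in GROUPS:
        if g not in cells.index or cells.loc[g].isna().any():
            raise InvalidInputError(f"empty cell(s) for group {g!r}")
    cells = cells.loc[list(GROUPS), list(TIMEPOINTS)]
    if weighting == "unweighted":
        time_margins = cells.mean(axis=0)
        group_margins = cells.mean(axis=1)
    else:
        time_margins = data.groupby("timepoint")["pei_percent"].mean()[list(TIMEPOINTS)]
        group_margins = data.groupby("group")["pei_percent"].mean()[list(GROUPS)]
    return {
        "cell_means": cells,
        "time_margins": time_margins,
        "group_margins": group_margins,
    }


def _wide(data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Pivot the validated cohort to an N x 4 matrix plus group codes."""
    wide = data.pivot(index="subject_id", columns="timepoint", values="pei_percent")
    wide = wide[list(TIMEPOINTS)]
    grp = data.drop_duplicates("subject_id").set_index("subject_id")["group"]
    grp = grp.loc[wide.index]
    order = np.argsort((grp != "control").to_numpy(), kind="stable")
    wide = wide.iloc[order]
    grp = grp.iloc[order]
    return wide.to_numpy(float), (grp == "experimental").to_numpy(), list(wide.index)


@dataclass
class RMAnovaReport:
    """Full mixed-design repeated-measures ANOVA report.

    Holds the between-subjects Type-III table, Roy's-largest-root tests
    for TIME and TIME x GROUP, estimated marginal means, Bonferroni
    pairwise time contrasts, per-timepoint parameter estimates, Levene
    screens per timepoint and KS normality screens per cell.
    """

    n_control: int
    n_experimental: int
    degenerate: bool
    between_table: list[BetweenSubjectsRow]
    roy_tests: list[RoyTest]
    emm: dict
    pairwise: list[PairwiseContrast]
    per_time: list[TimepointGLMRow]
    levene: dict[str, tuple[float, float]]
    normality: dict[str, tuple[float, float]]

    def to_dict(self) -> dict:
        return {
            "n_control": self.n_control,
            "n_experimental": self.n_experimental,
            "degenerate": self.degenerate,
            "between_table": [r.to_dict() for r in self.between_table],
            "roy_tests": [r.to_dict() for r in self.roy_tests],
            "emm": {
                "cell_means": {
                    g: [float(v) for v in self.emm["cell_means"].loc[g]]
                    for g in GROUPS
                },
                "time_margins": {
                    tp: float(self.emm["time_margins"][tp]) for tp in TIMEPOINTS
                },
                "group_margins": {
                    g: float(self.emm["group_margins"][g]) for g in GROUPS
                },
            },
            "pairwise": [c.to_dict() for c in self.pairwise],
            "per_time": [r.to_dict() for r in self.per_time],
            "levene": {tp: list(v) for tp, v in self.levene.items()},
            "normality": {cell: list(v) for cell, v in self.normality.items()},
        }

    def render_markdown(self) -> str:
        """Plain-text tables mirroring the published report layout.

        p-values are shown to 3 decimal places; full precision is kept in
        the underlying report objects.
        """
        out = []
        out.append("## Tests of between-subject effects\n")
        out.append("| Source | Type III SS | df | MS | F | p | partial eta^2 |")
        out.append("|---|---|---|---|---|---|---|")
        for r in self.between_table:
            f = "" if r.F is None else f"{r.F:.3f}"
            p = "" if r.p is None else f"{r.p:.3f}"
            e = "" if r.partial_eta_sq is None else f"{r.partial_eta_sq:.3f}"
            out.append(
                f"| {r.source} | {r.ss:.3f} | {r.df} | {r.ms:.3f} | {f} | {p} | {e} |"
            )
        out.append("\n## Multivariate tests (Roy's largest root)\n")
        out.append("| Effect | largest root | F | df1 | df2 | p | partial eta^2 |")
        out.append("|---|---|---|---|---|---|---|")
        for r in self.roy_tests:
            out.append(
                f"| {r.effect} | {r.largest_root:.3f} | {r.F:.3f} | {r.df1} |"
                f" {r.df2} | {r.p:.3f} | {r.partial_eta_sq:.3f} |"
            )
        out.append("\n## Pairwise comparisons of time margins (Bonferroni)\n")
        out.append("| (I) | (J) | Mean diff (I-J) | SE | p | CI low | CI high |")
        out.append("|---|---|---|---|---|---|---|")
        for c in self.pairwise:
            out.append(
                f"| {c.pair[0]} | {c.pair[1]} | {c.diff:.3f} | {c.se:.3f} |"
                f" {c.p_adj:.3f} | {c.ci_low:.3f} | {c.ci_high:.3f} |"
            )
        out.append("\n## Parameter estimates per timepoint\n")
        out.append("| Timepoint | Intercept | SE | p | B | SE | p | eta^2 |")
        out.append("|---|---|---|---|---|---|---|---|")
        for r in self.per_time:
            out.append(
                f"| {r.timepoint} | {r.intercept:.3f} | {r.se_intercept:.3f} |"
                f" {r.p_intercept:.3f} | {r.B:.3f} | {r.se_B:.3f} | {r.p:.3f} |"
                f" {r.eta_sq:.3f} |"
            )
        out.append("\n## Levene's test per timepoint\n")
        out.append("| Timepoint | F | p |")
        out.append("|---|---|---|")
        for tp, (f, p) in self.levene.items():
            out.append(f"| {tp} | {f:.3f} | {p:.3f} |")
        out.append("\n## One-sample KS normality per cell\n")
        out.append("| Cell | D | p |")
        out.append("|---|---|---|")
        for cell, (d, p) in self.normality.items():
            out.append(f"| {cell} | {d:.3f} | {p:.3f} |")
        return "\n".join(out) + "\n"


def roy_multivariate_tests(D: np.ndarray, is_experimental: np.ndarray) -> list[RoyTest]:
    """Roy's-largest-root tests of TIME and TIME x GROUP on difference variables.

    ``D`` is the N x q matrix of within-subject difference scores.  Both
    effects are single-df hypotheses in the effect-coded two-group GLM
    ``D = X B + e`` (X columns: intercept, group): TIME tests the
    intercept row of B, TIME x GROUP the group row.  Roy's largest root is
    the top eigenvalue of ``H E^-1`` and its exact F uses
    ``F = lambda * (df_err - q + 1) / q`` on ``(q, df_err - q + 1)``
    degrees of freedom, which is exact when the hypothesis has one df.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim == 1:
        D = D[:, None]
    is_exp = np.asarray(is_experimental, dtype=bool)
    N, q = D.shape
    if is_exp.size != N or not (2 <= is_exp.sum() <= N - 2):
        raise InvalidInputError("need >= 2 subjects in each group")
    g_eff = np.where(is_exp, -1.0, 1.0)  # effect coding, control = +1
    X = np.column_stack([np.ones(N), g_eff])
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    B_hat = XtX_inv @ X.T @ D  # 2 x q
    E = D.T @ D - B_hat.T @ XtX @ B_hat
    df_err = N - 2
    if df_err - q + 1 < 1:
        raise InvalidInputError("too few subjects for the multivariate test")
    tests = []
    for row, effect in ((0, "TIME"), (1, "TIME x GROUP")):
        b = B_hat[row : row + 1, :]  # 1 x q
        H = b.T @ b / XtX_inv[row, row]
        lam = float(np.max(np.real(np.linalg.eigvals(np.linalg.solve(E, H)))))
        df2 = df_err - q + 1
        F = lam * df2 / q
        p = float(sp_stats.f.sf(F, q, df2))
        tests.append(RoyTest(effect, lam, F, q, df2, p, lam / (1.0 + lam)))
    return tests


def mixed_rm_anova(
    data: pd.DataFrame,
    alpha: float = 0.05,
    family_size: int | None = None,
    emm_weighting: str = "unweighted",
    ks_method: str = "legacy",
    levene_center: str = "mean",
) -> RMAnovaReport:
    """Mixed-design repeated-measures ANOVA with Roy's-largest-root tests.

    The between-subjects Type-III table is the one-way ANOVA on subject
    means, scaled by the number of timepoints; the within-subject TIME and
    TIME x GROUP effects are multivariate tests on the three successive
    difference variables, using Roy's largest root (the largest eigenvalue
    of H E^-1) with its exact-F transformation (exact because both
    hypotheses have a single degree of freedom).  Time-margin pairwise
    contrasts take their standard errors from pooled within-group
    difference scores with ``df = N - 2``.
    """
    df_long = validate_cohort(data)
    Y, is_exp, _ = _wide(df_long)
    n2 = int(is_exp.sum())
    n1 = Y.shape[0] - n2
    N = n1 + n2
    k = family_size if family_size is not None else len(TIMEPOINTS) * (len(TIMEPOINTS) - 1) // 2

    # between-subjects table on subject means, scaled to the observation level
    subj_means = Y.mean(axis=1)
    m1 = subj_means[~is_exp].mean()
    m2 = subj_means[is_exp].mean()
    mu_unweighted = 0.5 * (m1 + m2)
    ss_error = 4.0 * (
        ((subj_means[~is_exp] - m1) ** 2).sum() + ((subj_means[is_exp] - m2) ** 2).sum()
    )
    ss_group = 4.0 * (n1 * n2 / N) * (m1 - m2) ** 2
    ss_intercept = 16.0 * (n1 * n2 / N) * mu_unweighted**2
    df_error = N - 2

    degenerate = bool(ss_error < 1e-12 * max(1.0, abs(float(np.mean(Y))) ** 2))
    if degenerate:
        between = [
            BetweenSubjectsRow("Intercept", ss_intercept, 1, ss_intercept, None, None, None),
            BetweenSubjectsRow("Group", ss_group, 1, ss_group, None, None, None),
            BetweenSubjectsRow("Error", ss_error, df_error, 0.0, None, None, None),
        ]
        emm = estimated_marginal_means(df_long, emm_weighting)
        return RMAnovaReport(
            n_control=n1,
            n_experimental=n2,
            degenerate=True,
            between_table=between,
            roy_tests=[],
            emm=emm,
            pairwise=[],
            per_time=[],
            levene={},
            normality={},
        )

    between = between_effects_table(
        {"Intercept": (ss_intercept, 1), "Group": (ss_group, 1)}, ss_error, df_error
    )

    # multivariate within-subject tests on successive differences
    D = Y[:, 1:] - Y[:, :-1]  # N x q, q = 3
    roy_tests = roy_multivariate_tests(D, is_exp)

    emm = estimated_marginal_means(df_long, emm_weighting)

    # pairwise time-margin contrasts from within-subject difference scores
    tp_idx = {tp: i for i, tp in enumerate(TIMEPOINTS)}
    pairwise = []
    for tp_i, tp_j in combinations(TIMEPOINTS, 2):
        d = Y[:, tp_idx[tp_i]] - Y[:, tp_idx[tp_j]]
        d1, d2 = d[~is_exp], d[is_exp]
        diff = 0.5 * (d1.mean() + d2.mean())  # unweighted margin difference
        s2p = ((n1 - 1) * d1.var(ddof=1) + (n2 - 1) * d2.var(ddof=1)) / (N - 2)
        se = math.sqrt(0.25 * s2p * (1.0 / n1 + 1.0 / n2))
        pairwise.append(
            bonferroni_pairwise(diff, se, N - 2, k, alpha=alpha, pair=(tp_i, tp_j))
        )

    per_time = [per_time_glm(df_long, tp) for tp in TIMEPOINTS]
    levene_by_tp = {}
    normality = {}
    for tp in TIMEPOINTS:
        sub = df_long[df_long["timepoint"] == tp]
        g1 = sub.loc[sub["group"] == "control", "pei_percent"].to_numpy(float)
        g2 = sub.loc[sub["group"] == "experimental", "pei_percent"].to_numpy(float)
        levene_by_tp[tp] = levene([g1, g2], center=levene_center)
        for g, vals in (("control", g1), ("experimental", g2)):
            normality[f"{g}:{tp}"] = ks_normality(vals, method=ks_method)

    return RMAnovaReport(
        n_control=n1,
        n_experimental=n2,
        degenerate=False,
        between_table=between,
        roy_tests=roy_tests,
        emm=emm,
        pairwise=pairwise,
        per_time=per_time,
        levene=levene_by_tp,
        normality=normality,
    )


# ==========================================================================
# Section 4 — Published-table fixtures and verification
# ==========================================================================

#: Printed inputs and outputs of the published inference tables, bundled so
#: verification runs offline.  "inputs" are the quantities the tables print
#: (mean differences, SEs, sums of squares, coefficients); "printed" are the
#: published p-values, CI bounds, F and effect sizes recomputed from them.
PRINTED_TABLES: dict = {
    "version": 1,
    "df_error": 28,
    "family_size": 6,
    "alpha": 0.05,
    "pairwise": [
        # (I, J, diff, se, printed p, printed CI low, printed CI high)
        ("T1", "T2", -2.458, 0.872, 0.052, -4.932, 0.017),
        ("T1", "T3", -3.195, 0.908, 0.009, -5.773, -0.617),
        ("T1", "T4", -5.613, 1.505, 0.005, -9.884, -1.341),
        ("T2", "T3", -0.738, 0.829, 1.000, -3.092, 1.617),
        ("T2", "T4", -3.155, 1.045, 0.032, -6.122, -0.188),
        ("T3", "T4", -2.417, 1.049, 0.173, -5.396, 0.561),
    ],
    "between": {
        # source: (SS, df, printed F, printed p, printed partial eta^2)
        "Intercept": (385970.522, 1, 16311.522, 0.000, 0.998),
        "Group": (129.360, 1, 5.467, 0.027, 0.163),
        "Error": (662.548, 28, None, None, None),
    },
    "per_time": [
        # (timepoint, B, se_B, printed p, printed eta^2 or None)
        ("T1", -1.075, 1.976, 0.591, None),
        ("T2", 1.910, 1.234, 0.133, None),
        ("T3", 3.935, 1.352, 0.007, 0.232),
        ("T4", 4.040, 1.740, 0.028, 0.162),
    ],
}

# Tolerances for matching the printed values when recomputing from printed,
# 3-d.p.-rounded inputs: printed precision (half a unit in the last place)
# plus the propagated half-ULP of the rounded inputs through each formula.
_TOL = {"p": 5e-4, "F": 5e-4, "eta": 1e-3, "ci": 2.5e-3}


def verify_paper_tables(fixtures: dict | None = None) -> list[dict]:
    """Recompute every published inferential number from its printed inputs.

    Returns a checklist of dicts with keys ``target``, ``computed``,
    ``printed``, ``tol``, ``passed``.  Failures are reported, never raised.
    An empty fixture override yields an empty checklist.
    """
    fx = PRINTED_TABLES if fixtures is None else fixtures
    if not fx:
        return []
    checks: list[dict] = []

    def add(target: str, computed: float, printed: float, tol: float) -> None:
        checks.append(
            {
                "target": target,
                "computed": round(float(computed), 6),
                "printed": printed,
                "tol": tol,
                "passed": bool(abs(computed - printed) <= tol),
            }
        )

    df = fx.get("df_error", 28)
    k = fx.get("family_size", 6)
    alpha = fx.get("alpha", 0.05)
    for tp_i, tp_j, diff, se, p_pr, lo_pr, hi_pr in fx.get("pairwise", []):
        c = bonferroni_pairwise(diff, se, df, k, alpha=alpha, pair=(tp_i, tp_j))
        tag = f"pairwise {tp_i} vs {tp_j}"
        add(f"{tag}: p", c.p_adj, p_pr, _TOL["p"])
        add(f"{tag}: ci_low", c.ci_low, lo_pr, _TOL["ci"])
        add(f"{tag}: ci_high", c.ci_high, hi_pr, _TOL["ci"])

    between = fx.get("between", {})
    if between:
        ss_error, df_error = between["Error"][0], between["Error"][1]
        effects = {
            name: (vals[0], vals[1])
            for name, vals in between.items()
            if name != "Error"
        }
        rows = between_effects_table(effects, ss_error, df_error)
        for row in rows:
            if row.source == "Error":
                continue
            _, _, f_pr, p_pr, eta_pr = between[row.source]
            if f_pr is not None and row.source != "Intercept":
                add(f"between {row.source}: F", row.F, f_pr, _TOL["F"])
            if p_pr is not None:
                add(f"between {row.source}: p", row.p, p_pr, _TOL["p"])
            if eta_pr is not None:
                add(
                    f"between {row.source}: partial_eta_sq",
                    row.partial_eta_sq,
                    eta_pr,
                    _TOL["eta"],
                )

    for tp, B, se_B, p_pr, eta_pr in fx.get("per_time", []):
        t = B / se_B
        p = 2.0 * float(sp_stats.t.sf(abs(t), df))
        add(f"per_time {tp}: p", p, p_pr, _TOL["p"])
        if eta_pr is not None:
            add(f"per_time {tp}: eta_sq", t * t / (t * t + df), eta_pr, _TOL["eta"])
    return checks


# ==========================================================================
# Section 5 — Pipeline orchestration
# ==========================================================================


@dataclass
class RunConfig:
    """Fully serialisable configuration of an end-to-end pipeline run."""

    seed: int = 0
    out_dir: str = "runs/run"
    n_control: int = 20
    n_experimental: int = 10
    error_sd: float = math.sqrt(DEFAULT_ERROR_MS)
    within_corr: float = 0.107
    cell_means: dict = field(
        default_factory=lambda: {g: list(DEFAULT_CELL_MEANS[g]) for g in GROUPS}
    )
    m: int = 2
    S: int = 1
    alpha: float = 0.05
    family_size: int = 6
    emm_weighting: str = "unweighted"
    ks: str = "legacy"
    levene_center: str = "mean"
    signal_enabled: bool = False
    signal_subjects: int = 4
    signal_visits: int = 4
    signal_n_beats: int = 700
    signal_fs: float = 250.0
    signal_rho: float = 0.8
    make_plots: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(
            n_control=self.n_control,
            n_experimental=self.n_experimental,
            cell_means={g: tuple(self.cell_means[g]) for g in GROUPS},
            error_sd=self.error_sd,
            within_corr=self.within_corr,
            seed=self.seed,
        )


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _signal_path_pei(config: RunConfig) -> list[dict]:
    """Per-subject-visit PEI values via the waveform -> peaks -> PEI route."""
    root = np.random.SeedSequence(config.seed).generate_state(
        config.signal_subjects * config.signal_visits
    ) % (2**31)
    out = []
    params = PEIParams(config.m, config.S)
    i = 0
    for subj in range(1, config.signal_subjects + 1):
        for visit in range(1, config.signal_visits + 1):
            spec = CouplingSpec(
                rho=config.signal_rho,
                lag=1,
                n_beats=config.signal_n_beats,
                seed=int(root[i]),
            )
            i += 1
            _, x, _ = gen_waveform(spec, fs=config.signal_fs)
            series = extract_peaks(x, fs=config.signal_fs)
            res = pei(series.ppi, series.wa, params)
            out.append(
                {
                    "subject": f"S{subj:02d}",
                    "visit": f"T{visit}",
                    "pei": res.pei,
                    "pei_percent": res.pei_percent,
                }
            )
    return out


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run generate -> (optional signal PEI) -> analyze -> verify.

    Writes every intermediate under ``config.out_dir``: the cohort CSV,
    the per-subject PEI table when the signal path is enabled, the
    analysis report (JSON + Markdown tables), the printed-table
    verification checklist, the serialized config and a run log with
    seeds, config hash and per-stage record counts and timings.  The
    report files themselves carry no timestamps, so a repeated run with
    the same config is byte-identical.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    cfg_hash = hashlib.sha256(cfg_json.encode()).hexdigest()[:16]
    log_lines = [f"seed={config.seed} config_hash={cfg_hash}"]
    paths: dict[str, Path] = {}

    def stage(name: str):
        t0 = time.perf_counter()

        def done(n_records: int) -> None:
            dt = time.perf_counter() - t0
            log_lines.append(f"stage={name} records={n_records} elapsed_s={dt:.3f}")
            logger.info("stage %s: %d records in %.3fs", name, n_records, dt)

        return done

    try:
        done = stage("generate")
        cohort = gen_cohort(config.cohort_spec())
        paths["cohort"] = out / "cohort.csv"
        cohort.to_csv(paths["cohort"], index=False)
        done(len(cohort))

        if config.signal_enabled:
            done = stage("signal_pei")
            pei_rows = _signal_path_pei(config)
            paths["signal_pei"] = out / "signal_pei.csv"
            pd.DataFrame(pei_rows).to_csv(paths["signal_pei"], index=False)
            done(len(pei_rows))

        done = stage("analyze")
        report = mixed_rm_anova(
            cohort,
            alpha=config.alpha,
            family_size=config.family_size,
            emm_weighting=config.emm_weighting,
            ks_method=config.ks,
            levene_center=config.levene_center,
        )
        paths["report"] = out / "report.json"
        _json_dump(report.to_dict(), paths["report"])
        paths["tables"] = out / "tables.md"
        paths["tables"].write_text(report.render_markdown())
        if config.make_plots:
            _write_plots(report, cohort, out, paths)
        done(len(report.pairwise))

        done = stage("verify")
        checklist = verify_paper_tables()
        paths["verify"] = out / "verify.json"
        _json_dump(checklist, paths["verify"])
        done(len(checklist))
    except Exception as exc:
        snapshot = out / "failure_config.json"
        _json_dump(config.to_dict(), snapshot)
        raise RuntimeError(
            f"pipeline failed (config snapshot at {snapshot}): {exc}"
        ) from exc

    paths["config"] = out / "config.json"
    paths["config"].write_text(cfg_json + "\n")
    paths["log"] = out / "run.log"
    paths["log"].write_text("\n".join(log_lines) + "\n")
    return paths


def _write_plots(
    report: RMAnovaReport, cohort: pd.DataFrame, out: Path, paths: dict
) -> None:
    """EMM-by-time line plot and per-timepoint boxplot (structure only)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for g in GROUPS:
        ax.plot(TIMEPOINTS, report.emm["cell_means"].loc[g], marker="o", label=g)
    ax.set_xlabel("measurement")
    ax.set_ylabel("estimated marginal mean PEI (%)")
    ax.legend()
    paths["emm_plot"] = out / "emm_by_time.png"
    fig.savefig(paths["emm_plot"], dpi=100)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    data = [
        cohort.loc[cohort["timepoint"] == tp, "pei_percent"].to_numpy()
        for tp in TIMEPOINTS
    ]
    ax.boxplot(data, tick_labels=list(TIMEPOINTS))
    ax.set_xlabel("measurement")
    ax.set_ylabel("PEI (%)")
    paths["box_plot"] = out / "pei_boxplot.png"
    fig.savefig(paths["box_plot"], dpi=100)
    plt.close(fig)
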