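"""Sigmoidal QC of SYBR Green amplification traces.

Multiple displacement amplification (MDA) of a successfully lysed and
deposited cell produces a characteristic sigmoidal rise in SYBR Green
fluorescence over the course of the isothermal reaction; empty or failed
wells stay flat.  This module fits a four-parameter logistic to each
well's multicomponent trace, declares a well "amplified" when the fitted
rate constant (the k parameter) clears a threshold, and tests the
association between curve shape and downstream 16S PCR outcome with
Fisher's exact test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.stats.contingency import odds_ratio as _odds_ratio

__all__ = [
    "FluorescenceSeries",
    "LogisticFit",
    "WellClassification",
    "FitConfig",
    "logistic4",
    "fit_logistic",
    "classify_fit",
    "threshold_time",
    "fisher_2x2",
    "curve_pcr_association",
    "classify_wells",
]

#: Joint curve-shape x PCR-outcome categories.
CATEGORIES = (
    "sigmoid_pcr_positive",
    "sigmoid_pcr_negative",
    "flat_pcr_positive",
    "flat_pcr_negative",
)


@dataclass(frozen=True)
class FluorescenceSeries:
    """One well's fluorescence trace: times in minutes, values in a.u."""

    well_id: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or v.ndim != 1 or len(t) != len(v):
            raise ValueError(f"{self.well_id}: times and values must be equal-length 1-D")
        if len(t) < 10:
            raise ValueError(f"{self.well_id}: need at least 10 points, got {len(t)}")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(v)):
            raise ValueError(f"{self.well_id}: non-finite times or values")
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"{self.well_id}: times must be strictly increasing")


@dataclass(frozen=True)
class LogisticFit:
    """Least-squares logistic fit of one trace.

    ``rate`` is the k parameter (per minute) used for the amplified /
    non-amplified call; ``converged`` is False for flat or degenerate wells.
    """

    well_id: str
    baseline: float
    amplitude: float
    rate: float
    midpoint: float
    rss: float
    converged: bool


@dataclass(frozen=True)
class WellClassification:
    well_id: str
    fits_sigmoid: bool
    pcr_positive: Optional[bool]
    threshold_time: Optional[float]
    category: Optional[str]


@dataclass(frozen=True)
class FitConfig:
    """Knobs for :func:`fit_logistic`.

    min_amplitude_frac: fits with amplitude below this fraction of the
        observed value range are declared non-sigmoidal (flat wells must not
        pass via spurious tiny-amplitude fits).
    min_amplitude_snr: fits whose amplitude is below this multiple of the
        residual RMS are declared non-sigmoidal; on a noise-only trace the
        observed range is itself noise, so the range-based floor alone lets
        steep noise-riding fits through and the rise must also be large
        compared with the residual scatter.
    rate_init / rate_max: initial value and upper bound for the rate (1/min).
    threshold_fraction: fractional rise defining :func:`threshold_time`.
    """

    min_amplitude_frac: float = 0.05
    min_amplitude_snr: float = 5.0
    rate_init: float = 0.05
    rate_max: float = 10.0
    threshold_fraction: float = 0.10
    max_nfev: int = 10_000


def logistic4(t, baseline, amplitude, rate, midpoint):
    """4-parameter logistic: baseline + amplitude / (1 + exp(-rate*(t-midpoint)))."""
    z = np.clip(-rate * (np.asarray(t, dtype=float) - midpoint), -700, 700)
    return baseline + amplitude / (1.0 + np.exp(z))


def _initial_guess(t: np.ndarray, v: np.ndarray, config: FitConfig):
    baseline0 = float(np.min(v))
    amplitude0 = float(np.max(v) - np.min(v))
    # midpoint: time where a lightly smoothed trace crosses half-rise
    k = min(5, len(v))
    kernel = np.ones(k) / k
    smooth = np.convolve(v, kernel, mode="same")
    half = baseline0 + amplitude0 / 2.0
    above = np.nonzero(smooth >= half)[0]
    mid0 = float(t[above[0]]) if len(above) else float(t[len(t) // 2])
    return baseline0, max(amplitude0, 1e-12), config.rate_init, mid0


def fit_logistic(series: FluorescenceSeries, config: FitConfig | None = None) -> LogisticFit:
    """Fit the 4-parameter logistic to one trace by least squares.

    Degenerate outcomes (optimizer failure, amplitude below
    ``min_amplitude_frac`` of the observed range, midpoint outside the
    sampled window) are reported with ``converged=False``; the fitted
    numbers are still returned for inspection.
    """
    config = config or FitConfig()
    t, v = series.times, series.values
    value_range = float(np.max(v) - np.min(v))

    p0 = _initial_guess(t, v, config)
    lower = [-np.inf, 0.0, 0.0, -np.inf]
    upper = [np.inf, np.inf, config.rate_max, np.inf]
    try:
        popt, _ = optimize.curve_fit(
            logistic4, t, v, p0=p0, bounds=(lower, upper), maxfev=config.max_nfev
        )
    except (RuntimeError, ValueError):
        baseline0, amplitude0, rate0, mid0 = p0
        return LogisticFit(series.well_id, baseline0, amplitude0, 0.0, mid0,
                           float(np.sum((v - np.mean(v)) ** 2)), converged=False)

    baseline, amplitude, rate, midpoint = (float(x) for x in popt)
    rss = float(np.sum((v - logistic4(t, *popt)) ** 2))

    rms_resid = math.sqrt(rss / len(v))
    degenerate = (
        value_range <= 0
        or amplitude < config.min_amplitude_frac * value_range
        or amplitude < config.min_amplitude_snr * rms_resid
        or not (t[0] <= midpoint <= t[-1])
    )
    return LogisticFit(series.well_id, baseline, amplitude, rate, midpoint, rss,
                       converged=not degenerate)


def classify_fit(fit: LogisticFit, k_min: float = 0.1) -> bool:
    """Amplified call: converged fit with rate >= k_min (boundary inclusive)."""
    return bool(fit.converged and fit.rate >= k_min)


def threshold_time(fit: LogisticFit, fraction: float = 0.1) -> float:
    """Time at which the fitted curve first reaches baseline + fraction*amplitude.

    Closed form for the logistic: midpoint - ln((1-fraction)/fraction)/rate.
    Only defined for a sigmoidal (converged, rising) fit.
    """
    if not fit.converged or fit.rate <= 0:
        raise ValueError(f"{fit.well_id}: threshold time undefined for a non-sigmoidal fit")
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    return fit.midpoint - math.log((1.0 - fraction) / fraction) / fit.rate


def fisher_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    Returns (conditional odds ratio, two-sided p). The p-value sums
    hypergeometric probabilities of all tables with the observed margins
    whose probability does not exceed the observed table's.
    """
    arr = np.asarray(table, dtype=np.int64)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(arr < 0):
        raise ValueError("counts must be nonnegative")
    if arr.sum() == 0:
        raise ValueError("table total must be positive")
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    oddsr = float(_odds_ratio(arr, kind="conditional").statistic)
    return oddsr, float(p)


def curve_pcr_association(
    classifications: Sequence[WellClassification],
) -> tuple[np.ndarray, float, float]:
    """Cross-tabulate sigmoid-fit status against PCR outcome and test association.

    Returns (2x2 table [[sig+,sig-],[flat+,flat-]], odds ratio, two-sided p).
    Every well must carry a known PCR result.
    """
    table = np.zeros((2, 2), dtype=np.int64)
    for c in classifications:
        if c.pcr_positive is None:
            raise ValueError(f"{c.well_id}: PCR status unknown")
        row = 0 if c.fits_sigmoid else 1
        col = 0 if c.pcr_positive else 1
        table[row, col] += 1
    oddsr, p = fisher_2x2(table)
    return table, oddsr, p


def classify_wells(
    series_list: Sequence[FluorescenceSeries],
    pcr_results: Optional[dict[str, bool]] = None,
    k_min: float = 0.1,
    config: FitConfig | None = None,
) -> tuple[list[LogisticFit], list[WellClassification]]:
    """Fit, call and categorize every well in one pass.

    ``pcr_results`` maps well id -> 16S PCR positivity; wells without an
    entry get ``pcr_positive=None`` and no joint category.
    """
    config = config or FitConfig()
    fits, calls = [], []
    for series in series_list:
        fit = fit_logistic(series, config)
        sig = classify_fit(fit, k_min=k_min)
        tthr = threshold_time(fit, config.threshold_fraction) if sig else None
        pcr = None if pcr_results is None else pcr_results.get(series.well_id)
        if pcr is None:
            category = None
        else:
            category = CATEGORIES[(0 if sig else 2) + (0 if pcr else 1)]
        fits.append(fit)
        calls.append(WellClassification(series.well_id, sig, pcr, tthr, category))
    return fits, calls
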