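"""Aggregation and binding-curve statistics.

Quantifies inhibition the way bench assays report it: a thioflavin-T
(ThT) aggregation trace is fitted with a four-parameter logistic to
extract the half-time t50, apparent growth rate, and lag time; treated
vs control lag times give the fold-change in lag. ELISA-style saturation
binding curves are fitted with a one-site model to extract Bmax and the
half-saturation concentration.

Lag time uses the tangent-at-midpoint convention, lag = t50 - 2/rate;
this is stated here because "lag time" has no universal definition.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import FibrilCapError

__all__ = [
    "KineticTrace",
    "KineticFit",
    "BindingFit",
    "fit_tht_curve",
    "lag_ratio",
    "fit_saturation_binding",
    "NO_AGGREGATION",
]

#: Sentinel lag ratio when the treated trace never aggregates: stronger
#: inhibition than any finite fold-change.
NO_AGGREGATION = float("inf")

MIN_TRACE_POINTS = 8
MULTISTART = 5


@dataclass(frozen=True)
class KineticTrace:
    """One ThT fluorescence trace: time in hours, signal in a.u."""

    time: np.ndarray
    signal: np.ndarray
    replicate_id: str = "r1"

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "signal", s)
        if t.size < MIN_TRACE_POINTS:
            raise FibrilCapError(f"trace needs >= {MIN_TRACE_POINTS} points")
        if t.size != s.size:
            raise FibrilCapError("time and signal lengths differ")
        if not np.all(np.diff(t) > 0):
            raise FibrilCapError("time points must be strictly increasing")
        if not np.all(np.isfinite(s)):
            raise FibrilCapError("signal contains non-finite values")


@dataclass
class KineticFit:
    baseline: float
    amplitude: float
    t50: float
    rate: float
    lag_time: float | None
    aggregated_flag: bool
    residual_sse: float
    fit_failed: bool = False


@dataclass
class BindingFit:
    bmax: float
    half_saturation: float
    residual_sse: float
    fit_failed: bool = False
    wide_ci_flag: bool = False


def _logistic(t, baseline, amplitude, t50, rate):
    return baseline + amplitude / (1.0 + np.exp(-rate * (t - t50)))


def _baseline_noise(residuals: np.ndarray) -> float:
    """Robust noise scale: MAD of the first quartile of fit residuals.

    Residuals about the fitted curve are used (rather than the raw
    signal about its median) so the estimate stays a noise scale even
    when the growth transition begins inside the first quartile of the
    time window.
    """
    k = max(3, residuals.size // 4)
    head = residuals[:k]
    mad = np.median(np.abs(head - np.median(head)))
    return float(1.4826 * mad)


def fit_tht_curve(trace: KineticTrace) -> KineticFit:
    """Fit a 4-parameter logistic to an aggregation trace.

    signal(t) = baseline + amplitude / (1 + exp(-rate (t - t50))).

    Five deterministic starts guard against logistic local minima; the
    best sum-of-squares fit is kept. The trace is called non-aggregating
    when the fitted amplitude is below three times the baseline noise
    (MAD of the first quartile of points), in which case the lag time is
    undefined. Non-convergence sets ``fit_failed`` instead of raising.
    """
    t, s = trace.time, trace.signal
    span = float(s.max() - s.min())
    t_range = float(t[-1] - t[0])
    starts = [
        (s.min(), max(span, 1e-9), t[0] + f * t_range, 4.0 / max(t_range * g, 1e-9))
        for f, g in ((0.5, 0.5), (0.25, 0.25), (0.75, 0.25), (0.5, 0.1), (0.35, 1.0))
    ]
    lower = [-np.inf, 0.0, t[0] - t_range, 1e-9]
    upper = [np.inf, np.inf, t[-1] + 2 * t_range, np.inf]
    best = None
    for x0 in starts:
        try:
            res = least_squares(
                lambda p: _logistic(t, *p) - s, x0, bounds=(lower, upper),
                max_nfev=2000,
            )
        except Exception:
            continue
        sse = float((res.fun**2).sum())
        if best is None or sse < best[0]:
            best = (sse, res)
    if best is None:
        return KineticFit(np.nan, np.nan, np.nan, np.nan, None, False, np.nan, True)
    sse, res = best
    baseline, amplitude, t50, rate = map(float, res.x)
    noise = _baseline_noise(res.fun)
    aggregated = amplitude > max(3.0 * noise, 1e-8) and rate > 0
    lag = t50 - 2.0 / rate if aggregated else None
    return KineticFit(baseline, amplitude, t50, rate, lag, aggregated, sse)


def lag_ratio(treated: KineticFit, control: KineticFit) -> float:
    """Fold-change in lag time, treated / control.

    Returns the ``NO_AGGREGATION`` sentinel (infinity) when either fit
    shows no aggregation — complete abolition is stronger than any finite
    delay.
    """
    if not treated.aggregated_flag or not control.aggregated_flag:
        return NO_AGGREGATION
    if control.lag_time is None or control.lag_time <= 0:
        raise FibrilCapError("control lag time must be positive for a ratio")
    return float(treated.lag_time / control.lag_time)


def fit_saturation_binding(conc: np.ndarray, signal: np.ndarray) -> BindingFit:
    """One-site saturation binding fit: signal = Bmax c / (K50 + c).

    Concentrations in nM. Requires >= 5 points; if they span less than
    one order of magnitude the fit proceeds but is flagged wide-CI. An
    all-zero (or non-positive) signal sets ``fit_failed``.
    """
    c = np.asarray(conc, dtype=float)
    s = np.asarray(signal, dtype=float)
    if c.size < 5:
        raise FibrilCapError("need at least 5 concentration points")
    if c.size != s.size:
        raise FibrilCapError("concentration and signal lengths differ")
    pos = c[c > 0]
    wide_ci = bool(pos.size == 0 or (pos.max() / pos.min()) < 10.0)
    if s.max() <= 0:
        return BindingFit(np.nan, np.nan, np.nan, fit_failed=True, wide_ci_flag=wide_ci)

    def resid(p):
        bmax, k = p
        return bmax * c / (k + c) - s

    best = None
    cmax = float(c.max())
    for k0 in (cmax / 10, cmax / 3, cmax):
        try:
            res = least_squares(resid, (float(s.max()), k0),
                                bounds=([1e-12, 1e-12], [np.inf, np.inf]),
                                max_nfev=2000)
        except Exception:
            continue
        sse = float((res.fun**2).sum())
        if best is None or sse < best[0]:
            best = (sse, res)
    if best is None:
        return BindingFit(np.nan, np.nan, np.nan, fit_failed=True, wide_ci_flag=wide_ci)
    sse, res = best
    bmax, k = map(float, res.x)
    return BindingFit(bmax, k, sse, wide_ci_flag=wide_ci)
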