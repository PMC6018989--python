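"""Gompertz growth-curve fitting for microplate OD600 readings.

Each strain's growth curve is summarised by two population-growth
features: the maximal specific growth rate ``alpha_max`` (1/h) and the
saturating density ``od_max`` (mean OD600 over the final hour of
growth).  ``alpha_max`` comes from a nonlinear least-squares fit of the
modified (Zwietering) Gompertz function to the log-relative OD,

    y(t) = ln(OD(t) / OD(0)) = A * exp(-exp((mu * e / A) * (lambda - t) + 1)),

where ``A`` is the total log-increase, ``mu`` the maximal slope of y(t)
(the specific growth rate, per unit of ``t``) and ``lambda`` the lag
time.  Times are expected in minutes; ``alpha_max = 60 * mu`` converts
the fitted rate to 1/h.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = ["GrowthCurve", "GrowthFit", "gompertz_log", "fit_gompertz", "od_max"]

_E = np.e


@dataclass
class GrowthCurve:
    """A single strain's OD600 time series (times in minutes)."""

    strain_id: str
    times: np.ndarray
    od: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.od.shape:
            raise ValueError("times and od must be 1D arrays of equal length")
        if len(self.times) < 8:
            raise ValueError("growth curve needs at least 8 points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.od < 0):
            raise ValueError("od must be non-negative")

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass
class GrowthFit:
    strain_id: str
    alpha_max: float  # 1/h
    od_max: float
    lag: float  # minutes
    amplitude: float  # ln(OD_sat / OD_0), dimensionless
    rss: float
    converged: bool
    mu: float = field(default=np.nan)  # per input time unit (1/min)


def gompertz_log(t, amplitude, mu, lag):
    """Modified Gompertz on the log-relative OD scale."""
    t = np.asarray(t, dtype=float)
    # exponent clipped to avoid overflow during optimisation excursions
    inner = np.clip((mu * _E / amplitude) * (lag - t) + 1.0, -700.0, 700.0)
    return amplitude * np.exp(-np.exp(inner))


def _initial_guesses(times: np.ndarray, y: np.ndarray) -> list[tuple[float, float, float]]:
    amp0 = max(float(np.max(y)), 1e-3)
    dy = np.gradient(y, times)
    i = int(np.argmax(dy))
    mu0 = max(float(dy[i]), 1e-6)
    # tangent at the steepest point extrapolated back to y = 0
    lag0 = float(times[i] - y[i] / mu0)
    guesses = []
    for f_mu in (1.0, 0.5, 2.0):
        guesses.append((amp0, mu0 * f_mu, lag0))
    guesses.append((amp0 * 1.5, mu0, max(lag0, times[0])))
    guesses.append((amp0, mu0, times[0] + 0.25 * (times[-1] - times[0])))
    return guesses


def fit_gompertz(curve: GrowthCurve) -> GrowthFit:
    """Fit the Gompertz model; flat or non-increasing curves yield
    ``converged=False`` rather than an exception.

    The model is parameterized on the log-relative scale (so ``mu`` is a
    specific growth rate), but the residuals are evaluated on the OD
    scale, OD(t) = OD_0 * exp(y(t)) with the baseline OD_0 as a fourth
    fitted parameter.  OD-scale residuals keep the near-baseline
    readings — where plate-reader noise is comparable to the signal —
    from dominating the fit, which they would on the log scale.
    """
    if curve.duration < 120.0:
        raise ValueError("curve must span at least 2 h for fitting")
    od0_guess = max(float(np.median(curve.od[:3])), 1e-4)
    y = np.log(np.clip(curve.od, 1e-6, None) / od0_guess)
    odm = od_max(curve)

    if float(np.max(y)) < 0.05:  # essentially no growth on the log scale
        return GrowthFit(curve.strain_id, 0.0, odm, np.nan, 0.0,
                         float(np.sum((curve.od - np.mean(curve.od)) ** 2)), False)

    t = curve.times
    od = curve.od
    span = float(t[-1] - t[0])
    lo = np.array([1e-3, 1e-7, t[0] - span, 1e-5])
    hi = np.array([10.0 * max(np.max(y), 0.1), 1.0, t[-1], max(np.max(od), 1.0)])

    def resid(p):
        return p[3] * np.exp(gompertz_log(t, p[0], p[1], p[2])) - od

    best = None
    for guess in _initial_guesses(t, y):
        p0 = np.clip(np.array([*guess, od0_guess], dtype=float), lo, hi)
        try:
            sol = least_squares(resid, p0, bounds=(lo, hi), method="trf")
        except Exception:  # pragma: no cover - defensive
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.isfinite(best.cost):
        return GrowthFit(curve.strain_id, np.nan, odm, np.nan, np.nan, np.nan, False)

    amp, mu, lag, _od0 = (float(v) for v in best.x)
    rss = float(2.0 * best.cost)
    converged = bool(best.success) and mu > 1e-6 and amp > 1e-3
    return GrowthFit(curve.strain_id, 60.0 * mu, odm, lag, amp, rss, converged, mu=mu)


def od_max(curve: GrowthCurve, window: float = 60.0) -> float:
    """Mean OD over the final ``window`` minutes (saturating density)."""
    if curve.duration < window:
        raise ValueError("curve shorter than the averaging window")
    mask = curve.times >= curve.times[-1] - window
    return float(np.mean(curve.od[mask]))
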