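"""Time-series smoothing for RSS and coordinate series.

Two smoothers, applied per (trial × node) RSS series or per track
coordinate axis, never pooled across nodes:

* cubic smoothing spline with the penalty chosen by generalised
  cross-validation (GCV);
* local-level state-space model — a latent random-walk level observed with
  additive white noise — with both variances estimated by maximum
  likelihood (quasi-Newton on the log-variances) and the fixed-interval
  Kalman smoother evaluated on a regular time grid.

Series shorter than the smoother's minimum (5 points for splines, 2 for the
local-level model) pass through unchanged and are flagged unsmoothed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import minimize

__all__ = [
    "LocalLevelFit",
    "regularize_series",
    "smooth_spline",
    "fit_local_level_ml",
    "kalman_smooth",
    "smooth_series",
]

MIN_POINTS_SPLINE = 5
MIN_POINTS_KALMAN = 2
_VAR_FLOOR = 1e-12
_LN2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class LocalLevelFit:
    """ML estimates of the local-level model's two variances."""

    sigma2_level: float
    sigma2_obs: float
    loglik: float
    converged: bool = True
    n_obs: int = 0


def regularize_series(
    times: np.ndarray,
    values: np.ndarray,
    step: float,
    collision: str = "max",
):
    """Snap an irregular series onto a regular grid with missing slots.

    The grid spans [t_min, t_max] at increment ``step``; each observation
    lands in its nearest slot (halfway points round up).  When two
    observations map to one slot, ``collision='max'`` keeps the strongest
    value (RSS semantics) and ``'first'`` keeps the earliest (coordinate
    semantics).  Untouched slots are NaN.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size == 0:
        return np.empty(0), np.empty(0)
    t0 = times.min()
    n_slots = int(np.floor((times.max() - t0) / step)) + 1
    slots = np.clip(np.floor((times - t0) / step + 0.5).astype(int), 0, n_slots - 1)
    grid_t = t0 + step * np.arange(n_slots)
    grid_v = np.full(n_slots, np.nan)
    if collision == "max":
        np.fmax.at(grid_v, slots, values)
    elif collision == "first":
        # reversed order: the earliest observation wins the slot
        grid_v[slots[::-1]] = values[::-1]
    else:
        raise ValueError(f"unknown collision rule {collision!r}")
    return grid_t, grid_v


def smooth_spline(times, values, min_points: int = MIN_POINTS_SPLINE):
    """GCV cubic smoothing spline evaluated at the input times.

    Returns ``(smoothed_values, smoothed_flag)``; series with fewer than
    ``min_points`` observations pass through unchanged (flag False).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if len(times) < min_points:
        return values.copy(), False
    spl = make_smoothing_spline(times, values)  # lam=None -> GCV
    return spl(times), True


def _loclevel_filter(y: np.ndarray, q: float, h: float):
    """Kalman filter with exact diffuse start at the first observed slot.

    Returns (loglik, filtered means, filtered variances, first-obs index).
    Missing slots (NaN) are predicted through.  The diffuse first
    observation initialises the level exactly (filtered variance = h) and
    contributes no likelihood term.
    """
    T = len(y)
    obs = np.isfinite(y)
    t0 = int(np.argmax(obs))
    a_f = np.full(T, np.nan)
    P_f = np.full(T, np.nan)
    a, P = float(y[t0]), h
    a_f[t0], P_f[t0] = a, P
    ll = 0.0
    for t in range(t0 + 1, T):
        P = P + q
        if obs[t]:
            F = P + h
            v = y[t] - a
            ll -= 0.5 * (_LN2PI + np.log(F) + v * v / F)
            K = P / F
            a = a + K * v
            P = (1.0 - K) * P
        a_f[t], P_f[t] = a, P
    return ll, a_f, P_f, t0


def fit_local_level_ml(values: np.ndarray) -> LocalLevelFit:
    """Maximum-likelihood variances of the local-level model.

    ``values`` lie on a regular grid with NaN for missing slots.  The
    diffuse prediction-error-decomposition likelihood is maximised over the
    log-variances with BFGS; starting values come from the moments of the
    first differences (var(Δy) = σ²_level + 2σ²_obs, lag-1 autocovariance
    = −σ²_obs).  Optimiser failure falls back to the moment estimates with
    ``converged=False``.
    """
    y = np.asarray(values, dtype=float)
    obs = np.isfinite(y)
    n_obs = int(obs.sum())
    if n_obs < MIN_POINTS_KALMAN:
        raise ValueError(f"need >= {MIN_POINTS_KALMAN} observed points, got {n_obs}")
    d = np.diff(y)
    d = d[np.isfinite(d)]
    if d.size >= 2:
        g0 = float(np.var(d))
        g1 = float(np.mean((d[:-1] - d.mean()) * (d[1:] - d.mean())))
    else:
        g0 = float(np.nanvar(y))
        g1 = -0.25 * g0
    scale = max(g0, float(np.nanvar(y)), _VAR_FLOOR)
    h0 = max(-g1, 1e-3 * scale)
    q0 = max(g0 - 2.0 * h0, 1e-3 * scale)

    def negll(theta):
        q, h = np.exp(theta)
        ll, *_ = _loclevel_filter(y, q + _VAR_FLOOR, h + _VAR_FLOOR)
        return -ll

    res = minimize(negll, np.log([q0, h0]), method="BFGS")
    if res.success or np.isfinite(res.fun):
        q, h = np.exp(res.x)
        converged = bool(res.success)
    else:
        q, h = q0, h0
        converged = False
    ll, *_ = _loclevel_filter(y, q + _VAR_FLOOR, h + _VAR_FLOOR)
    return LocalLevelFit(float(q), float(h), float(ll), converged, n_obs)


def kalman_smooth(values: np.ndarray, fit: LocalLevelFit) -> np.ndarray:
    """Fixed-interval (RTS) smoothed level on the regular grid.

    Missing slots are filled with their smoothed prediction; slots before
    the first observation repeat the first smoothed level.
    """
    y = np.asarray(values, dtype=float)
    q = fit.sigma2_level + _VAR_FLOOR
    h = fit.sigma2_obs + _VAR_FLOOR
    _, a_f, P_f, t0 = _loclevel_filter(y, q, h)
    T = len(y)
    alpha = np.full(T, np.nan)
    alpha[T - 1] = a_f[T - 1]
    for t in range(T - 2, t0 - 1, -1):
        P_pred = P_f[t] + q
        C = P_f[t] / P_pred if P_pred > 0 else 0.0
        alpha[t] = a_f[t] + C * (alpha[t + 1] - a_f[t])
    alpha[:t0] = alpha[t0]
    return alpha


def smooth_series(
    times,
    values,
    method: str,
    step: float | None = None,
    collision: str = "max",
    min_points_spline: int = MIN_POINTS_SPLINE,
    min_points_kalman: int = MIN_POINTS_KALMAN,
):
    """Smooth one series and read the result back at the input times.

    ``method`` is ``none`` (identity), ``spline`` (GCV spline at the raw
    times) or ``kalman`` (local-level smoother on a regular grid of
    ``step`` seconds — the tag's nominal emission interval — mapped back by
    nearest slot).  Returns ``(values_out, smoothed_flag)``.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if method == "none":
        return values.copy(), False
    if method == "spline":
        return smooth_spline(times, values, min_points=min_points_spline)
    if method == "kalman":
        if step is None:
            raise ValueError("kalman smoothing needs the regular grid step")
        if len(times) < min_points_kalman:
            return values.copy(), False
        grid_t, grid_v = regularize_series(times, values, step, collision=collision)
        fit = fit_local_level_ml(grid_v)
        alpha = kalman_smooth(grid_v, fit)
        slots = np.clip(
            np.floor((times - grid_t[0]) / step + 0.5).astype(int), 0, len(grid_t) - 1
        )
        return alpha[slots], True
    raise ValueError(f"unknown smoothing method {method!r}")
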