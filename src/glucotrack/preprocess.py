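"""Fluorescence detrending and signal conditioning.

Bulk fluorescence recorded through chronically implanted optics decays
slowly as the indicator photobleaches, on top of which neural activity
rides as transient deflections.  The detrending strategy here assumes the
bleaching envelope is traced out by the *floor* of the signal: the lower
convex hull of the (time, fluorescence) point set is extracted, a
sum-of-exponentials baseline is least-squares fitted through the hull
vertices, and the trace is expressed as a fractional deviation from that
baseline, ``(F - fit) / fit``.  The dimensionless trace is finally
z-scored against a pre-infusion reference window so that sessions with
different expression levels and fiber placements share a common scale.

The remaining functions are the small conditioning primitives the
downstream analyses share: centered moving mean with truncated edges,
decimation, Savitzky-Golay smoothing, and linear-interpolation resampling
onto a uniform grid.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.signal import savgol_filter


class InsufficientSupportError(ValueError):
    """Too few hull support points to fit any exponential baseline."""


class FitConvergenceError(RuntimeError):
    """No multi-start converged; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


@dataclass
class DetrendModel:
    """Sum-of-exponentials baseline ``f(t) = sum_i a_i exp(-(t-t0)/tau_i) + c``.

    ``n_components`` is 3 in the default (triple-exponential) fit and drops
    to 2 or 1 when the hull support is too small to constrain seven
    parameters; the fallback is recorded here so provenance survives.
    """

    amplitudes: np.ndarray
    time_constants: np.ndarray
    offset: float
    t0: float
    residual_norm: float
    support_indices: np.ndarray
    n_components: int = 3

    def predict(self, times: np.ndarray) -> np.ndarray:
        t = np.asarray(times, dtype=float) - self.t0
        out = np.full(t.shape, self.offset, dtype=float)
        for a, tau in zip(self.amplitudes, self.time_constants):
            out += a * np.exp(-t / tau)
        return out


@dataclass
class NormalizedTrace:
    """A z-scored trace together with the reference-window statistics."""

    time: np.ndarray
    values: np.ndarray
    baseline_window: tuple[float, float]
    baseline_mean: float
    baseline_sd: float
    meta: dict = field(default_factory=dict)


def lower_hull_support(values, times=None) -> np.ndarray:
    """Indices of the lower convex hull of the (time, value) point set.

    Andrew monotone-chain restricted to the lower chain; collinear points
    are retained, and the first and last samples are always vertices.
    """
    y = np.asarray(values, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 samples for a hull")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in trace")
    t = np.arange(y.size, dtype=float) if times is None else np.asarray(times, dtype=float)
    stack: list[int] = []
    for i in range(y.size):
        # pop while the new point lies strictly below the chord -> clockwise turn
        while len(stack) >= 2:
            o, a = stack[-2], stack[-1]
            cross = (t[a] - t[o]) * (y[i] - y[o]) - (y[a] - y[o]) * (t[i] - t[o])
            if cross < 0.0:
                stack.pop()
            else:
                break
        stack.append(i)
    return np.asarray(stack, dtype=int)


def _exp_model(params: np.ndarray, t: np.ndarray, k: int) -> np.ndarray:
    out = np.full(t.shape, params[-1], dtype=float)
    for i in range(k):
        out += params[i] * np.exp(-t / params[k + i])
    return out


def fit_triple_exponential(times, values, max_nfev: int = 4000) -> DetrendModel:
    """Least-squares multi-exponential baseline fit with multi-start.

    Fits ``sum a_i exp(-t/tau_i) + c`` with ``a_i, c >= 0`` and ``tau_i > 0``
    from a deterministic grid of 27 tau starting triples (3 log-spaced
    guesses per component, 0.01/0.1/1 x trace duration).  Fewer than 8
    support points fall back to two components (>=6 points) or one
    (>=4 points); fewer than 4 raise :class:`InsufficientSupportError`.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape:
        raise ValueError("times and values must have the same shape")
    n = y.size
    if n >= 8:
        k = 3
    elif n >= 6:
        k = 2
    elif n >= 4:
        k = 1
    else:
        raise InsufficientSupportError(
            f"{n} support points cannot constrain an exponential baseline"
        )
    t0 = float(t[0])
    tt = t - t0
    span = max(float(tt[-1] - tt[0]), 1.0)
    amp0 = max(float(np.ptp(y)), 1e-12) / k
    c0 = max(float(np.min(y)), 0.0)
    lo = np.concatenate([np.zeros(k), np.full(k, span * 1e-4), [0.0]])
    hi = np.concatenate(
        [np.full(k, np.inf), np.full(k, span * 1e3), [np.inf]]
    )

    best = None
    diagnostics = []
    tau_grid = [0.01 * span, 0.1 * span, 1.0 * span]
    for taus in itertools.product(tau_grid, repeat=k):
        p0 = np.concatenate([np.full(k, amp0), np.asarray(taus), [c0]])
        try:
            res = least_squares(
                lambda p: _exp_model(p, tt, k) - y,
                p0,
                bounds=(lo, hi),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                max_nfev=max_nfev,
            )
        except Exception as exc:  # pragma: no cover - defensive
            diagnostics.append((taus, repr(exc)))
            continue
        if not np.all(np.isfinite(res.x)):
            diagnostics.append((taus, "non-finite solution"))
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitConvergenceError("all multi-starts failed", diagnostics)
    p = best.x
    return DetrendModel(
        amplitudes=p[:k].copy(),
        time_constants=p[k : 2 * k].copy(),
        offset=float(p[-1]),
        t0=t0,
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        support_indices=np.arange(n),
        n_components=k,
    )


def detrend(times, values, model: DetrendModel) -> np.ndarray:
    """Fractional deviation from the fitted baseline, ``(y - f) / f``."""
    y = np.asarray(values, dtype=float)
    f = model.predict(times)
    if np.any(f <= 0.0):
        raise ValueError("fitted baseline is non-positive somewhere; cannot divide")
    return (y - f) / f


def zscore_baseline(times, values, window: tuple[float, float]) -> NormalizedTrace:
    """Z-score a trace against the statistics of a reference time window."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    start, end = window
    mask = (t >= start) & (t <= end)
    if mask.sum() < 2:
        raise ValueError("baseline window contains fewer than 2 samples")
    mu = float(np.mean(y[mask]))
    sd = float(np.std(y[mask]))
    if sd <= 0.0:
        raise ValueError("baseline window has zero variance")
    return NormalizedTrace(
        time=t,
        values=(y - mu) / sd,
        baseline_window=(float(start), float(end)),
        baseline_mean=mu,
        baseline_sd=sd,
    )


def moving_mean(values, window_s: float, rate: float) -> np.ndarray:
    """Centered moving mean; edge windows shrink rather than pad."""
    w = int(round(window_s * rate))
    if w < 1:
        raise ValueError("window shorter than one sample")
    s = pd.Series(np.asarray(values, dtype=float))
    return s.rolling(w, center=True, min_periods=1).mean().to_numpy()


def downsample(values, step_s: float, rate: float) -> np.ndarray:
    """Take every step-th sample of an (already smoothed) series."""
    step = int(round(step_s * rate))
    if step < 1:
        raise ValueError("step shorter than one sample")
    return np.asarray(values, dtype=float)[::step].copy()


def savgol(values, order: int = 1, window: int = 5) -> np.ndarray:
    """Savitzky-Golay filter (defaults: first order, five-sample window)."""
    y = np.asarray(values, dtype=float)
    if window > y.size:
        raise ValueError("window longer than trace")
    return savgol_filter(y, window_length=window, polyorder=order)


def resample_to(times, values, rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Linear interpolation onto a uniform grid at ``rate`` Hz."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if rate <= 0:
        raise ValueError("rate must be positive")
    n = int(np.floor((t[-1] - t[0]) * rate)) + 1
    new_t = t[0] + np.arange(n) / rate
    return new_t, np.interp(new_t, t, y)


def photometry_dff(
    times, raw, baseline_window: tuple[float, float]
) -> tuple[NormalizedTrace, DetrendModel]:
    """Full detrend pipeline: hull -> exponential fit -> dF/F -> z-score.

    The baseline fit uses only the lower-hull vertices of the raw trace so
    that upward activity transients do not drag the bleaching estimate.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(raw, dtype=float)
    support = lower_hull_support(y, t)
    model = fit_triple_exponential(t[support], y[support])
    model.support_indices = support
    dff = detrend(t, y, model)
    norm = zscore_baseline(t, dff, baseline_window)
    norm.meta["n_components"] = model.n_components
    norm.meta["n_support"] = int(support.size)
    return norm, model
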