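"""Temporal analyses relating neural activity to slow physiological signals.

Derivative computation, lagged cross-correlation, linear fits,
glucose-transient boundary detection, hysteresis loops, epoch summaries,
indirect-calorimetry formulas and locomotion bout detection.  All
operations act on uniformly sampled numpy arrays; time is in seconds,
glucose in mM, speeds in cm/s and derivatives are reported per minute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


class NoTransientError(RuntimeError):
    """The glucose trace never leaves the baseline band."""


@dataclass
class LagCorrelation:
    lags: np.ndarray        # seconds; positive lag = y delayed relative to x
    r: np.ndarray           # Pearson r per lag (NaN where undefined)
    peak_lag: float
    peak_r: float


@dataclass
class LinearFitResult:
    slope: float
    intercept: float
    r_squared: float
    p_slope: float
    n: int


@dataclass
class HysteresisLoop:
    points: np.ndarray      # (n, 2) ordered (x, activity) pairs
    bounds: tuple[float, float]
    signed_area: float


@dataclass
class EpochSummary:
    windows: dict[str, tuple[float, float]]   # minutes relative to infusion
    means: dict[str, float]
    paired_diffs: dict[str, float]


@dataclass
class BoutSet:
    bouts: list[tuple[float, float, float]]   # (start s, end s, mean speed)
    count: int
    mean_duration: float
    mean_speed: float
    threshold: float


def finite_derivative(values, dt_s: float) -> np.ndarray:
    """First time derivative in units per *minute*.

    Central differences in the interior, one-sided at the edges
    (``numpy.gradient`` convention).
    """
    y = np.asarray(values, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 samples to differentiate")
    return np.gradient(y, dt_s) * 60.0


def lag_crosscorr(x, y, rate: float, max_lag_s: float) -> LagCorrelation:
    """Pearson correlation of overlapping segments at each integer-sample lag.

    Positive lag means ``y`` is delayed relative to ``x``: at lag ``+L`` the
    correlation is computed between ``x[:-L]`` and ``y[L:]``.  The peak is
    the extremum of ``|r|`` over the grid.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size != yv.size:
        raise ValueError("series must share a grid")
    n = xv.size
    max_lag = int(round(max_lag_s * rate))
    if n - max_lag < 10:
        raise ValueError("overlap shorter than 10 samples at maximum lag")
    lags = np.arange(-max_lag, max_lag + 1)
    rs = np.full(lags.size, np.nan)
    for i, lag in enumerate(lags):
        if lag >= 0:
            a, b = xv[: n - lag], yv[lag:]
        else:
            a, b = xv[-lag:], yv[: n + lag]
        if np.std(a) == 0.0 or np.std(b) == 0.0:
            continue  # undefined r at this lag, recorded as missing
        rs[i] = float(np.corrcoef(a, b)[0, 1])
    if np.all(np.isnan(rs)):
        raise ValueError("correlation undefined at every lag (constant input)")
    k = int(np.nanargmax(np.abs(rs)))
    return LagCorrelation(
        lags=lags / rate, r=rs, peak_lag=float(lags[k] / rate), peak_r=float(rs[k])
    )


def linfit(x, y) -> LinearFitResult:
    """Ordinary least-squares line with a two-sided slope test."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size < 3:
        raise ValueError("need at least 3 points")
    if np.std(xv) == 0.0:
        raise ValueError("predictor is constant")
    res = stats.linregress(xv, yv)
    return LinearFitResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_slope=float(res.pvalue),
        n=int(xv.size),
    )


def detect_transient(
    times,
    glucose,
    baseline_window: tuple[float, float],
    k: float = 3.0,
    sustain_s: float = 60.0,
) -> tuple[float, float]:
    """Temporal boundaries of a blood-glucose transient.

    Onset is the first time glucose exceeds (baseline mean + k * baseline sd)
    for a sustained ``sustain_s``; offset is the first later time it stays
    back below that level equally long, else the last sample.
    """
    t = np.asarray(times, dtype=float)
    g = np.asarray(glucose, dtype=float)
    b0, b1 = baseline_window
    mask = (t >= b0) & (t <= b1)
    if mask.sum() < 2:
        raise ValueError("baseline window contains fewer than 2 samples")
    thr = float(np.mean(g[mask]) + k * np.std(g[mask]))
    above = g > thr
    dt = float(np.median(np.diff(t)))
    m = max(1, int(round(sustain_s / dt)))
    run = np.convolve(above.astype(int), np.ones(m, dtype=int), mode="valid")
    starts = np.flatnonzero(run == m)
    starts = starts[t[starts] > b1]
    if starts.size == 0:
        raise NoTransientError(f"glucose never exceeds {thr:.2f} mM for {sustain_s} s")
    i0 = int(starts[0])
    below_run = np.convolve((~above).astype(int), np.ones(m, dtype=int), mode="valid")
    ends = np.flatnonzero(below_run == m)
    ends = ends[ends > i0]
    t_end = float(t[int(ends[0])]) if ends.size else float(t[-1])
    return float(t[i0]), t_end


def hysteresis_loop(times, activity, x, bounds: tuple[float, float], n: int = 50) -> HysteresisLoop:
    """Activity-versus-x loop over a transient, sampled at n equal time steps.

    Both series are linearly interpolated at ``n`` equally spaced times
    across ``bounds``; the signed area of the traversed (x, activity)
    polygon is computed by the shoelace formula (counterclockwise
    traversal positive).
    """
    t = np.asarray(times, dtype=float)
    a = np.asarray(activity, dtype=float)
    xv = np.asarray(x, dtype=float)
    t0, t1 = bounds
    if t0 < t[0] or t1 > t[-1] or t1 <= t0:
        raise ValueError("bounds outside the recorded data")
    ts = np.linspace(t0, t1, n)
    px = np.interp(ts, t, xv)
    pa = np.interp(ts, t, a)
    area = 0.5 * float(
        np.sum(px * np.roll(pa, -1) - np.roll(px, -1) * pa)
    )
    return HysteresisLoop(
        points=np.column_stack([px, pa]), bounds=(float(t0), float(t1)), signed_area=area
    )


DEFAULT_EPOCHS = {"baseline": (-11.0, -2.0), "deriv": (2.0, 11.0), "abs": (11.0, 20.0)}


def epoch_means(times, activity, infusion_time: float, windows=None) -> EpochSummary:
    """Mean activity in canonical epochs around the infusion.

    Windows are half-open ``[start, end)`` in minutes relative to the
    infusion; the defaults are a pre-infusion baseline (-11..-2 min), the
    high-glucose-derivative period (2..11 min) and the high-absolute-glucose
    period (11..20 min).
    """
    windows = dict(DEFAULT_EPOCHS if windows is None else windows)
    t_min = (np.asarray(times, dtype=float) - infusion_time) / 60.0
    a = np.asarray(activity, dtype=float)
    means = {}
    for name, (w0, w1) in windows.items():
        mask = (t_min >= w0) & (t_min < w1)
        if not mask.any():
            raise ValueError(f"epoch window {name!r} contains no samples")
        means[name] = float(np.mean(a[mask]))
    diffs = {}
    if "baseline" in means:
        for name in means:
            if name != "baseline":
                diffs[f"{name}-baseline"] = means[name] - means["baseline"]
    return EpochSummary(windows=windows, means=means, paired_diffs=diffs)


def weir_ee(vo2, vco2):
    """Respiratory energy expenditure, kcal/min = 3.94*VO2 + 1.1*VCO2 (l/min)."""
    v1 = np.asarray(vo2, dtype=float)
    v2 = np.asarray(vco2, dtype=float)
    if np.any(v1 < 0) or np.any(v2 < 0):
        raise ValueError("gas volumes must be non-negative")
    out = 3.94 * v1 + 1.1 * v2
    return float(out) if out.ndim == 0 else out


def rer(vo2, vco2):
    """Respiratory exchange ratio, VCO2/VO2, elementwise."""
    v1 = np.asarray(vo2, dtype=float)
    v2 = np.asarray(vco2, dtype=float)
    if np.any(v1 <= 0):
        raise ValueError("VO2 must be strictly positive")
    out = v2 / v1
    return float(out) if out.ndim == 0 else out


def detect_bouts(
    speed,
    rate: float,
    threshold: float,
    min_dur: float = 1.0,
    gap: float = 2.0,
) -> BoutSet:
    """Locomotion bouts: super-threshold runs, gap-merged, duration-filtered.

    Runs of samples strictly above ``threshold`` that are separated by
    ``gap`` seconds or less are merged into one bout; merged bouts shorter
    than ``min_dur`` are then discarded.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    v = np.asarray(speed, dtype=float)
    above = v > threshold
    if not above.any():
        return BoutSet([], 0, 0.0, 0.0, threshold)
    padded = np.concatenate([[False], above, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    runs = [(int(edges[i]), int(edges[i + 1]) - 1) for i in range(0, edges.size, 2)]
    # merge runs whose separating gap is <= gap seconds
    merged = [list(runs[0])]
    for s, e in runs[1:]:
        if (s - merged[-1][1] - 1) / rate <= gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    bouts = []
    for s, e in merged:
        dur = (e - s + 1) / rate
        if dur + 1e-12 >= min_dur:
            bouts.append((s / rate, (e + 1) / rate, float(np.mean(v[s : e + 1]))))
    durations = [b[1] - b[0] for b in bouts]
    speeds = [b[2] for b in bouts]
    return BoutSet(
        bouts=bouts,
        count=len(bouts),
        mean_duration=float(np.mean(durations)) if bouts else 0.0,
        mean_speed=float(np.mean(speeds)) if bouts else 0.0,
        threshold=threshold,
    )
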