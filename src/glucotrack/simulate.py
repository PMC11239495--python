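"""Synthetic multichannel session generator with ground-truth labels.

Emulates the statistical structure of a head-fixed recording session in
which blood glucose telemetry, bulk neural activity, wheel running,
respiratory gas exchange and body temperature are co-recorded around a
glucose infusion:

* the glucose transient is a bi-exponential absorption/clearance curve
  whose defaults keep the noiseless peak and maximum rate of change
  inside the physiological ranges of such experiments (baseline
  3.5-11.1 mM, peaks 11.1-34.9 mM, rates 0.12-1.45 mM/min);
* locomotion is a bout point process (Poisson starts, exponential
  durations, super-threshold speeds);
* gas traces rise with running through a lagged kernel, and the
  respiratory exchange ratio and body temperature drift upward after the
  infusion;
* single cells at 5 Hz mix a glucose-coupled slow waveform (one of the
  proportional / derivative / inverted classes), an indicator-convolved
  locomotion component, optional photobleaching and white noise, with the
  generating labels and gains recorded for parameter-recovery tests.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .classify import GLUCOSE_CLASSES, NO_RESPONSE, class_waveforms
from .preprocess import zscore_baseline

#: class prevalences emulating the measured single-cell survey: two thirds
#: of cells glucose-inhibited (proportional iG / derivative idG), the rest
#: activated, plus a small no-response remainder.
DEFAULT_PREVALENCES = {"G": 0.245, "dG": 0.108, "iG": 0.323, "idG": 0.304, NO_RESPONSE: 0.020}
DEFAULT_RUNNING_PREVALENCES = {"positive": 0.50, "negative": 0.17, "none": 0.33}

PEAK_RANGE_MM = (11.1, 34.9)
RATE_RANGE_MM_MIN = (0.12, 1.45)


class DegenerateKineticsError(ValueError):
    """Absorption and clearance time constants coincide."""


@dataclass
class GlucoseParams:
    """Bi-exponential infusion transient parameters (times in minutes)."""

    baseline: float = 7.3
    amplitude: float = 7.0
    tau_abs: float = 9.0
    tau_clear: float = 27.0
    noise_sd: float = 0.15


@dataclass
class SimConfig:
    duration: float = 5400.0          # s
    master_rate: float = 1.0          # Hz
    cell_rate: float = 5.0            # Hz
    infusion_time: float | None = 1500.0  # s; None -> no infusion
    infusion_route: str = "IP"        # IP or IG
    seed: int = 0
    n_cells: int = 100
    prevalences: dict = field(default_factory=lambda: dict(DEFAULT_PREVALENCES))
    running_prevalences: dict = field(
        default_factory=lambda: dict(DEFAULT_RUNNING_PREVALENCES)
    )
    glucose: GlucoseParams | None = None
    slow_gain: float = 5.0            # z-units per unit-SD class waveform
    # per-class response-amplitude scale: derivative-activated cells respond
    # weakly and the two proportional classes nearly cancel in the summed
    # population, which is what makes the net response derivative-inhibited
    class_amplitudes: dict = field(
        default_factory=lambda: {"G": 1.25, "dG": 0.4, "iG": 1.0, "idG": 1.0}
    )
    running_gain: float = 1.0         # z-units per unit-SD convolved speed
    gain_jitter: float = 0.25         # lognormal sigma on per-cell gains
    noise_sd: float = 1.0             # z-units, cell traces
    indicator_tau: float = 1.5        # s, calcium-indicator decay
    cell_bleach_amp: float = 0.0      # z-units; per-trace additive bleach
    bleach_amplitudes: tuple = (0.15, 0.1, 0.05)   # relative, raw photometry
    bleach_taus: tuple = (4000.0, 900.0, 150.0)    # s
    bleach_offset: float = 0.7
    # locomotion
    bout_rate: float = 0.02           # bouts per second
    bout_duration_mean: float = 4.0   # s
    speed_threshold: float = 18.0     # cm/s (untethered wheel criterion)
    # metabolics
    vo2_base: float = 0.002           # l/min
    rer_base: float = 0.85
    rer_glucose_gain: float = 0.10
    vo2_run_gain: float = 0.3         # fractional VO2 rise at reference speed
    temp_base: float = 37.0           # deg C
    temp_glucose_gain: float = 0.6    # deg C at transient peak
    met_noise_frac: float = 0.01
    # independent slow metabolic variability (keeps predictor collinearity low,
    # as in real gas-exchange data where metabolism has many drivers)
    vo2_slow_sd: float = 0.15         # fraction of vo2_base
    vco2_slow_sd: float = 0.15        # fraction of vo2_base, independent of VO2's
    rer_slow_sd: float = 0.03
    temp_slow_sd: float = 0.30        # deg C

    def glucose_params(self) -> GlucoseParams:
        if self.glucose is not None:
            return self.glucose
        if self.infusion_route.upper() == "IG":
            return GlucoseParams(tau_abs=14.0)  # slower gut absorption
        return GlucoseParams()

    def validate(self) -> None:
        total = sum(self.prevalences.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"prevalences sum to {total}, not 1")
        if min(self.prevalences.values(), default=0.0) < 0:
            raise ValueError("negative prevalence")
        for r in (self.master_rate, self.cell_rate):
            if r <= 0:
                raise ValueError("rates must be positive")
        if self.infusion_time is not None:
            if self.infusion_time < 1200.0:
                raise ValueError("need >= 20 min of pre-infusion recording")
            if self.duration - self.infusion_time < 1500.0:
                raise ValueError("need >= 25 min of post-infusion recording")


@dataclass
class SessionRecord:
    """Aligned multichannel 1-Hz physiological time series + event metadata."""

    time: np.ndarray          # s, uniform
    glucose: np.ndarray       # mM
    activity: np.ndarray      # z-units, population
    running: np.ndarray       # cm/s
    vo2: np.ndarray           # l/min
    vco2: np.ndarray          # l/min
    temperature: np.ndarray   # deg C
    events: list = field(default_factory=list)   # (label, time_s)
    meta: dict = field(default_factory=dict)

    @property
    def rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))

    def infusion_time(self) -> float | None:
        for label, t in self.events:
            if label.startswith("infusion"):
                return float(t)
        return None


@dataclass
class GroundTruth:
    cell_labels: list
    cell_running_labels: list
    slow_gains: np.ndarray
    running_gains: np.ndarray
    bleach: dict = field(default_factory=dict)


def simulate_glucose(params: GlucoseParams, times, onset: float, rng) -> np.ndarray:
    """Blood glucose transient: baseline + peak-normalized bi-exponential.

    For t >= onset,
    ``G = baseline + amplitude * k * (exp(-(t-onset)/tau_c) - exp(-(t-onset)/tau_a))``
    with ``k`` chosen so the noiseless peak sits exactly ``amplitude`` above
    baseline.  Telemetry noise is additive throughout.  The noiseless peak
    and maximum rate are checked against the physiological ranges post hoc
    and a warning is raised when either falls outside.
    """
    t = np.asarray(times, dtype=float)
    if params.amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    if abs(params.tau_abs - params.tau_clear) < 1e-12:
        raise DegenerateKineticsError("tau_abs == tau_clear")
    if not (t[0] <= onset <= t[-1]):
        raise ValueError("onset outside the time grid")
    ta, tc = params.tau_abs * 60.0, params.tau_clear * 60.0
    g = np.full(t.shape, params.baseline, dtype=float)
    if params.amplitude > 0:
        tpeak = ta * tc / (tc - ta) * np.log(tc / ta)
        k = 1.0 / (np.exp(-tpeak / tc) - np.exp(-tpeak / ta))
        dt = np.clip(t - onset, 0.0, None)
        shape = np.exp(-dt / tc) - np.exp(-dt / ta)
        g = g + params.amplitude * k * shape
        peak = params.baseline + params.amplitude
        max_rate = params.amplitude * k * abs(1.0 / ta - 1.0 / tc) * 60.0
        if not (PEAK_RANGE_MM[0] <= peak <= PEAK_RANGE_MM[1]):
            warnings.warn(
                f"noiseless peak {peak:.1f} mM outside {PEAK_RANGE_MM}", stacklevel=2
            )
        if not (RATE_RANGE_MM_MIN[0] <= max_rate <= RATE_RANGE_MM_MIN[1]):
            warnings.warn(
                f"max rate {max_rate:.2f} mM/min outside {RATE_RANGE_MM_MIN}",
                stacklevel=2,
            )
    if params.noise_sd > 0:
        g = g + params.noise_sd * rng.standard_normal(t.size)
    return g


def simulate_locomotion(config: SimConfig, rng, return_bouts: bool = False):
    """Bout-structured wheel-speed trace at the master rate.

    Bout starts form a Poisson point process, durations are >= 1 s with an
    exponential tail, and bout speeds are drawn strictly above the
    configured detection threshold; the speed is zero between bouts.
    """
    if config.bout_rate < 0:
        raise ValueError("bout rate must be non-negative")
    n = int(round(config.duration * config.master_rate))
    speed = np.zeros(n)
    bouts = []
    if config.bout_rate > 0:
        n_bouts = rng.poisson(config.bout_rate * config.duration)
        starts = np.sort(rng.uniform(0.0, config.duration, size=n_bouts))
        durations = 1.0 + rng.exponential(
            max(config.bout_duration_mean - 1.0, 1e-6), size=n_bouts
        )
        speeds = config.speed_threshold + 2.0 + rng.gamma(2.0, 3.0, size=n_bouts)
        for s, d, v in zip(starts, durations, speeds):
            i0 = int(np.floor(s * config.master_rate))
            i1 = min(n, int(np.ceil((s + d) * config.master_rate)))
            if i1 > i0:
                speed[i0:i1] = np.maximum(speed[i0:i1], v)
                bouts.append((float(s), float(d), float(v)))
    if return_bouts:
        return speed, bouts
    return speed


def _exp_kernel(tau_s: float, rate: float, length_s: float | None = None) -> np.ndarray:
    if length_s is None:
        length_s = 5.0 * tau_s
    t = np.arange(0.0, length_s, 1.0 / rate)
    k = np.exp(-t / tau_s)
    return k / k.sum()


def _causal_smooth(x: np.ndarray, tau_s: float, rate: float) -> np.ndarray:
    k = _exp_kernel(tau_s, rate)
    return np.convolve(x, k)[: x.size]


def simulate_metabolics(glucose, running, config: SimConfig, rng):
    """VO2, VCO2 and body temperature coupled to running and glucose.

    VO2 rises with running through a lagged exponential kernel; the
    respiratory exchange ratio (VCO2/VO2) drifts upward after the glucose
    transient as metabolism shifts toward carbohydrate oxidation; body
    temperature rises slowly post-infusion.  Each channel additionally
    carries an independent slow fluctuation process (intrinsic metabolic
    variability, which keeps predictor collinearity low), plus fast sensor
    noise.  All channels stay strictly positive.
    """
    g = np.asarray(glucose, dtype=float)
    v = np.asarray(running, dtype=float)
    if g.size != v.size:
        raise ValueError("glucose and running must share a grid")
    rate = config.master_rate
    n = g.size
    gp = config.glucose_params()
    exc = np.clip(g - gp.baseline, 0.0, None)
    scale = gp.amplitude if gp.amplitude > 0 else 1.0
    exc_n = _causal_smooth(exc / scale, 300.0, rate)       # lagged, 5-min kernel
    run_n = _causal_smooth(v / max(config.speed_threshold, 1e-9), 30.0, rate)

    def slow_fluct(sd: float, tau_s: float) -> np.ndarray:
        if sd <= 0:
            return np.zeros(n)
        w = _causal_smooth(rng.standard_normal(n), tau_s, rate)
        wsd = np.std(w)
        return sd * w / wsd if wsd > 0 else np.zeros(n)

    vo2_drive = config.vo2_base * (1.0 + config.vo2_run_gain * run_n)
    vo2 = vo2_drive + config.vo2_base * slow_fluct(config.vo2_slow_sd, 120.0)
    rer_series = (
        config.rer_base
        + config.rer_glucose_gain * exc_n
        + slow_fluct(config.rer_slow_sd, 180.0)
    )
    # CO2 production carries its own intrinsic variability on top of the
    # RER-scaled aerobic drive, so VO2's fluctuations do not copy into VCO2
    vco2 = vo2_drive * rer_series + config.vo2_base * slow_fluct(
        config.vco2_slow_sd, 120.0
    )
    temp = (
        config.temp_base
        + config.temp_glucose_gain * _causal_smooth(exc / scale, 600.0, rate)
        + slow_fluct(config.temp_slow_sd, 300.0)
    )
    if config.met_noise_frac > 0:
        vo2 = vo2 + config.met_noise_frac * config.vo2_base * rng.standard_normal(n)
        vco2 = vco2 + config.met_noise_frac * config.vo2_base * rng.standard_normal(n)
        temp = temp + 0.02 * rng.standard_normal(n)
    floor = 1e-6
    return np.maximum(vo2, floor), np.maximum(vco2, floor), np.maximum(temp, floor)


def _draw_labels(rng, n, prevalences, classes):
    probs = np.array([prevalences.get(c, 0.0) for c in classes], dtype=float)
    probs = probs / probs.sum()
    return [classes[i] for i in rng.choice(len(classes), size=n, p=probs)]


def simulate_cells(
    config: SimConfig,
    times,
    glucose,
    running,
    rng,
    labels=None,
    running_labels=None,
):
    """Single-cell trace matrix at the cell rate plus generating labels.

    Each cell is ``slow_gain * class_waveform(glucose) +
    running_gain * indicator_convolved(speed) + bleach(t) + noise``; the
    class waveform is the same smoothed glucose transformation the
    classifier's templates use, normalized to unit SD over the session, so
    ``slow_gain / noise_sd`` is the slow-signal SNR.  No-response cells
    have zero slow gain; the sign of the running gain sets the running
    label.
    """
    if config.n_cells <= 0 and labels is None:
        raise ValueError("n_cells must be positive")
    t = np.asarray(times, dtype=float)
    g = np.asarray(glucose, dtype=float)
    v = np.asarray(running, dtype=float)
    n_cells = len(labels) if labels is not None else config.n_cells
    ct = t[0] + np.arange(int(round((t[-1] - t[0]) * config.cell_rate)) + 1) / config.cell_rate

    # slow glucose coupling only exists when the session carries a glucose
    # signal: with no infusion (or zero amplitude) the cells' glucose input
    # does not fluctuate and the slow component vanishes
    gp = config.glucose_params()
    signal_present = config.infusion_time is not None and gp.amplitude > 0
    waves = class_waveforms(t, g, 90.0, config.master_rate)
    wave_c = {}
    for name in GLUCOSE_CLASSES:
        w = np.interp(ct, t, waves[name])
        sd = np.std(w)
        if not signal_present or sd <= 1e-12:
            wave_c[name] = np.zeros_like(w)
        else:
            wave_c[name] = (w - np.mean(w)) / sd

    run_c = np.interp(ct, t, v)
    run_reg = _causal_smooth(run_c, config.indicator_tau, config.cell_rate)
    sd = np.std(run_reg)
    run_reg = (run_reg - np.mean(run_reg)) / sd if sd > 1e-12 else run_reg * 0.0

    if labels is None:
        labels = _draw_labels(
            rng, n_cells, config.prevalences, (*GLUCOSE_CLASSES, NO_RESPONSE)
        )
    if running_labels is None:
        running_labels = _draw_labels(
            rng, n_cells, config.running_prevalences, ("positive", "negative", "none")
        )

    bleach = np.zeros(ct.size)
    if config.cell_bleach_amp > 0:
        b = sum(
            a * np.exp(-(ct - ct[0]) / tau)
            for a, tau in zip(config.bleach_amplitudes, config.bleach_taus)
        )
        bleach = config.cell_bleach_amp * b / max(np.max(np.abs(b)), 1e-12)

    jitter = lambda size: (
        rng.lognormal(0.0, config.gain_jitter, size=size)
        if config.gain_jitter > 0
        else np.ones(size)
    )
    slow_gains = config.slow_gain * jitter(n_cells)
    if not signal_present:
        slow_gains = np.zeros(n_cells)
    run_gains = config.running_gain * jitter(n_cells)
    mat = np.empty((ct.size, n_cells))
    for j in range(n_cells):
        lab, rlab = labels[j], running_labels[j]
        if lab == NO_RESPONSE:
            slow_gains[j] = 0.0
            slow = 0.0
        else:
            slow_gains[j] *= config.class_amplitudes.get(lab, 1.0)
            slow = slow_gains[j] * wave_c[lab]
        if rlab == "none":
            run_gains[j] = 0.0
            fast = 0.0
        else:
            if rlab == "negative":
                run_gains[j] = -run_gains[j]
            fast = run_gains[j] * run_reg
        mat[:, j] = (
            slow + fast + bleach + config.noise_sd * rng.standard_normal(ct.size)
        )
    gt = GroundTruth(
        cell_labels=list(labels),
        cell_running_labels=list(running_labels),
        slow_gains=slow_gains,
        running_gains=run_gains,
        bleach={
            "amplitude_z": config.cell_bleach_amp,
            "taus_s": list(config.bleach_taus),
        },
    )
    return ct, mat, gt


def raw_photometry(
    times,
    activity,
    config: SimConfig,
    f0: float = 100.0,
    response_scale: float = 0.05,
    rng=None,
) -> np.ndarray:
    """Raw fluorescence: multiplicative photobleaching on top of activity.

    ``F(t) = f0 * bleach(t) * (1 + response_scale * activity)`` with a
    triple-exponential-plus-offset bleach — exactly the structure the
    detrender assumes.
    """
    t = np.asarray(times, dtype=float)
    a = np.asarray(activity, dtype=float)
    b = config.bleach_offset + sum(
        amp * np.exp(-(t - t[0]) / tau)
        for amp, tau in zip(config.bleach_amplitudes, config.bleach_taus)
    )
    raw = f0 * b * (1.0 + response_scale * a)
    if rng is not None:
        raw = raw + 0.001 * f0 * rng.standard_normal(t.size)
    return raw


def simulate_session(config: SimConfig):
    """Generate a full mutually consistent session.

    Returns ``(SessionRecord, cell_time, cell_matrix, GroundTruth)``.  The
    population activity channel is the mean of the single-cell traces,
    resampled to the master rate and z-scored against the 20 min before
    the infusion (whole session if there is none).
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    r_glu, r_loc, r_met, r_cell = [np.random.default_rng(s) for s in ss.spawn(4)]
    n = int(round(config.duration * config.master_rate))
    t = np.arange(n) / config.master_rate
    gp = config.glucose_params()
    events = []
    if config.infusion_time is not None:
        glucose = simulate_glucose(gp, t, config.infusion_time, r_glu)
        events.append((f"infusion:{config.infusion_route}", float(config.infusion_time)))
    else:
        glucose = np.full(n, gp.baseline) + gp.noise_sd * r_glu.standard_normal(n)
    running, bouts = simulate_locomotion(config, r_loc, return_bouts=True)
    vo2, vco2, temp = simulate_metabolics(glucose, running, config, r_met)
    ct, cells, gt = simulate_cells(config, t, glucose, running, r_cell)
    pop = np.interp(t, ct, cells.mean(axis=1))
    if config.infusion_time is not None:
        win = (config.infusion_time - 1200.0, config.infusion_time)
    else:
        win = (float(t[0]), float(t[-1]))
    activity = zscore_baseline(t, pop, win).values
    session = SessionRecord(
        time=t,
        glucose=glucose,
        activity=activity,
        running=running,
        vo2=vo2,
        vco2=vco2,
        temperature=temp,
        events=events,
        meta={
            "config": asdict(config),
            "seed": config.seed,
            "generated_bouts": bouts,
            "baseline_window_s": list(win),
        },
    )
    return session, ct, cells, gt
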