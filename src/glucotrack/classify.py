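"""Single-cell classification against glucose-derived response templates.

Four reference waveforms are derived from a measured (or simulated) blood
glucose transient: the smoothed glucose itself (G), its smoothed first
derivative (dG) and their sign inversions (iG, idG).  Each cell's trace,
aligned to the first 20 min after the infusion, is correlated with every
template; the cell joins the class with the maximum Pearson r unless no
correlation survives a Bonferroni-corrected significance threshold
(family alpha / 4), in which case it is a no-response ("N/A") cell.

A second, faster axis classifies every cell by its Spearman correlation
with running speed over the whole session, and the two class axes are
cross-tabulated to quantify how many cells multiplex glucose and
locomotion information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import moving_mean
from .temporal import finite_derivative

GLUCOSE_CLASSES = ("G", "dG", "iG", "idG")
NO_RESPONSE = "N/A"
RUNNING_CLASSES = ("positive", "negative", "none")


@dataclass
class TemplateSet:
    """Glucose-derived reference waveforms on a common post-infusion grid."""

    time_min: np.ndarray            # minutes post-infusion
    abs_time_s: np.ndarray          # absolute session seconds of the grid
    waveforms: dict[str, np.ndarray]
    construction: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in GLUCOSE_CLASSES:
            if name not in self.waveforms:
                raise ValueError(f"missing template {name!r}")


@dataclass
class CellClassification:
    cell_id: str
    glucose_class: str
    r_per_template: dict[str, float]
    p_per_template: dict[str, float]
    alpha_per_template: float
    flagged: bool = False           # constant trace; correlation undefined


@dataclass
class RunningCorrelationResult:
    cell_id: str
    rho: float
    p: float
    running_class: str
    flagged: bool = False


@dataclass
class MultiplexTable:
    counts: pd.DataFrame            # glucose class x running class
    fractions: pd.DataFrame
    multiplexed_fraction: float
    n_cells: int


@dataclass
class PopulationReconstruction:
    prevalences: dict[str, float]
    amplitudes: dict[str, float]
    time_min: np.ndarray
    reconstructed: np.ndarray


def class_waveforms(
    times, glucose, smooth_window_s: float = 90.0, rate: float | None = None
) -> dict[str, np.ndarray]:
    """The four class waveforms evaluated on a glucose trace.

    The trace is smoothed with a moving mean (default 1.5-min window);
    the derivative template is re-smoothed with the same filter after
    differentiation.  Inverted templates are exact negations.
    """
    t = np.asarray(times, dtype=float)
    g = np.asarray(glucose, dtype=float)
    if rate is None:
        rate = 1.0 / float(np.median(np.diff(t)))
    G = moving_mean(g, smooth_window_s, rate)
    dG = moving_mean(finite_derivative(G, 1.0 / rate), smooth_window_s, rate)
    return {"G": G, "dG": dG, "iG": -G, "idG": -dG}


def _center_scale(w: np.ndarray) -> np.ndarray:
    c = w - np.mean(w)
    sd = np.std(c)
    return c / sd if sd > 1e-12 else c


def build_templates(
    times,
    glucose,
    infusion_time: float,
    smooth_window_s: float = 90.0,
    post_min: float = 20.0,
) -> TemplateSet:
    """Build the G/dG/iG/idG template set from a glucose trace.

    Smoothing is applied on the full trace before cropping to the first
    ``post_min`` minutes after the infusion; each template is centered and
    scaled to unit standard deviation (left centered if degenerate) so
    that prevalence-weighted reconstructions are on a common scale.
    """
    t = np.asarray(times, dtype=float)
    rate = 1.0 / float(np.median(np.diff(t)))
    if t[-1] < infusion_time + post_min * 60.0 - 0.5 / rate:
        raise ValueError(f"trace must cover {post_min} min past the infusion")
    waves = class_waveforms(t, glucose, smooth_window_s, rate)
    mask = (t >= infusion_time) & (t < infusion_time + post_min * 60.0)
    G = _center_scale(waves["G"][mask])
    dG = _center_scale(waves["dG"][mask])
    return TemplateSet(
        time_min=(t[mask] - infusion_time) / 60.0,
        abs_time_s=t[mask].copy(),
        waveforms={"G": G, "dG": dG, "iG": -G, "idG": -dG},
        construction={
            "smooth_window_s": smooth_window_s,
            "post_min": post_min,
            "infusion_time": infusion_time,
            "derivative_resmoothed": True,
        },
    )


def align_to_templates(trace_times, trace, templates: TemplateSet) -> np.ndarray:
    """Linear interpolation of a cell trace onto the template grid."""
    t = np.asarray(trace_times, dtype=float)
    y = np.asarray(trace, dtype=float)
    grid = templates.abs_time_s
    if grid[0] < t[0] - 1e-9 or grid[-1] > t[-1] + 1e-9:
        raise ValueError("trace does not cover the template window")
    return np.interp(grid, t, y)


def _circular_shift_pvalue(
    x: np.ndarray, template: np.ndarray, r_obs: float, n_shifts: int, rng
) -> float:
    """Null distribution from circular shifts of the trace.

    Shifting preserves the trace's autocorrelation, so this is the
    conservative alternative to the t-approximation p-value.
    """
    n = x.size
    offsets = rng.integers(1, n, size=n_shifts)
    hits = 1  # include the observed statistic
    for off in offsets:
        r = np.corrcoef(np.roll(x, int(off)), template)[0, 1]
        hits += abs(r) >= abs(r_obs)
    return hits / (n_shifts + 1)


def classify_cell(
    trace_times,
    trace,
    templates: TemplateSet,
    family_alpha: float = 0.001,
    cell_id: str = "cell",
    p_method: str = "t",
    n_shifts: int = 500,
    seed: int = 0,
) -> CellClassification:
    """Assign one cell to a glucose-response class by template correlation.

    Maximum Pearson r over the four templates wins; if no template's
    two-sided p-value beats the Bonferroni-corrected threshold
    ``family_alpha / 4``, the cell is a no-response cell.  Exact r ties
    break in the fixed order G, dG, iG, idG.  ``p_method="t"`` (default)
    uses the Pearson t-approximation, which ignores autocorrelation;
    ``p_method="permutation"`` uses a circular-shift null instead.
    """
    aligned = align_to_templates(trace_times, trace, templates)
    alpha = family_alpha / len(GLUCOSE_CLASSES)
    if np.std(aligned) <= 1e-12:
        return CellClassification(
            cell_id,
            NO_RESPONSE,
            {k: float("nan") for k in GLUCOSE_CLASSES},
            {k: float("nan") for k in GLUCOSE_CLASSES},
            alpha,
            flagged=True,
        )
    rs, ps = {}, {}
    rng = np.random.default_rng(seed)
    for name in GLUCOSE_CLASSES:
        r, p = stats.pearsonr(aligned, templates.waveforms[name])
        rs[name] = float(r)
        if p_method == "permutation":
            p = _circular_shift_pvalue(
                aligned, templates.waveforms[name], float(r), n_shifts, rng)
        elif p_method != "t":
            raise ValueError(f"unknown p_method {p_method!r}")
        ps[name] = float(p)
    if min(ps.values()) >= alpha:
        label = NO_RESPONSE
    else:
        label = max(GLUCOSE_CLASSES, key=lambda k: (rs[k], -GLUCOSE_CLASSES.index(k)))
    return CellClassification(cell_id, label, rs, ps, alpha)


def classify_batch(
    sessions,
    templates: TemplateSet,
    family_alpha: float = 0.001,
    cell_ids=None,
) -> tuple[list[CellClassification], dict[str, float]]:
    """Classify a population of cells, averaging repeated sessions per cell.

    ``sessions`` is one ``(times, matrix)`` pair or a list of such pairs
    recorded under the same condition; matrices are (n_samples, n_cells)
    with a shared cell ordering.  Each cell's sessions are aligned to the
    template grid and averaged before classification.
    """
    if isinstance(sessions, tuple):
        sessions = [sessions]
    if not sessions:
        raise ValueError("no sessions supplied")
    stacks = []
    n_cells = None
    for t, mat in sessions:
        mat = np.asarray(mat, dtype=float)
        if mat.ndim != 2 or mat.shape[1] == 0:
            raise ValueError("cell matrix must be 2-D with at least one cell")
        if n_cells is None:
            n_cells = mat.shape[1]
        elif mat.shape[1] != n_cells:
            raise ValueError("sessions disagree on the number of cells")
        stacks.append(
            np.column_stack(
                [align_to_templates(t, mat[:, j], templates) for j in range(n_cells)]
            )
        )
    mean_mat = np.mean(stacks, axis=0)
    if cell_ids is None:
        cell_ids = [f"cell_{j:04d}" for j in range(n_cells)]
    results = [
        classify_cell(templates.abs_time_s, mean_mat[:, j], templates, family_alpha, cid)
        for j, cid in zip(range(n_cells), cell_ids)
    ]
    labels = [r.glucose_class for r in results]
    prevalence = {
        k: labels.count(k) / len(labels) for k in (*GLUCOSE_CLASSES, NO_RESPONSE)
    }
    return results, prevalence


def classify_running(
    cell_trace,
    speed,
    cell_id: str = "cell",
    alpha: float = 0.05,
    rho_min: float = 0.01,
) -> RunningCorrelationResult:
    """Spearman correlation of a cell with running speed over a session.

    positive: p < alpha and rho > rho_min; negative: p < alpha and
    rho < -rho_min; otherwise none.
    """
    y = np.asarray(cell_trace, dtype=float)
    s = np.asarray(speed, dtype=float)
    if y.size != s.size:
        raise ValueError("trace and speed must share a grid")
    if np.std(y) <= 1e-12 or np.std(s) <= 1e-12:
        return RunningCorrelationResult(cell_id, float("nan"), float("nan"), "none", True)
    rho, p = stats.spearmanr(y, s)
    if p < alpha and rho > rho_min:
        label = "positive"
    elif p < alpha and rho < -rho_min:
        label = "negative"
    else:
        label = "none"
    return RunningCorrelationResult(cell_id, float(rho), float(p), label)


def crosstab_multiplex(glucose_classes, running_classes) -> MultiplexTable:
    """Joint table of glucose class x running class and multiplexed fraction.

    A cell multiplexes when it has both a non-N/A glucose class and a
    non-none running class.
    """
    g = list(glucose_classes)
    r = list(running_classes)
    if len(g) != len(r) or not g:
        raise ValueError("glucose and running class lists must match and be non-empty")
    g_order = [*GLUCOSE_CLASSES, NO_RESPONSE]
    counts = pd.crosstab(
        pd.Categorical(g, categories=g_order),
        pd.Categorical(r, categories=list(RUNNING_CLASSES)),
        dropna=False,
    )
    counts.index.name = "glucose_class"
    counts.columns.name = "running_class"
    fractions = counts / len(g)
    multiplexed = sum(
        1 for gi, ri in zip(g, r) if gi != NO_RESPONSE and ri != "none"
    ) / len(g)
    return MultiplexTable(counts, fractions, float(multiplexed), len(g))


def reconstruct_population(
    templates: TemplateSet,
    prevalences: dict[str, float],
    amplitudes: dict[str, float] | None = None,
) -> PopulationReconstruction:
    """Prevalence- and amplitude-weighted sum of the class templates."""
    if amplitudes is None:
        amplitudes = {k: 1.0 for k in GLUCOSE_CLASSES}
    for k, v in prevalences.items():
        if v < 0:
            raise ValueError(f"negative prevalence for {k!r}")
    recon = np.zeros_like(templates.time_min, dtype=float)
    for k in GLUCOSE_CLASSES:
        recon += prevalences.get(k, 0.0) * amplitudes.get(k, 1.0) * templates.waveforms[k]
    return PopulationReconstruction(
        prevalences=dict(prevalences),
        amplitudes=dict(amplitudes),
        time_min=templates.time_min.copy(),
        reconstructed=recon,
    )
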