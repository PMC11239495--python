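"""Linear encoding model with bootstrap leave-one-predictor-out deltaR2.

Population activity is predicted from five physiological predictors
(running, blood glucose, body temperature, VO2, VCO2) and their first
time derivatives — ten z-scored columns on a common 1-min grid.  Each
bootstrap iteration splits the session into contiguous quarter-duration
chunks at a random phase (so temporal autocorrelation stays inside
folds), assigns chunks at random to 70% training / 30% validation, fits
the full ordinary-least-squares model and the ten partial models (each
missing one predictor) on the training rows, and evaluates the
coefficient of determination on the validation rows.  A predictor's
deltaR2 is the drop in validation R2 when it is removed, clipped at zero;
relative contributions normalize the median deltaR2 values to percent of
their sum.

A leave-one-session-out mode cross-checks the bootstrap on multi-session
data: each session in turn is held out as the validation set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import savgol
from .temporal import finite_derivative

BASE_PREDICTORS = ("running", "glucose", "temperature", "vo2", "vco2")
PREDICTOR_ORDER = tuple(list(BASE_PREDICTORS) + [f"d_{p}" for p in BASE_PREDICTORS])


@dataclass
class BootstrapSpec:
    chunk_fraction: float = 0.25
    iterations: int = 2000
    train_fraction: float = 0.7
    seed: int = 0
    mode: str = "chunk_bootstrap"     # or "leave_one_session_out"

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class EncodingFit:
    predictor_names: tuple
    r2_full: np.ndarray               # per iteration
    r2_partial: np.ndarray            # iterations x predictors
    delta_r2: np.ndarray              # iterations x predictors, clipped at 0
    delta_r2_median: np.ndarray
    relative_contribution: np.ndarray  # percent, per predictor
    relative_contribution_mean: np.ndarray
    coefficients: np.ndarray          # median full-model weights
    collinearity_matrix: np.ndarray
    all_zero: bool = False
    provenance: dict = field(default_factory=dict)


def _block_mean(x: np.ndarray, per: int) -> np.ndarray:
    nb = x.size // per
    return x[: nb * per].reshape(nb, per).mean(axis=1)


def _zscore_named(x: np.ndarray, name: str) -> np.ndarray:
    sd = np.std(x)
    if sd <= 1e-12:
        raise ValueError(f"constant column: {name}")
    return (x - np.mean(x)) / sd


def build_predictors(session, bin_s: float = 60.0) -> tuple[pd.DataFrame, np.ndarray]:
    """Predictor matrix and response on a common 1-min grid.

    Each channel is block-averaged to ``bin_s``, Savitzky-Golay filtered
    (first order, five samples), differentiated (derivative columns,
    per-minute units) and z-scored; the response (activity) receives the
    same conditioning.  Column order is fixed: the five base predictors
    followed by their derivatives.
    """
    per = int(round(bin_s * session.rate))
    channels = {
        "running": session.running,
        "glucose": session.glucose,
        "temperature": session.temperature,
        "vo2": session.vo2,
        "vco2": session.vco2,
    }
    n_bins = session.time.size // per
    if n_bins < 20:
        raise ValueError("session must cover at least 20 minutes")
    cols = {}
    for name, x in channels.items():
        b = savgol(_block_mean(np.asarray(x, dtype=float), per))
        cols[name] = b
        cols[f"d_{name}"] = finite_derivative(b, bin_s)
    X = pd.DataFrame(
        {name: _zscore_named(cols[name], name) for name in PREDICTOR_ORDER}
    )
    yb = savgol(_block_mean(np.asarray(session.activity, dtype=float), per))
    y = _zscore_named(yb, "activity")
    return X, y


def fit_linear(X, y, rows=None) -> np.ndarray:
    """OLS with intercept on the selected rows; errors on rank deficiency.

    Returns ``[intercept, beta_1, ..., beta_p]``.
    """
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float)
    if rows is not None:
        Xa, ya = Xa[rows], ya[rows]
    if Xa.shape[0] < Xa.shape[1] + 2:
        raise ValueError("need at least p + 2 rows")
    D = np.column_stack([np.ones(Xa.shape[0]), Xa])
    beta, _, rank, _ = np.linalg.lstsq(D, ya, rcond=None)
    if rank < D.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design matrix")
    return beta


def r_squared(y, yhat) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot (may be negative)."""
    ya = np.asarray(y, dtype=float)
    ph = np.asarray(yhat, dtype=float)
    if ya.size != ph.size or ya.size < 2:
        raise ValueError("need equal-length series with n >= 2")
    ss_tot = float(np.sum((ya - ya.mean()) ** 2))
    if ss_tot <= 0.0:
        raise ValueError("zero-variance response")
    return 1.0 - float(np.sum((ya - ph) ** 2)) / ss_tot


def _ols_beta(D: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.linalg.lstsq(D, y, rcond=None)[0]


def _chunks(n: int, chunk_len: int, phase: int) -> list[np.ndarray]:
    edges = [0]
    e = phase if phase > 0 else chunk_len
    while e < n:
        edges.append(e)
        e += chunk_len
    edges.append(n)
    return [np.arange(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]


def bootstrap_contributions(X, y, spec: BootstrapSpec | None = None) -> EncodingFit:
    """Chunked-bootstrap leave-one-predictor-out contribution analysis."""
    spec = spec or BootstrapSpec()
    names = tuple(X.columns) if isinstance(X, pd.DataFrame) else tuple(
        f"x{j}" for j in range(np.asarray(X).shape[1])
    )
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float)
    n, p = Xa.shape
    chunk_len = max(1, int(round(n * spec.chunk_fraction)))
    if n // chunk_len < 2:
        raise ValueError("fewer than 2 chunks at this chunk size")
    rng = np.random.default_rng(spec.seed)
    D = np.column_stack([np.ones(n), Xa])

    r2_full = np.full(spec.iterations, np.nan)
    r2_partial = np.full((spec.iterations, p), np.nan)
    betas = np.full((spec.iterations, p + 1), np.nan)
    keep = [np.r_[0, 1 + np.delete(np.arange(p), j)] for j in range(p)]
    for it in range(spec.iterations):
        phase = int(rng.integers(0, chunk_len))
        chunks = _chunks(n, chunk_len, phase)
        order = rng.permutation(len(chunks))
        train_rows, val_rows, n_train = [], [], 0
        for ci in order:
            if n_train < spec.train_fraction * n:
                train_rows.append(chunks[ci])
                n_train += chunks[ci].size
            else:
                val_rows.append(chunks[ci])
        if not val_rows:   # degenerate split: move the last train chunk over
            val_rows.append(train_rows.pop())
        tr = np.concatenate(train_rows)
        va = np.concatenate(val_rows)
        yva = ya[va]
        if np.std(yva) <= 1e-12:
            continue
        ss_tot = float(np.sum((yva - yva.mean()) ** 2))
        beta = _ols_beta(D[tr], ya[tr])
        betas[it] = beta
        r2_full[it] = 1.0 - float(np.sum((yva - D[va] @ beta) ** 2)) / ss_tot
        for j in range(p):
            bj = _ols_beta(D[tr][:, keep[j]], ya[tr])
            r2_partial[it, j] = (
                1.0 - float(np.sum((yva - D[va][:, keep[j]] @ bj) ** 2)) / ss_tot
            )

    delta = np.clip(r2_full[:, None] - r2_partial, 0.0, None)
    med = np.nanmedian(delta, axis=0)
    mean = np.nanmean(delta, axis=0)
    total = med.sum()
    # contributions are meaningless when the full model explains nothing
    # out of sample (or when every clipped deltaR2 is zero): flag and zero
    all_zero = bool(total <= 0.0 or np.nanmedian(r2_full) <= 0.0)
    contrib = np.zeros(p) if all_zero else 100.0 * med / total
    contrib_mean = (
        np.zeros(p) if mean.sum() <= 0 else 100.0 * mean / mean.sum()
    )
    return EncodingFit(
        predictor_names=names,
        r2_full=r2_full,
        r2_partial=r2_partial,
        delta_r2=delta,
        delta_r2_median=med,
        relative_contribution=contrib,
        relative_contribution_mean=contrib_mean,
        coefficients=np.nanmedian(betas, axis=0),
        collinearity_matrix=np.corrcoef(Xa.T),
        all_zero=all_zero,
        provenance={
            "mode": "chunk_bootstrap",
            "chunk_fraction": spec.chunk_fraction,
            "iterations": spec.iterations,
            "train_fraction": spec.train_fraction,
            "seed": spec.seed,
            "zscore": "per-column, before chunk selection",
            "derivatives": "after Savitzky-Golay filtering",
        },
    )


def leave_one_session_out(sessions_Xy) -> EncodingFit:
    """Cross-validated contributions with whole sessions as folds.

    ``sessions_Xy`` is a list of ``(X, y)`` pairs (as produced by
    :func:`build_predictors`, one per session); each session in turn is
    the validation set while the model trains on the others.
    """
    if len(sessions_Xy) < 2:
        raise ValueError("need at least 2 sessions")
    names = tuple(sessions_Xy[0][0].columns)
    mats = [(np.asarray(X, dtype=float), np.asarray(y, dtype=float)) for X, y in sessions_Xy]
    p = mats[0][0].shape[1]
    k = len(mats)
    r2_full = np.full(k, np.nan)
    r2_partial = np.full((k, p), np.nan)
    keep = [np.r_[0, 1 + np.delete(np.arange(p), j)] for j in range(p)]
    for i in range(k):
        Xtr = np.vstack([m[0] for j, m in enumerate(mats) if j != i])
        ytr = np.concatenate([m[1] for j, m in enumerate(mats) if j != i])
        Xva, yva = mats[i]
        Dtr = np.column_stack([np.ones(Xtr.shape[0]), Xtr])
        Dva = np.column_stack([np.ones(Xva.shape[0]), Xva])
        ss_tot = float(np.sum((yva - yva.mean()) ** 2))
        beta = _ols_beta(Dtr, ytr)
        r2_full[i] = 1.0 - float(np.sum((yva - Dva @ beta) ** 2)) / ss_tot
        for j in range(p):
            bj = _ols_beta(Dtr[:, keep[j]], ytr)
            r2_partial[i, j] = (
                1.0 - float(np.sum((yva - Dva[:, keep[j]] @ bj) ** 2)) / ss_tot
            )
    delta = np.clip(r2_full[:, None] - r2_partial, 0.0, None)
    med = np.nanmedian(delta, axis=0)
    total = med.sum()
    all_zero = bool(total <= 0.0 or np.nanmedian(r2_full) <= 0.0)
    X_all = np.vstack([m[0] for m in mats])
    return EncodingFit(
        predictor_names=names,
        r2_full=r2_full,
        r2_partial=r2_partial,
        delta_r2=delta,
        delta_r2_median=med,
        relative_contribution=np.zeros(p) if all_zero else 100.0 * med / total,
        relative_contribution_mean=np.zeros(p)
        if all_zero
        else 100.0 * np.nanmean(delta, axis=0) / max(np.nanmean(delta, axis=0).sum(), 1e-300),
        coefficients=np.full(p + 1, np.nan),
        collinearity_matrix=np.corrcoef(X_all.T),
        all_zero=all_zero,
        provenance={"mode": "leave_one_session_out", "n_sessions": k},
    )


def rank_contributions(fit: EncodingFit) -> list[tuple[str, float]]:
    """Predictors in descending contribution order; name breaks ties."""
    pairs = list(zip(fit.predictor_names, fit.relative_contribution))
    return sorted(pairs, key=lambda kv: (-kv[1], kv[0]))
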