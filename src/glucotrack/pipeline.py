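"""End-to-end pipeline orchestration: simulate -> analyze -> report.

A :class:`PipelineConfig` fixes the generator settings, analysis options
and seed; :func:`run_pipeline` runs the stages in dependency order and
assembles an analysis report whose every number is a pure function of
(config, seed).  Templates for single-cell classification are built from
a held-out session (a separate seed stream with the same glucose
parameters) so the classified cells never see their own template source.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import classify, encoding, temporal
from .io import _jsonable, write_cells, write_session
from .simulate import SimConfig, simulate_session


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str | None = None
    sim: dict = field(default_factory=dict)      # SimConfig field overrides
    encode_iterations: int = 200
    family_alpha: float = 0.001
    max_lag_s: float = 600.0
    stages: tuple = ("simulate", "temporal", "encode", "classify")

    def sim_config(self, seed: int) -> SimConfig:
        valid = {f.name for f in dataclasses.fields(SimConfig)}
        unknown = set(self.sim) - valid
        if unknown:
            raise ValueError(f"unknown simulation fields: {sorted(unknown)}")
        return SimConfig(seed=seed, **self.sim)


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the requested stages and return the analysis report dict."""
    seeds = _child_seeds(config.seed, 3)
    sim_cfg = config.sim_config(seeds[0])
    session, cell_time, cells, truth = simulate_session(sim_cfg)
    report: dict = {
        "config": _jsonable(dataclasses.asdict(config)),
        "seeds": {"session": seeds[0], "templates": seeds[1], "bootstrap": seeds[2]},
        "simulate": {
            "n_samples": int(session.time.size),
            "n_cells": int(cells.shape[1]),
            "events": [[label, t] for label, t in session.events],
        },
    }
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        write_session(session, out_dir / "session.csv")
        write_cells(cell_time, cells, out_dir / "cells.csv", truth)

    infusion = session.infusion_time()
    rate = session.rate
    if "temporal" in config.stages and infusion is not None:
        base_win = (infusion - 1200.0, infusion)
        dglucose = temporal.finite_derivative(session.glucose, 1.0 / rate)
        xc_g = temporal.lag_crosscorr(
            session.glucose, session.activity, rate, config.max_lag_s
        )
        xc_dg = temporal.lag_crosscorr(
            dglucose, session.activity, rate, config.max_lag_s
        )
        fit_g = temporal.linfit(session.glucose, session.activity)
        fit_dg = temporal.linfit(dglucose, session.activity)
        try:
            bounds = temporal.detect_transient(session.time, session.glucose, base_win)
            loop_g = temporal.hysteresis_loop(
                session.time, session.activity, session.glucose, bounds
            )
            loop_dg = temporal.hysteresis_loop(
                session.time, session.activity, dglucose, bounds
            )
            transient = {
                "t_start_s": bounds[0],
                "t_end_s": bounds[1],
                "area_vs_glucose": loop_g.signed_area,
                "area_vs_derivative": loop_dg.signed_area,
                "n_points": int(loop_g.points.shape[0]),
            }
        except temporal.NoTransientError:
            transient = None
        epochs = temporal.epoch_means(session.time, session.activity, infusion)
        bouts = temporal.detect_bouts(session.running, rate, sim_cfg.speed_threshold)
        ee = temporal.weir_ee(session.vo2, session.vco2)
        report["temporal"] = {
            "peak_lag_vs_glucose_s": xc_g.peak_lag,
            "peak_r_vs_glucose": xc_g.peak_r,
            "peak_lag_vs_derivative_s": xc_dg.peak_lag,
            "peak_r_vs_derivative": xc_dg.peak_r,
            "linfit_vs_glucose": {"slope": fit_g.slope, "r_squared": fit_g.r_squared,
                                  "p": fit_g.p_slope},
            "linfit_vs_derivative": {"slope": fit_dg.slope, "r_squared": fit_dg.r_squared,
                                     "p": fit_dg.p_slope},
            "transient": transient,
            "epoch_means": epochs.means,
            "epoch_diffs": epochs.paired_diffs,
            "bouts": {"count": bouts.count, "mean_duration_s": bouts.mean_duration,
                      "mean_speed_cms": bouts.mean_speed},
            "mean_energy_expenditure_kcal_min": float(np.mean(ee)),
        }

    if "encode" in config.stages:
        X, y = encoding.build_predictors(session)
        spec = encoding.BootstrapSpec(iterations=config.encode_iterations, seed=seeds[2])
        fit = encoding.bootstrap_contributions(X, y, spec)
        report["encode"] = {
            "ranking": encoding.rank_contributions(fit),
            "contributions_pct": dict(
                zip(fit.predictor_names, fit.relative_contribution)
            ),
            "median_r2_full": float(np.nanmedian(fit.r2_full)),
            "all_zero": fit.all_zero,
            "max_abs_predictor_correlation": float(
                np.max(np.abs(fit.collinearity_matrix - np.eye(len(fit.predictor_names))))
            ),
        }

    if "classify" in config.stages and infusion is not None:
        tmpl_cfg = dataclasses.replace(sim_cfg, seed=seeds[1], n_cells=1)
        tmpl_session, _, _, _ = simulate_session(tmpl_cfg)
        templates = classify.build_templates(
            tmpl_session.time, tmpl_session.glucose, infusion
        )
        results, prevalence = classify.classify_batch(
            (cell_time, cells), templates, config.family_alpha
        )
        running_5hz = np.interp(cell_time, session.time, session.running)
        run_results = [
            classify.classify_running(cells[:, j], running_5hz, r.cell_id)
            for j, r in enumerate(results)
        ]
        table = classify.crosstab_multiplex(
            [r.glucose_class for r in results], [r.running_class for r in run_results]
        )
        recon = classify.reconstruct_population(templates, prevalence)
        idg = templates.waveforms["idG"]
        recon_r = (
            float(np.corrcoef(recon.reconstructed, idg)[0, 1])
            if np.std(recon.reconstructed) > 1e-12
            else float("nan")
        )
        report["classify"] = {
            "prevalence": prevalence,
            "running_prevalence": {
                k: sum(1 for r in run_results if r.running_class == k) / len(run_results)
                for k in classify.RUNNING_CLASSES
            },
            "multiplexed_fraction": table.multiplexed_fraction,
            "reconstruction_corr_with_idG": recon_r,
            "truth_accuracy": float(
                np.mean(
                    [r.glucose_class == lab for r, lab in zip(results, truth.cell_labels)]
                )
            ),
        }

    if out_dir:
        with open(out_dir / "report.json", "w") as fh:
            json.dump(_jsonable(report), fh, indent=1, sort_keys=True)
    return report


def report_hash(report: dict) -> str:
    """Deterministic digest of a report for reproducibility checks."""
    blob = json.dumps(_jsonable(report), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()
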