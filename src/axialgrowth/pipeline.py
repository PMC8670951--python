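"""End-to-end report assembly: simulate/load -> summarize -> allometry ->
gradient models -> tabular + JSON outputs."""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .allometry import (format_stage_set, hinge_bootstrap_ci, hinge_fit,
                        segment_coefficient_profile, stage_for_size,
                        standardize_changepoint_to_bol)
from .data_model import (HOLASPID, MERASPID, derived_value, load_specimens,
                         save_specimens, stage_summaries, summaries_to_rows)
from .growth_gradients import (ALL_MODELS, GradientObservations, SG_MODELS,
                               compare_models, fit_gradient_model,
                               pyl_stasis_test)
from .synthetic_data import SimulationConfig, simulate_ontogeny

log = logging.getLogger("axialgrowth")

#: Hinge model pairs fitted by default: (response, predictor).
DEFAULT_THRESHOLD_PAIRS = (
    ("TRL", "BOL"), ("CEL", "BOL"), ("FAL", "CEL"), ("PGL", "CEL"),
    ("LTS1", "TRL"), ("LTS2", "TRL"), ("LTS3", "TRL"),
)


@dataclass
class PipelineConfig:
    """Run configuration; seeds are recorded in every output."""

    input_csv: Optional[str] = None
    simulation: Optional[SimulationConfig] = None
    seed: int = 0
    boot_reps: int = 1000
    response: str = "RLS"
    gradient_models: Sequence[str] = ALL_MODELS
    threshold_pairs: Sequence = DEFAULT_THRESHOLD_PAIRS
    run_allometry: bool = True
    run_gradients: bool = True
    gradient_stages: tuple = (1, 12)
    out_dir: str = "report"


def _sig(value, digits: int = 6):
    """Round to significant digits for stable serialized output."""
    if value is None or isinstance(value, (str, int, bool)):
        return value
    if isinstance(value, float):
        if not math.isfinite(value) or value == 0.0:
            return value
        return float(f"{value:.{digits}g}")
    return value


def _round_df(df: pd.DataFrame) -> pd.DataFrame:
    return df.map(_sig)


def _log_lengths(specimens, response: str, predictor: str):
    xs, ys = [], []
    for s in specimens:
        yv = derived_value(s, response)
        xv = derived_value(s, predictor)
        if yv is not None and xv is not None:
            xs.append(math.log(xv))
            ys.append(math.log(yv))
    return np.asarray(xs), np.asarray(ys)


def threshold_table(specimens, pairs=DEFAULT_THRESHOLD_PAIRS, *,
                    boot_reps: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Fit hinge models and assemble the change-point table.

    CEL- and TRL-scale change points are also standardized to the BOL scale
    through reference hinge fits of BOL on the same predictor; the stage
    column lists the degrees whose size range contains the change point.
    """
    references = {}
    for pred in ("CEL", "TRL"):
        x, y = _log_lengths(specimens, "BOL", pred)
        if len(x) >= 8:
            try:
                references[pred] = hinge_fit(x, y, response="BOL",
                                             predictor=pred)
            except ValueError as exc:
                log.warning("reference fit BOL~%s failed: %s", pred, exc)

    rows = []
    for resp, pred in pairs:
        x, y = _log_lengths(specimens, resp, pred)
        try:
            fit = hinge_fit(x, y, response=resp, predictor=pred)
        except ValueError as exc:
            log.warning("hinge fit %s~%s skipped: %s", resp, pred, exc)
            continue
        try:
            fit.ci_mm = hinge_bootstrap_ci(x, y, reps=boot_reps, seed=seed)
        except RuntimeError as exc:
            log.warning("bootstrap CI for %s~%s failed: %s", resp, pred, exc)
        cp = fit.changepoint_mm
        if pred == "BOL":
            bol_cp = cp
        elif pred in references:
            try:
                bol_cp = standardize_changepoint_to_bol(cp, references[pred])
            except ValueError:
                bol_cp = None
        else:
            bol_cp = None
        degrees = stage_for_size(cp, pred, specimens)
        hol_max = max((derived_value(s, pred) or -math.inf
                       for s in specimens if s.period == HOLASPID),
                      default=-math.inf)
        meraspid_max = max((derived_value(s, pred) or -math.inf
                            for s in specimens if s.period == MERASPID),
                           default=-math.inf)
        in_holaspid_range = cp > meraspid_max and cp <= hol_max
        rows.append({
            "model": f"{resp}~{pred}",
            "change_point_mm": cp,
            "bol_change_point_mm": bol_cp,
            "stage": format_stage_set(degrees, holaspid=in_holaspid_range),
            "pre_AC": fit.slope_pre,
            "post_AC": fit.slope_post,
            "ci_low_mm": None if fit.ci_mm is None else fit.ci_mm[0],
            "ci_high_mm": None if fit.ci_mm is None else fit.ci_mm[1],
            "n": fit.n,
        })
        log.info("hinge %s~%s: cp=%.3f mm, pre=%.2f, post=%.2f",
                 resp, pred, cp, fit.slope_pre, fit.slope_post)
    return pd.DataFrame(rows)


def coefficient_profile_table(specimens, *, boot_reps: int = 200,
                              seed: int = 0) -> pd.DataFrame:
    """MA allometric coefficients per part for both periods."""
    rows = []
    for period in (MERASPID, HOLASPID):
        try:
            fits = segment_coefficient_profile(
                specimens, period, boot_reps=boot_reps, seed=seed)
        except ValueError as exc:
            log.warning("coefficient profile (%s) skipped: %s", period, exc)
            continue
        for f in fits:
            rows.append({
                "part": f.response, "predictor": f.predictor,
                "period": f.period, "coefficient": f.slope,
                "ci_low": f.ci[0], "ci_high": f.ci[1], "n": f.n,
            })
    return pd.DataFrame(rows)


def gradient_comparison_table(specimens, *, response: str = "RLS",
                              models: Sequence[str] = ALL_MODELS,
                              stages: tuple = (1, 12)) -> pd.DataFrame:
    """Fit the requested gradient models on stage means and compare by AICc."""
    summaries = stage_summaries(specimens,
                                degrees=range(stages[0], stages[1] + 1))
    obs = GradientObservations.from_summaries(summaries, response=response)
    fits = []
    for name in models:
        if name in SG_MODELS and response != "RLS":
            log.info("skipping %s: requires RLS response", name)
            continue
        fit = fit_gradient_model(name, obs)
        log.info("gradient %s: RSS=%.3g, converged %d/%d starts",
                 name, fit.rss, fit.n_converged, fit.n_starts)
        fits.append(fit)
    if len(fits) < 2:
        raise ValueError("fewer than two gradient models could be fitted")
    return compare_models(fits)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all enabled stages and write the report bundle.

    Returns the JSON manifest (also written to ``manifest.json``); outputs
    are deterministic for fixed seeds and carry no timestamps.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "axialgrowth",
        "version": __version__,
        "seed": cfg.seed,
        "boot_reps": cfg.boot_reps,
        "response": cfg.response,
        "outputs": {},
        "warnings": [],
    }

    if cfg.input_csv is not None:
        loaded = load_specimens(cfg.input_csv)
        specimens = loaded.specimens
        manifest["input"] = {"path": str(cfg.input_csv),
                             "n_loaded": len(loaded),
                             "n_rejected": len(loaded.warnings)}
        manifest["warnings"].extend(loaded.warnings)
    else:
        sim = cfg.simulation or SimulationConfig(seed=cfg.seed)
        specimens = simulate_ontogeny(sim)
        sim_path = out / "specimens.csv"
        save_specimens(specimens, sim_path)
        manifest["input"] = {"simulated": sim.to_dict(),
                             "n_generated": len(specimens)}
        manifest["outputs"]["specimens"] = sim_path.name
    log.info("dataset: %d specimens", len(specimens))

    summaries = stage_summaries(specimens)
    summary_df = _round_df(pd.DataFrame(summaries_to_rows(summaries)))
    summary_path = out / "stage_summary.csv"
    summary_df.to_csv(summary_path, index=False)
    manifest["outputs"]["stage_summary"] = summary_path.name

    if cfg.run_allometry:
        thr = _round_df(threshold_table(
            specimens, cfg.threshold_pairs, boot_reps=cfg.boot_reps,
            seed=cfg.seed))
        thr_path = out / "threshold_table.csv"
        thr.to_csv(thr_path, index=False)
        manifest["outputs"]["threshold_table"] = thr_path.name

        prof = _round_df(coefficient_profile_table(
            specimens, boot_reps=min(cfg.boot_reps, 200), seed=cfg.seed))
        prof_path = out / "coefficient_profile.csv"
        prof.to_csv(prof_path, index=False)
        manifest["outputs"]["coefficient_profile"] = prof_path.name

    if cfg.run_gradients:
        comp = _round_df(gradient_comparison_table(
            specimens, response=cfg.response, models=cfg.gradient_models,
            stages=cfg.gradient_stages))
        comp_path = out / "model_comparison.csv"
        comp.to_csv(comp_path, index=False)
        manifest["outputs"]["model_comparison"] = comp_path.name

        stasis = pyl_stasis_test(specimens, (0, 10))
        manifest["pygidial_stasis"] = {
            "slope": _sig(stasis.slope), "t": _sig(stasis.t_statistic),
            "p": _sig(stasis.p_value), "n": stasis.n,
            "stage_range": "D0-D10",
        }

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("report written to %s", out)
    return manifest
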