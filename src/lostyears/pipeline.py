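"""End-to-end pipeline: simulate -> preprocess -> pseudoabs -> covariates ->
fit -> predict -> report.

Each stage consumes the previous stage's products, writes its artifacts under
the output directory, and contributes to a run log that records per-stage row
attrition (tracks in -> usable tracks -> segments -> CRW replicates kept),
so a run can be audited the way a tracking study reports its data filtering.
Stage failures abort with the failing stage named; partial outputs are kept.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from lostyears import covariates as cov
from lostyears import habitat_model as hm
from lostyears import io as lio
from lostyears import prediction_mapping as pm
from lostyears import pseudo_absence as pa
from lostyears import synthetic_data as sd
from lostyears import track_processing as tp
from lostyears.config import PipelineConfig

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline failed in stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


def _class_errors(config: PipelineConfig) -> dict:
    errs = dict(tp.DEFAULT_CLASS_ERRORS_DEG)
    errs["GL"] = tuple(config.geolocator_error_deg)
    return errs


# ---------------------------------------------------------------------------
# stages (each usable on its own)
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig):
    """Synthetic ocean + telemetry with the planted preference."""
    domain = sd.SyntheticDomain(
        lon_min=config.domain_lon[0], lon_max=config.domain_lon[1],
        lat_min=config.domain_lat[0], lat_max=config.domain_lat[1],
        grid_step=config.grid_step, start=config.start_date, n_days=config.n_days)
    seed = config.child_seed("simulate")
    stack = sd.gen_environment(domain, n_eddies=config.n_eddies, seed=seed)
    cov.add_derived_fields(stack, sd_window_days=config.sd_window_days,
                           rugosity_window=config.rugosity_window)
    truth = sd.default_truth()
    tracks = sd.gen_tracks(stack, truth, n_tracks=config.n_tracks, seed=seed + 1)
    return stack, truth, tracks


def preprocess_track(raw: tp.RawTrack, stack, config: PipelineConfig) -> list[tp.TrackSegment]:
    """Raw fixes -> daily land-free presence segments for one animal."""
    filtered = tp.prefilter_speed(raw, v_max=config.v_max_mps)
    regular = tp.regularize(filtered, dt_hours=config.dt_hours, v_max=config.v_max_mps,
                            class_errors=_class_errors(config))
    regular = tp.reroute_on_land(regular, stack)
    segs = tp.segment(regular, filtered, gap_days=config.gap_days,
                      min_len=config.min_segment_len)
    segs = tp.trim_release(segs, raw.release_from_shore, trim_days=config.trim_days,
                           min_len=config.min_segment_len)
    if segs and len(regular.data) >= config.mpm_window_days:
        series = tp.move_persistence(regular, window_days=config.mpm_window_days)
        segs = tp.exclude_migration(segs, series, gamma_thresh=config.mpm_gamma_thresh,
                                    heading_sector=config.mpm_heading_sector,
                                    min_run_days=config.mpm_min_run_days,
                                    min_len=config.min_segment_len)
    return segs


def stage_preprocess(tracks, stack, config: PipelineConfig):
    segments = []
    n_unusable = 0
    for raw in tracks:
        try:
            segments.extend(preprocess_track(raw, stack, config))
        except ValueError as e:
            n_unusable += 1
            log.warning("track %s unusable: %s", raw.track_id, e)
    attrition = {
        "tracks_in": len(tracks),
        "tracks_unusable": n_unusable,
        "tracks_with_segments": len({s.track_id for s in segments}),
        "segments": len(segments),
        "presence_days": int(sum(len(s) for s in segments)),
    }
    return segments, attrition


def stage_pseudoabs(segments, stack, config: PipelineConfig):
    seed = config.child_seed("pseudoabs")
    kept_all = []
    n_sim = 0
    counts_total = {"removed_speed": 0, "removed_missing_current": 0}
    for seg in segments:
        dist = pa.empirical_steps(seg)
        if dist.degenerate:
            log.warning("segment %s skipped for CRWs: stationary", seg.segment_id)
            continue
        reps = pa.simulate_crw(seg, dist, n_rep=config.n_rep, stack=stack, seed=seed)
        n_sim += len(reps)
        kept, counts = pa.filter_crw(reps, stack, v_active_max=config.v_active_max_mps)
        kept_all.extend(kept)
        for k in counts_total:
            counts_total[k] += counts[k]
    attrition = {"crw_simulated": n_sim, "crw_kept": len(kept_all), **counts_total}
    return kept_all, attrition


def stage_covariates(segments, pseudo, stack):
    return cov.build_observation_table(segments, pseudo, stack)


def stage_fit(table: pd.DataFrame, config: PipelineConfig):
    seed = config.child_seed("fit")
    extras = {}
    if config.run_ratio_experiment:
        best_ratio, ratio_report = hm.ratio_experiment(
            table, ratios=config.ratio_grid, seed=seed,
            cv_folds=config.cv_folds, step_size=config.step_size,
            max_trees=config.max_trees)
        extras["ratio_report"] = ratio_report
        ratio = best_ratio
    else:
        ratio = config.ratio
    if config.run_grid_search:
        best_cfg, board = hm.grid_search(
            table, lr_grid=config.lr_grid, tc_grid=config.tc_grid, ratio=ratio,
            seed=seed, cv_folds=config.cv_folds, step_size=config.step_size,
            max_trees=config.max_trees)
        extras["leaderboard"] = board
        lr, tc = best_cfg.learning_rate, best_cfg.tree_complexity
    else:
        lr, tc = config.learning_rate, config.tree_complexity
    data = hm.assemble_dataset(table, ratio, seed=seed)
    brt_cfg = hm.BRTConfig(learning_rate=lr, tree_complexity=tc,
                           bag_fraction=config.bag_fraction, seed=seed)
    model = hm.fit_brt(data, brt_cfg, step_size=config.step_size,
                       cv_folds=config.cv_folds, max_trees=config.max_trees)
    report = hm.evaluate_all(model, data, seed=seed, regimes=config.eval_regimes)
    influence = hm.relative_influence(model)
    return model, data, report, influence, extras


def stage_predict(model, stack, config: PipelineConfig):
    dates = stack.dates[:: max(1, config.predict_every_n_days)]
    cube = pm.predict_daily(model, stack, dates=dates)
    threshold = pm.persistence_threshold(cube, floor=config.persistence_floor,
                                         q=config.persistence_quantile)
    seasonal = pm.seasonal_mean(cube)
    maps = pm.persistence(cube, threshold, by_season=True)
    return cube, threshold, seasonal, maps


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, out_dir, write_stack: bool = False) -> dict:
    """Execute the full pipeline on the synthetic ocean and write the bundle.

    Returns a dict of in-memory artifacts (stack, truth, segments, model,
    cube, ...). Every stage writes its outputs plus a JSON provenance record
    under ``out_dir``; a failure raises :class:`StageError` naming the stage
    and leaves earlier outputs in place.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {s: config.child_seed(s) for s in
             ("simulate", "preprocess", "pseudoabs", "fit", "predict")}
    artifacts: dict = {}
    run_log: dict = {}

    def run_stage(name, fn):
        try:
            return fn()
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001 - stage boundary
            raise StageError(name, e) from e

    def _simulate():
        stack, truth, tracks = stage_simulate(config)
        lio.write_tracks(tracks, out / "tracks.csv")
        lio.write_eddies(stack.eddies, out / "eddies.csv")
        if write_stack:
            lio.write_stack(stack, out / "stack.nc")
        return stack, truth, tracks

    stack, truth, tracks = run_stage("simulate", _simulate)
    artifacts.update(stack=stack, truth=truth, tracks=tracks)

    def _preprocess():
        segments, attrition = stage_preprocess(tracks, stack, config)
        lio.write_segments(segments, out / "segments.csv")
        return segments, attrition

    segments, attr_pre = run_stage("preprocess", _preprocess)
    run_log["preprocess"] = attr_pre
    artifacts["segments"] = segments

    def _pseudoabs():
        pseudo, attrition = stage_pseudoabs(segments, stack, config)
        lio.write_pseudo(pseudo, out / "pseudo.csv")
        return pseudo, attrition

    pseudo, attr_pa = run_stage("pseudoabs", _pseudoabs)
    run_log["pseudoabs"] = attr_pa
    artifacts["pseudo"] = pseudo

    def _covariates():
        table = stage_covariates(segments, pseudo, stack)
        table.to_csv(out / "observations.csv", index=False, float_format="%.8f")
        units = {v: stack.units.get(v, "") for v in cov.MODEL_VARIABLES}
        units["dist_cyclonic"] = units["dist_anticyclonic"] = "dimensionless"
        (out / "observations_units.json").write_text(json.dumps(units, indent=2))
        return table

    table = run_stage("covariates", _covariates)
    run_log["covariates"] = {"rows": len(table),
                             "presence_rows": int((table["label"] == 1).sum())}
    artifacts["table"] = table

    def _fit():
        model, data, report, influence, extras = stage_fit(table, config)
        report.to_csv(out / "evaluation.csv", float_format="%.6f")
        influence.rename("influence_pct").to_csv(out / "influence.csv", float_format="%.4f")
        if "ratio_report" in extras:
            extras["ratio_report"].to_csv(out / "ratio_report.csv", float_format="%.6f")
        if "leaderboard" in extras:
            extras["leaderboard"].to_csv(out / "leaderboard.csv", index=False,
                                         float_format="%.6f")
        return model, data, report, influence

    model, data, report, influence = run_stage("fit", _fit)
    run_log["fit"] = {"rows": len(data), "n_trees": model.config.n_trees}
    artifacts.update(model=model, train_data=data, evaluation=report, influence=influence)

    def _predict():
        cube, threshold, seasonal, maps = stage_predict(model, stack, config)
        grids = {"persistence": maps.overall}
        grids.update({f"persistence_{s}": g for s, g in maps.seasonal.items()})
        grids.update({f"seasonal_mean_{s}": g for s, g in seasonal.items()})
        lio.write_maps(grids, out / "maps.nc")
        summary = pd.DataFrame({
            "quantity": ["persistence_threshold"] + [f"mean_suitability_{s}" for s in pm.SEASONS],
            "value": [threshold] + [float(seasonal[s].mean(skipna=True)) for s in pm.SEASONS],
        })
        summary.to_csv(out / "prediction_summary.csv", index=False, float_format="%.6f")
        return cube, threshold, seasonal, maps

    cube, threshold, seasonal, maps = run_stage("predict", _predict)
    run_log["predict"] = {"days": int(cube.sizes["time"]),
                          "persistence_threshold": threshold}
    artifacts.update(cube=cube, threshold=threshold, seasonal=seasonal, persistence=maps)

    def _report():
        lio.write_provenance(out / "provenance.json", config, "pipeline", seeds, run_log)
        (out / "run_log.json").write_text(json.dumps(run_log, indent=2, sort_keys=True))

    run_stage("report", _report)
    artifacts["run_log"] = run_log
    return artifacts


# ---------------------------------------------------------------------------
# recovery study (the package's flagship validation experiment)
# ---------------------------------------------------------------------------

def recovery_study(seed: int = 1, n_tracks: int = 40, n_days: int = 731,
                   n_rep: int = 100, n_eval_cells: int = 2000,
                   out_dir=None) -> dict:
    """End-to-end planted-preference recovery on the default synthetic ocean.

    Simulates ``n_tracks`` animals over a 30 x 30 deg, 2-year ocean whose
    true preference is a logistic function of SST and bathymetry; runs the
    full pipeline at ratio 1:1, learning rate 0.1, tree complexity 5; and
    measures how well the model recovers the truth:

    * 75/25 held-out AUC;
    * Spearman rank correlation between predicted and true suitability on
      ``n_eval_cells`` random held-out sea cell-days (cells never visited by
      the training data are included);
    * the influence ranks of the two planted driver variables;
    * the realized persistence threshold and maximum observed active speed.
    """
    from scipy.stats import spearmanr

    config = PipelineConfig(master_seed=seed, n_tracks=n_tracks, n_days=n_days,
                            n_rep=n_rep, ratio=1, learning_rate=0.1,
                            tree_complexity=5, predict_every_n_days=7,
                            eval_regimes=("full", "split75"))
    import tempfile
    ctx = tempfile.TemporaryDirectory() if out_dir is None else None
    out = Path(ctx.name) if ctx else Path(out_dir)
    try:
        art = run_pipeline(config, out)
        stack, truth, model = art["stack"], art["truth"], art["model"]
        cube = art["cube"]

        # held-out sea cells: per-cell mean predicted suitability over the
        # prediction days vs the per-cell mean true suitability on the same
        # days (the model never sees cell-center vectors during training)
        rng = np.random.default_rng(seed + 7)
        sea_iy, sea_ix = np.nonzero(stack.sea_mask)
        n_pick = min(n_eval_cells, len(sea_iy))
        pick = rng.choice(len(sea_iy), size=n_pick, replace=False)
        iy, ix = sea_iy[pick], sea_ix[pick]
        lons, lats = stack.lons[ix], stack.lats[iy]
        cube_dates = pd.DatetimeIndex(cube["time"].values)
        true_cells = np.zeros((len(cube_dates), n_pick))
        for k, date in enumerate(cube_dates):
            true_cells[k] = sd._suitability_nocheck(
                stack, truth, lons, lats, np.repeat(date, n_pick))
        true_mean = np.nanmean(true_cells, axis=0)
        pred_mean = np.nanmean(cube.values[:, iy, ix], axis=0)
        ok = np.isfinite(true_mean) & np.isfinite(pred_mean)
        rho = float(spearmanr(pred_mean[ok], true_mean[ok]).statistic)

        influence = art["influence"]
        drivers = [v for v, w in truth.weights.items() if w != 0]
        ranks = {v: int(np.flatnonzero(influence.index == v)[0]) + 1 for v in drivers}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vmax = pa.observed_max_active_speed(art["segments"], stack)
        return {
            "auc_75_25": float(art["evaluation"].loc["split75", "auc"]),
            "auc_full": float(art["evaluation"].loc["full", "auc"]),
            "spearman_pred_true": rho,
            "driver_influence_ranks": ranks,
            "influence": influence,
            "persistence_threshold": float(art["threshold"]),
            "max_active_speed_mps": vmax,
            "n_eval_cells": int(ok.sum()),
            "run_log": art["run_log"],
            "n_trees": int(model.config.n_trees),
        }
    finally:
        if ctx:
            ctx.cleanup()
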