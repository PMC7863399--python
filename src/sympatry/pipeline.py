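"""End-to-end orchestration: simulate a study, run every analysis stage,
write all result tables and rasters.

Stage order matters scientifically: accelerometer classification labels
the canid fixes; per-period/per-state dBBMM occurrence distributions
feed the individual RUFs; deer (prey) surfaces must exist before canid
RUFs; the *wolf* population prediction surface must exist before any
*coyote* RUF is fit, because predicted wolf occurrence enters the coyote
design as an avoidance covariate. Diet and activity-overlap stages are
independent of the spatial chain.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import activity as act
from . import diet as diet_mod
from . import io as sio
from . import movement, ruf
from .config import PERIOD_LABELS, StudyConfig, assign_period, filter_individuals
from .grids import GridGeometry, LandscapeStack, read_stack, write_ascii_grid, write_stack
from .simulate import SimulatedTrack, SyntheticScenario, generate_landscape, \
    habitat_preference, simulate_activity, simulate_scats, simulate_track
from .tracks import GpsTrack

CANID_COVARIATES = ["patch_size", "dist_road", "dist_water", "dist_edge",
                    "hare_density", "grouse_density",
                    "deer_adult_occ", "deer_fawn_occ"]
DEER_COVARIATES = ["patch_size", "dist_road", "dist_water", "dist_edge"]


@dataclass
class AnalysisResult:
    """In-memory bundle of everything the pipeline computed."""

    config: StudyConfig
    activity_proportions: pd.DataFrame | None = None
    activity_tests: pd.DataFrame | None = None
    overlap: pd.DataFrame | None = None
    diet_table: pd.DataFrame | None = None
    diet_indices: pd.DataFrame | None = None
    item_anova: pd.DataFrame | None = None
    individual_rufs: pd.DataFrame | None = None
    population_rufs: pd.DataFrame | None = None
    cv: pd.DataFrame | None = None
    ods: dict = field(default_factory=dict)
    surfaces: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Scenario -> input files


def simulate_scenario(scenario: SyntheticScenario, config: StudyConfig,
                      out_dir: str | Path,
                      geometry: GridGeometry | None = None,
                      n_fixes_per_period: int = 240,
                      n_deer_fixes: int | None = None,
                      n_scats_per_cell: int = 60) -> dict[str, Path]:
    """Write a complete synthetic input bundle (CSVs + rasters) to disk.

    Canids get ``n_fixes_per_period`` 15-min fixes in each of the three
    periods plus matching 5-min accelerometer records; deer get sparse
    VHF-style relocations with triangulation error across the whole
    season; scats are drawn per species and period. Deterministic in
    ``scenario.rng_seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(scenario.rng_seed)
    if geometry is None:
        geometry = GridGeometry(0.0, 0.0, config.grid_cell, 80, 80)
    stack = generate_landscape(scenario, geometry, rng)
    write_stack(out / "rasters", stack)

    extent = min(geometry.x_max - geometry.x_min, geometry.y_max - geometry.y_min)
    center = (geometry.x_min + extent / 2, geometry.y_min + extent / 2)

    period_starts = {"PPP": "2014-05-05T00:00:00", "LMP": "2014-06-01T00:00:00",
                     "SMP": "2014-07-05T00:00:00"}
    tracks: list[GpsTrack] = []
    activity_frames: list[pd.DataFrame] = []
    specs = ([("wolf", f"W{k:02d}") for k in range(scenario.n_wolves)]
             + [("coyote", f"C{k:02d}") for k in range(scenario.n_coyotes)])
    habitats = {sp: habitat_preference(stack, eff)
                for sp, eff in scenario.true_ruf.items()}
    for species, ind in specs:
        origin = (center[0] + rng.uniform(-0.3, 0.3) * extent,
                  center[1] + rng.uniform(-0.3, 0.3) * extent)
        for period in PERIOD_LABELS:
            sim = simulate_track(scenario, ind, species,
                                 period_starts[period], n_fixes_per_period,
                                 rng, origin=origin,
                                 fix_interval_minutes=config.fix_interval,
                                 habitat=habitats.get(species),
                                 habitat_geometry=geometry)
            tracks.append(sim.track)
            activity_frames.append(simulate_activity(
                scenario, sim, rng, threshold=config.activity_threshold))

    # adults are on the landscape all season; fawns appear at the birth
    # pulse (start of LMP). VHF-style fixes every 12 h, triangulation error.
    deer_specs = ([("deer_adult", f"DA{k:02d}", "2014-05-01T06:00:00")
                   for k in range(scenario.n_deer_adult)]
                  + [("deer_fawn", f"DF{k:02d}", "2014-05-27T06:00:00")
                     for k in range(scenario.n_deer_fawn)])
    roads = getattr(stack, "roads", None)
    season_end = np.datetime64("2014-08-31T18:00:00")
    for species, ind, start in deer_specs:
        origin = (center[0] + rng.uniform(-0.35, 0.35) * extent,
                  center[1] + rng.uniform(-0.35, 0.35) * extent)
        if n_deer_fixes is None:
            n_fix = int((season_end - np.datetime64(start))
                        / np.timedelta64(12, "h")) + 1
        else:
            n_fix = n_deer_fixes
        sim = simulate_track(scenario, ind, species, start,
                             n_fix, rng, origin=origin,
                             fix_interval_minutes=12 * 60.0,
                             error_sd=scenario.vhf_error_sd,
                             attractor=roads, attraction=0.02,
                             habitat=habitats.get(species),
                             habitat_geometry=geometry,
                             step_minutes=30.0)
        tracks.append(sim.track)

    scat_frames = []
    for species in ("wolf", "coyote"):
        for period in PERIOD_LABELS:
            scat_frames.append(simulate_scats(scenario, species, period,
                                              n_scats_per_cell, rng))
    paths = {
        "gps": out / "gps.csv",
        "activity": out / "activity.csv",
        "scats": out / "scats.csv",
        "rasters": out / "rasters",
    }
    sio.write_gps(paths["gps"], tracks)
    sio.write_activity(paths["activity"], pd.concat(activity_frames, ignore_index=True))
    sio.write_scats(paths["scats"], pd.concat(scat_frames, ignore_index=True))
    return paths


# ---------------------------------------------------------------------------
# Helpers


def split_by_period(track: GpsTrack) -> dict[str, GpsTrack]:
    """Slice one track into per-period subtracks by fix date."""
    dates = pd.to_datetime(track.timestamps)
    labels = np.array([assign_period(d.date()) or "" for d in dates])
    out = {}
    for period in PERIOD_LABELS:
        mask = labels == period
        if mask.sum() >= 2:
            out[period] = track.subset(mask)
    return out


def _ruf_row(fit: ruf.RufFit) -> list[dict]:
    rows = []
    for name in fit.coef_std.index:
        rows.append({
            "individual": fit.individual, "species": fit.species,
            "period": fit.period, "state": fit.state, "covariate": name,
            "beta_std": fit.coef_std[name], "se_std": fit.se_std[name],
            "beta_unstd": fit.coef_unstd[name], "n_cells": fit.n_cells,
        })
    return rows


def _pop_rows(pop: ruf.PopulationRuf) -> list[dict]:
    rows = []
    for name, row in pop.table.iterrows():
        rows.append({
            "species": pop.species, "period": pop.period, "state": pop.state,
            "covariate": name, "mean": row["mean"], "var": row["var"],
            "se": row["se"], "ci_lo": row["ci_lo"], "ci_hi": row["ci_hi"],
            "t": row["t"], "p": row["p"], "n": pop.n,
        })
    return rows


# ---------------------------------------------------------------------------
# Full analysis


def run_full_analysis(config: StudyConfig,
                      gps_path: str | Path,
                      activity_path: str | Path,
                      scat_path: str | Path,
                      raster_dir: str | Path,
                      out_dir: str | Path) -> AnalysisResult:
    """Execute every stage in order and write results under ``out_dir``.

    Raises a configuration error before any computation if the inputs
    lack wolves or coyotes; any stage failure propagates with the stage
    named in the exception.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = AnalysisResult(config=config)
    config.to_yaml(out / "config_used.yaml")

    tracks = sio.read_gps(gps_path)
    species_present = {t.species for t in tracks}
    if not {"wolf", "coyote"} <= species_present:
        raise ValueError("inputs must contain both wolf and coyote tracks")
    activity_df = sio.read_activity(activity_path)
    scats = sio.read_scats(scat_path)
    stack = read_stack(raster_dir)

    log: list[str] = [f"seed={config.rng_seed}"]

    def stage(name):
        log.append(f"stage:{name}")

    try:
        # -- 1. activity classification ---------------------------------
        stage("activity")
        classified = act.classify_activity(activity_df, config.activity_threshold)
        classified["period"] = [assign_period(d.date()) or ""
                                for d in pd.to_datetime(classified["interval_start"])]
        prop_frames = []
        for period in PERIOD_LABELS:
            sub = classified[classified["period"] == period]
            if sub.empty:
                continue
            pp = act.proportion_active(sub)
            pp.insert(0, "period", period)
            prop_frames.append(pp)
        result.activity_proportions = pd.concat(prop_frames, ignore_index=True)

        test_rows = []
        for period in PERIOD_LABELS:
            sub = classified[classified["period"] == period]
            try:
                cmp_res = act.proportion_active_test(sub, "coyote", "wolf",
                                                     alternative="less")
                test_rows.append({
                    "period": period,
                    "coyote_mean": cmp_res.mean_a, "coyote_sd": cmp_res.sd_a,
                    "wolf_mean": cmp_res.mean_b, "wolf_sd": cmp_res.sd_b,
                    "t": cmp_res.t, "df": cmp_res.df, "p": cmp_res.p,
                })
            except ValueError as exc:
                warnings.warn(f"activity test skipped for {period}: {exc}",
                              stacklevel=2)
        result.activity_tests = pd.DataFrame(test_rows)

        # -- 2. activity overlap ----------------------------------------
        stage("overlap")
        active_only = classified[classified["state"] == "active"]
        hours = act.times_of_day_hours(active_only["interval_start"].to_numpy())
        active_only = active_only.assign(hour=hours)
        overlap_rows = []
        for period in PERIOD_LABELS:
            sub = active_only[active_only["period"] == period]
            t_w = sub.loc[sub["species"] == "wolf", "hour"].to_numpy()
            t_c = sub.loc[sub["species"] == "coyote", "hour"].to_numpy()
            if len(t_w) < 2 or len(t_c) < 2:
                continue
            res = act.activity_overlap(t_c, t_w)
            overlap_rows.append({"period": period, "delta": res.delta,
                                 "n_coyote": len(t_c), "n_wolf": len(t_w)})
        result.overlap = pd.DataFrame(overlap_rows)

        # -- 3. diet -----------------------------------------------------
        stage("diet")
        assigned = diet_mod.assign_scat_table(scats)
        if "period" not in assigned.columns:
            assigned["period"] = [assign_period(d.date()) or ""
                                  for d in pd.to_datetime(assigned["date"])]
        diet_rows, index_rows = [], []
        for period in PERIOD_LABELS:
            summaries = {}
            for species in ("wolf", "coyote"):
                try:
                    summaries[species] = diet_mod.diet_proportions(
                        assigned, species, period)
                except ValueError:
                    continue
            for species, summ in summaries.items():
                for item, value in summ.p.items():
                    diet_rows.append({"species": species, "period": period,
                                      "item": item, "proportion": value,
                                      "n_scats": summ.n_scats})
            if len(summaries) == 2:
                p, q = summaries["coyote"].p, summaries["wolf"].p
                index_rows.append({
                    "period": period,
                    "B_coyote": diet_mod.dietary_breadth(p),
                    "B_wolf": diet_mod.dietary_breadth(q),
                    "alpha": diet_mod.food_niche_overlap(p, q),
                })
        result.diet_table = pd.DataFrame(diet_rows)
        result.diet_indices = pd.DataFrame(index_rows)
        result.item_anova = diet_mod.compare_item_volumes(assigned)

        # -- 4. label canid fixes, split periods ------------------------
        stage("label_fixes")
        canids = [t for t in tracks if t.species in ("wolf", "coyote")]
        deer = [t for t in tracks if t.species.startswith("deer")]
        labelled = [act.assign_activity_to_fixes(
            t, classified[classified["id"] == t.individual],
            config.fix_interval, config.activity_interval) for t in canids]

        # -- 5. per-period deer ODs and prey surfaces -------------------
        # location-count inclusion filters apply within each period; the
        # period's population prediction replaces the corresponding
        # prey-occurrence raster for that period's canid RUFs
        stage("deer_surfaces")
        ind_rows, pop_rows, cv_rows = [], [], []
        deer_surface: dict[tuple[str, str], np.ndarray] = {}
        for age in ("deer_adult", "deer_fawn"):
            for period in PERIOD_LABELS:
                subs = [split_by_period(t).get(period)
                        for t in deer if t.species == age]
                subs = filter_individuals([s for s in subs if s is not None],
                                          config)
                fits = []
                for track in subs:
                    try:
                        od = movement.fit_vhf_od(
                            track, config.vhf_max_lag, geometry=stack.geometry,
                            od_level=config.od_level, cell=config.grid_cell,
                            period=period)
                        retained = ruf.screen_covariates(
                            stack, DEER_COVARIATES, config.correlation_cutoff,
                            config.covariate_priority, od.level_mask)
                        fits.append(ruf.fit_individual_ruf(od, stack, retained))
                    except ValueError as exc:
                        warnings.warn(
                            f"deer OD/RUF skipped ({track.individual}/{period}): {exc}",
                            stacklevel=2)
                if len(fits) >= 2:
                    pop = ruf.population_ruf(fits, config.alpha)
                    pop_rows.extend(_pop_rows(pop))
                    for f in fits:
                        ind_rows.extend(_ruf_row(f))
                    surface = ruf.predict_surface(pop, stack)
                    deer_surface[(age, period)] = surface
                    result.surfaces[(age, period)] = surface

        # -- 6. canid dBBMM ODs and RUFs --------------------------------
        stage("canid_rufs")
        surfaces_by_period: dict[str, np.ndarray] = {}
        for species in ("wolf", "coyote"):     # wolves strictly first
            covs = list(CANID_COVARIATES)
            if species == "coyote":
                covs.append("wolf_occ")
            for period in PERIOD_LABELS:
                # period-specific stack: deer surfaces from this period's
                # population RUFs replace the raster prey layers
                stack_p = stack
                for age in ("deer_adult", "deer_fawn"):
                    if (age, period) in deer_surface:
                        stack_p = stack_p.with_layer(f"{age}_occ",
                                                     deer_surface[(age, period)])
                for state in ("active", "inactive"):
                    fits, ods = [], []
                    for track in labelled:
                        if track.species != species:
                            continue
                        sub = split_by_period(track).get(period)
                        if sub is None or sub.n_fixes < 3:
                            continue
                        try:
                            profile = movement.fit_dynamic_motion_variance(
                                sub, config.dbbmm_window, config.dbbmm_margin)
                            od = movement.occurrence_distribution(
                                sub, profile, geometry=stack.geometry,
                                state=state, od_level=config.od_level,
                                cell=config.grid_cell, period=period)
                        except ValueError as exc:
                            warnings.warn(
                                f"OD skipped ({track.individual}/{period}/{state}): {exc}",
                                stacklevel=2)
                            continue
                        use_stack = stack_p
                        if species == "coyote":
                            if period not in surfaces_by_period:
                                raise ValueError(
                                    "coyote RUFs require the wolf prediction "
                                    f"surface for {period}; none was fit")
                            use_stack = stack_p.with_layer(
                                "wolf_occ", surfaces_by_period[period])
                        try:
                            retained = ruf.screen_covariates(
                                use_stack, [c for c in covs if c in use_stack],
                                config.correlation_cutoff,
                                config.covariate_priority, od.level_mask)
                            fits.append(ruf.fit_individual_ruf(od, use_stack, retained))
                        except ValueError as exc:
                            warnings.warn(
                                f"RUF skipped ({track.individual}/{period}/{state}): {exc}",
                                stacklevel=2)
                            continue
                        ods.append(od)
                        result.ods[(track.individual, period, state)] = od
                    if len(fits) < 2:
                        continue
                    pop = ruf.population_ruf(fits, config.alpha)
                    pop_rows.extend(_pop_rows(pop))
                    for f in fits:
                        ind_rows.extend(_ruf_row(f))
                    pred_stack = stack_p
                    if species == "coyote":
                        pred_stack = stack_p.with_layer(
                            "wolf_occ", surfaces_by_period[period])
                    surface = ruf.predict_surface(pop, pred_stack)
                    result.surfaces[(species, period, state)] = surface
                    if species == "wolf" and state == "active":
                        surfaces_by_period[period] = surface
                    if len(fits) >= 3:
                        cv = ruf.loio_cv(fits, ods, pred_stack,
                                         config.cv_bins, config.alpha)
                        for _, row in cv.folds.iterrows():
                            cv_rows.append({
                                "species": species, "period": period,
                                "state": state, **row.to_dict()})
                        cv_rows.append({
                            "species": species, "period": period, "state": state,
                            "individual": "MEAN", "slope": cv.mean_slope,
                            "r2": cv.mean_r2})
        result.individual_rufs = pd.DataFrame(ind_rows)
        result.population_rufs = pd.DataFrame(pop_rows)
        result.cv = pd.DataFrame(cv_rows)
    except Exception as exc:
        (out / "run_log.txt").write_text("\n".join(log + [f"FAILED: {exc}"]))
        raise RuntimeError(f"pipeline failed at {log[-1]}: {exc}") from exc

    # -- 7. write outputs -----------------------------------------------
    stage("write")
    tables = {
        "activity_proportions.csv": result.activity_proportions,
        "activity_tests.csv": result.activity_tests,
        "activity_overlap.csv": result.overlap,
        "diet_proportions.csv": result.diet_table,
        "diet_indices.csv": result.diet_indices,
        "diet_item_anova.csv": result.item_anova,
        "ruf_individual.csv": result.individual_rufs,
        "ruf_population.csv": result.population_rufs,
        "cv.csv": result.cv,
    }
    for name, df in tables.items():
        if df is not None:
            df.to_csv(out / name, index=False, float_format="%.10g")
    for key, surface in result.surfaces.items():
        name = key if isinstance(key, str) else "_".join(key)
        write_ascii_grid(out / f"surface_{name}.asc", stack.geometry, surface)
    summary = {
        "n_tracks": len(tracks),
        "n_ods": len(result.ods),
        "periods": list(PERIOD_LABELS),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    (out / "run_log.txt").write_text("\n".join(log + ["done"]))
    return result
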