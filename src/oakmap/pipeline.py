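"""Stage-wise pipeline: simulate -> prepare -> fit -> filter -> validate.

Each stage reads its inputs from the run directory (or from the in-memory
state when stages are chained), writes its artifacts as plain-text formats
(ASCII grids, GeoJSON, CSV, JSON) and records a manifest with the seed, a
parameter echo and SHA-256 hashes of inputs and outputs, so every artifact
is traceable and a re-run with the same config reproduces it bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import ensemble as ens
from . import filters as flt
from . import prep
from . import synthetic as syn
from . import validation as val
from .config import PipelineConfig
from .grids import GridSpec
from .io import read_ascii_grid, read_geojson, write_ascii_grid, write_geojson

log = logging.getLogger("oakmap")

STAGES = ("simulate", "prepare", "fit", "filter", "validate")

__all__ = ["run_stage", "run_all", "PipelineState", "STAGES"]


class PipelineState(dict):
    """Loose bag of in-memory objects passed between chained stages."""


def _stage_seed(seed: int, stage: str) -> int:
    ss = np.random.SeedSequence(seed, spawn_key=(STAGES.index(stage),))
    return int(ss.generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(out: Path, stage: str, config: PipelineConfig, inputs: list[Path], outputs: list[Path]) -> None:
    manifest = {
        "stage": stage,
        "seed": config.seed,
        "config": config.to_dict(),
        "inputs": {p.name: _sha256(p) for p in inputs},
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    with open(out / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def _require(out: Path, *names: str) -> list[Path]:
    paths = [out / n for n in names]
    missing = [str(p) for p in paths if not p.exists()]
    if missing:
        raise FileNotFoundError(f"missing input artifact(s): {missing}")
    return paths


# ---------------------------------------------------------------------------
# simulate


def stage_simulate(config: PipelineConfig, state: PipelineState | None = None) -> PipelineState:
    state = state if state is not None else PipelineState()
    p = config.simulation
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = _stage_seed(config.seed, "simulate")
    rng = np.random.default_rng(seed)

    grid = GridSpec(
        n_rows=p.n_rows, n_cols=p.n_cols, pixel_size=p.pixel_size, region_count=p.region_count
    )
    stack = syn.generate_biophysical(grid, seed=int(rng.integers(2**31)), roughness=p.roughness)
    stands = syn.generate_stands(
        stack, seed=int(rng.integers(2**31)), min_area=p.min_stand_area, max_area=p.max_stand_area
    )
    truth = syn.TruthModel(
        niche_coefficients=dict(p.niche_coefficients),
        intercept=p.intercept,
        dem_optimum=p.dem_optimum,
        dem_tolerance=p.dem_tolerance,
        management_bias=p.management_bias,
        occupancy_area_fraction=p.occupancy_area_fraction,
        estate_fraction=p.estate_fraction,
        area_noise_sd=p.area_noise_sd,
    )
    occupancy, inventory = syn.generate_truth_and_inventory(
        stands,
        stack,
        truth,
        seed=int(rng.integers(2**31)),
        sample_fraction=p.sample_fraction,
        min_sample_stands=p.min_sample_stands,
        n_validation_sites=p.n_validation_sites,
    )

    outputs: list[Path] = []
    for name, layer in stack.layers.items():
        outputs.append(write_ascii_grid(out / f"layer_{name}.asc", layer, grid))
    outputs.append(write_ascii_grid(out / "region_id.asc", stack.region_id.astype(float), grid, fmt="%d"))
    outputs.append(write_ascii_grid(out / "stand_labels.asc", stands.labels.astype(float), grid, fmt="%d"))
    stands.table.to_csv(out / "stand_table.csv")
    outputs.append(out / "stand_table.csv")
    outputs.append(write_ascii_grid(out / "occupancy.asc", occupancy.astype(float), grid, fmt="%d"))

    pd.DataFrame(
        [{"region": r, "area_ha": a} for r, a in inventory.regional_area_targets.items()]
    ).to_csv(out / "area_targets.csv", index=False)
    outputs.append(out / "area_targets.csv")
    rows = []
    for region, hist in inventory.elevation_histograms.items():
        for lower, count in hist.counts.items():
            rows.append({"region": region, "elev_class_lower": lower, "count": count})
    pd.DataFrame(rows).to_csv(out / "elevation_histograms.csv", index=False)
    outputs.append(out / "elevation_histograms.csv")

    with open(out / "truth.json", "w") as fh:
        json.dump(
            {
                "niche_coefficients": truth.niche_coefficients,
                "intercept": truth.intercept,
                "dem_optimum": truth.dem_optimum,
                "dem_tolerance": truth.dem_tolerance,
                "management_bias": truth.management_bias,
                "occupancy_area_fraction": truth.occupancy_area_fraction,
                "estate_fraction": truth.estate_fraction,
                "area_noise_sd": truth.area_noise_sd,
                "sample_fraction": inventory.sample_fraction,
                "validation_stand_ids": inventory.validation_stand_ids,
                "sampled_stand_ids": inventory.sampled_stand_ids,
            },
            fh,
            indent=1,
        )
    outputs.append(out / "truth.json")

    outputs.append(
        write_geojson(
            out / "validation_sites.geojson",
            inventory.validation_sites,
            [{"stand_id": s} for s in inventory.validation_stand_ids],
            crs=grid.crs,
        )
    )
    if p.export_geojson:
        geoms, props = [], []
        for sid in stands.stand_ids:
            geoms.append(stands.polygon(int(sid)))
            rec = stands.table.loc[sid]
            props.append(
                {
                    "stand_id": int(sid),
                    "region_id": int(rec["region_id"]),
                    "ift": rec["ift"],
                    "ownership": rec["ownership"],
                    "pct_oak": int(rec["pct_oak"]),
                    "area_ha": float(rec["area_ha"]),
                }
            )
        outputs.append(write_geojson(out / "stands.geojson", geoms, props, crs=grid.crs))

    _write_manifest(out, "simulate", config, [], outputs)
    log.info("simulate: %d stands, %d occupied pixels, %d validation sites",
             len(stands.table), int(occupancy.sum()), len(inventory.validation_sites))
    state.update(stack=stack, stands=stands, truth=truth, occupancy=occupancy, inventory=inventory)
    return state


def _load_simulated(config: PipelineConfig, state: PipelineState) -> PipelineState:
    if "stack" in state:
        return state
    out = Path(config.out_dir)
    _require(out, "layer_DEM.asc", "region_id.asc", "stand_labels.asc", "stand_table.csv",
             "area_targets.csv", "elevation_histograms.csv", "validation_sites.geojson")
    layers = {}
    grid = None
    for name in syn.ALL_LAYERS:
        values, g, _ = read_ascii_grid(out / f"layer_{name}.asc")
        layers[name] = values
        grid = g
    region_id, _, _ = read_ascii_grid(out / "region_id.asc")
    grid = GridSpec(
        n_rows=grid.n_rows, n_cols=grid.n_cols, pixel_size=grid.pixel_size,
        origin=grid.origin, region_count=int(np.nanmax(region_id)) + 1,
    )
    stack = syn.BiophysicalStack(grid=grid, layers=layers, region_id=region_id.astype(np.int32))
    labels, _, _ = read_ascii_grid(out / "stand_labels.asc")
    table = pd.read_csv(out / "stand_table.csv", index_col="stand_id")
    stands = syn.StandPolygonLayer(grid=grid, labels=labels.astype(np.int32), table=table)

    areas = pd.read_csv(out / "area_targets.csv")
    area_targets = {int(r.region): float(r.area_ha) for r in areas.itertuples()}
    hist_rows = pd.read_csv(out / "elevation_histograms.csv")
    histograms = {
        int(region): flt.ElevationHistogram(
            {float(r.elev_class_lower): int(r.count) for r in grp.itertuples()}
        )
        for region, grp in hist_rows.groupby("region")
    }
    sites, props = read_geojson(out / "validation_sites.geojson")
    inventory = syn.InventoryProducts(
        regional_area_targets=area_targets,
        elevation_histograms=histograms,
        sample_fraction=float("nan"),
        sampled_stand_ids={},
        validation_stand_ids=[p.get("stand_id", -1) for p in props],
        validation_sites=sites,
    )
    occ_path = out / "occupancy.asc"
    if occ_path.exists():
        occupancy, _, _ = read_ascii_grid(occ_path)
        state["occupancy"] = occupancy == 1
    state.update(stack=stack, stands=stands, inventory=inventory)
    return state


# ---------------------------------------------------------------------------
# prepare


def stage_prepare(config: PipelineConfig, state: PipelineState | None = None) -> PipelineState:
    state = _load_simulated(config, state if state is not None else PipelineState())
    p = config.prep
    out = Path(config.out_dir)
    seed = _stage_seed(config.seed, "prepare")
    rng = np.random.default_rng(seed)
    stack: syn.BiophysicalStack = state["stack"]
    stands: syn.StandPolygonLayer = state["stands"]

    training = stands
    if p.training_ownership and "ownership" in stands.table.columns:
        training = stands.subset(
            stands.table.index[stands.table["ownership"] == p.training_ownership]
        )

    pa_sets: dict[int, prep.PresenceAbsenceSet] = {}
    screening: dict[int, prep.CollinearityReport] = {}
    long_rows = []
    for region in stack.regions():
        full = prep.build_presence_absence(
            training, stack, region, seed=int(rng.integers(2**31)),
            oak_min_pct=p.oak_min_pct, oak_max_pct=p.oak_max_pct,
            k=p.k_replicates, presence_fraction=p.presence_fraction,
        )
        X, y = full.design(0)
        report = prep.screen_collinearity(
            X, full.variable_names, r_threshold=p.r_threshold,
            vif_threshold=p.vif_threshold, response=y,
        )
        screening[region] = report
        pa_sets[region] = prep.PresenceAbsenceSet(
            region_id=region,
            presence=full.presence,
            absence_replicates=full.absence_replicates,
            variable_names=report.retained,
        )
        pres = full.presence.assign(label=1, replicate=0, region=region)
        long_rows.append(pres)
        for i, rep_df in enumerate(full.absence_replicates):
            long_rows.append(rep_df.assign(label=0, replicate=i + 1, region=region))
        log.info(
            "prepare: region %d, %d presence pixels, %d replicates, removed %s",
            region, full.n_presence, full.k_replicates, report.removed or "nothing",
        )

    table = pd.concat(long_rows, ignore_index=True)
    lead = ["region", "row", "col", "label", "replicate"]
    table = table[lead + [c for c in table.columns if c not in lead]]
    table.to_csv(out / "presence_absence.csv", index=False)

    coll = {
        str(region): {
            "removed": rep.removed,
            "retained": rep.retained,
            "r_threshold": rep.r_threshold,
            "vif_threshold": rep.vif_threshold,
            "vif_values": {k: float(v) for k, v in rep.vif_values.items()},
            "removal_log": rep.removal_log,
        }
        for region, rep in screening.items()
    }
    with open(out / "collinearity.json", "w") as fh:
        json.dump(coll, fh, indent=1)
    pd.DataFrame(
        [
            {"region": region, "removed": ";".join(rep.removed) or "-", "retained": ";".join(rep.retained)}
            for region, rep in screening.items()
        ]
    ).to_csv(out / "collinearity.csv", index=False)

    _write_manifest(
        out, "prepare", config,
        _require(out, "stand_table.csv"),
        [out / "presence_absence.csv", out / "collinearity.json", out / "collinearity.csv"],
    )
    state.update(pa_sets=pa_sets, screening=screening)
    return state


def _load_prepared(config: PipelineConfig, state: PipelineState) -> PipelineState:
    if "pa_sets" in state:
        return state
    out = Path(config.out_dir)
    _require(out, "presence_absence.csv", "collinearity.json")
    table = pd.read_csv(out / "presence_absence.csv")
    with open(out / "collinearity.json") as fh:
        coll = json.load(fh)
    pa_sets = {}
    for region, grp in table.groupby("region"):
        retained = coll[str(region)]["retained"]
        pres = grp[grp["label"] == 1].reset_index(drop=True)
        reps = [
            grp[(grp["label"] == 0) & (grp["replicate"] == i)].reset_index(drop=True)
            for i in sorted(grp.loc[grp["label"] == 0, "replicate"].unique())
        ]
        pa_sets[int(region)] = prep.PresenceAbsenceSet(
            region_id=int(region), presence=pres, absence_replicates=reps,
            variable_names=list(retained),
        )
    state["pa_sets"] = pa_sets
    return state


# ---------------------------------------------------------------------------
# fit


def stage_fit(config: PipelineConfig, state: PipelineState | None = None) -> PipelineState:
    state = state if state is not None else PipelineState()
    state = _load_simulated(config, state)
    state = _load_prepared(config, state)
    p = config.fit
    out = Path(config.out_dir)
    seed = _stage_seed(config.seed, "fit")
    rng = np.random.default_rng(seed)
    stack: syn.BiophysicalStack = state["stack"]
    pa_sets = state["pa_sets"]

    all_evals: list[ens.RunEvaluation] = []
    all_runs: list[ens.FittedRun] = []
    for region, data in sorted(pa_sets.items()):
        evals, runs = ens.cross_validate_region(
            data, algorithms=tuple(p.algorithms), n_repeats=p.n_repeats,
            split=p.split, seed=int(rng.integers(2**31)),
        )
        all_evals.extend(evals)
        all_runs.extend(runs)
        frame = ens.evaluations_to_frame(evals)
        log.info(
            "fit: region %d, %d/%d runs converged, median TSS %.3f",
            region, int(frame["converged"].sum()), len(frame),
            float(frame.loc[frame["converged"], "tss"].median()),
        )

    ledger = ens.evaluations_to_frame(all_evals)
    ledger.to_csv(out / "evaluation_ledger.csv", index=False)
    retained, report = ens.exclude_unstable_algorithms(ledger, p.min_converged_fraction)

    rasters: dict[int, ens.ProbabilityRaster] = {}
    outputs = [out / "evaluation_ledger.csv"]
    for region in sorted(pa_sets):
        raster = ens.ensemble_predict(
            stack, all_runs, region_id=region,
            algorithms=tuple(retained[region]),
            per_algorithm=p.per_algorithm_weighting,
        )
        rasters[region] = raster
        outputs.append(
            write_ascii_grid(out / f"probability_region{region}.asc", raster.values, stack.grid)
        )

    meta = {
        "retained_algorithms": {str(k): v for k, v in retained.items()},
        "convergence_report": report.to_dict(orient="records"),
        "weighting": "per-algorithm mean TSS" if p.per_algorithm_weighting else "per-run TSS",
        "n_evaluations": len(ledger),
        "provenance": {str(r): rasters[r].provenance for r in rasters},
    }
    with open(out / "ensemble_meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    outputs.append(out / "ensemble_meta.json")

    _write_manifest(out, "fit", config, _require(out, "presence_absence.csv"), outputs)
    state.update(evaluations=all_evals, fitted_runs=all_runs, rasters=rasters, retained=retained)
    return state


def _load_fitted(config: PipelineConfig, state: PipelineState) -> PipelineState:
    if "rasters" in state:
        return state
    out = Path(config.out_dir)
    stack: syn.BiophysicalStack = state["stack"]
    rasters = {}
    for region in stack.regions():
        path = out / f"probability_region{region}.asc"
        if not path.exists():
            raise FileNotFoundError(f"missing input artifact(s): ['{path}']")
        values, _, _ = read_ascii_grid(path)
        rasters[region] = ens.ProbabilityRaster(
            region_id=region, values=values, grid=stack.grid, provenance={}
        )
    state["rasters"] = rasters
    return state


# ---------------------------------------------------------------------------
# filter


def stage_filter(config: PipelineConfig, state: PipelineState | None = None) -> PipelineState:
    state = state if state is not None else PipelineState()
    state = _load_simulated(config, state)
    state = _load_fitted(config, state)
    p = config.filter
    out = Path(config.out_dir)
    stack: syn.BiophysicalStack = state["stack"]
    stands: syn.StandPolygonLayer = state["stands"]
    inventory: syn.InventoryProducts = state["inventory"]
    rasters: dict[int, ens.ProbabilityRaster] = state["rasters"]
    dem = stack.layers["DEM"]
    pa = stack.grid.pixel_area_ha

    training_pixels = _training_oak_pixels(config, state)

    sel_area: dict[int, flt.SelectionResult] = {}
    sel_elev: dict[int, flt.SelectionResult] = {}
    adjust_diffs: dict[int, float] = {}
    report: dict = {"regions": {}}
    outputs: list[Path] = []
    for region, prob in sorted(rasters.items()):
        adjusted, mean_diff = flt.manual_adjust_check(prob, training_pixels.get(region, (np.array([], int), np.array([], int))))
        adjust_diffs[region] = mean_diff
        if p.apply_manual_adjustment:
            prob = ens.ProbabilityRaster(
                region_id=region, values=adjusted, grid=prob.grid, provenance=prob.provenance
            )
        masked = flt.mask_to_broadleaf(prob, stands)
        ranked = flt.rank_pixels(masked)
        target = inventory.regional_area_targets[region]
        a = flt.area_filter(ranked, target, mode=p.area_mode)
        quota = inventory.elevation_histograms[region]
        if p.quota_scale == "area_target":
            quota = quota.scaled_to_total(int(np.floor(target / pa + 1e-9)))
        e = flt.elevation_filter(ranked, dem, quota)
        sel_area[region], sel_elev[region] = a, e
        report["regions"][str(region)] = {
            "target_area_ha": target,
            "area_filter": {
                "achieved_area_ha": a.achieved_area,
                "n_selected": a.n_selected,
                "min_selected_probability": a.min_selected_probability,
                "shortfall_area_ha": a.shortfall_area,
            },
            "elevation_filter": {
                "achieved_area_ha": e.achieved_area,
                "n_selected": e.n_selected,
                "min_selected_probability": e.min_selected_probability,
                "shortfall_area_ha": e.shortfall_area,
                "n_shortfall_classes": len(e.shortfalls),
            },
            "manual_adjustment_mean_difference": mean_diff,
        }
        per_class = pd.DataFrame(
            [
                {
                    "region": region,
                    "elev_class_lower": lo,
                    "quota": e.per_class_quota.counts.get(lo, 0),
                    "achieved": e.per_class_achieved.counts.get(lo, 0),
                }
                for lo in e.per_class_quota.counts
            ]
        )
        per_class.to_csv(out / f"elevation_classes_region{region}.csv", index=False)
        outputs.append(out / f"elevation_classes_region{region}.csv")
        outputs.append(
            write_ascii_grid(out / f"selection_area_region{region}.asc", a.mask().astype(float), stack.grid, fmt="%d")
        )
        outputs.append(
            write_ascii_grid(out / f"selection_elevation_region{region}.asc", e.mask().astype(float), stack.grid, fmt="%d")
        )
        log.info(
            "filter: region %d, area filter %d px (min p %.3f), elevation filter %d px (min p %.3f)",
            region, a.n_selected, a.min_selected_probability, e.n_selected, e.min_selected_probability,
        )

    probs_a = np.concatenate([s.probs for s in sel_area.values()])
    probs_e = np.concatenate([s.probs for s in sel_elev.values()])
    D, ks_p = flt.compare_selections_ks(probs_a, probs_e)
    report["ks"] = {"D": D, "p_value": ks_p}
    report["mean_manual_adjustment_difference"] = float(np.mean(list(adjust_diffs.values())))
    with open(out / "selection_report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    outputs.append(out / "selection_report.json")

    _write_manifest(out, "filter", config, _require(out, "area_targets.csv"), outputs)
    state.update(selection_area=sel_area, selection_elevation=sel_elev, selection_report=report)
    return state


def _training_oak_pixels(config: PipelineConfig, state: PipelineState) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Per-region (rows, cols) of the presence pixels used in training."""
    out = Path(config.out_dir)
    if "pa_sets" in state:
        return {
            region: (
                data.presence["row"].to_numpy(int), data.presence["col"].to_numpy(int)
            )
            for region, data in state["pa_sets"].items()
        }
    path = out / "presence_absence.csv"
    if not path.exists():
        return {}
    table = pd.read_csv(path)
    pres = table[table["label"] == 1]
    return {
        int(region): (grp["row"].to_numpy(int), grp["col"].to_numpy(int))
        for region, grp in pres.groupby("region")
    }


# ---------------------------------------------------------------------------
# validate


def _combine(selections: dict[int, flt.SelectionResult]) -> flt.SelectionResult:
    regions = sorted(selections)
    first = selections[regions[0]]
    return flt.SelectionResult(
        rows=np.concatenate([selections[r].rows for r in regions]),
        cols=np.concatenate([selections[r].cols for r in regions]),
        probs=np.concatenate([selections[r].probs for r in regions]),
        grid=first.grid,
        target_area=sum(selections[r].target_area for r in regions),
        pixel_area=first.pixel_area,
    )


def stage_validate(config: PipelineConfig, state: PipelineState | None = None) -> PipelineState:
    state = state if state is not None else PipelineState()
    state = _load_simulated(config, state)
    out = Path(config.out_dir)
    p = config.validate
    if "selection_area" not in state:
        state = _load_selections(config, state)
    inventory: syn.InventoryProducts = state["inventory"]
    sites = inventory.validation_sites

    reports = {}
    for name, selections in (
        ("area_filter", state["selection_area"]),
        ("elevation_filter", state["selection_elevation"]),
    ):
        combined = _combine(selections)
        rep = val.validate(combined, sites, p0=p.p0, confidence=p.confidence)
        reports[name] = rep
        log.info(
            "validate: %s %d/%d coincident (%.0f%%, CI %.0f-%.0f%%, p=%.4g)",
            name, rep.n_coincident, rep.n_sites, rep.rate, rep.ci_low, rep.ci_high, rep.p_value,
        )

    doc = {name: rep.to_dict() for name, rep in reports.items()}
    with open(out / "validation.json", "w") as fh:
        json.dump(doc, fh, indent=1)
    pd.DataFrame([{"filter": k, **v} for k, v in doc.items()]).to_csv(
        out / "validation.csv", index=False
    )
    _write_manifest(
        out, "validate", config, _require(out, "validation_sites.geojson"),
        [out / "validation.json", out / "validation.csv"],
    )
    state["validation_reports"] = reports
    return state


def _load_selections(config: PipelineConfig, state: PipelineState) -> PipelineState:
    out = Path(config.out_dir)
    state = _load_fitted(config, state)
    rasters = state["rasters"]
    for key, pattern in (
        ("selection_area", "selection_area_region{r}.asc"),
        ("selection_elevation", "selection_elevation_region{r}.asc"),
    ):
        selections = {}
        for region, prob in rasters.items():
            path = out / pattern.format(r=region)
            if not path.exists():
                raise FileNotFoundError(f"missing input artifact(s): ['{path}']")
            mask, _, _ = read_ascii_grid(path)
            rows, cols = np.nonzero(mask == 1)
            selections[region] = flt.SelectionResult(
                rows=rows, cols=cols, probs=prob.values[rows, cols],
                grid=prob.grid, target_area=float("nan"),
                pixel_area=prob.grid.pixel_area_ha,
            )
        state[key] = selections
    return state


# ---------------------------------------------------------------------------


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "prepare": stage_prepare,
    "fit": stage_fit,
    "filter": stage_filter,
    "validate": stage_validate,
}


def run_stage(stage: str, config: PipelineConfig, state: PipelineState | None = None) -> PipelineState:
    """Run one pipeline stage (or ``'all'`` to chain every stage)."""
    if not config.quiet and not log.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(name)s %(message)s"))
        log.addHandler(handler)
        log.setLevel(logging.INFO)
    if stage == "all":
        return run_all(config, state)
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES + ('all',)}")
    Path(config.out_dir).mkdir(parents=True, exist_ok=True)
    config.to_yaml(Path(config.out_dir) / "config.yaml")
    return _STAGE_FUNCS[stage](config, state)


def run_all(config: PipelineConfig, state: PipelineState | None = None) -> PipelineState:
    state = state if state is not None else PipelineState()
    for stage in STAGES:
        state = run_stage(stage, config, state)
    return state
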