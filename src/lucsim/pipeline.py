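"""One-command pipeline: synthesize -> calibrate -> scenarios -> simulate -> account -> validate.

The timeline mirrors the study design: the model is calibrated on a
2005-2010 interval, validated by simulating 2005-2012 against the
"observed" 2012 map, and the three Forest-Code scenarios are then run
2013-2025 from the 2012 map. On synthetic landscapes the "observed"
history is produced by the known forward model, so calibration quality is
measurable.

A single run seed fans out to per-stage child seeds by stable hashing, so
each stage is independently reproducible.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calibration, engine, roads as roads_mod, scenarios as scen_mod, validation
from .carbon import CarbonParams, forest_carbon, ledger_from_run, summarize
from .grids import GridMap, LandCover, Region, class_areas, write_grid
from .rates import RateTable, F_TO_D, S_TO_D, D_TO_S
from .synth import SynthConfig, SyntheticLandscape, generate_landscape, evolve_landscape

log = logging.getLogger("lucsim")

__all__ = ["RunConfig", "child_seed", "synthesize_history", "calibrate",
           "build_scenario", "simulate_scenario", "run_pipeline"]

SCENARIO_BUILDERS = {
    "BASELINE": scen_mod.baseline,
    "CODE1965": scen_mod.code1965,
    "CODE2012": scen_mod.code2012,
}


def child_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the run seed (< 2^31)."""
    return zlib.crc32(f"{seed}:{stage}".encode()) % (2**31)


@dataclass
class RunConfig:
    """Declarative description of one full run."""

    seed: int = 0
    n_rows: int = 200
    n_cols: int = 200
    years: int = 13              # 2013-2025
    start_year: int = 2012
    calibration_years: int = 5   # 2005-2010
    scenario_names: tuple = ("BASELINE", "CODE1965", "CODE2012")
    carbon: CarbonParams = field(default_factory=CarbonParams)
    beta: float = 1.0            # road-feedback coefficient
    road_budget_km: float = 0.0  # per-year road growth (0 disables feedback)
    windows: tuple = (1, 3, 5, 7, 9, 11)
    n_bins: int = 10

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "carbon" in raw:
            raw["carbon"] = CarbonParams(**raw["carbon"])
        for key in ("scenario_names", "windows"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        raw["carbon"] = asdict(self.carbon)
        raw["scenario_names"] = list(self.scenario_names)
        raw["windows"] = list(self.windows)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def synthesize_history(cfg: RunConfig) -> dict:
    """Generate the study area at 2005 and evolve it to 2008, 2010 and 2012
    with the known forward model."""
    synth_cfg = SynthConfig(
        n_rows=cfg.n_rows, n_cols=cfg.n_cols, seed=child_seed(cfg.seed, "synth")
    )
    land = generate_landscape(synth_cfg)
    susceptibility = 0.2 + np.exp(-land.static["dist_roads"] / 1500.0) \
        + 0.5 * np.exp(-land.static["dist_rivers"] / 2000.0)
    regions0 = _history_regions(land)
    lc2005 = land.lc
    ev = lambda lc, yrs, tag: evolve_landscape(
        lc, land.true_rates, yrs, child_seed(cfg.seed, tag),
        regions=regions0, susceptibility=susceptibility,
    )
    lc2008 = ev(lc2005, 3, "evolve08")
    lc2010 = ev(lc2008, 2, "evolve10")
    lc2012 = ev(lc2010, 2, "evolve12")
    return {
        "land": land,
        "susceptibility": susceptibility,
        "history_regions": regions0,
        "lc2005": lc2005, "lc2008": lc2008, "lc2010": lc2010, "lc2012": lc2012,
    }


def _history_regions(land: SyntheticLandscape) -> GridMap:
    """Six-region map (no APP carve-out) used by the true forward model."""
    cfg0 = scen_mod.baseline()
    # the baseline APP never restricts anything but is still a region with
    # its own rates; it uses the max-water-level delineation
    app = scen_mod.app_buffer(
        land.rivers, scen_mod.AppRule(), scen_mod.MAX_WATER_LEVEL, land.lc
    )
    return scen_mod.build_regions(
        land.cu, land.il, land.rivers, land.road_influence, app, cfg0, land.lc
    )


def default_bins(land: SyntheticLandscape, n_bins: int = 10) -> dict:
    return {
        "dist_roads": calibration.quantile_bins(land.static["dist_roads"], n_bins),
        "dist_rivers": calibration.quantile_bins(land.static["dist_rivers"], n_bins),
        "altitude": calibration.quantile_bins(land.static["altitude"], n_bins),
        "slope": calibration.quantile_bins(land.static["slope"], n_bins),
        "soil": calibration.BinSpec(categories=(0, 1, 2)),
    }


def calibrate(hist: dict, regions: GridMap, cfg: RunConfig) -> tuple:
    """Weights of evidence and annual rates from the 2005-2010 interval,
    on the given region map."""
    land = hist["land"]
    bins = default_bins(land, cfg.n_bins)
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        weights = calibration.compute_weights(
            hist["lc2005"], hist["lc2010"], land.static, bins, regions
        )
        rate_table = calibration.compute_rates(
            hist["lc2005"], hist["lc2010"], regions, years=cfg.calibration_years
        )
    return weights, rate_table


def build_scenario(name: str, hist: dict, cfg: RunConfig) -> dict:
    """Region map, calibrated weights/rates and restrictions for a scenario."""
    land = hist["land"]
    scenario = SCENARIO_BUILDERS[name]()
    app = scen_mod.app_buffer(
        land.rivers, scen_mod.AppRule(), scenario.app_reference, land.lc
    )
    regions = scen_mod.build_regions(
        land.cu, land.il, land.rivers, land.road_influence, app, scenario, land.lc,
        lc_2008=hist["lc2008"] if scenario.regions_used == 7 else None,
    )
    weights, rate_table = calibrate(hist, regions, cfg)
    if scenario.leakage_enabled:
        demand = scen_mod.app_annual_demand(hist["lc2012"], regions, rate_table)
        receiving = scen_mod.secondary_by_region(hist["lc2012"], regions)
        rate_table = scen_mod.leakage_transfer(rate_table, demand, receiving)
    return {
        "scenario": scenario,
        "regions": regions,
        "weights": weights,
        "rates": rate_table,
        "app": app,
    }


def simulate_scenario(
    built: dict,
    hist: dict,
    cfg: RunConfig,
    seed: int | None = None,
) -> dict:
    """Run one scenario 13 years from the 2012 map, with optional yearly
    road growth feeding back into clearing rates."""
    land = hist["land"]
    scenario = built["scenario"]
    state = engine.SimulationState.from_landcover(
        hist["lc2012"].like(hist["lc2012"].values.copy(), role="landcover"),
        year=cfg.start_year,
        seed=seed if seed is not None else child_seed(cfg.seed, f"sim:{scenario.name}"),
        initial_secondary_age=cfg.carbon.initial_secondary_age,
        roads=land.roads,
    )
    rate_table = built["rates"].copy()
    variables = dict(land.static)
    snapshots = [(state.lc.values.copy(), state.secondary_age.copy())]
    reg_vals = built["regions"].values
    friction = roads_mod.friction_from_layers(
        variables["dist_roads"], variables["dist_rivers"], variables["slope"],
        land.cu | land.il,
    )
    rng_roads = np.random.default_rng(child_seed(cfg.seed, f"roads:{scenario.name}"))

    for _ in range(cfg.years):
        engine.step(
            state, rate_table, built["weights"], built["regions"], variables,
            restrictions=set(scenario.forbidden), urban_mask=land.urban_mask,
        )
        if cfg.road_budget_km > 0:
            new_net, built_km = roads_mod.build_roads(
                state.roads, friction, cfg.road_budget_km, state.lc, rng=rng_roads
            )
            if built_km > 0:
                new_lines = new_net[len(state.roads):]
                new_by_region, total_by_region = _road_lengths(
                    state.roads, new_lines, reg_vals, state.lc
                )
                rate_table = roads_mod.update_rates(
                    rate_table, new_by_region, total_by_region, beta=cfg.beta
                )
                state.roads = new_net
                road_mask = roads_mod.rasterize_lines(new_net, state.lc)
                from scipy import ndimage as _ndi
                variables["dist_roads"] = (
                    _ndi.distance_transform_edt(~road_mask) * state.lc.cell_size
                )
        snapshots.append((state.lc.values.copy(), state.secondary_age.copy()))

    areas = pd.DataFrame(
        [class_areas(state.lc.like(s[0], role="landcover")).rename(cfg.start_year + i)
         for i, s in enumerate(snapshots)]
    )
    areas.index.name = "year"
    return {"snapshots": snapshots, "state": state, "areas": areas}


def _road_lengths(old: list, new: list, reg_vals: np.ndarray, template: GridMap) -> tuple:
    """Apportion new and total network length (km) to regions by rasterized
    cell membership."""
    cell_km = template.cell_size / 1000.0
    new_by, tot_by = {}, {}
    for lines, acc in ((new, new_by), (old + new, tot_by)):
        for line in lines:
            mask = roads_mod.rasterize_lines([line], template)
            for r, n in zip(*np.unique(reg_vals[mask], return_counts=True)):
                if r >= 0:
                    acc[int(r)] = acc.get(int(r), 0.0) + float(n) * cell_km
    return new_by, tot_by


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Execute every stage and write rasters, tables and a summary under
    *out_dir*. Deterministic given cfg.seed. Returns the in-memory results."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")
    cfg.to_yaml(out / "run_config.yaml")

    log.info("stage synth: generating %dx%d landscape", cfg.n_rows, cfg.n_cols)
    hist = synthesize_history(cfg)
    for tag in ("lc2005", "lc2008", "lc2010", "lc2012"):
        write_grid(hist[tag], out / f"{tag}.asc")

    log.info("stage validate-calibration: simulating 2005-2012 with fitted model")
    val_built = build_scenario("BASELINE", hist, cfg)
    val_state = engine.SimulationState.from_landcover(
        hist["lc2005"].like(hist["lc2005"].values.copy(), role="landcover"),
        year=2005, seed=child_seed(cfg.seed, "validate"),
        initial_secondary_age=cfg.carbon.initial_secondary_age,
    )
    for _ in range(7):
        engine.step(val_state, val_built["rates"], val_built["weights"],
                    val_built["regions"], hist["land"].static,
                    urban_mask=hist["land"].urban_mask)
    sim2012 = val_state.lc
    fuzz = validation.fuzzy_similarity(hist["lc2005"], hist["lc2012"], sim2012,
                                       windows=cfg.windows)
    fuzz.to_csv(out / "fuzzy_similarity.csv", index=False)
    quant = validation.quantitative_validation(hist["lc2012"], sim2012)
    quant.to_csv(out / "quantitative_validation.csv", index=False)

    results = {"hist": hist, "fuzzy": fuzz, "quantitative": quant, "scenarios": {}}
    forest_c = forest_carbon(hist["land"].biomass, cfg.carbon).values
    ledgers, finals = [], {}
    for name in cfg.scenario_names:
        log.info("stage simulate: scenario %s (%d years)", name, cfg.years)
        built = build_scenario(name, hist, cfg)
        built["rates"].to_csv(out / f"rates_{name}.csv")
        built["weights"].to_csv(out / f"weights_{name}.csv")
        write_grid(built["regions"], out / f"regions_{name}.asc")
        run = simulate_scenario(built, hist, cfg)
        run["areas"].to_csv(out / f"class_areas_{name}.csv")
        final_lc = hist["lc2012"].like(run["snapshots"][-1][0], role="landcover")
        write_grid(final_lc, out / f"lc_final_{name}.asc")
        finals[name] = final_lc
        ledger = ledger_from_run(
            run["snapshots"], forest_c, hist["lc2012"].cell_area_ha,
            cfg.start_year, name, cfg.carbon, regions=built["regions"].values,
        )
        ledgers.append(ledger)
        results["scenarios"][name] = {"built": built, "run": run, "ledger": ledger}

    ledger_all = pd.concat(ledgers, ignore_index=True)
    ledger_all.to_csv(out / "carbon_ledger.csv", index=False)
    comp = validation.compare_scenarios(hist["lc2012"], finals)
    comp.to_csv(out / "scenario_comparison.csv", index=False)
    summary = {
        name: summarize(
            results["scenarios"][name]["ledger"],
            results["scenarios"][name]["run"]["areas"]["FOREST"],
        )[name]
        for name in cfg.scenario_names
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    results["comparison"] = comp
    results["summary"] = summary
    log.info("run complete: %s", out)
    return results
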