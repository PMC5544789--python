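"""Carbon stock and committed-emission accounting.

Forest carbon is 0.485 of total (above- plus below-ground) dry biomass;
secondary-vegetation carbon is 0.45 of a dry biomass that accumulates
linearly with stand age at a configurable growth rate. Clearing releases a
cell's full carbon content in the clearing year (committed, instantaneous
emission); secondary regrowth absorbs carbon, so a year's net emission is
gross release minus uptake. The ledger is closed-system: the stock drop
between consecutive years equals that year's net emission exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import GridMap, LandCover

__all__ = [
    "CarbonParams", "forest_carbon", "secondary_carbon", "carbon_stock",
    "annual_emission", "ledger_from_run", "summarize", "mean_annual_loss",
]


@dataclass(frozen=True)
class CarbonParams:
    """Carbon-accounting constants.

    forest_carbon_fraction: carbon share of forest dry biomass (0.485).
    secondary_carbon_fraction: carbon share of secondary-forest dry
    biomass (0.45). secondary_growth: mean dry-biomass accumulation of
    regrowth on abandoned pasture, Mg/ha/yr (default 10.0; site-specific,
    and every bundled check is written to be independent of its value).
    initial_secondary_age: mean age (yr) assigned to secondary vegetation
    present in the initial map (5). age_cap: optional ceiling on the age
    used for accumulation (None = uncapped; simulation horizons are short).
    """

    forest_carbon_fraction: float = 0.485
    secondary_carbon_fraction: float = 0.45
    secondary_growth: float = 10.0
    initial_secondary_age: int = 5
    age_cap: int | None = None

    def __post_init__(self) -> None:
        for name in ("forest_carbon_fraction", "secondary_carbon_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if self.secondary_growth < 0:
            raise ValueError("secondary_growth must be >= 0")


def forest_carbon(biomass: GridMap, params: CarbonParams = CarbonParams()) -> GridMap:
    """Forest carbon density map (MgC/ha) = biomass x carbon fraction."""
    if (biomass.values[biomass.mask] < 0).any():
        raise ValueError("biomass must be >= 0")
    return biomass.like(biomass.values * params.forest_carbon_fraction)


def secondary_carbon(age, params: CarbonParams = CarbonParams()):
    """Secondary-vegetation carbon density (MgC/ha) at a given stand age:
    carbon fraction x growth rate x age, linear and uncapped by default."""
    age = np.asarray(age, dtype=float)
    if (age < 0).any():
        raise ValueError("age must be >= 0")
    if params.age_cap is not None:
        age = np.minimum(age, params.age_cap)
    out = params.secondary_carbon_fraction * params.secondary_growth * age
    return float(out) if out.ndim == 0 else out


def carbon_stock(
    lc: np.ndarray,
    secondary_age: np.ndarray,
    forest_c_density: np.ndarray,
    cell_area_ha: float,
    params: CarbonParams = CarbonParams(),
    region_mask: np.ndarray | None = None,
) -> float:
    """Total stock (MgC) over forest and secondary cells (optionally within
    a region mask)."""
    if region_mask is None:
        region_mask = np.ones(lc.shape, dtype=bool)
    f = (lc == LandCover.FOREST) & region_mask
    s = (lc == LandCover.SECONDARY) & region_mask
    stock = forest_c_density[f].sum() * cell_area_ha
    stock += secondary_carbon(secondary_age[s], params).sum() * cell_area_ha
    return float(stock)


def annual_emission(
    lc_t: np.ndarray,
    lc_t1: np.ndarray,
    age_t: np.ndarray,
    age_t1: np.ndarray,
    forest_c_density: np.ndarray,
    cell_area_ha: float,
    params: CarbonParams = CarbonParams(),
    region_mask: np.ndarray | None = None,
) -> dict:
    """One ledger row for a consecutive year pair.

    gross: committed release — forest carbon of cells cleared plus
    secondary carbon (at its age when cut) of secondary cells cut.
    uptake: one year's accumulation over every cell that remains or enters
    SECONDARY. net = gross - uptake (negative in pure-regrowth years).
    """
    if lc_t.shape != lc_t1.shape:
        raise ValueError("year maps must share one grid")
    if region_mask is None:
        region_mask = np.ones(lc_t.shape, dtype=bool)
    cleared = (lc_t == LandCover.FOREST) & (lc_t1 == LandCover.DEFORESTED) & region_mask
    cut = (lc_t == LandCover.SECONDARY) & (lc_t1 == LandCover.DEFORESTED) & region_mask
    gross = forest_c_density[cleared].sum() * cell_area_ha
    gross += secondary_carbon(age_t[cut], params).sum() * cell_area_ha

    secondary_now = (lc_t1 == LandCover.SECONDARY) & region_mask
    per_ha = params.secondary_carbon_fraction * params.secondary_growth
    uptake = per_ha * cell_area_ha * int(secondary_now.sum())

    return {
        "gross_MgC": float(gross),
        "uptake_MgC": float(uptake),
        "net_MgC": float(gross - uptake),
    }


def ledger_from_run(
    snapshots: list,
    forest_c_density: np.ndarray,
    cell_area_ha: float,
    start_year: int,
    scenario: str,
    params: CarbonParams = CarbonParams(),
    regions: np.ndarray | None = None,
) -> pd.DataFrame:
    """Carbon ledger for a run: one row per year (x region when a region
    map is given) with stock, gross, uptake and net emission in MgC.

    snapshots are (land-cover array, secondary-age array) pairs as returned
    by the engine, the first being the initial state.
    """
    masks = {"ALL": None}
    if regions is not None:
        for r in np.unique(regions[regions >= 0]):
            masks[int(r)] = regions == r
    rows = []
    for name, mask in masks.items():
        lc0, age0 = snapshots[0]
        prev_stock = carbon_stock(lc0, age0, forest_c_density, cell_area_ha, params, mask)
        rows.append(
            {"year": start_year, "scenario": scenario, "region": name,
             "stock_MgC": prev_stock, "gross_MgC": 0.0, "uptake_MgC": 0.0, "net_MgC": 0.0}
        )
        for i in range(1, len(snapshots)):
            lc_t, age_t = snapshots[i - 1]
            lc_t1, age_t1 = snapshots[i]
            row = annual_emission(
                lc_t, lc_t1, age_t, age_t1, forest_c_density, cell_area_ha, params, mask
            )
            stock = carbon_stock(lc_t1, age_t1, forest_c_density, cell_area_ha, params, mask)
            rows.append(
                {"year": start_year + i, "scenario": scenario, "region": name,
                 "stock_MgC": stock, **row}
            )
            prev_stock = stock
    return pd.DataFrame(rows)


def mean_annual_loss(total_loss_km2: float, iterations: int) -> float:
    """Average annual forest loss (km²/yr) over a run: total reduction in
    forest area divided by the number of iterations."""
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    return total_loss_km2 / iterations


def summarize(
    ledger: pd.DataFrame,
    forest_area_km2: pd.Series | None = None,
) -> dict:
    """Per-scenario totals from a (possibly multi-scenario) ledger.

    Returns, per scenario: initial and final whole-area stock, cumulative
    net emission, percentage stock reduction, and — when a per-year forest
    area series is supplied — the mean annual forest loss in km²/yr.
    """
    out = {}
    for scen, grp in ledger[ledger["region"] == "ALL"].groupby("scenario"):
        grp = grp.sort_values("year")
        initial = float(grp["stock_MgC"].iloc[0])
        final = float(grp["stock_MgC"].iloc[-1])
        entry = {
            "initial_stock_MgC": initial,
            "final_stock_MgC": final,
            "cumulative_net_MgC": float(grp["net_MgC"].sum()),
            "stock_reduction_pct": 100.0 * (initial - final) / initial if initial else 0.0,
            "iterations": int(len(grp) - 1),
        }
        if forest_area_km2 is not None:
            total_loss = float(forest_area_km2.iloc[0] - forest_area_km2.iloc[-1])
            entry["mean_annual_forest_loss_km2"] = mean_annual_loss(
                total_loss, len(forest_area_km2) - 1
            )
        out[scen] = entry
    return out
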