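"""Forest-Code scenarios: riparian buffers, region assembly, leakage.

Brazil's Forest Code protects a riparian strip (APP, "area of permanent
preservation") along every watercourse, with a width that steps up with
channel width. The 1965 code (Law 4771/1965) measures the strip from the
maximum water level — outward from the floodplain edge — while the 2012
code (Law 12,651/2012) measures from the "regular" (minimum) channel, so
it protects strictly less land wherever floodplains are wider than
channels.

Three scenarios are modeled over 2013-2025:

* BASELINE — historical behavior; no APP restriction (six regions).
* CODE1965 — no clearing in the wide 1965 APP; the clearing demand that
  would have fallen there leaks into unprotected regions as extra
  secondary-vegetation cutting.
* CODE2012 — no clearing in the narrower 2012 APP, except that the part of
  the APP already cleared by 2008 (the APP2008 region) keeps its
  secondary-cutting transition (seven regions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely.ops import unary_union

from .grids import GridMap, LandCover, Region, RiverNetwork
from .rates import RateTable, F_TO_D, S_TO_D

__all__ = [
    "AppRule", "ScenarioConfig", "app_buffer", "build_regions",
    "leakage_transfer", "baseline", "code1965", "code2012",
]

MAX_WATER_LEVEL = "max_water_level"
REGULAR_CHANNEL = "regular_channel"


@dataclass(frozen=True)
class AppRule:
    """Width-class table mapping watercourse width to APP buffer width (m).

    Default is the Law 12,651/2012 table: <30 m -> 30 m; 30-50 m -> 50 m;
    50-200 m -> 100 m; 200-600 m -> 200 m; >600 m -> 500 m. (Narrow rivers
    get a single modeled 30-m buffer at the 30-m grid resolution.)
    """

    classes: tuple = (
        (0.0, 30.0, 30.0),
        (30.0, 50.0, 50.0),
        (50.0, 200.0, 100.0),
        (200.0, 600.0, 200.0),
        (600.0, float("inf"), 500.0),
    )

    def __post_init__(self) -> None:
        prev_hi, prev_buf = 0.0, 0.0
        for lo, hi, buf in self.classes:
            if lo != prev_hi:
                raise ValueError("width classes must tile (0, inf) with no gaps")
            if buf < prev_buf:
                raise ValueError("buffer width must be non-decreasing in channel width")
            prev_hi, prev_buf = hi, buf

    def buffer_width(self, channel_width_m: float) -> float:
        """APP buffer width (m) for a watercourse of the given width.

        The narrow class is strictly < 30 m (wider rivers are measured);
        upper boundaries are inclusive, so the >600 m class starts above
        600 m.
        """
        if channel_width_m <= 0:
            raise ValueError(f"channel width must be positive, got {channel_width_m}")
        first_lo, first_hi, first_buf = self.classes[0]
        if channel_width_m < first_hi:
            return first_buf
        for lo, hi, buf in self.classes[1:]:
            if channel_width_m <= hi:
                return buf
        raise AssertionError("width classes tile (0, inf)")  # pragma: no cover


@dataclass(frozen=True)
class ScenarioConfig:
    """Rules for one scenario: APP reference level, forbidden transitions,
    leakage, and the number of model regions."""

    name: str
    app_reference: str
    forbidden: frozenset = frozenset()  # {(region_code, transition)}
    leakage_enabled: bool = False
    regions_used: int = 6

    def __post_init__(self) -> None:
        if self.name == "CODE2012":
            if self.regions_used != 7 or self.app_reference != REGULAR_CHANNEL:
                raise ValueError(
                    "CODE2012 requires 7 regions and the regular-channel APP reference"
                )
        if self.name == "CODE1965" and not self.leakage_enabled:
            raise ValueError("CODE1965 requires leakage_enabled")


def baseline() -> ScenarioConfig:
    """Historical behavior; APPs (1965 delineation) carry no restriction."""
    return ScenarioConfig(name="BASELINE", app_reference=MAX_WATER_LEVEL)


def code1965() -> ScenarioConfig:
    """Full compliance with Law 4771/1965: no clearing of forest or
    secondary vegetation inside the max-water-level APP, with leakage."""
    forbidden = frozenset({(int(Region.APP), F_TO_D), (int(Region.APP), S_TO_D)})
    return ScenarioConfig(
        name="CODE1965", app_reference=MAX_WATER_LEVEL,
        forbidden=forbidden, leakage_enabled=True,
    )


def code2012() -> ScenarioConfig:
    """Full compliance with Law 12,651/2012: no clearing in the
    regular-channel APP; secondary cutting stays permitted in APP2008."""
    forbidden = frozenset({(int(Region.APP), F_TO_D), (int(Region.APP), S_TO_D),
                           (int(Region.APP2008), F_TO_D)})
    return ScenarioConfig(
        name="CODE2012", app_reference=REGULAR_CHANNEL,
        forbidden=forbidden, regions_used=7,
    )


# ---------------------------------------------------------------------------
# buffers and regions
# ---------------------------------------------------------------------------

def _rasterize_polygon(geom, template: GridMap) -> np.ndarray:
    """Cells whose centers fall inside *geom*."""
    import shapely

    rows, cols = np.mgrid[0 : template.n_rows, 0 : template.n_cols]
    x0, ytop = template.origin
    cs = template.cell_size
    xs = x0 + (cols + 0.5) * cs
    ys = ytop - (rows + 0.5) * cs
    return shapely.contains_xy(geom, xs.ravel(), ys.ravel()).reshape(rows.shape)


def app_buffer(
    rivers: RiverNetwork,
    rule: AppRule,
    reference: str,
    template: GridMap,
) -> GridMap:
    """Rasterized APP membership (1 inside the buffer union, else 0).

    Under REGULAR_CHANNEL the class width and buffer distance use the
    regular (minimum) channel; under MAX_WATER_LEVEL they use the
    maximum-water-level width, measuring outward from the floodplain edge,
    and the floodplain itself (where provided) is included.
    """
    geoms = []
    for line, reg_w, max_w in rivers.reaches:
        width = reg_w if reference == REGULAR_CHANNEL else max_w
        if width <= 0:
            raise ValueError(f"non-positive channel width {width}")
        app_w = rule.buffer_width(width)
        # buffer measured outward from the channel/floodplain edge, so the
        # centerline distance is half the reference width plus the APP width
        geoms.append(line.buffer(width / 2.0 + app_w, cap_style="flat"))
    mask = np.zeros((template.n_rows, template.n_cols), dtype=np.int64)
    if geoms:
        mask |= _rasterize_polygon(unary_union(geoms), template)
    if reference == MAX_WATER_LEVEL and rivers.floodplain_mask is not None:
        mask |= rivers.floodplain_mask.values.astype(np.int64)
    return template.like(mask, role="binary")


def build_regions(
    cu: np.ndarray,
    il: np.ndarray,
    rivers: RiverNetwork,
    road_influence: np.ndarray,
    app: GridMap,
    scenario: ScenarioConfig,
    template: GridMap,
    lc_2008: GridMap | None = None,
) -> GridMap:
    """Assemble the region map for a scenario.

    Base split is isolated areas vs road influence; the 1-km river buffer
    (rivers >= 30 m wide), indigenous lands and conservation units override
    in that order. The APP then overrides everything except CU and IR; under
    CODE2012 the part of the APP cleared by 2008 becomes APP2008.
    """
    reg = np.full((template.n_rows, template.n_cols), int(Region.IA), dtype=np.int64)

    wide = [line for line, reg_w, _ in rivers.reaches if reg_w >= 30.0]
    if wide:
        rb_geom = unary_union([ln.buffer(1000.0) for ln in wide])
        reg[_rasterize_polygon(rb_geom, template)] = int(Region.RB)

    # riverside cells under road influence follow road dynamics
    reg[road_influence.astype(bool)] = int(Region.IR)
    reg[il.astype(bool)] = int(Region.IL)
    reg[cu.astype(bool)] = int(Region.CU)

    app_cells = app.values.astype(bool)
    overridable = ~np.isin(reg, [int(Region.CU), int(Region.IR)])
    reg[app_cells & overridable] = int(Region.APP)

    if scenario.regions_used == 7:
        if lc_2008 is None:
            raise ValueError("CODE2012 scenario requires the 2008 land-cover map")
        cleared = np.isin(lc_2008.values, [int(LandCover.DEFORESTED), int(LandCover.SECONDARY)])
        reg[(reg == int(Region.APP)) & cleared] = int(Region.APP2008)

    reg[~template.mask] = int(template.nodata) if isinstance(template.nodata, (int, np.integer)) else -9999
    out = template.like(reg, role="region")
    return out


# ---------------------------------------------------------------------------
# leakage
# ---------------------------------------------------------------------------

def leakage_transfer(
    rate_table: RateTable,
    app_demand: dict,
    receiving_secondary: dict,
) -> RateTable:
    """Displace the APP's clearing demand into unprotected regions.

    *app_demand* maps each forbidden APP transition to its annual cell
    demand; *receiving_secondary* maps receiving region codes to their
    secondary-vegetation source-cell counts. APP clearing rates are zeroed
    and the displaced total is spread over receiving regions in proportion
    to their secondary area, arriving as additive increments to the
    secondary-cutting net rate. Because shares are proportional to source
    areas, every receiving region gets the same rate increment
    displaced_total / total_secondary, and summing increment x source area
    over regions returns the displaced demand exactly.
    """
    out = rate_table.copy()
    app = int(Region.APP)
    for tr in (F_TO_D, S_TO_D):
        if (app, tr) in out.rates:
            out.rates[(app, tr)] = 0.0
    displaced = float(sum(app_demand.values()))
    if displaced == 0:
        return out
    total_secondary = float(sum(receiving_secondary.values()))
    if total_secondary <= 0:
        warnings.warn(
            f"leakage: {displaced:.0f} cells/yr of displaced demand dropped — "
            "no receiving secondary-vegetation cells",
            stacklevel=2,
        )
        return out
    increment = displaced / total_secondary
    for region, n_src in receiving_secondary.items():
        if n_src <= 0:
            continue
        key = (int(region), S_TO_D)
        out.rates[key] = float(np.clip(out.rates.get(key, 0.0) + increment, 0.0, 1.0))
    return out


def app_annual_demand(
    lc: GridMap, regions: GridMap, rate_table: RateTable
) -> dict:
    """Year-1 cell demand of the clearing transitions inside the APP."""
    app = int(Region.APP)
    demand = {}
    for tr in (F_TO_D, S_TO_D):
        src = tr[0]
        n = int(((lc.values == src) & (regions.values == app) & lc.mask).sum())
        demand[tr] = rate_table.get_rate(app, tr) * n
    return demand


def secondary_by_region(
    lc: GridMap, regions: GridMap, exclude: tuple = (Region.APP, Region.APP2008)
) -> dict:
    """Secondary-vegetation source cells per receiving (non-APP) region."""
    excl = {int(e) for e in exclude}
    out = {}
    for r in np.unique(regions.values[regions.values >= 0]):
        if int(r) in excl:
            continue
        out[int(r)] = int(
            ((lc.values == LandCover.SECONDARY) & (regions.values == r) & lc.mask).sum()
        )
    return out
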