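"""Synthetic study areas with known dynamics.

Generates complete landscapes — land cover, static evidence layers, a
river network spanning the buffer-rule width classes, roads, protected
areas and a biomass map — on which every downstream stage can be exercised
and, because the true transition rates are known, recovered.

The landscape emulates a southwestern-Amazonia frontier municipality:
mostly forest, with clearing clustered near roads and rivers, a major
highway along one edge, large protected blocks (conservation units and
indigenous lands) away from the road network, rivers in several width
classes whose floodplains are strictly wider than their channels, and a
small urban seat on the main river. Spatial structure comes from smoothed
Gaussian random fields thresholded into classes; the forward model used to
evolve the landscape between dates is the same conditionally-independent
susceptibility family the calibrator assumes, so parameter-recovery tests
are well-posed. All randomness is driven by explicit seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import LineString

from .grids import GridMap, LandCover, Region, RiverNetwork
from .rates import RateTable, PatchParams, F_TO_D, S_TO_D, D_TO_S
from .roads import rasterize_lines

__all__ = ["SynthConfig", "SyntheticLandscape", "default_rates",
           "generate_landscape", "evolve_landscape"]


class ConfigurationError(ValueError):
    """The requested landscape cannot be placed on the grid."""


def default_rates() -> RateTable:
    """Annual rates emulating a frontier municipality: fast clearing under
    road influence, slower along rivers, very slow in protected areas and
    isolated land; secondary vegetation is cut quickly and deforested land
    regenerates at a moderate rate."""
    t = RateTable(default_patch=PatchParams())
    clearing = {
        Region.CU: 0.001, Region.IL: 0.001, Region.RB: 0.010,
        Region.IR: 0.020, Region.IA: 0.003, Region.APP: 0.015,
    }
    for region, rate in clearing.items():
        t.set_rate(int(region), F_TO_D, rate)
    for region in clearing:
        t.set_rate(int(region), S_TO_D, 0.10 if region in (Region.IR, Region.RB, Region.APP) else 0.02)
        t.set_rate(int(region), D_TO_S, 0.05)
    return t


@dataclass
class SynthConfig:
    """Recipe for one synthetic study area.

    river_spec lists (regular_width_m, maxlevel_width_m) per river; the
    defaults span the buffer rule's width classes. protected_fraction is
    the approximate share of the grid inside CU + IL blocks.
    """

    n_rows: int = 200
    n_cols: int = 200
    seed: int = 0
    cell_size: float = 30.0
    true_rates: RateTable = field(default_factory=default_rates)
    river_spec: tuple = ((15.0, 40.0), (40.0, 90.0), (120.0, 260.0), (250.0, 520.0))
    road_spec: tuple = ()  # extra roads as ((x0, y0), (x1, y1)) in map units
    road_influence_m: float = 1500.0  # corridor width defining the IR region
    protected_fraction: float = 0.15
    deforested_fraction: float = 0.09
    secondary_share: float = 0.25  # share of cleared land regenerating at t0
    nonforest_fraction: float = 0.02
    biomass_mean: float = 350.0
    biomass_sd: float = 50.0

    def __post_init__(self) -> None:
        for name in ("protected_fraction", "deforested_fraction",
                     "secondary_share", "nonforest_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0,1], got {v}")
        for rate in self.true_rates.rates.values():
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"rate {rate} outside [0,1]")
        # every river needs its channel plus room between neighbors
        need = sum(max(1, int(round(w / self.cell_size))) + 4 for w, _ in self.river_spec)
        if self.river_spec and self.n_rows < need:
            raise ConfigurationError(
                f"grid of {self.n_rows} rows too small for {len(self.river_spec)} rivers "
                f"(needs >= {need})"
            )


@dataclass
class SyntheticLandscape:
    """Everything a run needs, on one shared grid."""

    lc: GridMap                    # land cover at t0
    static: dict                   # evidence layers: dist_roads, dist_rivers, altitude, slope, soil
    rivers: RiverNetwork
    roads: list                    # shapely LineStrings
    cu: np.ndarray                 # conservation-unit mask
    il: np.ndarray                 # indigenous-land mask
    road_influence: np.ndarray     # IR-region precursor mask
    urban_mask: np.ndarray
    biomass: GridMap               # Mg/ha total dry biomass where forest
    true_rates: RateTable


def _smooth_field(rng: np.random.Generator, shape: tuple, sigma: float) -> np.ndarray:
    """Spatially autocorrelated field in [0, 1]."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    lo, hi = f.min(), f.max()
    return (f - lo) / (hi - lo) if hi > lo else np.zeros(shape)


def _template(cfg: SynthConfig) -> GridMap:
    return GridMap(
        np.zeros((cfg.n_rows, cfg.n_cols), dtype=np.int64),
        cell_size=cfg.cell_size,
        origin=(0.0, cfg.n_rows * cfg.cell_size),
        nodata=-9999,
        role="int",
    )


def generate_landscape(cfg: SynthConfig) -> SyntheticLandscape:
    """Build the full study area. Deterministic given cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    shape = (cfg.n_rows, cfg.n_cols)
    template = _template(cfg)
    cs = cfg.cell_size
    width_m = cfg.n_cols * cs
    height_m = cfg.n_rows * cs

    # --- terrain ----------------------------------------------------------
    altitude = 100.0 + 200.0 * _smooth_field(rng, shape, sigma=12)
    gy, gx = np.gradient(altitude, cs)
    slope = 100.0 * np.hypot(gx, gy)  # percent

    # --- rivers: horizontal-ish, mildly sinuous, spanning width classes ---
    reaches = []
    channel = np.zeros(shape, dtype=bool)
    floodplain = np.zeros(shape, dtype=bool)
    n_riv = len(cfg.river_spec)
    for i, (reg_w, max_w) in enumerate(cfg.river_spec):
        frac = (i + 1) / (n_riv + 1)
        y0 = height_m * (1.0 - frac)
        amp = rng.uniform(2, 6) * cs
        phase = rng.uniform(0, 2 * np.pi)
        xs = np.linspace(0, width_m, 40)
        ys = y0 + amp * np.sin(2 * np.pi * xs / width_m * rng.uniform(1, 3) + phase)
        line = LineString(np.column_stack([xs, ys]))
        reaches.append((line, float(reg_w), float(max_w)))
        ch = _band_mask(line, reg_w, template)
        channel |= ch
        floodplain |= _band_mask(line, max_w, template) | ch
    rivers = RiverNetwork(
        reaches=reaches,
        floodplain_mask=template.like(floodplain.astype(np.int64), role="binary"),
    )

    # --- roads: a highway along the eastern edge plus feeder roads --------
    margin = 3 * cs
    roads = [LineString([(width_m - margin, 0.0), (width_m - margin, height_m)])]
    n_feeders = max(2, cfg.n_rows // 70)
    for k in range(n_feeders):
        y = height_m * (k + 1) / (n_feeders + 1) + rng.uniform(-5, 5) * cs
        x_end = width_m * rng.uniform(0.3, 0.6)
        roads.append(LineString([(width_m - margin, y), (x_end, y + rng.uniform(-10, 10) * cs)]))
    for (p0, p1) in cfg.road_spec:
        roads.append(LineString([p0, p1]))
    road_mask = rasterize_lines(roads, template)

    # --- distances --------------------------------------------------------
    dist_roads = ndimage.distance_transform_edt(~road_mask) * cs
    dist_rivers = ndimage.distance_transform_edt(~channel) * cs
    road_influence = dist_roads < cfg.road_influence_m

    # --- protected blocks away from the highway ---------------------------
    cu = np.zeros(shape, dtype=bool)
    il = np.zeros(shape, dtype=bool)
    if cfg.protected_fraction > 0:
        target = cfg.protected_fraction * cfg.n_rows * cfg.n_cols
        half = int(np.sqrt(target / 2.0))
        if half >= 1:
            # CU in the far northwest, IL in the far southwest
            cu[1 : 1 + half, 1 : 1 + half] = True
            il[cfg.n_rows - 1 - half : cfg.n_rows - 1, 1 : 1 + half] = True
            cu &= ~channel
            il &= ~channel

    # --- urban seat where the main river meets the highway ----------------
    urban = np.zeros(shape, dtype=bool)
    widest = int(np.argmax([r for _, r, _ in reaches])) if reaches else 0
    if reaches:
        c_urb = max(cfg.n_cols - 10, 0)
        col_band = channel[:, max(c_urb - 2, 0) : c_urb + 3]
        riv_rows = np.flatnonzero(col_band.any(axis=1))
        if riv_rows.size:
            r_urb = max(int(riv_rows.min()) - 4, 0)  # on the bank, not in the water
            urban[max(r_urb - 2, 0) : r_urb + 3, max(c_urb - 2, 0) : c_urb + 3] = True
            urban &= ~channel

    # --- land cover at t0 -------------------------------------------------
    lc = np.full(shape, int(LandCover.FOREST), dtype=np.int64)
    noise = _smooth_field(rng, shape, sigma=6)
    suscept = (
        0.6 * np.exp(-dist_roads / 1500.0)
        + 0.3 * np.exp(-dist_rivers / 1500.0)
        + 0.3 * noise
    )
    suscept[cu | il] *= 0.05  # protected areas historically little cleared
    convertible = ~(channel | urban)
    n_clear = int(cfg.deforested_fraction * convertible.sum())
    if n_clear > 0:
        flat = np.flatnonzero(convertible)
        order = np.argsort(suscept.ravel()[flat])[::-1]
        chosen = flat[order[:n_clear]]
        lc.ravel()[chosen] = int(LandCover.DEFORESTED)
        n_sec = int(cfg.secondary_share * n_clear)
        if n_sec > 0:
            sec = rng.choice(chosen, size=n_sec, replace=False)
            lc.ravel()[sec] = int(LandCover.SECONDARY)
    if cfg.nonforest_fraction > 0:
        nf_field = _smooth_field(rng, shape, sigma=8)
        thresh = np.quantile(nf_field, 1.0 - cfg.nonforest_fraction)
        nf = (nf_field >= thresh) & (lc == int(LandCover.FOREST)) & convertible
        lc[nf] = int(LandCover.NONFOREST)
    lc[channel] = int(LandCover.WATER)
    lc[urban] = int(LandCover.URBAN)

    lc_map = template.like(lc, role="landcover")

    # --- biomass: smooth field by "forest type" ---------------------------
    soil = (np.digitize(_smooth_field(rng, shape, sigma=15), [0.33, 0.66])).astype(np.int64)
    biomass = np.clip(
        cfg.biomass_mean + cfg.biomass_sd * (2.0 * _smooth_field(rng, shape, sigma=10) - 1.0)
        + 15.0 * soil,
        0.0,
        None,
    )
    static = {
        "dist_roads": dist_roads,
        "dist_rivers": dist_rivers,
        "altitude": altitude,
        "slope": slope,
        "soil": soil,
    }
    return SyntheticLandscape(
        lc=lc_map,
        static=static,
        rivers=rivers,
        roads=roads,
        cu=cu,
        il=il,
        road_influence=road_influence,
        urban_mask=urban,
        biomass=template.like(biomass, role="float"),
        true_rates=cfg.true_rates,
    )


def _band_mask(line, width_m: float, template: GridMap) -> np.ndarray:
    """Cells whose centers lie within width/2 of the line (the channel)."""
    import shapely

    geom = line.buffer(max(width_m / 2.0, template.cell_size / 2.0), cap_style="flat")
    rows, cols = np.mgrid[0 : template.n_rows, 0 : template.n_cols]
    x0, ytop = template.origin
    cs = template.cell_size
    xs = x0 + (cols + 0.5) * cs
    ys = ytop - (rows + 0.5) * cs
    return shapely.intersects_xy(geom, xs.ravel(), ys.ravel()).reshape(rows.shape)


def evolve_landscape(
    lc: GridMap,
    true_rates: RateTable,
    years: int,
    seed: int,
    regions: GridMap | None = None,
    susceptibility: np.ndarray | None = None,
) -> GridMap:
    """Advance a land-cover map with the known ("true") forward model.

    Each year, each eligible cell undergoes its region's transition
    independently with probability rate x w_i / mean(w), where w is the
    optional susceptibility surface (uniform by default), so the realized
    per-region annual fraction converges to the true rate as cell count
    grows. Transitions run in the engine's order: clearing, secondary
    cutting, regeneration.
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    rng = np.random.default_rng(seed)
    out = lc.values.copy()
    reg = regions.values if regions is not None else np.zeros(out.shape, dtype=np.int64)
    w = np.ones(out.shape) if susceptibility is None else np.asarray(susceptibility, dtype=float)
    for _ in range(years):
        # a cell cleared or cut this year must not regrow the same year,
        # matching the allocation engine's within-year ordering
        regrowable = out == int(LandCover.DEFORESTED)
        for tr in (F_TO_D, S_TO_D, D_TO_S):
            src, dst = tr
            converted = np.zeros(out.shape, dtype=bool)
            for r in np.unique(reg[reg >= 0]):
                rate = true_rates.get_rate(int(r), tr)
                if rate <= 0:
                    continue
                eligible = (out == src) & (reg == r) & lc.mask
                if tr == D_TO_S:
                    eligible &= regrowable
                n = int(eligible.sum())
                if n == 0:
                    continue
                wr = w[eligible]
                p = np.clip(rate * wr / wr.mean(), 0.0, 1.0)
                draw = rng.random(n) < p
                idx = np.flatnonzero(eligible)
                converted.ravel()[idx[draw]] = True
            out[converted] = dst
    return lc.like(out, role="landcover")
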