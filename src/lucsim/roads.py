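"""Road-network growth over a friction surface, with rate feedback.

Each year new road segments are traced as least-cost paths from the
existing network toward targets sampled from an attractiveness surface.
Roads and rivers attract road building (low friction); conservation units,
indigenous lands and steep slopes repel it (high or infinite friction).
The relative yearly increment of road length in a region then scales that
region's clearing rates multiplicatively — regions gaining access get
faster deforestation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import LineString
from skimage.graph import MCP_Geometric

from .grids import GridMap
from .rates import RateTable, F_TO_D

__all__ = ["FrictionSurface", "friction_from_layers", "rasterize_lines",
           "build_roads", "update_rates"]


@dataclass
class FrictionSurface:
    """Per-cell traversal cost; np.inf marks impassable cells."""

    cost: np.ndarray

    def __post_init__(self) -> None:
        self.cost = np.asarray(self.cost, dtype=float)
        finite = self.cost[np.isfinite(self.cost)]
        if finite.size and (finite <= 0).any():
            raise ValueError("friction costs must be positive")


def friction_from_layers(
    dist_roads: np.ndarray,
    dist_rivers: np.ndarray,
    slope: np.ndarray,
    protected: np.ndarray,
    attract_scale: float = 1000.0,
    slope_threshold: float = 20.0,
    protected_cost: float = np.inf,
) -> FrictionSurface:
    """Default multi-criteria friction: proximity to roads/rivers lowers
    cost, slopes above *slope_threshold* (%) and protected areas raise it."""
    cost = 1.0 + dist_roads / attract_scale + 0.5 * dist_rivers / attract_scale
    cost = np.where(slope > slope_threshold, cost * 10.0, cost)
    cost = np.where(protected, protected_cost, cost)
    return FrictionSurface(cost)


def rasterize_lines(lines: list, template: GridMap) -> np.ndarray:
    """Burn polylines onto the template grid (True where a line crosses a
    cell), sampling each segment at half-cell steps."""
    mask = np.zeros((template.n_rows, template.n_cols), dtype=bool)
    x0, ytop = template.origin
    cs = template.cell_size
    for line in lines:
        length = line.length
        n = max(int(length / (cs / 2.0)), 1)
        for d in np.linspace(0.0, length, n + 1):
            pt = line.interpolate(d)
            col = int((pt.x - x0) / cs)
            row = int((ytop - pt.y) / cs)
            if 0 <= row < template.n_rows and 0 <= col < template.n_cols:
                mask[row, col] = True
    return mask


def _cells_to_line(cells: list, template: GridMap) -> LineString:
    pts = [template.cell_center(r, c) for r, c in cells]
    if len(pts) == 1:
        pts = pts * 2
    return LineString(pts)


def least_cost_path(
    friction: FrictionSurface, sources: list, target: tuple
) -> tuple[list, float]:
    """Least-cost path (list of (row, col)) from the nearest source cell to
    *target*, and its accumulated cost. Raises ValueError if unreachable."""
    mcp = MCP_Geometric(friction.cost)
    costs, _ = mcp.find_costs(starts=sources, ends=[target])
    if not np.isfinite(costs[target]):
        raise ValueError("target unreachable through finite-friction cells")
    path = mcp.traceback(target)
    return [tuple(p) for p in path], float(costs[target])


def build_roads(
    network: list,
    friction: FrictionSurface,
    budget_km: float,
    template: GridMap,
    attractiveness: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    n_targets: int = 1,
) -> tuple[list, float]:
    """Extend the road network by up to *budget_km* of new least-cost
    segments toward probability-sampled high-attractiveness targets.

    Returns (extended network, km actually built). Impassable (infinite
    friction) cells are never crossed; unreachable targets are skipped.
    """
    if budget_km < 0:
        raise ValueError("budget must be >= 0")
    if budget_km == 0 or not network:
        return list(network), 0.0
    rng = rng or np.random.default_rng()
    road_mask = rasterize_lines(network, template)
    sources = [tuple(rc) for rc in np.argwhere(road_mask)]
    if not sources:
        return list(network), 0.0

    passable = np.isfinite(friction.cost) & ~road_mask
    if attractiveness is None:
        with np.errstate(divide="ignore"):
            attractiveness = np.where(passable, 1.0 / friction.cost, 0.0)
    att = np.where(passable, np.clip(attractiveness, 0.0, None), 0.0).ravel()
    if att.sum() <= 0:
        return list(network), 0.0

    new_net = list(network)
    built_km = 0.0
    cell_km = template.cell_size / 1000.0
    for _ in range(n_targets):
        if built_km >= budget_km:
            break
        flat = rng.choice(att.size, p=att / att.sum())
        target = tuple(int(v) for v in divmod(flat, template.n_cols))
        try:
            path, _ = least_cost_path(friction, sources, target)
        except ValueError:
            continue
        # truncate the segment to the remaining budget
        max_cells = int((budget_km - built_km) / cell_km)
        path = path[: max_cells + 1]
        if len(path) < 2:
            continue
        new_net.append(_cells_to_line(path, template))
        built_km += (len(path) - 1) * cell_km
        sources.extend(path)
    return new_net, built_km


def update_rates(
    base: RateTable,
    new_length_km: dict,
    network_length_km: dict,
    beta: float = 1.0,
    eps: float = 1e-9,
) -> RateTable:
    """Scale each region's clearing rate by the relative road increment:

        rate' = rate * (1 + beta * new_length / max(network_length, eps))

    clipped to [0, 1]. Only the forest-clearing transition responds to
    road growth.
    """
    out = base.copy()
    for (region, tr), rate in base.rates.items():
        if tuple(tr) != F_TO_D:
            continue
        dl = new_length_km.get(region, 0.0)
        total = network_length_km.get(region, 0.0)
        if dl < 0 or total < 0:
            raise ValueError("road lengths must be >= 0")
        scaled = rate * (1.0 + beta * dl / max(total, eps))
        out.rates[(region, tr)] = float(np.clip(scaled, 0.0, 1.0))
    return out
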