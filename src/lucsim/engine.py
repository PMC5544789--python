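"""Cellular-automata allocation engine.

Each iteration represents one year. Per region and transition, the annual
demand (rate x source-cell count) is allocated onto the grid by two
operators: the *expander* grows existing patches of the destination class
by converting cells 8-adjacent to them, and the *patcher* seeds new patches
whose sizes are drawn lognormally around the region's mean patch size.
Candidate cells come from the top ``demand * pruning_factor`` cells of the
posterior-probability surface and are sampled probability-weighted, so
allocation tracks the weights-of-evidence susceptibility while staying
stochastic.

Within a year transitions run in fixed order — forest clearing, secondary
cutting, then regeneration — so a cell cleared this year cannot regrow the
same year. Demand is rounded to the nearest cell with the residual fraction
carried across years to avoid systematic bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .calibration import EvidenceWeights, probability_surface
from .grids import GridMap, LandCover, IMMUTABLE_CLASSES
from .rates import RateTable, F_TO_D, S_TO_D, D_TO_S, TRANSITIONS, PatchParams

__all__ = ["SimulationState", "demand", "allocate", "step", "run_years"]

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class SimulationState:
    """Mutable state of one simulation run.

    secondary_age is >= 1 wherever the class is SECONDARY and 0 elsewhere;
    the year advances by 1 per iteration.
    """

    lc: GridMap
    year: int
    secondary_age: np.ndarray
    rng: np.random.Generator
    roads: list = field(default_factory=list)
    residuals: dict = field(default_factory=dict)  # (region, transition) -> float
    shortfalls: list = field(default_factory=list)

    @classmethod
    def from_landcover(
        cls,
        lc: GridMap,
        year: int,
        seed: int | np.random.Generator = 0,
        initial_secondary_age: int = 5,
        roads: list | None = None,
    ) -> "SimulationState":
        """Start a run from a land-cover map; secondary vegetation present in
        the initial map is assigned the mean initial age (5 years)."""
        age = np.where(lc.values == LandCover.SECONDARY, initial_secondary_age, 0)
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        return cls(lc=lc, year=year, secondary_age=age.astype(np.int32), rng=rng,
                   roads=list(roads or []))

    def check_invariants(self) -> None:
        sec = self.lc.values == LandCover.SECONDARY
        assert (self.secondary_age[sec] >= 1).all(), "secondary cell with age 0"
        assert (self.secondary_age[~sec] == 0).all(), "non-secondary cell with age > 0"


def demand(rate: float, source_count: int) -> int:
    """Number of cells to transition this iteration: round(rate x sources)."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must be in [0,1], got {rate}")
    return int(round(rate * source_count))


def _adjacent_to(mask: np.ndarray) -> np.ndarray:
    """Cells 8-adjacent to (but not inside) *mask*."""
    return ndimage.binary_dilation(mask, structure=_EIGHT) & ~mask


def _weighted_sample(rng, indices: np.ndarray, probs: np.ndarray, k: int) -> np.ndarray:
    k = min(k, indices.size)
    if k == 0:
        return indices[:0]
    total = probs.sum()
    if total <= 0:
        return rng.choice(indices, size=k, replace=False)
    return rng.choice(indices, size=k, replace=False, p=probs / total)


def allocate(
    state: SimulationState,
    transition: tuple,
    n_cells: int,
    prob: np.ndarray,
    params: PatchParams,
    region_mask: np.ndarray,
    pruning_factor: float = 10.0,
) -> int:
    """Convert ~*n_cells* cells of the transition's source class inside
    *region_mask*, expander first, then patcher. Returns cells converted.

    If demand exceeds the eligible candidates, all candidates convert and
    the shortfall is logged on the state.
    """
    if n_cells <= 0:
        return 0
    src, dst = transition
    lc = state.lc.values
    shape = lc.shape
    eligible = (lc == src) & region_mask & state.lc.mask
    flat_idx = np.flatnonzero(eligible)
    if flat_idx.size == 0:
        state.shortfalls.append((state.year, tuple(transition), n_cells))
        return 0

    # candidate pool: top (demand x pruning_factor) cells by probability
    pool_size = min(flat_idx.size, max(n_cells, int(math.ceil(n_cells * pruning_factor))))
    p_flat = prob.ravel()[flat_idx]
    order = np.argsort(p_flat)[::-1]
    pool = flat_idx[order[:pool_size]]
    pool_p = p_flat[order[:pool_size]]

    if n_cells > flat_idx.size:
        state.shortfalls.append((state.year, tuple(transition), n_cells - flat_idx.size))
        n_cells = flat_idx.size

    converted = np.zeros(shape, dtype=bool)
    n_done = 0

    # --- expander: grow existing destination-class patches ----------------
    n_expand = int(round(params.expander_fraction * n_cells))
    if n_expand > 0:
        frontier = _adjacent_to(lc == dst).ravel()[pool]
        exp_pool = pool[frontier]
        exp_p = pool_p[frontier]
        chosen = _weighted_sample(state.rng, exp_pool, exp_p, n_expand)
        converted.ravel()[chosen] = True
        n_done += chosen.size

    # --- patcher: seed and grow new patches -------------------------------
    cell_area_ha = state.lc.cell_area_ha
    mu_cells = max(params.mean_patch_size_ha / cell_area_ha, 1.0)
    var_cells = max(params.patch_size_variance / cell_area_ha**2, 1e-9)
    # lognormal parameterized by mean/variance on the natural scale
    sigma2 = math.log(1.0 + var_cells / mu_cells**2)
    mu_log = math.log(mu_cells) - sigma2 / 2.0

    avail = ~converted.ravel()[pool]
    while n_done < n_cells:
        open_pool = pool[avail]
        if open_pool.size == 0:
            state.shortfalls.append((state.year, tuple(transition), n_cells - n_done))
            break
        open_p = pool_p[avail]
        seed = _weighted_sample(state.rng, open_pool, open_p, 1)[0]
        size = max(1, int(round(state.rng.lognormal(mu_log, math.sqrt(sigma2)))))
        size = min(size, n_cells - n_done)
        patch = _grow_patch(state, seed, size, prob, eligible & ~converted, params)
        converted.ravel()[list(patch)] = True
        n_done += len(patch)
        avail = ~converted.ravel()[pool]

    # --- apply ------------------------------------------------------------
    lc[converted] = dst
    if dst == LandCover.SECONDARY:
        state.secondary_age[converted] = 1
    if src == LandCover.SECONDARY:
        state.secondary_age[converted] = 0
    return n_done


def _grow_patch(
    state: SimulationState,
    seed_flat: int,
    size: int,
    prob: np.ndarray,
    eligible: np.ndarray,
    params: PatchParams,
) -> set:
    """Grow a patch from a seed cell: repeatedly add the 8-neighbor that
    maximizes posterior probability + isometry x (converted-neighbor count)."""
    n_rows, n_cols = eligible.shape
    patch = {int(seed_flat)}
    in_patch = lambda r, c: (r * n_cols + c) in patch
    while len(patch) < size:
        best, best_score = None, -np.inf
        for flat in patch:
            r0, c0 = divmod(flat, n_cols)
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    r, c = r0 + dr, c0 + dc
                    if (dr == dc == 0) or not (0 <= r < n_rows and 0 <= c < n_cols):
                        continue
                    f = r * n_cols + c
                    if f in patch or not eligible[r, c]:
                        continue
                    n_conv = sum(
                        in_patch(r + i, c + j)
                        for i in (-1, 0, 1)
                        for j in (-1, 0, 1)
                        if not (i == j == 0) and 0 <= r + i < n_rows and 0 <= c + j < n_cols
                    )
                    score = prob[r, c] + params.isometry * n_conv
                    if score > best_score:
                        best, best_score = f, score
        if best is None:
            break
        patch.add(best)
    return patch


def step(
    state: SimulationState,
    rate_table: RateTable,
    weights: EvidenceWeights,
    regions: GridMap,
    variables: dict,
    restrictions: set = frozenset(),
    urban_mask: np.ndarray | None = None,
    pruning_factor: float = 10.0,
) -> SimulationState:
    """Advance the state by one year.

    All three transitions are applied per region in the order forest
    clearing, secondary cutting, regeneration. Restricted
    (region, transition) pairs allocate nothing. Regeneration is suppressed
    on URBAN cells and under the optional urban mask. Secondary ages advance
    at the end of the year; the residual of each rounded demand carries over.
    """
    lc = state.lc.values
    reg = regions.values
    before_secondary = lc == LandCover.SECONDARY
    # cells deforested at the start of the year: a cell cleared or cut this
    # year must not regrow the same year
    regrowable = lc == LandCover.DEFORESTED

    for tr in (F_TO_D, S_TO_D, D_TO_S):
        src, dst = tr
        for r in np.unique(reg[reg >= 0]):
            r = int(r)
            if (r, tuple(tr)) in restrictions:
                continue
            rate = rate_table.get_rate(r, tr)
            if rate <= 0:
                continue
            region_mask = reg == r
            if tr == D_TO_S:
                region_mask = region_mask & regrowable & (lc != LandCover.URBAN)
                if urban_mask is not None:
                    region_mask = region_mask & ~urban_mask
            n_src = int(((lc == src) & region_mask & state.lc.mask).sum())
            key = (r, tuple(tr))
            exact = rate * n_src + state.residuals.get(key, 0.0)
            n = int(round(exact))
            state.residuals[key] = exact - n
            if n <= 0:
                continue
            prob = probability_surface(weights, r, tr, variables, prior=min(max(rate, 1e-6), 1 - 1e-6))
            allocate(state, tr, n, prob, rate_table.get_patch(r, tr), region_mask,
                     pruning_factor=pruning_factor)

    # age bookkeeping: survivors age one year; cells regenerated this year
    # were set to age 1 in allocate and must not age again
    surviving = before_secondary & (lc == LandCover.SECONDARY)
    state.secondary_age[surviving] += 1
    state.year += 1
    state.check_invariants()
    return state


def run_years(
    state: SimulationState,
    years: int,
    rate_table: RateTable,
    weights: EvidenceWeights,
    regions: GridMap,
    variables: dict,
    restrictions: set = frozenset(),
    urban_mask: np.ndarray | None = None,
    callback=None,
) -> list:
    """Run *years* iterations, returning the per-year snapshots
    (land-cover array copy, secondary-age copy) including the initial state."""
    snapshots = [(state.lc.values.copy(), state.secondary_age.copy())]
    for _ in range(years):
        step(state, rate_table, weights, regions, variables,
             restrictions=restrictions, urban_mask=urban_mask)
        snapshots.append((state.lc.values.copy(), state.secondary_age.copy()))
        if callback is not None:
            callback(state)
    return snapshots
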