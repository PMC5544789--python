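"""Allocation engine: demand, patcher/expander, yearly step invariants."""

import numpy as np
import pytest

from lucsim.calibration import EvidenceWeights
from lucsim.engine import SimulationState, allocate, demand, run_years, step
from lucsim.grids import IMMUTABLE_CLASSES, LandCover
from lucsim.rates import D_TO_S, F_TO_D, S_TO_D, PatchParams, RateTable

from conftest import make_grid, uniform_landcover


def _state(values, seed=0, **kw):
    lc = make_grid(values)
    return SimulationState.from_landcover(lc, year=2012, seed=seed, **kw)


def _uniform_setup(n=30, code=LandCover.FOREST):
    state = _state(np.full((n, n), int(code)))
    regions = make_grid(np.zeros((n, n)), role="int")
    variables = {"x": np.zeros((n, n))}
    weights = EvidenceWeights()  # empty: probability surface equals the prior
    return state, regions, variables, weights


@pytest.mark.parametrize(
    "rate,count,expected",
    [(0.0, 500, 0), (0.02, 10_000, 200), (1.0, 777, 777), (0.5, 3, 2)],
)
def test_demand_arithmetic(rate, count, expected):
    assert demand(rate, count) == expected


def test_demand_rejects_rate_outside_unit_interval():
    with pytest.raises(ValueError):
        demand(1.2, 10)


def test_allocate_zero_demand_changes_nothing():
    state, regions, _, _ = _uniform_setup(10)
    before = state.lc.values.copy()
    n = allocate(state, F_TO_D, 0, np.full((10, 10), 0.5), PatchParams(),
                 np.ones((10, 10), dtype=bool))
    assert n == 0 and np.array_equal(state.lc.values, before)


def test_allocate_exact_demand_converted():
    state, _, _, _ = _uniform_setup(40)
    n = allocate(state, F_TO_D, 120, np.full((40, 40), 0.5), PatchParams(),
                 np.ones((40, 40), dtype=bool))
    assert n == 120
    assert (state.lc.values == LandCover.DEFORESTED).sum() == 120


def test_pure_expander_converts_the_frontier():
    """With expander_fraction 1 and demand equal to the candidate frontier,
    exactly the cells 8-adjacent to the existing patch convert."""
    values = np.full((8, 8), int(LandCover.FOREST))
    values[3:5, 3:5] = int(LandCover.DEFORESTED)  # 2x2 seed patch
    # frontier of a 2x2 block under 8-adjacency: 4x4 ring minus the patch = 12
    frontier = set()
    for r in range(8):
        for c in range(8):
            if values[r, c] == LandCover.DEFORESTED:
                continue
            if any(values[r + dr, c + dc] == LandCover.DEFORESTED
                   for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                   if 0 <= r + dr < 8 and 0 <= c + dc < 8):
                frontier.add((r, c))
    assert len(frontier) == 12
    state = _state(values, seed=5)
    params = PatchParams(expander_fraction=1.0)
    n = allocate(state, F_TO_D, 12, np.full((8, 8), 0.5), params,
                 np.ones((8, 8), dtype=bool), pruning_factor=100.0)
    converted = {
        (r, c)
        for r, c in zip(*np.nonzero(state.lc.values == LandCover.DEFORESTED))
    } - {(3, 3), (3, 4), (4, 3), (4, 4)}
    assert n == 12
    assert converted == frontier


def test_allocation_deterministic_under_fixed_seed():
    results = []
    for _ in range(2):
        state, regions, variables, weights = _uniform_setup(25)
        state.rng = np.random.default_rng(42)
        rates = RateTable()
        rates.set_rate(0, F_TO_D, 0.1)
        step(state, rates, weights, regions, variables)
        results.append(state.lc.values.copy())
    assert np.array_equal(results[0], results[1])


def test_demand_exceeding_candidates_converts_all_and_logs_shortfall():
    state, _, _, _ = _uniform_setup(5)
    n = allocate(state, F_TO_D, 60, np.full((5, 5), 0.5), PatchParams(),
                 np.ones((5, 5), dtype=bool))
    assert n == 25
    assert state.shortfalls and state.shortfalls[-1][2] == 35


def test_step_with_zero_rates_only_ages_advance():
    values = np.full((12, 12), int(LandCover.FOREST))
    values[0, :3] = int(LandCover.SECONDARY)
    state = _state(values)
    age_before = state.secondary_age.copy()
    regions = make_grid(np.zeros((12, 12)), role="int")
    step(state, RateTable(), EvidenceWeights(), regions, {"x": np.zeros((12, 12))})
    assert np.array_equal(state.lc.values, values)
    sec = values == int(LandCover.SECONDARY)
    assert (state.secondary_age[sec] == age_before[sec] + 1).all()
    assert state.year == 2013


def test_restriction_blocks_all_clearing_in_region():
    state, regions, variables, weights = _uniform_setup(30)
    reg = regions.values
    reg[:, :15] = 6  # protected strip
    rates = RateTable()
    rates.set_rate(0, F_TO_D, 0.2)
    rates.set_rate(6, F_TO_D, 0.2)
    restrictions = {(6, F_TO_D)}
    for _ in range(5):
        step(state, rates, weights, regions, variables, restrictions=restrictions)
    protected = state.lc.values[:, :15]
    assert (protected == LandCover.FOREST).all()
    assert (state.lc.values[:, 15:] == LandCover.DEFORESTED).any()


def test_conservation_of_total_cells_and_immutable_classes():
    rng = np.random.default_rng(8)
    values = rng.choice(
        [int(c) for c in LandCover], size=(40, 40),
        p=[0.6, 0.15, 0.1, 0.08, 0.05, 0.02],
    )
    state = _state(values, seed=2)
    regions = make_grid(np.zeros((40, 40)), role="int")
    variables = {"x": np.zeros((40, 40))}
    rates = RateTable()
    for tr, r in ((F_TO_D, 0.05), (S_TO_D, 0.2), (D_TO_S, 0.1)):
        rates.set_rate(0, tr, r)
    immutable_before = {c: (values == c).sum() for c in IMMUTABLE_CLASSES}
    for _ in range(6):
        step(state, rates, EvidenceWeights(), regions, variables)
        assert state.lc.values.size == values.size
        for c in IMMUTABLE_CLASSES:
            assert (state.lc.values == c).sum() == immutable_before[c]


def test_forest_monotone_nonincreasing_without_regeneration():
    state, regions, variables, weights = _uniform_setup(25)
    rates = RateTable()
    rates.set_rate(0, F_TO_D, 0.03)
    rates.set_rate(0, S_TO_D, 0.1)
    prev = (state.lc.values == LandCover.FOREST).sum()
    for _ in range(8):
        step(state, rates, weights, regions, variables)
        cur = (state.lc.values == LandCover.FOREST).sum()
        assert cur <= prev
        prev = cur


def test_urban_cells_never_regenerate():
    values = np.full((20, 20), int(LandCover.DEFORESTED))
    values[5:8, 5:8] = int(LandCover.URBAN)
    urban_mask = np.zeros((20, 20), dtype=bool)
    urban_mask[10:13, 10:13] = True  # deforested but urban-masked
    state = _state(values, seed=1)
    regions = make_grid(np.zeros((20, 20)), role="int")
    rates = RateTable()
    rates.set_rate(0, D_TO_S, 1.0)
    for _ in range(3):
        step(state, rates, EvidenceWeights(), regions, {"x": np.zeros((20, 20))},
             urban_mask=urban_mask)
    assert (state.lc.values[5:8, 5:8] == LandCover.URBAN).all()
    assert not (state.lc.values[urban_mask] == LandCover.SECONDARY).any()


def test_no_same_year_clear_then_regrow():
    """A secondary cell cut this year stays deforested until next year even
    at regeneration rate 1."""
    values = np.full((15, 15), int(LandCover.SECONDARY))
    state = _state(values, seed=3)
    regions = make_grid(np.zeros((15, 15)), role="int")
    rates = RateTable()
    rates.set_rate(0, S_TO_D, 0.5)
    rates.set_rate(0, D_TO_S, 1.0)
    step(state, rates, EvidenceWeights(), regions, {"x": np.zeros((15, 15))})
    assert (state.lc.values == LandCover.DEFORESTED).sum() > 0


def test_thirteen_year_compound_clearing_matches_expectation():
    """With a flat probability surface, cumulative clearing over 13 years
    tracks N(1 - (1-r)^13) closely (demand is near-deterministic)."""
    n = 60
    state, regions, variables, weights = _uniform_setup(n)
    r = 0.02
    rates = RateTable()
    rates.set_rate(0, F_TO_D, r)
    run_years(state, 13, rates, weights, regions, variables)
    expected_forest = n * n * (1.0 - r) ** 13
    got = (state.lc.values == LandCover.FOREST).sum()
    assert got == pytest.approx(expected_forest, rel=0.01)


def test_residual_demand_accumulates_across_years():
    # rate x sources = 0.45 cells/yr rounds to 0 each year alone, but the
    # carried residual must realize ~ 4-5 conversions over 10 years
    n = 30
    state, regions, variables, weights = _uniform_setup(n)
    rates = RateTable()
    rates.set_rate(0, F_TO_D, 0.0005)
    run_years(state, 10, rates, weights, regions, variables)
    cleared = (state.lc.values == LandCover.DEFORESTED).sum()
    assert 3 <= cleared <= 6


def test_secondary_age_invariant_maintained():
    values = np.full((20, 20), int(LandCover.DEFORESTED))
    state = _state(values, seed=9)
    regions = make_grid(np.zeros((20, 20)), role="int")
    rates = RateTable()
    rates.set_rate(0, D_TO_S, 0.3)
    rates.set_rate(0, S_TO_D, 0.2)
    for _ in range(6):
        step(state, rates, EvidenceWeights(), regions, {"x": np.zeros((20, 20))})
        state.check_invariants()  # raises on violation
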