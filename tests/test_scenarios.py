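"""Riparian-buffer rules, region assembly and leakage transfer."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import LineString

from lucsim.grids import LandCover, Region, RiverNetwork
from lucsim.rates import F_TO_D, S_TO_D, RateTable
from lucsim.scenarios import (
    MAX_WATER_LEVEL, REGULAR_CHANNEL, AppRule, ScenarioConfig,
    app_annual_demand, app_buffer, baseline, build_regions, code1965, code2012,
    leakage_transfer, secondary_by_region,
)

from conftest import make_grid, uniform_landcover


@pytest.mark.parametrize(
    "width,expected",
    [(10.0, 30.0), (29.9, 30.0), (30.0, 50.0), (40.0, 50.0), (50.0, 50.0),
     (150.0, 100.0), (200.0, 100.0), (400.0, 200.0), (600.0, 200.0),
     (700.0, 500.0), (5000.0, 500.0)],
)
def test_buffer_width_class_table(width, expected):
    assert AppRule().buffer_width(width) == expected


def test_buffer_width_rejects_nonpositive_width():
    with pytest.raises(ValueError, match="positive"):
        AppRule().buffer_width(0.0)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(a=st.floats(0.1, 2000.0), b=st.floats(0.1, 2000.0))
def test_buffer_width_monotone_in_channel_width(a, b):
    lo, hi = sorted((a, b))
    rule = AppRule()
    assert rule.buffer_width(lo) <= rule.buffer_width(hi)


def test_rule_table_must_tile_without_gaps():
    with pytest.raises(ValueError, match="gaps"):
        AppRule(classes=((0.0, 30.0, 30.0), (40.0, 50.0, 50.0)))
    with pytest.raises(ValueError, match="non-decreasing"):
        AppRule(classes=((0.0, 30.0, 50.0), (30.0, float("inf"), 30.0)))


def _straight_net(width_reg, width_max, n=60, cs=30.0):
    y = (n / 2) * cs
    line = LineString([(0.0, y), (n * cs, y)])
    template = make_grid(np.zeros((n, n)), role="int", cell_size=cs)
    return RiverNetwork(reaches=[(line, width_reg, width_max)]), template


def test_max_water_level_app_at_least_regular_channel_app():
    net, template = _straight_net(150.0, 400.0)
    app_reg = app_buffer(net, AppRule(), REGULAR_CHANNEL, template)
    app_max = app_buffer(net, AppRule(), MAX_WATER_LEVEL, template)
    assert app_max.values.sum() >= app_reg.values.sum()
    # wherever the regular-channel APP is, the max-level APP is too
    assert (app_max.values >= app_reg.values).all()


def test_app_area_with_floodplain_mask_included(small_land):
    app_max = app_buffer(small_land.rivers, AppRule(), MAX_WATER_LEVEL, small_land.lc)
    flood = small_land.rivers.floodplain_mask.values.astype(bool)
    assert (app_max.values.astype(bool) | ~flood).all()


def test_scenario_config_invariants():
    assert baseline().regions_used == 6
    assert code1965().leakage_enabled
    assert code2012().regions_used == 7
    with pytest.raises(ValueError):
        ScenarioConfig(name="CODE2012", app_reference=MAX_WATER_LEVEL,
                       regions_used=7)
    with pytest.raises(ValueError):
        ScenarioConfig(name="CODE1965", app_reference=MAX_WATER_LEVEL,
                       leakage_enabled=False)


def _region_inputs(n=40):
    cu = np.zeros((n, n), dtype=bool)
    il = np.zeros((n, n), dtype=bool)
    ir = np.zeros((n, n), dtype=bool)
    template = make_grid(np.zeros((n, n)), role="int")
    net, _ = _straight_net(150.0, 300.0, n=n)
    app = app_buffer(net, AppRule(), REGULAR_CHANNEL, template)
    return cu, il, ir, net, app, template


def test_app_overrides_isolated_area_but_not_cu_or_ir():
    cu, il, ir, net, app, template = _region_inputs()
    app_cells = app.values.astype(bool)
    r0, c0 = np.argwhere(app_cells)[0]
    cu[r0, c0] = True          # this APP cell is also a conservation unit
    rN, cN = np.argwhere(app_cells)[-1]
    ir[rN, cN] = True          # this APP cell is under road influence
    regions = build_regions(cu, il, net, ir, app, baseline(), template)
    assert regions.values[r0, c0] == Region.CU
    assert regions.values[rN, cN] == Region.IR
    # some APP cell in plain isolated area stays APP
    others = app_cells & ~cu & ~ir
    assert (regions.values[others] == Region.APP).all()


def test_river_buffer_region_only_for_wide_rivers():
    n = 60
    cu = il = ir = np.zeros((n, n), dtype=bool)
    template = make_grid(np.zeros((n, n)), role="int")
    narrow = RiverNetwork(
        reaches=[(LineString([(0, 900), (1800, 900)]), 20.0, 25.0)]
    )
    app = app_buffer(narrow, AppRule(), REGULAR_CHANNEL, template)
    regions = build_regions(cu, il, narrow, ir, app, baseline(), template)
    assert not (regions.values == Region.RB).any()


def test_code2012_requires_2008_landcover():
    cu, il, ir, net, app, template = _region_inputs()
    with pytest.raises(ValueError, match="2008"):
        build_regions(cu, il, net, ir, app, code2012(), template, lc_2008=None)


def test_app2008_is_the_cleared_part_of_the_app():
    cu, il, ir, net, app, template = _region_inputs()
    lc08 = uniform_landcover(40, 40, LandCover.FOREST)
    app_cells = np.argwhere(app.values.astype(bool))
    half = app_cells[: len(app_cells) // 2]
    for r, c in half:
        lc08.values[r, c] = int(LandCover.DEFORESTED)
    regions = build_regions(cu, il, net, ir, app, code2012(), template, lc_2008=lc08)
    for r, c in half:
        assert regions.values[r, c] == Region.APP2008
    rest = app_cells[len(app_cells) // 2:]
    assert all(regions.values[r, c] == Region.APP for r, c in rest)


# ---------------------------------------------------------------------------
# leakage
# ---------------------------------------------------------------------------

def _base_rates():
    t = RateTable()
    t.set_rate(int(Region.APP), F_TO_D, 0.02)
    t.set_rate(int(Region.APP), S_TO_D, 0.1)
    t.set_rate(int(Region.IR), S_TO_D, 0.05)
    t.set_rate(int(Region.IA), S_TO_D, 0.01)
    return t


def test_zero_app_demand_leaves_receiving_rates_unchanged():
    out = leakage_transfer(_base_rates(), {F_TO_D: 0.0, S_TO_D: 0.0},
                           {int(Region.IR): 400, int(Region.IA): 600})
    assert out.get_rate(int(Region.IR), S_TO_D) == pytest.approx(0.05)
    assert out.get_rate(int(Region.APP), F_TO_D) == 0.0  # still zeroed


def test_proportional_apportionment_hand_arithmetic():
    # 100 displaced cells/yr into regions holding 400 and 600 secondary
    # cells: shares 40 and 60, increments 40/400 = 60/600 = 0.10
    out = leakage_transfer(_base_rates(), {F_TO_D: 100.0},
                           {int(Region.IR): 400, int(Region.IA): 600})
    assert out.get_rate(int(Region.IR), S_TO_D) == pytest.approx(0.05 + 0.10)
    assert out.get_rate(int(Region.IA), S_TO_D) == pytest.approx(0.01 + 0.10)


def test_leakage_conserves_displaced_demand():
    base = _base_rates()
    receiving = {int(Region.IR): 350, int(Region.IA): 650, int(Region.RB): 123}
    demand = {F_TO_D: 77.0, S_TO_D: 33.0}
    out = leakage_transfer(base, demand, receiving)
    transferred = sum(
        (out.get_rate(r, S_TO_D) - base.get_rate(r, S_TO_D)) * n
        for r, n in receiving.items()
    )
    assert transferred == pytest.approx(sum(demand.values()), rel=1e-12)


def test_leakage_without_receivers_warns_and_drops():
    with pytest.warns(UserWarning, match="dropped"):
        out = leakage_transfer(_base_rates(), {F_TO_D: 50.0}, {})
    assert out.get_rate(int(Region.APP), F_TO_D) == 0.0


def test_app_demand_and_receiving_helpers(small_land):
    from lucsim.pipeline import RunConfig, synthesize_history, build_scenario

    cfg = RunConfig(seed=5, n_rows=80, n_cols=80)
    hist = synthesize_history(cfg)
    built = build_scenario("CODE1965", hist, cfg)
    demand = app_annual_demand(hist["lc2012"], built["regions"], _base_rates())
    assert set(demand) == {F_TO_D, S_TO_D}
    assert all(v >= 0 for v in demand.values())
    receiving = secondary_by_region(hist["lc2012"], built["regions"])
    assert int(Region.APP) not in receiving
    assert all(v >= 0 for v in receiving.values())
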