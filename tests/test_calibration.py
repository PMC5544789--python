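"""Weights-of-evidence estimation against brute-force contingency oracles."""

import warnings

import numpy as np
import pytest

from lucsim.calibration import (
    BinSpec, EvidenceWeights, compute_rates, compute_weights,
    posterior_probability, probability_surface, quantile_bins,
)
from lucsim.grids import LandCover
from lucsim.rates import F_TO_D, RateTable

from conftest import make_grid, uniform_landcover


def bayes_oracle(n_t_by_combo, n_not_by_combo):
    """Exhaustive contingency Bayes: P(T | combo) from raw joint counts."""
    return {
        combo: n_t_by_combo[combo] / (n_t_by_combo[combo] + n_not_by_combo[combo])
        for combo in n_t_by_combo
    }


def _maps_from_counts(counts):
    """Build (t0, t1, layers) grids realizing exact joint counts.

    counts: {(transitioned, a, b): n} over binary evidence layers a, b.
    """
    cells = []
    for (tr, a, b), n in counts.items():
        cells += [(tr, a, b)] * n
    n_cells = len(cells)
    side = int(np.ceil(np.sqrt(n_cells)))
    tr = np.zeros(side * side, dtype=np.int64)
    la = np.zeros(side * side, dtype=np.int64)
    lb = np.zeros(side * side, dtype=np.int64)
    for i, (t, a, b) in enumerate(cells):
        tr[i], la[i], lb[i] = t, a, b
    # pad with nodata so only the constructed cells count
    t0 = np.full(side * side, int(LandCover.FOREST), dtype=np.int64)
    t0[n_cells:] = -9999
    t1 = np.where(tr == 1, int(LandCover.DEFORESTED), int(LandCover.FOREST))
    t1[n_cells:] = -9999
    shape = (side, side)
    return (
        make_grid(t0.reshape(shape)),
        make_grid(t1.reshape(shape)),
        {"A": la.reshape(shape), "B": lb.reshape(shape)},
        n_cells,
    )


BINS_AB = {"A": BinSpec(categories=(0, 1)), "B": BinSpec(categories=(0, 1))}


def test_single_layer_weight_is_log_odds_ratio():
    # P(B|T) = 0.5, P(B|not-T) = 0.25 on a 1000-cell grid -> W+ = ln 2
    counts = {(1, 1, 0): 50, (1, 0, 0): 50, (0, 1, 0): 225, (0, 0, 0): 675}
    t0, t1, layers, _ = _maps_from_counts(counts)
    region = t0.like(np.where(t0.values == -9999, -9999, 0), role="int")
    ew = compute_weights(t0, t1, layers, {"A": BinSpec(categories=(0, 1))}, region,
                         transitions=(F_TO_D,))
    w = ew.get(0, F_TO_D)["A"]
    assert w[1] == pytest.approx(np.log(2.0), abs=1e-12)


def test_bin_with_proportional_occupancy_gets_zero_weight():
    # bin holds transitioned and untransitioned cells in proportion to totals
    counts = {(1, 1, 0): 20, (1, 0, 0): 80, (0, 1, 0): 180, (0, 0, 0): 720}
    t0, t1, layers, _ = _maps_from_counts(counts)
    region = t0.like(np.where(t0.values == -9999, -9999, 0), role="int")
    ew = compute_weights(t0, t1, layers, {"A": BinSpec(categories=(0, 1))}, region,
                         transitions=(F_TO_D,))
    assert ew.get(0, F_TO_D)["A"] == pytest.approx([0.0, 0.0], abs=1e-12)


def test_absent_transition_yields_zero_weights_and_warning():
    t0 = uniform_landcover(10, 10)
    t1 = uniform_landcover(10, 10)
    region = t0.like(np.zeros((10, 10), dtype=np.int64), role="int")
    with pytest.warns(UserWarning, match="absent"):
        ew = compute_weights(t0, t1, {"A": np.zeros((10, 10), dtype=np.int64)},
                             {"A": BinSpec(categories=(0,))}, region,
                             transitions=(F_TO_D,))
    assert (ew.get(0, F_TO_D)["A"] == 0).all()


def test_missing_variable_for_declared_bins_is_an_error():
    t0 = uniform_landcover(4, 4)
    region = t0.like(np.zeros((4, 4), dtype=np.int64), role="int")
    with pytest.raises(KeyError, match="missing variable"):
        compute_weights(t0, t0, {}, {"A": BinSpec(categories=(0,))}, region)


def test_posterior_equals_prior_when_all_weights_zero():
    assert posterior_probability(0.0, 0.37) == pytest.approx(0.37, abs=1e-15)


def test_posterior_hand_bayes():
    # prior 0.2 -> odds 0.25; one weight ln 2 doubles the odds -> P = 1/3
    assert posterior_probability(np.log(2.0), 0.2) == pytest.approx(1.0 / 3.0, abs=1e-12)


def test_posterior_monotone_in_weight_sum():
    ps = [posterior_probability(w, 0.3) for w in np.linspace(-3, 3, 13)]
    assert all(b > a for a, b in zip(ps, ps[1:]))
    assert all(0 < p < 1 for p in ps)


def test_two_layer_posterior_matches_exhaustive_frequency_oracle():
    """On a grid whose evidence layers are conditionally independent by
    construction, the combined posterior reproduces the per-combination
    transition frequency to 1e-10."""
    # counts factorize given T and given not-T, so the model family holds
    n_t, n_not = 400, 1600
    pa_t, pb_t = (0.5, 0.5), (0.25, 0.75)
    pa_n, pb_n = (0.75, 0.25), (0.5, 0.5)
    counts = {}
    for a in (0, 1):
        for b in (0, 1):
            counts[(1, a, b)] = int(round(n_t * pa_t[a] * pb_t[b]))
            counts[(0, a, b)] = int(round(n_not * pa_n[a] * pb_n[b]))
    t0, t1, layers, n_cells = _maps_from_counts(counts)
    region = t0.like(np.where(t0.values == -9999, -9999, 0), role="int")
    ew = compute_weights(t0, t1, layers, BINS_AB, region, transitions=(F_TO_D,))
    prior = n_t / (n_t + n_not)
    surf = probability_surface(ew, 0, F_TO_D, layers, prior)

    oracle = bayes_oracle(
        {k[1:]: v for k, v in counts.items() if k[0] == 1},
        {k[1:]: v for k, v in counts.items() if k[0] == 0},
    )
    flat = surf.ravel()[:n_cells]
    la, lb = layers["A"].ravel()[:n_cells], layers["B"].ravel()[:n_cells]
    for (a, b), expected in oracle.items():
        got = flat[(la == a) & (lb == b)]
        assert got == pytest.approx(expected, abs=1e-10)


def test_weights_invariant_to_bin_relabeling():
    counts = {(1, 1, 1): 30, (1, 0, 0): 70, (0, 1, 0): 300, (0, 0, 1): 600}
    t0, t1, layers, n_cells = _maps_from_counts(counts)
    region = t0.like(np.where(t0.values == -9999, -9999, 0), role="int")
    ew = compute_weights(t0, t1, layers, BINS_AB, region, transitions=(F_TO_D,))
    relabeled = {"A": BinSpec(categories=(1, 0)), "B": BinSpec(categories=(0, 1))}
    ew2 = compute_weights(t0, t1, layers, relabeled, region, transitions=(F_TO_D,))
    w, w2 = ew.get(0, F_TO_D), ew2.get(0, F_TO_D)
    assert w["A"][::-1] == pytest.approx(w2["A"], abs=1e-12)
    assert w["B"] == pytest.approx(w2["B"], abs=1e-12)


def test_identical_maps_give_zero_rates():
    t0 = uniform_landcover(10, 10)
    region = t0.like(np.zeros((10, 10), dtype=np.int64), role="int")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = compute_rates(t0, t0, region, years=5)
    assert all(r == 0 for r in table.rates.values())


def test_compound_annualization_closed_form():
    # 50 of 1000 forest cells cleared over 5 years: f = 0.05,
    # annual = 1 - 0.95^(1/5) ~ 0.010206
    values0 = np.full((25, 40), int(LandCover.FOREST))
    values1 = values0.copy()
    values1.ravel()[:50] = int(LandCover.DEFORESTED)
    region = make_grid(np.zeros((25, 40)), role="int")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = compute_rates(make_grid(values0), make_grid(values1), region, years=5)
    expected = 1.0 - 0.95 ** 0.2
    assert table.get_rate(0, F_TO_D) == pytest.approx(expected, rel=1e-12)
    assert expected == pytest.approx(0.01021, abs=5e-6)


def test_one_year_interval_annual_rate_equals_period_fraction():
    values0 = np.full((10, 10), int(LandCover.FOREST))
    values1 = values0.copy()
    values1.ravel()[:17] = int(LandCover.DEFORESTED)
    region = make_grid(np.zeros((10, 10)), role="int")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = compute_rates(make_grid(values0), make_grid(values1), region, years=1)
    assert table.get_rate(0, F_TO_D) == pytest.approx(0.17, rel=1e-12)


def test_zero_source_region_warns_and_rates_zero():
    t0 = uniform_landcover(6, 6, LandCover.WATER)
    region = t0.like(np.zeros((6, 6), dtype=np.int64), role="int")
    with pytest.warns(UserWarning, match="no .* source cells"):
        table = compute_rates(t0, t0, region, years=2)
    assert all(r == 0 for r in table.rates.values())


def test_weights_round_trip_through_csv(tmp_path):
    counts = {(1, 1, 1): 30, (1, 0, 0): 70, (0, 1, 0): 300, (0, 0, 1): 600}
    t0, t1, layers, _ = _maps_from_counts(counts)
    region = t0.like(np.where(t0.values == -9999, -9999, 0), role="int")
    ew = compute_weights(t0, t1, layers, BINS_AB, region, transitions=(F_TO_D,))
    ew.to_csv(tmp_path / "w.csv")
    back = EvidenceWeights.from_csv(tmp_path / "w.csv")
    for var in ("A", "B"):
        assert back.get(0, F_TO_D)[var] == pytest.approx(ew.get(0, F_TO_D)[var])


def test_quantile_bins_partition_observed_range():
    rng = np.random.default_rng(0)
    vals = rng.exponential(size=5000)
    spec = quantile_bins(vals, 10)
    idx = spec.assign(vals)
    assert idx.min() == 0 and idx.max() == spec.n_bins - 1
    counts = np.bincount(idx)
    assert (counts > 0.5 * len(vals) / spec.n_bins).all()
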