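"""Weights-of-evidence calibration and transition-rate estimation.

Given land-cover maps at two dates plus a stack of static evidence layers,
this module estimates (a) the spatial susceptibility of each cell to each
transition as a table of weights of evidence, and (b) annual transition
rates per region from the observed transition matrix.

Weights of evidence follow the Bonham-Carter positive-weight formulation:
for transition T and evidence bin B,

    W+(B) = ln[ P(B | T) / P(B | not-T) ]

computed over cells eligible for T at the first date. Per-cell transition
probability combines the weights additively on the log-odds scale under an
assumption of conditional independence between evidence layers:

    logit(P) = logit(prior) + sum_i W+_i .

Bins with no eligible cells, and transitions with no observed events, get
weight 0 ("no evidence"), keeping every posterior finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import GridMap, LandCover
from .rates import RateTable, TRANSITIONS, transition_name, transition_from_name

__all__ = [
    "BinSpec",
    "EvidenceWeights",
    "quantile_bins",
    "compute_weights",
    "posterior_probability",
    "probability_surface",
    "compute_rates",
]


@dataclass(frozen=True)
class BinSpec:
    """Discretization of one evidence variable.

    For continuous variables, ``breaks`` are interior cut points: bin k is
    (breaks[k-1], breaks[k]]. For categorical variables, ``categories``
    lists the codes and each code is its own bin.
    """

    breaks: tuple = ()
    categories: tuple = ()

    @property
    def is_categorical(self) -> bool:
        return len(self.categories) > 0

    @property
    def n_bins(self) -> int:
        if self.is_categorical:
            return len(self.categories)
        return len(self.breaks) + 1

    def assign(self, values: np.ndarray) -> np.ndarray:
        """Bin index per cell (categorical codes not listed map to -1)."""
        if self.is_categorical:
            lut = {c: i for i, c in enumerate(self.categories)}
            flat = np.array([lut.get(v, -1) for v in values.ravel()])
            return flat.reshape(values.shape)
        return np.searchsorted(np.asarray(self.breaks), values, side="left")


def quantile_bins(values: np.ndarray, n_bins: int = 10) -> BinSpec:
    """Default binning for a continuous variable: *n_bins* quantile bins."""
    qs = np.quantile(np.asarray(values, dtype=float).ravel(), np.linspace(0, 1, n_bins + 1)[1:-1])
    return BinSpec(breaks=tuple(np.unique(qs)))


@dataclass
class EvidenceWeights:
    """Per (region, transition, variable, bin) weights of evidence.

    ``weights[(region, transition)][variable]`` is an array of W+ values
    aligned with ``bins[variable]``.
    """

    bins: dict = field(default_factory=dict)  # variable -> BinSpec
    weights: dict = field(default_factory=dict)  # (region, transition) -> {var: array}

    def get(self, region: int, transition: tuple) -> dict:
        return self.weights.get((int(region), tuple(transition)), {})

    # -- tabular serialization --------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (region, tr), per_var in sorted(self.weights.items()):
            for var, w in per_var.items():
                spec = self.bins[var]
                for k in range(spec.n_bins):
                    if spec.is_categorical:
                        lo = hi = spec.categories[k]
                    else:
                        edges = (-np.inf, *spec.breaks, np.inf)
                        lo, hi = edges[k], edges[k + 1]
                    rows.append(
                        {
                            "transition": transition_name(tr),
                            "region": region,
                            "variable": var,
                            "bin_low": lo,
                            "bin_high": hi,
                            "weight": w[k],
                        }
                    )
        return pd.DataFrame(
            rows, columns=["transition", "region", "variable", "bin_low", "bin_high", "weight"]
        )

    def to_csv(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EvidenceWeights":
        ew = cls()
        for (tr_name, region, var), grp in df.groupby(["transition", "region", "variable"]):
            grp = grp.reset_index(drop=True)
            if var not in ew.bins:
                lows = grp["bin_low"].to_numpy()
                highs = grp["bin_high"].to_numpy()
                if np.isinf(lows[0]) or len(lows) == 1 and not np.all(lows == highs):
                    ew.bins[var] = BinSpec(breaks=tuple(highs[:-1]))
                elif np.all(lows == highs):
                    ew.bins[var] = BinSpec(categories=tuple(int(c) for c in lows))
                else:
                    ew.bins[var] = BinSpec(breaks=tuple(highs[:-1]))
            key = (int(region), transition_from_name(tr_name))
            ew.weights.setdefault(key, {})[var] = grp["weight"].to_numpy(dtype=float)
        return ew

    @classmethod
    def from_csv(cls, path: str | Path) -> "EvidenceWeights":
        return cls.from_frame(pd.read_csv(path))


def _as_array(layer) -> np.ndarray:
    return layer.values if isinstance(layer, GridMap) else np.asarray(layer)


def compute_weights(
    lc_t0: GridMap,
    lc_t1: GridMap,
    variables: dict,
    bins: dict,
    region: GridMap,
    transitions: tuple = TRANSITIONS,
) -> EvidenceWeights:
    """Estimate W+ per (region, transition, variable, bin) from an observed
    change interval.

    Parameters
    ----------
    variables
        Mapping of variable name to grid/array of evidence values.
    bins
        Mapping of variable name to :class:`BinSpec`; every declared
        variable must be present in *variables*.
    """
    for var in bins:
        if var not in variables:
            raise KeyError(f"bin spec declared for missing variable {var!r}")

    t0 = lc_t0.values
    t1 = lc_t1.values
    reg = _as_array(region)
    ew = EvidenceWeights(bins=dict(bins))
    bin_idx = {var: bins[var].assign(_as_array(variables[var])) for var in bins}

    for r in np.unique(reg[reg >= 0]):
        for tr in transitions:
            src, dst = tr
            eligible = (t0 == src) & (reg == r) & lc_t0.mask
            transitioned = eligible & (t1 == dst)
            n_t = int(transitioned.sum())
            n_not = int(eligible.sum()) - n_t
            per_var: dict[str, np.ndarray] = {}
            if n_t == 0 or n_not == 0:
                if eligible.any() and n_t == 0:
                    warnings.warn(
                        f"transition {transition_name(tr)} absent in region {int(r)}; "
                        "weights set to 0",
                        stacklevel=2,
                    )
                for var, spec in bins.items():
                    per_var[var] = np.zeros(spec.n_bins)
                ew.weights[(int(r), tr)] = per_var
                continue
            for var, spec in bins.items():
                idx = bin_idx[var]
                w = np.zeros(spec.n_bins)
                for k in range(spec.n_bins):
                    in_bin = idx == k
                    n_bt = int((in_bin & transitioned).sum())
                    n_bnot = int((in_bin & eligible).sum()) - n_bt
                    if n_bt == 0 or n_bnot == 0:
                        continue  # zero-count bin: no evidence
                    w[k] = np.log((n_bt / n_t) / (n_bnot / n_not))
                per_var[var] = w
            ew.weights[(int(r), tr)] = per_var
    return ew


def posterior_probability(weights_sum: float, prior: float) -> float:
    """Combine a prior probability with summed weights of evidence on the
    log-odds scale. Monotone increasing in the weight sum."""
    if not 0.0 < prior < 1.0:
        raise ValueError(f"prior must be in (0,1), got {prior}")
    logit = np.log(prior / (1.0 - prior)) + weights_sum
    return float(1.0 / (1.0 + np.exp(-logit)))


def probability_surface(
    ew: EvidenceWeights,
    region_code: int,
    transition: tuple,
    variables: dict,
    prior: float,
) -> np.ndarray:
    """Per-cell posterior transition probability over the whole grid.

    Cells' evidence-bin memberships are looked up per variable; weights are
    summed and combined with the prior additively on the logit scale.
    """
    per_var = ew.get(region_code, transition)
    shape = _as_array(next(iter(variables.values()))).shape
    wsum = np.zeros(shape)
    for var, w in per_var.items():
        idx = ew.bins[var].assign(_as_array(variables[var]))
        valid = idx >= 0
        wsum[valid] += w[idx[valid]]
    logit = np.log(prior / (1.0 - prior)) + wsum
    return 1.0 / (1.0 + np.exp(-logit))


def _annualize(period_matrix: np.ndarray, years: float) -> np.ndarray:
    """Annual single-step matrix A with A^years = P, via the real part of
    the fractional matrix power, clipped and row-renormalized.

    For a pure-survival chain (one destination, no onward transitions) this
    reduces to the closed form annual = 1 - (1 - f)^(1/years)."""
    from scipy.linalg import fractional_matrix_power

    a = np.real(fractional_matrix_power(period_matrix, 1.0 / years))
    a = np.clip(a, 0.0, None)
    rows = a.sum(axis=1, keepdims=True)
    return np.divide(a, rows, out=np.eye(a.shape[0]), where=rows > 0)


def compute_rates(
    lc_t0: GridMap,
    lc_t1: GridMap,
    region: GridMap,
    years: float,
    transitions: tuple = TRANSITIONS,
) -> RateTable:
    """Annual transition rates per region from the observed transition matrix.

    Per region, the empirical period matrix P over the three dynamic states
    (forest, deforested, secondary) is annualized by the matrix root
    A = P^(1/years), which corrects for cells chaining through two states
    within a multi-year window (cleared then regenerated, or cut then
    regrown). With a single observed transition this reduces to the
    compound-survival form annual = 1 - (1 - f)^(1/years); with years = 1
    the annual rate is exactly the period fraction.
    """
    if years < 1:
        raise ValueError(f"calibration interval must be >= 1 year, got {years}")
    t0, t1 = lc_t0.values, lc_t1.values
    reg = _as_array(region)
    states = [int(LandCover.FOREST), int(LandCover.DEFORESTED), int(LandCover.SECONDARY)]
    idx = {s: i for i, s in enumerate(states)}
    table = RateTable()
    for r in np.unique(reg[reg >= 0]):
        counts = np.zeros((3, 3))
        in_region = (reg == r) & lc_t0.mask
        for s0 in states:
            row_mask = in_region & (t0 == s0)
            for s1 in states:
                counts[idx[s0], idx[s1]] = int((row_mask & (t1 == s1)).sum())
        row_tot = counts.sum(axis=1, keepdims=True)
        period = np.divide(counts, row_tot, out=np.eye(3), where=row_tot > 0)
        annual = _annualize(period, years)
        for tr in transitions:
            src, dst = tr
            if row_tot[idx[int(src)], 0] == 0:
                warnings.warn(
                    f"no {transition_name(tr)} source cells in region {int(r)}; rate 0",
                    stacklevel=2,
                )
                table.set_rate(int(r), tr, 0.0)
                continue
            table.set_rate(int(r), tr, float(np.clip(annual[idx[int(src)], idx[int(dst)]], 0.0, 1.0)))
    return table
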