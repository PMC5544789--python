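"""Map-comparison validation: fuzzy spatial similarity and class-area checks.

The spatial check compares *change* maps (cells that changed class between
two dates), not raw maps: a changed cell scores 1 when a cell with the same
(from, to) change exists within a k x k window in the other map, so credit
decays with spatial offset rather than demanding cell-perfect overlap. The
reported value per window size is the minimum of the two directional
scores. An exponential distance decay inside the window is available as an
alternative to the default constant (crisp) credit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import GridMap, LandCover, class_areas

__all__ = ["fuzzy_similarity", "quantitative_validation", "compare_scenarios"]

DEFAULT_WINDOWS = (1, 3, 5, 7, 9, 11)


def _change_codes(t0: np.ndarray, t1: np.ndarray) -> np.ndarray:
    """Unique code per (from, to) pair where the class changed; 0 elsewhere."""
    changed = t0 != t1
    return np.where(changed, t0.astype(np.int64) * 100 + t1.astype(np.int64), 0)


def _directional(a: np.ndarray, b: np.ndarray, k: int, decay: str) -> float:
    """Mean credit of a's changed cells against b within a k x k window."""
    changed_a = a != 0
    n = int(changed_a.sum())
    if n == 0:
        return float("nan")
    credit = np.zeros(a.shape)
    for code in np.unique(a[changed_a]):
        in_b = b == code
        if not in_b.any():
            continue
        if decay == "constant":
            hit = ndimage.maximum_filter(in_b.astype(np.uint8), size=k, mode="constant")
            credit = np.where((a == code) & (hit > 0), 1.0, credit)
        else:  # exponential distance decay inside the window
            dist = ndimage.distance_transform_edt(~in_b)
            half = (k - 1) / 2.0
            score = np.where(dist <= half, np.exp(-dist / max(half, 1e-9)), 0.0)
            credit = np.where(a == code, np.maximum(credit, score), credit)
    return float(credit[changed_a].sum() / n)


def fuzzy_similarity(
    real_t0: GridMap,
    real_t1: GridMap,
    sim_t1: GridMap,
    windows: tuple = DEFAULT_WINDOWS,
    decay: str = "constant",
) -> pd.DataFrame:
    """Minimum two-way fuzzy similarity of simulated vs observed change.

    Both change maps share the common t0. Returns one row per window size
    with the two directional scores and their minimum; when neither map has
    any changed cell the similarity is undefined (NaN).
    """
    real_chg = _change_codes(real_t0.values, real_t1.values)
    sim_chg = _change_codes(real_t0.values, sim_t1.values)
    rows = []
    for k in windows:
        if k % 2 != 1 or k < 1:
            raise ValueError(f"window sizes must be odd and >= 1, got {k}")
        r2s = _directional(real_chg, sim_chg, k, decay)
        s2r = _directional(sim_chg, real_chg, k, decay)
        both = [v for v in (r2s, s2r) if not np.isnan(v)]
        sim = min(both) if len(both) == 2 else float("nan")
        rows.append({"window": k, "real_to_sim": r2s, "sim_to_real": s2r, "similarity": sim})
    return pd.DataFrame(rows)


def quantitative_validation(real: GridMap, simulated: GridMap) -> pd.DataFrame:
    """Per-class area differences, real minus simulated.

    absolute_km2 = real - simulated; pct = absolute / real x 100 (flagged
    undefined when the class is absent from the real map). A positive sign
    means the model underestimated the class.
    """
    real_a = class_areas(real)
    sim_a = class_areas(simulated)
    rows = []
    for cls in LandCover:
        r, s = real_a[cls.name], sim_a[cls.name]
        rows.append(
            {
                "class": cls.name,
                "real_km2": r,
                "simulated_km2": s,
                "absolute_km2": r - s,
                "pct": 100.0 * (r - s) / r if r > 0 else float("nan"),
                "pct_defined": r > 0,
            }
        )
    return pd.DataFrame(rows)


def compare_scenarios(initial: GridMap, finals: dict) -> pd.DataFrame:
    """Per-class change of each scenario's final map against the common
    initial map: absolute km² and percentage of the initial class area."""
    init_a = class_areas(initial)
    rows = []
    for scen, final in finals.items():
        fin_a = class_areas(final)
        for cls in LandCover:
            i, f = init_a[cls.name], fin_a[cls.name]
            rows.append(
                {
                    "scenario": scen,
                    "class": cls.name,
                    "initial_km2": i,
                    "final_km2": f,
                    "change_km2": f - i,
                    "change_pct": 100.0 * (f - i) / i if i > 0 else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def scenario_difference(loss_a_km2: float, loss_b_km2: float) -> float:
    """Absolute difference between two scenarios' total losses (km²)."""
    return abs(loss_a_km2 - loss_b_km2)
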