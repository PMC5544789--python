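"""Per-region annual transition rates and patch-geometry parameters."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .grids import LandCover

# the model's three transitions
F_TO_D = (LandCover.FOREST, LandCover.DEFORESTED)
D_TO_S = (LandCover.DEFORESTED, LandCover.SECONDARY)
S_TO_D = (LandCover.SECONDARY, LandCover.DEFORESTED)
TRANSITIONS = (F_TO_D, S_TO_D, D_TO_S)

_TRANSITION_NAMES = {
    F_TO_D: "forest_to_deforested",
    D_TO_S: "deforested_to_secondary",
    S_TO_D: "secondary_to_deforested",
}
_NAME_TO_TRANSITION = {v: k for k, v in _TRANSITION_NAMES.items()}


def transition_name(tr: tuple) -> str:
    return _TRANSITION_NAMES[tuple(tr)]


def transition_from_name(name: str) -> tuple:
    return _NAME_TO_TRANSITION[name]


@dataclass(frozen=True)
class PatchParams:
    """Geometry of allocated change patches.

    mean_patch_size_ha / patch_size_variance parameterize the lognormal
    patch-size draw; isometry in [0, 1] weights compactness during patch
    growth; expander_fraction in [0, 1] is the share of each year's demand
    allocated by expanding existing patches rather than seeding new ones.
    """

    mean_patch_size_ha: float = 1.5
    patch_size_variance: float = 2.0
    isometry: float = 0.5
    expander_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.isometry <= 1.0:
            raise ValueError(f"isometry must be in [0,1], got {self.isometry}")
        if not 0.0 <= self.expander_fraction <= 1.0:
            raise ValueError(
                f"expander_fraction must be in [0,1], got {self.expander_fraction}"
            )


@dataclass
class RateTable:
    """Annual transition rates per (region, transition), with patch parameters.

    Rates are annual fractions of the transition's source class in [0, 1].
    Unlisted (region, transition) pairs have rate 0.
    """

    rates: dict = field(default_factory=dict)  # (region_code, transition) -> float
    patch_params: dict = field(default_factory=dict)  # same key -> PatchParams
    default_patch: PatchParams = field(default_factory=PatchParams)

    def get_rate(self, region: int, transition: tuple) -> float:
        return self.rates.get((int(region), tuple(transition)), 0.0)

    def set_rate(self, region: int, transition: tuple, rate: float) -> None:
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"rate must be in [0,1], got {rate}")
        self.rates[(int(region), tuple(transition))] = float(rate)

    def get_patch(self, region: int, transition: tuple) -> PatchParams:
        return self.patch_params.get((int(region), tuple(transition)), self.default_patch)

    def regions(self) -> list[int]:
        return sorted({r for r, _ in self.rates})

    def copy(self) -> "RateTable":
        return RateTable(
            rates=dict(self.rates),
            patch_params=dict(self.patch_params),
            default_patch=self.default_patch,
        )

    # -- tabular serialization --------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (region, tr), rate in sorted(self.rates.items()):
            p = self.get_patch(region, tr)
            rows.append(
                {
                    "region": region,
                    "transition": transition_name(tr),
                    "annual_rate": rate,
                    "mean_patch_size_ha": p.mean_patch_size_ha,
                    "patch_size_variance": p.patch_size_variance,
                    "isometry": p.isometry,
                    "expander_fraction": p.expander_fraction,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "region",
                "transition",
                "annual_rate",
                "mean_patch_size_ha",
                "patch_size_variance",
                "isometry",
                "expander_fraction",
            ],
        )

    def to_csv(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RateTable":
        table = cls()
        for _, row in df.iterrows():
            tr = transition_from_name(row["transition"])
            key = (int(row["region"]), tr)
            table.set_rate(*key, float(row["annual_rate"]))
            table.patch_params[key] = PatchParams(
                mean_patch_size_ha=float(row.get("mean_patch_size_ha", 1.5)),
                patch_size_variance=float(row.get("patch_size_variance", 2.0)),
                isometry=float(row.get("isometry", 0.5)),
                expander_fraction=float(row.get("expander_fraction", 0.5)),
            )
        return table

    @classmethod
    def from_csv(cls, path: str | Path) -> "RateTable":
        return cls.from_frame(pd.read_csv(path))
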