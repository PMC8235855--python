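"""Long-format phenotype records (animal x week x trait) with explicit missingness."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sad import TimeGrid

__all__ = ["PhenotypeTable"]

CORE_COLUMNS = ("animal", "week", "trait", "value")


@dataclass
class PhenotypeTable:
    """Long table of records; missing values are absent rows, never sentinels.

    Extra columns beyond (animal, week, trait, value) are fixed-effect levels
    or covariates and ride along untouched.
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        missing = [c for c in CORE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"phenotype table lacks columns {missing}")
        if df["value"].isna().any():
            raise ValueError("missing values must be absent rows, not NaN")
        if df.duplicated(["animal", "week", "trait"]).any():
            raise ValueError("(animal, week, trait) must be unique")
        df = df.copy()
        df["animal"] = df["animal"].astype(str)
        df["week"] = df["week"].astype(int)
        df["trait"] = df["trait"].astype(str)
        self.data = df.reset_index(drop=True)

    @property
    def animals(self) -> list[str]:
        return sorted(self.data["animal"].unique())

    @property
    def traits(self) -> list[str]:
        return sorted(self.data["trait"].unique())

    def grid(self) -> TimeGrid:
        return TimeGrid(tuple(sorted(self.data["week"].unique())))

    def to_wide(
        self, traits: list[str], grid: TimeGrid, animals: list[str] | None = None
    ) -> tuple[list[str], np.ndarray, np.ndarray]:
        """(animals, Y, mask): Y is (N, T*n) trait-major, NaN where unobserved."""
        animals = animals if animals is not None else self.animals
        weeks = [int(t) for t in grid.times]
        n, T = len(weeks), len(traits)
        apos = {a: i for i, a in enumerate(animals)}
        wpos = {w: j for j, w in enumerate(weeks)}
        tpos = {s: k for k, s in enumerate(traits)}
        Y = np.full((len(animals), T * n), np.nan)
        df = self.data
        sel = (
            df["animal"].isin(apos)
            & df["week"].isin(wpos)
            & df["trait"].isin(tpos)
        )
        for a, w, s, v in df.loc[sel, ["animal", "week", "trait", "value"]].itertuples(
            index=False
        ):
            Y[apos[a], tpos[s] * n + wpos[w]] = v
        return animals, Y, ~np.isnan(Y)

    def is_complete(self, traits: list[str], grid: TimeGrid) -> bool:
        _, _, mask = self.to_wide(traits, grid)
        return bool(mask.all())

    def record_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in CORE_COLUMNS]
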