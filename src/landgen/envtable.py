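"""Site x environmental-variable tables with category tags and scaling state.

Thin wrapper over a pandas DataFrame (rows = sites or populations,
columns = variables) that tracks which variables belong to which
category (climate / soil / topography) and whether columns have been
z-scored, so distance builders and ordinations can ask for exactly the
standardization the analysis needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CATEGORIES = ("climate", "soil", "topography")


@dataclass
class EnvTable:
    data: pd.DataFrame
    categories: dict[str, str] = field(default_factory=dict)
    scaled: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        for var, cat in self.categories.items():
            if var not in self.data.columns:
                raise ValueError(f"category tag for unknown variable {var!r}")
            if cat not in CATEGORIES:
                raise ValueError(f"unknown category {cat!r} for {var!r}")

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    @property
    def sites(self) -> list[str]:
        return list(self.data.index.astype(str))

    @property
    def n_sites(self) -> int:
        return len(self.data)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def category_of(self, var: str) -> str:
        return self.categories.get(var, "climate")

    def subset(self, variables: list[str]) -> "EnvTable":
        return EnvTable(
            self.data[variables].copy(),
            {v: c for v, c in self.categories.items() if v in variables},
            self.scaled,
        )

    def by_category(self) -> dict[str, "EnvTable"]:
        """Split into one table per represented category."""
        out: dict[str, EnvTable] = {}
        for cat in CATEGORIES:
            cols = [v for v in self.variables if self.category_of(v) == cat]
            if cols:
                out[cat] = self.subset(cols)
        return out

    def zscored(self) -> "EnvTable":
        """Column-standardized copy (mean 0, sd 1; constant columns -> 0)."""
        if self.scaled:
            return self
        x = self.data.to_numpy(dtype=float)
        mu = x.mean(axis=0)
        sd = x.std(axis=0, ddof=0)
        sd = np.where(sd == 0.0, 1.0, sd)
        z = pd.DataFrame((x - mu) / sd, index=self.data.index, columns=self.data.columns)
        return EnvTable(z, dict(self.categories), scaled=True)

    def constant_variables(self) -> list[str]:
        x = self.data.to_numpy(dtype=float)
        return [v for v, sd in zip(self.variables, x.std(axis=0)) if sd == 0.0]

    # -------------------------------------------------------------- I/O

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index_label="site")

    @classmethod
    def from_csv(cls, path: str | Path, categories: dict[str, str] | None = None) -> "EnvTable":
        df = pd.read_csv(path, index_col=0)
        return cls(df, categories or {})
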