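"""Labeled symmetric distance matrices and their builders.

Geographic distances are great-circle (haversine, Earth radius 6371 km);
environmental distances are Euclidean on z-scored variables, one matrix
per variable category. Resistance matrices are accepted as externally
computed CSV inputs, never derived here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .envtable import EnvTable
from .grids import haversine_km

KINDS = ("geo", "env_climate", "env_soil", "env_topo", "resistance", "genetic")


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    kind: str = "genetic"
    flagged: bool = False  # set when entries were capped (e.g. infinite Nei distance)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-10):
            raise ValueError("distance matrix must have zero diagonal")
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries, row-major (scipy squareform order)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def reorder(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)], self.kind, self.flagged)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, kind: str = "resistance") -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls([str(c) for c in df.columns], df.to_numpy(float), kind)


def geographic_distances(labels: list[str], lat: np.ndarray, lon: np.ndarray) -> DistanceMatrix:
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude outside [-90, 90]")
    if np.any(np.abs(lon) > 180.0):
        raise ValueError("longitude outside [-180, 180]")
    d = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(list(labels), d, "geo")


_ENV_KIND = {"climate": "env_climate", "soil": "env_soil", "topography": "env_topo"}


def environmental_distances(env: EnvTable) -> dict[str, DistanceMatrix]:
    """One Euclidean matrix per variable category, on z-scored columns."""
    from scipy.spatial.distance import pdist, squareform

    out: dict[str, DistanceMatrix] = {}
    for cat, table in env.zscored().by_category().items():
        d = squareform(pdist(table.values()))
        out[cat] = DistanceMatrix(table.sites, d, _ENV_KIND[cat])
    return out


def build_distances(
    coords: pd.DataFrame, env: EnvTable, resistance: dict[str, str | Path] | None = None
) -> dict[str, DistanceMatrix]:
    """Assemble the model-competition predictor set.

    ``coords`` needs columns ``lat``/``lon`` indexed by site label, with
    rows aligned to ``env``. Resistance CSVs, if given, are loaded as-is.
    """
    labels = [str(i) for i in coords.index]
    if labels != env.sites:
        raise ValueError("coords and env tables must list the same sites in the same order")
    out = {"geo": geographic_distances(labels, coords["lat"].to_numpy(), coords["lon"].to_numpy())}
    for cat, dm in environmental_distances(env).items():
        out[f"env_{'topo' if cat == 'topography' else cat}"] = dm
    for name, path in (resistance or {}).items():
        dm = DistanceMatrix.from_csv(path, "resistance")
        out[name] = dm.reorder(labels)
    return out
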