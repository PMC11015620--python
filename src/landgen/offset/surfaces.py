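"""Per-cell offset surfaces with migration distance and bearing."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ..grids import ClimateGrid, write_esri_ascii


@dataclass
class OffsetSurface:
    """Local/forward/reverse offsets on a grid.

    All arrays share the grid shape; masked cells are NaN. The forward
    target is the flat cell index of the minimum-offset destination;
    ``distance_km``/``bearing_deg`` describe the great-circle move to
    it (bearing 0 = north, clockwise). distance is 0 iff the target is
    the focal cell.
    """

    grid: ClimateGrid
    local: np.ndarray
    forward: np.ndarray
    reverse: np.ndarray
    forward_target: np.ndarray  # flat index, -1 where masked
    distance_km: np.ndarray
    bearing_deg: np.ndarray
    scenario: str = "future"

    def to_frame(self) -> pd.DataFrame:
        rows, cols = np.nonzero(self.grid.mask)
        lat, lon = self.grid.cell_coords(rows, cols)
        flat = rows * self.grid.shape[1] + cols
        return pd.DataFrame(
            {
                "cell": flat,
                "lat": lat,
                "lon": lon,
                "local": self.local[rows, cols],
                "forward": self.forward[rows, cols],
                "reverse": self.reverse[rows, cols],
                "forward_target": self.forward_target[rows, cols],
                "distance_km": self.distance_km[rows, cols],
                "bearing_deg": self.bearing_deg[rows, cols],
            }
        )

    def write(self, directory: str | Path, prefix: str = "offset_") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        g = self.grid
        for name, arr in (
            ("local", self.local),
            ("forward", self.forward),
            ("reverse", self.reverse),
            ("distance_km", self.distance_km),
            ("bearing_deg", self.bearing_deg),
        ):
            out = np.where(np.isnan(arr), -9999.0, arr)
            write_esri_ascii(directory / f"{prefix}{name}.asc", out, g.lat0, g.lon0, g.cell_size, g.mask)
        self.to_frame().to_csv(directory / f"{prefix}table.csv", index=False)


def offset_rgb(surface: OffsetSurface) -> np.ndarray:
    """RGB composite: local, forward, reverse offsets min-max scaled to
    [0, 1] as the red, green, blue channels (NaN where masked)."""
    out = np.full(surface.grid.shape + (3,), np.nan)
    for ch, arr in enumerate((surface.local, surface.forward, surface.reverse)):
        vals = arr[surface.grid.mask]
        lo, hi = np.nanmin(vals), np.nanmax(vals)
        span = hi - lo if hi > lo else 1.0
        out[..., ch] = np.where(surface.grid.mask, (arr - lo) / span, np.nan)
    return out
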