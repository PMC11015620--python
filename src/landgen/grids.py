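"""Regular lat/lon raster stacks of environmental variables.

A :class:`ClimateGrid` holds one scenario (current or future): a set of
named 2-D layers on a shared regular grid, plus a boolean suitability
mask. Masked-out cells are excluded from every downstream computation.
Grids are stored and exchanged as ESRI ASCII grids (one file per layer),
a plain-text raster format readable by standard GIS software.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

NODATA = -9999.0


@dataclass
class ClimateGrid:
    """Stack of environmental layers for one climate scenario.

    Parameters
    ----------
    variables : list of str
        Layer names, e.g. ``["bio1", "bio12"]``.
    layers : ndarray, shape (n_var, n_rows, n_cols)
        Layer values; row 0 is the northernmost row.
    lat0, lon0 : float
        Cell-center coordinates of the upper-left cell (decimal degrees).
    cell_size : float
        Cell edge length in decimal degrees.
    mask : ndarray of bool, shape (n_rows, n_cols)
        True for suitable (active) cells.
    scenario : str
        ``"current"`` or ``"future"``.
    """

    variables: list[str]
    layers: np.ndarray
    lat0: float = 24.0
    lon0: float = 121.0
    cell_size: float = 0.05
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    scenario: str = "current"

    def __post_init__(self) -> None:
        self.layers = np.asarray(self.layers, dtype=float)
        if self.layers.ndim != 3:
            raise ValueError("layers must be (n_var, n_rows, n_cols)")
        if len(self.variables) != self.layers.shape[0]:
            raise ValueError("variable names do not match layer count")
        if self.mask is None:
            self.mask = np.ones(self.layers.shape[1:], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.layers.shape[1:]:
            raise ValueError("mask shape does not match layers")

    @property
    def shape(self) -> tuple[int, int]:
        return self.layers.shape[1:]

    @property
    def n_var(self) -> int:
        return len(self.variables)

    def layer(self, name: str) -> np.ndarray:
        return self.layers[self.variables.index(name)]

    def cell_coords(self, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Cell-center (lat, lon) for row/col indices; rows count southward."""
        lat = self.lat0 - np.asarray(rows) * self.cell_size
        lon = self.lon0 + np.asarray(cols) * self.cell_size
        return lat, lon

    def unmasked_indices(self) -> np.ndarray:
        """Flat indices of active cells, in row-major order."""
        return np.flatnonzero(self.mask.ravel())

    def env_at_cells(self, flat_idx: np.ndarray) -> np.ndarray:
        """Environment matrix (n_cells, n_var) at the given flat indices."""
        flat = self.layers.reshape(self.n_var, -1)
        return flat[:, flat_idx].T

    def copy(self, scenario: str | None = None) -> "ClimateGrid":
        return ClimateGrid(
            list(self.variables),
            self.layers.copy(),
            self.lat0,
            self.lon0,
            self.cell_size,
            self.mask.copy(),
            scenario or self.scenario,
        )

    # ------------------------------------------------------------------ I/O

    def write_ascii(self, directory: str | Path, prefix: str = "") -> list[Path]:
        """Write one ESRI ASCII grid per layer; returns the paths written."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for name, layer in zip(self.variables, self.layers):
            path = directory / f"{prefix}{name}.asc"
            write_esri_ascii(path, layer, self.lat0, self.lon0, self.cell_size, self.mask)
            paths.append(path)
        return paths


def write_esri_ascii(
    path: str | Path,
    layer: np.ndarray,
    lat0: float,
    lon0: float,
    cell_size: float,
    mask: np.ndarray | None = None,
) -> None:
    layer = np.asarray(layer, dtype=float)
    nrows, ncols = layer.shape
    # ESRI convention: corner of the lower-left cell
    xll = lon0 - cell_size / 2.0
    yll = lat0 - (nrows - 1) * cell_size - cell_size / 2.0
    out = layer.copy()
    if mask is not None:
        out[~mask] = NODATA
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {xll:.10g}\n")
        fh.write(f"yllcorner {yll:.10g}\n")
        fh.write(f"cellsize {cell_size:.10g}\n")
        fh.write(f"NODATA_value {NODATA:.10g}\n")
        for row in out:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def read_esri_ascii(path: str | Path) -> tuple[np.ndarray, float, float, float, np.ndarray]:
    """Read one ESRI ASCII grid.

    Returns ``(layer, lat0, lon0, cell_size, mask)`` with lat0/lon0 the
    center of the upper-left cell and mask True where data are valid.
    """
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and not _is_number(parts[0]):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    layer = np.array(rows, dtype=float)
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    if layer.shape != (nrows, ncols):
        raise ValueError(f"grid body {layer.shape} does not match header ({nrows}, {ncols})")
    cell = header["cellsize"]
    if "xllcorner" in header:
        lon0 = header["xllcorner"] + cell / 2.0
    else:
        lon0 = header["xllcenter"]
    if "yllcorner" in header:
        yll_center = header["yllcorner"] + cell / 2.0
    else:
        yll_center = header["yllcenter"]
    lat0 = yll_center + (nrows - 1) * cell
    nodata = header.get("nodata_value", NODATA)
    mask = ~np.isclose(layer, nodata)
    return layer, lat0, lon0, cell, mask


def read_grid_stack(paths: dict[str, str | Path], scenario: str = "current") -> ClimateGrid:
    """Assemble a ClimateGrid from ``{variable: ascii path}``."""
    layers = []
    mask = None
    geo = None
    for name, path in paths.items():
        layer, lat0, lon0, cell, m = read_esri_ascii(path)
        if geo is None:
            geo = (lat0, lon0, cell)
            mask = m
        else:
            if not np.allclose(geo, (lat0, lon0, cell)):
                raise ValueError(f"layer {name} georeference mismatch")
            mask = mask & m
        layers.append(layer)
    assert geo is not None and mask is not None
    return ClimateGrid(list(paths), np.array(layers), geo[0], geo[1], geo[2], mask, scenario)


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


EARTH_RADIUS_KM = 6371.0


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km between points in decimal degrees."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def initial_bearing_deg(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Initial great-circle bearing from point 1 to point 2.

    0 deg = north, measured clockwise, in [0, 360).
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlon = lon2 - lon1
    y = np.sin(dlon) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return np.degrees(np.arctan2(y, x)) % 360.0
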