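"""Aligned gridded environmental layers: data model, ESRI ASCII I/O, cell areas.

A stack (:class:`EnvStack`) holds one or more co-registered layers on a common
:class:`GridSpec`.  Cells invalid in *any* layer are masked in *all* layers
("unified mask"), so every downstream computation sees a single valid-cell set.

Conventions
-----------
* Array row 0 is the **top** (northernmost) row; ``(x_origin, y_origin)`` is the
  map coordinate of the **lower-left corner** of the grid.
* A point maps to the cell ``col = floor((x - x_origin)/cell_size)`` with
  half-open intervals ``[left, right)``; the y axis is treated analogously
  (half-open ``[bottom, top)`` per row counted from the bottom).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GridSpec",
    "Layer",
    "EnvStack",
    "AreaModel",
    "AlignmentError",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_stack",
    "write_stack",
    "cell_areas",
    "extract",
]

DEFAULT_NODATA = -9999.0
EARTH_RADIUS_KM = 6371.0


class AlignmentError(ValueError):
    """Raised when grids that must share a GridSpec do not."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular grid.

    Parameters
    ----------
    n_rows, n_cols : int
        Grid dimensions (rows ≥ 1, cols ≥ 1).
    x_origin, y_origin : float
        Map coordinates of the lower-left **corner**.
    cell_size : float
        Cell edge length (degrees for geographic grids, km or abstract units
        otherwise). Cells are square.
    crs_tag : str
        ``"geographic"``, ``"projected"`` or ``"abstract"``.
    nodata : float
        Sentinel written for invalid cells on output.
    """

    n_rows: int
    n_cols: int
    x_origin: float = 0.0
    y_origin: float = 0.0
    cell_size: float = 1.0
    crs_tag: str = "abstract"
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    def aligned(self, other: "GridSpec", tol: float = 1e-9) -> bool:
        """True iff the six numeric fields match within absolute tolerance."""
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and abs(self.x_origin - other.x_origin) <= tol
            and abs(self.y_origin - other.y_origin) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
            and abs(self.nodata - other.nodata) <= tol
        )

    # -- coordinate helpers -------------------------------------------------

    def cell_of(self, x: float, y: float) -> tuple[int, int] | None:
        """(row, col) of the cell containing (x, y); None if outside extent."""
        col = math.floor((x - self.x_origin) / self.cell_size)
        row_from_bottom = math.floor((y - self.y_origin) / self.cell_size)
        if not (0 <= col < self.n_cols and 0 <= row_from_bottom < self.n_rows):
            return None
        return self.n_rows - 1 - row_from_bottom, col

    def cell_centre(self, row: int, col: int) -> tuple[float, float]:
        x = self.x_origin + (col + 0.5) * self.cell_size
        y = self.y_origin + (self.n_rows - row - 0.5) * self.cell_size
        return x, y

    def row_centre_latitudes(self) -> np.ndarray:
        """Per-row y (latitude) of cell centres, ordered top row first."""
        rows = np.arange(self.n_rows)
        return self.y_origin + (self.n_rows - rows - 0.5) * self.cell_size


@dataclass
class Layer:
    """One named variable on a grid; invalid cells are NaN."""

    name: str
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"layer {self.name!r}: values must be 2-D")


@dataclass
class EnvStack:
    """Aligned multi-layer environmental data for one scenario/period."""

    spec: GridSpec
    layers: list[Layer]
    scenario_id: str = "current"
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        names = [lay.name for lay in self.layers]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate layer names in stack: {names}")
        shape = (self.spec.n_rows, self.spec.n_cols)
        for lay in self.layers:
            if lay.values.shape != shape:
                raise AlignmentError(
                    f"layer {lay.name!r} shape {lay.values.shape} != grid {shape}"
                )
        self._unify_mask()

    def _unify_mask(self) -> None:
        shape = (self.spec.n_rows, self.spec.n_cols)
        valid = np.ones(shape, dtype=bool)
        for lay in self.layers:
            valid &= np.isfinite(lay.values)
        for lay in self.layers:
            lay.values = np.where(valid, lay.values, np.nan)
        self.mask = valid

    # -- access -------------------------------------------------------------

    @property
    def layer_names(self) -> list[str]:
        return [lay.name for lay in self.layers]

    def __getitem__(self, name: str) -> Layer:
        for lay in self.layers:
            if lay.name == name:
                return lay
        raise KeyError(f"no layer named {name!r} in stack {self.scenario_id!r}")

    def __contains__(self, name: str) -> bool:
        return name in self.layer_names

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def values_matrix(self, names: Sequence[str] | None = None) -> np.ndarray:
        """Valid-cell values as an (n_valid, n_layers) matrix (row-major cell order)."""
        names = list(names) if names is not None else self.layer_names
        cols = [self[nm].values[self.mask] for nm in names]
        return np.column_stack(cols) if cols else np.empty((self.n_valid, 0))

    def subset(self, names: Sequence[str]) -> "EnvStack":
        layers = [Layer(lay.name, lay.values.copy(), lay.units) for lay in self.layers if lay.name in set(names)]
        missing = set(names) - {lay.name for lay in layers}
        if missing:
            raise KeyError(f"layers not in stack: {sorted(missing)}")
        return EnvStack(self.spec, layers, self.scenario_id)

    def copy(self) -> "EnvStack":
        return EnvStack(
            self.spec,
            [Layer(lay.name, lay.values.copy(), lay.units) for lay in self.layers],
            self.scenario_id,
        )


@dataclass(frozen=True)
class AreaModel:
    """How a cell's area in km² is computed.

    ``constant`` assigns every cell the same area (default 1 km², which makes
    counts and areas interchangeable on abstract grids).  ``latitude-cosine``
    treats the grid as geographic (cell_size in degrees) and uses
    ``(R·Δ)² · cos(lat_row_centre)`` with Δ in radians — area varies by row only.
    """

    mode: str = "constant"
    constant_cell_area_km2: float = 1.0
    earth_radius_km: float = EARTH_RADIUS_KM

    def __post_init__(self) -> None:
        if self.mode not in ("constant", "latitude-cosine"):
            raise ValueError(f"unknown area model mode {self.mode!r}")
        if self.mode == "constant" and not self.constant_cell_area_km2 > 0:
            raise ValueError("constant cell area must be positive")


def cell_areas(spec: GridSpec, model: AreaModel) -> np.ndarray:
    """Per-row cell areas in km² (top row first)."""
    if model.mode == "constant":
        return np.full(spec.n_rows, model.constant_cell_area_km2, dtype=float)
    lats = spec.row_centre_latitudes()
    if np.any(np.abs(lats) >= 90.0):
        raise ValueError("latitude-cosine area model: row-centre |latitude| >= 90 deg")
    d = math.radians(spec.cell_size) * model.earth_radius_km
    return d * d * np.cos(np.radians(lats))


def area_grid(spec: GridSpec, model: AreaModel) -> np.ndarray:
    """Full (n_rows, n_cols) grid of cell areas."""
    rows = cell_areas(spec, model)
    return np.repeat(rows[:, None], spec.n_cols, axis=1)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

_HEADER_KEYS = {"ncols", "nrows", "xllcorner", "yllcorner", "xllcenter", "yllcenter", "cellsize", "nodata_value"}


def read_ascii_grid(path: str | Path, name: str | None = None, crs_tag: str = "abstract") -> Layer | tuple[GridSpec, Layer]:
    """Read one ESRI ASCII grid (.asc).

    Accepts both ``xllcorner/yllcorner`` and ``xllcenter/yllcenter`` headers,
    normalising centre-registered origins to corner internally.  Returns
    ``(GridSpec, Layer)``; invalid cells become NaN.
    """
    path = Path(path)
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in _HEADER_KEYS and len(parts) == 2 and not data_lines:
                header[key] = float(parts[1])
            else:
                data_lines.append(line)
    for req in ("ncols", "nrows", "cellsize"):
        if req not in header:
            raise IOError(f"{path}: missing ESRI ASCII header field {req!r}")
    n_cols = int(header["ncols"])
    n_rows = int(header["nrows"])
    cell = header["cellsize"]
    if "xllcorner" in header:
        x0 = header["xllcorner"]
    elif "xllcenter" in header:
        x0 = header["xllcenter"] - cell / 2.0
    else:
        raise IOError(f"{path}: missing xllcorner/xllcenter")
    if "yllcorner" in header:
        y0 = header["yllcorner"]
    elif "yllcenter" in header:
        y0 = header["yllcenter"] - cell / 2.0
    else:
        raise IOError(f"{path}: missing yllcorner/yllcenter")
    nodata = header.get("nodata_value", DEFAULT_NODATA)

    values = np.loadtxt(data_lines, dtype=float)
    values = np.atleast_2d(values)
    if values.shape != (n_rows, n_cols):
        values = values.reshape(n_rows, n_cols)
    values = np.where(np.isclose(values, nodata), np.nan, values)
    spec = GridSpec(n_rows, n_cols, x0, y0, cell, crs_tag=crs_tag, nodata=nodata)
    return spec, Layer(name or path.stem, values)


def write_ascii_grid(path: str | Path, spec: GridSpec, values: np.ndarray, fmt: str = "%.6g") -> None:
    """Write one layer as ESRI ASCII (corner-registered, 6 significant digits)."""
    path = Path(path)
    out = np.where(np.isfinite(values), values, spec.nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {spec.n_cols}\n")
        fh.write(f"nrows {spec.n_rows}\n")
        fh.write(f"xllcorner {spec.x_origin!r}\n")
        fh.write(f"yllcorner {spec.y_origin!r}\n")
        fh.write(f"cellsize {spec.cell_size!r}\n")
        fh.write(f"nodata_value {spec.nodata!r}\n")
        for row in out:
            fh.write(" ".join(fmt % v for v in row) + "\n")


def read_stack(
    paths: Iterable[str | Path],
    scenario_id: str = "current",
    names: Sequence[str] | None = None,
    crs_tag: str = "abstract",
    tol: float = 1e-9,
) -> EnvStack:
    """Read several single-layer grids into an aligned stack with a unified mask.

    Raises :class:`AlignmentError` naming the first layer whose GridSpec does
    not match the first file's.
    """
    paths = list(paths)
    if not paths:
        raise ValueError("read_stack: no paths given")
    names = list(names) if names is not None else [Path(p).stem for p in paths]
    spec0 = None
    layers: list[Layer] = []
    for p, nm in zip(paths, names):
        spec, layer = read_ascii_grid(p, name=nm, crs_tag=crs_tag)
        if spec0 is None:
            spec0 = spec
        elif not spec0.aligned(spec, tol):
            raise AlignmentError(f"layer {nm!r} ({p}) is not aligned with {names[0]!r}")
        layers.append(layer)
    return EnvStack(spec0, layers, scenario_id)


def write_stack(stack: EnvStack, directory: str | Path) -> list[Path]:
    """Write every layer of the stack as <directory>/<name>.asc."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for lay in stack.layers:
        p = directory / f"{lay.name}.asc"
        write_ascii_grid(p, stack.spec, lay.values)
        written.append(p)
    return written


# ---------------------------------------------------------------------------
# Point extraction
# ---------------------------------------------------------------------------

def extract(
    stack: EnvStack,
    xs: np.ndarray,
    ys: np.ndarray,
    names: Sequence[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Extract per-layer cell values at points.

    Returns ``(X, status)`` where ``X`` is (n_points, n_layers) with NaN rows
    for unusable points, and ``status`` is ``"ok"``, ``"masked"`` or
    ``"outside"`` per point.  Callers exclude non-ok rows downstream.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    names = list(names) if names is not None else stack.layer_names
    arrs = [stack[nm].values for nm in names]
    n = len(xs)
    X = np.full((n, len(names)), np.nan)
    status = np.full(n, "ok", dtype=object)
    for i in range(n):
        cell = stack.spec.cell_of(xs[i], ys[i])
        if cell is None:
            status[i] = "outside"
            continue
        r, c = cell
        if not stack.mask[r, c]:
            status[i] = "masked"
            continue
        X[i] = [a[r, c] for a in arrs]
    return X, status
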