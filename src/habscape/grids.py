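"""Raster domain types and file I/O.

All stages of the pipeline exchange data through the containers defined
here: a categorical :class:`LandUseMap`, a :class:`DriverStack` of
continuous explanatory surfaces, and the small parameter objects
(:class:`TransitionMatrix`, :class:`DemandVector`, :class:`ConversionMatrix`,
:class:`RestrictedMask`).

Two on-disk raster dialects are supported: single-band TIFF (via
``tifffile``, with the cell size and nodata value carried in the image
description tag) and the ESRI ASCII grid. Rasters are row-major with the
origin at the top-left corner and 0-based row/column indexing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

#: The eight land classes of the delta landscape, in canonical order.
DEFAULT_CLASS_TABLE: list[tuple[int, str]] = [
    (1, "cultivated"),
    (2, "garden"),
    (3, "forest"),
    (4, "grassland"),
    (5, "construction"),
    (6, "water"),
    (7, "wetland"),
    (8, "unused"),
]

INT_NODATA = -9999


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class LandUseMap:
    """Categorical land-use raster over a fixed class table.

    Parameters
    ----------
    codes : ndarray of int, shape (rows, cols)
        Per-cell class code. Values on nodata cells are ignored.
    class_table : list of (code, name)
        The legal codes and their names, in canonical order.
    cell_size : float
        Edge length of one square cell, in meters.
    nodata_mask : ndarray of bool, shape (rows, cols)
        True where the cell is outside the study area.
    """

    codes: np.ndarray
    class_table: list[tuple[int, str]] = field(
        default_factory=lambda: list(DEFAULT_CLASS_TABLE)
    )
    cell_size: float = 30.0
    nodata_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2 or min(self.codes.shape) < 1:
            raise ValueError("codes must be a 2-D raster of at least 1x1")
        if not np.issubdtype(self.codes.dtype, np.integer):
            if not np.all(np.mod(self.codes[np.isfinite(self.codes)], 1) == 0):
                raise ValueError("land-use band contains non-integer values")
            self.codes = self.codes.astype(np.int32)
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.codes.shape, dtype=bool)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.codes.shape:
            raise ValueError("nodata_mask shape differs from codes shape")
        valid = self.codes[~self.nodata_mask]
        legal = np.array([c for c, _ in self.class_table])
        bad = np.setdiff1d(np.unique(valid), legal)
        if bad.size:
            raise ValueError(f"unknown class code(s): {bad.tolist()}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    @property
    def class_codes(self) -> np.ndarray:
        return np.array([c for c, _ in self.class_table])

    @property
    def class_names(self) -> list[str]:
        return [n for _, n in self.class_table]

    def counts(self) -> np.ndarray:
        """Cell count per class (class-table order), nodata excluded."""
        valid = self.codes[~self.nodata_mask]
        return np.array([(valid == c).sum() for c in self.class_codes])

    def code_of(self, name: str) -> int:
        for c, n in self.class_table:
            if n == name:
                return c
        raise KeyError(name)

    def copy(self) -> "LandUseMap":
        return LandUseMap(
            self.codes.copy(),
            list(self.class_table),
            self.cell_size,
            self.nodata_mask.copy(),
        )


@dataclass
class DriverStack:
    """Named stack of continuous driver rasters sharing one footprint."""

    names: list[str]
    data: np.ndarray  # (layers, rows, cols)
    nodata_mask: np.ndarray | None = None
    normalization_bounds: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] != len(self.names):
            raise ValueError("data must be (n_layers, rows, cols) matching names")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.data.shape[1:], dtype=bool)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.data.shape[1:]:
            raise ValueError("nodata_mask shape differs from layer shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def layer(self, name: str) -> np.ndarray:
        return self.data[self.names.index(name)]

    def normalized(self) -> "DriverStack":
        """Min-max scale every layer to [0, 1], recording the bounds."""
        bounds: dict[str, tuple[float, float]] = {}
        out = np.empty_like(self.data)
        for i, name in enumerate(self.names):
            vals = self.data[i][~self.nodata_mask]
            lo, hi = float(vals.min()), float(vals.max())
            bounds[name] = (lo, hi)
            span = hi - lo if hi > lo else 1.0
            out[i] = (self.data[i] - lo) / span
        return DriverStack(list(self.names), out, self.nodata_mask.copy(), bounds)


@dataclass
class TransitionMatrix:
    """Row-stochastic class transition matrix over a calibration span."""

    P: np.ndarray
    classes: np.ndarray
    interval_years: float = 1.0

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        self.classes = np.asarray(self.classes)
        k = len(self.classes)
        if self.P.shape != (k, k):
            raise ValueError("P must be KxK for K classes")
        if np.any(self.P < -1e-12) or np.any(self.P > 1 + 1e-12):
            raise ValueError("transition probabilities must lie in [0, 1]")
        rows = self.P.sum(axis=1)
        if np.any(np.abs(rows - 1) > 1e-9):
            raise ValueError(f"rows must sum to 1 (got {rows})")


@dataclass
class DemandVector:
    """Per-class target cell counts for the simulation horizon."""

    counts: np.ndarray
    classes: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.classes = np.asarray(self.classes)
        if len(self.counts) != len(self.classes):
            raise ValueError("counts and classes length mismatch")
        if np.any(self.counts < 0):
            raise ValueError("demand counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ConversionMatrix:
    """Binary allowance matrix: allow[c, p] = 1 if class c may become p."""

    allow: np.ndarray
    classes: np.ndarray

    def __post_init__(self) -> None:
        self.allow = np.asarray(self.allow, dtype=np.int8)
        self.classes = np.asarray(self.classes)
        k = len(self.classes)
        if self.allow.shape != (k, k):
            raise ValueError("allow must be KxK")
        if not np.all(np.isin(self.allow, (0, 1))):
            raise ValueError("allowance entries must be 0 or 1")
        if not np.all(np.diag(self.allow) == 1):
            raise ValueError("a class must always be allowed to remain itself")


@dataclass
class RestrictedMask:
    """Boolean raster of frozen cells (True = may not change class)."""

    frozen: np.ndarray

    def __post_init__(self) -> None:
        self.frozen = np.asarray(self.frozen, dtype=bool)
        if self.frozen.ndim != 2:
            raise ValueError("frozen must be a 2-D raster")


# ---------------------------------------------------------------------------
# raster I/O
# ---------------------------------------------------------------------------


def _write_ascii(array, path, cell_size, nodata_value, mask) -> None:
    arr = np.array(array, dtype=float)
    arr[mask] = nodata_value
    is_int = np.issubdtype(np.asarray(array).dtype, np.integer)
    fmt = "%d" if is_int else "%.10g"
    header = (
        f"ncols {arr.shape[1]}\n"
        f"nrows {arr.shape[0]}\n"
        "xllcorner 0.0\n"
        "yllcorner 0.0\n"
        f"cellsize {cell_size:.10g}\n"
        f"NODATA_value {nodata_value:.10g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, arr, fmt=fmt)


def _read_ascii(path):
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, val = line.partition(" ")
            key = key.strip().lower()
            if key in (
                "ncols",
                "nrows",
                "xllcorner",
                "yllcorner",
                "cellsize",
                "nodata_value",
            ):
                header[key] = float(val)
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        arr = np.loadtxt(fh, ndmin=2)
    nodata = header.get("nodata_value", INT_NODATA)
    mask = arr == nodata
    return arr, header.get("cellsize", 1.0), nodata, mask


def _write_tiff(array, path, cell_size, nodata_value, mask) -> None:
    arr = np.asarray(array)
    if np.issubdtype(arr.dtype, np.integer):
        out = arr.astype(np.int32).copy()
        out[mask] = int(nodata_value)
    else:
        out = arr.astype(np.float64).copy()
        out[mask] = float(nodata_value)
    meta = {"cell_size": cell_size, "nodata": float(nodata_value)}
    tifffile.imwrite(path, out, description=json.dumps(meta))


def _read_tiff(path):
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        arr = page.asarray()
        desc = page.tags.get("ImageDescription")
        meta = {}
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except (json.JSONDecodeError, TypeError):
                meta = {}
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-band raster")
    nodata = meta.get("nodata", INT_NODATA)
    mask = arr == nodata
    return arr, float(meta.get("cell_size", 1.0)), nodata, mask


def _dispatch(path: str | Path):
    suffix = Path(path).suffix.lower()
    if suffix in (".asc", ".txt"):
        return _read_ascii, _write_ascii
    if suffix in (".tif", ".tiff"):
        return _read_tiff, _write_tiff
    raise ValueError(f"unsupported raster format: {suffix!r} (use .tif or .asc)")


def read_raster(path: str | Path) -> tuple[np.ndarray, np.ndarray, float]:
    """Read any supported raster. Returns (array, nodata_mask, cell_size)."""
    if not Path(path).exists():
        raise FileNotFoundError(path)
    reader, _ = _dispatch(path)
    arr, cell_size, _, mask = reader(path)
    return arr, mask, cell_size


def read_landuse(
    path: str | Path,
    class_table: list[tuple[int, str]] | None = None,
) -> LandUseMap:
    """Read a categorical land-use raster, validating codes against the table."""
    arr, mask, cell_size = read_raster(path)
    if not np.all(np.mod(arr[~mask], 1) == 0):
        raise ValueError(f"{path}: land-use band is not integer-valued")
    return LandUseMap(
        arr.astype(np.int32),
        class_table or list(DEFAULT_CLASS_TABLE),
        cell_size,
        mask,
    )


def write_raster(
    grid,
    path: str | Path,
    *,
    cell_size: float | None = None,
    nodata_mask: np.ndarray | None = None,
) -> Path:
    """Write a LandUseMap or bare array to TIFF/ASCII (chosen by extension).

    Integer rasters round-trip bit-faithfully; float rasters to at least
    10 significant digits in ASCII and exactly in TIFF (float64).
    """
    path = Path(path)
    _, writer = _dispatch(path)
    if isinstance(grid, LandUseMap):
        arr, mask, cs = grid.codes, grid.nodata_mask, grid.cell_size
    else:
        arr = np.asarray(grid)
        mask = (
            nodata_mask
            if nodata_mask is not None
            else (~np.isfinite(arr) if np.issubdtype(arr.dtype, np.floating)
                  else np.zeros(arr.shape, dtype=bool))
        )
        cs = cell_size if cell_size is not None else 1.0
    nodata = INT_NODATA if np.issubdtype(arr.dtype, np.integer) else float(INT_NODATA)
    writer(arr, path, cs, nodata, np.asarray(mask, dtype=bool))
    return path


def read_float_raster(path: str | Path) -> tuple[np.ndarray, np.ndarray, float]:
    """Read a continuous raster; nodata cells become NaN."""
    arr, mask, cell_size = read_raster(path)
    out = arr.astype(float)
    out[mask] = np.nan
    return out, mask, cell_size
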