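"""Core in-memory containers shared by every pipeline stage.

The geospatial conventions used throughout the package:

* pixel indices are 0-based ``(row, col)``;
* a pixel's map position is the position of its **center** — crown polygons
  are built from pixel centers, so this convention is load-bearing;
* map coordinates are in meters (projected CRS assumed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from shapely.geometry.base import BaseGeometry


@dataclass(frozen=True)
class Affine:
    """Affine pixel->map transform, rasterio-style coefficient order.

    ``x = a*col + b*row + c`` ; ``y = d*col + e*row + f``.
    For north-up rasters ``a`` is the pixel width, ``e`` the (negative)
    pixel height, and ``(c, f)`` the map position of the raster's
    upper-left *corner*.
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    def __post_init__(self) -> None:
        if abs(self.a * self.e - self.b * self.d) < 1e-12:
            raise ValueError("transform is not invertible")

    @classmethod
    def north_up(cls, x_origin: float, y_origin: float, pixel_size: float) -> "Affine":
        if pixel_size <= 0:
            raise ValueError("pixel size must be strictly positive")
        return cls(pixel_size, 0.0, x_origin, 0.0, -pixel_size, y_origin)

    @property
    def pixel_width(self) -> float:
        return math.hypot(self.a, self.d)

    @property
    def pixel_height(self) -> float:
        return math.hypot(self.b, self.e)

    def pixel_center(self, row, col):
        """Map coordinates of the center(s) of pixel(s) ``(row, col)``."""
        col = np.asarray(col, dtype=float) + 0.5
        row = np.asarray(row, dtype=float) + 0.5
        x = self.a * col + self.b * row + self.c
        y = self.d * col + self.e * row + self.f
        return x, y

    def map_to_pixel(self, x, y):
        """Fractional (row, col) such that pixel_center(row-0.5, col-0.5) = (x, y)."""
        x = np.asarray(x, dtype=float) - self.c
        y = np.asarray(y, dtype=float) - self.f
        det = self.a * self.e - self.b * self.d
        col = (self.e * x - self.b * y) / det
        row = (-self.d * x + self.a * y) / det
        return row - 0.5, col - 0.5


@dataclass
class RasterGrid:
    """Single-band georeferenced grid (radiance, reflectance or height)."""

    values: np.ndarray
    transform: Affine
    nodata: Optional[float] = None
    crs: Optional[str] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("RasterGrid values must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def valid_mask(self) -> np.ndarray:
        """True where the pixel holds real data (finite, not nodata)."""
        ok = np.isfinite(self.values.astype(float))
        if self.nodata is not None:
            ok &= self.values != self.nodata
        return ok

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        rows, cols = np.indices(self.shape)
        return self.transform.pixel_center(rows, cols)


@dataclass
class HyperCube:
    """Ordered stack of co-registered bands with center wavelengths in nm."""

    bands: list[RasterGrid]
    wavelengths_nm: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if len(self.bands) != len(self.wavelengths_nm):
            raise ValueError("one wavelength per band required")
        if len(self.bands) == 0:
            raise ValueError("empty cube")
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        ref = self.bands[0]
        for b in self.bands[1:]:
            if b.shape != ref.shape or b.transform != ref.transform:
                raise ValueError("all bands must share shape and transform")
            if b.crs != ref.crs:
                raise ValueError(f"CRS mismatch between bands: {b.crs!r} vs {ref.crs!r}")

    @property
    def transform(self) -> Affine:
        return self.bands[0].transform

    @property
    def crs(self) -> Optional[str]:
        return self.bands[0].crs

    @property
    def shape(self) -> tuple[int, int]:
        return self.bands[0].shape

    def as_array(self) -> np.ndarray:
        """(n_bands, rows, cols) float array."""
        return np.stack([b.values for b in self.bands]).astype(float)


def band_nearest(cube: HyperCube, target_nm: float) -> int:
    """Index of the band whose center wavelength is closest to ``target_nm``.

    Ties are broken toward the lower wavelength, so the result is the first
    argmin of ``|wavelength - target|`` in wavelength order.
    """
    delta = np.abs(cube.wavelengths_nm - float(target_nm))
    return int(np.argmin(delta))


@dataclass
class Crown:
    """One individual tree crown polygon with optional survey attributes."""

    crown_id: int | str
    geometry: BaseGeometry
    plot_id: Optional[int | str] = None
    species: Optional[str] = None
    height_m: Optional[float] = None
    radius_m: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.geometry.is_valid:
            raise ValueError(f"crown {self.crown_id}: invalid geometry")

    @property
    def area_m2(self) -> float:
        return self.geometry.area

    def equal_area_radius(self) -> float:
        """Radius of the circle with the same area as the polygon."""
        return math.sqrt(self.geometry.area / math.pi)


@dataclass
class CrownSet:
    crowns: list[Crown] = field(default_factory=list)
    crs: Optional[str] = None

    def __post_init__(self) -> None:
        ids = [c.crown_id for c in self.crowns]
        if len(ids) != len(set(ids)):
            raise ValueError("crown_id values must be unique")

    def __len__(self) -> int:
        return len(self.crowns)

    def __iter__(self):
        return iter(self.crowns)

    def get(self, crown_id) -> Crown:
        for c in self.crowns:
            if c.crown_id == crown_id:
                return c
        raise KeyError(crown_id)

    def plot_ids(self) -> list:
        seen: dict = {}
        for c in self.crowns:
            seen.setdefault(c.plot_id, None)
        return list(seen)


@dataclass
class FieldTree:
    """One field-surveyed stem record."""

    stem_id: int | str
    x: float
    y: float
    height_m: Optional[float] = None
    dbh_cm: Optional[float] = None
    crown_radius_m: Optional[float] = None

    def __post_init__(self) -> None:
        if self.dbh_cm is not None and self.dbh_cm <= 0:
            raise ValueError(f"tree {self.stem_id}: stem diameter must be > 0")
        if self.height_m is not None and self.height_m <= 0:
            raise ValueError(f"tree {self.stem_id}: height must be > 0")


@dataclass
class FieldTreeSet:
    trees: list[FieldTree] = field(default_factory=list)
    crs: Optional[str] = None

    def __post_init__(self) -> None:
        ids = [t.stem_id for t in self.trees]
        if len(ids) != len(set(ids)):
            raise ValueError("stem_id values must be unique")

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)


def check_same_crs(*layers) -> None:
    """Raise if layers carry explicitly different CRS identifiers.

    Layers with ``crs=None`` are treated as unknown and not compared;
    nothing is ever silently reprojected.
    """
    known = [layer.crs for layer in layers if getattr(layer, "crs", None) is not None]
    if len(set(known)) > 1:
        raise ValueError(f"CRS mismatch between layers: {sorted(set(known))}")


def sequence_wavelengths(values: Sequence[float]) -> np.ndarray:
    return np.asarray(list(values), dtype=float)
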