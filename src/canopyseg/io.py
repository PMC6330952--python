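"""Readers and writers for the formats the pipeline consumes.

Rasters are GeoTIFFs: plain TIFF pixel data plus the two georeferencing
tags that define a north-up affine transform (ModelPixelScale, code 33550,
and ModelTiepoint, code 33922). CRS identifier, nodata sentinel and band
wavelengths travel in a JSON block stored in the ImageDescription tag, and
wavelengths may alternatively come from a sidecar CSV ``band,wavelength_nm``.
Crown polygons are GeoJSON; field-tree tables are CSV.
"""

from __future__ import annotations

import csv
import json
import os
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import mapping, shape

from .core import (
    Affine,
    Crown,
    CrownSet,
    FieldTree,
    FieldTreeSet,
    HyperCube,
    RasterGrid,
)

_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922

#: default field-tree CSV header mapping (configurable per call)
DEFAULT_TREE_COLUMNS = {
    "stem_id": "stem_id",
    "x": "x",
    "y": "y",
    "height_m": "height_m",
    "dbh_cm": "dbh_cm",
    "crown_radius_m": "crown_radius_m",
}


def _geo_extratags(transform: Affine, description: dict) -> list:
    if transform.b != 0.0 or transform.d != 0.0:
        raise ValueError("only north-up (non-rotated) transforms can be written")
    scale = (transform.a, -transform.e, 0.0)
    tiepoint = (0.0, 0.0, 0.0, transform.c, transform.f, 0.0)
    return [
        (_MODEL_PIXEL_SCALE, "d", 3, scale, True),
        (_MODEL_TIEPOINT, "d", 6, tiepoint, True),
    ]


def _parse_geo(page) -> tuple[Affine, dict]:
    scale = page.tags.get(_MODEL_PIXEL_SCALE)
    tie = page.tags.get(_MODEL_TIEPOINT)
    if scale is None or tie is None:
        raise ValueError("TIFF lacks georeferencing tags (not a GeoTIFF?)")
    sx, sy = float(scale.value[0]), float(scale.value[1])
    i, j, _, x, y, _ = (float(v) for v in tie.value[:6])
    # tiepoint maps raster point (i, j) to map point (x, y)
    transform = Affine(sx, 0.0, x - i * sx, 0.0, -sy, y + j * sy)
    desc = page.tags.get(270)
    meta: dict = {}
    if desc is not None:
        try:
            meta = json.loads(desc.value)
        except (TypeError, ValueError):
            meta = {}
    return transform, meta


def write_raster(grid: RasterGrid, path: str | os.PathLike) -> None:
    """Write a single-band RasterGrid as a GeoTIFF."""
    meta = {"crs": grid.crs, "nodata": grid.nodata}
    tifffile.imwrite(
        path,
        np.asarray(grid.values),
        description=json.dumps(meta),
        metadata=None,
        extratags=_geo_extratags(grid.transform, meta),
    )


def read_raster(path: str | os.PathLike) -> RasterGrid:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        values = tif.asarray()
        transform, meta = _parse_geo(tif.pages[0])
    if values.ndim == 3:
        raise ValueError(f"{path} is multi-band; use read_cube")
    return RasterGrid(values, transform, nodata=meta.get("nodata"), crs=meta.get("crs"))


def write_cube(cube: HyperCube, path: str | os.PathLike) -> None:
    """Write a HyperCube as a multi-page GeoTIFF with wavelengths in metadata."""
    meta = {
        "crs": cube.crs,
        "nodata": cube.bands[0].nodata,
        "wavelengths_nm": list(map(float, cube.wavelengths_nm)),
    }
    tifffile.imwrite(
        path,
        cube.as_array(),
        description=json.dumps(meta),
        metadata=None,
        extratags=_geo_extratags(cube.transform, meta),
    )


def read_wavelength_table(path: str | os.PathLike) -> np.ndarray:
    """Read a sidecar ``band,wavelength_nm`` CSV ordered by band index."""
    df = pd.read_csv(path)
    if "wavelength_nm" not in df.columns:
        raise ValueError("wavelength table needs a 'wavelength_nm' column")
    if "band" in df.columns:
        df = df.sort_values("band")
    return df["wavelength_nm"].to_numpy(dtype=float)


def read_cube(
    path: str | os.PathLike,
    wavelengths: Optional[Sequence[float] | str | os.PathLike] = None,
) -> HyperCube:
    """Read a multi-band GeoTIFF into a HyperCube.

    ``wavelengths`` may be an explicit sequence (nm), the path of a sidecar
    CSV, or None to use the wavelengths embedded in the file metadata.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        values = tif.asarray()
        transform, meta = _parse_geo(tif.pages[0])
    if values.ndim == 2:
        values = values[None]
    if wavelengths is None:
        wl = meta.get("wavelengths_nm")
        if wl is None:
            raise ValueError("no wavelengths in file metadata; pass them explicitly")
        wl = np.asarray(wl, dtype=float)
    elif isinstance(wavelengths, (str, os.PathLike)):
        wl = read_wavelength_table(wavelengths)
    else:
        wl = np.asarray(list(wavelengths), dtype=float)
    bands = [
        RasterGrid(v, transform, nodata=meta.get("nodata"), crs=meta.get("crs"))
        for v in values
    ]
    return HyperCube(bands, wl)


_CROWN_PROPS = ("plot_id", "species", "height_m", "radius_m")


def write_crowns(crown_set: CrownSet, path: str | os.PathLike) -> None:
    features = []
    for c in crown_set:
        props = {"crown_id": c.crown_id}
        for name in _CROWN_PROPS:
            value = getattr(c, name)
            if value is not None:
                props[name] = value
        features.append(
            {"type": "Feature", "geometry": mapping(c.geometry), "properties": props}
        )
    doc = {"type": "FeatureCollection", "features": features}
    if crown_set.crs is not None:
        doc["crs"] = {"type": "name", "properties": {"name": crown_set.crs}}
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_crowns(path: str | os.PathLike) -> CrownSet:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with open(path) as fh:
        doc = json.load(fh)
    crs = None
    if isinstance(doc.get("crs"), dict):
        crs = doc["crs"].get("properties", {}).get("name")
    crowns = []
    for i, feat in enumerate(doc.get("features", [])):
        props = feat.get("properties") or {}
        crowns.append(
            Crown(
                crown_id=props.get("crown_id", i),
                geometry=shape(feat["geometry"]),
                plot_id=props.get("plot_id"),
                species=props.get("species"),
                height_m=props.get("height_m"),
                radius_m=props.get("radius_m"),
            )
        )
    return CrownSet(crowns, crs=crs)


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    return float(value)


def read_field_trees(
    path: str | os.PathLike,
    columns: Optional[dict] = None,
    crs: Optional[str] = None,
) -> FieldTreeSet:
    """Read a stem table CSV.

    ``columns`` remaps the default header names
    (``stem_id,x,y,height_m,dbh_cm,crown_radius_m``) to those in the file.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    colmap = dict(DEFAULT_TREE_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path)
    for key in ("stem_id", "x", "y"):
        if colmap[key] not in df.columns:
            raise ValueError(f"tree table lacks required column {colmap[key]!r}")
    def column(key):
        name = colmap[key]
        return df[name] if name in df.columns else None

    trees = []
    for i in range(len(df)):
        sid = column("stem_id").iloc[i]
        if hasattr(sid, "item"):  # preserve integer ids (iterrows would upcast)
            sid = sid.item()
        trees.append(
            FieldTree(
                stem_id=sid,
                x=float(column("x").iloc[i]),
                y=float(column("y").iloc[i]),
                height_m=_opt_float(
                    column("height_m").iloc[i] if column("height_m") is not None else None
                ),
                dbh_cm=_opt_float(
                    column("dbh_cm").iloc[i] if column("dbh_cm") is not None else None
                ),
                crown_radius_m=_opt_float(
                    column("crown_radius_m").iloc[i]
                    if column("crown_radius_m") is not None
                    else None
                ),
            )
        )
    return FieldTreeSet(trees, crs=crs)


def write_field_trees(trees: FieldTreeSet, path: str | os.PathLike) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(DEFAULT_TREE_COLUMNS))
        for t in trees:
            writer.writerow(
                [t.stem_id, t.x, t.y, t.height_m, t.dbh_cm, t.crown_radius_m]
            )
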