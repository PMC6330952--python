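"""Individual tree crown delineation by seeded region growing.

The method works on a single near-infrared band of a hyperspectral cube
(the band nearest 810 nm by default), under the assumption that crown
apices are local radiance maxima:

1. non-vegetated pixels are masked out by an NDVI threshold;
2. tree tops (seeds) are local maxima of a square moving window;
3. each seed grows a 4-connected region, adding a neighbor pixel when it
   lies within ``dist_max`` pixels of the seed *and* its value exceeds
   ``perc_thresh`` times the seed value, iterated until no region grows;
4. each region's pixel centers are wrapped in a 2-D convex hull to give
   the final crown polygon.

Growth sweeps are level-synchronous: every region expands by one ring per
sweep, and a pixel claimed by several regions in the same sweep goes to
the region with the nearest seed (ties to the lower seed id). This makes
the output deterministic and independent of seed enumeration order.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Optional

import numpy as np
from scipy import ndimage
from shapely.geometry import MultiPoint, Polygon
from shapely.ops import unary_union

from .core import Affine, Crown, CrownSet, HyperCube, RasterGrid, band_nearest

logger = logging.getLogger(__name__)

NEIGHBORS_4 = ((0, -1), (-1, 0), (0, 1), (1, 0))


@dataclass(frozen=True)
class DelineationParams:
    """Tunable parameters of the region-growing delineation.

    window_px
        Side of the square moving window used for seed detection (odd, >= 3).
    perc_thresh
        Minimum fraction of the seed value a pixel must *exceed* to join
        the seed's region, in (0, 1).
    dist_max
        Maximum Euclidean distance (strict, in pixel units) from a region
        pixel's center to its seed center.
    ndvi_threshold
        Pixels with NDVI strictly below this are masked as non-vegetation.
    ndvi_red_nm / ndvi_nir_nm
        Wavelengths whose nearest bands provide the red and NIR reflectance
        for NDVI.
    delineation_nm
        Wavelength whose nearest band drives seed detection and growth.
    """

    window_px: int = 3
    perc_thresh: float = 0.4
    dist_max: float = 4.0
    ndvi_threshold: float = 0.6
    ndvi_red_nm: float = 680.0
    ndvi_nir_nm: float = 800.0
    delineation_nm: float = 810.0

    def __post_init__(self) -> None:
        if self.window_px < 3 or self.window_px % 2 == 0:
            raise ValueError("window_px must be an odd integer >= 3")
        if not 0.0 < self.perc_thresh < 1.0:
            raise ValueError("perc_thresh must lie in (0, 1)")
        if self.dist_max <= 0:
            raise ValueError("dist_max must be > 0")


class Seed(NamedTuple):
    seed_id: int
    row: int
    col: int
    value: float


@dataclass
class SeedSet:
    seeds: list[Seed] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.seeds)

    def __iter__(self):
        return iter(self.seeds)


@dataclass
class LabelMap:
    """Integer grid assigning pixels to crown regions (0 = unassigned)."""

    labels: np.ndarray
    transform: Affine
    seeds: SeedSet

    def region_pixels(self, k: int) -> np.ndarray:
        """(n, 2) array of (row, col) members of region k, scan order."""
        return np.argwhere(self.labels == k)

    def region_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


def compute_ndvi_mask(cube: HyperCube, params: DelineationParams) -> RasterGrid:
    """Boolean vegetation mask: True where NDVI >= threshold and data valid.

    NDVI = (NIR - RED) / (NIR + RED); only pixels strictly below the
    threshold are masked, so NDVI exactly at the threshold is kept.
    """
    red_band = cube.bands[band_nearest(cube, params.ndvi_red_nm)]
    nir_band = cube.bands[band_nearest(cube, params.ndvi_nir_nm)]
    red = red_band.values.astype(float)
    nir = nir_band.values.astype(float)
    valid = red_band.valid_mask() & nir_band.valid_mask()
    denom = nir + red
    valid &= denom != 0
    ndvi = np.full(red.shape, -np.inf)
    np.divide(nir - red, denom, out=ndvi, where=valid)
    mask = valid & (ndvi >= params.ndvi_threshold)
    if not mask.any():
        warnings.warn("NDVI mask removed every pixel", stacklevel=2)
    return RasterGrid(mask, cube.transform, crs=cube.crs)


def detect_seeds(
    band: RasterGrid, mask: RasterGrid, params: DelineationParams
) -> SeedSet:
    """Local-maximum seed detection with a square moving window.

    A pixel is a seed iff it is unmasked and equals the maximum of the
    window centered on it; masked pixels are excluded from the maximum and
    the window is clipped at image edges. Plateau pixels all tie the
    maximum, so each plateau pixel becomes a seed. Seed ids are assigned
    in raster-scan order starting from 1.
    """
    if band.shape != mask.shape:
        raise ValueError("band and mask must be aligned")
    values = band.values.astype(float)
    keep = mask.values.astype(bool) & band.valid_mask()
    padded = np.where(keep, values, -np.inf)
    local_max = ndimage.maximum_filter(
        padded, size=params.window_px, mode="constant", cval=-np.inf
    )
    is_seed = keep & (padded == local_max)
    seeds = [
        Seed(i + 1, int(r), int(c), float(values[r, c]))
        for i, (r, c) in enumerate(np.argwhere(is_seed))
    ]
    logger.info("detected %d seeds", len(seeds))
    return SeedSet(seeds)


def grow_regions(
    band: RasterGrid,
    seeds: SeedSet,
    mask: RasterGrid,
    params: DelineationParams,
) -> LabelMap:
    """Grow one region per seed by level-synchronous 4-connected sweeps.

    An unlabeled, unmasked neighbor of a region pixel joins region n iff
    its center lies strictly within ``dist_max`` pixels of seed n's center
    and its value strictly exceeds ``perc_thresh * s_n``. Within a sweep,
    a pixel proposed by several regions is claimed by the region with the
    nearest seed, ties to the lower seed id.
    """
    values = band.values.astype(float)
    keep = mask.values.astype(bool) & band.valid_mask()
    nrows, ncols = values.shape
    labels = np.zeros((nrows, ncols), dtype=np.int32)

    seed_pos: dict[int, tuple[int, int]] = {}
    seed_val: dict[int, float] = {}
    for s in seeds:
        if not keep[s.row, s.col]:
            raise ValueError(f"seed {s.seed_id} lies on a masked pixel")
        labels[s.row, s.col] = s.seed_id
        seed_pos[s.seed_id] = (s.row, s.col)
        seed_val[s.seed_id] = s.value

    frontier: dict[int, list[tuple[int, int]]] = {
        s.seed_id: [(s.row, s.col)] for s in seeds
    }
    n_sweeps = 0
    while frontier:
        n_sweeps += 1
        # pixel -> (distance-to-seed, seed_id) of the best claim so far
        claims: dict[tuple[int, int], tuple[float, int]] = {}
        for n, pixels in frontier.items():
            sr, sc = seed_pos[n]
            threshold = seed_val[n] * params.perc_thresh
            for r, c in pixels:
                for dr, dc in NEIGHBORS_4:
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < nrows and 0 <= cc < ncols):
                        continue
                    if labels[rr, cc] != 0 or not keep[rr, cc]:
                        continue
                    if values[rr, cc] <= threshold:
                        continue
                    dist = math.hypot(rr - sr, cc - sc)
                    if dist >= params.dist_max:
                        continue
                    best = claims.get((rr, cc))
                    if best is None or (dist, n) < best:
                        claims[(rr, cc)] = (dist, n)
        next_frontier: dict[int, list[tuple[int, int]]] = {}
        for (rr, cc), (_, n) in claims.items():
            labels[rr, cc] = n
            next_frontier.setdefault(n, []).append((rr, cc))
        frontier = next_frontier
    logger.info(
        "grew %d regions in %d sweeps", len(np.unique(labels[labels > 0])), n_sweeps
    )
    return LabelMap(labels, band.transform, seeds)


def _pixel_footprint(row: int, col: int, transform: Affine) -> Polygon:
    corners = [(col, row), (col + 1, row), (col + 1, row + 1), (col, row + 1)]
    pts = [
        (
            transform.a * c + transform.b * r + transform.c,
            transform.d * c + transform.e * r + transform.f,
        )
        for c, r in corners
    ]
    return Polygon(pts)


def regions_to_crowns(label_map: LabelMap, transform: Optional[Affine] = None) -> CrownSet:
    """Wrap every region's pixel centers in a 2-D convex hull polygon.

    Regions whose centers are degenerate (fewer than 3 points, or all
    collinear) would yield a zero-area hull; those regions instead emit
    the dissolved union of their member pixels' 1-pixel footprint squares
    so that area accounting downstream stays meaningful.
    """
    if transform is None:
        transform = label_map.transform
    crowns = []
    for k in label_map.region_ids():
        members = label_map.region_pixels(int(k))
        xs, ys = transform.pixel_center(members[:, 0], members[:, 1])
        hull = MultiPoint(list(zip(np.atleast_1d(xs), np.atleast_1d(ys)))).convex_hull
        if not isinstance(hull, Polygon) or hull.area == 0:
            hull = unary_union(
                [_pixel_footprint(int(r), int(c), transform) for r, c in members]
            )
        crowns.append(Crown(crown_id=int(k), geometry=hull))
    return CrownSet(crowns)


def delineate(
    cube: HyperCube,
    params: Optional[DelineationParams] = None,
    return_intermediate: bool = False,
):
    """Full delineation chain: NDVI mask -> seeds -> regions -> crowns.

    Crown ids equal seed ids. With ``return_intermediate=True`` also
    returns the vegetation mask, the seed set and the label map.
    """
    if params is None:
        params = DelineationParams()
    mask = compute_ndvi_mask(cube, params)
    band = cube.bands[band_nearest(cube, params.delineation_nm)]
    seeds = detect_seeds(band, mask, params)
    label_map = grow_regions(band, seeds, mask, params)
    crowns = regions_to_crowns(label_map)
    crowns.crs = cube.crs
    if return_intermediate:
        return crowns, mask, seeds, label_map
    return crowns


def tune_parameters(
    cube: HyperCube,
    reference: CrownSet,
    grid: Iterable[DelineationParams],
):
    """Supervised parameter search maximizing the two-level Jaccard score.

    Each candidate is run through :func:`delineate` and scored against the
    reference crowns with the plot-averaged Jaccard of
    :func:`canopyseg.evaluation.score_dataset`. Returns ``(best_params,
    table)`` where the table lists every candidate with its score; ties go
    to the earliest candidate in grid order.
    """
    from .evaluation import score_dataset

    candidates = list(grid)
    if not candidates:
        raise ValueError("empty parameter grid")
    rows = []
    best: tuple[float, int] | None = None
    for i, params in enumerate(candidates):
        predicted = delineate(cube, params)
        result = score_dataset(reference, predicted)
        score = result.dataset_score
        rows.append(
            {
                "window_px": params.window_px,
                "perc_thresh": params.perc_thresh,
                "dist_max": params.dist_max,
                "score": score,
                "n_crowns": len(predicted),
            }
        )
        if best is None or score > best[0]:
            best = (score, i)
    import pandas as pd

    return candidates[best[1]], pd.DataFrame(rows)


def parameter_grid(
    windows: Iterable[int],
    perc_threshs: Iterable[float],
    dist_maxes: Iterable[float],
    base: Optional[DelineationParams] = None,
) -> list[DelineationParams]:
    """Cartesian product of the three tunable parameters, grid order."""
    if base is None:
        base = DelineationParams()
    return [
        replace(base, window_px=w, perc_thresh=p, dist_max=d)
        for w in windows
        for p in perc_threshs
        for d in dist_maxes
    ]
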