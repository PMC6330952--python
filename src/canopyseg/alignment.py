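"""Crown-to-stem alignment with allometric gap filling.

Field stem tables and delineated crowns rarely carry complete attributes:
many stems lack a measured crown radius, and delineated crowns lack a
height unless one is read off a canopy height model. Both gaps are filled
with power-law allometries fitted by nonlinear least squares —

* field crown radius from height × stem diameter:  R = a·(H·D)^b
* crown height from crown radius:                   H = a·R^b

— after which each delineated crown is linked to the field tree minimizing

    D = D_pos + D_attr
    D_pos  = sqrt((X_itc − X_field)² + (Y_itc − Y_field)²)
    D_attr = sqrt((H_itc − H_field)² + (R_itc − R_field)²)

All distances are in meters; D_attr adds height and radius discrepancies
without weighting. The stem diameter stays in cm as recorded, so the H·D
regressor is in m·cm — the fitted coefficient ``a`` absorbs the units.

Crown position is the polygon centroid and crown radius the radius of the
equal-area circle, r = sqrt(area/π).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import shapely
from scipy.optimize import least_squares
from shapely.geometry.base import BaseGeometry

from .core import Crown, CrownSet, FieldTreeSet, RasterGrid


@dataclass
class PowerLawModel:
    """Fitted y = a·x^b relationship."""

    a: float
    b: float
    residual_sse: float
    n_fit: int
    converged: bool = True

    def predict(self, x) -> np.ndarray:
        return self.a * np.asarray(x, dtype=float) ** self.b


def _loglog_init(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    coef = np.polyfit(np.log(x), np.log(y), 1)
    return float(np.exp(coef[1])), float(coef[0])


def fit_power_law(x, y) -> PowerLawModel:
    """Nonlinear least squares for y = a·x^b on positive data.

    The search starts from the log–log ordinary-least-squares solution and
    stops when the relative SSE change drops below 1e-10 or after 200
    iterations. If the optimizer fails, the log–log estimate is returned
    with ``converged=False``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points to fit a power law")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fit requires strictly positive data")
    a0, b0 = _loglog_init(x, y)

    def residuals(p):
        return p[0] * x ** p[1] - y

    try:
        sol = least_squares(
            residuals, x0=[a0, b0], method="trf", ftol=1e-10, max_nfev=200 * 3
        )
        a, b = float(sol.x[0]), float(sol.x[1])
        sse = float(np.sum(sol.fun**2))
        converged = bool(sol.success) and a > 0
    except Exception:
        converged = False
    if not converged:
        warnings.warn("power-law fit did not converge; using log-log estimate")
        a, b = a0, b0
        sse = float(np.sum((a * x**b - y) ** 2))
    return PowerLawModel(a, b, sse, int(x.size), converged)


def impute_field_radius(trees: FieldTreeSet) -> tuple[FieldTreeSet, Optional[PowerLawModel]]:
    """Fill missing field crown radii from R = a·(H·D)^b.

    The model is fitted on stems with measured radius, height and
    diameter; measured radii are never overwritten. Returns the completed
    set and the fitted model (None when nothing was missing).
    """
    complete = [
        t
        for t in trees
        if t.crown_radius_m is not None
        and t.height_m is not None
        and t.dbh_cm is not None
    ]
    missing = [t for t in trees if t.crown_radius_m is None]
    if not missing:
        return trees, None
    if len(complete) < 3:
        raise ValueError("need >= 3 stems with radius, height and diameter to impute")
    x = np.array([t.height_m * t.dbh_cm for t in complete])
    y = np.array([t.crown_radius_m for t in complete])
    model = fit_power_law(x, y)
    out = []
    for t in trees:
        if t.crown_radius_m is None:
            if t.height_m is None or t.dbh_cm is None:
                raise ValueError(
                    f"tree {t.stem_id}: cannot impute radius without height and diameter"
                )
            t = replace(
                t, crown_radius_m=float(model.predict(t.height_m * t.dbh_cm))
            )
        out.append(t)
    return FieldTreeSet(out, crs=trees.crs), model


def itc_height_from_chm(crown: BaseGeometry | Crown, chm: RasterGrid) -> Optional[float]:
    """Maximum CHM value over pixels whose centers fall inside the crown.

    Returns None when no valid pixel center lies inside the polygon.
    """
    geom = crown.geometry if isinstance(crown, Crown) else crown
    minx, miny, maxx, maxy = geom.bounds
    r0, c0 = chm.transform.map_to_pixel(minx, miny)
    r1, c1 = chm.transform.map_to_pixel(maxx, maxy)
    rows = np.arange(
        max(0, int(np.floor(min(r0, r1)))), min(chm.shape[0], int(np.ceil(max(r0, r1))) + 1)
    )
    cols = np.arange(
        max(0, int(np.floor(min(c0, c1)))), min(chm.shape[1], int(np.ceil(max(c0, c1))) + 1)
    )
    if rows.size == 0 or cols.size == 0:
        return None
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    xs, ys = chm.transform.pixel_center(rr.ravel(), cc.ravel())
    inside = shapely.contains_xy(geom, xs, ys)
    if not inside.any():
        return None
    vals = chm.values[rr.ravel()[inside], cc.ravel()[inside]].astype(float)
    ok = np.isfinite(vals)
    if chm.nodata is not None:
        ok &= vals != chm.nodata
    if not ok.any():
        return None
    return float(vals[ok].max())


def impute_itc_height(crowns: CrownSet, chm: Optional[RasterGrid] = None) -> tuple[CrownSet, Optional[PowerLawModel]]:
    """Fill missing crown heights from H = a·R^b.

    When a CHM is supplied, heights are first read off it via
    :func:`itc_height_from_chm`; crowns still lacking a height (no CHM
    cover) are predicted from the allometry fitted on crowns with height.
    Crown radius is always derived from polygon area (equal-area circle).
    """
    staged = []
    for c in crowns:
        radius = c.radius_m if c.radius_m is not None else c.equal_area_radius()
        height = c.height_m
        if height is None and chm is not None:
            height = itc_height_from_chm(c, chm)
        staged.append(replace(c, radius_m=radius, height_m=height))
    missing = [c for c in staged if c.height_m is None]
    model = None
    if missing:
        complete = [c for c in staged if c.height_m is not None]
        if len(complete) < 3:
            raise ValueError("need >= 3 crowns with height to impute the rest")
        model = fit_power_law(
            [c.radius_m for c in complete], [c.height_m for c in complete]
        )
        staged = [
            replace(c, height_m=float(model.predict(c.radius_m)))
            if c.height_m is None
            else c
            for c in staged
        ]
    return CrownSet(staged, crs=crowns.crs), model


@dataclass
class MatchPair:
    itc_id: object
    stem_id: object
    d_pos: float
    d_attr: float
    d_total: float


@dataclass
class MatchResult:
    pairs: list[MatchPair]
    unmatched_itcs: list
    unmatched_trees: list

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "itc_id": p.itc_id,
                    "stem_id": p.stem_id,
                    "d_pos": p.d_pos,
                    "d_attr": p.d_attr,
                    "d_total": p.d_total,
                }
                for p in self.pairs
            ]
        )


def _distance_components(crown: Crown, tree) -> tuple[float, float]:
    cx, cy = crown.geometry.centroid.x, crown.geometry.centroid.y
    d_pos = float(np.hypot(cx - tree.x, cy - tree.y))
    if crown.height_m is None or crown.radius_m is None:
        raise ValueError(f"crown {crown.crown_id}: height/radius not imputed")
    if tree.height_m is None or tree.crown_radius_m is None:
        raise ValueError(f"tree {tree.stem_id}: height/radius not imputed")
    d_attr = float(
        np.hypot(crown.height_m - tree.height_m, crown.radius_m - tree.crown_radius_m)
    )
    return d_pos, d_attr


def match(
    itcs: CrownSet,
    trees: FieldTreeSet,
    mode: str = "nearest",
    max_distance: Optional[float] = None,
) -> MatchResult:
    """Link delineated crowns to field stems by combined distance D.

    ``mode="nearest"``: every crown takes its argmin-D tree; a tree may be
    claimed by several crowns. ``mode="one-to-one"``: candidate pairs are
    accepted greedily in ascending D with each crown and tree used at most
    once. ``max_distance`` optionally rejects pairs with D above it
    (off by default).
    """
    if mode not in ("nearest", "one-to-one"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(itcs) == 0 or len(trees) == 0:
        raise ValueError("need at least one crown and one tree")
    crowns = list(itcs)
    stems = list(trees)
    d_pos = np.empty((len(crowns), len(stems)))
    d_attr = np.empty_like(d_pos)
    for i, c in enumerate(crowns):
        for j, t in enumerate(stems):
            d_pos[i, j], d_attr[i, j] = _distance_components(c, t)
    d_total = d_pos + d_attr

    pairs: list[MatchPair] = []
    if mode == "nearest":
        for i, c in enumerate(crowns):
            j = int(np.argmin(d_total[i]))
            if max_distance is not None and d_total[i, j] > max_distance:
                continue
            pairs.append(
                MatchPair(
                    c.crown_id,
                    stems[j].stem_id,
                    float(d_pos[i, j]),
                    float(d_attr[i, j]),
                    float(d_total[i, j]),
                )
            )
    else:
        order = sorted(
            ((d_total[i, j], i, j) for i in range(len(crowns)) for j in range(len(stems)))
        )
        used_i: set[int] = set()
        used_j: set[int] = set()
        for d, i, j in order:
            if i in used_i or j in used_j:
                continue
            if max_distance is not None and d > max_distance:
                break
            used_i.add(i)
            used_j.add(j)
            pairs.append(
                MatchPair(
                    crowns[i].crown_id,
                    stems[j].stem_id,
                    float(d_pos[i, j]),
                    float(d_attr[i, j]),
                    float(d),
                )
            )
    matched_itcs = {p.itc_id for p in pairs}
    matched_trees = {p.stem_id for p in pairs}
    return MatchResult(
        pairs,
        [c.crown_id for c in crowns if c.crown_id not in matched_itcs],
        [t.stem_id for t in stems if t.stem_id not in matched_trees],
    )
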