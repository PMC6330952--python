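"""Scoring of delineated crowns against reference (manually drawn) crowns.

Two complementary views are provided:

* per-crown **Jaccard** overlap, averaged first within field plots and
  then across plots (the two-level mean used to rank delineations); and
* an area-based **overall confusion matrix** (OCM) accumulating, in m²,
  how much reference crown area was covered, how much was missed, and how
  much delineated area fell outside every reference crown.

The OCM cells are stored under neutral names (``ref_covered_m2``,
``ref_missed_m2``, ``pred_excess_m2``); the challenge's own bar-chart
labels call these TruePositive, FalsePositive and FalseNegative
respectively, and :meth:`AreaConfusion.report_labels` exposes that
(non-standard) naming for comparability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union
from shapely.strtree import STRtree

from .core import CrownSet, check_same_crs

#: intersection/union areas below this (m²) are treated as zero
AREA_EPS = 1e-9


def jaccard(a: BaseGeometry, b: BaseGeometry) -> float:
    """Jaccard overlap |A∩B| / |A∪B| of two polygons, in [0, 1].

    Returns 0 when the union area is zero (two empty geometries).
    """
    if not (a.is_valid and b.is_valid):
        raise ValueError("invalid geometry")
    inter = a.intersection(b).area
    union = a.area + b.area - inter
    if union <= AREA_EPS:
        return 0.0
    if inter <= AREA_EPS:
        return 0.0
    return inter / union


@dataclass
class OverlapScore:
    reference_id: object
    best_predicted_id: Optional[object]
    jaccard: float


@dataclass
class DatasetScore:
    scores: list[OverlapScore]
    plot_scores: dict
    dataset_score: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "reference_id": s.reference_id,
                    "best_predicted_id": s.best_predicted_id,
                    "jaccard": s.jaccard,
                }
                for s in self.scores
            ]
        )


def _best_overlaps(reference: CrownSet, predicted: CrownSet) -> list[OverlapScore]:
    pred_geoms = [c.geometry for c in predicted]
    pred_ids = [c.crown_id for c in predicted]
    tree = STRtree(pred_geoms) if pred_geoms else None
    out = []
    for ref in reference:
        best_id, best_j = None, 0.0
        if tree is not None:
            for idx in tree.query(ref.geometry):
                j = jaccard(ref.geometry, pred_geoms[idx])
                if j > best_j:
                    best_j, best_id = j, pred_ids[idx]
        out.append(OverlapScore(ref.crown_id, best_id, best_j))
    return out


def score_dataset(reference: CrownSet, predicted: CrownSet) -> DatasetScore:
    """Two-level Jaccard score of a delineation.

    Every reference crown keeps the Jaccard of its best-overlapping
    predicted crown (0 if none overlaps; a predicted crown may be the best
    match of several references). The plot score is the mean over the
    plot's reference crowns and the dataset score the mean over plot
    scores — *not* the flat mean over crowns.
    """
    check_same_crs(reference, predicted)
    scores = _best_overlaps(reference, predicted)
    by_plot: dict = {}
    for ref, s in zip(reference, scores):
        by_plot.setdefault(ref.plot_id, []).append(s.jaccard)
    plot_scores = {}
    for plot_id, vals in by_plot.items():
        if not vals:
            warnings.warn(f"plot {plot_id!r} has no reference crowns; excluded")
            continue
        plot_scores[plot_id] = float(np.mean(vals))
    dataset = float(np.mean(list(plot_scores.values()))) if plot_scores else 0.0
    return DatasetScore(scores, plot_scores, dataset)


@dataclass
class AreaConfusion:
    """Area accounting (m²) between dissolved reference and predicted crowns."""

    ref_covered_m2: float
    ref_missed_m2: float
    pred_excess_m2: float
    per_plot: dict = field(default_factory=dict)

    @property
    def reference_area_m2(self) -> float:
        return self.ref_covered_m2 + self.ref_missed_m2

    @property
    def predicted_area_m2(self) -> float:
        return self.ref_covered_m2 + self.pred_excess_m2

    def report_labels(self) -> dict:
        """The challenge's bar-chart naming of the three cells."""
        return {
            "TruePositive": self.ref_covered_m2,
            "FalsePositive": self.ref_missed_m2,
            "FalseNegative": self.pred_excess_m2,
        }


def _confusion_cells(ref_geoms, pred_geoms) -> tuple[float, float, float]:
    ref_union = unary_union(ref_geoms) if ref_geoms else None
    pred_union = unary_union(pred_geoms) if pred_geoms else None
    ref_area = ref_union.area if ref_union is not None else 0.0
    pred_area = pred_union.area if pred_union is not None else 0.0
    if ref_union is None or pred_union is None:
        tp = 0.0
    else:
        tp = ref_union.intersection(pred_union).area
    return tp, max(ref_area - tp, 0.0), max(pred_area - tp, 0.0)


def area_confusion(reference: CrownSet, predicted: CrownSet) -> AreaConfusion:
    """Overall confusion matrix of crown area, total and per plot.

    Reference and predicted polygons are dissolved (unioned) before
    intersecting so overlapping crowns are never double counted. For the
    per-plot breakdown each predicted crown is attributed to the plot
    whose reference crowns it overlaps most (by intersection area);
    predicted crowns overlapping no reference fall under plot ``None``.
    """
    check_same_crs(reference, predicted)
    ref_geoms = [c.geometry for c in reference]
    pred_geoms = [c.geometry for c in predicted]
    tp, fp, fn = _confusion_cells(ref_geoms, pred_geoms)

    per_plot: dict = {}
    plots = reference.plot_ids()
    if plots and plots != [None]:
        plot_ref_union = {
            plot_id: unary_union(
                [c.geometry for c in reference if c.plot_id == plot_id]
            )
            for plot_id in plots
        }
        plot_preds: dict = {plot_id: [] for plot_id in plots}
        plot_preds[None] = []
        for g in pred_geoms:
            overlaps = {
                plot_id: plot_ref_union[plot_id].intersection(g).area
                for plot_id in plots
            }
            best = max(overlaps, key=lambda p: (overlaps[p],))
            plot_preds[best if overlaps[best] > AREA_EPS else None].append(g)
        for plot_id in plots:
            cells = _confusion_cells(
                [plot_ref_union[plot_id]], plot_preds[plot_id]
            )
            per_plot[plot_id] = AreaConfusion(*cells)
        if plot_preds[None]:
            per_plot[None] = AreaConfusion(
                0.0, 0.0, unary_union(plot_preds[None]).area
            )
    return AreaConfusion(tp, fp, fn, per_plot)


def score_by_area_bins(
    scores: Sequence[OverlapScore] | DatasetScore,
    reference: CrownSet,
    bin_edges_m2: Sequence[float],
) -> pd.DataFrame:
    """Mean best-Jaccard of reference crowns grouped by crown area (m²).

    Bins are ``[edge_i, edge_{i+1})`` with the last bin closed on the
    right. Empty bins are reported with a NaN mean, not zero.
    """
    if isinstance(scores, DatasetScore):
        scores = scores.scores
    edges = np.asarray(list(bin_edges_m2), dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be increasing with at least two values")
    areas = np.array([reference.get(s.reference_id).area_m2 for s in scores])
    if len(areas) and (areas.min() < edges[0] or areas.max() > edges[-1]):
        raise ValueError("bins do not cover the observed crown areas")
    values = np.array([s.jaccard for s in scores])
    idx = np.clip(np.digitize(areas, edges) - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        members = values[idx == b]
        rows.append(
            {
                "area_min_m2": edges[b],
                "area_max_m2": edges[b + 1],
                "n_crowns": int(members.size),
                "mean_jaccard": float(members.mean()) if members.size else np.nan,
            }
        )
    return pd.DataFrame(rows)
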