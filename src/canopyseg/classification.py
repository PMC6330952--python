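"""Pixel-level tree species classification with crown-level aggregation.

The classification chain is: (1) per-pixel brightness normalization (each
spectrum divided by its band sum, removing illumination differences
between flight lines); (2) band selection by sequential forward floating
selection (SFFS) under the Jeffries–Matusita (JM) separability criterion;
(3) a multiclass RBF support vector machine on the selected bands plus
the crown's canopy-height value; (4) a majority vote over the pixels of
each crown; (5) confusion-matrix accuracy metrics (overall, kappa,
producer's/user's, mean class accuracy).

The JM distance between two classes modeled as Gaussians N(μi, Σi),
N(μj, Σj) is ``JM = 2(1 − e^(−B))`` with Bhattacharyya distance

    B = 1/8 (μi−μj)ᵀ [(Σi+Σj)/2]⁻¹ (μi−μj)
        + 1/2 ln( |(Σi+Σj)/2| / sqrt(|Σi||Σj|) )

bounded in [0, 2], with 2 meaning asymptotically perfect separability.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import shapely
from sklearn.model_selection import GridSearchCV, KFold, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core import CrownSet, HyperCube, RasterGrid, check_same_crs


@dataclass
class ClassifierConfig:
    """Knobs of the species-classification chain."""

    max_features: int = 40
    criterion: str = "mean"  # mean or min of pairwise JM
    ridge: float = 1e-6
    svm_c: Sequence[float] = (1.0, 10.0, 100.0)
    svm_gamma_factors: Sequence[float] = (0.1, 1.0, 10.0)
    cv_folds: int = 5
    seed: int = 1234


@dataclass
class PixelTable:
    """Per-pixel feature rows extracted from crowns."""

    features: np.ndarray  # (n_pixels, n_features)
    crown_id: np.ndarray
    plot_id: np.ndarray
    species: Optional[np.ndarray] = None

    def __len__(self) -> int:
        return len(self.features)


def normalize_pixels(spectra: np.ndarray) -> np.ndarray:
    """Divide every pixel spectrum by its sum over bands (rows sum to 1).

    All-zero rows cannot be normalized; they are dropped with a warning.
    """
    spectra = np.asarray(spectra, dtype=float)
    sums = spectra.sum(axis=1)
    keep = sums != 0
    if not keep.all():
        warnings.warn(f"dropped {np.count_nonzero(~keep)} all-zero pixel rows")
        spectra, sums = spectra[keep], sums[keep]
    return spectra / sums[:, None]


@dataclass
class ClassStats:
    """Gaussian summary (mean, covariance, count) of one class's pixels."""

    mean: np.ndarray
    cov: np.ndarray
    count: int


def class_stats(
    features: np.ndarray, labels: np.ndarray, ridge: float = 1e-6
) -> dict[str, ClassStats]:
    """Per-class mean/covariance with a diagonal ridge for invertibility.

    Classes with fewer than 2 pixels cannot provide a covariance and are
    excluded with a warning.
    """
    out: dict[str, ClassStats] = {}
    for cls in np.unique(labels):
        rows = features[labels == cls]
        if len(rows) < 2:
            warnings.warn(f"class {cls!r} has < 2 pixels; excluded from separability")
            continue
        cov = np.cov(rows, rowvar=False).reshape(rows.shape[1], rows.shape[1])
        cov = cov + ridge * np.eye(rows.shape[1])
        out[str(cls)] = ClassStats(rows.mean(axis=0), cov, len(rows))
    return out


def jm_distance(stats_i: ClassStats, stats_j: ClassStats) -> float:
    """Jeffries–Matusita separability of two Gaussian classes, in [0, 2]."""
    dmu = stats_i.mean - stats_j.mean
    sigma = 0.5 * (stats_i.cov + stats_j.cov)
    maha = float(dmu @ np.linalg.solve(sigma, dmu)) / 8.0
    sign, logdet_avg = np.linalg.slogdet(sigma)
    _, logdet_i = np.linalg.slogdet(stats_i.cov)
    _, logdet_j = np.linalg.slogdet(stats_j.cov)
    if sign <= 0:
        raise np.linalg.LinAlgError("average covariance not positive definite")
    bhatt = maha + 0.5 * (logdet_avg - 0.5 * (logdet_i + logdet_j))
    return float(2.0 * (1.0 - np.exp(-bhatt)))


def _subset_criterion(
    features: np.ndarray,
    labels: np.ndarray,
    subset: Sequence[int],
    ridge: float,
    how: str,
) -> float:
    stats = class_stats(features[:, list(subset)], labels, ridge)
    if len(stats) < 2:
        raise ValueError("need >= 2 classes with >= 2 pixels each")
    pairwise = [
        jm_distance(stats[a], stats[b]) for a, b in combinations(sorted(stats), 2)
    ]
    return float(np.mean(pairwise) if how == "mean" else np.min(pairwise))


@dataclass
class SFFSResult:
    selected: list[int]
    best_at_size: dict[int, tuple[list[int], float]]
    trace: list[tuple[list[int], float]] = field(default_factory=list)

    @property
    def criterion(self) -> float:
        return self.best_at_size[len(self.selected)][1]


def sffs_select(
    features: np.ndarray,
    labels: np.ndarray,
    max_features: int,
    ridge: float = 1e-6,
    criterion: str = "mean",
) -> SFFSResult:
    """Sequential forward floating selection of band indices.

    Forward steps add the band maximizing the JM criterion of the
    candidate subset; after each addition, bands are conditionally removed
    as long as removal beats the best criterion already recorded at the
    smaller size. Returns the best subset found at ``max_features`` along
    with the best-at-size record for every cardinality visited.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    n_bands = features.shape[1]
    max_features = min(max_features, n_bands)
    if max_features < 1:
        raise ValueError("max_features must be >= 1")

    def score(subset: Sequence[int]) -> float:
        return _subset_criterion(features, labels, subset, ridge, criterion)

    current: list[int] = []
    best_at_size: dict[int, tuple[list[int], float]] = {}
    trace: list[tuple[list[int], float]] = []

    def record(subset: list[int], value: float) -> None:
        trace.append((list(subset), value))
        k = len(subset)
        if k not in best_at_size or value > best_at_size[k][1]:
            best_at_size[k] = (list(subset), value)

    while len(current) < max_features:
        remaining = [j for j in range(n_bands) if j not in current]
        if not remaining:
            break
        scores = [score(current + [j]) for j in remaining]
        j_best = remaining[int(np.argmax(scores))]
        current.append(j_best)
        record(current, max(scores))
        # floating (conditional exclusion) phase
        while len(current) > 2:
            drop_scores = [
                (score([b for b in current if b != j]), j) for j in current
            ]
            value, j_drop = max(drop_scores, key=lambda t: (t[0], -current.index(t[1])))
            k = len(current) - 1
            if j_drop != current[-1] and value > best_at_size.get(k, (None, -np.inf))[1]:
                current = [b for b in current if b != j_drop]
                record(current, value)
            else:
                break
    selected = best_at_size[max_features][0] if max_features in best_at_size else current
    return SFFSResult(list(selected), best_at_size, trace)


def train_and_predict(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    test_features: np.ndarray,
    config: Optional[ClassifierConfig] = None,
) -> np.ndarray:
    """Cross-validated RBF SVM: fit on training pixels, label test pixels.

    Features are z-scored with training statistics inside the model
    pipeline; C and γ are chosen by k-fold cross-validation (stratified
    when every class has at least ``cv_folds`` pixels, plain otherwise).
    Deterministic for a fixed config seed.
    """
    if config is None:
        config = ClassifierConfig()
    train_features = np.asarray(train_features, dtype=float)
    test_features = np.asarray(test_features, dtype=float)
    train_labels = np.asarray(train_labels)
    if len(np.unique(train_labels)) < 2:
        raise ValueError("need >= 2 classes to train the classifier")
    d = train_features.shape[1]
    gamma_grid = [f / d for f in config.svm_gamma_factors]
    counts = Counter(train_labels.tolist())
    n_folds = min(config.cv_folds, len(train_labels))
    if min(counts.values()) >= n_folds:
        cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=config.seed)
    else:
        warnings.warn("a class has too few pixels to stratify; plain k-fold used")
        cv = KFold(n_splits=n_folds, shuffle=True, random_state=config.seed)
    pipe = Pipeline(
        [("scale", StandardScaler()), ("svm", SVC(kernel="rbf", random_state=config.seed))]
    )
    search = GridSearchCV(
        pipe,
        {"svm__C": list(config.svm_c), "svm__gamma": gamma_grid},
        cv=cv,
        n_jobs=1,
    )
    search.fit(train_features, train_labels)
    return search.predict(test_features)


def aggregate_majority(
    pixel_labels: Sequence,
    crown_ids: Sequence,
    training_counts: Optional[dict] = None,
) -> dict:
    """Per-crown species by majority vote over the crown's pixel labels.

    Ties go to the class with more training samples (when counts are
    given), then alphabetically.
    """
    pixel_labels = list(pixel_labels)
    crown_ids = list(crown_ids)
    if len(pixel_labels) != len(crown_ids):
        raise ValueError("one crown_id per pixel label required")
    votes: dict = {}
    for label, cid in zip(pixel_labels, crown_ids):
        votes.setdefault(cid, Counter())[label] += 1
    out = {}
    for cid, counter in votes.items():
        top = max(counter.values())
        tied = sorted(c for c, n in counter.items() if n == top)
        if len(tied) > 1 and training_counts:
            tied.sort(key=lambda c: (-training_counts.get(c, 0), c))
        out[cid] = tied[0]
    return out


@dataclass
class ConfusionMatrix:
    """Square count matrix, rows = predicted species, columns = reference."""

    counts: np.ndarray
    classes: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        n = len(self.classes)
        if self.counts.shape != (n, n):
            raise ValueError("counts must be square with one row per class")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_labels(
        cls, predicted: Sequence, reference: Sequence, classes: Optional[Sequence[str]] = None
    ) -> "ConfusionMatrix":
        if classes is None:
            classes = sorted(set(map(str, predicted)) | set(map(str, reference)))
        classes = list(classes)
        index = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)))
        for p, r in zip(predicted, reference):
            counts[index[str(p)], index[str(r)]] += 1
        return cls(counts, classes)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


def confusion_metrics(cm: ConfusionMatrix) -> dict:
    """Accuracy metrics of a confusion matrix, all in percent.

    overall_accuracy = 100·trace/total; producer's(c) = 100·diag/column
    total (recall); user's(c) = 100·diag/row total (precision); mean class
    accuracy = unweighted mean of producer's over classes with samples;
    kappa = 100·(p_o − p_e)/(1 − p_e) with p_e from the marginals.
    Classes with a zero denominator get NaN and are excluded from the mean.
    """
    counts = cm.counts
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(counts)
    row_tot = counts.sum(axis=1)
    col_tot = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        producers = np.where(col_tot > 0, 100.0 * diag / col_tot, np.nan)
        users = np.where(row_tot > 0, 100.0 * diag / row_tot, np.nan)
    p_o = diag.sum() / total
    p_e = float(row_tot @ col_tot) / total**2
    kappa = 100.0 * (p_o - p_e) / (1.0 - p_e) if p_e < 1.0 else 100.0
    return {
        "overall_accuracy": 100.0 * p_o,
        "kappa": kappa,
        "mean_class_accuracy": float(np.nanmean(producers)),
        "producers_accuracy": dict(zip(cm.classes, producers.tolist())),
        "users_accuracy": dict(zip(cm.classes, users.tolist())),
        "n_samples": float(total),
    }


def extract_crown_pixels(
    cube: HyperCube, crowns: CrownSet, with_species: bool = True
) -> PixelTable:
    """Raw spectra of every pixel whose center falls inside a crown polygon.

    Crowns covering no pixel center are flagged with a warning and skipped.
    """
    check_same_crs(cube.bands[0], crowns)
    data = cube.as_array()
    rows_feat, rows_cid, rows_pid, rows_sp = [], [], [], []
    nrows, ncols = cube.shape
    for crown in crowns:
        minx, miny, maxx, maxy = crown.geometry.bounds
        r0, c0 = cube.transform.map_to_pixel(minx, miny)
        r1, c1 = cube.transform.map_to_pixel(maxx, maxy)
        rr = np.arange(max(0, int(np.floor(min(r0, r1)))), min(nrows, int(np.ceil(max(r0, r1))) + 1))
        cc = np.arange(max(0, int(np.floor(min(c0, c1)))), min(ncols, int(np.ceil(max(c0, c1))) + 1))
        if rr.size == 0 or cc.size == 0:
            warnings.warn(f"crown {crown.crown_id} covers no pixel; skipped")
            continue
        gr, gc = np.meshgrid(rr, cc, indexing="ij")
        xs, ys = cube.transform.pixel_center(gr.ravel(), gc.ravel())
        inside = shapely.contains_xy(crown.geometry, xs, ys)
        if not inside.any():
            warnings.warn(f"crown {crown.crown_id} covers no pixel; skipped")
            continue
        sel_r, sel_c = gr.ravel()[inside], gc.ravel()[inside]
        rows_feat.append(data[:, sel_r, sel_c].T)
        rows_cid.extend([crown.crown_id] * len(sel_r))
        rows_pid.extend([crown.plot_id] * len(sel_r))
        rows_sp.extend([crown.species] * len(sel_r))
    if not rows_feat:
        raise ValueError("no crown covered any pixel")
    return PixelTable(
        np.vstack(rows_feat),
        np.asarray(rows_cid, dtype=object),
        np.asarray(rows_pid, dtype=object),
        np.asarray(rows_sp, dtype=object) if with_species else None,
    )


@dataclass
class ClassificationReport:
    crown_species: dict
    selected_bands: list[int]
    confusion: Optional[ConfusionMatrix]
    metrics: Optional[dict]


def classify_crowns(
    cube: HyperCube,
    chm: RasterGrid,
    train_crowns: CrownSet,
    test_crowns: CrownSet,
    config: Optional[ClassifierConfig] = None,
) -> ClassificationReport:
    """End-to-end crown species classification.

    Pixels inside the training/test crowns are extracted from the cube and
    sum-normalized; SFFS selects the most separable bands on the training
    pixels; each pixel's feature vector is the selected bands plus its
    crown's maximum CHM value; an RBF SVM labels test pixels, which are
    aggregated per crown by majority vote. When the test crowns carry
    species labels, a confusion matrix and accuracy metrics are computed.
    """
    from .alignment import itc_height_from_chm

    if config is None:
        config = ClassifierConfig()
    train_px = extract_crown_pixels(cube, train_crowns)
    if train_px.species is None or len(set(train_px.species) - {None}) < 2:
        raise ValueError("training crowns must carry >= 2 species labels")
    test_px = extract_crown_pixels(cube, test_crowns)

    def prepare(px: PixelTable) -> PixelTable:
        sums = px.features.sum(axis=1)
        keep = sums != 0
        if not keep.all():
            warnings.warn(f"dropped {np.count_nonzero(~keep)} all-zero pixel rows")
        return PixelTable(
            normalize_pixels(px.features[keep]),
            px.crown_id[keep],
            px.plot_id[keep],
            None if px.species is None else px.species[keep],
        )

    train_px = prepare(train_px)
    test_px = prepare(test_px)

    sffs = sffs_select(
        train_px.features,
        train_px.species,
        config.max_features,
        ridge=config.ridge,
        criterion=config.criterion,
    )

    chm_by_crown: dict = {}
    for crown_set in (train_crowns, test_crowns):
        for crown in crown_set:
            h = itc_height_from_chm(crown, chm)
            chm_by_crown[crown.crown_id] = 0.0 if h is None else h

    def feature_matrix(px: PixelTable) -> np.ndarray:
        chm_col = np.array([chm_by_crown[cid] for cid in px.crown_id])
        return np.column_stack([px.features[:, sffs.selected], chm_col])

    pixel_pred = train_and_predict(
        feature_matrix(train_px), train_px.species, feature_matrix(test_px), config
    )
    training_counts = Counter(map(str, train_px.species))
    crown_species = aggregate_majority(
        [str(p) for p in pixel_pred], test_px.crown_id, training_counts
    )

    confusion = None
    metrics = None
    truth = {c.crown_id: c.species for c in test_crowns if c.species is not None}
    scored = [cid for cid in crown_species if cid in truth]
    if scored:
        classes = sorted(
            set(map(str, training_counts)) | {str(truth[c]) for c in scored}
        )
        confusion = ConfusionMatrix.from_labels(
            [crown_species[c] for c in scored],
            [str(truth[c]) for c in scored],
            classes,
        )
        metrics = confusion_metrics(confusion)
    return ClassificationReport(crown_species, list(sffs.selected), confusion, metrics)
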