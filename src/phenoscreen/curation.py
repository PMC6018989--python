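"""Automated curation of segmented cell contours.

High-throughput segmentation inevitably produces mis-detected contours
(merged cells, debris, out-of-focus objects).  This module trains a
linear max-margin classifier (SVM) over 16 robustly normalized per-cell
features to separate correctly detected cells from artefacts, evaluates
it by k-fold cross-validation / AUROC / balanced classification rate,
and applies it to whole screens.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import LinearSVC

from . import geometry

__all__ = [
    "CONTOUR_FEATURES",
    "SchemaError",
    "ContourFeatures",
    "CurationModel",
    "ClassifierReport",
    "extract_contour_features",
    "train_curation_model",
    "cross_validate",
    "evaluate_classifier",
    "apply_curation",
]

#: the 16 per-cell features used by the contour classifier
CONTOUR_FEATURES = [
    "length",
    "width",
    "area",
    "volume",
    "perimeter",
    "constriction_degree",
    "division_ratio",
    "integrated_phase",
    "integrated_dapi",
    "mean_contour_phase",
    "intracell_width_variability",
    "nucleoid_area",
    "nucleoid_variability",
    "circularity",
    "nucleoid_intensity",
    "nucleoid_count",
]

_REQUIRED_COLUMNS = [
    "length_um",
    "width_um",
    "area_um2",
    "perimeter_um",
    "constriction_degree",
    "division_ratio",
    "phase_mean",
    "dapi_total",
    "contour_phase_mean",
    "intracell_width_cv",
    "nucleoid_area_um2",
    "nucleoid_constriction_degree",
    "nucleoid_count",
]


class SchemaError(KeyError):
    """A required cell-table column is absent."""


@dataclass
class ContourFeatures:
    """Raw 16-feature vectors plus the robust normalization fitted on them."""

    values: pd.DataFrame  # rows = cells, columns = CONTOUR_FEATURES (+ indicator)
    center: pd.Series  # per-feature median
    scale: pd.Series  # per-feature iqr (0 replaced by 1)

    @property
    def normalized(self) -> pd.DataFrame:
        return (self.values - self.center) / self.scale


def extract_contour_features(table: pd.DataFrame) -> ContourFeatures:
    """Build the 16 normalized features from a cell table.

    Missing division ratios (cells without a visible constriction) are
    imputed at 0.5 and tracked through an explicit missingness
    indicator column so the classifier can use the absence itself.
    """
    missing = [c for c in _REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"cell table is missing required column(s): {missing}")

    l = table["length_um"].to_numpy(dtype=float)
    w = table["width_um"].to_numpy(dtype=float)
    area = table["area_um2"].to_numpy(dtype=float)
    perim = table["perimeter_um"].to_numpy(dtype=float)
    dr = table["division_ratio"].to_numpy(dtype=float)
    dr_missing = ~np.isfinite(dr)
    na = table["nucleoid_area_um2"].to_numpy(dtype=float)

    with np.errstate(divide="ignore", invalid="ignore"):
        feats = pd.DataFrame(
            {
                "length": l,
                "width": w,
                "area": area,
                "volume": geometry.spherocylinder_volume(l, w),
                "perimeter": perim,
                "constriction_degree": table["constriction_degree"].to_numpy(dtype=float),
                "division_ratio": np.where(dr_missing, 0.5, dr),
                "integrated_phase": table["phase_mean"].to_numpy(dtype=float) * area,
                "integrated_dapi": table["dapi_total"].to_numpy(dtype=float),
                "mean_contour_phase": table["contour_phase_mean"].to_numpy(dtype=float),
                "intracell_width_variability": table["intracell_width_cv"].to_numpy(dtype=float),
                "nucleoid_area": na,
                "nucleoid_variability": table["nucleoid_constriction_degree"].to_numpy(dtype=float),
                "circularity": geometry.circularity(area, perim),
                "nucleoid_intensity": np.where(
                    na > 0, table["dapi_total"].to_numpy(dtype=float) / np.where(na > 0, na, 1.0), 0.0
                ),
                "nucleoid_count": table["nucleoid_count"].to_numpy(dtype=float),
            },
            index=table.index,
        )
    feats["division_ratio_missing"] = dr_missing.astype(float)
    feats = feats.replace([np.inf, -np.inf], np.nan)
    feats = feats.fillna(feats.median(numeric_only=True)).fillna(0.0)

    center = feats.median()
    scale = feats.quantile(0.75) - feats.quantile(0.25)
    scale = scale.where(scale > 0, 1.0)
    return ContourFeatures(values=feats, center=center, scale=scale)


@dataclass
class CurationModel:
    """A linear decision rule over normalized contour features."""

    feature_names: list[str]
    weights: np.ndarray
    bias: float
    center: np.ndarray
    scale: np.ndarray
    metadata: dict = field(default_factory=dict)

    def decision_function(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names].to_numpy(dtype=float)
        Xn = (np.asarray(X, dtype=float) - self.center) / self.scale
        return Xn @ self.weights + self.bias

    def predict(self, X) -> np.ndarray:
        return self.decision_function(X) > 0

    def to_json(self) -> str:
        d = asdict(self)
        for k in ("weights", "center", "scale"):
            d[k] = list(map(float, d[k]))
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "CurationModel":
        d = json.loads(text)
        for k in ("weights", "center", "scale"):
            d[k] = np.asarray(d[k], dtype=float)
        return cls(**d)


@dataclass
class ClassifierReport:
    tp: int
    fp: int
    tn: int
    fn: int
    auroc: float
    balanced_rate: float
    misclassification: float


def _rank_auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUROC by the Mann-Whitney rank statistic (exact average-rank ties)."""
    labels = np.asarray(labels, dtype=bool)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        return np.nan
    ranks = rankdata(scores, method="average")
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _fit_linear_svm(Xn: np.ndarray, y: np.ndarray, C: float, seed: int) -> LinearSVC:
    clf = LinearSVC(C=C, class_weight="balanced", dual=False, max_iter=20000,
                    random_state=seed)
    clf.fit(Xn, y)
    return clf


def train_curation_model(
    X: pd.DataFrame,
    labels,
    seed: int = 0,
    cv_folds: int = 5,
    C_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0),
) -> CurationModel:
    """Train the max-margin classifier; regularization C is chosen by
    internal stratified k-fold cross-validation on balanced accuracy."""
    y = np.asarray(labels, dtype=bool)
    if y.all() or (~y).all():
        raise ValueError("training data must contain both classes")
    feats = list(X.columns)
    center = X.median().to_numpy(dtype=float)
    iqr = (X.quantile(0.75) - X.quantile(0.25)).to_numpy(dtype=float)
    scale = np.where(iqr > 0, iqr, 1.0)
    Xn = (X.to_numpy(dtype=float) - center) / scale

    best_C, best_score = C_grid[0], -np.inf
    n_splits = min(cv_folds, int(y.sum()), int((~y).sum()))
    if n_splits >= 2 and len(C_grid) > 1:
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        for C in C_grid:
            accs = []
            for tr, te in skf.split(Xn, y):
                clf = _fit_linear_svm(Xn[tr], y[tr], C, seed)
                pred = clf.predict(Xn[te])
                sens = (pred & y[te]).sum() / max(y[te].sum(), 1)
                spec = (~pred & ~y[te]).sum() / max((~y[te]).sum(), 1)
                accs.append(0.5 * (sens + spec))
            score = float(np.mean(accs))
            if score > best_score:
                best_C, best_score = C, score

    clf = _fit_linear_svm(Xn, y, best_C, seed)
    return CurationModel(
        feature_names=feats,
        weights=clf.coef_.ravel().astype(float),
        bias=float(clf.intercept_[0]),
        center=center,
        scale=scale,
        metadata={"n": int(len(y)), "seed": int(seed), "cv_folds": int(cv_folds),
                  "C": float(best_C)},
    )


def cross_validate(X: pd.DataFrame, labels, k: int = 10, seed: int = 0) -> float:
    """k-fold cross-validated misclassification rate of the curation model."""
    y = np.asarray(labels, dtype=bool)
    n = len(y)
    if not 2 <= k <= n:
        raise ValueError("k must lie in [2, n]")
    n_min = min(int(y.sum()), int((~y).sum()))
    if k <= n_min:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(n), y)
    else:  # leave-one-out style folds cannot be stratified
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(n))
    errors = 0
    total = 0
    for tr, te in splits:
        if y[tr].all() or (~y[tr]).all():
            continue
        model = train_curation_model(X.iloc[tr], y[tr], seed=seed, C_grid=(1.0,))
        pred = model.predict(X.iloc[te])
        errors += int((pred != y[te]).sum())
        total += len(te)
    if total == 0:
        raise ValueError("no valid folds (a class is too small)")
    return errors / total


def evaluate_classifier(model: CurationModel, X: pd.DataFrame, labels) -> ClassifierReport:
    y = np.asarray(labels, dtype=bool)
    scores = model.decision_function(X)
    pred = scores > 0
    tp = int((pred & y).sum())
    fp = int((pred & ~y).sum())
    tn = int((~pred & ~y).sum())
    fn = int((~pred & y).sum())
    sens = tp / max(tp + fn, 1)
    spec = tn / max(tn + fp, 1)
    return ClassifierReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        auroc=_rank_auroc(scores, y),
        balanced_rate=0.5 * (sens + spec),
        misclassification=(fp + fn) / max(len(y), 1),
    )


def apply_curation(model: CurationModel, table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Retain model-positive cells; return the filtered table and a log."""
    feats = extract_contour_features(table)
    keep = model.predict(feats.values)
    log = {"n_in": int(len(table)), "n_kept": int(keep.sum()),
           "n_rejected": int((~keep).sum())}
    return table.loc[keep], log
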