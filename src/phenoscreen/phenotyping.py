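"""Strain-level feature summarization and WT-referenced scoring.

Each strain's imaged population is reduced to a 26-feature "phenoprint":

* 19 morphological features — mean and CV of length L, width W,
  projected area A, perimeter P, volume V, surface area SA,
  surface-to-volume ratio S/V, aspect ratio Ar = W/L and circularity
  C = 4*pi*A/P^2, plus the CV of the division ratio;
* 5 cell-cycle features — relative timings of nucleoid separation and
  constriction onset, mean nucleoid area (summing nucleoids per cell),
  the cell/nucleoid constriction-degree correlation rhoCD, and the
  nucleoid constriction degree at constriction onset CDN_C0;
* 2 growth features — alpha_max and od_max from the growth curves.

Raw features are corrected for plate-to-plate bias against the parental
strain's medians and then converted into robust z-like scores

    s = 1.35 * (F - median_WT) / iqr_WT,

expressed in WT standard-deviation units (for a normal distribution
iqr = 1.35 * sigma).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cellcycle, geometry
from .growth import GrowthFit

__all__ = [
    "MORPH_FEATURES",
    "CELLCYCLE_FEATURES",
    "GROWTH_FEATURES",
    "ALL_FEATURES",
    "FEATURE_CLASSES",
    "ScoreMatrix",
    "strain_features",
    "features_table",
    "correct_plate_bias",
    "compute_scores",
    "flag_phenotypes",
]

MORPH_FEATURES = [
    "<L>", "CV_L", "<W>", "CV_W", "<A>", "CV_A", "<P>", "CV_P",
    "<V>", "CV_V", "<SA>", "CV_SA", "<SV>", "CV_SV",
    "<Ar>", "CV_Ar", "<C>", "CV_C", "CV_DR",
]
CELLCYCLE_FEATURES = ["rel_T_nuc", "rel_T_const", "<NA>", "rhoCD", "CDN_C0"]
GROWTH_FEATURES = ["alpha_max", "od_max"]
ALL_FEATURES = MORPH_FEATURES + CELLCYCLE_FEATURES + GROWTH_FEATURES
FEATURE_CLASSES = {
    "morphological": MORPH_FEATURES,
    "cellcycle": CELLCYCLE_FEATURES,
    "growth": GROWTH_FEATURES,
}


def _mean_cv(x: np.ndarray) -> tuple[float, float]:
    m = float(np.mean(x))
    if len(x) < 2 or m == 0:
        return m, 0.0
    return m, float(np.std(x, ddof=1) / m)


def strain_features(
    table: pd.DataFrame,
    fit: GrowthFit | None = None,
    constriction_threshold: float = 0.15,
    min_cells: int = 30,
) -> pd.Series:
    """Summarise one strain's cell population into the 26-feature vector.

    Populations smaller than ``min_cells`` are still summarised but the
    result carries ``low_n = True`` in ``Series.attrs`` so downstream
    stages can exclude them.
    """
    if len(table) == 0:
        raise ValueError("empty cell table")
    l = table["length_um"].to_numpy(dtype=float)
    w = table["width_um"].to_numpy(dtype=float)
    a = table["area_um2"].to_numpy(dtype=float)
    p = table["perimeter_um"].to_numpy(dtype=float)
    v = geometry.spherocylinder_volume(l, w)
    sa = geometry.spherocylinder_surface_area(l, w)
    sv = sa / v
    ar = w / l
    circ = geometry.circularity(a, p)

    out: dict[str, float] = {}
    for name, x in (("L", l), ("W", w), ("A", a), ("P", p), ("V", v),
                    ("SA", sa), ("SV", sv), ("Ar", ar), ("C", circ)):
        out[f"<{name}>"], out[f"CV_{name}"] = _mean_cv(x)

    # division-ratio variability over constricting cells; pole identity is
    # unknown, so the set is augmented with complements {r, 1 - r}, which
    # pins the mean at 0.5 and leaves the spread as the signal
    dr = table.loc[table["constriction_degree"] > 0, "division_ratio"].dropna().to_numpy(dtype=float)
    if len(dr) >= 2:
        aug = np.concatenate([dr, 1.0 - dr])
        out["CV_DR"] = float(np.std(aug, ddof=1) / np.mean(aug))
    else:
        out["CV_DR"] = np.nan

    out.update(cellcycle.strain_cellcycle_features(table, constriction_threshold))
    out["alpha_max"] = fit.alpha_max if fit is not None else np.nan
    out["od_max"] = fit.od_max if fit is not None else np.nan

    s = pd.Series(out).reindex(ALL_FEATURES)
    s.attrs["low_n"] = len(table) < min_cells
    s.attrs["n_cells"] = int(len(table))
    return s


def features_table(
    cells_by_strain: dict[str, pd.DataFrame],
    fits: dict[str, GrowthFit] | None = None,
    constriction_threshold: float = 0.15,
    min_cells: int = 30,
) -> pd.DataFrame:
    """Stack per-strain feature vectors into a strains x features matrix.

    A boolean ``low_n`` column records undersampled strains.
    """
    fits = fits or {}
    rows = {}
    low_n = {}
    for sid, tab in cells_by_strain.items():
        vec = strain_features(tab, fits.get(sid), constriction_threshold, min_cells)
        rows[sid] = vec
        low_n[sid] = vec.attrs["low_n"]
    mat = pd.DataFrame(rows).T.reindex(columns=ALL_FEATURES)
    mat.index.name = "strain_id"
    mat["low_n"] = pd.Series(low_n)
    return mat


def correct_plate_bias(
    matrix: pd.DataFrame,
    plate_map: pd.Series | dict,
    parental_medians: pd.Series,
) -> pd.DataFrame:
    """Recenter every plate's per-feature median onto the parental median.

    Strictly positive features are rescaled multiplicatively; features
    that can change sign (e.g. rhoCD) are shifted additively.
    """
    plates = pd.Series(plate_map).reindex(matrix.index)
    out = matrix.copy()
    feat_cols = [c for c in matrix.columns if c in ALL_FEATURES]
    for col in feat_cols:
        if col not in parental_medians or not np.isfinite(parental_medians[col]):
            continue
        multiplicative = bool((matrix[col].dropna() > 0).all())
        for plate, idx in matrix.groupby(plates).groups.items():
            med = matrix.loc[idx, col].median()
            if not np.isfinite(med):
                continue
            if multiplicative and med > 0:
                out.loc[idx, col] = matrix.loc[idx, col] * (parental_medians[col] / med)
            else:
                out.loc[idx, col] = matrix.loc[idx, col] + (parental_medians[col] - med)
    return out


@dataclass
class ScoreMatrix:
    """Strain x feature scores in WT-SD units, with the WT reference used."""

    scores: pd.DataFrame
    wt_ids: list[str]
    median_wt: pd.Series
    iqr_wt: pd.Series


def compute_scores(matrix: pd.DataFrame, wt_ids, min_wt: int = 10) -> ScoreMatrix:
    """Robust score transform s = 1.35 (F - median_WT) / iqr_WT.

    Features whose WT iqr is zero are dropped with a warning, as no
    meaningful deviation scale exists for them.
    """
    wt_ids = [w for w in wt_ids if w in matrix.index]
    if len(wt_ids) < min_wt:
        raise ValueError(f"need at least {min_wt} WT replicate rows, got {len(wt_ids)}")
    feat_cols = [c for c in matrix.columns if c in ALL_FEATURES]
    wt = matrix.loc[wt_ids, feat_cols]
    med = wt.median()
    iqr = wt.quantile(0.75) - wt.quantile(0.25)
    bad = iqr[~(iqr > 0)].index.tolist()
    if bad:
        warnings.warn(f"dropping features with zero WT iqr: {bad}")
    keep = [c for c in feat_cols if c not in bad]
    scores = 1.35 * (matrix[keep] - med[keep]) / iqr[keep]
    return ScoreMatrix(scores=scores, wt_ids=wt_ids, median_wt=med[keep], iqr_wt=iqr[keep])


def flag_phenotypes(
    scores: ScoreMatrix | pd.DataFrame,
    threshold: float = 3.0,
    feature_class: str | list[str] | None = None,
    exclude: set | None = None,
) -> dict:
    """Strains with at least one |s| >= threshold among the given features.

    ``feature_class`` may be one of ``FEATURE_CLASSES`` keys, an explicit
    column list, or None for all features.  Returns per-feature strain
    sets, the union set, and its size.
    """
    df = scores.scores if isinstance(scores, ScoreMatrix) else scores
    if feature_class is None:
        cols = list(df.columns)
    elif isinstance(feature_class, str):
        cols = [c for c in FEATURE_CLASSES[feature_class] if c in df.columns]
    else:
        cols = [c for c in feature_class if c in df.columns]
    sub = df[cols]
    if exclude:
        sub = sub.loc[[i for i in sub.index if i not in exclude]]
    hits = sub.abs() >= threshold
    per_feature = {c: set(sub.index[hits[c].fillna(False)]) for c in cols}
    strains = set(sub.index[hits.any(axis=1)])
    return {"per_feature": per_feature, "strains": strains, "count": len(strains)}
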