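"""Snapshot-based cell-cycle inference for steady-state populations.

In an exponentially growing population at steady state the density of
relative cell ages ``a`` (0 = birth, 1 = division) is proportional to
``2^-a`` (Collins–Richmond / Powell age distribution).  Two consequences
are used throughout:

* the rank fraction ``F`` of a cell in the length distribution maps to a
  relative age via ``age(F) = -ln(1 - F/2) / ln(2)``;
* the population fraction ``p`` of cells *past* a cell-cycle event that
  occurs at relative age ``T`` is ``p = 2^(1-T) - 1``, hence
  ``T = 1 - log2(1 + p)``.

These identities let population snapshots (fractions of cells with two
nucleoids, or with a visible division constriction) be converted into
relative event timings without any time-lapse information.  Only
population-average timings are identifiable this way; single-cell
timing variability is not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, rankdata

__all__ = [
    "AgeAssignment",
    "EventCurve",
    "age_from_rank",
    "relative_event_timing",
    "event_curves",
    "coupling_stats",
    "strain_cellcycle_features",
]

LN2 = np.log(2.0)


@dataclass
class AgeAssignment:
    rank_fraction: np.ndarray  # F in (0, 1]
    age: np.ndarray  # relative age in (0, 1]


@dataclass
class EventCurve:
    """Fraction of cells past an event, per relative-age bin."""

    ages: np.ndarray  # bin centres
    fraction: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "fraction": self.fraction})

    def crossing(self, level: float = 0.5) -> float:
        """First age at which the curve reaches ``level`` (interpolated)."""
        above = self.fraction >= level
        if not above.any():
            return np.nan
        i = int(np.argmax(above))
        if i == 0:
            return float(self.ages[0])
        a0, a1 = self.ages[i - 1], self.ages[i]
        f0, f1 = self.fraction[i - 1], self.fraction[i]
        if f1 == f0:
            return float(a1)
        return float(a0 + (level - f0) * (a1 - a0) / (f1 - f0))


def age_from_rank(lengths) -> AgeAssignment:
    """Relative ages from cell-length ranks; ties share the average rank."""
    lengths = np.asarray(lengths, dtype=float)
    if lengths.ndim != 1 or len(lengths) < 2:
        raise ValueError("need at least 2 cell lengths")
    n = len(lengths)
    frac = rankdata(lengths, method="average") / n
    age = -np.log(1.0 - frac / 2.0) / LN2
    return AgeAssignment(rank_fraction=frac, age=age)


def relative_event_timing(fraction_past: float) -> float:
    """Relative age T of an event from the fraction of cells past it."""
    p = float(fraction_past)
    if not 0.0 <= p <= 1.0:
        raise ValueError("fraction_past must lie in [0, 1]")
    return 1.0 - np.log2(1.0 + p)


def event_curves(
    table: pd.DataFrame,
    constriction_threshold: float = 0.15,
    n_bins: int = 50,
) -> tuple[EventCurve, EventCurve]:
    """Event frequency versus relative age for nucleoid separation and
    cell constriction.

    Ages come from length ranks; cells are binned on a regular age grid
    and the per-bin frequency of the event (two or more nucleoids;
    constriction degree above the threshold) is reported.  Empty bins
    inherit the last observed value so the curve is defined on the full
    grid.
    """
    ages = age_from_rank(table["length_um"].to_numpy()).age
    two_nuc = (table["nucleoid_count"].to_numpy() >= 2).astype(float)
    constricted = (table["constriction_degree"].to_numpy() > constriction_threshold).astype(float)

    edges = np.linspace(0.0, 1.0, n_bins + 1)
    centres = 0.5 * (edges[:-1] + edges[1:])
    idx = np.clip(np.digitize(ages, edges) - 1, 0, n_bins - 1)

    curves = []
    for event in (two_nuc, constricted):
        frac = np.full(n_bins, np.nan)
        for b in range(n_bins):
            sel = idx == b
            if sel.any():
                frac[b] = event[sel].mean()
        # forward-fill empty bins, starting from 0
        last = 0.0
        for b in range(n_bins):
            if np.isnan(frac[b]):
                frac[b] = last
            else:
                last = frac[b]
        curves.append(EventCurve(ages=centres, fraction=frac))
    return curves[0], curves[1]


def coupling_stats(
    table: pd.DataFrame,
    min_cells: int = 10,
    onset_quantile: float = 0.1,
) -> tuple[float, float]:
    """Coupling between cell and nucleoid constriction.

    Returns ``(rho_CD, cdn_c0)`` where ``rho_CD`` is the Pearson
    correlation of cell versus nucleoid constriction degree across
    constricting cells, and ``cdn_c0`` the mean nucleoid constriction
    degree in the onset band (lowest ``onset_quantile`` of strictly
    positive cell constriction degrees).  Missing values are NaN-coded
    when fewer than ``min_cells`` constricting cells are available.
    """
    cd = table["constriction_degree"].to_numpy(dtype=float)
    nd = table["nucleoid_constriction_degree"].to_numpy(dtype=float)
    ok = np.isfinite(cd) & np.isfinite(nd) & (cd > 0)
    if ok.sum() < min_cells:
        return np.nan, np.nan
    cd, nd = cd[ok], nd[ok]
    if np.ptp(cd) == 0 or np.ptp(nd) == 0:
        # a constant vector carries no correlation information
        rho = 1.0 if np.array_equal(cd, nd) else np.nan
    else:
        rho = float(pearsonr(cd, nd).statistic)
    band = cd <= np.quantile(cd, onset_quantile)
    cdn_c0 = float(nd[band].mean()) if band.any() else np.nan
    return rho, cdn_c0


def strain_cellcycle_features(
    table: pd.DataFrame,
    constriction_threshold: float = 0.15,
    use_curve_crossing: bool = False,
) -> dict[str, float]:
    """The five cell-cycle features of one strain's population.

    By default the relative timings come straight from the population
    fractions via :func:`relative_event_timing`; with
    ``use_curve_crossing`` they are read off the 50% crossing of the
    rank-age event curves instead.
    """
    if use_curve_crossing:
        nuc_curve, const_curve = event_curves(table, constriction_threshold)
        t_nuc = nuc_curve.crossing(0.5)
        t_const = const_curve.crossing(0.5)
    else:
        p_nuc = float((table["nucleoid_count"] >= 2).mean())
        p_const = float((table["constriction_degree"] > constriction_threshold).mean())
        t_nuc = relative_event_timing(p_nuc)
        t_const = relative_event_timing(p_const)
    rho_cd, cdn_c0 = coupling_stats(table)
    return {
        "rel_T_nuc": t_nuc,
        "rel_T_const": t_const,
        "<NA>": float(table["nucleoid_area_um2"].mean()),
        "rhoCD": rho_cd,
        "CDN_C0": cdn_c0,
    }
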