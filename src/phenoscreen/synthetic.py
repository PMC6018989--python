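"""Synthetic single-cell screens with known ground truth.

The generator emulates the statistical structure of a genome-wide
imaging screen of exponentially growing *E. coli*:

* steady-state age structure Pr(age) ∝ 2^(-age) on [0, 1];
* exponential single-cell elongation, L(a) = L_birth * 2^a, with
  lognormal multiplicative size noise (WT length CV = 0.11);
* age-thresholded cell-cycle states — two nucleoids past ``t_nuc``, a
  division constriction ramping linearly from ``t_const`` to division;
* Gompertz microplate growth curves with observation noise;
* WT replicates sharing one baseline parameter set (sampling noise
  only) and mutants displaced on selected features by a stated number
  of WT standard deviations, optionally organised into planted
  phenoprint islands.

All lognormals are parameterized by their arithmetic mean and CV.
Everything is driven by ``numpy.random.default_rng`` seeds, so outputs
are byte-identical under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import lognorm, truncnorm

from . import geometry
from .growth import GrowthCurve, gompertz_log

__all__ = [
    "StrainSpec",
    "ScreenTruth",
    "sample_ages",
    "generate_cell_population",
    "generate_growth_curve",
    "generate_screen",
    "make_island_truth",
    "simulate_length_mixture",
    "corrupt_cells",
    "PLANTABLE_FEATURES",
]

LN2 = np.log(2.0)
#: age-induced CV of length when per-age noise is zero:
#: E[2^a] = 2 ln 2 and E[4^a] = 2 under Pr(age) = 2 ln2 * 2^(-a)
AGE_CV2 = 2.0 / (2.0 * LN2) ** 2 - 1.0


@dataclass
class StrainSpec:
    """Generative ground-truth parameters of one strain."""

    strain_id: str
    birth_length: float = 2.0  # µm
    length_cv: float = 0.11
    mean_width: float = 0.9  # µm
    width_cv: float = 0.04
    t_nuc: float = 0.55  # relative age of nucleoid separation
    t_const: float = 0.75  # relative age of constriction onset
    nucleoid_area_ratio: float = 0.55
    growth_params: tuple[float, float, float] = (0.7, 0.01, 120.0)  # (A: OD, mu: 1/min, lambda: min)
    score_offsets: dict[str, float] = field(default_factory=dict)
    island_label: int | None = None
    division_ratio_sd: float = 0.03
    nucleoid_noise_cv: float = 0.05

    def validate(self) -> None:
        for name in ("birth_length", "mean_width", "nucleoid_area_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("length_cv", "width_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0.0 <= self.t_nuc <= 1.0 and 0.0 <= self.t_const <= 1.0):
            raise ValueError("t_nuc and t_const must lie in [0, 1]")
        if not 0.0 < self.nucleoid_area_ratio < 1.0:
            raise ValueError("nucleoid_area_ratio must lie in (0, 1)")
        a, mu, lam = self.growth_params
        if a <= 0 or mu <= 0:
            raise ValueError("growth amplitude and rate must be positive")
        if not all(np.isfinite(v) for v in self.score_offsets.values()):
            raise ValueError("score_offsets must be finite")


@dataclass
class ScreenTruth:
    """Ground truth of a whole synthetic screen."""

    specs: list[StrainSpec]
    wt_ids: set[str]
    plate_map: dict[str, tuple[int, str]]
    seed: int = 0
    n_cells_mean: float = 291.0
    n_cells_sd: float = 116.0

    def validate(self) -> None:
        ids = {s.strain_id for s in self.specs}
        if len(ids) != len(self.specs):
            raise ValueError("duplicate strain ids")
        if not self.wt_ids or not self.wt_ids <= ids:
            raise ValueError("wt_ids must be a non-empty subset of strain ids")
        if len(self.wt_ids) < 2:
            raise ValueError("need at least 2 WT replicates")
        if set(self.plate_map) != ids:
            raise ValueError("every strain needs a plate/well assignment")

    def island_labels(self) -> pd.Series:
        return pd.Series({s.strain_id: s.island_label for s in self.specs})


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _lognormal(rng: np.random.Generator, mean: float, cv: float, n: int) -> np.ndarray:
    """Lognormal draws parameterized by arithmetic mean and CV."""
    if cv == 0:
        return np.full(n, float(mean))
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), n)


def sample_ages(n: int, seed=0) -> np.ndarray:
    """Relative ages from the steady-state density 2 ln2 * 2^(-a) on [0, 1].

    Inverse-CDF sampling: a = -log2(1 - u/2) for u ~ Uniform(0, 1).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    u = _rng(seed).uniform(0.0, 1.0, int(n))
    return -np.log2(1.0 - u / 2.0)


def generate_cell_population(
    spec: StrainSpec,
    n: int,
    seed=0,
    plate: int = 1,
    well: str = "A1",
    image_time_min: float = 0.0,
    od_imaging: float = 0.2,
) -> pd.DataFrame:
    """Sample one strain's imaged population as a cell table."""
    if n < 1:
        raise ValueError("n must be >= 1")
    spec.validate()
    rng = _rng(seed)
    age = sample_ages(n, rng)
    length = spec.birth_length * 2.0**age * _lognormal(rng, 1.0, spec.length_cv, n)
    width = _lognormal(rng, spec.mean_width, spec.width_cv, n)
    area = geometry.projected_area(length, width)
    perimeter = geometry.projected_perimeter(length, width)

    nucleoid_count = np.where(age >= spec.t_nuc, 2, 1)
    if spec.t_const >= 1.0:
        constriction = np.zeros(n)
    else:
        constriction = np.clip((age - spec.t_const) / (1.0 - spec.t_const), 0.0, None)
    constricted = constriction > 0

    division_ratio = np.full(n, np.nan)
    if constricted.any():
        sd = max(spec.division_ratio_sd, 1e-9)
        a_, b_ = (0.0 - 0.5) / sd, (1.0 - 0.5) / sd
        division_ratio[constricted] = truncnorm.rvs(
            a_, b_, loc=0.5, scale=sd, size=int(constricted.sum()), random_state=rng
        )

    if spec.t_nuc >= 1.0:
        nuc_ramp = np.zeros(n)
    else:
        nuc_ramp = np.clip((age - spec.t_nuc) / (1.0 - spec.t_nuc), 0.0, None)
    nucleoid_constriction = np.clip(nuc_ramp + rng.normal(0.0, 0.03, n), 0.0, 1.0)

    nucleoid_area = spec.nucleoid_area_ratio * area * _lognormal(rng, 1.0, spec.nucleoid_noise_cv, n)
    dapi_total = 50.0 * nucleoid_area * _lognormal(rng, 1.0, 0.1, n)

    return pd.DataFrame(
        {
            "strain_id": spec.strain_id,
            "plate": plate,
            "well": well,
            "image_time_min": image_time_min,
            "od_imaging": od_imaging,
            "cell_id": np.arange(n),
            "length_um": length,
            "width_um": width,
            "area_um2": area,
            "perimeter_um": perimeter,
            "constriction_degree": constriction,
            "division_ratio": division_ratio,
            "nucleoid_count": nucleoid_count,
            "nucleoid_area_um2": nucleoid_area,
            "nucleoid_constriction_degree": nucleoid_constriction,
            "dapi_total": dapi_total,
            "phase_mean": rng.normal(0.5, 0.02, n),
            "intracell_width_cv": np.abs(rng.normal(0.03, 0.01, n)),
            "contour_phase_mean": rng.normal(0.3, 0.02, n),
            "true_age": age,
        }
    )


def generate_growth_curve(
    spec: StrainSpec,
    seed=0,
    od0: float = 0.005,
    duration_min: float = 960.0,
    step_min: float = 5.0,
    noise_sd: float = 0.002,
) -> GrowthCurve:
    """Gompertz OD600 curve with additive Gaussian observation noise."""
    rng = _rng(seed)
    a_od, mu, lam = spec.growth_params
    times = np.arange(0.0, duration_min + step_min / 2, step_min)
    amplitude = np.log(a_od / od0)
    od = od0 * np.exp(gompertz_log(times, amplitude, mu, lam))
    od = np.clip(od + rng.normal(0.0, noise_sd, len(times)), 1e-4, None)
    return GrowthCurve(strain_id=spec.strain_id, times=times, od=od)


# features whose WT-SD displacement can be planted through a closed-form
# inverse mapping onto a generative parameter
PLANTABLE_FEATURES = {
    "<L>", "CV_L", "<W>", "CV_W", "CV_DR",
    "rel_T_nuc", "rel_T_const", "<NA>",
    "alpha_max", "od_max",
}


def _apply_offsets(spec: StrainSpec, deltas: dict[str, float], wt_median: pd.Series) -> StrainSpec:
    """Shift a spec's generative parameters so the measured feature moves
    by ``deltas[f]`` (raw feature units) from the WT baseline."""
    unsupported = set(deltas) - PLANTABLE_FEATURES
    if unsupported:
        raise ValueError(f"offsets not plantable for features: {sorted(unsupported)}")
    new = replace(spec, score_offsets=dict(spec.score_offsets))
    for feat, d in deltas.items():
        if feat == "<L>":
            # mean length = birth_length * E[2^a] = birth_length * 2 ln 2
            new = replace(new, birth_length=max(new.birth_length + d / (2.0 * LN2), 0.05))
        elif feat == "CV_L":
            target = max(wt_median["CV_L"] + d, 1e-3)
            cv2 = max((1.0 + target**2) / (1.0 + AGE_CV2) - 1.0, 0.0)
            new = replace(new, length_cv=float(np.sqrt(cv2)))
        elif feat == "<W>":
            new = replace(new, mean_width=max(new.mean_width + d, 0.05))
        elif feat == "CV_W":
            new = replace(new, width_cv=max(wt_median["CV_W"] + d, 1e-4))
        elif feat == "CV_DR":
            # augmented-set CV_DR = sd(r)/0.5 = 2 * division_ratio_sd
            target = max(wt_median["CV_DR"] + d, 1e-4)
            new = replace(new, division_ratio_sd=target / 2.0)
        elif feat == "rel_T_nuc":
            new = replace(new, t_nuc=float(np.clip(new.t_nuc + d, 0.02, 0.98)))
        elif feat == "rel_T_const":
            new = replace(new, t_const=float(np.clip(new.t_const + d, 0.02, 0.98)))
        elif feat == "<NA>":
            target = max(wt_median["<NA>"] + d, 1e-3)
            ratio = new.nucleoid_area_ratio * target / wt_median["<NA>"]
            new = replace(new, nucleoid_area_ratio=float(np.clip(ratio, 0.01, 0.99)))
        elif feat == "alpha_max":
            a_od, mu, lam = new.growth_params
            new = replace(new, growth_params=(a_od, max(mu + d / 60.0, 1e-4), lam))
        elif feat == "od_max":
            a_od, mu, lam = new.growth_params
            new = replace(new, growth_params=(max(a_od + d, 0.01), mu, lam))
    return new


def generate_screen(truth: ScreenTruth):
    """Generate per-strain cell tables and growth curves for a screen.

    WT replicates are sampled from the shared baseline spec.  Mutant
    specs carrying ``score_offsets`` (in WT-SD units) are first
    calibrated against the realized WT replicate spread: the WT
    populations are generated and summarised, the per-feature WT SD is
    taken as iqr/1.35, and each offset is converted into a raw-feature
    displacement that is planted through the generative parameters.

    Returns ``(cells, curves, truth)`` where ``cells`` and ``curves``
    are dicts keyed by strain id; ``truth`` echoes the input with the
    mutant specs replaced by their realized (post-planting) versions.
    """
    from . import phenotyping  # deferred: phenotyping does not import synthetic
    from .growth import fit_gompertz

    truth.validate()
    rng = _rng(truth.seed)
    ids = [s.strain_id for s in truth.specs]
    n_cells = {
        sid: int(max(np.round(rng.normal(truth.n_cells_mean, truth.n_cells_sd)), 50))
        for sid in ids
    }
    pop_seeds = {sid: int(rng.integers(0, 2**31 - 1)) for sid in ids}
    curve_seeds = {sid: int(rng.integers(0, 2**31 - 1)) for sid in ids}

    specs = {s.strain_id: s for s in truth.specs}
    cells: dict[str, pd.DataFrame] = {}
    curves: dict[str, GrowthCurve] = {}

    def _make(sid: str, spec: StrainSpec) -> None:
        plate, well = truth.plate_map[sid]
        cells[sid] = generate_cell_population(
            spec, n_cells[sid], pop_seeds[sid], plate=plate, well=well
        )
        curves[sid] = generate_growth_curve(spec, curve_seeds[sid])

    for sid in truth.wt_ids:
        _make(sid, specs[sid])

    mutant_ids = [sid for sid in ids if sid not in truth.wt_ids]
    needs_cal = any(specs[sid].score_offsets for sid in mutant_ids)
    if needs_cal:
        wt_fits = {sid: fit_gompertz(curves[sid]) for sid in truth.wt_ids}
        wt_feat = phenotyping.features_table(
            {sid: cells[sid] for sid in truth.wt_ids}, wt_fits
        ).drop(columns="low_n")
        wt_median = wt_feat.median()
        wt_sd = (wt_feat.quantile(0.75) - wt_feat.quantile(0.25)) / 1.35
        wt_sd = wt_sd.where(wt_sd > 0, wt_feat.std().fillna(0.0) + 1e-9)

    realized: list[StrainSpec] = [specs[sid] for sid in ids if sid in truth.wt_ids]
    for sid in mutant_ids:
        spec = specs[sid]
        if spec.score_offsets:
            deltas = {f: off * float(wt_sd[f]) for f, off in spec.score_offsets.items()}
            spec = _apply_offsets(spec, deltas, wt_median)
        _make(sid, spec)
        realized.append(spec)

    out_truth = replace(truth, specs=sorted(realized, key=lambda s: ids.index(s.strain_id)))
    return cells, curves, out_truth


def make_island_truth(
    n_wt: int = 40,
    islands: list[dict] | None = None,
    n_background: int = 0,
    seed: int = 0,
    n_cells_mean: float = 291.0,
    n_cells_sd: float = 116.0,
    baseline: StrainSpec | None = None,
) -> ScreenTruth:
    """Convenience constructor: WT replicates plus planted islands.

    ``islands`` is a list of dicts ``{"n": int, "offsets": {feature:
    WT-SD units}}``; island labels are assigned 1..k in order (WT's
    implicit label is 0).  ``n_background`` adds offset-free mutants.
    """
    base = baseline or StrainSpec(strain_id="WT")
    specs: list[StrainSpec] = []
    wt_ids = set()
    for i in range(n_wt):
        sid = f"WT_{i:03d}"
        specs.append(replace(base, strain_id=sid, island_label=0))
        wt_ids.add(sid)
    for k, isl in enumerate(islands or [], start=1):
        for j in range(isl["n"]):
            specs.append(
                replace(
                    base,
                    strain_id=f"isl{k}_{j:03d}",
                    score_offsets=dict(isl["offsets"]),
                    island_label=k,
                )
            )
    for j in range(n_background):
        specs.append(replace(base, strain_id=f"bg_{j:03d}", island_label=None))

    plate_map = {}
    for i, s in enumerate(specs):
        plate, pos = divmod(i, 96)
        plate_map[s.strain_id] = (plate + 1, f"{chr(ord('A') + pos // 12)}{pos % 12 + 1}")
    return ScreenTruth(
        specs=specs, wt_ids=wt_ids, plate_map=plate_map, seed=seed,
        n_cells_mean=n_cells_mean, n_cells_sd=n_cells_sd,
    )


#: canonical planted-archipelago conditions used for recovery experiments:
#: three islands displaced on disjoint feature pairs by 7 WT-SD, against a
#: backdrop of WT replicates (internal score spread ~1 SD per feature)
PLANTED_ISLANDS = [
    {"n": 12, "offsets": {"<L>": 7.0, "CV_L": 7.0}},
    {"n": 12, "offsets": {"<W>": -7.0, "CV_DR": 7.0}},
    {"n": 12, "offsets": {"rel_T_nuc": -7.0, "<NA>": 7.0}},
]


def planted_archipelago_truth(
    seed: int = 0,
    n_wt: int = 24,
    n_cells_mean: float = 200.0,
    n_cells_sd: float = 40.0,
) -> ScreenTruth:
    """The standard planted-island screen: WT replicates plus three
    mutant islands displaced on disjoint feature pairs."""
    return make_island_truth(
        n_wt=n_wt, islands=PLANTED_ISLANDS, seed=seed,
        n_cells_mean=n_cells_mean, n_cells_sd=n_cells_sd,
    )


@dataclass
class LengthMixture:
    lengths: np.ndarray
    population_pdf: np.ndarray
    constricted_pdf: np.ndarray
    cv_population: float
    cv_constricted: float


def simulate_length_mixture(
    stage_cv: float,
    base_cv: float = 0.11,
    n_ages: int = 100,
    constricted_age_min: float = 0.8,
    n_grid: int = 2048,
) -> LengthMixture:
    """Population length distribution as an age-weighted lognormal mixture.

    At each of ``n_ages`` equidistant ages the length distribution is
    lognormal with mean 2^age (unit birth length) and CV ``base_cv``
    (``stage_cv`` for ages above ``constricted_age_min``, the
    constricted stage).  Distributions are summed with steady-state age
    weights ∝ 2^(-age); the constricted-stage distribution sums only
    the late ages.  CVs are computed from the exact mixture moments.
    """
    if stage_cv <= 0 or base_cv <= 0:
        raise ValueError("CVs must be strictly positive")
    if n_ages < 2:
        raise ValueError("n_ages must be >= 2")
    ages = np.linspace(0.0, 1.0, n_ages)
    w = 2.0 ** (-ages)
    w = w / w.sum()
    means = 2.0**ages
    cvs = np.where(ages > constricted_age_min, stage_cv, base_cv)

    grid = np.linspace(1e-4, float(means.max()) * (1.0 + 6.0 * max(stage_cv, base_cv)), n_grid)
    pdfs = np.empty((n_ages, n_grid))
    for i in range(n_ages):
        sigma2 = np.log1p(cvs[i] ** 2)
        mu = np.log(means[i]) - sigma2 / 2.0
        pdfs[i] = lognorm.pdf(grid, np.sqrt(sigma2), scale=np.exp(mu))

    pop_pdf = w @ pdfs
    pop_pdf = pop_pdf / np.trapezoid(pop_pdf, grid)

    late = ages > constricted_age_min
    wl = w[late] / w[late].sum()
    con_pdf = wl @ pdfs[late]
    con_pdf = con_pdf / np.trapezoid(con_pdf, grid)

    def _cv(weights, sel):
        ww = weights[sel] / weights[sel].sum()
        m1 = float(ww @ means[sel])
        m2 = float(ww @ (means[sel] ** 2 * (1.0 + cvs[sel] ** 2)))
        return float(np.sqrt(max(m2 - m1**2, 0.0)) / m1)

    return LengthMixture(
        lengths=grid,
        population_pdf=pop_pdf,
        constricted_pdf=con_pdf,
        cv_population=_cv(w, np.ones(n_ages, dtype=bool)),
        cv_constricted=_cv(w, late),
    )


def corrupt_cells(table: pd.DataFrame, fraction: float, seed=0) -> pd.DataFrame:
    """Perturb a random subset of cells into implausible regimes.

    Adds a boolean ``label_good`` column (False = corrupted).  Used to
    train and benchmark the contour-curation classifier.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    rng = _rng(seed)
    out = table.copy().reset_index(drop=True)
    n = len(out)
    bad = rng.uniform(size=n) < fraction
    idx = np.flatnonzero(bad)
    modes = rng.integers(0, 4, len(idx))
    for i, mode in zip(idx, modes):
        if mode == 0:  # wider than long — impossible for a rod
            out.loc[i, "width_um"] = out.loc[i, "length_um"] * rng.uniform(1.05, 1.6)
            out.loc[i, "intracell_width_cv"] = abs(rng.normal(0.3, 0.1))
        elif mode == 1:  # collapsed contour: vanishing area analog, clipped
            out.loc[i, "area_um2"] = 1e-3
            out.loc[i, "perimeter_um"] = out.loc[i, "perimeter_um"] * rng.uniform(2.0, 4.0)
        elif mode == 2:  # intensity outlier (debris / out-of-focus)
            out.loc[i, "dapi_total"] = out.loc[i, "dapi_total"] * rng.uniform(10.0, 50.0)
            out.loc[i, "phase_mean"] = out.loc[i, "phase_mean"] * rng.uniform(3.0, 6.0)
        else:  # merged cells: doubled length, saturated constriction
            out.loc[i, "length_um"] = out.loc[i, "length_um"] * rng.uniform(2.5, 4.0)
            out.loc[i, "constriction_degree"] = 1.0
            out.loc[i, "division_ratio"] = rng.uniform(0.01, 0.08)
            out.loc[i, "nucleoid_count"] = rng.integers(3, 6)
    out["label_good"] = ~bad
    return out
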