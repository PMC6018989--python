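"""Correlation confidence intervals, KDE probability contours and local
density utilities.

* Pearson CIs use the Fisher z-transform: z = atanh(rho) is
  approximately normal with standard error 1/sqrt(n - 3), so the CI is
  tanh(z ± z_crit/sqrt(n - 3)).
* Kendall tau has no comparable transform; its CI is a percentile
  bootstrap over resampled variable pairs (default 5,000 resamples).
* Probability contours (e.g. the envelope containing 95% of a
  reference population) come from a fast binned 2D KDE on a 128x128
  lattice: the density threshold for level p is chosen so the enclosed
  KDE mass equals p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist
from scipy.stats import kendalltau, norm
from skimage import measure

__all__ = [
    "CorrelationCI",
    "fisher_pearson_ci",
    "kendall_bootstrap_ci",
    "KDE2D",
    "kde_contours",
    "local_density",
]


@dataclass
class CorrelationCI:
    estimate: float
    lower: float
    upper: float
    n: int
    method: str
    level: float


def fisher_pearson_ci(rho: float, n: int, level: float = 0.95) -> CorrelationCI:
    """Fisher z confidence interval for a Pearson correlation."""
    rho = float(rho)
    n = int(n)
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    if n < 4:
        raise ValueError("n must be >= 4")
    if abs(rho) == 1.0:
        warnings.warn("|rho| = 1 gives a degenerate confidence interval")
        return CorrelationCI(rho, rho, rho, n, "fisher-pearson", level)
    z = np.arctanh(rho)
    half = norm.ppf(0.5 + level / 2.0) / np.sqrt(n - 3)
    return CorrelationCI(
        estimate=rho,
        lower=float(np.tanh(z - half)),
        upper=float(np.tanh(z + half)),
        n=n,
        method="fisher-pearson",
        level=level,
    )


def kendall_bootstrap_ci(
    x,
    y,
    n_boot: int = 5000,
    level: float = 0.95,
    seed: int = 0,
) -> CorrelationCI:
    """Percentile-bootstrap CI for Kendall's tau."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 4:
        raise ValueError("x and y must be equal-length with n >= 4")
    tau = float(kendalltau(x, y).statistic)
    rng = np.random.default_rng(seed)
    taus = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        t = kendalltau(x[idx], y[idx]).statistic
        taus[b] = t
    taus = taus[np.isfinite(taus)]
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(taus, [100 * alpha, 100 * (1 - alpha)])
    return CorrelationCI(tau, float(lo), float(hi), n, "bootstrap-kendall", level)


@dataclass
class KDE2D:
    """Binned Gaussian KDE on a regular lattice with mass thresholds."""

    x_grid: np.ndarray
    y_grid: np.ndarray
    density: np.ndarray  # shape (len(y_grid), len(x_grid)), integrates to 1
    thresholds: dict[float, float]  # probability level -> density threshold

    def density_at(self, points: np.ndarray) -> np.ndarray:
        interp = RegularGridInterpolator(
            (self.y_grid, self.x_grid), self.density, bounds_error=False, fill_value=0.0
        )
        pts = np.asarray(points, dtype=float)
        return interp(np.column_stack([pts[:, 1], pts[:, 0]]))

    def coverage(self, points: np.ndarray, level: float) -> float:
        """Fraction of points falling inside the given probability contour."""
        d = self.density_at(points)
        return float(np.mean(d >= self.thresholds[level]))


def kde_contours(
    points: np.ndarray,
    levels: tuple[float, ...] = (0.5, 0.75, 0.95),
    grid: int = 128,
    bandwidth_factor: float = 1.0,
) -> tuple[dict[float, list[np.ndarray]], KDE2D]:
    """Probability contours of a 2D point cloud.

    The density is a histogram on a ``grid`` x ``grid`` lattice (padded
    so the kernel mass stays inside) smoothed with a Gaussian kernel of
    Scott's-rule bandwidth; the contour for probability ``p`` is drawn
    at the density value enclosing mass ``p``.  Returns a dict mapping
    each level to a list of polygon vertex arrays (in data
    coordinates), plus the underlying KDE.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    n = len(pts)
    if n < 10:
        raise ValueError("need at least 10 points for a 2D KDE")

    stds = pts.std(axis=0, ddof=1)
    stds = np.where(stds > 0, stds, 1e-9)
    bw = bandwidth_factor * stds * n ** (-1.0 / 6.0)  # Scott's rule per axis

    lo = pts.min(axis=0) - 4.0 * bw
    hi = pts.max(axis=0) + 4.0 * bw
    x_grid = np.linspace(lo[0], hi[0], grid)
    y_grid = np.linspace(lo[1], hi[1], grid)
    dx = x_grid[1] - x_grid[0]
    dy = y_grid[1] - y_grid[0]

    hist, _, _ = np.histogram2d(pts[:, 1], pts[:, 0], bins=[grid, grid],
                                range=[[lo[1], hi[1]], [lo[0], hi[0]]])
    dens = gaussian_filter(hist, sigma=[bw[1] / dy, bw[0] / dx], mode="constant")
    dens /= dens.sum() * dx * dy

    flat = np.sort(dens.ravel())[::-1]
    cum = np.cumsum(flat) * dx * dy
    thresholds = {}
    for p in levels:
        i = int(np.searchsorted(cum, p))
        thresholds[p] = float(flat[min(i, len(flat) - 1)])

    kde = KDE2D(x_grid=x_grid, y_grid=y_grid, density=dens, thresholds=thresholds)

    polygons: dict[float, list[np.ndarray]] = {}
    for p in levels:
        polys = []
        for contour in measure.find_contours(dens, thresholds[p]):
            xy = np.column_stack(
                [np.interp(contour[:, 1], np.arange(grid), x_grid),
                 np.interp(contour[:, 0], np.arange(grid), y_grid)]
            )
            polys.append(xy)
        polygons[p] = polys
    return polygons, kde


def write_contours_csv(polygons: dict[float, list[np.ndarray]], path) -> None:
    """Export contour polygons as a long CSV (level, polygon, x, y)."""
    import pandas as pd

    rows = []
    for level, polys in polygons.items():
        for k, poly in enumerate(polys):
            rows.append(
                pd.DataFrame(
                    {"level": level, "polygon": k, "x": poly[:, 0], "y": poly[:, 1]}
                )
            )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def local_density(
    points: np.ndarray,
    radius_percentile: float = 0.03,
    radius: float | None = None,
) -> np.ndarray:
    """Neighbor counts (self included) within a fixed radius.

    The default radius is the 0.03 percentile (quantile 0.0003) of the
    pairwise-distance distribution — the convention used for density
    shading of scatter plots; pass ``radius`` to override.
    """
    pts = np.asarray(points, dtype=float)
    if radius is None:
        radius = float(np.percentile(pdist(pts), radius_percentile))
    tree = cKDTree(pts)
    return np.array([len(nb) for nb in tree.query_ball_point(pts, r=radius)])
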