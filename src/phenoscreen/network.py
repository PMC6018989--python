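"""Feature-level relevance network: collinearity screen, mutual
information and ARACNE pruning with bootstrap edge support.

Collinear features are first removed by Belsley's diagnostic (condition
indices above 30 with high variance-decomposition proportions).  Over
the retained features a pairwise mutual-information matrix is estimated
(rank transform, equal-frequency binning with B = ceil(n^(1/3)) bins,
Miller–Madow bias correction) and pruned with ARACNE's data-processing
inequality: in every feature triangle the weakest edge is removed, so
indirect associations explained by a stronger two-step path disappear.
Edge robustness is the fraction of strain-resampled bootstrap networks
(default 200) containing the edge; edges above 70% support are kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BelsleyResult",
    "PhenoNetwork",
    "belsley_screen",
    "mutual_information",
    "mi_matrix",
    "aracne",
    "bootstrap_network",
]


@dataclass
class BelsleyResult:
    retained: list[str]
    excluded: list[str]
    condition_indices: np.ndarray
    variance_decomposition: pd.DataFrame  # indices x features proportions


def belsley_screen(matrix: pd.DataFrame, threshold: float = 30.0) -> BelsleyResult:
    """Flag features implicated in near-degenerate directions.

    Columns are scaled to unit norm (no centering, per Belsley); the
    condition indices are sigma_max/sigma_i of the SVD.  A feature is
    implicated when its variance-decomposition proportion exceeds 0.5
    on any index above ``threshold``.
    """
    X = matrix.to_numpy(dtype=float)
    norms = np.linalg.norm(X, axis=0)
    norms = np.where(norms > 0, norms, 1.0)
    Xs = X / norms
    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    s = np.where(s > 0, s, 1e-300)
    cond = s.max() / s
    # variance-decomposition proportions: phi_ki = V[i,k]^2 / s_k^2
    phi = (Vt.T**2) / (s**2)[None, :]  # features x indices
    pi = phi / phi.sum(axis=1, keepdims=True)
    vdp = pd.DataFrame(pi.T, columns=matrix.columns)  # indices x features

    bad_idx = cond > threshold
    implicated = (vdp.loc[bad_idx] > 0.5).any(axis=0) if bad_idx.any() else pd.Series(
        False, index=matrix.columns
    )
    retained = [c for c in matrix.columns if not implicated[c]]
    excluded = [c for c in matrix.columns if implicated[c]]
    return BelsleyResult(
        retained=retained, excluded=excluded,
        condition_indices=cond, variance_decomposition=vdp,
    )


def _equal_frequency_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Rank-based equal-frequency bin assignment (deterministic on ties)."""
    n = len(x)
    order = np.argsort(x, kind="stable")
    bins = np.empty(n, dtype=np.int64)
    bins[order] = (np.arange(n) * n_bins) // n
    return bins


def mutual_information(x, y, n_bins: int | None = None) -> float:
    """Binned MI in nats with Miller–Madow bias correction.

    Both variables are rank-transformed and discretized into
    B = ceil(n^(1/3)) equal-frequency bins (so the estimate depends on
    the copula only, making it invariant to monotone rescaling).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 8:
        raise ValueError("x and y must be equal-length with n >= 8")
    B = int(n_bins) if n_bins else int(np.ceil(n ** (1.0 / 3.0)))
    bx = _equal_frequency_bins(x, B)
    by = _equal_frequency_bins(y, B)
    joint = np.zeros((B, B), dtype=np.int64)
    np.add.at(joint, (bx, by), 1)
    pj = joint[joint > 0] / n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    px = px[px > 0] / n
    py = py[py > 0] / n
    h_x = -np.sum(px * np.log(px))
    h_y = -np.sum(py * np.log(py))
    h_xy = -np.sum(pj * np.log(pj))
    mi = h_x + h_y - h_xy
    # Miller–Madow: H_mm = H + (m - 1)/(2n) per entropy term
    mi += (len(px) + len(py) - len(pj) - 1) / (2.0 * n)
    return float(max(mi, 0.0))


def mi_matrix(matrix: pd.DataFrame, n_bins: int | None = None) -> pd.DataFrame:
    cols = list(matrix.columns)
    X = matrix.to_numpy(dtype=float)
    p = len(cols)
    out = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            out[i, j] = out[j, i] = mutual_information(X[:, i], X[:, j], n_bins)
    return pd.DataFrame(out, index=cols, columns=cols)


def aracne(mi: pd.DataFrame | np.ndarray, dpi_tolerance: float = 0.0,
           mi_threshold: float = 0.0) -> np.ndarray:
    """Data-processing-inequality pruning of an MI matrix.

    Edge (i, j) is removed whenever some third feature k satisfies
    MI_ij < min(MI_ik, MI_jk) * (1 - dpi_tolerance), strictly — ties
    keep the edge.  All removals are judged against the original MI
    matrix, so the result is order-independent and idempotent.
    """
    M = mi.to_numpy(dtype=float) if isinstance(mi, pd.DataFrame) else np.asarray(mi, dtype=float)
    p = M.shape[0]
    adj = M > mi_threshold
    np.fill_diagonal(adj, False)
    keep = adj.copy()
    for i in range(p):
        for j in range(i + 1, p):
            if not adj[i, j]:
                continue
            for k in range(p):
                if k == i or k == j or not (adj[i, k] and adj[j, k]):
                    continue
                if M[i, j] < min(M[i, k], M[j, k]) * (1.0 - dpi_tolerance):
                    keep[i, j] = keep[j, i] = False
                    break
    return keep


def null_mi_threshold(
    matrix: pd.DataFrame,
    n_perm: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    n_bins: int | None = None,
) -> float:
    """MI significance floor from a row-permutation null.

    Random column pairs are decoupled by permuting one member; the
    minimum MI for an edge to enter the network is the null quantile at
    level 1 - alpha/n_pairs, i.e. Bonferroni-controlled across all
    candidate edges so that a fully independent feature set yields an
    empty network with probability about 1 - alpha.
    """
    rng = np.random.default_rng(seed)
    X = matrix.to_numpy(dtype=float)
    n, p = X.shape
    if p < 2:
        return 0.0
    vals = []
    for _ in range(n_perm):
        i, j = rng.choice(p, 2, replace=False)
        vals.append(mutual_information(X[:, i], X[rng.permutation(n), j], n_bins))
    n_pairs = p * (p - 1) // 2
    q = 1.0 - alpha / n_pairs
    return float(np.quantile(vals, min(q, 1.0)))


@dataclass
class PhenoNetwork:
    """Undirected feature network with bootstrap edge support."""

    nodes: list[str]
    edges: pd.DataFrame  # feature_a, feature_b, mi_nats, support
    support_matrix: pd.DataFrame
    n_boot: int
    support_threshold: float

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.feature_a, row.feature_b, mi=row.mi_nats, support=row.support)
        return g

    def write_edges_csv(self, path) -> None:
        self.edges.to_csv(path, index=False)

    def write_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)


def bootstrap_network(
    matrix: pd.DataFrame,
    n_boot: int = 200,
    support_threshold: float = 0.7,
    seed: int = 0,
    dpi_tolerance: float = 0.0,
    n_bins: int | None = None,
    mi_threshold: float | None = None,
) -> PhenoNetwork:
    """ARACNE network with strain-resampling bootstrap edge support.

    Strains (rows) are resampled with replacement ``n_boot`` times; the
    full MI + DPI pipeline runs per replicate and an edge's support is
    the fraction of replicate networks containing it.  Edges with
    support strictly above ``support_threshold`` are retained; their MI
    values come from the full (un-resampled) data.

    ``mi_threshold`` is the significance floor below which candidate
    edges are discarded before DPI pruning; by default it is estimated
    once from a row-permutation null (:func:`null_mi_threshold`), which
    keeps chance-level associations — reproducible across bootstrap
    replicates because they share the same rows — out of the network.
    """
    rng = np.random.default_rng(seed)
    cols = list(matrix.columns)
    n = len(matrix)
    p = len(cols)
    if mi_threshold is None:
        mi_threshold = null_mi_threshold(matrix, seed=seed, n_bins=n_bins)
    counts = np.zeros((p, p))
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        boot = matrix.iloc[idx]
        counts += aracne(mi_matrix(boot, n_bins), dpi_tolerance, mi_threshold)
    support = counts / n_boot
    full_mi = mi_matrix(matrix, n_bins)

    rows = []
    for i in range(p):
        for j in range(i + 1, p):
            if support[i, j] > support_threshold:
                rows.append(
                    {
                        "feature_a": cols[i],
                        "feature_b": cols[j],
                        "mi_nats": float(full_mi.iloc[i, j]),
                        "support": float(support[i, j]),
                    }
                )
    edges = pd.DataFrame(rows, columns=["feature_a", "feature_b", "mi_nats", "support"])
    return PhenoNetwork(
        nodes=cols, edges=edges,
        support_matrix=pd.DataFrame(support, index=cols, columns=cols),
        n_boot=n_boot, support_threshold=support_threshold,
    )
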