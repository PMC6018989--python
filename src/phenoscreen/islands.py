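"""Phenotypic islands: consensus embedding plus density clustering.

Strains with similar phenoprints are grouped by repeating a stochastic
2D embedding (t-SNE) many times, clustering every map with DBSCAN, and
keeping only groups of strains that co-cluster in more than a stated
fraction (default 90%) of the maps.  The surviving groups — "islands" —
are the connected components of the thresholded co-clustering graph;
strains without a stable affiliation remain unassigned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import DBSCAN
from sklearn.manifold import TSNE

__all__ = [
    "EmbeddingSet",
    "IslandPartition",
    "embed_consensus",
    "dbscan_cluster",
    "consensus_islands",
    "tune_dbscan",
    "island_stability",
    "island_phenoprints",
]


@dataclass
class EmbeddingSet:
    strain_ids: list[str]
    maps: list[np.ndarray]  # each (n, 2)
    seeds: list[int]
    perplexity: float


@dataclass
class IslandPartition:
    strain_ids: list[str]
    labels: np.ndarray  # island id >= 0, or -1 for unassigned
    co_matrix: np.ndarray  # pairwise co-clustering frequencies in [0, 1]
    eps: float
    min_points: int
    co_threshold: float

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.strain_ids, name="island_id")

    @property
    def n_islands(self) -> int:
        return int(len(set(self.labels[self.labels >= 0])))


def _scores_frame(scores) -> pd.DataFrame:
    from .phenotyping import ScoreMatrix

    return scores.scores if isinstance(scores, ScoreMatrix) else scores


def embed_consensus(
    scores,
    n_maps: int = 100,
    perplexity: float = 30.0,
    seed: int = 0,
) -> EmbeddingSet:
    """Repeat the t-SNE projection ``n_maps`` times with per-map seeds
    ``seed + i`` derived from the master seed."""
    df = _scores_frame(scores)
    if len(df) < 10:
        raise ValueError("need at least 10 strains to embed")
    if df.isna().any().any():
        raise ValueError("scores contain missing values; impute upstream")
    X = df.to_numpy(dtype=float)
    perp = min(perplexity, (len(df) - 1) / 3.0)
    maps, seeds = [], []
    for i in range(n_maps):
        s = seed + i
        tsne = TSNE(
            n_components=2, perplexity=perp, init="random", random_state=s,
            max_iter=500,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            maps.append(tsne.fit_transform(X))
        seeds.append(s)
    return EmbeddingSet(strain_ids=list(df.index), maps=maps, seeds=seeds, perplexity=perp)


def dbscan_cluster(points: np.ndarray, eps: float, min_points: int = 3) -> np.ndarray:
    """Canonical DBSCAN labels (noise = -1).

    A core point has at least ``min_points`` points (itself included)
    within ``eps``; clusters are the density-reachable sets.
    """
    points = np.asarray(points, dtype=float)
    return DBSCAN(eps=eps, min_samples=min_points).fit(points).labels_


def _co_matrix(label_sets: list[np.ndarray]) -> np.ndarray:
    n = len(label_sets[0])
    co = np.zeros((n, n))
    for lab in label_sets:
        same = (lab[:, None] == lab[None, :]) & (lab[:, None] >= 0)
        co += same
    co /= len(label_sets)
    np.fill_diagonal(co, 1.0)
    return co


def consensus_islands(
    embeds: EmbeddingSet,
    eps: float,
    min_points: int = 3,
    co_threshold: float = 0.9,
) -> IslandPartition:
    """Islands = connected components (size >= min_points) of the graph
    joining strain pairs that co-cluster in > co_threshold of the maps."""
    label_sets = [dbscan_cluster(m, eps, min_points) for m in embeds.maps]
    co = _co_matrix(label_sets)
    adj = csr_matrix(co > co_threshold)
    n_comp, comp = connected_components(adj, directed=False)
    labels = np.full(len(comp), -1)
    next_id = 0
    # stable island ids: decreasing size, then first-member order
    comp_sizes = [(np.sum(comp == c), -np.argmax(comp == c), c) for c in range(n_comp)]
    for size, _, c in sorted(comp_sizes, reverse=True):
        if size >= min_points:
            labels[comp == c] = next_id
            next_id += 1
    return IslandPartition(
        strain_ids=embeds.strain_ids, labels=labels, co_matrix=co,
        eps=eps, min_points=min_points, co_threshold=co_threshold,
    )


def tune_dbscan(
    embeds: EmbeddingSet,
    wt_ids,
    eps_grid,
    min_points: int = 3,
    wt_bulk: float = 0.9,
    co_threshold: float = 0.9,
) -> tuple[float, int]:
    """Pick eps maximizing the island count subject to the bulk of WT
    replicates staying in a single island; ties favour the smaller eps."""
    wt_idx = [i for i, s in enumerate(embeds.strain_ids) if s in set(wt_ids)]
    if not wt_idx:
        raise ValueError("no WT strains present in the embedding")
    best = None
    for eps in sorted(eps_grid):
        part = consensus_islands(embeds, eps, min_points, co_threshold)
        wt_labels = part.labels[wt_idx]
        assigned = wt_labels[wt_labels >= 0]
        ok = (
            len(assigned) > 0
            and np.max(np.bincount(assigned)) >= wt_bulk * len(wt_idx)
        )
        if ok and (best is None or part.n_islands > best[1]):
            best = (eps, part.n_islands)
    if best is None:
        raise ValueError("no eps on the grid keeps the WT bulk in one island")
    return best[0], min_points


def island_stability(
    scores,
    eps: float,
    min_points: int = 3,
    n_partitions: int = 50,
    maps_per_partition: int = 10,
    holdout_fraction: float = 0.02,
    reference: IslandPartition | None = None,
    perplexity: float = 30.0,
    seed: int = 0,
    reference_maps: int = 20,
) -> pd.DataFrame:
    """Subsampling stability of the islands (Jaccard-like indexes).

    Disjoint holdouts of ``holdout_fraction`` of the strains are removed
    in turn; the remainder is re-embedded ``maps_per_partition`` times
    and re-clustered per map.  For each reference island the index is
    the largest fraction of its surviving members that land in one
    cluster, averaged over the maps of a partition.  Returns a
    partitions x islands table of indexes.
    """
    df = _scores_frame(scores)
    if reference is None:
        ref_embeds = embed_consensus(df, n_maps=reference_maps, perplexity=perplexity, seed=seed)
        reference = consensus_islands(ref_embeds, eps, min_points)
    ref = reference.as_series()
    island_ids = sorted(set(ref[ref >= 0]))

    rng = np.random.default_rng(seed)
    n = len(df)
    order = rng.permutation(n)
    hold_size = max(int(round(holdout_fraction * n)), 1)
    rows = []
    for p in range(n_partitions):
        lo = (p * hold_size) % n
        held = set(order[lo : lo + hold_size])
        keep = [i for i in range(n) if i not in held]
        sub = df.iloc[keep]
        embeds = embed_consensus(
            sub, n_maps=maps_per_partition, perplexity=perplexity,
            seed=seed + 1000 * (p + 1),
        )
        per_island = {k: [] for k in island_ids}
        for m in embeds.maps:
            lab = dbscan_cluster(m, eps, min_points)
            lab = pd.Series(lab, index=sub.index)
            for k in island_ids:
                members = [s for s in ref.index[ref == k] if s in lab.index]
                if not members:
                    continue
                mlab = lab[members]
                clustered = mlab[mlab >= 0]
                frac = (
                    clustered.value_counts().iloc[0] / len(members)
                    if len(clustered)
                    else 0.0
                )
                per_island[k].append(frac)
        rows.append({k: float(np.mean(v)) if v else np.nan for k, v in per_island.items()})
    return pd.DataFrame(rows, columns=island_ids)


def island_phenoprints(partition: IslandPartition, scores) -> pd.DataFrame:
    """Island x feature table of mean scores (the island phenoprints)."""
    df = _scores_frame(scores)
    lab = partition.as_series().reindex(df.index)
    assigned = lab[lab >= 0]
    return df.loc[assigned.index].groupby(assigned).mean()
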