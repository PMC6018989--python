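"""Consensus embedding + DBSCAN islands, with a brute-force oracle."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from phenoscreen import islands as isl


def dbscan_oracle(points, eps, min_points):
    """O(n^2) density-reachability DBSCAN.

    Returns (core_labels, noise_mask, border_choices): core points get a
    cluster id via connected components over eps-close core pairs;
    border points may legally join any neighboring core's cluster; the
    rest is noise.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    neigh = d <= eps
    core = neigh.sum(axis=1) >= min_points  # includes self
    # connected components over core-core eps edges
    comp = -np.ones(n, dtype=int)
    cid = 0
    for i in np.where(core)[0]:
        if comp[i] >= 0:
            continue
        stack = [i]
        comp[i] = cid
        while stack:
            j = stack.pop()
            for k in np.where(neigh[j] & core)[0]:
                if comp[k] < 0:
                    comp[k] = cid
                    stack.append(k)
        cid += 1
    border_choices = {}
    noise = np.zeros(n, dtype=bool)
    for i in np.where(~core)[0]:
        owners = set(comp[j] for j in np.where(neigh[i] & core)[0])
        if owners:
            border_choices[i] = owners
        else:
            noise[i] = True
    return comp, core, noise, border_choices


def assert_matches_oracle(points, eps, min_points, labels):
    comp, core, noise, border = dbscan_oracle(points, eps, min_points)
    # noise sets agree exactly
    np.testing.assert_array_equal(labels == -1, noise)
    # core partition agrees up to label permutation
    assert adjusted_rand_score(comp[core], labels[core]) == pytest.approx(1.0)
    # border points joined one of their legal owner clusters
    core_map = {}
    for j in np.where(core)[0]:
        core_map.setdefault(comp[j], labels[j])
    for i, owners in border.items():
        assert labels[i] in {core_map[o] for o in owners}


class TestDBSCAN:
    def test_two_distant_blobs(self, rng):
        pts = np.vstack([rng.normal(0, 0.1, (20, 2)), rng.normal(100, 0.1, (20, 2))])
        labels = isl.dbscan_cluster(pts, eps=1.0, min_points=3)
        assert len(set(labels)) == 2 and (labels >= 0).all()

    def test_all_close_single_cluster(self, rng):
        pts = rng.normal(0, 0.01, (15, 2))
        labels = isl.dbscan_cluster(pts, eps=1.0, min_points=3)
        assert set(labels) == {0}

    def test_isolated_point_is_noise(self, rng):
        pts = np.vstack([rng.normal(0, 0.1, (10, 2)), [[50.0, 50.0]]])
        labels = isl.dbscan_cluster(pts, eps=1.0, min_points=3)
        assert labels[-1] == -1

    def test_matches_bruteforce_oracle_random_instances(self):
        rng = np.random.default_rng(7)
        for trial in range(50):
            n = int(rng.integers(20, 200))
            pts = rng.uniform(0, 10, (n, 2))
            eps = float(rng.uniform(0.3, 1.5))
            mp = int(rng.integers(2, 6))
            labels = isl.dbscan_cluster(pts, eps, mp)
            assert_matches_oracle(pts, eps, mp, labels)

    def test_point_order_invariance(self, rng):
        pts = rng.uniform(0, 10, (100, 2))
        perm = rng.permutation(100)
        l1 = isl.dbscan_cluster(pts, 0.8, 3)
        l2 = isl.dbscan_cluster(pts[perm], 0.8, 3)
        assert adjusted_rand_score(l1[perm], l2) == pytest.approx(1.0)
        np.testing.assert_array_equal(l1[perm] == -1, l2 == -1)


def manual_embeds(maps, ids=None):
    ids = ids or [f"s{i}" for i in range(len(maps[0]))]
    return isl.EmbeddingSet(strain_ids=ids, maps=[np.asarray(m, float) for m in maps],
                            seeds=list(range(len(maps))), perplexity=5)


class TestConsensus:
    def test_identical_maps_equal_per_map_clustering(self, rng):
        pts = np.vstack([rng.normal(0, 0.1, (5, 2)), rng.normal(10, 0.1, (5, 2))])
        embeds = manual_embeds([pts] * 4)
        part = isl.consensus_islands(embeds, eps=1.0, min_points=3)
        per_map = isl.dbscan_cluster(pts, 1.0, 3)
        assert adjusted_rand_score(per_map, part.labels) == pytest.approx(1.0)

    def test_half_coclustered_pair_not_joined(self):
        # a tight triple plus a 4th point that joins it in only 1 of 2 maps
        tight = np.array([[0, 0], [0.1, 0], [0, 0.1]])
        with_pair = np.vstack([tight, [0.05, 0.05]])
        without = np.vstack([tight, [50.0, 50.0]])
        part = isl.consensus_islands(manual_embeds([with_pair, without]), eps=1.0,
                                     min_points=3, co_threshold=0.9)
        assert part.labels[3] == -1  # f = 0.5 < 0.9
        assert (part.labels[:3] >= 0).all()

    def test_co_matrix_exact_rationals(self, rng):
        pts1 = rng.uniform(0, 5, (12, 2))
        pts2 = rng.uniform(0, 5, (12, 2))
        part = isl.consensus_islands(manual_embeds([pts1, pts2, pts1]), eps=1.0)
        co = part.co_matrix * 3
        np.testing.assert_allclose(co, np.round(co))

    def test_symmetric_unit_diagonal(self, rng):
        pts = rng.uniform(0, 5, (15, 2))
        part = isl.consensus_islands(manual_embeds([pts, pts]), eps=1.0)
        np.testing.assert_allclose(part.co_matrix, part.co_matrix.T)
        np.testing.assert_allclose(np.diag(part.co_matrix), 1.0)

    def test_raising_threshold_refines(self, rng):
        maps = [rng.normal(0, 1, (30, 2)) + rng.normal(0, 3, (1, 2)) for _ in range(6)]
        base = rng.normal(0, 4, (30, 2))
        maps = [base + rng.normal(0, 0.8, (30, 2)) for _ in range(6)]
        embeds = manual_embeds(maps)
        low = isl.consensus_islands(embeds, eps=2.0, co_threshold=0.5)
        high = isl.consensus_islands(embeds, eps=2.0, co_threshold=0.9)
        # every high-threshold island lies inside one low-threshold island
        for k in set(high.labels[high.labels >= 0]):
            members = np.where(high.labels == k)[0]
            parents = set(low.labels[members])
            assert len(parents) == 1 and parents != {-1}


class TestTuning:
    def test_degenerate_grid(self, planted_screen):
        emb = isl.embed_consensus(
            planted_screen["scores"].scores.dropna(axis=1), n_maps=4,
            perplexity=10, seed=0,
        )
        eps, mp = isl.tune_dbscan(emb, planted_screen["wt_ids"], [3.0])
        assert eps == 3.0 and mp == 3

    def test_infeasible_grid_raises(self, planted_screen):
        emb = isl.embed_consensus(
            planted_screen["scores"].scores.dropna(axis=1), n_maps=4,
            perplexity=10, seed=0,
        )
        with pytest.raises(ValueError):
            isl.tune_dbscan(emb, planted_screen["wt_ids"], [1e-6])


class TestRecovery:
    def test_planted_archipelago_recovered(self, planted_screen):
        scores = planted_screen["scores"].scores.dropna(axis=1)
        truth = planted_screen["truth"].island_labels().reindex(scores.index)
        emb = isl.embed_consensus(scores, n_maps=20, perplexity=10, seed=5)
        eps, _ = isl.tune_dbscan(emb, planted_screen["wt_ids"], [2, 3, 4, 5, 6])
        part = isl.consensus_islands(emb, eps)
        ari = adjusted_rand_score(truth.fillna(-1).astype(int), part.labels)
        assert ari >= 0.9
        assert part.n_islands == 4  # WT island + three planted islands

    def test_island_phenoprints(self, planted_screen):
        scores = planted_screen["scores"].scores.dropna(axis=1)
        truth = planted_screen["truth"]
        emb = isl.embed_consensus(scores, n_maps=20, perplexity=10, seed=5)
        part = isl.consensus_islands(emb, eps=3.0)
        prints = isl.island_phenoprints(part, scores)
        lab = part.as_series()
        wt_island = lab[list(truth.wt_ids)].mode()[0]
        assert prints.loc[wt_island].abs().mean() < 0.5
        # the length island carries its planted displacement
        long_ids = [s.strain_id for s in truth.specs if s.island_label == 1]
        long_island = lab[long_ids].mode()[0]
        assert prints.loc[long_island, "<L>"] > 4.0

    def test_stability_of_planted_islands(self, planted_screen):
        scores = planted_screen["scores"].scores.dropna(axis=1)
        emb = isl.embed_consensus(scores, n_maps=10, perplexity=10, seed=5)
        ref = isl.consensus_islands(emb, eps=3.0)
        idx = isl.island_stability(
            scores, eps=3.0, n_partitions=6, maps_per_partition=4,
            holdout_fraction=0.05, reference=ref, perplexity=10, seed=9,
        )
        assert np.nanmedian(idx.to_numpy()) >= 0.9


class TestValidation:
    def test_nan_scores_rejected(self):
        df = pd.DataFrame(np.full((12, 3), np.nan), columns=list("abc"))
        with pytest.raises(ValueError):
            isl.embed_consensus(df, n_maps=1)

    def test_too_few_strains(self, rng):
        df = pd.DataFrame(rng.standard_normal((5, 3)), columns=list("abc"))
        with pytest.raises(ValueError):
            isl.embed_consensus(df, n_maps=1)
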