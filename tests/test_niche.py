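"""Neighborhood features, Delaunay graph, graph embedding, district clustering."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from stampseq import niche, synthdata
from stampseq.niche import (
    EmbeddingConfig,
    build_delaunay,
    cluster_districts,
    district_pipeline,
    embed_graphsage,
    neighborhood_features,
)


def cells_df(coords, types):
    return pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(len(coords))],
        "x": [c[0] for c in coords], "y": [c[1] for c in coords],
        "cell_type": types,
    })


class TestNeighborhoodFeatures:
    def test_isolated_cell_excluded(self):
        cells = cells_df([(0, 0), (5, 0), (500, 500)], ["A", "B", "A"])
        feats, excluded = neighborhood_features(cells, radius_um=30)
        assert excluded == ["c2"]
        assert set(feats.index) == {"c0", "c1"}

    def test_single_neighbor_indicator_vector(self):
        cells = cells_df([(0, 0), (5, 0)], ["A", "B"])
        feats, _ = neighborhood_features(cells, radius_um=30)
        assert feats.loc["c0", "B"] == 1.0
        assert feats.loc["c0", "A"] == 0.0

    def test_five_neighbor_mix_proportions(self):
        coords = [(0, 0)] + [(1, 0), (0, 1), (-1, 0), (0, -1), (1, 1)]
        types = ["X", "A", "A", "A", "B", "B"]
        feats, _ = neighborhood_features(cells_df(coords, types), radius_um=5)
        assert feats.loc["c0", "A"] == pytest.approx(0.6)
        assert feats.loc["c0", "B"] == pytest.approx(0.4)

    def test_rows_on_simplex(self, planted_cells):
        feats, _ = neighborhood_features(planted_cells.head(400))
        sums = feats.to_numpy().sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)
        assert (feats.to_numpy() >= 0).all()


class TestDelaunay:
    def test_triangle_has_three_edges(self):
        g = build_delaunay(cells_df([(0, 0), (10, 0), (5, 8)], ["A"] * 3))
        assert len(g.edges) == 3

    def test_unit_square_five_edges(self):
        g = build_delaunay(cells_df([(0, 0), (1, 0), (0, 1), (1, 1)], ["A"] * 4))
        assert len(g.edges) == 5

    def test_under_three_points_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            build_delaunay(cells_df([(0, 0), (1, 1)], ["A", "A"]))

    def test_collinear_falls_back_to_knn(self):
        g = build_delaunay(cells_df([(i, 0) for i in range(6)], ["A"] * 6))
        assert g.used_knn_fallback
        assert len(g.edges) > 0

    def test_edge_pruning_by_length(self):
        cells = cells_df([(0, 0), (10, 0), (5, 8), (500, 0)], ["A"] * 4)
        g = build_delaunay(cells, prune_longer_than_um=100)
        coords = cells[["x", "y"]].to_numpy()
        lengths = np.hypot(*(coords[g.edges[:, 0]] - coords[g.edges[:, 1]]).T)
        assert (lengths <= 100).all()

    def test_matches_empty_circumcircle_oracle(self, rng):
        """Every returned edge belongs to a triangle whose circumcircle is
        empty — the defining property, checked by brute force at small n."""
        pts = rng.uniform(0, 100, size=(30, 2))
        cells = cells_df(pts.tolist(), ["A"] * 30)
        g = build_delaunay(cells)

        def circumcircle(a, b, c):
            ax, ay = a; bx, by = b; cx, cy = c
            d = 2 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
            if abs(d) < 1e-12:
                return None
            ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
                  + (cx**2 + cy**2) * (ay - by)) / d
            uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
                  + (cx**2 + cy**2) * (bx - ax)) / d
            r = np.hypot(ax - ux, ay - uy)
            return (ux, uy), r

        # oracle edge set: edges of all triangles with empty circumcircles
        oracle = set()
        n = len(pts)
        for i in range(n):
            for j in range(i + 1, n):
                for k in range(j + 1, n):
                    cc = circumcircle(pts[i], pts[j], pts[k])
                    if cc is None:
                        continue
                    (ux, uy), r = cc
                    d = np.hypot(pts[:, 0] - ux, pts[:, 1] - uy)
                    inside = d < r - 1e-9
                    inside[[i, j, k]] = False
                    if not inside.any():
                        oracle |= {(i, j), (i, k), (j, k)}
        got = {tuple(e) for e in g.edges}
        assert got == oracle


@pytest.fixture(scope="module")
def two_block_setup():
    """Two disconnected homogeneous blocks with distinct compositions."""
    rng = np.random.default_rng(8)
    blk1 = rng.uniform(0, 40, size=(40, 2))
    blk2 = rng.uniform(500, 540, size=(40, 2))
    coords = np.vstack([blk1, blk2]).tolist()
    types = ["A"] * 40 + ["B"] * 40
    cells = cells_df(coords, types)
    feats, _ = neighborhood_features(cells, radius_um=30)
    featured = cells[cells["cell_id"].isin(feats.index)]
    graph = build_delaunay(featured, prune_longer_than_um=100)
    return graph, feats


class TestEmbedding:
    def test_epochs_zero_reproducible_forward_pass(self, two_block_setup):
        graph, feats = two_block_setup
        cfg = EmbeddingConfig(epochs=0, seed=4)
        r1 = embed_graphsage(graph, feats, cfg)
        r2 = embed_graphsage(graph, feats, cfg)
        np.testing.assert_array_equal(r1.embeddings, r2.embeddings)
        assert r1.losses == []

    def test_deterministic_training(self, two_block_setup):
        graph, feats = two_block_setup
        cfg = EmbeddingConfig(epochs=25, seed=4)
        r1 = embed_graphsage(graph, feats, cfg)
        r2 = embed_graphsage(graph, feats, cfg)
        np.testing.assert_array_equal(r1.embeddings, r2.embeddings)
        assert r1.losses == r2.losses

    def test_disconnected_blocks_linearly_separable(self, two_block_setup):
        graph, feats = two_block_setup
        cfg = EmbeddingConfig(epochs=60, seed=1)
        result = embed_graphsage(graph, feats, cfg)
        is_blk1 = np.array([int(c[1:]) < 40 for c in graph.node_ids])
        Z = result.embeddings
        # project on the difference of block means and threshold at midpoint
        w = Z[is_blk1].mean(0) - Z[~is_blk1].mean(0)
        proj = Z @ w
        thresh = (proj[is_blk1].mean() + proj[~is_blk1].mean()) / 2
        acc = ((proj > thresh) == is_blk1).mean()
        assert acc == 1.0

    def test_loss_decreases_on_smoothed_curve(self, two_block_setup):
        graph, feats = two_block_setup
        cfg = EmbeddingConfig(epochs=150, seed=2)
        result = embed_graphsage(graph, feats, cfg)
        losses = np.array(result.losses)
        smooth = np.convolve(losses, np.ones(25) / 25, mode="valid")
        assert smooth[-1] <= smooth[0] + 1e-3

    def test_empty_graph_rejected(self, two_block_setup):
        _, feats = two_block_setup
        empty = niche.SpatialGraph(node_ids=np.array([]), edges=np.empty((0, 2), int))
        with pytest.raises(ValueError, match="empty graph"):
            embed_graphsage(empty, feats)


def gapped_two_block_cells(seed, dominant=0.9, n_per_block=150):
    """Two 0.9-dominant blocks separated by a 300 um gap (no feature blending)."""
    rng = np.random.default_rng(seed)
    b1 = np.column_stack([rng.uniform(0, 200, n_per_block),
                          rng.uniform(0, 150, n_per_block)])
    b2 = np.column_stack([rng.uniform(500, 700, n_per_block),
                          rng.uniform(0, 150, n_per_block)])
    coords = np.vstack([b1, b2])
    t1 = np.where(rng.uniform(size=n_per_block) < dominant, "A", "B")
    t2 = np.where(rng.uniform(size=n_per_block) < dominant, "B", "A")
    return cells_df(coords.tolist(), np.concatenate([t1, t2]).tolist())


class TestClustering:
    def test_homogeneous_tissue_single_district(self, rng):
        coords = rng.uniform(0, 200, size=(300, 2)).tolist()
        cells = cells_df(coords, list(rng.choice(["A", "B"], 300)))
        feats, _ = neighborhood_features(cells)
        a = cluster_districts(feats.to_numpy(), feats.index.to_numpy(),
                              resolution=1e-4, seed=0)
        assert a.labels.nunique() == 1

    def test_planted_two_niche_perfect_recovery(self):
        cells = gapped_two_block_cells(seed=1)
        feats, _ = neighborhood_features(cells)
        featured = cells[cells["cell_id"].isin(feats.index)]
        graph = build_delaunay(featured, prune_longer_than_um=100)
        emb = embed_graphsage(graph, feats, EmbeddingConfig(seed=1))
        a = cluster_districts(emb.embeddings, graph.node_ids,
                              resolution=0.05, seed=1)
        truth = ["N1" if int(c[1:]) < 150 else "N2" for c in a.labels.index]
        assert a.labels.nunique() == 2
        assert adjusted_rand_score(truth, a.labels.to_numpy()) == 1.0

    def test_planted_five_niche_high_ari(self, planted_cells):
        """Full embedding path recovers the planted 5-strip partition."""
        assignment, _, _ = district_pipeline(
            planted_cells, config=EmbeddingConfig(seed=5)
        )
        truth = planted_cells.set_index("cell_id").loc[assignment.labels.index,
                                                       "niche"]
        assert assignment.labels.nunique() == 5
        assert adjusted_rand_score(truth, assignment.labels) >= 0.8

    def test_pipeline_invariant_to_cell_order(self):
        cells = synthdata.simulate_cell_table(n_cells=400, n_niches=2, seed=10)
        cfg = EmbeddingConfig(epochs=20, seed=6)
        a1, _, _ = district_pipeline(cells, config=cfg)
        shuffled = cells.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a2, _, _ = district_pipeline(shuffled, config=cfg)
        joint = pd.concat([a1.labels.rename("p1"), a2.labels.rename("p2")], axis=1)
        assert adjusted_rand_score(joint["p1"], joint["p2"]) == 1.0
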