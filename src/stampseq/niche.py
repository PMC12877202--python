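"""Unsupervised spatial districting.

Each cell is described by the cell-type composition of its neighbors within a
30 um radius; cells are linked by a Delaunay triangulation of their positions;
a small GraphSAGE-style encoder (mean aggregation over neighbors combined with
each node's own features) is trained unsupervised with a negative-sampling
neighbor-proximity loss plus a lambda-weighted InfoNCE contrastive term
(temperature tau, positives = graph neighbors); and Leiden community detection
on a kNN graph of the embeddings yields the districts.

The encoder is a deliberately small, dependency-free implementation: dense
numpy forward/backward passes with an Adam optimizer, all randomness (weight
init, edge and negative sampling, dropout masks) drawn from a single seed so
embeddings are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import Delaunay, QhullError, cKDTree


# ---------------------------------------------------------------- features

def neighborhood_features(
    cells: pd.DataFrame, radius_um: float = 30.0
) -> tuple[pd.DataFrame, list]:
    """Per-cell neighbor type composition within ``radius_um`` (self excluded).

    Returns (features, excluded_cell_ids).  Feature rows lie on the simplex;
    cells with zero neighbors inside the radius are excluded and listed.
    """
    if cells.empty:
        raise ValueError("no cells")
    coords = cells[["x", "y"]].to_numpy(dtype=float)
    types = sorted(cells["cell_type"].unique())
    type_idx = cells["cell_type"].map({t: i for i, t in enumerate(types)}).to_numpy()
    n = len(cells)
    counts = np.zeros((n, len(types)))
    pairs = cKDTree(coords).query_pairs(r=radius_um, output_type="ndarray")
    if len(pairs):
        np.add.at(counts, (pairs[:, 0], type_idx[pairs[:, 1]]), 1.0)
        np.add.at(counts, (pairs[:, 1], type_idx[pairs[:, 0]]), 1.0)
    totals = counts.sum(axis=1)
    keep = totals > 0
    feats = counts[keep] / totals[keep, None]
    features = pd.DataFrame(feats, index=cells["cell_id"].to_numpy()[keep], columns=types)
    excluded = cells["cell_id"].to_numpy()[~keep].tolist()
    return features, excluded


# ---------------------------------------------------------------- graph

@dataclass
class SpatialGraph:
    """Undirected graph over featured cells (no self-loops)."""

    node_ids: np.ndarray  # cell ids in node order
    edges: np.ndarray  # (m, 2) int, i < j
    used_knn_fallback: bool = False

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def adjacency(self) -> sparse.csr_matrix:
        n, e = self.n_nodes, self.edges
        if len(e) == 0:
            return sparse.csr_matrix((n, n))
        data = np.ones(2 * len(e))
        rows = np.concatenate([e[:, 0], e[:, 1]])
        cols = np.concatenate([e[:, 1], e[:, 0]])
        return sparse.csr_matrix((data, (rows, cols)), shape=(n, n))


def build_delaunay(
    cells: pd.DataFrame,
    prune_longer_than_um: float | None = None,
    knn_fallback: int = 6,
) -> SpatialGraph:
    """Delaunay triangulation graph of cell positions.

    Fewer than 3 cells is an error; degenerate (e.g. collinear) inputs fall
    back to a k-nearest-neighbor graph, flagged on the result.  Edges longer
    than ``prune_longer_than_um`` are optionally removed.
    """
    coords = cells[["x", "y"]].to_numpy(dtype=float)
    ids = cells["cell_id"].to_numpy()
    if len(coords) < 3:
        raise ValueError("need at least 3 cells for a triangulation")
    used_fallback = False
    try:
        tri = Delaunay(coords)
        edge_set = set()
        for simplex in tri.simplices:
            for a in range(3):
                i, j = int(simplex[a]), int(simplex[(a + 1) % 3])
                edge_set.add((min(i, j), max(i, j)))
        edges = np.array(sorted(edge_set), dtype=int)
    except QhullError:
        used_fallback = True
        k = min(knn_fallback, len(coords) - 1)
        _, nbrs = cKDTree(coords).query(coords, k=k + 1)
        edge_set = set()
        for i in range(len(coords)):
            for j in nbrs[i, 1:]:
                edge_set.add((min(i, int(j)), max(i, int(j))))
        edges = np.array(sorted(edge_set), dtype=int)
    if prune_longer_than_um is not None and len(edges):
        lengths = np.hypot(*(coords[edges[:, 0]] - coords[edges[:, 1]]).T)
        edges = edges[lengths <= prune_longer_than_um]
    return SpatialGraph(node_ids=ids, edges=edges, used_knn_fallback=used_fallback)


# ---------------------------------------------------------------- embedding

@dataclass
class EmbeddingConfig:
    hidden_dim: int = 64
    out_dim: int = 32
    n_layers: int = 2
    learning_rate: float = 0.001
    epochs: int = 150
    tau: float = 0.3
    lam: float = 0.3
    dropout_p: float = 0.25
    n_negatives: int = 5
    batch_edges: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout_p must be in [0, 1)")
        if self.n_layers < 1:
            raise ValueError("need at least one layer")


@dataclass
class EmbeddingResult:
    embeddings: np.ndarray
    losses: list[float] = field(default_factory=list)
    config: EmbeddingConfig | None = None


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[:] = b1 * m + (1 - b1) * g
            v[:] = b2 * v + (1 - b2) * g**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


def _mean_adjacency(graph: SpatialGraph) -> sparse.csr_matrix:
    A = graph.adjacency()
    deg = np.asarray(A.sum(axis=1)).ravel()
    inv = np.where(deg > 0, 1.0 / np.maximum(deg, 1e-12), 0.0)
    return sparse.diags(inv) @ A


def _forward(X, A_mean, weights, dropout_p=0.0, rng=None):
    """Returns (embeddings, cache) for backprop."""
    H = X
    cache = []
    n_layers = len(weights)
    for l, (Ws, Wn, b) in enumerate(weights):
        M = A_mean @ H
        Z = H @ Ws + M @ Wn + b
        last = l == n_layers - 1
        act = Z if last else np.maximum(Z, 0.0)
        if not last and dropout_p > 0 and rng is not None:
            mask = (rng.uniform(size=act.shape) >= dropout_p) / (1 - dropout_p)
            out = act * mask
        else:
            mask = None
            out = act
        cache.append((H, M, Z, mask))
        H = out
    return H, cache


def _backward(dZ_out, A_mean, weights, cache, dropout_p):
    grads = []
    dH = dZ_out
    for l in range(len(weights) - 1, -1, -1):
        Ws, Wn, b = weights[l]
        H_in, M, Z, mask = cache[l]
        last = l == len(weights) - 1
        if not last:
            if mask is not None:
                dH = dH * mask
            dH = dH * (Z > 0)
        dZ = dH
        gWs = H_in.T @ dZ
        gWn = M.T @ dZ
        gb = dZ.sum(axis=0)
        grads.append((gWs, gWn, gb))
        if l > 0:
            dH = dZ @ Ws.T + A_mean.T @ (dZ @ Wn.T)
    return list(reversed(grads))


def _loss_and_grad(Z, edges_batch, negatives, tau, lam):
    """Neighbor-proximity (negative sampling) + InfoNCE losses and dZ."""
    u, v = edges_batch[:, 0], edges_batch[:, 1]
    B = len(u)
    dZ = np.zeros_like(Z)

    # negative-sampling proximity loss
    s_pos = np.einsum("ij,ij->i", Z[u], Z[v])
    sig_pos = 1.0 / (1.0 + np.exp(-np.clip(s_pos, -30, 30)))
    loss = -np.log(np.maximum(sig_pos, 1e-12)).sum()
    g_pos = (sig_pos - 1.0) / B
    np.add.at(dZ, u, g_pos[:, None] * Z[v])
    np.add.at(dZ, v, g_pos[:, None] * Z[u])
    # negatives: shape (B, K)
    s_neg = np.einsum("ij,ikj->ik", Z[u], Z[negatives])
    sig_neg = 1.0 / (1.0 + np.exp(-np.clip(s_neg, -30, 30)))
    loss += -np.log(np.maximum(1.0 - sig_neg, 1e-12)).sum()
    g_neg = sig_neg / B
    np.add.at(dZ, u, np.einsum("ik,ikj->ij", g_neg, Z[negatives]))
    np.add.at(dZ, negatives, g_neg[:, :, None] * Z[u][:, None, :])
    loss /= B

    if lam > 0:
        # InfoNCE over the batch: anchors u, positives v, in-batch negatives
        norms = np.linalg.norm(Z, axis=1, keepdims=True)
        norms = np.maximum(norms, 1e-12)
        Zh = Z / norms
        S = (Zh[u] @ Zh[v].T) / tau
        S = S - S.max(axis=1, keepdims=True)
        expS = np.exp(S)
        P = expS / expS.sum(axis=1, keepdims=True)
        nce = -np.mean(np.log(np.maximum(P[np.arange(B), np.arange(B)], 1e-12)))
        loss += lam * nce
        G = (P - np.eye(B)) / B  # dL/dS
        dZh = np.zeros_like(Zh)
        np.add.at(dZh, u, lam * (G @ Zh[v]) / tau)
        np.add.at(dZh, v, lam * (G.T @ Zh[u]) / tau)
        # through the row normalization: dz = (dzh - (dzh . zh) zh) / ||z||
        proj = np.einsum("ij,ij->i", dZh, Zh)[:, None]
        dZ += (dZh - proj * Zh) / norms
    return loss, dZ


def embed_graphsage(
    graph: SpatialGraph, features: pd.DataFrame, config: EmbeddingConfig | None = None
) -> EmbeddingResult:
    """Train the unsupervised graph encoder and return per-cell embeddings.

    ``features`` rows must align with ``graph.node_ids``.  With ``epochs=0``
    the embeddings are the untrained forward pass of the seeded initial
    weights.  Isolated nodes aggregate a zero neighbor vector and rely on
    their own features.
    """
    config = config or EmbeddingConfig()
    if graph.n_nodes == 0:
        raise ValueError("empty graph")
    feats = features.loc[graph.node_ids]
    X = feats.to_numpy(dtype=float)
    A_mean = _mean_adjacency(graph)
    rng = np.random.default_rng(config.seed)

    dims = [X.shape[1]] + [config.hidden_dim] * (config.n_layers - 1) + [config.out_dim]
    weights = []
    for l in range(config.n_layers):
        fan_in, fan_out = dims[l], dims[l + 1]
        scale = np.sqrt(2.0 / (fan_in + fan_out))
        weights.append(
            (
                rng.normal(0, scale, size=(fan_in, fan_out)),
                rng.normal(0, scale, size=(fan_in, fan_out)),
                np.zeros(fan_out),
            )
        )

    losses: list[float] = []
    edges = graph.edges
    if config.epochs > 0 and len(edges) > 0:
        flat_params = [arr for triple in weights for arr in triple]
        opt = _Adam(flat_params, config.learning_rate)
        n = graph.n_nodes
        for _ in range(config.epochs):
            batch_idx = rng.integers(0, len(edges), size=min(config.batch_edges, len(edges)))
            batch = edges[batch_idx]
            # random orientation so both endpoints act as anchors over training
            flip = rng.uniform(size=len(batch)) < 0.5
            batch = np.where(flip[:, None], batch[:, ::-1], batch)
            negatives = rng.integers(0, n, size=(len(batch), config.n_negatives))
            Z, cache = _forward(X, A_mean, weights, config.dropout_p, rng)
            loss, dZ = _loss_and_grad(Z, batch, negatives, config.tau, config.lam)
            losses.append(float(loss))
            grads = _backward(dZ, A_mean, weights, cache, config.dropout_p)
            opt.step([g for triple in grads for g in triple])

    Z_final, _ = _forward(X, A_mean, weights, dropout_p=0.0, rng=None)
    return EmbeddingResult(embeddings=Z_final, losses=losses, config=config)


# ---------------------------------------------------------------- clustering

@dataclass
class DistrictAssignment:
    labels: pd.Series  # cell_id -> district label "D1", "D2", ...
    resolution: float

    def as_frame(self) -> pd.DataFrame:
        return self.labels.rename("district").rename_axis("cell_id").reset_index()


#: default Leiden resolution; calibrated so district-scale communities
#: (hundreds of um) come out whole rather than fragmented
DEFAULT_RESOLUTION = 0.1


def cluster_districts(
    embeddings: np.ndarray,
    node_ids: np.ndarray,
    resolution: float = DEFAULT_RESOLUTION,
    n_neighbors: int = 15,
    seed: int = 0,
) -> DistrictAssignment:
    """Leiden community detection on a kNN graph of the embeddings.

    Districts are labeled D1, D2, ... in decreasing size order; the partition
    is deterministic under the seed.
    """
    import igraph
    import leidenalg
    from sklearn.neighbors import NearestNeighbors

    n = len(embeddings)
    k = min(n_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embeddings)
    _, idx = nn.kneighbors(embeddings)
    edge_set = set()
    for i in range(n):
        for j in idx[i, 1:]:
            edge_set.add((min(i, int(j)), max(i, int(j))))
    g = igraph.Graph(n=n, edges=sorted(edge_set))
    # duplicate-heavy embeddings can fragment the kNN graph; bridge components
    # at their closest point pairs so the partition is set by the resolution,
    # not by accidental disconnection
    comps = g.connected_components()
    while len(comps) > 1:
        members = [np.asarray(c) for c in comps]
        base = members[0]
        best = None
        for other in members[1:]:
            d = np.linalg.norm(
                embeddings[base][:, None, :] - embeddings[other][None, :, :],
                axis=2,
            )
            i, j = np.unravel_index(np.argmin(d), d.shape)
            cand = (float(d[i, j]), int(base[i]), int(other[j]))
            if best is None or cand < best:
                best = cand
        g.add_edge(best[1], best[2])
        comps = g.connected_components()
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
    )
    membership = np.asarray(part.membership)
    # relabel by decreasing community size for stable, readable names
    sizes = pd.Series(membership).value_counts()
    rename = {old: f"D{rank + 1}" for rank, old in enumerate(sizes.index)}
    labels = pd.Series([rename[m] for m in membership], index=node_ids)
    return DistrictAssignment(labels=labels, resolution=resolution)


def district_pipeline(
    cells: pd.DataFrame,
    radius_um: float = 30.0,
    resolution: float = DEFAULT_RESOLUTION,
    config: EmbeddingConfig | None = None,
) -> tuple[DistrictAssignment, EmbeddingResult, SpatialGraph]:
    """Full path: composition features -> Delaunay -> embedding -> Leiden.

    Cells are processed in canonical cell_id order, so the partition is
    invariant to the input row order.
    """
    cells = cells.sort_values("cell_id", kind="stable").reset_index(drop=True)
    features, excluded = neighborhood_features(cells, radius_um)
    featured = cells[cells["cell_id"].isin(features.index)]
    graph = build_delaunay(featured)
    result = embed_graphsage(graph, features, config)
    assignment = cluster_districts(
        result.embeddings,
        graph.node_ids,
        resolution=resolution,
        seed=(config.seed if config else 0),
    )
    return assignment, result, graph
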