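"""Benchmarking assigned nucleus positions against ground-truth centroids.

Covers the control-point coordinate transform between the assay frame and an
imaging frame, one-to-one nearest matching of predicted to true nuclei, a
uniform-random positioning baseline, and marker overlap-ratio concordance
between two expression matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist


@dataclass
class AffineTransform2D:
    """p' = A @ p + b."""

    linear: np.ndarray  # 2x2
    offset: np.ndarray  # 2

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.linear.T + self.offset


def fit_affine(control_pairs, similarity: bool = False) -> AffineTransform2D:
    """Least-squares 2D transform from >= 3 non-collinear control pairs.

    ``control_pairs`` is a sequence of ((x, y), (x', y')).  The default is a
    full 6-dof affine; ``similarity=True`` constrains to rotation + uniform
    scale + translation (Umeyama closed form).
    """
    src = np.array([p for p, _ in control_pairs], dtype=float)
    dst = np.array([q for _, q in control_pairs], dtype=float)
    if len(src) < 3:
        raise ValueError("need at least 3 control pairs")
    # collinearity check on the source points
    centered = src - src.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise ValueError("control points are collinear")
    if similarity:
        mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
        sc, dc = src - mu_s, dst - mu_d
        cov = dc.T @ sc / len(src)
        U, D, Vt = np.linalg.svd(cov)
        S = np.eye(2)
        if np.linalg.det(U @ Vt) < 0:
            S[1, 1] = -1
        R = U @ S @ Vt
        var_s = (sc**2).sum() / len(src)
        scale = np.trace(np.diag(D) @ S) / var_s
        A = scale * R
        b = mu_d - A @ mu_s
        return AffineTransform2D(A, b)
    # full affine via one lstsq on homogeneous coordinates
    X = np.column_stack([src, np.ones(len(src))])
    sol, *_ = np.linalg.lstsq(X, dst, rcond=None)
    return AffineTransform2D(sol[:2].T.copy(), sol[2].copy())


@dataclass
class MatchResult:
    """One-to-one pairing of predicted nuclei to truth nuclei."""

    pairs: pd.DataFrame  # columns: pred_id, truth_id, offset_um
    unmatched_pred: list = field(default_factory=list)
    unmatched_truth: list = field(default_factory=list)

    @property
    def offsets(self) -> np.ndarray:
        return self.pairs["offset_um"].to_numpy()


def match_nearest(
    predicted: pd.DataFrame,
    truth: pd.DataFrame,
    pred_cols: tuple[str, str] = ("x_um", "y_um"),
    truth_cols: tuple[str, str] = ("true_x_um", "true_y_um"),
    pred_id: str = "cell_id",
    truth_id: str = "nucleus_id",
) -> MatchResult:
    """Globally-shortest-first greedy one-to-one matching.

    All candidate pairs are ranked by distance; pairs are accepted in that
    order whenever both endpoints are still free, so each truth nucleus is
    used at most once and the pairing is order-independent and deterministic.
    """
    if predicted.empty or truth.empty:
        raise ValueError("both point sets must be non-empty")
    P = predicted[list(pred_cols)].to_numpy(dtype=float)
    T = truth[list(truth_cols)].to_numpy(dtype=float)
    D = cdist(P, T)
    order = np.argsort(D, axis=None, kind="stable")
    used_p = np.zeros(len(P), dtype=bool)
    used_t = np.zeros(len(T), dtype=bool)
    rows = []
    n_pairs_max = min(len(P), len(T))
    for flat in order:
        i, j = divmod(flat, len(T))
        if used_p[i] or used_t[j]:
            continue
        used_p[i] = used_t[j] = True
        rows.append((predicted[pred_id].iloc[i], truth[truth_id].iloc[j], D[i, j]))
        if len(rows) == n_pairs_max:
            break
    pairs = pd.DataFrame(rows, columns=["pred_id", "truth_id", "offset_um"])
    return MatchResult(
        pairs=pairs,
        unmatched_pred=predicted[pred_id].iloc[np.flatnonzero(~used_p)].tolist(),
        unmatched_truth=truth[truth_id].iloc[np.flatnonzero(~used_t)].tolist(),
    )


def random_baseline(
    n: int,
    bounds_um: tuple[float, float, float, float],
    truth: pd.DataFrame,
    seed: int = 0,
    truth_cols: tuple[str, str] = ("true_x_um", "true_y_um"),
) -> np.ndarray:
    """Offsets of n uniform-random positions matched one-to-one to truth."""
    rng = np.random.default_rng(seed)
    x0, y0, x1, y1 = bounds_um
    pts = pd.DataFrame(
        {
            "cell_id": [f"rand{i}" for i in range(n)],
            "x_um": rng.uniform(x0, x1, n),
            "y_um": rng.uniform(y0, y1, n),
        }
    )
    return match_nearest(pts, truth, truth_cols=truth_cols).offsets


def overlap_ratio(cells_a: set, cells_b: set) -> float:
    """|A ∩ B| / max(|A|, |B|); zero when both sets are empty."""
    if not cells_a and not cells_b:
        return 0.0
    return len(cells_a & cells_b) / max(len(cells_a), len(cells_b))


def _expressing(matrix: pd.DataFrame, gene: str) -> set:
    """Cells with raw count > 0 for the gene (index = cell ids)."""
    col = matrix[gene]
    return set(matrix.index[col.to_numpy() > 0])


def marker_overlap_vector(matrix: pd.DataFrame, markers: list[str]) -> np.ndarray:
    """Pairwise overlap ratios over all unordered marker pairs, fixed order."""
    missing = [g for g in markers if g not in matrix.columns]
    if missing:
        raise ValueError(f"markers absent from matrix: {missing}")
    sets = {g: _expressing(matrix, g) for g in markers}
    vals = []
    for i in range(len(markers)):
        for j in range(i + 1, len(markers)):
            vals.append(overlap_ratio(sets[markers[i]], sets[markers[j]]))
    return np.array(vals)


def marker_concordance(
    matrix_1: pd.DataFrame, matrix_2: pd.DataFrame, markers: list[str]
) -> float:
    """Pearson r between the two platforms' marker overlap-ratio vectors.

    Returns NaN when either vector is constant (correlation undefined).
    """
    v1 = marker_overlap_vector(matrix_1, markers)
    v2 = marker_overlap_vector(matrix_2, markers)
    if np.std(v1) == 0 or np.std(v2) == 0:
        return float("nan")
    return float(np.corrcoef(v1, v2)[0, 1])
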