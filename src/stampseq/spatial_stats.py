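"""Tissue-preference and colocalization statistics on localized, typed cells.

Ro/e compares observed cluster-by-group cell counts with chi-square expected
counts; PCCF compares observed within-radius cross-type pair counts with their
mean over label permutations (a CSR-conditional null that keeps the observed
point pattern fixed); radial profiles summarize per-type distances to a niche
centroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree


def roe(contingency: pd.DataFrame) -> pd.DataFrame:
    """Ratio of observed to chi-square expected counts per cell.

    expected_ij = row_i * col_j / total.  Entries with expected 0 (an all-zero
    row or column) are reported as NaN.  A cluster is called enriched in a
    group when its Ro/e exceeds 1.
    """
    obs = contingency.to_numpy(dtype=float)
    if (obs < 0).any():
        raise ValueError("contingency counts must be non-negative")
    total = obs.sum()
    if total <= 0:
        raise ValueError("all-zero contingency table")
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(expected > 0, obs / expected, np.nan)
    return pd.DataFrame(ratio, index=contingency.index, columns=contingency.columns)


def contingency_from_cells(
    cells: pd.DataFrame, cluster_col: str = "cell_type", group_col: str = "sample"
) -> pd.DataFrame:
    return pd.crosstab(cells[cluster_col], cells[group_col])


@dataclass
class PccfResult:
    type_a: str
    type_b: str
    observed_pairs: int
    expected_pairs: float
    pccf: float
    p_value: float  # two-sided permutation p for pccf != 1
    n_perm: int
    radius_um: float
    seed: int


def _pairs_within(coords: np.ndarray, radius: float) -> np.ndarray:
    """All unordered index pairs (i < j) at distance <= radius."""
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=radius, output_type="ndarray")
    return pairs if len(pairs) else np.empty((0, 2), dtype=int)


def _count_cross_pairs(labels: np.ndarray, pairs: np.ndarray, a: str, b: str) -> int:
    if len(pairs) == 0:
        return 0
    li, lj = labels[pairs[:, 0]], labels[pairs[:, 1]]
    if a == b:
        return int(np.sum((li == a) & (lj == a)))
    return int(np.sum(((li == a) & (lj == b)) | ((li == b) & (lj == a))))


def pccf(
    cells: pd.DataFrame,
    type_a: str,
    type_b: str,
    radius_um: float = 30.0,
    n_perm: int = 100,
    seed: int = 0,
) -> PccfResult:
    """Pairwise cross-correlation function with a label-permutation null.

    observed = number of unordered (type_a, type_b) pairs within ``radius_um``
    (inclusive); expected = mean of the same count after permuting all cell
    type labels over the fixed positions, ``n_perm`` times.  The two-sided
    permutation p-value uses the add-one estimator on each tail.
    """
    labels = cells["cell_type"].to_numpy(dtype=object)
    for t in (type_a, type_b):
        if t not in labels:
            raise ValueError(f"cell type {t!r} not present")
    coords = cells[["x", "y"]].to_numpy(dtype=float)
    pairs = _pairs_within(coords, radius_um)
    observed = _count_cross_pairs(labels, pairs, type_a, type_b)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        null[k] = _count_cross_pairs(rng.permutation(labels), pairs, type_a, type_b)
    expected = float(null.mean())
    if observed == 0:
        value = 0.0  # no colocalization observed, whatever the null says
    elif expected > 0:
        value = observed / expected
    else:
        value = float("nan")  # degenerate: observed pairs but a null of zeros
    p_hi = (1 + np.sum(null >= observed)) / (1 + n_perm)
    p_lo = (1 + np.sum(null <= observed)) / (1 + n_perm)
    p = min(1.0, 2.0 * min(p_hi, p_lo))
    return PccfResult(type_a, type_b, observed, expected, value, float(p),
                      n_perm, radius_um, seed)


def pccf_all_pairs_oracle(
    cells: pd.DataFrame, type_a: str, type_b: str, radius_um: float
) -> int:
    """Brute-force observed pair count (contract check for the spatial index)."""
    coords = cells[["x", "y"]].to_numpy(dtype=float)
    labels = cells["cell_type"].to_numpy(dtype=object)
    n = len(coords)
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            if np.hypot(*(coords[i] - coords[j])) <= radius_um:
                pair = {labels[i], labels[j]}
                if (type_a == type_b and pair == {type_a}) or (
                    type_a != type_b and pair == {type_a, type_b}
                ):
                    count += 1
    return count


def niche_centroid(cells: pd.DataFrame) -> tuple[float, float]:
    """Arithmetic mean of member coordinates (um)."""
    if cells.empty:
        raise ValueError("no cells to average")
    return float(cells["x"].mean()), float(cells["y"].mean())


def radial_profile(
    cells: pd.DataFrame, centroid: tuple[float, float]
) -> tuple[pd.Series, pd.Series]:
    """Distances to a niche centroid, per type.

    Returns (per-type mean distance, per-cell distance indexed like ``cells``).
    """
    cx, cy = centroid
    if not (np.isfinite(cx) and np.isfinite(cy)):
        raise ValueError("centroid must be finite")
    d = np.hypot(cells["x"].to_numpy() - cx, cells["y"].to_numpy() - cy)
    per_cell = pd.Series(d, index=cells.index, name="distance_um")
    per_type = per_cell.groupby(cells["cell_type"]).mean()
    return per_type, per_cell
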