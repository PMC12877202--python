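"""Directed district-to-district movements inferred from shared clonotypes.

Plasma cells descending from one B-cell clone share a clonotype; when the same
clonotype is found in two districts, the district with the earlier mean
pseudotime is read as the origin of one movement toward the later district.
Summed over clonotypes and district pairs this yields a migration graph whose
non-randomness is tested against a uniform distribution over all n*(n-1)
ordered district pairs with a chi-square test.  Isotype (IGHG1/IGHA1) ratios
are computed per district and along an ordered route in distance bands from
the next district's territory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree


@dataclass
class MigrationGraph:
    """Ordered district-pair transition counts."""

    counts: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def out_totals(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for (src, _), c in self.counts.items():
            out[src] = out.get(src, 0) + c
        return out

    def in_totals(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for (_, dst), c in self.counts.items():
            out[dst] = out.get(dst, 0) + c
        return out

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"from": src, "to": dst, "count": c}
            for (src, dst), c in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["from", "to", "count"])


def infer_movements(records: pd.DataFrame) -> MigrationGraph:
    """One movement per clonotype per district pair, earlier mean pseudotime first.

    ``records`` columns: cell_id, clonotype, district, pseudotime.  For every
    clonotype present in >= 2 districts, each unordered district pair it spans
    contributes one movement from the district with the smaller mean
    pseudotime to the larger; exact ties contribute nothing (the direction is
    indeterminate).
    """
    graph = MigrationGraph()
    means = records.groupby(["clonotype", "district"])["pseudotime"].mean()
    for clonotype, sub in means.groupby(level=0):
        districts = sub.index.get_level_values(1).tolist()
        for i in range(len(districts)):
            for j in range(i + 1, len(districts)):
                da, db = districts[i], districts[j]
                ta, tb = sub[(clonotype, da)], sub[(clonotype, db)]
                if ta == tb:
                    continue
                src, dst = (da, db) if ta < tb else (db, da)
                graph.counts[(src, dst)] = graph.counts.get((src, dst), 0) + 1
    return graph


def chisq_sf(chi2: float, df: int) -> float:
    """Upper-tail probability of the chi-square distribution."""
    if chi2 < 0:
        raise ValueError("chi2 must be non-negative")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.chi2.sf(chi2, df))


def chisq_uniform(
    graph: MigrationGraph,
    districts: Sequence[str],
    expected: np.ndarray | None = None,
) -> tuple[float, int, float]:
    """Chi-square test of movement counts against a uniform null.

    Counts are laid over all n*(n-1) ordered district pairs (zeros included);
    the default expected vector is uniform, total / (n*(n-1)), giving
    df = n*(n-1) - 1.  Returns (chi2, df, p).
    """
    districts = list(districts)
    n = len(districts)
    categories = [(a, b) for a in districts for b in districts if a != b]
    observed = np.array([graph.counts.get(c, 0) for c in categories], dtype=float)
    total = observed.sum()
    if total == 0:
        raise ValueError("no movements to test")
    if expected is None:
        expected_arr = np.full(len(categories), total / len(categories))
    else:
        expected_arr = np.asarray(expected, dtype=float)
        if len(expected_arr) != len(categories):
            raise ValueError("expected vector length must equal n*(n-1)")
        expected_arr = expected_arr / expected_arr.sum() * total
    chi2 = float(((observed - expected_arr) ** 2 / expected_arr).sum())
    df = len(categories) - 1
    return chi2, df, chisq_sf(chi2, df)


def isotype_ratio(
    cells: pd.DataFrame,
    group_col: str = "district",
    numerator: str = "IGHG1",
    denominator: str = "IGHA1",
) -> pd.DataFrame:
    """Per-group count(IGHG1) / count(IGHA1); NA ratio when the denominator is 0."""
    rows = []
    for group, sub in cells.groupby(group_col, sort=True):
        n_num = int((sub["isotype"] == numerator).sum())
        n_den = int((sub["isotype"] == denominator).sum())
        ratio = n_num / n_den if n_den > 0 else np.nan
        rows.append({group_col: group, f"n_{numerator}": n_num,
                     f"n_{denominator}": n_den, "ratio": ratio})
    return pd.DataFrame(rows)


DEFAULT_BANDS_UM = (0.0, 50.0, 100.0, 150.0)
BAND_ZERO_TOL_UM = 1.0


def band_label(distance: float, bands: Sequence[float] = DEFAULT_BANDS_UM) -> str | None:
    """Discrete band for a distance to the next district's territory.

    Band "0" is distance <= 1 um; then half-open intervals (b_k, b_{k+1}];
    distances beyond the last edge fall outside every band.
    """
    if distance <= BAND_ZERO_TOL_UM:
        return "0"
    for lo, hi in zip(bands[:-1], bands[1:]):
        if lo < distance <= hi:
            return f"{lo:g}-{hi:g}"
    return None


def ratio_along_route(
    cells: pd.DataFrame,
    route: Sequence[str],
    bands_um: Sequence[float] = DEFAULT_BANDS_UM,
    numerator: str = "IGHG1",
    denominator: str = "IGHA1",
) -> pd.DataFrame:
    """Isotype ratios in distance bands along consecutive route transitions.

    For each transition (Da -> Db) in the route, every isotyped cell of Da is
    banded by its Euclidean distance to the nearest cell of Db; each band's
    IGHG1/IGHA1 ratio is reported.  ``cells`` needs x, y (um), district and
    isotype columns.  An empty band yields an NA ratio with zero counts.
    """
    route = list(route)
    present = set(cells["district"].dropna().unique())
    missing = [d for d in route if d not in present]
    if missing:
        raise ValueError(f"route districts absent from cells: {missing}")
    band_names = ["0"] + [
        f"{lo:g}-{hi:g}" for lo, hi in zip(bands_um[:-1], bands_um[1:])
    ]
    rows = []
    for da, db in zip(route[:-1], route[1:]):
        src = cells[cells["district"] == da]
        dst_xy = cells.loc[cells["district"] == db, ["x", "y"]].to_numpy(dtype=float)
        tree = cKDTree(dst_xy)
        dist, _ = tree.query(src[["x", "y"]].to_numpy(dtype=float))
        labels = [band_label(d, bands_um) for d in dist]
        for band in band_names:
            members = src[[b == band for b in labels]]
            n_num = int((members["isotype"] == numerator).sum())
            n_den = int((members["isotype"] == denominator).sum())
            rows.append(
                {
                    "transition": f"{da}->{db}",
                    "band_um": band,
                    f"n_{numerator}": n_num,
                    f"n_{denominator}": n_den,
                    "ratio": n_num / n_den if n_den > 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)
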