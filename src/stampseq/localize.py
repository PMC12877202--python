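"""Nucleus localization from spatial-barcode footprints.

Each nucleus's captured barcodes are binned on a coarse grid (default 100 px =
26.5 um per side).  The bin with the highest UMI support is the core center;
the 5x5 block around it is the core.  The best bin outside the core anchors a
secondary 5x5 block, and the ratio of core UMI to secondary-block UMI
classifies the footprint: >= 10 unique center, >= 2 major center, < 2 multiple
centers (droplet collision or debris — not localizable).  Unique/major nuclei
are then assigned the candidate barcode position inside the core minimizing
the UMI-weighted sum of Euclidean distances to all core barcodes (a discrete
weighted geometric median), and the spread of their barcodes around that
position is summarized as 50/75/95% diffusion quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .chip_io import PIXEL_PITCH_UM

UNIQUE_RATIO = 10.0
MAJOR_RATIO = 2.0


@dataclass
class BinGrid:
    """Per-cell mapping of (col, row) bin index to summed UMI."""

    bin_px: int
    sums: dict[tuple[int, int], float]

    def total(self) -> float:
        return float(sum(self.sums.values()))


@dataclass
class CenterClassification:
    label: Literal["unique", "major", "multiple"]
    ratio: float  # may be +inf when no bin exists outside the core
    core_bin: tuple[int, int]
    secondary_bin: tuple[int, int] | None


@dataclass
class LocalizedNucleus:
    cell_id: str
    x_px: float
    y_px: float
    classification: CenterClassification
    total_spatial_umi: int
    d50_um: float
    d75_um: float
    d95_um: float

    def as_row(self, pixel_pitch_um: float = PIXEL_PITCH_UM) -> dict:
        return {
            "cell_id": self.cell_id,
            "x_px": self.x_px,
            "y_px": self.y_px,
            "x_um": self.x_px * pixel_pitch_um,
            "y_um": self.y_px * pixel_pitch_um,
            "class": self.classification.label,
            "ratio": self.classification.ratio,
            "total_umi": self.total_spatial_umi,
            "d50": self.d50_um,
            "d75": self.d75_um,
            "d95": self.d95_um,
        }


def bin_cell_umis(cell_rows: pd.DataFrame, bin_px: int = 100) -> BinGrid:
    """Sum a cell's UMIs onto the coarse grid.

    Cells with fewer than 2 spatial-barcode UMIs carry too little signal to
    classify and raise ``ValueError`` (callers flag them as unclassifiable).
    """
    total = int(cell_rows["umi_count"].sum())
    if total < 2:
        raise ValueError("cell has < 2 spatial-barcode UMIs; unclassifiable")
    bx = np.floor(cell_rows["x"].to_numpy() / bin_px).astype(int)
    by = np.floor(cell_rows["y"].to_numpy() / bin_px).astype(int)
    sums: dict[tuple[int, int], float] = {}
    for cx, cy, u in zip(bx, by, cell_rows["umi_count"].to_numpy()):
        key = (int(cx), int(cy))
        sums[key] = sums.get(key, 0.0) + float(u)
    return BinGrid(bin_px=bin_px, sums=sums)


def _block_sum(sums: dict[tuple[int, int], float], center: tuple[int, int]) -> float:
    """UMI total over the 5x5 block centered on ``center`` (edge-truncated)."""
    cx, cy = center
    return sum(
        sums.get((cx + dx, cy + dy), 0.0)
        for dx in range(-2, 3)
        for dy in range(-2, 3)
    )


def _block_members(center: tuple[int, int]) -> set[tuple[int, int]]:
    cx, cy = center
    return {(cx + dx, cy + dy) for dx in range(-2, 3) for dy in range(-2, 3)}


def classify_center(grid: BinGrid) -> CenterClassification:
    """Classify a footprint as unique / major / multiple center.

    Core center = max-UMI bin (ties broken to the lexicographically smallest
    index); secondary center = max-UMI bin outside the core 5x5 block.  The
    secondary block may overlap the core — each block is summed independently.
    With no bin outside the core the ratio is +inf and the cell is unique.
    """
    if not grid.sums:
        raise ValueError("empty bin grid")
    max_umi = max(grid.sums.values())
    core_bin = min(b for b, v in grid.sums.items() if v == max_umi)
    core_block = _block_members(core_bin)
    core_sum = _block_sum(grid.sums, core_bin)

    outside = {b: v for b, v in grid.sums.items() if b not in core_block}
    if not outside:
        return CenterClassification("unique", float("inf"), core_bin, None)
    max_out = max(outside.values())
    secondary_bin = min(b for b, v in outside.items() if v == max_out)
    secondary_sum = _block_sum(grid.sums, secondary_bin)
    ratio = core_sum / secondary_sum if secondary_sum > 0 else float("inf")

    if ratio >= UNIQUE_RATIO:
        label: Literal["unique", "major", "multiple"] = "unique"
    elif ratio >= MAJOR_RATIO:
        label = "major"
    else:
        label = "multiple"
    return CenterClassification(label, ratio, core_bin, secondary_bin)


def _core_rows(cell_rows: pd.DataFrame, core_bin: tuple[int, int], bin_px: int) -> pd.DataFrame:
    bx = np.floor(cell_rows["x"].to_numpy() / bin_px).astype(int)
    by = np.floor(cell_rows["y"].to_numpy() / bin_px).astype(int)
    cx, cy = core_bin
    inside = (np.abs(bx - cx) <= 2) & (np.abs(by - cy) <= 2)
    return cell_rows[inside]


def assign_position(
    core_rows: pd.DataFrame, candidates: np.ndarray | None = None
) -> tuple[float, float]:
    """UMI-weighted 1-median over the discrete candidate set.

    Candidates default to the barcode coordinates inside the core; the
    returned position is argmin_p sum_b umi_b * ||p - pos_b||.  Ties are
    broken to the lexicographically smaller (x, y).
    """
    if core_rows.empty:
        raise ValueError("empty core: no barcodes to position against")
    pos = core_rows[["x", "y"]].to_numpy(dtype=float)
    w = core_rows["umi_count"].to_numpy(dtype=float)
    cand = pos if candidates is None else np.asarray(candidates, dtype=float)
    # cost[j] = sum_b w_b * ||cand_j - pos_b||
    diff = cand[:, None, :] - pos[None, :, :]
    cost = np.einsum("b,jb->j", w, np.sqrt((diff**2).sum(axis=2)))
    best = cost.min()
    ties = np.flatnonzero(np.isclose(cost, best, rtol=0, atol=1e-9))
    order = np.lexsort((cand[ties, 1], cand[ties, 0]))
    x, y = cand[ties[order[0]]]
    return float(x), float(y)


def diffusion_quantiles(
    rows: pd.DataFrame,
    position: tuple[float, float],
    pixel_pitch_um: float = PIXEL_PITCH_UM,
) -> tuple[float, float, float]:
    """UMI-weighted 50/75/95% quantiles of barcode-to-position distance (um).

    Each UMI counts as one observation of its barcode's distance to the
    assigned position.
    """
    if rows.empty:
        return (0.0, 0.0, 0.0)
    pos = rows[["x", "y"]].to_numpy(dtype=float)
    w = rows["umi_count"].to_numpy(dtype=float)
    d_um = np.hypot(pos[:, 0] - position[0], pos[:, 1] - position[1]) * pixel_pitch_um
    order = np.argsort(d_um)
    d_sorted, w_sorted = d_um[order], w[order]
    cum = np.cumsum(w_sorted) / w_sorted.sum()
    out = []
    for q in (0.50, 0.75, 0.95):
        idx = int(np.searchsorted(cum, q, side="left"))
        out.append(float(d_sorted[min(idx, len(d_sorted) - 1)]))
    return tuple(out)  # type: ignore[return-value]


@dataclass
class LocalizeConfig:
    bin_px: int = 100
    unique_ratio: float = UNIQUE_RATIO
    major_ratio: float = MAJOR_RATIO
    pixel_pitch_um: float = PIXEL_PITCH_UM
    quantiles_core_only: bool = True
    tissue_mask: Sequence[tuple[float, float]] | None = None  # polygon in px


def _point_in_polygon(x: float, y: float, poly: Sequence[tuple[float, float]]) -> bool:
    """Even-odd rule; boundary points count as inside (half-open convention)."""
    inside = False
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xin = (x2 - x1) * (y - y1) / (y2 - y1) + x1
            if x <= xin:
                inside = not inside
    return inside


def localize_cell(
    cell_id: str, cell_rows: pd.DataFrame, config: LocalizeConfig | None = None
) -> LocalizedNucleus | None:
    """Full per-cell pipeline; None when the cell is not localizable."""
    config = config or LocalizeConfig()
    try:
        grid = bin_cell_umis(cell_rows, config.bin_px)
    except ValueError:
        return None
    cls = classify_center(grid)
    if cls.ratio >= config.unique_ratio:
        cls.label = "unique"
    elif cls.ratio >= config.major_ratio:
        cls.label = "major"
    else:
        cls.label = "multiple"
    total = int(cell_rows["umi_count"].sum())
    if cls.label == "multiple":
        return LocalizedNucleus(cell_id, float("nan"), float("nan"), cls, total,
                                float("nan"), float("nan"), float("nan"))
    core = _core_rows(cell_rows, cls.core_bin, config.bin_px)
    x, y = assign_position(core)
    qrows = core if config.quantiles_core_only else cell_rows
    d50, d75, d95 = diffusion_quantiles(qrows, (x, y), config.pixel_pitch_um)
    return LocalizedNucleus(cell_id, x, y, cls, total, d50, d75, d95)


def localize_all(
    positioned: pd.DataFrame, config: LocalizeConfig | None = None
) -> tuple[pd.DataFrame, dict]:
    """Localize every cell in a positioned count table.

    Returns a per-cell table (cell_id, x_px, y_px, x_um, y_um, class, ratio,
    total_umi, d50, d75, d95) and a summary dict with per-class counts.
    Unclassifiable cells (< 2 UMIs) appear in the summary only.  When a tissue
    mask polygon is configured, localized nuclei falling outside it are
    reported under class "off_tissue".
    """
    config = config or LocalizeConfig()
    rows = []
    summary = {"unique": 0, "major": 0, "multiple": 0, "unclassifiable": 0,
               "off_tissue": 0}
    for cell_id, sub in positioned.groupby("cell_id", sort=True):
        loc = localize_cell(cell_id, sub, config)
        if loc is None:
            summary["unclassifiable"] += 1
            continue
        row = loc.as_row(config.pixel_pitch_um)
        if loc.classification.label in ("unique", "major") and config.tissue_mask is not None:
            if not _point_in_polygon(loc.x_px, loc.y_px, config.tissue_mask):
                summary["off_tissue"] += 1
                row["class"] = "off_tissue"
                rows.append(row)
                continue
        summary[loc.classification.label] += 1
        rows.append(row)
    columns = ["cell_id", "x_px", "y_px", "x_um", "y_um", "class", "ratio",
               "total_umi", "d50", "d75", "d95"]
    table = pd.DataFrame(rows, columns=columns)
    summary["localized"] = summary["unique"] + summary["major"]
    return table, summary


def _parse_cell_id(cell_id: str) -> tuple[int, str]:
    """Split 't<tube>-d<droplet>' into (tube, droplet)."""
    try:
        tube_part, droplet_part = cell_id.split("-", 1)
        return int(tube_part[1:]), droplet_part
    except (ValueError, IndexError) as exc:
        raise ValueError(f"cell_id {cell_id!r} is not of the form t<tube>-d<droplet>") from exc


def demux_recovery(
    positioned: pd.DataFrame,
    ks: Iterable[int] = (1, 2, 4, 8),
    n_tubes: int = 8,
    config: LocalizeConfig | None = None,
) -> dict[int, int]:
    """Localized-cell count after collapsing multiplex tubes into k groups.

    Collapsing the ``n_tubes`` tubes into ``k`` contiguous blocks merges cells
    that share (block, droplet) — emulating an experiment run with only k
    multiplex barcodes.  k = ``n_tubes`` reproduces the baseline; k = 1 merges
    every co-droplet nucleus.  Returns localized (unique or major) cell counts
    per k.
    """
    config = config or LocalizeConfig()
    out: dict[int, int] = {}
    tubes_droplets = positioned["cell_id"].map(_parse_cell_id)
    tubes = tubes_droplets.map(lambda td: td[0]).to_numpy()
    droplets = tubes_droplets.map(lambda td: td[1]).to_numpy(dtype=object)
    for k in ks:
        if n_tubes % k != 0:
            raise ValueError(f"k={k} does not divide the tube count {n_tubes}")
        group = tubes * k // n_tubes
        merged_ids = pd.Series(
            [f"t{g}-d{d}" for g, d in zip(group, droplets)], index=positioned.index
        )
        merged = positioned.assign(cell_id=merged_ids)
        merged = (
            merged.groupby(["cell_id", "spatial_barcode", "x", "y"], as_index=False)
            ["umi_count"].sum()
        )
        _, summary = localize_all(merged, config)
        out[int(k)] = summary["localized"]
    return out
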