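"""Removal of detached/prevalent spatial barcodes by bin thresholding.

A barcode that detaches from the chip can be swept into many droplets and
shows anomalously high UMI support concentrated in one chip bin, dragging the
cells that captured it toward a wrong position.  The filter partitions the
chip into square bins, flags bins whose total UMI support exceeds k times the
mean per-bin total, and removes the single worst-supported cell per flagged
bin (with all of that cell's barcodes, chip-wide) before re-evaluating.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class FilterReport:
    threshold_value: float
    bins_flagged: int
    cells_removed: list[str] = field(default_factory=list)
    barcodes_removed: int = 0
    iterations: int = 1

    def to_dict(self) -> dict:
        return {
            "threshold_value": self.threshold_value,
            "bins_flagged": self.bins_flagged,
            "cells_removed": list(self.cells_removed),
            "barcodes_removed": self.barcodes_removed,
            "iterations": self.iterations,
        }


def _bin_index(positioned: pd.DataFrame, bin_px: int) -> pd.Series:
    """Half-open [m*w, (m+1)*w) bins anchored at the chip origin."""
    bx = np.floor(positioned["x"].to_numpy() / bin_px).astype(int)
    by = np.floor(positioned["y"].to_numpy() / bin_px).astype(int)
    return pd.Series(list(zip(bx, by)), index=positioned.index)


def filter_prevalent_barcodes(
    positioned: pd.DataFrame,
    bin_px: int = 30,
    k: float = 20.0,
    max_iter: int = 100,
    single_pass: bool = False,
) -> tuple[pd.DataFrame, FilterReport]:
    """Iteratively remove cells dominated by prevalent barcodes.

    ``positioned`` must carry ``x``/``y`` pixel coordinates per row.  Per
    iteration: (i) bin the chip at ``bin_px``; (ii) total UMI per bin; (iii)
    rank bins; (iv) threshold = ``k`` times the mean per-bin total over
    non-empty bins; (v) in every bin strictly exceeding the threshold, drop
    the cell with the highest UMI support in that bin together with all its
    barcodes everywhere.  Repeats until no bin exceeds the threshold (or one
    pass when ``single_pass``).  A bin exactly at the threshold is retained.
    """
    report = FilterReport(threshold_value=float("nan"), bins_flagged=0)
    out = positioned.copy()
    if out.empty:
        return out, report

    for iteration in range(1, max_iter + 1):
        report.iterations = iteration
        bins = _bin_index(out, bin_px)
        bin_totals = out.groupby(bins)["umi_count"].sum()
        threshold = k * float(bin_totals.mean())
        report.threshold_value = threshold
        flagged = bin_totals.index[bin_totals.to_numpy() > threshold]
        report.bins_flagged = len(flagged)
        if len(flagged) == 0:
            break
        victims: set[str] = set()
        for b in flagged:
            in_bin = out[bins == b]
            per_cell = in_bin.groupby("cell_id")["umi_count"].sum()
            # deterministic tie-break: highest UMI, then lexicographic id
            best = min(per_cell.index[per_cell == per_cell.max()])
            victims.add(best)
        keep = ~out["cell_id"].isin(victims)
        report.barcodes_removed += int((~keep).sum())
        report.cells_removed.extend(sorted(victims - set(report.cells_removed)))
        out = out[keep]
        if single_pass or out.empty:
            break
    # dedupe while keeping insertion order
    report.cells_removed = list(dict.fromkeys(report.cells_removed))
    return out.reset_index(drop=True), report


def restrict_to_cells(counts: pd.DataFrame, valid_cells: set[str]) -> pd.DataFrame:
    """Keep only rows of biologically meaningful cells."""
    return counts[counts["cell_id"].isin(valid_cells)].reset_index(drop=True)
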