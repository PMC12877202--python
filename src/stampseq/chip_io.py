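"""Chip maps and spatial-barcode count tables.

A chip map is the whitelist linking every spatial barcode (a 32-mer cleaved
off one sequencing cluster) to the pixel coordinate of that cluster.  A
barcode count table links captured nuclei (``cell_id`` = multiplex tube +
droplet barcode) to spatial barcodes with UMI support.  This module reads and
writes both, removes chip barcodes that occur at more than one coordinate,
corrects observed barcodes against the whitelist at Hamming distance one, and
annotates count tables with chip coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: physical pixel pitch of the chip, micrometres per pixel
PIXEL_PITCH_UM = 0.265

_BASES = frozenset("ACGT")


@dataclass
class ChipMap:
    """Spatial barcode whitelist: one row per cluster, columns barcode/x/y (px)."""

    entries: pd.DataFrame
    pixel_pitch_um: float = PIXEL_PITCH_UM
    bounds: tuple[float, float, float, float] | None = None  # x0, y0, x1, y1 in px
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"barcode", "x", "y"}
        missing = required - set(self.entries.columns)
        if missing:
            raise ValueError(f"chip map missing columns: {sorted(missing)}")
        if self.bounds is None and len(self.entries):
            self.bounds = (
                float(self.entries["x"].min()),
                float(self.entries["y"].min()),
                float(self.entries["x"].max()),
                float(self.entries["y"].max()),
            )

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def barcode_length(self) -> int:
        if not len(self.entries):
            raise ValueError("empty chip map has no barcode length")
        return len(self.entries["barcode"].iloc[0])

    def coordinate_lookup(self) -> Mapping[str, tuple[float, float]]:
        """barcode -> (x, y); requires a deduplicated map."""
        df = self.entries
        if df["barcode"].duplicated().any():
            raise ValueError("chip map contains duplicated barcodes; dedup first")
        return {
            b: (x, y)
            for b, x, y in zip(df["barcode"].to_numpy(), df["x"].to_numpy(), df["y"].to_numpy())
        }


def _validate_barcode(bc: str, lineno: int | None = None) -> None:
    if not set(bc) <= _BASES:
        where = f" at line {lineno}" if lineno is not None else ""
        raise ValueError(f"barcode {bc!r}{where} contains non-ACGT characters")


def load_chip_map(path: str | Path, pixel_pitch_um: float = PIXEL_PITCH_UM) -> ChipMap:
    """Read a chip map TSV with columns barcode, x, y (header optional).

    Malformed rows raise ``ValueError`` naming the offending line number.
    """
    rows: list[tuple[str, float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].lower() in ("barcode", "spatial_barcode"):
                continue
            if len(parts) < 3:
                raise ValueError(f"line {lineno}: expected 3 tab-separated fields, got {len(parts)}")
            bc = parts[0]
            _validate_barcode(bc, lineno)
            try:
                x, y = float(parts[1]), float(parts[2])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-numeric coordinate") from exc
            rows.append((bc, x, y))
    df = pd.DataFrame(rows, columns=["barcode", "x", "y"])
    return ChipMap(df, pixel_pitch_um=pixel_pitch_um)


def write_chip_map(chip: ChipMap, path: str | Path) -> None:
    chip.entries.to_csv(path, sep="\t", index=False, header=True)


def dedup_chip_barcodes(chip: ChipMap) -> tuple[ChipMap, int]:
    """Drop every barcode observed at more than one distinct coordinate.

    All entries of an ambiguous barcode are removed (its true position cannot
    be known).  Returns the cleaned map and the number of distinct barcodes
    removed.  Exact duplicate rows (same barcode, same coordinate) collapse to
    one entry and are not counted as removals.
    """
    df = chip.entries.drop_duplicates(["barcode", "x", "y"])
    counts = df["barcode"].value_counts()
    dup_barcodes = counts.index[counts.to_numpy() > 1]
    kept = df[~df["barcode"].isin(dup_barcodes)].reset_index(drop=True)
    cleaned = ChipMap(kept, pixel_pitch_um=chip.pixel_pitch_um, bounds=chip.bounds,
                      meta=dict(chip.meta))
    return cleaned, int(len(dup_barcodes))


def load_counts(path: str | Path) -> pd.DataFrame:
    """Read a counts TSV: cell_id, spatial_barcode, umi_count."""
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "spatial_barcode": str})
    required = {"cell_id", "spatial_barcode", "umi_count"}
    if not required <= set(df.columns):
        raise ValueError(f"counts table must have columns {sorted(required)}")
    return aggregate_counts(df)


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def aggregate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Collapse repeated (cell_id, spatial_barcode) rows by summing UMIs."""
    out = (
        counts.groupby(["cell_id", "spatial_barcode"], as_index=False, sort=True)["umi_count"]
        .sum()
    )
    if (out["umi_count"] < 1).any():
        raise ValueError("umi_count must be >= 1")
    return out


class Hamming1Corrector:
    """Whitelist lookup with single-substitution correction.

    Exact whitelist members are returned unchanged.  A query at Hamming
    distance one from exactly one whitelist barcode is corrected to it; with
    several candidates the one with the highest read support wins, and ties
    are reported as no-match to keep correction deterministic.  Queries more
    than one substitution away are no-match.  Implemented by hashing all 3*L
    single-substitution neighbours of the query; no indel correction.
    """

    def __init__(self, whitelist: Iterable[str], read_counts: Mapping[str, float] | None = None):
        self._whitelist = set(whitelist)
        if not self._whitelist:
            raise ValueError("empty whitelist")
        lengths = {len(b) for b in self._whitelist}
        if len(lengths) != 1:
            raise ValueError("whitelist barcodes must share one length")
        (self._length,) = lengths
        self._counts = dict(read_counts) if read_counts else {}

    @property
    def barcode_length(self) -> int:
        return self._length

    def correct(self, query: str) -> str | None:
        if len(query) != self._length:
            raise ValueError(
                f"query length {len(query)} != whitelist length {self._length}"
            )
        if query in self._whitelist:
            return query
        candidates = []
        for i, orig in enumerate(query):
            for base in "ACGT":
                if base == orig:
                    continue
                neighbor = query[:i] + base + query[i + 1:]
                if neighbor in self._whitelist:
                    candidates.append(neighbor)
        if not candidates:
            return None
        if len(candidates) == 1:
            return candidates[0]
        scored = sorted(
            candidates, key=lambda b: (-self._counts.get(b, 0.0), b)
        )
        best, runner = scored[0], scored[1]
        if self._counts.get(best, 0.0) == self._counts.get(runner, 0.0):
            return None  # ambiguous tie: drop rather than guess
        return best


def correct_barcode(query: str, whitelist: Iterable[str],
                    read_counts: Mapping[str, float] | None = None) -> str | None:
    """One-shot form of :class:`Hamming1Corrector` for a single query."""
    return Hamming1Corrector(whitelist, read_counts).correct(query)


def correct_counts(counts: pd.DataFrame, chip: ChipMap) -> tuple[pd.DataFrame, int]:
    """Correct every off-whitelist barcode in a counts table.

    Whitelist read support is the summed UMI count each whitelist barcode
    already has in the table.  Returns the corrected (re-aggregated) table and
    the number of rows whose barcode could not be rescued.
    """
    whitelist = set(chip.entries["barcode"])
    on = counts["spatial_barcode"].isin(whitelist)
    support = (
        counts[on].groupby("spatial_barcode")["umi_count"].sum().to_dict()
    )
    corrector = Hamming1Corrector(whitelist, support)
    corrected = counts["spatial_barcode"].to_numpy(dtype=object).copy()
    dropped = np.zeros(len(counts), dtype=bool)
    for idx in np.flatnonzero(~on.to_numpy()):
        fixed = corrector.correct(corrected[idx])
        if fixed is None:
            dropped[idx] = True
        else:
            corrected[idx] = fixed
    out = counts.assign(spatial_barcode=corrected)[~dropped]
    return aggregate_counts(out), int(dropped.sum())


def attach_coordinates(counts: pd.DataFrame, chip: ChipMap) -> tuple[pd.DataFrame, int]:
    """Annotate each count row with the chip coordinate of its barcode.

    The chip map must be deduplicated.  Rows whose barcode is absent from the
    chip (invalid barcodes) are dropped; their number is returned alongside
    the positioned table with added ``x``/``y`` pixel columns.
    """
    if chip.entries["barcode"].duplicated().any():
        raise ValueError("chip map must be deduplicated before attaching coordinates")
    merged = counts.merge(chip.entries, left_on="spatial_barcode", right_on="barcode",
                          how="left")
    valid = merged["x"].notna()
    n_dropped = int((~valid).sum())
    out = merged[valid].drop(columns=["barcode"]).reset_index(drop=True)
    return out, n_dropped
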