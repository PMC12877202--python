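"""Synthetic chips, tissues and capture tables with known ground truth.

The generator emulates the physical capture process end to end: a sequencing
chip carries barcode clusters on a jittered grid at ~1.6 um pitch with a small
barcode duplication rate; nuclei sitting on the chip pick up barcodes from
nearby clusters with probability proportional to an isotropic Gaussian kernel
(so captured-barcode offsets follow a Rayleigh law of scale sigma); nuclei are
split across multiplex tubes and co-encapsulated in droplets, occasionally
colliding; debris contributes low-UMI barcode sets at random positions.  Every
emitted table is paired with a ground-truth record so downstream stages can be
scored exactly.

All randomness flows from the seed carried by each spec; identical specs give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree

from .chip_io import PIXEL_PITCH_UM, ChipMap, aggregate_counts

_BASE_ARRAY = np.array(list("ACGT"))


@dataclass(frozen=True)
class SyntheticChipSpec:
    """Parameters of a simulated barcode chip.

    Clusters sit on a jittered square grid at ``pitch_px`` spacing (default
    6.2 px = 1.64 um at 0.265 um/px).  A ``duplication_rate`` fraction of
    barcodes is re-used at a second, distinct coordinate, mimicking rare oligo
    synthesis duplications.
    """

    width_px: int = 800
    height_px: int = 800
    pitch_px: float = 6.2
    barcode_length: int = 32
    duplication_rate: float = 3e-4
    jitter_frac: float = 0.15  # cluster jitter as a fraction of the pitch
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pitch_px <= 0:
            raise ValueError("pitch_px must be positive")
        if not 0 <= self.duplication_rate < 1:
            raise ValueError("duplication_rate must be in [0, 1)")
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("chip dimensions must be positive")


@dataclass(frozen=True)
class NicheRegion:
    """A labeled tissue region (disc or axis-aligned rectangle) in um.

    ``mixture`` gives the cell-type mixing proportions inside the region,
    aligned with ``SyntheticTissueSpec.cell_types``; it must sum to one.
    """

    label: str
    shape: Literal["disc", "rect"]
    params: tuple[float, ...]  # disc: (cx, cy, r); rect: (x0, y0, x1, y1)
    mixture: tuple[float, ...]

    def area(self) -> float:
        if self.shape == "disc":
            return float(np.pi * self.params[2] ** 2)
        x0, y0, x1, y1 = self.params
        return float((x1 - x0) * (y1 - y0))

    def sample_points(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Uniform points inside the region (CSR-compatible null)."""
        if self.shape == "disc":
            cx, cy, r = self.params
            theta = rng.uniform(0, 2 * np.pi, n)
            rad = r * np.sqrt(rng.uniform(0, 1, n))
            return np.column_stack([cx + rad * np.cos(theta), cy + rad * np.sin(theta)])
        x0, y0, x1, y1 = self.params
        return np.column_stack([rng.uniform(x0, x1, n), rng.uniform(y0, y1, n)])

    def bounds(self) -> tuple[float, float, float, float]:
        if self.shape == "disc":
            cx, cy, r = self.params
            return (cx - r, cy - r, cx + r, cy + r)
        return self.params  # type: ignore[return-value]


@dataclass(frozen=True)
class SyntheticTissueSpec:
    """Parameters of a simulated tissue section sitting on the chip."""

    n_nuclei: int = 500
    cell_types: tuple[str, ...] = ("A", "B", "C")
    niche_layout: tuple[NicheRegion, ...] = ()
    diffusion_sigma_um: float = 2.0
    umi_mean: float = 50.0
    umi_dispersion: float = 10.0
    min_umi: int = 20
    debris_rate: float = 0.05
    debris_umi_mean: float = 3.0
    co_droplet_rate: float = 0.0
    n_multiplex: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.diffusion_sigma_um <= 0:
            raise ValueError("diffusion_sigma_um must be positive")
        if self.n_multiplex < 1:
            raise ValueError("n_multiplex must be >= 1")
        for region in self.niche_layout:
            if len(region.mixture) != len(self.cell_types):
                raise ValueError(
                    f"niche {region.label!r}: mixture length != number of cell types"
                )
            if abs(sum(region.mixture) - 1.0) > 1e-9:
                raise ValueError(f"niche {region.label!r}: mixture must sum to 1")


def default_niche_layout(
    width_um: float,
    height_um: float,
    n_niches: int = 2,
    n_types: int = 3,
) -> tuple[NicheRegion, ...]:
    """Tile the tissue into ``n_niches`` vertical strips with distinct mixes.

    Each niche is dominated (70%) by one cell type, cycling through the type
    vocabulary, with the remainder spread evenly — a simple planted-niche
    layout with unambiguous ground truth.
    """
    regions = []
    strip = width_um / n_niches
    for i in range(n_niches):
        mix = np.full(n_types, 0.3 / max(n_types - 1, 1))
        mix[i % n_types] = 0.7
        if n_types == 1:
            mix = np.array([1.0])
        regions.append(
            NicheRegion(
                label=f"N{i + 1}",
                shape="rect",
                params=(i * strip, 0.0, (i + 1) * strip, height_um),
                mixture=tuple(mix / mix.sum()),
            )
        )
    return tuple(regions)


def _random_barcodes(n: int, length: int, rng: np.random.Generator) -> np.ndarray:
    """n distinct random ACGT strings of the given length."""
    if length < 1 or 4.0**length < 2 * n:
        raise ValueError(f"barcode space 4^{length} too small for {n} clusters")
    out: set[str] = set()
    while len(out) < n:
        draw = rng.integers(0, 4, size=(n - len(out), length))
        out.update("".join(row) for row in _BASE_ARRAY[draw])
    codes = sorted(out)
    rng.shuffle(codes)
    return np.array(codes, dtype=object)


def make_chip(spec: SyntheticChipSpec) -> ChipMap:
    """Simulate a barcode chip: jittered-grid clusters, rare duplicated barcodes."""
    rng = np.random.default_rng(spec.seed)
    xs = np.arange(spec.pitch_px / 2, spec.width_px, spec.pitch_px)
    ys = np.arange(spec.pitch_px / 2, spec.height_px, spec.pitch_px)
    if len(xs) == 0 or len(ys) == 0:
        raise ValueError("chip too small for a single cluster at this pitch")
    gx, gy = np.meshgrid(xs, ys)
    pos = np.column_stack([gx.ravel(), gy.ravel()])
    pos = pos + rng.normal(0.0, spec.jitter_frac * spec.pitch_px, size=pos.shape)
    pos[:, 0] = np.clip(pos[:, 0], 0, spec.width_px)
    pos[:, 1] = np.clip(pos[:, 1], 0, spec.height_px)
    n = len(pos)

    barcodes = _random_barcodes(n, spec.barcode_length, rng)
    dup_mask = rng.uniform(size=n) < spec.duplication_rate
    dup_idx = np.flatnonzero(dup_mask)
    # each flagged cluster re-uses the barcode of another (unflagged) cluster,
    # so the duplicated barcode occurs at exactly two distinct coordinates
    donors_pool = np.flatnonzero(~dup_mask)
    if dup_idx.size and donors_pool.size:
        donors = rng.choice(donors_pool, size=dup_idx.size, replace=False)
        barcodes[dup_idx] = barcodes[donors]

    df = pd.DataFrame({"barcode": barcodes, "x": pos[:, 0], "y": pos[:, 1]})
    chip = ChipMap(
        df,
        pixel_pitch_um=PIXEL_PITCH_UM,
        bounds=(0.0, 0.0, float(spec.width_px), float(spec.height_px)),
        meta={
            "pitch_px": spec.pitch_px,
            "n_clusters": n,
            "n_duplicated_barcodes": int(dup_idx.size),
            "seed": spec.seed,
        },
    )
    return chip


@dataclass
class GroundTruth:
    """Per-nucleus truth emitted alongside every simulated capture table.

    ``nuclei`` has one row per simulated nucleus (and one per debris particle,
    flagged by ``is_debris``): cell_id, true position (um), cell type, niche
    label, multiplex tube and droplet id.  Under co-droplet collisions two
    nuclei sharing tube and droplet legitimately share a cell_id.
    """

    nuclei: pd.DataFrame
    pixel_pitch_um: float = PIXEL_PITCH_UM
    n_capture_events: int = 0
    meta: dict = field(default_factory=dict)

    def real_nuclei(self) -> pd.DataFrame:
        return self.nuclei[~self.nuclei["is_debris"]].reset_index(drop=True)


def _negbin(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    """NB draws parameterized by mean and dispersion (shape) r: var = m + m^2/r."""
    if mean <= 0:
        return np.zeros(size, dtype=int)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def _capture_from_point(
    tree: cKDTree,
    cluster_xy: np.ndarray,
    point_px: np.ndarray,
    sigma_px: float,
    n_umi: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Indices of captured clusters: P(cluster) ∝ exp(-d^2 / 2 sigma^2)."""
    if n_umi <= 0:
        return np.empty(0, dtype=int)
    radius = max(5.0 * sigma_px, 1e-9)
    cand = tree.query_ball_point(point_px, r=radius)
    if not cand:
        _, nearest = tree.query(point_px)
        return np.full(n_umi, nearest, dtype=int)
    cand = np.asarray(cand, dtype=int)
    d2 = np.sum((cluster_xy[cand] - point_px) ** 2, axis=1)
    w = np.exp(-d2 / (2.0 * sigma_px**2))
    total = w.sum()
    if total <= 0 or not np.isfinite(total):  # degenerate kernel: nearest wins
        return np.full(n_umi, cand[int(np.argmin(d2))], dtype=int)
    return rng.choice(cand, size=n_umi, replace=True, p=w / total)


def simulate_capture(
    chip: ChipMap, tissue: SyntheticTissueSpec
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate barcode capture of a tissue on a chip.

    Returns the aggregated (cell_id, spatial_barcode, umi_count) table and the
    matching :class:`GroundTruth`.  Nuclei are placed uniformly within their
    niche regions (area-proportional allocation); every UMI of a nucleus is an
    independent draw from nearby clusters under the Gaussian diffusion kernel.
    """
    if not len(chip):
        raise ValueError("empty chip")
    rng = np.random.default_rng(tissue.seed)
    pitch = chip.pixel_pitch_um
    x0, y0, x1, y1 = chip.bounds  # px
    chip_w_um, chip_h_um = (x1 - x0) * pitch, (y1 - y0) * pitch

    layout = tissue.niche_layout or default_niche_layout(
        chip_w_um, chip_h_um, n_niches=1, n_types=len(tissue.cell_types)
    )
    for region in layout:
        bx0, by0, bx1, by1 = region.bounds()
        if bx0 < -1e-6 or by0 < -1e-6 or bx1 > chip_w_um + 1e-6 or by1 > chip_h_um + 1e-6:
            raise ValueError(f"niche {region.label!r} extends beyond the chip")

    # allocate nuclei to niches proportionally to area
    areas = np.array([r.area() for r in layout])
    alloc = rng.multinomial(tissue.n_nuclei, areas / areas.sum())

    pos_list, type_list, niche_list = [], [], []
    for region, n_region in zip(layout, alloc):
        if n_region == 0:
            continue
        pos_list.append(region.sample_points(n_region, rng))
        type_idx = rng.choice(len(tissue.cell_types), size=n_region, p=region.mixture)
        type_list.append(np.asarray(tissue.cell_types, dtype=object)[type_idx])
        niche_list.extend([region.label] * n_region)
    pos_um = np.vstack(pos_list) if pos_list else np.empty((0, 2))
    cell_type = np.concatenate(type_list) if type_list else np.empty(0, dtype=object)
    niche = np.array(niche_list, dtype=object)
    n = len(pos_um)

    tubes = rng.integers(0, tissue.n_multiplex, size=n)
    droplets = np.arange(n)
    # droplet collisions: flagged nuclei are paired up and share a droplet id
    flagged = np.flatnonzero(rng.uniform(size=n) < tissue.co_droplet_rate)
    rng.shuffle(flagged)
    for a, b in zip(flagged[0::2], flagged[1::2]):
        droplets[b] = droplets[a]

    n_umi = np.maximum(
        _negbin(rng, tissue.umi_mean, tissue.umi_dispersion, n), tissue.min_umi
    )

    # debris: low-UMI barcode sets at uniform random positions; a debris
    # particle rides in the droplet of a random nucleus with its own tube draw
    n_debris = rng.binomial(n, tissue.debris_rate) if n else 0
    debris_pos = np.column_stack(
        [rng.uniform(0, chip_w_um, n_debris), rng.uniform(0, chip_h_um, n_debris)]
    )
    debris_host = rng.integers(0, n, size=n_debris) if n else np.empty(0, dtype=int)
    debris_tube = rng.integers(0, tissue.n_multiplex, size=n_debris)
    debris_umi = np.maximum(rng.poisson(tissue.debris_umi_mean, size=n_debris), 1)

    cluster_xy = chip.entries[["x", "y"]].to_numpy()
    barcodes = chip.entries["barcode"].to_numpy(dtype=object)
    tree = cKDTree(cluster_xy)
    sigma_px = tissue.diffusion_sigma_um / pitch

    rows_cell, rows_bc = [], []
    all_pos_px = pos_um / pitch
    for i in range(n):
        idx = _capture_from_point(tree, cluster_xy, all_pos_px[i], sigma_px,
                                  int(n_umi[i]), rng)
        rows_cell.extend([f"t{tubes[i]}-d{droplets[i]}"] * len(idx))
        rows_bc.extend(barcodes[idx])
    for j in range(n_debris):
        idx = _capture_from_point(tree, cluster_xy, debris_pos[j] / pitch, sigma_px,
                                  int(debris_umi[j]), rng)
        cid = f"t{debris_tube[j]}-d{droplets[debris_host[j]]}"
        rows_cell.extend([cid] * len(idx))
        rows_bc.extend(barcodes[idx])

    raw = pd.DataFrame(
        {"cell_id": rows_cell, "spatial_barcode": rows_bc, "umi_count": 1}
    )
    n_events = len(raw)
    counts = aggregate_counts(raw) if n_events else raw

    truth_rows = pd.DataFrame(
        {
            "nucleus_id": [f"nuc{i}" for i in range(n)],
            "cell_id": [f"t{tubes[i]}-d{droplets[i]}" for i in range(n)],
            "true_x_um": pos_um[:, 0],
            "true_y_um": pos_um[:, 1],
            "cell_type": cell_type,
            "niche": niche,
            "tube": tubes,
            "droplet": droplets,
            "is_debris": False,
        }
    )
    debris_rows = pd.DataFrame(
        {
            "nucleus_id": [f"deb{j}" for j in range(n_debris)],
            "cell_id": [
                f"t{debris_tube[j]}-d{droplets[debris_host[j]]}" for j in range(n_debris)
            ],
            "true_x_um": debris_pos[:, 0] if n_debris else np.empty(0),
            "true_y_um": debris_pos[:, 1] if n_debris else np.empty(0),
            "cell_type": "debris",
            "niche": pd.NA,
            "tube": debris_tube,
            "droplet": droplets[debris_host] if n_debris else np.empty(0, dtype=int),
            "is_debris": True,
        }
    )
    truth = GroundTruth(
        nuclei=pd.concat([truth_rows, debris_rows], ignore_index=True),
        pixel_pitch_um=pitch,
        n_capture_events=n_events,
        meta={"seed": tissue.seed, "n_nuclei": n, "n_debris": int(n_debris)},
    )
    return counts, truth


def simulate_expression(
    truth: GroundTruth,
    markers_per_type: int = 5,
    n_background_genes: int = 30,
    fold: float = 5.0,
    base_mean: float = 1.0,
    dispersion: float = 2.0,
    seed: int = 0,
) -> tuple[sparse.csr_matrix, list[str], list[str]]:
    """Cell-type-structured negative-binomial expression for truth nuclei.

    Each type gets ``markers_per_type`` marker genes whose mean is elevated by
    ``fold`` in cells of that type.  Returns (cells x genes CSR matrix, cell
    ids, gene names); debris rows are skipped.  One expression profile is
    drawn per nucleus; nuclei sharing a cell_id each contribute a row keyed by
    nucleus_id suffix.
    """
    rng = np.random.default_rng(seed)
    nuclei = truth.real_nuclei()
    types = sorted(nuclei["cell_type"].unique())
    genes = [
        f"{t}_marker{k}" for t in types for k in range(markers_per_type)
    ] + [f"bg{k}" for k in range(n_background_genes)]
    n_cells, n_genes = len(nuclei), len(genes)
    means = np.full((n_cells, n_genes), base_mean)
    for ti, t in enumerate(types):
        rows = np.flatnonzero((nuclei["cell_type"] == t).to_numpy())
        cols = slice(ti * markers_per_type, (ti + 1) * markers_per_type)
        means[np.ix_(rows, range(*cols.indices(n_genes)))] *= fold
    p = dispersion / (dispersion + means)
    counts = rng.negative_binomial(dispersion, p)
    cell_ids = nuclei["nucleus_id"].tolist()
    return sparse.csr_matrix(counts), cell_ids, genes


def simulate_clonotypes(
    truth: GroundTruth,
    route: Sequence[str],
    n_clonotypes: int = 30,
    cells_per_clonotype: int = 4,
    drift: float = 1.0,
    noise_sd: float = 0.1,
    p_ighg: float = 0.6,
    seed: int = 0,
) -> pd.DataFrame:
    """Clonotype table with pseudotime drifting along a district route.

    Clonotype members are drawn from nuclei whose niche labels lie on the
    route; each member's pseudotime is its district's route index times
    ``drift`` plus Gaussian noise, so a positive drift orients every clonotype
    along the route direction.
    """
    rng = np.random.default_rng(seed)
    nuclei = truth.real_nuclei()
    route = list(route)
    pool = {d: nuclei[nuclei["niche"] == d] for d in route}
    for d, sub in pool.items():
        if not len(sub):
            raise ValueError(f"route district {d!r} has no nuclei in truth")
    rows = []
    for c in range(n_clonotypes):
        districts = [route[rng.integers(0, len(route))] for _ in range(cells_per_clonotype)]
        # guarantee the clonotype spans at least two route districts
        if len(set(districts)) < 2 and len(route) > 1:
            districts[0], districts[1] = route[0], route[-1]
        for d in districts:
            member = pool[d].iloc[rng.integers(0, len(pool[d]))]
            rows.append(
                {
                    "cell_id": member["nucleus_id"],
                    "clonotype": f"clone{c}",
                    "district": d,
                    "pseudotime": route.index(d) * drift + rng.normal(0.0, noise_sd),
                    "isotype": "IGHG1" if rng.uniform() < p_ighg else "IGHA1",
                }
            )
    return pd.DataFrame(rows)


def simulate_cell_table(
    n_cells: int = 2000,
    n_niches: int = 5,
    niche_width_um: float = 200.0,
    height_um: float = 250.0,
    dominant_fraction: float = 0.7,
    n_samples: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Typed, localized cells in planted vertical-strip niches (um coordinates).

    A district-level fixture for the spatial statistics: ``n_niches`` strips of
    ``niche_width_um`` (TLS-scale territories, comfortably wider than the
    30 um neighborhood radius), each dominated by one of ``n_niches`` cell
    types at ``dominant_fraction`` with the remainder spread evenly.  Returns
    a cell table with cell_id, x, y, cell_type, sample and the true ``niche``
    label.
    """
    rng = np.random.default_rng(seed)
    width = n_niches * niche_width_um
    x = rng.uniform(0, width, n_cells)
    y = rng.uniform(0, height_um, n_cells)
    niche_idx = np.minimum((x / niche_width_um).astype(int), n_niches - 1)
    types = np.array([f"T{k + 1}" for k in range(n_niches)], dtype=object)
    mix = np.full((n_niches, n_niches),
                  (1 - dominant_fraction) / max(n_niches - 1, 1))
    np.fill_diagonal(mix, dominant_fraction if n_niches > 1 else 1.0)
    labels = np.array(
        [types[rng.choice(n_niches, p=mix[k])] for k in niche_idx], dtype=object
    )
    return pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n_cells)],
            "x": x,
            "y": y,
            "cell_type": labels,
            "sample": [f"s{rng.integers(0, n_samples)}" for _ in range(n_cells)],
            "niche": [f"N{k + 1}" for k in niche_idx],
        }
    )


def write_expression_mtx(matrix: sparse.spmatrix, cell_ids: Sequence[str],
                         genes: Sequence[str], outdir) -> None:
    """Write an MTX + sidecar gene/cell label files (genes x cells orientation)."""
    from pathlib import Path
    from scipy.io import mmwrite

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mmwrite(str(outdir / "matrix.mtx"), sparse.csr_matrix(matrix).T)
    (outdir / "genes.tsv").write_text("\n".join(genes) + "\n")
    (outdir / "cells.tsv").write_text("\n".join(cell_ids) + "\n")
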