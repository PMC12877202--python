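import numpy as np
import pandas as pd
import pytest

from stampseq import chip_io, synthdata


@pytest.fixture(scope="session")
def small_chip():
    """A 300x300 px chip (~80x80 um), ~2300 clusters."""
    return synthdata.make_chip(
        synthdata.SyntheticChipSpec(width_px=300, height_px=300, seed=11)
    )


@pytest.fixture(scope="session")
def medium_chip():
    """A 1000x1000 px chip (265x265 um) for localization-scale tests."""
    return synthdata.make_chip(
        synthdata.SyntheticChipSpec(width_px=1000, height_px=1000, seed=12)
    )


@pytest.fixture(scope="session")
def clean_tissue_positioned(medium_chip):
    """Positioned counts for 200 clean nuclei (no debris, no collisions)."""
    tissue = synthdata.SyntheticTissueSpec(
        n_nuclei=200, seed=13, debris_rate=0.0, co_droplet_rate=0.0
    )
    counts, truth = synthdata.simulate_capture(medium_chip, tissue)
    chip_clean, _ = chip_io.dedup_chip_barcodes(medium_chip)
    positioned, _ = chip_io.attach_coordinates(counts, chip_clean)
    return positioned, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def planted_cells():
    """2000 cells in five planted 200-um strip niches."""
    return synthdata.simulate_cell_table(n_cells=2000, n_niches=5, seed=5)


def make_positioned(rows):
    """Helper: positioned counts frame from (cell_id, barcode, x, y, umi) tuples."""
    return pd.DataFrame(
        rows, columns=["cell_id", "spatial_barcode", "x", "y", "umi_count"]
    )
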