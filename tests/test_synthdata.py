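"""Simulator contracts: determinism, conservation, and the stated capture physics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stampseq import chip_io, synthdata
from stampseq.synthdata import (
    NicheRegion,
    SyntheticChipSpec,
    SyntheticTissueSpec,
    make_chip,
    simulate_capture,
    simulate_cell_table,
    simulate_clonotypes,
    simulate_expression,
)


class TestMakeChip:
    def test_zero_duplication_rate_gives_unique_barcodes(self):
        chip = make_chip(SyntheticChipSpec(width_px=200, height_px=200,
                                           duplication_rate=0.0, seed=1))
        assert chip.entries["barcode"].is_unique

    def test_deterministic_under_seed(self):
        spec = SyntheticChipSpec(width_px=200, height_px=200, seed=7)
        a, b = make_chip(spec), make_chip(spec)
        pd.testing.assert_frame_equal(a.entries, b.entries)

    def test_duplicated_count_matches_binomial_rate(self):
        # ~10,000 clusters at rate 0.01: expect 100 +- 3*sqrt(100*0.99)
        spec = SyntheticChipSpec(width_px=620, height_px=620, pitch_px=6.2,
                                 duplication_rate=0.01, seed=3)
        chip = make_chip(spec)
        n = len(chip)
        counts = chip.entries["barcode"].value_counts()
        n_dup = int((counts > 1).sum())
        expect = n * 0.01
        sd = np.sqrt(n * 0.01 * 0.99)
        assert abs(n_dup - expect) <= 3 * sd

    def test_barcode_space_too_small_raises(self):
        with pytest.raises(ValueError, match="barcode space"):
            make_chip(SyntheticChipSpec(width_px=300, height_px=300,
                                        barcode_length=3, seed=0))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SyntheticChipSpec(pitch_px=-1.0)
        with pytest.raises(ValueError):
            SyntheticChipSpec(duplication_rate=1.0)


class TestSimulateCapture:
    def test_empty_chip_rejected(self):
        empty = chip_io.ChipMap(pd.DataFrame(columns=["barcode", "x", "y"]),
                                bounds=(0, 0, 100, 100))
        with pytest.raises(ValueError, match="empty chip"):
            simulate_capture(empty, SyntheticTissueSpec(n_nuclei=5, seed=0))

    def test_degenerate_kernel_hits_nearest_cluster(self, small_chip):
        tissue = SyntheticTissueSpec(n_nuclei=1, diffusion_sigma_um=1e-9,
                                     debris_rate=0.0, seed=4)
        counts, truth = simulate_capture(small_chip, tissue)
        nuc = truth.real_nuclei().iloc[0]
        p_px = np.array([nuc.true_x_um, nuc.true_y_um]) / small_chip.pixel_pitch_um
        xy = small_chip.entries[["x", "y"]].to_numpy()
        nearest = small_chip.entries["barcode"].iloc[
            np.argmin(((xy - p_px) ** 2).sum(axis=1))
        ]
        assert set(counts["spatial_barcode"]) == {nearest}

    def test_no_collisions_gives_one_nucleus_per_cell_id(self, small_chip):
        tissue = SyntheticTissueSpec(n_nuclei=60, co_droplet_rate=0.0,
                                     debris_rate=0.0, n_multiplex=8, seed=5)
        counts, truth = simulate_capture(small_chip, tissue)
        real = truth.real_nuclei()
        assert real["cell_id"].is_unique
        assert set(counts["cell_id"]) <= set(real["cell_id"])

    def test_umi_conservation(self, small_chip):
        tissue = SyntheticTissueSpec(n_nuclei=40, seed=6)
        counts, truth = simulate_capture(small_chip, tissue)
        assert int(counts["umi_count"].sum()) == truth.n_capture_events

    def test_deterministic_under_seed(self, small_chip):
        tissue = SyntheticTissueSpec(n_nuclei=30, seed=9)
        c1, t1 = simulate_capture(small_chip, tissue)
        c2, t2 = simulate_capture(small_chip, tissue)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(t1.nuclei, t2.nuclei)

    def test_capture_distance_follows_rayleigh_law(self, medium_chip):
        """Pooled barcode-to-nucleus distances match Rayleigh(sigma): KS p > 0.01."""
        sigma = 2.0
        tissue = SyntheticTissueSpec(n_nuclei=250, diffusion_sigma_um=sigma,
                                     umi_mean=60.0, min_umi=40,
                                     debris_rate=0.0, co_droplet_rate=0.0, seed=7)
        counts, truth = simulate_capture(medium_chip, tissue)
        chip_clean, _ = chip_io.dedup_chip_barcodes(medium_chip)
        positioned, _ = chip_io.attach_coordinates(counts, chip_clean)
        real = truth.real_nuclei().set_index("cell_id")
        m = positioned.merge(real[["true_x_um", "true_y_um"]],
                             left_on="cell_id", right_index=True)
        pitch = medium_chip.pixel_pitch_um
        d = np.hypot(m["x"] * pitch - m["true_x_um"], m["y"] * pitch - m["true_y_um"])
        d = np.repeat(d.to_numpy(), m["umi_count"].to_numpy())
        assert len(d) >= 10_000
        # mean within 3 SE of the Rayleigh mean sigma*sqrt(pi/2)
        ray_mean = sigma * np.sqrt(np.pi / 2)
        ray_sd = sigma * np.sqrt(2 - np.pi / 2)
        assert abs(d.mean() - ray_mean) <= 3 * ray_sd / np.sqrt(len(d))
        ks = stats.kstest(d, stats.rayleigh(scale=sigma).cdf)
        assert ks.pvalue > 0.01

    def test_niche_outside_chip_rejected(self, small_chip):
        bad = NicheRegion("far", "rect", (0, 0, 10_000, 10_000), (1.0,))
        tissue = SyntheticTissueSpec(n_nuclei=5, cell_types=("A",),
                                     niche_layout=(bad,), seed=0)
        with pytest.raises(ValueError, match="beyond the chip"):
            simulate_capture(small_chip, tissue)

    def test_mixture_validation(self):
        bad = NicheRegion("n", "rect", (0, 0, 10, 10), (0.5, 0.3))
        with pytest.raises(ValueError, match="sum to 1"):
            SyntheticTissueSpec(cell_types=("A", "B"), niche_layout=(bad,))


class TestSimulateExpression:
    def test_fold_one_gives_no_marker_structure(self, small_chip):
        _, truth = simulate_capture(small_chip,
                                    SyntheticTissueSpec(n_nuclei=80, seed=8))
        mat, cells, genes = simulate_expression(truth, fold=1.0, seed=1)
        dense = np.asarray(mat.todense(), dtype=float)
        marker_cols = [i for i, g in enumerate(genes) if "marker" in g]
        bg_cols = [i for i, g in enumerate(genes) if g.startswith("bg")]
        ratio = dense[:, marker_cols].mean() / dense[:, bg_cols].mean()
        assert 0.85 < ratio < 1.15

    def test_marker_mean_ratio_matches_fold(self, small_chip):
        _, truth = simulate_capture(small_chip,
                                    SyntheticTissueSpec(n_nuclei=150, seed=8))
        fold = 5.0
        mat, cells, genes = simulate_expression(truth, fold=fold,
                                                markers_per_type=10, seed=2)
        dense = np.asarray(mat.todense(), dtype=float)
        types = truth.real_nuclei()["cell_type"].to_numpy()
        for t in np.unique(types):
            own = [i for i, g in enumerate(genes) if g.startswith(f"{t}_marker")]
            in_type = dense[types == t][:, own].mean()
            out_type = dense[types != t][:, own].mean()
            assert in_type / out_type == pytest.approx(fold, rel=0.25)

    def test_deterministic(self, small_chip):
        _, truth = simulate_capture(small_chip,
                                    SyntheticTissueSpec(n_nuclei=30, seed=8))
        m1, *_ = simulate_expression(truth, seed=3)
        m2, *_ = simulate_expression(truth, seed=3)
        assert (m1 != m2).nnz == 0


@pytest.fixture(scope="module")
def routed_truth(small_chip):
    layout = synthdata.default_niche_layout(79, 79, n_niches=3, n_types=3)
    tissue = SyntheticTissueSpec(n_nuclei=120, niche_layout=layout, seed=10)
    _, truth = simulate_capture(small_chip, tissue)
    return truth


class TestSimulateClonotypes:
    def test_deterministic(self, routed_truth):
        a = simulate_clonotypes(routed_truth, ["N1", "N2", "N3"], seed=1)
        b = simulate_clonotypes(routed_truth, ["N1", "N2", "N3"], seed=1)
        pd.testing.assert_frame_equal(a, b)

    def test_large_drift_orients_along_route(self, routed_truth):
        from stampseq.migration import infer_movements

        table = simulate_clonotypes(routed_truth, ["N1", "N2", "N3"],
                                    drift=5.0, noise_sd=0.01, seed=2)
        graph = infer_movements(table)
        forward = sum(
            c for (a, b), c in graph.counts.items()
            if ["N1", "N2", "N3"].index(a) < ["N1", "N2", "N3"].index(b)
        )
        assert forward / graph.total > 0.95

    def test_zero_drift_roughly_symmetric(self, routed_truth):
        from stampseq.migration import infer_movements

        table = simulate_clonotypes(routed_truth, ["N1", "N2", "N3"],
                                    n_clonotypes=150, drift=0.0, noise_sd=1.0,
                                    seed=3)
        graph = infer_movements(table)
        forward = sum(
            c for (a, b), c in graph.counts.items()
            if ["N1", "N2", "N3"].index(a) < ["N1", "N2", "N3"].index(b)
        )
        frac = forward / graph.total
        # binomial fluctuation around 1/2
        assert abs(frac - 0.5) <= 3 * 0.5 / np.sqrt(graph.total)


class TestSimulateCellTable:
    def test_niche_structure_and_determinism(self):
        a = simulate_cell_table(n_cells=500, n_niches=3, seed=4)
        b = simulate_cell_table(n_cells=500, n_niches=3, seed=4)
        pd.testing.assert_frame_equal(a, b)
        assert set(a["niche"]) == {"N1", "N2", "N3"}
        # dominant type matches the planted niche in most cells
        hit = (a["cell_type"] == "T" + a["niche"].str[1:]).mean()
        assert hit > 0.6
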