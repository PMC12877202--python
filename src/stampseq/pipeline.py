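"""End-to-end pipeline orchestration (simulate -> attach -> filter -> localize).

Each stage writes its outputs plus a JSON report into the output directory;
the resolved configuration is echoed to ``run_config.yaml``.  A stage failure
raises with the stage name so callers (and the CLI) can report it.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import barcode_filter, chip_io, evaluate, localize, synthdata
from .config import PipelineConfig

log = logging.getLogger("stampseq")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, default=float))


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    chip_spec: synthdata.SyntheticChipSpec | None = None,
    tissue_spec: synthdata.SyntheticTissueSpec | None = None,
    chip: chip_io.ChipMap | None = None,
    counts: pd.DataFrame | None = None,
) -> Path:
    """Run simulate -> attach -> filter -> localize (-> evaluate when truth known).

    Inputs may come from the simulator (specs) or be supplied directly
    (``chip`` + ``counts``).  Returns the output directory.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "run_config.yaml")
    truth = None

    stage = "simulate"
    try:
        if chip is None:
            chip_spec = chip_spec or synthdata.SyntheticChipSpec(seed=config.seed)
            chip = synthdata.make_chip(chip_spec)
        if counts is None:
            tissue_spec = tissue_spec or synthdata.SyntheticTissueSpec(seed=config.seed)
            counts, truth = synthdata.simulate_capture(chip, tissue_spec)
            truth.nuclei.to_csv(outdir / "truth.csv", index=False)
        chip_io.write_chip_map(chip, outdir / "chip_map.tsv")
        chip_io.write_counts(counts, outdir / "counts.tsv")
        log.info("simulate: %d chip clusters, %d count rows", len(chip), len(counts))
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError(stage, exc) from exc

    stage = "attach"
    try:
        chip_clean, n_dup = chip_io.dedup_chip_barcodes(chip)
        corrected, n_uncorrectable = chip_io.correct_counts(counts, chip_clean)
        positioned, n_invalid = chip_io.attach_coordinates(corrected, chip_clean)
        _write_json(outdir / "attach_report.json", {
            "duplicated_chip_barcodes_removed": n_dup,
            "uncorrectable_rows_dropped": n_uncorrectable,
            "invalid_rows_dropped": n_invalid,
            "rows_positioned": len(positioned),
        })
        log.info("attach: %d positioned rows (%d invalid dropped)",
                 len(positioned), n_invalid)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    stage = "filter"
    try:
        filtered, report = barcode_filter.filter_prevalent_barcodes(
            positioned, bin_px=config.filter_bin_px, k=config.filter_k,
            max_iter=config.filter_max_iter, single_pass=config.filter_single_pass,
        )
        _write_json(outdir / "filter_report.json", report.to_dict())
        chip_io.write_counts(
            filtered.drop(columns=[c for c in ("x", "y") if c in filtered]),
            outdir / "counts_filtered.tsv",
        )
        log.info("filter: removed %d cells in %d iterations",
                 len(report.cells_removed), report.iterations)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    stage = "localize"
    try:
        loc_config = localize.LocalizeConfig(
            bin_px=config.localize_bin_px,
            unique_ratio=config.unique_ratio,
            major_ratio=config.major_ratio,
            pixel_pitch_um=config.pixel_pitch_um,
        )
        table, summary = localize.localize_all(filtered, loc_config)
        table.to_csv(outdir / "localized.csv", index=False)
        _write_json(outdir / "localize_report.json", summary)
        log.info("localize: %s", summary)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    if truth is not None:
        stage = "evaluate"
        try:
            localized = table[table["class"].isin(["unique", "major"])]
            real = truth.real_nuclei().drop_duplicates("cell_id", keep=False)
            pred = localized.merge(real[["cell_id"]], on="cell_id")
            if len(pred) and len(real):
                match = evaluate.match_nearest(pred, real)
                offsets = match.offsets
                payload = {
                    "n_matched": len(offsets),
                    "mean_offset_um": float(offsets.mean()),
                    "median_offset_um": float(pd.Series(offsets).median()),
                }
            else:
                payload = {"n_matched": 0}
            _write_json(outdir / "evaluate_report.json", payload)
            log.info("evaluate: %s", payload)
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    return outdir
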