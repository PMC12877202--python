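"""Pipeline configuration: every stage parameter with its standard default.

The defaults pin the constants used throughout the method: 30 px filter bins
with a 20x threshold, 100 px localization bins with unique/major ratio cuts of
10 and 2, 30 um neighborhood and colocalization radii, a 100 um
ligand-receptor radius, 100/1000 permutations, embedding hyperparameters
(lr 0.001, 150 epochs, tau 0.3, lam 0.3, dropout 0.25) and the 0.265 um/px
chip pixel pitch.  A config round-trips through YAML unchanged and every run
writes the resolved config beside its outputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .chip_io import PIXEL_PITCH_UM


@dataclass
class PipelineConfig:
    # chip / units
    pixel_pitch_um: float = PIXEL_PITCH_UM
    # prevalent-barcode filter
    filter_bin_px: int = 30
    filter_k: float = 20.0
    filter_max_iter: int = 100
    filter_single_pass: bool = False
    # localization
    localize_bin_px: int = 100
    unique_ratio: float = 10.0
    major_ratio: float = 2.0
    # spatial statistics
    neighborhood_radius_um: float = 30.0
    pccf_radius_um: float = 30.0
    pccf_n_perm: int = 100
    # districting
    embed_hidden_dim: int = 64
    embed_out_dim: int = 32
    embed_n_layers: int = 2
    embed_learning_rate: float = 0.001
    embed_epochs: int = 150
    embed_tau: float = 0.3
    embed_lam: float = 0.3
    embed_dropout_p: float = 0.25
    embed_n_negatives: int = 5
    leiden_resolution: float = 0.1
    # ligand-receptor screen
    ligrec_radius_um: float = 100.0
    ligrec_n_perm: int = 1000
    ligrec_significance: float = 0.005
    # global
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def self_test(self) -> None:
        """Assert the fixed method constants have not drifted."""
        expect = {
            "filter_bin_px": 30, "filter_k": 20.0, "localize_bin_px": 100,
            "unique_ratio": 10.0, "major_ratio": 2.0,
            "neighborhood_radius_um": 30.0, "pccf_radius_um": 30.0,
            "pccf_n_perm": 100, "ligrec_radius_um": 100.0,
            "ligrec_n_perm": 1000, "embed_learning_rate": 0.001,
            "embed_epochs": 150, "embed_tau": 0.3, "embed_lam": 0.3,
            "embed_dropout_p": 0.25, "pixel_pitch_um": PIXEL_PITCH_UM,
        }
        cfg = type(self)()  # defaults, not this instance's overrides
        for key, value in expect.items():
            actual = getattr(cfg, key)
            if actual != value:
                raise AssertionError(f"default {key} = {actual}, expected {value}")
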