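"""Serializable pipeline configuration.

Every tunable in the pipeline lives here with its default, and a config
round-trips losslessly through YAML, so any run is reproducible from its
config file plus the master seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

#: default folder-name -> class-code mapping (matches the public 4-class set)
DEFAULT_LABELS = {
    "NonDemented": 0, "VeryMildDemented": 1,
    "MildDemented": 2, "ModerateDemented": 3,
}


@dataclass
class PipelineConfig:
    # preprocessing
    bit_depth: int = 8
    stretch: bool = True
    mask_mode: str = "tissue"        # "tissue" (> Th1) or "zero" (> 0)
    closing_size: int = 3
    # histogram smoothing
    passband: float = 0.005
    atten_db: float = 60.0
    transition: float = 0.15
    # threshold selection
    noise_floor: float = 1e-3
    th1_rule: str = "second_minimum"
    normalize_heights: bool = False
    # ranking
    mrmr_bins: int = 16
    chi2_bins: int = 10
    # evaluation
    classifier: str = "svm"
    n_repeats: int = 10
    eval_mode: str = "repeated_split"
    # reproducibility
    seed: int = 0
    label_table: dict = field(default_factory=lambda: dict(DEFAULT_LABELS))

    def extractor_params(self) -> dict:
        return dict(bit_depth=self.bit_depth, stretch=self.stretch,
                    passband=self.passband, atten_db=self.atten_db,
                    transition=self.transition, noise_floor=self.noise_floor,
                    th1_rule=self.th1_rule,
                    normalize_heights=self.normalize_heights,
                    mask_mode=self.mask_mode, closing_size=self.closing_size)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
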