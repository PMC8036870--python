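"""Pipeline configuration.

All tunable parameters of the processing chain live here with their default
values. A YAML/JSON file can override any subset; CLI flags override the file.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

#: ITU-R BT.601 luma weights used for RGB -> grayscale conversion.
GRAYSCALE_WEIGHTS = (0.299, 0.587, 0.114)

#: Candidate grids for the motion-detector parameter optimization. The thr2
#: grid is kept verbatim from the published list, including the outlying 0.09
#: entry (likely intended as 0.009); both grids are configurable.
DEFAULT_GRID_F1 = (4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0, 11.0, 12.0)
DEFAULT_GRID_THR2 = (0.004, 0.005, 0.006, 0.007, 0.008, 0.09, 0.010, 0.011, 0.012)


@dataclass
class PipelineConfig:
    """Every parameter actually used by the pipeline, with published defaults."""

    # preprocessing
    rate_hz: float = 9.0
    window_s: float = 8.0
    slide_s: float = 1.0
    downscale_factor: int = 3
    grayscale_weights: tuple[float, float, float] = GRAYSCALE_WEIGHTS

    # gross-motion detector
    f1: float = 8.0
    thr2: float = 0.005
    grid_f1: Sequence[float] = DEFAULT_GRID_F1
    grid_thr2: Sequence[float] = DEFAULT_GRID_THR2

    # respiration-rate estimation
    kappa1: float = 70.0
    kappa2: float = 16.0
    kappa3: float = 0.9
    lim1_hz: float = 0.5
    lim2_hz: float = 1.83
    pad_factor: int = 120
    bandpass_order: int = 4
    # If True the final spectral-peak search is restricted to [lim1, lim2];
    # by default the bandpass filter alone confines the peak, which also lets
    # strongly attenuated out-of-band fundamentals survive.
    band_limited_peak: bool = False

    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grayscale_weights"] = list(self.grayscale_weights)
        d["grid_f1"] = list(self.grid_f1)
        d["grid_thr2"] = list(self.grid_thr2)
        return d

    def dump(self, path: str | Path) -> None:
        """Write the effective configuration next to the outputs (provenance)."""
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        for key in ("grayscale_weights", "grid_f1", "grid_thr2"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})
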