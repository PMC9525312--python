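"""Pipeline configuration: every analysis threshold with its default.

Defaults are the acquisition/analysis constants of the septal SMT
protocol: 300 nm linking radius, 8-frame gap closing, 60-300 nm sigma
band-pass, 0.75 z rescale, R <= 0.4 and P >= 0.5 classification, 200x
bootstrap. Configs round-trip losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .simcell import AstigmatismModel, SimParams


@dataclass
class PipelineConfig:
    # linking
    max_disp: float = 300.0          # nm per frame transition
    max_gap: int = 8                 # frames
    # localization filtering / 3D
    band_lo: float = 60.0            # nm
    band_hi: float = 300.0           # nm
    rescale_factor: float = 0.75
    # septal selection / geometry
    axial_window: float = 200.0      # nm
    geometry_mode: str = "config"    # "config" (simulation truth) or "fit"
    # segmentation / classification
    min_segment_len: int = 6         # points ("> 5 frames")
    r_max: float = 0.4
    p_min: float = 0.5
    # population fitting
    bootstrap_B: int = 200
    n_components: str | int = "auto"
    stationary_bin_width: float = 2.0   # nm/s
    # ring statistics
    acf_bins: int = 72
    # simulation
    n_cells: int = 50
    sim: SimParams = field(default_factory=SimParams)
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.get("sim")
        if isinstance(sim, dict):
            sim = dict(sim)
            psf = sim.get("psf")
            if isinstance(psf, dict):
                sim["psf"] = AstigmatismModel(**psf)
            for key in ("population_fractions", "slow_speed_logparams",
                        "fast_speed_logparams"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(sim[key])
            d["sim"] = SimParams(**sim)
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
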