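"""Run configuration: one structured YAML file drives the whole pipeline.

Every physical quantity is in the package's internal units (kcal/mol, A, ps,
K); force constants may be declared in kJ/mol/nm^2 via the ``*_units`` keys
and are converted on load.  Configs round-trip unchanged through
``to_dict``/``from_dict``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import yaml

from .constants import DEFAULT_TEMPERATURE
from .geometry import convert_force_constant

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class ModelConfig:
    gaussians: List[List[float]] = field(
        default_factory=lambda: [[-6.0, 0.0, 1.2], [-4.0, -3.5, 1.0], [-4.0, 3.5, 1.0]]
    )
    radial_k: float = 1.0


@dataclass
class WindowConfig:
    z_start: float = 0.0
    z_stop: float = 25.0
    spacing: float = 1.0
    k_z: float = 500.0 / 418.4
    k_z_units: str = "kcal/mol/A^2"


@dataclass
class RestraintConfig:
    r_cyl: float = 2.5
    k_fb: float = 5000.0 / 418.4
    k_fb_units: str = "kcal/mol/A^2"


@dataclass
class SamplingConfig:
    diffusion: float = 1.0
    dt: float = 0.01
    n_steps: int = 200_000
    sample_every: int = 1
    equil_discard: float = 100.0
    n_blocks: int = 3


@dataclass
class AnalysisConfig:
    bin_width: float = 0.1
    reference_region: Optional[List[float]] = None
    water_cutoff: float = 3.4
    host_cutoff: float = 4.0
    cavity_cutoff: float = 3.0
    site_bounds: Optional[List[float]] = None
    signed_bins: bool = True
    hydration_bin_width: float = 1.0


@dataclass
class SolventConfig:
    bulk_count_mean: float = 6.0
    replacement_halfwidth: float = 1.0
    k_wet: float = 0.35
    k_dry: float = 0.05
    cavity_radius: float = 3.0
    shell_cutoff: float = 3.4
    frame_stride: int = 50


@dataclass
class HostConfig:
    ring_radius: float = 3.0
    n_ring: int = 12


@dataclass
class OutputConfig:
    write_windows: bool = True
    write_xyz: bool = False


@dataclass
class RunConfig:
    seed: int = 2026
    temperature: float = DEFAULT_TEMPERATURE
    model: ModelConfig = field(default_factory=ModelConfig)
    windows: WindowConfig = field(default_factory=WindowConfig)
    restraint: RestraintConfig = field(default_factory=RestraintConfig)
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    solvent: SolventConfig = field(default_factory=SolventConfig)
    host: HostConfig = field(default_factory=HostConfig)
    output: OutputConfig = field(default_factory=OutputConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        kwargs = dict(data)
        for key, sub in (
            ("model", ModelConfig),
            ("windows", WindowConfig),
            ("restraint", RestraintConfig),
            ("sampling", SamplingConfig),
            ("analysis", AnalysisConfig),
            ("solvent", SolventConfig),
            ("host", HostConfig),
            ("output", OutputConfig),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        return cls(**kwargs)

    def k_z_internal(self) -> float:
        """Umbrella force constant in kcal/mol/A^2 regardless of declared units."""
        return convert_force_constant(self.windows.k_z, self.windows.k_z_units, "kcal/mol/A^2")

    def k_fb_internal(self) -> float:
        return convert_force_constant(
            self.restraint.k_fb, self.restraint.k_fb_units, "kcal/mol/A^2"
        )

    def digest(self) -> str:
        """Stable hash of the full configuration, for provenance records."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.from_dict(data)


def save_config(path, config: RunConfig) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
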