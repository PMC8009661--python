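"""Imaging and pipeline configuration.

Physical and acquisition constants shared by all stages: TIRF pixel size,
frame interval, substrate elasticity, PSF width, detection and segmentation
thresholds.  Values default to the reference acquisition setup (80 nm pixels,
5 kPa silicone substrate, diffraction-limited PSF of 2.1 px ~ 180 nm).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = ["ImagingConfig", "PipelineConfig", "load_config", "save_config"]


@dataclass
class ImagingConfig:
    """Physical/acquisition constants.

    Attributes
    ----------
    pixel_size_um : float
        Effective pixel size in the object plane (µm).
    frame_interval_s : float
        Time between consecutive frames (s).
    youngs_modulus_pa : float
        Young's modulus of the elastic substrate (Pa).
    poisson_ratio : float
        Poisson ratio of the substrate; 0.5 for incompressible silicone.
    psf_sigma_px : float
        Standard deviation of the isotropic Gaussian PSF model (px).
    gof_alpha : float
        Significance level for the point-source amplitude test.
    fc_min_area_um2 : float
        Minimum segmented area considered a focal contact/adhesion (µm²).
    fc_min_length_um : float
        Minimum major-axis length of a focal contact (µm).
    fa_min_length_um : float
        Major-axis length above which a segment counts as a focal adhesion (µm).
    traction_floor_pa : float
        Noise floor of the traction reconstruction (Pa); tractions below it
        are considered insignificant.
    bead_density_per_um2 : float
        Fiducial bead density on the substrate (beads/µm²).
    """

    pixel_size_um: float = 0.08
    frame_interval_s: float = 2.0
    youngs_modulus_pa: float = 5000.0
    poisson_ratio: float = 0.5
    psf_sigma_px: float = 2.1
    gof_alpha: float = 0.05
    fc_min_area_um2: float = 0.2
    fc_min_length_um: float = 0.5
    fa_min_length_um: float = 2.0
    traction_floor_pa: float = 20.0
    bead_density_per_um2: float = 1.54
    bead_min_spacing_um: float = 0.05

    _RANGES = {
        "pixel_size_um": (0.0, 10.0),
        "frame_interval_s": (0.0, 3600.0),
        "youngs_modulus_pa": (0.0, 1e9),
        "poisson_ratio": (-1.0, 0.5),
        "psf_sigma_px": (0.0, 50.0),
        "gof_alpha": (0.0, 1.0),
        "fc_min_area_um2": (0.0, 1e4),
        "fc_min_length_um": (0.0, 1e3),
        "fa_min_length_um": (0.0, 1e3),
        "traction_floor_pa": (0.0, 1e6),
        "bead_density_per_um2": (0.0, 1e3),
        "bead_min_spacing_um": (0.0, 1e3),
    }

    def __post_init__(self) -> None:
        for name, (lo, hi) in self._RANGES.items():
            v = getattr(self, name)
            if not (lo <= v <= hi) or v != v:
                raise ValueError(f"{name}={v!r} outside valid range [{lo}, {hi}]")
        for name in ("pixel_size_um", "frame_interval_s", "youngs_modulus_pa",
                     "psf_sigma_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def um_per_min_per_px_per_frame(self) -> float:
        """Conversion factor px/frame -> µm/min."""
        return self.pixel_size_um * 60.0 / self.frame_interval_s


@dataclass
class PipelineConfig:
    """Full pipeline configuration: imaging constants plus per-stage blocks."""

    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)
    seed: int = 0

    def stage(self, name: str) -> dict[str, Any]:
        return dict(self.stages.get(name, {}))

    def to_dict(self) -> dict[str, Any]:
        return {
            "imaging": dataclasses.asdict(self.imaging),
            "stages": self.stages,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        imaging = ImagingConfig(**d.get("imaging", {}))
        return cls(imaging=imaging, stages=dict(d.get("stages", {})),
                   seed=int(d.get("seed", 0)))


def load_config(path: str | Path) -> PipelineConfig:
    """Read a pipeline configuration from YAML."""
    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(config: PipelineConfig, path: str | Path) -> None:
    """Write a pipeline configuration to YAML (round-trips losslessly)."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
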