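"""Acquisition descriptor: every physical constant of the motion encoding.

Defaults mirror a breath-hold renal MRE protocol at 3 T: 50 Hz excitation,
2.5 mm isotropic voxels, 8 slices, four wave phases per direction, and a
fractional bipolar motion-encoding gradient of 35 mT/m and 6.1 ms.  The
default in-plane matrix (64 x 54) is half the acquired matrix so that the
full pipeline runs in seconds; the acquired size (128 x 108) is supported
via configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .physics import GAMMA_1H, RHO_TISSUE, encoding_efficiency


@dataclass(frozen=True)
class AcquisitionDescriptor:
    f_excitation: float = 50.0  # Hz
    voxel_size: tuple[float, float, float] = (2.5, 2.5, 2.5)  # mm
    grid_shape: tuple[int, int, int] = (64, 54, 8)
    n_wave_phases: int = 4
    meg_amplitude: float = 35.0  # mT/m
    meg_duration: float = 6.1  # ms
    meg_shape: str = "bipolar_rect"
    gamma: float = GAMMA_1H  # rad / (s T)
    rho: float = RHO_TISSUE  # kg / m^3

    def __post_init__(self):
        if self.f_excitation <= 0:
            raise ValueError("f_excitation must be positive")
        if self.n_wave_phases < 4:
            raise ValueError("need at least 4 wave phases per period")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if any(n < 1 for n in self.grid_shape):
            raise ValueError("grid shape must be positive")
        if self.rho <= 0:
            raise ValueError("density must be positive")
        if self.meg_duration <= 0:
            raise ValueError("MEG duration must be positive")

    @property
    def omega(self) -> float:
        return 2.0 * np.pi * self.f_excitation

    @property
    def period(self) -> float:
        """Vibration period in seconds."""
        return 1.0 / self.f_excitation

    def encoding_efficiency(self, harmonic: int = 1, method: str = "closed",
                            n_quad: int = 256) -> complex:
        """Encoding efficiency xi (rad/um) at ``harmonic * f_excitation``."""
        return encoding_efficiency(
            harmonic * self.f_excitation,
            self.meg_amplitude,
            self.meg_duration,
            shape=self.meg_shape,
            gamma=self.gamma,
            method=method,
            n_quad=n_quad,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["voxel_size"] = list(self.voxel_size)
        d["grid_shape"] = list(self.grid_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionDescriptor":
        d = dict(d)
        d["voxel_size"] = tuple(d.get("voxel_size", (2.5, 2.5, 2.5)))
        d["grid_shape"] = tuple(d.get("grid_shape", (64, 54, 8)))
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        return cls(**{k: v for k, v in d.items() if k in known})

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "AcquisitionDescriptor":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
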