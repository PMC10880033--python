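"""In-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Compartment label legend used throughout the package.
LABELS = {"background": 0, "cortex": 1, "medulla": 2, "sinus": 3, "vessel": 4}
LABEL_NAMES = {v: k for k, v in LABELS.items()}

#: MEG direction ordering in a PhaseStack ("ref" is the no-MEG acquisition).
MEG_DIRECTIONS = ("x", "y", "z", "ref")


@dataclass
class LabelMap:
    """Integer compartment labels on the acquisition grid."""

    data: np.ndarray
    legend: dict = field(default_factory=lambda: dict(LABELS))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("label map must be 3D")

    @property
    def shape(self):
        return self.data.shape

    def mask(self, name: str) -> np.ndarray:
        """Boolean mask of one compartment; 'kidney' is the union of all."""
        if name == "kidney":
            return self.data > 0
        return self.data == self.legend[name]

    def counts(self) -> dict:
        out = {}
        for name, lab in self.legend.items():
            if name == "background":
                continue
            out[name] = int(np.count_nonzero(self.data == lab))
        out["kidney"] = int(np.count_nonzero(self.data > 0))
        return out


def mechanical_groups(labels: "LabelMap") -> np.ndarray:
    """Group compartments into mechanically similar unwrap regions.

    Renal parenchyma (cortex + medulla) and the sinus complex (sinus +
    vessels) each share near-identical wavenumbers, so the motion-encoded
    phase is continuous within a group; the large phase jump sits at the
    parenchyma/sinus interface, which separates the groups.  Used to keep
    wrap errors from propagating across that interface while giving the
    unwrapping the largest possible statistical context.
    """
    data = labels.data
    legend = labels.legend
    out = np.zeros(data.shape, dtype=np.int16)
    out[np.isin(data, (legend["cortex"], legend["medulla"]))] = 1
    out[np.isin(data, (legend["sinus"], legend["vessel"]))] = 2
    return out


@dataclass
class ComplexWaveField:
    """Per-voxel complex displacement (um) at f (U1) and 2f (U2).

    Components are stored as (3, nx, ny, nz) complex arrays; the physical
    displacement is ``u(t) = Re[U1 exp(-i omega t)] + Re[U2 exp(-2 i omega t)]``.
    """

    U1: np.ndarray
    U2: np.ndarray
    voxel_size: tuple[float, float, float]  # mm

    def __post_init__(self):
        self.U1 = np.asarray(self.U1, dtype=complex)
        self.U2 = np.asarray(self.U2, dtype=complex)
        if self.U1.shape != self.U2.shape or self.U1.ndim != 4 or self.U1.shape[0] != 3:
            raise ValueError("expected complex fields of shape (3, nx, ny, nz)")

    @property
    def grid_shape(self):
        return self.U1.shape[1:]

    def total_amplitude(self) -> np.ndarray:
        """Per-voxel displacement magnitude sqrt(sum_d |U1_d|^2), um."""
        return np.sqrt(np.sum(np.abs(self.U1) ** 2, axis=0))


@dataclass
class PhaseStack:
    """Wrapped motion-encoded phase volumes, rad in (-pi, pi].

    ``phase[d, n]`` is the wrapped phase for MEG direction ``d`` (x, y, z,
    then the no-MEG reference) and wave-phase index ``n``.
    """

    phase: np.ndarray  # (4, n_wave_phases, nx, ny, nz)
    magnitude: np.ndarray  # (nx, ny, nz)
    directions: tuple = MEG_DIRECTIONS

    def __post_init__(self):
        self.phase = np.asarray(self.phase, dtype=float)
        if self.phase.ndim != 5 or self.phase.shape[0] != len(self.directions):
            raise ValueError("expected phase of shape (n_dir, n_wave_phases, nx, ny, nz)")

    @property
    def n_wave_phases(self) -> int:
        return self.phase.shape[1]

    @property
    def grid_shape(self):
        return self.phase.shape[2:]

    def has_reference(self) -> bool:
        return "ref" in self.directions


@dataclass
class ParameterMaps:
    """Voxel-wise viscoelastic parameter maps with a shared validity mask."""

    gd_kpa: np.ndarray
    gl_kpa: np.ndarray
    cs_mps: np.ndarray
    alpha_per_mm: np.ndarray
    upsilon: np.ndarray
    valid: np.ndarray

    PARAMETERS = ("gd_kpa", "gl_kpa", "cs_mps", "alpha_per_mm", "upsilon")

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in self.PARAMETERS}
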