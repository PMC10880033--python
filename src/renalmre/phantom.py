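"""Digital kidney phantom with known viscoelastic ground truth.

The phantom is a caricature of a kidney imaged as a thin axial slab: nested
ellipsoids for the whole kidney, the central sinus and an intrasinusoidal
vessel, plus a ring of discrete medullary blobs; the cortex is the
remainder of the kidney.  The through-slab semi-axes are much longer than
the 8-slice slab (a kidney is ~11 cm long), so compartment boundaries are
dominantly in-plane, as in the acquisition this emulates.

Within each compartment the displacement field is a locally exact
viscoelastic plane wave using that compartment's complex wavenumber, so
the homogeneous Helmholtz equation holds exactly away from compartment
boundaries and every downstream stage can be checked against ground truth.
Displacement is converted to wrapped MR phase with the fractional bipolar
motion-encoding model and optional Gaussian phase noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .acquisition import AcquisitionDescriptor
from .fields import LABELS, LABEL_NAMES, ComplexWaveField, LabelMap, ParameterMaps, PhaseStack
from .io import load_nifti, save_nifti
from .physics import complex_wavenumber, phase_angle, shear_speed_and_attenuation, wrap_phase


# ---------------------------------------------------------------------------
# geometry


@dataclass(frozen=True)
class KidneyGeometry:
    """Nested-ellipsoid compartment geometry, all lengths in mm.

    Semi-axes are (x, y, z) about the volume centre.  Medullary pyramids are
    approximated by ``n_medulla_blobs`` ellipsoidal blobs placed on an
    elliptical ring between sinus and cortex.
    """

    kidney_semi: tuple = (55.0, 35.0, 55.0)
    sinus_semi: tuple = (28.0, 18.0, 50.0)
    vessel_semi: tuple | None = (14.0, 9.0, 45.0)  # None drops the vessel
    medulla_blob_semi: tuple = (14.0, 11.0, 50.0)
    n_medulla_blobs: int = 4  # 0 drops the medulla
    medulla_ring_frac: tuple = (0.62, 0.64)  # ring radius as fraction of kidney semi-axes
    medulla_angle_offset_deg: float = 45.0


#: Two-compartment geometry for a small (24 x 24 x 8) test grid.
TINY_GEOMETRY = KidneyGeometry(
    kidney_semi=(26.0, 26.0, 60.0),
    sinus_semi=(11.0, 11.0, 55.0),
    vessel_semi=None,
    n_medulla_blobs=0,
)


def _grid_coords_mm(descriptor: AcquisitionDescriptor):
    """Voxel-centre coordinates (mm) relative to the volume centre."""
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * dv
        for n, dv in zip(descriptor.grid_shape, descriptor.voxel_size)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(coords, center, semi) -> np.ndarray:
    if any(s <= 0 for s in semi):
        raise ValueError("ellipsoid semi-axes must be positive")
    X, Y, Z = coords
    return (
        ((X - center[0]) / semi[0]) ** 2
        + ((Y - center[1]) / semi[1]) ** 2
        + ((Z - center[2]) / semi[2]) ** 2
    ) <= 1.0


def build_kidney_phantom(
    descriptor: AcquisitionDescriptor | None = None,
    geometry: KidneyGeometry | None = None,
) -> LabelMap:
    """Rasterize the compartment geometry into an integer label map.

    Labels are mutually exclusive with priority vessel > sinus > medulla >
    cortex, so the sub-compartments exactly partition the kidney.  Raises
    ``ValueError`` naming the first compartment that comes out empty.
    """
    descriptor = descriptor or AcquisitionDescriptor()
    geometry = geometry or KidneyGeometry()
    coords = _grid_coords_mm(descriptor)

    kidney = _ellipsoid(coords, (0, 0, 0), geometry.kidney_semi)
    sinus = _ellipsoid(coords, (0, 0, 0), geometry.sinus_semi) & kidney
    if geometry.vessel_semi is not None:
        vessel = _ellipsoid(coords, (0, 0, 0), geometry.vessel_semi) & sinus
    else:
        vessel = np.zeros_like(kidney)

    medulla = np.zeros_like(kidney)
    fx, fy = geometry.medulla_ring_frac
    for j in range(geometry.n_medulla_blobs):
        theta = np.deg2rad(geometry.medulla_angle_offset_deg + 360.0 * j / geometry.n_medulla_blobs)
        center = (
            fx * geometry.kidney_semi[0] * np.cos(theta),
            fy * geometry.kidney_semi[1] * np.sin(theta),
            0.0,
        )
        medulla |= _ellipsoid(coords, center, geometry.medulla_blob_semi)
    medulla &= kidney & ~sinus

    data = np.zeros(descriptor.grid_shape, dtype=np.int16)
    data[kidney] = LABELS["cortex"]
    data[medulla] = LABELS["medulla"]
    data[sinus] = LABELS["sinus"]
    data[vessel] = LABELS["vessel"]

    labels = LabelMap(data)
    required = ["cortex", "sinus"]
    if geometry.n_medulla_blobs > 0:
        required.append("medulla")
    if geometry.vessel_semi is not None:
        required.append("vessel")
    for name in required:
        if not labels.mask(name).any():
            raise ValueError(f"degenerate geometry: compartment '{name}' is empty")
    return labels


# ---------------------------------------------------------------------------
# tissue properties


@dataclass(frozen=True)
class TissueProperties:
    """Storage and loss modulus of one compartment, in kPa."""

    label: str
    G_d: float
    G_l: float

    def __post_init__(self):
        if self.G_d <= 0:
            raise ValueError("storage modulus must be positive")
        if self.G_l < 0:
            raise ValueError("loss modulus must be non-negative")

    @property
    def G_star_pa(self) -> complex:
        return complex(self.G_d * 1000.0, self.G_l * 1000.0)


#: Default compartment moduli (kPa): cortex/medulla around 0.68/0.47 and
#: sinusoidal structures around 0.48/0.24, the range seen in healthy human
#: kidney at 50 Hz; the vessel is given a slightly stiffer, less lossy
#: modulus so all four compartments are distinguishable in recovery tests.
DEFAULT_MODULI = (
    TissueProperties("cortex", 0.68, 0.48),
    TissueProperties("medulla", 0.68, 0.47),
    TissueProperties("sinus", 0.48, 0.24),
    TissueProperties("vessel", 0.50, 0.22),
)


def assign_moduli(labels: LabelMap, table=DEFAULT_MODULI) -> np.ndarray:
    """Per-voxel complex shear modulus G* in Pa; background voxels are NaN."""
    table = tuple(table)
    if not table:
        raise ValueError("empty moduli table")
    by_name = {t.label: t for t in table}
    G = np.full(labels.shape, np.nan + 1j * np.nan, dtype=complex)
    for name, lab in labels.legend.items():
        if name == "background":
            continue
        mask = labels.data == lab
        if not mask.any():
            continue
        if name not in by_name:
            raise ValueError(f"no moduli given for label '{name}'")
        G[mask] = by_name[name].G_star_pa
    return G


def ground_truth_maps(G_star: np.ndarray, descriptor: AcquisitionDescriptor) -> ParameterMaps:
    """Derive the ground-truth parameter maps from the assigned G* volume."""
    valid = np.isfinite(G_star.real) & (G_star.real > 0)
    gd = np.where(valid, G_star.real, np.nan) / 1000.0
    gl = np.where(valid, G_star.imag, np.nan) / 1000.0
    cs = np.full(G_star.shape, np.nan)
    al = np.full(G_star.shape, np.nan)
    if valid.any():
        c, a = shear_speed_and_attenuation(
            G_star[valid], rho=descriptor.rho, f=descriptor.f_excitation
        )
        cs[valid], al[valid] = c.real, a
    ups = np.where(valid, phase_angle(np.nan_to_num(gd, nan=1.0), np.nan_to_num(gl)), np.nan)
    return ParameterMaps(gd, gl, cs, al, ups, valid)


# ---------------------------------------------------------------------------
# wave sources and synthesis


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length direction vector")
    return v / n


@dataclass(frozen=True)
class WaveSource:
    """One plane-wave component of the synthetic drive.

    ``anchor`` places the unit-amplitude point of the (decaying) wave:
    ``"rim"`` anchors at the wave's entry into the kidney (amplitude <= 1
    inside, as for a wave coupled in from outside), ``"center"`` at the
    volume centre.
    """

    propagation: tuple
    polarization: tuple
    amplitude_um: float
    phase0: float = 0.0
    mode: str = "shear"
    anchor: str = "rim"

    def __post_init__(self):
        if self.anchor not in ("rim", "center"):
            raise ValueError(f"unknown anchor: {self.anchor!r}")
        n = _unit(self.propagation)
        p = _unit(self.polarization)
        object.__setattr__(self, "propagation", tuple(n))
        object.__setattr__(self, "polarization", tuple(p))
        if self.amplitude_um < 0:
            raise ValueError("amplitude must be non-negative")
        if self.mode == "shear":
            if abs(float(np.dot(n, p))) > 1e-10:
                raise ValueError("shear polarization must be orthogonal to propagation")
        elif self.mode == "compressional":
            if float(np.linalg.norm(np.cross(n, p))) > 1e-10:
                raise ValueError("compressional polarization must be parallel to propagation")
        else:
            raise ValueError(f"unknown source mode: {self.mode!r}")


def default_sources(total_amplitude_um: float = 163.0) -> tuple:
    """Default drive: through-slab shear pairs, rim shear waves, compression.

    In a strongly attenuating medium (about 1 neper/cm at these moduli) an
    in-plane traveling wave decays by several e-folds across the kidney, so
    in-plane displacement is carried by counter-propagating through-slab
    (+-z) shear pairs, which stay within a narrow amplitude band over the
    8-slice slab; through-slab displacement comes from in-plane z-polarized
    waves entering at the rim from eight azimuths, and a weak
    long-wavelength compressional wave contaminates the field.  This keeps
    the motion-encoded phase everywhere below the spatial sampling limit of
    the unwrapping (neighbor steps < pi) at the nominal 163 um total
    displacement.  Amplitudes are scaled so their quadrature sum equals
    ``total_amplitude_um``, which the synthesizer realizes as the
    kidney-mean total displacement.
    """
    xhat, yhat, zhat = (1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0)
    # equal-amplitude counter-propagating pairs with a pi relative phase:
    # the flattest standing profile over the slab (max/mean ~ 1.24 in all
    # compartments, with a mid-slab valley that seeds wrap correction)
    weights_sources = [
        (0.42, WaveSource(zhat, xhat, 1.0, phase0=0.0)),
        (0.42, WaveSource((0.0, 0.0, -1.0), xhat, 1.0, phase0=np.pi)),
        (0.42, WaveSource(zhat, yhat, 1.0, phase0=1.9)),
        (0.42, WaveSource((0.0, 0.0, -1.0), yhat, 1.0, phase0=1.9 + np.pi)),
    ]
    for j in range(8):
        phi = np.deg2rad(10.0 + 45.0 * j)
        n = (np.cos(phi), np.sin(phi), 0.0)
        weights_sources.append((0.15, WaveSource(n, zhat, 1.0, phase0=0.77 * j)))
    n_c = (np.cos(np.deg2rad(70.0)), np.sin(np.deg2rad(70.0)), 0.0)
    weights_sources.append(
        (0.14, WaveSource(n_c, n_c, 1.0, phase0=0.3, mode="compressional"))
    )
    w = np.array([ws[0] for ws in weights_sources])
    amps = total_amplitude_um * w / np.sqrt(np.sum(w**2))
    return tuple(
        WaveSource(s.propagation, s.polarization, float(a), s.phase0, s.mode, s.anchor)
        for a, (_, s) in zip(amps, weights_sources)
    )


@dataclass(frozen=True)
class WaveSourceSpec:
    """Drive configuration: plane-wave components, harmonics and noise."""

    sources: tuple = field(default_factory=default_sources)
    second_harmonic_fraction: float = 0.23
    noise_sd: float = 0.05  # rad, Gaussian on each phase volume
    seed: int = 0
    compressional_k_ratio: float = 6.0  # shear |k| / compressional k

    def __post_init__(self):
        if self.second_harmonic_fraction < 0:
            raise ValueError("second_harmonic_fraction must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.compressional_k_ratio < 5.0:
            raise ValueError("compressional wavenumber must be >= 5x smaller than shear")

    def target_amplitude_um(self) -> float:
        return float(np.sqrt(sum(s.amplitude_um**2 for s in self.sources)))


def _compartment_moduli(labels: LabelMap, G_star: np.ndarray) -> dict:
    out = {}
    for name, lab in labels.legend.items():
        if name == "background":
            continue
        mask = labels.data == lab
        if mask.any():
            vals = G_star[mask]
            out[lab] = complex(np.median(vals.real), np.median(vals.imag))
    return out


def synthesize_wavefield(
    labels: LabelMap,
    G_star: np.ndarray,
    spec: WaveSourceSpec | None = None,
    descriptor: AcquisitionDescriptor | None = None,
) -> ComplexWaveField:
    """Superpose locally exact plane waves on the phantom grid.

    Each shear component is ``p A exp(i k_local (n.r) + i phi0)`` with the
    compartment's complex wavenumber, so the Helmholtz equation is satisfied
    exactly inside compartments.  The compressional contaminant uses a real
    wavenumber ``min|k_shear| / compressional_k_ratio``.  Each component is
    normalized to unit peak amplitude inside the kidney before weighting
    (so source amplitudes bound the local displacement), and the total
    field is scaled so the kidney-mean total displacement equals the
    quadrature sum of the source amplitudes (scaling is homogeneous of
    degree one in the amplitudes, so encoding stays linear in them).

    The second-harmonic field repeats the shear pattern with wavenumbers at
    ``2f`` and kidney-mean amplitude ``second_harmonic_fraction`` times that
    of the fundamental.
    """
    spec = spec or WaveSourceSpec()
    descriptor = descriptor or AcquisitionDescriptor()
    if labels.shape != G_star.shape:
        raise ValueError("labels and moduli must share one grid")
    for s in spec.sources:
        if not np.isfinite(s.amplitude_um):
            raise ValueError("source amplitudes must be finite")

    coords = _grid_coords_mm(descriptor)
    X = np.stack(coords) * 1e-3  # (3, nx, ny, nz) in metres
    kidney = labels.data > 0
    if not kidney.any():
        raise ValueError("empty kidney mask")

    moduli = _compartment_moduli(labels, G_star)
    k_by_label = {
        m: {
            lab: complex_wavenumber(G, rho=descriptor.rho, f=m * descriptor.f_excitation)
            for lab, G in moduli.items()
        }
        for m in (1, 2)
    }
    k_shear_min = min(abs(k) for k in k_by_label[1].values())
    k_comp = k_shear_min / spec.compressional_k_ratio

    def plane_wave(source: WaveSource) -> np.ndarray:
        n = np.asarray(source.propagation)
        p = np.asarray(source.polarization)
        proj = np.tensordot(n, X, axes=1)  # n.r, metres
        if source.anchor == "rim":
            # with Im(k) < 0 (branch fixed by the e^{-i omega t} convention)
            # |exp(i k s)| grows along +s, so unit amplitude sits at the
            # max-projection face and the wave decays into the kidney
            proj = proj - proj[kidney].max()
        amp = np.zeros(labels.shape, dtype=complex)
        if source.mode == "compressional":
            amp[kidney] = np.exp(1j * (k_comp * proj[kidney] + source.phase0))
        else:
            for lab, k in k_by_label[1].items():
                m = labels.data == lab
                amp[m] = np.exp(1j * (k * proj[m] + source.phase0))
        u = p[:, None, None, None] * amp[None]
        peak = np.max(np.abs(amp[kidney]))
        if peak > 0:
            u /= peak
        return u

    shape = (3,) + labels.shape
    U1 = np.zeros(shape, dtype=complex)
    for s in spec.sources:
        if s.amplitude_um > 0:
            U1 += s.amplitude_um * plane_wave(s)

    target = spec.target_amplitude_um()
    tot = np.sqrt(np.sum(np.abs(U1) ** 2, axis=0))
    mean_tot = float(np.mean(tot[kidney]))
    if target > 0 and mean_tot > 0:
        U1 *= target / mean_tot

    # Second harmonic: the fundamental pattern remodulated to the 2f
    # wavenumber along the first shear propagation direction, with the
    # amplitude envelope of the fundamental.  Harmonic contamination of the
    # drive is a local percentage of the shear displacement, so
    # |U2| = fraction * |U1| voxel-wise.
    U2 = np.zeros(shape, dtype=complex)
    if spec.second_harmonic_fraction > 0:
        shear_sources = [s for s in spec.sources if s.mode == "shear"]
        n_ref = np.asarray((shear_sources or spec.sources)[0].propagation)
        proj = np.tensordot(n_ref, X, axes=1)
        psi = np.zeros(labels.shape)
        for lab in k_by_label[1]:
            m = labels.data == lab
            dk = k_by_label[2][lab].real - k_by_label[1][lab].real
            psi[m] = dk * proj[m]
        U2 = spec.second_harmonic_fraction * U1 * np.exp(1j * psi)[None]

    return ComplexWaveField(U1, U2, descriptor.voxel_size)


# ---------------------------------------------------------------------------
# motion encoding


def _static_background_phase(descriptor: AcquisitionDescriptor) -> np.ndarray:
    """Smooth deterministic background phase common to all acquisitions.

    Mimics static field inhomogeneity / receiver phase; it must cancel in
    the reference subtraction, which is what makes the no-MEG stack useful.
    """
    X, Y, Z = _grid_coords_mm(descriptor)
    lx = max(descriptor.grid_shape[0] * descriptor.voxel_size[0], 1.0)
    ly = max(descriptor.grid_shape[1] * descriptor.voxel_size[1], 1.0)
    return 0.9 * X / lx - 0.7 * (Y / ly) ** 2 + 0.3 * X * Y / (lx * ly)


def encode_to_phase(
    field: ComplexWaveField,
    descriptor: AcquisitionDescriptor | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    magnitude: np.ndarray | None = None,
    static_background: bool = True,
    n_quad: int = 256,
) -> PhaseStack:
    """Accumulate MEG phase from the harmonic displacement field.

    For wave-phase index n and MEG direction d the displacement is
    ``u_d(t) = Re[U1_d exp(-i w (t + nT/N))] + Re[U2_d exp(-2 i w (t + nT/N))]``
    and the accrued phase is ``gamma int_0^tau G_meg(t) u_d(t) dt``, evaluated
    by midpoint quadrature with ``n_quad`` (>= 200) steps via the complex
    encoding efficiency.  Gaussian noise of ``noise_sd`` rad is added to every
    volume (including the no-MEG reference) and the result wrapped to
    (-pi, pi].
    """
    descriptor = descriptor or AcquisitionDescriptor()
    N = descriptor.n_wave_phases
    xi1 = descriptor.encoding_efficiency(1, method="quadrature", n_quad=n_quad)
    xi2 = descriptor.encoding_efficiency(2, method="quadrature", n_quad=n_quad)

    grid = field.grid_shape
    phase = np.zeros((4, N) + grid, dtype=float)
    background = _static_background_phase(descriptor) if static_background else 0.0
    omega = descriptor.omega
    for n in range(N):
        t_n = n * descriptor.period / N
        rot1 = np.exp(-1j * omega * t_n)
        rot2 = np.exp(-2j * omega * t_n)
        for d in range(3):
            phase[d, n] = (
                background
                + np.real(xi1 * field.U1[d] * rot1)
                + np.real(xi2 * field.U2[d] * rot2)
            )
        phase[3, n] = background + np.zeros(grid)

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        phase = phase + rng.normal(0.0, noise_sd, size=phase.shape)

    if magnitude is None:
        magnitude = 10.0 + 90.0 * (field.total_amplitude() > 1e-9)

    return PhaseStack(wrap_phase(phase), np.asarray(magnitude, dtype=float))


# ---------------------------------------------------------------------------
# on-disk phantom


def write_phantom(
    stack: PhaseStack,
    labels: LabelMap,
    truth: ParameterMaps,
    descriptor: AcquisitionDescriptor,
    path,
    meta: dict | None = None,
) -> dict:
    """Write phase/magnitude/labels/ground-truth NIfTI volumes + sidecar.

    Returns a manifest dict of the files written.  Round-trips through
    :func:`read_phantom` (labels bit-identically, floats to float32).
    """
    if stack.grid_shape != labels.shape:
        raise ValueError("phase stack and label map must share one grid")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    vox = descriptor.voxel_size
    files = {}
    for d, dname in enumerate(stack.directions):
        for n in range(stack.n_wave_phases):
            p = path / f"phase_{dname}_{n}.nii"
            save_nifti(stack.phase[d, n], vox, p, dtype=np.float32)
            files[f"phase_{dname}_{n}"] = p.name
    save_nifti(stack.magnitude, vox, path / "magnitude.nii", dtype=np.float32)
    files["magnitude"] = "magnitude.nii"
    save_nifti(labels.data, vox, path / "labels.nii", dtype=np.int16)
    files["labels"] = "labels.nii"
    for name, arr in truth.as_dict().items():
        p = path / f"truth_{name}.nii"
        save_nifti(arr, vox, p, dtype=np.float32)
        files[f"truth_{name}"] = p.name
    sidecar = {
        "descriptor": descriptor.to_dict(),
        "n_wave_phases": stack.n_wave_phases,
        "meta": meta or {},
        "files": files,
    }
    (path / "phantom.yaml").write_text(yaml.safe_dump(sidecar, sort_keys=False))
    return sidecar


def read_phantom(path):
    """Load a phantom directory written by :func:`write_phantom`.

    Returns ``(stack, labels, truth, descriptor, meta)``.
    """
    path = Path(path)
    sidecar = yaml.safe_load((path / "phantom.yaml").read_text())
    descriptor = AcquisitionDescriptor.from_dict(sidecar["descriptor"])
    N = sidecar["n_wave_phases"]
    grid = tuple(descriptor.grid_shape)
    phase = np.zeros((4, N) + grid, dtype=float)
    from .fields import MEG_DIRECTIONS

    for d, dname in enumerate(MEG_DIRECTIONS):
        for n in range(N):
            phase[d, n], _ = load_nifti(path / f"phase_{dname}_{n}.nii")
    magnitude, _ = load_nifti(path / "magnitude.nii")
    labels_data, _ = load_nifti(path / "labels.nii")
    labels = LabelMap(labels_data.astype(np.int16))
    truth_arrays = {}
    for name in ParameterMaps.PARAMETERS:
        truth_arrays[name] = load_nifti(path / f"truth_{name}.nii")[0]
    valid = np.isfinite(truth_arrays["gd_kpa"]) & (truth_arrays["gd_kpa"] > 0)
    truth = ParameterMaps(valid=valid, **truth_arrays)
    stack = PhaseStack(phase, magnitude)
    return stack, labels, truth, descriptor, sidecar.get("meta", {})


def make_phantom_dataset(
    descriptor: AcquisitionDescriptor | None = None,
    geometry: KidneyGeometry | None = None,
    moduli=DEFAULT_MODULI,
    spec: WaveSourceSpec | None = None,
):
    """Convenience: labels, G*, truth maps, wave field and phase stack."""
    descriptor = descriptor or AcquisitionDescriptor()
    spec = spec or WaveSourceSpec()
    labels = build_kidney_phantom(descriptor, geometry)
    G_star = assign_moduli(labels, moduli)
    truth = ground_truth_maps(G_star, descriptor)
    fieldv = synthesize_wavefield(labels, G_star, spec, descriptor)
    magnitude = 10.0 + 90.0 * (labels.data > 0)
    stack = encode_to_phase(
        fieldv, descriptor, noise_sd=spec.noise_sd, seed=spec.seed, magnitude=magnitude
    )
    return labels, G_star, truth, fieldv, stack
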