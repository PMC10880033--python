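"""Shared viscoelastic wave physics.

The tissue is modelled as a homogeneous, isotropic, linear viscoelastic
medium with complex shear modulus ``G* = G_d + i G_l`` (storage and loss
modulus, Pa).  A time-harmonic shear wave at angular frequency
``omega = 2 pi f`` then obeys the homogeneous Helmholtz equation

    G* lap(u) + rho omega**2 u = 0

with the complex wavenumber ``k = omega * sqrt(rho / G*)``.  The real part
of ``k`` sets the shear wave speed ``c_s = omega / Re(k)`` and the imaginary
part the spatial attenuation ``alpha = |Im(k)|`` (converted to 1/mm for
reporting).  The time convention is ``exp(-i omega t)``; with the square
root branch chosen so that ``Re(k) > 0``, a lossy medium (``G_l > 0``)
yields ``Im(k) < 0``, i.e. exponential decay along the propagation
direction.
"""

from __future__ import annotations

import numpy as np

#: Gyromagnetic ratio of the proton, rad / (s T).
GAMMA_1H = 267.522187e6

#: Mass density assumed for soft tissue, kg / m^3.
RHO_TISSUE = 1000.0


def complex_wavenumber(G_star, rho: float = RHO_TISSUE, f: float = 50.0):
    """Complex shear wavenumber ``k = omega sqrt(rho / G*)`` in 1/m.

    Parameters
    ----------
    G_star : complex or ndarray
        Complex shear modulus in Pa; requires ``Re(G*) > 0`` and
        ``Im(G*) >= 0``.
    rho : float
        Density in kg/m^3.
    f : float
        Vibration frequency in Hz.

    Returns
    -------
    complex or ndarray
        Wavenumber with ``Re(k) > 0`` and ``Im(k) <= 0`` (decaying wave
        under the ``exp(-i omega t)`` convention).
    """
    G_star = np.asarray(G_star, dtype=complex)
    if np.any(G_star == 0):
        raise ValueError("complex modulus must be non-zero")
    if np.any(G_star.real <= 0) or np.any(G_star.imag < 0):
        raise ValueError("require Re(G*) > 0 and Im(G*) >= 0")
    omega = 2.0 * np.pi * f
    k = omega * np.sqrt(rho / G_star)
    # principal sqrt of rho/G* with Im(G*) >= 0 lands in the fourth
    # quadrant already; normalize defensively so Re(k) > 0.
    k = np.where(k.real < 0, -k, k)
    if k.ndim == 0:
        return complex(k)
    return k


def shear_speed_and_attenuation(G_star, rho: float = RHO_TISSUE, f: float = 50.0):
    """Shear wave speed (m/s) and attenuation (1/mm) from ``G*`` in Pa."""
    k = complex_wavenumber(G_star, rho=rho, f=f)
    omega = 2.0 * np.pi * f
    c_s = omega / np.real(k)
    alpha = np.abs(np.imag(k)) / 1000.0  # 1/m -> 1/mm
    return c_s, alpha


def phase_angle(G_d, G_l):
    """Viscoelastic phase angle ``Y = (2/pi) atan(G_l / G_d)``.

    Dimensionless, 0 for a purely elastic material and -> 1 for a purely
    viscous one.  ``G_d`` and ``G_l`` may be given in any common unit.
    """
    G_d = np.asarray(G_d, dtype=float)
    G_l = np.asarray(G_l, dtype=float)
    out = (2.0 / np.pi) * np.arctan2(G_l, G_d)
    if out.ndim == 0:
        return float(out)
    return out


def meg_waveform(t: np.ndarray, duration: float, shape: str = "bipolar_rect") -> np.ndarray:
    """Normalized motion-encoding-gradient waveform s(t) in [-1, 1].

    ``bipolar_rect`` is two rectangular lobes of opposite sign, each of
    length ``duration / 2``.  ``bipolar_trapezoid`` adds 10% linear ramps
    inside each lobe.  Outside ``[0, duration]`` the gradient is zero.
    """
    t = np.asarray(t, dtype=float)
    if duration <= 0:
        raise ValueError("MEG duration must be positive")
    half = duration / 2.0
    if shape == "bipolar_rect":
        s = np.where(t < half, 1.0, -1.0)
    elif shape == "bipolar_trapezoid":
        ramp = 0.1 * half
        tt = np.where(t < half, t, t - half)
        flat = np.clip(tt / ramp, 0.0, None)
        flat = np.minimum(flat, 1.0)
        flat = np.minimum(flat, np.clip((half - tt) / ramp, 0.0, 1.0))
        s = np.where(t < half, flat, -flat)
    else:
        raise ValueError(f"unknown MEG shape: {shape!r}")
    return np.where((t >= 0) & (t <= duration), s, 0.0)


def encoding_efficiency(
    f_motion: float,
    meg_amplitude_mT_per_m: float,
    meg_duration_ms: float,
    shape: str = "bipolar_rect",
    gamma: float = GAMMA_1H,
    method: str = "closed",
    n_quad: int = 256,
) -> complex:
    """Complex fractional-encoding efficiency xi in rad per micrometre.

    For a displacement component ``u(t) = Re[U exp(-i omega t)]`` (U in um)
    the phase accrued over one MEG of amplitude G and normalized waveform
    s(t) is ``phi = Re[xi U]`` with

        xi = gamma G integral_0^tau s(t) exp(-i omega t) dt   (per metre)

    scaled to rad/um.  For the rectangular bipolar waveform the integral has
    the closed form ``-(i/omega) (1 - exp(-i omega tau/2))**2``.

    ``method='quadrature'`` evaluates the integral numerically with
    ``n_quad`` midpoint steps (>= 200 enforced), for any waveform shape.
    """
    omega = 2.0 * np.pi * f_motion
    G = meg_amplitude_mT_per_m * 1e-3  # T/m
    tau = meg_duration_ms * 1e-3  # s
    if tau <= 0:
        raise ValueError("MEG duration must be positive")
    if method == "closed":
        if shape != "bipolar_rect":
            raise ValueError("closed form implemented for bipolar_rect only")
        integral = -1j / omega * (1.0 - np.exp(-1j * omega * tau / 2.0)) ** 2
    elif method == "quadrature":
        n = max(int(n_quad), 200)
        dt = tau / n
        t = (np.arange(n) + 0.5) * dt
        integral = np.sum(meg_waveform(t, tau, shape) * np.exp(-1j * omega * t)) * dt
    else:
        raise ValueError(f"unknown method: {method!r}")
    xi = gamma * G * integral  # rad per metre of displacement
    xi_per_um = xi * 1e-6
    if xi_per_um == 0:
        raise ValueError("encoding efficiency is zero at this motion frequency")
    return complex(xi_per_um)


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap phase values into (-pi, pi]."""
    return -np.mod(-np.asarray(phi) + np.pi, 2.0 * np.pi) + np.pi
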