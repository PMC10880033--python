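"""From wrapped motion-encoded phase to the complex displacement field.

The processing chain is: subtract the no-MEG reference acquisition
(removing static background phase), spatially unwrap each volume, take the
temporal discrete Fourier transform over the captured wave phases, and
scale the first/second-harmonic coefficients by the complex fractional
encoding efficiency to obtain displacement in micrometres.  QA metrics
(total shear displacement, second-harmonic contamination, curl/divergence
ratio) quantify wave quality the way scanner in-line reconstructions do.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.restoration import unwrap_phase as _skimage_unwrap

from .acquisition import AcquisitionDescriptor
from .fields import ComplexWaveField, LabelMap, PhaseStack
from .physics import wrap_phase


def reference_subtract(stack: PhaseStack) -> PhaseStack:
    """Wrapped difference (phi_d - phi_ref) per direction and wave phase."""
    if not stack.has_reference():
        raise ValueError("phase stack has no reference (no-MEG) acquisition")
    ref_idx = stack.directions.index("ref")
    keep = [i for i in range(len(stack.directions)) if i != ref_idx]
    diff = wrap_phase(stack.phase[keep] - stack.phase[ref_idx][None])
    return PhaseStack(
        diff, stack.magnitude, directions=tuple(stack.directions[i] for i in keep)
    )


def _unwrap_regions(mask: np.ndarray, regions: np.ndarray | None) -> list[np.ndarray]:
    """Split the mask into independently unwrapped connected regions."""
    from scipy import ndimage

    if regions is None:
        return [mask]
    out = []
    values = [v for v in np.unique(regions) if v != 0] + [0]
    for v in values:
        rmask = mask & ((regions == v) if v != 0 else (regions == 0))
        if not rmask.any():
            continue
        comp, n = ndimage.label(rmask)
        for c in range(1, n + 1):
            out.append(comp == c)
    return out


def unwrap_phase(
    phase: np.ndarray, mask: np.ndarray, regions: np.ndarray | None = None
) -> np.ndarray:
    """Spatially unwrap wrapped phase volumes inside a mask.

    Accepts a single 3D volume or a stack whose last three axes are the
    volume; each volume is unwrapped with a 3D reliability-sorted
    algorithm.  Output equals input modulo 2 pi at every masked voxel;
    unmasked voxels are zero.

    ``regions`` (an integer map, typically the compartment labels) makes
    each connected region unwrap independently, so sampling-limit
    violations near wave crests or true phase jumps at tissue interfaces
    cannot propagate across anatomy.  Each region's arbitrary 2 pi offset
    is anchored by zeroing the rounded region mean — valid whenever the
    region spans at least about one wavelength, so its true mean
    motion-encoded phase is far from +-pi.
    """
    phase = np.asarray(phase, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("unwrap mask is empty")
    if phase.shape[-3:] != mask.shape:
        raise ValueError("mask does not match volume shape")
    region_masks = _unwrap_regions(mask, regions)
    flat = phase.reshape((-1,) + phase.shape[-3:])
    out = np.zeros_like(flat)
    for i, vol in enumerate(flat):
        for rmask in region_masks:
            ma = np.ma.MaskedArray(vol, mask=~rmask)
            uw = np.ma.filled(_skimage_unwrap(ma), 0.0)
            if regions is not None:
                uw = uw - 2.0 * np.pi * np.round(np.mean(uw[rmask]) / (2.0 * np.pi))
            out[i][rmask] = uw[rmask]
    return out.reshape(phase.shape)


def model_guided_unwrap(
    phase: np.ndarray,
    mask: np.ndarray,
    regions: np.ndarray | None = None,
    sweep_iterations: int = 12,
    n_seeds: int = 3,
) -> np.ndarray:
    """Wrap correction for motion-encoded phase beyond the spatial Nyquist.

    At this acquisition's operating point (about 4 rad of motion-encoded
    phase at 6-8 voxels per wavelength) the voxel-to-voxel phase step of
    the raw wrapped data approaches or exceeds pi, where purely spatial
    unwrapping breaks down.  This solver instead exploits the temporal
    model: over one vibration period the phase at every voxel is
    ``phi_n = Re[A1 e1_n] + Re[A2 e2_n]`` (fundamental plus second
    harmonic).  Starting from wrap-free low-amplitude seed voxels, a
    priority-driven region growth predicts each new voxel's full temporal
    sample vector from an already-solved neighbour, extrapolated with the
    locally estimated complex per-voxel ratio (~ exp(i k h)), and snaps
    the measured wrapped samples to the nearest 2 pi-congruent values.
    The prediction error scales with the local change of the wavenumber
    rather than with the wavenumber itself, so steps stay far below pi
    even where the raw data are undersampled.

    ``phase`` has shape (N, nx, ny, nz) — the wave-phase samples of one
    MEG direction after reference subtraction — or (D, N, nx, ny, nz) for
    several directions.  Returns the wrap-corrected phases (congruent to
    the input modulo 2 pi at every voxel).
    """
    import heapq

    phase = np.asarray(phase, dtype=float)
    if phase.ndim == 5:
        return np.stack(
            [model_guided_unwrap(p, mask, regions, sweep_iterations, n_seeds) for p in phase]
        )
    if phase.ndim != 4:
        raise ValueError("expected (N, nx, ny, nz) phase samples")
    N = phase.shape[0]
    if N < 4:
        raise ValueError("need at least 4 wave phases")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("unwrap mask is empty")
    nvec = np.arange(N)
    e1 = np.exp(-2j * np.pi * nvec / N)
    e2 = np.exp(-4j * np.pi * nvec / N)
    two_pi = 2.0 * np.pi

    def harmonics(samples):
        a1 = (2.0 / N) * np.dot(samples, np.conj(e1))
        scale2 = (1.0 / N) if N == 4 else (2.0 / N)
        a2 = scale2 * np.dot(samples, np.conj(e2))
        return a1, a2

    def model(a1, a2, a0=0.0):
        return a0 + np.real(a1 * e1) + np.real(a2 * e2)

    # For N = 4 the opposite wave phases cancel the fundamental exactly:
    # phi_0 + phi_2 = 2(A0 + A2) and phi_1 + phi_3 = 2(A0 - A2), and these
    # sums are small enough to recover from the wrapped data directly, so
    # the harmonic/offset part of the temporal model needs no unwrapping.
    A0_direct = A2_direct = None
    if N == 4:
        a = wrap_phase(phase[0] + phase[2]) / 2.0
        b = wrap_phase(phase[1] + phase[3]) / 2.0
        A0_direct = (a + b) / 2.0
        A2_direct = (a - b) / 2.0

    corrected = phase.copy()
    shape = mask.shape
    peak = np.max(np.abs(phase), axis=0)
    steps = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]

    def inside(v):
        return all(0 <= v[i] < shape[i] for i in range(3))

    def make_state():
        return {
            "corr": phase.copy(),
            "A1": np.zeros(shape, dtype=complex),
            "A2": np.zeros(shape, dtype=complex),
            "solved": np.zeros(shape, dtype=bool),
            # Per-axis "dispersion" field C ~ cos(k_ax h): any superposition
            # of two exponentials along an axis obeys the exact three-term
            # recurrence A1(s+h) = 2 C A1(s) - A1(s-h), which is what makes
            # extrapolation accurate far beyond the naive sampling limit.
            "C": np.ones((3,) + shape, dtype=complex),
            "C_known": np.zeros((3,) + shape, dtype=bool),
        }

    def grow(state, rmask, seed):
        """One confidence-ordered region growth from ``seed``.

        State is shared across the regions of a pass: voxels solved in a
        neighbouring compartment provide extra (approximate) context at
        region boundaries without letting wrap errors propagate across
        them.
        """
        A1, A2 = state["A1"], state["A2"]
        solved = state["solved"]
        C, C_known = state["C"], state["C_known"]
        corr_vol = state["corr"]
        region_C = [[], [], []]

        def local_C(u, ax):
            if C_known[ax][u]:
                return C[ax][u]
            acc, n_acc = 0.0 + 0.0j, 0
            for st in steps:
                nb = (u[0] + st[0], u[1] + st[1], u[2] + st[2])
                if inside(nb) and C_known[ax][nb]:
                    acc += C[ax][nb]
                    n_acc += 1
            if n_acc:
                return acc / n_acc
            vals = region_C[ax]
            if len(vals) >= 20:
                return complex(
                    np.median([c.real for c in vals]),
                    np.median([c.imag for c in vals]),
                )
            return None

        def predict_from(u, v):
            """Predicted (A1, A2, confidence) at v from solved neighbour u.

            Confidence ranks the extrapolation model: 2 = exact three-term
            recurrence, 1 = first-order complex ratio, 0 = persistence.
            """
            st = tuple(v[i] - u[i] for i in range(3))
            ax = next(i for i in range(3) if st[i] != 0)
            w = tuple(u[i] - st[i] for i in range(3))
            a2p = A2_direct[v] if A2_direct is not None else A2[u]
            c = local_C(u, ax)
            if inside(w) and solved[w] and c is not None:
                return 2.0 * c * A1[u] - A1[w], a2p, 2
            if inside(w) and solved[w] and abs(A1[w]) > 1e-9:
                r = A1[u] / A1[w]
                mag = abs(r)
                if mag > 1.6 or mag < 0.6:
                    r /= mag
                return A1[u] * r, a2p, 1
            return A1[u], a2p, 0

        a1s, a2s = harmonics(phase[(slice(None),) + seed])
        A1[seed], A2[seed] = a1s, a2s
        solved[seed] = True
        heap = []
        counter = 0  # tie-breaker keeps heap entries comparable

        def push(u, v):
            # order the frontier by (confidence, predictor amplitude): all
            # recurrence-backed steps run before any ratio or persistence
            # step, so the few unavoidable blind steps happen where the
            # field is flattest and the region dispersion is established
            nonlocal counter
            counter += 1
            _, _, conf = predict_from(u, v)
            heapq.heappush(heap, (2 - conf, abs(A1[u]), counter, v, u))

        for st in steps:
            v = (seed[0] + st[0], seed[1] + st[1], seed[2] + st[2])
            if inside(v) and rmask[v]:
                push(seed, v)
        while heap:
            _, _, _, v, u = heapq.heappop(heap)
            if solved[v]:
                continue
            best = None
            for st in steps:
                nb = (v[0] + st[0], v[1] + st[1], v[2] + st[2])
                if inside(nb) and solved[nb]:
                    a1p, a2p, conf = predict_from(nb, v)
                    key = (-conf, abs(A1[nb]))
                    if best is None or key < best[0]:
                        best = (key, a1p, a2p, nb)
            a0 = A0_direct[v] if A0_direct is not None else 0.0
            samples = phase[(slice(None),) + v]

            def snap(a1p):
                m = np.round((model(a1p, best[2], a0) - samples) / two_pi)
                corr = samples + two_pi * m
                return corr, harmonics(corr)

            conf = -best[0][0]
            u = best[3]
            corr, (a1v, a2v) = snap(best[1])
            if conf < 2:
                # Low-confidence extrapolation (e.g. the first step out of
                # an interference valley, where a one-sided ratio is
                # unreliable): test the 2*pi-congruent candidates around
                # the nominal prediction and keep the one whose implied
                # local dispersion best predicts the wrapped samples one
                # and two voxels ahead.
                st = tuple(v[i] - u[i] for i in range(3))
                w = tuple(u[i] - st[i] for i in range(3))
                y = tuple(v[i] + st[i] for i in range(3))
                y2 = tuple(v[i] + 2 * st[i] for i in range(3))
                have_w = inside(w) and solved[w]
                # without upstream context the ratio-chain discriminator is
                # only meaningful (and only needed) for larger steps, where
                # blind persistence could exceed the snapping margin
                engage = have_w or abs(A1[u]) > 1.0
                if engage and inside(y) and rmask[y] and abs(A1[u]) > 0.3:
                    ahead = [(y, phase[(slice(None),) + y])]
                    if inside(y2) and rmask[y2]:
                        ahead.append((y2, phase[(slice(None),) + y2]))
                    scored = []
                    for dre in (-1, 0, 1):
                        for dim in (-1, 0, 1):
                            cand = best[1] + np.pi * (dre + 1j * dim)
                            ccorr, (ca1, ca2) = snap(cand)
                            score = 0.1 * (abs(dre) + abs(dim))
                            if have_w:
                                cdisp = (A1[w] + ca1) / (2.0 * A1[u])
                                advance = None
                            else:
                                # no upstream context yet: chain with the
                                # candidate's own clamped complex ratio
                                advance = ca1 / A1[u]
                                mag = abs(advance)
                                if mag > 1.6 or mag < 0.6:
                                    advance /= mag
                            prev, back = ca1, A1[u]
                            for yv, ysamples in ahead:
                                if advance is None:
                                    cur = 2.0 * cdisp * prev - back
                                else:
                                    cur = prev * advance
                                a0y = A0_direct[yv] if A0_direct is not None else 0.0
                                a2y = A2_direct[yv] if A2_direct is not None else best[2]
                                resid = wrap_phase(model(cur, a2y, a0y) - ysamples)
                                score += float(np.sum(np.abs(resid)))
                                back, prev = prev, cur
                            scored.append((score, abs(dre) + abs(dim), ccorr, ca1, ca2))
                    scored.sort(key=lambda t: (t[0], t[1]))
                    _, _, corr, a1v, a2v = scored[0]
            corr_vol[(slice(None),) + v] = corr
            A1[v], A2[v] = a1v, a2v
            solved[v] = True
            # learn the per-axis dispersion from every consecutive solved
            # triple that this voxel completes
            for ax in range(3):
                st = tuple(int(i == ax) for i in range(3))
                for cshift in (-1, 0, 1):
                    ctr = tuple(v[i] + cshift * st[i] for i in range(3))
                    lo = tuple(ctr[i] - st[i] for i in range(3))
                    hi = tuple(ctr[i] + st[i] for i in range(3))
                    if not (inside(lo) and inside(hi) and inside(ctr)):
                        continue
                    if not (solved[lo] and solved[ctr] and solved[hi]):
                        continue
                    if C_known[ax][ctr] or abs(A1[ctr]) <= 0.3:
                        continue
                    cval = (A1[lo] + A1[hi]) / (2.0 * A1[ctr])
                    if abs(cval) < 2.0:
                        C[ax][ctr] = cval
                        C_known[ax][ctr] = True
                        region_C[ax].append(cval)
            for st2 in steps:
                nb = (v[0] + st2[0], v[1] + st2[1], v[2] + st2[2])
                if inside(nb) and rmask[nb] and not solved[nb]:
                    push(v, nb)

    def sweep(corr_vol, rmask, ridx):
        """Consistency polish: re-snap voxels against the recurrence
        predictions of their neighbours, with the per-axis dispersion
        pinned to its robust region median, until stable.  Isolated
        mis-solved patches are eroded from their boundary by the
        majority."""
        A1 = (2.0 / N) * np.tensordot(np.conj(e1), corr_vol, axes=(0, 0))
        scale2 = (1.0 / N) if N == 4 else (2.0 / N)
        A2 = scale2 * np.tensordot(np.conj(e2), corr_vol, axes=(0, 0))
        cbar = {}
        for ax in range(3):
            lo = np.roll(A1, 1, axis=ax)
            hi = np.roll(A1, -1, axis=ax)
            mlo = np.roll(rmask, 1, axis=ax)
            mhi = np.roll(rmask, -1, axis=ax)
            ok = rmask & mlo & mhi & (np.abs(A1) > 0.3)
            if not ok.any():
                continue
            with np.errstate(invalid="ignore", divide="ignore"):
                cv = (lo + hi) / (2.0 * A1)
            cv = cv[ok]
            cv = cv[np.isfinite(cv) & (np.abs(cv) < 2.0)]
            if cv.size >= 5:
                cbar[ax] = complex(np.median(cv.real), np.median(cv.imag))
        active = {tuple(idx) for idx in ridx}
        for _ in range(sweep_iterations):
            if not active:
                break
            next_active = set()
            for v in sorted(active):
                preds = []
                for ax in range(3):
                    if ax not in cbar:
                        continue
                    st = tuple(int(i == ax) for i in range(3))
                    for sgn in (1, -1):
                        u = tuple(v[i] + sgn * st[i] for i in range(3))
                        w = tuple(v[i] + 2 * sgn * st[i] for i in range(3))
                        if inside(u) and inside(w) and rmask[u] and rmask[w]:
                            preds.append(2.0 * cbar[ax] * A1[u] - A1[w])
                if len(preds) < 2:
                    continue
                a1p = complex(
                    np.median([p.real for p in preds]),
                    np.median([p.imag for p in preds]),
                )
                if abs(a1p) > 8.0:  # runaway extrapolation guard, rad
                    continue
                a0 = A0_direct[v] if A0_direct is not None else 0.0
                a2p = A2_direct[v] if A2_direct is not None else A2[v]
                samples = phase[(slice(None),) + v]
                m = np.round((model(a1p, a2p, a0) - samples) / two_pi)
                corr = samples + two_pi * m
                if not np.allclose(corr, corr_vol[(slice(None),) + v]):
                    corr_vol[(slice(None),) + v] = corr
                    A1[v] = (2.0 / N) * np.dot(corr, np.conj(e1))
                    for st2 in steps:
                        nb = (v[0] + st2[0], v[1] + st2[1], v[2] + st2[2])
                        if inside(nb) and rmask[nb]:
                            next_active.add(nb)
            active = next_active
        return corr_vol

    # Region bookkeeping: per region, a handful of well-separated
    # low-amplitude candidate seeds (independent growths rarely fail
    # identically, so the per-sample median over passes is robust to a
    # single bad early decision).
    region_info = []
    for rmask in _unwrap_regions(mask, regions):
        ridx = np.argwhere(rmask)
        order = np.argsort(peak[tuple(ridx.T)], kind="stable")
        seeds = []
        for oi in order:
            cand = tuple(int(c) for c in ridx[oi])
            if all(sum(abs(cand[i] - s[i]) for i in range(3)) >= 5 for s in seeds):
                seeds.append(cand)
            if len(seeds) == n_seeds:
                break
        region_info.append((rmask, ridx, seeds))

    passes = []
    for rank in range(n_seeds):
        state = make_state()
        for rmask, ridx, seeds in region_info:
            grow(state, rmask, seeds[min(rank, len(seeds) - 1)])
        passes.append(state["corr"])
    combined = np.median(np.stack(passes), axis=0) if len(passes) >= 3 else passes[0]
    for rmask, ridx, seeds in region_info:
        combined = sweep(combined, rmask, ridx)
        sel = (slice(None),) + tuple(ridx.T)
        corrected[sel] = combined[sel]
    return corrected


def temporal_harmonics(unwrapped: np.ndarray, n_wave_phases: int | None = None):
    """First and second temporal DFT coefficients over the wave phases.

    ``unwrapped`` has shape (..., N, nx, ny, nz) with N >= 4 equally spaced
    samples over one vibration period.  Returns ``(A1, A2)`` where
    ``A_m = (2/N) sum_n phi_n exp(+i 2 pi m n / N)``; when ``m = N/2`` (the
    Nyquist bin, always the case for the second harmonic at N = 4) the 1/N
    convention is used and the coefficient is real: it carries amplitude
    information for the cosine quadrature component only.
    """
    phi = np.asarray(unwrapped, dtype=float)
    N = phi.shape[-4] if n_wave_phases is None else n_wave_phases
    if phi.shape[-4] != N:
        raise ValueError("wave-phase axis length mismatch")
    if N < 4:
        raise ValueError("need at least 4 wave phases")
    n = np.arange(N)
    shape = (N,) + (1, 1, 1)

    def coeff(m: int) -> np.ndarray:
        w = np.exp(2j * np.pi * m * n / N).reshape(shape)
        scale = (1.0 / N) if 2 * m == N else (2.0 / N)
        return scale * np.sum(phi * w, axis=-4)

    return coeff(1), coeff(2)


def phase_to_displacement(
    A1: np.ndarray,
    A2: np.ndarray,
    descriptor: AcquisitionDescriptor,
    mask: np.ndarray | None = None,
) -> ComplexWaveField:
    """Scale harmonic phase coefficients (rad) to displacement (um).

    ``U_m = A_m / xi(m f)`` with the closed-form fractional-encoding
    efficiency; the inverse of the phantom encoder in the noise-free,
    wrap-free limit.  Note the second-harmonic coefficient from 4 wave
    phases is phase-blind (Nyquist bin), so ``U2`` is a lower bound on the
    true second-harmonic amplitude.
    """
    xi1 = descriptor.encoding_efficiency(1, method="closed")
    xi2 = descriptor.encoding_efficiency(2, method="closed")
    U1 = np.asarray(A1, dtype=complex) / xi1
    U2 = np.asarray(A2, dtype=complex) / xi2
    if mask is not None:
        U1 = np.where(mask[None], U1, 0.0)
        U2 = np.where(mask[None], U2, 0.0)
    return ComplexWaveField(U1, U2, descriptor.voxel_size)


def magnitude_mask(stack: PhaseStack, rel_threshold: float = 0.5) -> np.ndarray:
    """Foreground mask from the magnitude image (relative threshold)."""
    mag = stack.magnitude
    return mag > rel_threshold * float(np.max(mag))


def reconstruct_wavefield(
    stack: PhaseStack,
    descriptor: AcquisitionDescriptor,
    mask: np.ndarray | None = None,
    regions: np.ndarray | None = None,
) -> ComplexWaveField:
    """Full chain: reference subtraction, unwrapping, DFT, scaling.

    ``regions`` (e.g. the compartment label map) is forwarded to the
    unwrapper for region-wise unwrapping.
    """
    if mask is None:
        mask = magnitude_mask(stack)
    corrected = reference_subtract(stack)
    unwrapped = model_guided_unwrap(corrected.phase, mask, regions=regions)
    A1, A2 = temporal_harmonics(unwrapped)
    return phase_to_displacement(A1, A2, descriptor, mask=mask)


# ---------------------------------------------------------------------------
# QA metrics


@dataclass
class QaMaps:
    """Wave-quality maps: displacement (um), nonlinearity (%), curl/div."""

    total_displacement: np.ndarray
    nonlinearity: np.ndarray  # percent; NaN where the fundamental vanishes
    curl_div_ratio: float  # RMS(|curl U1|) / RMS(|div U1|) over the mask
    mask: np.ndarray


def qa_metrics(field: ComplexWaveField, mask: np.ndarray) -> QaMaps:
    """Compute the acquisition QA quantities over a mask.

    * total displacement: sqrt(sum_d |U1_d|^2) per voxel, um;
    * nonlinearity: 100 * sqrt(sum_d |U2_d|^2) / total displacement, the
      percent contamination by the (destructive) second upper harmonic;
    * curl/divergence ratio: RMS of |curl U1| over RMS of |div U1| within
      the mask, quantifying shear dominance over compressional motion.
    """
    from .inversion import curl, divergence  # finite differences live there

    mask = np.asarray(mask, dtype=bool)
    total = field.total_amplitude()
    amp2 = np.sqrt(np.sum(np.abs(field.U2) ** 2, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        nonlin = np.where(total > 1e-12, 100.0 * amp2 / total, np.nan)
    q = curl(field.U1, field.voxel_size)
    d = divergence(field.U1, field.voxel_size)
    qmag2 = np.sum(np.abs(q) ** 2, axis=0)
    ratio = float(
        np.sqrt(np.mean(qmag2[mask]) / np.mean(np.abs(d[mask]) ** 2))
    )
    return QaMaps(total, nonlin, ratio, mask)


def qa_roi_summary(field: ComplexWaveField, labels: LabelMap, rois=None) -> pd.DataFrame:
    """Per-ROI QA table (one row per ROI) mirroring a scanner QA report."""
    from .roistats import DEFAULT_ROIS

    rois = rois or DEFAULT_ROIS
    rows = []
    for roi, names in rois.items():
        m = np.zeros(labels.shape, dtype=bool)
        for nm in names:
            m |= labels.mask(nm)
        if not m.any():
            raise ValueError(f"ROI '{roi}' is empty")
        qa = qa_metrics(field, m)
        nl = qa.nonlinearity[m]
        td = qa.total_displacement[m]
        rows.append(
            {
                "roi": roi,
                "n_voxels": int(m.sum()),
                "nonlinearity_mean": float(np.nanmean(nl)),
                "nonlinearity_sd": float(np.nanstd(nl, ddof=1)),
                "total_disp_mean": float(np.mean(td)),
                "total_disp_sd": float(np.std(td, ddof=1)),
                "curl_div_mean": qa.curl_div_ratio,
                "curl_div_sd": float("nan"),
            }
        )
    return pd.DataFrame(rows)
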