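"""Displacement reconstruction from wrapped motion-encoded phase."""

import numpy as np
import pytest

from renalmre.acquisition import AcquisitionDescriptor
from renalmre.fields import ComplexWaveField, PhaseStack, mechanical_groups
from renalmre.phantom import WaveSourceSpec, encode_to_phase, complex_wavenumber
from renalmre.physics import wrap_phase
from renalmre.waveproc import (
    magnitude_mask,
    model_guided_unwrap,
    phase_to_displacement,
    qa_metrics,
    qa_roi_summary,
    reconstruct_wavefield,
    reference_subtract,
    temporal_harmonics,
    unwrap_phase,
)


def _stack(phase, magnitude=None):
    mag = magnitude if magnitude is not None else np.full(phase.shape[2:], 100.0)
    return PhaseStack(phase, mag)


class TestReferenceSubtract:
    def test_identical_stacks_cancel(self):
        phase = np.random.default_rng(0).uniform(-3, 3, (4, 4, 6, 6, 4))
        phase[3] = phase[0]
        out = reference_subtract(_stack(phase))
        assert np.allclose(out.phase[0], 0.0)

    def test_constant_offset_preserved(self):
        phase = np.zeros((4, 4, 6, 6, 4))
        phase[0] = 0.3
        out = reference_subtract(_stack(phase))
        assert np.allclose(out.phase[0], 0.3)

    def test_wraparound_difference(self):
        # 3.0 - (-3.0) = 6.0 re-wraps to 6.0 - 2 pi
        phase = np.zeros((4, 4, 6, 6, 4))
        phase[0] = 3.0
        phase[3] = -3.0
        out = reference_subtract(_stack(phase))
        assert np.allclose(out.phase[0], 6.0 - 2 * np.pi)

    def test_missing_reference_rejected(self):
        stack = PhaseStack(
            np.zeros((3, 4, 6, 6, 4)), np.full((6, 6, 4), 1.0), directions=("x", "y", "z")
        )
        with pytest.raises(ValueError):
            reference_subtract(stack)


class TestSpatialUnwrap:
    def test_identity_without_wraps(self):
        vol = 0.3 * np.random.default_rng(1).standard_normal((8, 8, 6))
        mask = np.ones(vol.shape, bool)
        out = unwrap_phase(vol, mask)
        assert np.allclose(out - out[0, 0, 0] + vol[0, 0, 0], vol, atol=1e-9)

    def test_wrapped_ramp_recovered_modulo_global_offset(self):
        x = np.linspace(0, 4 * np.pi, 32)
        ramp = np.broadcast_to(x[:, None, None], (32, 6, 4)).copy()
        mask = np.ones(ramp.shape, bool)
        out = unwrap_phase(wrap_phase(ramp), mask)
        offset = out[0, 0, 0] - ramp[0, 0, 0]
        assert offset / (2 * np.pi) == pytest.approx(round(offset / (2 * np.pi)), abs=1e-9)
        assert np.allclose(out - offset, ramp, atol=1e-9)

    def test_output_congruent_to_input(self):
        rng = np.random.default_rng(2)
        vol = np.cumsum(rng.uniform(-1, 1, (16, 8, 4)), axis=0)
        mask = np.ones(vol.shape, bool)
        out = unwrap_phase(wrap_phase(vol), mask)
        m = (out - wrap_phase(vol)) / (2 * np.pi)
        assert np.allclose(m, np.round(m), atol=1e-9)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            unwrap_phase(np.zeros((4, 4, 4)), np.zeros((4, 4, 4), bool))


class TestModelGuidedUnwrap:
    def test_recovers_wave_beyond_spatial_nyquist(self):
        # 4.5 rad amplitude at ~7.7 voxels/wavelength: neighbour steps of
        # the wrapped data exceed pi, where plain spatial unwrapping fails
        nx, ny, nz = 16, 16, 8
        k = complex_wavenumber(680 + 470j)
        z = np.arange(nz) * 2.5e-3
        up = np.exp(1j * k * (z - z[-1]))
        dn = 0.8 * np.exp(-1j * k * (z - z[0]) + 0.9j)
        A1 = 4.5 * (up + dn)[None, None, :] * np.ones((nx, ny, 1))
        true = np.stack(
            [np.real(A1 * np.exp(-2j * np.pi * n / 4)) for n in range(4)]
        )
        mask = np.ones((nx, ny, nz), bool)
        out = model_guided_unwrap(wrap_phase(true), mask)
        assert np.allclose(out, true, atol=1e-9)

    def test_output_congruent_to_input(self, tiny_phantom, tiny_field, tiny_descriptor):
        labels = tiny_phantom[0]
        stack = encode_to_phase(tiny_field, tiny_descriptor, noise_sd=0.03, seed=5,
                                magnitude=10.0 + 90.0 * (labels.data > 0))
        corrected = reference_subtract(stack)
        out = model_guided_unwrap(
            corrected.phase, labels.data > 0, regions=mechanical_groups(labels)
        )
        m = (out - corrected.phase) / (2 * np.pi)
        sel = np.broadcast_to((labels.data > 0), out.shape)
        assert np.allclose(m[sel], np.round(m[sel]), atol=1e-9)


class TestTemporalHarmonics:
    def test_pure_fundamental(self):
        phi = np.array([1.0, 0.0, -1.0, 0.0]).reshape(4, 1, 1, 1)
        A1, A2 = temporal_harmonics(phi)
        assert abs(A1[0, 0, 0]) == pytest.approx(1.0, abs=1e-12)
        assert abs(A2[0, 0, 0]) == pytest.approx(0.0, abs=1e-12)

    def test_pure_second_harmonic_is_nyquist_bin(self):
        phi = np.array([1.0, -1.0, 1.0, -1.0]).reshape(4, 1, 1, 1)
        A1, A2 = temporal_harmonics(phi)
        assert abs(A1[0, 0, 0]) == pytest.approx(0.0, abs=1e-12)
        assert abs(A2[0, 0, 0]) == pytest.approx(1.0, abs=1e-12)

    def test_harmonic_mixture_ratio(self):
        t = np.arange(4) / 4.0
        phi = (np.cos(2 * np.pi * t) + 0.25 * np.cos(4 * np.pi * t)).reshape(4, 1, 1, 1)
        A1, A2 = temporal_harmonics(phi)
        assert abs(A2[0, 0, 0]) / abs(A1[0, 0, 0]) == pytest.approx(0.25, abs=1e-12)

    def test_matches_direct_dft_summation(self):
        rng = np.random.default_rng(3)
        phi = rng.standard_normal((4, 5, 5, 3))
        A1, A2 = temporal_harmonics(phi)
        n = np.arange(4)
        direct1 = (2 / 4) * np.tensordot(np.exp(2j * np.pi * n / 4), phi, axes=(0, 0))
        direct2 = (1 / 4) * np.tensordot(np.exp(4j * np.pi * n / 4), phi, axes=(0, 0))
        assert np.allclose(A1, direct1, atol=1e-12)
        assert np.allclose(A2, direct2, atol=1e-12)

    def test_linearity(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal((4, 3, 3, 3))
        b = rng.standard_normal((4, 3, 3, 3))
        A1ab, _ = temporal_harmonics(a + 2 * b)
        A1a, _ = temporal_harmonics(a)
        A1b, _ = temporal_harmonics(b)
        assert np.allclose(A1ab, A1a + 2 * A1b, atol=1e-12)

    def test_too_few_wave_phases_rejected(self):
        with pytest.raises(ValueError):
            temporal_harmonics(np.zeros((3, 2, 2, 2)))


class TestPhaseToDisplacement:
    def test_zero_coefficients_give_zero_displacement(self, descriptor):
        Z = np.zeros((3, 4, 4, 4), complex)
        field = phase_to_displacement(Z, Z, descriptor)
        assert np.all(field.U1 == 0)

    def test_doubling_meg_amplitude_halves_displacement(self, descriptor):
        import dataclasses

        A1 = np.full((3, 2, 2, 2), 1.0 + 0.5j)
        A2 = np.zeros_like(A1)
        d2 = dataclasses.replace(descriptor, meg_amplitude=2 * descriptor.meg_amplitude)
        U_strong = phase_to_displacement(A1, A2, d2).U1
        U_weak = phase_to_displacement(A1, A2, descriptor).U1
        assert np.allclose(U_strong, U_weak / 2.0, rtol=1e-12)

    def test_encode_decode_roundtrip_on_phantom(self, tiny_phantom, tiny_field, tiny_descriptor):
        labels = tiny_phantom[0]
        kidney = labels.data > 0
        stack = encode_to_phase(
            tiny_field, tiny_descriptor, noise_sd=0.0,
            magnitude=10.0 + 90.0 * kidney,
        )
        rec = reconstruct_wavefield(
            stack, tiny_descriptor, regions=mechanical_groups(labels)
        )
        err = np.sqrt(
            np.mean(np.abs(rec.U1 - tiny_field.U1)[:, kidney] ** 2)
            / np.mean(np.abs(tiny_field.U1)[:, kidney] ** 2)
        )
        assert err < 0.01


class TestQaMetrics:
    def test_pure_fundamental_has_zero_nonlinearity(self, tiny_field):
        field = ComplexWaveField(tiny_field.U1, np.zeros_like(tiny_field.U2), tiny_field.voxel_size)
        qa = qa_metrics(field, np.abs(field.U1[0]) >= 0)
        m = field.total_amplitude() > 1e-9
        assert np.allclose(qa.nonlinearity[m], 0.0)

    def test_invariant_under_global_phase_rotation(self, tiny_field, tiny_phantom):
        mask = tiny_phantom[0].data > 0
        rot = np.exp(0.7j)
        rotated = ComplexWaveField(
            tiny_field.U1 * rot, tiny_field.U2 * rot, tiny_field.voxel_size
        )
        qa0 = qa_metrics(tiny_field, mask)
        qa1 = qa_metrics(rotated, mask)
        assert np.allclose(qa1.total_displacement, qa0.total_displacement)
        assert qa1.curl_div_ratio == pytest.approx(qa0.curl_div_ratio, rel=1e-9)

    def test_nonlinearity_equals_configured_fraction(self, tiny_field, tiny_phantom):
        mask = tiny_phantom[0].data > 0
        qa = qa_metrics(tiny_field, mask)
        assert np.nanmean(qa.nonlinearity[mask]) == pytest.approx(23.0, abs=0.01)

    def test_total_displacement_matches_drive_amplitude(self, tiny_field, tiny_phantom):
        mask = tiny_phantom[0].data > 0
        qa = qa_metrics(tiny_field, mask)
        assert qa.total_displacement[mask].mean() == pytest.approx(163.0, rel=1e-6)

    def test_roi_summary_mirrors_scanner_qa_table(self, tiny_field, tiny_phantom):
        labels = tiny_phantom[0]
        rois = {"kidneys": ("cortex", "sinus"), "cortex": ("cortex",), "sinus": ("sinus",)}
        table = qa_roi_summary(tiny_field, labels, rois=rois)
        assert list(table.columns) == [
            "roi", "n_voxels", "nonlinearity_mean", "nonlinearity_sd",
            "total_disp_mean", "total_disp_sd", "curl_div_mean", "curl_div_sd",
        ]
        kid = table.set_index("roi").loc["kidneys"]
        assert kid["n_voxels"] == int((labels.data > 0).sum())
        assert kid["nonlinearity_mean"] == pytest.approx(23.0, abs=0.01)


def test_magnitude_mask_thresholds_foreground(tiny_field, tiny_phantom, tiny_descriptor):
    labels = tiny_phantom[0]
    stack = encode_to_phase(
        tiny_field, tiny_descriptor, magnitude=10.0 + 90.0 * (labels.data > 0)
    )
    assert np.array_equal(magnitude_mask(stack), labels.data > 0)
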