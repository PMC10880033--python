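"""Digital kidney phantom: geometry, moduli, synthesis and encoding."""

import dataclasses

import numpy as np
import pytest

from renalmre.acquisition import AcquisitionDescriptor
from renalmre.fields import LABELS
from renalmre.inversion import curl, divergence, laplacian
from renalmre.phantom import (
    DEFAULT_MODULI,
    KidneyGeometry,
    TissueProperties,
    WaveSource,
    WaveSourceSpec,
    assign_moduli,
    build_kidney_phantom,
    encode_to_phase,
    ground_truth_maps,
    read_phantom,
    synthesize_wavefield,
    write_phantom,
)
from renalmre.roistats import erode_mask


class TestGeometry:
    def test_compartment_counts_ordered_like_renal_anatomy(self, demo_phantom):
        # cortex is the largest structure, vessels the smallest
        counts = demo_phantom[0].counts()
        assert (
            counts["cortex"] > counts["medulla"] > counts["sinus"] > counts["vessel"]
        )

    def test_sub_compartments_partition_the_kidney(self, demo_phantom):
        counts = demo_phantom[0].counts()
        assert (
            counts["cortex"] + counts["medulla"] + counts["sinus"] + counts["vessel"]
            == counts["kidney"]
        )

    def test_zero_radius_kidney_is_rejected(self, descriptor):
        geom = dataclasses.replace(KidneyGeometry(), kidney_semi=(0.0, 35.0, 55.0))
        with pytest.raises(ValueError):
            build_kidney_phantom(descriptor, geom)

    def test_empty_compartment_error_names_it(self, descriptor):
        geom = dataclasses.replace(KidneyGeometry(), vessel_semi=(0.1, 0.1, 0.1))
        with pytest.raises(ValueError, match="vessel"):
            build_kidney_phantom(descriptor, geom)

    def test_every_kidney_voxel_carries_exactly_one_sublabel(self, demo_phantom):
        labels = demo_phantom[0]
        kidney = labels.data > 0
        sub = sum(labels.mask(n) for n in ("cortex", "medulla", "sinus", "vessel"))
        assert np.array_equal(sub[kidney], np.ones(kidney.sum(), dtype=int))


class TestModuli:
    def test_cortex_complex_modulus_in_pa(self, demo_phantom):
        labels, G, _ = demo_phantom
        cortex_values = G[labels.mask("cortex")]
        assert np.allclose(cortex_values, 680 + 480j)

    def test_background_is_undefined(self, demo_phantom):
        labels, G, _ = demo_phantom
        assert np.isnan(G[labels.data == 0].real).all()

    def test_empty_table_rejected(self, demo_phantom):
        with pytest.raises(ValueError):
            assign_moduli(demo_phantom[0], ())

    def test_missing_label_rejected(self, demo_phantom):
        with pytest.raises(ValueError, match="medulla"):
            assign_moduli(demo_phantom[0], (TissueProperties("cortex", 0.68, 0.48),))

    def test_zero_loss_modulus_gives_real_modulus(self, demo_phantom):
        labels = demo_phantom[0]
        table = tuple(
            TissueProperties(t.label, t.G_d, 0.0) for t in DEFAULT_MODULI
        )
        G = assign_moduli(labels, table)
        assert np.all(G[labels.data > 0].imag == 0)

    def test_tissue_properties_validation(self):
        with pytest.raises(ValueError):
            TissueProperties("x", -1.0, 0.1)
        with pytest.raises(ValueError):
            TissueProperties("x", 1.0, -0.1)


class TestWaveSource:
    def test_shear_polarization_must_be_transverse(self):
        with pytest.raises(ValueError):
            WaveSource((0, 0, 1), (0, 0.1, 1), 10.0, mode="shear")

    def test_compressional_polarization_must_be_longitudinal(self):
        with pytest.raises(ValueError):
            WaveSource((1, 0, 0), (0, 1, 0), 10.0, mode="compressional")


class TestSynthesis:
    def test_kidney_mean_total_displacement_equals_amplitude_quadrature_sum(
        self, demo_phantom, descriptor
    ):
        labels, G, _ = demo_phantom
        spec = WaveSourceSpec(noise_sd=0.0)
        field = synthesize_wavefield(labels, G, spec, descriptor)
        mean_tot = field.total_amplitude()[labels.data > 0].mean()
        assert mean_tot == pytest.approx(spec.target_amplitude_um(), rel=1e-9)

    def test_second_harmonic_is_a_fixed_local_fraction(self, demo_phantom, descriptor):
        labels, G, _ = demo_phantom
        field = synthesize_wavefield(labels, G, WaveSourceSpec(noise_sd=0.0), descriptor)
        kidney = labels.data > 0
        a1 = np.sqrt(np.sum(np.abs(field.U1) ** 2, axis=0))[kidney]
        a2 = np.sqrt(np.sum(np.abs(field.U2) ** 2, axis=0))[kidney]
        assert np.allclose(a2, 0.23 * a1)

    def test_zero_amplitude_source_gives_zero_field(self, demo_phantom, descriptor):
        labels, G, _ = demo_phantom
        spec = WaveSourceSpec(
            sources=(WaveSource((0, 0, 1), (1, 0, 0), 0.0),),
            second_harmonic_fraction=0.0,
            noise_sd=0.0,
        )
        field = synthesize_wavefield(labels, G, spec, descriptor)
        assert np.all(field.U1 == 0) and np.all(field.U2 == 0)

    def test_shear_field_is_divergence_free_on_interiors(
        self, demo_phantom, descriptor, shear_only_spec
    ):
        labels, G, _ = demo_phantom
        field = synthesize_wavefield(labels, G, shear_only_spec, descriptor)
        inner = np.zeros(labels.shape, bool)
        for name in ("cortex", "medulla", "sinus", "vessel"):
            inner |= erode_mask(labels.mask(name), 2)
        q = curl(field.U1, descriptor.voxel_size)
        dv = divergence(field.U1, descriptor.voxel_size)
        ratio = np.sqrt(
            np.mean(np.abs(dv[inner]) ** 2)
            / np.mean(np.sum(np.abs(q) ** 2, axis=0)[inner])
        )
        assert ratio < 1e-6

    def test_compressional_field_is_curl_free_to_fd_truncation(
        self, demo_phantom, descriptor, compressional_only_spec
    ):
        # an oblique long-wavelength wave has a discrete-curl residual of
        # order (k h)^3 from the odd truncation of central differences
        labels, G, _ = demo_phantom
        field = synthesize_wavefield(labels, G, compressional_only_spec, descriptor)
        inner = np.zeros(labels.shape, bool)
        for name in ("cortex", "medulla", "sinus", "vessel"):
            inner |= erode_mask(labels.mask(name), 2)
        q = curl(field.U1, descriptor.voxel_size)
        dv = divergence(field.U1, descriptor.voxel_size)
        ratio = np.sqrt(
            np.mean(np.sum(np.abs(q) ** 2, axis=0)[inner])
            / np.mean(np.abs(dv[inner]) ** 2)
        )
        assert ratio < 2e-3

    def test_helmholtz_equation_holds_on_compartment_interiors(
        self, demo_phantom, descriptor
    ):
        labels, G, _ = demo_phantom
        from renalmre.phantom import default_sources

        spec = WaveSourceSpec(
            sources=tuple(s for s in default_sources() if s.mode == "shear"),
            second_harmonic_fraction=0.0,
            noise_sd=0.0,
        )
        field = synthesize_wavefield(labels, G, spec, descriptor)
        lap = laplacian(field.U1, descriptor.voxel_size, order=6)
        w2rho = descriptor.rho * descriptor.omega**2
        num = den = 0.0
        for name in ("cortex", "medulla", "sinus", "vessel"):
            m = erode_mask(labels.mask(name), 2)
            Gc = G[labels.mask(name)][0]
            num += np.sum(np.abs(Gc * lap[:, m] + w2rho * field.U1[:, m]) ** 2)
            den += np.sum(np.abs(w2rho * field.U1[:, m]) ** 2)
        assert np.sqrt(num / den) < 0.02

    def test_synthesis_is_linear_in_source_amplitudes(self, tiny_phantom, tiny_descriptor):
        labels, G, _ = tiny_phantom
        base = WaveSourceSpec(noise_sd=0.0)
        doubled = WaveSourceSpec(
            sources=tuple(
                dataclasses.replace(s, amplitude_um=2 * s.amplitude_um)
                for s in base.sources
            ),
            second_harmonic_fraction=base.second_harmonic_fraction,
            noise_sd=0.0,
        )
        f1 = synthesize_wavefield(labels, G, base, tiny_descriptor)
        f2 = synthesize_wavefield(labels, G, doubled, tiny_descriptor)
        assert np.allclose(f2.U1, 2 * f1.U1, rtol=1e-9, atol=1e-9)


class TestEncoding:
    def test_zero_displacement_zero_noise_gives_zero_phase(
        self, tiny_phantom, tiny_descriptor
    ):
        labels, G, _ = tiny_phantom
        spec = WaveSourceSpec(
            sources=(WaveSource((0, 0, 1), (1, 0, 0), 0.0),),
            second_harmonic_fraction=0.0,
            noise_sd=0.0,
        )
        field = synthesize_wavefield(labels, G, spec, tiny_descriptor)
        stack = encode_to_phase(field, tiny_descriptor, static_background=False)
        assert np.all(stack.phase == 0.0)

    def test_encoded_phase_linear_in_amplitude_below_wrap(
        self, tiny_phantom, tiny_descriptor
    ):
        labels, G, _ = tiny_phantom
        from renalmre.phantom import default_sources

        f1 = synthesize_wavefield(
            labels, G, WaveSourceSpec(sources=default_sources(20.0), noise_sd=0.0),
            tiny_descriptor,
        )
        f2 = synthesize_wavefield(
            labels, G, WaveSourceSpec(sources=default_sources(40.0), noise_sd=0.0),
            tiny_descriptor,
        )
        s1 = encode_to_phase(f1, tiny_descriptor, static_background=False)
        s2 = encode_to_phase(f2, tiny_descriptor, static_background=False)
        assert np.allclose(s2.phase, 2 * s1.phase, rtol=1e-9, atol=1e-9)

    def test_reference_stack_carries_no_motion_phase(self, tiny_field, tiny_descriptor):
        stack = encode_to_phase(tiny_field, tiny_descriptor, static_background=False)
        assert np.all(stack.phase[3] == 0.0)

    def test_fixed_seed_is_bit_reproducible(self, tiny_field, tiny_descriptor):
        s1 = encode_to_phase(tiny_field, tiny_descriptor, noise_sd=0.05, seed=3)
        s2 = encode_to_phase(tiny_field, tiny_descriptor, noise_sd=0.05, seed=3)
        assert np.array_equal(s1.phase, s2.phase)

    def test_phases_are_wrapped(self, tiny_field, tiny_descriptor):
        stack = encode_to_phase(tiny_field, tiny_descriptor, noise_sd=0.05, seed=1)
        assert np.all(stack.phase > -np.pi) and np.all(stack.phase <= np.pi)


class TestOnDisk:
    def test_roundtrip(self, tiny_phantom, tiny_field, tiny_descriptor, tmp_path):
        labels, G, truth = tiny_phantom
        stack = encode_to_phase(
            tiny_field, tiny_descriptor, noise_sd=0.05, seed=11,
            magnitude=10.0 + 90.0 * (labels.data > 0),
        )
        write_phantom(
            stack, labels, truth, tiny_descriptor, tmp_path / "ph", meta={"seed": 11}
        )
        stack2, labels2, truth2, desc2, meta = read_phantom(tmp_path / "ph")
        assert np.array_equal(labels2.data, labels.data)  # bit-identical labels
        assert np.allclose(stack2.phase, stack.phase, atol=1e-6)  # float32 rounding
        assert meta["seed"] == 11
        assert desc2.grid_shape == tiny_descriptor.grid_shape
        assert np.allclose(
            truth2.gd_kpa[labels.data > 0], truth.gd_kpa[labels.data > 0], atol=1e-6
        )

    def test_grid_mismatch_rejected(self, tiny_phantom, tiny_field, tiny_descriptor, tmp_path, demo_phantom, descriptor):
        stack = encode_to_phase(tiny_field, tiny_descriptor)
        labels_demo, _, truth_demo = demo_phantom
        with pytest.raises(ValueError):
            write_phantom(stack, labels_demo, truth_demo, descriptor, tmp_path / "x")
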