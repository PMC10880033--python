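"""Shared fixtures: small phantoms with known ground truth."""

import numpy as np
import pytest

from renalmre.acquisition import AcquisitionDescriptor
from renalmre.phantom import (
    DEFAULT_MODULI,
    TINY_GEOMETRY,
    WaveSource,
    WaveSourceSpec,
    assign_moduli,
    build_kidney_phantom,
    default_sources,
    ground_truth_maps,
    synthesize_wavefield,
)


@pytest.fixture(scope="session")
def descriptor():
    return AcquisitionDescriptor()


@pytest.fixture(scope="session")
def tiny_descriptor():
    return AcquisitionDescriptor(grid_shape=(24, 24, 8))


@pytest.fixture(scope="session")
def tiny_phantom(tiny_descriptor):
    """Two-compartment 24x24x8 phantom: labels, moduli and truth maps."""
    labels = build_kidney_phantom(tiny_descriptor, TINY_GEOMETRY)
    moduli = tuple(t for t in DEFAULT_MODULI if t.label in ("cortex", "sinus"))
    G = assign_moduli(labels, moduli)
    truth = ground_truth_maps(G, tiny_descriptor)
    return labels, G, truth


@pytest.fixture(scope="session")
def tiny_field(tiny_phantom, tiny_descriptor):
    labels, G, _ = tiny_phantom
    spec = WaveSourceSpec(noise_sd=0.0)
    return synthesize_wavefield(labels, G, spec, tiny_descriptor)


@pytest.fixture(scope="session")
def demo_phantom(descriptor):
    """Five-label 64x54x8 phantom (no encoding; cheap to build)."""
    labels = build_kidney_phantom(descriptor)
    G = assign_moduli(labels)
    truth = ground_truth_maps(G, descriptor)
    return labels, G, truth


@pytest.fixture(scope="session")
def shear_only_spec():
    """A single through-slab shear plane wave, no harmonics or noise."""
    return WaveSourceSpec(
        sources=(WaveSource((0.0, 0.0, 1.0), (1.0, 0.0, 0.0), 100.0),),
        second_harmonic_fraction=0.0,
        noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def compressional_only_spec():
    n = (np.cos(np.deg2rad(70.0)), np.sin(np.deg2rad(70.0)), 0.0)
    return WaveSourceSpec(
        sources=(WaveSource(n, n, 100.0, mode="compressional"),),
        second_harmonic_fraction=0.0,
        noise_sd=0.0,
    )
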