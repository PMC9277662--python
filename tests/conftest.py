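import numpy as np
import pytest

from sbmech.synthetic import (
    LayerMaterial,
    SpecimenGeometry,
    make_protocol,
    simulate_response,
)


@pytest.fixture(scope="session")
def geometry():
    return SpecimenGeometry(diameter=6.66, flat_cut_chord=4.95, height=10.0)


@pytest.fixture(scope="session")
def palmar_protocol():
    return make_protocol("palmar")


@pytest.fixture(scope="session")
def two_layer_record(palmar_protocol, geometry):
    """Noiseless two-layer dissipative record with known truth."""
    layers = [
        LayerMaterial(2.0, 5000.0, 0.30, 1e-4, 0.5),
        LayerMaterial(2.0, 9000.0, 0.15, 1e-4, 0.5),
    ]
    record, truth = simulate_response(
        palmar_protocol, geometry, layers, remainder_modulus=7000.0,
        noise_sd=0.0, seed=11,
    )
    return record, truth


@pytest.fixture(scope="session")
def reversible_record(palmar_protocol, geometry):
    """Loss-free, residual-free record: every loop closes exactly."""
    layers = [LayerMaterial(2.0, 5000.0), LayerMaterial(2.0, 9000.0)]
    record, truth = simulate_response(
        palmar_protocol, geometry, layers, remainder_modulus=7000.0,
        noise_sd=0.0, seed=0,
    )
    return record, truth


def sine_record(geometry, periods=3.5, frequency=2.0, fs=500.0, modulus=3000.0):
    """Plain sinusoidal stress record without preload, for segmentation tests."""
    from sbmech.mechanics import LoadDisplacementRecord

    t = np.arange(0.0, periods / frequency, 1.0 / fs)
    stress = 20.5 - 19.5 * np.cos(2 * np.pi * frequency * t)
    area = geometry.cross_section_area
    return LoadDisplacementRecord(
        time=t, load=stress * area,
        displacement=stress / modulus * geometry.height,
        sampling_rate=fs, geometry=geometry, reference_length=geometry.height,
    )
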