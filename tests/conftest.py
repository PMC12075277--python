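import numpy as np
import pytest

from cartmap import CreepCurve, MaterialState, STUDY_PROTOCOL, forward_creep


@pytest.fixture(scope="session")
def protocol():
    return STUDY_PROTOCOL


@pytest.fixture(scope="session")
def healthy_material():
    """A representative healthy sample: mid-range modulus, fast-draining k."""
    return MaterialState(eq_modulus_mpa=0.5, permeability_m4_ns=1e-15,
                         thickness_mm=0.7)


@pytest.fixture(scope="session")
def clean_curve(healthy_material, protocol):
    return forward_creep(healthy_material, protocol)


@pytest.fixture
def noisy_curve_factory(protocol):
    """Factory: noiseless forward curve + seeded Gaussian instrument noise."""

    def make(material: MaterialState, sigma_um: float = 0.5, seed: int = 0):
        clean = forward_creep(material, protocol)
        rng = np.random.default_rng(seed)
        return CreepCurve(
            time_s=clean.time_s,
            deformation_um=clean.deformation_um
            + rng.normal(0.0, sigma_um, clean.n_points),
            protocol=protocol,
        )

    return make
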