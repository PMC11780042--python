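import numpy as np
import pytest

from compositia import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def phantom_pair():
    """One deterministic default-geometry phantom."""
    return generate_phantom(PhantomSpec(seed=7, subject_id="fixture"))


@pytest.fixture(scope="session")
def small_phantoms():
    """Eight small, quick phantoms for smoke tests."""
    from compositia import generate_dataset

    base = PhantomSpec(shape=(64, 64, 80), body_rx=23.0, body_ry=19.0,
                       sat_thickness=3.5, muscle_thickness=2.5, spine_radius=5.5,
                       vertebra_height=8, disc_gap=2, rib_length=7.0)
    return generate_dataset(8, seed=11, base=base)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
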