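"""Shared fixtures: phantom datasets and a trained system C.

Training a three-pipeline system on phantoms takes a couple of minutes, so
it happens once per session; phantoms are rendered at 360x480 px (the
generator adapts pixel sizes within the clinical range so heads still fit).
"""

import numpy as np
import pytest

from fetalhc import generate_dataset, measure_hc, synthetic_growth_curve, train_system

PHANTOM_SHAPE = (360, 480)


@pytest.fixture(scope="session")
def growth_curve():
    return synthetic_growth_curve()


@pytest.fixture(scope="session")
def train_phantoms():
    return generate_dataset(18, (1, 1, 1), seed=42, shape=PHANTOM_SHAPE)


@pytest.fixture(scope="session")
def system_c_models(train_phantoms):
    imgs = [s.image for s in train_phantoms]
    anns = {s.image.id: s.annotation for s in train_phantoms}
    ga = {s.image.id: s.ga_days for s in train_phantoms}
    return train_system(imgs, anns, ga, system="C", seed=7)


@pytest.fixture(scope="session")
def test_phantoms():
    return generate_dataset(20, (1, 1, 1), seed=4242, shape=PHANTOM_SHAPE)


@pytest.fixture(scope="session")
def system_c_measurements(system_c_models, test_phantoms):
    """measure_hc of system C on the 20 held-out mixed-trimester phantoms."""
    return [(s, measure_hc(s.image, system_c_models, system="C")) for s in test_phantoms]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
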