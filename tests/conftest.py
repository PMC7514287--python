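"""Shared fixtures: small synthetic cohorts and handcrafted grids."""

import numpy as np
import pytest

from sigentropy.records import RawChannel, SignatureRecord
from sigentropy.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_ad=4, n_hc=4, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size cohort (31 AD / 39 HC) for statistics-level tests."""
    return generate_cohort(SimulationConfig(seed=5))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240925)


def make_signature(
    subject_id="S01",
    instance=1,
    n=64,
    seed=0,
    sampling_rate=125.0,
) -> SignatureRecord:
    """A minimal valid signature with nontrivial channels."""
    r = np.random.default_rng(seed)
    t = np.arange(n)
    channels = {
        "x": RawChannel("x", np.sin(t / 5.0) + 0.1 * r.standard_normal(n)),
        "y": RawChannel("y", np.cos(t / 7.0) + 0.1 * r.standard_normal(n)),
        "p": RawChannel("p", np.abs(100 + 20 * r.standard_normal(n))),
        "Az": RawChannel("Az", 900 + r.standard_normal(n)),
        "Alt": RawChannel("Alt", 600 + 5 * r.standard_normal(n)),
    }
    return SignatureRecord(subject_id, instance, channels, sampling_rate)
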