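import numpy as np
import pytest

from kardia.io import RRSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def constant_series():
    return RRSeries(intervals=np.full(400, 800.0), subject_id="const")


def make_sinusoid(n=600, mean=850.0, amp=60.0, step=0.7, phase=0.0):
    """RR series sampling a limit cycle: phase step in rad/beat,
    incommensurate with 2*pi so the closed curve is covered densely."""
    k = np.arange(n)
    return RRSeries(intervals=mean + amp * np.sin(step * k + phase),
                    subject_id="limit-cycle")


def make_torus(n=1200, mean=850.0, amp=40.0, step=0.7):
    """RR series on a 2-torus: two incommensurate frequencies (ratio = golden)."""
    k = np.arange(n)
    golden = (1 + np.sqrt(5)) / 2
    return RRSeries(
        intervals=mean + amp * np.sin(step * k) + amp * np.sin(step * golden * k),
        subject_id="torus",
    )


def make_noise(n=400, mean=850.0, sd=30.0, seed=42):
    g = np.random.default_rng(seed)
    return RRSeries(intervals=mean + sd * g.standard_normal(n),
                    subject_id="noise")


@pytest.fixture
def sinusoid_series():
    return make_sinusoid()


@pytest.fixture
def torus_series():
    return make_torus()


@pytest.fixture
def noise_series():
    return make_noise()
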