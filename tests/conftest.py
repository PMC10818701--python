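import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from falldetect import Recording, run_comparison

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def build_recording(n=100, seed=0, participant_id="P00", labels=None, dt=0.1):
    """A valid noisy standing recording of n samples."""
    rng = np.random.default_rng(seed)
    return Recording(
        participant_id=participant_id,
        t=dt * np.arange(n),
        ax=rng.normal(0, 0.02, n),
        ay=rng.normal(0, 0.02, n),
        az=1.0 + rng.normal(0, 0.02, n),
        pitch=rng.normal(0, 2, n).clip(-90, 90),
        roll=rng.normal(0, 2, n).clip(-180, 180),
        labels=np.zeros(n, dtype=int) if labels is None else labels,
        sampling_interval=dt,
    )


@pytest.fixture
def recording():
    return build_recording()


@pytest.fixture(scope="session")
def cohort_comparison():
    """The full 30-participant, 25/5-split comparison at seed 1.

    Session-scoped: simulating, calibrating and training once (~1 min) and
    sharing the result across the end-to-end assertions.
    """
    return run_comparison(n_participants=30, n_train=25, seed=1)
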