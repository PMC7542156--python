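import numpy as np
import pytest

from sibdetect.preprocess import Window
from sibdetect.synthetic import CohortSpec, ParticipantProfile, generate_session


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def profile():
    return ParticipantProfile(
        participant_id="P1",
        sib_frequency_hz=3.0,
        sib_amplitude_g=1.0,
        baseline_activity_scale=0.15,
        episode_rate_per_min=2.0,
        episode_duration_range_s=(2.0, 6.0),
    )


@pytest.fixture(scope="session")
def session(profile):
    return generate_session(profile, duration_s=60.0, rate_hz=60.0, seed=7)


@pytest.fixture(scope="session")
def small_cohort_spec():
    profiles = tuple(
        ParticipantProfile(
            participant_id=f"P{j + 1}",
            sib_frequency_hz=2.0 + j,
            sib_amplitude_g=0.9,
            baseline_activity_scale=0.15,
            episode_rate_per_min=2.5,
            episode_duration_range_s=(2.0, 5.0),
        )
        for j in range(3)
    )
    return CohortSpec(profiles=profiles, session_duration_s=60.0, seed=11)


def make_window(raw: np.ndarray, rate_hz: float = 60.0, outcome: int = 0) -> Window:
    """Build a Window whose raw and filtered content are the given array."""
    raw = np.asarray(raw, dtype=float)
    if raw.ndim == 1:
        raw = np.column_stack([raw, raw, raw])
    return Window(
        participant_id="T", start_s=0.0, filtered=raw.copy(), raw=raw,
        outcome=outcome, prompt=0,
    )
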