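import numpy as np
import pytest

from emgsleep import (
    BinaryHypnogram,
    Channel,
    Cohort,
    CohortItem,
    Recording,
    SyntheticSpec,
    simulate_night,
)


@pytest.fixture(scope="session")
def small_night():
    """One short synthetic night: 40 epochs at 250 Hz."""
    spec = SyntheticSpec(duration_epochs=40, target_se=90.0, seed=42)
    rec, binary, stages = simulate_night(spec)
    return rec, binary, stages


@pytest.fixture(scope="session")
def small_cohort():
    """Three short synthetic subjects with strong sleep/wake contrast."""
    items = []
    for i in range(3):
        spec = SyntheticSpec(duration_epochs=40, target_se=85.0, seed=100 + i)
        rec, binary, _ = simulate_night(spec)
        rec.subject_id = f"s{i}"
        items.append(CohortItem(rec, binary, None, f"s{i}"))
    return Cohort(items)


def random_recording(rng, n_epochs=2, fs=200, n_channels=1):
    """White-noise recording helper for property tests (fs > 150 for FDA)."""
    n = n_epochs * fs * 30
    channels = [
        Channel(f"ch{i}", rng.standard_normal(n)) for i in range(n_channels)
    ]
    return Recording(channels, fs, subject_id="rand")


def random_binary(rng, n):
    return BinaryHypnogram(
        [("SLEEP", "WAKE")[i] for i in rng.integers(0, 2, size=n)]
    )
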