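import numpy as np
import pytest

from spikeval import SimulationSpec, simulate_recording


def brute_force_matches(gt_times, sorted_times, delta) -> int:
    """O(N*M) literal evaluation of the tolerance-window match count."""
    return sum(
        1 for t in gt_times if any(abs(t - s) <= delta for s in sorted_times)
    )


@pytest.fixture(scope="session")
def small_recording():
    """Seeded 4-channel, 3-unit, 60 s recording shared across tests."""
    spec = SimulationSpec(
        num_channels=4,
        num_units=3,
        duration_s=60.0,
        firing_rates=[6.0, 6.0, 6.0],
        target_snrs=[6.0, 9.0, 12.0],
        seed=42,
    )
    recording, firings = simulate_recording(spec)
    return spec, recording, firings


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
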