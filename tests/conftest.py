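import numpy as np
import pytest

from axodyne.profiles import SimConfig, TransportProfile, get_profile


@pytest.fixture(scope="session")
def wt():
    return get_profile("WT")


@pytest.fixture(scope="session")
def asyn():
    return get_profile("aSyn")


@pytest.fixture()
def sim():
    """Default acquisition: 1 Hz, 6 min, 50-μm segment, 0.2 μm/px."""
    return SimConfig()


@pytest.fixture()
def quiet_sim():
    """Noise-free acquisition for deterministic fixtures."""
    return SimConfig(noise_sigma=0.0)


def make_transport_profile(**overrides) -> TransportProfile:
    """A consistent transport profile with selective overrides."""
    base = dict(
        motile_fraction=0.274,
        anterograde_run_speed_mean=0.56,
        anterograde_run_speed_sd=0.21,
        retrograde_run_speed_mean=0.57,
        retrograde_run_speed_sd=0.25,
        mean_run_duration=8.0,
        mean_pause_duration=5.617,
        prob_next_run_retrograde=0.3797,
        target_time_fraction_paused=0.4125,
    )
    base.update(overrides)
    return TransportProfile(**base)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
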