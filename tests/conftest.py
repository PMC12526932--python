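import pytest

from audiotactile.paradigm import generate_schedule
from audiotactile.profiles import DeviceProfile, bundled_profile


@pytest.fixture(scope="session")
def perfect_profile() -> DeviceProfile:
    """Idealized handset: zero latencies and zero sensor noise."""
    return DeviceProfile(
        name="perfect",
        accel_rate_hz=500.0,
        touch_rate_hz=120.0,
        audio_latency_ms=(0.0, 0.0),
        vib_latency_ms=(0.0, 0.0),
        touch_pipeline_latency_ms=(0.0, 0.0),
        accel_noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def pixel_profile() -> DeviceProfile:
    return bundled_profile("pixel_2_xl")


@pytest.fixture(scope="session")
def default_schedule():
    """The standard 6-block, 432-trial session."""
    return generate_schedule(n_blocks=6, seed=11)
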