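"""Device profiles: declared sensor rates, latencies and audio feature flags.

A :class:`DeviceProfile` captures the static hardware characteristics that
govern stimulus-delivery timing and response logging on a handset: the
accelerometer and touchscreen sampling rates, the mean/SD of the audio,
vibration and touch-pipeline latencies, the accelerometer noise floor, and
the Android low-latency/pro audio feature flags.  Profiles are plain,
human-editable YAML; a small registry of nominal profiles for the five
handsets used in the timing benchmarks ships with the package.

Latency standard deviations and the vibration/touch-pipeline latencies in the
bundled profiles are nominal synthetic values chosen to be plausible for each
device class; only the sensor rates, round-trip audio latencies and feature
flags are manufacturer/declared figures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import yaml

__all__ = ["DeviceProfile", "load_profile", "bundled_profile", "bundled_profile_names"]


@dataclass(frozen=True)
class DeviceProfile:
    """Static timing characteristics of one handset.

    Latencies are (mean, sd) pairs in milliseconds; rates in Hz.
    """

    name: str
    accel_rate_hz: float
    touch_rate_hz: float
    audio_latency_ms: tuple[float, float] = (0.0, 0.0)
    vib_latency_ms: tuple[float, float] = (0.0, 0.0)
    touch_pipeline_latency_ms: tuple[float, float] = (0.0, 0.0)
    accel_noise_sd: float = 0.0
    has_low_latency: bool = False
    has_pro: bool = False

    def __post_init__(self) -> None:
        if self.accel_rate_hz <= 0 or self.touch_rate_hz <= 0:
            raise ValueError("sampling rates must be positive")
        for label in ("audio_latency_ms", "vib_latency_ms", "touch_pipeline_latency_ms"):
            mean, sd = getattr(self, label)
            if mean < 0:
                raise ValueError(f"{label}: latency mean must be >= 0")
            if sd < 0:
                raise ValueError(f"{label}: latency SD must be >= 0")
        if self.accel_noise_sd < 0:
            raise ValueError("accel_noise_sd must be >= 0")

    @property
    def accel_period_ms(self) -> float:
        """Accelerometer sampling period (temporal resolution), ms."""
        return 1000.0 / self.accel_rate_hz

    @property
    def touch_frame_period_ms(self) -> float:
        """Touchscreen scan period — the quantization step of logged taps, ms."""
        return 1000.0 / self.touch_rate_hz

    def to_dict(self) -> dict:
        d = asdict(self)
        for label in ("audio_latency_ms", "vib_latency_ms", "touch_pipeline_latency_ms"):
            d[label] = list(d[label])
        return d


def _profile_from_mapping(data: dict) -> DeviceProfile:
    kwargs = dict(data)
    for label in ("audio_latency_ms", "vib_latency_ms", "touch_pipeline_latency_ms"):
        if label in kwargs:
            pair = kwargs[label]
            if isinstance(pair, (int, float)):
                pair = (float(pair), 0.0)
            kwargs[label] = (float(pair[0]), float(pair[1]))
    return DeviceProfile(**kwargs)


def load_profile(path: str | Path) -> DeviceProfile:
    """Read a device profile from a YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping of profile fields")
    return _profile_from_mapping(data)


def bundled_profile_names() -> list[str]:
    """Names of the profiles shipped with the package."""
    pkg = resources.files("audiotactile") / "profiles"
    return sorted(p.name[: -len(".yaml")] for p in pkg.iterdir() if p.name.endswith(".yaml"))


def bundled_profile(name: str) -> DeviceProfile:
    """Load one of the bundled device profiles by name (e.g. ``pixel_2_xl``)."""
    pkg = resources.files("audiotactile") / "profiles" / f"{name}.yaml"
    try:
        text = pkg.read_text()
    except FileNotFoundError:
        raise KeyError(
            f"no bundled profile {name!r}; available: {bundled_profile_names()}"
        ) from None
    return _profile_from_mapping(yaml.safe_load(text))
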