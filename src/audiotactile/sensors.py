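"""Synthetic sensor streams and a fully simulated timing bench.

Emulates the raw material a handset produces during an audio-tactile trial:

* 3-axis accelerometer traces at the device's sampling rate, with a constant
  gravity baseline, Gaussian sensor noise, and a brief triangular transient
  injected at each tap;
* touchscreen events delayed by the OS input pipeline and quantized *up* to
  the next frame of the screen's scan grid (a physical digitizer reports a
  contact at the following scan, never before it);
* a virtual validation bench: per trial, an audio command, a vibration
  command after a randomized inter-stimulus interval, a robotic tap a random
  delay after the (externally observed) vibration onset, and the fused
  detector's estimate of the tap time.  Internal command timestamps and
  external ground-truth timestamps are recorded side by side, mirroring
  dual-logging hardware benches where an audio interface provides the
  external reference.

All generators are pure functions of their inputs and an integer seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .fusion import FusionParams, detect_peaks, fuse_rt, trace_envelope
from .profiles import DeviceProfile

__all__ = [
    "AccelTrace",
    "TouchEvent",
    "BenchTrialRecord",
    "simulate_accel_trace",
    "simulate_touch_events",
    "simulate_bench_session",
    "default_fusion_params",
    "write_bench_csv",
    "read_bench_csv",
]

GRAVITY = 9.81  # baseline magnitude on the z axis, m/s^2

#: Relative amplitudes of the injected 3-sample triangular tap transient.
TAP_PULSE = np.array([0.5, 1.0, 0.5])

DEFAULT_TAP_AMPLITUDE = 20.0  # m/s^2 — a sharp intentional tap


@dataclass(frozen=True)
class AccelTrace:
    """Uniformly sampled 3-axis accelerometer record with tap ground truth."""

    t: np.ndarray
    acc_x: np.ndarray
    acc_y: np.ndarray
    acc_z: np.ndarray
    true_tap_times_ms: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.t)
        if not (len(self.acc_x) == len(self.acc_y) == len(self.acc_z) == n):
            raise ValueError("time base and axis series must have equal lengths")
        if n >= 2:
            dt = np.diff(np.asarray(self.t))
            if dt.min() <= 0:
                raise ValueError("timestamps must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-9):
                raise ValueError("sampling interval must be uniform")

    @property
    def rate_hz(self) -> float:
        return 1000.0 / float(self.t[1] - self.t[0])


@dataclass(frozen=True)
class TouchEvent:
    """A logged screen tap; ``true_contact_ms`` is simulation-only ground truth."""

    logged_time_ms: float
    true_contact_ms: float | None = None

    def __post_init__(self) -> None:
        if self.true_contact_ms is not None and self.logged_time_ms < self.true_contact_ms - 1e-9:
            raise ValueError("a tap cannot be logged before the physical contact")


@dataclass(frozen=True)
class BenchTrialRecord:
    """One bench trial: internal command timestamps vs external ground truth.

    t0/t1/t2 are the handset's own timestamps for audio command, vibration
    command and detected tap; the primed (``_ext``) times are what an external
    reference actually observed (stimulus onsets after device latency, and the
    true robotic-tap contact).
    """

    t0: float
    t1: float
    t2: float
    t0_ext: float
    t1_ext: float
    t2_ext: float
    delta1_ms: float

    def __post_init__(self) -> None:
        if not (self.t0 < self.t1 < self.t2):
            raise ValueError("internal timestamps must satisfy t0 < t1 < t2")
        if not (self.t0_ext < self.t1_ext < self.t2_ext):
            raise ValueError("external timestamps must satisfy t0' < t1' < t2'")


def simulate_accel_trace(
    tap_times: list[float] | np.ndarray,
    profile: DeviceProfile,
    duration_ms: float,
    tap_amplitude: float = DEFAULT_TAP_AMPLITUDE,
    seed: int = 0,
) -> AccelTrace:
    """Synthesize a 3-axis accelerometer trace containing finger taps.

    The baseline is gravity on the z axis plus independent Gaussian noise of
    SD ``profile.accel_noise_sd`` per axis.  Each tap adds a 3-sample
    triangular transient of peak ``tap_amplitude`` on the z axis, starting at
    the first sample at-or-after the tap time.
    """
    if duration_ms <= 0:
        raise ValueError("duration_ms must be positive")
    tap_times = np.sort(np.asarray(tap_times, dtype=float))
    if len(tap_times) and (tap_times[0] < 0 or tap_times[-1] >= duration_ms):
        raise ValueError("tap times must lie within [0, duration_ms)")

    rng = np.random.default_rng(seed)
    period = profile.accel_period_ms
    n = int(round(duration_ms / period))
    t = np.arange(n) * period

    sd = profile.accel_noise_sd
    acc = rng.normal(0.0, sd, size=(3, n)) if sd > 0 else np.zeros((3, n))
    acc[2] += GRAVITY

    for tap in tap_times:
        k = int(np.searchsorted(t, tap - 1e-9))  # first sample at-or-after the tap
        stop = min(k + len(TAP_PULSE), n)
        acc[2, k:stop] += tap_amplitude * TAP_PULSE[: stop - k]

    return AccelTrace(
        t=t, acc_x=acc[0], acc_y=acc[1], acc_z=acc[2], true_tap_times_ms=tap_times
    )


def simulate_touch_events(
    true_contact_times: list[float] | np.ndarray,
    profile: DeviceProfile,
    seed: int = 0,
) -> list[TouchEvent]:
    """Turn physical contact times into OS-logged touchscreen events.

    Each contact is delayed by a pipeline-latency draw (Gaussian, truncated at
    zero) and then rounded up to the next boundary of the screen's scan grid;
    a contact exactly on a boundary with zero latency is logged at that
    boundary.
    """
    contacts = np.asarray(true_contact_times, dtype=float)
    if np.any(np.diff(contacts) < 0):
        raise ValueError("contact times must be sorted ascending")
    rng = np.random.default_rng(seed)
    mean, sd = profile.touch_pipeline_latency_ms
    lat = rng.normal(mean, sd, size=len(contacts)) if sd > 0 else np.full(len(contacts), mean)
    lat = np.maximum(lat, 0.0)
    period = profile.touch_frame_period_ms
    logged = np.ceil((contacts + lat) / period - 1e-9) * period
    return [
        TouchEvent(logged_time_ms=float(lg), true_contact_ms=float(tc))
        for lg, tc in zip(logged, contacts)
    ]


def default_fusion_params(
    profile: DeviceProfile, tap_amplitude: float = DEFAULT_TAP_AMPLITUDE
) -> FusionParams:
    """Detector parameters matched to a device profile.

    The fusion window is one touchscreen frame period.  The threshold sits
    well below the envelope level of a tap onset (~ amplitude/4 with the
    default smoothing) and well above the sensor noise floor.
    """
    threshold = max(tap_amplitude / 8.0, 12.0 * profile.accel_noise_sd)
    return FusionParams(threshold=threshold, window_ms=profile.touch_frame_period_ms)


def simulate_bench_session(
    profile: DeviceProfile,
    n_trials: int,
    isi_range_ms: tuple[float, float] = (500.0, 1500.0),
    tap_delay_range_ms: tuple[float, float] = (1000.0, 2000.0),
    seed: int = 0,
    fusion_params: FusionParams | None = None,
    tap_amplitude: float = DEFAULT_TAP_AMPLITUDE,
) -> list[BenchTrialRecord]:
    """Run a fully simulated validation bench.

    Per trial: the handset issues the audio command at t0 and the vibration
    command at t1 = t0 + delta1 (delta1 uniform in ``isi_range_ms``); the
    external reference observes the stimuli after the device latency draws
    (t0', t1'); a virtual robotic finger taps the screen a uniform
    ``tap_delay_range_ms`` draw after the observed vibration onset (t2' = true
    contact); t2 is the fused detector's estimate from the simulated
    accelerometer trace and touchscreen event.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    for lo, hi in (isi_range_ms, tap_delay_range_ms):
        if not (0 <= lo <= hi):
            raise ValueError("ranges must satisfy 0 <= low <= high")

    if fusion_params is None:
        fusion_params = default_fusion_params(profile, tap_amplitude)

    rng = np.random.default_rng(seed)
    records: list[BenchTrialRecord] = []
    session_clock = 0.0
    for i in range(n_trials):
        delta1 = rng.uniform(*isi_range_ms)
        audio_lat = max(0.0, rng.normal(*profile.audio_latency_ms))
        vib_lat = max(0.0, rng.normal(*profile.vib_latency_ms))
        tap_delay = rng.uniform(*tap_delay_range_ms)

        # local (per-trial) clock, t0 = 0
        t1 = delta1
        t0_ext = audio_lat
        t1_ext = t1 + vib_lat
        true_tap = t1_ext + tap_delay

        trace = simulate_accel_trace(
            [true_tap],
            profile,
            duration_ms=true_tap + 100.0,
            tap_amplitude=tap_amplitude,
            seed=int(rng.integers(2**31)),
        )
        (touch,) = simulate_touch_events([true_tap], profile, seed=int(rng.integers(2**31)))
        env = trace_envelope(trace, fusion_params.alpha)
        peaks = detect_peaks(env, fusion_params)
        fused = fuse_rt(touch, peaks, stimulus_time=t1, params=fusion_params)
        t2 = fused.response_time_ms

        records.append(
            BenchTrialRecord(
                t0=session_clock,
                t1=session_clock + t1,
                t2=session_clock + t2,
                t0_ext=session_clock + t0_ext,
                t1_ext=session_clock + t1_ext,
                t2_ext=session_clock + true_tap,
                delta1_ms=delta1,
            )
        )
        session_clock += true_tap + 500.0
    return records


_BENCH_COLUMNS = ["trial", "t0", "t1", "t2", "t0_ext", "t1_ext", "t2_ext", "delta1_ms"]


def write_bench_csv(records: list[BenchTrialRecord], path: str | Path) -> None:
    """Export a bench session to CSV (times in ms, one header row)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_BENCH_COLUMNS)
        for i, r in enumerate(records):
            writer.writerow(
                [i, r.t0, r.t1, r.t2, r.t0_ext, r.t1_ext, r.t2_ext, r.delta1_ms]
            )


def read_bench_csv(path: str | Path) -> list[BenchTrialRecord]:
    """Read a bench CSV written by :func:`write_bench_csv`."""
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(_BENCH_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"{path}: missing bench columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(
                    BenchTrialRecord(
                        t0=float(row["t0"]),
                        t1=float(row["t1"]),
                        t2=float(row["t2"]),
                        t0_ext=float(row["t0_ext"]),
                        t1_ext=float(row["t1_ext"]),
                        t2_ext=float(row["t2_ext"]),
                        delta1_ms=float(row["delta1_ms"]),
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}: malformed bench row at line {lineno}: {exc}") from exc
    return records
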