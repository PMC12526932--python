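"""Audio-tactile peripersonal-space session schedules and session CSV I/O.

A session probes tactile detection speed while a task-irrelevant sound plays.
Each trial presents a 3250 ms sound that is either *fixed* (static source,
640 cm away) or *looming* (approaching from 640 cm to 20 cm).  On
experimental trials a 50 ms vibration is delivered at one of six onset
asynchronies from sound onset (T1–T6); in the looming condition each delay
corresponds to a source distance on a logarithmic scale, so later touches
coincide with a nearer sound.  Catch trials present the sound with no
vibration, to curb tactile expectancy; the correct response is to withhold.

The default design: 6 blocks, each with 48 experimental trials (4 repetitions
of the 12 movement × delay cells) and 24 catch trials — 432 trials per
session, 288 experimental, 33.3% catch, 24 repetitions per cell.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "Trial",
    "SessionSchedule",
    "DELAYS_MS",
    "LOOMING_DISTANCES_CM",
    "FIXED_DISTANCE_CM",
    "SOUND_DURATION_MS",
    "generate_schedule",
    "delay_to_distance",
    "write_session_csv",
    "read_session_csv",
]

#: Tactile onset asynchronies from sound onset, ms.
DELAYS_MS = {"T1": 105.0, "T2": 1625.0, "T3": 2385.0, "T4": 2765.0, "T5": 2955.0, "T6": 3050.0}

#: Looming-source distance at tactile onset per delay, cm (logarithmic scale).
LOOMING_DISTANCES_CM = {"T1": 640.0, "T2": 320.0, "T3": 160.0, "T4": 80.0, "T5": 40.0, "T6": 20.0}

FIXED_DISTANCE_CM = 640.0
SOUND_DURATION_MS = 3250.0
PRE_SILENCE_MS = 300.0
POST_SILENCE_RANGE_MS = (1000.0, 1400.0)

MOVEMENTS = ("fixed", "looming")
DELAY_LABELS = tuple(DELAYS_MS)

#: Valid values of a trial's response field.
RESPONSES = ("hit", "miss", "false_alarm", "correct_rejection")


def delay_to_distance(delay_label: str, movement: str) -> float:
    """Source distance (cm) at tactile onset for a delay and movement condition.

    Looming sounds travel 640→20 cm, so the distance is the per-delay lookup;
    fixed sounds stay at 640 cm regardless of delay.
    """
    if movement not in MOVEMENTS:
        raise ValueError(f"unknown movement condition {movement!r}")
    if delay_label not in DELAYS_MS:
        raise ValueError(f"unknown delay label {delay_label!r}")
    if movement == "fixed":
        return FIXED_DISTANCE_CM
    return LOOMING_DISTANCES_CM[delay_label]


@dataclass(frozen=True)
class Trial:
    """One paradigm trial (catch trials carry no delay/distance)."""

    block: int
    index_in_block: int
    movement: str
    delay_label: str | None
    delay_ms: float | None
    is_catch: bool
    distance_cm: float | None
    pre_silence_ms: float = PRE_SILENCE_MS
    post_silence_ms: float = 1200.0

    def __post_init__(self) -> None:
        if self.movement not in MOVEMENTS:
            raise ValueError(f"unknown movement condition {self.movement!r}")
        if self.is_catch != (self.delay_label is None):
            raise ValueError("a trial is a catch trial iff it has no delay label")
        if not self.is_catch:
            if self.delay_label not in DELAYS_MS:
                raise ValueError(f"unknown delay label {self.delay_label!r}")
            if self.delay_ms != DELAYS_MS[self.delay_label]:
                raise ValueError("delay_ms inconsistent with delay_label")
            if not self.delay_ms < SOUND_DURATION_MS:
                raise ValueError("tactile delay must fall within the sound duration")


@dataclass(frozen=True)
class SessionSchedule:
    """Ordered trial list for one session."""

    trials: tuple[Trial, ...]
    n_blocks: int
    seed: int

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_experimental(self) -> int:
        return sum(not t.is_catch for t in self.trials)

    @property
    def n_catch(self) -> int:
        return sum(t.is_catch for t in self.trials)

    @property
    def catch_fraction_pct(self) -> float:
        return 100.0 * self.n_catch / self.n_trials

    def cell_counts(self) -> dict[tuple[str, str], int]:
        """Repetitions of each (movement, delay) experimental cell."""
        counts: dict[tuple[str, str], int] = {}
        for t in self.trials:
            if not t.is_catch:
                key = (t.movement, t.delay_label)
                counts[key] = counts.get(key, 0) + 1
        return counts


def generate_schedule(
    n_blocks: int = 6,
    seed: int = 0,
    reps_per_cell_per_block: int = 4,
    catch_per_block: int = 24,
) -> SessionSchedule:
    """Generate a balanced, shuffled session schedule.

    Each block holds ``reps_per_cell_per_block`` repetitions of each of the
    12 movement × delay cells plus ``catch_per_block`` catch trials split
    evenly between fixed and looming sounds, in a uniformly shuffled order.
    Defaults reproduce the standard design (48 + 24 trials per block,
    24 repetitions per cell over 6 blocks).
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if catch_per_block % 2:
        raise ValueError("catch_per_block must be even (split across movements)")
    rng = np.random.default_rng(seed)
    trials: list[Trial] = []
    for block in range(1, n_blocks + 1):
        proto: list[tuple[str, str | None]] = []
        for movement in MOVEMENTS:
            for label in DELAY_LABELS:
                proto.extend([(movement, label)] * reps_per_cell_per_block)
            proto.extend([(movement, None)] * (catch_per_block // 2))
        order = rng.permutation(len(proto))
        for idx, j in enumerate(order):
            movement, label = proto[j]
            is_catch = label is None
            trials.append(
                Trial(
                    block=block,
                    index_in_block=idx,
                    movement=movement,
                    delay_label=label,
                    delay_ms=None if is_catch else DELAYS_MS[label],
                    is_catch=is_catch,
                    distance_cm=None if is_catch else delay_to_distance(label, movement),
                    pre_silence_ms=PRE_SILENCE_MS,
                    post_silence_ms=float(rng.uniform(*POST_SILENCE_RANGE_MS)),
                )
            )
    return SessionSchedule(trials=tuple(trials), n_blocks=n_blocks, seed=seed)


SESSION_COLUMNS = [
    "block",
    "trial",
    "movement",
    "delay_label",
    "delay_ms",
    "distance_cm",
    "is_catch",
    "rt_ms",
    "response",
    "pre_silence_ms",
    "post_silence_ms",
]


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return str(value).lower()
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_session_csv(
    path: str | Path,
    trials: "SessionSchedule | list[Trial] | tuple[Trial, ...]",
    rts_ms: list[float | None] | None = None,
    responses: list[str | None] | None = None,
) -> None:
    """Write a session CSV (one row per trial; UTF-8, '.' decimal).

    ``rts_ms``/``responses`` are optional per-trial result vectors aligned
    with the trial order; RT fields are left empty for misses and catch
    trials.
    """
    if isinstance(trials, SessionSchedule):
        trials = trials.trials
    n = len(trials)
    if rts_ms is not None and len(rts_ms) != n:
        raise ValueError("rts_ms length must match the trial count")
    if responses is not None and len(responses) != n:
        raise ValueError("responses length must match the trial count")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(SESSION_COLUMNS)
        for i, t in enumerate(trials):
            rt = rts_ms[i] if rts_ms is not None else None
            resp = responses[i] if responses is not None else None
            writer.writerow(
                [
                    t.block,
                    t.index_in_block,
                    t.movement,
                    _fmt(t.delay_label),
                    _fmt(t.delay_ms),
                    _fmt(t.distance_cm),
                    _fmt(t.is_catch),
                    _fmt(rt),
                    _fmt(resp),
                    _fmt(t.pre_silence_ms),
                    _fmt(t.post_silence_ms),
                ]
            )


def read_session_csv(
    path: str | Path,
) -> tuple[list[Trial], list[float | None], list[str | None]]:
    """Read a session CSV back into trials plus per-trial RT/response vectors."""
    trials: list[Trial] = []
    rts: list[float | None] = []
    responses: list[str | None] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(SESSION_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"{path}: missing session columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                is_catch = row["is_catch"] == "true"
                label = row["delay_label"] or None
                trials.append(
                    Trial(
                        block=int(row["block"]),
                        index_in_block=int(row["trial"]),
                        movement=row["movement"],
                        delay_label=label,
                        delay_ms=float(row["delay_ms"]) if row["delay_ms"] else None,
                        is_catch=is_catch,
                        distance_cm=float(row["distance_cm"]) if row["distance_cm"] else None,
                        pre_silence_ms=float(row["pre_silence_ms"]),
                        post_silence_ms=float(row["post_silence_ms"]),
                    )
                )
                rts.append(float(row["rt_ms"]) if row["rt_ms"] else None)
                resp = row["response"] or None
                if resp is not None and resp not in RESPONSES:
                    raise ValueError(f"unknown response value {resp!r}")
                responses.append(resp)
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}: malformed session row at line {lineno}: {exc}") from exc
    return trials, rts, responses
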