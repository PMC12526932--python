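"""Synthetic participant cohorts for the audio-tactile paradigm.

Reaction times are drawn from a lognormal distribution — the canonical
positively skewed RT model — whose *median* is set on the millisecond scale:

    median(participant, movement, delay) =
        base_median[delay] + participant_offset - looming_effect[delay] * [looming]

    RT = median * exp(sigma_log * Z),   Z ~ N(0, 1)

The base medians decrease across delays T1→T6, emulating tactile expectancy
(the later in the trial the touch arrives, the more it is anticipated).  The
looming facilitation is applied subtractively in ms, so the injected effect
equals the headline quantity the analysis pipeline should recover; by default
it is 0 at T1–T2 and 22.5 ms at T3–T6, the middle of the 20–25 ms band
expected when a looming source has entered peripersonal space.  Misses occur
independently per experimental trial; catch trials yield correct rejections
(an optional uniform false-alarm rate can be switched on).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .paradigm import DELAY_LABELS, SessionSchedule, write_session_csv

__all__ = ["CohortParams", "simulate_cohort", "write_cohort_csvs"]


@dataclass(frozen=True)
class CohortParams:
    """Generative parameters of a synthetic cohort.

    base_median_rt_ms
        Median RT per delay T1..T6 in the fixed-sound condition, strictly
        decreasing (expectancy profile).
    looming_effect_ms
        Per-delay median reduction when the sound looms (facilitation).
    sigma_log
        Lognormal shape of within-cell RT variability.
    participant_sd_ms
        SD of the between-participant offset added to every cell median.
    miss_prob
        Per-experimental-trial probability of a miss (no response).
    false_alarm_prob
        Per-catch-trial probability of a spurious response (default off).
    """

    n_participants: int = 18
    base_median_rt_ms: tuple[float, ...] = (420.0, 400.0, 380.0, 360.0, 345.0, 330.0)
    looming_effect_ms: tuple[float, ...] = (0.0, 0.0, 22.5, 22.5, 22.5, 22.5)
    sigma_log: float = 0.15
    participant_sd_ms: float = 30.0
    miss_prob: float = 0.014
    false_alarm_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        base = np.asarray(self.base_median_rt_ms, dtype=float)
        eff = np.asarray(self.looming_effect_ms, dtype=float)
        if len(base) != len(DELAY_LABELS) or len(eff) != len(DELAY_LABELS):
            raise ValueError(f"need one base median and one effect per delay ({len(DELAY_LABELS)})")
        if np.any(base <= 0):
            raise ValueError("base medians must be positive")
        if np.any(np.diff(base) >= 0):
            raise ValueError("base medians must be strictly decreasing across delays")
        if np.any(eff < 0) or np.any(eff >= base):
            raise ValueError("effects must be >= 0 and smaller than the matching median")
        if self.sigma_log < 0:
            raise ValueError("sigma_log must be >= 0")
        if self.participant_sd_ms < 0:
            raise ValueError("participant_sd_ms must be >= 0")
        if not 0.0 <= self.miss_prob < 1.0:
            raise ValueError("miss_prob must lie in [0, 1)")
        if not 0.0 <= self.false_alarm_prob < 1.0:
            raise ValueError("false_alarm_prob must lie in [0, 1)")


def simulate_cohort(schedule: SessionSchedule, params: CohortParams) -> pd.DataFrame:
    """Simulate every participant running the given schedule.

    Returns a tidy frame with one row per (participant, trial): columns
    ``participant, block, trial, movement, delay_label, delay_ms,
    distance_cm, is_catch, rt_ms, response``.  ``rt_ms`` is NaN for misses
    and catch trials.
    """
    rng = np.random.default_rng(params.seed)
    base = dict(zip(DELAY_LABELS, params.base_median_rt_ms))
    effect = dict(zip(DELAY_LABELS, params.looming_effect_ms))

    trials = schedule.trials
    n_trials = len(trials)
    exp_mask = np.array([not t.is_catch for t in trials])
    movement = np.array([t.movement for t in trials])
    labels = np.array([t.delay_label if t.delay_label else "" for t in trials])

    # per-trial cell medians before the participant offset
    cell_median = np.zeros(n_trials)
    for i, t in enumerate(trials):
        if not t.is_catch:
            m = base[t.delay_label]
            if t.movement == "looming":
                m -= effect[t.delay_label]
            cell_median[i] = m

    frames = []
    for p in range(1, params.n_participants + 1):
        offset = rng.normal(0.0, params.participant_sd_ms) if params.participant_sd_ms > 0 else 0.0
        median = cell_median + offset
        if np.any(median[exp_mask] <= 0):
            raise ValueError("participant offset drove a cell median non-positive")
        z = rng.standard_normal(n_trials)
        rt = median * np.exp(params.sigma_log * z)

        miss = rng.random(n_trials) < params.miss_prob
        fa = rng.random(n_trials) < params.false_alarm_prob

        rt_out = np.where(exp_mask & ~miss, rt, np.nan)
        response = np.empty(n_trials, dtype=object)
        response[exp_mask & ~miss] = "hit"
        response[exp_mask & miss] = "miss"
        response[~exp_mask & ~fa] = "correct_rejection"
        response[~exp_mask & fa] = "false_alarm"

        frames.append(
            pd.DataFrame(
                {
                    "participant": f"p{p:02d}",
                    "block": [t.block for t in trials],
                    "trial": [t.index_in_block for t in trials],
                    "movement": movement,
                    "delay_label": labels,
                    "delay_ms": [t.delay_ms for t in trials],
                    "distance_cm": [t.distance_cm for t in trials],
                    "is_catch": ~exp_mask,
                    "rt_ms": rt_out,
                    "response": response,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_cohort_csvs(
    df: pd.DataFrame,
    schedule: SessionSchedule,
    params: CohortParams,
    out_dir: str | Path,
) -> list[Path]:
    """Write one session CSV per participant plus a ground-truth JSON.

    The JSON records the injected generative parameters so recovery analyses
    can be scored against them.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for pid, sub in df.groupby("participant", sort=True):
        sub = sub.sort_values(["block", "trial"])
        rts = [None if np.isnan(v) else float(v) for v in sub["rt_ms"]]
        responses = list(sub["response"])
        path = out_dir / f"{pid}.csv"
        write_session_csv(path, schedule, rts_ms=rts, responses=responses)
        paths.append(path)
    truth = asdict(params)
    truth["base_median_rt_ms"] = list(truth["base_median_rt_ms"])
    truth["looming_effect_ms"] = list(truth["looming_effect_ms"])
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    return paths
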