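"""Reaction-time analysis pipeline for audio-tactile sessions.

Stages, in order:

1. **Participant exclusion** — participants with an anomalously high miss
   rate (default: above sample mean + 3 SD, single pass) are dropped.
2. **RT filtering** — responses outside [100, 1000] ms are removed as
   anticipations or lapses (bounds inclusive on the keep side).
3. **Log transform and back-transformed cell means** — RT distributions are
   right-skewed, so each RT is ln-transformed; per participant and
   (movement × delay) cell the mean ln(RT) is exponentiated back, i.e. the
   cell summary is the geometric mean RT.  Group cell means are arithmetic
   means of the participant geometric means; facilitation per delay is the
   fixed-minus-looming group mean (positive = looming is faster).
4. **Two-way within-subject ANOVA** on the participant cell means with
   factors SOUND MOVEMENT (2) and DELAY (6), classical decomposition: each
   effect is tested against its effect × subject interaction, with partial
   eta-squared ηp² = SS_effect / (SS_effect + SS_error).  Uncorrected df by
   default; Greenhouse–Geisser correction available.
5. **Per-delay contrasts** — paired t tests (fixed vs looming) on the
   ln-scale participant cell means, unadjusted by default (Holm available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .paradigm import DELAY_LABELS, MOVEMENTS, read_session_csv

__all__ = [
    "ConditionSummary",
    "AnalysisResult",
    "miss_rates",
    "exclude_participants",
    "filter_rts",
    "condition_means",
    "rm_anova",
    "per_delay_contrast",
    "analyze",
    "load_sessions",
]

DEFAULT_RT_BOUNDS_MS = (100.0, 1000.0)


# ---------------------------------------------------------------------------
# exclusion and filtering


def miss_rates(records: pd.DataFrame) -> pd.Series:
    """Per-participant miss rate, % of experimental trials."""
    exp = records[~records["is_catch"]]
    return exp.groupby("participant")["response"].apply(
        lambda r: 100.0 * (r == "miss").mean()
    )


def exclude_participants(
    rates_pct: pd.Series | dict[str, float],
    rule: str | Callable[[pd.Series], pd.Series] = "mean3sd",
) -> tuple[list[str], dict]:
    """Flag participants with anomalous miss rates.

    The default ``mean3sd`` rule excludes anyone whose rate exceeds the full
    sample's mean + 3·SD, applied once (no iterative re-screening).  A custom
    rule may be passed as a callable mapping the rate series to a boolean
    exclusion mask.
    """
    rates = pd.Series(rates_pct, dtype=float)
    if len(rates) < 2:
        raise ValueError("need at least 2 participants to screen miss rates")
    if callable(rule):
        mask = rule(rates).astype(bool)
        cutoff = np.nan
    elif rule == "mean3sd":
        cutoff = rates.mean() + 3.0 * rates.std(ddof=1)
        mask = rates > cutoff
    else:
        raise ValueError(f"unknown exclusion rule {rule!r}")
    kept = sorted(rates.index[~mask])
    report = {
        "rule": rule if isinstance(rule, str) else "custom",
        "mean_pct": float(rates.mean()),
        "sd_pct": float(rates.std(ddof=1)),
        "cutoff_pct": float(cutoff),
        "excluded": sorted(rates.index[mask]),
    }
    return kept, report


def filter_rts(
    records: pd.DataFrame,
    low_ms: float = DEFAULT_RT_BOUNDS_MS[0],
    high_ms: float = DEFAULT_RT_BOUNDS_MS[1],
) -> tuple[pd.DataFrame, float]:
    """Drop RT-bearing rows outside [low, high] ms (bounds kept).

    Rows without an RT (misses, catch trials) pass through untouched.
    Returns the kept rows and the removed fraction as a percentage of
    RT-bearing rows (0 with a warning if there are none).
    """
    if not 0 < low_ms < high_ms:
        raise ValueError("bounds must satisfy 0 < low < high")
    has_rt = records["rt_ms"].notna()
    n_rt = int(has_rt.sum())
    if n_rt == 0:
        warnings.warn("no RT-bearing trials to filter", stacklevel=2)
        return records.copy(), 0.0
    out_of_range = has_rt & ~records["rt_ms"].between(low_ms, high_ms)
    kept = records[~out_of_range].copy()
    return kept, 100.0 * float(out_of_range.sum()) / n_rt


# ---------------------------------------------------------------------------
# condition means


@dataclass(frozen=True)
class ConditionSummary:
    """Back-transformed RT summaries per (movement × delay) cell.

    participant_cells
        Tidy frame: participant, movement, delay_label, mean_rt_ms (geometric
        mean RT of the cell) and mean_ln_rt (cell mean on the ln scale).
    group_cells
        movement, delay_label, mean_rt_ms (arithmetic mean of participant
        geometric means), sem_ms (across participants).
    facilitation_ms
        Per-delay fixed-minus-looming group means (positive = looming faster).
    """

    participant_cells: pd.DataFrame
    group_cells: pd.DataFrame
    facilitation_ms: pd.Series


def condition_means(records: pd.DataFrame) -> ConditionSummary:
    """ln-transform, per-cell geometric means, group means, facilitation."""
    rts = records[records["rt_ms"].notna() & ~records["is_catch"]]
    participants = sorted(rts["participant"].unique())

    grouped = rts.groupby(["participant", "movement", "delay_label"])["rt_ms"]
    mean_ln = grouped.apply(lambda v: float(np.mean(np.log(v))))

    full_index = pd.MultiIndex.from_product(
        [participants, MOVEMENTS, DELAY_LABELS],
        names=["participant", "movement", "delay_label"],
    )
    missing = full_index.difference(mean_ln.index)
    if len(missing):
        p, m, d = missing[0]
        raise ValueError(f"participant {p} has no usable RTs in cell ({m}, {d})")
    mean_ln = mean_ln.reindex(full_index)

    part = mean_ln.rename("mean_ln_rt").reset_index()
    part["mean_rt_ms"] = np.exp(part["mean_ln_rt"])

    group = (
        part.groupby(["movement", "delay_label"])["mean_rt_ms"]
        .agg(mean_rt_ms="mean", sem_ms=lambda v: v.std(ddof=1) / np.sqrt(len(v)))
        .reset_index()
    )
    pivot = group.pivot(index="delay_label", columns="movement", values="mean_rt_ms")
    facilitation = (pivot["fixed"] - pivot["looming"]).reindex(list(DELAY_LABELS))
    facilitation.name = "facilitation_ms"
    return ConditionSummary(
        participant_cells=part, group_cells=group, facilitation_ms=facilitation
    )


# ---------------------------------------------------------------------------
# repeated-measures ANOVA


def _gg_epsilon(wide: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a subjects x levels matrix."""
    k = wide.shape[1]
    if k < 2:
        return 1.0
    s = np.cov(wide, rowvar=False)
    # double-center the covariance matrix
    row = s.mean(axis=0, keepdims=True)
    col = s.mean(axis=1, keepdims=True)
    sc = s - row - col + s.mean()
    num = np.trace(sc) ** 2
    den = (k - 1) * np.sum(sc**2)
    return float(num / den) if den > 0 else 1.0


def rm_anova(
    cell_means: pd.DataFrame,
    dv: str = "mean_rt_ms",
    correction: str = "none",
) -> pd.DataFrame:
    """Two-way fully within-subject ANOVA (movement × delay).

    ``cell_means`` must hold one row per participant × movement × delay with
    the dependent variable in ``dv`` — a complete balanced design.  Classical
    decomposition: SS for each effect is tested against the corresponding
    effect × subject interaction MS.  ``correction='gg'`` applies the
    Greenhouse-Geisser epsilon to the df (and p) of multi-level effects.

    Returns a frame with columns effect, df1, df2, F, p, eta_p2 (and eps when
    corrected).
    """
    df = cell_means
    subjects = sorted(df["participant"].unique())
    a_levels = sorted(df["movement"].unique())
    b_levels = sorted(df["delay_label"].unique())
    n, a, b = len(subjects), len(a_levels), len(b_levels)
    if len(df) != n * a * b or df.duplicated(["participant", "movement", "delay_label"]).any():
        raise ValueError("design must be complete and balanced: one row per participant x cell")

    # y[s, i, j]: subject x movement x delay
    y = (
        df.set_index(["participant", "movement", "delay_label"])[dv]
        .unstack(["movement", "delay_label"])
        .reindex(index=subjects)
        .to_numpy()
        .reshape(n, a, b)
    )
    if np.isnan(y).any():
        raise ValueError("design must be complete: found missing cells")

    grand = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)
    m_ab = y.mean(axis=0)

    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_sa = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_sb = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    ss_sab = np.sum(
        (
            y
            - m_sa[:, :, None]
            - m_sb[:, None, :]
            - m_ab[None, :, :]
            + m_s[:, None, None]
            + m_a[None, :, None]
            + m_b[None, None, :]
            - grand
        )
        ** 2
    )

    rows = []
    specs = [
        ("movement", ss_a, a - 1, ss_sa, (a - 1) * (n - 1), None),
        ("delay", ss_b, b - 1, ss_sb, (b - 1) * (n - 1), m_sb),
        ("movement*delay", ss_ab, (a - 1) * (b - 1), ss_sab, (a - 1) * (b - 1) * (n - 1),
         (y[:, 0, :] - y[:, 1, :]) if a == 2 else None),
    ]
    for name, ss_eff, df1, ss_err, df2, eps_matrix in specs:
        if ss_eff <= 0:
            f = 0.0
        elif ss_err <= 0:
            f = np.inf
        else:
            f = (ss_eff / df1) / (ss_err / df2)
        eps = 1.0
        if correction == "gg" and eps_matrix is not None:
            eps = _gg_epsilon(np.asarray(eps_matrix))
        p = float(stats.f.sf(f, df1 * eps, df2 * eps)) if np.isfinite(f) else 0.0
        row = {
            "effect": name,
            "df1": df1 * eps if correction == "gg" else df1,
            "df2": df2 * eps if correction == "gg" else df2,
            "F": float(f),
            "p": p,
            "eta_p2": float(ss_eff / (ss_eff + ss_err)) if (ss_eff + ss_err) > 0 else 0.0,
        }
        if correction == "gg":
            row["eps"] = eps
        rows.append(row)
    return pd.DataFrame(rows)


def per_delay_contrast(
    cell_means: pd.DataFrame,
    adjust: str = "none",
) -> pd.DataFrame:
    """Paired fixed-vs-looming comparison at each delay.

    The t statistic is computed on the ln-scale participant cell means; the
    reported difference is on the back-transformed ms scale (facilitation =
    fixed − looming, positive when looming is faster).  ``adjust='holm'``
    applies the Holm step-down correction across the six delays.
    """
    wide_ln = cell_means.pivot_table(
        index="participant", columns=["movement", "delay_label"], values="mean_ln_rt"
    )
    wide_ms = cell_means.pivot_table(
        index="participant", columns=["movement", "delay_label"], values="mean_rt_ms"
    )
    rows = []
    for label in DELAY_LABELS:
        fixed_ln = wide_ln[("fixed", label)]
        loom_ln = wide_ln[("looming", label)]
        t, p = stats.ttest_rel(fixed_ln, loom_ln)
        diff_ms = float((wide_ms[("fixed", label)] - wide_ms[("looming", label)]).mean())
        rows.append({"delay_label": label, "facilitation_ms": diff_ms, "t": float(t), "p": float(p)})
    out = pd.DataFrame(rows)
    if adjust == "holm":
        from statsmodels.stats.multitest import multipletests

        out["p_adj"] = multipletests(out["p"], method="holm")[1]
    elif adjust != "none":
        raise ValueError(f"unknown adjustment {adjust!r}")
    return out


# ---------------------------------------------------------------------------
# end-to-end analysis


@dataclass(frozen=True)
class AnalysisResult:
    """Bundle of all pipeline outputs."""

    exclusion_report: dict
    removed_rt_pct: float
    summary: ConditionSummary
    anova: pd.DataFrame
    contrasts: pd.DataFrame
    kept_participants: list[str]


def load_sessions(directory: str | Path) -> pd.DataFrame:
    """Read a directory of per-participant session CSVs into one tidy frame."""
    directory = Path(directory)
    paths = sorted(directory.glob("*.csv"))
    if not paths:
        raise ValueError(f"no session CSVs found in {directory}")
    frames = []
    for path in paths:
        trials, rts, responses = read_session_csv(path)
        frames.append(
            pd.DataFrame(
                {
                    "participant": path.stem,
                    "block": [t.block for t in trials],
                    "trial": [t.index_in_block for t in trials],
                    "movement": [t.movement for t in trials],
                    "delay_label": [t.delay_label or "" for t in trials],
                    "is_catch": [t.is_catch for t in trials],
                    "rt_ms": [np.nan if r is None else r for r in rts],
                    "response": responses,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def analyze(
    records: pd.DataFrame,
    rt_bounds_ms: tuple[float, float] = DEFAULT_RT_BOUNDS_MS,
    exclusion_rule: str | Callable = "mean3sd",
    adjust: str = "none",
    anova_correction: str = "none",
) -> AnalysisResult:
    """Run the full pipeline on a tidy trial frame (one row per trial)."""
    kept_ids, report = exclude_participants(miss_rates(records), rule=exclusion_rule)
    records = records[records["participant"].isin(kept_ids)]
    records, removed_pct = filter_rts(records, *rt_bounds_ms)
    summary = condition_means(records)
    anova = rm_anova(summary.participant_cells, correction=anova_correction)
    contrasts = per_delay_contrast(summary.participant_cells, adjust=adjust)
    return AnalysisResult(
        exclusion_report=report,
        removed_rt_pct=removed_pct,
        summary=summary,
        anova=anova,
        contrasts=contrasts,
        kept_participants=kept_ids,
    )
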