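"""Exclusion, RT filtering, back-transformed means, ANOVA and contrasts."""

import itertools

import numpy as np
import pandas as pd
import pytest

from audiotactile.analysis import (
    analyze,
    condition_means,
    exclude_participants,
    filter_rts,
    load_sessions,
    miss_rates,
    per_delay_contrast,
    rm_anova,
)
from audiotactile.behavior import CohortParams, simulate_cohort, write_cohort_csvs
from audiotactile.paradigm import DELAY_LABELS, generate_schedule


def _records(rows):
    return pd.DataFrame(rows, columns=["participant", "movement", "delay_label", "is_catch", "rt_ms", "response"])


class TestExclusion:
    def test_equal_rates_exclude_nobody(self):
        kept, report = exclude_participants({f"p{i}": 2.0 for i in range(5)})
        assert len(kept) == 5
        assert report["excluded"] == []

    def test_high_miss_outlier_is_excluded(self):
        # 20 rates constructed to have mean 1.4 and sample SD 2.0 including a
        # 9.0% outlier; the mean + 3 SD cutoff is then 7.4, so 9.0 is out
        d = np.sqrt(15.2 / 18)
        rates = [1.0 + d] * 9 + [1.0 - d] * 9 + [1.0, 9.0]
        series = pd.Series(rates, index=[f"p{i:02d}" for i in range(20)])
        assert series.mean() == pytest.approx(1.4)
        assert series.std(ddof=1) == pytest.approx(2.0)
        kept, report = exclude_participants(series)
        assert report["cutoff_pct"] == pytest.approx(7.4)
        assert report["excluded"] == ["p19"]
        assert len(kept) == 19

    def test_rule_applied_single_pass_only(self):
        # after removing the big outlier a second pass would also flag 4.0;
        # the contract is one pass on the full sample
        rates = pd.Series([0.0] * 10 + [4.0, 50.0], index=[f"p{i}" for i in range(12)])
        kept, report = exclude_participants(rates)
        assert report["excluded"] == ["p11"]
        assert "p10" in kept

    def test_custom_rule_callable(self):
        rates = pd.Series({"a": 1.0, "b": 5.0})
        kept, _ = exclude_participants(rates, rule=lambda r: r > 4.0)
        assert kept == ["a"]


class TestFilterRTs:
    def test_bounds_are_inclusive_on_the_keep_side(self):
        df = _records(
            [("p1", "fixed", "T1", False, rt, "hit") for rt in (99.0, 100.0, 500.0, 1000.0, 1001.0)]
        )
        kept, removed_pct = filter_rts(df)
        assert sorted(kept["rt_ms"]) == [100.0, 500.0, 1000.0]
        assert removed_pct == pytest.approx(40.0)

    def test_all_in_range_removes_nothing(self):
        df = _records([("p1", "fixed", "T1", False, rt, "hit") for rt in (150.0, 300.0)])
        kept, removed_pct = filter_rts(df)
        assert removed_pct == 0.0
        assert len(kept) == 2

    def test_empty_input_warns_and_returns_zero(self):
        df = _records([("p1", "fixed", "T1", True, np.nan, "correct_rejection")])
        with pytest.warns(UserWarning):
            kept, removed_pct = filter_rts(df)
        assert removed_pct == 0.0

    def test_rows_without_rt_pass_through(self):
        df = _records(
            [
                ("p1", "fixed", "T1", False, 50.0, "hit"),
                ("p1", "fixed", "T1", False, np.nan, "miss"),
            ]
        )
        kept, removed_pct = filter_rts(df)
        assert removed_pct == pytest.approx(100.0)
        assert len(kept) == 1 and kept["response"].iloc[0] == "miss"

    def test_invalid_bounds_rejected(self):
        df = _records([("p1", "fixed", "T1", False, 500.0, "hit")])
        with pytest.raises(ValueError):
            filter_rts(df, 1000.0, 100.0)


def _full_design_records(rt_fn, participants=("p1", "p2"), reps=2):
    rows = []
    for p, m, d in itertools.product(participants, ("fixed", "looming"), DELAY_LABELS):
        for r in range(reps):
            rows.append((p, m, d, False, rt_fn(p, m, d, r), "hit"))
    return _records(rows)


class TestConditionMeans:
    def test_constant_cell_back_transforms_to_itself(self):
        df = _full_design_records(lambda p, m, d, r: 250.0)
        summary = condition_means(df)
        assert np.allclose(summary.participant_cells["mean_rt_ms"], 250.0)

    def test_cell_summary_is_the_geometric_mean(self):
        rts = {0: 100.0, 1: 400.0}
        df = _full_design_records(lambda p, m, d, r: rts[r])
        summary = condition_means(df)
        # exp(mean(ln(100), ln(400))) = sqrt(100 * 400) = 200
        assert np.allclose(summary.participant_cells["mean_rt_ms"], 200.0)

    def test_invariant_to_relabeling_within_cell(self):
        rng = np.random.default_rng(0)
        df = _full_design_records(lambda p, m, d, r: float(rng.uniform(200, 600)), reps=6)
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = condition_means(df).group_cells
        b = condition_means(shuffled).group_cells
        pd.testing.assert_frame_equal(a, b)

    def test_facilitation_sign_positive_when_looming_faster(self):
        df = _full_design_records(lambda p, m, d, r: 300.0 if m == "looming" else 330.0)
        summary = condition_means(df)
        assert (summary.facilitation_ms > 0).all()

    def test_empty_cell_error_names_participant_and_cell(self):
        df = _full_design_records(lambda p, m, d, r: 300.0)
        df = df[~((df["participant"] == "p2") & (df["movement"] == "looming") & (df["delay_label"] == "T4"))]
        with pytest.raises(ValueError, match=r"p2.*looming.*T4"):
            condition_means(df)


def brute_force_rm_anova(y):
    """Definitional two-way within-subject decomposition via explicit loops."""
    n, a, b = y.shape
    grand = y.mean()
    ss = {"A": 0.0, "B": 0.0, "AB": 0.0, "SA": 0.0, "SB": 0.0, "SAB": 0.0}
    for i in range(a):
        ss["A"] += n * b * (y[:, i, :].mean() - grand) ** 2
    for j in range(b):
        ss["B"] += n * a * (y[:, :, j].mean() - grand) ** 2
    for i in range(a):
        for j in range(b):
            ss["AB"] += n * (y[:, i, j].mean() - y[:, i, :].mean() - y[:, :, j].mean() + grand) ** 2
    for s in range(n):
        for i in range(a):
            ss["SA"] += b * (y[s, i, :].mean() - y[s].mean() - y[:, i, :].mean() + grand) ** 2
        for j in range(b):
            ss["SB"] += a * (y[s, :, j].mean() - y[s].mean() - y[:, :, j].mean() + grand) ** 2
        for i in range(a):
            for j in range(b):
                ss["SAB"] += (
                    y[s, i, j] - y[s, i, :].mean() - y[s, :, j].mean() - y[:, i, j].mean()
                    + y[s].mean() + y[:, i, :].mean() + y[:, :, j].mean() - grand
                ) ** 2
    f_a = (ss["A"] / (a - 1)) / (ss["SA"] / ((a - 1) * (n - 1)))
    f_b = (ss["B"] / (b - 1)) / (ss["SB"] / ((b - 1) * (n - 1)))
    f_ab = (ss["AB"] / ((a - 1) * (b - 1))) / (ss["SAB"] / ((a - 1) * (b - 1) * (n - 1)))
    return f_a, f_b, f_ab


def _cell_frame(y, movements, delays):
    rows = []
    for s in range(y.shape[0]):
        for i, m in enumerate(movements):
            for j, d in enumerate(delays):
                rows.append({"participant": f"s{s}", "movement": m, "delay_label": d, "mean_rt_ms": y[s, i, j]})
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_flat_data_has_zero_effects(self):
        y = np.full((4, 2, 6), 300.0)
        table = rm_anova(_cell_frame(y, ["fixed", "looming"], list(DELAY_LABELS)))
        assert (table["F"] == 0.0).all()
        assert (table["eta_p2"] == 0.0).all()

    def test_df_structure_for_18_participants(self):
        rng = np.random.default_rng(2)
        y = rng.normal(350, 30, size=(18, 2, 6))
        table = rm_anova(_cell_frame(y, ["fixed", "looming"], list(DELAY_LABELS))).set_index("effect")
        assert (table.loc["movement", "df1"], table.loc["movement", "df2"]) == (1, 17)
        assert (table.loc["delay", "df1"], table.loc["delay", "df2"]) == (5, 85)
        assert (table.loc["movement*delay", "df1"], table.loc["movement*delay", "df2"]) == (5, 85)

    @pytest.mark.parametrize("shape", [(3, 2, 2), (4, 2, 3)])
    def test_matches_brute_force_decomposition(self, shape):
        rng = np.random.default_rng(shape[0])
        y = rng.normal(300, 40, size=shape)
        movements = ["fixed", "looming"]
        delays = [f"T{j+1}" for j in range(shape[2])]
        table = rm_anova(_cell_frame(y, movements, delays)).set_index("effect")
        f_a, f_b, f_ab = brute_force_rm_anova(y)
        assert table.loc["movement", "F"] == pytest.approx(f_a)
        assert table.loc["delay", "F"] == pytest.approx(f_b)
        assert table.loc["movement*delay", "F"] == pytest.approx(f_ab)

    def test_matches_pingouin_cross_check(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        y = rng.normal(350, 25, size=(10, 2, 6))
        df = _cell_frame(y, ["fixed", "looming"], list(DELAY_LABELS))
        ours = rm_anova(df).set_index("effect")
        theirs = pingouin.rm_anova(
            data=df, dv="mean_rt_ms", within=["movement", "delay_label"],
            subject="participant", detailed=True,
        ).set_index("Source")
        assert ours.loc["movement", "F"] == pytest.approx(theirs.loc["movement", "F"], rel=1e-6)
        assert ours.loc["delay", "F"] == pytest.approx(theirs.loc["delay_label", "F"], rel=1e-6)
        assert ours.loc["movement*delay", "F"] == pytest.approx(
            theirs.loc["movement * delay_label", "F"], rel=1e-6
        )

    def test_unbalanced_design_rejected(self):
        y = np.full((3, 2, 6), 300.0)
        df = _cell_frame(y, ["fixed", "looming"], list(DELAY_LABELS)).iloc[:-1]
        with pytest.raises(ValueError):
            rm_anova(df)

    def test_gg_correction_shrinks_df(self):
        rng = np.random.default_rng(6)
        y = rng.normal(350, 25, size=(8, 2, 6))
        plain = rm_anova(_cell_frame(y, ["fixed", "looming"], list(DELAY_LABELS))).set_index("effect")
        gg = rm_anova(
            _cell_frame(y, ["fixed", "looming"], list(DELAY_LABELS)), correction="gg"
        ).set_index("effect")
        assert gg.loc["delay", "df1"] <= plain.loc["delay", "df1"]
        assert gg.loc["delay", "F"] == pytest.approx(plain.loc["delay", "F"])


class TestPerDelayContrast:
    def _summary(self, effect_late):
        schedule = generate_schedule(n_blocks=6, seed=7)
        params = CohortParams(
            looming_effect_ms=(0.0, 0.0) + (effect_late,) * 4, seed=17
        )
        df = simulate_cohort(schedule, params)
        return condition_means(df)

    def test_injected_effect_detected_only_at_late_delays(self):
        cells = self._summary(22.5)
        contrasts = per_delay_contrast(cells.participant_cells).set_index("delay_label")
        assert (contrasts.loc[["T3", "T4", "T5", "T6"], "p"] < 0.001).all()
        assert (contrasts.loc[["T3", "T4", "T5", "T6"], "facilitation_ms"] > 0).all()

    def test_zero_effect_differences_centered_on_zero(self):
        cells = self._summary(0.0)
        contrasts = per_delay_contrast(cells.participant_cells)
        assert abs(contrasts["facilitation_ms"]).max() < 10.0

    def test_holm_adjustment_is_monotone(self):
        cells = self._summary(22.5)
        out = per_delay_contrast(cells.participant_cells, adjust="holm")
        assert (out["p_adj"] >= out["p"] - 1e-12).all()


class TestPipeline:
    def test_analyze_is_deterministic(self, default_schedule):
        df = simulate_cohort(default_schedule, CohortParams(seed=23))
        a = analyze(df)
        b = analyze(df)
        pd.testing.assert_frame_equal(a.summary.group_cells, b.summary.group_cells)
        pd.testing.assert_frame_equal(a.anova, b.anova)

    def test_round_trip_through_session_csvs(self, default_schedule, tmp_path):
        params = CohortParams(n_participants=4, seed=31)
        df = simulate_cohort(default_schedule, params)
        write_cohort_csvs(df, default_schedule, params, tmp_path / "cohort")
        loaded = load_sessions(tmp_path / "cohort")
        direct = analyze(df)
        via_csv = analyze(loaded)
        pd.testing.assert_frame_equal(
            direct.summary.group_cells, via_csv.summary.group_cells
        )

    def test_miss_rates_count_experimental_trials_only(self, default_schedule):
        df = simulate_cohort(default_schedule, CohortParams(n_participants=2, miss_prob=0.2, seed=3))
        rates = miss_rates(df)
        exp = df[~df["is_catch"]]
        expected = exp.groupby("participant")["response"].apply(
            lambda s: 100.0 * (s == "miss").mean()
        )
        pd.testing.assert_series_equal(rates, expected, check_names=False)
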