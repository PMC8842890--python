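"""Statistical pipeline: contrasts, factorial tests, correlations, models."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pendulearn.exceptions import (DataCompletenessError, DesignError,
                                   InsufficientDataError)
from pendulearn.stats import (factorial_test, interaction_posthoc,
                              learning_curve_compare, phase_score_correlation,
                              questionnaire_subscale_table, retention_contrast,
                              score_questionnaire, training_contrast,
                              transfer_kinematics_mixed_anova)

GROUP_FACTORS = {
    "Visual": (False, False),
    "SupportedVisual": (False, True),
    "VisuoHaptic": (True, False),
    "SupportedVisuoHaptic": (True, True),
}


def make_table(values_fn, n_per_group=3):
    """Long metric table with the full 36-block protocol per participant.

    ``values_fn(participant_index, phase, training_position)`` supplies the
    metric value.
    """
    rows = []
    pid = 0
    for group, (hr, ws) in GROUP_FACTORS.items():
        for _ in range(n_per_group):
            pid += 1
            blocks = ([("BL", None)] * 2 + [("TBL", None)] * 2
                      + [("CT" if k in (5, 9, 13, 17) else "T", k)
                         for k in range(1, 25)]
                      + [("STR", None)] * 2 + [("TSTR", None)] * 2
                      + [("LTR", None)] * 2 + [("TLTR", None)] * 2)
            for idx, (phase, pos) in enumerate(blocks, start=1):
                rows.append({
                    "participant": f"P{pid:03d}", "group": group,
                    "hr_train": hr, "ws_train": ws, "block_index": idx,
                    "phase": phase, "training_position": pos,
                    "value": values_fn(pid, phase, pos),
                })
    return pd.DataFrame(rows)


class TestTrainingContrast:
    def test_constant_levels(self):
        table = make_table(lambda p, ph, k: 5.0 if ph == "T" else 3.0)
        out = training_contrast(table, "value")
        assert np.allclose(out["value"], 2.0)

    def test_linear_trend_gives_1_8_slope(self):
        # value = s * training position; CT at 5/9/13/17 -> T-CT = 1.8*s
        s = 0.7
        table = make_table(
            lambda p, ph, k: s * k if ph in ("T", "CT") else 0.0)
        out = training_contrast(table, "value")
        assert np.allclose(out["value"], 1.8 * s, atol=1e-12)

    def test_identical_blocks_give_zero(self):
        table = make_table(lambda p, ph, k: 4.2)
        assert np.allclose(training_contrast(table, "value")["value"], 0.0)

    def test_missing_blocks_rejected(self):
        table = make_table(lambda p, ph, k: 1.0)
        broken = table[~((table.participant == "P001")
                         & (table.phase == "CT")
                         & (table.training_position == 9))]
        with pytest.raises(DataCompletenessError):
            training_contrast(broken, "value")


class TestRetentionContrast:
    def test_mean_difference(self):
        vals = {"STR": [10.0, 12.0], "BL": [4.0, 6.0]}
        counters = {}

        def fn(p, ph, k):
            if ph in vals:
                i = counters.get((p, ph), 0)
                counters[(p, ph)] = i + 1
                return vals[ph][i]
            return 0.0

        out = retention_contrast(make_table(fn), "value")
        assert np.allclose(out["value"], 6.0)

    def test_identical_endpoint_and_baseline(self):
        table = make_table(lambda p, ph, k: 2.0)
        assert np.allclose(
            retention_contrast(table, "value", "LTR", "BL")["value"], 0.0)

    def test_transfer_variant_uses_transfer_blocks(self):
        table = make_table(
            lambda p, ph, k: {"TSTR": 9.0, "TBL": 2.0}.get(ph, 0.0))
        out = retention_contrast(table, "value", endpoint="TSTR",
                                 baseline="TBL")
        assert np.allclose(out["value"], 7.0)


def anova_oracle(values, hr, ws):
    """Explicit sums-of-squares two-way ANOVA for the balanced 2x2 design."""
    values = np.asarray(values, float)
    hr = np.asarray(hr, bool)
    ws = np.asarray(ws, bool)
    grand = values.mean()
    n = values.size

    def level_ss(factor):
        return sum(np.sum(factor == lv) * (values[factor == lv].mean()
                                           - grand) ** 2
                   for lv in (False, True))

    ss_hr, ss_ws = level_ss(hr), level_ss(ws)
    cell_means = {}
    ss_err = 0.0
    for a in (False, True):
        for b in (False, True):
            cell = values[(hr == a) & (ws == b)]
            cell_means[(a, b)] = cell.mean()
            ss_err += np.sum((cell - cell.mean()) ** 2)
    ss_int = sum(
        np.sum((hr == a) & (ws == b))
        * (cell_means[(a, b)] - values[hr == a].mean()
           - values[ws == b].mean() + grand) ** 2
        for a in (False, True) for b in (False, True))
    df_err = n - 4
    ms_err = ss_err / df_err
    return tuple(ss / ms_err for ss in (ss_hr, ss_ws, ss_int))


def balanced_factors(n_per_cell):
    hr = np.repeat([False, False, True, True], n_per_cell)
    ws = np.repeat([False, True, False, True], n_per_cell)
    return hr, ws


class TestFactorialTest:
    def test_f_statistics_match_sums_of_squares_oracle(self, rng):
        hr, ws = balanced_factors(6)
        for _ in range(25):
            values = rng.standard_normal(24)
            results = factorial_test(values, hr, ws)
            oracle = anova_oracle(values, hr, ws)
            assert [r.test for r in results] == ["anova"] * 3
            for res, expected in zip(results, oracle):
                assert abs(res.statistic - expected) < 1e-10

    def test_strong_hr_effect_detected(self):
        rng = np.random.Generator(np.random.PCG64(0))
        hr, ws = balanced_factors(10)
        values = np.where(hr, 10.0, 0.0) + 0.1 * rng.standard_normal(40)
        results = {r.effect: r for r in factorial_test(values, hr, ws)}
        assert results["HR"].p < 1e-6
        assert results["WS"].p > 0.05
        assert results["HR x WS"].p > 0.05

    def test_constant_response_never_rejects(self):
        hr, ws = balanced_factors(3)
        results = factorial_test(np.full(12, 7.0), hr, ws)
        assert all(r.p == 1.0 for r in results)

    def test_non_normal_data_fall_back_to_kruskal(self, rng):
        hr, ws = balanced_factors(10)
        values = rng.lognormal(0.0, 2.5, size=40) ** 2
        results = factorial_test(values, hr, ws)
        assert [r.test for r in results] == ["kruskal", "kruskal"]
        assert [r.effect for r in results] == ["HR", "WS"]
        h, p = sps.kruskal(values[hr], values[~hr])
        assert results[0].statistic == pytest.approx(h, abs=1e-12)
        assert results[0].p == pytest.approx(p, abs=1e-12)

    def test_empty_cell_rejected(self):
        hr = np.array([False] * 6 + [True] * 2)
        ws = np.array([False, True] * 3 + [False, False])
        with pytest.raises(DesignError):
            factorial_test(np.arange(8.0), hr, ws)


class TestInteractionPosthoc:
    def test_identical_subgroups_give_p_one(self):
        hr, ws = balanced_factors(4)
        results = interaction_posthoc(np.ones(16), hr, ws)
        assert all(r.p == 1.0 for r in results)

    def test_separated_subgroups_significant(self, rng):
        hr, ws = balanced_factors(10)
        values = np.where(hr, 10.0, 0.0) + 0.1 * rng.standard_normal(40)
        results = {r.effect: r for r in interaction_posthoc(values, hr, ws)}
        assert results["HR | WS:OFF"].p < 1e-6
        assert results["HR | WS:ON"].p < 1e-6

    def test_bonferroni_is_four_times_raw(self, rng):
        hr, ws = balanced_factors(5)
        values = rng.standard_normal(20)
        res = {r.effect: r for r in interaction_posthoc(values, hr, ws)}
        t, p_raw = sps.ttest_ind(values[hr & ~ws], values[~hr & ~ws])
        assert res["HR | WS:OFF"].p == pytest.approx(min(1.0, 4 * p_raw),
                                                     abs=1e-12)
        assert res["HR | WS:OFF"].correction == "bonferroni(4)"


class TestPhaseScoreCorrelation:
    def _table(self, phase_vals, score_vals):
        rows = []
        for i, (ph, sc) in enumerate(zip(phase_vals, score_vals)):
            for _ in range(2):  # two BL blocks each
                rows.append({"participant": f"P{i:03d}", "hr_train": False,
                             "ws_train": False, "group": "Visual",
                             "phase": "BL", "phase_diff": ph, "score": sc})
        return pd.DataFrame(rows)

    def test_perfect_linear_relation(self):
        phase = np.linspace(0.1, 1.0, 10)
        res = phase_score_correlation(self._table(phase, 2 * phase), "BL")
        assert res.statistic == pytest.approx(1.0, abs=1e-12)

    def test_matches_covariance_formula(self, rng):
        phase = rng.standard_normal(20)
        score = rng.standard_normal(20)
        res = phase_score_correlation(self._table(phase, score), "BL")
        a, b = np.abs(phase), score
        oracle = (np.mean(a * b) - a.mean() * b.mean()) / (
            a.std(ddof=0) * b.std(ddof=0))
        assert res.statistic == pytest.approx(oracle, abs=1e-12)

    def test_null_rejection_rate_near_alpha(self, rng):
        hits = 0
        for _ in range(500):
            res = phase_score_correlation(
                self._table(rng.standard_normal(40),
                            rng.standard_normal(40)), "BL")
            hits += res.p < 0.05
        assert 0.02 <= hits / 500 <= 0.08

    def test_too_few_participants(self):
        with pytest.raises(InsufficientDataError):
            phase_score_correlation(self._table([0.1, 0.2], [1.0, 2.0]), "BL")


class TestLearningCurveCompare:
    def test_noise_free_linear_has_no_log_term(self):
        blocks = np.arange(1.0, 25.0)
        res = learning_curve_compare(blocks, 3.0 + 0.5 * blocks)
        assert res.statistic == pytest.approx(0.0, abs=1e-6)

    def test_linear_data_rarely_prefers_log(self, rng):
        blocks = np.tile(np.arange(1.0, 25.0), 5)
        false_hits = 0
        for _ in range(200):
            scores = 2.0 * blocks + rng.normal(0, 5.0, blocks.size)
            false_hits += learning_curve_compare(blocks, scores).p < 0.05
        assert false_hits / 200 <= 0.10

    def test_saturating_curve_detected(self, rng):
        blocks = np.tile(np.arange(1.0, 25.0), 5)
        hits = 0
        for _ in range(200):
            scores = 20.0 * np.log(blocks) + rng.normal(0, 5.0, blocks.size)
            hits += learning_curve_compare(blocks, scores).p < 0.05
        assert hits / 200 >= 0.80

    def test_too_short_series(self):
        with pytest.raises(InsufficientDataError):
            learning_curve_compare(np.arange(1.0, 6.0), np.arange(5.0))


class TestTransferKinematicsMixedAnova:
    def _table(self, long_vals, short_vals):
        rows = []
        groups = list(GROUP_FACTORS)
        for i, (lv, sv) in enumerate(zip(long_vals, short_vals)):
            group = groups[i % 4]
            for phase, v in (("LTR", lv), ("TLTR", sv)):
                for _ in range(2):
                    rows.append({"participant": f"P{i:03d}", "group": group,
                                 "phase": phase, "value": v})
        return pd.DataFrame(rows)

    def test_no_within_difference_gives_zero_f(self, rng):
        vals = rng.uniform(1, 2, size=12)
        res = transfer_kinematics_mixed_anova(self._table(vals, vals),
                                              "value")
        within = next(r for r in res if "within" in r.effect)
        assert within.statistic == pytest.approx(0.0, abs=1e-9)

    def test_constant_within_shift_significant(self, rng):
        long_vals = rng.uniform(1, 2, size=12)
        short_vals = long_vals + 0.5 + rng.normal(0, 1e-3, 12)
        res = transfer_kinematics_mixed_anova(
            self._table(long_vals, short_vals), "value")
        within = next(r for r in res if "within" in r.effect)
        assert within.p < 1e-6

    def test_missing_condition_rejected(self):
        table = self._table(np.ones(8), np.ones(8))
        broken = table[~((table.participant == "P000")
                         & (table.phase == "TLTR"))]
        with pytest.raises(DataCompletenessError):
            transfer_kinematics_mixed_anova(broken, "value")


class TestQuestionnaire:
    def test_subscale_mean(self):
        assert score_questionnaire([2, 3, -1]) == pytest.approx(4 / 3)

    def test_single_missing_item_tolerated(self):
        assert score_questionnaire([5.0, np.nan, 7.0]) == pytest.approx(6.0)

    def test_ceiling(self):
        assert score_questionnaire([7, 7, 7]) == 7.0

    def test_two_missing_items_rejected(self):
        with pytest.raises(DataCompletenessError):
            score_questionnaire([np.nan, np.nan, 3.0])

    def test_subscale_table_aggregates_items(self):
        quest = pd.DataFrame([
            {"participant": "P1", "group": "Visual", "time_point": "BL",
             "subscale": "agency", "item": i, "response": r}
            for i, r in ((1, 2.0), (2, 3.0), (3, -1.0))])
        out = questionnaire_subscale_table(quest)
        assert len(out) == 1
        assert out.loc[0, "value"] == pytest.approx(4 / 3)
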