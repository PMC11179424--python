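"""Tests for baseline deltas, two-stage rate estimation, and Tukey contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cagtrace import (
    InputError,
    baseline_relative,
    compare_conditions,
    fit_condition_rates,
)
from cagtrace.timecourse import replicate_slopes


def make_study(slopes_by_condition, times=(0, 20, 40, 60, 80), noise_sd=0.0,
               control="NTC", time_unit="day", rng=None, baseline_value=10.0):
    """Linear-trend results + sheet; slopes_by_condition maps name -> list of
    per-replicate true slopes (in metric units per time unit)."""
    rows_r, rows_s = [], []
    for cond, rep_slopes in slopes_by_condition.items():
        for i, slope in enumerate(rep_slopes):
            rep = f"r{i + 1}"
            for t in times:
                value = baseline_value + slope * t
                if noise_sd and t != times[0]:
                    value += rng.normal(0.0, noise_sd)
                sid = f"{cond}_{rep}_t{t}"
                rows_r.append(
                    {"sample_id": sid, "modal_repeat": int(round(value)),
                     "instability_index": value, "n_peaks_retained": 5,
                     "reference_repeat": 125}
                )
                rows_s.append(
                    {"sample_id": sid, "condition": cond, "replicate": rep,
                     "time": t, "time_unit": time_unit,
                     "is_control": cond == control, "is_baseline": t == times[0]}
                )
    return pd.DataFrame(rows_r), pd.DataFrame(rows_s)


class TestBaselineRelative:
    def test_baseline_rows_become_zero_and_deltas_propagate(self):
        results, sheet = make_study({"NTC": [0.025]}, times=(0, 20))
        deltas = baseline_relative(results, sheet)
        base = deltas[deltas["is_baseline"]]
        assert (base["delta_instability_index"] == 0).all()
        d20 = deltas.loc[deltas["time"] == 20, "delta_instability_index"].iloc[0]
        assert d20 == pytest.approx(0.5)

    def test_constant_series_gives_zero_deltas(self):
        results, sheet = make_study({"NTC": [0.0, 0.0]})
        deltas = baseline_relative(results, sheet)
        assert np.allclose(deltas["delta_instability_index"], 0.0)

    def test_missing_baseline_error_names_replicate(self):
        results, sheet = make_study({"NTC": [0.02]})
        sheet.loc[sheet["replicate"] == "r1", "is_baseline"] = False
        with pytest.raises(InputError, match="NTC/r1"):
            baseline_relative(results, sheet)

    def test_empty_sheet_rejected(self):
        results, sheet = make_study({"NTC": [0.02]})
        with pytest.raises(InputError):
            baseline_relative(results, sheet.iloc[0:0])


class TestFitConditionRates:
    def test_noiseless_linear_data_recovered_exactly(self):
        results, sheet = make_study({"NTC": [0.025, 0.025, 0.025]})
        (est,) = fit_condition_rates(results, sheet, "instability_index")
        assert est.slope == pytest.approx(0.025, abs=1e-12)
        assert est.se == pytest.approx(0.0, abs=1e-12)
        assert est.percent_slowing == pytest.approx(0.0, abs=1e-9)

    def test_control_slowing_against_itself_is_zero(self):
        rng = np.random.default_rng(0)
        results, sheet = make_study(
            {"NTC": [0.02, 0.025, 0.03, 0.022]}, noise_sd=0.1, rng=rng
        )
        (est,) = fit_condition_rates(results, sheet)
        assert est.percent_slowing == pytest.approx(0.0, abs=1e-9)

    def test_zero_control_slope_makes_slowing_undefined(self):
        results, sheet = make_study({"NTC": [0.0, 0.0], "TGT": [0.01, 0.01]})
        ests = fit_condition_rates(results, sheet)
        assert all(np.isnan(e.percent_slowing) for e in ests)

    def test_short_replicate_excluded_with_warning(self, caplog):
        results, sheet = make_study({"NTC": [0.02, 0.03, 0.025]})
        # leave replicate r1 with only two timepoints
        drop = (sheet["replicate"] == "r1") & (sheet["time"] > 20)
        keep_ids = sheet.loc[~drop, "sample_id"]
        sheet = sheet[sheet["sample_id"].isin(keep_ids)].reset_index(drop=True)
        results = results[results["sample_id"].isin(keep_ids)].reset_index(drop=True)
        with caplog.at_level("WARNING"):
            (est,) = fit_condition_rates(results, sheet)
        assert est.n_replicates == 2
        assert "r1" in caplog.text

    def test_condition_with_no_usable_replicates_errors(self):
        results, sheet = make_study({"NTC": [0.02, 0.03]}, times=(0, 20))
        with pytest.raises(InputError, match="NTC"):
            fit_condition_rates(results, sheet)

    def test_estimates_invariant_to_row_order(self):
        rng = np.random.default_rng(4)
        results, sheet = make_study(
            {"NTC": [0.02, 0.03, 0.025], "TGT": [0.01, 0.012, 0.008]},
            noise_sd=0.05, rng=rng,
        )
        ests = fit_condition_rates(results, sheet)
        perm = rng.permutation(len(results))
        ests_shuffled = fit_condition_rates(
            results.iloc[perm].reset_index(drop=True),
            sheet.sample(frac=1.0, random_state=7).reset_index(drop=True),
        )
        for a, b in zip(ests, ests_shuffled):
            assert a.condition == b.condition
            assert a.slope == pytest.approx(b.slope, abs=1e-12)
            assert a.percent_slowing == pytest.approx(b.percent_slowing, abs=1e-9)

    def test_simulation_recovery_of_percent_slowing(self):
        # 80-day, 5-timepoint, 4-replicate design; target at 0.35x control
        rng = np.random.default_rng(11)
        truth = 65.0
        ctrl, tgt = 0.025, 0.35 * 0.025
        results, sheet = make_study(
            {
                "NTC": list(rng.normal(ctrl, 0.1 * ctrl, 4)),
                "TGT": list(rng.normal(tgt, 0.1 * tgt, 4)),
            },
            noise_sd=0.05, rng=rng,
        )
        ests = {e.condition: e for e in fit_condition_rates(results, sheet)}
        lo, hi = ests["TGT"].percent_slowing_ci95
        assert lo < truth < hi

    def test_two_stage_estimator_is_unbiased_on_linear_trends(self):
        # mean bias < 5% of true slope over 200 noisy simulations
        rng = np.random.default_rng(99)
        true_slope = 0.03
        total_change = true_slope * 80
        means = []
        for _ in range(200):
            results, sheet = make_study(
                {"NTC": [true_slope] * 4}, noise_sd=0.20 * total_change, rng=rng
            )
            (est,) = fit_condition_rates(results, sheet)
            means.append(est.slope)
        assert abs(np.mean(means) - true_slope) < 0.05 * true_slope

    def test_mixed_model_agrees_with_two_stage_on_balanced_data(self):
        rng = np.random.default_rng(8)
        results, sheet = make_study(
            {"NTC": list(rng.normal(0.025, 0.002, 4)),
             "TGT": list(rng.normal(0.010, 0.002, 4))},
            noise_sd=0.05, rng=rng,
        )
        two = {e.condition: e.slope for e in fit_condition_rates(results, sheet)}
        mixed = {
            e.condition: e.slope
            for e in fit_condition_rates(results, sheet, method="mixed")
        }
        for cond in two:
            assert mixed[cond] == pytest.approx(two[cond], rel=0.02)


class TestCompareConditions:
    def _slopes(self, groups):
        rows = []
        for cond, values in groups.items():
            for i, v in enumerate(values):
                rows.append({"condition": cond, "replicate": f"r{i}", "slope": v,
                             "n_timepoints": 5, "is_control": cond == "NTC"})
        return pd.DataFrame(rows)

    def test_identical_groups_give_p_one_and_zero_difference(self):
        slopes = self._slopes({"A": [0.02, 0.03, 0.025], "B": [0.02, 0.03, 0.025]})
        table = compare_conditions(slopes)
        assert table["difference"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert table["p_adj"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_two_groups_match_pooled_t_test(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0.02, 0.005, 5), rng.normal(0.015, 0.005, 6)
        table = compare_conditions(self._slopes({"A": list(a), "B": list(b)}))
        t_p = stats.ttest_ind(a, b, equal_var=True).pvalue
        assert table["p_adj"].iloc[0] == pytest.approx(t_p, rel=1e-6)

    def test_strong_effect_is_flagged_significant(self):
        rng = np.random.default_rng(5)
        ctrl = rng.normal(0.025, 0.001, 4)
        tgt = rng.normal(0.35 * 0.025, 0.001, 4)
        table = compare_conditions(self._slopes({"NTC": list(ctrl),
                                                 "TGT": list(tgt)}))
        assert bool(table["significant"].iloc[0])

    def test_tukey_p_never_below_unadjusted_pairwise_p(self):
        # the unadjusted comparison uses the same pooled variance estimate,
        # so the studentized-range adjustment can only raise the p value
        rng = np.random.default_rng(17)
        for _ in range(25):
            groups = {
                name: rng.normal(rng.uniform(0, 0.03), 0.01, 4)
                for name in ("A", "B", "C", "D")
            }
            table = compare_conditions(
                self._slopes({k: list(v) for k, v in groups.items()})
            )
            n_total = sum(len(v) for v in groups.values())
            df = n_total - len(groups)
            pooled = sum(np.var(v, ddof=1) * (len(v) - 1) for v in groups.values()) / df
            for row in table.itertuples():
                a, b = groups[row.condition_a], groups[row.condition_b]
                t_stat = abs(np.mean(a) - np.mean(b)) / np.sqrt(
                    pooled * (1 / len(a) + 1 / len(b))
                )
                t_p = 2 * stats.t.sf(t_stat, df)
                assert row.p_adj >= t_p - 1e-12

    def test_single_condition_rejected(self):
        with pytest.raises(InputError):
            compare_conditions(self._slopes({"A": [0.01, 0.02]}))

    def test_single_replicate_group_rejected(self):
        with pytest.raises(InputError):
            compare_conditions(self._slopes({"A": [0.01, 0.02], "B": [0.01]}))
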