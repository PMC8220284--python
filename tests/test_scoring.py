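"""AUC, composites, deciles, bias and arm assignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from tdmed.scoring import (
    TRUST_Q1_LEVELS,
    IncomePercentileTable,
    annual_total_income,
    assign_arm,
    auc,
    auc_from_log,
    auc_from_points,
    build_composites,
    decile_and_bias,
    default_percentile_table,
    score_cohort,
    standardize,
    trust_binary,
)
from tdmed.task import IndifferenceSet, TaskConfig, extract_indifference

DELAYS = (21.0, 90.0, 730.0)


class TestAUC:
    @pytest.mark.parametrize(
        "amounts,expected",
        [
            ((70, 70, 70), 49_630.0),
            ((69.5, 69.5, 69.5), 49_275.5),
            ((1, 1, 1), 709.0),
            ((70, 0, 0), 2_415.0),
        ],
    )
    def test_trapezoid_examples(self, amounts, expected):
        assert auc_from_points(DELAYS, amounts) == pytest.approx(expected)

    def test_indifference_set_route(self, task_cfg):
        points = IndifferenceSet(points={21: 10.0, 90: 5.0, 730: 1.0})
        expected = 69 * 7.5 + 640 * 3.0
        assert auc(points, task_cfg) == pytest.approx(expected)

    def test_missing_point_is_an_error(self, task_cfg):
        points = IndifferenceSet(points={21: 10.0, 90: 5.0})
        with pytest.raises(ValueError):
            auc(points, task_cfg)

    @given(
        y=st.tuples(*[st.floats(0.5, 69.5) for _ in range(3)]),
        bump=st.floats(0.0, 5.0),
        which=st.integers(0, 2),
    )
    def test_monotone_and_bounded(self, y, bump, which):
        base = auc_from_points(DELAYS, y)
        assert 709 * min(y) - 1e-9 <= base <= 709 * max(y) + 1e-9
        raised = list(y)
        raised[which] = min(raised[which] + bump, 70.0)
        assert auc_from_points(DELAYS, raised) >= base - 1e-9


class TestStandardize:
    def test_two_point_sample(self):
        np.testing.assert_allclose(standardize([1, 3]),
                                   [-0.70710678, 0.70710678])

    def test_idempotent_on_standardized_sample(self, rng):
        z = standardize(rng.normal(3.0, 2.0, size=100))
        np.testing.assert_allclose(standardize(z), z, atol=1e-12)

    @pytest.mark.parametrize("bad", [[2.0, 2.0, 2.0], [1.0]])
    def test_degenerate_samples_rejected(self, bad):
        with pytest.raises(ValueError):
            standardize(bad)


def _toy_cohort(n=40, seed=3):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "monthly_income": rng.lognormal(7.5, 0.5, n).round(2),
            "monthly_benefits": rng.choice([0.0, 300.0], n),
            "education_level": rng.integers(1, 7, n),
            "macarthur_ladder": rng.integers(1, 11, n),
            "grisk1": rng.integers(1, 8, n),
            "grisk2": rng.integers(1, 8, n),
            "grisk3": rng.integers(1, 8, n),
            "trust_q1": rng.choice(list(TRUST_Q1_LEVELS), n),
            "trust_q2": rng.integers(1, 11, n),
            "trust_q3": rng.integers(1, 11, n),
        }
    )


class TestComposites:
    def test_zero_mean_by_construction(self):
        comps = build_composites(_toy_cohort())
        for col in comps:
            assert comps[col].mean() == pytest.approx(0.0, abs=1e-12)

    def test_mirrored_pair_gives_exact_negatives(self):
        # two participants exactly mirrored on every component
        cohort = pd.DataFrame(
            {
                "monthly_income": [1000.0, 3000.0],
                "monthly_benefits": [0.0, 0.0],
                "education_level": [2, 5],
                "macarthur_ladder": [3, 8],
                "grisk1": [2, 6],
                "grisk2": [1, 7],
                "grisk3": [3, 5],
                "trust_q1": ["cant_be_too_careful", "can_be_trusted"],
                "trust_q2": [2, 9],
                "trust_q3": [4, 7],
            }
        )
        comps = build_composites(cohort)
        for col in comps:
            assert comps[col].iloc[0] == pytest.approx(-comps[col].iloc[1])

    @given(scale=st.floats(0.05, 50.0), shift=st.floats(-500.0, 500.0))
    def test_invariant_to_affine_rescaling_of_a_raw_column(self, scale, shift):
        cohort = _toy_cohort()
        base = build_composites(cohort)
        rescaled = cohort.copy()
        rescaled["education_level"] = rescaled["education_level"] * scale + shift
        out = build_composites(rescaled)
        pd.testing.assert_frame_equal(base, out, atol=1e-8, rtol=0)

    def test_objective_ses_tracks_income_when_ranks_agree(self, rng):
        income = np.sort(rng.lognormal(7.5, 0.6, 60))
        cohort = _toy_cohort(60)
        cohort["monthly_income"] = income
        cohort["monthly_benefits"] = 0.0
        cohort["education_level"] = np.arange(60) // 10 + 1  # same ranking
        comps = build_composites(cohort)
        rho = pd.Series(comps["objective_ses"]).corr(pd.Series(income), method="spearman")
        assert rho == pytest.approx(1.0)

    def test_dont_know_maps_to_zero(self):
        vals = trust_binary(["can_be_trusted", "dont_know", "cant_be_too_careful"])
        np.testing.assert_array_equal(vals, [1.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            trust_binary(["maybe"])


class TestIncome:
    @pytest.mark.parametrize(
        "inc,ben,expected", [(1000, 200, 14_400), (0, 0, 0), (12_500, 0, 150_000)]
    )
    def test_annual_total_income(self, inc, ben, expected):
        assert annual_total_income(inc, ben) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            annual_total_income(-1.0, 0.0)


class TestDecileAndBias:
    def test_examples(self):
        table = default_percentile_table()
        # an income in the 7th decile of the packaged table
        actual, bias, sign = decile_and_bias(28_000.0, 3, table)
        assert (actual, bias, sign) == (7, -4, "negative")
        actual, bias, sign = decile_and_bias(28_000.0, 7, table)
        assert (actual, bias, sign) == (7, 0, "none")
        actual, bias, sign = decile_and_bias(15_000.0, 6, table)
        assert (actual, bias, sign) == (3, 3, "positive")

    def test_tie_at_a_cut_point_resolves_upward(self):
        table = default_percentile_table()
        assert int(table.decile(10_000.0)) == 2
        assert int(table.decile(9_999.99)) == 1

    def test_matches_brute_force_linear_scan(self, rng):
        table = default_percentile_table()
        incomes = rng.uniform(0, 80_000, 10_000)
        fast = table.decile(incomes)
        cuts = table.cuts
        for income, got in zip(incomes[:50], fast[:50]):
            assert got == 1 + sum(c <= income for c in cuts)
        slow = 1 + np.array([[c <= x for c in cuts] for x in incomes]).sum(axis=1)
        np.testing.assert_array_equal(fast, slow)

    def test_invalid_ladder_rejected(self):
        with pytest.raises(ValueError):
            decile_and_bias(20_000.0, 0, default_percentile_table())

    def test_table_validation_and_csv_roundtrip(self, tmp_path):
        with pytest.raises(ValueError):
            IncomePercentileTable(cuts=(1, 2, 3))
        table = default_percentile_table()
        table.to_csv(tmp_path / "t.csv")
        assert IncomePercentileTable.from_csv(tmp_path / "t.csv") == table


class TestAssignArm:
    def test_non_negative_bias_gets_no_arm(self):
        assert assign_arm(0, 1) == "none"
        assert assign_arm(1, 1) == "none"

    def test_negative_bias_is_a_fair_coin_over_seeds(self):
        n = 2_000
        arms = [assign_arm(-2, seed) for seed in range(n)]
        share = np.mean([a == "treated" for a in arms])
        assert abs(share - 0.5) <= 3 * np.sqrt(0.25 / n)
        assert set(arms) == {"treated", "control"}


class TestScoreCohort:
    def test_log_scoring_agrees_with_per_block_extraction(self, small_cohort, task_cfg):
        """Dual route: the vectorized trial-log AUC equals replaying
        extract_indifference block by block."""
        trials = small_cohort.trials
        fast = auc_from_log(trials, task_cfg)
        tit = trials[~trials["is_catch"]]
        for pid, group in list(tit.groupby("participant_id"))[:25]:
            points = {}
            for delay, block in group.groupby("later_delay_days"):
                history = list(block.sort_values("trial_index")["choice"])
                points[delay] = extract_indifference(history, task_cfg)
            expected = auc_from_points(sorted(points), [points[d] for d in sorted(points)])
            assert fast.loc[pid] == pytest.approx(expected)

    def test_scored_columns_present_and_consistent(self, small_scored):
        for col in ("annual_total_income", "actual_decile", "bias", "bias_sign",
                    "auc", "objective_ses", "subjective_ses", "trust_index"):
            assert col in small_scored.columns
        assert small_scored["trust_index"].mean() == pytest.approx(0.0, abs=1e-10)
        assert ((small_scored["actual_decile"] >= 1)
                & (small_scored["actual_decile"] <= 10)).all()
        np.testing.assert_array_equal(
            small_scored["bias"],
            small_scored["macarthur_ladder"] - small_scored["actual_decile"],
        )
        assert small_scored["auc"].between(354.5, 49_275.5).all()

    def test_missing_trial_log_is_an_error(self, small_cohort):
        participants = small_cohort.participants
        trials = small_cohort.trials
        broken = trials[trials["participant_id"] != participants["participant_id"].iloc[0]]
        with pytest.raises(ValueError, match="p00000|incomplete"):
            score_cohort(participants, broken)
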