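"""Power analysis, deviation tests, reliability, and the model ladder."""

import numpy as np
import pingouin
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.power import FTestAnovaPower

from motimsg.simulate import (
    StudySimSpec,
    simulate_user_study,
    study_records_frame,
)
from motimsg.study import (
    anova_power,
    anova_power_n,
    cronbach_alpha,
    fit_ladder,
    one_sample_t,
    posthoc_pairwise,
    read_overall_csv,
    read_records_csv,
)


class TestAnovaPowerN:
    def test_reference_sample_size(self):
        assert anova_power_n(3, 0.25, 0.05, 0.90) == 207

    def test_agrees_with_statsmodels_solver(self):
        # statsmodels solves the same noncentral-F equation continuously;
        # our balanced N is its ceiling to a multiple of k.
        for f, power in [(0.25, 0.9), (0.4, 0.8), (0.1, 0.95)]:
            continuous = FTestAnovaPower().solve_power(
                effect_size=f, k_groups=3, alpha=0.05, power=power
            )
            ours = anova_power_n(3, f, 0.05, power)
            assert ours >= continuous - 1e-6
            assert ours - continuous < 3  # tightest multiple of k above

    def test_zero_effect_size_rejected(self):
        with pytest.raises(ValueError):
            anova_power_n(3, 0.0, 0.05, 0.90)

    def test_unbalanced_scan_never_larger(self):
        balanced = anova_power_n(3, 0.25, 0.05, 0.80)
        unbalanced = anova_power_n(3, 0.25, 0.05, 0.80, balanced=False)
        assert unbalanced <= balanced
        assert anova_power(unbalanced, 3, 0.25, 0.05) >= 0.80
        assert anova_power(unbalanced - 1, 3, 0.25, 0.05) < 0.80

    def test_monotone_in_effect_alpha_and_power(self):
        n_ref = anova_power_n(3, 0.25, 0.05, 0.90)
        assert anova_power_n(3, 0.30, 0.05, 0.90) <= n_ref
        assert anova_power_n(3, 0.25, 0.10, 0.90) <= n_ref
        assert anova_power_n(3, 0.25, 0.05, 0.95) >= n_ref


class TestOneSampleT:
    def test_symmetric_sample_gives_zero_t(self):
        t, df, p = one_sample_t([-2.0, -1.0, 1.0, 2.0])
        assert t == pytest.approx(0.0)
        assert df == 3
        assert p == pytest.approx(1.0)

    def test_constant_sample_is_degenerate(self):
        with pytest.raises(ValueError):
            one_sample_t([1.0, 1.0, 1.0, 1.0])

    def test_direct_formula(self):
        values = [2.0, 4.0, 6.0]
        t, df, p = one_sample_t(values)
        expected = np.mean(values) / (np.std(values, ddof=1) / np.sqrt(3))
        assert t == pytest.approx(expected)

    @given(
        values=st.lists(
            st.floats(min_value=-10, max_value=10, allow_nan=False),
            min_size=3,
            max_size=40,
        ),
        mu0=st.floats(min_value=-5, max_value=5, allow_nan=False),
    )
    def test_matches_scipy_oracle(self, values, mu0):
        x = np.asarray(values)
        if x.std(ddof=1) == 0:
            return
        t, df, p = one_sample_t(values, mu0)
        ref = stats.ttest_1samp(x, mu0)
        assert t == pytest.approx(ref.statistic, rel=1e-9, abs=1e-9)
        assert p == pytest.approx(ref.pvalue, rel=1e-9, abs=1e-9)


class TestCronbachAlpha:
    def test_identical_items_give_alpha_one(self):
        x = np.tile(np.arange(10.0)[:, None], (1, 4))
        assert cronbach_alpha(x) == pytest.approx(1.0)

    def test_two_items_spearman_brown_equivalence(self, rng):
        # r = .5 with equal variances -> alpha = 2r / (1 + r)
        cov = [[1.0, 0.5], [0.5, 1.0]]
        x = rng.multivariate_normal([0, 0], cov, size=200_000)
        assert cronbach_alpha(x) == pytest.approx(2 * 0.5 / 1.5, abs=0.01)

    def test_zero_total_variance_rejected(self):
        x = np.array([[1.0, -1.0], [2.0, -2.0], [3.0, -3.0]])
        with pytest.raises(ValueError):
            cronbach_alpha(x)

    @settings(max_examples=100, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matches_pingouin_oracle(self, seed):
        gen = np.random.default_rng(seed)
        k = int(gen.integers(2, 8))
        n = int(gen.integers(5, 40))
        x = gen.normal(size=(n, k)) + gen.normal(size=(n, 1))
        import pandas as pd

        ours = cronbach_alpha(x)
        theirs = pingouin.cronbach_alpha(data=pd.DataFrame(x))[0]
        assert ours == pytest.approx(theirs, rel=1e-9, abs=1e-9)


@pytest.fixture(scope="module")
def null_frame():
    spec = StudySimSpec(n_participants=45, seed=404)
    return study_records_frame(simulate_user_study(spec)[0])


class TestFitLadder:
    def test_step_labels_and_dfs(self, null_frame):
        result = fit_ladder(null_frame, "motivation")
        assert [s.label for s in result.steps] == [
            f"M{i}vsM{i + 1}" for i in range(7)
        ]
        assert [s.df for s in result.steps] == [2, 2, 2, 4, 4, 4, 8]

    def test_statistics_are_nonnegative_chisquare(self, null_frame):
        result = fit_ladder(null_frame, "trust")
        for step in result.steps:
            assert step.statistic >= 0
            assert 0 <= step.p_value <= 1

    def test_strong_condition_effect_detected_first_step(self):
        spec = StudySimSpec(
            n_participants=60,
            condition_effects={"personalized": 2.0},
            seed=11,
        )
        frame = study_records_frame(simulate_user_study(spec)[0])
        result = fit_ladder(frame, "motivation")
        assert result.steps[0].p_value < 0.01

    def test_requires_all_nine_situations(self, null_frame):
        subset = null_frame[null_frame["trend"] != "rising"]
        with pytest.raises(ValueError):
            fit_ladder(subset, "motivation")


class TestPosthocPairwise:
    def test_three_level_factor_gives_three_contrasts(self):
        spec = StudySimSpec(n_participants=30, seed=2)
        frame = study_records_frame(simulate_user_study(spec)[0])
        contrasts = posthoc_pairwise(frame)
        assert len(contrasts) == 3
        pairs = {frozenset((c.level_a, c.level_b)) for c in contrasts}
        assert len(pairs) == 3

    def test_null_contrasts_near_zero(self):
        spec = StudySimSpec(n_participants=90, seed=3)
        frame = study_records_frame(simulate_user_study(spec)[0])
        for c in posthoc_pairwise(frame):
            assert abs(c.estimate) < 1.5
            assert c.ci_low < c.estimate < c.ci_high

    def test_shift_direction_recovered(self):
        spec = StudySimSpec(
            n_participants=60,
            condition_effects={"personalized": 2.0},
            seed=19,
        )
        frame = study_records_frame(simulate_user_study(spec)[0])
        for c in posthoc_pairwise(frame):
            involved = {c.level_a, c.level_b}
            if "personalized" not in involved:
                continue
            signed = c.estimate if c.level_a == "personalized" else -c.estimate
            assert signed < 0  # personalized level sits higher


class TestCSV:
    def test_records_round_trip(self, tmp_path):
        spec = StudySimSpec(n_participants=6, seed=1)
        records, overall = simulate_user_study(spec)
        frame = study_records_frame(records)
        path = tmp_path / "records.csv"
        frame.to_csv(path, index=False)
        loaded = read_records_csv(path)
        assert len(loaded) == len(frame)
        np.testing.assert_allclose(
            loaded["d_motivation"], frame["d_motivation"]
        )

    def test_overall_round_trip(self, tmp_path):
        import pandas as pd

        spec = StudySimSpec(n_participants=6, seed=1)
        _records, overall = simulate_user_study(spec)
        rows = []
        for r in overall:
            row = {
                "participant_id": r.participant_id,
                "condition": r.condition,
                "overall_d_motivation": r.overall_d_motivation,
                "overall_d_trust": r.overall_d_trust,
            }
            row.update({
                f"fbh_item{i + 1}": v for i, v in enumerate(r.fbh_items)
            })
            rows.append(row)
        path = tmp_path / "overall.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        loaded = read_overall_csv(path)
        assert loaded[0].fbh_score == pytest.approx(overall[0].fbh_score)
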