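import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from axodyne.stats import (
    anova_oneway,
    newman_keuls,
    studentized_range_quantile,
    survival_percent,
    ttest_unpaired,
)
from axodyne.synthetic import simulate_cohort


def _cohort(n_t1, n_surviving, n_new, condition="WT"):
    rows = []
    for i in range(n_t1):
        rows.append(
            dict(
                cell_id=f"c{i}",
                condition=condition,
                present_at_t1=True,
                present_at_t2=i < n_surviving,
                newly_appeared=False,
            )
        )
    for i in range(n_new):
        rows.append(
            dict(
                cell_id=f"n{i}",
                condition=condition,
                present_at_t1=False,
                present_at_t2=True,
                newly_appeared=True,
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# survival


def test_survival_basic_percentage():
    assert survival_percent(_cohort(10, 8, 0)).pct_survival == pytest.approx(80.0)


def test_survival_can_exceed_100_with_new_expression():
    assert survival_percent(_cohort(10, 10, 1)).pct_survival == pytest.approx(110.0)


def test_survival_requires_cells_at_t1():
    with pytest.raises(ValueError):
        survival_percent(_cohort(0, 0, 2))


def test_survival_scale_invariant_in_counts():
    a = survival_percent(_cohort(10, 7, 1)).pct_survival
    b = survival_percent(_cohort(20, 14, 2)).pct_survival
    assert a == pytest.approx(b)


def test_simulated_asyn_cohorts_recover_survival_probability(asyn):
    rng = np.random.default_rng(0)
    pcts = []
    for _ in range(500):
        n = max(1, rng.poisson(5))
        pcts.append(survival_percent(simulate_cohort(asyn, n, rng)).pct_survival)
    se = np.std(pcts, ddof=1) / np.sqrt(len(pcts))
    assert np.mean(pcts) == pytest.approx(100 * asyn.survival_2to3dpf, abs=3 * se)


# ---------------------------------------------------------------------------
# t-test


def test_identical_samples_give_t0_p1():
    res = ttest_unpaired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)


def test_shifted_sample_is_detected():
    a = np.array([1.0, 2.0, 3.0])
    res = ttest_unpaired(a, a + 10)
    # closed form with pooled SD 1: t = -10 / (1·sqrt(2/3))
    assert res.statistic == pytest.approx(-10 / np.sqrt(2 / 3), rel=1e-6)
    assert res.p_value < 0.01


def test_degenerate_equal_constant_samples_p1_by_convention():
    res = ttest_unpaired([2.0, 2.0, 2.0], [2.0, 2.0])
    assert res.p_value == 1.0


def test_small_samples_rejected():
    with pytest.raises(ValueError):
        ttest_unpaired([1.0], [1.0, 2.0])


def test_type_one_error_rate_near_alpha():
    rng = np.random.default_rng(11)
    reps = 4000
    a = rng.normal(size=(reps, 8))
    b = rng.normal(size=(reps, 8))
    res = sps.ttest_ind(a, b, axis=1)
    ours = [ttest_unpaired(a[i], b[i]).p_value for i in range(200)]
    np.testing.assert_allclose(ours, res.pvalue[:200], rtol=1e-10)
    rate = float(np.mean(res.pvalue < 0.05))
    mc = 3 * np.sqrt(0.05 * 0.95 / reps)
    assert rate == pytest.approx(0.05, abs=mc)


# ---------------------------------------------------------------------------
# ANOVA


def test_identical_groups_give_f0_p1():
    g = [1.0, 2.0, 3.0]
    res = anova_oneway([g, g, g])
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_separated_groups_drive_p_to_zero():
    eps = 1e-6
    res = anova_oneway([[0, eps, -eps], [1, 1 + eps, 1 - eps]])
    assert res.p_value < 1e-9


def test_f_matches_hand_computed_sums_of_squares():
    groups = [np.array([1.0, 2.0, 3.0]), np.array([2.0, 4.0]), np.array([5.0, 6.0, 9.0])]
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    k, n = 3, allv.size
    f_expected = (ss_between / (k - 1)) / (ss_within / (n - k))
    res = anova_oneway(groups)
    assert res.statistic == pytest.approx(f_expected, rel=1e-10)
    assert res.df == (2, 5)


def test_anova_with_two_groups_equals_t_squared():
    rng = np.random.default_rng(5)
    a, b = rng.normal(size=10), rng.normal(1.0, 1.0, size=12)
    f = anova_oneway([a, b]).statistic
    t = ttest_unpaired(a, b).statistic
    assert f == pytest.approx(t**2, rel=1e-10)


def test_group_too_small_rejected():
    with pytest.raises(ValueError):
        anova_oneway([[1.0, 2.0], [3.0]])


# ---------------------------------------------------------------------------
# Newman–Keuls


def test_published_studentized_range_quantile():
    assert studentized_range_quantile(0.05, 3, 18) == pytest.approx(3.609, abs=5e-4)


def test_identical_groups_all_nonsignificant():
    g = [1.0, 2.0, 3.0, 4.0]
    res = newman_keuls([g, g, g])
    assert not res.pairwise.significant.any()


def test_two_groups_match_t_test_decision():
    rng = np.random.default_rng(8)
    for shift in (0.0, 0.5, 1.5, 3.0):
        a = rng.normal(size=10)
        b = rng.normal(shift, 1.0, size=10)
        t_sig = ttest_unpaired(a, b).p_value < 0.05
        nk = newman_keuls([a, b])
        assert bool(nk.pairwise.significant.iloc[0]) == t_sig
        # q² = 2t² equivalence makes the p-values agree exactly
        assert nk.pairwise.p_value.iloc[0] == pytest.approx(
            ttest_unpaired(a, b).p_value, rel=1e-6
        )


def test_outlier_group_only_significant_pairs():
    rng = np.random.default_rng(9)
    a = rng.normal(0, 1, 10)
    b = rng.normal(0, 1, 10)
    c = rng.normal(10, 1, 10)
    res = newman_keuls([a, b, c], labels=["a", "b", "c"])
    pw = res.pairwise.set_index(["group_a", "group_b"])
    assert pw.loc[("a", "c"), "significant"].item()
    assert pw.loc[("b", "c"), "significant"].item()
    assert not pw.loc[("a", "b"), "significant"].item()


def test_interior_comparisons_blocked_by_nonsignificant_span():
    # all three groups from one distribution: if the widest span is not
    # significant, interior pairs must be declared non-significant too
    rng = np.random.default_rng(10)
    groups = [rng.normal(0, 1, 6) for _ in range(3)]
    res = newman_keuls(groups)
    span3 = res.pairwise[res.pairwise.stretch == 3]
    if not span3.significant.any():
        assert not res.pairwise.significant.any()


def test_significance_monotone_in_mean_separation():
    rng = np.random.default_rng(12)
    base = rng.normal(0, 1, 10)
    p_values = []
    for shift in (0.5, 1.5, 3.0, 6.0):
        res = newman_keuls([base, base + shift])
        p_values.append(res.pairwise.p_value.iloc[0])
    assert all(b <= a for a, b in zip(p_values, p_values[1:]))


def test_fewer_than_two_groups_rejected():
    with pytest.raises(ValueError):
        newman_keuls([[1.0, 2.0]])
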