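"""Tests for the statistical layer: tables, odds, logistic fits, reliability."""

import math

import numpy as np
import pandas as pd
import pytest

from frailkit import (
    CrossTab,
    chi_square,
    cronbach_alpha,
    crosstab,
    fit_logistic,
    fit_univariable,
    odds_ratio,
    prevalence_ci,
    subgroup_frailty_odds,
    t_test,
)
from frailkit.association import Z95
from frailkit.errors import (
    DegenerateTableError,
    DomainError,
    InfiniteOddsError,
    RankDeficiencyError,
    SeparationError,
    UndefinedAlphaError,
    ValidationError,
)
from frailkit.reference_cohort import REFERENCE_CROSSTABS


def _pearson_oracle(counts: np.ndarray) -> float:
    """Brute-force O/E summation, independent of the tested path."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    stat = 0.0
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            e = counts[i].sum() * counts[:, j].sum() / total
            stat += (counts[i, j] - e) ** 2 / e
    return stat


# ---------------------------------------------------------------------------
# cross-tabs


def test_crosstab_counts_match_generating_tables(reference_cohort):
    table = crosstab(reference_cohort, "gender")
    assert table.levels == ("Male", "Female")
    assert table.counts.tolist() == [[27, 74, 78, 50], [7, 46, 67, 51]]
    assert table.binary_counts() == {"Male": (101, 128), "Female": (53, 118)}
    assert table.grand_total == 400


def test_crosstab_empty_cohort_and_singleton():
    empty = pd.DataFrame({"gender": [], "category": []})
    table = crosstab(empty, "gender", level_order=["Male", "Female"])
    assert table.counts.sum() == 0 and table.levels == ("Male", "Female")
    one = pd.DataFrame({"gender": ["Male"], "category": ["FIT"]})
    table = crosstab(one, "gender", level_order=["Male", "Female"])
    assert table.counts.tolist() == [[1, 0, 0, 0], [0, 0, 0, 0]]


def test_crosstab_rejects_unknown_covariate_and_undeclared_level(reference_cohort):
    with pytest.raises(ValidationError):
        crosstab(reference_cohort, "shoe_size")
    with pytest.raises(ValidationError, match="undeclared"):
        crosstab(reference_cohort, "gender", level_order=["Male"])


def test_crosstab_row_sums_equal_binary_collapse(reference_cohort):
    for cov in REFERENCE_CROSSTABS:
        table = crosstab(reference_cohort, cov)
        binary = table.binary_counts()
        for lvl, row in zip(table.levels, table.counts):
            assert sum(binary[lvl]) == row.sum()


# ---------------------------------------------------------------------------
# chi-square


def test_chi_square_gender_table_matches_published_p():
    res = chi_square(CrossTab.from_reference("gender"))
    assert res.statistic == pytest.approx(10.96, abs=0.01)
    assert res.df == 3
    assert round(res.p_value, 3) == 0.012


def test_chi_square_perfect_independence_is_zero():
    res = chi_square(np.array([[10, 10], [10, 10]]))
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(1.0)


def test_chi_square_agrees_with_expected_count_oracle(rng):
    for _ in range(20):
        counts = rng.integers(1, 50, size=(rng.integers(2, 5), rng.integers(2, 5)))
        res = chi_square(counts)
        assert res.statistic == pytest.approx(_pearson_oracle(counts), rel=1e-12)
        assert res.df == (counts.shape[0] - 1) * (counts.shape[1] - 1)


def test_chi_square_permutation_and_scaling_invariance(rng):
    counts = rng.integers(1, 40, size=(3, 4))
    base = chi_square(counts).statistic
    perm = counts[rng.permutation(3)][:, rng.permutation(4)]
    assert chi_square(perm).statistic == pytest.approx(base, rel=1e-12)
    assert chi_square(counts * 7).statistic == pytest.approx(base * 7, rel=1e-12)


def test_chi_square_degenerate_table_errors():
    with pytest.raises(DegenerateTableError):
        chi_square(np.array([[5, 5, 5, 5]]))
    with pytest.raises(DegenerateTableError):
        chi_square(np.array([[5, 0], [7, 0]]))


def test_chi_square_flags_low_expected_counts():
    assert chi_square(np.array([[1, 2], [2, 1]])).low_expected
    assert not chi_square(np.array([[50, 50], [50, 50]])).low_expected


# ---------------------------------------------------------------------------
# odds


def test_subgroup_odds_reproduce_published_unadjusted_column():
    expected = {
        ("age_group", "60-64"): 65 / 25,
        ("age_group", "70+"): 77 / 22,
        ("gender", "Female"): 118 / 53,
    }
    for (cov, lvl), value in expected.items():
        res = subgroup_frailty_odds(CrossTab.from_reference(cov), lvl)
        assert res.estimate == pytest.approx(value)


def test_subgroup_odds_female_wald_interval_closed_form():
    res = subgroup_frailty_odds(CrossTab.from_reference("gender"), "Female")
    se = math.sqrt(1 / 118 + 1 / 53)
    assert res.ci_low == pytest.approx(math.exp(math.log(118 / 53) - Z95 * se))
    assert res.ci_high == pytest.approx(math.exp(math.log(118 / 53) + Z95 * se))
    assert (round(res.ci_low, 2), round(res.ci_high, 2)) == (1.61, 3.08)


def test_subgroup_odds_is_frail_fraction_identity(rng):
    """odds = p/(1-p) where p is the level's frail fraction."""
    for _ in range(20):
        counts = rng.integers(1, 60, size=(3, 4))
        table = CrossTab("x", ("a", "b", "c"), counts)
        for lvl, (fit, frail) in table.binary_counts().items():
            p = frail / (fit + frail)
            assert subgroup_frailty_odds(table, lvl).estimate == pytest.approx(p / (1 - p))


def test_subgroup_odds_balanced_level_is_one():
    table = CrossTab("x", ("a",), np.array([[5, 5, 5, 5]]))
    assert subgroup_frailty_odds(table, "a").estimate == 1.0


def test_subgroup_odds_empty_fit_cell_errors():
    table = CrossTab("x", ("a",), np.array([[0, 0, 3, 4]]))
    with pytest.raises(InfiniteOddsError):
        subgroup_frailty_odds(table, "a")


def test_odds_ratio_reference_contrast():
    table = CrossTab.from_reference("gender")
    res = odds_ratio(table, "Female", "Male")
    assert res.estimate == pytest.approx((118 * 101) / (53 * 128))
    assert odds_ratio(table, "Male", "Male").estimate == 1.0


def test_odds_ratio_matches_cross_product_oracle(rng):
    for _ in range(20):
        counts = rng.integers(1, 60, size=(2, 4))
        table = CrossTab("x", ("a", "b"), counts)
        binary = table.binary_counts()
        (fa, ra), (fb, rb) = binary["a"], binary["b"]
        assert odds_ratio(table, "a", "b").estimate == pytest.approx((ra * fb) / (fa * rb))


def test_odds_ratio_zero_cell_haldane():
    table = CrossTab("x", ("a", "b"), np.array([[5, 5, 0, 0], [2, 2, 3, 3]]))
    with pytest.raises(ValidationError):
        odds_ratio(table, "a", "b")
    res = odds_ratio(table, "a", "b", haldane=True)
    assert res.estimate == pytest.approx((0.5 * 4.5) / (10.5 * 6.5))


# ---------------------------------------------------------------------------
# logistic regression


def _binary_cohort(n00, n01, n10, n11):
    """Cohort with counts (exposed, frail): 00/01/10/11."""
    rows = (
        [{"x": "ref", "frail": 0}] * n00
        + [{"x": "ref", "frail": 1}] * n01
        + [{"x": "lvl", "frail": 0}] * n10
        + [{"x": "lvl", "frail": 1}] * n11
    )
    return pd.DataFrame(rows)


def test_univariable_logistic_equals_closed_form_2x2_odds_ratio():
    df = _binary_cohort(40, 25, 18, 33)
    fit = fit_univariable(df, "x", references={"x": "ref"}, level_order={"x": ["ref", "lvl"]})
    closed = (33 * 40) / (18 * 25)
    term = fit.term("x", "lvl")
    assert term.odds_ratio == pytest.approx(closed, abs=1e-6)
    assert term.se == pytest.approx(math.sqrt(1 / 40 + 1 / 25 + 1 / 18 + 1 / 33), rel=1e-6)
    assert fit.converged


def test_intercept_only_model_recovers_log_odds_of_prevalence():
    df = pd.DataFrame({"frail": [1] * 30 + [0] * 70})
    fit = fit_logistic(df, [], outcome="frail")
    assert fit.intercept == pytest.approx(math.log(30 / 70), abs=1e-8)


def test_logistic_detects_complete_separation():
    df = _binary_cohort(40, 0, 0, 40)
    with pytest.raises(SeparationError, match="x=lvl"):
        fit_univariable(df, "x", references={"x": "ref"}, level_order={"x": ["ref", "lvl"]})


def test_logistic_detects_rank_deficiency():
    df = _binary_cohort(40, 25, 18, 33)
    df["y"] = df["x"]  # perfectly collinear copy
    with pytest.raises(RankDeficiencyError):
        fit_logistic(
            df,
            ["x", "y"],
            references={"x": "ref", "y": "ref"},
            level_order={"x": ["ref", "lvl"], "y": ["ref", "lvl"]},
        )


def test_logistic_requires_both_outcome_classes():
    df = pd.DataFrame({"x": ["a", "b"], "frail": [1, 1]})
    with pytest.raises(ValidationError):
        fit_logistic(df, ["x"], references={"x": "a"}, level_order={"x": ["a", "b"]})


def test_logistic_reference_rows_carry_no_estimate(reference_cohort):
    fit = fit_logistic(reference_cohort, ["age_group", "gender"])
    ref_terms = [t for t in fit.terms if t.is_reference]
    assert {(t.name, t.level) for t in ref_terms} == {("age_group", "55-59"), ("gender", "Male")}
    assert all(t.beta is None for t in ref_terms)
    est = fit.term("gender", "Female")
    assert est.odds_ratio == pytest.approx(math.exp(est.beta))
    assert est.ci_low == pytest.approx(math.exp(est.beta - Z95 * est.se))


# ---------------------------------------------------------------------------
# t-test, alpha, prevalence


def test_t_test_identical_groups():
    res = t_test([0.1, 0.2, 0.3, 0.4], [0.1, 0.2, 0.3, 0.4])
    assert res.t == 0.0 and res.p_value == pytest.approx(1.0)


def test_t_test_published_gender_summaries():
    res = t_test((229, 0.271, 0.118), (171, 0.303, 0.114))
    assert res.t == pytest.approx(-2.72, abs=0.01)
    assert res.df == 398
    assert res.p_value == pytest.approx(0.007, abs=5e-4)
    assert math.copysign(1, res.t) == math.copysign(1, res.mean_diff)


def test_t_test_raw_vectors_equal_their_summaries(rng):
    a = rng.normal(0.27, 0.1, 40)
    b = rng.normal(0.31, 0.12, 55)
    raw = t_test(a, b)
    summ = t_test((40, float(a.mean()), float(a.std(ddof=1))), (55, float(b.mean()), float(b.std(ddof=1))))
    assert raw.t == pytest.approx(summ.t, rel=1e-12)


def test_t_test_degenerate_group_errors():
    with pytest.raises(ValidationError):
        t_test([0.1], [0.2, 0.3])
    with pytest.raises(ValidationError):
        t_test((5, 0.2, 0.0), (5, 0.3, 0.1))


def test_cronbach_alpha_duplicated_items_is_one(rng):
    col = rng.random(50)
    X = np.tile(col[:, None], (1, 30))
    assert cronbach_alpha(X).alpha == pytest.approx(1.0)


def test_cronbach_alpha_two_item_closed_form(rng):
    X = rng.random((80, 2))
    v1, v2 = X.var(axis=0, ddof=1)
    vt = X.sum(axis=1).var(ddof=1)
    assert cronbach_alpha(X).alpha == pytest.approx(2 * (1 - (v1 + v2) / vt), rel=1e-12)


def test_cronbach_alpha_independent_items_near_zero(rng):
    X = rng.random((5000, 10))
    assert abs(cronbach_alpha(X).alpha) < 0.1


def test_cronbach_alpha_matches_independent_implementation(rng):
    pingouin = pytest.importorskip("pingouin")
    X = pd.DataFrame(rng.random((60, 8)))
    expected = pingouin.cronbach_alpha(data=X)[0]
    assert cronbach_alpha(X).alpha == pytest.approx(expected, rel=1e-9)


def test_cronbach_alpha_zero_variance_undefined():
    with pytest.raises(UndefinedAlphaError):
        cronbach_alpha(np.ones((10, 5)))


def test_prevalence_ci_edge_and_symmetry():
    res = prevalence_ci(0, 50)
    assert res.estimate == 0.0 and res.ci_low == 0.0
    res = prevalence_ci(200, 400)
    assert res.estimate == 0.5
    assert res.ci_low + res.ci_high == pytest.approx(1.0)


def test_prevalence_ci_wilson_closed_form():
    k, n, z = 34, 400, Z95
    p = k / n
    centre = (p + z**2 / (2 * n)) / (1 + z**2 / n)
    half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / (1 + z**2 / n)
    res = prevalence_ci(k, n, method="wilson")
    assert res.ci_low == pytest.approx(centre - half, rel=1e-6)
    assert res.ci_high == pytest.approx(centre + half, rel=1e-6)


def test_prevalence_ci_wald_closed_form():
    res = prevalence_ci(100, 400, method="wald")
    half = Z95 * math.sqrt(0.25 * 0.75 / 400)
    assert res.ci_low == pytest.approx(0.25 - half, rel=1e-6)


def test_prevalence_ci_rejects_bad_inputs():
    with pytest.raises(DomainError):
        prevalence_ci(5, 0)
    with pytest.raises(DomainError):
        prevalence_ci(10, 5)
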