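"""Strategy-analysis pipeline: curves, fits, classification, comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from conftest import make_response_table
from oracles import firth_grid_argmax, firth_penalized_loglik
from streaklab.analysis import (
    AnalysisError,
    BETA_CAP,
    StrategyFit,
    aggregate_curve,
    classify_strategies,
    compare_groups,
    dichotomize,
    fit_logodds_pct,
    fit_participants,
    fit_slope,
    participant_repeat_rates,
)

STREAKS = (2, 3, 4, 5, 6, 7)


def _continuous_table(responses_by_pid, condition="Bingo"):
    rows = []
    for pid, responses in responses_by_pid.items():
        for trial, (L, resp) in enumerate(zip(STREAKS, responses), start=1):
            rows.append((pid, condition, "continuous", trial, "target", L, "ABABABAA", resp))
    return make_response_table(rows)


# ---------------------------------------------------------------------------
# aggregate_curve


def test_aggregate_constant_ratings():
    table = _continuous_table({"p1": [100] * 6, "p2": [100] * 6})
    curve = aggregate_curve(table)
    assert (curve["mean"] == 100).all()
    assert (curve["se"] == 0).all()
    assert (curve["n"] == 2).all()
    assert not curve["filler_flag"].any()


def test_aggregate_hand_arithmetic():
    table = _continuous_table({"p1": [40] * 6, "p2": [60] * 6})
    curve = aggregate_curve(table)
    at3 = curve[curve["streak_length"] == 3].iloc[0]
    assert at3["mean"] == 50
    assert at3["se"] == pytest.approx(10.0)  # sd 14.14 / sqrt(2)


def test_aggregate_flags_fillers_and_averages_within_participant():
    rows = [
        ("p1", "Bingo", "continuous", 1, "filler", 1, "ABABABAB", 30),
        ("p1", "Bingo", "continuous", 2, "filler", 1, "BABABABA", 50),
        ("p2", "Bingo", "continuous", 1, "filler", 1, "ABABABAB", 60),
        ("p2", "Bingo", "continuous", 2, "filler", 1, "BABABABA", 80),
    ]
    curve = aggregate_curve(make_response_table(rows))
    row = curve.iloc[0]
    assert row["filler_flag"]
    # participant means 40 and 70; SE from the two participant means
    assert row["mean"] == 55
    assert row["se"] == pytest.approx(np.std([40, 70], ddof=1) / np.sqrt(2))


def test_aggregate_rejects_mixed_formats():
    table = _continuous_table({"p1": [50] * 6})
    table.loc[0, "format"] = "dichotomous"
    with pytest.raises(AnalysisError):
        aggregate_curve(table)


# ---------------------------------------------------------------------------
# per-participant fits


def test_slope_of_exact_line_is_five():
    slope, intercept = fit_slope([50, 55, 60, 65, 70, 75])
    assert slope == pytest.approx(5.0)
    assert intercept == pytest.approx(40.0)


def test_slope_of_constant_ratings_is_zero():
    slope, _ = fit_slope([62] * 6)
    assert slope == pytest.approx(0.0)


def test_slope_matches_normal_equations():
    y = np.array([60.0, 50.0, 70.0, 55.0, 65.0, 75.0])
    x = np.array(STREAKS, dtype=float)
    slope, intercept = fit_slope(y)
    beta = np.linalg.solve(
        np.array([[len(x), x.sum()], [x.sum(), (x**2).sum()]]),
        np.array([y.sum(), (x * y).sum()]),
    )
    assert slope == pytest.approx(beta[1])
    assert intercept == pytest.approx(beta[0])
    assert slope == pytest.approx(3.0)


def test_fit_rejects_wrong_trials():
    with pytest.raises(AnalysisError):
        fit_slope([1, 2, 3, 4, 5], streaks=(2, 3, 4, 5, 6))
    with pytest.raises(AnalysisError):
        fit_slope([1] * 6, streaks=(1, 2, 3, 4, 5, 6))


def test_logodds_percent_change_transform():
    fit = fit_logodds_pct([0, 1, 0, 1, 1, 0])
    assert fit.pct_change == pytest.approx(100 * (np.exp(fit.beta) - 1))
    # beta = ln 2 would mean the odds double per unit streak length
    assert 100 * (np.exp(np.log(2)) - 1) == pytest.approx(100.0)


def test_logodds_matches_penalized_likelihood_oracle():
    x = np.array(STREAKS, dtype=float)
    for y in ([0, 1, 0, 1, 1, 1], [1, 0, 0, 1, 0, 1], [0, 0, 1, 0, 1, 1]):
        fit = fit_logodds_pct(y)
        b0, b1 = firth_grid_argmax(np.array(y, dtype=float), x)
        assert fit.beta == pytest.approx(b1, abs=0.02)
        impl_ll = firth_penalized_loglik(
            *_intercept_and_beta(y), np.array(y, dtype=float), x
        )
        assert impl_ll >= firth_penalized_loglik(b0, b1, np.array(y, dtype=float), x) - 1e-6


def _intercept_and_beta(y):
    from streaklab.analysis import _firth_logistic

    b = _firth_logistic(np.array(y, dtype=float), np.array(STREAKS, dtype=float))
    return float(b[0]), float(b[1])


def test_separated_responses_are_flagged_and_finite():
    fit = fit_logodds_pct([0, 0, 0, 1, 1, 1])
    assert "separation" in fit.fit_flags
    assert np.isfinite(fit.beta) and abs(fit.beta) <= BETA_CAP
    assert fit.pct_change > -100
    assert fit.strategy == "positive"
    # Firth keeps the maximizer finite; compare against the grid oracle
    b0, b1 = firth_grid_argmax(np.array([0, 0, 0, 1, 1, 1.0]), np.array(STREAKS, dtype=float))
    assert fit.beta == pytest.approx(b1, abs=0.02)


def test_constant_choices_are_flagged_not_overflowed():
    fit = fit_logodds_pct([1, 1, 1, 1, 1, 1])
    assert "constant-responses" in fit.fit_flags
    assert np.isfinite(fit.beta)
    assert abs(fit.beta) <= BETA_CAP


# ---------------------------------------------------------------------------
# classification


def _fit(slope, condition="Bingo", pid="p"):
    return StrategyFit(
        participant_id=pid,
        format="continuous",
        condition=condition,
        slope=slope,
        strategy="",
    )


def test_classify_all_positive():
    shares = classify_strategies([_fit(5.0, pid=f"p{i}") for i in range(4)])
    assert shares.loc["Bingo", "positive"] == 1.0
    assert shares.loc["Bingo", "negative"] == 0.0
    assert shares.loc["Bingo", "n"] == 4


def test_classify_split_and_flat():
    shares = classify_strategies([_fit(1.0, pid="a"), _fit(-1.0, pid="b")])
    assert shares.loc["Bingo", "positive"] == 0.5
    assert shares.loc["Bingo", "negative"] == 0.5
    shares = classify_strategies([_fit(0.0, pid="a")])
    assert shares.loc["Bingo", "flat"] == 1.0


def test_classification_mirror_invariance():
    """Mirroring every rating (p -> 100 - p) must flip positive and negative
    strategy shares exactly."""
    rng = np.random.default_rng(8)
    ratings = {f"p{i}": list(rng.uniform(0, 100, size=6)) for i in range(12)}
    table = _continuous_table(ratings)
    mirrored = table.copy()
    mirrored["response"] = 100 - mirrored["response"]
    a = classify_strategies(fit_participants(table))
    b = classify_strategies(fit_participants(mirrored))
    assert a.loc["Bingo", "positive"] == b.loc["Bingo", "negative"]
    assert a.loc["Bingo", "negative"] == b.loc["Bingo", "positive"]


@given(st.lists(st.floats(0, 100), min_size=6, max_size=6), st.floats(0, 40))
@settings(derandomize=True, max_examples=60)
def test_uniform_raise_never_lowers_slope(ratings, shift):
    """Raising every rating by a common amount leaves the fitted slope
    unchanged (a weak raise), shifting only the intercept."""
    base, _ = fit_slope(ratings)
    shifted, _ = fit_slope([min(r + shift, 1e6) for r in ratings])
    assert shifted == pytest.approx(base, abs=1e-6)


# ---------------------------------------------------------------------------
# dichotomization and group comparison


def test_dichotomize_codes_and_audits():
    table = _continuous_table({"p1": [73, 12, 50, 49.5, 50.5, 88]})
    result = dichotomize(table)
    assert result.n_excluded == 1
    coded = dict(zip(result.table["trial_index"], result.table["response"]))
    assert coded[1] == 1 and coded[2] == 0 and coded[4] == 0 and coded[5] == 1
    assert (result.table["format"] == "dichotomous").all()

    clean = _continuous_table({"p1": [60, 40, 70, 30, 80, 20]})
    assert len(dichotomize(clean).table) == len(clean)


def test_welch_identical_groups():
    cmp = compare_groups([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
    assert cmp.difference == 0.0
    assert cmp.t == 0.0


def test_welch_hand_example():
    cmp = compare_groups([0, 0, 1, 1], [1, 1, 1, 1], "A", "B")
    assert cmp.difference == -0.5
    assert cmp.t == pytest.approx(-np.sqrt(3))
    assert cmp.df == pytest.approx(3.0)


def test_welch_matches_scipy_oracle():
    rng = np.random.default_rng(21)
    a = rng.normal(0.6, 0.2, size=40)
    b = rng.normal(0.5, 0.3, size=55)
    cmp = compare_groups(a, b)
    t, p = sps.ttest_ind(a, b, equal_var=False)
    assert cmp.t == pytest.approx(t)
    assert cmp.p_value == pytest.approx(p)


def test_welch_needs_two_per_group():
    with pytest.raises(AnalysisError):
        compare_groups([1.0], [0.0, 1.0])


def test_repeat_rates_are_target_means():
    table = _continuous_table({"p1": [0, 0, 1, 1, 1, 1]})
    rates = participant_repeat_rates(table)
    assert rates.loc[0, "repeat_rate"] == pytest.approx(4 / 6)
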