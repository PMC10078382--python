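"""Observer models: Bayesian updating, urn depletion, and their regimes.

Every frozen rational below was reproduced by an independent oracle
(direct posterior sums or exhaustive enumeration of ordered urn draws)
before being asserted.
"""

from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import iid_repeat_probability_direct, urn_repeat_probability_enumerated
from streaklab.observers import (
    DegeneratePosteriorError,
    ObserverError,
    ObserverSpec,
    PriorSpec,
    UrnSpec,
    ZeroProbabilityHistoryError,
    iid_posterior,
    model_curve,
    predict_repeat_iid,
    urn_posterior_predict,
    urn_predict_known,
)
from streaklab.stimuli import canonical_streak_sequence

THREE = PriorSpec.three_rate()
sequences = st.lists(st.sampled_from("ab"), min_size=1, max_size=8).map(tuple)


# ---------------------------------------------------------------------------
# i.i.d. Bayes


def test_point_prior_is_inert():
    prior = PriorSpec.point(Fraction(1, 2))
    assert iid_posterior(prior, "abbabbba") is prior
    for seq in ("abbbbbbb", "aaaaaaaa", "ab"):
        assert predict_repeat_iid(prior, seq) == Fraction(1, 2)


def test_discrete_posterior_after_seven_streak():
    # "a b b b b b b b": the low focal rate (1/4) best explains seven b's
    post = iid_posterior(THREE, "abbbbbbb")
    direct = []
    for t, p in zip(THREE.support, THREE.probs):
        direct.append(p * t * (1 - t) ** 7)
    total = sum(direct)
    assert post.probs == tuple(w / total for w in direct)
    assert float(post.probs[0]) == pytest.approx(0.894, abs=5e-4)


def test_discrete_repeat_probability_after_seven_streak():
    expected = iid_repeat_probability_direct(THREE.support, THREE.probs, "abbbbbbb")
    got = predict_repeat_iid(THREE, "abbbbbbb")
    assert got == expected
    assert float(got) == pytest.approx(0.723, abs=5e-4)


def test_discrete_posterior_symmetry_on_balanced_sequence():
    post = iid_posterior(THREE, "aabbabab")  # four of each
    assert post.probs[0] == post.probs[2]
    assert predict_repeat_iid(THREE, "aabbabab") == Fraction(1, 2)


def test_conjugate_laplace_rule():
    prior = PriorSpec.conjugate(1, 1)
    # seven of eight outcomes are the terminal symbol
    assert predict_repeat_iid(prior, "abbbbbbb") == Fraction(8, 10)
    post = iid_posterior(prior, "abbbbbbb")
    assert (post.alpha, post.beta) == (Fraction(2), Fraction(8))


@given(sequences)
@settings(derandomize=True, max_examples=80)
def test_discrete_posterior_normalizes_and_bounds_hold(seq):
    post = iid_posterior(THREE, seq)
    assert sum(post.probs) == 1
    p = predict_repeat_iid(THREE, seq)
    assert Fraction(1, 4) <= p <= Fraction(3, 4)


def test_prior_validation():
    with pytest.raises(ObserverError):
        PriorSpec.point(0)
    with pytest.raises(ObserverError):
        PriorSpec.discrete((0.25, 0.75), (0.6, 0.6))
    with pytest.raises(ObserverError):
        PriorSpec.conjugate(0, 1)


# ---------------------------------------------------------------------------
# Urn observers


def test_known_urn_examples():
    assert urn_predict_known(0.5, 100, "") == Fraction(1, 2)
    assert urn_predict_known(0.5, 10, "bbb") == Fraction(2, 7)
    assert urn_predict_known(0.5, 8, "bbbb") == 0


def test_known_urn_matches_enumeration_oracle():
    got = urn_predict_known(0.5, 10, "bbb")
    oracle = urn_repeat_probability_enumerated(10, [5], [Fraction(1)], "bbb")
    assert got == oracle


def test_known_urn_depletion_is_strictly_decreasing():
    values = [urn_predict_known(0.5, 20, "b" * k) for k in range(1, 8)]
    assert all(x > y for x, y in zip(values, values[1:]))


def test_known_urn_impossible_history():
    with pytest.raises(ZeroProbabilityHistoryError):
        urn_predict_known(0.25, 12, "aaaa")  # only three a's in the urn
    with pytest.raises(ObserverError):
        urn_predict_known(0.3, 11, "ab")  # θN not an integer


def test_uncertain_urn_seven_streak():
    urn = UrnSpec(N=20, prior=THREE)
    result = urn_posterior_predict(urn, "abbbbbbb")
    # the 15-a composition holds only five b's and cannot supply seven
    assert result.posterior.support == (Fraction(1, 4), Fraction(1, 2))
    oracle = urn_repeat_probability_enumerated(
        20, [5, 10, 15], [Fraction(1, 3)] * 3, "abbbbbbb"
    )
    assert result.p_repeat == oracle
    assert float(result.p_repeat) == pytest.approx(0.652, abs=5e-4)


def test_uncertain_urn_symmetric_history_is_even_money():
    urn = UrnSpec(N=20, prior=THREE)
    assert urn_posterior_predict(urn, "aabbabab").p_repeat == Fraction(1, 2)


def test_uncertain_urn_degenerate_history():
    urn = UrnSpec(N=12, prior=PriorSpec.discrete((Fraction(1, 4),)))
    with pytest.raises(DegeneratePosteriorError):
        urn_posterior_predict(urn, "aaaa")


def test_urn_converges_to_iid_for_large_N():
    urn = UrnSpec(N=100_000, prior=THREE)
    for seq in ("abbbbbbb", "aabbabab", "bbbaaaab"):
        big = urn_posterior_predict(urn, seq).p_repeat
        iid = predict_repeat_iid(THREE, seq)
        assert abs(big - iid) < Fraction(1, 1000)


def test_urn_spec_validation():
    with pytest.raises(ObserverError):
        UrnSpec(N=8, prior=THREE)  # too small for 8 draws + prediction
    with pytest.raises(ObserverError):
        UrnSpec(N=10, prior=THREE)  # θN not integral for θ=1/4
    with pytest.raises(ObserverError):
        UrnSpec(N=20, prior=PriorSpec.conjugate(1, 1))  # no finite composition


# ---------------------------------------------------------------------------
# Regimes and curves


def test_regime_transition_fall_then_rise():
    """With a prior concentrated on θ=.5, depletion dominates short streaks
    (repeat probability dips below the streak-1 level) and belief updating
    dominates long ones (it rises above): the gambler's-fallacy-to-hot-hand
    transition."""
    prior = PriorSpec.discrete(
        (Fraction(1, 4), Fraction(1, 2), Fraction(3, 4)),
        (Fraction(1, 10), Fraction(8, 10), Fraction(1, 10)),
    )
    urn = UrnSpec(N=20, prior=prior)
    curve = [urn_posterior_predict(urn, canonical_streak_sequence(L)).p_repeat for L in range(1, 8)]
    support_counts = [5, 10, 15]
    oracle = [
        urn_repeat_probability_enumerated(20, support_counts, prior.probs, canonical_streak_sequence(L))
        for L in range(1, 8)
    ]
    assert curve == oracle
    base = curve[0]
    assert min(curve[1:]) < base < max(curve[1:])
    assert curve.index(min(curve[1:])) < curve.index(max(curve[1:]))


def test_iid_bayes_nondecreasing_on_pure_streak_targets():
    for prior in (PriorSpec.conjugate(1, 1), THREE):
        values = [predict_repeat_iid(prior, canonical_streak_sequence(L)) for L in range(2, 8)]
        assert all(x <= y for x, y in zip(values, values[1:]))


def test_model_curve_flat_for_fair_point_observer(stimset):
    curve = model_curve(ObserverSpec.iid(PriorSpec.point(0.5)), stimset)
    assert [pt.p_repeat for pt in curve.points] == [0.5] * len(curve.points)
    flags = {pt.streak_length: pt.filler_flag for pt in curve.points}
    assert flags[1] and not any(flags[L] for L in range(2, 8))
    assert next(pt.n_sequences for pt in curve.points if pt.streak_length == 1) == 12


def test_model_curve_observer_families_disagree_as_expected(stimset):
    """On the same session the known-rate urn observer sits at or below the
    fair coin value while the Beta(1,1) updater sits above it for long streaks."""
    urn = ObserverSpec.from_urn(UrnSpec(N=20, prior=PriorSpec.discrete((Fraction(1, 2),))))
    bayes = ObserverSpec.iid(PriorSpec.conjugate(1, 1))
    urn_curve = model_curve(urn, stimset).as_dict()
    bayes_curve = model_curve(bayes, stimset).as_dict()
    assert urn_curve[7] < 0.5 < bayes_curve[7]


def test_observer_spec_validation():
    with pytest.raises(ObserverError):
        ObserverSpec(family="urn")
    with pytest.raises(ObserverError):
        ObserverSpec(family="momentum", prior=THREE)
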