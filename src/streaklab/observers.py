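"""Normative observer models for streak-repetition predictions.

Two families of observer map an observed binary sequence to the probability
that its terminal streak repeats on the next outcome:

* **i.i.d. Bayes** — outcomes are independent draws at an unknown base rate
  θ (probability of the focal symbol).  The observer starts from a point,
  discrete, or Beta prior over θ, conditions on the ordered sequence
  (likelihood θ^{n_a}(1-θ)^{n_b}), and reports the posterior-predictive
  probability of the terminal symbol.  With any nondegenerate prior this
  produces a *hot-hand* pattern: longer streaks push the posterior toward
  the streak symbol's rate, so repetition probability rises.

* **finite urn (sampling without replacement)** — the Law-of-Small-Numbers
  observer imagines the generator as an urn of N signals containing exactly
  θN focal signals.  Draws deplete the urn, so with a *known* rate the
  probability a streak repeats falls as the streak grows (*gambler's
  fallacy*).  Under rate uncertainty the observer also updates beliefs over
  urn compositions (ordered-draw likelihood: a ratio of falling factorials),
  and as streaks lengthen the updating term overtakes depletion — the
  prediction curve falls, then rises.

All probability arithmetic on sequences of at most nine outcomes is exact
(`fractions.Fraction`); public predict functions return exact rationals,
which float-convert transparently downstream.
"""

from __future__ import annotations

import dataclasses
from fractions import Fraction
from typing import Mapping

from .stimuli import FOCAL_SYMBOL, StimulusSet, coerce_outcomes

__all__ = [
    "PriorSpec",
    "UrnSpec",
    "ObserverSpec",
    "PredictionCurve",
    "CurvePoint",
    "ObserverError",
    "DegeneratePosteriorError",
    "ZeroProbabilityHistoryError",
    "iid_posterior",
    "predict_repeat_iid",
    "urn_predict_known",
    "urn_posterior_predict",
    "UrnPrediction",
    "model_curve",
]


class ObserverError(ValueError):
    """Invalid observer specification or input."""


class DegeneratePosteriorError(ObserverError):
    """Every prior atom assigns zero likelihood to the observed sequence."""


class ZeroProbabilityHistoryError(ObserverError):
    """The observed history is impossible under the stated urn composition."""


def as_rational(x) -> Fraction:
    """Exact rational from int/Fraction, or decimal-faithful from float/str.

    Floats go through their shortest decimal repr so 0.6 means 3/5, not the
    nearest binary double.
    """
    if isinstance(x, Fraction):
        return x
    if isinstance(x, int):
        return Fraction(x)
    return Fraction(str(x))


@dataclasses.dataclass(frozen=True)
class PriorSpec:
    """Prior belief over the focal-symbol base rate θ.

    kind='point'     : all mass at theta.
    kind='discrete'  : finite support with probabilities summing to 1
                       (the distributional-rate studies use {.25,.50,.75},
                       each 1/3).
    kind='conjugate' : Beta(alpha, beta) over θ.
    """

    kind: str
    theta: Fraction | None = None
    support: tuple[Fraction, ...] | None = None
    probs: tuple[Fraction, ...] | None = None
    alpha: Fraction | None = None
    beta: Fraction | None = None

    def __post_init__(self):
        if self.kind == "point":
            object.__setattr__(self, "theta", as_rational(self.theta))
            if not 0 < self.theta < 1:
                raise ObserverError("point prior needs theta strictly in (0,1)")
        elif self.kind == "discrete":
            support = tuple(as_rational(t) for t in self.support)
            if self.probs is None:
                probs = (Fraction(1, len(support)),) * len(support)
            else:
                probs = tuple(as_rational(p) for p in self.probs)
            if len(probs) != len(support):
                raise ObserverError("support and probs must have equal length")
            if any(not 0 < t < 1 for t in support):
                raise ObserverError("all support rates must be strictly in (0,1)")
            if any(p < 0 for p in probs) or sum(probs) != 1:
                raise ObserverError("discrete prior probabilities must be >=0 and sum to 1")
            object.__setattr__(self, "support", support)
            object.__setattr__(self, "probs", probs)
        elif self.kind == "conjugate":
            object.__setattr__(self, "alpha", as_rational(self.alpha))
            object.__setattr__(self, "beta", as_rational(self.beta))
            if self.alpha <= 0 or self.beta <= 0:
                raise ObserverError("Beta shape parameters must be positive")
        else:
            raise ObserverError(f"unknown prior kind {self.kind!r}")

    # -- constructors ------------------------------------------------------
    @classmethod
    def point(cls, theta) -> "PriorSpec":
        return cls(kind="point", theta=theta)

    @classmethod
    def discrete(cls, support, probs=None) -> "PriorSpec":
        return cls(kind="discrete", support=tuple(support), probs=None if probs is None else tuple(probs))

    @classmethod
    def conjugate(cls, alpha, beta) -> "PriorSpec":
        return cls(kind="conjugate", alpha=alpha, beta=beta)

    @classmethod
    def three_rate(cls) -> "PriorSpec":
        """The distributional-rate studies' prior: {1/4, 1/2, 3/4}, each 1/3."""
        return cls.discrete((Fraction(1, 4), Fraction(1, 2), Fraction(3, 4)))


def _counts(seq, focal: str) -> tuple[int, int, str]:
    out = coerce_outcomes(seq)
    if not out:
        raise ObserverError("sequence must be non-empty")
    n_focal = sum(1 for s in out if s == focal)
    return n_focal, len(out) - n_focal, out[-1]


def iid_posterior(prior: PriorSpec, seq, focal: str = FOCAL_SYMBOL) -> PriorSpec:
    """Posterior over θ after observing the ordered sequence, i.i.d. model.

    The likelihood of a sequence with ``n_a`` focal and ``n_b`` non-focal
    outcomes is θ^{n_a}(1-θ)^{n_b}.  Point priors return themselves; Beta
    priors update (α, β) → (α + n_a, β + n_b); discrete priors reweight and
    renormalise exactly.
    """
    n_a, n_b, _ = _counts(seq, focal)
    if prior.kind == "point":
        return prior
    if prior.kind == "conjugate":
        return PriorSpec.conjugate(prior.alpha + n_a, prior.beta + n_b)
    weights = [p * t**n_a * (1 - t) ** n_b for t, p in zip(prior.support, prior.probs)]
    total = sum(weights)
    if total == 0:
        raise DegeneratePosteriorError("sequence has zero likelihood under every prior atom")
    return PriorSpec.discrete(prior.support, tuple(w / total for w in weights))


def predict_repeat_iid(prior: PriorSpec, seq, focal: str = FOCAL_SYMBOL) -> Fraction:
    """Posterior-predictive probability that the terminal symbol repeats.

    With terminal symbol t, this is E[rate_t(θ) | sequence] where rate_t(θ)
    is θ for the focal symbol and 1-θ otherwise; the Beta case reduces to
    the Laplace form (n_t + α_t) / (n + α + β).
    """
    n_a, n_b, terminal = _counts(seq, focal)
    post = iid_posterior(prior, seq, focal)
    if post.kind == "point":
        t = post.theta
        return t if terminal == focal else 1 - t
    if post.kind == "conjugate":
        num = post.alpha if terminal == focal else post.beta
        return num / (post.alpha + post.beta)
    rate = (lambda t: t) if terminal == focal else (lambda t: 1 - t)
    return sum(p * rate(t) for t, p in zip(post.support, post.probs))


@dataclasses.dataclass(frozen=True)
class UrnSpec:
    """A finite-urn observer's mental model: N signals, θN of them focal.

    ``renewal='per-sequence'`` (the only policy implemented) means one urn
    spans the eight observed outcomes plus the predicted ninth draw, never
    refreshed mid-sequence; hence N >= 9.
    """

    N: int
    prior: PriorSpec
    renewal: str = "per-sequence"

    def __post_init__(self):
        if self.renewal != "per-sequence":
            raise ObserverError(f"unsupported renewal policy {self.renewal!r}")
        if int(self.N) != self.N or self.N < 9:
            raise ObserverError("urn size N must be an integer >= 9 under per-sequence renewal")
        object.__setattr__(self, "N", int(self.N))
        if self.prior.kind not in ("point", "discrete"):
            raise ObserverError("urn priors must be point or discrete (finite compositions)")
        for t in self._support():
            if (t * self.N).denominator != 1:
                raise ObserverError(f"θN must be an integer: θ={t} with N={self.N}")

    def _support(self) -> tuple[Fraction, ...]:
        return (self.prior.theta,) if self.prior.kind == "point" else self.prior.support


def _falling(x: int, k: int) -> int:
    out = 1
    for i in range(k):
        out *= x - i
        if out == 0:
            return 0
    return out


def urn_predict_known(theta, N: int, seq, focal: str = FOCAL_SYMBOL) -> Fraction:
    """Repeat probability for an urn with a *known* composition.

    With θ_t N signals of the terminal type in the urn, of which k_t have
    been drawn among n total, the next draw repeats with probability
    (θ_t N - k_t) / (N - n): strictly decreasing in the drawn streak — the
    depletion signature of gambler's-fallacy reasoning.
    """
    theta = as_rational(theta)
    N = int(N)
    if (theta * N).denominator != 1:
        raise ObserverError(f"θN must be an integer: θ={theta}, N={N}")
    if len(coerce_outcomes(seq)) == 0:
        return theta  # undepleted urn: first draw of the focal type
    n_a, n_b, terminal = _counts(seq, focal)
    n = n_a + n_b
    if n >= N:
        raise ObserverError(f"history of {n} draws exhausts an urn of {N}")
    m_a, m_b = int(theta * N), N - int(theta * N)
    if n_a > m_a or n_b > m_b:
        raise ZeroProbabilityHistoryError(
            f"history with {n_a} focal / {n_b} non-focal draws is impossible "
            f"from an urn holding {m_a}/{m_b}"
        )
    m_t, k_t = (m_a, n_a) if terminal == focal else (m_b, n_b)
    return Fraction(m_t - k_t, N - n)


@dataclasses.dataclass(frozen=True)
class UrnPrediction:
    posterior: PriorSpec  # discrete over the surviving compositions
    p_repeat: Fraction


def urn_posterior_predict(urn: UrnSpec, seq, focal: str = FOCAL_SYMBOL) -> UrnPrediction:
    """Belief updating over urn compositions, then depletion-aware prediction.

    The ordered-draw likelihood of a history with counts (n_a, n_b) under
    composition θ is (θN)_{n_a} (1-θ)N)_{n_b} / (N)_n with falling
    factorials (x)_k.  Compositions that cannot supply the history get zero
    weight and are dropped; the prediction mixes the known-composition
    depletion formula over the posterior.
    """
    n_a, n_b, terminal = _counts(seq, focal)
    n = n_a + n_b
    if n >= urn.N:
        raise ObserverError(f"history of {n} draws exhausts an urn of {urn.N}")
    support = urn._support()
    probs = (Fraction(1),) if urn.prior.kind == "point" else urn.prior.probs

    denom = _falling(urn.N, n)
    weights: list[Fraction] = []
    for t, p in zip(support, probs):
        m_a = int(t * urn.N)
        lik = Fraction(_falling(m_a, n_a) * _falling(urn.N - m_a, n_b), denom)
        weights.append(p * lik)
    total = sum(weights)
    if total == 0:
        raise DegeneratePosteriorError("history impossible under every urn composition")

    kept = [(t, w / total) for t, w in zip(support, weights) if w > 0]
    post = PriorSpec.discrete(tuple(t for t, _ in kept), tuple(w for _, w in kept))
    p_repeat = Fraction(0)
    for t, w in kept:
        m_a = int(t * urn.N)
        m_t, k_t = (m_a, n_a) if terminal == focal else (urn.N - m_a, n_b)
        p_repeat += w * Fraction(m_t - k_t, urn.N - n)
    return UrnPrediction(posterior=post, p_repeat=p_repeat)


@dataclasses.dataclass(frozen=True)
class ObserverSpec:
    """An observer model: i.i.d. Bayes over θ, or a finite urn.

    ``predict`` maps any observed sequence to the probability its terminal
    streak repeats on the next outcome.
    """

    family: str  # 'iid_bayes' | 'urn'
    prior: PriorSpec | None = None
    urn: UrnSpec | None = None
    focal_symbol: str = FOCAL_SYMBOL

    def __post_init__(self):
        if self.family == "iid_bayes":
            if self.prior is None or self.urn is not None:
                raise ObserverError("iid_bayes observers take a prior and no urn")
        elif self.family == "urn":
            if self.urn is None:
                raise ObserverError("urn observers need an UrnSpec")
        else:
            raise ObserverError(f"unknown observer family {self.family!r}")

    @classmethod
    def iid(cls, prior: PriorSpec) -> "ObserverSpec":
        return cls(family="iid_bayes", prior=prior)

    @classmethod
    def from_urn(cls, urn: UrnSpec) -> "ObserverSpec":
        return cls(family="urn", urn=urn)

    def predict(self, seq) -> float:
        return float(self.predict_exact(seq))

    def predict_exact(self, seq) -> Fraction:
        if self.family == "iid_bayes":
            return predict_repeat_iid(self.prior, seq, self.focal_symbol)
        if self.urn.prior.kind == "point":
            return urn_predict_known(self.urn.prior.theta, self.urn.N, seq, self.focal_symbol)
        return urn_posterior_predict(self.urn, seq, self.focal_symbol).p_repeat

    def describe(self) -> str:
        if self.family == "iid_bayes":
            return f"iid_bayes({self.prior.kind})"
        return f"urn(N={self.urn.N}, {self.urn.prior.kind})"


@dataclasses.dataclass(frozen=True)
class CurvePoint:
    streak_length: int
    p_repeat: float
    n_sequences: int
    filler_flag: bool


@dataclasses.dataclass(frozen=True)
class PredictionCurve:
    """Mean repeat probability per terminal streak length for one observer.

    Streak-1 entries come from filler trials and are flagged: figures include
    them, inferential summaries exclude them.
    """

    points: tuple[CurvePoint, ...]
    provenance: str = ""

    def as_dict(self) -> Mapping[int, float]:
        return {pt.streak_length: pt.p_repeat for pt in self.points}

    def target_values(self) -> tuple[float, ...]:
        return tuple(pt.p_repeat for pt in self.points if not pt.filler_flag)


def model_curve(observer: ObserverSpec, stimset: StimulusSet) -> PredictionCurve:
    """Average observer predictions by terminal streak length over a session."""
    by_L: dict[int, list[Fraction]] = {}
    for seq in stimset.sequences:
        by_L.setdefault(seq.terminal_streak, []).append(observer.predict_exact(seq))
    points = tuple(
        CurvePoint(
            streak_length=L,
            p_repeat=float(sum(vals) / len(vals)),
            n_sequences=len(vals),
            filler_flag=(L == 1),
        )
        for L, vals in sorted(by_L.items())
    )
    return PredictionCurve(points=points, provenance=f"{observer.describe()} on {stimset.session_id}")
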