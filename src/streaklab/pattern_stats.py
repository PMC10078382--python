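"""Exact waiting-time and occurrence statistics for binary patterns.

Under i.i.d. coin tosses every pattern of length m has the same probability
in any single window, yet patterns differ sharply in how long one waits to
first encounter them: self-overlapping patterns such as HHHH wait longer on
average (30 fair tosses) than non-overlapping ones such as HHTT (16).  This
is the statistical backdrop of ecological accounts of reversal expectations:
in finite samples, streak patterns really are the last to show up.

Waiting times are computed by solving the absorbing Markov chain on the
pattern's prefix automaton (exact rational arithmetic via sympy); for a fair
coin the Conway leading-number closed form — the sum of 2^k over self-overlap
lengths k — is available as an independent cross-check.  Occurrence
probabilities within a finite horizon come from powering the same automaton.
"""

from __future__ import annotations

import dataclasses
from fractions import Fraction

__all__ = [
    "PatternQuery",
    "PatternError",
    "expected_wait",
    "occurrence_probability",
    "conway_leading_number",
]

_ALPHABET = ("H", "T")


class PatternError(ValueError):
    """Invalid pattern or query."""


def _check_pattern(pattern: str) -> str:
    pattern = pattern.upper()
    if not pattern or set(pattern) - set(_ALPHABET):
        raise PatternError(f"pattern must be a non-empty string over {{H,T}}, got {pattern!r}")
    return pattern


def _check_p(p_heads) -> Fraction:
    p = p_heads if isinstance(p_heads, Fraction) else Fraction(str(p_heads))
    if not 0 < p < 1:
        raise PatternError("p_heads must lie strictly in (0,1)")
    return p


@dataclasses.dataclass(frozen=True)
class PatternQuery:
    """A pattern of length 1-8, a heads rate, and an optional horizon."""

    pattern: str
    p_heads: Fraction = Fraction(1, 2)
    horizon: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "pattern", _check_pattern(self.pattern))
        object.__setattr__(self, "p_heads", _check_p(self.p_heads))
        if len(self.pattern) > 8:
            raise PatternError("queries cover patterns of length 1-8")
        if self.horizon is not None and self.horizon < len(self.pattern):
            raise PatternError("horizon must be at least the pattern length")

    def expected_wait(self) -> Fraction:
        return expected_wait(self.pattern, self.p_heads)

    def occurrence_probability(self) -> Fraction:
        if self.horizon is None:
            raise PatternError("occurrence probability needs a horizon")
        return occurrence_probability(self.pattern, self.horizon, self.p_heads)


def prefix_automaton(pattern: str) -> list[dict[str, int]]:
    """KMP prefix automaton: state = length of the longest matched prefix.

    Returns one transition table per state 0..m-1; reaching state m means the
    pattern has occurred.
    """
    pattern = _check_pattern(pattern)
    m = len(pattern)
    trans: list[dict[str, int]] = []
    for state in range(m):
        row = {}
        for sym in _ALPHABET:
            cand = pattern[:state] + sym
            k = min(len(cand), m)
            while k > 0 and cand[-k:] != pattern[:k]:
                k -= 1
            row[sym] = k
        trans.append(row)
    return trans


def expected_wait(pattern: str, p_heads=Fraction(1, 2)) -> Fraction:
    """Expected tosses until the pattern first occurs (overlaps allowed).

    Solves E_s = 1 + p·E_{δ(s,H)} + (1-p)·E_{δ(s,T)} over the non-absorbing
    automaton states, exactly.
    """
    from sympy import Matrix, Rational

    pattern = _check_pattern(pattern)
    p = _check_p(p_heads)
    trans = prefix_automaton(pattern)
    m = len(pattern)
    step = {"H": Rational(p.numerator, p.denominator)}
    step["T"] = 1 - step["H"]

    A = Matrix.eye(m)
    b = Matrix.ones(m, 1)
    for s, row in enumerate(trans):
        for sym, nxt in row.items():
            if nxt < m:
                A[s, nxt] -= step[sym]
    sol = A.LUsolve(b)
    r = Rational(sol[0])
    return Fraction(int(r.p), int(r.q))


def conway_leading_number(pattern: str) -> int:
    """Fair-coin waiting time via self-overlaps: sum of 2^k over lengths k
    where the pattern's length-k prefix equals its length-k suffix."""
    pattern = _check_pattern(pattern)
    return sum(
        2**k for k in range(1, len(pattern) + 1) if pattern[:k] == pattern[-k:]
    )


def occurrence_probability(pattern: str, horizon: int, p_heads=Fraction(1, 2)) -> Fraction:
    """Probability the pattern appears at least once within ``horizon`` tosses.

    Exact dynamic programming over automaton states with a sticky absorbing
    state; monotone nondecreasing in the horizon.
    """
    pattern = _check_pattern(pattern)
    p = _check_p(p_heads)
    if horizon < len(pattern):
        raise PatternError("horizon must be at least the pattern length")
    trans = prefix_automaton(pattern)
    m = len(pattern)
    step = {"H": p, "T": 1 - p}

    dist = [Fraction(0)] * (m + 1)
    dist[0] = Fraction(1)
    for _ in range(horizon):
        nxt = [Fraction(0)] * (m + 1)
        nxt[m] = dist[m]
        for s in range(m):
            if dist[s] == 0:
                continue
            for sym, prob in step.items():
                nxt[trans[s][sym]] += dist[s] * prob
        dist = nxt
    return dist[m]
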