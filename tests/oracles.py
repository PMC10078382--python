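"""Independent oracles used by the test suite.

Each function recomputes a quantity by a route deliberately different from
the library implementation: exhaustive enumeration of urn draws, direct
evaluation of posterior sums, brute-force string enumeration, Monte Carlo
simulation, and grid maximization of penalized likelihoods.
"""

from fractions import Fraction
from itertools import product

import numpy as np


def urn_history_probability(m_a: int, m_b: int, history) -> Fraction:
    """P(exactly this ordered history) drawn without replacement, by stepping
    the urn state symbol by symbol."""
    p = Fraction(1)
    for sym in history:
        total = m_a + m_b
        if sym == "a":
            if m_a == 0:
                return Fraction(0)
            p *= Fraction(m_a, total)
            m_a -= 1
        else:
            if m_b == 0:
                return Fraction(0)
            p *= Fraction(m_b, total)
            m_b -= 1
    return p


def urn_repeat_probability_enumerated(N: int, support_counts, prior_probs, history) -> Fraction:
    """P(next draw repeats the terminal symbol | history) by enumerating all
    ordered draw outcomes of length len(history)+1 under the composition prior.

    ``support_counts`` lists the number of 'a' signals per composition.
    """
    history = tuple(history)
    n = len(history)
    terminal = history[-1]
    p_hist = Fraction(0)
    p_hist_and_repeat = Fraction(0)
    for m_a, w in zip(support_counts, prior_probs):
        m_b = N - m_a
        # sanity: enumerate the full outcome tree and check it sums to 1
        total = sum(
            urn_history_probability(m_a, m_b, seq) for seq in product("ab", repeat=n + 1)
        )
        assert total == 1
        p_hist += w * urn_history_probability(m_a, m_b, history)
        p_hist_and_repeat += w * urn_history_probability(m_a, m_b, history + (terminal,))
    return p_hist_and_repeat / p_hist


def iid_repeat_probability_direct(support, probs, seq, focal="a") -> Fraction:
    """Posterior-predictive repeat probability by one direct rational sum."""
    seq = tuple(seq)
    terminal = seq[-1]
    num = Fraction(0)
    den = Fraction(0)
    for theta, p in zip(support, probs):
        theta = Fraction(theta)
        lik = p
        for sym in seq:
            lik *= theta if sym == focal else (1 - theta)
        rate = theta if terminal == focal else 1 - theta
        num += lik * rate
        den += lik
    return num / den


def occurrence_probability_enumerated(pattern: str, horizon: int) -> Fraction:
    """Fair-coin occurrence probability by enumerating all 2^horizon strings."""
    pat = pattern.upper().replace("H", "1").replace("T", "0")
    hits = sum(1 for i in range(2**horizon) if pat in format(i, f"0{horizon}b"))
    return Fraction(hits, 2**horizon)


def simulate_waiting_times(pattern: str, n_runs: int, seed: int, max_len: int = 400) -> np.ndarray:
    """Monte Carlo first-occurrence times of a pattern in fair-coin tosses.

    Vectorised: steps all runs through the pattern's prefix states at once.
    Runs that never hit the pattern within ``max_len`` raise (make it long
    enough for the pattern under test).
    """
    from streaklab.pattern_stats import prefix_automaton

    trans = prefix_automaton(pattern)
    m = len(pattern)
    # transition lookup tables: state x symbol -> state (m = absorbing, sticky)
    table = np.zeros((m + 1, 2), dtype=np.int64)
    for s, row in enumerate(trans):
        table[s, 1] = row["H"]
        table[s, 0] = row["T"]
    table[m, :] = m

    rng = np.random.default_rng(seed)
    states = np.zeros(n_runs, dtype=np.int64)
    waits = np.zeros(n_runs, dtype=np.int64)
    for step in range(1, max_len + 1):
        tosses = rng.integers(0, 2, size=n_runs)
        states = table[states, tosses]
        newly = (states == m) & (waits == 0)
        waits[newly] = step
        if (waits > 0).all():
            break
    assert (waits > 0).all(), "increase max_len"
    return waits


def firth_penalized_loglik(beta0: float, beta1: float, y, x) -> float:
    """Jeffreys-penalized logistic log-likelihood (the quantity Firth's
    method maximizes)."""
    X = np.column_stack([np.ones(len(x)), np.asarray(x, dtype=float)])
    eta = X @ np.array([beta0, beta1])
    p = 1.0 / (1.0 + np.exp(-eta))
    ll = float(np.sum(np.asarray(y) * eta - np.log1p(np.exp(eta))))
    w = p * (1 - p)
    info = (X.T * w) @ X
    sign, logdet = np.linalg.slogdet(info)
    return ll + 0.5 * logdet if sign > 0 else -np.inf


def firth_grid_argmax(y, x, b0_range=(-12, 12), b1_range=(-8, 8), coarse=121, refine=81):
    """Two-stage grid maximization of the penalized likelihood."""
    best = (-np.inf, 0.0, 0.0)
    b0s = np.linspace(*b0_range, coarse)
    b1s = np.linspace(*b1_range, coarse)
    for b0 in b0s:
        for b1 in b1s:
            ll = firth_penalized_loglik(b0, b1, y, x)
            if ll > best[0]:
                best = (ll, b0, b1)
    _, c0, c1 = best
    b0s = np.linspace(c0 - 0.3, c0 + 0.3, refine)
    b1s = np.linspace(c1 - 0.3, c1 + 0.3, refine)
    for b0 in b0s:
        for b1 in b1s:
            ll = firth_penalized_loglik(b0, b1, y, x)
            if ll > best[0]:
                best = (ll, b0, b1)
    return best[1], best[2]
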