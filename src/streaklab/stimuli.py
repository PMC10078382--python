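"""Balanced stimulus sets of eight-outcome binary sequences.

One experimental session shows a participant 18 sequences of eight binary
outcomes and asks for a prediction of the ninth.  Six *target* sequences end
in a terminal streak of 2-7 identical outcomes (one of each length); twelve
*filler* sequences end in a reversal (terminal streak of length 1).  Fillers
exist to balance the session: across all 144 outcomes the two symbols appear
equally often, and the internal run-length profile of the fillers is pushed,
by bounded random search, toward that of the targets so streaks are not
diagnostic of trial role.

Outcomes are stored abstractly as ``a`` / ``b``; condition labels
(Red/Blue, Up/Down) are a presentation-layer mapping.  ``a`` is the focal
symbol throughout the package.
"""

from __future__ import annotations

import dataclasses
import json
from collections import Counter
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

SYMBOLS = ("a", "b")
FOCAL_SYMBOL = "a"

__all__ = [
    "SYMBOLS",
    "FOCAL_SYMBOL",
    "Sequence",
    "SequenceStats",
    "StimulusSet",
    "DesignConfig",
    "ValidationReport",
    "StimulusError",
    "SolverFailure",
    "sequence_stats",
    "make_target_sequence",
    "build_stimulus_set",
    "validate_stimulus_set",
]


class StimulusError(ValueError):
    """Invalid sequence or design input."""


class SolverFailure(RuntimeError):
    """The balance search exhausted its attempt budget.

    ``rule`` names the constraint that could not be satisfied.
    """

    def __init__(self, rule: str, message: str):
        super().__init__(f"{rule}: {message}")
        self.rule = rule


def coerce_outcomes(outcomes) -> tuple[str, ...]:
    """Normalise a sequence of outcomes to a tuple over {'a','b'}.

    Accepts a :class:`Sequence`, an iterable of symbols, or a string such as
    ``"abbabbaa"`` / ``"ABBABBAA"`` (whitespace ignored).
    """
    if isinstance(outcomes, Sequence):
        return outcomes.outcomes
    if isinstance(outcomes, str):
        outcomes = outcomes.replace(" ", "")
    out = tuple(str(o).lower() for o in outcomes)
    bad = sorted(set(out) - set(SYMBOLS))
    if bad:
        raise StimulusError(f"unknown outcome symbols {bad}; expected one of {SYMBOLS}")
    return out


def _terminal_streak(out: tuple[str, ...]) -> int:
    last = out[-1]
    run = 0
    for sym in reversed(out):
        if sym != last:
            break
        run += 1
    return run


def _streak_census(out: tuple[str, ...]) -> dict[int, int]:
    census: Counter[int] = Counter()
    run = 1
    for prev, cur in zip(out, out[1:]):
        if cur == prev:
            run += 1
        else:
            census[run] += 1
            run = 1
    census[run] += 1
    return dict(sorted(census.items()))


@dataclasses.dataclass(frozen=True)
class SequenceStats:
    terminal_streak: int
    alternation_rate: float
    streak_census: Mapping[int, int]


@dataclasses.dataclass(frozen=True)
class Sequence:
    """An ordered run of eight binary outcomes with a trial role.

    The terminal streak is always recomputed from the outcomes, never stored,
    so it cannot drift out of sync.  Role constraints are enforced at
    construction: targets end in a streak of 2-7, fillers in a reversal.
    """

    outcomes: tuple[str, ...]
    role: str = "filler"
    condition_tag: str = ""

    def __post_init__(self):
        object.__setattr__(self, "outcomes", coerce_outcomes(self.outcomes))
        if len(self.outcomes) != 8:
            raise StimulusError(f"a stimulus sequence has exactly 8 outcomes, got {len(self.outcomes)}")
        if self.role not in ("target", "filler"):
            raise StimulusError(f"role must be 'target' or 'filler', got {self.role!r}")
        streak = self.terminal_streak
        if self.role == "target" and not 2 <= streak <= 7:
            raise StimulusError(f"target sequences end in a streak of 2-7, got {streak}")
        if self.role == "filler" and streak != 1:
            raise StimulusError(f"filler sequences end in a reversal, got terminal streak {streak}")

    @property
    def terminal_streak(self) -> int:
        return _terminal_streak(self.outcomes)

    @property
    def terminal_symbol(self) -> str:
        return self.outcomes[-1]

    def as_string(self) -> str:
        """Upper-case 8-character serialisation, e.g. ``'ABBABBAA'``."""
        return "".join(self.outcomes).upper()


def sequence_stats(seq) -> SequenceStats:
    """Terminal streak, alternation rate and run-length census of a sequence.

    The alternation rate is the fraction of adjacent outcome pairs that
    differ; the census maps maximal run length to the number of such runs
    (run lengths weighted by counts always sum to the sequence length).
    """
    out = coerce_outcomes(seq)
    if len(out) < 2:
        raise StimulusError("sequence_stats needs at least 2 outcomes")
    changes = sum(1 for x, y in zip(out, out[1:]) if x != y)
    return SequenceStats(
        terminal_streak=_terminal_streak(out),
        alternation_rate=changes / (len(out) - 1),
        streak_census=_streak_census(out),
    )


def make_target_sequence(
    L: int,
    final_symbol: str,
    rng: np.random.Generator,
    prefix_policy: str = "uniform",
    condition_tag: str = "",
) -> Sequence:
    """Build a target sequence whose last ``L`` outcomes equal ``final_symbol``.

    The outcome just before the terminal streak is forced to the other symbol
    so the streak length is exactly ``L``; earlier positions are drawn under
    ``prefix_policy`` ("uniform" draws each free symbol independently at .5).
    """
    if not 2 <= int(L) <= 7:
        raise StimulusError(f"target streak length must be in 2..7, got {L}")
    final_symbol = coerce_outcomes([final_symbol])[0]
    other = "b" if final_symbol == "a" else "a"
    if prefix_policy != "uniform":
        raise StimulusError(f"unknown prefix_policy {prefix_policy!r}")
    free = 8 - int(L) - 1
    prefix = [SYMBOLS[i] for i in rng.integers(0, 2, size=free)]
    outcomes = tuple(prefix) + (other,) + (final_symbol,) * int(L)
    return Sequence(outcomes, role="target", condition_tag=condition_tag)


def _make_filler(rng: np.random.Generator) -> list[str]:
    body = [SYMBOLS[i] for i in rng.integers(0, 2, size=6)]
    if rng.integers(0, 2):
        return body + ["a", "b"]
    return body + ["b", "a"]


def _census_distance(fillers: list[list[str]], targets: list[Sequence]) -> float:
    """L1 distance between normalised run-length profiles of fillers vs targets."""

    def profile(seqs: Iterable[tuple[str, ...]]) -> dict[int, float]:
        census: Counter[int] = Counter()
        for s in seqs:
            census.update(_streak_census(tuple(s)))
        total = sum(census.values())
        return {k: v / total for k, v in census.items()}

    pf = profile(tuple(f) for f in fillers)
    pt = profile(t.outcomes for t in targets)
    keys = set(pf) | set(pt)
    return sum(abs(pf.get(k, 0.0) - pt.get(k, 0.0)) for k in keys)


@dataclasses.dataclass(frozen=True)
class DesignConfig:
    """Session design parameters.

    ``max_attempts`` bounds the random search over filler drafts; each draft
    is repaired to exact symbol balance and scored by how closely the filler
    run-length profile matches the targets'.
    """

    n_targets: int = 6
    n_fillers: int = 12
    streak_lengths: tuple[int, ...] = (2, 3, 4, 5, 6, 7)
    symbol_balance: bool = True
    max_attempts: int = 64

    def __post_init__(self):
        if len(self.streak_lengths) != self.n_targets:
            raise StimulusError("one streak length per target is required")


@dataclasses.dataclass(frozen=True)
class StimulusSet:
    """One session's 18 sequences plus provenance and a balance report."""

    sequences: tuple[Sequence, ...]
    seed: int
    config: DesignConfig = DesignConfig()
    balance_report: Mapping[str, object] = dataclasses.field(default_factory=dict)

    @property
    def session_id(self) -> str:
        return f"session-{self.seed}"

    @property
    def targets(self) -> tuple[Sequence, ...]:
        return tuple(s for s in self.sequences if s.role == "target")

    @property
    def fillers(self) -> tuple[Sequence, ...]:
        return tuple(s for s in self.sequences if s.role == "filler")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "session_id": self.session_id,
                "trial_index": np.arange(1, len(self.sequences) + 1),
                "role": [s.role for s in self.sequences],
                "terminal_streak": [s.terminal_streak for s in self.sequences],
                "outcomes": [s.as_string() for s in self.sequences],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self) -> str:
        payload = {
            "session_id": self.session_id,
            "seed": self.seed,
            "sequences": self.to_frame().to_dict(orient="records"),
            "balance_report": dict(self.balance_report),
        }
        return json.dumps(payload, indent=2)


def build_stimulus_set(seed: int, config: DesignConfig | None = None) -> StimulusSet:
    """Generate a balanced 18-trial session; a pure function of (seed, config).

    Targets get one terminal streak of each requested length, with final
    symbols split evenly between ``a`` and ``b``.  Fillers are drafted at
    random, repaired to make the session-wide symbol counts exactly equal,
    and the draft whose internal run-length profile best matches the targets
    is kept.  Trial order is a uniform shuffle.
    """
    config = config or DesignConfig()
    rng = np.random.default_rng(seed)

    # Final symbols: half a-final, half b-final, assigned to streak lengths at random.
    finals = ["a", "b"] * ((config.n_targets + 1) // 2)
    finals = [finals[i] for i in rng.permutation(config.n_targets)]
    targets = [
        make_target_sequence(L, fin, rng) for L, fin in zip(config.streak_lengths, finals)
    ]

    n_outcomes = 8 * (config.n_targets + config.n_fillers)
    want_a = n_outcomes // 2
    target_a = sum(s.outcomes.count("a") for s in targets)
    need_a = want_a - target_a  # focal symbols the fillers must supply

    best: list[list[str]] | None = None
    best_score = np.inf
    for _ in range(config.max_attempts):
        fillers = [_make_filler(rng) for _ in range(config.n_fillers)]
        if config.symbol_balance and not _repair_balance(fillers, need_a, rng):
            continue
        score = _census_distance(fillers, targets)
        if score < best_score:
            best, best_score = fillers, score
    if best is None:
        raise SolverFailure(
            "symbol balance",
            f"could not supply {need_a} focal symbols from {config.n_fillers} fillers "
            f"in {config.max_attempts} attempts",
        )

    sequences = targets + [Sequence(tuple(f), role="filler") for f in best]
    order = rng.permutation(len(sequences))
    ordered = tuple(sequences[i] for i in order)

    census: Counter[int] = Counter()
    for s in ordered:
        census.update(_streak_census(s.outcomes))
    report = {
        "count_a": sum(s.outcomes.count("a") for s in ordered),
        "count_b": sum(s.outcomes.count("b") for s in ordered),
        "streak_census": {int(k): int(v) for k, v in sorted(census.items())},
        "filler_target_census_distance": float(best_score),
    }
    return StimulusSet(ordered, seed=int(seed), config=config, balance_report=report)


def _repair_balance(fillers: list[list[str]], need_a: int, rng: np.random.Generator) -> bool:
    """Flip free filler positions (0..5) until they hold exactly ``need_a`` a's.

    The terminal reversal pair always contributes one ``a`` per filler, so only
    the 6 free positions are touched.  Returns False when infeasible.
    """
    have = sum(f.count("a") for f in fillers)
    delta = need_a - have
    if delta == 0:
        return True
    frm, to = ("b", "a") if delta > 0 else ("a", "b")
    slots = [(i, j) for i, f in enumerate(fillers) for j in range(6) if f[j] == frm]
    if len(slots) < abs(delta):
        return False
    for k in rng.permutation(len(slots))[: abs(delta)]:
        i, j = slots[k]
        fillers[i][j] = to
    return True


@dataclasses.dataclass(frozen=True)
class ValidationReport:
    passed: bool
    violations: tuple[str, ...]

    def __bool__(self) -> bool:
        return self.passed


def validate_stimulus_set(stimset: StimulusSet) -> ValidationReport:
    """Check every session invariant; reports violations, never raises."""
    violations: list[str] = []
    cfg = stimset.config
    seqs = stimset.sequences

    if len(seqs) != cfg.n_targets + cfg.n_fillers:
        violations.append("trial count")
    if any(len(s.outcomes) != 8 for s in seqs):
        violations.append("sequence length")

    target_streaks = sorted(s.terminal_streak for s in stimset.targets)
    if target_streaks != sorted(cfg.streak_lengths):
        violations.append("target streak multiset")
    if len(stimset.fillers) != cfg.n_fillers:
        violations.append("filler count")
    if any(s.terminal_streak != 1 for s in stimset.fillers):
        violations.append("filler terminal reversal")

    if cfg.symbol_balance:
        n_a = sum(s.outcomes.count("a") for s in seqs)
        n_b = sum(s.outcomes.count("b") for s in seqs)
        if n_a != n_b:
            violations.append("symbol balance")

    return ValidationReport(passed=not violations, violations=tuple(violations))


def canonical_streak_sequence(L: int, final_symbol: str = "b") -> tuple[str, ...]:
    """Reference 8-outcome sequence ending in a streak of exactly ``L``.

    The prefix alternates symbols (maximally balanced), ending opposite to the
    terminal symbol; used for model curves on a fixed, prefix-controlled family.
    """
    if not 1 <= int(L) <= 8:
        raise StimulusError(f"streak length must be in 1..8, got {L}")
    final_symbol = coerce_outcomes([final_symbol])[0]
    other = "b" if final_symbol == "a" else "a"
    prefix_len = 8 - int(L)
    prefix = []
    sym = other
    for _ in range(prefix_len):
        prefix.append(sym)
        sym = final_symbol if sym == other else other
    prefix.reverse()  # ends with `other`, alternating backwards
    return tuple(prefix) + (final_symbol,) * int(L)
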