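"""Synthetic participants for the six-study design.

The real experiments put human participants in one of three generator
conditions (Bingo / Analyst / Stock), one of three base-rate regimes
(unknown; fixed .50; uniform over {.25,.50,.75}), and one of two response
formats (0-100 probability rating, or a dichotomous repeat/reverse choice).
This module simulates trial-level response tables with that structure so the
whole analysis pipeline is testable without any download.

Each simulated participant carries a :class:`StrategyProfile`:

* ``updater``     — responds with an observer model's repeat probability
                    (belief updating; positive streak-length slope);
* ``reverser``    — mirror image, p ↦ 1-p (gambler's-fallacy-like negative
                    slope);
* ``constant``    — a fixed probability (e.g. sticking to the stated .50);
* ``alternation`` — expects reversal at a fixed alternation rate (default
                    .60, the rate observers typically consider "random"),
                    so repeat probability is 1 - .60 = .40 on every trial.

Continuous responses are 100·p plus Gaussian rating noise, clipped to
[0, 100]; dichotomous responses are Bernoulli with a logistic link
sigmoid(temperature · (p - .5)).  Everything is reproducible from
(config, seed).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from .observers import ObserverSpec, PriorSpec, UrnSpec
from .stimuli import StimulusSet, build_stimulus_set

__all__ = [
    "StrategyProfile",
    "ConditionSpec",
    "CohortConfig",
    "ConfigError",
    "simulate_participant",
    "simulate_study",
    "study_preset",
    "STUDY_PRESETS",
    "RESPONSE_COLUMNS",
]

RESPONSE_COLUMNS = (
    "participant_id",
    "study_tag",
    "condition",
    "format",
    "trial_index",
    "role",
    "terminal_streak",
    "sequence",
    "response",
)


class ConfigError(ValueError):
    """Invalid cohort or profile configuration."""


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


@dataclasses.dataclass(frozen=True)
class StrategyProfile:
    """One participant's latent response strategy.

    noise_sd is rating noise on the 0-100 scale; temperature is the slope of
    the logistic rating→choice link (larger = more deterministic choices).
    """

    kind: str  # 'updater' | 'reverser' | 'constant' | 'alternation'
    observer: ObserverSpec | None = None
    constant_p: float = 0.5
    alternation_rate: float = 0.6
    noise_sd: float = 10.0
    temperature: float = 8.0

    def __post_init__(self):
        if self.kind not in ("updater", "reverser", "constant", "alternation"):
            raise ConfigError(f"unknown strategy kind {self.kind!r}")
        if self.kind in ("updater", "reverser") and self.observer is None:
            raise ConfigError(f"{self.kind} profiles need an observer model")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.temperature <= 0:
            raise ConfigError("temperature must be > 0")

    def latent_p(self, seq) -> float:
        """Latent repeat probability for one sequence."""
        if self.kind == "updater":
            return self.observer.predict(seq)
        if self.kind == "reverser":
            return 1.0 - self.observer.predict(seq)
        if self.kind == "constant":
            return float(self.constant_p)
        return 1.0 - float(self.alternation_rate)


def simulate_participant(
    profile: StrategyProfile,
    stimset: StimulusSet,
    response_format: str,
    rng: np.random.Generator,
    participant_id: str = "p0",
    condition: str = "",
    study_tag: str = "",
) -> list[dict]:
    """Simulate one participant's 18 trial responses.

    Continuous: response = clip(100·p + N(0, noise_sd), 0, 100).
    Dichotomous: response ~ Bernoulli(sigmoid(temperature·(p - .5))).
    """
    if response_format not in ("continuous", "dichotomous"):
        raise ConfigError(f"unknown response format {response_format!r}")
    records = []
    for trial, seq in enumerate(stimset.sequences, start=1):
        p = profile.latent_p(seq)
        if response_format == "continuous":
            response = float(np.clip(100.0 * p + rng.normal(0.0, profile.noise_sd)
                                     if profile.noise_sd > 0 else 100.0 * p, 0.0, 100.0))
        else:
            response = int(rng.random() < _sigmoid(profile.temperature * (p - 0.5)))
        records.append(
            {
                "participant_id": participant_id,
                "study_tag": study_tag,
                "condition": condition,
                "format": response_format,
                "trial_index": trial,
                "role": seq.role,
                "terminal_streak": seq.terminal_streak,
                "sequence": seq.as_string(),
                "response": response,
            }
        )
    return records


# ---------------------------------------------------------------------------
# Cohort-level simulation


@dataclasses.dataclass(frozen=True)
class ConditionSpec:
    """One between-subjects cell: a generator label, its size and mixture.

    ``mixture`` maps strategy kind to weight (must sum to 1).  ``updater``
    and ``reverser`` participants share ``observer`` as the latent model
    (the reverser mirrors it).
    """

    name: str
    n: int
    observer: ObserverSpec
    mixture: Mapping[str, float]

    def __post_init__(self):
        total = sum(self.mixture.values())
        if abs(total - 1.0) > 1e-9 or any(w < 0 for w in self.mixture.values()):
            raise ConfigError(f"mixture weights must be >= 0 and sum to 1, got {dict(self.mixture)}")
        if self.n < 1:
            raise ConfigError("each condition needs at least one participant")


@dataclasses.dataclass(frozen=True)
class CohortConfig:
    study_tag: str
    response_format: str
    conditions: tuple[ConditionSpec, ...]
    noise_sd: float = 10.0
    temperature: float = 8.0
    stimulus_seed: int | None = None  # default: derived from the global seed


def simulate_study(config: CohortConfig, seed: int) -> pd.DataFrame:
    """Simulate a full study: one row per participant × trial.

    All participants in a study judge the same 18-trial stimulus session
    (as in the real design, where a single balanced set was deployed).
    Strategy assignment and response noise derive deterministically from
    ``seed`` via spawned child streams.
    """
    root = np.random.SeedSequence(seed)
    stim_ss, assign_ss = root.spawn(2)
    stim_seed = (
        config.stimulus_seed
        if config.stimulus_seed is not None
        else int(stim_ss.generate_state(1)[0] % 2**31)
    )
    stimset = build_stimulus_set(stim_seed)

    assign_rng = np.random.default_rng(assign_ss)
    rows: list[dict] = []
    pid = 0
    for cond in config.conditions:
        kinds = list(cond.mixture)
        weights = np.array([cond.mixture[k] for k in kinds], dtype=float)
        draws = assign_rng.choice(len(kinds), size=cond.n, p=weights / weights.sum())
        for i, k_idx in enumerate(draws):
            profile = StrategyProfile(
                kind=kinds[k_idx],
                observer=cond.observer if kinds[k_idx] in ("updater", "reverser") else None,
                noise_sd=config.noise_sd,
                temperature=config.temperature,
            )
            rng = np.random.default_rng([seed % 2**31, pid])
            rows.extend(
                simulate_participant(
                    profile,
                    stimset,
                    config.response_format,
                    rng,
                    participant_id=f"{config.study_tag}-{cond.name}-{i:04d}",
                    condition=cond.name,
                    study_tag=config.study_tag,
                )
            )
            pid += 1
    table = pd.DataFrame(rows, columns=list(RESPONSE_COLUMNS))
    table.attrs["config"] = {
        "study_tag": config.study_tag,
        "response_format": config.response_format,
        "seed": int(seed),
        "stimulus_seed": int(stim_seed),
        "noise_sd": config.noise_sd,
        "temperature": config.temperature,
        "conditions": {c.name: {"n": c.n, "mixture": dict(c.mixture)} for c in config.conditions},
    }
    return table


# ---------------------------------------------------------------------------
# Study presets
#
# Cohort sizes are the per-condition Ns of the six studies; reverser shares
# mimic each study's reported share of negative-slope / negative-percent-
# change participants.  These are qualitative presets for exercising the
# pipeline, not ground truth.


def _iid(prior: PriorSpec) -> ObserverSpec:
    return ObserverSpec.iid(prior)


_UNKNOWN = lambda: _iid(PriorSpec.conjugate(1, 1))  # flat prior over the rate
_FIXED50 = lambda: _iid(PriorSpec.conjugate(4, 4))  # anchored, conservative updating
_THREE = lambda: _iid(PriorSpec.three_rate())

_PRESET_TABLE: dict[str, dict] = {
    # tag: format, latent factory, {condition: (n, reverser_share)}
    "1A": ("continuous", _UNKNOWN, {"Stock": (44, 0.07), "Analyst": (50, 0.14), "Bingo": (50, 0.20)}),
    "1B": ("dichotomous", _UNKNOWN, {"Stock": (97, 0.10), "Analyst": (95, 0.08), "Bingo": (108, 0.16)}),
    "2A": ("continuous", _FIXED50, {"Stock": (48, 0.10), "Analyst": (52, 0.10), "Bingo": (56, 0.54)}),
    "2B": ("dichotomous", _FIXED50, {"Stock": (103, 0.13), "Analyst": (97, 0.14), "Bingo": (101, 0.26)}),
    "3A": ("continuous", _THREE, {"Stock": (50, 0.14), "Analyst": (50, 0.04), "Bingo": (50, 0.12)}),
    "3B": ("dichotomous", _THREE, {"Stock": (93, 0.16), "Analyst": (98, 0.18), "Bingo": (109, 0.28)}),
}

STUDY_PRESETS = tuple(_PRESET_TABLE)


def study_preset(tag: str) -> CohortConfig:
    """A ready-made cohort config named after one of the six studies."""
    if tag not in _PRESET_TABLE:
        raise ConfigError(f"unknown study preset {tag!r}; available: {STUDY_PRESETS}")
    response_format, latent, cells = _PRESET_TABLE[tag]
    conditions = tuple(
        ConditionSpec(
            name=name,
            n=n,
            observer=latent(),
            mixture={"updater": 1.0 - share, "reverser": share},
        )
        for name, (n, share) in cells.items()
    )
    return CohortConfig(study_tag=tag, response_format=response_format, conditions=conditions)
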