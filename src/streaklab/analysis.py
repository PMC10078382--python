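"""The per-participant strategy-analysis pipeline.

Stages mirror the study's reporting: aggregate streak-length curves with
standard errors; per-participant least-squares slopes (continuous ratings)
or logistic log-odds coefficients with their percent-change-in-odds
transform (dichotomous choices); classification of each participant as
repetition-increasing, reversal-increasing, or flat; dichotomization of
ratings for cross-format comparison; and Welch's unequal-variance t test
between groups.

Filler trials (terminal streak 1) are carried through curves but excluded
from all per-participant fits and tests.

With six binary responses, per-participant logistic fits frequently hit
perfect or quasi-separation; the log-odds coefficient is therefore estimated
by Firth's penalized likelihood (Jeffreys-prior score correction), with
|β| additionally capped at ±5 and a flag recorded, so the percent-change
transform stays finite and comparable across participants.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence as TSequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnalysisError",
    "StrategyFit",
    "GroupComparison",
    "DichotomizeResult",
    "FLAT_TOL",
    "BETA_CAP",
    "aggregate_curve",
    "fit_slope",
    "fit_logodds_pct",
    "fit_participants",
    "classify_strategies",
    "dichotomize",
    "compare_groups",
    "participant_repeat_rates",
]

FLAT_TOL = 1e-9  # |slope| or |beta| below this counts as a flat strategy
BETA_CAP = 5.0  # cap on the logistic coefficient magnitude
TARGET_STREAKS = (2, 3, 4, 5, 6, 7)


class AnalysisError(ValueError):
    """Invalid analysis input."""


@dataclasses.dataclass(frozen=True)
class StrategyFit:
    """One participant's strategy estimate.

    Continuous format: ``slope`` is the least-squares rating change per unit
    streak length.  Dichotomous: ``beta`` is the logistic log-odds change per
    unit streak length and ``pct_change`` = 100·(e^β − 1).  ``strategy`` is
    'positive', 'negative', or 'flat' from the sign of the estimate under
    :data:`FLAT_TOL`.
    """

    participant_id: str
    format: str
    condition: str = ""
    slope: float | None = None
    intercept: float | None = None
    beta: float | None = None
    pct_change: float | None = None
    fit_flags: tuple[str, ...] = ()
    strategy: str = "flat"


def _classify_value(value: float, tol: float = FLAT_TOL) -> str:
    if value > tol:
        return "positive"
    if value < -tol:
        return "negative"
    return "flat"


def _check_targets(streaks) -> np.ndarray:
    streaks = np.asarray(streaks, dtype=float)
    if sorted(streaks.tolist()) != list(map(float, TARGET_STREAKS)):
        raise AnalysisError(
            f"per-participant fits use exactly the six target trials with streaks {TARGET_STREAKS}"
        )
    return streaks


def fit_slope(responses, streaks=TARGET_STREAKS) -> tuple[float, float]:
    """Ordinary least squares of a participant's six target ratings on streak
    length; returns (slope, intercept)."""
    x = _check_targets(streaks)
    y = np.asarray(responses, dtype=float)
    if y.shape != x.shape:
        raise AnalysisError("one response per target trial is required")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def _firth_logistic(y: np.ndarray, x: np.ndarray, max_iter: int = 80, tol: float = 1e-10):
    """Firth-penalized logistic regression of y on [1, x].

    Newton iteration on the modified score U*(β) = Xᵀ(y − p + h·(½ − p)),
    where h are the leverages of the weighted design.  The Jeffreys penalty
    keeps the maximizer finite under complete separation.
    """
    X = np.column_stack([np.ones_like(x, dtype=float), np.asarray(x, dtype=float)])
    beta = np.zeros(2)
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        XtW = X.T * w
        info = XtW @ X
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            break
        h = np.einsum("ij,jk,ik->i", X, info_inv, X) * w
        score = X.T @ (y - p + h * (0.5 - p))
        step = info_inv @ score
        # dampen huge steps for stability
        norm = np.max(np.abs(step))
        if norm > 5.0:
            step *= 5.0 / norm
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def fit_logodds_pct(
    choices,
    streaks=TARGET_STREAKS,
    participant_id: str = "",
    condition: str = "",
) -> StrategyFit:
    """Per-participant logistic fit of repeat/reverse choices on streak length.

    Returns the (penalized) log-odds coefficient β, its percent-change
    transform 100·(e^β − 1), and separation/degeneracy flags.  β is capped
    at ±:data:`BETA_CAP`.
    """
    x = _check_targets(streaks)
    y = np.asarray(choices, dtype=float)
    if y.shape != x.shape:
        raise AnalysisError("one choice per target trial is required")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise AnalysisError("dichotomous responses must be 0/1")

    flags: list[str] = []
    if len(set(y)) == 1:
        flags.append("constant-responses")
    else:
        # perfect separation: responses are a step function of streak length
        ys = y[np.argsort(x)]
        k = int(ys.sum())
        if np.array_equal(ys, np.r_[np.zeros(6 - k), np.ones(k)]) or np.array_equal(
            ys, np.r_[np.ones(k), np.zeros(6 - k)]
        ):
            flags.append("separation")

    beta0, beta1 = _firth_logistic(y, x)
    if abs(beta1) > BETA_CAP:
        beta1 = float(np.sign(beta1) * BETA_CAP)
        flags.append("beta-capped")
    pct = 100.0 * (np.exp(beta1) - 1.0)
    return StrategyFit(
        participant_id=participant_id,
        format="dichotomous",
        condition=condition,
        beta=float(beta1),
        pct_change=float(pct),
        fit_flags=tuple(flags),
        strategy=_classify_value(pct),
    )


def fit_participants(table: pd.DataFrame) -> list[StrategyFit]:
    """Fit every participant in a response table (target trials only)."""
    _require_single_format(table)
    fmt = table["format"].iloc[0]
    fits: list[StrategyFit] = []
    targets = table[table["role"] == "target"]
    for pid, grp in targets.groupby("participant_id", sort=True):
        condition = grp["condition"].iloc[0]
        streaks = grp["terminal_streak"].to_numpy()
        responses = grp["response"].to_numpy()
        if fmt == "continuous":
            slope, intercept = fit_slope(responses, streaks)
            fits.append(
                StrategyFit(
                    participant_id=str(pid),
                    format=fmt,
                    condition=condition,
                    slope=slope,
                    intercept=intercept,
                    strategy=_classify_value(slope),
                )
            )
        else:
            fits.append(
                fit_logodds_pct(responses, streaks, participant_id=str(pid), condition=condition)
            )
    return fits


def fits_frame(fits: Iterable[StrategyFit]) -> pd.DataFrame:
    rows = [dataclasses.asdict(f) for f in fits]
    frame = pd.DataFrame(rows)
    frame["fit_flags"] = frame["fit_flags"].map(lambda t: ";".join(t))
    return frame


def classify_strategies(fits: Iterable[StrategyFit], tol: float = FLAT_TOL) -> pd.DataFrame:
    """Share of negative / positive / flat strategies per condition.

    Proportions sum to 1 within each condition.
    """
    rows = []
    for f in fits:
        value = f.slope if f.format == "continuous" else f.pct_change
        rows.append({"condition": f.condition, "strategy": _classify_value(value, tol)})
    frame = pd.DataFrame(rows)
    if frame.empty:
        raise AnalysisError("no fits to classify")
    out = (
        frame.groupby("condition")["strategy"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=["negative", "positive", "flat"], fill_value=0.0)
    )
    out["n"] = frame.groupby("condition").size()
    return out


def _require_single_format(table: pd.DataFrame) -> str:
    formats = table["format"].unique()
    if len(formats) != 1:
        raise AnalysisError(f"expected a single response format per call, got {list(formats)}")
    return formats[0]


def aggregate_curve(table: pd.DataFrame) -> pd.DataFrame:
    """Mean response (or proportion predicting repeat) by condition × streak.

    Returns columns condition, streak_length, mean, se, n, filler_flag; the
    standard error is the across-participant sample SD over √n.  Filler rows
    (streak 1) are included but flagged.  Empty cells simply do not appear.
    """
    _require_single_format(table)
    per_participant = (
        table.groupby(["condition", "terminal_streak", "participant_id"])["response"]
        .mean()
        .reset_index()
    )
    grouped = per_participant.groupby(["condition", "terminal_streak"])["response"]
    out = grouped.agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count").reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n"])
    out.loc[out["n"] == 1, "se"] = np.nan
    out["filler_flag"] = out["terminal_streak"] == 1
    out = out.rename(columns={"terminal_streak": "streak_length"})
    return out[["condition", "streak_length", "mean", "se", "n", "filler_flag"]]


@dataclasses.dataclass(frozen=True)
class DichotomizeResult:
    table: pd.DataFrame
    n_excluded: int  # ratings of exactly 50, dropped with an audit count


def dichotomize(table: pd.DataFrame) -> DichotomizeResult:
    """Code ratings >50 as repeat (1) and <50 as reverse (0).

    Ratings of exactly 50 express indifference between the two outcomes and
    are excluded, with the exclusion count reported.
    """
    if _require_single_format(table) != "continuous":
        raise AnalysisError("dichotomize expects a continuous-format table")
    keep = table["response"] != 50
    out = table[keep].copy()
    out["response"] = (out["response"] > 50).astype(int)
    out["format"] = "dichotomous"
    return DichotomizeResult(table=out.reset_index(drop=True), n_excluded=int((~keep).sum()))


@dataclasses.dataclass(frozen=True)
class GroupComparison:
    label_a: str
    label_b: str
    mean_a: float
    mean_b: float
    difference: float  # mean_a - mean_b
    se: float
    t: float
    df: float
    p_value: float


def compare_groups(a, b, label_a: str = "A", label_b: str = "B") -> GroupComparison:
    """Welch's unequal-variance t test between two groups of per-participant
    values, from the closed form with Welch–Satterthwaite degrees of freedom."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise AnalysisError("each group needs at least two participants")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    se = float(np.sqrt(se2))
    diff = float(a.mean() - b.mean())
    if se == 0.0:
        t = 0.0 if diff == 0.0 else np.inf * np.sign(diff)
        df = float(na + nb - 2)
    else:
        t = diff / se
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = float(2 * stats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    return GroupComparison(
        label_a=label_a,
        label_b=label_b,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        difference=diff,
        se=se,
        t=float(t),
        df=float(df),
        p_value=p,
    )


def participant_repeat_rates(table: pd.DataFrame) -> pd.DataFrame:
    """Per-participant mean repeat response over the six target trials.

    The cross-format comparisons dichotomize ratings first, then compare
    these per-participant proportions between studies with Welch's t.
    Returns columns participant_id, condition, repeat_rate.
    """
    _require_single_format(table)
    targets = table[table["role"] == "target"]
    out = (
        targets.groupby(["participant_id", "condition"])["response"]
        .mean()
        .reset_index()
        .rename(columns={"response": "repeat_rate"})
    )
    return out
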