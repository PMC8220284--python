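"""Derived analysis variables: AUC, SES and trust composites, income deciles.

The area under the discounting curve (AUC) summarises the three
indifference points y1, y2, y3 at delays x1 < x2 < x3 as the sum of the
two trapezoids ``(x2-x1)(y1+y2)/2 + (x3-x2)(y2+y3)/2`` (£·days); lower
AUC means steeper discounting.  Composites are sums of z-scored
components computed within the analysed cohort:

* objective SES  = z(total monthly income) + z(education level 1-6)
* subjective SES = z(each of the three relative-affluence items, 1-7)
                   + z(MacArthur ladder, 1-10)
* trust index    = z(general-trust binary) + z(helpful, 1-10) + z(fair, 1-10)

The general-trust item maps "most people can be trusted" to 1 and every
other answer (including "don't know") to 0.  Annual total income is
12 x (monthly income + monthly benefits); the income decile comes from a
reference table of nine upper cut points, ties resolving to the higher
decile, and the perception bias is the MacArthur ladder answer minus the
actual decile.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .task import IndifferenceSet, TaskConfig

TRUST_Q1_LEVELS = ("can_be_trusted", "cant_be_too_careful", "dont_know")

GRISK_COLS = ["grisk1", "grisk2", "grisk3"]


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def auc_from_points(delays: Sequence[float], amounts: Sequence[float]) -> float:
    """Trapezoidal AUC over consecutive (delay, amount) points (£·days)."""
    d = np.asarray(delays, dtype=float)
    y = np.asarray(amounts, dtype=float)
    if d.size != y.size or d.size < 2:
        raise ValueError("need matching delays and amounts, at least two points")
    if np.any(np.diff(d) <= 0):
        raise ValueError("delays must be strictly increasing")
    return float(np.sum(np.diff(d) * (y[:-1] + y[1:]) / 2.0))


def auc(points: IndifferenceSet, cfg: TaskConfig) -> float:
    """AUC of one participant's indifference set at the configured delays."""
    return auc_from_points(cfg.block_delays, points.amounts(cfg.block_delays))


# ---------------------------------------------------------------------------
# standardization and composites
# ---------------------------------------------------------------------------

def standardize(values) -> np.ndarray:
    """z-score a sample: mean 0, sample (n-1 denominator) standard deviation 1."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("standardize requires a 1-d sample of size >= 2")
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot standardize a sample with zero spread")
    return (x - x.mean()) / sd


def trust_binary(trust_q1) -> np.ndarray:
    """General-trust item: 1 for 'most people can be trusted', 0 for the others."""
    q1 = np.asarray(trust_q1)
    bad = ~np.isin(q1, TRUST_Q1_LEVELS)
    if bad.any():
        raise ValueError(f"invalid trust_q1 values: {np.unique(q1[bad])}")
    return (q1 == "can_be_trusted").astype(float)


def build_composites(cohort: pd.DataFrame) -> pd.DataFrame:
    """Objective SES, subjective SES and trust-index composites for a cohort.

    Each component is z-scored across the cohort, then summed; the
    composites therefore have sample mean exactly 0 by construction.
    Returns a frame with columns ``objective_ses``, ``subjective_ses``,
    ``trust_index`` indexed like ``cohort``.
    """
    total_income = cohort["monthly_income"].to_numpy(float) + cohort[
        "monthly_benefits"
    ].to_numpy(float)
    objective = standardize(total_income) + standardize(
        cohort["education_level"].to_numpy(float)
    )
    subjective = standardize(cohort["macarthur_ladder"].to_numpy(float))
    for col in GRISK_COLS:
        subjective = subjective + standardize(cohort[col].to_numpy(float))
    trust = standardize(trust_binary(cohort["trust_q1"]))
    trust = trust + standardize(cohort["trust_q2"].to_numpy(float))
    trust = trust + standardize(cohort["trust_q3"].to_numpy(float))
    return pd.DataFrame(
        {
            "objective_ses": objective,
            "subjective_ses": subjective,
            "trust_index": trust,
        },
        index=cohort.index,
    )


# ---------------------------------------------------------------------------
# income deciles and perception bias
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IncomePercentileTable:
    """Nine upper cut points (annual total income, £) defining ten deciles."""

    cuts: tuple[float, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.cuts, dtype=float)
        if c.size != 9:
            raise ValueError("a decile table needs exactly 9 cut points")
        if np.any(c <= 0) or np.any(np.diff(c) <= 0):
            raise ValueError("cut points must be positive and strictly increasing")

    def decile(self, annual_income) -> np.ndarray:
        """Decile (1-10) of each annual income; ties at a cut resolve upward."""
        income = np.asarray(annual_income, dtype=float)
        if np.any(income < 0):
            raise ValueError("annual income must be non-negative")
        return (np.searchsorted(np.asarray(self.cuts), income, side="right") + 1).astype(int)

    @classmethod
    def from_csv(cls, path) -> "IncomePercentileTable":
        frame = pd.read_csv(path)
        frame = frame.sort_values("decile")
        return cls(cuts=tuple(frame["upper_bound_gbp"].astype(float)))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"decile": np.arange(1, 10), "upper_bound_gbp": self.cuts}
        ).to_csv(path, index=False)


def default_percentile_table() -> IncomePercentileTable:
    """The synthetic reference decile table shipped with the package."""
    here = Path(__file__).parent / "data" / "percentiles_synthetic.csv"
    return IncomePercentileTable.from_csv(here)


def annual_total_income(monthly_income, monthly_benefits):
    """Annual total income: 12 x (monthly income + monthly benefits)."""
    inc = np.asarray(monthly_income, dtype=float)
    ben = np.asarray(monthly_benefits, dtype=float)
    if np.any(inc < 0) or np.any(ben < 0):
        raise ValueError("income and benefits must be non-negative")
    return 12.0 * (inc + ben)


def decile_and_bias(annual_income: float, macarthur_ladder: int,
                    table: IncomePercentileTable) -> tuple[int, int, str]:
    """Actual decile, perception bias and its sign for one participant.

    Bias is the perceived (ladder) minus the actual decile; a shift of
    one decile or more in either direction classifies the participant as
    negatively / positively biased.
    """
    ladder = int(macarthur_ladder)
    if not 1 <= ladder <= 10:
        raise ValueError(f"MacArthur ladder {ladder} outside 1-10")
    actual = int(table.decile(annual_income))
    bias = ladder - actual
    sign = "negative" if bias <= -1 else ("positive" if bias >= 1 else "none")
    return actual, bias, sign


def bias_sign(bias) -> np.ndarray:
    b = np.asarray(bias)
    return np.where(b <= -1, "negative", np.where(b >= 1, "positive", "none"))


def assign_arm(bias: int, rng_seed: int) -> str:
    """Study arm for one participant: negative bias -> fair coin, else none."""
    if bias is None:
        raise ValueError("bias must be computed before arm assignment")
    if bias >= 0:
        return "none"
    coin = np.random.default_rng(rng_seed).random()
    return "treated" if coin < 0.5 else "control"


def assign_arms(bias, rng: np.random.Generator) -> np.ndarray:
    """Vectorized arm assignment for a cohort."""
    b = np.asarray(bias)
    coins = rng.random(b.shape)
    arms = np.where(coins < 0.5, "treated", "control")
    return np.where(b <= -1, arms, "none")


# ---------------------------------------------------------------------------
# cohort-level scoring
# ---------------------------------------------------------------------------

def _indifference_points_from_log(trials: pd.DataFrame, cfg: TaskConfig) -> pd.DataFrame:
    """Per-participant indifference points recovered from the raw trial log.

    Replays the unrounded bisection arithmetic in vectorized form: the
    hypothetical next offer is ``L/2 + sum_n s_n L 2^-(n+1)`` with
    ``s_n = +1`` for a later choice on trial n and -1 otherwise, then
    display-rounded.  Equivalent to :func:`tdmed.task.extract_indifference`
    applied per block (checked in the test suite).
    """
    t = trials.loc[~trials["is_catch"].astype(bool)].copy()
    L = cfg.later_amount
    sign = np.where(t["choice"].to_numpy() == "later", 1.0, -1.0)
    t["contrib"] = sign * L * 2.0 ** -(t["trial_index"].to_numpy(float) + 1.0)
    grouped = t.groupby(["participant_id", "later_delay_days"], sort=True)
    counts = grouped.size()
    if (counts != cfg.trials_per_block).any():
        bad = counts[counts != cfg.trials_per_block]
        raise ValueError(f"incomplete titration blocks for: {list(bad.index)[:5]}")
    unrounded = L / 2.0 + grouped["contrib"].sum()
    step = cfg.rounding_step
    rounded = np.floor(unrounded / step + 0.5) * step
    points = rounded.unstack("later_delay_days")
    missing = [d for d in cfg.block_delays if d not in points.columns]
    if missing:
        raise ValueError(f"trial log lacks blocks at delays {missing}")
    return points[list(cfg.block_delays)]


def auc_from_log(trials: pd.DataFrame, cfg: TaskConfig) -> pd.Series:
    """Per-participant AUC computed from the raw trial log."""
    points = _indifference_points_from_log(trials, cfg)
    delays = np.asarray(cfg.block_delays, dtype=float)
    y = points.to_numpy(float)
    vals = np.sum(np.diff(delays) * (y[:, :-1] + y[:, 1:]) / 2.0, axis=1)
    return pd.Series(vals, index=points.index, name="auc")


def score_cohort(
    participants: pd.DataFrame,
    trials: pd.DataFrame,
    table: IncomePercentileTable | None = None,
    cfg: TaskConfig | None = None,
) -> pd.DataFrame:
    """Attach every derived analysis variable to a (QC-passed) cohort.

    Adds: annual_total_income, actual_decile, bias, bias_sign, auc, and
    the three composites.  Standardization is computed within this
    cohort, so composites must be (re)built after any exclusions.
    """
    table = table or default_percentile_table()
    cfg = cfg or TaskConfig()
    out = participants.copy()
    out["annual_total_income"] = annual_total_income(
        out["monthly_income"], out["monthly_benefits"]
    )
    out["actual_decile"] = table.decile(out["annual_total_income"])
    ladder = out["macarthur_ladder"].to_numpy(int)
    if np.any((ladder < 1) | (ladder > 10)):
        raise ValueError("MacArthur ladder answers must lie in 1-10")
    out["bias"] = ladder - out["actual_decile"]
    out["bias_sign"] = bias_sign(out["bias"])
    aucs = auc_from_log(trials, cfg)
    out = out.set_index("participant_id", drop=False)
    missing = out.index.difference(aucs.index)
    if len(missing) > 0:
        raise ValueError(f"no trial log for participants {list(missing)[:5]}")
    out["auc"] = aucs.reindex(out.index)
    out[["objective_ses", "subjective_ses", "trust_index"]] = build_composites(out)
    return out.reset_index(drop=True)


class CohortScorer(BaseEstimator, TransformerMixin):
    """sklearn-style wrapper around :func:`score_cohort`.

    The trial log, percentile table and task config are estimator
    parameters; ``transform`` maps a raw participant table to the scored
    table.  Because composites are cohort-relative, ``fit`` records the
    cohort used and ``transform`` re-scores it as one batch.
    """

    def __init__(self, trials: pd.DataFrame | None = None,
                 table: IncomePercentileTable | None = None,
                 cfg: TaskConfig | None = None):
        self.trials = trials
        self.table = table
        self.cfg = cfg

    def fit(self, X: pd.DataFrame, y=None):
        if self.trials is None:
            raise ValueError("CohortScorer requires a trial log")
        self.n_participants_ = len(X)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "n_participants_"):
            raise ValueError("CohortScorer must be fitted before transform")
        return score_cohort(X, self.trials, self.table, self.cfg)
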