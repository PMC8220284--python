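"""Participant exclusion rules.

A participant is dropped from all analyses if they failed one or more
catch trials, or if any single-question screen was answered in under
500 ms or over 2 minutes, or any multi-question page in under 3 s or
over 5 minutes.  Thresholds are read strictly ("less than" / "greater
than"), so boundary response times are retained.  Screens carry their
kind (``single`` / ``multi``) from generation; nothing is inferred from
content.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FLAG_COLS = ["catch_fail", "rt_fast_single", "rt_slow_single",
             "rt_fast_multi", "rt_slow_multi"]


@dataclass(frozen=True)
class QCThresholds:
    """Response-time windows in milliseconds (strict inequalities)."""

    single_fast_ms: float = 500.0
    single_slow_ms: float = 120_000.0   # 2 minutes
    multi_fast_ms: float = 3_000.0
    multi_slow_ms: float = 300_000.0    # 5 minutes


@dataclass
class QCReport:
    """Per-participant exclusion flags plus cohort counts."""

    flags: pd.DataFrame       # participant_id + FLAG_COLS + retained
    n_before: int
    n_after: int

    @property
    def retained_ids(self) -> pd.Index:
        return pd.Index(self.flags.loc[self.flags["retained"], "participant_id"])

    def summary(self) -> str:
        return f"QC: before {self.n_before} / after {self.n_after}"

    def to_csv(self, path) -> None:
        self.flags.to_csv(path, index=False)


def apply_exclusions(
    participants: pd.DataFrame,
    screens: pd.DataFrame,
    trials: pd.DataFrame,
    thresholds: QCThresholds | None = None,
) -> QCReport:
    """Flag and count exclusions for a cohort.

    ``screens`` is a long table (participant_id, screen_kind, rt_ms);
    ``trials`` is the task log used for catch-trial failures.  A
    participant is retained iff no flag is set.  Participants without
    any screen response times are an error (named in the message).
    """
    thresholds = thresholds or QCThresholds()
    ids = participants["participant_id"]
    if ids.duplicated().any():
        raise ValueError("duplicate participant ids")

    have_screens = set(screens["participant_id"].unique())
    missing = [pid for pid in ids if pid not in have_screens]
    if missing:
        raise ValueError(f"missing screen response times for participant(s) {missing[:5]}")
    bad_kind = ~screens["screen_kind"].isin(["single", "multi"])
    if bad_kind.any():
        raise ValueError(
            f"unknown screen kinds: {screens.loc[bad_kind, 'screen_kind'].unique()}"
        )

    single = screens[screens["screen_kind"] == "single"]
    multi = screens[screens["screen_kind"] == "multi"]

    def _any_by_id(frame: pd.DataFrame, mask: np.ndarray) -> pd.Series:
        if len(frame) == 0:
            return pd.Series(False, index=ids)
        hit = frame.loc[mask, "participant_id"].unique()
        return ids.isin(hit)

    flags = pd.DataFrame({"participant_id": ids})
    flags["rt_fast_single"] = _any_by_id(
        single, single["rt_ms"].to_numpy() < thresholds.single_fast_ms
    ).to_numpy()
    flags["rt_slow_single"] = _any_by_id(
        single, single["rt_ms"].to_numpy() > thresholds.single_slow_ms
    ).to_numpy()
    flags["rt_fast_multi"] = _any_by_id(
        multi, multi["rt_ms"].to_numpy() < thresholds.multi_fast_ms
    ).to_numpy()
    flags["rt_slow_multi"] = _any_by_id(
        multi, multi["rt_ms"].to_numpy() > thresholds.multi_slow_ms
    ).to_numpy()

    catch = trials[trials["is_catch"].astype(bool)]
    if len(catch) == 0:
        raise ValueError("trial log contains no catch trials")
    # a catch trial is failed iff the dominated option was chosen; in the
    # logged catch trials the sooner option strictly dominates
    sooner_dominates = (
        (catch["sooner_amount"].to_numpy() >= catch["later_amount"].to_numpy())
        & (catch["sooner_delay_days"].to_numpy() <= catch["later_delay_days"].to_numpy())
    )
    dominated_choice = np.where(sooner_dominates, "later", "sooner")
    failed = catch.loc[catch["choice"].to_numpy() == dominated_choice, "participant_id"]
    flags["catch_fail"] = ids.isin(failed.unique()).to_numpy()

    flags["retained"] = ~flags[FLAG_COLS].any(axis=1)
    report = QCReport(
        flags=flags[["participant_id", *FLAG_COLS, "retained"]],
        n_before=len(ids),
        n_after=int(flags["retained"].sum()),
    )
    logger.info(report.summary())
    return report


def filter_cohort(
    participants: pd.DataFrame, trials: pd.DataFrame, report: QCReport
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop excluded participants from the participant and trial tables."""
    keep = report.retained_ids
    return (
        participants[participants["participant_id"].isin(keep)].reset_index(drop=True),
        trials[trials["participant_id"].isin(keep)].reset_index(drop=True),
    )
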