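"""Adaptive adjusting-amount (bisection) intertemporal-choice task.

The task offers a choice between a smaller-sooner reward (3 days) and a
fixed larger-later reward (£70 by default) at three delays -- three weeks,
three months and two years -- in three blocks of six binary trials.  The
sooner amount starts at half the later amount and is adjusted after every
choice by ``later_amount * 2**-(n+1)`` where ``n`` is the trial just
completed: up after a patient (later) choice, down after an impatient
(sooner) choice.  Two catch trials with a strictly dominated option close
the task.  The per-block indifference point is the amount the schedule
would offer on a hypothetical seventh trial, display-rounded.

Adjustments operate on the *unrounded* amount; rounding to the nearest
£0.50 is applied only to what the participant sees.  This keeps the
halving schedule exact: for a deterministic responder with true
indifference y* the unrounded extracted point is within
``later_amount * 2**-(trials_per_block+1)`` of y*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

Choice = Literal["sooner", "later", "none"]

#: default catch trials: (sooner_amount, sooner_delay, later_amount, later_delay)
DEFAULT_CATCH_TRIALS: tuple[tuple[float, int, float, int], ...] = (
    (30.0, 3, 1.0, 730),
    (25.0, 3, 0.5, 730),
)


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the titration task.

    Defaults reproduce the standard protocol: £70 later reward, sooner
    delay of 3 days, block delays of 21/90/730 days, six trials per
    block, 50p display rounding and two dominated catch trials.
    """

    later_amount: float = 70.0
    sooner_delay: int = 3
    block_delays: tuple[int, ...] = (21, 90, 730)
    trials_per_block: int = 6
    rounding_step: float = 0.50
    catch_trials: tuple[tuple[float, int, float, int], ...] = DEFAULT_CATCH_TRIALS
    randomize_block_order: bool = True
    randomize_screen_position: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.later_amount <= 0:
            raise ValueError("later_amount must be positive")
        if self.trials_per_block < 1:
            raise ValueError("trials_per_block must be at least 1")
        if self.rounding_step <= 0:
            raise ValueError("rounding_step must be positive")
        delays = tuple(self.block_delays)
        if any(d2 <= d1 for d1, d2 in zip(delays, delays[1:])):
            raise ValueError("block_delays must be strictly increasing")
        if any(d <= self.sooner_delay for d in delays):
            raise ValueError("block_delays must all exceed sooner_delay")
        for sa, sd, la, ld in self.catch_trials:
            dominates = (sa > la and sd <= ld) or (sa >= la and sd < ld)
            if not dominates:
                raise ValueError(
                    f"catch trial ({sa}, {sd}, {la}, {ld}) has no strictly "
                    "dominating option"
                )

    @property
    def n_blocks(self) -> int:
        return len(self.block_delays)

    @property
    def n_trials_total(self) -> int:
        return self.n_blocks * self.trials_per_block + len(self.catch_trials)

    def to_dict(self) -> dict:
        return {
            "later_amount": self.later_amount,
            "sooner_delay": self.sooner_delay,
            "block_delays": list(self.block_delays),
            "trials_per_block": self.trials_per_block,
            "rounding_step": self.rounding_step,
            "catch_trials": [list(c) for c in self.catch_trials],
            "randomize_block_order": self.randomize_block_order,
            "randomize_screen_position": self.randomize_screen_position,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        d = dict(d)
        if "block_delays" in d:
            d["block_delays"] = tuple(d["block_delays"])
        if "catch_trials" in d:
            d["catch_trials"] = tuple(tuple(c) for c in d["catch_trials"])
        return cls(**d)


@dataclass
class TrialRecord:
    """One binary intertemporal choice as shown to the participant."""

    block_index: int
    trial_index: int
    sooner_amount: float
    sooner_delay: int
    later_amount: float
    later_delay: int
    sooner_on_top: bool = True
    is_catch: bool = False
    choice: Choice = "none"
    response_time: float = 0.0


@dataclass
class BisectionState:
    """Running state of one titration block (unrounded trajectory)."""

    current_unrounded_amount: float
    next_trial_index: int = 1
    history: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class IndifferenceSet:
    """Per-participant indifference amounts, one per block delay (£)."""

    points: dict[int, float]

    def __post_init__(self) -> None:
        if len(self.points) == 0:
            raise ValueError("IndifferenceSet requires at least one point")

    def amounts(self, delays: Sequence[int]) -> list[float]:
        try:
            return [self.points[d] for d in delays]
        except KeyError as exc:
            raise ValueError(f"missing indifference point for delay {exc}") from exc


def init_block(cfg: TaskConfig, block_index: int) -> BisectionState:
    """Start a titration block: the first sooner offer is half the later amount."""
    if not 0 <= block_index < cfg.n_blocks:
        raise ValueError(f"block_index {block_index} out of range")
    return BisectionState(current_unrounded_amount=cfg.later_amount * 0.5)


def advance(state: BisectionState, cfg: TaskConfig, choice: Choice) -> BisectionState:
    """Apply one choice: step the unrounded amount by ``later_amount * 2**-(n+1)``.

    ``n`` is the just-completed (1-based) trial index.  A "later" choice
    means the sooner offer was too small, so the amount goes up; a
    "sooner" choice brings it down.
    """
    n = state.next_trial_index
    if n > cfg.trials_per_block:
        raise ValueError("cannot advance past the last trial of the block")
    if choice not in ("sooner", "later"):
        raise ValueError(f"invalid choice {choice!r}")
    step = cfg.later_amount * 2.0 ** -(n + 1)
    amount = state.current_unrounded_amount + (step if choice == "later" else -step)
    return BisectionState(
        current_unrounded_amount=amount,
        next_trial_index=n + 1,
        history=state.history + [choice],
    )


def round_display(amount: float, cfg: TaskConfig) -> float:
    """Round to the nearest rounding step; exact half-steps round away from zero."""
    if amount <= 0:
        raise ValueError("displayed amount must be positive")
    step = cfg.rounding_step
    return math.floor(amount / step + 0.5) * step


def extract_indifference(history: Sequence[str], cfg: TaskConfig) -> float:
    """Indifference point of a completed block.

    Replays the unrounded bisection trajectory and returns the amount
    that would be offered on trial ``trials_per_block + 1``, display
    rounded.
    """
    if len(history) != cfg.trials_per_block:
        raise ValueError(
            f"history has {len(history)} choices, expected {cfg.trials_per_block}"
        )
    state = BisectionState(current_unrounded_amount=cfg.later_amount * 0.5)
    for choice in history:
        state = advance(state, cfg, choice)
    return round_display(state.current_unrounded_amount, cfg)


def score_catch(trials: Sequence[TrialRecord]) -> int:
    """Count failed catch trials (the strictly dominated option was chosen)."""
    catches = [t for t in trials if t.is_catch]
    if not catches:
        raise ValueError("no catch trials present")
    failures = 0
    for t in catches:
        sooner_dominates = (
            t.sooner_amount > t.later_amount and t.sooner_delay <= t.later_delay
        ) or (t.sooner_amount >= t.later_amount and t.sooner_delay < t.later_delay)
        dominated: Choice = "later" if sooner_dominates else "sooner"
        if t.choice == dominated:
            failures += 1
    return failures


def run_task(cfg: TaskConfig, agent, rng_seed: int):
    """Simulate one participant through the full task.

    Block order and screen positions are drawn from ``rng_seed``; the
    agent (see :mod:`tdmed.agents`) supplies choices, with any choice
    randomness drawn from the same stream.  Returns the ordered list of
    :class:`TrialRecord` (titration blocks then catch trials) and the
    :class:`IndifferenceSet` extracted per block.

    Identical config, agent and seed give identical logs.
    """
    from . import agents as _agents  # local import to avoid a cycle

    rng = np.random.default_rng(rng_seed)
    n_blocks = cfg.n_blocks
    block_order = (
        rng.permutation(n_blocks) if cfg.randomize_block_order else np.arange(n_blocks)
    )
    n_records = cfg.n_trials_total
    tops = (
        rng.random(n_records) < 0.5
        if cfg.randomize_screen_position
        else np.zeros(n_records, dtype=bool)
    )
    # response times: lognormal around ~1.5 s, clipped inside the QC window
    rts = np.clip(rng.lognormal(mean=np.log(1500.0), sigma=0.4, size=n_records),
                  600.0, 60_000.0)
    choice_noise = rng.random(n_records)

    records: list[TrialRecord] = []
    points: dict[int, float] = {}
    rec_i = 0
    for block_index in block_order:
        later_delay = cfg.block_delays[block_index]
        state = init_block(cfg, int(block_index))
        for _ in range(cfg.trials_per_block):
            # the agent values the exact offer; the log stores the rounded
            # amount actually displayed (rounding is presentational only)
            trial = TrialRecord(
                block_index=int(block_index),
                trial_index=state.next_trial_index,
                sooner_amount=state.current_unrounded_amount,
                sooner_delay=cfg.sooner_delay,
                later_amount=cfg.later_amount,
                later_delay=later_delay,
                sooner_on_top=bool(tops[rec_i]),
            )
            trial.choice = _agents.choose(agent, trial, u=choice_noise[rec_i])
            trial.sooner_amount = round_display(state.current_unrounded_amount, cfg)
            trial.response_time = float(rts[rec_i])
            records.append(trial)
            state = advance(state, cfg, trial.choice)
            rec_i += 1
        points[later_delay] = round_display(state.current_unrounded_amount, cfg)
    for ci, (sa, sd, la, ld) in enumerate(cfg.catch_trials, start=1):
        trial = TrialRecord(
            block_index=-1,
            trial_index=ci,
            sooner_amount=sa,
            sooner_delay=sd,
            later_amount=la,
            later_delay=ld,
            sooner_on_top=bool(tops[rec_i]),
            is_catch=True,
        )
        trial.choice = _agents.choose(agent, trial, u=choice_noise[rec_i])
        trial.response_time = float(rts[rec_i])
        records.append(trial)
        rec_i += 1
    return records, IndifferenceSet(points=points)


def trials_to_frame(records: Sequence[TrialRecord], participant_id: str) -> pd.DataFrame:
    """Long-format trial log, one row per trial."""
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "block_index": [t.block_index for t in records],
            "trial_index": [t.trial_index for t in records],
            "sooner_amount": [t.sooner_amount for t in records],
            "sooner_delay_days": [t.sooner_delay for t in records],
            "later_amount": [t.later_amount for t in records],
            "later_delay_days": [t.later_delay for t in records],
            "sooner_on_top": [t.sooner_on_top for t in records],
            "is_catch": [t.is_catch for t in records],
            "choice": [t.choice for t in records],
            "rt_ms": [t.response_time for t in records],
        }
    )


def frame_to_trials(frame: pd.DataFrame) -> list[TrialRecord]:
    """Inverse of :func:`trials_to_frame` for a single participant's rows."""
    return [
        TrialRecord(
            block_index=int(r.block_index),
            trial_index=int(r.trial_index),
            sooner_amount=float(r.sooner_amount),
            sooner_delay=int(r.sooner_delay_days),
            later_amount=float(r.later_amount),
            later_delay=int(r.later_delay_days),
            sooner_on_top=bool(r.sooner_on_top),
            is_catch=bool(r.is_catch),
            choice=str(r.choice),
            response_time=float(r.rt_ms),
        )
        for r in frame.itertuples()
    ]
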