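"""Parametric simulated respondents for the intertemporal-choice task.

Agents value a delayed amount with a hyperbolic (Mazur, V = A/(1+kD)) or
exponential (V = A*exp(-kD)) discount function and choose either
deterministically (higher subjective value wins, ties to the later
option) or stochastically through a logistic (softmax) rule on the value
difference with sensitivity ``beta``.  ``beta = inf`` is deterministic;
``beta = 0`` is a fair coin.  Degenerate ``always_sooner`` /
``always_later`` / ``random`` agents are provided for oracle tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .task import TaskConfig, TrialRecord

Model = Literal["hyperbolic", "exponential", "random", "always_sooner", "always_later"]


@dataclass(frozen=True)
class AgentSpec:
    model: Model = "hyperbolic"
    k: float = 0.01
    beta: float = math.inf
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("discount rate k must be non-negative")
        if self.beta < 0:
            raise ValueError("choice sensitivity beta must be non-negative")

    @property
    def deterministic(self) -> bool:
        if self.model in ("always_sooner", "always_later"):
            return True
        if self.model == "random":
            return False
        return math.isinf(self.beta)

    def to_dict(self) -> dict:
        return {"model": self.model, "k": self.k,
                "beta": None if math.isinf(self.beta) else self.beta,
                "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict) -> "AgentSpec":
        d = dict(d)
        if d.get("beta") is None:
            d["beta"] = math.inf
        return cls(**d)


def subjective_value(agent: AgentSpec, amount: float, delay: float) -> float:
    """Discounted present value of ``amount`` delivered after ``delay`` days."""
    if amount < 0 or delay < 0:
        raise ValueError("amount and delay must be non-negative")
    if agent.model == "exponential":
        return amount * math.exp(-agent.k * delay)
    # hyperbolic is also used as the value model for the degenerate agents
    return amount / (1.0 + agent.k * delay)


def choose(agent: AgentSpec, trial: TrialRecord, u: float | None = None) -> str:
    """One choice on one trial.

    Deterministic agents pick the option with the higher subjective
    value (ties go to the later option).  Stochastic agents pick later
    with probability ``logistic(beta * (V_later - V_sooner))``; the
    uniform draw ``u`` may be supplied by the task driver for
    reproducibility, otherwise the agent's own seed is used.
    """
    if agent.model == "always_sooner":
        return "sooner"
    if agent.model == "always_later":
        return "later"
    if agent.model == "random":
        p_later = 0.5
    else:
        v_sooner = subjective_value(agent, trial.sooner_amount, trial.sooner_delay)
        v_later = subjective_value(agent, trial.later_amount, trial.later_delay)
        if agent.deterministic:
            return "later" if v_later >= v_sooner else "sooner"
        p_later = 1.0 / (1.0 + math.exp(-agent.beta * (v_later - v_sooner)))
    if u is None:
        u = float(np.random.default_rng(agent.seed).random())
    return "later" if u < p_later else "sooner"


def theoretical_indifference(agent: AgentSpec, cfg: TaskConfig, later_delay: float) -> float:
    """Closed-form indifference amount y* with V(y*, sooner_delay) = V(L, later_delay).

    Hyperbolic: ``y* = L * (1 + k*s) / (1 + k*D)``; exponential:
    ``y* = L * exp(-k*(D - s))``.  Only defined for deterministic
    discounting agents.
    """
    if agent.model not in ("hyperbolic", "exponential"):
        raise ValueError(f"no indifference point for model {agent.model!r}")
    if not agent.deterministic:
        raise ValueError("theoretical indifference is defined for deterministic agents")
    L, s = cfg.later_amount, cfg.sooner_delay
    if agent.model == "hyperbolic":
        return L * (1.0 + agent.k * s) / (1.0 + agent.k * later_delay)
    return L * math.exp(-agent.k * (later_delay - s))
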