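"""Minimum detectable effect (Bloom) power analysis for a two-arm design.

``MDE = (t_{1-k} + t_{a/2}) * sqrt(sigma^2 / (P(1-P) N))`` where N is the
number of observations, sigma the outcome standard deviation, P the
treated share, ``t_{a/2}`` the two-tailed critical value (1.96 at
alpha = 0.05) and ``t_{1-k}`` the power quantile (0.84 at 80% power).
With the defaults this is ``2.8 * 2 * sigma / sqrt(N)``.  The recruited
sample is inflated for anticipated attrition by ``ceil(N * (1 + rate))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

#: conventional rounded critical values
T_ALPHA_2 = 1.96
T_POWER = 0.84


@dataclass(frozen=True)
class PowerSpec:
    alpha: float = 0.05
    power: float = 0.80
    treated_share: float = 0.5
    sigma: float = 1.0
    n: int | None = None
    mde: float | None = None
    attrition_rate: float = 0.10
    exact_quantiles: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")
        if not 0 < self.treated_share < 1:
            raise ValueError("treated share must be in (0, 1)")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0 <= self.attrition_rate < 1:
            raise ValueError("attrition rate must be in [0, 1)")

    @property
    def multiplier(self) -> float:
        """t_{1-k} + t_{a/2}; rounded conventional values unless exact."""
        if self.exact_quantiles:
            return float(
                stats.norm.ppf(self.power) + stats.norm.ppf(1 - self.alpha / 2)
            )
        if self.alpha == 0.05 and self.power == 0.80:
            return T_POWER + T_ALPHA_2
        return float(stats.norm.ppf(self.power) + stats.norm.ppf(1 - self.alpha / 2))


def mde(spec: PowerSpec) -> float:
    """Minimum detectable standardized effect at the spec's sample size."""
    if spec.n is None or spec.n < 2:
        raise ValueError("spec must carry a sample size N >= 2")
    p = spec.treated_share
    return spec.multiplier * math.sqrt(spec.sigma**2 / (p * (1 - p) * spec.n))


def required_n(spec: PowerSpec) -> int:
    """Smallest integer N whose MDE does not exceed the spec's target MDE."""
    if spec.mde is None or spec.mde <= 0:
        raise ValueError("spec must carry a target MDE > 0")
    p = spec.treated_share
    exact = spec.multiplier**2 * spec.sigma**2 / (p * (1 - p) * spec.mde**2)
    n = math.ceil(exact - 1e-9)  # tolerate float dust on exact solutions
    return max(n, 2)


def inflate_for_attrition(n: int, rate: float) -> int:
    """Recruitment target compensating an anticipated attrition fraction."""
    if not 0 <= rate < 1:
        raise ValueError("attrition rate must be in [0, 1)")
    if n < 0:
        raise ValueError("sample size must be non-negative")
    return math.ceil(n * (1 + rate))


def summarize(spec: PowerSpec) -> dict:
    """One-shot summary: N, MDE and the attrition-inflated recruitment N."""
    if spec.n is not None:
        n = spec.n
        effect = mde(spec)
    else:
        n = required_n(spec)
        effect = mde(PowerSpec(**{**spec.__dict__, "n": n, "mde": None}))
    return {
        "n": int(n),
        "mde": effect,
        "recruit_n": inflate_for_attrition(int(n), spec.attrition_rate),
        "alpha": spec.alpha,
        "power": spec.power,
        "treated_share": spec.treated_share,
        "sigma": spec.sigma,
        "attrition_rate": spec.attrition_rate,
    }
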