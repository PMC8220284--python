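"""Causal-steps regressions and simulation-based mediation estimation.

The causal-steps (Baron-Kenny) diagnostic fits three OLS models on
standardized variables:

    (1)  Y ~ X          total effect of the treatment X on the outcome Y
    (2)  M ~ X          effect of X on the mediator M
    (3)  Y ~ X + M      direct effect of X and the mediator path

With linear models and no treatment-mediator interaction the average
causal mediation effect (ACME), average direct effect (ADE) and total
effect for a treatment contrast t0 -> t1 are

    ACME  = a * b * (t1 - t0)
    ADE   = c' * (t1 - t0)
    total = ACME + ADE          (exact decomposition)

where a is the X coefficient of model (2), and b, c' the M and X
coefficients of model (3).  Uncertainty is propagated by the
quasi-Bayesian Monte Carlo approximation: coefficient vectors are drawn
from the fitted models' asymptotic normal distributions, the effects are
recomputed per draw, and percentile intervals / sign-based two-sided
p-values are reported.  A nonparametric bootstrap (resampling
participants) is available as an alternative.  The proportion mediated
is the ratio of the ACME and total-effect point estimates; its interval
is the percentile interval of the per-draw ratios with all draws
retained, so it may fall outside [0, 1] when the total effect is near 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .scoring import standardize

_STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p_value: float) -> str:
    """Report stars: * p<0.05, ** p<0.01, *** p<0.001."""
    for level, stars in _STAR_LEVELS:
        if p_value < level:
            return stars
    return ""


@dataclass(frozen=True)
class EffectEstimate:
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "stars": self.stars,
        }


@dataclass
class RegressionTable:
    """Summary of one causal-steps OLS fit."""

    name: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    r_squared: float
    r_squared_adj: float
    resid_se: float
    f_statistic: float
    df_model: int
    df_resid: int
    nobs: int

    @classmethod
    def from_results(cls, name: str, res) -> "RegressionTable":
        return cls(
            name=name,
            params=res.params,
            bse=res.bse,
            pvalues=res.pvalues,
            r_squared=float(res.rsquared),
            r_squared_adj=float(res.rsquared_adj),
            resid_se=float(np.sqrt(res.mse_resid)),
            f_statistic=float(res.fvalue),
            df_model=int(res.df_model),
            df_resid=int(res.df_resid),
            nobs=int(res.nobs),
        )


@dataclass
class MediationResult:
    """ACME/ADE/total-effect/proportion-mediated estimates for one contrast."""

    treatment: str
    mediator: str
    outcome: str
    control_value: float
    treat_value: float
    method: str
    n_draws: int
    ci_level: float
    n_obs: int
    acme: EffectEstimate
    ade: EffectEstimate
    total_effect: EffectEstimate
    prop_mediated: EffectEstimate
    prop_mediated_defined: bool = True
    steps: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "treatment": self.treatment,
            "mediator": self.mediator,
            "outcome": self.outcome,
            "control_value": self.control_value,
            "treat_value": self.treat_value,
            "method": self.method,
            "n_draws": self.n_draws,
            "ci_level": self.ci_level,
            "n_obs": self.n_obs,
            "prop_mediated_defined": self.prop_mediated_defined,
            "effects": {
                "ACME": self.acme.to_dict(),
                "ADE": self.ade.to_dict(),
                "total_effect": self.total_effect.to_dict(),
                "prop_mediated": self.prop_mediated.to_dict(),
            },
        }


def quartile_contrast(data: pd.DataFrame, variable: str) -> tuple[float, float]:
    """First and third sample quartiles (linear interpolation) of a column."""
    x = data[variable].to_numpy(float)
    if x.size < 4:
        raise ValueError("need at least 4 observations for a quartile contrast")
    t0, t1 = np.percentile(x, [25.0, 75.0])
    if t0 == t1:
        raise ValueError("degenerate contrast: the quartiles coincide")
    return float(t0), float(t1)


def causal_steps(data: pd.DataFrame, treatment: str, mediator: str, outcome: str,
                 standardize_vars: bool = True) -> dict[str, RegressionTable]:
    """Fit the three causal-steps OLS models on (optionally z-scored) columns."""
    cols = {}
    for name in (treatment, mediator, outcome):
        x = data[name].to_numpy(float)
        cols[name] = standardize(x) if standardize_vars else x
    X = cols[treatment]
    M = cols[mediator]
    Y = cols[outcome]

    def _fit(y, xs, xnames):
        design = sm.add_constant(pd.DataFrame(dict(zip(xnames, xs))))
        return sm.OLS(y, design).fit()

    res1 = _fit(Y, [X], [treatment])
    res2 = _fit(M, [X], [treatment])
    res3 = _fit(Y, [X, M], [treatment, mediator])
    for res in (res1, res2, res3):
        if np.linalg.matrix_rank(res.model.exog) < res.model.exog.shape[1]:
            raise ValueError("rank-deficient design in causal-steps regression")
    return {
        "Y~X": RegressionTable.from_results("Y~X", res1),
        "M~X": RegressionTable.from_results("M~X", res2),
        "Y~X+M": RegressionTable.from_results("Y~X+M", res3),
        "_results": {"Y~X": res1, "M~X": res2, "Y~X+M": res3},
    }


def _sign_p_value(draws: np.ndarray) -> float:
    """Two-sided Monte Carlo p-value: 2 * min(share > 0, share < 0)."""
    return float(2.0 * min(np.mean(draws > 0), np.mean(draws < 0)))


def _percentile_ci(draws: np.ndarray, ci_level: float) -> tuple[float, float]:
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.percentile(draws, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


class CausalMediation(BaseEstimator):
    """Linear mediation estimator for a treatment -> mediator -> outcome triple.

    Parameters
    ----------
    treatment, mediator, outcome
        Column names in the fitted data frame.
    control_value, treat_value
        Treatment contrast t0 -> t1.  If left as None they default to the
        first and third sample quartiles of the (standardized) treatment.
    n_draws
        Monte Carlo draws for the uncertainty propagation (>= 100).
    ci_level
        Central interval coverage, e.g. 0.95.
    method
        ``"quasi_bayesian"`` (coefficient draws from the asymptotic
        normal) or ``"bootstrap"`` (resample participants and refit).
    standardize
        z-score the three variables within the fitted cohort first
        (the convention used throughout this package).
    random_state
        Seed for the Monte Carlo stream; fits are bit-reproducible.

    Attributes (after ``fit``)
    --------------------------
    steps_ : dict of RegressionTable for Y~X, M~X, Y~X+M
    acme_, ade_, total_effect_, prop_mediated_ : EffectEstimate
    contrast_ : (t0, t1) actually used
    result_ : MediationResult bundling everything
    """

    def __init__(self, treatment: str = "objective_ses", mediator: str = "auc",
                 outcome: str = "trust_index", control_value: float | None = None,
                 treat_value: float | None = None, n_draws: int = 1000,
                 ci_level: float = 0.95, method: str = "quasi_bayesian",
                 standardize: bool = True, random_state: int | None = None):
        self.treatment = treatment
        self.mediator = mediator
        self.outcome = outcome
        self.control_value = control_value
        self.treat_value = treat_value
        self.n_draws = n_draws
        self.ci_level = ci_level
        self.method = method
        self.standardize = standardize
        self.random_state = random_state

    # -- internal -----------------------------------------------------------

    def _validate(self, data: pd.DataFrame) -> None:
        for col in (self.treatment, self.mediator, self.outcome):
            if col not in data.columns:
                raise ValueError(f"column {col!r} not in data")
        if self.n_draws < 100:
            raise ValueError("n_draws must be at least 100")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if self.method not in ("quasi_bayesian", "bootstrap"):
            raise ValueError(f"unknown method {self.method!r}")
        if (self.control_value is not None and self.treat_value is not None
                and self.control_value == self.treat_value):
            raise ValueError("control and treatment values must differ")

    def _draw_coefficients(self, steps, rng, frame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-draw (a, b, c') vectors under the selected method."""
        if self.method == "quasi_bayesian":
            res2 = steps["_results"]["M~X"]
            res3 = steps["_results"]["Y~X+M"]
            d2 = rng.multivariate_normal(
                np.asarray(res2.params), np.asarray(res2.cov_params()),
                size=self.n_draws, method="cholesky")
            d3 = rng.multivariate_normal(
                np.asarray(res3.params), np.asarray(res3.cov_params()),
                size=self.n_draws, method="cholesky")
            return d2[:, 1], d3[:, 2], d3[:, 1]
        # bootstrap: resample participants, refit both models per replicate
        n = len(frame)
        a = np.empty(self.n_draws)
        b = np.empty(self.n_draws)
        c = np.empty(self.n_draws)
        Xc = frame["__X"].to_numpy()
        Mc = frame["__M"].to_numpy()
        Yc = frame["__Y"].to_numpy()
        for i in range(self.n_draws):
            idx = rng.integers(0, n, size=n)
            x, m, y = Xc[idx], Mc[idx], Yc[idx]
            d2 = np.column_stack([np.ones(n), x])
            d3 = np.column_stack([np.ones(n), x, m])
            beta2, *_ = np.linalg.lstsq(d2, m, rcond=None)
            beta3, *_ = np.linalg.lstsq(d3, y, rcond=None)
            a[i], b[i], c[i] = beta2[1], beta3[2], beta3[1]
        return a, b, c

    # -- public -------------------------------------------------------------

    def fit(self, X: pd.DataFrame, y=None) -> "CausalMediation":
        data = X
        self._validate(data)
        steps = causal_steps(data, self.treatment, self.mediator, self.outcome,
                             standardize_vars=self.standardize)

        cols = {}
        for name in (self.treatment, self.mediator, self.outcome):
            v = data[name].to_numpy(float)
            cols[name] = standardize(v) if self.standardize else v
        frame = pd.DataFrame({"__X": cols[self.treatment],
                              "__M": cols[self.mediator],
                              "__Y": cols[self.outcome]})

        if self.control_value is None or self.treat_value is None:
            t0, t1 = quartile_contrast(frame, "__X")
        else:
            t0, t1 = float(self.control_value), float(self.treat_value)
        if t0 == t1:
            raise ValueError("degenerate contrast: t0 == t1")
        delta = t1 - t0

        a_hat = float(steps["M~X"].params.iloc[1])
        b_hat = float(steps["Y~X+M"].params.iloc[2])
        c_hat = float(steps["Y~X+M"].params.iloc[1])

        rng = np.random.default_rng(self.random_state)
        a_dr, b_dr, c_dr = self._draw_coefficients(steps, rng, frame)
        acme_dr = a_dr * b_dr * delta
        ade_dr = c_dr * delta
        total_dr = acme_dr + ade_dr

        acme_pt = a_hat * b_hat * delta
        ade_pt = c_hat * delta
        total_pt = acme_pt + ade_pt

        self.acme_ = EffectEstimate(acme_pt, *_percentile_ci(acme_dr, self.ci_level),
                                    _sign_p_value(acme_dr))
        self.ade_ = EffectEstimate(ade_pt, *_percentile_ci(ade_dr, self.ci_level),
                                   _sign_p_value(ade_dr))
        self.total_effect_ = EffectEstimate(
            total_pt, *_percentile_ci(total_dr, self.ci_level), _sign_p_value(total_dr))

        prop_defined = total_pt != 0.0
        if prop_defined:
            with np.errstate(divide="ignore", invalid="ignore"):
                prop_dr = acme_dr / total_dr
            prop_dr = prop_dr[np.isfinite(prop_dr)]
            self.prop_mediated_ = EffectEstimate(
                acme_pt / total_pt, *_percentile_ci(prop_dr, self.ci_level),
                _sign_p_value(prop_dr))
        else:
            self.prop_mediated_ = EffectEstimate(np.nan, np.nan, np.nan, np.nan)

        self.steps_ = {k: v for k, v in steps.items() if k != "_results"}
        self.contrast_ = (t0, t1)
        self.n_obs_ = len(frame)
        self.result_ = MediationResult(
            treatment=self.treatment, mediator=self.mediator, outcome=self.outcome,
            control_value=t0, treat_value=t1, method=self.method,
            n_draws=self.n_draws, ci_level=self.ci_level, n_obs=self.n_obs_,
            acme=self.acme_, ade=self.ade_, total_effect=self.total_effect_,
            prop_mediated=self.prop_mediated_, prop_mediated_defined=prop_defined,
            steps=self.steps_,
        )
        return self

    def estimate_effects(self) -> MediationResult:
        if not hasattr(self, "result_"):
            raise ValueError("CausalMediation must be fitted first")
        return self.result_


def mediate(data: pd.DataFrame, treatment: str, mediator: str, outcome: str,
            **kwargs) -> MediationResult:
    """Functional one-liner over :class:`CausalMediation`."""
    est = CausalMediation(treatment=treatment, mediator=mediator, outcome=outcome,
                          **kwargs)
    return est.fit(data).result_
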