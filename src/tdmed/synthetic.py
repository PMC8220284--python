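"""Synthetic study cohorts with a known structural truth.

The generator emulates an online British cohort: a truncated lognormal
monthly income (capped at £12,500, the recruitment ceiling), a benefits
mixture concentrated at zero, an ordinal 1-6 education level, a
MacArthur ladder answer equal to the actual income decile plus an
integer perception bias (mostly positive), and a latent discount rate
that falls with socio-economic status.  Each participant is simulated
through the full adaptive titration task (:mod:`tdmed.task` driven by a
:mod:`tdmed.agents` respondent), so the trial log, catch trials and
response times are produced by the same machinery the analysis consumes.

The structural model is the linear mediation triple on standardized,
cohort-measured variables:

    M = a * X + noise          (standardized AUC on standardized SES)
    Y = c' * X + b * M + noise (standardized trust index)

with an optional information-shock effect ``tau`` that shifts the
treated participants' standardized AUC target before the discount rate
is solved (default 0: a null shock).  Because the trust items are
discrete, the generator calibrates the latent's scale against the
measured summed z-score index (a single shrink factor, two fixed-point
iterations) so that (a, b, c') hold on the measured variables -- the
scale on which every analysis in this package operates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import agents as _agents
from . import qc as _qc
from . import scoring as _scoring
from . import task as _task
from .mediation import CausalMediation, MediationResult

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticConfig:
    """Structural coefficients, marginal distributions and nuisance rates.

    The defaults reproduce a study-1-like cohort: n = 855, structural
    coefficients (a, b, c') = (0.135, 0.111, 0.153) on standardized
    variables, a null information shock (tau = 0), an AUC distribution
    centred near 20,500 £·days, a predominantly positive decile
    perception bias, and ~4% of participants carrying an injected
    quality-control violation.
    """

    n: int = 855
    seed: int | None = None

    # income / benefits / education
    income_logmean: float = math.log(1800.0)
    income_logsd: float = 0.65
    income_cap_monthly: float = 12_500.0
    income_ses_loading: float = 0.85
    benefit_rate_scale: float = 0.6
    benefit_logmean: float = math.log(400.0)
    benefit_logsd: float = 0.6
    education_mean: float = 3.9
    education_ses_slope: float = 0.55
    education_noise: float = 0.8
    grisk_mean: float = 4.2
    grisk_ses_slope: float = 0.9
    grisk_noise: float = 1.1

    # decile misperception (integer bias, mean > 0: mostly positive)
    bias_mean: float = 1.0
    bias_sd: float = 1.8

    # structural coefficients on standardized variables
    a: float = 0.135
    b: float = 0.111
    c_prime: float = 0.153
    tau: float = 0.0

    # discounting distribution (measured AUC scale, £·days)
    auc_mean: float = 20_500.0
    auc_sd: float = 8_000.0
    auc_floor: float = 1_500.0
    auc_ceiling: float = 49_500.0

    # trust-item construction
    trust_item_noise: float = 0.6
    trust_item_slope: float = 1.9
    dont_know_rate: float = 0.10

    # choice noise: None means deterministic responding
    beta: float | None = None

    # QC violation injection
    catch_fail_rate: float = 0.02
    rt_violation_rate: float = 0.02
    n_single_survey: int = 12
    n_multi_survey: int = 5

    task: _task.TaskConfig = field(default_factory=_task.TaskConfig)

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError("n must be at least 4")
        for name in ("catch_fail_rate", "rt_violation_rate", "dont_know_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("income_logsd", "benefit_logsd", "auc_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.auc_floor < self.auc_mean < self.auc_ceiling:
            raise ValueError("auc_mean must lie between auc_floor and auc_ceiling")


@dataclass(frozen=True)
class GeneratorTruth:
    """Structural coefficients used for a cohort, for parameter recovery."""

    a: float
    b: float
    c_prime: float
    tau: float

    def implied_effects(self, control_value: float, treat_value: float) -> dict:
        delta = treat_value - control_value
        acme = self.a * self.b * delta
        ade = self.c_prime * delta
        return {"acme": acme, "ade": ade, "total_effect": acme + ade}

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticCohort:
    participants: pd.DataFrame
    trials: pd.DataFrame
    screens: pd.DataFrame
    truth: GeneratorTruth
    config: SyntheticConfig


# ---------------------------------------------------------------------------
# discount-rate inversion
# ---------------------------------------------------------------------------

def theoretical_auc(k: float, cfg: _task.TaskConfig) -> float:
    """AUC of a deterministic hyperbolic responder with discount rate ``k``."""
    agent = _agents.AgentSpec(model="hyperbolic", k=k)
    y = [_agents.theoretical_indifference(agent, cfg, d) for d in cfg.block_delays]
    return _scoring.auc_from_points(cfg.block_delays, y)


def solve_k_for_auc(target_auc: np.ndarray, cfg: _task.TaskConfig,
                    k_lo: float = 1e-8, k_hi: float = 10.0,
                    grid_size: int = 8000) -> np.ndarray:
    """Discount rates whose theoretical AUC matches each target (monotone
    inversion on a dense log-spaced grid)."""
    k_grid = np.logspace(np.log10(k_lo), np.log10(k_hi), grid_size)
    auc_grid = np.array([theoretical_auc(k, cfg) for k in k_grid])
    # AUC is strictly decreasing in k: interpolate on the reversed axis
    target = np.clip(np.asarray(target_auc, float), auc_grid[-1], auc_grid[0])
    return np.interp(target, auc_grid[::-1], k_grid[::-1])


# ---------------------------------------------------------------------------
# trust-item construction
# ---------------------------------------------------------------------------

def _build_trust_items(T: np.ndarray, nu: np.ndarray, slope: float):
    """Discretize one latent draw into the three survey answers."""
    lat1 = T + nu[0]
    lat2 = T + nu[1]
    lat3 = T + nu[2]
    q1 = lat1 > np.median(lat1)
    q2 = np.clip(np.rint(5.5 + slope * _scoring.standardize(lat2)), 1, 10).astype(int)
    q3 = np.clip(np.rint(5.5 + slope * _scoring.standardize(lat3)), 1, 10).astype(int)
    return q1, q2, q3


def _calibrated_trust(X: np.ndarray, M: np.ndarray, cfg: SyntheticConfig,
                      rng: np.random.Generator):
    """Trust items whose measured standardized index obeys Y = c'X + bM + e.

    The discrete items attenuate the latent by an unknown shrink factor;
    two fixed-point iterations estimate it from the cohort itself and
    rescale the latent's structural part accordingly.
    """
    n = X.size
    e = rng.standard_normal(n)
    nu = cfg.trust_item_noise * rng.standard_normal((3, n))
    u_dk = rng.random(n)

    a, b, c = cfg.a, cfg.b, cfg.c_prime
    var_struct = c * c + b * b + 2.0 * a * b * c
    sig_e = math.sqrt(max(1.0 - var_struct, 0.2))
    theta_c, theta_b = c, b

    for _ in range(2):
        T = theta_c * X + theta_b * M + sig_e * e
        q1, q2, q3 = _build_trust_items(T, nu, cfg.trust_item_slope)
        if theta_c == 0.0 and theta_b == 0.0:
            break
        index = (_scoring.standardize(q1.astype(float))
                 + _scoring.standardize(q2.astype(float))
                 + _scoring.standardize(q3.astype(float)))
        Y = _scoring.standardize(index)
        Tz = _scoring.standardize(T)
        lam = float(np.mean(Y * Tz) * n / (n - 1))  # OLS slope of Y on z(T)
        lam = max(lam, 0.2)
        sT = float(np.std(T, ddof=1))
        theta_c, theta_b = c * sT / lam, b * sT / lam

    q1_str = np.where(q1, "can_be_trusted",
                      np.where(u_dk < cfg.dont_know_rate, "dont_know",
                               "cant_be_too_careful"))
    return q1_str, q2, q3


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_cohort(cfg: SyntheticConfig,
                    table: _scoring.IncomePercentileTable | None = None) -> SyntheticCohort:
    """Draw a complete cohort: survey answers, trial logs, screen RTs, truth."""
    table = table or _scoring.default_percentile_table()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    ids = np.array([f"p{i:05d}" for i in range(n)])

    # latent affluence factor and observable SES components
    L = rng.standard_normal(n)
    rho = cfg.income_ses_loading
    resid_sd = math.sqrt(max(1.0 - rho * rho, 1e-12))
    income = np.empty(n)
    pending = np.ones(n, dtype=bool)
    while pending.any():  # truncation at the recruitment cap: redraw, keep L
        eps = rng.standard_normal(pending.sum())
        draw = np.exp(cfg.income_logmean
                      + cfg.income_logsd * (rho * L[pending] + resid_sd * eps))
        income[pending] = draw
        pending = pending & (income > cfg.income_cap_monthly)

    p_benefit = cfg.benefit_rate_scale / (1.0 + np.exp(0.9 * L))
    has_benefit = rng.random(n) < p_benefit
    benefit_amt = np.exp(rng.normal(cfg.benefit_logmean, cfg.benefit_logsd, size=n))
    benefits = np.where(has_benefit, np.round(benefit_amt, 2), 0.0)
    income = np.round(income, 2)

    education = np.clip(
        np.rint(cfg.education_mean + cfg.education_ses_slope * L
                + cfg.education_noise * rng.standard_normal(n)), 1, 6
    ).astype(int)
    grisk = [
        np.clip(np.rint(cfg.grisk_mean + cfg.grisk_ses_slope * L
                        + cfg.grisk_noise * rng.standard_normal(n)), 1, 7).astype(int)
        for _ in range(3)
    ]
    age = np.clip(np.rint(rng.normal(40.0, 10.5, size=n)), 21, 75).astype(int)
    sex = rng.choice(["female", "male"], size=n, p=[0.52, 0.48])

    # measured objective SES composite (standardized within the cohort)
    X = _scoring.standardize(
        _scoring.standardize(income + benefits)
        + _scoring.standardize(education.astype(float))
    )

    # ladder = actual decile + integer misperception bias, clipped to the scale
    annual = _scoring.annual_total_income(income, benefits)
    decile = table.decile(annual)
    drawn_bias = np.rint(rng.normal(cfg.bias_mean, cfg.bias_sd, size=n)).astype(int)
    ladder = np.clip(decile + drawn_bias, 1, 10).astype(int)
    arm = _scoring.assign_arms(ladder - decile, rng)

    # target standardized AUC: structural path a, plus the information shock
    m_star = cfg.a * X + math.sqrt(max(1.0 - cfg.a**2, 0.05)) * rng.standard_normal(n)
    m_star = m_star + cfg.tau * (arm == "treated")
    target_auc = np.clip(cfg.auc_mean + cfg.auc_sd * m_star,
                         cfg.auc_floor, cfg.auc_ceiling)
    k = solve_k_for_auc(target_auc, cfg.task)

    # run every participant through the full task
    beta = math.inf if cfg.beta is None else cfg.beta
    task_seeds = rng.integers(0, 2**31, size=n)
    fail_catch = rng.random(n) < cfg.catch_fail_rate
    all_records: list[_task.TrialRecord] = []
    rec_ids: list[str] = []
    auc_measured = np.empty(n)
    for i in range(n):
        agent = _agents.AgentSpec(model="hyperbolic", k=float(k[i]), beta=beta)
        records, points = _task.run_task(cfg.task, agent, int(task_seeds[i]))
        if fail_catch[i]:
            for t in records:
                if t.is_catch:  # flip the first catch to the dominated option
                    t.choice = "later"
                    break
        all_records.extend(records)
        rec_ids.extend([ids[i]] * len(records))
        auc_measured[i] = _scoring.auc(points, cfg.task)
    trials = _task.trials_to_frame(all_records, "x")
    trials["participant_id"] = rec_ids

    M = _scoring.standardize(auc_measured)
    q1, q2, q3 = _calibrated_trust(X, M, cfg, rng)

    participants = pd.DataFrame(
        {
            "participant_id": ids,
            "age": age,
            "sex": sex,
            "is_student": False,
            "monthly_income": income,
            "monthly_benefits": benefits,
            "education_level": education,
            "macarthur_ladder": ladder,
            "grisk1": grisk[0],
            "grisk2": grisk[1],
            "grisk3": grisk[2],
            "trust_q1": q1,
            "trust_q2": q2,
            "trust_q3": q3,
            "arm": arm,
            "drawn_bias": drawn_bias,
        }
    )

    screens = _make_screens(cfg, ids, trials, rng)
    truth = GeneratorTruth(a=cfg.a, b=cfg.b, c_prime=cfg.c_prime, tau=cfg.tau)
    return SyntheticCohort(participants=participants, trials=trials,
                           screens=screens, truth=truth, config=cfg)


def _make_screens(cfg: SyntheticConfig, ids: np.ndarray, trials: pd.DataFrame,
                  rng: np.random.Generator) -> pd.DataFrame:
    """Screen-level response times: task trials plus survey pages, with
    QC violations injected at the configured per-participant rate."""
    n = ids.size
    n_single = cfg.n_single_survey
    n_multi = cfg.n_multi_survey
    single_rts = np.clip(
        rng.lognormal(np.log(3500.0), 0.5, size=(n, n_single)), 600.0, 100_000.0)
    multi_rts = np.clip(
        rng.lognormal(np.log(25_000.0), 0.5, size=(n, n_multi)), 3_500.0, 280_000.0)

    violate = rng.random(n) < cfg.rt_violation_rate
    viol_kind = rng.integers(0, 4, size=n)  # single-fast/slow, multi-fast/slow
    viol_single_col = rng.integers(0, n_single, size=n)
    viol_multi_col = rng.integers(0, n_multi, size=n)
    for i in np.flatnonzero(violate):
        kind = viol_kind[i]
        if kind == 0:
            single_rts[i, viol_single_col[i]] = 200.0
        elif kind == 1:
            single_rts[i, viol_single_col[i]] = 130_000.0
        elif kind == 2:
            multi_rts[i, viol_multi_col[i]] = 1_500.0
        else:
            multi_rts[i, viol_multi_col[i]] = 320_000.0

    survey = pd.DataFrame(
        {
            "participant_id": np.concatenate(
                [np.repeat(ids, n_single), np.repeat(ids, n_multi)]),
            "screen_kind": ["single"] * (n * n_single) + ["multi"] * (n * n_multi),
            "rt_ms": np.concatenate([single_rts.ravel(), multi_rts.ravel()]),
        }
    )
    trial_screens = pd.DataFrame(
        {
            "participant_id": trials["participant_id"],
            "screen_kind": "single",
            "rt_ms": trials["rt_ms"],
        }
    )
    return pd.concat([trial_screens, survey], ignore_index=True)


# ---------------------------------------------------------------------------
# pipeline composition
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    cohort: SyntheticCohort
    qc_report: _qc.QCReport
    scored: pd.DataFrame
    mediation: MediationResult


def end_to_end(cfg: SyntheticConfig,
               table: _scoring.IncomePercentileTable | None = None,
               **mediation_kwargs) -> PipelineResult:
    """generate -> QC -> score -> mediate, with stage counts logged.

    ``mediation_kwargs`` are forwarded to :class:`CausalMediation`; the
    default analyses objective SES -> AUC -> trust index at the quartile
    contrast.  When the treatment is the binary study arm, only
    participants assigned to an arm are analysed.
    """
    table = table or _scoring.default_percentile_table()
    cohort = generate_cohort(cfg, table)
    logger.info("generated %d participants, %d trials",
                len(cohort.participants), len(cohort.trials))
    report = _qc.apply_exclusions(cohort.participants, cohort.screens, cohort.trials)
    participants, trials = _qc.filter_cohort(cohort.participants, cohort.trials, report)
    scored = _scoring.score_cohort(participants, trials, table, cfg.task)
    logger.info("scored %d retained participants", len(scored))

    kwargs = dict(mediation_kwargs)
    treatment = kwargs.pop("treatment", "objective_ses")
    data = scored
    if treatment == "arm":
        data = scored[scored["arm"].isin(["control", "treated"])].copy()
        data["arm"] = (data["arm"] == "treated").astype(float)
        kwargs.setdefault("standardize", False)
        kwargs.setdefault("control_value", 0.0)
        kwargs.setdefault("treat_value", 1.0)
        # the mediator and outcome still enter standardized
        data["auc"] = _scoring.standardize(data["auc"].to_numpy())
        data["trust_index"] = _scoring.standardize(data["trust_index"].to_numpy())
    est = CausalMediation(treatment=treatment,
                          mediator=kwargs.pop("mediator", "auc"),
                          outcome=kwargs.pop("outcome", "trust_index"),
                          **kwargs)
    est.fit(data)
    return PipelineResult(cohort=cohort, qc_report=report, scored=scored,
                          mediation=est.result_)
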