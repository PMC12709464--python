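"""Synthetic trial generators with counterfactual ground truth.

Four generators cover the situations where functional unmasking distorts a
naive analysis:

* :func:`simulate_collider` — a single-timepoint trial where a latent-ish
  responder trait drives both post-treatment belief and the outcome, so
  stratifying on belief opens a collider path and can reverse the sign of
  a strongly beneficial treatment.
* :func:`simulate_vaccine` — a weekly-tested vaccine trial where perceived
  protection feeds back into risk behavior (efficacy-expectancy feedback),
  shrinking the between-arm gap in cumulative infections even though the
  per-exposure effect is untouched.
* :func:`simulate_dose_response` — a dose-ranging trial where expectancy
  itself has a dose-response profile, so the naive dose trend conflates
  direct and expectancy-mediated effects.
* :func:`simulate_sequential` — a two-timepoint design that randomizes both
  treatment and an expectancy-manipulation message at every timepoint,
  yielding 16 regimes analysable with marginal structural models.

Every generator returns ``(dataset, OracleTruth)``.  The oracle is computed
by intervening on the generating equations — closed form, numeric
integration over the trait density, or counterfactual Monte Carlo with
common random numbers — never by running any estimator.

Randomness is drawn as whole ``(n, k)`` blocks from a single generator per
stream, so enlarging ``n`` extends the subject list without reshuffling
earlier subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import integrate, stats
from scipy.special import expit

from .trial_data import (
    LongitudinalDataset,
    LongitudinalSchema,
    TrialDataset,
    TrialSchema,
)

__all__ = [
    "ConfigError",
    "OracleTruth",
    "ColliderSimConfig",
    "VaccineSimConfig",
    "DoseResponseSimConfig",
    "SequentialSimConfig",
    "simulate_collider",
    "simulate_vaccine",
    "simulate_dose_response",
    "simulate_sequential",
]


class ConfigError(ValueError):
    """A simulator configuration violates its invariants."""


@dataclass
class OracleTruth:
    """Counterfactual ground truth emitted by a simulator.

    ``true_CDE`` maps an expectancy level e (or a dose d for dose-response
    data, where the contrast is dose d vs 0 at fixed e) to the controlled
    direct effect.  ``true_tfCDE`` maps ``(a, (e1, e0))`` to the within-arm
    expectancy contrast.  ``regime_means`` maps a full treatment/message
    sequence to the mean final outcome under that regime.  ``extras`` holds
    scenario-specific truths (stratified-contrast values, infection
    trajectories, naive trends).
    """

    true_ATE: float | None = None
    true_CDE: dict = field(default_factory=dict)
    true_tfCDE: dict = field(default_factory=dict)
    regime_means: dict = field(default_factory=dict)
    method: str = "closed_form"
    mc_reps: int | None = None
    extras: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        def _clean(obj):
            if isinstance(obj, dict):
                return {str(k): _clean(v) for k, v in obj.items()}
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            return obj

        return {
            "true_ATE": self.true_ATE,
            "true_CDE": _clean(self.true_CDE),
            "true_tfCDE": _clean(self.true_tfCDE),
            "regime_means": _clean(self.regime_means),
            "method": self.method,
            "mc_reps": self.mc_reps,
            "extras": _clean(self.extras),
        }


def _check_prob(value: float, name: str) -> None:
    if not (0.0 <= value <= 1.0):
        raise ConfigError(f"{name} must lie in [0, 1], got {value}")


def _streams(seed: int, n_streams: int) -> list[np.random.Generator]:
    """Independent generators, one per randomness block.

    Each block (assignments, noise, ...) is drawn as a single (n, k) array
    from its own stream, so enlarging n appends subjects without
    reshuffling the draws of earlier ones.
    """
    return [np.random.default_rng(np.random.SeedSequence([seed, k]))
            for k in range(n_streams)]


# ---------------------------------------------------------------------------
# Collider / belief-stratification world
# ---------------------------------------------------------------------------


@dataclass
class ColliderSimConfig:
    """Single-dose trial where a responder trait confounds belief and outcome.

    The trait Z (e.g. pre-treatment expectancies or a biological
    responsiveness score, recorded post treatment as a trip-intensity-like
    measure) raises both the chance of believing one was treated and the
    amount of improvement.  The outcome is a change-from-baseline severity
    score, so beneficial effects are negative.

    Defaults are chosen so the within-belief stratified contrast has the
    opposite sign of the true (negative, beneficial) direct effect, and the
    numeric-integration oracle certifies both signs.
    """

    n: int = 2000
    beta_A: float = -10.0     # direct treatment effect on the change score
    beta_U: float = -16.0     # responder-trait effect on the change score
    kappa_A: float = 5.0      # treatment effect on belief (log-odds)
    kappa_U: float = 3.0      # trait effect on belief (log-odds)
    kappa_0: float = -2.5     # belief intercept (log-odds)
    sigma_Y: float = 5.0
    y_intercept: float = -5.0  # mean change score under control at trait 0
    baseline_mean: float = 40.0  # CAPS-like baseline severity
    baseline_sd: float = 8.0
    p_treat: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n < 1:
            raise ConfigError("n must be >= 1")
        if self.sigma_Y <= 0:
            raise ConfigError("sigma_Y must be > 0")
        _check_prob(self.p_treat, "p_treat")


def _collider_stratum_mean(cfg: ColliderSimConfig, a: int, b: int):
    """(E[Z | A=a, B=b], P(B=b | A=a)) by numeric integration over Z~N(0,1)."""

    def p_b(z):
        p1 = expit(cfg.kappa_0 + cfg.kappa_A * a + cfg.kappa_U * z)
        return p1 if b == 1 else 1.0 - p1

    num = integrate.quad(lambda z: z * stats.norm.pdf(z) * p_b(z), -12, 12)[0]
    den = integrate.quad(lambda z: stats.norm.pdf(z) * p_b(z), -12, 12)[0]
    return num / den, den


def collider_oracle(cfg: ColliderSimConfig) -> OracleTruth:
    """Intervene on the collider generating equations.

    The ATE and CDE are closed form (the trait is independent of the
    randomized treatment, and belief/expectancy never enters the outcome
    equation, so CDE(e) = beta_A at every level).  The stratified and
    rebalanced pseudo-truths require E[Z | A, B], obtained by numeric
    integration over the standard-normal trait density.
    """
    strat = {}
    p_b1 = {}
    for b in (0, 1):
        m1, p1 = _collider_stratum_mean(cfg, 1, b)
        m0, p0 = _collider_stratum_mean(cfg, 0, b)
        strat[b] = cfg.beta_A + cfg.beta_U * (m1 - m0)
        if b == 1:
            p_b1 = {1: p1, 0: p0}
    pool1 = cfg.p_treat * p_b1[1] + (1 - cfg.p_treat) * p_b1[0]
    gap = {
        b: _collider_stratum_mean(cfg, 1, b)[0] - _collider_stratum_mean(cfg, 0, b)[0]
        for b in (0, 1)
    }
    rebalanced = cfg.beta_A + cfg.beta_U * (pool1 * gap[1] + (1 - pool1) * gap[0])
    return OracleTruth(
        true_ATE=cfg.beta_A,
        true_CDE={0: cfg.beta_A, 1: cfg.beta_A},
        true_tfCDE={(0, (1, 0)): 0.0, (1, (1, 0)): 0.0},
        method="numeric_integration",
        extras={
            "stratified_truth": strat,
            "rebalanced_truth": rebalanced,
            "p_belief1_given_arm": p_b1,
        },
    )


def simulate_collider(cfg: ColliderSimConfig) -> tuple[TrialDataset, OracleTruth]:
    cfg.validate()
    rng_u, rng_n = _streams(cfg.seed, 2)
    U = rng_u.random((cfg.n, 2))           # uniforms: treatment, belief
    N = rng_n.standard_normal((cfg.n, 3))  # normals: trait, outcome noise, baseline
    A = (U[:, 0] < cfg.p_treat).astype(int)
    Z = N[:, 0]
    logit_b = cfg.kappa_0 + cfg.kappa_A * A + cfg.kappa_U * Z
    B = (U[:, 1] < expit(logit_b)).astype(int)
    Y = cfg.y_intercept + cfg.beta_A * A + cfg.beta_U * Z + cfg.sigma_Y * N[:, 1]
    baseline = cfg.baseline_mean + cfg.baseline_sd * N[:, 2]
    df = pd.DataFrame(
        {
            "subject_id": np.arange(cfg.n),
            "baseline_severity": baseline,
            "A": A,
            "B": B,
            "E": B,  # expectancy operationalized as post-treatment belief
            "z_trait": Z,
            "Y": Y,
        }
    )
    schema = TrialSchema(
        treatment="A",
        expectancy="E",
        outcome="Y",
        belief="B",
        covariates=("baseline_severity",),
        post_confounders=("z_trait",),
        subject="subject_id",
    )
    return TrialDataset(df, schema), collider_oracle(cfg)


# ---------------------------------------------------------------------------
# Vaccine / efficacy-expectancy feedback world
# ---------------------------------------------------------------------------


@dataclass
class VaccineSimConfig:
    """Weekly-tested vaccine trial with optional behavioral feedback.

    Each week a subject is exposed with probability ``p_exposure`` scaled by
    their current risk-behavior level (the expectancy proxy, starting at 1);
    an exposure infects with probability ``p_infect_exposed`` reduced by the
    per-exposure ``vaccine_efficacy`` in the vaccinated arm.  A positive
    weekly test scares the subject: with feedback on, each infection
    multiplies the risk level by ``rho_feedback``.  The cure is instant and
    non-immunizing, so reinfection is possible every week.
    """

    n_per_arm: int = 10_000
    T_weeks: int = 12
    p_exposure: float = 0.30
    p_infect_exposed: float = 0.25
    vaccine_efficacy: float = 0.50
    feedback_enabled: bool = True
    rho_feedback: float = 0.5
    seed: int = 0
    oracle_mc_reps: int = 20_000

    def validate(self) -> None:
        if self.n_per_arm < 1 or self.T_weeks < 1:
            raise ConfigError("n_per_arm and T_weeks must be >= 1")
        for name in ("p_exposure", "p_infect_exposed", "vaccine_efficacy"):
            _check_prob(getattr(self, name), name)
        if not (0.0 < self.rho_feedback <= 1.0):
            raise ConfigError("rho_feedback must lie in (0, 1]")


def _vaccine_trajectory(
    cfg: VaccineSimConfig, a: int, U: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Run the weekly mechanism for one fixed arm over shared uniforms U.

    U has shape (n, T, 2): exposure and infection draws.  Returns per-week
    (exposed, infected, risk-level-entering-week, cumulative) arrays.
    """
    n = U.shape[0]
    risk = np.ones(n)
    p_inf = cfg.p_infect_exposed * (1.0 - cfg.vaccine_efficacy * a)
    exposed = np.empty((n, cfg.T_weeks), dtype=int)
    infected = np.empty((n, cfg.T_weeks), dtype=int)
    risk_path = np.empty((n, cfg.T_weeks))
    for t in range(cfg.T_weeks):
        risk_path[:, t] = risk
        p_exp = np.clip(cfg.p_exposure * risk, 0.0, 1.0)
        exposed[:, t] = U[:, t, 0] < p_exp
        infected[:, t] = exposed[:, t] & (U[:, t, 1] < p_inf)
        if cfg.feedback_enabled:
            risk = np.where(infected[:, t] == 1, risk * cfg.rho_feedback, risk)
    cum = np.cumsum(infected, axis=1)
    return exposed, infected, risk_path, cum


def vaccine_oracle(cfg: VaccineSimConfig) -> OracleTruth:
    """Counterfactual Monte Carlo: every oracle subject is run under both
    arms with common random numbers; the per-exposure risk ratio is closed
    form (1 − efficacy), untouched by feedback because infection probability
    per exposure never depends on the risk level."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7_001]))
    U = rng.random((cfg.oracle_mc_reps, cfg.T_weeks, 2))
    _, _, _, cum1 = _vaccine_trajectory(cfg, 1, U)
    _, _, _, cum0 = _vaccine_trajectory(cfg, 0, U)
    traj1 = cum1.mean(axis=0)
    traj0 = cum0.mean(axis=0)
    return OracleTruth(
        true_ATE=float(traj1[-1] - traj0[-1]),
        method="monte_carlo_counterfactual",
        mc_reps=cfg.oracle_mc_reps,
        extras={
            "per_exposure_risk_ratio": 1.0 - cfg.vaccine_efficacy,
            "per_exposure_risk_reduction": cfg.vaccine_efficacy,
            "expected_cumulative_a1": traj1,
            "expected_cumulative_a0": traj0,
            "final_week_gap": float(traj0[-1] - traj1[-1]),
        },
    )


def simulate_vaccine(cfg: VaccineSimConfig) -> tuple[LongitudinalDataset, OracleTruth]:
    cfg.validate()
    (rng,) = _streams(cfg.seed, 1)
    n = 2 * cfg.n_per_arm
    A = (np.arange(n) % 2 == 0).astype(int)  # alternating balanced allocation
    U = rng.random((n, cfg.T_weeks, 2))
    # run both arms' mechanics on each subject's draws, pick the assigned one
    exp1, inf1, risk1, cum1 = _vaccine_trajectory(cfg, 1, U)
    exp0, inf0, risk0, cum0 = _vaccine_trajectory(cfg, 0, U)
    pick = A[:, None]
    exposed = np.where(pick == 1, exp1, exp0)
    infected = np.where(pick == 1, inf1, inf0)
    risk = np.where(pick == 1, risk1, risk0)
    cum = np.where(pick == 1, cum1, cum0)
    T = cfg.T_weeks
    df = pd.DataFrame(
        {
            "subject_id": np.repeat(np.arange(n), T),
            "week": np.tile(np.arange(1, T + 1), n),
            "A": np.repeat(A, T),
            "exposed": exposed.ravel(),
            "infected": infected.ravel(),
            "risk_level": risk.ravel(),
            "cum_infections": cum.ravel(),
        }
    )
    schema = LongitudinalSchema(
        subject="subject_id",
        time="week",
        treatment="A",
        outcome="infected",
        expectancy="risk_level",  # behavioral proxy for expectancy
    )
    return LongitudinalDataset(df, schema), vaccine_oracle(cfg)


# ---------------------------------------------------------------------------
# Dose-response world
# ---------------------------------------------------------------------------


@dataclass
class DoseResponseSimConfig:
    """Dose-ranging trial where expectancy has its own dose-response.

    Expectancy is binary with P(E=1 | dose d) = e_intercept + alpha_d * d
    (a linear-probability profile), and the outcome is
    Y = gamma_d * d + gamma_E * E + beta_X * X + noise.  Full mediation of
    the dose trend through expectancy is the special case gamma_d = 0.
    """

    n: int = 4000
    dose_levels: tuple[int, ...] = (0, 1, 2, 3)
    gamma_E: float = 5.0   # expectancy effect on the outcome
    gamma_d: float = 1.0   # direct per-level dose effect
    alpha_d: float = 0.2   # per-level increase in P(E = 1)
    e_intercept: float = 0.2
    beta_X: float = 1.0
    sigma_Y: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if self.n < 1:
            raise ConfigError("n must be >= 1")
        if self.sigma_Y <= 0:
            raise ConfigError("sigma_Y must be > 0")
        if len(self.dose_levels) < 2:
            raise ConfigError("need at least two dose levels")
        for d in self.dose_levels:
            _check_prob(self.e_intercept + self.alpha_d * d, f"P(E=1 | dose={d})")


def dose_oracle(cfg: DoseResponseSimConfig) -> OracleTruth:
    """All dose-response truths are closed form in the linear DGP."""
    doses = list(cfg.dose_levels)
    naive_means = {
        d: cfg.gamma_d * d + cfg.gamma_E * (cfg.e_intercept + cfg.alpha_d * d)
        for d in doses
    }
    d1 = doses[1]
    return OracleTruth(
        true_ATE=naive_means[d1] - naive_means[doses[0]],
        true_CDE={d: cfg.gamma_d * (d - doses[0]) for d in doses},
        true_tfCDE={(d, (1, 0)): cfg.gamma_E for d in doses},
        method="closed_form",
        extras={
            "naive_trend_per_level": cfg.gamma_d + cfg.gamma_E * cfg.alpha_d,
            "cde_slope_per_level": cfg.gamma_d,
            "naive_means_by_dose": naive_means,
        },
    )


def simulate_dose_response(
    cfg: DoseResponseSimConfig,
) -> tuple[TrialDataset, OracleTruth]:
    cfg.validate()
    rng_u, rng_n = _streams(cfg.seed, 2)
    U = rng_u.random((cfg.n, 2))           # dose assignment, expectancy
    N = rng_n.standard_normal((cfg.n, 2))  # covariate, outcome noise
    doses = np.asarray(cfg.dose_levels)
    dose = doses[(U[:, 0] * len(doses)).astype(int).clip(0, len(doses) - 1)]
    p_e = cfg.e_intercept + cfg.alpha_d * dose
    E = (U[:, 1] < p_e).astype(int)
    X = N[:, 0]
    Y = cfg.gamma_d * dose + cfg.gamma_E * E + cfg.beta_X * X + cfg.sigma_Y * N[:, 1]
    df = pd.DataFrame(
        {
            "subject_id": np.arange(cfg.n),
            "x_base": X,
            "dose": dose,
            "E": E,
            "Y": Y,
        }
    )
    schema = TrialSchema(
        treatment="dose",
        expectancy="E",
        outcome="Y",
        covariates=("x_base",),
        subject="subject_id",
        treatment_is_dose=True,
    )
    return TrialDataset(df, schema), dose_oracle(cfg)


# ---------------------------------------------------------------------------
# Sequential / MSM world
# ---------------------------------------------------------------------------

REGIMES: tuple[tuple[tuple[int, int], tuple[int, int]], ...] = tuple(
    ((a1, m1), (a2, m2))
    for a1 in (0, 1)
    for m1 in (0, 1)
    for a2 in (0, 1)
    for m2 in (0, 1)
)

#: the four sequential-regime estimands: (regime_1, regime_0)
SEQUENTIAL_CONTRASTS: dict[str, tuple] = {
    # treatment vs control at both timepoints, message fixed on everywhere
    "cde_style": (((1, 1), (1, 1)), ((0, 1), (0, 1))),
    # early vs late single treatment: durability of the treatment effect
    "time_dependency": (((1, 0), (0, 0)), ((0, 0), (1, 0))),
    # message vs no-message among the twice-treated
    "expectancy_manipulation": (((1, 1), (1, 1)), ((1, 0), (1, 0))),
    # two treatments vs one
    "number_of_treatments": (((1, 0), (1, 0)), ((1, 0), (0, 0))),
}


@dataclass
class SequentialSimConfig:
    """Two-timepoint trial randomizing treatment and message at each step.

    Expectancy is binary with a logistic response to the message, the
    treatment and (through ``feedback_strength``) the previous outcome.
    The outcome accumulates a decaying treatment contribution plus the
    current expectancy effect.  All 16 (A1,M1,A2,M2) regimes are realized.
    """

    n: int = 2000
    message_effect: float = 1.0        # M_t on the expectancy log-odds
    treatment_effect: float = 3.0      # A_t on the outcome
    expectancy_effect: float = 1.5     # E_t on the outcome
    carryover_decay: float = 0.6       # retention of the prior A contribution
    feedback_strength: float = 0.5     # (Y_{t-1} - baseline) on E_t log-odds
    treatment_on_expectancy: float = 1.0  # A_t on the expectancy log-odds
    e_intercept: float = 0.0
    y_intercept: float = 0.0
    sigma_Y: float = 1.0
    p_treat: float = 0.5
    p_message: float = 0.5
    seed: int = 0
    oracle_mc_reps: int = 200_000

    def validate(self) -> None:
        if self.n < 1:
            raise ConfigError("n must be >= 1")
        if not (0.0 < self.carryover_decay <= 1.0):
            raise ConfigError("carryover_decay must lie in (0, 1]")
        if self.sigma_Y <= 0:
            raise ConfigError("sigma_Y must be > 0")
        _check_prob(self.p_treat, "p_treat")
        _check_prob(self.p_message, "p_message")


def _sequential_outcomes(
    cfg: SequentialSimConfig,
    a1: np.ndarray,
    m1: np.ndarray,
    a2: np.ndarray,
    m2: np.ndarray,
    UE: np.ndarray,
    NY: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Generating equations given assignments and shared noise draws."""
    e1_logit = (
        cfg.e_intercept
        + cfg.message_effect * m1
        + cfg.treatment_on_expectancy * a1
    )
    E1 = (UE[:, 0] < expit(e1_logit)).astype(int)
    Y1 = (
        cfg.y_intercept
        + cfg.treatment_effect * a1
        + cfg.expectancy_effect * E1
        + cfg.sigma_Y * NY[:, 0]
    )
    e2_logit = (
        cfg.e_intercept
        + cfg.message_effect * m2
        + cfg.treatment_on_expectancy * a2
        + cfg.feedback_strength * (Y1 - cfg.y_intercept)
    )
    E2 = (UE[:, 1] < expit(e2_logit)).astype(int)
    Y2 = (
        cfg.y_intercept
        + cfg.carryover_decay * cfg.treatment_effect * a1
        + cfg.treatment_effect * a2
        + cfg.expectancy_effect * E2
        + cfg.sigma_Y * NY[:, 1]
    )
    return E1, Y1, E2, Y2


def sequential_oracle(cfg: SequentialSimConfig) -> OracleTruth:
    """Counterfactual Monte Carlo over all 16 regimes.

    Every regime is evaluated on the same noise draws (common random
    numbers), so a zero-effect configuration yields *exactly* equal regime
    means and regime contrasts carry far less Monte-Carlo error than the
    individual means.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7_002]))
    N = cfg.oracle_mc_reps
    UE = rng.random((N, 2))
    NY = rng.standard_normal((N, 2))
    ones = np.ones(N)
    means: dict[tuple, float] = {}
    for regime in REGIMES:
        (a1, m1), (a2, m2) = regime
        _, _, _, Y2 = _sequential_outcomes(
            cfg, a1 * ones, m1 * ones, a2 * ones, m2 * ones, UE, NY
        )
        means[regime] = float(Y2.mean())
    contrasts = {
        name: means[r1] - means[r0]
        for name, (r1, r0) in SEQUENTIAL_CONTRASTS.items()
    }
    # ATE of the final-period treatment with everything else randomized
    UA = rng.random((N, 3))  # a1, m1, m2 assignment draws
    a1_draw = (UA[:, 0] < cfg.p_treat).astype(float)
    m1_draw = (UA[:, 1] < cfg.p_message).astype(float)
    m2_draw = (UA[:, 2] < cfg.p_message).astype(float)
    _, _, _, y_a2_1 = _sequential_outcomes(cfg, a1_draw, m1_draw, ones, m2_draw, UE, NY)
    _, _, _, y_a2_0 = _sequential_outcomes(
        cfg, a1_draw, m1_draw, 0 * ones, m2_draw, UE, NY
    )
    return OracleTruth(
        true_ATE=float((y_a2_1 - y_a2_0).mean()),
        # flattened final-period CDE: Y2 is linear in (A2, E2), so fixing E2
        # makes the contrast exactly the per-period treatment effect
        true_CDE={0: cfg.treatment_effect, 1: cfg.treatment_effect},
        true_tfCDE={
            (0, (1, 0)): cfg.expectancy_effect,
            (1, (1, 0)): cfg.expectancy_effect,
        },
        regime_means=means,
        method="monte_carlo_counterfactual",
        mc_reps=N,
        extras={"contrasts": contrasts},
    )


def simulate_sequential(
    cfg: SequentialSimConfig,
) -> tuple[LongitudinalDataset, OracleTruth]:
    cfg.validate()
    rng_a, rng_e, rng_y = _streams(cfg.seed, 3)
    UA = rng_a.random((cfg.n, 4))  # A1, M1, A2, M2
    UE = rng_e.random((cfg.n, 2))
    NY = rng_y.standard_normal((cfg.n, 2))
    A1 = (UA[:, 0] < cfg.p_treat).astype(int)
    M1 = (UA[:, 1] < cfg.p_message).astype(int)
    A2 = (UA[:, 2] < cfg.p_treat).astype(int)
    M2 = (UA[:, 3] < cfg.p_message).astype(int)
    E1, Y1, E2, Y2 = _sequential_outcomes(cfg, A1, M1, A2, M2, UE, NY)
    df = pd.DataFrame(
        {
            "subject_id": np.repeat(np.arange(cfg.n), 2),
            "t": np.tile([1, 2], cfg.n),
            "A": np.column_stack([A1, A2]).ravel(),
            "M": np.column_stack([M1, M2]).ravel(),
            "E": np.column_stack([E1, E2]).ravel(),
            "Y": np.column_stack([Y1, Y2]).ravel(),
        }
    )
    schema = LongitudinalSchema(
        subject="subject_id",
        time="t",
        treatment="A",
        outcome="Y",
        expectancy="E",
        message="M",
    )
    return LongitudinalDataset(df, schema), sequential_oracle(cfg)
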