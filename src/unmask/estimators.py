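"""Estimators for unmasking-aware causal contrasts.

Honest estimators
-----------------
* :func:`estimate_ate` — difference in arm means, the randomized-trial ATE.
* :func:`estimate_cde_gcomp` / :func:`estimate_cde_ipw` /
  :func:`estimate_cde_dr` — the controlled direct effect
  E[Y(a1, e) − Y(a0, e)] by sequential-regression g-computation, inverse
  probability weighting, and the doubly-robust influence-function
  estimator.  On saturated discrete data the three coincide exactly.
* :func:`estimate_tfcde` — the treatment-fixed CDE of expectancy
  E[Y(a, e1) − Y(a, e0)], through any of the three engines.
* :func:`estimate_msm` — regime contrasts in sequentially randomized
  designs via stabilized inverse-probability-weighted regime means.

Critiqued baselines (labelled ``BIASED_DEMO``)
----------------------------------------------
* :func:`estimate_stratified_naive` — within-belief (or within-expectancy)
  arm contrasts; conditioning on a post-treatment collider, the analysis
  that can make a beneficial treatment look harmful.
* :func:`estimate_rebalanced_naive` — reweighting each arm to the pooled
  expectancy distribution; balances the *sample* but not the individual
  level confounding, and can likewise reverse the sign of the direct
  effect.

No estimator ever reads simulator ground truth.  The honest CDE engines
fix an expectancy level only through the g-formula machinery — never by
subsetting on E alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .nuisance import LearnerSpec, NuisanceSet, fit_nuisances
from .trial_data import (
    EffectEstimate,
    EstimandSpec,
    LongitudinalDataset,
    TrialDataset,
)

__all__ = [
    "EstimationError",
    "estimate_ate",
    "estimate_stratified_naive",
    "estimate_rebalanced_naive",
    "estimate_cde_gcomp",
    "estimate_cde_ipw",
    "estimate_cde_dr",
    "estimate_tfcde",
    "MSMWeightSet",
    "compute_msm_weights",
    "estimate_msm",
]


class EstimationError(RuntimeError):
    pass


_BIAS_BANNER = (
    "BIASED_DEMO estimator: this method conditions on a post-treatment "
    "variable without g-formula adjustment and is included only to "
    "demonstrate its bias; do not interpret its output causally."
)


# ---------------------------------------------------------------------------
# ATE and the critiqued baselines
# ---------------------------------------------------------------------------


def _arm_mask(data: TrialDataset, a: float) -> np.ndarray:
    m = data.A == a
    if not m.any():
        raise EstimationError(f"no subjects in arm A={a}")
    return m


def estimate_ate(
    data: TrialDataset, a1: float = 1, a0: float = 0
) -> EffectEstimate:
    """Difference in arm means with a Welch standard error."""
    y1 = data.Y[_arm_mask(data, a1)]
    y0 = data.Y[_arm_mask(data, a0)]
    point = y1.mean() - y0.mean()
    se = float(np.sqrt(y1.var(ddof=1) / len(y1) + y0.var(ddof=1) / len(y0))) \
        if min(len(y1), len(y0)) > 1 else 0.0
    return EffectEstimate.from_point_se(
        point, se, "ate", len(y1) + len(y0),
        diagnostics={"n_a1": len(y1), "n_a0": len(y0)},
    )


def estimate_stratified_naive(
    data: TrialDataset,
    stratum_role: str = "belief",
    a1: float = 1,
    a0: float = 0,
) -> dict[float, EffectEstimate | None]:
    """Arm contrasts within strata of a post-treatment variable.

    This deliberately reproduces the flawed belief-stratified analysis; a
    stratum with an empty arm is reported as ``None`` (undefined).
    """
    warnings.warn(_BIAS_BANNER, UserWarning, stacklevel=2)
    if stratum_role == "belief":
        S = data.B
    elif stratum_role == "expectancy":
        S = data.E
    else:
        raise ValueError("stratum_role must be 'belief' or 'expectancy'")
    out: dict[float, EffectEstimate | None] = {}
    for s in sorted(np.unique(S)):
        m = S == s
        y1 = data.Y[m & (data.A == a1)]
        y0 = data.Y[m & (data.A == a0)]
        if len(y1) == 0 or len(y0) == 0:
            out[float(s)] = None
            continue
        point = y1.mean() - y0.mean()
        se = float(
            np.sqrt(y1.var(ddof=1) / len(y1) + y0.var(ddof=1) / len(y0))
        ) if min(len(y1), len(y0)) > 1 else 0.0
        out[float(s)] = EffectEstimate.from_point_se(
            point, se, "stratified_naive[BIASED_DEMO]", len(y1) + len(y0),
            diagnostics={"stratum": float(s)},
        )
    return out


def estimate_rebalanced_naive(
    data: TrialDataset, a1: float = 1, a0: float = 0
) -> EffectEstimate:
    """Arm contrast after post-stratification weights p_pool(E) / p_arm(E).

    The weights force the empirical expectancy distribution of each arm to
    the pooled one; sample-level balance does not remove individual-level
    confounding of the E→Y path, hence the demonstrated sign reversals.
    """
    warnings.warn(_BIAS_BANNER, UserWarning, stacklevel=2)
    A, E, Y = data.A, data.E, data.Y
    use = (A == a1) | (A == a0)
    A, E, Y = A[use], E[use], Y[use]
    levels = np.unique(E)
    p_pool = {e: np.mean(E == e) for e in levels}
    w = np.empty(len(E))
    for a in (a1, a0):
        in_arm = A == a
        if not in_arm.any():
            raise EstimationError(f"no subjects in arm A={a}")
        for e in levels:
            cell = in_arm & (E == e)
            p_arm = cell.sum() / in_arm.sum()
            if p_pool[e] > 0 and p_arm == 0:
                raise EstimationError(
                    f"arm A={a} has no mass at expectancy level E={e}; "
                    "rebalancing weights are undefined"
                )
            if p_arm > 0:
                w[cell] = p_pool[e] / p_arm

    def _wmean_se(mask):
        ww, yy = w[mask], Y[mask]
        mean = np.sum(ww * yy) / np.sum(ww)
        var = np.sum(ww**2 * (yy - mean) ** 2) / np.sum(ww) ** 2
        return mean, var

    m1, v1 = _wmean_se(A == a1)
    m0, v0 = _wmean_se(A == a0)
    return EffectEstimate.from_point_se(
        m1 - m0, float(np.sqrt(v1 + v0)), "rebalanced_naive[BIASED_DEMO]",
        int(use.sum()),
        diagnostics={"weight_mean": float(w.mean())},
    )


# ---------------------------------------------------------------------------
# CDE engines
# ---------------------------------------------------------------------------


def _psi_gcomp(nuis: NuisanceSet, a: float, e: float) -> float:
    return float(np.mean(nuis.eta[(a, e)]))


def _psi_ipw(
    data: TrialDataset, nuis: NuisanceSet, a: float, e: float, hajek: bool
) -> float:
    ind = (data.A == a) & (data.E == e)
    if not ind.any():
        raise EstimationError(
            f"no subjects observed at (A={a}, E={e}): positivity violated"
        )
    denom = nuis.p_a[a] * nuis.pi_e_obs[e]
    w = np.where(ind, 1.0 / denom, 0.0)
    if w.sum() == 0:
        raise EstimationError(
            f"all weights zero in cell (A={a}, E={e}): positivity violated"
        )
    if hajek:
        return float(np.sum(w * data.Y) / np.sum(w))
    return float(np.mean(w * data.Y))


def _dr_contributions(
    data: TrialDataset, nuis: NuisanceSet, a: float, e: float
) -> np.ndarray:
    """Per-subject influence-function contributions for psi(a, e)."""
    ind_a = (data.A == a).astype(float)
    ind_ae = ind_a * (data.E == e).astype(float)
    p_a = nuis.p_a[a]
    pi_e = nuis.pi_e_obs[e]
    mu = nuis.mu[(a, e)]
    eta = nuis.eta[(a, e)]
    return (
        ind_ae / (p_a * pi_e) * (data.Y - mu)
        + ind_a / p_a * (mu - eta)
        + eta
    )


def _resolve_nuisances(data, spec, nuisances, learners, known_treatment_probs,
                       delta, seed):
    if nuisances is not None:
        return nuisances, learners
    learners = learners or LearnerSpec()
    return (
        fit_nuisances(
            data, spec, learners,
            known_treatment_probs=known_treatment_probs,
            delta=delta, seed=seed,
        ),
        learners,
    )


def _cde_pair(spec: EstimandSpec) -> tuple[tuple[float, float], tuple[float, float]]:
    if spec.kind != "CDE":
        raise ValueError(f"expected a CDE estimand, got kind={spec.kind}")
    return (float(spec.a1), float(spec.e)), (float(spec.a0), float(spec.e))


def _bootstrap_se(
    data: TrialDataset,
    spec: EstimandSpec,
    point_fn,
    learners: LearnerSpec,
    known_treatment_probs,
    delta: float,
    n_boot: int,
    seed: int,
) -> float:
    """Nonparametric bootstrap refitting the nuisances on every resample."""
    if n_boot <= 0:
        return 0.0
    rng = np.random.default_rng(seed)
    points = []
    for b in range(n_boot):
        idx = rng.integers(0, data.n, size=data.n)
        boot = TrialDataset(
            data.df.iloc[idx].reset_index(drop=True), data.schema,
            supports=dict(data.supports),
        )
        try:
            nuis = fit_nuisances(
                boot, spec, learners,
                known_treatment_probs=known_treatment_probs,
                delta=delta, seed=seed + 1 + b,
            )
            points.append(point_fn(boot, nuis))
        except Exception:
            continue  # degenerate resample (e.g. empty cell): drop it
    if len(points) < 2:
        return 0.0
    return float(np.std(points, ddof=1))


def estimate_cde_gcomp(
    data: TrialDataset,
    spec: EstimandSpec,
    nuisances: NuisanceSet | None = None,
    learners: LearnerSpec | None = None,
    known_treatment_probs=None,
    delta: float = 0.01,
    n_boot: int = 500,
    seed: int = 0,
) -> EffectEstimate:
    """Sequential-regression g-computation of the CDE.

    psi(a, e) is the sample mean of eta(X, a), the within-arm projection of
    the outcome regression mu(X, a, Z, e); the estimate contrasts the two
    arms at the fixed level e.  SE by nonparametric bootstrap (``n_boot``
    resamples; 0 skips the bootstrap and reports se=0).
    """
    nuisances, learners = _resolve_nuisances(
        data, spec, nuisances, learners, known_treatment_probs, delta, seed
    )
    (c1, c0) = _cde_pair(spec)

    def point_fn(d, nuis):
        return _psi_gcomp(nuis, *c1) - _psi_gcomp(nuis, *c0)

    point = point_fn(data, nuisances)
    se = _bootstrap_se(
        data, spec, point_fn, learners or LearnerSpec(),
        known_treatment_probs, delta, n_boot, seed,
    )
    return EffectEstimate.from_point_se(
        point, se, "cde_gcomp", data.n,
        diagnostics={**nuisances.diagnostics, "n_boot": n_boot},
    )


def estimate_cde_ipw(
    data: TrialDataset,
    spec: EstimandSpec,
    nuisances: NuisanceSet | None = None,
    learners: LearnerSpec | None = None,
    known_treatment_probs=None,
    delta: float = 0.01,
    hajek: bool = True,
    n_boot: int = 500,
    seed: int = 0,
) -> EffectEstimate:
    """Inverse-probability-weighted CDE.

    Weights 1 / (P(A=a|X) · P(E=e|X,A,Z)) on the subjects observed at the
    intervention levels; Hájek-normalized by default, Horvitz–Thompson with
    ``hajek=False`` (the variant that coincides with g-computation on
    saturated discrete data).
    """
    nuisances, learners = _resolve_nuisances(
        data, spec, nuisances, learners, known_treatment_probs, delta, seed
    )
    (c1, c0) = _cde_pair(spec)

    def point_fn(d, nuis):
        return _psi_ipw(d, nuis, *c1, hajek) - _psi_ipw(d, nuis, *c0, hajek)

    point = point_fn(data, nuisances)
    se = _bootstrap_se(
        data, spec, point_fn, learners or LearnerSpec(),
        known_treatment_probs, delta, n_boot, seed,
    )
    return EffectEstimate.from_point_se(
        point, se, "cde_ipw_hajek" if hajek else "cde_ipw_ht", data.n,
        diagnostics={**nuisances.diagnostics, "n_boot": n_boot},
    )


def estimate_cde_dr(
    data: TrialDataset,
    spec: EstimandSpec,
    nuisances: NuisanceSet | None = None,
    learners: LearnerSpec | None = None,
    known_treatment_probs=None,
    delta: float = 0.01,
    seed: int = 0,
) -> EffectEstimate:
    """Doubly-robust (influence-function) CDE with cross-fit CLT SEs.

    Consistent if either the outcome regressions (mu, eta) or the
    propensities (pi_E and the arm probability) are correct.  The SE is the
    empirical standard deviation of the per-subject contribution contrasts
    over sqrt(n).
    """
    nuisances, _ = _resolve_nuisances(
        data, spec, nuisances, learners, known_treatment_probs, delta, seed
    )
    (c1, c0) = _cde_pair(spec)
    contrib = _dr_contributions(data, nuisances, *c1) - _dr_contributions(
        data, nuisances, *c0
    )
    point = float(contrib.mean())
    se = float(contrib.std(ddof=1) / np.sqrt(data.n)) if data.n > 1 else 0.0
    return EffectEstimate.from_point_se(
        point, se, "cde_dr", data.n, diagnostics=dict(nuisances.diagnostics)
    )


def estimate_tfcde(
    data: TrialDataset,
    spec: EstimandSpec,
    nuisances: NuisanceSet | None = None,
    learners: LearnerSpec | None = None,
    known_treatment_probs=None,
    delta: float = 0.01,
    engine: str = "dr",
    n_boot: int = 500,
    seed: int = 0,
) -> EffectEstimate:
    """Treatment-fixed CDE of expectancy: psi(a, e1) − psi(a, e0)."""
    if spec.kind != "tfCDE":
        raise ValueError(f"expected a tfCDE estimand, got kind={spec.kind}")
    a, e1, e0 = float(spec.a), float(spec.e1), float(spec.e0)
    if e1 == e0:
        return EffectEstimate.from_point_se(
            0.0, 0.0, f"tfcde_{engine}", data.n,
            diagnostics={"note": "e1 == e0: contrast is identically zero"},
        )
    nuisances, learners = _resolve_nuisances(
        data, spec, nuisances, learners, known_treatment_probs, delta, seed
    )
    if engine == "gcomp":
        def point_fn(d, nuis):
            return _psi_gcomp(nuis, a, e1) - _psi_gcomp(nuis, a, e0)
    elif engine == "ipw":
        def point_fn(d, nuis):
            return _psi_ipw(d, nuis, a, e1, True) - _psi_ipw(d, nuis, a, e0, True)
    elif engine == "dr":
        contrib = _dr_contributions(data, nuisances, a, e1) - _dr_contributions(
            data, nuisances, a, e0
        )
        return EffectEstimate.from_point_se(
            float(contrib.mean()),
            float(contrib.std(ddof=1) / np.sqrt(data.n)) if data.n > 1 else 0.0,
            "tfcde_dr", data.n, diagnostics=dict(nuisances.diagnostics),
        )
    else:
        raise ValueError("engine must be one of 'gcomp', 'ipw', 'dr'")
    point = point_fn(data, nuisances)
    se = _bootstrap_se(
        data, spec, point_fn, learners or LearnerSpec(),
        known_treatment_probs, delta, n_boot, seed,
    )
    return EffectEstimate.from_point_se(
        point, se, f"tfcde_{engine}", data.n,
        diagnostics=dict(nuisances.diagnostics),
    )


# ---------------------------------------------------------------------------
# Marginal structural models for sequential regimes
# ---------------------------------------------------------------------------


@dataclass
class MSMWeightSet:
    """Per-subject stabilized weights for a sequentially randomized design.

    The weight is the product over timepoints of
    P(A_t, M_t | assignment history) / P(A_t, M_t | full history incl.
    expectancy and outcomes).  Under marginal randomization both factors
    coincide and every weight is exactly 1.
    """

    subjects: np.ndarray
    weights: np.ndarray
    truncation_quantile: float | None
    diagnostics: dict[str, Any] = field(default_factory=dict)

    @property
    def effective_sample_size(self) -> float:
        w = self.weights
        return float(w.sum() ** 2 / np.sum(w**2))


def _fit_binary_prob(F: np.ndarray, y: np.ndarray) -> np.ndarray:
    """P(y_i = observed value | F_i) from a logistic fit (marginal if F empty
    or y degenerate)."""
    if len(np.unique(y)) < 2:
        p1 = float(np.mean(y))
        p1 = min(max(p1, 1e-12), 1 - 1e-12)
        return np.where(y == 1, p1, 1 - p1)
    if F.shape[1] == 0:
        p1 = float(np.mean(y))
        return np.where(y == 1, p1, 1 - p1)
    model = LogisticRegression(max_iter=2000)
    model.fit(F, y)
    p1 = model.predict_proba(F)[:, np.flatnonzero(model.classes_ == 1)[0]]
    return np.where(y == 1, p1, 1 - p1)


def compute_msm_weights(
    ldata: LongitudinalDataset,
    randomized_probs: Mapping[str, float] | None = None,
    truncation_quantile: float | None = 0.99,
    mean_tolerance: float = 0.1,
) -> MSMWeightSet:
    """Stabilized weights for every subject's observed regime.

    If the design is known to randomize marginally, pass
    ``randomized_probs={"treatment": p, "message": q}`` and the stabilized
    weights are identically 1.  Otherwise logistic models are fit per
    timepoint: numerator conditional on the assignment history only,
    denominator additionally on expectancy/outcome history (the
    response-conditional randomization case).
    """
    s = ldata.schema
    times = ldata.timepoints
    wideA = ldata.wide(s.treatment)
    wideM = ldata.wide(s.message) if s.message is not None else None
    wideE = ldata.wide(s.expectancy) if s.expectancy is not None else None
    wideY = ldata.wide(s.outcome)
    subjects = wideA.index.to_numpy()
    n = len(subjects)
    diag: dict[str, Any] = {}

    if randomized_probs is not None:
        w = np.ones(n)
        diag["mode"] = "known_randomization"
    else:
        diag["mode"] = "fitted"
        log_w = np.zeros(n)
        for j, t in enumerate(times):
            hist_assign, hist_full = [], []
            for tp in times[:j]:
                hist_assign.append(wideA[tp].to_numpy(dtype=float))
                if wideM is not None:
                    hist_assign.append(wideM[tp].to_numpy(dtype=float))
                hist_full.append(wideY[tp].to_numpy(dtype=float))
                if wideE is not None:
                    hist_full.append(wideE[tp].to_numpy(dtype=float))
            F_num = np.column_stack(hist_assign) if hist_assign else np.empty((n, 0))
            F_den = (
                np.column_stack(hist_assign + hist_full)
                if (hist_assign or hist_full)
                else np.empty((n, 0))
            )
            for wide in (wideA, wideM):
                if wide is None:
                    continue
                y = wide[t].to_numpy(dtype=int)
                num = _fit_binary_prob(F_num, y)
                den = _fit_binary_prob(F_den, y)
                log_w += np.log(num) - np.log(den)
        w = np.exp(log_w)

    if truncation_quantile is not None and len(w):
        cap = np.quantile(w, truncation_quantile)
        diag["truncation_fraction"] = float(np.mean(w > cap))
        w = np.minimum(w, cap)
    diag["mean_weight"] = float(w.mean())
    if abs(diag["mean_weight"] - 1.0) > mean_tolerance:
        diag["mean_weight_flag"] = (
            f"stabilized-weight mean {diag['mean_weight']:.3f} deviates from 1 "
            f"by more than {mean_tolerance}"
        )
    return MSMWeightSet(subjects, w, truncation_quantile, diag)


def estimate_msm(
    ldata: LongitudinalDataset,
    regime_1: tuple,
    regime_0: tuple,
    weights: MSMWeightSet | None = None,
) -> EffectEstimate:
    """Contrast of weighted final-outcome means between two exact regimes.

    A regime is the full assignment sequence ((A_1, M_1), ..., (A_T, M_T));
    only subjects whose observed sequence matches exactly contribute.
    """
    if weights is None:
        weights = compute_msm_weights(ldata)
    s = ldata.schema
    regs = ldata.regimes()
    final_t = ldata.timepoints[-1]
    yT = ldata.wide(s.outcome)[final_t]
    wmap = pd.Series(weights.weights, index=weights.subjects)

    def _regime_mean(regime):
        regime = tuple((int(a), int(m)) for a, m in regime)
        mask = regs["regime"] == regime
        if not mask.any():
            raise EstimationError(
                f"no subjects follow regime {regime}: positivity violated"
            )
        idx = regs.index[mask]
        ww = wmap.loc[idx].to_numpy()
        yy = yT.loc[idx].to_numpy(dtype=float)
        mean = np.sum(ww * yy) / np.sum(ww)
        var = np.sum(ww**2 * (yy - mean) ** 2) / np.sum(ww) ** 2
        return mean, var, int(mask.sum())

    m1, v1, n1 = _regime_mean(regime_1)
    m0, v0, n0 = _regime_mean(regime_0)
    return EffectEstimate.from_point_se(
        m1 - m0, float(np.sqrt(v1 + v0)), "msm", n1 + n0,
        diagnostics={
            **weights.diagnostics,
            "n_regime_1": n1,
            "n_regime_0": n0,
            "effective_sample_size": weights.effective_sample_size,
        },
    )
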