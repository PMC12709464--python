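"""Cross-fitted nuisance functions for controlled-direct-effect estimation.

The CDE/tfCDE estimators consume four nuisance functions:

* ``p_a(x)``        — treatment propensity P(A = a | X), or the known
                      randomization probability in a designed trial;
* ``pi_e(x, a, z)`` — expectancy propensity P(E = e | X, A, Z), the model
                      for the "as good as randomized" intermediate;
* ``mu(x, a, z, e)``— outcome regression E[Y | X, A=a, Z, E=e];
* ``eta(x, a)``     — the sequential-regression projection
                      E[mu(X, a, Z, e) | X = x, A = a].

All are fit with interchangeable scikit-learn style learners and, by
default, K-fold cross-fitting: a subject's predictions come only from
models trained on folds that exclude that subject.  ``n_folds=1`` disables
splitting and fits every model on the full sample; this mode exists for
saturated discrete problems where the three CDE estimators coincide
algebraically (the identity requires in-sample empirical frequencies).

Probability outputs are clipped to ``[delta, 1 - delta]`` and the clipping
is reported, never silent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
from sklearn.ensemble import HistGradientBoostingClassifier, HistGradientBoostingRegressor
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor

from .trial_data import EstimandSpec, TrialDataset

__all__ = ["LearnerSpec", "NuisanceSet", "fit_nuisances"]


class NuisanceError(RuntimeError):
    """A nuisance model could not be fit under the requested configuration."""


# ---------------------------------------------------------------------------
# Learners
# ---------------------------------------------------------------------------


class _ConstantRegressor:
    """Mean-only model; the fallback when no features are available."""

    def fit(self, F, y):
        self.mean_ = float(np.mean(y))
        return self

    def predict(self, F):
        return np.full(len(F), self.mean_)


class _ConstantClassifier:
    def fit(self, F, y):
        self.classes_, counts = np.unique(y, return_counts=True)
        self.proba_ = counts / counts.sum()
        return self

    def predict_proba(self, F):
        return np.tile(self.proba_, (len(F), 1))


class CellMeanRegressor:
    """Saturated regressor over discrete feature tuples (cell means)."""

    def fit(self, F, y):
        F = np.asarray(F)
        y = np.asarray(y, dtype=float)
        self.global_mean_ = float(y.mean())
        self.table_ = {}
        sums: dict[tuple, list] = {}
        for row, val in zip(map(tuple, F), y):
            s = sums.setdefault(row, [0.0, 0])
            s[0] += val
            s[1] += 1
        self.table_ = {k: v[0] / v[1] for k, v in sums.items()}
        return self

    def predict(self, F):
        return np.array(
            [self.table_.get(tuple(row), self.global_mean_) for row in np.asarray(F)]
        )


class CellFrequencyClassifier:
    """Saturated classifier: empirical class frequencies within each cell."""

    def fit(self, F, y):
        F = np.asarray(F)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        k = len(self.classes_)
        cls_index = {c: j for j, c in enumerate(self.classes_)}
        counts: dict[tuple, np.ndarray] = {}
        for row, val in zip(map(tuple, F), y):
            counts.setdefault(row, np.zeros(k))[cls_index[val]] += 1
        self.table_ = {key: c / c.sum() for key, c in counts.items()}
        _, mc = np.unique(y, return_counts=True)
        self.marginal_ = mc / mc.sum()
        return self

    def predict_proba(self, F):
        return np.vstack(
            [self.table_.get(tuple(row), self.marginal_) for row in np.asarray(F)]
        )


@dataclass(frozen=True)
class LearnerSpec:
    """Which learner family fits the nuisances, and how to cross-fit.

    ``family`` is one of ``auto`` (linear below n=1000, gradient boosting
    above), ``linear``, ``gbm``, ``knn`` or ``saturated``; classification
    problems use the family's probabilistic counterpart.  ``mu_features``
    restricts the blocks entering the outcome regressions (subset of
    {"X", "Z"}); dropping "Z" deliberately misspecifies mu, which the
    double-robustness tests exploit.
    """

    family: str = "auto"
    params: Mapping[str, Any] = field(default_factory=dict)
    n_folds: int = 5
    mu_features: tuple[str, ...] = ("X", "Z")

    def resolve(self, n: int) -> str:
        if self.family != "auto":
            return self.family
        return "linear" if n < 1000 else "gbm"


def _make_regressor(family: str, params: Mapping, n_features: int, seed: int):
    if n_features == 0:
        return _ConstantRegressor()
    if family == "linear":
        return LinearRegression(**dict(params))
    if family == "gbm":
        return HistGradientBoostingRegressor(random_state=seed, **dict(params))
    if family == "knn":
        return KNeighborsRegressor(**dict(params))
    if family == "saturated":
        return CellMeanRegressor()
    raise ValueError(f"unknown learner family {family!r}")


def _make_classifier(family: str, params: Mapping, n_features: int, seed: int):
    if n_features == 0:
        return _ConstantClassifier()
    if family == "linear":
        return LogisticRegression(max_iter=2000, **dict(params))
    if family == "gbm":
        return HistGradientBoostingClassifier(random_state=seed, **dict(params))
    if family == "knn":
        return KNeighborsClassifier(**dict(params))
    if family == "saturated":
        return CellFrequencyClassifier()
    raise ValueError(f"unknown learner family {family!r}")


def _proba_for(model, F: np.ndarray, level: float) -> np.ndarray:
    """P(class == level) from a fitted classifier, 0 if level unseen."""
    proba = model.predict_proba(F)
    classes = np.asarray(model.classes_, dtype=float)
    matches = np.flatnonzero(np.isclose(classes, level))
    if len(matches) == 0:
        return np.zeros(len(F))
    return proba[:, matches[0]]


# ---------------------------------------------------------------------------
# NuisanceSet
# ---------------------------------------------------------------------------


@dataclass
class NuisanceSet:
    """Per-subject cross-fitted nuisance predictions.

    ``p_a[a]`` is P(A = a | X_i); ``pi_e_obs[e]`` is P(E = e | X_i, A_i, Z_i)
    at the subject's *observed* treatment (that is the only place the
    estimators evaluate it); ``mu[(a, e)]`` and ``eta[(a, e)]`` are the
    outcome regressions evaluated at the intervention levels.
    """

    arms: tuple[float, ...]
    e_levels: tuple[float, ...]
    p_a: dict[float, np.ndarray]
    pi_e_obs: dict[float, np.ndarray]
    mu: dict[tuple[float, float], np.ndarray]
    eta: dict[tuple[float, float], np.ndarray]
    folds: np.ndarray
    delta: float
    diagnostics: dict[str, Any] = field(default_factory=dict)

    def replace_pi_e(self, value) -> "NuisanceSet":
        """Copy with the expectancy propensity overridden (misspecification
        experiments); ``value`` is a scalar or a dict level → array."""
        n = len(self.folds)
        if np.isscalar(value):
            new = {e: np.full(n, float(value)) for e in self.pi_e_obs}
        else:
            new = {e: np.asarray(v, dtype=float) for e, v in value.items()}
        return NuisanceSet(
            self.arms, self.e_levels, self.p_a, new, self.mu, self.eta,
            self.folds, self.delta,
            {**self.diagnostics, "pi_e_overridden": True},
        )


def _clip_record(p: np.ndarray, delta: float, diag: dict, name: str) -> np.ndarray:
    diag.setdefault("pre_clip_min", {})[name] = float(np.min(p)) if len(p) else np.nan
    diag.setdefault("pre_clip_max", {})[name] = float(np.max(p)) if len(p) else np.nan
    if delta <= 0:
        return p
    clipped = np.clip(p, delta, 1.0 - delta)
    diag.setdefault("clip_fraction", {})[name] = float(np.mean(clipped != p))
    return clipped


def fit_nuisances(
    data: TrialDataset,
    spec: EstimandSpec,
    learners: LearnerSpec | None = None,
    known_treatment_probs: Mapping[float, float] | float | None = None,
    delta: float = 0.01,
    seed: int = 0,
) -> NuisanceSet:
    """Fit the nuisance set for a CDE or tfCDE estimand.

    In a randomized trial pass ``known_treatment_probs`` (a scalar P(A=1)
    for binary treatment, or a map level → probability) to fix the
    treatment propensity at its design value instead of fitting it.
    """
    if learners is None:
        learners = LearnerSpec()
    if spec.kind == "CDE":
        arms = (float(spec.a1), float(spec.a0))
        e_levels = (float(spec.e),)
    elif spec.kind == "tfCDE":
        arms = (float(spec.a),)
        e_levels = (float(spec.e1), float(spec.e0))
    else:
        raise ValueError("nuisances are defined for CDE / tfCDE estimands")
    spec.check_supports(data)

    n = data.n
    family = learners.resolve(n)
    A, E, Y = data.A, data.E, data.Y
    X, Z = data.X, data.Z
    if np.ptp(Y) == 0:
        warnings.warn("outcome is constant; outcome regressions are degenerate")

    blocks = {"X": X, "Z": Z}
    mu_block = [blocks[b] for b in learners.mu_features if blocks[b].shape[1]]
    F_mu = np.hstack(mu_block) if mu_block else np.empty((n, 0))
    F_e = np.hstack([X, A[:, None], Z])

    n_folds = int(learners.n_folds)
    if n_folds < 1:
        raise ValueError("n_folds must be >= 1")
    if n_folds == 1:
        fold_pairs = [(np.arange(n), np.arange(n))]
        folds = np.zeros(n, dtype=int)
    else:
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        fold_pairs = list(kf.split(np.arange(n)))
        folds = np.empty(n, dtype=int)
        for k, (_, test) in enumerate(fold_pairs):
            folds[test] = k

    diag: dict[str, Any] = {"delta": delta, "n_folds": n_folds, "family": family}
    p_a = {a: np.empty(n) for a in arms}
    pi_e_obs = {e: np.empty(n) for e in e_levels}
    mu = {(a, e): np.empty(n) for a in arms for e in e_levels}
    eta = {(a, e): np.empty(n) for a in arms for e in e_levels}

    for k, (train, test) in enumerate(fold_pairs):
        # --- treatment propensity -------------------------------------
        if known_treatment_probs is not None:
            if np.isscalar(known_treatment_probs):
                probs = {1.0: float(known_treatment_probs),
                         0.0: 1.0 - float(known_treatment_probs)}
            else:
                probs = {float(kk): float(v) for kk, v in known_treatment_probs.items()}
            for a in arms:
                if a not in probs:
                    raise ValueError(f"known_treatment_probs lacks arm {a}")
                p_a[a][test] = probs[a]
        else:
            a_model = _make_classifier(family, learners.params, X.shape[1], seed + k)
            a_model.fit(X[train], A[train])
            for a in arms:
                p_a[a][test] = _proba_for(a_model, X[test], a)

        # --- expectancy propensity ------------------------------------
        if len(np.unique(E[train])) < 2:
            raise NuisanceError(
                f"expectancy has a single class in training fold {k}; "
                "use fewer folds or a coarser expectancy coding"
            )
        e_model = _make_classifier(family, learners.params, F_e.shape[1], seed + k)
        e_model.fit(F_e[train], E[train])
        for e in e_levels:
            pi_e_obs[e][test] = _proba_for(e_model, F_e[test], e)

        # --- outcome regressions and sequential projection -------------
        for a in arms:
            in_arm_train = train[A[train] == a]
            if len(in_arm_train) == 0:
                raise NuisanceError(f"no subjects with A={a} in training fold {k}")
            for e in e_levels:
                cell = in_arm_train[E[in_arm_train] == e]
                if len(cell) == 0:
                    raise NuisanceError(
                        f"empty training cell (A={a}, E={e}) in fold {k}: "
                        "positivity violated"
                    )
                mu_model = _make_regressor(
                    family, learners.params, F_mu.shape[1], seed + k
                )
                mu_model.fit(F_mu[cell], Y[cell])
                mu[(a, e)][test] = mu_model.predict(F_mu[test])
                # project mu onto X within arm a (over the training fold)
                mu_train_arm = mu_model.predict(F_mu[in_arm_train])
                eta_model = _make_regressor(
                    family, learners.params, X.shape[1], seed + k
                )
                eta_model.fit(X[in_arm_train], mu_train_arm)
                eta[(a, e)][test] = eta_model.predict(X[test])

    for a in arms:
        p_a[a] = _clip_record(p_a[a], delta, diag, f"p_a[{a}]")
    for e in e_levels:
        pi_e_obs[e] = _clip_record(pi_e_obs[e], delta, diag, f"pi_e[{e}]")

    return NuisanceSet(
        arms=arms,
        e_levels=e_levels,
        p_a=p_a,
        pi_e_obs=pi_e_obs,
        mu=mu,
        eta=eta,
        folds=folds,
        delta=delta,
        diagnostics=diag,
    )
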