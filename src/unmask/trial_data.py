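"""Domain types, schema'd readers/writers and validation for trial datasets.

A trial dataset is a plain table, one row per subject (cross-sectional) or
one row per subject-timepoint (longitudinal), together with an explicit
*schema* that maps causal roles to column names:

    covariates (X)        baseline, pre-treatment variables (hype, age, ...)
    treatment (A)         randomized assignment, binary or ordered dose
    belief (B)            post-treatment belief of having received treatment
    expectancy (E)        post-treatment expectancy level
    post_confounders (Z)  post-treatment common causes of E and Y
    outcome (Y)           follow-up outcome
    subject / time / message   bookkeeping and sequential-design roles

Roles are declared, never inferred from column names, and each column holds
exactly one role.  Missing values are rejected rather than imputed: the
methods here target trials with full follow-up and adherence.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SchemaError",
    "ValidationError",
    "TrialSchema",
    "TrialDataset",
    "LongitudinalSchema",
    "LongitudinalDataset",
    "EstimandSpec",
    "EffectEstimate",
    "PositivityReport",
    "read_trial",
    "write_trial",
    "read_longitudinal",
    "write_longitudinal",
    "validate_positivity_support",
    "flatten_two_period",
]


class SchemaError(ValueError):
    """A role is missing from the schema or maps to an absent column."""


class ValidationError(ValueError):
    """Data violate a declared invariant (missing values, bad supports)."""


# ---------------------------------------------------------------------------
# Schemas
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrialSchema:
    """Role → column mapping for a cross-sectional trial table."""

    treatment: str
    expectancy: str
    outcome: str
    covariates: tuple[str, ...] = ()
    post_confounders: tuple[str, ...] = ()
    belief: str | None = None
    subject: str | None = None
    #: when True the treatment column is an ordered dose level, not {0,1}
    treatment_is_dose: bool = False

    def __post_init__(self) -> None:
        cols = self.all_columns()
        dup = {c for c in cols if cols.count(c) > 1}
        if dup:
            raise SchemaError(
                f"columns assigned more than one role: {sorted(dup)}"
            )

    def all_columns(self) -> list[str]:
        cols = [self.treatment, self.expectancy, self.outcome]
        cols += list(self.covariates) + list(self.post_confounders)
        if self.belief is not None:
            cols.append(self.belief)
        if self.subject is not None:
            cols.append(self.subject)
        return cols

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "TrialSchema":
        """Build from a role map, e.g. loaded from YAML/JSON.

        Required roles: ``treatment``, ``expectancy``, ``outcome``.  List
        roles (``covariates``, ``post_confounders``) accept a string or a
        list of strings.
        """
        m = dict(mapping)
        for role in ("treatment", "expectancy", "outcome"):
            if role not in m or m[role] is None:
                raise SchemaError(f"schema missing required role {role!r}")

        def _tup(key: str) -> tuple[str, ...]:
            v = m.get(key, ())
            if v is None:
                return ()
            if isinstance(v, str):
                return (v,)
            return tuple(v)

        return cls(
            treatment=m["treatment"],
            expectancy=m["expectancy"],
            outcome=m["outcome"],
            covariates=_tup("covariates"),
            post_confounders=_tup("post_confounders"),
            belief=m.get("belief"),
            subject=m.get("subject"),
            treatment_is_dose=bool(m.get("treatment_is_dose", False)),
        )

    @classmethod
    def from_yaml(cls, path: str) -> "TrialSchema":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    def to_mapping(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["covariates"] = list(d["covariates"])
        d["post_confounders"] = list(d["post_confounders"])
        return d


@dataclass(frozen=True)
class LongitudinalSchema:
    """Role → column mapping for a subject × timepoint table."""

    subject: str
    time: str
    treatment: str
    outcome: str
    expectancy: str | None = None
    message: str | None = None
    covariates: tuple[str, ...] = ()

    def all_columns(self) -> list[str]:
        cols = [self.subject, self.time, self.treatment, self.outcome]
        if self.expectancy is not None:
            cols.append(self.expectancy)
        if self.message is not None:
            cols.append(self.message)
        cols += list(self.covariates)
        return cols

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "LongitudinalSchema":
        m = dict(mapping)
        for role in ("subject", "time", "treatment", "outcome"):
            if role not in m or m[role] is None:
                raise SchemaError(f"schema missing required role {role!r}")
        cov = m.get("covariates", ())
        if isinstance(cov, str):
            cov = (cov,)
        return cls(
            subject=m["subject"],
            time=m["time"],
            treatment=m["treatment"],
            outcome=m["outcome"],
            expectancy=m.get("expectancy"),
            message=m.get("message"),
            covariates=tuple(cov or ()),
        )


# ---------------------------------------------------------------------------
# Datasets
# ---------------------------------------------------------------------------


def _check_no_missing(df: pd.DataFrame, cols: Sequence[str]) -> None:
    sub = df[list(cols)]
    if sub.isna().any().any():
        bad = sub.isna().any(axis=1)
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"missing values found (first offending row index {row}); "
            "these methods assume no dropout and full adherence"
        )


def _check_binary(values: np.ndarray, name: str) -> None:
    uniq = set(np.unique(values).tolist())
    if not uniq <= {0, 1}:
        raise ValidationError(
            f"{name} must be binary in {{0,1}}, found values {sorted(uniq)}"
        )


@dataclass
class TrialDataset:
    """Validated cross-sectional trial data plus its role schema.

    ``supports`` records the observed level sets of treatment and
    expectancy; estimators consult it to check that requested intervention
    levels exist in the data.
    """

    df: pd.DataFrame
    schema: TrialSchema
    supports: dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in self.schema.all_columns() if c not in self.df.columns]
        if missing:
            raise SchemaError(f"schema names absent columns: {missing}")
        self.df = self.df.reset_index(drop=True)
        _check_no_missing(self.df, self.schema.all_columns())
        a = self.A
        if self.schema.treatment_is_dose:
            if not np.all(a == np.round(a)):
                raise ValidationError("dose levels must be integer-coded")
        else:
            _check_binary(a, f"treatment column {self.schema.treatment!r}")
        if self.schema.belief is not None and len(self.df):
            _check_binary(
                self.df[self.schema.belief].to_numpy(),
                f"belief column {self.schema.belief!r}",
            )
        if not self.supports:
            self.supports = {
                "treatment": sorted(np.unique(a).tolist()),
                "expectancy": sorted(np.unique(self.E).tolist()),
            }

    # -- array accessors ----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def A(self) -> np.ndarray:
        return self.df[self.schema.treatment].to_numpy(dtype=float)

    @property
    def E(self) -> np.ndarray:
        return self.df[self.schema.expectancy].to_numpy(dtype=float)

    @property
    def Y(self) -> np.ndarray:
        return self.df[self.schema.outcome].to_numpy(dtype=float)

    @property
    def B(self) -> np.ndarray:
        if self.schema.belief is None:
            raise SchemaError("no belief role declared in schema")
        return self.df[self.schema.belief].to_numpy(dtype=float)

    @property
    def X(self) -> np.ndarray:
        return self.df[list(self.schema.covariates)].to_numpy(dtype=float)

    @property
    def Z(self) -> np.ndarray:
        return self.df[list(self.schema.post_confounders)].to_numpy(dtype=float)

    def subset(self, mask: np.ndarray) -> "TrialDataset":
        return TrialDataset(self.df.loc[mask].reset_index(drop=True), self.schema)


@dataclass
class LongitudinalDataset:
    """Validated subject × timepoint trial data for sequential designs."""

    df: pd.DataFrame
    schema: LongitudinalSchema

    def __post_init__(self) -> None:
        missing = [c for c in self.schema.all_columns() if c not in self.df.columns]
        if missing:
            raise SchemaError(f"schema names absent columns: {missing}")
        self.df = self.df.sort_values(
            [self.schema.subject, self.schema.time]
        ).reset_index(drop=True)
        _check_no_missing(self.df, self.schema.all_columns())
        times = self.timepoints
        counts = self.df.groupby(self.schema.subject)[self.schema.time].apply(
            lambda s: tuple(s.tolist())
        )
        if len(counts) and not (counts == tuple(times)).all():
            raise ValidationError(
                "every subject must share the same ordered timepoints"
            )

    @property
    def timepoints(self) -> list:
        return sorted(self.df[self.schema.time].unique().tolist())

    @property
    def n_subjects(self) -> int:
        return self.df[self.schema.subject].nunique()

    @property
    def T(self) -> int:
        return len(self.timepoints)

    def wide(self, column: str) -> pd.DataFrame:
        """Pivot one column to subjects × timepoints."""
        return self.df.pivot(
            index=self.schema.subject, columns=self.schema.time, values=column
        ).sort_index()

    def regimes(self) -> pd.DataFrame:
        """Observed (A_t, M_t) sequence per subject, one tuple column."""
        a = self.wide(self.schema.treatment)
        parts = [a]
        if self.schema.message is not None:
            parts.append(self.wide(self.schema.message))
        out = pd.DataFrame(index=a.index)
        m = parts[1] if len(parts) > 1 else None
        seqs = []
        for idx in a.index:
            seq = tuple(
                (int(a.loc[idx, t]), int(m.loc[idx, t]) if m is not None else 0)
                for t in a.columns
            )
            seqs.append(seq)
        out["regime"] = seqs
        return out


# ---------------------------------------------------------------------------
# Estimand and estimate containers
# ---------------------------------------------------------------------------

_KINDS = (
    "ATE",
    "CDE",
    "tfCDE",
    "MSM_contrast",
    "stratified_naive",
    "rebalanced_naive",
)


@dataclass(frozen=True)
class EstimandSpec:
    """Which causal contrast is targeted.

    * ATE: E[Y(a1)] − E[Y(a0)]
    * CDE: E[Y(a1, e)] − E[Y(a0, e)] for a fixed expectancy level e
    * tfCDE: E[Y(a, e1)] − E[Y(a, e0)] within a fixed arm a
    * MSM_contrast: mean final outcome under regime_1 vs regime_0
    """

    kind: str
    a1: float | None = None
    a0: float | None = None
    e: float | None = None
    a: float | None = None
    e1: float | None = None
    e0: float | None = None
    regime_1: tuple | None = None
    regime_0: tuple | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown estimand kind {self.kind!r}; one of {_KINDS}")
        required: dict[str, tuple[str, ...]] = {
            "ATE": ("a1", "a0"),
            "CDE": ("a1", "a0", "e"),
            "tfCDE": ("a", "e1", "e0"),
            "MSM_contrast": ("regime_1", "regime_0"),
            "stratified_naive": ("a1", "a0"),
            "rebalanced_naive": ("a1", "a0"),
        }[self.kind]
        for f in required:
            if getattr(self, f) is None:
                raise ValueError(f"estimand kind {self.kind} requires field {f!r}")
        allowed = set(required)
        for f in ("a1", "a0", "e", "a", "e1", "e0", "regime_1", "regime_0"):
            if f not in allowed and getattr(self, f) is not None:
                raise ValueError(
                    f"field {f!r} is not part of estimand kind {self.kind}"
                )

    def check_supports(self, data: TrialDataset) -> None:
        sup_a = data.supports.get("treatment", [])
        sup_e = data.supports.get("expectancy", [])
        for f, sup in (("a1", sup_a), ("a0", sup_a), ("a", sup_a),
                       ("e", sup_e), ("e1", sup_e), ("e0", sup_e)):
            v = getattr(self, f)
            if v is not None and sup and v not in sup:
                raise ValidationError(
                    f"level {f}={v} not in declared support {sup}"
                )


@dataclass
class EffectEstimate:
    point: float
    se: float
    ci_low: float
    ci_high: float
    method: str
    n_used: int
    level: float = 0.95
    diagnostics: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("standard error must be non-negative")
        if not (self.ci_low <= self.point <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")

    @classmethod
    def from_point_se(
        cls,
        point: float,
        se: float,
        method: str,
        n_used: int,
        level: float = 0.95,
        diagnostics: dict | None = None,
    ) -> "EffectEstimate":
        from scipy import stats

        zq = stats.norm.ppf(0.5 + level / 2.0)
        return cls(
            point=float(point),
            se=float(se),
            ci_low=float(point - zq * se),
            ci_high=float(point + zq * se),
            method=method,
            n_used=int(n_used),
            level=level,
            diagnostics=dict(diagnostics or {}),
        )

    def to_dict(self) -> dict[str, Any]:
        return {
            "point": self.point,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "method": self.method,
            "n_used": self.n_used,
            "level": self.level,
            "diagnostics": self.diagnostics,
        }


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------


def read_trial(path: str, schema: TrialSchema | Mapping[str, Any]) -> TrialDataset:
    """Read a CSV trial table and validate it against ``schema``."""
    if not isinstance(schema, TrialSchema):
        schema = TrialSchema.from_mapping(schema)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in schema.all_columns() if c not in df.columns]
    if missing:
        role_of = {}
        for role in ("treatment", "expectancy", "outcome", "belief", "subject"):
            col = getattr(schema, role)
            if col is not None:
                role_of[col] = role
        for c in schema.covariates:
            role_of[c] = "covariates"
        for c in schema.post_confounders:
            role_of[c] = "post_confounders"
        roles = sorted({role_of[c] for c in missing})
        raise SchemaError(
            f"file {path!r} lacks columns {missing} for role(s) {roles}"
        )
    return TrialDataset(df, schema)


def write_trial(data: TrialDataset, path: str) -> str:
    """Write a validated dataset as CSV with a header row; returns the path.

    Uses shortest-repr float formatting so a read-back reproduces every
    float bit (pair with the round-trip parser in :func:`read_trial`).
    """
    data.df.to_csv(path, index=False)
    return path


def read_longitudinal(
    path: str, schema: LongitudinalSchema | Mapping[str, Any]
) -> LongitudinalDataset:
    if not isinstance(schema, LongitudinalSchema):
        schema = LongitudinalSchema.from_mapping(schema)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in schema.all_columns() if c not in df.columns]
    if missing:
        raise SchemaError(f"file {path!r} lacks columns {missing}")
    return LongitudinalDataset(df, schema)


def write_longitudinal(data: LongitudinalDataset, path: str) -> str:
    data.df.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Positivity / overlap reporting
# ---------------------------------------------------------------------------


@dataclass
class PositivityReport:
    """Empirical (A, E) cell counts, overall and within coarsened strata."""

    cell_counts: dict[tuple, int]
    strata_counts: dict[str, dict[tuple, int]]
    flagged_cells: list[tuple]
    spec: EstimandSpec

    @property
    def ok(self) -> bool:
        return not self.flagged_cells

    def to_dict(self) -> dict[str, Any]:
        return {
            "cell_counts": {str(k): v for k, v in self.cell_counts.items()},
            "strata_counts": {
                k: {str(kk): vv for kk, vv in v.items()}
                for k, v in self.strata_counts.items()
            },
            "flagged_cells": [str(c) for c in self.flagged_cells],
            "ok": self.ok,
        }


def _coarsen(v: np.ndarray, bins: int = 2) -> np.ndarray:
    """Median-split (or quantile-bin) a column for overlap inspection."""
    uniq = np.unique(v)
    if len(uniq) <= bins:
        return v
    qs = np.quantile(v, np.linspace(0, 1, bins + 1)[1:-1])
    return np.digitize(v, qs).astype(float)


def validate_positivity_support(
    data: TrialDataset, spec: EstimandSpec
) -> PositivityReport:
    """Report empirical support for the (a, e) cells an estimand touches.

    Empty cells are flagged, never raised: positivity violations are a
    property of the design the analyst must see, not an exception to
    swallow.
    """
    if spec.kind not in ("CDE", "tfCDE"):
        raise ValueError("positivity report applies to CDE / tfCDE estimands")
    A, E = data.A, data.E
    cells: dict[tuple, int] = {}
    for a in sorted(np.unique(A)):
        for e in sorted(np.unique(E)):
            cells[(a, e)] = int(np.sum((A == a) & (E == e)))

    strata_counts: dict[str, dict[tuple, int]] = {}
    for name, cols in (
        ("X", list(data.schema.covariates)),
        ("Z", list(data.schema.post_confounders)),
    ):
        if not cols:
            continue
        coarse = _coarsen(data.df[cols[0]].to_numpy(dtype=float))
        d: dict[tuple, int] = {}
        for s in sorted(np.unique(coarse)):
            m = coarse == s
            for a in sorted(np.unique(A)):
                for e in sorted(np.unique(E)):
                    d[(s, a, e)] = int(np.sum(m & (A == a) & (E == e)))
        strata_counts[f"{name}:{cols[0]}"] = d

    if spec.kind == "CDE":
        touched = [(spec.a1, spec.e), (spec.a0, spec.e)]
    else:
        touched = [(spec.a, spec.e1), (spec.a, spec.e0)]
    flagged = [c for c in touched if cells.get((float(c[0]), float(c[1])), 0) == 0]
    return PositivityReport(cells, strata_counts, flagged, spec)


# ---------------------------------------------------------------------------
# Two-period flattening for CDE analysis of sequential data
# ---------------------------------------------------------------------------


def flatten_two_period(ldata: LongitudinalDataset) -> TrialDataset:
    """Cast a two-timepoint sequential trial as a cross-sectional CDE problem.

    Treatment is the final-period assignment A_2, expectancy the final-period
    E_2 and outcome the final Y_2; the entire first-period history
    (A_1, M_1, E_1, Y_1) plus the final message M_2 enter Z.  Because final
    expectancy depends on the past only through these recorded variables,
    E_2 is as good as randomized given (A_2, Z), which is exactly the
    identification condition the CDE estimators rely on.
    """
    if ldata.T != 2:
        raise ValidationError("flattening requires exactly two timepoints")
    s = ldata.schema
    t1, t2 = ldata.timepoints
    wideA = ldata.wide(s.treatment)
    wideY = ldata.wide(s.outcome)
    out = pd.DataFrame(index=wideA.index)
    out["A1"] = wideA[t1]
    out["A"] = wideA[t2]
    out["Y1"] = wideY[t1]
    out["Y"] = wideY[t2]
    z_cols = ["A1", "Y1"]
    if s.message is not None:
        wideM = ldata.wide(s.message)
        out["M1"] = wideM[t1]
        out["M2"] = wideM[t2]
        z_cols += ["M1", "M2"]
    if s.expectancy is not None:
        wideE = ldata.wide(s.expectancy)
        out["E1"] = wideE[t1]
        out["E"] = wideE[t2]
        z_cols.append("E1")
    else:
        raise ValidationError("flattening requires an expectancy role")
    x_cols = []
    if s.covariates:
        base = ldata.df.groupby(s.subject)[list(s.covariates)].first()
        for c in s.covariates:
            out[c] = base[c]
            x_cols.append(c)
    out = out.reset_index().rename(columns={s.subject: "subject_id"})
    schema = TrialSchema(
        treatment="A",
        expectancy="E",
        outcome="Y",
        covariates=tuple(x_cols),
        post_confounders=tuple(z_cols),
        subject="subject_id",
    )
    return TrialDataset(out, schema)


def estimate_to_json(est: EffectEstimate, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(est.to_dict(), fh, indent=2)
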