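"""Preprocessing chain turning a raw cohort table into the clean, complete,
comparable-scale matrix the topographic model requires.

Pipeline order: validity/unit harmonisation -> missingness filtering
(variables first, then subjects) -> log transform of positively skewed
variables -> multivariate iterative imputation -> z-scoring.  Each step is
also exposed individually.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from sklearn.exceptions import ConvergenceWarning
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer
from sklearn.linear_model import Ridge

from .cohort import CohortTable, Role, VType, VariableMeta

__all__ = [
    "PreprocessConfig",
    "PreprocessReport",
    "ValidityRule",
    "Standardizer",
    "apply_validity_and_units",
    "filter_missingness",
    "transform_skewed",
    "impute",
    "standardize",
    "encode_ordinals",
    "run_pipeline",
]


@dataclass
class PreprocessConfig:
    """Thresholds and seeds for the preprocessing chain.

    ``var_missing_threshold`` / ``subject_missing_threshold`` are the maximum
    tolerated missing fractions (strict: a variable is dropped only when its
    missing fraction exceeds the threshold).  Defaults are 25% per variable
    and 30% per subject.
    """

    var_missing_threshold: float = 0.25
    subject_missing_threshold: float = 0.30
    skew_threshold: float = 1.0
    imputation_rounds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("var_missing_threshold", "subject_missing_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.imputation_rounds < 1:
            raise ValueError("imputation_rounds must be a positive integer")


@dataclass
class PreprocessReport:
    dropped_variables: list[str] = field(default_factory=list)
    dropped_subjects: list = field(default_factory=list)
    log_transformed: list[str] = field(default_factory=list)
    imputed_cell_count: int = 0
    unit_conversions: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))


@dataclass(frozen=True)
class ValidityRule:
    """A per-variable cleaning rule: valid range and/or a unit conversion.

    ``factor`` multiplies every non-missing cell (e.g. 2.54 for inches->cm);
    ``to_unit`` records the canonical unit after conversion.  The valid range
    is applied after any conversion.
    """

    variable: str
    valid_range: tuple[float, float] | None = None
    factor: float | None = None
    to_unit: str | None = None


def apply_validity_and_units(table: CohortTable, rules: list[ValidityRule]) -> CohortTable:
    """Mask invalid measurements and harmonise units.

    Cells outside a rule's ``valid_range`` become missing; unit-converted
    columns are multiplied by the rule's factor.  All other cells are
    untouched.
    """
    known = set(v.name for v in table.variables)
    for rule in rules:
        if rule.variable not in known:
            raise KeyError(f"validity rule references unknown variable {rule.variable!r}")
    df = table.data.copy()
    out = table.with_data(df)
    for rule in rules:
        col = df[rule.variable].astype(float)
        if rule.factor is not None:
            col = col * rule.factor
            if rule.to_unit is not None:
                m = out.meta(rule.variable)
                out.replace_variable(
                    rule.variable,
                    VariableMeta(m.name, m.role, m.vtype, rule.to_unit, m.valid_range),
                )
        if rule.valid_range is not None:
            low, high = rule.valid_range
            col = col.where((col.isna()) | ((col >= low) & (col <= high)))
        df[rule.variable] = col
    return out


def filter_missingness(
    table: CohortTable, cfg: PreprocessConfig
) -> tuple[CohortTable, PreprocessReport]:
    """Drop over-sparse variables, then over-sparse subjects.

    Variables whose missing fraction strictly exceeds
    ``cfg.var_missing_threshold`` are removed first; subjects are then judged
    on their missing fraction over the *surviving* variables against
    ``cfg.subject_missing_threshold``.  Comparisons are strict, so boundary
    cases are retained.
    """
    if table.n_subjects == 0 or table.n_variables == 0:
        raise ValueError("cannot filter an empty table")
    df = table.data
    var_frac = df.isna().mean(axis=0)
    keep_vars = [v.name for v in table.variables if var_frac[v.name] <= cfg.var_missing_threshold]
    dropped_vars = [n for n in df.columns if n not in keep_vars]
    if not keep_vars:
        raise ValueError("empty after filtering: every variable exceeded the threshold")
    df2 = df[keep_vars]
    subj_frac = df2.isna().mean(axis=1)
    keep_mask = subj_frac <= cfg.subject_missing_threshold
    dropped_subjects = list(df2.index[~keep_mask])
    df3 = df2.loc[keep_mask]
    if df3.shape[0] == 0:
        raise ValueError("empty after filtering: every subject exceeded the threshold")
    report = PreprocessReport(dropped_variables=dropped_vars, dropped_subjects=dropped_subjects)
    return table.subset(subjects=df3.index, variables=keep_vars), report


def transform_skewed(
    table: CohortTable, skew_threshold: float = 1.0
) -> tuple[CohortTable, list[str]]:
    """Apply ``log(1 + x)`` to positively skewed continuous modelling variables.

    A variable qualifies when its moment-based sample skewness exceeds the
    threshold and every non-missing value is nonnegative (the transform must
    stay real).  Returns the transformed table and the list of variables
    transformed.
    """
    df = table.data.copy()
    transformed: list[str] = []
    for name in table.names(role=Role.MODELLING, vtype=VType.CONTINUOUS):
        x = df[name].to_numpy(dtype=float)
        obs = x[~np.isnan(x)]
        if obs.size < 3:
            continue
        g1 = stats.skew(obs, bias=True)
        if g1 > skew_threshold and obs.min() >= 0:
            df[name] = np.log1p(df[name].astype(float))
            transformed.append(name)
    return table.with_data(df), transformed


def impute(table: CohortTable, cfg: PreprocessConfig) -> CohortTable:
    """Fill remaining missing values in modelling variables.

    Round-robin conditional ridge regression of each incomplete variable on
    all the others (MICE-style chained equations), ``cfg.imputation_rounds``
    passes, initialised from column means.  Observed cells are never altered
    and the result is deterministic for a fixed seed.
    """
    names = table.modelling_names
    X = table.data[names].to_numpy(dtype=float)
    all_missing = [n for n, col in zip(names, X.T) if np.isnan(col).all()]
    if all_missing:
        raise ValueError(f"modelling variables with zero observed values: {all_missing}")
    if not np.isnan(X).any():
        return table
    imputer = IterativeImputer(
        estimator=Ridge(alpha=1e-6),
        max_iter=cfg.imputation_rounds,
        initial_strategy="mean",
        sample_posterior=False,
        random_state=cfg.seed,
        tol=1e-8,
    )
    with warnings.catch_warnings():
        # a fixed number of round-robin passes is the contract, not convergence
        warnings.simplefilter("ignore", ConvergenceWarning)
        filled = imputer.fit_transform(X)
    # guard: restore observed cells bit-exactly
    obs = ~np.isnan(X)
    filled[obs] = X[obs]
    df = table.data.copy()
    df[names] = filled
    return table.with_data(df)


@dataclass
class Standardizer:
    """Per-variable location/scale parameters for z-scoring and its inverse."""

    names: list[str]
    mean: np.ndarray
    scale: np.ndarray

    def inverse(self, table: CohortTable) -> CohortTable:
        df = table.data.copy()
        for n, m, s in zip(self.names, self.mean, self.scale):
            df[n] = df[n] * s + m
        return table.with_data(df)

    def inverse_column(self, name: str, values: np.ndarray) -> np.ndarray:
        i = self.names.index(name)
        return np.asarray(values, dtype=float) * self.scale[i] + self.mean[i]

    def to_dict(self) -> dict:
        return {"names": self.names, "mean": self.mean.tolist(), "scale": self.scale.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        return cls(list(d["names"]), np.asarray(d["mean"], float), np.asarray(d["scale"], float))


def standardize(table: CohortTable) -> tuple[CohortTable, Standardizer]:
    """Z-score the continuous modelling variables (mean 0, unit sd).

    Requires a complete table; a zero-variance variable is an error because
    it carries no information and would divide by zero.
    """
    names = table.names(role=Role.MODELLING, vtype=VType.CONTINUOUS)
    sub = table.data[names].to_numpy(dtype=float)
    if np.isnan(sub).any():
        raise ValueError("standardize requires a complete table; run impute first")
    mean = sub.mean(axis=0)
    scale = sub.std(axis=0)  # population sd, matching the z-score convention
    zero = [n for n, s in zip(names, scale) if s == 0]
    if zero:
        raise ValueError(f"zero-variance variables cannot be standardized: {zero}")
    df = table.data.copy()
    df[names] = (sub - mean) / scale
    return table.with_data(df), Standardizer(names, mean, scale)


def encode_ordinals(table: CohortTable, variables: list[str]) -> CohortTable:
    """Replace each named ordinal variable by one indicator column per level.

    Indicators sum to 1 per subject where the source is non-missing; where it
    is missing, every indicator is missing.
    """
    for name in variables:
        if table.meta(name).vtype is not VType.ORDINAL:
            raise ValueError(f"{name!r} is not an ordinal variable")
    df = table.data.copy()
    metas = list(table.variables)
    for name in variables:
        src = df[name]
        levels = sorted(src.dropna().unique(), key=str)
        pos = [v.name for v in metas].index(name)
        role = table.meta(name).role
        new_cols = {}
        for lev in levels:
            col = (src == lev).astype(float)
            col[src.isna()] = np.nan
            new_cols[f"{name}={lev}"] = col
        df = df.drop(columns=[name])
        for j, (cname, col) in enumerate(new_cols.items()):
            df.insert(pos + j, cname, col)
        metas[pos: pos + 1] = [
            VariableMeta(cname, role, VType.CATEGORICAL) for cname in new_cols
        ]
    return CohortTable(data=df, variables=metas)


def run_pipeline(
    table: CohortTable,
    cfg: PreprocessConfig | None = None,
    rules: list[ValidityRule] | None = None,
    scale: bool = True,
) -> tuple[CohortTable, PreprocessReport, Standardizer | None]:
    """Full chain: validity/units -> missingness filter -> skew transform ->
    impute -> (optionally) standardize."""
    cfg = cfg or PreprocessConfig()
    if rules:
        table = apply_validity_and_units(table, rules)
    table, report = filter_missingness(table, cfg)
    if rules:
        report.unit_conversions = [
            {"variable": r.variable, "factor": r.factor, "to_unit": r.to_unit}
            for r in rules
            if r.factor is not None
        ]
    table, logged = transform_skewed(table, cfg.skew_threshold)
    report.log_transformed = logged
    n_missing = int(table.data[table.modelling_names].isna().sum().sum())
    table = impute(table, cfg)
    report.imputed_cell_count = n_missing
    scaler = None
    if scale:
        table, scaler = standardize(table)
    return table, report, scaler
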