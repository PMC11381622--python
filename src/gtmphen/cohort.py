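"""Cohort table container: subjects x variables with per-variable metadata.

A :class:`CohortTable` wraps a pandas DataFrame (rows = subjects, columns =
variables) together with a :class:`VariableMeta` record per variable giving
its role in the analysis (``modelling`` variables enter the topographic
model; ``investigative`` variables are only used post hoc) and its
measurement type.  Missing values are represented as NaN.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = ["Role", "VType", "VariableMeta", "CohortTable", "read_cohort", "write_cohort"]


class Role(str, enum.Enum):
    MODELLING = "modelling"
    INVESTIGATIVE = "investigative"


class VType(str, enum.Enum):
    CONTINUOUS = "continuous"
    CATEGORICAL = "categorical"
    ORDINAL = "ordinal"


@dataclass(frozen=True)
class VariableMeta:
    """Metadata for one cohort variable.

    ``valid_range`` is only meaningful for continuous variables and is an
    inclusive-exclusive pair ``(low, high)``; cells outside it are treated as
    invalid measurements (e.g. a negative heart rate).
    """

    name: str
    role: Role = Role.MODELLING
    vtype: VType = VType.CONTINUOUS
    unit: str | None = None
    valid_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "role", Role(self.role))
        object.__setattr__(self, "vtype", VType(self.vtype))
        if self.valid_range is not None:
            if self.vtype is not VType.CONTINUOUS:
                raise ValueError(
                    f"valid_range only applies to continuous variables, not {self.name!r}"
                )
            low, high = self.valid_range
            if not low < high:
                raise ValueError(f"valid_range for {self.name!r} must have low < high")
            object.__setattr__(self, "valid_range", (float(low), float(high)))

    def to_dict(self) -> dict:
        d = {"name": self.name, "role": self.role.value, "vtype": self.vtype.value}
        if self.unit is not None:
            d["unit"] = self.unit
        if self.valid_range is not None:
            d["valid_range"] = list(self.valid_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "VariableMeta":
        vr = d.get("valid_range")
        return cls(
            name=d["name"],
            role=Role(d.get("role", "modelling")),
            vtype=VType(d.get("vtype", "continuous")),
            unit=d.get("unit"),
            valid_range=tuple(vr) if vr is not None else None,
        )


@dataclass
class CohortTable:
    """Subjects x variables table plus variable metadata.

    Invariants enforced at construction: subject ids unique, variable names
    unique, and the DataFrame columns exactly match the metadata (same names,
    same order).
    """

    data: pd.DataFrame
    variables: list[VariableMeta] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("variable names must be unique")
        if list(self.data.columns) != names:
            raise ValueError("DataFrame columns must match variable metadata in order")
        if self.data.index.has_duplicates:
            raise ValueError("subject ids must be unique")
        self._meta = {v.name: v for v in self.variables}

    # -- basic accessors -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_variables(self) -> int:
        return self.data.shape[1]

    @property
    def subject_ids(self) -> list:
        return list(self.data.index)

    def meta(self, name: str) -> VariableMeta:
        try:
            return self._meta[name]
        except KeyError:
            raise KeyError(f"unknown variable {name!r}") from None

    def names(
        self, role: Role | None = None, vtype: VType | None = None
    ) -> list[str]:
        out = []
        for v in self.variables:
            if role is not None and v.role is not Role(role):
                continue
            if vtype is not None and v.vtype is not VType(vtype):
                continue
            out.append(v.name)
        return out

    @property
    def modelling_names(self) -> list[str]:
        return self.names(role=Role.MODELLING)

    # -- derived views ---------------------------------------------------
    def modelling_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Numeric matrix of the modelling variables (float64), plus names."""
        names = self.modelling_names
        X = self.data[names].to_numpy(dtype=float)
        return X, names

    def with_data(self, data: pd.DataFrame) -> "CohortTable":
        return CohortTable(data=data, variables=[self._meta[c] for c in data.columns])

    def subset(
        self, subjects: Sequence | None = None, variables: Iterable[str] | None = None
    ) -> "CohortTable":
        df = self.data
        if variables is not None:
            df = df[list(variables)]
        if subjects is not None:
            df = df.loc[list(subjects)]
        return CohortTable(data=df, variables=[self._meta[c] for c in df.columns])

    def replace_variable(self, name: str, meta: VariableMeta) -> None:
        idx = [v.name for v in self.variables].index(name)
        self.variables[idx] = meta
        self._meta = {v.name: v for v in self.variables}


# ---------------------------------------------------------------------------
# I/O: CSV/TSV table + YAML/JSON metadata sidecar
# ---------------------------------------------------------------------------

_NA_VALUES = ["", "NA"]


def read_cohort(table_path: str | Path, meta_path: str | Path) -> CohortTable:
    """Read a cohort from a delimited table and a metadata sidecar.

    The table must have a header row; the first column holds subject ids.
    Missing cells are empty or ``NA``.  The sidecar is YAML or JSON: a list
    of variable records (name, role, vtype, optional unit / valid_range).
    """
    table_path = Path(table_path)
    sep = "\t" if table_path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(table_path, sep=sep, index_col=0, na_values=_NA_VALUES,
                     keep_default_na=False)
    meta_path = Path(meta_path)
    text = meta_path.read_text()
    raw = json.loads(text) if meta_path.suffix.lower() == ".json" else yaml.safe_load(text)
    if isinstance(raw, dict) and "variables" in raw:
        raw = raw["variables"]
    variables = [VariableMeta.from_dict(d) for d in raw]
    order = [v.name for v in variables]
    missing = set(order) - set(df.columns)
    if missing:
        raise ValueError(f"metadata names variables absent from table: {sorted(missing)}")
    return CohortTable(data=df[order], variables=variables)


def write_cohort(table: CohortTable, table_path: str | Path, meta_path: str | Path) -> None:
    table_path = Path(table_path)
    sep = "\t" if table_path.suffix.lower() in {".tsv", ".tab"} else ","
    table.data.to_csv(table_path, sep=sep, index_label="subject_id", na_rep="NA")
    meta_path = Path(meta_path)
    payload = [v.to_dict() for v in table.variables]
    if meta_path.suffix.lower() == ".json":
        meta_path.write_text(json.dumps(payload, indent=2))
    else:
        meta_path.write_text(yaml.safe_dump(payload, sort_keys=False))
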