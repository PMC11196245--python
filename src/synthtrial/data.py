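"""Domain types and schema-validated I/O for patient-level control-arm tables.

A trial table holds one row per subject: an arbitrary set of baseline
covariates plus the four time-to-event endpoint columns — progression-free
survival (PFS) and overall survival (OS), each as a time in days and a
0/1 event flag.  Every valid table satisfies the survival-ordering
constraints ``pfs_time > 0``, ``os_time > 0`` and ``pfs_time <= os_time``:
a subject cannot progress after dying.

The :class:`VariableSchema` carries per-variable type and role metadata and
the order in which the synthesis engine visits the covariates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import yaml

VarType = Literal["continuous", "categorical", "integer"]
Role = Literal["covariate", "pfs_time", "pfs_event", "os_time", "os_event"]

VARTYPES: frozenset[str] = frozenset({"continuous", "categorical", "integer"})
ENDPOINT_ROLES: tuple[str, ...] = ("pfs_time", "pfs_event", "os_time", "os_event")
ROLES: frozenset[str] = frozenset({"covariate", *ENDPOINT_ROLES})

#: Sentinel level substituted for missing categorical covariate values.
MISSING_LEVEL = "missing"


class SchemaError(ValueError):
    """Schema is internally inconsistent or does not match a data file."""


class TableValidationError(ValueError):
    """A table breaches one or more row-level invariants."""

    def __init__(self, violations: list["Violation"]):
        self.violations = violations
        lines = "; ".join(str(v) for v in violations[:10])
        extra = "" if len(violations) <= 10 else f" (+{len(violations) - 10} more)"
        super().__init__(f"{len(violations)} violation(s): {lines}{extra}")


@dataclass(frozen=True)
class Variable:
    """One column of a trial table: its name, measurement type and role."""

    name: str
    vartype: VarType
    role: Role = "covariate"

    def __post_init__(self) -> None:
        if self.vartype not in VARTYPES:
            raise SchemaError(f"unknown vartype {self.vartype!r} for {self.name!r}")
        if self.role not in ROLES:
            raise SchemaError(f"unknown role {self.role!r} for {self.name!r}")


@dataclass(frozen=True)
class VariableSchema:
    """Ordered variable metadata plus the covariate visit order for synthesis.

    Endpoint variables (one per role in :data:`ENDPOINT_ROLES`) are always
    synthesized after all covariates, so ``visit_order`` ranges over covariate
    names only.  When omitted it defaults to the covariates' schema order.
    """

    entries: tuple[Variable, ...]
    visit_order: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        entries = tuple(self.entries)
        object.__setattr__(self, "entries", entries)
        names = [v.name for v in entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise SchemaError(f"duplicate variable names: {dupes}")
        for role in ENDPOINT_ROLES:
            k = sum(v.role == role for v in entries)
            if k != 1:
                raise SchemaError(f"need exactly one variable with role {role!r}, found {k}")
        covs = [v.name for v in entries if v.role == "covariate"]
        order = tuple(self.visit_order) or tuple(covs)
        if sorted(order) != sorted(covs):
            raise SchemaError(
                f"visit_order must be a permutation of the covariate names {covs}, got {list(order)}"
            )
        object.__setattr__(self, "visit_order", order)

    # -- lookups ---------------------------------------------------------

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.entries]

    @property
    def covariate_names(self) -> list[str]:
        return [v.name for v in self.entries if v.role == "covariate"]

    def endpoint_name(self, role: str) -> str:
        return next(v.name for v in self.entries if v.role == role)

    def variable(self, name: str) -> Variable:
        try:
            return next(v for v in self.entries if v.name == name)
        except StopIteration:
            raise KeyError(name) from None

    def synthesis_order(self) -> list[str]:
        """Full visit sequence: covariates, then event flag and time per endpoint.

        Events precede times so that synthesized time distributions can
        condition on censoring status.
        """
        return list(self.visit_order) + [
            self.endpoint_name(r) for r in ("pfs_event", "pfs_time", "os_event", "os_time")
        ]

    # -- serialization ---------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "VariableSchema":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        entries = tuple(
            Variable(d["name"], d["type"], d.get("role", "covariate"))
            for d in raw["variables"]
        )
        return cls(entries, tuple(raw.get("visit_order", ())))

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "variables": [
                {"name": v.name, "type": v.vartype, "role": v.role} for v in self.entries
            ],
            "visit_order": list(self.visit_order),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass(frozen=True)
class Violation:
    """One (row, rule) breach found by :func:`validate_table`."""

    row: int | None
    rule: str
    severity: str = "error"  # "error" breaks an invariant; "warning" is advisory

    def __str__(self) -> str:
        where = "table" if self.row is None else f"row {self.row}"
        return f"{where}: {self.rule} [{self.severity}]"


@dataclass
class TrialTable:
    """A validated patient-level table bound to its :class:`VariableSchema`."""

    schema: VariableSchema
    df: pd.DataFrame
    validate: dataclasses.InitVar[bool] = True

    def __post_init__(self, validate: bool) -> None:
        missing = [n for n in self.schema.names if n not in self.df.columns]
        extra = [c for c in self.df.columns if c not in self.schema.names]
        if missing or extra:
            raise SchemaError(f"columns do not match schema (missing={missing}, extra={extra})")
        self.df = self.df.loc[:, self.schema.names].reset_index(drop=True)
        for v in self.schema.entries:
            if v.role.endswith("_time") or v.vartype == "continuous":
                self.df[v.name] = self.df[v.name].astype(float)
        if validate:
            errors = [x for x in validate_table(self) if x.severity == "error"]
            if errors:
                raise TableValidationError(errors)

    @property
    def n(self) -> int:
        return len(self.df)

    def endpoint(self, which: Literal["pfs", "os"]) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(times, events)`` arrays in days / {0,1} for an endpoint."""
        t = self.df[self.schema.endpoint_name(f"{which}_time")].to_numpy(float)
        e = self.df[self.schema.endpoint_name(f"{which}_event")].to_numpy(float).astype(int)
        return t, e


def validate_table(table: TrialTable) -> list[Violation]:
    """Report every (row, rule) breach of the trial-table invariants.

    Returns an empty list iff the table satisfies all invariants.  Missing
    categorical covariates are permitted but flagged with severity
    ``"warning"``; all other findings have severity ``"error"``.
    """
    out: list[Violation] = []
    df = table.df
    sch = table.schema
    pt = df[sch.endpoint_name("pfs_time")].to_numpy(float)
    ot = df[sch.endpoint_name("os_time")].to_numpy(float)
    for role in ENDPOINT_ROLES:
        col = df[sch.endpoint_name(role)]
        for i in np.flatnonzero(col.isna().to_numpy()):
            out.append(Violation(int(i), f"{role} missing"))
    for i in np.flatnonzero(~(pt > 0)):
        if not np.isnan(pt[i]):
            out.append(Violation(int(i), "pfs_time > 0"))
    for i in np.flatnonzero(~(ot > 0)):
        if not np.isnan(ot[i]):
            out.append(Violation(int(i), "os_time > 0"))
    with np.errstate(invalid="ignore"):
        for i in np.flatnonzero(pt > ot):
            out.append(Violation(int(i), "pfs_time <= os_time"))
    for role in ("pfs_event", "os_event"):
        flags = df[sch.endpoint_name(role)].to_numpy(float)
        bad = ~np.isin(flags, (0.0, 1.0)) & ~np.isnan(flags)
        for i in np.flatnonzero(bad):
            out.append(Violation(int(i), f"{role} in {{0, 1}}"))
    for v in sch.entries:
        if v.role != "covariate":
            continue
        isna = df[v.name].isna().to_numpy()
        sev = "warning" if v.vartype == "categorical" else "error"
        for i in np.flatnonzero(isna):
            out.append(Violation(int(i), f"covariate {v.name} missing", severity=sev))
    return out


def read_trial_table(path: str | Path, schema: VariableSchema) -> TrialTable:
    """Read and validate a patient-level CSV against ``schema``.

    Categorical covariates are read as strings, with missing values mapped
    to the sentinel level ``"missing"``.  Times are parsed as days (float).
    """
    header = pd.read_csv(path, nrows=0).columns.tolist()
    missing = [n for n in schema.names if n not in header]
    extra = [c for c in header if c not in schema.names]
    if missing or extra:
        raise SchemaError(f"CSV header does not match schema (missing={missing}, extra={extra})")
    cat_cols = [v.name for v in schema.entries if v.vartype == "categorical"]
    df = pd.read_csv(path, dtype={c: str for c in cat_cols}, float_precision="round_trip")
    for c in cat_cols:
        df[c] = df[c].fillna(MISSING_LEVEL)
    return TrialTable(schema, df)


def write_trial_table(table: TrialTable, path: str | Path) -> None:
    """Write a table as UTF-8 comma-separated CSV, times at full precision.

    ``read_trial_table(write_trial_table(t))`` reproduces ``t``
    value-for-value; repeated writes are byte-identical.
    """
    table.df.to_csv(
        path,
        index=False,
        lineterminator="\n",
        encoding="utf-8",
        # repr is the shortest decimal that parses back to the same double
        float_format=lambda v: repr(float(v)),
    )


@dataclass
class RunConfig:
    """Study-level configuration: replicate count, seeding and outputs."""

    master_seed: int
    n_replicates: int = 1000
    conf_level: float = 0.95
    methods: tuple[str, ...] = ("cart", "rf")
    output_dir: str | None = None
    make_plots: bool = False

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0.0 < self.conf_level < 1.0:
            raise ValueError("conf_level must lie in (0, 1)")
        self.methods = tuple(self.methods)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)
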