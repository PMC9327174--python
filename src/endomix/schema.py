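"""Feature schemas and cohort tables with explicit missingness.

A cohort is a patient-by-feature table of mixed-type admission data
(continuous labs and physiology, ordinal severity scores such as the
Glasgow coma scale, binary flags, nominal categories) with an explicit
boolean mask marking which cells were observed.  Missingness is kept
first-class because the clustering model marginalises missing entries
rather than imputing them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

KINDS = ("continuous", "ordinal", "binary", "nominal")
ROLES = ("cluster_input", "outcome", "id", "auxiliary")

#: feature kinds that can be coded on a numeric axis (and hence may sit on a
#: dependency-forest edge)
NUMERIC_KINDS = ("continuous", "ordinal", "binary")


class SchemaError(ValueError):
    """The schema itself, or a table's conformance to it, is invalid."""


class ValidationError(ValueError):
    """A data value violates the declared schema."""


@dataclass(frozen=True)
class FeatureSpec:
    """Declaration of a single feature.

    Parameters
    ----------
    name : unique identifier within the schema.
    kind : one of ``continuous``, ``ordinal``, ``binary``, ``nominal``.
    units : free-text units, e.g. ``"mmol/L"``.
    levels : ordered category labels; required for every non-continuous
        kind (ordinal levels must be numeric, e.g. GCS total 3..15).
    role : ``cluster_input`` features enter the mixture model; at most one
        ``outcome`` (GOS-E) and exactly one ``id`` per schema.
    """

    name: str
    kind: str
    units: str = ""
    levels: tuple | None = None
    role: str = "cluster_input"

    def __post_init__(self):
        if self.kind not in KINDS:
            raise SchemaError(f"unknown kind {self.kind!r} for feature {self.name!r}")
        if self.role not in ROLES:
            raise SchemaError(f"unknown role {self.role!r} for feature {self.name!r}")
        if self.role == "id":
            # identifier columns hold free-text labels; level checks don't apply
            if self.levels is not None:
                object.__setattr__(self, "levels", tuple(self.levels))
            return
        if self.kind == "continuous":
            if self.levels is not None:
                raise SchemaError(f"continuous feature {self.name!r} must not declare levels")
        else:
            if not self.levels:
                raise SchemaError(f"{self.kind} feature {self.name!r} must declare levels")
            object.__setattr__(self, "levels", tuple(self.levels))
            if self.kind == "binary" and len(self.levels) != 2:
                raise SchemaError(f"binary feature {self.name!r} needs exactly 2 levels")
            if self.kind == "ordinal" and not all(
                isinstance(v, (int, float, np.integer, np.floating)) for v in self.levels
            ):
                raise SchemaError(f"ordinal feature {self.name!r} needs numeric levels")

    @property
    def is_numeric(self) -> bool:
        return self.kind in NUMERIC_KINDS


def validate_schema(schema: Sequence[FeatureSpec]) -> None:
    names = [f.name for f in schema]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise SchemaError(f"duplicate feature names: {dup}")
    n_id = sum(f.role == "id" for f in schema)
    if n_id != 1:
        raise SchemaError(f"schema must declare exactly one id feature, found {n_id}")
    n_out = sum(f.role == "outcome" for f in schema)
    if n_out > 1:
        raise SchemaError(f"schema declares {n_out} outcome features, at most 1 allowed")


def load_schema(path) -> list[FeatureSpec]:
    """Read a schema declaration from YAML (a list of feature mappings)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    specs = [
        FeatureSpec(
            name=item["name"],
            kind=item["kind"],
            units=item.get("units", ""),
            levels=tuple(item["levels"]) if item.get("levels") is not None else None,
            role=item.get("role", "cluster_input"),
        )
        for item in raw
    ]
    validate_schema(specs)
    return specs


def save_schema(schema: Sequence[FeatureSpec], path) -> None:
    raw = [
        {
            "name": f.name,
            "kind": f.kind,
            "units": f.units,
            "levels": list(f.levels) if f.levels is not None else None,
            "role": f.role,
        }
        for f in schema
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


class CohortTable:
    """A typed patient-by-feature table with an explicit missingness mask.

    ``records`` holds feature values (NaN/None where missing), ``mask`` is
    True where a value was observed.  Both share the same shape and column
    order as the schema.
    """

    def __init__(
        self,
        schema: Sequence[FeatureSpec],
        records: pd.DataFrame,
        mask: pd.DataFrame | None = None,
        log: list[str] | None = None,
    ):
        validate_schema(schema)
        self.schema = list(schema)
        names = [f.name for f in self.schema]
        if list(records.columns) != names:
            missing = [n for n in names if n not in records.columns]
            if missing:
                raise SchemaError(f"records missing declared columns: {missing}")
            records = records[names]
        self.records = records.reset_index(drop=True)
        if mask is None:
            mask = self.records.notna()
        if mask.shape != records.shape:
            raise SchemaError("mask and records must have identical shape")
        mask = pd.DataFrame(np.asarray(mask, dtype=bool), columns=names)
        self.mask = mask.reset_index(drop=True)
        self.log = list(log or [])
        self._validate_values()

    # -- basic accessors ---------------------------------------------------
    @property
    def n_patients(self) -> int:
        return len(self.records)

    def feature(self, name: str) -> FeatureSpec:
        for f in self.schema:
            if f.name == name:
                return f
        raise KeyError(name)

    @property
    def cluster_input_names(self) -> list[str]:
        return [f.name for f in self.schema if f.role == "cluster_input"]

    @property
    def id_name(self) -> str:
        return next(f.name for f in self.schema if f.role == "id")

    @property
    def outcome_name(self) -> str | None:
        return next((f.name for f in self.schema if f.role == "outcome"), None)

    def observed(self, name: str) -> np.ndarray:
        """Observed values of one feature (1-d array)."""
        m = self.mask[name].to_numpy()
        return self.records[name].to_numpy()[m]

    # -- validation --------------------------------------------------------
    def _validate_values(self) -> None:
        for f in self.schema:
            if f.role == "id":
                continue
            col = self.records[f.name]
            m = self.mask[f.name].to_numpy()
            if not m.any():
                continue
            vals = col[m]
            if f.kind == "continuous":
                arr = pd.to_numeric(vals, errors="coerce")
                bad = arr.index[~np.isfinite(arr.to_numpy(dtype=float))]
                if len(bad):
                    raise ValidationError(
                        f"non-finite value for continuous feature {f.name!r} at row {bad[0]}"
                    )
            elif f.role != "id":
                allowed = set(f.levels)
                for idx, v in vals.items():
                    if v not in allowed:
                        raise ValidationError(
                            f"value {v!r} outside declared levels for feature "
                            f"{f.name!r} at row {idx}"
                        )

    def copy(self) -> "CohortTable":
        return CohortTable(self.schema, self.records.copy(), self.mask.copy(), list(self.log))


def _parse_cell(raw: str, spec: FeatureSpec, row: int):
    if spec.role == "id":
        return raw
    if spec.kind == "continuous":
        try:
            return float(raw)
        except ValueError:
            raise ValidationError(
                f"cannot parse {raw!r} as number for feature {spec.name!r} at row {row}"
            ) from None
    # categorical kinds: match against declared level labels
    for lv in spec.levels:
        if raw == str(lv):
            return lv
        if isinstance(lv, (int, float, np.integer, np.floating)):
            try:
                if float(raw) == float(lv):
                    return lv
            except ValueError:
                pass
    raise ValidationError(
        f"value {raw!r} outside declared levels for feature {spec.name!r} at row {row}"
    )


def load_cohort(
    path,
    schema: Sequence[FeatureSpec],
    missing_values: Iterable[str] = ("",),
    drop_missing_outcome: bool = False,
) -> CohortTable:
    """Read a cohort CSV against a declared schema.

    Empty cells (or any configured sentinel, e.g. ``"NA"``) denote missing.
    Patients with zero observed ``cluster_input`` features are excluded with
    a warning recorded in the returned table's ``log``.  With
    ``drop_missing_outcome`` patients lacking the outcome are excluded as
    well (otherwise they are retained for clustering and only dropped at
    the outcome-evaluation stage).
    """
    validate_schema(schema)
    sentinels = set(missing_values)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    names = [f.name for f in schema]
    unknown = [c for c in df.columns if c not in names]
    if unknown:
        raise SchemaError(f"unknown column(s) in CSV not declared in schema: {unknown}")
    absent = [n for n in names if n not in df.columns]
    if absent:
        raise SchemaError(f"schema column(s) absent from CSV: {absent}")
    df = df[names]

    n = len(df)
    records = {}
    mask = {}
    for spec in schema:
        vals: list[Any] = []
        obs = np.empty(n, dtype=bool)
        for i, raw in enumerate(df[spec.name]):
            if raw in sentinels:
                vals.append(np.nan if spec.kind == "continuous" else None)
                obs[i] = False
            else:
                vals.append(_parse_cell(raw, spec, i))
                obs[i] = True
        records[spec.name] = vals
        mask[spec.name] = obs
    rec_df = pd.DataFrame(records, columns=names)
    mask_df = pd.DataFrame(mask, columns=names)

    log: list[str] = []
    ci = [f.name for f in schema if f.role == "cluster_input"]
    keep = mask_df[ci].to_numpy().any(axis=1) if ci else np.ones(n, dtype=bool)
    if not keep.all():
        excluded = np.flatnonzero(~keep)
        id_col = next(f.name for f in schema if f.role == "id")
        for i in excluded:
            log.append(
                f"excluded patient {rec_df[id_col].iloc[i]!r} (row {i}): "
                "no observed cluster_input feature"
            )
        warnings.warn(
            f"excluded {len(excluded)} patient(s) with no observed cluster_input feature",
            UserWarning,
            stacklevel=2,
        )
    outcome = next((f.name for f in schema if f.role == "outcome"), None)
    if drop_missing_outcome and outcome is not None:
        miss_out = ~mask_df[outcome].to_numpy()
        drop = keep & miss_out
        if drop.any():
            log.append(f"excluded {int(drop.sum())} patient(s) with missing outcome")
        keep &= ~miss_out
    rec_df = rec_df.loc[keep].reset_index(drop=True)
    mask_df = mask_df.loc[keep].reset_index(drop=True)
    return CohortTable(schema, rec_df, mask_df, log)


def write_cohort(cohort: CohortTable, path, missing_sentinel: str = "") -> None:
    """Write a cohort to CSV; masked cells are written as the sentinel."""
    out = {}
    for spec in cohort.schema:
        col = cohort.records[spec.name]
        m = cohort.mask[spec.name].to_numpy()
        vals = []
        for i, v in enumerate(col):
            if not m[i]:
                vals.append(missing_sentinel)
            elif spec.kind == "continuous":
                vals.append(repr(float(v)))
            else:
                vals.append(str(v))
        out[spec.name] = vals
    pd.DataFrame(out).to_csv(path, index=False)


def completeness_report(cohort: CohortTable) -> pd.DataFrame:
    """Per-feature observed counts and fractions (one row per feature)."""
    n = cohort.n_patients
    rows = []
    for f in cohort.schema:
        obs = int(cohort.mask[f.name].sum())
        rows.append(
            {
                "feature": f.name,
                "n_observed": obs,
                "n_missing": n - obs,
                "fraction_observed": obs / n if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)
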