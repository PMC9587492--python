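"""Feature tables, schemas and cost partitioning.

A :class:`FeatureTable` is a record×feature matrix of numeric codes with NaN
marking missing cells, plus an optional binary frailty label.  A
:class:`FeatureSchema` declares, per feature, its cost of acquisition
(``low`` — routinely collected administrative data, or ``high`` — requires
chart review / clinician effort), its value domain, and its provenance
(``administrative``, ``deficit``, or ``derived`` — an automatable combination
of administrative features).  The schema also carries the eFI configuration.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import train_test_split

from .efi import EFIConfig
from .expressions import ExpressionError, evaluate_expression, referenced_names

RECORD_ID_COLUMN = "record_id"
COST_CLASSES = ("low", "high")
SOURCES = ("administrative", "deficit", "derived")
_ORDINAL_RE = re.compile(r"^ordinal\((\d+)\)$")


class SchemaError(ValueError):
    """Schema/table inconsistency (unknown features, bad domains, ...)."""


@dataclass(frozen=True)
class FeatureSpec:
    """Declaration of a single feature column."""

    name: str
    cost_class: str
    domain: str  # "binary" | "ordinal(k)" | "continuous"
    source: str
    definition: str | None = None  # expression, derived features only

    def __post_init__(self) -> None:
        if self.cost_class not in COST_CLASSES:
            raise SchemaError(f"{self.name}: cost_class must be one of {COST_CLASSES}")
        if self.source not in SOURCES:
            raise SchemaError(f"{self.name}: source must be one of {SOURCES}")
        if self.domain not in ("binary", "continuous") and not _ORDINAL_RE.match(self.domain):
            raise SchemaError(f"{self.name}: bad domain {self.domain!r}")
        if self.source == "derived" and not self.definition:
            raise SchemaError(f"{self.name}: derived feature needs a definition")

    @property
    def n_levels(self) -> int | None:
        if self.domain == "binary":
            return 2
        match = _ORDINAL_RE.match(self.domain)
        return int(match.group(1)) if match else None

    @property
    def is_continuous(self) -> bool:
        return self.domain == "continuous"


@dataclass
class FeatureSchema:
    """Ordered collection of :class:`FeatureSpec` plus the eFI configuration."""

    features: dict[str, FeatureSpec]
    efi: EFIConfig | None = None
    label_name: str = "frail"

    def __post_init__(self) -> None:
        for name, spec in self.features.items():
            if name != spec.name:
                raise SchemaError(f"schema key {name!r} != spec name {spec.name!r}")
        # derived features may only reference administrative features
        for spec in self.derived_features():
            for ref in referenced_names(spec.definition or ""):
                target = self.features.get(ref)
                if target is None:
                    raise SchemaError(f"{spec.name}: definition references unknown feature {ref!r}")
                if target.source != "administrative":
                    raise SchemaError(
                        f"{spec.name}: derived features may only reference administrative "
                        f"features, not {ref!r} ({target.source})"
                    )

    def derived_features(self) -> list[FeatureSpec]:
        return [s for s in self.features.values() if s.source == "derived"]

    def partition(self, feature_names: Iterable[str] | None = None) -> "CostPartition":
        """Cost partition restricted to *feature_names* (default: all)."""
        names = list(feature_names) if feature_names is not None else list(self.features)
        unknown = [n for n in names if n not in self.features]
        if unknown:
            raise SchemaError(f"features not in schema: {unknown}")
        low = tuple(n for n in names if self.features[n].cost_class == "low")
        high = tuple(n for n in names if self.features[n].cost_class == "high")
        return CostPartition(low_cost=low, high_cost=high)

    def to_dict(self) -> dict:
        payload: dict = {
            "features": [
                {
                    k: v
                    for k, v in {
                        "name": s.name,
                        "cost_class": s.cost_class,
                        "domain": s.domain,
                        "source": s.source,
                        "definition": s.definition,
                    }.items()
                    if v is not None
                }
                for s in self.features.values()
            ],
            "label": self.label_name,
        }
        if self.efi is not None:
            payload["efi"] = self.efi.to_dict()
        return payload

    @classmethod
    def from_dict(cls, payload: Mapping) -> "FeatureSchema":
        specs = {}
        for entry in payload["features"]:
            spec = FeatureSpec(**entry)
            if spec.name in specs:
                raise SchemaError(f"duplicate feature {spec.name!r} in schema")
            specs[spec.name] = spec
        efi = EFIConfig.from_dict(payload["efi"]) if "efi" in payload else None
        return cls(features=specs, efi=efi, label_name=payload.get("label", "frail"))

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "FeatureSchema":
        # YAML is a superset of JSON, so one loader covers both formats
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class CostPartition:
    """Disjoint low-/high-cost feature name sets, in schema order."""

    low_cost: tuple[str, ...]
    high_cost: tuple[str, ...]

    def __post_init__(self) -> None:
        overlap = set(self.low_cost) & set(self.high_cost)
        if overlap:
            raise SchemaError(f"features in both cost classes: {sorted(overlap)}")


@dataclass
class FeatureTable:
    """Record×feature matrix with NaN missingness and optional binary label."""

    values: pd.DataFrame
    label: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise SchemaError(f"duplicate feature columns: {dupes}")
        self.values = self.values.astype(float)
        if self.label is not None:
            if len(self.label) != len(self.values):
                raise SchemaError("label length does not match number of records")
            lab = pd.Series(self.label, index=self.values.index)
            bad = set(lab.dropna().unique()) - {0, 1}
            if bad:
                raise SchemaError(f"label must be binary 0/1, found {sorted(bad)}")
            self.label = lab.astype(int)

    @property
    def record_ids(self) -> list:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_records(self) -> int:
        return len(self.values)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def select_features(self, names: Sequence[str]) -> "FeatureTable":
        unknown = [n for n in names if n not in self.values.columns]
        if unknown:
            raise SchemaError(f"unknown feature(s): {unknown}")
        return replace(self, values=self.values[list(names)])

    def take(self, ids: Sequence) -> "FeatureTable":
        label = self.label.loc[ids] if self.label is not None else None
        return replace(self, values=self.values.loc[ids], label=label)


# ---------------------------------------------------------------------------
# I/O


def _parse_column(raw: pd.Series, spec: FeatureSpec) -> pd.Series:
    values = pd.to_numeric(raw.replace("", np.nan), errors="coerce")
    observed = values.dropna()
    if spec.domain == "binary":
        bad = set(observed.unique()) - {0.0, 1.0}
        if bad:
            raise SchemaError(f"{spec.name}: binary feature has values {sorted(bad)}")
    elif spec.n_levels is not None:
        k = spec.n_levels
        bad = observed[(observed < 0) | (observed >= k) | (observed % 1 != 0)]
        if len(bad):
            raise SchemaError(
                f"{spec.name}: ordinal({k}) feature has out-of-domain values "
                f"{sorted(set(bad))[:5]}"
            )
    return values


def load_table(table_path: str | Path, schema_path: str | Path) -> tuple[FeatureTable, FeatureSchema]:
    """Load a CSV feature table with its sidecar schema.

    Empty or unparseable cells become missing; categorical domains are
    validated against the schema.  Derived features may be absent from the
    CSV (they can be recomputed with :func:`apply_derived_features`); every
    other schema entry must have a column.
    """
    schema = FeatureSchema.load(schema_path)
    raw = pd.read_csv(table_path, dtype=str, keep_default_na=False)
    if RECORD_ID_COLUMN not in raw.columns:
        raise SchemaError(f"table is missing the {RECORD_ID_COLUMN!r} column")
    feature_cols = [c for c in raw.columns if c not in (RECORD_ID_COLUMN, schema.label_name)]
    unknown = [c for c in feature_cols if c not in schema.features]
    if unknown:
        raise SchemaError(f"CSV column(s) not declared in schema: {unknown}")
    absent = [
        n
        for n, s in schema.features.items()
        if n not in feature_cols and s.source != "derived"
    ]
    if absent:
        raise SchemaError(f"schema feature(s) without a CSV column: {absent}")
    frame = pd.DataFrame(index=raw[RECORD_ID_COLUMN].tolist())
    for name in feature_cols:
        frame[name] = _parse_column(
            pd.Series(raw[name].tolist(), index=frame.index), schema.features[name]
        )
    label = None
    if schema.label_name in raw.columns:
        lab = pd.to_numeric(
            pd.Series(raw[schema.label_name].tolist(), index=frame.index).replace("", np.nan),
            errors="coerce",
        )
        bad = set(lab.dropna().unique()) - {0.0, 1.0}
        if bad or lab.isna().any():
            raise SchemaError(f"non-binary label values in column {schema.label_name!r}")
        label = lab.astype(int)
    return FeatureTable(values=frame, label=label), schema


def write_table(
    table: FeatureTable,
    schema: FeatureSchema,
    table_path: str | Path,
    schema_path: str | Path | None = None,
) -> None:
    """Write the table as CSV (empty string = missing) and, optionally, the schema."""
    out = table.values.copy()
    out.insert(0, RECORD_ID_COLUMN, table.record_ids)
    if table.label is not None:
        out[schema.label_name] = table.label.values
    out.to_csv(table_path, index=False, na_rep="")
    if schema_path is not None:
        schema.save(schema_path)


# ---------------------------------------------------------------------------
# Transformations


def missingness_filter(
    table: FeatureTable, max_missing_fraction: float = 0.30
) -> tuple[FeatureTable, pd.DataFrame]:
    """Drop features whose missing fraction exceeds the threshold.

    Returns the filtered table and an exclusion report listing each dropped
    feature with its missing fraction.  Idempotent at a fixed threshold.
    """
    if not 0.0 <= max_missing_fraction < 1.0:
        raise ValueError("max_missing_fraction must lie in [0, 1)")
    fractions = table.values.isna().mean(axis=0)
    dropped = fractions[fractions > max_missing_fraction]
    if len(dropped) == table.n_features:
        raise ValueError(
            f"all features exceed the missingness threshold {max_missing_fraction}"
        )
    report = pd.DataFrame(
        {"feature": dropped.index, "missing_fraction": dropped.values}
    ).reset_index(drop=True)
    kept = [n for n in table.feature_names if n not in set(dropped.index)]
    return table.select_features(kept), report


def apply_derived_features(table: FeatureTable, schema: FeatureSchema) -> FeatureTable:
    """Compute/refresh derived columns from their administrative inputs.

    A derived cell is masked whenever any referenced feature is masked for
    that record.  Recomputing is idempotent: existing derived columns are
    overwritten in place.
    """
    values = table.values.copy()
    for spec in schema.derived_features():
        try:
            series = evaluate_expression(spec.definition or "", values)
        except ExpressionError as exc:
            raise SchemaError(f"{spec.name}: {exc}") from exc
        values[spec.name] = series
    return replace(table, values=values)


def split_train_test(
    table: FeatureTable,
    test_fraction: float = 0.25,
    stratify: bool = True,
    seed: int = 0,
) -> tuple[FeatureTable, FeatureTable]:
    """Disjoint, exhaustive train/test split of the records.

    With ``stratify`` the per-class test fractions are within one record of
    the target.  Identical seeds give identical splits.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction must lie in (0, 1), got {test_fraction}")
    if stratify and table.label is None:
        raise ValueError("stratified split requires a label")
    strat = table.label.values if stratify else None
    train_ids, test_ids = train_test_split(
        table.record_ids,
        test_size=test_fraction,
        stratify=strat,
        random_state=seed,
        shuffle=True,
    )
    return table.take(train_ids), table.take(test_ids)


def fit_imputer(table: FeatureTable, schema: FeatureSchema | None = None) -> dict[str, float]:
    """Per-feature fill values learned from *table* (normally the training split).

    Continuous features use the median; categorical codes use the mode
    (smallest on ties).  Features with no observed values get no fill and
    will raise at :func:`apply_imputer` time.
    """
    fills: dict[str, float] = {}
    for name in table.feature_names:
        col = table.values[name].dropna()
        if col.empty:
            continue
        spec = schema.features.get(name) if schema is not None else None
        if spec is not None and spec.is_continuous:
            fills[name] = float(col.median())
        else:
            fills[name] = float(col.mode().min())
    return fills


def apply_imputer(table: FeatureTable, fills: Mapping[str, float]) -> FeatureTable:
    """Fill every missing cell from *fills*; error if a column cannot be completed."""
    values = table.values.copy()
    for name in table.feature_names:
        if values[name].isna().any():
            if name not in fills:
                raise ValueError(f"no fill value available for feature {name!r}")
            values[name] = values[name].fillna(fills[name])
    return replace(table, values=values)
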