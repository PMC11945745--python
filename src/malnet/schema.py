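"""Cohort schema: the single source of truth for feature encoding order.

A clinical cohort is a rectangular table (one row per patient) whose
columns are demographic variables, laboratory indices, binary symptom
indicators and five binary subtype labels.  :class:`FeatureSchema`
declares every column once — its name, its kind (continuous / binary /
categorical) and, for categorical features, the ordered category codes —
and from that declaration derives a deterministic encoded column order:

* continuous feature  -> one min-max-scaled column
* binary feature      -> one 0/1 column
* categorical feature -> one 0/1 column per declared category

Two cohorts encoded under the same schema therefore always share the
same column layout.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

CONTINUOUS = "continuous"
BINARY = "binary"
CATEGORICAL = "categorical"
_KINDS = (CONTINUOUS, BINARY, CATEGORICAL)

#: value written for a missing cell in cohort CSV files
MISSING_TOKENS = ("", "NA")


class SchemaError(ValueError):
    """Invalid schema declaration or schema/data mismatch."""


@dataclass(frozen=True)
class FeatureDef:
    """One input column: its name, kind and (for categoricals) codes."""

    name: str
    kind: str
    categories: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise SchemaError(f"unknown feature kind {self.kind!r} "
                              f"for feature {self.name!r}")
        if self.kind == CATEGORICAL and len(self.categories) < 2:
            raise SchemaError(f"categorical feature {self.name!r} needs "
                              f">= 2 categories, got {self.categories!r}")
        if self.kind != CATEGORICAL and self.categories:
            raise SchemaError(f"feature {self.name!r} of kind {self.kind!r} "
                              "must not declare categories")


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered feature declarations plus the five subtype label names."""

    features: tuple[FeatureDef, ...]
    label_names: tuple[str, ...]

    def __post_init__(self):
        if not self.features:
            raise SchemaError("schema declares no features")
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate feature names in schema")
        if len(set(self.label_names)) != len(self.label_names):
            raise SchemaError("duplicate label names in schema")
        if set(names) & set(self.label_names):
            raise SchemaError("label names overlap feature names")

    # -- lookups ----------------------------------------------------------

    @property
    def feature_names(self) -> list[str]:
        return [f.name for f in self.features]

    def feature(self, name: str) -> FeatureDef:
        for f in self.features:
            if f.name == name:
                return f
        raise SchemaError(f"unknown feature {name!r}")

    def continuous_features(self) -> list[FeatureDef]:
        return [f for f in self.features if f.kind == CONTINUOUS]

    def binary_features(self) -> list[FeatureDef]:
        return [f for f in self.features if f.kind == BINARY]

    def categorical_features(self) -> list[FeatureDef]:
        return [f for f in self.features if f.kind == CATEGORICAL]

    # -- encoding layout --------------------------------------------------

    def encoded_columns(self) -> list[str]:
        """Deterministic encoded column order for this schema."""
        cols: list[str] = []
        for f in self.features:
            if f.kind == CATEGORICAL:
                cols.extend(f"{f.name}={c}" for c in f.categories)
            else:
                cols.append(f.name)
        return cols

    @property
    def n_encoded(self) -> int:
        return len(self.encoded_columns())

    @property
    def n_labels(self) -> int:
        return len(self.label_names)

    def fingerprint(self) -> str:
        """Stable hash of the schema; used to guard checkpoint loading."""
        payload = json.dumps(
            {"features": [[f.name, f.kind, list(f.categories)]
                          for f in self.features],
             "labels": list(self.label_names)},
            sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "features": {
                f.name: ({"kind": f.kind, "categories": list(f.categories)}
                         if f.kind == CATEGORICAL else {"kind": f.kind})
                for f in self.features
            },
            "feature_order": self.feature_names,
            "labels": list(self.label_names),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSchema":
        order = d.get("feature_order") or list(d["features"])
        feats = []
        for name in order:
            spec = d["features"][name]
            feats.append(FeatureDef(
                name=name, kind=spec["kind"],
                categories=tuple(str(c) for c in spec.get("categories", ()))))
        return cls(features=tuple(feats), label_names=tuple(d["labels"]))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FeatureSchema":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# -- cohort table I/O -----------------------------------------------------

FLOAT_FORMAT = "%.10g"  # documented CSV float precision


def validate_cohort(df: pd.DataFrame, schema: FeatureSchema,
                    require_labels: bool = True) -> None:
    """Check a cohort table against a schema; raise SchemaError if off."""
    missing_cols = [f.name for f in schema.features if f.name not in df.columns]
    if missing_cols:
        raise SchemaError(f"cohort lacks feature columns: {missing_cols}")
    if require_labels:
        missing_lab = [l for l in schema.label_names if l not in df.columns]
        if missing_lab:
            raise SchemaError(f"cohort lacks label columns: {missing_lab}")
        lab = df[list(schema.label_names)]
        if lab.isna().any().any() or not lab.isin([0, 1]).all().all():
            raise SchemaError("label columns must be complete and 0/1")
    for f in schema.binary_features():
        observed = df[f.name].dropna()
        if not observed.isin([0, 1]).all():
            raise SchemaError(f"binary feature {f.name!r} has values "
                              "outside {0, 1}")
    for f in schema.categorical_features():
        observed = set(df[f.name].dropna().astype(str))
        unknown = observed - set(f.categories)
        if unknown:
            raise SchemaError(f"categorical feature {f.name!r} has "
                              f"undeclared codes {sorted(unknown)}")


def read_cohort(path: str | Path, schema: FeatureSchema | None = None,
                require_labels: bool = True) -> pd.DataFrame:
    """Read a cohort CSV (missing cells as empty string or 'NA')."""
    df = pd.read_csv(path, na_values=list(MISSING_TOKENS),
                     keep_default_na=False, dtype=None)
    if schema is not None:
        for f in schema.categorical_features():
            if f.name in df.columns:
                df[f.name] = df[f.name].map(
                    lambda v: v if pd.isna(v) else _canon(v))
        validate_cohort(df, schema, require_labels=require_labels)
    return df


def _canon(v) -> str:
    """Canonical string form of a category code ('3' and 3.0 agree)."""
    if isinstance(v, float) and v.is_integer():
        return str(int(v))
    return str(v)


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort CSV; missing cells become empty strings."""
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT, na_rep="")
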