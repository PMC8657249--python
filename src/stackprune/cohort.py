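"""Tabular cohort handling: schema, loading, splitting, balancing, encoding.

A cohort is one row per subject, ``p`` typed feature columns (categorical,
ordinal or continuous) and one binary outcome column.  All downstream stages
consume the :class:`CohortTable` produced here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

VALID_KINDS = ("categorical", "ordinal", "continuous")


class SchemaError(ValueError):
    """Raised when input data does not match the declared schema."""


class CohortValidationError(ValueError):
    """Raised when cohort values violate the schema contract."""


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered feature names with per-feature kinds and the outcome column.

    Parameters
    ----------
    feature_names
        Ordered, unique feature identifiers.
    feature_kinds
        One of ``{"categorical", "ordinal", "continuous"}`` per feature.
    outcome_name
        Name of the binary outcome column; must not be a feature.
    """

    feature_names: tuple[str, ...]
    feature_kinds: tuple[str, ...]
    outcome_name: str

    def __post_init__(self) -> None:
        names = tuple(self.feature_names)
        kinds = tuple(self.feature_kinds)
        object.__setattr__(self, "feature_names", names)
        object.__setattr__(self, "feature_kinds", kinds)
        if len(names) != len(kinds):
            raise SchemaError(
                f"{len(names)} feature names but {len(kinds)} kinds"
            )
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise SchemaError(f"duplicate feature names: {dupes}")
        for name, kind in zip(names, kinds):
            if kind not in VALID_KINDS:
                raise SchemaError(f"feature {name!r} has invalid kind {kind!r}")
        if self.outcome_name in names:
            raise SchemaError(
                f"outcome {self.outcome_name!r} is also a feature"
            )

    @property
    def p(self) -> int:
        return len(self.feature_names)

    def kind_of(self, name: str) -> str:
        try:
            return self.feature_kinds[self.feature_names.index(name)]
        except ValueError:
            raise KeyError(f"unknown feature {name!r}") from None

    @classmethod
    def from_mapping(cls, cfg: Mapping) -> "FeatureSchema":
        """Build from ``{"features": {name: kind, ...}, "outcome": name}``."""
        features = cfg["features"]
        return cls(
            feature_names=tuple(features),
            feature_kinds=tuple(features[n] for n in features),
            outcome_name=cfg["outcome"],
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FeatureSchema":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    def to_mapping(self) -> dict:
        return {
            "features": dict(zip(self.feature_names, self.feature_kinds)),
            "outcome": self.outcome_name,
        }


@dataclass
class CohortTable:
    """Validated feature table plus binary outcome labels.

    ``records`` holds the feature columns in schema order; ``labels`` is an
    integer array of 0/1 aligned with the rows.
    """

    schema: FeatureSchema
    records: pd.DataFrame
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if len(self.records) != len(self.labels):
            raise CohortValidationError(
                f"{len(self.records)} records but {len(self.labels)} labels"
            )
        bad = ~np.isin(self.labels, (0, 1))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise CohortValidationError(
                f"non-binary outcome value {self.labels[row]!r} at row {row}"
            )
        self.labels = self.labels.astype(np.int64)
        missing = [c for c in self.schema.feature_names if c not in self.records.columns]
        if missing:
            raise SchemaError(f"records missing feature columns: {missing}")
        self.records = self.records.loc[:, list(self.schema.feature_names)].reset_index(
            drop=True
        )

    @property
    def n(self) -> int:
        return len(self.labels)

    def class_counts(self) -> dict[int, int]:
        values, counts = np.unique(self.labels, return_counts=True)
        return {int(v): int(c) for v, c in zip(values, counts)}

    def subset(self, idx: Sequence[int]) -> "CohortTable":
        idx = np.asarray(idx)
        return CohortTable(
            schema=self.schema,
            records=self.records.iloc[idx].reset_index(drop=True),
            labels=self.labels[idx],
        )


@dataclass(frozen=True)
class SplitIndices:
    """Disjoint train/test row indices covering the whole cohort."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        tr = np.asarray(self.train_idx)
        te = np.asarray(self.test_idx)
        object.__setattr__(self, "train_idx", tr)
        object.__setattr__(self, "test_idx", te)
        if np.intersect1d(tr, te).size:
            raise CohortValidationError("train and test indices overlap")

    def to_frame(self) -> pd.DataFrame:
        n = len(self.train_idx) + len(self.test_idx)
        part = np.empty(n, dtype=object)
        part[self.train_idx] = "train"
        part[self.test_idx] = "test"
        return pd.DataFrame({"row_index": np.arange(n), "partition": part})


def load_cohort(path: str | Path, schema: FeatureSchema) -> CohortTable:
    """Read a CSV cohort file and validate it against *schema*.

    Row order is preserved.  Raises :class:`SchemaError` for missing columns
    and :class:`CohortValidationError` (citing the row) for non-binary
    outcome values.
    """
    df = pd.read_csv(path)
    missing = [
        c
        for c in (*schema.feature_names, schema.outcome_name)
        if c not in df.columns
    ]
    if missing:
        raise SchemaError(f"cohort file {path} missing columns: {missing}")
    labels_raw = df[schema.outcome_name].to_numpy()
    bad = ~np.isin(labels_raw, (0, 1))
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise CohortValidationError(
            f"non-binary outcome value {labels_raw[row]!r} at row {row}"
        )
    return CohortTable(
        schema=schema,
        records=df[list(schema.feature_names)],
        labels=labels_raw,
    )


def split_cohort(
    cohort: CohortTable,
    train_frac: float = 0.6,
    seed: int = 0,
    stratify: bool = True,
) -> SplitIndices:
    """Randomly split the cohort into train/test index sets.

    ``|train| = round(train_frac * n)``.  With ``stratify=True`` the per-class
    train counts are apportioned by largest remainder so each class proportion
    is preserved within one case.  Deterministic for a fixed *seed*.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError(f"train_frac must be in (0, 1), got {train_frac}")
    n = cohort.n
    if n < 2:
        raise ValueError("need at least two rows to split")
    rng = np.random.default_rng(seed)
    n_train = int(round(train_frac * n))

    if not stratify:
        perm = rng.permutation(n)
        train = np.sort(perm[:n_train])
        test = np.sort(perm[n_train:])
        if len(np.unique(cohort.labels[train])) < 2:
            warnings.warn(
                "unstratified split produced a single-class training set",
                stacklevel=2,
            )
        return SplitIndices(train_idx=train, test_idx=test, seed=seed)

    classes = np.unique(cohort.labels)
    raw = {
        c: train_frac * int((cohort.labels == c).sum()) for c in classes
    }
    take = {c: int(np.floor(v)) for c, v in raw.items()}
    short = n_train - sum(take.values())
    # distribute the remainder to classes with the largest fractional part
    for c in sorted(classes, key=lambda c: raw[c] - take[c], reverse=True):
        if short <= 0:
            break
        take[c] += 1
        short -= 1
    train_parts = []
    for c in classes:
        members = np.flatnonzero(cohort.labels == c)
        perm = rng.permutation(members)
        train_parts.append(perm[: take[c]])
    train = np.sort(np.concatenate(train_parts))
    test = np.sort(np.setdiff1d(np.arange(n), train))
    return SplitIndices(train_idx=train, test_idx=test, seed=seed)


def upsample_minority(cohort: CohortTable, seed: int = 0) -> CohortTable:
    """Resample minority-class rows with replacement until classes balance.

    Majority rows are untouched; the original minority rows are kept and
    extra draws are appended, so post-upsampling prevalence is exactly 0.5.
    """
    counts = cohort.class_counts()
    if len(counts) < 2:
        raise CohortValidationError("upsampling requires both classes present")
    minority = min(counts, key=counts.get)
    deficit = counts[1 - minority] - counts[minority]
    if deficit == 0:
        return cohort
    rng = np.random.default_rng(seed)
    pool = np.flatnonzero(cohort.labels == minority)
    extra = rng.choice(pool, size=deficit, replace=True)
    idx = np.concatenate([np.arange(cohort.n), extra])
    return cohort.subset(idx)


class FeatureEncoder:
    """Frozen mixed-type encoding map: fit on train, reuse verbatim on test.

    categorical -> one-hot indicators over levels observed at fit time
    (reference level dropped when ``drop_reference``); ordinal -> integer
    codes (numeric ordinals pass through); continuous -> passthrough.
    Unseen categorical levels at transform time map to all-zero indicators
    with a warning.
    """

    def __init__(self, schema: FeatureSchema, drop_reference: bool = True):
        self.schema = schema
        self.drop_reference = drop_reference
        self.levels_: dict[str, list] = {}
        self.ordinal_codes_: dict[str, dict] = {}
        self.columns_: list[str] = []
        self.groups_: dict[str, list[int]] = {}
        self.fitted_ = False

    def fit(self, records: pd.DataFrame) -> "FeatureEncoder":
        self.levels_.clear()
        self.ordinal_codes_.clear()
        cols: list[str] = []
        groups: dict[str, list[int]] = {}
        for name, kind in zip(self.schema.feature_names, self.schema.feature_kinds):
            start = len(cols)
            if kind == "categorical":
                levels = sorted(pd.unique(records[name]).tolist(), key=str)
                self.levels_[name] = levels
                emit = levels[1:] if self.drop_reference and len(levels) > 1 else levels
                cols.extend(f"{name}={lv}" for lv in emit)
            elif kind == "ordinal":
                if pd.api.types.is_numeric_dtype(records[name]):
                    self.ordinal_codes_[name] = {}
                else:
                    levels = sorted(pd.unique(records[name]).tolist(), key=str)
                    self.ordinal_codes_[name] = {lv: i for i, lv in enumerate(levels)}
                cols.append(name)
            else:
                cols.append(name)
            groups[name] = list(range(start, len(cols)))
        self.columns_ = cols
        self.groups_ = groups
        self.fitted_ = True
        return self

    def transform(self, records: pd.DataFrame) -> pd.DataFrame:
        if not self.fitted_:
            raise RuntimeError("encoder not fitted")
        out = np.zeros((len(records), len(self.columns_)), dtype=np.float64)
        col_of = {c: j for j, c in enumerate(self.columns_)}
        for name, kind in zip(self.schema.feature_names, self.schema.feature_kinds):
            values = records[name]
            if kind == "categorical":
                levels = self.levels_[name]
                known = set(levels)
                unseen = sorted({v for v in pd.unique(values) if v not in known}, key=str)
                if unseen:
                    warnings.warn(
                        f"feature {name!r}: unseen levels {unseen} mapped to "
                        "all-zero reference",
                        stacklevel=2,
                    )
                emit = levels[1:] if self.drop_reference and len(levels) > 1 else levels
                for lv in emit:
                    out[:, col_of[f"{name}={lv}"]] = (values == lv).to_numpy(float)
            elif kind == "ordinal":
                codes = self.ordinal_codes_[name]
                if codes:
                    out[:, col_of[name]] = values.map(codes).fillna(-1).to_numpy(float)
                else:
                    out[:, col_of[name]] = values.to_numpy(float)
            else:
                out[:, col_of[name]] = values.to_numpy(float)
        return pd.DataFrame(out, columns=self.columns_)

    def fit_transform(self, records: pd.DataFrame) -> pd.DataFrame:
        return self.fit(records).transform(records)


def encode_features(
    cohort: CohortTable, drop_reference: bool = True
) -> tuple[pd.DataFrame, FeatureEncoder]:
    """Fit an encoder on the cohort and return (design matrix, encoder)."""
    enc = FeatureEncoder(cohort.schema, drop_reference=drop_reference)
    X = enc.fit_transform(cohort.records)
    return X, enc
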