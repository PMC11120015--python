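"""Data model for positive-unlabeled (PU) tabular datasets.

A PU dataset ``D = P_L + U`` holds labeled-positive instances ``P_L`` (and,
in benchmark data, labeled negatives) together with unlabeled instances
``U``.  Each instance carries an *observed* label — what the learner sees —
and, when known, a hidden *true* label retained purely for evaluation, so
that masked instances can still be scored in cross-validation.

This module provides the container types, CSV/ARFF readers, CSV writing,
seeded label masking (the device that simulates the PU setting on fully
labeled data), and the 20-instance two-feature teaching example used
throughout the test-suite and documentation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

POSITIVE = "positive"
NEGATIVE = "negative"
UNLABELED = "unlabeled"
UNKNOWN = "unknown"

#: sentinel for a missing feature value
MISSING = None

#: tokens treated as missing when reading CSV ("?" is the ARFF convention)
MISSING_TOKENS = ("?", "")


class NpuludError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(NpuludError):
    """Instance/feature structure does not match the dataset schema."""


class DomainError(NpuludError):
    """Label values violate the binary-classification contract."""


class InputError(NpuludError):
    """Malformed or empty input file."""


class ParameterError(NpuludError):
    """A configuration parameter is out of its valid range."""


class FormatError(NpuludError):
    """A serialized artifact cannot be parsed."""


@dataclass(frozen=True)
class FeatureSpec:
    """Schema of one feature dimension.

    ``observed_range`` (numeric features) is the (min, max) over non-missing
    training values, used for min-max distance normalization.
    """

    name: str
    kind: str  # "numeric" | "categorical"
    categories: tuple[str, ...] = ()
    observed_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("numeric", "categorical"):
            raise SchemaError(f"unknown feature kind {self.kind!r}")
        if self.kind == "categorical":
            if not self.categories:
                raise SchemaError(f"categorical feature {self.name!r} needs categories")
            if len(set(self.categories)) != len(self.categories):
                raise SchemaError(f"duplicate categories in feature {self.name!r}")
        if self.kind == "numeric" and self.observed_range is not None:
            lo, hi = self.observed_range
            if lo > hi:
                raise SchemaError(f"invalid range for feature {self.name!r}: {lo} > {hi}")


@dataclass(frozen=True)
class Instance:
    """One row: feature values plus observed and (optionally hidden) true label.

    In a dataset as read or masked, a labeled instance's observed label
    agrees with its true label (enforced at construction from files and
    fixtures).  After relabeling, the observed label is an *assignment* and
    may disagree with the retained truth — measuring that disagreement is
    how recovery is scored.
    """

    id: int
    values: tuple
    observed_label: str
    true_label: str = UNKNOWN

    def __post_init__(self) -> None:
        if self.observed_label not in (POSITIVE, NEGATIVE, UNLABELED):
            raise DomainError(f"bad observed label {self.observed_label!r}")
        if self.true_label not in (POSITIVE, NEGATIVE, UNKNOWN):
            raise DomainError(f"bad true label {self.true_label!r}")

    def consistent_with_truth(self) -> bool:
        """True when the observed label does not contradict the true label."""
        if self.observed_label in (POSITIVE, NEGATIVE):
            return self.true_label in (self.observed_label, UNKNOWN)
        return True


@dataclass
class PUDataset:
    """A PU dataset: feature schema plus instances (``D = P_L + U``)."""

    specs: list[FeatureSpec]
    instances: list[Instance]
    positive_class_name: str = POSITIVE
    negative_class_name: str = NEGATIVE
    label_column: str = "class"
    unlabeled_token: str = UNLABELED

    def __post_init__(self) -> None:
        ids = [inst.id for inst in self.instances]
        if len(set(ids)) != len(ids):
            raise SchemaError("instance ids are not unique")
        nfeat = len(self.specs)
        for inst in self.instances:
            if len(inst.values) != nfeat:
                raise SchemaError(
                    f"instance {inst.id} has {len(inst.values)} values, expected {nfeat}"
                )

    def __len__(self) -> int:
        return len(self.instances)

    @property
    def n_p(self) -> int:
        return sum(1 for i in self.instances if i.observed_label == POSITIVE)

    @property
    def n_u(self) -> int:
        return sum(1 for i in self.instances if i.observed_label == UNLABELED)

    @property
    def n_n(self) -> int:
        return sum(1 for i in self.instances if i.observed_label == NEGATIVE)

    def ids(self) -> list[int]:
        return [i.id for i in self.instances]

    def by_id(self, id_: int) -> Instance:
        for inst in self.instances:
            if inst.id == id_:
                return inst
        raise KeyError(id_)

    def subset(self, ids: Iterable[int]) -> "PUDataset":
        wanted = set(ids)
        return replace(self, instances=[i for i in self.instances if i.id in wanted])

    def copy(self) -> "PUDataset":
        return replace(self, instances=list(self.instances))

    def unmask(self) -> "PUDataset":
        """Restore observed labels from true labels (exact inverse of masking)."""
        out = []
        for inst in self.instances:
            if inst.observed_label == UNLABELED and inst.true_label != UNKNOWN:
                out.append(replace(inst, observed_label=inst.true_label))
            else:
                out.append(inst)
        return replace(self, instances=out)

    def to_dataframe(self, labels: str = "observed") -> pd.DataFrame:
        """Feature table plus the label column (observed or true labels)."""
        rows = {}
        for j, spec in enumerate(self.specs):
            rows[spec.name] = [inst.values[j] for inst in self.instances]
        if labels == "observed":
            rows[self.label_column] = [i.observed_label for i in self.instances]
        else:
            rows[self.label_column] = [i.true_label for i in self.instances]
        return pd.DataFrame(rows, index=self.ids())


# ---------------------------------------------------------------------------
# Reading and writing


def _infer_specs(df: pd.DataFrame) -> list[FeatureSpec]:
    specs = []
    for name in df.columns:
        col = df[name]
        nonmiss = col[~col.isin(MISSING_TOKENS) & col.notna()]
        numeric = pd.to_numeric(nonmiss, errors="coerce")
        if len(nonmiss) > 0 and not numeric.isna().any():
            specs.append(
                FeatureSpec(
                    name=str(name),
                    kind="numeric",
                    observed_range=(float(numeric.min()), float(numeric.max())),
                )
            )
        else:
            cats = tuple(dict.fromkeys(str(v) for v in nonmiss))
            specs.append(FeatureSpec(name=str(name), kind="categorical", categories=cats or ("",)))
    return specs


def _build_dataset(
    df: pd.DataFrame,
    label_column: str,
    positive_class_name: str,
    unlabeled_token: str,
) -> PUDataset:
    if label_column not in df.columns:
        raise SchemaError(f"label column {label_column!r} not found")
    labels = df[label_column].astype(str)
    distinct = set(labels)
    others = distinct - {positive_class_name, unlabeled_token}
    if len(others) > 1:
        raise DomainError(f"more than two classes: {sorted(distinct)}")
    negative_name = others.pop() if others else NEGATIVE

    feat = df.drop(columns=[label_column]).astype(object)
    feat = feat.where(~feat.isin(MISSING_TOKENS), other=np.nan)
    feat_str = feat.map(lambda v: None if pd.isna(v) else str(v))
    specs = _infer_specs(feat_str.fillna(""))

    instances = []
    for idx, (_, row) in enumerate(feat_str.iterrows(), start=1):
        values = []
        for spec in specs:
            raw = row[spec.name]
            if raw is None or raw == "":
                values.append(MISSING)
            elif spec.kind == "numeric":
                values.append(float(raw))
            else:
                values.append(raw)
        raw_label = labels.iloc[idx - 1]
        if raw_label == positive_class_name:
            obs, true = POSITIVE, POSITIVE
        elif raw_label == unlabeled_token:
            obs, true = UNLABELED, UNKNOWN
        else:
            obs, true = NEGATIVE, NEGATIVE
        instances.append(Instance(id=idx, values=tuple(values), observed_label=obs, true_label=true))

    return PUDataset(
        specs=specs,
        instances=instances,
        positive_class_name=positive_class_name,
        negative_class_name=negative_name,
        label_column=label_column,
        unlabeled_token=unlabeled_token,
    )


def read_table(
    path: str | Path,
    format: str = "csv",
    label_column: str = "class",
    positive_class_name: str = POSITIVE,
    unlabeled_token: str = UNLABELED,
) -> PUDataset:
    """Read a PU dataset from CSV (header row required) or ARFF.

    Label values must be ``positive_class_name``, ``unlabeled_token``, or
    exactly one other value (mapped to negative); a third class is a
    :class:`DomainError`.  "?" and empty cells are missing markers.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if format == "csv":
        try:
            df = pd.read_csv(path, dtype=str, keep_default_na=False)
        except pd.errors.EmptyDataError as exc:
            raise InputError(f"empty file: {path}") from exc
        if df.empty:
            raise InputError(f"no data rows in {path}")
    elif format == "arff":
        from scipy.io import arff as scipy_arff

        try:
            data, meta = scipy_arff.loadarff(str(path))
        except Exception as exc:  # scipy raises assorted parse errors
            raise FormatError(f"cannot parse ARFF file {path}: {exc}") from exc
        cols = {}
        for name in meta.names():
            col = data[name]
            if col.dtype.kind == "S":
                cols[name] = [v.decode() for v in col]
            else:
                cols[name] = ["" if np.isnan(v) else repr(float(v)) for v in col]
        df = pd.DataFrame(cols).astype(str)
        if df.empty:
            raise InputError(f"no data rows in {path}")
    else:
        raise ParameterError(f"unknown format {format!r}")
    return _build_dataset(df, label_column, positive_class_name, unlabeled_token)


def write_csv(dataset: PUDataset, path: str | Path) -> None:
    """Write the dataset back as CSV with observed labels (round-trips with
    :func:`read_table` for values, labels and feature kinds)."""
    path = Path(path)
    buf = io.StringIO()
    header = [s.name for s in dataset.specs] + [dataset.label_column]
    buf.write(",".join(header) + "\n")
    for inst in dataset.instances:
        cells = []
        for spec, v in zip(dataset.specs, inst.values):
            if v is MISSING:
                cells.append("?")
            elif spec.kind == "numeric":
                cells.append(repr(float(v)))
            else:
                cells.append(str(v))
        if inst.observed_label == POSITIVE:
            cells.append(dataset.positive_class_name)
        elif inst.observed_label == NEGATIVE:
            cells.append(dataset.negative_class_name)
        else:
            cells.append(dataset.unlabeled_token)
        buf.write(",".join(cells) + "\n")
    path.write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# Label masking


@dataclass(frozen=True)
class MaskingConfig:
    """How many labels to hide and with which seed.

    The masked count is ``round_half_up(ratio × n)``; selection is uniform
    without replacement from all instances regardless of class.
    """

    ratio: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.ratio <= 1.0):
            raise ParameterError(f"masking ratio {self.ratio} outside [0, 1]")

    def masked_count(self, n: int) -> int:
        exact = Decimal(str(self.ratio)) * n
        return int(exact.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def mask_labels(dataset: PUDataset, config: MaskingConfig) -> PUDataset:
    """Hide the labels of a seeded uniform subset of instances.

    True labels are preserved on every instance, so evaluation can always
    score against ground truth.  Same seed and ratio give the same selection.
    """
    if dataset.n_u > 0:
        raise ParameterError("dataset already contains unlabeled instances")
    n = len(dataset)
    m = config.masked_count(n)
    rng = np.random.default_rng(config.seed)
    ids = np.array(sorted(dataset.ids()))
    chosen = set(int(i) for i in rng.choice(ids, size=m, replace=False)) if m else set()
    out = []
    for inst in dataset.instances:
        if inst.id in chosen:
            out.append(replace(inst, observed_label=UNLABELED))
        else:
            out.append(inst)
    return replace(dataset, instances=out)


# ---------------------------------------------------------------------------
# The 20-instance teaching example

# (id, weight, count, class) — two numeric features, binary class.  The PU
# variant hides the labels of 12 of the 20 rows, leaving 8 observed
# positives; true labels are retained for every row.
_TOY_ROWS = [
    (1, 1, 6, POSITIVE),
    (2, 1, 9, POSITIVE),
    (3, 2, 1, POSITIVE),
    (4, 2, 3, POSITIVE),
    (5, 2, 10, POSITIVE),
    (6, 3, 4, POSITIVE),
    (7, 4, 2, POSITIVE),
    (8, 4, 6, POSITIVE),
    (9, 4, 7, POSITIVE),
    (10, 6, 4, POSITIVE),
    (11, 6, 11, NEGATIVE),
    (12, 7, 10, NEGATIVE),
    (13, 8, 2, POSITIVE),
    (14, 8, 5, NEGATIVE),
    (15, 8, 8, NEGATIVE),
    (16, 10, 12, NEGATIVE),
    (17, 10, 5, NEGATIVE),
    (18, 10, 8, NEGATIVE),
    (19, 11, 10, NEGATIVE),
    (20, 12, 6, NEGATIVE),
]

#: ids whose labels stay observed in the PU variant (all positives)
_TOY_PU_LABELED = {1, 3, 5, 6, 7, 9, 10, 13}


def toy_fixture(variant: str = "supervised") -> PUDataset:
    """The built-in 20-instance weight/count example.

    ``variant="supervised"``: all 20 labels observed (11 positive, 9
    negative).  ``variant="pu"``: only 8 positives keep their label, the
    other 12 rows are unlabeled; every row retains its true label.
    """
    if variant not in ("supervised", "pu"):
        raise ParameterError(f"unknown toy variant {variant!r}")
    weights = [float(r[1]) for r in _TOY_ROWS]
    counts = [float(r[2]) for r in _TOY_ROWS]
    specs = [
        FeatureSpec("weight", "numeric", observed_range=(min(weights), max(weights))),
        FeatureSpec("count", "numeric", observed_range=(min(counts), max(counts))),
    ]
    instances = []
    for id_, w, c, label in _TOY_ROWS:
        if variant == "supervised" or id_ in _TOY_PU_LABELED:
            obs = label
        else:
            obs = UNLABELED
        instances.append(
            Instance(id=id_, values=(float(w), float(c)), observed_label=obs, true_label=label)
        )
    return PUDataset(specs=specs, instances=instances)
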