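"""BI-RADS feature schema, sample-table I/O and min-max normalization.

The lexicon used throughout the package is a fixed set of 14 discrete
ultrasound descriptors (shape, orientation, margin properties, echo
pattern, posterior features, calcification, ...).  Each descriptor takes a
small set of consecutive integer scores starting at 0; a sample is one row
of 14 scores plus a benign/malignant label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BENIGN",
    "MALIGNANT",
    "LABEL_COLUMN",
    "FeatureSchema",
    "SampleTable",
    "NormalizedMatrix",
    "SchemaError",
    "ValidationError",
    "load_schema",
    "read_samples",
    "write_samples",
    "minmax_normalize",
    "encode_labels",
    "decode_labels",
]

#: Internal label encoding used by the boosting machinery.
BENIGN: int = 1
MALIGNANT: int = -1

LABEL_COLUMN = "label"

#: The default descriptor set: (name, number of consecutive integer levels).
_DEFAULT_FEATURES: tuple[tuple[str, int], ...] = (
    ("Shape", 3),                     # Oval, Round, Irregular
    ("Orientation", 2),               # Parallel, Not parallel
    ("Margin integrality", 2),        # Circumscribed, Not circumscribed
    ("Margin ambiguity", 2),          # Distinct, Indistinct
    ("Angular", 2),
    ("Microlobulated", 2),
    ("Spiculated", 2),
    ("Echo pattern", 6),              # Anechoic ... Hypoechoic
    ("Posterior feature", 4),         # Enhancement, None, Combined, Shadowing
    ("Calcification in mass", 4),     # Absent, Coarse, Scattered, Clustered
    ("Architectural distortion", 2),
    ("Ducts changes", 3),             # Normal, Cystic extension, Object in ducts
    ("Skin thickening", 2),
    ("Edema", 2),
)


class SchemaError(ValueError):
    """Raised for malformed feature-schema definitions."""


class ValidationError(ValueError):
    """Raised when sample data violates the feature schema."""


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered set of discrete features, each with consecutive 0-based levels.

    Parameters
    ----------
    features
        Sequence of ``(name, levels)`` pairs where ``levels`` is the ordered
        tuple of allowed integer scores, e.g. ``("Shape", (0, 1, 2))``.
    """

    features: tuple[tuple[str, tuple[int, ...]], ...]

    def __post_init__(self) -> None:
        names = [name for name, _ in self.features]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate feature names in schema")
        for name, levels in self.features:
            if len(levels) < 2:
                raise SchemaError(f"feature {name!r} must have >= 2 levels")
            if tuple(levels) != tuple(range(len(levels))):
                raise SchemaError(
                    f"feature {name!r}: levels {levels!r} are not consecutive "
                    "integers starting at 0"
                )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.features)

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_levels(self) -> tuple[int, ...]:
        return tuple(len(levels) for _, levels in self.features)

    def levels_of(self, name: str) -> tuple[int, ...]:
        for fname, levels in self.features:
            if fname == name:
                return levels
        raise KeyError(name)


def default_schema() -> FeatureSchema:
    """The standard 14-descriptor schema."""
    return FeatureSchema(
        tuple((name, tuple(range(k))) for name, k in _DEFAULT_FEATURES)
    )


def load_schema(spec: None | str | Path | Mapping | Sequence = None) -> FeatureSchema:
    """Build a :class:`FeatureSchema`.

    ``spec`` may be ``None`` (the default 14-feature schema), a mapping
    ``{name: n_levels}`` or ``{name: [0, 1, ...]}``, a sequence of
    ``(name, levels)`` pairs, or a path to a YAML/JSON file holding one of
    those forms.
    """
    if spec is None:
        return default_schema()
    if isinstance(spec, (str, Path)):
        text = Path(spec).read_text()
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            import yaml

            data = yaml.safe_load(text)
        return load_schema(data)
    if isinstance(spec, Mapping):
        items: list[tuple[str, tuple[int, ...]]] = []
        for name, levels in spec.items():
            if isinstance(levels, int):
                levels = tuple(range(levels))
            items.append((str(name), tuple(int(v) for v in levels)))
        return FeatureSchema(tuple(items))
    # sequence of (name, levels) pairs
    items = []
    for name, levels in spec:
        if isinstance(levels, int):
            levels = tuple(range(levels))
        items.append((str(name), tuple(int(v) for v in levels)))
    return FeatureSchema(tuple(items))


def encode_labels(raw: Iterable) -> np.ndarray:
    """Map label tokens to the internal +1 (benign) / -1 (malignant) coding.

    Accepts case-insensitive ``"benign"``/``"malignant"`` strings, the
    0/1 coding (0 = benign), or the internal +1/-1 coding itself.  Integer
    input is interpreted as a whole: a vector containing any -1 is taken as
    already internally coded; otherwise 0/1 coding is assumed.
    """
    toks = list(raw)
    numeric: list[int] = []
    for tok in toks:
        if isinstance(tok, str):
            t = tok.strip().lower()
            if t == "benign":
                numeric.append(BENIGN)
            elif t == "malignant":
                numeric.append(MALIGNANT)
            elif t in {"0", "1"}:
                numeric.append(BENIGN if t == "0" else MALIGNANT)
            else:
                raise ValidationError(f"unknown label token {tok!r}")
        else:
            v = int(tok)
            if v not in (-1, 0, 1):
                raise ValidationError(f"unknown label value {tok!r}")
            numeric.append(v)
    arr = np.asarray(numeric, dtype=np.int8)
    if (arr == 0).any():  # 0/1 coding: 0 = benign, 1 = malignant
        return np.where(arr == 0, BENIGN, MALIGNANT).astype(np.int8)
    return arr  # strings and/or internal +1/-1 coding


def decode_labels(encoded: np.ndarray) -> np.ndarray:
    """Inverse of :func:`encode_labels`, producing ``"benign"``/``"malignant"``."""
    return np.where(np.asarray(encoded) == BENIGN, "benign", "malignant")


@dataclass
class SampleTable:
    """N samples x 14 discrete feature scores plus a binary label.

    ``values`` is an integer matrix validated against ``schema``; ``labels``
    uses the internal +1 (benign) / -1 (malignant) coding.
    """

    values: np.ndarray
    labels: np.ndarray
    schema: FeatureSchema = field(default_factory=default_schema)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        n, f = self.values.shape
        if f != self.schema.n_features:
            raise ValidationError(
                f"expected {self.schema.n_features} feature columns, got {f}"
            )
        if self.labels.shape != (n,):
            raise ValidationError("labels length must match number of rows")
        bad = ~np.isin(self.labels, (BENIGN, MALIGNANT))
        if bad.any():
            raise ValidationError("labels must be +1 (benign) or -1 (malignant)")
        n_levels = np.asarray(self.schema.n_levels)
        out_lo = self.values < 0
        out_hi = self.values >= n_levels[np.newaxis, :]
        if out_lo.any() or out_hi.any():
            i, j = np.argwhere(out_lo | out_hi)[0]
            raise ValidationError(
                f"value {self.values[i, j]} out of range for feature "
                f"{self.schema.names[j]!r} at row {i}"
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_benign(self) -> int:
        return int((self.labels == BENIGN).sum())

    @property
    def n_malignant(self) -> int:
        return int((self.labels == MALIGNANT).sum())

    def subset(self, rows: np.ndarray) -> "SampleTable":
        rows = np.asarray(rows)
        return SampleTable(self.values[rows], self.labels[rows], self.schema)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.schema.names))
        df[LABEL_COLUMN] = decode_labels(self.labels)
        return df


def read_samples(
    path: str | Path,
    schema: FeatureSchema | None = None,
    sep: str = ",",
) -> SampleTable:
    """Read a delimited sample table (header row required).

    The file must contain one column per schema feature plus a ``label``
    column; extra columns are rejected to surface schema mismatches early.
    """
    schema = schema or default_schema()
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in (*schema.names, LABEL_COLUMN) if c not in df.columns]
    if missing:
        raise ValidationError(f"missing columns in {path}: {missing}")
    labels = encode_labels(df[LABEL_COLUMN])
    values = df[list(schema.names)].to_numpy()
    try:
        values = values.astype(np.int64)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-integer feature value in {path}: {exc}") from exc
    return SampleTable(values, labels, schema)


def write_samples(table: SampleTable, path: str | Path, sep: str = ",") -> None:
    table.to_frame().to_csv(path, sep=sep, index=False)


@dataclass
class NormalizedMatrix:
    """Per-column min-max scaled feature matrix with its scaling extrema.

    The extrema are those of the matrix the scaling was fitted on (the
    training matrix); they are reused unchanged when mapping new samples,
    whose scaled values are clipped to [0, 1].  Columns that are constant in
    the training matrix scale to all-zeros.
    """

    values: np.ndarray
    col_min: np.ndarray
    col_max: np.ndarray

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def transform(self, raw: np.ndarray) -> np.ndarray:
        """Scale new raw rows with the fitted extrema, clipping to [0, 1]."""
        raw = np.asarray(raw, dtype=float)
        span = self.col_max - self.col_min
        safe = np.where(span > 0, span, 1.0)
        out = (raw - self.col_min) / safe
        out[..., span == 0] = 0.0
        return np.clip(out, 0.0, 1.0)


def minmax_normalize(table: SampleTable | np.ndarray) -> NormalizedMatrix:
    """Min-max scale each feature column of a sample table to [0, 1].

    Extrema are taken from the data itself, not from the schema's theoretical
    ranges, so they can later serve as the range denominators of the rule
    distances.  Constant columns map to zero.
    """
    raw = table.values if isinstance(table, SampleTable) else np.asarray(table)
    if raw.ndim != 2 or raw.shape[0] < 1:
        raise ValidationError("cannot normalize an empty table")
    raw = raw.astype(float)
    col_min = raw.min(axis=0)
    col_max = raw.max(axis=0)
    span = col_max - col_min
    safe = np.where(span > 0, span, 1.0)
    values = (raw - col_min) / safe
    values[:, span == 0] = 0.0
    return NormalizedMatrix(values=values, col_min=col_min, col_max=col_max)
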