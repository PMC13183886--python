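"""Reading and writing UCI-dialect clinical CSV tables.

The on-disk dialect is the one used by the UCI heart-disease distribution:
comma-separated values, an optional header row, ``"?"`` marking missing
cells, and the final column holding a binary diagnosis target.  In memory a
table is a :class:`Dataset`: a float matrix (``NaN`` = missing), ordered
column names, a per-column kind tag (numeric, or categorical with an
enumerated level set), the 0/1 target, and a *group map* linking each
original clinical feature to the encoded columns that represent it (the
identity before one-hot encoding).
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError

__all__ = [
    "FeatureKind",
    "Dataset",
    "UCI_SCHEMA",
    "read_uci_csv",
    "write_uci_csv",
    "numeric",
    "categorical",
]


@dataclass(frozen=True)
class FeatureKind:
    """Column kind: ``"numeric"`` or ``"categorical"`` with its level set."""

    kind: str
    levels: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("numeric", "categorical"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.kind == "categorical" and not self.levels:
            raise ValueError("categorical kind requires levels")

    @property
    def is_categorical(self) -> bool:
        return self.kind == "categorical"


def numeric() -> FeatureKind:
    return FeatureKind("numeric")


def categorical(*levels: float) -> FeatureKind:
    return FeatureKind("categorical", tuple(float(v) for v in levels))


#: Pinned column schema for the 13-predictor heart-disease table: age,
#: resting blood pressure, cholesterol, max heart rate, ST depression and
#: fluoroscopy vessel count are numeric; sex, chest-pain type, fasting
#: blood sugar, resting ECG, exercise angina, ST slope and thalassemia
#: category are categorical with their clinical level sets.
UCI_SCHEMA: dict[str, FeatureKind] = {
    "age": numeric(),
    "sex": categorical(0, 1),
    "cp": categorical(0, 1, 2, 3),
    "trestbps": numeric(),
    "chol": numeric(),
    "fbs": categorical(0, 1),
    "restecg": categorical(0, 1, 2),
    "thalach": numeric(),
    "exang": categorical(0, 1),
    "oldpeak": numeric(),
    "slope": categorical(0, 1, 2),
    "ca": numeric(),
    "thal": categorical(1, 2, 3),
}


@dataclass
class Dataset:
    """A column-typed feature table with a binary target.

    ``features`` is an ``(n_samples, n_columns)`` float matrix with ``NaN``
    as the missing sentinel.  ``group_map`` maps each original feature index
    to the tuple of encoded column indices representing it; ``group_names``
    holds the original feature names in group order.
    """

    features: np.ndarray
    feature_names: list[str]
    feature_kinds: list[FeatureKind]
    target: np.ndarray
    group_map: dict[int, tuple[int, ...]] = field(default_factory=dict)
    group_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        self.target = np.asarray(self.target)
        if not self.group_map:
            self.group_map = {j: (j,) for j in range(self.features.shape[1])}
        if not self.group_names:
            self.group_names = list(self.feature_names)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        n, p = self.features.shape
        if len(self.target) != n:
            raise SchemaError(
                f"feature rows ({n}) and target length ({len(self.target)}) differ"
            )
        vals = set(np.unique(self.target).tolist())
        if not vals <= {0, 1}:
            raise SchemaError(f"target values must be in {{0,1}}, got {sorted(vals)}")
        if len(self.feature_names) != p or len(self.feature_kinds) != p:
            raise SchemaError("feature_names/feature_kinds length mismatch")
        seen: list[int] = []
        for cols in self.group_map.values():
            seen.extend(cols)
        if sorted(seen) != list(range(p)):
            raise SchemaError("group_map must partition the encoded columns")

    # -- convenience -----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_columns(self) -> int:
        return self.features.shape[1]

    @property
    def n_groups(self) -> int:
        return len(self.group_map)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.features)

    def numeric_columns(self) -> list[int]:
        return [j for j, k in enumerate(self.feature_kinds) if not k.is_categorical]

    def categorical_columns(self) -> list[int]:
        return [j for j, k in enumerate(self.feature_kinds) if k.is_categorical]

    def copy(self) -> "Dataset":
        return Dataset(
            self.features.copy(),
            list(self.feature_names),
            list(self.feature_kinds),
            self.target.copy(),
            {g: tuple(c) for g, c in self.group_map.items()},
            list(self.group_names),
        )

    def columns_for_groups(self, groups: np.ndarray | list[int]) -> list[int]:
        """Encoded column indices for a set of group indices, in order."""
        cols: list[int] = []
        for g in groups:
            cols.extend(self.group_map[int(g)])
        return sorted(cols)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=self.feature_names)
        df["target"] = self.target
        return df


def _infer_kind(col: np.ndarray) -> FeatureKind:
    """Fallback kind inference: <=5 distinct integer values => categorical."""
    vals = np.unique(col[~np.isnan(col)])
    if len(vals) <= 5 and np.allclose(vals, np.round(vals)):
        return FeatureKind("categorical", tuple(float(v) for v in vals))
    return numeric()


def read_uci_csv(
    path: str | Path | io.IOBase,
    missing_marker: str = "?",
    header: bool | str = "auto",
    schema: dict[str, FeatureKind] | None = None,
    kinds: list[FeatureKind] | None = None,
    binarize_target: bool = False,
) -> Dataset:
    """Read a UCI-dialect CSV into a :class:`Dataset`.

    Parameters
    ----------
    missing_marker : cell text treated as missing (``NaN``), default ``"?"``.
    header : ``True``/``False``, or ``"auto"`` to sniff a non-numeric first row.
    schema : name -> kind mapping applied when a header is present; defaults
        to :data:`UCI_SCHEMA` for matching names.  Columns not covered fall
        back to inference (<= 5 distinct integer values => categorical).
    kinds : explicit per-column kinds (overrides schema and inference).
    binarize_target : map any target value > 0 to 1 (the original Cleveland
        file codes disease severity 0-4).  Off by default: the target must
        already be 0/1.
    """
    if schema is None:
        schema = UCI_SCHEMA
    try:
        peek = pd.read_csv(
            path, header=None, na_values=[missing_marker], nrows=1, dtype=str
        )
    except pd.errors.ParserError as exc:  # pragma: no cover - peek is 1 row
        raise ParseError(str(exc)) from exc

    def _looks_numeric(v: object) -> bool:
        try:
            float(v)
            return True
        except (TypeError, ValueError):
            return False

    if header == "auto":
        first = peek.iloc[0].tolist()
        has_header = not all(_looks_numeric(v) or pd.isna(v) for v in first)
    else:
        has_header = bool(header)

    if hasattr(path, "seek"):
        path.seek(0)
    try:
        df = pd.read_csv(
            path,
            header=0 if has_header else None,
            na_values=[missing_marker],
        )
    except pd.errors.ParserError as exc:
        raise ParseError(f"malformed CSV: {exc}") from exc
    if df.shape[1] < 2:
        raise SchemaError("need at least one predictor column plus the target")

    target_raw = pd.to_numeric(df.iloc[:, -1], errors="coerce").to_numpy()
    if np.isnan(target_raw).any():
        raise SchemaError("target column contains missing or non-numeric values")
    if binarize_target:
        target = (target_raw > 0).astype(int)
    else:
        vals = set(np.unique(target_raw).tolist())
        if not vals <= {0.0, 1.0}:
            raise SchemaError(
                f"target must be binary 0/1 (got values {sorted(vals)}); "
                "pass binarize_target=True to map >0 to 1"
            )
        target = target_raw.astype(int)

    feat_df = df.iloc[:, :-1]
    names = (
        [str(c).strip().rstrip(".") for c in feat_df.columns]
        if has_header
        else [f"x{j}" for j in range(feat_df.shape[1])]
    )
    try:
        features = feat_df.apply(pd.to_numeric, errors="raise").to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"non-numeric predictor cell: {exc}") from exc

    if kinds is not None:
        if len(kinds) != features.shape[1]:
            raise SchemaError("kinds length does not match column count")
        col_kinds = list(kinds)
    else:
        col_kinds = []
        for j, name in enumerate(names):
            if has_header and name in schema:
                col_kinds.append(schema[name])
            else:
                col_kinds.append(_infer_kind(features[:, j]))

    return Dataset(features, names, col_kinds, target)


def _fmt(value: float) -> str:
    if np.isnan(value):
        return ""
    if float(value).is_integer():
        return str(int(value))
    return repr(float(value))


def write_uci_csv(
    data: Dataset, path: str | Path, missing_marker: str = "?"
) -> None:
    """Write a :class:`Dataset` back to the UCI dialect (header included).

    Missing cells become ``missing_marker``; integral values are written
    without a decimal point so a read/write cycle is value-identical.
    """
    lines = [",".join([*data.feature_names, "target"])]
    for i in range(data.n_samples):
        cells = [
            _fmt(v) if not np.isnan(v) else missing_marker
            for v in data.features[i]
        ]
        cells.append(str(int(data.target[i])))
        lines.append(",".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def dataset_schema_dict(data: Dataset) -> dict:
    """JSON-serializable description of names/kinds/groups (sidecar)."""
    return {
        "feature_names": data.feature_names,
        "feature_kinds": [dataclasses.asdict(k) for k in data.feature_kinds],
        "group_names": data.group_names,
        "group_map": {str(g): list(c) for g, c in data.group_map.items()},
    }
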