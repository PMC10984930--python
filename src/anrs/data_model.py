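"""Decision-table data model and ARFF/CSV input/output.

A *decision table* is a tabular information system whose attributes split
into condition attributes (numeric or categorical) and one categorical
decision attribute.  Records are indexed by their 0-based position in file
order; that index is the sample identity used by every downstream index set
(neighborhoods, approximations).

Missing values ("?" or empty cells) are handled by a declared policy:
numeric cells are imputed with the column mean over non-missing entries,
categorical cells become the literal token ``"?"`` and are treated as an
ordinary string by the edit-distance machinery thereafter.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ContractViolation, ParseError

NUMERIC = "numeric"
CATEGORICAL = "categorical"

#: reserved missing-value marker in both ARFF and CSV
MISSING = "?"


@dataclass(frozen=True)
class HybridSchema:
    """Attribute names/kinds, the decision attribute, and optional weights.

    Parameters
    ----------
    attributes
        Ordered ``(name, kind)`` pairs for the condition attributes, where
        kind is ``"numeric"`` or ``"categorical"``.
    decision
        Name of the decision attribute (not among the condition attributes).
    weights
        Optional per-condition-attribute nonnegative weights; every
        attribute missing from the map gets weight 1.
    """

    attributes: tuple[tuple[str, str], ...]
    decision: str
    weights: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.attributes:
            raise ConfigurationError("schema needs at least one condition attribute")
        names = [n for n, _ in self.attributes]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate attribute names in schema")
        if self.decision in names:
            raise ConfigurationError(
                f"decision attribute {self.decision!r} is also a condition attribute"
            )
        for name, kind in self.attributes:
            if kind not in (NUMERIC, CATEGORICAL):
                raise ConfigurationError(f"unknown kind {kind!r} for attribute {name!r}")
        for key, w in self.weights.items():
            if key not in names:
                raise ConfigurationError(f"weight given for unknown attribute {key!r}")
            if w < 0:
                raise ConfigurationError(f"negative weight for attribute {key!r}")

    @property
    def condition_names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.attributes)

    @property
    def numeric_names(self) -> tuple[str, ...]:
        return tuple(n for n, k in self.attributes if k == NUMERIC)

    @property
    def categorical_names(self) -> tuple[str, ...]:
        return tuple(n for n, k in self.attributes if k == CATEGORICAL)

    def kind_of(self, name: str) -> str:
        for n, k in self.attributes:
            if n == name:
                return k
        raise ConfigurationError(f"unknown attribute {name!r}")

    def weight_of(self, name: str) -> float:
        return float(self.weights.get(name, 1.0))


@dataclass(frozen=True)
class HybridRecord:
    """One sample: attribute values plus an optional decision label."""

    values: Mapping[str, object]
    label: Optional[str] = None


class HybridTable:
    """An ordered universe of hybrid records conforming to a schema.

    Internally backed by a :class:`pandas.DataFrame` whose columns are the
    condition attributes (numeric columns as floats, categorical as strings)
    plus, when present, the decision column.  Row position is identity.
    """

    def __init__(self, schema: HybridSchema, df: pd.DataFrame):
        self.schema = schema
        missing_cols = [c for c in schema.condition_names if c not in df.columns]
        if missing_cols:
            raise ContractViolation(f"table missing condition columns {missing_cols}")
        df = df.reset_index(drop=True)
        for name in schema.numeric_names:
            df[name] = pd.to_numeric(df[name], errors="raise").astype(float)
        for name in schema.categorical_names:
            df[name] = df[name].astype("string").astype(object)
        if schema.decision in df.columns:
            df[schema.decision] = df[schema.decision].astype("string").astype(object)
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def has_labels(self) -> bool:
        return self.schema.decision in self.df.columns

    @property
    def labels(self) -> np.ndarray:
        """Decision values as an object array of strings (or raises)."""
        if not self.has_labels:
            raise ContractViolation("table has no decision column")
        return self.df[self.schema.decision].to_numpy(dtype=object)

    def record(self, i: int) -> HybridRecord:
        row = self.df.iloc[i]
        values = {n: row[n] for n in self.schema.condition_names}
        label = row[self.schema.decision] if self.has_labels else None
        if label is not None and isinstance(label, float) and math.isnan(label):
            label = None
        return HybridRecord(values=values, label=label)

    def records(self) -> list[HybridRecord]:
        return [self.record(i) for i in range(len(self))]

    def subset(self, indices: Sequence[int]) -> "HybridTable":
        """New table holding the given rows, in the given order."""
        return HybridTable(self.schema, self.df.iloc[list(indices)].copy())

    def numeric_matrix(self) -> np.ndarray:
        """(n, n_numeric) float matrix in schema order of numeric attributes."""
        if not self.schema.numeric_names:
            return np.empty((len(self), 0))
        return self.df[list(self.schema.numeric_names)].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# ARFF

_ATTR_RE = re.compile(r"@attribute\s+('(?:[^']*)'|\"(?:[^\"]*)\"|\S+)\s+(.+)", re.I)


def _unquote(token: str) -> str:
    if len(token) >= 2 and token[0] == token[-1] and token[0] in "'\"":
        return token[1:-1]
    return token


def _split_csv_line(line: str) -> list[str]:
    """Split one ARFF data line on commas, honoring single/double quotes."""
    fields: list[str] = []
    buf: list[str] = []
    quote = None
    for ch in line:
        if quote:
            if ch == quote:
                quote = None
            else:
                buf.append(ch)
        elif ch in "'\"":
            quote = ch
        elif ch == ",":
            fields.append("".join(buf).strip())
            buf = []
        else:
            buf.append(ch)
    fields.append("".join(buf).strip())
    return fields


def read_arff(path, decision: Optional[str] = None) -> HybridTable:
    """Read a dense ARFF file into a :class:`HybridTable`.

    Nominal (``{a,b,...}``) attributes map to categorical kind; ``numeric``,
    ``real`` and ``integer`` declarations map to numeric kind.  ``decision``
    defaults to the last declared attribute.  Missing cells (``?``) are
    resolved by :func:`apply_missing_policy`.
    """
    names: list[str] = []
    kinds: list[str] = []
    rows: list[list[str]] = []
    in_data = False
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("%"):
                continue
            low = line.lower()
            if not in_data:
                if low.startswith("@relation"):
                    continue
                if low.startswith("@attribute"):
                    m = _ATTR_RE.match(line)
                    if not m:
                        raise ParseError(f"line {lineno}: malformed @attribute: {line!r}")
                    name = _unquote(m.group(1))
                    spec = m.group(2).strip()
                    if spec.startswith("{"):
                        kinds.append(CATEGORICAL)
                    elif spec.lower() in ("numeric", "real", "integer"):
                        kinds.append(NUMERIC)
                    else:
                        # string/date attributes: treat as categorical text
                        kinds.append(CATEGORICAL)
                    names.append(name)
                    continue
                if low.startswith("@data"):
                    if not names:
                        raise ParseError(f"line {lineno}: @data before any @attribute")
                    in_data = True
                    continue
                raise ParseError(f"line {lineno}: unrecognized header line: {line!r}")
            else:
                fields = [_unquote(f) for f in _split_csv_line(line)]
                if len(fields) != len(names):
                    raise ParseError(
                        f"line {lineno}: expected {len(names)} fields, got {len(fields)}"
                    )
                rows.append(fields)
    if not in_data:
        raise ParseError("no @data section found")
    if not rows:
        raise ParseError("empty table: @data section has no rows")

    dec = decision if decision is not None else names[-1]
    if dec not in names:
        raise ConfigurationError(f"unknown decision attribute {dec!r}")
    if kinds[names.index(dec)] == NUMERIC:
        raise ConfigurationError(f"decision attribute {dec!r} must be nominal")

    df = pd.DataFrame(rows, columns=names, dtype=object)
    schema = HybridSchema(
        attributes=tuple((n, k) for n, k in zip(names, kinds) if n != dec),
        decision=dec,
    )
    return apply_missing_policy(_coerce_raw(schema, df))


def write_arff(table: HybridTable, path, relation: str = "hybrid") -> None:
    """Write the table as dense ARFF; nominal domains are the observed values."""
    schema = table.schema
    cols = list(schema.condition_names)
    if table.has_labels:
        cols.append(schema.decision)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"@relation {relation}\n\n")
        for name in cols:
            if name != schema.decision and schema.kind_of(name) == NUMERIC:
                fh.write(f"@attribute {name} numeric\n")
            else:
                domain = sorted(set(str(v) for v in table.df[name]))
                fh.write("@attribute %s {%s}\n" % (name, ",".join(domain)))
        fh.write("\n@data\n")
        for _, row in table.df[cols].iterrows():
            fh.write(",".join(_format_cell(v) for v in row) + "\n")


def _format_cell(v) -> str:
    if isinstance(v, float):
        return repr(v)
    s = str(v)
    return f"'{s}'" if ("," in s or " " in s) else s


# ---------------------------------------------------------------------------
# CSV

_NUM_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def _parses_as_real(cell: str) -> bool:
    return bool(_NUM_RE.match(cell.strip()))


def read_csv(path, decision: str, schema: Optional[HybridSchema] = None) -> HybridTable:
    """Read a CSV decision table, inferring kinds when no schema is given.

    A column is numeric only if *every* non-missing cell parses as a real
    number (missing = empty string or ``"?"``); anything else is
    categorical.  The inference result is recorded in the returned schema.
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise ParseError("empty table: no header row")
    if len(df) == 0:
        raise ParseError("empty table: header but no data rows")
    if decision not in df.columns:
        raise ConfigurationError(f"decision column {decision!r} not in CSV header")

    if schema is None:
        attrs = []
        for col in df.columns:
            if col == decision:
                continue
            non_missing = [c for c in df[col] if c.strip() not in ("", MISSING)]
            kind = NUMERIC if non_missing and all(_parses_as_real(c) for c in non_missing) else CATEGORICAL
            attrs.append((col, kind))
        schema = HybridSchema(attributes=tuple(attrs), decision=decision)
    else:
        if schema.decision != decision:
            raise ConfigurationError("schema decision disagrees with `decision` argument")
    return apply_missing_policy(_coerce_raw(schema, df))


def write_csv(table: HybridTable, path) -> None:
    cols = list(table.schema.condition_names)
    if table.has_labels:
        cols.append(table.schema.decision)
    table.df[cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Missing-value policy

class _Raw(HybridTable):
    """A table that may still contain NaN/missing cells (pre-policy)."""

    def __init__(self, schema: HybridSchema, df: pd.DataFrame):  # bypass coercion
        self.schema = schema
        self.df = df.reset_index(drop=True)


def _coerce_raw(schema: HybridSchema, df: pd.DataFrame) -> "_Raw":
    out = df.copy()
    for name in schema.numeric_names:
        col = out[name].astype(str).str.strip()
        col = col.mask(col.isin(("", MISSING)))
        try:
            out[name] = pd.to_numeric(col)
        except (ValueError, TypeError) as exc:
            raise ParseError(f"column {name!r}: non-numeric cell in numeric column ({exc})")
    for name in schema.categorical_names:
        col = out[name].astype(str).str.strip()
        out[name] = col.mask(col == "").astype(object)
    if schema.decision in out.columns:
        out[schema.decision] = out[schema.decision].astype(str).str.strip()
    return _Raw(schema, out)


def apply_missing_policy(table: HybridTable) -> HybridTable:
    """Impute numeric missing cells with the column mean; categorical with ``"?"``.

    A table with no missing values is returned (semantically) unchanged; the
    record/attribute counts are always preserved.
    """
    df = table.df.copy()
    schema = table.schema
    for name in schema.numeric_names:
        col = pd.to_numeric(df[name], errors="coerce")
        if col.isna().all():
            raise ConfigurationError(f"numeric column {name!r} entirely missing; no mean defined")
        df[name] = col.fillna(col.mean())
    for name in schema.categorical_names:
        col = df[name].astype(object)
        df[name] = col.where(pd.notna(col), MISSING)
    return HybridTable(schema, df)


def table_from_records(
    schema: HybridSchema,
    records: Iterable[HybridRecord],
) -> HybridTable:
    """Assemble a table from record objects (labels included when present)."""
    rows = []
    for rec in records:
        row = dict(rec.values)
        if rec.label is not None:
            row[schema.decision] = rec.label
        rows.append(row)
    if not rows:
        raise ContractViolation("cannot build a table from zero records")
    return HybridTable(schema, pd.DataFrame(rows))
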