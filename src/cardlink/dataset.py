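"""Tabular datasets with a typed variable schema.

Every card in the system reads from a :class:`Dataset`: an ordered list of
:class:`Variable` descriptors plus one :class:`Record` per data row.  Variables
belong to one of three kinds — *categorical*, *ordinal* or *quantitative* —
and that trichotomy decides which filter controls, view axes and statistical
tests apply downstream.

Data arrive as CSV or XLSX, one row per element, header row of variable
names, incomplete cells allowed.  Schema inference is automatic and
idempotent; the user may recast, rename, remove and reorder variables
afterwards.
"""

from __future__ import annotations

import csv
import itertools
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

__all__ = [
    "Variable",
    "Record",
    "Dataset",
    "SchemaError",
    "Rename",
    "Remove",
    "Reorder",
    "Recast",
    "MISSING_SPELLINGS",
    "is_missing",
    "load_table",
    "write_table",
    "infer_schema",
    "edit_schema",
    "append_rows",
]

Kind = Literal["categorical", "ordinal", "quantitative"]

#: Cell spellings treated as missing on load (case-insensitive), besides the
#: empty cell.  Common CSV dialects.
MISSING_SPELLINGS = frozenset({"", "na", "nan", "null"})


class SchemaError(ValueError):
    """Raised for malformed headers, unknown variables or invalid recasts."""


def is_missing(value) -> bool:
    """True for the in-memory missing marker (None)."""
    return value is None


def _normalise_cell(raw) -> str | None:
    if raw is None:
        return None
    text = str(raw).strip()
    if text.lower() in MISSING_SPELLINGS:
        return None
    return text


@dataclass(frozen=True)
class Variable:
    """A typed column descriptor.

    ``categories`` is present iff the kind is not quantitative; its order is
    meaningful for ordinals (rank order) and is first-appearance order for
    categoricals.
    """

    name: str
    kind: Kind = "categorical"
    categories: tuple | None = None
    display_order: int = 0

    def __post_init__(self):
        if self.kind not in ("categorical", "ordinal", "quantitative"):
            raise SchemaError(f"unknown variable kind: {self.kind!r}")
        if self.kind == "quantitative":
            if self.categories is not None:
                raise SchemaError(f"{self.name}: quantitative variables carry no categories")
        elif self.categories is not None:
            cats = tuple(self.categories)
            if len(cats) != len(set(cats)):
                raise SchemaError(f"{self.name}: duplicate categories")
            object.__setattr__(self, "categories", cats)

    def rank(self, value) -> int:
        """Position of ``value`` in the category order (ordinal rank)."""
        if self.categories is None:
            raise SchemaError(f"{self.name}: no categories defined")
        try:
            return self.categories.index(value)
        except ValueError:
            raise KeyError(f"{value!r} is not a category of {self.name}") from None


@dataclass(frozen=True)
class Record:
    """One data row: a stable opaque id plus variable-name → value-or-None."""

    row_id: str
    values: dict

    def get(self, variable: str):
        return self.values.get(variable)


@dataclass
class Dataset:
    """Typed variables + records + per-row provenance labels."""

    variables: list[Variable] = field(default_factory=list)
    rows: list[Record] = field(default_factory=list)
    source_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        names = [v.name for v in self.variables]
        if len(names) != len(set(names)):
            raise SchemaError("duplicate variable names")
        ids = [r.row_id for r in self.rows]
        if len(ids) != len(set(ids)):
            raise SchemaError("duplicate row_ids")
        if not self.source_ids:
            self.source_ids = ["local"] * len(self.rows)

    # -- lookup -----------------------------------------------------------

    @property
    def variable_names(self) -> list[str]:
        return [v.name for v in self.variables]

    def variable(self, name: str) -> Variable:
        for v in self.variables:
            if v.name == name:
                return v
        raise SchemaError(f"unknown variable: {name!r}")

    def column(self, name: str) -> list:
        self.variable(name)
        return [r.values.get(name) for r in self.rows]

    def row_ids(self) -> list[str]:
        return [r.row_id for r in self.rows]

    def row(self, row_id: str) -> Record:
        for r in self.rows:
            if r.row_id == row_id:
                return r
        raise KeyError(row_id)

    def __len__(self) -> int:
        return len(self.rows)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{v.name: r.values.get(v.name) for v in self.variables} for r in self.rows],
            index=self.row_ids(),
        )

    def schema_snapshot(self) -> list[dict]:
        """JSON-serialisable description of the current schema."""
        return [
            {
                "name": v.name,
                "kind": v.kind,
                "categories": list(v.categories) if v.categories is not None else None,
                "display_order": v.display_order,
            }
            for v in self.variables
        ]


def _fresh_row_ids(start: int, n: int) -> list[str]:
    return [f"r{i}" for i in range(start, start + n)]


# ---------------------------------------------------------------------------
# Loading / writing


def _read_csv_cells(path: Path) -> tuple[list[str], list[list[str | None]]]:
    with open(path, newline="", encoding="utf-8-sig") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file, no header row") from None
        # keep all-empty data rows (",,,"); skip only truly blank lines
        body = [row for row in reader if row]
    return [h.strip() for h in header], body


def _read_xlsx_cells(path: Path) -> tuple[list[str], list[list]]:
    import openpyxl

    wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
    ws = wb.worksheets[0]
    rows = list(ws.iter_rows(values_only=True))
    wb.close()
    if not rows:
        raise SchemaError(f"{path}: empty sheet, no header row")
    header = [("" if c is None else str(c).strip()) for c in rows[0]]
    body = [list(r) for r in rows[1:]]
    # trailing all-empty rows are sheet padding, not data
    while body and all(c is None or not str(c).strip() for c in body[-1]):
        body.pop()
    return header, body


def load_table(
    path: str | Path,
    format: Literal["csv", "xlsx", "auto"] = "auto",
    max_ordinal_levels: int = 10,
    source_id: str | None = None,
) -> Dataset:
    """Load a CSV or XLSX table into a typed Dataset.

    First row holds variable names; empty cells and the spellings in
    :data:`MISSING_SPELLINGS` become missing.  The schema is inferred with
    :func:`infer_schema`.  Zero data rows yield a valid empty dataset with a
    warning.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if format == "auto":
        format = "xlsx" if path.suffix.lower() in (".xlsx", ".xlsm", ".xls") else "csv"
    if format == "csv":
        header, body = _read_csv_cells(path)
    elif format == "xlsx":
        header, body = _read_xlsx_cells(path)
    else:
        raise ValueError(f"unknown format: {format!r}")

    if len(header) != len(set(header)):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise SchemaError(f"{path}: duplicate header names: {dupes}")
    if any(not h for h in header):
        raise SchemaError(f"{path}: blank variable name in header")

    records = []
    for i, raw_row in enumerate(body):
        cells = list(raw_row) + [None] * (len(header) - len(raw_row))
        values = {name: _normalise_cell(cells[j]) for j, name in enumerate(header)}
        records.append(Record(row_id=f"r{i}", values=values))

    if not records:
        warnings.warn(f"{path}: zero data rows (empty dataset)", stacklevel=2)

    ds = Dataset(
        variables=[Variable(name=h, display_order=j) for j, h in enumerate(header)],
        rows=records,
        source_ids=[source_id or str(path)] * len(records),
    )
    return infer_schema(ds, max_ordinal_levels=max_ordinal_levels)


def write_table(dataset: Dataset, path: str | Path, format: Literal["csv", "xlsx", "auto"] = "auto") -> None:
    """Write the dataset back out; missing cells become empty cells."""
    path = Path(path)
    if format == "auto":
        format = "xlsx" if path.suffix.lower() == ".xlsx" else "csv"
    names = dataset.variable_names
    if format == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(names)
            for r in dataset.rows:
                w.writerow(["" if is_missing(r.values.get(n)) else r.values.get(n) for n in names])
    elif format == "xlsx":
        df = dataset.to_dataframe()
        df.to_excel(path, index=False)
    else:
        raise ValueError(f"unknown format: {format!r}")


# ---------------------------------------------------------------------------
# Schema inference


def _try_number(value) -> float | None:
    if isinstance(value, bool):
        return None
    if isinstance(value, (int, float)):
        return float(value)
    try:
        return float(str(value).strip())
    except (TypeError, ValueError):
        return None


def infer_schema(dataset: Dataset, max_ordinal_levels: int = 10) -> Dataset:
    """Assign each variable a kind from its observed values.

    Rules, applied per column over non-missing cells:

    * every value parses as a number, and they are all integers with at most
      ``max_ordinal_levels`` distinct values → **ordinal** (categories sorted
      numerically, values stored as int);
    * every value parses as a number otherwise → **quantitative** (stored as
      float);
    * anything else → **categorical** (categories in first-appearance order,
      values stored as str).

    A column with no observed values becomes categorical with an empty
    category list, with a warning.  The operation is idempotent.
    """
    new_vars = []
    new_values: dict[str, list] = {}
    for var in dataset.variables:
        col = [r.values.get(var.name) for r in dataset.rows]
        present = [v for v in col if not is_missing(v)]
        if not present:
            warnings.warn(f"{var.name}: column entirely missing; typed categorical", stacklevel=2)
            new_vars.append(replace(var, kind="categorical", categories=()))
            new_values[var.name] = col
            continue
        numbers = [_try_number(v) for v in present]
        if all(x is not None for x in numbers):
            distinct = set(numbers)
            if all(x.is_integer() for x in numbers) and len(distinct) <= max_ordinal_levels:
                cats = tuple(sorted(int(x) for x in distinct))
                new_vars.append(replace(var, kind="ordinal", categories=cats))
                new_values[var.name] = [None if is_missing(v) else int(_try_number(v)) for v in col]
            else:
                new_vars.append(replace(var, kind="quantitative", categories=None))
                new_values[var.name] = [None if is_missing(v) else _try_number(v) for v in col]
        else:
            seen: dict[str, None] = {}
            for v in present:
                seen.setdefault(str(v), None)
            new_vars.append(replace(var, kind="categorical", categories=tuple(seen)))
            new_values[var.name] = [None if is_missing(v) else str(v) for v in col]

    rows = [
        Record(r.row_id, {v.name: new_values[v.name][i] for v in new_vars})
        for i, r in enumerate(dataset.rows)
    ]
    return Dataset(variables=new_vars, rows=rows, source_ids=list(dataset.source_ids))


# ---------------------------------------------------------------------------
# Schema editing


@dataclass(frozen=True)
class Rename:
    old: str
    new: str


@dataclass(frozen=True)
class Remove:
    name: str


@dataclass(frozen=True)
class Reorder:
    """New display order: full list of variable names."""

    order: tuple

    def __init__(self, order: Sequence[str]):
        object.__setattr__(self, "order", tuple(order))


@dataclass(frozen=True)
class Recast:
    name: str
    kind: Kind
    categories: tuple | None = None  # explicit order for ordinal recasts

    def __post_init__(self):
        if self.categories is not None:
            object.__setattr__(self, "categories", tuple(self.categories))


SchemaOp = Rename | Remove | Reorder | Recast


def _recast_variable(dataset: Dataset, op: Recast) -> tuple[Variable, list]:
    var = dataset.variable(op.name)
    col = dataset.column(op.name)
    present = [(i, v) for i, v in enumerate(col) if not is_missing(v)]
    if op.kind == "quantitative":
        converted = list(col)
        for i, v in present:
            num = _try_number(v)
            if num is None:
                raise TypeError(
                    f"cannot recast {op.name!r} to quantitative: "
                    f"row {dataset.rows[i].row_id} holds non-numeric value {v!r}"
                )
            converted[i] = num
        return replace(var, kind="quantitative", categories=None), converted
    # categorical / ordinal: re-derive categories
    if op.categories is not None:
        cats = tuple(op.categories)
        extra = {v for _, v in present} - set(cats)
        if extra:
            raise TypeError(f"recast of {op.name!r}: values {sorted(map(str, extra))} not in given categories")
    else:
        values = [v for _, v in present]
        nums = [_try_number(v) for v in values]
        if op.kind == "ordinal" and all(x is not None for x in nums):
            cats = tuple(sorted(set(values), key=lambda v: _try_number(v)))
        else:
            seen: dict = {}
            for v in values:
                seen.setdefault(v, None)
            cats = tuple(seen)
    return replace(var, kind=op.kind, categories=cats), list(col)


def edit_schema(dataset: Dataset, ops: Iterable[SchemaOp]) -> Dataset:
    """Apply rename/remove/reorder/recast operations in order.

    Row ids and untouched columns are unchanged.  Reordering is
    presentation-only: it rewrites ``display_order`` (and the variable list
    order) but never the record values.
    """
    variables = list(dataset.variables)
    columns = {v.name: dataset.column(v.name) for v in variables}

    for op in ops:
        if isinstance(op, Rename):
            var = next((v for v in variables if v.name == op.old), None)
            if var is None:
                raise SchemaError(f"unknown variable: {op.old!r}")
            if any(v.name == op.new for v in variables):
                raise SchemaError(f"rename target already exists: {op.new!r}")
            variables[variables.index(var)] = replace(var, name=op.new)
            columns[op.new] = columns.pop(op.old)
        elif isinstance(op, Remove):
            var = next((v for v in variables if v.name == op.name), None)
            if var is None:
                raise SchemaError(f"unknown variable: {op.name!r}")
            variables.remove(var)
            del columns[op.name]
        elif isinstance(op, Reorder):
            names = {v.name for v in variables}
            if set(op.order) != names:
                raise SchemaError(f"reorder must list all variables exactly once, got {op.order}")
            variables = sorted(variables, key=lambda v: op.order.index(v.name))
        elif isinstance(op, Recast):
            var = next((v for v in variables if v.name == op.name), None)
            if var is None:
                raise SchemaError(f"unknown variable: {op.name!r}")
            sub = Dataset(
                variables=[replace(var, display_order=0)],
                rows=[
                    Record(r.row_id, {op.name: columns[op.name][i]})
                    for i, r in enumerate(dataset.rows)
                ],
                source_ids=list(dataset.source_ids),
            )
            new_var, new_col = _recast_variable(sub, op)
            variables[variables.index(var)] = new_var
            columns[op.name] = new_col
        else:
            raise TypeError(f"unknown schema op: {op!r}")

    variables = [replace(v, display_order=i) for i, v in enumerate(variables)]
    rows = [
        Record(r.row_id, {v.name: columns[v.name][i] for v in variables})
        for i, r in enumerate(dataset.rows)
    ]
    return Dataset(variables=variables, rows=rows, source_ids=list(dataset.source_ids))


# ---------------------------------------------------------------------------
# Merging ("Add to current")


def append_rows(dataset: Dataset, other: Dataset, max_ordinal_levels: int = 10) -> Dataset:
    """Outer-union merge: rows are concatenated, variables unioned.

    Cells absent in one source become missing.  A variable present in both
    sources with conflicting kinds is re-typed by running schema inference on
    the merged column (with a warning).  Provenance is kept per row in
    ``source_ids``.
    """
    if len(other) == 0 and not other.variables:
        return Dataset(
            variables=list(dataset.variables),
            rows=list(dataset.rows),
            source_ids=list(dataset.source_ids),
        )

    variables = list(dataset.variables)
    known = {v.name for v in variables}
    conflicts = []
    for v in other.variables:
        if v.name not in known:
            variables.append(v)
            known.add(v.name)
        else:
            mine = dataset.variable(v.name)
            if mine.kind != v.kind or mine.categories != v.categories:
                conflicts.append(v.name)

    counter = itertools.count()
    rows, source_ids = [], []
    for ds in (dataset, other):
        for r, src in zip(ds.rows, ds.source_ids):
            rows.append(Record(f"r{next(counter)}", {v.name: r.values.get(v.name) for v in variables}))
            source_ids.append(src)

    merged = Dataset(
        variables=[replace(v, display_order=i) for i, v in enumerate(variables)],
        rows=rows,
        source_ids=source_ids,
    )
    if conflicts:
        warnings.warn(f"re-resolving kinds of shared variables: {conflicts}", stacklevel=2)
        inferred = infer_schema(merged, max_ordinal_levels=max_ordinal_levels)
        variables = [
            inferred.variable(v.name) if v.name in conflicts else v for v in merged.variables
        ]
        rows = [
            Record(
                r.row_id,
                {
                    v.name: (ir.values.get(v.name) if v.name in conflicts else r.values.get(v.name))
                    for v in variables
                },
            )
            for r, ir in zip(merged.rows, inferred.rows)
        ]
        merged = Dataset(variables=variables, rows=rows, source_ids=source_ids)
    return merged
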