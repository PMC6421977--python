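"""Renderer-agnostic view specifications.

Each builder is a pure function of (dataset, filter state, selection,
view configuration): same inputs, identical spec.  Specs carry positions,
widths and flags — everything a renderer needs and nothing it should decide
itself.  They serialise to versioned JSON documents (``spec_version`` 1).

Six views are covered: parallel coordinates, parallel sets, radar chart,
scatter plot, Tukey box plot and the raw table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from statistics import median

from .coordination import Board, FilterCard, FilterState, Range, SelectionState
from .dataset import Dataset, SchemaError, Variable, is_missing

__all__ = [
    "SPEC_VERSION",
    "Axis",
    "ParallelCoordinatesSpec",
    "ParallelSetSpec",
    "RadarSpec",
    "ScatterSpec",
    "BoxStats",
    "BoxPlotSpec",
    "TableSpec",
    "tukey_box_stats",
    "build_parallel_coordinates",
    "reorder_axes",
    "add_axis",
    "remove_axis",
    "build_parallel_sets",
    "build_radar",
    "build_scatter",
    "build_box_plot",
    "build_table",
]

logger = logging.getLogger(__name__)

SPEC_VERSION = 1


def _active_records(dataset: Dataset, filter_state: FilterState | None):
    active = filter_state.active_rows if filter_state is not None else set(dataset.row_ids())
    return [r for r in dataset.rows if r.row_id in active]


def _positions(var: Variable, dataset: Dataset):
    """Per-axis normalisation: quantitative → (v-min)/(max-min) over the full
    column; categorical/ordinal → evenly spaced category positions."""
    if var.kind == "quantitative":
        col = [v for v in dataset.column(var.name) if not is_missing(v)]
        lo, hi = (min(col), max(col)) if col else (0.0, 1.0)

        def pos(v):
            if hi == lo:
                return 0.5
            return (float(v) - lo) / (hi - lo)

        return {"type": "numeric", "min": lo, "max": hi}, pos

    cats = list(var.categories or ())
    k = len(cats)

    def pos(v):
        if k <= 1:
            return 0.5
        return cats.index(v) / (k - 1)

    return {"type": "categories", "categories": cats}, pos


# ---------------------------------------------------------------------------
# Parallel coordinates


@dataclass(frozen=True)
class Axis:
    variable: str
    kind: str
    domain: dict
    brush: tuple | None = None  # (lo, hi) in raw value space (rank for ordinal)


@dataclass
class ParallelCoordinatesSpec:
    axes: list[Axis]
    polylines: list[dict]  # {row_id, positions: [float|None per axis], highlighted}
    newly_added_axis: str | None = None
    spec_version: int = SPEC_VERSION

    def to_dict(self) -> dict:
        return {
            "spec_version": self.spec_version,
            "view": "parallel_coordinates",
            "axes": [
                {"variable": a.variable, "kind": a.kind, "domain": a.domain,
                 "brush": list(a.brush) if a.brush else None}
                for a in self.axes
            ],
            "polylines": self.polylines,
            "newly_added_axis": self.newly_added_axis,
        }


def build_parallel_coordinates(
    dataset: Dataset,
    axes,
    filter_state: FilterState | None = None,
    selection: SelectionState | None = None,
    newly_added_axis: str | None = None,
) -> ParallelCoordinatesSpec:
    """One polyline per active row across the given axes.

    Missing cells become gaps (None positions).  Axis brushes are ordinary
    Range filter cards living in the FilterState; see :func:`brush_axis`.
    """
    axis_names = list(axes)
    if len(axis_names) < 2:
        raise ValueError("parallel coordinates needs at least 2 axes")
    variables = [dataset.variable(a) for a in axis_names]

    brushes = {}
    if filter_state is not None:
        for card in filter_state.cards():
            if isinstance(card.predicate, Range) and card.card_id.startswith("brush:"):
                brushes[card.variable] = (card.predicate.lo, card.predicate.hi)

    axis_specs, pos_fns = [], []
    for var in variables:
        domain, pos = _positions(var, dataset)
        axis_specs.append(Axis(var.name, var.kind, domain, brushes.get(var.name)))
        pos_fns.append(pos)

    highlighted = selection.highlighted_rows if selection is not None else set()
    polylines = []
    for record in _active_records(dataset, filter_state):
        positions = []
        for var, pos in zip(variables, pos_fns):
            v = record.values.get(var.name)
            positions.append(None if is_missing(v) else pos(v))
        polylines.append(
            {"row_id": record.row_id, "positions": positions, "highlighted": record.row_id in highlighted}
        )
    return ParallelCoordinatesSpec(axes=axis_specs, polylines=polylines, newly_added_axis=newly_added_axis)


def brush_axis(board: Board, variable: str, lo: float, hi: float) -> FilterCard:
    """Define a range filter directly on a parallel axis.

    The brush is mirrored into the shared FilterState as an ordinary Range
    filter card (id ``brush:<variable>``), replacing the need for a separate
    filter card per variable; every linked card sees it.
    """
    card_id = f"brush:{variable}"
    if card_id in board.filter_state.filters:
        board.set_predicate(card_id, Range(lo, hi))
        return board.filter_state.filters[card_id]
    return board.create_filter(variable, Range(lo, hi), card_id=card_id)


def reorder_axes(
    spec: ParallelCoordinatesSpec, order, dataset: Dataset,
    filter_state: FilterState | None = None, selection: SelectionState | None = None,
) -> ParallelCoordinatesSpec:
    """Permute the axes; polyline per-axis values permute identically."""
    current = [a.variable for a in spec.axes]
    if sorted(order) != sorted(current):
        raise ValueError(f"reorder must permute the current axes {current}")
    return build_parallel_coordinates(dataset, list(order), filter_state, selection)


def add_axis(
    spec: ParallelCoordinatesSpec, variable: str, dataset: Dataset,
    filter_state: FilterState | None = None, selection: SelectionState | None = None,
) -> ParallelCoordinatesSpec:
    """Append an axis; the new variable is flagged so renderers can colour it
    differently."""
    current = [a.variable for a in spec.axes]
    if variable in current:
        raise ValueError(f"axis {variable!r} already shown")
    return build_parallel_coordinates(
        dataset, current + [variable], filter_state, selection, newly_added_axis=variable
    )


def remove_axis(
    spec: ParallelCoordinatesSpec, variable: str, dataset: Dataset,
    board: Board | None = None,
    filter_state: FilterState | None = None, selection: SelectionState | None = None,
) -> ParallelCoordinatesSpec:
    """Drop an axis; a brush on it is discarded from the FilterState (logged),
    so the active row set can only grow or stay equal."""
    current = [a.variable for a in spec.axes]
    if variable not in current:
        raise ValueError(f"axis {variable!r} not shown")
    if len(current) <= 2:
        raise ValueError("parallel coordinates needs at least 2 axes")
    if board is not None:
        brush_id = f"brush:{variable}"
        if brush_id in board.filter_state.filters:
            logger.info("removing axis %r discards its brush filter", variable)
            board.remove_filter(brush_id)
        filter_state = board.filter_state
    current.remove(variable)
    return build_parallel_coordinates(dataset, current, filter_state, selection)


# ---------------------------------------------------------------------------
# Parallel sets


@dataclass
class ParallelSetSpec:
    tiers: list[dict]    # {variable, bars: [{value, width_fraction}]}
    ribbons: list[dict]  # {path: (value per tier), width_fraction}
    n_complete: int
    spec_version: int = SPEC_VERSION

    def to_dict(self) -> dict:
        return {
            "spec_version": self.spec_version,
            "view": "parallel_sets",
            "n_complete": self.n_complete,
            "tiers": [
                {"variable": t["variable"],
                 "bars": [{"value": b["value"], "width_fraction": float(b["width_fraction"])}
                          for b in t["bars"]]}
                for t in self.tiers
            ],
            "ribbons": [
                {"path": list(r["path"]), "width_fraction": float(r["width_fraction"])}
                for r in self.ribbons
            ],
        }


def build_parallel_sets(
    dataset: Dataset, variables, filter_state: FilterState | None = None,
    category_order: dict | None = None,
) -> ParallelSetSpec:
    """Joint category frequencies over active rows complete in every tier.

    Bar widths are the marginal fractions per tier; ribbon widths the joint
    fractions of full category paths.  Widths are exact rationals, so the
    conservation laws (bars sum to 1 per tier; each bar equals the sum of its
    incident ribbons) hold with no rounding error.  Quantitative variables
    must be recast/binned first.
    """
    names = list(variables)
    if len(names) < 2:
        raise ValueError("parallel sets needs at least 2 variables")
    tiers_vars = []
    for name in names:
        var = dataset.variable(name)
        if var.kind == "quantitative":
            raise SchemaError(
                f"{name} is quantitative; recast it to categorical/ordinal (binning is not guessed)"
            )
        tiers_vars.append(var)

    records = [
        r for r in _active_records(dataset, filter_state)
        if all(not is_missing(r.values.get(n)) for n in names)
    ]
    n = len(records)

    order = category_order or {}

    def cats_for(var: Variable):
        cats = list(order.get(var.name, var.categories or ()))
        return cats

    counts: dict[tuple, int] = {}
    for r in records:
        path = tuple(r.values[n_] for n_ in names)
        counts[path] = counts.get(path, 0) + 1

    tiers = []
    for i, var in enumerate(tiers_vars):
        bars = []
        for cat in cats_for(var):
            c = sum(v for path, v in counts.items() if path[i] == cat)
            bars.append({"value": cat, "width_fraction": Fraction(c, n) if n else Fraction(0)})
        tiers.append({"variable": var.name, "bars": bars})

    def path_key(path):
        return tuple(cats_for(v).index(p) for v, p in zip(tiers_vars, path))

    ribbons = [
        {"path": path, "width_fraction": Fraction(c, n)}
        for path, c in sorted(counts.items(), key=lambda kv: path_key(kv[0]))
    ]
    return ParallelSetSpec(tiers=tiers, ribbons=ribbons, n_complete=n)


# ---------------------------------------------------------------------------
# Radar chart


@dataclass
class RadarSpec:
    axes: list[str]
    polygons: list[dict]  # {row_id, positions: [0..1 per axis], highlighted}
    domains: list[dict]
    spec_version: int = SPEC_VERSION

    def to_dict(self) -> dict:
        return {
            "spec_version": self.spec_version,
            "view": "radar",
            "axes": self.axes,
            "domains": self.domains,
            "polygons": self.polygons,
        }


def build_radar(
    dataset: Dataset, variables, filter_state: FilterState | None = None,
    selection: SelectionState | None = None,
) -> RadarSpec:
    """Min–max normalised polygons over active rows complete in every axis.

    Normalisation runs over ACTIVE rows, so polygons stay comparable within
    the current filter context; a degenerate axis (min == max) maps every
    row to 0.5.
    """
    names = list(variables)
    if len(names) < 3:
        raise ValueError("radar chart needs at least 3 axes")
    vars_ = []
    for name in names:
        var = dataset.variable(name)
        if var.kind == "categorical":
            raise SchemaError(f"radar axes must be quantitative/ordinal, {name} is categorical")
        vars_.append(var)

    records = _active_records(dataset, filter_state)

    def numeric(var: Variable, v):
        return float(var.rank(v)) if var.kind == "ordinal" else float(v)

    domains, scales = [], []
    for var in vars_:
        vals = [numeric(var, r.values[var.name]) for r in records if not is_missing(r.values.get(var.name))]
        if not vals:
            raise ValueError(f"{var.name}: no active non-missing values for radar axis")
        lo, hi = min(vals), max(vals)
        domains.append({"variable": var.name, "min": lo, "max": hi})
        scales.append((lo, hi))

    highlighted = selection.highlighted_rows if selection is not None else set()
    polygons = []
    for r in records:
        if any(is_missing(r.values.get(v.name)) for v in vars_):
            continue
        positions = []
        for var, (lo, hi) in zip(vars_, scales):
            x = numeric(var, r.values[var.name])
            positions.append(0.5 if hi == lo else (x - lo) / (hi - lo))
        polygons.append({"row_id": r.row_id, "positions": positions, "highlighted": r.row_id in highlighted})
    return RadarSpec(axes=names, polygons=polygons, domains=domains)


# ---------------------------------------------------------------------------
# Scatter plot


@dataclass
class ScatterSpec:
    x_variable: str
    y_variable: str
    points: list[dict]  # {row_id, x, y, highlighted, tooltip}
    spec_version: int = SPEC_VERSION

    def to_dict(self) -> dict:
        return {
            "spec_version": self.spec_version,
            "view": "scatter",
            "x_variable": self.x_variable,
            "y_variable": self.y_variable,
            "points": self.points,
        }


def build_scatter(
    dataset: Dataset, x: str, y: str, filter_state: FilterState | None = None,
    selection: SelectionState | None = None,
) -> ScatterSpec:
    """One point per active row non-missing in both variables; the tooltip
    payload carries the full record."""
    vars_ = []
    for name in (x, y):
        var = dataset.variable(name)
        if var.kind == "categorical":
            raise SchemaError(f"scatter axes must be quantitative/ordinal, {name} is categorical")
        vars_.append(var)
    xv, yv = vars_

    def numeric(var: Variable, v):
        return float(var.rank(v)) if var.kind == "ordinal" else float(v)

    highlighted = selection.highlighted_rows if selection is not None else set()
    points = []
    for r in _active_records(dataset, filter_state):
        vx, vy = r.values.get(x), r.values.get(y)
        if is_missing(vx) or is_missing(vy):
            continue
        points.append(
            {
                "row_id": r.row_id,
                "x": numeric(xv, vx),
                "y": numeric(yv, vy),
                "highlighted": r.row_id in highlighted,
                "tooltip": dict(r.values),
            }
        )
    return ScatterSpec(x_variable=x, y_variable=y, points=points)


# ---------------------------------------------------------------------------
# Box plot (Tukey)


@dataclass(frozen=True)
class BoxStats:
    n: int
    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    outliers: tuple

    def to_dict(self) -> dict:
        return {
            "n": self.n, "median": self.median, "q1": self.q1, "q3": self.q3,
            "whisker_lo": self.whisker_lo, "whisker_hi": self.whisker_hi,
            "outliers": list(self.outliers),
        }


def _tukey_hinges(sorted_vals: list[float]) -> tuple[float, float]:
    """Hinges as medians of the lower/upper halves, the median included in
    both halves when n is odd."""
    n = len(sorted_vals)
    half = (n + 1) // 2
    return median(sorted_vals[:half]), median(sorted_vals[n - half:])


def tukey_box_stats(values, interpolated_quartiles: bool = False) -> BoxStats:
    """Five-number summary with 1.5·IQR fences.

    Whiskers extend to the most extreme data points within the fences;
    values beyond them are listed as outliers.  Hinges follow Tukey's
    median-of-halves convention by default; ``interpolated_quartiles``
    switches to linearly interpolated percentiles.
    """
    vals = sorted(float(v) for v in values if not is_missing(v))
    if not vals:
        raise ValueError("box plot needs at least one value")
    med = median(vals)
    if interpolated_quartiles:
        import numpy as np

        q1, q3 = (float(q) for q in np.percentile(vals, [25, 75]))
    else:
        q1, q3 = _tukey_hinges(vals)
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = [v for v in vals if lo_fence <= v <= hi_fence]
    outliers = tuple(v for v in vals if v < lo_fence or v > hi_fence)
    return BoxStats(
        n=len(vals), median=med, q1=q1, q3=q3,
        whisker_lo=min(inside), whisker_hi=max(inside), outliers=outliers,
    )


@dataclass
class BoxPlotSpec:
    value_variable: str
    group_variable: str | None
    groups: list[dict]  # {value, stats: BoxStats}
    omitted_groups: list
    spec_version: int = SPEC_VERSION

    def to_dict(self) -> dict:
        return {
            "spec_version": self.spec_version,
            "view": "box_plot",
            "value_variable": self.value_variable,
            "group_variable": self.group_variable,
            "groups": [{"value": g["value"], "stats": g["stats"].to_dict()} for g in self.groups],
            "omitted_groups": list(self.omitted_groups),
        }


def build_box_plot(
    dataset: Dataset, value: str, group: str | None = None,
    filter_state: FilterState | None = None, interpolated_quartiles: bool = False,
) -> BoxPlotSpec:
    """Per-group Tukey box statistics of a quantitative variable.

    Groups with zero active non-missing values are omitted and noted.
    Without a grouping variable, one box over all active rows is returned.
    """
    value_var = dataset.variable(value)
    if value_var.kind != "quantitative":
        raise SchemaError(f"box plot value variable must be quantitative, {value} is {value_var.kind}")
    records = _active_records(dataset, filter_state)

    if group is None:
        vals = [r.values.get(value) for r in records]
        vals = [v for v in vals if not is_missing(v)]
        if not vals:
            raise ValueError(f"{value}: no active non-missing values")
        return BoxPlotSpec(value, None, [{"value": None, "stats": tukey_box_stats(vals, interpolated_quartiles)}], [])

    group_var = dataset.variable(group)
    if group_var.kind == "quantitative":
        raise SchemaError(f"box plot grouping variable must be categorical/ordinal, not {group}")
    groups, omitted = [], []
    for cat in group_var.categories or ():
        vals = [
            r.values.get(value) for r in records
            if r.values.get(group) == cat and not is_missing(r.values.get(value))
        ]
        if not vals:
            omitted.append(cat)
            continue
        groups.append({"value": cat, "stats": tukey_box_stats(vals, interpolated_quartiles)})
    if not groups:
        raise ValueError(f"no group of {group} has active non-missing {value} values")
    return BoxPlotSpec(value, group, groups, omitted)


# ---------------------------------------------------------------------------
# Raw table


@dataclass
class TableSpec:
    columns: list[str]
    rows: list[dict]  # {row_id, values: {col: value-or-""}}
    spec_version: int = SPEC_VERSION

    def to_dict(self) -> dict:
        return {"spec_version": self.spec_version, "view": "table", "columns": self.columns, "rows": self.rows}


def build_table(dataset: Dataset, filter_state: FilterState | None = None, columns=None) -> TableSpec:
    """Active rows in dataset order; missing cells render as empty strings."""
    cols = list(columns) if columns is not None else dataset.variable_names
    for c in cols:
        dataset.variable(c)
    rows = [
        {"row_id": r.row_id, "values": {c: ("" if is_missing(r.values.get(c)) else r.values.get(c)) for c in cols}}
        for r in _active_records(dataset, filter_state)
    ]
    return TableSpec(columns=cols, rows=rows)


__all__.append("brush_axis")
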