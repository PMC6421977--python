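"""Linked-card coordination: filters, selection and the event bus.

Filter cards hold one predicate over one variable.  The active row set is
the conjunction of all filter cards; inside a checked-set card the checked
values combine by disjunction.  Rows missing a value on a filtered variable
fail that filter (overridable with ``keep_missing``).  Every mutation
publishes a typed event on a publish/subscribe bus so that all subscribed
cards stay consistent without the sender knowing its receivers.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable, Literal

from .dataset import Dataset, SchemaError, Variable, is_missing

__all__ = [
    "CheckedSet",
    "Range",
    "Spatial",
    "FilterCard",
    "FilterState",
    "SelectionState",
    "CardEvent",
    "EventBus",
    "Board",
    "evaluate",
    "row_passes",
]

logger = logging.getLogger(__name__)

EventType = Literal["filter_changed", "selection_changed", "schema_changed", "data_changed"]


# ---------------------------------------------------------------------------
# Predicates


@dataclass(frozen=True)
class CheckedSet:
    """Checked-box predicate for categorical/ordinal variables.

    Disjunction over the checked values; an empty set matches nothing
    (distinct from the pass-all default of a freshly created card).
    """

    values: frozenset

    def __init__(self, values):
        object.__setattr__(self, "values", frozenset(values))


@dataclass(frozen=True)
class Range:
    """Dual-knob inclusive range for quantitative (raw value) or ordinal
    (category rank) variables."""

    lo: float
    hi: float

    def __post_init__(self):
        if self.lo > self.hi:
            raise ValueError(f"range lo {self.lo} > hi {self.hi}")


@dataclass(frozen=True)
class Spatial:
    """Image-backed predicate: values toggled by clicking annotated regions.

    Unlike :class:`CheckedSet`, an empty value set means *no region selected*
    and passes every row (clicking a region twice returns to pass-all).
    """

    image_id: str
    values: frozenset

    def __init__(self, image_id: str, values=()):
        object.__setattr__(self, "image_id", image_id)
        object.__setattr__(self, "values", frozenset(values))


Predicate = CheckedSet | Range | Spatial


@dataclass
class FilterCard:
    card_id: str
    variable: str
    predicate: Predicate


def _check_predicate(var: Variable, predicate: Predicate) -> None:
    if isinstance(predicate, CheckedSet):
        if var.kind == "quantitative":
            raise SchemaError(f"checked-set filter needs a categorical/ordinal variable, {var.name} is quantitative")
        unknown = predicate.values - set(var.categories or ())
        if unknown:
            raise ValueError(f"{var.name}: unknown categories in checked set: {sorted(map(str, unknown))}")
    elif isinstance(predicate, Range):
        if var.kind == "categorical":
            raise SchemaError(f"range filter needs a quantitative/ordinal variable, {var.name} is categorical")
    elif isinstance(predicate, Spatial):
        if var.kind == "quantitative":
            raise SchemaError(f"spatial filter needs a categorical/ordinal variable, {var.name} is quantitative")
        unknown = predicate.values - set(var.categories or ())
        if unknown:
            raise ValueError(f"{var.name}: unknown categories in spatial selection: {sorted(map(str, unknown))}")
    else:
        raise TypeError(f"unknown predicate type: {predicate!r}")


def row_passes(card: FilterCard, dataset: Dataset, row_values: dict, keep_missing: bool = False) -> bool:
    """Does a single row satisfy one filter card?"""
    var = dataset.variable(card.variable)
    value = row_values.get(card.variable)
    pred = card.predicate
    if isinstance(pred, Spatial) and not pred.values:
        return True  # no region selected: pass-all
    if is_missing(value):
        return keep_missing
    if isinstance(pred, (CheckedSet, Spatial)):
        return value in pred.values
    if isinstance(pred, Range):
        # ordinals with numeric categories filter in value space (slider shows
        # the values); string-coded ordinal scales filter by category rank
        if var.kind == "ordinal" and not isinstance(value, (int, float)):
            return pred.lo <= var.rank(value) <= pred.hi
        return pred.lo <= float(value) <= pred.hi
    raise TypeError(f"unknown predicate type: {pred!r}")


def evaluate(filters, dataset: Dataset, keep_missing: bool = False) -> set[str]:
    """Active row set: rows satisfying EVERY filter card (empty set of
    filters passes all rows)."""
    cards = list(filters)
    for card in cards:
        _check_predicate(dataset.variable(card.variable), card.predicate)
    active = set()
    for record in dataset.rows:
        if all(row_passes(c, dataset, record.values, keep_missing) for c in cards):
            active.add(record.row_id)
    return active


# ---------------------------------------------------------------------------
# Events


@dataclass(frozen=True)
class CardEvent:
    event_type: EventType
    source_card: str
    payload: dict = field(default_factory=dict)


class EventBus:
    """Publish/subscribe hub.  Senders never address receivers directly;
    subscribers are invoked in registration order, and one subscriber's
    failure never silences the rest."""

    def __init__(self):
        self._subs: list[tuple[str, EventType, Callable[[CardEvent], None]]] = []

    def subscribe(self, card_id: str, event_type: EventType, callback: Callable[[CardEvent], None]) -> None:
        self._subs.append((card_id, event_type, callback))

    def unsubscribe(self, card_id: str, event_type: EventType | None = None) -> None:
        self._subs = [
            s for s in self._subs if not (s[0] == card_id and (event_type is None or s[1] == event_type))
        ]

    def publish(self, event: CardEvent) -> int:
        """Deliver to every matching subscriber exactly once; returns the
        number of deliveries."""
        delivered = 0
        for card_id, event_type, callback in list(self._subs):
            if event_type == event.event_type:
                try:
                    callback(event)
                except Exception:
                    logger.exception("subscriber %s failed on %s", card_id, event.event_type)
                delivered += 1
        return delivered


# ---------------------------------------------------------------------------
# State containers


@dataclass
class SelectionState:
    """Highlighted rows.  Highlighting flags rows for emphasis in views; it
    never removes rows from anything."""

    highlighted_rows: set = field(default_factory=set)


class FilterState:
    """The set of filter cards and the derived active row set."""

    def __init__(self, dataset: Dataset, keep_missing: bool = False):
        self.dataset = dataset
        self.keep_missing = keep_missing
        self.filters: dict[str, FilterCard] = {}
        self._active: set[str] | None = None

    def cards(self) -> list[FilterCard]:
        return list(self.filters.values())

    @property
    def active_rows(self) -> set[str]:
        if self._active is None:
            self._active = evaluate(self.cards(), self.dataset, self.keep_missing)
        return set(self._active)

    def invalidate(self) -> None:
        self._active = None


def pass_all_predicate(var: Variable, dataset: Dataset) -> Predicate:
    """The initial predicate of a fresh filter card: all boxes checked, or
    the full observed range."""
    if var.kind == "categorical":
        return CheckedSet(var.categories or ())
    if var.kind == "ordinal":
        return CheckedSet(var.categories or ())
    col = [v for v in dataset.column(var.name) if not is_missing(v)]
    if not col:
        raise ValueError(f"{var.name}: cannot build a range filter on an all-missing column")
    return Range(float(min(col)), float(max(col)))


class Board:
    """The linking hub: one dataset, one filter state, one selection, one bus.

    Cards (filters, views, images, stats) coordinate exclusively through this
    object; any mutation republishes the appropriate event so subscribers
    rebuild from fresh state.
    """

    def __init__(self, dataset: Dataset, keep_missing: bool = False, bus: EventBus | None = None):
        self.dataset = dataset
        self.bus = bus or EventBus()
        self.filter_state = FilterState(dataset, keep_missing=keep_missing)
        self.selection = SelectionState()
        self._card_counter = itertools.count(1)

    # -- filters ----------------------------------------------------------

    @property
    def active_rows(self) -> set[str]:
        return self.filter_state.active_rows

    def create_filter(self, variable: str, predicate: Predicate | None = None, card_id: str | None = None) -> FilterCard:
        var = self.dataset.variable(variable)
        if predicate is None:
            predicate = pass_all_predicate(var, self.dataset)
        _check_predicate(var, predicate)
        card_id = card_id or f"filter-{next(self._card_counter)}"
        if card_id in self.filter_state.filters:
            raise ValueError(f"duplicate card id: {card_id}")
        card = FilterCard(card_id=card_id, variable=variable, predicate=predicate)
        self.filter_state.filters[card_id] = card
        self.filter_state.invalidate()
        self.bus.publish(CardEvent("filter_changed", card_id, {"variable": variable}))
        return card

    def set_predicate(self, card: FilterCard | str, predicate: Predicate) -> FilterState:
        card_id = card if isinstance(card, str) else card.card_id
        if card_id not in self.filter_state.filters:
            raise KeyError(f"no such filter card: {card_id}")
        target = self.filter_state.filters[card_id]
        _check_predicate(self.dataset.variable(target.variable), predicate)
        target.predicate = predicate
        self.filter_state.invalidate()
        self.bus.publish(CardEvent("filter_changed", card_id, {"variable": target.variable}))
        return self.filter_state

    def remove_filter(self, card: FilterCard | str) -> None:
        card_id = card if isinstance(card, str) else card.card_id
        removed = self.filter_state.filters.pop(card_id, None)
        if removed is None:
            raise KeyError(f"no such filter card: {card_id}")
        self.filter_state.invalidate()
        self.bus.publish(CardEvent("filter_changed", card_id, {"variable": removed.variable, "removed": True}))

    # -- selection --------------------------------------------------------

    def select_rows(self, row_ids, source_card: str = "selection") -> None:
        ids = set(row_ids)
        unknown = ids - set(self.dataset.row_ids())
        if unknown:
            raise KeyError(f"unknown row ids: {sorted(unknown)}")
        self.selection.highlighted_rows = ids
        self.bus.publish(CardEvent("selection_changed", source_card, {"rows": sorted(ids)}))

    # -- dataset mutation -------------------------------------------------

    def replace_dataset(self, dataset: Dataset, event: EventType = "data_changed") -> None:
        """Swap the dataset (after schema edits or appends), keeping filter
        cards that still make sense and dropping the rest with a log line."""
        old_names = set(self.dataset.variable_names)
        self.dataset = dataset
        self.filter_state.dataset = dataset
        kept: dict[str, FilterCard] = {}
        for card_id, card in self.filter_state.filters.items():
            try:
                _check_predicate(dataset.variable(card.variable), card.predicate)
            except (SchemaError, ValueError, KeyError):
                logger.info("dropping filter %s on %r: incompatible with new schema", card_id, card.variable)
                continue
            kept[card_id] = card
        self.filter_state.filters = kept
        self.selection.highlighted_rows &= set(dataset.row_ids())
        self.filter_state.invalidate()
        payload = {"added": sorted(set(dataset.variable_names) - old_names)}
        self.bus.publish(CardEvent(event, "board", payload))


class LinkedCard:
    """Minimal coordinated card: caches the active row set and rebuilds it on
    every relevant event.  View/stats cards in this package derive from it;
    it also serves as the probe that coordination stays consistent."""

    def __init__(self, board: Board, card_id: str):
        self.board = board
        self.card_id = card_id
        self.cached_active: set[str] = set(board.active_rows)
        self.cached_selection: set[str] = set(board.selection.highlighted_rows)
        for event_type in ("filter_changed", "data_changed", "schema_changed"):
            board.bus.subscribe(card_id, event_type, self._refresh)
        board.bus.subscribe(card_id, "selection_changed", self._refresh_selection)

    def _refresh(self, event: CardEvent) -> None:
        self.cached_active = set(self.board.active_rows)
        self.on_refresh(event)

    def _refresh_selection(self, event: CardEvent) -> None:
        self.cached_selection = set(self.board.selection.highlighted_rows)
        self.on_refresh(event)

    def on_refresh(self, event: CardEvent) -> None:  # pragma: no cover - hook
        pass


__all__.append("LinkedCard")
__all__.append("pass_all_predicate")
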