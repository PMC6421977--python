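"""Save and resume an analysis session.

The session file is versioned JSON holding the dataset *by reference*
(path + a schema snapshot so recasts and renames survive), every card
descriptor (filters with predicates, image cards with their spatial
annotations, view configurations, statistics configuration), the selection
and the card layout order.  Loading a session rebuilds a Board whose active
rows, view specs and statistics reports equal the saved session's exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .coordination import Board, CheckedSet, Range, Spatial
from .dataset import Dataset, Record, Variable, load_table
from .images import ImageRegistry, SpatialAssociation
from .stats import StatsConfig

__all__ = ["SessionState", "SPEC_VERSION", "save_session", "load_session", "snapshot", "restore"]

SPEC_VERSION = 1


class SessionVersionError(ValueError):
    pass


@dataclass
class SessionState:
    dataset_path: str
    schema: list  # schema snapshot, applied over the loaded file
    filters: list = field(default_factory=list)
    images: list = field(default_factory=list)
    view_configs: list = field(default_factory=list)
    stats_config: dict = field(default_factory=lambda: asdict(StatsConfig()))
    selection: list = field(default_factory=list)
    layout_order: list = field(default_factory=list)
    keep_missing: bool = False
    renames: dict = field(default_factory=dict)  # file column name -> session variable name
    spec_version: int = SPEC_VERSION


def _predicate_to_doc(pred) -> dict:
    if isinstance(pred, CheckedSet):
        return {"type": "checked_set", "values": sorted(pred.values, key=repr)}
    if isinstance(pred, Range):
        return {"type": "range", "lo": pred.lo, "hi": pred.hi}
    if isinstance(pred, Spatial):
        return {"type": "spatial", "image_id": pred.image_id, "values": sorted(pred.values, key=repr)}
    raise TypeError(f"unknown predicate: {pred!r}")


def _predicate_from_doc(doc: dict):
    t = doc["type"]
    if t == "checked_set":
        return CheckedSet(doc["values"])
    if t == "range":
        return Range(doc["lo"], doc["hi"])
    if t == "spatial":
        return Spatial(doc["image_id"], doc["values"])
    raise ValueError(f"unknown predicate type in session: {t!r}")


def snapshot(
    board: Board,
    dataset_path: str | Path,
    registry: ImageRegistry | None = None,
    view_configs: list | None = None,
    stats_config: StatsConfig = StatsConfig(),
    layout_order: list | None = None,
    renames: dict | None = None,
) -> SessionState:
    """Capture the board (and optional image registry) as a SessionState."""
    filters = [
        {"card_id": c.card_id, "variable": c.variable, "predicate": _predicate_to_doc(c.predicate)}
        for c in board.filter_state.cards()
    ]
    images = []
    if registry is not None:
        for card in registry.cards.values():
            doc = {
                "image_id": card.image_id,
                "path": str(card.path),
                "title": card.title,
                "tags": sorted(card.tags),
                "associations": dict(card.associations),
                "notes": card.notes,
                "spatial": None,
            }
            if card.spatial is not None:
                doc["spatial"] = {
                    "variable": card.spatial.variable,
                    "regions": [
                        {"value": r.value, "polygon": [[x, y] for x, y in r.polygon]}
                        for r in card.spatial.regions
                    ],
                }
            images.append(doc)
    return SessionState(
        dataset_path=str(dataset_path),
        schema=board.dataset.schema_snapshot(),
        filters=filters,
        images=images,
        view_configs=list(view_configs or []),
        stats_config=asdict(stats_config),
        selection=sorted(board.selection.highlighted_rows),
        layout_order=list(layout_order or [c["card_id"] for c in filters]),
        keep_missing=board.filter_state.keep_missing,
        renames=dict(renames or {}),
    )


def save_session(state: SessionState, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(asdict(state), fh, indent=1, sort_keys=True, ensure_ascii=False)
        fh.write("\n")


def load_session(path: str | Path) -> SessionState:
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such session file: {path}")
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    version = doc.get("spec_version")
    if version != SPEC_VERSION:
        raise SessionVersionError(
            f"session version {version!r} is not supported (expected {SPEC_VERSION}); no migration available"
        )
    return SessionState(**doc)


def _apply_schema_snapshot(dataset: Dataset, schema: list) -> Dataset:
    """Re-impose saved kinds/categories/order on a freshly loaded table."""
    variables, columns = [], {}
    by_loaded_name = {v.name: v for v in dataset.variables}
    for i, doc in enumerate(schema):
        name = doc["name"]
        if name not in by_loaded_name:
            raise ValueError(f"session schema names variable {name!r} absent from the dataset file")
        var = Variable(
            name=name,
            kind=doc["kind"],
            categories=tuple(doc["categories"]) if doc["categories"] is not None else None,
            display_order=i,
        )
        variables.append(var)
        col = dataset.column(name)
        if var.kind == "quantitative":
            columns[name] = [None if v is None else float(v) for v in col]
        elif var.kind == "ordinal" and all(isinstance(c, int) for c in var.categories or ()):
            columns[name] = [None if v is None else int(float(v)) for v in col]
        else:
            columns[name] = [None if v is None else (v if v in (var.categories or ()) else str(v)) for v in col]
    rows = [
        Record(r.row_id, {v.name: columns[v.name][i] for v in variables})
        for i, r in enumerate(dataset.rows)
    ]
    return Dataset(variables=variables, rows=rows, source_ids=list(dataset.source_ids))


def restore(state: SessionState, dataset_path: str | Path | None = None) -> tuple[Board, ImageRegistry]:
    """Rebuild a Board (+ image registry) from a session.

    ``dataset_path`` overrides the stored reference when the file has moved;
    a missing file raises an error naming the path.
    """
    path = Path(dataset_path or state.dataset_path)
    if not path.exists():
        raise IOError(
            f"dataset file {path} referenced by the session is missing; "
            "pass dataset_path= (or --dataset) to point at its new location"
        )
    dataset = load_table(path)
    if state.renames:
        from .dataset import Rename, edit_schema

        dataset = edit_schema(
            dataset,
            [Rename(src, dst) for src, dst in state.renames.items()
             if src != dst and src in dataset.variable_names],
        )
    dataset = _apply_schema_snapshot(dataset, state.schema)
    board = Board(dataset, keep_missing=state.keep_missing)
    registry = ImageRegistry(board)

    for doc in state.images:
        card = registry.register_image(
            doc["path"], title=doc["title"], tags=doc["tags"],
            associations=doc["associations"], notes=doc["notes"],
        )
        registry.cards.pop(card.image_id)
        card.image_id = doc["image_id"]  # keep ids stable across the round trip
        registry.cards[card.image_id] = card
        if doc["spatial"] is not None:
            registry.attach_spatial(card, SpatialAssociation(doc["spatial"]["variable"], doc["spatial"]["regions"]))

    for doc in state.filters:
        board.create_filter(doc["variable"], _predicate_from_doc(doc["predicate"]), card_id=doc["card_id"])
    if state.selection:
        board.select_rows(state.selection)
    return board, registry
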