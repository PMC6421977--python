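"""Domain-specific data cards: an image registry and spatial filters.

Raw histology images (e.g. immunostained hippocampal sections) are
registered with free-form tags and associations to categorical/ordinal
values (an image "belongs" to patient Az1, say).  A *spatial association*
annotates image areas with category values of one variable; clicking inside
an annotated area then toggles that value in a spatial filter card, so the
raw image itself becomes a filter over the tabular data.

Coordinates are pixels, origin at the top-left corner, x rightward and
y downward.  Overlapping regions resolve in listed order (first hit wins);
polygon boundaries count as inside so border clicks act.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from PIL import Image
from shapely.geometry import Point, Polygon, box

from .coordination import Board, CardEvent, FilterCard, Spatial
from .dataset import Dataset, SchemaError

__all__ = [
    "SpatialRegion",
    "SpatialAssociation",
    "ImageCard",
    "ImageRegistry",
    "hit_test",
    "load_annotation",
    "save_annotation",
    "mask_to_association",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpatialRegion:
    value: str | int
    polygon: tuple  # ((x, y), ...) pixel vertices

    def __init__(self, value, polygon):
        object.__setattr__(self, "value", value)
        object.__setattr__(self, "polygon", tuple((float(x), float(y)) for x, y in polygon))
        if len(self.polygon) < 3:
            raise ValueError(f"region {value!r}: polygon needs at least 3 vertices")

    def shape(self) -> Polygon:
        return Polygon(self.polygon)


@dataclass(frozen=True)
class SpatialAssociation:
    variable: str
    regions: tuple

    def __init__(self, variable: str, regions):
        object.__setattr__(self, "variable", variable)
        object.__setattr__(
            self,
            "regions",
            tuple(r if isinstance(r, SpatialRegion) else SpatialRegion(**r) for r in regions),
        )


@dataclass
class ImageCard:
    image_id: str
    path: Path
    title: str = ""
    tags: set = field(default_factory=set)
    associations: dict = field(default_factory=dict)  # variable -> category value
    notes: str = ""
    width: int = 0
    height: int = 0
    spatial: SpatialAssociation | None = None


def hit_test(assoc: SpatialAssociation, point: tuple[float, float], bounds: tuple[int, int] | None = None):
    """Category value of the first listed region containing ``point``.

    Boundary points count as inside; returns None when no region contains
    the point.  With ``bounds`` given, points outside the image raise.
    """
    x, y = point
    if bounds is not None:
        w, h = bounds
        if not (0 <= x <= w and 0 <= y <= h):
            raise ValueError(f"point {point} outside image bounds {bounds}")
    p = Point(x, y)
    for region in assoc.regions:
        if region.shape().covers(p):
            return region.value
    return None


def load_annotation(path: str | Path) -> SpatialAssociation:
    """Read a sidecar annotation JSON:
    ``{"variable": str, "regions": [{"value": v, "polygon": [[x,y],...]}]}``."""
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    return SpatialAssociation(variable=doc["variable"], regions=doc["regions"])


def save_annotation(assoc: SpatialAssociation, path: str | Path) -> None:
    doc = {
        "variable": assoc.variable,
        "regions": [
            {"value": r.value, "polygon": [[x, y] for x, y in r.polygon]} for r in assoc.regions
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def mask_to_association(mask_path: str | Path, variable: str, value_map: dict) -> SpatialAssociation:
    """Convenience importer: indexed/grayscale PNG label mask + label→value map.

    Each labelled pixel block is converted to polygons by unioning unit pixel
    squares; intended for small masks, not megapixel segmentations.
    """
    import numpy as np
    from shapely.ops import unary_union

    arr = np.asarray(Image.open(mask_path).convert("I"))
    regions = []
    for label, value in value_map.items():
        ys, xs = np.nonzero(arr == int(label))
        if len(xs) == 0:
            logger.warning("label %s absent from mask %s", label, mask_path)
            continue
        union = unary_union([box(x, y, x + 1, y + 1) for x, y in zip(xs.tolist(), ys.tolist())])
        polys = [union] if union.geom_type == "Polygon" else list(union.geoms)
        for poly in polys:
            regions.append(SpatialRegion(value=value, polygon=list(poly.exterior.coords)[:-1]))
    if not regions:
        raise ValueError(f"{mask_path}: no labelled pixels matched the value map")
    return SpatialAssociation(variable=variable, regions=regions)


class ImageRegistry:
    """All registered image cards, queryable by tag and by associated value."""

    def __init__(self, board: Board | None = None):
        self.board = board
        self.cards: dict[str, ImageCard] = {}
        self._counter = itertools.count(1)

    def _dataset(self) -> Dataset:
        if self.board is None:
            raise RuntimeError("registry is not attached to a board")
        return self.board.dataset

    # -- registration -----------------------------------------------------

    def register_image(
        self,
        path: str | Path,
        title: str = "",
        tags=(),
        associations: dict | None = None,
        notes: str = "",
    ) -> ImageCard:
        """Register an image file; width/height are read from the file.

        Associations must target categorical/ordinal variables and existing
        category values.  Duplicate paths create independent cards.
        """
        path = Path(path)
        try:
            with Image.open(path) as im:
                im.verify()
            with Image.open(path) as im:
                width, height = im.size
        except FileNotFoundError:
            raise IOError(f"no such image: {path}") from None
        except Exception as exc:
            raise ValueError(f"{path}: not a decodable image ({exc})") from None

        associations = dict(associations or {})
        if self.board is not None:
            for name, value in associations.items():
                var = self._dataset().variable(name)
                if var.kind == "quantitative":
                    raise SchemaError(
                        f"image association must target a categorical/ordinal variable, {name} is quantitative"
                    )
                if var.categories and value not in var.categories:
                    raise ValueError(f"{name}: {value!r} is not a category")

        card = ImageCard(
            image_id=f"image-{next(self._counter)}",
            path=path,
            title=title or path.stem,
            tags=set(tags),
            associations=associations,
            notes=notes,
            width=width,
            height=height,
        )
        self.cards[card.image_id] = card
        if self.board is not None:
            self.board.bus.publish(CardEvent("data_changed", card.image_id, {"image": str(path)}))
        return card

    def query_images(self, tag: str | None = None, variable: str | None = None, value=None) -> list[ImageCard]:
        """Cards matching the conjunction of the given criteria (all cards
        when none is given)."""
        out = []
        for card in self.cards.values():
            if tag is not None and tag not in card.tags:
                continue
            if variable is not None:
                if variable not in card.associations:
                    continue
                if value is not None and card.associations[variable] != value:
                    continue
            elif value is not None:
                if value not in card.associations.values():
                    continue
            out.append(card)
        return out

    # -- spatial filtering ------------------------------------------------

    def attach_spatial(self, image: ImageCard | str, assoc: SpatialAssociation) -> ImageCard:
        """Attach region annotations; the image becomes a spatial filter
        source.  Region values must be categories of the variable; polygons
        reaching outside the image are clipped with a warning."""
        card = self.cards[image if isinstance(image, str) else image.image_id]
        if not assoc.regions:
            raise ValueError("spatial association needs at least one region (nothing clickable otherwise)")
        var = self._dataset().variable(assoc.variable)
        if var.kind == "quantitative":
            raise SchemaError(f"spatial association must target a categorical/ordinal variable, not {assoc.variable}")
        cats = set(var.categories or ())
        frame = box(0, 0, card.width, card.height)
        clipped_regions = []
        for region in assoc.regions:
            if region.value not in cats:
                raise ValueError(f"{assoc.variable}: region value {region.value!r} is not a category")
            shape = region.shape()
            if not frame.covers(shape):
                logger.warning(
                    "image %s: region %r extends outside %dx%d bounds; clipped",
                    card.image_id, region.value, card.width, card.height,
                )
                shape = shape.intersection(frame)
                if shape.is_empty or shape.geom_type not in ("Polygon",):
                    raise ValueError(f"region {region.value!r} lies entirely outside the image")
                region = SpatialRegion(region.value, list(shape.exterior.coords)[:-1])
            clipped_regions.append(region)
        card.spatial = SpatialAssociation(assoc.variable, clipped_regions)
        if self.board is not None:
            self.board.bus.publish(CardEvent("data_changed", card.image_id, {"spatial": assoc.variable}))
        return card

    def _spatial_filter_card(self, card: ImageCard) -> FilterCard:
        assert card.spatial is not None
        board = self.board
        for fc in board.filter_state.cards():
            if isinstance(fc.predicate, Spatial) and fc.predicate.image_id == card.image_id:
                return fc
        return board.create_filter(
            card.spatial.variable,
            Spatial(card.image_id, ()),
            card_id=f"spatial-{card.image_id}",
        )

    def click_to_filter(self, image: ImageCard | str, point: tuple[float, float]):
        """Toggle the clicked region's value in the image's spatial filter.

        Clicks on unannotated areas are no-ops.  Returns the board's filter
        state so callers can read the updated active rows.
        """
        card = self.cards[image if isinstance(image, str) else image.image_id]
        if card.spatial is None:
            raise RuntimeError(f"{card.image_id} has no spatial association")
        value = hit_test(card.spatial, point, bounds=(card.width, card.height))
        if value is None:
            return self.board.filter_state
        fc = self._spatial_filter_card(card)
        values = set(fc.predicate.values)
        values.symmetric_difference_update({value})
        self.board.set_predicate(fc, Spatial(card.image_id, values))
        return self.board.filter_state
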