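"""Random dataset/filter generators and independent oracles.

The oracles here deliberately re-derive results by the most literal route
possible (row-by-row predicate checks, label-mask rasterisation, median-of-
halves on slices) and never call the code paths they check.
"""

from __future__ import annotations

import math

import numpy as np

from cardlink.coordination import CheckedSet, FilterCard, Range, Spatial
from cardlink.dataset import Dataset, Record, Variable



# ---------------------------------------------------------------------------
# Random typed datasets (<=50 rows, <=6 variables) with missing cells


def random_dataset(rng: np.random.Generator, max_rows: int = 50, max_vars: int = 6) -> Dataset:
    n_rows = int(rng.integers(1, max_rows + 1))
    n_vars = int(rng.integers(1, max_vars + 1))
    variables, columns = [], {}
    for j in range(n_vars):
        name = f"v{j}"
        kind = rng.choice(["categorical", "ordinal", "quantitative"])
        if kind == "categorical":
            cats = tuple(f"c{k}" for k in range(int(rng.integers(2, 6))))
            col = [str(rng.choice(cats)) for _ in range(n_rows)]
            variables.append(Variable(name, "categorical", cats, j))
        elif kind == "ordinal":
            cats = tuple(range(2, 2 + int(rng.integers(2, 6))))  # value != rank
            col = [int(rng.choice(cats)) for _ in range(n_rows)]
            variables.append(Variable(name, "ordinal", cats, j))
        else:
            col = [float(rng.normal(10, 5)) for _ in range(n_rows)]
            variables.append(Variable(name, "quantitative", None, j))
        for i in range(n_rows):
            if rng.random() < 0.08:
                col[i] = None
        columns[name] = col
    rows = [Record(f"r{i}", {v.name: columns[v.name][i] for v in variables}) for i in range(n_rows)]
    return Dataset(variables=variables, rows=rows)


def random_filters(rng: np.random.Generator, dataset: Dataset, max_filters: int = 4) -> list[FilterCard]:
    cards = []
    n = int(rng.integers(0, max_filters + 1))
    candidates = list(dataset.variables)
    for k in range(n):
        var = candidates[int(rng.integers(0, len(candidates)))]
        if var.kind == "quantitative":
            col = [v for v in dataset.column(var.name) if v is not None]
            lo_base, hi_base = (min(col), max(col)) if col else (0.0, 1.0)
            a, b = sorted(rng.uniform(lo_base - 1, hi_base + 1, size=2))
            pred = Range(float(a), float(b))
        elif var.kind == "ordinal" and rng.random() < 0.5:
            a, b = sorted(rng.choice(var.categories, size=2, replace=True))
            pred = Range(int(a), int(b))
        else:
            k_checked = int(rng.integers(0, len(var.categories) + 1))
            checked = rng.choice(len(var.categories), size=k_checked, replace=False)
            pred = CheckedSet(var.categories[i] for i in checked)
        cards.append(FilterCard(f"f{k}", var.name, pred))
    return cards


# ---------------------------------------------------------------------------
# Brute-force filter oracle: literal per-row predicate conjunction


def oracle_active_rows(filters, dataset: Dataset, keep_missing: bool = False) -> set[str]:
    active = set()
    for record in dataset.rows:
        ok = True
        for card in filters:
            var = dataset.variable(card.variable)
            value = record.values.get(card.variable)
            pred = card.predicate
            if isinstance(pred, Spatial) and len(pred.values) == 0:
                continue  # no region selected: pass-all
            if value is None:
                if not keep_missing:
                    ok = False
                    break
                continue
            if isinstance(pred, (CheckedSet, Spatial)):
                if value not in pred.values:
                    ok = False
                    break
            else:
                if var.kind == "ordinal" and not isinstance(value, (int, float)):
                    x = var.categories.index(value)
                else:
                    x = float(value)
                if not (pred.lo <= x <= pred.hi):
                    ok = False
                    break
        if ok:
            active.add(record.row_id)
    return active


# ---------------------------------------------------------------------------
# Tukey hinge oracle: median-of-halves spelled out on slices


def oracle_tukey(values):
    vals = np.sort(np.asarray([float(v) for v in values if v is not None]))
    n = len(vals)
    half = math.ceil(n / 2)
    q1 = float(np.median(vals[:half]))
    q3 = float(np.median(vals[-half:]))
    med = float(np.median(vals))
    iqr = q3 - q1
    lo_f, hi_f = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = vals[(vals >= lo_f) & (vals <= hi_f)]
    outliers = vals[(vals < lo_f) | (vals > hi_f)]
    return {
        "n": n, "median": med, "q1": q1, "q3": q3,
        "whisker_lo": float(inside.min()), "whisker_hi": float(inside.max()),
        "outliers": sorted(outliers.tolist()),
    }


# ---------------------------------------------------------------------------
# Rasterised label-mask oracle for point-in-polygon hit testing


def rasterise_labels(regions, width: int, height: int) -> np.ndarray:
    """First-hit-wins label mask (0 = background, i+1 = regions[i])."""
    from PIL import Image, ImageDraw

    mask = np.zeros((height, width), dtype=np.int32)
    for i, region in enumerate(regions):
        im = Image.new("I", (width, height), 0)
        ImageDraw.Draw(im).polygon([(x, y) for x, y in region.polygon], fill=1, outline=1)
        layer = np.asarray(im)
        mask[(mask == 0) & (layer == 1)] = i + 1
    return mask


def random_simple_polygon(rng: np.random.Generator, cx, cy, r_max, n_vertices=8):
    """Star-shaped (hence simple) polygon around a centre."""
    angles = np.sort(rng.uniform(0, 2 * math.pi, size=n_vertices))
    radii = rng.uniform(0.3 * r_max, r_max, size=n_vertices)
    return [(cx + r * math.cos(a), cy + r * math.sin(a)) for a, r in zip(angles, radii)]

NEUN = "Neuronal density per volume (NeuN)"
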