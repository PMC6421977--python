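"""Build the six coordinated view specs from one shared filter state.

Every builder is a pure function of (dataset, filter state, selection):
all views computed from the same state agree on the active rows, and the
parallel-set widths obey exact conservation laws.
"""

from cardlink import (
    Board,
    CheckedSet,
    build_box_plot,
    build_parallel_coordinates,
    build_parallel_sets,
    build_radar,
    build_scatter,
    build_table,
    generate_clinical_dataset,
)
from cardlink.fixtures import FixtureConfig

NEUN = "Neuronal density per volume (NeuN)"
ds = generate_clinical_dataset(FixtureConfig(seed=2))
board = Board(ds)
card = board.create_filter("Condition")
board.set_predicate(card, CheckedSet({"AD"}))
fs, sel = board.filter_state, board.selection

pcp = build_parallel_coordinates(ds, ["Patient", "Region", NEUN], fs, sel)
print(f"parallel coordinates: {len(pcp.polylines)} polylines (one per active AD row)")

psets = build_parallel_sets(ds, ["Region", "Braak Scale"], fs)
for tier in psets.tiers:
    widths = {b['value']: float(b['width_fraction']) for b in tier['bars']}
    print(f"parallel sets tier {tier['variable']!r}: {widths}")
print("  (bar widths are joint-frequency fractions; they sum to 1 exactly)")

radar = build_radar(ds, ["Age at diagnosis", NEUN, "Disease progression (years)"], fs, sel)
print(f"radar: {len(radar.polygons)} polygons, axes min-max normalised over active rows")

scatter = build_scatter(ds, "Age at diagnosis", NEUN, fs, sel)
print(f"scatter: {len(scatter.points)} points (active rows complete in both variables)")

box = build_box_plot(ds, NEUN, "Region", fs)
for g in box.groups:
    s = g["stats"]
    print(f"box {g['value']:>4}: median={s.median:7.2f}  IQR=[{s.q1:.2f}, {s.q3:.2f}]  outliers={list(s.outliers)}")
print("  (Tukey hinges; whiskers clamp to data within 1.5*IQR fences)")

table = build_table(ds, fs, columns=["Patient", "Region", NEUN])
print(f"table: {len(table.rows)} rows x {len(table.columns)} columns")
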