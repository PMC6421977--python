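"""Load a table, inspect the inferred schema, and compose filters.

Generates a small synthetic AD-shaped cohort (12 patients x 5 hippocampal
subfields), writes it to CSV, loads it back with automatic variable typing,
and narrows the active row set with two linked filter cards.
"""

import tempfile
from pathlib import Path

from cardlink import Board, CheckedSet, Range, generate_clinical_dataset, load_table, write_table
from cardlink.fixtures import FixtureConfig

NEUN = "Neuronal density per volume (NeuN)"

with tempfile.TemporaryDirectory() as tmp:
    csv = Path(tmp) / "cohort.csv"
    write_table(generate_clinical_dataset(FixtureConfig(seed=1)), csv)
    ds = load_table(csv)

print(f"{len(ds)} rows x {len(ds.variables)} variables")
for v in ds.variables:
    cats = f" {list(v.categories)[:4]}..." if v.categories else ""
    print(f"  {v.name:45s} {v.kind}{cats}")

board = Board(ds)
region = board.create_filter("Region")          # pass-all: every box checked
print(f"\nfresh Region filter: {len(board.active_rows)} active rows (pass-all)")

board.set_predicate(region, CheckedSet({"CA1", "DG"}))
print(f"Region in {{CA1, DG}}:  {len(board.active_rows)} active rows")

col = [v for v in ds.column(NEUN) if v is not None]
neun = board.create_filter(NEUN)
board.set_predicate(neun, Range(min(col), sum(col) / len(col)))
print(f"+ NeuN <= column mean: {len(board.active_rows)} active rows")
print("\nFilters AND together across cards; checked values OR within a card.")
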