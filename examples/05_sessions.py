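"""Suspend an analysis to a session file and resume it exactly.

The session JSON stores the dataset by reference plus a schema snapshot,
every filter card, image card and the selection; restoring it reproduces
the active rows, view specs and statistics reports bit for bit.
"""

import json
import tempfile
from pathlib import Path

from cardlink import (
    Board,
    CheckedSet,
    build_table,
    generate_clinical_dataset,
    load_session,
    load_table,
    restore,
    save_session,
    snapshot,
    write_table,
)
from cardlink.fixtures import FixtureConfig

with tempfile.TemporaryDirectory() as tmp:
    csv = Path(tmp) / "cohort.csv"
    write_table(generate_clinical_dataset(FixtureConfig(seed=5)), csv)
    board = Board(load_table(csv))
    card = board.create_filter("Braak Scale")
    board.set_predicate(card, CheckedSet({"III-IV", "V-VI"}))
    board.select_rows(["r0", "r12"])

    path = Path(tmp) / "analysis.cardlink.json"
    save_session(snapshot(board, csv), path)
    print(f"saved session: {path.stat().st_size} bytes of JSON")

    restored, _ = restore(load_session(path))
    same_active = restored.active_rows == board.active_rows
    a = build_table(board.dataset, board.filter_state).to_dict()
    b = build_table(restored.dataset, restored.filter_state).to_dict()
    print(f"active rows identical after reload: {same_active}")
    print(f"table spec bit-identical after reload: {json.dumps(a) == json.dumps(b)}")
    print(f"({len(board.active_rows)} rows with intermediate/late Braak stage stay active)")
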