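"""View builders: content, conservation laws, purity and coordination."""

from fractions import Fraction

import numpy as np
import pytest

from cardlink.coordination import Board, CheckedSet, Range
from cardlink.dataset import SchemaError, infer_schema
from cardlink.views import (
    add_axis,
    brush_axis,
    build_box_plot,
    build_parallel_coordinates,
    build_parallel_sets,
    build_radar,
    build_scatter,
    build_table,
    remove_axis,
    reorder_axes,
    tukey_box_stats,
)
from conftest import NEUN, oracle_tukey, random_dataset
from test_dataset import make_raw

AXES = ["Patient", "Region", NEUN]


class TestParallelCoordinates:
    def test_one_polyline_per_active_row(self, ad_dataset):
        board = Board(ad_dataset)
        spec = build_parallel_coordinates(ad_dataset, AXES, board.filter_state, board.selection)
        assert len(spec.polylines) == len(board.active_rows)
        assert [a.variable for a in spec.axes] == AXES

    def test_quantitative_axis_scaled_to_column_extent(self, ad_dataset):
        spec = build_parallel_coordinates(ad_dataset, AXES)
        dom = spec.axes[2].domain
        col = [v for v in ad_dataset.column(NEUN) if v is not None]
        assert (dom["min"], dom["max"]) == (min(col), max(col))
        positions = [p["positions"][2] for p in spec.polylines if p["positions"][2] is not None]
        assert min(positions) == 0.0 and max(positions) == 1.0

    def test_missing_value_becomes_gap(self):
        ds = infer_schema(make_raw({"a": ["1.0", "2.5"], "b": ["5.5", None]}))
        spec = build_parallel_coordinates(ds, ["a", "b"])
        assert spec.polylines[1]["positions"][1] is None

    def test_brush_mirrors_into_filter_state(self, ad_dataset):
        board = Board(ad_dataset)
        col = [v for v in ad_dataset.column(NEUN) if v is not None]
        mean = float(np.mean(col))
        brush_axis(board, NEUN, min(col), mean)
        spec = build_parallel_coordinates(ad_dataset, AXES, board.filter_state)
        expected = sum(
            1 for r in ad_dataset.rows
            if r.values.get(NEUN) is not None and r.values[NEUN] <= mean
        )
        assert len(spec.polylines) == expected
        assert spec.axes[2].brush == (min(col), mean)

    def test_zero_active_rows_keeps_axes(self, ad_dataset):
        board = Board(ad_dataset)
        card = board.create_filter("Region")
        board.set_predicate(card, CheckedSet(()))
        spec = build_parallel_coordinates(ad_dataset, AXES, board.filter_state)
        assert spec.polylines == [] and len(spec.axes) == 3

    def test_reorder_is_a_permutation(self, ad_dataset):
        spec = build_parallel_coordinates(ad_dataset, AXES)
        perm = [AXES[2], AXES[0], AXES[1]]
        out = reorder_axes(spec, perm, ad_dataset)
        for before, after in zip(spec.polylines, out.polylines):
            assert after["positions"] == [before["positions"][2], before["positions"][0], before["positions"][1]]

    def test_add_axis_flags_new_variable(self, ad_dataset):
        spec = build_parallel_coordinates(ad_dataset, ["Region", NEUN, "Condition"])
        out = add_axis(spec, "Patient", ad_dataset)
        assert [a.variable for a in out.axes] == ["Region", NEUN, "Condition", "Patient"]
        assert out.newly_added_axis == "Patient"

    def test_remove_brushed_axis_grows_active_rows(self, ad_dataset):
        board = Board(ad_dataset)
        col = [v for v in ad_dataset.column(NEUN) if v is not None]
        brush_axis(board, NEUN, min(col), float(np.median(col)))
        before = set(board.active_rows)
        spec = build_parallel_coordinates(ad_dataset, AXES, board.filter_state)
        remove_axis(spec, NEUN, ad_dataset, board=board)
        assert board.active_rows >= before
        assert f"brush:{NEUN}" not in board.filter_state.filters

    def test_too_few_axes_rejected(self, ad_dataset):
        with pytest.raises(ValueError, match="at least 2"):
            build_parallel_coordinates(ad_dataset, ["Region"])


class TestParallelSets:
    def test_simple_fractions(self):
        ds = infer_schema(make_raw({
            "Region": ["CA1"] * 4 + ["DG"] * 6,
            "Cond": ["AD"] * 5 + ["Ctl"] * 5,
        }))
        spec = build_parallel_sets(ds, ["Region", "Cond"])
        widths = {b["value"]: b["width_fraction"] for b in spec.tiers[0]["bars"]}
        assert widths == {"CA1": Fraction(2, 5), "DG": Fraction(3, 5)}

    def test_quantitative_tier_rejected(self, ad_dataset):
        with pytest.raises(SchemaError, match="recast"):
            build_parallel_sets(ad_dataset, ["Region", NEUN])

    def test_conservation_laws_exact_on_random_fixtures(self):
        """Bar widths sum to 1 per tier; each bar equals the sum of incident
        ribbons; ribbon widths sum to 1 — all in exact rational arithmetic,
        checked against a brute-force contingency table."""
        rng = np.random.default_rng(55)
        checked = 0
        while checked < 50:
            ds = random_dataset(rng, max_rows=40, max_vars=5)
            cats = [v.name for v in ds.variables if v.kind != "quantitative"]
            if len(cats) < 2:
                continue
            names = cats[:3]
            complete = [
                r for r in ds.rows if all(r.values.get(n) is not None for n in names)
            ]
            if not complete:
                continue
            spec = build_parallel_sets(ds, names)
            assert sum(r["width_fraction"] for r in spec.ribbons) == 1
            # brute-force contingency oracle
            for i, tier in enumerate(spec.tiers):
                assert sum(b["width_fraction"] for b in tier["bars"]) == 1
                for bar in tier["bars"]:
                    count = sum(1 for r in complete if r.values[tier["variable"]] == bar["value"])
                    assert bar["width_fraction"] == Fraction(count, len(complete))
                    incident = sum(
                        r["width_fraction"] for r in spec.ribbons if r["path"][i] == bar["value"]
                    )
                    assert incident == bar["width_fraction"]
            checked += 1

    def test_category_shuffle_changes_order_not_widths(self, ad_dataset):
        spec = build_parallel_sets(ad_dataset, ["Region", "Condition"])
        shuffled = build_parallel_sets(
            ad_dataset, ["Region", "Condition"],
            category_order={"Region": ["SUB", "CA3", "CA2", "CA1", "DG"]},
        )
        a = {b["value"]: b["width_fraction"] for b in spec.tiers[0]["bars"]}
        b = {x["value"]: x["width_fraction"] for x in shuffled.tiers[0]["bars"]}
        assert a == b
        assert [x["value"] for x in shuffled.tiers[0]["bars"]] == ["SUB", "CA3", "CA2", "CA1", "DG"]


class TestRadar:
    VARS = ["Age at diagnosis", NEUN, "Disease progression (years)"]

    def test_row_at_axis_maximum_maps_to_one(self, ad_dataset):
        spec = build_radar(ad_dataset, self.VARS)
        cols = np.array([[p["positions"][i] for p in spec.polygons] for i in range(3)])
        assert np.allclose(cols.max(axis=1), 1.0) and np.allclose(cols.min(axis=1), 0.0)

    def test_constant_axis_maps_to_half(self):
        ds = infer_schema(make_raw({
            "a": ["1.5", "2.5", "3.5"], "b": ["7.7", "7.7", "7.7"], "c": ["0.5", "1.0", "2.0"],
        }))
        spec = build_radar(ds, ["a", "b", "c"])
        assert all(p["positions"][1] == 0.5 for p in spec.polygons)

    def test_highlight_flags_only_selected(self, ad_dataset):
        board = Board(ad_dataset)
        board.select_rows(["r7"])
        spec = build_radar(ad_dataset, self.VARS, board.filter_state, board.selection)
        flags = {p["row_id"]: p["highlighted"] for p in spec.polygons}
        assert flags["r7"] is True
        assert sum(flags.values()) == 1

    def test_all_missing_axis_rejected(self):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ds = infer_schema(make_raw({"a": ["1.5", "2.5"], "b": [None, None], "c": ["1.0", "2.0"]}))
        ds = ds  # b typed categorical-empty; recast not possible — use numeric missing instead
        ds2 = infer_schema(make_raw({"a": ["1.5", "2.5"], "b": ["3.0", "4.5"], "c": ["1.0", "2.0"]}))
        board = Board(ds2)
        card = board.create_filter("b")
        board.set_predicate(card, Range(100, 200))  # no active rows with b
        with pytest.raises(ValueError):
            build_radar(ds2, ["a", "b", "c"], board.filter_state)


class TestScatter:
    def test_pairwise_complete_points_and_tooltip(self, ad_dataset):
        spec = build_scatter(ad_dataset, "Age at diagnosis", NEUN)
        n_expected = sum(
            1 for r in ad_dataset.rows
            if r.values.get("Age at diagnosis") is not None and r.values.get(NEUN) is not None
        )
        assert len(spec.points) == n_expected
        p0 = spec.points[0]
        assert p0["tooltip"] == ad_dataset.row(p0["row_id"]).values

    def test_row_missing_y_omitted_but_active_elsewhere(self):
        ds = infer_schema(make_raw({"x": ["1.0", "2.0"], "y": ["5.5", None]}))
        board = Board(ds)
        spec = build_scatter(ds, "x", "y", board.filter_state)
        assert [p["row_id"] for p in spec.points] == ["r0"]
        assert board.active_rows == {"r0", "r1"}

    def test_selecting_point_publishes_selection(self, ad_dataset):
        board = Board(ad_dataset)
        events = []
        board.bus.subscribe("probe", "selection_changed", events.append)
        spec = build_scatter(ad_dataset, "Age at diagnosis", NEUN, board.filter_state)
        target = spec.points[0]["row_id"]
        board.select_rows([target], source_card="scatter-1")
        assert board.selection.highlighted_rows == {target}
        assert len(events) == 1 and events[0].source_card == "scatter-1"
        spec2 = build_scatter(ad_dataset, "Age at diagnosis", NEUN, board.filter_state, board.selection)
        flagged = {p["row_id"] for p in spec2.points if p["highlighted"]}
        assert flagged == {target}


class TestBoxPlot:
    def test_worked_example_with_outlier(self):
        stats = tukey_box_stats([1, 2, 3, 4, 100])
        assert (stats.median, stats.q1, stats.q3) == (3, 2, 4)
        assert (stats.whisker_lo, stats.whisker_hi) == (1, 4)
        assert stats.outliers == (100,)
        assert stats.n == 5

    def test_all_equal_group_zero_width(self):
        stats = tukey_box_stats([7.5] * 6)
        assert stats.q1 == stats.median == stats.q3 == 7.5
        assert stats.outliers == ()

    def test_matches_hinge_oracle_on_random_samples(self):
        rng = np.random.default_rng(404)
        for _ in range(1000):
            vals = rng.normal(size=rng.integers(3, 60)).tolist()
            got = tukey_box_stats(vals)
            exp = oracle_tukey(vals)
            assert got.n == exp["n"]
            assert got.median == pytest.approx(exp["median"])
            assert got.q1 == pytest.approx(exp["q1"]) and got.q3 == pytest.approx(exp["q3"])
            assert got.whisker_lo == pytest.approx(exp["whisker_lo"])
            assert got.whisker_hi == pytest.approx(exp["whisker_hi"])
            assert sorted(got.outliers) == pytest.approx(exp["outliers"])
            # partition conservation: every value is in the box/whisker span or an outlier
            inside = sum(1 for v in vals if got.whisker_lo <= v <= got.whisker_hi)
            assert got.n == inside + len(got.outliers)

    def test_grouped_by_patient(self, ad_dataset):
        spec = build_box_plot(ad_dataset, NEUN, "Patient")
        assert {g["value"] for g in spec.groups} <= set(ad_dataset.variable("Patient").categories)
        for g in spec.groups:
            s = g["stats"]
            assert s.q1 <= s.median <= s.q3

    def test_non_quantitative_value_rejected(self, ad_dataset):
        with pytest.raises(SchemaError, match="quantitative"):
            build_box_plot(ad_dataset, "Region", "Condition")

    def test_empty_groups_omitted_with_note(self, ad_dataset):
        board = Board(ad_dataset)
        card = board.create_filter("Region")
        board.set_predicate(card, CheckedSet({"CA1"}))
        spec = build_box_plot(ad_dataset, NEUN, "Region", board.filter_state)
        assert [g["value"] for g in spec.groups] == ["CA1"]
        assert set(spec.omitted_groups) == {"DG", "CA2", "CA3", "SUB"}


class TestTable:
    def test_no_filters_full_table(self, ad_dataset):
        spec = build_table(ad_dataset)
        assert len(spec.rows) == len(ad_dataset)
        assert spec.columns == ad_dataset.variable_names

    def test_filtered_and_column_subset(self, ad_dataset):
        board = Board(ad_dataset)
        card = board.create_filter("Region")
        board.set_predicate(card, CheckedSet({"CA1"}))
        full = build_table(ad_dataset, board.filter_state)
        sub = build_table(ad_dataset, board.filter_state, columns=["Patient", NEUN])
        assert all(r["values"]["Region"] == "CA1" for r in full.rows)
        for fr, sr in zip(full.rows, sub.rows):
            assert sr["values"] == {k: fr["values"][k] for k in ("Patient", NEUN)}

    def test_missing_rendered_empty(self):
        ds = infer_schema(make_raw({"x": ["1.0", None]}))
        spec = build_table(ds)
        assert spec.rows[1]["values"]["x"] == ""


class TestCrossViewCoordination:
    def test_builders_pure_and_agree_on_active_rows(self, ad_dataset):
        """All six specs built from one FilterState agree on the active set,
        and rebuilding with identical inputs is bit-identical."""
        board = Board(ad_dataset)
        card = board.create_filter("Condition")
        board.set_predicate(card, CheckedSet({"AD"}))
        fs, sel = board.filter_state, board.selection
        active = board.active_rows

        pcp = build_parallel_coordinates(ad_dataset, AXES, fs, sel)
        table = build_table(ad_dataset, fs)
        scatter = build_scatter(ad_dataset, "Age at diagnosis", NEUN, fs, sel)
        radar = build_radar(ad_dataset, TestRadar.VARS, fs, sel)
        psets = build_parallel_sets(ad_dataset, ["Region", "Braak Scale"], fs)
        box = build_box_plot(ad_dataset, NEUN, "Region", fs)

        assert {p["row_id"] for p in pcp.polylines} == active
        assert {r["row_id"] for r in table.rows} == active
        assert {p["row_id"] for p in scatter.points} <= active
        assert {p["row_id"] for p in radar.polygons} <= active
        n_complete = sum(
            1 for r in ad_dataset.rows
            if r.row_id in active
            and r.values.get("Region") is not None and r.values.get("Braak Scale") is not None
        )
        assert psets.n_complete == n_complete
        assert sum(g["stats"].n for g in box.groups) == sum(
            1 for r in ad_dataset.rows if r.row_id in active and r.values.get(NEUN) is not None
        )
        # purity: identical inputs -> identical specs
        assert build_parallel_coordinates(ad_dataset, AXES, fs, sel).to_dict() == pcp.to_dict()
        assert build_table(ad_dataset, fs).to_dict() == table.to_dict()
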