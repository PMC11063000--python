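"""Designs, response tables, validation and occasion counting."""

import numpy as np
import pandas as pd
import pytest

from gtirt import (
    FacetSpec,
    MeasurementDesign,
    ResponseTable,
    count_occasions,
    count_responses,
    validate,
)
from gtirt.synthgen import example1


def crossed_design():
    return MeasurementDesign(
        n_objects=3,
        facets=(FacetSpec("rater", 2), FacetSpec("time", 2)),
        n_items=2,
        categories=3,
    )


# ---------------------------------------------------------------------------
# specification validation


def test_facet_reserved_names_rejected():
    for bad in ("object", "item", "response"):
        with pytest.raises(ValueError, match="reserved"):
            FacetSpec(bad, 3)


def test_facet_relation_and_kind_validated():
    with pytest.raises(ValueError):
        FacetSpec("rater", 3, relation="diagonal")
    with pytest.raises(ValueError):
        FacetSpec("rater", 3, kind="mixed")
    with pytest.raises(ValueError):
        FacetSpec("rater", 0)


def test_nested_under_rules():
    f = FacetSpec("student", 10, relation="nested")
    assert f.nested_under == "object"
    with pytest.raises(ValueError, match="only nesting under the object"):
        FacetSpec("student", 10, relation="nested", nested_under="rater")
    with pytest.raises(ValueError, match="only valid for nested"):
        FacetSpec("rater", 3, nested_under="object")


def test_design_validation_errors():
    with pytest.raises(ValueError, match="unique"):
        MeasurementDesign(3, (FacetSpec("r", 2), FacetSpec("r", 3)), 2)
    with pytest.raises(ValueError, match="one entry per item"):
        MeasurementDesign(3, (FacetSpec("r", 2),), 2, categories=[3])
    with pytest.raises(ValueError, match="at least 2 categories"):
        MeasurementDesign(3, (FacetSpec("r", 2),), 2, categories=[3, 1])
    with pytest.raises(ValueError, match="repeated"):
        MeasurementDesign(
            3,
            (FacetSpec("a", 2, relation="repeated"), FacetSpec("b", 2, relation="repeated")),
            2,
        )


def test_design_category_views():
    d = MeasurementDesign(2, (FacetSpec("r", 2),), 3, categories=[2, 3, 4])
    assert d.n_categories.tolist() == [2, 3, 4]
    assert d.max_category.tolist() == [1, 2, 3]
    assert d.facet("r").levels == 2
    with pytest.raises(KeyError):
        d.facet("nope")


# ---------------------------------------------------------------------------
# response tables


def full_table(design):
    rows = []
    for j in range(design.n_objects):
        for r in range(2):
            for t in range(2):
                for k in range(design.n_items):
                    rows.append((j, r, t, k, (j + r + t + k) % 3))
    return ResponseTable.from_records(rows, design.facet_names)


def test_from_records_and_columns():
    design = crossed_design()
    table = full_table(design)
    assert len(table) == 3 * 2 * 2 * 2
    assert table.objects.max() == 2
    assert set(table.frame.columns) == {"object", "rater", "time", "item", "response"}


def test_missing_column_rejected():
    with pytest.raises(ValueError, match="missing columns"):
        ResponseTable(pd.DataFrame({"object": [0], "item": [0]}), ("rater",))


def test_occasion_keys_sorted_unique():
    design = crossed_design()
    table = full_table(design)
    keys = table.occasion_keys()
    assert len(keys) == 12
    arr = keys.to_numpy()
    assert (np.lexsort(arr.T[::-1]) == np.arange(12)).all()


def test_occasion_index_maps_records():
    design = crossed_design()
    table = full_table(design)
    keys, idx = table.occasion_index()
    cols = ["object", *design.facet_names]
    recon = keys.to_numpy()[idx]
    np.testing.assert_array_equal(recon, table.frame[cols].to_numpy())


def test_empty_table():
    t = ResponseTable.empty(("rater", "time"))
    assert len(t) == 0
    assert len(t.occasion_keys()) == 0
    keys, idx = t.occasion_index()
    assert len(idx) == 0


# ---------------------------------------------------------------------------
# validation


def test_validate_clean_and_empty():
    design = crossed_design()
    assert validate(full_table(design), design)
    report = validate(ResponseTable.empty(design.facet_names), design)
    assert report.passed and report.n_records == 0


def test_validate_flags_out_of_range():
    design = crossed_design()
    bad = ResponseTable.from_records(
        [
            (5, 0, 0, 0, 1),   # object out of range
            (0, 7, 0, 0, 1),   # rater out of range
            (0, 0, 0, 9, 1),   # item out of range
            (0, 0, 1, 0, 4),   # response above M_k
            (0, 0, 0, 1, -1),  # negative response
        ],
        design.facet_names,
    )
    report = validate(bad, design)
    assert not report
    text = "\n".join(report.errors)
    assert "object id out of range" in text
    assert "rater id out of range" in text
    assert "item id out of range" in text
    assert "response category out of range" in text


def test_validate_flags_duplicates():
    design = crossed_design()
    dup = ResponseTable.from_records(
        [(0, 0, 0, 0, 1), (0, 0, 0, 0, 2)], design.facet_names
    )
    report = validate(dup, design)
    assert not report
    assert any("duplicate cell" in e for e in report.errors)


def test_validate_flags_nested_level_under_two_objects():
    design = MeasurementDesign(
        2, (FacetSpec("student", 4, relation="nested"),), 1, 2
    )
    bad = ResponseTable.from_records(
        [(0, 0, 0, 1), (1, 0, 0, 1)], design.facet_names
    )
    report = validate(bad, design)
    assert not report
    assert any("appears under 2 objects" in e for e in report.errors)


def test_validate_facet_mismatch():
    design = crossed_design()
    other = ResponseTable.from_records([(0, 0, 0, 1)], ("judge",))
    report = validate(other, design)
    assert not report and "do not match design" in report.errors[0]


# ---------------------------------------------------------------------------
# counting


def test_count_occasions_crossed_product():
    design = crossed_design()
    assert count_occasions(design) == 3 * 2 * 2
    assert count_occasions(design, full_table(design)) == 12


def test_count_occasions_example1_scale():
    truth = example1()
    assert count_occasions(truth.design) == 34 * 4 * 6 == 816


def test_count_occasions_nested_needs_table():
    design = MeasurementDesign(
        2, (FacetSpec("student", 4, relation="nested"),), 1, 2
    )
    with pytest.raises(ValueError, match="need a ResponseTable"):
        count_occasions(design)
    table = ResponseTable.from_records(
        [(0, 0, 0, 1), (0, 1, 0, 0), (1, 2, 0, 1)], design.facet_names
    )
    assert count_occasions(design, table) == 3
    assert count_responses(table) == 3


def test_count_occasions_repeated_closed_form():
    design = MeasurementDesign(
        5, (FacetSpec("time", 3, relation="repeated"),), 2, 3
    )
    assert count_occasions(design) == 15


# ---------------------------------------------------------------------------
# CSV round trips


def test_read_csv_factorizes_string_labels(tmp_path):
    design = crossed_design()
    raw = pd.DataFrame(
        {
            "object": ["T-b", "T-b", "T-a"],
            "rater": ["r1", "r2", "r1"],
            "time": [1, 1, 2],
            "item": ["q1", "q2", "q1"],
            "response": [1, 2, 3],
        }
    )
    path = tmp_path / "resp.csv"
    raw.to_csv(path, index=False)
    table, mappings = ResponseTable.read_csv(path, design, recode_base1=True)
    assert table.objects.tolist() == [0, 0, 1]
    assert mappings["object"] == {"T-b": 0, "T-a": 1}
    assert table.responses.tolist() == [0, 1, 2]  # recoded to 0-based


def test_to_csv_round_trip(tmp_path):
    design = crossed_design()
    table = full_table(design)
    path = tmp_path / "out.csv"
    table.to_csv(path)
    back, _ = ResponseTable.read_csv(path, design)
    pd.testing.assert_frame_equal(back.frame, table.frame)
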