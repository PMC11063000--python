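"""GT decomposition layer: families, composition, manifest scores."""

import math

import numpy as np
import pandas as pd
import pytest

from gtirt import (
    FacetSpec,
    MeasurementDesign,
    ResponseTable,
    VarianceComponents,
    compose_crossed,
    compose_nested,
    compose_repeated,
    crossed_occasions,
    effect_families,
    manifest_logit_scores,
    total_variance,
)


def crossed_design(n_obj=2, r=2, t=3):
    return MeasurementDesign(
        n_obj, (FacetSpec("rater", r), FacetSpec("time", t)), 2, 3
    )


def test_crossed_occasions_lexicographic():
    occ = crossed_occasions(crossed_design())
    assert len(occ) == 2 * 2 * 3
    assert occ.columns.tolist() == ["object", "rater", "time"]
    # lexicographic: time varies fastest
    assert occ["time"].tolist()[:4] == [0, 1, 2, 0]
    assert occ["object"].tolist() == [0] * 6 + [1] * 6


def test_effect_families_crossed_two_facets():
    design = crossed_design()
    occ = crossed_occasions(design)
    fams = {f.name: f for f in effect_families(design, occ)}
    assert set(fams) == {
        "object",
        "rater",
        "time",
        "object:rater",
        "object:time",
        "rater:time",
    }
    assert fams["object"].n_levels == 2
    assert fams["object:rater"].n_levels == 4
    assert fams["rater:time"].n_levels == 6
    # interaction index = object * levels + facet level
    row = occ.iloc[7]  # object 1, rater 0, time 1
    assert fams["object:rater"].occ_index[7] == row["object"] * 2 + row["rater"]
    assert fams["rater:time"].occ_index[7] == row["rater"] * 3 + row["time"]


def test_effect_families_single_crossed_facet_has_no_interactions():
    design = MeasurementDesign(3, (FacetSpec("rater", 2),), 2, 3)
    fams = effect_families(design, crossed_occasions(design))
    assert [f.name for f in fams] == ["object", "rater"]


def test_effect_families_fixed_facet_flagged():
    design = MeasurementDesign(
        3, (FacetSpec("rater", 2, kind="fixed"), FacetSpec("time", 2)), 2, 3
    )
    fams = {f.name: f for f in effect_families(design, crossed_occasions(design))}
    assert not fams["rater"].random
    assert fams["time"].random


def test_effect_families_nested():
    design = MeasurementDesign(
        2,
        (FacetSpec("student", 4, relation="nested"), FacetSpec("time", 3)),
        2,
        3,
    )
    occ = pd.DataFrame(
        {
            "object": [0, 0, 1, 1],
            "student": [0, 1, 2, 3],
            "time": [0, 0, 0, 0],
        }
    )
    names = {f.name for f in effect_families(design, occ)}
    # student main is confounded with object:student; the object-by-crossed
    # interaction survives nesting
    assert names == {"object", "time", "student", "object:time"}


def test_effect_families_repeated_contributes_nothing():
    design = MeasurementDesign(
        3, (FacetSpec("time", 4, relation="repeated"),), 2, 3
    )
    fams = effect_families(design, crossed_occasions(design))
    assert [f.name for f in fams] == ["object"]


# ---------------------------------------------------------------------------
# composition


def test_compose_crossed_hand_check():
    design = crossed_design(n_obj=2, r=2, t=2)
    occ = crossed_occasions(design)
    effects = {
        "object": np.array([1.0, -1.0]),
        "rater": np.array([0.1, -0.1]),
        "time": np.array([0.2, -0.2]),
        "object:rater": np.array([0.01, 0.02, 0.03, 0.04]),
        "object:time": np.array([0.05, 0.06, 0.07, 0.08]),
        "rater:time": np.array([0.001, 0.002, 0.003, 0.004]),
    }
    resid = np.arange(8) * 0.0001
    scores = compose_crossed({**effects, "residual": resid}, design)
    # occasion 5: object 1, rater 0, time 1
    want = (
        -1.0 + 0.1 + (-0.2) + effects["object:rater"][2]
        + effects["object:time"][3] + effects["rater:time"][1] + resid[5]
    )
    assert abs(scores.theta[5] - want) < 1e-15
    assert len(scores) == 8


def test_compose_crossed_rejects_nested_design():
    design = MeasurementDesign(
        2, (FacetSpec("student", 4, relation="nested"),), 2, 3
    )
    with pytest.raises(ValueError, match="fully crossed"):
        compose_crossed({}, design)


def test_compose_shape_errors():
    design = crossed_design(n_obj=2, r=2, t=2)
    effects = {
        "object": np.zeros(3),  # wrong: 2 objects
        "rater": np.zeros(2),
        "time": np.zeros(2),
        "object:rater": np.zeros(4),
        "object:time": np.zeros(4),
        "rater:time": np.zeros(4),
        "residual": np.zeros(8),
    }
    with pytest.raises(ValueError, match="object"):
        compose_crossed(effects, design)
    effects["object"] = np.zeros(2)
    effects["residual"] = np.zeros(3)
    with pytest.raises(ValueError, match="residual"):
        compose_crossed(effects, design)


def test_compose_nested_roster_check():
    design = MeasurementDesign(
        2,
        (FacetSpec("student", 3, relation="nested"), FacetSpec("time", 1)),
        2,
        3,
    )
    effects = {
        "object": np.zeros(2),
        "time": np.zeros(1),
        "student": np.array([0.5, -0.5, 0.25]),
        "object:time": np.zeros(2),
    }
    occ = pd.DataFrame(
        {"object": [0, 0, 1], "student": [0, 1, 2], "time": [0, 0, 0]}
    )
    scores = compose_nested({**effects, "residual": np.zeros(3)}, design, occ)
    np.testing.assert_allclose(scores.theta, [0.5, -0.5, 0.25])
    bad = pd.DataFrame(
        {"object": [0, 1], "student": [0, 0], "time": [0, 0]}
    )
    with pytest.raises(ValueError, match="more than one object"):
        compose_nested(effects, design, bad)
    crossed_only = crossed_design()
    with pytest.raises(ValueError, match="no nested facet"):
        compose_nested(effects, crossed_only, occ)


def test_compose_repeated():
    design = MeasurementDesign(
        2, (FacetSpec("time", 2, relation="repeated"),), 2, 3
    )
    scores = compose_repeated(
        {"object": np.array([1.0, 2.0]), "residual": np.array([0.1, -0.1, 0.2, -0.2])},
        design,
    )
    np.testing.assert_allclose(scores.theta, [1.1, 0.9, 2.2, 1.8])
    with pytest.raises(ValueError, match="only repeated"):
        compose_repeated({}, crossed_design())


# ---------------------------------------------------------------------------
# variance bookkeeping


def test_total_variance_and_negatives():
    vc = VarianceComponents({"object": 1.0, "rater": 0.25, "residual": 0.5})
    assert vc.total() == 1.75
    with pytest.raises(ValueError, match="negative"):
        total_variance({"object": -0.1})


# ---------------------------------------------------------------------------
# manifest logit scores


def test_manifest_logit_scores_hand_case():
    design = MeasurementDesign(1, (FacetSpec("rater", 1),), 2, 3)
    # one occasion: S = 1 + 2 = 3, S_max = 4 -> logit(3.5 / 5)
    table = ResponseTable.from_records(
        [(0, 0, 0, 1), (0, 0, 1, 2)], design.facet_names
    )
    scores = manifest_logit_scores(table, design)
    want = math.log(0.7 / 0.3)
    assert abs(scores.theta[0] - want) < 1e-12


def test_manifest_logit_midpoint_is_zero_and_extremes_finite():
    design = MeasurementDesign(3, (FacetSpec("rater", 1),), 2, 3)
    table = ResponseTable.from_records(
        [
            (0, 0, 0, 1), (0, 0, 1, 1),   # midpoint: S=2, Smax=4 -> 0
            (1, 0, 0, 0), (1, 0, 1, 0),   # all-zero pattern
            (2, 0, 0, 2), (2, 0, 1, 2),   # all-maximum pattern
        ],
        design.facet_names,
    )
    scores = manifest_logit_scores(table, design)
    assert scores.theta[0] == 0.0
    assert np.isfinite(scores.theta).all()
    assert scores.theta[1] < 0 < scores.theta[2]


def test_manifest_logit_empty_table():
    design = MeasurementDesign(2, (FacetSpec("rater", 1),), 2, 3)
    scores = manifest_logit_scores(ResponseTable.empty(design.facet_names), design)
    assert len(scores) == 0
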