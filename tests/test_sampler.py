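"""Sampler contracts: settings, identification invariants, diagnostics, DIC."""

import numpy as np
import pandas as pd
import pytest

from gtirt import (
    DimensionSpec,
    FacetSpec,
    GpcmItemBank,
    IdentificationRule,
    ItemParameterMode,
    McmcSettings,
    MeasurementDesign,
    MultilevelSpec,
    PriorSpec,
    TruthSpec,
    VarianceComponents,
    diagnostics,
    dic,
    fit,
    fit_dimensions,
    generate,
    generate_dimensions,
    initialize,
)
from gtirt.sampler import PosteriorDraws
from gtirt.synthgen import StructuralTruth

from conftest import small_truth


FAST = McmcSettings(iterations=300, burn_in=100, seed=5)


# ---------------------------------------------------------------------------
# configuration objects


def test_settings_validation():
    with pytest.raises(ValueError, match="burn_in"):
        McmcSettings(iterations=100, burn_in=100)
    with pytest.raises(ValueError, match=">= 1"):
        McmcSettings(iterations=100, burn_in=10, thin=0)
    s = McmcSettings(iterations=1000, burn_in=200, thin=4)
    assert s.n_retained == 200


def test_priors_validation():
    with pytest.raises(ValueError, match="strictly positive"):
        PriorSpec(delta_var=0.0)
    with pytest.raises(ValueError, match="strictly positive"):
        PriorSpec(precision_rate=-1.0)


def test_item_mode_validation():
    with pytest.raises(ValueError, match="unknown"):
        ItemParameterMode("plugin")
    with pytest.raises(ValueError, match="complete item-parameter"):
        ItemParameterMode("fixed", alpha=np.ones(3), delta=None)


def test_identification_rule_validation():
    r = IdentificationRule("fix_object_variance", mu=3.0, sigma2=9.0)
    assert r.mu == 0.0 and r.sigma2 == 1.0  # forced to canonical moments
    with pytest.raises(ValueError, match="unknown"):
        IdentificationRule("standardize")
    with pytest.raises(ValueError, match=">= 0"):
        IdentificationRule("fix_plugin_moments", sigma2=-1.0)


def test_dimension_spec_validation():
    design = small_truth().design
    with pytest.raises(ValueError, match="response table"):
        DimensionSpec(design=design, table=None)
    with pytest.raises(ValueError, match="scores"):
        DimensionSpec(design=design, measurement="manifest")
    with pytest.raises(ValueError, match="gpcm.*manifest"):
        DimensionSpec(design=design, measurement="rasch")


# ---------------------------------------------------------------------------
# initialization


def test_initialize_defaults_and_log_odds(small_data):
    design = small_data.truth.design
    state = initialize(small_data.table, design)
    assert np.all(state["alpha"] == 1.0)
    assert state["delta"].shape == (4, 2)
    # pooled adjacent-category log odds, smoothed
    items = small_data.table.items
    resp = small_data.table.responses
    counts = np.bincount(resp[items == 0], minlength=3)
    want = np.log((counts[0] + 0.5) / (counts[1] + 0.5))
    assert abs(state["delta"][0, 0] - want) < 1e-12
    assert state["warnings"] == []


def test_initialize_empty_category_warning(caplog):
    design = MeasurementDesign(2, (FacetSpec("rater", 1),), 1, 3)
    from gtirt import ResponseTable

    table = ResponseTable.from_records(
        [(0, 0, 0, 0), (1, 0, 0, 0)], design.facet_names
    )  # category 1 and 2 never observed
    with caplog.at_level("WARNING"):
        state = initialize(table, design)
    assert state["warnings"]
    assert state["delta"][0, 1] == 2.0  # left at the prior mean (category index)
    assert "empty category" in caplog.text


# ---------------------------------------------------------------------------
# draw container and core invariants


def test_fit_shapes_and_names(small_fit):
    names = small_fit.names
    for expected in (
        "alpha", "delta", "e_object", "S", "deviance",
        "vc.object", "vc.rater", "vc.time", "vc.object:rater",
        "vc.object:time", "vc.rater:time", "vc.residual",
        "rho2_R", "rho2_A",
    ):
        assert expected in names
    assert small_fit["alpha"].shape == (400, 4)
    assert small_fit["delta"].shape == (400, 4, 2)
    assert small_fit["e_object"].shape == (400, 12)
    lo, hi = small_fit.interval("vc.rater")
    assert lo <= small_fit.median("vc.rater") <= hi
    summ = small_fit.summary(["vc.rater"])
    assert {"parameter", "median", "lower2.5", "upper97.5"} <= set(summ.columns)


def test_fix_object_variance_invariant(small_fit):
    """Every retained draw has object-effect sample mean 0, variance 1."""
    e = small_fit["e_object"]
    np.testing.assert_allclose(e.mean(axis=1), 0.0, atol=1e-10)
    np.testing.assert_allclose(e.var(axis=1), 1.0, atol=1e-10)
    assert np.all(small_fit["vc.object"] == 1.0)


def test_rho_draws_consistent_with_components(small_fit):
    vc = small_fit.vc_draws()
    from gtirt import reliability_rho

    want = reliability_rho(vc, 2, 3)
    np.testing.assert_allclose(small_fit["rho2_R"], want, atol=1e-10)


def test_seed_determinism(small_data):
    design = small_data.truth.design
    a = fit(small_data.table, design, settings=FAST)
    b = fit(small_data.table, design, settings=FAST)
    for name in a.names:
        np.testing.assert_array_equal(a[name], b[name])
    c = fit(small_data.table, design, settings=McmcSettings(
        iterations=300, burn_in=100, seed=6))
    assert not np.array_equal(a["deviance"], c["deviance"])


def test_fixed_mode_holds_items_constant(small_data):
    truth = small_data.truth
    mode = ItemParameterMode.fixed(truth.bank.alpha, truth.bank.delta)
    draws = fit(small_data.table, truth.design, mode=mode, settings=FAST)
    assert np.all(draws["alpha"] == truth.bank.alpha)
    assert np.all(draws["delta"] == truth.bank.delta)


def test_plugin_zero_variance_pins_objects(small_data):
    design = small_data.truth.design
    rule = IdentificationRule.fix_plugin_moments(mu=0.25, sigma2=0.0)
    draws = fit(small_data.table, design, identification=rule, settings=FAST)
    assert np.all(draws["e_object"] == 0.25)


def test_store_occasions(small_data):
    design = small_data.truth.design
    draws = fit(small_data.table, design, settings=FAST, store_occasions=True)
    assert draws["theta_occ"].shape == (FAST.n_retained, 72)


def test_structural_fit_names(small_data):
    spec = MultilevelSpec(level1=("x",))
    truth = small_truth()
    truth.structural = StructuralTruth(
        spec=spec, beta=[0.5], gamma=[0.1, 0.4],
        sigma2_level1=0.5, sigma2_level2=0.1, units_per_object=6,
    )
    data = generate(truth)
    draws = fit(
        data.table, truth.design, settings=FAST,
        structural=spec, structural_data=data.structural_data,
    )
    assert draws["beta"].shape == (FAST.n_retained, 1)
    assert draws["gamma"].shape == (FAST.n_retained, 2)
    assert np.all(draws["sig2_level1"] > 0)
    assert np.all((0 < draws["icc"]) & (draws["icc"] < 1))


def test_fit_dimensions_argument_errors(small_data):
    design = small_data.truth.design
    dim = DimensionSpec(design=design, table=small_data.table)
    with pytest.raises(ValueError, match="latent"):
        fit_dimensions([dim], latent="entangled", settings=FAST)
    with pytest.raises(ValueError, match="together"):
        fit_dimensions([dim], settings=FAST, structural=MultilevelSpec())


def test_shared_latent_equalizes_object_effects():
    t1 = small_truth(seed=21)
    t2 = small_truth(seed=22)
    datasets = generate_dimensions(
        [t1, t2], np.zeros(2), np.eye(2), np.random.default_rng(2)
    )
    dims = [
        DimensionSpec(design=d.truth.design, table=d.table, bank=i)
        for i, d in enumerate(datasets)
    ]
    draws = fit_dimensions(dims, latent="shared", settings=FAST)
    np.testing.assert_array_equal(draws["d0.e_object"], draws["d1.e_object"])


# ---------------------------------------------------------------------------
# diagnostics


def fake_draws(cols: dict, chains: int, n_per: int) -> PosteriorDraws:
    meta = {
        "n_dimensions": 1,
        "chains": chains,
        "n_per_chain": n_per,
        "deviance_at_mean": 0.0,
    }
    return PosteriorDraws({k: np.asarray(v) for k, v in cols.items()}, meta, {})


def test_diagnostics_identical_chains_rhat_one(rng):
    noise = rng.standard_normal(300)
    d = fake_draws({"x": np.concatenate([noise, noise])}, chains=2, n_per=300)
    out = diagnostics(d)
    assert list(out.columns) == ["parameter", "rhat", "ess"]
    assert abs(float(out["rhat"][0]) - 1.0) < 0.01


def test_diagnostics_white_noise_ess_near_draw_count(rng):
    n = 1000
    d = fake_draws({"x": rng.standard_normal(n)}, chains=2, n_per=n // 2)
    out = diagnostics(d)
    assert abs(float(out["ess"][0]) - n) / n < 0.2


def test_diagnostics_shifted_chain_flagged(rng):
    a = rng.standard_normal(200)
    d = fake_draws({"x": np.concatenate([a, a + 5.0])}, chains=2, n_per=200)
    out = diagnostics(d)
    assert float(out["rhat"][0]) > 1.1


def test_diagnostics_too_few_draws():
    d = fake_draws({"x": np.zeros(4)}, chains=1, n_per=4)
    with pytest.raises(ValueError, match="too few"):
        diagnostics(d)


def test_diagnostics_on_real_fit(small_fit):
    out = diagnostics(small_fit, ["vc.rater", "vc.time"])
    assert len(out) == 2
    assert (out["rhat"] > 0.9).all()
    assert (out["ess"] > 10).all()


# ---------------------------------------------------------------------------
# DIC


def test_dic_point_mass_has_zero_pd():
    d = fake_draws({"deviance": np.full(50, 123.5)}, chains=1, n_per=50)
    d.meta["deviance_at_mean"] = 123.5
    dic_val, pd_eff, dbar = dic(d)
    assert pd_eff == 0.0
    assert dic_val == dbar == 123.5


def test_dic_nonfinite_deviance_names_draw():
    dev = np.zeros(20)
    dev[7] = np.inf
    d = fake_draws({"deviance": dev}, chains=1, n_per=20)
    with pytest.raises(ValueError, match="draw 7"):
        dic(d)


def test_dic_effective_parameters_linear_normal():
    """Conjugate normal model with effectively free object effects:
    pD approximates the free parameter count (N effects + 1 variance)."""
    rng = np.random.default_rng(17)
    N, T = 40, 15
    design = MeasurementDesign(
        N, (FacetSpec("time", T, relation="repeated"),), 1, 2
    )
    occ = pd.DataFrame(
        {"object": np.repeat(np.arange(N), T), "time": np.tile(np.arange(T), N)}
    )
    scores = rng.standard_normal(N)[occ["object"]] + rng.standard_normal(N * T)
    draws = fit(
        None,
        design,
        measurement="manifest",
        scores=scores,
        occasions=occ,
        identification=IdentificationRule.none(object_variance=100.0),
        settings=McmcSettings(iterations=3000, burn_in=500, seed=9),
    )
    _, pd_eff, _ = dic(draws)
    p = N + 1
    assert abs(pd_eff - p) / p < 0.15


def _sharp_truth(seed):
    """Well-determined occasion scores: 8 discriminating items, tiny residual,
    so the conditional deviance can see latent-structure misfit."""
    design = MeasurementDesign(
        16, (FacetSpec("rater", 2), FacetSpec("time", 2)), 8, 3
    )
    rng = np.random.default_rng(seed)
    bank = GpcmItemBank(
        [
            (float(a), (float(d) - 0.4, float(d) + 0.4))
            for a, d in zip(rng.uniform(1.2, 2.2, 8), rng.normal(0, 0.7, 8))
        ]
    )
    vc = VarianceComponents(
        {
            "object": 1.0,
            "rater": 0.05,
            "time": 0.05,
            "object:rater": 0.05,
            "object:time": 0.05,
            "rater:time": 0.05,
            "residual": 0.1,
        }
    )
    return TruthSpec(design, bank, vc, seed=seed)


def test_dic_prefers_generating_dimensionality():
    """Data with two independent dimensions: the correlated model beats the
    one-dimensional (shared) model by DIC in most replicates."""
    wins = 0
    reps = (1, 2, 4, 5)
    for rep in reps:
        t1 = _sharp_truth(300 + rep)
        t2 = _sharp_truth(400 + rep)
        datasets = generate_dimensions(
            [t1, t2], np.zeros(2), np.eye(2), np.random.default_rng(2000 + rep)
        )
        dims = [
            DimensionSpec(design=d.truth.design, table=d.table, bank=i)
            for i, d in enumerate(datasets)
        ]
        settings = McmcSettings(iterations=2500, burn_in=500, seed=rep)
        d_corr = dic(fit_dimensions(dims, latent="correlated", settings=settings))[0]
        d_shared = dic(fit_dimensions(dims, latent="shared", settings=settings))[0]
        wins += int(d_corr < d_shared)
    assert wins >= len(reps) - 1
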