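"""Shared fixtures: one small but real MCMC fit reused across test modules."""

import numpy as np
import pytest

from gtirt import (
    FacetSpec,
    GpcmItemBank,
    McmcSettings,
    MeasurementDesign,
    TruthSpec,
    VarianceComponents,
    fit,
    generate,
)


def small_truth(seed: int = 7) -> TruthSpec:
    """12 objects x 2 raters x 3 time-points, 4 three-category items."""
    design = MeasurementDesign(
        n_objects=12,
        facets=(FacetSpec("rater", 2), FacetSpec("time", 3)),
        n_items=4,
        categories=3,
    )
    bank = GpcmItemBank(
        [
            (1.4, (-1.0, 0.2)),
            (0.9, (-0.4, 0.6)),
            (1.1, (-0.8, -0.1)),
            (0.7, (0.0, 0.9)),
        ]
    )
    vc = VarianceComponents(
        {
            "object": 1.0,
            "rater": 0.2,
            "time": 0.2,
            "object:rater": 0.2,
            "object:time": 0.2,
            "rater:time": 0.2,
            "residual": 0.4,
        }
    )
    return TruthSpec(design, bank, vc, seed=seed)


@pytest.fixture(scope="session")
def small_data():
    return generate(small_truth())


@pytest.fixture(scope="session")
def small_fit(small_data):
    """A short but genuine GT-IRT fit on the small crossed design."""
    draws = fit(
        small_data.table,
        small_data.truth.design,
        settings=McmcSettings(iterations=600, burn_in=200, seed=3),
    )
    assert draws.n_draws == 400
    return draws


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
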