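"""Synthetic-data generation with the exact structure the models assume.

A :class:`TruthSpec` bundles a measurement design, true item parameters and
true variance components (plus, optionally, a structural regression truth).
:func:`generate` draws every random effect i.i.d. normal with its stated
variance, composes the latent occasion scores per the design's GT equation,
and samples polytomous responses from the GPCM — so fitted posteriors can be
checked against recorded truth.  Presets encode three reference designs at
the scale of published observation studies (classroom observation ratings),
so recovery experiments never need external data:

* ``example1``: 34 objects x 4 raters x 6 time-points, 10 four-category
  items (816 occasions, 8,160 responses);
* ``example2``: 51 teachers x 3 raters x 3 lessons with nine teachers
  missing one lesson (432 occasion patterns), plus a two-level structural
  model on 953 students;
* ``example3``: three latent dimensions with correlated teacher effects —
  external raters (crossed), students (nested, 20-30 per teacher), and
  teacher self-ratings (repeated) — with group-specific 15-item banks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .designs import FacetSpec, MeasurementDesign, ResponseTable
from .gpcm import GpcmItemBank
from .gt_model import (
    OBJECT,
    RESIDUAL,
    VarianceComponents,
    compose,
    crossed_occasions,
    effect_families,
)
from .gcoefficients import reliability_rho
from .structural import MultilevelData, MultilevelSpec

__all__ = [
    "StructuralTruth",
    "TruthSpec",
    "SyntheticData",
    "generate",
    "generate_dimensions",
    "augment",
    "solve_error_variance",
    "reliability_power_study",
    "nested_occasions",
    "example1",
    "example2",
    "example3",
    "Example3Truth",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# truth specifications


@dataclass
class StructuralTruth:
    """True two-level regression attached to the object effects.

    ``beta`` stacks the level-1 coefficients and then the cross-level
    interaction coefficients; ``gamma`` is (grand mean, latent slope, W
    coefficients).  ``units_per_object`` is an integer, a (low, high)
    range sampled uniformly, or an explicit per-object sequence.
    ``covariates`` optionally maps a covariate name to a ``draw(rng, n)``
    callable; unnamed covariates are standard normal.
    """

    spec: MultilevelSpec
    beta: np.ndarray
    gamma: np.ndarray
    sigma2_level1: float
    sigma2_level2: float
    units_per_object: int | tuple[int, int] | Sequence[int] = 10
    covariates: dict[str, Callable] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, float)
        self.gamma = np.asarray(self.gamma, float)
        if len(self.beta) != self.spec.n_level1:
            raise ValueError("beta must match level-1 covariates + interactions")
        if len(self.gamma) != self.spec.n_level2:
            raise ValueError("gamma must be (grand mean, latent slope, W...)")
        if self.sigma2_level1 < 0 or self.sigma2_level2 < 0:
            raise ValueError("structural variances must be >= 0")


@dataclass
class TruthSpec:
    """Complete generating truth for one latent dimension."""

    design: MeasurementDesign
    bank: GpcmItemBank
    vc: VarianceComponents
    structural: StructuralTruth | None = None
    latent_mean: float = 0.0
    occasions: pd.DataFrame | None = None
    missingness: Callable | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.vc = VarianceComponents(self.vc)
        for k, v in self.vc.items():
            if v < 0:
                raise ValueError(f"negative truth variance {k!r}")
        if np.any(self.bank.alpha <= 0):
            raise ValueError("true discriminations must be positive")
        if self.bank.delta.shape[0] != self.design.n_items:
            raise ValueError("bank size must match the design's item count")


@dataclass
class SyntheticData:
    """A generated data set together with its recorded latent truth."""

    table: ResponseTable
    occasions: pd.DataFrame
    theta: np.ndarray
    effects: dict[str, np.ndarray]
    truth: TruthSpec
    units: pd.DataFrame | None = None
    objects: pd.DataFrame | None = None
    structural_data: MultilevelData | None = None


# ---------------------------------------------------------------------------
# generation


def _sample_responses(
    bank: GpcmItemBank,
    design: MeasurementDesign,
    occasions: pd.DataFrame,
    theta: np.ndarray,
    rng: np.random.Generator,
) -> ResponseTable:
    n = len(theta)
    K = design.n_items
    probs = np.exp(bank.log_prob_table(theta))  # (n, K, M+1)
    cum = probs.cumsum(axis=2)
    u = rng.random((n, K, 1))
    resp = (u > cum[:, :, :-1]).sum(axis=2)
    frame = occasions.loc[occasions.index.repeat(K)].reset_index(drop=True)
    frame["item"] = np.tile(np.arange(K), n)
    frame["response"] = resp.ravel()
    return ResponseTable(frame, design.facet_names)


def _draw_effects(
    truth: TruthSpec, occasions: pd.DataFrame, rng: np.random.Generator
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    fams = effect_families(truth.design, occasions)
    effects: dict[str, np.ndarray] = {}
    for fam in fams:
        if fam.name not in truth.vc:
            raise KeyError(f"truth has no variance for effect family {fam.name!r}")
        sd = float(np.sqrt(truth.vc[fam.name]))
        e = sd * rng.standard_normal(fam.n_levels)
        if fam.name == OBJECT:
            e = e + truth.latent_mean
        effects[fam.name] = e
    resid = float(np.sqrt(truth.vc[RESIDUAL])) * rng.standard_normal(len(occasions))
    effects[RESIDUAL] = resid
    theta = compose(effects, fams, resid)
    return effects, theta


def _resolve_occasions(truth: TruthSpec, rng: np.random.Generator) -> pd.DataFrame:
    if truth.occasions is not None:
        occ = truth.occasions.reset_index(drop=True)
    else:
        if any(f.relation == "nested" for f in truth.design.facets):
            raise ValueError("nested designs need an explicit occasion roster")
        occ = crossed_occasions(truth.design)
    if truth.missingness is not None:
        keep = np.asarray(truth.missingness(occ, rng), bool)
        occ = occ.loc[keep].reset_index(drop=True)
    return occ


def _generate_structural(
    st: StructuralTruth, theta_obj: np.ndarray, rng: np.random.Generator
):
    N = len(theta_obj)
    upo = st.units_per_object
    if isinstance(upo, int):
        counts = np.full(N, upo)
    elif isinstance(upo, tuple) and len(upo) == 2:
        counts = rng.integers(upo[0], upo[1] + 1, size=N)
    else:
        counts = np.asarray(upo, int)
        if len(counts) != N:
            raise ValueError("units_per_object must give one count per object")
    obj = np.repeat(np.arange(N), counts)
    n = len(obj)

    def draw(name, size):
        fn = st.covariates.get(name)
        return fn(rng, size) if fn else rng.standard_normal(size)

    units = pd.DataFrame({"object": obj})
    for c in st.spec.level1:
        units[c] = draw(c, n)
    objects = pd.DataFrame({"object": np.arange(N)})
    for c in st.spec.level2:
        objects[c] = draw(c, N)
    data = MultilevelData.from_frames(st.spec, units.assign(y=0.0), objects)
    p1 = data.X.shape[1]
    b0 = (
        st.gamma[0]
        + st.gamma[1] * theta_obj
        + data.W @ st.gamma[2:]
        + np.sqrt(st.sigma2_level2) * rng.standard_normal(N)
    )
    y = (
        b0[obj]
        + data.X @ st.beta[:p1]
        + (data.Dint * theta_obj[obj][:, None]) @ st.beta[p1:]
        + np.sqrt(st.sigma2_level1) * rng.standard_normal(n)
    )
    units["y"] = y
    data.y = y
    return units, objects, data


def generate(truth: TruthSpec, rng: np.random.Generator | int | None = None) -> SyntheticData:
    """Draw one full data set from a truth specification.

    Effects are i.i.d. normal with the stated component variances, occasion
    scores are composed per the design's GT equation, and responses are
    drawn from the GPCM at those scores.  Everything is reproducible from
    ``truth.seed`` (or an explicitly passed generator/seed).
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    occ = _resolve_occasions(truth, rng)
    effects, theta = _draw_effects(truth, occ, rng)
    table = _sample_responses(truth.bank, truth.design, occ, theta, rng)
    units = objects = sdata = None
    if truth.structural is not None:
        units, objects, sdata = _generate_structural(
            truth.structural, effects[OBJECT], rng
        )
    return SyntheticData(table, occ, theta, effects, truth, units, objects, sdata)


def generate_dimensions(
    truths: list[TruthSpec],
    mu: np.ndarray,
    Sigma: np.ndarray,
    rng: np.random.Generator | int | None = None,
) -> list[SyntheticData]:
    """Generate several dimensions with jointly multivariate-normal object
    effects (overriding each truth's marginal object distribution)."""
    D = len(truths)
    mu = np.asarray(mu, float)
    Sigma = np.asarray(Sigma, float)
    if mu.shape != (D,) or Sigma.shape != (D, D):
        raise ValueError("mu/Sigma must match the number of dimensions")
    if rng is None or not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(truths[0].seed if rng is None else rng)
    N = truths[0].design.n_objects
    if any(t.design.n_objects != N for t in truths):
        raise ValueError("all dimensions must share the object population")
    E = rng.multivariate_normal(mu, Sigma, size=N)  # (N, D)
    out = []
    for d, truth in enumerate(truths):
        occ = _resolve_occasions(truth, rng)
        fams = effect_families(truth.design, occ)
        effects: dict[str, np.ndarray] = {}
        for fam in fams:
            if fam.name == OBJECT:
                effects[OBJECT] = E[:, d].copy()
                continue
            sd = float(np.sqrt(truth.vc[fam.name]))
            effects[fam.name] = sd * rng.standard_normal(fam.n_levels)
        resid = float(np.sqrt(truth.vc[RESIDUAL])) * rng.standard_normal(len(occ))
        effects[RESIDUAL] = resid
        theta = compose(effects, fams, resid)
        table = _sample_responses(truth.bank, truth.design, occ, theta, rng)
        out.append(SyntheticData(table, occ, theta, effects, truth))
    return out


def augment(
    data: SyntheticData, factor: int, rng: np.random.Generator | int | None = None
) -> SyntheticData:
    """Multiply the object sample by ``factor``, keeping the facets as-is.

    New objects get freshly drawn object effects, object-by-facet
    interactions and residuals from the same truth; the facet main effects,
    facet-pair interactions and item parameters are reused unchanged, so the
    measurement conditions stay identical while the sample grows.
    """
    if factor not in (2, 4, 8):
        raise ValueError("augmentation factor must be 2, 4 or 8")
    truth = data.truth
    if any(f.relation != "crossed" for f in truth.design.facets):
        raise ValueError("augment supports fully crossed designs")
    if rng is None or not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(
            truth.seed + 1000 * factor if rng is None else rng
        )
    N0 = truth.design.n_objects
    N_new = (factor - 1) * N0
    design_new = replace(truth.design, n_objects=factor * N0)
    extra_design = replace(truth.design, n_objects=N_new)
    occ_extra = crossed_occasions(extra_design)
    fams = effect_families(extra_design, occ_extra)
    effects_new: dict[str, np.ndarray] = {}
    for fam in fams:
        involves_obj = fam.name == OBJECT or fam.name.startswith(f"{OBJECT}:")
        if involves_obj:
            sd = float(np.sqrt(truth.vc[fam.name]))
            e = sd * rng.standard_normal(fam.n_levels)
            if fam.name == OBJECT:
                e = e + truth.latent_mean
            effects_new[fam.name] = e
        else:
            effects_new[fam.name] = data.effects[fam.name]
    resid = float(np.sqrt(truth.vc[RESIDUAL])) * rng.standard_normal(len(occ_extra))
    effects_new[RESIDUAL] = resid
    theta_extra = compose(effects_new, fams, resid)
    table_extra = _sample_responses(
        truth.bank, extra_design, occ_extra, theta_extra, rng
    )
    # shift the new objects' ids past the originals
    occ_shift = occ_extra.copy()
    occ_shift["object"] += N0
    tf = table_extra.frame.copy()
    tf["object"] += N0
    occ_all = pd.concat([data.occasions, occ_shift], ignore_index=True)
    frame_all = pd.concat([data.table.frame, tf], ignore_index=True)
    effects_all = dict(data.effects)
    effects_all[OBJECT] = np.concatenate(
        [data.effects[OBJECT], effects_new[OBJECT]]
    )
    for fam in fams:
        if fam.name.startswith(f"{OBJECT}:"):
            effects_all[fam.name] = np.concatenate(
                [data.effects[fam.name], effects_new[fam.name]]
            )
    effects_all[RESIDUAL] = np.concatenate([data.effects[RESIDUAL], resid])
    truth_new = replace(truth, design=design_new)
    return SyntheticData(
        ResponseTable(frame_all, design_new.facet_names),
        occ_all,
        np.concatenate([data.theta, theta_extra]),
        effects_all,
        truth_new,
    )


# ---------------------------------------------------------------------------
# reliability engineering


def solve_error_variance(vc: dict, R: int, T: int, target: float) -> float:
    """Residual variance that yields a requested reliability, exactly.

    Inverts the reliability formula for the residual component given the
    object and object-by-facet components (``vc`` must not already contain a
    residual).  An unreachable target raises an error naming the achievable
    supremum (the reliability at zero residual variance).
    """
    if RESIDUAL in vc:
        raise ValueError("pass the components without the residual")
    if not 0 < target <= 1:
        raise ValueError("target reliability must be in (0, 1]")
    probe = dict(vc)
    probe[RESIDUAL] = 0.0
    sup = reliability_rho(probe, R, T)
    if target > sup + 1e-12:
        raise ValueError(
            f"target {target} unreachable; supremum at zero residual "
            f"variance is {sup}"
        )
    s1 = float(probe[OBJECT])
    den0 = s1 / sup  # object + interaction terms
    x = R * T * (s1 / target - den0)
    return max(0.0, float(x))


def reliability_power_study(
    truth: TruthSpec,
    targets: Sequence[float],
    replicates: int,
    settings,
    base_seed: int = 0,
    gamma_index: int = 1,
) -> pd.DataFrame:
    """Replicated fits across engineered reliability conditions.

    For each target reliability the residual component is re-solved, data
    are regenerated and the full model refitted; the table reports, per
    condition, the fraction of replicates whose central 95% bounds for the
    latent-predictor coefficient exclude zero, with the average posterior
    median.  ``truth`` must carry a structural part.
    """
    from .sampler import fit  # deferred: avoid import cycle
    from .structural import significant

    if truth.structural is None:
        raise ValueError("power study needs a structural truth")
    design = truth.design
    crossed = [f for f in design.facets if f.relation == "crossed"]
    R, T = crossed[0].levels, crossed[1].levels
    base = {k: v for k, v in truth.vc.items() if k != RESIDUAL}
    rows = []
    for target in targets:
        s7 = solve_error_variance(base, R, T, float(target))
        vc_t = VarianceComponents({**base, RESIDUAL: s7})
        flags, medians = [], []
        for rep in range(replicates):
            t = replace(truth, vc=vc_t, seed=truth.seed)
            data = generate(t, np.random.default_rng([base_seed, int(target * 1e6), rep]))
            draws = fit(
                data.table,
                design,
                settings=replace(settings, seed=base_seed + rep),
                structural=truth.structural.spec,
                structural_data=data.structural_data,
            )
            g = draws["gamma"][:, gamma_index]
            lo, hi = np.quantile(g, [0.025, 0.975])
            flags.append(significant(lo, hi))
            medians.append(float(np.median(g)))
        rows.append(
            {
                "target_reliability": float(target),
                "residual_variance": s7,
                "replicates": replicates,
                "fraction_significant": float(np.mean(flags)),
                "mean_gamma_median": float(np.mean(medians)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rosters and presets


def nested_occasions(
    n_objects: int,
    per_object: tuple[int, int],
    crossed_levels: dict[str, int],
    nested_name: str,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, int]:
    """Roster for a nested facet: objects carry ``per_object`` uniformly
    drawn nested levels (globally numbered), crossed with the given facets.
    Returns the occasion table and the total nested level count."""
    counts = rng.integers(per_object[0], per_object[1] + 1, size=n_objects)
    rows = []
    nid = 0
    for j in range(n_objects):
        for _ in range(counts[j]):
            rows.append((j, nid))
            nid += 1
    base = pd.DataFrame(rows, columns=["object", nested_name])
    for name, L in crossed_levels.items():
        base = base.merge(pd.DataFrame({name: np.arange(L)}), how="cross")
    return base.reset_index(drop=True), nid


def _spread_bank(avg_delta: np.ndarray, alpha: np.ndarray, spacing: float = 1.0) -> GpcmItemBank:
    """Bank whose per-item thresholds are symmetric around given averages."""
    K = len(alpha)
    M = 3
    offs = spacing * (np.arange(1, M + 1) - (M + 1) / 2.0)  # (-1, 0, 1)
    items = [
        (float(alpha[k]), tuple(avg_delta[k] + offs)) for k in range(K)
    ]
    return GpcmItemBank(items)


def example1() -> TruthSpec:
    """34 objects x 4 raters x 6 time-points, 10 four-category items.

    816 occasions, 8,160 responses.  Item truths follow published medians
    for a 10-item classroom-observation subset; component truths follow the
    concurrent-calibration variance-component medians with the object
    variance fixed at 1.
    """
    alpha = np.array(
        [2.628, 2.316, 2.695, 2.464, 1.168, 0.793, 1.810, 1.066, 0.896, 0.612]
    )
    avg_delta = np.array(
        [-1.817, -0.956, -1.686, -1.338, -0.736, -0.432, -0.220, -0.173, 0.095, 0.382]
    )
    design = MeasurementDesign(
        n_objects=34,
        facets=(FacetSpec("rater", 4), FacetSpec("time", 6)),
        n_items=10,
        categories=4,
    )
    vc = VarianceComponents(
        {
            OBJECT: 1.0,
            "rater": 0.204,
            "time": 0.193,
            "object:rater": 0.192,
            "object:time": 0.229,
            "rater:time": 0.166,
            RESIDUAL: 0.387,
        }
    )
    return TruthSpec(design, _spread_bank(avg_delta, alpha), vc, seed=11)


def _binary(p: float) -> Callable:
    return lambda rng, n: (rng.random(n) < p).astype(float)


def example2(n_items: int = 10) -> TruthSpec:
    """51 teachers x 3 raters x 3 lessons; 9 teachers missing one lesson.

    432 occasion patterns; a two-level structural model on 953 students with
    grade/gender/weight/pretest/ability covariates, ability-by-theta
    cross-level interactions and a planning covariate at teacher level.
    ``n_items`` defaults to a light 10-item bank (the full instrument has
    35 items; tests scale this down).
    """
    design = MeasurementDesign(
        n_objects=51,
        facets=(FacetSpec("rater", 3), FacetSpec("time", 3)),
        n_items=n_items,
        categories=4,
    )
    rng = np.random.default_rng(202)
    alpha = np.exp(rng.normal(0.2, 0.35, n_items)).round(3)
    avg_delta = rng.normal(-0.6, 0.8, n_items).round(3)
    vc = VarianceComponents(
        {
            OBJECT: 0.447,
            "rater": 0.222,
            "time": 0.217,
            "object:rater": 0.224,
            "object:time": 0.157,
            "rater:time": 0.191,
            RESIDUAL: 0.185,
        }
    )
    spec = MultilevelSpec(
        level1=("grade", "gender", "weight", "pretest", "high", "low"),
        interactions=("high", "low"),
        level2=("planning",),
    )
    counts = np.full(51, 18)
    counts[:35] = 19  # totals 953 students
    structural = StructuralTruth(
        spec=spec,
        beta=np.array([0.888, -0.075, 0.005, 0.477, 0.401, -0.211, 0.081, -0.145]),
        gamma=np.array([-0.583, 0.147, -0.054]),
        sigma2_level1=0.163,
        sigma2_level2=0.030,
        units_per_object=counts,
        covariates={
            "grade": _binary(0.5),
            "gender": _binary(0.5),
            "weight": _binary(0.12),
            "high": _binary(0.25),
            "low": _binary(0.25),
        },
    )

    def drop_one_lesson(occ: pd.DataFrame, rng: np.random.Generator) -> np.ndarray:
        # the first nine teachers are observed at lessons 0-1 only
        return ~((occ["object"] < 9) & (occ["time"] == 2)).to_numpy()

    return TruthSpec(
        design,
        _spread_bank(avg_delta, alpha),
        vc,
        structural=structural,
        missingness=drop_one_lesson,
        seed=22,
    )


@dataclass
class Example3Truth:
    """Three correlated dimensions: external raters, students, self-ratings."""

    dims: list[TruthSpec]
    mu: np.ndarray
    Sigma: np.ndarray

    def generate(self, rng=None) -> list[SyntheticData]:
        return generate_dimensions(self.dims, self.mu, self.Sigma, rng)


def example3(seed: int = 33) -> Example3Truth:
    """25 teachers, 3 lessons; external raters crossed (3), students nested
    (20-30 per teacher), self-ratings repeated; 15 four-category items per
    observer group, group-specific banks; correlated object effects."""
    rng = np.random.default_rng(seed)
    K = 15

    def bank(r):
        alpha = np.exp(r.normal(0.1, 0.3, K))
        avg = r.normal(-0.3, 0.9, K)
        return _spread_bank(avg, alpha)

    d_ext = MeasurementDesign(
        25, (FacetSpec("rater", 3), FacetSpec("time", 3)), K, 4
    )
    vc_ext = VarianceComponents(
        {
            OBJECT: 1.0,
            "rater": 0.15,
            "time": 0.12,
            "object:rater": 0.18,
            "object:time": 0.16,
            "rater:time": 0.10,
            RESIDUAL: 0.69,
        }
    )
    roster, n_students = nested_occasions(
        25, (20, 30), {"time": 3}, "student", rng
    )
    d_stu = MeasurementDesign(
        25,
        (FacetSpec("student", n_students, relation="nested"), FacetSpec("time", 3)),
        K,
        4,
    )
    vc_stu = VarianceComponents(
        {
            OBJECT: 1.0,
            "time": 0.10,
            "student": 0.35,
            "object:time": 0.15,
            RESIDUAL: 0.55,
        }
    )
    d_self = MeasurementDesign(
        25, (FacetSpec("time", 3, relation="repeated"),), K, 4
    )
    vc_self = VarianceComponents({OBJECT: 1.0, RESIDUAL: 0.84})
    mu = np.array([-0.49, 0.0, 0.11])
    corr = np.array(
        [[1.0, 0.806, 0.795], [0.806, 1.0, 0.761], [0.795, 0.761, 1.0]]
    )
    dims = [
        TruthSpec(d_ext, bank(rng), vc_ext, seed=seed),
        TruthSpec(d_stu, bank(rng), vc_stu, occasions=roster, seed=seed),
        TruthSpec(d_self, bank(rng), vc_self, seed=seed),
    ]
    return Example3Truth(dims, mu, corr)
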