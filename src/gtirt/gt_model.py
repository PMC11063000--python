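"""Generalizability-theory decomposition of latent occasion scores.

The latent score of a measurement occasion is the sum of a main effect of the
object of measurement, main effects of random facets, their interactions, and
a residual that absorbs the highest-order interaction confounded with random
error.  For a two-facet fully crossed design (objects j, raters r,
time-points t):

    theta_jrt = theta_j + tau_r + tau_t + tau_jr + tau_jt + tau_rt + eps_jrt

with every effect family carrying its own variance component; the total
variance is the sum of the components (orthogonal effects).  Nested designs
(students i nested in teachers j, crossed with lessons t) drop the terms that
are confounded by the nesting:

    theta_(i:j)t = theta_j + omega_t + omega_(i:j) + omega_jt + eps_(i:j)t

where the rater (student) main effect is indistinguishable from the
object-by-rater interaction and is represented by the single family
``omega_(i:j)``.  A repeated facet contributes residual scatter only:
theta_jt = theta_j + eps_jt.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logit

from .designs import MeasurementDesign, ResponseTable

__all__ = [
    "EffectFamily",
    "VarianceComponents",
    "LatentOccasionScores",
    "crossed_occasions",
    "effect_families",
    "compose",
    "compose_crossed",
    "compose_nested",
    "compose_repeated",
    "total_variance",
    "manifest_logit_scores",
]

logger = logging.getLogger(__name__)

OBJECT = "object"
RESIDUAL = "residual"


@dataclass
class EffectFamily:
    """One family of exchangeable effects (e.g. rater main effects).

    ``occ_index`` maps each realized occasion to the family level whose
    effect enters that occasion's score.
    """

    name: str
    n_levels: int
    occ_index: np.ndarray
    random: bool = True


class VarianceComponents(dict):
    """Map from effect-family name (plus ``"residual"``) to sigma^2 >= 0."""

    def __init__(self, *args, **kwargs):
        super().__init__(*args, **kwargs)
        for k, v in self.items():
            self[k] = float(v)

    def total(self) -> float:
        return total_variance(self)


@dataclass
class LatentOccasionScores:
    """Theta value per realized occasion."""

    occasions: pd.DataFrame
    theta: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if len(self.theta) != len(self.occasions):
            raise ValueError("one theta per occasion required")

    def __len__(self) -> int:
        return len(self.theta)


def crossed_occasions(design: MeasurementDesign) -> pd.DataFrame:
    """Occasion grid for a fully crossed design, lexicographic in
    (object, facet_1, facet_2, ...)."""
    axes = [np.arange(design.n_objects)] + [
        np.arange(f.levels) for f in design.facets
    ]
    grids = np.meshgrid(*axes, indexing="ij")
    cols = ["object", *design.facet_names]
    return pd.DataFrame({c: g.ravel() for c, g in zip(cols, grids)})


def effect_families(
    design: MeasurementDesign, occasions: pd.DataFrame
) -> list[EffectFamily]:
    """Derive the effect families implied by a design over realized occasions.

    Rules: the object main effect is always present; every crossed facet
    contributes a main effect and (if there is more than one crossed facet)
    an object-by-facet interaction; pairs of crossed facets contribute a
    facet-by-facet interaction; a nested facet contributes a single family
    for its levels (its main effect confounded with the object interaction);
    a repeated facet contributes nothing (pure residual scatter).  The
    residual is not a family: it is the per-occasion remainder.
    """
    obj = occasions["object"].to_numpy(dtype=int)
    fams = [EffectFamily(OBJECT, design.n_objects, obj)]
    crossed = [f for f in design.facets if f.relation == "crossed"]
    for spec in crossed:
        idx = occasions[spec.name].to_numpy(dtype=int)
        fams.append(
            EffectFamily(spec.name, spec.levels, idx, random=spec.kind == "random")
        )
    if len(crossed) > 1:
        for spec in crossed:
            idx = occasions[spec.name].to_numpy(dtype=int)
            fams.append(
                EffectFamily(
                    f"object:{spec.name}",
                    design.n_objects * spec.levels,
                    obj * spec.levels + idx,
                )
            )
        for a in range(len(crossed)):
            for b in range(a + 1, len(crossed)):
                fa, fb = crossed[a], crossed[b]
                ia = occasions[fa.name].to_numpy(dtype=int)
                ib = occasions[fb.name].to_numpy(dtype=int)
                fams.append(
                    EffectFamily(
                        f"{fa.name}:{fb.name}",
                        fa.levels * fb.levels,
                        ia * fb.levels + ib,
                    )
                )
    for spec in design.facets:
        if spec.relation == "nested":
            idx = occasions[spec.name].to_numpy(dtype=int)
            fams.append(EffectFamily(spec.name, spec.levels, idx))
            # object x crossed-facet interaction survives nesting (omega_jt)
            for cf in crossed:
                icf = occasions[cf.name].to_numpy(dtype=int)
                fams.append(
                    EffectFamily(
                        f"object:{cf.name}",
                        design.n_objects * cf.levels,
                        obj * cf.levels + icf,
                    )
                )
    return fams


def _check_nested_roster(design: MeasurementDesign, occasions: pd.DataFrame) -> None:
    for spec in design.facets:
        if spec.relation == "nested":
            per_level = occasions.groupby(spec.name)["object"].nunique()
            if (per_level > 1).any():
                bad = per_level[per_level > 1].index.tolist()
                raise ValueError(
                    f"nested facet {spec.name}: levels {bad} appear under "
                    "more than one object"
                )


def compose(
    effects: dict[str, np.ndarray],
    families: list[EffectFamily],
    residual: np.ndarray,
) -> np.ndarray:
    """Sum effect families plus residual over realized occasions."""
    residual = np.asarray(residual, dtype=float)
    theta = residual.copy()
    for fam in families:
        arr = np.asarray(effects[fam.name], dtype=float)
        if arr.shape != (fam.n_levels,):
            raise ValueError(
                f"effect family {fam.name!r} has shape {arr.shape}, "
                f"expected ({fam.n_levels},)"
            )
        theta += arr[fam.occ_index]
    return theta


def _compose_for(
    effects: dict[str, np.ndarray],
    design: MeasurementDesign,
    occasions: pd.DataFrame,
) -> LatentOccasionScores:
    fams = effect_families(design, occasions)
    residual = np.asarray(effects.get(RESIDUAL, np.zeros(len(occasions))), float)
    if residual.shape != (len(occasions),):
        raise ValueError("residual must have one entry per occasion")
    return LatentOccasionScores(occasions, compose(effects, fams, residual))


def compose_crossed(
    effects: dict[str, np.ndarray], design: MeasurementDesign
) -> LatentOccasionScores:
    """Seven-term crossed composition theta_jrt (two crossed facets), or its
    analogue for other fully crossed layouts."""
    if not design.is_fully_crossed:
        raise ValueError("compose_crossed requires a fully crossed design")
    return _compose_for(effects, design, crossed_occasions(design))


def compose_nested(
    effects: dict[str, np.ndarray],
    design: MeasurementDesign,
    occasions: pd.DataFrame,
) -> LatentOccasionScores:
    """Nested composition (e.g. students in teachers crossed with lessons).

    ``occasions`` supplies the realized roster: one row per (object, nested
    level, crossed facets...) occasion; rosters may vary per occasion.
    """
    if not any(f.relation == "nested" for f in design.facets):
        raise ValueError("design has no nested facet")
    _check_nested_roster(design, occasions)
    return _compose_for(effects, design, occasions.reset_index(drop=True))


def compose_repeated(
    effects: dict[str, np.ndarray], design: MeasurementDesign
) -> LatentOccasionScores:
    """Repeated-measurement composition theta_jt = theta_j + eps_jt."""
    if not all(f.relation == "repeated" for f in design.facets):
        raise ValueError("compose_repeated requires only repeated facets")
    return _compose_for(effects, design, crossed_occasions(design))


def total_variance(vc: dict[str, float]) -> float:
    """Sum of orthogonal variance components."""
    for k, v in vc.items():
        if v < 0:
            raise ValueError(f"negative variance component {k!r} = {v}")
    return float(sum(vc.values()))


def manifest_logit_scores(
    table: ResponseTable, design: MeasurementDesign
) -> LatentOccasionScores:
    """Continuity-corrected logits of per-occasion sum scores.

    The observed-score baseline (a GT model applied directly to scores, no
    IRT layer) needs a continuous occasion score.  With S the sum of the item
    categories over the occasion's observed items and S_max the corresponding
    maximum, the score is ``logit((S + 0.5) / (S_max + 1))``; the correction
    keeps all-zero and all-maximum patterns finite and maps the midpoint to
    exactly zero.  Occasions with no responses are excluded (logged).
    """
    keys, occ_of_row = table.occasion_index()
    if len(keys) == 0:
        return LatentOccasionScores(keys, np.zeros(0))
    n_occ = len(keys)
    s = np.bincount(occ_of_row, weights=table.responses, minlength=n_occ)
    smax = np.bincount(
        occ_of_row,
        weights=design.max_category[table.items].astype(float),
        minlength=n_occ,
    )
    n_resp = np.bincount(occ_of_row, minlength=n_occ)
    keep = n_resp > 0
    if not keep.all():
        logger.warning(
            "manifest_logit_scores: excluded %d occasions with no responses",
            int((~keep).sum()),
        )
    scores = logit((s[keep] + 0.5) / (smax[keep] + 1.0))
    return LatentOccasionScores(keys.loc[keep].reset_index(drop=True), scores)
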