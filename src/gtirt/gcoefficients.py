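"""Generalizability summaries: reliability, agreement, EAP scores, D-studies.

With variance components sigma^2 for the object (true-score) effect, the
object-by-facet interactions and the residual, the reliability of the mean
score over R raters and T time-points is

    rho^2_R = s2_obj / ( s2_obj + s2_obj:r / R + s2_obj:t / T + s2_res / (R T) )

(facet main effects drop out of a relative comparison because they shift all
objects equally), and the coefficient of agreement additionally carries the
facet main effects and their interaction in the denominator:

    rho^2_A = s2_obj / ( rho^2_R denominator + s2_r / R + s2_t / T
                         + s2_rt / (R T) ).

All posterior summaries are computed per draw and then summarized, so the
credibility bounds of the ratios come directly from the chain; plugging
posterior medians of the components into the formulas gives (slightly)
different numbers than the posterior medians of the per-draw ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gt_model import OBJECT, RESIDUAL

__all__ = [
    "GCoefficient",
    "reliability_rho",
    "agreement_rho",
    "gcoefficient",
    "d_study",
    "eap_scores",
    "local_reliability",
]

logger = logging.getLogger(__name__)


@dataclass
class GCoefficient:
    """One generalizability coefficient at a (R, T) design point.

    ``kind`` is ``"reliability"`` or ``"agreement"``; ``values`` holds the
    per-draw ratios (a length-1 array for plug-in components).
    """

    kind: str
    R: int
    T: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_1d(np.asarray(self.values, float))

    @property
    def median(self) -> float:
        return float(np.median(self.values))

    @property
    def lower(self) -> float:
        return float(np.quantile(self.values, 0.025))

    @property
    def upper(self) -> float:
        return float(np.quantile(self.values, 0.975))


def _classify(vc: dict) -> tuple[str, str, list[str], list[str], list[str]]:
    """Split component names into object interactions, mains and pairs.

    Returns (object key, residual key, object-interaction facets in order,
    facet mains, facet-pair keys).
    """
    if OBJECT not in vc:
        raise KeyError("variance components must include 'object'")
    if RESIDUAL not in vc:
        raise KeyError("variance components must include 'residual'")
    inter, mains, pairs = [], [], []
    for key in vc:
        if key in (OBJECT, RESIDUAL):
            continue
        if key.startswith(f"{OBJECT}:"):
            inter.append(key.split(":", 1)[1])
        elif ":" in key:
            pairs.append(key)
        else:
            mains.append(key)
    return OBJECT, RESIDUAL, inter, mains, pairs


def _facet_counts(vc: dict, R: int, T: int, facets=None) -> dict[str, float]:
    """Map facet name -> replication count, pairing (R, T) with the first and
    second facet appearing in the component names (or in ``facets``)."""
    if R < 1 or T < 1:
        raise ValueError("R and T must be >= 1")
    _, _, inter, mains, _ = _classify(vc)
    if facets is None:
        seen: list[str] = []
        for name in inter + mains:
            if name not in seen:
                seen.append(name)
        facets = tuple(seen)
    counts = dict(zip(facets, (float(R), float(T))))
    if len(facets) > 2:
        raise ValueError(
            f"reliability over (R, T) needs at most two facets, got {facets}"
        )
    return counts


def _denominators(vc: dict, R: int, T: int, facets=None):
    obj_key, res_key, inter, mains, pairs = _classify(vc)
    counts = _facet_counts(vc, R, T, facets)
    num = np.asarray(vc[obj_key], float)
    nt = float(np.prod(list(counts.values()))) if counts else 1.0
    den_rel = num + np.asarray(vc[res_key], float) / nt
    for f in inter:
        den_rel = den_rel + np.asarray(vc[f"{OBJECT}:{f}"], float) / counts[f]
    den_agr = den_rel
    for f in mains:
        den_agr = den_agr + np.asarray(vc[f], float) / counts[f]
    for key in pairs:
        a, b = key.split(":", 1)
        den_agr = den_agr + np.asarray(vc[key], float) / (counts[a] * counts[b])
    return num, den_rel, den_agr


def reliability_rho(vc: dict, R: int, T: int, facets=None):
    """Reliability rho^2_R of the R x T mean score (relative comparisons).

    ``vc`` maps component names (``object``, facet mains, ``object:<facet>``
    interactions, facet pairs, ``residual``) to variances — scalars or
    per-draw arrays, in which case the ratio is returned per draw.  Facet
    main effects and their interaction do not enter the denominator.
    """
    num, den_rel, _ = _denominators(vc, R, T, facets)
    if np.any(den_rel == 0):
        raise ZeroDivisionError("reliability denominator is zero")
    out = num / den_rel
    return float(out) if np.ndim(out) == 0 else out


def agreement_rho(vc: dict, R: int, T: int, facets=None):
    """Agreement rho^2_A of the R x T mean score (absolute comparisons).

    Like :func:`reliability_rho` but with the facet main effects and their
    interaction added to the denominator, so rho^2_A <= rho^2_R always.
    """
    num, _, den_agr = _denominators(vc, R, T, facets)
    if np.any(den_agr == 0):
        raise ZeroDivisionError("agreement denominator is zero")
    out = num / den_agr
    return float(out) if np.ndim(out) == 0 else out


def gcoefficient(draws, kind: str, R: int, T: int, dim: int = 0) -> GCoefficient:
    """Per-draw coefficient of one kind at one (R, T) point from a fit."""
    fn = {"reliability": reliability_rho, "agreement": agreement_rho}.get(kind)
    if fn is None:
        raise ValueError("kind must be 'reliability' or 'agreement'")
    vc = draws.vc_draws(dim)
    return GCoefficient(kind, R, T, fn(vc, R, T))


def d_study(draws, R_list, T_list, dim: int = 0) -> pd.DataFrame:
    """Decision-study table over a grid of rater and time-point counts.

    For every (R, T) pair and both coefficient kinds the ratio is evaluated
    per retained draw; the table reports the posterior median and central
    95% bounds (columns ``kind, R, T, lower2.5, median, upper97.5``).
    """
    R_list, T_list = list(R_list), list(T_list)
    if not R_list or not T_list:
        raise ValueError("D-study grid must be non-empty")
    vc = draws.vc_draws(dim)
    rows = []
    for kind, fn in (("reliability", reliability_rho), ("agreement", agreement_rho)):
        for R in R_list:
            for T in T_list:
                g = GCoefficient(kind, int(R), int(T), fn(vc, int(R), int(T)))
                rows.append(
                    {
                        "kind": kind,
                        "R": g.R,
                        "T": g.T,
                        "lower2.5": g.lower,
                        "median": g.median,
                        "upper97.5": g.upper,
                    }
                )
    return pd.DataFrame(rows)


def eap_scores(draws, dim: int = 0) -> pd.DataFrame:
    """Expected a posteriori score per object.

    S_j is, within each retained draw, the mean of the occasion scores over
    the object's realized raters and time-points; the EAP is its posterior
    mean, reported with the posterior variance.  Objects without occasions
    are excluded (logged).
    """
    key = draws._prefix(dim) + "S"
    S = draws.draws[key]
    has = ~np.isnan(S).all(axis=0)
    if not has.all():
        logger.warning(
            "eap_scores: excluded %d objects with no occasions",
            int((~has).sum()),
        )
    idx = np.flatnonzero(has)
    return pd.DataFrame(
        {
            "object": idx,
            "eap": S[:, idx].mean(axis=0),
            "posterior_var": S[:, idx].var(axis=0),
        }
    )


def local_reliability(
    draws, R: int | None = None, T: int | None = None, dim: int = 0
) -> pd.DataFrame:
    """Object-specific reliability of the R x T mean score.

    The population error term of the global coefficient is replaced by the
    object's own posterior variance of S_j, rescaled from the fitted design
    (R0, T0) to the prospective (R, T) by the factor (R0 T0)/(R T) — an
    object measured with little posterior uncertainty keeps a high local
    coefficient even where the global average is modest, and vice versa.
    Defaults to the fitted design counts.  Returns columns ``object,
    reliability, agreement``.
    """
    design = draws.meta["designs"][dim]
    crossed = [f for f in design.facets if f.relation == "crossed"]
    if len(crossed) != 2:
        raise ValueError("local reliability needs two crossed facets")
    R0, T0 = crossed[0].levels, crossed[1].levels
    R = R0 if R is None else int(R)
    T = T0 if T is None else int(T)
    if R < 1 or T < 1:
        raise ValueError("R and T must be >= 1")
    eap = eap_scores(draws, dim)
    v_obj = float(np.mean(draws.vc_draws(dim)[OBJECT]))
    vc_mean = {k: float(np.mean(v)) for k, v in draws.vc_draws(dim).items()}
    scale = (R0 * T0) / (R * T)
    err = eap["posterior_var"].to_numpy() * scale
    rel = v_obj / (v_obj + err)
    extra = sum(
        vc_mean.get(name, 0.0) / c
        for name, c in ((crossed[0].name, R), (crossed[1].name, T))
    ) + vc_mean.get(f"{crossed[0].name}:{crossed[1].name}", 0.0) / (R * T)
    agr = v_obj / (v_obj + err + extra)
    return pd.DataFrame(
        {"object": eap["object"], "reliability": rel, "agreement": agr}
    )
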