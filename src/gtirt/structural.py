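"""Structural models on the object-level latent variables.

The object main effect theta_j of the measurement model can be embedded in a
two-level random-intercept regression as a latent level-2 predictor:

    level 1:  Y_ij    = beta_0j + X_ij beta + (sum_c beta_c D_cij theta_j) + R_ij
    level 2:  beta_0j = gamma_0 + gamma_1 theta_j + W_j gamma_W + U_0j

Because theta_j enters the regression free of rater/time/item error, gamma_1
is not attenuated the way a manifest mean-score slope is.  Cross-level
interaction columns (theta_j times level-1 dummies) are rebuilt from the
current latent draw at every MCMC iteration.

This module also provides posterior summaries for latent facet-mean
contrasts and for the correlations of a multivariate latent covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MultilevelSpec",
    "MultilevelData",
    "level_predictor_matrix",
    "predict",
    "icc",
    "LatentMeanContrast",
    "latent_contrast",
    "latent_correlations",
    "significant",
]


@dataclass(frozen=True)
class MultilevelSpec:
    """Declared covariate structure of the two-level model.

    ``level1``: level-1 covariate names (entering with coefficients beta);
    ``interactions``: level-1 covariate names whose product with theta_j
    enters level 1 (cross-level interactions);
    ``level2``: manifest object-level covariate names W_j.
    """

    level1: tuple[str, ...] = ()
    interactions: tuple[str, ...] = ()
    level2: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "level1", tuple(self.level1))
        object.__setattr__(self, "interactions", tuple(self.interactions))
        object.__setattr__(self, "level2", tuple(self.level2))
        missing = set(self.interactions) - set(self.level1)
        if missing:
            raise ValueError(
                f"interaction covariates {sorted(missing)} are not declared "
                "level-1 covariates"
            )

    @property
    def n_level1(self) -> int:
        return len(self.level1) + len(self.interactions)

    @property
    def n_level2(self) -> int:
        # grand mean + latent predictor + manifest W
        return 2 + len(self.level2)


@dataclass
class MultilevelData:
    """Unit- and object-level covariate arrays for a MultilevelSpec."""

    y: np.ndarray
    obj: np.ndarray
    X: np.ndarray
    Dint: np.ndarray
    W: np.ndarray
    spec: MultilevelSpec = field(default_factory=MultilevelSpec)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, float)
        self.obj = np.asarray(self.obj, int)
        self.X = np.atleast_2d(np.asarray(self.X, float))
        self.Dint = np.asarray(self.Dint, float).reshape(len(self.y), -1)
        self.W = np.atleast_2d(np.asarray(self.W, float))
        n = len(self.y)
        if self.obj.shape != (n,) or self.X.shape[0] != n:
            raise ValueError("level-1 arrays must share the unit dimension")
        if np.isnan(self.y).any() or np.isnan(self.X).any() or np.isnan(self.W).any():
            raise ValueError("missing covariate or outcome values (no imputation)")

    @property
    def n_units(self) -> int:
        return len(self.y)

    @property
    def n_objects(self) -> int:
        return self.W.shape[0]

    @classmethod
    def from_frames(
        cls,
        spec: MultilevelSpec,
        units: pd.DataFrame,
        objects: pd.DataFrame,
        outcome: str = "y",
    ) -> "MultilevelData":
        """Build arrays from a unit table (object id + covariates + outcome)
        and an object table (one row per object, sorted by object id)."""
        for c in ("object", outcome, *spec.level1):
            if c not in units.columns:
                raise ValueError(f"unit table is missing column {c!r}")
        for c in spec.level2:
            if c not in objects.columns:
                raise ValueError(f"object table is missing column {c!r}")
        objects = objects.sort_values("object").reset_index(drop=True)
        return cls(
            y=units[outcome].to_numpy(float),
            obj=units["object"].to_numpy(int),
            X=units[list(spec.level1)].to_numpy(float)
            if spec.level1
            else np.zeros((len(units), 0)),
            Dint=units[list(spec.interactions)].to_numpy(float)
            if spec.interactions
            else np.zeros((len(units), 0)),
            W=objects[list(spec.level2)].to_numpy(float)
            if spec.level2
            else np.zeros((len(objects), 0)),
            spec=spec,
        )


def level_predictor_matrix(
    spec: MultilevelSpec, data: MultilevelData, theta: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Design matrices for the two levels at the current latent draw.

    Returns ``(X1, Z2)`` where ``X1`` (n_units x (p1 + p_int)) stacks the
    level-1 covariates and the cross-level columns ``theta_j * D_c``, and
    ``Z2`` (n_objects x (2 + p2)) is ``[1, theta_j, W_j]``.  The theta
    columns must be rebuilt at every iteration from the current draw.
    """
    theta = np.asarray(theta, float)
    if theta.shape != (data.n_objects,):
        raise ValueError("one theta per object required")
    theta_u = theta[data.obj]
    X1 = np.column_stack([data.X, data.Dint * theta_u[:, None]])
    Z2 = np.column_stack(
        [np.ones(data.n_objects), theta, data.W]
    )
    return X1, Z2


def predict(
    spec: MultilevelSpec,
    data: MultilevelData,
    theta: np.ndarray,
    beta: np.ndarray,
    gamma: np.ndarray,
) -> np.ndarray:
    """Fixed-part prediction per unit (random residuals at zero)."""
    X1, Z2 = level_predictor_matrix(spec, data, theta)
    b0 = Z2 @ np.asarray(gamma, float)
    return b0[data.obj] + X1 @ np.asarray(beta, float)


def icc(level1_var: float, level2_var: float) -> float:
    """Intraclass correlation: share of outcome variance at level 2."""
    if level1_var < 0 or level2_var < 0:
        raise ValueError("variances must be non-negative")
    tot = level1_var + level2_var
    if tot == 0:
        raise ValueError("ICC undefined when both variances are zero")
    return level2_var / tot


@dataclass(frozen=True)
class LatentMeanContrast:
    """Partition of a facet's levels into two disjoint groups, compared as a
    per-draw difference of group means (group_b minus group_a)."""

    group_a: tuple[int, ...]
    group_b: tuple[int, ...]

    def __post_init__(self) -> None:
        a, b = tuple(self.group_a), tuple(self.group_b)
        object.__setattr__(self, "group_a", a)
        object.__setattr__(self, "group_b", b)
        if not a or not b:
            raise ValueError("contrast groups must be non-empty")
        if set(a) & set(b):
            raise ValueError("contrast groups must be disjoint")


def latent_contrast(
    level_mean_draws: np.ndarray, contrast: LatentMeanContrast
) -> dict:
    """Posterior summary of a group-mean difference.

    ``level_mean_draws`` has shape (n_draws, n_levels): per-draw means of a
    facet's levels (or object groups).  Returns the per-draw differences
    plus mean, central 95% bounds and their span.
    """
    draws = np.asarray(level_mean_draws, float)
    levels = draws.shape[1]
    for g in (*contrast.group_a, *contrast.group_b):
        if not 0 <= g < levels:
            raise ValueError(f"group level {g} outside 0..{levels - 1}")
    diff = draws[:, list(contrast.group_b)].mean(axis=1) - draws[
        :, list(contrast.group_a)
    ].mean(axis=1)
    lo, hi = np.quantile(diff, [0.025, 0.975])
    return {
        "draws": diff,
        "mean": float(diff.mean()),
        "lower": float(lo),
        "upper": float(hi),
        "range": float(hi - lo),
    }


def latent_correlations(sigma_draws: np.ndarray) -> dict[tuple[int, int], dict]:
    """Per-pair correlation summaries from covariance-matrix draws.

    ``sigma_draws`` has shape (n_draws, D, D).  Returns, per pair (d, d')
    with d < d', the per-draw correlations and their posterior median and
    central 95% bounds.
    """
    S = np.asarray(sigma_draws, float)
    if S.ndim != 3 or S.shape[1] != S.shape[2]:
        raise ValueError("sigma_draws must have shape (n_draws, D, D)")
    sd = np.sqrt(np.einsum("ndd->nd", S))
    out = {}
    D = S.shape[1]
    for a in range(D):
        for b in range(a + 1, D):
            r = S[:, a, b] / (sd[:, a] * sd[:, b])
            lo, hi = np.quantile(r, [0.025, 0.975])
            out[(a, b)] = {
                "draws": r,
                "median": float(np.median(r)),
                "lower": float(lo),
                "upper": float(hi),
            }
    return out


def significant(lower: float, upper: float) -> bool:
    """Flag an effect whose central 95% credibility bounds share a sign."""
    return (lower > 0 and upper > 0) or (lower < 0 and upper < 0)
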