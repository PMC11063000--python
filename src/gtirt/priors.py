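"""Prior specifications, MCMC settings, and identification rules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PriorSpec",
    "McmcSettings",
    "ItemParameterMode",
    "IdentificationRule",
]


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the prior distributions.

    * discrimination: normal truncated to the positive reals,
      mean ``alpha_mean`` and variance ``alpha_var`` (both default 1);
    * thresholds: normal with mean equal to the category index h (so the
      prior gently encourages the usual ordering) and variance
      ``delta_var``; in empirical-Bayes mode the means are replaced by
      supplied estimates with variance ``eb_delta_var``;
    * precisions (reciprocal variance components): Gamma with shape
      ``precision_shape`` and rate ``precision_rate`` (0.01/0.01: vague,
      prior mean 1);
    * latent covariance matrix: inverse Wishart with ``wishart_df`` extra
      degrees of freedom above the dimension and an identity scale;
    * regression coefficients: normal, mean 0, variance ``coef_var``.
    """

    alpha_mean: float = 1.0
    alpha_var: float = 1.0
    delta_var: float = 1.0
    eb_delta_var: float = 10.0
    precision_shape: float = 0.01
    precision_rate: float = 0.01
    wishart_identity_scale: float = 1.0
    coef_var: float = 100.0

    def __post_init__(self) -> None:
        for name in (
            "alpha_var",
            "delta_var",
            "eb_delta_var",
            "precision_shape",
            "precision_rate",
            "wishart_identity_scale",
            "coef_var",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class McmcSettings:
    """Chain length and bookkeeping. Defaults match routine applied use of
    the framework (long vague-prior chains); tests and desk-scale studies
    pass much smaller values."""

    iterations: int = 60_000
    burn_in: int = 5_000
    thin: int = 1
    chains: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thin < 1 or self.chains < 1:
            raise ValueError("thin and chains must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


@dataclass(frozen=True)
class ItemParameterMode:
    """How item parameters are treated during estimation.

    ``concurrent``: sampled jointly with everything else.
    ``empirical_bayes``: sampled, but thresholds get informative normal
    priors centred on supplied estimates (variance ``eb_delta_var``).
    ``fixed``: supplied values are held constant (auxiliary data).
    """

    mode: str = "concurrent"
    alpha: np.ndarray | None = None
    delta: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("concurrent", "empirical_bayes", "fixed"):
            raise ValueError(f"unknown item-parameter mode {self.mode!r}")
        if self.mode in ("empirical_bayes", "fixed"):
            if self.alpha is None or self.delta is None:
                raise ValueError(
                    f"mode {self.mode!r} requires a complete item-parameter "
                    "table (alpha and delta)"
                )
            object.__setattr__(self, "alpha", np.asarray(self.alpha, float))
            object.__setattr__(self, "delta", np.asarray(self.delta, float))

    @classmethod
    def concurrent(cls) -> "ItemParameterMode":
        return cls("concurrent")

    @classmethod
    def empirical_bayes(cls, alpha, delta) -> "ItemParameterMode":
        return cls("empirical_bayes", alpha, delta)

    @classmethod
    def fixed(cls, alpha, delta) -> "ItemParameterMode":
        return cls("fixed", alpha, delta)


@dataclass(frozen=True)
class IdentificationRule:
    """Rule fixing origin and scale of one latent dimension.

    ``fix_object_variance``: every retained draw is affinely transformed so
    that the object-effect sample moments are exactly mean 0, variance 1
    (the object variance component is then 1 by construction); the item
    bank, the other variance components and the structural coefficients are
    reparameterized along, so the recorded draw describes the same fitted
    model on the identified scale.  The chain itself is only softly
    identified through the object-effect prior centred on the target
    moments.  ``fix_plugin_moments``: same, but to supplied moments mu /
    sigma2; with ``sigma2 == 0`` the object effects are pinned to mu
    exactly within the chain.  ``none``: no constraint (only sensible when
    item parameters are fixed, or for prior-sampling checks); the object
    variance component is then sampled like any other.
    """

    rule: str = "fix_object_variance"
    mu: float = 0.0
    sigma2: float = 1.0
    object_variance: float | None = field(default=None)

    def __post_init__(self) -> None:
        if self.rule not in ("fix_object_variance", "fix_plugin_moments", "none"):
            raise ValueError(f"unknown identification rule {self.rule!r}")
        if self.rule == "fix_object_variance":
            object.__setattr__(self, "mu", 0.0)
            object.__setattr__(self, "sigma2", 1.0)
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")

    @classmethod
    def fix_object_variance(cls) -> "IdentificationRule":
        return cls("fix_object_variance")

    @classmethod
    def fix_plugin_moments(cls, mu: float, sigma2: float) -> "IdentificationRule":
        return cls("fix_plugin_moments", mu=float(mu), sigma2=float(sigma2))

    @classmethod
    def none(cls, object_variance: float | None = None) -> "IdentificationRule":
        """No constraint; optionally fix the object variance component to a
        constant (e.g. a large value for an effectively diffuse prior)."""
        return cls("none", object_variance=object_variance)
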