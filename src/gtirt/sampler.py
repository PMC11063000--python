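"""Fully Bayesian MCMC engine for GT-IRT models.

The joint model has three layers: a GPCM measurement layer mapping polytomous
responses to latent occasion scores, a generalizability-theory layer
decomposing those scores into object and facet effects with variance
components, and an optional structural layer (a two-level regression with
the object effect as latent predictor, or a multivariate normal across
latent dimensions).  All layers are estimated concurrently, so the
uncertainty of the latent scores propagates into every downstream quantity
and regression coefficients on the latent predictor are free of
facet-error attenuation.

Update scheme (Metropolis-within-Gibbs):

* occasion scores theta and item parameters (alpha_k, delta_kh): adaptive
  random-walk Metropolis, target acceptance 0.44, adaptation frozen after
  burn-in;
* effect arrays, structural coefficients and random intercepts: conjugate
  normal updates;
* variance components: conjugate gamma updates on the precisions;
* latent covariance matrix: conjugate inverse Wishart.

Derived quantities (variance components, reliability/agreement ratios, the
ICC, facet-level means, per-object score averages, the conditional
deviance) are tracked within each retained iteration, so their credibility
regions come directly from the chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .designs import MeasurementDesign, ResponseTable, validate
from .gt_model import OBJECT, RESIDUAL, EffectFamily, effect_families
from .priors import IdentificationRule, ItemParameterMode, McmcSettings, PriorSpec
from .structural import MultilevelData, MultilevelSpec, level_predictor_matrix

__all__ = [
    "DimensionSpec",
    "PosteriorDraws",
    "initialize",
    "fit",
    "fit_dimensions",
    "diagnostics",
    "dic",
]

logger = logging.getLogger(__name__)

_TARGET_ACCEPT = 0.44
_ADAPT_EVERY = 25


# ---------------------------------------------------------------------------
# model specification


@dataclass
class DimensionSpec:
    """One latent dimension: a design, its data, and estimation choices.

    ``measurement`` is ``"gpcm"`` (responses in ``table`` modeled by the
    item layer) or ``"manifest"`` (observed continuous occasion scores in
    ``scores``; the GT layer is applied directly, as in the sum-score
    baseline).  ``bank`` indexes the item bank used by this dimension, so
    several dimensions may share one bank or each carry their own.
    """

    design: MeasurementDesign
    table: ResponseTable | None = None
    measurement: str = "gpcm"
    scores: np.ndarray | None = None
    occasions: pd.DataFrame | None = None
    identification: IdentificationRule = field(
        default_factory=IdentificationRule.fix_object_variance
    )
    mode: ItemParameterMode = field(default_factory=ItemParameterMode.concurrent)
    bank: int | None = 0

    def __post_init__(self) -> None:
        if self.measurement not in ("gpcm", "manifest"):
            raise ValueError("measurement must be 'gpcm' or 'manifest'")
        if self.measurement == "gpcm":
            if self.table is None:
                raise ValueError("gpcm dimension requires a response table")
        else:
            self.bank = None
            if self.scores is None or self.occasions is None:
                raise ValueError(
                    "manifest dimension requires scores and their occasions"
                )


# ---------------------------------------------------------------------------
# initialization


def initialize(
    table: ResponseTable | None,
    design: MeasurementDesign,
    mode: ItemParameterMode | None = None,
) -> dict:
    """Heuristic starting state for the sampler.

    Discriminations start at 1 (or the supplied values); thresholds start at
    the pooled adjacent-category empirical log-odds ``log(n_{h-1} / n_h)``
    (with 0.5 smoothing), which are zero under uniform frequencies; an item
    category that was never observed leaves its adjacent thresholds at the
    prior mean (the category index), with a warning.  Effects start at 0,
    variances at 1, regression coefficients at 0.
    """
    mode = mode or ItemParameterMode.concurrent()
    K = design.n_items
    M = int(design.max_category.max())
    alpha = np.ones(K)
    delta = np.full((K, M), np.nan)
    for k in range(K):
        delta[k, : design.max_category[k]] = np.arange(
            1, design.max_category[k] + 1, dtype=float
        )
    warnings: list[str] = []
    if mode.mode in ("empirical_bayes", "fixed"):
        alpha = mode.alpha.copy()
        delta_s = np.asarray(mode.delta, float)
        delta[:, : delta_s.shape[1]] = delta_s
    elif table is not None and len(table) > 0:
        items = table.items
        resp = table.responses
        for k in range(K):
            counts = np.bincount(
                resp[items == k], minlength=design.n_categories[k]
            ).astype(float)
            for h in range(1, design.max_category[k] + 1):
                if counts[h - 1] == 0 or counts[h] == 0:
                    warnings.append(
                        f"item {k}: empty category near step {h}; threshold "
                        "left at its prior mean"
                    )
                else:
                    delta[k, h - 1] = float(
                        np.log((counts[h - 1] + 0.5) / (counts[h] + 0.5))
                    )
    for w in warnings:
        logger.warning("initialize: %s", w)
    return {
        "alpha": alpha,
        "delta": delta,
        "effects": 0.0,
        "variances": 1.0,
        "coefficients": 0.0,
        "warnings": warnings,
    }


# ---------------------------------------------------------------------------
# internal state containers


class _BankState:
    def __init__(self, design: MeasurementDesign, mode: ItemParameterMode,
                 priors: PriorSpec, start: dict):
        self.mode = mode
        self.K = design.n_items
        self.n_steps = design.max_category.copy()
        M = int(self.n_steps.max())
        self.alpha = np.asarray(start["alpha"], float).copy()
        self.delta = np.asarray(start["delta"], float).copy()
        self.valid = np.arange(M)[None, :] < self.n_steps[:, None]
        # threshold prior means: category index, or supplied estimates (EB)
        self.delta_prior_mean = np.where(
            self.valid, np.arange(1, M + 1)[None, :].astype(float), np.nan
        )
        self.delta_prior_var = priors.delta_var
        if mode.mode == "empirical_bayes":
            dm = np.full((self.K, M), np.nan)
            dm[:, : mode.delta.shape[1]] = mode.delta
            self.delta_prior_mean = dm
            self.delta_prior_var = priors.eb_delta_var
        self.alpha_prior_mean = priors.alpha_mean
        self.alpha_prior_var = priors.alpha_var
        self.scale = np.full(self.K, 0.2)
        self.acc = np.zeros(self.K)
        self.acc_total = 0.0
        self.n_prop = 0

    @property
    def fixed(self) -> bool:
        return self.mode.mode == "fixed"

    def cum_delta(self, delta: np.ndarray) -> np.ndarray:
        K, M = delta.shape
        cum = np.zeros((K, M + 1))
        cum[:, 1:] = np.nancumsum(delta, axis=1)
        return cum

    def log_prior(self, alpha: np.ndarray, delta: np.ndarray) -> np.ndarray:
        """Per-item log prior (up to constants shared by current/proposal)."""
        with np.errstate(invalid="ignore"):
            lp = np.where(
                alpha > 0,
                -0.5 * (alpha - self.alpha_prior_mean) ** 2 / self.alpha_prior_var,
                -np.inf,
            )
            d = np.where(self.valid, (delta - self.delta_prior_mean) ** 2, 0.0)
        return lp - 0.5 * d.sum(axis=1) / self.delta_prior_var


def _gamma_prec(rng, shape: float, rate: float) -> float:
    """Gamma(shape, rate) precision draw, floored at the smallest positive
    normal float.  With a vague shape (0.01) and no data the draw underflows
    to exactly 0 about once in a thousand iterations; the floor keeps the
    implied variance finite while moving only mass already below 1e-300."""
    return max(float(rng.gamma(shape, 1.0 / rate)), float(np.finfo(float).tiny))


def _log_prob_table(theta, alpha, cum_delta, valid_cat):
    m = np.arange(cum_delta.shape[1])
    A = alpha[:, None] * m[None, :]
    B = alpha[:, None] * cum_delta
    S = theta[:, None, None] * A[None] - B[None]
    S = np.where(valid_cat[None], S, -np.inf)
    Smax = S.max(axis=2, keepdims=True)
    lse = Smax[..., 0] + np.log(np.exp(S - Smax).sum(axis=2))
    return S - lse[..., None]


def _record_ll(theta, resp_mat, alpha, cum_delta, valid_cat):
    lp = _log_prob_table(theta, alpha, cum_delta, valid_cat)
    r = np.clip(resp_mat, 0, None)
    out = np.take_along_axis(lp, r[:, :, None], axis=2)[:, :, 0]
    return np.where(resp_mat >= 0, out, 0.0)


class _DimState:
    def __init__(self, spec: DimensionSpec, priors: PriorSpec):
        self.spec = spec
        design = spec.design
        if spec.measurement == "gpcm":
            report = validate(spec.table, design)
            if not report:
                raise ValueError(
                    "response table failed validation:\n" + "\n".join(report.errors)
                )
            keys, occ_of_row = spec.table.occasion_index()
            self.occasions = keys
            self.n_occ = len(keys)
            resp_mat = np.full((self.n_occ, design.n_items), -1, dtype=int)
            if self.n_occ:
                resp_mat[occ_of_row, spec.table.items] = spec.table.responses
            self.resp_mat = resp_mat
            self.y_obs = None
        else:
            self.occasions = spec.occasions.reset_index(drop=True)
            self.n_occ = len(self.occasions)
            self.resp_mat = None
            self.y_obs = np.asarray(spec.scores, float)
            if self.y_obs.shape != (self.n_occ,):
                raise ValueError("manifest scores must match occasions")
        self.obj = (
            self.occasions["object"].to_numpy(dtype=int)
            if self.n_occ
            else np.zeros(0, dtype=int)
        )
        fams = effect_families(design, self.occasions)
        self.obj_family = next(f for f in fams if f.name == OBJECT)
        self.families: list[EffectFamily] = [f for f in fams if f.name != OBJECT]
        self.N = design.n_objects

        # state
        self.e_obj = np.zeros(self.N)
        self.effects = {f.name: np.zeros(f.n_levels) for f in self.families}
        self.var = {f.name: 1.0 for f in self.families if f.random}
        self.var[RESIDUAL] = 1.0
        rule = spec.identification
        self.sample_object_var = rule.rule == "none" and rule.object_variance is None
        if self.sample_object_var:
            self.var[OBJECT] = 1.0
        self.theta = np.zeros(self.n_occ)
        self.m_occ = np.zeros(self.n_occ)
        self.scale = np.full(self.n_occ, 0.5)
        self.acc = np.zeros(self.n_occ)
        self.acc_total = 0.0
        self.n_prop = 0
        self.ll_rec = None  # (n_occ, K) cache, gpcm only
        self.crossed = [f for f in design.facets if f.relation == "crossed"]
        self._build_sweeps(design)

    def _build_sweeps(self, design: MeasurementDesign) -> None:
        """Translation ("sweep") moves between effect families.

        A common offset added to one family and subtracted from another
        leaves every occasion score unchanged, so such directions are
        informed by the priors alone; Gibbs-sampling the offsets from their
        exact full conditionals stops those directions from random-walking
        (which would otherwise inflate the small families' sampled
        variances).
        """
        self.sweeps: list[tuple] = []
        facet_names = {f.name for f in design.facets}
        for fam in self.families:
            if ":" not in fam.name:
                spec_f = design.facet(fam.name)
                if spec_f.relation == "nested":
                    parent = np.full(fam.n_levels, -1)
                    if self.n_occ:
                        g = self.occasions.groupby(fam.name)["object"].first()
                        parent[g.index.to_numpy(int)] = g.to_numpy(int)
                    self.sweeps.append(("obj_vector", fam.name, parent))
            elif fam.name.startswith(f"{OBJECT}:"):
                fname = fam.name.split(":", 1)[1]
                L = design.facet(fname).levels
                lv = np.arange(fam.n_levels)
                self.sweeps.append(("obj_vector", fam.name, lv // L))
                self.sweeps.append(("fam_vector", fam.name, fname, lv % L))
            else:
                a, b = fam.name.split(":", 1)
                if a in facet_names and b in facet_names:
                    Lb = design.facet(b).levels
                    lv = np.arange(fam.n_levels)
                    self.sweeps.append(("fam_vector", fam.name, a, lv // Lb))
                    self.sweeps.append(("fam_vector", fam.name, b, lv % Lb))

    def object_prior_moments(self) -> tuple[float, float]:
        rule = self.spec.identification
        if rule.rule == "none":
            v = (
                self.var[OBJECT]
                if self.sample_object_var
                else float(rule.object_variance)
            )
            return 0.0, v
        return rule.mu, rule.sigma2

    def object_variance_value(self) -> float:
        if self.sample_object_var:
            return self.var[OBJECT]
        rule = self.spec.identification
        if rule.rule == "none":
            return float(rule.object_variance)
        return rule.sigma2


# ---------------------------------------------------------------------------
# posterior draws container


class PosteriorDraws:
    """Retained per-iteration samples plus run metadata.

    ``draws`` maps a parameter name to an array whose leading axis is the
    retained draw (chains concatenated); ``meta`` records settings, seeds,
    identification rules and the deviance at the posterior means (for DIC);
    ``acceptance`` holds Metropolis acceptance rates.
    """

    def __init__(self, draws: dict[str, np.ndarray], meta: dict, acceptance: dict):
        self.draws = draws
        self.meta = meta
        self.acceptance = acceptance

    @property
    def names(self) -> list[str]:
        return sorted(self.draws)

    @property
    def n_draws(self) -> int:
        return len(next(iter(self.draws.values())))

    def __getitem__(self, name: str) -> np.ndarray:
        return self.draws[name]

    def mean(self, name: str) -> np.ndarray:
        return self.draws[name].mean(axis=0)

    def median(self, name: str) -> np.ndarray:
        return np.median(self.draws[name], axis=0)

    def interval(self, name: str, level: float = 0.95) -> tuple:
        a = (1 - level) / 2
        q = np.quantile(self.draws[name], [a, 1 - a], axis=0)
        return q[0], q[1]

    def vc_draws(self, dim: int = 0) -> dict[str, np.ndarray]:
        """Variance-component draws {family: (n_draws,)} for one dimension."""
        prefix = self._prefix(dim) + "vc."
        out = {
            k[len(prefix):]: v for k, v in self.draws.items() if k.startswith(prefix)
        }
        if not out:
            raise KeyError(f"no variance components for dimension {dim}")
        return out

    def _prefix(self, dim: int) -> str:
        return "" if self.meta["n_dimensions"] == 1 else f"d{dim}."

    def summary(self, names: list[str] | None = None) -> pd.DataFrame:
        """Posterior median and central 95% bounds per scalar element."""
        rows = []
        for name in names or self.names:
            arr = self.draws[name]
            flat = arr.reshape(self.n_draws, -1)
            for j in range(flat.shape[1]):
                col = flat[:, j]
                if np.isnan(col).all():
                    continue
                lo, med, hi = np.nanquantile(col, [0.025, 0.5, 0.975])
                label = name if flat.shape[1] == 1 else f"{name}[{j}]"
                rows.append(
                    {
                        "parameter": label,
                        "lower2.5": lo,
                        "median": med,
                        "upper97.5": hi,
                        "mean": float(np.nanmean(col)),
                    }
                )
        return pd.DataFrame(rows)

    def to_long_frame(self, names: list[str] | None = None) -> pd.DataFrame:
        """Columnar (parameter, iteration, value) export."""
        frames = []
        for name in names or self.names:
            flat = self.draws[name].reshape(self.n_draws, -1)
            for j in range(flat.shape[1]):
                label = name if flat.shape[1] == 1 else f"{name}[{j}]"
                frames.append(
                    pd.DataFrame(
                        {
                            "parameter": label,
                            "iteration": np.arange(self.n_draws),
                            "value": flat[:, j],
                        }
                    )
                )
        return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# the engine


def fit(
    table: ResponseTable | None,
    design: MeasurementDesign,
    *,
    priors: PriorSpec | None = None,
    settings: McmcSettings | None = None,
    mode: ItemParameterMode | None = None,
    identification: IdentificationRule | None = None,
    structural: MultilevelSpec | None = None,
    structural_data: MultilevelData | None = None,
    measurement: str = "gpcm",
    scores: np.ndarray | None = None,
    occasions: pd.DataFrame | None = None,
    store_occasions: bool = False,
) -> PosteriorDraws:
    """Fit a single-dimension GT-IRT (or manifest GT) model.

    Thin wrapper over :func:`fit_dimensions` for the common case.
    """
    dim = DimensionSpec(
        design=design,
        table=table,
        measurement=measurement,
        scores=scores,
        occasions=occasions,
        identification=identification or IdentificationRule.fix_object_variance(),
        mode=mode or ItemParameterMode.concurrent(),
    )
    return fit_dimensions(
        [dim],
        priors=priors,
        settings=settings,
        structural=structural,
        structural_data=structural_data,
        store_occasions=store_occasions,
    )


def fit_dimensions(
    dimensions: list[DimensionSpec],
    *,
    latent: str = "independent",
    priors: PriorSpec | None = None,
    settings: McmcSettings | None = None,
    structural: MultilevelSpec | None = None,
    structural_data: MultilevelData | None = None,
    store_occasions: bool = False,
) -> PosteriorDraws:
    """Fit a GT-IRT model with one or more latent dimensions.

    ``latent`` governs the object effects across dimensions:
    ``"independent"`` (each dimension its own normal distribution),
    ``"correlated"`` (multivariate normal with an inverse-Wishart prior on
    the covariance), or ``"shared"`` (a single common object effect — a
    strictly unidimensional model).  The structural model, when given,
    attaches to dimension 0's object effect.
    """
    priors = priors or PriorSpec()
    settings = settings or McmcSettings()
    if latent not in ("independent", "correlated", "shared"):
        raise ValueError("latent must be independent, correlated or shared")
    if len(dimensions) == 1:
        latent = "independent"
    if (structural is None) != (structural_data is None):
        raise ValueError("structural spec and data must be supplied together")

    all_draws: list[dict[str, np.ndarray]] = []
    accum: dict | None = None
    acceptance: dict = {}
    for chain in range(settings.chains):
        rng = np.random.default_rng([settings.seed, chain])
        chain_draws, accum, acceptance = _run_chain(
            dimensions, latent, priors, settings, structural, structural_data,
            store_occasions, rng, accum,
        )
        all_draws.append(chain_draws)

    draws = {
        k: np.asarray([*all_draws[0][k]])
        if settings.chains == 1
        else np.concatenate([cd[k] for cd in all_draws], axis=0)
        for k in all_draws[0]
    }
    dev_at_mean = _deviance_at_mean(dimensions, accum)
    meta = {
        "n_dimensions": len(dimensions),
        "latent": latent,
        "settings": settings,
        "priors": priors,
        "seed": settings.seed,
        "chains": settings.chains,
        "n_per_chain": settings.n_retained,
        "identification": [d.identification.rule for d in dimensions],
        "modes": [d.mode.mode for d in dimensions],
        "deviance_at_mean": dev_at_mean,
        "designs": [d.design for d in dimensions],
        "structural": structural,
    }
    return PosteriorDraws(draws, meta, acceptance)


def _run_chain(dimensions, latent, priors, settings, struct_spec, struct_data,
               store_occasions, rng, accum):
    dims = [_DimState(d, priors) for d in dimensions]
    D = len(dims)
    multi = D > 1

    if latent == "shared":
        for d in dims[1:]:
            if d.N != dims[0].N:
                raise ValueError("shared object effects require equal n_objects")

    # banks
    bank_ids = sorted({d.spec.bank for d in dims if d.spec.bank is not None})
    banks: dict[int, _BankState] = {}
    for b in bank_ids:
        users = [d for d in dims if d.spec.bank == b]
        d0 = users[0]
        start = initialize(d0.spec.table, d0.spec.design, d0.spec.mode)
        banks[b] = _BankState(d0.spec.design, d0.spec.mode, priors, start)
        for d in users[1:]:
            if (
                not np.array_equal(
                    d.spec.design.max_category, d0.spec.design.max_category
                )
                or d.spec.design.n_items != d0.spec.design.n_items
            ):
                raise ValueError("dimensions sharing a bank need matching items")

    # theta starting values: standardized logit sum scores
    for d in dims:
        if d.spec.measurement == "manifest":
            d.theta = d.y_obs.copy()
        elif d.n_occ:
            s = d.resp_mat.clip(0).sum(axis=1).astype(float)
            smax = np.where(
                d.resp_mat >= 0, d.spec.design.max_category[None, :], 0
            ).sum(axis=1)
            raw = np.log((s + 0.5) / (smax - s + 0.5))
            sd = raw.std()
            d.theta = (raw - raw.mean()) / (sd if sd > 1e-9 else 1.0)

    mu = np.zeros(D)
    Sigma = np.eye(D)

    st = None
    if struct_spec is not None:
        if struct_data.n_objects != dims[0].N:
            raise ValueError("structural data objects must match dimension 0")
        st = {
            "beta": np.zeros(struct_data.X.shape[1] + struct_data.Dint.shape[1]),
            "gamma": np.zeros(2 + struct_data.W.shape[1]),
            "b0": np.zeros(struct_data.n_objects),
            "vR": 1.0,
            "vU": 1.0,
        }

    a0, b0_rate = priors.precision_shape, priors.precision_rate
    rec: dict[str, list] = {}
    if accum is None:
        accum = {
            "n": 0,
            "theta": [np.zeros(d.n_occ) for d in dims],
            "m_occ": [np.zeros(d.n_occ) for d in dims],
            "vres": [0.0 for _ in dims],
            "alpha": {b: np.zeros_like(banks[b].alpha) for b in banks},
            "delta": {b: np.zeros_like(banks[b].delta) for b in banks},
        }

    def key(i, name):
        return name if D == 1 else f"d{i}.{name}"

    def bkey(b, name):
        return name if len(banks) == 1 else f"bank{b}.{name}"

    for it in range(settings.iterations):
        in_burn = it < settings.burn_in

        # ---- 1. item parameters -------------------------------------------
        for b, bank in banks.items():
            users = [d for d in dims if d.spec.bank == b]
            for d in users:
                if d.ll_rec is None:
                    d.ll_rec = _record_ll(
                        d.theta, d.resp_mat, bank.alpha,
                        bank.cum_delta(bank.delta), _cat_valid(bank),
                    )
            if bank.fixed:
                continue
            K = bank.K
            alpha_p = bank.alpha + bank.scale * rng.standard_normal(K)
            delta_p = bank.delta + np.where(
                bank.valid,
                bank.scale[:, None] * rng.standard_normal(bank.delta.shape),
                0.0,
            )
            lp_cur = bank.log_prior(bank.alpha, bank.delta)
            lp_prop = bank.log_prior(alpha_p, delta_p)
            ll_cur = np.zeros(K)
            ll_prop = np.zeros(K)
            prop_rec = []
            cum_p = bank.cum_delta(np.where(bank.valid, delta_p, 0.0))
            vcats = _cat_valid(bank)
            safe_alpha = np.where(alpha_p > 0, alpha_p, 1.0)
            for d in users:
                ll_cur += d.ll_rec.sum(axis=0)
                lr = _record_ll(d.theta, d.resp_mat, safe_alpha, cum_p, vcats)
                prop_rec.append(lr)
                ll_prop += lr.sum(axis=0)
            log_r = (ll_prop + lp_prop) - (ll_cur + lp_cur)
            accept = np.log(rng.random(K)) < log_r
            if accept.any():
                bank.alpha[accept] = alpha_p[accept]
                bank.delta[accept] = delta_p[accept]
                for d, lr in zip(users, prop_rec):
                    d.ll_rec[:, accept] = lr[:, accept]
            bank.acc += accept
            bank.acc_total += float(accept.mean())
            bank.n_prop += 1
            if in_burn and (it + 1) % _ADAPT_EVERY == 0:
                rate = bank.acc / _ADAPT_EVERY
                bank.scale *= np.exp(
                    np.clip(rate - _TARGET_ACCEPT, -0.5, 0.5)
                    / np.sqrt(1.0 + it / _ADAPT_EVERY)
                )
                bank.acc[:] = 0

        # ---- 2. occasion scores -------------------------------------------
        for d in dims:
            if d.spec.measurement == "manifest" or d.n_occ == 0:
                continue
            bank = banks[d.spec.bank]
            cum = bank.cum_delta(bank.delta)
            vcats = _cat_valid(bank)
            theta_p = d.theta + d.scale * rng.standard_normal(d.n_occ)
            ll_prop_rec = _record_ll(theta_p, d.resp_mat, bank.alpha, cum, vcats)
            vres = d.var[RESIDUAL]
            log_r = (
                ll_prop_rec.sum(axis=1)
                - d.ll_rec.sum(axis=1)
                - 0.5
                * ((theta_p - d.m_occ) ** 2 - (d.theta - d.m_occ) ** 2)
                / vres
            )
            accept = np.log(rng.random(d.n_occ)) < log_r
            d.theta[accept] = theta_p[accept]
            d.ll_rec[accept] = ll_prop_rec[accept]
            d.acc += accept
            d.acc_total += float(accept.mean())
            d.n_prop += 1
            if in_burn and (it + 1) % _ADAPT_EVERY == 0:
                rate = d.acc / _ADAPT_EVERY
                d.scale *= np.exp(
                    np.clip(rate - _TARGET_ACCEPT, -0.5, 0.5)
                    / np.sqrt(1.0 + it / _ADAPT_EVERY)
                )
                d.acc[:] = 0

        # ---- 3. facet effects and their variance components ---------------
        # Random families are kept sum-to-zero by sweeping their mean into
        # the object effects after each draw (a likelihood-invariant move:
        # the occasion means are unchanged).  A free common offset would
        # otherwise random-walk between the families, whose vague sampled
        # variances can absorb it almost for free and blow up; the variance
        # components are then, as in classical ANOVA, variances of centred
        # effects, sampled with the matching n_levels - 1 degrees of
        # freedom (cf. Vines, Gilks & Wild, 1996).
        center_ok = not (latent == "shared" and multi)
        for d in dims:
            vres = d.var[RESIDUAL]
            for fam in d.families:
                e = d.effects[fam.name]
                if d.n_occ:
                    partial = d.m_occ - e[fam.occ_index]
                    resid = d.theta - partial
                    sums = np.bincount(
                        fam.occ_index, weights=resid, minlength=fam.n_levels
                    )
                    counts = np.bincount(fam.occ_index, minlength=fam.n_levels)
                else:
                    partial = d.m_occ
                    sums = np.zeros(fam.n_levels)
                    counts = np.zeros(fam.n_levels)
                prior_prec = 1.0 / d.var[fam.name] if fam.random else 1e-10
                prec = counts / vres + prior_prec
                mean = (sums / vres) / prec
                e_new = mean + rng.standard_normal(fam.n_levels) / np.sqrt(prec)
                dof = fam.n_levels
                if fam.random and center_ok:
                    c = float(e_new.mean())
                    e_new = e_new - c
                    d.e_obj = d.e_obj + c
                    dof -= 1
                else:
                    c = 0.0
                d.effects[fam.name] = e_new
                if d.n_occ:
                    d.m_occ = partial + e_new[fam.occ_index] + c
                if fam.random:
                    ss = float(e_new @ e_new)
                    prec_f = _gamma_prec(
                        rng, a0 + dof / 2.0, b0_rate + 0.5 * ss
                    )
                    d.var[fam.name] = 1.0 / prec_f

        # ---- 4. object effects --------------------------------------------
        if st is not None:
            prec_x, num_x = _structural_object_terms(st, struct_data)
        else:
            prec_x = num_x = None

        if latent == "correlated" and multi:
            _update_objects_correlated(dims, mu, Sigma, prec_x, num_x, rng)
        else:
            groups = [dims] if latent == "shared" else [[d] for d in dims]
            for gi, group in enumerate(groups):
                lead = group[0]
                prec = np.zeros(lead.N)
                num = np.zeros(lead.N)
                for d in group:
                    vres = d.var[RESIDUAL]
                    if d.n_occ:
                        partial = d.m_occ - d.e_obj[d.obj]
                        resid = d.theta - partial
                        prec += np.bincount(d.obj, minlength=d.N) / vres
                        num += (
                            np.bincount(d.obj, weights=resid, minlength=d.N)
                            / vres
                        )
                mu0, v0 = lead.object_prior_moments()
                if gi == 0 and prec_x is not None:
                    prec += prec_x
                    num += num_x
                if v0 == 0.0:
                    e_new = np.full(lead.N, mu0)
                else:
                    prec += 1.0 / v0
                    num += mu0 / v0
                    mean = num / prec
                    e_new = mean + rng.standard_normal(lead.N) / np.sqrt(prec)
                for d in group:
                    delta_e = e_new - d.e_obj
                    if d.n_occ:
                        d.m_occ += delta_e[d.obj]
                    d.e_obj = e_new.copy()
                if lead.sample_object_var:
                    ss = float(e_new @ e_new)
                    prec_o = _gamma_prec(
                        rng, a0 + lead.N / 2.0, b0_rate + 0.5 * ss
                    )
                    for d in group:
                        if d.sample_object_var:
                            d.var[OBJECT] = 1.0 / prec_o

        # ---- 4a. location sweeps ------------------------------------------
        _apply_sweeps(dims, latent, mu, Sigma, rng, banks, prec_x, num_x)

        # ---- 4b. residual variances ---------------------------------------
        for d in dims:
            ss = float(((d.theta - d.m_occ) ** 2).sum()) if d.n_occ else 0.0
            prec_r = _gamma_prec(rng, a0 + d.n_occ / 2.0, b0_rate + 0.5 * ss)
            d.var[RESIDUAL] = 1.0 / prec_r

        # ---- 5. latent mean/covariance (correlated case) ------------------
        if latent == "correlated" and multi:
            E = np.column_stack([d.e_obj for d in dims])
            N = dims[0].N
            Sinv = np.linalg.inv(Sigma)
            prec_mu = N * Sinv + np.eye(D) / priors.coef_var
            mean_mu = np.linalg.solve(prec_mu, Sinv @ E.sum(axis=0))
            Lmu = np.linalg.cholesky(np.linalg.inv(prec_mu))
            mu = mean_mu + Lmu @ rng.standard_normal(D)
            C = E - mu
            scale = priors.wishart_identity_scale * np.eye(D) + C.T @ C
            Sigma = np.atleast_2d(
                stats.invwishart.rvs(df=D + 2 + N, scale=scale, random_state=rng)
            )

        # ---- 6. structural model ------------------------------------------
        if st is not None:
            _update_structural(st, struct_spec, struct_data, dims[0].e_obj,
                               priors, a0, b0_rate, rng)

        # ---- 7. identification transforms (recording only) ----------------
        # The chain itself is softly identified by the object-effect prior
        # centred on the rule's target moments; the exact moment constraint
        # is imposed on every retained draw by an affine transform (with the
        # compensating reparameterization of the item bank whenever the bank
        # is free to absorb it, leaving the likelihood untouched).  Feeding
        # the transform back into the chain state would compose a systematic
        # contraction into the dynamics and make the item parameters drift.
        ident: list[tuple[float, float, float]] = []  # (shift m, scale a, mu)
        for i, d in enumerate(dims):
            if latent == "shared" and i > 0:
                ident.append(ident[0])
                continue
            rule = d.spec.identification
            if rule.rule == "none" or rule.sigma2 == 0.0:
                ident.append((0.0, 1.0, 0.0))
                continue
            src = dims[0].e_obj if latent == "shared" else d.e_obj
            m = float(src.mean())
            s = float(src.std())
            a = float(np.sqrt(rule.sigma2)) / s if s > 1e-12 else 1.0
            ident.append((m, a, rule.mu))

        # ---- 8. record -----------------------------------------------------
        if not in_burn and (it - settings.burn_in) % settings.thin == 0:
            dev = 0.0
            snap: dict[str, np.ndarray] = {}
            for i, d in enumerate(dims):
                m_id, a_id, mu_id = ident[i]

                def tf(x):
                    return mu_id + a_id * (np.asarray(x) - m_id)

                for name, v in d.var.items():
                    if name == OBJECT:
                        snap[key(i, f"vc.{name}")] = v
                    else:
                        snap[key(i, f"vc.{name}")] = a_id * a_id * v
                if OBJECT not in d.var:
                    snap[key(i, "vc.object")] = d.object_variance_value()
                if d.n_occ:
                    counts = np.bincount(d.obj, minlength=d.N).astype(float)
                    sums = np.bincount(d.obj, weights=d.theta, minlength=d.N)
                    with np.errstate(invalid="ignore"):
                        snap[key(i, "S")] = np.where(
                            counts > 0, tf(sums / counts), np.nan
                        )
                    for f in d.crossed:
                        idx = d.occasions[f.name].to_numpy(int)
                        fc = np.bincount(idx, minlength=f.levels).astype(float)
                        fs = np.bincount(
                            idx, weights=d.theta, minlength=f.levels
                        )
                        with np.errstate(invalid="ignore"):
                            snap[key(i, f"facet_means.{f.name}")] = tf(fs / fc)
                if len(d.crossed) == 2:
                    R, T = d.crossed[0].levels, d.crossed[1].levels
                    rho_r, rho_a = _rho_draws(
                        d, R, T, snap[key(i, "vc.object")], a_id * a_id
                    )
                    snap[key(i, "rho2_R")] = rho_r
                    snap[key(i, "rho2_A")] = rho_a
                if store_occasions:
                    snap[key(i, "theta_occ")] = tf(d.theta)
                snap[key(i, "e_object")] = tf(d.e_obj)
                if d.spec.measurement == "gpcm":
                    if d.ll_rec is None:
                        bank = banks[d.spec.bank]
                        d.ll_rec = _record_ll(
                            d.theta, d.resp_mat, bank.alpha,
                            bank.cum_delta(bank.delta), _cat_valid(bank),
                        )
                    dev += -2.0 * float(d.ll_rec.sum())
                elif d.n_occ:
                    vres = d.var[RESIDUAL]
                    r = d.theta - d.m_occ
                    dev += float(
                        len(r) * np.log(2 * np.pi * vres) + (r @ r) / vres
                    )
                accum["theta"][i] += d.theta
                accum["m_occ"][i] += d.m_occ
                accum["vres"][i] += d.var[RESIDUAL]
            for b, bank in banks.items():
                users = [i for i, d in enumerate(dims) if d.spec.bank == b]
                tfs = {ident[i] for i in users}
                if bank.fixed or len(tfs) != 1:
                    # fixed banks must be recorded verbatim; a bank shared by
                    # dimensions with different transforms cannot compensate
                    snap[bkey(b, "alpha")] = bank.alpha.copy()
                    snap[bkey(b, "delta")] = bank.delta.copy()
                else:
                    m_id, a_id, mu_id = next(iter(tfs))
                    snap[bkey(b, "alpha")] = bank.alpha / a_id
                    snap[bkey(b, "delta")] = np.where(
                        bank.valid, mu_id + a_id * (bank.delta - m_id), np.nan
                    )
                accum["alpha"][b] += bank.alpha
                accum["delta"][b] += np.where(bank.valid, bank.delta, 0.0)
            if latent == "correlated" and multi:
                shift = np.array([t[0] for t in ident])
                scl = np.array([t[1] for t in ident])
                mus = np.array([t[2] for t in ident])
                snap["Sigma"] = Sigma * np.outer(scl, scl)
                snap["mu"] = mus + scl * (mu - shift)
            if st is not None:
                m_id, a_id, mu_id = ident[0]
                beta_rec = st["beta"].copy()
                gamma_rec = st["gamma"].copy()
                # reparameterize the latent-predictor terms so they refer to
                # the transformed (recorded) object effects
                off = m_id - mu_id / a_id
                gamma_rec[1] = st["gamma"][1] / a_id
                gamma_rec[0] = st["gamma"][0] + st["gamma"][1] * off
                if struct_data is not None and struct_data.Dint.shape[1]:
                    p1 = struct_data.X.shape[1]
                    for c, name in enumerate(struct_spec.interactions):
                        j = struct_spec.level1.index(name)
                        beta_rec[j] = st["beta"][j] + st["beta"][p1 + c] * off
                        beta_rec[p1 + c] = st["beta"][p1 + c] / a_id
                snap["beta"] = beta_rec
                snap["gamma"] = gamma_rec
                snap["sig2_level1"] = st["vR"]
                snap["sig2_level2"] = st["vU"]
                snap["icc"] = st["vU"] / (st["vR"] + st["vU"])
            snap["deviance"] = dev
            accum["n"] += 1
            for k2, v2 in snap.items():
                rec.setdefault(k2, []).append(v2)

    chain_draws = {k2: np.asarray(v2) for k2, v2 in rec.items()}
    acceptance = {}
    for i, d in enumerate(dims):
        if d.n_prop:
            acceptance[key(i, "occasions")] = d.acc_total / d.n_prop
    for b, bank in banks.items():
        if bank.n_prop:
            acceptance[bkey(b, "items")] = bank.acc_total / bank.n_prop
    return chain_draws, accum, acceptance


def _cat_valid(bank: _BankState) -> np.ndarray:
    M = bank.delta.shape[1]
    return np.arange(M + 1)[None, :] <= bank.n_steps[:, None]


def _rho_draws(
    d: _DimState, R: int, T: int, v_obj: float, scale2: float
) -> tuple[float, float]:
    """Within-iteration reliability/agreement on the recorded (identified)
    scale: ``v_obj`` is the recorded object variance and ``scale2`` the
    squared affine factor applied to the nuisance components."""
    f1, f2 = d.crossed[0].name, d.crossed[1].name
    den_rel = (
        v_obj
        + scale2 * d.var.get(f"object:{f1}", 0.0) / R
        + scale2 * d.var.get(f"object:{f2}", 0.0) / T
        + scale2 * d.var[RESIDUAL] / (R * T)
    )
    den_agr = (
        den_rel
        + scale2 * d.var.get(f1, 0.0) / R
        + scale2 * d.var.get(f2, 0.0) / T
        + scale2 * d.var.get(f"{f1}:{f2}", 0.0) / (R * T)
    )
    return v_obj / den_rel, v_obj / den_agr


def _apply_sweeps(
    dims, latent, mu, Sigma, rng, banks, prec_x=None, num_x=None
) -> None:
    """Gibbs updates of the likelihood-null offset directions.

    Each sweep draws an offset from its exact full conditional (a normal
    combining the two families' priors) and moves it between the families;
    occasion scores are invariant, so the likelihood never enters.  Under a
    shared object effect, moves into the object family would change the
    other dimensions' scores, so they are skipped there.

    A second group of sweeps handles the score-versus-threshold location:
    shifting every occasion score and every threshold of the dimension's
    bank by the same offset (theta - u, delta - u) leaves the partial
    credit likelihood exactly unchanged, so that direction too is informed
    by priors alone.  Pairing it in turn with each effect family (and with
    the object effects and residuals) keeps the threshold location anchored
    at its prior without parking a compensating offset in one of the small
    effect families, whose sampled variance it would otherwise inflate.
    These sweeps require a bank that is actually sampled and serves a
    single dimension, and are skipped otherwise.
    """
    multi = len(dims) > 1
    correlated = latent == "correlated" and multi
    if correlated:
        Sinv = np.linalg.inv(Sigma)
    for i, d in enumerate(dims):
        allow_obj = not (latent == "shared" and multi)
        if correlated:
            obj_prec = float(Sinv[i, i])
            E = np.column_stack([x.e_obj for x in dims])
            grad = (E - mu) @ Sinv[:, i]
        else:
            mu0, v0 = d.object_prior_moments()
            if v0 == 0.0:
                allow_obj = False
                obj_prec, grad = 0.0, None
            else:
                obj_prec = 1.0 / v0
                grad = (d.e_obj - mu0) * obj_prec
        # The structural model observes dimension 0's object effects, so any
        # sweep that moves e_obj must include its Gaussian terms; otherwise
        # the sweep parks facet-interaction noise in the structural predictor
        # and attenuates the latent regression slope.
        if i == 0 and prec_x is not None and grad is not None:
            obj_prec = obj_prec + prec_x
            grad = grad + prec_x * d.e_obj - num_x
        fams = {f.name: f for f in d.families}
        for sw in d.sweeps:
            kind, name = sw[0], sw[1]
            vA = d.var.get(name)
            if vA is None or vA <= 0:
                continue
            eA = d.effects[name]
            if kind == "obj_vector":
                if not allow_obj:
                    continue
                parent = sw[2]
                mask = parent >= 0
                nb = np.bincount(parent[mask], minlength=d.N)
                sums = np.bincount(
                    parent[mask], weights=eA[mask], minlength=d.N
                )
                prec = nb / vA + obj_prec
                num = sums / vA - grad
                u = num / prec + rng.standard_normal(d.N) / np.sqrt(prec)
                eA = eA.copy()
                eA[mask] -= u[parent[mask]]
                d.effects[name] = eA
                d.e_obj = d.e_obj + u
                grad = grad + u * obj_prec
            else:  # fam_vector
                target, gidx = sw[2], sw[3]
                tfam = fams[target]
                vB = d.var.get(target)
                precB = 1.0 / vB if (vB and tfam.random) else 1e-10
                eB = d.effects[target]
                nb = np.bincount(gidx, minlength=tfam.n_levels)
                sums = np.bincount(gidx, weights=eA, minlength=tfam.n_levels)
                prec = nb / vA + precB
                num = sums / vA - eB * precB
                u = num / prec + rng.standard_normal(tfam.n_levels) / np.sqrt(
                    prec
                )
                d.effects[name] = eA - u[gidx]
                d.effects[target] = eB + u

        # ---- bank-location sweeps -----------------------------------------
        if d.spec.measurement != "gpcm":
            continue
        bank = banks.get(d.spec.bank)
        n_users = sum(
            1
            for x in dims
            if x.spec.measurement == "gpcm" and x.spec.bank == d.spec.bank
        )
        if bank is None or bank.fixed or n_users != 1:
            continue
        pv = bank.delta_prior_var
        nthr = float(bank.valid.sum())
        hosts = [("resid", None)]
        if allow_obj and np.all(np.asarray(obj_prec) > 0.0):
            hosts.append(("obj", None))
        for hkind, _ in hosts:
            dsum = float(np.nansum(bank.delta - bank.delta_prior_mean))
            prec = nthr / pv
            num = dsum / pv
            if hkind == "resid":
                vres = d.var[RESIDUAL]
                prec += d.n_occ / vres
                num += float((d.theta - d.m_occ).sum()) / vres
            else:  # obj
                prec += float(np.sum(obj_prec * np.ones(d.N)))
                num += float(grad.sum())
            u = num / prec + rng.standard_normal() / np.sqrt(prec)
            bank.delta[bank.valid] -= u
            d.theta -= u
            if hkind == "obj":
                d.e_obj = d.e_obj - u
                d.m_occ -= u
                grad = grad - u * obj_prec
            # resid: m_occ unchanged, the offset lands in the residuals
        d.ll_rec = None  # theta and delta moved; cache is stale


def _structural_object_terms(st, data: MultilevelData):
    """Gaussian contributions of the structural layer to each theta_j."""
    N = data.n_objects
    p1 = data.X.shape[1]
    beta_main = st["beta"][:p1]
    beta_int = st["beta"][p1:]
    gamma = st["gamma"]
    prec = np.zeros(N)
    num = np.zeros(N)
    # level 2: b0_j ~ N(g0 + g1 theta_j + W gW, vU)
    g1 = gamma[1]
    base = gamma[0] + data.W @ gamma[2:]
    prec += g1 * g1 / st["vU"]
    num += g1 * (st["b0"] - base) / st["vU"]
    # level 1: y - (b0 + X beta) = (Dint beta_int) * theta_j + R
    if beta_int.size:
        a_unit = data.Dint @ beta_int
        resid = data.y - data.X @ beta_main - st["b0"][data.obj]
        prec += np.bincount(data.obj, weights=a_unit**2, minlength=N) / st["vR"]
        num += (
            np.bincount(data.obj, weights=a_unit * resid, minlength=N)
            / st["vR"]
        )
    return prec, num


def _update_structural(st, spec, data, theta, priors, a0, b0_rate, rng):
    N = data.n_objects
    X1, Z2 = level_predictor_matrix(spec, data, theta)
    p = X1.shape[1]
    r = data.y - st["b0"][data.obj]
    if p:
        prec = X1.T @ X1 / st["vR"] + np.eye(p) / priors.coef_var
        mean = np.linalg.solve(prec, X1.T @ r / st["vR"])
        L = np.linalg.cholesky(np.linalg.inv(prec))
        st["beta"] = mean + L @ rng.standard_normal(p)
    r2 = data.y - X1 @ st["beta"]
    counts = np.bincount(data.obj, minlength=N).astype(float)
    sums = np.bincount(data.obj, weights=r2, minlength=N)
    mu_b = Z2 @ st["gamma"]
    prec_b = counts / st["vR"] + 1.0 / st["vU"]
    mean_b = (sums / st["vR"] + mu_b / st["vU"]) / prec_b
    st["b0"] = mean_b + rng.standard_normal(N) / np.sqrt(prec_b)
    q = Z2.shape[1]
    prec_g = Z2.T @ Z2 / st["vU"] + np.eye(q) / priors.coef_var
    mean_g = np.linalg.solve(prec_g, Z2.T @ st["b0"] / st["vU"])
    Lg = np.linalg.cholesky(np.linalg.inv(prec_g))
    st["gamma"] = mean_g + Lg @ rng.standard_normal(q)
    e1 = data.y - X1 @ st["beta"] - st["b0"][data.obj]
    st["vR"] = 1.0 / _gamma_prec(rng, a0 + len(e1) / 2.0, b0_rate + 0.5 * e1 @ e1)
    e2 = st["b0"] - Z2 @ st["gamma"]
    st["vU"] = 1.0 / _gamma_prec(rng, a0 + N / 2.0, b0_rate + 0.5 * e2 @ e2)


def _update_objects_correlated(dims, mu, Sigma, prec_x, num_x, rng):
    D = len(dims)
    N = dims[0].N
    Lam0 = np.linalg.inv(Sigma)
    A = np.tile(Lam0, (N, 1, 1))
    b = np.tile(Lam0 @ mu, (N, 1))
    for i, d in enumerate(dims):
        vres = d.var[RESIDUAL]
        if d.n_occ:
            partial = d.m_occ - d.e_obj[d.obj]
            resid = d.theta - partial
            A[:, i, i] += np.bincount(d.obj, minlength=N) / vres
            b[:, i] += np.bincount(d.obj, weights=resid, minlength=N) / vres
    if prec_x is not None:
        A[:, 0, 0] += prec_x
        b[:, 0] += num_x
    mean = np.linalg.solve(A, b[:, :, None])[:, :, 0]
    L = np.linalg.cholesky(A)
    z = rng.standard_normal((N, D, 1))
    noise = np.linalg.solve(np.transpose(L, (0, 2, 1)), z)[:, :, 0]
    E = mean + noise
    for i, d in enumerate(dims):
        delta_e = E[:, i] - d.e_obj
        if d.n_occ:
            d.m_occ += delta_e[d.obj]
        d.e_obj = E[:, i].copy()


def _deviance_at_mean(dimensions, accum) -> float:
    n = max(1, accum["n"])
    dev = 0.0
    for i, spec in enumerate(dimensions):
        if spec.measurement == "gpcm":
            keys, occ_of_row = spec.table.occasion_index()
            resp_mat = np.full((len(keys), spec.design.n_items), -1, dtype=int)
            if len(keys):
                resp_mat[occ_of_row, spec.table.items] = spec.table.responses
            b = spec.bank
            alpha = accum["alpha"][b] / n
            delta = accum["delta"][b] / n
            nst = spec.design.max_category
            M = delta.shape[1]
            valid_cat = np.arange(M + 1)[None, :] <= nst[:, None]
            cum = np.zeros((len(alpha), M + 1))
            cum[:, 1:] = np.cumsum(delta, axis=1)
            theta = accum["theta"][i] / n
            ll = _record_ll(theta, resp_mat, alpha, cum, valid_cat)
            dev += -2.0 * float(ll.sum())
        else:
            theta = accum["theta"][i] / n
            m_occ = accum["m_occ"][i] / n
            vres = accum["vres"][i] / n
            r = theta - m_occ
            if len(r):
                dev += float(len(r) * np.log(2 * np.pi * vres) + (r @ r) / vres)
    return dev


# ---------------------------------------------------------------------------
# diagnostics and model comparison


def diagnostics(draws: PosteriorDraws, names: list[str] | None = None) -> pd.DataFrame:
    """Split R-hat and effective sample size per scalar parameter element.

    With a single chain the retained draws are split in half; with multiple
    chains the stored chain structure is used.
    """
    import arviz as az

    chains = draws.meta["chains"]
    n_per = draws.meta["n_per_chain"]
    if chains * n_per < 8:
        raise ValueError("too few retained draws for convergence diagnostics")
    rows = []
    for name in names or draws.names:
        arr = draws.draws[name].reshape(draws.n_draws, -1)
        for j in range(arr.shape[1]):
            col = arr[:, j]
            if np.isnan(col).any():
                continue
            if chains == 1:
                half = len(col) // 2
                mat = np.stack([col[:half], col[half : 2 * half]])
            else:
                mat = col.reshape(chains, n_per)
            label = name if arr.shape[1] == 1 else f"{name}[{j}]"
            rows.append(
                {
                    "parameter": label,
                    "rhat": float(az.rhat(mat)),
                    "ess": float(az.ess(mat)),
                }
            )
    return pd.DataFrame(rows)


def plot_traces(draws: PosteriorDraws, names: list[str], path) -> None:
    """Export trace plots for the named parameters (first element each)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(
        len(names), 1, figsize=(8, 2.2 * len(names)), squeeze=False
    )
    for ax, name in zip(axes[:, 0], names):
        arr = draws.draws[name].reshape(draws.n_draws, -1)
        ax.plot(arr[:, 0], lw=0.5)
        ax.set_ylabel(name)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def dic(draws: PosteriorDraws) -> tuple[float, float, float]:
    """Conditional-likelihood deviance information criterion.

    Returns ``(DIC, pD, mean deviance)`` with Dbar the posterior mean of the
    conditional deviance -2 log p(y | draw), ``pD = Dbar - D(posterior
    means)`` and ``DIC = Dbar + pD``.  Smaller is better.
    """
    dev = draws["deviance"]
    if not np.all(np.isfinite(dev)):
        bad = int(np.flatnonzero(~np.isfinite(dev))[0])
        raise ValueError(f"non-finite deviance at retained draw {bad}")
    dbar = float(dev.mean())
    dhat = float(draws.meta["deviance_at_mean"])
    pd_eff = dbar - dhat
    return dbar + pd_eff, pd_eff, dbar
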