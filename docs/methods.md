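# Methods

This note records the statistical model implemented by `gtirt`, the prior
choices, the sampler design, and the deliberate deviations or caveats a
user should know about.

## 1. Model

### 1.1 Measurement layer (GPCM)

Each measurement occasion *i* (an object observed under a combination of
facet levels, e.g. teacher × rater × time-point) yields polytomous
responses to *K* items. Responses follow Muraki's generalized partial
credit model with occasion score θᵢ:

```
P(X_ik = m | θ_i) ∝ exp( Σ_{h=1..m} α_k (θ_i − δ_kh) ),   m = 0..M_k
```

with the empty sum for m = 0. Items may have different numbers of
categories; threshold arrays are NaN-padded internally. A *manifest*
measurement mode replaces the GPCM by observed occasion scores with a
normal error term, which is used for G-theory-only analyses and for
conjugate validation of the sampler.

### 1.2 Generalizability-theory layer

The occasion score decomposes additively into variance components defined
by the measurement design. For the fully crossed two-facet design
(object × rater × time):

```
θ_jrt = e_j + e_r + e_t + e_jr + e_jt + e_rt + ε_jrt
```

with each effect family mean-zero normal with its own variance. Nested
designs (facet levels nested in objects) drop the confounded families;
repeated facets (fixed occasions of observation, e.g. survey waves)
contribute no random families beyond object and residual. Effects are of
kind *random* (variance sampled) or *fixed* (variance pinned).

### 1.3 Structural layer

Object-level latent scores e_j enter a two-level linear model:

```
level 1:  y_ij = b_0j + X_ij β + (D_ij β_int) e_j + r_ij,     r ~ N(0, σ²_R)
level 2:  b_0j = γ_0 + γ_1 e_j + W_j γ_W + u_j,               u ~ N(0, σ²_U)
```

so the latent G-theory universe score acts as a level-2 predictor (and
optionally moderates level-1 slopes through cross-level interactions).
Because e_j is estimated concurrently with its measurement error, the
slope γ₁ is *disattenuated* relative to regressions on manifest mean
scores, whose expected attenuation factor is exactly the Eq.-6
reliability of the mean score.

### 1.4 Generalizability coefficients

From variance components (plug-in values or per-draw posterior samples):

```
ρ²_R(R,T) = σ²_obj / ( σ²_obj + σ²_o:r/R + σ²_o:t/T + σ²_res/(RT) )
ρ²_A(R,T) = σ²_obj / ( ρ²_R denominator + σ²_r/R + σ²_t/T + σ²_rt/(RT) )
```

(relative/reliability and absolute/agreement). D-studies evaluate these
per retained draw over a grid of (R, T) and report posterior medians and
central 95% bounds. `solve_error_variance` inverts ρ²_R for the residual
component, which the disattenuation and power utilities use to engineer a
target manifest reliability.

## 2. Priors

- Discriminations: α_k ~ N(1, 1) truncated to α > 0 (via rejection in the
  Metropolis proposal's support).
- Thresholds: δ_kh ~ N(h, 1) by category index; an empirical-Bayes mode
  re-centres this prior at supplied estimates with variance 10.
- All precisions (family, object, residual, structural): Gamma(0.01, 0.01)
  (shape/rate), i.e. a vague prior on the variance scale.
- Regression coefficients (β, γ): N(0, 100).
- Correlated multi-dimensional object effects: inverse-Wishart with
  identity scale and dimension-plus-two degrees of freedom.

Caveat: the by-category threshold prior mean sits 2–3 SD above thresholds
typical of real instruments (fitted averages near −1.8..0.4). With very
small designs the genuine posterior trades this prior pull into inflated
residual and facet variances. The remedies offered are the
empirical-Bayes mode and identification to known moments; both are plain
arguments to `fit`.

## 3. Sampler

A single-site Metropolis-within-Gibbs chain:

1. occasion scores θᵢ: random-walk Metropolis against the GPCM likelihood
   plus the GT-layer normal;
2. item parameters (concurrent/EB modes): random-walk Metropolis per item;
3. effect families: conjugate normal updates given partial residuals,
   then conjugate Gamma precision updates;
4. object effects: conjugate normal combining the GT layer, the object
   prior, and (dimension 0) the structural layer's Gaussian terms;
5. structural coefficients and variances: conjugate updates in the order
   β → γ₀(b₀) → γ → σ²_R → σ²_U, with b₀ sampled per object;
6. latent mean/covariance for correlated multi-dimensional fits.

### 3.1 Hierarchical centring sweeps

The additive decomposition has likelihood-null directions (a constant can
move between a family and the object effects without changing any θᵢ).
These directions mix poorly under single-site Gibbs, so the sampler adds
exact *sweep* updates: for each such direction the offset's full
conditional involves only the two priors and is sampled in closed form.
Sweeps cover (a) family means into the object effects, (b) per-object
means of object×facet families into the object effects, (c) margins
between facet families, and (d) the score-versus-threshold location
(θ − u, δ − u leaves the GPCM likelihood invariant), paired alternately
with the residuals and the object effects.

Two implementation details matter for correctness:

- When a structural model is attached, the object effects appear in an
  additional likelihood. Every sweep that moves e_obj therefore folds the
  structural layer's Gaussian terms into its conditional. Omitting them
  leaves the chain stationary at an attenuated slope (the sweep re-injects
  facet-interaction noise into the structural predictor each iteration;
  the attenuation factor is approximately 1/(1 + σ²_o:r/R + σ²_o:t/T)).
- Precision draws from Gamma(0.01, ·) underflow to exactly zero about
  once per thousand draws when the data contribution is empty; all
  precision draws are floored at the smallest positive normal float.

### 3.2 Identification

The latent scale is identified *at recording time*, not in the chain. The
chain runs with proper priors only; each retained draw is passed through
an affine transform chosen by the identification rule
(`fix_object_variance`: object-effect sample mean 0 and variance 1;
`fix_plugin_moments`: match supplied moments; `none`: record verbatim).
Variance components scale by a², occasion/object scores map affinely, the
structural slope divides by a, and a sampled single-dimension item bank is
compensated (δ′ = μ + a(δ − m), α′ = α/a) so recorded item parameters sit
on the recorded latent scale. This keeps every recorded draw exactly on
the reported scale while the chain itself remains a correct sampler for
the (soft-prior) posterior.

Consequence for synthetic-truth comparisons: recorded components are
relative to the *realized* sample variance of the generated object
effects, which for small object counts is visibly χ²-noisy. Recovery
checks either use designs where this is negligible or rescale the truth
by the realized variance.

### 3.3 Model comparison and diagnostics

`dic` reports the conditional DIC (D̄, p_D, DIC) using the deviance of the
measurement layer at the recorded draws and at accumulated posterior
means. Conditional DIC discriminates latent dimensionality only weakly at
small scale, because free occasion scores absorb misfit into the residual
variance; comparisons need informative measurement (high discrimination,
small residual) and reasonably long chains. `diagnostics` reports split-R̂
and effective sample size per recorded scalar (via ArviZ), splitting a
single chain in half when only one chain is run.

## 4. Synthetic generation

`generate` simulates from the exact model: effects per family, occasion
scores, GPCM responses, and optionally the two-level structural outcome.
Presets reproduce published design shapes: a 34 × 4 × 6 classroom
observation design with 10 four-category items (816 occasions, 8,160
responses); a two-group survey design with 9 partially observed objects
(432 occasion patterns, 953 level-1 units) with a structural layer; and a
three-dimension correlated design mixing crossed, nested and repeated
facets. `augment` replicates observed facet patterns for planned-missing
designs; `reliability_power_study` re-solves the residual component for a
target reliability, regenerates and refits, and reports the fraction of
replicates whose 95% interval for γ₁ excludes zero.

## 5. Known limitations

- Runtime is tuned for desk-scale designs (hundreds of occasions, tens of
  items); chains are held in memory.
- The conditional DIC caveat above: dimensionality comparisons at low
  measurement information are unreliable.
- Identification-at-recording means the *chain-scale* parameters are not
  interpretable; always read recorded draws.
- Nested designs require an explicit occasion roster; there is no
  automatic balancing.
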