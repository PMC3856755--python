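# Methods

This note documents the models implemented in `trophicsdm`, the choices
made where the design was genuinely open, and what the synthetic studies
do and do not demonstrate.

## The latent-trait link model

The probability of a trophic link between plant *i* and butterfly *j* is

    logit P_ij = α + β₁ N_i + β₂ AvH_i + δ₁ v_i⁽¹⁾ f_j⁽¹⁾ + δ₂ v_i⁽²⁾ f_j⁽²⁾

with measured plant traits (leaf nitrogen, % dry mass; average height) and
two latent-trait dimensions per species. Trait columns are z-scored before
fitting, so the reported slopes are per standard deviation of the trait;
the scaler is stored with the fitted parameters and re-applied at
prediction time. The likelihood is the Bernoulli product over knowable
cells only — pairs that co-occur at least once (`z_ij = 1`). All Bernoulli
terms are evaluated on the logit scale (`a·η − log(1+e^η)`), so the
log-likelihood is finite for any finite parameters; probabilities are never
clipped inside the likelihood.

### Identifiability and priors

The likelihood is invariant to (a) rescaling latents against δ, (b)
jointly flipping the sign of both latent vectors of a dimension, and (c)
permuting the two latent dimensions. These are resolved by:

* standard-normal priors on all latent traits (fixes the scale);
* the ordering constraint δ₁ ≥ δ₂ ≥ 0, enforced through a half-normal
  (sd 10) prior that is −∞ outside the cone (resolves label switching);
* post-hoc sign alignment of every retained sample to the first retained
  sample, per dimension, by the sign of the inner product of plant
  latents (makes posterior-mean latents meaningful for the downstream
  phylogenetic regression).

α and β get normal(0, 10²) priors: weakly informative on the logit scale.

### Sampler

Block-wise Gaussian random-walk Metropolis–Hastings with four blocks:
(α, β₁, β₂) jointly; (δ₁, δ₂) jointly; plant latent pairs; butterfly
latent pairs. Given the other guild's latents and the global parameters,
the posterior factorizes over plants (rows) and over butterflies
(columns), so the per-species updates are proposed for all species of a
guild at once and accepted/rejected independently — a vectorized
Metropolis-within-Gibbs sweep with the same stationary distribution as
sequential per-species blocks, an order of magnitude faster in practice.
Default proposal scales (0.05 linear, 0.10 δ, 0.25 latent) are adapted
toward ~30% acceptance during burn-in only, so the retained chain is
Markovian. Defaults: 20 000 iterations, half discarded as burn-in,
thinning 10. Chains are bit-reproducible from the seed.

Two point summaries are exposed: the posterior-mean parameter vector
(after alignment), used for phylogenetic extrapolation and export, and the
posterior-mean link matrix (per-sample probabilities averaged), which is
the Bayes estimate of each P_ij and invariant to sign flips by
construction.

On very small webs (of order 150 cells against ~60 parameters) the
posterior is diffuse and posterior means of δ and β can drift high as the
likelihood rewards saturated fits; this is a property of the model at that
data size, not of the sampler. Recovery is reliable from a few hundred
knowable cells upward (r ≳ 0.9 between true and posterior-mean
probabilities at 1200 cells).

## Phylogenetic signal and imputation

Shared-time fractions `t_ij` are the root-to-MRCA depth divided by tree
depth on the input ultrametric tree (verified to relative tolerance 1e-6;
trees are not rescaled, and non-ultrametric input is refused rather than
silently normalized). Each latent dimension of each guild is modelled
independently as y ~ N(μ·1, C(λ)) with `C(λ)` having diagonal σ² and
off-diagonal σ²·λ·t_ij — an intercept-only phylogenetic regression, since
phylogeny is the only predictor of latent traits. (μ, σ²) have closed-form
GLS/ML solutions at fixed λ; λ is maximized by an 11-point grid pre-scan
plus bounded refinement (tolerance 1e-4), which matches a dense-grid
search to 1e-2 on random instances.

Signal is tested with the likelihood-ratio statistic 2(ℓ(λ̂) − ℓ(0))
against the 50:50 mixture of a point mass at zero and χ²₁ — the correct
null when λ = 0 lies on the parameter boundary.

Species without recorded interactions get each latent trait from the
conditional expectation μ + C_xo C_oo⁻¹ (y_obs − μ) at the fitted (σ², λ).
Imputation is performed from posterior-mean latents; per-sample imputation
(propagating posterior uncertainty) is possible by looping the same
functions over retained samples, but the default pipeline uses the point
estimates.

λ̂ estimated from posterior-mean latents is attenuated relative to the
generating λ, because posterior means are shrunken, noisy versions of the
true latents; the attenuation is strongest for the weaker second dimension
(δ₂ < δ₁) and for small webs. This mirrors the errors-in-variables bias
any two-stage pipeline incurs.

## Species distribution models

Abiotic predictors are growing degree-days (ddeg), moisture index (mind,
precipitation minus potential evapotranspiration) and solar radiation
(srad), z-scored on the training sites (re-fit per cross-validation fold).
Model forms per technique:

* **glm** — binomial GLM with linear + quadratic terms of the three
  standardized variables (quadratic terms give the unimodal responses
  expected along elevation gradients);
* **gam** — binomial regression splines: cubic B-spline bases (4 df per
  variable, fixed knots over ±2 sd with linear extrapolation outside);
* **gbm** — gradient boosting (100 trees, depth 3, learning rate 0.1);
* **rf** — random forest (200 trees); tree models use the raw
  (standardized linear) variables.

Hyperparameters are fixed, documented defaults; no tuning is performed.
Constant predictor columns are dropped with a warning; species with fewer
than 10 presences are refused.

The biotic predictors are: the **literature term** (1 iff any known host
plant is present at the site) and the **trophic term** — the maximum
modelled link probability between the focal butterfly and the plants
present at the site, with the empty-site maximum defined as 0 ("no host
available" is the worst case for an herbivore).

Cross-validation is stratified tenfold (plain shuffled folds when
stratification is infeasible, e.g. leave-one-out); the fold assignment
depends only on the presence vector, fold count and seed, so it is shared
across predictor sets and techniques, giving exactly paired out-of-fold
site sets.

## Community stacking and evaluation

Site communities are assembled threshold-independently: predicted richness
is round(Σ p) (half rounds up) and the community is that many top-ranked
species, ties broken by species id. A probabilistic resampling variant
(one seeded Bernoulli draw per species) is available behind a flag; the
deterministic rule is the default because it is reproducible and testable.
Evaluation: Sørensen index 2a/(2a+b+c) (defined as 1 when both sets are
empty), richness residuals (sign convention: predicted − observed),
rank-based AUC with ties counted 0.5, paired Wilcoxon signed-rank tests
(V = sum of positive-difference ranks; zero differences dropped; exact p
for ≤ 25 tie-free differences, otherwise normal approximation with
continuity correction; two-sided), and a Kruskal–Wallis test across
butterfly families for food-web predictive performance.

## The synthetic-data generator

Trees are pure-birth (Yule) with depth normalized to 1. Latent traits are
single draws from N(0, C(λ)) on each tree (default λ = 0.8 per
dimension). Measured traits: nitrogen ~ N(2.5, 0.7) % dry mass, height
lognormal (median ≈ 0.3 m). The web is drawn cell-wise from the link model
(defaults α = −1, β = (1, 0.5), δ = (2, 1)).

Sites sit on a latent elevation-like gradient driving ddeg (negatively),
mind (positively) and weakly srad, each with independent noise. Every
species has a unimodal (Gaussian-on-the-gradient) occupancy niche with a
random optimum and width; the intercept is calibrated by bisection so that
the species' expected prevalence matches a target drawn from a configured
range — for butterflies the calibration includes the trophic coupling
γ · T_k (T_k = maximum true link probability with the plants realized at
site k), so prevalences are comparable across γ. The observed web handed
to fitting is masked by realized co-occurrence, emulating field studies in
which many pairs are never observed together.

What the generator does **not** emulate: spatial autocorrelation of
environments or occupancy, imperfect detection, quantitative interaction
strengths, environment-dependent link probabilities, and the empirical
dimensions or prevalences of any particular field system. Passing tests
therefore demonstrate statistical correctness and qualitative behaviour of
the methods, not predictive skill on real communities.

A consequence worth knowing: the trophic term only carries spatial
information when host availability varies between sites. If most plants
occur almost everywhere, the per-species maximum saturates and both the
generative coupling and the predictor become uninformative — adding the
term then changes nothing, regardless of method. The reproduction script
therefore uses a scarce-host, high-turnover configuration (50 plants at
5–20% per-species occupancy, 192 sites), which is also the regime where
combining food-web and distribution models is ecologically motivated in
the first place.

## Problem sizes and numerical choices

Test-suite simulations use webs up to 30×40 with 20 000 MCMC iterations,
200-tip trees for λ recovery (20 replicates per setting), and 150-site
studies with 30 butterfly species for the end-to-end comparisons; the
reproduction script runs a 50×40×192 study. These sizes were chosen so
each recovery quantity is estimated with useful precision while the whole
suite stays desk-scale. Cholesky factorizations back all GLS and kriging
solves (singular covariances are reported as errors, not patched);
the λ optimizer tolerance is 1e-4; MCMC proposal adaptation is clipped to
[1e-4, 5].

## Known limitations

* Two-stage extrapolation (posterior means → λ regression → kriging)
  ignores posterior uncertainty in the latents and attenuates λ̂.
* The λ-model fits each latent dimension independently; cross-dimension
  phylogenetic covariance is not modelled.
* The GAM variant uses fixed-df regression splines rather than
  penalized smoothing with automatic smoothness selection.
* Only bottom-up (host → herbivore) constraints are represented; no
  predator links, no environment-dependent link probabilities.
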