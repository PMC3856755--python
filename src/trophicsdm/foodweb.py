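"""Latent-trait logistic model of bipartite trophic links.

The probability that herbivore (butterfly larva) ``j`` feeds on plant ``i``
is modelled on the logit scale as

    logit P_ij = alpha + beta1 * N_i + beta2 * AvH_i
                 + delta1 * v_i1 * f_j1 + delta2 * v_i2 * f_j2

where ``N_i`` is leaf nitrogen content and ``AvH_i`` average canopy height
of the plant, and ``(v_i1, v_i2)`` / ``(f_j1, f_j2)`` are per-species latent
traits capturing plant susceptibility and herbivore foraging preference
beyond the measured traits.  The link matrix is only partially observable:
a pair's link status is knowable only where the two species co-occur at
least once, so the Bernoulli likelihood runs over cells with mask
``z_ij = 1`` and masked cells carry no information.

Inference is Bayesian, by block-wise random-walk Metropolis-Hastings over
the intercept/slopes, the scaling factors ``delta``, and each species'
latent-trait pair.  Latent traits get standard-normal priors (fixing the
scale non-identifiability against ``delta``); ``delta1 >= delta2 >= 0``
resolves label switching between the two latent dimensions, and a post-hoc
sign alignment resolves the joint sign flip that leaves every P_ij
unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrophicWeb",
    "PlantTraits",
    "LinkModelParams",
    "PriorConfig",
    "McmcConfig",
    "PosteriorChain",
    "LinkProbabilityMatrix",
    "link_probability",
    "log_likelihood",
    "log_prior",
    "log_posterior",
    "fit_mcmc",
    "predict_link_matrix",
    "compute_cooccurrence_mask",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


def _as_binary(arr, name: str) -> np.ndarray:
    a = np.asarray(arr)
    if not np.isin(a, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 entries")
    return a.astype(np.int8)


@dataclass
class TrophicWeb:
    """Binary plant x butterfly interaction matrix with a knowability mask.

    ``links[i, j] = 1`` if butterfly j was recorded feeding (as a
    caterpillar) on plant i; ``mask[i, j] = 1`` if the pair co-occurs at
    least once so its link status is knowable.  Cells with ``mask == 0``
    never contribute to any likelihood.
    """

    plant_ids: list
    butterfly_ids: list
    links: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        self.plant_ids = list(self.plant_ids)
        self.butterfly_ids = list(self.butterfly_ids)
        self.links = _as_binary(self.links, "links")
        self.mask = _as_binary(self.mask, "mask")
        shape = (len(self.plant_ids), len(self.butterfly_ids))
        if self.links.shape != shape or self.mask.shape != shape:
            raise ValueError(
                f"links {self.links.shape} and mask {self.mask.shape} must both be {shape}"
            )

    @property
    def n_plants(self) -> int:
        return len(self.plant_ids)

    @property
    def n_butterflies(self) -> int:
        return len(self.butterfly_ids)

    @property
    def n_knowable(self) -> int:
        return int(self.mask.sum())


@dataclass
class PlantTraits:
    """Measured plant traits: leaf nitrogen (% dry mass) and average height."""

    frame: pd.DataFrame  # index = species, columns nitrogen, avg_height

    def __post_init__(self):
        missing = {"nitrogen", "avg_height"} - set(self.frame.columns)
        if missing:
            raise ValueError(f"trait table missing columns: {sorted(missing)}")
        vals = self.frame[["nitrogen", "avg_height"]].to_numpy(float)
        if not np.isfinite(vals).all():
            raise ValueError("non-finite plant trait values")

    def values_for(self, plant_ids: Sequence) -> np.ndarray:
        """(n, 2) array of [nitrogen, avg_height] rows aligned to plant_ids."""
        missing = [p for p in plant_ids if p not in self.frame.index]
        if missing:
            raise KeyError(f"plants missing from trait table: {missing}")
        return self.frame.loc[list(plant_ids), ["nitrogen", "avg_height"]].to_numpy(float)


@dataclass
class LinkModelParams:
    """Full parameter vector of the link model.

    Latent-trait tables are indexed by species and may carry a
    ``provenance`` column (``fitted`` or ``imputed``).  ``trait_center`` /
    ``trait_scale`` record the z-scoring applied to measured traits during
    fitting; when present they are re-applied at prediction time.
    """

    alpha: float
    beta_nitrogen: float
    beta_height: float
    delta: tuple
    plant_latents: pd.DataFrame  # columns v1, v2 [, provenance]
    butterfly_latents: pd.DataFrame  # columns f1, f2 [, provenance]
    trait_center: np.ndarray | None = None
    trait_scale: np.ndarray | None = None

    def __post_init__(self):
        d1, d2 = self.delta
        if not (np.isfinite(d1) and np.isfinite(d2)):
            raise ValueError("delta must be finite")
        if not (d1 >= d2 >= 0):
            raise ValueError(f"identifiability requires delta1 >= delta2 >= 0, got {self.delta}")

    def latent_arrays(self, plant_ids: Sequence, butterfly_ids: Sequence):
        for ids, table, cols, guild in (
            (plant_ids, self.plant_latents, ["v1", "v2"], "plant"),
            (butterfly_ids, self.butterfly_latents, ["f1", "f2"], "butterfly"),
        ):
            missing = [s for s in ids if s not in table.index]
            if missing:
                raise KeyError(f"{guild} species lacking latent traits: {missing}")
        V = self.plant_latents.loc[list(plant_ids), ["v1", "v2"]].to_numpy(float)
        F = self.butterfly_latents.loc[list(butterfly_ids), ["f1", "f2"]].to_numpy(float)
        return V, F

    def standardized_traits(self, traits: PlantTraits, plant_ids: Sequence) -> np.ndarray:
        NH = traits.values_for(plant_ids)
        if not np.isfinite(NH).all():
            raise ValueError("non-finite trait values")
        if self.trait_center is not None:
            NH = (NH - np.asarray(self.trait_center)) / np.asarray(self.trait_scale)
        return NH


@dataclass
class LinkProbabilityMatrix:
    """Dense link probabilities over all pairs, with per-species provenance."""

    probabilities: pd.DataFrame  # plants x butterflies, values in (0, 1)
    plant_provenance: pd.Series
    butterfly_provenance: pd.Series


def _eta_matrix(alpha, beta, delta, NH, V, F) -> np.ndarray:
    lin = alpha + NH @ np.asarray(beta, float)
    return (
        lin[:, None]
        + delta[0] * np.outer(V[:, 0], F[:, 0])
        + delta[1] * np.outer(V[:, 1], F[:, 1])
    )


def _cell_loglik(eta, a):
    # a*log(p) + (1-a)*log(1-p) computed from the logit: a*eta - log(1+e^eta)
    return a * eta - np.logaddexp(0.0, eta)


def link_probability(params: LinkModelParams, traits: PlantTraits, plant, butterfly) -> float:
    """Link probability for one plant-butterfly pair (the logistic model)."""
    from scipy.special import expit

    NH = params.standardized_traits(traits, [plant])
    V, F = params.latent_arrays([plant], [butterfly])
    eta = _eta_matrix(
        params.alpha, (params.beta_nitrogen, params.beta_height), params.delta, NH, V, F
    )
    return float(expit(eta[0, 0]))


def log_likelihood(web: TrophicWeb, params: LinkModelParams, traits: PlantTraits) -> float:
    """Masked Bernoulli log-likelihood over knowable cells only.

    Cells with ``mask == 0`` contribute exactly 0 regardless of their
    recorded link value.
    """
    NH = params.standardized_traits(traits, web.plant_ids)
    V, F = params.latent_arrays(web.plant_ids, web.butterfly_ids)
    eta = _eta_matrix(
        params.alpha, (params.beta_nitrogen, params.beta_height), params.delta, NH, V, F
    )
    z = web.mask.astype(float)
    a = web.links.astype(float)
    return float((z * _cell_loglik(eta, a)).sum())


@dataclass
class PriorConfig:
    """Weakly informative priors; latent traits are standard normal."""

    sd_linear: float = 10.0  # alpha, beta ~ N(0, sd_linear^2)
    sd_delta: float = 10.0  # delta ~ half-normal(sd_delta), delta1 >= delta2

    def __post_init__(self):
        if self.sd_linear <= 0 or self.sd_delta <= 0:
            raise ValueError("prior scales must be positive")


def _normal_logpdf(x, sd):
    x = np.asarray(x, float)
    return float(np.sum(-0.5 * (x / sd) ** 2 - np.log(sd) - 0.5 * _LOG_2PI))


def log_prior(alpha, beta, delta, V, F, priors: PriorConfig) -> float:
    d1, d2 = float(delta[0]), float(delta[1])
    if not (d1 >= d2 >= 0):
        return -np.inf
    lp = _normal_logpdf([alpha, beta[0], beta[1]], priors.sd_linear)
    # half-normal: 2 * N(0, sd) density on [0, inf)
    lp += _normal_logpdf([d1, d2], priors.sd_delta) + 2.0 * np.log(2.0)
    lp += _normal_logpdf(V, 1.0) + _normal_logpdf(F, 1.0)
    return lp


def log_posterior(
    web: TrophicWeb,
    params: LinkModelParams,
    traits: PlantTraits,
    priors: PriorConfig | None = None,
) -> float:
    """Unnormalized log posterior; -inf when the delta ordering is violated."""
    priors = priors or PriorConfig()
    d1, d2 = params.delta
    V, F = params.latent_arrays(web.plant_ids, web.butterfly_ids)
    lp = log_prior(
        params.alpha, (params.beta_nitrogen, params.beta_height), (d1, d2), V, F, priors
    )
    if not np.isfinite(lp):
        return -np.inf
    return log_likelihood(web, params, traits) + lp


@dataclass
class McmcConfig:
    """Sampler settings: chain length, per-block proposal scales, priors, seed."""

    n_iterations: int = 20000
    burn_in: int | None = None  # default: half the chain
    thinning: int = 10
    prop_linear: float = 0.05
    prop_delta: float = 0.10
    prop_latent: float = 0.25
    priors: PriorConfig = field(default_factory=PriorConfig)
    seed: int = 0
    adapt: bool = True  # proposal-scale adaptation during burn-in only
    delta_fixed: tuple | None = None  # pin delta (e.g. (0, 0) for the plain-GLM collapse)
    standardize_traits: bool = True

    def __post_init__(self):
        if self.burn_in is None:
            self.burn_in = self.n_iterations // 2
        if not (0 <= self.burn_in < self.n_iterations):
            raise ValueError("require 0 <= burn_in < n_iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        for name in ("prop_linear", "prop_delta", "prop_latent"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.delta_fixed is not None:
            d1, d2 = self.delta_fixed
            if not (d1 >= d2 >= 0):
                raise ValueError("delta_fixed must satisfy delta1 >= delta2 >= 0")


@dataclass
class PosteriorChain:
    """Retained, thinned posterior samples after sign alignment."""

    plant_ids: list
    butterfly_ids: list
    alpha: np.ndarray  # (S,)
    beta: np.ndarray  # (S, 2)
    delta: np.ndarray  # (S, 2)
    plant_latents: np.ndarray  # (S, n_plants, 2)
    butterfly_latents: np.ndarray  # (S, n_butterflies, 2)
    log_post: np.ndarray  # (S,)
    acceptance: dict
    config: McmcConfig
    trait_center: np.ndarray | None = None
    trait_scale: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return len(self.alpha)

    def posterior_mean_params(self) -> LinkModelParams:
        """Posterior-mean parameter vector (latents averaged after alignment)."""
        Vm = self.plant_latents.mean(axis=0)
        Fm = self.butterfly_latents.mean(axis=0)
        dm = self.delta.mean(axis=0)
        d1, d2 = float(max(dm[0], dm[1])), float(min(dm[0], dm[1]))
        plant = pd.DataFrame(Vm, index=self.plant_ids, columns=["v1", "v2"])
        plant["provenance"] = "fitted"
        bfly = pd.DataFrame(Fm, index=self.butterfly_ids, columns=["f1", "f2"])
        bfly["provenance"] = "fitted"
        return LinkModelParams(
            alpha=float(self.alpha.mean()),
            beta_nitrogen=float(self.beta[:, 0].mean()),
            beta_height=float(self.beta[:, 1].mean()),
            delta=(d1, d2),
            plant_latents=plant,
            butterfly_latents=bfly,
            trait_center=self.trait_center,
            trait_scale=self.trait_scale,
        )

    def mean_link_matrix(self, traits: PlantTraits) -> pd.DataFrame:
        """Posterior mean of P_ij: per-sample probabilities averaged.

        This is the Bayes estimate of each link probability and is invariant
        to latent sign flips by construction.
        """
        from scipy.special import expit

        NH = traits.values_for(self.plant_ids)
        if self.trait_center is not None:
            NH = (NH - self.trait_center) / self.trait_scale
        acc = np.zeros((len(self.plant_ids), len(self.butterfly_ids)))
        for s in range(self.n_samples):
            eta = _eta_matrix(
                self.alpha[s],
                self.beta[s],
                self.delta[s],
                NH,
                self.plant_latents[s],
                self.butterfly_latents[s],
            )
            acc += expit(eta)
        acc /= self.n_samples
        return pd.DataFrame(acc, index=self.plant_ids, columns=self.butterfly_ids)


def fit_mcmc(web: TrophicWeb, traits: PlantTraits, config: McmcConfig) -> PosteriorChain:
    """Block-wise random-walk Metropolis-Hastings for the link model.

    Blocks: (alpha, beta1, beta2) jointly; (delta1, delta2) jointly with the
    ordering constraint enforced through the prior; each plant's latent pair;
    each butterfly's latent pair.  Because the per-species conditionals
    factorize over rows/columns given everything else, all species of one
    guild are proposed in a single vectorized sweep with independent
    accept/reject decisions, which leaves the stationary distribution
    unchanged.  Optional scale adaptation runs during burn-in only, so the
    retained chain is Markovian.
    """
    if web.n_knowable == 0:
        raise ValueError("no information: web has zero knowable cells")
    priors = config.priors
    rng = np.random.default_rng(config.seed)
    n_p, n_b = web.n_plants, web.n_butterflies

    NH = traits.values_for(web.plant_ids)
    center = scale = None
    if config.standardize_traits:
        center = NH.mean(axis=0)
        scale = NH.std(axis=0)
        scale = np.where(scale == 0, 1.0, scale)
        NH = (NH - center) / scale

    z = web.mask.astype(float)
    a = web.links.astype(float)

    alpha = 0.0
    beta = np.zeros(2)
    fixed_delta = config.delta_fixed is not None
    delta = np.array(config.delta_fixed if fixed_delta else (1.0, 0.5), float)
    V = rng.standard_normal((n_p, 2))
    F = rng.standard_normal((n_b, 2))

    eta = _eta_matrix(alpha, beta, delta, NH, V, F)
    llc = z * _cell_loglik(eta, a)  # per-cell log-lik, masked

    scales = {
        "linear": config.prop_linear,
        "delta": config.prop_delta,
        "plant": config.prop_latent,
        "butterfly": config.prop_latent,
    }
    accepted = {k: 0.0 for k in scales}
    attempts = {k: 0.0 for k in scales}
    window_acc = {k: 0.0 for k in scales}
    window_att = {k: 0.0 for k in scales}

    n_keep = (config.n_iterations - config.burn_in) // config.thinning
    S = {
        "alpha": np.empty(n_keep),
        "beta": np.empty((n_keep, 2)),
        "delta": np.empty((n_keep, 2)),
        "V": np.empty((n_keep, n_p, 2)),
        "F": np.empty((n_keep, n_b, 2)),
        "lp": np.empty(n_keep),
    }
    kept = 0

    sd_lin2 = 2.0 * priors.sd_linear**2
    sd_del2 = 2.0 * priors.sd_delta**2

    for it in range(config.n_iterations):
        # --- linear block: alpha, beta1, beta2 jointly -------------------
        step = rng.normal(0.0, scales["linear"], 3)
        alpha_n = alpha + step[0]
        beta_n = beta + step[1:]
        shift = (alpha_n - alpha) + NH @ (beta_n - beta)
        eta_n = eta + shift[:, None]
        llc_n = z * _cell_loglik(eta_n, a)
        dprior = (alpha**2 - alpha_n**2 + (beta**2).sum() - (beta_n**2).sum()) / sd_lin2
        attempts["linear"] += 1
        window_att["linear"] += 1
        if np.log(rng.uniform()) < llc_n.sum() - llc.sum() + dprior:
            alpha, beta, eta, llc = alpha_n, beta_n, eta_n, llc_n
            accepted["linear"] += 1
            window_acc["linear"] += 1

        # --- delta block -------------------------------------------------
        if not fixed_delta:
            step = rng.normal(0.0, scales["delta"], 2)
            delta_n = delta + step
            attempts["delta"] += 1
            window_att["delta"] += 1
            if delta_n[0] >= delta_n[1] >= 0:
                eta_n = (
                    eta
                    + (delta_n[0] - delta[0]) * np.outer(V[:, 0], F[:, 0])
                    + (delta_n[1] - delta[1]) * np.outer(V[:, 1], F[:, 1])
                )
                llc_n = z * _cell_loglik(eta_n, a)
                dprior = ((delta**2).sum() - (delta_n**2).sum()) / sd_del2
                if np.log(rng.uniform()) < llc_n.sum() - llc.sum() + dprior:
                    delta, eta, llc = delta_n, eta_n, llc_n
                    accepted["delta"] += 1
                    window_acc["delta"] += 1

        # --- plant latent block (vectorized over plants) ------------------
        Vn = V + rng.normal(0.0, scales["plant"], (n_p, 2))
        eta_n = (
            eta
            + delta[0] * np.outer(Vn[:, 0] - V[:, 0], F[:, 0])
            + delta[1] * np.outer(Vn[:, 1] - V[:, 1], F[:, 1])
        )
        llc_n = z * _cell_loglik(eta_n, a)
        dprior = 0.5 * ((V**2).sum(axis=1) - (Vn**2).sum(axis=1))
        keep = np.log(rng.uniform(size=n_p)) < llc_n.sum(axis=1) - llc.sum(axis=1) + dprior
        V[keep] = Vn[keep]
        eta[keep] = eta_n[keep]
        llc[keep] = llc_n[keep]
        attempts["plant"] += n_p
        window_att["plant"] += n_p
        accepted["plant"] += keep.sum()
        window_acc["plant"] += keep.sum()

        # --- butterfly latent block (vectorized over butterflies) ---------
        Fn = F + rng.normal(0.0, scales["butterfly"], (n_b, 2))
        eta_n = (
            eta
            + delta[0] * np.outer(V[:, 0], Fn[:, 0] - F[:, 0])
            + delta[1] * np.outer(V[:, 1], Fn[:, 1] - F[:, 1])
        )
        llc_n = z * _cell_loglik(eta_n, a)
        dprior = 0.5 * ((F**2).sum(axis=1) - (Fn**2).sum(axis=1))
        keep = np.log(rng.uniform(size=n_b)) < llc_n.sum(axis=0) - llc.sum(axis=0) + dprior
        F[keep] = Fn[keep]
        eta[:, keep] = eta_n[:, keep]
        llc[:, keep] = llc_n[:, keep]
        attempts["butterfly"] += n_b
        window_att["butterfly"] += n_b
        accepted["butterfly"] += keep.sum()
        window_acc["butterfly"] += keep.sum()

        # --- burn-in-only adaptation --------------------------------------
        if config.adapt and it < config.burn_in and (it + 1) % 100 == 0:
            for k in scales:
                if window_att[k] > 0:
                    rate = window_acc[k] / window_att[k]
                    scales[k] = float(np.clip(scales[k] * np.exp(rate - 0.3), 1e-4, 5.0))
                window_acc[k] = window_att[k] = 0.0

        if it >= config.burn_in and (it - config.burn_in + 1) % config.thinning == 0:
            S["alpha"][kept] = alpha
            S["beta"][kept] = beta
            S["delta"][kept] = delta
            S["V"][kept] = V
            S["F"][kept] = F
            S["lp"][kept] = llc.sum() + log_prior(alpha, beta, delta, V, F, priors)
            kept += 1

    # sign alignment: per latent dimension, align to the first retained sample
    ref = S["V"][0]
    for d in (0, 1):
        dots = S["V"][:, :, d] @ ref[:, d]
        flip = dots < 0
        S["V"][flip, :, d] *= -1.0
        S["F"][flip, :, d] *= -1.0

    rates = {
        k: (accepted[k] / attempts[k]) if attempts[k] else float("nan") for k in scales
    }
    return PosteriorChain(
        plant_ids=web.plant_ids,
        butterfly_ids=web.butterfly_ids,
        alpha=S["alpha"],
        beta=S["beta"],
        delta=S["delta"],
        plant_latents=S["V"],
        butterfly_latents=S["F"],
        log_post=S["lp"],
        acceptance=rates,
        config=config,
        trait_center=center,
        trait_scale=scale,
    )


def predict_link_matrix(
    params: LinkModelParams,
    traits: PlantTraits,
    plant_ids: Sequence,
    butterfly_ids: Sequence,
) -> LinkProbabilityMatrix:
    """Dense P_ij over all listed pairs, including unobservable ones."""
    from scipy.special import expit

    NH = params.standardized_traits(traits, plant_ids)
    V, F = params.latent_arrays(plant_ids, butterfly_ids)
    eta = _eta_matrix(
        params.alpha, (params.beta_nitrogen, params.beta_height), params.delta, NH, V, F
    )
    probs = pd.DataFrame(expit(eta), index=list(plant_ids), columns=list(butterfly_ids))

    def _prov(table, ids):
        if "provenance" in table.columns:
            return table.loc[list(ids), "provenance"].copy()
        return pd.Series("fitted", index=list(ids))

    return LinkProbabilityMatrix(
        probabilities=probs,
        plant_provenance=_prov(params.plant_latents, plant_ids),
        butterfly_provenance=_prov(params.butterfly_latents, butterfly_ids),
    )


def compute_cooccurrence_mask(
    plant_occurrences: pd.DataFrame, butterfly_occurrences: pd.DataFrame
) -> pd.DataFrame:
    """Knowability mask: z_ij = 1 iff plant i and butterfly j share >= 1 site.

    Both tables are site x species presence/absence with a shared site index.
    """
    if set(plant_occurrences.index) != set(butterfly_occurrences.index):
        raise ValueError("plant and butterfly occurrence tables cover different site sets")
    P = _as_binary(plant_occurrences.to_numpy(), "plant occurrences")
    B = _as_binary(
        butterfly_occurrences.loc[plant_occurrences.index].to_numpy(), "butterfly occurrences"
    )
    co = P.T.astype(np.int64) @ B.astype(np.int64)
    return pd.DataFrame(
        (co > 0).astype(np.int8),
        index=plant_occurrences.columns,
        columns=butterfly_occurrences.columns,
    )
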