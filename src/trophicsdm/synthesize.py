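"""Synthetic plant-butterfly studies with known ground truth.

Generates everything the rest of the package consumes: two pure-birth
ultrametric phylogenies, lambda-structured latent traits simulated on them,
measured plant traits, a trophic web drawn from the latent-trait link
model, an environmental landscape along an elevation-like gradient, plant
occurrences from quadratic logistic niches, and butterfly occurrences whose
occupancy logit carries an additive trophic coupling ``gamma`` times the
"best-case" link probability with the plants realized at each site.  The
partially observed web handed to the fitting machinery is masked by the
realized co-occurrence pattern, mirroring field studies where many species
pairs are never recorded at the same site.

All randomness flows from a single seed expanded into fixed per-component
substreams, so regeneration is bit-identical and adding a component never
perturbs earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.special import expit

from .foodweb import (
    LinkModelParams,
    PlantTraits,
    TrophicWeb,
    compute_cooccurrence_mask,
    predict_link_matrix,
)
from .phylo import lambda_vcv, shared_time_matrix
from .sdm import OccurrenceStudy, trophic_term

__all__ = [
    "SyntheticConfig",
    "SyntheticStudy",
    "simulate_tree",
    "simulate_latents",
    "simulate_web",
    "simulate_occurrences",
    "make_study",
]


@dataclass
class SyntheticConfig:
    """Generating conditions of a synthetic study.

    Defaults give a mid-sized alpine-style study: a few dozen species per
    guild, 150 sampled sites, strong latent-trait structure in the web
    (delta = (2, 1)), clear phylogenetic signal (lambda = 0.8) and strong
    trophic coupling of herbivore occupancy (gamma = 3).
    """

    seed: int
    n_plants: int = 25
    n_butterflies: int = 30
    n_sites: int = 150
    # link model (Eq.-1-style) truth
    alpha: float = -1.0
    beta_nitrogen: float = 1.0
    beta_height: float = 0.5
    delta: tuple = (2.0, 1.0)
    # latent-trait phylogenetic structure per dimension
    lambda_plant: tuple = (0.8, 0.8)
    lambda_butterfly: tuple = (0.8, 0.8)
    sigma2_latent: float = 1.0
    # measured trait distributions: leaf N in % dry mass, height in m
    nitrogen_mean: float = 2.5
    nitrogen_sd: float = 0.7
    height_log_mean: float = -1.2
    height_log_sd: float = 0.7
    # occupancy model
    plant_prevalence: tuple = (0.2, 0.6)
    butterfly_prevalence: tuple = (0.15, 0.45)
    niche_width: tuple = (0.15, 0.35)
    gamma: float = 3.0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if min(self.n_plants, self.n_butterflies, self.n_sites) < 3:
            raise ValueError("species and site counts must be >= 3")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        d1, d2 = self.delta
        if not (d1 >= d2 >= 0):
            raise ValueError("delta must satisfy delta1 >= delta2 >= 0")


@dataclass
class SyntheticStudy:
    """Inputs for the whole pipeline plus the generating truth."""

    config: SyntheticConfig
    web: TrophicWeb  # mask from realized co-occurrence
    full_web: TrophicWeb  # same links, all-ones mask
    traits: PlantTraits
    plant_tree: dendropy.Tree
    butterfly_tree: dendropy.Tree
    occurrences: OccurrenceStudy
    truth: dict
    masked_fraction: float


def _yule_newick(n_tips: int, rng: np.random.Generator, prefix: str) -> str:
    """Pure-birth tree, depth normalized to 1, as a Newick string."""
    birth = {0: 0.0, 1: 0.0}
    children: dict = {}
    split_time: dict = {}
    active = [0, 1]
    nxt = 2
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        node = active.pop(i)
        split_time[node] = t
        kids = [nxt, nxt + 1]
        nxt += 2
        for k in kids:
            birth[k] = t
        children[node] = kids
        active.extend(kids)
    t_end = t + rng.exponential(1.0 / n_tips)

    counter = {"k": 0}

    def render(node: int) -> str:
        if node in children:
            parts = ",".join(render(c) for c in children[node])
            length = (split_time[node] - birth[node]) / t_end
            return f"({parts}):{length:.10f}"
        counter["k"] += 1
        length = (t_end - birth[node]) / t_end
        return f"{prefix}{counter['k']:03d}:{length:.10f}"

    return f"({render(0)},{render(1)});"


def simulate_tree(n_tips: int, seed, prefix: str = "t") -> dendropy.Tree:
    """Pure-birth ultrametric tree with depth 1 and labelled tips."""
    if n_tips < 3:
        raise ValueError("need >= 3 tips")
    rng = np.random.default_rng(seed)
    newick = _yule_newick(n_tips, rng, prefix)
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


def simulate_latents(tree: dendropy.Tree, lam: float, sigma2: float, mu: float, seed) -> pd.Series:
    """One multivariate-normal draw of a tip trait under the lambda model."""
    stm = shared_time_matrix(tree)
    C = lambda_vcv(stm, sigma2, lam)
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        L = np.linalg.cholesky(C + 1e-10 * np.eye(len(C)))
    rng = np.random.default_rng(seed)
    draw = mu + L @ rng.standard_normal(len(C))
    return pd.Series(draw, index=stm.tip_labels)


def simulate_web(params: LinkModelParams, traits: PlantTraits, seed) -> TrophicWeb:
    """Bernoulli draw of the full link matrix; mask all ones."""
    plant_ids = list(params.plant_latents.index)
    butterfly_ids = list(params.butterfly_latents.index)
    p = predict_link_matrix(params, traits, plant_ids, butterfly_ids).probabilities.to_numpy()
    rng = np.random.default_rng(seed)
    links = (rng.uniform(size=p.shape) < p).astype(np.int8)
    return TrophicWeb(
        plant_ids=plant_ids,
        butterfly_ids=butterfly_ids,
        links=links,
        mask=np.ones_like(links),
    )


def _calibrate_intercept(offset: np.ndarray, target: float) -> float:
    """Intercept b0 such that mean(expit(b0 + offset)) equals the target prevalence."""
    lo, hi = -30.0, 30.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if expit(mid + offset).mean() < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_occurrences(config: SyntheticConfig, link_matrix_truth: pd.DataFrame, seed) -> OccurrenceStudy:
    """Environmental landscape plus niche-driven, trophically coupled occupancy.

    Sites lie along an elevation-like gradient that drives degree-days,
    moisture and (weakly) radiation.  Each species has a unimodal
    (quadratic logistic) niche on the gradient with an intercept calibrated
    to a drawn target prevalence -- for butterflies the calibration includes
    the gamma-weighted trophic term, so prevalences are comparable across
    coupling strengths.
    """
    rng = np.random.default_rng(seed)
    n = config.n_sites
    plant_ids = list(link_matrix_truth.index)
    butterfly_ids = list(link_matrix_truth.columns)
    sites = [f"s{k + 1:03d}" for k in range(n)]

    elev = rng.uniform(0.0, 1.0, n)
    ddeg = 3200.0 - 2600.0 * elev + rng.normal(0.0, 120.0, n)
    mind = -20.0 + 90.0 * elev + rng.normal(0.0, 15.0, n)
    srad = 200.0 + 10.0 * elev + rng.normal(0.0, 25.0, n)
    env = pd.DataFrame({"ddeg": ddeg, "mind": mind, "srad": srad}, index=sites)

    def niche_logits(n_species, prevalence_range):
        opts = rng.uniform(0.0, 1.0, n_species)
        widths = rng.uniform(*config.niche_width, n_species)
        targets = rng.uniform(*prevalence_range, n_species)
        scores = -((elev[:, None] - opts[None, :]) ** 2) / (2.0 * widths[None, :] ** 2)
        return scores, targets, {"optimum": opts, "width": widths, "target_prevalence": targets}

    p_scores, p_targets, plant_niche = niche_logits(config.n_plants, config.plant_prevalence)
    plant_occ = np.empty((n, config.n_plants), dtype=np.int8)
    plant_b0 = np.empty(config.n_plants)
    for i in range(config.n_plants):
        plant_b0[i] = _calibrate_intercept(p_scores[:, i], p_targets[i])
        plant_occ[:, i] = rng.uniform(size=n) < expit(plant_b0[i] + p_scores[:, i])
    plant_occ = pd.DataFrame(plant_occ, index=sites, columns=plant_ids)

    P = link_matrix_truth.to_numpy()
    trophic = np.array(
        [
            [trophic_term(plant_occ.iloc[k].to_numpy(), P[:, j]) for j in range(len(butterfly_ids))]
            for k in range(n)
        ]
    )

    b_scores, b_targets, butterfly_niche = niche_logits(
        config.n_butterflies, config.butterfly_prevalence
    )
    bf_occ = np.empty((n, config.n_butterflies), dtype=np.int8)
    bf_b0 = np.empty(config.n_butterflies)
    for j in range(config.n_butterflies):
        offset = b_scores[:, j] + config.gamma * trophic[:, j]
        bf_b0[j] = _calibrate_intercept(offset, b_targets[j])
        bf_occ[:, j] = rng.uniform(size=n) < expit(bf_b0[j] + offset)
    bf_occ = pd.DataFrame(bf_occ, index=sites, columns=butterfly_ids)

    study = OccurrenceStudy(plant_occ=plant_occ, butterfly_occ=bf_occ, env=env)
    study.truth = {  # type: ignore[attr-defined]
        "elevation": pd.Series(elev, index=sites),
        "plant_niche": {**plant_niche, "intercept": plant_b0},
        "butterfly_niche": {**butterfly_niche, "intercept": bf_b0},
        "trophic_term": pd.DataFrame(trophic, index=sites, columns=butterfly_ids),
    }
    return study


def make_study(config: SyntheticConfig) -> SyntheticStudy:
    """Compose all simulators into a complete study with attached truth."""
    ss = np.random.SeedSequence(config.seed)
    (
        s_ptree,
        s_btree,
        s_v1,
        s_v2,
        s_f1,
        s_f2,
        s_traits,
        s_web,
        s_occ,
    ) = ss.spawn(9)

    plant_tree = simulate_tree(config.n_plants, s_ptree, prefix="p")
    butterfly_tree = simulate_tree(config.n_butterflies, s_btree, prefix="b")
    plant_ids = shared_time_matrix(plant_tree).tip_labels
    butterfly_ids = shared_time_matrix(butterfly_tree).tip_labels

    v1 = simulate_latents(plant_tree, config.lambda_plant[0], config.sigma2_latent, 0.0, s_v1)
    v2 = simulate_latents(plant_tree, config.lambda_plant[1], config.sigma2_latent, 0.0, s_v2)
    f1 = simulate_latents(butterfly_tree, config.lambda_butterfly[0], config.sigma2_latent, 0.0, s_f1)
    f2 = simulate_latents(butterfly_tree, config.lambda_butterfly[1], config.sigma2_latent, 0.0, s_f2)

    rng = np.random.default_rng(s_traits)
    nitrogen = rng.normal(config.nitrogen_mean, config.nitrogen_sd, config.n_plants)
    height = rng.lognormal(config.height_log_mean, config.height_log_sd, config.n_plants)
    traits = PlantTraits(
        pd.DataFrame({"nitrogen": nitrogen, "avg_height": height}, index=plant_ids)
    )
    NH = traits.frame[["nitrogen", "avg_height"]].to_numpy()
    center, scale = NH.mean(axis=0), NH.std(axis=0)

    plant_latents = pd.DataFrame({"v1": v1, "v2": v2}).loc[plant_ids]
    butterfly_latents = pd.DataFrame({"f1": f1, "f2": f2}).loc[butterfly_ids]
    true_params = LinkModelParams(
        alpha=config.alpha,
        beta_nitrogen=config.beta_nitrogen,
        beta_height=config.beta_height,
        delta=tuple(config.delta),
        plant_latents=plant_latents,
        butterfly_latents=butterfly_latents,
        trait_center=center,
        trait_scale=scale,
    )
    true_p = predict_link_matrix(true_params, traits, plant_ids, butterfly_ids).probabilities

    full_web = simulate_web(true_params, traits, s_web)
    occurrences = simulate_occurrences(config, true_p, s_occ)

    mask = compute_cooccurrence_mask(occurrences.plant_occ, occurrences.butterfly_occ)
    mask = mask.loc[plant_ids, butterfly_ids]
    web = TrophicWeb(
        plant_ids=plant_ids,
        butterfly_ids=butterfly_ids,
        links=full_web.links,
        mask=mask.to_numpy(),
    )
    return SyntheticStudy(
        config=config,
        web=web,
        full_web=full_web,
        traits=traits,
        plant_tree=plant_tree,
        butterfly_tree=butterfly_tree,
        occurrences=occurrences,
        truth={
            "params": true_params,
            "link_matrix": true_p,
            "plant_latents": plant_latents,
            "butterfly_latents": butterfly_latents,
            "occupancy": getattr(occurrences, "truth", None),
        },
        masked_fraction=float(1.0 - mask.to_numpy().mean()),
    )
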