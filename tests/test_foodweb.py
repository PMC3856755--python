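"""Unit tests of the latent-trait link model: probability formula, masked
likelihood, priors, MCMC behaviour and the co-occurrence mask."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from trophicsdm.foodweb import (
    LinkModelParams,
    McmcConfig,
    PlantTraits,
    PriorConfig,
    TrophicWeb,
    compute_cooccurrence_mask,
    fit_mcmc,
    link_probability,
    log_likelihood,
    log_posterior,
    log_prior,
    predict_link_matrix,
)

from conftest import random_link_problem


def _one_pair_params(alpha=0.0, b1=0.0, b2=0.0, delta=(0.0, 0.0), v=(0.0, 0.0), f=(0.0, 0.0)):
    return LinkModelParams(
        alpha=alpha,
        beta_nitrogen=b1,
        beta_height=b2,
        delta=delta,
        plant_latents=pd.DataFrame([v], index=["p"], columns=["v1", "v2"]),
        butterfly_latents=pd.DataFrame([f], index=["b"], columns=["f1", "f2"]),
    )


def _one_pair_traits(n=0.0, h=0.0):
    return PlantTraits(pd.DataFrame({"nitrogen": [n], "avg_height": [h]}, index=["p"]))


@pytest.mark.parametrize(
    "params_kw, traits_kw, expected",
    [
        (dict(), dict(), 0.5),
        (dict(alpha=1.0), dict(), 1.0 / (1.0 + math.exp(-1.0))),
        (dict(b1=0.145), dict(n=2.0), float(expit(0.29))),
    ],
)
def test_link_probability_closed_form(params_kw, traits_kw, expected):
    p = link_probability(_one_pair_params(**params_kw), _one_pair_traits(**traits_kw), "p", "b")
    assert p == pytest.approx(expected, abs=1e-10)
    assert 0.0 < p < 1.0


def test_link_probability_faults_on_bad_input():
    params = _one_pair_params()
    with pytest.raises(KeyError):
        link_probability(params, _one_pair_traits(), "p", "nope")
    bad = PlantTraits.__new__(PlantTraits)
    bad.frame = pd.DataFrame({"nitrogen": [np.nan], "avg_height": [0.0]}, index=["p"])
    with pytest.raises(ValueError):
        link_probability(params, bad, "p", "b")


def test_log_likelihood_single_pair_and_empty_mask():
    params = _one_pair_params()
    traits = _one_pair_traits()
    web = TrophicWeb(["p"], ["b"], links=[[1]], mask=[[1]])
    assert log_likelihood(web, params, traits) == pytest.approx(math.log(0.5), abs=1e-12)
    empty = TrophicWeb(["p"], ["b"], links=[[1]], mask=[[0]])
    assert log_likelihood(empty, params, traits) == 0.0


@pytest.mark.parametrize("seed", range(6))
def test_log_likelihood_matches_cellwise_brute_force(seed):
    web, params, traits = random_link_problem(seed)
    brute = 0.0
    for i, p in enumerate(web.plant_ids):
        for j, b in enumerate(web.butterfly_ids):
            if web.mask[i, j]:
                pij = link_probability(params, traits, p, b)
                brute += math.log(pij) if web.links[i, j] else math.log(1 - pij)
    assert log_likelihood(web, params, traits) == pytest.approx(brute, abs=1e-12)


@pytest.mark.parametrize("seed", range(4))
def test_masked_cells_carry_no_information(seed):
    web, params, traits = random_link_problem(seed)
    base = log_likelihood(web, params, traits)
    flipped = web.links.copy()
    flipped[web.mask == 0] = 1 - flipped[web.mask == 0]
    web2 = TrophicWeb(web.plant_ids, web.butterfly_ids, flipped, web.mask)
    assert log_likelihood(web2, params, traits) == base


def test_sign_flip_of_a_latent_dimension_leaves_probabilities_unchanged():
    web, params, traits = random_link_problem(3)
    base = predict_link_matrix(params, traits, web.plant_ids, web.butterfly_ids).probabilities
    for d, (vc, fc) in enumerate((("v1", "f1"), ("v2", "f2"))):
        pl = params.plant_latents.copy()
        bl = params.butterfly_latents.copy()
        pl[vc] *= -1
        bl[fc] *= -1
        flipped = LinkModelParams(
            params.alpha, params.beta_nitrogen, params.beta_height, params.delta, pl, bl
        )
        out = predict_link_matrix(flipped, traits, web.plant_ids, web.butterfly_ids).probabilities
        np.testing.assert_allclose(out.to_numpy(), base.to_numpy(), atol=1e-14)


def test_log_posterior_is_likelihood_plus_termwise_priors():
    web, params, traits = random_link_problem(5)
    priors = PriorConfig(sd_linear=3.0, sd_delta=2.0)

    def norm_lp(x, sd):
        return -0.5 * (x / sd) ** 2 - math.log(sd) - 0.5 * math.log(2 * math.pi)

    V = params.plant_latents[["v1", "v2"]].to_numpy()
    F = params.butterfly_latents[["f1", "f2"]].to_numpy()
    expected = log_likelihood(web, params, traits)
    expected += sum(norm_lp(x, 3.0) for x in (params.alpha, params.beta_nitrogen, params.beta_height))
    expected += sum(norm_lp(d, 2.0) + math.log(2.0) for d in params.delta)
    expected += sum(norm_lp(x, 1.0) for x in V.ravel()) + sum(norm_lp(x, 1.0) for x in F.ravel())
    assert log_posterior(web, params, traits, priors) == pytest.approx(expected, abs=1e-10)


def test_log_posterior_flat_likelihood_and_delta_ordering():
    web, params, traits = random_link_problem(7)
    masked = TrophicWeb(
        web.plant_ids, web.butterfly_ids, web.links, np.zeros_like(web.mask)
    )
    priors = PriorConfig()
    V = params.plant_latents[["v1", "v2"]].to_numpy()
    F = params.butterfly_latents[["f1", "f2"]].to_numpy()
    prior_only = log_prior(
        params.alpha, (params.beta_nitrogen, params.beta_height), params.delta, V, F, priors
    )
    assert log_posterior(masked, params, traits, priors) == pytest.approx(prior_only, abs=1e-12)
    # prior mode (everything at zero) dominates any other state under a flat likelihood
    mode = _one_pair_params()
    assert log_prior(0.0, (0.0, 0.0), (0.0, 0.0), np.zeros((4, 2)), np.zeros((4, 2)), priors) > log_prior(
        1.0, (0.5, -0.5), (1.0, 0.2), np.ones((4, 2)), np.ones((4, 2)), priors
    )
    # violated ordering is an impossible (rejected) state
    assert log_prior(0.0, (0.0, 0.0), (1.0, 2.0), V, F, priors) == -np.inf
    assert log_prior(0.0, (0.0, 0.0), (-0.5, -1.0), V, F, priors) == -np.inf


def test_params_constructor_rejects_bad_delta():
    with pytest.raises(ValueError):
        _one_pair_params(delta=(1.0, 2.0))


def test_fit_mcmc_requires_information_and_valid_config():
    web, _, traits = random_link_problem(1)
    hollow = TrophicWeb(web.plant_ids, web.butterfly_ids, web.links, np.zeros_like(web.mask))
    with pytest.raises(ValueError, match="no information"):
        fit_mcmc(hollow, traits, McmcConfig(n_iterations=100, burn_in=10))
    with pytest.raises(ValueError):
        McmcConfig(n_iterations=100, burn_in=10, prop_latent=-1.0)
    with pytest.raises(ValueError):
        McmcConfig(n_iterations=100, burn_in=200)


def test_saturated_web_drives_probabilities_high():
    rng = np.random.default_rng(0)
    plants = [f"p{i}" for i in range(6)]
    bflies = [f"b{j}" for j in range(8)]
    traits = PlantTraits(
        pd.DataFrame(
            {"nitrogen": rng.normal(2, 1, 6), "avg_height": rng.normal(0.5, 0.2, 6)}, index=plants
        )
    )
    web = TrophicWeb(plants, bflies, np.ones((6, 8)), np.ones((6, 8)))
    chain = fit_mcmc(web, traits, McmcConfig(n_iterations=4000, seed=2))
    mean_p = chain.mean_link_matrix(traits).to_numpy()
    assert (mean_p > 0.9).all()


def test_chain_is_bit_reproducible_for_fixed_seed():
    web, _, traits = random_link_problem(2, n_plants=5, n_butterflies=6)
    cfg = dict(n_iterations=600, burn_in=200, thinning=4, seed=123)
    c1 = fit_mcmc(web, traits, McmcConfig(**cfg))
    c2 = fit_mcmc(web, traits, McmcConfig(**cfg))
    assert c1.n_samples == (600 - 200) // 4
    np.testing.assert_array_equal(c1.alpha, c2.alpha)
    np.testing.assert_array_equal(c1.plant_latents, c2.plant_latents)
    np.testing.assert_array_equal(c1.log_post, c2.log_post)
    assert c1.acceptance == c2.acceptance
    assert all(0.0 <= r <= 1.0 for r in c1.acceptance.values() if np.isfinite(r))


def test_predict_link_matrix_matches_pairwise_and_is_monotone_in_nitrogen():
    web, params, traits = random_link_problem(9)
    out = predict_link_matrix(params, traits, web.plant_ids, web.butterfly_ids)
    for i, p in enumerate(web.plant_ids):
        for j, b in enumerate(web.butterfly_ids):
            assert out.probabilities.iloc[i, j] == pytest.approx(
                link_probability(params, traits, p, b), abs=1e-14
            )
    assert ((out.probabilities.to_numpy() > 0) & (out.probabilities.to_numpy() < 1)).all()

    pos_beta = LinkModelParams(
        params.alpha, abs(params.beta_nitrogen) + 0.1, params.beta_height, params.delta,
        params.plant_latents, params.butterfly_latents,
    )
    bumped = PlantTraits(traits.frame.assign(nitrogen=traits.frame["nitrogen"] + 1.0))
    lo = predict_link_matrix(pos_beta, traits, web.plant_ids, web.butterfly_ids).probabilities
    hi = predict_link_matrix(pos_beta, bumped, web.plant_ids, web.butterfly_ids).probabilities
    assert (hi.to_numpy() >= lo.to_numpy()).all()


def test_predict_link_matrix_single_trivial_cell_and_missing_species():
    params = _one_pair_params()
    traits = _one_pair_traits()
    out = predict_link_matrix(params, traits, ["p"], ["b"])
    assert out.probabilities.iloc[0, 0] == pytest.approx(0.5)
    with pytest.raises(KeyError, match="ghost"):
        predict_link_matrix(params, traits, ["p"], ["ghost"])


def test_cooccurrence_mask_enumeration():
    sites = ["s1", "s2", "s3"]
    plants = pd.DataFrame({"A": [1, 1, 0]}, index=sites)
    bflies = pd.DataFrame({"X": [0, 1, 1], "Y": [0, 0, 1]}, index=sites)
    mask = compute_cooccurrence_mask(plants, bflies)
    assert mask.loc["A", "X"] == 1
    assert mask.loc["A", "Y"] == 0

    disjoint = compute_cooccurrence_mask(
        pd.DataFrame({"A": [1, 0]}, index=["s1", "s2"]),
        pd.DataFrame({"X": [0, 1]}, index=["s1", "s2"]),
    )
    assert (disjoint.to_numpy() == 0).all()

    one_site = compute_cooccurrence_mask(
        pd.DataFrame({"A": [1], "B": [1]}, index=["s1"]),
        pd.DataFrame({"X": [1], "Y": [1]}, index=["s1"]),
    )
    assert (one_site.to_numpy() == 1).all()

    with pytest.raises(ValueError, match="site"):
        compute_cooccurrence_mask(
            pd.DataFrame({"A": [1]}, index=["s1"]),
            pd.DataFrame({"X": [1]}, index=["s9"]),
        )
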