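"""Phylogenetic signal and imputation of latent traits.

On an ultrametric tree, the shared-history fraction ``t_ij`` of two tips is
the root-to-MRCA depth divided by the tree depth.  A trait measured at the
tips is modelled as multivariate normal with mean ``mu`` and covariance

    C(lambda)_ii = sigma^2,     C(lambda)_ij = sigma^2 * lambda * t_ij

where Pagel's ``lambda`` in [0, 1] scales the phylogenetic correlation
(0 = star-like independence, 1 = full Brownian structure).  ``lambda`` is
estimated by profile maximum likelihood (closed-form GLS for ``mu`` and
``sigma^2`` at each ``lambda``); the presence of signal is tested with a
likelihood-ratio statistic against the boundary-corrected 50:50
chi2_0 / chi2_1 mixture null.  Latent traits of species without recorded
interactions are predicted by the conditional expectation of this normal
model given the fitted species (phylogenetic kriging).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy.stats import chi2

__all__ = [
    "SharedTimeMatrix",
    "LambdaFit",
    "shared_time_matrix",
    "lambda_vcv",
    "fit_lambda_regression",
    "lambda_signal_test",
    "impute_latent",
    "impute_all_latents",
]

ULTRAMETRIC_RTOL = 1e-6


@dataclass
class SharedTimeMatrix:
    """Symmetric matrix of shared-history fractions with its tip ordering."""

    values: np.ndarray
    tip_labels: list

    def index_of(self, labels: Sequence) -> np.ndarray:
        pos = {t: i for i, t in enumerate(self.tip_labels)}
        missing = [s for s in labels if s not in pos]
        if missing:
            raise KeyError(f"species absent from tree: {missing}")
        return np.array([pos[s] for s in labels], dtype=int)


@dataclass
class LambdaFit:
    """Profile-ML fit of the lambda model: GLS mean, variance, lambda, log-likelihoods."""

    mu: float
    sigma2: float
    lam: float
    loglik: float
    loglik_lambda0: float

    def __post_init__(self):
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError("lambda must lie in [0, 1]")


def shared_time_matrix(tree: dendropy.Tree, rtol: float = ULTRAMETRIC_RTOL) -> SharedTimeMatrix:
    """Shared-time fractions t_ij = depth(MRCA(i, j)) / tree depth.

    The tree must be rooted and ultrametric within ``rtol`` relative to its
    depth; depths are measured from the root of the input tree, which is not
    rescaled.
    """
    root = tree.seed_node
    depth = {root: 0.0}
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        el = node.edge.length if node.edge.length is not None else 0.0
        if el < 0:
            raise ValueError(f"negative branch length {el} on edge to {node}")
        depth[node] = depth[node.parent_node] + el

    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label if lf.taxon is not None else str(lf) for lf in leaves]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tip labels")
    tip_depth = np.array([depth[lf] for lf in leaves])
    total = tip_depth.max()
    if total <= 0:
        raise ValueError("tree has zero depth")
    dev = tip_depth.max() - tip_depth.min()
    if dev > rtol * total:
        raise ValueError(
            f"tree is not ultrametric: root-to-tip depths deviate by {dev:.6g} "
            f"(> {rtol:.1e} x depth {total:.6g})"
        )

    n = len(leaves)
    idx = {lf: i for i, lf in enumerate(leaves)}
    T = np.zeros((n, n))
    tipsets: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            tipsets[node] = [idx[node]]
            continue
        child_sets = [tipsets.pop(ch) for ch in node.child_nodes()]
        frac = depth[node] / total
        for i in range(len(child_sets)):
            for j in range(i + 1, len(child_sets)):
                T[np.ix_(child_sets[i], child_sets[j])] = frac
        tipsets[node] = [t for cs in child_sets for t in cs]
    T = T + T.T
    np.fill_diagonal(T, 1.0)
    return SharedTimeMatrix(values=T, tip_labels=labels)


def lambda_vcv(t: SharedTimeMatrix | np.ndarray, sigma2: float, lam: float) -> np.ndarray:
    """C(lambda): diagonal sigma^2, off-diagonal sigma^2 * lambda * t_ij."""
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    T = t.values if isinstance(t, SharedTimeMatrix) else np.asarray(t, float)
    C = sigma2 * lam * T
    np.fill_diagonal(C, sigma2)
    return C


def _profile_loglik(lam: float, T: np.ndarray, y: np.ndarray):
    """Profile log-likelihood at lambda with (mu, sigma2) maximized in closed form."""
    n = len(y)
    C0 = lam * T
    np.fill_diagonal(C0, 1.0)
    try:
        cf = linalg.cho_factor(C0, lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError(f"singular phylogenetic covariance at lambda={lam}") from exc
    logdet = 2.0 * np.log(np.diag(cf[0])).sum()
    ones = np.ones(n)
    Ci1 = linalg.cho_solve(cf, ones)
    Ciy = linalg.cho_solve(cf, y)
    mu = float(ones @ Ciy / (ones @ Ci1))
    r = y - mu
    s2 = float(r @ linalg.cho_solve(cf, r) / n)
    if s2 <= 0:
        raise ValueError("degenerate (zero-variance) trait values")
    ll = -0.5 * (n * np.log(2.0 * np.pi * s2) + logdet + n)
    return ll, mu, s2


def fit_lambda_regression(
    values: Mapping | pd.Series, tree: dendropy.Tree, xatol: float = 1e-4
) -> LambdaFit:
    """Intercept-only phylogenetic regression with Pagel's-lambda correlation.

    ``values`` maps tip labels (a subset of the tree's tips is allowed; the
    shared-time fractions stay relative to the full tree) to trait values.
    lambda is found by an 11-point grid pre-scan followed by bounded
    refinement; (mu, sigma2) are profiled out by GLS at each lambda.
    """
    s = pd.Series(values, dtype=float)
    if len(s) < 3:
        raise ValueError(f"need >= 3 tips with values, got {len(s)}")
    stm = shared_time_matrix(tree)
    ix = stm.index_of(s.index)
    T = stm.values[np.ix_(ix, ix)]
    y = s.to_numpy()

    grid = np.linspace(0.0, 1.0, 11)
    grid_ll = np.array([_profile_loglik(g, T, y)[0] for g in grid])
    best = int(np.argmax(grid_ll))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda g: -_profile_loglik(g, T, y)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": xatol},
    )
    candidates = [(grid_ll[best], grid[best]), (-res.fun, float(res.x))]
    ll_hat, lam_hat = max(candidates)
    _, mu, s2 = _profile_loglik(lam_hat, T, y)
    ll0 = _profile_loglik(0.0, T, y)[0]
    return LambdaFit(mu=mu, sigma2=s2, lam=lam_hat, loglik=ll_hat, loglik_lambda0=ll0)


def lambda_signal_test(fit: LambdaFit) -> tuple[float, float]:
    """LRT of lambda = 0 against the 50:50 chi2_0 / chi2_1 boundary mixture.

    Returns (statistic, p).  The mixture null reflects lambda = 0 lying on
    the boundary of the parameter space.
    """
    stat = max(0.0, 2.0 * (fit.loglik - fit.loglik_lambda0))
    p = 1.0 if stat == 0.0 else 0.5 * float(chi2.sf(stat, df=1))
    return stat, p


def impute_latent(
    fit: LambdaFit,
    t: SharedTimeMatrix,
    observed: Mapping | pd.Series,
    targets: Sequence,
) -> pd.Series:
    """Conditional-expectation (kriging) prediction for unobserved tips.

    For target x: mu + C_xo C_oo^-1 (y_obs - mu), with C = C(lambda) at the
    fitted (sigma2, lambda).  Observed tips are the species with at least
    one recorded interaction.
    """
    obs = pd.Series(observed, dtype=float)
    overlap = set(obs.index) & set(targets)
    if overlap:
        raise ValueError(f"targets overlap observed tips: {sorted(overlap)}")
    oi = t.index_of(obs.index)
    xi = t.index_of(list(targets))
    C = lambda_vcv(t, fit.sigma2, fit.lam)
    C_oo = C[np.ix_(oi, oi)]
    C_xo = C[np.ix_(xi, oi)]
    try:
        w = linalg.cho_solve(linalg.cho_factor(C_oo, lower=True), obs.to_numpy() - fit.mu)
    except linalg.LinAlgError as exc:
        raise ValueError("singular covariance among observed tips") from exc
    return pd.Series(fit.mu + C_xo @ w, index=list(targets))


def impute_all_latents(
    plant_latents: pd.DataFrame,
    butterfly_latents: pd.DataFrame,
    plant_tree: dendropy.Tree,
    butterfly_tree: dendropy.Tree,
    plant_ids: Sequence,
    butterfly_ids: Sequence,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Fill latent-trait tables for every listed species by phylogenetic kriging.

    Each of the four latent dimensions (plant v1, v2; butterfly f1, f2) gets
    its own intercept-only lambda regression on the species with fitted
    (MCMC posterior mean) values, then conditional-expectation prediction
    for the remaining species.  Returns the two completed tables (with a
    ``provenance`` column) and a dict of the four LambdaFit records keyed
    ``plant_v1``, ``plant_v2``, ``butterfly_f1``, ``butterfly_f2``.
    """
    fits: dict = {}
    out = []
    for table, tree, ids, cols, guild in (
        (plant_latents, plant_tree, plant_ids, ["v1", "v2"], "plant"),
        (butterfly_latents, butterfly_tree, butterfly_ids, ["f1", "f2"], "butterfly"),
    ):
        stm = shared_time_matrix(tree)
        stm.index_of(list(ids))  # fault naming any species absent from its tree
        fitted = list(table.index)
        targets = [s for s in ids if s not in set(fitted)]
        if len(fitted) < 3:
            raise ValueError(f"need >= 3 fitted {guild} species, got {len(fitted)}")
        full = pd.DataFrame(index=list(ids), columns=cols, dtype=float)
        for col in cols:
            obs = table[col].astype(float)
            fit = fit_lambda_regression(obs, tree)
            fits[f"{guild}_{col}"] = fit
            present = [s for s in fitted if s in set(ids)]
            full.loc[present, col] = obs.loc[present]
            if targets:
                full.loc[targets, col] = impute_latent(fit, stm, obs, targets)
        full["provenance"] = ["fitted" if s in set(table.index) else "imputed" for s in ids]
        out.append(full)
    return out[0], out[1], fits
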