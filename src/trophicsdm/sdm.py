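"""Species distribution models with an optional trophic predictor.

Each butterfly species' presence/absence across sites is modelled from
three abiotic predictors -- growing degree-days (ddeg), a moisture index
(mind) and solar radiation (srad) -- under three predictor sets:

* ``abiotic``            -- linear + quadratic terms of the standardized
                            environmental variables;
* ``abiotic+literature`` -- plus presence of any literature-known host;
* ``abiotic+foodweb``    -- plus the "best-case scenario" trophic term, the
                            maximum modelled link probability between the
                            focal herbivore and any plant present at the
                            site.

Four techniques are supported: a binomial GLM with quadratic terms, a GAM
(regression splines of the three variables), gradient boosting (GBM) and
random forest (RF).  Evaluation is by stratified tenfold cross-validation;
fold assignment depends only on the presence vector and the seed, so it is
identical across predictor sets and techniques, giving a paired design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ENV_VARS",
    "TECHNIQUES",
    "PREDICTOR_TAGS",
    "OccurrenceStudy",
    "PredictorSet",
    "SdmFit",
    "CvResult",
    "trophic_term",
    "literature_term",
    "build_predictors",
    "fit_sdm",
    "predict_sdm",
    "cross_validate",
]

ENV_VARS = ("ddeg", "mind", "srad")
TECHNIQUES = ("glm", "gam", "gbm", "rf")
PREDICTOR_TAGS = ("abiotic", "abiotic+literature", "abiotic+foodweb")


@dataclass
class OccurrenceStudy:
    """Site x species presence/absence for both guilds plus site environments."""

    plant_occ: pd.DataFrame  # sites x plants, 0/1
    butterfly_occ: pd.DataFrame  # sites x butterflies, 0/1
    env: pd.DataFrame  # sites x (ddeg, mind, srad)

    def __post_init__(self):
        sites = list(self.plant_occ.index)
        for name, tab in (("butterfly_occ", self.butterfly_occ), ("env", self.env)):
            if list(tab.index) != sites:
                if set(tab.index) != set(sites):
                    raise ValueError(f"{name} site index differs from plant_occ")
                setattr(self, name, tab.loc[sites])
        missing = set(ENV_VARS) - set(self.env.columns)
        if missing:
            raise ValueError(f"environment table missing columns: {sorted(missing)}")
        if not np.isfinite(self.env[list(ENV_VARS)].to_numpy(float)).all():
            raise ValueError("non-finite environmental values")
        for name, tab in (("plant_occ", self.plant_occ), ("butterfly_occ", self.butterfly_occ)):
            if not np.isin(tab.to_numpy(), (0, 1)).all():
                raise ValueError(f"{name} must contain only 0/1 entries")

    @property
    def sites(self) -> list:
        return list(self.plant_occ.index)


@dataclass
class PredictorSet:
    """Per-site predictor matrix for one focal butterfly under one tag."""

    tag: str
    frame: pd.DataFrame  # index = sites
    center: pd.Series
    scale: pd.Series

    def __post_init__(self):
        if self.tag not in PREDICTOR_TAGS:
            raise ValueError(f"unknown predictor tag {self.tag!r}")


@dataclass
class SdmFit:
    """Fitted distribution model of one technique on one predictor set."""

    technique: str
    tag: str
    columns: list
    model: object
    training_sites: list
    extra: dict = field(default_factory=dict)


@dataclass
class CvResult:
    """Out-of-fold predictions for one species x technique x predictor set."""

    species: object
    technique: str
    tag: str
    oof_prob: pd.Series  # index = sites, each predicted exactly once
    fold: pd.Series
    auc: float


def trophic_term(plant_presence_row, link_probabilities_for_butterfly) -> float:
    """"Best-case scenario" trophic term: max link probability over plants present.

    Defined as 0 when no plant is present (no host available).
    """
    pres = np.asarray(plant_presence_row, float)
    p = np.asarray(link_probabilities_for_butterfly, float)
    if pres.shape != p.shape:
        raise ValueError(f"length mismatch: presences {pres.shape} vs probabilities {p.shape}")
    sel = p[pres > 0]
    return float(sel.max()) if sel.size else 0.0


def literature_term(plant_presence_row: pd.Series, known_host_set: Sequence) -> int:
    """1 iff at least one literature-known host plant is present at the site."""
    hosts = list(known_host_set)
    unknown = [h for h in hosts if h not in plant_presence_row.index]
    if unknown:
        warnings.warn(f"unknown plant ids in host set ignored: {unknown}")
    hosts = [h for h in hosts if h in plant_presence_row.index]
    if not hosts:
        return 0
    return int((plant_presence_row.loc[hosts] > 0).any())


def _biotic_column(study: OccurrenceStudy, species, tag, link_matrix, literature):
    if tag == "abiotic+foodweb":
        if link_matrix is None:
            raise ValueError("abiotic+foodweb requires a link-probability matrix")
        col = link_matrix[species].reindex(link_matrix.index)
        plants = list(link_matrix.index)
        pres = study.plant_occ[plants]
        vals = [trophic_term(pres.loc[s].to_numpy(), col.to_numpy()) for s in study.sites]
        return pd.Series(vals, index=study.sites, name="biotic")
    if tag == "abiotic+literature":
        hosts = (literature or {}).get(species, [])
        vals = [literature_term(study.plant_occ.loc[s], hosts) for s in study.sites]
        return pd.Series(vals, index=study.sites, name="biotic", dtype=float)
    raise ValueError(f"tag {tag!r} has no biotic column")


def build_predictors(
    study: OccurrenceStudy,
    species,
    tag: str,
    link_matrix: pd.DataFrame | None = None,
    literature: Mapping | None = None,
    center: pd.Series | None = None,
    scale: pd.Series | None = None,
    sites: Sequence | None = None,
) -> PredictorSet:
    """Assemble the predictor matrix for one species under one predictor set.

    Abiotic columns are the z-scored environmental variables plus their
    squares (identical across tags); the biotic column is appended last.
    ``center``/``scale`` default to statistics of the selected sites; in
    cross-validation they are computed on the training fold and re-used for
    the held-out fold.
    """
    if tag not in PREDICTOR_TAGS:
        raise ValueError(f"unknown predictor tag {tag!r}")
    sites = list(sites) if sites is not None else study.sites
    env = study.env.loc[sites, list(ENV_VARS)].astype(float)
    if center is None:
        center = env.mean()
        scale = env.std(ddof=0).replace(0.0, 1.0)
    z = (env - center) / scale
    frame = z.copy()
    for v in ENV_VARS:
        frame[f"{v}2"] = z[v] ** 2
    if tag != "abiotic":
        frame["biotic"] = _biotic_column(study, species, tag, link_matrix, literature).loc[sites]
    return PredictorSet(tag=tag, frame=frame, center=center, scale=scale)


def _spline_basis(z: np.ndarray, df: int = 4) -> np.ndarray:
    """Cubic B-spline basis on a fixed window of the standardized variable."""
    k = 3
    n_internal = df - k
    internal = np.linspace(-2.0, 2.0, n_internal + 2)[1:-1] if n_internal > 0 else []
    t = np.r_[[-4.0] * (k + 1), internal, [4.0] * (k + 1)]
    return BSpline.design_matrix(np.clip(z, -4.0, 4.0), t, k, extrapolate=False).toarray()


def _design(frame: pd.DataFrame, technique: str):
    """Technique-specific design matrix from the predictor frame."""
    if technique == "glm":
        X = frame.to_numpy(float)
    elif technique == "gam":
        blocks = [_spline_basis(frame[v].to_numpy(float)) for v in ENV_VARS]
        if "biotic" in frame.columns:
            blocks.append(frame[["biotic"]].to_numpy(float))
        X = np.hstack(blocks)
    else:  # tree ensembles use the raw (standardized linear) variables
        cols = [v for v in ENV_VARS] + (["biotic"] if "biotic" in frame.columns else [])
        X = frame[cols].to_numpy(float)
    return np.column_stack([np.ones(len(frame)), X]) if technique in ("glm", "gam") else X


def fit_sdm(
    presence_vector: pd.Series,
    predictors: PredictorSet,
    technique: str,
    seed: int = 0,
    min_presences: int = 10,
) -> SdmFit:
    """Fit one probabilistic presence/absence model; deterministic given seed.

    ``min_presences`` enforces the modelling floor of 10 occurrences; the
    cross-validation driver relaxes it per training fold (having applied the
    floor to the full dataset) so folds only need both classes present.
    """
    import statsmodels.api as sm

    if technique not in TECHNIQUES:
        raise ValueError(f"unknown technique {technique!r}; choose from {TECHNIQUES}")
    y = presence_vector.loc[predictors.frame.index].to_numpy(float)
    n_pres = int(y.sum())
    if n_pres < min_presences:
        raise ValueError(f"refusing to fit: only {n_pres} presences (< {min_presences} required)")
    if n_pres == len(y):
        raise ValueError("refusing to fit: no absences in training data")

    frame = predictors.frame
    const_cols = [c for c in frame.columns if frame[c].nunique() <= 1]
    if const_cols:
        warnings.warn(f"dropping constant predictor columns: {const_cols}")
        frame = frame.drop(columns=const_cols)

    X = _design(frame, technique)
    if technique in ("glm", "gam"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
    elif technique == "gbm":
        model = GradientBoostingClassifier(
            n_estimators=100, learning_rate=0.1, max_depth=3, random_state=seed
        ).fit(X, y)
    else:
        model = RandomForestClassifier(n_estimators=200, random_state=seed).fit(X, y)
    return SdmFit(
        technique=technique,
        tag=predictors.tag,
        columns=list(frame.columns),
        model=model,
        training_sites=list(frame.index),
    )


def predict_sdm(fit: SdmFit, predictors: PredictorSet) -> pd.Series:
    """Per-site presence probability from a fitted model."""
    frame = predictors.frame
    missing = [c for c in fit.columns if c not in frame.columns]
    if missing:
        raise ValueError(f"predictor schema mismatch, missing columns: {missing}")
    frame = frame[fit.columns]
    X = _design(frame, fit.technique)
    if fit.technique in ("glm", "gam"):
        p = np.asarray(fit.model.predict(X), float)
    else:
        p = fit.model.predict_proba(X)[:, 1]
    return pd.Series(np.clip(p, 0.0, 1.0), index=frame.index)


def cross_validate(
    study: OccurrenceStudy,
    species,
    technique: str,
    tag: str,
    k: int = 10,
    seed: int = 0,
    link_matrix: pd.DataFrame | None = None,
    literature: Mapping | None = None,
) -> CvResult:
    """Stratified k-fold cross-validation for one species/technique/tag.

    Fold assignment is a function of (presence vector, k, seed) only, so the
    out-of-fold site sets match exactly across predictor sets and
    techniques, supporting paired comparisons.  Standardization of the
    abiotic variables is refit on each training fold.
    """
    from .community import auc as _auc

    y = study.butterfly_occ[species].astype(int)
    sites = np.array(study.sites, dtype=object)
    k_eff = min(k, len(sites))
    folds = pd.Series(index=study.sites, dtype=int, name="fold")
    oof = pd.Series(index=study.sites, dtype=float, name="probability")
    n_minor = int(min(y.sum(), (1 - y).sum()))
    if k_eff <= n_minor:
        splitter = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    else:  # stratification infeasible (e.g. leave-one-out); plain shuffled folds
        from sklearn.model_selection import KFold

        splitter = KFold(n_splits=k_eff, shuffle=True, random_state=seed)
    for f, (tr, te) in enumerate(splitter.split(np.zeros(len(sites)), y.to_numpy())):
        tr_sites, te_sites = list(sites[tr]), list(sites[te])
        train = build_predictors(
            study, species, tag, link_matrix=link_matrix, literature=literature, sites=tr_sites
        )
        test = build_predictors(
            study,
            species,
            tag,
            link_matrix=link_matrix,
            literature=literature,
            center=train.center,
            scale=train.scale,
            sites=te_sites,
        )
        y_train = y.loc[tr_sites]
        if y_train.min() == y_train.max():
            raise ValueError(
                f"fold {f} has single-class training data for {species}; "
                "too few presences for stratified folds"
            )
        fit = fit_sdm(y.astype(float), train, technique, seed=seed, min_presences=1)
        oof.loc[te_sites] = predict_sdm(fit, test).to_numpy()
        folds.loc[te_sites] = f
    return CvResult(
        species=species,
        technique=technique,
        tag=tag,
        oof_prob=oof,
        fold=folds,
        auc=_auc(oof.to_numpy(), y.to_numpy()),
    )
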