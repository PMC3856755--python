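"""Community stacking and evaluation of site-level predictions.

Per-species presence probabilities are stacked into site communities with a
threshold-independent rule: predicted richness is the rounded sum of
probabilities and the community is the corresponding number of top-ranked
species.  Agreement with observed communities is measured with the Sorensen
index 2a / (2a + b + c) and richness residuals; species-level discrimination
with the rank-based (Mann-Whitney) AUC.  Model variants are compared with
paired Wilcoxon signed-rank tests (V = sum of positive-difference ranks)
and per-family differences with a Kruskal-Wallis test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CommunityPrediction",
    "EvaluationReport",
    "stack_site",
    "stack_site_resampled",
    "sorensen",
    "richness_residual",
    "auc",
    "paired_signed_rank",
    "kruskal_wallis",
    "compare_models",
]


@dataclass
class CommunityPrediction:
    """Predicted community at one site."""

    richness: int
    species: set
    probabilities: pd.Series

    def __post_init__(self):
        if len(self.species) != self.richness:
            raise ValueError("predicted set size must equal predicted richness")


@dataclass
class EvaluationReport:
    """Per-species, per-site and test-level evaluation of model variants."""

    species_auc: pd.DataFrame  # columns species, technique, tag, auc
    site_metrics: pd.DataFrame  # columns site, technique, tag, sorensen, richness_residual
    auc_tests: pd.DataFrame  # paired Wilcoxon on species AUCs, abiotic vs biotic tags
    community_tests: pd.DataFrame  # paired Wilcoxon on Sorensen and |richness residuals|
    family_test: dict | None = None  # Kruskal-Wallis across butterfly families
    metadata: dict = field(default_factory=dict)


def stack_site(probabilities_for_site: pd.Series) -> CommunityPrediction:
    """Threshold-independent stacking: round(sum p) top-ranked species.

    Richness is the summed probability rounded half-up; the community is the
    corresponding number of highest-probability species, ties broken by
    species-id order so the selection is deterministic.
    """
    p = pd.Series(probabilities_for_site, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    richness = int(np.floor(p.sum() + 0.5))
    order = sorted(p.index, key=lambda s: (-p[s], str(s)))
    return CommunityPrediction(
        richness=richness, species=set(order[:richness]), probabilities=p
    )


def stack_site_resampled(probabilities_for_site: pd.Series, seed: int) -> CommunityPrediction:
    """Probabilistic stacking variant: one Bernoulli draw per species."""
    p = pd.Series(probabilities_for_site, dtype=float)
    rng = np.random.default_rng(seed)
    draw = rng.uniform(size=len(p)) < p.to_numpy()
    members = set(p.index[draw])
    return CommunityPrediction(richness=len(members), species=members, probabilities=p)


def sorensen(predicted: set, observed: set) -> float:
    """Sorensen similarity 2a / (2a + b + c); 1.0 when both sets are empty."""
    predicted, observed = set(predicted), set(observed)
    a = len(predicted & observed)
    b = len(observed - predicted)
    c = len(predicted - observed)
    if a + b + c == 0:
        return 1.0
    return 2.0 * a / (2.0 * a + b + c)


def richness_residual(predicted_richness: int, observed_richness: int) -> int:
    """Signed richness error, predicted minus observed."""
    if predicted_richness < 0 or observed_richness < 0:
        raise ValueError("richness must be non-negative")
    return int(predicted_richness) - int(observed_richness)


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC with ties counted 0.5."""
    s = np.asarray(scores, float)
    y = np.asarray(labels)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: labels contain a single class")
    ranks = stats.rankdata(s)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def paired_signed_rank(x, y) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test.

    Returns (V, p) with V the sum of ranks of positive differences (the R
    convention).  Zero differences are dropped; p is two-sided, exact for
    n <= 25 tie-free differences and a normal approximation with continuity
    correction otherwise.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    if len(d) == 0:
        warnings.warn("all paired differences are zero")
        return 0.0, 1.0
    if len(d) < 5:
        raise ValueError(f"need >= 5 nonzero differences, got {len(d)}")
    ranks = stats.rankdata(np.abs(d))
    V = float(ranks[d > 0].sum())
    tied = len(np.unique(np.abs(d))) < len(d)
    method = "exact" if (len(d) <= 25 and not tied) else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.wilcoxon(d, alternative="two-sided", correction=True, method=method)
    return V, float(res.pvalue)


def kruskal_wallis(groups: Sequence) -> tuple[float, float]:
    """Kruskal-Wallis rank test across >= 2 groups (tie-corrected H, chi2 p)."""
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    H, p = stats.kruskal(*groups)
    return float(H), float(p)


def _stacked_site_metrics(oof: pd.DataFrame, observed: pd.DataFrame) -> pd.DataFrame:
    """Per-site Sorensen and richness residual from an out-of-fold probability table."""
    rows = []
    for site in oof.index:
        pred = stack_site(oof.loc[site])
        obs = set(observed.columns[observed.loc[site] > 0]) & set(oof.columns)
        rows.append(
            {
                "site": site,
                "sorensen": sorensen(pred.species, obs),
                "richness_residual": richness_residual(pred.richness, len(obs)),
            }
        )
    return pd.DataFrame(rows)


def compare_models(
    cv_results: Sequence,
    observed_butterflies: pd.DataFrame,
    baseline_tag: str = "abiotic",
    family_map: Mapping | None = None,
) -> EvaluationReport:
    """Evaluate and compare predictor sets from paired cross-validation runs.

    ``cv_results`` is a flat collection of CvResult objects covering
    identical species/site/fold sets across tags.  For every technique the
    species AUCs of each biotic tag are compared to the baseline with a
    paired Wilcoxon test, as are site-level Sorensen values and absolute
    richness residuals of the stacked communities.  When ``family_map``
    (butterfly species -> family) is given, a Kruskal-Wallis test asks
    whether food-web-informed predictive performance differs among families.
    """
    recs = [
        {"species": r.species, "technique": r.technique, "tag": r.tag, "auc": r.auc, "_r": r}
        for r in cv_results
    ]
    table = pd.DataFrame(recs)
    species_auc = table[["species", "technique", "tag", "auc"]].copy()

    tags = sorted(table["tag"].unique())
    if baseline_tag not in tags:
        raise ValueError(f"baseline tag {baseline_tag!r} absent from results")
    techniques = sorted(table["technique"].unique())

    cover = table.groupby(["technique", "tag"])["species"].apply(lambda s: tuple(sorted(map(str, s))))
    if len(set(cover)) != 1:
        raise ValueError("species coverage differs across technique/tag combinations")

    auc_rows, site_rows, comm_rows = [], [], []
    site_metric_cache: dict = {}
    for tech in techniques:
        sub = table[table["technique"] == tech]
        base = sub[sub["tag"] == baseline_tag].sort_values("species", key=lambda s: s.astype(str))
        oof_by_tag = {}
        for tag in tags:
            part = sub[sub["tag"] == tag]
            oof = pd.DataFrame({r.species: r.oof_prob for r in part["_r"]})
            oof_by_tag[tag] = oof
            m = _stacked_site_metrics(oof, observed_butterflies)
            m.insert(0, "technique", tech)
            m.insert(1, "tag", tag)
            site_rows.append(m)
            site_metric_cache[(tech, tag)] = m
        for tag in tags:
            if tag == baseline_tag:
                continue
            alt = sub[sub["tag"] == tag].sort_values("species", key=lambda s: s.astype(str))
            folds_match = all(
                rb.fold.equals(ra.fold)
                for rb, ra in zip(base["_r"], alt["_r"])
            )
            if not folds_match:
                raise ValueError(f"fold assignments differ between {baseline_tag} and {tag}")
            V, p = paired_signed_rank(alt["auc"].to_numpy(), base["auc"].to_numpy())
            auc_rows.append(
                {"technique": tech, "comparison": f"{tag} vs {baseline_tag}", "V": V, "p": p}
            )
            mb = site_metric_cache[(tech, baseline_tag)]
            ma = site_metric_cache[(tech, tag)]
            for metric, transform in (("sorensen", lambda v: v), ("richness_residual", np.abs)):
                V2, p2 = paired_signed_rank(
                    transform(ma[metric].to_numpy()), transform(mb[metric].to_numpy())
                )
                comm_rows.append(
                    {
                        "technique": tech,
                        "comparison": f"{tag} vs {baseline_tag}",
                        "metric": "abs_richness_residual" if metric == "richness_residual" else metric,
                        "V": V2,
                        "p": p2,
                    }
                )

    family_test = None
    if family_map is not None:
        fw = table[table["tag"].str.contains("foodweb")]
        if len(fw):
            fw = fw.assign(family=[family_map.get(s) for s in fw["species"]])
            groups = [g["auc"].to_numpy() for _, g in fw.groupby("family") if len(g)]
            if len(groups) >= 2:
                H, p = kruskal_wallis(groups)
                family_test = {"H": H, "p": p, "n_families": len(groups)}

    return EvaluationReport(
        species_auc=species_auc,
        site_metrics=pd.concat(site_rows, ignore_index=True),
        auc_tests=pd.DataFrame(auc_rows),
        community_tests=pd.DataFrame(comm_rows),
        family_test=family_test,
        metadata={"baseline_tag": baseline_tag, "richness_residual_sign": "predicted-observed"},
    )
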