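"""Readers and writers for the package's plain-text interchange formats.

Interaction matrices, masks, trait and occurrence tables are CSV with
species/site labels as headers; trees are Newick with branch lengths;
fitted link-model parameters travel as a single JSON document carrying the
parameter vector, latent-trait tables with provenance, the trait
standardization, and a config/seed echo.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd

from .foodweb import LinkModelParams, PlantTraits, TrophicWeb
from .sdm import OccurrenceStudy

__all__ = [
    "read_web",
    "write_web",
    "read_traits",
    "write_traits",
    "read_tree",
    "write_tree",
    "read_occurrences",
    "write_occurrences",
    "read_params",
    "write_params",
    "read_link_matrix",
    "write_link_matrix",
]


def read_web(links_path, mask_path) -> TrophicWeb:
    """Interaction matrix + mask CSVs (plants as rows, butterflies as columns)."""
    links = pd.read_csv(links_path, index_col=0)
    mask = pd.read_csv(mask_path, index_col=0)
    if list(links.index) != list(mask.index) or list(links.columns) != list(mask.columns):
        raise ValueError("links and mask label sets differ")
    return TrophicWeb(
        plant_ids=list(links.index),
        butterfly_ids=list(links.columns),
        links=links.to_numpy(),
        mask=mask.to_numpy(),
    )


def write_web(web: TrophicWeb, links_path, mask_path) -> None:
    pd.DataFrame(web.links, index=web.plant_ids, columns=web.butterfly_ids).to_csv(links_path)
    pd.DataFrame(web.mask, index=web.plant_ids, columns=web.butterfly_ids).to_csv(mask_path)


def read_traits(path) -> PlantTraits:
    frame = pd.read_csv(path, index_col="species")
    return PlantTraits(frame[["nitrogen", "avg_height"]])


def write_traits(traits: PlantTraits, path) -> None:
    out = traits.frame[["nitrogen", "avg_height"]].copy()
    out.index.name = "species"
    out.to_csv(path)


def read_tree(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_occurrences(plant_path, butterfly_path, env_path) -> OccurrenceStudy:
    plant = pd.read_csv(plant_path, index_col=0)
    bfly = pd.read_csv(butterfly_path, index_col=0)
    env = pd.read_csv(env_path, index_col=0)
    return OccurrenceStudy(plant_occ=plant, butterfly_occ=bfly, env=env)


def write_occurrences(occ: OccurrenceStudy, plant_path, butterfly_path, env_path) -> None:
    occ.plant_occ.to_csv(plant_path)
    occ.butterfly_occ.to_csv(butterfly_path)
    occ.env.to_csv(env_path)


def _latents_to_dict(table: pd.DataFrame, cols) -> dict:
    out = {}
    for sp, row in table.iterrows():
        rec = {c: float(row[c]) for c in cols}
        rec["provenance"] = str(row["provenance"]) if "provenance" in table.columns else "fitted"
        out[str(sp)] = rec
    return out


def write_params(params: LinkModelParams, path, extra: Mapping | None = None) -> None:
    doc = {
        "alpha": params.alpha,
        "beta_nitrogen": params.beta_nitrogen,
        "beta_height": params.beta_height,
        "delta": [float(d) for d in params.delta],
        "trait_center": None
        if params.trait_center is None
        else [float(x) for x in np.asarray(params.trait_center)],
        "trait_scale": None
        if params.trait_scale is None
        else [float(x) for x in np.asarray(params.trait_scale)],
        "plant_latents": _latents_to_dict(params.plant_latents, ["v1", "v2"]),
        "butterfly_latents": _latents_to_dict(params.butterfly_latents, ["f1", "f2"]),
        "meta": dict(extra or {}),
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def read_params(path) -> LinkModelParams:
    doc = json.loads(Path(path).read_text())
    plant = pd.DataFrame.from_dict(doc["plant_latents"], orient="index")
    bfly = pd.DataFrame.from_dict(doc["butterfly_latents"], orient="index")
    return LinkModelParams(
        alpha=float(doc["alpha"]),
        beta_nitrogen=float(doc["beta_nitrogen"]),
        beta_height=float(doc["beta_height"]),
        delta=tuple(doc["delta"]),
        plant_latents=plant,
        butterfly_latents=bfly,
        trait_center=None if doc["trait_center"] is None else np.asarray(doc["trait_center"]),
        trait_scale=None if doc["trait_scale"] is None else np.asarray(doc["trait_scale"]),
    )


def read_link_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_link_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path)
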