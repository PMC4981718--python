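"""Similarity-downweighted genome weights, abundance and prevalence.

To compensate for database sampling bias, each genome's contribution to
family statistics is downweighted when it has many close relatives.  A
neighbor-joining tree is built from the compositional distance matrix,
rooted at its midpoint, and Gerstein–Sonnhammer–Chothia (GSC) weights are
extracted: each edge's length is divided equally among the leaves below it
and a leaf's raw weight is the sum along its root path.  Weights are
normalised to sum to 1.

Family *abundance* is the summed weight of genomes carrying the family
(1 means present in every genome); *prevalence* in a genome group is the
carried weight divided by the group's total weight.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skbio import DistanceMatrix as SkbioDM
from skbio import TreeNode
from skbio.tree import nj

from .coregenes import DistanceMatrix
from .genomes import GenomeSet


def gsc_weights(tree: TreeNode) -> dict[str, float]:
    """Raw Gerstein–Sonnhammer–Chothia leaf weights on a rooted tree.

    Negative branch lengths (an artefact of neighbor joining) are clamped
    to zero.  If every branch length is zero the weights are uniform.
    """
    leaf_count: dict[int, int] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            leaf_count[id(node)] = 1
        else:
            leaf_count[id(node)] = sum(leaf_count[id(c)] for c in node.children)
    acc: dict[int, float] = {id(tree): 0.0}
    weights: dict[str, float] = {}
    for node in tree.preorder(include_self=False):
        length = max(node.length or 0.0, 0.0)
        acc[id(node)] = acc[id(node.parent)] + length / leaf_count[id(node)]
        if node.is_tip():
            weights[str(node.name)] = acc[id(node)]
    if sum(weights.values()) == 0.0:
        return {name: 1.0 for name in weights}
    return weights


def genome_weights(distances: DistanceMatrix) -> pd.Series:
    """Normalised GSC weights from an NJ tree of the distance matrix.

    Trees with fewer than 3 genomes are degenerate for neighbor joining;
    such sets get uniform weights (the symmetric limit).
    """
    ids = distances.ids
    n = len(ids)
    if n == 0:
        raise ValueError("no genomes")
    if n <= 2:
        return pd.Series(1.0 / n, index=ids)
    tree = nj(SkbioDM(distances.values, ids))
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            node.length = 0.0
    try:
        tree = tree.root_at_midpoint()
    except Exception:
        pass  # zero-diameter trees cannot be midpoint-rooted; keep NJ rooting
    raw = gsc_weights(tree)
    w = np.array([raw[g] for g in ids], dtype=float)
    if np.any(w <= 0):
        # leaves on an all-zero root path (identical genomes) share weight;
        # keep them strictly positive as a tiny fraction of the largest
        floor = max(w.max(), 1.0) * 1e-9
        w = np.maximum(w, floor)
    w = w / w.sum()
    return pd.Series(w, index=ids)


def family_abundance(family_id: str, genomes: GenomeSet, weights: pd.Series) -> float:
    """Sum of weights of genomes carrying the family; in [0, 1]."""
    if family_id not in set(genomes.family_ids):
        raise ValueError(f"unknown family {family_id}")
    return float(sum(weights[g] for g in genomes.genomes_with_family(family_id)))


def family_prevalence(
    family_id: str,
    group: set[str],
    genomes: GenomeSet,
    weights: pd.Series,
) -> float:
    """Weight of carriers within ``group`` divided by the group's total weight."""
    if not group:
        raise ValueError("group must be non-empty")
    total = float(sum(weights[g] for g in group))
    carriers = set(genomes.genomes_with_family(family_id)) & group
    return float(sum(weights[g] for g in carriers)) / total


def abundance_table(genomes: GenomeSet, weights: pd.Series) -> pd.Series:
    """Abundance for every family at once (vectorised)."""
    P = genomes.presence_matrix()
    w = weights.reindex(P.index).to_numpy()
    return pd.Series(P.to_numpy().T @ w, index=P.columns)


def prevalence_table(
    genomes: GenomeSet, groups: dict[str, set[str]], weights: pd.Series
) -> pd.DataFrame:
    """Prevalence of every family (rows) in every genome group (columns)."""
    P = genomes.presence_matrix()
    w = weights.reindex(P.index).to_numpy()
    cols = {}
    index = {g: i for i, g in enumerate(P.index)}
    for name, group in groups.items():
        rows = [index[g] for g in group if g in index]
        if not rows:
            raise ValueError(f"group {name} has no genomes in the set")
        sub_w = w[rows]
        cols[name] = (P.to_numpy()[rows].T @ sub_w) / sub_w.sum()
    return pd.DataFrame(cols, index=P.columns)
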