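"""Hallmark, connector and signature gene classification; betweenness shares.

Hallmark genes are connectors between primary modules whose weighted
prevalence exceeds 0.35 in at least one of the two major supermodules (the
two with the most genomes).  Signature genes are diagnostic of a single
module: normalized mutual information (MI) above 0.6 with their best-
matching module and below 0.02 with the second best.  The MI between a
gene's presence pattern and a module keeps only the agreement terms,

    MI = a log2[a / ((a+b)(a+c))] + d log2[d / ((c+d)(b+d))],

where a, b, c, d are the summed relative genome weights of in-module
carriers, out-module carriers, in-module non-carriers and out-module
non-carriers (a+b+c+d = 1); it is normalised by the joint entropy
H = -Σ i log2 i with the 0·log 0 := 0 convention.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pandas as pd

from .genomes import GenomeSet
from .hierarchy import ConnectorTable, HierarchyTree
from .network import BipartiteNetwork

HALLMARK_PREVALENCE = 0.35
SIGNATURE_BEST = 0.6
SIGNATURE_SECOND = 0.02


def _xlog2(v: float) -> float:
    return 0.0 if v <= 0.0 else v * math.log2(v)


def mutual_information_cells(a: float, b: float, c: float, d: float) -> float:
    """Normalised MI from the four weight cells (must sum to 1)."""
    total = a + b + c + d
    if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValueError(f"cells must sum to 1, got {total}")
    mi = 0.0
    if a > 0:
        mi += a * math.log2(a / ((a + b) * (a + c)))
    if d > 0:
        mi += d * math.log2(d / ((c + d) * (b + d)))
    h = -(_xlog2(a) + _xlog2(b) + _xlog2(c) + _xlog2(d))
    if h == 0.0:
        return 0.0
    return mi / h


def normalized_mutual_information(
    family_id: str,
    module: set[str],
    genomes: GenomeSet,
    weights: pd.Series,
) -> float:
    """Normalised MI between a family's presence pattern and a genome module."""
    w = weights / weights.sum()
    carriers = set(genomes.genomes_with_family(family_id))
    a = float(sum(w[g] for g in module if g in carriers))
    b = float(sum(w[g] for g in carriers if g not in module))
    c = float(sum(w[g] for g in module if g not in carriers))
    d = max(0.0, 1.0 - a - b - c)
    return mutual_information_cells(a, b, c, d)


def mi_table(
    genomes: GenomeSet,
    modules: dict[str, set[str]],
    weights: pd.Series,
    families=None,
) -> pd.DataFrame:
    """Normalised MI of every family (rows) against every module (columns)."""
    P = genomes.presence_matrix()
    if families is not None:
        P = P[[f for f in P.columns if f in set(families)]]
    w = (weights / weights.sum()).reindex(P.index).to_numpy()
    pres = P.to_numpy()
    cols = {}
    for name, module in modules.items():
        inmod = np.array([g in module for g in P.index])
        a = pres[inmod].T @ w[inmod]
        b = pres[~inmod].T @ w[~inmod]
        c = (~pres[inmod]).T @ w[inmod]
        d = np.maximum(0.0, 1.0 - a - b - c)
        with np.errstate(divide="ignore", invalid="ignore"):
            mi = np.where(
                a > 0, a * np.log2(np.maximum(a, 1e-300) / ((a + b) * (a + c))), 0.0
            )
            mi += np.where(
                d > 0, d * np.log2(np.maximum(d, 1e-300) / ((c + d) * (b + d))), 0.0
            )
            h = np.zeros_like(a)
            for cell in (a, b, c, d):
                h -= np.where(cell > 0, cell * np.log2(np.maximum(cell, 1e-300)), 0.0)
        vals = np.where(h > 0, mi / np.maximum(h, 1e-300), 0.0)
        cols[name] = vals
    return pd.DataFrame(cols, index=P.columns)


def classify_hallmark(
    connectors: ConnectorTable,
    supermodules: dict[str, set[str]] | HierarchyTree,
    genomes: GenomeSet,
    weights: pd.Series,
    prevalence_threshold: float = HALLMARK_PREVALENCE,
) -> pd.DataFrame:
    """Hallmark flags: connector AND prevalence > threshold in a major supermodule.

    The two "major" supermodules are the two containing the most genomes.
    With fewer than two supermodules the hallmark set is empty.
    """
    if isinstance(supermodules, HierarchyTree):
        supermodules = supermodules.supermodules()
    fams = list(connectors.prevalence.index)
    conn = connectors.connectors
    if len(supermodules) < 2:
        return pd.DataFrame(
            {
                "family_id": fams,
                "connector": [f in conn for f in fams],
                "max_major_prevalence": np.nan,
                "hallmark": False,
            }
        )
    major = sorted(supermodules, key=lambda s: (-len(supermodules[s]), s))[:2]
    from .weights import prevalence_table

    prev = prevalence_table(genomes, {s: supermodules[s] for s in major}, weights)
    prev = prev.reindex(fams).fillna(0.0)
    max_prev = prev.max(axis=1)
    rows = pd.DataFrame(
        {
            "family_id": fams,
            "connector": [f in conn for f in fams],
            "max_major_prevalence": max_prev.to_numpy(),
            "hallmark": [
                (f in conn) and (max_prev[f] > prevalence_threshold) for f in fams
            ],
        }
    )
    return rows


def classify_signature(
    mi: pd.DataFrame,
    best_threshold: float = SIGNATURE_BEST,
    second_threshold: float = SIGNATURE_SECOND,
) -> pd.DataFrame:
    """Signature flags from the family × module MI table.

    Signature ⇔ best MI > ``best_threshold`` and second-best MI <
    ``second_threshold``; with a single module the second-best MI is 0.
    """
    vals = mi.to_numpy()
    order = np.argsort(-vals, axis=1)
    best = vals[np.arange(len(mi)), order[:, 0]]
    best_module = mi.columns.to_numpy()[order[:, 0]]
    if vals.shape[1] >= 2:
        second = vals[np.arange(len(mi)), order[:, 1]]
    else:
        second = np.zeros(len(mi))
    return pd.DataFrame(
        {
            "family_id": mi.index,
            "mi_best": best,
            "mi_second": second,
            "best_module": best_module,
            "signature": (best > best_threshold) & (second < second_threshold),
        }
    ).set_index("family_id", drop=False)


def classify_genes(
    connectors: ConnectorTable,
    supermodules: dict[str, set[str]] | HierarchyTree,
    modules: dict[str, set[str]],
    genomes: GenomeSet,
    weights: pd.Series,
    families=None,
    prevalence_threshold: float = HALLMARK_PREVALENCE,
    best_threshold: float = SIGNATURE_BEST,
    second_threshold: float = SIGNATURE_SECOND,
) -> pd.DataFrame:
    """Full gene class table: hallmark > connector > signature > other."""
    fams = list(families) if families is not None else list(connectors.prevalence.index)
    hall = classify_hallmark(
        connectors, supermodules, genomes, weights, prevalence_threshold
    ).set_index("family_id")
    mi = mi_table(genomes, modules, weights, families=fams)
    sig = classify_signature(mi, best_threshold, second_threshold)
    rows = []
    conn = connectors.connectors
    for f in fams:
        is_hall = bool(hall["hallmark"].get(f, False))
        is_conn = f in conn
        is_sig = bool(sig["signature"].get(f, False))
        if is_hall:
            cls = "hallmark"
        elif is_conn:
            cls = "connector"
        elif is_sig:
            cls = "signature"
        else:
            cls = "other"
        rows.append(
            (
                f,
                is_conn,
                is_hall,
                is_sig,
                sig["best_module"].get(f),
                float(sig["mi_best"].get(f, np.nan)),
                float(sig["mi_second"].get(f, np.nan)),
                float(hall["max_major_prevalence"].get(f, np.nan)),
                cls,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "family_id",
            "connector",
            "hallmark",
            "signature",
            "best_module",
            "mi_best",
            "mi_second",
            "max_major_prevalence",
            "gene_class",
        ],
    )


def betweenness_accounting(
    network: BipartiteNetwork,
    classes: pd.DataFrame,
    top_n: int = 50,
) -> dict:
    """Shortest-path betweenness shares of each gene class.

    Returns the per-node betweenness, the share of total family-node
    betweenness held by each class, and the class composition of the
    ``top_n`` family nodes by betweenness.  On a disconnected network the
    centralities are still exact (paths within components); a flag notes it.
    """
    bc = nx.betweenness_centrality(network.graph, normalized=True)
    cls = classes.set_index("family_id")["gene_class"] if len(classes) else pd.Series(dtype=object)
    fam_bc = pd.DataFrame(
        {
            "family_id": network.families,
            "betweenness": [bc[f] for f in network.families],
        }
    )
    fam_bc["gene_class"] = [cls.get(f, "other") for f in network.families]
    total = fam_bc["betweenness"].sum()
    if total > 0:
        shares = (
            fam_bc.groupby("gene_class")["betweenness"].sum() / total
        ).to_dict()
    else:
        shares = {}
    top = fam_bc.sort_values("betweenness", ascending=False).head(top_n)
    return {
        "node_betweenness": bc,
        "family_table": fam_bc,
        "class_shares": shares,
        "top_composition": top["gene_class"].value_counts().to_dict(),
        "top_table": top,
        "connected": nx.is_connected(network.graph),
    }
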