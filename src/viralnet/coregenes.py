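"""Core-gene inference under a pure-loss gene-content divergence model.

Pairwise genome distances are compositional: D = -ln(S / sqrt(N_i * N_j)),
with S the number of shared families and N the repertoire sizes; disjoint
pairs get the conservative bound ln(1 + sqrt(N_i * N_j)).  For each family,
conditional on presence in a pair's common ancestor and on not being absent
from both genomes, the pattern probabilities at distance D are

    P11 = exp(-r D) / Z,
    P10 = 2 exp(-r D / 2) (1 - exp(-r D / 2)) / Z,   Z = P11 + P10,

and the family-specific loss rate r is the maximiser of the pairwise
log-likelihood over genome pairs closer than ``max_distance`` (distant
pairs are excluded to limit the influence of horizontal transfer).  A
family is "core" when r < 1, i.e. its retention probability exp(-r)
exceeds exp(-1), provided it appears in at least three genomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .genomes import GenomeSet

R_MIN = 1e-6
R_MAX = 50.0


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if not np.all(np.isfinite(v)):
            raise ValueError("distances must be finite")
        self.values = v

    def get(self, gi: str, gj: str) -> float:
        idx = {g: i for i, g in enumerate(self.ids)}
        return float(self.values[idx[gi], idx[gj]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def compositional_distance(fi: frozenset, fj: frozenset) -> float:
    """-ln(S / sqrt(N_i N_j)); ln(1 + sqrt(N_i N_j)) for disjoint repertoires."""
    if not fi or not fj:
        raise ValueError("genomes must be non-empty")
    ni, nj = len(fi), len(fj)
    s = len(fi & fj)
    if s == 0:
        return math.log(1.0 + math.sqrt(ni * nj))
    return max(0.0, -math.log(s / math.sqrt(ni * nj)))


def distance_matrix(genomes: GenomeSet) -> DistanceMatrix:
    """All-pairs compositional distances (vectorised over the presence matrix)."""
    P = genomes.presence_matrix().to_numpy()
    n_fam = P.sum(axis=1).astype(float)
    if np.any(n_fam == 0):
        empty = [g for g, n in zip(genomes.genome_ids, n_fam) if n == 0]
        raise ValueError(f"empty genome(s): {empty[:5]}")
    S = (P.astype(np.int64) @ P.T.astype(np.int64)).astype(float)
    geo = np.sqrt(np.outer(n_fam, n_fam))
    with np.errstate(divide="ignore"):
        D = -np.log(S / geo)
    D[S == 0] = np.log(1.0 + geo[S == 0])
    np.fill_diagonal(D, 0.0)
    D = np.maximum(D, 0.0)
    D = (D + D.T) / 2.0
    return DistanceMatrix(genomes.genome_ids, D)


def pattern_probabilities(r: float, d: float) -> tuple[float, float]:
    """(P11, P10) at loss rate r and distance d; they sum to 1."""
    if r <= 0 or d < 0:
        raise ValueError("r must be > 0 and d >= 0")
    x = math.exp(-r * d / 2.0)  # per-lineage retention over the pair
    z = x * x + 2.0 * x * (1.0 - x)
    if z == 0.0:
        return 0.0, 0.0
    return x * x / z, 2.0 * x * (1.0 - x) / z


def _pair_loglik(r: float, d11: np.ndarray, d10: np.ndarray) -> float:
    x11 = np.exp(-r * d11 / 2.0)
    x10 = np.exp(-r * d10 / 2.0)
    with np.errstate(divide="ignore"):
        ll = np.sum(np.log(x11) - np.log(2.0 - x11))
        ll += np.sum(np.log(2.0 * x10 * (1.0 - x10)) - np.log(x10 * (2.0 - x10)))
    return float(ll)


@dataclass
class LossRateEstimate:
    r: float
    n11: int
    n10: int
    at_boundary: bool

    @property
    def retention(self) -> float:
        return math.exp(-self.r)


def _eligible_pairs(distances: DistanceMatrix, max_distance: float):
    D = distances.values
    iu, ju = np.triu_indices(len(distances.ids), k=1)
    mask = D[iu, ju] < max_distance
    return iu[mask], ju[mask], D[iu, ju][mask]


def _estimate_from_patterns(d11: np.ndarray, d10: np.ndarray) -> LossRateEstimate:
    if d11.size + d10.size == 0:
        raise ValueError("no informative pair")
    if d10.size == 0:
        # no observed loss: likelihood decreases with r
        return LossRateEstimate(R_MIN, d11.size, 0, True)
    res = minimize_scalar(
        lambda r: -_pair_loglik(r, d11, d10),
        bounds=(R_MIN, R_MAX),
        method="bounded",
        options={"xatol": 1e-7},
    )
    r = float(res.x)
    at_boundary = r <= R_MIN * 1.01 or r >= R_MAX * 0.999
    return LossRateEstimate(r, d11.size, d10.size, at_boundary)


def estimate_loss_rate(
    family_id: str,
    genomes: GenomeSet,
    distances: DistanceMatrix,
    max_distance: float = 1.0,
) -> LossRateEstimate | None:
    """ML loss rate for one family over genome pairs with D < ``max_distance``.

    Pairs lacking the family in both genomes are discarded (no evidence the
    ancestor had it).  Returns None when no eligible informative pair exists.
    Raises if the family is absent from every genome.
    """
    carriers = set(genomes.genomes_with_family(family_id))
    if not carriers:
        raise ValueError(f"family {family_id} absent from every genome")
    idx = {g: i for i, g in enumerate(distances.ids)}
    present = np.zeros(len(distances.ids), dtype=bool)
    for g in carriers:
        present[idx[g]] = True
    iu, ju, d = _eligible_pairs(distances, max_distance)
    pi, pj = present[iu], present[ju]
    d11 = d[pi & pj]
    d10 = d[pi ^ pj]
    if d11.size + d10.size == 0:
        return None
    return _estimate_from_patterns(d11, d10)


def classify_core(
    genomes: GenomeSet,
    distances: DistanceMatrix,
    max_distance: float = 1.0,
    core_rate_threshold: float = 1.0,
    min_appearances: int = 3,
) -> pd.DataFrame:
    """Loss rate, retention and core flag for every family.

    Returns a DataFrame with columns family_id, appearances, n_pairs, r,
    retention, core, at_boundary.  Families with fewer than
    ``min_appearances`` appearances, or with no eligible pair, get NaN rate
    and ``core=False``.
    """
    P = genomes.presence_matrix()
    order = {g: i for i, g in enumerate(distances.ids)}
    row = np.array([order[g] for g in P.index])
    pres = np.zeros((len(distances.ids), P.shape[1]), dtype=bool)
    pres[row, :] = P.to_numpy()
    iu, ju, d = _eligible_pairs(distances, max_distance)
    rows = []
    for j, fid in enumerate(P.columns):
        col = pres[:, j]
        appearances = int(col.sum())
        r = math.nan
        retention = math.nan
        n_pairs = 0
        boundary = False
        if appearances >= min_appearances:
            pi, pj = col[iu], col[ju]
            d11 = d[pi & pj]
            d10 = d[pi ^ pj]
            n_pairs = int(d11.size + d10.size)
            if n_pairs > 0:
                est = _estimate_from_patterns(d11, d10)
                r = est.r
                retention = est.retention
                boundary = est.at_boundary
        core = bool(
            appearances >= min_appearances
            and not math.isnan(r)
            and r < core_rate_threshold
        )
        rows.append((fid, appearances, n_pairs, r, retention, core, boundary))
    return pd.DataFrame(
        rows,
        columns=[
            "family_id",
            "appearances",
            "n_pairs",
            "r",
            "retention",
            "core",
            "at_boundary",
        ],
    )
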