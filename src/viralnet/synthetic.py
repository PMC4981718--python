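"""Synthetic genome × gene-family data with known ground truth.

Two generators are provided:

* :func:`simulate_pure_loss` evolves an ancestral gene repertoire down a
  phylogeny under a pure-loss process (each family lost independently at its
  own rate along each branch).  This is the generative counterpart of the
  loss-rate estimator: for a leaf pair at path distance ``D`` the expected
  fraction of ancestral families retained in both is ``exp(-r*D)``.

* :func:`generate_planted_network` builds a block-structured incidence
  matrix with planted modules and supermodules held together by four gene
  archetypes — signature genes (module-exclusive), connector genes (shared
  by a designated module pair), hallmark genes (spread across all modules
  of a supermodule) — plus per-genome ORFans and global noise families.

Both return a :class:`~viralnet.genomes.GenomeSet` together with a
:class:`SimulationTruth` carrying the planted labels for recovery tests.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

from .genomes import GenomeSet

FAMILY_CLASSES = ("signature", "connector", "hallmark", "orfan", "noise", "ancestral")


@dataclass
class PlantedConfig:
    """Layout and signal strengths of a planted modular network.

    Counts are per the unit named in the field; probabilities are per-genome
    presence probabilities.  A config is "strong-signal" when the three
    archetype probabilities all exceed exp(-1), the prevalence threshold the
    downstream analysis uses to call connectors.
    """

    n_supermodules: int = 2
    modules_per_supermodule: int = 3
    genomes_per_module: int = 12
    n_signature_per_module: int = 5
    p_signature: float = 0.9
    n_connector_per_module_pair: int = 3
    p_connector: float = 0.9
    n_hallmark_per_supermodule: int = 6
    p_hallmark: float = 0.9
    n_orfans_per_genome: int = 12
    n_noise_families: int = 10
    p_noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_supermodules",
            "modules_per_supermodule",
            "genomes_per_module",
            "n_signature_per_module",
            "n_connector_per_module_pair",
            "n_hallmark_per_supermodule",
            "n_orfans_per_genome",
            "n_noise_families",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("p_signature", "p_connector", "p_hallmark", "p_noise"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")

    @property
    def strong_signal(self) -> bool:
        thr = math.exp(-1)
        return min(self.p_signature, self.p_connector, self.p_hallmark) > thr


@dataclass
class SimulationTruth:
    """Ground-truth labels for a simulated GenomeSet."""

    genome_module: dict[str, str] = field(default_factory=dict)
    genome_supermodule: dict[str, str] = field(default_factory=dict)
    family_class: dict[str, str] = field(default_factory=dict)
    family_module: dict[str, str] = field(default_factory=dict)
    family_loss_rate: dict[str, float] = field(default_factory=dict)
    tree_newick: str | None = None

    def families_of_class(self, cls: str) -> set[str]:
        return {f for f, c in self.family_class.items() if c == cls}


def simulate_pure_loss(
    tree: str,
    n_ancestral_families: int,
    loss_rates,
    seed: int,
) -> tuple[GenomeSet, SimulationTruth]:
    """Evolve an ancestral repertoire down ``tree`` under pure gene loss.

    Every family is present at the root; along a branch of length ``t`` it
    is lost with probability ``1 - exp(-r * t)``, independently per family
    and branch.  Leaves become genomes named after the leaf labels.

    Parameters
    ----------
    tree
        Newick string with branch lengths.
    n_ancestral_families
        Number of families in the ancestral repertoire.
    loss_rates
        Positive per-family loss rates, length ``n_ancestral_families``.
    seed
        Seed for the loss draws.
    """
    rates = np.asarray(loss_rates, dtype=float)
    if rates.shape != (n_ancestral_families,):
        raise ValueError(
            f"loss_rates must have length {n_ancestral_families}, got {rates.shape}"
        )
    if np.any(rates <= 0):
        raise ValueError("all loss rates must be > 0")
    try:
        root = TreeNode.read(io.StringIO(tree))
    except Exception as exc:  # skbio raises several parse error types
        raise ValueError(f"malformed newick tree: {exc}") from exc
    leaves = list(root.tips())
    if len(leaves) < 2:
        raise ValueError("tree must have at least 2 leaves")

    rng = np.random.default_rng(seed)
    fam_ids = [f"F{j:05d}" for j in range(n_ancestral_families)]
    presence_at: dict[int, np.ndarray] = {
        id(root): np.ones(n_ancestral_families, dtype=bool)
    }
    memberships: dict[str, dict[str, int]] = {}
    for node in root.preorder(include_self=False):
        t = node.length or 0.0
        if t < 0:
            raise ValueError("branch lengths must be >= 0")
        parent_mask = presence_at[id(node.parent)]
        survive = rng.random(n_ancestral_families) < np.exp(-rates * t)
        mask = parent_mask & survive
        presence_at[id(node)] = mask
        if node.is_tip():
            name = node.name or f"leaf{len(memberships)}"
            memberships[str(name)] = {fam_ids[j]: 1 for j in np.nonzero(mask)[0]}
    truth = SimulationTruth(
        family_class={f: "ancestral" for f in fam_ids},
        family_loss_rate=dict(zip(fam_ids, rates.tolist())),
        tree_newick=tree,
    )
    # families lost everywhere are unobservable and omitted from the GenomeSet
    genomes = GenomeSet(memberships)
    return genomes, truth


def generate_planted_network(config: PlantedConfig) -> tuple[GenomeSet, SimulationTruth]:
    """Build a GenomeSet with planted modules, supermodules and gene archetypes.

    Signature families appear only in their module, connector families only
    in a designated pair of modules of the same supermodule, hallmark
    families across every module of one supermodule, ORFan families in a
    single genome each, and noise families independently everywhere.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    truth = SimulationTruth()

    module_genomes: dict[str, list[str]] = {}
    for s in range(config.n_supermodules):
        sm = f"S{s}"
        for m in range(config.modules_per_supermodule):
            mod = f"S{s}.M{m}"
            gids = [f"{mod}.G{i:03d}" for i in range(config.genomes_per_module)]
            module_genomes[mod] = gids
            for g in gids:
                truth.genome_module[g] = mod
                truth.genome_supermodule[g] = sm
    all_genomes = [g for gids in module_genomes.values() for g in gids]
    if not all_genomes:
        raise ValueError("config yields zero genomes")

    memberships: dict[str, dict[str, int]] = {g: {} for g in all_genomes}

    def _plant(fid: str, carriers: list[str], p: float, cls: str, mod: str | None):
        truth.family_class[fid] = cls
        if mod is not None:
            truth.family_module[fid] = mod
        for g in carriers:
            if p >= 1.0 or rng.random() < p:
                memberships[g][fid] = 1

    for mod, gids in module_genomes.items():
        for j in range(config.n_signature_per_module):
            _plant(f"sig.{mod}.{j}", gids, config.p_signature, "signature", mod)

    # connectors link every pair of modules within a supermodule
    for s in range(config.n_supermodules):
        mods = [f"S{s}.M{m}" for m in range(config.modules_per_supermodule)]
        for a in range(len(mods)):
            for b in range(a + 1, len(mods)):
                carriers = module_genomes[mods[a]] + module_genomes[mods[b]]
                for j in range(config.n_connector_per_module_pair):
                    _plant(
                        f"con.{mods[a]}-{mods[b]}.{j}",
                        carriers,
                        config.p_connector,
                        "connector",
                        None,
                    )

    for s in range(config.n_supermodules):
        mods = [f"S{s}.M{m}" for m in range(config.modules_per_supermodule)]
        carriers = [g for m in mods for g in module_genomes[m]]
        for j in range(config.n_hallmark_per_supermodule):
            _plant(f"hal.S{s}.{j}", carriers, config.p_hallmark, "hallmark", None)

    for g in all_genomes:
        for j in range(config.n_orfans_per_genome):
            fid = f"orf.{g}.{j}"
            truth.family_class[fid] = "orfan"
            memberships[g][fid] = 1

    for j in range(config.n_noise_families):
        _plant(f"noise.{j}", all_genomes, config.p_noise, "noise", None)

    if not truth.family_class:
        raise ValueError("config yields zero families")
    # guarantee every genome is observable (network nodes need degree >= 1)
    for g in all_genomes:
        if not memberships[g]:
            fid = f"orf.{g}.rescue"
            truth.family_class[fid] = "orfan"
            memberships[g][fid] = 1
    genomes = GenomeSet(memberships)
    return genomes, truth


def attach_lifestyles(
    genomes: GenomeSet,
    truth: SimulationTruth,
    p_temperate_by_module: dict[str, float],
    coverage: float,
    seed: int,
) -> GenomeSet:
    """Label a fraction ``coverage`` of each module's genomes with a lifestyle.

    Labeled genomes are temperate with the module's probability and virulent
    otherwise; unlabeled genomes are ``unknown``.
    """
    if not 0.0 <= coverage <= 1.0:
        raise ValueError("coverage must be in [0, 1]")
    for mod, p in p_temperate_by_module.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p_temperate for module {mod} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    modules: dict[str, list[str]] = {}
    for g in genomes.genome_ids:
        mod = truth.genome_module.get(g)
        if mod is None:
            continue
        modules.setdefault(mod, []).append(g)
    lifestyle = {g: "unknown" for g in genomes.genome_ids}
    for mod, gids in modules.items():
        if mod not in p_temperate_by_module:
            raise ValueError(f"module {mod} missing from p_temperate_by_module")
        p = p_temperate_by_module[mod]
        n_label = int(round(coverage * len(gids)))
        chosen = rng.choice(len(gids), size=n_label, replace=False)
        for idx in chosen:
            lifestyle[gids[idx]] = "temperate" if rng.random() < p else "virulent"
    return GenomeSet(
        {g: dict(f) for g, f in genomes.memberships.items()},
        taxon=dict(genomes.taxon),
        lifestyle=lifestyle,
        members={g: list(m) for g, m in genomes.members.items()},
    )


def write_truth_tables(truth: SimulationTruth, genome_path, family_path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            (g, truth.genome_module.get(g, ""), truth.genome_supermodule.get(g, ""))
            for g in truth.genome_module
        ],
        columns=["genome_id", "module", "supermodule"],
    ).to_csv(genome_path, sep="\t", index=False)
    pd.DataFrame(
        [
            (
                f,
                truth.family_class.get(f, ""),
                truth.family_module.get(f, ""),
                truth.family_loss_rate.get(f, ""),
            )
            for f in truth.family_class
        ],
        columns=["family_id", "class", "module", "loss_rate"],
    ).to_csv(family_path, sep="\t", index=False)
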