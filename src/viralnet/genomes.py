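"""Genome–gene-family membership data and its tab-separated I/O.

The central container is :class:`GenomeSet`: an ordered collection of
genomes, each holding a multiset of gene-family identifiers (copy counts),
with optional per-genome metadata (taxon, lifestyle).  All downstream
network analyses are presence-based; copy counts are preserved only through
I/O round trips.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LIFESTYLES = ("temperate", "virulent", "unknown")


@dataclass
class GenomeSet:
    """Genomes with their gene-family memberships.

    Parameters
    ----------
    memberships
        Mapping ``genome_id -> {family_id: copy_count}``.  Insertion order
        defines the canonical genome ordering.
    taxon
        Optional ``genome_id -> taxon`` labels.
    lifestyle
        Optional ``genome_id -> lifestyle`` labels drawn from
        ``{"temperate", "virulent", "unknown"}``.
    members
        For pangenomes produced by merging near-identical genomes: the
        original genome ids collapsed into each record.  Defaults to each
        genome mapping to itself.
    """

    memberships: dict[str, dict[str, int]]
    taxon: dict[str, str] = field(default_factory=dict)
    lifestyle: dict[str, str] = field(default_factory=dict)
    members: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.memberships:
            raise ValueError("GenomeSet requires at least one genome")
        for gid, fams in self.memberships.items():
            for fid, count in fams.items():
                if count < 1:
                    raise ValueError(
                        f"copy count for ({gid}, {fid}) must be >= 1, got {count}"
                    )
        for gid, ls in self.lifestyle.items():
            if ls not in LIFESTYLES:
                raise ValueError(f"unknown lifestyle {ls!r} for genome {gid}")
        if not self.members:
            self.members = {g: [g] for g in self.memberships}

    # -- basic accessors ---------------------------------------------------

    @property
    def genome_ids(self) -> list[str]:
        return list(self.memberships)

    @property
    def family_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for fams in self.memberships.values():
            for fid in fams:
                seen.setdefault(fid)
        return list(seen)

    @property
    def n_genomes(self) -> int:
        return len(self.memberships)

    @property
    def n_families(self) -> int:
        return len(self.family_ids)

    def family_set(self, genome_id: str) -> frozenset[str]:
        return frozenset(self.memberships[genome_id])

    def family_sets(self) -> dict[str, frozenset[str]]:
        return {g: frozenset(f) for g, f in self.memberships.items()}

    def genomes_with_family(self, family_id: str) -> list[str]:
        return [g for g, fams in self.memberships.items() if family_id in fams]

    def presence_matrix(self) -> pd.DataFrame:
        """Boolean genomes × families presence matrix (canonical order)."""
        gids = self.genome_ids
        fids = self.family_ids
        fam_index = {f: j for j, f in enumerate(fids)}
        mat = np.zeros((len(gids), len(fids)), dtype=bool)
        for i, gid in enumerate(gids):
            for fid in self.memberships[gid]:
                mat[i, fam_index[fid]] = True
        return pd.DataFrame(mat, index=gids, columns=fids)

    # -- tabular form ------------------------------------------------------

    def to_table(self) -> pd.DataFrame:
        rows = [
            (g, f, c)
            for g, fams in self.memberships.items()
            for f, c in fams.items()
        ]
        return pd.DataFrame(rows, columns=["genome_id", "family_id", "copy_count"])

    @classmethod
    def from_table(
        cls,
        table: pd.DataFrame,
        taxon: dict[str, str] | None = None,
        lifestyle: dict[str, str] | None = None,
    ) -> "GenomeSet":
        required = {"genome_id", "family_id", "copy_count"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"missing required column(s): {sorted(missing)}")
        memberships: dict[str, dict[str, int]] = {}
        for row in table.itertuples(index=False):
            count = int(row.copy_count)
            fams = memberships.setdefault(str(row.genome_id), {})
            # duplicate (genome, family) rows accumulate into the copy count
            fams[str(row.family_id)] = fams.get(str(row.family_id), 0) + count
        return cls(memberships, taxon=taxon or {}, lifestyle=lifestyle or {})


def read_genome_table(path, metadata_path=None) -> GenomeSet:
    """Read a GenomeSet from a TSV with columns genome_id, family_id, copy_count.

    Duplicate (genome, family) rows are summed into copy counts.  An optional
    metadata TSV provides per-genome ``taxon`` and ``lifestyle`` columns.
    """
    try:
        table = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty genome table: {path}") from exc
    missing = {"genome_id", "family_id", "copy_count"} - set(table.columns)
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {sorted(missing)} in header"
        )
    bad = table[~table["copy_count"].str.fullmatch(r"\d+")]
    if len(bad):
        lines = (bad.index + 2).tolist()  # +2: header line and 1-based
        raise ValueError(f"{path}: non-integer copy_count on line(s) {lines}")
    table["copy_count"] = table["copy_count"].astype(int)
    taxon: dict[str, str] = {}
    lifestyle: dict[str, str] = {}
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
        if "genome_id" not in meta.columns:
            raise ValueError(f"{metadata_path}: missing genome_id column")
        for row in meta.itertuples(index=False):
            gid = str(row.genome_id)
            if "taxon" in meta.columns and pd.notna(row.taxon):
                taxon[gid] = str(row.taxon)
            if "lifestyle" in meta.columns and pd.notna(row.lifestyle):
                lifestyle[gid] = str(row.lifestyle)
    return GenomeSet.from_table(table, taxon=taxon, lifestyle=lifestyle)


def write_genome_table(genomes: GenomeSet, path, metadata_path=None) -> None:
    genomes.to_table().to_csv(path, sep="\t", index=False)
    if metadata_path is not None:
        rows = [
            (
                g,
                genomes.taxon.get(g, ""),
                genomes.lifestyle.get(g, "unknown"),
            )
            for g in genomes.genome_ids
        ]
        pd.DataFrame(rows, columns=["genome_id", "taxon", "lifestyle"]).to_csv(
            metadata_path, sep="\t", index=False
        )
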