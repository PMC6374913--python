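"""Orthogroup tables, single-ortholog sets, orphans and in-paralogs.

Orthology is consumed, not inferred: the input is an Orthofinder-style
``Orthogroups.tsv`` (header of species names; per-row comma+space separated
gene lists, empty cell = species absent) plus a 12-column BLAST tabular hit
file for the orphan screen.

Derived sets follow the comparative design for a four-species study:

* ASO ("all single orthologs"): orthogroups with exactly one gene in every
  species (1:1:1:1) or exactly one gene in all but one species and none in
  the remaining one (1:1:1:0).
* PSO ("pairwise single orthologs"): per species pair, orthogroups with
  exactly one gene in each species of the pair, whatever the other species.
* Orphans: genes of one species with no cross-taxon hit at e-value <= 1e-4.
* In-paralogs: same-species co-members of an orthogroup.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

ORPHAN_EVALUE_CUTOFF = 1e-4

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass
class OrthologyMap:
    """orthogroup id -> {species: [gene ids]} over a fixed species roster."""

    groups: dict[str, dict[str, list[str]]]
    species: list[str]

    def copy_counts(self) -> pd.DataFrame:
        """Per-orthogroup per-species gene copy number."""
        return pd.DataFrame(
            {og: {sp: len(members[sp]) for sp in self.species} for og, members in self.groups.items()}
        ).T[self.species]

    def genes_of(self, species: str) -> list[str]:
        out = []
        for members in self.groups.values():
            out.extend(members[species])
        return out


@dataclass
class OrthologSets:
    aso: list[str]
    pso: dict[tuple[str, str], list[str]]
    orphans: dict[str, set[str]] = field(default_factory=dict)
    inparalogs: dict[str, list[tuple[str, str]]] = field(default_factory=dict)


def read_orthogroups(path) -> OrthologyMap:
    """Parse an ``Orthogroups.tsv``-dialect table.

    Raises on duplicated gene ids across rows (an orthogroup partition must
    be disjoint) and on rows with the wrong number of cells.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        species = header[1:]
        groups: dict[str, dict[str, list[str]]] = {}
        seen: dict[str, str] = {}
        for lineno, line in enumerate(fh, start=2):
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(species) + 1:
                raise ValueError(f"{path}:{lineno}: expected {len(species)+1} columns, got {len(cells)}")
            og = cells[0]
            members: dict[str, list[str]] = {}
            for sp, cell in zip(species, cells[1:]):
                genes = [g for g in (x.strip() for x in cell.split(",")) if g] if cell.strip() else []
                for g in genes:
                    if g in seen:
                        raise ValueError(f"gene {g!r} appears in both {seen[g]} and {og}")
                    seen[g] = og
                members[sp] = genes
            groups[og] = members
    return OrthologyMap(groups=groups, species=species)


def derive_sets(
    omap: OrthologyMap, species_pairs: list[tuple[str, str]] | None = None
) -> OrthologSets:
    """ASO / PSO / in-paralog sets from the copy-number patterns."""
    n_sp = len(omap.species)
    if species_pairs is None:
        species_pairs = [
            (a, b) for i, a in enumerate(omap.species) for b in omap.species[i + 1 :]
        ]
    counts = omap.copy_counts()

    ones = (counts == 1).sum(axis=1)
    zeros = (counts == 0).sum(axis=1)
    aso_mask = (ones == n_sp) | ((ones == n_sp - 1) & (zeros == 1))
    aso = counts.index[aso_mask].tolist()

    pso = {
        pair: counts.index[(counts[pair[0]] == 1) & (counts[pair[1]] == 1)].tolist()
        for pair in species_pairs
    }

    inparalogs: dict[str, list[tuple[str, str]]] = {sp: [] for sp in omap.species}
    for og, members in omap.groups.items():
        for sp, genes in members.items():
            if len(genes) > 1:
                inparalogs[sp].extend(
                    (genes[i], genes[j]) for i in range(len(genes)) for j in range(i + 1, len(genes))
                )
    return OrthologSets(aso=aso, pso=pso, inparalogs=inparalogs)


def read_blast6(path) -> pd.DataFrame:
    """Read a 12-column BLAST tabular (outfmt 6) hit file."""
    return pd.read_csv(path, sep="\t", names=BLAST6_COLUMNS)


def find_orphans(
    genes_by_species: dict[str, list[str]],
    hits: pd.DataFrame,
    gene_species: pd.Series,
    cutoff: float = ORPHAN_EVALUE_CUTOFF,
) -> dict[str, set[str]]:
    """Orphan (taxonomically restricted) genes per species.

    A gene is an orphan when it has no hit with e-value <= cutoff (inclusive)
    against any gene of a *different* species; same-species hits never rescue
    a gene from orphan status.  ``gene_species`` maps every subject id that
    can appear in the hit table to its species.
    """
    unknown = set(hits["sseqid"]) - set(gene_species.index)
    if unknown:
        raise ValueError(f"subjects with unresolvable species: {sorted(unknown)[:5]}")
    sig = hits[hits["evalue"] <= cutoff]
    qsp = sig["qseqid"].map(gene_species)
    ssp = sig["sseqid"].map(gene_species)
    cross = sig[qsp.isna() | (qsp != ssp)]  # queries outside the map count as cross-taxon
    rescued = set(cross["qseqid"])
    return {
        sp: {g for g in genes if g not in rescued}
        for sp, genes in genes_by_species.items()
    }
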