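"""Standard genetic code tables shared by the sequence-evolution and divergence modules."""

from __future__ import annotations

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]

STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.forward_table))
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)

NUCLEOTIDES = "ACGT"

assert len(SENSE_CODONS) == 61


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a sense codon; '*' for a stop."""
    if codon in STOP_CODONS:
        return "*"
    return CODON_TO_AA[codon]


def single_nt_neighbors(codon: str) -> list[str]:
    """All 9 codons reachable by one nucleotide change (stops included)."""
    out = []
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt != codon[pos]:
                out.append(codon[:pos] + nt + codon[pos + 1 :])
    return out


def _family_sizes() -> dict[str, int]:
    sizes: dict[str, int] = {}
    for aa in set(CODON_TO_AA.values()):
        sizes[aa] = sum(1 for c in SENSE_CODONS if CODON_TO_AA[c] == aa)
    return sizes


#: amino acid -> number of synonymous codons (degeneracy class)
AA_DEGENERACY: dict[str, int] = _family_sizes()

#: codons per amino acid, in sorted codon order
AA_CODONS: dict[str, tuple[str, ...]] = {
    aa: tuple(c for c in SENSE_CODONS if CODON_TO_AA[c] == aa)
    for aa in AA_DEGENERACY
}
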