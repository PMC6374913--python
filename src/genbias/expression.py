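"""TPM quantification, species-level expression floors, and gene-model statistics.

Expression is quantified as transcripts per million (TPM) computed from raw
counts and coding-sequence lengths.  A species-level "expression floor" — the
5th percentile of all pooled replicate-level TPM values for that species —
separates expressed from non-expressed genes: a gene is kept when its mean TPM
reaches the floor in at least one life-cycle generation (gametophyte GA or
sporophyte SP).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pyranges as pr
from Bio import SeqIO

GENERATIONS = ("GA", "SP")


@dataclass
class ExpressionMatrix:
    """Counts (and optionally TPM) for one species, genes x samples.

    ``samples`` carries one row per sample with columns ``species``,
    ``generation`` (GA or SP) and ``replicate``; its index holds sample ids
    matching the count-matrix columns.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    lengths: pd.Series | None = None
    tpm: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if not self.counts.columns.equals(self.samples.index):
            raise ValueError("count-matrix columns must match the sample sheet index")
        bad = set(self.samples["generation"]) - set(GENERATIONS)
        if bad:
            raise ValueError(f"unknown generation labels: {sorted(bad)}")

    @classmethod
    def from_files(cls, counts_tsv, samples_tsv, lengths: pd.Series | None = None) -> "ExpressionMatrix":
        counts = pd.read_csv(counts_tsv, sep="\t", index_col="gene_id")
        samples = pd.read_csv(samples_tsv, sep="\t", index_col="sample_id")
        return cls(counts=counts, samples=samples.loc[counts.columns], lengths=lengths)

    def with_tpm(self) -> "ExpressionMatrix":
        if self.lengths is None:
            raise ValueError("gene lengths required to compute TPM")
        return ExpressionMatrix(
            counts=self.counts,
            samples=self.samples,
            lengths=self.lengths,
            tpm=compute_tpm(self.counts, self.lengths),
        )


@dataclass(frozen=True)
class GeneModelStats:
    """Structural statistics of one gene model."""

    gene_id: str
    cds_length: int
    gc: float
    gc3: float
    intron_count: int


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million from raw counts and per-gene lengths (nt).

    tpm_ij = 1e6 * (c_ij / l_i) / sum_k (c_kj / l_k); every column sums to 1e6.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()
        raise ValueError(f"missing lengths for genes: {missing[:5]}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    rate = counts.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    zero = denom.index[denom == 0].tolist()
    if zero:
        raise ValueError(f"all-zero count column(s): {zero}")
    return rate.div(denom, axis=1) * 1e6


def expression_floor(tpm: pd.DataFrame, q: float = 5.0) -> float:
    """Species expression floor: the ``q``-th percentile of all pooled
    replicate-level TPM values (linear interpolation between order statistics)."""
    values = tpm.to_numpy().ravel()
    if values.size == 0:
        raise ValueError("empty TPM matrix")
    return float(np.percentile(values, q))


def generation_means(tpm: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Mean TPM per gene per generation (columns GA, SP)."""
    samples = samples.loc[samples.index.intersection(tpm.columns)]
    out = {}
    for gen in GENERATIONS:
        cols = samples.index[samples["generation"] == gen]
        out[gen] = tpm[cols].mean(axis=1)
    return pd.DataFrame(out)


def filter_expressed(
    tpm: pd.DataFrame, samples: pd.DataFrame, floor: float
) -> tuple[pd.Index, pd.DataFrame]:
    """Expressed genes and the per-generation mean-TPM table.

    A gene is expressed when its mean TPM reaches the floor in at least one
    generation; everything else is treated as not expressed downstream.
    """
    if floor < 0:
        raise ValueError("floor must be non-negative")
    means = generation_means(tpm, samples)
    expressed = means.index[(means >= floor).any(axis=1)]
    return expressed, means


def _gc_fraction(seq: str) -> float:
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / acgt


def seq_stats(gene_id: str, cds: str, n_cds_segments: int = 1) -> GeneModelStats:
    """GC, third-position GC and intron count for one gene model.

    ``cds`` is the spliced coding sequence (multiple of 3); ``n_cds_segments``
    the number of CDS features in the gene's GFF3 record (introns = segments - 1).
    N bases are excluded from both numerator and denominator.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"{gene_id}: CDS length {len(cds)} is not a multiple of 3")
    if set(cds) - set("ACGTN"):
        raise ValueError(f"{gene_id}: CDS contains non-ACGTN characters")
    if n_cds_segments < 1:
        raise ValueError("n_cds_segments must be >= 1")
    third = cds[2::3]
    return GeneModelStats(
        gene_id=gene_id,
        cds_length=len(cds),
        gc=_gc_fraction(cds),
        gc3=_gc_fraction(third),
        intron_count=n_cds_segments - 1,
    )


def stats_from_files(cds_fasta, gff3_path) -> pd.DataFrame:
    """GeneModelStats for every gene in a CDS FASTA + GFF3 pair.

    CDS segment counts are read per gene from the GFF3 (CDS features grouped
    by their mRNA parent, one mRNA per gene).
    """
    gff = pr.read_gff3(gff3_path).df
    cds_feats = gff[gff.Feature == "CDS"]
    mrna = gff[gff.Feature == "mRNA"].set_index("ID")["Parent"]
    seg_per_mrna = cds_feats.groupby("Parent").size()
    seg_per_gene = {mrna[m]: n for m, n in seg_per_mrna.items()}

    rows = []
    for rec in SeqIO.parse(str(cds_fasta), "fasta"):
        st = seq_stats(rec.id, str(rec.seq), seg_per_gene.get(rec.id, 1))
        rows.append(st.__dict__)
    return pd.DataFrame(rows).set_index("gene_id")
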