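"""Sequence- and expression-level divergence.

Implements the counting route to pairwise dN/dS (Nei & Gojobori 1986 with
Jukes–Cantor correction), codon-aware back-translation of protein alignments,
gapless-codon curation with the >100 bp retention rule, Wright's effective
number of codons (with a background-composition corrected variant), and the
Euclidean distance between two species' (GA, SP) expression profiles of an
ortholog pair.

Conventions (stated because they decide the numbers):

* Site counting: at each codon position the synonymous fraction is the number
  of synonymous single-nucleotide changes over 3; changes creating a stop
  codon count as nonsynonymous, so S + N equals the ungapped length in nt.
* Multi-hit codons: substitution pathways are weighted equally; pathways
  traversing a stop codon are excluded (all-blocked codons fall back to the
  full pathway set).
* Saturation: dS > 2, or an uncorrectable proportion (p >= 3/4), flags the
  estimate as saturated; saturated records are excluded from omega summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np

from ._codons import (
    AA_CODONS,
    AA_DEGENERACY,
    CODON_TO_AA,
    NUCLEOTIDES,
    SENSE_CODONS,
    STOP_CODONS,
    translate_codon,
)

GAP_CODON = "---"
MIN_GAPLESS_LEN = 100  # nt; strict "> 100" retention


# ---------------------------------------------------------------------------
# codon alignment construction and curation


@dataclass
class CodonAlignment:
    """Aligned coding sequences (equal length, whole-codon gaps)."""

    ids: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if len({len(s) for s in self.seqs}) > 1:
            raise ValueError("aligned sequences differ in length")
        if self.seqs and len(self.seqs[0]) % 3 != 0:
            raise ValueError("alignment length is not a multiple of 3")

    @property
    def n_codons(self) -> int:
        return len(self.seqs[0]) // 3 if self.seqs else 0

    def codon_columns(self):
        for i in range(self.n_codons):
            yield tuple(s[3 * i : 3 * i + 3] for s in self.seqs)


def backtranslate(protein_rows: dict[str, str], cds: dict[str, str]) -> CodonAlignment:
    """Thread each CDS onto its aligned protein row (pal2nal-style).

    Every amino acid is replaced by its source codon, every protein gap by
    '---'.  The CDS (trailing stop allowed) must translate exactly to the
    ungapped protein row.
    """
    ids, seqs = [], []
    for sid, prot in protein_rows.items():
        if sid not in cds:
            raise ValueError(f"no CDS provided for {sid!r}")
        nt = cds[sid].upper().replace("U", "T")
        if len(nt) % 3 != 0:
            raise ValueError(f"{sid}: CDS length {len(nt)} not a multiple of 3")
        codons = [nt[i : i + 3] for i in range(0, len(nt), 3)]
        if codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]
        residues = [a for a in prot if a != "-"]
        if len(codons) != len(residues):
            raise ValueError(
                f"{sid}: CDS encodes {len(codons)} residues but protein row has {len(residues)}"
            )
        for pos, (codon, aa) in enumerate(zip(codons, residues), start=1):
            if translate_codon(codon) != aa.upper():
                raise ValueError(
                    f"{sid}: codon {codon} at residue {pos} translates to "
                    f"{translate_codon(codon)}, protein row has {aa}"
                )
        it = iter(codons)
        seqs.append("".join(GAP_CODON if a == "-" else next(it) for a in prot))
        ids.append(sid)
    return CodonAlignment(ids=ids, seqs=seqs)


@dataclass
class CurationResult:
    retained: bool
    alignment: CodonAlignment | None
    gapless_length: int
    reason: str = ""


def curate(aln: CodonAlignment, min_len: int = MIN_GAPLESS_LEN) -> CurationResult:
    """Drop every codon column containing a gap; retain iff the remaining
    gapless alignment is strictly longer than ``min_len`` nt."""
    kept = [col for col in aln.codon_columns() if all("-" not in c for c in col)]
    length = 3 * len(kept)
    if length <= min_len:
        return CurationResult(False, None, length, f"gapless alignment {length} nt <= {min_len} nt")
    seqs = ["".join(col[i] for col in kept) for i in range(len(aln.ids))]
    return CurationResult(True, CodonAlignment(ids=list(aln.ids), seqs=seqs), length)


# ---------------------------------------------------------------------------
# NG86 pairwise dN/dS


def _syn_fraction(codon: str) -> float:
    """Number of synonymous sites in a codon (0..3); stop-creating changes
    count as nonsynonymous."""
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if alt not in STOP_CODONS and CODON_TO_AA[alt] == aa:
                syn += 1
        s += syn / 3.0
    return s


_SYN_SITES = {c: _syn_fraction(c) for c in SENSE_CODONS}


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Expected (synonymous, nonsynonymous) difference counts between two
    codons, averaging over equally weighted substitution pathways and
    excluding pathways that traverse a stop codon."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    valid, all_paths = [], []
    for order in permutations(diff):
        sd = nd = 0
        cur = c1
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
            if translate_codon(cur) == translate_codon(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        all_paths.append((sd, nd, blocked))
        if not blocked:
            valid.append((sd, nd))
    pool = valid if valid else [(s, n) for s, n, _ in all_paths]
    sd = sum(p[0] for p in pool) / len(pool)
    nd = sum(p[1] for p in pool) / len(pool)
    return sd, nd


@dataclass
class DivergenceEstimate:
    """Pairwise NG86 divergence for one curated ortholog pair."""

    pair: tuple[str, str]
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float | None
    dN: float | None
    omega: float | None
    saturated: bool

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        d["pair"] = "|".join(self.pair)
        return d


def _jc_correct(p: float) -> float | None:
    """Jukes–Cantor multiple-hit correction; None when p >= 3/4."""
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86(aln: CodonAlignment, saturation_ds: float = 2.0) -> DivergenceEstimate:
    """Nei–Gojobori (1986) pairwise dN/dS on a curated two-sequence codon
    alignment (gap-free, no internal stops)."""
    if len(aln.seqs) != 2:
        raise ValueError("ng86 requires exactly two sequences")
    S = N = Sd = Nd = 0.0
    for c1, c2 in aln.codon_columns():
        if "-" in c1 or "-" in c2:
            raise ValueError("ng86 requires a gap-free (curated) alignment")
        if c1 in STOP_CODONS or c2 in STOP_CODONS:
            raise ValueError("internal stop codon in curated alignment")
        s_sites = 0.5 * (_SYN_SITES[c1] + _SYN_SITES[c2])
        S += s_sites
        N += 3.0 - s_sites
        sd, nd = _pathway_counts(c1, c2)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = _jc_correct(pS)
    dN = _jc_correct(pN)
    saturated = dS is None or dN is None or (dS is not None and dS > saturation_ds)
    omega = None
    if dS is not None and dN is not None and dS > 0:
        omega = dN / dS
    return DivergenceEstimate(
        pair=(aln.ids[0], aln.ids[1]),
        S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN,
        dS=dS, dN=dN, omega=omega, saturated=saturated,
    )


# ---------------------------------------------------------------------------
# effective number of codons


def codon_usage(cds: str) -> dict[str, int]:
    """Sense-codon counts of one coding sequence (stops ignored)."""
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise ValueError("CDS length not a multiple of 3")
    counts = dict.fromkeys(SENSE_CODONS, 0)
    for i in range(0, len(cds), 3):
        c = cds[i : i + 3]
        if c in counts:
            counts[c] += 1
    return counts


def _class_means(f_by_aa: dict[str, float]) -> dict[int, float]:
    means = {}
    for k in (2, 3, 4, 6):
        vals = [f for aa, f in f_by_aa.items() if AA_DEGENERACY[aa] == k]
        if vals:
            means[k] = float(np.mean(vals))
    return means


def _enc_from_class_means(fbar: dict[int, float]) -> float:
    # Wright's imputation for missing degeneracy classes
    if 3 not in fbar:
        if 2 in fbar and 4 in fbar:
            fbar[3] = (fbar[2] + fbar[4]) / 2.0
        elif 2 in fbar:
            fbar[3] = fbar[2]
        elif 4 in fbar:
            fbar[3] = fbar[4]
    weights = {2: 9.0, 3: 1.0, 4: 5.0, 6: 3.0}
    enc = 2.0
    for k, w in weights.items():
        f = fbar.get(k)
        if f is None or f <= 0:
            f = 1.0 / k  # unobserved class: assume no bias
        enc += w / f
    return min(enc, 61.0)


def enc(counts: dict[str, int], background: dict[str, float] | None = None) -> tuple[float, float | None]:
    """Wright's effective number of codons, and the background-corrected
    variant (ENC') when a background codon-frequency profile is given.

    Homozygosity per amino acid is F = sum(p_i^2) over its codons (the
    uncorrected form, so that perfectly uniform usage gives exactly 61 and
    single-codon usage exactly 20).  ENC' replaces F by
    (X^2/n + 1)/k, where X^2 measures deviation of the observed codon counts
    from the background-expected ones within the amino acid.
    """
    if sum(counts.values()) == 0:
        raise ValueError("empty codon counts")
    f_by_aa: dict[str, float] = {}
    fprime_by_aa: dict[str, float] = {}
    for aa, codons in AA_CODONS.items():
        k = AA_DEGENERACY[aa]
        if k == 1:
            continue
        n = sum(counts.get(c, 0) for c in codons)
        if n == 0:
            continue
        p = np.array([counts.get(c, 0) / n for c in codons])
        f_by_aa[aa] = float(np.sum(p**2))
        if background is not None:
            b = np.array([background.get(c, 0.0) for c in codons], dtype=float)
            if b.sum() <= 0:
                b = np.full(k, 1.0 / k)
            b = b / b.sum()
            x2 = float(n * np.sum((p - b) ** 2 / b))
            fprime_by_aa[aa] = (x2 / n + 1.0) / k
    enc_val = _enc_from_class_means(_class_means(f_by_aa))
    enc_prime = None
    if background is not None:
        enc_prime = _enc_from_class_means(_class_means(fprime_by_aa))
    return enc_val, enc_prime


def background_from_sequences(seqs: list[str]) -> dict[str, float]:
    """Pooled codon-frequency background (e.g. from ribosomal genes)."""
    total = dict.fromkeys(SENSE_CODONS, 0)
    for s in seqs:
        for c, n in codon_usage(s).items():
            total[c] += n
    tot = sum(total.values())
    if tot == 0:
        raise ValueError("background sequences contain no sense codons")
    return {c: n / tot for c, n in total.items()}


# ---------------------------------------------------------------------------
# expression divergence


def euclidean_divergence(profile1: dict[str, float], profile2: dict[str, float], log_transform: bool = False) -> float:
    """Euclidean distance between two species' expression profiles of an
    ortholog over the life-cycle stages (GA, SP), on raw TPM by default.

    EucD = sqrt(sum_j (x1j - x2j)^2), j over stages.  ``log_transform``
    applies log2(TPM + 1) first.
    """
    stages = ("GA", "SP")
    for prof in (profile1, profile2):
        for st in stages:
            if st not in prof or prof[st] is None or not np.isfinite(prof[st]):
                raise ValueError(f"missing expression value for stage {st}")
            if prof[st] < 0:
                raise ValueError("TPM values must be non-negative")
    x1 = np.array([profile1[s] for s in stages], dtype=float)
    x2 = np.array([profile2[s] for s in stages], dtype=float)
    if log_transform:
        x1, x2 = np.log2(x1 + 1.0), np.log2(x2 + 1.0)
    return float(np.sqrt(np.sum((x1 - x2) ** 2)))
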