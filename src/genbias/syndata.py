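"""Self-consistent synthetic four-species dataset with a ground-truth ledger.

The generator emulates the design of a comparative gametophyte/sporophyte
RNA-seq study: two pairs of species from two orders on a rooted four-taxon
tree, orthogroups with realistic occupancy patterns (single-copy 1:1:1:1,
missing-in-one 1:1:1:0, lineage-specific duplications, and single-species
orphans), generation-bias states evolved as two binary characters under a
two-state Markov chain on the tree, negative-binomial counts with planted
log2 fold changes, and codon sequences diverged from a common ancestor under
a bias-class-specific dN/dS.  Every emitted file is derivable from the
ground-truth ledger, so each downstream stage of the pipeline can be tested
against known truth without external data.

Everything is driven by one integer seed; the same seed yields a
byte-identical output bundle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._codons import CODON_TO_AA, SENSE_CODONS, STOP_CODONS, single_nt_neighbors
from .traitmap import MISSING, Phylogeny

PATTERNS = ("single_copy", "missing_one", "duplicated", "orphan")

DEFAULT_SPECIES = ("Esp", "Slo", "Sja", "Mpy")
DEFAULT_TREE = "((Esp:0.25,Slo:0.25):0.55,(Sja:0.25,Mpy:0.25):0.55);"


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic dataset.

    Defaults mirror the structure of the four-species brown-algal design:
    orthogroup occupancy fractions close to the observed pattern mix
    (~31% 1:1:1:1, ~20% 1:1:1:0), bias gain/loss rates near the reported
    mean per-gene transition rate (~1.3 per unit branch length for both
    characters), and a wide planted-effect distribution so all three
    fold-change bins ([2,6), [6,20), >=20) are populated.
    """

    species_names: tuple[str, ...] = DEFAULT_SPECIES
    tree_newick: str = DEFAULT_TREE
    n_orthogroups: int = 300
    pattern_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "single_copy": 0.31,
            "missing_one": 0.20,
            "duplicated": 0.34,
            "orphan": 0.15,
        }
    )
    # Mk gain/loss rates per trait and root state probability (P(biased at root))
    bias_gain_rate: float = 1.3
    bias_loss_rate: float = 1.3
    root_bias_prob: float = 0.25
    # planted |log2FC| ~ location + scale * |N(0,1)|
    effect_location: float = 2.5
    effect_scale: float = 1.5
    # NB counts
    nb_dispersion: float = 0.05
    base_mean_log: float = np.log(100.0)
    base_mean_sigma: float = 1.0
    library_size_sigma: float = 0.2
    n_replicates: int = 3
    # codon model: omega per bias class, pairwise divergence, length
    omega_by_class: dict[str, float] = field(
        default_factory=lambda: {"GA": 0.6, "SP": 0.3, "unbiased": 0.2}
    )
    divergence_t: float = 0.3
    mean_n_codons: int = 200
    # structural knobs: third-position GC and intron Poisson mean per class
    gc3_by_class: dict[str, float] = field(
        default_factory=lambda: {"GA": 0.50, "SP": 0.62, "unbiased": 0.62}
    )
    intron_lambda_by_class: dict[str, float] = field(
        default_factory=lambda: {"GA": 5.0, "SP": 3.5, "unbiased": 3.5}
    )
    seed: int = 0

    def validate(self) -> None:
        frac_sum = sum(self.pattern_fractions.values())
        if abs(frac_sum - 1.0) > 1e-9:
            raise ValueError(f"pattern_fractions sum to {frac_sum}, expected 1")
        if set(self.pattern_fractions) != set(PATTERNS):
            raise ValueError(f"pattern_fractions must have keys {PATTERNS}")
        if any(v < 0 for v in self.pattern_fractions.values()):
            raise ValueError("pattern_fractions must be non-negative")
        for name in ("bias_gain_rate", "bias_loss_rate", "divergence_t", "mean_n_codons"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if not 0.0 <= self.root_bias_prob <= 1.0:
            raise ValueError("root_bias_prob must lie in [0, 1]")
        if self.n_orthogroups < 1:
            raise ValueError("n_orthogroups must be >= 1")


# ---------------------------------------------------------------------------
# elementary simulators


def simulate_counts(mean: float, dispersion: float, n: int, rng) -> np.ndarray:
    """NB draws with E = mean and Var = mean + dispersion * mean^2
    (Poisson at dispersion 0)."""
    if mean <= 0:
        raise ValueError("mean must be strictly positive")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng)
    if dispersion == 0.0:
        return rng.poisson(mean, size=n)
    size = 1.0 / dispersion
    return rng.negative_binomial(size, size / (size + mean), size=n)


# per-codon jump process: neighbors and whether each change is synonymous
_NEIGHBORS: dict[str, tuple[list[str], np.ndarray]] = {}
for _c in SENSE_CODONS:
    _nb = [x for x in single_nt_neighbors(_c) if x not in STOP_CODONS]
    _syn = np.array([CODON_TO_AA[x] == CODON_TO_AA[_c] for x in _nb])
    _NEIGHBORS[_c] = (_nb, _syn)


def _evolve_codon(codon: str, omega: float, t: float, rng) -> str:
    """Continuous-time evolution of one codon: each synonymous single-nt
    change at rate 1, each nonsynonymous at rate omega, stops rejected."""
    time = 0.0
    while True:
        nbs, syn = _NEIGHBORS[codon]
        rates = np.where(syn, 1.0, omega)
        total = rates.sum()
        if total <= 0:
            return codon
        time += rng.exponential(1.0 / total)
        if time >= t:
            return codon
        codon = nbs[rng.choice(len(nbs), p=rates / total)]


def evolve_codon_seq(seq: str, omega: float, t: float, rng) -> str:
    """Evolve a codon sequence for time t (independent codons)."""
    return "".join(
        _evolve_codon(seq[i : i + 3], omega, t, rng) for i in range(0, len(seq), 3)
    )


def random_codon_seq(n_codons: int, rng, gc3: float = 0.5) -> str:
    """Ancestor sequence: codons drawn over the 61 sense codons with the
    third position biased toward G/C with weight ``gc3``."""
    w = np.array([gc3 if c[2] in "GC" else 1.0 - gc3 for c in SENSE_CODONS])
    w = w / w.sum()
    idx = rng.choice(len(SENSE_CODONS), size=n_codons, p=w)
    return "".join(SENSE_CODONS[i] for i in idx)


def simulate_codon_pair(omega: float, t: float, n_codons: int, seed) -> tuple[str, str]:
    """An aligned pair of CDS diverged by t: uniform sense-codon ancestor,
    each lineage evolved independently for t/2."""
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    if omega < 0 or t < 0:
        raise ValueError("omega and t must be non-negative")
    rng = np.random.default_rng(seed)
    anc = random_codon_seq(n_codons, rng, gc3=0.5)
    a = evolve_codon_seq(anc, omega, t / 2.0, rng)
    b = evolve_codon_seq(anc, omega, t / 2.0, rng)
    return a, b


def simulate_trait_history(
    tree: Phylogeny, q01: float, q10: float, root_prob: float, rng
) -> dict[int, int]:
    """Evolve a binary trait over the tree: root ~ Bernoulli(root_prob),
    then a 2-state CTMC along each branch.  Returns states for every node
    (keyed by the tree's internal node index)."""
    if q01 < 0 or q10 < 0:
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(rng)
    states: dict[int, int] = {tree.root: int(rng.random() < root_prob)}
    for node in reversed(tree.postorder):  # preorder: parents first
        for child in tree.children[node]:
            s = states[node]
            remaining = tree.blen[child]
            while True:
                rate = q01 if s == 0 else q10
                if rate <= 0:
                    break
                wait = rng.exponential(1.0 / rate)
                if wait >= remaining:
                    break
                remaining -= wait
                s = 1 - s
            states[child] = s
    return states


# ---------------------------------------------------------------------------
# full-bundle simulation


@dataclass
class OrthogroupTruth:
    og_id: str
    pattern: str
    members: dict[str, list[str]]
    omega_class: str
    ga_history: dict[str, int]  # branch-id/leaf-name -> state (plus "root")
    sp_history: dict[str, int]


@dataclass
class GeneTruth:
    gene_id: str
    species: str
    orthogroup: str
    bias_state: str  # "GA" | "SP" | "unbiased"
    true_log2fc: float
    base_mean: float
    omega_class: str
    n_codons: int
    intron_count: int


@dataclass
class TruthLedger:
    species: list[str]
    tree_newick: str
    genes: dict[str, GeneTruth]
    orthogroups: dict[str, OrthogroupTruth]

    def biased_genes(self) -> set[str]:
        return {g for g, t in self.genes.items() if t.bias_state != "unbiased"}

    def orphan_genes(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {sp: set() for sp in self.species}
        for og in self.orthogroups.values():
            if og.pattern == "orphan":
                for sp, genes in og.members.items():
                    out[sp].update(genes)
        return out

    def aso_orthogroups(self) -> set[str]:
        return {
            og.og_id
            for og in self.orthogroups.values()
            if og.pattern in ("single_copy", "missing_one")
        }

    def to_json(self) -> str:
        payload = {
            "species": self.species,
            "tree_newick": self.tree_newick,
            "genes": {g: asdict(t) for g, t in sorted(self.genes.items())},
            "orthogroups": {o: asdict(t) for o, t in sorted(self.orthogroups.items())},
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthLedger":
        raw = json.loads(text)
        return cls(
            species=raw["species"],
            tree_newick=raw["tree_newick"],
            genes={g: GeneTruth(**t) for g, t in raw["genes"].items()},
            orthogroups={o: OrthogroupTruth(**t) for o, t in raw["orthogroups"].items()},
        )


@dataclass
class Bundle:
    """Everything the pipeline consumes, plus the truth ledger."""

    config: SimConfig
    counts: dict[str, pd.DataFrame]
    samples: pd.DataFrame  # sample_id index; species, generation, replicate
    cds: dict[str, dict[str, str]]  # species -> gene -> CDS
    gff3: dict[str, str]  # species -> GFF3 text
    orthogroups_tsv: str
    hits: pd.DataFrame
    annotations: pd.DataFrame
    tree_newick: str
    truth: TruthLedger

    def cds_lengths(self, species: str) -> pd.Series:
        return pd.Series({g: len(s) for g, s in self.cds[species].items()}, name="length")

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        for sp in self.config.species_names:
            p = outdir / f"counts_{sp}.tsv"
            self.counts[sp].to_csv(p, sep="\t", index_label="gene_id")
            paths[f"counts_{sp}"] = p
            p = outdir / f"cds_{sp}.fasta"
            with open(p, "w") as fh:
                for g in sorted(self.cds[sp]):
                    fh.write(f">{g}\n{self.cds[sp][g]}\n")
            paths[f"cds_{sp}"] = p
            p = outdir / f"genes_{sp}.gff3"
            p.write_text(self.gff3[sp])
            paths[f"gff3_{sp}"] = p

        p = outdir / "samples.tsv"
        self.samples.to_csv(p, sep="\t", index_label="sample_id")
        paths["samples"] = p

        p = outdir / "Orthogroups.tsv"
        p.write_text(self.orthogroups_tsv)
        paths["orthogroups"] = p

        p = outdir / "hits.tsv"
        self.hits.to_csv(p, sep="\t", index=False, header=False)
        paths["hits"] = p

        p = outdir / "annotations.tsv"
        self.annotations.to_csv(p, sep="\t", index=False)
        paths["annotations"] = p

        p = outdir / "tree.nwk"
        p.write_text(self.tree_newick.strip() + "\n")
        paths["tree"] = p

        p = outdir / "gene_species_map.tsv"
        rows = [
            (g, sp)
            for sp in self.config.species_names
            for g in sorted(self.cds[sp])
        ]
        pd.DataFrame(rows, columns=["gene_id", "species"]).to_csv(p, sep="\t", index=False)
        paths["gene_species_map"] = p

        p = outdir / "truth.json"
        p.write_text(self.truth.to_json())
        paths["truth"] = p
        return paths


def _assign_patterns(cfg: SimConfig, rng) -> list[str]:
    labels = rng.choice(
        PATTERNS,
        size=cfg.n_orthogroups,
        p=[cfg.pattern_fractions[k] for k in PATTERNS],
    )
    return [str(x) for x in labels]


def _node_history_by_name(tree: Phylogeny, states: dict[int, int]) -> dict[str, int]:
    """Keyed by branch id for non-root nodes and 'root' for the root."""
    out = {"root": states[tree.root]}
    for i, bid in tree.branch_id.items():
        out[bid] = states[i]
    return out


def _simulate_trait_pair(tree: Phylogeny, cfg: SimConfig, rng, max_tries: int = 1000):
    """Two trait histories (GA-bias, SP-bias) with no tip carrying both;
    rejection-resampled, with a deterministic SP-zeroing fallback."""
    leaf_ids = list(tree.leaf_index.values())
    for _ in range(max_tries):
        ga = simulate_trait_history(tree, cfg.bias_gain_rate, cfg.bias_loss_rate, cfg.root_bias_prob, rng)
        sp = simulate_trait_history(tree, cfg.bias_gain_rate, cfg.bias_loss_rate, cfg.root_bias_prob, rng)
        if not any(ga[i] == 1 and sp[i] == 1 for i in leaf_ids):
            return ga, sp
    for i in leaf_ids:
        if ga[i] == 1 and sp[i] == 1:
            sp[i] = 0
    return ga, sp


def _gff3_for_genes(genes: list[tuple[str, int, int]], rng) -> str:
    """Minimal GFF3: one gene/mRNA per gene on its own scaffold (+ strand),
    CDS split into intron-separated segments; 1-based inclusive coordinates."""
    lines = ["##gff-version 3"]
    intron_len = 120
    for gene_id, cds_len, n_introns in genes:
        n_seg = n_introns + 1
        cuts = sorted(rng.choice(np.arange(1, cds_len // 3), size=n_seg - 1, replace=False)) if n_seg > 1 else []
        bounds = [0] + [3 * c for c in cuts] + [cds_len]
        seg_lens = [bounds[i + 1] - bounds[i] for i in range(n_seg)]
        scaffold = f"scaf_{gene_id}"
        start = 1
        segs = []
        pos = start
        for sl in seg_lens:
            segs.append((pos, pos + sl - 1))
            pos += sl + intron_len
        end = segs[-1][1]
        lines.append(f"{scaffold}\tsyndata\tgene\t{start}\t{end}\t.\t+\t.\tID={gene_id}")
        lines.append(f"{scaffold}\tsyndata\tmRNA\t{start}\t{end}\t.\t+\t.\tID={gene_id}.t1;Parent={gene_id}")
        for s, e in segs:
            lines.append(f"{scaffold}\tsyndata\tCDS\t{s}\t{e}\t.\t+\t0\tID={gene_id}.cds;Parent={gene_id}.t1")
    return "\n".join(lines) + "\n"


def simulate_dataset(config: SimConfig | None = None) -> Bundle:
    """Generate the full synthetic bundle (see module docstring)."""
    cfg = config or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    species = list(cfg.species_names)
    tree = Phylogeny.from_newick(cfg.tree_newick)
    if sorted(tree.leaves) != sorted(species):
        raise ValueError("tree leaf labels must match species_names")

    patterns = _assign_patterns(cfg, rng)
    gene_counter = {sp: 0 for sp in species}

    genes: dict[str, GeneTruth] = {}
    ogs: dict[str, OrthogroupTruth] = {}
    cds: dict[str, dict[str, str]] = {sp: {} for sp in species}
    gene_meta: dict[str, list[tuple[str, int, int]]] = {sp: [] for sp in species}
    og_rows: list[tuple[str, dict[str, list[str]]]] = []

    def new_gene(sp: str) -> str:
        gene_counter[sp] += 1
        return f"{sp}_g{gene_counter[sp]:05d}"

    for k, pattern in enumerate(patterns):
        og_id = f"OG{k:07d}"
        ga_hist = _simulate_trait_pair(tree, cfg, rng)
        ga_states, sp_states = ga_hist

        # which species carry the gene
        if pattern == "single_copy":
            present = list(species)
            copies = {sp: 1 for sp in present}
        elif pattern == "missing_one":
            missing = species[int(rng.integers(len(species)))]
            present = [s for s in species if s != missing]
            copies = {sp: 1 for sp in present}
        elif pattern == "duplicated":
            dup = species[int(rng.integers(len(species)))]
            present = list(species)
            copies = {sp: (2 if sp == dup else 1) for sp in present}
        else:  # orphan
            host = species[int(rng.integers(len(species)))]
            present = [host]
            copies = {host: 1}

        # bias-class of the orthogroup for sequence evolution
        tip_ga = {sp: ga_states[tree.leaf_index[sp]] for sp in species}
        tip_sp = {sp: sp_states[tree.leaf_index[sp]] for sp in species}
        if any(tip_ga[sp] for sp in present):
            og_class = "GA"
        elif any(tip_sp[sp] for sp in present):
            og_class = "SP"
        else:
            og_class = "unbiased"

        n_codons = max(50, int(rng.poisson(cfg.mean_n_codons * (1.25 if og_class == "GA" else 1.0))))
        gc3 = cfg.gc3_by_class[og_class]
        ancestor = random_codon_seq(n_codons, rng, gc3=gc3)
        omega = cfg.omega_by_class[og_class]

        members: dict[str, list[str]] = {sp: [] for sp in species}
        base_mean = float(np.exp(rng.normal(cfg.base_mean_log, cfg.base_mean_sigma)))
        for sp in species:
            if sp not in present:
                continue
            seq = evolve_codon_seq(ancestor, omega, cfg.divergence_t / 2.0, rng)
            for _copy in range(copies[sp]):
                gid = new_gene(sp)
                members[sp].append(gid)
                if tip_ga[sp]:
                    state = "GA"
                    lfc = cfg.effect_location + cfg.effect_scale * abs(rng.normal())
                elif tip_sp[sp]:
                    state = "SP"
                    lfc = -(cfg.effect_location + cfg.effect_scale * abs(rng.normal()))
                else:
                    state, lfc = "unbiased", 0.0
                if cfg.effect_scale == 0.0 and cfg.effect_location == 0.0:
                    state, lfc = "unbiased", 0.0
                introns = int(rng.poisson(cfg.intron_lambda_by_class[og_class]))
                cds[sp][gid] = seq
                gene_meta[sp].append((gid, len(seq), introns))
                genes[gid] = GeneTruth(
                    gene_id=gid,
                    species=sp,
                    orthogroup=og_id,
                    bias_state=state,
                    true_log2fc=float(lfc),
                    base_mean=base_mean,
                    omega_class=og_class,
                    n_codons=len(seq) // 3,
                    intron_count=introns,
                )
        ogs[og_id] = OrthogroupTruth(
            og_id=og_id,
            pattern=pattern,
            members={sp: list(m) for sp, m in members.items()},
            omega_class=og_class,
            ga_history=_node_history_by_name(tree, ga_states),
            sp_history=_node_history_by_name(tree, sp_states),
        )
        og_rows.append((og_id, members))

    # ---- counts ------------------------------------------------------------
    sample_rows = []
    for sp in species:
        for gen in ("GA", "SP"):
            for rep in range(1, cfg.n_replicates + 1):
                sample_rows.append((f"{sp}_{gen}_{rep}", sp, gen, rep))
    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "species", "generation", "replicate"]
    ).set_index("sample_id")

    counts: dict[str, pd.DataFrame] = {}
    for sp in species:
        sp_samples = samples[samples["species"] == sp]
        lib = np.exp(rng.normal(0.0, cfg.library_size_sigma, size=len(sp_samples)))
        gene_ids = sorted(cds[sp])
        mat = np.zeros((len(gene_ids), len(sp_samples)), dtype=int)
        for gi, g in enumerate(gene_ids):
            t = genes[g]
            mu_ga = t.base_mean * 2.0 ** (t.true_log2fc / 2.0)
            mu_sp = t.base_mean * 2.0 ** (-t.true_log2fc / 2.0)
            for si, (sid, row) in enumerate(sp_samples.iterrows()):
                mu = (mu_ga if row["generation"] == "GA" else mu_sp) * lib[si]
                mat[gi, si] = simulate_counts(mu, cfg.nb_dispersion, 1, rng)[0]
        counts[sp] = pd.DataFrame(mat, index=pd.Index(gene_ids, name="gene_id"), columns=sp_samples.index)

    # ---- orthogroup table --------------------------------------------------
    lines = ["Orthogroup\t" + "\t".join(species)]
    for og_id, members in og_rows:
        lines.append(og_id + "\t" + "\t".join(", ".join(members[sp]) for sp in species))
    orthogroups_tsv = "\n".join(lines) + "\n"

    # ---- homology hits -----------------------------------------------------
    hit_rows = []

    def hit(q: str, s: str, ident: float, ln: int, ev: float) -> None:
        hit_rows.append((q, s, round(ident, 1), ln, 0, 0, 1, ln, 1, ln, ev, 200.0))

    for og_id, members in og_rows:
        all_members = [(sp, g) for sp in species for g in members[sp]]
        if ogs[og_id].pattern == "orphan":
            for _, g in all_members:  # self-hit only: must not rescue from orphan status
                hit(g, g, 100.0, genes[g].n_codons, 0.0)
            continue
        for i, (sp1, g1) in enumerate(all_members):
            for sp2, g2 in all_members:
                if g1 == g2:
                    continue
                ev = 1e-50 if sp1 != sp2 else 1e-60
                hit(g1, g2, 90.0, min(genes[g1].n_codons, genes[g2].n_codons), ev)
    hits = pd.DataFrame(hit_rows, columns=[
        "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    ])

    # ---- annotations: shared per orthogroup, one term enriched in GA bias --
    n_terms = 40
    ann_rows = []
    for og_id, members in og_rows:
        term_ids = rng.choice(n_terms, size=int(rng.integers(1, 4)), replace=False)
        if ogs[og_id].omega_class == "GA" and rng.random() < 0.6:
            term_ids = np.append(term_ids, 0)  # TERM0000: planted GA-associated
        for sp in species:
            for g in members[sp]:
                for t in sorted(set(int(x) for x in term_ids)):
                    ann_rows.append((g, f"TERM{t:04d}", f"term {t}"))
    annotations = pd.DataFrame(ann_rows, columns=["gene_id", "term_id", "term_name"])

    # ---- GFF3 --------------------------------------------------------------
    gff3 = {sp: _gff3_for_genes(sorted(gene_meta[sp]), rng) for sp in species}

    truth = TruthLedger(
        species=species, tree_newick=cfg.tree_newick, genes=genes, orthogroups=ogs
    )
    return Bundle(
        config=cfg,
        counts=counts,
        samples=samples,
        cds=cds,
        gff3=gff3,
        orthogroups_tsv=orthogroups_tsv,
        hits=hits,
        annotations=annotations,
        tree_newick=cfg.tree_newick,
        truth=truth,
    )
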