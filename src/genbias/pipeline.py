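"""End-to-end orchestration: simulate -> tpm -> callbias -> orthology ->
conserve -> divergence -> traitmap -> enrich -> report.

Every stage reads and writes conventional file names inside one working
directory, so stages can be re-run individually once their upstream outputs
exist.  A run manifest records the configuration snapshot, seeds, stage
order and SHA-256 checksums of every output file; deterministic stages
reproduce identical checksums on re-run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
import tomllib
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from . import __version__
from . import biascall as bc
from . import conservation as cons
from . import expression as expr
from . import moldiv, orthology, syndata, traitmap

STAGE_ORDER = [
    "simulate", "tpm", "callbias", "orthology", "conserve",
    "divergence", "traitmap", "enrich", "report",
]

#: files each stage needs (template with {sp} expanded over species)
_REQUIRES = {
    "simulate": [],
    "tpm": ["counts_{sp}.tsv", "samples.tsv", "cds_{sp}.fasta"],
    "callbias": ["tpm_{sp}.tsv", "counts_{sp}.tsv", "samples.tsv"],
    "orthology": ["Orthogroups.tsv", "hits.tsv", "gene_species_map.tsv"],
    "conserve": ["biascall_{sp}.tsv", "aso.tsv", "Orthogroups.tsv"],
    "divergence": ["cds_{sp}.fasta", "tpm_{sp}.tsv", "biascall_{sp}.tsv"],
    "traitmap": ["biascall_{sp}.tsv", "aso.tsv", "tree.nwk", "Orthogroups.tsv"],
    "enrich": ["biascall_{sp}.tsv", "annotations.tsv"],
    "report": ["biascall_{sp}.tsv"],
}

_PRODUCER = {
    "counts_{sp}.tsv": "simulate", "samples.tsv": "simulate", "cds_{sp}.fasta": "simulate",
    "Orthogroups.tsv": "simulate", "hits.tsv": "simulate", "gene_species_map.tsv": "simulate",
    "annotations.tsv": "simulate", "tree.nwk": "simulate",
    "tpm_{sp}.tsv": "tpm", "biascall_{sp}.tsv": "callbias", "aso.tsv": "orthology",
}


def _log(level: str, stage: str, msg: str, **extra) -> None:
    rec = {"ts": round(time.time(), 3), "level": level, "stage": stage, "msg": msg}
    rec.update(extra)
    print(json.dumps(rec), file=sys.stderr)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(path) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def _sim_config(cfg: dict, seed: int | None) -> syndata.SimConfig:
    kwargs = dict(cfg.get("simulate", {}))
    for key in ("species_names",):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    sc = syndata.SimConfig(**kwargs)
    if seed is not None:
        sc = dataclasses.replace(sc, seed=seed)
    return sc


def _species(cfg: dict) -> list[str]:
    return list(cfg.get("simulate", {}).get("species_names", syndata.DEFAULT_SPECIES))


def _species_pairs(cfg: dict) -> list[tuple[str, str]]:
    sp = _species(cfg)
    pairs = cfg.get("orthology", {}).get("species_pairs")
    if pairs:
        return [tuple(p) for p in pairs]
    # convention: first two species form one order, last two the other
    return [(sp[0], sp[1]), (sp[2], sp[3])] if len(sp) == 4 else [
        (a, b) for i, a in enumerate(sp) for b in sp[i + 1 :]
    ]


def _check_inputs(stage: str, outdir: Path, species: list[str]) -> None:
    for tmpl in _REQUIRES[stage]:
        names = [tmpl.format(sp=s) for s in species] if "{sp}" in tmpl else [tmpl]
        for name in names:
            if not (outdir / name).exists():
                producer = _PRODUCER.get(tmpl, "an upstream stage")
                raise FileNotFoundError(
                    f"stage {stage!r} needs {name}; run stage {producer!r} first"
                )


# ---------------------------------------------------------------------------
# stages


def stage_simulate(outdir: Path, cfg: dict, seed: int | None) -> None:
    bundle = syndata.simulate_dataset(_sim_config(cfg, seed))
    bundle.write(outdir)


def stage_tpm(outdir: Path, cfg: dict, seed: int | None) -> None:
    for sp in _species(cfg):
        lengths = pd.Series(
            {r.id: len(r.seq) for r in SeqIO.parse(str(outdir / f"cds_{sp}.fasta"), "fasta")}
        )
        em = expr.ExpressionMatrix.from_files(
            outdir / f"counts_{sp}.tsv", outdir / "samples.tsv", lengths
        )
        em = expr.ExpressionMatrix(
            counts=em.counts,
            samples=em.samples[em.samples["species"] == sp].pipe(
                lambda df: df.loc[[c for c in em.counts.columns if c in df.index]]
            ),
            lengths=lengths,
        )
        em = expr.ExpressionMatrix(
            counts=em.counts[em.samples.index], samples=em.samples, lengths=lengths
        ).with_tpm()
        em.tpm.to_csv(outdir / f"tpm_{sp}.tsv", sep="\t", index_label="gene_id")
        expr.stats_from_files(outdir / f"cds_{sp}.fasta", outdir / f"genes_{sp}.gff3").to_csv(
            outdir / f"stats_{sp}.tsv", sep="\t"
        )


def _load_species_expr(outdir: Path, sp: str):
    tpm = pd.read_csv(outdir / f"tpm_{sp}.tsv", sep="\t", index_col="gene_id")
    counts = pd.read_csv(outdir / f"counts_{sp}.tsv", sep="\t", index_col="gene_id")
    samples = pd.read_csv(outdir / "samples.tsv", sep="\t", index_col="sample_id")
    samples = samples.loc[tpm.columns]
    return counts[tpm.columns], tpm, samples


def stage_callbias(outdir: Path, cfg: dict, seed: int | None) -> None:
    floors = {}
    for sp in _species(cfg):
        counts, tpm, samples = _load_species_expr(outdir, sp)
        floor = expr.expression_floor(tpm)
        floors[sp] = floor
        expressed, means = expr.filter_expressed(tpm, samples, floor)
        test = bc.nb_wald_test(counts, samples)
        calls = bc.classify_bias(test, means, floor, expressed)
        calls.to_csv(outdir / f"biascall_{sp}.tsv", sep="\t", index_label="gene_id")
    (outdir / "floors.json").write_text(json.dumps(floors, indent=1, sort_keys=True))


def stage_orthology(outdir: Path, cfg: dict, seed: int | None) -> None:
    omap = orthology.read_orthogroups(outdir / "Orthogroups.tsv")
    sets = orthology.derive_sets(omap, _species_pairs(cfg))
    counts = omap.copy_counts()
    counts.loc[sets.aso].to_csv(outdir / "aso.tsv", sep="\t", index_label="orthogroup")
    for pair, ogs in sets.pso.items():
        counts.loc[ogs].to_csv(
            outdir / f"pso_{pair[0]}_{pair[1]}.tsv", sep="\t", index_label="orthogroup"
        )
    gene_species = pd.read_csv(
        outdir / "gene_species_map.tsv", sep="\t", index_col="gene_id"
    )["species"]
    hits = orthology.read_blast6(outdir / "hits.tsv")
    genes_by_species = {
        sp: gene_species.index[gene_species == sp].tolist() for sp in _species(cfg)
    }
    orphans = orthology.find_orphans(genes_by_species, hits, gene_species)
    pd.DataFrame(
        [(sp, g) for sp in sorted(orphans) for g in sorted(orphans[sp])],
        columns=["species", "gene_id"],
    ).to_csv(outdir / "orphans.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(sp, a, b) for sp in sorted(sets.inparalogs) for a, b in sorted(sets.inparalogs[sp])],
        columns=["species", "gene1", "gene2"],
    ).to_csv(outdir / "inparalogs.tsv", sep="\t", index=False)


def _load_calls(outdir: Path, species: list[str]) -> dict[str, pd.DataFrame]:
    return {
        sp: pd.read_csv(outdir / f"biascall_{sp}.tsv", sep="\t", index_col="gene_id")
        for sp in species
    }


def stage_conserve(outdir: Path, cfg: dict, seed: int | None) -> None:
    species = _species(cfg)
    calls = _load_calls(outdir, species)
    omap = orthology.read_orthogroups(outdir / "Orthogroups.tsv")
    aso = pd.read_csv(outdir / "aso.tsv", sep="\t", index_col="orthogroup").index.tolist()
    states = cons.bias_state_table(calls, omap, aso)
    categories = cons.classify_aso_table(states)
    pd.concat([states, categories], axis=1).to_csv(
        outdir / "aso_categories.tsv", sep="\t", index_label="orthogroup"
    )
    for pair in _species_pairs(cfg):
        pso = pd.read_csv(
            outdir / f"pso_{pair[0]}_{pair[1]}.tsv", sep="\t", index_col="orthogroup"
        ).index.tolist()
        pstates = cons.bias_state_table(calls, omap, pso, species=list(pair))
        pcat = cons.classify_pso_table(pstates, pair)
        pd.concat([pstates[list(pair)], pcat], axis=1).to_csv(
            outdir / f"pso_categories_{pair[0]}_{pair[1]}.tsv", sep="\t", index_label="orthogroup"
        )
    floors = json.loads((outdir / "floors.json").read_text())
    report = cons.summary_report(calls, categories, floors)
    biased_ogs = {}
    for sp in species:
        biased = set(calls[sp].index[calls[sp]["class"].isin(["GA-biased", "SP-biased"])])
        biased_ogs[sp] = {
            og for og, members in omap.groups.items() if set(members[sp]) & biased
        }
    report["venn_biased_ogs"] = cons.venn_counts(biased_ogs)
    (outdir / "conservation_summary.json").write_text(json.dumps(report, indent=1, sort_keys=True))


def stage_divergence(outdir: Path, cfg: dict, seed: int | None) -> None:
    species = _species(cfg)
    cds = {
        sp: {r.id: str(r.seq) for r in SeqIO.parse(str(outdir / f"cds_{sp}.fasta"), "fasta")}
        for sp in species
    }
    calls = _load_calls(outdir, species)
    rows, eucd_rows = [], []
    for pair in _species_pairs(cfg):
        pso = pd.read_csv(
            outdir / f"pso_{pair[0]}_{pair[1]}.tsv", sep="\t", index_col="orthogroup"
        ).index.tolist()
        omap = orthology.read_orthogroups(outdir / "Orthogroups.tsv")
        tpm_means = {
            sp: expr.generation_means(
                pd.read_csv(outdir / f"tpm_{sp}.tsv", sep="\t", index_col="gene_id"),
                pd.read_csv(outdir / "samples.tsv", sep="\t", index_col="sample_id"),
            )
            for sp in pair
        }
        for og in pso:
            g1 = omap.groups[og][pair[0]][0]
            g2 = omap.groups[og][pair[1]][0]
            s1, s2 = cds[pair[0]][g1], cds[pair[1]][g2]
            if len(s1) != len(s2):
                continue  # only pre-aligned equal-length pairs are analyzable without MSA
            aln = moldiv.CodonAlignment(ids=[g1, g2], seqs=[s1, s2])
            cur = moldiv.curate(aln)
            if not cur.retained:
                continue
            est = moldiv.ng86(cur.alignment)
            d = est.as_dict()
            d.update(orthogroup=og, pair=f"{pair[0]}|{pair[1]}", gene1=g1, gene2=g2)
            rows.append(d)
            prof1 = {g: float(tpm_means[pair[0]].loc[g1, g]) for g in ("GA", "SP")}
            prof2 = {g: float(tpm_means[pair[1]].loc[g2, g]) for g in ("GA", "SP")}
            eucd_rows.append(
                {
                    "orthogroup": og, "gene1": g1, "gene2": g2,
                    "pair": f"{pair[0]}|{pair[1]}",
                    "eucd": moldiv.euclidean_divergence(prof1, prof2),
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "divergence.tsv", sep="\t", index=False)
    pd.DataFrame(eucd_rows).to_csv(outdir / "eucd.tsv", sep="\t", index=False)

    enc_rows = []
    for sp in species:
        background = moldiv.background_from_sequences(list(cds[sp].values()))
        for g in sorted(cds[sp]):
            e, ep = moldiv.enc(moldiv.codon_usage(cds[sp][g]), background)
            cls = calls[sp]["class"].get(g, "unbiased")
            enc_rows.append({"species": sp, "gene_id": g, "enc": e, "enc_prime": ep, "class": cls})
    pd.DataFrame(enc_rows).to_csv(outdir / "enc.tsv", sep="\t", index=False)


def _tip_state_tables(outdir: Path, cfg: dict):
    """Two binary characters per ASO (GA-bias present, SP-bias present);
    missing species are missing tips."""
    species = _species(cfg)
    calls = _load_calls(outdir, species)
    omap = orthology.read_orthogroups(outdir / "Orthogroups.tsv")
    aso = pd.read_csv(outdir / "aso.tsv", sep="\t", index_col="orthogroup").index.tolist()
    states = cons.bias_state_table(calls, omap, aso)
    tables = {"GA": {}, "SP": {}}
    for og, row in states.iterrows():
        for trait in ("GA", "SP"):
            tables[trait][og] = {
                sp: (traitmap.MISSING if row[sp] == "missing" else int(row[sp] == trait))
                for sp in species
            }
    return tables


def stage_traitmap(outdir: Path, cfg: dict, seed: int | None) -> None:
    tree = traitmap.Phylogeny.from_newick((outdir / "tree.nwk").read_text())
    tables = _tip_state_tables(outdir, cfg)
    tcfg = cfg.get("traitmap", {})
    n_maps = int(tcfg.get("n_maps", 1000))
    base_seed = seed if seed is not None else int(tcfg.get("seed", 0))
    out = {}
    fit_rows = []
    for trait, table in tables.items():
        results = traitmap.fit_and_map_genes(
            tree, table, n_maps=n_maps, seed=base_seed + (0 if trait == "GA" else 1)
        )
        out[trait] = traitmap.aggregate(results, tree)
        # per-gene rate MLEs on a 4-taxon tree often sit on a bound, so also
        # report the rate fitted jointly to all genes of this trait
        pooled = traitmap.fit_mk_pooled(tree, list(table.values()), "ER")
        out[trait]["pooled_q"] = pooled.model.q01
        for og, res in sorted(results.items()):
            fit_rows.append(
                {
                    "orthogroup": og, "trait": trait,
                    "q01": res.model.q01, "q10": res.model.q10,
                    "lnl_er": res.lnl_er, "lnl_ard": res.lnl_ard, "lrt_p": res.lrt_p,
                    "n_maps": res.n_maps, "seed": res.seed,
                }
            )
    pd.DataFrame(fit_rows).to_csv(outdir / "traitmap_fits.tsv", sep="\t", index=False)
    branch_rows = []
    for trait, agg in out.items():
        if agg.get("empty"):
            continue
        for b, t in sorted(agg["branch_totals"].items()):
            branch_rows.append({"trait": trait, "branch": b, "expected_gains": t["gain"], "expected_losses": t["loss"]})
    pd.DataFrame(branch_rows).to_csv(outdir / "branch_totals.tsv", sep="\t", index=False)
    summary = {
        t: {k: v for k, v in agg.items() if k != "branch_totals"} for t, agg in out.items()
    }
    (outdir / "traitmap_summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))


def stage_enrich(outdir: Path, cfg: dict, seed: int | None) -> None:
    species = _species(cfg)
    ann = pd.read_csv(outdir / "annotations.tsv", sep="\t")
    calls = _load_calls(outdir, species)
    for sp in species:
        c = calls[sp]
        background = set(c.index[c["class"] != "not-expressed"])
        for direction in ("GA-biased", "SP-biased"):
            target = set(c.index[c["class"] == direction])
            if not target or not background:
                continue
            res = cons.fisher_enrichment(target, background, ann)
            res.to_csv(outdir / f"enrichment_{sp}_{direction.split('-')[0]}.tsv", sep="\t", index=False)


def stage_report(outdir: Path, cfg: dict, seed: int | None) -> None:
    species = _species(cfg)
    calls = _load_calls(outdir, species)
    report = cons.summary_report(calls)
    report["version"] = __version__
    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))


_STAGES = {
    "simulate": stage_simulate,
    "tpm": stage_tpm,
    "callbias": stage_callbias,
    "orthology": stage_orthology,
    "conserve": stage_conserve,
    "divergence": stage_divergence,
    "traitmap": stage_traitmap,
    "enrich": stage_enrich,
    "report": stage_report,
}


def run(
    config: dict | str | Path,
    outdir,
    stages: list[str] | None = None,
    seed: int | None = None,
) -> dict:
    """Run the pipeline (or a stage subset) and return the run manifest."""
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = stages or STAGE_ORDER
    unknown = set(stages) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in STAGE_ORDER if s in stages]
    species = _species(config)

    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "stages": [],
        "outputs": {},
    }
    for stage in stages:
        _check_inputs(stage, outdir, species)
        _log("info", stage, "start")
        t0 = time.time()
        before = {p.name for p in outdir.iterdir()}
        mtimes = {p.name: p.stat().st_mtime_ns for p in outdir.iterdir()}
        _STAGES[stage](outdir, config, seed)
        wrote = sorted(
            p.name
            for p in outdir.iterdir()
            if p.name not in before or p.stat().st_mtime_ns != mtimes.get(p.name)
        )
        for name in wrote:
            manifest["outputs"][name] = _sha256(outdir / name)
        manifest["stages"].append({"stage": stage, "seconds": round(time.time() - t0, 3), "wrote": wrote})
        _log("info", stage, "done", seconds=round(time.time() - t0, 3))
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
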