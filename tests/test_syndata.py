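"""The synthetic-data generator: determinism, internal consistency, planted
patterns, and the elementary simulators."""

import dataclasses
import hashlib

import numpy as np
import pytest
from scipy import stats

from genbias import syndata
from genbias._codons import STOP_CODONS
from genbias.moldiv import CodonAlignment, ng86
from genbias.syndata import (
    SimConfig,
    simulate_codon_pair,
    simulate_counts,
    simulate_dataset,
    simulate_trait_history,
)
from genbias.traitmap import Phylogeny


class TestSimConfig:
    def test_bad_fraction_sum_names_field(self, make_config):
        cfg = make_config(
            pattern_fractions={"single_copy": 0.5, "missing_one": 0.2, "duplicated": 0.2, "orphan": 0.2}
        )
        with pytest.raises(ValueError, match="pattern_fractions"):
            cfg.validate()

    def test_nonpositive_rate_names_field(self, make_config):
        with pytest.raises(ValueError, match="bias_gain_rate"):
            make_config(bias_gain_rate=0.0).validate()

    def test_single_replicate_rejected(self, make_config):
        with pytest.raises(ValueError, match="n_replicates"):
            make_config(n_replicates=1).validate()


class TestSimulateCounts:
    def test_zero_dispersion_is_poisson(self):
        x = simulate_counts(50.0, 0.0, 20000, np.random.default_rng(0))
        assert x.var() / x.mean() == pytest.approx(1.0, rel=0.05)

    def test_nb_variance_matches_moment_formula(self):
        # Var = mu + alpha * mu^2 = 100 + 0.1 * 1e4 = 1100
        x = simulate_counts(100.0, 0.1, 10000, np.random.default_rng(1))
        assert x.var() == pytest.approx(1100.0, rel=0.05)
        assert x.mean() == pytest.approx(100.0, rel=0.05)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            simulate_counts(100.0, 0.1, 0, 0)
        with pytest.raises(ValueError):
            simulate_counts(0.0, 0.1, 5, 0)
        with pytest.raises(ValueError):
            simulate_counts(10.0, -1.0, 5, 0)


class TestSimulateCodonPair:
    def test_zero_time_identical(self):
        a, b = simulate_codon_pair(0.5, 0.0, 100, seed=0)
        assert a == b

    def test_omega_zero_changes_all_synonymous(self):
        """With the nonsynonymous rate at zero every substitution preserves
        the amino acid, so the two proteins are identical."""
        from Bio.Seq import Seq

        a, b = simulate_codon_pair(0.0, 1.0, 300, seed=1)
        assert a != b
        assert str(Seq(a).translate()) == str(Seq(b).translate())

    def test_no_stop_codons_emitted(self):
        a, b = simulate_codon_pair(1.0, 2.0, 200, seed=2)
        for seq in (a, b):
            codons = {seq[i : i + 3] for i in range(0, len(seq), 3)}
            assert not codons & STOP_CODONS

    def test_omega_recovery_ordering(self):
        means = []
        for omega in (0.2, 1.0):
            vals = []
            for r in range(40):
                a, b = simulate_codon_pair(omega, 0.4, 500, seed=1000 * r + int(10 * omega))
                est = ng86(CodonAlignment(ids=["a", "b"], seqs=[a, b]))
                if est.omega is not None:
                    vals.append(est.omega)
            means.append(np.mean(vals))
        assert means[0] < means[1]


class TestSimulateTraitHistory:
    tree = Phylogeny.from_newick("((A:0.5,B:0.5):0.5,(C:0.5,D:0.5):0.5);")

    def test_zero_rates_all_nodes_share_root_state(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            h = simulate_trait_history(self.tree, 0.0, 0.0, 0.7, rng)
            assert len(set(h.values())) == 1

    def test_saturated_rates_approach_half_half(self):
        rng = np.random.default_rng(4)
        ones = 0
        n = 4000
        for _ in range(n):
            h = simulate_trait_history(self.tree, 50.0, 50.0, 0.0, rng)
            ones += h[self.tree.leaf_index["A"]]
        freq = ones / n
        assert abs(freq - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_fixed_seed_reproducible(self):
        a = simulate_trait_history(self.tree, 1.0, 2.0, 0.3, 99)
        b = simulate_trait_history(self.tree, 1.0, 2.0, 0.3, 99)
        assert a == b


class TestSimulateDataset:
    def test_same_seed_byte_identical_bundle(self, tmp_path):
        cfg = SimConfig(n_orthogroups=40, seed=7)
        d1, d2 = tmp_path / "r1", tmp_path / "r2"
        simulate_dataset(cfg).write(d1)
        simulate_dataset(cfg).write(d2)
        for p1 in sorted(d1.iterdir()):
            h1 = hashlib.sha256(p1.read_bytes()).hexdigest()
            h2 = hashlib.sha256((d2 / p1.name).read_bytes()).hexdigest()
            assert h1 == h2, p1.name

    def test_bundle_internally_consistent(self, bundle):
        truth = bundle.truth
        for og in truth.orthogroups.values():
            for sp, genes in og.members.items():
                for g in genes:
                    assert g in bundle.cds[sp]
                    assert g in bundle.counts[sp].index

    def test_every_gene_appears_exactly_once(self, bundle):
        seen = []
        for og in bundle.truth.orthogroups.values():
            for genes in og.members.values():
                seen.extend(genes)
        assert len(seen) == len(set(seen)) == len(bundle.truth.genes)

    def test_orphans_have_no_cross_species_hits(self, bundle):
        orphan_genes = {g for s in bundle.truth.orphan_genes().values() for g in s}
        gene_sp = {g: t.species for g, t in bundle.truth.genes.items()}
        cross = bundle.hits[
            bundle.hits.apply(lambda r: gene_sp[r.qseqid] != gene_sp[r.sseqid], axis=1)
        ]
        assert not (set(cross["qseqid"]) & orphan_genes)
        assert not (set(cross["sseqid"]) & orphan_genes)

    def test_non_orphans_have_reciprocal_significant_hits(self, bundle):
        sig = bundle.hits[bundle.hits["evalue"] <= 1e-6]
        pairs = set(zip(sig["qseqid"], sig["sseqid"]))
        gene_sp = {g: t.species for g, t in bundle.truth.genes.items()}
        non_orphan_multi = [
            og for og in bundle.truth.orthogroups.values() if og.pattern != "orphan"
        ]
        for og in non_orphan_multi[:30]:
            members = [(sp, g) for sp, gs in og.members.items() for g in gs]
            for sp1, g1 in members:
                for sp2, g2 in members:
                    if g1 != g2 and sp1 != sp2:
                        assert (g1, g2) in pairs and (g2, g1) in pairs

    def test_no_internal_stops_and_length_multiple_of_three(self, bundle):
        for sp, seqs in bundle.cds.items():
            for g, seq in seqs.items():
                assert len(seq) % 3 == 0
                codons = {seq[i : i + 3] for i in range(0, len(seq), 3)}
                assert not codons & STOP_CODONS

    def test_pattern_fractions_within_binomial_bounds(self, bundle):
        cfg = bundle.config
        n = cfg.n_orthogroups
        tally = {p: 0 for p in syndata.PATTERNS}
        for og in bundle.truth.orthogroups.values():
            tally[og.pattern] += 1
        for p, frac in cfg.pattern_fractions.items():
            lo, hi = stats.binom.ppf([0.005, 0.995], n, frac)
            assert lo <= tally[p] <= hi, (p, tally[p])

    def test_zero_orphan_fraction_all_genes_hit_other_species(self, make_config):
        cfg = make_config(
            n_orthogroups=40,
            seed=5,
            pattern_fractions={"single_copy": 0.5, "missing_one": 0.25, "duplicated": 0.25, "orphan": 0.0},
        )
        b = simulate_dataset(cfg)
        gene_sp = {g: t.species for g, t in b.truth.genes.items()}
        cross_hits = {
            q for q, s in zip(b.hits["qseqid"], b.hits["sseqid"]) if gene_sp[q] != gene_sp[s]
        }
        assert set(b.truth.genes) == cross_hits

    def test_zero_effect_scale_gives_no_biased_genes(self, make_config):
        cfg = make_config(n_orthogroups=30, seed=6, effect_location=0.0, effect_scale=0.0)
        b = simulate_dataset(cfg)
        assert b.truth.biased_genes() == set()

    def test_tip_states_match_ledger_histories(self, bundle):
        tree = Phylogeny.from_newick(bundle.tree_newick)
        for og in bundle.truth.orthogroups.values():
            for sp, genes in og.members.items():
                leaf_branch = tree.branch_id[tree.leaf_index[sp]]
                for g in genes:
                    t = bundle.truth.genes[g]
                    assert (t.bias_state == "GA") == bool(og.ga_history[leaf_branch])
                    assert (t.bias_state == "SP") == bool(og.sp_history[leaf_branch])

    def test_round_trip_bias_recovery(self):
        """Running the expression + DE stages on a ~2000-gene bundle recovers
        the planted biased genes: sensitivity >= 0.9 for strong effects
        (|log2FC| >= 3, base mean >= 100) and observed FDR <= 0.1 at a
        nominal BH level of 0.05."""
        from genbias import biascall as bc
        from genbias import expression as expr

        cfg = SimConfig(n_orthogroups=620, seed=13)
        b = simulate_dataset(cfg)
        assert len(b.truth.genes) >= 2000
        tp = fn = fp = n_disc = 0
        for sp in cfg.species_names:
            samples = b.samples[b.samples["species"] == sp]
            counts = b.counts[sp][samples.index]
            tpm = expr.compute_tpm(counts, b.cds_lengths(sp))
            floor = expr.expression_floor(tpm)
            expressed, means = expr.filter_expressed(tpm, samples, floor)
            test = bc.nb_wald_test(counts, samples)
            calls = bc.classify_bias(test, means, floor, expressed)
            for g in counts.index:
                t = b.truth.genes[g]
                called = calls.loc[g, "class"]
                if called in ("GA-biased", "SP-biased"):
                    n_disc += 1
                    if t.bias_state == "unbiased":
                        fp += 1
                if (
                    t.bias_state != "unbiased"
                    and abs(t.true_log2fc) >= 3
                    and t.base_mean >= 100
                ):
                    if called == f"{t.bias_state}-biased":
                        tp += 1
                    else:
                        fn += 1
        assert tp / (tp + fn) >= 0.9
        assert fp / max(n_disc, 1) <= 0.1

    def test_truth_ledger_json_roundtrip(self, bundle):
        text = bundle.truth.to_json()
        back = syndata.TruthLedger.from_json(text)
        assert back.to_json() == text
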