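# Methods

This note records the models, estimators, defaults and numerical choices
behind each module, and what the synthetic-data tests do and do not
demonstrate about real data.

## Expression quantification and the species floor

Expression is quantified as TPM from raw counts c and effective lengths ℓ
(tpm_ij = 10⁶·(c_ij/ℓ_i)/Σ_k(c_kj/ℓ_k)); the effective length is the CDS
length, with no fragment-length correction — adequate for gene-level,
single-isoform models. The species expression floor is the 5th percentile
of the pooled replicate-level TPM values of that species, using the linear
interpolation between order statistics (numpy default). Replicate-level
pooling (rather than pooling per-gene means) was chosen because the floor
is later compared against per-generation means of the same matrix. A gene
counts as expressed when its mean TPM reaches the floor in at least one
generation; the gene is otherwise excluded from all downstream stages.
Note the interpolated percentile is not exactly invariant under duplicating
the pooled sample (only inverse-CDF quantiles are); the discrepancy is
bounded by the local gap between order statistics and is irrelevant at
transcriptome scale.

## Differential expression and bias classification

The DE engine is a self-contained negative-binomial Wald test in the
DESeq2 mould, not a wrapper:

* size factors by median-of-ratios over genes with all-positive counts,
  rescaled to geometric mean 1;
* gene-wise method-of-moments dispersions from within-group variability of
  normalized counts, a mean-dispersion trend α(μ) = a₀ + a₁/μ fitted by
  least squares over genes with a positive moment estimate, and geometric
  interpolation between gene and trend with weight 0.5 (genes whose moment
  estimate collapses to zero take the trend value; lower bound 10⁻⁸);
* per-group NB means by Newton iteration on the log scale with the
  dispersion held fixed; Wald z from the Fisher information
  I_g = Σ_i μ_i/(1+αμ_i).

Genes with zero counts everywhere are reported NA and excluded from the BH
correction (implemented in-package and cross-checked against a brute-force
step-up and against statsmodels in the tests). There is no independent
filtering, no outlier (Cook's) handling and no LFC shrinkage; with two
replicates per group the normal Wald approximation is mildly
anti-conservative in the far tail, which the calibration tests quantify
(global-null BH rejections stay near 1% of genes at a nominal 0.05).

Classification uses the raw fold-change estimate: GA-biased iff
log₂FC ≥ 1 and padj < 0.05 (threshold inclusive on fold change, strict on
FDR, the sign convention being positive = gametophyte-biased); specific iff
biased and the losing generation's mean TPM is below the floor; |FC| binned
into [2,6), [6,20), ≥20 with upper boundaries assigned upward and the
comparison done on the log₂ scale so the edges are exact in floating point.

## Orthology sets

ASOs are orthogroups with exactly one gene in every species or exactly one
in all but one species; PSOs are per-pair 1:1 orthogroups regardless of the
other species. The orphan screen uses any-hit semantics with an inclusive
cutoff (a single cross-taxon hit at e ≤ 10⁻⁴ rescues); same-species hits
never rescue, since taxonomic restriction is a cross-taxon property.
Subject species are resolved through an explicit gene→species map file
rather than id-prefix parsing.

## Conservation categories

An ASO with both a GA- and an SP-biased member is discordant regardless of
how many species share one direction; otherwise shared-k counts the biased
species (missing species never block sharing). PSO pairs are conserved,
discordant, gain-loss (exactly one biased) or unbiased. Enrichment reports
the one-sided hypergeometric p per term with the study-style uncorrected
0.05 cutoff alongside a BH column. A chi-squared goodness-of-fit utility
with explicit df is provided for event-total contrasts; note that for the
published totals 3469 vs 3008 an equal-expectation GOF gives χ² ≈ 32.8,
not the printed 16.281 — the contingency behind that printed value is not
recoverable, so the utility implements the standard GOF and this
discrepancy is simply documented.

## Molecular divergence

Pairwise dN/dS uses Nei–Gojobori (1986) counting rather than codeml ML:
synonymous site fractions per codon averaged over both sequences, with
changes that create a stop codon counted as nonsynonymous so that
S + N equals the ungapped length in nucleotides; observed differences
resolved by equal-weight pathway averaging with stop-traversing pathways
excluded (if every pathway is blocked, all are used); Jukes–Cantor
correction d = −¾·ln(1 − 4p/3); ω undefined when dS = 0; saturated when
dS > 2 or p ≥ ¾ in either class, and saturated records are excluded from ω
summaries. Because counting methods compress large ω slightly (pathway
averaging attributes some purely synonymous multi-hit codons to
nonsynonymous routes), recovery tests check ordering across planted ω
classes rather than unbiasedness. Alignment curation drops whole codon
columns containing any gap and retains pairs whose gapless alignment
exceeds 100 nt (strict), replacing heuristic block filtering.

ENC uses Wright's formula 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆ with
homozygosity F = Σp² per amino acid (the uncorrected form, so uniform
usage of all 61 sense codons gives exactly 61 and single-codon usage
exactly 20 at any depth); a missing 3-fold class is imputed as the mean of
the 2- and 4-fold classes, and unobserved classes default to no bias. With
a background codon-frequency profile (e.g. ribosomal genes), ENC′ replaces
F by (X²/n + 1)/k, where X² measures deviation of observed codon counts
from background-expected ones within the amino acid — the
background-correction idea of ENCprime, with matching limits (usage equal
to background ⇒ 61) but not bit-identical numerics.

Expression divergence between the two members of a PSO is the Euclidean
distance over the k = 2 stages, EucD = √Σⱼ(x₁ⱼ−x₂ⱼ)², on raw TPM by
default (a log₂(TPM+1) flag exists; raw TPM makes the measure dominated by
highly expressed genes, which is inherent to the definition).

## Stochastic mapping of bias gain/loss

Each orthogroup carries two independent binary characters — GA-bias
present, SP-bias present — with missing species as missing tips. The
two-state chain with gain rate q01 and loss rate q10 has the closed-form
transition matrix used throughout; likelihoods come from Felsenstein
pruning with an equal (½, ½) root prior by default (a stationary-prior
option exists). ML fitting optimizes log-rates in [10⁻⁸, 10³] with L-BFGS-B
and 5 fixed-seed multistarts; ER constrains q01 = q10. Invariant tip
patterns pin the rate at the lower bound and record LRT p = 1.

Stochastic maps draw the joint internal-node states exactly (backward
pruning, forward root-to-tip sampling); a branch records a gain when its
sampled parent/child states are 0→1 and a loss for 1→0, so within-branch
multiple hits deliberately do not count, and per-gene per-map events on a
branch never exceed one. An inside–outside computation of the exact
parent≠child posterior per branch is provided; the sampler is tested to
converge to it within Monte-Carlo error.

Two facts shape the many-gene drivers. First, a single binary character on
a four-taxon tree barely constrains two free rates: the ER-vs-ARD LRT
statistic has a supremum below the χ²₁ critical value over *all* tip
patterns, so per-gene tests at α = 0.05 never reject — rate equality can
only be meaningfully tested by pooling genes, and the pooled LRT is well
calibrated (tested over replicate 500-gene datasets). Second, per-gene
rate MLEs frequently sit on an optimization bound, so per-gene rate means
are dominated by boundary estimates; the pipeline therefore also reports
the pooled per-trait rate, and recovery tests use pooled fits.

## Synthetic data: what it emulates and what it does not

The generator mirrors the design of a four-species gametophyte/sporophyte
RNA-seq comparison: two species pairs from two orders on a rooted tree
(default depth ≈ 0.8 in rate units), orthogroup occupancy fractions close
to the observed mix (31% 1:1:1:1, 20% 1:1:1:0, 34% duplicated, 15%
orphan), bias characters evolved at gain = loss = 1.3 (the scale of the
reported mean per-gene transition rates) with root bias probability 0.25,
planted |log₂FC| = 2.5 + 1.5·|N(0,1)| so that all three fold-change bins
are populated, NB counts with dispersion 0.05 around lognormal base means
(median 100), three replicates per generation, and codon sequences
diverged from a common ancestor at t = 0.3 under class-specific ω
(0.6/0.3/0.2 for GA-/SP-/unbiased) with class-specific third-position GC
and intron counts so the structural contrasts are reproducible
qualitatively. Orthogroups where a tip would be biased in both directions
are rejection-resampled, keeping histories and tip states consistent.
Effect-size and dispersion distributions are conventional choices, not
fitted to any real dataset.

Deliberately not emulated: read-level noise and mapping artifacts, indels
(sequences are emitted pre-aligned and gap-free), assembly/annotation
error, unequal codon frequencies in the substitution process (F-equal, not
F3x4), batch effects and multi-factor designs. Passing the round-trip
tests therefore shows the estimators are correct and calibrated under the
stated generative model, not that real draft-genome data would behave as
cleanly.

## Problem sizes and determinism

Default test and acceptance runs use 150–620 orthogroups, 2000-gene DE
simulations, 200 codon pairs per ω class at 500 codons, 500-gene Mk
recovery sets with 200 LRT replicates, and 20 000 stochastic maps —
sizes at which every Monte-Carlo band in the tests is meaningful while the
whole suite stays desk-scale. Every random stage takes an explicit seed;
one seed reproduces a byte-identical bundle, and the pipeline manifest
records SHA-256 checksums of every output.
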