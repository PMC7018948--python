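# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `mirsnp`. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and alphabets

External tables (variant, LD, gene-interval TSVs, GFF3, VCF) use 1-based
inclusive genomic coordinates; all internal sequence arithmetic is 0-based
half-open. Conversion happens once, at the I/O boundary. Sequences are
normalised to uppercase RNA (T→U); multi-allelic variant records are split
into biallelic pairs at load time and indel alleles are dropped with a
warning, since the analysis is defined for single-nucleotide substitutions
only. Minus-strand transcripts receive complemented alleles before
substitution (UTR sequences are stored in transcript sense).

## Seed engine

Canonical sites are defined on the UTR as exact Watson–Crick complements
of the miRNA seed: 6mer (nt 2–7), 7mer-m8 (nt 2–8), 7mer-A1 (nt 2–7 plus a
UTR adenosine opposite miRNA position 1) and 8mer (both). The A of
A1-containing sites is required in the UTR regardless of the identity of
miRNA position 1, following seed-match-predictor convention. Each
seed-complement window is reported once under its most specific type;
overlapping sites of the same miRNA are all reported, with no
site-spacing suppression. Transcripts with the
`nonsense_mediated_decay` biotype are skipped and marked.

Sites are scored with a deliberately simple additive context-style model:

    score = baseline(site type) + w_AU·f_AU + w_pos·f_pos + w_3p·f_3p

with default baselines −0.31 / −0.16 / −0.10 / −0.03 for
8mer / 7mer-m8 / 7mer-A1 / 6mer, w_AU = −0.05 on the AU fraction of the
15-nt flanks on either side of the site, w_pos = +0.03 on the site's
distance to the closer UTR end divided by UTR length (central sites are
mildly penalised), and w_3p = −0.01 per contiguous Watson–Crick pair
between miRNA nt 13–16 and the UTR region opposite. These constants are
calibration choices that preserve the published strength ordering of site
types and the qualitative direction of the three context features; they
are **not** the trained multi-feature context++ model, whose conservation
and P_CT branches require genome alignments out of scope here. The
downstream analysis consumes per-allele score *differences*, which makes
it robust to the absolute scale of the scoring model; absolute context
values from this model should not be compared against published
context++ tables.

## Duplex engine

The aligner is a Smith–Waterman/Gotoh local alignment over
*complementarity*: Watson–Crick pairs score +5, G:U wobbles +1,
mismatches −3, gaps −9 to open and −4 to extend (gap cost of a run of
length k is −9 − 4(k−1)), and every substitution column pairing a miRNA
position in 2–8 (counted from the mature 5' end) is multiplied by 4. The
miRNA is laid 3'→5' against the target 5'→3'. Ties are broken by highest
score, then smallest target start, then shortest alignment, making output
deterministic. Only the reporting cutoffs S ≥ 80 and MFE ≤ −16 kcal/mol
(both inclusive) are anchored in the published analysis; the remaining
constants are explicit configuration in the spirit of miRanda's strong
5'-seed weighting. The test suite proves the DP equal to exhaustive
enumeration of all gapped local alignments on short sequences, and that
seed scale 1 reduces it to a plain wobble-aware local aligner.

Duplex free energy is a simplified additive nearest-neighbor model: a
packaged stack table (standard Turner ΔG°37 constants for Watson–Crick
stacks; an approximate set for G:U-containing stacks), +4.0 kcal/mol per
maximal run of unpaired columns (internal loop or bulge), and +0.5
kcal/mol per helix terminus. A pair-of-pairs absent from the table is
treated as a loop event and logged once. An alignment with no paired
columns has energy 0 ("no stable duplex"), which is also the value an
absent hit contributes to allele differences. This is not a
partition-function fold; since the pipeline consumes only per-allele MFE
*differences* of near-identical windows, systematic offsets of the
simplified model largely cancel.

Multiple sites per target are found by masking the target span of each
accepted hit and rescanning. For the per-SNP::miRNA allele difference,
hits are matched across alleles by overlapping target span (the two
allele windows share coordinates); an unmatched hit is compared against 0
kcal/mol. max|ΔMFE| is the maximum absolute difference over matched
pairs, so identical hit lists give exactly 0.

## Per-allele comparison

The seed engine runs on full allele-substituted UTRs (seed predictors
operate on whole UTRs); the duplex engine runs on windows of 25 nt flank
on either side of the allele (51 nt when not truncated by a UTR end) —
an asymmetry that mirrors how the two tools are used in practice. The
per-allele context score at a SNP is the minimum (strongest) score over
sites whose window covers the SNP offset; absent predictions count as 0
in Δcontext = context(alt) − context(ref), so a single-allele prediction
passes the threshold on the strength of the predicted allele. The delta
cutoff 0.151 is inclusive (it was set *at* the weakest validated score);
the expression cutoffs RPM > 1 and TPM > 1 are strict, following their
">1" definitions. Engine agreement requires, by default, that both
engines favor the same allele; records where they disagree are flagged
`discordant`, and a switch relaxes the requirement to co-occurrence.

## DAE analysis

AE_norm = log2((RNA_A/RNA_B)/(DNA_A/DNA_B)) cancels DNA dosage and probe
effects; it is antisymmetric under allele relabeling and invariant under
per-channel rescaling (property-tested). DAE is called when |AE_norm| ≥
0.58 (1.5-fold) in at least 10% of heterozygotes and at least three
samples; the 10% requirement is rounded up (the stricter reading), with
floor rounding available as an option.

QC precedes calling, in this order: (1) mean over samples of
log2(RNA_A + RNA_B) ≥ 9.5; (2) allelic discrimination — equal-variance
two-sample t-tests of RNA log-ratios, heterozygotes against each
homozygote group, both p ≤ 0.05 (Welch available as an option; an empty
genotype group makes the comparison untestable and fails the SNP);
(3) call rate ≥ 90%, exact Hardy–Weinberg p > 10⁻⁵, ≥ 5 heterozygotes;
then structural exclusions (multi-mapping, dbSNP-suspect, sex chromosome)
consumed as pre-annotated flags. The first failing rule is recorded. The
intensity summand log2(RNA_A + RNA_B) is this package's interpretation of
"average log2 RNA signal intensity" as a per-SNP array summary.

The Hardy–Weinberg test is the exact conditional test: the probability,
under HWE and conditional on observed allele counts, of heterozygote
counts at least as improbable as the one observed, computed in log space
with gamma functions. The suite verifies it against full enumeration in
exact rational arithmetic for totals up to 200 and against the chi-square
approximation for large balanced counts.

## eQTL scan

Per gene, SNPs within ±1 Mb of the TSS are tested by ordinary
least-squares regression of expression on allele dosage (two-sided), with
Benjamini–Hochberg correction across all tests and a gene flagged when
any q ≤ 0.05. Zero-variance dosages are skipped. This is intentionally a
minimal scanner — not a permutation-based tissue-eQTL pipeline — so that
synthetic runs need no external data; the pipeline accepts precomputed
eQTL evidence equally well.

## The cis gate

The pipeline's default gate requires DAE (`cis_rule="dae_only"`), with
eQTL support computed and reported per candidate row; options
`dae_or_eqtl` and `dae_and_eqtl` are available. Rationale: DAE measures
cis-regulation directly within individuals and was the stated
requirement, while eQTL evidence is corroborative; moreover an FDR-based
scan admits occasional false gene flags by design, so conditioning the
candidate set on it would make results needlessly run-dependent.

The allele-direction check asks whether the allele with preferential
predicted binding is the under-expressed allele, as canonical repression
implies. It needs the candidate SNP and the DAE SNP on a known haplotype:
with r² < 0.2 or unknown phase it returns `untestable` rather than
guessing; a signed D′ convention carries phase when available. In
synthetic runs the DAE SNP is the candidate SNP itself, so phase is exact.

## Synthetic data generator

The generator emulates the study conditions: 64 array samples, 100 eQTL
samples, MAF 0.2–0.5, a 2-fold planted allelic imbalance, per-channel
array log-ratio noise 0.15, eQTL effect 1.0 expression units with residual
sd 0.5, 30 genes with 240–600-nt UTRs, 60 SNPs, 8 miRNAs of 22 nt. A
planted allele-specific site embeds the full antiparallel complement of
the chosen miRNA (with A opposite position 1) so the favored allele has an
8mer and a strong duplex while the other allele carries a seed mismatch
that abolishes the canonical site — both engines then agree in direction
by construction. Planted SNPs cycle through support strata (fully
supported; DAE without eQTL; unexpressed gene), and a few background
genes carry DAE without any planted site. Genotypes are drawn under HWE;
homozygote array log-ratios sit at ±3 with heterozygotes at 0 plus the
planted shift; intensities are exponentiated above the QC floor except a
small deliberately failing fraction, drawn only from genes without
planted DAE so failures cannot mask truth. Chance allele-differential
seed sites at non-planted SNPs are screened after generation and
recorded in the truth table (default) or regenerated away (option). Each
stage draws from its own RNG stream derived from one seed, so changing
one stage's parameters does not perturb the others.

What the generator does *not* emulate: real human UTR composition beyond
a GC-content knob, LD structure beyond a stated r² mixture (point mass
≥ 0.8 for true proxies, uniform [0, 0.5] for decoys), trans effects,
array normalisation artefacts, or multi-SNP haplotypes. Passing tests on
this generator therefore demonstrate correctness of the pipeline's logic
and calibration of its statistics, not genome-scale performance on real
annotation databases, whose site counts depend on database versions.

## Problem sizes and determinism

Default verification sizes: seed-engine oracle 200 UTRs (≤ 500 nt) × 5
miRNAs; alignment oracle 500 pairs of length ≤ 8 (exhaustive enumeration
grows combinatorially, and length 8 already exercises every recurrence
case); HWE oracle 100 random configurations with totals ≤ 200; DAE
recovery 200 SNPs × 20 heterozygotes at AE-noise 0.2; eQTL null
calibration 100 genes × 100 samples; end-to-end runs on the default
generator configuration. All stochastic components are seeded; pipeline
reruns on the same inputs are bit-identical, and output TSVs carry a
config hash for auditability.

## Known limitations

* No conservation scoring, no ORF/5'-UTR sites, no non-canonical
  (centred or 3'-compensatory) sites in the seed engine.
* The duplex energy model has no thermodynamic ensemble; G:U stack
  constants are approximate.
* The eQTL scanner is OLS + BH, not a permutation pipeline; its per-gene
  flags inherit FDR-level false positives by construction.
* LD is consumed, never estimated; phase inference between candidate and
  DAE SNPs is not attempted beyond the signed-D′ convention.
* Genome-wide catalogue counts are out of scope by design: all inputs are
  files (or the generator), never live database queries.
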