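# mirsnp

Allele-specific miRNA-binding prediction and cis-regulation evidence
integration for GWAS risk SNPs.

## The problem

Most disease risk variants found by genome-wide association studies sit in
non-coding sequence and are thought to act in *cis* on gene expression. One
under-examined mechanism is miRNA-mediated regulation: a SNP in the 3'-UTR
of a protein-coding gene can create, destroy or weaken a miRNA binding
site, so that the two alleles of a heterozygote are repressed unequally.
`mirsnp` implements a post-GWAS pipeline that queries each allele of a
3'-UTR risk SNP independently with two miRNA-target prediction engines,
quantifies the allelic difference, and prioritises candidate regulatory
SNPs (rSNPs) whose target gene shows independent evidence of
cis-regulation in the relevant tissue.

## The method

Starting from a GWAS association table, the cascade is:

1. keep genome-wide significant SNPs (P ≤ 5×10⁻⁸) and expand each with its
   LD proxies (r² ≥ 0.8 within 500 kb);
2. keep clean biallelic SNPs annotated `3_prime_UTR_variant` in
   protein-coding genes (and report overlap with miRNA genes separately);
3. for each SNP allele, run
   * a **seed engine**: canonical site detection (8mer, 7mer-m8, 7mer-A1,
     6mer — UTR segments Watson–Crick complementary to miRNA nucleotides
     2–7/2–8) on the full allele-substituted UTR, scored with an additive
     context-style model (lower = stronger repression), and
   * a **duplex engine**: Smith–Waterman/Gotoh local alignment of the
     miRNA (3'→5') against a 51-nt window centred on the allele, with G:U
     wobbles, affine gaps and 4× seed weighting, reporting hits with
     complementarity score S ≥ 80 and nearest-neighbor duplex free energy
     MFE ≤ −16 kcal/mol;
4. reduce to per-allele differences: Δcontext = context(alt) − context(ref)
   (an absent prediction counts as 0) and max|ΔMFE| across matched hits;
5. filter on |Δcontext| ≥ 0.151, miRNA expression (RPM > 1), target-gene
   expression (median TPM > 1), and directional agreement between the two
   engines;
6. gate on evidence of cis-regulation: differential allelic expression
   (DAE), measured on paired DNA/RNA arrays as

       AE_norm = log2((RNA_A/RNA_B) / (DNA_A/DNA_B)),

   calling DAE when |AE_norm| ≥ 0.58 (1.5-fold) in ≥ 10% of heterozygotes
   and ≥ 3 samples after a QC cascade (intensity, allelic discrimination,
   call rate, exact Hardy–Weinberg test, heterozygote count), with a
   cis-eQTL scan (OLS on allele dosage within ±1 Mb of the TSS,
   Benjamini–Hochberg FDR ≤ 0.05) as supporting evidence.

Candidates are ranked by decreasing |Δcontext|, and each row reports
whether the allele predicted to bind preferentially is also the
under-expressed allele (`consistent` / `discordant` / `untestable`), as
canonical miRNA repression predicts.

A synthetic-data module generates every input with planted ground truth
(allele-specific sites, allelic imbalance, eQTL effects), so the whole
analysis runs and is testable without any external download.

## Worked example

```bash
mirsnp simulate --seed 1 --outdir data/
mirsnp run-all --indir data/ --outdir out/ --seed 1
```

or equivalently in Python:

```python
from mirsnp import SimulationConfig, PipelineConfig, simulate, run_pipeline

ds = simulate(SimulationConfig(rng_seed=1))
result = run_pipeline(ds, PipelineConfig())
print(result.funnel)
```

The run prints the stage-by-stage funnel (distinct SNPs surviving each
filter):

```
total_variants       60
utr3_variants        59
predicted_variants   27
delta_pass           24
expression_pass      20
both_algorithms      20
cis_supported        20
```

Sixty risk-associated SNPs enter; one is removed as annotation-flagged; 27
show any allelic difference in either engine; 24 clear the |Δcontext| ≥
0.151 threshold; expression and engine-agreement filters leave 20, all of
which have DAE support here. The top candidate rows look like:

```
candidate_rsnp     gene     mirna  ref_context  alt_context  delta_context  ref_mfe  alt_mfe favored_allele  dae_supported  eqtl_supported expression_direction_consistent
      rs900015 SIMG0015 sim-miR-8    -0.373509          NaN       0.373509   -40.58   -29.06            ref           True            True                      consistent
      rs900001 SIMG0001 sim-miR-2    -0.371689          NaN       0.371689   -51.40   -39.72            ref           True            True                      consistent
      rs900012 SIMG0012 sim-miR-5    -0.369888          NaN       0.369888   -37.48   -25.96            ref           True            True                      consistent
      rs900011 SIMG0011 sim-miR-4          NaN    -0.369534      -0.369534   -27.97   -39.49            alt           True            True                      consistent
      rs900023 SIMG0023 sim-miR-8          NaN    -0.367720      -0.367720   -29.06   -40.58            alt           True           False                      consistent
```

Reading the first row: the reference allele of rs900015 carries a strong
predicted site for sim-miR-8 (context −0.374) that the alternative allele
abolishes (no prediction), the duplex engine agrees (MFE −40.6 vs −29.1
kcal/mol), the gene is expressed, shows DAE and an eQTL, and the favored
(ref) allele is indeed the under-expressed one — a fully supported
candidate regulatory SNP. Because these are planted truths, the final
table can be checked against the generator's truth tables
(`truth_snps.tsv`, `truth_genes.tsv`); the pipeline recovers exactly the
planted, supported SNPs and nothing from the no-effect stratum.

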