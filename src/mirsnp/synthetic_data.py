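"""Synthetic study generator with planted ground truth.

Generates every input the pipeline consumes — GWAS associations, LD-proxy
links, gene annotation, 3'-UTR and mature miRNA sequences, expression
tables, paired DNA/RNA allelic array intensities, and eQTL genotype +
expression matrices — with a truth table recording exactly which effects
were planted where. Defaults emulate the study conditions of the analysis
this package implements: 64 array samples, a 2-fold planted allelic
imbalance, ~0.15 log2 array noise, 100 eQTL samples with a planted dosage
effect of 1.0 expression units.

Planted allele-specific binding sites embed a full-length antiparallel
complement of the chosen miRNA in the UTR (with an A opposite miRNA
position 1), so the favored allele carries both a canonical 8mer seed
site and a high-S / low-MFE duplex, while the other allele holds a seed
mismatch that abolishes the canonical site and weakens the duplex — the
two engines therefore agree in direction by construction.

Each generator stage draws from its own RNG stream derived from
``rng_seed``, so reconfiguring one stage does not perturb the others.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seed_scan import RNA_COMPLEMENT, MatureMiRNA, UTRSequence, find_canonical_sites
from .variant_catalog import AnnotatedVariant, AssociationRecord, GeneInterval, ProxyRecord

logger = logging.getLogger(__name__)

_RNA = "ACGU"
_DNA_OF = {"A": "A", "C": "C", "G": "G", "U": "T"}

#: support stratum of each planted SNP, cycled in order
PLANTED_STRATA = ("full", "full", "full", "dae_only", "expr_fail")


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions."""

    rng_seed: int = 0
    n_genes: int = 30
    n_transcripts_per_gene: int = 1
    utr_length_range: tuple[int, int] = (240, 600)
    n_snps: int = 60                      # two per gene by default
    n_mirnas: int = 8
    n_leads: int = 6
    maf_range: tuple[float, float] = (0.2, 0.5)
    n_samples_array: int = 64             # array cohort size
    n_samples_eqtl: int = 100
    planted_site_fraction: float = 0.4
    dae_fold: float = 2.0                 # planted allelic fold change
    noise_sd_log2: float = 0.15           # per-channel array log-ratio noise
    eqtl_beta: float = 1.0
    eqtl_noise_sd: float = 0.5
    gc_content: float = 0.5
    chrom: str = "chr1"
    gene_spacing_bp: int = 200_000
    mirna_gene_margin: int = 2000
    qc_fail_fraction: float = 0.05        # deliberately low-intensity SNPs
    decoy_flagged: int = 1                # annotation-flagged UTR decoys
    screen_chance_sites: str = "report"   # 'report' | 'regenerate'

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_snps < 1 or self.n_mirnas < 1:
            raise ValueError("all counts must be >= 1")
        if not 0 <= self.planted_site_fraction <= 1:
            raise ValueError("planted_site_fraction must be in [0, 1]")
        if self.dae_fold < 1:
            raise ValueError("dae_fold must be >= 1")
        if self.screen_chance_sites not in ("report", "regenerate"):
            raise ValueError("screen_chance_sites must be 'report' or 'regenerate'")


@dataclass
class SyntheticDataset:
    """In-memory bundle of everything the pipeline reads, plus the truth."""

    config: SimulationConfig
    mirnas: list[MatureMiRNA]
    utrs: list[UTRSequence]
    genes: list[GeneInterval]
    variants: list[AnnotatedVariant]
    associations: list[AssociationRecord]
    ld: list[ProxyRecord]
    mirna_expression: pd.DataFrame   # mirna_id, rpm
    gene_expression: pd.DataFrame    # gene_id, tpm
    array_data: pd.DataFrame         # snp_id, sample_id, genotype, dna_a...
    eqtl_genotypes: pd.DataFrame     # samples × snps
    eqtl_expression: pd.DataFrame    # samples × genes
    snp_positions: dict[str, int]
    tss: dict[str, int]
    snp_gene: dict[str, str]         # snp -> gene whose UTR hosts it
    truth_snps: pd.DataFrame
    truth_genes: pd.DataFrame
    truth_mirnas: pd.DataFrame


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = ("sequences", "variants", "array", "expression", "eqtl")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _random_rna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list(_RNA), size=length, p=p))


def _complement_block(mirna: MatureMiRNA) -> str:
    """UTR 5'→3' block pairing the whole miRNA, A opposite position 1."""
    L = len(mirna.sequence)
    block = []
    for j in range(L):
        pos = L - j  # miRNA position paired by block offset j
        block.append("A" if pos == 1 else RNA_COMPLEMENT[mirna.sequence[pos - 1]])
    return "".join(block)


def _mismatch_base(rng: np.random.Generator, mirna_base: str, avoid: str) -> str:
    """A base that neither WC- nor wobble-pairs ``mirna_base``."""
    partner = {RNA_COMPLEMENT[mirna_base]}
    if mirna_base == "G":
        partner.add("U")
    elif mirna_base == "U":
        partner.add("G")
    choices = [b for b in _RNA if b not in partner and b != avoid]
    return str(rng.choice(choices))


def _distinct_mirnas(rng: np.random.Generator, n: int, gc: float) -> list[MatureMiRNA]:
    seen: set[str] = set()
    out: list[MatureMiRNA] = []
    i = 0
    while len(out) < n:
        seq = _random_rna(rng, 22, gc)
        if seq[1:8] in seen:
            continue
        seen.add(seq[1:8])
        i += 1
        out.append(MatureMiRNA(f"sim-miR-{i}", seq))
    return out


def _seed_diff_mirnas(
    utr_seq: str, offset: int, ref: str, alt: str, mirnas: list[MatureMiRNA],
    transcript_id: str,
) -> list[str]:
    """miRNAs whose canonical sites covering ``offset`` differ between alleles."""
    out = []
    for mirna in mirnas:
        per_allele = []
        for base in (ref, alt):
            seq = utr_seq[:offset] + base + utr_seq[offset + 1:]
            utr = UTRSequence(transcript_id, "g", seq)
            sites = {
                (s.site_type, s.start)
                for s in find_canonical_sites(utr, mirna)
                if s.covers(offset)
            }
            per_allele.append(sites)
        if per_allele[0] != per_allele[1]:
            out.append(mirna.mirna_id)
    return out


def simulate_annotation_and_sequences(
    config: SimulationConfig,
    rngs: dict[str, np.random.Generator] | None = None,
) -> dict:
    """Gene intervals, UTRs, miRNAs, variants, associations and LD table.

    Returns a dict of intermediate products consumed by :func:`simulate`.
    Deterministic for a fixed ``config.rng_seed``.
    """
    rngs = rngs or _streams(config.rng_seed)
    rng = rngs["sequences"]
    vrng = rngs["variants"]
    cfg = config

    mirnas = _distinct_mirnas(rng, cfg.n_mirnas, cfg.gc_content)

    genes: list[GeneInterval] = []
    utrs: list[UTRSequence] = []
    tss: dict[str, int] = {}
    lo, hi = cfg.utr_length_range
    utr_genomic_start: dict[str, int] = {}
    for g in range(cfg.n_genes):
        gene_id = f"SIMG{g:04d}"
        start = 100_000 + g * cfg.gene_spacing_bp
        length = int(rng.integers(lo, hi + 1))
        gene_end = start + 5_000 + length
        genes.append(GeneInterval(gene_id, "protein_coding", cfg.chrom, start, gene_end))
        tss[gene_id] = start
        seq = _random_rna(rng, length, cfg.gc_content)
        tid = f"SIMT{g:04d}"
        utrs.append(UTRSequence(tid, gene_id, seq, "protein_coding", "+"))
        utr_genomic_start[tid] = start + 5_000

    # a few miRNA genes in a variant-free gap: the 'within' list stays empty
    mir_start = 100_000 + cfg.n_genes * cfg.gene_spacing_bp + 50_000
    for k in range(2):
        genes.append(
            GeneInterval(
                f"SIM-MIRGENE{k}", "miRNA", cfg.chrom,
                mir_start + k * 10_000, mir_start + k * 10_000 + 80,
            )
        )

    # SNP placement: cycle genes, two SNPs per gene by default
    n_planted = round(cfg.planted_site_fraction * cfg.n_snps)
    snp_rows: list[dict] = []
    gene_cycle = [g % cfg.n_genes for g in range(cfg.n_snps)]
    for s, gidx in enumerate(gene_cycle):
        utr = utrs[gidx]
        planted = s < n_planted
        attempts = 0
        while True:
            attempts += 1
            if attempts > 50:
                raise RuntimeError("could not place SNP; UTR too short")
            L = len(utr.sequence)
            if L < 80:
                raise RuntimeError(f"UTR {utr.transcript_id} too short for planting")
            off = int(rng.integers(40, L - 40))
            if any(abs(off - r["offset"]) < 60 for r in snp_rows
                   if r["transcript_id"] == utr.transcript_id):
                continue
            break
        snp_id = f"rs90{s:04d}"
        if planted:
            mirna = mirnas[s % cfg.n_mirnas]
            block = _complement_block(mirna)
            j_snp = len(mirna.sequence) - 4   # block offset pairing miRNA nt 4
            bstart = off - j_snp
            if bstart < 0 or bstart + len(block) > L:
                off = j_snp + 5
                bstart = off - j_snp
            seq = list(utr.sequence)
            seq[bstart:bstart + len(block)] = block
            favored = block[j_snp]
            disfavored = _mismatch_base(vrng, mirna.sequence[3], favored)
            favored_is_ref = bool(vrng.random() < 0.5)
            seq[off] = favored if favored_is_ref else disfavored
            utr.sequence = "".join(seq)
            ref = utr.sequence[off]
            alt = disfavored if favored_is_ref else favored
            snp_rows.append(
                dict(
                    snp_id=snp_id, transcript_id=utr.transcript_id,
                    gene_id=utr.gene_id, offset=off,
                    ref=ref, alt=alt, planted_site=True,
                    favored_allele="ref" if favored_is_ref else "alt",
                    mirna_id=mirna.mirna_id,
                    stratum=PLANTED_STRATA[s % len(PLANTED_STRATA)],
                )
            )
        else:
            ref = utr.sequence[off]
            alt = str(vrng.choice([b for b in _RNA if b != ref]))
            snp_rows.append(
                dict(
                    snp_id=snp_id, transcript_id=utr.transcript_id,
                    gene_id=utr.gene_id, offset=off,
                    ref=ref, alt=alt, planted_site=False,
                    favored_allele="", mirna_id="", stratum="none",
                )
            )

    # chance-site screen on non-planted SNPs
    for row in snp_rows:
        utr = next(u for u in utrs if u.transcript_id == row["transcript_id"])
        expected = {row["mirna_id"]} if row["planted_site"] else set()
        diff = set(
            _seed_diff_mirnas(
                utr.sequence, row["offset"], row["ref"], row["alt"], mirnas,
                utr.transcript_id,
            )
        )
        chance = diff - expected
        if chance and cfg.screen_chance_sites == "regenerate":
            for _ in range(20):
                row["alt"] = str(vrng.choice([b for b in _RNA if b != row["ref"]]))
                diff = set(
                    _seed_diff_mirnas(
                        utr.sequence, row["offset"], row["ref"], row["alt"],
                        mirnas, utr.transcript_id,
                    )
                )
                chance = diff - expected
                if not chance:
                    break
        row["chance_site"] = bool(chance)
        row["chance_mirnas"] = ",".join(sorted(chance))
        if chance:
            logger.info("chance allele-differential site at %s (%s)",
                        row["snp_id"], row["chance_mirnas"])

    # genomic positions and offsets
    snp_positions: dict[str, int] = {}
    for row in snp_rows:
        utr = next(u for u in utrs if u.transcript_id == row["transcript_id"])
        utr.snp_offsets[row["snp_id"]] = row["offset"]
        snp_positions[row["snp_id"]] = (
            utr_genomic_start[row["transcript_id"]] + row["offset"]
        )

    # GWAS leads (intergenic positions between genes) and the LD table
    associations: list[AssociationRecord] = []
    ld: list[ProxyRecord] = []
    lead_ids = []
    for k in range(cfg.n_leads):
        lead = f"rs10{k:04d}"
        lead_ids.append(lead)
        pos = 90_000 + k * (cfg.n_genes // cfg.n_leads) * cfg.gene_spacing_bp
        p = float(10.0 ** vrng.uniform(-12, -8.5))
        associations.append(AssociationRecord(lead, cfg.chrom, pos, p, "sim trait", "sim"))
    # non-significant associations exercising the significance filter
    for k in range(3):
        associations.append(
            AssociationRecord(
                f"rs11{k:04d}", cfg.chrom, 50_000 + k * 1000,
                float(10.0 ** vrng.uniform(-6, -3)), "sim trait", "sim",
            )
        )
    for row in snp_rows:
        lead = lead_ids[
            min(snp_positions[row["snp_id"]] // (cfg.gene_spacing_bp *
                max(1, cfg.n_genes // cfg.n_leads)), cfg.n_leads - 1)
        ]
        dist = abs(snp_positions[row["snp_id"]] -
                   next(a.pos for a in associations if a.snp_id == lead))
        ld.append(
            ProxyRecord(
                lead, row["snp_id"], float(vrng.uniform(0.8, 1.0)),
                float(vrng.uniform(0.9, 1.0)), min(dist, 499_000),
            )
        )
        row["lead_snp"] = lead
    # decoy proxies in weak LD: excluded by the r2 filter
    for k in range(5):
        ld.append(
            ProxyRecord(
                lead_ids[k % cfg.n_leads], f"rs12{k:04d}",
                float(vrng.uniform(0.0, 0.5)), float(vrng.uniform(0.0, 0.9)),
                int(vrng.integers(1000, 400_000)),
            )
        )

    # variant annotation table
    variants: list[AnnotatedVariant] = []
    flagged_budget = cfg.decoy_flagged
    for row in snp_rows:
        flag = False
        if not row["planted_site"] and flagged_budget > 0 and row["stratum"] == "none":
            flag = flagged_budget > 0 and row["snp_id"].endswith("9")
            if flag:
                flagged_budget -= 1
        variants.append(
            AnnotatedVariant(
                snp_id=row["snp_id"], chrom=cfg.chrom,
                pos=snp_positions[row["snp_id"]],
                ref_allele=_DNA_OF[row["ref"]], alt_allele=_DNA_OF[row["alt"]],
                consequence_terms={"3_prime_UTR_variant"},
                gene_ids={row["gene_id"]}, transcript_ids={row["transcript_id"]},
                flagged=flag,
            )
        )
        row["flagged"] = flag
    # non-UTR decoy variants: removed by the consequence filter
    for k in range(4):
        snp = f"rs12{k:04d}"
        variants.append(
            AnnotatedVariant(
                snp_id=snp, chrom=cfg.chrom, pos=60_000 + k * 500,
                ref_allele="A", alt_allele="G",
                consequence_terms={"intron_variant" if k % 2 else "missense_variant"},
            )
        )

    truth_snps = pd.DataFrame(snp_rows)
    return dict(
        mirnas=mirnas, genes=genes, utrs=utrs, variants=variants,
        associations=associations, ld=ld, snp_positions=snp_positions,
        tss=tss, truth_snps=truth_snps,
    )


def _gene_truth(config: SimulationConfig, truth_snps: pd.DataFrame,
                rng: np.random.Generator, gene_ids: list[str]) -> pd.DataFrame:
    """Per-gene planted support derived from the SNP strata."""
    rows = []
    planted = truth_snps[truth_snps.planted_site]
    stratum_of_gene = dict(zip(planted.gene_id, planted.stratum))
    n_bg_dae = 0
    for gene in gene_ids:
        stratum = stratum_of_gene.get(gene, "none")
        if stratum == "full":
            is_dae, has_eqtl, expressed = True, True, True
        elif stratum == "dae_only":
            is_dae, has_eqtl, expressed = True, False, True
        elif stratum == "expr_fail":
            is_dae, has_eqtl, expressed = True, True, False
        else:
            # background cis-regulated genes without any planted site
            is_dae = n_bg_dae < 3
            n_bg_dae += 1 if is_dae else 0
            has_eqtl, expressed = False, True
        rows.append(
            dict(
                gene_id=gene, stratum=stratum, is_dae_gene=is_dae,
                dae_fold=config.dae_fold if is_dae else 1.0,
                has_eqtl=has_eqtl,
                beta=config.eqtl_beta if has_eqtl else 0.0,
                expressed=expressed,
            )
        )
    return pd.DataFrame(rows)


def simulate_array_data(
    config: SimulationConfig,
    truth_snps: pd.DataFrame,
    truth_genes: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Paired DNA/RNA allelic intensities with genotypes for every SNP.

    Genotypes are drawn under HWE at a per-SNP MAF. Homozygote log2
    allelic ratios sit at ±3 (allelic discrimination), heterozygotes at 0
    plus the planted DAE shift; the DNA channel carries no shift. Raw
    intensities are exponentiated around a base level above the intensity
    QC floor, except for a configurable fraction of deliberately failing
    SNPs drawn from genes without planted DAE.
    """
    cfg = config
    gene_truth = truth_genes.set_index("gene_id")
    rows: list[dict] = []
    base_log2 = 12.0
    fail_candidates = [
        r.snp_id for r in truth_snps.itertuples()
        if not gene_truth.loc[r.gene_id, "is_dae_gene"]
    ]
    n_fail = int(round(cfg.qc_fail_fraction * len(truth_snps)))
    fail_snps = set(fail_candidates[:n_fail])
    for r in truth_snps.itertuples():
        maf = float(rng.uniform(*cfg.maf_range))
        gt_probs = [(1 - maf) ** 2, 2 * maf * (1 - maf), maf ** 2]
        is_dae = bool(gene_truth.loc[r.gene_id, "is_dae_gene"])
        fold = float(gene_truth.loc[r.gene_id, "dae_fold"])
        # under-expressed allele follows the planted favored allele so the
        # canonical-repression direction check comes out consistent
        under_ref = r.favored_allele != "alt"
        shift = math.log2(fold) * (1 if not under_ref else -1)
        level = base_log2 if r.snp_id not in fail_snps else 8.0
        for s in range(cfg.n_samples_array):
            gt = str(rng.choice(["AA", "AB", "BB"], p=gt_probs))
            dna_ratio = {"AA": 3.0, "AB": 0.0, "BB": -3.0}[gt] + rng.normal(0, cfg.noise_sd_log2)
            rna_mean = {"AA": 3.0, "AB": 0.0, "BB": -3.0}[gt]
            if gt == "AB" and is_dae:
                rna_mean += shift
            rna_ratio = rna_mean + rng.normal(0, cfg.noise_sd_log2)
            total_dna = 2.0 ** (level + rng.normal(0, 0.1))
            total_rna = 2.0 ** (level + rng.normal(0, 0.1))
            dna_a = total_dna * 2.0 ** (dna_ratio / 2)
            dna_b = total_dna * 2.0 ** (-dna_ratio / 2)
            rna_a = total_rna * 2.0 ** (rna_ratio / 2)
            rna_b = total_rna * 2.0 ** (-rna_ratio / 2)
            rows.append(
                dict(
                    snp_id=r.snp_id, sample_id=f"S{s:03d}", genotype=gt,
                    dna_a=dna_a, dna_b=dna_b, rna_a=rna_a, rna_b=rna_b,
                )
            )
    return pd.DataFrame(rows)


def simulate_expression(
    config: SimulationConfig,
    truth_snps: pd.DataFrame,
    truth_genes: pd.DataFrame,
    truth_mirnas: pd.DataFrame,
    rng: np.random.Generator,
    snp_positions: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """miRNA RPM, gene TPM, and eQTL genotype/expression matrices."""
    cfg = config
    mirna_rows = [
        dict(
            mirna_id=r.mirna_id,
            rpm=float(rng.uniform(5, 500)) if r.expressed else float(rng.uniform(0, 0.9)),
        )
        for r in truth_mirnas.itertuples()
    ]
    gene_rows = [
        dict(
            gene_id=r.gene_id,
            tpm=float(rng.uniform(3, 60)) if r.expressed else float(rng.uniform(0, 0.9)),
        )
        for r in truth_genes.itertuples()
    ]
    samples = [f"E{s:03d}" for s in range(cfg.n_samples_eqtl)]
    geno = {}
    for r in truth_snps.itertuples():
        maf = float(rng.uniform(*cfg.maf_range))
        geno[r.snp_id] = rng.choice(
            [0, 1, 2], size=cfg.n_samples_eqtl,
            p=[(1 - maf) ** 2, 2 * maf * (1 - maf), maf ** 2],
        )
    genotypes = pd.DataFrame(geno, index=samples)
    gene_snp = truth_snps.groupby("gene_id")["snp_id"].first().to_dict()
    expr = {}
    for r in truth_genes.itertuples():
        y = 10.0 + rng.normal(0, cfg.eqtl_noise_sd, size=cfg.n_samples_eqtl)
        if r.has_eqtl and r.gene_id in gene_snp:
            y = y + r.beta * genotypes[gene_snp[r.gene_id]].to_numpy()
        expr[r.gene_id] = y
    expression = pd.DataFrame(expr, index=samples)
    return (
        pd.DataFrame(mirna_rows), pd.DataFrame(gene_rows), genotypes, expression,
    )


def simulate(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Run all generator stages and assemble the full dataset."""
    cfg = config or SimulationConfig()
    rngs = _streams(cfg.rng_seed)
    ann = simulate_annotation_and_sequences(cfg, rngs)
    truth_snps = ann["truth_snps"]
    truth_genes = _gene_truth(cfg, truth_snps, rngs["expression"],
                              [g.gene_id for g in ann["genes"] if g.biotype == "protein_coding"])
    # The expression-failure stratum is realized on the gene side (TPM <= 1);
    # miRNAs are shared across planted SNPs, so per-miRNA knockouts would
    # leak between strata. All generated miRNAs are marked expressed.
    truth_mirnas = pd.DataFrame(
        [dict(mirna_id=m.mirna_id, expressed=True) for m in ann["mirnas"]]
    )
    array_df = simulate_array_data(cfg, truth_snps, truth_genes, rngs["array"])
    mirna_expr, gene_expr, genotypes, eqtl_expr = simulate_expression(
        cfg, truth_snps, truth_genes, truth_mirnas, rngs["eqtl"],
    )
    return SyntheticDataset(
        config=cfg,
        mirnas=ann["mirnas"],
        utrs=ann["utrs"],
        genes=ann["genes"],
        variants=ann["variants"],
        associations=ann["associations"],
        ld=ann["ld"],
        mirna_expression=mirna_expr,
        gene_expression=gene_expr,
        array_data=array_df,
        eqtl_genotypes=genotypes,
        eqtl_expression=eqtl_expr,
        snp_positions=ann["snp_positions"],
        tss=ann["tss"],
        snp_gene=dict(zip(truth_snps.snp_id, truth_snps.gene_id)),
        truth_snps=truth_snps,
        truth_genes=truth_genes,
        truth_mirnas=truth_mirnas,
    )
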