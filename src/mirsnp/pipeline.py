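"""End-to-end orchestration of the candidate-rSNP funnel.

The cascade mirrors the post-GWAS analysis this package implements:

1. genome-wide significant associations (P <= 5e-8);
2. LD-proxy expansion (r2 >= 0.8 within 500 kb);
3. annotation filtering to clean 3'-UTR SNPs of protein-coding genes;
4. allele-specific binding prediction with both engines;
5. |Δcontext| >= 0.151, miRNA RPM > 1 and gene TPM > 1 filters;
6. both-algorithm directional agreement;
7. gating on evidence of cis-regulation (DAE and/or eQTL).

The funnel summary counts distinct SNPs surviving each stage and is
monotone non-increasing. Candidate rows are ranked by decreasing
|Δcontext|.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import allelic_predict as ap
from . import cis_regulation as cis
from . import variant_catalog as vc
from .duplex_align import AlignmentParams, default_energy_model
from .seed_scan import ContextModel, UTRSequence

logger = logging.getLogger(__name__)

FUNNEL_STAGES = (
    "total_variants",
    "utr3_variants",
    "predicted_variants",
    "delta_pass",
    "expression_pass",
    "both_algorithms",
    "cis_supported",
)


@dataclass
class PipelineConfig:
    """All thresholds of the cascade, at their published defaults."""

    gwas_p_max: float = 5e-8
    proxy_r2_min: float = 0.8
    proxy_distance_max_bp: int = 500_000
    delta_context_min: float = 0.151
    s_min: float = 80.0
    mfe_max: float = -16.0
    rpm_min: float = 1.0
    tpm_min: float = 1.0
    dae_threshold: float = 0.58
    dae_min_fraction: float = 0.10
    dae_min_samples: int = 3
    eqtl_window_bp: int = 1_000_000
    eqtl_fdr: float = 0.05
    flank: int = 25
    cis_rule: str = "dae_only"  # dae_only | dae_or_eqtl | dae_and_eqtl
    require_concordance: bool = True
    rng_seed: int = 0
    paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cis_rule not in ("dae_only", "dae_or_eqtl", "dae_and_eqtl"):
            raise ValueError(f"unknown cis_rule {self.cis_rule!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        """Short hash of the configuration, for output provenance."""
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class PipelineResult:
    candidates: pd.DataFrame
    funnel: dict[str, int]
    records: list[ap.AllelicPredictionRecord]
    dae_calls: dict[str, cis.DAECall]
    qc_reports: dict[str, cis.SnpQCReport]
    gene_dae: dict[str, bool]
    gene_eqtl: dict[str, bool]
    eqtl_records: pd.DataFrame
    mirna_gene_hits: list[vc.GeneOverlapHit]


def check_allele_direction(
    favored_allele: str,
    dae_mean_ae: float,
    r2: float,
    d_prime_signed: float | None = 1.0,
) -> str:
    """Consistency of predicted preferential binding with DAE direction.

    Under canonical miRNA repression the allele with preferential binding
    should be the *least* expressed. ``dae_mean_ae`` is the mean AE_norm of
    the DAE SNP with allele A = ref (negative means ref under-expressed);
    ``d_prime_signed`` conveys haplotype phase between the candidate SNP
    and the DAE SNP (positive: ref travels with ref). Weak LD (r2 < 0.2)
    or unknown phase is untestable rather than guessed.
    """
    if r2 < 0.2 or d_prime_signed is None or dae_mean_ae == 0:
        return "untestable"
    under = "ref" if dae_mean_ae < 0 else "alt"
    if d_prime_signed < 0:
        under = "alt" if under == "ref" else "ref"
    return "consistent" if favored_allele == under else "discordant"


def run_dae_analysis(
    array_data: pd.DataFrame,
    snp_gene: Mapping[str, str],
    config: PipelineConfig,
) -> tuple[dict[str, cis.SnpQCReport], dict[str, cis.DAECall], dict[str, bool]]:
    """QC every SNP, call DAE on QC-passing SNPs, flag genes."""
    qc_reports: dict[str, cis.SnpQCReport] = {}
    calls: dict[str, cis.DAECall] = {}
    by_gene: dict[str, list[cis.DAECall]] = {g: [] for g in set(snp_gene.values())}
    for snp_id, sub in array_data.groupby("snp_id", sort=True):
        ms = [
            cis.ArrayMeasurement(
                str(r.snp_id), str(r.sample_id), str(r.genotype),
                float(r.dna_a), float(r.dna_b), float(r.rna_a), float(r.rna_b),
            )
            for r in sub.itertuples()
        ]
        report = cis.qc_snp(ms)
        qc_reports[str(snp_id)] = report
        if not report.passed:
            continue
        ae = [
            cis.ae_norm(m.rna_a, m.rna_b, m.dna_a, m.dna_b)
            for m in ms if m.genotype == "AB"
        ]
        call = cis.call_dae(
            ae, threshold=config.dae_threshold,
            min_fraction=config.dae_min_fraction,
            min_samples=config.dae_min_samples, snp_id=str(snp_id),
        )
        calls[str(snp_id)] = call
        gene = snp_gene.get(str(snp_id))
        if gene is not None:
            by_gene.setdefault(gene, []).append(call)
    gene_flags = cis.gene_cis_flag(by_gene)
    return qc_reports, calls, gene_flags


def run_pipeline(bundle: Any, config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full cascade on an input bundle.

    ``bundle`` is any object exposing the attributes of
    :class:`mirsnp.synthetic_data.SyntheticDataset` (a simulated dataset or
    a file-loaded equivalent).
    """
    config = config or PipelineConfig()
    cm = ContextModel()
    params = AlignmentParams(s_min=config.s_min, mfe_max=config.mfe_max)
    em = default_energy_model()

    # stage 1–2: significance and proxy expansion
    leads = vc.select_genome_wide_significant(bundle.associations, config.gwas_p_max)
    assignments = vc.expand_proxies(
        leads, bundle.ld, config.proxy_r2_min, config.proxy_distance_max_bp
    )
    ra_snp_ids = {a.snp_id for a in assignments}
    lead_of = {a.snp_id: a.lead_snp for a in assignments}
    ld_of = {a.snp_id: (a.r2, a.d_prime) for a in assignments}

    variants = [v for v in bundle.variants if v.snp_id in ra_snp_ids]
    funnel: dict[str, int] = {"total_variants": len({v.snp_id for v in variants})}

    # stage 3: 3'-UTR consequence filter (flagged removed first)
    utr_variants = vc.filter_by_consequence(variants)
    funnel["utr3_variants"] = len({v.snp_id for v in utr_variants})

    mirna_hits = vc.overlap_mirna_genes(variants, bundle.genes)

    # stage 4: allele-specific predictions with both engines
    utr_by_tid: dict[str, UTRSequence] = {u.transcript_id: u for u in bundle.utrs}
    records: list[ap.AllelicPredictionRecord] = []
    for v in utr_variants:
        for tid in sorted(v.transcript_ids):
            utr = utr_by_tid.get(tid)
            if utr is None or v.snp_id not in utr.snp_offsets:
                logger.warning("SNP %s has no usable UTR sequence in %s", v.snp_id, tid)
                continue
            records.extend(
                ap.compare_alleles(utr, v, bundle.mirnas, cm, params, em,
                                   flank=config.flank)
            )
    funnel["predicted_variants"] = len({r.snp_id for r in records})

    # stage 5: delta + expression filters
    records = ap.apply_delta_threshold(records, config.delta_context_min)
    expression = [
        ap.ExpressionRecord(str(r[0]), "mirna", float(r[1]))
        for r in bundle.mirna_expression.itertuples(index=False)
    ] + [
        ap.ExpressionRecord(str(r[0]), "gene", float(r[1]))
        for r in bundle.gene_expression.itertuples(index=False)
    ]
    records = ap.filter_expression(records, expression, config.rpm_min, config.tpm_min)
    records = ap.intersect_algorithms(records, config.require_concordance)
    funnel["delta_pass"] = len({r.snp_id for r in records if r.passed_delta})
    funnel["expression_pass"] = len(
        {r.snp_id for r in records if r.passed_delta and r.passed_expression}
    )
    funnel["both_algorithms"] = len(
        {
            r.snp_id
            for r in records
            if r.passed_delta and r.passed_expression and r.passed_both_algorithms
        }
    )

    # stage 6: cis-regulation evidence
    qc_reports, dae_calls, gene_dae = run_dae_analysis(
        bundle.array_data, bundle.snp_gene, config
    )
    eqtl_records, gene_eqtl = cis.eqtl_scan(
        bundle.eqtl_genotypes, bundle.eqtl_expression, bundle.snp_positions,
        bundle.tss, config.eqtl_window_bp, config.eqtl_fdr,
    )

    def cis_supported(gene: str) -> bool:
        dae = gene_dae.get(gene, False)
        eqtl = gene_eqtl.get(gene, False)
        if config.cis_rule == "dae_only":
            return dae
        if config.cis_rule == "dae_or_eqtl":
            return dae or eqtl
        return dae and eqtl

    rows = []
    for r in records:
        if not (r.passed_delta and r.passed_expression and r.passed_both_algorithms):
            continue
        if not cis_supported(r.gene_id):
            continue
        r2, d_prime = ld_of.get(r.snp_id, (float("nan"), float("nan")))
        dae_call = dae_calls.get(r.snp_id)
        direction = (
            check_allele_direction(r.favored_allele, dae_call.mean_ae, 1.0, 1.0)
            if dae_call is not None and dae_call.is_dae
            else "untestable"
        )
        rows.append(
            dict(
                lead_snp=lead_of.get(r.snp_id, ""),
                locus=r.gene_id,
                candidate_rsnp=r.snp_id,
                r2_with_lead=r2,
                d_prime=d_prime,
                gene=r.gene_id,
                transcript=r.transcript_id,
                ref_allele=r.ref_allele,
                alt_allele=r.alt_allele,
                mirna=r.mirna_id,
                ref_context=r.ref_context,
                alt_context=r.alt_context,
                delta_context=r.delta_context,
                ref_mfe=r.ref_mfe,
                alt_mfe=r.alt_mfe,
                max_abs_mfe_diff=r.max_abs_mfe_diff,
                favored_allele=r.favored_allele,
                dae_supported=gene_dae.get(r.gene_id, False),
                eqtl_supported=gene_eqtl.get(r.gene_id, False),
                expression_direction_consistent=direction,
            )
        )
    candidates = pd.DataFrame(rows)
    if len(candidates):
        candidates = candidates.reindex(
            candidates["delta_context"].abs().sort_values(
                ascending=False, kind="mergesort"
            ).index
        ).reset_index(drop=True)
    funnel["cis_supported"] = (
        candidates["candidate_rsnp"].nunique() if len(candidates) else 0
    )

    for a, b in zip(FUNNEL_STAGES, FUNNEL_STAGES[1:]):
        if funnel[b] > funnel[a]:  # pragma: no cover - defensive
            logger.error("funnel not monotone: %s=%d < %s=%d", a, funnel[a], b, funnel[b])

    logger.info("funnel: %s (config %s)", funnel, config.digest())
    return PipelineResult(
        candidates=candidates,
        funnel=funnel,
        records=records,
        dae_calls=dae_calls,
        qc_reports=qc_reports,
        gene_dae=gene_dae,
        gene_eqtl=gene_eqtl,
        eqtl_records=eqtl_records,
        mirna_gene_hits=mirna_hits,
    )
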