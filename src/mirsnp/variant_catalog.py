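"""Risk-variant catalogue: significance filtering, LD-proxy expansion,
consequence filtering and miRNA-gene overlap.

All external tables use 1-based inclusive genomic coordinates (VCF
convention); internal sequence arithmetic elsewhere in the package is
0-based half-open. Conversion happens exactly once, at I/O boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

DEFAULT_GWAS_P = 5e-8
DEFAULT_R2_MIN = 0.8
DEFAULT_MAX_DISTANCE_BP = 500_000
UTR3_TERM = "3_prime_UTR_variant"

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class AssociationRecord:
    """One GWAS association: SNP, position, p-value, trait, source."""

    snp_id: str
    chrom: str
    pos: int
    p_value: float
    trait: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            raise ValueError(f"{self.snp_id}: p-value {self.p_value} outside (0, 1]")
        if self.pos < 1:
            raise ValueError(f"{self.snp_id}: position {self.pos} < 1")


@dataclass(frozen=True)
class ProxyRecord:
    """An LD link between a lead SNP and a proxy SNP."""

    lead_snp: str
    proxy_snp: str
    r2: float
    d_prime: float
    distance_bp: int

    def __post_init__(self) -> None:
        if not 0 <= self.r2 <= 1:
            raise ValueError(f"r2 {self.r2} outside [0, 1]")
        if not 0 <= self.d_prime <= 1:
            raise ValueError(f"d_prime {self.d_prime} outside [0, 1]")
        if self.distance_bp < 0:
            raise ValueError("distance_bp must be non-negative")


@dataclass
class AnnotatedVariant:
    """A biallelic SNP with annotation and provenance."""

    snp_id: str
    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    consequence_terms: set[str] = field(default_factory=set)
    gene_ids: set[str] = field(default_factory=set)
    transcript_ids: set[str] = field(default_factory=set)
    flagged: bool = False
    lead_snp: str = ""

    def __post_init__(self) -> None:
        self.ref_allele = self.ref_allele.upper()
        self.alt_allele = self.alt_allele.upper()
        for a in (self.ref_allele, self.alt_allele):
            if len(a) != 1 or a not in _BASES:
                raise ValueError(
                    f"{self.snp_id}: allele {a!r} is not a single A/C/G/T base "
                    "(indels are not supported)"
                )
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.snp_id}: ref and alt alleles are identical")


@dataclass(frozen=True)
class GeneInterval:
    """A gene locus, 1-based inclusive coordinates."""

    gene_id: str
    biotype: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")


@dataclass(frozen=True)
class ProxyAssignment:
    """A risk-associated SNP (lead or proxy) with its lead provenance."""

    snp_id: str
    lead_snp: str
    r2: float
    d_prime: float
    distance_bp: int
    is_lead: bool


@dataclass(frozen=True)
class GeneOverlapHit:
    """A variant falling within ('within') or near ('near') a gene."""

    variant: AnnotatedVariant
    gene: GeneInterval
    category: str  # 'within' | 'near'


def select_genome_wide_significant(
    records: Iterable[AssociationRecord],
    threshold: float = DEFAULT_GWAS_P,
) -> list[AssociationRecord]:
    """Records with p <= threshold (inclusive), input order preserved.

    Duplicate snp_ids collapse to the smallest p-value at the first
    occurrence's position.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold {threshold} outside (0, 1]")
    best: dict[str, AssociationRecord] = {}
    order: list[str] = []
    for rec in records:
        if rec.snp_id not in best:
            best[rec.snp_id] = rec
            order.append(rec.snp_id)
        elif rec.p_value < best[rec.snp_id].p_value:
            best[rec.snp_id] = rec
    return [best[s] for s in order if best[s].p_value <= threshold]


def expand_proxies(
    leads: Sequence[AssociationRecord],
    ld: Iterable[ProxyRecord],
    r2_min: float = DEFAULT_R2_MIN,
    max_distance_bp: int = DEFAULT_MAX_DISTANCE_BP,
) -> list[ProxyAssignment]:
    """Each lead SNP plus every proxy with r2 >= r2_min within distance.

    Duplicate (lead, proxy) rows keep the maximum r2 (conservative
    inclusion); proxies of unknown leads are skipped with a warning. A
    SNP proxying several leads appears once per lead.
    """
    if not 0 <= r2_min <= 1:
        raise ValueError(f"r2_min {r2_min} outside [0, 1]")
    lead_ids = {rec.snp_id for rec in leads}
    dedup: dict[tuple[str, str], ProxyRecord] = {}
    for rec in ld:
        if rec.lead_snp not in lead_ids:
            logger.warning("proxy %s references unknown lead %s; skipped",
                           rec.proxy_snp, rec.lead_snp)
            continue
        key = (rec.lead_snp, rec.proxy_snp)
        if key not in dedup or rec.r2 > dedup[key].r2:
            dedup[key] = rec
    out = [
        ProxyAssignment(rec.snp_id, rec.snp_id, 1.0, 1.0, 0, True)
        for rec in leads
    ]
    for rec in dedup.values():
        if rec.r2 >= r2_min and rec.distance_bp <= max_distance_bp:
            out.append(
                ProxyAssignment(
                    rec.proxy_snp, rec.lead_snp, rec.r2, rec.d_prime,
                    rec.distance_bp, False,
                )
            )
    return out


def filter_by_consequence(
    variants: Iterable[AnnotatedVariant],
    term: str = UTR3_TERM,
) -> list[AnnotatedVariant]:
    """Variants carrying ``term``; annotation-flagged variants removed first."""
    if not term or not isinstance(term, str):
        raise ValueError("term must be a non-empty Sequence Ontology term string")
    return [
        v for v in variants
        if not v.flagged and term in v.consequence_terms
    ]


def overlap_mirna_genes(
    variants: Iterable[AnnotatedVariant],
    genes: Iterable[GeneInterval],
    margin: int = 2000,
) -> list[GeneOverlapHit]:
    """Variants overlapping ('within') or flanking ('near') miRNA genes.

    'within' means pos in [start, end]; 'near' means within ``margin`` bp
    outside the gene body. The categories are disjoint.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        if g.biotype != "miRNA":
            continue
        # half-open tree coordinates over 1-based inclusive gene intervals
        trees.setdefault(g.chrom, IntervalTree()).addi(
            g.start - margin, g.end + margin + 1, g
        )
    hits: list[GeneOverlapHit] = []
    for v in variants:
        tree = trees.get(v.chrom)
        if tree is None:
            continue
        for iv in sorted(tree[v.pos]):
            g: GeneInterval = iv.data
            category = "within" if g.start <= v.pos <= g.end else "near"
            hits.append(GeneOverlapHit(v, g, category))
    return hits


def classify_region(variant: AnnotatedVariant, genes: Sequence[GeneInterval],
                    desert_distance: int = 1_000_000) -> str:
    """Summary category: 'genic', 'intergenic' or 'gene_desert'.

    Purely descriptive (drives no downstream computation).
    """
    nearest = None
    for g in genes:
        if g.chrom != variant.chrom:
            continue
        if g.start <= variant.pos <= g.end:
            return "genic"
        d = min(abs(variant.pos - g.start), abs(variant.pos - g.end))
        nearest = d if nearest is None else min(nearest, d)
    if nearest is None or nearest > desert_distance:
        return "gene_desert"
    return "intergenic"


def split_multiallelic(
    snp_id: str,
    chrom: str,
    pos: int,
    ref: str,
    alt_field: str,
    **kwargs,
) -> list[AnnotatedVariant]:
    """Split a possibly multi-allelic record into biallelic SNVs.

    Indel alleles are dropped with a warning (the analysis is SNP-only).
    """
    out = []
    for alt in str(alt_field).split(","):
        alt = alt.strip().upper()
        if len(alt) != 1 or len(ref) != 1 or alt not in _BASES or ref.upper() not in _BASES:
            logger.warning("%s: allele pair %s/%s is not a SNV; dropped", snp_id, ref, alt)
            continue
        out.append(AnnotatedVariant(snp_id, chrom, pos, ref, alt, **kwargs))
    return out


def attach_leads(
    variants: Iterable[AnnotatedVariant],
    assignments: Iterable[ProxyAssignment],
) -> list[AnnotatedVariant]:
    """Annotate variants with lead-SNP provenance; one copy per lead."""
    by_snp: dict[str, list[ProxyAssignment]] = {}
    for a in assignments:
        by_snp.setdefault(a.snp_id, []).append(a)
    out: list[AnnotatedVariant] = []
    for v in variants:
        for a in by_snp.get(v.snp_id, []):
            out.append(replace_lead(v, a.lead_snp))
    return out


def replace_lead(variant: AnnotatedVariant, lead: str) -> AnnotatedVariant:
    import copy

    v = copy.copy(variant)
    v.lead_snp = lead
    return v
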