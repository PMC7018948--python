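"""Per-allele miRNA-binding comparison and the candidate filter cascade.

This is the analytical core of the package: for a SNP in a 3'-UTR, build
the two allele-specific target sequences, run the seed engine (full-length
allele UTRs) and the duplex engine (SNP-centred windows of 25 nt flank on
either side) on each allele, and reduce the outputs to per-record allele
differences:

* ``delta_context`` — alt-allele context score minus ref-allele context
  score, with an absent prediction contributing 0 (Table-style single-
  allele predictions then pass on the strength of the predicted allele);
* ``max_abs_mfe_diff`` — maximum |MFE_ref − MFE_alt| across matched duplex
  hits, with an absent hit contributing 0 kcal/mol.

Records then flow through three independent filters: the |Δcontext|
threshold (default 0.151, inclusive), expression of both the miRNA
(RPM > 1) and the target gene (median TPM > 1, both strict), and
directional agreement between the two engines.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable

from .duplex_align import (
    AlignmentParams,
    EnergyModel,
    default_energy_model,
    max_abs_mfe_diff,
    scan_hits,
)
from .seed_scan import (
    RNA_COMPLEMENT,
    ContextModel,
    MatureMiRNA,
    UTRSequence,
    find_canonical_sites,
    score_site,
)
from .variant_catalog import AnnotatedVariant

logger = logging.getLogger(__name__)

DEFAULT_DELTA_THRESHOLD = 0.151
DEFAULT_FLANK = 25
DEFAULT_RPM_MIN = 1.0
DEFAULT_TPM_MIN = 1.0


@dataclass(frozen=True)
class AlleleWindow:
    """A target sequence carrying one allele of a SNP."""

    snp_id: str
    allele: str  # transcript-sense base actually substituted
    sequence: str
    snp_offset: int  # 0-based offset of the allele base in ``sequence``
    provenance: str  # 'full_utr' | 'flank25'

    def __post_init__(self) -> None:
        if self.sequence[self.snp_offset] != self.allele:
            raise ValueError(
                f"{self.snp_id}: window base {self.sequence[self.snp_offset]!r} "
                f"at offset {self.snp_offset} does not match allele {self.allele!r}"
            )


@dataclass
class AlleleWindows:
    """Ref/alt windows in both provenance modes for one SNP::UTR pair."""

    full_utr: tuple[AlleleWindow, AlleleWindow]
    flank: tuple[AlleleWindow, AlleleWindow]


@dataclass(frozen=True)
class ExpressionRecord:
    """An expression measurement: RPM for miRNAs, median TPM otherwise."""

    feature_id: str
    kind: str  # 'mirna' | 'gene' | 'transcript'
    value: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"{self.feature_id}: negative expression value")


@dataclass
class AllelicPredictionRecord:
    """One gene–SNP–miRNA comparison with per-allele engine outputs."""

    gene_id: str
    transcript_id: str
    snp_id: str
    mirna_id: str
    ref_allele: str = ""
    alt_allele: str = ""
    ref_context: float | None = None
    alt_context: float | None = None
    delta_context: float = 0.0      # alt − ref, absent = 0
    ref_mfe: float | None = None
    alt_mfe: float | None = None
    max_abs_mfe_diff: float = 0.0
    n_hits_ref: int = 0
    n_hits_alt: int = 0
    favored_allele: str = "ref"
    passed_delta: bool = False
    passed_expression: bool = False
    passed_both_algorithms: bool = False
    discordant: bool = False

    @property
    def seed_direction(self) -> str | None:
        """Allele favored by the seed engine ('ref'/'alt'), None if tied."""
        ref = self.ref_context if self.ref_context is not None else 0.0
        alt = self.alt_context if self.alt_context is not None else 0.0
        if math.isclose(ref, alt, abs_tol=1e-12):
            return None
        return "ref" if ref < alt else "alt"

    @property
    def duplex_direction(self) -> str | None:
        """Allele favored by the duplex engine (lower MFE), None if tied."""
        ref = self.ref_mfe if self.ref_mfe is not None else 0.0
        alt = self.alt_mfe if self.alt_mfe is not None else 0.0
        if (self.n_hits_ref == 0 and self.n_hits_alt == 0) or math.isclose(
            ref, alt, abs_tol=1e-12
        ):
            return None
        return "ref" if ref < alt else "alt"


def transcript_sense_alleles(
    variant: AnnotatedVariant, strand: str
) -> tuple[str, str]:
    """Ref/alt alleles as RNA bases in transcript sense.

    Alleles are reported on the genomic plus strand; minus-strand
    transcripts receive the complemented bases.
    """
    ref = variant.ref_allele.replace("T", "U")
    alt = variant.alt_allele.replace("T", "U")
    if strand == "-":
        ref, alt = RNA_COMPLEMENT[ref], RNA_COMPLEMENT[alt]
    return ref, alt


def _substitute(seq: str, offset: int, base: str) -> str:
    return seq[:offset] + base + seq[offset + 1:]


def build_allele_windows(
    utr: UTRSequence,
    variant: AnnotatedVariant,
    flank: int = DEFAULT_FLANK,
) -> AlleleWindows:
    """Ref/alt windows for one SNP: whole-UTR and SNP-centred flank mode.

    Flank windows are truncated, never padded, at the UTR ends; a SNP
    ``flank`` nt or more from both ends yields length 2·flank + 1.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    off = utr.snp_offsets.get(variant.snp_id)
    if off is None:
        raise KeyError(
            f"SNP {variant.snp_id} has no recorded offset in transcript "
            f"{utr.transcript_id}"
        )
    ref, alt = transcript_sense_alleles(variant, utr.strand)
    seq = utr.sequence
    full = tuple(
        AlleleWindow(variant.snp_id, a, _substitute(seq, off, a), off, "full_utr")
        for a in (ref, alt)
    )
    lo = max(0, off - flank)
    hi = min(len(seq), off + flank + 1)
    sub = seq[lo:hi]
    flk = tuple(
        AlleleWindow(
            variant.snp_id, a, _substitute(sub, off - lo, a), off - lo, "flank25"
        )
        for a in (ref, alt)
    )
    return AlleleWindows(full_utr=full, flank=flk)


def _allele_context(
    window: AlleleWindow,
    utr: UTRSequence,
    mirna: MatureMiRNA,
    model: ContextModel,
) -> float | None:
    """Strongest (minimum) context score among sites covering the SNP."""
    allele_utr = UTRSequence(
        transcript_id=utr.transcript_id,
        gene_id=utr.gene_id,
        sequence=window.sequence,
        biotype=utr.biotype,
        strand=utr.strand,
    )
    sites = find_canonical_sites(allele_utr, mirna)
    scores = [
        score_site(s, allele_utr, mirna, model).context_score
        for s in sites
        if s.covers(window.snp_offset)
    ]
    return min(scores) if scores else None


def compare_alleles(
    utr: UTRSequence,
    variant: AnnotatedVariant,
    mirnas: Iterable[MatureMiRNA],
    context_model: ContextModel | None = None,
    align_params: AlignmentParams | None = None,
    energy_model: EnergyModel | None = None,
    flank: int = DEFAULT_FLANK,
) -> list[AllelicPredictionRecord]:
    """Allele-differential records for one SNP against a set of miRNAs.

    A record is emitted whenever the two alleles differ in either
    engine's output; SNPs invisible to both engines produce nothing.
    """
    context_model = context_model or ContextModel()
    align_params = align_params or AlignmentParams()
    energy_model = energy_model or default_energy_model()
    windows = build_allele_windows(utr, variant, flank)
    ref_full, alt_full = windows.full_utr
    ref_flank, alt_flank = windows.flank
    records: list[AllelicPredictionRecord] = []
    for mirna in mirnas:
        ref_ctx = _allele_context(ref_full, utr, mirna, context_model)
        alt_ctx = _allele_context(alt_full, utr, mirna, context_model)
        hits_ref = scan_hits(
            mirna, f"{variant.snp_id}:{ref_flank.allele}", ref_flank.sequence,
            align_params, energy_model,
        )
        hits_alt = scan_hits(
            mirna, f"{variant.snp_id}:{alt_flank.allele}", alt_flank.sequence,
            align_params, energy_model,
        )
        mad = max_abs_mfe_diff(hits_ref, hits_alt)
        seed_differs = _differs(ref_ctx, alt_ctx)
        duplex_differs = mad > 0 or (len(hits_ref) != len(hits_alt))
        if not seed_differs and not duplex_differs:
            continue
        rec = AllelicPredictionRecord(
            gene_id=utr.gene_id,
            transcript_id=utr.transcript_id,
            snp_id=variant.snp_id,
            mirna_id=mirna.mirna_id,
            ref_allele=variant.ref_allele,
            alt_allele=variant.alt_allele,
            ref_context=ref_ctx,
            alt_context=alt_ctx,
            delta_context=(alt_ctx or 0.0) - (ref_ctx or 0.0),
            ref_mfe=min((h.mfe for h in hits_ref), default=None),
            alt_mfe=min((h.mfe for h in hits_alt), default=None),
            max_abs_mfe_diff=mad,
            n_hits_ref=len(hits_ref),
            n_hits_alt=len(hits_alt),
        )
        rec.favored_allele = rec.seed_direction or rec.duplex_direction or "ref"
        records.append(rec)
    return records


def _differs(a: float | None, b: float | None) -> bool:
    if a is None and b is None:
        return False
    if (a is None) != (b is None):
        return True
    return not math.isclose(a, b, abs_tol=1e-12)


def apply_delta_threshold(
    records: Iterable[AllelicPredictionRecord],
    threshold: float = DEFAULT_DELTA_THRESHOLD,
) -> list[AllelicPredictionRecord]:
    """Set ``passed_delta`` = |Δcontext| >= threshold (boundary inclusive)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    out = []
    for rec in records:
        rec = replace(rec)
        rec.passed_delta = abs(rec.delta_context) >= threshold
        out.append(rec)
    return out


def filter_expression(
    records: Iterable[AllelicPredictionRecord],
    expression: Iterable[ExpressionRecord],
    rpm_min: float = DEFAULT_RPM_MIN,
    tpm_min: float = DEFAULT_TPM_MIN,
) -> list[AllelicPredictionRecord]:
    """Set ``passed_expression``: miRNA RPM > rpm_min AND gene TPM > tpm_min.

    Both inequalities are strict; features missing from the expression
    table count as not expressed (logged once per feature).
    """
    mirna_rpm: dict[str, float] = {}
    gene_tpm: dict[str, float] = {}
    for e in expression:
        if e.kind == "mirna":
            mirna_rpm[e.feature_id] = e.value
        else:
            gene_tpm[e.feature_id] = e.value
    missing: set[str] = set()
    out = []
    for rec in records:
        rec = replace(rec)
        rpm = mirna_rpm.get(rec.mirna_id)
        tpm = gene_tpm.get(rec.gene_id)
        if rpm is None and rec.mirna_id not in missing:
            missing.add(rec.mirna_id)
            logger.info("miRNA %s absent from expression table; treated as unexpressed",
                        rec.mirna_id)
        if tpm is None and rec.gene_id not in missing:
            missing.add(rec.gene_id)
            logger.info("gene %s absent from expression table; treated as unexpressed",
                        rec.gene_id)
        rec.passed_expression = (
            rpm is not None and rpm > rpm_min and tpm is not None and tpm > tpm_min
        )
        out.append(rec)
    return out


def intersect_algorithms(
    records: Iterable[AllelicPredictionRecord],
    require_concordance: bool = True,
) -> list[AllelicPredictionRecord]:
    """Set ``passed_both_algorithms``.

    A record passes when the seed engine produced a context difference and
    the duplex engine a hit-bearing MFE difference, and — unless
    ``require_concordance`` is disabled — both favor the same allele.
    Engines favoring opposite alleles are flagged ``discordant``.
    """
    out = []
    for rec in records:
        rec = replace(rec)
        seed_dir = rec.seed_direction
        duplex_dir = rec.duplex_direction
        has_both = seed_dir is not None and duplex_dir is not None
        rec.discordant = has_both and seed_dir != duplex_dir
        rec.passed_both_algorithms = has_both and (
            seed_dir == duplex_dir or not require_concordance
        )
        out.append(rec)
    return out
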