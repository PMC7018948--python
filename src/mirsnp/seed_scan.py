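"""Canonical miRNA seed-site detection and context-style scoring.

The seed engine finds canonical target sites in 3'-UTR sequences — UTR
segments Watson–Crick complementary to the miRNA seed (nucleotides 2–7,
extended to 2–8) — and scores each site with a simplified additive
context-style model: a site-type baseline adjusted by local AU content,
relative position within the UTR, and supplementary 3' pairing. Lower
(more negative) scores mean stronger predicted repression.

Site types follow the standard hierarchy:

* ``8mer``     — complement of miRNA nt 2–8 followed by an A in the UTR
* ``7mer-m8``  — complement of miRNA nt 2–8
* ``7mer-A1``  — complement of miRNA nt 2–7 followed by an A
* ``6mer``     — complement of miRNA nt 2–7

The A of 7mer-A1/8mer sites is an adenosine in the UTR regardless of the
identity of miRNA position 1 (the convention of seed-match predictors).
Transcripts with the nonsense-mediated-decay biotype are skipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

logger = logging.getLogger(__name__)

RNA_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
RNA_ALPHABET = frozenset("ACGU")

#: transcript biotype excluded from seed scanning
NMD_BIOTYPE = "nonsense_mediated_decay"

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
#: rank of each site type, 0 = most specific
SITE_RANK = {t: i for i, t in enumerate(SITE_TYPES)}


class AlphabetError(ValueError):
    """Raised when a sequence contains characters outside the RNA alphabet."""


def normalize_rna(seq: str, *, extra: str = "") -> str:
    """Uppercase ``seq``, convert T to U and validate the alphabet.

    ``extra`` lists additional characters to tolerate (used internally for
    the ``N`` masking character during iterative alignment scans).
    """
    s = seq.strip().upper().replace("T", "U")
    allowed = RNA_ALPHABET | set(extra)
    bad = sorted(set(s) - allowed)
    if bad:
        raise AlphabetError(
            f"sequence contains non-RNA characters {bad!r} "
            "(expected A, C, G, U; T is accepted and converted)"
        )
    return s


def revcomp_rna(seq: str) -> str:
    """Reverse complement of an RNA string (Watson–Crick, no wobble)."""
    return "".join(RNA_COMPLEMENT[b] for b in reversed(seq))


def is_wc_pair(a: str, b: str) -> bool:
    """True when a:b is a Watson–Crick RNA pair."""
    return RNA_COMPLEMENT.get(a) == b


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA sequence, 5'→3', with miRBase-style identifier."""

    mirna_id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_rna(self.sequence))
        n = len(self.sequence)
        if not 18 <= n <= 26:
            raise ValueError(
                f"{self.mirna_id}: mature miRNA length {n} outside 18–26 nt"
            )

    @property
    def seed6(self) -> str:
        """Seed nucleotides 2–7 (0-based slice [1:7])."""
        return self.sequence[1:7]

    @property
    def seed7(self) -> str:
        """Extended seed nucleotides 2–8 (0-based slice [1:8])."""
        return self.sequence[1:8]


@dataclass
class UTRSequence:
    """A spliced 3'-UTR in mRNA sense (minus-strand genes pre-flipped).

    ``snp_offsets`` maps SNP identifiers to 0-based offsets within
    ``sequence``; ``strand`` records the genomic strand so that allele
    substitution can complement alleles reported on the plus strand.
    """

    transcript_id: str
    gene_id: str
    sequence: str
    biotype: str = "protein_coding"
    strand: str = "+"
    snp_offsets: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequence = normalize_rna(self.sequence)
        for snp, off in self.snp_offsets.items():
            if not 0 <= off < len(self.sequence):
                raise ValueError(
                    f"{self.transcript_id}: offset {off} of SNP {snp} "
                    f"outside UTR of length {len(self.sequence)}"
                )

    @property
    def is_nmd(self) -> bool:
        return self.biotype == NMD_BIOTYPE


@dataclass(frozen=True)
class SeedSite:
    """One canonical seed match, 0-based half-open UTR coordinates."""

    mirna_id: str
    transcript_id: str
    site_type: str
    start: int
    end: int

    def covers(self, offset: int) -> bool:
        return self.start <= offset < self.end


class SiteList(list):
    """List of SeedSite with a marker for NMD-skipped transcripts."""

    skipped_nmd: bool = False


@dataclass
class ContextModel:
    """Additive context-style scoring model.

    This is deliberately not the trained 14-feature context++ model of
    TargetScan; it is a documented simplification that preserves the
    published site-type ordering (8mer strongest) and the qualitative
    effect of AU-rich flanks, site position and 3'-supplementary pairing.
    The per-allele *differencing* downstream is model-agnostic.
    """

    baselines: dict[str, float] = field(
        default_factory=lambda: {
            "8mer": -0.31,
            "7mer-m8": -0.16,
            "7mer-A1": -0.10,
            "6mer": -0.03,
        }
    )
    w_au: float = -0.05        # reward for AU-rich flanks (f_AU in [0, 1])
    w_pos: float = 0.03        # penalty for central sites (f_pos in [0, 0.5])
    w_3p: float = -0.01        # reward per contiguous 3'-supplementary pair (0–4)

    def __post_init__(self) -> None:
        b = self.baselines
        if not (b["8mer"] < b["7mer-m8"] < b["7mer-A1"] < b["6mer"]):
            raise ValueError("site-type baselines must be ordered 8mer < 7mer-m8 < 7mer-A1 < 6mer")


@dataclass(frozen=True)
class SitePrediction:
    """A SeedSite with its context-style score (lower = stronger)."""

    site: SeedSite
    gene_id: str
    context_score: float


def _core_start(site: SeedSite) -> int:
    # UTR start of the 6-nt segment opposite miRNA nt 2–7
    return site.start + 1 if site.site_type in ("8mer", "7mer-m8") else site.start


def find_canonical_sites(utr: UTRSequence, mirna: MatureMiRNA) -> SiteList:
    """All canonical seed sites of ``mirna`` in ``utr``.

    Each seed-complement window is reported once under its most specific
    type (8mer > 7mer-m8 > 7mer-A1 > 6mer). NMD-biotype transcripts
    return an empty list flagged ``skipped_nmd``.
    """
    out = SiteList()
    if utr.is_nmd:
        out.skipped_nmd = True
        return out
    seq = utr.sequence
    m6 = revcomp_rna(mirna.seed6)           # complement of nt 2–7
    c8 = RNA_COMPLEMENT[mirna.sequence[7]]  # complement of nt 8
    i = seq.find(m6)
    while i != -1:
        match8 = i >= 1 and seq[i - 1] == c8
        has_a = i + 6 < len(seq) and seq[i + 6] == "A"
        if match8 and has_a:
            site = SeedSite(mirna.mirna_id, utr.transcript_id, "8mer", i - 1, i + 7)
        elif match8:
            site = SeedSite(mirna.mirna_id, utr.transcript_id, "7mer-m8", i - 1, i + 6)
        elif has_a:
            site = SeedSite(mirna.mirna_id, utr.transcript_id, "7mer-A1", i, i + 7)
        else:
            site = SeedSite(mirna.mirna_id, utr.transcript_id, "6mer", i, i + 6)
        out.append(site)
        i = seq.find(m6, i + 1)
    return out


def local_au_fraction(seq: str, start: int, end: int, flank: int = 15) -> float:
    """AU fraction of the ``flank``-nt windows on either side of [start, end)."""
    left = seq[max(0, start - flank):start]
    right = seq[end:end + flank]
    window = left + right
    if not window:
        return 0.0
    return sum(b in "AU" for b in window) / len(window)


def _supplementary_pairs(seq: str, site: SeedSite, mirna: MatureMiRNA) -> int:
    """Contiguous WC pairs between miRNA nt 13–16 and the UTR region opposite."""
    core = _core_start(site)
    count = 0
    for pos in (13, 14, 15, 16):
        if pos > len(mirna.sequence):
            break
        u = core + 7 - pos  # UTR index opposite miRNA position ``pos``
        if u < 0 or not is_wc_pair(seq[u], mirna.sequence[pos - 1]):
            break
        count += 1
    return count


def score_site(
    site: SeedSite,
    utr: UTRSequence,
    mirna: MatureMiRNA,
    model: ContextModel | None = None,
) -> SitePrediction:
    """Score one site: baseline + AU, position and 3'-pairing adjustments."""
    model = model or ContextModel()
    seq = utr.sequence
    if not (0 <= site.start < site.end <= len(seq)):
        raise ValueError(f"site {site} outside UTR {utr.transcript_id}")
    f_au = local_au_fraction(seq, site.start, site.end)
    f_pos = min(site.start, len(seq) - site.end) / len(seq)
    f_3p = _supplementary_pairs(seq, site, mirna)
    score = (
        model.baselines[site.site_type]
        + model.w_au * f_au
        + model.w_pos * f_pos
        + model.w_3p * f_3p
    )
    return SitePrediction(site=site, gene_id=utr.gene_id, context_score=score)


def scan_transcriptome(
    utrs: Iterable[UTRSequence],
    mirnas: Iterable[MatureMiRNA],
    model: ContextModel | None = None,
) -> list[SitePrediction]:
    """Find and score all sites for every UTR × miRNA pair.

    Output is deterministically ordered by (transcript_id, mirna_id, start).
    """
    model = model or ContextModel()
    mirnas = list(mirnas)
    preds: list[SitePrediction] = []
    for utr in utrs:
        for mirna in mirnas:
            sites = find_canonical_sites(utr, mirna)
            if sites.skipped_nmd:
                logger.info("skipped_nmd: %s (biotype %s)", utr.transcript_id, utr.biotype)
                continue
            preds.extend(score_site(s, utr, mirna, model) for s in sites)
    preds.sort(key=lambda p: (p.site.transcript_id, p.site.mirna_id, p.site.start))
    return preds
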