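"""Evidence of cis-regulation: differential allelic expression and eQTL.

Differential allelic expression (DAE) compares the expression of a gene's
two alleles within heterozygous individuals on paired DNA/RNA genotyping
arrays. The DNA channel cancels dosage and probe effects:

    AE_norm = log2( (RNA_A / RNA_B) / (DNA_A / DNA_B) )

A SNP shows DAE when |AE_norm| >= 0.58 (a 1.5-fold allelic difference)
in at least 10% of heterozygotes and at least three samples. SNPs first
pass a QC cascade: mean log2 RNA intensity >= 9.5, allelic discrimination
t-tests (AB vs each homozygote group) with p <= 0.05, genotype call rate
>= 90%, Hardy–Weinberg exact p > 1e-5, >= 5 heterozygotes, and no
structural exclusion (multi-mapping, dbSNP-suspect, sex chromosome).

The eQTL scan regresses expression on allele dosage for SNPs within
±1 Mb of a gene's transcription start site and controls the FDR with
Benjamini–Hochberg at 0.05. It is a minimal OLS scanner so that synthetic
runs need no external eQTL download; a precomputed flag table is equally
accepted by the pipeline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DAE_THRESHOLD = 0.58          # |log2 AE ratio| for a 1.5-fold difference
DAE_MIN_FRACTION = 0.10
DAE_MIN_SAMPLES = 3
INTENSITY_MIN = 9.5
DISCRIM_ALPHA = 0.05
CALL_RATE_MIN = 0.9
HWE_P_MIN = 1e-5
MIN_HET = 5
EQTL_WINDOW_BP = 1_000_000
EQTL_FDR = 0.05

GENOTYPES = ("AA", "AB", "BB", "missing")


@dataclass(frozen=True)
class ArrayMeasurement:
    """Paired DNA/RNA allelic intensities for one SNP in one sample."""

    snp_id: str
    sample_id: str
    genotype: str
    dna_a: float
    dna_b: float
    rna_a: float
    rna_b: float

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        for name in ("dna_a", "dna_b", "rna_a", "rna_b"):
            if getattr(self, name) <= 0:
                raise ValueError(
                    f"{self.snp_id}/{self.sample_id}: {name} must be > 0 "
                    "(log-ratios undefined otherwise)"
                )


@dataclass
class SnpQCReport:
    snp_id: str
    mean_log2_rna: float
    discrim_p_aa: float
    discrim_p_bb: float
    call_rate: float
    hwe_p: float
    n_het: int
    excluded_reason: str | None = None

    @property
    def passed(self) -> bool:
        return self.excluded_reason is None


@dataclass
class DAECall:
    snp_id: str
    ae_norm_per_het: list[float]
    n_het: int
    n_beyond: int
    threshold: float
    is_dae: bool
    mean_ae: float = 0.0  # sign: negative = allele A (ref) under-expressed


@dataclass(frozen=True)
class EQTLRecord:
    gene_id: str
    snp_id: str
    beta: float
    p: float
    q: float
    within_window: bool = True


def ae_norm(rna_a: float, rna_b: float, dna_a: float, dna_b: float) -> float:
    """DNA-normalized log2 allelic expression ratio."""
    for name, v in (("rna_a", rna_a), ("rna_b", rna_b),
                    ("dna_a", dna_a), ("dna_b", dna_b)):
        if v <= 0:
            raise ValueError(f"{name} must be strictly positive, got {v}")
    return math.log2((rna_a / rna_b) / (dna_a / dna_b))


def hwe_exact_pvalue(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact conditional Hardy–Weinberg test p-value.

    Probability, under HWE and conditional on the observed allele counts,
    of heterozygote counts at least as improbable as the observed one.
    """
    for n in (n_aa, n_ab, n_bb):
        if n < 0 or n != int(n):
            raise ValueError("genotype counts must be non-negative integers")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("at least one genotype count must be positive")
    na = 2 * n_aa + n_ab  # allele A count
    nb = 2 * n_bb + n_ab

    def log_prob(nab: int) -> float:
        naa = (na - nab) // 2
        nbb = (nb - nab) // 2
        return (
            gammaln(n + 1) - gammaln(naa + 1) - gammaln(nab + 1) - gammaln(nbb + 1)
            + nab * math.log(2)
            + gammaln(na + 1) + gammaln(nb + 1) - gammaln(2 * n + 1)
        )

    start = na % 2  # heterozygote count parity is fixed by the allele count
    support = range(start, min(na, nb) + 1, 2)
    logs = np.array([log_prob(k) for k in support])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    obs = (n_ab - start) // 2
    p = probs[probs <= probs[obs] * (1 + 1e-12)].sum()
    return float(min(1.0, p))


def _log2_ratios(ms: Sequence[ArrayMeasurement], genotype: str) -> np.ndarray:
    return np.array(
        [math.log2(m.rna_a / m.rna_b) for m in ms if m.genotype == genotype]
    )


def qc_snp(
    measurements: Sequence[ArrayMeasurement],
    structural_exclusion: str | None = None,
    *,
    intensity_min: float = INTENSITY_MIN,
    discrim_alpha: float = DISCRIM_ALPHA,
    call_rate_min: float = CALL_RATE_MIN,
    hwe_p_min: float = HWE_P_MIN,
    min_het: int = MIN_HET,
    welch: bool = False,
) -> SnpQCReport:
    """QC one SNP's array measurements; first failing rule is recorded.

    ``structural_exclusion`` carries a pre-annotated reason (multi-mapping,
    dbSNP-suspect, sex chromosome); these flags are consumed, not
    recomputed.
    """
    if len(measurements) < 2:
        raise ValueError("need at least two samples for QC")
    snp_id = measurements[0].snp_id
    mean_log2_rna = float(
        np.mean([math.log2(m.rna_a + m.rna_b) for m in measurements])
    )
    het = _log2_ratios(measurements, "AB")
    p_aa = _ttest(het, _log2_ratios(measurements, "AA"), welch)
    p_bb = _ttest(het, _log2_ratios(measurements, "BB"), welch)
    n_called = sum(m.genotype != "missing" for m in measurements)
    call_rate = n_called / len(measurements)
    counts = {
        g: sum(m.genotype == g for m in measurements) for g in ("AA", "AB", "BB")
    }
    hwe_p = (
        hwe_exact_pvalue(counts["AA"], counts["AB"], counts["BB"])
        if n_called else 0.0
    )
    n_het = counts["AB"]

    reason = None
    if mean_log2_rna < intensity_min:
        reason = "intensity"
    elif not (p_aa <= discrim_alpha and p_bb <= discrim_alpha):
        reason = "discrimination"
    elif call_rate < call_rate_min:
        reason = "call_rate"
    elif hwe_p <= hwe_p_min:
        reason = "hwe"
    elif n_het < min_het:
        reason = "n_het"
    elif structural_exclusion:
        reason = f"structural:{structural_exclusion}"
    return SnpQCReport(
        snp_id=snp_id,
        mean_log2_rna=mean_log2_rna,
        discrim_p_aa=p_aa,
        discrim_p_bb=p_bb,
        call_rate=call_rate,
        hwe_p=hwe_p,
        n_het=n_het,
        excluded_reason=reason,
    )


def _ttest(het: np.ndarray, hom: np.ndarray, welch: bool) -> float:
    # an empty genotype group makes the comparison untestable -> p = 1
    if len(het) < 2 or len(hom) < 2:
        return 1.0
    res = stats.ttest_ind(het, hom, equal_var=not welch)
    p = float(res.pvalue)
    return 1.0 if math.isnan(p) else p


def call_dae(
    ae_values: Iterable[float],
    threshold: float = DAE_THRESHOLD,
    min_fraction: float = DAE_MIN_FRACTION,
    min_samples: int = DAE_MIN_SAMPLES,
    fraction_rounding: str = "ceil",
    snp_id: str = "",
) -> DAECall:
    """DAE decision for one SNP from its heterozygotes' AE_norm values.

    DAE requires |AE_norm| >= threshold in at least ``min_fraction`` of
    heterozygotes and at least ``min_samples`` samples. The fractional
    requirement is rounded up by default (stricter); set
    ``fraction_rounding='floor'`` for the lenient reading.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    values = [float(v) for v in ae_values]
    n_het = len(values)
    n_beyond = sum(abs(v) >= threshold for v in values)
    rounder = math.ceil if fraction_rounding == "ceil" else math.floor
    required = max(min_samples, rounder(min_fraction * n_het)) if n_het else min_samples
    is_dae = n_het > 0 and n_beyond >= required
    return DAECall(
        snp_id=snp_id,
        ae_norm_per_het=values,
        n_het=n_het,
        n_beyond=n_beyond,
        threshold=threshold,
        is_dae=is_dae,
        mean_ae=float(np.mean(values)) if values else 0.0,
    )


def gene_cis_flag(
    calls_by_gene: Mapping[str, Iterable[DAECall]],
) -> dict[str, bool]:
    """A gene shows evidence of cis-regulation when any SNP has DAE."""
    return {
        gene: any(call.is_dae for call in calls)
        for gene, calls in calls_by_gene.items()
    }


def eqtl_scan(
    genotypes: pd.DataFrame,
    expression: pd.DataFrame,
    snp_positions: Mapping[str, int],
    tss: Mapping[str, int],
    window_bp: int = EQTL_WINDOW_BP,
    fdr: float = EQTL_FDR,
) -> tuple[pd.DataFrame, dict[str, bool]]:
    """cis-eQTL scan: OLS of expression on dosage, BH across all tests.

    ``genotypes``: samples × SNPs allele-dosage matrix (0/1/2).
    ``expression``: samples × genes matrix, rows aligned with genotypes.
    Only SNPs within ``window_bp`` of a gene's TSS are tested; a gene is
    flagged when any of its tests reaches q <= fdr.
    """
    if not genotypes.index.equals(expression.index):
        raise ValueError("genotype and expression matrices must share sample index")
    rows: list[dict] = []
    for gene in expression.columns:
        if gene not in tss:
            continue
        y = expression[gene].to_numpy(dtype=float)
        for snp in genotypes.columns:
            pos = snp_positions.get(snp)
            if pos is None or abs(pos - tss[gene]) > window_bp:
                continue
            x = genotypes[snp].to_numpy(dtype=float)
            if np.allclose(x, x[0]):
                logger.info("eQTL: %s has zero dosage variance; skipped", snp)
                continue
            fit = stats.linregress(x, y)
            rows.append(
                dict(gene_id=gene, snp_id=snp, beta=fit.slope, p=fit.pvalue)
            )
    records = pd.DataFrame(rows, columns=["gene_id", "snp_id", "beta", "p"])
    if len(records):
        records["q"] = multipletests(records["p"], method="fdr_bh")[1]
    else:
        records["q"] = pd.Series(dtype=float)
    records["within_window"] = True
    flags = {gene: False for gene in expression.columns}
    for gene, sub in records.groupby("gene_id"):
        flags[gene] = bool((sub["q"] <= fdr).any())
    return records, flags
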