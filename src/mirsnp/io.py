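"""Readers and writers for the pipeline's file formats.

External tables use 1-based inclusive genomic coordinates; 0-based
half-open arithmetic is internal. FASTA I/O goes through Biopython.
UTR FASTA headers are ``transcript_id|gene_id|biotype``; miRNA FASTA
headers are miRBase-style (first whitespace token is the ID).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .allelic_predict import AllelicPredictionRecord, ExpressionRecord
from .cis_regulation import ArrayMeasurement
from .seed_scan import MatureMiRNA, UTRSequence
from .variant_catalog import (
    AnnotatedVariant,
    AssociationRecord,
    GeneInterval,
    ProxyRecord,
    split_multiallelic,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- variants

def read_association_table(path: str | Path) -> list[AssociationRecord]:
    """TSV with columns snp_id, chrom, pos, p_value[, trait, source]."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        AssociationRecord(
            str(r.snp_id), str(r.chrom), int(r.pos), float(r.p_value),
            str(getattr(r, "trait", "")), str(getattr(r, "source", "")),
        )
        for r in df.itertuples()
    ]


def read_variant_table(path: str | Path) -> list[AnnotatedVariant]:
    """TSV variant annotation; multi-allelic rows split, indels dropped."""
    df = pd.read_csv(path, sep="\t", comment="#")
    out: list[AnnotatedVariant] = []
    for r in df.itertuples():
        out.extend(
            split_multiallelic(
                str(r.snp_id), str(r.chrom), int(r.pos), str(r.ref), str(r.alt),
                consequence_terms=_split_set(getattr(r, "consequences", "")),
                gene_ids=_split_set(getattr(r, "gene_ids", "")),
                transcript_ids=_split_set(getattr(r, "transcript_ids", "")),
                flagged=bool(getattr(r, "flagged", False)),
            )
        )
    return out


def read_variant_vcf(path: str | Path) -> list[AnnotatedVariant]:
    """GT-less sites VCF; SO terms from INFO/CSQ, flag from INFO/FLAGGED."""
    from cyvcf2 import VCF

    out: list[AnnotatedVariant] = []
    for v in VCF(str(path)):
        csq = v.INFO.get("CSQ") or ""
        flagged = bool(v.INFO.get("FLAGGED"))
        out.extend(
            split_multiallelic(
                v.ID or f"{v.CHROM}:{v.POS}", v.CHROM, v.POS, v.REF,
                ",".join(v.ALT),
                consequence_terms=_split_set(csq),
                flagged=flagged,
            )
        )
    return out


def _split_set(value) -> set[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return set()
    s = str(value).strip()
    return {t for t in s.split(",") if t} if s else set()


def write_variant_table(variants: Iterable[AnnotatedVariant], path: str | Path) -> None:
    rows = [
        dict(
            snp_id=v.snp_id, chrom=v.chrom, pos=v.pos, ref=v.ref_allele,
            alt=v.alt_allele, consequences=",".join(sorted(v.consequence_terms)),
            gene_ids=",".join(sorted(v.gene_ids)),
            transcript_ids=",".join(sorted(v.transcript_ids)),
            flagged=v.flagged,
        )
        for v in variants
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_association_table(records: Iterable[AssociationRecord], path: str | Path) -> None:
    rows = [
        dict(snp_id=a.snp_id, chrom=a.chrom, pos=a.pos, p_value=a.p_value,
             trait=a.trait, source=a.source)
        for a in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------- LD

def read_ld_table(path: str | Path) -> list[ProxyRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        ProxyRecord(str(r.lead_snp), str(r.proxy_snp), float(r.r2),
                    float(r.d_prime), int(r.distance_bp))
        for r in df.itertuples()
    ]


def write_ld_table(records: Iterable[ProxyRecord], path: str | Path) -> None:
    rows = [
        dict(lead_snp=r.lead_snp, proxy_snp=r.proxy_snp, r2=r.r2,
             d_prime=r.d_prime, distance_bp=r.distance_bp)
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------- genes

_GFF_COLUMNS = ["seqid", "source", "type", "start", "end", "score", "strand",
                "phase", "attributes"]


def read_gene_intervals(path: str | Path) -> list[GeneInterval]:
    """Gene intervals from TSV or GFF3 (detected by extension)."""
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return _read_gff3_genes(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        GeneInterval(str(r.gene_id), str(r.biotype), str(r.chrom),
                     int(r.start), int(r.end), str(getattr(r, "strand", "+")))
        for r in df.itertuples()
    ]


def _read_gff3_genes(path: Path) -> list[GeneInterval]:
    df = pd.read_csv(path, sep="\t", comment="#", names=_GFF_COLUMNS,
                     dtype={"seqid": str})
    genes = []
    for r in df[df["type"] == "gene"].itertuples():
        attrs = dict(
            kv.split("=", 1) for kv in str(r.attributes).split(";") if "=" in kv
        )
        genes.append(
            GeneInterval(
                attrs.get("ID", attrs.get("gene_id", "unknown")),
                attrs.get("biotype", attrs.get("gene_biotype", "protein_coding")),
                str(r.seqid), int(r.start), int(r.end), str(r.strand),
            )
        )
    return genes


def write_gene_intervals(genes: Iterable[GeneInterval], path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for g in genes:
                fh.write(
                    f"{g.chrom}\tmirsnp\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t."
                    f"\tID={g.gene_id};biotype={g.biotype}\n"
                )
        return
    rows = [
        dict(gene_id=g.gene_id, biotype=g.biotype, chrom=g.chrom,
             start=g.start, end=g.end, strand=g.strand)
        for g in genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------- sequences

def read_utr_fasta(path: str | Path, offsets_path: str | Path | None = None) -> list[UTRSequence]:
    """UTR FASTA (headers transcript|gene|biotype) plus optional offsets TSV.

    The offsets TSV has columns transcript_id, snp_id, offset (0-based).
    """
    offsets: dict[str, dict[str, int]] = {}
    if offsets_path is not None:
        df = pd.read_csv(offsets_path, sep="\t", comment="#")
        for r in df.itertuples():
            offsets.setdefault(str(r.transcript_id), {})[str(r.snp_id)] = int(r.offset)
    utrs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        tid = parts[0]
        gene = parts[1] if len(parts) > 1 else tid
        biotype = parts[2] if len(parts) > 2 else "protein_coding"
        utrs.append(
            UTRSequence(tid, gene, str(rec.seq), biotype,
                        snp_offsets=offsets.get(tid, {}))
        )
    return utrs


def write_utr_fasta(utrs: Iterable[UTRSequence], path: str | Path,
                    offsets_path: str | Path | None = None) -> None:
    records = [
        SeqRecord(Seq(u.sequence), id=f"{u.transcript_id}|{u.gene_id}|{u.biotype}",
                  description="")
        for u in utrs
    ]
    SeqIO.write(records, str(path), "fasta")
    if offsets_path is not None:
        rows = [
            dict(transcript_id=u.transcript_id, snp_id=snp, offset=off)
            for u in utrs for snp, off in sorted(u.snp_offsets.items())
        ]
        pd.DataFrame(rows, columns=["transcript_id", "snp_id", "offset"]).to_csv(
            offsets_path, sep="\t", index=False
        )


def read_mirna_fasta(path: str | Path) -> list[MatureMiRNA]:
    return [
        MatureMiRNA(rec.id.split()[0], str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_mirna_fasta(mirnas: Iterable[MatureMiRNA], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(m.sequence), id=m.mirna_id, description="")
        for m in mirnas
    ]
    SeqIO.write(records, str(path), "fasta")


# -------------------------------------------------------------- expression

def read_expression_table(path: str | Path, kind: str) -> list[ExpressionRecord]:
    """Expression TSV: first column feature id, second column value."""
    df = pd.read_csv(path, sep="\t", comment="#")
    id_col, val_col = df.columns[:2]
    return [
        ExpressionRecord(str(r[0]), kind, float(r[1]))
        for r in df[[id_col, val_col]].itertuples(index=False)
    ]


# ------------------------------------------------------------------- array

def read_array_table(path: str | Path) -> list[ArrayMeasurement]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        ArrayMeasurement(str(r.snp_id), str(r.sample_id), str(r.genotype),
                         float(r.dna_a), float(r.dna_b),
                         float(r.rna_a), float(r.rna_b))
        for r in df.itertuples()
    ]


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Samples × features TSV with the sample id in the first column."""
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


# ----------------------------------------------------------------- records

def records_to_frame(records: Iterable[AllelicPredictionRecord]) -> pd.DataFrame:
    rows = [
        dict(
            gene=r.gene_id, transcript=r.transcript_id, snp_id=r.snp_id,
            ref_allele=r.ref_allele, alt_allele=r.alt_allele, mirna=r.mirna_id,
            ref_context=r.ref_context, alt_context=r.alt_context,
            delta_context=r.delta_context, ref_mfe=r.ref_mfe, alt_mfe=r.alt_mfe,
            max_abs_mfe_diff=r.max_abs_mfe_diff, favored_allele=r.favored_allele,
            passed_delta=r.passed_delta, passed_expression=r.passed_expression,
            passed_both_algorithms=r.passed_both_algorithms,
            discordant=r.discordant,
        )
        for r in records
    ]
    return pd.DataFrame(rows)


def write_tsv_with_header(df: pd.DataFrame, path: str | Path,
                          header_lines: Iterable[str] = ()) -> None:
    """Write a TSV with ``#``-prefixed provenance header lines."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


# ----------------------------------------------------------------- bundles

@dataclass
class InputBundle:
    """File-loaded equivalent of a simulated dataset."""

    mirnas: list
    utrs: list
    genes: list
    variants: list
    associations: list
    ld: list
    mirna_expression: pd.DataFrame
    gene_expression: pd.DataFrame
    array_data: pd.DataFrame
    eqtl_genotypes: pd.DataFrame
    eqtl_expression: pd.DataFrame
    snp_positions: dict
    tss: dict
    snp_gene: dict


DATASET_FILES = {
    "associations": "associations.tsv",
    "ld": "ld.tsv",
    "variants": "variants.tsv",
    "genes": "genes.tsv",
    "utr_fasta": "utrs.fa",
    "utr_offsets": "utr_snp_offsets.tsv",
    "mirna_fasta": "mirnas.fa",
    "mirna_expression": "mirna_expression.tsv",
    "gene_expression": "gene_expression.tsv",
    "array": "array_data.tsv",
    "eqtl_genotypes": "eqtl_genotypes.tsv",
    "eqtl_expression": "eqtl_expression.tsv",
    "snp_map": "snp_map.tsv",
    "tss": "tss.tsv",
}


def write_dataset(ds, outdir: str | Path) -> None:
    """Write a simulated dataset as the exact files the pipeline reads,
    plus the truth tables and the generating config as a reproducibility
    record."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    f = {k: out / v for k, v in DATASET_FILES.items()}
    write_association_table(ds.associations, f["associations"])
    write_ld_table(ds.ld, f["ld"])
    write_variant_table(ds.variants, f["variants"])
    write_gene_intervals(ds.genes, f["genes"])
    write_utr_fasta(ds.utrs, f["utr_fasta"], f["utr_offsets"])
    write_mirna_fasta(ds.mirnas, f["mirna_fasta"])
    ds.mirna_expression.to_csv(f["mirna_expression"], sep="\t", index=False)
    ds.gene_expression.to_csv(f["gene_expression"], sep="\t", index=False)
    ds.array_data.to_csv(f["array"], sep="\t", index=False)
    ds.eqtl_genotypes.to_csv(f["eqtl_genotypes"], sep="\t")
    ds.eqtl_expression.to_csv(f["eqtl_expression"], sep="\t")
    pd.DataFrame(
        [
            dict(snp_id=s, gene_id=ds.snp_gene[s], pos=ds.snp_positions[s])
            for s in sorted(ds.snp_gene)
        ]
    ).to_csv(f["snp_map"], sep="\t", index=False)
    pd.DataFrame(
        [dict(gene_id=g, tss=t) for g, t in sorted(ds.tss.items())]
    ).to_csv(f["tss"], sep="\t", index=False)
    ds.truth_snps.to_csv(out / "truth_snps.tsv", sep="\t", index=False)
    ds.truth_genes.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
    ds.truth_mirnas.to_csv(out / "truth_mirnas.tsv", sep="\t", index=False)
    import yaml
    from dataclasses import asdict

    with open(out / "simulation_config.yaml", "w") as fh:
        yaml.safe_dump(asdict(ds.config), fh, sort_keys=True)


def load_bundle(indir: str | Path) -> InputBundle:
    """Load a dataset directory written by :func:`write_dataset`."""
    d = Path(indir)
    f = {k: d / v for k, v in DATASET_FILES.items()}
    snp_map = pd.read_csv(f["snp_map"], sep="\t")
    tss_df = pd.read_csv(f["tss"], sep="\t")
    return InputBundle(
        mirnas=read_mirna_fasta(f["mirna_fasta"]),
        utrs=read_utr_fasta(f["utr_fasta"], f["utr_offsets"]),
        genes=read_gene_intervals(f["genes"]),
        variants=read_variant_table(f["variants"]),
        associations=read_association_table(f["associations"]),
        ld=read_ld_table(f["ld"]),
        mirna_expression=pd.read_csv(f["mirna_expression"], sep="\t"),
        gene_expression=pd.read_csv(f["gene_expression"], sep="\t"),
        array_data=pd.read_csv(f["array"], sep="\t"),
        eqtl_genotypes=read_matrix(f["eqtl_genotypes"]),
        eqtl_expression=read_matrix(f["eqtl_expression"]),
        snp_positions=dict(zip(snp_map.snp_id.astype(str), snp_map.pos.astype(int))),
        tss=dict(zip(tss_df.gene_id.astype(str), tss_df.tss.astype(int))),
        snp_gene=dict(zip(snp_map.snp_id.astype(str), snp_map.gene_id.astype(str))),
    )
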