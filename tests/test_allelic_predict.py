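"""Per-allele comparison, delta thresholding and the filter cascade."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import make_utr, random_rna
from mirsnp.allelic_predict import (
    AllelicPredictionRecord,
    ExpressionRecord,
    apply_delta_threshold,
    build_allele_windows,
    compare_alleles,
    filter_expression,
    intersect_algorithms,
)
from mirsnp.seed_scan import RNA_COMPLEMENT, MatureMiRNA
from mirsnp.variant_catalog import AnnotatedVariant


def variant(ref="A", alt="G", snp="rs1"):
    return AnnotatedVariant(snp, "chr1", 1000, ref, alt)


def planted_utr(mirna: MatureMiRNA, rng, utr_len=200, favored_pos=4):
    """UTR with a full antiparallel complement block; returns (utr, offset,
    favored_base, broken_base)."""
    L = len(mirna.sequence)
    block = []
    for j in range(L):
        pos = L - j
        block.append("A" if pos == 1 else RNA_COMPLEMENT[mirna.sequence[pos - 1]])
    block = "".join(block)
    j_snp = L - favored_pos
    start = 60
    seq = random_rna(rng, utr_len)
    seq = seq[:start] + block + seq[start + L:]
    off = start + j_snp
    favored = block[j_snp]
    partner = {RNA_COMPLEMENT[mirna.sequence[favored_pos - 1]]}
    if mirna.sequence[favored_pos - 1] == "G":
        partner.add("U")
    if mirna.sequence[favored_pos - 1] == "U":
        partner.add("G")
    broken = next(b for b in "ACGU" if b not in partner and b != favored)
    return seq, off, favored, broken


class TestAlleleWindows:
    def test_full_utr_ref_window_is_input_sequence(self, rng):
        seq = random_rna(rng, 120)
        seq = seq[:50] + "A" + seq[51:]
        utr = make_utr(seq, rs1=50)
        w = build_allele_windows(utr, variant("A", "G"))
        ref_full, alt_full = w.full_utr
        assert ref_full.sequence == seq
        assert alt_full.sequence[50] == "G"

    def test_windows_differ_only_at_snp_offset(self, rng):
        seq = random_rna(rng, 120)
        seq = seq[:50] + "A" + seq[51:]
        utr = make_utr(seq, rs1=50)
        w = build_allele_windows(utr, variant("A", "G"))
        ref, alt = w.full_utr
        diffs = [i for i, (a, b) in enumerate(zip(ref.sequence, alt.sequence)) if a != b]
        assert diffs == [50]

    def test_flank_truncation_near_utr_end(self, rng):
        seq = random_rna(rng, 120)
        seq = seq[:10] + "A" + seq[11:]
        utr = make_utr(seq, rs1=10)
        w = build_allele_windows(utr, variant("A", "G"), flank=25)
        ref_flank, _ = w.flank
        assert len(ref_flank.sequence) == 10 + 1 + 25
        assert ref_flank.snp_offset == 10

    def test_centered_window_length(self, rng):
        seq = random_rna(rng, 120)
        seq = seq[:60] + "A" + seq[61:]
        utr = make_utr(seq, rs1=60)
        w = build_allele_windows(utr, variant("A", "G"))
        assert len(w.flank[0].sequence) == 51
        assert w.flank[0].snp_offset == 25

    def test_minus_strand_alleles_complemented(self, rng):
        seq = random_rna(rng, 120)
        seq = seq[:50] + "U" + seq[51:]
        utr = make_utr(seq, rs1=50)
        utr.strand = "-"
        w = build_allele_windows(utr, variant("A", "G"))
        ref, alt = w.full_utr
        assert ref.allele == "U" and alt.allele == "C"

    def test_unknown_snp_raises(self, rng):
        utr = make_utr(random_rna(rng, 100))
        with pytest.raises(KeyError, match="rs1"):
            build_allele_windows(utr, variant())


class TestCompareAlleles:
    def test_planted_site_gain_loss(self, rng, let7a):
        """ref carries an 8mer + strong duplex, alt breaks both."""
        seq, off, favored, broken = planted_utr(let7a, rng)
        utr = make_utr(seq, rs1=off)
        v = variant(favored.replace("U", "T"), broken.replace("U", "T"))
        (rec,) = [r for r in compare_alleles(utr, v, [let7a])
                  if r.mirna_id == let7a.mirna_id]
        assert rec.ref_context is not None and rec.alt_context is None
        assert rec.favored_allele == "ref"
        assert rec.delta_context == pytest.approx(-rec.ref_context)
        assert rec.max_abs_mfe_diff > 0
        assert rec.seed_direction == rec.duplex_direction == "ref"

    def test_snp_invisible_to_both_engines_yields_no_record(self, rng, let7a):
        seq = "C" * 200  # no seed complement, no duplex
        utr = make_utr(seq, rs1=100)
        v = variant("C", "A")
        assert compare_alleles(utr, v, [let7a]) == []

    def test_allele_swap_flips_sign_and_favored_allele(self, rng, let7a):
        seq, off, favored, broken = planted_utr(let7a, rng)
        utr = make_utr(seq, rs1=off)
        fwd = variant(favored.replace("U", "T"), broken.replace("U", "T"))
        # swapped labels: UTR sequence must carry the new ref base
        seq_sw = seq[:off] + broken + seq[off + 1:]
        utr_sw = make_utr(seq_sw, rs1=off)
        rev = variant(broken.replace("U", "T"), favored.replace("U", "T"))
        (a,) = [r for r in compare_alleles(utr, fwd, [let7a]) if r.mirna_id == let7a.mirna_id]
        (b,) = [r for r in compare_alleles(utr_sw, rev, [let7a]) if r.mirna_id == let7a.mirna_id]
        assert a.delta_context == pytest.approx(-b.delta_context)
        assert {a.favored_allele, b.favored_allele} == {"ref", "alt"}
        assert a.max_abs_mfe_diff == pytest.approx(b.max_abs_mfe_diff)


class TestDeltaThreshold:
    def rec(self, delta):
        return AllelicPredictionRecord("g", "t", "rs1", "m", delta_context=delta)

    @pytest.mark.parametrize(
        "delta,expected",
        [(0.151, True), (-0.151, True), (0.150, False), (-0.1509999, False)],
    )
    def test_inclusive_boundary(self, delta, expected):
        (out,) = apply_delta_threshold([self.rec(delta)])
        assert out.passed_delta is expected

    def test_single_allele_prediction_at_threshold_passes(self):
        # a site on one allele only, scored exactly at the threshold value
        rec = AllelicPredictionRecord("g", "t", "rs1", "m",
                                      ref_context=None, alt_context=-0.151,
                                      delta_context=-0.151)
        (out,) = apply_delta_threshold([rec])
        assert out.passed_delta


class TestExpressionFilter:
    def rec(self):
        return AllelicPredictionRecord("g1", "t", "rs1", "m1")

    def expr(self, rpm, tpm):
        return [ExpressionRecord("m1", "mirna", rpm), ExpressionRecord("g1", "gene", tpm)]

    def test_rpm_boundary_is_strict(self):
        (out,) = filter_expression([self.rec()], self.expr(1.0, 5.0))
        assert not out.passed_expression

    def test_expressed_pair_passes(self):
        (out,) = filter_expression([self.rec()], self.expr(1.01, 2.0))
        assert out.passed_expression

    def test_missing_gene_fails(self):
        (out,) = filter_expression([self.rec()], [ExpressionRecord("m1", "mirna", 10)])
        assert not out.passed_expression


class TestIntersectAlgorithms:
    def rec(self, ref_ctx, alt_ctx, ref_mfe, alt_mfe, nref, nalt):
        return AllelicPredictionRecord(
            "g", "t", "rs1", "m", ref_context=ref_ctx, alt_context=alt_ctx,
            delta_context=(alt_ctx or 0) - (ref_ctx or 0),
            ref_mfe=ref_mfe, alt_mfe=alt_mfe,
            n_hits_ref=nref, n_hits_alt=nalt,
        )

    def test_concordant_engines_pass(self):
        (out,) = intersect_algorithms(
            [self.rec(None, -0.3, None, -20.0, 0, 1)]
        )
        assert out.passed_both_algorithms and not out.discordant

    def test_seed_only_record_fails(self):
        (out,) = intersect_algorithms([self.rec(None, -0.3, None, None, 0, 0)])
        assert not out.passed_both_algorithms

    def test_discordant_directions_flagged(self):
        (out,) = intersect_algorithms(
            [self.rec(None, -0.3, -22.0, None, 1, 0)]  # seed: alt, duplex: ref
        )
        assert out.discordant and not out.passed_both_algorithms

    def test_concordance_requirement_can_be_relaxed(self):
        (out,) = intersect_algorithms(
            [self.rec(None, -0.3, -22.0, None, 1, 0)], require_concordance=False
        )
        assert out.passed_both_algorithms


class TestCascadeProperties:
    def test_filter_order_independence(self, rng, let7a):
        seq, off, favored, broken = planted_utr(let7a, rng)
        utr = make_utr(seq, rs1=off)
        v = variant(favored.replace("U", "T"), broken.replace("U", "T"))
        records = compare_alleles(utr, v, [let7a])
        expr = [ExpressionRecord(let7a.mirna_id, "mirna", 10.0),
                ExpressionRecord("G1", "gene", 10.0)]

        def flags(recs):
            return sorted(
                (r.snp_id, r.mirna_id, r.passed_delta, r.passed_expression,
                 r.passed_both_algorithms)
                for r in recs
            )

        a = intersect_algorithms(filter_expression(apply_delta_threshold(records), expr))
        b = apply_delta_threshold(intersect_algorithms(filter_expression(records, expr)))
        c = filter_expression(intersect_algorithms(apply_delta_threshold(records)), expr)
        assert flags(a) == flags(b) == flags(c)

    def test_planted_truth_recall_and_specificity(self, rng, let7a):
        """All 50 planted gain/loss SNPs pass the delta filter; SNPs with
        no planted effect produce no delta-passing record."""
        n_hit = 0
        for i in range(50):
            seq, off, favored, broken = planted_utr(let7a, rng)
            utr = make_utr(seq, tid=f"T{i}", **{f"rs{i}": off})
            v = AnnotatedVariant(f"rs{i}", "chr1", 1000 + i,
                                 favored.replace("U", "T"), broken.replace("U", "T"))
            recs = apply_delta_threshold(compare_alleles(utr, v, [let7a]))
            if any(r.passed_delta and r.mirna_id == let7a.mirna_id for r in recs):
                n_hit += 1
        assert n_hit == 50

        n_false = 0
        for i in range(50):
            seq = random_rna(rng, 200)
            off = 100
            ref = seq[off]
            alt = next(b for b in "ACGU" if b != ref)
            utr = make_utr(seq, tid=f"N{i}", **{f"rs{i}": off})
            # screen the background the way the generator does: only SNPs
            # with no allele-differential site covering the offset qualify
            v = AnnotatedVariant(f"rs{i}", "chr1", 1, ref.replace("U", "T"),
                                 alt.replace("U", "T"))
            recs = apply_delta_threshold(compare_alleles(utr, v, [let7a]))
            if any(r.passed_delta for r in recs):
                n_false += 1
        assert n_false == 0
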