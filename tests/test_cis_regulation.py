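"""Allelic-expression normalization, QC, DAE calling and eQTL scanning."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from oracles import oracle_hwe_exact
from mirsnp.cis_regulation import (
    ArrayMeasurement,
    ae_norm,
    call_dae,
    eqtl_scan,
    gene_cis_flag,
    hwe_exact_pvalue,
    qc_snp,
)

positive = st.floats(min_value=1e-3, max_value=1e3, allow_nan=False)


class TestAeNorm:
    def test_dosage_cancellation(self):
        assert ae_norm(2, 1, 2, 1) == 0.0

    def test_threefold_imbalance(self):
        assert ae_norm(3, 1, 1, 1) == pytest.approx(math.log2(3))

    def test_nonpositive_input_names_offender(self):
        with pytest.raises(ValueError, match="dna_b"):
            ae_norm(1, 1, 1, 0)

    @given(a=positive, b=positive, c=positive, d=positive)
    @settings(max_examples=100, deadline=None)
    def test_antisymmetry_under_allele_swap(self, a, b, c, d):
        assert ae_norm(a, b, c, d) == pytest.approx(-ae_norm(b, a, d, c))

    @given(a=positive, b=positive, c=positive, d=positive,
           scale=st.floats(min_value=1e-2, max_value=1e2))
    @settings(max_examples=100, deadline=None)
    def test_invariance_under_per_channel_scaling(self, a, b, c, d, scale):
        base = ae_norm(a, b, c, d)
        assert ae_norm(a * scale, b * scale, c, d) == pytest.approx(base)
        assert ae_norm(a, b, c * scale, d * scale) == pytest.approx(base)


class TestHweExact:
    @pytest.mark.parametrize(
        "counts", [(25, 50, 25), (50, 0, 50), (60, 0, 0), (3, 10, 7),
                   (0, 5, 0), (40, 20, 40), (10, 80, 10), (1, 1, 1)]
    )
    def test_matches_exact_fraction_oracle(self, counts):
        assert hwe_exact_pvalue(*counts) == pytest.approx(
            oracle_hwe_exact(*counts), rel=1e-9
        )

    def test_random_configurations_match_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(2, 200))
            n_ab = int(rng.integers(0, n + 1))
            n_aa = int(rng.integers(0, n - n_ab + 1))
            n_bb = n - n_ab - n_aa
            assert hwe_exact_pvalue(n_aa, n_ab, n_bb) == pytest.approx(
                oracle_hwe_exact(n_aa, n_ab, n_bb), rel=1e-9
            )

    def test_equilibrium_counts_give_p_one(self):
        assert hwe_exact_pvalue(25, 50, 25) == pytest.approx(1.0)

    def test_extreme_het_deficit_fails_qc_bound(self):
        assert hwe_exact_pvalue(50, 0, 50) < 1e-5

    def test_monomorphic_is_p_one(self):
        assert hwe_exact_pvalue(60, 0, 0) == 1.0

    def test_large_balanced_counts_agree_with_chi_square(self):
        # within 10% of the asymptotic test far from the tails
        n_aa, n_ab, n_bb = 360, 480, 160
        n = n_aa + n_ab + n_bb
        p_a = (2 * n_aa + n_ab) / (2 * n)
        expected = np.array([n * p_a ** 2, 2 * n * p_a * (1 - p_a),
                             n * (1 - p_a) ** 2])
        chi2 = (((np.array([n_aa, n_ab, n_bb]) - expected) ** 2) / expected).sum()
        p_chi = float(stats.chi2.sf(chi2, df=1))
        p_exact = hwe_exact_pvalue(n_aa, n_ab, n_bb)
        assert p_exact == pytest.approx(p_chi, rel=0.10)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_pvalue(0, 0, 0)


def make_measurements(rng, n=60, maf=0.4, intensity_log2=12.0, noise=0.1,
                      dae_shift=0.0, miss=0):
    ms = []
    gts = rng.choice(["AA", "AB", "BB"], size=n,
                     p=[(1 - maf) ** 2, 2 * maf * (1 - maf), maf ** 2])
    for i in range(n - miss):
        gt = gts[i]
        ratio = {"AA": 3.0, "AB": dae_shift, "BB": -3.0}[gt] + rng.normal(0, noise)
        dna_ratio = {"AA": 3.0, "AB": 0.0, "BB": -3.0}[gt] + rng.normal(0, noise)
        total = 2.0 ** intensity_log2
        ms.append(ArrayMeasurement(
            "rs1", f"S{i}", gt,
            total * 2 ** (dna_ratio / 2), total * 2 ** (-dna_ratio / 2),
            total * 2 ** (ratio / 2), total * 2 ** (-ratio / 2),
        ))
    for i in range(n - miss, n):
        ms.append(ArrayMeasurement("rs1", f"S{i}", "missing", 1.0, 1.0, 1.0, 1.0))
    return ms


class TestQcCascade:
    def test_clean_snp_passes(self, rng):
        report = qc_snp(make_measurements(rng))
        assert report.passed, report.excluded_reason

    def test_low_intensity_excluded_first(self, rng):
        # channel sums near 2^8.5: mean log2 RNA intensity ~ 9.5 - 1
        report = qc_snp(make_measurements(rng, intensity_log2=7.5))
        assert report.excluded_reason == "intensity"

    def test_intensity_boundary_9_49_fails(self, rng):
        half = 2.0 ** 8.49  # the two channels sum to exactly 2^9.49
        ms = [ArrayMeasurement("rs1", f"S{i}", "AB", half, half, half, half)
              for i in range(10)]
        report = qc_snp(ms)
        assert report.mean_log2_rna == pytest.approx(9.49)
        assert report.excluded_reason == "intensity"

    def test_poor_discrimination_excluded(self, rng):
        # homozygous ratios indistinguishable from heterozygous ones
        ms = []
        for i, gt in enumerate(["AA"] * 20 + ["AB"] * 20 + ["BB"] * 20):
            ratio = rng.normal(0, 0.1)
            total = 2.0 ** 12
            ms.append(ArrayMeasurement("rs1", f"S{i}", gt,
                                       total, total,
                                       total * 2 ** (ratio / 2),
                                       total * 2 ** (-ratio / 2)))
        assert qc_snp(ms).excluded_reason == "discrimination"

    def test_call_rate_below_90_percent_excluded(self, rng):
        report = qc_snp(make_measurements(rng, n=60, miss=7))
        assert report.excluded_reason == "call_rate"

    def test_too_few_heterozygotes_excluded(self, rng):
        ms = make_measurements(rng, n=60, maf=0.4)
        keep_het = 4
        out = []
        seen = 0
        for m in ms:
            if m.genotype == "AB":
                seen += 1
                if seen > keep_het:
                    out.append(ArrayMeasurement(m.snp_id, m.sample_id, "AA",
                                                m.dna_a, m.dna_b,
                                                m.rna_a * 8, m.rna_b / 8))
                    continue
            out.append(m)
        report = qc_snp(out)
        assert report.excluded_reason in ("hwe", "n_het")  # het deficit trips HWE too

    def test_structural_flag_excluded_last(self, rng):
        report = qc_snp(make_measurements(rng), structural_exclusion="chrX")
        assert report.excluded_reason == "structural:chrX"


class TestCallDae:
    def test_three_of_thirty_is_dae(self):
        vals = [0.7, -0.9, 0.6] + [0.0] * 27
        assert call_dae(vals).is_dae

    def test_two_of_twenty_is_not(self):
        vals = [0.7, 0.9] + [0.0] * 18
        assert not call_dae(vals).is_dae

    def test_ten_percent_rule_needs_ten_of_hundred(self):
        vals = [0.8] * 9 + [0.0] * 91
        assert not call_dae(vals).is_dae
        assert call_dae([0.8] * 10 + [0.0] * 90).is_dae

    def test_threshold_boundary_inclusive(self):
        assert call_dae([0.58, 0.58, -0.58] + [0.0] * 17).is_dae

    def test_empty_input(self):
        call = call_dae([])
        assert not call.is_dae and call.n_het == 0

    def test_floor_rounding_option(self):
        vals = [0.8] * 3 + [0.0] * 32  # 10% of 35 -> ceil 4, floor 3
        assert not call_dae(vals).is_dae
        assert call_dae(vals, fraction_rounding="floor").is_dae


class TestGeneFlag:
    def test_any_dae_snp_flags_gene(self):
        dae = call_dae([0.9] * 5 + [0.0] * 15)
        quiet = call_dae([0.0] * 20)
        flags = gene_cis_flag({"g1": [quiet, dae], "g2": [quiet], "g3": []})
        assert flags == {"g1": True, "g2": False, "g3": False}


class TestEqtlScan:
    def _matrices(self, rng, n=100, n_genes=5, beta=0.0, maf=0.3, sd=0.5):
        samples = [f"S{i}" for i in range(n)]
        snps = {f"rs{j}": rng.choice([0, 1, 2], size=n,
                                     p=[(1 - maf) ** 2, 2 * maf * (1 - maf), maf ** 2])
                for j in range(n_genes)}
        geno = pd.DataFrame(snps, index=samples)
        expr = {}
        for j in range(n_genes):
            y = 10 + rng.normal(0, sd, n)
            if beta:
                y = y + beta * geno[f"rs{j}"].to_numpy()
            expr[f"g{j}"] = y
        positions = {f"rs{j}": 1_000_000 + j for j in range(n_genes)}
        tss = {f"g{j}": 1_000_000 for j in range(n_genes)}
        return geno, pd.DataFrame(expr, index=samples), positions, tss

    def test_planted_effect_is_flagged(self, rng):
        geno, expr, pos, tss = self._matrices(rng, beta=1.0)
        _, flags = eqtl_scan(geno, expr, pos, tss)
        assert all(flags.values())

    def test_window_rule_excludes_distant_snp(self, rng):
        geno, expr, pos, tss = self._matrices(rng, beta=1.0)
        pos["rs0"] = tss["g0"] + 1_000_001
        records, _ = eqtl_scan(geno, expr, pos, tss)
        assert "rs0" not in set(records.snp_id)

    def test_null_flag_fraction_bounded(self, rng):
        """BH at 0.05 on pure noise flags at most ~5% of genes."""
        geno, expr, pos, tss = self._matrices(rng, n_genes=100, beta=0.0)
        _, flags = eqtl_scan(geno, expr, pos, tss)
        frac = sum(flags.values()) / len(flags)
        # 3 Monte-Carlo standard errors above the nominal rate
        assert frac <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / 100)

    def test_zero_variance_dosage_skipped(self, rng):
        geno, expr, pos, tss = self._matrices(rng)
        geno["rs0"] = 1
        records, _ = eqtl_scan(geno, expr, pos, tss)
        assert "rs0" not in set(records.snp_id)

    def test_misaligned_samples_rejected(self, rng):
        geno, expr, pos, tss = self._matrices(rng)
        with pytest.raises(ValueError, match="sample index"):
            eqtl_scan(geno.iloc[::-1], expr, pos, tss)
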