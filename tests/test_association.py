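"""QC filters, transmission counting, the TDT statistic, MAF and lambda."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from conftest import make_cohort, oracle_count_snp, oracle_trio_tallies
from triorank.association import (
    QcCriteria,
    TransmissionCounts,
    compute_maf,
    count_transmissions,
    filter_snps,
    genomic_inflation,
    hwe_test,
    mega_tdt,
    tdt_statistic,
    tdt_table,
    CHI2_1DF_MEDIAN,
)
from triorank.simulate import MISSING, simulate_trios, _default_markers


class TestTransmissionCounting:
    def test_all_27_configurations_match_enumeration_oracle(self):
        """The vectorised counter agrees with per-trio enumeration on every
        ordered (father, mother, child) genotype configuration."""
        for (f, m, c) in itertools.product((0, 1, 2), repeat=3):
            cohort = make_cohort([[f]], [[m]], [[c]])
            got = count_transmissions(cohort, "s0")
            want = oracle_trio_tallies(f, m, c)
            if want is None:
                assert (got.a, got.b, got.c, got.d, got.q) == (0, 0, 0, 0, 0)
            else:
                assert (got.a, got.b, got.c, got.d) == want
                assert got.q == 1

    def test_homozygous_parents_uninformative(self):
        # father M1M1, mother M1M1, child M1M1 -> a += 2
        got = count_transmissions(make_cohort([[2]], [[2]], [[2]]), "s0")
        assert (got.a, got.b, got.c, got.d, got.q) == (2, 0, 0, 0, 1)

    def test_het_father_hom_mother(self):
        # father M1M2, mother M1M1, child M1M1 -> mother a, father b
        got = count_transmissions(make_cohort([[1]], [[2]], [[2]]), "s0")
        assert (got.a, got.b, got.c, got.d) == (1, 1, 0, 0)

    def test_double_het_ambiguous_phase(self):
        # both parents and child M1M2: one parent gave M1, the other M2
        got = count_transmissions(make_cohort([[1]], [[1]], [[1]]), "s0")
        assert (got.a, got.b, got.c, got.d) == (0, 1, 1, 0)

    def test_missing_member_excludes_trio(self):
        got = count_transmissions(make_cohort([[1]], [[MISSING]], [[1]]), "s0")
        assert (got.a + got.b + got.c + got.d, got.q) == (0, 0)

    def test_mendelian_inconsistency_excludes_trio(self):
        # M1M1 x M1M1 cannot produce M2M2
        got = count_transmissions(make_cohort([[2]], [[2]], [[0]]), "s0")
        assert got.q == 0

    def test_unknown_snp(self):
        with pytest.raises(KeyError):
            count_transmissions(make_cohort([[1]], [[1]], [[1]]), "missing_id")

    def test_simulated_cohort_matches_oracle_recount(self):
        """Every SNP's (a,b,c,d,q) equals a trio-by-trio brute-force recount
        on a cohort with missingness and injected Mendelian errors."""
        from triorank.association import _count_all_transmissions

        cohort = simulate_trios(np.linspace(0.05, 0.5, 60), 80,
                                missing_rate=0.05, mendel_error_rate=0.02,
                                seed=17)
        table = _count_all_transmissions(cohort)
        for j in range(cohort.n_snps):
            want = oracle_count_snp(cohort.father[:, j], cohort.mother[:, j],
                                    cohort.child[:, j])
            row = table.iloc[j]
            assert (row.a, row.b, row.c, row.d, row.q) == want

    @given(st.integers(0, 2), st.integers(0, 2), st.integers(0, 2))
    @settings(max_examples=27, deadline=None, derandomize=True)
    def test_counts_sum_identity(self, f, m, c):
        got = count_transmissions(make_cohort([[f]], [[m]], [[c]]), "s0")
        assert got.a + got.b + got.c + got.d == 2 * got.q


class TestTdtStatistic:
    def test_symmetric_counts(self):
        chi2, p = tdt_statistic(TransmissionCounts(0, 7, 7, 0, 7))
        assert chi2 == 0 and p == 1

    def test_printed_formula(self):
        chi2, p = tdt_statistic(TransmissionCounts(0, 16, 4, 0, 10))
        assert chi2 == pytest.approx(144 / 20)
        assert p == pytest.approx(stats.chi2.sf(7.2, 1))

    def test_asymptotic_close_to_exact_binomial(self):
        """The chi-square tail at b=16, c=4 is the asymptotic version of the
        two-sided exact Binomial(20, 1/2) tail; same order of magnitude."""
        _, p_asym = tdt_statistic(TransmissionCounts(0, 16, 4, 0, 10))
        p_exact = 2 * sum(stats.binom.pmf(k, 20, 0.5) for k in range(16, 21))
        assert 0.2 < p_asym / p_exact < 5

    def test_uninformative_returns_nan(self):
        chi2, p = tdt_statistic(TransmissionCounts(4, 0, 0, 4, 4))
        assert np.isnan(chi2) and np.isnan(p)

    def test_allele_label_swap_invariance(self):
        """Swapping M1/M2 swaps (a,d) and (b,c) but leaves chi2 and p fixed."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            a, b, c, d = (int(x) for x in rng.integers(0, 30, size=4))
            if (a + b + c + d) % 2:
                a += 1
            q = (a + b + c + d) // 2
            if b + c == 0:
                continue
            s1 = tdt_statistic(TransmissionCounts(a, b, c, d, q))
            s2 = tdt_statistic(TransmissionCounts(d, c, b, a, q))
            assert s1 == s2

    def test_genotype_flip_swaps_counts(self):
        """Relabelling alleles in the genotypes themselves swaps a<->d and
        b<->c in the counted table."""
        cohort = simulate_trios(np.linspace(0.1, 0.5, 20), 50, seed=8)
        flipped = make_cohort(2 - cohort.father, 2 - cohort.mother,
                              2 - cohort.child)
        for j in (0, 7, 19):
            snp = cohort.markers["snp"][j]
            c1 = count_transmissions(cohort, snp)
            c2 = count_transmissions(flipped, f"s{j}")
            assert (c1.a, c1.b, c1.c, c1.d) == (c2.d, c2.c, c2.b, c2.a)


class TestQc:
    def test_exact_hwe_proportions_pass(self):
        # parent genotype counts at exact HWE for p=0.5: 25/50/25
        father = np.repeat([2, 1, 1, 0], 25)[:, None] * np.ones((1, 1), int)
        mother = np.repeat([1, 2, 0, 1], 25)[:, None] * np.ones((1, 1), int)
        # fathers: 25 hom1, 50 het, 25 hom2; mothers likewise
        child = np.ones((100, 1), int)
        qc = filter_snps(make_cohort(father, mother, child))
        assert qc["qc_pass"].all()
        assert qc["hwe_p"].iloc[0] == pytest.approx(1.0)

    def test_sixteen_percent_missing_fails(self):
        n = 100  # 300 genotype calls; 48 missing = 16%
        father = np.repeat([2, 1, 0], [25, 50, 25])[:, None].astype(np.int8)
        mother = father.copy()  # parents at exact HWE proportions
        child = np.ones((n, 1), np.int8)
        child[:48] = MISSING
        qc = filter_snps(make_cohort(father, mother, child))
        assert not qc["qc_pass"].iloc[0]
        assert qc["reason"].iloc[0] == "missingness"

    def test_monomorphic_passes_with_flag(self):
        n = 50
        g = np.full((n, 1), 2, np.int8)
        qc = filter_snps(make_cohort(g, g, g))
        assert qc["qc_pass"].iloc[0]
        assert qc["monomorphic"].iloc[0]
        assert qc["hwe_p"].iloc[0] == pytest.approx(1.0)

    def test_hwe_violation_fails(self):
        # all parents heterozygous: extreme excess heterozygosity
        n = 400
        het = np.ones((n, 1), np.int8)
        qc = filter_snps(make_cohort(het, het, het),
                         QcCriteria(hwe_min_p=1e-6))
        assert not qc["qc_pass"].iloc[0]
        assert qc["reason"].iloc[0] == "hwe"

    def test_exact_vs_asymptotic_hwe_agree_at_large_n(self):
        p_asym = hwe_test(240, 520, 240, exact=False)
        p_exact = hwe_test(240, 520, 240, exact=True)
        assert abs(p_asym - p_exact) < 0.05

    def test_empty_cohort_rejected(self):
        cohort = simulate_trios(np.array([0.3]), 1, seed=0)
        cohort.father = cohort.father[:0]
        cohort.mother = cohort.mother[:0]
        cohort.child = cohort.child[:0]
        with pytest.raises(ValueError, match="empty"):
            filter_snps(cohort)


class TestMaf:
    def test_all_heterozygous(self):
        g = np.ones((10, 1), np.int8)
        assert compute_maf(make_cohort(g, g, g), "s0") == 0.5

    def test_direct_allele_count(self):
        # offspring: 2 M1M1, 4 M1M2, 4 M2M2 -> f(M1) = 8/20 = 0.4
        child = np.array([[2]] * 2 + [[1]] * 4 + [[0]] * 4, np.int8)
        par = np.ones_like(child)
        assert compute_maf(make_cohort(par, par, child), "s0") == \
            pytest.approx(0.4)

    def test_monomorphic_zero(self):
        g = np.full((10, 1), 2, np.int8)
        assert compute_maf(make_cohort(g, g, g), "s0") == 0.0

    def test_all_missing_is_nan(self):
        child = np.full((5, 1), MISSING, np.int8)
        par = np.ones_like(child)
        assert np.isnan(compute_maf(make_cohort(par, par, child), "s0"))


class TestGenomicInflation:
    def test_null_median_gives_one(self):
        lam = genomic_inflation(np.full(10, CHI2_1DF_MEDIAN))
        assert lam == pytest.approx(1.0)

    def test_null_simulation(self):
        rng = np.random.default_rng(12)
        chi2 = rng.chisquare(1, size=100_000)
        assert abs(genomic_inflation(chi2) - 1.0) < 0.02

    def test_scale_equivariance(self):
        x = np.random.default_rng(1).chisquare(1, size=1_000)
        assert genomic_inflation(2 * x) == pytest.approx(
            2 * genomic_inflation(x))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            genomic_inflation(np.array([]))


class TestMega:
    def test_single_cohort_identity(self):
        cohort = simulate_trios(np.linspace(0.1, 0.5, 30), 60, seed=21)
        solo = tdt_table(cohort)
        mega = mega_tdt([cohort])
        keep = solo[solo["qc_pass"]].reset_index(drop=True)
        pd.testing.assert_frame_equal(
            mega[["snp", "a", "b", "c", "d", "q"]],
            keep[["snp", "a", "b", "c", "d", "q"]])
        np.testing.assert_allclose(mega["chi2"], keep["chi2"])

    def test_pooled_counts_additive(self):
        # counts (b=5, c=1) and (b=3, c=3) -> pooled chi2 = 16/12
        c1 = TransmissionCounts(0, 5, 1, 0, 3)
        c2 = TransmissionCounts(0, 3, 3, 0, 3)
        pooled = c1 + c2
        assert (pooled.b, pooled.c) == (8, 4)
        chi2, _ = tdt_statistic(pooled)
        assert chi2 == pytest.approx(16 / 12)

    def test_qc_intersection_rule(self):
        """A SNP failing QC in one cohort is absent from the mega table."""
        freqs = np.linspace(0.2, 0.4, 10)
        markers = _default_markers(10, rng=np.random.default_rng(0))
        a = simulate_trios(freqs, 80, seed=22, markers=markers)
        b = simulate_trios(freqs, 80, seed=23, markers=markers)
        # make snp index 3 fail missingness in cohort b only
        b.father[:, 3] = MISSING
        b.mother[:, 3] = MISSING
        b.child[:, 3] = MISSING
        mega = mega_tdt([a, b])
        assert b.markers["snp"][3] not in set(mega["snp"])
        assert len(mega) == 9

    def test_no_shared_snps_empty_with_warning(self, caplog):
        freqs = np.array([0.3])
        markers = _default_markers(1, rng=np.random.default_rng(0))
        a = simulate_trios(freqs, 30, seed=24, markers=markers)
        b = simulate_trios(freqs, 30, seed=25, markers=markers)
        b.father[:] = MISSING
        b.mother[:] = MISSING
        b.child[:] = MISSING
        with caplog.at_level("WARNING"):
            mega = mega_tdt([a, b])
        assert mega.empty
        assert any("no SNP passes QC" in r.message for r in caplog.records)
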