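"""Shared-haplotype extension, rescue rule, Gamma-method dating."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rcnvclock.io_formats import MISSING, GeneticMap, PhasedHaplotypeSet
from rcnvclock.haplotype_coalescence import (
    FlankingWindows,
    SharedLengthSummary,
    age_abundance_correlation,
    carrier_cnv_haplotypes,
    compare_ages,
    date_rcnv,
    estimate_age,
    max_shared_haplotype,
    select_flanking_snps,
    share_support,
    weighted_mean_length,
)
from rcnvclock.rcnv_detection import RCNVLocus


def _locus(start, end, chrom="1", carriers=("S1", "S2")):
    return RCNVLocus(
        locus_id="L1", chrom=chrom, start=start, end=end, state="deletion",
        carriers=frozenset(carriers), carrier_frequency=0.1,
    )


def _window_only_3(n_snps, spacing=1000, locus_end=500):
    """A synthetic downstream window: SNPs at locus_end + spacing, 2*spacing, ..."""
    positions = np.arange(1, n_snps + 1, dtype=np.int64) * spacing + locus_end
    all_pos = np.concatenate([[1], positions])  # one upstream SNP to satisfy both sides
    return FlankingWindows(
        idx_5=np.array([0]),
        idx_3=np.arange(1, n_snps + 1),
        positions=all_pos,
        locus_start=2,
        locus_end=locus_end,
    )


def _haps_with_test_row(test_alleles, n_background=9, n_snps=None):
    """9 all-zero haplotypes (fixing the ancestral reference at 0) plus one
    test haplotype; column 0 is the single upstream SNP."""
    n_snps = len(test_alleles) if n_snps is None else n_snps
    mat = np.zeros((n_background + 1, n_snps + 1), dtype=np.int8)
    mat[-1, 1:] = np.asarray(test_alleles, dtype=np.int8)
    return mat


class TestSelectFlankingSnps:
    def test_full_windows(self, small_cohort, cohort_locus):
        _, haps, _, _, _ = small_cohort
        win = select_flanking_snps(cohort_locus, haps, k_per_side=60)
        assert win.idx_5.size == 60 and win.idx_3.size == 60
        assert not win.truncated_5 and not win.truncated_3
        # ordered outward: 5' decreasing, 3' increasing positions
        assert np.all(np.diff(win.pos_5) < 0) and np.all(np.diff(win.pos_3) > 0)
        assert win.pos_5[0] < cohort_locus.start and win.pos_3[0] > cohort_locus.end

    def test_truncated_side_flagged(self):
        positions = np.arange(1, 21, dtype=np.int64) * 1000
        haps = PhasedHaplotypeSet(
            ["A"], positions, np.zeros((2, 20), dtype=np.int8)
        )
        locus = _locus(10_500, 11_500)
        win = select_flanking_snps(locus, haps, k_per_side=60)
        assert win.truncated_5 and win.idx_5.size == 10

    def test_k1_takes_nearest(self, small_cohort, cohort_locus):
        _, haps, _, _, _ = small_cohort
        win = select_flanking_snps(cohort_locus, haps, k_per_side=1)
        assert win.idx_5.size == 1 and win.idx_3.size == 1

    def test_no_flank_errors(self):
        positions = np.arange(1, 11, dtype=np.int64) * 1000
        haps = PhasedHaplotypeSet(["A"], positions, np.zeros((2, 10), dtype=np.int8))
        with pytest.raises(ValueError, match="downstream"):
            select_flanking_snps(_locus(50_000, 60_000), haps)


class TestMaxSharedHaplotype:
    def test_identical_haplotype_censored_at_edge(self):
        win = _window_only_3(20)
        summary = max_shared_haplotype(_haps_with_test_row([0] * 20), win)
        row = summary.table.iloc[-1]
        assert row["censored_3"] and row["n_shared_3"] == 20

    def test_single_mismatch_rescued(self):
        # mismatch at SNP 7 (1-based) followed by >= 5 matches -> rescued
        alleles = [0] * 20
        alleles[6] = 1
        summary = max_shared_haplotype(_haps_with_test_row(alleles), win := _window_only_3(20))
        row = summary.table.iloc[-1]
        assert row["n_shared_3"] == 20 and row["censored_3"]

    def test_two_mismatches_within_rescue_stop_at_first(self):
        # mismatches at SNPs 7 and 9: rescue fails, breakpoint at SNP 6
        alleles = [0] * 20
        alleles[6] = 1
        alleles[8] = 1
        summary = max_shared_haplotype(_haps_with_test_row(alleles), _window_only_3(20))
        row = summary.table.iloc[-1]
        assert row["n_shared_3"] == 6 and not row["censored_3"]
        # breakpoint at the last concordant SNP (SNP 6 at 500 + 6*1000)
        assert row["breakpoint_bp_3"] == 6_500

    def test_rescue_disabled_stops_at_first_mismatch(self):
        alleles = [0] * 20
        alleles[6] = 1
        summary = max_shared_haplotype(
            _haps_with_test_row(alleles), _window_only_3(20), rescue_len=0
        )
        assert summary.table.iloc[-1]["n_shared_3"] == 6

    def test_missing_alleles_never_terminate(self):
        alleles = [0] * 20
        alleles[3] = MISSING
        alleles[4] = MISSING
        summary = max_shared_haplotype(_haps_with_test_row(alleles), _window_only_3(20))
        assert summary.table.iloc[-1]["censored_3"]

    def test_mismatch_at_first_snp_gives_zero_shared(self):
        alleles = [1, 1] + [0] * 18
        summary = max_shared_haplotype(_haps_with_test_row(alleles), _window_only_3(20))
        row = summary.table.iloc[-1]
        assert row["n_shared_3"] == 0
        assert row["breakpoint_bp_3"] == 500  # the locus edge

    def test_all_missing_haplotype_excluded_with_warning(self):
        mat = _haps_with_test_row([0] * 20)
        mat[-1, :] = MISSING
        with pytest.warns(UserWarning, match="all-missing"):
            summary = max_shared_haplotype(mat, _window_only_3(20))
        assert summary.n_haplotypes == mat.shape[0] - 1


class TestWeightedMeanLength:
    gmap = GeneticMap("1", [1, 30_000_000], [0.0, 30.0])  # uniform 1 cM/Mb

    def _summary(self, rows):
        table = pd.DataFrame.from_records(rows)
        win = FlankingWindows(
            idx_5=np.array([0]), idx_3=np.array([1]),
            positions=np.array([9_000_000, 11_000_000], dtype=np.int64),
            locus_start=10_000_001, locus_end=10_100_000,
        )
        return SharedLengthSummary(table=table, windows=win)

    def _row(self, label, bp5_off, bp3_off, sig):
        return {
            "hap_label": label,
            "n_shared_5": sig, "censored_5": False,
            "n_shared_3": sig, "censored_3": False,
            "breakpoint_bp_5": 10_000_001 - bp5_off,
            "breakpoint_bp_3": 10_100_000 + bp3_off,
        }

    def test_distinct_breakpoints_reduce_to_simple_mean(self):
        rows = [self._row(f"h{i}", 100_000 * (i + 1), 100_000 * (i + 1), i) for i in range(4)]
        summary = self._summary(rows)
        l_ave = weighted_mean_length(summary, self.gmap)
        sizes_m = [2 * 0.001 * (i + 1) for i in range(4)]  # 0.1 cM/100kb/side
        assert l_ave == pytest.approx(np.mean(sizes_m))
        assert all(w == 1 for w in summary.groups.values())

    def test_hand_computed_weighted_mean(self):
        # 3 haplotypes sharing a 1 cM total, 1 haplotype with 3 cM -> 1.5 cM
        rows = [self._row(f"a{i}", 500_000, 500_000, 1) for i in range(3)]
        rows.append(self._row("b", 1_500_000, 1_500_000, 2))
        summary = self._summary(rows)
        assert weighted_mean_length(summary, self.gmap) == pytest.approx(0.015)
        assert sorted(summary.groups.values()) == [1, 3]

    def test_uniform_map_one_mb_each_side(self):
        rows = [self._row(f"h{i}", 1_000_000, 1_000_000, 1) for i in range(5)]
        summary = self._summary(rows)
        assert weighted_mean_length(summary, self.gmap) == pytest.approx(0.02)

    def test_all_censored_both_sides_errors(self):
        rows = [self._row("h0", 500_000, 500_000, 1)]
        rows[0]["censored_5"] = rows[0]["censored_3"] = True
        with pytest.raises(ValueError, match="censored"):
            weighted_mean_length(self._summary(rows), self.gmap)


class TestEstimateAge:
    @pytest.mark.parametrize("l_ave,expected", [(0.02, 100.0), (0.004, 500.0)])
    def test_closed_form(self, l_ave, expected):
        est = estimate_age(l_ave, n_haplotypes=20)
        assert est.tau_hat == pytest.approx(expected)

    def test_ci_from_gamma_quantiles(self):
        est = estimate_age(0.02, n_haplotypes=10)
        lo = stats.gamma.ppf(0.025, a=20) / (10 * 0.02)
        hi = stats.gamma.ppf(0.975, a=20) / (10 * 0.02)
        assert est.ci == pytest.approx((lo, hi))

    def test_antitone_in_l_ave(self):
        taus = [estimate_age(l, 10).tau_hat for l in np.linspace(0.001, 0.1, 25)]
        assert np.all(np.diff(taus) < 0)

    def test_ci_contains_estimate_and_shrinks(self):
        widths = []
        for n in (2, 5, 20, 100, 1000):
            est = estimate_age(0.02, n)
            assert est.ci[0] <= est.tau_hat <= est.ci[1]
            widths.append(est.ci[1] - est.ci[0])
        assert np.all(np.diff(widths) < 0)

    def test_years_and_sensitivity(self):
        est = estimate_age(0.02, 10, years_per_generation=28.0)
        assert est.years == pytest.approx(2800.0)
        assert est.rate_sensitivity == pytest.approx((100 / 1.2, 100 / 0.8))

    def test_inconsistent_inputs(self):
        with pytest.raises(ValueError, match="genetic span"):
            estimate_age(0.5, 10, region_genetic_span=0.3)
        with pytest.raises(ValueError, match="l_ave"):
            estimate_age(0.0, 10)

    def test_high_censoring_warns(self):
        with pytest.warns(UserWarning, match="biased downward"):
            estimate_age(0.02, 10, censoring_fraction=0.5)


class TestCompareAges:
    def test_identical_lists_p_one(self):
        u, p = compare_ages([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_exact_small_sample(self):
        u, p = compare_ages([1, 2, 3], [10, 20, 30])
        assert u == 0.0 and p == pytest.approx(0.1)
        # exact enumeration oracle over all C(6,3) group assignments
        pooled = [1, 2, 3, 10, 20, 30]
        obs_u = 0
        count = 0
        total = 0
        for combo in itertools.combinations(range(6), 3):
            a = [pooled[i] for i in combo]
            b = [pooled[i] for i in range(6) if i not in combo]
            u_ = sum(1 for x in a for y in b if x > y) + 0.5 * sum(
                1 for x in a for y in b if x == y
            )
            total += 1
            if min(u_, 9 - u_) <= min(obs_u, 9 - obs_u):
                count += 1
        assert p == pytest.approx(count / total)

    def test_separated_groups_detected(self):
        """Age-estimate draws from the Gamma sampling model at tau 1000 vs
        100 (10 loci per group, n=20 haplotypes each): p < 0.05 in >= 90%
        of 100 replicates."""
        rng = np.random.default_rng(0)
        n = 20
        hits = 0
        for _ in range(100):
            a = 2 * n * 1000.0 / rng.gamma(2 * n, 1.0, size=10)  # shared: old
            b = 2 * n * 100.0 / rng.gamma(2 * n, 1.0, size=10)  # specific: young
            _, p = compare_ages(a, b)
            hits += p < 0.05
        assert hits >= 90

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            compare_ages([], [1.0])


class TestAgeAbundanceCorrelation:
    def test_perfect_line(self):
        r, slope, p = age_abundance_correlation([1, 2, 3, 4], [0.1, 0.2, 0.3, 0.4])
        assert r == pytest.approx(1.0) and slope == pytest.approx(0.1)

    def test_anti_monotone_negative(self):
        r, _, _ = age_abundance_correlation([1, 2, 3, 4], [9, 6, 4, 1])
        assert r < 0

    def test_null_p_uniform(self):
        """Independent vectors: p approximately U(0,1) over 200 replicates."""
        rng = np.random.default_rng(1)
        ps = [
            age_abundance_correlation(rng.normal(size=12), rng.normal(size=12))[2]
            for _ in range(200)
        ]
        assert stats.kstest(ps, "uniform").pvalue > 0.01
        assert np.mean(np.abs([age_abundance_correlation(rng.normal(size=50),
                                                         rng.normal(size=50))[0]
                               for _ in range(50)])) < 0.2

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            age_abundance_correlation([1, 1, 1], [1, 2, 3])


class TestEndToEnd:
    def test_share_support_high_for_carriers_low_for_background(
        self, small_cohort, cohort_locus
    ):
        _, haps, _, truth, _ = small_cohort
        win = select_flanking_snps(cohort_locus, haps, k_per_side=60)
        mat, _ = carrier_cnv_haplotypes(haps, cohort_locus, truth.carrier_ids)
        assert share_support(mat, win) > 0.9
        background = haps.alleles[2 * len(truth.carrier_ids) + 1 :: 2]
        assert share_support(background, win) < 0.9

    def test_date_rcnv_recovers_simulated_age(self, small_cohort, cohort_locus):
        _, haps, gmap, truth, _ = small_cohort
        est, summary = date_rcnv(
            cohort_locus, haps, gmap, truth.carrier_ids, k_per_side=400
        )
        assert summary.n_haplotypes == len(truth.carrier_ids)
        # single cohort at n=30: the interval should bracket the truth here
        assert 50 < est.tau_hat < 200
        assert est.ci[0] < 100 < est.ci[1]

    def test_carrier_haplotype_identification(self, small_cohort, cohort_locus):
        _, haps, _, truth, _ = small_cohort
        mat, labels = carrier_cnv_haplotypes(haps, cohort_locus, truth.carrier_ids)
        for row, sid in zip(mat, truth.carrier_ids):
            assert np.array_equal(row, haps.haplotype(sid, 0))
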