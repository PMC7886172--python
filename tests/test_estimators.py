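"""Screen estimators: printed-value checks, calibration and recovery."""

import numpy as np
import pandas as pd
import pytest

from drivesim import estimators as est
from drivesim.estimators import DepositionCounts, ScreenCounts


class TestTransmission:
    def test_point_estimate(self):
        assert est.transmission_rate(ScreenCounts(50, 100)).estimate == 0.5

    def test_boundary_interval(self):
        result = est.transmission_rate(ScreenCounts(100, 100))
        assert result.estimate == 1.0
        assert result.ci_high == pytest.approx(1.0)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            ScreenCounts(0, 0)

    def test_pooled_clutches_reproduce_strain_rate(self):
        # clutches pooling to 93.5% positive: the zpg paternal male rate
        clutches = [ScreenCounts(187, 200), ScreenCounts(561, 600)]
        assert est.transmission_rate(clutches).estimate == pytest.approx(0.935)

    def test_table_emits_both_interval_styles(self):
        counts = [ScreenCounts(45, 50, f"c{i}", "male", "paternal", "zpg")
                  for i in range(4)]
        table = est.transmission_table(counts)
        assert set(["wilson_low", "wilson_high", "clutch_sem"]) <= set(table)
        assert table["transmission"].iloc[0] == pytest.approx(0.9)


class TestHomingConversion:
    @pytest.mark.parametrize("p,h", [(0.602, 0.204), (0.996, 0.992),
                                     (0.5, 0.0), (1.0, 1.0)])
    def test_printed_pairs(self, p, h):
        value, flagged = est.homing_from_inheritance(p)
        assert value == pytest.approx(h, abs=1e-12)
        assert not flagged

    def test_sub_mendelian_reported_as_zero_with_flag(self):
        value, flagged = est.homing_from_inheritance(0.45)
        assert value == 0.0
        assert flagged

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            est.homing_from_inheritance(1.3)


class TestRelativeFecundity:
    def test_identical_distributions(self):
        counts = [80, 95, 110, 60]
        assert est.relative_fecundity(counts, counts) == pytest.approx(1.0)

    def test_printed_ratio(self):
        wt = [100.0] * 10
        strain = [54.9] * 10
        assert est.relative_fecundity(strain, wt) == pytest.approx(0.549)

    def test_all_zero_clutches(self):
        assert est.relative_fecundity([0, 0, 0], [90, 110]) == 0.0

    def test_sperm_absent_females_excluded(self):
        strain = [0, 0, 100, 100]
        flags = [True, True, False, False]
        assert est.relative_fecundity(strain, [100, 100],
                                      strain_sperm_absent=flags) == 1.0

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            est.relative_fecundity([], [100])

    def test_median_option_and_bootstrap_ci(self):
        rng = np.random.default_rng(1)
        ratio, low, high = est.relative_fecundity(
            [50] * 20, [100] * 20, ci=True, rng=rng)
        assert low <= ratio <= high
        assert est.relative_fecundity([10, 50, 900], [50, 100, 150],
                                      use_median=True) == 0.5


class TestDepositionArithmetic:
    def test_no_novel_alleles(self):
        assert est.embryonic_ej_rate_f2(DepositionCounts(30, 30, 0)) == 0.0

    def test_printed_maternal_rates(self):
        # strong deposition: 70 novel vs 30 WT -> 70% of sensitive alleles
        assert est.embryonic_ej_rate_f2(DepositionCounts(30, 100, 70)) == 0.70
        # moderate deposition: 21 novel vs 179 WT -> 10.5%
        assert est.embryonic_ej_rate_f2(DepositionCounts(179, 200, 21)) == 0.105

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            est.embryonic_ej_rate_f2(DepositionCounts(0, 10, 0))

    def test_f3_four_fold_dilution_rule(self):
        assert est.embryonic_ej_rate_f3(0.0) == (0.0, False)
        rate, flagged = est.embryonic_ej_rate_f3(0.05)
        assert rate == pytest.approx(0.20)
        assert not flagged
        _, flagged = est.embryonic_ej_rate_f3(0.30)
        assert flagged

    def test_f2_estimator_unbiased(self):
        rng = np.random.default_rng(8)
        e, n = 0.3, 5000
        errors = []
        for _ in range(200):
            novel = rng.binomial(n, e)
            counts = DepositionCounts(n - novel, n, novel)
            errors.append(est.embryonic_ej_rate_f2(counts) - e)
        assert abs(np.mean(errors)) < 0.01


class TestMendelianDilution:
    def test_exact_two_fold_consistent(self):
        check = est.mendelian_dilution_check(0.30, 150, 1000)
        assert check.fold_reduction == pytest.approx(2.0)
        assert check.consistent_with_mendelian

    def test_no_reduction_flags_amplification(self):
        check = est.mendelian_dilution_check(0.30, 300, 1000)
        assert check.fold_reduction == pytest.approx(1.0)
        assert not check.consistent_with_mendelian

    def test_zero_f3_frequency_flagged_without_ratio(self):
        check = est.mendelian_dilution_check(0.30, 0, 50)
        assert check.fold_reduction is None
        assert check.flagged

    def test_halving_on_matched_synthetic_counts(self):
        # a mutation at 20% in the F2 observed near 10% in the F3
        rng = np.random.default_rng(3)
        f3 = rng.binomial(2000, 0.10)
        check = est.mendelian_dilution_check(0.20, f3, 2000)
        assert check.consistent_with_mendelian


class TestWtDepletion:
    def test_balanced_control_no_departure(self):
        result = est.wt_depletion_test(DepositionCounts(100, 100, 0))
        assert not result.depleted
        assert result.wt_fraction == 0.5

    def test_maximal_depletion(self):
        result = est.wt_depletion_test(DepositionCounts(0, 100, 100))
        assert result.depleted
        assert result.wt_fraction == 0.0

    def test_type_i_error_calibrated(self):
        """Without deposition the exact test rejects at <= the nominal 5%."""
        rng = np.random.default_rng(77)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            wt = rng.binomial(200, 0.5)
            result = est.wt_depletion_test(DepositionCounts(wt, 200 - wt, 0))
            rejections += result.depleted
        assert 0.01 <= rejections / n_sim <= 0.07


class TestMeioticSummary:
    def test_all_wild_type(self):
        records = pd.DataFrame({"allele": ["WT"] * 10, "klass": ["WT"] * 10})
        summary = est.meiotic_ej_summary(records)
        assert summary["fraction_mutated"] == 0.0
        assert summary["distinct_alleles"] == 0

    def test_female_germline_printed_summary(self):
        # 218 captured chromosomes, 192 mutated across 4 identities -> 88%
        rows = [("WT", "WT")] * 26
        for i, n in enumerate([120, 40, 20, 12]):
            rows += [(f"allele{i}", "confirmed_r1" if i < 2 else "confirmed_r2")] * n
        summary = est.meiotic_ej_summary(rows)
        assert summary["n"] == 218
        assert summary["fraction_mutated"] == pytest.approx(0.88, abs=0.005)
        assert summary["distinct_alleles"] == 4

    def test_male_germline_printed_summary(self):
        # 239 captured chromosomes, 82 mutated across 18 identities
        rows = [("WT", "WT")] * 157
        # 18 identities totalling 82 mutated chromosomes
        for i, n in enumerate([10] * 4 + [3] * 12 + [3, 3]):
            rows += [(f"a{i}", "in_frame" if i % 3 == 0 else "out_of_frame")] * n
        summary = est.meiotic_ej_summary(rows)
        assert summary["n"] == 239
        assert summary["n_mutated"] == 82
        assert summary["fraction_mutated"] == pytest.approx(0.343, abs=0.001)
        assert summary["distinct_alleles"] == 18

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            est.meiotic_ej_summary(pd.DataFrame(columns=["allele", "klass"]))


def test_homing_rate_recovered_within_interval(zpg):
    """Coverage: simulated screens at known c*hdr recover the truth inside
    the 95% Wilson interval in >= 93% of replicates (n = 500 progeny)."""
    rng = np.random.default_rng(12345)
    true_h = 0.9
    p = (1 + true_h) / 2
    covered = 0
    n_rep = 500
    for _ in range(n_rep):
        positives = rng.binomial(500, p)
        estimate = est.transmission_rate(ScreenCounts(int(positives), 500))
        low, _ = est.homing_from_inheritance(estimate.ci_low)
        high, _ = est.homing_from_inheritance(estimate.ci_high)
        covered += low <= true_h <= high
    assert covered / n_rep >= 0.93
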