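"""Mutation-spectrum, dose-response and rate statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ionexome.core import Caller, ReferenceGenome, TargetRegion, TargetSet, VarClass, VariantRecord
from ionexome.spectrum import (
    CohortPhenotype,
    DoseGroup,
    base_preference,
    cdm_mutation_rate,
    chrom_frequency,
    dose_response_table,
    extrapolate_genome,
    gaussian_fit,
    is_transition,
    per_gy_rate,
    size_histogram,
    summarize_spectrum,
    target_gc_at_ratio,
)


def _snv(ref, alt, chrom="c", pos=0):
    return VariantRecord("m", Caller.SNV_CALLER, chrom, pos, ref, alt, VarClass.SNV, 0, 50, 0)


def _sized(var_class, size, chrom="c", pos=0):
    ref = "A" * size if var_class is VarClass.DEL else ""
    alt = "A" * size if var_class is VarClass.INS else ""
    return VariantRecord("m", Caller.SV_CALLER, chrom, pos, ref, alt, var_class, size, 50, 0)


class TestIsTransition:
    @pytest.mark.parametrize(
        "r,a,expected",
        [("A", "G", True), ("G", "A", True), ("C", "T", True), ("T", "C", True),
         ("C", "G", False), ("A", "T", False), ("A", "C", False), ("G", "T", False)],
    )
    def test_classification(self, r, a, expected):
        assert is_transition(r, a) is expected

    @pytest.mark.parametrize("r,a", [("A", "A"), ("N", "G"), ("A", "x")])
    def test_invalid_inputs_raise(self, r, a):
        with pytest.raises(ValueError):
            is_transition(r, a)


class TestSummarizeSpectrum:
    def test_class_fractions_on_observed_composition(self):
        calls = (
            [_snv("A", "G", pos=i) for i in range(573)]
            + [_sized(VarClass.DEL, 2, pos=i) for i in range(372)]
            + [_sized(VarClass.INS, 1, pos=i) for i in range(36)]
            + [_sized(VarClass.RPL, 3, pos=i) for i in range(13)]
            + [_sized(VarClass.INV, 100, pos=i) for i in range(3)]
        )
        s = summarize_spectrum(calls)
        assert s.n_total == 997
        f = {k: round(100 * v, 1) for k, v in s.class_fractions.items()}
        assert f == {"SNV": 57.5, "DEL": 37.3, "INS": 3.6, "RPL": 1.3, "INV": 0.3}

    def test_single_transition(self):
        s = summarize_spectrum([_snv("A", "G")])
        assert (s.n_transitions, s.n_transversions) == (1, 0)

    def test_matrix_row_sums_equal_base_counts_on_random_calls(self):
        rng = np.random.default_rng(0)
        bases = "ACGT"
        calls = []
        for i in range(500):
            r = bases[rng.integers(4)]
            a = rng.choice([b for b in bases if b != r])
            calls.append(_snv(r, a, pos=i))
        s = summarize_spectrum(calls)
        for b in bases:
            assert s.substitution_matrix.loc[b].sum() == s.base_counts[b]
        assert s.n_transitions + s.n_transversions == s.n_snv
        assert sum(s.base_counts.values()) == s.n_snv
        assert int(s.substitution_matrix.values.sum()) == s.n_snv


class TestBasePreference:
    def test_observed_counts_give_gc_enrichment(self):
        calls = (
            [_snv("A", "G", pos=i) for i in range(96)]
            + [_snv("T", "C", pos=i) for i in range(115)]
            + [_snv("C", "T", pos=i) for i in range(176)]
            + [_snv("G", "A", pos=i) for i in range(186)]
        )
        s = summarize_spectrum(calls)
        out = base_preference(s, target_at_gc_ratio=1.07)
        assert out["ratio_mut"] == pytest.approx(362 / 211)
        assert round(out["ratio_mut"], 2) == pytest.approx(1.72, abs=0.005)
        assert round(out["enrichment"], 2) == 1.60

    def test_equal_counts_and_unit_target_ratio_give_unit_enrichment(self):
        calls = [_snv(b, "G" if b != "G" else "A", pos=i) for i, b in enumerate("ACGT" * 5)]
        out = base_preference(summarize_spectrum(calls), target_at_gc_ratio=1.0)
        assert out["enrichment"] == pytest.approx(1.0)

    def test_target_ratio_matches_composition_oracle(self, small_cohort):
        _, genome, _, targets, _, _ = small_cohort
        ratio = target_gc_at_ratio(genome, targets)
        at = gc = 0
        for r in targets:
            for b in genome.seq(r.chrom, r.start, r.end):
                if b in "GC":
                    gc += 1
                elif b in "AT":
                    at += 1
        assert ratio == pytest.approx(gc / at)

    def test_zero_at_count_reported_undefined(self):
        s = summarize_spectrum([_snv("G", "C", pos=i) for i in range(5)])
        assert base_preference(s, 1.0)["ratio_mut"] is None


class TestSizeHistogram:
    def test_deletion_and_insertion_size_fractions(self):
        dels = (
            [_sized(VarClass.DEL, 1, pos=i) for i in range(124)]
            + [_sized(VarClass.DEL, 2 + (i % 9), pos=i) for i in range(199)]
            + [_sized(VarClass.DEL, 50, pos=i) for i in range(49)]
        )
        df = size_histogram(dels, VarClass.DEL, bins=[(1, 1), (2, 10), (11, 10**9)])
        assert df["count"].tolist() == [124, 199, 49]
        assert round(100 * df["fraction"][0], 1) == 33.3
        assert round(100 * df["fraction"][1], 1) == 53.5
        ins = [_sized(VarClass.INS, 1, pos=i) for i in range(23)] + [
            _sized(VarClass.INS, 5, pos=i) for i in range(13)
        ]
        df2 = size_histogram(ins, VarClass.INS, bins=[(1, 1), (2, 11)])
        assert round(100 * df2["fraction"][0], 1) == 63.9

    def test_empty_class_is_empty(self):
        assert size_histogram([], VarClass.INS).empty


class TestGaussianFit:
    def test_mle_closed_form(self):
        fit = gaussian_fit([8, 9, 10], method="mle")
        assert fit.mu == pytest.approx(9.0)
        assert fit.sigma == pytest.approx(np.sqrt(2 / 3))

    @given(st.lists(st.integers(0, 30), min_size=2, max_size=60))
    @settings(max_examples=60, deadline=None)
    def test_mle_matches_moments_on_any_input(self, counts):
        x = np.array(counts, dtype=float)
        if x.std() == 0:
            with pytest.raises(ValueError):
                gaussian_fit(counts, method="mle")
            return
        fit = gaussian_fit(counts, method="mle")
        assert fit.mu == pytest.approx(x.mean())
        assert fit.sigma == pytest.approx(np.sqrt(((x - x.mean()) ** 2).mean()))

    def test_parameter_recovery_within_three_se(self):
        """Counts drawn per the per-line model recover mu within 3 SE."""
        rng = np.random.default_rng(42)
        mu_true, sigma_true, n = 8.66, 4.37, 110
        counts = np.maximum(np.round(rng.normal(mu_true, sigma_true, size=n)), 0)
        fit = gaussian_fit(counts, method="mle")
        se = sigma_true / np.sqrt(n)
        # truncation at zero biases the mean slightly upward; 3 SE absorbs it
        assert abs(fit.mu - mu_true) < 3 * se

    def test_histogram_ls_recovers_simulated_peak(self):
        rng = np.random.default_rng(1)
        counts = np.round(rng.normal(9, 4, size=400)).astype(int)
        fit = gaussian_fit(counts, method="histogram_ls")
        assert fit.mu == pytest.approx(9, abs=1.0)

    def test_degenerate_and_short_inputs_raise(self):
        with pytest.raises(ValueError):
            gaussian_fit([5, 5, 5], method="mle")
        with pytest.raises(ValueError):
            gaussian_fit([5], method="mle")


class TestRates:
    @pytest.mark.parametrize(
        "mean,dose,expected_e2",
        [(9.06, 150, 6.04), (2.75, 15, 18.33), (2.80, 75, 3.73), (4.44, 100, 4.44),
         (10.33, 175, 5.90), (11.75, 200, 5.88)],
    )
    def test_per_gy_rates(self, mean, dose, expected_e2):
        out = per_gy_rate(mean, dose)
        assert round(100 * out["rate_per_gy"], 2) == pytest.approx(expected_e2, abs=0.005)

    def test_identity_dose_and_errors(self):
        assert per_gy_rate(3.3, 1)["rate_per_gy"] == 3.3
        with pytest.raises(ValueError):
            per_gy_rate(1.0, 0)

    @given(st.floats(0.1, 50), st.floats(1, 300), st.floats(0.5, 4))
    @settings(max_examples=50, deadline=None)
    def test_linearity_in_mean(self, mean, dose, k):
        a = per_gy_rate(mean, dose)["rate_per_gy"]
        b = per_gy_rate(k * mean, dose)["rate_per_gy"]
        assert b == pytest.approx(k * a)

    @pytest.mark.parametrize(
        "count,expected",
        [(9.06, 99.3), (2.80, 30.7), (4.44, 48.7), (10.33, 113.2), (11.75, 128.8), (2.75, 30.1)],
    )
    def test_genome_extrapolation(self, count, expected):
        # one printed decimal, occasionally truncated: one ulp tolerance
        assert extrapolate_genome(count) == pytest.approx(expected, abs=0.1)

    def test_extrapolation_identity_and_errors(self):
        assert extrapolate_genome(7.0, 100, 100) == 7.0
        with pytest.raises(ValueError):
            extrapolate_genome(1.0, 0, 100)


class TestChromFrequency:
    def test_ratio_between_extreme_chromosomes(self):
        # 1 Mb of targets on each of two chromosomes, 100 lines:
        # counts 77 and 120 give frequencies 0.77 and 1.20 per Mb per line
        targets = TargetSet(
            [TargetRegion("chr07", 0, 1_000_000, "a"), TargetRegion("chr11", 0, 1_000_000, "b")]
        )
        calls = [_snv("A", "G", chrom="chr07", pos=i) for i in range(77)] + [
            _snv("A", "G", chrom="chr11", pos=i) for i in range(120)
        ]
        df, ratio = chrom_frequency(calls, targets, n_lines=100)
        assert df.set_index("chrom")["frequency"].round(2).to_dict() == {
            "chr07": 0.77,
            "chr11": 1.20,
        }
        assert round(ratio, 2) == 1.56

    def test_total_count_conserved(self, small_cohort, small_cohort_filtered):
        _, _, _, targets, _, _ = small_cohort
        per_line, _ = small_cohort_filtered
        calls = [v for cs in per_line.values() for v in cs]
        df, _ = chrom_frequency(calls, targets, n_lines=len(per_line))
        assert df["count"].sum() == len(calls)

    def test_zero_target_chromosome_excluded_from_ratio(self):
        targets = TargetSet([TargetRegion("c1", 0, 1_000_000, "a")])
        calls = [_snv("A", "G", chrom="c1")] + [_snv("A", "G", chrom="c2")]
        df, ratio = chrom_frequency(calls, targets, n_lines=10)
        assert df.loc[df["chrom"] == "c2", "frequency"].isna().all()
        assert ratio == pytest.approx(1.0)

    def test_invalid_line_count_raises(self):
        with pytest.raises(ValueError):
            chrom_frequency([], TargetSet([]), 0)


class TestCdmRate:
    @pytest.mark.parametrize(
        "counts,n,expected",
        [
            ({"albino": 10, "pale_green": 7, "yellow": 3, "virescent": 2, "stripe": 2}, 243, 9.9),
            ({"albino": 15, "pale_green": 8, "yellow": 2, "virescent": 4, "stripe": 6}, 225, 15.6),
            ({"albino": 3, "pale_green": 3, "yellow": 0, "virescent": 0, "stripe": 0}, 95, 6.3),
            ({"albino": 1, "pale_green": 1, "yellow": 0, "virescent": 0, "stripe": 0}, 97, 2.1),
            ({"albino": 4, "pale_green": 3, "yellow": 0, "virescent": 1, "stripe": 0}, 97, 8.3),
            ({"albino": 6, "pale_green": 2, "yellow": 4, "virescent": 0, "stripe": 3}, 226, 6.6),
        ],
    )
    def test_rates_from_cdm_class_counts(self, counts, n, expected):
        # one reported rate (200 Gy) is 0.05 above its own class counts
        # (8/97 = 8.25): compare within one unit in the last digit
        phen = CohortPhenotype("dry", 150, 30, n, counts)
        assert cdm_mutation_rate(phen) == pytest.approx(expected, abs=0.1)

    def test_all_zero_and_empty_cohort(self):
        assert cdm_mutation_rate(CohortPhenotype("dry", 0, 30, 98, {"albino": 0})) == 0.0
        with pytest.raises(ValueError):
            cdm_mutation_rate(CohortPhenotype("dry", 0, 30, 0, {}))

    def test_class_count_exceeding_lines_rejected(self):
        with pytest.raises(ValueError):
            CohortPhenotype("dry", 150, 30, 5, {"albino": 6})


class TestDoseResponse:
    def test_per_gy_maximum_at_optimum_dose(self):
        groups = []
        for dose, mean in [(75, 2.80), (100, 4.44), (150, 9.06), (175, 10.33), (200, 11.75)]:
            # constant-count lines at exactly the observed group means
            groups.append(DoseGroup(dose, 30.0, "dry", [mean] * 10))
        df = dose_response_table(groups)
        best = df.loc[df["max_per_gy"], "dose_gy"]
        assert best.tolist() == [150.0]

    def test_single_group_trivially_maximal(self):
        df = dose_response_table([DoseGroup(15, 50.0, "imbibed", [2, 3, 3])])
        assert df["max_per_gy"].all()

    def test_table_matches_hand_computed_oracle(self):
        counts = [4, 6, 8, 10]
        g = DoseGroup(100.0, 30.0, "dry", counts)
        df = dose_response_table([g])
        x = np.array(counts, float)
        assert df["mean_count"].iloc[0] == pytest.approx(x.mean())
        assert df["se_count"].iloc[0] == pytest.approx(x.std(ddof=1) / 2)
        assert df["rate_per_gy"].iloc[0] == pytest.approx(x.mean() / 100)
        assert df["genome_extrapolated"].iloc[0] == pytest.approx(
            x.mean() * 373245519 / 34040553
        )
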