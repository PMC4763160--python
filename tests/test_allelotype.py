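"""Allelotyping pipeline: ratios, Tukey filtering, baseline, tests, report."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from asekit import (
    AllelotypeConfig,
    BaselineEstimate,
    SimulationConfig,
    compute_ratios,
    diff_of_means,
    estimate_baseline,
    fold_change,
    render_allelotype_report,
    run_allelotype,
    simulate_cohort,
    test_sample,
    tukey_filter,
)
from asekit.allelotype import PeakTableError, baseline_sidecar
from asekit.datasets import GDNA_BASELINE_AT_G


def peaks_frame(rows):
    return pd.DataFrame(
        rows, columns=["sample_id", "template", "replicate", "area_AT", "area_G", "sex"]
    )


class TestComputeRatios:
    def test_simple_ratio_and_identity(self):
        peaks = peaks_frame(
            [
                ("s1", "gDNA", 1, 2.0, 1.0, "male"),
                ("s1", "gDNA", 2, 3.5, 3.5, "male"),
            ]
        )
        out = compute_ratios(peaks, numerator="AT")
        assert out["ratio"].tolist() == [2.0, 1.0]
        assert out["included"].all()

    def test_numerator_swap_is_per_record_reciprocal(self, study_cohort):
        peaks, _ = study_cohort
        at = compute_ratios(peaks, numerator="AT")["ratio"].to_numpy()
        g = compute_ratios(peaks, numerator="G")["ratio"].to_numpy()
        assert np.allclose(at * g, 1.0, rtol=1e-12)

    def test_nonpositive_area_identifies_record(self):
        peaks = peaks_frame(
            [
                ("s1", "gDNA", 1, 2.0, 1.0, "male"),
                ("s9", "cDNA", 3, 0.0, 1.0, "male"),
            ]
        )
        with pytest.raises(PeakTableError, match="s9 cDNA replicate 3"):
            compute_ratios(peaks)


class TestTukeyFilter:
    def test_excludes_far_outlier(self):
        # Q1=2, Q3=4 by linear interpolation; fences [-1, 7]
        included, excluded = tukey_filter([1, 2, 3, 4, 100])
        assert included == [1, 2, 3, 4]
        assert excluded == [100]

    def test_constant_values_all_kept(self):
        included, excluded = tukey_filter([5.0] * 6)
        assert included == [5.0] * 6 and excluded == []

    def test_survivors_lie_within_original_fences(self, rng):
        for _ in range(50):
            values = rng.lognormal(0, 1, size=rng.integers(4, 30))
            included, excluded = tukey_filter(values)
            q1, q3 = np.percentile(values, [25, 75])
            lo, hi = q1 - 1.5 * (q3 - q1), q3 + 1.5 * (q3 - q1)
            assert all(lo <= v <= hi for v in included)
            assert all(v < lo or v > hi for v in excluded)
            assert len(included) + len(excluded) == len(values)

    def test_order_preserved(self):
        included, _ = tukey_filter([3, 1, 4, 2, 3.5])
        assert included == [3, 1, 4, 2, 3.5]

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            tukey_filter([1, 2, 3])


class TestEstimateBaseline:
    def test_noise_free_cohort_recovers_bias_exactly(self):
        config = SimulationConfig(
            n_samples=5,
            replicate_cv=0.0,
            outlier_prob=0.0,
            ase_effect_sd_log=0.0,
            bias_b=1.78,
        )
        peaks, _ = simulate_cohort(config)
        ratios = compute_ratios(peaks)
        gdna = ratios.loc[ratios["template"] == "gDNA", "ratio"]
        est = estimate_baseline(gdna)
        # ulp-level division noise may trip the zero-IQR fences, but every
        # value is 1.78 to machine precision so the mean is unaffected
        assert est.mean_ratio == pytest.approx(1.78, rel=1e-12)

    def test_noisy_cohort_close_to_bias(self, study_cohort):
        peaks, _ = study_cohort
        ratios = compute_ratios(peaks)
        est = estimate_baseline(ratios.loc[ratios["template"] == "gDNA", "ratio"])
        assert abs(est.mean_ratio - 1.78) < 0.02
        assert est.n_used + est.n_excluded == 35 * 8

    def test_filtering_is_pooled_once(self):
        values = [1.8] * 20 + [9.0]
        est = estimate_baseline(values)
        assert est.n_excluded == 1
        assert est.mean_ratio == pytest.approx(1.8)


class TestTestSample:
    BASELINE = BaselineEstimate(mean_ratio=1.8, n_used=100, n_excluded=0, sd=0.1)

    def test_symmetric_sample_is_null(self):
        s = test_sample([1.6, 1.8, 2.0], self.BASELINE, "s1")
        assert s.diff_of_means == pytest.approx(0.0)
        assert s.p_value == pytest.approx(1.0)
        assert s.fold_change == pytest.approx(1.0)
        assert s.overexpressed_allele == "none"
        assert s.ci_lower == pytest.approx(-s.ci_upper)

    @pytest.mark.parametrize(
        "mean_cdna, want_diff, want_fold",
        [(2.7290, 0.9447, 1.5295), (0.6981, -1.0862, 0.3912), (2.0702, 0.2859, 1.1602)],
    )
    def test_published_row_arithmetic(self, mean_cdna, want_diff, want_fold):
        """Fold change and diff of means reproduce published summary rows."""
        assert fold_change(mean_cdna, GDNA_BASELINE_AT_G) == pytest.approx(
            want_fold, abs=5e-4
        )
        assert diff_of_means(mean_cdna, GDNA_BASELINE_AT_G) == pytest.approx(
            want_diff, abs=5e-4
        )

    def test_strong_low_ratio_called_for_denominator_allele(self):
        baseline = BaselineEstimate(GDNA_BASELINE_AT_G, 295, 9, sd=0.1)
        values = 0.6981 + np.array([-0.02, -0.01, 0.0, 0.0, 0.01, 0.02])
        s = test_sample(values, baseline, "s_low")
        assert s.p_value < 0.05
        assert s.overexpressed_allele == "G"
        assert s.fold_change == pytest.approx(0.3912, abs=5e-4)

    def test_outlying_replicate_filtered_before_test(self):
        values = [1.9, 2.0, 2.1, 2.0, 1.95, 2.05, 2.0, 8.0]
        s = test_sample(values, self.BASELINE, "s1")
        assert s.N == 8 and s.n == 7
        assert s.mean_cdna_ratio == pytest.approx(np.mean(values[:-1]))

    def test_tiny_sample_flagged_untestable(self):
        s = test_sample([1.9, 2.0], self.BASELINE, "s1")
        assert not s.testable
        assert math.isnan(s.p_value)
        assert s.overexpressed_allele == "none"
        assert s.fold_change == pytest.approx(1.95 / 1.8)

    def test_ci_is_t_quantile_times_se(self):
        values = np.array([1.9, 2.0, 2.2, 2.1, 1.8])
        s = test_sample(values, self.BASELINE, "s1", prefiltered=True)
        se = values.std(ddof=1) / np.sqrt(5)
        assert s.ci_half_width == pytest.approx(stats.t.ppf(0.975, 4) * se, abs=1e-12)
        assert (s.ci_lower, s.ci_upper) == (
            pytest.approx(s.diff_of_means - s.ci_half_width),
            pytest.approx(s.diff_of_means + s.ci_half_width),
        )


class TestRunAllelotype:
    def test_replicate_accounting_invariants(self, study_cohort):
        peaks, _ = study_cohort
        res = run_allelotype(peaks)
        strata = {c.stratum: c for c in res.strata}
        pop = strata["population"]
        assert pop.N == 35 * 8
        assert pop.n == sum(s.n for s in res.samples)
        clean = [s for s in res.samples if s.n == s.N]
        assert strata["population_edited"].N == 8 * len(clean)
        assert strata["population_edited"].N == strata["population_edited"].n
        assert strata["male"].n_samples + strata["female"].n_samples == 35
        assert strata["male"].N + strata["female"].N == pop.N

    def test_true_effects_recovered_per_sample(self, clean_cohort):
        peaks, truth = clean_cohort
        res = run_allelotype(peaks)
        effects = truth.set_index("sample_id")["true_ase_effect"]
        for s in res.samples:
            assert s.fold_change == pytest.approx(effects[s.sample_id], abs=0.12)

    def test_two_identical_samples_match_population_row(self):
        rows = []
        gvals = [1.7, 1.75, 1.8, 1.85, 1.9, 1.78, 1.82, 1.76]
        cvals = [2.0, 2.1, 2.05, 1.95, 2.02, 2.08, 1.98, 2.04]
        for sid in ("s1", "s2"):
            for i, v in enumerate(gvals, 1):
                rows.append((sid, "gDNA", i, v, 1.0, "male"))
            for i, v in enumerate(cvals, 1):
                rows.append((sid, "cDNA", i, v, 1.0, "male"))
        res = run_allelotype(peaks_frame(rows))
        pop = {c.stratum: c for c in res.strata}["population"]
        assert pop.mean_cdna_ratio == pytest.approx(np.mean(cvals))
        assert pop.fold_change == pytest.approx(res.samples[0].fold_change)
        assert pop.n == 16

    def test_small_sex_stratum_omitted_with_warning(self):
        rows = []
        for sid, sex in (("s1", "male"), ("s2", "male"), ("s3", "female")):
            for i in range(1, 9):
                rows.append((sid, "gDNA", i, 1.8 + 0.01 * i, 1.0, sex))
                rows.append((sid, "cDNA", i, 2.0 + 0.01 * i, 1.0, sex))
        with pytest.warns(UserWarning, match="female"):
            res = run_allelotype(peaks_frame(rows))
        names = {c.stratum for c in res.strata}
        assert "female" not in names and "male" in names

    def test_pairing_and_pooling_modes_agree_on_point_estimates(self, study_cohort):
        peaks, _ = study_cohort
        default = run_allelotype(peaks)
        paired = run_allelotype(peaks, AllelotypeConfig(pairing_mode="replicate_paired"))
        by_means = run_allelotype(peaks, AllelotypeConfig(pooling_mode="sample_means"))
        for a, b in zip(default.samples, paired.samples):
            assert a.sample_id == b.sample_id
            assert b.fold_change == pytest.approx(a.fold_change)
            assert np.isfinite(b.p_value)
        pop_a = {c.stratum: c for c in default.strata}["population"]
        pop_m = {c.stratum: c for c in by_means.strata}["population"]
        assert pop_m.fold_change == pytest.approx(pop_a.fold_change, rel=0.05)

    def test_bonferroni_only_removes_calls(self, study_cohort):
        peaks, _ = study_cohort
        plain = run_allelotype(peaks)
        strict = run_allelotype(peaks, AllelotypeConfig(bonferroni=True))
        called = {s.sample_id for s in plain.samples if s.overexpressed_allele != "none"}
        called_strict = {
            s.sample_id for s in strict.samples if s.overexpressed_allele != "none"
        }
        assert called_strict <= called

    def test_baseline_error_mode_widens_intervals(self, study_cohort):
        peaks, _ = study_cohort
        narrow = run_allelotype(peaks)
        wide = run_allelotype(peaks, AllelotypeConfig(include_baseline_error=True))
        for a, b in zip(narrow.strata, wide.strata):
            assert b.ci_half_width > a.ci_half_width

    def test_null_ci_coverage_matches_method_calibration(self):
        """The constant-baseline CI under-covers by construction (its SE
        ignores baseline sampling error, which here equals the cDNA SE, so
        true coverage is ~P(|Z| < 1.96/sqrt(2)) ~ 0.83); the Welch-style
        baseline-error mode restores ~0.95 coverage.  Both are checked
        against their own calibration."""
        cover_const = cover_welch = 0
        n_seeds = 100
        for seed in range(n_seeds):
            config = SimulationConfig(
                ase_effect_median=1.0, ase_effect_sd_log=0.0, seed=30_000 + seed
            )
            peaks, _ = simulate_cohort(config)
            pop = {
                c.stratum: c for c in run_allelotype(peaks).strata
            }["population"]
            cover_const += pop.ci_lower <= 0 <= pop.ci_upper
            pop_w = {
                c.stratum: c
                for c in run_allelotype(
                    peaks, AllelotypeConfig(include_baseline_error=True)
                ).strata
            }["population"]
            cover_welch += pop_w.ci_lower <= 0 <= pop_w.ci_upper
        assert 70 <= cover_const <= 92
        assert cover_welch >= 88


class TestReport:
    def test_empty_report_is_header_only(self, tmp_path):
        path = tmp_path / "report.tsv"
        report = render_allelotype_report([], [], path)
        assert report.empty
        assert path.read_text().strip().split("\t")[0] == "Sample"

    def test_report_rows_and_roundtrip(self, study_cohort, tmp_path):
        peaks, _ = study_cohort
        res = run_allelotype(peaks)
        path = tmp_path / "report.tsv"
        report = render_allelotype_report(res.samples, res.strata, path)
        assert len(report) == 35 + 6
        back = pd.read_csv(path, sep="\t")
        for col in ("MeanCDNA", "DiffOfMeans", "FoldChange", "Lower", "Upper"):
            assert np.allclose(back[col], report[col].astype(float), atol=1e-9)
        assert np.allclose(
            back["FoldChange"],
            [round(s.fold_change, 4) for s in res.samples]
            + [round(c.fold_change, 4) for c in res.strata],
        )

    def test_sidecar_contents(self, study_cohort):
        peaks, _ = study_cohort
        res = run_allelotype(peaks)
        side = baseline_sidecar(res)
        assert side["baseline"]["n_used"] == res.baseline.n_used
        assert set(side["strata"]) == {c.stratum for c in res.strata}


def test_invalid_config_rejected():
    with pytest.raises(ValueError, match="pairing_mode"):
        AllelotypeConfig(pairing_mode="nope").validate()
    with pytest.raises(ValueError, match="alpha"):
        AllelotypeConfig(alpha=1.5).validate()
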