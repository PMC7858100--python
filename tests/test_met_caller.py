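import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metskip.met_caller import (
    CutoffStats,
    DetectabilityRule,
    call_skipping,
    categorize_expression,
    compare_groups,
    dex14_log_ratio,
    distribution_diagnostics,
    estimate_cutoff,
)
from metskip.qc_normalize import normalize_two_step


def brute_force_mean_sd(values):
    """Independent two-pass mean / sample-SD oracle."""
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var)


class TestEstimateCutoff:
    def test_zero_variance_is_degenerate(self):
        cs = estimate_cutoff([1, 1, 1], k=2)
        assert (cs.mean, cs.sd, cs.cutoff, cs.degenerate) == (1, 0, 1, True)

    def test_two_point_hand_arithmetic(self):
        cs = estimate_cutoff([0, 2], k=2)
        assert cs.mean == pytest.approx(1)
        assert cs.sd == pytest.approx(math.sqrt(2))
        assert cs.cutoff == pytest.approx(1 + 2 * math.sqrt(2))

    def test_seeded_standard_normal_cutoff_range(self):
        x = np.random.default_rng(42).normal(size=100)
        cs = estimate_cutoff(x, k=2)
        m, s = brute_force_mean_sd(list(x))
        assert cs.cutoff == pytest.approx(m + 2 * s, abs=1e-12)
        assert 1.5 < cs.cutoff < 2.5

    def test_fewer_than_two_values_rejected(self):
        with pytest.raises(ValueError, match=">=2"):
            estimate_cutoff([1.0], k=2)

    @settings(deadline=None, max_examples=200)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=50),
           st.floats(0, 5))
    def test_matches_brute_force_to_1e12(self, values, k):
        cs = estimate_cutoff(values, k)
        m, s = brute_force_mean_sd(values)
        scale = max(1.0, abs(m), s)
        assert abs(cs.mean - m) <= 1e-12 * scale
        assert abs(cs.sd - s) <= 1e-9 * scale
        assert abs(cs.cutoff - (m + k * s)) <= 1e-9 * scale


def norm_from_ratios(make_uniform_matrix, codeset5, wt, d14):
    m = make_uniform_matrix(wt, d14)
    return normalize_two_step(m, codeset5)


class TestLogRatio:
    def test_equal_isoform_counts_give_zero(self, make_uniform_matrix, codeset5):
        norm = norm_from_ratios(make_uniform_matrix, codeset5, [500], [500])
        assert dex14_log_ratio(norm).iloc[0] == pytest.approx(0.0)

    def test_exact_power_of_two(self, make_uniform_matrix, codeset5):
        norm = norm_from_ratios(make_uniform_matrix, codeset5, [400], [25])
        assert dex14_log_ratio(norm).iloc[0] == pytest.approx(-4.0)

    def test_zero_junction_count_is_undefined_and_negative(self, make_uniform_matrix, codeset5):
        norm = norm_from_ratios(make_uniform_matrix, codeset5, [400, 400, 400], [0, 100, 120])
        lr = dex14_log_ratio(norm)
        assert np.isnan(lr.iloc[0]) and not np.isnan(lr.iloc[1])
        calls, cut, _ = call_skipping(norm)
        assert calls.iloc[0] == "negative"
        assert cut.n == 2  # only detectable samples enter the cutoff cohort

    def test_zero_wildtype_in_passing_sample_raises(self, make_uniform_matrix, codeset5):
        norm = norm_from_ratios(make_uniform_matrix, codeset5, [0, 400], [10, 10])
        with pytest.raises(ValueError, match="zero MET wild-type"):
            dex14_log_ratio(norm)

    def test_equals_log_ratio_of_raw_counts(self, sim_codeset, cohort7):
        """Within-sample factor cancellation: raw and normalized ratios agree."""
        matrix, _ = cohort7
        norm = normalize_two_step(matrix, sim_codeset)
        lr = dex14_log_ratio(norm)
        raw = norm.raw
        detected = raw["MET_dex14"] > 0
        expected = np.log2(raw.loc[detected, "MET_dex14"] / raw.loc[detected, "MET_wt"])
        assert np.allclose(lr[detected], expected, rtol=1e-12)
        assert lr[~detected].isna().all()


class TestCallSkipping:
    def test_bimodal_cohort_recovers_exactly_the_shifted_samples(
        self, make_uniform_matrix, codeset5
    ):
        rng = np.random.default_rng(5)
        ratios = np.concatenate([rng.normal(-3, 0.2, 97), rng.normal(0, 0.1, 3)])
        wt = [4096] * 100
        d14 = np.round(4096 * np.power(2.0, ratios)).astype(int)
        norm = norm_from_ratios(make_uniform_matrix, codeset5, wt, list(d14))
        calls, cut, lr = call_skipping(norm)
        # independent recomputation of mean + 2 SD on the realized log-ratios
        m, s = brute_force_mean_sd(list(lr))
        expected_pos = set(lr.index[lr > m + 2 * s])
        assert set(calls.index[calls == "positive"]) == expected_pos
        assert expected_pos == set(lr.index[-3:])  # exactly the 3 shifted samples

    def test_all_zero_junction_counts_means_all_negative_no_cutoff(
        self, make_uniform_matrix, codeset5
    ):
        norm = norm_from_ratios(make_uniform_matrix, codeset5, [400] * 5, [0] * 5)
        calls, cut, _ = call_skipping(norm)
        assert (calls == "negative").all() and cut is None

    def test_monotonicity_under_frozen_cutoff(self, make_uniform_matrix, codeset5):
        """Raising one sample's junction count never flips positive -> negative."""
        norm = norm_from_ratios(make_uniform_matrix, codeset5, [400] * 6,
                                [5, 10, 40, 80, 200, 400])
        _, cut, _ = call_skipping(norm)
        frozen = cut
        previous_positive = False
        for d in [5, 20, 100, 300, 400, 800]:
            norm2 = norm_from_ratios(make_uniform_matrix, codeset5, [400] * 6,
                                     [d, 10, 40, 80, 200, 400])
            calls, _, _ = call_skipping(norm2, frozen=frozen)
            is_pos = calls.iloc[0] == "positive"
            assert is_pos or not previous_positive
            previous_positive = previous_positive or is_pos

    def test_background_detectability_mode(self, codeset5, make_uniform_matrix):
        # junction count 5 is below the negative-control background, 100 above
        m = make_uniform_matrix([400, 400], [5, 100])
        m.counts.loc[:, "NEG_A"] = [20, 20]
        norm = normalize_two_step(m, codeset5)
        lr = dex14_log_ratio(norm, rule=DetectabilityRule("background"))
        assert np.isnan(lr.iloc[0]) and not np.isnan(lr.iloc[1])


class TestCategorizeExpression:
    def test_constant_cohort_is_degenerate_all_normal(self, make_uniform_matrix, codeset5):
        norm = norm_from_ratios(make_uniform_matrix, codeset5, [400] * 4, [10] * 4)
        tiers, cut_mod, cut_high, _ = categorize_expression(norm)
        assert (tiers == "normal").all()
        assert cut_high.degenerate

    def test_three_component_mixture_recovers_very_high(self, make_uniform_matrix, codeset5):
        rng = np.random.default_rng(9)
        logs = np.concatenate([
            rng.normal(0, 1, 380), rng.normal(1.6, 0.1, 36), rng.normal(4.5, 0.2, 15)
        ])
        wt = np.round(1000 * np.power(2.0, logs)).astype(int)
        norm = norm_from_ratios(make_uniform_matrix, codeset5, list(wt), [10] * 431)
        tiers, cut_mod, cut_high, log_met = categorize_expression(norm)
        m, s = brute_force_mean_sd(list(log_met))
        assert cut_high.cutoff == pytest.approx(m + 2 * s, rel=1e-12)
        expected_vh = set(log_met.index[log_met >= m + 2 * s])
        assert set(tiers.index[tiers == "very_high"]) == expected_vh
        assert len(expected_vh) == 15

    def test_boundary_convention_is_inclusive(self, make_uniform_matrix, codeset5):
        """log-MET exactly at a cutoff falls in the upper tier (>=)."""
        norm = norm_from_ratios(make_uniform_matrix, codeset5, [1024, 2048, 4096], [10] * 3)
        frozen = (
            CutoffStats(mean=10, sd=1, k=1, cutoff=11.0, n=3),
            CutoffStats(mean=10, sd=1, k=2, cutoff=12.0, n=3),
        )
        tiers, *_ = categorize_expression(norm, frozen=frozen)
        assert tiers.tolist() == ["normal", "mod_elevated", "very_high"]


class TestDistributionDiagnostics:
    def test_single_gaussian_is_unimodal(self):
        x = np.random.default_rng(3).normal(size=500)
        assert distribution_diagnostics(x).verdict == "unimodal"

    def test_two_well_separated_modes_are_bimodal_with_boundary(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(-3, 0.2, 97), rng.normal(0, 0.1, 3)])
        rep = distribution_diagnostics(x)
        assert rep.verdict == "bimodal"
        assert -2 < rep.mixture.boundary < -0.6

    def test_constant_vector_is_degenerate(self):
        assert distribution_diagnostics(np.ones(20)).verdict == "degenerate"

    def test_mixture_fit_is_deterministic(self):
        x = np.random.default_rng(8).normal(size=200)
        r1, r2 = distribution_diagnostics(x), distribution_diagnostics(x)
        assert r1.mixture.loglik == r2.mixture.loglik
        assert r1.mixture.means == r2.mixture.means


def permutation_pvalue(a, b, n_perm=10_000, seed=0):
    """Two-sided permutation oracle on the difference of means."""
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    obs = abs(a.mean() - b.mean())
    count = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        if abs(pooled[: len(a)].mean() - pooled[len(a):].mean()) >= obs:
            count += 1
    return (count + 1) / (n_perm + 1)


class TestCompareGroups:
    def test_identical_groups_are_not_significant(self):
        rng = np.random.default_rng(21)
        vals = pd.Series(np.concatenate([rng.normal(0, 1, 20), rng.normal(0, 1, 20)]))
        labels = pd.Series(["none"] * 20 + ["g"] * 20)
        out = compare_groups(vals, labels)
        assert out.loc[0, "p_value"] > 0.1  # no shift; p concentrated near 1

    def test_three_sd_shift_is_significant_and_matches_permutation_oracle(self):
        rng = np.random.default_rng(22)
        a = rng.normal(0, 1, 20)
        b = rng.normal(3, 1, 20)
        vals = pd.Series(np.concatenate([a, b]))
        labels = pd.Series(["none"] * 20 + ["shifted"] * 20)
        out = compare_groups(vals, labels)
        assert out.loc[0, "p_value"] < 0.01
        assert permutation_pvalue(a, b, seed=22) < 0.01

    def test_small_group_skipped_with_warning(self):
        vals = pd.Series(np.arange(12, dtype=float))
        labels = pd.Series(["none"] * 10 + ["tiny"] * 2)
        with pytest.warns(UserWarning, match="tiny"):
            out = compare_groups(vals, labels)
        assert len(out) == 0

    def test_amplified_stratum_has_elevated_expression(self, sim_codeset, cohort7):
        from metskip.pipeline import run_pipeline

        matrix, truth = cohort7
        res = run_pipeline(matrix, sim_codeset, diagnostics=False)
        log_met = res.calls["log_met"].dropna()
        drivers = matrix.sample_meta.loc[log_met.index, "driver"]
        out = compare_groups(log_met, drivers).set_index("group")
        assert out.loc["MET_amp", "p_value"] < 0.05
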