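"""Method-agreement statistics against brute-force and published oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from gaitdist.agreement import (
    DEFAULT_BIN_EDGES,
    PairedSeries,
    bin_errors,
    bland_altman,
    compute_report,
    icc_agreement,
    icc_label,
    kendall_tau_b,
    pearson_r,
    relative_error,
    two_sample_ttest,
    weighted_group_mean,
)


def _pairs(ref, est, ids=None):
    ref = np.asarray(ref, dtype=float)
    ids = ids if ids is not None else [f"s{i}" for i in range(len(ref))]
    return PairedSeries(ids=ids, reference_m=ref, estimate_m=np.asarray(est, float))


class TestBlandAltman:
    def test_identical_series_collapse_to_zero(self):
        ba = bland_altman(_pairs([100, 110, 120], [100, 110, 120]))
        assert ba == {"mean_diff": 0.0, "sd_diff": 0.0, "loa_low": 0.0, "loa_high": 0.0}

    def test_constant_offset(self):
        ba = bland_altman(_pairs([100, 110], [103, 113]), "ref_minus_est")
        assert ba["mean_diff"] == pytest.approx(-3.0)
        assert ba["sd_diff"] == pytest.approx(0.0)
        assert ba["loa_low"] == pytest.approx(-3.0)
        assert ba["loa_high"] == pytest.approx(-3.0)

    def test_hand_computed_toy(self):
        # diffs (2, -3, 1): mean 0, sample SD sqrt(14/2)
        ba = bland_altman(_pairs([100, 110, 120], [98, 113, 119]))
        assert ba["mean_diff"] == pytest.approx(0.0, abs=1e-12)
        assert ba["sd_diff"] == pytest.approx(np.sqrt(7.0))
        assert ba["loa_high"] == pytest.approx(1.96 * np.sqrt(7.0))
        assert ba["loa_low"] == pytest.approx(-1.96 * np.sqrt(7.0))

    @given(
        ref=st.lists(st.floats(50, 200), min_size=2, max_size=20),
        shift=st.floats(-30, 30),
        scale=st.floats(0.5, 1.5),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_loa_identity_holds_for_any_input(self, ref, shift, scale):
        est = [scale * r + shift for r in ref]
        ba = bland_altman(_pairs(ref, est))
        mid = (ba["loa_low"] + ba["loa_high"]) / 2
        half = (ba["loa_high"] - ba["loa_low"]) / 2
        assert mid == pytest.approx(ba["mean_diff"], abs=1e-9)
        assert half == pytest.approx(1.96 * ba["sd_diff"], abs=1e-9)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            _pairs([100], [99])


class TestPearson:
    def test_perfect_linear_relation(self):
        assert pearson_r(_pairs([1, 2, 3, 4], [3, 5, 7, 9])) == pytest.approx(1.0)

    def test_perfect_inverse_relation(self):
        assert pearson_r(_pairs([1, 2, 3, 4], [-1, -2, -3, -4])) == pytest.approx(-1.0)

    def test_matches_definitional_formula(self):
        ref = np.array([100.0, 120.0, 90.0, 150.0, 130.0])
        est = np.array([104.0, 115.0, 95.0, 148.0, 128.0])
        r = pearson_r(_pairs(ref, est))
        cov = np.mean((ref - ref.mean()) * (est - est.mean()))
        expected = cov / (ref.std() * est.std())
        assert r == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r(_pairs([5, 5, 5], [1, 2, 3]))

    def test_affine_invariance(self):
        ref = [100.0, 120.0, 90.0, 150.0]
        est = [104.0, 115.0, 95.0, 148.0]
        r1 = pearson_r(_pairs(ref, est))
        r2 = pearson_r(_pairs([3 * x + 7 for x in ref], est))
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestIcc:
    TOY_REF = np.array([100.0, 110.0, 120.0, 130.0, 140.0, 150.0])
    TOY_EST = np.array([98.0, 115.0, 118.0, 133.0, 139.0, 155.0])

    def test_identity_gives_one(self):
        res = icc_agreement(_pairs([100, 120, 140], [100, 120, 140]))
        assert res["icc"] == pytest.approx(1.0)
        assert res["label"] == "excellent"

    def test_degenerate_all_identical_defined_as_one(self):
        res = icc_agreement(_pairs([100, 100, 100], [100, 100, 100]))
        assert res == {"icc": 1.0, "label": "excellent"}

    def test_offset_penalised_relative_to_pearson(self):
        ref = [100.0, 110.0, 120.0, 130.0]
        est = [140.0, 150.0, 160.0, 170.0]
        res = icc_agreement(_pairs(ref, est))
        assert res["icc"] < pearson_r(_pairs(ref, est))

    def test_six_pair_toy_matches_longhand_anova(self):
        # frozen from the two-rater mean-squares decomposition by hand
        res = icc_agreement(_pairs(self.TOY_REF, self.TOY_EST))
        assert res["icc"] == pytest.approx(0.9849955869373345, abs=1e-12)
        assert res["label"] == "excellent"

    def test_matches_independent_implementation(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        n = len(self.TOY_REF)
        frame = pd.DataFrame(
            {
                "targets": list(range(n)) * 2,
                "raters": ["ref"] * n + ["est"] * n,
                "score": np.concatenate([self.TOY_REF, self.TOY_EST]),
            }
        )
        table = pg.intraclass_corr(
            frame, targets="targets", raters="raters", ratings="score"
        ).set_index("Type")
        ours = icc_agreement(_pairs(self.TOY_REF, self.TOY_EST))["icc"]
        label = "ICC(A,1)" if "ICC(A,1)" in table.index else "ICC2"
        assert ours == pytest.approx(table.loc[label, "ICC"], abs=1e-9)

    def test_never_exceeds_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            ref = rng.normal(140, 30, 8)
            est = ref + rng.normal(0, 10, 8)
            assert icc_agreement(_pairs(ref, est))["icc"] <= 1.0

    def test_equals_pearson_without_systematic_offset(self):
        # same means and variances: identical series give both exactly 1;
        # a large decorrelated sample agrees to O(1/n)
        ref = [100.0, 120.0, 140.0, 160.0]
        assert icc_agreement(_pairs(ref, ref))["icc"] == pytest.approx(
            pearson_r(_pairs(ref, ref)), abs=1e-9
        )
        rng = np.random.default_rng(1)
        x = rng.normal(140.0, 30.0, 4000)
        noise = rng.normal(0.0, 30.0, 4000)
        y = (x - x.mean()) * 0.6 + noise - noise.mean() * 0.0
        y = (y - y.mean()) / y.std(ddof=1) * x.std(ddof=1) + x.mean()
        p = _pairs(x, y)
        assert icc_agreement(p)["icc"] == pytest.approx(pearson_r(p), abs=5e-3)

    @pytest.mark.parametrize(
        "value,label",
        [(0.95, "excellent"), (0.90, "excellent"), (0.80, "good"), (0.75, "good"),
         (0.60, "moderate"), (0.50, "moderate"), (0.49, "poor"), (-0.2, "poor")],
    )
    def test_interpretation_bands(self, value, label):
        assert icc_label(value) == label


class TestRelativeError:
    def test_exact_estimate_is_zero(self):
        err = relative_error(_pairs([100, 150], [100, 150]), "signed")
        np.testing.assert_allclose(err, 0.0)

    def test_under_estimate_is_positive_ten_percent(self):
        err = relative_error(_pairs([100, 100], [90, 90]), "signed")
        np.testing.assert_allclose(err, 10.0)
        np.testing.assert_allclose(
            relative_error(_pairs([100, 100], [90, 90]), "absolute"), 10.0
        )

    def test_published_mean_pair_gives_minus_3_957(self):
        # over-estimation shows as a negative signed error
        err = relative_error(_pairs([143.52, 143.52], [149.20, 149.20]), "signed")
        assert err[0] == pytest.approx(-3.9576, abs=1e-4)

    def test_zero_reference_names_session(self):
        with pytest.raises(ValueError, match="s1"):
            relative_error(_pairs([100, 0], [90, 10]))


class TestBinErrors:
    def test_all_zero_fall_in_first_bin(self):
        table = bin_errors([0.0] * 8)
        assert table["counts"] == [8, 0, 0, 0]
        assert table["proportions"][0] == 1.0

    def test_published_first_bin_share(self):
        # 272 of 562 recordings below 5% -> 48.4% share
        errors = [2.0] * 272 + [7.0] * 145 + [25.0] * 145
        table = bin_errors(errors)
        assert table["n"] == 562
        assert table["counts"][0] == 272
        assert round(table["proportions"][0] * 100, 1) == 48.4

    def test_uniform_draws_match_analytic_masses(self):
        rng = np.random.default_rng(9)
        draws = rng.uniform(0.0, 40.0, 10_000)
        table = bin_errors(draws)
        masses = np.array([5, 5, 10, 20]) / 40.0
        se = np.sqrt(masses * (1 - masses) / 10_000)
        for p, m, s in zip(table["proportions"], masses, se):
            assert abs(p - m) < 3 * s

    @given(
        errors=st.lists(st.floats(0.0, 99.0), min_size=1, max_size=200)
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_counts_sum_to_n_proportions_to_one(self, errors):
        table = bin_errors(errors)
        assert sum(table["counts"]) == len(errors)
        assert sum(table["proportions"]) == pytest.approx(1.0, abs=1e-12)

    def test_half_open_bins(self):
        table = bin_errors([5.0, 4.9999, 10.0, 20.0])
        assert table["counts"] == [1, 1, 1, 1]

    def test_non_increasing_edges_rejected(self):
        with pytest.raises(ValueError):
            bin_errors([1.0], edges=(0.0, 5.0, 5.0))


def _tau_brute(x, y):
    """O(n^2) pair enumeration with tie corrections (test oracle)."""
    n = len(x)
    conc = disc = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                ties_x += 1
                ties_y += 1
            elif dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    denom = np.sqrt((n0 - ties_x) * (n0 - ties_y))
    return (conc - disc) / denom if denom else float("nan")


class TestKendallTauB:
    def test_strictly_increasing_gives_one(self):
        assert kendall_tau_b([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)

    def test_strictly_decreasing_gives_minus_one(self):
        assert kendall_tau_b([1, 2, 3, 4], [5, 4, 3, 2]) == pytest.approx(-1.0)

    def test_all_tied_variable_undefined(self):
        assert np.isnan(kendall_tau_b([1, 1, 1], [1, 2, 3]))

    @given(
        x=st.lists(st.integers(0, 5), min_size=4, max_size=12),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_exhaustive_pair_count_with_ties(self, x):
        rng = np.random.default_rng(sum(x) + len(x))
        y = rng.integers(0, 5, size=len(x)).tolist()
        if len(set(x)) < 2 or len(set(y)) < 2:
            return
        ours = kendall_tau_b(x, y)
        assert ours == pytest.approx(_tau_brute(x, y), abs=1e-12)

    def test_monotone_transform_invariance(self):
        x = [1.0, 4.0, 2.0, 8.0, 5.0]
        y = [2.0, 3.0, 1.0, 9.0, 7.0]
        t1 = kendall_tau_b(x, y)
        t2 = kendall_tau_b(np.exp(x), y)  # strictly monotone transform
        assert t1 == pytest.approx(t2, abs=1e-12)


class TestWelch:
    def test_identical_groups_give_t_zero_p_one(self):
        res = two_sample_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["t"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_huge_separation_gives_tiny_p(self):
        res = two_sample_ttest(
            [0.0, 0.1, -0.1, 0.05] * 5, [100.0, 100.1, 99.9, 100.05] * 5
        )
        assert res["p"] < 1e-6

    def test_toy_groups_match_longhand_welch(self):
        # groups (1,2,3) vs (2,3,4): t = -1/sqrt(2/3), df = 4 (hand-derived)
        res = two_sample_ttest([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert res["t"] == pytest.approx(-1.224744871391589, abs=1e-12)
        assert res["p"] == pytest.approx(
            2 * stats.t.sf(1.224744871391589, df=4), abs=1e-12
        )

    def test_pooled_variant_available(self):
        res = two_sample_ttest([1.0, 2.0, 3.0], [2.0, 3.0, 4.0], equal_var=True)
        assert res["t"] == pytest.approx(-1.224744871391589, abs=1e-12)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            two_sample_ttest([1.0], [2.0, 3.0])


class TestWeightedGroupMean:
    def test_single_group_returns_its_mean(self):
        assert weighted_group_mean([42.0], [17]) == 42.0

    def test_published_subgroups_reproduce_overall_reference_mean(self):
        # with-aids / without-aids subgroup means recombine to the overall mean
        assert weighted_group_mean([70.98, 148.34], [35, 527]) == pytest.approx(
            143.52, abs=0.005
        )

    def test_published_subgroups_reproduce_overall_estimator_mean(self):
        assert weighted_group_mean([85.42, 153.44], [35, 527]) == pytest.approx(
            149.20, abs=0.005
        )


class TestComputeReport:
    def test_report_is_internally_consistent(self):
        rng = np.random.default_rng(4)
        ref = rng.normal(140, 30, 24)
        est = ref + rng.normal(-3, 8, 24)
        report = compute_report(_pairs(ref, est))
        assert report.loa_high_m == pytest.approx(
            report.mean_diff_m + 1.96 * report.sd_diff_m, abs=1e-12
        )
        assert report.loa_low_m == pytest.approx(
            report.mean_diff_m - 1.96 * report.sd_diff_m, abs=1e-12
        )
        assert report.icc_label == icc_label(report.icc)
        assert sum(report.bin_table["counts"]) == report.n
        assert report.error_stats["mean_pct"] >= 0.0
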