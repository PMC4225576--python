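import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vitisnet.preprocess import (
    consistency_filter,
    differential_abundance,
    log_transform,
    normalize_internal_standard,
    normalize_total_intensity,
    pca_scores,
    trait_correlation,
)
from vitisnet.synthetic import generate, preset_paper_like

from conftest import profile_from_array, two_group_profile


class TestInternalStandardNormalization:
    def test_direct_division_and_standard_removed(self):
        pm = profile_from_array([[10, 2], [6, 3]], ["metA", "ribitol"])
        out = normalize_internal_standard(pm, "ribitol")
        assert out.metabolites == ["metA"]
        assert out.values["metA"].tolist() == [5.0, 2.0]

    def test_constant_standard_preserves_ratios(self):
        pm = profile_from_array([[10, 2], [30, 2]], ["metA", "std"])
        out = normalize_internal_standard(pm, "std")
        ratio = out.values["metA"].iloc[1] / out.values["metA"].iloc[0]
        assert ratio == pytest.approx(3.0)

    def test_water_content_double_division(self):
        # 3 samples x 2 metabolites, water contents (0.5, 1, 2): hand-computed
        pm = profile_from_array([[8, 4], [9, 3], [10, 2]], ["m1", "ribitol"])
        wc = pd.Series([0.5, 1.0, 2.0], index=pm.sample_ids)
        out = normalize_internal_standard(pm, "ribitol", water_content=wc)
        assert out.values["m1"].tolist() == [4.0, 3.0, 2.5]  # (8/4)/0.5 etc.

    def test_nonpositive_standard_names_samples(self):
        pm = profile_from_array([[10, 0], [6, 3]], ["metA", "std"])
        with pytest.raises(ValueError, match="s1"):
            normalize_internal_standard(pm, "std")


class TestTotalIntensityNormalization:
    def test_proportions_preserved_sum_10000(self):
        pm = profile_from_array([[1, 3]])
        out = normalize_total_intensity(pm)
        assert out.values.iloc[0].tolist() == [2500.0, 7500.0]

    def test_fixed_point(self):
        pm = profile_from_array([[4000, 6000]])
        out = normalize_total_intensity(pm)
        assert out.values.iloc[0].tolist() == [4000.0, 6000.0]

    def test_missing_entries_excluded_from_sum(self):
        pm = profile_from_array([[1, 3, np.nan]])
        out = normalize_total_intensity(pm)
        assert np.nansum(out.values.iloc[0]) == pytest.approx(10000.0)
        assert math.isnan(out.values.iloc[0, 2])

    def test_zero_sum_row_is_error(self):
        pm = profile_from_array([[0.0, 0.0]])
        with pytest.raises(ValueError, match="s1"):
            normalize_total_intensity(pm)


class TestLogTransform:
    def test_elementwise_log10_and_missing_preserved(self):
        pm = profile_from_array([[100, 1], [10, np.nan]])
        out = log_transform(pm)
        assert out.scale == "log10"
        assert out.values.iloc[0].tolist() == [2.0, 0.0]
        assert math.isnan(out.values.iloc[1, 1])

    def test_zero_gets_half_min_positive_offset(self):
        pm = profile_from_array([[100, 0], [1, 10]])
        out = log_transform(pm)
        assert out.values.iloc[0, 1] == pytest.approx(np.log10(0.5))

    def test_zero_policy_error(self):
        pm = profile_from_array([[1, 0]])
        with pytest.raises(ValueError, match="zero"):
            log_transform(pm, zero_policy="error")


class TestDifferentialAbundance:
    def test_toy_3v3_matches_textbook_t(self):
        """fc = mean(D)/mean(IR); t and p from the pooled-variance formula."""
        pm = two_group_profile([10, 11, 9], [20, 22, 18])
        res = differential_abundance(pm).iloc[0]
        assert res["fc"] == pytest.approx(2.0)
        assert res["log10_fc"] == pytest.approx(np.log10(2.0))
        # hand-computed pooled t: sp2 = (2*1 + 2*4)/4, se = sqrt(sp2*(2/3))
        sp2 = (2 * 1.0 + 2 * 4.0) / 4.0
        t_hand = (20.0 - 10.0) / math.sqrt(sp2 * (2.0 / 3.0))
        p_hand = 2 * stats.t.sf(abs(t_hand), 4)
        assert res["t_stat"] == pytest.approx(t_hand, abs=1e-10)
        assert res["p"] == pytest.approx(p_hand, abs=1e-12)

    def test_identical_groups_p_one_convention(self):
        pm = two_group_profile([5, 5, 5], [5, 5, 5])
        res = differential_abundance(pm).iloc[0]
        assert res["p"] == 1.0 and res["t_stat"] == 0.0

    def test_label_swap_inverts_fc_and_preserves_p(self):
        rng = np.random.default_rng(42)
        pm = two_group_profile(rng.lognormal(1, 0.3, 5), rng.lognormal(2, 0.3, 5))
        fwd = differential_abundance(pm).iloc[0]
        rev = differential_abundance(pm, deficit="IR", irrigated="D").iloc[0]
        assert rev["fc"] == pytest.approx(1.0 / fwd["fc"])
        assert rev["p"] == pytest.approx(fwd["p"], abs=1e-14)

    def test_bh_within_stratum(self):
        """q is BH-adjusted jointly over the metabolites of one stratum."""
        rng = np.random.default_rng(0)
        vals = rng.lognormal(3, 0.2, size=(12, 6))
        days = [18] * 12
        pm = profile_from_array(vals, days=days)
        pm.samples.loc[:, "treatment"] = ["IR"] * 6 + ["D"] * 6
        pm.samples.loc[:, "replicate"] = [1, 2, 3, 4, 5, 6] * 2
        pm.validate()
        res = differential_abundance(pm)
        p = res["p"].to_numpy()
        q = res["q"].to_numpy()
        # brute-force step-up over the stratum
        order = np.argsort(p)
        m = len(p)
        stepped = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        expect = np.empty(m)
        expect[order] = np.minimum(stepped, 1.0)
        np.testing.assert_allclose(q, expect, atol=1e-12)
        assert (q >= p - 1e-15).all()

    def test_null_generator_raw_significance_near_alpha(self):
        """Under no treatment effect and rho = 0, ~5% of raw p fall below 0.05."""
        spec = preset_paper_like(seed=7).null_variant()
        data = generate(spec, seed=7)
        res = differential_abundance(data.profile, days=[18, 26, 34])
        n_tests = len(res)
        hits = int(res["significant_raw"].sum())
        lo = stats.binom.ppf(0.005, n_tests, 0.05)
        hi = stats.binom.ppf(0.995, n_tests, 0.05)
        assert lo <= hits <= hi, f"{hits} of {n_tests} raw-significant"


class TestConsistencyFilter:
    def _frame(self, fcs, sigs):
        return pd.DataFrame(
            dict(
                metabolite=["m"] * len(fcs),
                cultivar=["Cs"] * len(fcs),
                day=[18, 26, 34][: len(fcs)],
                log10_fc=np.log10(fcs),
                significant_raw=sigs,
                significant=sigs,
            )
        )

    def test_same_trend_one_significant_day_passes(self):
        res = self._frame([2, 3, 4], [False, True, False])
        assert consistency_filter(res)[("m", "Cs")] is True

    def test_trend_reversal_fails_even_if_all_significant(self):
        res = self._frame([2, 0.5, 3], [True, True, True])
        assert consistency_filter(res)[("m", "Cs")] is False

    def test_no_significant_day_fails(self):
        res = self._frame([2, 3, 4], [False, False, False])
        assert consistency_filter(res)[("m", "Cs")] is False

    def test_undefined_fold_change_fails(self):
        res = self._frame([2, 3, 4], [True, True, True])
        res.loc[1, "log10_fc"] = np.nan
        assert consistency_filter(res)[("m", "Cs")] is False


class TestTraitCorrelation:
    def test_perfect_and_inverse_correlation(self):
        pm = profile_from_array([[1.0], [2.0], [3.0], [4.0]], ["metA"])
        traits = pd.DataFrame(
            {"same": [1.0, 2, 3, 4], "neg": [-1.0, -2, -3, -4]},
            index=pm.sample_ids,
        )
        out = trait_correlation(pm, traits).set_index("trait")
        assert out.loc["same", "r"] == pytest.approx(1.0)
        assert out.loc["neg", "r"] == pytest.approx(-1.0)
        assert (out["n"] == 4).all()

    def test_zero_variance_flagged_undefined(self):
        pm = profile_from_array([[1.0], [1.0], [1.0]], ["metA"])
        traits = pd.DataFrame({"t": [1.0, 2.0, 3.0]}, index=pm.sample_ids)
        out = trait_correlation(pm, traits)
        assert math.isnan(out["r"].iloc[0])


class TestPCA:
    def test_rank_one_matrix_pc1_explains_everything(self):
        u = np.array([1.0, 2.0, 3.0, 4.0])
        v = np.array([0.5, 1.0, 2.0])
        pm = profile_from_array(np.outer(u, v))
        res = pca_scores(pm)
        assert res.variance_fraction[0] == pytest.approx(1.0)

    def test_variance_fractions_non_increasing_and_sum_to_one(self):
        rng = np.random.default_rng(3)
        pm = profile_from_array(rng.lognormal(0, 1, (10, 5)))
        res = pca_scores(pm)
        assert (np.diff(res.variance_fraction) <= 1e-12).all()
        assert res.variance_fraction.sum() == pytest.approx(1.0)

    def test_loadings_match_eigendecomposition(self):
        rng = np.random.default_rng(8)
        vals = rng.lognormal(0, 0.5, (4, 3))
        pm = profile_from_array(vals)
        res = pca_scores(pm)
        centered = vals - vals.mean(axis=0)
        cov = centered.T @ centered / (len(vals) - 1)
        eigval, eigvec = np.linalg.eigh(cov)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        np.testing.assert_allclose(
            res.variance_fraction, eigval / eigval.sum(), atol=1e-10
        )
        for k in range(3):
            dot = abs(np.dot(res.loadings.iloc[:, k], eigvec[:, k]))
            assert dot == pytest.approx(1.0, abs=1e-8)  # same axis up to sign
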