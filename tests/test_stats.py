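import numpy as np
import pandas as pd
import pytest

from gbmphen.errors import FitError, ParameterError
from gbmphen.stats import (adjusted_group_regression, bh_adjust, compare_cohort,
                           fisher_exact_test, kmeans_phenotype_cluster,
                           mann_whitney, pearson_matrix, shapiro_gate)


class TestMannWhitney:
    def test_exact_enumeration_small_samples(self):
        """{1,2,3} vs {4,5,6}: U = 0 and two-sided p = 2/20 = 0.1."""
        cmp = mann_whitney([1, 2, 3], [4, 5, 6])
        assert cmp.u_stat == 0.0
        assert cmp.p_raw == pytest.approx(0.1)

    def test_identical_groups(self):
        cmp = mann_whitney([2.0, 2.0, 2.0], [2.0, 2.0])
        assert cmp.p_raw == 1.0

    def test_exact_and_asymptotic_agree_without_ties(self, rng):
        x = rng.normal(0, 1, 8)
        y = rng.normal(0.5, 1, 8)
        import scipy.stats as sps
        p_exact = sps.mannwhitneyu(x, y, method="exact").pvalue
        p_asym = sps.mannwhitneyu(x, y, method="asymptotic").pvalue
        assert abs(p_exact - p_asym) < 0.01
        assert mann_whitney(x, y).p_raw == pytest.approx(p_exact)

    def test_empty_group_rejected(self):
        with pytest.raises(ParameterError):
            mann_whitney([], [1.0])


class TestFisherExact:
    def test_reference_location_tables(self):
        """The frontal and temporal 2×2 tables give the expected
        two-sided point-probability p-values."""
        assert fisher_exact_test([[7, 30], [22, 28]]).p_raw == pytest.approx(0.0209, abs=5e-5)
        assert fisher_exact_test([[13, 24], [8, 42]]).p_raw == pytest.approx(0.0464, abs=5e-5)

    def test_balanced_table_gives_one(self):
        res = fisher_exact_test([[5, 5], [5, 5]])
        assert res.p_raw == 1.0
        assert res.odds_ratio == pytest.approx(1.0)

    def test_invariant_to_simultaneous_row_and_column_swap(self, rng):
        for _ in range(10):
            t = rng.integers(0, 30, size=(2, 2))
            swapped = t[::-1, ::-1]
            assert fisher_exact_test(t).p_raw == pytest.approx(
                fisher_exact_test(swapped).p_raw, rel=1e-12)

    def test_zero_margin_flagged(self):
        res = fisher_exact_test([[0, 0], [3, 4]])
        assert res.p_raw == 1.0
        assert np.isnan(res.odds_ratio)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        adj, rej = bh_adjust([0.03])
        assert adj[0] == pytest.approx(0.03)
        assert rej[0]

    def test_location_family_has_no_rejections(self):
        """The two nominally significant location p-values lose significance after BH
        over the five-location family."""
        adj, rej = bh_adjust([0.0209, 0.0464, 0.30, 0.50, 0.70])
        assert adj.min() == pytest.approx(0.1045, abs=1e-4)
        assert not rej.any()

    def test_equal_ps_all_rejected(self):
        adj, rej = bh_adjust([0.01] * 5)
        assert adj == pytest.approx([0.01] * 5)
        assert rej.all()

    def test_monotone_and_never_more_than_unadjusted(self, rng):
        p = rng.uniform(1e-4, 1, 20)
        adj, rej = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj >= p - 1e-12).all()
        assert rej.sum() <= (p <= 0.05).sum()

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            bh_adjust([0.0, 0.5])


class TestAdjustedRegression:
    def test_exact_recovery_on_noiseless_data(self, rng):
        qt2 = rng.uniform(80, 130, 60)
        group = np.array(["high", "low"] * 30)
        y = 1.0 + 0.6 * (group == "high") + 0.01 * qt2
        res = adjusted_group_regression(y, group, qt2)
        assert res.beta_group == pytest.approx(0.6, abs=1e-10)
        assert res.r2 == pytest.approx(1.0)

    def test_permuted_phenotype_is_null(self, rng):
        n = 1000
        qt2 = rng.uniform(80, 130, n)
        y = rng.normal(2.0, 0.5, n)
        group = rng.permutation(["high"] * 500 + ["low"] * 500)
        res = adjusted_group_regression(y, group, qt2)
        assert abs(res.beta_group) < 0.15
        assert res.p_group > 0.001

    def test_zero_variance_qt2_dropped(self):
        group = ["high"] * 5 + ["low"] * 5
        y = [2.5] * 5 + [2.0] * 5
        res = adjusted_group_regression(y, group, [100.0] * 10)
        assert res.beta_group == pytest.approx(0.5, abs=1e-10)

    def test_too_few_cases_rejected(self):
        with pytest.raises(FitError):
            adjusted_group_regression([1.0, 2.0], ["high", "low"], [1.0, 2.0])


class TestPearson:
    def test_linear_and_antilinear(self):
        x = np.arange(10.0)
        r, p = pearson_matrix({"x": x, "y": 2 * x, "z": -x})
        assert r.loc["x", "y"] == pytest.approx(1.0)
        assert r.loc["x", "z"] == pytest.approx(-1.0)
        assert (np.diag(r) == 1.0).all()

    def test_independent_columns_near_zero(self, rng):
        r, _ = pearson_matrix({"a": rng.normal(size=1000), "b": rng.normal(size=1000)})
        assert abs(r.loc["a", "b"]) < 0.1

    def test_zero_variance_flagged_nan(self):
        r, _ = pearson_matrix({"a": np.arange(5.0), "c": np.ones(5)})
        assert np.isnan(r.loc["a", "c"])


class TestShapiroGate:
    def test_uniform_rejected(self, rng):
        p, normal = shapiro_gate(rng.uniform(size=500))
        assert p < 0.05 and not normal

    def test_normal_usually_passes(self):
        passed = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            _, normal = shapiro_gate(r.normal(size=500))
            passed += normal
        assert passed >= 18

    def test_constant_input_skipped(self):
        assert shapiro_gate(np.ones(10)) is None


class TestKMeansClustering:
    def _frame(self, rng, sep=True):
        n = 40
        adc = np.concatenate([rng.normal(1500, 80, n), rng.normal(1000, 80, n)])
        shift = 0.4 if sep else 0.0
        rcbv = np.concatenate([rng.normal(1.0, 0.1, n), rng.normal(1.0 + shift, 0.1, n)])
        mtr = np.concatenate([rng.normal(2.4, 0.2, n), rng.normal(2.4 - shift, 0.2, n)])
        return pd.DataFrame({"adc_l": adc, "median_rcbv": rcbv, "median_mtr_asym": mtr})

    def test_separated_groups_fully_concordant(self, rng):
        df = self._frame(rng)
        res = kmeans_phenotype_cluster(df, seed=3)
        assert res.concordance == 1.0
        assert res.n_discordant == 0

    def test_cluster_one_is_high_adc(self, rng):
        df = self._frame(rng)
        res = kmeans_phenotype_cluster(df, seed=3)
        lab = res.labels
        assert df["adc_l"][lab == 1].mean() > df["adc_l"][lab == 2].mean()

    def test_deterministic_under_seed(self, rng):
        df = self._frame(rng)
        a = kmeans_phenotype_cluster(df, seed=9)
        b = kmeans_phenotype_cluster(df, seed=9)
        assert (a.labels == b.labels).all()

    def test_missing_features_dropped(self, rng):
        df = self._frame(rng)
        df.loc[0, "median_rcbv"] = np.nan
        res = kmeans_phenotype_cluster(df, seed=3)
        assert res.labels[0] == 0  # dropped row
        assert (res.labels[1:] > 0).all()


class TestCompareCohort:
    def _cohort_frame(self, rng, n_high=37, n_low=50):
        rows = []
        locs = ["frontal", "temporal", "parietal", "occipital", "other"]
        for i in range(n_high + n_low):
            high = i < n_high
            rows.append({
                "phenotype": "high" if high else "low",
                "adc_l": rng.normal(1480 if high else 1020, 90),
                "volume_cc": rng.lognormal(np.log(20), 0.5),
                "median_deltat1": rng.normal(0.35, 0.08),
                "median_rcbv": rng.normal(1.02 if high else 1.28, 0.15),
                "median_mtr_asym": rng.normal(2.36 if high else 2.10, 0.35),
                "median_qt2": rng.normal(114.8 if high else 100.9, 10),
                "median_qt2star": rng.normal(60, 6),
                "location": locs[i % 5],
                "sex": "male" if i % 2 else "female",
                "mgmt": ["methylated", "unmethylated", "unknown"][i % 3],
                "egfr": ["amplified", "non_amplified"][i % 2],
            })
        return pd.DataFrame(rows)

    def test_report_structure(self, rng):
        report = compare_cohort(self._cohort_frame(rng))
        assert len(report.metric_comparisons) == 6
        assert len(report.location_tests) == 5
        assert len(report.covariate_tests) == 3
        assert report.regression is not None
        assert report.clustering is not None
        for c in report.metric_comparisons:
            assert 0 < c.p_raw <= 1
            assert c.p_adj >= c.p_raw - 1e-12
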