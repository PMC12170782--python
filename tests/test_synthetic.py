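import numpy as np
import pytest

from gbmphen.cest import (cluster_zspectra, compute_mtr_asym, correct_b0,
                          estimate_b0)
from gbmphen.core import BinaryMask, ImageVolume
from gbmphen.dsc import compute_rcbv
from gbmphen.errors import ConfigError
from gbmphen.sage import solve_sage
from gbmphen.scalar_maps import compute_adc
from gbmphen.synthetic import (CohortConfig, generate_truth_table,
                               simulate_dsc, simulate_dwi, simulate_sage,
                               simulate_zspectra, smooth_field)


class TestTruthTable:
    def test_cohort_composition_matches_defaults(self):
        df = generate_truth_table(CohortConfig(seed=5))
        assert len(df) == 87
        assert (df.group == "high").sum() == 37
        assert (df.group == "low").sum() == 50

    def test_location_counts_exact(self):
        df = generate_truth_table(CohortConfig(seed=5))
        hi = df[df.group == "high"]
        lo = df[df.group == "low"]
        assert (hi.location == "frontal").sum() == 7
        assert (lo.location == "frontal").sum() == 22
        assert (hi.location == "temporal").sum() == 13
        assert (lo.location == "temporal").sum() == 8
        assert (hi.sex == "male").sum() == 25
        assert (lo.mgmt == "methylated").sum() == 19

    def test_group_medians_near_targets(self):
        df = generate_truth_table(CohortConfig(seed=3))
        hi = df[df.group == "high"]
        lo = df[df.group == "low"]
        assert hi.rcbv_median.median() == pytest.approx(1.02, rel=0.03)
        assert lo.rcbv_median.median() == pytest.approx(1.28, rel=0.03)
        assert hi.qt2_median_ms.median() == pytest.approx(114.8, rel=0.03)
        assert hi.volume_cc.median() == pytest.approx(21.4, rel=0.12)

    def test_phenotype_margin_from_cutoff(self):
        df = generate_truth_table(CohortConfig(seed=2))
        assert (df[df.group == "high"].mu_lo >= 1240 + 100).all()
        assert (df[df.group == "low"].mu_lo <= 1240 - 100).all()

    def test_deterministic_under_seed(self):
        a = generate_truth_table(CohortConfig(seed=9))
        b = generate_truth_table(CohortConfig(seed=9))
        assert a.equals(b)

    def test_single_group_edge(self):
        from dataclasses import replace
        cfg = CohortConfig(seed=1)
        cfg = CohortConfig(high=replace(cfg.high, n=0, location_counts={},
                                        sex_counts={}, mgmt_counts={}, egfr_counts={}),
                           low=cfg.low, seed=1)
        df = generate_truth_table(cfg)
        assert (df.group == "low").all()

    def test_null_preset_has_no_group_difference(self):
        df = generate_truth_table(CohortConfig.null(seed=4))
        hi = df[df.group == "high"]
        lo = df[df.group == "low"]
        # identical distributions: medians close at these sample sizes
        assert abs(hi.rcbv_median.median() - lo.rcbv_median.median()) < 0.15
        assert abs(hi.mu_lo.median() - lo.mu_lo.median()) < 120

    def test_invalid_configs_rejected(self):
        from dataclasses import replace
        base = CohortConfig(seed=0)
        with pytest.raises(ConfigError):
            CohortConfig(high=replace(base.high, rcbv_median=-1.0), seed=0)
        with pytest.raises(ConfigError):
            CohortConfig(high=replace(base.high, location_counts={"frontal": 5}), seed=0)
        with pytest.raises(ConfigError):
            CohortConfig(snr_dwi=-3.0, seed=0)


class TestSimulateDwi:
    def _truth(self, value=1000.0):
        return ImageVolume(np.full((6, 6, 6), value))

    def test_noiseless_inversion(self):
        pair = simulate_dwi(self._truth(1000.0))
        adc = compute_adc(pair)
        assert adc.data == pytest.approx(1000.0, rel=1e-9)

    def test_zero_adc_gives_equal_signals(self):
        pair = simulate_dwi(self._truth(0.0))
        assert pair.s_b0.data == pytest.approx(pair.s_b1000.data)

    def test_noisy_roi_recovery(self, rng):
        from gbmphen.phenotyping import fit_adc_double_gaussian
        shape = (30, 30, 22)
        pick = rng.uniform(size=shape) < 0.5
        truth = np.where(pick, rng.normal(1000.0, 150.0, shape),
                         rng.normal(1700.0, 250.0, shape))
        pair = simulate_dwi(ImageVolume(truth), snr=50.0, rng=rng)
        vals = compute_adc(pair).data.ravel()
        fit = fit_adc_double_gaussian(vals[np.isfinite(vals)])
        assert abs(fit.adc_l - 1000.0) < 50.0

    def test_bad_snr_rejected(self):
        with pytest.raises(ConfigError):
            simulate_dwi(self._truth(), snr=0.0)


class TestSimulateZSpectra:
    def test_zero_target_symmetric(self):
        series = simulate_zspectra(ImageVolume(np.zeros((3, 3, 1))),
                                   ImageVolume(np.zeros((3, 3, 1))))
        mtr = compute_mtr_asym(series)
        assert np.abs(mtr.data).max() < 1e-9

    def test_target_inverted_analytically(self):
        target = np.full((3, 3, 1), 2.36)
        series = simulate_zspectra(ImageVolume(target), ImageVolume(np.zeros((3, 3, 1))))
        mtr = compute_mtr_asym(series)
        assert mtr.data == pytest.approx(2.36, abs=0.01)

    def test_b0_correction_removes_shift_bias(self):
        shape = (8, 8, 2)
        target = np.full(shape, 2.36)
        b0 = np.full(shape, 0.1)
        series = simulate_zspectra(ImageVolume(target), ImageVolume(b0))
        uncorrected = compute_mtr_asym(series).data
        mask = BinaryMask(np.ones(shape, dtype=bool), kind="brain")
        labels, centroids = cluster_zspectra(series, mask, n_clusters=2, seed=0)
        b0map = estimate_b0(centroids, labels, series.offsets_ppm)
        corrected = compute_mtr_asym(correct_b0(series, b0map)).data
        assert np.abs(uncorrected - 2.36).max() > 0.10   # shift biases the band
        assert np.abs(corrected - 2.36).max() < 0.05

    def test_negative_target_rejected(self):
        with pytest.raises(ConfigError):
            simulate_zspectra(ImageVolume(np.full((2, 2, 1), -1.0)),
                              ImageVolume(np.zeros((2, 2, 1))))


class TestSimulateSage:
    def test_noiseless_inversion(self):
        qt2 = ImageVolume(np.full((4, 4, 2), 114.8))
        qt2s = ImageVolume(np.full((4, 4, 2), 55.0))
        maps = solve_sage(simulate_sage(qt2, qt2s))
        assert maps[0].data == pytest.approx(114.8, rel=1e-9)
        assert maps[1].data == pytest.approx(55.0, rel=1e-9)

    def test_inverted_relaxation_generated_with_warning(self, caplog):
        qt2 = ImageVolume(np.full((2, 2, 1), 50.0))
        qt2s = ImageVolume(np.full((2, 2, 1), 80.0))  # unphysical T2* > T2
        import logging
        with caplog.at_level(logging.WARNING):
            simulate_sage(qt2, qt2s)
        assert any("T2* > T2" in m for m in caplog.messages)

    def test_noisy_roi_median_within_2pct(self, rng):
        shape = (10, 10, 10)
        qt2 = ImageVolume(np.full(shape, 100.0))
        qt2s = ImageVolume(np.full(shape, 50.0))
        es = simulate_sage(qt2, qt2s, snr=100.0, rng=rng)
        m2 = np.nanmedian(solve_sage(es)[0].data)
        assert abs(m2 - 100.0) / 100.0 < 0.02


class TestSimulateDsc:
    def test_leak_free_noiseless_recovery(self, small_brain):
        brain, tumor = small_brain
        truth = np.zeros(brain.shape)
        truth[brain.data] = 1.0
        truth[tumor.data] = 1.28
        # enforce the brain-median normalization the metric assumes
        truth[brain.data] /= np.median(truth[brain.data])
        k2 = ImageVolume(np.zeros(brain.shape))
        series = simulate_dsc(ImageVolume(truth), k2, kep=0.01, support=brain.data)
        rcbv = compute_rcbv(series, brain, tumor=tumor)
        got = np.nanmedian(rcbv.data[tumor.data])
        want = np.median(truth[tumor.data])
        assert got == pytest.approx(want, rel=1e-3)

    def test_leaky_tumor_corrected_within_5pct(self, small_brain):
        brain, tumor = small_brain
        truth = np.zeros(brain.shape)
        truth[brain.data] = 1.0
        truth[tumor.data] = 1.28
        k2 = np.zeros(brain.shape)
        k2[tumor.data] = 0.04
        series = simulate_dsc(ImageVolume(truth), ImageVolume(k2), kep=0.02,
                              support=brain.data)
        corrected = compute_rcbv(series, brain, tumor=tumor)
        uncorrected = compute_rcbv(series, brain, tumor=tumor,
                                   kep_grid=np.array([0.0]))
        got = np.nanmedian(corrected.data[tumor.data])
        got_unc = np.nanmedian(uncorrected.data[tumor.data])
        assert got == pytest.approx(1.28, rel=0.05)
        # the uncorrected estimate must be visibly biased by the leak
        assert abs(got_unc - 1.28) > abs(got - 1.28)

    def test_uniform_truth_gives_unity(self, small_brain):
        brain, tumor = small_brain
        truth = np.zeros(brain.shape)
        truth[brain.data] = 1.0
        series = simulate_dsc(ImageVolume(truth), ImageVolume(np.zeros(brain.shape)),
                              kep=0.0, support=brain.data)
        rcbv = compute_rcbv(series, brain, tumor=tumor)
        vals = rcbv.data[brain.data]
        assert np.nanmax(np.abs(vals - 1.0)) < 1e-3


class TestSmoothField:
    def test_rms_and_smoothness(self, rng):
        f = smooth_field((32, 32, 32), rms=0.05, rng=rng)
        assert f.std() == pytest.approx(0.05, rel=1e-6)
        # neighboring voxels are strongly correlated (a white-noise
        # field would give a difference s.d. of sqrt(2)·field s.d.)
        dx = np.diff(f, axis=0)
        assert dx.std() < 0.5 * f.std()
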