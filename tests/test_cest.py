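import numpy as np
import pytest

from gbmphen.cest import (B0Map, ZSpectrumSeries, cluster_zspectra,
                          compute_mtr_asym, correct_b0, estimate_b0,
                          lesion_b0_exclusion, lorentzian_dip)
from gbmphen.core import BinaryMask, ImageVolume
from gbmphen.errors import ClusteringError, ParameterError
from gbmphen.synthetic import amine_band_gain, default_offsets_ppm

OFFSETS = default_offsets_ppm()


def _spectrum(delta_b0=0.0, amine_amp=0.0, water_amp=0.82, water_fwhm=1.4,
              amine_fwhm=1.0):
    """Analytic two-pool z-spectrum (fraction of S0)."""
    z = lorentzian_dip(OFFSETS, water_amp, water_fwhm, delta_b0)
    z -= amine_amp * (1.0 - lorentzian_dip(OFFSETS, 1.0, amine_fwhm, delta_b0 + 3.0))
    return z


def _series_from_map(delta_map, amine_map=None, s0=800.0):
    shape = delta_map.shape
    sig = np.empty(shape + (OFFSETS.size,))
    amine_map = np.zeros(shape) if amine_map is None else amine_map
    for idx in np.ndindex(shape):
        sig[idx] = s0 * _spectrum(delta_map[idx], amine_map[idx])
    return ZSpectrumSeries(signal=sig, offsets_ppm=OFFSETS,
                           s0=ImageVolume(np.full(shape, s0)))


def _full_mask(shape=(6, 6, 2)):
    return BinaryMask(np.ones(shape, dtype=bool), kind="brain")


class TestClustering:
    def test_two_b0_populations_separate(self):
        delta = np.zeros((6, 6, 2))
        delta[3:, :, :] = 0.2
        series = _series_from_map(delta)
        labels, centroids = cluster_zspectra(series, _full_mask(), n_clusters=2, seed=0)
        left = labels[:3].ravel()
        right = labels[3:].ravel()
        assert len(np.unique(left)) == 1
        assert len(np.unique(right)) == 1
        assert left[0] != right[0]

    def test_homogeneous_spectra_coincident_centroids(self):
        series = _series_from_map(np.zeros((6, 6, 2)))
        _, centroids = cluster_zspectra(series, _full_mask(), n_clusters=3, seed=0)
        assert np.ptp(centroids, axis=0).max() < 1e-9

    def test_deterministic_under_seed(self):
        delta = np.linspace(-0.1, 0.1, 72).reshape(6, 6, 2)
        series = _series_from_map(delta)
        l1, _ = cluster_zspectra(series, _full_mask(), n_clusters=4, seed=11)
        l2, _ = cluster_zspectra(series, _full_mask(), n_clusters=4, seed=11)
        assert (l1 == l2).all()

    def test_too_few_voxels_rejected(self):
        series = _series_from_map(np.zeros((6, 6, 2)))
        mask = np.zeros((6, 6, 2), dtype=bool)
        mask[0, 0, 0] = True
        with pytest.raises(ClusteringError):
            cluster_zspectra(series, BinaryMask(mask, kind="brain"), n_clusters=4)


class TestB0Estimation:
    def test_shifted_centroid_recovered(self):
        centroids = np.array([_spectrum(0.10), _spectrum(-0.05)])
        labels = np.array([[[0, 1]]])
        b0 = estimate_b0(centroids, labels, OFFSETS)
        assert b0.delta_b0.data[0, 0, 0] == pytest.approx(0.10, abs=0.01)
        assert b0.delta_b0.data[0, 0, 1] == pytest.approx(-0.05, abs=0.01)
        assert not b0.flagged.data.any()

    def test_symmetric_spectrum_gives_zero(self):
        b0 = estimate_b0(np.array([_spectrum(0.0)]), np.zeros((1, 1, 1), dtype=int), OFFSETS)
        assert b0.delta_b0.data[0, 0, 0] == pytest.approx(0.0, abs=1e-6)

    def test_excessive_offset_flagged(self):
        b0 = estimate_b0(np.array([_spectrum(0.35)]), np.zeros((2, 2, 1), dtype=int), OFFSETS)
        assert b0.flagged.data.all()
        assert b0.delta_b0.data[0, 0, 0] == pytest.approx(0.35, abs=0.02)


class TestB0Correction:
    def test_zero_shift_is_identity(self):
        series = _series_from_map(np.zeros((4, 4, 1)))
        b0 = B0Map(delta_b0=ImageVolume(np.zeros((4, 4, 1))),
                   flagged=BinaryMask(np.zeros((4, 4, 1), dtype=bool), kind="brain"))
        out = correct_b0(series, b0)
        assert np.abs(out.signal - series.signal).max() == 0.0

    def test_shifted_lorentzian_restored(self):
        shape = (4, 4, 1)
        series = _series_from_map(np.full(shape, 0.1))
        b0 = B0Map(delta_b0=ImageVolume(np.full(shape, 0.1)),
                   flagged=BinaryMask(np.zeros(shape, dtype=bool), kind="brain"))
        out = correct_b0(series, b0)
        target = 800.0 * _spectrum(0.0)
        interior = slice(2, -2)  # edge offsets are clamp-extrapolated
        err = np.abs(out.signal[0, 0, 0, interior] - target[interior]).max()
        assert err < 0.005 * 800.0

    def test_reestimation_after_correction_is_near_zero(self):
        shape = (6, 6, 2)
        series = _series_from_map(np.full(shape, 0.12))
        labels, centroids = cluster_zspectra(series, _full_mask(shape), n_clusters=2, seed=0)
        b0 = estimate_b0(centroids, labels, OFFSETS)
        corrected = correct_b0(series, b0)
        labels2, centroids2 = cluster_zspectra(corrected, _full_mask(shape), n_clusters=2, seed=0)
        b0_2 = estimate_b0(centroids2, labels2, OFFSETS)
        assert np.abs(b0_2.delta_b0.data).max() < 0.01


class TestMtrAsym:
    def test_symmetric_spectrum_gives_exact_zero(self):
        series = _series_from_map(np.zeros((4, 4, 1)))
        mtr = compute_mtr_asym(series)
        assert np.abs(mtr.data).max() < 1e-9

    def test_two_pool_analytic_oracle(self):
        """Band-mean asymmetry equals the analytic two-Lorentzian value."""
        amp = 0.03
        shape = (2, 2, 1)
        series = _series_from_map(np.zeros(shape), amine_map=np.full(shape, amp))
        mtr = compute_mtr_asym(series)
        band = (OFFSETS >= 2.8) & (OFFSETS <= 3.2)
        w = OFFSETS[band]
        la = lambda x: 1.0 - lorentzian_dip(x, 1.0, 1.0, 3.0)
        expected = 100.0 * amp * np.mean(la(w) - la(-w))
        assert mtr.data[0, 0, 0] == pytest.approx(expected, abs=1e-9)
        # and the generator's gain solves the inverse problem
        assert expected == pytest.approx(100.0 * amp * amine_band_gain(OFFSETS, 1.0), abs=1e-12)

    def test_monotone_in_amine_amplitude(self):
        shape = (1, 1, 1)
        vals = []
        for amp in (0.0, 0.01, 0.02, 0.04):
            series = _series_from_map(np.zeros(shape), amine_map=np.full(shape, amp))
            vals.append(compute_mtr_asym(series).data[0, 0, 0])
        assert np.all(np.diff(vals) > 0)

    def test_nonpositive_s0_masked(self):
        series = _series_from_map(np.zeros((2, 2, 1)))
        series.s0.data[0, 0, 0] = 0.0
        mtr = compute_mtr_asym(series)
        assert np.isnan(mtr.data[0, 0, 0])

    def test_offsets_must_cover_band(self):
        offs = np.concatenate([-np.arange(0.2, 3.0, 0.2)[::-1], [0.0], np.arange(0.2, 3.0, 0.2)])
        with pytest.raises(ParameterError):
            ZSpectrumSeries(signal=np.ones((1, 1, 1, offs.size)), offsets_ppm=offs,
                            s0=ImageVolume(np.ones((1, 1, 1))))


class TestLesionExclusion:
    def test_fraction_rule(self):
        flagged = np.zeros((4, 4, 1), dtype=bool)
        flagged[:2] = True  # half the grid
        b0 = B0Map(delta_b0=ImageVolume(np.zeros((4, 4, 1))),
                   flagged=BinaryMask(flagged, kind="brain"))
        tumor_all = BinaryMask(np.ones((4, 4, 1), dtype=bool))
        excluded, frac = lesion_b0_exclusion(b0, tumor_all)
        assert excluded and frac == pytest.approx(0.5)
        tumor_clean = BinaryMask(~flagged)
        excluded, frac = lesion_b0_exclusion(b0, tumor_clean)
        assert not excluded and frac == 0.0
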