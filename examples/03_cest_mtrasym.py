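"""Amine CEST MTR_asym @ 3 ppm with B0 correction.

Z-spectra carrying a uniform +0.1 ppm static-field offset are clustered,
the water dip of each cluster centroid is Lorentzian-fitted to estimate
ΔB0, and the spectra are resampled before band integration.  The
uncorrected asymmetry is visibly biased; the corrected one recovers the
2.36% target.
"""

import numpy as np

from gbmphen.cest import cluster_zspectra, compute_mtr_asym, correct_b0, estimate_b0
from gbmphen.core import BinaryMask, ImageVolume
from gbmphen.synthetic import simulate_zspectra

shape = (10, 10, 4)
target = np.full(shape, 2.36)          # %
b0 = np.full(shape, 0.10)              # ppm

series = simulate_zspectra(ImageVolume(target), ImageVolume(b0),
                           snr=100.0, rng=np.random.default_rng(5))
mask = BinaryMask(np.ones(shape, dtype=bool), kind="brain")

uncorrected = compute_mtr_asym(series)

labels, centroids = cluster_zspectra(series, mask, n_clusters=2, seed=0)
b0map = estimate_b0(centroids, labels, series.offsets_ppm)
corrected = compute_mtr_asym(correct_b0(series, b0map))

print(f"target MTR_asym       : 2.36 %")
print(f"estimated ΔB0         : {np.nanmean(b0map.delta_b0.data):+.3f} ppm (true +0.100)")
print(f"uncorrected median    : {np.nanmedian(uncorrected.data):.2f} %")
print(f"corrected median      : {np.nanmedian(corrected.data):.2f} %")
print(f"flagged voxels (>0.3) : {int(b0map.flagged.data.sum())}")
# A 0.1 ppm shift asymmetrizes the water dip at ±3 ppm and corrupts the
# band average; after correction the amine asymmetry is recovered.
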