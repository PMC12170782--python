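"""Leakage-corrected rCBV on a synthetic DSC phantom.

A small brain phantom holds a tumor with true relative blood volume
1.28 and contrast extravasation (k2 = 0.04 s⁻¹, kep = 0.02 s⁻¹).  The
bidirectional correction restores the ROI median; skipping the
efflux-rate grid (kep = 0 only) leaves a visible bias.
"""

import numpy as np

from gbmphen.core import BinaryMask, ImageVolume
from gbmphen.dsc import compute_rcbv
from gbmphen.synthetic import simulate_dsc

gx, gy, gz = np.ogrid[:32, :32, :32]
brain = BinaryMask(((gx - 15.5) / 14) ** 2 + ((gy - 15.5) / 14) ** 2
                   + ((gz - 15.5) / 13) ** 2 <= 1, kind="brain")
tumor = BinaryMask(((gx - 15.5) / 5) ** 2 + ((gy - 15.5) / 5) ** 2
                   + ((gz - 15.5) / 5) ** 2 <= 1, kind="tumor_ce")

truth = np.zeros(brain.shape)
truth[brain.data] = 1.0
truth[tumor.data] = 1.28
k2 = np.zeros(brain.shape)
k2[tumor.data] = 0.04

series = simulate_dsc(ImageVolume(truth), ImageVolume(k2), kep=0.02,
                      snr=50.0, rng=np.random.default_rng(3), support=brain.data)

corrected = compute_rcbv(series, brain, tumor=tumor)
unidirectional = compute_rcbv(series, brain, tumor=tumor, kep_grid=np.array([0.0]))

print(f"true tumor rCBV            : 1.280")
print(f"bidirectional correction   : {np.nanmedian(corrected.data[tumor.data]):.3f}")
print(f"kep = 0 (unidirectional)   : {np.nanmedian(unidirectional.data[tumor.data]):.3f}")
print(f"brain median (both maps)   : {np.nanmedian(corrected.data[brain.data]):.3f}")
# The brain median is 1 by construction; the bidirectional fit
# recovers the leaky tumor's blood volume where the kep = 0 model
# misattributes part of the efflux to perfusion.
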