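"""Quantitative T2 / T2* from 4-echo SAGE signals.

Forward-simulates the piecewise gradient/spin-echo decay for a tumor
ROI (T2 = 114.8 ms, T2* = 60 ms) at SNR 100 and inverts it with the
closed-form solver.
"""

import numpy as np

from gbmphen.core import BinaryMask, ImageVolume
from gbmphen.sage import roi_qt2_medians, solve_sage
from gbmphen.synthetic import simulate_sage

shape = (12, 12, 12)
qt2_truth = ImageVolume(np.full(shape, 114.8))
qt2star_truth = ImageVolume(np.full(shape, 60.0))

echoes = simulate_sage(qt2_truth, qt2star_truth, snr=100.0,
                       rng=np.random.default_rng(11))
qt2, qt2star = solve_sage(echoes)
m2, m2s = roi_qt2_medians(qt2, qt2star, BinaryMask(np.ones(shape, dtype=bool)))

print(f"echo times (ms)   : {echoes.te_ms} (spin echo at {echoes.te_se_ms})")
print(f"median qT2        : {m2:6.1f} ms (true 114.8)")
print(f"median qT2*       : {m2s:6.1f} ms (true  60.0)")
# R2* comes from the two gradient echoes, 2R2−R2* from the mixed/spin
# pair; with four echoes the closed form is exactly determined.
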