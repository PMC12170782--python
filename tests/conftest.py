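import numpy as np
import pytest

from gbmphen.core import BinaryMask, ImageVolume
from gbmphen.synthetic import CohortConfig, GroupParams


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_brain():
    """A 24³ grid with an ellipsoidal brain and a centered tumor."""
    shape = (24, 24, 24)
    center = (11.5, 11.5, 11.5)
    gx, gy, gz = np.ogrid[:24, :24, :24]
    brain = ((gx - center[0]) / 10) ** 2 + ((gy - center[1]) / 10) ** 2 + ((gz - center[2]) / 9) ** 2 <= 1
    tumor = ((gx - center[0]) / 4) ** 2 + ((gy - center[1]) / 4) ** 2 + ((gz - center[2]) / 4) ** 2 <= 1
    return (
        BinaryMask(brain, kind="brain"),
        BinaryMask(tumor, kind="tumor_ce"),
    )


def tiny_cohort_config(n_high=3, n_low=3, seed=7, **kwargs) -> CohortConfig:
    """A fast, small-grid cohort for pipeline-level tests."""
    from dataclasses import replace

    cfg = CohortConfig(seed=seed)
    hi = replace(cfg.high, n=n_high, volume_median_cc=4.0, volume_sigma_log=0.2,
                 volume_bounds_cc=(2.5, 8.0), location_counts={}, sex_counts={},
                 mgmt_counts={}, egfr_counts={})
    lo = replace(cfg.low, n=n_low, volume_median_cc=4.0, volume_sigma_log=0.2,
                 volume_bounds_cc=(2.5, 8.0), location_counts={}, sex_counts={},
                 mgmt_counts={}, egfr_counts={})
    return CohortConfig(
        high=hi, low=lo, seed=seed,
        grid_shape=(48, 48, 48), brain_semiaxes_mm=(20.0, 20.0, 18.0),
        dsc_n_frames=40, **kwargs,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """Full default synthetic cohort run end-to-end through the pipeline.

    Expensive (several minutes); session-scoped so the cohort-level
    checks share one run.
    """
    from gbmphen.pipeline import run_cohort

    df, report, exclusions = run_cohort(CohortConfig(seed=1))
    return df, report, exclusions
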