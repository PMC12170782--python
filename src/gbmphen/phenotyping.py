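"""Diffusion-phenotype characterization of contrast-enhancing lesions.

The central statistic is ADC_L: a two-Gaussian model is fitted to the
histogram of ADC values inside the contrast-enhancing tumor mask, and
ADC_L is the mean of the lower-mean component.  Lesions are classified
high-ADC_L (ADC_L ≥ 1240 µm²/s, the phenotype previously associated
with favorable anti-VEGF response) or low-ADC_L (< 1240).  The module
also extracts the per-lesion profile row (ROI medians of every map,
contrast-enhancing volume, covariates), checks RANO measurability and
builds group frequency maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import norm

from .core import BinaryMask, ImageVolume, check_same_grid, masked_values
from .errors import FitError, ParameterError

log = logging.getLogger(__name__)

__all__ = [
    "ADC_CUTOFF_UM2_S",
    "AdcFitConfig",
    "AdcHistogramFit",
    "LesionProfile",
    "fit_adc_double_gaussian",
    "classify_phenotype",
    "extract_lesion_profile",
    "check_rano_measurable",
    "compute_frequency_map",
]

ADC_CUTOFF_UM2_S = 1240.0  # validated threshold separating diffusion phenotypes


@dataclass
class AdcFitConfig:
    """Histogram-fit settings for the two-Gaussian ADC model."""

    hist_range: tuple[float, float] = (0.0, 4000.0)  # µm²/s
    bin_width: float = 50.0  # µm²/s
    min_values: int = 100
    # degenerate-fit collapse rules: means closer than this, a vanishing
    # component weight, or a single Gaussian fitting almost as well
    # (an effectively unimodal histogram can be split into two strongly
    # overlapping components with near-zero residual) trigger a
    # single-Gaussian refit
    min_separation: float = 100.0  # µm²/s
    min_weight: float = 0.02
    parsimony_ratio: float = 1.5   # collapse when rss_single < ratio · rss_double
    method: str = "histogram"  # or "em" (Gaussian mixture on raw values)


@dataclass
class AdcHistogramFit:
    """Parameters of the two-Gaussian ADC histogram model.

    ``adc_l`` equals ``mu_lo`` (mean of the lower component) unless the
    fit collapsed to a single Gaussian, in which case it is that
    Gaussian's mean.
    """

    w_lo: float
    mu_lo: float
    sigma_lo: float
    w_hi: float
    mu_hi: float
    sigma_hi: float
    adc_l: float
    n_voxels: int
    converged: bool = True
    collapsed_to_single: bool = False
    rss: float = float("nan")


@dataclass
class LesionProfile:
    """One cohort-table row for a lesion."""

    lesion_id: str
    adc_l: float
    phenotype: str  # "high" | "low"
    volume_cc: float
    median_rcbv: float = float("nan")
    median_mtr_asym: float = float("nan")
    median_qt2: float = float("nan")
    median_qt2star: float = float("nan")
    median_deltat1: float = float("nan")
    location: str = "unknown"
    sex: str = "unknown"
    mgmt: str = "unknown"
    egfr: str = "unknown"
    steroid_dose_mg: float = float("nan")


def _two_gaussian_density(x, w_lo, mu1, s1, mu2, s2):
    return w_lo * norm.pdf(x, mu1, s1) + (1.0 - w_lo) * norm.pdf(x, mu2, s2)


def _single_gaussian_density(x, mu, s):
    return norm.pdf(x, mu, s)


def _fit_histogram(values: np.ndarray, cfg: AdcFitConfig) -> AdcHistogramFit:
    lo, hi = cfg.hist_range
    edges = np.arange(lo, hi + cfg.bin_width, cfg.bin_width)
    density, _ = np.histogram(values, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])

    q25, q75 = np.percentile(values, [25, 75])
    s_init = max(50.0, float(values.std()) / 2.0)
    p0 = [0.5, float(q25), s_init, float(q75), s_init]
    bounds = ([0.0, lo, 10.0, lo, 10.0], [1.0, hi, 1500.0, hi, 1500.0])
    converged = True
    try:
        popt, _ = curve_fit(_two_gaussian_density, centers, density, p0=p0,
                            bounds=bounds, maxfev=20000)
    except RuntimeError:
        converged = False
        popt = p0
    w_lo, mu1, s1, mu2, s2 = popt
    if mu1 > mu2:  # enforce mu_lo <= mu_hi
        w_lo, mu1, s1, mu2, s2 = 1.0 - w_lo, mu2, s2, mu1, s1
    rss = float(np.sum((_two_gaussian_density(centers, w_lo, mu1, s1, mu2, s2) - density) ** 2))

    try:
        popt1, _ = curve_fit(_single_gaussian_density, centers, density,
                             p0=[float(values.mean()), max(10.0, float(values.std()))],
                             bounds=([lo, 10.0], [hi, 2000.0]), maxfev=20000)
        mu_single, s_single = float(popt1[0]), float(popt1[1])
        rss_single = float(np.sum((_single_gaussian_density(centers, *popt1) - density) ** 2))
        single_ok = True
    except RuntimeError:
        mu_single, s_single = float(values.mean()), float(values.std())
        rss_single = np.inf
        single_ok = False

    collapsed = (
        (mu2 - mu1) < cfg.min_separation
        or min(w_lo, 1.0 - w_lo) < cfg.min_weight
        or rss_single < cfg.parsimony_ratio * max(rss, 1e-300)
    )
    if collapsed or not converged:
        converged = single_ok or converged
        return AdcHistogramFit(
            w_lo=1.0, mu_lo=mu_single, sigma_lo=s_single,
            w_hi=0.0, mu_hi=mu_single, sigma_hi=s_single,
            adc_l=mu_single, n_voxels=values.size,
            converged=converged, collapsed_to_single=True, rss=rss,
        )
    return AdcHistogramFit(
        w_lo=float(w_lo), mu_lo=float(mu1), sigma_lo=float(s1),
        w_hi=float(1.0 - w_lo), mu_hi=float(mu2), sigma_hi=float(s2),
        adc_l=float(mu1), n_voxels=values.size,
        converged=converged, collapsed_to_single=False, rss=rss,
    )


def _fit_em(values: np.ndarray, cfg: AdcFitConfig) -> AdcHistogramFit:
    from sklearn.mixture import GaussianMixture

    gm = GaussianMixture(n_components=2, random_state=0, n_init=3)
    gm.fit(values[:, None])
    means = gm.means_.ravel()
    sigmas = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    mu1, mu2 = means[order]
    s1, s2 = sigmas[order]
    w_lo = float(weights[order][0])
    collapsed = (mu2 - mu1) < cfg.min_separation or min(w_lo, 1.0 - w_lo) < cfg.min_weight
    if collapsed:
        mu = float(values.mean())
        s = float(values.std())
        return AdcHistogramFit(1.0, mu, s, 0.0, mu, s, mu, values.size,
                               converged=True, collapsed_to_single=True)
    return AdcHistogramFit(w_lo, float(mu1), float(s1), 1.0 - w_lo, float(mu2),
                           float(s2), float(mu1), values.size, converged=True)


def fit_adc_double_gaussian(
    adc_values: Sequence[float] | np.ndarray,
    config: AdcFitConfig | None = None,
) -> AdcHistogramFit:
    """Fit the two-Gaussian model to a lesion's ADC values (µm²/s).

    Default method: bounded nonlinear least squares on the
    density-normalized histogram (range 0–4000 µm²/s, 50 µm²/s bins),
    initialized from the 25th/75th percentiles.  If the two means are
    closer than the collapse threshold or one weight vanishes, the
    distribution is effectively unimodal and a single Gaussian is
    refitted (``collapsed_to_single``).  ``config.method = "em"``
    selects an expectation-maximization fit on the raw values instead.
    """
    cfg = config or AdcFitConfig()
    values = np.asarray(adc_values, dtype=np.float64)
    values = values[np.isfinite(values)]
    if values.size < cfg.min_values:
        raise FitError(f"need >= {cfg.min_values} finite ADC values, got {values.size}")
    values = np.clip(values, *cfg.hist_range)
    if cfg.method == "em":
        return _fit_em(values, cfg)
    return _fit_histogram(values, cfg)


def classify_phenotype(adc_l: float, cutoff: float = ADC_CUTOFF_UM2_S) -> str:
    """``"high"`` iff ADC_L ≥ cutoff (boundary inclusive), else ``"low"``."""
    if not np.isfinite(adc_l):
        raise ParameterError(f"ADC_L must be finite, got {adc_l}")
    return "high" if adc_l >= cutoff else "low"


def extract_lesion_profile(
    maps: Mapping[str, ImageVolume],
    tumor: BinaryMask,
    clinical: Mapping[str, object] | None = None,
    lesion_id: str = "lesion",
    adc_fit: AdcHistogramFit | None = None,
    cutoff: float = ADC_CUTOFF_UM2_S,
) -> LesionProfile:
    """Assemble one cohort row from the per-voxel maps and the tumor mask.

    ``maps`` may contain any of ``adc``, ``rcbv``, ``mtr_asym``, ``qt2``,
    ``qt2star``, ``deltat1``; medians are taken over valid tumor voxels
    and missing maps leave their field NaN.  If ``adc_fit`` is not
    supplied, the double-Gaussian fit is run on the ADC map's tumor
    values.
    """
    if tumor.n_voxels == 0:
        raise ParameterError("empty tumor mask")
    for vol in maps.values():
        check_same_grid(vol, tumor)

    def roi_median(name: str) -> float:
        if name not in maps:
            log.info("extract_lesion_profile[%s]: map %r missing", lesion_id, name)
            return float("nan")
        vals = masked_values(maps[name], tumor)
        return float(np.median(vals)) if vals.size else float("nan")

    if adc_fit is None:
        if "adc" not in maps:
            raise ParameterError("either an ADC map or a precomputed adc_fit is required")
        adc_fit = fit_adc_double_gaussian(masked_values(maps["adc"], tumor))
    clinical = dict(clinical or {})
    return LesionProfile(
        lesion_id=lesion_id,
        adc_l=adc_fit.adc_l,
        phenotype=classify_phenotype(adc_fit.adc_l, cutoff),
        volume_cc=tumor.volume_cc(),
        median_rcbv=roi_median("rcbv"),
        median_mtr_asym=roi_median("mtr_asym"),
        median_qt2=roi_median("qt2"),
        median_qt2star=roi_median("qt2star"),
        median_deltat1=roi_median("deltat1"),
        location=str(clinical.get("location", "unknown")),
        sex=str(clinical.get("sex", "unknown")),
        mgmt=str(clinical.get("mgmt", "unknown")),
        egfr=str(clinical.get("egfr", "unknown")),
        steroid_dose_mg=float(clinical.get("steroid_dose_mg", float("nan"))),
    )


def check_rano_measurable(tumor: BinaryMask, min_extent_mm: float = 10.0) -> bool:
    """True iff the mask's bounding box spans ≥ 10 mm on all three axes.

    Operationalizes the RANO ≥ 1 cm × 1 cm × 1 cm measurability rule by
    the axis-aligned bounding box rather than perpendicular in-plane
    diameters.
    """
    if tumor.n_voxels == 0:
        log.warning("check_rano_measurable: empty mask")
        return False
    idx = np.nonzero(tumor.data)
    for axis in range(3):
        extent = (idx[axis].max() - idx[axis].min() + 1) * tumor.spacing[axis]
        if extent < min_extent_mm:
            return False
    return True


def compute_frequency_map(
    masks: Sequence[BinaryMask],
    phenotypes: Sequence[str],
) -> dict[str, ImageVolume]:
    """Voxelwise lesion frequency maps per phenotype group.

    Each group's map is the mean of its binary masks (range [0, 1]); all
    masks must share the common grid.
    """
    if len(masks) != len(phenotypes):
        raise ParameterError("masks and phenotypes lengths differ")
    check_same_grid(*masks)
    out: dict[str, ImageVolume] = {}
    for group in sorted(set(phenotypes)):
        stack = [m.data for m, p in zip(masks, phenotypes) if p == group]
        freq = np.mean(np.stack(stack, axis=0), axis=0)
        out[group] = ImageVolume(data=freq, spacing=masks[0].spacing)
    return out
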