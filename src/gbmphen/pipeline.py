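"""End-to-end orchestration: raw lesion bundles → maps → profile table
→ cohort report.

Each lesion is processed independently; a failure in one modality marks
that lesion's field missing (per-analysis exclusion) rather than
aborting the cohort, mirroring clinical-study accounting where lesions
drop out of individual analyses for blood products, B0 artifacts or
missing echoes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .cest import (cluster_zspectra, compute_mtr_asym, correct_b0, estimate_b0,
                   lesion_b0_exclusion)
from .core import BinaryMask, ImageVolume, masked_values
from .dsc import compute_rcbv
from .errors import GbmphenError
from .phenotyping import (ADC_CUTOFF_UM2_S, AdcFitConfig, check_rano_measurable,
                          classify_phenotype, extract_lesion_profile,
                          fit_adc_double_gaussian)
from .sage import roi_qt2_medians, solve_sage
from .scalar_maps import DeltaT1Inputs, compute_adc, compute_delta_t1
from .stats import CohortComparisonReport, compare_cohort
from .synthetic import CohortConfig, LesionBundle, generate_cohort

log = logging.getLogger(__name__)

__all__ = ["ExclusionReason", "PipelineConfig", "process_lesion", "run_cohort",
           "report_to_dict"]


class ExclusionReason(str, Enum):
    """Why a lesion dropped out of a specific analysis."""

    BLOOD_PRODUCTS = "blood_products"          # unreliable rCBV estimation
    B0_INHOMOGENEITY = "b0_inhomogeneity"      # flagged CEST voxels > limit
    MISSING_ECHOES = "missing_echoes"          # no SAGE relaxometry data
    NOT_MEASURABLE = "not_rano_measurable"
    PROCESSING_ERROR = "processing_error"


@dataclass
class PipelineConfig:
    """Resolved processing settings for a cohort run."""

    cutoff: float = ADC_CUTOFF_UM2_S
    adc_fit: AdcFitConfig = field(default_factory=AdcFitConfig)
    cest_n_clusters: int = 4
    cest_seed: int = 0
    cest_band_halfwidth: float = 0.2
    b0_threshold_ppm: float = 0.3
    max_flagged_fraction: float = 0.25
    cluster_seed: int = 42

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def load_config(path) -> tuple[CohortConfig, PipelineConfig]:
    """Load cohort + pipeline settings from a YAML file.

    The file may contain a ``cohort`` section (flat CohortConfig field
    overrides, plus optional ``high``/``low`` group-parameter mappings)
    and a ``pipeline`` section (flat PipelineConfig overrides); omitted
    fields keep their defaults.
    """
    import yaml

    raw = yaml.safe_load(open(path)) or {}
    cohort_kwargs = dict(raw.get("cohort", {}))
    for group in ("high", "low"):
        if group in cohort_kwargs:
            base = CohortConfig().__getattribute__(group)
            cohort_kwargs[group] = dataclasses.replace(base, **cohort_kwargs[group])
    cohort = CohortConfig(**cohort_kwargs)
    p_kwargs = dict(raw.get("pipeline", {}))
    if "adc_fit" in p_kwargs:
        p_kwargs["adc_fit"] = AdcFitConfig(**p_kwargs["adc_fit"])
    pipeline = PipelineConfig(**p_kwargs)
    return cohort, pipeline


def process_lesion(bundle: LesionBundle, config: PipelineConfig | None = None
                   ) -> tuple[dict, list[tuple[str, str]]]:
    """Run every map computation for one lesion and assemble its row.

    Returns (profile row dict, exclusion list); excluded analyses leave
    NaN fields.
    """
    cfg = config or PipelineConfig()
    exclusions: list[tuple[str, str]] = []
    brain, tumor = bundle.brain, bundle.tumor

    if not check_rano_measurable(tumor):
        exclusions.append(("all", ExclusionReason.NOT_MEASURABLE.value))

    # ADC → double-Gaussian → phenotype
    adc_map = compute_adc(bundle.dwi)
    adc_fit = fit_adc_double_gaussian(masked_values(adc_map, tumor), cfg.adc_fit)

    # deltaT1 (also feeds the non-enhancing reference for rCBV)
    deltat1 = compute_delta_t1(DeltaT1Inputs(bundle.t1w_pre, bundle.t1w_post, brain))

    maps: dict[str, ImageVolume] = {"adc": adc_map, "deltat1": deltat1}

    try:
        maps["rcbv"] = compute_rcbv(bundle.dsc, brain, deltat1=deltat1)
    except GbmphenError as exc:
        log.warning("lesion %s: rCBV failed (%s)", bundle.lesion_id, exc)
        exclusions.append(("rcbv", ExclusionReason.BLOOD_PRODUCTS.value))

    try:
        labels, centroids = cluster_zspectra(bundle.zspectra, brain,
                                             cfg.cest_n_clusters, cfg.cest_seed)
        b0 = estimate_b0(centroids, labels, bundle.zspectra.offsets_ppm,
                         spacing=brain.spacing, threshold_ppm=cfg.b0_threshold_ppm)
        corrected = correct_b0(bundle.zspectra, b0)
        mtr_map = compute_mtr_asym(corrected, band_halfwidth=cfg.cest_band_halfwidth)
        excluded, frac = lesion_b0_exclusion(b0, tumor, cfg.max_flagged_fraction)
        if excluded:
            log.warning("lesion %s: %.0f%% tumor voxels B0-flagged; MTR_asym excluded",
                        bundle.lesion_id, 100 * frac)
            exclusions.append(("mtr_asym", ExclusionReason.B0_INHOMOGENEITY.value))
        else:
            maps["mtr_asym"] = mtr_map
    except GbmphenError as exc:
        log.warning("lesion %s: CEST failed (%s)", bundle.lesion_id, exc)
        exclusions.append(("mtr_asym", ExclusionReason.PROCESSING_ERROR.value))

    median_qt2 = median_qt2star = float("nan")
    if bundle.sage is not None:
        try:
            qt2_map, qt2star_map = solve_sage(bundle.sage)
            median_qt2, median_qt2star = roi_qt2_medians(qt2_map, qt2star_map, tumor)
        except GbmphenError as exc:
            log.warning("lesion %s: SAGE failed (%s)", bundle.lesion_id, exc)
            exclusions.append(("qt2", ExclusionReason.PROCESSING_ERROR.value))
    else:
        exclusions.append(("qt2", ExclusionReason.MISSING_ECHOES.value))

    profile = extract_lesion_profile(
        maps, tumor, clinical=bundle.clinical, lesion_id=bundle.lesion_id,
        adc_fit=adc_fit, cutoff=cfg.cutoff,
    )
    row = dataclasses.asdict(profile)
    row["median_qt2"] = median_qt2
    row["median_qt2star"] = median_qt2star
    row["collapsed_to_single"] = adc_fit.collapsed_to_single
    return row, exclusions


def run_cohort(
    cohort_config: CohortConfig | None = None,
    pipeline_config: PipelineConfig | None = None,
    bundles=None,
) -> tuple[pd.DataFrame, CohortComparisonReport, dict]:
    """Simulate (or accept) a cohort, process every lesion, run the stats.

    ``bundles`` may be an iterable of (LesionBundle, truth-dict) pairs;
    otherwise the synthetic generator supplies the default cohort.
    Returns (profile table, comparison report, exclusion log).
    """
    p_cfg = pipeline_config or PipelineConfig()
    if bundles is None:
        bundles = generate_cohort(cohort_config or CohortConfig())
    rows = []
    exclusion_log: dict[str, list] = {}
    for bundle, truth in bundles:
        try:
            row, exclusions = process_lesion(bundle, p_cfg)
        except GbmphenError as exc:
            log.error("lesion %s excluded entirely: %s", bundle.lesion_id, exc)
            exclusion_log[bundle.lesion_id] = [("all", ExclusionReason.PROCESSING_ERROR.value)]
            continue
        if truth is not None:
            row["true_group"] = truth.get("group")
        rows.append(row)
        if exclusions:
            exclusion_log[bundle.lesion_id] = exclusions
    df = pd.DataFrame(rows)
    report = compare_cohort(df, cluster_seed=p_cfg.cluster_seed)
    return df, report, exclusion_log


def report_to_dict(report: CohortComparisonReport) -> dict:
    """JSON-serializable view of a cohort comparison report."""
    out: dict = {
        "metric_comparisons": [dataclasses.asdict(c) for c in report.metric_comparisons],
        "location_tests": [dataclasses.asdict(t) for t in report.location_tests],
        "covariate_tests": [dataclasses.asdict(t) for t in report.covariate_tests],
        "n_per_analysis": report.n_per_analysis,
    }
    if report.regression is not None:
        out["regression"] = dataclasses.asdict(report.regression)
    if report.correlations is not None:
        out["correlations"] = report.correlations.round(4).to_dict()
    if report.clustering is not None:
        c = report.clustering
        out["clustering"] = {
            "labels": c.labels.tolist(),
            "concordance": c.concordance,
            "n_discordant": c.n_discordant,
            "seed": c.seed,
        }
    return json.loads(json.dumps(out, default=float))
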