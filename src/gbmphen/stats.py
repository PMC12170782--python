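"""Cohort statistics on the per-lesion profile table.

Implements the cohort analysis plan: nonparametric Mann-Whitney U
group comparisons of the MRI metrics (with a Shapiro-Wilk normality
gate that is logged but never switches the test parametric),
Fisher's exact tests for categorical covariates and lesion locations,
Benjamini-Hochberg FDR correction per test family, a qT2-adjusted
linear regression of MTR_asym on the phenotype, Pearson correlations
between metrics, and k = 2 k-means clustering of (ADC_L, rCBV,
MTR_asym) with concordance against the 1240 µm²/s threshold groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .errors import ClusteringError, FitError, ParameterError
from .phenotyping import ADC_CUTOFF_UM2_S

log = logging.getLogger(__name__)

__all__ = [
    "GroupComparison",
    "ContingencyResult",
    "AdjustedRegressionResult",
    "ClusterResult",
    "CohortComparisonReport",
    "METRIC_COLUMNS",
    "LOCATION_CATEGORIES",
    "mann_whitney",
    "fisher_exact_test",
    "bh_adjust",
    "adjusted_group_regression",
    "pearson_matrix",
    "kmeans_phenotype_cluster",
    "shapiro_gate",
    "compare_cohort",
]

# the six MRI-metric comparisons forming one multiplicity family
METRIC_COLUMNS = [
    "volume_cc",
    "median_deltat1",
    "median_rcbv",
    "median_mtr_asym",
    "median_qt2",
    "median_qt2star",
]
# five location categories forming the second family
LOCATION_CATEGORIES = ["frontal", "temporal", "parietal", "occipital", "other"]


@dataclass
class GroupComparison:
    metric: str
    n_high: int
    n_low: int
    median_high: float
    median_low: float
    u_stat: float
    p_raw: float
    p_adj: float | None = None
    family: str = ""


@dataclass
class ContingencyResult:
    label: str
    table: list[list[int]]
    odds_ratio: float
    p_raw: float
    p_adj: float | None = None
    family: str = ""


@dataclass
class AdjustedRegressionResult:
    beta_group: float  # % units, high-vs-low effect on MTR_asym
    p_group: float
    r2: float
    n: int


@dataclass
class ClusterResult:
    labels: np.ndarray  # 1 = higher-ADC_L cluster, 2 = lower
    centroids: np.ndarray  # standardized feature space
    concordance: float
    n_discordant: int
    seed: int


@dataclass
class CohortComparisonReport:
    metric_comparisons: list[GroupComparison]
    location_tests: list[ContingencyResult]
    covariate_tests: list[ContingencyResult]
    regression: AdjustedRegressionResult | None
    correlations: pd.DataFrame | None
    clustering: ClusterResult | None
    n_per_analysis: dict[str, int] = field(default_factory=dict)


def shapiro_gate(values: np.ndarray) -> tuple[float, bool] | None:
    """Shapiro-Wilk normality check; logged, never used to switch tests.

    Returns (p, normal-at-0.05) or None for degenerate input.
    """
    values = np.asarray(values, dtype=np.float64)
    values = values[np.isfinite(values)]
    if values.size < 3 or np.ptp(values) == 0:
        log.warning("shapiro_gate: skipped (n=%d, constant=%s)", values.size,
                    values.size > 0 and np.ptp(values) == 0)
        return None
    p = float(sps.shapiro(values).pvalue)
    return p, p >= 0.05


def mann_whitney(values_high, values_low, metric: str = "", family: str = "") -> GroupComparison:
    """Two-sided Mann-Whitney U test between phenotype groups.

    Exact enumeration when both groups have n ≤ 8 and no ties cross the
    groups; otherwise the normal approximation with tie and continuity
    correction.
    """
    x = np.asarray(values_high, dtype=np.float64)
    y = np.asarray(values_low, dtype=np.float64)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size == 0 or y.size == 0:
        raise ParameterError("both groups must be nonempty")
    if np.ptp(np.concatenate([x, y])) == 0:
        log.warning("mann_whitney[%s]: all values identical; p = 1", metric)
        return GroupComparison(metric, x.size, y.size, float(np.median(x)),
                               float(np.median(y)), u_stat=x.size * y.size / 2.0,
                               p_raw=1.0, family=family)
    method = "exact" if (x.size <= 8 and y.size <= 8) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return GroupComparison(
        metric=metric, n_high=x.size, n_low=y.size,
        median_high=float(np.median(x)), median_low=float(np.median(y)),
        u_stat=float(res.statistic), p_raw=float(res.pvalue), family=family,
    )


def fisher_exact_test(table, label: str = "", family: str = "") -> ContingencyResult:
    """Two-sided Fisher's exact test (point-probability method) on a 2×2 table."""
    tab = np.asarray(table, dtype=np.int64)
    if tab.shape != (2, 2) or (tab < 0).any():
        raise ParameterError(f"need a nonnegative 2x2 table, got {table}")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        log.warning("fisher_exact_test[%s]: zero margin; p = 1", label)
        return ContingencyResult(label, tab.tolist(), float("nan"), 1.0, family=family)
    a, b = tab[0]
    c, d = tab[1]
    odds = float(a * d) / (b * c) if b * c > 0 else float("inf")
    p = float(sps.fisher_exact(tab, alternative="two-sided").pvalue)
    return ContingencyResult(label, tab.tolist(), odds, p, family=family)


def bh_adjust(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and rejection flags."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p, np.zeros(0, dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ParameterError("p-values must lie in (0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, reject


def adjusted_group_regression(mtr, phenotype, qt2) -> AdjustedRegressionResult:
    """OLS of MTR_asym on the phenotype indicator, adjusting for qT2.

    mtr ~ intercept + 1[high] + qt2, complete cases only.  A
    zero-variance qT2 column is dropped with a warning rather than
    producing a singular design.
    """
    mtr = np.asarray(mtr, dtype=np.float64)
    qt2 = np.asarray(qt2, dtype=np.float64)
    group = np.asarray([1.0 if p == "high" else 0.0 for p in phenotype])
    ok = np.isfinite(mtr) & np.isfinite(qt2)
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.info("adjusted_group_regression: dropped %d incomplete cases", n_dropped)
    mtr, qt2, group = mtr[ok], qt2[ok], group[ok]
    if mtr.size < 3:
        raise FitError(f"need >= 3 complete cases, got {mtr.size}")
    if group.std() == 0:
        raise FitError("phenotype has a single level; group effect undefined")
    cols = [np.ones_like(mtr), group]
    names = ["const", "group_high"]
    if qt2.std() > 0:
        cols.append(qt2)
        names.append("qt2")
    else:
        log.warning("adjusted_group_regression: zero-variance qT2 dropped from the design")
    X = np.column_stack(cols)
    fit = sm.OLS(mtr, X).fit()
    i = names.index("group_high")
    return AdjustedRegressionResult(
        beta_group=float(fit.params[i]),
        p_group=float(fit.pvalues[i]),
        r2=float(fit.rsquared),
        n=int(mtr.size),
    )


def pearson_matrix(columns: dict[str, np.ndarray]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations (pairwise-complete observations).

    Returns (r, p) DataFrames; zero-variance pairs give NaN entries.
    """
    names = list(columns)
    k = len(names)
    r = pd.DataFrame(np.eye(k), index=names, columns=names)
    p = pd.DataFrame(np.full((k, k), np.nan), index=names, columns=names)
    for i in range(k):
        for j in range(i + 1, k):
            x = np.asarray(columns[names[i]], dtype=np.float64)
            y = np.asarray(columns[names[j]], dtype=np.float64)
            ok = np.isfinite(x) & np.isfinite(y)
            x, y = x[ok], y[ok]
            if x.size < 3 or x.std() == 0 or y.std() == 0:
                log.warning("pearson_matrix: degenerate pair (%s, %s)", names[i], names[j])
                rij, pij = np.nan, np.nan
            else:
                res = sps.pearsonr(x, y)
                rij, pij = float(res.statistic), float(res.pvalue)
            r.iloc[i, j] = r.iloc[j, i] = rij
            p.iloc[i, j] = p.iloc[j, i] = pij
    return r, p


def kmeans_phenotype_cluster(
    features: pd.DataFrame,
    phenotype=None,
    seed: int = 42,
    cutoff: float = ADC_CUTOFF_UM2_S,
) -> ClusterResult:
    """k = 2 k-means on standardized (ADC_L, rCBV, MTR_asym) features.

    ADC_L enters as a continuous variable with the same weight as the
    other metrics (z-scored).  Cluster 1 is relabeled to be the one with
    the higher mean ADC_L; concordance is the fraction of lesions whose
    cluster matches their threshold group (cluster 1 ↔ high-ADC_L).
    Rows with missing features are dropped (complete cases).
    """
    feats = features[["adc_l", "median_rcbv", "median_mtr_asym"]].astype(float)
    ok = feats.notna().all(axis=1).to_numpy()
    X = feats.to_numpy()[ok]
    if np.unique(X, axis=0).shape[0] < 2:
        raise ClusteringError("need >= 2 distinct complete-case feature rows")
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    km = KMeans(n_clusters=2, n_init=50, random_state=seed)
    raw = km.fit_predict(Z)
    mean_adc = [X[raw == c, 0].mean() for c in (0, 1)]
    high_cluster = int(np.argmax(mean_adc))
    labels = np.where(raw == high_cluster, 1, 2)
    centroids = km.cluster_centers_[[high_cluster, 1 - high_cluster]]
    if phenotype is None:
        groups = np.where(X[:, 0] >= cutoff, "high", "low")
    else:
        groups = np.asarray(phenotype)[ok]
    match = (labels == 1) == (groups == "high")
    concordance = float(match.mean())
    full_labels = np.zeros(len(features), dtype=int)  # 0 = dropped row
    full_labels[ok] = labels
    return ClusterResult(
        labels=full_labels,
        centroids=centroids,
        concordance=concordance,
        n_discordant=int((~match).sum()),
        seed=seed,
    )


def _location_table(df: pd.DataFrame, category: str) -> np.ndarray:
    hi = df[df["phenotype"] == "high"]
    lo = df[df["phenotype"] == "low"]
    a = int((hi["location"] == category).sum())
    c = int((lo["location"] == category).sum())
    return np.array([[a, len(hi) - a], [c, len(lo) - c]])


def _covariate_table(df: pd.DataFrame, column: str, level: str) -> np.ndarray:
    """2×2 of level vs other-known-levels by phenotype; unknowns excluded."""
    known = df[df[column] != "unknown"]
    hi = known[known["phenotype"] == "high"]
    lo = known[known["phenotype"] == "low"]
    a = int((hi[column] == level).sum())
    c = int((lo[column] == level).sum())
    return np.array([[a, len(hi) - a], [c, len(lo) - c]])


def compare_cohort(
    df: pd.DataFrame,
    alpha: float = 0.05,
    cluster_seed: int = 42,
) -> CohortComparisonReport:
    """Run the full analysis battery on a lesion-profile table.

    Expects the columns produced by the phenotyping stage: ``phenotype``
    plus the metric columns, and ``location`` / ``sex`` / ``mgmt`` /
    ``egfr`` covariates.  Missing metric values are handled per
    analysis (complete cases); BH correction is applied within the
    MRI-metric family and within the location family separately.
    """
    hi = df[df["phenotype"] == "high"]
    lo = df[df["phenotype"] == "low"]
    n_per: dict[str, int] = {}

    metric_comparisons: list[GroupComparison] = []
    for metric in METRIC_COLUMNS:
        if metric not in df.columns:
            continue
        x = hi[metric].to_numpy(dtype=float)
        y = lo[metric].to_numpy(dtype=float)
        x, y = x[np.isfinite(x)], y[np.isfinite(y)]
        shapiro_gate(np.concatenate([x, y]))
        cmp = mann_whitney(x, y, metric=metric, family="mri_metrics")
        metric_comparisons.append(cmp)
        n_per[metric] = x.size + y.size
    if metric_comparisons:
        p_adj, _ = bh_adjust([c.p_raw for c in metric_comparisons], alpha)
        for c, pa in zip(metric_comparisons, p_adj):
            c.p_adj = float(pa)

    location_tests = [
        fisher_exact_test(_location_table(df, cat), label=f"location_{cat}", family="location")
        for cat in LOCATION_CATEGORIES
    ]
    p_adj, _ = bh_adjust([t.p_raw for t in location_tests], alpha)
    for t, pa in zip(location_tests, p_adj):
        t.p_adj = float(pa)

    covariate_tests = []
    for column, level in [("sex", "male"), ("mgmt", "methylated"), ("egfr", "amplified")]:
        if column in df.columns:
            covariate_tests.append(
                fisher_exact_test(_covariate_table(df, column, level),
                                  label=f"{column}_{level}", family="covariates")
            )

    regression = None
    try:
        regression = adjusted_group_regression(
            df["median_mtr_asym"], df["phenotype"], df["median_qt2"]
        )
        n_per["regression"] = regression.n
    except FitError as exc:
        log.warning("adjusted regression skipped: %s", exc)

    corr_cols = {
        "adc_l": df["adc_l"].to_numpy(dtype=float),
        "median_qt2": df["median_qt2"].to_numpy(dtype=float),
        "median_qt2star": df["median_qt2star"].to_numpy(dtype=float),
        "median_mtr_asym": df["median_mtr_asym"].to_numpy(dtype=float),
    }
    correlations, _ = pearson_matrix(corr_cols)

    clustering = None
    try:
        clustering = kmeans_phenotype_cluster(df, df["phenotype"].to_numpy(), seed=cluster_seed)
        n_per["clustering"] = int((clustering.labels > 0).sum())
    except ClusteringError as exc:
        log.warning("clustering skipped: %s", exc)

    return CohortComparisonReport(
        metric_comparisons=metric_comparisons,
        location_tests=location_tests,
        covariate_tests=covariate_tests,
        regression=regression,
        correlations=correlations,
        clustering=clustering,
        n_per_analysis=n_per,
    )
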