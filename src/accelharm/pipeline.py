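"""Cohort-level statistical workflow.

Reproduces the comparability analysis on a long-format cohort table of
per-second metric values: trimming the first/last seconds of every
condition, truncating all participants to a common condition length,
grouping conditions into eight superordinate activity categories,
descriptive statistics, between-person variance, the 24 x 24 Pearson
correlation matrix over (metric, location) series, pairwise linear
conversion models, and ROC-based intensity cut-point calibration.

The cohort table is a pandas DataFrame with columns
``participant, location, condition, category, metric, second, value``.
Seconds are aligned across locations and metrics by
``(participant, condition, second)``; any misalignment is a hard error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    AlignmentError,
    ConfigurationError,
    ParameterError,
    StructuralError,
    TooShortError,
)
from .signal_core import LOCATIONS, METRICS, EpochMetricSeries

CATEGORIES = (
    "lying", "sitting", "standing", "adl",
    "climbing_stairs", "walking", "jogging", "cycling",
)

COHORT_COLUMNS = (
    "participant", "location", "condition", "category", "metric", "second", "value",
)

#: Canonical ordering of the 24 (metric, location) series labels.
SERIES_LABELS = tuple(f"{m}_{loc}" for m in METRICS for loc in LOCATIONS)


def series_label(metric: str, location: str) -> str:
    return f"{metric}_{location}"


def split_label(label: str) -> tuple[str, str]:
    metric, location = label.split("_", 1)
    return metric, location


def trim_condition(series: EpochMetricSeries, trim_s: int = 5) -> EpochMetricSeries:
    """Drop the first and last ``trim_s`` epochs of a condition.

    Removes start/stop transients (and, incidentally, the filter edge
    effects of the metric stage).
    """
    n = len(series)
    if trim_s < 0:
        raise ParameterError(f"trim_s must be >= 0, got {trim_s}")
    if n <= 2 * trim_s:
        raise TooShortError(
            f"series of {n} epochs cannot be trimmed by {trim_s} s at both ends"
        )
    return EpochMetricSeries(
        metric=series.metric,
        values=series.values[trim_s : n - trim_s],
        epoch_len=series.epoch_len,
        location=series.location,
        second_index=series.second_index[trim_s : n - trim_s],
    )


def truncate_to_common_length(
    group: list[EpochMetricSeries],
) -> list[EpochMetricSeries]:
    """Cut every series in a condition group to the group's minimum length.

    The earliest epochs are kept, so all streams stay aligned on the
    condition start. Idempotent.
    """
    if not group:
        raise StructuralError("cannot truncate an empty group of series")
    if any(len(s) == 0 for s in group):
        raise StructuralError("cannot truncate a group containing an empty series")
    n = min(len(s) for s in group)
    return [
        EpochMetricSeries(
            metric=s.metric,
            values=s.values[:n],
            epoch_len=s.epoch_len,
            location=s.location,
            second_index=s.second_index[:n],
        )
        for s in group
    ]


def assign_categories(condition_id: str, mapping: dict[str, str]) -> str:
    """Map a condition identifier onto its superordinate activity category."""
    try:
        category = mapping[condition_id]
    except KeyError:
        raise ConfigurationError(
            f"condition {condition_id!r} is not covered by the category mapping; "
            f"known conditions: {sorted(mapping)}"
        ) from None
    if category not in CATEGORIES:
        raise ConfigurationError(
            f"mapping sends {condition_id!r} to unknown category {category!r}; "
            f"valid categories: {CATEGORIES}"
        )
    return category


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Check the cohort-table contract (columns, categories, no missing values)."""
    missing = set(COHORT_COLUMNS) - set(cohort.columns)
    if missing:
        raise StructuralError(f"cohort table lacks columns: {sorted(missing)}")
    if cohort["value"].isna().any():
        raise StructuralError("cohort table contains missing values")
    bad = set(cohort["category"].unique()) - set(CATEGORIES)
    if bad:
        raise ConfigurationError(f"unknown categories in cohort: {sorted(bad)}")
    return cohort


def descriptive_table(
    cohort: pd.DataFrame, participant_means: bool = False
) -> pd.DataFrame:
    """Mean and SD per (location, category, metric).

    By default statistics pool all seconds of all participants (the same
    resolution as the second-level correlation analysis); with
    ``participant_means=True`` they are computed over per-participant mean
    values instead. SDs use the sample (n-1) denominator.
    """
    validate_cohort(cohort)
    data = cohort
    if participant_means:
        data = (
            cohort.groupby(
                ["location", "category", "metric", "participant"], observed=True
            )["value"].mean().reset_index()
        )
    out = (
        data.groupby(["location", "category", "metric"], observed=True)["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1))
        .reset_index()
    )
    return out


@dataclass
class BetweenPersonResult:
    """Between-person variance summaries.

    ``table`` holds the SD of participant means per (location, category,
    metric); ``participant_means`` the underlying means (boxplot input);
    ``location_summary`` the average of the per-category SDs per
    (location, metric) — the "average standard deviations" comparison.
    """

    table: pd.DataFrame
    participant_means: pd.DataFrame
    location_summary: pd.DataFrame


def between_person_variance(cohort: pd.DataFrame) -> BetweenPersonResult:
    """SD across participant means per (location, category, metric).

    Participant means are computed first; the SD (n-1 denominator) is then
    taken across participants. Cells with a single participant get an
    undefined (NaN) SD and are flagged with a warning.
    """
    validate_cohort(cohort)
    pmeans = (
        cohort.groupby(
            ["location", "category", "metric", "participant"], observed=True
        )["value"].mean().reset_index(name="participant_mean")
    )
    table = (
        pmeans.groupby(["location", "category", "metric"], observed=True)[
            "participant_mean"
        ]
        .agg(between_person_sd=lambda v: v.std(ddof=1), n_participants="count")
        .reset_index()
    )
    singles = table[table["n_participants"] < 2]
    if len(singles):
        warnings.warn(
            f"{len(singles)} cells have a single participant; their "
            "between-person SD is undefined",
            stacklevel=2,
        )
    location_summary = (
        table.groupby(["location", "metric"], observed=True)["between_person_sd"]
        .mean()
        .reset_index(name="mean_between_person_sd")
    )
    return BetweenPersonResult(table, pmeans, location_summary)


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson matrix over the (metric, location) series."""

    labels: tuple[str, ...]
    r: pd.DataFrame

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        if list(self.r.index) != list(self.labels) or list(self.r.columns) != list(
            self.labels
        ):
            raise StructuralError("correlation matrix axes do not match labels")

    def pair(self, label_a: str, label_b: str) -> float:
        return float(self.r.loc[label_a, label_b])

    def n_pairs(self) -> int:
        k = len(self.labels)
        return k * (k - 1) // 2


def cohort_wide(cohort: pd.DataFrame) -> pd.DataFrame:
    """Pivot the cohort to one column per (metric, location) series.

    Rows are (participant, condition, second); any missing cell means the
    series are not aligned and raises.
    """
    validate_cohort(cohort)
    labeled = cohort.assign(
        label=cohort["metric"].astype(str) + "_" + cohort["location"].astype(str)
    )
    dup = labeled.duplicated(
        subset=["participant", "condition", "second", "label"]
    )
    if dup.any():
        raise AlignmentError("duplicate (participant, condition, second, series) rows")
    wide = labeled.pivot(
        index=["participant", "condition", "second"], columns="label", values="value"
    )
    if wide.isna().any().any():
        holes = wide.columns[wide.isna().any()].tolist()
        raise AlignmentError(
            f"series not second-aligned across locations/metrics: holes in {holes}"
        )
    order = [lab for lab in SERIES_LABELS if lab in wide.columns]
    extra = [lab for lab in wide.columns if lab not in SERIES_LABELS]
    return wide[order + sorted(extra)]


def correlation_matrix(cohort: pd.DataFrame) -> CorrelationMatrix:
    """Pearson r between all (metric, location) series over pooled seconds.

    Zero-variance series yield undefined correlations, reported as NaN with
    a warning (never as 0). Diagonal entries are exactly 1.
    """
    wide = cohort_wide(cohort)
    variances = wide.var(ddof=1)
    degenerate = variances.index[variances == 0].tolist()
    if degenerate:
        warnings.warn(
            f"zero-variance series {degenerate}: correlations undefined (NaN)",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = wide.corr(method="pearson")
    for lab in degenerate:
        r.loc[lab, :] = np.nan
        r.loc[:, lab] = np.nan
    np.fill_diagonal(r.values, 1.0)
    return CorrelationMatrix(tuple(wide.columns), r)


@dataclass(frozen=True)
class ConversionModel:
    """OLS linear mapping ``target = slope * source + intercept``."""

    source: str
    target: str
    slope: float
    intercept: float
    r: float
    r2: float
    n: int
    slope_se: float
    intercept_se: float

    def predict(self, x):
        return self.slope * np.asarray(x) + self.intercept


def fit_conversion(
    source_series, target_series, source_label: str = "source",
    target_label: str = "target",
) -> ConversionModel:
    """Ordinary least squares fit of target on source over aligned seconds."""
    x = np.asarray(
        source_series.values
        if isinstance(source_series, EpochMetricSeries)
        else source_series,
        dtype=float,
    )
    y = np.asarray(
        target_series.values
        if isinstance(target_series, EpochMetricSeries)
        else target_series,
        dtype=float,
    )
    if len(x) != len(y):
        raise StructuralError(f"series lengths differ: {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise ParameterError(f"need at least 3 aligned seconds, got {len(x)}")
    if np.var(x) == 0:
        raise ParameterError(f"source series {source_label!r} has zero variance")
    fit = stats.linregress(x, y)
    r = float(fit.rvalue)
    return ConversionModel(
        source=source_label,
        target=target_label,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=r,
        r2=r * r,
        n=len(x),
        slope_se=float(fit.stderr),
        intercept_se=float(fit.intercept_stderr),
    )


def conversion_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Fit all unique pairwise conversion models between series.

    With the full 24 series this yields the 276 unordered pairs; the model
    is fitted with the first label as source.
    """
    wide = cohort_wide(cohort)
    rows = []
    cols = list(wide.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            m = fit_conversion(wide[a].values, wide[b].values, a, b)
            rows.append(
                {
                    "source": a, "target": b, "slope": m.slope,
                    "intercept": m.intercept, "r": m.r, "r2": m.r2, "n": m.n,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class Cutpoint:
    """One intensity-zone boundary with its operating characteristics."""

    metric: str
    location: str
    lower_class: str
    upper_class: str
    threshold: float
    sensitivity: float
    specificity: float
    youden_j: float
    reliable: bool


def _youden_threshold(values: np.ndarray, positive: np.ndarray):
    """Threshold maximizing Youden's J for `value >= t` predicting `positive`."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thresholds = roc_curve(positive, values, drop_intermediate=False)
    j = tpr - fpr
    best = int(np.argmax(j))
    # roc_curve's first threshold is +inf (predict nothing positive)
    t = thresholds[best] if np.isfinite(thresholds[best]) else float(np.max(values))
    # report the midpoint between the boundary value and the next value
    # below it, so the cut-point lies strictly between the classes
    below = values[values < t]
    if len(below):
        t = (t + float(np.max(below))) / 2.0
    return float(t), float(j[best]), float(tpr[best]), float(1.0 - fpr[best])


def calibrate_cutpoints(
    cohort: pd.DataFrame,
    intensity_labels: dict[str, str],
    class_order: list[str],
    min_j: float = 0.5,
) -> pd.DataFrame:
    """Calibrate intensity-zone thresholds per (metric, location).

    For every adjacent pair of intensity classes the threshold maximizing
    Youden's J (one-vs-rest at that boundary: seconds in classes above the
    boundary are positives) is selected over pooled second-level values,
    and reported with its sensitivity and specificity. Boundaries with
    J below ``min_j`` are flagged unreliable.
    """
    validate_cohort(cohort)
    if len(class_order) < 2:
        raise ParameterError("need at least two intensity classes")
    unknown = set(intensity_labels.values()) - set(class_order)
    if unknown:
        raise ConfigurationError(f"classes missing from class_order: {sorted(unknown)}")
    data = cohort[cohort["category"].isin(intensity_labels)].copy()
    data["iclass"] = data["category"].map(intensity_labels)
    rank = {c: i for i, c in enumerate(class_order)}
    for c in class_order:
        if not (data["iclass"] == c).any():
            raise ConfigurationError(f"intensity class {c!r} has no seconds")
    data["irank"] = data["iclass"].map(rank)

    rows = []
    for (metric, location), grp in data.groupby(["metric", "location"], observed=True):
        values = grp["value"].to_numpy(dtype=float)
        ranks = grp["irank"].to_numpy()
        prev_t = -np.inf
        for b in range(len(class_order) - 1):
            t, j, sens, spec = _youden_threshold(values, ranks > b)
            if t <= prev_t:
                warnings.warn(
                    f"non-increasing cut-points for {metric}/{location} at "
                    f"{class_order[b]}|{class_order[b + 1]}",
                    stacklevel=2,
                )
            prev_t = t
            rows.append(
                Cutpoint(
                    metric=metric, location=location,
                    lower_class=class_order[b], upper_class=class_order[b + 1],
                    threshold=t, sensitivity=sens, specificity=spec,
                    youden_j=j, reliable=bool(j >= min_j),
                ).__dict__
            )
    return pd.DataFrame(rows)
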