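"""Published reference tables of the six-position, four-metric comparison.

Packages the printed descriptive table (mean/SD per location x activity
category x metric; 192 cells) and the 24 x 24 Pearson correlation matrix
between all (metric, location) series, with lookup and summary operations
so the headline comparability numbers are recomputable offline.

The stored correlation values are the printed two-decimal numbers; the
printed matrix is lower-triangular and is mirrored to symmetric form with
a unit diagonal. Rounding for presentation is decimal half-up, matching
the printed precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParameterError
from .pipeline import CATEGORIES, SERIES_LABELS, split_label
from .signal_core import LOCATIONS, METRICS

TABLE1_RESOURCE = "table1_reference.csv"
TABLE2_RESOURCE = "table2_reference.csv"


def round_half_up(value: float, decimals: int) -> float:
    """Decimal half-up rounding (the convention of printed tables)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _resource_path(name: str):
    return resources.files("accelharm.data").joinpath(name)


@dataclass
class ReferenceTables:
    """Queryable copy of the printed descriptive and correlation tables."""

    table1: pd.DataFrame
    table2: pd.DataFrame

    @classmethod
    def load(cls) -> "ReferenceTables":
        t1 = pd.read_csv(_resource_path(TABLE1_RESOURCE))
        t2 = pd.read_csv(_resource_path(TABLE2_RESOURCE), index_col=0)
        obj = cls(table1=t1, table2=t2)
        obj.validate()
        return obj

    def validate(self) -> None:
        if len(self.table1) != len(LOCATIONS) * len(CATEGORIES) * len(METRICS):
            raise ConfigurationError(
                f"descriptive table has {len(self.table1)} rows, expected "
                f"{len(LOCATIONS) * len(CATEGORIES) * len(METRICS)}"
            )
        if list(self.table2.index) != list(SERIES_LABELS) or list(
            self.table2.columns
        ) != list(SERIES_LABELS):
            raise ConfigurationError("correlation table labels are not canonical")
        r = self.table2.values
        if not np.allclose(r, r.T):
            raise ConfigurationError("correlation table is not symmetric")
        if not np.all(np.diag(r) == 1.0):
            raise ConfigurationError("correlation table diagonal must be 1")
        off = r[~np.eye(len(r), dtype=bool)]
        if off.min() < 0 or off.max() > 1:
            raise ConfigurationError("correlation entries outside [0, 1]")

    # ---- descriptive-table operations -------------------------------------

    def lookup_mean(
        self, location: str, category: str, metric: str
    ) -> tuple[float, float]:
        """Printed (mean, sd) for one (location, category, metric) cell."""
        sel = self.table1[
            (self.table1["location"] == location)
            & (self.table1["category"] == category)
            & (self.table1["metric"] == metric)
        ]
        if len(sel) != 1:
            raise KeyError(
                f"no reference cell for ({location!r}, {category!r}, {metric!r}); "
                f"valid locations {LOCATIONS}, categories {CATEGORIES}, "
                f"metrics {METRICS}"
            )
        row = sel.iloc[0]
        return float(row["mean"]), float(row["sd"])

    def activity_ratio(
        self,
        location: str,
        metric: str,
        category_a: str,
        category_b: str,
        decimals: int | None = None,
    ) -> float:
        """Ratio of printed means between two activity categories."""
        mean_a, _ = self.lookup_mean(location, category_a, metric)
        mean_b, _ = self.lookup_mean(location, category_b, metric)
        if mean_b == 0:
            raise ParameterError(
                f"undefined ratio: {category_b} mean is zero at {location}/{metric}"
            )
        ratio = mean_a / mean_b
        return round_half_up(ratio, decimals) if decimals is not None else ratio

    # ---- correlation-table operations -------------------------------------

    def _within_metric_pairs(self, metric: str) -> list[tuple[str, str]]:
        labels = [lab for lab in SERIES_LABELS if split_label(lab)[0] == metric]
        if not labels:
            raise KeyError(f"unknown metric {metric!r}; valid: {METRICS}")
        return list(combinations(labels, 2))

    def _between_metric_pairs(self) -> list[tuple[str, str]]:
        pairs = []
        for loc in LOCATIONS:
            labels = [lab for lab in SERIES_LABELS if split_label(lab)[1] == loc]
            pairs.extend(combinations(labels, 2))
        return pairs

    def within_metric_between_location_mean_r(
        self, metrics, decimals: int | None = None
    ) -> float:
        """Mean of the between-location correlations within the metric(s).

        One metric has 15 location pairs; pooling several metrics averages
        over all their pairs (45 for three metrics).
        """
        if isinstance(metrics, str):
            metrics = (metrics,)
        pairs = [p for m in metrics for p in self._within_metric_pairs(m)]
        vals = [self.table2.loc[a, b] for a, b in pairs]
        mean = float(np.mean(vals))
        return round_half_up(mean, decimals) if decimals is not None else mean

    def extreme_pair(
        self, scope: str, which: str
    ) -> list[tuple[str, str, float]]:
        """Arg-extreme correlation over a pair family.

        ``scope`` is ``within_metric_between_location`` (60 pairs: 15
        location pairs x 4 metrics) or ``between_metric_within_location``
        (36 pairs: 6 metric pairs x 6 locations); ``which`` is min or max.
        All pairs tied at the stored two-decimal precision are returned.
        """
        if scope == "within_metric_between_location":
            pairs = [p for m in METRICS for p in self._within_metric_pairs(m)]
        elif scope == "between_metric_within_location":
            pairs = self._between_metric_pairs()
        else:
            raise ParameterError(f"unknown scope {scope!r}")
        if which not in ("min", "max"):
            raise ParameterError(f"which must be min or max, got {which!r}")
        vals = np.array([self.table2.loc[a, b] for a, b in pairs])
        extreme = vals.min() if which == "min" else vals.max()
        return [
            (a, b, float(v)) for (a, b), v in zip(pairs, vals) if v == extreme
        ]

    def headline_summaries(self) -> dict[str, float]:
        """The published comparability summary numbers, recomputed."""
        summaries = {
            "mean_r_within_cpm": self.within_metric_between_location_mean_r(
                "CPM", decimals=2
            ),
            "mean_r_within_mai_enmo_mad": self.within_metric_between_location_mean_r(
                ("MAI", "ENMO", "MAD"), decimals=1
            ),
            "min_r_within_metric": self.extreme_pair(
                "within_metric_between_location", "min"
            )[0][2],
            "max_r_within_metric": self.extreme_pair(
                "within_metric_between_location", "max"
            )[0][2],
            "max_r_between_metric": self.extreme_pair(
                "between_metric_within_location", "max"
            )[0][2],
            "r_chest_mad_cpm": float(self.table2.loc["MAD_chest", "CPM_chest"]),
            "ratio_jogging_cycling_thigh_cpm": self.activity_ratio(
                "thigh", "CPM", "jogging", "cycling", decimals=1
            ),
            "ratio_jogging_cycling_hip_cpm": self.activity_ratio(
                "hip", "CPM", "jogging", "cycling", decimals=1
            ),
            "ratio_jogging_cycling_thigh_enmo": self.activity_ratio(
                "thigh", "ENMO", "jogging", "cycling", decimals=1
            ),
        }
        return summaries
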