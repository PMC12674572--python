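"""Readers, writers, run configuration and the end-to-end workflow.

The interchange format is delimited text throughout: raw signals are CSV
with header ``time,x,y,z`` (time in seconds or sample index, acceleration
in g, gzip-transparent), cohorts are long-format CSV with columns
``participant,location,condition,category,metric,second,value``.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, ParameterError, StructuralError
from .pipeline import (
    COHORT_COLUMNS,
    assign_categories,
    between_person_variance,
    calibrate_cutpoints,
    conversion_table,
    correlation_matrix,
    descriptive_table,
    trim_condition,
    truncate_to_common_length,
    validate_cohort,
)
from .signal_core import (
    CountConfig,
    EpochMetricSeries,
    FilterSpec,
    RawTriaxialSignal,
    compute_counts,
    compute_enmo,
    compute_mad,
    compute_mai,
    counts_to_cpm,
)
from .synthetic import CohortBundle

CATEGORY_MAP_RESOURCE = "condition_categories.yaml"

#: Default intensity-zone assignment used by cut-point calibration.
DEFAULT_INTENSITY_LABELS = {
    "lying": "sedentary",
    "sitting": "sedentary",
    "standing": "light",
    "adl": "light",
    "walking": "moderate",
    "climbing_stairs": "moderate",
    "cycling": "moderate",
    "jogging": "vigorous",
}
DEFAULT_CLASS_ORDER = ("sedentary", "light", "moderate", "vigorous")


def load_category_map(path=None) -> dict[str, str]:
    """Condition -> category mapping (packaged 32-entry default)."""
    if path is None:
        text = resources.files("accelharm.data").joinpath(
            CATEGORY_MAP_RESOURCE
        ).read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    mapping = yaml.safe_load(text)
    if not isinstance(mapping, dict) or not mapping:
        raise ConfigurationError("category mapping must be a non-empty mapping")
    return {str(k): str(v) for k, v in mapping.items()}


def read_raw_csv(
    path, fs: float | None = None, fs_tolerance: float = 0.01
) -> RawTriaxialSignal:
    """Read a raw triaxial CSV into a validated signal.

    The sampling rate is inferred from the time column; when ``fs`` is
    given too, a mismatch beyond ``fs_tolerance`` (relative) is an error.
    A time column of consecutive integers is treated as a sample index
    (requires ``fs``).
    """
    frame = pd.read_csv(path)
    frame.columns = [c.strip().lower() for c in frame.columns]
    missing = {"time", "x", "y", "z"} - set(frame.columns)
    if missing:
        raise StructuralError(f"{path}: missing column(s) {sorted(missing)}")
    for col in ("time", "x", "y", "z"):
        bad = frame.index[frame[col].isna() | ~np.isfinite(frame[col].astype(float))]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise StructuralError(
                f"{path}: non-finite value in column {col!r} at row {bad[0] + 2}"
            )
    time = frame["time"].to_numpy(dtype=float)
    if len(time) > 1:
        dt = np.diff(time)
        if np.any(dt <= 0):
            row = int(np.argmax(dt <= 0)) + 2
            raise StructuralError(f"{path}: non-monotone time at row {row}")
        index_like = np.allclose(dt, 1.0) and np.allclose(time, np.round(time))
        if index_like and fs is not None and fs != 1.0:
            inferred = fs  # sample-index convention
        else:
            inferred = 1.0 / float(np.median(dt))
        if fs is not None and abs(inferred - fs) / fs > fs_tolerance:
            raise ParameterError(
                f"{path}: timestamps imply {inferred:.3f} Hz, configured {fs} Hz "
                f"(mismatch > {fs_tolerance:.0%})"
            )
    else:
        if fs is None:
            raise ParameterError(f"{path}: single-sample file needs an explicit fs")
        inferred = fs
    return RawTriaxialSignal(
        fs=float(fs if fs is not None else inferred),
        x=frame["x"].to_numpy(dtype=float),
        y=frame["y"].to_numpy(dtype=float),
        z=frame["z"].to_numpy(dtype=float),
        t0=float(time[0]),
    )


def write_raw_csv(signal: RawTriaxialSignal, path) -> None:
    t = signal.t0 + np.arange(signal.n_samples) / signal.fs
    pd.DataFrame(
        {"time": t, "x": signal.x, "y": signal.y, "z": signal.z}
    ).to_csv(path, index=False, float_format="%.6f")


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    validate_cohort(cohort)
    cohort.loc[:, COHORT_COLUMNS].to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    return validate_cohort(pd.read_csv(path))


@dataclass
class RunConfig:
    """Resolved scientific parameters of one pipeline run.

    Every value here appears verbatim in the machine-readable run report;
    nothing is silently defaulted downstream.
    """

    filter: FilterSpec = field(default_factory=FilterSpec)
    counts: CountConfig = field(default_factory=CountConfig)
    trim_s: int = 5
    epoch_len: float = 1.0
    seed: int = 0
    category_map_path: str | None = None
    intensity_labels: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_INTENSITY_LABELS)
    )
    class_order: tuple[str, ...] = DEFAULT_CLASS_ORDER

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        metrics = raw.get("metrics", {})
        kwargs = {}
        if "filter" in metrics:
            kwargs["filter"] = FilterSpec(**metrics["filter"])
        if "counts" in metrics:
            kwargs["counts"] = CountConfig(**metrics["counts"])
        for key in ("trim_s", "epoch_len", "seed", "category_map_path"):
            if key in raw:
                kwargs[key] = raw[key]
        if "intensity_labels" in raw:
            kwargs["intensity_labels"] = dict(raw["intensity_labels"])
        if "class_order" in raw:
            kwargs["class_order"] = tuple(raw["class_order"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["class_order"] = list(self.class_order)
        return d


def metrics_from_signal(
    signal: RawTriaxialSignal, config: RunConfig
) -> dict[str, EpochMetricSeries]:
    """All four per-second metric series for one raw stream.

    CPM is the per-second upscaling (epoch counts x 60), the form used for
    second-level correlations; condition-level CPM descriptives follow from
    averaging it, since mean(60 c_i) equals 60 mean(c_i).
    """
    counts, _ = compute_counts(signal, config.counts, config.epoch_len)
    return {
        "MAI": compute_mai(signal, config.filter, config.epoch_len),
        "ENMO": compute_enmo(signal, config.epoch_len),
        "MAD": compute_mad(signal, config.epoch_len),
        "CPM": counts_to_cpm(counts, "per_second"),
    }


def assemble_cohort(
    signals: dict[tuple[str, str, str], RawTriaxialSignal],
    config: RunConfig,
    category_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Raw signals -> trimmed, truncated, categorised long cohort table.

    Keys of ``signals`` are (participant, condition, location). Per
    condition, every stream (all participants, locations and metrics) is
    cut to the common minimum length so seconds stay aligned.
    """
    if not signals:
        raise StructuralError("no signals to assemble")
    if category_map is None:
        category_map = load_category_map(config.category_map_path)

    per_condition: dict[str, list[tuple[str, str, str, EpochMetricSeries]]] = {}
    for (pid, cond, loc), signal in signals.items():
        for metric, series in metrics_from_signal(signal, config).items():
            trimmed = trim_condition(series, config.trim_s)
            per_condition.setdefault(cond, []).append((pid, loc, metric, trimmed))

    frames = []
    for cond, entries in per_condition.items():
        category = assign_categories(cond, category_map)
        truncated = truncate_to_common_length([s for *_, s in entries])
        for (pid, loc, metric, _), series in zip(entries, truncated):
            frames.append(
                pd.DataFrame(
                    {
                        "participant": pid,
                        "location": loc,
                        "condition": cond,
                        "category": category,
                        "metric": metric,
                        "second": np.arange(len(series)),
                        "value": series.values,
                    }
                )
            )
    cohort = pd.concat(frames, ignore_index=True)
    return validate_cohort(cohort)


def run_end_to_end(
    config: RunConfig,
    signals: dict[tuple[str, str, str], RawTriaxialSignal] | CohortBundle,
    outdir,
) -> dict[str, Path]:
    """Full workflow: metrics -> trim -> truncate -> group -> statistics.

    Writes ``cohort.csv``, ``descriptives.csv``, ``between_person.csv``,
    ``correlations.csv``, ``conversions.csv``, ``cutpoints.csv`` and a
    ``run_report.json`` (package/library versions, config, config hash)
    into ``outdir``; returns the paths.
    """
    if isinstance(signals, CohortBundle):
        signals = signals.signals
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cohort = assemble_cohort(signals, config)
    descriptives = descriptive_table(cohort)
    between = between_person_variance(cohort)
    corr = correlation_matrix(cohort)
    conversions = conversion_table(cohort)
    # restrict the intensity ladder to classes whose categories are present
    present = set(cohort["category"].unique())
    labels = {
        cat: cls for cat, cls in config.intensity_labels.items() if cat in present
    }
    order = [c for c in config.class_order if c in set(labels.values())]
    if len(order) >= 2:
        cutpoints = calibrate_cutpoints(cohort, labels, order)
    else:
        cutpoints = pd.DataFrame(
            columns=["metric", "location", "lower_class", "upper_class",
                     "threshold", "sensitivity", "specificity", "youden_j",
                     "reliable"]
        )

    paths = {}
    writers = {
        "cohort": (cohort, "cohort.csv"),
        "descriptives": (descriptives, "descriptives.csv"),
        "between_person": (between.table, "between_person.csv"),
        "between_person_location_summary": (
            between.location_summary, "between_person_location_summary.csv",
        ),
        "conversions": (conversions, "conversions.csv"),
        "cutpoints": (cutpoints, "cutpoints.csv"),
    }
    for key, (frame, name) in writers.items():
        paths[key] = outdir / name
        frame.to_csv(paths[key], index=False)
    paths["correlations"] = outdir / "correlations.csv"
    corr.r.to_csv(paths["correlations"])

    config_dict = config.to_dict()
    config_json = json.dumps(config_dict, sort_keys=True, default=str)
    report = {
        "package": {"name": "accelharm", "version": __version__},
        "python": platform.python_version(),
        "libraries": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "config": config_dict,
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": config.seed,
        "n_signals": len(signals),
        "n_cohort_rows": int(len(cohort)),
        "n_correlation_series": len(corr.labels),
    }
    paths["run_report"] = outdir / "run_report.json"
    paths["run_report"].write_text(json.dumps(report, indent=2, default=str))
    return paths


def write_bundle(bundle: CohortBundle, outdir) -> dict[str, Path]:
    """Write a simulated bundle as one CSV per signal plus the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = bundle.manifest.copy()
    filenames = []
    for _, row in manifest.iterrows():
        name = f"{row['participant']}__{row['condition']}__{row['location']}.csv"
        write_raw_csv(
            bundle.signals[(row["participant"], row["condition"], row["location"])],
            outdir / name,
        )
        filenames.append(name)
    manifest["filename"] = filenames
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return {"manifest": outdir / "manifest.csv", "outdir": outdir}


def read_bundle_signals(
    raw_dir, fs: float = 64.0
) -> dict[tuple[str, str, str], RawTriaxialSignal]:
    """Read back a simulated (or equivalent) raw directory via its manifest."""
    raw_dir = Path(raw_dir)
    manifest_path = raw_dir / "manifest.csv"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.csv in {raw_dir}")
    manifest = pd.read_csv(manifest_path)
    required = {"participant", "condition", "location", "filename"}
    missing = required - set(manifest.columns)
    if missing:
        raise StructuralError(f"manifest lacks columns {sorted(missing)}")
    return {
        (row["participant"], row["condition"], row["location"]): read_raw_csv(
            raw_dir / row["filename"], fs=fs
        )
        for _, row in manifest.iterrows()
    }
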