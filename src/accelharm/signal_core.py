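"""Per-second movement-intensity metrics from raw triaxial acceleration.

Implements the four metrics commonly used to summarise wearable
accelerometer data:

* **MAI** (movement acceleration intensity): Butterworth band-pass
  (0.25-11 Hz, 4th order) applied to each axis, Euclidean norm of the
  filtered axes, averaged per epoch, expressed in mg.
* **ENMO** (Euclidean norm minus one): per-sample ``max(|a| - 1, 0)``,
  averaged per epoch, in mg.
* **MAD** (mean amplitude deviation): per epoch, the mean absolute
  deviation of the vector magnitude from its epoch mean, in mg.
* **Activity counts** in the ActiGraph lineage: per axis, resample,
  band-pass in a narrow human-movement band, clip, rectify, apply a
  deadband, quantize to ADC levels and count levels beyond a threshold;
  counts are summed per epoch and combined across axes by Euclidean norm.

All metrics aggregate over half-open epochs ``[k*epoch_len, (k+1)*epoch_len)``
anchored at the signal start; a trailing partial epoch is dropped.  Values
are kept in g-derived units internally and converted to mg exactly once,
at epoch aggregation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Literal

import numpy as np
from scipy import signal as sps

from .errors import ParameterError, StructuralError

METRICS = ("MAI", "ENMO", "MAD", "CPM")
LOCATIONS = ("ankle", "chest", "hip", "thigh", "upper_arm", "wrist")

MAX_RANGE_G = 16.0  # sensor dynamic range is +/- 16 g


@dataclass(frozen=True)
class RawTriaxialSignal:
    """Uniformly sampled triaxial acceleration in g.

    Parameters
    ----------
    fs : float
        Sampling rate in Hz (nominally 64).
    x, y, z : array-like
        Equal-length acceleration traces in g.
    t0 : float
        Start time in seconds (epoch anchor).
    """

    fs: float
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        for axis in ("x", "y", "z"):
            object.__setattr__(
                self, axis, np.asarray(getattr(self, axis), dtype=float)
            )
        if not (self.x.ndim == self.y.ndim == self.z.ndim == 1):
            raise StructuralError("axes must be one-dimensional")
        if not (len(self.x) == len(self.y) == len(self.z)):
            raise StructuralError(
                f"axis lengths differ: x={len(self.x)} y={len(self.y)} z={len(self.z)}"
            )
        if len(self.x) < 1:
            raise StructuralError("signal must contain at least one sample")
        if self.fs <= 0:
            raise ParameterError(f"sampling rate must be positive, got {self.fs}")
        for axis in ("x", "y", "z"):
            a = getattr(self, axis)
            if not np.all(np.isfinite(a)):
                raise StructuralError(f"non-finite sample in axis {axis}")
            if np.any(np.abs(a) > MAX_RANGE_G):
                raise StructuralError(
                    f"axis {axis} exceeds the +/-{MAX_RANGE_G:g} g sensor range"
                )

    @property
    def n_samples(self) -> int:
        return len(self.x)

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return self.n_samples / self.fs

    def as_array(self) -> np.ndarray:
        """Return an (n, 3) array of the three axes."""
        return np.column_stack([self.x, self.y, self.z])


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass filter used by the MAI metric.

    ``order`` is the Butterworth design order of the band-pass prototype.
    ``phase`` selects causal (single-pass, streaming-compatible) or
    zero-phase (forward-backward) application; causal is the default
    because commercial pipelines process streams causally.
    """

    low_hz: float = 0.25
    high_hz: float = 11.0
    order: int = 4
    phase: Literal["causal", "zero_phase"] = "causal"
    kind: Literal["butterworth_bandpass"] = "butterworth_bandpass"

    def validate(self, fs: float) -> None:
        if self.order < 1:
            raise ParameterError(f"filter order must be >= 1, got {self.order}")
        if not (0.0 < self.low_hz < self.high_hz):
            raise ParameterError(
                f"need 0 < low_hz < high_hz, got {self.low_hz}, {self.high_hz}"
            )
        if self.high_hz >= fs / 2:
            raise ParameterError(
                f"high corner {self.high_hz} Hz is not below Nyquist ({fs / 2} Hz)"
            )
        if self.phase not in ("causal", "zero_phase"):
            raise ParameterError(f"unknown phase mode {self.phase!r}")

    def sos(self, fs: float) -> np.ndarray:
        self.validate(fs)
        return sps.butter(
            self.order, [self.low_hz, self.high_hz], btype="bandpass",
            fs=fs, output="sos",
        )


@dataclass(frozen=True)
class CountConfig:
    """Constants of the activity-count algorithm.

    The rectified signal is quantized with a 12-bit converter whose
    resolution is ``peak_g / 2**adc_bits`` g per level; every level beyond
    ``deadband_levels`` contributes one count.  At the defaults the level
    threshold (128 levels = 0.0666 g) coincides with ``deadband_g`` = 0.068 g,
    so the analog deadband and the level threshold describe the same floor.
    """

    resample_hz: float = 30.0
    band_low_hz: float = 0.29
    band_high_hz: float = 1.63
    peak_g: float = 2.13
    deadband_g: float = 0.068
    adc_bits: int = 12
    deadband_levels: int = 128
    filter_order: int = 4

    def validate(self, fs: float) -> None:
        if not (self.peak_g > self.deadband_g >= 0):
            raise ParameterError("need peak_g > deadband_g >= 0")
        if not (8 <= self.adc_bits <= 16):
            raise ParameterError(f"adc_bits must be in 8..16, got {self.adc_bits}")
        if self.deadband_levels < 0:
            raise ParameterError("deadband_levels must be >= 0")
        if self.resample_hz > fs:
            raise ParameterError(
                f"resample_hz {self.resample_hz} exceeds signal rate {fs}; "
                "upsampling is not supported"
            )
        if not (0 < self.band_low_hz < self.band_high_hz < self.resample_hz / 2):
            raise ParameterError("count band corners must lie below resample Nyquist")

    @property
    def adc_resolution_g(self) -> float:
        """Quantization step in g per ADC level."""
        return self.peak_g / 2 ** self.adc_bits


@dataclass
class EpochMetricSeries:
    """Per-epoch values of one metric for one signal stream.

    ``values`` are in mg for MAI/ENMO/MAD, raw counts for ``counts`` and
    counts-per-minute-scaled for CPM.  ``second_index`` gives the epoch
    offsets (in epochs) relative to the signal start.
    """

    metric: str
    values: np.ndarray
    epoch_len: float = 1.0
    location: str | None = None
    second_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.epoch_len <= 0:
            raise ParameterError(f"epoch_len must be positive, got {self.epoch_len}")
        if self.second_index is None:
            self.second_index = np.arange(len(self.values))
        else:
            self.second_index = np.asarray(self.second_index, dtype=int)
        if len(self.second_index) != len(self.values):
            raise StructuralError("second_index and values lengths differ")
        if len(self.values) and np.nanmin(self.values) < 0:
            raise StructuralError(f"negative {self.metric} value")

    def __len__(self) -> int:
        return len(self.values)


def vector_magnitude(signal: RawTriaxialSignal) -> np.ndarray:
    """Per-sample Euclidean norm of the three axes, in g."""
    return np.sqrt(signal.x ** 2 + signal.y ** 2 + signal.z ** 2)


def _epoch_view(values: np.ndarray, fs: float, epoch_len: float) -> np.ndarray:
    """Reshape a per-sample array into (n_epochs, samples_per_epoch).

    Epochs are half-open windows of ``round(fs * epoch_len)`` samples; a
    trailing partial epoch is dropped.
    """
    if epoch_len <= 0:
        raise ParameterError(f"epoch_len must be positive, got {epoch_len}")
    spe = int(round(fs * epoch_len))
    if spe < 1 or len(values) < spe:
        raise ParameterError(
            f"signal shorter ({len(values)} samples) than one epoch ({spe} samples)"
        )
    n_epochs = len(values) // spe
    return values[: n_epochs * spe].reshape(n_epochs, spe)


def compute_mai(
    signal: RawTriaxialSignal,
    filt: FilterSpec = FilterSpec(),
    epoch_len: float = 1.0,
) -> EpochMetricSeries:
    """Movement acceleration intensity per epoch, in mg.

    Each axis is band-pass filtered (gravity and non-movement content are
    outside the pass band), the per-sample Euclidean norm of the filtered
    axes is taken and averaged per epoch.
    """
    sos = filt.sos(signal.fs)
    axes = signal.as_array()
    if filt.phase == "zero_phase":
        filtered = sps.sosfiltfilt(sos, axes, axis=0)
    else:
        filtered = sps.sosfilt(sos, axes, axis=0)
    norm = np.sqrt(np.sum(filtered ** 2, axis=1))
    means = _epoch_view(norm, signal.fs, epoch_len).mean(axis=1)
    return EpochMetricSeries("MAI", means * 1000.0, epoch_len)


def compute_enmo(
    signal: RawTriaxialSignal, epoch_len: float = 1.0
) -> EpochMetricSeries:
    """Euclidean norm minus one per epoch, in mg (negatives clipped)."""
    r = np.maximum(vector_magnitude(signal) - 1.0, 0.0)
    means = _epoch_view(r, signal.fs, epoch_len).mean(axis=1)
    return EpochMetricSeries("ENMO", means * 1000.0, epoch_len)


def compute_mad(
    signal: RawTriaxialSignal, epoch_len: float = 1.0
) -> EpochMetricSeries:
    """Mean amplitude deviation per epoch, in mg.

    The static (gravity) component is removed by subtracting the epoch mean
    of the vector magnitude rather than by filtering.
    """
    r = _epoch_view(vector_magnitude(signal), signal.fs, epoch_len)
    mad = np.abs(r - r.mean(axis=1, keepdims=True)).mean(axis=1)
    return EpochMetricSeries("MAD", mad * 1000.0, epoch_len)


@dataclass
class AxisCounts:
    """Per-axis integer epoch counts plus their vector-magnitude combination."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    @property
    def vm(self) -> np.ndarray:
        return np.sqrt(
            self.x.astype(float) ** 2 + self.y ** 2 + self.z ** 2
        )


def _count_one_axis(
    samples: np.ndarray, fs: float, cfg: CountConfig, epoch_len: float
) -> np.ndarray:
    frac = Fraction(cfg.resample_hz / fs).limit_denominator(1000)
    resampled = sps.resample_poly(samples, frac.numerator, frac.denominator)
    sos = sps.butter(
        cfg.filter_order, [cfg.band_low_hz, cfg.band_high_hz],
        btype="bandpass", fs=cfg.resample_hz, output="sos",
    )
    filtered = sps.sosfilt(sos, resampled)
    clipped = np.clip(filtered, -cfg.peak_g, cfg.peak_g)
    rectified = np.abs(clipped)
    rectified[rectified < cfg.deadband_g] = 0.0
    levels = np.floor(rectified / cfg.adc_resolution_g)
    counts = np.maximum(levels - cfg.deadband_levels, 0.0)
    per_epoch = _epoch_view(counts, cfg.resample_hz, epoch_len).sum(axis=1)
    return per_epoch.astype(np.int64)


def compute_counts(
    signal: RawTriaxialSignal,
    cfg: CountConfig = CountConfig(),
    epoch_len: float = 1.0,
) -> tuple[EpochMetricSeries, AxisCounts]:
    """Activity counts per epoch.

    Returns the vector-magnitude count series (``metric='counts'``) together
    with the per-axis integer counts it combines.
    """
    cfg.validate(signal.fs)
    per_axis = AxisCounts(
        x=_count_one_axis(signal.x, signal.fs, cfg, epoch_len),
        y=_count_one_axis(signal.y, signal.fs, cfg, epoch_len),
        z=_count_one_axis(signal.z, signal.fs, cfg, epoch_len),
    )
    return EpochMetricSeries("counts", per_axis.vm, epoch_len), per_axis


def counts_to_cpm(
    epoch_counts: EpochMetricSeries,
    mode: Literal["per_second", "per_condition"] = "per_second",
):
    """Upscale one-second counts to counts per minute.

    ``per_second`` multiplies each epoch value by 60 (used for second-level
    correlations; a constant rescaling that leaves Pearson r unchanged).
    ``per_condition`` averages over the condition's epochs and multiplies by
    60, returning a scalar (used for descriptive tables).
    """
    if not math.isclose(epoch_counts.epoch_len, 1.0):
        raise ParameterError("CPM upscaling requires 1-second epochs")
    if len(epoch_counts) == 0:
        raise ParameterError("cannot upscale an empty count series")
    if mode == "per_second":
        return replace(
            epoch_counts, metric="CPM", values=epoch_counts.values * 60.0
        )
    if mode == "per_condition":
        return float(np.mean(epoch_counts.values) * 60.0)
    raise ParameterError(f"unknown CPM mode {mode!r}")
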