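"""Unit and property tests of the four movement-intensity metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import signal as sps
from scipy.spatial.transform import Rotation

from accelharm.errors import ParameterError, StructuralError
from accelharm.signal_core import (
    CountConfig,
    EpochMetricSeries,
    FilterSpec,
    RawTriaxialSignal,
    compute_counts,
    compute_enmo,
    compute_mad,
    compute_mai,
    counts_to_cpm,
    vector_magnitude,
)

from conftest import constant_signal, random_signal, sine_magnitude_signal

FS = 64.0


class TestVectorMagnitude:
    def test_unit_gravity(self):
        assert vector_magnitude(constant_signal(z=1.0)).tolist() == pytest.approx(
            [1.0] * 640
        )

    def test_three_four_five_triangle(self):
        sig = constant_signal(x=3e-3, y=4e-3, z=0.0, duration_s=1.0)
        assert vector_magnitude(sig) == pytest.approx(np.full(64, 5e-3))

    def test_matches_per_sample_loop(self):
        rng = np.random.default_rng(0)
        sig = random_signal(rng, duration_s=1.0)
        loop = [
            (sig.x[i] ** 2 + sig.y[i] ** 2 + sig.z[i] ** 2) ** 0.5
            for i in range(sig.n_samples)
        ]
        np.testing.assert_allclose(vector_magnitude(sig), loop, rtol=1e-12)

    def test_unequal_axes_rejected(self):
        with pytest.raises(StructuralError):
            RawTriaxialSignal(fs=FS, x=[0.0, 0.0], y=[0.0], z=[0.0])


class TestMai:
    def test_dc_is_outside_pass_band(self):
        values = compute_mai(constant_signal(z=1.0, duration_s=30.0)).values
        # the causal 0.25 Hz corner needs ~15 s to ring down below 1 mg
        assert np.all(values[15:] <= 1.0)

    def test_in_band_sinusoid_matches_filter_gain(self):
        # magnitude of the band-passed 2 Hz component is amplitude * |H(2)|;
        # the epoch mean of its absolute value is 2/pi of that, in mg
        filt = FilterSpec()
        t = np.arange(0.0, 40.0, 1.0 / FS)
        z = 1.0 + 0.2 * np.sin(2.0 * np.pi * 2.0 * t)
        sig = RawTriaxialSignal(fs=FS, x=np.zeros_like(t), y=np.zeros_like(t), z=z)
        _, h = sps.sosfreqz(filt.sos(FS), worN=[2.0], fs=FS)
        gain = float(np.abs(h[0]))
        expected = 1000.0 * 0.2 * gain * 2.0 / np.pi
        steady = compute_mai(sig, filt).values[15:-5]
        assert np.mean(steady) == pytest.approx(expected, rel=5e-3)
        assert expected == pytest.approx(2.0 * 200.0 / np.pi, rel=0.05)

    def test_stop_band_sinusoid_attenuated(self):
        t = np.arange(0.0, 40.0, 1.0 / FS)
        mk = lambda f: RawTriaxialSignal(
            fs=FS, x=np.zeros_like(t), y=np.zeros_like(t),
            z=1.0 + 0.2 * np.sin(2.0 * np.pi * f * t),
        )
        in_band = compute_mai(mk(2.0)).values[15:-5].mean()
        stop_band = compute_mai(mk(20.0)).values[15:-5].mean()
        assert stop_band < in_band / 10

    def test_zero_phase_mode(self):
        sig = sine_magnitude_signal(0.2, freq_hz=2.0, duration_s=40.0)
        filt = FilterSpec(phase="zero_phase")
        steady = compute_mai(sig, filt).values[15:-15]
        assert np.mean(steady) == pytest.approx(2.0 * 200.0 / np.pi, rel=5e-3)

    def test_parameter_errors(self):
        sig = constant_signal(duration_s=2.0)
        with pytest.raises(ParameterError):
            compute_mai(sig, FilterSpec(high_hz=40.0))  # >= Nyquist at 64 Hz
        with pytest.raises(ParameterError):
            compute_mai(sig, epoch_len=0.0)


class TestEnmo:
    def test_exact_cancellation_at_one_g(self):
        assert compute_enmo(constant_signal(z=1.0)).values == pytest.approx(0.0)

    def test_negative_clipped(self):
        assert compute_enmo(constant_signal(z=0.5)).values == pytest.approx(0.0)

    def test_half_sine_closed_form(self):
        # mean of max(A sin, 0) over a full period is A/pi
        values = compute_enmo(sine_magnitude_signal(0.3)).values
        assert values == pytest.approx(1000.0 * 0.3 / np.pi, rel=5e-3)


class TestMad:
    def test_constant_magnitude_is_zero(self):
        assert compute_mad(constant_signal(z=1.2)).values == pytest.approx(0.0)

    def test_alternating_magnitude(self):
        n = 640
        r = np.where(np.arange(n) % 2 == 0, 0.9, 1.1)
        sig = RawTriaxialSignal(fs=FS, x=r, y=np.zeros(n), z=np.zeros(n))
        assert compute_mad(sig).values == pytest.approx(100.0)

    def test_full_sine_closed_form(self):
        # mean |A sin| over a full period is 2A/pi
        values = compute_mad(sine_magnitude_signal(0.3)).values
        assert values == pytest.approx(1000.0 * 2.0 * 0.3 / np.pi, rel=5e-3)


class TestScaleCovariance:
    @pytest.mark.parametrize("c", [0.5, 2.0, 3.7])
    def test_enmo_mad_scale_with_amplitude(self, c):
        base_enmo = compute_enmo(sine_magnitude_signal(0.1)).values.mean()
        base_mad = compute_mad(sine_magnitude_signal(0.1)).values.mean()
        scaled_enmo = compute_enmo(sine_magnitude_signal(0.1 * c)).values.mean()
        scaled_mad = compute_mad(sine_magnitude_signal(0.1 * c)).values.mean()
        assert scaled_enmo == pytest.approx(c * base_enmo, rel=1e-2)
        assert scaled_mad == pytest.approx(c * base_mad, rel=1e-2)

    @pytest.mark.parametrize("c", [0.5, 2.0])
    def test_mai_linear_in_amplitude(self, c):
        t = np.arange(0.0, 30.0, 1.0 / FS)

        def mai_mean(a):
            z = 1.0 + a * np.sin(2.0 * np.pi * 2.0 * t)
            sig = RawTriaxialSignal(
                fs=FS, x=np.zeros_like(t), y=np.zeros_like(t), z=z
            )
            return compute_mai(sig).values[15:-5].mean()

        # linear up to the (unscaled) DC-step transient tail in the window
        assert mai_mean(0.1 * c) == pytest.approx(c * mai_mean(0.1), rel=1e-3)


class TestRotationInvariance:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_enmo_mad_invariant_under_rotation(self, seed):
        rng = np.random.default_rng(seed)
        sig = random_signal(rng)
        rot = Rotation.random(rng=np.random.default_rng(seed + 100)).as_matrix()
        rotated_axes = sig.as_array() @ rot.T
        rotated = RawTriaxialSignal(
            fs=FS, x=rotated_axes[:, 0], y=rotated_axes[:, 1], z=rotated_axes[:, 2]
        )
        np.testing.assert_allclose(
            compute_enmo(sig).values, compute_enmo(rotated).values,
            rtol=1e-10, atol=1e-9,
        )
        np.testing.assert_allclose(
            compute_mad(sig).values, compute_mad(rotated).values,
            rtol=1e-10, atol=1e-9,
        )


def naive_enmo(sig, epoch_len=1.0):
    spe = int(round(sig.fs * epoch_len))
    out = []
    for k in range(sig.n_samples // spe):
        acc = 0.0
        for i in range(k * spe, (k + 1) * spe):
            r = (sig.x[i] ** 2 + sig.y[i] ** 2 + sig.z[i] ** 2) ** 0.5
            acc += max(r - 1.0, 0.0)
        out.append(1000.0 * acc / spe)
    return np.array(out)


def naive_mad(sig, epoch_len=1.0):
    spe = int(round(sig.fs * epoch_len))
    out = []
    for k in range(sig.n_samples // spe):
        rs = [
            (sig.x[i] ** 2 + sig.y[i] ** 2 + sig.z[i] ** 2) ** 0.5
            for i in range(k * spe, (k + 1) * spe)
        ]
        mean_r = sum(rs) / spe
        out.append(1000.0 * sum(abs(r - mean_r) for r in rs) / spe)
    return np.array(out)


def naive_mai(sig, filt, epoch_len=1.0):
    sos = filt.sos(sig.fs)
    fx = sps.sosfilt(sos, sig.x)
    fy = sps.sosfilt(sos, sig.y)
    fz = sps.sosfilt(sos, sig.z)
    spe = int(round(sig.fs * epoch_len))
    out = []
    for k in range(sig.n_samples // spe):
        acc = 0.0
        for i in range(k * spe, (k + 1) * spe):
            acc += (fx[i] ** 2 + fy[i] ** 2 + fz[i] ** 2) ** 0.5
        out.append(1000.0 * acc / spe)
    return np.array(out)


def naive_counts(sig, cfg, epoch_len=1.0):
    """Independent stage-by-stage count reference with explicit loops."""
    from fractions import Fraction

    per_axis = []
    for samples in (sig.x, sig.y, sig.z):
        frac = Fraction(cfg.resample_hz / sig.fs).limit_denominator(1000)
        res = sps.resample_poly(samples, frac.numerator, frac.denominator)
        sos = sps.butter(
            cfg.filter_order, [cfg.band_low_hz, cfg.band_high_hz],
            btype="bandpass", fs=cfg.resample_hz, output="sos",
        )
        filt = sps.sosfilt(sos, res)
        counts = []
        for v in filt:
            v = min(max(v, -cfg.peak_g), cfg.peak_g)
            v = abs(v)
            if v < cfg.deadband_g:
                v = 0.0
            level = int(v // (cfg.peak_g / 2 ** cfg.adc_bits))
            counts.append(max(level - cfg.deadband_levels, 0))
        spe = int(round(cfg.resample_hz * epoch_len))
        per_axis.append(
            [sum(counts[k * spe : (k + 1) * spe]) for k in range(len(counts) // spe)]
        )
    cx, cy, cz = (np.array(a, dtype=np.int64) for a in per_axis)
    return cx, cy, cz, np.sqrt(cx.astype(float) ** 2 + cy ** 2 + cz ** 2)


class TestCounts:
    def test_all_zero_signal(self):
        sig = constant_signal(x=0.0, y=0.0, z=0.0, duration_s=5.0)
        vm, per_axis = compute_counts(sig)
        assert np.all(vm.values == 0)
        assert np.all(per_axis.x == 0)

    def test_static_gravity_zero_in_steady_state(self):
        vm, _ = compute_counts(constant_signal(z=1.0, duration_s=30.0))
        assert np.all(vm.values[10:] == 0)

    def test_matches_stage_by_stage_oracle(self):
        t = np.arange(0.0, 60.0, 1.0 / FS)
        sig = RawTriaxialSignal(
            fs=FS,
            x=0.5 * np.sin(2.0 * np.pi * 2.0 * t),
            y=0.3 * np.sin(2.0 * np.pi * 1.0 * t + 0.4),
            z=1.0 + 0.2 * np.sin(2.0 * np.pi * 0.7 * t),
        )
        cfg = CountConfig()
        vm, per_axis = compute_counts(sig, cfg)
        ox, oy, oz, ovm = naive_counts(sig, cfg)
        np.testing.assert_array_equal(per_axis.x, ox)
        np.testing.assert_array_equal(per_axis.y, oy)
        np.testing.assert_array_equal(per_axis.z, oz)
        np.testing.assert_allclose(vm.values, ovm, rtol=1e-12)
        assert per_axis.x.dtype == np.int64  # per-axis epoch counts are integers

    def test_no_upsampling(self):
        sig = constant_signal(duration_s=2.0)
        with pytest.raises(ParameterError):
            compute_counts(sig, CountConfig(resample_hz=128.0))


class TestLoopOracleEquivalence:
    """Vectorized metrics equal the naive per-sample loop on random signals."""

    @pytest.mark.parametrize("seed", [10, 11])
    def test_all_metrics(self, seed):
        rng = np.random.default_rng(seed)
        sig = random_signal(rng, duration_s=5.0)
        filt = FilterSpec()
        np.testing.assert_allclose(
            compute_enmo(sig).values, naive_enmo(sig), rtol=1e-9
        )
        np.testing.assert_allclose(
            compute_mad(sig).values, naive_mad(sig), rtol=1e-9
        )
        np.testing.assert_allclose(
            compute_mai(sig, filt).values, naive_mai(sig, filt), rtol=1e-9
        )


class TestCpm:
    def test_per_condition_mean(self):
        series = EpochMetricSeries("counts", [10.0, 20.0, 30.0])
        assert counts_to_cpm(series, "per_condition") == pytest.approx(1200.0)

    def test_per_second(self):
        series = EpochMetricSeries("counts", [10.0, 20.0, 30.0])
        out = counts_to_cpm(series, "per_second")
        assert out.metric == "CPM"
        assert out.values.tolist() == [600.0, 1200.0, 1800.0]

    def test_zero_counts(self):
        series = EpochMetricSeries("counts", [0.0, 0.0])
        assert counts_to_cpm(series, "per_condition") == 0.0

    def test_empty_series_rejected(self):
        with pytest.raises(ParameterError):
            counts_to_cpm(EpochMetricSeries("counts", []), "per_condition")


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    data=hnp.arrays(
        np.float64,
        shape=st.integers(64, 256).map(lambda n: (n, 3)),
        elements=st.floats(-15.9, 15.9, allow_nan=False),
    )
)
def test_metrics_are_non_negative(data):
    """Every metric is non-negative for arbitrary finite in-range input."""
    sig = RawTriaxialSignal(fs=FS, x=data[:, 0], y=data[:, 1], z=data[:, 2])
    assert np.all(compute_enmo(sig).values >= 0)
    assert np.all(compute_mad(sig).values >= 0)
    assert np.all(compute_mai(sig).values >= 0)
    vm, _ = compute_counts(sig)
    assert np.all(vm.values >= 0)
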