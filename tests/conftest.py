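import numpy as np
import pytest

from accelharm.io import RunConfig, assemble_cohort
from accelharm.signal_core import RawTriaxialSignal
from accelharm.synthetic import CohortConfig, simulate_cohort

FS = 64.0


def sine_magnitude_signal(amplitude, freq_hz=1.0, duration_s=10.0, fs=FS):
    """Signal whose vector magnitude is exactly 1 + amplitude*sin(2 pi f t)."""
    t = np.arange(0.0, duration_s, 1.0 / fs)
    r = 1.0 + amplitude * np.sin(2.0 * np.pi * freq_hz * t)
    zeros = np.zeros_like(t)
    return RawTriaxialSignal(fs=fs, x=r, y=zeros, z=zeros)


def constant_signal(x=0.0, y=0.0, z=1.0, duration_s=10.0, fs=FS):
    n = int(round(duration_s * fs))
    return RawTriaxialSignal(
        fs=fs, x=np.full(n, x), y=np.full(n, y), z=np.full(n, z)
    )


def random_signal(rng, duration_s=5.0, fs=FS, scale=0.5):
    n = int(round(duration_s * fs))
    return RawTriaxialSignal(
        fs=fs,
        x=1.0 + scale * rng.standard_normal(n).clip(-10, 10) * 0.1,
        y=scale * rng.standard_normal(n).clip(-10, 10) * 0.1,
        z=scale * rng.standard_normal(n).clip(-10, 10) * 0.1,
    )


@pytest.fixture(scope="session")
def small_bundle():
    """Reduced synthetic cohort: 4 participants, quarter-length conditions.

    Profile structure (amplitudes, sigmas, orderings) is the shipped
    default; only the problem size is reduced to keep the suite fast.
    """
    cfg = CohortConfig(n_participants=4, seed=11, duration_scale=0.25)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort(small_bundle):
    return assemble_cohort(small_bundle.signals, RunConfig(seed=11))


@pytest.fixture(scope="session")
def reference_tables():
    from accelharm.reference import ReferenceTables

    return ReferenceTables.load()
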