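"""Synthetic cohort generator.

Emulates a laboratory protocol in which every participant performs a list
of activity conditions while wearing sensors at six body positions. Each
generated stream is

``a(t) = g_hat * 1 g  +  m_pc * sum_k w_k A sin(2 pi k f t + phi_k) * u_hat
+ white noise``,

where ``g_hat`` is the posture-dependent gravity orientation (unit
vector), ``A`` the location-dependent movement amplitude, ``f`` the
activity fundamental with harmonic weights ``w_k``, ``u_hat`` the movement
axis (defaults to the gravity axis: dominant vertical oscillation) and
``m_pc`` a lognormal per-(participant, category) amplitude multiplier that
carries all between-person variability.

Randomness is fully deterministic under (seed, config): phases and noise
are drawn from substreams keyed by (condition, location) — shared across
participants — and multipliers from substreams keyed by (participant,
category). With a between-person sigma of zero all participants therefore
produce bit-identical signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, ParameterError
from .signal_core import LOCATIONS, RawTriaxialSignal, EpochMetricSeries

PROFILES_RESOURCE = "default_profiles.yaml"

# substream domains (keep rng keys disjoint across uses)
_DOMAIN_MULTIPLIER = 1
_DOMAIN_CONDITION = 2


@dataclass(frozen=True)
class LocationProfile:
    """Signal-model parameters of one activity at one sensor location."""

    gravity_orientation: tuple[float, float, float]
    dynamic_amplitude_mg: float
    fundamental_hz: float
    harmonic_weights: dict[int, float]
    noise_sd_mg: float
    movement_axis: tuple[float, float, float] | None = None

    def validate(self) -> None:
        g = np.asarray(self.gravity_orientation, dtype=float)
        if not np.isclose(np.linalg.norm(g), 1.0, atol=1e-9):
            raise ConfigurationError(
                f"gravity orientation {self.gravity_orientation} is not a unit vector"
            )
        if self.dynamic_amplitude_mg < 0:
            raise ConfigurationError("dynamic amplitude must be >= 0")
        if not (0.0 < self.fundamental_hz < 32.0):
            raise ConfigurationError(
                f"fundamental {self.fundamental_hz} Hz outside (0, 32)"
            )


@dataclass(frozen=True)
class ActivityProfile:
    """One activity condition: category plus per-location signal parameters."""

    condition: str
    category: str
    duration_s: float
    between_person_sigma: float
    locations: dict[str, LocationProfile]

    def validate(self) -> None:
        if self.duration_s < 30:
            raise ConfigurationError(
                f"{self.condition}: duration {self.duration_s} s must be >= 30 s "
                "to survive trimming"
            )
        for lp in self.locations.values():
            lp.validate()


@dataclass(frozen=True)
class CohortConfig:
    """Shape of the simulated cohort.

    ``between_person_sd`` overrides every profile's lognormal sigma when
    not None (0 disables between-person variability entirely).
    ``duration_scale`` shrinks condition durations uniformly, for fast
    test-scale cohorts; the floor of 30 s keeps trimming safe.
    """

    n_participants: int = 20
    locations: tuple[str, ...] = LOCATIONS
    seed: int = 0
    fs: float = 64.0
    between_person_sd: float | None = None
    duration_scale: float = 1.0
    conditions: tuple[str, ...] | None = None  # None = all profiled conditions

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ParameterError("n_participants must be >= 1")
        if self.duration_scale <= 0:
            raise ParameterError("duration_scale must be positive")
        unknown = set(self.locations) - set(LOCATIONS)
        if unknown:
            raise ConfigurationError(f"unknown locations: {sorted(unknown)}")


def load_profiles(path=None) -> dict[str, ActivityProfile]:
    """Load activity profiles from YAML (packaged default set if no path)."""
    if path is None:
        text = resources.files("accelharm.data").joinpath(
            PROFILES_RESOURCE
        ).read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    harmonics = {int(k): float(v) for k, v in raw.get("harmonics", {1: 1.0}).items()}
    profiles: dict[str, ActivityProfile] = {}
    for cond, entry in raw["conditions"].items():
        cat = entry["category"]
        try:
            cat_params = raw["categories"][cat]
        except KeyError:
            raise ConfigurationError(
                f"condition {cond!r} references unprofiled category {cat!r}"
            ) from None
        gravity = cat_params["gravity"]
        scale = float(entry.get("scale", 1.0))
        locs = {}
        for loc, amp in cat_params["amplitude_mg"].items():
            g = gravity.get(loc, gravity["default"])
            locs[loc] = LocationProfile(
                gravity_orientation=tuple(float(v) for v in g),
                dynamic_amplitude_mg=float(amp) * scale,
                fundamental_hz=float(cat_params["fundamental_hz"]),
                harmonic_weights=harmonics,
                noise_sd_mg=float(cat_params["noise_sd_mg"]),
            )
        profile = ActivityProfile(
            condition=cond,
            category=cat,
            duration_s=float(entry["duration_s"]),
            between_person_sigma=float(cat_params["between_person_sigma"]),
            locations=locs,
        )
        profile.validate()
        profiles[cond] = profile
    return profiles


def simulate_condition(
    profile: ActivityProfile,
    location: str,
    duration_s: float,
    participant_multiplier: float,
    rng: np.random.Generator,
    fs: float = 64.0,
) -> RawTriaxialSignal:
    """Generate one raw triaxial stream for one condition at one location."""
    if duration_s < 1.0:
        raise ParameterError(f"duration {duration_s} s must be >= 1 s")
    try:
        lp = profile.locations[location]
    except KeyError:
        raise ConfigurationError(
            f"profile {profile.condition!r} has no parameters for {location!r}"
        ) from None
    lp.validate()
    g_hat = np.asarray(lp.gravity_orientation, dtype=float)
    u_hat = (
        np.asarray(lp.movement_axis, dtype=float)
        if lp.movement_axis is not None
        else g_hat
    )
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    dynamic = np.zeros(n)
    amp_g = lp.dynamic_amplitude_mg / 1000.0
    for k, w in sorted(lp.harmonic_weights.items()):
        phi = rng.uniform(0.0, 2.0 * np.pi)
        dynamic += w * amp_g * np.sin(2.0 * np.pi * k * lp.fundamental_hz * t + phi)
    noise = rng.normal(0.0, lp.noise_sd_mg / 1000.0, size=(n, 3))
    samples = (
        g_hat[None, :]
        + participant_multiplier * dynamic[:, None] * u_hat[None, :]
        + noise
    )
    return RawTriaxialSignal(
        fs=fs, x=samples[:, 0], y=samples[:, 1], z=samples[:, 2]
    )


@dataclass
class CohortBundle:
    """Simulated raw signals plus the ground-truth manifest."""

    signals: dict[tuple[str, str, str], RawTriaxialSignal]
    manifest: pd.DataFrame
    config: CohortConfig
    profiles: dict[str, ActivityProfile] = field(repr=False, default=None)


def _participant_ids(n: int) -> list[str]:
    return [f"P{p + 1:02d}" for p in range(n)]


def simulate_cohort(
    cfg: CohortConfig, profiles: dict[str, ActivityProfile] | None = None
) -> CohortBundle:
    """Simulate one raw stream per (participant, condition, location).

    The manifest records every multiplier and resolved profile parameter so
    recovery tests can compare pipeline output against ground truth.
    """
    if profiles is None:
        profiles = load_profiles()
    conditions = list(cfg.conditions) if cfg.conditions else list(profiles)
    missing = [c for c in conditions if c not in profiles]
    if missing:
        raise ConfigurationError(f"no profile for conditions: {missing}")
    for cond in conditions:
        absent = set(cfg.locations) - set(profiles[cond].locations)
        if absent:
            raise ConfigurationError(
                f"profile {cond!r} lacks locations {sorted(absent)}"
            )

    participants = _participant_ids(cfg.n_participants)
    categories = sorted({profiles[c].category for c in conditions})

    multipliers: dict[tuple[str, str], float] = {}
    for pi, pid in enumerate(participants):
        for ci, cat in enumerate(categories):
            sigma = (
                cfg.between_person_sd
                if cfg.between_person_sd is not None
                else next(
                    profiles[c].between_person_sigma
                    for c in conditions
                    if profiles[c].category == cat
                )
            )
            rng = np.random.default_rng(
                np.random.SeedSequence([cfg.seed, _DOMAIN_MULTIPLIER, pi, ci])
            )
            # lognormal with median 1; sigma 0 degenerates to exactly 1
            multipliers[(pid, cat)] = (
                float(np.exp(rng.normal(0.0, sigma))) if sigma > 0 else 1.0
            )

    signals: dict[tuple[str, str, str], RawTriaxialSignal] = {}
    rows = []
    for ki, cond in enumerate(conditions):
        profile = profiles[cond]
        duration = max(30.0, profile.duration_s * cfg.duration_scale)
        for li, loc in enumerate(cfg.locations):
            for pid in participants:
                # identical per-(condition, location) substream for every
                # participant: between-person differences enter only via
                # the amplitude multiplier
                rng = np.random.default_rng(
                    np.random.SeedSequence([cfg.seed, _DOMAIN_CONDITION, ki, li])
                )
                mult = multipliers[(pid, profile.category)]
                signals[(pid, cond, loc)] = simulate_condition(
                    profile, loc, duration, mult, rng, fs=cfg.fs
                )
                lp = profile.locations[loc]
                rows.append(
                    {
                        "participant": pid,
                        "condition": cond,
                        "category": profile.category,
                        "location": loc,
                        "duration_s": duration,
                        "multiplier": mult,
                        "amplitude_mg": lp.dynamic_amplitude_mg,
                        "fundamental_hz": lp.fundamental_hz,
                        "noise_sd_mg": lp.noise_sd_mg,
                    }
                )
    manifest = pd.DataFrame(rows)
    return CohortBundle(signals=signals, manifest=manifest, config=cfg,
                        profiles=profiles)


def linear_pair_cohort(
    a: float,
    b: float,
    noise_sd: float,
    n_seconds: int,
    seed: int,
    source_metric: str = "MAD",
    target_metric: str = "CPM",
) -> tuple[EpochMetricSeries, EpochMetricSeries]:
    """Aligned second-level pair with known linear ground truth.

    ``target = a * source + b + N(0, noise_sd)``; negative target seconds
    are clipped to zero (metric values are non-negative), so choose ``a``,
    ``b`` and ``noise_sd`` such that clipping is negligible when exact
    recovery matters.
    """
    if n_seconds < 10:
        raise ParameterError(f"n_seconds must be >= 10, got {n_seconds}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    source = rng.uniform(50.0, 500.0, n_seconds)
    target = a * source + b + rng.normal(0.0, noise_sd, n_seconds)
    target = np.maximum(target, 0.0)
    return (
        EpochMetricSeries(source_metric, source),
        EpochMetricSeries(target_metric, target),
    )


def saturating_pair_cohort(
    vmax: float,
    half_sat: float,
    noise_sd: float,
    n_seconds: int,
    seed: int,
) -> tuple[EpochMetricSeries, EpochMetricSeries]:
    """Aligned pair where the target saturates in the source.

    ``target = vmax * source / (half_sat + source) + noise``; emulates a
    count-like metric that compresses high intensities, so its Pearson r
    with the source is lower than an equally noisy linear pairing's.
    """
    if n_seconds < 10:
        raise ParameterError(f"n_seconds must be >= 10, got {n_seconds}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    source = rng.uniform(50.0, 500.0, n_seconds)
    target = vmax * source / (half_sat + source) + rng.normal(
        0.0, noise_sd, n_seconds
    )
    target = np.maximum(target, 0.0)
    return EpochMetricSeries("MAD", source), EpochMetricSeries("CPM", target)
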