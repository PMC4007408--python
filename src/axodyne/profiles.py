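"""Condition parameter profiles.

Each experimental condition (WT, aSyn, aSyn+WldS, aSyn+PGC1a) is described by a
:class:`ConditionProfile` bundling four parameter blocks:

* :class:`TransportProfile` — axonal mitochondrial transport kinetics
  (motile fraction, run speeds, run/pause dwell times, directional bias),
* :class:`MorphologyProfile` — mitochondrial density and shape,
* :class:`AxonopathyProfile` — the 5-point axonopathy stage distribution at
  2 dpf and its day-to-day Markov evolution,
* :class:`TimingProfile` — Wallerian-degeneration lag/clearance kinetics and
  the lead time of axonopathy onset before soma death.

Shipped default values live in ``data/condition_profiles.yaml`` and encode the
in-vivo measurements for larval zebrafish Rohon-Beard neurons expressing human
wild-type α-synuclein (and the WldS / PGC-1α co-expression conditions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "TransportProfile",
    "MorphologyProfile",
    "AxonopathyProfile",
    "TimingProfile",
    "ConditionProfile",
    "SimConfig",
    "load_profiles",
    "load_default_profiles",
    "get_profile",
    "save_profiles",
    "CONDITIONS",
]

CONDITIONS = ("WT", "aSyn", "aSyn+WldS", "aSyn+PGC1a")


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be a probability in [0, 1], got {value}")


def _check_pos(name: str, value: float) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be > 0, got {value}")


@dataclass(frozen=True)
class TransportProfile:
    """Run/pause/reverse kinetics of axonal mitochondria.

    Motility is a latent per-mitochondrion Bernoulli label
    (``motile_fraction``).  Motile organelles follow an alternating renewal
    process with exponential run and pause dwell times; each run picks the
    retrograde direction with probability ``prob_next_run_retrograde`` and a
    speed from a direction-specific normal distribution.

    ``target_time_fraction_paused`` is the long-run expected fraction of time
    a motile mitochondrion spends paused; for consistency it must equal
    ``mean_pause_duration / (mean_pause_duration + mean_run_duration)``.
    """

    motile_fraction: float
    anterograde_run_speed_mean: float  # μm/s
    anterograde_run_speed_sd: float
    retrograde_run_speed_mean: float  # μm/s
    retrograde_run_speed_sd: float
    mean_run_duration: float  # s
    mean_pause_duration: float  # s
    prob_next_run_retrograde: float
    target_time_fraction_paused: float

    def __post_init__(self) -> None:
        _check_prob("motile_fraction", self.motile_fraction)
        _check_prob("prob_next_run_retrograde", self.prob_next_run_retrograde)
        _check_prob("target_time_fraction_paused", self.target_time_fraction_paused)
        for name in (
            "anterograde_run_speed_mean",
            "retrograde_run_speed_mean",
            "mean_run_duration",
            "mean_pause_duration",
        ):
            _check_pos(name, getattr(self, name))
        for name in ("anterograde_run_speed_sd", "retrograde_run_speed_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        implied = self.mean_pause_duration / (
            self.mean_pause_duration + self.mean_run_duration
        )
        if abs(implied - self.target_time_fraction_paused) > 0.01:
            raise ValueError(
                "target_time_fraction_paused inconsistent with dwell times: "
                f"implied {implied:.4f}, declared {self.target_time_fraction_paused:.4f}"
            )


@dataclass(frozen=True)
class MorphologyProfile:
    """Mitochondrial density and shape along the axon.

    Length:width aspect ratios are sampled from a shifted log-normal
    (support ≥ 1) whose mean equals ``aspect_ratio_mean`` exactly; a
    ``swollen_fraction`` of organelles are spherical (ratio 1) with an
    enlarged minor axis, emulating pathological swelling.
    """

    density_per_100um: float
    aspect_ratio_mean: float
    aspect_ratio_sd: float
    mito_minor_axis_um: float
    swollen_fraction: float

    def __post_init__(self) -> None:
        if self.density_per_100um < 0:
            raise ValueError("density_per_100um must be >= 0")
        if self.aspect_ratio_mean < 1:
            raise ValueError("aspect_ratio_mean must be >= 1")
        if self.aspect_ratio_sd < 0:
            raise ValueError("aspect_ratio_sd must be >= 0")
        _check_pos("mito_minor_axis_um", self.mito_minor_axis_um)
        _check_prob("swollen_fraction", self.swollen_fraction)


@dataclass(frozen=True)
class AxonopathyProfile:
    """Stage distribution at 2 dpf and per-day monotone Markov transitions."""

    stage_probabilities_at_2dpf: tuple[float, ...]
    stage_transition_matrix_per_day: tuple[tuple[float, ...], ...]
    death_given_stage5: float

    def __post_init__(self) -> None:
        p = np.asarray(self.stage_probabilities_at_2dpf, dtype=float)
        if p.shape != (5,) or not math.isclose(p.sum(), 1.0, abs_tol=1e-6):
            raise ValueError("stage_probabilities_at_2dpf must be a 5-vector summing to 1")
        m = np.asarray(self.stage_transition_matrix_per_day, dtype=float)
        if m.shape != (5, 5):
            raise ValueError("stage_transition_matrix_per_day must be 5x5")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("transition matrix rows must sum to 1")
        if np.any(np.tril(m, k=-1) > 1e-12):
            raise ValueError("transitions to lower stages are forbidden (monotone degeneration)")
        _check_prob("death_given_stage5", self.death_given_stage5)

    @property
    def stage_probs(self) -> np.ndarray:
        return np.asarray(self.stage_probabilities_at_2dpf, dtype=float)

    @property
    def transition_matrix(self) -> np.ndarray:
        return np.asarray(self.stage_transition_matrix_per_day, dtype=float)


@dataclass(frozen=True)
class TimingProfile:
    """Wallerian-degeneration and axonopathy-onset timing parameters (minutes)."""

    lag_mean: float
    lag_sd: float
    clearance_mean: float
    clearance_sd: float
    axonopathy_onset_lead_hours: float
    sampling_interval: float  # minutes

    def __post_init__(self) -> None:
        for name in ("lag_mean", "clearance_mean", "sampling_interval"):
            _check_pos(name, getattr(self, name))
        for name in ("lag_sd", "clearance_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.axonopathy_onset_lead_hours <= 0:
            raise ValueError("axonopathy_onset_lead_hours must be > 0")


@dataclass(frozen=True)
class ConditionProfile:
    """Full parameter bundle for one experimental condition."""

    name: str
    transport: TransportProfile
    morphology: MorphologyProfile
    axonopathy: AxonopathyProfile
    timing: TimingProfile
    survival_2to3dpf: float
    new_expression_rate: float

    def __post_init__(self) -> None:
        _check_prob("survival_2to3dpf", self.survival_2to3dpf)
        _check_prob("new_expression_rate", self.new_expression_rate)


@dataclass(frozen=True)
class SimConfig:
    """Acquisition geometry and optics for the synthetic microscope.

    Defaults emulate confocal time-lapse imaging of a single optical section
    at ~1 Hz for 6 minutes over a 50-μm axon segment, at a 40×/3×-zoom pixel
    scale (0.2 μm/px) with a 0.3-μm PSF and 8-bit dynamic range.
    """

    pixel_size_um: float = 0.2
    frame_interval_s: float = 1.0
    movie_duration_s: float = 360.0
    segment_length_um: float = 50.0
    noise_sigma: float = 10.0
    psf_sigma_um: float = 0.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        _check_pos("pixel_size_um", self.pixel_size_um)
        _check_pos("frame_interval_s", self.frame_interval_s)
        _check_pos("segment_length_um", self.segment_length_um)
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_frames < 2:
            raise ValueError("movie must span at least 2 frames")

    @property
    def n_frames(self) -> int:
        return int(round(self.movie_duration_s / self.frame_interval_s))


# ---------------------------------------------------------------------------
# YAML (de)serialization


def _profile_from_dict(name: str, d: dict) -> ConditionProfile:
    ax = d["axonopathy"]
    return ConditionProfile(
        name=name,
        transport=TransportProfile(**d["transport"]),
        morphology=MorphologyProfile(**d["morphology"]),
        axonopathy=AxonopathyProfile(
            stage_probabilities_at_2dpf=tuple(ax["stage_probabilities_at_2dpf"]),
            stage_transition_matrix_per_day=tuple(
                tuple(row) for row in ax["stage_transition_matrix_per_day"]
            ),
            death_given_stage5=ax["death_given_stage5"],
        ),
        timing=TimingProfile(**d["timing"]),
        survival_2to3dpf=d["survival_2to3dpf"],
        new_expression_rate=d["new_expression_rate"],
    )


def load_profiles(path: str | Path) -> dict[str, ConditionProfile]:
    """Load condition profiles from a YAML file keyed by condition name."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    conditions = raw["conditions"] if "conditions" in raw else raw
    return {name: _profile_from_dict(name, d) for name, d in conditions.items()}


def load_default_profiles() -> dict[str, ConditionProfile]:
    """Load the profiles shipped with the package."""
    ref = resources.files("axodyne").joinpath("data/condition_profiles.yaml")
    with resources.as_file(ref) as path:
        return load_profiles(path)


def get_profile(name: str) -> ConditionProfile:
    """Return the shipped profile for one condition (e.g. ``"WT"``)."""
    profiles = load_default_profiles()
    try:
        return profiles[name]
    except KeyError:
        raise KeyError(f"unknown condition {name!r}; available: {sorted(profiles)}") from None


def save_profiles(profiles: dict[str, ConditionProfile], path: str | Path) -> None:
    out = {"schema_version": 1, "conditions": {}}
    for name, prof in profiles.items():
        d = asdict(prof)
        d.pop("name")
        d["axonopathy"]["stage_probabilities_at_2dpf"] = list(
            d["axonopathy"]["stage_probabilities_at_2dpf"]
        )
        d["axonopathy"]["stage_transition_matrix_per_day"] = [
            list(row) for row in d["axonopathy"]["stage_transition_matrix_per_day"]
        ]
        out["conditions"][name] = d
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)
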