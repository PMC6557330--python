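"""Configuration dataclasses for the simulator and analysis pipeline.

Defaults mirror the free-swimming assay conditions: a 35 mm arena imaged at
24.8 px/mm, fish kinematics at 700 Hz, full-frame prey video at 17.5 Hz,
~80 paramecia, and two-photon imaging at 3.6 Hz.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value}")


@dataclass
class BehaviorSimConfig:
    """Parameters of the synthetic free-swimming hunting assay.

    Angles are degrees, lengths mm, times s, rates Hz unless noted.
    """

    arena_diameter: float = 35.0          # mm, Petri dish
    px_per_mm: float = 24.8
    rate_hi: float = 700.0                # kinematics sampling rate
    rate_lo: float = 17.5                 # full-frame prey video rate
    duration: float = 60.0                # session length, s
    n_prey: int = 80
    hunt_rate: float = 3.0                # routine initiations per minute
    p_abort: float = 0.60
    p_ram_given_attempt: float = 0.25
    p_success_given_attempt: float = 0.50
    p_negative_gain_abort: float = 0.37   # abort routines ending in a negative-gain bout
    p_negative_gain_attempt: float = 0.09
    vergence_baseline_deg: float = 15.0
    vergence_baseline_sd: float = 3.0
    vergence_hunting_deg: float = 55.0
    vergence_hunting_sd: float = 5.0
    bout_rate: float = 1.0                # spontaneous bouts per second outside hunting
    bout_duration: float = 0.150          # s, raised-cosine displacement profile
    tail_beat_hz: float = 20.0
    tail_noise_sd: float = 0.1            # deg, per segment-sum sample
    prey_speed: float = 1.0               # mm/s, OU process stationary mean speed
    prey_tau: float = 1.0                 # s, OU velocity relaxation time
    escape_rate: float = 0.0              # escapes per minute (0: none)
    eye_offset_mm: float = 0.1            # eyes-center forward of body centroid
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_abort", "p_ram_given_attempt", "p_success_given_attempt",
                     "p_negative_gain_abort", "p_negative_gain_attempt"):
            _check_prob(name, getattr(self, name))
        for name in ("rate_hi", "rate_lo", "px_per_mm", "duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.arena_diameter <= 0:
            raise ValueError("arena_diameter must be > 0")
        if self.n_prey < 0:
            raise ValueError("n_prey must be >= 0")
        if self.n_prey == 0 and self.hunt_rate > 0:
            raise ValueError("cannot hunt with n_prey=0; set hunt_rate=0")


@dataclass
class CalciumSimConfig:
    """Parameters of the synthetic trial-structured calcium recording."""

    n_cells: dict[str, int] = field(default_factory=lambda: {
        "aCh-A": 40, "pCh-A": 40, "Ch-B": 30, "OT": 60, "pretectum": 30})
    frame_rate: float = 3.6               # Hz, frame-scanning rate
    kernel_tau: float = 3.0               # s, nuclear GCaMP6s decay
    noise_sd: float = 1.0                 # fluorescence units
    # cell-class mixture fractions; remainder is silent
    mixture: dict[str, float] = field(default_factory=lambda: {
        "whole-field": 0.25, "spot-CW": 0.08, "spot-CCW": 0.08,
        "loom-phasic": 0.08, "loom-sustained": 0.06,
        "dimming-nonselective": 0.05, "convergence-modulated": 0.15})
    go_fraction: float = 0.25             # probability a prey-spot trial is GO
    n_repeats: int = 30                   # repetitions per stimulus type
    isi: float = 10.0                     # inter-stimulus interval, s
    spont_conv_rate: float = 1.0          # spontaneous convergences per minute
    response_amplitude: float = 5.0       # event amplitude, fluorescence units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.kernel_tau <= 0:
            raise ValueError("kernel_tau must be > 0")
        _check_prob("go_fraction", self.go_fraction)
        total = sum(self.mixture.values())
        if total > 1.0 + 1e-9:
            raise ValueError(f"mixture fractions sum to {total} > 1")
        if any(v < 0 for v in self.mixture.values()):
            raise ValueError("mixture fractions must be >= 0")


@dataclass
class TrackingConfig:
    """Video-tracking thresholds (intensity units on background-subtracted frames)."""

    background_update_rate: float = 0.02
    body_threshold: float = 40.0
    eye_threshold: float = 80.0
    body_area_limits: tuple[float, float] = (100.0, 6000.0)  # px^2
    eye_area_limits: tuple[float, float] = (5.0, 400.0)
    eye_search_radius_px: float = 25.0
    tail_n_points: int = 9
    tail_sector_deg: float = 60.0         # half-width of forward scan sector
    prey_sigma_px: float = 7.0            # Gaussian smoothing before peak finding
    prey_min_prominence: float = 3.0
    prey_max_value: float = 30.0          # peaks above this are the fish, not prey
    max_link_distance_px: float = 15.0
    gap_frames: int = 2


@dataclass
class KinematicsConfig:
    """Vergence, bout and escape segmentation constants."""

    bout_velocity_threshold: float = 500.0     # deg/s on smoothed cumulative tail angle
    bout_onset_floor: float = 100.0            # deg/s, onset/offset refinement floor
    bout_merge_gap: float = 0.030              # s
    bout_min_duration: float = 0.020           # s
    epoch_merge_gap: float = 0.070             # s
    epoch_min_duration: float = 0.100          # s
    escape_speed_threshold: float = 75.0       # mm/s
    savgol_window: int = 21                    # samples at 700 Hz
    savgol_order: int = 3
    mixture_n_init: int = 10
    mixture_tol: float = 1e-6
    mixture_min_weight: float = 0.02
    mixture_min_separation_sd: float = 3.0     # mode separation in pooled SDs


@dataclass
class HuntingConfig:
    """Target criterion and gain bookkeeping constants."""

    max_target_distance_mm: float = 6.0
    max_target_azimuth_deg: float = 120.0
    eye_offset_mm: float = 0.1
    field_at: str = "epoch_onset"              # or "first_bout"


@dataclass
class NeuralConfig:
    """CMI and clustering constants."""

    cmi_window: float = 4.0                    # s, centered on convergence
    cmi_positive_cutoff: float = 3.0
    min_nogo: int = 3
    n_perm: int = 1000
    strict_corr: float = 0.9                   # stage-1 dendrogram cut
    lenient_corr: float = 0.7                  # stage-3 cut
    centroid_dist_limit: float = 0.5
    archetype_min_size: int = 5
    flat_eps: float = 1e-6
    vrv_tail: float = 5.0                      # s appended after each stimulus epoch


@dataclass
class PipelineConfig:
    behavior: BehaviorSimConfig = field(default_factory=BehaviorSimConfig)
    calcium: CalciumSimConfig = field(default_factory=CalciumSimConfig)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    kinematics: KinematicsConfig = field(default_factory=KinematicsConfig)
    hunting: HuntingConfig = field(default_factory=HuntingConfig)
    neural: NeuralConfig = field(default_factory=NeuralConfig)
    seed: int = 0


def _to_dict(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_dict(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_dict(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def save_config(config: Any, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_dict(config), fh, sort_keys=False)


_SECTION_TYPES = {
    "behavior": BehaviorSimConfig, "calcium": CalciumSimConfig,
    "tracking": TrackingConfig, "kinematics": KinematicsConfig,
    "hunting": HuntingConfig, "neural": NeuralConfig,
}


def load_pipeline_config(path: str) -> PipelineConfig:
    """Load a PipelineConfig from YAML; unknown fields raise, values are validated."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict[str, Any] = {}
    for key, value in raw.items():
        if key == "seed":
            kwargs["seed"] = int(value)
            continue
        if key not in _SECTION_TYPES:
            raise ValueError(f"unknown config section: {key}")
        cls = _SECTION_TYPES[key]
        names = {f.name for f in dataclasses.fields(cls)}
        bad = set(value) - names
        if bad:
            raise ValueError(f"unknown field(s) in {key}: {sorted(bad)}")
        sub = dict(value)
        for f in dataclasses.fields(cls):
            if f.name in sub and isinstance(getattr(cls, f.name, None), tuple):
                sub[f.name] = tuple(sub[f.name])
        kwargs[key] = cls(**sub)
    return PipelineConfig(**kwargs)
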