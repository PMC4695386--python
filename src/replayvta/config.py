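"""Configuration objects: simulation settings and analysis constants."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from ._utils import config_hash


@dataclass
class SimConfig:
    """Parameters of the synthetic session generator.

    The defaults describe a single linear-track recording: a rat shuttling
    between two reward wells on a 200 cm track, ~30 hippocampal place cells
    recorded clusterlessly on 5 tetrodes, and a handful of VTA units whose
    firing carries reward responses, SPW-R-locked gain at a fixed lag, and
    von Mises theta locking.
    """

    seed: int = 0
    task: str = "linear"  # {"linear", "swm"}
    track_length_cm: float = 200.0
    swm_arm_cm: float = 75.0
    swm_central_cm: float = 150.0

    # hippocampus
    n_place_cells: int = 30
    place_field_width_cm: float = 20.0  # FWHM of the Gaussian tuning curve
    place_peak_hz: float = 15.0
    pause_rate_hz: float = 0.25  # per-cell rate outside events during pauses
    theta_freq_hz: float = 8.0
    theta_depth: float = 0.7  # run-epoch rate modulation depth
    n_tetrodes: int = 5
    mark_sd_uv: float = 15.0
    mark_min_separation_uv: float = 40.0
    mark_lo_uv: float = 120.0
    mark_hi_uv: float = 320.0

    # SPW-R events during pauses
    spwr_rate_hz: float = 0.25
    replay_fraction: float = 0.25
    replay_speed_cms: float = 200.0
    event_duration_s: tuple = (0.1, 0.3)  # uniform draw
    event_gain: float = 8.0  # burst gain on tuning-curve rates inside events
    reward_bias: float = 0.5  # probability a replayed trajectory starts in a reward region

    # VTA
    n_vta_units: int = 6
    vta_baseline_hz: float = 6.0
    rr_fraction: float = 0.55
    rr_correct_gain: float = 2.5  # acquisition-window gain on correct trials
    rr_error_gain: float = 1.0
    vta_spwr_gain: float = 3.0
    vta_lag_ms: float = 84.0
    couple_reward_only: bool = False  # gain only in reward-region trajectory bins
    kappa_true: float = 0.15
    mu_true_deg: float = 0.0

    # behavior
    n_trials: int = 30
    error_rate: float = 0.25
    run_speed_cms: float = 40.0
    dwell_median_s: float = 9.0
    dwell_sigma_log: float = 0.4
    tracking_hz: float = 30.0
    lfp_fs: float = 2000.0

    # slow wave sleep
    sws_duration_s: float = 300.0
    frame_mean_s: float = 1.2
    silent_mean_s: float = 0.6
    frame_rate_hz: float = 25.0  # per-cell peak drive inside frames
    silent_rate_hz: float = 0.0
    frame_spwr_rate_hz: float = 0.6
    vta_sws_scale: float = 0.5
    vta_frame_anticorr_gain: float = 1.0  # VTA gain in above-mean SPW-R frames

    def __post_init__(self) -> None:
        if self.task not in ("linear", "swm"):
            raise ValueError(f"unknown task {self.task!r}")
        for name in (
            "track_length_cm", "n_place_cells", "place_field_width_cm",
            "place_peak_hz", "theta_freq_hz", "spwr_rate_hz",
            "replay_speed_cms", "vta_baseline_hz", "n_trials",
            "run_speed_cms", "tracking_hz", "lfp_fs",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("replay_fraction", "rr_fraction", "error_rate", "reward_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def hash(self) -> str:
        return config_hash(self)


@dataclass
class AnalysisConfig:
    """Every fixed constant of the analysis pipeline, in one place."""

    speed_threshold_cms: float = 10.0
    mua_bin_s: float = 0.010
    mua_sigma_s: float = 0.010
    spwr_threshold_sd: float = 4.0
    spwr_min_duration_s: float = 0.050
    ripple_band_hz: tuple = (100.0, 300.0)
    theta_band_hz: tuple = (4.0, 12.0)
    delta_band_hz: tuple = (1.0, 4.0)
    spatial_bin_cm: float = 10.0
    run_decode_bin_s: float = 0.500
    event_decode_bin_s: float = 0.025
    replay_band_cm: float = 15.0
    speed_grid_cms: tuple = (50.0, 1500.0, 25.0)  # (min, max, step), both signs
    n_shuffles: int = 1500
    replay_p: float = 0.05
    nonreplay_p: float = 0.20
    min_event_bins: int = 3
    di_threshold: float = 0.5
    vta_lag_s: float = 0.084
    lag_sweep_s: tuple = (0.0, 0.200, 0.025)  # (start, stop, step)
    peth_sigma_s: float = 0.050
    peth_bin_s: float = 0.005
    baseline_window_s: tuple = (0.300, 0.100)  # length, gap before event
    rate_floor_hz: float = 0.3
    frame_bin_s: float = 0.010
    frame_sigma_s: float = 0.030
    n_permutation: int = 1000
    n_bootstrap: int = 1000
    mark_min_amp_uv: float = 100.0
    mark_min_width_us: float = 300.0
    sorted_peak_min_hz: float = 3.0
    pos_bandwidth_cm: float = 6.0
    mark_bandwidth_uv: float = 15.0
    speed_sigma_s: float = 0.25
    sws_ratio_threshold: float = 1.0
    sws_window_s: float = 10.0
    sws_hop_s: float = 1.0

    @property
    def hash(self) -> str:
        return config_hash(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw = {k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()}
        return cls(**raw)
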