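"""LFP filtering, multiunit rate estimation, and event detection.

Covers ripple/theta band filtering, multiunit activity (MUA) traces, SPW-R
burst detection with a speed constraint, ripple-power z-scores, slow-wave
sleep (SWS) epoch detection from the theta/delta ratio, frame detection
within SWS, and event-triggered LFP averages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import filtfilt, firwin, hilbert

from ._utils import gaussian_smooth
from .config import AnalysisConfig
from .intervals import IntervalSet


@dataclass
class LfpChannel:
    samples: np.ndarray  # microvolts
    fs: float  # Hz
    band: tuple | None = None
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("LFP samples must be finite")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs


@dataclass
class MuaTrace:
    times: np.ndarray  # bin centers, s
    rate: np.ndarray  # Hz per tetrode
    bin_width: float
    smoothing_sigma: float
    mean_rate: float = 0.0
    sd_rate: float = 0.0

    def __post_init__(self) -> None:
        self.mean_rate = float(np.mean(self.rate))
        self.sd_rate = float(np.std(self.rate))


@dataclass
class FrameConfig:
    bin_width: float = 0.010
    sigma: float = 0.030
    fallback_quantile: float = 0.75
    min_duration: float = 0.050


def bandpass(lfp: LfpChannel, band: tuple[float, float]) -> LfpChannel:
    """Zero-phase FIR bandpass (Blackman window) of an LFP trace."""
    lo, hi = band
    nyq = lfp.fs / 2.0
    if not 0 < lo < hi < nyq:
        raise ValueError(f"band {band} outside (0, {nyq}) Hz")
    # taps sized for ~3 transition cycles of the low edge, odd length
    numtaps = int(min(3.3 * lfp.fs / lo, lfp.samples.size // 3 - 1)) | 1
    taps = firwin(numtaps, [lo, hi], pass_zero=False, window="blackman", fs=lfp.fs)
    out = filtfilt(taps, [1.0], lfp.samples)
    return LfpChannel(out, lfp.fs, band=(lo, hi), t0=lfp.t0)


def compute_mua(
    spike_times: np.ndarray,
    span: tuple[float, float],
    bin_width: float = 0.010,
    sigma: float = 0.010,
    n_tetrodes: int = 1,
) -> MuaTrace:
    """Binned, Gaussian-smoothed multiunit rate (Hz per tetrode)."""
    spike_times = np.asarray(spike_times, dtype=float)
    if spike_times.size == 0:
        warnings.warn("empty spike set: MUA trace is all zero")
    lo, hi = span
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, _ = np.histogram(spike_times, bins=edges)
    rate = counts / bin_width / max(n_tetrodes, 1)
    rate = gaussian_smooth(rate, sigma / bin_width)
    centers = edges[:-1] + bin_width / 2.0
    return MuaTrace(centers, rate, bin_width, sigma)


def detect_spwr(
    mua: MuaTrace,
    speed_times: np.ndarray,
    speed: np.ndarray,
    threshold_sd: float = 4.0,
    speed_max: float = 10.0,
    min_duration: float = 0.050,
) -> IntervalSet:
    """SPW-R multiunit events: bursts whose peak exceeds mean + k*sd.

    Event boundaries are the nearest crossings of the mean rate on either
    side of the peak; only events whose peak occurs at low speed
    (< speed_max cm/s) are kept; touching events are merged.
    """
    rate, t = mua.rate, mua.times
    mean, sd = mua.mean_rate, mua.sd_rate
    if sd == 0:
        warnings.warn("constant MUA trace: no events detectable")
        return IntervalSet(np.empty((0, 2)), "spwr")
    thresh = mean + threshold_sd * sd
    above = rate > thresh
    if not above.any():
        return IntervalSet(np.empty((0, 2)), "spwr")

    below_mean = rate <= mean
    intervals = []
    padded = np.concatenate([[False], above, [False]])
    d = np.diff(padded.astype(int))
    run_starts = np.where(d == 1)[0]
    run_ends = np.where(d == -1)[0]
    for rs, re in zip(run_starts, run_ends):
        peak_i = rs + int(np.argmax(rate[rs:re]))
        if speed_times.size:
            v = float(np.interp(t[peak_i], speed_times, speed))
            if v >= speed_max:
                continue
        # expand to the nearest mean-crossing on each side
        left_candidates = np.where(below_mean[: peak_i + 1])[0]
        start_i = left_candidates[-1] + 1 if left_candidates.size else 0
        right_candidates = np.where(below_mean[peak_i:])[0]
        end_i = peak_i + right_candidates[0] if right_candidates.size else rate.size
        s = t[start_i] - mua.bin_width / 2.0
        e = t[min(end_i, rate.size - 1)] + mua.bin_width / 2.0
        intervals.append((s, e))

    if not intervals:
        return IntervalSet(np.empty((0, 2)), "spwr")
    arr = np.array(sorted(set(intervals)))
    # merge touching/overlapping candidates
    merged = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    arr = np.array([iv for iv in merged if iv[1] - iv[0] >= min_duration])
    return IntervalSet(arr.reshape(-1, 2), "spwr")


def ripple_power_z(
    ripple_lfp: LfpChannel,
    events: IntervalSet,
    baseline_mask: np.ndarray,
) -> np.ndarray:
    """Per-event ripple power z-score.

    The event statistic is the maximum of the Hilbert envelope within the
    event; the reference is the envelope over baseline samples (non-event,
    low-speed periods).
    """
    env = np.abs(hilbert(ripple_lfp.samples))
    t = ripple_lfp.times
    base = env[np.asarray(baseline_mask, dtype=bool)]
    mu, sd = float(np.mean(base)), float(np.std(base))
    if sd == 0:
        raise ValueError("zero-variance baseline envelope")
    out = np.empty(len(events))
    for i, (s, e) in enumerate(events):
        sel = (t >= s) & (t < e)
        out[i] = (float(np.max(env[sel])) - mu) / sd if sel.any() else np.nan
    return out


def detect_sws(
    lfp: LfpChannel,
    posture_ok,
    ratio_threshold: float = 1.0,
    window_s: float = 10.0,
    hop_s: float = 1.0,
    gap_tol: float = 10.0,
    theta_band: tuple = (4.0, 12.0),
    delta_band: tuple = (1.0, 4.0),
) -> IntervalSet:
    """SWS epochs: windows of low theta/delta power ratio with sleep posture.

    posture_ok may be a scalar bool or a per-window callable/array aligned to
    window start times.
    """
    theta = bandpass(lfp, theta_band).samples
    delta = bandpass(lfp, delta_band).samples
    n_win = int(window_s * lfp.fs)
    n_hop = int(hop_s * lfp.fs)
    starts = np.arange(0, lfp.samples.size - n_win + 1, n_hop)
    if starts.size == 0:
        raise ValueError("LFP shorter than the analysis window")
    ratios = np.empty(starts.size)
    for i, s0 in enumerate(starts):
        sl = slice(s0, s0 + n_win)
        p_theta = float(np.mean(theta[sl] ** 2))
        p_delta = float(np.mean(delta[sl] ** 2))
        ratios[i] = p_theta / p_delta if p_delta > 0 else np.inf
    win_t = lfp.t0 + starts / lfp.fs
    if np.isscalar(posture_ok) or isinstance(posture_ok, (bool, np.bool_)):
        posture = np.full(starts.size, bool(posture_ok))
    else:
        posture = np.asarray(posture_ok, dtype=bool)[: starts.size]
    ok = (ratios < ratio_threshold) & posture
    if not ok.any():
        return IntervalSet(np.empty((0, 2)), "sws")
    # each window's decision is assigned to its central hop, which keeps
    # epoch boundaries at hop (not window) resolution
    centers = win_t + window_s / 2.0 - hop_s / 2.0
    ivs = IntervalSet.from_mask(ok, centers, "sws")
    return ivs.merge(gap_tol)


def frame_threshold(counts: np.ndarray, fallback_quantile: float = 0.75) -> float:
    """Spike-count threshold at the first minimum of the count distribution."""
    counts = np.asarray(counts)
    hist = np.bincount(np.round(counts).astype(int))
    for k in range(1, hist.size - 1):
        if hist[k] < hist[k - 1] and hist[k] <= hist[k + 1]:
            return float(k)
    warnings.warn("unimodal spike-count histogram; falling back to quantile")
    return float(np.quantile(counts, fallback_quantile))


def detect_frames(
    spike_times: np.ndarray,
    sws: IntervalSet,
    cfg: FrameConfig | None = None,
) -> IntervalSet:
    """Frames: runs of elevated smoothed multiunit count within SWS."""
    cfg = cfg or FrameConfig()
    frames = []
    for s, e in sws:
        edges = np.arange(s, e + cfg.bin_width, cfg.bin_width)
        if edges.size < 3:
            continue
        counts, _ = np.histogram(spike_times, bins=edges)
        thresh = frame_threshold(counts, cfg.fallback_quantile)
        smoothed = gaussian_smooth(counts.astype(float), cfg.sigma / cfg.bin_width)
        mask = smoothed > thresh
        centers = edges[:-1]
        ivs = IntervalSet.from_mask(mask, centers, "frame")
        for fs, fe in ivs:
            if fe - fs >= cfg.min_duration:
                frames.append((fs, fe))
    return IntervalSet(np.array(frames).reshape(-1, 2), "frame")


def event_triggered_lfp(
    lfp: LfpChannel,
    events: IntervalSet,
    window: tuple[float, float] = (-0.1, 0.3),
):
    """Average event-onset-aligned LFP and its negative-peak latency (ms).

    Events whose window is truncated by the recording edge are dropped; the
    number dropped is returned alongside.
    """
    if len(events) == 0:
        raise ValueError("need at least one event")
    n_pre = int(round(-window[0] * lfp.fs))
    n_post = int(round(window[1] * lfp.fs))
    snippets = []
    dropped = 0
    for s, _ in events:
        i0 = int(round((s - lfp.t0) * lfp.fs))
        if i0 - n_pre < 0 or i0 + n_post > lfp.samples.size:
            dropped += 1
            continue
        snippets.append(lfp.samples[i0 - n_pre : i0 + n_post])
    if not snippets:
        raise ValueError("all events truncated by the recording edge")
    avg = np.mean(snippets, axis=0)
    lags = (np.arange(-n_pre, n_post)) / lfp.fs
    post = lags >= 0
    latency_ms = float(lags[post][np.argmin(avg[post])] * 1000.0)
    return lags, avg, latency_ms, dropped
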