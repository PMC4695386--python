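"""Bayesian reconstruction of position and run direction from tetrode spikes.

Two decoders are provided. The clusterless decoder works directly on
unsorted spikes and their 4-channel peak-amplitude marks through a marked
point-process encoding model: per tetrode, a Gaussian kernel density over
(linear position, mark) estimated from run-epoch spikes, normalized by the
position occupancy. The sorted decoder is classical Poisson population
decoding from place-cell tuning curves. Both use a uniform spatial prior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .config import AnalysisConfig
from .track import LinearTrack


@dataclass
class MarkedSpikes:
    """Unsorted spikes with tetrode ids and 4-channel amplitude marks."""

    time: np.ndarray  # s, sorted
    tetrode: np.ndarray  # int id per spike
    mark: np.ndarray  # (n, 4) peak amplitudes, microvolts
    width: np.ndarray | None = None  # s
    cell: np.ndarray | None = None  # ground-truth / sorted unit id, optional

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.tetrode = np.asarray(self.tetrode, dtype=int)
        self.mark = np.atleast_2d(np.asarray(self.mark, dtype=float))
        if self.mark.shape[0] != self.time.size:
            raise ValueError("mark rows must match spike count")
        order = np.argsort(self.time, kind="stable")
        self.time = self.time[order]
        self.tetrode = self.tetrode[order]
        self.mark = self.mark[order]
        if self.width is not None:
            self.width = np.asarray(self.width, dtype=float)[order]
        if self.cell is not None:
            self.cell = np.asarray(self.cell, dtype=int)[order]

    def __len__(self) -> int:
        return self.time.size

    def select(self, mask: np.ndarray) -> "MarkedSpikes":
        return MarkedSpikes(
            self.time[mask],
            self.tetrode[mask],
            self.mark[mask],
            None if self.width is None else self.width[mask],
            None if self.cell is None else self.cell[mask],
        )

    def amplitude_filter(self, min_amp_uv: float = 100.0,
                         min_width_us: float = 300.0) -> "MarkedSpikes":
        """Keep putative pyramidal spikes: large peak amplitude, wide spikes."""
        keep = self.mark.max(axis=1) > min_amp_uv
        if self.width is not None:
            keep &= self.width > min_width_us * 1e-6
        return self.select(keep)


@dataclass
class Posterior:
    """Time-bin x space-bin probability matrix; rows sum to one."""

    time_edges: np.ndarray  # (T+1,)
    P: np.ndarray  # (T, S)
    bin_centers: np.ndarray  # (S,) linear cm
    direction_P: np.ndarray | None = None  # (T, 2): [outbound, inbound]

    def __post_init__(self) -> None:
        rows = self.P.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise ValueError("posterior rows must sum to 1")
        if self.direction_P is not None and not np.allclose(
            self.direction_P.sum(axis=1), 1.0, atol=1e-9
        ):
            raise ValueError("direction posterior rows must sum to 1")

    @property
    def n_bins(self) -> int:
        return self.P.shape[0]

    @property
    def time_centers(self) -> np.ndarray:
        return 0.5 * (self.time_edges[:-1] + self.time_edges[1:])

    @property
    def map_positions(self) -> np.ndarray:
        # ties broken toward the lowest bin index by argmax convention
        return self.bin_centers[np.argmax(self.P, axis=1)]


@dataclass
class DecodingReport:
    median_error_cm: float
    confusion: np.ndarray  # (S_true, S_decoded) counts
    direction_error: float | None = None
    n_bins: int = 0


@dataclass
class TetrodeModel:
    enc_pos: np.ndarray  # (n,) linear positions of encoding spikes
    enc_mark: np.ndarray  # (n, 4)
    enc_dir: np.ndarray  # (n,) +1 outbound / -1 inbound
    kx: np.ndarray  # (n, S) position kernel at bin centers


@dataclass
class EncodingModel:
    """Per-tetrode joint (position, mark) densities plus occupancy."""

    track: LinearTrack
    tetrodes: dict  # tetrode id -> TetrodeModel
    occupancy: np.ndarray  # (S,) seconds per spatial bin, floored
    dir_occupancy: np.ndarray  # (2,) seconds per direction
    total_time: float
    pos_bw: float
    mark_bw: float

    @property
    def rate_per_bin(self) -> dict:
        """Spatial intensity Lambda_tet(x) in Hz at each bin center."""
        out = {}
        for tid, tm in self.tetrodes.items():
            out[tid] = tm.kx.sum(axis=0) / self.occupancy
        return out


def fit_encoding(
    spikes: MarkedSpikes,
    pos_times: np.ndarray,
    linpos: np.ndarray,
    direction: np.ndarray,
    run_mask: np.ndarray,
    track: LinearTrack,
    pos_bw: float = 6.0,
    mark_bw: float = 15.0,
    min_spikes: int = 50,
) -> EncodingModel:
    """Fit the clusterless encoding model from run-epoch data.

    pos_times/linpos/direction are the tracking samples; run_mask selects
    encoding samples (speed above threshold and, for cross-validation,
    membership in training blocks). Tetrodes with fewer than `min_spikes`
    encoding spikes are excluded.
    """
    run_mask = np.asarray(run_mask, dtype=bool)
    if not run_mask.any():
        raise ValueError("no run-epoch samples to encode from")
    dt = float(np.median(np.diff(pos_times)))
    enc_pos_samples = linpos[run_mask]
    enc_dir_samples = direction[run_mask]

    S = track.n_bins
    occ, _ = np.histogram(enc_pos_samples, bins=S,
                          range=(0.0, S * track.bin_width))
    occupancy = occ * dt
    floor = 1e-3 * occupancy.sum() / S
    occupancy = np.maximum(occupancy, floor)
    dir_occupancy = np.array([
        max((enc_dir_samples > 0).sum() * dt, 1e-6),
        max((enc_dir_samples < 0).sum() * dt, 1e-6),
    ])

    # spike is an encoding spike if its nearest tracking sample is in-run
    idx = np.clip(np.searchsorted(pos_times, spikes.time), 0, pos_times.size - 1)
    in_run = run_mask[idx]
    spike_pos = np.interp(spikes.time, pos_times, linpos)
    spike_dir = direction[idx]

    tetrodes = {}
    for tid in np.unique(spikes.tetrode):
        sel = (spikes.tetrode == tid) & in_run
        if sel.sum() < min_spikes:
            warnings.warn(f"tetrode {tid}: {int(sel.sum())} encoding spikes; excluded")
            continue
        p = spike_pos[sel]
        kx = np.exp(-0.5 * ((track.bin_centers[None, :] - p[:, None]) / pos_bw) ** 2)
        kx /= pos_bw * np.sqrt(2 * np.pi)
        tetrodes[tid] = TetrodeModel(p, spikes.mark[sel], spike_dir[sel], kx)
    if not tetrodes:
        raise ValueError("no tetrode had enough encoding spikes")
    return EncodingModel(
        track, tetrodes, occupancy, dir_occupancy,
        float(run_mask.sum() * dt), pos_bw, mark_bw,
    )


def _mark_weights(marks: np.ndarray, enc_marks: np.ndarray, bw: float,
                  chunk: int = 512) -> np.ndarray:
    """(n_dec, n_enc) Gaussian product kernel over the 4 mark channels."""
    n = marks.shape[0]
    out = np.empty((n, enc_marks.shape[0]))
    for i0 in range(0, n, chunk):
        d = marks[i0 : i0 + chunk, None, :] - enc_marks[None, :, :]
        out[i0 : i0 + chunk] = np.exp(-0.5 * np.sum((d / bw) ** 2, axis=2))
    return out


def decode(
    model: EncodingModel,
    spikes: MarkedSpikes,
    time_edges: np.ndarray,
    with_direction: bool = False,
) -> Posterior:
    """Clusterless Bayesian decoding in non-overlapping time bins.

    Per bin, the log likelihood over space is the sum over in-bin spikes of
    log of the joint mark intensity, minus the Poisson no-spike exposure,
    summed across tetrodes; a uniform prior is applied and rows are
    normalized. Bins without any spike are returned as exactly uniform.
    """
    time_edges = np.asarray(time_edges, dtype=float)
    T = time_edges.size - 1
    S = model.track.n_bins
    dt_bins = np.diff(time_edges)
    ll = np.zeros((T, S))
    ll_dir = np.zeros((T, 2))
    has_spike = np.zeros(T, dtype=bool)

    for tid, tm in model.tetrodes.items():
        lam_x = tm.kx.sum(axis=0) / model.occupancy  # spatial intensity, Hz
        lam_total_out = (tm.enc_dir > 0).sum() / model.dir_occupancy[0]
        lam_total_in = (tm.enc_dir < 0).sum() / model.dir_occupancy[1]
        ll -= dt_bins[:, None] * lam_x[None, :]
        ll_dir -= dt_bins[:, None] * np.array([lam_total_out, lam_total_in])

        sel = spikes.tetrode == tid
        times = spikes.time[sel]
        marks = spikes.mark[sel]
        bin_idx = np.searchsorted(time_edges, times, side="right") - 1
        ok = (bin_idx >= 0) & (bin_idx < T) & (times < time_edges[-1])
        bin_idx, marks = bin_idx[ok], marks[ok]
        if bin_idx.size == 0:
            continue
        has_spike[np.unique(bin_idx)] = True
        W = _mark_weights(marks, tm.enc_mark, model.mark_bw)  # (n_dec, n_enc)
        joint = W @ tm.kx / model.occupancy[None, :]  # intensity up to constants
        log_joint = np.log(np.maximum(joint, 1e-300))
        np.add.at(ll, bin_idx, log_joint)
        if with_direction:
            w_out = W @ (tm.enc_dir > 0).astype(float) / model.dir_occupancy[0]
            w_in = W @ (tm.enc_dir < 0).astype(float) / model.dir_occupancy[1]
            log_dir = np.log(np.maximum(np.column_stack([w_out, w_in]), 1e-300))
            np.add.at(ll_dir, bin_idx, log_dir)

    P = np.exp(ll - logsumexp(ll, axis=1, keepdims=True))
    P[~has_spike] = 1.0 / S
    dP = None
    if with_direction:
        dP = np.exp(ll_dir - logsumexp(ll_dir, axis=1, keepdims=True))
        dP[~has_spike] = 0.5
    return Posterior(time_edges, P, model.track.bin_centers, dP)


def tuning_curves(
    spikes: MarkedSpikes,
    pos_times: np.ndarray,
    linpos: np.ndarray,
    run_mask: np.ndarray,
    track: LinearTrack,
    sigma_cm: float = 6.0,
    peak_min_hz: float = 3.0,
):
    """Smoothed spatial tuning curves for sorted cells (Hz per bin).

    Cells whose peak rate falls below `peak_min_hz` are dropped, mirroring
    the place-field criterion for sorted decoding.
    """
    if spikes.cell is None:
        raise ValueError("sorted decoding needs cell ids")
    from ._utils import gaussian_smooth

    dt = float(np.median(np.diff(pos_times)))
    S = track.n_bins
    occ, _ = np.histogram(linpos[run_mask], bins=S, range=(0, S * track.bin_width))
    occ_s = np.maximum(occ * dt, 1e-3 * occ.sum() * dt / S)

    idx = np.clip(np.searchsorted(pos_times, spikes.time), 0, pos_times.size - 1)
    in_run = run_mask[idx]
    spike_pos = np.interp(spikes.time, pos_times, linpos)
    curves, cells = [], []
    for cid in np.unique(spikes.cell):
        sel = (spikes.cell == cid) & in_run
        cnt, _ = np.histogram(spike_pos[sel], bins=S, range=(0, S * track.bin_width))
        rate = gaussian_smooth(cnt / occ_s, sigma_cm / track.bin_width)
        if rate.max() > peak_min_hz:
            curves.append(rate)
            cells.append(int(cid))
    if not curves:
        raise ValueError("no cell passed the peak-rate criterion")
    return np.array(curves), np.array(cells)


def decode_sorted(
    curves: np.ndarray,
    counts: np.ndarray,
    time_edges: np.ndarray,
    bin_centers: np.ndarray,
) -> Posterior:
    """Poisson population decoding from tuning curves with a uniform prior.

    counts: (T, n_cells) spike counts per time bin.
    """
    time_edges = np.asarray(time_edges, dtype=float)
    dt = np.diff(time_edges)
    lam = np.maximum(curves, 1e-6)  # (n_cells, S)
    ll = counts @ np.log(lam) - dt[:, None] * lam.sum(axis=0)[None, :]
    P = np.exp(ll - logsumexp(ll, axis=1, keepdims=True))
    P[counts.sum(axis=1) == 0] = 1.0 / curves.shape[1]
    return Posterior(time_edges, P, bin_centers)


def cross_validate(
    spikes: MarkedSpikes,
    pos_times: np.ndarray,
    linpos: np.ndarray,
    direction: np.ndarray,
    speed: np.ndarray,
    track: LinearTrack,
    mode: str = "clusterless",
    cfg: AnalysisConfig | None = None,
) -> DecodingReport:
    """Cross-validated decoding error on alternating 1 s train/test blocks.

    Training uses odd 1 s blocks of run behavior (speed above threshold);
    decoding runs on 500 ms bins inside even blocks. The error is the
    along-track distance between the MAP bin center and the true position.
    """
    cfg = cfg or AnalysisConfig()
    speed_ok = speed > cfg.speed_threshold_cms
    block = np.floor(pos_times).astype(int)
    train_mask = speed_ok & (block % 2 == 1)
    test_mask = speed_ok & (block % 2 == 0)
    if train_mask.sum() * np.median(np.diff(pos_times)) < 2.0:
        raise ValueError("need at least 2 s of run epochs")

    # 500 ms test bins fully inside even, in-run stretches
    bin_w = cfg.run_decode_bin_s
    t0, t1 = pos_times[0], pos_times[-1]
    edges = np.arange(t0, t1, bin_w)
    centers = edges[:-1] + bin_w / 2
    center_idx = np.clip(np.searchsorted(pos_times, centers), 0, pos_times.size - 1)
    usable = test_mask[center_idx]
    true_pos = np.interp(centers, pos_times, linpos)
    true_dir = direction[center_idx]

    if mode == "clusterless":
        filt = spikes.amplitude_filter(cfg.mark_min_amp_uv, cfg.mark_min_width_us)
        model = fit_encoding(
            filt, pos_times, linpos, direction, train_mask, track,
            cfg.pos_bandwidth_cm, cfg.mark_bandwidth_uv,
        )
        post = decode(model, filt, edges, with_direction=True)
    elif mode == "sorted":
        curves, cells = tuning_curves(
            spikes, pos_times, linpos, train_mask, track,
            peak_min_hz=cfg.sorted_peak_min_hz,
        )
        counts = np.zeros((edges.size - 1, cells.size))
        for j, cid in enumerate(cells):
            counts[:, j], _ = np.histogram(spikes.time[spikes.cell == cid], bins=edges)
        post = decode_sorted(curves, counts, edges, track.bin_centers)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    n_spikes_per_bin, _ = np.histogram(spikes.time, bins=edges)
    keep = usable & (n_spikes_per_bin > 0)
    if not keep.any():
        raise ValueError("no test bins with spikes")
    map_pos = post.map_positions[keep]
    errs = track.distance(map_pos, true_pos[keep])

    S = track.n_bins
    conf = np.zeros((S, S))
    ti = np.clip((true_pos[keep] / track.bin_width).astype(int), 0, S - 1)
    di = np.clip((map_pos / track.bin_width).astype(int), 0, S - 1)
    np.add.at(conf, (ti, di), 1)

    dir_err = None
    if post.direction_P is not None:
        dec_dir = np.where(post.direction_P[keep, 0] >= 0.5, 1, -1)
        known = true_dir[keep] != 0
        if known.any():
            dir_err = float(np.mean(dec_dir[known] != true_dir[keep][known]))
    return DecodingReport(float(np.median(errs)), conf, dir_err, int(keep.sum()))
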