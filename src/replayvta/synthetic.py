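"""Synthetic session generator with exported ground truth.

Generates complete recording sessions — behavior on a linear track or an
end-to-end T maze (spatial working memory, SWM), hippocampal marked spikes
with theta-modulated place fields and SPW-R bursts whose content encodes
constant-speed trajectories, VTA units with reward responses, SPW-R-locked
gain at a fixed lag and von Mises theta locking, and slow-wave-sleep frames
— emulating the statistical structure the downstream analysis assumes.

One master seed drives independent named substreams per stage, so the same
seed always yields byte-identical sessions regardless of which stages run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import i0 as bessel_i0

from ._utils import substream
from .config import SimConfig
from .decoding import MarkedSpikes
from .intervals import IntervalSet
from .signals import LfpChannel
from .track import LinearTrack


@dataclass
class BehaviorSession:
    t: np.ndarray  # tracking sample times, s
    lin_pos: np.ndarray  # linear position, cm
    xy: np.ndarray  # (n, 2) tracked 2-D position, cm
    direction: np.ndarray  # +1 outbound, -1 inbound, 0 paused
    trials: pd.DataFrame
    track: LinearTrack
    task: str
    pauses: IntervalSet

    @property
    def span(self) -> tuple[float, float]:
        return float(self.t[0]), float(self.t[-1])


@dataclass
class GroundTruth:
    events: pd.DataFrame = None  # one row per SPW-R event
    cells: pd.DataFrame = None  # one row per place cell
    vta_units: pd.DataFrame = None  # one row per VTA unit
    frames: IntervalSet = None
    frame_table: pd.DataFrame = None


@dataclass
class VtaSpikes:
    units: list  # list of spike-time arrays
    meta: pd.DataFrame


def _poisson_spikes(rng, rate: np.ndarray, t0: float, dt: float) -> np.ndarray:
    """Inhomogeneous Poisson sample from a rate array on a regular grid."""
    p = np.clip(rate * dt, 0.0, 1.0)
    hits = np.where(rng.random(p.size) < p)[0]
    return t0 + (hits + rng.random(hits.size)) * dt


def _lognormal_from_median(rng, median: float, sigma: float, n: int) -> np.ndarray:
    return np.exp(np.log(median) + sigma * rng.standard_normal(n))


# --------------------------------------------------------------------- behavior

def simulate_behavior(cfg: SimConfig) -> BehaviorSession:
    """Self-paced runs between reward wells with variable dwells.

    SWM trials alternate a sample (forced) and a test (choice) phase; the
    correct choice is the side opposite the forced turn, violated on
    injected error trials. On the linear track the animal shuttles between
    the two end wells.
    """
    rng = substream(cfg.seed, "behavior")
    if cfg.task == "linear":
        track = LinearTrack.linear(cfg.track_length_cm)
    else:
        track = LinearTrack.swm(cfg.swm_arm_cm, cfg.swm_central_cm)

    dt = 1.0 / cfg.tracking_hz
    t_chunks, pos_chunks, dir_chunks = [], [], []
    trials = []
    pauses = []
    now = 0.0

    def dwell(duration: float, lin: float) -> None:
        nonlocal now
        n = max(int(round(duration / dt)), 1)
        t_chunks.append(now + np.arange(n) * dt)
        pos_chunks.append(np.full(n, lin))
        dir_chunks.append(np.zeros(n, dtype=int))
        pauses.append((now, now + n * dt))
        now += n * dt

    def run_path(path, reverse: bool) -> None:
        """Traverse a path at roughly constant speed (outbound if not reverse)."""
        nonlocal now
        L = path.length
        duration = L / cfg.run_speed_cms
        n = max(int(round(duration / dt)), 2)
        s = np.linspace(0.0, L, n, endpoint=False) + L / n / 2
        if reverse:
            s = L - s
        lin = track.path_to_linear(path, s)
        t_chunks.append(now + np.arange(n) * dt)
        pos_chunks.append(lin)
        dir_chunks.append(np.full(n, -1 if reverse else 1, dtype=int))
        now += n * dt

    dwells = _lognormal_from_median(
        rng, cfg.dwell_median_s, cfg.dwell_sigma_log, 2 * cfg.n_trials + 2
    )
    errors = rng.random(cfg.n_trials) < cfg.error_rate

    if cfg.task == "linear":
        out_path, in_path = track.paths[0], track.paths[1]
        wells = [0.0, track.length]
        dwell(dwells[0], wells[0])
        for i in range(cfg.n_trials):
            outbound = i % 2 == 0
            run_path(out_path if outbound else in_path, reverse=False)
            well = wells[1] if outbound else wells[0]
            nosepoke = now + 0.3
            dwell(dwells[i + 1], well)
            trials.append({
                "trial": i, "phase": "run", "nosepoke_t": nosepoke,
                "reward_site_cm": well, "correct": not errors[i],
            })
    else:
        path_by_pair = {p.path_id: p for p in track.paths}
        wells = dict(zip(["R3", "R4", "R1", "R2"], track.reward_sites_cm))
        forced_seq = rng.integers(0, 2, cfg.n_trials)  # 0 -> left (R3)
        choice_well = "R1"
        dwell(dwells[0], wells[choice_well])
        for i in range(cfg.n_trials):
            forced = "R3" if forced_seq[i] == 0 else "R4"
            # sample phase: run from the current choice well back to the
            # forced well (inbound traversal of the connecting path)
            path = path_by_pair[f"{forced}-{choice_well}"]
            run_path(path, reverse=True)
            nosepoke = now + 0.3
            dwell(dwells[2 * i + 1], wells[forced])
            trials.append({
                "trial": i, "phase": "sample", "forced": forced,
                "choice": None, "nosepoke_t": nosepoke,
                "reward_site_cm": wells[forced], "correct": True,
            })
            # test phase: correct response is the side opposite the forced turn
            correct_choice = "R2" if forced == "R3" else "R1"
            wrong_choice = "R1" if correct_choice == "R2" else "R2"
            choice_well = wrong_choice if errors[i] else correct_choice
            path = path_by_pair[f"{forced}-{choice_well}"]
            run_path(path, reverse=False)
            nosepoke = now + 0.3
            dwell(dwells[2 * i + 2], wells[choice_well])
            trials.append({
                "trial": i, "phase": "test", "forced": forced,
                "choice": choice_well, "nosepoke_t": nosepoke,
                "reward_site_cm": wells[choice_well], "correct": not errors[i],
            })

    t = np.concatenate(t_chunks)
    lin = np.concatenate(pos_chunks)
    direction = np.concatenate(dir_chunks)
    lin = np.clip(lin + 0.3 * rng.standard_normal(lin.size), 0, track.length - 1e-6)
    xy = track.to_xy(lin)
    return BehaviorSession(
        t, lin, xy, direction, pd.DataFrame(trials), track, cfg.task,
        IntervalSet(np.array(pauses), "pause"),
    )


# ------------------------------------------------------------------ hippocampus

def _draw_mark_centroids(rng, n: int, lo: float, hi: float, min_sep: float):
    """Rejection-sample 4-D mark centroids at least min_sep apart."""
    centroids = []
    for _ in range(10000):
        c = rng.uniform(lo, hi, size=4)
        if all(np.linalg.norm(c - other) >= min_sep for other in centroids):
            centroids.append(c)
            if len(centroids) == n:
                return np.array(centroids)
    raise RuntimeError("could not separate mark centroids; widen the range")


def _make_cells(cfg: SimConfig, track: LinearTrack, rng) -> pd.DataFrame:
    sigma = cfg.place_field_width_cm / 2.3548  # FWHM -> Gaussian sd
    spacing = track.length / cfg.n_place_cells
    if spacing > cfg.place_field_width_cm:
        warnings.warn("place fields too sparse to tile the track")
    centers = (np.arange(cfg.n_place_cells) + 0.5) * spacing
    centers = centers + rng.uniform(-0.2, 0.2, cfg.n_place_cells) * spacing
    peaks = cfg.place_peak_hz * np.exp(0.2 * rng.standard_normal(cfg.n_place_cells))
    centroids = _draw_mark_centroids(
        rng, cfg.n_place_cells, cfg.mark_lo_uv, cfg.mark_hi_uv,
        cfg.mark_min_separation_uv,
    )
    return pd.DataFrame({
        "cell": np.arange(cfg.n_place_cells),
        "center_cm": np.clip(centers, 0, track.length),
        "sigma_cm": sigma,
        "peak_hz": peaks,
        "tetrode": np.arange(cfg.n_place_cells) % cfg.n_tetrodes,
        "pref_dir": np.where(rng.random(cfg.n_place_cells) < 0.5, 1, -1),
        "theta_phase_rad": rng.uniform(-np.pi, np.pi, cfg.n_place_cells),
        **{f"mark{k}_uv": centroids[:, k] for k in range(4)},
    })


def _tuning(cells: pd.DataFrame, x: np.ndarray) -> np.ndarray:
    """(n_cells, len(x)) Gaussian tuning curves evaluated at positions x."""
    c = cells["center_cm"].to_numpy()[:, None]
    s = cells["sigma_cm"].to_numpy()[:, None]
    p = cells["peak_hz"].to_numpy()[:, None]
    return p * np.exp(-0.5 * ((x[None, :] - c) / s) ** 2)


def _place_events(cfg: SimConfig, pauses: IntervalSet, rng) -> np.ndarray:
    """SPW-R event intervals inside pause epochs, non-overlapping."""
    events = []
    for s, e in pauses:
        usable = e - s - 0.6
        if usable <= 0:
            continue
        n = rng.poisson(cfg.spwr_rate_hz * usable)
        if n == 0:
            continue
        starts = np.sort(rng.uniform(s + 0.3, e - 0.4, n))
        durs = rng.uniform(*cfg.event_duration_s, n)
        last_end = -np.inf
        for st, du in zip(starts, durs):
            if st < last_end + 0.2 or st + du > e - 0.1:
                continue
            events.append((st, st + du))
            last_end = st + du
    return np.array(events).reshape(-1, 2)


def simulate_hippocampus(
    beh: BehaviorSession, cfg: SimConfig
) -> tuple[MarkedSpikes, LfpChannel, GroundTruth]:
    """Marked place-cell spiking, SPW-R bursts with trajectory content, LFP.

    Run-epoch spikes follow Gaussian tuning curves modulated by theta and
    run direction; pause epochs carry SPW-R bursts. Replay events drive the
    population along a constant-speed trajectory (evaluated at 1 ms
    resolution) whose start is biased into reward regions with probability
    cfg.reward_bias; nonreplay events use i.i.d. positions per 25 ms step.
    """
    rng_cells = substream(cfg.seed, "hc", "cells")
    rng_spk = substream(cfg.seed, "hc", "spikes")
    rng_ev = substream(cfg.seed, "hc", "events")
    rng_lfp = substream(cfg.seed, "hc", "lfp")
    track = beh.track
    cells = _make_cells(cfg, track, rng_cells)

    dt = 1e-3
    t0, t1 = beh.span
    grid = np.arange(t0, t1, dt)
    x = np.interp(grid, beh.t, beh.lin_pos)
    d_idx = np.clip(np.searchsorted(beh.t, grid), 0, beh.t.size - 1)
    direction = beh.direction[d_idx]
    running = direction != 0
    theta_phase = 2 * np.pi * cfg.theta_freq_hz * grid

    events = _place_events(cfg, beh.pauses, rng_ev)
    is_replay = rng_ev.random(len(events)) < cfg.replay_fraction
    event_rows = []
    # per-grid-sample event drive: replay trajectory or i.i.d. positions
    ev_pos = np.full(grid.size, np.nan)
    ev_mask = np.zeros(grid.size, dtype=bool)
    ev_dir = np.zeros(grid.size, dtype=int)

    for k, (s, e) in enumerate(events):
        i0, i1 = np.searchsorted(grid, [s, e])
        n = i1 - i0
        if n < 2:
            is_replay[k] = False
        path = track.paths[rng_ev.integers(len(track.paths))]
        row = {"start": s, "end": e, "is_replay": bool(is_replay[k]),
               "path_id": path.path_id, "start_cm": np.nan,
               "speed_cms": np.nan, "forward": True}
        if is_replay[k]:
            speed = cfg.replay_speed_cms * (1 if rng_ev.random() < 0.5 else -1)
            span = abs(speed) * (e - s)
            if rng_ev.random() < cfg.reward_bias:
                # start the trajectory inside a reward region of the path
                ends = np.array([0.0, path.length])
                anchor = ends[rng_ev.integers(2)]
                s0 = anchor + rng_ev.uniform(0, 10.0) * (1 if anchor == 0 else -1)
                speed = abs(speed) * (1 if anchor == 0 else -1)
            else:
                lo = max(0.0, -speed * (e - s))
                hi = min(path.length, path.length - speed * (e - s))
                s0 = rng_ev.uniform(min(lo, hi), max(lo, hi))
            tau = grid[i0:i1] - s
            s_path = np.clip(s0 + speed * tau, 0.0, path.length - 1e-9)
            ev_pos[i0:i1] = track.path_to_linear(path, s_path)
            forward = rng_ev.random() < 0.5
            prop_dir = 1 if speed > 0 else -1
            ev_dir[i0:i1] = prop_dir if forward else -prop_dir
            row.update(start_cm=float(s0), speed_cms=float(speed),
                       forward=bool(forward))
        else:
            # i.i.d. uniform positions held constant within 25 ms steps
            n_steps = int(np.ceil(n * dt / 0.025))
            pos_steps = rng_ev.uniform(0, track.length, n_steps)
            reps = np.repeat(pos_steps, int(np.ceil(0.025 / dt)))[:n]
            ev_pos[i0:i1] = reps
            ev_dir[i0:i1] = np.where(rng_ev.random(n) < 0.5, 1, -1)
        ev_mask[i0:i1] = True
        event_rows.append(row)

    # per-cell rates on the 1 ms grid
    all_t, all_cell = [], []
    theta_mod_base = np.cos(theta_phase)
    for _, cell in cells.iterrows():
        lam = np.zeros(grid.size)
        tune_run = cell.peak_hz * np.exp(
            -0.5 * ((x - cell.center_cm) / cell.sigma_cm) ** 2
        )
        theta_mod = 1 + cfg.theta_depth * np.cos(theta_phase - cell.theta_phase_rad)
        dir_mod = np.where(direction == cell.pref_dir, 1.0, 0.3)
        lam[running] = (tune_run * theta_mod * dir_mod)[running]
        lam[~running] = cfg.pause_rate_hz
        if ev_mask.any():
            tune_ev = cell.peak_hz * np.exp(
                -0.5 * ((ev_pos[ev_mask] - cell.center_cm) / cell.sigma_cm) ** 2
            )
            ev_dir_mod = np.where(ev_dir[ev_mask] == cell.pref_dir, 1.0, 0.3)
            lam[ev_mask] = cfg.event_gain * tune_ev * ev_dir_mod
        st = _poisson_spikes(rng_spk, lam, t0, dt)
        all_t.append(st)
        all_cell.append(np.full(st.size, cell.cell, dtype=int))

    times = np.concatenate(all_t)
    cell_ids = np.concatenate(all_cell)
    order = np.argsort(times, kind="stable")
    times, cell_ids = times[order], cell_ids[order]
    centroids = cells[[f"mark{k}_uv" for k in range(4)]].to_numpy()
    marks = centroids[cell_ids] + cfg.mark_sd_uv * rng_spk.standard_normal(
        (times.size, 4)
    )
    widths = rng_spk.uniform(350e-6, 600e-6, times.size)
    tetrodes = cells["tetrode"].to_numpy()[cell_ids]
    spikes = MarkedSpikes(times, tetrodes, marks, widths, cell_ids)

    # LFP: broadband noise + theta during run + ripple bursts during events
    fs = cfg.lfp_fs
    n_lfp = int((t1 - t0) * fs)
    lfp_t = t0 + np.arange(n_lfp) / fs
    lfp = 10.0 * rng_lfp.standard_normal(n_lfp)
    run_lfp = np.interp(lfp_t, grid, running.astype(float))
    lfp += 40.0 * np.cos(2 * np.pi * cfg.theta_freq_hz * lfp_t) * run_lfp
    for s, e in events:
        mid, dur = (s + e) / 2, e - s
        sel = (lfp_t >= s - dur) & (lfp_t <= e + dur)
        envelope = np.exp(-0.5 * ((lfp_t[sel] - mid) / (dur / 4)) ** 2)
        lfp[sel] += 30.0 * envelope * np.cos(2 * np.pi * 180.0 * (lfp_t[sel] - mid))
    lfp_ch = LfpChannel(lfp, fs, t0=t0)

    truth = GroundTruth(
        events=pd.DataFrame(
            event_rows,
            columns=["start", "end", "is_replay", "path_id", "start_cm",
                     "speed_cms", "forward"],
        ),
        cells=cells,
    )
    return spikes, lfp_ch, truth


# -------------------------------------------------------------------------- VTA

def event_reward_windows(
    truth: GroundTruth, track: LinearTrack, lag_s: float, bin_s: float = 0.025
) -> np.ndarray:
    """(n, 2) windows, shifted by lag, of replay bins in reward regions."""
    windows = []
    for _, ev in truth.events.iterrows():
        if not ev.is_replay:
            continue
        path = next(p for p in track.paths if p.path_id == ev.path_id)
        edges = np.arange(ev.start, ev.end + 1e-9, bin_s)
        for b0, b1 in zip(edges[:-1], edges[1:]):
            mid = (b0 + b1) / 2 - ev.start
            s_path = np.clip(ev.start_cm + ev.speed_cms * mid, 0, path.length - 1e-9)
            lin = float(track.path_to_linear(path, np.array([s_path]))[0])
            if track.in_reward_region(np.array([lin]))[0]:
                windows.append((b0 + lag_s, b1 + lag_s))
    return np.array(windows).reshape(-1, 2)


def simulate_vta(
    beh: BehaviorSession, hc_truth: GroundTruth, cfg: SimConfig
) -> tuple[VtaSpikes, LfpChannel, GroundTruth]:
    """VTA units: reward responses, lagged SPW-R gain, theta locking.

    RR units fire differentially on correct versus error trials around the
    nosepoke and multiply their rate by cfg.vta_spwr_gain in a window
    delayed by cfg.vta_lag_ms after each SPW-R onset (optionally only while
    the concurrent replayed trajectory occupies a reward region). Run-epoch
    spikes of every unit are von Mises theta locked with (mu, kappa).
    """
    rng = substream(cfg.seed, "vta")
    rng_lfp = substream(cfg.seed, "vta", "lfp")
    t0, t1 = beh.span
    dt = 1e-3
    grid = np.arange(t0, t1, dt)
    d_idx = np.clip(np.searchsorted(beh.t, grid), 0, beh.t.size - 1)
    running = beh.direction[d_idx] != 0
    theta_phase = 2 * np.pi * cfg.theta_freq_hz * grid
    lag = cfg.vta_lag_ms / 1000.0
    mu = np.deg2rad(cfg.mu_true_deg)

    n_rr = int(round(cfg.rr_fraction * cfg.n_vta_units))
    classes = ["RR"] * n_rr + ["nonRR"] * (cfg.n_vta_units - n_rr)
    events = hc_truth.events

    if cfg.couple_reward_only:
        gain_windows = event_reward_windows(hc_truth, beh.track, lag)
    else:
        gain_windows = np.column_stack(
            [events["start"].to_numpy() + lag, events["end"].to_numpy() + lag]
        ) if len(events) else np.empty((0, 2))
    gain_mask = np.zeros(grid.size, dtype=bool)
    for s, e in gain_windows:
        i0, i1 = np.searchsorted(grid, [s, e])
        gain_mask[i0:i1] = True

    approach_corr = np.zeros(grid.size, dtype=bool)
    approach_err = np.zeros(grid.size, dtype=bool)
    acq_corr = np.zeros(grid.size, dtype=bool)
    acq_err = np.zeros(grid.size, dtype=bool)
    for _, tr in beh.trials.iterrows():
        a0, a1 = np.searchsorted(grid, [tr.nosepoke_t - 2.0, tr.nosepoke_t])
        q0, q1 = np.searchsorted(grid, [tr.nosepoke_t, tr.nosepoke_t + 3.0])
        if tr.correct:
            approach_corr[a0:a1] = True
            acq_corr[q0:q1] = True
        else:
            approach_err[a0:a1] = True
            acq_err[q0:q1] = True

    units, rows = [], []
    theta_factor = np.ones(grid.size)
    if cfg.kappa_true > 0:
        theta_factor = np.where(
            running,
            np.exp(cfg.kappa_true * np.cos(theta_phase - mu)) / bessel_i0(cfg.kappa_true),
            1.0,
        )
    for u, klass in enumerate(classes):
        base = cfg.vta_baseline_hz * np.exp(0.2 * rng.standard_normal())
        lam = np.full(grid.size, base)
        lam = lam * theta_factor
        if klass == "RR":
            lam[acq_corr] *= cfg.rr_correct_gain
            lam[acq_err] *= cfg.rr_error_gain
            lam[approach_corr] *= 1.5
            lam[gain_mask] *= cfg.vta_spwr_gain
        st = _poisson_spikes(rng, lam, t0, dt)
        units.append(st)
        rows.append({
            "unit": u, "klass": klass, "baseline_hz": base,
            "gain": cfg.vta_spwr_gain if klass == "RR" else 1.0,
            "lag_ms": cfg.vta_lag_ms, "kappa": cfg.kappa_true,
            "mu_deg": cfg.mu_true_deg,
        })

    fs = cfg.lfp_fs
    n_lfp = int((t1 - t0) * fs)
    lfp_t = t0 + np.arange(n_lfp) / fs
    lfp = 8.0 * rng_lfp.standard_normal(n_lfp)
    for s in events["start"].to_numpy() if len(events) else []:
        lfp -= 60.0 * np.exp(-0.5 * ((lfp_t - (s + lag)) / 0.020) ** 2)
    meta = pd.DataFrame(rows)
    truth = GroundTruth(events=hc_truth.events, cells=hc_truth.cells,
                        vta_units=meta)
    return VtaSpikes(units, meta), LfpChannel(lfp, fs, t0=t0), truth


# -------------------------------------------------------------------------- SWS

def simulate_sws(
    cfg: SimConfig, cells: pd.DataFrame | None = None
) -> tuple[MarkedSpikes, VtaSpikes, LfpChannel, GroundTruth]:
    """Slow-wave-sleep epoch: frames of high activity between silent periods.

    Hippocampal cells fire inside frames (content drawn as i.i.d. positions
    per 25 ms step) and are silent between frames; SPW-R bursts occur only
    inside frames; VTA rates are scaled down relative to run, with an
    optional extra gain in frames whose SPW-R rate is above the mean. The
    LFP is delta-dominated throughout.
    """
    rng = substream(cfg.seed, "sws")
    if cells is None:
        track = (LinearTrack.linear(cfg.track_length_cm) if cfg.task == "linear"
                 else LinearTrack.swm(cfg.swm_arm_cm, cfg.swm_central_cm))
        cells = _make_cells(cfg, track, substream(cfg.seed, "sws", "cells"))
        length = track.length
    else:
        length = float(cells["center_cm"].max() + 20)

    # alternating silent / frame periods
    t = 1.0
    frames = []
    while t < cfg.sws_duration_s - 3.0:
        silent = cfg.silent_mean_s * np.exp(0.3 * rng.standard_normal())
        dur = cfg.frame_mean_s * np.exp(0.3 * rng.standard_normal())
        s = t + max(silent, 0.2)
        e = min(s + max(dur, 0.3), cfg.sws_duration_s - 1.0)
        if e <= s:
            break
        frames.append((s, e))
        t = e
    frames_arr = np.array(frames).reshape(-1, 2)
    frame_set = IntervalSet(frames_arr, "frame")

    dt = 1e-3
    grid = np.arange(0.0, cfg.sws_duration_s, dt)
    in_frame = frame_set.contains(grid)

    # SPW-Rs only inside frames; per-frame rate varies to create high/low split
    spwr = []
    frame_rows = []
    rate_scale = np.exp(0.6 * rng.standard_normal(len(frames)))
    for k, (s, e) in enumerate(frames):
        lam_ev = cfg.frame_spwr_rate_hz * rate_scale[k]
        n_ev = rng.poisson(lam_ev * (e - s))
        starts = np.sort(rng.uniform(s, max(e - 0.15, s + 1e-3), n_ev))
        kept = []
        last = -np.inf
        for st in starts:
            if st < last + 0.2:
                continue
            du = rng.uniform(0.08, 0.15)
            if st + du > e:
                continue
            kept.append((st, st + du))
            last = st + du
        spwr.extend(kept)
        frame_rows.append({
            "frame": k, "start": s, "end": e, "n_spwr": len(kept),
            "spwr_rate_hz": len(kept) / (e - s),
        })
    spwr_arr = np.array(spwr).reshape(-1, 2)
    frame_df = pd.DataFrame(frame_rows)

    # hippocampal content: i.i.d. positions per 25 ms step inside frames
    step = 0.025
    n_steps = int(np.ceil(cfg.sws_duration_s / step))
    pos_steps = rng.uniform(0, length, n_steps)
    pos_grid = pos_steps[np.minimum((grid / step).astype(int), n_steps - 1)]
    spwr_mask = IntervalSet(spwr_arr, "spwr").contains(grid) if len(spwr_arr) else \
        np.zeros(grid.size, dtype=bool)

    all_t, all_cell = [], []
    for _, cell in cells.iterrows():
        tune = cell.peak_hz * np.exp(
            -0.5 * ((pos_grid - cell.center_cm) / cell.sigma_cm) ** 2
        )
        lam = np.where(
            in_frame,
            cfg.frame_rate_hz * (0.25 + 0.75 * tune / cell.peak_hz),
            cfg.silent_rate_hz,
        )
        lam = np.where(spwr_mask, cfg.event_gain * tune, lam)
        st = _poisson_spikes(rng, lam, 0.0, dt)
        all_t.append(st)
        all_cell.append(np.full(st.size, cell.cell, dtype=int))
    times = np.concatenate(all_t)
    cell_ids = np.concatenate(all_cell)
    order = np.argsort(times, kind="stable")
    times, cell_ids = times[order], cell_ids[order]
    centroids = cells[[f"mark{k}_uv" for k in range(4)]].to_numpy()
    marks = centroids[cell_ids] + cfg.mark_sd_uv * rng.standard_normal((times.size, 4))
    widths = rng.uniform(350e-6, 600e-6, times.size)
    hc = MarkedSpikes(times, cells["tetrode"].to_numpy()[cell_ids], marks,
                      widths, cell_ids)

    # VTA: reduced rate in SWS; optional anti-correlated gain in high-rate frames
    mean_rate = frame_df["spwr_rate_hz"].mean() if len(frame_df) else 0.0
    high_mask = np.zeros(grid.size, dtype=bool)
    for _, fr in frame_df.iterrows():
        if fr.spwr_rate_hz > mean_rate:
            i0, i1 = np.searchsorted(grid, [fr.start, fr.end])
            high_mask[i0:i1] = True
    n_rr = int(round(cfg.rr_fraction * cfg.n_vta_units))
    units, rows = [], []
    for u in range(cfg.n_vta_units):
        klass = "RR" if u < n_rr else "nonRR"
        base = cfg.vta_baseline_hz * np.exp(0.2 * rng.standard_normal())
        lam = np.full(grid.size, base * cfg.vta_sws_scale)
        if klass == "RR" and cfg.vta_frame_anticorr_gain != 1.0:
            lam[high_mask] *= cfg.vta_frame_anticorr_gain
        units.append(_poisson_spikes(rng, lam, 0.0, dt))
        rows.append({"unit": u, "klass": klass, "baseline_hz": base,
                     "sws_scale": cfg.vta_sws_scale,
                     "anticorr_gain": cfg.vta_frame_anticorr_gain})
    vta = VtaSpikes(units, pd.DataFrame(rows))

    fs = cfg.lfp_fs
    n_lfp = int(cfg.sws_duration_s * fs)
    lfp_t = np.arange(n_lfp) / fs
    lfp = 60.0 * np.cos(2 * np.pi * 2.0 * lfp_t) + 10.0 * rng.standard_normal(n_lfp)
    truth = GroundTruth(
        events=pd.DataFrame({"start": spwr_arr[:, 0], "end": spwr_arr[:, 1]})
        if len(spwr_arr) else pd.DataFrame(columns=["start", "end"]),
        cells=cells, frames=frame_set, frame_table=frame_df,
    )
    return hc, vta, LfpChannel(lfp, fs), truth
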