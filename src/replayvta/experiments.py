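"""End-to-end validation experiments on synthetic sessions.

Each function runs one self-contained experiment — generate data with known
ground truth, run the analysis pipeline, measure recovery or calibration —
and returns a dict of summary metrics. They back both the acceptance
machinery and the worked examples in the documentation.

Problem sizes (session length, event counts, shuffle counts, seed counts)
are fixed here as the package's standard validation settings.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy.stats import kstest

from ._utils import mc_pvalue, substream
from .config import AnalysisConfig, SimConfig
from .decoding import decode, fit_encoding
from .intervals import IntervalSet
from .io import compute_speed
from .replay import (CandidateEvent, PathGrid, classify_replay,
                     column_cycle_shuffle, fit_trajectory)
from .synthetic import (_poisson_spikes, simulate_behavior,
                        simulate_hippocampus, simulate_sws, simulate_vta)
from .vta import bootstrap_modulation, peth, theta_locking
from . import coordination as co
from .signals import LfpChannel
from .decoding import Posterior


def decoder_recovery(seed: int, n_trials: int = 60) -> dict:
    """Cross-validated clusterless decoding error on a linear-track session
    with 30 place cells (~10 minutes of behavior)."""
    from .decoding import cross_validate

    cfg = SimConfig(seed=seed, n_trials=n_trials)
    beh = simulate_behavior(cfg)
    spikes, _, _ = simulate_hippocampus(beh, cfg)
    speed = compute_speed(beh)
    rep = cross_validate(spikes, beh.t, beh.lin_pos, beh.direction, speed,
                         beh.track, "clusterless")
    return {"median_error_cm": rep.median_error_cm,
            "direction_error": rep.direction_error,
            "n_test_bins": rep.n_bins}


def _decoded_session(seed: int, n_trials: int = 100, **cfg_kw):
    """Simulate a session and decode every true event in 25 ms bins."""
    cfg = SimConfig(seed=seed, n_trials=n_trials, spwr_rate_hz=0.5,
                    replay_fraction=0.6, **cfg_kw)
    beh = simulate_behavior(cfg)
    spikes, _, truth = simulate_hippocampus(beh, cfg)
    speed = compute_speed(beh)
    filt = spikes.amplitude_filter()
    model = fit_encoding(filt, beh.t, beh.lin_pos, beh.direction,
                         speed > 10, beh.track)
    cands = []
    for k, ev in truth.events.iterrows():
        nb = int((ev.end - ev.start) / 0.025)
        if nb < 3:
            continue
        edges = ev.start + np.arange(nb + 1) * 0.025
        post = decode(model, filt, edges)
        pos = float(np.interp((ev.start + ev.end) / 2, beh.t, beh.lin_pos))
        cands.append((CandidateEvent(k, (ev.start, ev.end), post, pos),
                      bool(ev.is_replay)))
    pool = np.vstack([c.posterior.P for c, _ in cands])
    return cfg, beh, truth, cands, pool


def replay_calibration(
    seed: int,
    n_null: int = 500,
    n_injected: int = 200,
    n_shuffles: int = 250,
) -> dict:
    """Sensitivity on injected constant-speed events and the false-positive
    rate on null events built by the pseudo-event generative process."""
    cfg, beh, truth, cands, pool = _decoded_session(seed)
    track = beh.track
    acfg = replace(AnalysisConfig(), n_shuffles=n_shuffles)
    grids = {p.path_id: PathGrid(track, p, acfg.replay_band_cm)
             for p in track.paths}

    injected = [c for c, r in cands if r][:n_injected]
    hits = sum(
        classify_replay(c, track, pool, seed, "standard", acfg, grids).label
        == "replay" for c in injected)

    rng = substream(seed, "null_events")
    durs = np.array([c.n_bins for c, _ in cands])
    n_fp = 0
    for i in range(n_null):
        T = int(rng.choice(durs))
        rows = pool[rng.integers(0, pool.shape[0], T)]
        edges = np.arange(T + 1) * 0.025
        ev = CandidateEvent(10_000 + i, (0.0, T * 0.025),
                            Posterior(edges, rows, track.bin_centers), 100.0)
        lab = classify_replay(ev, track, pool, seed, "standard", acfg, grids)
        n_fp += lab.label == "replay"
    return {"sensitivity": hits / len(injected),
            "false_positive_rate": n_fp / n_null,
            "n_injected": len(injected), "n_null": n_null}


def shuffle_uniformity(seed: int, n_events: int = 500,
                       n_shuffles: int = 250) -> dict:
    """Column-cycle p-values on row-shifted (null) events: KS uniformity."""
    cfg, beh, truth, cands, pool = _decoded_session(seed)
    track = beh.track
    acfg = replace(AnalysisConfig(), n_shuffles=n_shuffles)
    grids = {p.path_id: PathGrid(track, p, acfg.replay_band_cm)
             for p in track.paths}
    rng = substream(seed, "rowshift")
    ps = []
    for i in range(n_events):
        c, _ = cands[i % len(cands)]
        P = c.posterior.P.copy()
        S = P.shape[1]
        for t in range(P.shape[0]):
            P[t] = np.roll(P[t], rng.integers(0, S))
        ev = CandidateEvent(20_000 + i, c.interval,
                            Posterior(c.posterior.time_edges, P,
                                      track.bin_centers), c.animal_pos_cm)
        fits = fit_trajectory(ev, track, acfg, grids)
        null = column_cycle_shuffle(ev, track, n_shuffles, 500 + i, acfg, grids)
        best = max(fits, key=lambda f: f.score)
        ps.append(mc_pvalue(best.score, null[best.path_id]))
    return {"ks_p": float(kstest(ps, "uniform").pvalue), "n_events": n_events}


def modulation_recovery(seed: int, n_events: int = 200, n_units_per_gain: int = 6,
                        n_null_units: int = 200) -> dict:
    """PETH modulation-depth recovery for event gains {0.5, 2, 3} and the
    bootstrap false-positive rate on unmodulated units."""
    starts = 5.0 + 4.0 * np.arange(n_events)
    events = IntervalSet(np.column_stack([starts, starts + 0.25]), "spwr")
    grid = np.arange(0.0, starts[-1] + 5.0, 1e-3)
    in_ev = events.contains(grid)
    out = {}
    for gain in (0.5, 2.0, 3.0):
        depths = []
        for u in range(n_units_per_gain):
            rng = substream(seed, "depth", gain, u)
            st = _poisson_spikes(rng, np.where(in_ev, gain * 10.0, 10.0),
                                 0.0, 1e-3)
            depths.append(peth(st, events).modulation_depth)
        out[f"depth_gain_{gain}"] = float(np.mean(depths))
    fp = 0
    for u in range(n_null_units):
        rng = substream(seed, "boot_null", u)
        st = _poisson_spikes(rng, np.full(grid.size, 10.0), 0.0, 1e-3)
        fp += bootstrap_modulation(st, events, 1000, seed=u)
    out["bootstrap_false_positive_rate"] = fp / n_null_units
    return out


def vonmises_recovery(seed: int, n_spikes: int = 10_000,
                      kappa_true: float = 2.0) -> dict:
    """Theta-locking kappa recovery from Hilbert phases of a synthetic LFP."""
    rng = substream(seed, "vonmises")
    fs, f, duration = 500.0, 8.0, 400.0
    t = np.arange(0, duration, 1 / fs)
    lfp = LfpChannel(50 * np.cos(2 * np.pi * f * t), fs)
    run = IntervalSet(np.array([[0.0, duration]]), "run")

    def spikes_from_phases(ph):
        cyc = rng.integers(0, int(duration * f) - 1, ph.size)
        return np.sort((cyc + (ph % (2 * np.pi)) / (2 * np.pi)) / f)

    locked = theta_locking(
        spikes_from_phases(rng.vonmises(0.0, kappa_true, n_spikes)), lfp, run)
    uniform = theta_locking(
        spikes_from_phases(rng.uniform(-np.pi, np.pi, n_spikes)), lfp, run)
    return {"kappa_hat": locked.kappa, "kappa_true": kappa_true,
            "mu_hat_deg": locked.mu_deg, "kappa_uniform": uniform.kappa,
            "rayleigh_p_uniform": uniform.rayleigh_p}


def coupling_recovery(seed: int, n_seeds: int = 10) -> dict:
    """Recovery of reward-region-gated VTA coupling at an 84 ms lag.

    Per sub-seed: simulate a session whose RR units multiply their rate
    only while the replayed trajectory occupies a reward region (lag 84 ms),
    decode the replay events, and measure the excess reward-site bias of
    spike-associated bins, the RR-vs-nonRR permutation contrast, and the
    lag-sweep argmax.
    """
    rng_master = substream(seed, "coupling")
    results = {"perm_p": [], "excess_rr": [], "excess_nr": [], "lag_best": []}
    lag_curves = []
    for k in range(n_seeds):
        sub = int(rng_master.integers(0, 2**31 - 1))
        cfg_kw = dict(vta_spwr_gain=5.0, couple_reward_only=True)
        cfg, beh, truth, cands, pool = _decoded_session(sub, **cfg_kw)
        vta, _, _ = simulate_vta(beh, truth, cfg)
        reward_mask = beh.track.reward_bin_mask()
        bins, inds = [], []
        for c, is_rep in cands:
            if not is_rep:
                continue
            edges = c.posterior.time_edges
            bins.append(np.column_stack([edges[:-1], edges[1:]]))
            ind, _ = co.reward_site_bias(c.posterior.P, reward_mask)
            inds.append(ind)
        bins = np.vstack(bins)
        inds = np.concatenate(inds)
        ref = float(inds.mean())

        rr_ind, nr_ind = [], []
        for u, st in enumerate(vta.units):
            sel = co.spike_associated_bins(bins, st, 0.084)
            (rr_ind if vta.meta.klass[u] == "RR" else nr_ind).append(inds[sel])
        rr_ind = np.concatenate(rr_ind)
        nr_ind = np.concatenate(nr_ind)
        p, _ = co.permutation_interaction_test(
            ref, float(rr_ind.mean()), float(nr_ind.mean()),
            inds.size, rr_ind.size, nr_ind.size, seed=sub)
        results["perm_p"].append(p)
        results["excess_rr"].append(float(rr_ind.mean()) - ref)
        results["excess_nr"].append(float(nr_ind.mean()) - ref)

        rr_spikes = np.sort(np.concatenate(
            [vta.units[u] for u in range(len(vta.units))
             if vta.meta.klass[u] == "RR"]))
        lags, excess, best = co.lag_sweep(bins, inds, rr_spikes)
        results["lag_best"].append(best)
        lag_curves.append(excess)

    pooled = np.nanmean(lag_curves, axis=0)
    lags = np.arange(0.0, 0.200 + 1e-9, 0.025)
    return {
        "frac_perm_significant": float(np.mean(np.array(results["perm_p"]) < 0.05)),
        "frac_excess_rr_positive": float(np.mean(np.array(results["excess_rr"]) > 0)),
        "mean_excess_rr": float(np.mean(results["excess_rr"])),
        "mean_excess_nr": float(np.mean(results["excess_nr"])),
        "pooled_lag_argmax_ms": float(lags[np.nanargmax(pooled)] * 1000.0),
        "n_seeds": n_seeds,
    }


def frame_split_recovery(seed: int, n_seeds: int = 10,
                         anticorr_gain: float = 0.7) -> dict:
    """Anti-correlation between VTA rate and frame SPW-R rate in SWS.

    RR units carry a rate gain below one inside frames whose SPW-R rate is
    above the mean; the high-minus-low split difference must come out
    negative.
    """
    from .signals import FrameConfig, detect_frames

    rng_master = substream(seed, "frames")
    neg = 0
    diffs = []
    for k in range(n_seeds):
        sub = int(rng_master.integers(0, 2**31 - 1))
        cfg = SimConfig(seed=sub, sws_duration_s=300.0,
                        vta_frame_anticorr_gain=anticorr_gain)
        hc, vta, _, truth = simulate_sws(cfg)
        frames = detect_frames(hc.time, IntervalSet(
            np.array([[0.0, cfg.sws_duration_s]]), "sws"), FrameConfig())
        spwr = IntervalSet(truth.events[["start", "end"]].to_numpy(), "spwr") \
            if len(truth.events) else IntervalSet(np.empty((0, 2)), "spwr")
        rr_units = [vta.units[u] for u in range(len(vta.units))
                    if vta.meta.klass[u] == "RR"]
        stats = co.frame_stats(frames, [None] * len(frames), spwr, rr_units)
        diff = float(np.nanmean(stats.splits["unit_rate_by_spwr_rate"]))
        diffs.append(diff)
        neg += diff < 0
    return {"frac_negative": neg / n_seeds,
            "mean_rate_diff_hz": float(np.mean(diffs)), "n_seeds": n_seeds}
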