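"""Session file I/O and the end-to-end pipeline.

Sessions are stored as a directory of columnar UTF-8 text tables (with a
provenance header of commented key: value lines) plus one binary container
for the LFP traces. The pipeline chains the stages — simulate, detect,
decode, replay, vta, couple, frames — writing per-stage result tables that
all carry the config hash of the run that produced them.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._utils import config_hash
from .config import AnalysisConfig, SimConfig
from .decoding import MarkedSpikes, cross_validate, decode, fit_encoding
from .intervals import IntervalSet
from .replay import CandidateEvent, PathGrid, classify_replay
from .signals import LfpChannel, bandpass, compute_mua, detect_frames, detect_spwr
from .synthetic import (BehaviorSession, GroundTruth, VtaSpikes,
                        simulate_behavior, simulate_hippocampus, simulate_sws,
                        simulate_vta)
from .track import LinearTrack
from . import coordination, vta as vta_mod
from ._utils import gaussian_smooth


@dataclass
class Session:
    behavior: BehaviorSession
    hc_spikes: MarkedSpikes
    hc_lfp: LfpChannel
    vta: VtaSpikes
    vta_lfp: LfpChannel
    truth: GroundTruth | None
    sim_cfg: SimConfig | None = None


def _write_table(df: pd.DataFrame, path: Path, meta: dict) -> None:
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)


def _read_table(path: Path) -> tuple[pd.DataFrame, dict]:
    meta = {}
    lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("# "):
                k, _, v = line[2:].partition(":")
                meta[k.strip()] = v.strip()
            else:
                lines.append(line)
    df = pd.read_csv(_io.StringIO("".join(lines)))
    return df, meta


def simulate_session(cfg: SimConfig) -> Session:
    """Run all generator stages for one configuration."""
    beh = simulate_behavior(cfg)
    hc_spikes, hc_lfp, hc_truth = simulate_hippocampus(beh, cfg)
    vta_spk, vta_lfp, truth = simulate_vta(beh, hc_truth, cfg)
    return Session(beh, hc_spikes, hc_lfp, vta_spk, vta_lfp, truth, cfg)


def save_session(session: Session, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": session.sim_cfg.hash if session.sim_cfg else "external",
            "time_base": "seconds from session start"}
    beh = session.behavior
    _write_table(pd.DataFrame({
        "t_s": beh.t, "lin_cm": beh.lin_pos,
        "x_cm": beh.xy[:, 0], "y_cm": beh.xy[:, 1],
        "direction": beh.direction,
    }), out / "position.csv", meta)
    _write_table(beh.trials, out / "trials.csv", meta)
    sp = session.hc_spikes
    _write_table(pd.DataFrame({
        "t_s": sp.time, "tetrode": sp.tetrode,
        **{f"mark{k}_uv": sp.mark[:, k] for k in range(4)},
        "width_s": sp.width if sp.width is not None else np.nan,
        "cell": sp.cell if sp.cell is not None else -1,
    }), out / "hc_spikes.csv", meta)
    vta_rows = [pd.DataFrame({"unit": u, "t_s": st})
                for u, st in enumerate(session.vta.units)]
    _write_table(pd.concat(vta_rows, ignore_index=True) if vta_rows
                 else pd.DataFrame(columns=["unit", "t_s"]),
                 out / "vta_spikes.csv", meta)
    _write_table(session.vta.meta, out / "vta_units.csv", meta)
    np.savez(out / "lfp.npz",
             hc=session.hc_lfp.samples, hc_fs=session.hc_lfp.fs,
             hc_t0=session.hc_lfp.t0,
             vta=session.vta_lfp.samples, vta_fs=session.vta_lfp.fs,
             vta_t0=session.vta_lfp.t0)
    with open(out / "track.yaml", "w") as fh:
        yaml.safe_dump({"task": beh.task,
                        "segments": [
                            {"name": s.name, "length": float(s.length),
                             "node_start": s.node_start, "node_end": s.node_end}
                            for s in beh.track.segments]}, fh)
    _write_table(beh.pauses.to_frame(), out / "pauses.csv", meta)
    if session.truth is not None:
        _write_table(session.truth.events, out / "truth_events.csv", meta)
        _write_table(session.truth.cells, out / "truth_cells.csv", meta)
        if session.truth.vta_units is not None:
            _write_table(session.truth.vta_units, out / "truth_vta.csv", meta)
    if session.sim_cfg is not None:
        with open(out / "sim_config.yaml", "w") as fh:
            from dataclasses import asdict
            yaml.safe_dump(asdict(session.sim_cfg), fh)


def load_session(in_dir) -> Session:
    """Load a saved session, validating the shared time base."""
    d = Path(in_dir)
    for name in ("position.csv", "hc_spikes.csv", "vta_spikes.csv", "lfp.npz"):
        if not (d / name).exists():
            raise FileNotFoundError(f"session bundle missing {name}")
    pos, _ = _read_table(d / "position.csv")
    for col in ("t_s", "lin_cm"):
        if col not in pos.columns:
            raise ValueError(f"position.csv: missing column {col}")
    t = pos["t_s"].to_numpy()
    if np.any(np.diff(t) <= 0):
        row = int(np.argmax(np.diff(t) <= 0)) + 1
        raise ValueError(f"position.csv: non-monotone time at row {row}")
    trials, _ = _read_table(d / "trials.csv")
    hc, _ = _read_table(d / "hc_spikes.csv")
    span = (float(t[0]), float(t[-1]) + 1.0)
    bad = ~hc["t_s"].between(span[0] - 1.0, span[1] + 1.0)
    if bad.any():
        row = int(np.argmax(bad.to_numpy()))
        raise ValueError(f"hc_spikes.csv: out-of-range time at row {row}")
    spikes = MarkedSpikes(
        hc["t_s"].to_numpy(), hc["tetrode"].to_numpy(),
        hc[[f"mark{k}_uv" for k in range(4)]].to_numpy(),
        hc["width_s"].to_numpy() if "width_s" in hc else None,
        hc["cell"].to_numpy() if "cell" in hc else None,
    )
    vta_df, _ = _read_table(d / "vta_spikes.csv")
    vta_meta, _ = _read_table(d / "vta_units.csv")
    units = [vta_df.loc[vta_df["unit"] == u, "t_s"].to_numpy()
             for u in sorted(vta_df["unit"].unique())]
    lfp = np.load(d / "lfp.npz")
    n_hc = lfp["hc"].shape[0]
    expected = (span[1] - span[0] - 1.0) * float(lfp["hc_fs"])
    if abs(n_hc - expected) > float(lfp["hc_fs"]):
        raise ValueError("lfp.npz: sample count inconsistent with sampling rate")
    with open(d / "track.yaml") as fh:
        tr = yaml.safe_load(fh)
    sim_cfg = None
    if (d / "sim_config.yaml").exists():
        with open(d / "sim_config.yaml") as fh:
            raw = yaml.safe_load(fh)
        raw = {k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()}
        sim_cfg = SimConfig(**raw)
    if tr["task"] == "linear":
        track = LinearTrack.linear(tr["segments"][0]["length"])
    else:
        track = LinearTrack.swm(tr["segments"][0]["length"],
                                tr["segments"][2]["length"])
    pauses_df, _ = _read_table(d / "pauses.csv")
    beh = BehaviorSession(
        t, pos["lin_cm"].to_numpy(),
        pos[["x_cm", "y_cm"]].to_numpy(),
        pos["direction"].to_numpy(dtype=int), trials, track, tr["task"],
        IntervalSet.from_frame(pauses_df),
    )
    truth = None
    if (d / "truth_events.csv").exists():
        ev, _ = _read_table(d / "truth_events.csv")
        cells, _ = _read_table(d / "truth_cells.csv")
        vta_truth = None
        if (d / "truth_vta.csv").exists():
            vta_truth, _ = _read_table(d / "truth_vta.csv")
        truth = GroundTruth(events=ev, cells=cells, vta_units=vta_truth)
    hc_lfp = LfpChannel(lfp["hc"], float(lfp["hc_fs"]), t0=float(lfp["hc_t0"]))
    vta_lfp = LfpChannel(lfp["vta"], float(lfp["vta_fs"]), t0=float(lfp["vta_t0"]))
    return Session(beh, spikes, hc_lfp, VtaSpikes(units, vta_meta), vta_lfp,
                   truth, sim_cfg)


# ----------------------------------------------------------------- pipeline

def compute_speed(beh: BehaviorSession, sigma_s: float = 0.25) -> np.ndarray:
    """Run speed (cm/s) from the tracked position: smoothed centered difference."""
    dt = float(np.median(np.diff(beh.t)))
    v = np.gradient(beh.lin_pos, beh.t)
    return np.abs(gaussian_smooth(v, sigma_s / dt))


STAGE_ORDER = ["simulate", "detect", "decode", "replay", "vta", "couple",
               "report"]
STAGE_DEPS = {
    "detect": ["simulate"],
    "decode": ["simulate"],
    "replay": ["detect", "decode"],
    "vta": ["detect"],
    "couple": ["replay", "vta"],
    "report": [],
}


def run_pipeline(
    out_dir,
    sim_cfg: SimConfig | None = None,
    cfg: AnalysisConfig | None = None,
    stages: list | None = None,
    seed: int = 0,
    session: Session | None = None,
    n_shuffles: int | None = None,
) -> dict:
    """Run the requested stages end to end; returns the summary dict.

    Outputs are deterministic given (session, config, seed). Every result
    table carries the analysis-config hash; the summary is also written as
    report.json in out_dir.
    """
    cfg = cfg or AnalysisConfig()
    if n_shuffles is not None:
        from dataclasses import replace
        cfg = replace(cfg, n_shuffles=n_shuffles)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(stages or STAGE_ORDER)
    done = set(stages)
    for st in stages:
        missing = [d for d in STAGE_DEPS.get(st, []) if d not in done]
        if missing and session is None:
            raise ValueError(f"stage {st!r} requires {missing}")
    meta = {"config_hash": cfg.hash, "seed": seed}
    summary: dict = {"seed": seed, "config_hash": cfg.hash, "stages": {}}

    if "simulate" in stages:
        session = simulate_session(sim_cfg or SimConfig(seed=seed))
        save_session(session, out / "session")
        summary["stages"]["simulate"] = {
            "n_hc_spikes": len(session.hc_spikes),
            "n_vta_units": len(session.vta.units),
            "n_true_events": int(len(session.truth.events)),
        }
    if session is None:
        raise ValueError("no session: include the simulate stage or pass one")

    beh = session.behavior
    track = beh.track
    speed = compute_speed(beh, cfg.speed_sigma_s)
    events = None
    if "detect" in stages:
        mua = compute_mua(session.hc_spikes.time, beh.span, cfg.mua_bin_s,
                          cfg.mua_sigma_s, len(np.unique(session.hc_spikes.tetrode)))
        events = detect_spwr(mua, beh.t, speed, cfg.spwr_threshold_sd,
                             cfg.speed_threshold_cms, cfg.spwr_min_duration_s)
        _write_table(events.to_frame(), out / "spwr_events.csv", meta)
        summary["stages"]["detect"] = {"n_events": len(events)}

    model = None
    if "decode" in stages:
        report = cross_validate(session.hc_spikes, beh.t, beh.lin_pos,
                                beh.direction, speed, track, "clusterless", cfg)
        filt = session.hc_spikes.amplitude_filter(cfg.mark_min_amp_uv,
                                                  cfg.mark_min_width_us)
        model = fit_encoding(filt, beh.t, beh.lin_pos, beh.direction,
                             speed > cfg.speed_threshold_cms, track,
                             cfg.pos_bandwidth_cm, cfg.mark_bandwidth_uv)
        summary["stages"]["decode"] = {
            "median_error_cm": report.median_error_cm,
            "direction_error": report.direction_error,
            "n_test_bins": report.n_bins,
        }

    labels = []
    candidates = []
    if "replay" in stages:
        if events is None or model is None:
            raise ValueError("replay stage needs detect and decode outputs")
        grids = {p.path_id: PathGrid(track, p, cfg.replay_band_cm)
                 for p in track.paths}
        filt = session.hc_spikes.amplitude_filter(cfg.mark_min_amp_uv,
                                                  cfg.mark_min_width_us)
        for k, (s, e) in enumerate(events):
            nb = int((e - s) / cfg.event_decode_bin_s)
            if nb < 2:
                continue
            edges = s + np.arange(nb + 1) * cfg.event_decode_bin_s
            post = decode(model, filt, edges, with_direction=True)
            pos = float(np.interp((s + e) / 2, beh.t, beh.lin_pos))
            candidates.append(CandidateEvent(k, (s, e), post, pos))
        pool = np.vstack([c.posterior.P for c in candidates]) if candidates \
            else np.empty((0, track.n_bins))
        rows = []
        for c in candidates:
            lab = classify_replay(c, track, pool, seed, "standard", cfg, grids)
            labels.append((c, lab))
            best = lab.best_fit
            rows.append({
                "event_id": c.event_id, "start": c.interval[0],
                "end": c.interval[1], "label": lab.label,
                "path_id": best.path_id if best else "",
                "speed_cms": best.speed_cms if best else np.nan,
                "score": best.score if best else np.nan,
                "p_column": best.p_column if best else np.nan,
                "p_pseudo": best.p_pseudo if best else np.nan,
            })
        _write_table(pd.DataFrame(rows), out / "replay_labels.csv", meta)
        n_replay = sum(1 for _, l in labels if l.label == "replay")
        summary["stages"]["replay"] = {
            "n_candidates": len(candidates), "n_replay": n_replay,
            "replay_fraction": n_replay / max(len(candidates), 1),
        }

    profiles = None
    if "vta" in stages:
        if events is None:
            raise ValueError("vta stage needs detected events")
        theta = bandpass(session.hc_lfp, cfg.theta_band_hz)
        run_ivs = IntervalSet.from_mask(beh.direction != 0, beh.t, "run")
        profiles = vta_mod.profile_units(
            session.vta.units, beh.trials, beh.task, events, theta, run_ivs,
            beh.span, cfg, seed)
        _write_table(profiles, out / "vta_profiles.csv", meta)
        summary["stages"]["vta"] = {
            "n_units": len(profiles),
            "n_rr": int((profiles["klass"] == "RR").sum()),
            "n_significant": int(profiles["significant"].sum()),
        }

    if "couple" in stages:
        if not labels or profiles is None:
            raise ValueError("couple stage needs replay and vta outputs")
        reward_mask = track.reward_bin_mask()
        bins, inds = [], []
        for c, lab in labels:
            if lab.label != "replay":
                continue
            edges = c.posterior.time_edges
            iv = np.column_stack([edges[:-1], edges[1:]])
            ind, _ = coordination.reward_site_bias(c.posterior.P, reward_mask)
            bins.append(iv)
            inds.append(ind)
        rows = []
        if bins:
            bins_all = np.vstack(bins)
            ind_all = np.concatenate(inds)
            ref_bias = float(ind_all.mean())
            for u, st in enumerate(session.vta.units):
                sel = coordination.spike_associated_bins(bins_all, st, cfg.vta_lag_s)
                if not sel.any():
                    continue
                excess, chi2, p = coordination.excess_bias_chi2(
                    float(ind_all[sel].mean()), ref_bias, int(sel.sum()))
                rows.append({"unit": u, "klass": profiles["klass"].iloc[u],
                             "n_bins": int(sel.sum()), "excess": excess,
                             "chi2": chi2, "p": p, "ref_bias": ref_bias})
        _write_table(pd.DataFrame(rows), out / "coupling.csv", meta)
        summary["stages"]["couple"] = {
            "n_replay_bins": int(sum(len(i) for i in inds)),
            "n_units_tested": len(rows),
        }

    with open(out / "report.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary
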