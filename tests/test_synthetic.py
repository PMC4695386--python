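import hashlib

import numpy as np
import pytest
from scipy.stats import binomtest

import replayvta as rv
from replayvta.intervals import IntervalSet


def session_digest(cfg):
    beh = rv.simulate_behavior(cfg)
    spk, lfp, truth = rv.simulate_hippocampus(beh, cfg)
    vta, vlfp, _ = rv.simulate_vta(beh, truth, cfg)
    h = hashlib.sha256()
    for arr in (beh.t, beh.lin_pos, spk.time, spk.mark, lfp.samples,
                *vta.units, vlfp.samples):
        h.update(np.ascontiguousarray(arr).tobytes())
    h.update(truth.events.to_csv().encode())
    return h.hexdigest()


class TestBehavior:
    def test_swm_contingency_without_errors(self):
        """With error_rate 0 every test-phase choice opposes the forced turn."""
        cfg = rv.SimConfig(seed=5, task="swm", n_trials=12, error_rate=0.0)
        beh = rv.simulate_behavior(cfg)
        tests = beh.trials[beh.trials.phase == "test"]
        for _, tr in tests.iterrows():
            assert tr.choice == ("R2" if tr.forced == "R3" else "R1")
            assert tr.correct

    def test_error_fraction_within_binomial_ci(self):
        cfg = rv.SimConfig(seed=6, task="swm", n_trials=20, error_rate=0.25)
        beh = rv.simulate_behavior(cfg)
        tests = beh.trials[beh.trials.phase == "test"]
        n_err = int((~tests.correct).sum())
        # the observed error count must be consistent with p=0.25
        assert binomtest(n_err, 20, 0.25).pvalue > 0.05

    def test_linear_trial_table_has_no_choice_column(self):
        cfg = rv.SimConfig(seed=7, n_trials=6)
        beh = rv.simulate_behavior(cfg)
        assert "choice" not in beh.trials.columns
        assert set(beh.trials.reward_site_cm) == {0.0, 200.0}

    def test_speed_profile_separates_runs_and_pauses(self):
        from replayvta.io import compute_speed

        cfg = rv.SimConfig(seed=8, n_trials=10)
        beh = rv.simulate_behavior(cfg)
        speed = compute_speed(beh)
        pause_mid = beh.pauses.contains(beh.t) & ~beh.pauses.contains(beh.t + 1.0) \
            & ~beh.pauses.contains(beh.t - 1.0)
        run = beh.direction != 0
        assert np.median(speed[run]) > 10.0
        deep_pause = beh.pauses.contains(beh.t) & beh.pauses.contains(beh.t + 1) \
            & beh.pauses.contains(beh.t - 1)
        assert np.median(speed[deep_pause]) < 10.0

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            rv.SimConfig(task="circular")


class TestHippocampus:
    def test_same_seed_byte_identical(self):
        d1 = session_digest(rv.SimConfig(seed=42, n_trials=6))
        d2 = session_digest(rv.SimConfig(seed=42, n_trials=6))
        d3 = session_digest(rv.SimConfig(seed=43, n_trials=6))
        assert d1 == d2 and d1 != d3

    def test_zero_replay_fraction_has_no_replay_truth(self):
        cfg = rv.SimConfig(seed=9, n_trials=10, replay_fraction=0.0)
        beh = rv.simulate_behavior(cfg)
        _, _, truth = rv.simulate_hippocampus(beh, cfg)
        assert not truth.events.is_replay.any()

    def test_single_cell_spikes_histogram_peaks_at_field(self):
        cfg = rv.SimConfig(seed=10, n_trials=20, n_place_cells=1,
                           spwr_rate_hz=1e-6, pause_rate_hz=1e-3)
        beh = rv.simulate_behavior(cfg)
        with pytest.warns(UserWarning):  # one cell cannot tile the track
            spk, _, truth = rv.simulate_hippocampus(beh, cfg)
        center = truth.cells.center_cm.iloc[0]
        pos = np.interp(spk.time, beh.t, beh.lin_pos)
        counts, edges = np.histogram(pos, bins=20, range=(0, 200))
        peak = (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1]) / 2
        assert abs(peak - center) <= 10.0

    def test_replay_trajectory_kinematics(self):
        """A trajectory at speed v over duration d spans v*d centimeters."""
        cfg = rv.SimConfig(seed=12, n_trials=30, replay_fraction=1.0,
                           replay_speed_cms=500.0, event_duration_s=(0.2, 0.2),
                           reward_bias=0.0)
        beh = rv.simulate_behavior(cfg)
        _, _, truth = rv.simulate_hippocampus(beh, cfg)
        reps = truth.events[truth.events.is_replay]
        assert len(reps) > 5
        for _, ev in reps.iterrows():
            span = abs(ev.speed_cms) * (ev.end - ev.start)
            assert span == pytest.approx(100.0, abs=1.0)

    def test_events_lie_within_pauses(self):
        cfg = rv.SimConfig(seed=13, n_trials=20)
        beh = rv.simulate_behavior(cfg)
        _, _, truth = rv.simulate_hippocampus(beh, cfg)
        assert len(truth.events) > 5
        for _, ev in truth.events.iterrows():
            assert beh.pauses.contains(np.array([ev.start]))[0]
            assert beh.pauses.contains(np.array([ev.end]))[0]

    def test_mark_centroids_respect_separation(self):
        cfg = rv.SimConfig(seed=14, n_trials=6)
        beh = rv.simulate_behavior(cfg)
        _, _, truth = rv.simulate_hippocampus(beh, cfg)
        cent = truth.cells[[f"mark{k}_uv" for k in range(4)]].to_numpy()
        d = np.linalg.norm(cent[:, None] - cent[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= cfg.mark_min_separation_uv

    def test_spike_counts_scale_with_rate(self):
        """Doubling the tuning-curve peak doubles run-epoch spike counts."""
        base = rv.SimConfig(seed=15, n_trials=20, spwr_rate_hz=1e-6)
        cfg2 = rv.SimConfig(seed=15, n_trials=20, spwr_rate_hz=1e-6,
                            place_peak_hz=30.0, pause_rate_hz=0.5)
        beh = rv.simulate_behavior(base)
        n1 = len(rv.simulate_hippocampus(beh, base)[0])
        n2 = len(rv.simulate_hippocampus(beh, cfg2)[0])
        assert n2 / n1 == pytest.approx(2.0, rel=0.05)


class TestVta:
    def test_unit_gain_one_leaves_peth_flat(self):
        cfg = rv.SimConfig(seed=16, n_trials=30, vta_spwr_gain=1.0,
                           n_vta_units=2, rr_fraction=1.0)
        beh = rv.simulate_behavior(cfg)
        _, _, truth = rv.simulate_hippocampus(beh, cfg)
        vta, _, _ = rv.simulate_vta(beh, truth, cfg)
        events = IntervalSet(truth.events[["start", "end"]].to_numpy(), "spwr")
        # restrict to events well after the nosepoke windows are over
        p = rv.peth(vta.units[0], events)
        assert p.modulation_depth < 0.35

    def test_uniform_theta_phases_when_kappa_zero(self):
        hits = 0
        for seed in range(10):
            cfg = rv.SimConfig(seed=seed, n_trials=12, kappa_true=0.0,
                               n_vta_units=1, rr_fraction=0.0)
            beh = rv.simulate_behavior(cfg)
            _, lfp, truth = rv.simulate_hippocampus(beh, cfg)
            vta, _, _ = rv.simulate_vta(beh, truth, cfg)
            theta = rv.bandpass(lfp, (4, 12))
            run = IntervalSet.from_mask(beh.direction != 0, beh.t, "run")
            tl = rv.theta_locking(vta.units[0], theta, run)
            hits += tl.rayleigh_p > 0.05
        assert hits >= 9

    def test_vta_lfp_deflection_at_configured_lag(self):
        cfg = rv.SimConfig(seed=17, n_trials=30, vta_lag_ms=84.0)
        beh = rv.simulate_behavior(cfg)
        _, _, truth = rv.simulate_hippocampus(beh, cfg)
        _, vlfp, _ = rv.simulate_vta(beh, truth, cfg)
        events = IntervalSet(truth.events[["start", "end"]].to_numpy(), "spwr")
        _, _, latency, _ = rv.event_triggered_lfp(vlfp, events)
        assert abs(latency - 84.0) <= 10.0


class TestSws:
    def test_no_injected_events_means_empty_frames(self):
        cfg = rv.SimConfig(seed=18, sws_duration_s=60, frame_spwr_rate_hz=0.0)
        _, _, _, truth = rv.simulate_sws(cfg)
        assert len(truth.events) == 0
        assert (truth.frame_table.n_spwr == 0).all()

    def test_vta_rate_scales_with_sws_factor(self):
        cfg = rv.SimConfig(seed=19, sws_duration_s=200, vta_sws_scale=0.5,
                           n_vta_units=4, rr_fraction=0.0)
        _, vta, _, truth = rv.simulate_sws(cfg)
        for u, st in enumerate(vta.units):
            rate = len(st) / cfg.sws_duration_s
            base = truth.frame_table  # frames irrelevant; compare to meta
            expect = vta.meta.baseline_hz[u] * 0.5
            assert rate == pytest.approx(expect, rel=0.15)

    def test_silent_periods_give_exact_frame_recovery(self):
        cfg = rv.SimConfig(seed=20, sws_duration_s=120, silent_rate_hz=0.0)
        hc, _, _, truth = rv.simulate_sws(cfg)
        frames = rv.detect_frames(hc.time, IntervalSet(
            np.array([[0.0, cfg.sws_duration_s]]), "sws"))
        mids = (truth.frames.starts + truth.frames.ends) / 2
        assert frames.contains(mids).mean() > 0.9
        # every detected SPW-R midpoint lies inside a frame
        if len(truth.events):
            spwr_mids = (truth.events.start + truth.events.end) / 2
            assert frames.contains(spwr_mids.to_numpy()).all()


class TestPipelineRecovery:
    def test_spwr_detection_sensitivity_on_generated_session(self):
        """The burst detector recovers nearly all generated events with a
        negligible false-event rate at default settings."""
        from replayvta.io import compute_speed

        cfg = rv.SimConfig(seed=21, n_trials=30)
        beh = rv.simulate_behavior(cfg)
        spk, _, truth = rv.simulate_hippocampus(beh, cfg)
        speed = compute_speed(beh)
        mua = rv.compute_mua(spk.time, beh.span, n_tetrodes=cfg.n_tetrodes)
        detected = rv.detect_spwr(mua, beh.t, speed)
        mids = (truth.events.start + truth.events.end) / 2
        sensitivity = detected.contains(mids.to_numpy()).mean()
        assert sensitivity >= 0.95
        true_set = IntervalSet(truth.events[["start", "end"]].to_numpy(), "spwr")
        det_mids = (detected.starts + detected.ends) / 2
        false_rate = (~true_set.contains(det_mids)).sum() / beh.span[1]
        assert false_rate < 0.02

    def test_unit_profiling_recovers_true_classes(self):
        """The profiling pipeline recovers the generated RR / nonRR labels."""
        from replayvta.vta import profile_units

        cfg = rv.SimConfig(seed=22, n_trials=30)
        beh = rv.simulate_behavior(cfg)
        spk, lfp, truth = rv.simulate_hippocampus(beh, cfg)
        vta, _, _ = rv.simulate_vta(beh, truth, cfg)
        events = IntervalSet(truth.events[["start", "end"]].to_numpy(), "spwr")
        theta = rv.bandpass(lfp, (4, 12))
        run = IntervalSet.from_mask(beh.direction != 0, beh.t, "run")
        prof = profile_units(vta.units, beh.trials, beh.task, events, theta,
                             run, beh.span)
        agree = (prof["klass"].to_numpy() == vta.meta["klass"].to_numpy()).mean()
        assert agree >= 0.9
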