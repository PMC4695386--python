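import numpy as np
import pytest

import replayvta as rv
from replayvta._utils import mc_pvalue
from replayvta.config import AnalysisConfig
from replayvta.replay import (CandidateEvent, PathGrid, TrajectoryFit,
                              _candidate_grid, score_trajectories)
from replayvta.track import LinearTrack


def make_event(P, event_id=0, animal_pos=100.0, bin_s=0.025, direction_P=None,
               track=None):
    P = np.asarray(P, dtype=float)
    track = track or LinearTrack.linear(200.0)
    edges = np.arange(P.shape[0] + 1) * bin_s
    post = rv.Posterior(edges, P, track.bin_centers, direction_P)
    return CandidateEvent(event_id, (0.0, P.shape[0] * bin_s), post, animal_pos)


@pytest.fixture(scope="module")
def track():
    return LinearTrack.linear(200.0)


def linear_event_P(track, start_cm, speed_cms, n_bins, conc=40.0):
    """Posterior concentrated on a constant-speed line."""
    t = (np.arange(n_bins) + 0.5) * 0.025
    pos = start_cm + speed_cms * (t - t.mean())
    d = np.abs(track.bin_centers[None, :] - pos[:, None])
    P = np.exp(-0.5 * (d / 5.0) ** 2) * conc
    return P / P.sum(axis=1, keepdims=True)


class TestFitTrajectory:
    def test_perfect_line_scores_one(self, track):
        P = np.zeros((8, track.n_bins))
        # mass exactly on the bins of a 400 cm/s line through mid-track
        t = (np.arange(8) + 0.5) * 0.025
        pos = 60.0 + 400.0 * (t - t.mean())
        idx = (pos / 10).astype(int)
        P[np.arange(8), idx] = 1.0
        ev = make_event(P)
        fits = rv.fit_trajectory(ev, track)
        best = max(fits, key=lambda f: f.score)
        assert best.score == pytest.approx(1.0)
        speed_on_track = best.speed_cms if best.path_id == "outbound" \
            else -best.speed_cms
        assert abs(speed_on_track - 400.0) <= 100.0

    def test_uniform_posterior_band_counting(self, track100=None):
        """A mid-track flat line over a uniform posterior collects exactly
        the 3-of-10 bins inside the 15 cm band."""
        track100 = LinearTrack.linear(100.0)
        grid = PathGrid(track100, track100.paths[0], band_cm=15.0)
        P = np.full((10, 10), 0.1)
        cand_pos = np.full((1, 10), 55.0)  # flat line at mid-track
        score = score_trajectories(P, grid, cand_pos)[0]
        assert score == pytest.approx(0.3)

    def test_grid_scores_match_exhaustive_enumeration(self):
        """Every candidate score equals brute-force band counting on a
        2-bin, 4-spatial-bin toy posterior."""
        track4 = LinearTrack.linear(40.0)
        P = np.array([[0.4, 0.3, 0.2, 0.1], [0.1, 0.3, 0.2, 0.4]])
        path = track4.paths[0]
        cfg = AnalysisConfig()
        grid = PathGrid(track4, path, cfg.replay_band_cm)
        sp, ic, pos = _candidate_grid(path, np.array([0.0125, 0.0375]),
                                      cfg.speed_grid_cms)
        scores = score_trajectories(P, grid, pos)
        # brute force, using the position grid the scorer quantizes to
        for c in range(0, len(sp), 97):
            expect = 0.0
            for t in range(2):
                p_snap = grid.pos_grid[grid.pos_index(pos[c, t])]
                within = np.abs(track4.bin_centers - p_snap) <= 15.0
                expect += P[t, within].sum()
            assert scores[c] == pytest.approx(expect / 2, abs=1e-12)

    def test_short_path_rejected(self):
        tiny = LinearTrack.linear(10.0)
        ev = make_event(np.full((3, 1), 1.0), track=tiny)
        with pytest.raises(ValueError):
            rv.fit_trajectory(ev, tiny)

    def test_time_reversal_symmetry(self, track):
        """Reversing the event in time flips the best speed, not the score."""
        P = linear_event_P(track, 80.0, 300.0, 6)
        f_fwd = max(rv.fit_trajectory(make_event(P), track),
                    key=lambda f: f.score)
        f_rev = max(rv.fit_trajectory(make_event(P[::-1].copy()), track),
                    key=lambda f: f.score)
        assert f_fwd.score == pytest.approx(f_rev.score, abs=1e-12)
        fwd_track_speed = f_fwd.speed_cms * (1 if f_fwd.path_id == "outbound" else -1)
        rev_track_speed = f_rev.speed_cms * (1 if f_rev.path_id == "outbound" else -1)
        assert fwd_track_speed == pytest.approx(-rev_track_speed)


class TestColumnCycleShuffle:
    def test_uniform_rows_are_shift_invariant(self, track):
        P = np.full((5, track.n_bins), 1.0 / track.n_bins)
        ev = make_event(P)
        fits = rv.fit_trajectory(ev, track)
        scores = rv.column_cycle_shuffle(ev, track, n=200, seed=3)
        for f in fits:
            assert np.allclose(scores[f.path_id], f.score, atol=1e-12)
            assert mc_pvalue(f.score, scores[f.path_id]) == 1.0

    def test_small_toy_matches_exhaustive_enumeration(self):
        """T=2, S=3: Monte-Carlo p converges to the full 9-shift enumeration."""
        track3 = LinearTrack.linear(30.0)
        P = np.array([[0.7, 0.2, 0.1], [0.1, 0.2, 0.7]])
        ev = make_event(P, track=track3)
        cfg = AnalysisConfig()
        grid = {p.path_id: PathGrid(track3, p) for p in track3.paths}
        fits = rv.fit_trajectory(ev, track3, cfg, grid)
        best = max(fits, key=lambda f: f.score)
        # exhaustive: all 9 combinations of row shifts
        from replayvta.replay import _best_scores_batch, _candidate_grid

        path = next(p for p in track3.paths if p.path_id == best.path_id)
        _, _, pos = _candidate_grid(path, ev.posterior.time_centers,
                                    cfg.speed_grid_cms)
        all_shifts = [np.vstack([np.roll(P[0], i), np.roll(P[1], j)])
                      for i in range(3) for j in range(3)]
        exact = _best_scores_batch(np.array(all_shifts), grid[best.path_id], pos)
        p_exact = np.mean(exact >= best.score - 1e-12)
        mc = rv.column_cycle_shuffle(ev, track3, n=5000, seed=5, cfg=cfg,
                                     grids=grid)
        p_mc = np.mean(mc[best.path_id] >= best.score - 1e-12)
        assert abs(p_mc - p_exact) <= 0.02


class TestPseudoEventShuffle:
    def test_identical_pool_rows_give_degenerate_p(self, track):
        row = np.full(track.n_bins, 1.0 / track.n_bins)
        pool = np.tile(row, (200, 1))
        ev = make_event(np.tile(row, (4, 1)))
        scores = rv.pseudo_event_shuffle(ev, pool, track, n=150, seed=9)
        for s in scores.values():
            assert np.allclose(s, s[0])
        fits = rv.fit_trajectory(ev, track)
        p = mc_pvalue(fits[0].score, scores[fits[0].path_id])
        assert p in (pytest.approx(1 / 151), pytest.approx(1.0))

    def test_pool_smaller_than_event_rejected(self, track):
        ev = make_event(np.full((6, track.n_bins), 1.0 / track.n_bins))
        with pytest.raises(ValueError):
            rv.pseudo_event_shuffle(ev, np.full((3, track.n_bins), 0.05),
                                    track, n=100, seed=0)

    def test_location_concentrated_event_not_significant(self, track):
        """A temporally constant, reward-site-concentrated event is exactly
        what this shuffle controls for: it must not reach significance."""
        row = np.exp(-0.5 * ((track.bin_centers - 5.0) / 5.0) ** 2)
        row /= row.sum()
        P = np.tile(row, (6, 1))
        ev = make_event(P)
        pool = np.vstack([P, P, P, P, P])  # session dominated by that content
        fits = rv.fit_trajectory(ev, track)
        scores = rv.pseudo_event_shuffle(ev, pool, track, n=300, seed=4)
        best = max(fits, key=lambda f: f.score)
        assert mc_pvalue(best.score, scores[best.path_id]) > 0.05


class TestClassifyReplay:
    def test_linear_event_is_replay(self, track, decoded_candidates):
        cands, pool = decoded_candidates
        P = linear_event_P(track, 60.0, 300.0, 8)
        ev = make_event(P, event_id=901)
        lab = rv.classify_replay(ev, track, pool, seed=1)
        assert lab.label == "replay"
        assert lab.best_fit.p_column < 0.05 and lab.best_fit.p_pseudo < 0.05

    def test_uniform_event_is_nonreplay_enriched(self, track, decoded_candidates):
        _, pool = decoded_candidates
        P = np.full((8, track.n_bins), 1.0 / track.n_bins)
        lab = rv.classify_replay(make_event(P, event_id=902), track, pool,
                                 seed=1)
        assert lab.label == "nonreplay_enriched"

    def test_short_event_is_ambiguous(self, track):
        P = np.full((2, track.n_bins), 1.0 / track.n_bins)
        lab = rv.classify_replay(make_event(P, event_id=903), track,
                                 np.full((200, track.n_bins), 0.05), seed=1)
        assert lab.label == "ambiguous" and lab.best_fit is None

    def test_stringent_mode_scores_single_path(self, track, decoded_candidates):
        _, pool = decoded_candidates
        P = linear_event_P(track, 60.0, 300.0, 8)
        lab = rv.classify_replay(make_event(P, event_id=904), track, pool,
                                 seed=1, mode="stringent")
        scored = [f for f in lab.fits if f.p_column is not None]
        assert len(scored) == 1
        assert lab.label == "replay"


class TestBinGeometry:
    def _dirP(self, outbound_mass):
        out = np.asarray(outbound_mass, dtype=float)
        return np.column_stack([out, 1 - out])

    def test_direction_index_formula(self, track):
        P = np.full((3, track.n_bins), 1.0 / track.n_bins)
        dP = self._dirP([0.9, 0.5, 0.2])
        ev = make_event(P, direction_P=dP)
        fit = TrajectoryFit("outbound", 200.0, 100.0, 0.5)
        lab = rv.label_bin_geometry(ev, fit, track)
        assert np.allclose(lab.di, [0.8, 0.0, -0.6])
        assert lab.directional.tolist() == [True, False, True]

    def test_centrifugal_forward_at_far_reward_site(self, track):
        """Animal paused at 190 cm; trajectory moves 180 -> 140 cm with
        decoded inbound running direction: centrifugal and forward."""
        n = 4
        P = np.full((n, track.n_bins), 1.0 / track.n_bins)
        dP = self._dirP([0.05] * n)  # strongly inbound
        ev = make_event(P, animal_pos=190.0, direction_P=dP)
        dur = n * 0.025
        fit = TrajectoryFit("outbound", (140.0 - 180.0) / dur, 160.0, 0.5)
        lab = rv.label_bin_geometry(ev, fit, track)
        assert lab.centrifugal
        assert lab.forward[lab.directional].all()

    def test_centripetal_reverse_at_near_site(self, track):
        """Animal at 0 cm; trajectory 100 -> 40 cm with decoded outbound
        direction: centripetal and reverse."""
        n = 4
        P = np.full((n, track.n_bins), 1.0 / track.n_bins)
        dP = self._dirP([0.95] * n)
        ev = make_event(P, animal_pos=0.0, direction_P=dP)
        dur = n * 0.025
        fit = TrajectoryFit("outbound", (40.0 - 100.0) / dur, 70.0, 0.5)
        lab = rv.label_bin_geometry(ev, fit, track)
        assert not lab.centrifugal
        assert not lab.forward[lab.directional].any()


class TestMatchEvents:
    def test_identical_distributions_keep_everything(self):
        vals = np.linspace(0.1, 0.3, 40)
        ia, ib = rv.match_events(vals, vals.copy(), seed=0)
        assert len(ia) == 40 and len(ib) == 40

    def test_zero_caliper_matches_intersection(self):
        a = np.array([1.0] * 8 + [2.0] * 8 + [3.0] * 8)
        b = np.array([2.0] * 8 + [3.0] * 8 + [4.0] * 8)
        ia, ib = rv.match_events(a, b, seed=0, caliper=0.0)
        assert set(a[ia]) == {2.0, 3.0}
        assert np.allclose(a[ia], b[ib])

    def test_shifted_lognormals_balance_after_matching(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(7)
        a = np.exp(rng.normal(np.log(0.209), 0.3, 300))
        b = np.exp(rng.normal(np.log(0.161), 0.3, 300))
        ia, ib = rv.match_events(a, b, seed=1)
        assert mannwhitneyu(a[ia], b[ib]).pvalue > 0.2

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            rv.match_events(np.zeros(5), np.ones(5) * 100, seed=0, caliper=1.0)
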