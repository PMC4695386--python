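"""Replay detection: trajectory fitting, shuffle nulls, classification.

A candidate SPW-R event is decoded in 25 ms bins; a constant-speed
trajectory is fitted per candidate path by grid search over (speed,
intercept), scored by the replay score R — the mean posterior mass within
15 cm (along the track) of the trajectory. Significance comes from two
Monte-Carlo shuffles: the column-cycle shuffle (circularly shift each time
bin's spatial PDF) controls for chance linear alignment, and the
pseudo-event shuffle (replace each PDF with one drawn from the session pool
of candidate-event PDFs) controls for location bias. An event is replay
when both shuffles give p < 0.05 on at least one path, and nonreplay-
enriched when both give p > 0.2 on every path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import mannwhitneyu

from ._utils import mc_pvalue, substream
from .config import AnalysisConfig
from .decoding import Posterior
from .track import LinearTrack, Path


@dataclass
class CandidateEvent:
    event_id: int
    interval: tuple
    posterior: Posterior
    animal_pos_cm: float
    spike_counts: np.ndarray | None = None  # per time bin
    participation: float | None = None  # fraction of units active

    @property
    def n_bins(self) -> int:
        return self.posterior.P.shape[0]

    @property
    def duration(self) -> float:
        return float(self.interval[1] - self.interval[0])


@dataclass
class TrajectoryFit:
    path_id: str
    speed_cms: float  # signed, along the path coordinate
    intercept_cm: float  # path coordinate at the event midpoint
    score: float  # replay score R in [0, 1]
    p_column: float | None = None
    p_pseudo: float | None = None
    n_shuffles: int = 0


@dataclass
class ReplayLabel:
    label: str  # {"replay", "nonreplay_enriched", "ambiguous"}
    best_fit: TrajectoryFit | None
    fits: list = field(default_factory=list)


@dataclass
class BinDirectionLabel:
    di: np.ndarray  # (T,) direction index in [-1, 1]
    directional: np.ndarray  # (T,) bool, |DI| > threshold
    forward: np.ndarray  # (T,) bool where directional, else False
    centrifugal: bool  # event-level: trajectory moves away from the animal


class PathGrid:
    """Precomputed scoring machinery for one candidate path.

    band_mask[k, s] is True when spatial bin s lies within the replay band
    of path position grid point k (along-track distance); the replay score
    of a candidate trajectory is then a lookup into P @ band_mask.T.
    """

    def __init__(self, track: LinearTrack, path: Path,
                 band_cm: float = 15.0, pos_step_cm: float = 5.0) -> None:
        self.path = path
        self.pos_grid = np.arange(0.0, path.length + pos_step_cm / 2, pos_step_cm)
        self.pos_step = pos_step_cm
        lin = track.path_to_linear(path, np.clip(self.pos_grid, 0,
                                                 path.length - 1e-9))
        d = track.distance(lin[:, None], track.bin_centers[None, :])
        self.band_mask = (d <= band_cm).astype(float)  # (n_pos, S)
        # narrow band used only to break ties among equal replay scores
        self.tie_mask = (d <= band_cm / 3.0).astype(float)

    def pos_index(self, pos: np.ndarray) -> np.ndarray:
        idx = np.round(np.clip(pos, 0, self.path.length) / self.pos_step)
        return idx.astype(int)


class _NarrowView:
    """PathGrid proxy exposing the tie-break band as the scoring band."""

    def __init__(self, grid: PathGrid) -> None:
        self.band_mask = grid.tie_mask
        self.pos_index = grid.pos_index


def _candidate_grid(path: Path, time_centers: np.ndarray,
                    speed_grid: tuple) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All (speed, intercept) candidates and their per-bin path positions."""
    smin, smax, step = speed_grid
    mags = np.arange(smin, smax + step / 2, step)
    speeds = np.concatenate([-mags[::-1], mags])
    bin_w = 10.0
    intercepts = np.arange(bin_w / 2, path.length, bin_w)
    sp, ic = np.meshgrid(speeds, intercepts, indexing="ij")
    sp, ic = sp.ravel(), ic.ravel()
    t_rel = time_centers - time_centers.mean()
    pos = ic[:, None] + sp[:, None] * t_rel[None, :]  # (n_cand, T)
    return sp, ic, np.clip(pos, 0.0, path.length)


def score_trajectories(P: np.ndarray, grid: PathGrid, cand_pos: np.ndarray
                       ) -> np.ndarray:
    """Replay score of every candidate trajectory for posterior P (T, S)."""
    B = P @ grid.band_mask.T  # (T, n_pos)
    idx = grid.pos_index(cand_pos)  # (n_cand, T)
    T = P.shape[0]
    acc = np.zeros(idx.shape[0])
    for t in range(T):
        acc += B[t, idx[:, t]]
    return acc / T


def fit_trajectory(
    event: CandidateEvent,
    track: LinearTrack,
    cfg: AnalysisConfig | None = None,
    grids: dict | None = None,
) -> list[TrajectoryFit]:
    """Best constant-speed trajectory per candidate path, by replay score."""
    cfg = cfg or AnalysisConfig()
    if event.n_bins < 2:
        raise ValueError("trajectory fitting needs at least 2 time bins")
    grids = grids or {p.path_id: PathGrid(track, p, cfg.replay_band_cm)
                      for p in track.paths}
    tc = event.posterior.time_centers
    fits = []
    for path in track.paths:
        if path.length < cfg.replay_band_cm:
            raise ValueError(f"path {path.path_id} shorter than the replay band")
        g = grids[path.path_id]
        sp, ic, pos = _candidate_grid(path, tc, cfg.speed_grid_cms)
        scores = score_trajectories(event.posterior.P, g, pos)
        top = scores.max()
        tied = np.where(scores >= top - 1e-12)[0]
        if tied.size > 1:
            # the wide band leaves many trajectories tied at the top score;
            # prefer the one hugging the posterior most tightly, then the
            # slowest candidate (symmetric under time reversal)
            narrow = score_trajectories(event.posterior.P,
                                        _NarrowView(g), pos[tied])
            final = tied[narrow >= narrow.max() - 1e-12]
            order = np.lexsort((ic[final], sp[final], np.abs(sp[final])))
            best = int(final[order[0]])
        else:
            best = int(tied[0])
        fits.append(TrajectoryFit(path.path_id, float(sp[best]),
                                  float(ic[best]), float(scores[best])))
    return fits


def _best_scores_batch(P_batch: np.ndarray, grid: PathGrid,
                       cand_pos: np.ndarray) -> np.ndarray:
    """Best replay score per shuffled posterior. P_batch: (n, T, S)."""
    n, T, S = P_batch.shape
    B = np.tensordot(P_batch, grid.band_mask, axes=([2], [1]))  # (n, T, n_pos)
    idx = grid.pos_index(cand_pos)  # (n_cand, T)
    acc = np.zeros((n, idx.shape[0]))
    for t in range(T):
        acc += B[:, t, idx[:, t]]
    return acc.max(axis=1) / T


def column_cycle_shuffle(
    event: CandidateEvent,
    track: LinearTrack,
    n: int = 1500,
    seed: int = 0,
    cfg: AnalysisConfig | None = None,
    grids: dict | None = None,
) -> dict:
    """Column-cycle shuffle null: per-path best-score samples.

    Each sample circularly shifts every time bin's spatial PDF by an
    independent random offset and refits the trajectory grid.
    """
    cfg = cfg or AnalysisConfig()
    if n < 100:
        warnings.warn("fewer than 100 shuffles: unstable p-values")
    rng = substream(seed, "column_cycle", event.event_id)
    P = event.posterior.P
    T, S = P.shape
    shifts = rng.integers(0, S, size=(n, T))
    cols = (np.arange(S)[None, None, :] - shifts[:, :, None]) % S
    P_shuf = np.take_along_axis(np.broadcast_to(P, (n, T, S)), cols, axis=2)
    grids = grids or {p.path_id: PathGrid(track, p, cfg.replay_band_cm)
                      for p in track.paths}
    tc = event.posterior.time_centers
    out = {}
    for path in track.paths:
        _, _, pos = _candidate_grid(path, tc, cfg.speed_grid_cms)
        out[path.path_id] = _best_scores_batch(P_shuf, grids[path.path_id], pos)
    return out


def pseudo_event_shuffle(
    event: CandidateEvent,
    session_bin_pool: np.ndarray,
    track: LinearTrack,
    n: int = 1500,
    seed: int = 0,
    cfg: AnalysisConfig | None = None,
    grids: dict | None = None,
) -> dict:
    """Pseudo-event shuffle null: rows drawn from the session bin pool.

    session_bin_pool is the (n_pool, S) stack of spatial PDFs from all
    candidate events of the session; each shuffle builds an artificial
    event of the same length from pool rows drawn with replacement.
    """
    cfg = cfg or AnalysisConfig()
    pool = np.asarray(session_bin_pool, dtype=float)
    T = event.n_bins
    if pool.shape[0] < T:
        raise ValueError("bin pool smaller than the event length")
    if pool.shape[0] < 100:
        warnings.warn("bin pool has fewer than 100 rows")
    rng = substream(seed, "pseudo_event", event.event_id)
    draws = rng.integers(0, pool.shape[0], size=(n, T))
    P_shuf = pool[draws]  # (n, T, S)
    grids = grids or {p.path_id: PathGrid(track, p, cfg.replay_band_cm)
                      for p in track.paths}
    tc = event.posterior.time_centers
    out = {}
    for path in track.paths:
        _, _, pos = _candidate_grid(path, tc, cfg.speed_grid_cms)
        out[path.path_id] = _best_scores_batch(P_shuf, grids[path.path_id], pos)
    return out


def classify_replay(
    event: CandidateEvent,
    track: LinearTrack,
    session_bin_pool: np.ndarray,
    seed: int = 0,
    mode: str = "standard",
    cfg: AnalysisConfig | None = None,
    grids: dict | None = None,
) -> ReplayLabel:
    """Classify one candidate event as replay / nonreplay-enriched / ambiguous.

    standard mode runs both shuffles on every path and requires both
    p < 0.05 on the same path for replay; stringent mode runs the shuffles
    only on the path with the strongest observed replay score. Events
    shorter than the minimum bin count are ambiguous by construction.
    """
    cfg = cfg or AnalysisConfig()
    if event.n_bins < cfg.min_event_bins:
        return ReplayLabel("ambiguous", None, [])
    grids = grids or {p.path_id: PathGrid(track, p, cfg.replay_band_cm)
                      for p in track.paths}
    fits = fit_trajectory(event, track, cfg, grids)
    col = column_cycle_shuffle(event, track, cfg.n_shuffles, seed, cfg, grids)
    pse = pseudo_event_shuffle(event, session_bin_pool, track, cfg.n_shuffles,
                               seed, cfg, grids)
    best_i = int(np.argmax([f.score for f in fits]))
    eval_idx = [best_i] if mode == "stringent" else range(len(fits))
    for i in eval_idx:
        f = fits[i]
        f.p_column = mc_pvalue(f.score, col[f.path_id])
        f.p_pseudo = mc_pvalue(f.score, pse[f.path_id])
        f.n_shuffles = cfg.n_shuffles

    scored = [fits[i] for i in eval_idx]
    is_replay = any(
        f.p_column < cfg.replay_p and f.p_pseudo < cfg.replay_p for f in scored
    )
    is_nonreplay = all(
        f.p_column > cfg.nonreplay_p and f.p_pseudo > cfg.nonreplay_p
        for f in scored
    )
    if is_replay:
        sig = [f for f in scored
               if f.p_column < cfg.replay_p and f.p_pseudo < cfg.replay_p]
        best = max(sig, key=lambda f: f.score)
        return ReplayLabel("replay", best, fits)
    if is_nonreplay:
        return ReplayLabel("nonreplay_enriched", fits[best_i], fits)
    return ReplayLabel("ambiguous", fits[best_i], fits)


def label_bin_geometry(
    event: CandidateEvent,
    fit: TrajectoryFit,
    track: LinearTrack,
    di_threshold: float = 0.5,
) -> BinDirectionLabel:
    """Forward/reverse and centrifugal/centripetal labels for event bins.

    The direction index DI = (O - I)/(O + I) uses the decoded run-direction
    posterior; bins with |DI| <= threshold stay unlabeled. The event is
    centrifugal when the along-track distance between the fitted trajectory
    and the animal increases over the event. A directional bin is forward
    when the decoded run direction matches the spatial propagation
    direction of the fitted trajectory.
    """
    if event.posterior.direction_P is None:
        raise ValueError("event has no direction posterior")
    dP = event.posterior.direction_P
    denom = dP[:, 0] + dP[:, 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        di = (dP[:, 0] - dP[:, 1]) / denom
    directional = (denom > 0) & (np.abs(di) > di_threshold)

    path = next(p for p in track.paths if p.path_id == fit.path_id)
    tc = event.posterior.time_centers
    t_rel = tc - tc.mean()
    s_path = np.clip(fit.intercept_cm + fit.speed_cms * t_rel, 0,
                     path.length - 1e-9)
    lin = track.path_to_linear(path, s_path)
    d_animal = track.distance(lin, np.full(lin.shape, event.animal_pos_cm))
    centrifugal = bool(d_animal[-1] > d_animal[0])

    # propagation direction in track coordinates: outbound when the linear
    # coordinate increases along the fit
    prop_outbound = lin[-1] >= lin[0]
    decoded_outbound = di > 0
    forward = directional & (decoded_outbound == prop_outbound)
    return BinDirectionLabel(di, directional, forward, centrifugal)


def match_events(
    group_a: np.ndarray,
    group_b: np.ndarray,
    seed: int = 0,
    caliper: float | None = None,
    p_target: float = 0.2,
    max_rounds: int = 20,
):
    """Covariate-match two event groups by greedy nearest neighbor.

    Pairs are matched without replacement within a caliper, which is
    tightened until the matched groups show no rank-sum covariate
    difference (p > p_target). Returns (indices into a, indices into b).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if caliper is None:
        caliper = max(a.std(), b.std(), 1e-12)
    rng = substream(seed, "match_events")
    for _ in range(max_rounds):
        order = rng.permutation(a.size)
        used = np.zeros(b.size, dtype=bool)
        ia, ib = [], []
        for i in order:
            d = np.abs(b - a[i])
            d[used] = np.inf
            j = int(np.argmin(d))
            if d[j] <= caliper:
                ia.append(i)
                ib.append(j)
                used[j] = True
        if len(ia) < 10:
            raise ValueError("fewer than 10 matchable pairs")
        av, bv = a[ia], b[ib]
        if np.allclose(av, bv) or mannwhitneyu(av, bv).pvalue > p_target:
            return np.array(ia), np.array(ib)
        caliper /= 2.0
    raise ValueError("could not balance the groups within the caliper budget")
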