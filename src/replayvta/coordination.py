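"""Coordination of VTA spiking with replayed spatial content.

Each 25 ms replay time bin gets a binary reward-site indicator: 1 when the
average posterior probability per spatial bin inside reward regions exceeds
the average outside them. VTA spike-associated bins are the subset of
replay bins that precede unit spikes by a fixed lag. The excess reward site
bias is the indicator proportion among spike-associated bins minus the
proportion among all replay bins; significance comes from a one-sample
chi-square against the replay proportion, and contrasts between unit groups
from a permutation test on the interaction term of a logistic regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from ._utils import substream
from .intervals import IntervalSet


@dataclass
class BiasResult:
    n_bins: int
    bias: float
    excess: float | None = None
    chi2: float | None = None
    p: float | None = None


@dataclass
class FrameStats:
    table: pd.DataFrame  # one row per frame
    splits: dict  # split name -> per-unit paired mean differences


def spike_associated_bins(
    bin_intervals: np.ndarray,
    vta_spikes: np.ndarray,
    lag: float = 0.084,
) -> np.ndarray:
    """Boolean mask of replay bins that precede unit spikes by `lag`.

    Bin b is selected when at least one spike falls in
    [b.start + lag, b.end + lag); half-open on the right, so a spike at
    exactly start + lag belongs to that bin. Selection is binary per bin.
    """
    bins = np.atleast_2d(np.asarray(bin_intervals, dtype=float))
    spikes = np.asarray(vta_spikes, dtype=float)
    sel = np.zeros(bins.shape[0], dtype=bool)
    if spikes.size == 0 or bins.size == 0:
        return sel
    idx = np.searchsorted(bins[:, 0] + lag, spikes, side="right") - 1
    ok = idx >= 0
    ok[ok] &= spikes[ok] < bins[idx[ok], 1] + lag
    sel[np.unique(idx[ok])] = True
    return sel


def reward_site_bias(
    P: np.ndarray, reward_mask: np.ndarray
) -> tuple[np.ndarray, float]:
    """Per-bin reward-site indicators and their mean (the bias).

    The indicator is 1 when the mean posterior probability per spatial bin
    inside reward regions strictly exceeds the mean outside them; ties are
    0 ("exceeds" is strict).
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    reward_mask = np.asarray(reward_mask, dtype=bool)
    if reward_mask.all():
        raise ValueError("reward regions cover the whole track")
    if not reward_mask.any():
        raise ValueError("reward regions are empty")
    inside = P[:, reward_mask].mean(axis=1)
    outside = P[:, ~reward_mask].mean(axis=1)
    ind = (inside > outside).astype(int)
    return ind, float(ind.mean()) if ind.size else 0.0


def excess_bias_chi2(
    unit_bias: float, ref_bias: float, n_unit_bins: int
) -> tuple[float, float, float]:
    """Excess bias of spike-associated bins with a one-sample chi-square.

    Tests the unit-bin indicator proportion against the all-replay-bin
    proportion treated as a fixed reference (df = 1):
    chi2 = n (p_hat - p0)^2 / (p0 (1 - p0)).
    """
    if n_unit_bins <= 0:
        raise ValueError("need at least one spike-associated bin")
    excess = unit_bias - ref_bias
    denom = ref_bias * (1.0 - ref_bias)
    if denom == 0:
        raise ValueError("degenerate reference proportion")
    if n_unit_bins * min(ref_bias, 1 - ref_bias) < 5:
        warnings.warn("expected counts below 5: chi-square approximation weak")
    chi2 = n_unit_bins * excess**2 / denom
    p = float(chi2_dist.sf(chi2, df=1))
    return float(excess), float(chi2), p


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return np.log(p / (1 - p))


def interaction_coefficient(pA1: float, pB: float, pA2: float, pC: float
                            ) -> float:
    """Interaction term of the saturated logistic regression.

    The model stacks two comparisons (B vs A, comparison = 1; C vs A,
    comparison = 0) with predictors unit-membership, comparison, and their
    interaction; with four cells and four parameters the fit is saturated,
    so the interaction coefficient has the closed form
    [logit pB - logit pA1] - [logit pC - logit pA2].
    """
    return float(_logit(np.array([pB]))[0] - _logit(np.array([pA1]))[0]
                 - _logit(np.array([pC]))[0] + _logit(np.array([pA2]))[0])


def interaction_se(pA: float, pB: float, pC: float,
                   nA: int, nB: int, nC: int) -> float:
    """Standard error of the interaction coefficient (saturated model)."""
    def v(p, n):
        p = min(max(p, 1e-9), 1 - 1e-9)
        return 1.0 / (n * p * (1 - p))
    return float(np.sqrt(v(pB, nB) + v(pC, nC) + 2 * v(pA, nA)))


def permutation_interaction_test(
    bias_a: float, bias_b: float, bias_c: float,
    n_a: int, n_b: int, n_c: int,
    n_iter: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """One-tail permutation test of the B-vs-A minus C-vs-A contrast.

    The observed statistic is the interaction coefficient of the logistic
    regression of the reward-site indicator on unit membership, comparison,
    and their interaction. The null distribution re-evaluates the
    coefficient on group proportions set to the overall mean plus Gaussian
    perturbations whose s.d. is calibrated (by bisection) so the simulated
    coefficients' spread matches the observed coefficient's standard error.
    Returns (p, observed coefficient).
    """
    if n_iter <= 0:
        raise ValueError("n_iter must be positive")
    beta_obs = interaction_coefficient(bias_a, bias_b, bias_a, bias_c)
    se_obs = interaction_se(bias_a, bias_b, bias_c, n_a, n_b, n_c)
    rng = substream(seed, "permutation_interaction")
    p0 = (bias_a + bias_b + bias_c) / 3.0
    noise = rng.standard_normal((n_iter, 4))

    def sim_betas(s: float) -> np.ndarray:
        p = np.clip(p0 + s * noise, 1e-6, 1 - 1e-6)
        return (_logit(p[:, 0]) - _logit(p[:, 1])
                - _logit(p[:, 2]) + _logit(p[:, 3]))

    lo, hi = 1e-5, 0.5
    betas = sim_betas(hi)
    for _ in range(20):
        mid = 0.5 * (lo + hi)
        betas = sim_betas(mid)
        sd = betas.std()
        if abs(sd - se_obs) <= 0.1 * se_obs:
            break
        if sd > se_obs:
            hi = mid
        else:
            lo = mid
    k = int(np.sum(betas >= beta_obs))
    p = (1.0 + k) / (n_iter + 1.0)
    return float(p), beta_obs


def lag_sweep(
    bin_intervals: np.ndarray,
    indicators: np.ndarray,
    vta_spikes: np.ndarray,
    lags: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Excess reward-site bias as a function of the VTA lag.

    Returns (lags, excess curve, argmax lag). Lags default to 0..200 ms in
    25 ms steps.
    """
    if lags is None:
        lags = np.arange(0.0, 0.200 + 1e-9, 0.025)
    indicators = np.asarray(indicators)
    ref = indicators.mean() if indicators.size else 0.0
    excess = np.full(lags.size, np.nan)
    for i, lag in enumerate(lags):
        sel = spike_associated_bins(bin_intervals, vta_spikes, lag)
        if sel.any():
            excess[i] = indicators[sel].mean() - ref
    best = float(lags[np.nanargmax(excess)]) if np.isfinite(excess).any() else np.nan
    return lags, excess, best


def frame_stats(
    frames: IntervalSet,
    frame_posteriors: list,
    spwr_events: IntervalSet,
    vta_units: list,
    min_per_side: int = 5,
) -> FrameStats:
    """Per-frame statistics and high/low split comparisons.

    Per frame: duration, SPW-R rate (events whose midpoint falls inside the
    frame, per second), spatial content (mean over time bins of the maximum
    decoded probability), and per-unit firing rate. Splits compare each
    unit's rate across frames above versus below the mean SPW-R rate and
    mean spatial content, plus the inverse split of frame SPW-R rate by
    unit rate relative to that unit's mean.
    """
    mids = (spwr_events.starts + spwr_events.ends) / 2 if len(spwr_events) else \
        np.empty(0)
    rows = []
    for k, (s, e) in enumerate(frames):
        dur = e - s
        n_ev = int(np.sum((mids >= s) & (mids < e)))
        P = frame_posteriors[k]
        content = float(P.max(axis=1).mean()) if P is not None and len(P) else np.nan
        row = {"frame": k, "start": s, "end": e, "duration": dur,
               "spwr_rate": n_ev / dur, "spatial_content": content}
        for u, st in enumerate(vta_units):
            st = np.asarray(st)
            row[f"unit{u}_rate"] = np.sum((st >= s) & (st < e)) / dur
        rows.append(row)
    table = pd.DataFrame(rows)

    splits = {}
    n_units = len(vta_units)
    for split_col in ("spwr_rate", "spatial_content"):
        vals = table[split_col].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        if not ok.any():
            continue  # statistic not computed for these frames
        high = ok & (vals > np.nanmean(vals))
        low = ok & ~high
        if high.sum() < min_per_side or low.sum() < min_per_side:
            warnings.warn(f"split on {split_col}: too few frames per side")
            continue
        diffs = np.array([
            table.loc[high, f"unit{u}_rate"].mean()
            - table.loc[low, f"unit{u}_rate"].mean()
            for u in range(n_units)
        ])
        splits[f"unit_rate_by_{split_col}"] = diffs
    # inverse split: frame SPW-R rate by unit rate above/below the unit mean
    inv = np.full(n_units, np.nan)
    for u in range(n_units):
        r = table[f"unit{u}_rate"].to_numpy(dtype=float)
        high = r > r.mean()
        if high.sum() >= min_per_side and (~high).sum() >= min_per_side:
            inv[u] = (table.loc[high, "spwr_rate"].mean()
                      - table.loc[~high, "spwr_rate"].mean())
    splits["spwr_rate_by_unit_rate"] = inv
    return FrameStats(table, splits)
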