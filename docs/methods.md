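# Methods

`replayvta` implements an analysis chain that links midbrain (VTA) unit
activity to hippocampal sharp wave-ripple (SPW-R) replay, together with a
synthetic session generator that produces complete recordings with exported
ground truth. This note documents the models, the fixed constants and why
they hold their values, the numerical choices, and what the synthetic
validation does and does not establish.

## Event detection

Hippocampal multiunit activity (MUA) is binned at 10 ms, expressed in Hz
per tetrode, and Gaussian-smoothed (σ = 10 ms). SPW-R multiunit events are
bursts whose peak exceeds the trace mean by 4 standard deviations while the
animal moves slower than 10 cm/s; each event's boundaries are the nearest
crossings of the mean rate on either side of the peak, touching events are
merged, and events shorter than 50 ms (two decoding bins) are dropped.
Boundary placement at the nearest mean-crossing is unique and independent
of processing order. Speed comes from the centered difference of the
tracked position, Gaussian-smoothed with σ = 0.25 s.

Ripple power is summarized per event as the maximum of the Hilbert
envelope of the 100–300 Hz (Blackman FIR, zero-phase) filtered LFP,
z-scored against the envelope over all non-event, low-speed samples. The
peak (rather than mean) envelope is used because a ripple is a transient;
the choice is isolated in one function.

Slow-wave sleep is detected from the theta (4–12 Hz) to delta (1–4 Hz)
power ratio in 10 s windows hopped every 1 s (threshold 1.0), gated by a
posture flag. Each window votes only for its central hop, which keeps epoch
boundaries at hop rather than window resolution. Frames within SWS are
maximal runs of 10 ms bins whose σ = 30 ms smoothed population spike count
exceeds a threshold set at the first local minimum of the per-bin
spike-count histogram; if the histogram is unimodal the threshold falls
back to a configurable quantile (default 0.75) with a warning.

## Track model and linearization

The track is a graph of straight segments adjoined into one linear
coordinate (linear track: one 200 cm segment; end-to-end T maze: two 75 cm
force arms, a 150 cm central arm, two 75 cm choice arms, adjoined in the
choice-run direction). Because adjacency in the linear coordinate is partly
artificial, every distance between linear coordinates is computed on the
segment graph (within-segment distance plus shortest node-to-node path),
never by naive subtraction. Tracked 2-D positions are projected to the
nearest segment; samples farther than 10 cm off-track are flagged and
interpolated. Candidate replay paths are the two directed traversals of the
linear track or the four force-to-choice well paths of the maze (each
300 cm).

## Clusterless decoding

The decoder is a marked point-process model. Per tetrode, encoding spikes
(run epochs, speed > 10 cm/s; peak amplitude > 100 μV and width > 300 μs)
contribute a product kernel — Gaussian in linearized position (bandwidth
6 cm) times an independent Gaussian in each of the four amplitude-mark
channels (bandwidth 15 μV) — normalized by the position occupancy, which is
floored at 10⁻³ of uniform to keep unvisited bins finite. The likelihood of
a time bin multiplies, over in-bin spikes, the joint (position, mark)
intensity, applies the Poisson no-spike factor exp(−Δ·Λ(x)) for the bin
exposure, combines tetrodes, and normalizes under a uniform spatial prior;
everything runs in log space. Bins without spikes are returned as exactly
uniform rows, so an empty bin can never express a spatial preference — this
is the stated fallback and doubles as the decoder-bias control (with no
spikes, reward and non-reward bins receive identical mass). Running
direction is reconstructed by the same machinery with two direction classes
in place of the spatial bins. Sorted-unit decoding is standard Poisson
population decoding from tuning curves of cells whose peak place-field rate
exceeds 3 Hz. Cross-validation alternates 1 s training and testing blocks,
decodes the test blocks in 500 ms bins, and reports the median along-track
error, a confusion matrix, and the run-direction 0/1 error.

Bandwidth values follow the spatial bin scale (10 cm) and the mark-noise
scale of tetrode amplitudes; both are configurable. MAP ties break toward
the lowest bin index.

## Replay detection

Candidate events are decoded in non-overlapping 25 ms bins; events with
fewer than 3 bins (75 ms) are automatically ambiguous. For each candidate
path a constant-speed trajectory is grid-searched: speeds ±0.5–15 m/s in
0.25 m/s steps, intercepts (path coordinate at the event midpoint) at
10 cm bin centers; trajectories are clamped at path ends. The replay score
R is the mean posterior mass within 15 cm along-track of the trajectory.
Because the 15 cm band leaves many trajectories exactly tied at the top
score, ties are broken by the score in a 5 cm band, then by preferring the
slowest candidate — a deterministic rule that is symmetric under time
reversal of the event.

Two Monte-Carlo nulls re-run the identical fit on perturbed data: the
column-cycle shuffle circularly shifts each time bin's spatial PDF by an
independent random offset (destroying temporal alignment while preserving
each bin's spatial concentration), and the pseudo-event shuffle rebuilds
the event from PDFs drawn with replacement from the session-wide pool of
candidate-event bins (destroying everything except the session's location
occupancy, hence controlling for static location bias). P-values use the
add-one rule (1 + #{R_null ≥ R_obs})/(n + 1) and can never be zero; the
default is 1500 shuffles. An event is *replay* when both shuffles give
p < 0.05 on the same path, *nonreplay-enriched* when both give p > 0.2 on
every path, otherwise *ambiguous*. The stringent variant runs the shuffles
only on the path with the strongest observed score. Shuffle random streams
are keyed by event id, so results do not depend on processing order.

Per-bin content direction uses the direction index DI = (O − I)/(O + I)
from the run-direction posterior; bins with |DI| ≤ 0.5 stay unlabeled. An
event is centrifugal when the along-track distance between the fitted
trajectory and the animal's position increases over the event, centripetal
when it decreases. A directional bin is forward when the decoded running
direction matches the spatial propagation direction of the fit, reverse
otherwise; this general rule reduces to the standard reading (outbound
content at a departure-end pause is forward) in the cases that matter.

Duration- or spike-count-matched event sets are built by greedy
nearest-neighbor matching without replacement inside a caliper that is
halved until a rank-sum test on the matched covariates exceeds p = 0.2.

## VTA unit characterization

Reward-responsive (RR) classification: on the maze task a unit is RR when
correct- and error-trial rates differ (two-sided t-test, p < 0.05) in
either the 2 s approach window before the nosepoke or the 3 s acquisition
window after it; on the linear track, when acquisition rates differ from a
3 s baseline ending 2 s before the nosepoke. Units with baseline rate below
0.3 Hz are unclassified (undersampled PETHs). Waveform summaries are the
duration from the major peak to the final peak and the trough-to-peak ratio
trough/(peak + trough) on absolute amplitudes.

The SPW-R PETH aligns spikes to event onsets (5 ms bins, σ = 50 ms
Gaussian smoothing). Modulation depth is |PETH(midpoint) − baseline| /
baseline, where the test point is the PETH at the median event-midpoint lag
(a fixed "midpoint bin" is ill-defined across variable-length events) and
the baseline is the mean over a 300 ms window ending 100 ms before onset
(a 5 s baseline ending 1 s before onset is available as an option). The
sign of modulation is read off the smoothed PETH. Significance bootstraps
the event rows jointly for the 50 ms midpoint bin and the baseline; the
default decision is whether the 95% bootstrap CI of the midpoint-minus-
baseline difference excludes zero, which operates at the nominal 5% level
(validated at 2–8% on null units). Declaring significance when the two
marginal CIs fail to overlap is available as `method="overlap"`, but that
rule is far more conservative (roughly a 0.5% test) and cannot sit in a
2–8% calibration band; the difference-CI is therefore the default.

Theta phase locking interpolates the Hilbert angle of the theta-filtered
LFP at run-epoch spike times (convention: 0° at the theta peak, increasing
with time), applies Rayleigh's test against a unimodal alternative, and
fits von Mises (μ, κ) by maximum likelihood with κ capped at 50; μ is
reported in [−180°, 180°). Units with fewer than 50 run spikes are flagged
unreliable.

## Coordination of VTA spiking with replayed content

Each 25 ms replay bin receives a binary reward-site indicator: 1 when the
mean posterior probability per spatial bin inside the reward regions
(default ±10 cm around each reward well, matching the 10 cm binning)
strictly exceeds the mean outside; ties are 0. Averaging per spatial bin
normalizes for the unequal sizes of the reward and non-reward areas. A
unit's spike-associated bins are the replay bins with at least one spike in
the bin window shifted by the VTA lag (default 84 ms, the latency of the
SPW-R-triggered VTA field potential); selection is binary per bin per unit,
and bins are pooled per unit within the RR and nonRR groups. The excess
reward-site bias is the spike-associated indicator proportion minus the
all-replay-bin proportion; its significance is a one-sample chi-square of
the unit-bin proportion against the replay proportion as a fixed reference
(df = 1), switchable to a 2×2 two-sample form. A current-location exclusion
mask is available for the variant that removes the animal's own position
from the regions.

Group contrasts (e.g., RR vs nonRR) use a logistic regression of the
indicator on unit membership, comparison, and their interaction. With four
cells and four parameters the model is saturated, so the interaction
coefficient and its standard error have closed forms (differences of
logits; delta-method SE), which a statsmodels GLM fit reproduces — the GLM
is kept as a cross-check, not the implementation. The one-tail permutation
p compares the observed coefficient with 1000 simulated coefficients whose
group proportions are the overall mean plus Gaussian perturbations; the
perturbation s.d. is calibrated by bisection (≤ 20 iterations) until the
simulated coefficients' spread is within 10% of the observed coefficient's
standard error. The lag sweep recomputes the excess bias at lags 0–200 ms
in 25 ms steps and reports the argmax.

Frame statistics: per frame, duration, SPW-R rate (event midpoints per
second), spatial content (mean over 25 ms bins of the row-maximum decoded
probability; 1/S for uniform rows), and per-unit rates, with splits of unit
rate by frames above/below the mean SPW-R rate or spatial content, and the
inverse split of SPW-R rate by unit rate; splits with fewer than 5 frames
per side are skipped.

## Synthetic session generator

One master seed drives named, independent substreams per stage (behavior,
place cells, spikes, events, LFP, VTA, SWS), so a seed fully determines the
session and stages can be re-run in any order. Defaults describe a linear-
track session: 200 cm track, 30 place cells (Gaussian tuning, 20 cm FWHM,
peak ≈ 15 Hz, theta-modulated at 8 Hz with per-cell preferred phase and a
direction preference), five tetrodes, 4-D mark centroids rejection-sampled
at least 40 μV apart with 15 μV within-cell noise. Behavior alternates
runs (~40 cm/s) with self-paced reward-well dwells (log-normal, median
9 s); maze sessions alternate forced-sample and free-choice test phases
with the correct choice opposite the forced turn and errors injected
uniformly at random (default rate 0.25).

SPW-R events occur only inside pauses (0.25 Hz by default), last 100–300
ms, and drive the population at a ×6 gain on the tuning curves evaluated
along the event content: for replay events a constant-speed trajectory
(default 2 m/s) sampled at 1 ms resolution whose start falls inside a
reward region with probability `reward_bias`; for nonreplay events
positions drawn i.i.d. per 25 ms step. The 2 m/s default matters: it keeps
a replayed trajectory inside a 10 cm reward region for about two 25 ms
bins, so reward-gated coupling (below) has support; it lies well inside
the fitted speed grid. LFP is broadband noise plus run-gated theta and a
180 Hz ripple burst under a Gaussian envelope during events.

VTA units are RR with probability `rr_fraction`; RR units gain ×2.5 in the
acquisition window on correct trials only, and multiply their rate by
`vta_spwr_gain` in a window delayed by `vta_lag_ms` (default 84) after each
event onset — optionally only while the concurrent true trajectory
occupies a reward region (`couple_reward_only`). All units are von Mises
theta-locked with concentration `kappa_true` through an
exp(κ cos(θ − μ))/I₀(κ) rate factor, which leaves the mean rate unchanged.
The VTA LFP carries a −60 μV deflection at the configured lag after each
event. SWS alternates frames (≈1.2 s, population drive ≈250 Hz) with
silent periods; SPW-Rs occur only inside frames at per-frame rates with
log-normal variation, and VTA rates are scaled down (default ×0.5), with
an optional extra gain in frames whose SPW-R rate is above the mean.

What the generator does *not* emulate: phase precession, rate remapping,
realistic waveform shapes beyond the four amplitude marks, non-Poisson
spike-train structure (bursting, refractoriness), electrode drift,
correlated mark noise, and across-unit heterogeneity in theta
concentration or coupling strength (every VTA unit shares one κ and one
gain, so correlations *between* per-unit κ and per-unit coupling have no
generative counterpart here). Passing the validation suite therefore shows that
the pipeline recovers the structures it targets when those structures are
present as modeled — not that it is robust to every pathology of real
tetrode data.

## Validation experiments and problem sizes

The standard validation suite (module `replayvta.experiments`, rerun by
`scripts/acceptance.py`) uses these sizes: decoder recovery on a 60-trial
(~15 min) session decoded in 500 ms bins; replay calibration with 200
injected trajectory events and 500 null events assembled by the
pseudo-event generative process, both at 250 shuffles; shuffle-null
uniformity on 500 row-shifted events (Kolmogorov–Smirnov against uniform);
modulation-depth recovery at gains {0.5, 2, 3} over 200 events (six units
per gain averaged) plus 200 null units for bootstrap calibration; von Mises
recovery at 10⁴ phases; coupling recovery over 10 session seeds with gain 5
restricted to reward-region trajectory bins; and the SWS frame split over
10 seeds at a 0.7× anti-correlated gain. On these sizes, typical outcomes
are a cross-validated median error of 3–5 cm, replay sensitivity above
95% with a null false-positive rate near 5%, depth recovery within 0.15,
κ̂ within 2% at n = 10⁴, permutation p < 0.05 for the RR-vs-nonRR contrast
in all seeds, and a pooled lag-sweep argmax at 75 ms — the grid point
nearest the injected 84 ms lag.

## Known limitations

- Trajectory clamping at path ends slightly inflates scores of events whose
  content sits at a track end; both shuffles share the clamping, so the
  p-values remain calibrated.
- The chi-square treats the all-replay-bin proportion as a fixed reference;
  with few spike-associated bins the approximation weakens (a warning fires
  below 5 expected counts), and the permutation contrast is the more
  trustworthy statistic.
- The SWS detector's windowing truncates epoch edges by up to half a window
  at recording boundaries.
- `IntervalSet.intersect` is quadratic; it is used only on small interval
  lists (epochs, not samples).
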