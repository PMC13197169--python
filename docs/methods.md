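# Methods

This note documents the models, statistical conventions, numerical choices
and known limitations of `planact`. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Task model

The Tower of London variant uses three pegs of capacities 3, 2 and 1 and
three colored balls; only the top ball of a peg may move, and only onto a
peg with free capacity. The state space has exactly 36 states (6 occupancy
distributions × 3! ball orderings) and its move graph is connected, so any
start/goal pair is solvable. The solver is a layer-synchronous breadth-first
search that retains every minimal-length predecessor, yielding both the
optimal length and the complete set of optimal move sequences; uniqueness of
the optimal solution is therefore verified exactly, not sampled.

Problem "families" are start/goal pairs up to relabeling of the three
colors (the 3! = 6 bijections). The published bank is not available, so the
generator samples families satisfying the stated constraints — unique
optimal solution, optimal length 2 or 4, half of each — and expands each
family into its six color permutations (12 × 6 = 72 problems by default).
Everything is deterministic under the seed: states serialize canonically
(pegs 1→3, bottom→top), moves and paths sort lexicographically, and family
candidates are sampled from a sorted list with `random.Random(seed)`.
A scheduling helper distributes a bank into blocks such that no block
contains two problems of the same family.

## Generative model of the recordings

The synthetic EEG is deliberately minimal and additive; every analysis
property tested here concerns the machinery, not the brain. Per trial:

* **Readiness potential**: zero before onset (default −0.9 s), a linear
  negative ramp reaching −|peak| µV at the key press (t = 0), then an
  exponential return (τ = 0.15 s). Cell-specific peaks: by default the
  self-generated first move gets 6 µV, self other moves 2 µV, all
  stimulus-driven cells 1.5 µV. Exact per-position amplitudes may override
  the position-class value (used by the trend studies). A per-participant
  amplitude scale ~ N(1, 0.1) adds between-subject variability.
* **Beta oscillation**: a 20 Hz cosine with uniform random phase whose
  envelope declines linearly from the base amplitude (3 µV) to
  base × (1 − suppression) over the 0.8 s before the press, recovering to
  base by +0.5 s. Suppression defaults: self first 0.6, self other 0.45,
  stimulus 0.3.
* **Noise**: spectrally shaped 1/f^a noise (a = 1, normalized to sample SD
  6 µV per realization) plus white noise (SD 3 µV), independent per
  channel.

Spatial profiles are fixed Gaussian-like weight maps peaking at FCz for the
RP and at C3/C1 for beta; mastoids and EOG carry noise only. The montage
has 17 channels (16 EEG + EOG) and documents its own channel count; the
decoding exclusion rule (EOG + O1/O2/POz) leaves 13 features.

Reaction times are log-normal per design cell. The defaults invert the
arithmetic mean/SD of the reference cells (e.g. self four-move first move
5.36 s, stimulus two-move other moves 1.18 s) into (µ, σ) via
σ² = ln(1 + CV²); the reported SDs are used as trial-level coefficients of
variation, which is a generator choice, not a claim about the original
trial-level spread. Epochs are time-locked to the first (selection) press
of each move; the config exposes `time_lock` because a two-press move
leaves the epoching press ambiguous.

`simulate_dataset` emits epochs directly on the analysis grid (a closed
[−1.0, +0.5] s window at 200 Hz → 301 samples; beta analyses use a separate
pass with the [−2.0, +1.0] s window). A continuous-recording generator
(`simulate_continuous`, with 2.5–6.5 s jittered inter-move intervals at a
1 kHz native rate) exists to exercise the full conditioning chain.

## Preprocessing

Fixed stage order: mastoid-average re-reference → zero-phase Butterworth
band-pass → polyphase downsampling to 200 Hz → epoch extraction → ±120 µV
rejection at the RP ROI. The "8th-order zero-phase" filter is an 8th-order
design applied forward–backward (squared magnitude). It is realized as
cascaded high-pass (0.05 Hz) and low-pass (30 Hz) second-order sections: a
single band-pass design with a cutoff at 10⁻⁴ of Nyquist is numerically
unreliable, while the cascade is stable and its designed response meets the
≥ 40 dB stopband requirement (verified on the transfer function — the
0.05 Hz high-pass has multi-second transients, so time-domain measurements
need long records). No baseline correction exists anywhere in the package;
the config refuses a baseline setting.

Epoch grids are closed intervals inclusive of both endpoints; t = 0 is the
event sample. The beta statistical window "−998 … +499 ms" is honored by
masking to the nearest available samples of the beta grid.

## Cluster-based permutation inference

Pointwise dependent-sample t against zero (df = n − 1); contiguous
same-sign samples exceeding the cluster-forming threshold (p < 0.05 on the
t distribution; 0.975 quantile two-tailed, 0.95 one-tailed) form clusters
scored by summed t (single-sample clusters allowed). The null is the
distribution of the maximum cluster mass over per-participant whole-series
sign flips; Monte-Carlo p = (b + 1)/(n_permutations + 1), never zero — at
5,000 permutations the floor prints as 0.0002.

Conventions chosen where the field varies:

* **Two-tailed testing** uses per-tail max-mass nulls with *alpha halving*
  (each cluster significant at test_alpha/2 per tail) rather than
  p-doubling. This keeps the printed p floor identical for one- and
  two-tailed tests and controls the family-wise rate at test_alpha.
* **Negation closure**: the sign-flip set contains −s for every drawn s.
  The positive- and negative-tail nulls are then identical as multisets, so
  a single null vector serves both tails and p is exactly monotone in
  |mass| within a result; the null is also invariant under flipping the
  input's sign.
* **Paired tests** (condition-label swaps within participant) are
  implemented as the sign-flip test on the paired difference — label
  swapping negates each participant's difference, so the two are the same
  test by construction.
* **NaN discipline**: masked samples propagate NaN through the t series and
  can never join a cluster, so clusters cannot span a masked gap.
* **Zero variance**: a zero-variance sample with nonzero mean yields
  t = ±∞ (logged); a cluster containing it has infinite mass and lands at
  or near the p floor. This makes degenerate inputs (e.g. constant perfect
  decoding accuracy) behave sensibly instead of silently vanishing.

The factorial contrasts operate on self-minus-stimulus difference waves per
cell: position = mean(first) − mean(other), length = mean(4-move) −
mean(2-move), interaction = (first−other)₄ − (first−other)₂, each submitted
to the one-sample test. The linear trend applies weights
[1.5, 0.5, −0.5, −1.5] across the four positions of four-move sequences;
the planned contrast compares nonfinal {2-move first; 4-move first, second,
third} against final {2-move final; 4-move final} cells. Participants with
a missing cell are excluded from the factorial-style tests only, with a log
entry. Permutation defaults follow the per-analysis counts (5,000 for
factorial/trend/planned and decoding-vs-chance, 1,000 for pairwise tests);
both are per-test configuration.

## Time–frequency analysis

Power at each of 1–35 Hz (1 Hz steps) is |⟨x, w_f⟩|² with w_f a Hanning
taper of fixed 0.4 s length (odd sample count, centered) modulating a
complex exponential — the single-taper degenerate case of windowed
multitaper convolution. The taper is normalized by 2/Σw so a pure sinusoid
of amplitude A yields power A² at its frequency; only ratios and
differences of power are interpreted, so the convention does not affect
inference (time-averaged power of a stationary tone equals 2 × its
variance under this scaling). Samples within half a window (0.2 s = 40
samples at 200 Hz) of either epoch end are NaN and excluded from all
statistics. Band power averages 13–30 Hz inclusive, then the Cz/C1/C3 ROI,
then trials within condition. The shared display axis pools the 2nd–98th
percentiles (linear interpolation between order statistics) of valid
in-band values over the −1.0 … +0.5 s window.

## Decoding

At each timepoint the channel pattern is the feature vector for a binary
LDA: w = S_γ⁻¹(m₁ − m₀), b = −wᵀ(m₀+m₁)/2, with the pooled within-class
covariance shrunk toward a scaled identity, S_γ = (1−γ)S + γ(trS/p)I. The
shrinkage intensity is a fixed, configurable policy (default γ = 0.1,
raised to 0.5 with a warning when a training fold has fewer trials than
channels + 2). Accuracy comes from stratified 5-fold cross-validation
repeated 5 times; z-normalization statistics (per-channel mean/SD) come
from training folds only. Decision-boundary ties resolve to the first
class in label order and are logged. Only same-time (diagonal) accuracy is
produced. Group inference reuses the cluster machinery one-sided against
chance 0.5 at α = 0.025; the factorial machinery applies unchanged to the
accuracy series.

RT residualization: log RT standardized within participant, then per
channel × timepoint OLS amplitude = a + b·RTz; the output removes only the
slope term, which zeroes corr(RTz, output) to numerical precision
(~10⁻¹⁶) and is idempotent.

## RT matching

Quantile bin edges come from the stimulus-driven RT distribution — six
edges for five bins, *including the minimum and maximum*, so self trials
outside the stimulus RT range belong to no bin and are never sampled. This
bounding is what makes mean-matching possible at all when self first-move
RTs exceed every stimulus-driven trial. Per iteration (default 1,000), self
trials are drawn without replacement within each bin to hit the stimulus
bin counts; if the self side is deficient in a bin, all targets are
rescaled proportionally (floor), and if a self bin is empty, targets are
clipped per bin — both logged. Matched means are averaged over iterations
and compared with the stimulus means by a closed-form paired t test across
participants. Matching quality is summarized as the mean matched-minus-
stimulus log-RT difference in within-participant log-RT SD units.

The trial-level mixed model of RT
(`log_rt ~ position * condition * length + (1 + position + condition | participant)`)
is recorded for reference; fitting is delegated to standard mixed-model
software and deliberately not implemented here.

## Calibration and recovery battery (`planact.studies`)

Study sizes were chosen so the battery runs in minutes on one CPU:

* **FWER calibration**: 1,000 replications per test family at 1,000
  permutations, 23 participants × 301 timepoints of 1/f + white noise with
  no effect. The one-sided decoding procedure is calibrated by applying it
  to both directions (its stated two-tailed equivalent), so all families
  target a 0.05 family-wise level.
* **Factorial/trend recovery**: 100 datasets each, 23 participants,
  20 trials per cell, ROI-only channel subsets. The factorial study injects
  a self-only first-move-only ramp boost (6 vs 1.5 µV); the trend study
  compares a monotone per-position gradient (5/4/3/2 µV) against a flat
  3.5 µV profile.
* **Decoding**: calibration over 200 null groups and recovery over 100
  groups of 12 participants, 25 trials/class, 13 channels, 2 CV repeats;
  the recovery pattern (amplitude 4 µV across channels) is confined to
  [−0.5, 0] s and detection requires a significant cluster overlapping that
  window.
* **RT matching**: 100 simulations of 23 participants with an RT-linked
  amplitude component (1 µV per log-RT z unit) plus a genuine −1 µV
  condition effect and 2 µV trial noise.

The generator emulates the structure the analyses assume — additive
components, stationary noise, no ocular artifacts, no volume-conduction
geometry, exchangeable trials. Passing calibration therefore shows the
statistics are correct under their own assumptions; it does not certify
behavior under violations (autocorrelated artifacts, non-stationary noise,
strongly unbalanced designs).

## Known limitations

* Ocular-artifact handling by ICA is not reproduced; synthetic data are
  ocular-free and only an EOG channel placeholder exists.
* No spatial (channel-adjacency) clustering — clustering is over time after
  ROI averaging, which is all the analyses here require.
* The problem bank matches the published constraints, not the unpublished
  72 problems; "detour/dead-end" screening beyond unique-optimality is
  exposed as path-multiplicity metrics rather than guessed definitions.
* Mixed-model fitting, post-hoc marginal means and multiplicity corrections
  beyond simple multiplication are out of scope.
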