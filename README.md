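# planact

Preparatory EEG analysis of **self-generated vs stimulus-driven action
sequences** in a Tower of London task — a tested, reusable re-implementation
of the full analysis pipeline, exercised end-to-end on a synthetic-data
generator that emulates the study's recordings.

The package is aimed at cognitive-neurophysiology researchers who want the
statistical machinery of movement-preparation studies (readiness-potential
and beta-band analyses, per-timepoint decoding, RT-confound controls) as
library code with verified calibration, rather than as one-off analysis
scripts.

## What it implements

- **`planact.tol`** — Tower of London state space (3 pegs with capacities
  3/2/1, three colored balls; 36 states), move legality, a BFS solver that
  enumerates *all* optimal move sequences, and a problem-bank generator
  (12 families × 6 color permutations = 72 problems, each verified to have a
  unique optimal solution of length 2 or 4).
- **`planact.simulate`** — multi-participant synthetic EEG epochs time-locked
  to key presses: a negative preparatory ramp (readiness potential, RP) with
  a frontocentral profile, an envelope-suppressed 20 Hz beta oscillation
  with a left-central profile, 1/f + white noise, and log-normal reaction
  times whose cell means reproduce the reference behavioral pattern.
- **`planact.preprocess`** — mastoid re-referencing, zero-phase Butterworth
  band-pass (0.05–30 Hz, 8th order), downsampling to 200 Hz, epoching
  (−1.0 … +0.5 s), ±120 µV rejection at the RP region of interest
  (Fz, FCz, Cz, FC1, FC2). No baseline correction anywhere.
- **`planact.cluster`** — cluster-based permutation inference over time:
  pointwise dependent-sample *t*, clusters scored by summed-*t* mass, sign-flip
  max-cluster-mass nulls (Monte-Carlo p = (b+1)/(n_perm+1)), plus the 2×2
  factorial (position × length) contrasts on self-minus-stim difference
  waves, the linear trend with weights [1.5, 0.5, −0.5, −1.5], and the
  planned final-vs-nonfinal contrast.
- **`planact.tfr`** — fixed-window (0.4 s) Hanning-taper convolution power
  across 1–35 Hz, 13–30 Hz beta-band/ROI averaging (Cz, C1, C3), edge-NaN
  masking (40 samples per epoch end at 200 Hz), difference spectrograms and
  the shared 2nd–98th percentile color axis.
- **`planact.decoding`** — per-timepoint shrinkage-LDA decoding of self vs
  stim (5-fold × 5-repeat stratified CV, fold-wise z-normalization, EOG and
  occipital channels excluded), one-sided cluster tests against chance 0.5
  at α = 0.025, and exact OLS residualization of RT from every
  channel × timepoint.
- **`planact.behavior`** — RT tables, RT-distribution-matched subsampling of
  self trials via stimulus-side quantile bins (5 bins × 1,000 iterations)
  with a paired *t* comparison of matched amplitudes, and RT–amplitude
  correlations.
- **`planact.pipeline`** — configuration, serialization, the `run_pipeline`
  driver and a PNG report.
- **`planact.studies`** — the calibration/recovery battery used by the
  acceptance machinery (false-positive rates, effect-recovery rates).

## Worked example

```python
from planact import tol
bank = tol.generate_problem_bank(n_families=12, n_permutations=6, seed=1)
print(len(bank), sum(p.n_optimal_paths == 1 for p in bank))
# 72 72        -> 72 problems, every one with a unique optimal solution

from planact import cluster
import numpy as np
rng = np.random.default_rng(0)
diff = rng.standard_normal((23, 301)) + 3.0       # 23 participants x time
res = cluster.cluster_test(diff, n_permutations=5000, seed=0)
c = res.clusters[0]
print(f"mass={c.mass:.1f} p={c.p:.4f}")
# mass=4468.7 p=0.0002   -> one full-window cluster at the Monte-Carlo floor
```

Running the full synthetic replica (simulation → rejection → ERP, beta,
decoding and behavioral analyses → JSON/CSV artifacts → figures):

```bash
planact run --out runs/demo --seed 1 --participants 8 --trials-per-cell 20 --nperm 1000
planact report runs/demo
```

The run directory contains per-analysis cluster tables (onset, offset,
mass, Monte-Carlo p), decoding accuracy series, RT-matching summaries and a
`summary.json`; the report renders RT distributions, RP waveforms with
significance bars, and decoding accuracy against the 0.5 chance line.

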