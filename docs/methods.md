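# Methods

This note documents the models, conventions and design choices behind
`sharewave`, in the spirit of a statistical software appendix.  It
states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Sensor model and adjacency

The montage is a fixed template: the 20 scalp electrodes of the
recording (the classic 19-channel 10–20 set plus Oz) and the A1/A2 ear
references.  Spherical template angles are projected
azimuthal-equidistantly onto the head plane (vertex at the origin, the
circumferential ring at radius 0.8).  Two scalp electrodes are spatial
neighbors when their head-plane distance is at most a threshold, default
0.5, chosen so that each interior electrode has 4–6 neighbors and the
scalp graph forms a single connected component; the threshold is
recorded in the montage export.  This mirrors standard
template-neighborhood definitions for low-density caps, where no
digitized positions exist.  Raising the threshold can only add edges
(monotonicity), and references never acquire adjacency.  A1/A2 are
excluded from every analysis stage.

## Synthetic EEG generator

Each trial and channel is simulated independently as

    x(t) = pink(t) + Σ_b g(b, channel, condition) · A_b · osc_b(t)

* `pink` — Gaussian white noise shaped in the frequency domain to a
  power spectrum ∝ f^(−slope), rescaled to an exact RMS of `noise_sd`.
  Defaults: slope 1, 10 µV RMS, matching the 1/f character of scalp EEG.
* `osc_b` — unit-RMS band-limited noise per band b, produced by applying
  the squared magnitude response of a 4th-order Butterworth band-pass
  (the zero-phase forward–backward response) to white noise in the
  frequency domain.  Band noise rather than fixed-frequency sinusoids
  keeps spectra smooth within bands, matching a band-level analysis.
* Base bands and RMS amplitudes: theta 4–8 Hz at 3 µV, alpha 8–12 Hz at
  4 µV, beta 12–20 Hz at 2 µV — oscillations sit below the broadband
  background so band power is a mixture, as in real recordings.
* Effects are multiplicative gains on `A_b` for named
  (band, channel-set, condition) triples; gain 1 is an exact null.  The
  study scenario applies gain 1.25 in the not-share condition to theta
  at F3/Fz/F4/P4/P8/O2 and alpha at Fz/F4/O2.  The asymmetric alpha gain
  at F4 (right) also induces the frontal-asymmetry contrast, since the
  FAA index is defined from those channels' alpha power — no separate
  mechanism is needed.
* Behavioral metadata: liking ratings are Beta-distributed on [0,1]
  with fixed concentration 5 and the shape solved so the median matches
  the configured per-condition value (defaults 0.75 share / 0.45
  not-share); response times are log-normal with the configured medians
  (0.95 s / 0.74 s) and fixed log-SD 0.6 — bounded support and right
  skew respectively, with the exact field distributions unknown.
* Trials are i.i.d. given condition (no subject random effect); the
  analyses pool trials across subjects, and the per-trial `subject` id
  exists for bookkeeping only.

Everything derives from one `numpy` generator seeded by `SimConfig.seed`
— identical configs give bit-identical epochs.  Internally the voltage
streams are drawn in single precision (≈1e−7 relative noise on a
stochastic signal) to halve memory traffic.

**What the generator does not emulate:** eye/muscle artifacts, volume
conduction and the resulting inter-channel correlation, non-stationarity
within trials, subject-level effect heterogeneity, and any coupling
between ratings/response times and the EEG beyond the shared condition
label.  Passing tests therefore demonstrate that the *analysis chain* is
correct and calibrated under its own assumptions — not that real scalp
data would show these effects.

### Scenario sizes

The full-size `paper` scenario keeps the study's acquisition parameters
(316 + 1099 trials, 10.7 s epochs from −0.5 s to 10.2 s at 600 Hz).  The
calibration and recovery studies use scaled variants — identical trial
counts and gains where those are part of the claim being checked, but
2.25–4 s epochs at 300 Hz and band-limited frequency grids — because the
statistical properties under test (null calibration, detection of a
1.25× gain, decoding gain) concern the inference machinery, not the
epoch length.  The shorter epochs make each trial's band-power estimate
noisier, i.e. the scaled studies are conservative for effect recovery.
Sizes used: null calibration 100+100 trials × 200 datasets × 500
permutations; theta recovery 150 vs 500 trials × 50 runs; FAA recovery
150+150 trials × 50 runs; decoding comparison 80+280 trials × 20 seeds.

## Preprocessing

* **Band-pass** (default 0.1–45 Hz): cascade of a 4th-order Butterworth
  high-pass and a 12th-order Butterworth low-pass, each applied forward
  and backward (zero phase) with Gustafsson initial conditions to keep
  edge transients small on epoch-length data.  A plain 4th-order
  band-pass leaves a 50 Hz mains tone at ≈30% amplitude after the
  double pass; the steeper low-pass brings one-octave stopband
  rejection far past 20 dB and 50 Hz below 10% while the maximally flat
  passband keeps repeated filtering idempotent to within 5%.
* **Common average reference**: each scalp channel minus the per-sample
  mean over the 20 scalp channels; A1/A2 are excluded from the mean and
  dropped.  Idempotent by construction.
* **Epoching**: one window per stimulus event, default −0.5 s to
  +10.2 s (6420 samples at 600 Hz); windows that leave the recording are
  an error naming the event.
* **Trial rejection**: any trial whose peak-to-peak amplitude on any
  scalp channel exceeds a threshold (default 300 µV in the pipeline) is
  dropped and logged with the offending channels.  This replaces manual
  visual rejection and ICA-based artifact removal, which are not
  reproducible procedures; the package deliberately offers no ICA.

## Spectral estimation

Power spectral density is estimated per trial/channel on a 1 Hz grid
(2–30 Hz by default) with a sliding window of 7 cycles per frequency —
so ~0.7 s at 10 Hz and ~0.35 s at 20 Hz — advanced in 50 ms steps.
Window lengths round to the nearest odd sample count so windows are
symmetric about their center.  Each window is Hann-tapered and

    P(f, t) = 2 |Σ_n w[n] x[t+n] e^(−i2πfn/fs)|² / (fs Σ_n w[n]²)

gives the one-sided density in µV²/Hz, comparable across window lengths.
No padding is used: centers whose window would cross the epoch edge are
omitted for that frequency (NaN in the TFR, excluded from time
averages).  Time averaging defaults to 0–9 s of the post-stimulus
period, excluding the final second of the 10.2 s epochs.

Band aggregation takes the arithmetic mean of the density over the grid
frequencies inside each band and then the natural log.  Band edges are
**inclusive on both sides**, so 8 Hz belongs to both theta and alpha and
12 Hz to both alpha and beta — the literal reading of the band
definitions; pass half-open intervals to `band_average` to change this.
The FAA index is `ln alpha(F4) − ln alpha(F3)` per trial.  Under the
usual inverse alpha–activity convention a negative index means
relatively greater right-frontal cortical activity.  (The field's verbal
glosses of this sign are notoriously inconsistent; the formula above is
what is computed, always.)

## Cluster-based permutation statistics

The cluster-forming threshold is the two-tailed Student-*t* critical
value at α = 0.05 with df = n₁ + n₂ − 2 (a "95th percentile" rule reads
one-tailed; the two-tailed convention is standard for this family of
tests and matches effects reported in both directions — a one-tailed
mode is available).  Clusters are sign-homogeneous connected components
under the combined frequency-neighbor / channel-neighbor relation,
scored by summed *t*.  The Monte-Carlo null is the maximum absolute
cluster mass over relabelings that preserve group sizes; p-values use
the +1/+1 correction so p ∈ (0, 1], and ties count toward the null
(conservative).  Trials are permuted as exchangeable units pooled across
subjects, matching a fixed-effects design.  Small designs can enumerate
all C(n, n₁) splits exactly, in which case p is the plain enumeration
fraction.  Points where both groups are constant and equal get t = 0.
Per-electrode post-hoc tests use the permutation distribution of the
maximum |t| across the tested electrode family as the multiple-
comparison correction.

## Behavioral tests

Response times are cleaned in a single pass: values at or beyond 3
sample SDs from the mean (both computed once, on the full input) and
values below 200 ms are removed.  The SD rule is deliberately not
iterated — iterating would change the sample the cutoffs were computed
on; when all values are identical (SD = 0) only the 200 ms rule can
fire.  The Mann-Whitney U counts x-above-y pairs with midrank ties;
p-values come from exhaustive enumeration of the rank-sum distribution
when n₁·n₂ ≤ 400 and otherwise from the tie-corrected normal
approximation (no continuity correction).  The effect size is
r = Z/√N, positive when the first group ranks above the second.

## Classification

Features: liking rating; log theta power at F3/Fz/F4/P8/P4/O2; log alpha
power at Fz/F4/O2; FAA — 11 columns.  The electrode sets default to
where the band contrasts are reliably found, or can be taken from a
cluster-test result when running end to end.  Features are z-scored with
training-fold statistics only.  The SVM is libSVM's C-SVC with a linear
kernel and C = 1 via scikit-learn.

SMOTE synthesizes minority rows on segments toward one of the k = 5
nearest minority neighbors.  Two cross-validation orderings exist:

* `paper` (default): balance the whole table, then split 10-fold.  At
  316 + 1099 trials this reproduces the 2198-sample bookkeeping with
  ≈1978/220 train/test partitions — and it leaks, because synthetic
  copies of held-out information reach the training folds.  Reported
  accuracies under this ordering are optimistic.
* `leakfree`: split the original trials first, oversample within each
  training fold only; predictions are made for real trials only.

Classifier significance is a label-permutation test on the CV accuracy
(+1/+1-corrected).  Two feature sets are compared with a paired t-test
on per-trial 0/1 correctness over the same held-out trials; a
zero-variance difference returns t = 0, p = 1 by convention.

## Numerical conventions and degenerate inputs

* Permutation mass comparisons use a 1e−9 absolute slack so that the
  observed labeling, recomputed along the vectorized permutation path,
  always counts toward its own null.
* Zero-denominator classification metrics are reported as 0 with a
  `degenerate` flag rather than NaN.
* Amplitude rejection of every trial yields an empty epoch set plus a
  warning, not an error.
* All Monte-Carlo machinery is deterministic per seed
  (`numpy.random.default_rng`); k-fold assignment, SMOTE draws and SVM
  tie-breaking all derive from explicit seeds.

## Known limitations

* The synthetic effect gains are calibrated to reproduce the
  *qualitative* pattern (direction and electrode placement) and reliable
  detection at the stated trial counts — not the study's reported
  t-values or the 3-percentage-point decoding improvement, which were
  computed on non-deposited human data.  The decoding gain on synthetic
  data is much larger than 3 points.
* Channel–frequency–time (time-resolved) cluster statistics, TFCE, and
  parametric corrections are out of scope; the engine clusters
  channel×frequency grids.
* No ICA, channel interpolation, or artifact simulation.
* EDF import is a thin optional wrapper over `mne` and assumes channel
  names matching the montage.
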