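# Methods

## Problem and pipeline

`ictalemo` classifies single-channel EEG segments as ictal (seizure) or
interictal. The pipeline is:

1. **Wavelet-packet decomposition.** Each segment is decomposed to level
   7 of the full wavelet-packet tree (Coiflet-1 by default), giving 128
   terminal nodes in sequency order; node *f* covers the band
   ((f−1)·fs/256, f·fs/256) Hz.
2. **Feature extraction.** Four families per node — standard deviation
   (F1) and range (F2) of the phase-space Euclidean-distance series,
   the largest singular value of the 3-column delay-embedding matrix
   (F3), and band energy (F4) — concatenated family-major into a
   512-column matrix.
3. **Feature selection.** NSGA-II over 512-bit masks minimizes the
   selected-feature count (O1) and the mean error of 10-fold randomized
   sub-sampling cross-validation of a GRNN on the training partition
   (O2), simultaneously. A single solution is drawn from the rank-1
   Pareto front by knockout binary tournament under the crowded
   comparison operator.
4. **Classification.** A generalized regression neural network — a
   one-pass Gaussian-kernel regressor over z-scored stored patterns —
   scores held-out segments; scores ≥ 0.5 are called ictal.

## Model details and numerical choices

**WPT.** Periodic boundary handling makes the orthogonal filter bank
orthonormal, so node energies sum to the signal energy. Signals whose
length is not a multiple of 2^level are zero-padded up to the next
multiple first: zero padding adds no energy, and at such lengths every
level halves evenly, which keeps Parseval exact (≈1e−16 relative; the
unpadded periodized transform of a 4000-sample segment is off by ≈2.6%).
Symmetric extension is available but excluded from energy guarantees.
A signal too short for the requested level raises an error naming the
maximum feasible level; there is no silent level reduction.

**Phase-space features.** The delay embedding uses lag τ (default 1,
in samples) and fixed dimension 3: rows (v(m), v(m+τ), v(m+2τ)),
m = 1..M−2τ. The distance series is the row-wise Euclidean norm of that
embedding; at τ=1 this is the consecutive-sample form. F1 uses the
sample standard deviation (divisor Q−1). F3 takes the largest singular
value of the trajectory matrix; the retained index is configurable
(`svd_rank_index`). F1–F3 are homogeneous of degree 1 in the input and
F4 of degree 2; F2 is shift-invariant per node. No normalization is
applied at extraction time — scaling belongs to the classifier and is
fitted on training data only, so no test-set statistics can leak in.

**GRNN.** Training stores z-scored patterns (zero-spread features get
unit spread) and 0/1 targets (non-ictal = 0, ictal = 1). Prediction
shifts kernel exponents by their row maximum before exponentiation, so
distances up to 1e3 at σ = 1e−3 stay finite; outputs are clipped to the
exact target range to absorb ~1-ulp summation overshoot. σ is chosen by
grid search over {0.05, 0.1, 0.2, 0.5, 1.0} using randomized
sub-sampling CV **on the training partition only** (`sigma_policy:
grid`, the default), or fixed via config. A follow-up output-update
step mentioned alongside the kernel-average formula in the source
literature is undefined there and not implemented.

**Cross-validation.** O2 uses 10 stratified half-splits (class
proportions within ±1 sample). The splits derive from one CV seed fixed
per run — every mask is scored on identical splits, which removes
objective noise between individuals, makes the objective a pure
function of the mask (hence memoizable), and gives monotone
non-increasing best front error under elitism. The behavior is
switchable by passing a different `cv_seed`. The split ratio is
configurable; "equal training and testing sets" is read as 50/50. MCC
with a zero denominator is reported as NaN, never 0, so trivial
one-class predictors are not silently rewarded.

**NSGA-II.** Canonical Deb machinery: fast non-dominated sorting,
crowding distance with infinite boundary values, binary tournament with
the crowded comparison operator (full ties resolved by the run's RNG),
uniform crossover (single-point available), per-bit mutation at 1/512
(one expected flip per offspring), empty masks repaired by setting one
uniformly chosen bit, and elitist environmental selection that fills
the next generation front by front, truncating the split front by
descending crowding (stable sort, index order breaks ties). "Until
convergence" is operationalized as a fixed generation budget (default
500, matching the reference experiment scale) with optional early stop
after a configurable number of generations with an unchanged rank-1
objective set. The crowding density uses the normalized cuboid
(neighbor-gap) definition; a raw Euclidean nearest-neighbor variant is
available as `crowding_metric="euclidean"` for comparison, since prose
descriptions of the operator sometimes state it that way.

**Experiment protocol.** The outer split is stratified 70/30
train/test. Mask optimization, σ selection and feature scaling see only
the training partition; a leakage test in the suite verifies that
corrupting held-out feature rows changes no training-time artifact.
All randomness flows from one master seed through named substreams
(synthesis, outer split, CV, EA, σ search), recorded in the report for
bit-exact replay. CT (classification wall-clock time) is reported but
never asserted against any reference value, being hardware-dependent.

## Synthetic data

The generator emulates the two-class structure the classifier assumes,
not physiological EEG. Background = 1/f^β Gaussian noise (β default 1,
unit RMS, zero mean) plus a 10 Hz oscillation at 0.5× RMS (a
posterior-rhythm analog). Ictal segments add a spike-and-wave train at
3 Hz: per cycle one sharp biphasic raised-cosine spike (70 ms) followed
by one full mean-zero slow cycle. The slow wave is a complete cycle
rather than a unipolar half-wave so the train is AC-coupled (as real
EEG is) and its power concentrates at the fundamental; with a unipolar
half-wave the background's 10 Hz line would dominate the class-average
periodogram, contradicting the intended 3 Hz rhythmic signature. The
train amplitude is `ictal_amplitude_ratio` × background RMS (default 4,
a strongly separable regime); as the ratio → 0 the classes become
exchangeable. Each segment draws from its own seed-sequence child
stream keyed by segment index, so enlarging a collection never
reshuffles existing segments.

Not emulated: multi-channel structure, artifacts, inter-subject
variability, pre-ictal morphology, non-stationary seizure evolution.
Passing tests therefore demonstrate algorithmic correctness and the
selection dynamics on data with a known planted structure — not
clinical performance.

## Problem sizes used in the checks

Unit tests run on 24-segment collections (12 per class, 5.12 s at
200 Hz). The end-to-end recovery experiment uses 100 segments per
class, 8 informative columns among 504 row-permuted noise columns, and
NSGA-II at population 20 for 100 generations, replicated over 20 seeds;
one replicate takes ~13 s on a single core. The acceptance script runs
one full experiment at the same scale.

## Known limitations

- Binary classification only; no pre-ictal class.
- The feature catalog is fixed to the four families; entropies,
  Lyapunov exponents etc. are out of scope.
- The GRNN stores all training patterns; memory and prediction cost
  grow linearly with training-set size.
- Selection by knockout tournament on the rank-1 front favors
  high-crowding (extreme) solutions; on fronts whose minimum-count end
  is inaccurate, a user may prefer to pick from the archived front CSV
  by hand.
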