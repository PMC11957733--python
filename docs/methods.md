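# Methods

This note records the models and procedures the toolkit implements, the
conventions chosen where the published method descriptions leave room, and
what the synthetic-fixture test results do and do not establish.

## Data model

All augmenters consume and produce a `LabeledWindowSet`: a dense float
tensor of shape *(N, T, S)* with one integer class label per window,
optional integer subject IDs, and a per-window provenance flag
(original/synthetic).  Windows are pre-segmented; the toolkit never
re-windows or imputes.  Time indices are 0-based with half-open slices.
Synthetic windows copy the label of their source window (the
label-preservation assumption underpinning RT and PM augmentation); only
the conditional GAN receives requested labels instead.

Randomness flows through a `RandomStream`: one integer seed plus a spawn
key per (method, window index) derived via `numpy.random.SeedSequence`, so
results are bit-for-bit reproducible and per-window draws are independent
of batch composition.

## Random transformations

Default parameters follow the values commonly used in the comparative
literature: jitter μ=0, σ=0.03 (sensor units); scaling α=0.1; magnitude
and time warping I=4 interior knots, μ=1, σ=0.2; slicing keeps 90 % of the
window; permutation uses 5 segments; window warping uses factors {½, 2};
SPAWNER uses mixing weight μ=0.5 with σ=0.

Conventions the published formulas do not fix:

* **Multichannel handling.**  Jitter and rotation draw independently per
  element, matching their elementwise definitions.  Magnitude warping
  draws an independent spline per channel.  Time-axis warps (slicing
  positions, permutation order, time-warp curve, window-warp windows) are
  shared across channels to preserve inter-channel synchrony of
  co-recorded sensors.  Scaling applies one α to the whole window.
* **Rotation granularity.**  Whether the angle is drawn per window, per
  channel or per element is not specified in the literature we follow; the
  elementwise matrix definition is implemented as written.
* **Spline layout.**  I interior knots evenly spaced over [0, T−1] plus
  the two endpoints, all heights drawn from N(μ, σ²), interpolated by a
  (not-a-knot) cubic spline.  Evaluation at a knot returns its height
  exactly, and an all-ones knot vector yields the identity curve.
* **Time-warp construction.**  The published description gives the smooth
  curve but not how it warps indices.  The standard speed-curve
  construction is used: the spline evaluated per timestep gives positive
  speeds, their cumulative sum rescaled to span [0, T−1] gives a strictly
  increasing warp with pinned endpoints, and the window is linearly
  resampled at the warped positions.  Non-positive speed curves are
  resampled (16 retries) before erroring.
* **Segment permutation.**  A literal timestamp bijection would destroy
  all temporal structure; the implementation shuffles contiguous
  near-equal segments (the first `T mod n` segments one step longer),
  matching the slice-shuffling description of the method's origin.
* **Window warping.**  Two random non-overlapping equal-length
  subsequences (default fraction 0.1 of T) are chosen, one stretched ×2
  and one contracted ×½ by linear interpolation, and the concatenation is
  linearly resampled back to T.  Equal-length windows with these factors
  change the total length by +L/2, so a final global resample is the only
  way to honour the stated "same size as the original" contract;
  consequently the untouched stretches are very slightly resampled too.

## Alignment

DTW uses squared Euclidean local costs across channels and the symmetric
step pattern {(1,1), (1,0), (0,1)} with unit weights, no global band, and
deterministic tie-breaking (diagonal first, then the step consuming a
sample timestep).  ShapeDTW replaces each timestep by its edge-padded raw
subsequence of length 5 (the simplest member of the descriptor family)
flattened across channels.  Suboptimal DTW splits the cost matrix at the
forced cell, aligns prefix and suffix rectangles independently, and joins
the paths, counting the forced cell's local cost once; its cost is by
construction ≥ the unconstrained optimum, with equality at the corners.
The dynamic program is verified exactly against exhaustive path
enumeration for all short sequences.

## Pattern mixing

* **SMOTE** finds the k = 5 nearest same-class neighbours under flattened
  Euclidean distance, picks one uniformly, and interpolates with
  λ ~ U(0, 1).  It is registered but excluded from the default benchmark
  set: interpolating raw sensor windows tends to produce implausible
  intermediate patterns.
* **RGW** warps the sample's values onto a uniformly drawn same-class
  reference's time base: along the DTW path, sample values aligned to each
  reference index are averaged, and the resulting series is linearly
  resampled to length T.
* **DGW** scores each same-label candidate of a bootstrap subset (default
  size 5) by its mean ShapeDTW distance to the subset's other-class
  windows minus its mean distance to the remaining same-label windows, and
  warps onto the argmax teacher via ShapeDTW.  The centroid phrasing found
  in parts of the literature is not computable as written (it does not
  depend on the candidate); the discriminative-teacher score above is the
  construction of the method's original proposal.  Subsets lacking a
  positive or a negative window trigger a warned fallback to RGW.
* **SPAWNER** draws one interior timestep uniformly, forces the alignment
  of the two (same-class) partners through that matching point, averages
  the aligned sequences with scalar weight μ, resamples to T, and adds
  N(0, σ²) noise.  Partners are drawn within the class so the output label
  is well defined.

## Conditional GAN

The cGAN is a deliberately compact, fully deterministic numpy
implementation: a dense generator (latent dim 32, hidden widths 64/64,
linear output) and discriminator (hidden 64/32, logit output), both
conditioned by concatenated one-hot labels, leaky-ReLU activations,
binary-cross-entropy losses, and a manual Adam optimiser (lr 10⁻³).
Windows are standardised per channel for training and de-standardised on
generation.  All widths, learning rates, epochs and batch size are
config-driven.  Training alternates one discriminator and one generator
update per minibatch and records mean per-epoch losses; non-finite losses
abort with the offending epoch.

Diagnostics: the mode-collapse proxy generates 64 windows from a seed
derived from the training seed and flags collapse when their mean pairwise
RMS distance (standardised units) falls below 0.05 — calibrated so a
zero-weight (constant-output) generator is flagged and healthy toy runs
are not.  The divergence proxy fits a line to the generator loss over the
last half of training and flags slopes above 0.05 per epoch.  The
discriminator's mean probability on generated samples is reported as well;
0.5 indicates the adversarial equilibrium.

## Strategy engine and harness

Balanced augmentation adds `round(n·m)` windows (round half away from
zero), sources drawn uniformly with replacement; the conventional factor
grid is {0.2, 0.4, 0.6, 0.8, 1, 2, 3, 4}.  Imbalanced augmentation leaves
the majority class untouched and grows each other class by factor n of its
own count, truncated at the majority count; `compute_nmax` returns
⌊N_majority / N_minority⌋, and the imbalanced grid runs {0.2 … 1} ∪
{2 … n_max}.  With several minority classes each is scaled relative to its
own count — the only reading compatible with the per-class cap.

The harness evaluates each (method, factor) cell under fixed-split,
stratified k-fold, or leave-one-subject-out schemes with independent
repeats, augmenting only the training fold; an assertion guarantees no
synthetic window ever reaches a test fold.  Failed cells are marked and
the sweep continues.  Default repeats: 5.

## Statistics

Macro F1 (AF1) is the unweighted mean of per-class one-vs-rest F1 scores;
zero-denominator precision/recall are set to 0, the standard convention
that keeps AF1 defined on degenerate folds.  The Friedman statistic uses
within-run average ranks with the tie-corrected denominator and the
chi-square approximation (k−1 df); all-constant rows return statistic 0,
p = 1 by convention.  Nemenyi p-values come from the studentized-range
distribution with infinite degrees of freedom applied to standardised
average-rank differences.  Following the comparison protocol the toolkit
mirrors, Nemenyi p-values are additionally compared against a
Bonferroni-adjusted threshold α / (k(k−1)/2) — redundant in principle
(Nemenyi self-corrects) but implemented as described.  Rank tables rank
methods within each dataset row by descending AF1 with average ranks on
ties; aggregation is the column mean.

## Synthetic data

The generator emulates the *structure* of wearable benchmark datasets,
not their physiology: each class is a sinusoid template (per-class
frequency and amplitude), channels are phase-shifted copies of the
template (correlated, as co-recorded sensors are), subjects contribute an
additive baseline offset, and additive Gaussian noise controls difficulty.
Imbalance is a count ratio.  The frozen fixture used throughout the suite
has two classes × 30 windows, T = 32, S = 2, frequencies 1 vs 3 cycles per
window, noise sd 0.1, five subjects with offset sd 0.05 — well separated
by design, so a nearest-centroid classifier reaches ~1.0 held-out AF1.

What passing tests show: shape/label/provenance contracts, exact
degenerate-limit behaviour, alignment optimality, count arithmetic, and
that every label-preserving method leaves performance on a separable
fixture essentially unchanged (drops > 0.1 AF1 would indicate an
implementation bug).  What they do not show: relative merits of the
methods on real physiological data, which depend on dataset-specific
structure (trends, artefacts, non-stationarity) the sinusoid fixtures do
not contain.

## Problem sizes and numerical choices

The default test-and-acceptance configuration uses the 60-window fixture,
a 2-fold × 2-repeat benchmark over factors {0.2, 1, 2} for the 11
non-generative benchmark methods, 1000 random pairs (lengths ≤ 6) for the
DTW oracle sweep, and 20 random 5 × 13 matrices for the statistics
cross-checks — sizes chosen so the whole pipeline remains comfortable on
a single CPU while exercising every code path.  Identity limits are
asserted at 10⁻⁹; exact arithmetic (counts, ranks, enumeration
equivalence) at 10⁻¹⁰ or tighter; Monte-Carlo statistics at tolerances
derived from their sampling error at the stated sample sizes.

## Known limitations

Variable-length windows, streaming augmentation, frequency-domain methods
and statistical generative models are out of scope.  The cGAN is a
reference implementation for desk-scale experiments, not a competitive
generative model; training reproducibility is guaranteed only within this
numpy backend.  The 1-NN-DTW reference classifier is quadratic in both
dataset size and window length and is intended for small fixtures only.
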