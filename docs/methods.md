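# Methods

This note documents the models, conventions and design choices behind
`transferkit`, and what the synthetic data generator does and does not
emulate.

## Sensor model and signal conditioning

Recordings are uniformly sampled triaxial chest accelerations in g-units at
a nominal 25 Hz, sensor range ±16 g, with body axes X vertical (+up),
Y lateral (+left), Z frontal (+front). Timing jitter above 1% of the median
inter-sample interval is rejected at read time rather than resampled;
uniform sampling is a precondition of every downstream step.

Conditioning is a single 8th-order Butterworth low-pass at 10 Hz applied
once to the full recording before any segmentation. The filter is applied
forward–backward (`sosfiltfilt`): phase distortion would shift waveform
landmarks relative to the externally annotated seat-off/landing timestamps,
and the phase windows are only 1.5 s wide, so zero-phase alignment matters
more than causality here. The effective magnitude response is the square of
the designed response (the passband deviation at 1 Hz stays below 1%, and
12 Hz — above the cutoff, near Nyquist — is attenuated by far more than 95%).

Jerk is the forward first difference scaled by the sampling rate (units
g/s, length n−1), keeping a jerk minimum causally tied to the onset of the
movement that produced it. Units are g and g/s throughout; nothing converts
to m/s².

## Phase windows and sliding windows

Quality evaluation cuts three per-transfer windows from the annotated
timestamps: ±0.75 s around seat-off (head-hip), seat-off −0.5 s to landing
+0.5 s (flight), ±0.75 s around landing. Time-to-index conversion is
round-half-up, so at 25 Hz the ±0.75 s half-width is 19 samples (39-sample
inclusive windows) and the ±0.5 s margin is 13 samples. Feature extrema are
taken over whole phase windows rather than sub-segment landmarks; landmark
detection within the window is deliberately not attempted.

Detection windows are 25 samples wide. A 50% overlap of an odd width is
non-integral, so the hop is ⌊25/2⌋ = 12, slightly more than 50% overlap;
this keeps the grid integral and every sample covered. A window is labeled
`transfer` iff it overlaps the [seat-off, landing] interval by at least one
sample — the labeling rule is deliberately the loosest one, and is isolated
so a stricter rule (e.g. majority overlap) can be substituted for
sensitivity analysis.

## Quality features

*Head-hip relationship.* A correct transfer opens with a quick, deep forward
lean: the frontal (Z) acceleration dips sharply as gravity re-projects onto
the frontal axis. Candidate features: min and range of Z, min of jerk(Z),
max of jerk of total acceleration, and max/range of the frontal-downward
composite `x − z` (vertical plus sign-inverted frontal — sign inversion is
the only dimensionally meaningful reading of combining these axes; a
reciprocal is physically nonsensical).

*Smooth landing.* Buttock contact produces a vertical impact spike;
candidates are max vertical and total acceleration, mean vertical and total
acceleration, RMS and range of total acceleration over the landing window.

*Controlled flight.* Smoothness of the pivot between surfaces. The speed
profile is reconstructed from the flight window by per-axis mean removal (a
crude gravity correction) and cumulative trapezoidal integration; over a
window of a few seconds the residual linear drift from imperfect mean
removal is tolerable. Four metrics: SPARC of the total acceleration, SPARC
of speed, and dimensionless jerk with its negative-log variant on speed.

SPARC follows the reference algorithm: zero-padded magnitude spectrum (pad
factor 4 on the next power of two), normalized by the 0 Hz magnitude,
truncated at min(10 Hz, highest frequency whose normalized magnitude still
reaches 0.05), and scored as minus the arc length of the spectrum with the
frequency axis rescaled to [0, 1]. The 10 Hz cap coincides with the filter
cutoff. Dimensionless jerk is −(T³/v²peak)·∫(d²v/dt²)² dt with a
rectangle-rule integral; both metrics are amplitude-invariant.

A caveat worth knowing: on raw total acceleration (which carries the ~1 g
gravity offset) SPARC's adaptive band selection can *extend* when a strong
oscillation is added, and the frequency renormalization then compresses the
low-frequency arc — so the acceleration-based SPARC does not reliably rank
a rippled flight as rougher. The speed-based metrics (SPARC of speed,
dimensionless jerk) do rank it correctly and are the ones the smoothness
literature defines the metrics on; tests assert the ordering there.

The default quality pipeline trains classifiers only for head-hip and
smooth landing. Controlled-flight labels are typically so imbalanced
(almost every transfer by an experienced user is rated good) that training
is refused unless forced; the features are still computed and exportable.

## Detection features

Fourteen features per signal — SD (n−1 denominator), variance (defined as
SD², preserving the definitional identity), 10/25/50/75/90th percentiles
(linear interpolation between order statistics; the dialect matters on
25-sample windows and is fixed), IQR, 10th–90th range, lag-one
autocorrelation, three wavelet norms, sample entropy — on X, Y, Z and the
total vector, plus three axis cross-correlations: 59 features in a fixed
canonical order. Computing sample entropy on the total vector as well as
the axes is the only composition that reaches the documented total of 59;
the composition lives behind one registry function so alternatives can be
configured.

Lag-one correlation is interpreted as the lag-one autocorrelation of the
filtered signal over a 10 s context centered on the window, truncated at
recording edges ("counts" in the actigraphy sense are not defined for this
sensor). Wavelet norms are Euclidean norms of the db2 level-1 detail,
level-2 detail and level-2 approximation coefficients with symmetric
boundary extension; with periodization instead, the orthogonal db2
coefficients conserve signal energy exactly, which the tests use as an
independent check. Sample entropy uses m = 2, Chebyshev distance,
tolerance 0.3 × SD (n−1 denominator, consistent with the SD feature), and
maps the degenerate cases to finite values: constant input → 0 (maximal
regularity), zero template matches → ln((n−m)(n−m−1)), so classifiers
never see infinities.

## Feature selection

CFS merit of a subset S of k features is k·r̄cf / √(k + k(k−1)·r̄ff), with
r̄cf the mean absolute Pearson correlation between the features and the
{0,1}-encoded class, and r̄ff the mean absolute pairwise feature
correlation; zero-variance features correlate 0. Association is measured by
Pearson correlation on the continuous features directly rather than the
discretize-and-symmetrical-uncertainty dialect of the original tooling —
all features here are continuous, and avoiding the discretization step
makes the selection a deterministic function of the matrix. Consequently,
selected subsets need not coincide with those a discretizing
implementation would report.

Search is forward best-first from the empty set with a priority queue by
merit, stopping after 5 expansions without improving the global best (hard
cap 10 000 evaluated subsets). Ties break toward the canonically earliest
subset. Selection defaults to running once on the full instance set
(before LOSO splitting), which leaks subject information by design of the
original protocol; a per-fold mode is available.

## Evaluation protocol

One LOSO fold per subject; per fold, features are z-scored with statistics
fitted on the training rows only, the classifier is fitted and scored on
the held-out subject, and a global 2×2 confusion matrix accumulates over
folds. Mean accuracy is the unweighted mean over subjects (one vote per
subject) with its n−1 SD. Weighted F1 is the support-weighted average of
per-class F1.

Hyperparameters are fixed, plain defaults, exposed in config: SVM linear
kernel with C = 1 on standardized features; random forest 100 trees,
seeded; Gaussian naive Bayes; multinomial logistic regression with mild L2
(strength 1e-4). No tuning is performed anywhere. The detection task is
rebalanced before cross-validation by per-subject random undersampling of
the majority class to 1:1 (minority rows untouched, nothing duplicated,
deterministic under the seed); the near-balanced quality tasks are not
rebalanced by default. All four families are reported side by side; the
package deliberately does not declare a winner.

## Synthetic data generator

The generator emulates the study protocol: nine subjects, ~40-minute
continuous sessions, 12 transfers each (two return transfers in each of
three scenarios) with at least 60 s of rest between events, plus
wheelchair-propulsion bursts (2–3 Hz band-limited oscillations) in the
gaps. Signals are modeled in the sensor frame *including* gravity: upright,
X ≈ 1 g; a forward lean of pitch θ gives X = cos θ, Z = −sin θ. This is
essential — the head-hip features are driven by gravity re-orientation, and
a purely dynamic simulation would not exercise them.

Per event: a bell-shaped lean-and-return pitch trajectory whose amplitude
and rise time encode head-hip quality (good ≈ 55° in 0.7 s, bad ≈ 18° in
1.4 s), with ±10% event-to-event jitter of depth and duration drawn
independently (so derived features are not artificially collinear) and an
optional class-independent backswing (the momentum-gathering backward trunk
motion seen in real transfers, which decorrelates range-type features from
the class); a flight segment with a lateral pivot swing, plus a 1 g, 8 Hz
lateral oscillation when flight is uncontrolled (1 g at 8 Hz corresponds to
~4 mm of displacement — a visible instability — whereas a few tenths of a g
would be sub-millimetre); and a landing impact modeled as a decaying ~6 Hz
sinusoid on X (peak 1.2 g smooth / 2.0 g hard, normalized so the peak equals
the configured amplitude), below the 10 Hz cutoff so the feature pipeline
sees it. The three quality flags act on disjoint signal aspects (Z-lean,
Y-ripple, X-impact) so each item is independently recoverable — a
deliberate simplification.

Between-subject variability comes from a fixed per-subject torso tilt
(uniform 0–10°) and movement-amplitude scale (uniform ±20%), which keeps
LOSO generalization non-trivial without modeling anthropometry. Measurement
noise is white Gaussian, default 0.05 g per axis. Per-item quality labels
are drawn with probability 0.5 — unlike the validation study, where
controlled flight was almost always good; the generator keeps all items
learnable and leaves the imbalance question to the pipeline's refusal
logic. The dataset is a pure, bit-reproducible function of the
configuration including its seed.

What the generator does **not** emulate: biomechanically validated forward
dynamics, scenario-specific signatures (bed/toilet/car differ only by
tag), sensor drift or orientation error, spasticity/tremor, or realistic
propulsion beyond band-limited oscillation. Passing tests on this data
therefore demonstrate that the pipelines recover the *intended
construction* under realistic noise and subject variability — not clinical
performance on real recordings, which the package cannot claim.

## Numerical choices and degenerate inputs

* Round-half-up time-to-index conversion, asserted in tests (banker's
  rounding would give a 12-sample flight margin instead of 13).
* The filter requires > 3×(order+1) samples (forward–backward padding);
  shorter inputs are an explicit error.
* Correlations of zero-variance inputs are defined as 0 with a logged note.
* An all-zero spectrum (SPARC) or zero peak speed (dimensionless jerk)
  raises a degenerate-signal error rather than returning a sentinel, since
  a flight window with no dynamics means the annotation is wrong.
* CFS on a matrix with no class-correlated feature falls back to the single
  best feature rather than the empty set.
* Default problem sizes used by the test suite are scaled-down sessions
  (3 subjects, 6 minutes, 3 transfers) except for the protocol-level checks,
  which run the full nine-subject default study; both complete in well under
  a minute on one core.

## Known limitations

* The detection labeling rule (any-overlap) and the 59-feature composition
  are documented interpretations where the protocol leaves room; both are
  isolated behind single functions for sensitivity analysis.
* Global CFS leaks subject information across folds by construction; use
  the per-fold mode for a leakage-free estimate.
* Seat-off/landing timestamps are required inputs; automatic transfer
  segmentation from the signal alone is out of scope (a second sensor such
  as a seat pressure switch is the usual answer).
* Accuracies on synthetic data are far higher than anything reported on
  real recordings; they validate the implementation, not the clinical
  method.
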