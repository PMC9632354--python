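# Methods

This note records the models implemented in `drowse`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic
experiments do and do not demonstrate.

## Synthetic landmark simulator (`drowse.synth`)

The simulator emulates the statistics a landmark detector would produce
watching a driver, not the images themselves.  Each session is one
continuous recording in a fixed state (awake or fatigued) at a constant
frame rate (default 15 fps, so the 900-frame classification window spans
the one-minute observation horizon over which fatigue signs are
considered reliable).

Event schedules are Poisson processes in start time, with same-kind
events pushed apart so they never overlap; counts over long sessions
therefore match the nominal rates.  Defaults per `SubjectProfile`:

| parameter | default | rationale |
|---|---|---|
| blink rate awake / fatigued | 15 / 18 per min | typical adult spontaneous rate; mildly elevated when drowsy |
| blink duration awake / fatigued | 0.2–0.3 s / 1.0–2.0 s | brisk blinks when alert; slow, microsleep-like closures when fatigued |
| yawn rate (fatigued) | 1 per min | intermittent yawning during drowsy episodes |
| yawn duration | 4 s (±0.4) | the characteristic length of a yawn |
| speech rate (both states) | 0.5 per min, 0.8–2.5 s | short mouth-opening confounder |
| nod / tilt rate (fatigued) | 2 / 1 per min, 1–3 s, 20–40° | head-control loss under fatigue |
| landmark jitter | 0.5 px isotropic Gaussian | detector noise |
| eye / mouth width | 40 / 60 px | face scale at dashboard-camera distance |

Blinks apply a piecewise-cosine close/hold/open envelope (30/40/30% of
the event) to the eyelid-pair gaps, bottoming out at 2% of the open gap;
yawns drive the lip gap to 90% of mouth width with fixed 0.4 s cosine
ramps; speech opens the mouth to ≤ 30% of width modulated at syllable
rate, so it never satisfies the yawn gate.  Head pose is a slow
low-passed wander (≈2° sd) plus nod (pitch) and tilt (roll) bumps; the 5
pose points are produced by actually projecting the generic 3D face model
under that rotation through the pinhole camera, so the pose solver
recovers the ground-truth angles rather than reading them from a lookup.

KSS labels are drawn from {1, 2} awake and {5..9} fatigued, re-sampled
every five minutes (the expert re-scoring cadence).  Binarization maps
scores below 3 to non-fatigue and above 4 to fatigue; 3 and 4 fall in
neither rule's range and are excluded rather than guessed.

What the simulator does **not** model: illumination, occlusion, detector
dropouts, gradual state transitions within a session, inter-subject
geometry variation, or correlation between eye and head behaviour.
Passing the end-to-end test therefore shows the pipeline recovers a
known, well-separated behavioural contrast from realistic event
statistics — not that it reaches any particular accuracy on real video.

## Features (`drowse.features`)

All formulas operate on the canonical landmark ordering (eye corners p1,
p6, lid pairs (p2, p3), (p4, p5); mouth corners M1, M5, lip pairs
(M2, M8), (M3, M7), (M4, M6)).  Ratio and angle features are invariant to
translation, rotation and uniform scale; S_mp, a raw coordinate-difference
product, is translation-invariant only.

Decisions where the formulas leave latitude:

- **Opening angles.**  EOA/MOA are implemented as arcsin(perpendicular
  distance of the upper lid/lip point to the corner line, over that
  point's distance to the near corner), using p2 (eye) and M3 (mouth);
  the lid point is configurable in principle but fixed here for
  determinism.  The result always lies in [0, π/2].
- **Per-frame closure.**  A frame counts as eyes-closed when the mean
  lid-pair gap falls below 20% of the calibrated fully-open gap — the P80
  convention of the PERCLOS literature.  Calibration takes the stream
  maxima of canthus distance and lid gap.
- **Yawn gate.**  A frame counts as yawning only inside a contiguous run
  with midline mouth aspect > 0.6 lasting ≥ 3 s.  The duration gate is
  what separates yawns (~4 s) from speech (< 2.5 s and shallow); both
  threshold and gate are arguments.
- **Scalarization.**  EAV and MAV enter the 11-vector as the mean of
  their 2 and 3 components, since the factor analysis treats each as a
  single variable.  Fixed order: EAV, MAV, S_ar, S_mp, pitch, yaw, roll,
  EOA, MOA, F_blink, F_yawn.
- **Frequency windows.**  F_blink and F_yawn use a trailing 60 s window
  that grows from the start of the stream until full history is
  available, so the feature table has no warm-up gap.

## Head pose (`drowse.headpose`)

Pose is recovered from five 2D–3D correspondences by damped Gauss–Newton
on the pinhole reprojection error, initialised from a scaled-orthographic
depth estimate (focal length times the 3D/2D spread ratio).  The Jacobian
is central-difference and the whole solve is batched over frames, which
is what makes per-frame pose on multi-hour sessions cheap.  A
purpose-built iterative solver was preferred over a closed-form P-n-P
derivation because with five points and a good initial depth it converges
in a handful of iterations and is easy to verify by forward projection;
noise-free round-trips recover angles to ≈1e-13 degrees and 0.5 px jitter
leaves a median error under 3°.

The generic face model (millimetres: eye centres ±32.5, 30, −25; nose tip
0, 0, 10; mouth corners ±25, −35, −15) and default intrinsics (fx = fy =
600 px, principal point 320, 240) are config values, not claims about any
particular camera.  Euler convention: intrinsic x–y–z = pitch–yaw–roll,
degrees; at gimbal lock the residual twist goes to pitch and roll is set
to zero.  Nod/tilt flags default to |pitch| or |roll| > 20°.

## Preprocessing (`drowse.preprocess`)

**Smoothing.**  "Filter window length 5" is realised as a zero-phase
moving average of span 5 computed by FFT convolution with reflection
padding (the alternative reading — keeping 5 Fourier coefficients — does
not behave like a short smoothing window).  The span is configurable and
must be odd so the filter is symmetric.  Raw features are smoothed before
factor analysis; factor scores are not smoothed again.

**Factor analysis.**  Extraction is principal-component based on the
correlation matrix — pinned down by the fact that component variances
must sum to the number of variables for the per-component shares
(eigenvalue/11 × 100) to total exactly 100%.  Rotation is varimax
(orthogonal, so communalities are preserved; the implementation carries a
deterministic sign convention).  Score weights use the regression method
W = R⁻¹Λ, computed with a pseudo-inverse so perfectly collinear inputs
degrade gracefully.  Retention keeps the smallest k whose cumulative
share reaches the threshold, default 95% (pass 90 for the looser "more
than 90%" convention).  Constant columns are rejected by name, with the
variance test made relative to column scale so float dust on a constant
column still triggers it.

## GRNN (`drowse.grnn`)

The classifier is Specht's generalized regression network: prediction is
the Gaussian-kernel-weighted average of stored training labels, a convex
combination that stays within [min label, max label] and tends to the
label mean as σ → ∞.  If every kernel weight underflows (tiny σ, distant
query) the nearest pattern's label is used — the σ → 0 limit.

σ is scored by **leave-one-out** MSE: with the query included in its own
kernel sum, resubstitution MSE goes to zero as σ → 0 for any data and the
search becomes degenerate; excluding each sample from its own prediction
is the standard remedy.  Pairwise distances are computed once and reused
across the whole σ search.

Windows aggregate 900 frames (step 80) by per-column mean — chosen over
flattening (900× dimensionality) and median (discards within-window
variation symmetric kernels handle fine); the window label is the
majority frame label with ties going to fatigue, and the decision
threshold 0.5 is inclusive on the fatigue side — the conservative calls
for a safety system.

Note that on cleanly separated classes the leave-one-out optimum is flat
near zero error for a wide σ range and the GA may return a very small σ,
putting the GRNN in its nearest-neighbour regime; this is a property of
the data, not a failure of the search.

## Genetic algorithm (`drowse.ga`)

Single real gene σ on (0, 2] (lower bound opened by ε = 1e-6).
Operators are standard real-coded defaults — tournament selection (k=3),
arithmetic blend crossover (p = 0.7), Gaussian mutation (p = 0.25, sd =
5% of bound width, clipped into bounds) and elitism of one, which makes
the best-so-far fitness non-increasing.  Population 80, cap 200
generations.  Fitness evaluations are memoized.

Stopping: the default rule stops at the cap, or earlier once the best
fitness is ≤ 0.03 *and* has not improved for 25 generations.  A `literal`
rule is also provided that requires both the generation cap and the
population *mean* below the threshold before stopping (with a 10× hard
ceiling to guarantee termination); it is selectable but not the default
because a mean-based conjunction can run arbitrarily long on noisy
fitness landscapes.

## Evaluation (`drowse.pipeline`, `drowse.metrics`)

Splits are chronological within each session (default 55/20/25
train/test/validate) and windows are built within a split segment, so no
window straddles a boundary and evaluation windows are temporally
disjoint from training.  The factor model is fitted on training frames
only and applied to the rest.

Metrics use **normal driving as the positive class** — the orientation
under which the worked-example confusion counts are internally consistent
— and report percentages to one decimal.  F1 is computed from the
already-rounded precision and recall by default (`round_first`), because
that is the convention the worked example follows; `exact` mode defers
all rounding to the end (the two differ by 0.1 on the reference counts).
Zero-denominator metrics are reported as undefined (None), never as 0.

Baselines for the repeated stratified k-fold comparison: an in-repo
Euclidean majority-vote KNN (default k = 5, ties to fatigue) and a
random-forest wrapper behind the same fit/predict surface; all models see
identical folds.

## Problem sizes used by the test suite and acceptance script

Unit tests run sessions of 2–600 s; the schedule-rate check simulates one
hour; the end-to-end experiment simulates two hours per driver state at
15 fps (216,000 frames total, ≈2,600 windows), which the batch pose
solver and cached-distance GA keep under two minutes on one CPU.  The
GRNN oracle comparison uses 100 random models, the GA recovery check 20
seeds against a 1e-4 grid oracle, and the loss-invariance fuzz 1,000
random box pairs.

## Known limitations

- The synthetic generator's class separation is by construction large;
  real-world accuracy claims cannot be transferred from it.
- The bounding-box loss is implemented exactly as specified — including
  the unusual quartic, (1−IoU)-damped aspect term; a standard CIoU
  variant is available behind `variant="ciou"` for comparison.
- Head-pose recovery assumes known intrinsics and a generic rigid face;
  no per-subject 3D calibration is attempted.
- Factor-analysis extraction is principal-component based; maximum-
  likelihood factoring and oblique rotations are out of scope.
- The GRNN stores all training windows; no pattern-layer compression is
  implemented, so prediction cost grows linearly with training size.
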