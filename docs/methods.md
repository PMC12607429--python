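# Methods

This note documents the models, parameter choices and numerical
conventions behind spinsense, and what the synthetic studies do and do
not establish about real collar data.

## The detection problem

A trained assistance dog signals by spinning: two uninterrupted clockwise
360° body rotations. A collar-mounted IMU samples six channels at 50 Hz
(linear acceleration `Accel_LN_X/Y/Z`, angular velocity `Gyro_X/Y/Z`).
The task is to recognise spin events in the continuous stream, with the
operating constraint of an alerting application: missed events are far
more costly than occasional false alarms, and the system must generalise
to dogs it was never trained on.

## Simulator

The generator produces labelled multi-subject studies whose statistical
structure follows a real six-dog corpus: event counts per subject
(74, 23, 16, 10, 9, 3), full-event durations drawn from a normal
distribution truncated to [1.02, 5.42] s with location 2.58 s, and about
8.5 min of labelled stream per subject (mirroring a ~3000 s annotated
corpus, not the hundreds of unlabelled hours such deployments also
collect).

**Duration model.** Only the range, mean (2.58 s) and median (2.52 s) of
real event durations are known; the truncated-normal sd = 0.7 s is a free
choice fixed once so that the truncated mean stays within a few
hundredths of 2.58 s while the tails populate the observed range. The
durations are treated as durations of the complete two-rotation event
(the configurable `rotations_per_event` defaults to 2); a single rotation
takes roughly half.

**Spin kinematics.** The yaw-rate magnitude is a trapezoid — linear ramps
over the first and last 10% of the event, constant plateau between — and
is rescaled so the *discrete* integral over the event equals exactly
`rotations × 360°`, making conservation checkable to float precision
regardless of sample alignment. Clockwise viewed from above with the
collar z-axis up is the negative-yaw convention (`clockwise_sign`,
configurable, since collar mounting fixes no global frame). The
accelerometer sees gravity on z plus a lateral component rotating with
the body at `rotations/duration` Hz whose amplitude follows ω²r with
r = 0.15 m of collar offset — so a 2.58 s event has its accelerometer
signature near 0.78 Hz, distinct from gait.

**Background and distractors.** Rest is a pure noise floor. Gait is a
2 Hz periodic acceleration pattern with gentle yaw/roll sway; a wet-dog
shake is a 12 Hz enveloped burst; a body turn (circling) is a single slow
rotation at 70–120 deg/s with a mild acceleration signature. The turn is
the deliberate hard negative: its windows overlap the weaker spin windows
in mean gyro magnitude, so a single magnitude threshold cannot be perfect
and transfers imperfectly across dogs, while the joint feature geometry
(rate level, accelerometer periodicity, spectral shape) still separates
it. Turn peak rates are capped below 720°/5.42 s ≈ 132.8 deg/s — the
lowest possible spin-interval mean — so a generator invariant holds for
every seed: at zero sensor noise, the mean gyro magnitude inside any spin
interval strictly exceeds that of every spin-free window. Distractor
blocks never overlap each other or spins (0.5 s guard), so their
signatures cannot stack above a spin's level.

**Subject heterogeneity and noise.** Each subject's sensor frame is
rotated by a random collar-mounting offset (±20° per Euler axis by
default); rotation preserves vector magnitudes, so the heuristic's
feature is unaffected while per-axis features shift realistically.
Sensor noise is white Gaussian (0.35 m/s² accel, 6 deg/s gyro). Spins
are placed by distributing the free time between events as a Dirichlet
draw, so any event load that fits at all is placed without rejection;
over-full requests raise with a diagnostic.

**Determinism.** All randomness flows from `numpy` generators seeded by
`(seed, subject_index)`; identical configurations produce bit-identical
arrays and byte-identical CSV exports (values are written at 6 decimals,
which is also the round-trip precision of the readers).

## Windowing and event curation

Windows are 2.6 s (130 samples) at a 1.3 s stride, labelled *spinning*
iff ≥ 50% of samples are inside a spin interval — the threshold is
inclusive, and trailing partial windows are dropped rather than padded so
feature vectors have fixed dimension. Annotation intervals are half-open
`[start, end)` in seconds from stream start.

A consequence of the labelling rule worth stating explicitly: a spin
shorter than window/2 + stride/2 = 1.95 s is never guaranteed a
majority-coverage window, so very short events can be unlabelable at the
window level no matter the classifier. Event-level OR aggregation softens
but does not remove this.

Curated events are 7.8 s stretches (five windows) that are behaviourally
pure: a spin event fully contains one or more complete spin intervals and
clips none; a non-spin event overlaps no spin at all. Placement walks the
sorted spin intervals, greedily groups neighbours whose joint span fits
one event, and positions each event inside its feasible start interval
(containing the group, after the previous event and spin, ending before
the next spin), preferring the centred position. Groups with no feasible
pure placement are dropped with a log message (a few percent on the
densest subject). Non-spin events tile the spin-free gaps with a seeded
random offset. Event splits are stratified by class, preserve proportions
to within one event per class, and are event-disjoint by construction.

## Features and selection

Each window yields 48 features: 8 traces (6 channels + the two magnitude
traces) × {mean, population SD, range, dominant frequency, spectral
energy, spectral entropy}. Spectra are single untapered periodograms of
the 130-sample window; the DC bin is excluded from all three spectral
features so they are not redundant with the mean (otherwise the
collinearity stage would drop one of the pair arbitrarily). Dominant
frequency is the largest non-DC bin; entropy is Shannon (base 2) of the
non-DC power normalised to unit sum, hence in [0, log2(65)]. A constant
trace degenerates to dominant frequency, energy and entropy of 0 — the
constant check guards against interpreting FFT round-off as a spectrum.
Spectral-shape features of *near*-silent windows (possible at behaviour
block edges when sensor noise is switched off) are numerically arbitrary;
real recordings always carry a noise floor beneath which this regime does
not occur.

Selection stages run in a fixed order — variance filter (< 0.1, on raw
unstandardised values), collinearity cut (|r| > 0.95, keeping the earlier
feature in schema order), ANOVA-F top-k (k = 20) — and the order matters:
a low-variance feature is removed before it can knock out its
high-variance collinear partner. The fitted `SelectionReport` is a pure
function of the training matrix and thresholds and suffices on its own to
transform new data.

## Models

The heuristic classifies a window as spin when its mean gyro magnitude
strictly exceeds a threshold chosen from the midpoints of consecutive
distinct training values (± infinite sentinels) by maximising spin-class
F1 on training data; ties break toward the larger threshold (fewer false
alarms). The candidate grid covers every achievable decision rule of the
form `magnitude > t`, so the search is exact.

The four supervised families map to scikit-learn estimators with widely
used defaults: 100-tree random forest; RBF SVM with C = 1 (margin scores
for ROC); Gaussian naive Bayes with 1e-9 variance smoothing; L2 logistic
regression with a 1000-iteration budget. Features are z-scored with
train-fitted statistics for the SVM and logistic regression only. The
hyperparameters behind the originally reported results are unpublished,
so third-decimal replication of those tables is explicitly not a goal;
no class reweighting is applied by default. All stochastic fitting is
seeded.

## Evaluation

Segment metrics are accuracy, spin-class F1 and rank-based ROC-AUC
(mid-rank ties; undefined and reported absent for single-class truth).
Event predictions OR the window predictions inside each curated event,
so event-level sensitivity can only improve on segment-level sensitivity.
LODO pools confusion counts across folds (micro) and keeps per-fold
metrics; folds whose training side degenerates to a single class are
skipped and recorded. Every run audits leakage — train/test event-id
intersection, and subject-id intersection for LODO — and reports the
result.

Four protocols are provided because both a single named hold-out dog and
full leave-one-dog-out cross-validation are legitimate readings of
subject-wise evaluation, and the within-subject random split is kept as
the deliberately lenient reference point (its event-level numbers are
computed over all curated events and inherit that leniency).

## What the synthetic studies show — and what they don't

Passing tests on simulated data establish that the pipeline's mechanics
are correct (labelling, selection, tuning, aggregation, fold hygiene,
determinism) and that its qualitative behaviour matches expectation: the
learned models beat the magnitude heuristic under subject-wise
evaluation, and OR aggregation converts mediocre window sensitivity into
near-complete event recall. They do not certify performance on real
collar data: the simulator's distractor repertoire is small and
stylised, real inter-dog variability in spin style is richer than a
frame rotation plus duration spread, and annotation timing error —
present in any video-aligned labelling — is not modelled. Quantities
like the ~0.99 simulated LODO accuracy should be read as properties of
the benchmark, not forecasts for deployment.

## Problem sizes and numerical conventions

The default study is six subjects × 8.5 min at 50 Hz (≈153k samples,
≈2350 windows, 135 events), which keeps a full LODO evaluation within
seconds per model on one CPU; the test suite uses this scale for
study-level checks and smaller three-dog studies elsewhere. Windows per
stream follow floor((L − w)/s) + 1. Window and stride lengths must be
whole numbers of samples at the declared rate — a 2.6 s window at a rate
where that is not 130 samples is an error, never a silent rescale.
Timestamps must be uniform within 2% period jitter on read. Exactly-50%
coverage labels spinning; magnitude exactly at the heuristic threshold
predicts non-spin.
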