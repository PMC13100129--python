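# Methods

## Signal model

A tapping recording is reduced to the palm-scaled thumb–index distance
`s(i) = d1(i) / d2(i)`, where `d1` is the Euclidean distance between thumb
tip and index-finger tip and `d2` the distance between wrist and the index
metacarpophalangeal joint, both in whatever planar unit the keypoints carry.
The ratio is dimensionless and invariant to translation, in-plane rotation
and uniform scaling of the landmark set; because the palm reference is
re-measured every frame, slow changes of hand orientation or camera distance
cancel frame-wise rather than contaminating the signal. Frames whose palm
length falls below 1e−6 input units are excluded (the ratio is undefined
there); if more than 20 % of frames are degenerate the recording is rejected
rather than silently thinned. Excluded frames keep their original timestamps,
so the speed signal `|Δs| / Δt` uses true time gaps. No smoothing is applied
by default; an optional odd-window moving average is available for noisy
keypoint tracks.

An angle signal (the wrist angle between the thumb-tip and index-tip rays)
is provided for representation comparisons. It is view-dependent by
construction and is the baseline representation the distance signal is meant
to improve on.

## Gap handling

Pose estimators drop landmarks. Runs of at most `max_gap` consecutive
missing frames (default 0.2 s worth, i.e. 5 frames at 25 fps / 10 at 50 fps)
are linearly interpolated per coordinate against the frame index; longer
runs stay missing and leading/trailing missing frames are trimmed. Filling
never alters observed frames, which makes the operation idempotent. The gap
report (count filled, longest run, frames trimmed) travels with the track.

## Cycle segmentation

Peaks and troughs come from a standard prominence-based local-extremum
detector (the trough pass runs on the negated signal) with two parameters:

* `min_separation_s = 0.1 s` — voluntary tapping rarely exceeds 10 Hz;
* `min_prominence_frac = 0.05` of the signal's 5th–95th-percentile range —
  scale-free rejection of jitter peaks.

Two repairs make segmentation total: (i) if no trough was detected between
two consecutive peaks, the minimum of the inter-peak segment is inserted, so
every cycle contains a closing event; (ii) if the recording starts with the
fingers essentially closed (pre-first-peak minimum within 10 % of the
excursion above the global minimum) that minimum is inserted as the opening
trough — an endpoint minimum is invisible to the detector but is a real
closed-hand state, and without it the first cycle's amplitude is lost. A
recording that starts mid-opening contributes no first amplitude, by design.

Amplitudes pair each peak with its nearest *preceding* trough (fingers close,
then fully open); cycle windows run peak-to-peak. `CAS_j` is the mean of the
speed samples in the half-open window `(T_{j−1}, T_j]`; `CMS_j` is the 95th
percentile (linear interpolation between order statistics) of the samples in
the closed window, which discounts single-frame keypoint glitches.

## Feature conventions

Averages divide by the number of terms actually available (amplitudes may
number one fewer than peaks; durations, CAS and CMS number `M−1` for `M`
peaks). The amplitude CV divides the squared-deviation sum by the peak count
`M` in its defining form; the other three CVs divide by the cycle count
`M−1`. The asymmetry is kept deliberately for fidelity to the defining
formulas; `consistent_cv=True` (CLI `--consistent-cv`) unifies all four to
the count of contributing terms. Trend slopes are ordinary least squares
against cycle index 0, 1, 2, … (per-cycle units); regressing against elapsed
peak time instead is available via `slope_regressor="time"` since the choice
is not dictated by the definitions — index units are reported by default
because "decrement per tap" is the clinically quoted quantity. Slopes need
at least three points; two points fit exactly and carry no information. An
interruption is a peak-to-peak duration exceeding twice the median duration
of the recording; the threshold scales with the median, so the count is
invariant under uniform time scaling.

`extract_all` materialises any stage failure (too few cycles, degenerate
signal, zero CV denominator) as an invalid feature row carrying the reason;
it never raises for data-dependent problems.

## Component analysis

The 12 features carry heterogeneous units, so the PCA runs on the
correlation matrix (columns standardised with ddof = 1). Loadings are the
orthonormal eigenvectors, eigenvalue-descending, each column signed so its
largest-magnitude entry is positive. The retained block is varimax-rotated
by the SVD-based iteration; Kaiser row normalisation is off by default and
exposed as a flag, and non-convergence flags the result instead of raising.
The rotation criterion (sum over components of the variance of squared
loadings) is non-decreasing over iterations, the recovered rotation is
orthogonal to 1e−10, and total squared loadings are preserved. The number of
retained components defaults to the scree point with maximal perpendicular
distance to the chord joining the scree endpoints; a linear scree makes that
rule uninformative (flagged, k = 1) and the choice is always overridable —
the elbow is advisory, as any automated reading of a visual criterion must
be.

## Severity classification

Item scores 0–4 merge to Mild (0–1) / Moderate (2) / Severe (3–4); multiple
ratings per recording are reduced by majority vote with ties broken toward
the less severe score (all tie-breaks in the package lean less-severe, fixed
and documented). Base learners are logistic regression (standardised
pipeline), LightGBM and random forest behind one interface. The ordinal
route trains the two cumulative binary tasks P(y > Mild) and P(y > Moderate)
and differences their probabilities into (1−q1, q1−q2, q2); a negative
middle (the two models disagreeing) is clipped to zero and the triplet
renormalised; prediction is the argmax with ties toward less severe. A
cumulative task seeing a single class degenerates to a constant probability
and is logged.

Evaluation is leave-one-subject-out: all recordings of one subject form the
test fold. Hyperparameters can be tuned inside each outer fold by a bounded
random search (budget configurable, 0 = library defaults) scored by grouped,
label-stratified 5-fold cross-validation on the training subjects — a
deliberate simplification of a full optimisation framework that keeps the
nesting honest at a fraction of the cost. Metrics: accuracy; balanced
accuracy (mean per-class recall over classes present in the truth); macro
precision with a never-predicted class contributing 0; macro F1 as the
standard harmonic mean 2PR/(P+R), 0 when P+R = 0. These conventions exactly
reproduce the closed-form constant-majority baseline row: at majority
prevalence p = 34.84 %, balanced accuracy 100/3 ≈ 33.33, macro precision
p/3 ≈ 11.61 and macro F1 (2p/(1+p))/3 ≈ 17.23 (all in percent). A printed
F1 without the factor 2 would give 8.61 and is inconsistent with that row,
which is why the standard form is implemented.

## Simulator

The simulator realises exactly the statistical structure the features
measure — it is a ground-truth generator, not a biomechanical model. Cycle
`j` draws amplitude `A_j = base·(1 + amp_slope·j)·exp(ε_A)` and duration
`D_j = base_cycle·(1 + cd_slope·j)·exp(ε_D)` with `ε ~ N(0, cv)`;
multiplicative log-normal variability keeps both positive and makes `cv`
approximately the realised coefficient of variation. Defaults describe an
unimpaired bout: 50 fps, 10 s, unit amplitude, 0.35 s cycles (~2.9 Hz),
resting trough level 0.2 palm units, no trends, no pauses, no noise.
Waveforms: `sinusoid`/`raised_cosine` (the same shape — a sinusoid started
at the trough *is* the raised cosine `sin²(π·phase)`) and `triangle`, whose
piecewise-constant speed `2A/D` gives closed forms for CAS/CMS tests.
Interruptions are flat trough-level segments of length
`interruption_factor × median(D)` at uniformly chosen internal cycle
boundaries; a factor above 2 makes the resulting peak-to-peak gap exceed the
2×-median rule by construction. The ground-truth record carries the drawn
per-cycle values plus the implied peak-to-peak gap sequence (half-cycle +
pause + half-cycle), which is the faithful programmed counterpart of what
the duration features measure.

The default cohort profiles place Mild around large fast regular taps
(amplitude 0.9–1.3, cycles 0.28–0.42 s, CV 3–8 %, at most one pause) through
Severe (amplitude 0.3–0.7, cycles 0.40–0.60 s, CV 10–22 %, 1–5 pauses), with
deliberately overlapping ranges between neighbouring groups and a
subject-level random effect plus small per-recording jitter, so simulated
classification is non-trivial but learnable. What the simulator does *not*
emulate: keypoint geometry and its structured failure modes (occlusion,
identity swaps), tremor superposition, camera autofocus artefacts, or
rater noise in the labels. Passing recovery tests therefore certifies the
estimator chain, not robustness to real video pathology.

## Numerical choices and limitations

* Recovery studies run at moderate variability (cycle CVs of 5 %) with small
  additive observation noise (sd 0.02 palm units); the deficit-grid
  rank-correlation study uses 100 fps, triangle waves and noise sd 0.002 so
  that extrema detection stays exact and the comparison isolates the
  estimators.
* Interruption counting is exact only while observation noise stays below
  the detector's prominence floor (5 % of the robust signal range): the
  expected noise excursion over an N-sample flat pause is roughly
  `2σ√(2 ln N)`, and once that approaches the floor, pauses sprout spurious
  peaks that split long gaps. Low-amplitude, noisy recordings — the severe
  end of the clinical spectrum — are exactly where this bites; smoothing or
  a larger prominence fraction is the practical remedy.
* Problem sizes in the tests and the acceptance script (200 recordings per
  recovery study, 60-subject cohorts with 2 recordings each) were chosen as
  the smallest sizes at which the binomial/bias bounds being checked are
  comfortably away from their thresholds.
* Confidence-based keypoint filtering is exposed (`min_confidence`) but off
  by default; there is no principled universal threshold, and gap-filling
  plus degenerate-frame exclusion already catch the gross failures.
* Real-cohort accuracies cannot be reproduced without the clinical videos;
  the classification machinery is validated structurally (no subject
  leakage, baseline metrics exact, separable simulated cohorts classified
  correctly) and on simulated cohorts only.
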