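# Methods

`povmark` analyzes behavioral markers of depression extracted from
egocentric (clinician-worn camera glasses) recordings of clinical
interviews. It does not process raw media: upstream extractors (a face-mesh
landmark model, a gaze-estimation network, an action-unit coder, an ASR
system with word timestamps, a voice-activity detector) are assumed to have
produced per-frame streams, and this package implements everything
downstream — feature definitions, quality control, group inference, and
classifier evaluation — plus a synthetic-cohort generator that stands in for
clinical recordings, which cannot be distributed.

## Data model

A cohort is 2 groups (MDD patients and healthy controls, default 44 vs 41),
each participant contributing four 30-second answer segments recorded at a
nominal 30 FPS. Per segment the visual stream carries, per frame: six eye
landmarks per eye (pixel units), head pose (pitch/yaw/roll, degrees), gaze
angles (radians), and AU activations in [0, 1]; the speech stream carries
voice-activity labels on a 10 ms hop grid, word-level timestamps with
speaker attribution, the question-end anchor, and the answer window. Frame
index is 0-based; the time of frame k is k/fps. Missingness is tracked per
channel group (eye, head, gaze, AU) rather than per scalar, matching how
upstream extractors fail (a lost face loses all face-derived channels at
once).

## Feature definitions

Fifteen features per participant, organized a priori into five domains
(sizes 3/4/3/2/3):

* **Gaze** — per-frame classification by the horizontal gaze component
  (the gaze network's "pitch" under the egocentric camera axis convention):
  right if pitch >= +0.17 rad, left if pitch <= -0.17 rad, center otherwise;
  frames with |vertical component| > 0.35 rad are invalid and excluded from
  aggregation (they are valid observations of an excluded condition, so they
  do not count as missing data for QC). Durations are frame counts / fps.
* **Facial affect** — smiling = AU12 activation >= 0.5; happy (Duchenne) =
  AU6 and AU12 both >= 0.5; neutral = no major expressive AU >= 0.5 (the
  "other" AUs are compressed on disk to their per-frame maximum); social
  smiling = smiling while gaze is center. The 0.5 threshold on [0, 1]
  detector outputs is configurable; the major-AU set defaults to
  {1, 2, 4, 5, 6, 9, 12, 15, 17, 20, 25, 26}.
* **Ocular** — the eye-aspect ratio EAR = (d(p2,p6) + d(p3,p5)) / (2 d(p1,p4))
  is computed per eye and averaged per frame (single-eye fallback when one
  eye is unusable). A blink is a maximal run of frames with EAR < 0.2; a run
  counts as a blink cycle only when the adjacent frames on both sides are
  observed and open (EAR > 0.2). Blink duration divides all sub-threshold
  frames (boundary runs included) by the cycle count and fps, and is defined
  as 0 when no cycle completed (avoiding 0/0). Eye openness is the mean EAR
  over open frames. A frame at exactly EAR = 0.20 is neither open nor closed
  and enters neither numerator — both inequalities are strict.
* **Head** — total movement is the sum of |frame-to-frame change| over all
  three axes; a rapid movement is a consecutive frame pair whose largest
  single-axis change strictly exceeds 5 degrees (counted per transition, not
  per merged episode). Pairs straddling missing frames are skipped.
* **Speech** — response latency is the time from question end to the onset
  of the participant's first word (clamped at 0 under overlap; the study
  protocol makes overlap rare and its handling is otherwise undefined).
  Silence ratio: non-speech gaps shorter than 150 ms (strict) between speech
  runs are relabeled as speech (articulatory gaps, not pauses), labels are
  clipped to the answer window, leading/trailing silence outside the first/
  last speech run is dropped, and the ratio is non-speech over retained
  frames. Word count covers participant tokens inside the answer window.

## Quality control

Three nested gates: (1) missing runs of <= 2 consecutive frames with
observed neighbors are linearly interpolated per component; (2) a segment is
excluded when its worst channel group still has >= 10% missing frames (the
worst group decides because a segment unusable for any domain was excluded
in the per-domain accounting this emulates; the rule is also conservative
and monotone); (3) a participant is excluded from a domain's group
statistics when that domain has >= 20% missing data (residual missingness in
kept segments plus wholly lost segments, averaged over the nominal segment
count). Speech availability is binary per segment. The classification path
keeps all participants and instead imputes per-feature training-fold medians
inside each cross-validation fold. Feature values are averaged over the
retained segments (the mean over fewer than four segments is the nearest
consistent reading when some are excluded).

## Group statistics

Shapiro-Wilk (alpha = .05, both groups) gates each feature into an
independent-samples t test or a Mann-Whitney U test; Kolmogorov-Smirnov
p-values are reported informationally. Welch's t is the parametric default
(pooled-variance available by flag, since published tables mix both
conventions). Mann-Whitney uses exact enumeration for n1+n2 <= 10 (valid
under ties) and otherwise the normal approximation with tie and continuity
corrections; U is reported in the min(U1, U2) convention and Z's sign
follows the group-1 minus group-2 mean-rank difference. Family-wise error is
controlled within domains: alpha_domain = .05/m_domain (.0167 for
gaze/ocular/speech, .0125 for affect, .0250 for head). p < alpha_domain is
"significant after correction"; alpha_domain <= p < .05 is "nominal only".
Effect sizes: Cohen's d (pooled SD) for parametric tests, rank-biserial
r = 1 - 2 U_min/(n1 n2) signed by the mean-rank difference otherwise.

The minimum-detectable-effect calculator uses the normal approximation
d = (z_{1-alpha/2} + z_power) sqrt(1/n1 + 1/n2); at n = 44/41 and power .80
it gives d = 0.61/0.67/0.70/0.72 for alpha = .05/.025/.0167/.0125. An exact
noncentral-t mode is available by flag and differs by < 0.02 at these sizes.

## Classifier evaluation

Nested leave-one-out cross-validation with six registry learners
(extra-trees, random forest, gradient boosting, AdaBoost, k-NN, SVM). Inside
each outer training fold, a stratified k-fold inner loop (default 5, reduced
automatically for small classes) selects: the RFE subset size (step-1
elimination ranked by impurity importances — the candidate learner's own
when it has them, otherwise an extra-trees ranker — scored by inner-CV
accuracy over candidate sizes {3, 5, 8, 10, 15}; one elimination sweep is
shared across sizes, which is arithmetically identical to running step-1 RFE
at each size), the hyperparameters (small visible grids), and the
calibration method (Platt vs isotonic by inner Brier score on out-of-fold
scores; ties go to Platt as the lower-parameter map). Learners without
probability outputs contribute decision-function scores; calibration maps
either to [0, 1]. Nothing fitted ever sees the held-out row; the per-fold
artifacts (imputer medians, subset, hyperparameters, calibration choice) are
recorded so an audit can refit them from the training rows alone.

Pooled outer-fold predictions yield confusion counts and accuracy/precision/
sensitivity/specificity/F1. Wilson 95% intervals come in two modes:
*replicate*, using the total cohort size as the common denominator for every
proportion (the convention under which one n is quoted for all intervals —
with counts 40/4/32/9 this reproduces sensitivity (82.9-95.4) and
specificity (68.1-85.5) at n=85), and *strict*, using each metric's own
denominator. The F1 interval is a stratified percentile bootstrap (B = 2000,
resampling within each true class). The ROC-AUC (on calibrated pooled
probabilities) carries the Hanley-McNeil normal-approximation interval with
Q1 = A/(2-A), Q2 = 2A^2/(1+A); at A = 0.89 with 44/41 this is (0.82, 0.96),
SE = 0.036. Gini feature importances are normalized per model, averaged
across the tree-ensemble learners only, and renormalized to sum to 1.

Under a permuted-label null, pooled LOOCV accuracy is *pessimistically*
biased (the held-out participant's class is always the training minority in
a near-balanced cohort, and inner selection on noise amplifies this): the
measured mean over 50 permutations of a 20-participant noise cohort is about
0.35, not 0.5. This is a property of leave-one-out itself, not of this
implementation; the no-leakage guard therefore asserts that the accuracy
distribution brackets 0.5 and shows no optimistic excursion above the
binomial band — optimism being the leakage signature.

## Synthetic cohort generator

The generator emits full cohorts in the pipeline's on-disk formats, with
every planted event recorded before noise/dropouts are applied:

* **Gaze**: a two-state semi-Markov process (center vs off-center, dwell
  times exponential with a 3 s center-dwell mean; off dwells split evenly
  left/right) tuned per participant to a center-occupancy fraction drawn
  from the group's target distribution (MDD 13.51 +/- 5.75 s per 30 s
  segment, controls 19.22 +/- 3.78 s). The semi-Markov form (rather than
  frame-wise i.i.d. classes) makes dwell-time ground truth well-defined.
  Angles are emitted strictly inside each class's band; planted invalid
  frames set |vertical| beyond the validity bound.
* **Blinks**: Poisson events (17/min) with lognormal closed durations
  (median 0.24 s MDD vs 0.18 s controls), placed with open margins so every
  planted blink is a complete cycle. Eye landmarks are *constructed from*
  the planted EAR trace (fixed horizontal span, vertical lid distances
  scaled to the target ratio), so the landmark-to-EAR path is testable, not
  just the EAR-to-blink path.
* **Affect**: Poisson AU12 episodes (1.0/min MDD vs 2.0/min controls,
  exponential lengths) with Duchenne co-activation probability 0.4 vs 0.6;
  background "other-AU" episodes generate non-neutral, non-smiling frames.
* **Head**: per-axis Gaussian random-walk steps (SD 0.3 degrees) plus
  planted 6-10 degree jumps (3/min) — the only steps crossing the rapid
  threshold at the default noise level.
* **Speech**: a burst-pause schedule (exponential bursts, mean 2.5 s;
  lognormal pauses, median 0.75 s MDD vs 0.55 s controls, floored at 0.2 s
  so no planted pause is merge-eligible), a lognormal first-response latency
  (median 0.7 vs 0.6 s), and words placed uniformly within bursts at a
  participant-level rate chosen so mean counts land near 43 vs 46 per
  segment. The interviewer's question occupies the pre-anchor interval.
* **Imperfections**: per-channel dropout runs (1/min, lengths 1-4 frames,
  mostly repairable by the 2-frame interpolation rule), rare invalid-gaze
  frames, and small Gaussian jitter on EAR and AU traces. A noiseless regime
  switches all of these off; on it, every pipeline feature must equal
  planted truth exactly (counts) or to one frame/hop quantum (durations and
  ratios).

Group effects enter only through interpretable parameters (dwell mass,
episode rate/length, closed-duration median, pause median), in the
directions the clinical literature reports (less center gaze, less smiling
and Duchenne smiling, longer blinks and pauses in depression). Where only a
direction — not a magnitude — is known, episode rates and lengths were set
once to values plausible for a 30 s structured interview answer and not
revisited. `calibrate_effect` bisects a designated monotone control-group
parameter (center-gaze mean, smile-episode rate, or blink-duration median)
against a fast feature-level simulator with common random numbers until a
target Cohen's d is met within 0.05.

What the generator does **not** emulate: correlated failures across
channels, upstream-model estimation error beyond i.i.d. jitter and dropout,
within-interview nonstationarity, acoustic waveforms, or realistic feature
correlations beyond those induced by shared processes (e.g., social smiling
inherits gaze and smiling structure). Passing tests on synthetic cohorts
therefore certify the *pipeline arithmetic and its statistical machinery*,
not clinical validity on real recordings; the synthetic cohort's classifier
performance in particular is higher than would be expected on real data
because several strong effects are planted independently.

## Numerical and protocol choices

* Published worked examples are reproduced from printed summaries: Welch
  t = -5.44 on the center-gaze summaries, with Welch-Satterthwaite
  df = 74.83 from the rounded inputs (published as 74.87, consistent with
  pre-rounding data); pooled t = -1.34 (df 83) for word count; Cohen's
  d = -1.165.
* The replicate-mode Wilson lower bound for accuracy 72/85 computes 75.6
  where 75.5 was published (truncation); the computed value is reported.
* Simulation sizes in the test suite: the permutation-null guard runs 50
  permutations of a 20-participant cohort with a reduced inner search (k-NN
  learner, two candidate subset sizes, single hyperparameter point); the
  strong-signal check runs 100 participants per group, where the Monte-Carlo
  SE (~1.8%) is small against the margin between the ~6.7% irreducible error
  at d = 3 and the 0.9 accuracy bound, and allows subset size 3 so noise
  dimensions cannot dilute the signal; effect-size calibration uses 2,000
  participants per group via the feature-level fast path.
* Degenerate inputs: coincident eye corners raise; an all-missing EAR series
  raises; zero blinks give duration 0; no open frames give missing openness;
  a speech window without speech gives a missing silence ratio; constant
  groups are routed nonparametric with a warning.

## Known limitations

Real deployments may swap the gaze axis convention; the interchange schema
fixes one convention and upstream adapters must match it. The 10%/20%
missingness accounting is defined per channel group / per domain here; other
reasonable readings (per scalar channel, overall) would shift borderline
exclusions. The sex-distribution chi-square printed alongside the original
demographics is not recoverable from the printed counts by plain Pearson or
Yates statistics and is not replicated. Acoustic/prosodic features (F0,
jitter, MFCCs) are out of scope.
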