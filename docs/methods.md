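# Methods

This note documents the models, conventions and numerical choices behind
`s2mr`, and what the synthetic-data tests do and do not establish about
real recordings.

## The question cycle and its phases

The unit of analysis is one multiple-choice question answered inside a
motion-based educational game. Each cycle passes through three phases:

* **see-solve** — the child reads and mentally solves the question;
  begins at the first fixation whose centroid falls inside the question
  area of interest (AOI) at or after question onset;
* **move** — the child moves their body to select an answer; begins at
  the first skeletal frame whose total joint displacement exceeds an
  individual movement threshold;
* **respond** — the selected answer is dragged to the response slot;
  begins at the logged selection event and ends at the logged response.

Segments are half-open `[start, end)` and always partition
`[see_solve_start, response)`; boundaries are clamped to preserve the
ordering (a move onset detected after the selection collapses the move
segment to zero length). A cycle whose gaze never lands on the question
is excluded and counted, never imputed.

**Movement threshold.** Displacement per frame is the sum over the 25
tracked joints of the Euclidean distance to the previous frame — the
least biased scalar when no joint is privileged. The threshold is
`mean + k·SD` (default `k = 2`) of the displacements in the first half
of the candidate see-solve interval; when that yields fewer than 6
frames the participant-level baseline (the idle lead-in before the
first question) is used instead. Because consecutive displacement
values share a frame, isolated jitter can exceed the threshold for two
adjacent frames; the detector therefore takes the first frame of the
super-threshold *run that reaches the selection* (answer movement is
sustained through selection by definition), falling back to the first
run of three or more frames. On synthetic cohorts this recovers the
planted move boundary within one skeletal frame for >90 % of cycles.

## Preprocessing

* **Gaze events** — velocity-threshold (I-VT) classification on
  point-to-point velocities in normalized screen units/s (default
  threshold 1.0). Runs of invalid samples (lost pupil) become blinks;
  fixations shorter than 60 ms are dropped and their flanking saccades
  merged. The threshold is a replaceable parameter: any proprietary
  event classifier can be substituted upstream by supplying an event
  table with the same columns.
* **Pupil** — both eyes averaged where valid, z-scored against the
  participant's first 30 s. This removes between-child differences in
  absolute pupil size; it is a deliberate simplification of
  wavelet-based cognitive-load indices, chosen because it is
  deterministic, parameter-free and monotone in pupil dilation.
* **EDA** — 0.5 s moving-average smoothing (removes single-sample
  artifacts), then tonic = centered 4 s moving median and phasic =
  residual, so tonic + phasic reconstructs the smoothed signal exactly.
  Peak counting (skin-conductance responses) runs on the raw-µS phasic
  component with a 0.01 µS prominence floor; tonic/phasic *levels* are
  additionally scaled by the participant's 30 s baseline statistics.
* **HR and EDA levels** — z-scored against the first 30 s of the
  stream; a zero-SD baseline divides by 1 and raises a flag.

## Windows and the phase/window reconciliation

Measurements are aggregated in 10 s windows hopping every 5 s. Phases,
however, are often shorter than a window (move and respond last a few
seconds), and labelling global windows by the phase at their midpoint
leaves the short phases almost without data. The pipeline therefore
tiles windows *within* each phase segment: full windows where they fit,
a trailing partial window if it is at least half a window long, and —
for a segment shorter than that — a single window spanning the segment,
so every phase of every cycle contributes at least one observation. The
midpoint-labelled global alternative is available via
`RunConfig.windowing = "global"` for sensitivity analysis; with it the
respond phase of a typical cycle is unobserved, which is the reason it
is not the default.

## Measurements

Per window: cognitive load (mean normalized pupil), saccade velocity
(mean of saccade peak velocities), mean HR, number of EDA peaks, tonic
and phasic EDA level, and the information processing index
IPI = (n_global + 1)/(n_local + 1), where a (fixation, following
saccade) pair is *global* if the fixation is short and the saccade long
and *local* in the opposite case, with thresholds at the
within-participant medians of fixation duration and saccade amplitude
(absolute visual-angle thresholds would require screen geometry the
pipeline deliberately does not assume). The +1 smoothing keeps the
ratio defined when a window has no pairs of one type.

Per cycle: time to first fixation on the question, and the percentage
shares of inter-AOI transitions of the three named types
(question↔right, question↔wrong, right↔wrong); wrong↔wrong pairs belong
to no named category and are excluded from the denominator, and
fixations outside every AOI break transition chains.

Before inference, each measurement (except time to first fixation) is
minmax-normalized to [0, 1] within its analysis domain; a constant
group maps to 0 and is flagged.

## Inferential carry-forward analysis

Per (measurement, phase): per-cycle values (window means within the
phase) are compared between right and wrong responses. Residual
normality is screened with Shapiro-Wilk; on failure a rank-based
inverse-normal (van der Waerden) transform is applied — a plain linear
z-score cannot change a distribution's shape, so the rank-based version
is what "normalizing" requires, and being monotone it cannot flip the
affinity. Homoscedasticity is screened with Breusch-Pagan on the group
indicator; on failure the test switches from a repeated-measures ANOVA
on participant×label cell means (participant as grouping variable) to a
Welch one-way ANOVA on participant-level means, since Welch's
correction has no repeated-measures form. Both screening decisions are
harmonized across the three phases of a measurement (any phase failing
a screen applies the remedy to all three): the carry-forward rule
compares effect sizes *between* phases, and partial eta-squared from a
paired ANOVA and from an unpaired Welch ANOVA are not on the same
scale, so mixing branches within one measurement would make the
ordering conditions meaningless. This also mirrors how heteroscedastic
measurements are reported: per measurement, not per phase. Effect size
is partial eta-squared in both branches. p-values are Bonferroni-corrected within
the family of all 7 measurements × 3 phases = 21 tests of one game
domain.

A measurement *carries forward* when (1) the group difference is
significant in all three phases, (2) the effect size peaks in
see-solve, (3) the move effect exceeds the respond effect, and (4) the
affinity (label of the larger group mean) is consistent. All four ⇒
perfect; conditions 1, 2, 4 with 3 failed ⇒ pseudo (default rule —
this matches the worked classifications where a respond-phase rebound
downgrades perfect to pseudo; the variant where inconsistent affinity
is the pseudo-breaking condition is selectable via
`RunConfig.pseudo_rule = "affinity"`). Ties fail the strict
comparisons; an untestable phase yields *none* with a recorded reason.

## Predictive carry-forward analysis

Features per (participant, question, phase): for each measurement's
window series — mean, median, SD (n≥2), skewness and kurtosis (n≥3),
the first two coefficients of an order-2 autoregressive fit (n≥6), and
GARCH(1,1) α/β from a Gaussian maximum-likelihood fit (n≥10; L-BFGS-B
with three starts and an α+β<1 barrier). Shorter series leave those
cells explicitly missing; missing cells are median-imputed from the
training fold only. A config switch (`feature_scope="game"`)
concatenates window series across a game's questions, which makes the
AR/GARCH features estimable at the price of per-question labels.

The ensemble has seven members: support-vector classifiers with linear,
radial and polynomial kernels; Gaussian-process classifiers with the
same three kernel families; and a model tree (depth-3 regression tree
with ridge models in the leaves, an M5-style stand-in). Members consume
standardized features and emit scores in [0, 1] (sigmoid-calibrated
margins for the SVMs, posterior probabilities for the GPs, clipped leaf
predictions for the tree); the ensemble score is the
validation-accuracy-weighted average thresholded at 0.5. The GP kernels
are scaled by the feature dimension and their hyperparameters held
fixed (single Laplace fit): on standardized inputs this keeps the Gram
matrix O(1), avoids the numerically fragile marginal-likelihood
optimization of a free polynomial kernel, and makes the whole stage
deterministic.

Splitting is by participant identity throughout: 10 % of participants
(rounded up) form an outer holdout; the rest cycle through
leave-one-participant-out train/validation folds. Class imbalance
(about five right answers per wrong one) is corrected on training folds
only, with a minority oversampler that, for each minority point, places
four synthetic points at the mean of its four nearest minority
neighbours jittered by +25, −25, +50 and −50 % of those neighbours'
per-feature SD — exactly the number that restores a 5:1 set to balance.
Validation and test data are never resampled.

Importance is permutation importance on each fold's validation
participant, combined across members by the ensemble weights and
averaged across folds, scaled to [0, 100] with dense ranks (rank 1 most
important; zero-importance features are never "top" regardless of their
shared rank). A feature carries forward perfectly when it is in the top
fraction (default 10 %) in all three phases with strictly decaying
ranks see-solve → move → respond; top everywhere with the see-solve
rank strictly smallest but move not outranking respond is pseudo.

Evaluation reports precision, recall and F1 with "right" as the
positive class, against the majority-class baseline (precision 5/6 ≈
0.83, recall 1.0 on 5:1 labels) rather than the random baseline (0.5 on
balanced labels), because of the skew.

## Feedback mapping and prioritization

Measurement → remediation: cognitive load → worked example or hint;
saccade velocity → small content hint; IPI → gaze-contingent expert
overlay; mean HR → pause suggestion; EDA (peaks, phasic, tonic) →
emotion-regulation support. A measurement whose affinity already lies
with the desired outcome maps to positive reinforcement
(encouragement) instead. Plans order measurements by carry-forward
class (perfect < pseudo < none); within perfect/pseudo by descending
see-solve effect size; within none by the lexicographic significance
pattern (see-solve, then move, then respond) before effect size — the
ordering that reproduces both worked no-carry-forward orderings, which
a pure effect-size rule cannot; final ties put undesired-outcome
affinity first, then measurement name for a stable total order. Plans
are advisory JSON artifacts; delivery timing and UI are out of scope.

## The synthetic cohort generator

The generator emulates the study conditions: 40 participants, 2 content
domains × 3 games × 5 questions, right answers with probability 5/6,
gaze at 50 Hz, EDA at 64 Hz, HR and skeleton at 1 Hz, and a 35 s idle
lead-in that provides the 30 s normalization baseline. Phase durations
are lognormal with medians 6 / 2 / 2 s (see-solve / move / respond) and
log-SDs 0.35 / 0.30 / 0.30 — conventions chosen so a cycle spans one to
three analysis windows; the source studies report only total session
length.

Each measurement summarizes a *latent channel* with three variance
components: a participant offset (between-child), a cycle offset
(within-child drift) and sampling noise. A planted effect of size `d`
shifts the channel of the affinity-labelled cycles by `d` pooled
(participant ⊕ cycle) SDs during the specified phase. Channels: pupil
level in mm (base 3.6, SDs 0.30/0.20); HR in bpm (85, 6.0/2.0, AR(1)
noise); saccade peak velocity in screen units/s (2.5, 0.35/0.25); an
IPI drive on the logit scale controlling the global-pair probability
(0.0, 0.6/0.4); SCR rate in events/s (0.08, 0.020/0.015); SCR amplitude
in µS (0.15, 0.040/0.030); tonic offset in µS (0.0, 0.25/0.15). The
per-(cycle, phase) channel values are recorded in the bundle's ground
truth, so effect recovery is directly checkable without running the
pipeline. Skin-conductance responses are gamma-shaped bumps (≈1 s rise,
≈3 s decay) on a slow tonic ramp; blinks are inserted as invalid gaze
runs; the skeletal stream plants a sustained whole-body excursion
starting exactly at the move boundary.

Because participant-level offsets are removed by the per-participant
baseline normalization (and by the repeated-measures pairing), the
within-participant analysis sees planted effects at a larger
standardized magnitude than the raw pooled `d` — exactly the power gain
that motivates repeated-measures designs, and the reason the
Monte-Carlo recovery of `d = 0.8/0.5/0.3` heart-rate effects succeeds
reliably at 40 participants.

**What the generator does not model** — and hence what green tests do
not establish about real data: sensor drop-out beyond simple blinks,
motion artifacts in EDA/HR during vigorous movement, gaze calibration
drift, inter-question learning or fatigue trends, age/gender
covariates, and any coupling between channels (planted effects are
channel-isolated by construction, which the leakage tests rely on).
Results on real recordings also depend on the homography/registration
chain that maps head-mounted gaze to screen coordinates, which is
upstream of this package.

## Problem sizes used by the test suite and acceptance script

Monte-Carlo checks run at the study-shaped cohort (n = 40, 2 × 3 × 5)
for the inferential recovery (20 planted seeds, 50 null cohorts) and at
reduced cohorts (8–10 participants, one domain) for the predictive
end-to-end checks, where the Gaussian-process members dominate the
cost; these sizes are the package's chosen trade-off between
Monte-Carlo resolution and a test suite that runs on one CPU in
minutes. Determinism is asserted byte-for-byte on the written reports.

## Known limitations

* The cognitive-load index is a windowed mean of normalized pupil
  diameter; wavelet-based indices are not implemented.
* The rank-based predictive carry-forward rule compares ranks across
  features, so a feature dominating every phase (rank 1/1/1) is
  classified *none* — a property of the rule, not a bug.
* GARCH(1,1) estimates are noisy below a few hundred observations; at
  the default per-question feature scope those cells are missing by
  design and carried as such into imputation.
* The Welch branch discards pairing, costing power when
  heteroscedasticity triggers it on small cohorts.
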