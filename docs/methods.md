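# Methods

## The frame-wise divergence statistic

The unit of analysis is the video frame. Gaze samples (60 Hz by default)
are assigned to half-open frame windows [f/fps, (f+1)/fps) and averaged
within a window; a window containing no valid sample is missing (blinks
and track losses are never imputed at the sample level). Frames are
0-indexed; the default frame rate is 30 fps and is configurable — the
statistic itself is fps-agnostic.

Per frame, each group's centre is the arithmetic mean position of its
non-missing members, *including* the member whose distance is being
computed (a leave-one-out variant is available via
`AnalysisConfig(leave_one_out=True)`; self-inclusion shrinks distances by
a factor √(1−1/n), identically for all members of a group, and neither
choice changes the statistic's behaviour appreciably). Each participant's
distance to their own group's centre is the quantity tested: it measures
within-group dispersion, so the two-sample comparison asks whether one
group's gaze diverges more than the other's. Distances to the *other*
group's centre are also computed and retained on the result object so the
alternative contrast can be explored, but they enter no test.

The per-frame test is the classical pooled-variance two-sample Student's
t (not Welch), two-sided, df = n₁+n₂−2, at an uncorrected α = 0.05.
No multiple-testing correction is applied, deliberately: the per-frame
p-values are never reported as inference, only counted. Degenerate
frames: zero pooled variance with equal means gives t = 0, p = 1; zero
pooled variance with unequal means is counted significant and flagged.
Frames with fewer than `min_per_group` (default 3) non-missing members in
either group are non-evaluable and excluded from the percentage
denominator rather than imputed.

### Null behaviour of the statistic

Under the null (both groups sampled from one distribution) the expected
fraction of significant frames is close to, but measurably above, the
nominal 5%: distances within a group share an *estimated* centre and are
therefore weakly dependent, which the t-test ignores. In a controlled
experiment (200,000 simulated Gaussian frames, 53/45 groups) the test on
distances to the true centre is level at 4.96%, while distances to the
estimated centre give 5.27% (5.28% leave-one-out). The full pipeline on
ten study-scale null cohorts reproduces this: 5.30% ± 0.05. Users should
read the per-video percentage against this empirical ≈5.3% baseline, not
against an exact 5.0%; the acceptance suite's strict nominal-level test
documents the discrepancy. The effect of unequal group sizes through the
self-inclusion factor (√(52/53) vs √(44/45)) is two orders of magnitude
smaller and negligible.

### Category summaries

The video is the unit of aggregation: a category's mean and SEM
(sd/√k) are taken over its k videos, and the one-way ANOVA across
categories operates on video-level percentages, giving df = (C−1, V−C)
(3, 12 for 4 × 4). η² = SS_between/SS_total. F and p are computed from
explicit sums of squares (needed for η² anyway) and are verified against
`scipy.stats.f_oneway` in the test suite. Single-video categories have
undefined SEM (flagged); zero total variance leaves F undefined (error).

## Questionnaire scoring

The craving scale has nine 1–7 Likert items in three 3-item subscales.
Subscale scores are item *sums* and the total is the sum of all nine
(range 9–63) — with a young, mostly low-craving sample this puts typical
totals near the scale floor. The published instrument does not fix which
item index belongs to which subscale, so the default mapping (items 1–3
anticipation, 4–6 desire, 7–9 relief) is an explicit package convention,
overridable from config; totals and the median split are unaffected by it.
Cronbach's α uses unbiased (n−1) sample variances throughout, the
conventional choice for scale reliability. The median split labels a
participant high iff total > median ("ties-to-low", the default); the
alternative ties-to-high policy is exposed because only the split's
outcome, not its tie rule, is ever published. Ties-to-low admits unequal
group sizes such as 45/53 out of 98.

## Evaluation protocol

Train fraction 0.8, 18 repetitions, 5-fold cross-validation, accuracy as
the sole headline metric. Splits and folds are stratified by group
(unstratified 20% test sets of ~20 participants would be noisy given a
45/53 imbalance); rounding is floor-per-class then top-up by largest
fractional remainder, so 98 participants yield 78 train / 20 test.
Repetition r derives its RNG seed from `SeedSequence((master_seed, r))`,
making repetitions mutually independent yet exactly reproducible; the
whole report is byte-identical under a repeated run with the same seed.

Within each repetition the frame-wise statistics, the video ranking, the
top-k selection (default k = 2, matching the two planted signal videos;
tunable) and the feature imputation statistics are computed on training
participants only. Rankings carry a provenance token; the protocol
refuses any ranking not derived from a training subset
(`ProtocolViolation`). Features are the minimal reading of "average
viewing position": per selected video, the mean non-missing (x, y) over
frames, 2k columns in total; a fully missing (participant, video) cell is
imputed with the training column mean and logged.

Hyperparameters are pinned rather than inherited silently: logistic
regression (C = 1, lbfgs, max 1000 iterations) and k-NN (k = 5, uniform
weights) behind a fold-internal standardiser; decision tree (unlimited
depth, min split 2); random forest (200 trees). Scikit-learn provides
the estimators and fold machinery behind the module surface.

### Leakage demonstration

With the default mean-position features, full-cohort video selection
barely inflates null accuracy — chance-significant frames reflect
dispersion noise, which mean positions do not encode. The demonstration
therefore uses the pipeline's exploratory modes, where the leak is
visible and instructive: frames significant on the *selection cohort*
are kept, and each participant's feature per selected video is the mean
of s_f · (d_{i,f} − mean_f), where d_{i,f} is the distance to the
selection cohort's frame centre and s_f the sign of the selection
cohort's low-minus-high difference. The feature requires no label at
prediction time, yet when selection includes the test participants their
chance fluctuations helped choose the frames and signs, and holdout
accuracy on pure noise approaches 1.0; with training-only selection the
same pipeline stays at chance (≈0.46–0.5 in seeded runs).

## Synthetic cohorts

The generator emulates the study conditions: 98 participants (53 low /
45 high craving), 16 videos (4 each FUN / SPORT / PRODUCT / CONTROL) of
30 s at 30 fps, gaze at 60 Hz on a 1280 × 900 display, blinks as i.i.d.
per-sample missingness at rate 0.05 (burstiness is not modelled — the
analysis only consumes missingness patterns).

Each video has one shared target trajectory — a reflected Gaussian random
walk (step SD 8 px/frame) emulating moving advert content — and each
participant's gaze is trajectory + isotropic Gaussian noise, SD 60 px,
clipped to the screen. On signal videos (default FUN_1 and FUN_3), within
a contiguous block of half the frames centred in the clip (a "video
section"), the high group's noise SD is multiplied by `dispersion_ratio`
(default 1.5) and its mean shifted by `offset_px` (default 0) along a
per-video random direction. Dispersion is the default mechanism because
the statistic tests divergence; the offset mode exists because
classification from *average positions* additionally needs a location
difference — dispersion alone leaves group means equal and classifiers at
chance. Questionnaire items are drawn from per-group discrete
distributions over 1–7 (low group mean ≈1.7/item, high ≈3.0/item), which
keeps totals in bounds by construction and lets the median split recover
the latent groups for ≈97% of participants. No published effect sizes
exist for the real group differences; these defaults are calibrated to
make pipeline properties testable, not to mimic the study's magnitudes.

What the generator does *not* emulate: saliency-driven gaze, fixation/
saccade dynamics, smooth pursuit, heavy-tailed noise, bursty track loss,
calibration drift, or demographic structure. Passing tests therefore
show the pipeline's statistical machinery is correct and calibrated, not
that real adolescent gaze behaves like the model.

## Numerical and scale choices

CSV timestamps are written at full precision and read with pandas'
round-trip float parser: at 60 Hz / 30 fps every other sample lies
exactly on a frame-window boundary, and truncated timestamps would fall
into the wrong frame. Coordinates are rounded to 0.001 px on write.
The vectorised cohort-binning path is property-tested against the
per-recording path.

Problem sizes: the statistical acceptance checks (null calibration,
ranking recovery, protocol accuracy bands, leakage) run at the full
98 × 16 × 900 study scale. Unit-level property tests (chance-level
classification calibration over ten null cohorts, dispersion
monotonicity across the ratio grid 1.0–2.0) use size-reduced cohorts
(24–40 participants, 4 videos, 120–150 frames), which exercise the same
code paths at equal statistical validity for the properties asserted.

## Known limitations

- The frame-wise test's null rate is ≈5.3%, not 5.0% (dependence through
  the estimated centre; see above). Percentages of significant frames
  are comparative screening values, not calibrated error rates.
- Frames are treated as independent; no cluster-mass or permutation
  correction over time is provided (out of scope by design).
- The horizontal/vertical mean-position comparison variant of the method
  is not implemented; only the distance-to-centre divergence reading is.
- `build_features`' imputation covers fully missing (participant, video)
  cells only; participants missing an entire *training* column abort.
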