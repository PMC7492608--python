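# Methods

`betarebound` re-implements, as a tested pipeline, the analysis of a
real-world motor-learning experiment: subjects learn repeated pool-billiards
shots while single-channel EEG over the left motor cortex, overhead ball
tracking, full-body kinematics, and head acceleration are recorded.  Because
no public dataset exists for this design, the package pairs the analysis
with a synthetic-cohort generator that reproduces the statistical structure
the analysis assumes, so every stage can be validated by parameter recovery.

## The analysis model

**Trial structure.** A session is 300 self-paced trials in 6 sets of 50,
analyzed as 12 blocks of 25.  Set and block indices follow ceiling
arithmetic on the 1-based trial index.

**Ball tracking.** Movement onset is the first sample at which the cue-ball
center leaves an axis-aligned 40 × 40 mm bounding box centered on its rest
position (ball diameter 48 mm; tracking at 200 Hz in mm).  The signed
directional error is the angle of the target ball's displacement at its
peak speed, minus the pocket angle, both measured from the cue-to-target
baseline; wrapped to (−180°, 180°], counterclockwise positive.  Speeds are
central finite differences after a 5-sample (25 ms) moving-average smooth;
peak-speed ties break to the earliest sample.  The smoothing window and the
sign/tie conventions are this package's choices; the source analysis did
not state them.

**Spectral analysis.** EEG (256 Hz, µV) is zero-phase FIR band-passed at
5–35 Hz, then convolved with complex Morlet wavelets in 1 Hz steps, 7
cycles at every frequency (temporal SD ≈ 56 ms at 20 Hz — wide enough to
resolve a 200-ms window, narrow enough for 1-Hz spacing).  Samples within
half a wavelet of an epoch edge are flagged invalid per frequency and never
enter any statistic.  Power is normalized per frequency row to percent
change from the block average of the *log* power:

    value = 100 · (ln P / ⟨ln P⟩_block − 1),

with ⟨·⟩ over the valid samples of all the block's trial epochs.  Two
properties of this formula matter:

* per block and frequency the mean normalized value is zero by
  construction (asserted to 1e-6 in tests);
* it is **unit-dependent** — rescaling the raw signal shifts ln P
  additively and changes the percent values (though not the sign pattern
  or any correlation-based conclusion; a test asserts classification
  invariance under a ×4 gain change).  Signals are therefore kept in
  physical microvolts.  The alternative order of operations (block-average
  the raw power, then take the log ratio) is available as
  `norm_mode="mean-then-log"`.

**PMBR.** Movement offset is proxied by the ball-movement onset.  The
per-trial PMBR is the mean normalized 13–30 Hz power over a 200-ms window
centered on the peak of the band-averaged series within the 2 s after
offset; the window truncates at the search boundary (flagged), ties break
earliest, and trials whose search window has no valid samples are excluded
from block means (exclusions counted).  A baseline beta value (mean band
power over 500 ms ending 100 ms before onset) is reported per trial; the
baseline window is this package's addition — the source defined none.
The peak search runs on the band-averaged series, not per-frequency peaks.

Analysis epochs are cropped to [−1.2 s, +2.6 s] around the offset: the
union of the baseline window, the 2-s search window plus half the 200-ms
averaging window, and the 0.44-s half-support of the 13-Hz wavelet.  Every
sample the statistics touch is edge-valid, and the Morlet transform runs on
a third of the samples of the full 6-s epoch.

**Behavioral metrics.**

* learning curve: block mean |error|; learning rate
  (E_block1 − E_trials201–300) / E_block1 (negative if performance worsens);
* intertrial variability: block SD of the signed error (n−1 denominator);
  its decay: SD(block 1) − SD(trials 201–300 pooled);
* trial-to-trial change: mean |e_t − e_{t−1}| over within-block pairs only
  (block boundaries excluded — a documented choice);
* ACF(1): lagged Pearson correlation of the signed error series, computed
  over session halves (150 trials) because short-series ACF estimates are
  biased; signed rather than absolute errors carry the error-correction
  structure;
* manipulative complexity: C = −Σ p_i ln p_i / ln N over the normalized
  eigenvalues p of the joint-velocity covariance (N joints).  C = 1 when
  all principal components contribute equally, C = 0 when one explains
  everything.  The entropy form is this package's concrete formula for the
  cited complexity statistic; it satisfies both published endpoint
  properties.
* head movement: peak |acceleration| in the same 2-s post-offset window,
  block-averaged — a control that must *not* correlate with PMBR.

**Grouping.** Each subject's coupling is the Pearson correlation between
the 12 block PMBR means and the 12 block mean |error| values.  The latent
group count is selected two ways:

* diagonal-covariance Gaussian mixtures of 1–5 components, EM with
  k-means++ initialization, 10 restarts, tolerance 1e-6; degenerate
  restarts (a component supported by < 2 points) are replaced; model choice
  by AICc = AIC + 2k(k+1)/(n−k−1) with k = 2dc + c − 1, recorded as +∞
  when n − k − 1 ≤ 0 (which is why the 12-dimensional block-PMBR matrix is
  selected by AIC: at n = 30, d = 12, AICc is undefined for c ≥ 2).
  For the 1-dim correlation grouping the EM covariance floor (`reg_covar`)
  is 0.01: an observed 12-block correlation carries sampling SD ≈ 0.2–0.3,
  so any mixture component narrower than SD 0.1 is fitting noise — the
  floor removes the spike-component pathology without rejecting fits.
* fuzzy c-means (fuzzifier m = 2, tolerance 1e-6, ≤1000 iterations, 10
  starts) over 2–10 clusters, compared by a within/between validity ratio

      V = Σ_k (Σ_i u_ik^m ‖x_i − v_k‖² / Σ_i u_ik) / min_{j≠k} ‖v_j − v_k‖².

  Normalizing each cluster's fuzzy scatter by its fuzzy cardinality keeps
  the numerator from shrinking automatically as clusters multiply, which
  the plainer Σu^m d²/(n·min-sep) ratio suffers from; with it the index
  bottoms out at the true count in ~98% of draws from the calibrated group
  distributions.  The exact published form of the cited validity index is
  not reprinted in the source; the implemented ratio honors its contract
  (within/between, smaller-better, minimum at the true count).

Labels come from the 2-component mixture posterior (lower-mean component =
"increaser", i.e. negative coupling); if the posterior labels are not
sign-pure the code warns and falls back to the correlation sign.  Group
PMBR trends are OLS fits of block means on block index with the F test
against the intercept-only model.

## The synthetic cohort

Defaults are the study conditions: 30 subjects — 16 increasers (true
coupling mean −0.40, SD parameter 0.26) and 14 decreasers (+0.47, SD
0.17) — 300 trials, 256-Hz EEG, 200-Hz tracking.

**Errors.** e_t = μ_t + x_t: bias μ_t and marginal SD decay exponentially
(one decay constant per group), x_t is AR(1) with innovation SD scheduled
to honor the marginal-SD decay.  Group defaults (increasers: bias 6→1.35°,
SD 4.0→3.2°, τ = 60 trials, ρ = 0.18; decreasers: bias 10→1.5°, SD
7.5→3.0°, τ = 18, ρ = 0.22) were calibrated so that the expected group
learning rates are 0.48 and 0.60 and the decreasers show the larger
variability decay, larger early trial-to-trial change and larger ACF(1)
decay, while both groups keep positive ACF(1) in both halves.  The ACF(1)
decay contrast is driven by the bias trend: the decreasers' large, fast
bias decay concentrates trend variance in the first session half (high
first-half ACF), while the increasers' slow shallow decay spreads it
across both halves.

**Coupling.** True correlations are drawn from Gaussians centered on the
group means and truncated at zero (the groups are strictly sign-separated).
Truncation shifts the realized *true* group means away from zero (to
−0.434/+0.472) and narrows the spread (realized SD 0.217 vs parameter 0.26
for the increasers).  The shift is a feature, not a bug: a correlation
fitted from 12 blocks is attenuated toward zero by Pearson small-sample
bias (≈ ρ(1−ρ²)/2n) plus a little extraction noise, and the truncation
shift compensates it, so the cohort's recovered *fitted* group means land
on the programmed ±0.40/0.47 — which is the right calibration target,
since the study's reported group means are themselves means of 12-block
fitted correlations.  Block PMBR
values are programmed as offset + scale·(r·z(E_b) + √(1−r²)·η_b), so their
expected correlation with the block errors equals the subject's true r, the
across-block SD equals `pmbr_scale` (default 5 %-change units), and their
center is `pmbr_offset` (default 21%, the middle of the calibrated
burst-mapping range).

**EEG.** Each 6-s trial epoch (offset at 3 s) is 1/f background noise plus
a 20-Hz beta oscillation (amplitude 6 µV, slow 10% amplitude modulation)
with a Gaussian ERD dip around the movement, plus a Gaussian-envelope
20-Hz burst (envelope SD 150 ms) centered 0.55 ± 0.05 s after offset.
`eeg_snr` (default 2) is the beta-to-broadband amplitude ratio.  Because
the burst amplitude is not the extracted percent change, the mapping is
established by a calibration sweep through the real extraction path:
blocks of constant-amplitude trials at 17 amplitudes, the mean extracted
PMBR fit with the monotone model y = c0 + c1·ln(1 + (a/c2)²) and inverted
analytically.  The sweep uses a fixed internal seed, is cached per
parameter set, and costs ~2 s once per process.

**Kinematics, head.** Joint velocities are latent components with a
geometric eigenvalue profile mixed by a random rotation; the decay ratio is
bisected until the sample complexity hits the per-block target (±0.02;
targets rise linearly per group, increasers 0.55→0.70, decreasers
0.45→0.60).  Head acceleration is smoothed white noise, independent of
everything — the control correlations must come out null.

**What the generator does not emulate.** No volume conduction or
multi-channel structure, no artifacts (blinks, EMG, line noise), no
beta-burst rate dynamics (the burst is one Gaussian per trial), no
follow-through between ball onset and true movement offset, no
collision physics.  Passing recovery tests therefore shows the *pipeline*
is correct and well-calibrated, not that it is robust to real-world
artifact structure — artifact rejection is explicitly out of scope.

## Numerical choices and degenerate inputs

* Ties (peak speed, PMBR peak) break to the earliest sample, with a 1e-9
  relative tolerance for floating-point equality.
* Zero-variance inputs to correlations/ACF return NaN ("reported missing");
  empty blocks and non-divisible segmentations raise with the offending
  block named.
* Nonpositive power entering the log-normalization raises (it can only be
  an upstream numerical fault).
* FCM re-initializes on coincident centers (up to 10 times) and hard-assigns
  points that coincide with a center.
* EDF output quantizes to int16 over a symmetric range rounded to the
  2-decimal header precision, so writer and reader scaling agree exactly.

## Expected recovery at the defaults

A 30-subject cohort has only 12 blocks per subject, so a fitted
PMBR-error correlation scatters around its true value with SD ≈ 0.25–0.3;
subjects with weak true coupling can flip sign.  At the calibrated
distributions this yields ~1–2 label flips per cohort (so ~15–16 of 30
subjects show negative fitted correlations) and caps truth-label agreement
near 28/30 — exact recovery is only expected when the coupling is made
strong (|r| ≈ 0.9), which is how the noise-free round-trip test is
constructed.  Likewise the AICc-selected component count on a 30-point
correlation vector is 2 in just under 90% of draws; the remainder are
samples that genuinely look unimodal at this n.

## Problem sizes

The recovery study used by the acceptance script and tests analyzes 20
independent 30-subject cohorts end-to-end (600 subjects, 180,000 trials);
selection-rate properties use 200 draws of 30-subject correlation vectors;
Monte-Carlo oracles use 200–1000 replicates.  Mini-cohorts (1–6 subjects)
exercise the disk formats and CLI.
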