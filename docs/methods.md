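# Methods

## Scope and model

`gaitsync` measures interpersonal gait synchronization from 2D pose
keypoints.  The observable is the vertical (image-y) position of each
walker's ankles; the latent quantity of interest is the walking phase, a
circular variable that advances by 2π per gait cycle (two steps).  The
central assumption is that the left−right ankle displacement of a steadily
walking person is well approximated by a narrowband oscillation at half the
step frequency, so its Hilbert (analytic-signal) phase is a usable proxy
for walking angle.  This holds for walkers seen from the front or back;
joint angles themselves cannot be recovered from single-view 2D data.

Relative phase is reported as walker 2 minus walker 1, wrapped to the
half-open interval (−π, π] with wrap(−π) = π; one wrap convention is used
everywhere.  A global sign flip of the displacement (e.g. mislabelled
left/right ankles) shifts both walkers' phases by π and cancels in the
relative phase.

## Signal chain

Per walker, per frame:

1. **Detrend.**  (y_ankle − y_neck)/l.  The neck is the reference part
   (rarely occluded); l is the vertical span from the topmost detected
   keypoint to the *mean* of the two ankle ordinates.  Averaging the
   ankles makes l constant over the gait cycle — the lower ankle is
   usually the lowest keypoint, so a raw min-to-max extent oscillates at
   twice the cycle frequency and leaks harmonics into the normalized
   signal — while the division still cancels camera zoom exactly, and the
   subtraction cancels camera translation exactly.
2. **Clean.**  Missing samples are linearly interpolated (ends held at the
   nearest observation); samples ≥ 2 SD from the mean (moments computed
   once on the filled series) are replaced by interpolation between
   non-outlier neighbours; the series is z-normalized.  A constant series
   cannot be normalized and rejects the segment with an explicit reason.
3. **Displacement.**  d(t) = left − right ankle ordinate.
4. **Filter.**  3rd-order Butterworth low-pass at 2 Hz, applied
   forward-backward (`sosfiltfilt`) because phase is the measurand; a
   causal single-pass mode exists for comparison.  Filtering follows
   differencing.  Requires a sampling rate above 4 Hz.
5. **Phase.**  φ(t) = angle of the analytic signal of d(t).

Relative phase wrap(φ₂ − φ₁) is summarized by the circular mean and the
circular variance 1 − R̄ after discarding an edge margin (default 0.25 s)
at both ends.

### Edge conditioning for the analytic signal

The FFT-based analytic transform of a finite window that covers a
non-integer number of cycles suffers spectral leakage: on a 5 s segment
the per-sample phase error reaches ~0.1 rad well inside the window and
biases the circular mean by ~0.01 rad, and the z-normalization of each
ankle series leaves the displacement with a DC offset relative to its
sinusoidal component (each series has zero sample mean, but a sinusoid
over fractional cycles does not).  `analyze_segment` therefore fits the
dominant sinusoid a·sin(2πft) + b·cos(2πft) + c (FFT peak, parabolic
interpolation, Gauss-Newton refinement), removes the baseline c, and pads
the series on both sides with ~3 cycles of the fitted sinusoid tapered to
zero, before filtering and the Hilbert transform; the padding is then
discarded.  Filter transients and Hilbert edge leakage land almost
entirely in the padding; noiseless phase recovery improves from ~1e-2 to
~1e-4 rad.  The standalone `hilbert_phase` function remains the plain
analytic-signal phase.

### Cadence

Cadence in steps/s is twice the frequency of the FFT magnitude peak of
d(t) (Hann window, DC excluded), zero-padded so bins land on multiples of
0.01 cycles/s.  The estimate is flagged low-confidence when the power
spectrum's spectral flatness (geometric/arithmetic mean ratio) exceeds
0.3 — simulated white noise measures ≥ 0.43 and clean or moderately noisy
sinusoids ≤ 0.14, so 0.3 separates the regimes — or when the segment
spans fewer than two displacement cycles.

## Pair detection and tracking

Detection runs at a subsampled 2 frames/s.  A skeleton is usable with
≥ 14 of 18 parts detected including both ankles.  A pair is accepted when
the joint bounding box has aspect (height:width) in [1, 3] and height
> 120 px, the per-skeleton mean ankle heights differ by at most 15% of the
box height, and the taller:shorter skeleton ratio is below 1.25.  Skeleton
height here is the max−min vertical extent of detected parts.  The mean
ankle (rather than either single ankle) makes the ground-level comparison
robust to mid-swing asymmetry.  Accepted pairs persisting for a minimum
duration (default 2.0 s, with span counted as (n_frames − 1)/rate) become
segments; pairs sharing a person with another accepted pair for ≥ 3
consecutive subsampled frames indicate a group of 3+ walkers and both
pairs are excluded from those frames.  Rejections are recorded with their
reasons, not raised.

Tracking associates the two seeded identities with candidate skeletons
frame by frame using the mean Euclidean displacement over shared keypoints
D = (1/n)Σ√(Δx²+Δy²).  The default mode solves the 2×k one-to-one
assignment optimally (`linear_sum_assignment` with per-identity dummy
candidates); a greedy per-identity mode reproduces the classic behaviour
whose conflicts are counted as switch suspects.  A match must cost less
than 0.5 × skeleton height × (frames since the identity was last seen);
the gap (dummy) is priced at the one-frame threshold so an identity that
has been occluded for a while cannot out-bid the other identity for its
own well-matched skeleton.  When both identities are unmatched for more
than 0.25 s the segment is truncated at the last matched frame and
flagged.  Gap frames are NaN and are filled later by the cleaning stage.

## Population model

Per-pair mean phases are modelled as a K-component von Mises mixture
fitted by EM: responsibilities from the component log-densities
κcos(θ−μ) − ln(2πI₀(κ)) (exponentially scaled Bessel functions keep large
κ finite), M-step means from weighted circular means, concentrations by
inverting A₁(κ) = I₁(κ)/I₀(κ) (monotone; Banerjee-style starting value
plus Newton, capped at 1e3).  Initialization draws component means from
the data at seeded random indices with κ = 1 and uniform weights; 20
restarts by default, best log-likelihood wins; convergence at an absolute
log-likelihood change below 1e-8 or 500 iterations.  The log-likelihood is
checked for monotonicity at every iteration.  K is selected over 1..4 by
BIC with p = 3K − 1 free parameters (K means, K concentrations, K−1
weights).  Mixing weights and raw concentrations are always reported
separately.  Hand-contact subgrouping is a metadata filter applied before
model selection, not a separate model.

## Validation route

Foot-strike times (the most reliably annotatable gait events) define a
"piecemeal sinewave" per walker: −1 at left strikes, +1 at right strikes,
piecewise half-cosines in between — the smooth oscillation that is exactly
±1 at strikes; a linear interpolant is available as an alternative since
the construction is otherwise unconstrained.  The signal is held constant
outside the first/last strike and sampled at the video rate, then pushed
through the same filter → Hilbert → relative-phase chain.  Agreement
between label-derived and pose-derived per-segment estimates is an
ordinary linear-fit R²; for circular quantities the second estimate is
first re-centered to the 2π branch nearest its reference, so a pair like
(−3.1, 3.1) counts as 0.08 rad apart.  A non-wrapped mode mimics a naive
computation.

## Synthetic scenes

The generator emulates exactly the structure the analysis assumes: per
walker, left ankle y = y₀ + A·sin(2π(f/2)t + φ₀) and right ankle in
anti-phase, with the remaining 16 parts at fixed anatomical fractions of
walker height (only completeness and bounding-box rules ever read them);
walker 2's gait leads walker 1's by a controllable relative phase.  On top
of the clean scene it can layer linear/sway/zoom camera drift applied to
every keypoint, i.i.d. Gaussian pixel noise, i.i.d. per-keypoint
missingness, burst occlusion of a whole walker, per-frame shuffling of
person slots, straight-line base motion (crossing paths), and distractor
skeletons (child-sized, distant, heavily occluded) that exercise each
rejection rule.  Ground truth (relative phase, cadence, foot-strike times,
identity map) is captured before any perturbation.  Defaults describe a
typical urban scene: 30 fps, 5 s, cadence 1.85 steps/s (the naturalistic
mean; the cohort sampler draws N(1.85, 0.32) clipped to 1.0–2.5),
300 px walkers 160 px apart, ankle oscillation amplitude 15 px (~5% of
height), synthetic confidences 1.0 (estimator confidence distributions are
not modelled).  Coordinates are y-down, the pose-estimator convention.

What the generator does *not* emulate — and what passing tests therefore
do not establish about real footage: non-sinusoidal ankle trajectories,
arm swing and limb self-occlusion, perspective foreshortening as walkers
approach the camera, correlated (non-i.i.d.) detection noise, and
estimator confidence structure.  Results on real scenes depend on pose
quality in ways the synthetic suite cannot certify.

## Problem sizes and numerics

Simulation studies use 5 s scenes at 30 fps (150 frames); recovery grids
run 4 phase offsets × 20 seeds, mixture studies 50 draws of n = 348 with
20 EM restarts, chosen to exercise the estimators at the scale of a
typical field data set of a few hundred segments.  Degenerate inputs are
explicit errors, not NaNs: constant series (normalization), all-zero
displacement (phase), resultant length ~0 (circular mean of e.g. {0, π}),
too-short segments, non-finite angles.  Ties in the assignment problem are
resolved by `linear_sum_assignment`'s deterministic ordering; FFT peak
ties by the lower frequency (argmax).  Angles at the wrap point map to +π.

## Known limitations

Two-walker tracking only (no re-identification after long occlusions);
frequency resolution limits cadence to ±0.02 steps/s on 5 s segments; the
validation R² is computed on per-segment scalars, not time-resolved
agreement; mixture selection is by BIC only.  Manual curation steps that a
field study would apply (lighting, occlusion screening) are replaced by
machine-readable accept/reject configuration and quality flags.
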