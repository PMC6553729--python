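# gaitsync

Do people walking side-by-side synchronize their steps?  `gaitsync` answers
this from markerless 2D pose estimates: given per-frame OpenPose-style
skeletons of street scenes, it finds side-by-side walking pairs, tracks
their identities through the frames, extracts each walker's gait phase from
vertical ankle motion, and characterizes synchronization across a
population of pairs with circular statistics and a von Mises mixture model.
It is aimed at movement scientists who want to quantify interpersonal
coordination from ordinary video instead of lab motion capture.

## Method

For each tracked walker the vertical ankle ordinates are detrended against
the skeleton itself — (y_ankle − y_neck)/l, with l the walker's vertical
extent — which cancels camera pan and zoom.  After interpolation of missing
samples, replacement of outliers beyond 2 SD, and z-normalization, the
left−right ankle displacement

    d(t) = y_L(t) − y_R(t)

is a cyclic signal with one cycle per two steps.  It is low-pass filtered
(3rd-order Butterworth, 2 Hz, forward-backward) and the walking phase φ(t)
is the angle of its analytic signal (Hilbert transform).  The relative
phase of a pair is Δφ(t) = wrap(φ₂ − φ₁) ∈ (−π, π]; 0 means in-phase
(left-left), ±π anti-phase (left-right).  Each pair is summarized by the
circular mean and circular variance (1 − mean resultant length) of Δφ(t),
and cadence is twice the FFT-peak frequency of d(t) in steps/s.

Across pairs, the distribution of mean relative phases is fitted with a
mixture of von Mises distributions

    p(θ) = Σ_k w_k · exp(κ_k cos(θ − μ_k)) / (2π I₀(κ_k)),

by EM (concentrations via inversion of A₁(κ) = I₁/I₀), with the number of
components K = 1..4 selected by BIC = (3K−1)·ln n − 2·log L.  Peaks near 0
and ±π indicate in-phase and anti-phase walking modes.

Pair detection follows simple per-frame rules: skeletons with ≥14/18 parts
including both ankles; a pair bounding box with height:width between 1:1
and 3:1, height over 120 px, ankle heights within 15% of the box, and a
skeleton size ratio under 1.25.  Identity tracking minimizes the mean
keypoint displacement between frames with an optimal one-to-one assignment.
A synthetic scene generator with known ground truth (sinusoidal antiphase
ankle motion, camera drift, pixel noise, missing keypoints, distractors)
makes every stage testable end to end, and a foot-strike-label route (a
±1 "piecemeal sinewave" through strike times) provides an independent
validation signal with R² agreement scoring.

## Worked example

```python
import numpy as np
from gaitsync import GaitParams, generate_pair_scene, analyze_frames

params = GaitParams(relative_phase=np.pi / 2, step_frequency=1.8,
                    noise_sd=0.75, seed=11)
frames, truth = generate_pair_scene(params)
result, tracked = analyze_frames(frames, params.fps)
print(f"true relative phase : {truth.true_relative_phase:+.3f} rad")
print(f"estimated mean phase: {result.mean_rel_phase:+.3f} rad")
print(f"phase variance      : {result.rel_phase_variance:.4f}")
print(f"cadence walker 1    : {result.cadence1.steps_per_s:.2f} steps/s")
```

prints

```
true relative phase : +1.571 rad
estimated mean phase: +1.561 rad
phase variance      : 0.0003
cadence walker 1    : 1.80 steps/s
```

The pair was generated a quarter-cycle apart at 1.8 steps/s with 5% pixel
noise; the pipeline recovers the phase offset to ~0.01 rad, the tiny
circular variance shows stable phase locking, and the cadence lands on the
true step rate.

The same workflow is available from the shell:

```bash
gaitsync simulate --rel-phase 1.57 --noise-sd 0.75 --seed 11 --out scene/
gaitsync detect   --in scene/frames --fps 30 --out segments.csv
gaitsync track    --in scene/frames --fps 30 --segments segments.csv --out tracked/
gaitsync analyze  --tracked tracked/ --fps 30 --out results.csv
gaitsync fit-mixture --phases results.csv --kmax 4 --seed 0 --out mixture.json
```

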