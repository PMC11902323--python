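# Methods

## Problem and scope

The Modified Mallet Score (MMS) grades upper-extremity function on five
movements — global abduction, global external rotation, hand to neck, hand
on spine, hand to mouth — each from I (no function) to V (normal).  It is
normally assigned by an experienced clinician watching the patient.
`malletscore` automates the assignment from ordinary single-camera video
that has already been run through a 2D pose model: the input is per-frame
OpenPose BODY25 keypoints (25 × (x, y, confidence)), one JSON file per
frame, and the output is a per-arm grade per movement trial.  The package
does not run a pose network and does not decode video; the BODY25 JSON
dialect is purely an interface.

## Pipeline

1. **Gating and filling.**  Keypoint samples with confidence below a
   threshold (default 0.1) are treated as unreliable and replaced by linear
   interpolation along the frame index between the nearest reliable samples
   (nearest-value extension at sequence ends).  A keypoint that is never
   reliable stays flagged invalid and surfaces as an error only if an angle
   actually needs it.  Gating runs *before* smoothing because a
   Savitzky–Golay window spanning dropout zeros corrupts its neighbours.
   The operation is idempotent.
2. **Smoothing.**  Each keypoint's x and y channel is filtered with a
   5th-order Savitzky–Golay filter, window 13 frames
   (`scipy.signal.savgol_filter`, `mode="interp"`).  Confidences are not
   smoothed.  For clips shorter than 13 frames the window shrinks to the
   largest odd value that still exceeds the polynomial order (the smallest
   usable window is 7); below that, smoothing is skipped with a warning
   rather than crashing on short fixtures.
3. **Angles.**  All angles are in degrees and are computed relative to the
   torso vector v_t (neck KP1 → mid-hip KP8), which makes them invariant to
   translation, uniform scale, and trunk lean:
   * **θUA** — angle between v_t and the shoulder→elbow vector; grades
     abduction, hand to neck, and hand to mouth.
   * **θE** — interior elbow angle between elbow→shoulder and elbow→wrist;
     grades hand on spine (recorded from the rear so the hands stay
     visible); a smaller θE means the hand reached further up the spine.
   * **θLATP** — the transverse-plane forearm angle for external rotation.
     A frontal camera cannot see this rotation directly, so it is estimated
     from the foreshortening of the forearm:
     `θLATP = ±(90° − arccos(l_proj / l_lower))`, where `l_proj` is the
     forearm's pixel length and `l_lower = l_upper × lr` its true length,
     reconstructed from the upper arm's pixel length and an arm-length
     ratio `lr` calibrated on the same session's global-abduction trial
     (during abduction the whole arm lies in the image plane).  `lr` is the
     *mean of per-frame ratios* over the calibration trial, not the ratio
     of mean lengths.  The sign comes from whether the wrist sits lateral
     (external, +) or medial (internal, −) to the elbow in image x, with a
     `mirror` flag for selfie-mode footage.
   Angle magnitudes use `atan2(|cross|, dot)` rather than a bare `arccos`;
   the two are algebraically identical but atan2 is well-conditioned near
   0° and 180°.
4. **Summary.**  A trial is reduced to the best value achieved in the
   movement's functional direction: max θUA (abduction, hand to neck), max
   θLATP (external rotation), min θE (hand on spine).  For hand to mouth the
   summary is θUA at the frame where the wrist comes closest to the nose —
   the touch attempt — not a global extremum, because the arm may overshoot
   before settling at the mouth.
5. **Grading.**  The quantified grade sheet maps the summary angle to I–V
   (see the table in `scoring.py`).  Two rules sit on top:
   * **Touch rule** (hand to mouth): if the wrist's distances to both the
     nose and the shoulder exceed `touch_limit × torso length` (default
     0.35) at the attempt frame, the trial is "not able to touch" → Grade I
     regardless of angle.  The torso length normalizer makes the rule
     scale-invariant.
   * **Symmetry rule**: Grade V means "normal *and symmetric* to the other
     arm".  When at least one arm's angle is in the Grade V range and the
     two summary angles differ by ≤ 15°, both arms are scored V; when they
     differ by more, an arm in the V range is capped at IV.  Grades below
     the IV/V boundary are never altered.  For hand to mouth the rule is
     skipped whenever either arm failed the touch test, so a no-touch arm
     can neither be promoted nor drag the other arm down.

### Grade sheet conventions

Intervals are half-open exactly as printed on the quantified sheet
(e.g. abduction IV is 90° < θ ≤ 150°).  At four boundaries the printed
sheet leaves a single value unassigned between two strict inequalities
(external rotation I/II at −40°, hand to neck I/II at 30°, hand on spine
IV/V at 70°, hand to mouth IV/V at 30°); in each case the unassigned value
is given to the open-ended extreme interval (so external-rotation Grade I
is θ ≤ −40°), which makes the five intervals a true partition of the
criterion's range.

### Numerical choices

* Before threshold comparison the summary angle (and the left/right
  difference in the symmetry rule) is rounded to 1e-6 °.  Sub-micro-degree
  differences are far below any physical meaning here, and the rounding
  makes grading stable when a pose sits exactly on a printed boundary and
  floating-point noise in project→arccos recovery is of order 1e-13 °.
* `l_proj / l_lower` is clamped to [0, 1] before the arccos: keypoint noise
  routinely pushes the projected length past the calibrated true length.
* Degenerate frames (coincident keypoints, missing joints) are masked out
  of an angle series rather than raised; a trial fails only if *no* frame
  is usable.

### Known error structure

Because `dθLATP/dl_proj → ∞` as |θLATP| → 90°, fixed pixel noise produces
much larger transverse-angle errors near end range than near 0°.  This is
verified empirically in the test suite (noise-injection Monte Carlo) and is
the mechanism behind external rotation being the least reliable movement to
grade from a frontal view.

## Synthetic data generator

`synthetic.py` provides the study conditions under which the pipeline is
validated, with no recording required:

* **Body model** — torso 0.50 m, upper arm 0.30 m, lower arm 0.26 m,
  shoulder width 0.36 m, neck→nose 0.12 m: average adult proportions.  At
  the default 800 px/m the projected torso is 400 px, a person filling
  about half of a portrait smartphone frame.
* **Kinematics** — per arm and frame, three commanded angles: shoulder
  abduction (coronal plane), humeral rotation about the upper-arm axis
  (positive = external), and elbow flexion (0 = straight).  Forward
  kinematics places elbow and wrist; all five movements are scripted from
  these three angles (hand-to-neck / hand-to-mouth solve rotation and
  flexion so the forearm aims at the neck / nose).  A constant torso lean
  option exercises the torso-referenced angle computation.
* **Projection** — orthographic, dropping the camera axis, image y down;
  the rear view mirrors image x.  Orthographic projection keeps every
  analytic ground truth exact, which is the point of the generator; the
  grading method itself is scale-invariant and assumes no camera model.
* **Noise** — i.i.d. Gaussian pixel jitter (default σ 2 px ≈ 0.5% of the
  projected torso), per-keypoint dropout (default 1%), and Gaussian
  confidence values (mean 0.85, sd 0.08, clipped to [0.05, 1]); all
  deterministic given a seed.  `NoiseModel.none()` gives exact projection.
* **Trials** — `make_trial(movement, grade)` ramps smoothly from neutral
  over 12 frames and holds the peak pose for the rest of a 30-frame trial
  (the hold exceeds the 13-frame smoothing window, so the filter is exact
  at the peak).  The commanded criterion angle sits at the midpoint of the
  target grade's interval, or 10° beyond the boundary for open-ended
  intervals.  Both arms move symmetrically.  Two special cases:
  external-rotation trials *hold* the commanded end-range angle for all
  frames — the summary is the best-achieved (max) angle, and a ramp through
  the neutral 0° start would mask internally rotated (negative) end
  ranges; and hand-to-mouth Grade I raises a straight arm that never
  approaches the face, producing the no-touch outcome.

What the generator deliberately does not emulate: perspective distortion,
camera shake, occlusion-correlated confidence, OpenPose's structured (non-
Gaussian, joint-dependent) error, soft-tissue/clothing artefacts, and
compensatory movement strategies beyond constant trunk lean.  Passing the
closure tests therefore shows the *algorithm* is implemented correctly and
is robust to moderate unstructured noise; it does not by itself establish
clinical accuracy on real video.

## Evaluation metrics

Agreement between two score sets (algorithm vs ground truth, rater vs
rater, …) is summarized by the Pearson correlation coefficient and the
RMSE in grade units over paired trials, each with a 95% CI, plus a 5×5
truth × predicted confusion matrix and a derived "all errors within one
grade" flag.  The PCC CI uses the Fisher z transform by default (seeded
bootstrap available); the RMSE CI uses a seeded nonparametric bootstrap
(10,000 resamples).  Reports from several raters are averaged by the
arithmetic mean of the point estimates, with the averaged CIs recomputed as
a t-interval across the rater point estimates (averaging per-rater CIs has
no clean interpretation).  Trial exclusions (e.g. a video the raters could
not agree on) are handled by a config-level exclusion list.

## Problem sizes used in the checks

The threshold sweeps hold each commanded pose for 15 frames and step 0.5°
across the criterion range (≈360 scored trials per movement, a few seconds
each on one core).  The generator/scorer closure uses the full 5 movement ×
5 grade grid at 30 frames per trial, once noise-free and ten seeded
repetitions at 2 px jitter.  The external-rotation Grade I/II boundary is
additionally located by bisection to 1e-6°.

## Limitations

* 2D frontal video cannot distinguish a hand behind the head from one in
  front of it; the optional hand-to-neck coupling flag (both arms get the
  lower grade) mirrors that limitation rather than fixing it.
* θLATP inherits the end-range noise amplification described above.
* The per-frame→per-trial reduction (best-achieved angle) is a design
  choice; clinicians score the apex of the attempt, but other reductions
  (e.g. sustained range) are conceivable and would change borderline
  trials.
* The arm-length ratio is calibrated per side from one abduction trial; a
  poor calibration trial (arm never in-plane, heavy dropout) degrades all
  external-rotation grades of the session, which is why the ratio warns
  outside the plausible human range [0.6, 1.3].
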