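# Methods

## The estimation problem

An RGB-D skeleton tracker reports, at ~30 Hz, the 3D positions of a set of
anatomical joint centers in the camera frame. These positions are noisy
(centimeter-scale) and mutually inconsistent: the implied segment lengths
vary over time, and angles recovered per frame can violate physiology.
`physikin` treats joint-angle estimation as causal state estimation over a
rigid-body model, so that every reported posture is physically feasible by
construction.

## Kinematic model

The skeleton is a tree of 22 revolute joints spanning 12 rigid segments,
rooted at the spine base (pelvis):

* base link: 3 co-located rotations (yaw–pitch–roll) plus a 3-DOF
  camera-frame root translation carried in the state;
* each leg: 3-DOF hip (flexion, abduction, axial rotation) + 1-DOF knee;
* trunk: 1-DOF flexion/extension; 1-DOF clavicle elevation per side;
* each arm: 3-DOF shoulder + 1-DOF elbow.

Every joint rotates about its local Z axis; arbitrary anatomical axes are
obtained by fixed pre-rotations, so a spherical joint is a stack of three
co-located Z-revolute joints realizing an intrinsic Euler sequence. Fixed
translations are affine in the 12 segment lengths, which makes the
measurement model affine in the lengths at a fixed posture and the length
Jacobian exact.

The 15 tracked joint centers are the spine base/mid/shoulder and the
bilateral shoulder, elbow, wrist, hip, knee, ankle. They were chosen so
that **every segment length equals the distance between one pair of
tracked centers** — hands, feet, fingers and the head are excluded, as
their tracker estimates are the least reliable and they would add
unobservable model structure.

**Rotation sequences.** Only "ISB-like" conventions constrain this choice,
and the within-cluster order matters numerically. Two rules drove the
default: (i) the *middle* angle of a 3-DOF cluster should stay far from
its ±90° singularity in the tasks of interest, and (ii) the poorly
observable axial rotation should come *last* in the chain so that an
erroneous value cannot corrupt the direction-setting axes of the same
cluster. Hips therefore use flexion → abduction → rotation (hip abduction
stays small), while shoulders use abduction → flexion → rotation (lateral
arm raises drive abduction to ~80–90°, which would gimbal-lock any
sequence with abduction in the middle). The skeleton is data-driven and
loadable from YAML, so alternates can be tested without code changes.

Joint limits ship as a documented table of conservative goniometric
ranges (e.g. knee −3…150°, hip abduction ±50°, shoulder axial rotation
±90°); the base link is effectively unbounded (±180°).

## Constrained extended Kalman filter

State: `[theta, theta_dot, theta_ddot, L, root, root_vel]` (84-dim).
Transition: constant-acceleration for angles, constant-velocity for the
root, identity for the lengths, with the corresponding process-noise rows
of `Q` identically zero so the length estimates converge to constants.
Measurement model: forward kinematics of the 15 centers with an analytic
Jacobian (geometric columns for angles, exact affine columns for lengths,
identity blocks for the root). Measurement covariance `R` is diagonal with
the fitted noise variance (pooled scalar by default, per-axis optional).

Inequality constraints (joint limits; segment lengths within ±20% of their
initial estimate) are single-component rows `sign * x_i <= b`. After the
standard update, the violated (or within-1e-9-of-boundary) rows are
corrected through the restricted gain

    K_R = K − C'(CC')⁻¹ (C x_unc − d) (ν'S⁻¹ν)⁻¹ ν'S⁻¹.

Numerical and semantic choices:

* The constraint residual is evaluated at the **unconstrained posterior**
  (not the prior): only then does the corrected estimate land exactly on
  the violated bounds. A config switch restores the literal prior-based
  form. With single-component rows the correction is exactly a
  componentwise clamp of the unconstrained posterior; the tests document
  how this differs from the minimum-variance (P-metric) projection, which
  also shifts correlated components.
* When `ν ≈ 0` with active constraints the scalar `(ν'S⁻¹ν)⁻¹` is
  undefined; the update falls back to a logged componentwise clamp.
* The error covariance is propagated in Joseph form with the **standard**
  gain by default (`p_gain="standard"`): the clamp is treated as a
  projection that leaves uncertainty untouched, so a component parked on
  its bound keeps enough variance to move off it when the data pull it
  back. Propagating the corrected gain instead (`p_gain="restricted"`)
  freezes poorly observed components at their bounds — both behaviors are
  available, the default was chosen for recoverability.
* A near-singular innovation covariance gets jitter `1e-9·tr(S)/45`
  (logged); `P` is symmetrized after every step.
* Frames with no valid joints receive a prediction-only step (flagged);
  frames with partially valid joints drop the corresponding measurement
  rows rather than imputing them.
* Angles are kept on a continuous branch; limits live well inside
  (−π, π), so no wrapping is applied by default.

## Initialization

Trials begin with quiet standing, and the filter exploits that:

* Segment lengths are the *bias-corrected* mean inter-center distances
  over the first 2 s: the naive mean distance between two noisy points
  overestimates short segments (`E|d+n|² = L² + 2Σσ²`), so the per-axis
  noise variance — estimated from frame-to-frame differences within the
  same window — is subtracted from the mean squared distance. Short
  segments (pelvis, clavicle) remain the least precise: their squared
  length is comparable to the noise power, and ~10–20% error at 7 cm
  noise is the attainable precision, not an implementation defect.
* Angles and root come from a bounded least-squares inverse-kinematics fit
  to the *time-averaged* positions of the same window, with a stronger
  neutral-posture pull (1e-3) than the per-frame default (1e-6) so that
  axial rotations — unobservable at rest — start at neutral.
* `P0` is the identity (equal influence to all state components),
  velocities and accelerations start at zero.

The same IK, warm-started frame to frame with fixed lengths, provides
reference joint-angle trajectories from clean data. It is a deliberately
lightweight stand-in for a full marker-based multibody optimization: it
consumes the same 15 joint centers, so tests validate recovery against
synthetic ground truth, not against a published marker pipeline.

## Covariance tuning

`R` comes from Gaussian moment fits of joint-center residuals (per-axis
and pooled). The defaults reproduce the empirical depth-camera moments:
x (−0.06 m, 0.0019 m²), y (0.06, 0.0050), z (−0.003, 0.0009), pooled
(0.00, 0.0052).

`Q` uses 11 grouped factors (4 leg, 4 arm, 2 base link, 1
trunk+clavicles; left/right shared; the second base-link factor drives the
root translation). Two tuning routes:

1. **Data-driven.** Per joint, amplitude `A` (half peak-to-peak) and
   cutoff `ω_max` (lowest frequency reaching 95% of the DC-removed
   spectral power) of reference trajectories feed a closed-form noise
   factor. The published form of that expression is typographically
   ambiguous; the default reading is
   `σ² = ((A·ω⁴·exp(ω·Δt/(4π)))·Δt)^(2/(3Δt))`, with two alternative
   groupings selectable by name and a user-callable override. Group
   factors take the within-group maximum (the group must accommodate its
   most dynamic joint) and are clipped to the bounds `[1e-3, 1e2]`. Note
   that at 30 Hz the default reading saturates a bound for almost any
   realistic (A, ω); it serves mainly as the optimizer's initial point,
   which is also how it behaves in practice against reference data.
2. **Optimized.** Bounded least squares on `log10 σ²` minimizing the
   summed squared difference between filtered and reference angles (all
   22 modeled angles by default; a subset is configurable). Because
   active-set changes and solution-branch switches make the objective
   rugged, a greedy per-parameter scan over the log-decade grid runs
   first — started from a moderately dynamic uniform level (σ² = 10)
   rather than from the often boundary-saturated data-driven point, since
   sweeps started from a frozen or saturated filter latch onto degenerate
   basins (e.g. whole-body pivoting standing in for hip flexion) — and a
   trust-region-reflective polish (`scipy.optimize.least_squares`,
   ftol 1e-8) follows. The returned objective never exceeds the
   objective of the initial point. Tolerances: ftol 1e-8, bounded by
   `max_nfev` trust-region iterations (default 200; the shipped pipelines
   use 8 with a 2-sweep prescan). One subject's data tunes; other
   subjects validate.

## Synthetic data

The generator scripts four rehabilitation tasks — deep squat with lateral
arm raises, stepping in place, sagittal trunk tilt, frontal trunk tilt —
as raised-cosine joint profiles (C¹, each repetition starting and ending
at rest), 10 repetitions of 4 s by default at 30 Hz, preceded by a 2 s
quiet-standing lead-in (subjects stand still before starting; the filter
and the length estimator use this window). Amplitudes are realistic
mid-range choices (squat: 100° knee, 80° hip, 80° arm raise, 0.38 m pelvis
drop) and are parameters, not constants. Default anthropometry is a
1.77 m adult; a seeded sampler draws mirror-symmetric subjects within
±10%.

Rendered centers are exactly rigid; corruption adds *white* per-axis
Gaussian noise with the empirical moments above, plus optional 0.3 m
outlier jumps and dropouts. Real depth-sensor error is pose-dependent and
strongly correlated in time — the white model is a documented fidelity
limit, and a consequential one: the printed variances aggregate slowly
varying, largely static offsets between the tracker's and the reference
system's joint centers, so injecting the full variance as frame-to-frame
white noise is a substantially *harsher* condition than the physical
recordings the reference accuracy figures come from (see Limitations).

## Evaluation

RMSD and Pearson correlation per angle (correlation returns a flagged NaN
for constant inputs rather than 0). Repetitions are time-normalized to
101 nodes. The 1D SPM paired t-test computes the node-wise paired t
continuum; the critical threshold comes from 1D random-field theory
(residual-based FWHM, expected Euler characteristic, Bonferroni-capped
for rough fields) or from the sign-flip permutation distribution of
max |t| (default; exhaustive when 2^n ≤ 10 000). Supra-threshold cluster
p-values always come from the permutation distribution of the maximal
cluster extent, which stays exact at the small sample sizes of movement
trials — also under the RFT threshold. Positive clusters mean the first
error set is larger (they favor the second method).
`compare_tunings` runs the filter under two covariance configurations on
identical corrupted trials and reports the per-angle SPM outcomes.

## Problem sizes

The shipped pipelines are desk-scale: tuning uses 3-repetition trials of
one synthetic subject (the ~40 s evaluation trials let the unidentifiable
axial-rotation error contaminate the tuning objective, and 3 repetitions
cover the task dynamics), with the objective averaged over two
independent corruptions of the same trial — selecting noise factors on a
single noise realization measurably overfits it (a config can score 4x
worse on a fresh draw of the same trial). Evaluation uses full
10-repetition trials of a second subject; the optimizer budget is
one/two prescan sweeps plus 8 trust-region iterations; SPM calibration
uses 1000 simulated null datasets.

## Known limitations

* **Axial rotations are near-unidentifiable.** With joint centers as the
  only measurements, shoulder (and, with a straight knee, hip) axial
  rotation is a gauge freedom: for an almost-straight elbow, rotating the
  humerus while counter-rotating the elbow flexion plane reproduces the
  wrist position within the noise. Under the white-noise model the
  constant-acceleration filter accumulates uncertainty in that subspace
  polynomially (its velocity and acceleration are never observed), the
  estimate random-walks, and once it reaches a joint limit the
  compensated solution branch is self-consistent — the estimate can park
  at ±90° for the rest of the trial. Hip rotations are contained by
  their tighter ±45° limits and by knee flexion restoring observability;
  shoulder rotations are the dominant error term of every squat summary.
  Temporally correlated (realistic) sensor noise does not kick this
  random walk, which is why physical recordings show markedly smaller
  axial-rotation errors than this white-noise replica.
* **Segment-length traces keep a sub-millimeter-to-millimeter jitter.**
  With zero length process noise the update gain decays like 1/k, so the
  length trace is asymptotically a running mean of noisy per-frame
  distance information; over the final half of a ~60 s trial its standard
  deviation is ~1 mm at the default noise — convergent, but the 7 cm
  white noise keeps the tail drift at the millimeter scale.
* The evaluation replica shares the skeleton between generator and
  filter; real data add model mismatch (soft tissue, tracker biases)
  that passing synthetic tests cannot speak to.
* The filter is strictly causal and single-pass: no smoothing, no
  adaptive `R`, no dynamics/force terms.
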