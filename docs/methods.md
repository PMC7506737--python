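# Methods

`reachkin` reconstructs upper-limb reach-to-grasp kinematics from a wearable
chain of eight inertial sensors (sternum, shoulder, upper arm, lower arm,
hand, and the thumb/index/middle fingertips, the fingertips paired with
force-sensitive resistors), and quantifies movement impairment through
displacement-phase joint ranges.  This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
generator does and does not emulate.

## Signal model and preprocessing

Accelerometers sample specific force (linear acceleration minus gravity, in
the sensor frame) at 100 Hz; gyroscopes sample body-frame angular velocity at
200 Hz.  Both channels are low-pass filtered with a 2nd-order Butterworth at
10 Hz run forward and backward (zero phase, effective 4th order) — the order
is our choice, the standard biomechanics compromise; zero phase matters
because phase lag would bias event timing.  Both channels are then linearly
interpolated onto a common 100 Hz grid (the accelerometer's native rate;
joint-angle dynamics live well below the 50 Hz Nyquist limit).  Constant
sensor biases are estimated from a six-orientation "box" recording — the
gyroscope bias as the mean rate over all static segments, each accelerometer
axis bias as half the sum of its +g and −g segment means — and subtracted.

## Orientation estimation

Each sensor's orientation is a Hamilton unit quaternion (scalar first)
rotating sensor-frame vectors into the global frame (Z up, Y mediolateral, X
anterior).  Propagation is first-order quaternion integration of the
gyroscope at 100 Hz with trapezoidal averaging of consecutive rate samples
(plain rectangular integration lags by half a sample, ~0.7° at peak reach
velocity) and renormalisation each step.

Inclination drift is corrected with a Madgwick-style gradient-descent update:
the step descends the gravity-alignment objective f(q) = R(q)ᵀẑ − â.  We
depart from the textbook filter in one respect: the textbook step has
constant magnitude β regardless of the residual, which makes the estimate
limit-cycle ±β·dt around convergence; with the raised static gain this dither
reached ±0.3° and measurably inflated range-of-motion metrics (ranges are
extrema, so zero-mean dither biases them upward).  We therefore scale the
step proportionally once the gravity residual falls below ~6° of inclination
error, which removes the limit cycle while preserving the large-error
behaviour.  Gravity corrections cannot observe heading; with no magnetometer
in the system, heading accuracy rests entirely on the zero-velocity updates
and the per-trial re-initialisation from the calibration poses, and slow
heading drift during long trials is a known accuracy limit.

Zero-velocity updates follow the protocol's static definition: a sample is
static when the angular-velocity norm is below 3°/s.  On static samples the
gyro is treated as zero (arresting bias and random-walk drift) and the
correction gain is raised from β = 0.1 rad/s to β_static = 2.0 rad/s so the
accelerometer keeps tracking genuine sub-threshold inclination motion while
the gyro is frozen; with the proportional small-residual step this tracking
is lag-limited to ~0.15° rather than dithering.  Both gains are configurable.

## Sensor-to-segment calibration

Anatomical frames use x along the segment pointing distally (arm, hand,
fingers), y mediolateral, z completing the right-handed triad; the trunk uses
z up, y mediolateral, x anterior.  A ten-pose protocol (eight static, two
dynamic) observes two axes per segment: in a static posture the normalised
mean accelerometer reading is the sensor-frame direction of the vertical
anatomical axis; in a single-axis movement the principal eigenvector of the
gyro outer-product sum is the rotation axis, oriented so the net signed
rotation about it is positive (eigenvalue-ratio threshold 4 and 45° minimum
sweep are our quality gates).  The better-observed (gravity) axis is kept
exact, the second re-orthogonalised against it, and the third follows by
cross product in right-handed x, y, z label order.  Per-side axis signs are
tabulated; note that the static upper-arm pose carries a negative sign for
*both* arms — with a distally pointing x-axis the hanging arm measures "up"
as −x on either side, so the equal signs are geometrically correct.  On the
right arm the signed protocol yields a trunk frame yawed 180° and an
upper-arm frame flipped about x relative to the left-arm convention; the
angle-sign table in `conventions.py` absorbs this so that reported angles are
anatomically signed on either side (mirror consistency is tested end to end).

The last two poses define the common global frame: standing straight gives
every sensor the vertical axis, bending forward by hip flexion (to ~60°)
gives every sensor the mediolateral axis, and together they fix each sensor's
neutral-pose orientation, which initialises the orientation filter before
each trial.

## Joint angles

Eleven degrees of freedom, all in degrees, flexion/abduction/supination
positive:

* **Trunk** flexion/lateral/torsion: intrinsic y–x–z decomposition of the
  sternum frame's displacement from the static neutral pose (equivalent to
  the projected-axis definition for single-plane motion).
* **Shoulder**: the upper-arm x-axis expressed in the sternum frame,
  projected into the x–z plane (flexion-extension) and the y–z plane
  (abduction-adduction), measured from the hanging direction.  These
  projection angles degenerate as flexion approaches 90° with simultaneous
  abduction; the generator keeps scripted flexion below ~75°.
* **Elbow**: unsigned angle between the upper- and lower-arm x-axes
  (the protocol excludes hyperextension, so the angle is non-negative).
* **Forearm pronation-supination**: swing-twist decomposition of the forearm
  orientation relative to the upper arm; the twist factor about the forearm
  x-axis, zeroed at the pre-trial neutral posture.  Computing the twist
  relative to the upper arm (rather than the global frame) makes the readout
  exact under arbitrary simultaneous shoulder and trunk motion.
* **Wrist and fingers**: angle between the proximal and distal x-axes,
  signed by the sense of rotation about the proximal segment's mediolateral
  axis so that flexion is positive.

The neutral reference (trunk axes, forearm twist zero) is re-captured from
the quiet standing segment at the start of every trial.

## Phase segmentation

Movement start/end: threshold detector on the upper-arm angular-velocity
norm at 0.1 rad/s with a 100 ms debounce (our choice; the rate is 100 Hz and
isolated spikes otherwise split the movement).  Grasp: the first time any
fingertip force channel exceeds its baseline mean plus 3 baseline standard
deviations (floored at 2% of the channel range so noise-free profiles remain
detectable), sustained 50 ms; baseline is the first 0.5 s inside the
movement bounds.  Release: the minimum of the lightly smoothed (50 ms boxcar)
summed force after the last sustained supra-threshold run, searched within
1 s of the plateau end.  When no channel meets the rise criterion the
kinematic fallback takes over: grasp is the closing-to-hold transition of the
mean index/middle flexion velocity (first drop below 2°/s after the peak
closing rate); release is the point of maximum elbow extension — because the
elbow profile is nearly flat at its extremum, the raw argmin jitters by over
0.1 s, so we take the midpoint of the contiguous valley within 0.25° of the
minimum — confirmed (quality flag only) by a finger-extension onset within
±0.25 s.  Every sample in [t_start, t_end) belongs to exactly one phase via
half-open intervals; there is no dead time.

## Metrics and statistics

Per trial, over the displacement window [t_grasp, t_release): range of
motion (max − min) per degree of freedom; trunk compensation =
√(r_flex² + r_lat² + r_tors²) over the three trunk ranges; finger
flexion-extension = mean of the index and middle ranges; movement time =
t_end − t_start.  Aggregation averages the three repetitions of each subject
× condition cell before factor-level summaries over tested arm (AF/NAF),
block mass (0.108/0.490/1.008 kg) and target height (table/top); metric
correlations relate per-subject medians by Spearman rank correlation
(Pearson on mid-ranks; two-sided p from the t approximation at n ≥ 10 and
the exact n! permutation distribution below).  Quartiles use linear
interpolation; the acceptance quantities use only medians and means, which
are method-independent.  A linear mixed-model wrapper
(metric ~ arm + weight + height with subject random intercepts) is provided
as a thin call into a standard fitter for convenience only.

## Synthetic generator

The generator is the forward model of the whole inverse problem: an
11-DOF trunk-to-fingertip chain executes minimum-jerk joint keyframe
trajectories (the standard motor-control smoothness assumption; smooth
derivatives are also what makes gyro rendering accurate); segment
orientations follow from the joint angles, sensor orientations from fixed
mounting rotations, body rates from central differences of the orientation
quaternions, and specific force as Rᵀ(a − g) with g = (0, 0, −9.81) m/s².
By default the translational term is zeroed (quasi-static rendering), so
accelerometers read pure gravity; full kinematic-chain accelerations can be
switched on (anthropometry: upper arm 0.30 m, forearm 0.26 m, hand 0.08 m,
configurable).  Noise defaults are consumer-MEMS magnitudes: accelerometer
0.05 m/s², gyro 0.005 rad/s white, gyro bias 0.01 rad/s drawn once per
sensor; all randomness flows through seeds and identical seeds give
bit-identical output.

The default trial scripts *are* the study conditions: an additive
arm + height (+ weight, for trunk compensation) model of the
displacement-phase targets whose cell means equal the reported group means
(trunk compensation 9.4/8.2° AF/NAF, 9.5/8.1° top/table, 10.2/8.4/7.9° for
the heavy/wooden/light block; elbow 44.3/54.2 and 61.3/37.2°; wrist
29.4/21.2 and 26.9/23.7°; finger 99.6/77.1 and 94.4/82.1°), with movement
time 4.9 s (affected) / 2.8 s (non-affected) split over reach /
displacement / return.  Trial-to-trial jitter (1–6° per metric, 4% on
durations) and subject-level offsets are seeded Gaussians chosen once as
plausible magnitudes.  Trials open with a neutral standing capture and a
move into the seated start posture (90° elbow flexion, hand pronated on the
table); movement onset and offset include brisk small shoulder adjustments,
emulating hand lift-off and set-down, which give the angular-velocity
threshold a sharp edge to detect.  Fingertip forces are trapezoid-like:
quiet baseline, smooth rise at grasp, plateau scaled by block mass, and a
decay whose minimum falls exactly at release.

What the generator does **not** emulate — and hence what passing tests do
not show about real recordings: soft-tissue artifact, sensor mounting slip,
magnetometer-free heading drift over minutes, FSR nonlinearity and contact
migration, true limb inertial accelerations under the default quasi-static
flag, movement variability beyond Gaussian keyframe jitter, and pathological
coordination patterns beyond shifted range targets (metric *correlations*
across subjects are therefore not calibrated to the study's).  The scripted
"shoulder horizontal abduction" calibration movement is realised as an
abduction sweep from neutral, which rotates the upper arm about the same
anatomical axis; the horizontal variant is not representable in the
projection parametrization at 90° flexion.

## Validation sizes and tolerances

The validation studies (also recomputed by `scripts/acceptance.py`) use:
36 noise-free trials for orientation recovery (< 0.5° RMS per sensor);
20 random sensor mountings for calibration recovery (frames within 1°,
joint-angle RMSE spread < 0.5°); 4 noise-free + 10 noisy trials for
joint-angle recovery (< 2° noise-free, < 5° with default noise); 50 seeded
clean trials for event recovery (± 0.05 s force route, ± 0.10 s kinematic
route, ordering always); 20 seeds × 4 subjects for factor-effect recovery
(within 2 SDs of the seed-to-seed scatter); and one simulated subject's
36 trials per arm, with default noise, for the group-mean summaries.  These
sizes keep a full validation run under a few minutes on one core while
leaving the statistical checks meaningful.

## Known limitations

Heading is unobservable except through zero-velocity updates; long dynamic
periods accumulate yaw error (trunk torsion is the most affected readout).
The projection-based shoulder angles are not an ISB Euler sequence and
degenerate near 90° flexion.  Pronosupination is defined relative to the
pre-trial neutral, so a drifted neutral capture offsets the whole series.
The kinematic release rule indexes maximum elbow extension, an indirect
proxy for object release; its quality flag should be honoured downstream.
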