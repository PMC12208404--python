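# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `paleogait`.  It is the place to look when a number in the
code ("why β/100?", "why 0.13 for the neck lever?") needs a justification.

## Coordinate and unit conventions

X is the direction of travel, Y mediolateral (positive left), Z vertical
(up); gravity is −9.81 m/s² in Z.  Lengths are metres, masses kilograms,
forces newtons, moments newton-metres.  Angles are radians internally and
degrees at user-facing interfaces.  Joint conventions: hip flexion positive
forward, adduction positive toward the midline, rotation positive internal;
knee flexion positive; ankle dorsiflexion positive.

## The two hip shape variants

`HipShapeParams` captures the hip functional complex with four numbers,
relative to the modern-human form at equal inter-hip-center distance:

| parameter | human | australopith | meaning |
|---|---|---|---|
| biacetabular_breadth_ratio | 1.00 | 1.22 | acetabular spacing relative to overall pelvis size; rescaled to a fixed hip spacing, a relatively broad pelvis ends up with a smaller iliac blade |
| neck_length_ratio | 1.00 | 1.08 | femoral neck length relative to femur length |
| iliac_flare_angle | 42° | 16° | anterior wrap of the iliac blade — how far in front of the coronal plane the abductor origin fan reaches |
| ap_depth_ratio | 1.00 | 0.75 | anteroposterior compression of the pelvic ring |

Three geometric commitments matter for the mechanics and deserve their
reasoning on record:

* **Neck length 1.08, not 1.25.**  The marked neck elongation of
  australopith femora reported in the comparative literature is relative to
  femoral *head size*; relative to femoral *length* — which is what
  survives the hybrid-femur construction, since hip-to-knee distance is
  preserved — the elongation is modest.  A head-relative ratio applied to
  length would hand the australopith abductors a large artificial leverage
  bonus.
* **Blade lateral reach tracks hip spacing; blade height tracks blade
  size.**  Australopith iliac blades are low but *laterally flaring*: at
  matched hip spacing their crests are about as far lateral as a human's
  while sitting much lower.  Abductor-origin fans therefore keep their
  hb-proportional lateral offsets across variants but lose height with the
  blade-size factor.
* **The ischial tuberosity does not compress with the pelvic ring.**  The
  hamstring origin keeps its hb-proportional position: the long,
  posteriorly projecting australopith ischium is an extension-favoring
  lever, and squeezing it with `ap_depth_ratio` (which models the
  front-to-back flattening of the ring) would contradict the anatomy.

With these in place the comparative experiment reproduces, as orderings,
the qualitative pattern the shape contrast is known for: higher gluteus
medius and minimus activation, lower gluteus maximus activation, higher
vertical and lower travel-direction hip reactions in the
australopith-shaped hip.  The mechanism in the model is inspectable: the
flare-limited fan loses the anterior fibers that serve combined
abduction/internal rotation, so the remaining fibers work harder; the
AP-compressed pelvis shortens the maximus extension lever, so the cubic
criterion shifts extension work to hamstrings and posterior abductor
fibers; and the extra abductor force compresses the joint vertically.

## Synthetic gait

The generator's job is a walking pass whose markers and plate records are
*mutually consistent* — the acid test being that inverse dynamics on a
noiseless trial closes the whole-body force balance.

**Kinematics.**  Foot (ankle) targets are planted on the floor through
stance and follow a quintic blend through swing (mid-swing lift 3.5 cm at
1.70 m stature).  Foot pitch follows a heel-strike rocker (0.45 rad,
rolling flat over the first 12 % of stance) and a terminal-stance heel rise
(1.1 rad from 42 % of the cycle), with the ankle riding up over the
0.13 m-per-stature rocker lever.  The pelvis translates at the commanded
speed with small sinusoidal oscillations (x 1.0 cm, y 1.5 cm, z 0.5 cm per
1.70 m stature) plus ±7° axial rotation, and its height rides a smooth
minimum of the two legs' straight-leg reach curves — the inverted-pendulum
ride — flattened to 65 % of its raw excursion (humans flatten the COM path
with stance-knee flexion and pelvic mechanisms the rigid IK lacks; the
flattening adapts so feet hover at most ~3 cm in the deepest double-support
frames).  Closed-form per-leg inverse kinematics (law-of-cosines knee, then
hip ab/adduction and flexion from the hip-to-ankle vector, then an ankle
angle tracking the foot-pitch target) converts targets to joint angles, and
the whole trajectory is band-limited at 4 cycles per stride (bounded to
3–5.5 Hz).  Stride length is 1.6 × (femur+shank length); stance occupies
60 % of the cycle with 10 % double support.  Per-trial seeded jitter (3 %)
on the profile amplitudes emulates stride-to-stride variability.

**Kinetics.**  The total external force is M·(a_com − g) with the COM
acceleration computed from the *same processing pipeline inverse dynamics
uses* (markers → 6 Hz zero-lag Butterworth → cluster pose fit → central
differences).  It is split between the plates by smoothstep stance-weight
functions; base centers of pressure progress heel-to-toe; per-frame
least-squares corrections to COP and vertical free moment close the
whole-body moment balance, after which COPs are clamped into the foot
(remaining yaw error goes to the free moment exactly).  Consequences worth
knowing: the noiseless residual *force* is zero to machine precision
(~1e-11 % BW; documented bound 1 % BW), while the residual *moment* retains
up to ≈ 0.2 BW·m around terminal stance, where the rigid model's pitch
angular-momentum demand exceeds what a foot-length COP excursion can
supply.  The two-peak vertical GRF (≈1.3/0.8 BW) emerges from the COM
dynamics rather than being prescribed.

**What the generator does not emulate:** soft-tissue artifact, marker
occlusion patterns, force-plate noise and crosstalk, turning or non-level
gait, arm swing (the trunk+arms are one static segment), and individual
gait idiosyncrasies beyond amplitude jitter.  Passing tests on this data
therefore validate the *pipeline machinery*, not claims about any
particular real walker.

## Musculoskeletal model

Segment masses are fixed anthropometric fractions of body mass (pelvis
11.17 %, thigh 14.16 %, shank 4.33 %, talus 0.2 %, foot 1.17 % per side;
the head-arms-trunk segment takes the remainder so total mass is exact).
Inertias are radius-of-gyration ellipsoids about segment COMs.  Muscle
elements are straight lines with optional via points; there are no wrapping
surfaces, and strengths are posture-independent (no force–length–velocity
scaling) — both documented simplifications.  Group strengths are
order-of-magnitude values in N per kg body mass (e.g. gluteus medius 28,
maximus 32, vasti 60), split equally across each group's elements; because
both variants share them exactly, comparative results do not depend on
their absolute calibration.  The 52-marker template lives on the
*subject's body* and is deliberately variant-independent: both models are
driven by identical marker data, which is the design's central control.

Moment arms use the tendon-excursion relation, r = −∂L/∂θ by central
differences with a 1e-5 rad step.  The path-plausibility report
(`check_muscle_paths`) flags reversals of moment arms larger than 2.5 cm
(smaller secondary-action arms crossing zero with posture — e.g. abductor
fibers switching rotation direction with hip flexion — are physiological),
paths passing within 6 mm of a joint center, and length excursions beyond
50 % of the mean.

## Inverse dynamics

Markers are gap-filled (≤ 10 frames), low-pass filtered (zero-lag 4th-order
Butterworth, 6 Hz default), fitted segment-by-segment with Kabsch cluster
fits, and the extracted coordinates are filtered once more before central
differencing — the nonlinear pose extraction regenerates content above the
marker filter band, and differentiating it would contaminate accelerations.
Plate signals are used as published by default (`grf_cutoff=0`); filtering
is available for noisy measured plates but would re-open the force balance
on synthetic data.  The hierarchical cluster fit is a documented
simplification of a joint-constrained trajectory optimization; with
noiseless markers it is exact.

The recursive Newton–Euler pass is verified against two independent
derivations on exact (analytically differentiated) kinematics: a
closed-form compound pendulum and a sympy-derived Lagrangian for the planar
thigh–shank double pendulum, both agreeing to ~1e-15 relative.  Whole-body
imbalance is reported as a residual wrench at the pelvis, never corrected.

## Muscle recruitment

The per-frame problem min Σa³ s.t. Ba = τ, a ≥ 0 is strictly convex on the
active set; stationarity gives aᵢ = √(max(0, (Bᵀλ)ᵢ)/3), and the DOF-sized
dual system g(λ) = B a(λ) − τ = 0 is solved by damped Newton with row
equilibration, backtracking, and warm starts from the previous frame
(SLSQP and non-negative least squares as fallbacks; infeasible frames are
flagged and carried as least-squares points, never hidden).  The recruited
DOF set is bilateral hip flexion/adduction/rotation plus knee and ankle
flexion — a documented simplification of full-body recruitment.
Activations may exceed 1 under the default policy so overload is visible.
Determinism: repeated solves agree to ~1e-9; the moment-balance residual is
checked at every frame.

Joint reactions including muscle pulls are computed from the free body of
the distal subtree: each crossing element applies its force at its first
attachment inside the subtree, directed toward the neighbouring path point
outside it.

## Curve statistics

Stride curves live on 101 nodes.  Element activations aggregate to
anatomical muscles by strength-weighted mean (forces by plain sum); the
weighted mean is one defensible choice among several (envelope, plain
mean) and is switchable via the `strengths` argument.  Loads are divided
by body weight.  Left-side trials are mirrored to pseudo-right by flipping
Y forces and X/Z moments (axial-vector reflection rules).

The condition effect is tested with a permutation repeated-measures ANOVA:
for a two-level factor the F-field equals the squared paired t-field on
per-subject condition means, and within-subject whole-block label flips are
sign flips of those differences.  With ≤ 11 subjects the sign-flip group is
enumerated exactly (2ⁿ patterns), making the test exact and slightly
conservative; otherwise flips are sampled (default 1000).  The critical
threshold is the upper (1−α) order statistic of the permuted field maxima;
cluster p-values come from the permutation distribution of the maximal
suprathreshold cluster extent.  Null calibration (500 simulated datasets,
10×2×3 design) gives a family-wise error rate of 0.048–0.056 at α = 0.05.

## Non-rigid registration details

CPD follows the standard Gaussian-mixture formulation (template points as
centroids displaced by a kernel-smoothed field).  Three details are fixed
here because the classic recipe misbehaves on this use case:

* **Kernel widths are percentages of the cloud RMS scale** (a configured
  β = 50 is an internal width of 0.5 on the unit-RMS normalized cloud).
  On unit-RMS clouds the literal staged values 50, 30, 10, 8 would all be
  global kernels and no bend could be recovered.
* **σ² threads across stages** instead of re-initializing from the
  all-pairs distance; re-initialization re-runs the coarse-correspondence
  collapse each stage and accumulates drift.
* **σ² initializes from nearest-neighbour mismatch** (clouds are
  pre-aligned by contract — ICP first), and **convergence is an absolute
  σ²-change tolerance**: running EM to machine convergence degenerates into
  density fitting, because the coherence penalty scales with σ².

With λ = 1 and the staged schedule, a known-homology smooth bend of a
femur-scale surface cloud is recovered with a mean correspondence error of
3–4 % of the cloud diameter; the identity case is exact.

The hybrid femur pipeline scales the fossil femur to the human femur
length, ICP-aligns equal proximal fractions, spreads 237 control vertices
on the proximal 20 % by seeded farthest-point sampling, finds their CPD
homologues, holds 2500 distal controls fixed, and warps every vertex with
the combined TPS — the shaft is the smooth interpolation between the ends.
Asymmetry reduction reflects the paired/midline landmark configuration
across the best-fit midsagittal plane, swaps labels, Procrustes-aligns and
averages; the surface and unpaired landmarks ride along on the TPS from
the original to the symmetrized configuration.

## Numerical choices and degenerate inputs

TPS uses the 3-D kernel U(r) = r with zero regularization by default
(exact interpolation); coplanar or duplicated landmark sets raise a
singular-configuration error naming the offending points.  ICP is
point-to-point with nearest-neighbour matching and no trimming;
non-convergence is flagged, not raised.  Uniform joint-center scaling
refuses conflicting targets, listing the implied scales.  The sacral
endplate is built at the generator's 30° target slope in the neutral
(anterior-pelvic-plane-vertical) construction pose.  All randomness flows
from explicit integer seeds; every generator is a pure function of its
inputs and seed.

## Problem sizes used by the shipped checks

The default comparative experiment is 10 subjects × 3 trials × 2 variants
(60 stride solves of ~100 frames × 160 elements), about 40 s on one CPU.
The statistics calibration uses 500 null datasets with exact 1024-pattern
permutation inference.  Registration checks use clouds of 100–600 points
and meshes of ~600 (pelvis) and ~3600 (femur) vertices.  These sizes were
chosen to make the full chain routinely re-runnable at a desk.

## Known limitations

Straight-line muscle paths without wrapping; posture-independent strengths;
a single lumped trunk segment and no arm swing; hierarchical rather than
global pose fitting; a stylized parametric bone geometry (the meshes carry
the variant contrasts and the landmark schema, not anatomical surface
detail); terminal-stance residual moments in the generator; and a
comparative — not absolute — interpretation of activations and joint
loads.  Conclusions about real gait require real marker, plate and bone
data at the same interfaces.
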