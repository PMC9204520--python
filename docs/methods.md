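# Methods

This note documents the models, algorithms, defaults and design choices in
`squatmc`, and what the synthetic pipeline does and does not establish
about real data.

## Reduced musculoskeletal model

A sagittal-plane (2D) right lower limb: pelvis, thigh, shank, foot, joined
by hip, knee and ankle flexion hinges (flexion-positive; internally each
DoF stores a sign mapping flexion onto the counter-clockwise rotation of
the child frame).  The head–arms–trunk mass and the contralateral limb are
lumped into the pelvis segment, so the model total equals the subject mass;
segment lengths and masses follow standard anthropometric fractions of
stature and body mass (thigh 0.245 H / 0.100 m, shank 0.246 H / 0.0465 m,
foot 0.152 H / 0.0145 m).  Fourteen muscle–tendon units (three vasti,
rectus femoris, both biceps femoris heads, semimembranosus, semitendinosus,
both gastrocnemii, soleus, tibialis anterior, gluteus maximus, iliopsoas)
cover all seven conventional muscle groups.  Pathways are point-to-point
with via points only; there are no wrapping surfaces.  Two geometric
devices keep moment arms physiological across deep flexion where a straight
chord would collapse into the joint centre: the knee extensors route
through a patellar via point placed anterior–distal on the femur
(extension arm 6.2 cm at full extension, 3.6 cm at 90° flexion), and
tibialis anterior routes under an extensor-retinaculum via-point pair.
The triceps surae insert on an effective calcaneal wrap point.  These are
reduced-model idealisations, not digitised anatomy.

Scaling: landmark distances (pelvis width, femur length, tibia length)
set per-segment isotropic factors (foot: mean of femur and tibia); masses
scale uniformly to the subject mass; optimal fiber length and tendon slack
length scale together by the ratio of scaled to generic muscle–tendon
length in the reference pose, preserving their ratio; maximum isometric
forces are copied from the generic model unchanged.

## Muscle mechanics

Rigid-tendon Hill model.  Fiber kinematics follow
`l_f·cosα = L_MTU − TSL` with the constant-thickness pennation rule
`l_f·sinα = l_opt·sin(PEN)`; at `L_MTU ≤ TSL` the fiber clamps at 1% of
`l_opt` and the state is flagged.  Force along the tendon is
`MIF·(a·f_L·f_V + f_PE)·cosα`, with one explicit curve set normalised so
`f_L(1)=1`, `f_PE(1)=0`, `f_V(0)=1`:

* active force–length: Gaussian `exp(−(l̃−1)²/0.45)`;
* passive force–length: exponential toe `(e^{4(l̃−1)/0.6}−1)/(e⁴−1)`
  reaching 1 at 60% strain, continued **linearly** (C1) beyond — the usual
  construction in equilibrium muscle models; without it, extreme Monte
  Carlo draws put fibers at l̃ ≈ 2 and the pure exponential produced
  knee loads an order of magnitude beyond physiology;
* force–velocity: hyperbolic (Hill constant 0.25) for shortening,
  saturating at 1.8 for lengthening; maximum shortening velocity
  10 `l_opt`/s.  The quasi-static mode (default for squats) sets f_V ≡ 1.

Tendon slack lengths in the shipped model are declared `auto`: they are
anchored so each fiber sits at optimal length in a mid-squat reference
pose (knee 45° with the kinematic closure below).  This keeps all muscles
inside sensible operating ranges over the cycle but means the TSL values
are calibration artifacts of the reduced geometry, not anatomical
measurements.

The elastic-tendon equilibrium solve is deliberately out of scope: static
optimization evaluates the force–length/velocity factors at the current
state with an inextensible tendon.  The main visible consequence is that
TSL perturbations shift normalized fiber length one-for-one (no tendon
stretch absorbs them), which **amplifies TSL sensitivity** relative to an
elastic-tendon pipeline; see Limitations.

## Kinetics

Moment arms use the tendon-excursion definition `r = −∂L/∂q`, evaluated by
central finite differences (step 1e−5 rad, configurable; one-sided with a
warning at joint-range boundaries).  Inverse dynamics is a bottom-up planar
Newton–Euler recursion with the per-limb GRF applied at the centre of
pressure and the foot assumed flat on the ground (which fixes the global
orientation of the chain).  Accelerations come from zero-phase low-pass
filtered (6 Hz default) double differentiation, or are zeroed entirely in
the quasi-static mode — the default, appropriate for a 4 s squat where
inertial moments are a few N·m.  Inverse kinematics (for marker-based
input) is a per-frame weighted least-squares fit of model markers with the
pelvis pose and joint angles free; trials may instead carry joint angles
directly, which is the synthetic generator's default.

## Static optimization and joint loading

Per frame: minimise Σa² subject to the net flexion moments and activation
bounds.  Activation-independent passive forces move to the constraint
right-hand side.  The QP is solved as bounded least squares in activation
space with the equality constraints enforced by a penalty weight of 1e4
(BVLS); at that weight the equality residual is ~1e−10 N·m and the
objective agrees with an SQP reference to ~1e−9.  Frames whose demand
exceeds capacity are flagged infeasible and keep the least-violation
solution — perturbed models may simply be too weak, and the Monte Carlo
must report their outputs rather than abort.  The knee contact force is
the intersegmental knee force minus the pull of every pathway segment
crossing the knee, expressed in the tibia frame; magnitudes are reported
in body weight (BW = m·g), the only place the BW unit enters.

## Probabilistic engine

Parameter variability is Gaussian.  Scalar classes (MIF, TSL, PEN) use
coefficients of variation aggregated from a literature-style table: several
sources for the same (muscle, parameter) combine by subject-count-weighted
averaging; a missing (muscle, parameter) falls back to the unweighted mean
CV of that parameter across muscles.  Pathway points use an isotropic
per-axis SD of 5 mm on each coordinate (a magnitude-mode alternative is a
config switch).  Draws truncate to physical bounds by resampling (MIF,
TSL > 0; PEN in [0°, 80°]), erroring after 100 consecutive rejections.
The shipped default table is synthetic: TSL CVs span the 2–9% working
range, MIF and PEN carry literature-plausible placeholder CVs of 0.22–0.32,
and each parameter deliberately omits at least one muscle to exercise the
fallback rule.

Designs follow the two-level layout: a *general* MC perturbs all five
classes of a muscle group (default 2000 iterations), *individual* MCs
perturb one class at a time (default 500).  The full study design — per
subject and muscle group one general plus five individual MCs, six
subjects, seven groups — plans 189,000 iterations; the muscle-group
contribution analysis rests on the six sub-group general MCs (72,000
simulations).  Each iteration derives its own RNG stream from
(seed, iteration) via `SeedSequence` spawning, so serial and parallel
execution, and per-iteration replay, are bit-identical.

Convergence is checked post hoc: the mean-over-time 5th–95th band width at
N iterations is compared with the width at ceil(1.1·N); converged means a
relative change below 1%.  Note that this statistic is itself random: in
null simulations even i.i.d. Gaussian outputs satisfy the 1% criterion
only ~89% of the time at N ≈ 2000, and heavy-tailed outputs much less
often — see Limitations.

## Uncertainty analysis

Percentiles interpolate linearly between order statistics (numpy default);
bands require ≥ 20 iterations.  Contribution factors are pointwise
percent ratios of band widths; frames where the reference width is below
1e−9 are masked.  The group-contribution reference is the all-lower-limb
general band.  Overlapping groups (the biarticular subsets) are reported
as-is and are not forced to sum to 100% — parameter and group interactions
make super- and sub-additivity informative, not erroneous.  For band and
error arithmetic across trials, traces resample to 101 points of percent
squat cycle using the trial's cycle events; RMSE is computed on that grid
in BW.  Best-model selection is the argmin of cycle RMSE over iterations,
ties broken toward the lowest iteration id.

## Synthetic data

The generator emulates the study conditions end-to-end with no external
data: subjects drawn from N(89, 13²) kg, N(1.72, 0.04²) m, N(74, 6²) y
(six by default), truncated positive; landmark distances from stature by
the allometric fractions above; a raised-cosine knee-flexion profile
0 → 90° → 0 over 4 s (101 frames) with hip and ankle angles from a
*hip-over-ankle closure* (shank lean `α = atan2(L_t sin k, L_s + L_t cos k)`,
ankle dorsiflexion α, hip flexion k − α, pelvis upright) — the simplest
closure keeping the centre of mass over the foot; per-limb GRF of half
body weight (quasi-static default; a COM-acceleration modulation is
available) with the centre of pressure under the model COM; optional
planar marker synthesis for IK tests.  The "measured" KCF comes from a
deterministic truth-perturbed reference model (per-group multiplicative
factors on MIF/TSL/PEN) plus N(0, 0.1²) BW noise by default.  Synthetic
EMG is band-limited Gaussian noise amplitude-modulated by an activation
trace.

What passing tests on this generator do **not** show: the quasi-static,
single-limb, upright-trunk squat suppresses co-contraction and hip
moments relative to real squatting; marker artifacts, implant telemetry
characteristics and 3D joint loading are absent.  Results validate the
propagation machinery, not subject-specific knee-load accuracy.

## EMG processing

Zero-phase 4th-order Butterworth band-pass (10–300 Hz read as the passband;
the sampling rate must exceed twice the upper edge), mean removal,
full-wave rectification, centred moving average (100 ms default), then
normalisation by the subject-level maximum across all supplied trials (the
global output maximum is exactly 1).  Quantitative EMG-to-activation
metrics are out of scope; the chain supports qualitative pattern
comparison only.

## Numerical choices

Moment-arm step 1e−5 rad; QP penalty 1e4, feasibility tolerance 1e−4 N·m;
percentile estimator linear; IK Levenberg–Marquardt with warm starts and a
rank check per frame (coincident or insufficient markers error out);
degenerate inputs (slack fibers, zero-width bands, measured KCF ≤ 0)
clamp-and-flag or mask rather than propagate NaNs silently.  All file I/O
is strict: malformed TRC/MOT/STO input raises a parse error naming the
line.

## Known limitations

* **Group-uniform MIF changes are unobservable in the KCF.**  The four
  knee extensors share the patellar mechanism, so at loaded flexion the
  joint moment pins their total force: scaling all extensor MIFs by a
  common factor rescales activations by its inverse and leaves muscle
  forces — and the KCF — unchanged (exactly, on interior solutions).  The
  same mechanism caps the *independent* MIF contribution in this planar
  model at a few percent, far below what richer 3D models with heterogeneous
  moment arms and obligatory co-contraction exhibit.  Consequently a
  ground truth defined by a uniform extensor-MIF scaling cannot be
  recovered by output matching; slack-length or pathway truths can (see
  `examples/05`).
* **Rigid-tendon TSL amplification.**  TSL draws shift fiber operating
  ranges one-for-one, so TSL dominates the KCF variance decomposition and
  produces heavy-tailed KCF distributions (passive-force excursions up to
  ~16 BW).  An elastic-tendon equilibrium model would buffer much of this.
* **Convergence at 2000 iterations is not guaranteed here.**  With the
  heavy-tailed output above, the +10%/<1% band-stability criterion
  typically fails at N = 2000 (observed nested-band changes of 1–4%); the
  checker reports this honestly rather than asserting convergence.
* Single-limb, sagittal-plane, foot-flat; no wrapping geometry, no
  frontal/transverse DoFs, no co-contraction cost terms, no elastic-tendon
  equilibrium, no correlation structure between parameter draws.
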