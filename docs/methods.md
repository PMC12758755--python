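# Methods

`gaitdyn` predicts sagittal-plane gait dynamics — joint angles, per-foot
ground reaction forces (GRFs), and lower-limb joint moments over one
full gait cycle — from three scalars per subject: leg length *l* (ASIS
to medial malleolus, m), body mass *M* (kg), and walking cadence *f*
(strides/s, period *T* = 1/*f*). This note documents the model, its
assumptions, the choices made where the design was genuinely open, and
what the synthetic-data generator does and does not emulate.

## Empirical joint-angle model

Left hip and knee angles are harmonic series

    phi_L(t) = B0*l + sum_{j=1..n} Bj*l*sin(2*pi*j*f*t + phi_j)

with amplitudes in rad/m, so the waveform scales linearly with leg
length. The right side adds `j*pi` to each phase, which is exactly a
half-period shift — the model is symmetric and periodic by
construction. Shipped coefficients (hip and knee, n = 3) are population
values for healthy adult level walking; no ankle coefficients ship, and
none are needed because the dynamic chains treat each supporting leg as
a rigid rod and ignore the foot.

Fitting is ordinary linear least squares on the basis
{1, sin(2πjft), cos(2πjft)} followed by conversion to amplitude–phase
form. That form is non-unique — (B, φ) ≡ (−B, φ+π) ≡ (B, φ+2π) — so a
canonical representative is fixed: **phase in (−π/2, π/2] with signed
amplitude**. This is the unique convention consistent with the shipped
coefficient tuples (e.g. hip B1 = −0.316, φ1 = −1.105), and it makes
the fitter deterministic: synthesizing a signal from the shipped models
and refitting returns the same tuples to 1e-9. Degenerate (zero)
harmonics report (0, 0); a rank-deficient design matrix (too few or
degenerate samples) raises rather than returning an arbitrary solution.

A per-signal fit at known leg length is used throughout (amplitudes are
divided by the caller's *l*); pooled multi-subject regression against
*l* is not implemented.

## Anthropometry

Segment masses, lengths, and centroid offsets come from a table of
dimensionless fractions (per-limb thigh and shank mass fractions of
body mass; thigh/shank split of leg length; proximal centroid
fractions). Defaults are Dempster-type adult values (thigh 0.100,
shank 0.0465, centroids at 0.433 of segment length) with a 0.53/0.47
length split; they are configuration, overridable from a plain-text
`key = value` file, and every test uses explicit toy tables so nothing
depends on the defaults' provenance. The trunk lump `m = M − 2(m_t+m_s)`
absorbs head, arms, and — because the model has no feet — foot mass.
The rigid whole-leg rod's centroid (`p_1`, from the ground contact)
defaults to the mass-weighted thigh+shank centroid implied by the
table; the leading double-support rod's centroid distance from the hip
(`p_2d`) defaults to its mirror image `l_1 − p_1`. Gravity is
9.81 m/s², configurable.

## Linkage chains and coordinate conventions

The ground contact of the supporting (or trailing) foot is the origin,
x anterior, y up. Segment angles are measured from the upward vertical,
positive when the distal end is anterior. With zero pelvic tilt the
thigh absolute angle equals the hip angle and the shank angle is
`hip − knee`.

Single support is a three-link chain: rigid stance rod (full leg) from
the origin with the trunk point mass at its tip (the hip), and a swing
thigh + shank hanging from that hip. Double support rigidifies both
legs: a trailing rod from the origin carrying the trunk at the hip, and
a leading rod hanging from the hip with its centroid at `p_2d`. The two
rod angles are both taken from the empirical hip models — the closed
loop is *not* reconciled; the implied foot-to-foot distance is exposed
as the `foot_separation` diagnostic.

One sign choice deserves emphasis: the supporting rod runs *upward*
from foot to hip while the empirical hip angle describes a thigh
hanging *downward* from the hip, so the rod coordinate is the negated
stance-side hip angle (`θ1 = −φ_hip`). This is forced by physical
consistency (a flexed hip at heel strike must put the hip behind the
foot) and is applied in one place, the cycle assembler.

Every point-mass position in either chain has the form
`(Σ a_i sinθ_i, Σ c_i cosθ_i)` with constant coefficient matrices, so
velocities and accelerations are exact analytic derivatives; numeric
differencing appears only in test oracles, which require agreement to
1e-5 relative (kinematics) on random smooth trajectories.

## Ground reaction forces

Single support is whole-body Newton: vertical GRF = body weight + the
mass-weighted sum of vertical centroid accelerations; anterior–posterior
GRF is the horizontal analogue; the swing foot carries exactly zero.
Double support uses the same totals over the two-rod chain, then splits
them per foot by **linear mass transfer**: with transfer fraction
`s = (t − t_heelstrike)/T_DT` running 0→1 over the double-support
window,

    GRFy_trail = Mg(1−s) + m*ÿ_c/2 + (m_t+m_s)*ÿ_s1
    GRFy_lead  = Mg·s    + m*ÿ_c/2 + (m_t+m_s)*ÿ_s2

which sums to the two-rod total *identically* (tested to 1e-9 N). The
horizontal split weights both legs' inertia terms by `s`:

    GRFx_trail = (m − m·s)*ẍ_c/2 + (m_t+m_s)·s·ẍ_s1
    GRFx_lead  = (m + m·s)*ẍ_c/2 + (m_t+m_s)·s·ẍ_s2

As published, these do **not** sum to the two-rod horizontal total
mid-window (only at s = 1). The model is implemented exactly in this
form — fidelity over correction; `horizontal_split_residual` exposes
the gap, and a clearly non-default `conserving=True` variant (trailing
leg weighted by 1−s) exists for sensitivity analysis only.

## Joint moments

Each chain's Lagrangian uses point masses at centroids (no segment
rotational inertia — the segments are centroid abstractions; a rod
inertia option was considered and rejected as outside the model) and
the trunk as a point mass at the hip, with the origin as zero
potential. Because positions are sums of `(a sinθ, c cosθ)` terms, the
kinetic energy is `½ ω'M(θ)ω` with

    M_ij = α_ij cosθ_i cosθ_j + γ_ij sinθ_i sinθ_j,
    α = A'diag(m)A,  γ = C'diag(m)C,   V = g·(m'C)·cosθ,

and the Euler–Lagrange left-hand side reduces to a closed form in which
the velocity cross-terms cancel:

    Q_i = cos_i(α(cos∘θ̈))_i + sin_i(γ(sin∘θ̈))_i
        − cos_i(α(sin∘θ̇²))_i + sin_i(γ(cos∘θ̇²))_i − g G_i sin_i.

This production path is validated against an energy-only
finite-difference Euler–Lagrange oracle (1e-4 relative on 100 random
trajectories), closed-form pendulum and statics limits, and energy
conservation under unforced forward integration.

Moments follow from the virtual-work chain of differences. Single
support: swing knee `M_k = Q_3`, swing hip `M_h2 = M_k − Q_2`, stance
ankle `M_a = M_h2 − Q_1`. Double support: leading ankle
`M_a^lead = Q_2d`, trailing hip `M_h^trail = M_a^lead − Q_1d`. The
stance-limb knee (rigid within the rod) is the lever-arm combination
`M_k = M_a·l_3/l_1 + M_h·l_2/l_1`.

Two closures are the package's own, because the reduced chains leave
them undetermined:

- **Contralateral hip moments.** The chains yield only one hip moment
  at a time (swing side in single support, trailing side in double
  support), yet the stance-knee formula needs the stance-side hip.
  The two limbs' hip moments are taken equal and opposite — torque
  balance at the point-mass, zero-tilt pelvis where both thighs and
  the trunk meet.
- **Trailing ankle moment in double support** is outside the two-link
  model and reported as zero; the trailing knee then reduces to
  `M_h^trail·l_2/l_1`. Real late-stance push-off moments are therefore
  *not* captured on the trailing side.

Reported moments keep the generalized-coordinate sign convention
(positive torque drives the segment toward +θ, i.e. anterior). No
anatomical flexion/extension re-signing is applied at export; users
comparing against clinically-signed data should map signs per joint.

## Cycle assembly

The stride starts at left heel strike. Default schedule: first double
support [0%, 12%) with the left leg leading, first single support
[12%, 50%) with left stance, then the mirror image; intervals are
half-open so the 12/38 sample counts are unambiguous at 100
samples/cycle (the default grid, configurable and required even).
Only the first half cycle is computed; the second half is the first
with legs swapped, so every right-side series equals the left-side
series rotated by exactly half the grid — exact by construction, not
to tolerance.

The chain swap at each double→single boundary re-anchors the trunk
from the trailing to the stance leg and re-decomposes the swing leg,
so kinetic signals are genuinely discontinuous there (≈0.4 body weight
in total vertical GRF for the default subject); at the heel-strike
boundaries the total vertical GRF is continuous to ≈0.012 bw.
`transition_discontinuity` reports all four jumps per signal. Over the
assembled cycle the mean total vertical GRF equals body weight within
1% (0.992·Mg for the default subject); the residual is the boundary
velocity mismatch, not quadrature error.

## Synthetic trials

`generate_trials` emulates a multi-trial gait session: each trial is
the predicted cycle plus independent, seeded Gaussian noise per sample
(defaults: 1° on angles, 2% body weight on GRFs, 0.02 N·m/kg on
moments), and `average_trials` is the pointwise mean. This reproduces
the statistics that trial averaging relies on — averaged-noise sd
σ/√n, coefficient-recovery error shrinking accordingly — and nothing
more: real trials vary in timing, waveform shape, and soft-tissue
artifact, none of which is simulated. Passing the recovery tests
therefore demonstrates correctness of the fitting/averaging machinery,
not field accuracy on real measurements.

## Numerical choices and problem sizes

- Time grid: 100 samples/cycle for assembly (even, half-open);
  101-sample closed grids for fitting demonstrations.
- Least squares via `numpy.linalg.lstsq` with a rank check; Pearson via
  `scipy.stats.pearsonr`.
- Finite-difference oracles (tests only): step 1e-6·T for kinematics,
  1e-5 for energy derivatives.
- Test suites use 100 random Fourier trajectories of ~20 samples each
  for oracle equivalence, 8 trials × 100 samples for recovery, and
  1000 replicates for the rRMSE-convergence property — sizes chosen so
  the statistical assertions have comfortable margins while the whole
  suite runs in seconds.
- Degenerate inputs fail loudly: non-positive subject scalars,
  mass/length fractions outside (0,1) or implying negative trunk mass,
  constant series for rRMSE/Pearson, times outside the double-support
  window, phase-mismatched states.

## Default subject

Body mass 58.7 kg (study-cohort mean), leg length 0.90 m and cadence
0.90 strides/s as cohort-representative values (≈0.53 of the cohort's
mean stature; natural self-selected stride rate). These feed the
shipped example and the double-hump and cycle-average checks.

## Known limitations

- Perfectly symmetric, periodic gait only; unsuitable for pathological
  or asymmetric gait.
- Sagittal plane only; mediolateral forces ignored.
- No foot segment: no center-of-pressure progression, zero swing-foot
  GRF by construction, no trailing-leg ankle/knee push-off moments in
  double support.
- The double-support closed loop is not enforced and the horizontal
  per-foot split does not conserve the horizontal total mid-window
  (both are faithful to the published model; diagnostics expose them).
- Population angle coefficients come from a small cohort; per-subject
  refitting requires measured angle series.
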