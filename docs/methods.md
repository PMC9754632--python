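# Methods

## Physical model

A magnetically labelled spheroid on a non-adhesive substrate is treated as a
liquid drop of uniform body-force density f = M_v·∇B (N/m³) and surface
tension γ (mN/m). At mechanical equilibrium the pressure jump across the
interface is ΔP(z) = 2γb + f·z, with z the depth below the apex and b the
apex mean curvature, so the meridian satisfies the axisymmetric Young–Laplace
(Bashforth–Adams) system

    dx/ds = cos φ,  dz/ds = sin φ,  dφ/ds = 2b + c·z − sin φ/x,  c = f/γ,

with the apex limit dφ/ds|₀ = b. The field gradient is inhomogeneous over the
working distance of a real magnet; it is collapsed here to a single averaged
constant, so f is uniform. The substrate is non-adhesive: the profile is
terminated at tangent angle φ = 180° (non-wetting contact). The volume of the
solid of revolution is carried as a quadrature state dV/ds = π·x²·sin φ,
which closes the body at the contact disc because z never decreases along
the meridian.

Assumptions worth keeping in mind: the aggregate is at shape equilibrium
(flattening dynamics — the fast elastic transient followed by viscous
relaxation — are out of scope); volume is conserved from the undeformed
sphere of radius R; the material is homogeneous enough for a single γ and,
for the contact analysis, a single incompressible elastic modulus.

## Integrator

Fixed-step classical Runge–Kutta (4th order), numba-compiled, on the
arc-length system above. Design choices:

- **Length scale.** The step is dimensionless in units of 1/√(b² + c), the
  smaller of the apex radius and the capillary length, so the same `step`
  resolves both sphere-like and puddle-like shapes. Default `step = 1e-3`;
  steps above 0.05 are rejected as unable to resolve the apex.
- **Apex start.** The sin φ/x singularity at s = 0 is handled by series
  expansion (φ = b·s + c·b·s³/8, x = s − b²s³/6, …), starting one step from
  the apex with O(s⁵) truncation, consistent with the scheme's order.
- **Pole regularization.** When a trial substep lands on or past the
  symmetry axis (x ≤ 0, which can only happen at the closing pole of
  near-spherical shapes), sin φ/x is replaced by its regular pole limit
  (2b + c·z)/2.
- **Termination.** The φ = π crossing is located by bisection inside the
  final step (60 iterations, machine precision); the terminal sample is
  therefore not uniformly spaced — finite-difference checks on the stored
  samples should exclude it.
- **Why fixed-step.** A fixed step gives a clean, directly testable
  convergence signal: h, w and V shift by ≤ 1/16 per step halving, and the
  scheme is cross-checked in the tests against an independent adaptive
  integrator. The maximum dimensionless arc length is 40, ample for every
  physical shape (a sphere uses π; large puddles use ≈ √(c)·R_puddle).
- **Width.** w = 2·max x with parabolic refinement through the three widest
  samples; volume from the RK quadrature rather than trapezoidal summation
  of the stored samples, which keeps the sphere volume exact to ~1e-13.

`solve_shape_for_volume` parameterizes the family by c at fixed volume by
root-finding on b (volume is strictly decreasing in b), bracketing
multiplicatively from the equivalent-sphere curvature and polishing with
Brent's method to ~1e-12 relative volume error.

## Landmark fit (surface tension)

The objective is the equally weighted sum of squared **relative** errors of
(h, w, V) between model and measurement — h, w, V carry different
dimensions, so relative errors are the only scale-free choice. V is taken
from the initial radius assuming volume conservation (direct V input is also
accepted). Minimization is Nelder–Mead over (log b, log c) — the log
parameterization enforces positivity without constraints — with
`xatol=1e-9`, `fatol=1e-16`, 500 iterations max, and convergence reported in
the diagnostics.

Seeding: shapes are self-similar in β = c/b², so a 25-point pre-scan over
γ ∈ [0.5, 500] mN/m evaluates one dimensionless profile per candidate β,
matches b to the volume exactly in closed form, and scores only the (h, w)
residual. This costs ~25 forward integrations and places the Nelder–Mead
start close enough that noise-free round trips recover γ to ~1e-9 relative.

Identifiability: γ → ∞ as the flattening 2R − h → 0. Landmark sets with
non-positive flattening raise an out-of-measurable-range error; flattening
below twice the pointing noise (default 5 µm) only warns. At the reference
condition (γ = 20 mN/m, R = 530 µm, f = 4.25e4 N/m³) the flattening is
≈ 220 µm and independent ±5 µm uniform noise on h and w propagates to a ~2%
coefficient of variation on γ — comfortably inside the 5–20% instrument
envelope asserted in the acceptance suite.

## Hertz modulus

Closed-form only: E = (1 − σ²)·π·f·R⁴/L³ with σ = 1/2 by default (exposed as
a parameter since it costs nothing). L is an image measurement, never the
Laplace-fit contact radius; the package warns if L exceeds w/2 (impossible
geometry). The inverse relation L(E) exists for fixture generation and
round-trip tests. Worst-case linear error propagation for 5 µm pointing
errors is |ΔE|/E = 4ΔR/R + 3ΔL/L ≈ 7.3% at the reference geometry
(R = 530 µm, L ≈ 429 µm). The modulus is physically meaningful only when the
spheroid radius is near the critical radius separating elastic- from
capillary-dominated flattening; that radius depends on material constants
not modelled here, so the package does not gate on it.

## Tension decomposition

T_CM = γ/(1 − cos(α/2)) and 2T_CC − J_CC = 2γ·cos(α/2)/(1 − cos(α/2)),
evaluated from the per-condition **mean** contact angle (a per-junction mode
is available by calling the function per angle). Angles are degrees at the
interface (180° = flat), radians internally. Only the combination
2T_CC − J_CC is identifiable; it is never split. α → 0 is rejected (both
tensions diverge). The angle dispersion sd(α) is reported but not propagated
into tension uncertainties by default. Note that for small α the two
tensions are individually large and nearly cancelling in the energy balance,
so that identity is verified to a tolerance scaled by T_CM, not γ.

## Roughness

Circle fit: Kåsa algebraic initialization refined by geometric
(Levenberg–Marquardt) least squares on (center, radius) — exact on noiseless
data, standard for noisy arcs; collinear inputs are rejected via an SVD rank
check. Rq = √(mean z_i²) with z_i the signed radial residuals, evaluated
only at the provided points. Rq as defined is sampling-weighted: non-uniform
manual pointing changes it slightly (the suite checks < 5% under midpoint
doubling); no resampling correction is applied.

## Dose–response

Unconstrained four-parameter Hill fit by Levenberg–Marquardt. The model is
evaluated at X = 0 through its analytic limit so zero-dose controls enter
the fit. Numerical choices: IC50 is carried internally as log IC50 — a
smooth reparameterization, not a bound, needed because (IC50/X)^n is
undefined for IC50 ≤ 0 at non-integer n mid-iteration; the optimizer is
started from data quartiles (plateaus from extreme-dose means, IC50 from the
dose bracketing the half response) with both slope signs tried. The
(Top, Bottom, slope) ↔ (Bottom, Top, −slope) gauge is canonicalized to
Top ≥ Bottom, with the covariance permuted accordingly. Parameter covariance
comes from the Jacobian at the optimum; se(IC50) by the delta method. Fits
with < 4 distinct doses or zero response variance are refused as
unidentifiable. Fitting is on linear concentration, as the model is written.

## Synthetic data

The generators emulate the experimental regime: R = 530 µm spheroids,
M_v = 250 A/m (range 150–500) in a 170 T/m gradient, reference condition
γ = 21 mN/m and E = 100 Pa, landmark pointing error 2–5 µm, blebbistatin-like
dose sets {0, 1, 3, 10, 30, 80, 160} µM with 10% relative Gaussian response
noise and n = 8 replicates per dose. The pointing-noise distribution is not
known beyond its magnitude, so it is modelled as uniform on ± the bound,
independently per landmark (stated in every fixture manifest). All
randomness flows from a single integer seed through
`numpy.random.default_rng`; identical seeds give byte-identical fixtures.

What the generator does **not** emulate: pixelation and optical blur of real
side-profile images, correlated pointing errors between landmarks, cell-scale
surface roughness on the Laplace profile, aggregate-to-aggregate variability
of M_v and R within a condition, and any deviation of real tissue from a
single-γ liquid at equilibrium. Passing tests therefore demonstrate
correctness and precision of the *analysis chain*, not of image acquisition
or segmentation.

## Problem sizes

The test and acceptance workloads are sized for interactive runs: 200 refits
for the tension-precision envelope, 100 simulated designs for the IC50
median, 100 Monte-Carlo seeds for the circle-fit bias check, and forward
profiles of ~3000 integration steps. Each forward integration costs ~1 ms
(numba-compiled) and a full landmark fit ~50 ms, so the entire suite runs in
well under a minute after JIT warm-up.

## Known limitations

- Equilibrium shapes only; no flattening dynamics or viscoelastic constants.
- The 180° contact condition is an idealization of "non-wetting"; partial
  wetting would need a contact-angle boundary condition the landmark data
  cannot constrain.
- f is uniform; real field gradients decay away from the magnet.
- The Laplace fit uses three landmarks, not the full contour (contour input
  is reduced to landmarks first, mirroring the measurement workflow).
- The Hill "±" uncertainties of the instrument literature may mix fit SE and
  replicate spread; this package reports fit SE (and the replicate spread is
  available from the fixture simulations).
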