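# Methods

## Model overview and assumptions

`axodyn` treats each growth cone as a point agent carrying ten state
variables, advanced by four coupled subsystems.  All variables are
dimensionless (concentrations, rates and lengths are rescaled); physical
units enter only through two conversion constants, the tubulin
polymerization velocity `v0` (μm/h) and the micropattern spatial period
`d` (μm).

**Traction.**  The clutch subsystem (`traction` module) assumes traction is
proportional to the product of actin and adhesion density, `F = k A C`,
actin turnover is linear, and adhesion assembly saturates in actin
(`A^2/(1+A^2)`).  The nonnegative orthant is forward-invariant, so
densities stay physical.  The steady states solve `C = alpha A` together
with `alpha beta A^2 - A + alpha beta = 0`; the quadratic is solved in the
cancellation-free form `A+ = (1 + sqrt(1-4(alpha beta)^2))/(2 alpha beta)`,
`A- = 1/A+` (the roots' product is exactly 1), avoiding loss of precision
at small `alpha beta`.  Equilibria are classified through the analytic
Jacobian `[[-alpha, 1], [2A/(1+A^2)^2, -beta]]`; finite differences serve
only as a cross-check in the tests.

**Heading.**  The torque is proportional to traction and to the substrate
stiffness anisotropy factor `(1-eps)`.  Two torque forms are provided and
this is deliberate: the polar form `-kappa sin(theta)` makes `theta = 0`
the only stable heading, while the nematic form `-kappa sin(2 theta)/2`
additionally stabilizes `theta = pi` and destabilizes `±pi/2`, which is
the fixed-point structure a groove that is symmetric under
`theta -> theta + pi` actually imposes.  Both linearize to
`-kappa theta` near alignment, so the stationary variance `D_theta/kappa`
and the lateral diffusion `D_eff = v D_theta/(2 kappa)` are form-independent
in the small-noise regime.  The default is the polar `sin` form; the choice
is a config switch, and the angular-variance observable has a matching
nematic folding option.

Note that the small-noise variance formula is the leading term of an
expansion: the exact stationary density of the `sin` form is
`p(theta) ∝ exp((kappa/D_theta) cos theta)`, whose second moment exceeds
`D_theta/kappa` by a relative `~(D_theta/kappa)/2` (2.5% at
`D_theta/kappa = 0.05`).  Stochastic tests therefore operate at
`D_theta/kappa <= 0.05`, where the correction sits inside a 3-standard-error
band at the sample sizes used.

**Lateral inhibition.**  The lattice couples only nearest neighbours
(filopodial reach), with periodic boundaries by default so the linear
analysis diagonalizes in Fourier modes; reflecting boundaries (missing
neighbour replaced by the cone's own ligand level) are available for
finite-array realism.  Two readings of the traction coupling are
implemented because the defining expression is ambiguous as typeset:
`production_suppressed` (default), `dS/dt = nu g(I) e^{-gamma F} - S`,
matches the intended biology — high-traction cones *emit fewer* repulsive
ligands — while `decay_scaled`, `dS/dt = nu g(I) - S e^{-gamma F}`, keeps
the literal operator order.  Both coincide at `gamma F = 0`.  Similarly the
control parameter `m = -f' g' e^{-gamma F}` is evaluated with `f'` at `S0`
and `g'` at `I0` by default (the arguments `f` and `g` receive in the
dynamics); the transposed convention is available behind a documented
switch.  As defined, `m >= 0` always, so the regime `m < -1` of the normal
form is not reachable from the lattice parameters; the normal form and the
lattice spectrum are therefore exposed as separate, individually testable
objects.

**Tubulin transport.**  Two well-mixed compartments exchange tubulin down
the concentration gradient, flux `phi = alpha_t (c0 - c1)/ell` from soma to
cone.  (With the opposite flux sign the gradient feeds back on itself:
`c1` diverges to minus infinity and every axon collapses, and no linear
solution with real speed exists — substituting `c0 = p + q t`,
`c1 = const`, `ell = v t` then requires `v^2 - alpha_t v + alpha_t = 0`,
complex for `alpha_t < 4`.  The down-gradient sign is the only convention
consistent with transient collapse followed by recovery and with an
attracting linear solution.)  The derivatives sum to 1 identically, so
`J = c0 + c1 + ell - t` is conserved exactly; every integration in the test
suite verifies `|ΔJ| < 1e-6`.

With the linear ansatz the attracting solution has
`v^2 = alpha_t (1 - v)`, i.e. `v = (sqrt(alpha_t(alpha_t+4)) - alpha_t)/2`
— the same closed form as the calibration map `v(Lambda)` but evaluated at
the transport rate.  The package keeps both: `steady_speed(Lambda)` /
`invert_steady_speed(v)` implement the calibration convention
(`v = 1/3  <->  Lambda = 1/6 ≈ 0.17`), and `attracting_speed(params)`
reports what the long-time slope of `ell` actually follows.  The test suite
scans `alpha_t` at fixed `Lambda` and records the observed dependence: the
late-time speed tracks `alpha_t` and is insensitive to `Lambda`, which
controls only the transient (collapse versus immediate growth).  The
defaults `alpha_t = beta_t = 1/6`, `gamma_t = 1` make both conventions
agree at the calibrated point `v = 1/3` (10 μm/h at `v0 = 30` μm/h).

The transport terms are singular at `ell = 0`; integration stops at a floor
`ell = 1e-6` with a recorded collapse-termination event, since the model
does not define behaviour at zero length.

## Coupled ensemble simulator

The `simulate` module advances N cones (default 10) by explicit
Euler–Maruyama with `dt = 1e-3` dimensionless time.  The only stochastic
term is angular, amplitude `sqrt(2 D_theta)`; one master seed drives a
single `numpy` generator, so runs are bit-reproducible.  Coupling is
exactly as in the subsystem definitions: `F_i = k A_i C_i` enters the
ligand-emission damping and the torque scale `kappa_i`; the tip advances at
`max(dell_i/dt, 0)` along `(sin theta_i, cos theta_i)` (y is the groove
axis).  The axon length `ell` may retract while the tip holds position —
whether a collapsing tip retraces its path is not specified by the model,
and this choice keeps both quantities inspectable.  A cone that reaches the
length floor is terminated (state frozen, event recorded) while the rest of
the ensemble continues.  A first-step stability check warns when
`|drift| * dt > 0.1`.

Default initial-condition ranges — `A ~ U(0.5, 4)`, `C ~ U(0.1, 2)`,
`I, S ~ U(0, 1)`, `c0 = 1`, `c1 ~ U(0, 2 Lambda)`, `ell = 1`,
`theta ~ U(-pi/4, pi/4)` — deliberately straddle the traction separatrix
and the elongation threshold, so a default ensemble exercises both basins
and both tubulin regimes.  All ranges are exposed in `SimConfig`.  The
remaining coupling constants (`nu = 1`, `gamma`, `lambda = 1`,
`eps = 0.5`, `D_theta = 0.27`) are package choices: `a = 1` encodes a
pattern period matched to the growth-cone size, `eps = 0.5` a moderate
stiffness contrast, and `D_theta = 0.27` gives an aligned-ensemble angular
variance of `D_theta/kappa ≈ 0.1` at the bistable default's high-traction
force `F+ = 27/5`.

This synthetic ensemble emulates the geometry of parallel-groove cultures —
one cone per stripe, neighbour-only signaling, groove-aligned statistics.
It does not emulate stripe crossing, axon branching, fasciculation,
cone-cone contact, or measurement noise of image-based tracking; agreement
of tests on simulated data therefore validates the numerics and the
internal consistency of the model, not its fit to any particular culture.

The calibration inputs `v_exp = 10 μm/h`, `v0 = 30 μm/h` and
`D_eff = 25 μm²/h` are treated as inputs, not reproducible outputs.  As
printed, the lateral-diffusion relation `D_eff = v D_theta/(2 kappa)` and
the quoted `D_theta/kappa = 0.50` are mutually inconsistent
(`2 * 25/10 = 5`, not 0.5); the formula is implemented verbatim in
`effective_diffusion` and nothing in the package pins 0.50.

## Numerical choices

- Deterministic integration: adaptive Runge–Kutta (`scipy.solve_ivp`,
  RK45) at `rtol = 1e-9`, `atol = 1e-12`, chosen so equilibria and the
  conserved `J` are verified to ~1e-8 or better.
- Fixed-point search: hybrid Powell root solves from a seeded
  Latin-hypercube of 64 starts plus the box corners and center (boundary
  equilibria such as the origin are easily missed by space-filling samples
  alone); roots merged at `1e-6` Euclidean distance, accepted below
  residual `1e-9`.
- Hyperbolicity: eigenvalues with `|Re| < 1e-8` mark an equilibrium
  nonhyperbolic — needed exactly at the fold `alpha beta = 1/2` and the
  pitchfork `m = -1`.
- Separatrix: the saddle's stable manifold, grown by integrating the
  time-reversed field from `±1e-6` offsets along the stable eigenvector,
  arc-length parameterized via an augmented state and terminated by an
  arc-length event.
- Uniform-lattice spectrum: the dense `2N x 2N` Jacobian is
  block-diagonalized by the exact unitary DFT (off-block residue verified
  below `1e-10`), and each 2x2 block's eigenvalues come from the quadratic
  formula with sub-machine-noise entries snapped to zero.  A general
  eigensolver on the dense matrix perturbs the defective
  `cos(2 pi q/N) = 0` modes by ~`sqrt(eps) ≈ 1e-8`, which would mask the
  exact block structure the analysis rests on.
- Homogeneous signaling state: damped fixed-point iteration (damping 0.5)
  on the scalar map `S -> nu g(f(S)) e^{-gamma F}` to residual `1e-12`
  (the map is decreasing and bounded, so the fixed point is unique).
- Stationary statistics discard the first half of each run as burn-in;
  late-time speeds are least-squares slopes over the final 20% window.

## Problem sizes in the test suite

Stochastic checks use 10^4 independent heading trajectories (endpoint
sampled at 20 relaxation times, `dt = 0.01`) for the angular-variance law,
200–300 synthetic Brownian tracks for diffusion recovery, and ensembles of
3–10 coupled cones over 1–30 dimensionless time units elsewhere; the
conservation and regime laws are verified over 100 randomly drawn parameter
sets each.  These sizes keep every statistical band at three standard
errors while the full suite runs in well under a minute of CPU.

## Known limitations

- The coupled simulator is first-order (Euler–Maruyama) in `dt`; the
  convergence test asserts observed order ≥ 0.9 on deterministic runs.
- No spatial structure below the lattice: no reaction–diffusion transport
  of ligand, no beyond-nearest-neighbour coupling, no explicit
  Semaphorin/Slit kinetics.
- The pitchfork normal form is analyzed on its own terms; the lattice's
  `m` is nonnegative by construction, so the uniform-stable branch
  `m < -1` of the normal form has no lattice counterpart.
- Collapse below the length floor is a termination event, not a modelled
  regime.
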