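# axodyn

Dynamical-systems modelling of axonal growth on parallel micropatterned
substrates.

Cortical axons cultured on micropatterned PDMS surfaces align with the
grooves and extend at a remarkably constant speed. `axodyn` implements a
compact mechanistic model of this behaviour for computational
neuroscientists and biomaterials researchers: each growth cone is described
by four coupled subsystems, and an ensemble of cones on adjacent
micropatterns interacts through short-range inhibitory signaling.

## The model

**Traction (molecular clutch).** Polymerized actin `A` and adhesion-complex
density `C` obey

    dA/dt = -alpha A + C,        dC/dt = A^2/(1+A^2) - beta C,       F = k A C.

For `alpha*beta < 1/2` the system is bistable — a quiescent state at the
origin and a protrusive high-traction node coexist, separated by the stable
manifold of a saddle — and the two nontrivial equilibria annihilate in a
saddle-node bifurcation exactly at `alpha*beta = 1/2`.

**Heading.** The growth angle `theta` (from the groove axis) relaxes under a
traction-scaled torque with angular noise,

    dtheta/dt = -lambda (1-eps) F sin(theta) + eta(t),     <eta eta'> = 2 D_theta delta,

giving a restoring rate `kappa = lambda (1-eps) F` near the high-traction
node, a stationary angular variance `D_theta/kappa`, and a lateral effective
diffusion `D_eff = v D_theta / (2 kappa)`.

**Lateral inhibition.** Received inhibition `I_i` and emitted ligand `S_i`
per micropattern follow a Delta–Notch-style motif with nearest-neighbour
averaging and traction-suppressed emission,

    dI_i/dt = f((S_{i-1}+S_{i+1})/2) - I_i,      dS_i/dt = nu g(I_i) e^{-gamma F_i} - S_i,

with Hill responses `f(x) = x^2/(a+x^2)`, `g(x) = 1/(1+a x^2)`.  The
uniform state undergoes a supercritical pitchfork governed by
`m = -f' g' e^{-gamma F}` (normal form `dy/dt = (m+1) y - y^3`, threshold
`m = -1`, branches `y = ±sqrt(m+1)`).

**Tubulin transport.** Soma and growth-cone tubulin pools `c0, c1` exchange
down the gradient across a shaft of length `ell`; `dell/dt = gamma_t c1 -
beta_t` so the axon shrinks when `c1` is below `Lambda = beta_t/gamma_t`
and grows above it.  `J = c0 + c1 + ell - t` is conserved exactly, and all
surviving trajectories approach linear elongation; the closed-form speed
map `v(x) = (sqrt(x(x+4)) - x)/2` links the measured speed to the model
rates.

A stochastic Euler–Maruyama simulator couples all four subsystems for an
ensemble of N axons (default 10) and computes ensemble observables
(angular variance, mean speed in μm/h, lateral MSD slope, stripe
alternation amplitude, bundle spacing).

## Worked example

Calibrate the elongation threshold from a measured growth speed of
10 μm/h with a tubulin polymerization velocity of 30 μm/h:

```bash
$ axodyn calibrate --speed-um-per-h 10 --v0 30
{"v_dimensionless": 0.333, "lambda_exact": 0.16666666666666663, "lambda_rounded": 0.17}
```

The dimensionless speed 10/30 ≈ 0.333 inverts through the speed map to
`Lambda = v^2/(1-v) = 1/6 ≈ 0.17`.

Scan the elongation regimes of the transport model:

```bash
$ axodyn tubulin --lambdas 0.25,1,2 --out out/
Lambda=0.25: regime=growing, late speed 0.6180 (v(alpha_t)=0.6180, v(Lambda)=0.3904)
Lambda=1: regime=collapsing, late speed 0.6180 (v(alpha_t)=0.6180, v(Lambda)=0.6180)
Lambda=2: regime=collapsing, late speed 0.6180 (v(alpha_t)=0.6180, v(Lambda)=0.7321)
```

With `c1(0) = 0.5`, the `Lambda=0.25` axon grows monotonically from the
outset while `Lambda=2` retracts until `c1` crosses the threshold and then
grows; all runs converge to the same late-time speed, which follows the
closed form evaluated at the transport rate (see `docs/methods.md`).

In Python, the bistable traction phase portrait at `alpha=0.6, beta=0.5`:

```python
>>> from axodyn.traction import TractionParams, equilibria_analytic
>>> for fp in equilibria_analytic(TractionParams(0.6, 0.5)):
...     print(fp.state, fp.classification)
[0. 0.] stable node
[0.33333333 0.2       ] saddle
[3.  1.8] stable node
```

The saddle at (1/3, 1/5) separates the collapsed basin from the protrusive
one; initial conditions above its stable manifold reach the high-traction
node (3, 9/5), which carries traction `F = k A C = 27/5`.

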