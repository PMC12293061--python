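"""Actin–adhesion traction subsystem of the growth cone.

A two-variable molecular-clutch model: polymerized F-actin density ``A``
feeds adhesion (CAM point-contact complex) assembly ``C`` through a
saturating sigmoid, adhesions feed actin back linearly, and the traction
force transmitted to the substrate is ``F = k A C``.  The dynamics

    dA/dt = -alpha * A + C
    dC/dt = A^2 / (1 + A^2) - beta * C

is bistable for ``alpha * beta < 1/2``: a collapsed state at the origin and
a protrusive high-traction node coexist, separated by the stable manifold of
a saddle (the separatrix).  The two nontrivial equilibria annihilate in a
saddle-node bifurcation exactly at ``alpha * beta = 1/2``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .dynsys import (
    FixedPoint,
    VectorField,
    classify_eigenvalues,
    integrate,
    HYPERBOLICITY_TOL,
)

__all__ = [
    "TractionParams",
    "TractionState",
    "traction_rhs",
    "traction_force",
    "traction_jacobian",
    "traction_field",
    "critical_product",
    "equilibria_analytic",
    "nullclines",
    "separatrix",
    "classify_basin",
    "phase_portrait_table",
]


@dataclass(frozen=True)
class TractionParams:
    """Turnover rates and force constant of the clutch subsystem.

    alpha : actin turnover (retrograde-flow) rate, dimensionless
    beta  : adhesion turnover rate, dimensionless
    k     : force constant in F = k A C
    """

    alpha: float
    beta: float
    k: float = 1.0

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0 or self.k <= 0:
            raise ValueError("alpha, beta and k must be strictly positive")

    @property
    def product(self) -> float:
        return self.alpha * self.beta


class TractionState(NamedTuple):
    A: float
    C: float


def traction_rhs(state: Sequence[float], params: TractionParams) -> np.ndarray:
    """Time derivatives (dA/dt, dC/dt)."""
    a, c = state
    return np.array(
        [-params.alpha * a + c, a * a / (1.0 + a * a) - params.beta * c]
    )


def traction_force(state: Sequence[float], params: TractionParams) -> float:
    """Traction force F = k A C transmitted to the substrate."""
    a, c = state
    return params.k * a * c


def traction_jacobian(state: Sequence[float], params: TractionParams) -> np.ndarray:
    """Analytic Jacobian [[-alpha, 1], [2A/(1+A^2)^2, -beta]]."""
    a, _ = state
    return np.array(
        [
            [-params.alpha, 1.0],
            [2.0 * a / (1.0 + a * a) ** 2, -params.beta],
        ]
    )


def traction_field(params: TractionParams) -> VectorField:
    """The (A, C) dynamics packaged as a :class:`VectorField`."""
    return VectorField(
        dimension=2,
        rhs=lambda t, y: traction_rhs(y, params),
        parameters={"alpha": params.alpha, "beta": params.beta, "k": params.k},
        jacobian=lambda y: traction_jacobian(y, params),
    )


def critical_product() -> float:
    """Saddle-node threshold of the product alpha*beta.

    The nontrivial equilibria solve ``alpha*beta*A^2 - A + alpha*beta = 0``,
    whose discriminant ``1 - 4(alpha*beta)^2`` vanishes at alpha*beta = 1/2.
    """
    return 0.5


def equilibria_analytic(
    params: TractionParams, hyperbolicity_tol: float = HYPERBOLICITY_TOL
) -> list[FixedPoint]:
    """Closed-form equilibria of the clutch subsystem, classified.

    The origin always exists.  For ``alpha*beta < 1/2`` two further roots
    A- < A+ of ``ab*A^2 - A + ab = 0`` exist with ``C = alpha*A``; they are
    solved in the cancellation-free form A+ = (1 + sqrt(disc)) / (2 ab),
    A- = 1/A+ (the roots' product is 1).  At ``alpha*beta = 1/2`` the two
    coincide (nonhyperbolic); above it only the origin remains.
    Returned sorted by A.
    """
    ab = params.product
    states = [np.array([0.0, 0.0])]
    disc = 1.0 - 4.0 * ab * ab
    if disc >= 0.0:
        a_plus = (1.0 + np.sqrt(disc)) / (2.0 * ab)
        a_minus = 1.0 / a_plus
        if disc == 0.0:
            states.append(np.array([a_plus, params.alpha * a_plus]))
        else:
            states.append(np.array([a_minus, params.alpha * a_minus]))
            states.append(np.array([a_plus, params.alpha * a_plus]))

    out = []
    for s in states:
        jac = traction_jacobian(s, params)
        eigs = np.linalg.eigvals(jac)
        out.append(
            FixedPoint(
                state=s,
                eigenvalues=eigs,
                classification=classify_eigenvalues(eigs, hyperbolicity_tol),
                residual=float(np.linalg.norm(traction_rhs(s, params))),
            )
        )
    return out


def nullclines(
    params: TractionParams, a_grid: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """The two nullclines sampled on ``a_grid``.

    Returns ``(adot_zero, cdot_zero)``, each of shape ``(n, 2)`` with
    columns (A, C): the actin-balance line ``C = alpha*A`` and the
    adhesion-balance curve ``C = A^2 / (beta (1 + A^2))``.
    """
    a = np.asarray(a_grid, dtype=float)
    if np.any(np.diff(a) <= 0):
        raise ValueError("a_grid must be strictly increasing")
    adot_zero = np.column_stack([a, params.alpha * a])
    cdot_zero = np.column_stack([a, a * a / (params.beta * (1.0 + a * a))])
    return adot_zero, cdot_zero


def _saddle(params: TractionParams) -> FixedPoint:
    for fp in equilibria_analytic(params):
        if fp.classification == "saddle":
            return fp
    raise ValueError(
        f"no saddle exists: alpha*beta = {params.product} >= {critical_product()}"
    )


def separatrix(
    params: TractionParams,
    arc_length: float = 10.0,
    delta: float = 1e-6,
) -> np.ndarray:
    """Stable manifold of the saddle — the basin boundary in the (A, C) plane.

    Both branches are grown by integrating the time-reversed field from
    offsets ``±delta`` along the saddle's stable eigenvector, each until the
    accumulated arc length reaches ``arc_length``.  Returned as a single
    polyline of shape ``(n, 2)`` passing through the saddle.
    """
    if arc_length <= 0:
        raise ValueError("arc_length must be positive")
    saddle = _saddle(params)
    jac = traction_jacobian(saddle.state, params)
    eigvals, eigvecs = np.linalg.eig(jac)
    stable_dir = np.real(eigvecs[:, np.argmin(np.real(eigvals))])
    stable_dir = stable_dir / np.linalg.norm(stable_dir)

    def reversed_aug(t, y):
        v = -traction_rhs(y[:2], params)
        return np.array([v[0], v[1], np.linalg.norm(v)])

    aug = VectorField(dimension=3, rhs=reversed_aug)

    def hit_arc(t, y):
        return y[2] - arc_length

    hit_arc.terminal = True

    branches = []
    for sign in (+1.0, -1.0):
        y0 = np.array([*(saddle.state + sign * delta * stable_dir), 0.0])
        # generous time horizon; the arc-length event terminates the solve
        sol = integrate(aug, y0, (0.0, 1e4), events=hit_arc, rtol=1e-9, atol=1e-12)
        branches.append(sol.states[:, :2])

    return np.vstack([branches[0][::-1], saddle.state, branches[1]])


def classify_basin(
    initial: Sequence[float],
    params: TractionParams,
    horizon: float = 200.0,
    capture_tol: float = 1e-4,
) -> str:
    """Which attractor a nonnegative initial condition flows to.

    Forward-integrates until the trajectory comes within ``capture_tol`` of
    a stable equilibrium: the origin gives ``"collapsed"``, the
    high-traction node ``"protrusive"``.  If the horizon is exhausted first,
    ``"undecided"``.
    """
    initial = np.asarray(initial, dtype=float)
    if np.any(initial < 0):
        raise ValueError("initial state must be nonnegative")
    stable = [fp for fp in equilibria_analytic(params) if fp.is_stable]
    labels = {}
    for fp in stable:
        labels[tuple(fp.state)] = (
            "collapsed" if np.allclose(fp.state, 0.0) else "protrusive"
        )

    for fp in stable:
        if np.linalg.norm(initial - fp.state) <= capture_tol:
            return labels[tuple(fp.state)]

    events = []
    for fp in stable:
        target = fp.state.copy()

        def ev(t, y, target=target):
            return np.linalg.norm(y - target) - capture_tol

        ev.terminal = True
        events.append(ev)

    sol = integrate(
        traction_field(params), initial, (0.0, horizon), events=events, rtol=1e-9,
        atol=1e-12,
    )
    for fp, hits in zip(stable, sol.t_events):
        if hits.size:
            return labels[tuple(fp.state)]
    return "undecided"


def phase_portrait_table(
    params: TractionParams,
    a_grid: Sequence[float],
    c_grid: Sequence[float],
) -> pd.DataFrame:
    """Vector field sampled on a grid, as a tidy table (A, C, dA, dC)."""
    aa, cc = np.meshgrid(np.asarray(a_grid, float), np.asarray(c_grid, float))
    da = -params.alpha * aa + cc
    dc = aa**2 / (1.0 + aa**2) - params.beta * cc
    return pd.DataFrame(
        {"A": aa.ravel(), "C": cc.ravel(), "dA": da.ravel(), "dC": dc.ravel()}
    )
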