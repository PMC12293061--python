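"""Shared dynamical-systems machinery.

Deterministic integration, stochastic (Euler–Maruyama) stepping, multi-start
fixed-point location, Jacobians and eigenvalue classification.  Every
subsystem module builds on these primitives; none of them knows about axons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import optimize
from scipy.integrate import solve_ivp
from scipy.stats import qmc

__all__ = [
    "VectorField",
    "FixedPoint",
    "IntegrationError",
    "SdeError",
    "integrate",
    "find_fixed_points",
    "euler_maruyama",
    "finite_difference_jacobian",
    "classify_eigenvalues",
]

#: default adaptive-RK tolerances; equilibria downstream are verified to ~1e-8
DEFAULT_RTOL = 1e-9
DEFAULT_ATOL = 1e-12
#: |Re lambda| below this is treated as marginal (nonhyperbolic)
HYPERBOLICITY_TOL = 1e-8
#: fixed points closer than this (Euclidean) are merged
MERGE_TOL = 1e-6


class IntegrationError(RuntimeError):
    """Raised when an ODE integration leaves the finite domain.

    Carries ``last_valid_time``, the largest time at which the state was
    still finite.
    """

    def __init__(self, message: str, last_valid_time: float):
        super().__init__(message)
        self.last_valid_time = last_valid_time


class SdeError(RuntimeError):
    """Raised when an SDE trajectory becomes non-finite; carries ``step_index``."""

    def __init__(self, message: str, step_index: int):
        super().__init__(message)
        self.step_index = step_index


@dataclass(frozen=True)
class VectorField:
    """An autonomous (or weakly time-dependent) ODE right-hand side.

    Parameters
    ----------
    dimension:
        Number of state variables.
    rhs:
        Callable ``rhs(t, y) -> dy/dt`` returning an array of length
        ``dimension``.
    parameters:
        Named parameter values, kept for provenance only.
    jacobian:
        Optional analytic Jacobian ``jacobian(y) -> (dimension, dimension)``.
    """

    dimension: int
    rhs: Callable[[float, np.ndarray], np.ndarray]
    parameters: Mapping[str, float] = field(default_factory=dict)
    jacobian: Callable[[np.ndarray], np.ndarray] | None = None

    def __call__(self, t: float, y: np.ndarray) -> np.ndarray:
        out = np.asarray(self.rhs(t, np.asarray(y, dtype=float)), dtype=float)
        if out.shape != (self.dimension,):
            raise ValueError(
                f"rhs returned shape {out.shape}, expected ({self.dimension},)"
            )
        return out


@dataclass(frozen=True)
class FixedPoint:
    """A located equilibrium with its linearization.

    ``classification`` is one of ``stable node``, ``stable focus``,
    ``saddle``, ``unstable node``, ``unstable focus``, ``nonhyperbolic``.
    """

    state: np.ndarray
    eigenvalues: np.ndarray
    classification: str
    residual: float

    @property
    def is_stable(self) -> bool:
        return self.classification in ("stable node", "stable focus")


def classify_eigenvalues(
    eigenvalues: Sequence[complex], hyperbolicity_tol: float = HYPERBOLICITY_TOL
) -> str:
    """Classify an equilibrium from the real parts of its eigenvalues."""
    re = np.real(np.asarray(eigenvalues, dtype=complex))
    im = np.imag(np.asarray(eigenvalues, dtype=complex))
    if np.any(np.abs(re) < hyperbolicity_tol):
        return "nonhyperbolic"
    has_complex = np.any(np.abs(im) > hyperbolicity_tol)
    if np.all(re < 0):
        return "stable focus" if has_complex else "stable node"
    if np.all(re > 0):
        return "unstable focus" if has_complex else "unstable node"
    return "saddle"


def finite_difference_jacobian(
    fun: Callable[[np.ndarray], np.ndarray], x: np.ndarray, rel_step: float = 1e-6
) -> np.ndarray:
    """Central-difference Jacobian of ``fun`` at ``x``."""
    x = np.asarray(x, dtype=float)
    n = x.size
    f0 = np.asarray(fun(x), dtype=float)
    jac = np.empty((f0.size, n))
    for j in range(n):
        h = rel_step * (1.0 + abs(x[j]))
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        jac[:, j] = (np.asarray(fun(xp)) - np.asarray(fun(xm))) / (2.0 * h)
    return jac


def integrate(
    field: VectorField,
    initial: Sequence[float],
    t_span: tuple[float, float],
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    t_eval: Sequence[float] | None = None,
    events=None,
    method: str = "RK45",
):
    """Integrate ``field`` over ``t_span`` with adaptive error control.

    Returns the ``scipy`` solution object with ``sol.y`` transposed so the
    state series has shape ``(n_times, dimension)`` in ``sol.states``.

    Raises
    ------
    IntegrationError
        If the solver fails or the state leaves the finite domain; the
        exception carries the last valid time reached.
    """
    initial = np.asarray(initial, dtype=float)
    if initial.shape != (field.dimension,):
        raise ValueError(
            f"initial state has shape {initial.shape}, expected ({field.dimension},)"
        )
    t0, t1 = t_span
    if t0 == t1:
        raise ValueError("t_span must be nondegenerate")
    sol = solve_ivp(
        field,
        (t0, t1),
        initial,
        method=method,
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
        events=events,
        dense_output=False,
    )
    if not sol.success and sol.status == -1:
        last = sol.t[-1] if sol.t.size else t0
        raise IntegrationError(
            f"integration failed at t={last}: {sol.message}", last_valid_time=last
        )
    if sol.y.size and not np.all(np.isfinite(sol.y)):
        finite = np.all(np.isfinite(sol.y), axis=0)
        last = sol.t[finite][-1] if finite.any() else t0
        raise IntegrationError(
            "non-finite state encountered", last_valid_time=float(last)
        )
    sol.states = sol.y.T
    return sol


def find_fixed_points(
    field: VectorField,
    search_box: Sequence[tuple[float, float]],
    n_starts: int = 64,
    seed: int = 0,
    residual_tol: float = 1e-9,
    merge_tol: float = MERGE_TOL,
    hyperbolicity_tol: float = HYPERBOLICITY_TOL,
) -> list[FixedPoint]:
    """Locate equilibria by multi-start root finding.

    Starts a hybrid Powell root solve from a seeded Latin-hypercube of
    ``n_starts`` points in ``search_box``, keeps converged roots inside the
    box with residual below ``residual_tol``, deduplicates to ``merge_tol``
    and classifies each root through its Jacobian eigenvalues (analytic if
    the field carries one, central differences otherwise).

    An empty list means no equilibrium was found in the box.
    """
    box = np.asarray(search_box, dtype=float)
    if box.shape != (field.dimension, 2):
        raise ValueError("search_box must give one (lo, hi) interval per dimension")
    if np.any(box[:, 1] <= box[:, 0]):
        raise ValueError("search_box intervals must be nondegenerate")

    fun = lambda y: field(0.0, y)
    sampler = qmc.LatinHypercube(d=field.dimension, seed=seed)
    starts = qmc.scale(sampler.random(n_starts), box[:, 0], box[:, 1])
    # deterministic extras: box corners and center (roots on the boundary,
    # e.g. an equilibrium at the origin, are easily missed by space-filling
    # samples in a large box)
    corners = np.stack(np.meshgrid(*box, indexing="ij"), axis=-1).reshape(-1, field.dimension)
    starts = np.vstack([starts, corners, box.mean(axis=1)[None, :]])

    roots: list[np.ndarray] = []
    for x0 in starts:
        res = optimize.root(fun, x0, method="hybr", tol=1e-12)
        if not res.success:
            continue
        x = res.x
        # allow a whisker outside the box so boundary equilibria survive
        pad = merge_tol * (1.0 + np.abs(box).max())
        if np.any(x < box[:, 0] - pad) or np.any(x > box[:, 1] + pad):
            continue
        if np.linalg.norm(fun(x)) > residual_tol:
            continue
        if all(np.linalg.norm(x - r) > merge_tol for r in roots):
            roots.append(x)

    roots.sort(key=lambda r: tuple(np.round(r, 9)))
    out = []
    for x in roots:
        jac = (
            field.jacobian(x)
            if field.jacobian is not None
            else finite_difference_jacobian(fun, x)
        )
        eigs = np.linalg.eigvals(np.asarray(jac, dtype=float))
        out.append(
            FixedPoint(
                state=x,
                eigenvalues=eigs,
                classification=classify_eigenvalues(eigs, hyperbolicity_tol),
                residual=float(np.linalg.norm(fun(x))),
            )
        )
    return out


def euler_maruyama(
    drift: VectorField,
    noise_amplitudes: Sequence[float],
    initial: Sequence[float],
    dt: float,
    n_steps: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Explicit Euler–Maruyama integration of an Itô SDE.

    Update rule: ``X_{n+1} = X_n + f(t_n, X_n) dt + sigma * sqrt(dt) * Z_n``
    with ``Z_n`` i.i.d. standard normal from a seeded generator, so an
    identical seed reproduces the trajectory bit-for-bit.

    Returns an array of shape ``(n_steps + 1, dimension)``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    sigma = np.asarray(noise_amplitudes, dtype=float)
    x = np.asarray(initial, dtype=float)
    if sigma.shape != x.shape or x.shape != (drift.dimension,):
        raise ValueError("initial state and noise amplitudes must match the drift dimension")
    if np.any(sigma < 0):
        raise ValueError("noise amplitudes must be nonnegative")
    if rng is None:
        rng = np.random.default_rng(seed)

    sqrt_dt = np.sqrt(dt)
    out = np.empty((n_steps + 1, x.size))
    out[0] = x
    for n in range(n_steps):
        z = rng.standard_normal(x.size)
        x = x + drift(n * dt, x) * dt + sigma * sqrt_dt * z
        if not np.all(np.isfinite(x)):
            raise SdeError(f"non-finite state at step {n + 1}", step_index=n + 1)
        out[n + 1] = x
    return out
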