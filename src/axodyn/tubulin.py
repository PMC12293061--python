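"""Two-compartment tubulin transport and axonal elongation.

Scaled tubulin concentrations in the soma (``c0``) and growth cone (``c1``)
exchange down the concentration gradient across the axonal shaft of length
``ell`` (flux ``phi = alpha_t (c0 - c1) / ell``, soma to cone):

    dc0/dt = 1 - phi
    dc1/dt = -gamma_t c1 + beta_t + phi
    dell/dt = gamma_t c1 - beta_t

The three derivatives sum to 1 identically, so J(t) = c0 + c1 + ell - t is
conserved along every trajectory.  The sign of the elongation rate is set by
``c1`` against the threshold ``Lambda = beta_t / gamma_t``: below it the
axon transiently collapses, above it it grows.  Every surviving trajectory
is attracted to a linearly elongating state; the closed-form speed map

    v(x) = (sqrt(x (x + 4)) - x) / 2,    inverse  x = v^2 / (1 - v)

is exposed through :func:`steady_speed` (argument Lambda, the calibration
convention) and :func:`attracting_speed` (argument alpha_t, which is what
the long-time slope of ``ell`` actually follows numerically — substituting
the linear ansatz into the equations gives ``v^2 = alpha_t (1 - v)``).  The
default parameters set ``alpha_t = Lambda = 1/6`` so the two coincide at
the calibrated speed v = 1/3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .dynsys import VectorField, integrate

__all__ = [
    "TubulinParams",
    "TubulinState",
    "TubulinTrajectory",
    "ELL_FLOOR",
    "tubulin_rhs",
    "tubulin_field",
    "conserved_J",
    "steady_speed",
    "invert_steady_speed",
    "attracting_speed",
    "classify_initial_regime",
    "integrate_tubulin",
]

#: the transport terms are singular at ell = 0; integration stops here instead
ELL_FLOOR = 1e-6


@dataclass(frozen=True)
class TubulinParams:
    """alpha_t: transport rate; beta_t: treadmilling offset; gamma_t:
    growth-cone consumption rate.  All dimensionless.  The defaults
    ``alpha_t = Lambda = beta_t / gamma_t = 1/6`` correspond to the
    calibrated dimensionless elongation speed v = 1/3."""

    alpha_t: float = 1.0 / 6.0
    beta_t: float = 1.0 / 6.0
    gamma_t: float = 1.0

    def __post_init__(self):
        if self.alpha_t <= 0 or self.gamma_t <= 0:
            raise ValueError("alpha_t and gamma_t must be strictly positive")
        if self.beta_t < 0:
            raise ValueError("beta_t must be nonnegative")

    @property
    def lambda_ratio(self) -> float:
        """Collapse/growth threshold Lambda = beta_t / gamma_t."""
        return self.beta_t / self.gamma_t


class TubulinState(NamedTuple):
    c0: float
    c1: float
    ell: float


def tubulin_rhs(state: Sequence[float], params: TubulinParams) -> np.ndarray:
    """Time derivatives (dc0/dt, dc1/dt, dell/dt); they sum to 1 exactly."""
    c0, c1, ell = state
    if ell <= 0:
        raise ValueError("ell must be positive (transport term singular at 0)")
    flux = params.alpha_t * (c0 - c1) / ell
    return np.array(
        [
            1.0 - flux,
            -params.gamma_t * c1 + params.beta_t + flux,
            params.gamma_t * c1 - params.beta_t,
        ]
    )


def tubulin_field(params: TubulinParams) -> VectorField:
    return VectorField(
        dimension=3,
        rhs=lambda t, y: tubulin_rhs(y, params),
        parameters={
            "alpha_t": params.alpha_t,
            "beta_t": params.beta_t,
            "gamma_t": params.gamma_t,
        },
    )


def conserved_J(state: Sequence[float], t: float) -> float:
    """The affine invariant J = c0 + c1 + ell - t (constant along flows)."""
    c0, c1, ell = state
    return c0 + c1 + ell - t


def steady_speed(lambda_ratio: float) -> float:
    """Dimensionless long-time elongation speed v(Lambda), in [0, 1).

    v = (sqrt(Lambda^2 + 4 Lambda) - Lambda) / 2; strictly increasing,
    v(0) = 0 and v -> 1 as Lambda -> infinity.
    """
    lam = lambda_ratio
    if lam < 0:
        raise ValueError("lambda_ratio must be nonnegative")
    return (np.sqrt(lam * (lam + 4.0)) - lam) / 2.0


def invert_steady_speed(v: float) -> float:
    """The unique Lambda with steady_speed(Lambda) = v, for v in [0, 1).

    Closed form: Lambda = v^2 / (1 - v).
    """
    if not (0.0 <= v < 1.0):
        raise ValueError("v must lie in [0, 1)")
    return v * v / (1.0 - v)


def attracting_speed(params: TubulinParams) -> float:
    """Long-time elongation speed of the attracting linear solution.

    Substituting ``c0 = p + q t``, ``c1 = const``, ``ell = v t`` into the
    transport equations gives ``v^2 = alpha_t (1 - v)``, i.e. the same
    closed form as :func:`steady_speed` evaluated at the transport rate:
    ``v = (sqrt(alpha_t (alpha_t + 4)) - alpha_t) / 2``.  The threshold
    ``Lambda`` controls only the transient (collapse versus immediate
    growth), not the final speed.
    """
    return steady_speed(params.alpha_t)


def classify_initial_regime(
    state: Sequence[float], params: TubulinParams, tol: float = 1e-12
) -> str:
    """Sign of the initial elongation rate relative to the threshold.

    ``c1 < Lambda`` -> "collapsing"; ``c1 > Lambda`` -> "growing";
    within ``tol`` of the threshold -> "marginal".
    """
    _, c1, _ = state
    lam = params.lambda_ratio
    if abs(c1 - lam) < tol:
        return "marginal"
    return "collapsing" if c1 < lam else "growing"


@dataclass
class TubulinTrajectory:
    """Integrated tubulin trajectory with regime and speed annotations.

    ``late_speed`` is the linear-fit slope of ell over the final 20% of the
    time window; ``collapse_time`` is set if ell hit the floor.
    """

    t: np.ndarray
    states: np.ndarray  # shape (n, 3): columns c0, c1, ell
    params: TubulinParams
    initial_regime: str
    late_speed: float
    collapse_time: float | None = None

    @property
    def J(self) -> np.ndarray:
        return self.states.sum(axis=1) - self.t

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.t,
                "c0": self.states[:, 0],
                "c1": self.states[:, 1],
                "ell": self.states[:, 2],
                "J": self.J,
            }
        )


def integrate_tubulin(
    initial: Sequence[float],
    params: TubulinParams,
    t_end: float,
    n_samples: int = 1001,
    ell_floor: float = ELL_FLOOR,
    late_window: float = 0.2,
) -> TubulinTrajectory:
    """Integrate the transport model and annotate the outcome.

    Stops with a recorded ``collapse_time`` if ``ell`` reaches
    ``ell_floor``.  The late-time elongation rate is the least-squares slope
    of ``ell`` over the final ``late_window`` fraction of the realized time
    span.
    """
    initial = np.asarray(initial, dtype=float)
    if initial[2] < ell_floor:
        raise ValueError(f"initial ell must be >= ell_floor = {ell_floor}")
    if t_end <= 0:
        raise ValueError("t_end must be positive")

    def hit_floor(t, y):
        return y[2] - ell_floor

    hit_floor.terminal = True
    hit_floor.direction = -1

    sol = integrate(
        tubulin_field(params),
        initial,
        (0.0, t_end),
        t_eval=np.linspace(0.0, t_end, n_samples),
        events=hit_floor,
    )
    collapse_time = float(sol.t_events[0][0]) if sol.t_events[0].size else None

    t, states = sol.t, sol.states
    n_tail = max(int(np.ceil(late_window * len(t))), 2)
    slope = float(np.polyfit(t[-n_tail:], states[-n_tail:, 2], 1)[0])

    return TubulinTrajectory(
        t=t,
        states=states,
        params=params,
        initial_regime=classify_initial_regime(initial, params),
        late_speed=slope,
        collapse_time=collapse_time,
    )
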