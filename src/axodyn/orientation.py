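"""Growth-cone heading dynamics on an anisotropic substrate.

The growth angle ``theta`` (radians from the groove axis) relaxes under a
traction-scaled aligning torque and diffuses under angular noise:

    dtheta/dt = -lambda (1 - eps) F sin(theta) + eta(t),
    <eta(t) eta(t')> = 2 D_theta delta(t - t')

Near a high-traction node with force ``F+`` this is ``-kappa sin(theta)``
with restoring rate ``kappa = lambda (1 - eps) F+``; small-noise stochastic
averaging gives the stationary angular variance ``D_theta / kappa`` and a
lateral effective diffusion ``D_eff = v D_theta / (2 kappa)`` for a cone
advancing at mean speed ``v``.

Two torque forms are provided.  ``sin`` is the printed law (theta = 0
stable, theta = pi unstable).  ``sin2`` is the nematic variant
``-kappa sin(2 theta)/2`` whose fixed-point structure (0 and pi stable,
+-pi/2 unstable) matches the stability statement accompanying the model;
both linearize to ``-kappa theta`` near alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OrientationParams",
    "wrap_angle",
    "kappa",
    "orientation_drift",
    "stationary_variance",
    "effective_diffusion",
    "simulate_orientation",
]

TORQUE_FORMS = ("sin", "sin2")


@dataclass(frozen=True)
class OrientationParams:
    """lam: torque coefficient; eps: stiffness anisotropy in [0, 1);
    d_theta: angular diffusion coefficient; torque_form: 'sin' or 'sin2'."""

    lam: float = 1.0
    eps: float = 0.0
    d_theta: float = 0.0
    torque_form: str = "sin"

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if not (0.0 <= self.eps < 1.0):
            raise ValueError("eps must lie in [0, 1)")
        if self.d_theta < 0:
            raise ValueError("d_theta must be nonnegative")
        if self.torque_form not in TORQUE_FORMS:
            raise ValueError(f"torque_form must be one of {TORQUE_FORMS}")


def wrap_angle(theta):
    """Wrap angles to the interval (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(theta, dtype=float), 2.0 * np.pi)


def kappa(params: OrientationParams, force: float) -> float:
    """Deterministic restoring rate kappa = lam (1 - eps) F."""
    if force < 0:
        raise ValueError("force must be nonnegative")
    return params.lam * (1.0 - params.eps) * force


def orientation_drift(theta, kappa_value: float, torque_form: str = "sin"):
    """Deterministic angular drift for the chosen torque form.

    ``sin``  -> -kappa sin(theta)
    ``sin2`` -> -kappa sin(2 theta)/2  (same linearization -kappa*theta at 0)
    """
    theta = np.asarray(theta, dtype=float)
    if torque_form == "sin":
        return -kappa_value * np.sin(theta)
    if torque_form == "sin2":
        return -kappa_value * np.sin(2.0 * theta) / 2.0
    raise ValueError(f"unknown torque_form {torque_form!r}")


def stationary_variance(kappa_value: float, d_theta: float) -> float:
    """Small-noise stationary variance of the heading, D_theta / kappa."""
    if kappa_value <= 0:
        raise ValueError("kappa must be positive (no restoring torque otherwise)")
    if d_theta < 0:
        raise ValueError("d_theta must be nonnegative")
    return d_theta / kappa_value


def effective_diffusion(
    mean_speed: float, kappa_value: float, d_theta: float
) -> float:
    """Lateral effective diffusion D_eff = v * D_theta / (2 kappa)."""
    if kappa_value <= 0:
        raise ValueError("kappa must be positive")
    if mean_speed < 0 or d_theta < 0:
        raise ValueError("mean_speed and d_theta must be nonnegative")
    return mean_speed * d_theta / (2.0 * kappa_value)


def simulate_orientation(
    theta0,
    kappa_value: float,
    params: OrientationParams,
    dt: float,
    n_steps: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Euler–Maruyama simulation of the heading SDE, wrapped each step.

    ``theta0`` may be a scalar or an array of initial angles; an array runs
    that many independent paths in lockstep from one seeded generator.
    Noise amplitude is ``sqrt(2 D_theta)``.  Returns shape
    ``(n_steps + 1,) + shape(theta0)``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    theta = wrap_angle(np.asarray(theta0, dtype=float))
    scalar = theta.ndim == 0
    theta = np.atleast_1d(theta)
    amp = np.sqrt(2.0 * params.d_theta * dt)
    out = np.empty((n_steps + 1, theta.size))
    out[0] = theta
    for n in range(n_steps):
        drift = orientation_drift(theta, kappa_value, params.torque_form)
        theta = wrap_angle(theta + drift * dt + amp * rng.standard_normal(theta.size))
        out[n + 1] = theta
    return out[:, 0] if scalar else out
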