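"""Quantitative summaries of simulated axon ensembles.

Angular variance about the groove axis (compared against the stationary
prediction D_theta / kappa), mean elongation speed in dimensionless and
physical units, lateral mean-squared displacement and its effective
diffusion coefficient, and the lattice pattern observables (alternation
amplitude and bundle spacing).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .orientation import wrap_angle

__all__ = [
    "SummaryStats",
    "angular_variance",
    "mean_speed",
    "lateral_msd_deff",
    "alternation_amplitude",
    "bundle_spacing",
    "summarize",
]


@dataclass(frozen=True)
class SummaryStats:
    """Observables of one ensemble run; physical speed is dimensionless
    speed times the tubulin polymerization velocity v0 (um/h)."""

    angular_variance: float
    mean_speed_dimensionless: float
    mean_speed_um_per_h: float
    deff: float | None
    alternation_amplitude: float
    bundle_spacing_um: float | None

    def to_dict(self) -> dict:
        return asdict(self)


def _fold_nematic(theta: np.ndarray) -> np.ndarray:
    """Fold angles into (-pi/2, pi/2] (theta and theta+pi identified)."""
    return np.pi / 2 - np.mod(np.pi / 2 - theta, np.pi)


def angular_variance(
    traj,
    burn_in_fraction: float = 0.5,
    convention: str = "polar",
) -> float:
    """Pooled second moment of the heading about the groove axis.

    Wrapped deviations over all cones and all post-burn-in sample times.
    ``convention="polar"`` keeps theta and theta+pi distinct (the default);
    ``"nematic"`` folds them together.
    """
    if not 0.0 <= burn_in_fraction < 1.0:
        raise ValueError("burn_in_fraction must lie in [0, 1)")
    theta = np.asarray(traj if isinstance(traj, np.ndarray) else traj.values("theta"))
    start = int(np.floor(burn_in_fraction * theta.shape[0]))
    window = theta[start:]
    if window.shape[0] < 2:
        raise ValueError("fewer than 2 post-burn-in time samples")
    dev = wrap_angle(window)
    if convention == "nematic":
        dev = _fold_nematic(dev)
    elif convention != "polar":
        raise ValueError("convention must be 'polar' or 'nematic'")
    return float(np.mean(dev**2))


def mean_speed(
    traj, window_fraction: float = 0.2, v0: float | None = None
) -> tuple[float, float]:
    """Late-time elongation speed (dimensionless, um/h).

    Least-squares slope of the cone-averaged axon length over the final
    ``window_fraction`` of the sampled times, converted to physical units
    with ``v0`` (taken from the run config when not given).
    """
    if not 0.0 < window_fraction <= 1.0:
        raise ValueError("window_fraction must lie in (0, 1]")
    times = np.asarray(traj.times)
    ell = np.asarray(traj.values("ell")).mean(axis=1)
    n_tail = max(int(np.ceil(window_fraction * times.size)), 2)
    slope = float(np.polyfit(times[-n_tail:], ell[-n_tail:], 1)[0])
    if v0 is None:
        v0 = traj.config.v0_um_per_h
    return slope, slope * v0


def lateral_msd_deff(traj, burn_in_fraction: float = 0.0) -> float | None:
    """Effective lateral diffusion coefficient from the MSD slope.

    Computes the cone-averaged squared lateral displacement from the first
    post-burn-in sample and returns half the least-squares slope of MSD
    versus time; ``None`` when the fit is degenerate (fewer than two
    distinct times).
    """
    times = np.asarray(traj.times, dtype=float)
    x = np.asarray(traj.values("x"), dtype=float)
    start = int(np.floor(burn_in_fraction * times.size))
    t = times[start:] - times[start]
    if t.size < 2 or np.ptp(t) == 0:
        return None
    disp = x[start:] - x[start]
    msd = np.mean(disp**2, axis=1) if disp.ndim == 2 else disp**2
    slope = float(np.polyfit(t, msd, 1)[0])
    return slope / 2.0


def alternation_amplitude(S: Sequence[float]) -> float:
    """Amplitude of the alternating (period-2) mode of a lattice profile.

    ``|(1/N) sum_i (-1)^i (S_i - mean(S))|`` — the order parameter of the
    stripe-selection pitchfork.
    """
    S = np.asarray(S, dtype=float)
    if S.size < 2:
        raise ValueError("need at least 2 lattice sites")
    signs = np.where(np.arange(S.size) % 2 == 0, 1.0, -1.0)
    return float(abs(np.mean(signs * (S - S.mean()))))


def bundle_spacing(S: Sequence[float], spatial_period_d: float) -> float | None:
    """Mean peak-to-peak distance of lattice maxima, in micrometres.

    Local maxima are found with periodic wrap-around; spacing is averaged
    over consecutive peaks (including the wrap) and multiplied by the
    pattern period ``d``.  Returns ``None`` with fewer than two maxima;
    a perfect alternating profile gives ``2 d``.
    """
    if spatial_period_d <= 0:
        raise ValueError("spatial_period_d must be positive")
    S = np.asarray(S, dtype=float)
    n = S.size
    if n < 2:
        return None
    peaks = [
        i for i in range(n) if S[i] > S[(i - 1) % n] and S[i] > S[(i + 1) % n]
    ]
    if len(peaks) < 2:
        return None
    gaps = np.diff(peaks + [peaks[0] + n])
    return float(np.mean(gaps) * spatial_period_d)


def summarize(traj, burn_in_fraction: float = 0.5) -> SummaryStats:
    """All observables of an :class:`EnsembleTrajectory` in one record."""
    slope, physical = mean_speed(traj)
    final_S = np.asarray(traj.values("S"))[-1]
    return SummaryStats(
        angular_variance=angular_variance(traj, burn_in_fraction),
        mean_speed_dimensionless=slope,
        mean_speed_um_per_h=physical,
        deff=lateral_msd_deff(traj, burn_in_fraction),
        alternation_amplitude=alternation_amplitude(final_S),
        bundle_spacing_um=bundle_spacing(final_S, traj.config.spatial_period_d_um),
    )
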