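"""Coupled stochastic simulation of N axons on parallel micropatterns.

Each growth cone carries ten state variables: traction (A, C), signaling
(I, S), tubulin transport (c0, c1, ell), heading theta and tip position
(x, y).  The subsystems are coupled through the traction force
``F_i = k A_i C_i``, which damps ligand emission and scales the aligning
torque ``kappa_i = lam (1 - eps) F_i``; elongation speed comes from the
tubulin subsystem (``dell/dt``, clipped at zero for tip advance) and the
tip moves along ``(sin theta, cos theta)`` — y is the groove direction.

Integration is explicit Euler–Maruyama: the only noise is angular, with
amplitude ``sqrt(2 D_theta)``.  A master seed makes runs bit-reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .inhibition import InhibitionParams, inhibition_rhs
from .orientation import OrientationParams, orientation_drift, wrap_angle
from .traction import TractionParams
from .tubulin import ELL_FLOOR, TubulinParams

__all__ = ["SimConfig", "EnsembleTrajectory", "COLUMNS", "step", "run_ensemble"]

#: per-cone state layout (and CSV column order after time, cone_id and F)
VAR_NAMES = ("A", "C", "I", "S", "c0", "c1", "ell", "theta", "x", "y")
COLUMNS = ("time", "cone_id", "A", "C", "F", "I", "S", "c0", "c1", "ell", "theta", "x", "y")

_IDX = {name: i for i, name in enumerate(VAR_NAMES)}


@dataclass(frozen=True)
class SimConfig:
    """Full configuration of a coupled ensemble run.

    Initial conditions are drawn uniformly from the configured ranges
    (``c0`` starts at a fixed value); the defaults straddle the traction
    separatrix and both tubulin regimes.  ``spatial_period_d_um`` and
    ``v0_um_per_h`` only convert dimensionless output to physical units.
    """

    n_cones: int = 10
    dt: float = 1e-3
    t_end: float = 20.0
    seed: int = 0
    spatial_period_d_um: float = 3.0
    v0_um_per_h: float = 30.0
    sample_stride: int = 100
    boundary: str = "periodic"
    traction: TractionParams = field(default_factory=lambda: TractionParams(0.6, 0.5, 1.0))
    orientation: OrientationParams = field(
        default_factory=lambda: OrientationParams(lam=1.0, eps=0.5, d_theta=0.27)
    )
    inhibition: InhibitionParams = field(default_factory=InhibitionParams)
    tubulin: TubulinParams = field(default_factory=TubulinParams)
    a_range: tuple[float, float] = (0.5, 4.0)
    c_range: tuple[float, float] = (0.1, 2.0)
    i_range: tuple[float, float] = (0.0, 1.0)
    s_range: tuple[float, float] = (0.0, 1.0)
    c0_init: float = 1.0
    c1_range: tuple[float, float] | None = None  # default (0, 2*Lambda)
    ell_init: float = 1.0
    theta_range: tuple[float, float] = (-np.pi / 4, np.pi / 4)
    ell_floor: float = ELL_FLOOR

    def __post_init__(self):
        if self.n_cones < 3:
            raise ValueError("n_cones must be at least 3")
        if self.dt <= 0 or self.t_end <= 0:
            raise ValueError("dt and t_end must be positive")
        if self.sample_stride < 1:
            raise ValueError("sample_stride must be >= 1")
        if self.inhibition.n_cones != self.n_cones or self.inhibition.boundary != self.boundary:
            object.__setattr__(
                self,
                "inhibition",
                InhibitionParams(
                    a=self.inhibition.a,
                    nu=self.inhibition.nu,
                    gamma=self.inhibition.gamma,
                    n_cones=self.n_cones,
                    coupling_reading=self.inhibition.coupling_reading,
                    boundary=self.boundary,
                ),
            )

    def draw_initial(self, rng: np.random.Generator) -> np.ndarray:
        """Initial (n_cones, 10) state matrix from the configured ranges."""
        n = self.n_cones
        states = np.empty((n, len(VAR_NAMES)))
        states[:, _IDX["A"]] = rng.uniform(*self.a_range, n)
        states[:, _IDX["C"]] = rng.uniform(*self.c_range, n)
        states[:, _IDX["I"]] = rng.uniform(*self.i_range, n)
        states[:, _IDX["S"]] = rng.uniform(*self.s_range, n)
        states[:, _IDX["c0"]] = self.c0_init
        c1_range = self.c1_range or (0.0, 2.0 * self.tubulin.lambda_ratio)
        states[:, _IDX["c1"]] = rng.uniform(*c1_range, n)
        states[:, _IDX["ell"]] = self.ell_init
        states[:, _IDX["theta"]] = rng.uniform(*self.theta_range, n)
        states[:, _IDX["x"]] = np.arange(n) * self.spatial_period_d_um
        states[:, _IDX["y"]] = 0.0
        return states


def _drift(states: np.ndarray, config: SimConfig) -> np.ndarray:
    """Deterministic part of the coupled update, per cone (n, 10)."""
    tp, op, ip, tup = (
        config.traction,
        config.orientation,
        config.inhibition,
        config.tubulin,
    )
    A, C = states[:, 0], states[:, 1]
    I, S = states[:, 2], states[:, 3]
    c0, c1, ell = states[:, 4], states[:, 5], states[:, 6]
    theta = states[:, 7]

    F = tp.k * A * C
    d = np.empty_like(states)
    d[:, 0] = -tp.alpha * A + C
    d[:, 1] = A * A / (1.0 + A * A) - tp.beta * C
    d[:, 2], d[:, 3] = inhibition_rhs((I, S), F, ip)
    flux = tup.alpha_t * (c0 - c1) / ell
    d[:, 4] = 1.0 - flux
    d[:, 5] = -tup.gamma_t * c1 + tup.beta_t + flux
    d[:, 6] = tup.gamma_t * c1 - tup.beta_t
    kappa_i = op.lam * (1.0 - op.eps) * F
    d[:, 7] = orientation_drift(theta, 1.0, op.torque_form) * kappa_i
    speed = np.maximum(d[:, 6], 0.0)
    d[:, 8] = speed * np.sin(theta)
    d[:, 9] = speed * np.cos(theta)
    return d


def step(
    states: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """One Euler–Maruyama step of the full coupled system.

    Returns the updated (n_cones, 10) state matrix; ``ell`` is floored at
    ``config.ell_floor`` (collapse bookkeeping is done by the caller).
    """
    dt = config.dt
    d = _drift(states, config)
    new = states + d * dt
    noise = np.sqrt(2.0 * config.orientation.d_theta * dt)
    new[:, _IDX["theta"]] = wrap_angle(
        new[:, _IDX["theta"]] + noise * rng.standard_normal(states.shape[0])
    )
    new[:, _IDX["ell"]] = np.maximum(new[:, _IDX["ell"]], config.ell_floor)
    return new


@dataclass
class EnsembleTrajectory:
    """Rectangular sampled output of a coupled run.

    ``data`` has shape (n_times, n_cones, 10) in VAR_NAMES order;
    ``collapse_events`` maps cone index -> first time ell hit the floor.
    """

    times: np.ndarray
    data: np.ndarray
    config: SimConfig
    seed: int
    collapse_events: dict[int, float] = field(default_factory=dict)

    def values(self, name: str) -> np.ndarray:
        """Time series of one variable, shape (n_times, n_cones)."""
        return self.data[:, :, _IDX[name]]

    def to_dataframe(self) -> pd.DataFrame:
        t_col, cone_col, rows = [], [], []
        n = self.config.n_cones
        for j, t in enumerate(self.times):
            t_col.append(np.full(n, t))
            cone_col.append(np.arange(n))
            rows.append(self.data[j])
        block = np.vstack(rows)
        df = pd.DataFrame(block, columns=list(VAR_NAMES))
        df.insert(0, "cone_id", np.concatenate(cone_col))
        df.insert(0, "time", np.concatenate(t_col))
        df.insert(2, "F", self.config.traction.k * df["A"] * df["C"])
        return df[list(COLUMNS)]

    def summary(self) -> dict:
        from . import observables

        stats = observables.summarize(self)
        return {
            "seed": self.seed,
            "config": _config_dict(self.config),
            "collapse_events": {str(k): v for k, v in self.collapse_events.items()},
            "final_state": {
                str(i): dict(zip(VAR_NAMES, self.data[-1, i]))
                for i in range(self.config.n_cones)
            },
            "observables": stats.to_dict(),
        }

    def save(self, out_dir: str | Path, stem: str = "ensemble") -> tuple[Path, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        csv_path = out_dir / f"{stem}_trajectories.csv"
        json_path = out_dir / f"{stem}_summary.json"
        self.to_dataframe().to_csv(csv_path, index=False)
        json_path.write_text(json.dumps(self.summary(), indent=2, default=float))
        return csv_path, json_path


def _config_dict(config: SimConfig) -> dict:
    d = asdict(config)
    for key in ("theta_range", "a_range", "c_range", "i_range", "s_range", "c1_range"):
        if d[key] is not None:
            d[key] = list(d[key])
    return d


def run_ensemble(config: SimConfig) -> EnsembleTrajectory:
    """Integrate the full coupled ensemble to ``t_end``.

    A first-step stability check warns if ``|drift| * dt`` exceeds 0.1
    anywhere.  A cone whose axon hits the length floor is recorded as a
    collapse event and terminated (its state frozen); the rest of the
    ensemble continues.
    """
    rng = np.random.default_rng(config.seed)
    states = config.draw_initial(rng)

    d0 = np.abs(_drift(states, config)) * config.dt
    if d0.max() > 0.1:
        warnings.warn(
            f"first-step drift*dt = {d0.max():.3g} exceeds 0.1; consider a smaller dt",
            RuntimeWarning,
        )

    n_steps = int(round(config.t_end / config.dt))
    sample_idx = range(0, n_steps + 1, config.sample_stride)
    times, samples = [], []
    collapse_events: dict[int, float] = {}
    frozen: dict[int, np.ndarray] = {}  # terminated cones keep their last state

    for n in range(n_steps + 1):
        if n > 0:
            states = step(states, config, rng)
            for i, row in frozen.items():
                states[i] = row
            at_floor = states[:, _IDX["ell"]] <= config.ell_floor
            for i in np.nonzero(at_floor)[0]:
                i = int(i)
                if i not in collapse_events:
                    collapse_events[i] = n * config.dt
                    frozen[i] = states[i].copy()
        if n in sample_idx:
            times.append(n * config.dt)
            samples.append(states.copy())

    return EnsembleTrajectory(
        times=np.array(times),
        data=np.stack(samples),
        config=config,
        seed=config.seed,
        collapse_events=collapse_events,
    )
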