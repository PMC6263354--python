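"""Dynamic simulation of gate netlists driven by time-varying sensors.

Each gate output y follows first-order on/off kinetics,

    dy/dt = alpha * f(x(t)) - gamma * (y - y_min),

where f is the x-dependent part of the gate's steady-state response
(so with alpha = gamma the fixed point is exactly the static response),
alpha is the ON rate and gamma the OFF rate, both 1/h.  Sensor inputs are
sampled time courses with linear interpolation between samples and
constant-hold extrapolation beyond either end.  The system is integrated
with a fixed-step explicit Euler scheme (dt = 0.025 h over 27 h by
default, mirroring the discrete solution the circuit models were built
with); a classic RK4 stepper is available to verify step-size adequacy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .circuits import Circuit, CircuitError
from .gates import Gate

__all__ = [
    "TimeCourse",
    "SimConfig",
    "interpolate",
    "gate_rhs",
    "steady_state_init",
    "simulate",
]


@dataclass(frozen=True)
class TimeCourse:
    """A sampled trajectory: strictly ascending times (hours) and values."""

    times: np.ndarray
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be matching 1-D arrays")
        if len(t) < 2:
            raise ValueError("a time course needs at least 2 samples")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def at(self, t):
        """Piecewise-linear value at ``t``; terminal values held beyond
        either end (np.interp clamps by construction)."""
        out = np.interp(t, self.times, self.values)
        return float(out) if np.ndim(t) == 0 else out


def interpolate(tc: TimeCourse, t):
    """Linear interpolation with constant-hold extrapolation."""
    return tc.at(t)


@dataclass(frozen=True)
class SimConfig:
    """Integration settings and rate constants.

    ``init_sensor_values`` fixes the sensor activities used to compute the
    steady-state initial condition; when None the supplied sensor time
    courses are interpolated at ``t_start`` instead.
    """

    t_start: float = 0.0
    t_end: float = 27.0
    dt: float = 0.025
    alpha: float = 1.0
    gamma: float = 1.0
    integrator: str = "euler"
    init_sensor_values: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")
        if self.alpha <= 0 or self.gamma <= 0:
            raise ValueError("alpha and gamma must be positive")
        if self.integrator not in ("euler", "rk4"):
            raise ValueError("integrator must be 'euler' or 'rk4'")


def gate_rhs(gate: Gate, xs: Sequence[float], y: float, cfg: SimConfig) -> float:
    """dy/dt for one gate at input values ``xs`` and current output ``y``."""
    if y < 0:
        raise ValueError("gate output must be non-negative")
    return cfg.alpha * gate.production(xs) - cfg.gamma * (y - gate.y_min)


def steady_state_init(
    circuit: Circuit,
    cfg: SimConfig,
    sensor_tcs: Mapping[str, TimeCourse] | None = None,
) -> dict[str, float]:
    """Fixed point of the gate ODEs at frozen sensor activities.

    Solved in closed form by topological substitution:
    y* = y_min + (alpha/gamma) f(x), which reduces to the static
    steady-state propagation when alpha = gamma.
    """
    if cfg.init_sensor_values is not None:
        sv = dict(cfg.init_sensor_values)
    elif sensor_tcs is not None:
        sv = {w: tc.at(cfg.t_start) for w, tc in sensor_tcs.items()}
    else:
        raise CircuitError("no sensor values available for initialisation")
    missing = [w for w in circuit.inputs if w not in sv]
    if missing:
        raise CircuitError(f"initial values missing for sensor wires: {missing}")
    scale = cfg.alpha / cfg.gamma
    values = {w: float(sv[w]) for w in circuit.inputs}
    out: dict[str, float] = {}
    for g in circuit.gate_order:
        y = g.y_min + scale * g.production([values[w] for w in g.inputs])
        values[g.id] = y
        out[g.id] = y
    return out


def simulate(
    circuit: Circuit,
    sensor_tcs: Mapping[str, TimeCourse],
    cfg: SimConfig = SimConfig(),
) -> dict[str, TimeCourse]:
    """Integrate all gate ODEs over [t_start, t_end].

    Returns one TimeCourse per gate, sampled at every integration step.
    Sensors are interpolated at each step (and at half-steps for RK4).
    Raises on NaN (naming the gate and step) and clamps a negative
    transient at zero with a warning (cannot occur under the default
    parameters, guard for user parameter files).
    """
    missing = [w for w in circuit.inputs if w not in sensor_tcs]
    if missing:
        raise CircuitError(f"no time course supplied for sensor wires: {missing}")
    span = cfg.t_end - cfg.t_start
    if cfg.dt >= span:
        raise ValueError("dt must be smaller than the simulated span")

    gates = circuit.gate_order
    n_steps = int(round(span / cfg.dt))
    times = cfg.t_start + cfg.dt * np.arange(n_steps + 1)

    gate_index = {g.id: i for i, g in enumerate(gates)}
    y_min = np.array([g.y_min for g in gates])

    def sensors_at(t: float) -> dict[str, float]:
        return {w: sensor_tcs[w].at(t) for w in circuit.inputs}

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        wire = sensors_at(t)
        for g, yi in zip(gates, y):
            wire[g.id] = yi
        prod = np.array(
            [g.production([wire[w] for w in g.inputs]) for g in gates]
        )
        return cfg.alpha * prod - cfg.gamma * (y - y_min)

    y0_map = steady_state_init(circuit, cfg, sensor_tcs)
    y = np.array([y0_map[g.id] for g in gates])
    traj = np.empty((n_steps + 1, len(gates)))
    traj[0] = y
    clamped = False
    for k in range(n_steps):
        t = times[k]
        if cfg.integrator == "euler":
            y = y + cfg.dt * rhs(t, y)
        else:
            h = cfg.dt
            k1 = rhs(t, y)
            k2 = rhs(t + h / 2, np.maximum(y + h / 2 * k1, 0.0))
            k3 = rhs(t + h / 2, np.maximum(y + h / 2 * k2, 0.0))
            k4 = rhs(t + h, np.maximum(y + h * k3, 0.0))
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        if np.any(np.isnan(y)):
            bad = gates[int(np.argmax(np.isnan(y)))].id
            raise FloatingPointError(
                f"NaN at step {k + 1} (t={times[k + 1]:.3f} h) in gate {bad!r}"
            )
        if np.any(y < 0):
            clamped = True
            y = np.maximum(y, 0.0)
        traj[k + 1] = y
    if clamped:
        warnings.warn(
            "negative gate transient clamped at 0 (check gate parameters)",
            RuntimeWarning,
            stacklevel=2,
        )
    return {
        g.id: TimeCourse(times, traj[:, gate_index[g.id]], name=g.id)
        for g in gates
    }
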