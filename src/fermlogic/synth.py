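"""Synthetic data generation: batch-growth stimuli, sensor time courses,
noisy dose-responses and cytometry-like populations.

The batch model emulates a shake-flask fermentation on 1.6 % glucose
minimal medium: Monod growth, stoichiometric glucose consumption,
quasi-static dissolved oxygen (fast gas transfer, respiration scales
with growth plus a maintenance term so DO stays depleted in stationary
phase), and phenomenological overflow acetate produced in proportion to
biomass while glucose lasts.  The default parameters are calibrated so
the culture reproduces the reference trajectory landmarks: glucose
exhausted near 15 h, dissolved oxygen below the 36 µmol/l sensor
half-max near 8 h, and acetate past 15 mM near 14 h.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .dynamics import TimeCourse
from .sensors import (
    DEFAULT_CALIBRATION,
    DoseResponse,
    HillSensor,
    SensorCalibration,
)

__all__ = [
    "BatchParams",
    "simulate_batch",
    "sensor_outputs_from_batch",
    "generate_dose_response",
    "generate_population",
]


@dataclass(frozen=True)
class BatchParams:
    """Shake-flask batch fermentation parameters.

    Units: biomass in OD600 units, glucose in % (g/g), dissolved oxygen in
    µmol/l, acetate in mM, time in hours.
    """

    X0: float = 0.01  # inoculum biomass, OD
    mu_max: float = 0.47  # maximal specific growth rate, 1/h
    K_s: float = 0.05  # Monod half-saturation, % glucose
    Y_xs: float = 5.0  # biomass yield, OD per % glucose
    glucose0: float = 1.6  # starting glucose, % (g/g)
    q_ac: float = 1.24  # overflow acetate production, mM per OD per h
    do_relax: float = 5.0  # DO relaxation toward its quasi-static target, 1/h
    do_sat: float = 210.0  # air-saturated dissolved oxygen, µmol/l
    do_floor: float = 20.0  # probe floor; DO is reported at >= this value
    o2_per_growth: float = 950.0  # µmol/l drawdown per unit of mu*X
    maintenance: float = 0.05  # maintenance respiration, 1/h equivalent
    glucose_detect: float = 0.01  # % glucose below which the feed counts as spent
    seed: int = 0  # reserved for stochastic variants; the ODE is deterministic

    def __post_init__(self) -> None:
        positive = (
            self.X0, self.mu_max, self.K_s, self.Y_xs, self.do_relax,
            self.do_sat, self.do_floor, self.o2_per_growth,
        )
        if min(positive) <= 0:
            raise ValueError("batch parameters must be positive")
        if self.glucose0 < 0 or self.q_ac < 0 or self.maintenance < 0:
            raise ValueError("glucose0, q_ac and maintenance must be >= 0")


def simulate_batch(
    p: BatchParams = BatchParams(), t_end: float = 27.0, dt: float = 0.01
) -> dict[str, TimeCourse]:
    """Integrate the batch model; returns biomass/glucose/do/acetate.

    Fixed-step RK4 on the smooth part; DO is relaxed toward its
    quasi-static target and clipped at the probe floor; acetate
    production stops with glucose exhaustion (no consumption phase).
    """
    n = int(round(t_end / dt))
    times = dt * np.arange(n + 1)

    def mu(G: float) -> float:
        return p.mu_max * G / (p.K_s + G) if G > 0 else 0.0

    def rhs(y: np.ndarray) -> np.ndarray:
        X, G, DO, A = y
        m = mu(G)
        dX = m * X
        dG = -m * X / p.Y_xs
        target = p.do_sat - p.o2_per_growth * (m + p.maintenance) * X
        dDO = p.do_relax * (max(target, p.do_floor) - DO)
        dA = p.q_ac * X if G > p.glucose_detect else 0.0
        return np.array([dX, dG, dDO, dA])

    y = np.array([p.X0, p.glucose0, p.do_sat, 0.0])
    traj = np.empty((n + 1, 4))
    traj[0] = y
    for i in range(n):
        k1 = rhs(y)
        k2 = rhs(np.maximum(y + dt / 2 * k1, 0.0))
        k3 = rhs(np.maximum(y + dt / 2 * k2, 0.0))
        k4 = rhs(np.maximum(y + dt * k3, 0.0))
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        y[1] = max(y[1], 0.0)  # glucose cannot go negative
        y[2] = max(y[2], p.do_floor)
        if np.any(y < 0):
            raise FloatingPointError(f"negative state at t={times[i + 1]:.2f} h")
        traj[i + 1] = y
    names = ("biomass", "glucose", "do", "acetate")
    return {
        nm: TimeCourse(times, traj[:, j], name=nm) for j, nm in enumerate(names)
    }


def sensor_outputs_from_batch(
    sensors: Sequence[HillSensor],
    batch: Mapping[str, TimeCourse],
    cal: SensorCalibration = DEFAULT_CALIBRATION,
) -> dict[str, TimeCourse]:
    """Map batch stimuli through each sensor onto its RPU range.

    The normalised Hill response u = (y - y_min)/(y_max - y_min) in [0, 1]
    is rescaled pointwise onto [rpu_min, rpu_max] for that sensor, so the
    wire carries the calibrated promoter activity the circuit model uses.
    Sensor names select the stimulus: glucose -> glucose (%), low_oxygen
    -> dissolved oxygen (µmol/l), acetate -> acetate (mM).
    """
    stimulus_for = {"glucose": "glucose", "low_oxygen": "do", "acetate": "acetate"}
    out: dict[str, TimeCourse] = {}
    for s in sensors:
        stim = batch[stimulus_for[s.name]]
        y = s.response(stim.values)
        u = (y - s.y_min) / (s.y_max - s.y_min)
        lo, hi = cal.rpu_ranges[s.name]
        out[s.name] = TimeCourse(stim.times, lo + (hi - lo) * u, name=s.name)
    return out


def generate_dose_response(
    sensor: HillSensor,
    doses: Sequence[float],
    noise_cv: float = 0.05,
    n_rep: int = 3,
    seed: int | None = 0,
) -> DoseResponse:
    """Noisy replicated dose-response drawn from a Hill sensor.

    Noise is multiplicative lognormal with the requested coefficient of
    variation and unit median, so the noiseless limit returns the exact
    model values and the median response stays on the curve.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    doses = np.asarray(doses, dtype=float)
    clean = sensor.response(doses)[:, None]
    if noise_cv == 0:
        return DoseResponse(doses, np.repeat(clean, n_rep, axis=1))
    sigma = np.sqrt(np.log1p(noise_cv**2))
    rng = np.random.default_rng(seed)
    noise = np.exp(sigma * rng.standard_normal((len(doses), n_rep)))
    return DoseResponse(doses, clean * noise)


#: Default 12-level dose panels for in-silico sensor characterisation.
#: Glucose and acetate panels are log-spaced over the experimentally used
#: stimulus ranges; the oxygen panel adds weight near air saturation
#: because the sensor's off state is only approached at high DO.
RECOVERY_DOSE_PANELS: dict[str, np.ndarray] = {
    "glucose": np.concatenate([[0.0], np.geomspace(0.016, 1.6, 11)]),
    "low_oxygen": np.array(
        [0.0, 6.0, 14.0, 24.0, 36.0, 54.0, 80.0, 120.0, 160.0, 190.0, 205.0, 210.0]
    ),
    "acetate": np.concatenate([[0.0], np.geomspace(1.0, 100.0, 11)]),
}


def sensor_recovery_experiment(
    sensor: HillSensor,
    seed: int,
    noise_cv: float = 0.05,
    n_rep: int = 3,
    doses: Sequence[float] | None = None,
):
    """One in-silico characterisation: generate a noisy dose-response from
    ``sensor`` and fit it back.

    The fit pins the Hill slope at the sensor's generating value (the
    slope is part of the declared simulation conditions, and leaving it
    free makes the off state of the oxygen sensor unidentifiable within
    its physical dose range).  Returns the fit report; the recovered
    half-max and dynamic range are read off the fitted sensor.
    """
    from .sensors import fit_hill

    if doses is None:
        doses = RECOVERY_DOSE_PANELS[sensor.name]
    data = generate_dose_response(sensor, doses, noise_cv, n_rep, seed)
    return fit_hill(
        data,
        mode=sensor.mode,
        name=f"{sensor.name}_recovered",
        stimulus_units=sensor.stimulus_units,
        hill_n=sensor.hill_n,
    )


def generate_population(
    median: float, cv: float, n_cells: int, seed: int | None = 0
) -> np.ndarray:
    """Lognormal cytometry-like fluorescence population with the requested
    median and coefficient of variation; cv = 0 gives constant samples."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if median <= 0:
        raise ValueError("median must be positive")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if cv == 0:
        return np.full(n_cells, float(median))
    sigma = np.sqrt(np.log1p(cv**2))
    rng = np.random.default_rng(seed)
    return median * np.exp(sigma * rng.standard_normal(n_cells))
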