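"""Phenomenological sensor transfer functions and Hill-curve fitting.

Three *E. coli* sensors report the state of a glucose batch culture: a
CRP-operator promoter activated by glucose, an FNR-operator promoter
activated by oxygen *depletion*, and an NtrC-dependent promoter activated
by acetate.  Each is modelled as a four-parameter Hill response.  Promoter
activities are expressed in relative promoter units (RPU), obtained from
background-subtracted fluorescence through a linear conversion factor.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import curve_fit

__all__ = [
    "HillSensor",
    "SensorCalibration",
    "DoseResponse",
    "HillFitReport",
    "sensor_response",
    "rpu_from_fluorescence",
    "fit_hill",
    "dynamic_range",
    "glucose_sensor",
    "low_oxygen_sensor",
    "acetate_sensor",
    "DEFAULT_CALIBRATION",
]

Mode = Literal["activating", "depletion_activating"]

#: RPU per background-subtracted fluorescence unit.
DEFAULT_RPU_CONVERSION = 1e-3

#: Measured output-promoter activity ranges (min RPU, max RPU) per sensor.
DEFAULT_RPU_RANGES: dict[str, tuple[float, float]] = {
    "glucose": (0.006, 0.237),
    "low_oxygen": (0.020, 1.346),
    "acetate": (0.002, 0.700),
}


@dataclass(frozen=True)
class HillSensor:
    """A saturating (Hill) dose-response of one sensor promoter.

    ``mode="activating"`` means output rises with the stimulus;
    ``mode="depletion_activating"`` means output rises as the stimulus
    *falls* (the low-oxygen sensor responds to dissolved-oxygen depletion).
    ``ec50`` is the stimulus at which the output crosses the midpoint of
    [y_min, y_max] for either mode.
    """

    name: str
    y_min: float
    y_max: float
    ec50: float
    hill_n: float = 1.0
    mode: Mode = "activating"
    stimulus_units: str = ""

    def __post_init__(self) -> None:
        if not (self.y_max > self.y_min >= 0):
            raise ValueError(
                f"require y_max > y_min >= 0, got {self.y_min}, {self.y_max}"
            )
        if self.ec50 <= 0:
            raise ValueError(f"ec50 must be positive, got {self.ec50}")
        if self.hill_n <= 0:
            raise ValueError(f"hill_n must be positive, got {self.hill_n}")
        if self.mode not in ("activating", "depletion_activating"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def response(self, stimulus):
        """Vectorised Hill response; clips nothing, exact at the nodes."""
        s = np.asarray(stimulus, dtype=float)
        if np.any(s < 0):
            raise ValueError("stimulus must be non-negative")
        kn = self.ec50**self.hill_n
        sn = s**self.hill_n
        if self.mode == "activating":
            frac = np.divide(sn, kn + sn, out=np.zeros_like(sn), where=(kn + sn) > 0)
        else:
            frac = kn / (kn + sn)
        out = self.y_min + (self.y_max - self.y_min) * frac
        return out if out.ndim else float(out)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "mode": self.mode,
            "y_min": float(self.y_min),
            "y_max": float(self.y_max),
            "ec50": float(self.ec50),
            "hill_n": float(self.hill_n),
            "stimulus_units": self.stimulus_units,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "HillSensor":
        return cls(**dict(d))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "HillSensor":
        return cls.from_dict(yaml.safe_load(text))


def sensor_response(sensor: HillSensor, stimulus):
    """Output of ``sensor`` at ``stimulus`` (same units as y_min/y_max)."""
    return sensor.response(stimulus)


def dynamic_range(sensor: HillSensor) -> float:
    """Fold induction y_max / y_min (infinite if the off state is zero)."""
    if sensor.y_min == 0:
        return float("inf")
    return sensor.y_max / sensor.y_min


@dataclass(frozen=True)
class SensorCalibration:
    """Fluorescence-to-RPU conversion plus per-sensor RPU extremes."""

    rpu_conversion_factor: float = DEFAULT_RPU_CONVERSION
    rpu_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RPU_RANGES)
    )

    def __post_init__(self) -> None:
        if self.rpu_conversion_factor <= 0:
            raise ValueError("conversion factor must be positive")
        for name, (lo, hi) in self.rpu_ranges.items():
            if not (hi > lo > 0):
                raise ValueError(f"rpu_max > rpu_min > 0 violated for {name!r}")

    def rpu_min(self, sensor: str) -> float:
        return self.rpu_ranges[sensor][0]

    def rpu_max(self, sensor: str) -> float:
        return self.rpu_ranges[sensor][1]


DEFAULT_CALIBRATION = SensorCalibration()


def rpu_from_fluorescence(
    fluor, background, cal: SensorCalibration = DEFAULT_CALIBRATION
):
    """Convert background-subtracted fluorescence (a.u.) to RPU.

    Raises if ``fluor < background``: a signal below background indicates a
    miscalibrated measurement rather than a meaningful negative activity.
    """
    f = np.asarray(fluor, dtype=float)
    b = np.asarray(background, dtype=float)
    if np.any(f < b):
        raise ValueError("fluorescence below background: miscalibration")
    out = (f - b) * cal.rpu_conversion_factor
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# dose-response data and fitting


@dataclass(frozen=True)
class DoseResponse:
    """Replicated dose-response measurements: doses strictly ascending,
    ``responses`` an (n_doses, n_replicates) array."""

    doses: np.ndarray
    responses: np.ndarray

    def __post_init__(self) -> None:
        doses = np.asarray(self.doses, dtype=float)
        responses = np.atleast_2d(np.asarray(self.responses, dtype=float))
        if responses.shape[0] != doses.shape[0]:
            responses = responses.T
        if responses.shape[0] != doses.shape[0]:
            raise ValueError("responses must have one row per dose")
        if np.any(doses < 0):
            raise ValueError("doses must be non-negative")
        if np.any(np.diff(doses) <= 0):
            raise ValueError("doses must be strictly ascending")
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "responses", responses)

    @property
    def n_doses(self) -> int:
        return len(self.doses)

    @property
    def n_replicates(self) -> int:
        return self.responses.shape[1]

    def to_csv(self, path_or_buf) -> None:
        rows = [
            {"dose": d, "replicate": r, "response": self.responses[i, r]}
            for i, d in enumerate(self.doses)
            for r in range(self.n_replicates)
        ]
        pd.DataFrame(rows).to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "DoseResponse":
        df = pd.read_csv(path_or_buf)
        required = {"dose", "replicate", "response"}
        if not required.issubset(df.columns):
            raise ValueError(f"dose-response CSV needs columns {sorted(required)}")
        wide = df.pivot(index="dose", columns="replicate", values="response")
        return cls(doses=wide.index.to_numpy(), responses=wide.to_numpy())

    def to_csv_string(self) -> str:
        buf = io.StringIO()
        self.to_csv(buf)
        return buf.getvalue()


@dataclass(frozen=True)
class HillFitReport:
    """Result of a Hill fit: the estimated sensor, residual diagnostics and
    a poor-fit flag (model mismatch or non-convergence is never silent)."""

    sensor: HillSensor
    residual_norm: float
    r_squared: float
    converged: bool
    poor_fit: bool
    message: str = ""


def _hill_log_model(mode: Mode, fixed_n: float | None):
    def model(s, *theta):
        if fixed_n is None:
            y_min, y_max, ec50, n = theta
        else:
            (y_min, y_max, ec50), n = theta, fixed_n
        kn = ec50**n
        sn = np.power(s, n)
        if mode == "activating":
            frac = np.divide(sn, kn + sn, out=np.zeros_like(sn), where=(kn + sn) > 0)
        else:
            frac = kn / (kn + sn)
        return np.log(y_min + (y_max - y_min) * frac)

    return model


def fit_hill(
    data: DoseResponse,
    mode: Mode = "activating",
    name: str = "fitted",
    stimulus_units: str = "",
    hill_n: float | None = None,
    r_squared_floor: float = 0.5,
) -> HillFitReport:
    """Least-squares Hill fit of a replicated dose-response.

    Residuals are taken on log-responses, the maximum-likelihood choice
    for the multiplicative (constant-CV) noise that fluorescence data
    carry; this keeps the off-state parameters identifiable when they sit
    orders of magnitude below the on state.  y_min, y_max and ec50 are
    always free, bounded positive; the Hill slope is free by default and
    can be pinned with ``hill_n`` when it is known (e.g. recovery
    experiments on data generated at a declared slope).  Initialisation:
    y_min = min(data), y_max = max(data), ec50 = dose nearest the
    midpoint response, n = 1.  A fit with log-scale R^2 below
    ``r_squared_floor`` (e.g. decreasing data fitted with an activating
    model) is flagged ``poor_fit``; failure to converge is flagged, never
    silently replaced.
    """
    if data.n_doses < 4:
        raise ValueError("need at least 4 distinct dose levels to fit")
    if np.any(data.responses <= 0):
        raise ValueError("responses must be positive")

    doses = np.repeat(data.doses, data.n_replicates)
    ys = data.responses.ravel()
    means = data.responses.mean(axis=1)

    y_lo, y_hi = float(means.min()), float(means.max())
    midpoint = 0.5 * (y_lo + y_hi)
    ec50_0 = float(data.doses[np.argmin(np.abs(means - midpoint))])
    if ec50_0 <= 0:
        ec50_0 = float(data.doses[data.doses > 0].min())
    p0 = [max(y_lo, 1e-12), y_hi, ec50_0]
    dose_cap = 1e3 * float(data.doses.max())
    lo_b, hi_b = [1e-15, 1e-15, 1e-12], [np.inf, np.inf, dose_cap]
    if hill_n is None:
        p0.append(1.0)
        lo_b.append(0.05)
        hi_b.append(20.0)

    model = _hill_log_model(mode, hill_n)
    try:
        popt, _ = curve_fit(
            model, doses, np.log(ys), p0=p0, bounds=(lo_b, hi_b),
            maxfev=20000, xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        converged = True
        message = ""
    except RuntimeError as exc:  # no convergence
        popt = np.array(p0)
        converged = False
        message = str(exc)

    log_ys = np.log(ys)
    resid = log_ys - model(doses, *popt)
    residual_norm = float(np.linalg.norm(resid))
    ss_tot = float(np.sum((log_ys - log_ys.mean()) ** 2))
    r_squared = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    poor_fit = (not converged) or (r_squared < r_squared_floor)

    if hill_n is None:
        y_min_hat, y_max_hat, ec50_hat, n_hat = (float(v) for v in popt)
    else:
        y_min_hat, y_max_hat, ec50_hat = (float(v) for v in popt)
        n_hat = float(hill_n)
    if y_max_hat <= y_min_hat:  # degenerate flat fit
        y_max_hat = y_min_hat + max(1e-12, 1e-9 * max(1.0, y_min_hat))
        poor_fit = True
    sensor = HillSensor(
        name=name,
        y_min=y_min_hat,
        y_max=y_max_hat,
        ec50=ec50_hat,
        hill_n=n_hat,
        mode=mode,
        stimulus_units=stimulus_units,
    )
    return HillFitReport(
        sensor=sensor,
        residual_norm=residual_norm,
        r_squared=r_squared,
        converged=converged,
        poor_fit=poor_fit,
        message=message,
    )


# ---------------------------------------------------------------------------
# the three study sensors
#
# Half-max points and fold inductions are the measured values for PgluA7,
# PfnrF8 and PglnAP2s.  The Hill slope was not reported; n = 1 is the model
# default and is always re-fittable from data.  Outputs are normalised to
# y_max = 1 with y_min = 1/fold unless an explicit RPU scale is requested.


def glucose_sensor(hill_n: float = 1.0, fold: float = 18.0) -> HillSensor:
    """CRP-operator promoter: activated by glucose, half-max 0.1 % (g/g)."""
    return HillSensor(
        name="glucose",
        y_min=1.0 / fold,
        y_max=1.0,
        ec50=0.1,
        hill_n=hill_n,
        mode="activating",
        stimulus_units="% glucose (g/g)",
    )


def low_oxygen_sensor(hill_n: float = 1.0, fold: float = 25.0) -> HillSensor:
    """FNR-operator promoter: activated by oxygen depletion, half-max at
    36 µmol/l dissolved oxygen."""
    return HillSensor(
        name="low_oxygen",
        y_min=1.0 / fold,
        y_max=1.0,
        ec50=36.0,
        hill_n=hill_n,
        mode="depletion_activating",
        stimulus_units="µmol/l DO",
    )


def acetate_sensor(hill_n: float = 1.0, fold: float = 250.0) -> HillSensor:
    """Truncated PglnAP2 promoter: activated by acetate, half-max 13.8 mM."""
    return HillSensor(
        name="acetate",
        y_min=1.0 / fold,
        y_max=1.0,
        ec50=13.8,
        hill_n=hill_n,
        mode="activating",
        stimulus_units="mM acetate",
    )


def rescale_to_rpu(sensor: HillSensor, cal: SensorCalibration) -> HillSensor:
    """Return a copy of ``sensor`` with its output span mapped onto the
    calibrated [rpu_min, rpu_max] interval for that sensor name."""
    lo, hi = cal.rpu_ranges[sensor.name]
    return replace(sensor, y_min=lo, y_max=hi)
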