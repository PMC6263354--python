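"""Steady-state response functions for the four gate types.

Repressor-based NOT/NOR gates follow a declining Hill function of the
summed input promoter activity.  The SicA/InvF AND gate follows a
saturating function of x1*x2^2 (the measured asymmetric cooperativity of
the chaperone/activator pair; the exponent is used exactly as measured,
not generalised).  The PhlF ANDN gate passes its first input scaled by a
repression factor K/(K + x2).  All activities are in RPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

__all__ = [
    "RepressorGateParams",
    "AndGateParams",
    "AndnGateParams",
    "Gate",
    "GATE_KINDS",
    "GATE_ARITY",
    "repressor_response",
    "and_response",
    "andn_response",
]

GATE_KINDS = ("NOT", "NOR", "AND", "ANDN")
GATE_ARITY = {"NOT": 1, "NOR": 2, "AND": 2, "ANDN": 2}


@dataclass(frozen=True)
class RepressorGateParams:
    """NOT/NOR gate constants.  Defaults are a neutral mid-range repressor;
    per-repressor values (PhlF, SrpR, ...) come from user parameter files."""

    y_min: float = 0.01
    y_max: float = 1.0
    K: float = 0.1
    n: float = 2.0

    def __post_init__(self) -> None:
        if not (self.y_max > self.y_min > 0):
            raise ValueError("require y_max > y_min > 0")
        if self.K <= 0 or self.n <= 0:
            raise ValueError("K and n must be positive")


@dataclass(frozen=True)
class AndGateParams:
    """SicA/InvF AND gate constants (RPU; K is in RPU^3)."""

    y_min: float = 0.001
    y_max: float = 0.3
    K: float = 1e-5

    def __post_init__(self) -> None:
        if not (self.y_max > self.y_min > 0):
            raise ValueError("require y_max > y_min > 0")
        if self.K <= 0:
            raise ValueError("K must be positive")


@dataclass(frozen=True)
class AndnGateParams:
    """PhlF ANDN gate constants: output tracks x1 attenuated by x2."""

    y_min: float = 0.001
    K: float = 0.0025

    def __post_init__(self) -> None:
        if self.y_min <= 0 or self.K <= 0:
            raise ValueError("y_min and K must be positive")


GateParams = Union[RepressorGateParams, AndGateParams, AndnGateParams]
_PARAMS_FOR_KIND = {
    "NOT": RepressorGateParams,
    "NOR": RepressorGateParams,
    "AND": AndGateParams,
    "ANDN": AndnGateParams,
}


def repressor_response(p: RepressorGateParams, x) -> float:
    """y = y_min + (y_max - y_min) K^n / (K^n + x^n); NOR callers pass
    x = x1 + x2.  Strictly decreasing in x, y(0) = y_max."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("gate input must be non-negative")
    kn = p.K**p.n
    out = p.y_min + (p.y_max - p.y_min) * kn / (kn + x**p.n)
    return out if out.ndim else float(out)


def and_response(p: AndGateParams, x1, x2) -> float:
    """y = y_min + (y_max - y_min) x1 x2^2 / (K + x1 x2^2)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if np.any(x1 < 0) or np.any(x2 < 0):
        raise ValueError("gate inputs must be non-negative")
    s = x1 * x2**2
    out = p.y_min + (p.y_max - p.y_min) * s / (p.K + s)
    return out if out.ndim else float(out)


def andn_response(p: AndnGateParams, x1, x2) -> float:
    """y = y_min + (x1 - y_min) K / (K + x2), clamped at y_min when
    x1 < y_min (the raw formula would undershoot its own floor)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if np.any(x1 < 0) or np.any(x2 < 0):
        raise ValueError("gate inputs must be non-negative")
    out = p.y_min + np.maximum(x1 - p.y_min, 0.0) * p.K / (p.K + x2)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class Gate:
    """One gate in a netlist: a kind, ordered input wires, and the matching
    parameter record.  For ANDN, inputs[0] is the passed signal x1 and
    inputs[1] the antagonist x2."""

    id: str
    kind: str
    inputs: tuple[str, ...]
    params: GateParams = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.kind not in GATE_KINDS:
            raise ValueError(f"unknown gate kind {self.kind!r}")
        object.__setattr__(self, "inputs", tuple(self.inputs))
        if len(self.inputs) != GATE_ARITY[self.kind]:
            raise ValueError(
                f"{self.kind} gate takes {GATE_ARITY[self.kind]} inputs, "
                f"got {len(self.inputs)}"
            )
        if self.params is None:
            object.__setattr__(self, "params", _PARAMS_FOR_KIND[self.kind]())
        elif not isinstance(self.params, _PARAMS_FOR_KIND[self.kind]):
            raise TypeError(
                f"{self.kind} gate needs {_PARAMS_FOR_KIND[self.kind].__name__}"
            )

    # -- steady-state response ------------------------------------------------

    def response(self, xs: Sequence[float]) -> float:
        """Steady-state output for input values ``xs`` (ordered as inputs)."""
        if self.kind == "NOT":
            return repressor_response(self.params, xs[0])
        if self.kind == "NOR":
            return repressor_response(self.params, xs[0] + xs[1])
        if self.kind == "AND":
            return and_response(self.params, xs[0], xs[1])
        return andn_response(self.params, xs[0], xs[1])

    def production(self, xs: Sequence[float]) -> float:
        """x-dependent production term: response minus the y_min floor.
        The dynamic model is dy/dt = alpha * production - gamma * (y - y_min)."""
        return self.response(xs) - self.params.y_min

    def logic(self, bits: Sequence[bool]) -> bool:
        """Ideal Boolean semantics of this gate kind."""
        if self.kind == "NOT":
            return not bits[0]
        if self.kind == "NOR":
            return not (bits[0] or bits[1])
        if self.kind == "AND":
            return bits[0] and bits[1]
        return bits[0] and not bits[1]

    @property
    def y_min(self) -> float:
        return self.params.y_min
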