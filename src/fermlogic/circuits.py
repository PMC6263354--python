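"""Acyclic gate netlists: steady-state propagation, truth-table
digitization, and bounded-depth enumeration of layered circuits.

A circuit wires three sensor input promoters through AND / ANDN / NOR /
NOT gates.  Steady-state propagation evaluates each gate's response in
topological order; digitization evaluates all 2^n input corners (each
sensor at its minimum or maximum RPU) and thresholds each output at the
geometric mean of its own corner extremes.  Enumeration explores all
layered wirings up to a depth bound, keeping one representative per
distinct Boolean truth table (at most 256 exist for 3 inputs).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from graphlib import CycleError, TopologicalSorter
from typing import Iterable, Iterator, Mapping, Sequence

from .gates import (
    GATE_ARITY,
    Gate,
    AndGateParams,
    AndnGateParams,
    RepressorGateParams,
)

__all__ = [
    "Circuit",
    "TruthTable",
    "CircuitError",
    "circuit_steady_state",
    "digitize",
    "boolean_table",
    "enumerate_circuits",
    "iter_layered_circuits",
    "idealize_params",
    "glucose_and_acetate",
    "glucose_andn_low_oxygen",
    "pulse_circuit",
    "repressor_cascade_example",
    "REFERENCE_INIT_SENSOR_RPU",
]


class CircuitError(ValueError):
    """Structural netlist problem: cycle, unknown wire, duplicate id."""


#: Steady-state sensor activities used to initialise the worked 3-input
#: example (x1, x2, x3 verbatim from the source modelling description; the
#: x1 value exceeds the glucose sensor maximum and is kept as printed).
REFERENCE_INIT_SENSOR_RPU = {"x1": 1.294, "x2": 0.006, "x3": 0.028}


@dataclass(frozen=True)
class Circuit:
    """An acyclic netlist over named wires.

    ``inputs`` are sensor wires; every gate's inputs must be sensor wires
    or outputs of earlier-validated gates; ``outputs`` name the wires that
    constitute the circuit's result.
    """

    inputs: tuple[str, ...]
    gates: tuple[Gate, ...]
    outputs: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "inputs", tuple(self.inputs))
        object.__setattr__(self, "gates", tuple(self.gates))
        object.__setattr__(self, "outputs", tuple(self.outputs))
        ids = [g.id for g in self.gates]
        dup = {i for i in ids if ids.count(i) > 1} | (
            set(ids) & set(self.inputs)
        )
        if dup:
            raise CircuitError(f"duplicate wire ids: {sorted(dup)}")
        known = set(self.inputs) | set(ids)
        for g in self.gates:
            for w in g.inputs:
                if w not in known:
                    raise CircuitError(f"gate {g.id!r} references unknown wire {w!r}")
        for w in self.outputs:
            if w not in known:
                raise CircuitError(f"output references unknown wire {w!r}")
        # acyclicity + cached topological order of gates
        ts = TopologicalSorter({g.id: set(g.inputs) for g in self.gates})
        try:
            order = [w for w in ts.static_order() if w in set(ids)]
        except CycleError as exc:
            raise CircuitError(f"netlist contains a cycle: {exc}") from exc
        by_id = {g.id: g for g in self.gates}
        object.__setattr__(self, "_topo", tuple(by_id[i] for i in order))

    @property
    def gate_order(self) -> tuple[Gate, ...]:
        """Gates in topological evaluation order."""
        return self._topo  # type: ignore[attr-defined]

    def gate(self, gate_id: str) -> Gate:
        for g in self.gates:
            if g.id == gate_id:
                return g
        raise KeyError(gate_id)

    def with_params(self, params: Mapping[str, object]) -> "Circuit":
        """Copy with per-gate parameter records replaced by id."""
        new = tuple(
            replace(g, params=params[g.id]) if g.id in params else g
            for g in self.gates
        )
        return Circuit(self.inputs, new, self.outputs)


def circuit_steady_state(
    circuit: Circuit, sensor_values: Mapping[str, float]
) -> dict[str, float]:
    """Propagate steady-state responses through the netlist.

    Returns the activity of every wire (sensors echoed, gates evaluated in
    topological order).  Deterministic and independent of the order in
    which gates were listed.
    """
    missing = [w for w in circuit.inputs if w not in sensor_values]
    if missing:
        raise CircuitError(f"unassigned sensor wires: {missing}")
    values: dict[str, float] = {w: float(sensor_values[w]) for w in circuit.inputs}
    for g in circuit.gate_order:
        values[g.id] = g.response([values[w] for w in g.inputs])
    return values


# ---------------------------------------------------------------------------
# truth tables


@dataclass(frozen=True)
class TruthTable:
    """Boolean map of input corners to one output bit.

    Bits are indexed in lexicographic corner order with input 1 most
    significant: corner (b1, b2, b3) lives at index b1*4 + b2*2 + b3.
    """

    n_inputs: int
    bits: tuple[bool, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "bits", tuple(bool(b) for b in self.bits))
        if len(self.bits) != 2**self.n_inputs:
            raise ValueError("truth table must have exactly 2^n_inputs bits")

    def __getitem__(self, corner: Sequence[bool]) -> bool:
        idx = 0
        for b in corner:
            idx = (idx << 1) | int(b)
        return self.bits[idx]

    def to_csv(self) -> str:
        """Rows ``x1,..,xn,output_bit`` in lexicographic corner order."""
        header = ",".join(f"x{i + 1}" for i in range(self.n_inputs)) + ",output_bit"
        lines = [header]
        for idx, bit in enumerate(self.bits):
            corner = [(idx >> (self.n_inputs - 1 - i)) & 1 for i in range(self.n_inputs)]
            lines.append(",".join(str(c) for c in corner) + f",{int(bit)}")
        return "\n".join(lines) + "\n"


def _corners(n: int) -> Iterator[tuple[int, ...]]:
    return itertools.product((0, 1), repeat=n)


def boolean_table(circuit: Circuit, output: str | None = None) -> TruthTable:
    """Ideal Boolean composition of the circuit's gate logics."""
    out = output or circuit.outputs[0]
    n = len(circuit.inputs)
    bits = []
    for corner in _corners(n):
        vals: dict[str, bool] = dict(zip(circuit.inputs, map(bool, corner)))
        for g in circuit.gate_order:
            vals[g.id] = g.logic([vals[w] for w in g.inputs])
        bits.append(vals[out])
    return TruthTable(n, tuple(bits))


def digitize(
    circuit: Circuit,
    ranges: Mapping[str, tuple[float, float]],
    constant_ratio: float = 3.0,
) -> dict[str, TruthTable]:
    """Digitize analog circuit outputs into truth tables.

    Evaluates ``circuit_steady_state`` at every input corner (each sensor
    wire at the low or high end of its ``ranges`` entry) and thresholds
    each output at the geometric mean of its own corner extremes.  An
    output whose corner extremes differ by less than ``constant_ratio``
    is degenerate: it is assigned a constant bit by comparison to the
    geometric mean of the producing gate's own floor and ceiling (or of
    the sensor range, for a pass-through output).
    """
    n = len(circuit.inputs)
    if n > 8:
        raise CircuitError("digitization limited to <= 8 input corners per wire")
    corner_values: dict[str, list[float]] = {w: [] for w in circuit.outputs}
    for corner in _corners(n):
        sv = {
            w: ranges[w][1] if bit else ranges[w][0]
            for w, bit in zip(circuit.inputs, corner)
        }
        state = circuit_steady_state(circuit, sv)
        for w in circuit.outputs:
            corner_values[w].append(state[w])

    tables: dict[str, TruthTable] = {}
    gate_ids = {g.id for g in circuit.gates}
    for w, vals in corner_values.items():
        lo, hi = min(vals), max(vals)
        if hi <= lo * constant_ratio:  # degenerate: flat across corners
            if w in gate_ids:
                g = circuit.gate(w)
                ceiling = getattr(g.params, "y_max", None)
                if ceiling is None:  # ANDN has no y_max; its ceiling tracks x1
                    ceiling = max(hi, 100 * g.params.y_min)
                thresh = math.sqrt(g.params.y_min * ceiling)
            else:
                thresh = math.sqrt(ranges[w][0] * ranges[w][1])
        else:
            thresh = math.sqrt(lo * hi)
        tables[w] = TruthTable(n, tuple(v > thresh for v in vals))
    return tables


# ---------------------------------------------------------------------------
# idealized parameter assignment
#
# For logic-equivalence checks we need parameters under which the fuzzy
# gate responses separate cleanly.  Because every response family here is
# soft (the AND form is first-order in its statistic, ANDN only attenuates
# by K/(K+x2)), a single global parameter set cannot separate layered
# outputs; instead each gate's K is placed relative to the analog corner
# values actually reaching it, which are propagated together with the
# ideal Boolean bits.


def idealize_params(
    circuit: Circuit, lo: float = 0.01, hi: float = 1.0
) -> Circuit:
    """Return a copy of ``circuit`` with per-gate near-ideal parameters.

    Sensor wires are assumed to sit at ``lo``/``hi`` RPU at their corners.
    Repressor gates get a steep Hill (n=4) with K at the geometric mean of
    the largest input seen in Boolean-ON corners and the smallest seen in
    Boolean-OFF corners; AND gates get K at the smallest ON-corner value of
    x1*x2^2 (half-max at the weakest ON state, maximising ON/OFF contrast);
    ANDN gates get K a third of the largest x2 seen in ON corners (strong
    blocking at the cost of pass amplitude).  Gates that are Boolean
    constants get K pushed far out so their output pins to floor/ceiling.
    """
    n = len(circuit.inputs)
    corners = list(_corners(n))
    analog: dict[str, list[float]] = {
        w: [hi if c[i] else lo for c in corners]
        for i, w in enumerate(circuit.inputs)
    }
    bits: dict[str, list[bool]] = {
        w: [bool(c[i]) for c in corners] for i, w in enumerate(circuit.inputs)
    }

    new_params: dict[str, object] = {}
    for g in circuit.gate_order:
        out_bits = [
            g.logic([bits[w][k] for w in g.inputs]) for k in range(len(corners))
        ]
        if g.kind in ("NOT", "NOR"):
            xs = [
                sum(analog[w][k] for w in g.inputs) for k in range(len(corners))
            ]
            on = [x for x, b in zip(xs, out_bits) if b]
            off = [x for x, b in zip(xs, out_bits) if not b]
            if on and off:
                K = math.sqrt(max(on) * min(off))
            elif on:  # constant-ON: never repressed
                K = 100.0 * max(xs)
            else:  # constant-OFF: always repressed
                K = min(xs) / 100.0
            p = RepressorGateParams(y_min=0.01, y_max=1.0, K=K, n=4.0)
            ys = [
                p.y_min + (p.y_max - p.y_min) * K**4 / (K**4 + x**4) for x in xs
            ]
        elif g.kind == "AND":
            stats = [
                analog[g.inputs[0]][k] * analog[g.inputs[1]][k] ** 2
                for k in range(len(corners))
            ]
            on = [s for s, b in zip(stats, out_bits) if b]
            if on:
                K = min(on)
            else:
                K = 1e4 * max(stats)  # constant-OFF
            p = AndGateParams(y_min=0.01, y_max=1.0, K=K)
            ys = [p.y_min + (p.y_max - p.y_min) * s / (K + s) for s in stats]
        else:  # ANDN
            x2s = [analog[g.inputs[1]][k] for k in range(len(corners))]
            pass_x2 = [x for x, b in zip(x2s, out_bits) if b]
            if pass_x2:
                K = max(pass_x2) / 3.0
            else:
                K = min(x2s) / 1000.0  # constant-OFF: block everything
            p = AndnGateParams(y_min=0.01, K=K)
            ys = [
                p.y_min
                + max(analog[g.inputs[0]][k] - p.y_min, 0.0) * K / (K + x2s[k])
                for k in range(len(corners))
            ]
        new_params[g.id] = p
        analog[g.id] = ys
        bits[g.id] = out_bits
    return circuit.with_params(new_params)


# ---------------------------------------------------------------------------
# enumeration of layered circuits


def _expr_depth(expr) -> int:
    if isinstance(expr, str):
        return 0
    _, args = expr
    return 1 + max(_expr_depth(a) for a in args)


def _exprs_up_to(depth: int, kinds: Sequence[str], inputs: Sequence[str]):
    """All gate expression trees of depth <= ``depth`` with structurally
    distinct operands (a gate never takes the same wire twice)."""
    levels: list[list] = [list(inputs)]
    for d in range(1, depth + 1):
        pool = [e for lvl in levels for e in lvl]
        prev = levels[d - 1]
        new = []
        for kind in kinds:
            if GATE_ARITY[kind] == 1:
                new.extend((kind, (a,)) for a in prev)
            elif kind == "NOR":  # logically symmetric: unordered pairs
                for i, a in enumerate(pool):
                    for b in pool[i + 1 :]:
                        if a in prev or b in prev:
                            new.append((kind, (a, b)))
            else:  # AND / ANDN: analog forms are asymmetric, keep order
                for a in pool:
                    for b in pool:
                        if a is not b and (a in prev or b in prev):
                            new.append((kind, (a, b)))
        levels.append(new)
    return levels


def _expr_to_circuit(expr, inputs: Sequence[str]) -> Circuit:
    gates: list[Gate] = []
    counter = itertools.count(1)

    def build(e) -> str:
        if isinstance(e, str):
            return e
        kind, args = e
        wires = tuple(build(a) for a in args)
        gid = f"g{next(counter)}"
        gates.append(Gate(id=gid, kind=kind, inputs=wires))
        return gid

    out = build(expr)
    if not gates:  # bare projection
        return Circuit(tuple(inputs), (), (out,))
    return Circuit(tuple(inputs), tuple(gates), (out,))


def iter_layered_circuits(
    max_depth: int,
    kinds: Iterable[str] = ("AND", "ANDN", "NOR", "NOT"),
    inputs: Sequence[str] = ("x1", "x2", "x3"),
) -> Iterator[Circuit]:
    """Yield every layered wiring (expression tree) of depth <= max_depth,
    without truth-table deduplication.  Projections come first."""
    kinds = tuple(kinds)
    for k in kinds:
        if k not in GATE_ARITY:
            raise ValueError(f"unknown gate kind {k!r}")
    if max_depth > 3:
        raise ValueError("max_depth > 3 exceeds the combinatorial guard")
    if max_depth >= 3 and len(kinds) > 2:
        est = sum(len(l) for l in _exprs_up_to(2, kinds, inputs)) ** 2 * len(kinds)
        raise ValueError(
            f"enumeration would explode (~{est} wirings at depth 3); "
            "restrict the gate kinds"
        )
    for level in _exprs_up_to(max_depth, kinds, inputs):
        for expr in level:
            yield _expr_to_circuit(expr, inputs)


def enumerate_circuits(
    max_depth: int,
    kinds: Iterable[str] = ("AND", "ANDN", "NOR", "NOT"),
    inputs: Sequence[str] = ("x1", "x2", "x3"),
) -> list[tuple[Circuit, TruthTable]]:
    """All distinct truth tables reachable by layered circuits of depth
    <= ``max_depth``, one representative circuit each (shallowest first).

    The distinct-table count is bounded by 2^(2^n_inputs) = 256 for three
    inputs.  Depth is capped at 3; the full four-kind alphabet at depth 3
    trips the explosion guard.
    """
    seen: dict[tuple[bool, ...], tuple[Circuit, TruthTable]] = {}
    for c in iter_layered_circuits(max_depth, kinds, inputs):
        t = boolean_table(c)
        if t.bits not in seen:
            seen[t.bits] = (c, t)
    return list(seen.values())


# ---------------------------------------------------------------------------
# named study circuits (sensor wires: glucose, low_oxygen, acetate)


def glucose_and_acetate() -> Circuit:
    """AND of the glucose and acetate sensors (drives the poxB knockdown:
    on late in growth, when acetate has accumulated but glucose remains)."""
    return Circuit(
        inputs=("glucose", "low_oxygen", "acetate"),
        gates=(Gate("out", "AND", ("glucose", "acetate"), AndGateParams()),),
        outputs=("out",),
    )


def glucose_andn_low_oxygen() -> Circuit:
    """Glucose ANDN low-oxygen (drives the pta knockdown: on during
    aerobic exponential growth, off once oxygen is depleted)."""
    return Circuit(
        inputs=("glucose", "low_oxygen", "acetate"),
        gates=(Gate("out", "ANDN", ("glucose", "low_oxygen"), AndnGateParams()),),
        outputs=("out",),
    )


def pulse_circuit() -> Circuit:
    """(glucose AND acetate) ANDN low-oxygen: the 3-input 1-output pulse
    circuit."""
    return Circuit(
        inputs=("glucose", "low_oxygen", "acetate"),
        gates=(
            Gate("and1", "AND", ("glucose", "acetate"), AndGateParams()),
            Gate("out", "ANDN", ("and1", "low_oxygen"), AndnGateParams()),
        ),
        outputs=("out",),
    )


def repressor_cascade_example(
    params: RepressorGateParams | None = None,
) -> Circuit:
    """The worked 3-input 1-output repressor cascade: y1 = NOR(x1, x2),
    y2 = NOT(x3), y3 = NOR(y1, y2)."""
    p = params or RepressorGateParams()
    return Circuit(
        inputs=("x1", "x2", "x3"),
        gates=(
            Gate("y1", "NOR", ("x1", "x2"), p),
            Gate("y2", "NOT", ("x3",), p),
            Gate("y3", "NOR", ("y1", "y2"), p),
        ),
        outputs=("y3",),
    )
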