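"""Netlist propagation, digitization, and circuit enumeration."""

import itertools

import pytest

from fermlogic.circuits import (
    Circuit,
    CircuitError,
    REFERENCE_INIT_SENSOR_RPU,
    boolean_table,
    circuit_steady_state,
    digitize,
    enumerate_circuits,
    glucose_and_acetate,
    glucose_andn_low_oxygen,
    idealize_params,
    iter_layered_circuits,
    pulse_circuit,
    repressor_cascade_example,
)
from fermlogic.gates import (
    AndGateParams,
    AndnGateParams,
    Gate,
    RepressorGateParams,
    and_response,
    andn_response,
    repressor_response,
)
from fermlogic.sensors import DEFAULT_CALIBRATION

SENSOR_RANGES = {
    "glucose": DEFAULT_CALIBRATION.rpu_ranges["glucose"],
    "low_oxygen": DEFAULT_CALIBRATION.rpu_ranges["low_oxygen"],
    "acetate": DEFAULT_CALIBRATION.rpu_ranges["acetate"],
}


class TestSteadyState:
    def test_cascade_matches_fixed_point_iteration(self):
        """Topological substitution equals damped fixed-point iteration."""
        c = repressor_cascade_example()
        sv = REFERENCE_INIT_SENSOR_RPU
        got = circuit_steady_state(c, sv)

        p = RepressorGateParams()
        y = {"y1": 0.5, "y2": 0.5, "y3": 0.5}  # independent oracle
        for _ in range(2000):
            y_new = {
                "y1": repressor_response(p, sv["x1"] + sv["x2"]),
                "y2": repressor_response(p, sv["x3"]),
                "y3": repressor_response(p, y["y1"] + y["y2"]),
            }
            if all(abs(y_new[k] - y[k]) < 1e-14 for k in y):
                break
            y = y_new
        for k in y:
            assert got[k] == pytest.approx(y[k], abs=1e-10)

    def test_empty_netlist_echoes_sensors(self):
        c = Circuit(("a", "b"), (), ("a",))
        assert circuit_steady_state(c, {"a": 0.3, "b": 0.4}) == {"a": 0.3, "b": 0.4}

    def test_gate_listing_order_is_irrelevant(self):
        c = repressor_cascade_example()
        shuffled = Circuit(c.inputs, tuple(reversed(c.gates)), c.outputs)
        sv = {"x1": 0.1, "x2": 0.2, "x3": 0.05}
        assert circuit_steady_state(c, sv) == circuit_steady_state(shuffled, sv)

    def test_structural_errors(self):
        with pytest.raises(CircuitError, match="unknown wire"):
            Circuit(("a",), (Gate("g", "NOT", ("zz",)),), ("g",))
        with pytest.raises(CircuitError, match="cycle"):
            Circuit(
                ("a",),
                (
                    Gate("g1", "NOR", ("a", "g2")),
                    Gate("g2", "NOT", ("g1",)),
                ),
                ("g2",),
            )
        with pytest.raises(CircuitError, match="unassigned"):
            circuit_steady_state(
                Circuit(("a", "b"), (), ("a",)), {"a": 1.0}
            )


def _corner_map(bits):
    return dict(zip(("glucose", "low_oxygen", "acetate"), bits))


class TestDigitize:
    @pytest.mark.parametrize(
        "circuit",
        [glucose_andn_low_oxygen(), glucose_and_acetate()],
        ids=["ANDN(glu,lowO2)", "AND(glu,ace)"],
    )
    def test_corner_thresholding_matches_hand_oracle(self, circuit):
        """Independent 8-corner oracle: evaluate the analog response at
        every RPU corner by hand, threshold at the geometric mean of the
        extremes, and compare bit-for-bit."""
        table = digitize(circuit, SENSOR_RANGES)["out"]

        import math

        vals = {}
        for bits in itertools.product((0, 1), repeat=3):
            sv = {
                w: SENSOR_RANGES[w][b]
                for w, b in _corner_map(bits).items()
            }
            g = circuit.gates[0]
            if g.kind == "ANDN":
                v = andn_response(g.params, sv["glucose"], sv["low_oxygen"])
            else:
                v = and_response(g.params, sv["glucose"], sv["acetate"])
            vals[bits] = v
        thr = math.sqrt(min(vals.values()) * max(vals.values()))
        for bits, v in vals.items():
            assert table[bits] == (v > thr)

    def test_andn_published_parameters_are_digital_at_the_corners(self):
        """With the published ANDN constants the gate separates cleanly:
        output high only when glucose is high and low-oxygen low."""
        table = digitize(glucose_andn_low_oxygen(), SENSOR_RANGES)["out"]
        for g, o, a in itertools.product((0, 1), repeat=3):
            assert table[(g, o, a)] == bool(g and not o)

    def test_and_boolean_pattern_under_separating_parameters(self):
        """The published AND constants are too sensitive to be digital at
        the sensor corners (K = 1e-5 saturates even at the glucose
        minimum); with separating (near-ideal) parameters the digitized
        table is exactly A AND B."""
        c = glucose_and_acetate()
        ranges = {w: (0.01, 1.0) for w in c.inputs}
        table = digitize(idealize_params(c), ranges)["out"]
        for g, o, a in itertools.product((0, 1), repeat=3):
            assert table[(g, o, a)] == bool(g and a)

    def test_projection_circuit_gives_identity_table(self):
        c = Circuit(("glucose", "low_oxygen", "acetate"), (), ("acetate",))
        table = digitize(c, SENSOR_RANGES)["acetate"]
        for bits in itertools.product((0, 1), repeat=3):
            assert table[bits] == bool(bits[2])

    def test_truth_table_csv_layout(self):
        c = Circuit(("glucose", "low_oxygen", "acetate"), (), ("glucose",))
        csv = digitize(c, SENSOR_RANGES)["glucose"].to_csv()
        lines = csv.strip().splitlines()
        assert lines[0] == "x1,x2,x3,output_bit"
        assert lines[1] == "0,0,0,0"
        assert lines[-1] == "1,1,1,1"


class TestEnumeration:
    def test_depth_zero_is_the_three_projections(self):
        got = enumerate_circuits(0)
        tables = {t.bits for _, t in got}
        assert len(got) == 3
        want = set()
        for i in range(3):
            want.add(
                tuple(bool(c[i]) for c in itertools.product((0, 1), repeat=3))
            )
        assert tables == want

    def test_distinct_tables_bounded_by_256(self):
        got = enumerate_circuits(2)
        assert len(got) <= 256
        assert len({t.bits for _, t in got}) == len(got)

    def test_and_only_circuits_are_conjunctive(self):
        """An AND-only table is never 1 at a corner with a 0 input among
        the wires it depends on -- checked exhaustively: no table may be 1
        at a corner dominated by another corner with fewer 1s."""
        for c, t in enumerate_circuits(2, kinds=("AND",)):
            for corner in itertools.product((0, 1), repeat=3):
                if t[corner]:
                    # monotone: any corner with more 1s must also be 1
                    for other in itertools.product((0, 1), repeat=3):
                        if all(o >= b for o, b in zip(other, corner)):
                            assert t[other]
            # and the all-zero corner is never on
            assert not t[(0, 0, 0)] or not c.gates

    def test_depth_guard(self):
        with pytest.raises(ValueError):
            enumerate_circuits(4)
        with pytest.raises(ValueError, match="explode"):
            enumerate_circuits(3)

    def test_idealized_depth_one_matches_boolean(self):
        for c in iter_layered_circuits(1):
            ic = idealize_params(c)
            ranges = {w: (0.01, 1.0) for w in c.inputs}
            assert digitize(ic, ranges)[c.outputs[0]].bits == boolean_table(c).bits


class TestNamedCircuits:
    def test_pulse_circuit_logic(self):
        t = boolean_table(pulse_circuit())
        for g, o, a in itertools.product((0, 1), repeat=3):
            assert t[(g, o, a)] == bool(g and a and not o)

    def test_with_params_replaces_by_id(self):
        c = pulse_circuit()
        new = c.with_params({"and1": AndGateParams(K=1e-4)})
        assert new.gate("and1").params.K == 1e-4
        assert new.gate("out").params == AndnGateParams()
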