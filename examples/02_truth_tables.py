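"""Digitize the 3-input pulse circuit and survey reachable logic.

The pulse circuit computes (glucose AND acetate) AND NOT low-oxygen.
Digitization evaluates the analog steady state at all 8 sensor corners
and thresholds at the geometric mean of the extremes; enumeration counts
how many distinct 3-input truth tables depth-<=2 layered circuits reach.
"""

from fermlogic.circuits import (
    digitize,
    enumerate_circuits,
    idealize_params,
    pulse_circuit,
)

circuit = pulse_circuit()
ranges = {w: (0.01, 1.0) for w in circuit.inputs}
table = digitize(idealize_params(circuit), ranges)["out"]
print("corner table (x1=glucose, x2=low_oxygen, x3=acetate):")
print(table.to_csv())

reachable = enumerate_circuits(max_depth=2)
print(f"distinct truth tables at depth <= 2: {len(reachable)} (ceiling 256)")
print("The single 1-row at 1,0,1 is the pulse condition: glucose and")
print("acetate present while oxygen is still available.")
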