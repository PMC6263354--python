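"""File formats and run provenance.

Time courses travel as long-format CSV (``time_h,series,value``), netlists
as JSON or YAML with explicit per-gate parameter records, and every CLI
run writes a manifest (command, config echo, seeds, package version,
input digests) so a run can be reproduced bit-for-bit from its run
directory.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .circuits import Circuit, CircuitError
from .dynamics import TimeCourse
from .gates import (
    AndGateParams,
    AndnGateParams,
    Gate,
    RepressorGateParams,
)

__all__ = [
    "read_timecourse_csv",
    "write_timecourse_csv",
    "read_netlist",
    "write_netlist",
    "circuit_to_dict",
    "circuit_from_dict",
    "RunManifest",
]


class ParseError(ValueError):
    """Malformed input file; the message names the offending lines."""


def write_timecourse_csv(tcs: Mapping[str, TimeCourse], path) -> None:
    frames = [
        pd.DataFrame({"time_h": tc.times, "series": name, "value": tc.values})
        for name, tc in tcs.items()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_timecourse_csv(path) -> dict[str, TimeCourse]:
    """Parse a ``time_h,series,value`` CSV into one TimeCourse per series.

    Times must be strictly ascending within each series; violations are
    reported with their line numbers (header = line 1).
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    required = ["time_h", "series", "value"]
    if list(df.columns[:3]) != required:
        raise ParseError(
            f"{path}: header must start with {','.join(required)}, "
            f"got {','.join(map(str, df.columns[:3]))}"
        )
    out: dict[str, TimeCourse] = {}
    df["_line"] = df.index + 2  # header is line 1
    for name, grp in df.groupby("series", sort=False):
        t = grp["time_h"].to_numpy(dtype=float)
        bad = grp["_line"].to_numpy()[1:][(t[1:] - t[:-1]) <= 0]
        if len(bad):
            raise ParseError(
                f"{path}: series {name!r} has unsorted or duplicate times "
                f"at lines {bad.tolist()}"
            )
        out[str(name)] = TimeCourse(t, grp["value"].to_numpy(dtype=float), str(name))
    return out


# ---------------------------------------------------------------------------
# netlists

_PARAM_TYPES = {
    "NOT": RepressorGateParams,
    "NOR": RepressorGateParams,
    "AND": AndGateParams,
    "ANDN": AndnGateParams,
}


def circuit_to_dict(circuit: Circuit) -> dict:
    return {
        "inputs": list(circuit.inputs),
        "gates": [
            {
                "id": g.id,
                "kind": g.kind,
                "inputs": list(g.inputs),
                "params": asdict(g.params),
            }
            for g in circuit.gates
        ],
        "outputs": list(circuit.outputs),
    }


def circuit_from_dict(d: Mapping) -> Circuit:
    errors: list[str] = []
    for key in ("inputs", "gates", "outputs"):
        if key not in d:
            errors.append(f"missing key {key!r}")
    if errors:
        raise CircuitError("; ".join(errors))
    gates = []
    for gd in d["gates"]:
        try:
            kind = gd["kind"]
            ptype = _PARAM_TYPES.get(kind)
            if ptype is None:
                errors.append(f"gate {gd.get('id')!r}: unknown kind {kind!r}")
                continue
            params = ptype(**gd.get("params", {})) if gd.get("params") else ptype()
            gates.append(Gate(gd["id"], kind, tuple(gd["inputs"]), params))
        except (KeyError, TypeError, ValueError) as exc:
            errors.append(f"gate {gd.get('id')!r}: {exc}")
    if errors:
        raise CircuitError("; ".join(errors))
    return Circuit(tuple(d["inputs"]), tuple(gates), tuple(d["outputs"]))


def read_netlist(path) -> Circuit:
    """Load and validate a JSON or YAML netlist (extension decides)."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise CircuitError(f"{path}: netlist must be a mapping")
    return circuit_from_dict(data)


def write_netlist(circuit: Circuit, path) -> None:
    path = Path(path)
    d = circuit_to_dict(circuit)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


# ---------------------------------------------------------------------------
# provenance


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance for one CLI run; serialised as manifest.json."""

    command: str
    config: dict = field(default_factory=dict)
    seed: int | None = None
    inputs: dict = field(default_factory=dict)  # path -> sha256
    package_version: str = ""
    python_version: str = field(default_factory=platform.python_version)
    timestamp: str = ""

    def add_input(self, path) -> None:
        p = Path(path)
        self.inputs[str(p)] = _sha256(p)

    def write(self, run_dir) -> Path:
        from . import __version__

        self.package_version = self.package_version or __version__
        self.timestamp = self.timestamp or datetime.now(timezone.utc).isoformat()
        out = Path(run_dir) / "manifest.json"
        out.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")
        return out

    def digest(self) -> str:
        """Stable digest of everything except the timestamp."""
        d = asdict(self)
        d.pop("timestamp")
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()
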