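"""Combinatorial design of operator-embedded constitutive promoters.

Transcription-factor operators (CRP, FNR, FruR) are embedded into σ70
constitutive promoter backbones to create signal-responsive promoters: a
backbone is a fixed −35..−1 core flanked by random spacers (−60..−35 and
+1..+50), and operators are placed at every position (single insertions)
or in pairs at named sites with varied spacing (dual insertions).  The
finished 150 bp designs are screened for synthesis- and function-
compromising features: duplicated ≥6 bp direct repeats, BsaI recognition
sites (Golden-Gate cloning conflicts, both strands), and spurious σ70
promoter-like −35/−10 pairs outside the intended core.  Passing designs
are finalised into 190 bp oligos by adding 20 bp amplification ends.

Coordinates are 0-based half-open throughout; designs live on the sense
strand, the BsaI screen checks both strands.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

__all__ = [
    "Operator",
    "Backbone",
    "DesignSpec",
    "LibraryMember",
    "LibrarySummary",
    "OPERATORS",
    "DEFAULT_TAILS",
    "generate_backbones",
    "scan_insert",
    "dual_insert",
    "apply_filters",
    "finalize_oligo",
    "build_library",
    "default_design_spec",
    "load_synthetic_cores",
    "write_fasta",
    "write_metadata",
    "library_hash",
]

log = logging.getLogger(__name__)

_BASES = "ACGT"
_BSAI = "GGTCTC"
_BSAI_RC = "GAGACC"
_MINUS35 = "TTGACA"
_MINUS10 = "TATAAT"

#: Consensus operator sequences for the three sensing transcription factors.
OPERATORS: dict[str, str] = {
    "CRP": "AAATGTGATCTAGATCACATTT",
    "FNR": "TTGATTTACATCAA",
    "FruR": "GCTGAAACGTTTCAAG",
}

#: 20 bp amplification ends (primer-annealing regions; the BsaI-carrying
#: 5' extensions belong to the PCR primers, not the synthesized oligo).
DEFAULT_TAILS: tuple[str, str] = (
    "AACTCAACTCCTGTGGCGTG",
    "CCACTCACGTATACGTGCGA",
)


def _check_dna(seq: str) -> str:
    seq = seq.upper()
    if set(seq) - set(_BASES):
        raise ValueError(f"non-ACGT characters in sequence: {seq[:30]}...")
    return seq


@dataclass(frozen=True)
class Operator:
    """A transcription-factor binding site to embed into a backbone."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _check_dna(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Backbone:
    """An assembled constitutive promoter design of fixed length.

    ``sequence`` spans upstream spacer (−60..−35), core (−35..−1) and
    downstream spacer (+1..+50 region, padded to the design length);
    element coordinates are 0-based half-open into ``sequence``.
    """

    name: str
    sequence: str
    core_name: str
    minus35: tuple[int, int]
    minus10: tuple[int, int]
    plus1: int
    core_span: tuple[int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _check_dna(self.sequence))
        for lo, hi in (self.minus35, self.minus10, self.core_span):
            if not (0 <= lo < hi <= len(self.sequence)):
                raise ValueError("element coordinates outside the sequence")
        if not 0 <= self.plus1 <= len(self.sequence):
            raise ValueError("+1 coordinate outside the sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class LibraryMember:
    """One designed promoter plus its provenance.

    ``filter_status`` is None before screening, an empty tuple for a pass,
    or the tuple of failure reasons.
    """

    sequence: str
    backbone: str
    operators: tuple[str, ...]
    positions: tuple[int, ...]
    mode: str
    filter_status: tuple[str, ...] | None = None

    @property
    def passed(self) -> bool:
        return self.filter_status == ()

    @property
    def member_id(self) -> str:
        pos = "_".join(str(p) for p in self.positions)
        ops = "-".join(self.operators)
        return f"lib_{self.backbone}_{ops}_{pos}"


@dataclass(frozen=True)
class DesignSpec:
    """Everything build_library needs: backbones, operators, geometry,
    screening rules, tails and the spacer-randomisation seed."""

    backbones: tuple[Backbone, ...]
    operators: tuple[Operator, ...]
    design_length: int = 150
    dual_sites: tuple[str, ...] = ("plus1", "minus10_minus35_spacer", "upstream_minus35")
    dual_spacings: tuple[int, ...] = tuple(range(-6, 7))
    dual_site_shifts: tuple[int, ...] = tuple(range(-6, 7))
    amplification_tails: tuple[str, str] = DEFAULT_TAILS
    filters: frozenset[str] = frozenset({"repeat", "bsai", "sigma70"})
    min_repeat_len: int = 6
    insertion_mode: str = "replace"
    rng_seed: int = 7

    def __post_init__(self) -> None:
        if any(abs(o) > 6 for o in self.dual_spacings):
            raise ValueError("dual spacing offsets limited to ±6 bp")
        if any(abs(o) > 6 for o in self.dual_site_shifts):
            raise ValueError("dual site shifts limited to ±6 bp")
        longest = max((len(op) for op in self.operators), default=0)
        if self.design_length <= longest:
            raise ValueError("design_length must exceed the longest operator")
        for t in self.amplification_tails:
            if len(t) != 20:
                raise ValueError("amplification tails must be 20 bp")
            _check_dna(t)


# ---------------------------------------------------------------------------
# screening filters


def _kmers(seq: str, k: int) -> list[str]:
    return [seq[i : i + k] for i in range(len(seq) - k + 1)]


def has_repeat(seq: str, min_len: int = 6) -> bool:
    """True if any exact direct repeat of length >= min_len occurs twice
    (equivalently: any duplicated min_len-mer)."""
    seen: set[str] = set()
    for km in _kmers(seq, min_len):
        if km in seen:
            return True
        seen.add(km)
    return False


def has_bsai(seq: str) -> bool:
    """BsaI recognition site on either strand."""
    return _BSAI in seq or _BSAI_RC in seq


def _near_matches(seq: str, motif: str, max_mm: int = 1) -> np.ndarray:
    """Start positions where ``motif`` matches with <= max_mm mismatches."""
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    m = np.frombuffer(motif.encode(), dtype=np.uint8)
    n = len(codes) - len(m) + 1
    if n <= 0:
        return np.empty(0, dtype=int)
    mism = np.zeros(n, dtype=np.int16)
    for i, c in enumerate(m):
        mism += codes[i : i + n] != c
    return np.nonzero(mism <= max_mm)[0]


def spurious_promoter_pairs(
    seq: str,
    whitelist: tuple[tuple[int, int], tuple[int, int]] | None = None,
    spacer_range: tuple[int, int] = (15, 19),
) -> list[tuple[int, int]]:
    """σ70 promoter-like pairs: a ≤1-mismatch −35 (TTGACA) followed
    ``spacer_range`` bp later by a ≤1-mismatch −10 (TATAAT).  The pair at
    the whitelisted (intended core) coordinates is ignored."""
    p35 = _near_matches(seq, _MINUS35)
    if len(p35) == 0:
        return []
    p10 = set(_near_matches(seq, _MINUS10).tolist())
    if not p10:
        return []
    wl = None
    if whitelist is not None:
        wl = (whitelist[0][0], whitelist[1][0])
    lo, hi = spacer_range
    pairs = []
    for a in p35.tolist():
        for gap in range(lo, hi + 1):
            b = a + 6 + gap
            if b in p10 and (a, b) != wl:
                pairs.append((a, b))
    return pairs


def apply_filters(
    seq: str,
    spec: DesignSpec | None = None,
    whitelist: tuple[tuple[int, int], tuple[int, int]] | None = None,
) -> tuple[str, ...]:
    """Screen one sequence; returns the tuple of failure reasons (empty
    means pass).  ``whitelist`` protects the intended core's −35/−10 pair
    from the spurious-promoter screen."""
    seq = _check_dna(seq)
    enabled = spec.filters if spec is not None else frozenset({"repeat", "bsai", "sigma70"})
    min_rep = spec.min_repeat_len if spec is not None else 6
    reasons = []
    if "repeat" in enabled and has_repeat(seq, min_rep):
        reasons.append("repeat")
    if "bsai" in enabled and has_bsai(seq):
        reasons.append("bsai")
    if "sigma70" in enabled and spurious_promoter_pairs(seq, whitelist):
        reasons.append("sigma70")
    return tuple(reasons)


# ---------------------------------------------------------------------------
# backbone assembly


def load_synthetic_cores() -> dict[str, str]:
    """Bundled σ70-style core promoter sequences (−35..−1, 35 bp).

    These are synthetic stand-ins constructed around the σ70 consensus
    hexamers, not the registry sequences of the named promoters the
    original library used; supply real core sequences through a custom
    DesignSpec to reproduce a specific published backbone.
    """
    text = resources.files("fermlogic.data").joinpath(
        "backbone_cores_synthetic.yaml"
    ).read_text()
    data = yaml.safe_load(text)
    return {k: _check_dna(v) for k, v in data["cores"].items()}


def _screened_spacer(
    length: int, rng: np.random.Generator, blocked: set[str], min_rep: int = 6
) -> str:
    """Draw a random spacer with no duplicated 6-mer internally or against
    ``blocked`` (core and companion-spacer k-mers), no BsaI site and no
    σ70 consensus hexamer.  Built incrementally with limited backtracking;
    100 consecutive restarts raise."""
    for _attempt in range(100):
        out: list[str] = []
        seen: set[str] = set()
        dead = False
        while len(out) < length and not dead:
            for _trial in range(24):
                base = _BASES[rng.integers(4)]
                cand = "".join(out[-(min_rep - 1):]) + base
                window = "".join(out[-9:]) + base
                if len(cand) == min_rep and (cand in seen or cand in blocked):
                    continue
                if _BSAI in window or _BSAI_RC in window:
                    continue
                if _MINUS35 in window or _MINUS10 in window:
                    continue
                out.append(base)
                if len(cand) == min_rep:
                    seen.add(cand)
                break
            else:
                dead = True  # painted into a corner; restart
        if not dead:
            return "".join(out)
    raise RuntimeError("spacer generation failed 100 consecutive times")


def assemble_backbone(
    name: str,
    core_name: str,
    core: str,
    upstream: str,
    downstream: str,
    minus35_offset: int = 0,
    minus10_offset: int = 23,
) -> Backbone:
    """Concatenate upstream spacer + core + downstream spacer and record
    element coordinates."""
    core = _check_dna(core)
    up = _check_dna(upstream)
    down = _check_dna(downstream)
    u = len(up)
    return Backbone(
        name=name,
        sequence=up + core + down,
        core_name=core_name,
        minus35=(u + minus35_offset, u + minus35_offset + 6),
        minus10=(u + minus10_offset, u + minus10_offset + 6),
        plus1=u + len(core),
        core_span=(u, u + len(core)),
    )


def generate_backbones(
    cores: Mapping[str, str] | None = None,
    n_spacers: int = 3,
    seed: int = 7,
    design_length: int = 150,
    upstream_len: int = 25,
) -> list[Backbone]:
    """|cores| × n_spacers backbones from seeded random spacers.

    Each backbone gets its own screened spacer pair (drawn and re-drawn
    until the full assembly passes the repeat/BsaI/σ70 screens), so the
    backbones themselves are filter-clean and the operator-insertion step
    is the only source of member-level filter failures.  Deterministic
    for a fixed seed.
    """
    if cores is None:
        cores = load_synthetic_cores()
    core_len = len(next(iter(cores.values())))
    if any(len(c) != core_len for c in cores.values()):
        raise ValueError("all core sequences must share one length")
    down_len = design_length - upstream_len - core_len
    if down_len <= 0:
        raise ValueError("design_length too short for the core and spacer")
    rng = np.random.default_rng(seed)
    backbones = []
    for core_name, core in cores.items():
        core_kmers = set(_kmers(core, 6))
        for i in range(n_spacers):
            for _attempt in range(100):
                up = _screened_spacer(upstream_len, rng, core_kmers)
                down = _screened_spacer(
                    down_len, rng, core_kmers | set(_kmers(up, 6))
                )
                bb = assemble_backbone(
                    f"{core_name}_s{i + 1}", core_name, core, up, down
                )
                # junction windows can still collide; screen the assembly
                if apply_filters(bb.sequence, None, (bb.minus35, bb.minus10)) == ():
                    backbones.append(bb)
                    break
            else:
                raise RuntimeError(
                    f"backbone assembly for {core_name} failed 100 times"
                )
    return backbones


# ---------------------------------------------------------------------------
# insertion


def _place(
    backbone: Backbone,
    pieces: Sequence[tuple[int, str]],
    mode: str,
) -> str | None:
    """Place operator ``pieces`` (start, sequence) into the backbone.

    replace: overwrite in place, preserving total length; insert: splice
    in, growing the sequence.  Returns None when out of bounds.
    """
    seq = backbone.sequence
    if mode == "replace":
        out = list(seq)
        for start, op in pieces:
            if start < 0 or start + len(op) > len(seq):
                return None
            out[start : start + len(op)] = op
        return "".join(out)
    if mode == "insert":
        out_s = seq
        offset = 0
        for start, op in sorted(pieces):
            pos = start + offset
            if pos < 0 or pos > len(out_s):
                return None
            out_s = out_s[:pos] + op + out_s[pos:]
            offset += len(op)
        return out_s
    raise ValueError(f"unknown insertion mode {mode!r}")


def scan_insert(
    backbone: Backbone,
    op: Operator,
    mode: str = "replace",
    positions: Iterable[int] | None = None,
) -> list[LibraryMember]:
    """One candidate per position at single-nucleotide resolution.

    Default scans the full feasible span: length L and operator length m
    give L - m + 1 replace candidates.
    """
    if len(op) >= len(backbone):
        raise ValueError("operator must be shorter than the backbone")
    if positions is None:
        stop = len(backbone) - len(op) + 1 if mode == "replace" else len(backbone) + 1
        positions = range(stop)
    members = []
    for p in positions:
        seq = _place(backbone, [(p, op.sequence)], mode)
        if seq is None:
            continue
        members.append(
            LibraryMember(
                sequence=seq,
                backbone=backbone.name,
                operators=(op.name,),
                positions=(p,),
                mode=mode,
            )
        )
    return members


_NOMINAL_GAP = 6  # bp between paired operators before the ±6 variation


def _dual_anchor(backbone: Backbone, site: str, total_len: int) -> int:
    if site == "plus1":
        return backbone.plus1
    if site == "minus10_minus35_spacer":
        return backbone.minus35[1]
    if site == "upstream_minus35":
        return backbone.minus35[0] - total_len
    raise ValueError(f"unknown dual-insertion site {site!r}")


def dual_insert(
    backbone: Backbone,
    op_a: Operator,
    op_b: Operator,
    site: str,
    spacings: Iterable[int] = tuple(range(-6, 7)),
    site_shifts: Iterable[int] = (0,),
    mode: str = "replace",
) -> list[LibraryMember]:
    """Operator pairs at a named site with varied geometry.

    The pair sits op_a, gap, op_b with a nominal 6 bp gap; ``spacings``
    varies the gap by ±6 bp (0..12 bp) and ``site_shifts`` moves the pair
    anchor by ±6 bp.  Geometrically infeasible combinations (pair runs
    off the design) are skipped with a logged reason.
    """
    members = []
    for shift in site_shifts:
        for ds in spacings:
            gap = _NOMINAL_GAP + ds
            if gap < 0:
                log.debug(
                    "skip %s %s+%s at %s: negative gap %d",
                    backbone.name, op_a.name, op_b.name, site, gap,
                )
                continue
            total = len(op_a) + gap + len(op_b)
            start_a = _dual_anchor(backbone, site, total) + shift
            start_b = start_a + len(op_a) + gap
            seq = _place(
                backbone,
                [(start_a, op_a.sequence), (start_b, op_b.sequence)],
                mode,
            )
            if seq is None:
                log.debug(
                    "skip %s %s+%s at %s: pair does not fit (start %d)",
                    backbone.name, op_a.name, op_b.name, site, start_a,
                )
                continue
            members.append(
                LibraryMember(
                    sequence=seq,
                    backbone=backbone.name,
                    operators=(op_a.name, op_b.name),
                    positions=(start_a, start_b),
                    mode=mode,
                )
            )
    return members


# ---------------------------------------------------------------------------
# oligo finalisation and library assembly


def finalize_oligo(member: LibraryMember, spec: DesignSpec) -> str:
    """tail + design + tail for synthesis; rejects members that have not
    passed screening and junctions that create a BsaI site."""
    if member.filter_status != ():
        raise ValueError("only filter-passing members can be finalised")
    t5, t3 = spec.amplification_tails
    oligo = t5 + member.sequence + t3
    for junction in (
        oligo[len(t5) - 5 : len(t5) + 5],
        oligo[-len(t3) - 5 : -len(t3) + 5],
    ):
        if _BSAI in junction or _BSAI_RC in junction:
            raise ValueError("amplification-tail junction creates a BsaI site")
    return oligo


@dataclass(frozen=True)
class LibrarySummary:
    """Counts from one build: raw candidates, passes, failures by reason,
    and per-backbone / per-operator pass counts."""

    n_raw: int
    n_pass: int
    n_duplicates: int
    by_reason: Mapping[str, int]
    by_backbone: Mapping[str, int]
    by_operator: Mapping[str, int]
    n_infeasible_dual: int = 0


def build_library(spec: DesignSpec) -> tuple[list[LibraryMember], LibrarySummary]:
    """Deduplicated union of all single- and dual-insertion candidates
    passing the screen, plus a summary report.

    Deterministic for a fixed spec (the backbones carry the randomness,
    already frozen by their seed).  Raises with the filter breakdown if
    nothing passes.
    """
    raw: list[LibraryMember] = []
    n_infeasible = 0
    for bb in spec.backbones:
        for op in spec.operators:
            raw.extend(scan_insert(bb, op, mode=spec.insertion_mode))
        for op_a in spec.operators:
            for op_b in spec.operators:
                if op_a.name == op_b.name:
                    continue
                for site in spec.dual_sites:
                    got = dual_insert(
                        bb, op_a, op_b, site,
                        spacings=spec.dual_spacings,
                        site_shifts=spec.dual_site_shifts,
                        mode=spec.insertion_mode,
                    )
                    n_infeasible += (
                        len(spec.dual_spacings) * len(spec.dual_site_shifts)
                        - len(got)
                    )
                    raw.extend(got)

    whitelists = {bb.name: (bb.minus35, bb.minus10) for bb in spec.backbones}
    by_reason: dict[str, int] = {}
    by_backbone: dict[str, int] = {}
    by_operator: dict[str, int] = {}
    passed: list[LibraryMember] = []
    seen_seqs: set[str] = set()
    n_dup = 0
    for m in raw:
        reasons = apply_filters(m.sequence, spec, whitelists[m.backbone])
        m = replace(m, filter_status=reasons)
        if reasons:
            for r in reasons:
                by_reason[r] = by_reason.get(r, 0) + 1
            continue
        if m.sequence in seen_seqs:
            n_dup += 1
            continue
        seen_seqs.add(m.sequence)
        passed.append(m)
        by_backbone[m.backbone] = by_backbone.get(m.backbone, 0) + 1
        for opn in m.operators:
            by_operator[opn] = by_operator.get(opn, 0) + 1

    summary = LibrarySummary(
        n_raw=len(raw),
        n_pass=len(passed),
        n_duplicates=n_dup,
        by_reason=by_reason,
        by_backbone=by_backbone,
        by_operator=by_operator,
        n_infeasible_dual=n_infeasible,
    )
    if not passed:
        raise RuntimeError(f"empty library; filter breakdown: {by_reason}")
    return passed, summary


def default_design_spec(seed: int = 7) -> DesignSpec:
    """The shipped default: 12 backbones (4 synthetic cores × 3 seeded
    spacers), all three operators, full-span singles and two-dial duals."""
    backbones = tuple(generate_backbones(seed=seed))
    operators = tuple(Operator(k, v) for k, v in OPERATORS.items())
    return DesignSpec(backbones=backbones, operators=operators, rng_seed=seed)


# ---------------------------------------------------------------------------
# output


def write_fasta(members: Sequence[LibraryMember], path) -> None:
    """FASTA wrapped at 80 columns, headers lib_<backbone>_<ops>_<pos>."""
    records = [
        SeqRecord(Seq(m.sequence), id=m.member_id, description="")
        for m in members
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
        writer.write_file(records)


def write_metadata(members: Sequence[LibraryMember], path) -> None:
    """Companion TSV: member id, backbone, operators, positions, status."""
    import pandas as pd

    rows = [
        {
            "member_id": m.member_id,
            "backbone": m.backbone,
            "operators": "-".join(m.operators),
            "positions": ";".join(str(p) for p in m.positions),
            "mode": m.mode,
            "filter_status": "pass" if m.passed else ";".join(m.filter_status or ()),
        }
        for m in members
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def library_hash(members: Sequence[LibraryMember]) -> str:
    """sha256 over the concatenated FASTA text; determinism fingerprint."""
    text = "".join(f">{m.member_id}\n{m.sequence}\n" for m in members)
    return hashlib.sha256(text.encode()).hexdigest()
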