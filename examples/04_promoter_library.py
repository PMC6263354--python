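"""Design an operator-insertion promoter library and inspect the screen.

Builds the full default library: CRP/FNR/FruR operators scanned across 12
sigma70 backbones (singles at every position, pairs at named sites with
varied spacing), screened for repeats, BsaI sites and spurious promoters.
"""

from fermlogic.promoters import (
    build_library,
    default_design_spec,
    finalize_oligo,
    library_hash,
)

spec = default_design_spec(seed=7)
members, summary = build_library(spec)

print(f"raw candidates: {summary.n_raw}")
print(f"passing members: {summary.n_pass} (duplicates removed: {summary.n_duplicates})")
print(f"failures by reason: {dict(summary.by_reason)}")
print(f"per-operator passes: {dict(summary.by_operator)}")
print(f"library sha256: {library_hash(members)[:16]}... (stable for seed 7)")

m = members[0]
oligo = finalize_oligo(m, spec)
print(f"\nexample member {m.member_id}:")
print(f"  design ({len(m.sequence)} bp): {m.sequence[:60]}...")
print(f"  synthesis oligo ({len(oligo)} bp) = 20 bp tail + design + 20 bp tail")
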