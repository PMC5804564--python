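"""Sequence reconciliation of a tagged, point-mutated construct.

The deposition carries a 9-residue N-terminal purification tag and one
depositor-declared Tyr->Trp substitution.  Reconciliation against the
reference database classifies both: the tag span (absent from the
reference but matching a His-tag motif) and the single mutation.
"""

from minidep.fixture_factory import (DefectPlan, make_deposition, mini_ccd,
                                     packaged_schema, refdb_records)
from minidep.pipeline import run_pipeline

dep, _ = make_deposition(DefectPlan(codes=("tag_and_mutation",), seed=1))
result = run_pipeline(dep, packaged_schema(), mini_ccd(), refdb_records(1))

print(f"sample sequence ({len(dep.sample_sequences['A'])} residues):")
print(" ", dep.sample_sequences["A"][:60], "...")
print(f"cross-reference chosen: {result.cross_references[1]}")
for a in result.annotations[1]:
    span = f"{a.start}" if a.start == a.end else f"{a.start}-{a.end}"
    print(f"  residues {span}: {a.cls} ({a.evidence})")
# Two annotation groups: the tag at 1-9 and the engineered mutation at 64.
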