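"""Chimera segmentation of a two-source fusion construct.

A 219-residue construct carries a 16-residue loop grafted from a second
protein.  The jumping-alignment dynamic program assigns every sample
position to a reference, recovering the three segments and the exact
graft boundaries.
"""

from minidep.fixture_factory import chimera_sample, refdb_records
from minidep.sequence_processor import segment_chimera

refdb = refdb_records(1)
sample = chimera_sample(refdb)
cmap, findings = segment_chimera(sample, refdb)

print(f"sample length: {len(sample)}; chimeric: {cmap.is_chimeric}")
for s0, s1, acc, r0, r1 in cmap.segments:
    print(f"  sample {s0:>3}-{s1:<3} -> {acc} residues {r0}-{r1}")
# The middle segment is the grafted loop; flanking segments return to the
# host protein's accession, so the construct needs per-segment source
# annotation rather than a single cross-reference.
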