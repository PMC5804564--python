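"""Dictionary validation of deposition metadata.

Builds the classic source-organism metadata block (a mouse protein
expressed in E. coli from plasmid pET28a), validates it against the
packaged dictionary, then shows how soft limits flag statistically
unusual merging-R values while letting the expected value through.
"""

from minidep.dictionary_engine import check_range, derive_soft_limits, validate_block
from minidep.fixture_factory import packaged_schema, source_organism_block

schema = packaged_schema()
block = source_organism_block()

findings = validate_block(block, schema)
print(f"conformant metadata block -> {len(findings)} findings")

block.tables["entity_src_gen"][0][
    "entity_src_gen.pdbx_host_org_vector_type"] = "plasmide"  # typo
for f in validate_block(block, schema):
    print(f"after introducing a typo -> {f.severity}: {f.code} [{f.item}]")

item = schema.find_item("reflns.pdbx_Rmerge_I_obs")
print(f"\nRmerge soft limits: {item.soft_range}")
for value in (0.7, 13.0, 0.13):
    f = check_range(value, item)
    verdict = "ok" if f is None else f"{f.severity} ({f.code})"
    print(f"  Rmerge = {value:>5}: {verdict}")

lo, hi = derive_soft_limits([0.11, 0.13, 0.15])
print(f"\nthree-sigma band derived from archive-like samples: "
      f"({lo:.2f}, {hi:.2f})")
# A value outside (lo, hi) would be reported to the depositor as an
# outlier; values inside pass without comment.
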