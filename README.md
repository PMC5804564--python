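# minidep

Desk-scale biocuration of macromolecular structure depositions.

Before a crystal structure enters a public archive it passes through a
curation pipeline: its metadata is validated against a data dictionary,
its molecules are organized into entities, every ligand is identified
against a chemical component dictionary (CCD), its sample sequence is
reconciled with the coordinates and a reference database, the model gets
value-added annotation (solvent repositioning under crystal symmetry,
covalent links, secondary structure, assemblies), and a workflow manager
drives the stages in order, schedules release under the one-year hold, and
compiles a findings report for the depositor. `minidep` implements that
whole pipeline as a compact, fully offline Python library for people who
study or teach curation workflows, build validation tooling, or need
reproducible synthetic depositions with known planted defects.

The core pieces, in the field's usual notation:

- **Hard/soft limits** — a value outside its hard range (pH ∉ [0, 14]) is
  an error; outside its soft range a warning. Soft bands follow the
  three-sigma rule, mean ± 3·sd (sample sd, n−1); the merging R value
  R<sub>merge</sub> carries the packaged soft band [0.01, 0.2].
- **Ligand matching** — element-labelled sub-graph isomorphism of the
  bond graph perceived from coordinates (d ≤ r_cov sum + 0.45 Å) into each
  CCD component, scored as
  (mapped atoms + mapped bonds)/(component atoms + component bonds);
  chirality by the signed volume at each stereocenter.
- **Sequence reconciliation** — Smith–Waterman reference search and
  Needleman–Wunsch reconciliation (match +2, mismatch −1, gap −5/−1, free
  reference end gaps), a controlled vocabulary of discrepancy classes, and
  chimera segmentation by a jumping alignment that charges κ = 20 per
  reference switch.
- **Annotation** — waters moved to the symmetry image nearest the polymer
  (enumerating operators × 27 lattice translations), secondary structure
  from backbone H-bond energetics (bond iff
  0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) < −0.5 kcal/mol), and a
  battery of per-structure checks (clashes, occupancies, special
  positions, torsion outliers, metadata consistency, bond-length
  deviations).
- **Workflow** — a six-stage state machine, geographic routing, the
  one-year hold calendar with 3/2/1-month reminders, percentile scores
  `100·(worse + 0.5·ties)/n`, and a deterministic depositor letter.

Everything is exercised on packaged fixtures and a seeded generator
(`fixture_factory`) that produces depositions with defects planted at
known loci — no network, no external databases.

## A worked example

```python
from minidep.fixture_factory import (DefectPlan, make_deposition, mini_ccd,
                                     packaged_schema, refdb_records)
from minidep.pipeline import run_pipeline

dep, _ = make_deposition(DefectPlan(codes=("tag_and_mutation",), seed=1))
result = run_pipeline(dep, packaged_schema(), mini_ccd(), refdb_records(1))
print(result.cross_references[1])
for a in result.annotations[1]:
    print(a.start, a.end, a.cls)
```

prints

```
REF001
1 9 expression tag
64 64 mutation
```

meaning: the construct cross-references accession REF001; residues 1–9 of
the sample sequence are absent from the reference and match a His-tag
motif, so they are annotated as an N-terminal expression tag; and the
single Tyr→Trp conflict at sample position 64, declared engineered by the
depositor, is annotated as a mutation. The `examples/` directory holds one
short script per capability (metadata validation, ligand identification,
sequence reconciliation, chimera segmentation, structural annotation,
workflow and release), each printing what it computes and what the numbers
mean.

A thin CLI wraps the same library:

```
minidep fixtures --plan chirality_flip --seed 2 --out fx/
minidep curate fx/deposition.cif --ccd fx/ccd.cif --refdb fx/refdb.fasta
minidep release-plan --deposited 2016-01-15 --published 2016-06-01
```

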