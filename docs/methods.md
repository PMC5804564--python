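# Methods

`minidep` reimplements, at desk scale, the curation pipeline that
macromolecular structure depositions pass through before archival release:
dictionary-driven metadata validation, entity transformation, ligand
identification, sequence reconciliation, value-added structural annotation,
and workflow/release management. Everything runs on packaged or generated
inputs; no network service, archive dictionary or external database is
consulted. This note records the models, the parameters that matter, and
the design decisions taken where the problem left room.

## Dictionary validation

Deposition metadata is a set of string-valued category tables, exactly as
it appears in a PDBx/mmCIF file (`"?"` unknown, `"."` inapplicable). The
packaged dictionary (`data/mini_schema.txt`, seven categories) declares per
item: a type (`text|int|float|enum|date`), whether it is mandatory, an
enumeration, inclusive *hard* and *soft* numeric limits, and parent/child
key links. Hard limits mark physically impossible values and raise errors
(pH outside 0–14); soft limits mark statistically unusual values and raise
warnings. For normally distributed archive quantities the soft band is the
three-standard-deviation rule, `mean ± 3·sd` with the n−1 sample standard
deviation (`derive_soft_limits`); the packaged schema freezes the merging-R
band at 0.01–0.2, so 0.13 passes silently while 0.7 or 13 warn.

Null values skip type/enumeration/range checks but count as missing for
mandatory items. Mandatory-ness is enforced per present category (a block
that legitimately omits a whole category, e.g. `cell` for a non-diffraction
entry, is not penalized item by item; a crystallographic entry missing its
cell is caught by the structure-level metadata check instead). Finding
order is deterministic — block category order, then row, then item — so
reports diff cleanly.

The schema serialization is a deliberately flat one-record-per-line dialect
rather than a DDL2 dictionary grammar; the archive dictionary's *content*
(types, enumerations, limits, keys) is the object of interest here, not its
meta-format.

## Entity transformation

Coordinates are organized as chains → residues → atoms. Entities are
derived as: chains sharing an identical sample sequence form one polymer
entity; all waters (`HOH`/`DOD`) pool into a single water entity; every
other residue instance — nonstandard residues, covalently attached sugars,
free-floating single amino acids — groups by component code into
non-polymer entities. A chain is polymeric when it has at least two
standard residues; single free standard residues are treated as ligands
(threshold configurable, a convention rather than archive policy).

Backbone continuity uses generous covalent windows: peptide C(i)–N(i+1)
within 1.2–1.8 Å, nucleic O3′(i)–P(i+1) within 1.4–1.8 Å. Pairs outside
the window are reported as backbone-linkage breaks with the measured
distance. Chains joined end-to-end by a standard link are merged (the
second chain renumbered to continue the first, the offset logged);
splits at detected breaks require depositor confirmation; a requested
merge without a supporting link is refused and routed to correspondence.
Highest-occupancy alternate conformers are used for all geometry.

Peptide-like small molecules are matched against a peptide reference
dictionary (PRD) by exact component sequence plus linear peptide linkage.
`transform_representation` converts between the two representations: the
non-polymer→polymer direction cuts the perceived graph at amide C–N bonds
(a C–N bond where the carbon also bears an oxygen), matches every fragment
to an amino-acid component (terminal fragments may carry OXT), and requires
the fragments to chain linearly; anything else is refused with the
offending atom set. Round trips conserve atoms and molecular formula.

## Ligand identification

Bond perception is the covalent-radius rule: atoms bond iff their distance
is at most r_cov(a) + r_cov(b) + 0.45 Å (classic single-bond radii,
packaged in `geometry.py`); atoms closer than 0.01 Å are duplicate-position
errors. Hydrogens are excluded from matching by default.

The CCD search tests element-labelled sub-graph isomorphism of the
perceived instance graph into each component's heavy-atom graph (networkx
monomorphism), so partially modeled ligands still hit. The match score is

    score = (n_mapped_atoms + n_mapped_bonds) / (n_component_atoms + n_component_bonds)

which is 1.0 exactly for full isomorphism. This formula, and the
auto-apply threshold of 1.0 for atom-name standardization, are package
definitions — the ranking concept exists in curation practice without a
published formula. Ties in score break by component id; among automorphic
atom mappings the lexicographically smallest is reported, so results are
reproducible run to run. Bond orders are *not* used in matching (deposited
coordinates carry none) and default to single, flagged for review, when a
new component is registered; registration refuses ids already taken and
graphs isomorphic to an existing component.

Chirality uses the signed volume of the triple product from each mapped
stereocenter to its first three ordered neighbors, compared with the
component's stored parity; |V| < 0.1 Å³ is indeterminate (near-planar)
rather than wrong. CIP priorities are not implemented; with the ordered
neighbor lists stored in the mini CCD the pass/fail decisions are
identical.

## Sequence reconciliation

Pairwise alignment is Bio.Align.PairwiseAligner with match +2, mismatch −1,
gap open −5, gap extend −1; reference search is local (Smith–Waterman),
reconciliation is global with free end gaps on the reference so tags pay
nothing. Hits below score 30 are dropped; taxonomy agreement with the
declared source organism breaks score ties. All positions are 1-based,
ranges inclusive.

Discrepancies classify in fixed order: terminal sample-only spans are
expression tags when they contain a packaged tag motif (6×His, thrombin,
TEV, Strep, FLAG, myc) or are depositor-declared, else cloning artifacts;
internal sample-only spans are insertions (linkers when declared);
reference-only spans are deletions; single-column conflicts are mutations
when declared engineered, variants when the reference records one, else
conflicts raised for correspondence; sample positions absent from the
coordinates are unmodeled. The motif table is an explicit surrogate for the
depositor's free-text construct description.

Chimera segmentation is a jumping alignment: a dynamic program threads the
sample through all references at once, per-position state = (reference,
reference position); diagonal moves score match/mismatch, re-anchoring to
any position of any reference costs κ = 20. The optimal path maximizes
total segment score minus κ per switch in a single exact DP (rather than a
two-stage extract-hits-then-chain heuristic, which is ambiguous when one
reference's alignment spans the grafted region). Traceback prefers
diagonal continuation on ties, then the lexicographically earlier
accession. Runs shorter than 10 positions are absorbed into the
higher-scoring flank: a span that short (an affinity tag, a linker) can
match a stretch of some unrelated reference by chance and is not evidence
of chimerism. κ, the minimum segment length and the alignment scores are
configuration with these defaults.

Residue-label repair relabels residues modeled as ALA/GLY, or with
sidechains incomplete for their labeled type, to the sample residue —
atoms untouched — and never auto-relabels a residue carrying its complete
sidechain (that conflict goes to correspondence).

## Structural annotation

*Solvent repositioning*: each water's images under all space-group
operators × lattice translations in {−1,0,1}³ are enumerated; the image
nearest any polymer atom wins (ties: lowest operator index, then
translation, lexicographically). Waters whose minimal achievable distance
exceeds 5.0 Å are flagged distant. Space-group operators come from gemmi's
tables via the Hermann–Mauguin symbol; fractional↔orthogonal conversion
uses the standard orthogonalization matrix (round-trip < 1e−9 Å).

*Links*: inter-residue heavy-atom pairs within the covalent window
[r_cov − 0.4, r_cov + 0.45] Å, excluding standard backbone bonds between
consecutive residues and water contacts — disulfides, glycosylation,
ligand attachments.

*Secondary structure*: backbone H-bond energetics,
E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol with the amide
H placed 1.0 Å from N opposite the preceding carbonyl; a bond exists below
−0.5 kcal/mol. Two consecutive (i, i+4) turns make residues i+1..i+4
helical; antiparallel/parallel bridge patterns mark strands; the rest is
coil. No 3₁₀/π subclasses or bends; residues with missing backbone atoms
are coil with a note. The assignment depends only on distances, hence is
rigid-motion invariant.

*Assemblies*: depositor-declared Cartesian operators are validated for
orthonormality (1e−6) and applied; the identity reproduces coordinates
bitwise, copies get the operator id as a chain suffix, and per-entity copy
counts are cross-checked against the declared oligomeric state. Interface
energetics (which assembly is biologically the right one) are out of
scope; only operator application and stoichiometry are performed.

*Hetero renumbering*: ligands and waters attach to the chain owning their
nearest polymer atom (ties to the lexicographically smaller chain id within
1e−6 Å), ligands numbering from 501 and waters from 1001 per chain in input
order; the map is recorded and the operation is idempotent.

*Extended checks* and their thresholds (all configuration, none archive
policy): clashes — non-bonded heavy-atom pairs closer than the van der
Waals sum minus 0.4 Å, excluding pairs within three bonds of each other
and pairs inside the covalent window; occupancies outside (0, 1]; zero
B-factors; hydrogens with no bonded heavy atom; atoms mapped onto
themselves by a symmetry operator within 0.3 Å whose occupancy is not
1/multiplicity; φ/ψ outside permissive boxes (glycine exempt; torsions
only computed across intact peptide bonds); model-vs-experiment wavelength
difference > 0.01 Å; absent free-R flag, anisotropic-B and completeness
metadata; backbone bonds deviating > 4σ from standard reference values
(N–CA 1.458(19), CA–C 1.525(21), C–O 1.231(20), C–N 1.329(14), CA–CB
1.530(20) Å) and ligand bonds deviating > 4σ (σ = 0.025 Å) from the
matched component's ideal geometry.

## Workflow and release

The six curation stages run in fixed order; a module may start only when
all predecessors are complete, and restarting a module resets it and all
successors (verified by exhaustive bounded event enumeration). Depositions
route geographically: Americas/Oceania, Europe/Africa and Asia to the
three regional centers. The release calendar enforces the one-year hold:
expiry is deposit + 12 calendar months (day-of-month preserved, clamped to
month end), reminders at −3, −2, −1 months, publication triggers release
at the next weekly release day (Wednesday by default, capped at expiry),
no event releases at expiry, withdrawal stops the calendar. Percentile
scores are `100·(worse + 0.5·ties)/n` against a reference cohort, oriented
by whether higher is better. The depositor letter is plain-text templating
with severity-major ordering; counts always conserve the finding multiset,
and any error-severity finding sets the overall status to
`needs_depositor`.

## The synthetic deposition generator

`fixture_factory.make_deposition` builds, deterministically per (plan,
seed), a defect-free base entry: a 30-residue idealized α-helix (backbone
+ CB from standard internal geometry, φ/ψ = −57°/−47°), one
N-acetylglucosamine ligand placed 3.4–6 Å from the chain, five waters at
identity-optimal symmetry positions 2.9–4.5 Å from the polymer, a
monoclinic P 1 2 1 cell, and clean reflection metadata including the
source-organism block (mouse protein, E. coli host, taxonomy ids
10090/562, plasmid pET28a). Each requested defect is planted exactly once
with its locus and the expected finding code recorded in a manifest; the
planted single-defect depositions produce exactly that finding and no
other error. Two constructs reproduce classic curation situations: a
9-residue N-terminal His-tag plus a declared Tyr→Trp substitution at
sample position 64, and a 219-residue chimera whose positions 182–197 come
from a second reference accession.

What the generator emulates: entity structure, covalent geometry, crystal
symmetry, metadata linkage, and the defect classes the checks target. What
it does not: experimental noise (coordinates are exact ideal geometry, so
geometry checks see either 0σ or the planted deviation), electron density
and structure factors (represented only as metadata stubs), full sidechains
(backbone + CB only), conformational heterogeneity, and realistic solvent
networks. Passing tests therefore demonstrate that each check detects its
target signature and nothing else under clean conditions — not calibrated
false-positive rates on real data.

The random chimera generator for boundary-recovery experiments
(`make_chimera_case`) enforces junction identifiability: the four residues
straddling each graft junction differ between the two sources. Without
this, a few percent of random constructs carry a junction residue matching
both sources, in which case two segmentations of identical optimal score
describe the same sequence and "the planted boundary" is not a property of
the generated data — no method could recover it. With identifiable
junctions, recovery is exact across seeds.

## Known limitations

- The dictionary is a seven-category subset; DDL2 parsing, date arithmetic
  beyond ISO parsing, and the archive's full item set are out of scope.
- Ligand matching is topology-only (elements + connectivity); no
  aromaticity, tautomer or protonation perception, no SMILES input.
- Sequence machinery assumes the protein alphabet by default; nucleic-acid
  mode reuses the same scoring machinery but has no dedicated scoring
  matrix.
- Oligosaccharide (branched-entity) representation, NMR chemical-shift
  remapping, map-based validation and interface-energy assembly ranking
  are not implemented.
- All thresholds named above are package defaults chosen to be defensible
  at desk scale; none should be cited as archive policy.
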