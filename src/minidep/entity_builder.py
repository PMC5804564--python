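"""Deposition data model and entity-level curation.

A deposition's coordinates are organized as chains of residues of atoms.
Curation groups them into *entities* — chemically distinct molecules, each
possibly instantiated several times: polymer entities (chains sharing one
sample sequence), non-polymer entities (ligand instances grouped by
component code) and a single pooled water entity.

The operations here mirror the first curation stage: classify polymer vs
non-polymer vs water, detect standard backbone linkage (peptide C–N,
nucleic-acid O3'–P), split or merge depositor chains according to the
detected links and the depositor's stated intent, recognize peptide-like
small molecules against a peptide reference dictionary (PRD), and
transform such molecules between their polymer and non-polymer
representations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .dictionary_engine import DataBlock
from .findings import Finding
from .geometry import COVALENT_RADII, AssemblyOp

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}
NUCLEOTIDES = {"A", "C", "G", "U", "DA", "DC", "DG", "DT", "DU"}
WATER_COMP_IDS = {"HOH", "DOD"}

#: covalent windows for standard backbone links, Å (configurable)
PEPTIDE_BOND_WINDOW = (1.2, 1.8)
NUCLEIC_BOND_WINDOW = (1.4, 1.8)


@dataclass
class AtomRecord:
    name: str
    element: str
    xyz: Tuple[float, float, float]
    occupancy: float = 1.0
    b_factor: float = 20.0
    alt_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.element.upper() not in COVALENT_RADII:
            raise ValueError(f"unknown element {self.element!r}")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")


@dataclass
class ResidueRecord:
    comp_id: str
    seq_num: int
    atoms: List[AtomRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for a in self.atoms:
            key = (a.name, a.alt_id)
            if key in seen:
                raise ValueError(
                    f"{self.comp_id} {self.seq_num}: duplicate atom {a.name}")
            seen.add(key)

    def atom(self, name: str) -> Optional[AtomRecord]:
        """Highest-occupancy conformer of a named atom (ties: alt id order)."""
        candidates = [a for a in self.atoms if a.name == name]
        if not candidates:
            return None
        return max(candidates, key=lambda a: (a.occupancy, -(ord(a.alt_id) if a.alt_id else 0)))

    @property
    def is_water(self) -> bool:
        return self.comp_id in WATER_COMP_IDS

    @property
    def is_standard_aa(self) -> bool:
        return self.comp_id in AA_3TO1

    @property
    def is_standard_nucleotide(self) -> bool:
        return self.comp_id in NUCLEOTIDES

    @property
    def is_standard_polymer_comp(self) -> bool:
        return self.is_standard_aa or self.is_standard_nucleotide


@dataclass
class ChainRecord:
    chain_id: str
    residues: List[ResidueRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        nums = [r.seq_num for r in self.residues]
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise ValueError(f"chain {self.chain_id}: seq numbers not increasing")

    def polymer_residues(self) -> List[ResidueRecord]:
        return [r for r in self.residues if r.is_standard_polymer_comp]


@dataclass
class EntityRecord:
    entity_id: int
    etype: str  # polymer | non-polymer | water
    sample_sequence: Optional[str] = None
    instances: List = field(default_factory=list)  # chain ids or (chain, seq_num)
    comp_id: Optional[str] = None  # for non-polymer entities
    source: Optional[Tuple[str, int, str]] = None  # (scientific_name, tax_id, production)

    def __post_init__(self) -> None:
        if (self.etype == "polymer") != (self.sample_sequence is not None):
            raise ValueError("polymer entities carry a sample sequence, others do not")


@dataclass
class Deposition:
    """The unit flowing through the curation pipeline."""

    dep_id: str
    chains: List[ChainRecord] = field(default_factory=list)
    entities: List[EntityRecord] = field(default_factory=list)
    metadata: DataBlock = field(default_factory=lambda: DataBlock("meta"))
    assemblies: List[List[AssemblyOp]] = field(default_factory=list)
    ligands_of_interest: List[str] = field(default_factory=list)
    sample_sequences: Dict[str, str] = field(default_factory=dict)
    declarations: Dict[str, object] = field(default_factory=dict)

    def chain(self, chain_id: str) -> Optional[ChainRecord]:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        return None


# ---------------------------------------------------------------------------
# entity construction

def build_entities(
    chains: Sequence[ChainRecord],
    sample_sequences: Mapping[str, str],
) -> Tuple[List[EntityRecord], List[Finding]]:
    """Group chains and residues into entities.

    Chains with identical sample sequences share one polymer entity; all
    waters pool into a single water entity; every other non-polymer residue
    instance is grouped by component code.  Covalently attached sugars and
    other ligands embedded in polymer chains become separate non-polymer
    entities.
    """
    findings: List[Finding] = []
    entities: List[EntityRecord] = []
    next_id = 1
    seq_to_entity: Dict[str, EntityRecord] = {}
    nonpoly: Dict[str, EntityRecord] = {}
    water_instances: List[Tuple[str, int]] = []

    for chain in chains:
        poly = chain.polymer_residues()
        if len(poly) >= 2:
            seq = sample_sequences.get(chain.chain_id)
            if seq is None:
                findings.append(Finding(
                    "missing_sequence", locus=chain.chain_id,
                    message=f"polymer chain {chain.chain_id} has no sample sequence"))
            else:
                ent = seq_to_entity.get(seq)
                if ent is None:
                    ent = EntityRecord(entity_id=next_id, etype="polymer",
                                       sample_sequence=seq)
                    next_id += 1
                    seq_to_entity[seq] = ent
                    entities.append(ent)
                ent.instances.append(chain.chain_id)
        for res in chain.residues:
            if res.is_water:
                water_instances.append((chain.chain_id, res.seq_num))
            elif not res.is_standard_polymer_comp or len(poly) < 2:
                # nonstandard residues, and free standard residues in a
                # chain too short to be polymeric, become ligand instances
                ent = nonpoly.get(res.comp_id)
                if ent is None:
                    ent = EntityRecord(entity_id=0, etype="non-polymer",
                                       comp_id=res.comp_id)
                    nonpoly[res.comp_id] = ent
                ent.instances.append((chain.chain_id, res.seq_num))
    for comp_id in sorted(nonpoly):
        ent = nonpoly[comp_id]
        entities.append(replace(ent, entity_id=next_id, instances=ent.instances))
        next_id += 1
    if water_instances:
        entities.append(EntityRecord(entity_id=next_id, etype="water",
                                     comp_id="HOH", instances=water_instances))
    return entities, findings


# ---------------------------------------------------------------------------
# backbone linkage

def _link_geometry(prev: ResidueRecord, curr: ResidueRecord):
    """Measured backbone-link distance between consecutive residues.

    Returns (kind, distance) where kind is 'peptide' or 'nucleic', or
    (None, reason) when the relevant backbone atoms are absent.
    """
    if prev.is_standard_aa or curr.is_standard_aa:
        a, b = prev.atom("C"), curr.atom("N")
        kind = "peptide"
    else:
        a, b = prev.atom("O3'"), curr.atom("P")
        kind = "nucleic"
    if a is None or b is None:
        return None, "missing_atom"
    d = float(np.linalg.norm(np.asarray(a.xyz) - np.asarray(b.xyz)))
    return kind, d


def detect_polymer_links(chain: ChainRecord) -> Tuple[List[dict], List[Finding]]:
    """Classify each consecutive residue pair as linked or broken.

    A peptide link requires C(i)–N(i+1) within 1.2–1.8 Å; a nucleic-acid
    link O3'(i)–P(i+1) within 1.4–1.8 Å.  Pairs outside the window are
    reported as breaks carrying the measured distance; missing backbone
    atoms are breaks with reason ``missing_atom``.
    """
    links: List[dict] = []
    breaks: List[Finding] = []
    poly = chain.polymer_residues()
    for prev, curr in zip(poly, poly[1:]):
        kind, d = _link_geometry(prev, curr)
        locus = (chain.chain_id, prev.seq_num)
        if kind is None:
            breaks.append(Finding(
                "Polymer backbone linkage", locus=locus,
                message=f"link {prev.seq_num}-{curr.seq_num}: {d}"))
            continue
        lo, hi = PEPTIDE_BOND_WINDOW if kind == "peptide" else NUCLEIC_BOND_WINDOW
        if lo <= d <= hi:
            links.append({"chain": chain.chain_id, "from": prev.seq_num,
                          "to": curr.seq_num, "kind": kind, "distance": d})
        else:
            breaks.append(Finding(
                "Polymer backbone linkage", locus=locus,
                message=(f"no standard {kind} link between residues "
                         f"{prev.seq_num} and {curr.seq_num}: {d:.2f} A")))
    return links, breaks


def _terminal_link(chain_a: ChainRecord, chain_b: ChainRecord):
    """Backbone-link geometry from the last residue of A to the first of B."""
    pa = chain_a.polymer_residues()
    pb = chain_b.polymer_residues()
    if not pa or not pb:
        return None, "missing_atom"
    return _link_geometry(pa[-1], pb[0])


def split_or_merge(
    chains: Sequence[ChainRecord],
    depositor_intent: Optional[Mapping[str, object]] = None,
) -> Tuple[List[ChainRecord], List[Finding]]:
    """Merge covalently continuous chains; split confirmed breaks.

    Two depositor chains joined end-to-end by a standard backbone link are
    merged into one chain, the second renumbered to continue the first
    (original numbers logged).  A chain with an unbridged internal break
    splits only on depositor confirmation (``intent["split"]``).  A merge
    requested without a supporting link is refused with an error finding.
    """
    intent = dict(depositor_intent or {})
    requested_merges = {tuple(p) for p in intent.get("merge", [])}
    requested_splits = set(intent.get("split", []))
    findings: List[Finding] = []
    chains = list(chains)

    # resolve merges (detected link, or requested + verified)
    merged = True
    while merged:
        merged = False
        for i, a in enumerate(chains):
            for j, b in enumerate(chains):
                if i == j or not a.polymer_residues() or not b.polymer_residues():
                    continue
                kind, d = _terminal_link(a, b)
                linked = kind is not None and (
                    (PEPTIDE_BOND_WINDOW if kind == "peptide"
                     else NUCLEIC_BOND_WINDOW)[0] <= d <=
                    (PEPTIDE_BOND_WINDOW if kind == "peptide"
                     else NUCLEIC_BOND_WINDOW)[1])
                wanted = (a.chain_id, b.chain_id) in requested_merges
                if linked:
                    offset = a.residues[-1].seq_num + 1 - b.residues[0].seq_num
                    renumbered = [replace(r, seq_num=r.seq_num + offset)
                                  for r in b.residues]
                    findings.append(Finding(
                        "merge_applied", locus=(a.chain_id, b.chain_id),
                        message=(f"chains {a.chain_id}+{b.chain_id} merged; "
                                 f"{b.chain_id} renumbered by {offset:+d}")))
                    chains[i] = ChainRecord(chain_id=a.chain_id,
                                            residues=a.residues + renumbered)
                    del chains[j]
                    requested_merges.discard((a.chain_id, b.chain_id))
                    merged = True
                    break
            if merged:
                break
    for pair in sorted(requested_merges):
        findings.append(Finding(
            "merge_conflict", locus=tuple(pair),
            message=(f"merge of {pair[0]} and {pair[1]} requested but no "
                     "standard backbone link found; depositor correspondence needed")))

    # resolve splits at detected breaks
    out: List[ChainRecord] = []
    for chain in chains:
        if chain.chain_id not in requested_splits:
            out.append(chain)
            continue
        _, breaks = detect_polymer_links(chain)
        break_after = {f.locus[1] for f in breaks}
        if not break_after:
            out.append(chain)
            continue
        part: List[ResidueRecord] = []
        idx = 0
        for res in chain.residues:
            part.append(res)
            if res.seq_num in break_after:
                cid = chain.chain_id if idx == 0 else f"{chain.chain_id}{idx}"
                out.append(ChainRecord(chain_id=cid, residues=part))
                findings.append(Finding(
                    "split_applied", locus=(chain.chain_id, res.seq_num),
                    message=f"chain {chain.chain_id} split after residue {res.seq_num}"))
                part = []
                idx += 1
        if part:
            cid = chain.chain_id if idx == 0 else f"{chain.chain_id}{idx}"
            out.append(ChainRecord(chain_id=cid, residues=part))
    return out, findings


# ---------------------------------------------------------------------------
# peptide reference dictionary (PRD)

@dataclass(frozen=True)
class PrdEntry:
    """A peptide-like small molecule: component sequence plus linkage."""

    prd_id: str
    components: Tuple[str, ...]
    linkage: str = "linear-peptide"


def match_prd(molecule, prd_db: Sequence[PrdEntry], ccd=None) -> Optional[str]:
    """Identify a peptide-like molecule against the PRD.

    ``molecule`` may be a :class:`ChainRecord` (polymer representation) or a
    single :class:`ResidueRecord` ligand (non-polymer representation, which
    is first transformed to polymer form using the chemical component
    dictionary).  Returns the PRD id whose component sequence and linear
    linkage match exactly, else ``None``.
    """
    if isinstance(molecule, ResidueRecord):
        if ccd is None:
            return None
        try:
            molecule = transform_representation(molecule, "to_polymer", ccd)
        except TransformError:
            return None
    comps = tuple(r.comp_id for r in molecule.residues)
    for entry in prd_db:
        if entry.components == comps and entry.linkage == "linear-peptide":
            return entry.prd_id
    return None


# ---------------------------------------------------------------------------
# polymer <-> non-polymer transformation

class TransformError(ValueError):
    """Raised when a ligand cannot be partitioned into polymer components."""

    def __init__(self, message: str, offending_atoms=()):
        super().__init__(message)
        self.offending_atoms = tuple(offending_atoms)


def _residue_graph(residue: ResidueRecord):
    from .ligand_processor import perceive_graph
    return perceive_graph(residue)


def transform_representation(molecule, direction: str, ccd) -> object:
    """Convert between polymer and non-polymer representations.

    ``to_polymer`` partitions the ligand's perceived bond graph at amide
    C–N bonds and matches every fragment to an amino-acid component of the
    CCD (terminal fragments may carry an OXT); a molecule that does not
    partition raises :class:`TransformError` naming the offending atoms.
    ``to_non_polymer`` flattens a chain into one residue with uniquified
    atom names.  Atom counts are conserved and a round trip restores an
    isomorphic graph.
    """
    import networkx as nx

    from .ligand_processor import component_graph, perceive_graph

    if direction == "to_non_polymer":
        atoms: List[AtomRecord] = []
        for i, res in enumerate(molecule.residues, start=1):
            for a in res.atoms:
                atoms.append(replace(a, name=f"{a.name}{i}"))
        return ResidueRecord(comp_id="LIG", seq_num=1, atoms=atoms)
    if direction != "to_polymer":
        raise ValueError(f"unknown direction {direction!r}")

    residue: ResidueRecord = molecule
    pg = perceive_graph(residue)
    g = nx.Graph()
    for idx, element in pg.nodes:
        g.add_node(idx, element=element)
    g.add_edges_from(pg.edges)
    atom_by_idx = {i: residue.atoms[i] for i, _ in pg.nodes}

    # candidate peptide bonds: C-N where the carbon also bonds an O
    cuts = []
    for u, v in g.edges:
        eu, ev = g.nodes[u]["element"], g.nodes[v]["element"]
        if {eu, ev} != {"C", "N"}:
            continue
        c = u if eu == "C" else v
        if any(g.nodes[w]["element"] == "O" for w in g.neighbors(c)):
            cuts.append((u, v))
    h = g.copy()
    h.remove_edges_from(cuts)
    fragments = [sorted(c) for c in nx.connected_components(h)]

    aa_comps = [c for c in ccd if c.comp_id in AA_3TO1]
    assigned: List[Tuple[list, str, dict]] = []
    for frag in fragments:
        sub = g.subgraph(frag)
        hit = None
        for comp in aa_comps:
            for drop_oxt in (True, False):
                cg = component_graph(comp, include_hydrogens=False)
                if drop_oxt and "OXT" in cg:
                    cg = cg.copy()
                    cg.remove_node("OXT")
                gm = nx.algorithms.isomorphism.GraphMatcher(
                    sub, cg,
                    node_match=lambda a, b: a["element"] == b["element"])
                if gm.is_isomorphic():
                    hit = (comp.comp_id, dict(gm.mapping))
                    break
            if hit:
                break
        if hit is None:
            names = [atom_by_idx[i].name for i in frag]
            raise TransformError(
                f"fragment {names} matches no amino-acid component", names)
        assigned.append((frag, hit[0], hit[1]))

    # order fragments along the peptide bonds (must form a simple path)
    frag_of = {}
    for k, (frag, _, _) in enumerate(assigned):
        for i in frag:
            frag_of[i] = k
    succ: Dict[int, int] = {}
    indeg = {k: 0 for k in range(len(assigned))}
    for u, v in cuts:
        c = u if g.nodes[u]["element"] == "C" else v
        n = v if c == u else u
        a, b = frag_of[c], frag_of[n]
        if a == b or a in succ:
            raise TransformError("linkage is not a simple peptide chain",
                                 [atom_by_idx[c].name])
        succ[a] = b
        indeg[b] += 1
    starts = [k for k in indeg if indeg[k] == 0]
    if len(assigned) > 1 and len(starts) != 1:
        raise TransformError("linkage is not a single linear chain", [])
    order = [starts[0] if starts else 0]
    while order[-1] in succ:
        order.append(succ[order[-1]])
    if len(order) != len(assigned):
        raise TransformError("cyclic peptide linkage not supported", [])

    residues = []
    for seq, k in enumerate(order, start=1):
        frag, comp_id, mapping = assigned[k]
        atoms = [replace(atom_by_idx[i], name=mapping[i]) for i in frag]
        atoms.sort(key=lambda a: a.name)
        residues.append(ResidueRecord(comp_id=comp_id, seq_num=seq, atoms=atoms))
    return ChainRecord(chain_id="X", residues=residues)
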