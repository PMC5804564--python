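"""Ligand identification against a chemical component dictionary (CCD).

Every non-polymer instance and nonstandard polymeric residue is identified
by perceiving a bond graph from its coordinates (covalent-radius rule) and
searching the CCD by element-labelled sub-graph isomorphism.  A component
is a hit when the instance graph embeds into the component graph, so
partially modeled ligands still match; hits are ranked by

    score = (n_mapped_atoms + n_mapped_bonds) / (n_component_atoms + n_component_bonds)

with 1.0 meaning exact isomorphism.  Atom nomenclature is standardized to
the matched component, chirality is checked by the signed volume of each
mapped stereocenter, and genuinely novel ligands are registered as new
components.

Bond orders are not used for matching — deposited coordinates carry no
orders — and hydrogens are excluded by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform

from .entity_builder import ResidueRecord
from .findings import Finding
from .geometry import BOND_TOLERANCE, covalent_radius

BOND_ORDERS = ("single", "double", "triple", "aromatic")


class PerceptionError(ValueError):
    pass


class IdCollisionError(ValueError):
    pass


class DuplicateComponentError(ValueError):
    def __init__(self, comp_id: str):
        super().__init__(f"graph is isomorphic to existing component {comp_id}")
        self.comp_id = comp_id


@dataclass(frozen=True)
class ChemComp:
    """Reference chemical component definition."""

    comp_id: str
    atoms: Tuple[Tuple[str, str, int], ...]  # (name, element, formal_charge)
    bonds: Tuple[Tuple[str, str, str], ...]  # (name_a, name_b, order)
    stereocenters: Tuple[Tuple[str, Tuple[str, ...], int], ...] = ()
    ideal_xyz: Optional[Dict[str, Tuple[float, float, float]]] = None

    def __post_init__(self) -> None:
        names = {a[0] for a in self.atoms}
        if len(names) != len(self.atoms):
            raise ValueError(f"{self.comp_id}: duplicate atom names")
        for a, b, order in self.bonds:
            if a not in names or b not in names:
                raise ValueError(f"{self.comp_id}: bond endpoint missing: {a}-{b}")
            if order not in BOND_ORDERS:
                raise ValueError(f"{self.comp_id}: bad bond order {order!r}")
        g = component_graph(self, include_hydrogens=True)
        if g.number_of_nodes() and not nx.is_connected(g):
            raise ValueError(f"{self.comp_id}: component graph not connected")
        for center, neighbors, parity in self.stereocenters:
            if parity not in (1, -1):
                raise ValueError(f"{self.comp_id}: parity must be +/-1")
            if len(neighbors) not in (3, 4):
                raise ValueError(
                    f"{self.comp_id}: stereocenter {center} needs 3 or 4 neighbors")

    def element_of(self, name: str) -> str:
        for n, el, _ in self.atoms:
            if n == name:
                return el
        raise KeyError(name)


def component_graph(comp: ChemComp, include_hydrogens: bool = False) -> nx.Graph:
    """Element-labelled graph of a component (atom names as nodes)."""
    g = nx.Graph()
    keep = {n for n, el, _ in comp.atoms
            if include_hydrogens or el.upper() not in ("H", "D")}
    for name, el, _ in comp.atoms:
        if name in keep:
            g.add_node(name, element=el.upper())
    for a, b, _ in comp.bonds:
        if a in keep and b in keep:
            g.add_edge(a, b)
    return g


@dataclass
class PerceivedGraph:
    """Distance-perceived bond graph of one residue instance."""

    nodes: List[Tuple[int, str]]  # (atom index in residue, element)
    edges: List[Tuple[int, int]]
    source: Optional[tuple] = None
    atom_names: Dict[int, str] = field(default_factory=dict)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for idx, el in self.nodes:
            g.add_node(idx, element=el)
        g.add_edges_from(self.edges)
        return g


def perceive_graph(residue: ResidueRecord, include_hydrogens: bool = False,
                   tolerance: float = BOND_TOLERANCE,
                   source: Optional[tuple] = None) -> PerceivedGraph:
    """Perceive bonds by the covalent-radius rule.

    An edge is drawn between atoms whose distance is at most the sum of
    their covalent radii plus ``tolerance`` (0.45 Å default).  Atoms closer
    than 0.01 Å are rejected as duplicates.
    """
    if not residue.atoms:
        raise PerceptionError("residue has no atoms")
    idx_atoms = [(i, a) for i, a in enumerate(residue.atoms)
                 if include_hydrogens or a.element.upper() not in ("H", "D")]
    if not idx_atoms:
        raise PerceptionError("residue has no heavy atoms")
    coords = np.array([a.xyz for _, a in idx_atoms], dtype=float)
    radii = np.array([covalent_radius(a.element) for _, a in idx_atoms])
    if len(idx_atoms) > 1:
        d = squareform(pdist(coords))
        np.fill_diagonal(d, np.inf)
        if d.min() < 0.01:
            i, j = np.unravel_index(int(d.argmin()), d.shape)
            raise PerceptionError(
                f"duplicate atom positions: {idx_atoms[i][1].name} and "
                f"{idx_atoms[j][1].name} are {d.min():.3f} A apart")
        cut = radii[:, None] + radii[None, :] + tolerance
        edges = [(idx_atoms[i][0], idx_atoms[j][0])
                 for i, j in zip(*np.nonzero(d <= cut)) if i < j]
    else:
        edges = []
    return PerceivedGraph(
        nodes=[(i, a.element.upper()) for i, a in idx_atoms],
        edges=edges, source=source,
        atom_names={i: a.name for i, a in idx_atoms})


@dataclass
class MatchResult:
    comp_id: str
    score: float
    mapping: Dict[str, str]  # instance atom name -> component atom name
    unmatched_component_atoms: List[str] = field(default_factory=list)
    discrepancies: List[Finding] = field(default_factory=list)


def _monomorphisms(inst: nx.Graph, comp: nx.Graph):
    gm = nx.algorithms.isomorphism.GraphMatcher(
        comp, inst, node_match=lambda a, b: a["element"] == b["element"])
    for mapping in gm.subgraph_monomorphisms_iter():
        # mapping: comp node -> inst node; invert
        yield {v: k for k, v in mapping.items()}


def search_ccd(graph: PerceivedGraph, ccd: Sequence[ChemComp],
               min_score: float = 0.0) -> List[MatchResult]:
    """Rank CCD components by sub-graph match against a perceived instance.

    A component is a hit iff the element-labelled instance graph is
    sub-graph-isomorphic to the component's heavy-atom graph.  Ties in
    score break by component id; the atom mapping reported for each hit is
    the lexicographically smallest over all automorphic alternatives, so
    results are deterministic.
    """
    if not ccd:
        raise ValueError("empty chemical component dictionary")
    inst = graph.to_networkx()
    names = graph.atom_names
    results: List[MatchResult] = []
    for comp in ccd:
        cg = component_graph(comp, include_hydrogens=False)
        if inst.number_of_nodes() > cg.number_of_nodes():
            continue
        best: Optional[List[Tuple[int, str]]] = None
        for mapping in _monomorphisms(inst, cg):
            key = sorted(mapping.items())
            if best is None or key < best:
                best = key
        if best is None:
            continue
        mapping = dict(best)
        n_atoms = inst.number_of_nodes()
        n_bonds = inst.number_of_edges()
        denom = cg.number_of_nodes() + cg.number_of_edges()
        score = (n_atoms + n_bonds) / denom if denom else 0.0
        unmatched = sorted(set(cg.nodes) - set(mapping.values()))
        discrepancies = []
        if unmatched:
            discrepancies.append(Finding(
                "not_applicable", locus=graph.source,
                message=(f"{comp.comp_id}: component atoms not modeled in "
                         f"instance: {', '.join(unmatched)}")))
        results.append(MatchResult(
            comp_id=comp.comp_id, score=score,
            mapping={names[i]: cname for i, cname in mapping.items()},
            unmatched_component_atoms=unmatched,
            discrepancies=discrepancies))
    results = [r for r in results if r.score >= min_score]
    results.sort(key=lambda r: (-r.score, r.comp_id))
    return results


def standardize_atoms(graph: PerceivedGraph, match: MatchResult,
                      threshold: float = 1.0) -> Dict[str, str]:
    """Renaming map instance atom -> component atom name.

    Applied automatically only for matches at or above ``threshold``
    (default: exact matches).  A post-renaming collision indicates an
    invalid mapping and raises ``ValueError``.
    """
    if match.score < threshold:
        raise ValueError(
            f"match score {match.score:.3f} below acceptance threshold {threshold}")
    renaming = dict(match.mapping)
    targets = list(renaming.values())
    if len(set(targets)) != len(targets):
        raise ValueError("renaming map is not a bijection: name collision")
    return renaming


def check_chirality(residue: ResidueRecord, comp: ChemComp,
                    mapping: Dict[str, str],
                    volume_tol: float = 0.1,
                    locus: Optional[tuple] = None) -> List[Finding]:
    """Compare each mapped stereocenter's handedness with the component.

    The signed volume (triple product of vectors from the center to its
    first three ordered neighbors) must agree in sign with the component's
    stored parity; an opposite sign is a chirality error, a near-zero
    volume (< ``volume_tol`` Å^3) is indeterminate.
    """
    if locus is None:
        locus = (residue.comp_id, residue.seq_num)
    inv = {cname: iname for iname, cname in mapping.items()}
    findings: List[Finding] = []
    for center, neighbors, parity in comp.stereocenters:
        needed = [center] + list(neighbors[:3])
        inst_names = [inv.get(n) for n in needed]
        if any(n is None for n in inst_names):
            findings.append(Finding(
                "stereocenter_unmapped", locus=locus,
                message=f"stereocenter {center}: neighbor not mapped, skipped"))
            continue
        atoms = [residue.atom(n) for n in inst_names]
        if any(a is None for a in atoms):
            findings.append(Finding(
                "stereocenter_unmapped", locus=locus,
                message=f"stereocenter {center}: atom missing, skipped"))
            continue
        c = np.asarray(atoms[0].xyz)
        v = [np.asarray(a.xyz) - c for a in atoms[1:]]
        vol = float(np.dot(v[0], np.cross(v[1], v[2])))
        if abs(vol) < volume_tol:
            findings.append(Finding(
                "chirality_indeterminate", locus=locus,
                message=f"stereocenter {center}: near-planar (|V|={abs(vol):.3f})"))
        elif (vol > 0) != (parity > 0):
            findings.append(Finding(
                "Chirality error", locus=locus,
                message=(f"stereocenter {center}: inverted configuration "
                         f"(signed volume {vol:+.2f}, expected sign {parity:+d})")))
    return findings


def register_component(graph: PerceivedGraph, proposed_id: str,
                       ccd: List[ChemComp]) -> ChemComp:
    """Create a new CCD component from a perceived graph.

    Bond orders default to single and are flagged for curator review.
    Refuses ids already taken and graphs isomorphic to an existing
    component (which should be identified, not re-registered).
    """
    if any(c.comp_id == proposed_id for c in ccd):
        raise IdCollisionError(f"component id {proposed_id!r} already taken")
    inst = graph.to_networkx()
    for comp in ccd:
        cg = component_graph(comp, include_hydrogens=False)
        if nx.is_isomorphic(inst, cg,
                            node_match=lambda a, b: a["element"] == b["element"]):
            raise DuplicateComponentError(comp.comp_id)
    counters: Dict[str, int] = {}
    names: Dict[int, str] = {}
    for idx, el in graph.nodes:
        counters[el] = counters.get(el, 0) + 1
        names[idx] = f"{el}{counters[el]}"
    comp = ChemComp(
        comp_id=proposed_id,
        atoms=tuple((names[i], el, 0) for i, el in graph.nodes),
        bonds=tuple((names[a], names[b], "single") for a, b in graph.edges),
    )
    ccd.append(comp)
    return comp


# ---------------------------------------------------------------------------
# CCD file format (mmCIF-style chem_comp tables, one block per component)

def write_ccd(comps: Sequence[ChemComp]) -> str:
    from gemmi import cif

    doc = cif.Document()
    for comp in comps:
        block = doc.add_new_block(comp.comp_id)
        block.set_pair("_chem_comp.id", comp.comp_id)
        loop = block.init_loop("_chem_comp_atom.", [
            "comp_id", "atom_id", "type_symbol", "charge",
            "model_Cartn_x_ideal", "model_Cartn_y_ideal", "model_Cartn_z_ideal"])
        for name, el, charge in comp.atoms:
            if comp.ideal_xyz and name in comp.ideal_xyz:
                x, y, z = comp.ideal_xyz[name]
                xyz = [f"{x:.3f}", f"{y:.3f}", f"{z:.3f}"]
            else:
                xyz = ["?", "?", "?"]
            loop.add_row([comp.comp_id, cif.quote(name), el, str(charge)] + xyz)
        if comp.bonds:
            loop = block.init_loop("_chem_comp_bond.", [
                "comp_id", "atom_id_1", "atom_id_2", "value_order"])
            for a, b, order in comp.bonds:
                loop.add_row([comp.comp_id, cif.quote(a), cif.quote(b), order])
        if comp.stereocenters:
            loop = block.init_loop("_minidep_stereo.", [
                "comp_id", "center", "neighbors", "parity"])
            for center, neighbors, parity in comp.stereocenters:
                loop.add_row([comp.comp_id, cif.quote(center),
                              cif.quote(" ".join(neighbors)), f"{parity:+d}"])
    return doc.as_string()


def read_ccd(source) -> List[ChemComp]:
    import os

    from gemmi import cif

    if isinstance(source, (str, os.PathLike)) and os.path.exists(str(source)):
        doc = cif.read_file(str(source))
    else:
        doc = cif.read_string(str(source))
    comps: List[ChemComp] = []
    for block in doc:
        atoms = []
        ideal: Dict[str, Tuple[float, float, float]] = {}
        tab = block.find("_chem_comp_atom.", [
            "atom_id", "type_symbol", "charge",
            "model_Cartn_x_ideal", "model_Cartn_y_ideal", "model_Cartn_z_ideal"])
        for row in tab:
            name = cif.as_string(row[0])
            atoms.append((name, cif.as_string(row[1]), int(row[2])))
            if row[3] != "?":
                ideal[name] = (float(row[3]), float(row[4]), float(row[5]))
        bonds = []
        for row in block.find("_chem_comp_bond.", ["atom_id_1", "atom_id_2", "value_order"]):
            bonds.append((cif.as_string(row[0]), cif.as_string(row[1]),
                          cif.as_string(row[2])))
        stereo = []
        for row in block.find("_minidep_stereo.", ["center", "neighbors", "parity"]):
            stereo.append((cif.as_string(row[0]),
                           tuple(cif.as_string(row[1]).split()), int(row[2])))
        comps.append(ChemComp(
            comp_id=block.name, atoms=tuple(atoms), bonds=tuple(bonds),
            stereocenters=tuple(stereo), ideal_xyz=ideal or None))
    return comps
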