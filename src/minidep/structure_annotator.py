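"""Value-added structural annotation.

The annotation stage runs after entities, ligands and sequences are
settled: it moves waters to the symmetry image nearest the asymmetric
unit's polymer, generates non-backbone covalent links (disulfides,
glycosylation, ligand attachments), assigns secondary structure from
backbone hydrogen-bond energetics, expands declared assembly operators
into quaternary structures, re-numbers ligands and waters onto their
owning polymer chains, and runs the battery of per-structure checks that
feed the curation issue vocabulary (clashes, occupancies, B-factors,
special positions, torsion outliers, wavelength and structure-factor
metadata consistency, reference bond-length deviations).

Thresholds (distant-water 5.0 Å, clash gap 0.4 Å, special-position 0.3 Å,
wavelength 0.01 Å) are package defaults, not archive policy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .dictionary_engine import DataBlock
from .entity_builder import (AA_3TO1, ChainRecord, Deposition, ResidueRecord,
                             detect_polymer_links)
from .findings import Finding
from .geometry import (AssemblyOp, CellParams, SymOp, covalent_radius,
                       space_group_ops, vdw_radius)
from .ligand_processor import ChemComp

DISTANT_WATER_CUTOFF = 5.0  # Å
CLASH_GAP = 0.4  # Å subtracted from the vdW sum
SPECIAL_POSITION_TOL = 0.3  # Å
WAVELENGTH_TOL = 0.01  # Å
HBOND_ENERGY_CUTOFF = -0.5  # kcal/mol
BOND_SIGMA_FACTOR = 4.0

#: reference backbone bond lengths (Å) with standard deviations
BACKBONE_BOND_REFS = {
    ("N", "CA"): (1.458, 0.019),
    ("CA", "C"): (1.525, 0.021),
    ("C", "O"): (1.231, 0.020),
    ("CA", "CB"): (1.530, 0.020),
}
PEPTIDE_C_N_REF = (1.329, 0.014)
LIGAND_BOND_SIGMA = 0.025  # Å, default sigma for CCD ideal-geometry bonds

#: permissive phi/psi boxes (deg); a residue outside all of them is flagged
PHI_PSI_BOXES = (
    ((-180.0, -30.0), (60.0, 180.0)),    # beta / PPII
    ((-180.0, -30.0), (-180.0, -150.0)),  # beta (wrapped)
    ((-180.0, -30.0), (-120.0, 50.0)),   # right-handed helical
    ((20.0, 100.0), (-60.0, 90.0)),      # left-handed helical
)


class OperatorError(ValueError):
    pass


# ---------------------------------------------------------------------------
# helpers

def cell_from_metadata(meta: DataBlock) -> Optional[CellParams]:
    rows = meta.rows("cell")
    if not rows:
        return None
    r = rows[0]
    try:
        return CellParams(
            a=float(r["cell.length_a"]), b=float(r["cell.length_b"]),
            c=float(r["cell.length_c"]), alpha=float(r["cell.angle_alpha"]),
            beta=float(r["cell.angle_beta"]), gamma=float(r["cell.angle_gamma"]))
    except (KeyError, ValueError):
        return None


def ops_from_metadata(meta: DataBlock) -> Optional[List[SymOp]]:
    rows = meta.rows("symmetry")
    if not rows:
        return None
    name = rows[0].get("symmetry.space_group_name_H-M")
    if not name or name in ("?", "."):
        return None
    try:
        return space_group_ops(name)
    except Exception:
        return None


def _polymer_atoms(dep: Deposition):
    coords, loci = [], []
    for chain in dep.chains:
        if len(chain.polymer_residues()) < 2:
            continue
        for res in chain.polymer_residues():
            for a in res.atoms:
                coords.append(a.xyz)
                loci.append((chain.chain_id, res.seq_num, a.name))
    return np.array(coords, dtype=float), loci


def _water_residues(dep: Deposition):
    for chain in dep.chains:
        for res in chain.residues:
            if res.is_water:
                yield chain, res


def dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle in degrees."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1 /= np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    return math.degrees(math.atan2(np.dot(np.cross(b1, v), w), np.dot(v, w)))


# ---------------------------------------------------------------------------
# solvent repositioning

LATTICE_SHIFTS = sorted(product((-1, 0, 1), repeat=3))


def reposition_waters(dep: Deposition, cell: Optional[CellParams] = None,
                      ops: Optional[Sequence[SymOp]] = None,
                      distant_cutoff: float = DISTANT_WATER_CUTOFF,
                      ) -> Tuple[List[dict], List[Finding]]:
    """Move each water to its symmetry image nearest the polymer.

    All images under (space-group operator × lattice translation in
    {-1,0,1}^3) are enumerated; the image minimizing the distance to the
    nearest polymer atom wins (ties: smallest operator index, then
    translation, lexicographically).  Waters whose minimal achievable
    distance exceeds ``distant_cutoff`` are flagged as distant.

    Entries without cell/symmetry information (non-crystallographic) are
    left untouched with an info finding.
    """
    findings: List[Finding] = []
    if cell is None:
        cell = cell_from_metadata(dep.metadata)
    if ops is None:
        ops = ops_from_metadata(dep.metadata)
    if cell is None or not ops:
        findings.append(Finding(
            "not_applicable", message="no cell/symmetry: solvent left in place"))
        return [], findings
    poly_xyz, _ = _polymer_atoms(dep)
    if poly_xyz.size == 0:
        findings.append(Finding(
            "not_applicable", message="no polymer atoms: solvent left in place"))
        return [], findings
    tree = cKDTree(poly_xyz)
    orth = cell.orth_matrix()
    moves: List[dict] = []
    for chain, res in _water_residues(dep):
        oxy = res.atom("O") or res.atoms[0]
        frac = cell.fractionalize(np.asarray(oxy.xyz))
        best = None  # (dist, op_index, shift, new_frac)
        for oi, op in enumerate(ops):
            base = op.apply(frac)
            for shift in LATTICE_SHIFTS:
                f = base + np.asarray(shift, dtype=float)
                xyz = f @ orth.T
                d = float(tree.query(xyz)[0])
                key = (round(d, 9), oi, shift)
                if best is None or key < best[0]:
                    best = (key, f)
        (dist, oi, shift), new_frac = best
        new_xyz = new_frac @ orth.T
        old_xyz = np.asarray(oxy.xyz)
        if not (oi == 0 and shift == (0, 0, 0)) and \
                float(np.linalg.norm(new_xyz - old_xyz)) > 1e-6:
            for a in res.atoms:
                f_a = ops[oi].apply(cell.fractionalize(np.asarray(a.xyz))) + \
                    np.asarray(shift, dtype=float)
                a.xyz = tuple(float(v) for v in (f_a @ orth.T))
            moves.append({"chain": chain.chain_id, "seq_num": res.seq_num,
                          "op_index": oi, "shift": shift,
                          "old_xyz": tuple(float(v) for v in old_xyz),
                          "new_xyz": tuple(float(v) for v in new_xyz),
                          "distance": dist})
        if dist > distant_cutoff:
            findings.append(Finding(
                "Distant waters", locus=(chain.chain_id, res.seq_num),
                message=(f"water {res.seq_num}: nearest polymer atom "
                         f"{dist:.1f} A away in every symmetry image")))
    return moves, findings


# ---------------------------------------------------------------------------
# link generation

def generate_links(dep: Deposition, ccd: Optional[Sequence[ChemComp]] = None,
                   tolerance: float = 0.45) -> Tuple[List[dict], List[Finding]]:
    """Covalent links between residues that are not standard backbone bonds.

    A candidate link is an inter-residue heavy-atom pair within the
    covalent-radius window; consecutive-residue peptide / nucleic-acid
    backbone bonds and water contacts are excluded.
    """
    atoms = []
    for chain in dep.chains:
        poly = {r.seq_num for r in chain.polymer_residues()}
        for res in chain.residues:
            if res.is_water:
                continue
            for a in res.atoms:
                if a.element.upper() in ("H", "D"):
                    continue
                atoms.append((chain.chain_id, res, a, res.seq_num in poly))
    if not atoms:
        return [], []
    coords = np.array([a[2].xyz for a in atoms])
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=2 * 1.96 + tolerance)
    links: List[dict] = []
    for i, j in sorted(pairs):
        ci, ri, ai, pi = atoms[i]
        cj, rj, aj, pj = atoms[j]
        if ri is rj:
            continue
        d = float(np.linalg.norm(coords[i] - coords[j]))
        rc = covalent_radius(ai.element) + covalent_radius(aj.element)
        # below the covalent window the pair is an error, not a bond
        if not (rc - CLASH_GAP <= d <= rc + tolerance):
            continue
        # standard backbone link between consecutive residues of one chain
        if ci == cj and abs(ri.seq_num - rj.seq_num) == 1:
            names = {ai.name, aj.name}
            if names == {"C", "N"} or names == {"O3'", "P"}:
                continue
        links.append({
            "atom1": (ci, ri.seq_num, ri.comp_id, ai.name),
            "atom2": (cj, rj.seq_num, rj.comp_id, aj.name),
            "distance": d,
        })
    return links, []


# ---------------------------------------------------------------------------
# secondary structure

@dataclass
class SecStructAssignment:
    """Per-residue state: H (helix), E (strand) or C (coil)."""

    states: Dict[int, str] = field(default_factory=dict)  # seq_num -> state

    def fraction(self, state: str) -> float:
        if not self.states:
            return 0.0
        return sum(1 for s in self.states.values() if s == state) / len(self.states)


def _hbond_energy(nc, hc, cc, oc) -> float:
    """Electrostatic backbone H-bond energy (kcal/mol)."""
    q = 0.084 * 332.0
    r_on = np.linalg.norm(oc - nc)
    r_ch = np.linalg.norm(cc - hc)
    r_oh = np.linalg.norm(oc - hc)
    r_cn = np.linalg.norm(cc - nc)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return 0.0
    return q * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def assign_secondary_structure(chain: ChainRecord
                               ) -> Tuple[SecStructAssignment, List[Finding]]:
    """Helix/strand/coil assignment from backbone H-bond energetics.

    The amide H is placed 1.0 Å from N opposite the preceding carbonyl;
    an H-bond exists between donor NH(i) and acceptor CO(j) when the
    electrostatic energy falls below −0.5 kcal/mol.  Two consecutive
    (i, i+4) bonds make residues i+1..i+4 helical; antiparallel or
    parallel bridge patterns mark strand residues; everything else is
    coil.  Residues with missing backbone atoms are coil with a note.
    """
    findings: List[Finding] = []
    residues = [r for r in chain.polymer_residues() if r.is_standard_aa]
    n = len(residues)
    coords = {}
    ok = [True] * n
    for i, res in enumerate(residues):
        bb = {}
        for name in ("N", "CA", "C", "O"):
            a = res.atom(name)
            if a is None:
                ok[i] = False
                break
            bb[name] = np.asarray(a.xyz, dtype=float)
        if ok[i]:
            coords[i] = bb
        else:
            findings.append(Finding(
                "not_applicable", locus=(chain.chain_id, res.seq_num),
                message="missing backbone atoms; assigned coil"))

    # donor H positions
    h_pos = {}
    for i in range(1, n):
        if ok[i] and ok[i - 1]:
            d = coords[i - 1]["C"] - coords[i - 1]["O"]
            nrm = np.linalg.norm(d)
            if nrm > 1e-6:
                h_pos[i] = coords[i]["N"] + d / nrm

    hbond = set()  # (donor i, acceptor j): NH(i) ... O=C(j)
    for i in range(n):
        if i not in h_pos or not ok[i]:
            continue
        for j in range(n):
            if not ok[j] or abs(i - j) < 2:
                continue
            e = _hbond_energy(coords[i]["N"], h_pos[i], coords[j]["C"],
                              coords[j]["O"])
            if e < HBOND_ENERGY_CUTOFF:
                hbond.add((i, j))

    states = ["C"] * n
    # helices: consecutive (i, i+4) turns
    for i in range(n - 5):
        if (i + 4, i) in hbond and (i + 5, i + 1) in hbond:
            for k in range(i + 1, i + 5):
                states[k] = "H"
    # bridges (strand)
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            anti = (((i, j) in hbond and (j, i) in hbond)
                    or ((i - 1 >= 0 and j + 1 < n and (j + 1, i - 1) in hbond)
                        and (i + 1 < n and (i + 1, j - 1) in hbond)))
            para = (((j, i - 1) in hbond and (i + 1, j) in hbond)
                    or ((i, j - 1) in hbond and (j + 1, i) in hbond))
            if anti or para:
                for k in (i, j):
                    if states[k] == "C":
                        states[k] = "E"
    for i in range(n):
        if not ok[i]:
            states[i] = "C"
    assignment = SecStructAssignment(
        states={res.seq_num: states[i] for i, res in enumerate(residues)})
    return assignment, findings


# ---------------------------------------------------------------------------
# assemblies

def build_assembly(dep: Deposition, ops: Sequence[AssemblyOp]
                   ) -> Tuple[List[ChainRecord], Dict[int, int]]:
    """Expand the asymmetric unit under Cartesian assembly operators.

    Each chain is copied under each operator; non-identity copies get the
    operator id as a chain-id suffix.  The identity operator reproduces
    coordinates bitwise.  Returns the chains and per-entity copy counts.
    """
    from dataclasses import replace

    for op in ops:
        if not op.is_orthonormal():
            raise OperatorError(f"assembly operator {op.op_id} is not orthonormal")
    chains_out: List[ChainRecord] = []
    for op in ops:
        is_identity = np.allclose(op.matrix(), np.eye(3)) and \
            np.allclose(op.tran, 0.0)
        for chain in dep.chains:
            if is_identity:
                chains_out.append(chain)
                continue
            new_res = []
            for res in chain.residues:
                new_atoms = [replace(a, xyz=tuple(float(v)
                                                  for v in op.apply(np.asarray(a.xyz))))
                             for a in res.atoms]
                new_res.append(ResidueRecord(comp_id=res.comp_id,
                                             seq_num=res.seq_num, atoms=new_atoms))
            chains_out.append(ChainRecord(chain_id=f"{chain.chain_id}_{op.op_id}",
                                          residues=new_res))
    stoich: Dict[int, int] = {}
    chain_entity = {}
    for ent in dep.entities:
        if ent.etype == "polymer":
            for cid in ent.instances:
                chain_entity[cid] = ent.entity_id
    for chain in chains_out:
        base = chain.chain_id.split("_", 1)[0]
        ent = chain_entity.get(base)
        if ent is not None:
            stoich[ent] = stoich.get(ent, 0) + 1
    return chains_out, stoich


# ---------------------------------------------------------------------------
# hetero renumbering

WATER_BASE = 1001
LIGAND_BASE = 501


def renumber_heteros(dep: Deposition) -> Dict[tuple, tuple]:
    """Attach ligands/waters to their nearest polymer chain and renumber.

    Each hetero residue joins the chain owning its nearest polymer atom
    (ties within 1e-6 Å go to the lexicographically smaller chain id).
    Ligands number from 501, waters from 1001, consecutively per chain in
    input order.  Returns the old→new locus map; idempotent.
    """
    poly_chains = [c for c in dep.chains if len(c.polymer_residues()) >= 2]
    if not poly_chains:
        return {}
    trees = []
    for c in poly_chains:
        xyz = np.array([a.xyz for r in c.polymer_residues() for a in r.atoms])
        trees.append((c.chain_id, cKDTree(xyz)))

    assignments: Dict[str, List[Tuple[tuple, ResidueRecord, bool]]] = {
        c.chain_id: [] for c in poly_chains}
    for chain in dep.chains:
        for res in chain.residues:
            is_poly = res.is_standard_polymer_comp and len(chain.polymer_residues()) >= 2
            if is_poly:
                continue
            ref = res.atoms[0]
            dists = sorted(
                (round(float(t.query(np.asarray(ref.xyz))[0]), 6), cid)
                for cid, t in trees)
            target = dists[0][1]
            assignments[target].append(((chain.chain_id, res.seq_num), res,
                                        res.is_water))

    mapping: Dict[tuple, tuple] = {}
    new_chains: List[ChainRecord] = []
    for c in poly_chains:
        residues = [r for r in c.residues
                    if r.is_standard_polymer_comp and len(c.polymer_residues()) >= 2]
        lig_n, wat_n = LIGAND_BASE, WATER_BASE
        ligs = [(old, r) for old, r, w in assignments[c.chain_id] if not w]
        wats = [(old, r) for old, r, w in assignments[c.chain_id] if w]
        for old, r in ligs:
            r.seq_num = lig_n
            mapping[old] = (c.chain_id, lig_n)
            residues.append(r)
            lig_n += 1
        for old, r in wats:
            r.seq_num = wat_n
            mapping[old] = (c.chain_id, wat_n)
            residues.append(r)
            wat_n += 1
        new_chains.append(ChainRecord(chain_id=c.chain_id, residues=residues))
    dep.chains = new_chains
    return mapping


# ---------------------------------------------------------------------------
# extended checks

def _global_bond_graph(dep: Deposition):
    """Atom-level bond graph (perceived intra-residue + backbone + links)."""
    import networkx as nx

    from .ligand_processor import perceive_graph

    g = nx.Graph()
    index = {}
    for chain in dep.chains:
        for res in chain.residues:
            for a in res.atoms:
                key = (chain.chain_id, res.seq_num, a.name)
                index[key] = (a, res)
                g.add_node(key)
            if len(res.atoms) > 1:
                try:
                    pg = perceive_graph(res, include_hydrogens=True)
                except Exception:
                    continue
                for i, j in pg.edges:
                    g.add_edge((chain.chain_id, res.seq_num, res.atoms[i].name),
                               (chain.chain_id, res.seq_num, res.atoms[j].name))
        links, _ = detect_polymer_links(chain)
        for link in links:
            a = "C" if link["kind"] == "peptide" else "O3'"
            b = "N" if link["kind"] == "peptide" else "P"
            g.add_edge((chain.chain_id, link["from"], a),
                       (chain.chain_id, link["to"], b))
    inter_links, _ = generate_links(dep)
    for link in inter_links:
        c1, s1, _, a1 = link["atom1"]
        c2, s2, _, a2 = link["atom2"]
        g.add_edge((c1, s1, a1), (c2, s2, a2))
    return g, index


def extended_checks(dep: Deposition, ccd: Optional[Sequence[ChemComp]] = None,
                    matches: Optional[Dict[tuple, str]] = None) -> List[Finding]:
    """Per-structure quality checks feeding the issue vocabulary.

    Covers atomic clashes, occupancy and B-factor sanity, stray hydrogens,
    special-position occupancies, torsion outliers, wavelength and
    structure-factor metadata consistency, and bond-length deviations from
    reference values for both polymers and ligands.
    """
    import networkx as nx

    findings: List[Finding] = []
    meta = dep.metadata

    # --- occupancy / B-factor / hydrogens
    graph, index = _global_bond_graph(dep)
    for chain in dep.chains:
        for res in chain.residues:
            for a in res.atoms:
                locus = (chain.chain_id, res.seq_num, a.name)
                if a.occupancy <= 0 or a.occupancy > 1:
                    findings.append(Finding(
                        "Atoms with unrealistic or zero occupancies",
                        locus=locus,
                        message=f"occupancy {a.occupancy:g}"))
                if a.b_factor == 0:
                    findings.append(Finding(
                        "Zero B-factor", locus=locus, message="B = 0"))
                if a.element.upper() in ("H", "D"):
                    heavy = [n for n in graph.neighbors(locus)
                             if index[n][0].element.upper() not in ("H", "D")]
                    if not heavy:
                        findings.append(Finding(
                            "Extra hydrogen atoms", locus=locus,
                            message="hydrogen without a bonded heavy atom"))

    # --- clashes
    heavy = [(k, a) for k, (a, _) in index.items()
             if a.element.upper() not in ("H", "D")]
    if len(heavy) > 1:
        coords = np.array([a.xyz for _, a in heavy])
        tree = cKDTree(coords)
        sp = dict(nx.all_pairs_shortest_path_length(graph, cutoff=3))
        for i, j in sorted(tree.query_pairs(r=3.5)):
            ki, ai = heavy[i]
            kj, aj = heavy[j]
            if ki[:2] == kj[:2]:
                continue
            d = float(np.linalg.norm(coords[i] - coords[j]))
            if sp.get(ki, {}).get(kj) is not None:
                continue  # within 3 bonds: covalent context, not a clash
            rc = covalent_radius(ai.element) + covalent_radius(aj.element)
            if rc - CLASH_GAP <= d <= rc + 0.45:
                continue  # plausible covalent link, reported by generate_links
            if d < vdw_radius(ai.element) + vdw_radius(aj.element) - CLASH_GAP:
                findings.append(Finding(
                    "Atomic clashes", locus=ki,
                    message=(f"{'/'.join(map(str, ki))} vs "
                             f"{'/'.join(map(str, kj))}: {d:.2f} A")))

    # --- special positions
    cell = cell_from_metadata(meta)
    ops = ops_from_metadata(meta)
    if cell is not None and ops:
        orth = cell.orth_matrix()
        for chain in dep.chains:
            for res in chain.residues:
                for a in res.atoms:
                    frac = cell.fractionalize(np.asarray(a.xyz))
                    mult = 0
                    for op in ops:
                        img = op.apply(frac)
                        delta = img - frac
                        delta -= np.round(delta)
                        if float(np.linalg.norm(delta @ orth.T)) <= SPECIAL_POSITION_TOL:
                            mult += 1
                    if mult > 1 and abs(a.occupancy - 1.0 / mult) > 0.01:
                        findings.append(Finding(
                            "Occupancy of atoms on special symmetry positions",
                            locus=(chain.chain_id, res.seq_num, a.name),
                            message=(f"site multiplicity {mult} expects occupancy "
                                     f"{1.0 / mult:g}, found {a.occupancy:g}")))

    # --- phi/psi outliers
    for chain in dep.chains:
        residues = [r for r in chain.polymer_residues() if r.is_standard_aa]
        links, _ = detect_polymer_links(chain)
        linked = {(l["from"], l["to"]) for l in links}
        for k in range(1, len(residues) - 1):
            prev, res, nxt = residues[k - 1], residues[k], residues[k + 1]
            if (prev.seq_num, res.seq_num) not in linked or \
                    (res.seq_num, nxt.seq_num) not in linked:
                continue
            if res.comp_id == "GLY":
                continue
            names = (prev.atom("C"), res.atom("N"), res.atom("CA"),
                     res.atom("C"), nxt.atom("N"))
            if any(a is None for a in names):
                continue
            phi = dihedral(names[0].xyz, names[1].xyz, names[2].xyz, names[3].xyz)
            psi = dihedral(names[1].xyz, names[2].xyz, names[3].xyz, names[4].xyz)
            inside = any(plo <= phi <= phi_hi and slo <= psi <= psi_hi
                         for (plo, phi_hi), (slo, psi_hi) in PHI_PSI_BOXES)
            if not inside:
                findings.append(Finding(
                    "Unusual phi/psi torsion angles",
                    locus=(chain.chain_id, res.seq_num),
                    message=f"phi={phi:.0f} psi={psi:.0f} outside permissive regions"))

    # --- polymer geometry
    for chain in dep.chains:
        residues = [r for r in chain.polymer_residues() if r.is_standard_aa]
        for res in residues:
            for (n1, n2), (ref, sigma) in BACKBONE_BOND_REFS.items():
                a, b = res.atom(n1), res.atom(n2)
                if a is None or b is None:
                    continue
                d = float(np.linalg.norm(np.asarray(a.xyz) - np.asarray(b.xyz)))
                if abs(d - ref) > BOND_SIGMA_FACTOR * sigma:
                    findings.append(Finding(
                        "Polymer geometry", locus=(chain.chain_id, res.seq_num),
                        message=(f"{n1}-{n2} bond {d:.3f} A deviates from "
                                 f"{ref:.3f} by more than {BOND_SIGMA_FACTOR:g} sigma")))
        links, _ = detect_polymer_links(chain)
        for link in links:
            if link["kind"] != "peptide":
                continue
            ref, sigma = PEPTIDE_C_N_REF
            if abs(link["distance"] - ref) > BOND_SIGMA_FACTOR * sigma:
                findings.append(Finding(
                    "Polymer geometry", locus=(chain.chain_id, link["from"]),
                    message=(f"peptide C-N bond {link['distance']:.3f} A deviates "
                             f"from {ref:.3f}")))

    # --- ligand geometry against CCD ideal coordinates
    if ccd:
        by_id = {c.comp_id: c for c in ccd}
        for chain in dep.chains:
            poly = {r.seq_num for r in chain.polymer_residues()}
            for res in chain.residues:
                if res.is_water or res.seq_num in poly:
                    continue
                comp = by_id.get(res.comp_id)
                if comp is None or not comp.ideal_xyz:
                    continue
                for a_name, b_name, _ in comp.bonds:
                    a, b = res.atom(a_name), res.atom(b_name)
                    if a is None or b is None:
                        continue
                    if a.element.upper() in ("H", "D") or b.element.upper() in ("H", "D"):
                        continue
                    if a_name not in comp.ideal_xyz or b_name not in comp.ideal_xyz:
                        continue
                    d = float(np.linalg.norm(np.asarray(a.xyz) - np.asarray(b.xyz)))
                    ideal = float(np.linalg.norm(
                        np.asarray(comp.ideal_xyz[a_name])
                        - np.asarray(comp.ideal_xyz[b_name])))
                    if abs(d - ideal) > BOND_SIGMA_FACTOR * LIGAND_BOND_SIGMA:
                        findings.append(Finding(
                            "Ligand geometry",
                            locus=(chain.chain_id, res.seq_num),
                            message=(f"{res.comp_id} {a_name}-{b_name} bond "
                                     f"{d:.3f} A vs ideal {ideal:.3f} A")))

    # --- metadata consistency
    reflns = meta.rows("reflns")
    if not reflns or not meta.rows("cell") or not meta.rows("symmetry"):
        findings.append(Finding(
            "Missing and/or inconsistent metadata values",
            message="cell, symmetry or reflection metadata absent"))
    else:
        r = reflns[0]
        wl_model = r.get("reflns.pdbx_wavelength")
        wl_sf = r.get("reflns.pdbx_sf_wavelength")
        try:
            if wl_model not in (None, "?", ".") and wl_sf not in (None, "?", "."):
                if abs(float(wl_model) - float(wl_sf)) > WAVELENGTH_TOL:
                    findings.append(Finding(
                        "Wavelength discrepancy", item="reflns.pdbx_sf_wavelength",
                        message=(f"model wavelength {wl_model} vs structure-factor "
                                 f"metadata {wl_sf}")))
        except ValueError:
            pass
        if r.get("reflns.pdbx_free_R_flag") != "yes":
            findings.append(Finding(
                "Missing free R test set in the structure factors",
                item="reflns.pdbx_free_R_flag",
                message="free R flag column absent from the structure factors"))
        if r.get("reflns.pdbx_aniso_B") != "yes":
            findings.append(Finding(
                "Missing anisotropic B-factor", item="reflns.pdbx_aniso_B",
                message="anisotropic B-factors not provided"))
        if r.get("reflns.pdbx_sf_complete") == "no":
            findings.append(Finding(
                "Incomplete data in the structure factors",
                item="reflns.pdbx_sf_complete",
                message="structure-factor data flagged incomplete"))

    # --- declared vs generated quaternary structure
    declared = dep.declarations.get("oligomeric_count")
    if declared is not None and dep.assemblies:
        n_poly = sum(1 for c in dep.chains if len(c.polymer_residues()) >= 2)
        generated = n_poly * len(dep.assemblies[0])
        if generated != int(declared):
            findings.append(Finding(
                "Reported and calculated quaternary structure do not agree",
                message=(f"depositor declares {declared} polymer copies, "
                         f"operators generate {generated}")))
    return findings
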