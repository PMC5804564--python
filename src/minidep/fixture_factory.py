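"""Seeded generation of every test input: mini-CCD, PRD, reference FASTA,
schema and depositions with planted defects.

All outputs are deterministic functions of (plan, seed).  The deposition
generator builds a defect-free base entry — an idealized helical protein
chain, one N-acetylglucosamine ligand, a handful of well-placed waters,
monoclinic cell and symmetry, and clean reflection metadata — then plants
each requested defect exactly once, recording the planted locus and the
finding code the pipeline is expected to raise in a manifest.

Two depositions replicate classic curation situations: a 9-residue
N-terminal expression tag plus one depositor-declared Tyr→Trp substitution
at sample position 64 (``tag_and_mutation``), and a 219-residue chimeric
construct whose positions 182–197 come from a second reference accession
(``chimera_swap``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .dictionary_engine import DataBlock, DictionarySchema, load_schema
from .entity_builder import (AA_1TO3, AA_3TO1, AtomRecord, ChainRecord,
                             Deposition, PrdEntry, ResidueRecord)
from .geometry import CellParams, IDENTITY_ASSEMBLY_OP, SymOp, space_group_ops
from .ligand_processor import ChemComp, perceive_graph, write_ccd
from .peptide_builder import (HELIX_PHI_PSI, STRAND_PHI_PSI, build_backbone,
                              place_atom, transform_chain)
from .sequence_processor import RefRecord, write_refdb

# --- worked-example constants (tag span, mutation site, chimera swap)
TAG_SEQUENCE = "GSSHHHHHH"          # 9-residue N-terminal expression tag
MUTATION_SAMPLE_POSITION = 64      # TYR->TRP, 1-based in the sample
MUTATION_REF_POSITION = 55         # = 64 - len(TAG_SEQUENCE)
CHIMERA_LENGTH = 219
SWAP_START, SWAP_END = 182, 197    # 1-based, inclusive
CHIMB_WINDOW_START = 61            # 1-based position of the swap in CHIMB

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"

#: plan code -> finding code the pipeline must raise (None: non-finding check)
PLAN_EXPECTATIONS: Dict[str, Optional[str]] = {
    "chirality_flip": "Chirality error",
    "backbone_break": "Polymer backbone linkage",
    "atomic_clash": "Atomic clashes",
    "zero_occupancy": "Atoms with unrealistic or zero occupancies",
    "zero_b_factor": "Zero B-factor",
    "extra_hydrogen": "Extra hydrogen atoms",
    "special_position_occupancy": "Occupancy of atoms on special symmetry positions",
    "distant_water": "Distant waters",
    "sequence_discrepancy": "Sequence discrepancy",
    "ligand_missing_atom": "ligand_incomplete",
    "ligand_identity": "Ligand identity",
    "ligand_geometry": "Ligand geometry",
    "polymer_geometry": "Polymer geometry",
    "phi_psi_outlier": "Unusual phi/psi torsion angles",
    "wavelength_mismatch": "Wavelength discrepancy",
    "missing_free_r": "Missing free R test set in the structure factors",
    "missing_aniso_b": "Missing anisotropic B-factor",
    "sf_incomplete": "Incomplete data in the structure factors",
    "metadata_missing": "Missing and/or inconsistent metadata values",
    "quaternary_mismatch": "Reported and calculated quaternary structure do not agree",
    "rmerge_outlier": "soft_range",
    "misplaced_water": None,
    "tag_and_mutation": None,
    "chimera_swap": None,
}


@dataclass(frozen=True)
class DefectPlan:
    codes: Tuple[str, ...] = ()
    seed: int = 1

    def __post_init__(self) -> None:
        unknown = [c for c in self.codes if c not in PLAN_EXPECTATIONS]
        if unknown:
            raise ValueError(f"unknown defect codes: {unknown}")
        if len(set(self.codes)) != len(self.codes):
            raise ValueError("duplicate defect codes in plan")


# ---------------------------------------------------------------------------
# mini chemical component dictionary

def _amino_acid_comp(comp_id: str) -> ChemComp:
    """Single standard residue with idealized geometry (no OXT, no H)."""
    chain = build_backbone([comp_id], [STRAND_PHI_PSI])
    res = chain.residues[0]
    xyz = {a.name: np.asarray(a.xyz) for a in res.atoms}
    atoms = [("N", "N", 0), ("CA", "C", 0), ("C", "C", 0), ("O", "O", 0)]
    bonds = [("N", "CA", "single"), ("CA", "C", "single"), ("C", "O", "double")]
    stereo: List[Tuple[str, Tuple[str, ...], int]] = []
    if comp_id != "GLY":
        atoms.append(("CB", "C", 0))
        bonds.append(("CA", "CB", "single"))
        stereo.append(("CA", ("N", "C", "CB"), 1))
    if comp_id == "CYS":
        xyz["SG"] = place_atom(xyz["N"], xyz["CA"], xyz["CB"], 1.81, 114.0, 180.0)
        atoms.append(("SG", "S", 0))
        bonds.append(("CB", "SG", "single"))
    elif comp_id == "VAL":
        xyz["CG1"] = place_atom(xyz["N"], xyz["CA"], xyz["CB"], 1.52, 111.0, 60.0)
        xyz["CG2"] = place_atom(xyz["N"], xyz["CA"], xyz["CB"], 1.52, 111.0, 180.0)
        atoms += [("CG1", "C", 0), ("CG2", "C", 0)]
        bonds += [("CB", "CG1", "single"), ("CB", "CG2", "single")]
    elif comp_id == "LEU":
        xyz["CG"] = place_atom(xyz["N"], xyz["CA"], xyz["CB"], 1.53, 111.0, 180.0)
        xyz["CD1"] = place_atom(xyz["CA"], xyz["CB"], xyz["CG"], 1.52, 111.0, 60.0)
        xyz["CD2"] = place_atom(xyz["CA"], xyz["CB"], xyz["CG"], 1.52, 111.0, 180.0)
        atoms += [("CG", "C", 0), ("CD1", "C", 0), ("CD2", "C", 0)]
        bonds += [("CB", "CG", "single"), ("CG", "CD1", "single"),
                  ("CG", "CD2", "single")]
    elif comp_id not in ("ALA", "GLY"):
        raise ValueError(f"no ideal geometry recipe for {comp_id}")
    return ChemComp(
        comp_id=comp_id, atoms=tuple(atoms), bonds=tuple(bonds),
        stereocenters=tuple(stereo),
        ideal_xyz={n: tuple(float(v) for v in xyz[n]) for n, _, _ in atoms})


def _nag_comp() -> ChemComp:
    """N-acetylglucosamine with a puckered six-ring and one stereocenter."""
    ring = ["C1", "C2", "C3", "C4", "C5", "O5"]
    rho, pucker = 1.45, 0.30
    xyz: Dict[str, np.ndarray] = {}
    theta: Dict[str, float] = {}
    for k, name in enumerate(ring):
        th = math.radians(60.0 * k)
        theta[name] = th
        z = pucker if k % 2 == 0 else -pucker
        xyz[name] = np.array([rho * math.cos(th), rho * math.sin(th), z])

    def radial(base: str, dist: float) -> np.ndarray:
        th = theta[base]
        return xyz[base] + dist * np.array([math.cos(th), math.sin(th), 0.0])

    xyz["N2"] = radial("C2", 1.47)
    xyz["O3"] = radial("C3", 1.43)
    xyz["O4"] = radial("C4", 1.43)
    xyz["C6"] = xyz["C5"] + np.array([0.0, 0.0, 1.52])
    th5 = theta["C5"]
    xyz["O6"] = xyz["C6"] + 1.43 * np.array([math.cos(th5), math.sin(th5), 0.0])
    th2 = theta["C2"]
    u = np.array([math.cos(th2), math.sin(th2), 0.0])
    t = np.array([-math.sin(th2), math.cos(th2), 0.0])
    xyz["C7"] = xyz["N2"] + 1.33 * u
    xyz["O7"] = xyz["C7"] + 1.23 * (0.5 * u + 0.866 * t)
    xyz["C8"] = xyz["C7"] + 1.50 * (0.5 * u - 0.866 * t)
    atoms = tuple((n, ("O" if n.startswith("O") else
                       "N" if n.startswith("N") else "C"), 0)
                  for n in ["C1", "C2", "C3", "C4", "C5", "O5", "C6", "O6",
                            "O3", "O4", "N2", "C7", "O7", "C8"])
    bonds = (
        ("C1", "C2", "single"), ("C2", "C3", "single"), ("C3", "C4", "single"),
        ("C4", "C5", "single"), ("C5", "O5", "single"), ("O5", "C1", "single"),
        ("C2", "N2", "single"), ("N2", "C7", "single"), ("C7", "O7", "double"),
        ("C7", "C8", "single"), ("C3", "O3", "single"), ("C4", "O4", "single"),
        ("C5", "C6", "single"), ("C6", "O6", "single"),
    )
    # parity of C2 over ordered neighbors (C1, C3, N2), from this geometry
    c2 = xyz["C2"]
    vol = float(np.dot(xyz["C1"] - c2,
                       np.cross(xyz["C3"] - c2, xyz["N2"] - c2)))
    parity = 1 if vol > 0 else -1
    return ChemComp(
        comp_id="NAG", atoms=atoms, bonds=bonds,
        stereocenters=(("C2", ("C1", "C3", "N2"), parity),),
        ideal_xyz={n: tuple(float(v) for v in xyz[n]) for n, _, _ in atoms})


def _lg7_comp() -> ChemComp:
    """Seven-atom placeholder ligand (unique graph within the mini CCD)."""
    xyz = {
        "C1": (0.0, 0.0, 0.0), "C2": (1.50, 0.0, 0.0), "C3": (3.00, 0.0, 0.0),
        "C4": (4.50, 0.0, 0.0), "N1": (1.50, 1.47, 0.0),
        "O1": (3.00, -1.43, 0.0), "S1": (4.50, 1.81, 0.0),
    }
    return ChemComp(
        comp_id="LG7",
        atoms=(("C1", "C", 0), ("C2", "C", 0), ("C3", "C", 0), ("C4", "C", 0),
               ("N1", "N", 0), ("O1", "O", 0), ("S1", "S", 0)),
        bonds=(("C1", "C2", "single"), ("C2", "C3", "single"),
               ("C3", "C4", "single"), ("C2", "N1", "single"),
               ("C3", "O1", "single"), ("C4", "S1", "single")),
        ideal_xyz=xyz)


def _tp3_comp() -> ChemComp:
    """Peptide-like tripeptide (Ala-Gly-Cys) in its non-polymer form."""
    chain = build_backbone(["ALA", "GLY", "CYS"], [STRAND_PHI_PSI] * 3)
    xyz: Dict[str, np.ndarray] = {}
    atoms: List[Tuple[str, str, int]] = []
    bonds: List[Tuple[str, str, str]] = []
    for i, res in enumerate(chain.residues, start=1):
        for a in res.atoms:
            xyz[f"{a.name}{i}"] = np.asarray(a.xyz)
            atoms.append((f"{a.name}{i}", a.element, 0))
        bonds += [(f"N{i}", f"CA{i}", "single"), (f"CA{i}", f"C{i}", "single"),
                  (f"C{i}", f"O{i}", "double")]
        if res.comp_id != "GLY":
            bonds.append((f"CA{i}", f"CB{i}", "single"))
    sg = place_atom(xyz["N3"], xyz["CA3"], xyz["CB3"], 1.81, 114.0, 180.0)
    xyz["SG3"] = sg
    atoms.append(("SG3", "S", 0))
    bonds.append(("CB3", "SG3", "single"))
    bonds += [("C1", "N2", "single"), ("C2", "N3", "single")]
    return ChemComp(
        comp_id="TP3", atoms=tuple(atoms), bonds=tuple(bonds),
        ideal_xyz={n: tuple(float(v) for v in xyz[n]) for n, _, _ in atoms})


def mini_ccd() -> List[ChemComp]:
    comps = [_amino_acid_comp(c) for c in ("ALA", "GLY", "LEU", "VAL", "CYS")]
    comps.append(ChemComp(comp_id="HOH", atoms=(("O", "O", 0),), bonds=()))
    comps += [_nag_comp(), _lg7_comp(), _tp3_comp()]
    return comps


def make_mini_ccd() -> str:
    """The packaged mini-CCD as mmCIF text (byte-identical across calls)."""
    return write_ccd(mini_ccd())


# ---------------------------------------------------------------------------
# peptide reference dictionary fixture

def mini_prd() -> List[PrdEntry]:
    return [PrdEntry(prd_id="PRD_900001", components=("ALA", "GLY", "CYS"),
                     linkage="linear-peptide")]


def write_prd(entries: Sequence[PrdEntry]) -> str:
    lines = ["# PRD fixture: one entry per line: id<TAB>linkage<TAB>comp,comp,..."]
    for e in entries:
        lines.append(f"{e.prd_id}\t{e.linkage}\t{','.join(e.components)}")
    return "\n".join(lines) + "\n"


def read_prd(text: str) -> List[PrdEntry]:
    entries = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        prd_id, linkage, comps = line.split("\t")
        entries.append(PrdEntry(prd_id=prd_id, linkage=linkage,
                                components=tuple(comps.split(","))))
    return entries


# ---------------------------------------------------------------------------
# reference sequence database

def _random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(AA_LETTERS), size=n))


def refdb_records(seed: int = 1) -> List[RefRecord]:
    """Five reference records, including the chimera pair (CHIMA/CHIMB).

    CHIMA is a 219-residue protein; CHIMB carries the 16-residue loop that
    the chimeric construct swaps in at sample positions 182–197.  The
    generator enforces, by construction, that the loop differs from CHIMA's
    own loop at every position and that its flanking residues mismatch the
    chimera junctions — the situation in which a swap is annotatable at
    all.  REF001 carries Tyr at position 55, the site the tagged-mutant
    deposition substitutes with Trp.
    """
    rng = np.random.default_rng(seed)
    a = list(_random_protein(rng, CHIMERA_LENGTH))
    b = list(_random_protein(rng, 120))
    w0 = CHIMB_WINDOW_START - 1  # 0-based window start in CHIMB

    def different(letter: str) -> str:
        i = AA_LETTERS.index(letter)
        return AA_LETTERS[(i + 1) % len(AA_LETTERS)]

    # CHIMA's own loop must differ position-wise from the planted B loop
    for k in range(SWAP_START - 1, SWAP_END):
        if a[k] == b[w0 + k - (SWAP_START - 1)]:
            a[k] = different(a[k])
    # junction flanks must mismatch so the swap boundary is well defined
    if b[w0 - 1] == a[SWAP_START - 2]:
        b[w0 - 1] = different(b[w0 - 1])
    if b[w0 + (SWAP_END - SWAP_START + 1)] == a[SWAP_END]:
        b[w0 + (SWAP_END - SWAP_START + 1)] = different(
            b[w0 + (SWAP_END - SWAP_START + 1)])

    ref1 = list(_random_protein(rng, 120))
    ref1[MUTATION_REF_POSITION - 1] = "Y"
    return [
        RefRecord("REF001", "".join(ref1), "Mus musculus", 10090),
        RefRecord("REF002", _random_protein(rng, 110), "Escherichia coli", 562),
        RefRecord("CHIMA", "".join(a), "Aplysia californica", 6500),
        RefRecord("CHIMB", "".join(b), "Homo sapiens", 9606),
        RefRecord("REF005", _random_protein(rng, 100),
                  "Saccharomyces cerevisiae", 4932),
    ]


def make_refdb(seed: int = 1) -> str:
    return write_refdb(refdb_records(seed))


def tagged_mutant_sample(records: Sequence[RefRecord]) -> Tuple[str, Dict[str, object]]:
    """Tagged-mutant sample: 9-residue tag + REF001 with Y55W."""
    ref = next(r for r in records if r.accession == "REF001")
    body = list(ref.sequence)
    assert body[MUTATION_REF_POSITION - 1] == "Y"
    body[MUTATION_REF_POSITION - 1] = "W"
    sample = TAG_SEQUENCE + "".join(body)
    declarations = {"mutations": [MUTATION_SAMPLE_POSITION],
                    "tags": [(1, len(TAG_SEQUENCE))]}
    return sample, declarations


def chimera_sample(records: Sequence[RefRecord]) -> str:
    """219-residue chimera: CHIMA with CHIMB's loop at 182–197."""
    a = next(r for r in records if r.accession == "CHIMA").sequence
    b = next(r for r in records if r.accession == "CHIMB").sequence
    w0 = CHIMB_WINDOW_START - 1
    n = SWAP_END - SWAP_START + 1
    return a[:SWAP_START - 1] + b[w0:w0 + n] + a[SWAP_END:]


def make_chimera_case(seed: int, total: int = 150, seg_len: int = 30,
                      ) -> Tuple[str, List[RefRecord], Tuple[int, int]]:
    """Random planted two-source construct for boundary-recovery tests.

    The sample copies reference A except for a ``seg_len``-residue window
    (identity 100% to reference B, random elsewhere); boundaries are not
    specially conditioned, so recovery is a statistical property.
    """
    rng = np.random.default_rng(seed)
    a = _random_protein(rng, total)
    b = list(_random_protein(rng, max(80, seg_len + 20)))
    start = int(rng.integers(30, total - seg_len - 30))  # 0-based
    w0 = int(rng.integers(1, len(b) - seg_len - 1))

    # the planted boundary must be identifiable: if a junction residue
    # matched both sources, two distinct segmentations would describe the
    # same sequence and "the" boundary would not exist
    def different(letter: str) -> str:
        i = AA_LETTERS.index(letter)
        return AA_LETTERS[(i + 1) % len(AA_LETTERS)]

    for b_idx, a_idx in ((w0 - 1, start - 1), (w0, start),
                         (w0 + seg_len - 1, start + seg_len - 1),
                         (w0 + seg_len, start + seg_len)):
        if b[b_idx] == a[a_idx]:
            b[b_idx] = different(b[b_idx])
    b = "".join(b)
    sample = a[:start] + b[w0:w0 + seg_len] + a[start + seg_len:]
    refs = [RefRecord("SRCA", a, "Organism a", 1000 + seed % 97),
            RefRecord("SRCB", b, "Organism b", 2000 + seed % 97)]
    return sample, refs, (start + 1, start + seg_len)  # 1-based inclusive


# ---------------------------------------------------------------------------
# beta-sheet fixture (secondary-structure tests)

_SHEET_ROT = np.array([
    [-0.5443440272, -0.7395768433, 0.3958733041],
    [-0.7616452482, 0.2379711903, -0.6027157111],
    [0.3515481417, -0.6295997184, -0.6928333845]])
_SHEET_TRAN = np.array([24.7475244, 11.11207362, 3.91292389])


def make_beta_sheet() -> ChainRecord:
    """Two-strand antiparallel sheet (one chain, residues 1-8 and 21-28)."""
    s1 = build_backbone(["VAL"] * 8, [STRAND_PHI_PSI] * 8, chain_id="A")
    s2 = transform_chain(s1, _SHEET_ROT, _SHEET_TRAN)
    res2 = [ResidueRecord(comp_id=r.comp_id, seq_num=r.seq_num + 20,
                          atoms=r.atoms) for r in s2.residues]
    return ChainRecord(chain_id="A", residues=s1.residues + res2)


# ---------------------------------------------------------------------------
# deposition generator

CELL = CellParams(a=46.0, b=36.0, c=40.0, alpha=90.0, beta=100.0, gamma=90.0)
SPACE_GROUP = "P 1 2 1"
BASE_LENGTH = 30
LIGAND_SEQ_NUM = 501
WATER_SEQ_START = 1001
N_WATERS = 5


def packaged_schema() -> DictionarySchema:
    from importlib.resources import files

    text = files("minidep").joinpath("data", "mini_schema.txt").read_text()
    return load_schema(text)


def source_organism_block(dep_id: str = "src-org") -> DataBlock:
    """The worked source-organism example: mouse protein expressed in E. coli."""
    return DataBlock(block_id=dep_id, tables={
        "entity": [{
            "entity.id": "1", "entity.type": "polymer",
            "entity.pdbx_description": "mouse protein",
        }],
        "entity_src_gen": [{
            "entity_src_gen.entity_id": "1",
            "entity_src_gen.pdbx_gene_src_scientific_name": "M. musculus",
            "entity_src_gen.gene_src_common_name": "Mouse",
            "entity_src_gen.pdbx_gene_src_ncbi_taxonomy_id": "10090",
            "entity_src_gen.gene_src_strain": "?",
            "entity_src_gen.pdbx_host_org_scientific_name": "E. coli",
            "entity_src_gen.pdbx_host_org_ncbi_taxonomy_id": "562",
            "entity_src_gen.pdbx_host_org_vector_type": "plasmid",
            "entity_src_gen.plasmid_name": "pET28a",
        }],
    })


def _min_image_distance(point: np.ndarray, cell: CellParams,
                        ops: Sequence[SymOp], tree: cKDTree
                        ) -> Tuple[float, bool]:
    """Min distance-to-polymer over all symmetry images; identity-optimal?"""
    orth = cell.orth_matrix()
    frac = cell.fractionalize(point)
    best = math.inf
    best_key = None
    for oi, op in enumerate(ops):
        base = op.apply(frac)
        for sx in (-1, 0, 1):
            for sy in (-1, 0, 1):
                for sz in (-1, 0, 1):
                    f = base + np.array([sx, sy, sz], dtype=float)
                    d = float(tree.query(f @ orth.T)[0])
                    key = (round(d, 9), oi, (sx, sy, sz))
                    if best_key is None or key < best_key:
                        best_key = key
                        best = d
    identity_optimal = best_key[1] == 0 and best_key[2] == (0, 0, 0)
    return best, identity_optimal


def _water(seq_num: int, xyz, occupancy: float = 1.0,
           b_factor: float = 30.0) -> ResidueRecord:
    return ResidueRecord(comp_id="HOH", seq_num=seq_num, atoms=[
        AtomRecord("O", "O", tuple(float(v) for v in xyz),
                   occupancy=occupancy, b_factor=b_factor)])


def _place_component(comp: ChemComp, target: np.ndarray,
                     mirror: bool = False) -> List[AtomRecord]:
    """Instantiate a CCD component with its centroid at ``target``."""
    names = [n for n, _, _ in comp.atoms]
    xyz = np.array([comp.ideal_xyz[n] for n in names])
    if mirror:
        xyz = xyz * np.array([1.0, 1.0, -1.0])
    xyz = xyz - xyz.mean(axis=0) + target
    return [AtomRecord(n, el, tuple(float(v) for v in p), b_factor=25.0)
            for (n, el, _), p in zip(comp.atoms, xyz)]


def _base_metadata(dep_id: str, sample: str) -> DataBlock:
    t1 = source_organism_block(dep_id)
    tables = {k: [dict(r) for r in v] for k, v in t1.tables.items()}
    tables["entity"] += [
        {"entity.id": "2", "entity.type": "non-polymer",
         "entity.pdbx_description": "ligand"},
        {"entity.id": "3", "entity.type": "water",
         "entity.pdbx_description": "water"},
    ]
    tables["entity_poly"] = [{
        "entity_poly.entity_id": "1",
        "entity_poly.type": "polypeptide(L)",
        "entity_poly.pdbx_seq_one_letter_code": sample,
        "entity_poly.pdbx_strand_id": "A",
    }]
    tables["cell"] = [{
        "cell.entry_id": dep_id,
        "cell.length_a": f"{CELL.a:.3f}", "cell.length_b": f"{CELL.b:.3f}",
        "cell.length_c": f"{CELL.c:.3f}", "cell.angle_alpha": f"{CELL.alpha:.2f}",
        "cell.angle_beta": f"{CELL.beta:.2f}",
        "cell.angle_gamma": f"{CELL.gamma:.2f}",
    }]
    tables["symmetry"] = [{
        "symmetry.entry_id": dep_id,
        "symmetry.space_group_name_H-M": SPACE_GROUP,
        "symmetry.Int_Tables_number": "3",
    }]
    tables["reflns"] = [{
        "reflns.entry_id": dep_id,
        "reflns.pdbx_Rmerge_I_obs": "0.13",
        "reflns.d_resolution_high": "1.90",
        "reflns.pdbx_redundancy": "4.5",
        "reflns.pdbx_wavelength": "0.9793",
        "reflns.pdbx_sf_wavelength": "0.9793",
        "reflns.pdbx_free_R_flag": "yes",
        "reflns.pdbx_aniso_B": "yes",
        "reflns.pdbx_sf_complete": "yes",
    }]
    return DataBlock(block_id=dep_id, tables=tables)


def make_deposition(plan: DefectPlan) -> Tuple[Deposition, Dict]:
    """Build a deposition with each planned defect planted exactly once.

    Returns the deposition and a manifest listing, per defect, the planted
    locus and the finding code the pipeline is expected to raise.  The
    empty plan yields a deposition that passes the full pipeline with zero
    error-severity findings.
    """
    codes = set(plan.codes)
    rng = np.random.default_rng(plan.seed)
    records = refdb_records(1)
    manifest: Dict = {"seed": plan.seed, "plan": sorted(codes), "defects": []}
    declarations: Dict[str, object] = {"oligomeric_count": 1}

    def note(code: str, locus, count: int = 1) -> None:
        manifest["defects"].append({
            "code": code, "expected_code": PLAN_EXPECTATIONS[code],
            "locus": list(locus) if isinstance(locus, (tuple, list)) else locus,
            "count": count})

    # --- sample sequence
    if "tag_and_mutation" in codes:
        sample, decl = tagged_mutant_sample(records)
        declarations.update(decl)
        manifest["expected_annotations"] = {
            "expression_tag": [1, len(TAG_SEQUENCE)],
            "mutation_position": MUTATION_SAMPLE_POSITION,
        }
    elif "chimera_swap" in codes:
        sample = chimera_sample(records)
        manifest["expected_segments"] = {
            "accessions": ["CHIMA", "CHIMB", "CHIMA"],
            "boundaries": [[1, SWAP_START - 1], [SWAP_START, SWAP_END],
                           [SWAP_END + 1, CHIMERA_LENGTH]],
        }
    else:
        sample = _random_protein(rng, BASE_LENGTH)

    # --- polymer chain from torsions
    n_res = len(sample)
    torsions = [HELIX_PHI_PSI] * n_res
    if "phi_psi_outlier" in codes:
        # penultimate residue: the swing moves only the chain tail
        k = n_res - 2
        if sample[k] == "G":  # glycine is exempt from torsion checks
            sample = sample[:k] + "A" + sample[k + 1:]
        torsions[k] = (60.0, -120.0)
        note("phi_psi_outlier", ("A", k + 1))
    comp_ids = [AA_1TO3[c] for c in sample]
    chain = build_backbone(comp_ids, torsions, chain_id="A")

    if "sequence_discrepancy" in codes:
        res = chain.residues[7]
        wrong = "VAL" if res.comp_id != "VAL" else "LEU"
        res.comp_id = wrong
        if wrong == "GLY":  # never happens, kept for clarity
            pass
        note("sequence_discrepancy", ("A", 8))

    if "backbone_break" in codes:
        ca = np.array([r.atom("CA").xyz for r in chain.residues])
        axis = ca[-1] - ca[0]
        axis /= np.linalg.norm(axis)
        shift = 25.0 * axis
        from dataclasses import replace as _replace
        for res in chain.residues[15:]:
            res.atoms = [_replace(a, xyz=tuple(float(v) for v in
                                               (np.asarray(a.xyz) + shift)))
                         for a in res.atoms]
        note("backbone_break", ("A", 15))

    # --- position the chain in the cell, clear of 2-fold axes
    ops = space_group_ops(SPACE_GROUP)
    orth = CELL.orth_matrix()
    all_xyz = np.array([a.xyz for r in chain.residues for a in r.atoms])
    target = np.array([6.0, CELL.b / 2.0, 3.0])
    offset = target - all_xyz.mean(axis=0)
    from dataclasses import replace as _replace
    for res in chain.residues:
        res.atoms = [_replace(a, xyz=tuple(float(v) for v in
                                           (np.asarray(a.xyz) + offset)))
                     for a in res.atoms]
    for _ in range(40):  # nudge off special positions if needed
        bad = False
        for res in chain.residues:
            for a in res.atoms:
                frac = CELL.fractionalize(np.asarray(a.xyz))
                for op in ops[1:]:
                    delta = op.apply(frac) - frac
                    delta -= np.round(delta)
                    if float(np.linalg.norm(delta @ orth.T)) < 0.6:
                        bad = True
                        break
                if bad:
                    break
            if bad:
                break
        if not bad:
            break
        for res in chain.residues:
            res.atoms = [_replace(a, xyz=(a.xyz[0] + 0.8, a.xyz[1], a.xyz[2]))
                         for a in res.atoms]

    poly_xyz = np.array([a.xyz for r in chain.residues for a in r.atoms])
    tree = cKDTree(poly_xyz)

    # --- ligand
    ccd = mini_ccd()
    nag = next(c for c in ccd if c.comp_id == "NAG")
    centroid = poly_xyz.mean(axis=0)
    lig_atoms = None
    for t in np.arange(7.0, 20.0, 0.5):
        for direction in (np.array([0.0, 0.0, 1.0]), np.array([0.0, 1.0, 1.0]),
                          np.array([1.0, 0.0, 1.0])):
            d = direction / np.linalg.norm(direction)
            cand = _place_component(nag, centroid + t * d,
                                    mirror="chirality_flip" in codes)
            dists = tree.query(np.array([a.xyz for a in cand]))[0]
            if dists.min() >= 3.4 and dists.min() <= 6.0:
                lig_atoms = cand
                break
        if lig_atoms is not None:
            break
    assert lig_atoms is not None, "no ligand placement found"
    ligand = ResidueRecord(comp_id="NAG", seq_num=LIGAND_SEQ_NUM,
                           atoms=lig_atoms)
    if "chirality_flip" in codes:
        note("chirality_flip", ("A", LIGAND_SEQ_NUM))
    if "ligand_missing_atom" in codes:
        ligand.atoms = [a for a in ligand.atoms if a.name != "O6"]
        note("ligand_missing_atom", ("A", LIGAND_SEQ_NUM))
    if "ligand_geometry" in codes:
        c5 = np.asarray(ligand.atom("C5").xyz)
        c6 = np.asarray(ligand.atom("C6").xyz)
        stretch = 0.30 * (c6 - c5) / np.linalg.norm(c6 - c5)
        for a in ligand.atoms:
            if a.name in ("C6", "O6"):
                a.xyz = tuple(float(v) for v in (np.asarray(a.xyz) + stretch))
        note("ligand_geometry", ("A", LIGAND_SEQ_NUM))
    if "ligand_identity" in codes:
        ligand.comp_id = "LG7"
        note("ligand_identity", ("A", LIGAND_SEQ_NUM))

    lig_xyz = np.array([a.xyz for a in ligand.atoms])

    # --- waters: identity-optimal, clash-free, within 4.5 A of polymer
    waters: List[ResidueRecord] = []
    water_xyz: List[np.ndarray] = []
    occupied = np.vstack([poly_xyz, lig_xyz])
    occ_tree = cKDTree(occupied)
    seq = WATER_SEQ_START
    ca_xyz = np.array([r.atom("CA").xyz for r in chain.residues
                       if r.atom("CA") is not None])
    axis_point = ca_xyz.mean(axis=0)
    axis_dir = np.linalg.svd(ca_xyz - axis_point)[2][0]
    for res in chain.residues[1::3]:
        if len(waters) >= N_WATERS:
            break
        base_atom = res.atom("CB") or res.atom("CA")
        o = res.atom("O")
        if base_atom is None or o is None:
            continue
        base = np.asarray(base_atom.xyz)
        rel = base - axis_point
        d = rel - np.dot(rel, axis_dir) * axis_dir  # radially outward
        if np.linalg.norm(d) < 1e-6:
            continue
        d /= np.linalg.norm(d)
        for t in (2.9, 3.2, 3.5):
            p = base + t * d
            if occ_tree.query(p)[0] < 2.9:
                continue
            if water_xyz and min(np.linalg.norm(p - w) for w in water_xyz) < 2.9:
                continue
            dist, ident = _min_image_distance(p, CELL, ops, tree)
            if not ident or dist > 4.5:
                continue
            waters.append(_water(seq, p))
            water_xyz.append(p)
            seq += 1
            break

    # --- planted water defects
    if "misplaced_water" in codes and waters:
        w = waters[0]
        frac = CELL.fractionalize(np.asarray(w.atoms[0].xyz))
        far = (ops[1].apply(frac) + np.array([1.0, 0.0, 0.0])) @ orth.T
        w.atoms[0].xyz = tuple(float(v) for v in far)
        note("misplaced_water", ("A", w.seq_num))
        manifest["expected_move"] = {"locus": ["A", w.seq_num],
                                     "final_xyz": [float(v) for v in
                                                   np.asarray(water_xyz[0])]}
    if "distant_water" in codes:
        placed = False
        for raw in ((1.0, 0.6, 0.8), (0.0, 1.0, 0.5), (1.0, 0.0, 0.0),
                    (0.5, -1.0, 0.8), (0.0, 0.0, 1.0)):
            d = np.asarray(raw)
            d /= np.linalg.norm(d)
            for t in np.arange(5.3, 16.0, 0.1):
                p = poly_xyz.max(axis=0) + t * d
                dist, _ = _min_image_distance(p, CELL, ops, tree)
                if 5.05 < dist <= 7.4 and occ_tree.query(p)[0] > 3.2:
                    waters.append(_water(seq, p))
                    note("distant_water", ("A", seq))
                    seq += 1
                    placed = True
                    break
            if placed:
                break
        assert placed, "no distant-water site found"
    if "atomic_clash" in codes:
        d = np.array([0.0, -1.0, 0.7])
        d /= np.linalg.norm(d)
        placed = False
        for t in np.arange(3.4, 8.0, 0.1):
            p1 = poly_xyz.min(axis=0) - t * d
            p2 = p1 + np.array([1.0, 0.0, 0.0]) * 1.0
            if occ_tree.query(p1)[0] > 3.2 and occ_tree.query(p2)[0] > 3.2 \
                    and (not water_xyz or min(
                        np.linalg.norm(p1 - w) for w in water_xyz) > 3.0):
                waters.append(_water(seq, p1))
                waters.append(_water(seq + 1, p2))
                note("atomic_clash", ("A", seq))
                seq += 2
                placed = True
                break
        assert placed, "no clash-pair site found"
    if "special_position_occupancy" in codes:
        placed = False
        for y in np.arange(0.0, 1.0, 0.002):
            p = np.array([0.0, y, 0.0]) @ orth.T
            dmin = float(tree.query(p)[0])
            if 2.9 <= dmin <= 4.5 and occ_tree.query(p)[0] >= 2.9:
                if not water_xyz or min(np.linalg.norm(p - w)
                                        for w in water_xyz) > 2.9:
                    waters.append(_water(seq, p, occupancy=1.0))
                    note("special_position_occupancy", ("A", seq, "O"))
                    seq += 1
                    placed = True
                    break
        assert placed, "no special-position site found"

    # --- atom-level defects
    if "zero_occupancy" in codes:
        chain.residues[9].atom("CA").occupancy = 0.0
        note("zero_occupancy", ("A", chain.residues[9].seq_num, "CA"))
    if "zero_b_factor" in codes:
        chain.residues[11].atom("O").b_factor = 0.0
        note("zero_b_factor", ("A", chain.residues[11].seq_num, "O"))
    if "extra_hydrogen" in codes:
        res = chain.residues[4]
        base = np.asarray(res.atom("O").xyz)
        placed = False
        for t in np.arange(3.0, 8.0, 0.25):
            for raw in ((0.0, -1.0, 1.0), (1.0, -1.0, 0.0), (0.0, 0.0, -1.0)):
                d = np.asarray(raw)
                d /= np.linalg.norm(d)
                p = base + t * d
                if occ_tree.query(p)[0] >= 2.5 and (
                        not water_xyz or min(np.linalg.norm(p - w)
                                             for w in water_xyz) >= 2.5):
                    res.atoms.append(AtomRecord(
                        "HX", "H", tuple(float(v) for v in p), b_factor=25.0))
                    placed = True
                    break
            if placed:
                break
        assert placed, "no stray-hydrogen site found"
        note("extra_hydrogen", ("A", res.seq_num, "HX"))
    if "polymer_geometry" in codes:
        res = chain.residues[19]
        c = np.asarray(res.atom("C").xyz)
        o = res.atom("O")
        d = np.asarray(o.xyz) - c
        d /= np.linalg.norm(d)
        o.xyz = tuple(float(v) for v in (np.asarray(o.xyz) + 0.12 * d))
        note("polymer_geometry", ("A", res.seq_num))

    # --- assemble deposition
    chain.residues.append(ligand)
    chain.residues.extend(waters)
    dep = Deposition(
        dep_id=f"MD{plan.seed:04d}",
        chains=[chain],
        metadata=_base_metadata(f"MD{plan.seed:04d}", sample),
        assemblies=[[IDENTITY_ASSEMBLY_OP]],
        ligands_of_interest=["NAG"],
        sample_sequences={"A": sample},
        declarations=declarations,
    )

    # --- metadata defects
    reflns = dep.metadata.tables["reflns"][0]
    if "rmerge_outlier" in codes:
        reflns["reflns.pdbx_Rmerge_I_obs"] = "0.7"
        note("rmerge_outlier", ("reflns", 0))
    if "wavelength_mismatch" in codes:
        reflns["reflns.pdbx_sf_wavelength"] = "1.5418"
        note("wavelength_mismatch", ("reflns", 0))
    if "missing_free_r" in codes:
        reflns["reflns.pdbx_free_R_flag"] = "?"
        note("missing_free_r", ("reflns", 0))
    if "missing_aniso_b" in codes:
        reflns["reflns.pdbx_aniso_B"] = "no"
        note("missing_aniso_b", ("reflns", 0))
    if "sf_incomplete" in codes:
        reflns["reflns.pdbx_sf_complete"] = "no"
        note("sf_incomplete", ("reflns", 0))
    if "metadata_missing" in codes:
        del dep.metadata.tables["cell"]
        note("metadata_missing", ("cell", 0))
    if "quaternary_mismatch" in codes:
        dep.declarations["oligomeric_count"] = 2
        note("quaternary_mismatch", ("assembly", 0))
    if "tag_and_mutation" in codes:
        note("tag_and_mutation", ("A", MUTATION_SAMPLE_POSITION))
    if "chimera_swap" in codes:
        note("chimera_swap", ("A", SWAP_START))

    manifest["dep_id"] = dep.dep_id
    return dep, manifest


def write_fixture_set(out_dir: str, plan: DefectPlan) -> Dict[str, str]:
    """Write deposition, CCD, reference FASTA, PRD and manifest to a directory."""
    import os

    from .depio import write_deposition

    os.makedirs(out_dir, exist_ok=True)
    dep, manifest = make_deposition(plan)
    paths = {}
    paths["deposition"] = os.path.join(out_dir, "deposition.cif")
    write_deposition(dep, paths["deposition"])
    paths["ccd"] = os.path.join(out_dir, "ccd.cif")
    with open(paths["ccd"], "w") as fh:
        fh.write(make_mini_ccd())
    paths["refdb"] = os.path.join(out_dir, "refdb.fasta")
    with open(paths["refdb"], "w") as fh:
        fh.write(make_refdb(1))
    paths["prd"] = os.path.join(out_dir, "prd.txt")
    with open(paths["prd"], "w") as fh:
        fh.write(write_prd(mini_prd()))
    paths["manifest"] = os.path.join(out_dir, "manifest.json")
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return paths
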