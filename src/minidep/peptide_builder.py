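"""Construction of idealized peptide geometry from torsion angles.

Backbones are grown atom-by-atom with the natural extension reference
frame (bond length, bond angle, torsion), using standard main-chain
geometry: N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, C–O 1.231 Å, CA–CB
1.530 Å; angles N–CA–C 111.2°, CA–C–N 116.2°, C–N–CA 121.7°, CA–C–O
120.8°; ω = 180° unless overridden.  CB is placed tetrahedrally with
L-configuration (positive signed volume over the N, C, CB neighbor
order).

The fixture generator uses this to build helices, strands and planted
torsion outliers; only backbone + CB atoms are produced.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .entity_builder import AtomRecord, ChainRecord, ResidueRecord

BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.530
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_N_CA_CB = 110.5

HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-139.0, 135.0)


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position atom D given reference atoms A-B-C (NeRF construction)."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(torsion),
        bond * math.sin(angle) * math.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _place_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray,
              chirality: str = "L") -> np.ndarray:
    u1 = (n - ca) / np.linalg.norm(n - ca)
    u2 = (c - ca) / np.linalg.norm(c - ca)
    bisector = (u1 + u2)
    bisector /= np.linalg.norm(bisector)
    normal = np.cross(u1, u2)
    normal /= np.linalg.norm(normal)
    theta = math.radians(ANGLE_N_CA_CB)
    # d = alpha*bisector + beta*normal with |d| = 1 and angle(d, u1) = theta
    alpha = math.cos(theta) / float(np.dot(bisector, u1))
    beta = math.sqrt(max(0.0, 1.0 - alpha * alpha))
    for sign in (1.0, -1.0):
        d = alpha * bisector + sign * beta * normal
        d /= np.linalg.norm(d)
        cb = ca + BOND_CA_CB * d
        vol = float(np.dot(u1, np.cross(u2, (cb - ca) / BOND_CA_CB)))
        if (vol > 0) == (chirality == "L"):
            return cb
    raise AssertionError("unreachable")


def build_backbone(
    sequence_comp_ids: Sequence[str],
    torsions: Sequence[Tuple[float, float]],
    omegas: Optional[Sequence[float]] = None,
    chain_id: str = "A",
    start_seq_num: int = 1,
    b_factor: float = 20.0,
) -> ChainRecord:
    """Grow a peptide chain (N, CA, C, O and CB except GLY) from torsions.

    ``torsions[i] = (phi_i, psi_i)``; phi of the first residue is unused.
    """
    n_res = len(sequence_comp_ids)
    if len(torsions) != n_res:
        raise ValueError("need one (phi, psi) pair per residue")
    omegas = list(omegas) if omegas is not None else [180.0] * n_res
    coords: List[Dict[str, np.ndarray]] = []
    for i in range(n_res):
        phi, psi = torsions[i]
        bb: Dict[str, np.ndarray] = {}
        if i == 0:
            bb["N"] = np.zeros(3)
            bb["CA"] = np.array([BOND_N_CA, 0.0, 0.0])
            ang = math.radians(ANGLE_N_CA_C)
            bb["C"] = bb["CA"] + BOND_CA_C * np.array(
                [-math.cos(ang), math.sin(ang), 0.0])
        else:
            prev = coords[i - 1]
            bb["N"] = place_atom(prev["N"], prev["CA"], prev["C"],
                                 BOND_C_N, ANGLE_CA_C_N, torsions[i - 1][1])
            bb["CA"] = place_atom(prev["CA"], prev["C"], bb["N"],
                                  BOND_N_CA, ANGLE_C_N_CA, omegas[i])
            bb["C"] = place_atom(prev["C"], bb["N"], bb["CA"],
                                 BOND_CA_C, ANGLE_N_CA_C, phi)
        coords.append(bb)
    # carbonyl O: torsion psi+180 about N-CA-C (points opposite the next N)
    for i in range(n_res):
        psi = torsions[i][1]
        coords[i]["O"] = place_atom(coords[i]["N"], coords[i]["CA"],
                                    coords[i]["C"], BOND_C_O, ANGLE_CA_C_O,
                                    psi + 180.0)
    residues: List[ResidueRecord] = []
    for i, comp in enumerate(sequence_comp_ids):
        bb = coords[i]
        atoms = [
            AtomRecord("N", "N", tuple(map(float, bb["N"])), b_factor=b_factor),
            AtomRecord("CA", "C", tuple(map(float, bb["CA"])), b_factor=b_factor),
            AtomRecord("C", "C", tuple(map(float, bb["C"])), b_factor=b_factor),
            AtomRecord("O", "O", tuple(map(float, bb["O"])), b_factor=b_factor),
        ]
        if comp != "GLY":
            cb = _place_cb(bb["N"], bb["CA"], bb["C"])
            atoms.append(AtomRecord("CB", "C", tuple(map(float, cb)),
                                    b_factor=b_factor))
        residues.append(ResidueRecord(comp_id=comp, seq_num=start_seq_num + i,
                                      atoms=atoms))
    return ChainRecord(chain_id=chain_id, residues=residues)


def transform_chain(chain: ChainRecord, rot: np.ndarray,
                    tran: np.ndarray) -> ChainRecord:
    """Rigid-body copy of a chain."""
    from dataclasses import replace

    residues = []
    for res in chain.residues:
        atoms = [replace(a, xyz=tuple(float(v) for v in
                                      (rot @ np.asarray(a.xyz) + tran)))
                 for a in res.atoms]
        residues.append(ResidueRecord(comp_id=res.comp_id, seq_num=res.seq_num,
                                      atoms=atoms))
    return ChainRecord(chain_id=chain.chain_id, residues=residues)
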