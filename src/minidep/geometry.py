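"""Geometric primitives: element radii, unit cells, symmetry operators.

Covalent-radius bond perception uses the classic single-bond radii with a
0.45 Å tolerance: atoms a, b are bonded iff d(a,b) <= r_cov(a)+r_cov(b)+tol.
Unit-cell fractional/orthogonal conversion uses the standard crystallographic
orthogonalization matrix (a along x, b in the xy plane).  Symmetry operators
are fractional rotation+translation pairs parsed from triplet strings
("x,y+1/2,-z"); the operator sets for common space groups come from gemmi's
space-group tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import gemmi
import numpy as np

#: single-bond covalent radii, Å
COVALENT_RADII = {
    "H": 0.37, "D": 0.37, "C": 0.77, "N": 0.75, "O": 0.73, "S": 1.02,
    "P": 1.06, "F": 0.71, "CL": 0.99, "BR": 1.14, "I": 1.33, "SE": 1.16,
    "B": 0.82, "SI": 1.11, "FE": 1.25, "ZN": 1.25, "MG": 1.30, "NA": 1.54,
    "K": 1.96, "CA": 1.74, "MN": 1.35, "CU": 1.28, "NI": 1.21, "CO": 1.26,
}

#: van der Waals radii, Å (clash screening)
VDW_RADII = {
    "H": 1.20, "D": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
    "FE": 1.60, "ZN": 1.39, "MG": 1.73, "NA": 2.27, "K": 2.75, "CA": 2.00,
    "MN": 1.60, "CU": 1.40, "NI": 1.63, "CO": 1.60, "B": 1.92, "SI": 2.10,
}

BOND_TOLERANCE = 0.45  # Å added to the covalent-radius sum


def covalent_radius(element: str) -> float:
    return COVALENT_RADII[element.upper()]


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), 1.7)


def bonded(el_a: str, xyz_a, el_b: str, xyz_b, tol: float = BOND_TOLERANCE) -> bool:
    d = float(np.linalg.norm(np.asarray(xyz_a) - np.asarray(xyz_b)))
    return d <= covalent_radius(el_a) + covalent_radius(el_b) + tol


@dataclass(frozen=True)
class CellParams:
    """Unit-cell lengths (Å) and angles (degrees)."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not (0.0 < ang < 180.0):
                raise ValueError("cell angles must lie in (0, 180)")
        if np.linalg.det(self.orth_matrix()) <= 0:
            raise ValueError("degenerate cell (metric not positive definite)")

    def orth_matrix(self) -> np.ndarray:
        """Fractional -> Cartesian matrix (a along x, b in the xy plane)."""
        al, be, ga = (math.radians(x) for x in (self.alpha, self.beta, self.gamma))
        ca, cb, cg, sg = math.cos(al), math.cos(be), math.cos(ga), math.sin(ga)
        v = math.sqrt(max(0.0, 1 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg))
        return np.array([
            [self.a, self.b * cg, self.c * cb],
            [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
            [0.0, 0.0, self.c * v / sg],
        ])

    def frac_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.orth_matrix())

    def orthogonalize(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac) @ self.orth_matrix().T

    def fractionalize(self, orth: np.ndarray) -> np.ndarray:
        return np.asarray(orth) @ self.frac_matrix().T


@dataclass(frozen=True)
class SymOp:
    """Crystallographic symmetry operator in fractional coordinates."""

    rot: Tuple[Tuple[int, int, int], ...]
    tran: Tuple[float, float, float]

    def __post_init__(self) -> None:
        for row in self.rot:
            for v in row:
                if v not in (-1, 0, 1):
                    raise ValueError("rotation entries must be -1, 0 or 1")

    @classmethod
    def from_triplet(cls, triplet: str) -> "SymOp":
        op = gemmi.Op(triplet)
        den = gemmi.Op.DEN
        rot = tuple(tuple(int(v // den) for v in row) for row in op.rot)
        tran = tuple(v / den for v in op.tran)
        return cls(rot=rot, tran=tran)

    def triplet(self) -> str:
        den = gemmi.Op.DEN
        op = gemmi.Op()
        op.rot = [[int(v) * den for v in row] for row in self.rot]
        op.tran = [int(round(v * den)) for v in self.tran]
        return op.triplet()

    def apply(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac) @ np.asarray(self.rot, dtype=float).T + np.asarray(self.tran)

    @property
    def is_identity(self) -> bool:
        return self.rot == ((1, 0, 0), (0, 1, 0), (0, 0, 1)) and all(
            abs(t) < 1e-9 for t in self.tran)


def space_group_ops(name: str) -> List[SymOp]:
    """Symmetry operators for a Hermann–Mauguin space-group symbol."""
    sg = gemmi.SpaceGroup(name)
    return [SymOp.from_triplet(op.triplet()) for op in sg.operations()]


@dataclass(frozen=True)
class AssemblyOp:
    """Cartesian rotation+translation used to build a quaternary assembly."""

    op_id: str
    rot: Tuple[Tuple[float, ...], ...]
    tran: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def matrix(self) -> np.ndarray:
        return np.asarray(self.rot, dtype=float)

    def is_orthonormal(self, tol: float = 1e-6) -> bool:
        r = self.matrix()
        return bool(np.allclose(r @ r.T, np.eye(3), atol=tol))

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz) @ self.matrix().T + np.asarray(self.tran)


IDENTITY_ASSEMBLY_OP = AssemblyOp(
    op_id="1", rot=((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0)))


def rotation_about_axis(axis: Sequence[float], angle_deg: float) -> Tuple[Tuple[float, ...], ...]:
    """Rotation matrix about an arbitrary axis through the origin."""
    u = np.asarray(axis, dtype=float)
    u = u / np.linalg.norm(u)
    th = math.radians(angle_deg)
    c, s = math.cos(th), math.sin(th)
    ux, uy, uz = u
    m = np.array([
        [c + ux * ux * (1 - c), ux * uy * (1 - c) - uz * s, ux * uz * (1 - c) + uy * s],
        [uy * ux * (1 - c) + uz * s, c + uy * uy * (1 - c), uy * uz * (1 - c) - ux * s],
        [uz * ux * (1 - c) - uy * s, uz * uy * (1 - c) + ux * s, c + uz * uz * (1 - c)],
    ])
    return tuple(tuple(float(v) for v in row) for row in m)
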