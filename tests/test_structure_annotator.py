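"""Solvent repositioning, links, secondary structure, assemblies, checks."""

import math
from dataclasses import replace

import numpy as np
import pytest

from minidep.entity_builder import (AtomRecord, ChainRecord, Deposition,
                                    ResidueRecord, build_entities)
from minidep.fixture_factory import (DefectPlan, make_beta_sheet,
                                     make_deposition)
from minidep.geometry import (AssemblyOp, CellParams, IDENTITY_ASSEMBLY_OP,
                              SymOp, rotation_about_axis, space_group_ops)
from minidep.peptide_builder import (HELIX_PHI_PSI, STRAND_PHI_PSI,
                                     build_backbone, transform_chain)
from minidep.structure_annotator import (OperatorError,
                                         assign_secondary_structure,
                                         build_assembly, extended_checks,
                                         generate_links, renumber_heteros,
                                         reposition_waters)

P2_CELL = CellParams(a=30.0, b=25.0, c=28.0, beta=95.0)
P2_OPS = space_group_ops("P 1 2 1")


def water(seq, xyz, occupancy=1.0):
    return ResidueRecord("HOH", seq, [AtomRecord("O", "O", xyz,
                                                 occupancy=occupancy)])


def simple_deposition(chain_residues, waters=(), cell=P2_CELL,
                      space_group="P 1 2 1"):
    chain = ChainRecord("A", list(chain_residues) + list(waters))
    from minidep.dictionary_engine import DataBlock

    meta = DataBlock("t", tables={
        "cell": [{"cell.entry_id": "t",
                  "cell.length_a": str(cell.a), "cell.length_b": str(cell.b),
                  "cell.length_c": str(cell.c),
                  "cell.angle_alpha": str(cell.alpha),
                  "cell.angle_beta": str(cell.beta),
                  "cell.angle_gamma": str(cell.gamma)}],
        "symmetry": [{"symmetry.entry_id": "t",
                      "symmetry.space_group_name_H-M": space_group}],
    })
    return Deposition(dep_id="t", chains=[chain], metadata=meta)


@pytest.fixture(scope="module")
def helix_chain():
    return build_backbone(["ALA"] * 10, [HELIX_PHI_PSI] * 10, chain_id="A")


class TestRepositionWaters:
    def _centered_helix(self):
        chain = build_backbone(["ALA"] * 8, [HELIX_PHI_PSI] * 8, chain_id="A")
        xyz = np.array([a.xyz for r in chain.residues for a in r.atoms])
        offset = np.array([8.0, 12.0, 7.0]) - xyz.mean(axis=0)
        residues = [ResidueRecord(r.comp_id, r.seq_num,
                                  [replace(a, xyz=tuple(np.asarray(a.xyz) + offset))
                                   for a in r.atoms])
                    for r in chain.residues]
        return ChainRecord("A", residues)

    def test_far_water_moved_to_nearer_image(self):
        chain = self._centered_helix()
        poly = np.array([a.xyz for r in chain.residues for a in r.atoms])
        near = poly.mean(axis=0) + np.array([0.0, 0.0, 6.5])
        # store the op-1 image of a near-chain site: reposition must undo it
        frac = P2_CELL.fractionalize(near)
        far = (P2_OPS[1].apply(frac) + np.array([1.0, 0.0, 0.0])) \
            @ P2_CELL.orth_matrix().T
        dep = simple_deposition(chain.residues, [water(1001, tuple(far))])
        moves, findings = reposition_waters(dep)
        assert len(moves) == 1
        moved = np.asarray(dep.chains[0].residues[-1].atoms[0].xyz)
        dists = np.linalg.norm(poly - moved, axis=1)
        assert dists.min() < np.linalg.norm(poly - far, axis=1).min()
        assert dists.min() == pytest.approx(
            np.linalg.norm(poly - near, axis=1).min(), abs=1e-6)

    def test_optimal_water_left_untouched(self):
        chain = self._centered_helix()
        poly = np.array([a.xyz for r in chain.residues for a in r.atoms])
        near = tuple(poly.mean(axis=0) + np.array([0.0, 0.0, 6.0]))
        dep = simple_deposition(chain.residues, [water(1001, near)])
        before = dep.chains[0].residues[-1].atoms[0].xyz
        moves, _ = reposition_waters(dep)
        maybe_same = dep.chains[0].residues[-1].atoms[0].xyz
        if not moves:
            assert maybe_same == before

    def test_unreachable_water_flagged_distant(self):
        chain = self._centered_helix()
        dep, _ = make_deposition(DefectPlan(codes=("distant_water",)))
        _, findings = reposition_waters(dep)
        assert [f.code for f in findings] == ["Distant waters"]

    def test_non_crystallographic_entry_is_noop(self, helix_chain):
        dep = Deposition(dep_id="t", chains=[helix_chain])
        moves, findings = reposition_waters(dep)
        assert moves == []
        assert [f.code for f in findings] == ["not_applicable"]

    def test_moves_never_worsen_and_map_back(self):
        # every moved water is an exact symmetry image of its original
        dep, _ = make_deposition(DefectPlan(codes=("misplaced_water",)))
        originals = {(c.chain_id, r.seq_num): np.asarray(r.atoms[0].xyz)
                     for c in dep.chains for r in c.residues if r.is_water}
        n_atoms = sum(len(r.atoms) for c in dep.chains for r in c.residues)
        poly = np.array([a.xyz for c in dep.chains
                         for r in c.residues if r.is_standard_aa
                         for a in r.atoms])
        moves, _ = reposition_waters(dep)
        assert sum(len(r.atoms) for c in dep.chains
                   for r in c.residues) == n_atoms
        for m in moves:
            old = originals[(m["chain"], m["seq_num"])]
            new = np.asarray(m["new_xyz"])
            d_old = np.linalg.norm(poly - old, axis=1).min()
            d_new = np.linalg.norm(poly - new, axis=1).min()
            assert d_new <= d_old + 1e-9
            # inverse mapping: applying the op to the original reproduces it
            from minidep.fixture_factory import CELL
            frac = CELL.fractionalize(old)
            ops = space_group_ops("P 1 2 1")
            img = (ops[m["op_index"]].apply(frac)
                   + np.asarray(m["shift"], dtype=float)) @ CELL.orth_matrix().T
            assert np.allclose(img, new, atol=1e-6)


class TestGenerateLinks:
    def test_disulfide_detected(self):
        r1 = ResidueRecord("CYS", 1, [AtomRecord("SG", "S", (0.0, 0.0, 0.0)),
                                      AtomRecord("CB", "C", (0.0, 1.8, 0.0))])
        r2 = ResidueRecord("CYS", 5, [AtomRecord("SG", "S", (2.05, 0.0, 0.0)),
                                      AtomRecord("CB", "C", (2.05, -1.8, 0.0))])
        dep = Deposition(dep_id="t", chains=[ChainRecord("A", [r1, r2])])
        links, _ = generate_links(dep)
        pairs = {(l["atom1"][3], l["atom2"][3]) for l in links}
        assert ("SG", "SG") in pairs
        ss = [l for l in links if l["atom1"][3] == "SG" and l["atom2"][3] == "SG"]
        assert ss[0]["distance"] == pytest.approx(2.05)

    def test_backbone_peptide_bond_excluded(self, helix_chain):
        dep = Deposition(dep_id="t", chains=[helix_chain])
        links, _ = generate_links(dep)
        assert not any({l["atom1"][3], l["atom2"][3]} == {"C", "N"}
                       and abs(l["atom1"][1] - l["atom2"][1]) == 1
                       for l in links)

    def test_glycosylation_link_detected(self):
        asn = ResidueRecord("ASN", 10, [AtomRecord("ND2", "N", (0.0, 0.0, 0.0)),
                                        AtomRecord("CG", "C", (0.0, 1.35, 0.0))])
        nag = ResidueRecord("NAG", 501, [AtomRecord("C1", "C", (1.45, 0.0, 0.0)),
                                         AtomRecord("O5", "O", (1.45, -1.4, 0.0))])
        dep = Deposition(dep_id="t", chains=[ChainRecord("A", [asn, nag])])
        links, _ = generate_links(dep)
        assert any({l["atom1"][3], l["atom2"][3]} == {"ND2", "C1"}
                   for l in links)


class TestSecondaryStructure:
    def test_ideal_helix_interior_assigned_h(self):
        chain = build_backbone(["ALA"] * 12, [HELIX_PHI_PSI] * 12)
        ss, findings = assign_secondary_structure(chain)
        assert findings == []
        assert all(ss.states[i] == "H" for i in range(3, 11))

    def test_short_isolated_extended_chain_is_coil(self):
        chain = build_backbone(["ALA"] * 5, [STRAND_PHI_PSI] * 5)
        ss, _ = assign_secondary_structure(chain)
        assert set(ss.states.values()) == {"C"}

    def test_antiparallel_sheet_assigned_strand(self):
        ss, _ = assign_secondary_structure(make_beta_sheet())
        n_strand = sum(1 for s in ss.states.values() if s == "E")
        assert n_strand >= 8

    def test_invariant_under_rigid_motion(self):
        chain = build_backbone(["ALA"] * 12, [HELIX_PHI_PSI] * 12)
        rot = np.asarray(rotation_about_axis([1.0, 2.0, 0.5], 73.0))
        moved = transform_chain(chain, rot, np.array([5.0, -3.0, 11.0]))
        ss1, _ = assign_secondary_structure(chain)
        ss2, _ = assign_secondary_structure(moved)
        assert ss1.states == ss2.states

    def test_missing_backbone_becomes_coil_with_note(self):
        chain = build_backbone(["ALA"] * 8, [HELIX_PHI_PSI] * 8)
        chain.residues[3].atoms = [a for a in chain.residues[3].atoms
                                   if a.name != "O"]
        ss, findings = assign_secondary_structure(chain)
        assert ss.states[4] == "C"
        assert any(f.code == "not_applicable" for f in findings)


class TestBuildAssembly:
    def _dep(self, helix_chain):
        dep = Deposition(dep_id="t", chains=[helix_chain],
                         sample_sequences={"A": "A" * 10})
        dep.entities, _ = build_entities(dep.chains, dep.sample_sequences)
        return dep

    def test_identity_reproduces_coordinates_bitwise(self, helix_chain):
        dep = self._dep(helix_chain)
        chains, stoich = build_assembly(dep, [IDENTITY_ASSEMBLY_OP])
        assert len(chains) == 1
        assert chains[0].residues[0].atoms[0].xyz == \
            helix_chain.residues[0].atoms[0].xyz
        assert stoich == {1: 1}

    def test_twofold_generates_dimer(self, helix_chain):
        dep = self._dep(helix_chain)
        two_fold = AssemblyOp("2", rotation_about_axis([0, 0, 1], 180.0),
                              (25.0, 0.0, 0.0))
        chains, stoich = build_assembly(dep, [IDENTITY_ASSEMBLY_OP, two_fold])
        assert [c.chain_id for c in chains] == ["A", "A_2"]
        assert stoich == {1: 2}

    def test_c3_closure_and_rigidity(self, helix_chain):
        dep = self._dep(helix_chain)
        ops = [IDENTITY_ASSEMBLY_OP,
               AssemblyOp("2", rotation_about_axis([0, 0, 1], 120.0)),
               AssemblyOp("3", rotation_about_axis([0, 0, 1], 240.0))]
        chains, stoich = build_assembly(dep, ops)
        assert stoich == {1: 3}
        rot = np.asarray(ops[1].rot)
        first = np.array([a.xyz for r in chains[0].residues for a in r.atoms])
        second = np.array([a.xyz for r in chains[1].residues for a in r.atoms])
        third = np.array([a.xyz for r in chains[2].residues for a in r.atoms])
        assert np.allclose(second @ rot.T, third, atol=1e-8)
        d0 = np.linalg.norm(first[:, None] - first[None, :], axis=-1)
        d1 = np.linalg.norm(second[:, None] - second[None, :], axis=-1)
        assert np.abs(d0 - d1).max() < 1e-8

    def test_non_orthonormal_operator_rejected(self, helix_chain):
        dep = self._dep(helix_chain)
        bad = AssemblyOp("9", ((1.1, 0, 0), (0, 1, 0), (0, 0, 1)))
        with pytest.raises(OperatorError, match="9"):
            build_assembly(dep, [bad])


class TestRenumberHeteros:
    def test_waters_renumbered_from_1001(self, helix_chain):
        poly = helix_chain.residues
        waters = [water(1 + i, tuple(np.asarray(poly[i].atom("O").xyz)
                                     + np.array([0.0, 0.0, 4.0])))
                  for i in range(3)]
        dep = Deposition(dep_id="t", chains=[
            ChainRecord("A", poly),
            ChainRecord("W", waters)])
        mapping = renumber_heteros(dep)
        new = sorted(v for k, v in mapping.items())
        assert new == [("A", 1001), ("A", 1002), ("A", 1003)]

    def test_second_application_is_identity(self, base_deposition):
        dep, _ = base_deposition
        renumber_heteros(dep)
        second = renumber_heteros(dep)
        assert all(k == v for k, v in second.items())

    def test_equidistant_water_goes_to_smaller_chain_id(self):
        r1 = ResidueRecord("ALA", 1, [AtomRecord("CA", "C", (0.0, 0.0, 0.0)),
                                      AtomRecord("N", "N", (1.46, 0.0, 0.0))])
        r2 = ResidueRecord("ALA", 2, [AtomRecord("CA", "C", (0.0, 3.8, 0.0)),
                                      AtomRecord("N", "N", (1.46, 3.8, 0.0))])
        b1 = ResidueRecord("ALA", 1, [AtomRecord("CA", "C", (10.0, 0.0, 0.0)),
                                      AtomRecord("N", "N", (8.54, 0.0, 0.0))])
        b2 = ResidueRecord("ALA", 2, [AtomRecord("CA", "C", (10.0, 3.8, 0.0)),
                                      AtomRecord("N", "N", (8.54, 3.8, 0.0))])
        w = water(1, (5.0, 0.0, 0.0))
        dep = Deposition(dep_id="t", chains=[
            ChainRecord("B", [b1, b2]), ChainRecord("A", [r1, r2]),
            ChainRecord("W", [w])])
        mapping = renumber_heteros(dep)
        assert mapping[("W", 1)][0] == "A"


class TestExtendedChecks:
    def test_interpenetrating_atoms_clash(self):
        r1 = ResidueRecord("ALA", 1, [AtomRecord("CB", "C", (0.0, 0.0, 0.0))])
        r2 = ResidueRecord("ALA", 5, [AtomRecord("CB", "C", (1.0, 0.0, 0.0))])
        dep = Deposition(dep_id="t", chains=[ChainRecord("A", [r1, r2])])
        codes = [f.code for f in extended_checks(dep)]
        assert "Atomic clashes" in codes

    def test_zero_occupancy_flagged(self, helix_chain):
        chain = ChainRecord("A", [
            ResidueRecord(r.comp_id, r.seq_num,
                          [replace(a) for a in r.atoms])
            for r in helix_chain.residues])
        chain.residues[0].atoms[0].occupancy = 0.0
        dep = Deposition(dep_id="t", chains=[chain])
        codes = [f.code for f in extended_checks(dep)]
        assert codes.count("Atoms with unrealistic or zero occupancies") == 1

    def test_wavelength_discrepancy_flagged(self, base_deposition):
        dep, _ = base_deposition
        dep.metadata.tables["reflns"][0]["reflns.pdbx_sf_wavelength"] = "1.5418"
        dep.metadata.tables["reflns"][0]["reflns.pdbx_wavelength"] = "0.9793"
        codes = [f.code for f in extended_checks(dep)]
        assert codes.count("Wavelength discrepancy") == 1

    def test_atom_on_twofold_with_full_occupancy(self, base_deposition):
        dep, _ = base_deposition
        # self-image oracle: a point on the b axis maps onto itself under -x,y,-z
        from minidep.fixture_factory import CELL
        p = np.array([0.0, 0.55, 0.0]) @ CELL.orth_matrix().T
        frac = CELL.fractionalize(p)
        img = P2_OPS[1].apply(frac)
        assert np.allclose((img - frac) - np.round(img - frac), 0.0, atol=1e-12)
        dep.chains[0].residues.append(water(2001, tuple(p), occupancy=1.0))
        codes = [f.code for f in extended_checks(dep)]
        assert codes.count("Occupancy of atoms on special symmetry positions") >= 1

    def test_defect_free_base_has_no_errors(self, base_deposition, ccd):
        from minidep.findings import VOCABULARY

        dep, _ = base_deposition
        findings = extended_checks(dep, ccd=ccd)
        assert [f for f in findings if VOCABULARY[f.code] == "error"] == []


class TestCellGeometry:
    @pytest.mark.parametrize("cell", [
        CellParams(46.0, 36.0, 40.0, 90.0, 100.0, 90.0),
        CellParams(30.0, 30.0, 90.0, 90.0, 90.0, 120.0),
        CellParams(52.3, 61.7, 73.1, 81.0, 95.5, 103.2),
    ])
    def test_fractional_orthogonal_round_trip(self, cell):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-50, 50, size=(100, 3))
        back = cell.orthogonalize(cell.fractionalize(pts))
        assert np.abs(back - pts).max() < 1e-9

    def test_symop_triplet_round_trip(self):
        for trip in ("x,y,z", "-x,y+1/2,-z", "-x+1/2,-y,z+1/2"):
            op = SymOp.from_triplet(trip)
            assert SymOp.from_triplet(op.triplet()) == op
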