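"""Ligand graph perception, CCD sub-graph search, chirality, registration.

The sub-graph matcher is cross-checked against an independent brute-force
backtracking enumerator over element-consistent injections.
"""

from dataclasses import replace
from itertools import permutations

import networkx as nx
import numpy as np
import pytest

from minidep.entity_builder import AtomRecord, ResidueRecord
from minidep.ligand_processor import (ChemComp, DuplicateComponentError,
                                      IdCollisionError, PerceptionError,
                                      check_chirality, component_graph,
                                      perceive_graph, register_component,
                                      search_ccd, standardize_atoms)
from tests.conftest import comp_instance


# ---------------------------------------------------------------------------
# independent oracle: brute-force enumeration of sub-graph embeddings

def brute_force_embeddings(inst: nx.Graph, comp: nx.Graph):
    """All injective maps inst -> comp preserving elements and edges."""
    inst_nodes = list(inst.nodes)
    results = []

    def extend(k, mapping):
        if k == len(inst_nodes):
            results.append(dict(mapping))
            return
        u = inst_nodes[k]
        for v in comp.nodes:
            if v in mapping.values():
                continue
            if inst.nodes[u]["element"] != comp.nodes[v]["element"]:
                continue
            ok = True
            for w in inst.neighbors(u):
                if w in mapping and not comp.has_edge(mapping[w], v):
                    ok = False
                    break
            if ok:
                mapping[u] = v
                extend(k + 1, mapping)
                del mapping[u]

    extend(0, {})
    return results


def brute_force_hits(graph, ccd):
    """Oracle version of search_ccd: hit set and scores by enumeration."""
    inst = graph.to_networkx()
    hits = {}
    for comp in ccd:
        cg = component_graph(comp)
        if brute_force_embeddings(inst, cg):
            denom = cg.number_of_nodes() + cg.number_of_edges()
            hits[comp.comp_id] = (inst.number_of_nodes()
                                  + inst.number_of_edges()) / denom
    return hits


def residue(atoms):
    return ResidueRecord("UNL", 1, [AtomRecord(n, el, xyz)
                                    for n, el, xyz in atoms])


class TestPerceiveGraph:
    def test_two_carbons_at_bonding_distance(self):
        g = perceive_graph(residue([("C1", "C", (0, 0, 0)),
                                    ("C2", "C", (1.5, 0, 0))]))
        assert len(g.edges) == 1

    def test_distant_atoms_unbonded(self):
        g = perceive_graph(residue([("C1", "C", (0, 0, 0)),
                                    ("N1", "N", (3.0, 0, 0))]))
        assert g.edges == []

    def test_ideal_alanine_topology(self, ccd):
        ala = next(c for c in ccd if c.comp_id == "ALA")
        g = perceive_graph(comp_instance(ala))
        assert len(g.nodes) == 5 and len(g.edges) == 4
        names = {frozenset((g.atom_names[a], g.atom_names[b]))
                 for a, b in g.edges}
        assert names == {frozenset(p) for p in
                         [("N", "CA"), ("CA", "C"), ("C", "O"), ("CA", "CB")]}

    def test_duplicate_positions_rejected(self):
        with pytest.raises(PerceptionError):
            perceive_graph(residue([("C1", "C", (0, 0, 0)),
                                    ("C2", "C", (0.005, 0, 0))]))


class TestSearchCcd:
    def test_complete_alanine_scores_one(self, ccd):
        ala = next(c for c in ccd if c.comp_id == "ALA")
        hits = search_ccd(perceive_graph(comp_instance(ala)), ccd)
        assert hits[0].comp_id == "ALA"
        assert hits[0].score == 1.0

    def test_partial_alanine_scores_seven_ninths(self, ccd):
        ala = next(c for c in ccd if c.comp_id == "ALA")
        inst = comp_instance(ala)
        inst.atoms = [a for a in inst.atoms if a.name != "CB"]
        hits = search_ccd(perceive_graph(inst), ccd)
        ala_hit = next(h for h in hits if h.comp_id == "ALA")
        assert ala_hit.score == pytest.approx(7 / 9)
        assert ala_hit.unmatched_component_atoms == ["CB"]

    def test_glycine_outranks_partial_alanine(self, ccd):
        gly = next(c for c in ccd if c.comp_id == "GLY")
        hits = search_ccd(perceive_graph(comp_instance(gly)),
                          [c for c in ccd if c.comp_id in ("ALA", "GLY")])
        assert [h.comp_id for h in hits] == ["GLY", "ALA"]
        assert hits[0].score == 1.0
        assert hits[1].score == pytest.approx(7 / 9)

    @pytest.mark.parametrize("comp_id", ["ALA", "GLY", "CYS", "VAL", "LEU", "LG7"])
    def test_matcher_agrees_with_brute_force(self, ccd, comp_id):
        comp = next(c for c in ccd if c.comp_id == comp_id)
        graph = perceive_graph(comp_instance(comp))
        got = {h.comp_id: h.score for h in search_ccd(graph, ccd)}
        oracle = brute_force_hits(graph, ccd)
        assert got == pytest.approx(oracle)

    def test_score_monotone_under_atom_deletion(self, ccd):
        nag = next(c for c in ccd if c.comp_id == "NAG")
        inst = comp_instance(nag)
        full = search_ccd(perceive_graph(inst), ccd)[0].score
        for drop in ("O6", "C8", "O3"):
            sub = replace(inst, atoms=[a for a in inst.atoms if a.name != drop])
            partial = next(h for h in search_ccd(perceive_graph(sub), ccd)
                           if h.comp_id == "NAG").score
            assert partial < full

    def test_ranking_invariant_under_atom_name_permutation(self, ccd):
        lg7 = next(c for c in ccd if c.comp_id == "LG7")
        inst = comp_instance(lg7)
        ranked1 = [(h.comp_id, h.score)
                   for h in search_ccd(perceive_graph(inst), ccd)]
        renamed = replace(inst, atoms=[replace(a, name=f"Q{i}")
                                       for i, a in enumerate(inst.atoms)])
        ranked2 = [(h.comp_id, h.score)
                   for h in search_ccd(perceive_graph(renamed), ccd)]
        assert ranked1 == ranked2

    def test_oversized_graph_yields_no_hits(self, ccd):
        atoms = [(f"C{i}", "C", (1.5 * i, 0.0, 0.0)) for i in range(20)]
        hits = search_ccd(perceive_graph(residue(atoms)), ccd)
        assert hits == []


class TestStandardizeAtoms:
    def test_mapping_applied_to_arbitrary_names(self, ccd):
        ala = next(c for c in ccd if c.comp_id == "ALA")
        inst = comp_instance(ala)
        inst.atoms = [replace(a, name=f"A{i}") for i, a in enumerate(inst.atoms)]
        hit = search_ccd(perceive_graph(inst), ccd)[0]
        renaming = standardize_atoms(perceive_graph(inst), hit)
        assert sorted(renaming.values()) == ["C", "CA", "CB", "N", "O"]

    def test_already_standard_names_map_identically(self, ccd):
        ala = next(c for c in ccd if c.comp_id == "ALA")
        inst = comp_instance(ala)
        hit = search_ccd(perceive_graph(inst), ccd)[0]
        renaming = standardize_atoms(perceive_graph(inst), hit)
        assert all(k == v for k, v in renaming.items())

    def test_symmetric_molecule_mapping_is_deterministic(self, ccd):
        # VAL's CG1/CG2 are interchangeable: the lexicographically smallest
        # of all automorphic mappings must be chosen every run
        val = next(c for c in ccd if c.comp_id == "VAL")
        inst = comp_instance(val)
        inst.atoms = [replace(a, name=f"X{i}") for i, a in enumerate(inst.atoms)]
        graph = perceive_graph(inst)
        maps = [search_ccd(graph, ccd)[0].mapping for _ in range(3)]
        assert maps[0] == maps[1] == maps[2]
        cg = component_graph(val)
        embeddings = brute_force_embeddings(graph.to_networkx(), cg)
        names = graph.atom_names
        candidates = [tuple(sorted((names[k], v) for k, v in e.items()))
                      for e in embeddings]
        assert tuple(sorted(maps[0].items())) == min(candidates)

    def test_below_threshold_is_rejected(self, ccd):
        ala = next(c for c in ccd if c.comp_id == "ALA")
        inst = comp_instance(ala)
        inst.atoms = inst.atoms[:-1]
        hit = next(h for h in search_ccd(perceive_graph(inst), ccd)
                   if h.comp_id == "ALA")
        with pytest.raises(ValueError):
            standardize_atoms(perceive_graph(inst), hit)


def _mirror(residue_record):
    return replace(residue_record, atoms=[
        replace(a, xyz=(a.xyz[0], a.xyz[1], -a.xyz[2]))
        for a in residue_record.atoms])


class TestCheckChirality:
    def test_correct_alanine_is_clean(self, ccd):
        ala = next(c for c in ccd if c.comp_id == "ALA")
        inst = comp_instance(ala)
        mapping = {a.name: a.name for a in inst.atoms}
        assert check_chirality(inst, ala, mapping) == []

    def test_mirror_image_raises_chirality_error(self, ccd):
        ala = next(c for c in ccd if c.comp_id == "ALA")
        inst = _mirror(comp_instance(ala))
        mapping = {a.name: a.name for a in inst.atoms}
        findings = check_chirality(inst, ala, mapping)
        assert [f.code for f in findings] == ["Chirality error"]

    def test_signed_volume_agrees_with_direct_computation(self, ccd):
        ala = next(c for c in ccd if c.comp_id == "ALA")
        inst = comp_instance(ala)
        ca = np.array(inst.atom("CA").xyz)
        v = [np.array(inst.atom(n).xyz) - ca for n in ("N", "C", "CB")]
        vol = float(np.dot(v[0], np.cross(v[1], v[2])))
        center, neighbors, parity = ala.stereocenters[0]
        assert (vol > 0) == (parity > 0)

    def test_flattened_center_is_indeterminate(self, ccd):
        ala = next(c for c in ccd if c.comp_id == "ALA")
        inst = comp_instance(ala)
        flat = replace(inst, atoms=[replace(a, xyz=(a.xyz[0], a.xyz[1], 0.0))
                                    for a in inst.atoms])
        mapping = {a.name: a.name for a in flat.atoms}
        findings = check_chirality(flat, ala, mapping)
        assert [f.code for f in findings] == ["chirality_indeterminate"]

    def test_mirror_findings_are_complementary(self, ccd):
        # every well-defined stereocenter errors in exactly one of the pair
        nag = next(c for c in ccd if c.comp_id == "NAG")
        inst = comp_instance(nag)
        mapping = {a.name: a.name for a in inst.atoms}
        direct = [f.code for f in check_chirality(inst, nag, mapping)]
        mirrored = [f.code for f in check_chirality(_mirror(inst), nag, mapping)]
        assert direct.count("Chirality error") + \
            mirrored.count("Chirality error") == len(nag.stereocenters)


class TestRegisterComponent:
    def _novel(self):
        return residue([("C1", "C", (0.0, 0.0, 0.0)),
                        ("C2", "C", (1.5, 0.0, 0.0)),
                        ("O1", "O", (1.5, 1.4, 0.0)),
                        ("N1", "N", (3.0, 0.0, 0.0)),
                        ("C3", "C", (3.0, -1.45, 0.0)),
                        ("S1", "S", (4.8, 0.0, 0.0)),
                        ("O2", "O", (4.8, 1.45, 0.0))])

    def test_novel_ligand_registered_and_found(self, ccd):
        working = list(ccd)
        graph = perceive_graph(self._novel())
        comp = register_component(graph, "XX1", working)
        assert comp.comp_id == "XX1"
        hits = search_ccd(graph, working)
        assert hits[0].comp_id == "XX1" and hits[0].score == 1.0

    def test_duplicate_graph_names_existing_component(self, ccd):
        ala = next(c for c in ccd if c.comp_id == "ALA")
        graph = perceive_graph(comp_instance(ala))
        with pytest.raises(DuplicateComponentError) as exc:
            register_component(graph, "XX2", list(ccd))
        assert exc.value.comp_id == "ALA"

    def test_taken_id_is_collision(self, ccd):
        graph = perceive_graph(self._novel())
        with pytest.raises(IdCollisionError):
            register_component(graph, "ALA", list(ccd))
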