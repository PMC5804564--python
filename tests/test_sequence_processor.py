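"""Sequence reconciliation: alignment, annotation classes, chimeras, repair.

The production aligner is cross-checked against a quadratic-space affine
(Gotoh) dynamic program written independently here.
"""

import numpy as np
import pytest

from minidep.entity_builder import AtomRecord, ChainRecord, ResidueRecord
from minidep.fixture_factory import (SWAP_END, SWAP_START, chimera_sample,
                                     tagged_mutant_sample, make_chimera_case,
                                     refdb_records)
from minidep.peptide_builder import HELIX_PHI_PSI, build_backbone
from minidep.sequence_processor import (MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND,
                                        RefRecord, derive_coord_sequence,
                                        global_align, local_align, read_refdb,
                                        reconcile, repair_residue_labels,
                                        search_references, segment_chimera,
                                        write_refdb)

NEG = -1e18


def gotoh_local(a, b):
    """Textbook affine-gap Smith-Waterman, score only."""
    n, m = len(a), len(b)
    best = 0.0
    M = np.zeros((n + 1, m + 1))
    X = np.full((n + 1, m + 1), NEG)  # gap in b (deletion)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a (insertion)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            X[i][j] = max(M[i - 1][j] + GAP_OPEN, X[i - 1][j] + GAP_EXTEND)
            Y[i][j] = max(M[i][j - 1] + GAP_OPEN, Y[i][j - 1] + GAP_EXTEND)
            M[i][j] = max(0.0, M[i - 1][j - 1] + s, X[i][j], Y[i][j])
            best = max(best, M[i][j])
    return best


def gotoh_global_free_ref_ends(a, b):
    """Textbook affine-gap global alignment, free end gaps on b."""
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b
    Y = np.full((n + 1, m + 1), NEG)  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = 0.0  # leading gap in b is free
    for j in range(1, m + 1):
        Y[0][j] = GAP_OPEN + GAP_EXTEND * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + GAP_OPEN, X[i - 1][j] + GAP_EXTEND)
            Y[i][j] = max(M[i][j - 1] + GAP_OPEN, Y[i][j - 1] + GAP_EXTEND)
    # trailing gap in b is free: finish at any row of the last column
    best = NEG
    for i in range(0, n + 1):
        best = max(best, M[i][m], Y[i][m])
    return best


def random_seq(rng, n):
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))


class TestAligner:
    @pytest.mark.parametrize("seed", range(5))
    def test_local_score_matches_textbook_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = random_seq(rng, int(rng.integers(5, 50)))
        b = random_seq(rng, int(rng.integers(5, 50)))
        score, *_ = local_align(a, b)
        assert score == pytest.approx(gotoh_local(a, b))

    @pytest.mark.parametrize("seed", range(5))
    def test_global_score_matches_textbook_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        a = random_seq(rng, int(rng.integers(5, 40)))
        b = random_seq(rng, int(rng.integers(5, 40)))
        score, srow, rrow = global_align(a, b)
        assert srow.replace("-", "") == a
        assert rrow.replace("-", "") == b
        assert score == pytest.approx(gotoh_global_free_ref_ends(a, b))


class TestDeriveCoordSequence:
    def _chain(self, sample, modeled):
        comps = {"A": "ALA", "G": "GLY", "L": "LEU", "V": "VAL", "S": "SER"}
        residues = []
        chain = build_backbone(
            [comps.get(c, "ALA") for c in sample], [HELIX_PHI_PSI] * len(sample))
        for res, pos in zip(chain.residues, range(1, len(sample) + 1)):
            if pos in modeled:
                residues.append(res)
        return ChainRecord("A", residues)

    def test_unmodeled_span_becomes_gap(self):
        sample = "A" * 50
        chain = self._chain(sample, set(range(1, 21)) | set(range(26, 51)))
        coord, findings = derive_coord_sequence(chain, sample)
        assert coord[20:25] == "-----"
        assert coord.count("A") == 45
        assert findings == []

    def test_fully_modeled_chain_reproduces_sample(self):
        sample = "AGLVS" * 4
        chain = self._chain(sample, set(range(1, 21)))
        coord, findings = derive_coord_sequence(chain, sample)
        assert coord == sample and findings == []

    def test_residue_conflict_is_sequence_discrepancy(self):
        sample = "A" * 10
        chain = self._chain(sample, set(range(1, 11)))
        chain.residues[4].comp_id = "VAL"
        coord, findings = derive_coord_sequence(chain, sample)
        assert coord[4] == "V"
        assert [f.code for f in findings] == ["Sequence discrepancy"]

    def test_residue_outside_sample_is_error(self):
        sample = "A" * 5
        chain = self._chain("A" * 8, set(range(1, 9)))
        _, findings = derive_coord_sequence(chain, sample)
        assert all(f.code == "Sequence discrepancy" for f in findings)
        assert len(findings) == 3


class TestSearchReferences:
    def test_identical_sequence_ranks_first(self, refdb):
        ref = refdb[0]
        hits = search_references(ref.sequence, refdb, ref.taxonomy_id)
        assert hits[0].accession == ref.accession
        assert hits[0].taxonomy_match

    def test_taxonomy_breaks_score_ties(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        refs = [RefRecord("AAA", seq, "other organism", 9999),
                RefRecord("BBB", seq, "declared organism", 10090)]
        hits = search_references(seq, refs, declared_taxonomy=10090)
        assert [h.accession for h in hits] == ["BBB", "AAA"]

    def test_unrelated_sample_yields_empty_list(self, refdb):
        rng = np.random.default_rng(42)
        sample = random_seq(rng, 30)
        # guard: the oracle SW score against every record stays below cutoff
        for rec in refdb:
            assert gotoh_local(sample, rec.sequence) < 30
        assert search_references(sample, refdb) == []


class TestReconcile:
    def test_tag_and_declared_mutation(self, refdb):
        sample, decl = tagged_mutant_sample(refdb)
        ref = next(r for r in refdb if r.accession == "REF001")
        anns, findings, alignment = reconcile(sample, sample, ref, decl)
        assert [(a.start, a.end, a.cls) for a in anns] == [
            (1, 9, "expression tag"), (64, 64, "mutation")]
        assert findings == []
        assert alignment.sample_row.replace("-", "") == sample

    def test_identical_fully_modeled_is_empty(self, refdb):
        ref = refdb[0]
        anns, findings, _ = reconcile(ref.sequence, ref.sequence, ref, {})
        assert anns == [] and findings == []

    def test_undeclared_conflict_raises_correspondence(self, refdb):
        ref = refdb[0]
        sample = list(ref.sequence)
        sample[20] = "W" if sample[20] != "W" else "Y"
        sample = "".join(sample)
        anns, findings, _ = reconcile(sample, sample, ref, {})
        assert [(a.start, a.cls) for a in anns] == [(21, "conflict")]
        assert [f.code for f in findings] == ["correspondence_needed"]

    def test_classes_partition_discrepant_columns(self, refdb):
        sample, decl = tagged_mutant_sample(refdb)
        ref = next(r for r in refdb if r.accession == "REF001")
        _, _, alignment = reconcile(sample, sample, ref, decl)
        for k in range(len(alignment.sample_row)):
            s, r = alignment.sample_row[k], alignment.reference_row[k]
            if s != r:
                assert alignment.column_classes[k] is not None
            else:
                assert alignment.column_classes[k] is None

    def test_unmodeled_span_annotated(self, refdb):
        ref = refdb[0]
        coord = "-" * 10 + ref.sequence[10:]
        anns, _, _ = reconcile(ref.sequence, coord, ref, {})
        assert [(a.start, a.end, a.cls) for a in anns] == [(1, 10, "unmodeled")]


class TestSegmentChimera:
    def test_grafted_loop_architecture_recovered_exactly(self, refdb):
        sample = chimera_sample(refdb)
        cmap, findings = segment_chimera(sample, refdb)
        assert findings == []
        assert cmap.is_chimeric
        assert [s[2] for s in cmap.segments] == ["CHIMA", "CHIMB", "CHIMA"]
        assert cmap.segments[1][:2] == (SWAP_START, SWAP_END)
        assert cmap.segments[1][1] - cmap.segments[1][0] + 1 == 16

    def test_single_source_sample_is_one_segment(self, refdb):
        ref = next(r for r in refdb if r.accession == "CHIMA")
        cmap, _ = segment_chimera(ref.sequence, refdb)
        assert len(cmap.segments) == 1
        assert cmap.segments[0][:3] == (1, len(ref.sequence), "CHIMA")

    def test_infinite_switch_penalty_collapses_to_one_reference(self, refdb):
        sample = chimera_sample(refdb)
        cmap, _ = segment_chimera(sample, refdb, kappa=1e9)
        accs = {s[2] for s in cmap.segments}
        assert len(accs) == 1

    def test_dp_matches_exhaustive_enumeration_on_small_fixture(self):
        # enumerate every <=3-segment ungapped segmentation of a 48-mer
        # against two references and check the DP picks the best pattern
        import itertools

        rng = np.random.default_rng(3)
        a = random_seq(rng, 48)
        b = random_seq(rng, 48)
        sample = a[:16] + b[16:32] + a[32:]
        refs = [RefRecord("RA", a, "a", 1), RefRecord("RB", b, "b", 2)]
        kappa = 20.0

        def best_offset_score(piece, ref):
            best = -1e18
            for off in range(0, len(ref.sequence) - len(piece) + 1):
                sc = sum(2.0 if x == y else -1.0
                         for x, y in zip(piece, ref.sequence[off:]))
                best = max(best, sc)
            return best

        n = len(sample)
        cuts = [()] + [(i,) for i in range(1, n)] + [
            (i, j) for i in range(1, n) for j in range(i + 1, n)]
        best_total, best_pattern = -1e18, None
        for cut in cuts:
            bounds = [0, *cut, n]
            pieces = [sample[bounds[k]:bounds[k + 1]]
                      for k in range(len(bounds) - 1)]
            per_ref = [[best_offset_score(p, r) for r in refs] for p in pieces]
            for combo in itertools.product(range(2), repeat=len(pieces)):
                total = sum(per_ref[k][c] for k, c in enumerate(combo))
                # every re-anchoring costs kappa, same reference or not
                total -= kappa * (len(pieces) - 1)
                if total > best_total:
                    pattern = []
                    for c in combo:  # merge adjacent same-reference pieces
                        acc = refs[c].accession
                        if not pattern or pattern[-1] != acc:
                            pattern.append(acc)
                    best_total, best_pattern = total, pattern
        cmap, _ = segment_chimera(sample, refs, kappa=kappa)
        assert [s[2] for s in cmap.segments] == best_pattern == ["RA", "RB", "RA"]

    def test_no_hits_returns_unassigned_segment(self):
        refs = [RefRecord("RX", "WWWWWWWWWWWWWWWWWWWW", "x", 1)]
        cmap, findings = segment_chimera("A" * 25, refs)
        assert cmap.segments[0][2] is None
        assert [f.code for f in findings] == ["chimera_unassigned"]

    def test_planted_boundaries_recovered_for_random_constructs(self):
        hits = 0
        for seed in range(20):
            sample, refs, (start, end) = make_chimera_case(seed)
            cmap, _ = segment_chimera(sample, refs)
            segs = [s for s in cmap.segments if s[2] == "SRCB"]
            if len(segs) == 1 and segs[0][:2] == (start, end):
                hits += 1
        assert hits >= 19


class TestRepairResidueLabels:
    def _chain_with(self, comp_id, atom_names, pos=1):
        atoms = [AtomRecord(n, "C" if n not in ("N", "O") else n[0],
                            (float(i), 0.0, 0.0))
                 for i, n in enumerate(atom_names)]
        other = build_backbone(["ALA"], [HELIX_PHI_PSI], start_seq_num=2)
        return ChainRecord("A", [ResidueRecord(comp_id, pos, atoms)]
                           + other.residues)

    def test_truncated_alanine_relabeled_to_sample(self):
        chain = self._chain_with("ALA", ["N", "CA", "C", "O", "CB"])
        edits, findings = repair_residue_labels(chain, "LA")
        assert edits == [("A", 1, "ALA", "LEU")]
        assert [f.code for f in findings] == ["residue_relabeled"]

    def test_consistent_residue_untouched(self):
        chain = self._chain_with("ALA", ["N", "CA", "C", "O", "CB"])
        edits, findings = repair_residue_labels(chain, "AA")
        assert edits == [] and findings == []

    def test_full_sidechain_mismatch_needs_correspondence(self):
        chain = self._chain_with("VAL", ["N", "CA", "C", "O", "CB",
                                         "CG1", "CG2"])
        edits, findings = repair_residue_labels(chain, "AA")
        assert edits == []
        assert [f.code for f in findings] == ["Sequence discrepancy"]

    def test_repair_never_moves_atoms(self):
        chain = self._chain_with("ALA", ["N", "CA", "C", "O", "CB"])
        before = [(a.name, a.xyz) for r in chain.residues for a in r.atoms]
        repair_residue_labels(chain, "LA")
        after = [(a.name, a.xyz) for r in chain.residues for a in r.atoms]
        assert before == after


class TestRefDbIo:
    def test_header_grammar_round_trips(self, refdb):
        again = read_refdb(write_refdb(refdb))
        assert [(r.accession, r.taxonomy_id, r.scientific_name, r.sequence)
                for r in again] == \
            [(r.accession, r.taxonomy_id, r.scientific_name, r.sequence)
             for r in refdb]
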