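"""Sequence reconciliation and cross-referencing.

Three sequences describe every polymer entity: the depositor's *sample
sequence* (the molecule in the experimental sample, tags and all), the
sequence extracted from the atomic coordinates, and the best-matching
record of a packaged reference database.  This module aligns the three,
classifies every discrepancy into a controlled vocabulary (expression tag,
cloning artifact, mutation, variant, conflict, insertion, deletion,
linker, unmodeled), segments chimeric constructs whose parts map to
different reference accessions, and repairs residue labels where a
truncated sidechain was modeled as alanine or glycine.

Pairwise alignment is delegated to Bio.Align.PairwiseAligner with fixed
scoring (match +2, mismatch −1, gap open −5, extend −1); positions are
1-based throughout, ranges inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from Bio import Align

from .entity_builder import AA_3TO1, AA_1TO3, ChainRecord
from .findings import Finding

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
NUCLEOTIDE_ALPHABET = set("ACGTUX")

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 2.0, -1.0, -5.0, -1.0
MIN_HIT_SCORE = 30.0

#: common affinity-tag / protease-site motifs (explicit surrogate for the
#: depositor's free-text construct description)
TAG_MOTIFS = {
    "HHHHHH": "6xHis tag",
    "LVPRGS": "thrombin cleavage site",
    "ENLYFQ": "TEV cleavage site",
    "WSHPQFEK": "Strep-tag II",
    "DYKDDDDK": "FLAG tag",
    "EQKLISEEDL": "myc tag",
    "GSSG": "GS linker",
}

DISCREPANCY_CLASSES = (
    "expression tag", "cloning artifact", "mutation", "variant", "conflict",
    "insertion", "deletion", "linker", "unmodeled",
)

#: heavy-atom complements of the 20 standard residues (sidechain completeness)
RESIDUE_HEAVY_ATOMS = {
    "GLY": {"N", "CA", "C", "O"},
    "ALA": {"N", "CA", "C", "O", "CB"},
    "SER": {"N", "CA", "C", "O", "CB", "OG"},
    "CYS": {"N", "CA", "C", "O", "CB", "SG"},
    "THR": {"N", "CA", "C", "O", "CB", "OG1", "CG2"},
    "VAL": {"N", "CA", "C", "O", "CB", "CG1", "CG2"},
    "LEU": {"N", "CA", "C", "O", "CB", "CG", "CD1", "CD2"},
    "ILE": {"N", "CA", "C", "O", "CB", "CG1", "CG2", "CD1"},
    "MET": {"N", "CA", "C", "O", "CB", "CG", "SD", "CE"},
    "PRO": {"N", "CA", "C", "O", "CB", "CG", "CD"},
    "PHE": {"N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"},
    "TRP": {"N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3",
            "CZ2", "CZ3", "CH2"},
    "ASP": {"N", "CA", "C", "O", "CB", "CG", "OD1", "OD2"},
    "GLU": {"N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "OE2"},
    "ASN": {"N", "CA", "C", "O", "CB", "CG", "OD1", "ND2"},
    "GLN": {"N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "NE2"},
    "HIS": {"N", "CA", "C", "O", "CB", "CG", "ND1", "CD2", "CE1", "NE2"},
    "LYS": {"N", "CA", "C", "O", "CB", "CG", "CD", "CE", "NZ"},
    "ARG": {"N", "CA", "C", "O", "CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"},
}


@dataclass(frozen=True)
class RefRecord:
    """One reference-database record (accession + taxonomy + sequence)."""

    accession: str
    sequence: str
    scientific_name: str
    taxonomy_id: int
    variants: Tuple[int, ...] = ()  # 1-based positions with known variants

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(self.sequence.upper()) - PROTEIN_ALPHABET - NUCLEOTIDE_ALPHABET
        if bad:
            raise ValueError(f"{self.accession}: bad alphabet characters {bad}")


def read_refdb(source: str) -> List[RefRecord]:
    """Parse a reference FASTA with headers ``>accession|taxonomy_id|name``."""
    import io
    import os

    from Bio import SeqIO

    if os.path.exists(str(source)):
        handle = open(source)
    else:
        handle = io.StringIO(str(source))
    records = []
    with handle:
        for rec in SeqIO.parse(handle, "fasta"):
            parts = rec.description.split("|", 2)
            if len(parts) != 3:
                raise ValueError(f"bad reference header: {rec.description!r}")
            records.append(RefRecord(
                accession=parts[0].strip(), taxonomy_id=int(parts[1]),
                scientific_name=parts[2].strip(), sequence=str(rec.seq).upper()))
    return records


def write_refdb(records: Sequence[RefRecord]) -> str:
    lines = []
    for r in records:
        lines.append(f">{r.accession}|{r.taxonomy_id}|{r.scientific_name}")
        for i in range(0, len(r.sequence), 60):
            lines.append(r.sequence[i:i + 60])
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# aligners

def _aligner(mode: str, free_ref_end_gaps: bool = False) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = mode
    al.match_score = MATCH
    al.mismatch_score = MISMATCH
    al.open_gap_score = GAP_OPEN
    al.extend_gap_score = GAP_EXTEND
    if free_ref_end_gaps:
        # reference is passed as the query; its terminal gaps are free so a
        # tagged sample does not pay for overhangs
        al.open_left_deletion_score = 0.0
        al.extend_left_deletion_score = 0.0
        al.open_right_deletion_score = 0.0
        al.extend_right_deletion_score = 0.0
    return al


def local_align(sample: str, reference: str):
    """Best Smith–Waterman local alignment (score, aligned rows, ranges)."""
    al = _aligner("local")
    try:
        best = al.align(sample, reference)[0]
    except IndexError:  # no positive-scoring local alignment exists
        return 0.0, "", "", (0, 0), (0, 0)
    s0, s1 = int(best.coordinates[0][0]), int(best.coordinates[0][-1])
    r0, r1 = int(best.coordinates[1][0]), int(best.coordinates[1][-1])
    return float(best.score), str(best[0]), str(best[1]), (s0 + 1, s1), (r0 + 1, r1)


def global_align(sample: str, reference: str) -> Tuple[float, str, str]:
    """Needleman–Wunsch with free end gaps on the reference."""
    al = _aligner("global", free_ref_end_gaps=True)
    best = al.align(sample, reference)[0]
    return float(best.score), str(best[0]), str(best[1])


@dataclass
class Alignment:
    """Three-row alignment (sample / coordinates / reference)."""

    sample_row: str
    coord_row: str
    reference_row: str
    column_classes: List[Optional[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (len(self.sample_row) == len(self.coord_row)
                == len(self.reference_row)):
            raise ValueError("alignment rows differ in length")


@dataclass(frozen=True)
class DiscrepancyAnnotation:
    """One annotated discrepancy span, in 1-based sample coordinates."""

    start: int
    end: int
    cls: str
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.cls not in DISCREPANCY_CLASSES:
            raise ValueError(f"unknown discrepancy class {self.cls!r}")
        if self.start > self.end or self.start < 1:
            raise ValueError("bad annotation range")


# ---------------------------------------------------------------------------
# coordinate-derived sequence

def derive_coord_sequence(chain: ChainRecord, sample: str
                          ) -> Tuple[str, List[Finding]]:
    """Thread the modeled residues onto the sample sequence.

    Residue numbers index the sample sequence (1-based); unmodeled sample
    positions become gaps.  A modeled residue disagreeing with the sample
    is a "Sequence discrepancy" error; a residue numbered outside the
    sample entirely cannot be aligned and is also an error.
    """
    findings: List[Finding] = []
    letters = ["-"] * len(sample)
    for res in chain.polymer_residues():
        pos = res.seq_num
        if not (1 <= pos <= len(sample)):
            findings.append(Finding(
                "Sequence discrepancy", locus=(chain.chain_id, pos),
                message=(f"residue {res.comp_id} {pos} falls outside the "
                         f"1..{len(sample)} sample sequence")))
            continue
        letter = AA_3TO1.get(res.comp_id, "X")
        letters[pos - 1] = letter
        if letter != "X" and sample[pos - 1] != "X" and letter != sample[pos - 1]:
            findings.append(Finding(
                "Sequence discrepancy", locus=(chain.chain_id, pos),
                message=(f"coordinates have {res.comp_id} at position {pos} "
                         f"where the sample sequence has "
                         f"{AA_1TO3.get(sample[pos - 1], sample[pos - 1])}")))
    return "".join(letters), findings


# ---------------------------------------------------------------------------
# reference search

@dataclass(frozen=True)
class ReferenceHit:
    accession: str
    score: float
    taxonomy_match: bool
    sample_range: Tuple[int, int]
    reference_range: Tuple[int, int]
    record: RefRecord


def search_references(sample: str, refdb: Sequence[RefRecord],
                      declared_taxonomy: Optional[int] = None,
                      min_score: float = MIN_HIT_SCORE) -> List[ReferenceHit]:
    """Rank reference records by local-alignment score.

    Taxonomy agreement with the declared source organism breaks score
    ties; hits below ``min_score`` are dropped.  An empty list is a valid
    return (no cross-reference found).
    """
    if not refdb:
        raise ValueError("empty reference database")
    hits: List[ReferenceHit] = []
    for rec in refdb:
        score, _, _, srange, rrange = local_align(sample, rec.sequence)
        if score < min_score:
            continue
        hits.append(ReferenceHit(
            accession=rec.accession, score=score,
            taxonomy_match=(declared_taxonomy is not None
                            and rec.taxonomy_id == declared_taxonomy),
            sample_range=srange, reference_range=rrange, record=rec))
    hits.sort(key=lambda h: (-h.score, not h.taxonomy_match, h.accession))
    return hits


# ---------------------------------------------------------------------------
# reconciliation

def _spans(positions: List[int]) -> List[Tuple[int, int]]:
    """Collapse a sorted 1-based position list into inclusive runs."""
    spans = []
    for p in positions:
        if spans and p == spans[-1][1] + 1:
            spans[-1] = (spans[-1][0], p)
        else:
            spans.append((p, p))
    return spans


def _matches_tag_motif(span_seq: str) -> Optional[str]:
    for motif, label in TAG_MOTIFS.items():
        if motif in span_seq:
            return label
    return None


def reconcile(sample: str, coord_seq: str, ref: RefRecord,
              depositor_declarations: Optional[Mapping[str, object]] = None,
              ) -> Tuple[List[DiscrepancyAnnotation], List[Finding], Alignment]:
    """Classify every sample/reference discrepancy.

    Rules, applied in order: terminal sample-only spans are expression
    tags (motif table or depositor declaration) else cloning artifacts;
    internal sample-only spans are insertions (linkers if declared);
    reference-only spans are deletions; single-column conflicts are
    mutations if declared engineered, variants if the reference records
    one, else conflicts raised for depositor correspondence; sample
    positions absent from the coordinates are unmodeled.
    """
    decl = dict(depositor_declarations or {})
    declared_mutations = {int(m[0]) if isinstance(m, (tuple, list)) else int(m)
                          for m in decl.get("mutations", [])}
    declared_tags = [tuple(t) for t in decl.get("tags", [])]  # (start, end)
    declared_linkers = [tuple(t) for t in decl.get("linkers", [])]
    known_variants = set(ref.variants) | {int(v) for v in decl.get("variants", [])}

    _, srow, rrow = global_align(sample, ref.sequence)
    if len(coord_seq) != len(sample):
        raise ValueError("coordinate sequence must be threaded on the sample")

    annotations: List[DiscrepancyAnnotation] = []
    findings: List[Finding] = []
    classes: List[Optional[str]] = [None] * len(srow)

    # map columns to 1-based sample / reference positions
    spos = rpos = 0
    col_sample = []
    col_ref = []
    for k, (sc, rc) in enumerate(zip(srow, rrow)):
        if sc != "-":
            spos += 1
        if rc != "-":
            rpos += 1
        col_sample.append(spos if sc != "-" else None)
        col_ref.append(rpos if rc != "-" else None)

    n_ref_cols = [k for k in range(len(srow)) if col_ref[k] is not None]
    first_ref_col = n_ref_cols[0] if n_ref_cols else len(srow)
    last_ref_col = n_ref_cols[-1] if n_ref_cols else -1

    # sample-only spans
    sample_only = [col_sample[k] for k in range(len(srow))
                   if srow[k] != "-" and rrow[k] == "-"]
    for start, end in _spans(sample_only):
        cols = [k for k in range(len(srow))
                if col_sample[k] is not None and start <= col_sample[k] <= end]
        terminal = cols[-1] < first_ref_col or cols[0] > last_ref_col
        span_seq = sample[start - 1:end]
        if terminal:
            motif = _matches_tag_motif(span_seq)
            declared = any(ds <= start and end <= de for ds, de in declared_tags)
            if motif or declared:
                cls, ev = "expression tag", motif or "declared by depositor"
            else:
                cls, ev = "cloning artifact", "terminal span without known tag motif"
        else:
            declared = any(ds <= start and end <= de for ds, de in declared_linkers)
            cls = "linker" if declared else "insertion"
            ev = "declared by depositor" if declared else "internal sample-only span"
        annotations.append(DiscrepancyAnnotation(start, end, cls, ev))
        for k in cols:
            classes[k] = cls

    # reference-only spans (deletions), reported at the flanking sample position
    ref_only_cols = [k for k in range(len(srow))
                     if rrow[k] != "-" and srow[k] == "-"]
    for span_cols in _spans([col_ref[k] for k in ref_only_cols]):
        cols = [k for k in ref_only_cols
                if span_cols[0] <= col_ref[k] <= span_cols[1]]
        anchor = max((col_sample[k] for k in range(cols[0]) if col_sample[k]),
                     default=1)
        annotations.append(DiscrepancyAnnotation(
            anchor, anchor, "deletion",
            f"reference residues {span_cols[0]}-{span_cols[1]} absent from sample"))
        for k in cols:
            classes[k] = "deletion"

    # single-column conflicts
    for k in range(len(srow)):
        sc, rc = srow[k], rrow[k]
        if sc == "-" or rc == "-" or sc == rc:
            continue
        pos = col_sample[k]
        if pos in declared_mutations:
            cls, ev = "mutation", "declared engineered by depositor"
        elif col_ref[k] in known_variants:
            cls, ev = "variant", "known reference variant"
        else:
            cls, ev = "conflict", "undeclared conflict"
            findings.append(Finding(
                "correspondence_needed", locus=("sample", pos),
                message=(f"undeclared sequence conflict at position {pos}: "
                         f"sample {sc} vs reference {rc}")))
        annotations.append(DiscrepancyAnnotation(pos, pos, cls, ev))
        classes[k] = cls

    # unmodeled sample positions
    unmodeled = [p for p in range(1, len(sample) + 1) if coord_seq[p - 1] == "-"]
    for start, end in _spans(unmodeled):
        annotations.append(DiscrepancyAnnotation(
            start, end, "unmodeled", "present in sample, absent from coordinates"))

    annotations.sort(key=lambda a: (a.start, a.end, a.cls))
    coord_row = "".join(
        coord_seq[col_sample[k] - 1] if col_sample[k] is not None else "-"
        for k in range(len(srow)))
    alignment = Alignment(sample_row=srow, coord_row=coord_row,
                          reference_row=rrow, column_classes=classes)
    return annotations, findings, alignment


# ---------------------------------------------------------------------------
# chimera segmentation

@dataclass
class ChimeraMap:
    """Ordered segments mapping sample ranges to reference accessions."""

    segments: List[Tuple[int, int, Optional[str], int, int]]
    # (sample_start, sample_end, accession, ref_start, ref_end)

    def __post_init__(self) -> None:
        prev_end = 0
        for s, e, _, _, _ in self.segments:
            if s != prev_end + 1:
                raise ValueError("segments must tile the sample without overlap")
            prev_end = e

    @property
    def is_chimeric(self) -> bool:
        accs = {a for _, _, a, _, _ in self.segments if a is not None}
        return len(accs) >= 2

    def accessions(self) -> List[Optional[str]]:
        return [a for _, _, a, _, _ in self.segments]


def segment_chimera(sample: str, refdb: Sequence[RefRecord],
                    kappa: float = 20.0, min_segment: int = 3,
                    min_segment_length: int = 10,
                    ) -> Tuple[ChimeraMap, List[Finding]]:
    """Assign each sample position to a reference by a jumping alignment.

    A dynamic program threads the sample through all references at once:
    within a reference the path moves diagonally (match +2 / mismatch −1);
    re-anchoring to any position of any reference (in particular switching
    reference) costs ``kappa`` (default 20).  The optimal path maximizes
    total segment score minus kappa per switch and is
    deterministic (ties prefer staying in the current reference, then the
    earlier accession).  Runs of at most ``min_segment`` positions, and
    any run shorter than ``min_segment_length`` (short spans such as
    expression tags that happen to resemble a stretch of some reference),
    are absorbed into the higher-scoring flanking segment.

    Without any local hit the whole sample is returned as one unassigned
    segment with a warning.
    """
    findings: List[Finding] = []
    if not refdb or not search_references(sample, refdb):
        findings.append(Finding(
            "chimera_unassigned", locus=("sample", 1),
            message="no reference hit; sample left unassigned"))
        return ChimeraMap([(1, len(sample), None, 0, 0)]), findings

    refs = sorted(refdb, key=lambda r: r.accession)
    n = len(sample)
    samp = np.frombuffer(sample.encode(), dtype=np.uint8)
    score_rows = []
    for rec in refs:
        refarr = np.frombuffer(rec.sequence.encode(), dtype=np.uint8)
        s = np.where(samp[:, None] == refarr[None, :], MATCH, MISMATCH)
        score_rows.append(s)

    # DP: M[r][i, j] best score ending at sample i aligned to ref r pos j
    M = [np.full(s.shape, -np.inf) for s in score_rows]
    for r, s in enumerate(score_rows):
        M[r][0] = s[0]
    for i in range(1, n):
        best_prev = max(float(M[r][i - 1].max()) for r in range(len(refs)))
        for r, s in enumerate(score_rows):
            diag = np.full(s.shape[1], -np.inf)
            diag[1:] = M[r][i - 1][:-1]
            M[r][i] = s[i] + np.maximum(diag, best_prev - kappa)

    # traceback, preferring diagonal continuation on ties
    eps = 1e-9
    r = min(range(len(refs)), key=lambda rr: (-float(M[rr][n - 1].max()), rr))
    j = int(M[r][n - 1].argmax())
    path = [(r, j)]
    for i in range(n - 1, 0, -1):
        cell = float(M[r][i][j]) - float(score_rows[r][i][j])
        if j > 0 and abs(float(M[r][i - 1][j - 1]) - cell) < eps:
            j -= 1
        else:
            best_prev = max(float(M[rr][i - 1].max()) for rr in range(len(refs)))
            assert abs(best_prev - kappa - cell) < 1e-6
            r = min(range(len(refs)),
                    key=lambda rr: (-float(M[rr][i - 1].max()), rr))
            j = int(M[r][i - 1].argmax())
        path.append((r, j))
    path.reverse()

    # collapse into segments
    segments: List[List[int]] = []  # [start, end, ref_index, ref_start, ref_end]
    for i, (r, j) in enumerate(path, start=1):
        if segments and segments[-1][2] == r and j == segments[-1][4] + 1:
            segments[-1][1] = i
            segments[-1][4] = j
        else:
            segments.append([i, i, r, j, j])

    # absorb short runs into the better-scoring flank
    def seg_score(seg):
        s0, s1, r, j0, _ = seg
        return float(sum(score_rows[r][s0 - 1 + k][j0 + k]
                         for k in range(s1 - s0 + 1)))

    changed = True
    while changed and len(segments) > 1:
        changed = False
        for idx, seg in enumerate(segments):
            if seg[1] - seg[0] + 1 > max(min_segment, min_segment_length - 1):
                continue
            length = seg[1] - seg[0] + 1
            left = segments[idx - 1] if idx > 0 else None
            right = segments[idx + 1] if idx + 1 < len(segments) else None
            if left is not None and (right is None
                                     or seg_score(left) >= seg_score(right)):
                left[1] = seg[1]
                left[4] += length
            else:
                right[0] = seg[0]
                right[3] -= length
            del segments[idx]
            changed = True
            break
    # merge adjacent segments that ended up on the same reference
    merged: List[List[int]] = []
    for seg in segments:
        if merged and merged[-1][2] == seg[2] and seg[3] == merged[-1][4] + 1:
            merged[-1][1] = seg[1]
            merged[-1][4] = seg[4]
        else:
            merged.append(seg)

    out = [(s0, s1, refs[r].accession,
            max(1, j0 + 1), min(len(refs[r].sequence), j1 + 1))
           for s0, s1, r, j0, j1 in merged]
    return ChimeraMap(out), findings


# ---------------------------------------------------------------------------
# residue-label repair

def repair_residue_labels(chain: ChainRecord, sample: str
                          ) -> Tuple[List[Tuple[str, int, str, str]], List[Finding]]:
    """Relabel truncated residues to match the sample sequence.

    A residue modeled as ALA/GLY, or with an incomplete sidechain for its
    labeled type, at a position where the sample says otherwise is
    relabeled to the sample residue with its atoms untouched.  A residue
    carrying its complete sidechain is never auto-relabeled; it is raised
    as a sequence discrepancy needing correspondence.
    """
    edits: List[Tuple[str, int, str, str]] = []
    findings: List[Finding] = []
    for res in chain.polymer_residues():
        pos = res.seq_num
        if not (1 <= pos <= len(sample)):
            continue
        expected3 = AA_1TO3.get(sample[pos - 1])
        if expected3 is None or res.comp_id == expected3:
            continue
        have = {a.name for a in res.atoms if a.element.upper() not in ("H", "D")}
        full = RESIDUE_HEAVY_ATOMS.get(res.comp_id, set())
        complete = bool(full) and full.issubset(have)
        if res.comp_id in ("ALA", "GLY") or not complete:
            old = res.comp_id
            res.comp_id = expected3
            edits.append((chain.chain_id, pos, old, expected3))
            findings.append(Finding(
                "residue_relabeled", locus=(chain.chain_id, pos),
                message=f"residue {pos} relabeled to {expected3} per sample sequence"))
        else:
            findings.append(Finding(
                "Sequence discrepancy", locus=(chain.chain_id, pos),
                message=(f"full {res.comp_id} sidechain modeled where sample "
                         f"has {expected3}; depositor correspondence needed")))
    return edits, findings
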