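"""End-to-end curation pipeline over one deposition.

Runs the fixed-order stages — entity transformation, ligand processing,
sequence reconciliation, value-added annotation, validation, communication
— advancing the workflow state machine as each completes, and aggregates
every finding into a report bundle with percentile scores and a depositor
letter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from . import entity_builder as eb
from . import ligand_processor as lp
from . import sequence_processor as sp
from . import structure_annotator as sa
from . import workflow_manager as wm
from .dictionary_engine import DictionarySchema, validate_block
from .findings import Finding
from .ligand_processor import ChemComp
from .sequence_processor import RefRecord

#: small reference cohorts for percentile scoring (typical archive-like
#: spreads; desk-scale stand-ins, not archive statistics)
PERCENTILE_REFERENCES = {
    "Rmerge": [0.04, 0.06, 0.08, 0.09, 0.10, 0.12, 0.14, 0.17, 0.22, 0.30],
    "resolution": [1.2, 1.5, 1.8, 2.0, 2.2, 2.5, 2.8, 3.0, 3.5, 4.0],
}


@dataclass
class PipelineResult:
    deposition: eb.Deposition
    findings: List[Finding] = field(default_factory=list)
    entities: List[eb.EntityRecord] = field(default_factory=list)
    ligand_matches: Dict[tuple, List[lp.MatchResult]] = field(default_factory=dict)
    annotations: Dict[int, List[sp.DiscrepancyAnnotation]] = field(default_factory=dict)
    chimera_maps: Dict[int, sp.ChimeraMap] = field(default_factory=dict)
    cross_references: Dict[int, str] = field(default_factory=dict)
    water_moves: List[dict] = field(default_factory=list)
    links: List[dict] = field(default_factory=list)
    sec_struct: Dict[str, sa.SecStructAssignment] = field(default_factory=dict)
    percentiles: Dict[str, float] = field(default_factory=dict)
    source_info: Dict[str, object] = field(default_factory=dict)
    report: Optional[wm.ReportBundle] = None
    state: wm.WorkflowState = field(default_factory=wm.WorkflowState)


def _stage(result: PipelineResult, module: str):
    result.state = wm.advance(result.state, module, "start")


def _done(result: PipelineResult, module: str):
    result.state = wm.advance(result.state, module, "complete")


def run_pipeline(dep: eb.Deposition, schema: DictionarySchema,
                 ccd: Sequence[ChemComp], refdb: Sequence[RefRecord],
                 prd_db: Sequence[eb.PrdEntry] = ()) -> PipelineResult:
    """Run all curation stages on a deposition and compile the report."""
    result = PipelineResult(deposition=dep)

    # initial review: dictionary validation of the metadata block
    result.findings.extend(validate_block(dep.metadata, schema))
    for row in dep.metadata.rows("entity_src_gen"):
        host = row.get("entity_src_gen.pdbx_host_org_ncbi_taxonomy_id")
        src = row.get("entity_src_gen.pdbx_gene_src_ncbi_taxonomy_id")
        if host not in (None, "?", "."):
            result.source_info["host_taxonomy_id"] = int(host)
        if src not in (None, "?", "."):
            result.source_info["source_taxonomy_id"] = int(src)

    # --- entity transformation
    _stage(result, "entity")
    entities, efind = eb.build_entities(dep.chains, dep.sample_sequences)
    result.entities = entities
    dep.entities = entities
    result.findings.extend(efind)
    for chain in dep.chains:
        _, breaks = eb.detect_polymer_links(chain)
        result.findings.extend(breaks)
    _done(result, "entity")

    # --- ligand processing
    _stage(result, "ligand")
    by_id = {c.comp_id: c for c in ccd}
    for ent in entities:
        if ent.etype != "non-polymer":
            continue
        for chain_id, seq_num in ent.instances:
            chain = dep.chain(chain_id)
            res = next(r for r in chain.residues if r.seq_num == seq_num)
            try:
                graph = lp.perceive_graph(res, source=(chain_id, seq_num))
            except lp.PerceptionError as exc:
                result.findings.append(Finding(
                    "Ligand identity", locus=(chain_id, seq_num),
                    message=f"bond perception failed: {exc}"))
                continue
            hits = lp.search_ccd(graph, ccd)
            result.ligand_matches[(chain_id, seq_num)] = hits
            declared = res.comp_id
            if not hits:
                result.findings.append(Finding(
                    "Ligand identity", locus=(chain_id, seq_num),
                    message=(f"{declared}: no CCD component matches; "
                             "new-component registration required")))
                continue
            top = hits[0]
            if top.comp_id != declared:
                result.findings.append(Finding(
                    "Ligand identity", locus=(chain_id, seq_num),
                    message=(f"declared {declared} but best CCD match is "
                             f"{top.comp_id} (score {top.score:.2f})")))
            elif top.score < 1.0:
                result.findings.append(Finding(
                    "ligand_incomplete", locus=(chain_id, seq_num),
                    message=(f"{declared} modeled partially "
                             f"(score {top.score:.2f}; missing "
                             f"{', '.join(top.unmatched_component_atoms)})")))
            comp = by_id.get(top.comp_id)
            if comp is not None and comp.stereocenters:
                result.findings.extend(
                    lp.check_chirality(res, comp, top.mapping,
                                       locus=(chain_id, seq_num)))
    _done(result, "ligand")

    # --- sequence processing
    _stage(result, "sequence")
    declared_tax = result.source_info.get("source_taxonomy_id")
    for ent in entities:
        if ent.etype != "polymer":
            continue
        sample = ent.sample_sequence
        for chain_id in ent.instances:
            chain = dep.chain(chain_id)
            coord_seq, cfind = sp.derive_coord_sequence(chain, sample)
            result.findings.extend(cfind)
            if not refdb:
                continue
            hits = sp.search_references(sample, refdb, declared_tax)
            if not hits:
                continue
            result.cross_references[ent.entity_id] = hits[0].accession
            cmap, cwarn = sp.segment_chimera(sample, refdb)
            result.findings.extend(cwarn)
            if cmap.is_chimeric:
                result.chimera_maps[ent.entity_id] = cmap
                anns: List[sp.DiscrepancyAnnotation] = []
                by_acc = {r.accession: r for r in refdb}
                for s0, s1, acc, r0, r1 in cmap.segments:
                    if acc is None:
                        continue
                    ref = by_acc[acc]
                    sub_ref = RefRecord(acc, ref.sequence[r0 - 1:r1],
                                        ref.scientific_name, ref.taxonomy_id)
                    sub_ann, sub_find, _ = sp.reconcile(
                        sample[s0 - 1:s1], coord_seq[s0 - 1:s1], sub_ref,
                        dep.declarations)
                    for a in sub_ann:
                        anns.append(sp.DiscrepancyAnnotation(
                            a.start + s0 - 1, a.end + s0 - 1, a.cls, a.evidence))
                    result.findings.extend(sub_find)
                result.annotations[ent.entity_id] = anns
            else:
                ref = hits[0].record
                anns, afind, _ = sp.reconcile(sample, coord_seq, ref,
                                              dep.declarations)
                result.annotations[ent.entity_id] = anns
                result.findings.extend(afind)
            _, rfind = sp.repair_residue_labels(chain, sample)
            result.findings.extend(rfind)
    _done(result, "sequence")

    # --- value-added annotation
    _stage(result, "annotation")
    moves, wfind = sa.reposition_waters(dep)
    result.water_moves = moves
    result.findings.extend(wfind)
    links, lfind = sa.generate_links(dep, ccd)
    result.links = links
    result.findings.extend(lfind)
    for chain in dep.chains:
        if len(chain.polymer_residues()) >= 2:
            ss, sfind = sa.assign_secondary_structure(chain)
            result.sec_struct[chain.chain_id] = ss
            result.findings.extend(sfind)
    result.findings.extend(sa.extended_checks(dep, ccd=ccd))
    _done(result, "annotation")

    # --- validation: percentile scores
    _stage(result, "validation")
    reflns = dep.metadata.rows("reflns")
    if reflns:
        r = reflns[0]
        rm = r.get("reflns.pdbx_Rmerge_I_obs")
        if rm not in (None, "?", "."):
            try:
                result.percentiles["Rmerge"] = wm.percentile_score(
                    float(rm), PERCENTILE_REFERENCES["Rmerge"],
                    higher_is_better=False)
            except ValueError:
                pass
        res_hi = r.get("reflns.d_resolution_high")
        if res_hi not in (None, "?", "."):
            try:
                result.percentiles["resolution"] = wm.percentile_score(
                    float(res_hi), PERCENTILE_REFERENCES["resolution"],
                    higher_is_better=False)
            except ValueError:
                pass
    _done(result, "validation")

    # --- communication
    _stage(result, "communication")
    result.report = wm.compile_report(
        result.findings, result.percentiles,
        {"dep_id": dep.dep_id})
    _done(result, "communication")
    return result
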