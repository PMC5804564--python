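"""Serialization of depositions to and from the mmCIF subset.

The file carries the metadata categories (entity, entity_poly,
entity_src_gen, cell, symmetry, reflns), the atom_site loop built from the
chain/residue/atom model, and a small depositor-declarations category
(``pdbx_depositor_info``) holding construct annotations (declared
mutations, tag ranges, oligomeric count) that the sequence and annotation
stages consume.  Dictionary validation sees only the metadata categories.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

from .dictionary_engine import DataBlock
from .entity_builder import (AtomRecord, ChainRecord, Deposition,
                             ResidueRecord, WATER_COMP_IDS)
from .geometry import IDENTITY_ASSEMBLY_OP
from .mmcif_io import read_block, write_block

DECL_CATEGORY = "pdbx_depositor_info"


def atom_site_rows(dep: Deposition) -> List[Dict[str, str]]:
    rows = []
    aid = 1
    for chain in dep.chains:
        poly = {r.seq_num for r in chain.polymer_residues()} \
            if len(chain.polymer_residues()) >= 2 else set()
        for res in chain.residues:
            group = "ATOM" if res.seq_num in poly else "HETATM"
            for a in res.atoms:
                rows.append({
                    "atom_site.group_PDB": group,
                    "atom_site.id": str(aid),
                    "atom_site.type_symbol": a.element,
                    "atom_site.label_atom_id": a.name,
                    "atom_site.label_alt_id": a.alt_id or ".",
                    "atom_site.label_comp_id": res.comp_id,
                    "atom_site.label_asym_id": chain.chain_id,
                    "atom_site.label_seq_id": str(res.seq_num),
                    "atom_site.Cartn_x": f"{a.xyz[0]:.3f}",
                    "atom_site.Cartn_y": f"{a.xyz[1]:.3f}",
                    "atom_site.Cartn_z": f"{a.xyz[2]:.3f}",
                    "atom_site.occupancy": f"{a.occupancy:.2f}",
                    "atom_site.B_iso_or_equiv": f"{a.b_factor:.2f}",
                })
                aid += 1
    return rows


def deposition_to_block(dep: Deposition) -> DataBlock:
    tables: Dict[str, List[Dict[str, str]]] = {
        k: [dict(r) for r in v] for k, v in dep.metadata.tables.items()}
    tables["atom_site"] = atom_site_rows(dep)
    decl_row: Dict[str, str] = {}
    d = dep.declarations
    if d.get("mutations"):
        decl_row[f"{DECL_CATEGORY}.mutations"] = ",".join(
            str(m[0] if isinstance(m, (list, tuple)) else m)
            for m in d["mutations"])
    if d.get("tags"):
        decl_row[f"{DECL_CATEGORY}.tags"] = ";".join(
            f"{t[0]}-{t[1]}" for t in d["tags"])
    if d.get("oligomeric_count") is not None:
        decl_row[f"{DECL_CATEGORY}.oligomeric_count"] = str(d["oligomeric_count"])
    if decl_row:
        tables[DECL_CATEGORY] = [decl_row]
    return DataBlock(block_id=dep.dep_id, tables=tables)


def _parse_declarations(rows: List[Dict[str, str]]) -> Dict[str, object]:
    decl: Dict[str, object] = {}
    if not rows:
        return decl
    r = rows[0]
    muts = r.get(f"{DECL_CATEGORY}.mutations")
    if muts and muts not in ("?", "."):
        decl["mutations"] = [int(x) for x in muts.split(",")]
    tags = r.get(f"{DECL_CATEGORY}.tags")
    if tags and tags not in ("?", "."):
        decl["tags"] = [tuple(int(x) for x in t.split("-"))
                        for t in tags.split(";")]
    oc = r.get(f"{DECL_CATEGORY}.oligomeric_count")
    if oc and oc not in ("?", "."):
        decl["oligomeric_count"] = int(oc)
    return decl


def deposition_from_block(block: DataBlock) -> Deposition:
    """Rebuild the chain/residue/atom model and metadata from a data block."""
    chains: Dict[str, List[ResidueRecord]] = {}
    current: Dict[Tuple[str, int], ResidueRecord] = {}
    for row in block.rows("atom_site"):
        cid = row["atom_site.label_asym_id"]
        seq = int(row["atom_site.label_seq_id"])
        key = (cid, seq)
        res = current.get(key)
        if res is None:
            res = ResidueRecord(comp_id=row["atom_site.label_comp_id"],
                                seq_num=seq, atoms=[])
            current[key] = res
            chains.setdefault(cid, []).append(res)
        alt = row.get("atom_site.label_alt_id", ".")
        res.atoms.append(AtomRecord(
            name=row["atom_site.label_atom_id"],
            element=row["atom_site.type_symbol"],
            xyz=(float(row["atom_site.Cartn_x"]),
                 float(row["atom_site.Cartn_y"]),
                 float(row["atom_site.Cartn_z"])),
            occupancy=float(row.get("atom_site.occupancy", "1.0")),
            b_factor=float(row.get("atom_site.B_iso_or_equiv", "20.0")),
            alt_id=None if alt in (".", "?", "") else alt))
    chain_records = [ChainRecord(chain_id=cid, residues=res_list)
                     for cid, res_list in chains.items()]

    sample_sequences: Dict[str, str] = {}
    for row in block.rows("entity_poly"):
        seq = row.get("entity_poly.pdbx_seq_one_letter_code", "")
        strands = row.get("entity_poly.pdbx_strand_id", "")
        if seq in ("?", "."):
            continue
        for cid in strands.split(","):
            if cid and cid not in ("?", "."):
                sample_sequences[cid.strip()] = seq

    metadata = DataBlock(block_id=block.block_id, tables={
        cat: [dict(r) for r in rows]
        for cat, rows in block.tables.items()
        if cat not in ("atom_site", DECL_CATEGORY)})
    return Deposition(
        dep_id=block.block_id,
        chains=chain_records,
        metadata=metadata,
        assemblies=[[IDENTITY_ASSEMBLY_OP]],
        sample_sequences=sample_sequences,
        declarations=_parse_declarations(block.rows(DECL_CATEGORY)))


def write_deposition(dep: Deposition, path: Optional[str] = None) -> str:
    text = write_block(deposition_to_block(dep))
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_deposition(source) -> Deposition:
    return deposition_from_block(read_block(source))
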