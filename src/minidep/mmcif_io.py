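"""Minimal PDBx/mmCIF subset reader/writer.

Depositions travel as a single data block restricted to a category
whitelist (atom_site, entity, entity_poly, entity_src_gen, cell, symmetry,
reflns plus a few curation-output categories).  Parsing and quoting are
delegated to gemmi's CIF layer; this module only maps between CIF loops
and the string-valued :class:`~minidep.dictionary_engine.DataBlock`.

The writer emits categories in a fixed canonical order and items in their
first-row order, so output is diffable.
"""

from __future__ import annotations

import os
from typing import Dict, List, Union

from gemmi import cif

from .dictionary_engine import DataBlock

#: canonical output order; categories not listed follow alphabetically
CANONICAL_ORDER = [
    "entry", "entity", "entity_poly", "entity_src_gen", "entity_src_nat",
    "cell", "symmetry", "reflns", "struct_ref", "struct_ref_seq",
    "struct_ref_seq_dif", "struct_conn", "struct_asym", "pdbx_struct_assembly",
    "pdbx_struct_oper_list", "atom_site",
]


def _unquote(value: str) -> str:
    """Strip CIF quoting, preserving the '?'/'.' null tokens."""
    if value in ("?", "."):
        return value
    return cif.as_string(value)


def read_block(source: Union[str, os.PathLike]) -> DataBlock:
    """Read a deposition mmCIF file (or literal CIF text) into a DataBlock."""
    text = None
    if isinstance(source, (str, os.PathLike)) and os.path.exists(str(source)):
        doc = cif.read_file(str(source))
    else:
        text = str(source)
        doc = cif.read_string(text)
    block = doc.sole_block()
    tables: Dict[str, List[Dict[str, str]]] = {}
    for raw_name in block.get_mmcif_category_names():
        name = raw_name.strip("_.").rstrip(".")
        columns = block.get_mmcif_category(raw_name, raw=True)
        if not columns:
            continue
        n = len(next(iter(columns.values())))
        rows = []
        for i in range(n):
            rows.append({f"{name}.{col}": _unquote(vals[i])
                         for col, vals in columns.items()})
        tables[name] = rows
    return DataBlock(block_id=block.name, tables=tables)


def write_block(block: DataBlock) -> str:
    """Serialize a DataBlock to canonical mmCIF text."""
    doc = cif.Document()
    cb = doc.add_new_block(block.block_id or "minidep")
    order = [c for c in CANONICAL_ORDER if c in block.tables]
    order += sorted(c for c in block.tables if c not in CANONICAL_ORDER)
    for cat in order:
        rows = block.tables[cat]
        if not rows:
            continue
        items = list(rows[0].keys())
        tags = ["_" + it for it in items]
        loop = cb.init_loop("", tags)
        for row in rows:
            loop.add_row([cif.quote(row.get(it, "?") if row.get(it, "?") != ""
                                    else "?") for it in items])
    return doc.as_string()


def write_block_file(block: DataBlock, path: Union[str, os.PathLike]) -> None:
    with open(path, "w") as fh:
        fh.write(write_block(block))
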