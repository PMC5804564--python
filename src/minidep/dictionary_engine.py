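"""Dictionary-driven validation of deposition metadata.

A deposition's metadata travels as a :class:`DataBlock`: string-valued rows
grouped into categories, exactly as they appear in a PDBx/mmCIF file
(``"?"`` marks an unknown value, ``"."`` an inapplicable one).  A
:class:`DictionarySchema` — a small packaged subset of the archive data
dictionary — declares for every item its type, whether it is mandatory, an
enumeration of allowed values, hard and soft numeric limits, and
parent/child key relationships between categories.

Validation distinguishes *hard* limits (physically impossible values, e.g.
a pH outside 0–14: error) from *soft* limits (statistically unusual values:
warning).  Soft limits for normally distributed archive quantities follow
the three-standard-deviation rule implemented by
:func:`derive_soft_limits`.

The schema serialization is a deliberately flat text dialect (one line per
record, ``;``-separated ``key=value`` fields) rather than a DDL2 dictionary
parser; see ``data/mini_schema.txt`` for the packaged instance and the
grammar notes in its header.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from datetime import date
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .findings import Finding

TYPE_CODES = ("text", "int", "float", "enum", "date")
NULLS = ("?", ".")


class SchemaError(ValueError):
    """Raised for malformed or internally inconsistent schema documents."""


@dataclass(frozen=True)
class ItemDef:
    """Definition of one dictionary item (``category.item``)."""

    name: str
    type_code: str = "text"
    mandatory: bool = False
    enumeration: Optional[Tuple[str, ...]] = None
    hard_range: Optional[Tuple[float, float]] = None
    soft_range: Optional[Tuple[float, float]] = None
    parent: Optional[str] = None

    def __post_init__(self) -> None:
        if self.type_code not in TYPE_CODES:
            raise SchemaError(f"{self.name}: unknown type code {self.type_code!r}")
        if (self.enumeration is not None) != (self.type_code == "enum"):
            raise SchemaError(f"{self.name}: enumeration present iff type is enum")
        if self.type_code not in ("int", "float"):
            if self.hard_range is not None or self.soft_range is not None:
                raise SchemaError(f"{self.name}: ranges only allowed for numeric items")
        for rng in (self.hard_range, self.soft_range):
            if rng is not None and rng[0] > rng[1]:
                raise SchemaError(f"{self.name}: inverted range {rng}")
        if self.hard_range is not None and self.soft_range is not None:
            if not (self.hard_range[0] <= self.soft_range[0]
                    and self.soft_range[1] <= self.hard_range[1]):
                raise SchemaError(f"{self.name}: soft range not inside hard range")

    @property
    def category(self) -> str:
        return self.name.split(".", 1)[0]


@dataclass(frozen=True)
class CategoryDef:
    name: str
    key_items: Tuple[str, ...]
    items: Tuple[ItemDef, ...]

    def __post_init__(self) -> None:
        names = {i.name for i in self.items}
        missing = set(self.key_items) - names
        if missing:
            raise SchemaError(f"{self.name}: key items not defined: {sorted(missing)}")

    def item(self, name: str) -> Optional[ItemDef]:
        for i in self.items:
            if i.name == name:
                return i
        return None


@dataclass(frozen=True)
class DictionarySchema:
    categories: Dict[str, CategoryDef]
    version: str = "1.0"

    def __post_init__(self) -> None:
        seen: Dict[str, str] = {}
        for cat in self.categories.values():
            for item in cat.items:
                if item.name in seen:
                    raise SchemaError(f"duplicate item name {item.name}")
                seen[item.name] = cat.name
        for cat in self.categories.values():
            for item in cat.items:
                if item.parent is not None and item.parent not in seen:
                    raise SchemaError(
                        f"{item.name}: parent {item.parent!r} not defined in schema")
        self._check_acyclic(seen)

    def _check_acyclic(self, owner: Dict[str, str]) -> None:
        # parent/child links between categories must not form a cycle
        edges: Dict[str, set] = {}
        for cat in self.categories.values():
            for item in cat.items:
                if item.parent is not None:
                    edges.setdefault(cat.name, set()).add(owner[item.parent])
        state: Dict[str, int] = {}

        def visit(node: str) -> None:
            state[node] = 1
            for nxt in edges.get(node, ()):
                if state.get(nxt) == 1:
                    raise SchemaError(f"parent/child cycle through category {node}")
                if nxt not in state:
                    visit(nxt)
            state[node] = 2

        for name in self.categories:
            if name not in state:
                visit(name)

    def find_item(self, name: str) -> Optional[ItemDef]:
        cat = self.categories.get(name.split(".", 1)[0])
        return cat.item(name) if cat else None


@dataclass
class DataBlock:
    """String-valued tabular content of one mmCIF data block."""

    block_id: str
    tables: Dict[str, List[Dict[str, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cat, rows in self.tables.items():
            if rows:
                cols = set(rows[0])
                for r in rows[1:]:
                    if set(r) != cols:
                        raise ValueError(f"{cat}: rows carry differing item sets")

    def rows(self, category: str) -> List[Dict[str, str]]:
        return self.tables.get(category, [])


# ---------------------------------------------------------------------------
# schema serialization: one record per line, ';'-separated key=value fields

_FIELD_RE = re.compile(r"\s*([A-Za-z_]+)\s*=\s*(.*?)\s*$")


def _parse_fields(parts: Sequence[str], lineno: int) -> Dict[str, str]:
    fields: Dict[str, str] = {}
    for part in parts:
        m = _FIELD_RE.match(part)
        if not m:
            raise SchemaError(f"line {lineno}: malformed field {part!r}")
        fields[m.group(1)] = m.group(2)
    return fields


def _parse_range(text: str, lineno: int) -> Tuple[float, float]:
    try:
        lo, hi = text.split(":")
        return (float(lo), float(hi))
    except ValueError as exc:
        raise SchemaError(f"line {lineno}: bad range {text!r}") from exc


def load_schema(schema_doc: str) -> DictionarySchema:
    """Parse the flat schema dialect into a :class:`DictionarySchema`.

    Raises :class:`SchemaError` naming the offending line for malformed
    input, and for dangling parent references via the schema invariants.
    """
    version = "1.0"
    cat_order: List[str] = []
    cat_keys: Dict[str, Tuple[str, ...]] = {}
    cat_items: Dict[str, List[ItemDef]] = {}
    current: Optional[str] = None
    for lineno, raw in enumerate(schema_doc.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        kind, _, rest = line.partition(";")
        kind = kind.strip()
        fields = _parse_fields([p for p in rest.split(";") if p.strip()], lineno)
        if kind == "schema":
            version = fields.get("version", version)
        elif kind == "category":
            if "name" not in fields:
                raise SchemaError(f"line {lineno}: category record lacks name")
            current = fields["name"]
            cat_order.append(current)
            keys = fields.get("keys", "")
            cat_keys[current] = tuple(
                k if "." in k else f"{current}.{k}"
                for k in keys.split("|") if k)
            cat_items[current] = []
        elif kind == "item":
            if current is None:
                raise SchemaError(f"line {lineno}: item record before any category")
            if "name" not in fields:
                raise SchemaError(f"line {lineno}: item record lacks name")
            name = fields["name"]
            if "." not in name:
                name = f"{current}.{name}"
            if name.split(".", 1)[0] != current:
                raise SchemaError(
                    f"line {lineno}: item {name} outside category {current}")
            enum = fields.get("enum")
            try:
                item = ItemDef(
                    name=name,
                    type_code=fields.get("type", "text"),
                    mandatory=fields.get("mandatory", "no") == "yes",
                    enumeration=tuple(enum.split("|")) if enum is not None else None,
                    hard_range=(_parse_range(fields["hard"], lineno)
                                if "hard" in fields else None),
                    soft_range=(_parse_range(fields["soft"], lineno)
                                if "soft" in fields else None),
                    parent=fields.get("parent"),
                )
            except SchemaError as exc:
                raise SchemaError(f"line {lineno}: {exc}") from exc
            cat_items[current].append(item)
        else:
            raise SchemaError(f"line {lineno}: unknown record kind {kind!r}")
    categories = {
        name: CategoryDef(name=name, key_items=cat_keys[name],
                          items=tuple(cat_items[name]))
        for name in cat_order
    }
    return DictionarySchema(categories=categories, version=version)


def serialize_schema(schema: DictionarySchema) -> str:
    lines = [f"schema; version={schema.version}"]
    for cat in schema.categories.values():
        keys = "|".join(k.split(".", 1)[1] for k in cat.key_items)
        lines.append(f"category; name={cat.name}; keys={keys}")
        for item in cat.items:
            parts = [f"item; name={item.name}", f"type={item.type_code}",
                     f"mandatory={'yes' if item.mandatory else 'no'}"]
            if item.enumeration is not None:
                parts.append("enum=" + "|".join(item.enumeration))
            if item.hard_range is not None:
                parts.append("hard={:g}:{:g}".format(*item.hard_range))
            if item.soft_range is not None:
                parts.append("soft={:g}:{:g}".format(*item.soft_range))
            if item.parent is not None:
                parts.append(f"parent={item.parent}")
            lines.append("; ".join(parts))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# validation

def _coerce(value: str, item: ItemDef) -> Optional[Finding]:
    """Type-check a non-null string value; return a finding on violation."""
    if item.type_code == "int":
        try:
            int(value)
        except ValueError:
            return Finding("type_violation", item=item.name,
                           message=f"expected integer, got {value!r}")
    elif item.type_code == "float":
        try:
            v = float(value)
        except ValueError:
            return Finding("type_violation", item=item.name,
                           message=f"expected number, got {value!r}")
        if not math.isfinite(v):
            return Finding("type_violation", item=item.name,
                           message=f"non-finite value {value!r}")
    elif item.type_code == "date":
        try:
            date.fromisoformat(value)
        except ValueError:
            return Finding("type_violation", item=item.name,
                           message=f"expected ISO date, got {value!r}")
    return None


def check_range(value, item: ItemDef) -> Optional[Finding]:
    """Classify a numeric value against an item's hard/soft limits.

    Outside the hard range is an error; inside the hard range but outside
    the soft range is a warning; inside both is conformant (``None``).  A
    value string that does not parse as a number is a type violation.
    """
    if isinstance(value, str):
        try:
            value = float(value)
        except ValueError:
            return Finding("type_violation", item=item.name,
                           message=f"expected number, got {value!r}")
    if not math.isfinite(value):
        return Finding("type_violation", item=item.name,
                       message="non-finite value")
    if item.hard_range is not None:
        lo, hi = item.hard_range
        if not (lo <= value <= hi):
            return Finding("hard_range", item=item.name,
                           message=f"value {value:g} outside hard limits [{lo:g}, {hi:g}]")
    if item.soft_range is not None:
        lo, hi = item.soft_range
        if not (lo <= value <= hi):
            return Finding("soft_range", item=item.name,
                           message=f"value {value:g} outside likely range [{lo:g}, {hi:g}]")
    return None


def derive_soft_limits(samples: Sequence[float], k: float = 3.0) -> Tuple[float, float]:
    """Soft limits as mean ± k standard deviations (sample sd, n−1).

    Values beyond three standard deviations from the mean of the archive
    distribution are flagged as outliers; this returns that band.
    """
    arr = np.asarray(samples, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 samples to derive soft limits")
    if not np.all(np.isfinite(arr)):
        raise ValueError("samples must be finite")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    return (mean - k * sd, mean + k * sd)


def check_keys(block: DataBlock, schema: DictionarySchema) -> List[Finding]:
    """Referential integrity of parent/child key links.

    One ``key_integrity`` error per child row whose parent-key value has no
    matching parent row; duplicated parent key values raise an error on the
    parent category.
    """
    findings: List[Finding] = []
    # item name -> owning category, for parent lookups
    owner: Dict[str, str] = {}
    for cat in schema.categories.values():
        for item in cat.items:
            owner[item.name] = cat.name
    checked_parents: set = set()
    for cat_name, rows in block.tables.items():
        cat = schema.categories.get(cat_name)
        if cat is None:
            continue
        for item in cat.items:
            if item.parent is None or item.name not in (rows[0] if rows else {}):
                continue
            parent_cat = owner[item.parent]
            parent_rows = block.rows(parent_cat)
            parent_values = [r.get(item.parent) for r in parent_rows
                             if r.get(item.parent) not in NULLS
                             and r.get(item.parent) is not None]
            if item.parent not in checked_parents:
                checked_parents.add(item.parent)
                seen: set = set()
                for v in parent_values:
                    if v in seen:
                        findings.append(Finding(
                            "key_integrity", item=item.parent,
                            locus=(parent_cat, parent_values.index(v)),
                            message=f"duplicate parent key value {v!r}"))
                    seen.add(v)
            parent_set = set(parent_values)
            for i, row in enumerate(rows):
                v = row.get(item.name)
                if v is None or v in NULLS:
                    continue
                if v not in parent_set:
                    findings.append(Finding(
                        "key_integrity", item=item.name, locus=(cat_name, i),
                        message=f"value {v!r} has no matching row in {parent_cat}"))
    return findings


def validate_block(block: DataBlock, schema: DictionarySchema) -> List[Finding]:
    """Validate one data block against the dictionary.

    Checks, per category in block order and per row: mandatory presence,
    type conformance, enumerations, hard/soft ranges; then referential key
    integrity.  An empty return means the block is fully conformant.
    A category unknown to the schema yields an ``unknown_category`` error
    finding rather than an exception.
    """
    findings: List[Finding] = []
    for cat_name, rows in block.tables.items():
        cat = schema.categories.get(cat_name)
        if cat is None:
            findings.append(Finding("unknown_category", locus=(cat_name, 0),
                                    message=f"category {cat_name!r} not in dictionary"))
            continue
        for i, row in enumerate(rows):
            for item in cat.items:
                value = row.get(item.name)
                is_null = value is None or value in NULLS or value == ""
                if item.mandatory and is_null:
                    findings.append(Finding(
                        "missing_mandatory", item=item.name, locus=(cat_name, i),
                        message="mandatory item absent or null"))
                    continue
                if is_null:
                    continue
                tf = _coerce(value, item)
                if tf is not None:
                    findings.append(Finding(tf.code, item=tf.item,
                                            locus=(cat_name, i), message=tf.message))
                    continue
                if item.type_code == "enum" and value not in item.enumeration:
                    findings.append(Finding(
                        "enum_violation", item=item.name, locus=(cat_name, i),
                        message=f"value {value!r} not in enumeration"))
                if item.type_code in ("int", "float"):
                    rf = check_range(value, item)
                    if rf is not None:
                        findings.append(Finding(rf.code, item=rf.item,
                                                locus=(cat_name, i),
                                                message=rf.message))
    findings.extend(check_keys(block, schema))
    return findings
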