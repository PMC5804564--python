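"""Controlled vocabulary of curation findings.

Every issue detected anywhere in the pipeline is a :class:`Finding` whose
``code`` comes from a fixed registry: the twenty issue categories raised
during biocuration of deposited structures (chirality errors, backbone
linkage breaks, atomic clashes, ...) plus the dictionary-level codes emitted
by schema validation (missing mandatory item, enumeration violation, ...)
and a handful of bookkeeping codes used by the curation stages themselves.

Severity is a property of the code, not of the individual finding, so that
reports are diffable: a hard-range violation is always an error, a
soft-range violation always a warning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple, Union

#: Issue codes from the biocuration issue taxonomy, verbatim.
CURATION_CODES = {
    "Chirality error": "error",
    "Polymer backbone linkage": "error",
    "Atomic clashes": "error",
    "Sequence discrepancy": "error",
    "Atoms with unrealistic or zero occupancies": "error",
    "High real space R-factor and low correlation in the structure factors": "warning",
    "Incomplete data in the structure factors": "warning",
    "Missing and/or inconsistent metadata values": "warning",
    "Reported and calculated quaternary structure do not agree": "error",
    "Ligand geometry": "warning",
    "Occupancy of atoms on special symmetry positions": "error",
    "Wavelength discrepancy": "warning",
    "Missing anisotropic B-factor": "warning",
    "Ligand identity": "error",
    "Distant waters": "warning",
    "Polymer geometry": "warning",
    "Unusual phi/psi torsion angles": "warning",
    "Extra hydrogen atoms": "warning",
    "Zero B-factor": "warning",
    "Missing free R test set in the structure factors": "warning",
}

#: Dictionary-validation codes.
DICTIONARY_CODES = {
    "missing_mandatory": "error",
    "enum_violation": "error",
    "type_violation": "error",
    "hard_range": "error",
    "soft_range": "warning",
    "key_integrity": "error",
    "unknown_category": "error",
}

#: Codes used internally by curation stages (merges, refusals, notes).
STAGE_CODES = {
    "missing_sequence": "error",
    "merge_conflict": "error",
    "split_applied": "info",
    "merge_applied": "info",
    "transform_refused": "error",
    "chirality_indeterminate": "info",
    "stereocenter_unmapped": "info",
    "atom_renamed": "info",
    "residue_relabeled": "info",
    "unmodeled_region": "info",
    "correspondence_needed": "error",
    "ligand_incomplete": "info",
    "not_applicable": "info",
    "chimera_unassigned": "warning",
    "new_component": "info",
}

VOCABULARY = {**CURATION_CODES, **DICTIONARY_CODES, **STAGE_CODES}

SEVERITY_ORDER = {"error": 0, "warning": 1, "info": 2}

Locus = Union[Tuple[str, int], Tuple[str, int, str], Tuple[str, ...], str, None]


@dataclass(frozen=True)
class Finding:
    """One detected issue.

    Parameters
    ----------
    code:
        Registry code; fixes the severity.
    item:
        Dictionary item name (``category.item``) when the finding concerns
        a metadata value.
    locus:
        Where in the deposition the issue sits: ``(category, row_index)``
        for tabular findings or ``(chain, residue_number[, atom])`` for
        structural ones.
    message:
        Human-readable one-liner.
    """

    code: str
    message: str = ""
    item: Optional[str] = None
    locus: Locus = None

    def __post_init__(self) -> None:
        if self.code not in VOCABULARY:
            raise ValueError(f"unknown finding code: {self.code!r}")

    @property
    def severity(self) -> str:
        return VOCABULARY[self.code]

    def __str__(self) -> str:  # pragma: no cover - convenience
        loc = f" at {self.locus}" if self.locus is not None else ""
        itm = f" [{self.item}]" if self.item else ""
        return f"{self.severity.upper()} {self.code}{itm}{loc}: {self.message}"


def sort_findings(findings):
    """Stable severity-major ordering used by reports."""
    return sorted(
        findings,
        key=lambda f: (SEVERITY_ORDER[f.severity], f.code, str(f.item), str(f.locus)),
    )
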