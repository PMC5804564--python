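"""Curation workflow orchestration, release policy and reporting.

The curation pipeline is a fixed-order state machine — entity, ligand,
sequence, annotation, validation, communication — where a module may run
only after all its predecessors completed, and restarting a module resets
it and everything downstream.  Depositions are routed to a regional
curation center by depositor geography.  Release scheduling enforces the
one-year hold: reminders go out three, two and one calendar months before
hold expiry, publication triggers release at the next weekly release day,
and an unpublished deposition is released (or withdrawn) when the hold
expires.  Structure-quality metrics are turned into percentile scores
against reference distributions, and all findings are compiled into a
report bundle with a deterministic depositor letter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .findings import Finding, SEVERITY_ORDER, sort_findings

MODULE_ORDER = ("entity", "ligand", "sequence", "annotation", "validation",
                "communication")
STATUSES = ("pending", "running", "complete", "error", "needs_depositor")
EVENTS = ("start", "complete", "fail", "restart")

ROUTING = {
    "Americas": "RCSB", "Oceania": "RCSB",
    "Europe": "PDBe", "Africa": "PDBe",
    "Asia": "PDBj",
}

RELEASE_WEEKDAY = 2  # Wednesday


class RoutingError(ValueError):
    pass


class OrderingError(ValueError):
    pass


class PolicyError(ValueError):
    pass


def route_deposition(region: str) -> str:
    """Geographic routing to a regional curation center."""
    try:
        return ROUTING[region]
    except KeyError:
        raise RoutingError(f"unknown region {region!r}; expected one of "
                           f"{sorted(ROUTING)}") from None


# ---------------------------------------------------------------------------
# workflow state machine

@dataclass(frozen=True)
class WorkflowState:
    status: Tuple[Tuple[str, str], ...] = tuple(
        (m, "pending") for m in MODULE_ORDER)
    history: Tuple[Tuple[int, str, str], ...] = ()  # (tick, module, event)

    def get(self, module: str) -> str:
        for m, s in self.status:
            if m == module:
                return s
        raise KeyError(module)

    def as_dict(self) -> Dict[str, str]:
        return dict(self.status)

    @property
    def is_terminal(self) -> bool:
        return all(s == "complete" for _, s in self.status)


def advance(state: WorkflowState, module: str, event: str) -> WorkflowState:
    """Apply one workflow event, enforcing the predecessor invariant.

    ``start`` requires every predecessor complete; ``restart`` of module m
    resets m and all its successors to pending.  Illegal transitions raise
    :class:`OrderingError` and leave the state untouched.
    """
    if module not in MODULE_ORDER:
        raise OrderingError(f"unknown module {module!r}")
    if event not in EVENTS:
        raise OrderingError(f"unknown event {event!r}")
    idx = MODULE_ORDER.index(module)
    current = state.get(module)
    new = dict(state.status)
    if event == "start":
        if any(state.get(m) != "complete" for m in MODULE_ORDER[:idx]):
            raise OrderingError(
                f"cannot start {module}: predecessors not complete")
        if current not in ("pending", "error"):
            raise OrderingError(f"cannot start {module} from state {current}")
        new[module] = "running"
    elif event == "complete":
        if current != "running":
            raise OrderingError(f"cannot complete {module} from state {current}")
        new[module] = "complete"
    elif event == "fail":
        if current != "running":
            raise OrderingError(f"cannot fail {module} from state {current}")
        new[module] = "error"
    elif event == "restart":
        for m in MODULE_ORDER[idx:]:
            new[m] = "pending"
    tick = len(state.history)
    return WorkflowState(
        status=tuple((m, new[m]) for m in MODULE_ORDER),
        history=state.history + ((tick, module, event),))


# ---------------------------------------------------------------------------
# release policy calendar

def _add_months(d: date, months: int) -> date:
    """Shift by calendar months preserving day-of-month, clamped to month end."""
    month = d.month - 1 + months
    year = d.year + month // 12
    month = month % 12 + 1
    # clamp to last day of target month
    for day in (d.day, 30, 29, 28):
        try:
            return date(year, month, day)
        except ValueError:
            continue
    raise AssertionError("unreachable")


def _next_release_day(d: date, weekday: int = RELEASE_WEEKDAY) -> date:
    return d + timedelta(days=(weekday - d.weekday()) % 7)


@dataclass(frozen=True)
class ReleaseSchedule:
    deposit_date: date
    hold_expiry: date
    reminder_dates: Tuple[date, date, date]
    release_date: Optional[date]
    trigger: str  # publication | hold_expiry | depositor_request | withdrawn

    def __post_init__(self) -> None:
        if any(r >= self.hold_expiry for r in self.reminder_dates):
            raise ValueError("reminders must precede hold expiry")
        if (self.trigger != "withdrawn" and self.release_date is not None
                and self.release_date > self.hold_expiry):
            raise ValueError("release cannot postdate hold expiry")


def plan_release(deposit_date: date,
                 events: Sequence[Tuple[date, str]] = ()) -> ReleaseSchedule:
    """Compute the hold/reminder/release calendar for one deposition.

    The hold expires one year after deposit (month arithmetic, day
    clamped); reminders fall three, two and one months before expiry.  A
    publication or depositor-request event before expiry releases at the
    next weekly release day (Wednesday by default, capped at expiry); with
    no event the entry releases when the hold expires.  Withdrawal stops
    the calendar; any event after a withdrawal is a policy error.
    """
    expiry = _add_months(deposit_date, 12)
    reminders = tuple(_add_months(expiry, -k) for k in (3, 2, 1))
    withdrawn_on: Optional[date] = None
    release: Optional[date] = None
    trigger = "hold_expiry"
    for when, kind in sorted(events):
        if withdrawn_on is not None:
            raise PolicyError(f"event {kind!r} on {when} after withdrawal")
        if kind == "withdrawn":
            withdrawn_on = when
            release, trigger = None, "withdrawn"
        elif kind in ("publication", "depositor_request"):
            if when <= expiry and release is None:
                release = min(_next_release_day(when), expiry)
                trigger = kind
        else:
            raise PolicyError(f"unknown release event kind {kind!r}")
    if release is None and trigger != "withdrawn":
        release, trigger = expiry, "hold_expiry"
    return ReleaseSchedule(deposit_date=deposit_date, hold_expiry=expiry,
                           reminder_dates=reminders, release_date=release,
                           trigger=trigger)


# ---------------------------------------------------------------------------
# percentile scores

def percentile_score(value: float, reference: Sequence[float],
                     higher_is_better: bool) -> float:
    """Percentile of a metric within a reference cohort (0 worst, 100 best)."""
    if len(reference) == 0:
        raise ValueError("empty reference distribution")
    if higher_is_better:
        worse = sum(1 for r in reference if r < value)
    else:
        worse = sum(1 for r in reference if r > value)
    ties = sum(1 for r in reference if r == value)
    return 100.0 * (worse + 0.5 * ties) / len(reference)


# ---------------------------------------------------------------------------
# report compilation

LETTER_HEADER = "Dear Depositor,\n\nThank you for your deposition {dep_id}.\n"
NO_ISSUES = "Our curation checks raised no outstanding issues.\n"


@dataclass
class ReportBundle:
    counts: Dict[str, int]
    percentiles: Dict[str, float]
    letter: str
    overall_status: str  # ok | needs_depositor
    findings: List[Finding] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "counts": self.counts,
            "percentiles": self.percentiles,
            "overall_status": self.overall_status,
            "findings": [
                {"code": f.code, "severity": f.severity, "item": f.item,
                 "locus": list(f.locus) if isinstance(f.locus, tuple) else f.locus,
                 "message": f.message}
                for f in self.findings],
            "letter": self.letter,
        }


def compile_report(findings: Sequence[Finding],
                   percentiles: Optional[Mapping[str, float]] = None,
                   metadata: Optional[Mapping[str, str]] = None) -> ReportBundle:
    """Group findings, render the depositor letter, set the overall status.

    Counts conserve the finding multiset; the letter lists errors first,
    then warnings, then info, each with its locus, from a fixed template.
    Any error-severity finding sets the status to ``needs_depositor``.
    """
    meta = dict(metadata or {})
    counts: Dict[str, int] = {}
    for f in findings:
        counts[f.code] = counts.get(f.code, 0) + 1
    ordered = sort_findings(findings)
    lines = [LETTER_HEADER.format(dep_id=meta.get("dep_id", "(unassigned)"))]
    if not ordered:
        lines.append(NO_ISSUES)
    else:
        lines.append("The following items were noted during biocuration:\n")
        for sev in ("error", "warning", "info"):
            group = [f for f in ordered if f.severity == sev]
            if not group:
                continue
            lines.append(f"{sev.upper()}S:")
            for f in group:
                loc = f" [{'/'.join(map(str, f.locus))}]" if isinstance(
                    f.locus, tuple) else (f" [{f.locus}]" if f.locus else "")
                lines.append(f"  - {f.code}{loc}: {f.message}")
            lines.append("")
    for metric in sorted(percentiles or {}):
        lines.append(f"Percentile ({metric}): {(percentiles or {})[metric]:.1f}")
    lines.append("\nSincerely,\nthe curation team\n")
    status = "needs_depositor" if any(
        f.severity == "error" for f in findings) else "ok"
    return ReportBundle(counts=counts, percentiles=dict(percentiles or {}),
                        letter="\n".join(lines), overall_status=status,
                        findings=list(findings))
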