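"""Common information model: mediated patient records and eligibility queries.

Every source dialect converges on :class:`PatientRecord` — demographics plus
dated, coded clinical statements of five kinds (condition, medication,
lab_result, procedure, allergy).  The record carries an ``extensions`` map so
new data elements can be added without disrupting existing ones.  Dates are
day-granular throughout; times are discarded on ingest.

Eligibility queries are ASTs over coded leaves: Boolean AND/OR nodes and
windowed temporal relations ("condition within 120 days after medication").
A :class:`StudyDefinition` pairs a foreground and a background query with
the grouping, statistics and risk-factor configuration of one
case-series characterization study.

Records serialize as NDJSON (one record per line); studies as YAML.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Iterable, Mapping, Optional

import yaml

__all__ = [
    "STATEMENT_KINDS",
    "CodedValue",
    "Quantity",
    "ClinicalStatement",
    "PatientRecord",
    "Leaf",
    "Bool",
    "Temporal",
    "EligibilityQuery",
    "StudyDefinition",
    "Finding",
    "ModelError",
    "validate_record",
    "read_records",
    "write_records",
    "record_to_dict",
    "record_from_dict",
    "normalize",
    "load_study",
    "study_from_dict",
]

STATEMENT_KINDS = ("condition", "medication", "lab_result", "procedure", "allergy")

_MIN_BIRTH_YEAR = 1900


class ModelError(Exception):
    """Raised on malformed records, queries or study definitions."""


@dataclass(frozen=True)
class CodedValue:
    """A code drawn from one terminology scheme, with an optional label."""

    scheme_id: str
    code: str
    label: Optional[str] = None

    @property
    def ref(self) -> tuple[str, str]:
        return (self.scheme_id, self.code)


@dataclass(frozen=True)
class Quantity:
    value: float
    unit: str


@dataclass(frozen=True)
class ClinicalStatement:
    """One dated, coded fact about a patient.

    ``value`` is only meaningful for lab results (a measured quantity or a
    coded result).  ``derived`` flags statements inferred by derived-condition
    rules rather than recorded at source.  ``groups`` holds the grouping
    annotation added by result enrichment; original codes are never altered.
    """

    kind: str
    code: CodedValue
    effective_start: Optional[dt.date] = None
    effective_end: Optional[dt.date] = None
    value: Optional[Quantity | CodedValue] = None
    derived: bool = False
    groups: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        if self.kind not in STATEMENT_KINDS:
            raise ModelError(f"unknown statement kind {self.kind!r}")


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    birth_year: Optional[int]
    gender: Optional[CodedValue] = None
    country: Optional[CodedValue] = None
    statements: tuple[ClinicalStatement, ...] = ()
    extensions: Mapping[str, Any] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Eligibility query AST
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Leaf:
    """Match patients with >=1 statement of ``kind`` coded in ``codes``."""

    kind: str
    codes: frozenset[CodedValue]
    negated: bool = False


@dataclass(frozen=True)
class Bool:
    op: str  # "AND" | "OR"
    children: tuple["CriteriaNode", ...]

    def __post_init__(self) -> None:
        if self.op not in ("AND", "OR"):
            raise ModelError(f"Bool op must be AND or OR, got {self.op!r}")
        if len(self.children) < 2:
            raise ModelError("Bool node requires at least 2 children")


@dataclass(frozen=True)
class Temporal:
    """``related`` occurs within ``window_days`` of ``anchor``.

    ``direction``: "after" means related.start in [anchor.start,
    anchor.start + window]; "before" mirrors it; "either" is the union.
    Bounds are inclusive at both ends (day 0 counts).
    """

    anchor: "CriteriaNode"
    related: "CriteriaNode"
    direction: str = "after"
    window_days: int = 0

    def __post_init__(self) -> None:
        if self.direction not in ("after", "before", "either"):
            raise ModelError(f"bad temporal direction {self.direction!r}")
        if self.window_days < 0:
            raise ModelError("window_days must be >= 0")


CriteriaNode = Leaf | Bool | Temporal


@dataclass(frozen=True)
class EligibilityQuery:
    root: CriteriaNode


def normalize(node: CriteriaNode) -> CriteriaNode:
    """Flatten nested same-op Bool nodes; idempotent, order-preserving."""
    if isinstance(node, Leaf):
        return node
    if isinstance(node, Temporal):
        return Temporal(normalize(node.anchor), normalize(node.related), node.direction, node.window_days)
    flat: list[CriteriaNode] = []
    for child in node.children:
        c = normalize(child)
        if isinstance(c, Bool) and c.op == node.op:
            flat.extend(c.children)
        else:
            flat.append(c)
    return Bool(node.op, tuple(flat))


@dataclass(frozen=True)
class StudyDefinition:
    """One case-series characterization study.

    ``grouping`` maps a statement kind to the (scheme, level) its codes are
    grouped under in the report; ``index_anchor`` is the criterion whose
    earliest matching statement defines a patient's index date for
    before/after boxes.
    """

    foreground: EligibilityQuery
    background: EligibilityQuery
    grouping: Mapping[str, tuple[str, str]]
    statistics: tuple[str, ...]
    risk_factors: frozenset[CodedValue] = frozenset()
    index_anchor: Optional[CriteriaNode] = None
    before_after_window_days: Optional[int] = None
    name: str = "study"

    def __post_init__(self) -> None:
        if not self.statistics:
            raise ModelError("statistics list must be non-empty")


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Finding:
    severity: str  # "error" | "warning"
    path: str
    message: str


def validate_record(record: PatientRecord, terminologies: Mapping[str, Any] | None = None) -> list[Finding]:
    """Check record invariants; returns findings rather than raising.

    With ``terminologies`` given, codes are resolved against the loaded
    schemes: an unloaded scheme is a warning, an unknown code in a loaded
    scheme an error.
    """
    out: list[Finding] = []
    this_year = dt.date.today().year
    if not record.patient_id:
        out.append(Finding("error", "patient_id", "patient_id is empty"))
    if record.birth_year is not None and not (_MIN_BIRTH_YEAR <= record.birth_year <= this_year):
        out.append(Finding("error", "birth_year", f"implausible birth_year {record.birth_year}"))
    for i, s in enumerate(record.statements):
        p = f"statements[{i}]"
        if s.effective_start and s.effective_end and s.effective_end < s.effective_start:
            out.append(Finding("error", p, "effective_end precedes effective_start"))
        if s.kind == "lab_result" and s.value is None:
            out.append(Finding("error", p, "lab_result requires a value"))
        if s.kind != "lab_result" and s.value is not None:
            out.append(Finding("error", p, f"value not allowed on kind {s.kind!r}"))
        if terminologies is not None:
            sch = terminologies.get(s.code.scheme_id)
            if sch is None:
                out.append(Finding("warning", p, f"scheme {s.code.scheme_id!r} not loaded"))
            elif s.code.code not in sch:
                out.append(Finding("error", p, f"code {s.code.code!r} unknown in {s.code.scheme_id!r}"))
    return out


# ---------------------------------------------------------------------------
# NDJSON serialization
# ---------------------------------------------------------------------------


def _coded_to_dict(c: CodedValue) -> dict:
    d = {"scheme": c.scheme_id, "code": c.code}
    if c.label is not None:
        d["label"] = c.label
    return d


def _coded_from_dict(d: Mapping, path: str) -> CodedValue:
    try:
        return CodedValue(scheme_id=d["scheme"], code=d["code"], label=d.get("label"))
    except (KeyError, TypeError) as exc:
        raise ModelError(f"{path}: malformed coded value {d!r}") from exc


def _date_out(d: Optional[dt.date]) -> Optional[str]:
    return d.isoformat() if d else None


def _date_in(s: Any, path: str) -> Optional[dt.date]:
    if s is None:
        return None
    try:
        return dt.date.fromisoformat(str(s)[:10])  # day granularity: trim any time part
    except ValueError as exc:
        raise ModelError(f"{path}: invalid date {s!r}") from exc


def record_to_dict(r: PatientRecord) -> dict:
    stmts = []
    for s in r.statements:
        d: dict[str, Any] = {"kind": s.kind, "code": _coded_to_dict(s.code)}
        if s.effective_start:
            d["start"] = _date_out(s.effective_start)
        if s.effective_end:
            d["end"] = _date_out(s.effective_end)
        if isinstance(s.value, Quantity):
            d["value"] = {"value": s.value.value, "unit": s.value.unit}
        elif isinstance(s.value, CodedValue):
            d["value"] = _coded_to_dict(s.value)
        if s.derived:
            d["derived"] = True
        if s.groups is not None:
            d["groups"] = sorted(s.groups)
        stmts.append(d)
    out: dict[str, Any] = {"patient_id": r.patient_id, "birth_year": r.birth_year, "statements": stmts}
    if r.gender:
        out["gender"] = _coded_to_dict(r.gender)
    if r.country:
        out["country"] = _coded_to_dict(r.country)
    if r.extensions:
        out["extensions"] = dict(r.extensions)
    return out


def _statement_from_dict(d: Mapping, path: str) -> ClinicalStatement:
    kind = d.get("kind")
    if kind not in STATEMENT_KINDS:
        raise ModelError(f"{path}: unknown statement kind {kind!r}")
    value: Optional[Quantity | CodedValue] = None
    if "value" in d:
        v = d["value"]
        if isinstance(v, Mapping) and "unit" in v:
            value = Quantity(value=float(v["value"]), unit=str(v["unit"]))
        elif isinstance(v, Mapping):
            value = _coded_from_dict(v, path + ".value")
        else:
            raise ModelError(f"{path}: malformed value {v!r}")
    groups = d.get("groups")
    return ClinicalStatement(
        kind=kind,
        code=_coded_from_dict(d.get("code", {}), path + ".code"),
        effective_start=_date_in(d.get("start"), path + ".start"),
        effective_end=_date_in(d.get("end"), path + ".end"),
        value=value,
        derived=bool(d.get("derived", False)),
        groups=frozenset(groups) if groups is not None else None,
    )


def record_from_dict(d: Mapping, path: str = "record") -> PatientRecord:
    if not isinstance(d, Mapping) or "patient_id" not in d:
        raise ModelError(f"{path}: missing patient_id")
    stmts = tuple(
        _statement_from_dict(s, f"{path}.statements[{i}]") for i, s in enumerate(d.get("statements", []))
    )
    gender = _coded_from_dict(d["gender"], path + ".gender") if d.get("gender") else None
    country = _coded_from_dict(d["country"], path + ".country") if d.get("country") else None
    by = d.get("birth_year")
    return PatientRecord(
        patient_id=str(d["patient_id"]),
        birth_year=int(by) if by is not None else None,
        gender=gender,
        country=country,
        statements=stmts,
        extensions=dict(d.get("extensions", {})),
    )


def write_records(records: Iterable[PatientRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(json.dumps(record_to_dict(r), sort_keys=True) + "\n")


def read_records(path: str | Path) -> list[PatientRecord]:
    out: list[PatientRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                d = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ModelError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
            try:
                out.append(record_from_dict(d, path=f"{path}:{lineno}"))
            except ModelError:
                raise
    return out


# ---------------------------------------------------------------------------
# Study definition YAML
# ---------------------------------------------------------------------------
#
# criteria:
#   kind: condition
#   codes: [{scheme: RSRCH, code: R1.2.3.1}]
# or {op: AND, children: [...]} or
#   {temporal: {anchor: {...}, related: {...}, direction: after, window_days: 120}}


def _criteria_from_dict(d: Mapping, path: str) -> CriteriaNode:
    if "op" in d:
        children = d.get("children", [])
        return Bool(
            op=str(d["op"]).upper(),
            children=tuple(_criteria_from_dict(c, f"{path}.children[{i}]") for i, c in enumerate(children)),
        )
    if "temporal" in d:
        t = d["temporal"]
        return Temporal(
            anchor=_criteria_from_dict(t["anchor"], path + ".anchor"),
            related=_criteria_from_dict(t["related"], path + ".related"),
            direction=t.get("direction", "after"),
            window_days=int(t.get("window_days", 0)),
        )
    if "kind" in d:
        codes = frozenset(_coded_from_dict(c, path + ".codes") for c in d.get("codes", []))
        if not codes:
            raise ModelError(f"{path}: leaf criterion has no codes")
        return Leaf(kind=d["kind"], codes=codes, negated=bool(d.get("negated", False)))
    raise ModelError(f"{path}: criterion must have 'kind', 'op' or 'temporal'")


def study_from_dict(d: Mapping) -> StudyDefinition:
    try:
        fg = EligibilityQuery(_criteria_from_dict(d["foreground"], "foreground"))
        bg = EligibilityQuery(_criteria_from_dict(d["background"], "background"))
    except KeyError as exc:
        raise ModelError(f"study definition missing section {exc}") from exc
    grouping = {k: (v["scheme"], v["level"]) for k, v in d.get("grouping", {}).items()}
    for k in grouping:
        if k not in STATEMENT_KINDS:
            raise ModelError(f"grouping declared for unknown kind {k!r}")
    risk = frozenset(_coded_from_dict(c, "risk_factors") for c in d.get("risk_factors", []))
    index = _criteria_from_dict(d["index_anchor"], "index_anchor") if d.get("index_anchor") else None
    return StudyDefinition(
        foreground=fg,
        background=bg,
        grouping=grouping,
        statistics=tuple(d.get("statistics", [])),
        risk_factors=risk,
        index_anchor=index,
        before_after_window_days=d.get("before_after_window_days"),
        name=str(d.get("name", "study")),
    )


def load_study(path: str | Path) -> StudyDefinition:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, Mapping):
        raise ModelError(f"{path}: study definition must be a mapping")
    return study_from_dict(d)
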