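"""Source-data formalization and declarative conversion to the common model.

Two source dialects are supported, mirroring the two kinds of EHR export a
regional data warehouse and a hospital information system typically offer:

* a *document* dialect — a simplified CDA/CCD-style XML patient summary set
  (sections for problems, medications, results, ...; observation entries
  carrying ``code/@code``, ``code/@codeSystem`` and ``effectiveTime/@value``
  as YYYYMMDD), and
* a *relational* dialect — CSV tables (``patients`` plus one table per
  statement kind) joined by ``patient_id`` foreign keys, dates ISO-8601.

XML input is first *formalized* into a :class:`NodeGraph`, a one-to-one
graph image of the document (one node per element, one literal per
attribute/text node) — lossless by construction, so the graph re-serializes
to an equivalent document.  Declarative :class:`ConversionRule` entries
(path patterns + attribute/column bindings, no embedded code) then map
graph fragments or table rows onto common-model demographics and clinical
statements.  Unmatched source content is counted and reported as residue,
never silently dropped.  Both dialects converge on identical
:class:`~caseseries.common_model.PatientRecord` sets after canonical
ordering — the central mediation contract.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Optional

import pandas as pd
import yaml
from lxml import etree

from .common_model import (
    STATEMENT_KINDS,
    ClinicalStatement,
    CodedValue,
    Finding,
    ModelError,
    PatientRecord,
    Quantity,
)

__all__ = [
    "NodeGraph",
    "ConversionRule",
    "MediationError",
    "formalize_xml",
    "graph_to_xml",
    "apply_rules",
    "convert_relational",
    "canonicalize_records",
    "default_xml_rules",
    "default_relational_rules",
    "CODE_SYSTEM_MAP",
    "scheme_for_code_system",
    "code_system_for_scheme",
    "ResidueReport",
]


class MediationError(Exception):
    """Raised on malformed sources or invalid conversion rules."""


# ---------------------------------------------------------------------------
# Code-system identifier normalization
# ---------------------------------------------------------------------------

#: Known code-system identifiers (OID-style) -> scheme_id.  Sources stamp raw
#: codeSystem attributes; the common model wants scheme ids.  Identifiers of
#: the form ``urn:scheme:<id>`` fall through to ``<id>`` by convention.
CODE_SYSTEM_MAP: dict[str, str] = {
    "2.16.840.1.113883.6.103": "ICD9CM",
    "2.16.840.1.113883.6.3": "ICD10",
    "2.16.840.1.113883.6.96": "SNOMEDCT",
    "2.16.840.1.113883.6.163": "MEDDRA",
    "2.16.840.1.113883.6.73": "ATC",
}

_URN_PREFIX = "urn:scheme:"


def scheme_for_code_system(ident: str) -> str:
    if ident in CODE_SYSTEM_MAP:
        return CODE_SYSTEM_MAP[ident]
    if ident.startswith(_URN_PREFIX):
        return ident[len(_URN_PREFIX):]
    return ident  # pass through: validation downstream will flag unknown schemes


def code_system_for_scheme(scheme_id: str) -> str:
    for oid, sid in CODE_SYSTEM_MAP.items():
        if sid == scheme_id:
            return oid
    return _URN_PREFIX + scheme_id


# ---------------------------------------------------------------------------
# NodeGraph: one-to-one formalization of an XML document
# ---------------------------------------------------------------------------


@dataclass
class NodeGraph:
    """Graph image of one XML document.

    ``edges`` are (parent, child-element-name, child) triples in document
    order; ``literals`` are (node, attribute-name, value) triples, with the
    reserved attribute name ``#text`` for stripped text content.  Element
    and attribute names are preserved verbatim.
    """

    root: str
    root_name: str
    nodes: set[str] = field(default_factory=set)
    edges: list[tuple[str, str, str]] = field(default_factory=list)
    literals: list[tuple[str, str, str]] = field(default_factory=list)

    def children(self, node: str) -> list[tuple[str, str]]:
        return [(name, c) for p, name, c in self.edges if p == node]

    def attrs(self, node: str) -> dict[str, str]:
        return {k: v for n, k, v in self.literals if n == node and k != "#text"}

    def text(self, node: str) -> Optional[str]:
        for n, k, v in self.literals:
            if n == node and k == "#text":
                return v
        return None


def formalize_xml(source: str | Path | bytes) -> NodeGraph:
    """Formalize an XML document into its one-to-one :class:`NodeGraph`.

    Node count equals element count; literal count equals attribute count
    plus non-empty text nodes.  Raises :class:`MediationError` with parser
    location on malformed input.
    """
    try:
        if isinstance(source, bytes):
            root = etree.fromstring(source)
        elif isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists()):
            root = etree.parse(str(source)).getroot()
        else:
            root = etree.fromstring(source.encode())
    except (etree.XMLSyntaxError, OSError) as exc:
        raise MediationError(f"malformed XML: {exc}") from exc

    g = NodeGraph(root="n0", root_name=root.tag)
    counter = 0

    def walk(el: etree._Element, node_id: str) -> None:
        nonlocal counter
        g.nodes.add(node_id)
        for k, v in el.attrib.items():
            g.literals.append((node_id, k, v))
        if el.text and el.text.strip():
            g.literals.append((node_id, "#text", el.text.strip()))
        for child in el:
            if not isinstance(child.tag, str):  # skip comments/PIs
                continue
            counter += 1
            cid = f"n{counter}"
            g.edges.append((node_id, child.tag, cid))
            walk(child, cid)

    walk(root, "n0")
    return g


def graph_to_xml(g: NodeGraph) -> bytes:
    """Deterministic re-serialization: equal to the source document up to
    attribute order and whitespace."""

    def build(node: str, tag: str) -> etree._Element:
        el = etree.Element(tag)
        for k in sorted(g.attrs(node)):
            el.set(k, g.attrs(node)[k])
        t = g.text(node)
        if t is not None:
            el.text = t
        for name, child in g.children(node):
            el.append(build(child, name))
        return el

    return etree.tostring(build(g.root, g.root_name), pretty_print=True)


# ---------------------------------------------------------------------------
# Conversion rules
# ---------------------------------------------------------------------------

# Binding targets understood by the record assembler.
_DEMOGRAPHIC_FIELDS = {"patient_id", "birth_year", "gender", "country"}
_STATEMENT_FIELDS = {
    "patient_id",  # relational statement rows carry their own foreign key
    "code", "code_system", "label", "start", "end", "value", "unit", "value_code", "value_code_system",
}


@dataclass(frozen=True)
class ConversionRule:
    """Declarative mapping from a source pattern to a common-model construct.

    For the document dialect ``source_pattern`` is an element path from the
    root, each segment optionally predicated on attributes
    (``section[type=problems]/observation``); bindings map relative literal
    paths (``code/@code``) to target fields.  For the relational dialect
    ``source_pattern`` is ``table:<name>`` and bindings map column names to
    the same fields.  ``constructor`` is a statement kind or ``demographics``.
    """

    source_pattern: str
    bindings: Mapping[str, str]
    constructor: str

    def __post_init__(self) -> None:
        valid = _DEMOGRAPHIC_FIELDS if self.constructor == "demographics" else _STATEMENT_FIELDS
        if self.constructor != "demographics" and self.constructor not in STATEMENT_KINDS:
            raise MediationError(f"rule {self.source_pattern!r}: unknown constructor {self.constructor!r}")
        for src, tgt in self.bindings.items():
            if tgt not in valid:
                raise MediationError(
                    f"rule {self.source_pattern!r}: binding {src!r} targets unknown field {tgt!r}"
                )


_DEFAULT_RULES_YAML = """
xml:
  - pattern: patientSummary/patient
    constructor: demographics
    bindings: {"@id": patient_id, "@birthYear": birth_year, "@gender": gender, "@country": country}
  - pattern: patientSummary/section[type=problems]/observation
    constructor: condition
    bindings: {"code/@code": code, "code/@codeSystem": code_system,
               "code/@displayName": label, "effectiveTime/@value": start}
  - pattern: patientSummary/section[type=medications]/substanceAdministration
    constructor: medication
    bindings: {"code/@code": code, "code/@codeSystem": code_system,
               "code/@displayName": label,
               "effectiveTime/@value": start, "effectiveTime/@high": end}
  - pattern: patientSummary/section[type=results]/observation
    constructor: lab_result
    bindings: {"code/@code": code, "code/@codeSystem": code_system,
               "code/@displayName": label, "effectiveTime/@value": start,
               "value/@value": value, "value/@unit": unit}
  - pattern: patientSummary/section[type=procedures]/procedure
    constructor: procedure
    bindings: {"code/@code": code, "code/@codeSystem": code_system,
               "code/@displayName": label, "effectiveTime/@value": start}
  - pattern: patientSummary/section[type=allergies]/observation
    constructor: allergy
    bindings: {"code/@code": code, "code/@codeSystem": code_system,
               "code/@displayName": label, "effectiveTime/@value": start}
relational:
  - pattern: "table:patients"
    constructor: demographics
    bindings: {patient_id: patient_id, birth_year: birth_year, gender: gender, country: country}
  - pattern: "table:conditions"
    constructor: condition
    bindings: {patient_id: patient_id, scheme: code_system, code: code, label: label, start_date: start}
  - pattern: "table:medications"
    constructor: medication
    bindings: {patient_id: patient_id, scheme: code_system, code: code, label: label,
               start_date: start, end_date: end}
  - pattern: "table:lab_results"
    constructor: lab_result
    bindings: {patient_id: patient_id, scheme: code_system, code: code, label: label,
               start_date: start, value: value, unit: unit}
  - pattern: "table:procedures"
    constructor: procedure
    bindings: {patient_id: patient_id, scheme: code_system, code: code, label: label, start_date: start}
  - pattern: "table:allergies"
    constructor: allergy
    bindings: {patient_id: patient_id, scheme: code_system, code: code, label: label, start_date: start}
"""

_DEFAULTS = yaml.safe_load(_DEFAULT_RULES_YAML)


def _rules_from(entries: list[dict]) -> list[ConversionRule]:
    return [
        ConversionRule(source_pattern=e["pattern"], bindings=dict(e["bindings"]), constructor=e["constructor"])
        for e in entries
    ]


def default_xml_rules() -> list[ConversionRule]:
    """The shipped ruleset for the document dialect (all statement kinds)."""
    return _rules_from(_DEFAULTS["xml"])


def default_relational_rules() -> list[ConversionRule]:
    return _rules_from(_DEFAULTS["relational"])


def load_rules(path: str | Path) -> dict[str, list[ConversionRule]]:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return {k: _rules_from(v) for k, v in d.items()}


# ---------------------------------------------------------------------------
# Rule application: document dialect
# ---------------------------------------------------------------------------


@dataclass
class ResidueReport:
    """Unconverted source content: counts plus the paths left behind."""

    unmatched_nodes: int = 0
    paths: list[str] = field(default_factory=list)
    findings: list[Finding] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "unmatched_nodes": self.unmatched_nodes,
                "paths": sorted(self.paths),
                "findings": [{"severity": f.severity, "path": f.path, "message": f.message} for f in self.findings],
            },
            sort_keys=True,
            indent=2,
        )


def _parse_segment(seg: str) -> tuple[str, dict[str, str]]:
    if "[" in seg:
        name, rest = seg.split("[", 1)
        preds = {}
        for clause in rest.rstrip("]").split(","):
            k, v = clause.split("=", 1)
            preds[k.strip()] = v.strip()
        return name, preds
    return seg, {}


def _match_pattern(g: NodeGraph, pattern: str) -> list[list[str]]:
    """Node chains (excluding the root) matching the path pattern."""
    segments = [_parse_segment(s) for s in pattern.split("/")]
    chains: list[list[str]] = [[]]
    frontier = [g.root]
    # breadth-wise match: each segment advances every live chain
    live: list[tuple[str, list[str]]] = [(g.root, [])]
    for name, preds in segments:
        nxt: list[tuple[str, list[str]]] = []
        for node, chain in live:
            for cname, child in g.children(node):
                if cname != name:
                    continue
                attrs = g.attrs(child)
                if all(attrs.get(k) == v for k, v in preds.items()):
                    nxt.append((child, chain + [child]))
        live = nxt
    return [chain for _, chain in live]


def _resolve_binding(g: NodeGraph, node: str, path: str) -> Optional[str]:
    """Resolve ``code/@code``-style relative literal paths."""
    if path.startswith("@"):
        return g.attrs(node).get(path[1:])
    if path == "#text":
        return g.text(node)
    head, _, rest = path.partition("/")
    for cname, child in g.children(node):
        if cname == head:
            got = _resolve_binding(g, child, rest)
            if got is not None:
                return got
    return None


def _parse_source_date(raw: Optional[str], path: str, findings: list[Finding]) -> Optional[dt.date]:
    """YYYYMMDD or ISO; unparseable -> None plus a finding, never dropped."""
    if raw is None or raw == "":
        return None
    s = str(raw)
    for fmt in ("%Y%m%d", "%Y-%m-%d"):
        try:
            return dt.datetime.strptime(s[:10].replace("T", " ")[: len(fmt) + 2], fmt).date()
        except ValueError:
            continue
    findings.append(Finding("warning", path, f"unparseable date {raw!r}; statement kept undated"))
    return None


def _assemble_statement(kind: str, vals: Mapping[str, Optional[str]], path: str, findings: list[Finding]) -> ClinicalStatement:
    scheme = scheme_for_code_system(str(vals.get("code_system") or ""))
    code = CodedValue(scheme_id=scheme, code=str(vals.get("code") or ""), label=vals.get("label"))
    value: Optional[Quantity | CodedValue] = None
    if vals.get("value") not in (None, ""):
        value = Quantity(value=float(vals["value"]), unit=str(vals.get("unit") or ""))
    elif vals.get("value_code") not in (None, ""):
        value = CodedValue(scheme_id=scheme_for_code_system(str(vals.get("value_code_system") or "")), code=str(vals["value_code"]))
    if kind == "lab_result" and value is None:
        findings.append(Finding("warning", path, "lab_result without value"))
    return ClinicalStatement(
        kind=kind,
        code=code,
        effective_start=_parse_source_date(vals.get("start"), path + "/start", findings),
        effective_end=_parse_source_date(vals.get("end"), path + "/end", findings),
        value=value,
    )


def _statement_sort_key(s: ClinicalStatement):
    return (
        s.kind,
        s.code.scheme_id,
        s.code.code,
        s.effective_start.isoformat() if s.effective_start else "",
        s.effective_end.isoformat() if s.effective_end else "",
        repr(s.value),
    )


def canonicalize_records(records: Iterable[PatientRecord]) -> list[PatientRecord]:
    """Sort records by patient id and statements by a canonical key, so that
    outputs of different source paths compare structurally."""
    out = []
    for r in sorted(records, key=lambda r: r.patient_id):
        out.append(
            PatientRecord(
                patient_id=r.patient_id,
                birth_year=r.birth_year,
                gender=r.gender,
                country=r.country,
                statements=tuple(sorted(r.statements, key=_statement_sort_key)),
                extensions=r.extensions,
            )
        )
    return out


def apply_rules(
    graph: NodeGraph, rules: list[ConversionRule] | None = None
) -> tuple[list[PatientRecord], ResidueReport]:
    """Convert a formalized document into common-model records.

    Each pattern match emits exactly one statement or demographics
    assignment.  A patient is identified by the document-dialect convention
    that the chain's first segment below the root is the per-patient
    container element.  Unmatched content (elements not consumed by any
    rule and not ancestors of a consumed element) is reported as residue.
    """
    rules = rules if rules is not None else default_xml_rules()
    for r in rules:
        if r.source_pattern.startswith("table:"):
            raise MediationError(f"relational rule {r.source_pattern!r} applied to a document")

    demographics: dict[str, dict[str, str]] = {}
    statements: dict[str, list[ClinicalStatement]] = {}
    container_of: dict[str, str] = {}
    consumed: set[str] = {graph.root}
    findings: list[Finding] = []

    def consume_subtree(node: str) -> None:
        consumed.add(node)
        for _, child in graph.children(node):
            consume_subtree(child)

    for rule in rules:
        for chain in _match_pattern(graph, rule.source_pattern):
            node = chain[-1]
            container = chain[0]
            consumed.update(chain[:-1])
            consume_subtree(node)
            vals = {tgt: _resolve_binding(graph, node, src) for src, tgt in rule.bindings.items()}
            path = "/".join(seg for seg, _ in map(_parse_segment, rule.source_pattern.split("/")))
            if rule.constructor == "demographics":
                d = demographics.setdefault(container, {})
                for k, v in vals.items():
                    if v is None:
                        continue
                    if k in d and d[k] != v:
                        findings.append(Finding("error", path, f"conflicting demographic {k}: {d[k]!r} vs {v!r}"))
                    d[k] = v
            else:
                stmt = _assemble_statement(rule.constructor, vals, path, findings)
                statements.setdefault(container, []).append(stmt)
                container_of[node] = container

    records: list[PatientRecord] = []
    for container in sorted(set(demographics) | set(statements)):
        d = demographics.get(container, {})
        pid = d.get("patient_id")
        if not pid:
            findings.append(Finding("error", container, "patient container without patient_id; skipped"))
            continue
        by = d.get("birth_year")
        records.append(
            PatientRecord(
                patient_id=pid,
                birth_year=int(by) if by else None,
                gender=CodedValue("GENDER", d["gender"]) if d.get("gender") else None,
                country=CodedValue("COUNTRY", d["country"]) if d.get("country") else None,
                statements=tuple(statements.get(container, ())),
            )
        )

    residue = ResidueReport(findings=findings)
    paths = _unconsumed_paths(graph, consumed)
    residue.unmatched_nodes = len(paths)
    residue.paths = paths
    return canonicalize_records(records), residue


def _unconsumed_paths(g: NodeGraph, consumed: set[str]) -> list[str]:
    out: list[str] = []

    def walk(node: str, path: str) -> None:
        for name, child in g.children(node):
            cpath = f"{path}/{name}"
            if child not in consumed:
                out.append(cpath)
            else:
                walk(child, cpath)

    walk(g.root, g.root_name)
    return out


# ---------------------------------------------------------------------------
# Relational dialect
# ---------------------------------------------------------------------------


def convert_relational(
    tables: Mapping[str, pd.DataFrame], rules: list[ConversionRule] | None = None
) -> tuple[list[PatientRecord], ResidueReport]:
    """Convert CSV tables to common-model records.

    ``patients`` is mandatory; statement tables are optional.  Rows whose
    ``patient_id`` does not join to ``patients`` are skipped with a finding
    (foreign-key violation), never converted into orphan statements.
    """
    rules = rules if rules is not None else default_relational_rules()
    if "patients" not in tables:
        raise MediationError("mandatory table 'patients' is missing")
    findings: list[Finding] = []
    residue = ResidueReport(findings=findings)

    demo_rule = next((r for r in rules if r.constructor == "demographics"), None)
    if demo_rule is None:
        raise MediationError("ruleset lacks a demographics rule")

    patients: dict[str, dict] = {}
    ptab = tables["patients"]
    for i, row in ptab.iterrows():
        vals = {tgt: row.get(src) for src, tgt in demo_rule.bindings.items()}
        pid = str(vals.get("patient_id") or "")
        if not pid:
            findings.append(Finding("error", f"patients[{i}]", "row without patient_id; skipped"))
            continue
        patients[pid] = vals

    statements: dict[str, list[ClinicalStatement]] = {p: [] for p in patients}
    handled_tables = {"patients"}
    for rule in rules:
        if rule.constructor == "demographics" or not rule.source_pattern.startswith("table:"):
            continue
        tname = rule.source_pattern.split(":", 1)[1]
        if tname not in tables:
            continue
        handled_tables.add(tname)
        for i, row in tables[tname].iterrows():
            raw = {tgt: row.get(src) for src, tgt in rule.bindings.items()}
            pid = str(raw.pop("patient_id", "") or "")
            if pid not in patients:
                findings.append(Finding("warning", f"{tname}[{i}]", f"dangling patient_id {pid!r}; row skipped"))
                continue
            vals = {k: (None if pd.isna(v) else str(v)) if not isinstance(v, str) else v for k, v in raw.items()}
            statements[pid].append(_assemble_statement(rule.constructor, vals, f"{tname}[{i}]", findings))

    for tname in tables:
        if tname not in handled_tables:
            residue.paths.append(f"table:{tname}")
            residue.unmatched_nodes += len(tables[tname])

    records = []
    for pid in sorted(patients):
        d = patients[pid]
        by = d.get("birth_year")
        records.append(
            PatientRecord(
                patient_id=pid,
                birth_year=int(by) if by is not None and not pd.isna(by) else None,
                gender=CodedValue("GENDER", str(d["gender"])) if d.get("gender") is not None and not pd.isna(d.get("gender")) else None,
                country=CodedValue("COUNTRY", str(d["country"])) if d.get("country") is not None and not pd.isna(d.get("country")) else None,
                statements=tuple(statements.get(pid, ())),
            )
        )
    return canonicalize_records(records), residue


def read_relational_dir(path: str | Path) -> dict[str, pd.DataFrame]:
    """Read all ``<table>.csv`` files of a relational-dialect directory."""
    path = Path(path)
    tables = {}
    for f in sorted(path.glob("*.csv")):
        tables[f.stem] = pd.read_csv(f, dtype=str)
    return tables
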