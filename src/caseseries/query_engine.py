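"""Eligibility-query localization, temporal evaluation and aggregation.

The analyst writes criteria in a research terminology; each source codes its
data in its own care terminology.  :func:`localize_query` rewrites every
query leaf into the source's scheme by close-match expansion plus descendant
closure — after which :func:`evaluate` is a purely local operation: a leaf
matches a patient iff some statement of the leaf's kind carries one of the
expanded codes (no hierarchy walk at evaluation time; expansion already did
it).

Temporal nodes implement the "reaction within N days after prescription"
pattern: a patient matches iff there exists a statement pair (anchor,
related) with the related statement's start date inside the inclusive
window.  Matching is existential — any qualifying pair suffices — and uses
``effective_start`` only (prescriptions are point events in the sources
modelled here).  Undated statements never satisfy a temporal constraint.

Multi-source results are merged by :func:`aggregate` with source-namespaced
patient ids, so counts add exactly and provenance survives.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

from .common_model import (
    Bool,
    ClinicalStatement,
    CodedValue,
    CriteriaNode,
    EligibilityQuery,
    Leaf,
    ModelError,
    PatientRecord,
    StudyDefinition,
    Temporal,
)
from .terminology import CloseMatchClosure, ConceptScheme, expand_query_codes

__all__ = [
    "LocalizedQuery",
    "Population",
    "DerivedConditionRule",
    "QueryConfigError",
    "localize_query",
    "evaluate",
    "matching_statements",
    "select_populations",
    "apply_derived_condition_rules",
    "aggregate",
    "SourceResult",
]


class QueryConfigError(Exception):
    """A query or study configuration cannot be executed as given."""


@dataclass(frozen=True)
class LocalizedQuery:
    """A query rewritten into one source's terminology.

    ``provenance`` maps each original (scheme, code) to the expanded code
    set it produced in the source scheme; ``unsatisfiable_codes`` lists
    originals whose expansion came back empty (their leaves match nothing).
    """

    source_id: str
    query: EligibilityQuery
    provenance: Mapping[tuple[str, str], frozenset[str]]
    unsatisfiable_codes: frozenset[tuple[str, str]]


@dataclass(frozen=True)
class Population:
    source_id: str
    patient_ids: frozenset[str]
    label: str  # "foreground" | "background"


def localize_query(
    query: EligibilityQuery,
    source_id: str,
    source_schemes: Mapping[str, str],
    closure: CloseMatchClosure,
    terminologies: Mapping[str, ConceptScheme],
) -> LocalizedQuery:
    """Expand every leaf's codes into the source's terminology.

    ``source_schemes`` maps statement kind -> the scheme the source uses for
    that kind; a kind with no declared scheme is a configuration error.
    """
    provenance: dict[tuple[str, str], frozenset[str]] = {}
    unsat: set[tuple[str, str]] = set()

    def rewrite(node: CriteriaNode) -> CriteriaNode:
        if isinstance(node, Leaf):
            scheme = source_schemes.get(node.kind)
            if scheme is None:
                raise QueryConfigError(f"source {source_id!r} declares no scheme for kind {node.kind!r}")
            expanded: set[str] = set()
            for cv in node.codes:
                codes = frozenset(expand_query_codes(cv.ref, scheme, closure, terminologies))
                provenance[cv.ref] = codes
                if not codes:
                    unsat.add(cv.ref)
                expanded |= codes
            return Leaf(kind=node.kind, codes=frozenset(CodedValue(scheme, c) for c in sorted(expanded)), negated=node.negated)
        if isinstance(node, Bool):
            return Bool(node.op, tuple(rewrite(c) for c in node.children))
        return Temporal(rewrite(node.anchor), rewrite(node.related), node.direction, node.window_days)

    return LocalizedQuery(
        source_id=source_id,
        query=EligibilityQuery(rewrite(query.root)),
        provenance=provenance,
        unsatisfiable_codes=frozenset(unsat),
    )


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def _leaves_under(node: CriteriaNode) -> list[Leaf]:
    """Statement-matching leaves of a Temporal child: Leaf or OR-of-Leaf only.

    AND under a Temporal node has no statement-pair semantics and is
    rejected up front.
    """
    if isinstance(node, Leaf):
        if node.negated:
            raise QueryConfigError("negated leaves cannot anchor a temporal constraint")
        return [node]
    if isinstance(node, Bool) and node.op == "OR":
        out: list[Leaf] = []
        for c in node.children:
            out.extend(_leaves_under(c))
        return out
    raise QueryConfigError("temporal anchor/related must be a Leaf or an OR of Leaves")


def matching_statements(record: PatientRecord, node: CriteriaNode) -> list[ClinicalStatement]:
    """Statements of ``record`` matching a Leaf/OR-of-Leaf criterion."""
    leaves = _leaves_under(node)
    out = []
    for s in record.statements:
        for leaf in leaves:
            if s.kind == leaf.kind and any(s.code.scheme_id == c.scheme_id and s.code.code == c.code for c in leaf.codes):
                out.append(s)
                break
    return out


def _window_ok(anchor: dt.date, related: dt.date, direction: str, window: int) -> bool:
    delta = (related - anchor).days
    if direction == "after":
        return 0 <= delta <= window
    if direction == "before":
        return -window <= delta <= 0
    return abs(delta) <= window


def _matches(record: PatientRecord, node: CriteriaNode) -> bool:
    if isinstance(node, Leaf):
        hit = bool(matching_statements(record, Leaf(node.kind, node.codes)))
        return (not hit) if node.negated else hit
    if isinstance(node, Bool):
        results = (_matches(record, c) for c in node.children)
        return all(results) if node.op == "AND" else any(results)
    anchors = [s for s in matching_statements(record, node.anchor) if s.effective_start]
    relateds = [s for s in matching_statements(record, node.related) if s.effective_start]
    return any(
        _window_ok(a.effective_start, r.effective_start, node.direction, node.window_days)
        for a in anchors
        for r in relateds
    )


def evaluate(query: EligibilityQuery, records: Iterable[PatientRecord]) -> set[str]:
    """Patient ids matching the query.  Expansion is assumed done; no
    hierarchy closure is applied here."""
    return {r.patient_id for r in records if _matches(r, query.root)}


def select_populations(
    study: StudyDefinition, records: list[PatientRecord], source_id: str = "local"
) -> tuple[Population, Population]:
    """Evaluate foreground and background queries over one record set.

    When the foreground is the background plus extra criteria (the usual
    case-series pattern), fg ⊆ bg holds by construction; it is asserted here
    as a guard against localization inconsistencies.
    """
    fg_ids = evaluate(study.foreground, records)
    bg_ids = evaluate(study.background, records)
    if _foreground_refines_background(study) and not fg_ids <= bg_ids:
        raise QueryConfigError("foreground refines background but fg ⊄ bg; inconsistent localization")
    ns = lambda ids: frozenset(f"{source_id}:{p}" for p in ids)
    return (
        Population(source_id, ns(fg_ids), "foreground"),
        Population(source_id, ns(bg_ids), "background"),
    )


def _foreground_refines_background(study: StudyDefinition) -> bool:
    """True when fg = AND(bg, ...): the background root appears among the
    foreground AND-children (structural check only)."""
    fg, bg = study.foreground.root, study.background.root
    return isinstance(fg, Bool) and fg.op == "AND" and bg in fg.children


# ---------------------------------------------------------------------------
# Derived-condition rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DerivedConditionRule:
    """Infer a condition from indirect evidence when it is not recorded.

    The classic example: flag diabetes from age, an antidiabetic medication
    (metformin-like), and an elevated glycosylated-haemoglobin lab value.
    All configured criteria must hold (conjunction); the inferred statement
    is dated at the earliest supporting evidence and flagged ``derived``.
    """

    inferred_code: CodedValue
    medication_codes: frozenset[CodedValue] = frozenset()
    lab_code: Optional[CodedValue] = None
    lab_threshold: Optional[float] = None
    min_age: Optional[int] = None
    reference_year: Optional[int] = None

    def evidence(self, record: PatientRecord) -> Optional[dt.date]:
        """Earliest supporting evidence date, or None when the rule fails."""
        dates: list[dt.date] = []
        if self.min_age is not None:
            ref = self.reference_year or dt.date.today().year
            if record.birth_year is None or ref - record.birth_year < self.min_age:
                return None
        if self.medication_codes:
            meds = [
                s
                for s in record.statements
                if s.kind == "medication" and any(s.code.ref == c.ref for c in self.medication_codes)
            ]
            if not meds:
                return None
            dates += [s.effective_start for s in meds if s.effective_start]
        if self.lab_code is not None:
            from .common_model import Quantity

            labs = [
                s
                for s in record.statements
                if s.kind == "lab_result"
                and s.code.ref == self.lab_code.ref
                and isinstance(s.value, Quantity)
                and (self.lab_threshold is None or s.value.value >= self.lab_threshold)
            ]
            if not labs:
                return None
            dates += [s.effective_start for s in labs if s.effective_start]
        return min(dates) if dates else None


def apply_derived_condition_rules(
    records: list[PatientRecord],
    rules: list[DerivedConditionRule],
    terminologies: Mapping[str, ConceptScheme] | None = None,
) -> list[PatientRecord]:
    """Add inferred condition statements; idempotent.

    A rule does not fire when the patient already carries the inferred code
    (recorded or previously derived), so re-application is a no-op.
    """
    if terminologies is not None:
        for rule in rules:
            if rule.inferred_code.scheme_id not in terminologies:
                raise QueryConfigError(
                    f"derived-condition rule targets unknown scheme {rule.inferred_code.scheme_id!r}"
                )
    out = []
    for r in records:
        new: list[ClinicalStatement] = []
        for rule in rules:
            already = any(s.kind == "condition" and s.code.ref == rule.inferred_code.ref for s in r.statements)
            if already:
                continue
            date = rule.evidence(r)
            if date is not None:
                new.append(
                    ClinicalStatement(kind="condition", code=rule.inferred_code, effective_start=date, derived=True)
                )
        out.append(replace(r, statements=r.statements + tuple(new)) if new else r)
    return out


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SourceResult:
    """One source's contribution: mediated records plus selected populations."""

    source_id: str
    records: tuple[PatientRecord, ...]
    foreground: Population
    background: Population


def aggregate(sources: list[SourceResult]) -> tuple[list[PatientRecord], Population, Population]:
    """Union the per-source results with namespaced patient ids.

    Source ids must be distinct; counts add exactly because namespacing makes
    the per-source id sets disjoint.
    """
    ids = [s.source_id for s in sources]
    if len(set(ids)) != len(ids):
        raise QueryConfigError(f"duplicate source ids in aggregation: {ids}")
    for s in sources:
        for pop in (s.foreground, s.background):
            bad = [p for p in pop.patient_ids if not p.startswith(f"{s.source_id}:")]
            if bad:
                raise QueryConfigError(
                    f"population ids of source {s.source_id!r} are not namespaced "
                    f"'{s.source_id}:<id>' (e.g. {bad[0]!r}); select populations with "
                    f"the matching source_id"
                )
    records: list[PatientRecord] = []
    fg: set[str] = set()
    bg: set[str] = set()
    for s in sources:
        for r in s.records:
            nsid = f"{s.source_id}:{r.patient_id}"
            records.append(replace(r, patient_id=nsid, extensions={**dict(r.extensions), "source_id": s.source_id}))
        fg |= s.foreground.patient_ids
        bg |= s.background.patient_ids
    return (
        records,
        Population("merged", frozenset(fg), "foreground"),
        Population("merged", frozenset(bg), "background"),
    )
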