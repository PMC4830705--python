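"""Comparative foreground/background characterization of a case series.

Given the two selected populations (patients with the drug and the event
inside the window, vs. all patients with the drug), this module computes the
statistics boxes a safety analyst reads side by side: demographics (age
bands, gender, country), the common conditions/medications — grouped under
the analyst's preferred terminology level — overall and strictly before or
after each patient's index date, and the prevalence of configured risk
factors (possible confounders) in both populations.

Counts are PATIENT counts: a patient with three conditions in one group
contributes 1, so rates are population-comparable.  An event-level tally is
carried alongside in the JSON for transparency.  Rates and the
foreground-share percentage are rounded half-up to two decimals.  Codes with
no route into the grouping scheme land in the reserved UNMAPPED group rather
than disappearing — silent loss is unacceptable in a safety analysis.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional

from .common_model import CodedValue, CriteriaNode, PatientRecord, StudyDefinition
from .query_engine import Population, matching_statements
from .terminology import UNMAPPED, CloseMatchClosure, ClosureLink, ConceptScheme, expand_query_codes

__all__ = [
    "StatRow",
    "StatBox",
    "ComparativeReport",
    "proportion",
    "rate",
    "enrich_codes",
    "demographics_box",
    "common_items_box",
    "risk_factor_box",
    "build_report",
]


def _round2(x: float) -> float:
    """Round half-up to 2 decimals (printed-percentage convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def proportion(fg_size: int, bg_size: int) -> Optional[float]:
    """Foreground share of the background, as a printed percentage.

    ``proportion(108, 34773) == 0.31``; undefined (None) for an empty
    background.
    """
    if bg_size <= 0:
        return None
    return _round2(100.0 * fg_size / bg_size)


def rate(count: int, denominator: int) -> float:
    if denominator <= 0:
        return 0.0
    return _round2(100.0 * count / denominator)


# ---------------------------------------------------------------------------
# Report containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StatRow:
    label: str
    code: str
    fg_count: int
    fg_rate: float
    bg_count: int
    bg_rate: float
    fg_events: Optional[int] = None
    bg_events: Optional[int] = None


@dataclass(frozen=True)
class StatBox:
    kind: str  # age | gender | country | common_items | risk_factor
    title: str
    rows: tuple[StatRow, ...]
    fg_denominator: int
    bg_denominator: int
    grouping: Optional[tuple[str, str]] = None  # (scheme, level) when coded
    scope: Optional[str] = None  # overall | before_index | after_index

    def __post_init__(self) -> None:
        for r in self.rows:
            assert r.fg_count <= self.fg_denominator or self.fg_denominator == 0
            assert r.bg_count <= self.bg_denominator or self.bg_denominator == 0


@dataclass(frozen=True)
class ComparativeReport:
    study_name: str
    fg_size: int
    bg_size: int
    fg_share_pct: Optional[float]
    boxes: tuple[StatBox, ...]

    def to_dict(self) -> dict:
        return {
            "study": self.study_name,
            "fg_size": self.fg_size,
            "bg_size": self.bg_size,
            "fg_share_pct": self.fg_share_pct,
            "boxes": [
                {
                    "kind": b.kind,
                    "title": b.title,
                    "scope": b.scope,
                    "grouping": list(b.grouping) if b.grouping else None,
                    "fg_denominator": b.fg_denominator,
                    "bg_denominator": b.bg_denominator,
                    "rows": [
                        {
                            "label": r.label,
                            "code": r.code,
                            "fg_count": r.fg_count,
                            "fg_rate": r.fg_rate,
                            "bg_count": r.bg_count,
                            "bg_rate": r.bg_rate,
                            "fg_events": r.fg_events,
                            "bg_events": r.bg_events,
                        }
                        for r in b.rows
                    ],
                }
                for b in self.boxes
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)

    def box_csv(self, box: StatBox) -> str:
        lines = ["label,code,fg_count,fg_rate,bg_count,bg_rate"]
        for r in box.rows:
            lines.append(f"{r.label},{r.code},{r.fg_count},{r.fg_rate},{r.bg_count},{r.bg_rate}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------


def enrich_codes(
    records: Iterable[PatientRecord],
    grouping: Mapping[str, tuple[str, str]],
    group_links: set[ClosureLink],
) -> list[PatientRecord]:
    """Annotate each coded statement with its group code(s) or UNMAPPED.

    Original codes are untouched; a multiaxial code keeps every group it
    reaches.  Only kinds present in ``grouping`` are annotated.
    """
    index: dict[tuple[str, str], set[str]] = {}
    for l in group_links:
        index.setdefault(l.a, set()).add(l.b[1])
    out = []
    for r in records:
        stmts = []
        for s in r.statements:
            if s.kind in grouping:
                groups = index.get(s.code.ref)
                stmts.append(replace(s, groups=frozenset(groups) if groups else frozenset({UNMAPPED})))
            else:
                stmts.append(s)
        out.append(replace(r, statements=tuple(stmts)))
    return out


# ---------------------------------------------------------------------------
# Boxes
# ---------------------------------------------------------------------------


def _split(records: Iterable[PatientRecord], fg: Population, bg: Population):
    by_id = {r.patient_id: r for r in records}
    fg_recs = [by_id[p] for p in sorted(fg.patient_ids) if p in by_id]
    bg_recs = [by_id[p] for p in sorted(bg.patient_ids) if p in by_id]
    return fg_recs, bg_recs


def _sorted_rows(rows: list[StatRow]) -> tuple[StatRow, ...]:
    return tuple(sorted(rows, key=lambda r: (-r.fg_rate, r.code)))


_UNKNOWN = "UNKNOWN"


def demographics_box(
    fg_records: list[PatientRecord],
    bg_records: list[PatientRecord],
    kind: str,
    reference_date: dt.date,
    age_band_years: int = 10,
) -> StatBox:
    """Tally age bands (decades by default), gender or country codes.

    Age is ``reference_year - birth_year``; missing demographics fall into
    an UNKNOWN row rather than shrinking the denominator.
    """

    def bucket(r: PatientRecord) -> str:
        if kind == "age":
            if r.birth_year is None:
                return _UNKNOWN
            age = reference_date.year - r.birth_year
            lo = (age // age_band_years) * age_band_years
            return f"{lo:02d}-{lo + age_band_years - 1:02d}"
        cv = r.gender if kind == "gender" else r.country
        return cv.code if cv else _UNKNOWN

    def tally(recs: list[PatientRecord]) -> dict[str, int]:
        d: dict[str, int] = {}
        for r in recs:
            b = bucket(r)
            d[b] = d.get(b, 0) + 1
        return d

    fg_t, bg_t = tally(fg_records), tally(bg_records)
    rows = [
        StatRow(
            label=key,
            code=key,
            fg_count=fg_t.get(key, 0),
            fg_rate=rate(fg_t.get(key, 0), len(fg_records)),
            bg_count=bg_t.get(key, 0),
            bg_rate=rate(bg_t.get(key, 0), len(bg_records)),
        )
        for key in sorted(set(fg_t) | set(bg_t))
    ]
    return StatBox(
        kind=kind,
        title=kind,
        rows=_sorted_rows(rows),
        fg_denominator=len(fg_records),
        bg_denominator=len(bg_records),
    )


def _index_date(record: PatientRecord, index_anchor: CriteriaNode) -> Optional[dt.date]:
    dates = [s.effective_start for s in matching_statements(record, index_anchor) if s.effective_start]
    return min(dates) if dates else None


def common_items_box(
    fg_records: list[PatientRecord],
    bg_records: list[PatientRecord],
    kind: str,
    grouping: tuple[str, str],
    scope: str = "overall",
    index_anchor: Optional[CriteriaNode] = None,
    window_days: Optional[int] = None,
    labels: Mapping[str, str] | None = None,
) -> StatBox:
    """Patient-level tally of grouped statements of one kind.

    ``scope`` restricts statements to strictly before / strictly after the
    patient's index date (earliest statement matching ``index_anchor``),
    optionally within ``window_days``.  Index-day events belong to neither
    side — they appear only in the overall box.  Patients without an index
    date are excluded from before/after denominators (the reported
    denominator reflects that).
    """
    if scope not in ("overall", "before_index", "after_index"):
        raise ValueError(f"unknown scope {scope!r}")
    if scope != "overall" and index_anchor is None:
        raise ValueError("before/after scope requires an index_anchor")

    def tally(recs: list[PatientRecord]) -> tuple[dict[str, int], dict[str, int], int]:
        patients: dict[str, int] = {}
        events: dict[str, int] = {}
        denom = 0
        for r in recs:
            idx: Optional[dt.date] = None
            if scope != "overall":
                idx = _index_date(r, index_anchor)
                if idx is None:
                    continue
            denom += 1
            seen: set[str] = set()
            for s in r.statements:
                if s.kind != kind or s.groups is None:
                    continue
                if scope != "overall":
                    d = s.effective_start
                    if d is None or d == idx:
                        continue
                    if scope == "before_index" and not (d < idx and (window_days is None or (idx - d).days <= window_days)):
                        continue
                    if scope == "after_index" and not (d > idx and (window_days is None or (d - idx).days <= window_days)):
                        continue
                for g in s.groups:
                    events[g] = events.get(g, 0) + 1
                    seen.add(g)
            for g in seen:
                patients[g] = patients.get(g, 0) + 1
        return patients, events, denom

    fg_p, fg_e, fg_n = tally(fg_records)
    bg_p, bg_e, bg_n = tally(bg_records)
    labels = labels or {}
    rows = [
        StatRow(
            label=labels.get(g, g),
            code=g,
            fg_count=fg_p.get(g, 0),
            fg_rate=rate(fg_p.get(g, 0), fg_n),
            bg_count=bg_p.get(g, 0),
            bg_rate=rate(bg_p.get(g, 0), bg_n),
            fg_events=fg_e.get(g, 0),
            bg_events=bg_e.get(g, 0),
        )
        for g in sorted(set(fg_p) | set(bg_p))
    ]
    return StatBox(
        kind="common_items",
        title=f"common {kind}s ({scope})",
        rows=_sorted_rows(rows),
        fg_denominator=fg_n,
        bg_denominator=bg_n,
        grouping=grouping,
        scope=scope,
    )


def risk_factor_box(
    fg_records: list[PatientRecord],
    bg_records: list[PatientRecord],
    risk_factors: Iterable[CodedValue],
    closure: CloseMatchClosure,
    terminologies: Mapping[str, ConceptScheme],
) -> StatBox:
    """Patient-level prevalence of each configured risk factor.

    Risk codes live in the analyst's scheme; matching expands each code into
    every scheme actually present on the records, so source-coded (and
    derived) statements are hit.
    """
    all_records = fg_records + bg_records
    schemes_present = sorted({s.code.scheme_id for r in all_records for s in r.statements})

    def match_set(cv: CodedValue) -> set[tuple[str, str]]:
        refs: set[tuple[str, str]] = set()
        for sch in schemes_present:
            if sch not in terminologies:
                continue
            for code in expand_query_codes(cv.ref, sch, closure, terminologies):
                refs.add((sch, code))
        return refs

    rows = []
    for cv in sorted(risk_factors, key=lambda c: (c.scheme_id, c.code)):
        refs = match_set(cv)
        fg_c = sum(1 for r in fg_records if any(s.code.ref in refs for s in r.statements))
        bg_c = sum(1 for r in bg_records if any(s.code.ref in refs for s in r.statements))
        rows.append(
            StatRow(
                label=cv.label or cv.code,
                code=cv.code,
                fg_count=fg_c,
                fg_rate=rate(fg_c, len(fg_records)),
                bg_count=bg_c,
                bg_rate=rate(bg_c, len(bg_records)),
            )
        )
    return StatBox(
        kind="risk_factor",
        title="risk factors",
        rows=_sorted_rows(rows),
        fg_denominator=len(fg_records),
        bg_denominator=len(bg_records),
    )


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------


def build_report(
    study: StudyDefinition,
    fg: Population,
    bg: Population,
    records: list[PatientRecord],
    closure: Optional[CloseMatchClosure] = None,
    terminologies: Optional[Mapping[str, ConceptScheme]] = None,
    reference_date: Optional[dt.date] = None,
    labels: Mapping[str, str] | None = None,
) -> ComparativeReport:
    """Assemble every requested statistics box; deterministic given inputs.

    Expects ``records`` already enriched (:func:`enrich_codes`) when coded
    boxes are requested.  ``reference_date`` anchors age computation (default:
    the latest statement date in the record set, keeping the report a pure
    function of its inputs).
    """
    fg_recs, bg_recs = _split(records, fg, bg)
    if reference_date is None:
        dates = [s.effective_start for r in records for s in r.statements if s.effective_start]
        reference_date = max(dates) if dates else dt.date(2000, 1, 1)

    boxes: list[StatBox] = []
    for stat in study.statistics:
        if stat in ("age", "gender", "country"):
            boxes.append(demographics_box(fg_recs, bg_recs, stat, reference_date))
        elif stat in ("common_conditions", "common_medications"):
            kind = "condition" if stat == "common_conditions" else "medication"
            if kind not in study.grouping:
                continue
            scopes = ["overall"]
            if study.index_anchor is not None:
                scopes += ["before_index", "after_index"]
            for scope in scopes:
                boxes.append(
                    common_items_box(
                        fg_recs,
                        bg_recs,
                        kind,
                        study.grouping[kind],
                        scope=scope,
                        index_anchor=study.index_anchor,
                        window_days=study.before_after_window_days,
                        labels=labels,
                    )
                )
        elif stat == "risk_factors":
            if study.risk_factors and closure is not None and terminologies is not None:
                boxes.append(risk_factor_box(fg_recs, bg_recs, study.risk_factors, closure, terminologies))
        else:
            raise ValueError(f"unknown statistics box {stat!r}")

    return ComparativeReport(
        study_name=study.name,
        fg_size=len(fg.patient_ids),
        bg_size=len(bg.patient_ids),
        fg_share_pct=proportion(len(fg.patient_ids), len(bg.patient_ids)),
        boxes=tuple(boxes),
    )
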