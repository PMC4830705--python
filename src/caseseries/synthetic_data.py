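"""Synthetic terminologies, mappings and cohorts with known ground truth.

Licensed vocabularies (MedDRA, SNOMED-CT, ICD) and real EHR extracts cannot
ship with the package, so every pipeline stage is exercised against
structurally analogous synthetic material:

* a **research scheme** (``RSRCH``) with four named levels
  (SOC > HLGT > HLT > PT), multiaxial at a configurable rate — the scheme
  the analyst writes queries and groupings in;
* a flat **pivot scheme** (``PIVOT``) standing between care and research
  vocabularies, as a SNOMED-like pivot does in curated mapping sets;
* two **care schemes** (``CARE_A``, ``CARE_B``) with their own 3-level
  hierarchies — what the sources actually code in;
* a **drug scheme** (``DRUG``, group > substance) plus a same-code care
  variant (``DRUG_A``) linked by identical-code assertions;
* mapping assertions in three relation tags (``protect_like`` research->pivot,
  ``omop_like`` care_a->pivot, ``crossmap_like`` pivot->care_b), so a care
  code only reaches its research group through multi-hop close-match
  closure — the topology materialization exists to flatten.

The cohort generator emulates the statistical structure a case-series
characterization study assumes: a drug-exposed background population, a
windowed drug-reaction model (probability ``p_w`` of a reaction within
``W`` days after a prescription for exposed patients, baseline rate
``p_bg`` for anyone), injected confounder prevalences that differ between
reactors and non-reactors, and demographic mixes.  Every draw derives from
per-concern RNG streams split off the master seed, so outputs are
byte-identical under a fixed seed and changing one concern leaves the
others' draws untouched.  Alongside the records the generator emits a
ground-truth table (true exposure and foreground membership per patient)
for oracle use in tests.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lxml import etree

from .common_model import ClinicalStatement, CodedValue, PatientRecord, Quantity
from .mediation import code_system_for_scheme
from .terminology import UNMAPPED, Concept, ConceptScheme, MappingAssertion

__all__ = [
    "GeneratorSpec",
    "TerminologyBundle",
    "generate_terminologies",
    "generate_cohort",
    "translate_records",
    "emit_source_dialects",
    "analytic_foreground_proportion",
    "OBSERVATION_START",
]

#: First day of the 10-year observation span all generated dates fall in.
OBSERVATION_START = dt.date(2005, 1, 1)


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for one synthetic build.

    Defaults encode the reference scenario the engine is tested under: a
    30%-exposed cohort, a 120-day reaction window with ``p_w = 0.05``
    against a baseline ``p_bg = 0.005``, a confounder more prevalent among
    reactors (25% vs 10%), and a 10-year observation span.
    """

    seed: int = 0
    n_patients: int = 2000
    # terminology shape
    research_branching: tuple[int, ...] = (3, 3, 3, 3)  # SOC, HLGT per SOC, HLT per HLGT, PT per HLT
    care_chapters: int = 3
    care_categories: int = 9
    drug_branching: tuple[int, int] = (4, 5)
    multiaxial_fraction: float = 0.10
    mapping_consistency: float = 1.0
    # exposure and reaction model
    exposure_prob: float = 0.30
    p_w: float = 0.05
    p_bg: float = 0.005
    window_days: int = 120
    span_days: int = 3650
    # confounder: (prevalence among reactors, among non-reactors)
    confounder_prev_reactors: float = 0.25
    confounder_prev_nonreactors: float = 0.10
    # demographics
    gender_split: Mapping[str, float] = field(default_factory=lambda: {"M": 0.5, "F": 0.5})
    birth_year_range: tuple[int, int] = (1930, 2000)
    country_dist: Mapping[str, float] = field(default_factory=lambda: {"IT": 0.5, "DE": 0.4, "XX": 0.1})
    # background noise
    noise_conditions_mean: float = 2.0
    noise_medications_mean: float = 1.0
    lab_prob: float = 0.2

    def __post_init__(self) -> None:
        for p in (self.multiaxial_fraction, self.mapping_consistency, self.exposure_prob, self.p_w, self.p_bg, self.lab_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1]: {p}")
        if self.window_days < 0 or self.span_days <= self.window_days:
            raise ValueError("need 0 <= window_days < span_days")
        if any(b < 1 for b in self.research_branching) or any(b < 1 for b in self.drug_branching):
            raise ValueError("branching factors must be >= 1")
        if len(self.research_branching) < 3:
            raise ValueError("research scheme needs >= 3 levels (grouping level + leaf level)")


def _rng(spec: GeneratorSpec, concern: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, concern])


RESEARCH, PIVOT, CARE_A, CARE_B, DRUG, DRUG_A, LAB = (
    "RSRCH",
    "PIVOT",
    "CARE_A",
    "CARE_B",
    "DRUG",
    "DRUG_A",
    "LAB",
)


@dataclass
class TerminologyBundle:
    """Generated schemes plus the ground truth tests compare against."""

    schemes: dict[str, ConceptScheme]
    assertions: list[MappingAssertion]
    research_scheme: str
    care_condition_schemes: dict[str, str]  # source variant -> scheme_id
    drug_scheme: str
    care_drug_scheme: str
    lab_scheme: str
    #: care (scheme, code) -> research HLGT group codes ({UNMAPPED} when the
    #: mapping chain was deliberately broken)
    ground_truth_groups: dict[tuple[str, str], frozenset[str]]
    #: research PT code -> care leaf code, per care scheme
    research_to_care: dict[str, dict[str, str]]
    #: research PT codes whose mapping chain is intact
    mapped_pts: frozenset[str]
    #: designated codes of the reference scenario
    reaction_pt: str
    confounder_pt: str
    drug_of_interest: str
    lab_code: str

    @property
    def source_schemes(self) -> dict[str, dict[str, str]]:
        """Per care variant: statement kind -> scheme the source codes in."""
        return {
            variant: {
                "condition": scheme,
                "medication": self.care_drug_scheme,
                "lab_result": self.lab_scheme,
                "procedure": scheme,
                "allergy": scheme,
            }
            for variant, scheme in self.care_condition_schemes.items()
        }

    @property
    def analyst_schemes(self) -> dict[str, str]:
        return {
            "condition": self.research_scheme,
            "medication": self.drug_scheme,
            "lab_result": self.lab_scheme,
            "procedure": self.research_scheme,
            "allergy": self.research_scheme,
        }


def _build_tree(scheme_id: str, level_names: Sequence[str], branching: Sequence[int], prefix: str) -> list[Concept]:
    """Balanced multi-root tree: branching[0] roots, then branching[i]
    children per node at depth i."""
    concepts: list[Concept] = []
    frontier: list[tuple[str, Optional[str]]] = [(f"{prefix}{i + 1}", None) for i in range(branching[0])]
    for depth, level in enumerate(level_names):
        nxt: list[tuple[str, Optional[str]]] = []
        for code, parent in frontier:
            concepts.append(
                Concept(
                    code=code,
                    scheme_id=scheme_id,
                    label=f"{scheme_id} {level} {code}",
                    level=level,
                    broader=frozenset([parent] if parent else []),
                )
            )
            if depth + 1 < len(level_names):
                for j in range(branching[depth + 1]):
                    nxt.append((f"{code}.{j + 1}", code))
        frontier = nxt
    return concepts


def generate_terminologies(spec: GeneratorSpec) -> TerminologyBundle:
    """Build all schemes, mapping assertions and the grouping ground truth."""
    rng = _rng(spec, 1)
    depth = len(spec.research_branching)
    if depth <= 4:
        # keep the MedDRA-style names; always end at PT, always include HLGT
        levels = ("SOC", "HLGT", "HLT", "PT")[-depth:]
    else:
        levels = ("SOC", "HLGT") + tuple(f"HLT{i}" for i in range(1, depth - 2)) + ("PT",)
    research_concepts = _build_tree(RESEARCH, levels, spec.research_branching, "R")
    by_code = {c.code: c for c in research_concepts}
    pts = sorted(c.code for c in research_concepts if c.level == "PT")
    hlts = sorted(c.code for c in research_concepts if c.level == levels[-2])

    # Multiaxiality: a fraction of PTs acquire a second HLT parent, giving
    # them a second HLGT group (as MedDRA PTs live on several axes).
    n_multi = int(round(spec.multiaxial_fraction * len(pts)))
    multi_pts = set(rng.choice(pts, size=n_multi, replace=False)) if n_multi else set()
    for code in sorted(multi_pts):
        own_parent = next(iter(by_code[code].broader))
        others = [h for h in hlts if h != own_parent]
        extra = str(rng.choice(others))
        by_code[code] = Concept(
            code=code, scheme_id=RESEARCH, label=by_code[code].label, level="PT",
            broader=by_code[code].broader | {extra},
        )
    research = ConceptScheme(RESEARCH, levels, by_code.values())

    # Pivot: one flat concept per research PT.
    pivot_codes = {pt: f"P{i + 1:04d}" for i, pt in enumerate(pts)}
    pivot = ConceptScheme(
        PIVOT, ("CONCEPT",),
        [Concept(code=c, scheme_id=PIVOT, label=f"pivot {c}", level="CONCEPT") for c in pivot_codes.values()],
    )

    # Care schemes: own 3-level hierarchies; one leaf per research PT,
    # assigned to categories independently of the research topology.
    def build_care(scheme_id: str, prefix: str, assign_rng: np.random.Generator) -> tuple[ConceptScheme, dict[str, str]]:
        concepts = []
        cat_codes = []
        per_chapter = max(1, spec.care_categories // spec.care_chapters)
        for ch in range(spec.care_chapters):
            ch_code = f"{prefix}{ch + 1}"
            concepts.append(Concept(ch_code, scheme_id, f"{scheme_id} chapter {ch_code}", "CHAPTER"))
            for k in range(per_chapter):
                cat = f"{ch_code}.{k + 1}"
                cat_codes.append(cat)
                concepts.append(Concept(cat, scheme_id, f"{scheme_id} category {cat}", "CATEGORY", frozenset([ch_code])))
        leaf_of: dict[str, str] = {}
        cat_assign = assign_rng.integers(0, len(cat_codes), size=len(pts))
        counters = {c: 0 for c in cat_codes}
        for pt, ci in zip(pts, cat_assign):
            cat = cat_codes[int(ci)]
            counters[cat] += 1
            leaf = f"{cat}.{counters[cat]}"
            concepts.append(Concept(leaf, scheme_id, f"{scheme_id} code {leaf}", "CODE", frozenset([cat])))
            leaf_of[pt] = leaf
        return ConceptScheme(scheme_id, ("CHAPTER", "CATEGORY", "CODE"), concepts), leaf_of

    care_a, a_leaf = build_care(CARE_A, "A", _rng(spec, 11))
    care_b, b_leaf = build_care(CARE_B, "B", _rng(spec, 12))

    # Drug scheme and its identical-code care variant.
    drug_levels = ("GROUP", "SUBSTANCE")
    drug_concepts = _build_tree(DRUG, drug_levels, spec.drug_branching, "D")
    drug = ConceptScheme(DRUG, drug_levels, drug_concepts)
    drug_a = ConceptScheme(
        DRUG_A, drug_levels,
        [Concept(c.code, DRUG_A, c.label.replace(DRUG, DRUG_A), c.level, c.broader) for c in drug_concepts],
    )
    substances = sorted(c.code for c in drug_concepts if c.level == "SUBSTANCE")

    lab = ConceptScheme(LAB, ("TEST",), [Concept("L1", LAB, "glycated haemoglobin analogue", "TEST")])

    # Designated scenario codes; their mapping chains are always intact so
    # the reference query stays expressible in every source.
    reaction_pt = pts[0]
    confounder_pt = pts[1]
    protected = {reaction_pt, confounder_pt}

    n_mapped = int(round(spec.mapping_consistency * len(pts)))
    candidates = [p for p in pts if p not in protected]
    keep = set(protected)
    extra_needed = max(0, n_mapped - len(keep))
    if extra_needed:
        keep |= set(rng.choice(candidates, size=min(extra_needed, len(candidates)), replace=False))
    mapped_pts = frozenset(keep)

    assertions: list[MappingAssertion] = []
    for pt in pts:
        pv = pivot_codes[pt]
        assertions.append(MappingAssertion((CARE_A, a_leaf[pt]), (PIVOT, pv), "omop_like"))
        assertions.append(MappingAssertion((PIVOT, pv), (CARE_B, b_leaf[pt]), "crossmap_like"))
        if pt in mapped_pts:
            assertions.append(MappingAssertion((RESEARCH, pt), (PIVOT, pv), "protect_like"))
    for s in substances:
        assertions.append(MappingAssertion((DRUG, s), (DRUG_A, s), "identical_code"))

    # Ground-truth grouping of every care condition code at HLGT level.
    truth: dict[tuple[str, str], frozenset[str]] = {}
    for pt in pts:
        groups = frozenset(research.ancestors_at_level(pt, "HLGT")) if pt in mapped_pts else frozenset({UNMAPPED})
        truth[(CARE_A, a_leaf[pt])] = groups
        truth[(CARE_B, b_leaf[pt])] = groups

    schemes = {s.scheme_id: s for s in (research, pivot, care_a, care_b, drug, drug_a, lab)}
    return TerminologyBundle(
        schemes=schemes,
        assertions=assertions,
        research_scheme=RESEARCH,
        care_condition_schemes={"A": CARE_A, "B": CARE_B},
        drug_scheme=DRUG,
        care_drug_scheme=DRUG_A,
        lab_scheme=LAB,
        ground_truth_groups=truth,
        research_to_care={CARE_A: a_leaf, CARE_B: b_leaf},
        mapped_pts=mapped_pts,
        reaction_pt=reaction_pt,
        confounder_pt=confounder_pt,
        drug_of_interest=substances[0],
        lab_code="L1",
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def _day(offset: int) -> dt.date:
    return OBSERVATION_START + dt.timedelta(days=int(offset))


def generate_cohort(spec: GeneratorSpec, bundle: TerminologyBundle) -> tuple[list[PatientRecord], pd.DataFrame]:
    """Generate the cohort in the common model, analyst-coded, plus truth.

    The truth table records per patient: exposure to the drug of interest,
    whether a reaction statement falls inside the [0, W] window after a
    prescription (true foreground membership — eligibility is deterministic
    given the events), and confounder carriage.
    """
    research = bundle.schemes[bundle.research_scheme]
    drug = bundle.schemes[bundle.drug_scheme]
    pts = sorted(c.code for c in research.concepts.values() if c.level == "PT")
    substances = sorted(c.code for c in drug.concepts.values() if c.level == "SUBSTANCE")
    noise_pts = [p for p in pts if p not in (bundle.reaction_pt, bundle.confounder_pt)]
    noise_subst = [s for s in substances if s != bundle.drug_of_interest]

    demo = _rng(spec, 2)
    expo = _rng(spec, 3)
    react = _rng(spec, 4)
    conf = _rng(spec, 5)
    noise = _rng(spec, 6)

    genders, gender_p = zip(*sorted(spec.gender_split.items()))
    countries, country_p = zip(*sorted(spec.country_dist.items()))
    T = spec.span_days
    W = spec.window_days

    def cv(scheme: str, code: str) -> CodedValue:
        return CodedValue(scheme, code, bundle.schemes[scheme].concept(code).label)

    records: list[PatientRecord] = []
    truth_rows = []
    for i in range(spec.n_patients):
        pid = f"p{i + 1:05d}"
        gender = str(demo.choice(genders, p=np.asarray(gender_p) / sum(gender_p)))
        country = str(demo.choice(countries, p=np.asarray(country_p) / sum(country_p)))
        birth_year = int(demo.integers(spec.birth_year_range[0], spec.birth_year_range[1] + 1))

        stmts: list[ClinicalStatement] = []
        exposed = bool(expo.random() < spec.exposure_prob)
        presc_day: Optional[int] = None
        if exposed:
            # one prescription, placed so its window fits inside the span
            presc_day = int(expo.integers(0, T - W))
            stmts.append(
                ClinicalStatement("medication", cv(DRUG, bundle.drug_of_interest), _day(presc_day))
            )

        reaction_days: list[int] = []
        if exposed and react.random() < spec.p_w:
            reaction_days.append(presc_day + int(react.integers(0, W + 1)))
        if react.random() < spec.p_bg:
            reaction_days.append(int(react.integers(0, T)))
        for d in reaction_days:
            stmts.append(ClinicalStatement("condition", cv(RESEARCH, bundle.reaction_pt), _day(d)))

        is_reactor = bool(reaction_days)
        prev = spec.confounder_prev_reactors if is_reactor else spec.confounder_prev_nonreactors
        has_confounder = bool(conf.random() < prev)
        if has_confounder:
            stmts.append(ClinicalStatement("condition", cv(RESEARCH, bundle.confounder_pt), _day(int(conf.integers(0, T)))))

        for _ in range(int(noise.poisson(spec.noise_conditions_mean))):
            code = str(noise.choice(noise_pts))
            stmts.append(ClinicalStatement("condition", cv(RESEARCH, code), _day(int(noise.integers(0, T)))))
        for _ in range(int(noise.poisson(spec.noise_medications_mean))):
            code = str(noise.choice(noise_subst))
            stmts.append(ClinicalStatement("medication", cv(DRUG, code), _day(int(noise.integers(0, T)))))
        if noise.random() < spec.lab_prob:
            stmts.append(
                ClinicalStatement(
                    "lab_result",
                    cv(LAB, bundle.lab_code),
                    _day(int(noise.integers(0, T))),
                    value=Quantity(round(float(noise.normal(6.0, 1.5)), 2), "pct"),
                )
            )

        in_window = exposed and any(0 <= d - presc_day <= W for d in reaction_days)
        truth_rows.append(
            {
                "patient_id": pid,
                "exposed": exposed,
                "foreground": in_window,
                "reactor": is_reactor,
                "confounder": has_confounder,
                "gender": gender,
            }
        )
        records.append(
            PatientRecord(
                patient_id=pid,
                birth_year=birth_year,
                gender=CodedValue("GENDER", gender),
                country=CodedValue("COUNTRY", country),
                statements=tuple(stmts),
            )
        )
    return records, pd.DataFrame(truth_rows)


def analytic_foreground_proportion(spec: GeneratorSpec) -> float:
    """E[fg/bg] under the generator's reaction model.

    A patient in the background (exposed) is foreground with probability
    ``p_w + (1 - p_w) * q`` where ``q = p_bg * (W + 1) / span`` is the
    chance an independent baseline reaction lands in the inclusive
    [0, W]-day window after the (uniformly placed) prescription.
    """
    q = spec.p_bg * (spec.window_days + 1) / spec.span_days
    return spec.p_w + (1.0 - spec.p_w) * q


# ---------------------------------------------------------------------------
# Source-dialect emission (feeds the two mediation paths)
# ---------------------------------------------------------------------------


def translate_records(records: list[PatientRecord], bundle: TerminologyBundle, variant: str) -> list[PatientRecord]:
    """Re-express analyst-coded records in a care source's terminologies,
    applying the ground-truth mapping in reverse (the inverse of what
    localization + enrichment undo at query time)."""
    care_scheme = bundle.care_condition_schemes[variant]
    leaf_of = bundle.research_to_care[care_scheme]
    care = bundle.schemes[care_scheme]
    drug_care = bundle.schemes[bundle.care_drug_scheme]

    def xlate(s: ClinicalStatement) -> ClinicalStatement:
        if s.code.scheme_id == bundle.research_scheme and s.code.code in leaf_of:
            code = leaf_of[s.code.code]
            return ClinicalStatement(s.kind, CodedValue(care_scheme, code, care.concept(code).label),
                                     s.effective_start, s.effective_end, s.value)
        if s.code.scheme_id == bundle.drug_scheme:
            return ClinicalStatement(s.kind, CodedValue(bundle.care_drug_scheme, s.code.code,
                                                        drug_care.concept(s.code.code).label),
                                     s.effective_start, s.effective_end, s.value)
        return s

    return [
        PatientRecord(r.patient_id, r.birth_year, r.gender, r.country,
                      tuple(xlate(s) for s in r.statements), r.extensions)
        for r in records
    ]


def reference_study_dict(bundle: TerminologyBundle, window_days: int = 120, with_temporal: bool = True) -> dict:
    """The reference study as a plain dict (YAML-shaped).

    Background: all patients on the drug of interest.  Foreground: the
    background AND a reaction within ``window_days`` after a prescription.
    Conditions grouped at research HLGT, medications at substance level;
    the confounder is the configured risk factor.
    """
    drug_leaf = {"kind": "medication", "codes": [{"scheme": bundle.drug_scheme, "code": bundle.drug_of_interest}]}
    reaction_leaf = {"kind": "condition", "codes": [{"scheme": bundle.research_scheme, "code": bundle.reaction_pt}]}
    fg_children: list[dict] = [dict(drug_leaf)]
    if with_temporal:
        fg_children.append(
            {
                "temporal": {
                    "anchor": dict(drug_leaf),
                    "related": reaction_leaf,
                    "direction": "after",
                    "window_days": window_days,
                }
            }
        )
    else:
        fg_children.append(reaction_leaf)
    return {
        "name": "reference-study",
        "background": dict(drug_leaf),
        "foreground": {"op": "AND", "children": fg_children},
        "statistics": ["age", "gender", "country", "common_conditions", "common_medications", "risk_factors"],
        "grouping": {
            "condition": {"scheme": bundle.research_scheme, "level": "HLGT"},
            "medication": {"scheme": bundle.drug_scheme, "level": "SUBSTANCE"},
        },
        "risk_factors": [{"scheme": bundle.research_scheme, "code": bundle.confounder_pt}],
        "index_anchor": dict(drug_leaf),
    }


def reference_study(bundle: TerminologyBundle, window_days: int = 120, with_temporal: bool = True):
    """The reference study as a parsed :class:`StudyDefinition`."""
    from .common_model import study_from_dict

    return study_from_dict(reference_study_dict(bundle, window_days, with_temporal))


_SECTION_OF = {
    "condition": ("problems", "observation"),
    "medication": ("medications", "substanceAdministration"),
    "lab_result": ("results", "observation"),
    "procedure": ("procedures", "procedure"),
    "allergy": ("allergies", "observation"),
}


def _emit_xml(records: list[PatientRecord], path: Path) -> None:
    root = etree.Element("summarySet")
    for r in records:
        summary = etree.SubElement(root, "patientSummary")
        pat = etree.SubElement(summary, "patient")
        pat.set("id", r.patient_id)
        if r.birth_year is not None:
            pat.set("birthYear", str(r.birth_year))
        if r.gender:
            pat.set("gender", r.gender.code)
        if r.country:
            pat.set("country", r.country.code)
        sections: dict[str, etree._Element] = {}
        for s in r.statements:
            sec_name, el_name = _SECTION_OF[s.kind]
            if sec_name not in sections:
                sections[sec_name] = etree.SubElement(summary, "section")
                sections[sec_name].set("type", sec_name)
            entry = etree.SubElement(sections[sec_name], el_name)
            code = etree.SubElement(entry, "code")
            code.set("code", s.code.code)
            code.set("codeSystem", code_system_for_scheme(s.code.scheme_id))
            if s.code.label:
                code.set("displayName", s.code.label)
            if s.effective_start:
                et = etree.SubElement(entry, "effectiveTime")
                et.set("value", s.effective_start.strftime("%Y%m%d"))
                if s.effective_end:
                    et.set("high", s.effective_end.strftime("%Y%m%d"))
            if isinstance(s.value, Quantity):
                val = etree.SubElement(entry, "value")
                val.set("value", repr(s.value.value))
                val.set("unit", s.value.unit)
    path.write_bytes(etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8"))


_TABLE_OF = {
    "condition": "conditions",
    "medication": "medications",
    "lab_result": "lab_results",
    "procedure": "procedures",
    "allergy": "allergies",
}


def _emit_relational(records: list[PatientRecord], outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    patients = []
    tables: dict[str, list[dict]] = {t: [] for t in _TABLE_OF.values()}
    for r in records:
        patients.append(
            {
                "patient_id": r.patient_id,
                "birth_year": r.birth_year if r.birth_year is not None else "",
                "gender": r.gender.code if r.gender else "",
                "country": r.country.code if r.country else "",
            }
        )
        for s in r.statements:
            row = {
                "patient_id": r.patient_id,
                "scheme": s.code.scheme_id,
                "code": s.code.code,
                "label": s.code.label or "",
                "start_date": s.effective_start.isoformat() if s.effective_start else "",
            }
            if s.kind == "medication":
                row["end_date"] = s.effective_end.isoformat() if s.effective_end else ""
            if s.kind == "lab_result":
                row["value"] = repr(s.value.value) if isinstance(s.value, Quantity) else ""
                row["unit"] = s.value.unit if isinstance(s.value, Quantity) else ""
            tables[_TABLE_OF[s.kind]].append(row)
    pd.DataFrame(patients).to_csv(outdir / "patients.csv", index=False)
    for tname, rows in tables.items():
        if rows:
            pd.DataFrame(rows).to_csv(outdir / f"{tname}.csv", index=False)


def emit_source_dialects(
    records: list[PatientRecord],
    bundle: TerminologyBundle,
    variant: str,
    dialect: str,
    path: str | Path,
) -> list[PatientRecord]:
    """Write the cohort as one care source would expose it.

    ``dialect='xml'`` writes a patient-summary document set to ``path`` (a
    file); ``dialect='relational'`` writes CSV tables into ``path`` (a
    directory).  Returns the care-coded records the files were built from —
    the ground truth the mediation round-trip must reproduce.
    """
    path = Path(path)
    care = translate_records(records, bundle, variant)
    if dialect == "xml":
        _emit_xml(care, path)
    elif dialect == "relational":
        _emit_relational(care, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return care
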