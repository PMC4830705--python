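"""Comparative statistics boxes: proportions, demographics, grouped tallies."""

from __future__ import annotations

import datetime as dt

import pytest

from caseseries.characterization import (
    build_report,
    common_items_box,
    demographics_box,
    enrich_codes,
    proportion,
    risk_factor_box,
)
from caseseries.common_model import ClinicalStatement, CodedValue, Leaf, PatientRecord
from caseseries.query_engine import Population, SourceResult, aggregate, select_populations
from caseseries.synthetic_data import GeneratorSpec, generate_cohort, generate_terminologies, reference_study
from caseseries.terminology import UNMAPPED, materialize_group_links


D0 = dt.date(2010, 6, 1)


class TestProportion:
    def test_reference_case_series_shares(self):
        """108 foreground of 34773 background is printed as 0.31%, and the
        423-patient foreground (no temporal constraint) as 1.22%."""
        assert proportion(108, 34773) == 0.31
        assert proportion(423, 34773) == 1.22

    def test_zero_foreground(self):
        assert proportion(0, 1000) == 0.0

    def test_empty_background_is_undefined(self):
        assert proportion(5, 0) is None

    def test_half_up_rounding(self):
        assert proportion(1, 800) == 0.13  # 0.125 rounds up, not to even


class TestEnrichment:
    def test_annotation_matches_per_code_lookup(self, bundle, cohort, closure):
        records, _ = cohort
        grouping = {"condition": (bundle.research_scheme, "HLGT")}
        links = materialize_group_links(closure, bundle.schemes, bundle.research_scheme, "HLGT")
        lookup: dict = {}
        for l in links:
            lookup.setdefault(l.a, set()).add(l.b[1])
        enriched = enrich_codes(records, grouping, links)
        for r in enriched:
            for s in r.statements:
                if s.kind == "condition":
                    expected = lookup.get(s.code.ref)
                    assert s.groups == (frozenset(expected) if expected else frozenset({UNMAPPED}))
                else:
                    assert s.groups is None

    def test_multiaxial_codes_keep_every_group(self, bundle, closure):
        research = bundle.schemes[bundle.research_scheme]
        multi = [
            c.code
            for c in research.concepts.values()
            if c.level == "PT" and len(research.ancestors_at_level(c.code, "HLGT")) > 1
        ]
        assert multi, "fixture must contain multiaxial PTs"
        links = materialize_group_links(closure, bundle.schemes, bundle.research_scheme, "HLGT")
        rec = PatientRecord(
            "p", 1950, statements=(ClinicalStatement("condition", CodedValue(bundle.research_scheme, multi[0]), D0),)
        )
        (out,) = enrich_codes([rec], {"condition": (bundle.research_scheme, "HLGT")}, links)
        assert len(out.statements[0].groups) >= 2

    def test_unmapped_code_routed_to_reserved_group(self, bundle, closure):
        links = materialize_group_links(closure, bundle.schemes, bundle.research_scheme, "HLGT")
        rec = PatientRecord("p", 1950, statements=(ClinicalStatement("condition", CodedValue("LAB", "L1"), D0),))
        (out,) = enrich_codes([rec], {"condition": (bundle.research_scheme, "HLGT")}, links)
        assert out.statements[0].groups == frozenset({UNMAPPED})


def demo_record(pid, gender=None, birth_year=1960, country=None, stmts=()):
    return PatientRecord(
        pid,
        birth_year,
        gender=CodedValue("GENDER", gender) if gender else None,
        country=CodedValue("COUNTRY", country) if country else None,
        statements=tuple(stmts),
    )


class TestDemographicsBox:
    def test_gender_rates(self):
        fg = [demo_record("a", "M"), demo_record("b", "M"), demo_record("c", "F")]
        box = demographics_box(fg, fg, "gender", D0)
        male = next(r for r in box.rows if r.code == "M")
        assert male.fg_count == 2 and male.fg_rate == 66.67

    def test_missing_birth_years_become_unknown_row(self):
        fg = [demo_record("a", birth_year=None), demo_record("b", birth_year=None)]
        box = demographics_box(fg, fg, "age", D0)
        assert len(box.rows) == 1
        assert box.rows[0].code == "UNKNOWN" and box.rows[0].fg_rate == 100.0

    def test_generator_gender_split_recovered_exactly(self):
        spec = GeneratorSpec(seed=5, n_patients=1000, gender_split={"M": 0.6, "F": 0.4})
        b = generate_terminologies(spec)
        records, truth = generate_cohort(spec, b)
        box = demographics_box(records, records, "gender", D0)
        male = next(r for r in box.rows if r.code == "M")
        assert male.fg_count == int((truth.gender == "M").sum())


class TestCommonItemsBox:
    def _enriched(self, stmts):
        rec = PatientRecord("p", 1950, statements=tuple(stmts))
        # manual annotation: every condition grouped under G
        from dataclasses import replace

        return [
            replace(
                rec,
                statements=tuple(
                    replace(s, groups=frozenset({"G"})) if s.kind == "condition" else s for s in rec.statements
                ),
            )
        ]

    ANCHOR = Leaf("medication", frozenset({CodedValue("D", "m")}))

    def test_two_statements_same_group_count_one_patient(self):
        recs = self._enriched(
            [
                ClinicalStatement("condition", CodedValue("S", "c1"), D0),
                ClinicalStatement("condition", CodedValue("S", "c2"), D0 + dt.timedelta(days=3)),
            ]
        )
        box = common_items_box(recs, recs, "condition", ("S", "L"))
        row = box.rows[0]
        assert row.fg_count == 1 and row.fg_events == 2

    @pytest.mark.parametrize("offset,in_before,in_after", [(-5, True, False), (0, False, False), (5, False, True)])
    def test_index_day_events_in_neither_window(self, offset, in_before, in_after):
        recs = self._enriched(
            [
                ClinicalStatement("medication", CodedValue("D", "m"), D0),
                ClinicalStatement("condition", CodedValue("S", "c"), D0 + dt.timedelta(days=offset)),
            ]
        )
        before = common_items_box(recs, recs, "condition", ("S", "L"), "before_index", self.ANCHOR)
        after = common_items_box(recs, recs, "condition", ("S", "L"), "after_index", self.ANCHOR)
        assert bool(before.rows and before.rows[0].fg_count) is in_before
        assert bool(after.rows and after.rows[0].fg_count) is in_after

    def test_patients_without_index_excluded_from_denominator(self):
        with_index = self._enriched(
            [
                ClinicalStatement("medication", CodedValue("D", "m"), D0),
                ClinicalStatement("condition", CodedValue("S", "c"), D0 + dt.timedelta(days=2)),
            ]
        )[0]
        without_index = self._enriched([ClinicalStatement("condition", CodedValue("S", "c"), D0)])[0]
        from dataclasses import replace

        without_index = replace(without_index, patient_id="q")
        recs = [with_index, without_index]
        box = common_items_box(recs, recs, "condition", ("S", "L"), "after_index", self.ANCHOR)
        assert box.fg_denominator == 1

    def test_known_prevalences_recovered_by_patient_tally(self, bundle, cohort, closure):
        records, _ = cohort
        links = materialize_group_links(closure, bundle.schemes, bundle.research_scheme, "HLGT")
        enriched = enrich_codes(records, {"condition": (bundle.research_scheme, "HLGT")}, links)
        box = common_items_box(enriched, enriched, "condition", (bundle.research_scheme, "HLGT"))
        # independent tally: patients per group, straight from annotations
        tally: dict = {}
        for r in enriched:
            for g in {g for s in r.statements if s.kind == "condition" and s.groups for g in s.groups}:
                tally[g] = tally.get(g, 0) + 1
        assert {r.code: r.fg_count for r in box.rows} == tally


class TestRiskFactorBox:
    def test_unmatched_risk_code_counts_zero(self):
        # in a cohort with no reaction events, the reaction code matches nobody
        spec = GeneratorSpec(seed=8, n_patients=100, p_w=0.0, p_bg=0.0)
        b = generate_terminologies(spec)
        records, _ = generate_cohort(spec, b)
        from caseseries.terminology import materialize_close_match

        cm = materialize_close_match(b.schemes, b.assertions)
        box = risk_factor_box(records, records, [CodedValue(b.research_scheme, b.reaction_pt)], cm, b.schemes)
        assert box.rows[0].fg_count == 0 and box.rows[0].bg_count == 0

    def test_confounder_prevalence_recovered(self):
        spec = GeneratorSpec(seed=5, n_patients=400, confounder_prev_reactors=0.25, confounder_prev_nonreactors=0.25)
        b = generate_terminologies(spec)
        records, truth = generate_cohort(spec, b)
        from caseseries.terminology import materialize_close_match

        cm = materialize_close_match(b.schemes, b.assertions)
        box = risk_factor_box(records, records, [CodedValue(b.research_scheme, b.confounder_pt)], cm, b.schemes)
        measured = box.rows[0].fg_count / len(records)
        se = (0.25 * 0.75 / len(records)) ** 0.5
        assert abs(measured - 0.25) <= 3 * se
        assert box.rows[0].fg_count == int(truth.confounder.sum())

    def test_source_coded_confounder_statements_are_hit(self, bundle, cohort, closure):
        """Risk codes written in the analyst scheme must match care-coded data."""
        from caseseries.synthetic_data import translate_records

        records, truth = cohort
        care = translate_records(records, bundle, "A")
        box = risk_factor_box(care, care, [CodedValue(bundle.research_scheme, bundle.confounder_pt)], closure, bundle.schemes)
        assert box.rows[0].fg_count == int(truth.confounder.sum()) > 0


class TestFullReport:
    def _report(self, bundle, records, study=None):
        study = study or reference_study(bundle)
        fg, bg = select_populations(study, records, source_id="s")
        merged, mfg, mbg = aggregate(
            [SourceResult("s", tuple(records), fg, bg)]
        )
        from caseseries.terminology import materialize_close_match, materialize_group_links

        cm = materialize_close_match(bundle.schemes, bundle.assertions)
        links = set()
        for kind, (scheme, level) in study.grouping.items():
            links |= materialize_group_links(cm, bundle.schemes, scheme, level)
        enriched = enrich_codes(merged, study.grouping, links)
        return build_report(study, mfg, mbg, enriched, closure=cm, terminologies=bundle.schemes)

    def test_empty_foreground_report_is_all_zero(self, bundle):
        spec = GeneratorSpec(seed=7, n_patients=100, p_w=0.0, p_bg=0.0)
        b = generate_terminologies(spec)
        records, _ = generate_cohort(spec, b)
        report = self._report(b, records)
        assert report.fg_size == 0 and report.fg_share_pct == 0.0
        for box in report.boxes:
            assert all(r.fg_count == 0 for r in box.rows)

    def test_rates_bounded_and_counts_within_denominators(self, bundle, cohort):
        records, _ = cohort
        report = self._report(bundle, records)
        assert report.boxes
        assert any(r.bg_count > 0 for b in report.boxes for r in b.rows)  # not vacuous
        for box in report.boxes:
            for row in box.rows:
                assert 0 <= row.fg_rate <= 100 and 0 <= row.bg_rate <= 100
                assert row.fg_count <= box.fg_denominator
                assert row.bg_count <= box.bg_denominator

    def test_report_is_deterministic(self, bundle, cohort):
        records, _ = cohort
        assert self._report(bundle, records).to_json() == self._report(bundle, records).to_json()

    def test_dropping_temporal_constraint_never_shrinks_foreground(self, bundle, cohort):
        records, _ = cohort
        with_t = self._report(bundle, records, reference_study(bundle, with_temporal=True))
        without_t = self._report(bundle, records, reference_study(bundle, with_temporal=False))
        assert without_t.fg_size >= with_t.fg_size
        assert without_t.bg_size == with_t.bg_size
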