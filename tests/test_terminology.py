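"""Terminology loading, closure materialization, grouping and expansion."""

from __future__ import annotations

import numpy as np
import pytest

from caseseries.terminology import (
    CloseMatchClosure,
    Concept,
    ConceptScheme,
    DerivationConfig,
    IntegrityError,
    LookupError_,
    MappingAssertion,
    ParseError,
    closure_inputs_hash,
    expand_query_codes,
    load_closure_cache,
    load_mappings,
    load_scheme,
    materialize_close_match,
    materialize_group_links,
    materialize_with_cache,
    write_closure_cache,
    write_mappings,
    write_scheme,
)
from conftest import tiny_scheme


# ---------------------------------------------------------------------------
# Oracles (independent of the implementation under test)
# ---------------------------------------------------------------------------


def bfs_closure_oracle(assertions: list[MappingAssertion]) -> set:
    """Breadth-first reachability over the symmetrized assertion graph."""
    adj: dict = {}
    for a in assertions:
        adj.setdefault(a.source, set()).add(a.target)
        adj.setdefault(a.target, set()).add(a.source)
    pairs = set()
    for start in adj:
        seen = {start}
        queue = [start]
        while queue:
            n = queue.pop()
            for m in adj.get(n, ()):
                if m not in seen:
                    seen.add(m)
                    queue.append(m)
        pairs |= {(start, other) for other in seen if other != start}
    return pairs


def matrix_reachability_oracle(scheme: ConceptScheme) -> dict[str, set[str]]:
    """Descendant sets via boolean matrix closure (narrower adjacency)."""
    codes = sorted(scheme.concepts)
    idx = {c: i for i, c in enumerate(codes)}
    n = len(codes)
    adj = np.zeros((n, n), dtype=bool)
    for c in scheme.concepts.values():
        for p in c.broader:
            adj[idx[p], idx[c.code]] = True
    reach = adj.copy()
    for _ in range(n):
        new = reach | (reach @ adj)
        if (new == reach).all():
            break
        reach = new
    return {c: {codes[j] for j in np.flatnonzero(reach[idx[c]])} for c in codes}


def random_mapping_fixture(seed: int, n_schemes: int = 4, n_per: int = 30, n_assert: int = 50):
    rng = np.random.default_rng(seed)
    schemes = {}
    for s in range(n_schemes):
        sid = f"S{s}"
        schemes[sid] = ConceptScheme(
            sid, ("L",), [Concept(f"c{i}", sid, f"c{i}", "L") for i in range(n_per)]
        )
    refs = [(sid, f"c{i}") for sid in schemes for i in range(n_per)]
    assertions = []
    for _ in range(n_assert):
        a, b = rng.choice(len(refs), size=2, replace=False)
        ra, rb = refs[int(a)], refs[int(b)]
        if ra[0] == rb[0]:
            continue
        assertions.append(MappingAssertion(ra, rb, "omop_like"))
    return schemes, assertions


# ---------------------------------------------------------------------------
# Scheme construction and I/O
# ---------------------------------------------------------------------------


class TestSchemeIntegrity:
    def test_minimal_chain_loads(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text(
            "#scheme: S\n#levels: SOC|HLGT|PT\n"
            "code\tlabel\tlevel\tbroader\n"
            "a\tA\tSOC\t\nb\tB\tHLGT\ta\nc\tC\tPT\tb\n"
        )
        s = load_scheme(p)
        assert len(s) == 3
        assert s.concept("c").broader == {"b"}

    def test_broader_to_absent_code_rejected(self):
        with pytest.raises(IntegrityError, match="absent"):
            ConceptScheme("S", ("A", "B"), [Concept("x", "S", "x", "B", frozenset({"ghost"}))])

    def test_parent_must_be_strictly_broader(self):
        cs = [Concept("x", "S", "x", "A"), Concept("y", "S", "y", "A", frozenset({"x"}))]
        with pytest.raises(IntegrityError, match="strictly broader"):
            ConceptScheme("S", ("A", "B"), cs)

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("#scheme: S\n#levels: A\ncode\tlabel\tlevel\tbroader\nonly_two\tfields\n")
        with pytest.raises(ParseError, match=":4"):
            load_scheme(p)

    @pytest.mark.parametrize("suffix", [".tsv", ".ttl"])
    def test_write_read_round_trip(self, tmp_path, suffix):
        spec_scheme = tiny_scheme("RT")
        p = tmp_path / f"rt{suffix}"
        write_scheme(spec_scheme, p)
        assert load_scheme(p) == spec_scheme

    def test_synthetic_scheme_round_trips(self, bundle, tmp_path):
        research = bundle.schemes[bundle.research_scheme]
        p = tmp_path / "research.tsv"
        write_scheme(research, p)
        assert load_scheme(p) == research

    def test_mapping_file_round_trip(self, bundle, tmp_path):
        p = tmp_path / "m.tsv"
        write_mappings(bundle.assertions, p)
        assert set(load_mappings(p)) == set(bundle.assertions)


class TestTraversals:
    def test_leaf_has_no_descendants(self, chain_scheme):
        assert chain_scheme.descendants("leaf1") == set()

    def test_descendants_exclude_self(self, chain_scheme):
        assert chain_scheme.descendants("root") == {"mid", "leaf1", "leaf2"}

    def test_ancestors_at_level_includes_self_at_that_level(self, chain_scheme):
        assert chain_scheme.ancestors_at_level("root", "TOP") == {"root"}
        assert chain_scheme.ancestors_at_level("leaf1", "TOP") == {"root"}

    def test_unknown_code_raises_lookup_error(self, chain_scheme):
        with pytest.raises(LookupError_):
            chain_scheme.descendants("ghost")

    def test_descendants_match_matrix_reachability_oracle(self, bundle):
        research = bundle.schemes[bundle.research_scheme]
        oracle = matrix_reachability_oracle(research)
        for code in research.concepts:
            assert research.descendants(code) == oracle[code]


# ---------------------------------------------------------------------------
# Close-match materialization
# ---------------------------------------------------------------------------


class TestCloseMatch:
    def _two_hop(self):
        schemes = {
            sid: ConceptScheme(sid, ("L",), [Concept("x", sid, "x", "L")]) for sid in ("A", "B", "C")
        }
        assertions = [
            MappingAssertion(("A", "x"), ("B", "x"), "omop_like"),
            MappingAssertion(("B", "x"), ("C", "x"), "crossmap_like"),
        ]
        return schemes, assertions

    def test_two_hop_transitivity_and_symmetry(self):
        schemes, assertions = self._two_hop()
        cm = materialize_close_match(schemes, assertions)
        assert (("A", "x"), ("C", "x")) in cm
        assert (("C", "x"), ("A", "x")) in cm

    def test_empty_assertions_give_empty_closure(self, bundle):
        cm = materialize_close_match(bundle.schemes, [])
        assert len(cm) == 0

    def test_broader_never_leaks_into_matching(self, bundle):
        """Rich hierarchies with zero mapping assertions must close to nothing."""
        cm = materialize_close_match(bundle.schemes, [])
        for sid, scheme in bundle.schemes.items():
            for code in scheme.concepts:
                assert cm.matches((sid, code)) == frozenset()

    def test_unresolvable_endpoint_reported(self):
        schemes, _ = self._two_hop()
        bad = [MappingAssertion(("A", "x"), ("B", "ghost"), "omop_like")]
        with pytest.raises(IntegrityError, match="ghost"):
            materialize_close_match(schemes, bad)

    def test_output_is_symmetric_and_transitive(self, closure):
        pairs = closure.pairs()
        assert all((b, a) in pairs for a, b in pairs)
        by_a: dict = {}
        for a, b in pairs:
            by_a.setdefault(a, set()).add(b)
        for a, bs in by_a.items():
            for b in bs:
                for c in by_a.get(b, ()):
                    if c != a:
                        assert (a, c) in pairs

    @pytest.mark.parametrize("seed", [7, 11, 23, 42])
    def test_matches_bfs_reachability_oracle(self, seed):
        schemes, assertions = random_mapping_fixture(seed)
        cm = materialize_close_match(schemes, assertions)
        assert cm.pairs() == bfs_closure_oracle(assertions)

    def test_direction_restriction_disables_symmetry(self):
        schemes, assertions = self._two_hop()
        cfg = DerivationConfig(directions={"omop_like": "forward", "crossmap_like": "forward"})
        cm = materialize_close_match(schemes, assertions, cfg)
        assert (("A", "x"), ("C", "x")) in cm
        assert (("C", "x"), ("A", "x")) not in cm


class TestGroupLinks:
    def test_single_path_gives_single_group(self, bundle, closure):
        care = bundle.schemes["CARE_A"]
        research = bundle.schemes[bundle.research_scheme]
        links = materialize_group_links(closure, bundle.schemes, bundle.research_scheme, "HLGT")
        by_code: dict = {}
        for l in links:
            by_code.setdefault(l.a, set()).add(l.b[1])
        # every linked group is exactly at HLGT level
        for groups in by_code.values():
            for g in groups:
                assert research.concept(g).level == "HLGT"

    def test_code_already_at_target_level_links_to_itself(self, bundle, closure):
        research = bundle.schemes[bundle.research_scheme]
        hlgt = next(c.code for c in research.concepts.values() if c.level == "HLGT")
        links = materialize_group_links(closure, bundle.schemes, bundle.research_scheme, "HLGT")
        assert any(l.a == (bundle.research_scheme, hlgt) and l.b == (bundle.research_scheme, hlgt) for l in links)

    def test_care_codes_share_group_per_ground_truth(self, bundle, closure):
        """Source codes of both care schemes group under the research-level
        group their mapping chain points at (the shared-membership contract
        of cross-terminology grouping)."""
        links = materialize_group_links(closure, bundle.schemes, bundle.research_scheme, "HLGT")
        by_code: dict = {}
        for l in links:
            by_code.setdefault(l.a, set()).add(l.b[1])
        checked = 0
        for ref, truth_groups in bundle.ground_truth_groups.items():
            if "UNMAPPED" in truth_groups:
                assert ref not in by_code
            else:
                assert by_code.get(ref) == set(truth_groups)
                checked += 1
        assert checked > 0

    def test_unknown_level_is_config_error(self, bundle, closure):
        with pytest.raises(LookupError_):
            materialize_group_links(closure, bundle.schemes, bundle.research_scheme, "NOPE")


class TestExpansion:
    def test_close_match_with_children_expands_to_descendants(self):
        src = tiny_scheme("SRC")
        other = ConceptScheme("O", ("L",), [Concept("q", "O", "q", "L")])
        cm = materialize_close_match(
            {"SRC": src, "O": other}, [MappingAssertion(("O", "q"), ("SRC", "mid"), "omop_like")]
        )
        assert expand_query_codes(("O", "q"), "SRC", cm, {"SRC": src, "O": other}) == {
            "mid",
            "leaf1",
            "leaf2",
        }

    def test_unmapped_code_expands_to_empty_set(self):
        from caseseries.synthetic_data import GeneratorSpec, generate_terminologies

        spec = GeneratorSpec(seed=9, n_patients=1, mapping_consistency=0.8)
        b = generate_terminologies(spec)
        cm = materialize_close_match(b.schemes, b.assertions)
        unmapped = sorted(set(b.research_to_care["CARE_A"]) - set(b.mapped_pts))
        assert unmapped, "consistency < 1 must break some mapping chains"
        for pt in unmapped[:5]:
            assert expand_query_codes((b.research_scheme, pt), "CARE_A", cm, b.schemes) == set()

    def test_same_scheme_code_expands_to_self_and_descendants(self, chain_scheme, closure):
        cm = materialize_close_match({"T": chain_scheme}, [])
        got = expand_query_codes(("T", "mid"), "T", cm, {"T": chain_scheme})
        assert got == {"mid", "leaf1", "leaf2"}

    def test_unknown_code_raises(self, bundle, closure):
        with pytest.raises(LookupError_):
            expand_query_codes(("RSRCH", "ghost"), "CARE_A", closure, bundle.schemes)

    @pytest.mark.parametrize("seed", [11, 19])
    def test_matches_exhaustive_dfs_oracle(self, seed):
        from caseseries.synthetic_data import GeneratorSpec, generate_terminologies

        spec = GeneratorSpec(seed=seed, n_patients=1)
        b = generate_terminologies(spec)
        cm = materialize_close_match(b.schemes, b.assertions)
        src = b.schemes["CARE_A"]
        pairs = cm.pairs()

        def dfs_desc(code):
            out, stack = set(), [code]
            while stack:
                n = stack.pop()
                for child in src.children(n):
                    if child not in out:
                        out.add(child)
                        stack.append(child)
            return out

        for pt in sorted(b.schemes[b.research_scheme].concepts)[:40]:
            ref = (b.research_scheme, pt)
            seeds = {c for (a, (s, c)) in ((p[0], p[1]) for p in pairs) if a == ref and s == "CARE_A"}
            expected = set(seeds)
            for s in seeds:
                expected |= dfs_desc(s)
            assert expand_query_codes(ref, "CARE_A", cm, b.schemes) == expected

    def test_expansion_monotone_in_assertions(self, bundle):
        """Adding assertions never shrinks an expansion."""
        half = bundle.assertions[: len(bundle.assertions) // 2]
        cm_half = materialize_close_match(bundle.schemes, half)
        cm_full = materialize_close_match(bundle.schemes, bundle.assertions)
        for pt in sorted(bundle.mapped_pts)[:20]:
            ref = (bundle.research_scheme, pt)
            small = expand_query_codes(ref, "CARE_A", cm_half, bundle.schemes)
            big = expand_query_codes(ref, "CARE_A", cm_full, bundle.schemes)
            assert small <= big


class TestClosureCache:
    def test_cache_round_trip_and_staleness(self, bundle, tmp_path):
        p = tmp_path / "closure.tsv"
        cm1 = materialize_with_cache(bundle.schemes, bundle.assertions, p)
        first_bytes = p.read_bytes()
        cm2 = materialize_with_cache(bundle.schemes, bundle.assertions, p)
        assert cm1.pairs() == cm2.pairs()
        assert p.read_bytes() == first_bytes  # bit-stable
        # stale: drop one assertion -> different hash -> rebuilt
        cm3 = materialize_with_cache(bundle.schemes, bundle.assertions[:-1], p)
        assert p.read_bytes() != first_bytes
        assert len(cm3.pairs()) <= len(cm1.pairs())

    def test_hash_sensitive_to_every_input(self, bundle):
        h0 = closure_inputs_hash(bundle.schemes, bundle.assertions)
        h1 = closure_inputs_hash(bundle.schemes, bundle.assertions[:-1])
        h2 = closure_inputs_hash(bundle.schemes, bundle.assertions, DerivationConfig({"omop_like": "forward"}))
        assert len({h0, h1, h2}) == 3
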