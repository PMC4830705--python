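"""Terminology systems, cross-system mappings, and materialized reasoning.

A :class:`ConceptScheme` models one coding system (a MedDRA-, ICD- or
ATC-style hierarchy) as a set of coded concepts arranged on named levels,
with ``broader`` edges pointing from narrower to broader concepts.  Multiple
parents are allowed (multiaxial hierarchies); levels are declared per scheme
rather than inferred from depth, because real terminologies have uneven
depth.

Cross-scheme links come in as :class:`MappingAssertion` rows tagged with the
mapping set they were curated in (an OMOP-style ICD-to-pivot map, a
PROTECT-style research-to-pivot map, a CrossMap-style pivot-to-ICD map, or
identical-code links between national variants of one system).  From these
the module materializes, ahead of query time:

* the *close-match closure* — the transitive closure of the (by default
  symmetrized) assertion graph.  Within-scheme ``broader`` edges are never
  folded into this closure: hierarchy is not equivalence, and treating
  curated directed mappings as freely transitive-and-symmetric SKOS
  relations is exactly the inference error this design avoids.
* *group links* — single-hop links from any code in any scheme to the
  concept(s) at a chosen level of a chosen target scheme that subsume its
  close matches.  Multiaxial codes keep every group.

Both products serve O(1) lookups for query expansion (analyst code -> the
codes and descendants a source actually uses) and for result grouping.
"""

from __future__ import annotations

import hashlib
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "Concept",
    "ConceptScheme",
    "MappingAssertion",
    "ClosureLink",
    "CloseMatchClosure",
    "DerivationConfig",
    "TerminologyError",
    "ParseError",
    "IntegrityError",
    "LookupError_",
    "load_scheme",
    "write_scheme",
    "load_mappings",
    "write_mappings",
    "materialize_close_match",
    "materialize_group_links",
    "expand_query_codes",
    "write_closure_cache",
    "load_closure_cache",
    "closure_inputs_hash",
    "UNMAPPED",
]

#: Reserved group code for statements whose code has no route into the
#: grouping scheme.  Unmapped codes are never silently dropped.
UNMAPPED = "UNMAPPED"

CodeRef = tuple[str, str]  # (scheme_id, code)


class TerminologyError(Exception):
    """Base class for terminology-layer failures."""


class ParseError(TerminologyError):
    """A terminology or mapping file is malformed."""


class IntegrityError(TerminologyError):
    """Loaded content violates a scheme or mapping invariant."""


class LookupError_(TerminologyError):
    """A (scheme, code) reference does not resolve."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Concept:
    """One coded entry of a terminology system.

    ``broader`` holds the codes of the direct parents *within the same
    scheme*; parents must sit on a strictly broader level.
    """

    code: str
    scheme_id: str
    label: str
    level: str
    broader: frozenset[str] = frozenset()


class ConceptScheme:
    """A terminology system: named levels plus a DAG of concepts.

    Parameters
    ----------
    scheme_id:
        Short identifier, unique among loaded schemes.
    level_names:
        Ordered from broadest to narrowest (e.g. SOC, HLGT, HLT, PT).
    concepts:
        The concepts of the scheme; validated on construction.
    """

    def __init__(self, scheme_id: str, level_names: Iterable[str], concepts: Iterable[Concept]):
        self.scheme_id = scheme_id
        self.level_names: tuple[str, ...] = tuple(level_names)
        self.concepts: dict[str, Concept] = {}
        for c in concepts:
            if c.code in self.concepts:
                raise IntegrityError(f"duplicate code {c.code!r} in scheme {scheme_id!r}")
            self.concepts[c.code] = c
        self._level_rank = {name: i for i, name in enumerate(self.level_names)}
        self._children: dict[str, set[str]] = {code: set() for code in self.concepts}
        self._validate()

    # -- validation --------------------------------------------------------

    def _validate(self) -> None:
        if not self.level_names:
            raise IntegrityError(f"scheme {self.scheme_id!r} declares no levels")
        if len(set(self.level_names)) != len(self.level_names):
            raise IntegrityError(f"scheme {self.scheme_id!r} has duplicate level names")
        for c in self.concepts.values():
            if not c.code:
                raise IntegrityError(f"scheme {self.scheme_id!r} contains an empty code")
            if c.scheme_id != self.scheme_id:
                raise IntegrityError(
                    f"concept {c.code!r} tagged scheme {c.scheme_id!r} inside {self.scheme_id!r}"
                )
            if c.level not in self._level_rank:
                raise IntegrityError(
                    f"concept {c.code!r}: level {c.level!r} not declared by {self.scheme_id!r}"
                )
            for p in c.broader:
                parent = self.concepts.get(p)
                if parent is None:
                    raise IntegrityError(
                        f"concept {c.code!r}: broader target {p!r} absent from {self.scheme_id!r}"
                    )
                if self._level_rank[parent.level] >= self._level_rank[c.level]:
                    raise IntegrityError(
                        f"concept {c.code!r}: parent {p!r} is not at a strictly broader level"
                    )
                self._children[p].add(c.code)
        # Strict level ordering already forbids cycles, but guard explicitly
        # so a future relaxation of the level rule cannot corrupt traversals.
        g = nx.DiGraph()
        g.add_nodes_from(self.concepts)
        for c in self.concepts.values():
            for p in c.broader:
                g.add_edge(p, c)
        if not nx.is_directed_acyclic_graph(g):
            raise IntegrityError(f"broader graph of {self.scheme_id!r} contains a cycle")

    # -- queries -----------------------------------------------------------

    def __contains__(self, code: str) -> bool:
        return code in self.concepts

    def __len__(self) -> int:
        return len(self.concepts)

    def concept(self, code: str) -> Concept:
        try:
            return self.concepts[code]
        except KeyError:
            raise LookupError_(f"unknown code {code!r} in scheme {self.scheme_id!r}") from None

    def level_rank(self, level: str) -> int:
        try:
            return self._level_rank[level]
        except KeyError:
            raise LookupError_(f"unknown level {level!r} in scheme {self.scheme_id!r}") from None

    def children(self, code: str) -> frozenset[str]:
        self.concept(code)
        return frozenset(self._children[code])

    def descendants(self, code: str) -> set[str]:
        """All transitively narrower codes, excluding ``code`` itself."""
        self.concept(code)
        seen: set[str] = set()
        stack = list(self._children[code])
        while stack:
            n = stack.pop()
            if n not in seen:
                seen.add(n)
                stack.extend(self._children[n])
        return seen

    def ancestors_at_level(self, code: str, level: str) -> set[str]:
        """Broader-transitive ancestors sitting exactly at ``level``.

        Includes ``code`` itself when it already sits at that level
        (ancestor-or-self semantics).
        """
        self.level_rank(level)
        out: set[str] = set()
        seen: set[str] = set()
        stack = [code]
        while stack:
            n = stack.pop()
            if n in seen:
                continue
            seen.add(n)
            c = self.concept(n)
            if c.level == level:
                out.add(n)
            stack.extend(c.broader)
        return out

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ConceptScheme)
            and self.scheme_id == other.scheme_id
            and self.level_names == other.level_names
            and self.concepts == other.concepts
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"ConceptScheme({self.scheme_id!r}, {len(self.concepts)} concepts)"


@dataclass(frozen=True)
class MappingAssertion:
    """A directed cross-scheme link from one curated mapping set.

    ``relation`` names the mapping set (``omop_like``, ``protect_like``,
    ``crossmap_like``, ``identical_code``); ``strength`` is always
    ``"close"`` — the curated sets assert close correspondence, not formal
    equivalence.
    """

    source: CodeRef
    target: CodeRef
    relation: str
    strength: str = "close"

    def __post_init__(self) -> None:
        if self.source[0] == self.target[0] and self.relation != "identical_code":
            raise IntegrityError(
                f"mapping {self.source} -> {self.target}: same-scheme link requires "
                f"relation 'identical_code', got {self.relation!r}"
            )
        if self.strength != "close":
            raise IntegrityError(f"unsupported mapping strength {self.strength!r}")


@dataclass(frozen=True)
class ClosureLink:
    """A materialized link: close-match pair or code-to-group link."""

    a: CodeRef
    b: CodeRef
    kind: str  # "close_match" | "group_link"


@dataclass(frozen=True)
class DerivationConfig:
    """How assertion relations contribute to the close-match derivation.

    ``directions`` maps a relation tag to ``"both"`` (the default for any
    relation not listed), ``"forward"`` or ``"backward"``.  Bidirectional
    relations contribute both arcs, so the default closure is symmetric;
    a restricted relation contributes a single arc and is *not* re-symmetrized.
    """

    directions: Mapping[str, str] = field(default_factory=dict)

    def arcs_for(self, assertion: MappingAssertion) -> list[tuple[CodeRef, CodeRef]]:
        d = self.directions.get(assertion.relation, "both")
        if d == "both":
            return [(assertion.source, assertion.target), (assertion.target, assertion.source)]
        if d == "forward":
            return [(assertion.source, assertion.target)]
        if d == "backward":
            return [(assertion.target, assertion.source)]
        raise IntegrityError(f"unknown direction {d!r} for relation {assertion.relation!r}")


class CloseMatchClosure:
    """Materialized close-match relation with O(1) neighbour lookup."""

    def __init__(self, pairs: Iterable[tuple[CodeRef, CodeRef]]):
        self._adj: dict[CodeRef, set[CodeRef]] = {}
        for a, b in pairs:
            self._adj.setdefault(a, set()).add(b)

    def matches(self, ref: CodeRef) -> frozenset[CodeRef]:
        return frozenset(self._adj.get(ref, ()))

    def __contains__(self, pair: tuple[CodeRef, CodeRef]) -> bool:
        a, b = pair
        return b in self._adj.get(a, ())

    def pairs(self) -> set[tuple[CodeRef, CodeRef]]:
        return {(a, b) for a, bs in self._adj.items() for b in bs}

    def links(self) -> set[ClosureLink]:
        return {ClosureLink(a, b, "close_match") for a, b in self.pairs()}

    def __len__(self) -> int:
        return sum(len(v) for v in self._adj.values())


# ---------------------------------------------------------------------------
# Scheme and mapping I/O
# ---------------------------------------------------------------------------
#
# TSV dialect:
#
#   #scheme: RSRCH
#   #levels: SOC|HLGT|HLT|PT
#   code<TAB>label<TAB>level<TAB>broader
#   R1<TAB>Disorders axis 1<TAB>SOC<TAB>
#   R1.1<TAB>Group 1.1<TAB>HLGT<TAB>R1
#
# ``broader`` is a |-separated list of parent codes.  An rdflib-backed
# Turtle serialization (skos vocabulary) is read/written for interchange;
# files ending in .ttl take that path.

_TSV_HEADER = ("code", "label", "level", "broader")


def load_scheme(path: str | Path) -> ConceptScheme:
    """Load a scheme from the TSV dialect or the skos Turtle serialization."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"terminology file not found: {path}")
    if path.suffix == ".ttl":
        return _load_scheme_ttl(path)
    return _load_scheme_tsv(path)


def _load_scheme_tsv(path: Path) -> ConceptScheme:
    scheme_id: str | None = None
    levels: list[str] | None = None
    concepts: list[Concept] = []
    header_seen = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#scheme:"):
            scheme_id = line.split(":", 1)[1].strip()
            continue
        if line.startswith("#levels:"):
            levels = [x.strip() for x in line.split(":", 1)[1].strip().split("|") if x.strip()]
            continue
        if line.startswith("#"):
            continue
        parts = line.split("\t")
        if not header_seen:
            if tuple(parts) != _TSV_HEADER:
                raise ParseError(f"{path}:{lineno}: expected header {_TSV_HEADER}, got {parts}")
            header_seen = True
            continue
        if scheme_id is None or levels is None:
            raise ParseError(f"{path}:{lineno}: rows before #scheme:/#levels: block")
        if len(parts) != 4:
            raise ParseError(f"{path}:{lineno}: expected 4 tab-separated fields, got {len(parts)}")
        code, label, level, broader = parts
        parents = frozenset(p for p in broader.split("|") if p)
        concepts.append(Concept(code=code, scheme_id=scheme_id, label=label, level=level, broader=parents))
    if scheme_id is None or levels is None:
        raise ParseError(f"{path}: missing #scheme:/#levels: header block")
    return ConceptScheme(scheme_id, levels, concepts)


def write_scheme(scheme: ConceptScheme, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".ttl":
        _write_scheme_ttl(scheme, path)
        return
    lines = [f"#scheme: {scheme.scheme_id}", "#levels: " + "|".join(scheme.level_names)]
    lines.append("\t".join(_TSV_HEADER))
    for code in sorted(scheme.concepts):
        c = scheme.concepts[code]
        lines.append("\t".join([c.code, c.label, c.level, "|".join(sorted(c.broader))]))
    path.write_text("\n".join(lines) + "\n")


_BASE = "urn:caseseries:term:"


def _write_scheme_ttl(scheme: ConceptScheme, path: Path) -> None:
    from rdflib import Graph, Literal, Namespace, RDF, URIRef
    from rdflib.namespace import SKOS

    cs = Namespace(_BASE)
    g = Graph()
    g.bind("skos", SKOS)
    g.bind("cs", cs)
    scheme_uri = URIRef(f"{_BASE}{scheme.scheme_id}")
    g.add((scheme_uri, RDF.type, SKOS.ConceptScheme))
    g.add((scheme_uri, cs.levelNames, Literal("|".join(scheme.level_names))))
    for code in sorted(scheme.concepts):
        c = scheme.concepts[code]
        uri = URIRef(f"{_BASE}{scheme.scheme_id}/{code}")
        g.add((uri, RDF.type, SKOS.Concept))
        g.add((uri, SKOS.inScheme, scheme_uri))
        g.add((uri, SKOS.notation, Literal(c.code)))
        g.add((uri, SKOS.prefLabel, Literal(c.label)))
        g.add((uri, cs.level, Literal(c.level)))
        for p in sorted(c.broader):
            g.add((uri, SKOS.broader, URIRef(f"{_BASE}{scheme.scheme_id}/{p}")))
    g.serialize(destination=str(path), format="turtle")


def _load_scheme_ttl(path: Path) -> ConceptScheme:
    from rdflib import Graph, Namespace, RDF, URIRef
    from rdflib.namespace import SKOS

    cs = Namespace(_BASE)
    g = Graph()
    try:
        g.parse(str(path), format="turtle")
    except Exception as exc:  # rdflib raises assorted parser errors
        raise ParseError(f"{path}: invalid turtle: {exc}") from exc
    schemes = list(g.subjects(RDF.type, SKOS.ConceptScheme))
    if len(schemes) != 1:
        raise ParseError(f"{path}: expected exactly one skos:ConceptScheme, found {len(schemes)}")
    scheme_uri = schemes[0]
    scheme_id = str(scheme_uri).rsplit(":", 1)[-1]
    levels_lit = g.value(scheme_uri, cs.levelNames)
    if levels_lit is None:
        raise ParseError(f"{path}: scheme lacks level declaration")
    levels = str(levels_lit).split("|")
    concepts = []
    for uri in g.subjects(RDF.type, SKOS.Concept):
        code = str(g.value(uri, SKOS.notation))
        label = str(g.value(uri, SKOS.prefLabel) or "")
        level = str(g.value(uri, cs.level))
        parents = frozenset(str(p).rsplit("/", 1)[-1] for p in g.objects(uri, SKOS.broader))
        concepts.append(Concept(code=code, scheme_id=scheme_id, label=label, level=level, broader=parents))
    return ConceptScheme(scheme_id, levels, concepts)


def load_mappings(path: str | Path) -> list[MappingAssertion]:
    """Load `source_scheme  source_code  target_scheme  target_code  relation` TSV."""
    path = Path(path)
    out: list[MappingAssertion] = []
    header = ("source_scheme", "source_code", "target_scheme", "target_code", "relation")
    header_seen = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        parts = raw.split("\t")
        if not header_seen:
            if tuple(parts) != header:
                raise ParseError(f"{path}:{lineno}: expected header {header}")
            header_seen = True
            continue
        if len(parts) != 5:
            raise ParseError(f"{path}:{lineno}: expected 5 fields, got {len(parts)}")
        ss, sc, ts, tc, rel = parts
        out.append(MappingAssertion(source=(ss, sc), target=(ts, tc), relation=rel))
    return out


def write_mappings(assertions: Iterable[MappingAssertion], path: str | Path) -> None:
    rows = sorted((a.source[0], a.source[1], a.target[0], a.target[1], a.relation) for a in assertions)
    lines = ["\t".join(("source_scheme", "source_code", "target_scheme", "target_code", "relation"))]
    lines += ["\t".join(r) for r in rows]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Materialization
# ---------------------------------------------------------------------------


def _check_endpoints(schemes: Mapping[str, ConceptScheme], assertions: Iterable[MappingAssertion]) -> None:
    bad = []
    for a in assertions:
        for ref in (a.source, a.target):
            sch = schemes.get(ref[0])
            if sch is None or ref[1] not in sch:
                bad.append((a, ref))
    if bad:
        listing = "; ".join(f"{a.source}->{a.target} ({a.relation}): missing {ref}" for a, ref in bad[:10])
        raise IntegrityError(f"{len(bad)} unresolvable mapping endpoint(s): {listing}")


def materialize_close_match(
    schemes: Mapping[str, ConceptScheme],
    assertions: Iterable[MappingAssertion],
    config: DerivationConfig | None = None,
) -> CloseMatchClosure:
    """Least fixed point of the close-match derivation.

    Each close-strength assertion contributes arc(s) per the derivation
    config (default: both directions); the result is the transitive closure
    of that arc set.  Within-scheme ``broader`` edges never participate:
    hierarchy must not leak into cross-terminology matching, however rich
    the hierarchies are.  Reflexive pairs are not emitted.
    """
    assertions = list(assertions)
    config = config or DerivationConfig()
    _check_endpoints(schemes, assertions)
    g = nx.DiGraph()
    for a in assertions:
        for u, v in config.arcs_for(a):
            if u != v:
                g.add_edge(u, v)
    pairs: list[tuple[CodeRef, CodeRef]] = []
    for node in g.nodes:
        for reached in nx.descendants(g, node):
            if reached != node:
                pairs.append((node, reached))
    return CloseMatchClosure(pairs)


def materialize_group_links(
    closure: CloseMatchClosure,
    schemes: Mapping[str, ConceptScheme],
    target_scheme: str,
    target_level: str,
) -> set[ClosureLink]:
    """Single-hop code-to-group links into ``target_scheme`` at ``target_level``.

    ``group_link(a, g)`` holds iff some concept ``m`` of the target scheme is
    a close match of ``a`` (zero hops allowed when ``a`` is already in the
    target scheme) and ``g`` is an ancestor-or-self of ``m`` at exactly the
    target level.  Multiaxial codes yield one link per group.
    """
    tsch = schemes.get(target_scheme)
    if tsch is None:
        raise IntegrityError(f"unknown target scheme {target_scheme!r}")
    tsch.level_rank(target_level)  # raises on unknown level
    links: set[ClosureLink] = set()
    for scheme in schemes.values():
        for code in scheme.concepts:
            ref = (scheme.scheme_id, code)
            matched = {m for m in closure.matches(ref) if m[0] == target_scheme}
            if scheme.scheme_id == target_scheme:
                matched.add(ref)
            for _, m in matched:
                for grp in tsch.ancestors_at_level(m, target_level):
                    links.add(ClosureLink(ref, (target_scheme, grp), "group_link"))
    return links


def expand_query_codes(
    code: CodeRef,
    source_scheme: str,
    closure: CloseMatchClosure,
    schemes: Mapping[str, ConceptScheme],
) -> set[str]:
    """Codes of ``source_scheme`` that stand for ``code``, with descendants.

    The close matches of ``code`` within the source scheme (plus ``code``
    itself when it already belongs to that scheme) are unioned with all their
    narrower-transitive descendants.  An unmapped code yields the empty set,
    never an error: the caller decides how to surface unsatisfiability.
    """
    sch = schemes.get(code[0])
    if sch is None or code[1] not in sch:
        raise LookupError_(f"unknown code {code!r}")
    src = schemes.get(source_scheme)
    if src is None:
        raise LookupError_(f"unknown source scheme {source_scheme!r}")
    seeds = {c for s, c in closure.matches(code) if s == source_scheme}
    if code[0] == source_scheme:
        seeds.add(code[1])
    out = set(seeds)
    for s in seeds:
        out |= src.descendants(s)
    return out


# ---------------------------------------------------------------------------
# Closure cache (content-hash keyed, bit-stable TSV)
# ---------------------------------------------------------------------------


def closure_inputs_hash(
    schemes: Mapping[str, ConceptScheme],
    assertions: Iterable[MappingAssertion],
    config: DerivationConfig | None = None,
) -> str:
    """Stable content hash over schemes, assertions and derivation config."""
    h = hashlib.sha256()
    for sid in sorted(schemes):
        sch = schemes[sid]
        h.update(sid.encode())
        h.update("|".join(sch.level_names).encode())
        for code in sorted(sch.concepts):
            c = sch.concepts[code]
            h.update(f"{c.code}\t{c.label}\t{c.level}\t{'|'.join(sorted(c.broader))}\n".encode())
    for row in sorted((a.source, a.target, a.relation) for a in assertions):
        h.update(repr(row).encode())
    directions = (config or DerivationConfig()).directions
    h.update(repr(sorted(directions.items())).encode())
    return h.hexdigest()


def write_closure_cache(
    links: Iterable[ClosureLink], path: str | Path, inputs_hash: str
) -> None:
    rows = sorted((l.kind, l.a[0], l.a[1], l.b[0], l.b[1]) for l in links)
    lines = [f"#inputs_hash: {inputs_hash}", "kind\tscheme_a\tcode_a\tscheme_b\tcode_b"]
    lines += ["\t".join(r) for r in rows]
    Path(path).write_text("\n".join(lines) + "\n")


def load_closure_cache(path: str | Path, expected_hash: str | None = None) -> set[ClosureLink] | None:
    """Load a cache; returns None when absent or stale (hash mismatch)."""
    path = Path(path)
    if not path.exists():
        return None
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("#inputs_hash:"):
        raise ParseError(f"{path}: missing #inputs_hash header")
    cached_hash = lines[0].split(":", 1)[1].strip()
    if expected_hash is not None and cached_hash != expected_hash:
        return None
    links: set[ClosureLink] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip() or line.startswith("kind\t"):
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise ParseError(f"{path}:{lineno}: expected 5 fields")
        kind, sa, ca, sb, cb = parts
        links.add(ClosureLink((sa, ca), (sb, cb), kind))
    return links


def materialize_with_cache(
    schemes: Mapping[str, ConceptScheme],
    assertions: Iterable[MappingAssertion],
    cache_path: str | Path,
    config: DerivationConfig | None = None,
) -> CloseMatchClosure:
    """Close-match closure, served from a content-hash-keyed TSV cache.

    A stale or absent cache is rebuilt and rewritten; the cache file is
    bit-stable for identical inputs.
    """
    assertions = list(assertions)
    key = closure_inputs_hash(schemes, assertions, config)
    cached = load_closure_cache(cache_path, expected_hash=key)
    if cached is not None:
        return CloseMatchClosure((l.a, l.b) for l in cached if l.kind == "close_match")
    closure = materialize_close_match(schemes, assertions, config)
    write_closure_cache(closure.links(), cache_path, key)
    return closure
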