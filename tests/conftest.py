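"""Shared fixtures: a tiny hand-built terminology and a reference cohort.

All synthetic material is generated at test time from fixed seeds; nothing
is stored on disk.
"""

from __future__ import annotations

import pytest

from caseseries.synthetic_data import GeneratorSpec, generate_cohort, generate_terminologies
from caseseries.terminology import Concept, ConceptScheme, MappingAssertion, materialize_close_match


@pytest.fixture(scope="session")
def ref_spec():
    return GeneratorSpec(seed=1, n_patients=400)


@pytest.fixture(scope="session")
def bundle(ref_spec):
    return generate_terminologies(ref_spec)


@pytest.fixture(scope="session")
def cohort(ref_spec, bundle):
    return generate_cohort(ref_spec, bundle)


@pytest.fixture(scope="session")
def closure(bundle):
    return materialize_close_match(bundle.schemes, bundle.assertions)


def tiny_scheme(scheme_id: str = "T") -> ConceptScheme:
    """3-level chain with a 2-child leaf layer:

        root (TOP) -> mid (MID) -> leaf1, leaf2 (BOT)
    """
    return ConceptScheme(
        scheme_id,
        ("TOP", "MID", "BOT"),
        [
            Concept("root", scheme_id, "root", "TOP"),
            Concept("mid", scheme_id, "mid", "MID", frozenset({"root"})),
            Concept("leaf1", scheme_id, "leaf one", "BOT", frozenset({"mid"})),
            Concept("leaf2", scheme_id, "leaf two", "BOT", frozenset({"mid"})),
        ],
    )


@pytest.fixture()
def chain_scheme():
    return tiny_scheme()
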