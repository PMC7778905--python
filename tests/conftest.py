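"""Shared fixtures: synthetic corpora, models and namespaces.

Everything is generated programmatically; no data files ship with the
tests.
"""

from __future__ import annotations

import pytest

from xrefforge.fixtures import (
    DEFAULT_CONFIG,
    figure1_sources,
    generate_model,
    generate_sources,
)
from xrefforge.reconcile import reconcile_sources


@pytest.fixture(scope="session")
def figure1():
    """(metabolites, reactions, truth) of the five-in-four worked example."""
    return figure1_sources()


@pytest.fixture(scope="session")
def default_corpus():
    """Default-preset corpus at the session seed."""
    return generate_sources(DEFAULT_CONFIG)


@pytest.fixture(scope="session")
def default_namespace(default_corpus):
    mets, rxns, _ = default_corpus
    return reconcile_sources(mets, rxns)


@pytest.fixture(scope="session")
def status_model():
    """Status-mix model with per-reaction ground-truth statuses."""
    return generate_model()
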