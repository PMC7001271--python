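from collections import deque

import pytest
from hypothesis import HealthCheck, settings

from phenodiff import Ontology, OntologyTerm, datasets

settings.register_profile(
    "default",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def toy_ontology():
    return datasets.toy_ontology()


@pytest.fixture()
def diamond_ontology():
    """A -> root with D reaching A along two paths (D->B->A, D->C->A)."""
    return Ontology(
        [
            OntologyTerm(id="TT:0000001", label="A"),
            OntologyTerm(id="TT:0000002", label="B", parents=frozenset({"TT:0000001"})),
            OntologyTerm(id="TT:0000003", label="C", parents=frozenset({"TT:0000001"})),
            OntologyTerm(
                id="TT:0000004",
                label="D",
                parents=frozenset({"TT:0000002", "TT:0000003"}),
            ),
        ]
    )


def bfs_ancestors(ontology, term, include_self=False):
    """Independent reachability oracle: breadth-first walk over parent sets."""
    seen = set()
    queue = deque(ontology.terms[term].parents)
    while queue:
        current = queue.popleft()
        if current in seen:
            continue
        seen.add(current)
        queue.extend(ontology.terms[current].parents)
    if include_self:
        seen.add(term)
    return seen
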