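import pytest

from ontoenrich.annotations import build_corpus, read_annotations
from ontoenrich.fixtures import SPECIES_A, FixtureSpec, generate_fixture
from ontoenrich.ontology import parse_obo

CHAIN_OBO = """\
format-version: 1.2

[Term]
id: GO:0000001
name: root

[Term]
id: GO:0000002
name: mid
is_a: GO:0000001

[Term]
id: GO:0000003
name: leaf
is_a: GO:0000002
"""


@pytest.fixture
def chain_graph():
    """Three-term chain leaf -> mid -> root."""
    return parse_obo(CHAIN_OBO)


@pytest.fixture(scope="session")
def fixture_bundle():
    return generate_fixture(FixtureSpec(seed=42, n_terms=50, branching=3, n_genes=200, annotation_density=3))


@pytest.fixture(scope="session")
def fixture_graph(fixture_bundle):
    return parse_obo(fixture_bundle.obo_text)


@pytest.fixture(scope="session")
def fixture_corpus(fixture_bundle, fixture_graph):
    records = read_annotations(fixture_bundle.annotation_tsv, format="tsv")
    return build_corpus(records, fixture_graph, SPECIES_A, "SYN")


def naive_ancestor_closure(parent_map: dict) -> dict:
    """Brute-force transitive closure by repeated edge expansion.

    Independent of the graph-library path: iterate 'add parents of
    everything reached so far' until no set grows.
    """
    closure = {node: set(parents) for node, parents in parent_map.items()}
    changed = True
    while changed:
        changed = False
        for node in closure:
            extra = set()
            for anc in closure[node]:
                extra |= set(parent_map.get(anc, ()))
            if not extra <= closure[node]:
                closure[node] |= extra
                changed = True
    return closure
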