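import pytest

from gosum.ontology import TermRecord, build_ontology


def make_graph(edge_list, extra_terms=(), names=None):
    """Build an OntologyGraph from (child, parent[, relation]) tuples."""
    edges = []
    term_ids = set(extra_terms)
    for e in edge_list:
        child, parent = e[0], e[1]
        rel = e[2] if len(e) > 2 else "is_a"
        edges.append((child, parent, rel))
        term_ids.update((child, parent))
    names = names or {}
    terms = {
        t: TermRecord(term_id=t, name=names.get(t, f"term {t}"),
                      namespace="synthetic")
        for t in term_ids
    }
    return build_ontology(terms, edges)


@pytest.fixture
def chain():
    """root <- a <- b, a 3-term is_a chain."""
    return make_graph([("a", "root"), ("b", "a")])


@pytest.fixture
def diamond():
    """root <- a, root <- b, a <- d, b <- c, c <- d.

    d has parents a (level 2) and c (level 3): its shortest-path level
    is 3 even though a length-4 path to the root exists.
    """
    return make_graph([
        ("a", "root"), ("b", "root"), ("d", "a"), ("c", "b"), ("d", "c"),
    ])
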