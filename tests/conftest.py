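"""Shared fixtures: toy hierarchies, the printed context, brute-force oracles."""

from itertools import chain, combinations

import pytest

from hoirefine import (
    FormalConcept,
    FormalContext,
    compute_closure,
    derive_extent,
    derive_intent,
)
from hoirefine.synthetic_fixtures import table1_context, table1_ontology, toy_graph


@pytest.fixture
def toy():
    """ROOT; A,B under ROOT; A1,A2 under A. A1 has blood-pressure synonyms."""
    return toy_graph()


@pytest.fixture
def toy_closure(toy):
    return compute_closure(toy)


@pytest.fixture
def table1():
    return table1_context()


@pytest.fixture
def table1_chain():
    graph = table1_ontology()
    return graph, compute_closure(graph)


def powerset(items):
    items = list(items)
    return chain.from_iterable(combinations(items, r) for r in range(len(items) + 1))


def brute_force_concepts(K: FormalContext) -> set[FormalConcept]:
    """Independent oracle: close every object subset (2^|G| of them)."""
    out = set()
    for A in powerset(K.objects):
        B = derive_intent(A, K)
        out.add(FormalConcept(extent=derive_extent(B, K), intent=B))
    return out


def reachability_closure(graph):
    """Brute-force ancestor sets: one-step parent expansion to fixpoint."""
    anc = {cid: set(c.parent_ids) for cid, c in graph.concepts.items()}
    changed = True
    while changed:
        changed = False
        for cid in anc:
            new = set().union(*(anc[p] | {p} for p in anc[cid])) if anc[cid] else set()
            if not new <= anc[cid]:
                anc[cid] |= new
                changed = True
    return anc


TSV_HEADER = "concept_id\tontology_id\tlabel\tsynonyms\tparents\txrefs\n"


def write_tsv(path, rows):
    """rows: iterable of 6-tuples matching the TSV dialect."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(TSV_HEADER)
        for row in rows:
            fh.write("\t".join(row) + "\n")
    return path
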