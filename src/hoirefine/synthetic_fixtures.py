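"""Deterministic synthetic ontologies, planted HOI subtrees and contexts.

Everything every pipeline stage needs to be exercised without downloading a
terminology: seeded random DAG ontologies with synonyms and cross-ontology
xrefs, a planted gold subtree standing in for one condition's term set, the
hypertriglyceridemia 4x4 context extract (with the chain ontology whose
ancestry reproduces its non-empty columns), and random binary contexts for
lattice stress tests.

Synonym text is deliberately synthetic ("term-<id>-<k>"): lexical matching
is exact-string, so imitation medical vocabulary would add nothing but
accidental ambiguity.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path

from hoirefine.fca_core import FormalContext
from hoirefine.ontology_store import Concept, OntologyGraph


@dataclass
class FixtureSpec:
    """Parameters of a generated single-root DAG ontology.

    Defaults give a mid-size ontology (120 concepts, ≤2 parents, 6 levels)
    — big enough for non-trivial lattices, small enough for exhaustive
    oracles in tests.
    """

    n_concepts: int = 120
    max_parents: int = 2
    depth: int = 6
    synonyms_per_concept: int = 1
    xref_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_concepts < 1 or self.max_parents < 1 or self.depth < 1:
            raise ValueError("counts must be positive")
        if self.synonyms_per_concept < 0:
            raise ValueError("synonyms_per_concept must be >= 0")
        if not 0.0 <= self.xref_rate <= 1.0:
            raise ValueError("xref_rate must be in [0, 1]")


def generate_dag_ontology(spec: FixtureSpec, ontology_id: str = "synth") -> OntologyGraph:
    """Single-root random DAG, acyclic by construction.

    Concepts are assigned to levels 0..depth-1 (level 0 = the unique root);
    each non-root concept draws 1..max_parents parents uniformly from
    strictly shallower levels, so no cycle can arise.  Byte-for-byte
    reproducible under (seed, spec).
    """
    rng = random.Random(spec.seed)
    n = spec.n_concepts
    ids = [f"{ontology_id}:{i:04d}" for i in range(n)]

    # level assignment: root alone at level 0; remaining concepts spread so
    # every level below depth is non-empty when n allows
    levels: dict[str, int] = {ids[0]: 0}
    n_levels = min(spec.depth, n)
    for k, cid in enumerate(ids[1:], start=1):
        levels[cid] = k if k < n_levels else rng.randint(1, n_levels - 1) if n_levels > 1 else 0

    by_level: dict[int, list[str]] = {}
    for cid in ids:
        by_level.setdefault(levels[cid], []).append(cid)

    graph = OntologyGraph()
    for cid in ids:
        lv = levels[cid]
        if lv == 0:
            parents: set[str] = set()
        else:
            pool = [c for c in ids if levels[c] < lv]
            k = rng.randint(1, min(spec.max_parents, len(pool)))
            parents = set(rng.sample(pool, k))
        synonyms = {f"term-{cid}-{k}" for k in range(spec.synonyms_per_concept)}
        graph.add(
            Concept(
                concept_id=cid,
                ontology_ids={ontology_id},
                preferred_label=f"label {cid}",
                synonyms=synonyms | {f"label {cid}"},
                parent_ids=parents,
                xrefs={f"XR:{cid}"} if rng.random() < spec.xref_rate else set(),
            )
        )
    graph.validate()
    return graph


def plant_hoi(graph: OntologyGraph, seed: int = 0) -> tuple[list[str], set[str]]:
    """Plant a gold HOI subtree and return (query terms, gold concept set).

    Picks an internal concept h (has both ancestors and descendants when
    possible); gold = {h} ∪ strict descendants of h — downward-closed, like
    a condition's full term subtree.  h receives a unique multi-word
    synonym and a random sample of other gold members receive unique
    synonyms of their own; those synonym strings are the query vocabulary.
    Mutates ``graph`` in place (adds synonyms).
    """
    from hoirefine.ontology_store import compute_closure

    rng = random.Random(seed)
    closure = compute_closure(graph)
    internal = sorted(
        cid
        for cid in graph.concepts
        if closure.strict_descendants(cid) and closure.strict_ancestors(cid)
    )
    if not internal:
        raise ValueError("graph has no internal concept to plant an HOI on")
    h = rng.choice(internal)
    gold = {h} | closure.strict_descendants(h)

    tag = f"planted {seed} {h.replace(':', ' ')}"
    graph.concepts[h].synonyms.add(tag)
    query_terms = [tag]
    others = sorted(gold - {h})
    for cid in rng.sample(others, min(3, len(others))):
        syn = f"planted {seed} extra {cid.replace(':', ' ')}"
        graph.concepts[cid].synonyms.add(syn)
        query_terms.append(syn)
    return query_terms, gold


# --- the printed hypertriglyceridemia context extract ---------------------

_T1_OBJECTS = ("10365", "12115", "10406", "191723")
_T1_ATTRIBUTES = ("0", "19118", "740154", "6260")
_T1_ROWS = {
    "10365": ("0", "19118", "740154"),
    "12115": ("0", "19118", "740154"),
    "10406": ("0", "19118"),
    "191723": ("0", "19118"),
}


def table1_context() -> FormalContext:
    """The published 4x4 hypertriglyceridemia context extract.

    Objects 10365/12115/10406/191723 (10365 = hyperlipoproteinemia type
    IV), attributes 0 (top concept), 19118, 740154 and 6260; ten 1-cells.
    Column 6260 is all-zero in the extract and survives file round-trips,
    though ancestry-built contexts never generate empty columns.
    """
    incidence = frozenset(
        (g, m) for g, ms in _T1_ROWS.items() for m in ms
    )
    return FormalContext(
        objects=_T1_OBJECTS, attributes=_T1_ATTRIBUTES, incidence=incidence
    )


def table1_ontology() -> OntologyGraph:
    """Chain ontology whose strict ancestry reproduces the extract's
    non-empty columns: 10365,12115 ⊑ 740154 ⊑ 19118 ⊑ 0 and
    10406,191723 ⊑ 19118."""
    graph = OntologyGraph()
    spec = {
        "0": set(),
        "19118": {"0"},
        "740154": {"19118"},
        "10365": {"740154"},
        "12115": {"740154"},
        "10406": {"19118"},
        "191723": {"19118"},
    }
    labels = {
        "0": "top concept",
        "19118": "lipid metabolism disorder",
        "740154": "hypertriglyceridemia",
        "10365": "hyperlipoproteinemia type IV",
        "12115": "familial hypertriglyceridemia",
        "10406": "hyperlipidemia",
        "191723": "hyperlipoproteinemia",
    }
    for cid, parents in spec.items():
        graph.add(
            Concept(
                concept_id=cid,
                ontology_ids={"demo"},
                preferred_label=labels[cid],
                synonyms={labels[cid]},
                parent_ids=parents,
            )
        )
    graph.validate()
    return graph


def generate_random_context(
    nG: int, nM: int, density: float, seed: int = 0
) -> FormalContext:
    """Random binary context: each cell 1 with probability ``density``."""
    if not 0.0 <= density <= 1.0:
        raise ValueError("density must be in [0, 1]")
    rng = random.Random(seed)
    objects = tuple(f"g{i}" for i in range(nG))
    attributes = tuple(f"m{j}" for j in range(nM))
    incidence = frozenset(
        (g, m) for g in objects for m in attributes if rng.random() < density
    )
    return FormalContext(objects=objects, attributes=attributes, incidence=incidence)


def write_ontology_tsv(graph: OntologyGraph, path: str | Path) -> None:
    """Serialize a graph in the loader's TSV dialect (round-trip safe)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("concept_id\tontology_id\tlabel\tsynonyms\tparents\txrefs\n")
        for cid in sorted(graph.concepts):
            c = graph.concepts[cid]
            fh.write(
                "\t".join(
                    [
                        c.concept_id,
                        "|".join(sorted(c.ontology_ids)),
                        c.preferred_label,
                        "|".join(sorted(c.synonyms)),
                        "|".join(sorted(c.parent_ids)),
                        "|".join(sorted(c.xrefs)),
                    ]
                )
                + "\n"
            )


def toy_graph() -> OntologyGraph:
    """Five-concept fixture: ROOT; A,B ⊑ ROOT; A1,A2 ⊑ A.

    A1 carries the synonyms 'hypertension' and 'high blood pressure' used
    throughout the matcher tests.
    """
    graph = OntologyGraph()
    rows = [
        ("ROOT", set(), "root", set()),
        ("A", {"ROOT"}, "condition a", set()),
        ("B", {"ROOT"}, "condition b", set()),
        ("A1", {"A"}, "condition a1", {"hypertension", "high blood pressure"}),
        ("A2", {"A"}, "condition a2", set()),
    ]
    for cid, parents, label, syns in rows:
        graph.add(
            Concept(
                concept_id=cid,
                ontology_ids={"toy"},
                preferred_label=label,
                synonyms=syns | {label},
                parent_ids=parents,
            )
        )
    graph.validate()
    return graph
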