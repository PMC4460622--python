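"""Loading, merging and indexing of subsumption hierarchies.

Concepts come from one or more source ontologies (OBO files or a simple TSV
dialect).  Cross-ontology mappings (xrefs, CUI-style shared keys) merge
equivalent concepts into single nodes, so that traversal of the merged graph
"hops" across ontologies for free.  The subsumption transitive closure is
materialized once into a :class:`ClosureTable` of strict ancestor and
descendant sets; every downstream stage (expansion, context construction,
coverage ratios) reads from it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

_TSV_HEADER = ["concept_id", "ontology_id", "label", "synonyms", "parents", "xrefs"]


class OntologyLoadError(ValueError):
    """Raised when an ontology file violates the format contract."""


class CyclicOntologyError(ValueError):
    """Raised when an operation requiring a DAG meets a cyclic graph."""

    def __init__(self, cycle: list[str]):
        self.cycle = cycle
        super().__init__(f"subsumption graph contains a cycle: {' -> '.join(cycle)}")


@dataclass
class Concept:
    """A node of the (possibly merged) subsumption graph.

    ``concept_id`` is an opaque CUI-like key, unique within a graph.
    ``parent_ids`` holds direct is-a parents only; transitive ancestry lives
    in the :class:`ClosureTable`.  ``xrefs`` are shared mapping keys used by
    :func:`merge_on_xrefs`.
    """

    concept_id: str
    ontology_ids: set[str] = field(default_factory=set)
    preferred_label: str = ""
    synonyms: set[str] = field(default_factory=set)
    parent_ids: set[str] = field(default_factory=set)
    xrefs: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.concept_id:
            raise ValueError("concept_id must be non-empty")
        if self.concept_id in self.parent_ids:
            raise ValueError(f"concept {self.concept_id!r} lists itself as parent")


@dataclass
class OntologyGraph:
    """Map of concept_id -> Concept plus the derived root set."""

    concepts: dict[str, Concept] = field(default_factory=dict)

    @property
    def root_ids(self) -> set[str]:
        return {cid for cid, c in self.concepts.items() if not c.parent_ids}

    def __len__(self) -> int:
        return len(self.concepts)

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.concepts

    def add(self, concept: Concept) -> None:
        if concept.concept_id in self.concepts:
            raise OntologyLoadError(f"duplicate concept_id {concept.concept_id!r}")
        self.concepts[concept.concept_id] = concept

    def validate(self) -> None:
        """Check referential integrity of parent links."""
        for cid, c in self.concepts.items():
            for p in c.parent_ids:
                if p not in self.concepts:
                    raise OntologyLoadError(
                        f"concept {cid!r} references unknown parent {p!r}"
                    )

    def to_networkx(self) -> nx.DiGraph:
        """Edges point child -> parent (the direction of subsumption)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.concepts)
        for cid, c in self.concepts.items():
            for p in c.parent_ids:
                g.add_edge(cid, p)
        return g


@dataclass
class ClosureTable:
    """Materialized strict transitive closure of the is-a hierarchy.

    ``ancestors[c]`` / ``descendants[c]`` never contain ``c`` itself; callers
    needing the reflexive closure add the concept explicitly.
    """

    ancestors: dict[str, set[str]]
    descendants: dict[str, set[str]]

    def strict_ancestors(self, concept_id: str) -> set[str]:
        return self.ancestors.get(concept_id, set())

    def strict_descendants(self, concept_id: str) -> set[str]:
        return self.descendants.get(concept_id, set())


def _split_multi(cell: str) -> set[str]:
    cell = cell.strip()
    if not cell:
        return set()
    return {v.strip() for v in cell.split("|") if v.strip()}


def load_ontology_tsv(path: str | Path) -> OntologyGraph:
    """Load a single-ontology TSV file.

    Format: UTF-8, tab-separated, one header line
    ``concept_id  ontology_id  label  synonyms  parents  xrefs`` with
    pipe-separated multi-value cells (empty cell = empty set).  The preferred
    label is always included among the synonyms.
    """
    path = Path(path)
    graph = OntologyGraph()
    with path.open(encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\n")
        header = header_line.split("\t")
        if header != _TSV_HEADER:
            raise OntologyLoadError(
                f"{path}: bad header {header!r}; expected {_TSV_HEADER!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != len(_TSV_HEADER):
                raise OntologyLoadError(
                    f"{path}:{lineno}: expected {len(_TSV_HEADER)} fields, "
                    f"got {len(cells)}"
                )
            cid, ont, label, syns, parents, xrefs = cells
            concept = Concept(
                concept_id=cid.strip(),
                ontology_ids={ont.strip()} if ont.strip() else set(),
                preferred_label=label.strip(),
                synonyms=_split_multi(syns) | ({label.strip()} if label.strip() else set()),
                parent_ids=_split_multi(parents),
                xrefs=_split_multi(xrefs),
            )
            try:
                graph.add(concept)
            except OntologyLoadError as e:
                raise OntologyLoadError(f"{path}:{lineno}: {e}") from e
    graph.validate()
    return graph


def load_obo(path: str | Path) -> OntologyGraph:
    """Load an OBO 1.2/1.4 ontology via :mod:`obonet`.

    Obsolete terms are skipped (a count is logged).  ``is_a`` lines define
    parents, ``synonym`` lines populate synonyms, ``xref`` lines the merge
    keys.  Parents pointing at obsolete/absent terms are dropped with a log
    message rather than failing, matching common OBO practice.
    """
    path = Path(path)
    try:
        g = obonet.read_obo(str(path), ignore_obsolete=False)
    except Exception as e:  # pragma: no cover - obonet raises various types
        raise OntologyLoadError(f"{path}: OBO parse error: {e}") from e

    ont_name = g.graph.get("ontology") or g.graph.get("name") or path.stem
    graph = OntologyGraph()
    n_obsolete = 0
    kept: dict[str, dict] = {}
    for node, data in g.nodes(data=True):
        if data.get("is_obsolete") in ("true", True):
            n_obsolete += 1
            continue
        kept[node] = data
    if n_obsolete:
        logger.info("%s: skipped %d obsolete terms", path, n_obsolete)

    for node, data in kept.items():
        label = data.get("name", "")
        synonyms = {label} if label else set()
        for syn_line in data.get("synonym", []):
            # synonym line: "text" SCOPE [...]  — obonet keeps the raw value
            if '"' in syn_line:
                text = syn_line.split('"')[1]
                if text:
                    synonyms.add(text)
        parents = {p for p in data.get("is_a", []) if p in kept}
        xrefs = set(data.get("xref", []))
        graph.add(
            Concept(
                concept_id=node,
                ontology_ids={ont_name},
                preferred_label=label,
                synonyms=synonyms,
                parent_ids=parents,
                xrefs=xrefs,
            )
        )
    graph.validate()
    return graph


def merge_on_xrefs(graphs: Iterable[OntologyGraph]) -> OntologyGraph:
    """Merge graphs by xref-connected components.

    Two concepts belong to the same merged node iff they are connected
    through shared xref keys (transitively: a↔b, b↔c collapse to one node).
    Each component's parent ids, synonyms, xrefs and ontology labels are
    unioned; the preferred label comes from the first-loaded member, other
    labels survive as synonyms.  Graphs without any xref overlap merge to a
    plain disjoint union.
    """
    graphs = list(graphs)
    members: list[Concept] = []
    for g in graphs:
        members.extend(g.concepts[cid] for cid in g.concepts)

    # union-find over concept ids; xref keys act as virtual nodes
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for c in members:
        parent.setdefault(c.concept_id, c.concept_id)
        for x in c.xrefs:
            key = f"\x00xref:{x}"
            parent.setdefault(key, key)
            union(c.concept_id, key)

    # group concepts by component, preserving load order
    comp_members: dict[str, list[Concept]] = {}
    for c in members:
        comp_members.setdefault(find(c.concept_id), []).append(c)

    # representative id = first-loaded member's id
    rep_of: dict[str, str] = {}
    for group in comp_members.values():
        rep = group[0].concept_id
        for c in group:
            rep_of[c.concept_id] = rep

    merged = OntologyGraph()
    for group in comp_members.values():
        first = group[0]
        node = Concept(
            concept_id=first.concept_id,
            ontology_ids=set().union(*(c.ontology_ids for c in group)),
            preferred_label=first.preferred_label,
            synonyms=set().union(*(c.synonyms for c in group))
            | {c.preferred_label for c in group if c.preferred_label},
            parent_ids=set(),
            xrefs=set().union(*(c.xrefs for c in group)),
        )
        raw_parents = set().union(*(c.parent_ids for c in group))
        node.parent_ids = {rep_of[p] for p in raw_parents} - {node.concept_id}
        merged.concepts[node.concept_id] = node
    merged.validate()
    return merged


def detect_cycles(graph: OntologyGraph) -> list[list[str]]:
    """Return witness cycles of the subsumption graph ([] iff it is a DAG).

    Cycles typically appear only after cross-ontology merging, where
    differing abstraction levels can invert a parent/child pair.
    """
    g = graph.to_networkx()
    try:
        cycle_edges = nx.find_cycle(g, orientation="original")
    except nx.NetworkXNoCycle:
        return []
    cycle = [e[0] for e in cycle_edges]
    return [cycle]


def compute_closure(graph: OntologyGraph) -> ClosureTable:
    """Materialize strict ancestor/descendant sets for every concept.

    Requires an acyclic graph; a cycle raises :class:`CyclicOntologyError`
    carrying one witness cycle.  Computed in one pass over a topological
    order, so cost is O(edges x average-set-size).
    """
    g = graph.to_networkx()  # edges child -> parent
    try:
        order = list(nx.topological_sort(g))
    except nx.NetworkXUnfeasible:
        raise CyclicOntologyError(detect_cycles(graph)[0])

    ancestors: dict[str, set[str]] = {cid: set() for cid in graph.concepts}
    # child->parent edges put children before parents in `order`;
    # reverse so every parent's ancestor set exists before its children need it
    for cid in reversed(order):
        acc: set[str] = set()
        for p in graph.concepts[cid].parent_ids:
            acc.add(p)
            acc |= ancestors[p]
        ancestors[cid] = acc

    descendants: dict[str, set[str]] = {cid: set() for cid in graph.concepts}
    for cid, ancs in ancestors.items():
        for a in ancs:
            descendants[a].add(cid)
    return ClosureTable(ancestors=ancestors, descendants=descendants)
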