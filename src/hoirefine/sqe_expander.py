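"""Semantic query expansion along the subsumption hierarchy.

Downward: two rounds of sub-concept derivation ("2-hop").  A round derives
the sub-concepts of the current set; because equivalent concepts from
different source ontologies are merged into shared nodes, each round hops
across every ontology containing the concepts.  Recursion to a fixed point
is deliberately avoided — mixed abstraction levels across ontologies induce
cycles in practice — so expansion always stops after two rounds.

Upward: a minimal cover of the lexical matches by super-concepts, found by
greedy set cover with deterministic tie-breaks (exact minimum cover is
NP-hard and nothing downstream needs it).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

from hoirefine.ontology_store import ClosureTable

HopMode = Literal["closure", "edge"]


@dataclass
class ExpansionResult:
    """C (seed) -> C' (first hop) -> C'' (seed ∪ C' ∪ second hop)."""

    seed: set[str]
    first_hop: set[str]
    second_hop: set[str]
    cover: set[str]


def expand_down(
    C: Iterable[str], closure: ClosureTable, mode: HopMode = "closure"
) -> set[str]:
    """One derivation round: the strict sub-concepts of C.

    ``closure`` mode (default) takes the full strict-descendant closure in
    the merged graph; ``edge`` mode takes direct children only (descendants
    with no intermediate concept between them and a member of C).
    """
    C = set(C)
    if mode == "closure":
        out: set[str] = set()
        for c in C:
            out |= closure.strict_descendants(c)
        return out
    elif mode == "edge":
        out = set()
        for c in C:
            for d in closure.strict_descendants(c):
                # direct child iff c is a parent at distance one:
                # d's ancestors include c, and no other descendant of c
                # lies strictly between d and c
                between = closure.strict_ancestors(d) & closure.strict_descendants(c)
                if not between:
                    out.add(d)
        return out
    raise ValueError(f"unknown hop mode {mode!r}")


def two_hop(
    C: Iterable[str], closure: ClosureTable, mode: HopMode = "closure"
) -> ExpansionResult:
    """Two rounds of downward derivation: C -> C' -> C''.

    C'' = C ∪ C' ∪ expand_down(C'); never recurses further.  With
    ``closure`` mode on a single merged graph the second round is already
    saturated; it matters when expansion is run per-ontology or in ``edge``
    mode.
    """
    C = set(C)
    first = expand_down(C, closure, mode)
    second = C | first | expand_down(first, closure, mode)
    return ExpansionResult(seed=C, first_hop=first, second_hop=second, cover=set())


def _depth(cid: str, closure: ClosureTable) -> int:
    """Depth proxy: number of strict ancestors (roots have 0)."""
    return len(closure.strict_ancestors(cid))


def minimal_ancestor_cover(
    matches: Iterable[str], closure: ClosureTable
) -> set[str]:
    """Greedy super-concept cover of the lexical matches.

    Every match with at least one parent must have a strict ancestor in the
    returned set; parentless matches are included verbatim.  Greedy rule:
    repeatedly pick the candidate ancestor covering the most uncovered
    matches, breaking ties by greater depth (more specific wins), then by
    lexicographic id.
    """
    matches = set(matches)
    cover: set[str] = set()
    uncovered = set()
    for m in matches:
        if closure.strict_ancestors(m):
            uncovered.add(m)
        else:
            cover.add(m)

    # candidate -> matches it covers
    coverage: dict[str, set[str]] = {}
    for m in uncovered:
        for a in closure.strict_ancestors(m):
            coverage.setdefault(a, set()).add(m)

    while uncovered:
        best = min(
            coverage,
            key=lambda a: (
                -len(coverage[a] & uncovered),
                -_depth(a, closure),
                a,
            ),
        )
        gained = coverage[best] & uncovered
        if not gained:  # defensive; cannot happen while uncovered non-empty
            break
        cover.add(best)
        uncovered -= gained
        del coverage[best]
    return cover
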