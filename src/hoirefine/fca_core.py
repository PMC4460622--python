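"""Formal concept analysis: contexts, derivation operators, lattices.

A formal context K = (G, M, I) is a binary incidence between objects G and
attributes M.  The derivation operators

    A' = {m in M | for all g in A: (g, m) in I}      (A subset of G)
    B' = {g in G | for all m in B: (g, m) in I}      (B subset of M)

form a Galois connection; a formal concept is a pair (A, B) with A' = B and
B' = A — a maximal rectangle of the incidence matrix.  Concepts ordered by
(A1, B1) <= (A2, B2) iff A1 ⊆ A2 (equivalently B2 ⊆ B1) form a complete
lattice.

Enumeration uses Ganter's NextClosure algorithm in lectic order over attribute
sets: deterministic, memory-light, and O(|concepts| x |G| x |M|^2) worst
case, which is ample for the context sizes produced here (hundreds of
objects/attributes).  A brute-force enumerator over all object subsets is
kept in the test suite as an independent oracle.

In this package's pipeline, objects are the query-matched/derived ontology
concepts and attributes their strict super-concepts (`build_context`), so
the lattice organizes the expansion for top-down coverage pruning.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from hoirefine.ontology_store import ClosureTable

DEFAULT_CELL_LIMIT = 10**6


class ContextSizeError(ValueError):
    """Raised when |G| x |M| exceeds the configured cell limit."""


@dataclass
class FormalContext:
    """Binary incidence between ordered object and attribute sets.

    Orderings are deterministic (sorted ids) so that enumeration output is
    byte-stable.  Internally rows are bitmasks over attribute positions.
    """

    objects: tuple[str, ...]
    attributes: tuple[str, ...]
    incidence: frozenset[tuple[str, str]]

    # derived lookup structures
    _obj_pos: dict[str, int] = field(init=False, repr=False, compare=False)
    _att_pos: dict[str, int] = field(init=False, repr=False, compare=False)
    _row_bits: list[int] = field(init=False, repr=False, compare=False)
    _col_bits: list[int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.objects = tuple(sorted(set(self.objects)))
        self.attributes = tuple(sorted(set(self.attributes)))
        self._obj_pos = {g: i for i, g in enumerate(self.objects)}
        self._att_pos = {m: j for j, m in enumerate(self.attributes)}
        for g, m in self.incidence:
            if g not in self._obj_pos or m not in self._att_pos:
                raise ValueError(f"incidence pair ({g!r}, {m!r}) outside G x M")
        self._row_bits = [0] * len(self.objects)
        self._col_bits = [0] * len(self.attributes)
        for g, m in self.incidence:
            i, j = self._obj_pos[g], self._att_pos[m]
            self._row_bits[i] |= 1 << j
            self._col_bits[j] |= 1 << i

    @property
    def n_objects(self) -> int:
        return len(self.objects)

    @property
    def n_attributes(self) -> int:
        return len(self.attributes)

    def has(self, g: str, m: str) -> bool:
        return (g, m) in self.incidence

    # bitmask <-> id-set conversions
    def _objs_from_bits(self, bits: int) -> frozenset[str]:
        return frozenset(
            g for i, g in enumerate(self.objects) if bits >> i & 1
        )

    def _atts_from_bits(self, bits: int) -> frozenset[str]:
        return frozenset(
            m for j, m in enumerate(self.attributes) if bits >> j & 1
        )

    def _obj_bits(self, A: Iterable[str]) -> int:
        bits = 0
        for g in A:
            bits |= 1 << self._obj_pos[g]
        return bits

    def _att_bits(self, B: Iterable[str]) -> int:
        bits = 0
        for m in B:
            bits |= 1 << self._att_pos[m]
        return bits

    def intent_bits(self, obj_bits: int) -> int:
        out = (1 << self.n_attributes) - 1
        i = 0
        while obj_bits:
            if obj_bits & 1:
                out &= self._row_bits[i]
            obj_bits >>= 1
            i += 1
        return out

    def extent_bits(self, att_bits: int) -> int:
        out = (1 << self.n_objects) - 1
        j = 0
        while att_bits:
            if att_bits & 1:
                out &= self._col_bits[j]
            att_bits >>= 1
            j += 1
        return out


@dataclass(frozen=True)
class FormalConcept:
    """A closed (extent, intent) pair of some context."""

    extent: frozenset[str]
    intent: frozenset[str]

    def as_sorted(self) -> tuple[list[str], list[str]]:
        return sorted(self.extent), sorted(self.intent)


@dataclass
class ConceptLattice:
    """All formal concepts of a context plus the Hasse cover relation.

    ``concepts`` is sorted by (extent size, sorted extent ids) so output is
    deterministic; ``hasse`` holds (lower, upper) index pairs of the cover
    relation (transitive reduction of <=).
    """

    context: FormalContext
    concepts: list[FormalConcept]
    hasse: list[tuple[int, int]] = field(default_factory=list)

    @property
    def top(self) -> FormalConcept:
        return max(self.concepts, key=lambda c: len(c.extent))

    @property
    def bottom(self) -> FormalConcept:
        return min(self.concepts, key=lambda c: len(c.extent))

    def __len__(self) -> int:
        return len(self.concepts)


def derive_intent(A: Iterable[str], K: FormalContext) -> frozenset[str]:
    """A' — attributes common to every object of A (all of M when A = ∅)."""
    return K._atts_from_bits(K.intent_bits(K._obj_bits(A)))


def derive_extent(B: Iterable[str], K: FormalContext) -> frozenset[str]:
    """B' — objects carrying every attribute of B (all of G when B = ∅)."""
    return K._objs_from_bits(K.extent_bits(K._att_bits(B)))


def is_formal_concept(A: Iterable[str], B: Iterable[str], K: FormalContext) -> bool:
    A, B = frozenset(A), frozenset(B)
    return derive_intent(A, K) == B and derive_extent(B, K) == A


def enumerate_concepts(
    K: FormalContext, cell_limit: int = DEFAULT_CELL_LIMIT
) -> ConceptLattice:
    """All formal concepts of K via NextClosure, plus the Hasse diagram.

    Closures are enumerated in lectic order over attribute sets, then sorted
    by (extent size, extent ids) for a stable public order.  Raises
    :class:`ContextSizeError` when |G| x |M| exceeds ``cell_limit`` (raise the
    limit explicitly for bigger contexts).
    """
    if K.n_objects * K.n_attributes > cell_limit:
        raise ContextSizeError(
            f"context has {K.n_objects} x {K.n_attributes} cells, "
            f"over the limit of {cell_limit}; pass a larger cell_limit"
        )
    nM = K.n_attributes

    def close(att_bits: int) -> int:
        return K.intent_bits(K.extent_bits(att_bits))

    intents: list[int] = []
    # lectic order: attribute j is "smaller" the lower its index; the
    # NextClosure step tries to add attributes from the largest index down
    current = close(0)
    intents.append(current)
    full = (1 << nM) - 1
    while current != full:
        nxt = None
        for j in range(nM - 1, -1, -1):
            if current >> j & 1:
                continue
            below = (1 << j) - 1
            candidate = close((current & below) | (1 << j))
            # candidate is the next closure iff it adds nothing below j
            if (candidate & below) == (current & below):
                nxt = candidate
                break
        if nxt is None:  # full set already closed and reached
            break
        current = nxt
        intents.append(current)
        if current == full:
            break

    concepts = [
        FormalConcept(
            extent=K._objs_from_bits(K.extent_bits(ib)),
            intent=K._atts_from_bits(ib),
        )
        for ib in set(intents)
    ]
    concepts.sort(key=lambda c: (len(c.extent), sorted(c.extent), sorted(c.intent)))
    lattice = ConceptLattice(context=K, concepts=concepts)
    lattice.hasse = hasse_edges(lattice)
    return lattice


def order_leq(F1: FormalConcept, F2: FormalConcept) -> bool:
    """(A1,B1) <= (A2,B2) iff A1 ⊆ A2 and B2 ⊆ B1."""
    return F1.extent <= F2.extent and F2.intent <= F1.intent


def hasse_edges(lattice: ConceptLattice) -> list[tuple[int, int]]:
    """Cover edges (i, j): concept i < concept j with nothing in between."""
    cs = lattice.concepts
    n = len(cs)
    lt = [[i != j and order_leq(cs[i], cs[j]) for j in range(n)] for i in range(n)]
    edges = []
    for i in range(n):
        for j in range(n):
            if not lt[i][j]:
                continue
            if any(lt[i][k] and lt[k][j] for k in range(n)):
                continue
            edges.append((i, j))
    return edges


def verify_galois(K: FormalContext, n_samples: int = 100, seed: int = 0) -> bool:
    """Spot-check the Galois laws of the derivation pair on random subsets.

    Antitonicity (A1 ⊆ A2 implies A2' ⊆ A1', dually for attributes) and
    extensivity (A ⊆ A'', B ⊆ B'').  True for every context by theorem;
    exists to catch implementation regressions and as an executable
    statement of the laws.
    """
    rng = random.Random(seed)

    def sub(seq: Sequence[str]) -> frozenset[str]:
        return frozenset(x for x in seq if rng.random() < 0.5)

    for _ in range(n_samples):
        A1, A2 = sub(K.objects), sub(K.objects)
        if A1 <= A2 and not (derive_intent(A2, K) <= derive_intent(A1, K)):
            return False
        B1, B2 = sub(K.attributes), sub(K.attributes)
        if B1 <= B2 and not (derive_extent(B2, K) <= derive_extent(B1, K)):
            return False
        A, B = sub(K.objects), sub(K.attributes)
        if not A <= derive_extent(derive_intent(A, K), K):
            return False
        if not B <= derive_intent(derive_extent(B, K), K):
            return False
    return True


def build_context(objects: Iterable[str], closure: ClosureTable) -> FormalContext:
    """Context with G = objects, M = their strict ancestors, I = ancestry.

    (g, m) in I iff m is a strict ancestor of g, so the lattice reflects the
    subsumption structure above the matched concepts.  An object is never
    its own attribute (strict ancestry); attributes all have non-empty
    extent by construction.
    """
    objects = sorted(set(objects))
    if not objects:
        raise ValueError("build_context requires a non-empty object set")
    attributes: set[str] = set()
    incidence: set[tuple[str, str]] = set()
    for g in objects:
        for m in closure.strict_ancestors(g):
            attributes.add(m)
            incidence.add((g, m))
    return FormalContext(
        objects=tuple(objects),
        attributes=tuple(sorted(attributes)),
        incidence=frozenset(incidence),
    )


def write_context_matrix(K: FormalContext, path: str | Path) -> None:
    """TSV: header = attribute ids, first column = object id, cells 0/1."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(("object",) + K.attributes) + "\n")
        for g in K.objects:
            cells = ["1" if K.has(g, m) else "0" for m in K.attributes]
            fh.write("\t".join([g] + cells) + "\n")


def read_context_matrix(path: str | Path) -> FormalContext:
    """Inverse of :func:`write_context_matrix`; cells must be 0 or 1."""
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 1:
            raise ValueError(f"{path}: empty header")
        attributes = tuple(header[1:])
        objects: list[str] = []
        incidence: set[tuple[str, str]] = set()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != len(attributes) + 1:
                raise ValueError(
                    f"{path}:{lineno}: expected {len(attributes) + 1} cells, "
                    f"got {len(cells)}"
                )
            g = cells[0]
            objects.append(g)
            for m, v in zip(attributes, cells[1:]):
                if v == "1":
                    incidence.add((g, m))
                elif v != "0":
                    raise ValueError(
                        f"{path}:{lineno}: cell value {v!r} is not 0/1"
                    )
    return FormalContext(
        objects=tuple(objects), attributes=attributes, incidence=frozenset(incidence)
    )
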