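"""Coverage-ratio pruning of the concept lattice, with user feedback.

The lattice built over the matched/derived concepts is walked top-down.
For a formal concept F = (O, A) every attribute a in A is scored by how
well the query objects cover its sub-tree:

    L_A(a) = strict sub-concepts of a        (in the whole ontology)
    L_O    = union over objects o of ({o} ∪ strict sub-concepts of o)
    ratio  = |L_A(a) ∩ L_O| / |L_A(a)|       (1 when L_A(a) is empty)

An attribute whose ratio falls strictly below the pruning threshold
(default 0.75) has too many sub-concepts unrelated to the query and is
pruned; a ratio at or above the threshold makes it a candidate — a tie at
the threshold is kept.  Pruning an attribute also pre-decides its strict
descendants within the attribute set by the same ratio rule, without any
oracle involvement, so the user is never asked about a region already found
irrelevant.

When a feedback oracle is supplied, the single lowest-ratio eligible
candidate of each lattice level is put to the user; a rejection eliminates
the concept and everything it subsumes — except concepts independently
supported by a lexical match or an earlier confirmation — while an
acceptance confirms it.  This bounds the user's burden to one question per
level while steering refinement where coverage is weakest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Literal

from hoirefine.fca_core import ConceptLattice
from hoirefine.ontology_store import ClosureTable
from hoirefine.sqe_expander import ExpansionResult

Status = Literal["pruned", "candidate", "confirmed", "rejected"]

#: feedback oracle: concept_id -> True (accept) / False (reject)
FeedbackOracle = Callable[[str], bool]


@dataclass
class PruningDecision:
    attribute_id: str
    ratio: float
    n_sub: int
    n_covered: int
    status: Status

    def to_dict(self) -> dict:
        return {
            "attribute": self.attribute_id,
            "ratio": self.ratio,
            "n_sub": self.n_sub,
            "n_covered": self.n_covered,
            "status": self.status,
        }


@dataclass
class RefinementResult:
    """Outcome of one refinement session.

    ``matched`` are the lexical hits, ``derived`` the expansion-only
    concepts, ``potential`` the surviving candidate/confirmed attributes,
    ``remaining_excluded`` everything pruned, rejected or eliminated by a
    rejection's subsumption closure.  ``final`` is the accepted concept
    set: matched ∪ derived ∪ potential minus the eliminated concepts.
    """

    matched: set[str] = field(default_factory=set)
    derived: set[str] = field(default_factory=set)
    potential: set[str] = field(default_factory=set)
    remaining_excluded: set[str] = field(default_factory=set)
    decisions: list[PruningDecision] = field(default_factory=list)
    final: set[str] = field(default_factory=set)
    #: concepts removed by oracle rejection closure (includes non-attributes)
    eliminated: set[str] = field(default_factory=set)
    #: concepts explicitly accepted (matched or oracle-confirmed)
    supported: set[str] = field(default_factory=set)

    def to_dict(self, query: str = "") -> dict:
        return {
            "query": query,
            "matched": sorted(self.matched),
            "derived": sorted(self.derived),
            "potential": sorted(self.potential),
            "pruned": sorted(
                d.attribute_id for d in self.decisions if d.status == "pruned"
            ),
            "rejected": sorted(
                d.attribute_id for d in self.decisions if d.status == "rejected"
            ),
            "decisions": [d.to_dict() for d in self.decisions],
            "final": sorted(self.final),
        }


def coverage_ratio(
    a: str, objects: Iterable[str], closure: ClosureTable
) -> PruningDecision:
    """Score attribute concept ``a`` against the query objects.

    L_A is the strict descendant set of ``a``; L_O the union of each
    object's reflexive descendant set (an object trivially covers itself,
    the attribute side stays strict).  Empty L_A yields ratio 1 by
    convention — a leaf attribute is vacuously covered.  The returned
    status is provisional (``candidate``); thresholding happens in the
    traversal.
    """
    objects = set(objects)
    lia = closure.strict_descendants(a)
    lio: set[str] = set()
    for o in objects:
        lio.add(o)
        lio |= closure.strict_descendants(o)
    n_sub = len(lia)
    n_covered = len(lia & lio)
    ratio = n_covered / n_sub if n_sub else 1.0
    return PruningDecision(
        attribute_id=a, ratio=ratio, n_sub=n_sub, n_covered=n_covered,
        status="candidate",
    )


def _levels(lattice: ConceptLattice) -> list[list[int]]:
    """BFS levels from the top concept along downward Hasse edges."""
    cs = lattice.concepts
    top_idx = max(range(len(cs)), key=lambda i: len(cs[i].extent))
    down: dict[int, list[int]] = {i: [] for i in range(len(cs))}
    for lower, upper in lattice.hasse:
        down[upper].append(lower)
    seen = {top_idx}
    levels = [[top_idx]]
    frontier = [top_idx]
    while frontier:
        nxt: set[int] = set()
        for i in frontier:
            for j in down[i]:
                if j not in seen:
                    nxt.add(j)
        if not nxt:
            break
        seen |= nxt
        ordered = sorted(nxt, key=lambda i: (-len(cs[i].extent), sorted(cs[i].extent)))
        levels.append(ordered)
        frontier = ordered
    return levels


class _Session:
    """Mutable state shared by the traversal and the rejection closure."""

    def __init__(
        self,
        objects: set[str],
        M: set[str],
        closure: ClosureTable,
        threshold: float,
        supported: set[str],
    ):
        self.objects = objects
        self.M = M
        self.closure = closure
        self.threshold = threshold
        self.supported = set(supported)
        self.decided: dict[str, PruningDecision] = {}
        self.eliminated: set[str] = set()
        # attributes decided inside a pruned region: never put to the oracle
        self.suppressed: set[str] = set()

    def decide(self, a: str) -> PruningDecision:
        d = coverage_ratio(a, self.objects, self.closure)
        if d.ratio < self.threshold:
            d.status = "pruned"
            self.decided[a] = d
            self.suppress_descendants(a)
        else:
            self.decided[a] = d
        return d

    def suppress_descendants(self, a: str) -> None:
        """Pre-decide the pruned attribute's undecided descendants.

        Suppressed attributes are never put to the oracle during the
        traversal (no re-ask inside a region already found irrelevant); an
        attribute that already earned candidate status on its own keeps its
        oracle eligibility.
        """
        for sub in sorted(self.closure.strict_descendants(a) & self.M):
            if sub not in self.decided:
                self.suppressed.add(sub)
                self.decide(sub)

    def protected(self) -> set[str]:
        """Concepts shielded from rejection closure: supported + below."""
        shield = set(self.supported)
        for s in self.supported:
            shield |= self.closure.strict_descendants(s)
        return shield

    def reject(self, a: str) -> None:
        """Eliminate ``a`` and everything it subsumes, sparing supported."""
        shield = self.protected()
        doomed = ({a} | self.closure.strict_descendants(a)) - shield
        self.eliminated |= doomed
        for x in sorted(doomed & self.M):
            self.suppressed.add(x)
            if x not in self.decided:
                d = coverage_ratio(x, self.objects, self.closure)
                d.status = "rejected"
                self.decided[x] = d
        if a in self.decided:
            self.decided[a].status = "rejected"


def traverse_and_prune(
    lattice: ConceptLattice,
    objects: Iterable[str],
    closure: ClosureTable,
    threshold: float = 0.75,
    oracle: FeedbackOracle | None = None,
    supported: Iterable[str] = (),
) -> RefinementResult:
    """Top-down breadth-first pruning pass over the lattice.

    Every attribute of the context receives exactly one decision; a formal
    concept whose intent is already fully decided contributes nothing.
    With an oracle, the lowest-ratio still-eligible candidate of each level
    is queried once; rejection triggers the subsumption-closure elimination
    (sparing concepts in ``supported`` — typically the lexical matches —
    and their descendants), acceptance upgrades it to ``confirmed`` and
    adds it to the supported set.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    objects = set(objects)
    M = set(lattice.context.attributes)
    sess = _Session(objects, M, closure, threshold, set(supported))

    for level in _levels(lattice):
        fresh: list[PruningDecision] = []
        for idx in level:
            concept = lattice.concepts[idx]
            for a in sorted(concept.intent):
                if a in sess.decided:
                    continue
                d = sess.decide(a)
                if d.status == "candidate" and a not in sess.suppressed:
                    fresh.append(d)
        if oracle is not None:
            eligible = [
                d for d in fresh
                if d.status == "candidate"
                and d.attribute_id not in sess.suppressed
                and d.attribute_id not in sess.eliminated
            ]
            if eligible:
                ask = min(eligible, key=lambda d: (d.ratio, d.attribute_id))
                if oracle(ask.attribute_id):
                    ask.status = "confirmed"
                    sess.supported.add(ask.attribute_id)
                else:
                    sess.reject(ask.attribute_id)

    # attributes in no traversed intent (possible when the lattice was cut
    # down externally) still get a decision: exhaustiveness contract
    for a in sorted(M - set(sess.decided)):
        sess.decide(a)

    decisions = [sess.decided[a] for a in sorted(M)]
    excluded = {
        d.attribute_id for d in decisions if d.status in ("pruned", "rejected")
    } | (sess.eliminated & M)
    return RefinementResult(
        decisions=decisions,
        remaining_excluded=excluded,
        eliminated=sess.eliminated,
        supported=sess.supported,
    )


def classify_roles(
    matched: Iterable[str],
    expansion: ExpansionResult,
    decisions: list[PruningDecision],
    eliminated: Iterable[str] = (),
) -> RefinementResult:
    """Assign the role partition: matched / derived / potential / excluded.

    matched: the lexical hits; derived: expansion concepts that were not
    matched; potential: attributes surviving as candidate or confirmed and
    not already matched/derived; remaining: attributes pruned or rejected.
    ``final`` keeps matched and derived concepts unless an oracle rejection
    eliminated them — automatic ratio pruning removes a concept's claim to
    be a *candidate attribute*, not an object's membership — and adds the
    potential attributes.
    """
    matched = set(matched)
    eliminated = set(eliminated)
    derived = expansion.second_hop - matched
    excluded = {
        d.attribute_id for d in decisions if d.status in ("pruned", "rejected")
    } | eliminated
    potential = (
        {d.attribute_id for d in decisions if d.status in ("candidate", "confirmed")}
        - matched
        - derived
        - eliminated
    )
    final = ((matched | derived) - eliminated) | potential
    return RefinementResult(
        matched=matched - eliminated,
        derived=derived - eliminated,
        potential=potential,
        remaining_excluded=excluded,
        decisions=decisions,
        final=final,
        eliminated=eliminated,
    )
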