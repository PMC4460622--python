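# Methods

## Problem setting

A health outcome of interest is represented as a concept set over one or
more is-a terminologies. The package turns a free-text query into such a
set in five stages: lexical synonym matching, downward semantic expansion,
formal-context construction, lattice-guided coverage pruning, and optional
user feedback. Each stage is an importable module; the pipeline composes
them deterministically.

## Ontology model and closure

Concepts are nodes with a preferred label, a synonym set, direct is-a
parents and cross-ontology mapping keys (xrefs). Loading merges xref-
connected components into single nodes (union-find; transitive chains
a↔b, b↔c collapse), unioning parents, synonyms and source labels; the
first-loaded member supplies the preferred label and node id, other labels
survive as synonyms. Merging can create cycles even when every source
ontology is acyclic (differing abstraction levels can invert a pair), so
cycle detection runs before any closure computation and reports a witness
cycle. The transitive closure is materialized once per graph as **strict**
ancestor/descendant sets — a concept is never its own ancestor; callers
needing reflexive closure add the concept explicitly. Strictness keeps the
sub-concept counts used by the pruning ratio unambiguous.

## Lexical matching

Normalization lowercases, maps punctuation runs to single spaces and
splits on whitespace. Matching is exact on normalized strings: a concept
fires when one of its synonyms equals the whole query or a contiguous
token span of it, scanned left-to-right with longest-match,
non-overlapping spans. There is deliberately no stemming, edit distance or
abbreviation handling — ambiguity resolution belongs to the pruning stage,
and fuzzier matching would make the downstream coverage statistics
unattributable. A synonym shared by several concepts returns all of them.

## Expansion

Downward expansion derives strict sub-concepts of the current set. The
default `closure` hop mode takes the full descendant closure per round; on
a single merged graph one round already saturates, and the second round
exists for the `edge` mode (direct children only) and for workflows that
expand per-ontology. Two rounds, never more: fixpoint recursion is
rejected outright because merged multi-ontology graphs are not reliably
acyclic at scale. The upward direction computes a cover of the matches by
super-concepts using greedy set cover — pick the candidate covering the
most uncovered matches, break ties by depth (more ancestors = deeper =
more specific), then by id. Exact minimum cover is NP-hard and nothing
downstream depends on minimality, only on soundness (every match with a
parent is covered; parentless matches cover themselves).

## Formal concept analysis

The context takes the matched-plus-derived concepts as objects and their
strict ancestors as attributes; incidence is strict ancestry, so an object
is never its own attribute and generated contexts never contain an
all-zero attribute column (a column like that survives file round-trips,
since the matrix reader preserves whatever it is given). Enumeration uses
NextClosure in lectic order over attribute sets with bitmask derivations:
deterministic, no concept stored twice, memory proportional to the output.
The public order sorts concepts by extent size then ids, so lattice output
is byte-stable. The Hasse diagram is the transitive reduction of the
concept order, computed pairwise — cubic in the number of concepts, which
is acceptable at the few-hundred-concept scale this tool produces. A
brute-force enumerator (close every object subset, 2^|G|) lives in the
test suite as the independent oracle; `verify_galois` spot-checks
antitonicity and extensivity of the derivation pair on sampled subsets.
Enumeration refuses contexts over a configurable cell budget
(default 10^6 cells) rather than silently grinding.

## Coverage pruning and feedback

For an attribute *a*: L_A(a) = strict descendants of *a* in the whole
merged graph; L_O = union of each object's reflexive descendant set (an
object trivially covers itself; the attribute side stays strict — the
16-out-of-4 worked arithmetic is insensitive to the object-side choice).
ratio(a) = |L_A(a) ∩ L_O| / |L_A(a)|, with empty L_A scored 1 (vacuously
covered, avoids 0/0). The traversal walks lattice levels breadth-first
from the top concept, visiting undecided intent attributes in sorted-id
order; each attribute receives exactly one decision:

- ratio < threshold → **pruned**; its undecided descendant attributes are
  decided immediately by the same rule and marked ineligible for oracle
  questions, so the user is never asked inside a region already found
  irrelevant. An attribute that already earned candidate status keeps it —
  a decision is a function of the attribute's own ratio, which makes the
  pruned set exactly {a : ratio(a) < t} and threshold-monotone by
  construction.
- ratio ≥ threshold → **candidate** (a tie at the threshold is kept: the
  worked 75 % example satisfies a 75 % threshold).

With a feedback oracle, the lowest-ratio eligible candidate of each level
is asked (one question per level bounds user burden); acceptance upgrades
to **confirmed**, rejection to **rejected** and eliminates the concept and
everything it subsumes *except* independently supported concepts — the
lexical matches and previously confirmed concepts, plus their descendants.
Without that exception a user rejecting a too-general ancestor would
silently discard the very matches below it. The pipeline ends with a
review of the surviving candidate list, most general candidates first so
one rejection can dismiss a whole region; this mirrors handing the
candidate list to the clinician and is what lets a gold-membership oracle
drive the final set to exactly the gold subtree.

Roles in the result: **matched** (lexical hits), **derived** (expansion
minus matched), **potential** (candidate/confirmed attributes not already
objects), **remaining/excluded** (pruned, rejected, eliminated). The final
set is matched ∪ derived ∪ potential minus everything eliminated.
Automatic ratio pruning removes a concept's claim to be a candidate
attribute but does not strip an object's membership; only explicit
rejection (with its subsumption closure) does that.

## Evaluation

Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP) over an explicitly
supplied concept universe — specificity is meaningless without declaring
which negatives are counted, so the universe is a required argument.
Degenerate denominators: Se = 0 with an empty gold set, Sp = 1 with no
negatives.

## Synthetic data

The generator emulates a merged biomedical terminology fragment: a
single-root DAG with level-stratified parent sampling (each non-root
concept draws 1–2 parents from strictly shallower levels, so acyclicity
holds by construction rather than by rejection), one synthetic synonym per
concept plus its label, and optional xref keys. Defaults — 120 concepts,
max 2 parents, 6 levels — give non-trivial lattices while keeping
exhaustive test oracles affordable; recovery tests use 150–300 concepts.
`plant_hoi` stands in for one condition's term set: it picks an internal
concept h, defines gold = {h} ∪ descendants(h) (downward-closed, like a
real condition subtree), and attaches unique multi-word synonyms to h and
to three sampled gold members as the query vocabulary. Synonym text is
synthetic (`term-<id>-<k>`): matching is exact-string, so imitation
medical vocabulary would add nothing but accidental ambiguity.

What passing synthetic tests do **not** show: robustness to real clinical
vocabulary (abbreviations, misspellings, lexical overlap between unrelated
conditions), to terminologies whose gold sets are not downward-closed, or
to merged graphs at the scale of a full metathesaurus. The planted-subtree
recovery result is a correctness check of the machinery under ideal
lexical conditions, not a clinical performance estimate.

## Numerical and procedural choices

- Threshold comparisons are exact float comparisons on ratios that are
  small-integer quotients; ties at the threshold are kept.
- All public orderings (context objects/attributes, lattice concepts,
  decision lists, JSON keys) are sorted, so identical inputs produce
  byte-identical JSON.
- The `seed` in the session config feeds fixture generation and sampling
  only; the core pipeline is deterministic without randomness.
- Degenerate inputs: empty query match yields an empty result with a
  warning (not an error); parentless objects yield an attribute-free
  context with a single formal concept; empty object sets are rejected.

## Known limitations

- Only is-a hierarchies: no part-of or other relations, no description-
  logic reasoning over complex axioms.
- The Hasse computation is O(n³) in concept count; fine for hundreds of
  concepts, not for lattices in the tens of thousands.
- The greedy ancestor cover can exceed the optimal cover size on
  adversarial DAGs (standard ln-factor set-cover behavior).
- One oracle question per lattice level plus the final review can still
  mean many questions on wide lattices; active ordering beyond
  lowest-ratio-first is out of scope.
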