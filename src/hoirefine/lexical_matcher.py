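"""Purely lexical matching of a free-text query against concept synonyms.

The query is tokenized (lowercased, punctuation stripped, whitespace
collapsed) and compared against the normalized form of every synonym of
every concept.  A concept matches when one of its synonyms equals the whole
query or a maximal contiguous token sub-span of it (longest-match,
left-to-right, non-overlapping).  No stemming, no edit distance, no
semantics — disambiguation of shared synonyms is deferred to lattice
pruning and user feedback.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from hoirefine.ontology_store import OntologyGraph

_PUNCT = re.compile(r"[^0-9a-z]+")


def normalize(text: str) -> list[str]:
    """Lowercase, map punctuation runs to spaces, split on whitespace."""
    return [t for t in _PUNCT.split(text.lower()) if t]


@dataclass
class SynonymIndex:
    """normalized synonym string -> set of concept ids carrying it."""

    entries: dict[str, set[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, normalized: str) -> set[str]:
        return self.entries.get(normalized, set())

    @property
    def max_tokens(self) -> int:
        """Longest synonym length in tokens (bounds the span search)."""
        return max((k.count(" ") + 1 for k in self.entries), default=0)


@dataclass
class MatchResult:
    query: str
    tokens: list[str]
    matched_ids: set[str]
    per_synonym_hits: dict[str, set[str]]


def build_index(graph: OntologyGraph) -> SynonymIndex:
    """Index every synonym of every concept under its normalized string."""
    entries: dict[str, set[str]] = {}
    for cid, concept in graph.concepts.items():
        for syn in concept.synonyms:
            key = " ".join(normalize(syn))
            if not key:
                continue
            entries.setdefault(key, set()).add(cid)
    return SynonymIndex(entries=entries)


def match_query(query: str, index: SynonymIndex) -> MatchResult:
    """Match the query against the synonym index.

    Policy: scan left to right over the normalized token sequence; at each
    position take the *longest* contiguous span that is an indexed synonym,
    record all concepts carrying it, then continue after the span
    (non-overlapping).  Positions starting no span advance by one token.
    A synonym shared by several concepts returns them all.
    """
    tokens = normalize(query)
    hits: dict[str, set[str]] = {}
    limit = index.max_tokens
    i = 0
    n = len(tokens)
    while i < n:
        best_len = 0
        best_key = None
        max_j = min(n, i + limit)
        for j in range(max_j, i, -1):
            key = " ".join(tokens[i:j])
            ids = index.lookup(key)
            if ids:
                best_len = j - i
                best_key = key
                break
        if best_key is not None:
            hits.setdefault(best_key, set()).update(index.lookup(best_key))
            i += best_len
        else:
            i += 1
    matched = set().union(*hits.values()) if hits else set()
    return MatchResult(
        query=query, tokens=tokens, matched_ids=matched, per_synonym_hits=hits
    )
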