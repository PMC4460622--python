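# hoirefine

Semi-automatic refinement of **health outcomes of interest** (HOIs).
An HOI — myocardial infarction, hypertension, hypertriglyceridemia — is
operationally a *set of ontology concepts* used to select patient cohorts or
mine clinical text. Assembling that set by hand means navigating many
overlapping terminologies concept by concept. `hoirefine` builds it from a
plain free-text query instead, for informaticians and pharmacovigilance
researchers who have terminologies loaded but no curated concept set.

## Method

1. **Lexical matching.** The query is tokenized (lowercase, punctuation
   stripped) and matched against the normalized form of every synonym of
   every concept in a merged multi-ontology graph; the longest contiguous
   token spans win. No semantics at this stage.
2. **Semantic query expansion (SQE).** Equivalent concepts from different
   source ontologies are merged on shared xref keys, so subsumption
   traversal hops across ontologies for free. The matched set *C* is
   expanded downward for two derivation rounds ("2-hop"):
   *C → C′ → C″ = C ∪ C′ ∪ sub(C′)* — deliberately short of a fixpoint,
   which is unsafe when mixed abstraction levels induce cycles. Upward, a
   greedy minimal cover of the matches by super-concepts is computed.
3. **Formal concept analysis (FCA).** A formal context *K = (G, M, I)*
   is built with objects *G* = matched ∪ derived concepts, attributes
   *M* = their strict super-concepts, and *(g, m) ∈ I* iff *m* subsumes
   *g*. All formal concepts — pairs *(A, B)* with *A′ = B*, *B′ = A* —
   are enumerated with Ganter's NextClosure algorithm and ordered into the
   concept lattice (*A₁,B₁) ≤ (A₂,B₂) ⇔ A₁ ⊆ A₂*.
4. **Coverage pruning with feedback.** The lattice is walked top-down.
   Each attribute *a* is scored by the coverage ratio
   |L_A(a) ∩ L_O| / |L_A(a)|, where L_A(a) is the strict sub-concept
   closure of *a* and L_O the union of the objects' reflexive sub-concept
   closures. A ratio below the pruning threshold (default **0.75**; ties
   kept) prunes the attribute; survivors become candidates. A feedback
   oracle (gold file or interactive) is asked about the lowest-ratio
   candidate per lattice level, then about the surviving candidate list;
   each rejection eliminates the concept and everything it subsumes except
   independently supported concepts.
5. **Evaluation.** Sensitivity TP/(TP+FN) and specificity TN/(TN+FP) of
   the final set against a gold concept set over an explicit universe.

## Worked example

```python
from hoirefine import enumerate_concepts, refine_hoi
from hoirefine.synthetic_fixtures import table1_context, toy_graph

lat = enumerate_concepts(table1_context())
for c in lat.concepts:
    print(sorted(c.extent), sorted(c.intent))
```

prints the three formal concepts of the published hypertriglyceridemia
context extract — a chain from the empty extent up to all four objects:

```
[] ['0', '19118', '6260', '740154']
['10365', '12115'] ['0', '19118', '740154']
['10365', '10406', '12115', '191723'] ['0', '19118']
```

The middle concept is the maximal "rectangle" of objects 10365 and 12115
(both sub-concepts of 0, 19118 and 740154). A full refinement session on a
five-concept toy ontology:

```python
res = refine_hoi("high blood pressure", toy_graph())
print(sorted(res.matched), sorted(res.final))
# ['A1'] ['A1']
```

The query matches concept A1 by synonym; its super-concepts A (ratio 0.5)
and ROOT (0.25) fall below the 0.75 threshold and are pruned, leaving the
match itself.

The same operations are exposed on the command line:

```bash
hoirefine refine --ontology onto.tsv --query "hypertension" \
    --threshold 0.75 --oracle gold:gold.txt --out result.json
hoirefine lattice --context table1.tsv --out lattice.json
hoirefine simulate --seed 3 --outdir fixture/   # synthetic test case
```

Ontologies load from OBO files or a simple TSV dialect
(`concept_id ontology_id label synonyms parents xrefs`, pipe-separated
multi-values); see `hoirefine --help` for the remaining subcommands.

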