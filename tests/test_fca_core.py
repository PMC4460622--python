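"""Derivation operators, NextClosure enumeration, lattice order, Galois laws."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hoirefine import (
    FormalConcept,
    FormalContext,
    build_context,
    compute_closure,
    derive_extent,
    derive_intent,
    enumerate_concepts,
    hasse_edges,
    is_formal_concept,
    order_leq,
    read_context_matrix,
    verify_galois,
    write_context_matrix,
)
from hoirefine.fca_core import ContextSizeError
from hoirefine.synthetic_fixtures import generate_random_context, table1_context

from conftest import brute_force_concepts, powerset


class TestDerivation:
    def test_single_object_intent_matches_printed_row(self, table1):
        assert derive_intent({"10365"}, table1) == {"0", "19118", "740154"}

    def test_empty_object_set_derives_all_attributes(self, table1):
        assert derive_intent(set(), table1) == {"0", "19118", "740154", "6260"}

    def test_two_row_intersection(self, table1):
        assert derive_intent({"10365", "10406"}, table1) == {"0", "19118"}

    def test_extent_of_three_attributes_is_printed_rectangle(self, table1):
        assert derive_extent({"0", "19118", "740154"}, table1) == {"10365", "12115"}

    def test_empty_attribute_set_derives_all_objects(self, table1):
        assert derive_extent(set(), table1) == set(table1.objects)

    def test_all_zero_column_has_empty_extent(self, table1):
        assert derive_extent({"6260"}, table1) == set()


class TestFormalConceptPredicate:
    def test_printed_rectangle_is_a_concept(self, table1):
        assert is_formal_concept({"10365", "12115"}, {"0", "19118", "740154"}, table1)

    def test_non_closed_extent_is_rejected(self, table1):
        assert not is_formal_concept({"10365"}, {"0", "19118", "740154"}, table1)

    def test_full_object_set_closes(self, table1):
        G = set(table1.objects)
        assert is_formal_concept(G, derive_intent(G, table1), table1)


class TestEnumeration:
    def test_printed_context_has_exactly_three_concepts(self, table1):
        lattice = enumerate_concepts(table1)
        expected = {
            (frozenset({"10365", "12115", "10406", "191723"}), frozenset({"0", "19118"})),
            (frozenset({"10365", "12115"}), frozenset({"0", "19118", "740154"})),
            (frozenset(), frozenset({"0", "19118", "740154", "6260"})),
        }
        assert {(c.extent, c.intent) for c in lattice.concepts} == expected

    def test_every_enumerated_pair_is_a_formal_concept(self, table1):
        for c in enumerate_concepts(table1).concepts:
            assert is_formal_concept(c.extent, c.intent, table1)

    def test_empty_context_has_one_concept(self):
        K = FormalContext(objects=(), attributes=(), incidence=frozenset())
        lattice = enumerate_concepts(K)
        assert len(lattice) == 1
        assert lattice.concepts[0] == FormalConcept(frozenset(), frozenset())

    def test_full_incidence_has_one_concept(self):
        K = generate_random_context(4, 3, density=1.0, seed=0)
        lattice = enumerate_concepts(K)
        assert len(lattice) == 1
        assert lattice.concepts[0].extent == frozenset(K.objects)
        assert lattice.concepts[0].intent == frozenset(K.attributes)

    def test_empty_incidence_has_two_concepts(self):
        K = generate_random_context(3, 3, density=0.0, seed=0)
        pairs = {(c.extent, c.intent) for c in enumerate_concepts(K).concepts}
        assert pairs == {
            (frozenset(K.objects), frozenset()),
            (frozenset(), frozenset(K.attributes)),
        }

    def test_cell_limit_enforced(self):
        K = generate_random_context(40, 30, density=0.3, seed=1)
        with pytest.raises(ContextSizeError, match="cell_limit"):
            enumerate_concepts(K, cell_limit=100)

    @pytest.mark.parametrize("seed", range(25))
    @pytest.mark.parametrize("density", [0.2, 0.5, 0.8])
    def test_nextclosure_equals_brute_force_on_random_contexts(self, seed, density):
        K = generate_random_context(7, 7, density=density, seed=seed)
        got = {(c.extent, c.intent) for c in enumerate_concepts(K).concepts}
        want = {(c.extent, c.intent) for c in brute_force_concepts(K)}
        assert got == want

    def test_concept_count_bounded_by_two_power_min_dimension(self):
        for seed in range(5):
            K = generate_random_context(6, 9, density=0.5, seed=seed)
            assert len(enumerate_concepts(K)) <= 2 ** min(K.n_objects, K.n_attributes)

    def test_enumeration_order_is_deterministic(self, table1):
        a = enumerate_concepts(table1)
        b = enumerate_concepts(table1)
        assert [(sorted(c.extent), sorted(c.intent)) for c in a.concepts] == [
            (sorted(c.extent), sorted(c.intent)) for c in b.concepts
        ]
        assert a.hasse == b.hasse


class TestOrderAndHasse:
    def test_printed_concepts_form_a_chain(self, table1):
        lattice = enumerate_concepts(table1)
        bottom, middle, top = lattice.concepts
        assert order_leq(bottom, middle) and order_leq(middle, top)
        assert order_leq(bottom, top)
        assert not order_leq(top, bottom)
        assert lattice.hasse == [(0, 1), (1, 2)]

    def test_reflexivity(self, table1):
        for c in enumerate_concepts(table1).concepts:
            assert order_leq(c, c)

    def test_single_concept_lattice_has_no_edges(self):
        K = generate_random_context(3, 2, density=1.0, seed=0)
        assert enumerate_concepts(K).hasse == []

    @pytest.mark.parametrize("seed", range(5))
    def test_hasse_is_transitive_reduction(self, seed):
        K = generate_random_context(6, 6, density=0.45, seed=seed)
        lattice = enumerate_concepts(K)
        cs = lattice.concepts
        n = len(cs)
        # independent pairwise reduction
        lt = [[i != j and order_leq(cs[i], cs[j]) for j in range(n)] for i in range(n)]
        expected = sorted(
            (i, j)
            for i in range(n)
            for j in range(n)
            if lt[i][j] and not any(lt[i][k] and lt[k][j] for k in range(n))
        )
        assert sorted(hasse_edges(lattice)) == expected

    @pytest.mark.parametrize("seed", range(5))
    def test_unique_top_bottom_and_meet_join_exist(self, seed):
        K = generate_random_context(5, 5, density=0.5, seed=seed)
        lattice = enumerate_concepts(K)
        cs = lattice.concepts
        tops = [c for c in cs if all(order_leq(o, c) for o in cs)]
        bots = [c for c in cs if all(order_leq(c, o) for o in cs)]
        assert len(tops) == 1 and len(bots) == 1
        for a in cs:
            for b in cs:
                lower = [c for c in cs if order_leq(c, a) and order_leq(c, b)]
                upper = [c for c in cs if order_leq(a, c) and order_leq(b, c)]
                assert any(all(order_leq(x, m) for x in lower) for m in lower)
                assert any(all(order_leq(m, x) for x in upper) for m in upper)


class TestGaloisLaws:
    def test_verify_galois_on_printed_and_random_contexts(self, table1):
        assert verify_galois(table1, n_samples=100, seed=0)
        for seed in range(5):
            K = generate_random_context(8, 8, density=0.4, seed=seed)
            assert verify_galois(K, n_samples=50, seed=seed)

    def test_corrupted_derivation_breaks_the_laws(self, table1):
        # dropping an attribute from A' breaks extensivity of B -> B''
        def bad_intent(A):
            out = set(derive_intent(A, table1))
            out.discard("0")
            return frozenset(out)

        violations = [
            B
            for B in map(frozenset, powerset(table1.attributes))
            if not B <= bad_intent(derive_extent(B, table1))
        ]
        assert violations

    @settings(max_examples=80, deadline=None)
    @given(data=st.data(), seed=st.integers(0, 30))
    def test_closure_laws_hold_on_sampled_subsets(self, data, seed):
        K = generate_random_context(6, 6, density=0.5, seed=seed)
        A1 = frozenset(data.draw(st.sets(st.sampled_from(K.objects or ("g0",)))))
        A2 = A1 | frozenset(data.draw(st.sets(st.sampled_from(K.objects or ("g0",)))))
        A1, A2 = A1 & set(K.objects), A2 & set(K.objects)
        # extensivity, idempotence, antitonicity
        assert A1 <= derive_extent(derive_intent(A1, K), K)
        assert derive_intent(A1, K) == derive_intent(
            derive_extent(derive_intent(A1, K), K), K
        )
        assert derive_intent(A2, K) <= derive_intent(A1, K)


class TestBuildContext:
    def test_chain_ontology_reproduces_printed_incidence(self, table1_chain):
        graph, closure = table1_chain
        K = build_context({"10365", "12115", "10406", "191723"}, closure)
        printed = table1_context()
        assert set(K.attributes) == {"0", "19118", "740154"}  # no empty column
        for g in K.objects:
            got = {m for m in K.attributes if K.has(g, m)}
            want = {m for m in printed.attributes if printed.has(g, m)}
            assert got == want

    def test_parentless_objects_give_empty_attribute_set(self, toy_closure):
        K = build_context({"ROOT"}, toy_closure)
        assert K.attributes == ()
        assert len(enumerate_concepts(K)) == 1

    def test_disjoint_components_give_block_diagonal_incidence(self):
        from hoirefine.ontology_store import Concept, OntologyGraph

        g = OntologyGraph()
        for cid, parents in [
            ("p", set()), ("c1", {"p"}),
            ("q", set()), ("c2", {"q"}),
        ]:
            g.add(Concept(concept_id=cid, preferred_label=cid,
                          synonyms={cid}, parent_ids=parents))
        closure = compute_closure(g)
        K = build_context({"c1", "c2"}, closure)
        assert K.has("c1", "p") and K.has("c2", "q")
        assert not K.has("c1", "q") and not K.has("c2", "p")

    def test_empty_object_set_rejected(self, toy_closure):
        with pytest.raises(ValueError):
            build_context(set(), toy_closure)


class TestContextMatrixIO:
    def test_printed_context_file_round_trip(self, tmp_path, table1):
        path = tmp_path / "table.tsv"
        write_context_matrix(table1, path)
        back = read_context_matrix(path)
        assert back.objects == table1.objects
        assert back.attributes == table1.attributes
        assert back.incidence == table1.incidence
        assert len(table1.incidence) == 10

    @pytest.mark.parametrize("seed", range(4))
    def test_round_trip_identity_on_random_contexts(self, tmp_path, seed):
        K = generate_random_context(6, 5, density=0.4, seed=seed)
        path = tmp_path / f"k{seed}.tsv"
        write_context_matrix(K, path)
        back = read_context_matrix(path)
        assert back.incidence == K.incidence

    def test_non_binary_cell_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("object\tm1\ng1\t2\n", encoding="utf-8")
        with pytest.raises(ValueError, match="not 0/1"):
            read_context_matrix(path)
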