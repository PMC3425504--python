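"""Matching analytics against brute-force oracles and known small cases."""

from fractions import Fraction
from random import Random

import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from prudent_matching import (
    all_matchings,
    approximation_ratio,
    bad_matchings,
    build_matching_chain,
    count_perfect_matchings,
    enumerate_matchings,
    hk_bound,
    is_maximal,
    make_bad_graph,
    maximum_matching_size,
    read_matching,
    shortest_augmenting_path,
    validate_matching,
    write_matching,
)
from prudent_matching.matching import MatchingError, normalize_matching

from conftest import (
    brute_force_matchings_of_size,
    brute_force_max_matching_size,
    random_graph,
)


class TestValidation:
    def test_valid_matching_passes(self, path4):
        assert validate_matching(path4, [("a", "b")]) is None

    def test_shared_endpoint_named(self, path4):
        msg = validate_matching(path4, [("a", "b"), ("b", "c")])
        assert msg is not None and "b" in msg

    def test_non_edge_named(self, path4):
        msg = validate_matching(path4, [("a", "c")])
        assert msg is not None and "not an edge" in msg


class TestMaximumMatching:
    def test_small_known_cases(self, path4):
        assert maximum_matching_size(path4) == 2
        assert maximum_matching_size(nx.star_graph(5)) == 1
        assert maximum_matching_size(make_bad_graph(4)) == 4

    def test_agrees_with_brute_force_on_random_corpus(self):
        rng = Random(42)
        for _ in range(60):
            G = random_graph(rng, 4, 9)
            assert maximum_matching_size(G) == brute_force_max_matching_size(G)


class TestMaximal:
    def test_p4_middle_edge_is_maximal(self, path4):
        assert is_maximal(path4, [("b", "c")])

    def test_empty_not_maximal(self, path4):
        assert not is_maximal(path4, [])

    def test_perfect_is_maximal(self):
        C6 = nx.cycle_graph(6)
        assert is_maximal(C6, [(0, 1), (2, 3), (4, 5)])

    def test_invalid_matching_rejected(self, path4):
        with pytest.raises(MatchingError):
            is_maximal(path4, [("a", "b"), ("b", "c")])


class TestApproximationRatio:
    def test_empty_matching(self, path4):
        assert approximation_ratio(path4, []) == 0

    def test_perfect_matching(self, path4):
        assert approximation_ratio(path4, [("a", "b"), ("c", "d")]) == 1

    def test_maximal_is_at_least_half(self):
        """Any maximal matching has at least half the maximum size."""
        rng = Random(7)
        for _ in range(40):
            G = random_graph(rng, 4, 9)
            # greedily build a maximal matching
            M, used = [], set()
            for u, v in sorted(map(lambda e: tuple(sorted(e)), G.edges())):
                if u not in used and v not in used:
                    M.append((u, v))
                    used.update((u, v))
            assert is_maximal(G, M)
            assert approximation_ratio(G, M) >= Fraction(1, 2)


class TestAugmentingPaths:
    def test_single_unmatched_edge(self, single_edge):
        rep = shortest_augmenting_path(single_edge, [])
        assert rep.shortest_length == 1
        assert rep.witness_path == ("a", "b")

    def test_p4_with_middle_edge(self, path4):
        rep = shortest_augmenting_path(path4, [("b", "c")])
        assert rep.shortest_length == 3
        assert rep.witness_path == ("a", "b", "c", "d")

    def test_maximum_matching_has_none(self, path4):
        assert shortest_augmenting_path(path4, [("a", "b"), ("c", "d")]).shortest_length is None

    def test_witness_alternates_and_ends_free(self):
        rng = Random(3)
        for _ in range(30):
            G = random_graph(rng, 4, 8)
            for M in all_matchings(G):
                rep = shortest_augmenting_path(G, M)
                if rep.shortest_length is None:
                    assert len(M) == maximum_matching_size(G)
                    continue
                path = rep.witness_path
                assert len(path) == rep.shortest_length + 1
                covered = {x for e in M for x in e}
                assert path[0] not in covered and path[-1] not in covered
                Mn = normalize_matching(M)
                for i in range(len(path) - 1):
                    e = tuple(sorted((path[i], path[i + 1])))
                    assert G.has_edge(*e)
                    assert (e in Mn) == (i % 2 == 1)  # odd edges are matched

    def test_berge_contract(self):
        """No augmenting path exists iff the matching is maximum."""
        rng = Random(11)
        for _ in range(25):
            G = random_graph(rng, 4, 8)
            m = maximum_matching_size(G)
            for M in all_matchings(G):
                none = shortest_augmenting_path(G, M, max_size=m).shortest_length is None
                assert none == (len(M) == m)


class TestHKBound:
    def test_values(self):
        assert hk_bound(1) == 0
        assert hk_bound(3) == Fraction(1, 2)
        assert hk_bound(5) == Fraction(2, 3)
        assert hk_bound(None) == 1

    def test_even_length_rejected(self):
        with pytest.raises(ValueError):
            hk_bound(4)

    def test_inequality_on_random_graphs(self):
        """size/maximum >= k/(k+1) when the shortest augmenting path has 2k+1 edges."""
        rng = Random(5)
        for _ in range(25):
            G = random_graph(rng, 4, 8)
            m = maximum_matching_size(G)
            for M in all_matchings(G):
                rep = shortest_augmenting_path(G, M, max_size=m)
                assert approximation_ratio(G, M, max_size=m) >= hk_bound(rep.shortest_length)


class TestCountPerfectMatchings:
    def test_known_cases(self, single_edge):
        assert count_perfect_matchings(single_edge) == 1
        assert count_perfect_matchings(nx.cycle_graph(6)) == 2
        assert count_perfect_matchings(nx.complete_graph(4)) == 3
        assert count_perfect_matchings(nx.path_graph(3)) == 0

    @pytest.mark.parametrize("n", range(1, 8))
    def test_bad_graph_unique(self, n):
        assert count_perfect_matchings(make_bad_graph(n)) == 1

    def test_guard(self):
        with pytest.raises(ValueError, match="24"):
            count_perfect_matchings(nx.empty_graph(30))


class TestEnumerateMatchings:
    def test_p3_singletons(self):
        G = nx.path_graph(3)
        assert set(enumerate_matchings(G, 1)) == {frozenset({(0, 1)}), frozenset({(1, 2)})}

    def test_c4_perfect(self):
        assert len(enumerate_matchings(nx.cycle_graph(4), 2)) == 2

    def test_agrees_with_subset_filter_oracle(self):
        rng = Random(9)
        for _ in range(20):
            G = random_graph(rng, 4, 8)
            for s in range(0, 4):
                assert set(enumerate_matchings(G, s)) == brute_force_matchings_of_size(G, s)


class TestBadMatchings:
    def test_n2_family(self):
        fam = bad_matchings(2)
        assert frozenset({("a2", "b1")}) in fam  # free: a1 and b2

    @pytest.mark.parametrize("n", range(2, 7))
    def test_every_member_has_one_free_node_per_side(self, n):
        G = make_bad_graph(n)
        for M in bad_matchings(n):
            free = set(G) - {x for e in M for x in e}
            assert len(free) == 2
            assert {x[0] for x in free} == {"a", "b"}

    def test_fraction_of_near_perfect_matchings_non_decreasing(self):
        fracs = [
            Fraction(len(bad_matchings(n)), len(enumerate_matchings(make_bad_graph(n), n - 1)))
            for n in range(4, 8)
        ]
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))


class TestMatchingChain:
    def test_single_edge_chain(self, single_edge):
        ch = build_matching_chain(single_edge)
        assert len(ch.states) == 2
        assert len(ch.transitions) == 1
        assert ch.transitions[0][2] == "add"

    def test_transitions_never_decrease_size(self):
        ch = build_matching_chain(nx.cycle_graph(6))
        for a, b, _k in ch.transitions:
            assert len(ch.states[b]) >= len(ch.states[a])

    def test_reversible_within_size_classes(self):
        rng = Random(13)
        for _ in range(10):
            G = random_graph(rng, 4, 8)
            assert build_matching_chain(G).is_reversible_within_size()

    def test_c4_hitting_time_finite_positive(self):
        ch = build_matching_chain(nx.cycle_graph(4))
        t = ch.hitting_time_from([])
        assert 0 < t < float("inf")

    def test_exports_round_trip(self, tmp_path):
        ch = build_matching_chain(nx.cycle_graph(4))
        ch.export_states_and_transitions(tmp_path / "s.csv", tmp_path / "t.csv")
        assert (tmp_path / "s.csv").read_text().count("\n") == len(ch.states) + 1


class TestMatchingIO:
    def test_round_trip(self, tmp_path, path4):
        write_matching([("a", "b")], tmp_path / "m.txt")
        assert read_matching(tmp_path / "m.txt", path4) == frozenset({("a", "b")})

    def test_overlapping_pairs_rejected(self, tmp_path, path4):
        (tmp_path / "m.txt").write_text("a b\nb c\n")
        with pytest.raises(MatchingError):
            read_matching(tmp_path / "m.txt", path4)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.integers(0, 10**6))
def test_hk_bound_never_exceeds_true_ratio(seed):
    """Property: on any random graph, for the maximal greedy matching the
    augmenting-path quality bound is a valid lower bound on the true ratio."""
    rng = Random(seed)
    G = random_graph(rng, 4, 8)
    M, used = [], set()
    edges = list(G.edges())
    rng.shuffle(edges)
    for u, v in edges:
        if u not in used and v not in used:
            M.append((u, v))
            used.update((u, v))
    rep = shortest_augmenting_path(G, M)
    assert approximation_ratio(G, M) >= hk_bound(rep.shortest_length)
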