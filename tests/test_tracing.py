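import numpy as np
import networkx as nx
import pytest

from cryotrace.candidates import CandidateSet, CaCandidate
from cryotrace.constants import AA_INDEX
from cryotrace.tracing import (
    Fragment,
    assign_chains,
    build_graph,
    build_score_matrix,
    dedupe_sequences,
    extract_traces,
    fill_gaps,
    merge_and_rank_fragments,
    propagate_scores,
    prune_graph,
    refine_with_af3,
    seed_and_extend_fragments,
    trace_backbone,
)


def _cands(coords, probs=None, aa_probs=None):
    cs = CandidateSet()
    for n, c in enumerate(coords):
        p = 0.9 if probs is None else probs[n]
        aa = np.full(20, 1 / 20.0) if aa_probs is None else aa_probs[n]
        cs.candidates.append(
            CaCandidate(coord=np.asarray(c, dtype=float), ca_prob=p,
                        backbone_score=p, aa_probs=aa)
        )
    return cs


def _chain_coords(n, spacing=3.8):
    return [(spacing * i, 0.0, 0.0) for i in range(n)]


class TestGraph:
    def test_pair_at_ideal_distance_connected(self):
        g = build_graph(_cands([(0, 0, 0), (3.8, 0, 0)]))
        assert g.has_edge(0, 1)

    def test_pair_below_minimum_not_connected(self):
        g = build_graph(_cands([(0, 0, 0), (1.5, 0, 0)]))
        assert g.number_of_edges() == 0

    def test_edges_match_all_pairs_scan(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 15, (40, 3))
        g = build_graph(_cands(coords))
        expected = set()
        for i in range(40):
            for j in range(i + 1, 40):
                d = np.linalg.norm(coords[i] - coords[j])
                if 2.0 <= d <= 6.0:
                    expected.add((i, j))
        assert {tuple(sorted(e)) for e in g.edges} == expected


class TestPrune:
    def test_star_center_keeps_two_best_edges(self):
        g = nx.Graph()
        for n, w in enumerate([0.1, 0.5, 0.9, 0.7], start=1):
            g.add_edge(0, n, weight=w, length=3.8)
        pruned = prune_graph(g)
        assert pruned.degree(0) == 2
        assert set(pruned.neighbors(0)) == {3, 4}

    def test_path_graph_unchanged(self):
        g = nx.path_graph(5)
        for u, v in g.edges:
            g.edges[u, v]["weight"] = 1.0
            g.edges[u, v]["length"] = 3.8
        pruned = prune_graph(g)
        assert set(pruned.edges) == set(g.edges)

    def test_random_geometric_graphs_pruned_to_degree_two(self):
        rng = np.random.default_rng(1)
        for seed in range(5):
            coords = np.random.default_rng(seed).uniform(0, 12, (50, 3))
            pruned = prune_graph(build_graph(_cands(coords)))
            assert max((d for _, d in pruned.degree()), default=0) <= 2

    def test_invariant_under_candidate_relabeling(self):
        rng = np.random.default_rng(2)
        coords = rng.uniform(0, 12, (25, 3))
        perm = rng.permutation(25)
        g1 = prune_graph(build_graph(_cands(coords)))
        g2 = prune_graph(build_graph(_cands(coords[perm])))
        # relabel g2 back into g1's namespace
        inv = {int(n): int(o) for n, o in enumerate(perm)}
        edges2 = {tuple(sorted((inv[u], inv[v]))) for u, v in g2.edges}
        assert edges2 == {tuple(sorted(e)) for e in g1.edges}


class TestTraces:
    def test_path_component_extracted_in_order(self):
        g = prune_graph(build_graph(_cands(_chain_coords(5))))
        traces = extract_traces(g)
        assert traces == [[0, 1, 2, 3, 4]]

    def test_cycle_cut_at_weakest_edge(self):
        g = nx.cycle_graph(4)
        for n, (u, v) in enumerate(g.edges):
            g.edges[u, v]["weight"] = 1.0
            g.edges[u, v]["length"] = 3.8
        g.edges[0, 1]["weight"] = 0.1
        traces = extract_traces(g)
        assert len(traces) == 1 and len(traces[0]) == 4
        assert set(traces[0]) == {0, 1, 2, 3}
        # the weak edge is the cut: 0 and 1 are the endpoints
        assert {traces[0][0], traces[0][-1]} == {0, 1}

    def test_traces_partition_nodes(self):
        rng = np.random.default_rng(3)
        coords = rng.uniform(0, 14, (40, 3))
        g = prune_graph(build_graph(_cands(coords)))
        traces = extract_traces(g)
        nodes = [n for t in traces for n in t]
        assert sorted(nodes) == sorted(g.nodes)

    def test_unpruned_graph_rejected(self):
        g = nx.star_graph(3)
        for u, v in g.edges:
            g.edges[u, v]["weight"] = 1.0
        with pytest.raises(ValueError):
            extract_traces(g)


def _one_hot(letter):
    v = np.zeros(20)
    v[AA_INDEX[letter]] = 1.0
    return v


class TestScoreMatrix:
    def test_one_hot_candidate(self):
        cs = _cands([(0, 0, 0)], aa_probs=[_one_hot("G")])
        S = build_score_matrix(cs, ["GA"])
        assert S[0][0, 0] == 1.0
        assert S[0][1, 0] == 0.0

    def test_uniform_probabilities(self):
        S = build_score_matrix(_cands([(0, 0, 0)]), ["AC"])
        np.testing.assert_allclose(S[0], 0.05)

    def test_unknown_residue_letter_uniform(self):
        cs = _cands([(0, 0, 0)], aa_probs=[_one_hot("G")])
        S = build_score_matrix(cs, ["X"])
        assert S[0][0, 0] == pytest.approx(1 / 20)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(4)
        aa = rng.dirichlet(np.ones(20), size=6)
        cs = _cands(rng.uniform(0, 20, (6, 3)), aa_probs=list(aa))
        seqs = ["GAVL", "WY"]
        S = build_score_matrix(cs, seqs)
        for i, seq in enumerate(seqs):
            for j, letter in enumerate(seq):
                for k in range(6):
                    assert S[i][j, k] == pytest.approx(aa[k][AA_INDEX[letter]])


class TestPropagation:
    def test_isolated_candidate_one_hop_divides_by_three(self):
        cs = _cands([(0, 0, 0)], aa_probs=[_one_hot("G")])
        g = nx.Graph()
        g.add_node(0)
        S = build_score_matrix(cs, ["GAG"])
        S2 = propagate_scores(S, g, n_hops=1)
        np.testing.assert_allclose(S2[0], S[0] / 3.0)

    def test_perfect_chain_saturates_interior(self):
        seq = "GAV"
        cs = _cands(_chain_coords(3), aa_probs=[_one_hot(c) for c in seq])
        g = prune_graph(build_graph(cs))
        S = build_score_matrix(cs, [seq])
        S2 = propagate_scores(S, g, n_hops=1)
        # middle residue on the true diagonal sees all three agreeing terms
        assert S2[0][1, 1] == pytest.approx(1.0)
        # chain ends lose the out-of-range term
        assert S2[0][0, 0] == pytest.approx(2 / 3)
        assert S2[0][2, 2] == pytest.approx(2 / 3)

    def test_zero_hops_is_identity(self):
        rng = np.random.default_rng(5)
        cs = _cands(rng.uniform(0, 10, (8, 3)))
        g = prune_graph(build_graph(cs))
        S = build_score_matrix(cs, ["GAVLIK"])
        S2 = propagate_scores(S, g, n_hops=0)
        np.testing.assert_array_equal(S2[0], S[0])


class TestFragments:
    def _perfect_case(self, n=10, seed=6):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), n))
        cs = _cands(_chain_coords(n), aa_probs=[_one_hot(c) for c in seq])
        g = prune_graph(build_graph(cs))
        S2 = propagate_scores(build_score_matrix(cs, [seq]), g)
        return cs, g, seq, S2

    def test_oracle_scores_recover_full_chain_fragment(self):
        cs, g, seq, S2 = self._perfect_case()
        frags = seed_and_extend_fragments(S2, g, [seq], cs)
        assert len(frags) >= 1
        best = max(frags, key=lambda f: len(f.cand_ids))
        assert best.start_j == 0
        assert best.cand_ids == list(range(10))

    def test_no_seeds_below_threshold(self):
        cs, g, seq, S2 = self._perfect_case()
        frags = seed_and_extend_fragments(
            [np.full_like(S2[0], 0.1)], g, [seq], cs
        )
        assert frags == []

    def test_fragment_candidates_are_unique(self):
        cs, g, seq, S2 = self._perfect_case(n=20, seed=7)
        for frag in seed_and_extend_fragments(S2, g, [seq], cs):
            assert len(set(frag.cand_ids)) == len(frag.cand_ids)


class TestMergeAndRank:
    def test_agreeing_overlap_merges(self):
        f1 = Fragment(0, 0, [10, 11, 12, 13, 14], 0.9)  # residues 0-4
        f2 = Fragment(0, 3, [13, 14, 15, 16, 17], 0.8)  # residues 3-7
        merged = merge_and_rank_fragments([f1, f2])
        assert len(merged) == 1
        assert merged[0].start_j == 0
        assert merged[0].cand_ids == [10, 11, 12, 13, 14, 15, 16, 17]

    def test_disjoint_fragments_sorted_by_score(self):
        f1 = Fragment(0, 0, [1, 2, 3], 0.5)
        f2 = Fragment(0, 10, [4, 5, 6], 0.9)
        merged = merge_and_rank_fragments([f1, f2])
        assert [f.score for f in merged] == [0.9, 0.5]

    def test_conflicting_overlap_trims_lower_score(self):
        f1 = Fragment(0, 0, [1, 2, 3, 4, 5, 6], 0.9)  # residues 0-5
        f2 = Fragment(0, 3, [7, 8, 9, 10, 11], 0.5)  # residues 3-7, conflicts 3-5
        merged = merge_and_rank_fragments([f1, f2])
        high = next(f for f in merged if f.score == 0.9)
        assert high.cand_ids == [1, 2, 3, 4, 5, 6]
        for f in merged:
            if f is high:
                continue
            assert set(range(f.start_j, f.end_j + 1)).isdisjoint(range(0, 6))


class TestAssignment:
    def test_non_conflicting_fragments_both_assigned(self):
        frags = [Fragment(0, 0, [1, 2, 3], 0.9), Fragment(0, 5, [4, 5, 6], 0.8)]
        a = assign_chains(frags, [("A", "ACDEFGHIKL")])
        assert len(a.copies[0].positions) == 6

    def test_position_conflict_keeps_higher_score(self):
        frags = [Fragment(0, 3, [1, 2, 3], 0.9), Fragment(0, 5, [4, 5, 6], 0.5)]
        a = assign_chains(frags, [("A", "ACDEFGHIKL")])
        # residue 5 claimed by the better fragment; the weaker one is skipped
        assert a.copies[0].positions[5] == 3
        assert 4 not in a.used_cands

    def test_homodimer_fills_copies_in_order(self):
        frags = [Fragment(0, 0, [1, 2, 3], 0.9), Fragment(0, 0, [4, 5, 6], 0.8)]
        a = assign_chains(frags, [("A", "GAV"), ("B", "GAV")])
        assert a.copies[0].positions == {0: 1, 1: 2, 2: 3}
        assert a.copies[1].positions == {0: 4, 1: 5, 2: 6}

    def test_dedupe_sequences_groups_copies(self):
        unique, copies = dedupe_sequences([("A", "GAV"), ("B", "WY"), ("C", "GAV")])
        assert unique == ["GAV", "WY"]
        assert copies == [["A", "C"], ["B"]]


class TestRegisterRefinement:
    def test_off_by_one_register_corrected(self, make_ca_structure):
        n = 12
        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), n))
        coords = np.array(_chain_coords(n)) + rng.normal(0, 0.05, (n, 3))
        predicted = make_ca_structure(coords, seq)
        cs = _cands(coords[2:8])
        # candidates 0..5 are truly residues 2..7, but registered at 3..8
        frags = [Fragment(0, 3, list(range(6)), 0.9)]
        a = assign_chains(frags, [("A", seq)])
        refined = refine_with_af3(a, {0: predicted}, cs)
        assert sorted(refined.copies[0].positions) == list(range(2, 8))

    def test_correct_register_is_fixed_point(self, make_ca_structure):
        n = 10
        seq = "ACDEFGHIKL"
        coords = np.array(_chain_coords(n))
        predicted = make_ca_structure(coords, seq)
        cs = _cands(coords[2:8])
        frags = [Fragment(0, 2, list(range(6)), 0.9)]
        a = assign_chains(frags, [("A", seq)])
        before = dict(a.copies[0].positions)
        refined = refine_with_af3(a, {0: predicted}, cs)
        assert refined.copies[0].positions == before

    def test_missing_predicted_chain_is_noop(self):
        frags = [Fragment(0, 0, [0, 1, 2], 0.9)]
        cs = _cands(_chain_coords(3))
        a = assign_chains(frags, [("A", "GAV")])
        before = dict(a.copies[0].positions)
        refined = refine_with_af3(a, {}, cs)
        assert refined.copies[0].positions == before


class TestGapFilling:
    def test_gap_closed_through_candidates(self):
        n = 9
        seq = "ACDEFGHIK"
        coords = _chain_coords(n)
        cs = _cands(coords)
        g = prune_graph(build_graph(cs))
        frags = [Fragment(0, 0, [0, 1, 2], 0.9), Fragment(0, 6, [6, 7, 8], 0.8)]
        a = assign_chains(frags, [("A", seq)])
        model = fill_gaps(a, cs, g)
        chain = model.chains[0]
        assert all(r.coord is not None for r in chain.residues)
        assert all(r.flag == "traced" for r in chain.residues)
        np.testing.assert_allclose(chain.residues[4].coord, coords[4])

    def test_gap_without_candidates_uses_predicted_segment(self, make_ca_structure):
        n = 9
        seq = "ACDEFGHIK"
        coords = np.array(_chain_coords(n))
        predicted = make_ca_structure(coords, seq)
        keep = [0, 1, 2, 6, 7, 8]
        cs = _cands(coords[keep])
        g = prune_graph(build_graph(cs))
        frags = [Fragment(0, 0, [0, 1, 2], 0.9), Fragment(0, 6, [3, 4, 5], 0.8)]
        a = assign_chains(frags, [("A", seq)])
        model = fill_gaps(a, cs, g, af3={0: predicted})
        chain = model.chains[0]
        flags = [r.flag for r in chain.residues]
        assert flags[3:6] == ["gap-filled"] * 3
        np.testing.assert_allclose(chain.residues[4].coord, coords[4], atol=1e-6)

    def test_zero_length_gap_identity(self):
        seq = "ACDEF"
        cs = _cands(_chain_coords(5))
        g = prune_graph(build_graph(cs))
        frags = [Fragment(0, 0, list(range(5)), 0.9)]
        a = assign_chains(frags, [("A", seq)])
        model = fill_gaps(a, cs, g)
        assert all(r.flag == "traced" for r in model.chains[0].residues)

    def test_unfillable_residues_flagged_unmodeled(self):
        seq = "ACDEFGHIK"
        coords = _chain_coords(9)
        cs = _cands(coords[:3])
        g = prune_graph(build_graph(cs))
        frags = [Fragment(0, 0, [0, 1, 2], 0.9)]
        a = assign_chains(frags, [("A", seq)])
        model = fill_gaps(a, cs, g)
        flags = [r.flag for r in model.chains[0].residues]
        assert flags[:3] == ["traced"] * 3
        assert set(flags[3:]) == {"unmodeled"}


class TestEndToEndUniqueness:
    def test_no_candidate_or_position_duplicated(self):
        rng = np.random.default_rng(9)
        n = 30
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), n))
        coords = np.array(_chain_coords(n)) + rng.normal(0, 0.1, (n, 3))
        cs = _cands(coords, aa_probs=[_one_hot(c) for c in seq])
        model = trace_backbone(cs, [("A", seq)])
        placed = [
            (c.chain_id, r.res_index)
            for c in model.chains
            for r in c.residues
            if r.coord is not None
        ]
        assert len(placed) == len(set(placed))
        coords_placed = [
            tuple(np.round(r.coord, 6))
            for c in model.chains
            for r in c.residues
            if r.coord is not None and r.flag == "traced"
        ]
        assert len(coords_placed) == len(set(coords_placed))
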