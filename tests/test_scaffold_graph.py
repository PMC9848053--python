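import itertools

import numpy as np
import pytest

from hicscaf.contact_matrix import ChunkIndex, build_matrix
from hicscaf.formats_io import Assembly, Contig, PairTable
from hicscaf.join_scoring import JoinScore
from hicscaf.scaffold_graph import (ScaffoldGraph, build_graph, drop_ambiguous,
                                    other_end, pop_bubbles, remove_transitive,
                                    resolve_orientations, run_cascade, solve_repeats,
                                    traverse, trim_blunt_ends, trim_tips,
                                    trim_weak_edges)


def graph_from_edges(edges):
    """edges: iterable of ((cid, side), (cid, side), score)."""
    g = ScaffoldGraph()
    for u, v, s in edges:
        g.add_edge(tuple(u), tuple(v), s)
    return g


def edge_set(g):
    return {(u, v) for u, v, _ in g.edges()}


def random_graph(rng, n_contigs=8, n_edges=10):
    contigs = [f"c{i:02d}" for i in range(n_contigs)]
    g = ScaffoldGraph(contigs)
    tries = 0
    while g.n_edges < n_edges and tries < 200:
        tries += 1
        a, b = rng.choice(n_contigs, 2, replace=False)
        u = (contigs[a], "HT"[rng.integers(2)])
        v = (contigs[b], "HT"[rng.integers(2)])
        if not g.has_edge(u, v):
            g.add_edge(u, v, float(np.round(rng.random(), 6)))
    return g


class TestBuildGraph:
    def test_edge_added(self):
        g = build_graph([JoinScore("A", "B", "TH", 0.9, 4)], min_score=0.1)
        assert g.has_edge(("A", "T"), ("B", "H"))

    def test_low_score_filtered(self):
        g = build_graph([JoinScore("A", "B", "TH", 0.9, 4)], min_score=0.95)
        assert g.n_edges == 0

    def test_count_matches_threshold(self):
        rng = np.random.default_rng(2)
        scores = [JoinScore(f"a{i}", f"b{i}", "TH", float(rng.random()), 1)
                  for i in range(40)]
        g = build_graph(scores, min_score=0.5)
        assert g.n_edges == sum(1 for s in scores if s.score >= 0.5)

    def test_duplicate_edge_rejected(self):
        scores = [JoinScore("A", "B", "TH", 0.9, 4), JoinScore("A", "B", "TH", 0.8, 4)]
        with pytest.raises(ValueError, match="duplicate"):
            build_graph(scores, min_score=0.1)


def oracle_is_tip(g, junction, first, max_tip):
    """Recursive re-derivation of the dead-end predicate."""
    def walk(entry, seen, count):
        if count > max_tip:
            return False
        out = other_end(entry)
        nbrs = g.neighbors(out)
        if not nbrs:
            return True
        if len(nbrs) > 1:
            return False
        (nxt,) = nbrs
        if nxt == junction or nxt[0] == junction[0] or nxt[0] in seen:
            return False
        if g.degree(nxt) > 1:
            return False
        return walk(nxt, seen | {nxt[0]}, count + 1)

    if g.degree(first) > 1:
        return False
    return walk(first, {first[0]}, 1)


def oracle_trim_tips(g, max_tip):
    g = g.copy()
    while True:
        changed = False
        for u in g.ends():
            while g.degree(u) >= 2:
                tips = sorted((v for v in g.neighbors(u)
                               if oracle_is_tip(g, u, v, max_tip)),
                              key=lambda v: (g.score(u, v), v))
                if not tips:
                    break
                g.remove_edge(u, tips[0])
                changed = True
        if not changed:
            return g


class TestTrimTips:
    def test_spur_removed(self):
        g = graph_from_edges([
            (("A", "T"), ("B", "H"), 0.9),
            (("B", "T"), ("C", "H"), 0.9),
            (("B", "T"), ("D", "H"), 0.3),
        ])
        trim_tips(g, 1)
        assert not g.has_edge(("B", "T"), ("D", "H"))
        assert g.has_edge(("B", "T"), ("C", "H"))

    def test_pure_path_unchanged(self):
        g = graph_from_edges([
            (("A", "T"), ("B", "H"), 0.9),
            (("B", "T"), ("C", "H"), 0.9),
        ])
        before = edge_set(g)
        trim_tips(g, 1)
        assert edge_set(g) == before

    def test_random_graphs_match_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(60):
            g = random_graph(rng, n_contigs=10, n_edges=12)
            want = edge_set(oracle_trim_tips(g, 1))
            got = edge_set(trim_tips(g.copy(), 1))
            assert got == want


class TestTrimBluntEnds:
    def test_non_reciprocal_best_removed(self):
        g = graph_from_edges([
            (("U", "T"), ("V", "H"), 0.9),
            (("U", "T"), ("W", "H"), 0.2),
            (("W", "H"), ("X", "H"), 0.5),
        ])
        trim_blunt_ends(g)
        assert not g.has_edge(("U", "T"), ("W", "H"))
        assert g.has_edge(("U", "T"), ("V", "H"))
        assert g.has_edge(("W", "H"), ("X", "H"))

    def test_reciprocal_best_kept(self):
        g = graph_from_edges([(("A", "T"), ("B", "H"), 0.5)])
        trim_blunt_ends(g)
        assert g.n_edges == 1

    def test_random_graphs_match_direct_definition(self):
        rng = np.random.default_rng(78)
        for _ in range(60):
            g = random_graph(rng)
            best = {e: max(g.score(e, v) for v in g.neighbors(e)) for e in g.ends()}
            want = {(u, v) for u, v, s in g.edges()
                    if s >= best[u] or s >= best[v]}
            got = edge_set(trim_blunt_ends(g.copy()))
            assert got == want


class TestSolveRepeats:
    @staticmethod
    def _matrix(lengths, pair_positions):
        asm = Assembly([Contig(n, ln) for n, ln in lengths.items()])
        idx = ChunkIndex(asm, 1000)
        names = asm.names
        c1, p1, c2, p2 = zip(*pair_positions)
        table = PairTable(names, [names.index(c) for c in c1], p1,
                          [names.index(c) for c in c2], p2)
        return build_matrix(table, idx)

    def test_uniform_coverage_keeps_all(self):
        lengths = {"A": 2000, "B": 2000, "C": 2000}
        pairs = [(c, 100, c, 1500) for c in lengths for _ in range(5)]
        m = self._matrix(lengths, pairs)
        g = graph_from_edges([(("A", "T"), ("B", "H"), 0.9),
                              (("B", "T"), ("C", "H"), 0.9)])
        solve_repeats(g, m, 2.0)
        assert g.n_edges == 2

    def test_dense_contig_isolated(self):
        lengths = {"A": 2000, "B": 2000, "C": 2000}
        pairs = [(c, 100, c, 1500) for c in lengths for _ in range(5)]
        pairs += [("B", 100, "B", 1500)] * 45  # 10x density on B
        m = self._matrix(lengths, pairs)
        g = graph_from_edges([(("A", "T"), ("B", "H"), 0.9),
                              (("B", "T"), ("C", "H"), 0.9),
                              (("A", "H"), ("C", "T"), 0.8)])
        solve_repeats(g, m, 2.0)
        assert g.degree(("B", "H")) == 0 and g.degree(("B", "T")) == 0
        assert g.has_edge(("A", "H"), ("C", "T"))

    def test_collapsed_repeat_simulation(self):
        # one contig receives 3x sampled signal: flagged by density
        lengths = {"A": 3000, "R": 3000, "C": 3000}
        pairs = []
        for c, mult in (("A", 1), ("R", 3), ("C", 1)):
            pairs += [(c, 200, c, 2500)] * (8 * mult)
        m = self._matrix(lengths, pairs)
        g = graph_from_edges([(("A", "T"), ("R", "H"), 0.9),
                              (("R", "T"), ("C", "H"), 0.9)])
        solve_repeats(g, m, 2.0)
        assert g.n_edges == 0  # R isolated; A and C keep no edges to it


class TestRemoveTransitive:
    def test_shortcut_removed(self):
        g = graph_from_edges([
            (("A", "T"), ("B", "H"), 0.9),
            (("B", "T"), ("C", "H"), 0.9),
            (("A", "T"), ("C", "H"), 0.4),
        ])
        remove_transitive(g)
        assert not g.has_edge(("A", "T"), ("C", "H"))
        assert g.n_edges == 2

    def test_inconsistent_ends_kept(self):
        g = graph_from_edges([
            (("A", "T"), ("B", "H"), 0.9),
            (("B", "T"), ("C", "H"), 0.9),
            (("A", "T"), ("C", "T"), 0.4),  # wrong end of C: not transitive
        ])
        remove_transitive(g)
        assert g.has_edge(("A", "T"), ("C", "T"))

    def test_random_graphs_match_enumeration(self):
        rng = np.random.default_rng(79)
        for _ in range(60):
            g = random_graph(rng, n_contigs=12, n_edges=14)
            doomed = set()
            for u, v, _s in g.edges():
                # u—v is transitive if some contig w chains u..w..v
                for w in g.contigs:
                    if w in (u[0], v[0]):
                        continue
                    for side in "HT":
                        e1, e2 = (w, side), (w, "T" if side == "H" else "H")
                        if g.has_edge(u, e1) and g.has_edge(e2, v):
                            doomed.add((u, v))
            want = edge_set(g) - doomed
            got = edge_set(remove_transitive(g.copy()))
            assert got == want


class TestPopBubbles:
    def test_weaker_branch_removed(self):
        g = graph_from_edges([
            (("A", "T"), ("B", "H"), 0.9), (("B", "T"), ("D", "H"), 0.95),
            (("A", "T"), ("C", "H"), 0.3), (("C", "T"), ("D", "H"), 0.8),
        ])
        pop_bubbles(g, 3)
        assert g.has_edge(("A", "T"), ("B", "H"))
        assert g.has_edge(("B", "T"), ("D", "H"))
        assert not g.has_edge(("A", "T"), ("C", "H"))
        assert not g.has_edge(("C", "T"), ("D", "H"))

    def test_no_parallel_paths_unchanged(self):
        g = graph_from_edges([
            (("A", "T"), ("B", "H"), 0.9),
            (("B", "T"), ("C", "H"), 0.9),
        ])
        before = edge_set(g)
        pop_bubbles(g, 3)
        assert edge_set(g) == before

    def test_direct_vs_detour(self):
        g = graph_from_edges([
            (("A", "T"), ("D", "H"), 0.95),
            (("A", "T"), ("C", "H"), 0.3), (("C", "T"), ("D", "H"), 0.8),
        ])
        pop_bubbles(g, 3)
        assert g.has_edge(("A", "T"), ("D", "H"))
        assert g.n_edges == 1


class TestResolveOrientations:
    def test_dominant_kept(self):
        g = graph_from_edges([
            (("A", "T"), ("B", "H"), 0.8),
            (("A", "T"), ("B", "T"), 0.2),
        ])
        resolve_orientations(g, 1.5)
        assert g.has_edge(("A", "T"), ("B", "H"))
        assert g.n_edges == 1

    def test_ambiguous_pair_cleared(self):
        g = graph_from_edges([
            (("A", "T"), ("B", "H"), 0.5),
            (("A", "H"), ("B", "T"), 0.4),
        ])
        resolve_orientations(g, 1.5)
        assert g.n_edges == 0

    def test_single_edge_untouched(self):
        g = graph_from_edges([(("A", "T"), ("B", "H"), 0.05)])
        resolve_orientations(g, 1.5)
        assert g.n_edges == 1


class TestTrimWeakEdges:
    def test_weak_edge_removed(self):
        g = graph_from_edges([
            (("A", "T"), ("B", "H"), 1.0),
            (("A", "T"), ("C", "H"), 0.5),
        ])
        trim_weak_edges(g, 0.7)
        assert not g.has_edge(("A", "T"), ("C", "H"))

    def test_equal_scores_unchanged(self):
        g = graph_from_edges([
            (("A", "T"), ("B", "H"), 0.6),
            (("A", "T"), ("C", "H"), 0.6),
        ])
        trim_weak_edges(g, 0.7)
        assert g.n_edges == 2

    def test_random_graphs_match_direct_definition(self):
        rng = np.random.default_rng(80)
        for _ in range(60):
            g = random_graph(rng)
            best = {e: max(g.score(e, v) for v in g.neighbors(e)) for e in g.ends()}
            want = {(u, v) for u, v, s in g.edges()
                    if s >= 0.75 * max(best[u], best[v])}
            got = edge_set(trim_weak_edges(g.copy(), 0.75))
            assert got == want


class TestDropAmbiguous:
    def test_tied_edges_both_removed(self):
        g = graph_from_edges([
            (("A", "T"), ("B", "H"), 0.6),
            (("A", "T"), ("C", "H"), 0.6),
        ])
        drop_ambiguous(g)
        assert g.n_edges == 0

    def test_clean_path_unchanged(self):
        g = graph_from_edges([
            (("A", "T"), ("B", "H"), 0.9),
            (("B", "T"), ("C", "H"), 0.9),
        ])
        drop_ambiguous(g)
        assert g.n_edges == 2

    def test_postcondition_degree_le_one(self):
        rng = np.random.default_rng(81)
        for _ in range(40):
            g = random_graph(rng, n_contigs=9, n_edges=14)
            drop_ambiguous(g)
            assert all(g.degree(e) <= 1 for e in g.ends())


class TestCascadeProperties:
    def test_ops_only_delete_edges(self):
        rng = np.random.default_rng(82)
        for _ in range(30):
            g = random_graph(rng)
            for op in (lambda h: trim_tips(h, 1), trim_blunt_ends, remove_transitive,
                       lambda h: pop_bubbles(h, 3),
                       lambda h: resolve_orientations(h, 1.5),
                       lambda h: trim_weak_edges(h, 0.75), drop_ambiguous):
                before = edge_set(g)
                op(g)
                assert edge_set(g) <= before

    def test_cascade_reaches_degree_le_one(self, toy_assembly):
        rng = np.random.default_rng(83)
        idx = ChunkIndex(toy_assembly, 100)
        empty = build_matrix(PairTable(toy_assembly.names, [], [], [], []), idx)
        for _ in range(25):
            g = random_graph(rng, n_contigs=3, n_edges=5)
            g2 = random_graph(rng, n_contigs=3, n_edges=5)
            # relabel to the toy assembly's contig names
            relabeled = ScaffoldGraph(toy_assembly.names)
            mapping = dict(zip(sorted(g.contigs | g2.contigs), toy_assembly.names))
            for u, v, s in g.edges():
                relabeled.add_edge((mapping[u[0]], u[1]), (mapping[v[0]], v[1]), s)
            run_cascade(relabeled, empty)
            assert all(relabeled.degree(e) <= 1 for e in relabeled.ends())


class TestTraverse:
    def test_simple_path(self):
        g = graph_from_edges([
            (("A", "T"), ("B", "H"), 0.9),
            (("B", "T"), ("C", "H"), 0.8),
        ])
        paths = traverse(g, {"A": 100, "B": 100, "C": 100})
        assert len(paths) == 1
        items = paths[0].items
        if items[0][0] == "C":
            items = [(c, {"+": "-", "-": "+"}[o]) for c, o in reversed(items)]
        assert items == [("A", "+"), ("B", "+"), ("C", "+")]

    def test_orientation_flip(self):
        g = graph_from_edges([(("A", "T"), ("B", "T"), 0.9)])
        paths = traverse(g, {"A": 100, "B": 100})
        assert paths[0].items in ([("A", "+"), ("B", "-")], [("B", "+"), ("A", "-")])

    def test_singletons_and_conservation(self):
        g = graph_from_edges([(("A", "T"), ("B", "H"), 0.9)])
        paths = traverse(g, {"A": 100, "B": 100, "Z": 500})
        placed = sorted(c for p in paths for c, _ in p.items)
        assert placed == ["A", "B", "Z"]
        assert paths[0].items == [("Z", "+")]  # longest first

    def test_cycle_broken_at_min_edge(self):
        g = graph_from_edges([
            (("A", "T"), ("B", "H"), 0.9),
            (("B", "T"), ("C", "H"), 0.8),
            (("C", "T"), ("A", "H"), 0.2),  # weakest: cut here
        ])
        paths = traverse(g, {"A": 100, "B": 100, "C": 100})
        assert len(paths) == 1
        items = paths[0].items
        if items[0][0] != "A":
            items = [(c, {"+": "-", "-": "+"}[o]) for c, o in reversed(items)]
        assert items == [("A", "+"), ("B", "+"), ("C", "+")]

    def test_cycle_cut_matches_exhaustive_choice(self):
        # removing the min edge yields the path with max total retained score
        scores = [0.5, 0.9, 0.7]
        g = graph_from_edges([
            (("A", "T"), ("B", "H"), scores[0]),
            (("B", "T"), ("C", "H"), scores[1]),
            (("C", "T"), ("A", "H"), scores[2]),
        ])
        paths = traverse(g, {"A": 100, "B": 100, "C": 100})
        assert len(paths) == 1 and len(paths[0].items) == 3
        # min edge (0.5) is A.T—B.H: path must not contain A+ followed by B+
        seq = paths[0].items
        for (c1, o1), (c2, o2) in zip(seq, seq[1:]):
            assert not (c1 == "A" and o1 == "+" and c2 == "B" and o2 == "+")
            assert not (c2 == "A" and o2 == "-" and c1 == "B" and o1 == "-")

    def test_degree_two_rejected(self):
        g = graph_from_edges([
            (("A", "T"), ("B", "H"), 0.9),
            (("A", "T"), ("C", "H"), 0.8),
        ])
        with pytest.raises(ValueError, match="degree"):
            traverse(g, {"A": 100, "B": 100, "C": 100})

    def test_contig_conservation_random(self):
        rng = np.random.default_rng(84)
        for _ in range(25):
            g = random_graph(rng, n_contigs=10, n_edges=12)
            drop_ambiguous(g)
            lengths = {f"c{i:02d}": 100 + i for i in range(10)}
            paths = traverse(g, lengths)
            placed = sorted(c for p in paths for c, _ in p.items)
            assert placed == sorted(lengths)
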