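"""Matching-path logic and iterative path extension."""

import itertools

import numpy as np
import pytest

from isoforge.align import LongReadPath, PairedLink
from isoforge.extend import (
    EdgePath,
    ExtensionConfig,
    PathSet,
    add_fl_paths,
    extend_all_paths,
    find_matching_paths,
    is_matching,
    longest_common_subpath,
    select_extension_edge_pe,
    select_extension_edges_lr,
)

from conftest import toy_graph


def oracle_is_matching(P, R):
    """Brute force over every suffix offset and containment position."""
    P, R = tuple(P), tuple(R)
    n = len(P)
    case_i = any(P[i:] == R[: n - i] for i in range(n) if n - i <= len(R))
    case_ii = any(R[s : s + n] == P for s in range(1, len(R) - n + 1))
    return case_i or case_ii


def oracle_lcs(P, R):
    """Longest common contiguous subpath by exhaustive substring enumeration."""
    best = ()
    for i in range(len(P)):
        for j in range(i + 1, len(P) + 1):
            sub = tuple(P[i:j])
            if len(sub) > len(best) and any(
                tuple(R[s : s + len(sub)]) == sub for s in range(len(R) - len(sub) + 1)
            ):
                best = sub
    return best


class TestIsMatching:
    @pytest.mark.parametrize(
        "P,R,expected",
        [
            (("a", "b", "c"), ("b", "c", "d"), True),   # suffix (b,c) prefix of R
            (("a", "b", "c"), ("x", "a", "b", "c", "y"), True),  # containment
            (("a", "b", "c"), ("a", "b", "c"), True),   # whole P is a prefix of R
            (("a", "b", "c"), ("c",), True),            # suffix (c) is all of R
            (("a", "b", "c"), ("a", "c"), False),
            (("a", "b", "c"), ("d", "b", "c"), False),  # (b,c) not a prefix of R
            (("a", "b", "c"), ("b",), False),           # ends before P does
        ],
    )
    def test_examples(self, P, R, expected):
        assert is_matching(P, R) is expected
        assert oracle_is_matching(P, R) is expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            is_matching((), ("a",))

    def test_oracle_equivalence_exhaustive_small(self):
        # every P,R over a 3-symbol alphabet with lengths <= 4
        syms = (0, 1, 2)
        for lp, lr in itertools.product(range(1, 4), range(1, 5)):
            for P in itertools.product(syms, repeat=lp):
                for R in itertools.product(syms, repeat=lr):
                    assert is_matching(P, R) == oracle_is_matching(P, R)


class TestFindMatchingPaths:
    @pytest.fixture
    def chain(self):
        g, ids = toy_graph(
            [("a", "u", "v", 150), ("b", "v", "w", 150), ("c", "w", "x", 150), ("d", "x", "y", 150)]
        )
        return g, ids

    def lr(self, *path):
        return LongReadPath("r", tuple(path), (0, 100))

    def test_common_subpath_length_filter(self, chain):
        g, ids = chain
        P = (ids["a"], ids["b"], ids["c"])
        R = self.lr(ids["b"], ids["c"], ids["d"])
        # common subpath (b,c): 150+150-24 = 276 nt >= 200, 2 edges >= 2
        rp = find_matching_paths(g, P, [R], l_min=200, n_min=2)
        assert rp.members == (R,)

    def test_single_edge_subpath_excluded(self, chain):
        g, ids = chain
        P = (ids["a"], ids["b"], ids["c"])
        R = self.lr(ids["c"], ids["d"])
        # common subpath (c) has 1 edge < n_min = 2
        assert find_matching_paths(g, P, [R], 200, 2).members == ()

    def test_vacuous_filters_admit_all_matching(self, chain):
        g, ids = chain
        P = (ids["a"], ids["b"], ids["c"])
        paths = [
            self.lr(ids["b"], ids["c"], ids["d"]),
            self.lr(ids["c"], ids["d"]),
            self.lr(ids["d"],),
        ]
        rp = find_matching_paths(g, P, paths, l_min=0, n_min=1)
        assert rp.members == tuple(p for p in paths if oracle_is_matching(P, p.path))

    def test_thresholds_capped_at_seed_size(self, chain):
        # a single-edge path must be extendable: the n_min/l_min filters
        # cannot demand more overlap than the path itself has
        g, ids = chain
        P = (ids["b"],)
        R = self.lr(ids["a"], ids["b"], ids["c"])
        rp = find_matching_paths(g, P, [R], l_min=200, n_min=2)
        assert rp.members == (R,)


class TestSelectExtensionEdges:
    @pytest.fixture
    def fork(self):
        g, ids = toy_graph(
            [("a", "u", "v", 150), ("b", "v", "w", 150), ("c", "w", "x", 150),
             ("d", "x", "y1", 150), ("e", "x", "y2", 150)]
        )
        return g, ids

    def test_lr_single_supported(self, fork):
        g, ids = fork
        P = (ids["a"], ids["b"], ids["c"])
        rp = find_matching_paths(g, P, [LongReadPath("r", (ids["b"], ids["c"], ids["d"]), (0, 1))], 0, 1)
        assert select_extension_edges_lr(P, rp, [ids["d"], ids["e"]]) == [ids["d"]]

    def test_lr_multi_select_forks_isoforms(self, fork):
        g, ids = fork
        P = (ids["a"], ids["b"], ids["c"])
        rp = find_matching_paths(
            g, P,
            [LongReadPath("r1", (ids["b"], ids["c"], ids["d"]), (0, 1)),
             LongReadPath("r2", (ids["a"], ids["b"], ids["c"], ids["e"]), (0, 1))],
            0, 1,
        )
        assert select_extension_edges_lr(P, rp, [ids["d"], ids["e"]]) == sorted([ids["d"], ids["e"]])

    def test_lr_empty_set_selects_nothing(self, fork):
        g, ids = fork
        P = (ids["a"], ids["b"], ids["c"])
        rp = find_matching_paths(g, P, [], 200, 2)
        assert select_extension_edges_lr(P, rp, [ids["d"], ids["e"]]) == []

    @pytest.mark.parametrize(
        "scores,expected",
        [({"d": 40, "e": 2}, "d"), ({"d": 40, "e": 30}, None), ({"d": 3}, None)],
    )
    def test_pe_rule(self, scores, expected):
        support = {("c", e): s for e, s in scores.items()}
        got = select_extension_edge_pe(
            ("a", "b", "c"), support, sorted(scores), min_support=5, dominance=2.0
        )
        assert got == expected

    def test_pe_window_limits_evidence(self):
        support = {("a", "e"): 40}  # support from an edge beyond the window
        got = select_extension_edge_pe(
            ("a", "b", "c", "d"), support, ["e"], min_support=5, dominance=2.0, window=3
        )
        assert got is None


class TestOracleEquivalence:
    def test_matching_and_selection_agree_with_brute_force(self):
        """find_matching_paths and select_extension_edges_lr vs exhaustive
        enumeration on 200 random graphs (<= 12 edges, <= 10 long-read
        paths each)."""
        rng = np.random.default_rng(31415)
        checked = 0
        for _ in range(200):
            n_edges = int(rng.integers(3, 13))
            # random chain-with-shortcuts topology keeps paths plentiful
            defs = []
            for i in range(n_edges):
                u = f"v{rng.integers(0, max(1, i))}" if i and rng.random() < 0.4 else f"v{i}"
                v = f"v{i + 1}"
                defs.append((f"e{i}", u, v, int(rng.integers(30, 300))))
            g, ids = toy_graph(defs)
            fids = [ids[f"e{i}"] for i in range(n_edges)]

            def random_walk():
                cur = fids[int(rng.integers(n_edges))]
                path = [cur]
                while rng.random() < 0.7:
                    nxt = [e for e in g.successors(cur) if e in fids]
                    if not nxt:
                        break
                    cur = nxt[int(rng.integers(len(nxt)))]
                    path.append(cur)
                return tuple(path)

            lr = [LongReadPath(f"r{j}", random_walk(), (0, 1)) for j in range(int(rng.integers(1, 11)))]
            P = random_walk()
            l_min = int(rng.integers(0, 300))
            n_min = int(rng.integers(1, 4))
            rp = find_matching_paths(g, P, lr, l_min, n_min)
            n_eff = min(n_min, len(P))
            l_eff = min(l_min, g.path_nt_length(P))
            expected = tuple(
                R for R in lr
                if oracle_is_matching(P, R.path)
                and len(oracle_lcs(P, R.path)) >= n_eff
                and g.path_nt_length(oracle_lcs(P, R.path)) >= l_eff
            )
            assert rp.members == expected
            cands = g.successors(P[-1])
            expected_sel = sorted(
                e for e in cands if any(oracle_is_matching(P + (e,), R.path) for R in rp.members)
            )
            assert select_extension_edges_lr(P, rp, cands) == expected_sel
            checked += 1
        assert checked == 200

    def test_lcs_matches_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            P = tuple(rng.integers(0, 5, rng.integers(1, 8)))
            R = tuple(rng.integers(0, 5, rng.integers(1, 8)))
            assert len(longest_common_subpath(P, R)) == len(oracle_lcs(P, R))


class TestExtendAllPaths:
    def test_linear_chain_with_pe_links(self):
        g, ids = toy_graph(
            [("a", "u", "v", 300), ("b", "v", "w", 300), ("c", "w", "x", 300)]
        )
        links = [PairedLink(ids["a"], ids["b"], 40), PairedLink(ids["b"], ids["c"], 40),
                 PairedLink(ids["c*"], ids["b*"], 40), PairedLink(ids["b*"], ids["a*"], 40)]
        ps = extend_all_paths(g, links, [])
        chains = {p.edges for p in ps.paths}
        assert (ids["a"], ids["b"], ids["c"]) in chains
        assert ps.covered_edges == set(g.edge_ids())

    def test_double_bubble_phased_by_long_reads(self):
        # A -> {B1,B2} -> C -> {D1,D2} -> E with ambiguous PE everywhere:
        # spanning long reads phase B1 with D1 and B2 with D2
        g, ids = toy_graph(
            [("A", "s", "t", 300), ("B1", "t", "u", 200), ("B2", "t", "u", 200),
             ("C", "u", "v", 2000), ("D1", "v", "w", 200), ("D2", "v", "w", 200),
             ("E", "w", "x", 300)]
        )
        iso1 = (ids["A"], ids["B1"], ids["C"], ids["D1"], ids["E"])
        iso2 = (ids["A"], ids["B2"], ids["C"], ids["D2"], ids["E"])
        lr = [LongReadPath(f"r1_{i}", iso1, (0, 1)) for i in range(3)]
        lr += [LongReadPath(f"r2_{i}", iso2, (0, 1)) for i in range(3)]
        links = [PairedLink(a, b, 20) for a, b in
                 [(ids["A"], ids["B1"]), (ids["A"], ids["B2"]),
                  (ids["C"], ids["D1"]), (ids["C"], ids["D2"])]]
        ps = extend_all_paths(g, links, lr)
        maximal = {p.edges for p in ps.paths if len(p.edges) == 5}
        assert iso1 in maximal and iso2 in maximal
        # no phase-crossing chimera
        assert (ids["A"], ids["B1"], ids["C"], ids["D2"], ids["E"]) not in maximal
        assert (ids["A"], ids["B2"], ids["C"], ids["D1"], ids["E"]) not in maximal

    def test_pe_priority_over_long_reads(self):
        # PE confidently supports b; a long read supports only c: growing
        # rightward from a, the PE choice must win at that step and the
        # branch must not fork onto the long-read edge
        from isoforge.extend import _grow_right

        g, ids = toy_graph(
            [("a", "u", "v", 300), ("b", "v", "w", 300), ("c", "v", "x", 300)]
        )
        support = {(ids["a"], ids["b"]): 40}
        lr = [LongReadPath("r", (ids["a"], ids["c"]), (0, 1))]
        grown = _grow_right(
            g, (ids["a"],), support, lr, ExtensionConfig(), [16], [0]
        )
        assert grown == [(ids["a"], ids["b"])]

    def test_untouched_edge_becomes_own_seed(self):
        g, ids = toy_graph(
            [("a", "u", "v", 300), ("b", "v", "w", 300), ("x", "p", "q", 120)]
        )
        ps = extend_all_paths(g, [PairedLink(ids["a"], ids["b"], 40)], [])
        assert ids["x"] in ps.covered_edges
        assert (ids["x"],) in {p.edges for p in ps.paths}

    def test_fork_budget_bounds_blowup(self):
        # hub with 6 supported extensions but budget 2: no crash, coverage
        # still complete through later seeds
        defs = [("h", "u", "v", 500)] + [(f"t{i}", "v", f"w{i}", 200) for i in range(6)]
        g, ids = toy_graph(defs)
        lr = [LongReadPath(f"r{i}", (ids["h"], ids[f"t{i}"]), (0, 1)) for i in range(6)]
        ps = extend_all_paths(g, [], lr, ExtensionConfig(max_forks=2))
        assert ps.covered_edges == set(g.edge_ids())

    def test_loop_multiplicity_bounded(self):
        g, ids = toy_graph([("a", "u", "u", 300)])  # self-loop
        lr = [LongReadPath("r", (ids["a"], ids["a"]), (0, 1))]
        ps = extend_all_paths(g, [], lr, ExtensionConfig(max_edge_multiplicity=4))
        assert max(len(p.edges) for p in ps.paths) <= 4

    def test_coverage_invariant_on_random_graphs(self):
        rng = np.random.default_rng(2718)
        for _ in range(40):
            n_edges = int(rng.integers(2, 13))
            defs = []
            for i in range(n_edges):
                u = f"v{rng.integers(0, max(1, i))}" if i and rng.random() < 0.5 else f"s{i}"
                defs.append((f"e{i}", u, f"v{i + 1}", int(rng.integers(30, 400))))
            g, ids = toy_graph(defs)
            fids = [ids[f"e{i}"] for i in range(n_edges)]
            lr = []
            for j in range(int(rng.integers(0, 8))):
                cur = fids[int(rng.integers(n_edges))]
                path = [cur]
                while rng.random() < 0.6 and g.successors(path[-1]):
                    path.append(g.successors(path[-1])[int(rng.integers(len(g.successors(path[-1]))))])
                lr.append(LongReadPath(f"r{j}", tuple(path), (0, 1)))
            ps = extend_all_paths(g, [], lr)
            assert ps.covered_edges == set(g.edge_ids())


class TestAddFlPaths:
    def test_fl_paths_added_verbatim(self):
        g, ids = toy_graph([("a", "u", "v", 300), ("x", "v", "w", 200), ("c", "w", "y", 300)])
        ps = PathSet([EdgePath((ids["a"],))])
        fl = [LongReadPath("f", (ids["a"], ids["x"], ids["c"]), (0, 1), is_fl=True)]
        out = add_fl_paths(ps, fl, g)
        fl_paths = [p for p in out.paths if p.origin == "fl"]
        assert (ids["a"], ids["x"], ids["c"]) in {p.edges for p in fl_paths}

    def test_empty_fl_collection_is_noop(self):
        g, ids = toy_graph([("a", "u", "v", 300)])
        ps = PathSet([EdgePath((ids["a"],))])
        assert add_fl_paths(ps, [], g).paths == [EdgePath((ids["a"],))]
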