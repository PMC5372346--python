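import itertools

import numpy as np
import pytest

from amst import (
    Node,
    Pathway,
    SWCRecord,
    SWCTree,
    WeightMatrix,
    WeightParams,
    assemble_tree,
    build_weight_matrix,
    edge_weight,
    euclidean_weight_matrix,
    minimum_spanning_tree,
    prune_spurs,
)


def brute_force_mst_weight(w: np.ndarray) -> float:
    """Oracle: enumerate every spanning tree over the complete graph."""
    n = len(w)
    if n <= 1:
        return 0.0
    edges = list(itertools.combinations(range(n), 2))
    best = np.inf
    for subset in itertools.combinations(edges, n - 1):
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        ok = True
        for a, b in subset:
            ra, rb = find(a), find(b)
            if ra == rb:
                ok = False
                break
            parent[ra] = rb
        if ok:
            best = min(best, sum(w[a, b] for a, b in subset))
    return best


def mst_total(w: np.ndarray, parents) -> float:
    return sum(w[v, u] for v, u in parents.items() if u is not None)


def path_of(points, success=True):
    pts = [np.asarray(p, float) for p in points]
    length = sum(
        float(np.linalg.norm(b - a)) for a, b in zip(pts[:-1], pts[1:])
    )
    return Pathway(nodes=pts, length=length, success=success)


class TestEdgeWeight:
    def test_unit_step_chain_weighs_two(self):
        path = path_of([(0, 0, 0), (1, 0, 0), (2, 0, 0)])
        assert edge_weight(path, Node(0, 0, 0), Node(2, 0, 0)) == pytest.approx(2.0)

    def test_failure_weight_is_penalty_times_distance(self):
        path = Pathway(success=False)
        w = edge_weight(path, Node(0, 0, 0), Node(7, 0, 0), WeightParams(M=100))
        assert w == pytest.approx(700.0)

    def test_successful_weight_at_least_chord(self, rng):
        for _ in range(20):
            pts = rng.uniform(0, 20, (5, 3))
            path = path_of(pts)
            w = edge_weight(path, Node(*pts[0]), Node(*pts[-1]))
            assert w >= np.linalg.norm(pts[-1] - pts[0]) - 1e-9

    def test_penalty_multiplier_must_exceed_ten(self):
        with pytest.raises(ValueError):
            WeightParams(M=10)


class TestBuildWeightMatrix:
    def test_single_node_zero_matrix(self, phantoms, masks):
        vol, _ = phantoms["straight_tube"]
        mat = build_weight_matrix([Node(10, 8, 8)], vol, masks["straight_tube"])
        assert mat.weights.shape == (1, 1) and mat.weights[0, 0] == 0

    def test_tube_pair_cheaper_than_penalty_gap_pair_exact_penalty(
        self, phantoms, masks
    ):
        vol, _ = phantoms["straight_tube"]
        nodes = [Node(8, 8, 8, intensity=200), Node(32, 8, 8, intensity=200)]
        mat = build_weight_matrix(nodes, vol, masks["straight_tube"])
        assert mat.weights[0, 1] < 100 * 24.0
        assert mat.pathway(0, 1) is not None

        volg, _ = phantoms["gap_pair"]
        gnodes = [Node(14, 8, 8, intensity=200), Node(26, 8, 8, intensity=200)]
        gmat = build_weight_matrix(gnodes, volg, masks["gap_pair"])
        assert gmat.weights[0, 1] == pytest.approx(100 * 12.0)
        assert gmat.pathway(0, 1) is None

    def test_matrix_symmetric_and_dominates_euclidean(self, phantoms, masks):
        vol, _ = phantoms["y_branch"]
        nodes = [
            Node(8, 22, 8, intensity=200),
            Node(24, 22, 8, intensity=200),
            Node(40, 33, 8, intensity=200),
        ]
        mat = build_weight_matrix(nodes, vol, masks["y_branch"])
        assert np.allclose(mat.weights, mat.weights.T)
        euc = euclidean_weight_matrix(nodes).weights
        assert np.all(mat.weights >= euc - 1e-9)


class TestMinimumSpanningTree:
    def test_three_node_unique_mst(self):
        w = np.array([[0, 1, 3], [1, 0, 2], [3, 2, 0]], dtype=float)
        parents = minimum_spanning_tree(WeightMatrix(w), root=0)
        assert parents == {0: None, 1: 0, 2: 1}
        assert mst_total(w, parents) == pytest.approx(3.0)

    def test_single_node(self):
        parents = minimum_spanning_tree(WeightMatrix(np.zeros((1, 1))), root=0)
        assert parents == {0: None}

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 7))
            w = rng.uniform(0.1, 10, (n, n))
            w = (w + w.T) / 2
            np.fill_diagonal(w, 0)
            parents = minimum_spanning_tree(WeightMatrix(w), root=0)
            assert mst_total(w, parents) == pytest.approx(brute_force_mst_weight(w))

    def test_matches_networkx_cross_check(self, rng):
        nx = pytest.importorskip("networkx")
        for _ in range(10):
            n = int(rng.integers(3, 9))
            w = rng.uniform(0.1, 10, (n, n))
            w = (w + w.T) / 2
            np.fill_diagonal(w, 0)
            parents = minimum_spanning_tree(WeightMatrix(w), root=0)
            g = nx.from_numpy_array(w)
            expected = nx.minimum_spanning_tree(g).size(weight="weight")
            assert mst_total(w, parents) == pytest.approx(expected)


class TestGapAvoidance:
    def test_adapted_mst_routes_detour_euclidean_crosses_gap(
        self, phantoms, masks
    ):
        vol, _ = phantoms["gap_vs_detour"]
        mask = masks["gap_vs_detour"]
        apex = 6 + float(np.sqrt(84.0))
        a = Node(10, 6, 8, radius=2, intensity=200)
        b = Node(18, 6, 8, radius=2, intensity=200)
        c = Node(14, apex, 8, radius=2, intensity=200)
        nodes = [a, b, c]
        adapted = minimum_spanning_tree(
            build_weight_matrix(nodes, vol, mask), root=0
        )
        euclid = minimum_spanning_tree(euclidean_weight_matrix(nodes), root=0)

        def edges(parents):
            return {
                frozenset((v, u)) for v, u in parents.items() if u is not None
            }

        assert edges(adapted) == {frozenset((0, 2)), frozenset((1, 2))}
        assert frozenset((0, 1)) in edges(euclid)


class TestAssembleTree:
    def test_pathway_fill_in_adds_exactly_intermediate_records(self):
        nodes = [Node(0, 0, 0, radius=2), Node(4, 0, 0, radius=1)]
        w = WeightMatrix(np.array([[0.0, 4.0], [4.0, 0.0]]))
        w.pathways[(0, 1)] = path_of([(0, 0, 0), (1, 0, 0), (2, 1, 0), (4, 0, 0)])
        tree = assemble_tree({0: None, 1: 0}, w, nodes)
        assert len(tree) == 4  # 2 endpoints + 2 intermediate centers
        tree.validate()

    def test_without_pathways_record_count_equals_node_count(self, rng):
        n = 6
        nodes = [Node(*rng.uniform(0, 30, 3), radius=1.5) for _ in range(n)]
        w = rng.uniform(1, 5, (n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        mat = WeightMatrix(w)
        parents = minimum_spanning_tree(mat, root=0)
        tree = assemble_tree(parents, mat, nodes)
        assert len(tree) == n

    def test_all_chains_reach_the_root(self, rng):
        n = 8
        nodes = [Node(*rng.uniform(0, 30, 3), radius=1.5) for _ in range(n)]
        w = rng.uniform(1, 5, (n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        mat = WeightMatrix(w)
        tree = assemble_tree(minimum_spanning_tree(mat, root=3), mat, nodes)
        by_id = {r.id: r for r in tree.records}
        roots = tree.roots()
        assert len(roots) == 1
        for r in tree.records:
            cur = r
            hops = 0
            while cur.parent != -1:
                cur = by_id[cur.parent]
                hops += 1
                assert hops <= len(tree)
            assert cur.id == roots[0].id


def make_y_tree(spur_len=2, limb_len=20):
    records = [SWCRecord(1, 1, 0, 0, 0, 1.0, -1)]
    nid = 2
    branch_at = 5
    for i in range(1, branch_at + 1):
        records.append(SWCRecord(nid, 3, float(i), 0, 0, 1.0, nid - 1))
        nid += 1
    branch_id = nid - 1
    parent = branch_id
    for i in range(1, limb_len + 1):  # long limb
        records.append(SWCRecord(nid, 3, 5.0 + i, 1.0 * i, 0, 1.0, parent))
        parent = nid
        nid += 1
    parent = branch_id
    for i in range(1, spur_len + 1):  # short spur
        records.append(SWCRecord(nid, 3, 5.0, -1.0 * i, 0, 1.0, parent))
        parent = nid
        nid += 1
    return SWCTree(records), branch_id


class TestPruneSpurs:
    def test_straight_chain_unchanged(self):
        records = [SWCRecord(1, 1, 0, 0, 0, 1.0, -1)] + [
            SWCRecord(i, 3, float(i - 1), 0, 0, 1.0, i - 1) for i in range(2, 22)
        ]
        tree = SWCTree(records)
        assert len(prune_spurs(tree, 5.0)) == len(tree)

    def test_short_spur_removed_long_limbs_kept(self):
        tree, branch_id = make_y_tree(spur_len=2, limb_len=20)
        out = prune_spurs(tree, 5.0)
        assert len(out) == len(tree) - 2
        assert branch_id in {r.id for r in out.records}

    def test_idempotent(self):
        tree, _ = make_y_tree(spur_len=2, limb_len=20)
        once = prune_spurs(tree, 5.0)
        twice = prune_spurs(once, 5.0)
        assert [r.id for r in once.records] == [r.id for r in twice.records]
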