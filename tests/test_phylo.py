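"""Distances, neighbor joining, bootstrap and Newick round-trips."""

import numpy as np
import pytest

from ncrip.phylo import (Alignment, DistanceMatrix, Node, SaturationError,
                         bootstrap, neighbor_joining, pairwise_distance,
                         parse_newick, write_newick)


def leaf_distances(tree: Node) -> dict[tuple[str, str], float]:
    """Path lengths between all leaf pairs (oracle for additivity checks)."""
    # gather distances to the (trifurcating) root from each child subtree
    dists = {}
    groups = [collect_sub(c) for c in tree.children]
    # cross-group pairs go through the root
    for gi in range(len(groups)):
        for gj in range(gi + 1, len(groups)):
            for n1, d1 in groups[gi]:
                for n2, d2 in groups[gj]:
                    dists[tuple(sorted((n1, n2)))] = d1 + d2
    # within-group pairs handled recursively
    for c in tree.children:
        dists.update(within(c))
    return dists


def collect_sub(node: Node):
    """(leaf, distance-to-this-node's-parent-edge-top) pairs."""
    if node.is_leaf():
        return [(node.name, node.branch_length)]
    out = []
    for c in node.children:
        out.extend((n, d + node.branch_length) for n, d in collect_sub(c))
    return out


def within(node: Node) -> dict:
    dists = {}
    if node.is_leaf():
        return dists
    subs = [collect_sub(c) for c in node.children]
    for gi in range(len(subs)):
        for gj in range(gi + 1, len(subs)):
            for n1, d1 in subs[gi]:
                for n2, d2 in subs[gj]:
                    dists[tuple(sorted((n1, n2)))] = d1 + d2
    for c in node.children:
        dists.update(within(c))
    return dists


def random_additive_matrix(rng, n):
    """Random unrooted binary tree -> its exact additive distance matrix."""
    taxa = [f"t{i}" for i in range(n)]
    # adjacency with branch lengths; start from a 3-star
    next_id = [n]
    edges = {}

    def add_edge(a, b, w):
        edges.setdefault(a, {})[b] = w
        edges.setdefault(b, {})[a] = w

    center = next_id[0]; next_id[0] += 1
    for leaf in range(3):
        add_edge(leaf, center, float(rng.uniform(0.05, 0.5)))
    for leaf in range(3, n):
        # split a random existing edge with a new internal node
        a = int(rng.choice(list(edges)))
        b = int(rng.choice(list(edges[a])))
        w = edges[a][b]
        mid = next_id[0]; next_id[0] += 1
        del edges[a][b]; del edges[b][a]
        t = rng.uniform(0.2, 0.8)
        add_edge(a, mid, w * t)
        add_edge(b, mid, w * (1 - t))
        add_edge(leaf, mid, float(rng.uniform(0.05, 0.5)))

    # all-pairs shortest paths over the tree
    import heapq
    D = np.zeros((n, n))
    for src in range(n):
        dist = {src: 0.0}
        heap = [(0.0, src)]
        while heap:
            d, u = heapq.heappop(heap)
            if d > dist.get(u, np.inf):
                continue
            for v, w in edges[u].items():
                nd = d + w
                if nd < dist.get(v, np.inf):
                    dist[v] = nd
                    heapq.heappush(heap, (nd, v))
        for dst in range(n):
            D[src, dst] = dist[dst]
    return DistanceMatrix(taxa, D)


class TestDistances:
    def test_p_distance(self):
        aln = Alignment(["a", "b"], ["AAAAAAAAAA", "AAAAAAAAAC"])
        assert pairwise_distance(aln, "p").values[0, 1] == pytest.approx(0.1)

    def test_poisson_closed_form(self):
        aln = Alignment(["a", "b"], ["AAAAAAAAAA", "AAAAAAAAAC"])
        d = pairwise_distance(aln, "poisson").values[0, 1]
        assert d == pytest.approx(-np.log(0.9))

    def test_identical_sequences_zero_under_every_model(self):
        aln = Alignment(["a", "b"], ["MKLV", "MKLV"])
        for model in ("p", "poisson", "jtt_like"):
            assert pairwise_distance(aln, model).values[0, 1] == 0.0

    def test_gap_columns_pairwise_deleted(self):
        aln = Alignment(["a", "b"], ["MK-V", "MKL-"])
        # only columns 1,2 are shared unngapped... column 4 gapped in b,
        # column 3 gapped in a -> 2 comparable columns, 0 mismatches
        assert pairwise_distance(aln, "p").values[0, 1] == 0.0

    def test_saturation_raises_with_pair_names(self):
        aln = Alignment(["sat1", "sat2"], ["AAAA", "CCCC"])
        with pytest.raises(SaturationError, match="sat1"):
            pairwise_distance(aln, "poisson")


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(["A", "B", "C"],
                            np.array([[0, 0.2, 0.3],
                                      [0.2, 0, 0.4],
                                      [0.3, 0.4, 0]]))
        tree = neighbor_joining(dm)
        assert write_newick(tree) == "(A:0.05,B:0.15,C:0.25);"

    @pytest.mark.parametrize("seed,n", [(0, 5), (1, 6), (2, 8), (3, 10), (4, 7)])
    def test_additive_matrix_recovered_exactly(self, seed, n):
        rng = np.random.default_rng(seed)
        dm = random_additive_matrix(rng, n)
        tree = neighbor_joining(dm)
        got = leaf_distances(tree)
        for i in range(n):
            for j in range(i + 1, n):
                key = tuple(sorted((dm.taxa[i], dm.taxa[j])))
                assert got[key] == pytest.approx(dm.values[i, j], abs=1e-9)

    def test_relabeling_preserves_topology(self):
        rng = np.random.default_rng(7)
        dm = random_additive_matrix(rng, 6)
        perm = rng.permutation(6)
        dm2 = DistanceMatrix([dm.taxa[i] for i in perm],
                             dm.values[np.ix_(perm, perm)])
        d1 = leaf_distances(neighbor_joining(dm))
        d2 = leaf_distances(neighbor_joining(dm2))
        for key, val in d1.items():
            assert d2[key] == pytest.approx(val, abs=1e-9)

    def test_ultrametric_tie_break_is_deterministic(self):
        d = np.full((4, 4), 0.4); np.fill_diagonal(d, 0)
        dm = DistanceMatrix(list("ABCD"), d)
        assert write_newick(neighbor_joining(dm)) == \
            write_newick(neighbor_joining(dm))

    def test_fewer_than_three_taxa_rejected(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0, 1.0], [1.0, 0]]))
        with pytest.raises(ValueError):
            neighbor_joining(dm)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["A", "B"], np.array([[0, 1.0], [2.0, 0]]))


def two_clade_alignment(n_per=3, n_cols=60, n_fixed=15, seed=0):
    rng = np.random.default_rng(seed)
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    base = rng.choice(aas, size=n_cols)
    rows, ids = [], []
    fixed = rng.choice(n_cols, size=n_fixed, replace=False)
    for clade, tag in ((0, "x"), (1, "y")):
        for i in range(n_per):
            row = base.copy()
            if clade == 1:
                for pos in fixed:
                    row[pos] = "W" if row[pos] != "W" else "Y"
            # one private substitution per sequence
            priv = rng.choice([c for c in range(n_cols) if c not in fixed])
            row[priv] = "H" if row[priv] != "H" else "K"
            rows.append("".join(row))
            ids.append(f"{tag}{i}")
    return Alignment(ids, rows)


class TestBootstrap:
    def test_single_replicate_supports_are_binary(self):
        aln = two_clade_alignment()
        tree = bootstrap(aln, n_reps=1, seed=5)
        sups = [n.support for n in iter_internal(tree) if n.support is not None]
        assert sups and all(s in (0, 100) for s in sups)

    def test_separated_clades_get_high_support(self):
        aln = two_clade_alignment()
        tree = bootstrap(aln, n_reps=200, seed=11)
        # find the bipartition splitting x* from y*
        from ncrip.phylo import _bipartitions
        target = frozenset({"y0", "y1", "y2"})
        found = False
        for node in iter_internal(tree):
            names = frozenset(node.leaf_names())
            if names in (target, frozenset({"x0", "x1", "x2"})):
                found = True
                assert node.support >= 95
        assert found

    def test_same_seed_reproduces_supports(self):
        aln = two_clade_alignment()
        t1 = bootstrap(aln, n_reps=50, seed=3)
        t2 = bootstrap(aln, n_reps=50, seed=3)
        assert write_newick(t1) == write_newick(t2)


def iter_internal(tree: Node):
    stack = [tree]
    while stack:
        node = stack.pop()
        if not node.is_leaf():
            yield node
            stack.extend(node.children)


class TestNewick:
    def test_round_trip_through_own_parser(self):
        aln = two_clade_alignment()
        tree = bootstrap(aln, n_reps=20, seed=1)
        text = write_newick(tree)
        assert write_newick(parse_newick(text)) == text

    def test_metacharacter_labels_quoted(self):
        tree = Node(children=[Node("a b", 0.1), Node("c(d", 0.2),
                              Node("e", 0.3)])
        text = write_newick(tree)
        assert "'a b'" in text and "'c(d'" in text

    def test_empty_tree_rejected(self):
        with pytest.raises(ValueError):
            write_newick(Node())
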