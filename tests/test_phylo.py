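"""Phylogenetics: alignment against an exhaustive oracle, NJ exactness on
additive matrices, UPGMA hand examples, bootstrap behaviour, Newick IO."""

import random

import numpy as np
import pytest

from xynscreen.phylo import (
    AA_ORDER, Alignment, DistanceMatrix, NewickParseError, PhyloTree,
    bootstrap_supports, global_align, kmer_distance, load_blosum62,
    neighbor_joining, pdist_from_msa, progressive_msa, read_newick, upgma,
    write_newick,
)


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def brute_force_best_score(a, b, S, gap):
    """Enumerate every global alignment explicitly (no DP)."""
    best = [-np.inf]

    def rec(i, j, score):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + S[a[i], b[j]])
        if i < len(a):
            rec(i + 1, j, score + gap)
        if j < len(b):
            rec(i, j + 1, score + gap)

    rec(0, 0, 0.0)
    return best[0]


def random_additive_tree(n, rng):
    """Random unrooted binary tree; returns (splits, leaf-pair distances)."""
    labels = [f"L{i}" for i in range(n)]
    # graph as adjacency with edge lengths; start from a 3-star
    nxt = [n]
    adj = {i: {} for i in range(n + 1)}

    def connect(u, v, w):
        adj[u][v] = w
        adj[v][u] = w

    for leaf in (0, 1, 2):
        connect(leaf, n, rng.uniform(0.5, 2.0))
    inner = [n]
    for leaf in range(3, n):
        # split a random existing edge with a new internal node
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        u, v = rng.choice(edges)
        w = adj[u][v]
        new = len(adj)
        del adj[u][v], adj[v][u]
        adj[new] = {}
        connect(u, new, w * 0.5)
        connect(v, new, w * 0.5)
        connect(leaf, new, rng.uniform(0.5, 2.0))
        inner.append(new)
    # distances by BFS from each leaf
    D = np.zeros((n, n))
    for src in range(n):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u].items():
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for dst in range(n):
            D[src, dst] = dist[dst]
    # splits: remove each internal edge, collect leaf side
    splits = set()
    ref = labels[0]
    for u in inner:
        for v in list(adj[u]):
            if v < n:
                continue
            seen = {u}
            stack = [u]
            while stack:
                x = stack.pop()
                for y in adj[x]:
                    if y != v and y not in seen and not (x == u and y == v):
                        if y not in seen:
                            seen.add(y)
                            stack.append(y)
            side = frozenset(labels[x] for x in seen if x < n)
            if ref in side:
                side = frozenset(labels) - side
            if 1 < len(side) < n - 1:
                splits.add(side)
    return labels, D, splits


# ---------------------------------------------------------------------------
# k-mer distance
# ---------------------------------------------------------------------------

class TestKmerDistance:
    def test_identical_is_zero(self):
        assert kmer_distance("MKWVTFISLL", "MKWVTFISLL") == 0.0

    def test_disjoint_alphabets_is_one(self):
        assert kmer_distance("AAAAAA", "WWWWWW") == 1.0

    def test_symmetry(self):
        rng = random.Random(0)
        for _ in range(20):
            a = "".join(rng.choices(AA_ORDER, k=rng.randint(5, 15)))
            b = "".join(rng.choices(AA_ORDER, k=rng.randint(5, 15)))
            assert kmer_distance(a, b) == pytest.approx(kmer_distance(b, a))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            kmer_distance("AB", "ABCD", k=3)


# ---------------------------------------------------------------------------
# Pairwise alignment
# ---------------------------------------------------------------------------

class TestGlobalAlign:
    def test_identical_no_gaps(self, identity_matrix):
        a, b, score = global_align("AAA", "AAA", identity_matrix, gap=-2)
        assert (a, b, score) == ("AAA", "AAA", 3.0)

    def test_empty_vs_one(self, identity_matrix):
        a, b, score = global_align("A", "", identity_matrix, gap=-2)
        assert (a, b, score) == ("A", "-", -2.0)

    def test_matches_exhaustive_oracle(self):
        """DP score equals brute-force enumeration on short random pairs."""
        S = load_blosum62()
        idx = {c: i for i, c in enumerate(AA_ORDER)}
        rng = random.Random(7)
        for _ in range(30):
            a = "".join(rng.choices(AA_ORDER, k=rng.randint(1, 8)))
            b = "".join(rng.choices(AA_ORDER, k=rng.randint(1, 8)))
            _, _, score = global_align(a, b, S, gap=-4.0)
            expect = brute_force_best_score(
                [idx[c] for c in a], [idx[c] for c in b], S, -4.0)
            assert score == pytest.approx(expect)

    def test_alignment_degaps_to_inputs(self):
        a, b, _ = global_align("MKWVTF", "MKVTF")
        assert a.replace("-", "") == "MKWVTF"
        assert b.replace("-", "") == "MKVTF"


# ---------------------------------------------------------------------------
# Progressive MSA
# ---------------------------------------------------------------------------

class TestProgressiveMSA:
    def test_identical_sequences_no_gaps(self):
        seqs = [(f"s{i}", "MKWVTFISLL") for i in range(4)]
        aln = progressive_msa(seqs)
        assert aln.length == 10 and all("-" not in r for r in aln.rows)

    def test_degap_invariant_mixed_lengths(self):
        seqs = [("a", "MKWVTFISLL"), ("b", "MKWISLL"), ("c", "MKWVTFSLL"),
                ("d", "KWVTFISLLAG")]
        aln = progressive_msa(seqs)
        assert len({len(r) for r in aln.rows}) == 1
        for i, (_, s) in enumerate(seqs):
            assert aln.degapped(i) == s

    def test_two_sequences_reduce_to_pairwise(self):
        a, b = "MKWVTFISLL", "MKWTFISL"
        pa, pb, _ = global_align(a, b)
        aln = progressive_msa([("x", a), ("y", b)])
        assert aln.rows == [pa, pb]

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            progressive_msa([("a", "MKWVTF")])


# ---------------------------------------------------------------------------
# p-distances
# ---------------------------------------------------------------------------

class TestPdist:
    def test_identical_rows(self):
        aln = Alignment(["a", "b"], ["MKWV", "MKWV"])
        assert pdist_from_msa(aln).values[0, 1] == 0.0

    def test_all_different(self):
        aln = Alignment(["a", "b"], ["MKWV", "KMVW"])
        assert pdist_from_msa(aln).values[0, 1] == 1.0

    def test_hand_computed_toy(self):
        # a vs b: 4 comparable, 1 mismatch -> 0.25
        # a vs c: 3 comparable (gap in c), 1 mismatch -> 1/3
        aln = Alignment(["a", "b", "c"], ["MKWV", "MKWA", "M-WA"])
        D = pdist_from_msa(aln)
        assert D[("a", "b")] == pytest.approx(0.25)
        assert D[("a", "c")] == pytest.approx(1 / 3)
        assert np.allclose(D.values, D.values.T)


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

class TestUpgma:
    def test_hand_agglomeration(self):
        D = DistanceMatrix(["A", "B", "C"],
                           np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
        tree = upgma(D)
        # expect cherry (A:1,B:1) at height 1 under a root with C:2
        by_len = {}
        for node in tree.postorder():
            if node.is_leaf:
                by_len[node.name] = node.length
        assert by_len == {"A": 1.0, "B": 1.0, "C": 2.0}

    def test_ultrametric_depths_equal(self):
        rng = np.random.default_rng(5)
        # build an ultrametric matrix from random cluster heights
        D = DistanceMatrix(["A", "B", "C", "D"], np.array([
            [0, 2, 8, 8], [2, 0, 8, 8], [8, 8, 0, 4], [8, 8, 4, 0]], float))
        tree = upgma(D)

        def depths(node, acc):
            if node.is_leaf:
                yield acc + (node.length or 0)
            for c in node.children:
                yield from depths(c, acc + (node.length or 0))

        ds = list(depths(tree.root, 0.0))
        assert max(ds) - min(ds) < 1e-12

    def test_two_taxa_cherry(self):
        D = DistanceMatrix(["A", "B"], np.array([[0, 3], [3, 0]], float))
        tree = upgma(D)
        assert sorted(n.length for n in tree.root.children) == [1.5, 1.5]


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

class TestNeighborJoining:
    def test_additive_quartet_exact(self):
        """The additive matrix of ((A:1,B:2):1,(C:3,D:4)) is inverted
        exactly: AB|CD topology and the generating branch lengths."""
        labels = ["A", "B", "C", "D"]
        M = np.array([[0, 3, 5, 6], [3, 0, 6, 7],
                      [5, 6, 0, 7], [6, 7, 7, 0]], float)
        tree = neighbor_joining(DistanceMatrix(labels, M))
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        lengths = {n.name: n.length for n in tree.leaves()}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}
        internal = [n for n in tree.postorder()
                    if not n.is_leaf and n is not tree.root]
        assert [n.length for n in internal] == [1.0]

    def test_star_matrix_zero_internal_branches(self):
        D = DistanceMatrix(list("ABCD"), np.full((4, 4), 2.0) - 2 * np.eye(4))
        tree = neighbor_joining(D)
        for n in tree.postorder():
            if not n.is_leaf and n is not tree.root:
                assert n.length == pytest.approx(0.0)

    def test_recovers_random_additive_topologies(self):
        """NJ is exact on additive matrices (n <= 8, random trees)."""
        rng = random.Random(13)
        for _ in range(25):
            n = rng.randint(4, 8)
            labels, D, splits = random_additive_tree(n, rng)
            tree = neighbor_joining(DistanceMatrix(labels, D))
            assert tree.bipartitions() == splits

    def test_agrees_with_dendropy(self):
        """Independent cross-check of the NJ topology on a random matrix."""
        dendropy = pytest.importorskip("dendropy")
        import io

        rng = np.random.default_rng(3)
        n = 7
        labels = [f"T{i}" for i in range(n)]
        base = rng.uniform(1, 5, size=(n, n))
        M = (base + base.T) / 2
        np.fill_diagonal(M, 0)
        mine = neighbor_joining(DistanceMatrix(labels, M))

        csv = "," + ",".join(labels) + "\n" + "\n".join(
            labels[i] + "," + ",".join(f"{M[i, j]:.6f}" for j in range(n))
            for i in range(n))
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=io.StringIO(csv), delimiter=",")
        theirs = read_newick(
            pdm.nj_tree().as_string(schema="newick",
                                    suppress_rooting=True).strip())
        assert mine.bipartitions() == theirs.bipartitions()

    def test_too_few_taxa(self):
        D = DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0]], float))
        with pytest.raises(ValueError):
            neighbor_joining(D)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def perfect_signal_alignment(copies=20):
    """Six taxa; every internal split of ((A,B),(C,D),(E,F)) is supported by
    `copies` identical columns, so all supports should hit 100."""
    taxa = ["A", "B", "C", "D", "E", "F"]
    cols = []
    for group in (("A", "B"), ("C", "D"), ("E", "F")):
        col = {t: ("W" if t in group else "G") for t in taxa}
        cols.extend([col] * copies)
    cols.extend([{t: "L" for t in taxa}] * copies)
    rows = ["".join(c[t] for c in cols) for t in taxa]
    return Alignment(taxa, rows)


class TestBootstrap:
    def test_perfect_signal_supports_100(self):
        aln = perfect_signal_alignment()
        tree = bootstrap_supports(aln, n_reps=100, seed=1)
        supports = [n.support for n in tree.postorder()
                    if not n.is_leaf and n is not tree.root
                    and n.support is not None]
        assert supports and all(s == 100 for s in supports)

    def test_single_replicate_is_binary(self):
        aln = perfect_signal_alignment(copies=3)
        tree = bootstrap_supports(aln, n_reps=1, seed=2)
        for n in tree.postorder():
            if n.support is not None:
                assert n.support in (0, 100)

    def test_supports_within_range_and_deterministic(self):
        rng = random.Random(4)
        rows = ["".join(rng.choices("AW", k=40)) for _ in range(5)]
        aln = Alignment(list("ABCDE"), rows)
        t1 = bootstrap_supports(aln, n_reps=30, seed=9)
        t2 = bootstrap_supports(aln, n_reps=30, seed=9)
        assert write_newick(t1) == write_newick(t2)
        for n in t1.postorder():
            if n.support is not None:
                assert 0 <= n.support <= 100

    def test_supports_stabilize_with_more_replicates(self):
        """Across seeds, support variance on a fixed edge shrinks as the
        replicate count grows."""
        aln = perfect_signal_alignment(copies=2)
        # add noise columns so supports are not saturated
        rng = random.Random(0)
        noisy_rows = [r + "".join(rng.choices("AWGL", k=30)) for r in aln.rows]
        noisy = Alignment(aln.ids, noisy_rows)

        def spread(n_reps):
            vals = []
            for seed in range(8):
                t = bootstrap_supports(noisy, n_reps=n_reps, seed=seed)
                sets = t.leafsets()
                for node in t.postorder():
                    if node.support is not None and sets[id(node)] == frozenset("AB"):
                        vals.append(node.support)
            return np.var(vals)

        assert spread(100) <= spread(5)


# ---------------------------------------------------------------------------
# Newick IO
# ---------------------------------------------------------------------------

class TestNewick:
    def test_direct_parse_with_support(self):
        tree = read_newick("((A:1,B:2)90:1,C:3);")
        cherry = tree.root.children[0]
        assert cherry.support == 90
        assert {c.name for c in cherry.children} == {"A", "B"}

    def test_random_tree_roundtrip(self):
        rng = random.Random(21)
        labels = [f"t{i}" for i in range(20)]
        _, D, _ = random_additive_tree(10, rng)
        tree = neighbor_joining(DistanceMatrix([f"t{i}" for i in range(10)], D))
        back = read_newick(write_newick(tree))
        assert back.bipartitions() == tree.bipartitions()
        assert sorted(back.leaf_names()) == sorted(tree.leaf_names())

    def test_unmatched_parenthesis(self):
        with pytest.raises(NewickParseError):
            read_newick("((A:1,B:2;")

    def test_missing_semicolon(self):
        with pytest.raises(NewickParseError):
            read_newick("(A,B)")
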