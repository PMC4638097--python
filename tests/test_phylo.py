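"""Distances, BioNJ/NJ/UPGMA trees, rooting, bootstrap support, clonality calls."""

import itertools
import shutil
import subprocess
import textwrap

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonetrace import (
    BinaryMarkerMatrix,
    DistanceMatrix,
    Marker,
    add_reference_row,
    binary_distance,
    bionj,
    bootstrap_support,
    flag_normal_contamination,
    neighbor_joining,
    partition_counts,
    root_with_reference,
    tumour_monophyly,
    upgma,
)
from clonetrace.trees import Node, bipartitions

ROLES = {"N": "normal", "T1": "tumour", "T2": "tumour", "T3": "tumour"}


def make_matrix(rows: dict[str, list[int]], roles=None) -> BinaryMarkerMatrix:
    samples = list(rows)
    data = np.array([rows[s] for s in samples], dtype=np.int8)
    markers = [Marker("chr1", j + 1, "A", "T") for j in range(data.shape[1])]
    return BinaryMarkerMatrix(samples, roles or dict(ROLES), data, markers)


# ---------------------------------------------------------------------------
# random additive trees (generator truth = unique additive representation)

def random_additive_tree(rng, n_taxa):
    """Random topology by sequential attachment, uniform branch lengths."""
    labels = [f"t{i}" for i in range(n_taxa)]
    nodes = [Node(labels[0]), Node(labels[1]), Node(labels[2])]
    root = Node(None, children=nodes)
    for node in nodes:
        node.length = rng.uniform(0.1, 2.0)
    edges = list(nodes)
    for label in labels[3:]:
        target = edges[rng.integers(len(edges))]
        # split target's edge, attach the new leaf at the split point
        split = Node(None, length=target.length * rng.uniform(0.2, 0.8))
        parent = next(p for p in root.walk() if target in p.children)
        target.length -= split.length
        parent.children[parent.children.index(target)] = split
        leaf = Node(label, rng.uniform(0.1, 2.0))
        split.children = [target, leaf]
        edges.extend([split, leaf])
    return root, labels


def patristic(root: Node, labels):
    n = len(labels)
    dist = {lbl: {} for lbl in labels}

    def rec(node, acc):
        if node.is_leaf:
            return {node.name: acc}
        merged = {}
        for child in node.children:
            sub = rec(child, acc + child.length)
            for a in merged:
                for b in sub:
                    d = merged[a] + sub[b] - 2 * acc
                    dist[a][b] = dist[b][a] = d
            merged.update(sub)
        return merged

    rec(root, 0.0)
    out = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                out[i, j] = dist[a][b]
    return out


def edge_lengths_by_split(root: Node) -> dict:
    """Map canonical bipartition -> internal edge length, plus leaf -> terminal length."""
    out = {}
    for split, node in bipartitions(root).items():
        out[split] = node.length
    # merge the two root edges of a bifurcating root into the single unrooted edge
    for leaf in root.walk():
        if leaf.is_leaf:
            out[leaf.name] = leaf.length
    return out


# ---------------------------------------------------------------------------
# textbook Saitou–Nei NJ, written independently as an oracle

def textbook_nj(labels, d):
    d = [list(map(float, row)) for row in d]
    nodes = [Node(lbl) for lbl in labels]
    idx = list(range(len(labels)))
    while len(idx) > 3:
        r = len(idx)
        S = {i: sum(d[i][k] for k in idx if k != i) for i in idx}
        best, best_q = None, None
        for i, j in itertools.combinations(idx, 2):
            q = (r - 2) * d[i][j] - S[i] - S[j]
            if best_q is None or q < best_q:
                best_q, best = q, (i, j)
        i, j = best
        bi = 0.5 * d[i][j] + (S[i] - S[j]) / (2 * (r - 2))
        bj = d[i][j] - bi
        nodes[i].length, nodes[j].length = bi, bj
        new = Node(None, children=[nodes[i], nodes[j]])
        for k in idx:
            if k not in (i, j):
                duk = 0.5 * (d[i][k] + d[j][k] - d[i][j])
                d[i][k] = d[k][i] = duk
        nodes[i] = new
        idx.remove(j)
    i, j, k = idx
    nodes[i].length = 0.5 * (d[i][j] + d[i][k] - d[j][k])
    nodes[j].length = 0.5 * (d[i][j] + d[j][k] - d[i][k])
    nodes[k].length = 0.5 * (d[i][k] + d[j][k] - d[i][j])
    return Node(None, children=[nodes[i], nodes[j], nodes[k]])


# ---------------------------------------------------------------------------
# distances

class TestBinaryDistance:
    def test_sqrt_of_differing_marker_count(self):
        m = make_matrix({"N": [0, 0, 0], "T1": [1, 1, 0], "T2": [1, 1, 0], "T3": [1, 0, 0]})
        d = binary_distance(m)
        assert d.values[0, 1] == pytest.approx(np.sqrt(2))
        assert d.values[1, 2] == 0.0
        assert d.values[0, 3] == pytest.approx(1.0)

    def test_reference_distance_is_sqrt_row_sum(self, default_truth):
        m = add_reference_row(default_truth.truth_matrix())
        d = binary_distance(m)
        ref = m.samples.index("reference")
        for i, s in enumerate(m.samples):
            assert d.values[ref, i] == pytest.approx(np.sqrt(m.data[i].sum()))

    def test_metric_properties_on_random_binary_rows(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 2, size=(6, 40)).astype(np.int8)
        X[:, 0] = 1  # keep every column non-zero
        m = BinaryMarkerMatrix(
            [f"s{i}" for i in range(6)],
            {"s0": "normal", **{f"s{i}": "tumour" for i in range(1, 6)}},
            X, [Marker("chr1", j + 1, "A", "T") for j in range(40)],
        )
        d = binary_distance(m).values
        for i, j, k in itertools.permutations(range(6), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12

    def test_single_row_is_fatal(self):
        m = make_matrix({"N": [1, 0]}, roles={"N": "normal"})
        with pytest.raises(ValueError):
            binary_distance(m)


# ---------------------------------------------------------------------------
# BioNJ

class TestBioNJ:
    def test_recovers_known_additive_quartet(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> dAB=3 dAC=5 dAD=6 dBC=6 dBD=7 dCD=7
        labels = list("ABCD")
        d = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ], dtype=float)
        tree = bionj(DistanceMatrix(labels, d))
        lengths = edge_lengths_by_split(tree)
        assert frozenset("CD") in lengths or frozenset("AB") in lengths
        internal = lengths.get(frozenset("CD"), lengths.get(frozenset("AB")))
        assert internal == pytest.approx(1.0, abs=1e-9)
        for leaf, expect in zip("ABCD", (1, 2, 3, 4)):
            assert lengths[leaf] == pytest.approx(expect, abs=1e-9)

    def test_three_taxa_equal_distances_give_unit_star(self):
        d = np.full((3, 3), 2.0) - 2.0 * np.eye(3)
        tree = bionj(DistanceMatrix(list("ABC"), d))
        assert all(c.length == pytest.approx(1.0) for c in tree.children)

    def test_recovers_random_additive_trees_exactly(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            n = int(rng.integers(4, 9))
            true_tree, labels = random_additive_tree(rng, n)
            d = patristic(true_tree, labels)
            est = bionj(DistanceMatrix(labels, d))
            want, got = edge_lengths_by_split(true_tree), edge_lengths_by_split(est)
            assert set(want) == set(got)
            for key in want:
                assert got[key] == pytest.approx(want[key], abs=1e-9)

    def test_matches_textbook_nj_with_uniform_variances(self):
        """Constant variances collapse BioNJ to classical neighbour joining."""
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = int(rng.integers(4, 8))
            tree, labels = random_additive_tree(rng, n)
            d = patristic(tree, labels)
            d += rng.uniform(0, 0.3, size=d.shape)  # non-additive noise
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            mine = neighbor_joining(DistanceMatrix(labels, d))
            oracle = textbook_nj(labels, d)
            a, b = edge_lengths_by_split(mine), edge_lengths_by_split(oracle)
            assert set(a) == set(b)
            for key in a:
                assert a[key] == pytest.approx(b[key], abs=1e-9)

    def test_non_symmetric_input_is_fatal(self):
        d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError):
            bionj(DistanceMatrix(list("ABC"), d))

    def test_fewer_than_three_taxa_fatal(self):
        with pytest.raises(ValueError):
            bionj(DistanceMatrix(["A", "B"], np.array([[0.0, 1.0], [1.0, 0.0]])))


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not available")
def test_bionj_matches_ape_reference_implementation(tmp_path):
    """Cross-check topology and branch lengths against R ape::bionj."""
    dendropy = pytest.importorskip("dendropy")
    rng = np.random.default_rng(23)
    labels = [f"t{i}" for i in range(6)]
    # additive inputs: the BioNJ result is agglomeration-order invariant there,
    # so branch lengths are comparable exactly; on noisy input ape breaks the
    # structural Q-tie at four remaining nodes differently, which shifts how
    # the last three edges share length (topology still comparable).
    cases = []
    for noisy in (False, False, True):
        tree, _ = random_additive_tree(rng, 6)
        d = patristic(tree, labels)
        if noisy:
            d += rng.uniform(0, 0.4, size=d.shape)
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
        cases.append((d, noisy))
    script = textwrap.dedent("""
        suppressMessages(library(ape))
        args <- commandArgs(trailingOnly=TRUE)
        m <- as.matrix(read.csv(args[1], row.names=1))
        colnames(m) <- rownames(m)
        write.tree(bionj(as.dist(m)), args[2])
    """)
    (tmp_path / "bionj.R").write_text(script)
    for i, (d, noisy) in enumerate(cases):
        csv = tmp_path / f"d{i}.csv"
        with open(csv, "w") as fh:
            fh.write("," + ",".join(labels) + "\n")
            for lbl, row in zip(labels, d):
                fh.write(lbl + "," + ",".join(f"{x:.12f}" for x in row) + "\n")
        out = tmp_path / f"ape{i}.nwk"
        subprocess.run(
            ["Rscript", str(tmp_path / "bionj.R"), str(csv), str(out)],
            check=True, capture_output=True,
        )
        ape_tree = dendropy.Tree.get(path=str(out), schema="newick")
        ape_lengths = {}
        for edge in ape_tree.preorder_edge_iter():
            if edge.head_node is ape_tree.seed_node:
                continue
            leaves = frozenset(
                lf.taxon.label for lf in edge.head_node.leaf_iter()
            )
            if len(leaves) == 1:
                ape_lengths[next(iter(leaves))] = edge.length
            elif 1 < len(leaves) < len(labels) - 1:
                side = leaves if min(labels) not in leaves else frozenset(labels) - leaves
                ape_lengths[side] = edge.length
        mine = edge_lengths_by_split(bionj(DistanceMatrix(labels, d)))
        assert set(mine) == set(ape_lengths)
        if not noisy:
            for key in mine:
                assert mine[key] == pytest.approx(ape_lengths[key], abs=1e-4)


# ---------------------------------------------------------------------------
# UPGMA

class TestUPGMA:
    def test_exact_recovery_on_ultrametric_input(self):
        # ((A:1,B:1):1,(C:1.5,D:1.5):0.5) is ultrametric with height 2
        labels = list("ABCD")
        d = np.array([
            [0, 2, 4, 4],
            [2, 0, 4, 4],
            [4, 4, 0, 3],
            [4, 4, 3, 0],
        ], dtype=float)
        tree = upgma(DistanceMatrix(labels, d))
        lengths = edge_lengths_by_split(tree)
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["C"] == pytest.approx(1.5)
        # ultrametric: all leaves equidistant from root
        def depth(node, acc=0.0):
            if node.is_leaf:
                return {acc}
            out = set()
            for c in node.children:
                out |= depth(c, acc + c.length)
            return out
        depths = depth(tree)
        assert max(depths) - min(depths) < 1e-9

    def test_two_taxa_cherry_heights(self):
        d = np.array([[0.0, 3.0], [3.0, 0.0]])
        tree = upgma(DistanceMatrix(["A", "B"], d))
        assert sorted(c.length for c in tree.children) == pytest.approx([1.5, 1.5])

    def test_concordant_tumour_clade_with_bionj_on_clonal_data(self, default_truth):
        m = add_reference_row(default_truth.truth_matrix())
        d = binary_distance(m)
        target = frozenset(["T1A", "T1B", "T2B"])
        for tree in (bionj(d), upgma(d)):
            splits = set(bipartitions(tree))
            all_leaves = frozenset(m.samples)
            side = target if min(all_leaves) not in target else all_leaves - target
            assert side in splits


# ---------------------------------------------------------------------------
# rooting

class TestRooting:
    def test_outgroup_is_reference(self, default_truth):
        tree = bionj(binary_distance(add_reference_row(default_truth.truth_matrix())))
        rooted = root_with_reference(tree)
        assert len(rooted.children) == 2
        assert any(c.is_leaf and c.name == "reference" for c in rooted.children)

    def test_rooting_is_idempotent(self, default_truth):
        tree = bionj(binary_distance(add_reference_row(default_truth.truth_matrix())))
        once = root_with_reference(tree)
        twice = root_with_reference(once)
        assert once.newick() == twice.newick()

    def test_leaf_set_unchanged(self, default_truth):
        tree = bionj(binary_distance(add_reference_row(default_truth.truth_matrix())))
        rooted = root_with_reference(tree)
        assert sorted(rooted.leaf_names()) == sorted(tree.leaf_names())

    def test_missing_reference_leaf_fatal(self):
        tree = bionj(DistanceMatrix(list("ABC"), np.full((3, 3), 2.0) - 2 * np.eye(3)))
        with pytest.raises(ValueError, match="reference"):
            root_with_reference(tree)


# ---------------------------------------------------------------------------
# bootstrap

class TestBootstrap:
    def test_pure_signal_gives_full_support(self):
        rows = {
            "N": [0] * 20, "T1": [1] * 20, "T2": [1] * 20, "T3": [1] * 20,
        }
        m = add_reference_row(make_matrix(rows))
        tree = bootstrap_support(m, reps=100, seed=1)
        mono = tumour_monophyly(tree, ROLES)
        assert mono.monophyletic and mono.support == 100.0

    def test_single_repeated_column_supports_in_0_or_100(self):
        rows = {"N": [0], "T1": [1], "T2": [1], "T3": [0]}
        m = add_reference_row(make_matrix(rows))
        tree = bootstrap_support(m, reps=50, seed=2)
        sups = [n.support for n in tree.walk() if n.support is not None]
        assert sups and all(s in (0.0, 100.0) for s in sups)

    def test_deterministic_given_seed(self, default_truth):
        m = add_reference_row(default_truth.truth_matrix())
        t1 = bootstrap_support(m, reps=50, seed=9)
        t2 = bootstrap_support(m, reps=50, seed=9)
        assert t1.newick() == t2.newick()

    def test_support_distribution_invariant_to_column_order(self):
        # column resampling is exchangeable only in distribution, so permuting
        # columns must leave supports unchanged up to Monte-Carlo error
        rng = np.random.default_rng(3)
        X = rng.integers(0, 2, size=(4, 30)).astype(np.int8)
        X[1:, :10] = 1
        X[0, :10] = 0
        X[:, 0] = 1
        m = add_reference_row(make_matrix(
            {s: X[i].tolist() for i, s in enumerate(["N", "T1", "T2", "T3"])}
        ))
        perm = rng.permutation(m.n_markers)
        m2 = BinaryMarkerMatrix(m.samples, m.roles, m.data[:, perm],
                                [m.markers[i] for i in perm])
        t1 = bootstrap_support(m, reps=1500, seed=4)
        t2 = bootstrap_support(m2, reps=1500, seed=4)
        s1 = {k: v.support for k, v in bipartitions(t1).items()}
        s2 = {k: v.support for k, v in bipartitions(t2).items()}
        assert set(s1) == set(s2)
        for k in s1:
            assert abs(s1[k] - s2[k]) < 5.0

    def test_noise_matrix_gives_reduced_support(self):
        rng = np.random.default_rng(5)
        X = rng.integers(0, 2, size=(4, 60)).astype(np.int8)
        X[:, 0] = 1
        m = add_reference_row(make_matrix(
            {s: X[i].tolist() for i, s in enumerate(["N", "T1", "T2", "T3"])}
        ))
        tree = bootstrap_support(m, reps=200, seed=6)
        mono = tumour_monophyly(tree, ROLES)
        assert mono.support is None or mono.support < 100.0

    def test_zero_reps_fatal(self, default_truth):
        m = add_reference_row(default_truth.truth_matrix())
        with pytest.raises(ValueError):
            bootstrap_support(m, reps=0, seed=1)


# ---------------------------------------------------------------------------
# monophyly & contamination

class TestClonalityCalls:
    def test_monophyletic_tumours_detected(self):
        t = Node(None, children=[
            Node("reference", 1.0),
            Node(None, 1.0, children=[
                Node("N", 0.5),
                Node(None, 1.0, support=97.0, children=[
                    Node("T1", 1.0),
                    Node(None, 0.5, support=88.0, children=[Node("T2", 1), Node("T3", 1)]),
                ]),
            ]),
        ])
        mono = tumour_monophyly(t, ROLES)
        assert mono.monophyletic and mono.support == 97.0

    def test_normal_inside_tumours_not_monophyletic(self):
        t = Node(None, children=[
            Node("reference", 1.0),
            Node(None, 1.0, support=99.0, children=[
                Node(None, 1.0, support=90.0, children=[Node("T1", 1), Node("N", 1)]),
                Node(None, 0.5, support=80.0, children=[Node("T2", 1), Node("T3", 1)]),
            ]),
        ])
        mono = tumour_monophyly(t, ROLES)
        assert not mono.monophyletic
        assert "N" in mono.clade

    def test_two_sister_tumours_are_monophyletic(self):
        roles2 = {"N": "normal", "T1": "tumour", "T2": "tumour"}
        t = Node(None, children=[
            Node("reference", 1.0),
            Node("N", 0.4),
            Node(None, 1.0, support=95.0, children=[Node("T1", 1), Node("T2", 1)]),
        ])
        mono = tumour_monophyly(t, roles2)
        assert mono.monophyletic and mono.support == 95.0

    def test_contamination_boundary_flags_at_equality(self, default_truth):
        """Normal branch exactly equal to shortest tumour terminal -> flagged."""
        partition = partition_counts(default_truth.truth_matrix())
        t = Node(None, children=[
            Node("reference", 1.0),
            Node(None, 1.0, children=[
                Node("N", 2.0),
                Node(None, 1.0, children=[
                    Node("T1A", 2.0), Node("T1B", 3.0), Node("T2B", 4.0),
                ]),
            ]),
        ])
        roles = {"N": "normal", "T1A": "tumour", "T1B": "tumour", "T2B": "tumour"}
        report = flag_normal_contamination(t, roles, partition)
        assert report.normal_branch_not_shorter and report.flagged

    def test_clean_clonal_run_not_flagged(self, default_truth):
        m = add_reference_row(default_truth.truth_matrix())
        partition = partition_counts(default_truth.truth_matrix())
        rooted = root_with_reference(bionj(binary_distance(m)))
        report = flag_normal_contamination(
            rooted,
            {"N": "normal", "T1A": "tumour", "T1B": "tumour", "T2B": "tumour"},
            partition,
            m,
        )
        assert not report.flagged

    def test_contaminated_normal_is_flagged(self):
        from clonetrace import SimConfig, simulate_patient

        truth = simulate_patient(SimConfig(seed=8, contamination=0.85))
        m = add_reference_row(truth.truth_matrix())
        partition = partition_counts(truth.truth_matrix())
        rooted = root_with_reference(bionj(binary_distance(m)))
        report = flag_normal_contamination(rooted, truth.roles, partition, m)
        assert report.flagged
        assert report.low_tumour_fraction  # patient-3 signature: ~11 % tumour-associated
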