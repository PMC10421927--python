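"""Parsimony tree, trunk metric and newick round-trip tests.

The exactness oracle is an independent test-side implementation: its own
topology enumeration (sequential leaf insertion) and its own per-variant
small-parsimony scoring with the germline root fixed to the absent
state.
"""

import numpy as np
import pytest

from metroute.phylogeny import (
    PhyloTree,
    build_parsimony_tree,
    classify_progression,
    parsimony_score,
    read_newick,
    trunk_metrics,
    write_newick,
)
from metroute.types import BinaryMutationMatrix, Topology, TrunkMetrics

from conftest import random_phylo_tree

INF = 10**9


# ---------------------------------------------------------------------------
# independent oracle
# ---------------------------------------------------------------------------

def oracle_topologies(n):
    """All rooted leaf-labeled binary topologies, built independently."""
    def insertions(t, leaf):
        yield (t, leaf)
        if isinstance(t, tuple):
            left, right = t
            for nl in insertions(left, leaf):
                yield (nl, right)
            for nr in insertions(right, leaf):
                yield (left, nr)

    trees = [(0, 1)]
    for leaf in range(2, n):
        trees = [t for base in trees for t in insertions(base, leaf)]
    return trees


def oracle_score(topology, P):
    """Minimum state changes with a germline (state 0) above the top node,
    computed per variant with plain scalar recursion."""
    total = 0
    for j in range(P.shape[1]):
        def cost(t):
            if isinstance(t, int):
                state = int(P[t, j])
                return (0 if state == 0 else INF, 0 if state == 1 else INF)
            (a0, a1), (b0, b1) = cost(t[0]), cost(t[1])
            c0 = min(a0, a1 + 1) + min(b0, b1 + 1)
            c1 = min(a1, a0 + 1) + min(b1, b0 + 1)
            return c0, c1
        c0, c1 = cost(topology)
        total += min(c0, c1 + 1)
    return total


def matrix_from(P):
    P = np.asarray(P, dtype=bool)
    samples = [f"s{i}" for i in range(P.shape[0])]
    keys = [f"1:{j + 1}:C:T" for j in range(P.shape[1])]
    return BinaryMutationMatrix(samples, keys, P)


def test_oracle_topology_count_is_double_factorial():
    assert len(oracle_topologies(4)) == 15
    assert len(oracle_topologies(5)) == 105


def test_tree_score_matches_exhaustive_oracle():
    rng = np.random.default_rng(11)
    topos = oracle_topologies(5)
    for _ in range(8):
        P = rng.random((5, 20)) < 0.4
        if not P.any():
            continue
        mat = matrix_from(P)
        tree = build_parsimony_tree(mat)
        best = min(oracle_score(t, P.astype(int)) for t in topos)
        assert parsimony_score(tree, mat) == best


def test_perfect_phylogeny_recovered():
    # trunk {m1,m2}; s0 extra {m3}; s1/s2 share {m4}, s2 private {m5}
    #        variants: m1 m2 m3 m4 m5
    P = np.array([
        [1, 1, 1, 0, 0],   # s0
        [1, 1, 0, 1, 0],   # s1
        [1, 1, 0, 1, 1],   # s2
    ], dtype=bool)
    mat = matrix_from(P)
    tree = build_parsimony_tree(mat)
    assert parsimony_score(tree, mat) == 5  # one gain per variant, no losses
    tm = trunk_metrics(tree)
    assert tm.trunk_len == 2
    # every mutation appears on exactly one edge
    placed = [k for ms in tree.edge_mutations.values() for k in ms]
    assert sorted(placed) == sorted(mat.variant_keys)
    assert all(not s for s in tree.edge_losses.values())


def test_single_sample_matrix_rejected():
    with pytest.raises(ValueError, match="at least 2"):
        build_parsimony_tree(matrix_from([[1, 0]]))


def test_parsimony_score_checks_leaf_set():
    mat = matrix_from([[1, 0], [0, 1]])
    tree = build_parsimony_tree(mat)
    other = matrix_from([[1, 0], [0, 1], [1, 1]])
    with pytest.raises(ValueError, match="do not match"):
        parsimony_score(tree, other)


# ---------------------------------------------------------------------------
# trunk metrics and progression calls
# ---------------------------------------------------------------------------

def manual_tree():
    """root -(4)- A -(1)- L1 ; A -(3)- L2"""
    parent = {"root": None, "A": "root", "L1": "A", "L2": "A"}
    return PhyloTree(parent=parent, leaf_sample={"L1": "s1", "L2": "s2"},
                     root="root",
                     edge_length={"A": 4.0, "L1": 1.0, "L2": 3.0})


def test_trunk_metrics_hand_example():
    tm = trunk_metrics(manual_tree())
    assert tm.trunk_len == 4
    assert tm.mean_root_leaf_len == pytest.approx(6.0)  # (5 + 7) / 2
    assert tm.trunk_ratio == pytest.approx(4.0 / 6.0)


def test_trunk_ratio_zero_tree_warns():
    parent = {"root": None, "A": "root", "L1": "A", "L2": "A"}
    tree = PhyloTree(parent=parent, leaf_sample={"L1": "s1", "L2": "s2"},
                     root="root",
                     edge_length={"A": 0.0, "L1": 0.0, "L2": 0.0})
    with pytest.warns(UserWarning, match="no mutations"):
        tm = trunk_metrics(tree)
    assert tm.trunk_ratio == 0.0


def test_classify_progression_threshold_and_borderline():
    call = classify_progression(TrunkMetrics(3, 10.0, 0.3))
    assert call.progression == Topology.BRANCHED  # >= is branched
    assert call.borderline
    call = classify_progression(TrunkMetrics(29, 100.0, 0.29))
    assert call.progression == Topology.DIASPORA
    assert call.borderline
    call = classify_progression(TrunkMetrics(6, 10.0, 0.6))
    assert call.progression == Topology.BRANCHED and not call.borderline
    call = classify_progression(TrunkMetrics(1, 10.0, 0.1))
    assert call.progression == Topology.DIASPORA and not call.borderline


# ---------------------------------------------------------------------------
# newick round trips
# ---------------------------------------------------------------------------

def canonical(tree):
    """Order-insensitive shape: nested frozensets of leaf sample names
    plus each subtree's edge length."""
    children = tree.children

    def rec(node):
        kids = children[node]
        length = tree.edge_length.get(node, 0.0) if node != tree.root else None
        if not kids:
            return (tree.leaf_sample[node], length)
        return (frozenset(rec(k) for k in kids), length)

    return rec(tree.root)


def test_newick_round_trip_100_random_trees():
    rng = np.random.default_rng(5)
    for _ in range(100):
        tree, _ = random_phylo_tree(rng, int(rng.integers(2, 9)))
        for node in tree.parent:
            if node != tree.root:
                tree.edge_length[node] = float(rng.integers(0, 30))
        back = read_newick(write_newick(tree))
        assert canonical(back) == canonical(tree)


def test_newick_file_round_trip(tmp_path):
    mat = matrix_from([[1, 1, 0], [1, 0, 1]])
    tree = build_parsimony_tree(mat)
    path = tmp_path / "t.nwk"
    write_newick(tree, path)
    back = read_newick(str(path))
    assert sorted(back.leaf_sample.values()) == ["s0", "s1"]


def test_newick_quoting_of_special_labels():
    parent = {"root": None, "L1": "root", "L2": "root"}
    tree = PhyloTree(parent=parent,
                     leaf_sample={"L1": "sample one", "L2": "b(2)"},
                     root="root", edge_length={"L1": 1.0, "L2": 2.0})
    back = read_newick(write_newick(tree))
    assert sorted(back.leaf_sample.values()) == ["b(2)", "sample one"]


def test_malformed_newick_raises():
    with pytest.raises(ValueError, match="malformed newick"):
        read_newick("((a,b;")
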