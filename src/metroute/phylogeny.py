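"""Maximum-parsimony sample phylogenies rooted at the germline.

Trees are built from the binary mutation matrix: leaves are tumor
samples, the root is the germline (all-absent profile), and each edge
carries the set of mutations gained on it.  For six or fewer leaves the
search is exact (all rooted leaf-labeled binary topologies are scored);
larger instances use stepwise addition followed by nearest-neighbor-
interchange hill climbing with a deterministic leaf order.  Per-variant
state changes are found by Sankoff dynamic programming with the root
constrained to the ancestral (absent) state; ties are resolved toward
the root so mutations are placed as early as possible.

The trunk — the path from the germline root to the most recent common
ancestor of all tumor leaves — carries the patient's clonal mutations;
its length relative to the mean root-to-leaf length separates branched
(long-trunk, late-dissemination) from diaspora (short-trunk, early
independent dissemination) progression.
"""

from __future__ import annotations

import io as _io
import itertools
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .types import BinaryMutationMatrix, Topology, TrunkMetrics

_BIG = np.int64(10**9)
EXACT_LEAF_LIMIT = 6


@dataclass
class PhyloTree:
    """Rooted tree; ``edge_mutations[node]`` / ``edge_losses[node]`` are
    the variant gains/losses on the edge above ``node``; ``edge_length``
    is an explicit length (mutation count) kept in sync when the tree is
    built from data and preserved through newick round trips."""

    parent: dict[str, str | None]
    leaf_sample: dict[str, str]
    root: str
    edge_mutations: dict[str, set[str]] = field(default_factory=dict)
    edge_losses: dict[str, set[str]] = field(default_factory=dict)
    edge_length: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        roots = [n for n, p in self.parent.items() if p is None]
        if roots != [self.root] and set(roots) != {self.root}:
            raise ValueError("tree must have exactly one root")
        for node in self.parent:
            if node != self.root:
                self.edge_length.setdefault(
                    node, float(len(self.edge_mutations.get(node, ()))))

    @property
    def children(self) -> dict[str, list[str]]:
        ch: dict[str, list[str]] = {n: [] for n in self.parent}
        for n, p in self.parent.items():
            if p is not None:
                ch[p].append(n)
        for kids in ch.values():
            kids.sort()
        return ch

    @property
    def leaves(self) -> list[str]:
        ch = self.children
        return sorted(n for n in self.parent if not ch[n])

    @property
    def samples(self) -> list[str]:
        return sorted(self.leaf_sample.values())

    def path_to_root(self, node: str) -> list[str]:
        path = []
        while node != self.root:
            path.append(node)
            node = self.parent[node]  # type: ignore[assignment]
        return path

    def mrca(self, nodes: list[str]) -> str:
        paths = [set(self.path_to_root(n) + [self.root]) | {n} for n in nodes]
        common = set.intersection(*paths)
        # deepest common ancestor = the one whose ancestor set is largest
        return max(common, key=lambda n: len(self.path_to_root(n)))


# ---------------------------------------------------------------------------
# topology enumeration (nested tuples of leaf indices)
# ---------------------------------------------------------------------------

def _insert_all(tree, leaf):
    yield (tree, leaf)  # attach above the current top
    if isinstance(tree, tuple):
        a, b = tree
        for na in _insert_all(a, leaf):
            yield (na, b)
        for nb in _insert_all(b, leaf):
            yield (a, nb)


def enumerate_topologies(n_leaves: int):
    """All rooted leaf-labeled binary topologies on ``n_leaves`` leaves
    ((2n-3)!! of them), as nested tuples of leaf indices."""
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    trees = [(0, 1)]
    for leaf in range(2, n_leaves):
        trees = [t2 for t in trees for t2 in _insert_all(t, leaf)]
    return trees


def _sankoff_costs(topology, P: np.ndarray) -> np.ndarray:
    """Cost array (2, n_variants) for the subtree top node being in
    state 0/1, leaves fixed to the presence matrix rows."""
    if isinstance(topology, int):
        row = P[topology]
        return np.where(np.array([[False], [True]]) == row[None, :], 0, _BIG)
    a, b = topology
    out = np.zeros((2, P.shape[1]), dtype=np.int64)
    for child in (a, b):
        c = _sankoff_costs(child, P)
        trans0 = np.minimum(c[0], c[1] + 1)
        trans1 = np.minimum(c[1], c[0] + 1)
        out += np.vstack([trans0, trans1])
    return out


def _topology_score(topology, P: np.ndarray) -> int:
    c = _sankoff_costs(topology, P)
    per_variant = np.minimum(c[0], c[1] + 1)  # germline parent in state 0
    return int(per_variant.sum())


def parsimony_score_matrix(topology, P: np.ndarray) -> int:
    return _topology_score(topology, P)


def _nni_neighbors(topology):
    """All nearest-neighbor interchanges of a nested-tuple topology."""

    def neigh(t):
        if isinstance(t, int):
            return []
        a, b = t
        out = [(na, b) for na in neigh(a)] + [(a, nb) for nb in neigh(b)]
        if isinstance(a, tuple):
            out.append(((a[0], b), a[1]))
            out.append(((a[1], b), a[0]))
        if isinstance(b, tuple):
            out.append((b[0], (a, b[1])))
            out.append((b[1], (a, b[0])))
        return out

    return neigh(topology)


def _search_topology(P: np.ndarray, n_leaves: int):
    """Exact search for small instances, stepwise addition + NNI beyond."""
    if n_leaves <= EXACT_LEAF_LIMIT:
        best, best_score = None, None
        for t in enumerate_topologies(n_leaves):
            s = _topology_score(t, P)
            if best_score is None or s < best_score:
                best, best_score = t, s
        return best
    # stepwise addition in deterministic (sorted-sample) leaf order
    tree = (0, 1)
    for leaf in range(2, n_leaves):
        candidates = list(_insert_all(tree, leaf))
        scores = [_topology_score(t, P) for t in candidates]
        tree = candidates[int(np.argmin(scores))]
    # NNI hill climbing
    current_score = _topology_score(tree, P)
    for _ in range(100):
        improved = False
        for cand in _nni_neighbors(tree):
            s = _topology_score(cand, P)
            if s < current_score:
                tree, current_score = cand, s
                improved = True
                break
        if not improved:
            break
    return tree


def build_parsimony_tree(matrix: BinaryMutationMatrix) -> PhyloTree:
    """Maximum-parsimony tree over the matrix samples, rooted at a
    germline node with the all-absent profile.

    Exact (minimum Fitch/Sankoff score over all rooted topologies) for up
    to six leaves; stepwise addition plus NNI hill climbing beyond.  Edge
    mutation sets come from the Sankoff traceback with ties resolved
    toward the root.
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 tumor samples to build a tree")
    order = sorted(matrix.sample_ids)
    idx = [matrix.sample_ids.index(s) for s in order]
    P = matrix.presence[idx]
    topology = _search_topology(P, len(order))
    return _materialize(topology, P, order, matrix.variant_keys)


def _materialize(topology, P: np.ndarray, samples: list[str],
                 variant_keys: list[str]) -> PhyloTree:
    parent: dict[str, str | None] = {"root": None}
    leaf_sample: dict[str, str] = {}
    node_topo: dict[str, object] = {}
    counter = itertools.count()

    def build(t, parent_id: str) -> str:
        if isinstance(t, int):
            nid = f"L{t}"
            leaf_sample[nid] = samples[t]
        else:
            nid = f"I{next(counter)}"
        parent[nid] = parent_id
        node_topo[nid] = t
        if isinstance(t, tuple):
            build(t[0], nid)
            build(t[1], nid)
        return nid

    top = build(topology, "root")

    # Sankoff traceback, vectorized over variants; ties prefer state 1
    # (gains placed as early, losses as late, as possible)
    cost_cache: dict[str, np.ndarray] = {}

    def costs(nid: str) -> np.ndarray:
        if nid not in cost_cache:
            cost_cache[nid] = _sankoff_costs(node_topo[nid], P)
        return cost_cache[nid]

    edge_mut: dict[str, set[str]] = {}
    edge_loss: dict[str, set[str]] = {}
    states: dict[str, np.ndarray] = {}

    children_of: dict[str, list[str]] = {}
    for n, p in parent.items():
        if p is not None:
            children_of.setdefault(p, []).append(n)

    c_top = costs(top)
    top_state = np.where(c_top[1] + 1 <= c_top[0], 1, 0)
    states[top] = top_state
    stack = [top]
    while stack:
        nid = stack.pop()
        ps = states[nid]
        for child in children_of.get(nid, []):
            cc = costs(child)
            keep = cc[ps, np.arange(P.shape[1])]
            flip = cc[1 - ps, np.arange(P.shape[1])] + 1
            child_state = np.where(
                ps == 1,
                np.where(keep <= flip, ps, 1 - ps),        # ties keep 1
                np.where(flip <= keep, 1 - ps, ps),        # ties gain now
            )
            states[child] = child_state
            stack.append(child)

    for nid, st in states.items():
        p = parent[nid]
        ps = np.zeros_like(st) if p == "root" else states[p]
        gains = (ps == 0) & (st == 1)
        losses = (ps == 1) & (st == 0)
        edge_mut[nid] = {variant_keys[j] for j in np.flatnonzero(gains)}
        edge_loss[nid] = {variant_keys[j] for j in np.flatnonzero(losses)}

    lengths = {n: float(len(edge_mut[n]) + len(edge_loss[n])) for n in states}
    return PhyloTree(parent=parent, leaf_sample=leaf_sample, root="root",
                     edge_mutations=edge_mut, edge_losses=edge_loss,
                     edge_length=lengths)


def parsimony_score(tree: PhyloTree, matrix: BinaryMutationMatrix) -> int:
    """Minimum state changes of the matrix on the tree's topology
    (Sankoff dynamic programming, root constrained to the absent state)."""
    tree_samples = set(tree.leaf_sample.values())
    if tree_samples != set(matrix.sample_ids):
        raise ValueError(
            f"tree leaves {sorted(tree_samples)} do not match matrix "
            f"samples {sorted(matrix.sample_ids)}")
    children = tree.children
    n_var = matrix.n_variants
    sample_row = {s: i for i, s in enumerate(matrix.sample_ids)}

    def costs(node: str) -> np.ndarray:
        kids = children[node]
        if not kids:
            row = matrix.presence[sample_row[tree.leaf_sample[node]]]
            return np.where(np.array([[False], [True]]) == row[None, :], 0, _BIG)
        out = np.zeros((2, n_var), dtype=np.int64)
        for child in kids:
            c = costs(child)
            out += np.vstack([np.minimum(c[0], c[1] + 1),
                              np.minimum(c[1], c[0] + 1)])
        return out

    # root is germline (state 0); its children pay for any change
    out = np.zeros(n_var, dtype=np.int64)
    root_kids = children[tree.root]
    for child in root_kids:
        c = costs(child)
        out += np.minimum(c[0], c[1] + 1)
    return int(out.sum())


def trunk_metrics(tree: PhyloTree) -> TrunkMetrics:
    """Trunk length, mean root-to-leaf length and trunk ratio."""
    leaves = [n for n in tree.parent if tree.leaf_sample.get(n)]
    mrca = tree.mrca(leaves)
    trunk_len = sum(tree.edge_length[n] for n in tree.path_to_root(mrca))
    leaf_lens = [sum(tree.edge_length[n] for n in tree.path_to_root(leaf))
                 for leaf in leaves]
    mean_len = float(np.mean(leaf_lens))
    if mean_len == 0:
        warnings.warn("tree has no mutations; trunk ratio set to 0")
        ratio = 0.0
    else:
        ratio = trunk_len / mean_len
    return TrunkMetrics(trunk_len=int(trunk_len),
                        mean_root_leaf_len=mean_len, trunk_ratio=ratio)


@dataclass
class ProgressionCall:
    progression: Topology
    trunk_ratio: float
    borderline: bool


def classify_progression(metrics: TrunkMetrics,
                         threshold: float = 0.3,
                         borderline_margin: float = 0.05) -> ProgressionCall:
    """Branched iff trunk ratio >= threshold; calls within the margin of
    the threshold are flagged borderline."""
    topo = (Topology.BRANCHED if metrics.trunk_ratio >= threshold
            else Topology.DIASPORA)
    borderline = abs(metrics.trunk_ratio - threshold) <= borderline_margin
    return ProgressionCall(progression=topo, trunk_ratio=metrics.trunk_ratio,
                           borderline=borderline)


# ---------------------------------------------------------------------------
# newick IO (via dendropy)
# ---------------------------------------------------------------------------

def write_newick(tree: PhyloTree, path: str | None = None) -> str:
    """Render (and optionally write) the tree as newick; leaf labels are
    sample ids, branch lengths are edge mutation counts."""
    children = tree.children

    def render(node: str) -> str:
        kids = children[node]
        label = tree.leaf_sample.get(node, "")
        if "'" in label:
            raise ValueError("labels must not contain single quotes")
        needs_quote = any(c in label for c in " (),:;[]")
        if needs_quote:
            label = f"'{label}'"
        length = tree.edge_length.get(node)
        suffix = "" if length is None or node == tree.root else f":{length:g}"
        if not kids:
            return f"{label}{suffix}"
        return f"({','.join(render(k) for k in kids)}){label}{suffix}"

    newick = render(tree.root) + ";"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(newick + "\n")
    return newick


def read_newick(source: str) -> PhyloTree:
    """Parse a newick string or file into a PhyloTree (topology, branch
    lengths and leaf names only; edge mutation sets are not represented
    in newick)."""
    import os
    try:
        if os.path.exists(source):
            dtree = dendropy.Tree.get(path=source, schema="newick")
        else:
            dtree = dendropy.Tree.get(data=source, schema="newick")
    except Exception as exc:  # dendropy reports position in its message
        raise ValueError(f"malformed newick: {exc}") from exc

    parent: dict[str, str | None] = {}
    leaf_sample: dict[str, str] = {}
    lengths: dict[str, float] = {}
    ids: dict[int, str] = {}
    counter = itertools.count()
    for node in dtree.preorder_node_iter():
        nid = f"N{next(counter)}"
        ids[id(node)] = nid
        parent[nid] = ids[id(node.parent_node)] if node.parent_node else None
        if node.is_leaf():
            label = node.taxon.label if node.taxon else ""
            leaf_sample[nid] = label
        if node.parent_node is not None:
            lengths[nid] = float(node.edge.length or 0.0)
    root = next(n for n, p in parent.items() if p is None)
    return PhyloTree(parent=parent, leaf_sample=leaf_sample, root=root,
                     edge_length=lengths)
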