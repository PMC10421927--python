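"""Minimum-migration anatomical labeling and seeding-pattern taxonomy.

Internal tree nodes are labeled with anatomical sites by Sankoff dynamic
programming under unit inter-site migration cost, with the root
constrained to the primary tumor (metastasis starts there).  Among
minimum-migration labelings the traceback prefers the parent's label,
then the primary site, then lexicographic order — a conservative choice
that avoids inventing intermediate seeding sites the data do not force.

Seeding patterns over the resulting site-level migration multigraph:

* parallel single-source — every metastatic site is seeded directly from
  the primary tumor;
* single-source — every metastatic site is seeded from exactly one other
  anatomical site (possibly a chain);
* multi-source — some site is seeded from two or more distinct sites,
  without directed cycles;
* reseeding — the migration graph contains a directed cycle.

A destination site is polyclonal when two or more migration edges enter
it, monoclonal otherwise.
"""

from __future__ import annotations

import networkx as nx

from .phylogeny import PhyloTree
from .types import Clonality, MigrationHistory, SeedingPattern


def infer_migration_labels(tree: PhyloTree, leaf_sites: dict[str, str],
                           primary_site: str = "primary") -> MigrationHistory:
    """Label internal nodes with sites minimizing the migration count.

    ``leaf_sites`` maps sample ids to site labels; every tumor leaf must
    be labeled and the root is fixed to ``primary_site``.
    """
    children = tree.children
    leaves = [n for n in tree.parent if not children[n]]
    unlabeled = [tree.leaf_sample.get(n, n) for n in leaves
                 if tree.leaf_sample.get(n) not in leaf_sites]
    if unlabeled:
        raise ValueError(f"unlabeled tumor leaves: {sorted(unlabeled)}")

    sites = sorted(set(leaf_sites.values()) | {primary_site})
    site_idx = {s: i for i, s in enumerate(sites)}
    BIG = 10**9

    cost: dict[str, list[int]] = {}

    def compute(node: str) -> list[int]:
        kids = children[node]
        if not kids:
            c = [BIG] * len(sites)
            c[site_idx[leaf_sites[tree.leaf_sample[node]]]] = 0
        else:
            c = [0] * len(sites)
            for child in kids:
                cc = compute(child)
                best = min(cc)
                for s in range(len(sites)):
                    c[s] += min(cc[s], best + 1)
        cost[node] = c
        return c

    compute(tree.root)

    labels: dict[str, str] = {}

    def assign(node: str, node_site: str) -> None:
        labels[node] = node_site
        ps = site_idx[node_site]
        for child in children[node]:
            cc = cost[child]
            best_total = min(cc[ps], min(cc) + 1)
            # candidate child sites achieving the optimum
            candidates = [s for s in range(len(sites))
                          if cc[s] + (1 if s != ps else 0) == best_total]
            if ps in candidates:
                choice = ps                       # prefer parent's label
            elif site_idx[primary_site] in candidates:
                choice = site_idx[primary_site]   # then primary
            else:
                choice = min(candidates)          # then lexicographic
            assign(child, sites[choice])

    root_cost = cost[tree.root][site_idx[primary_site]]
    if root_cost >= BIG:
        raise ValueError("no feasible labeling with the root at the primary site")
    assign(tree.root, primary_site)

    migration_edges = [
        (labels[p], labels[n])
        for n, p in tree.parent.items()
        if p is not None and labels[p] != labels[n]
    ]
    n_migrations = len(migration_edges)
    n_comigrations = len(set(migration_edges))
    pattern, clonality = classify_seeding_pattern_edges(
        migration_edges, primary_site)
    return MigrationHistory(
        node_site_labels=labels,
        migration_edges=migration_edges,
        n_migrations=n_migrations,
        n_comigrations=n_comigrations,
        pattern=pattern,
        clonality=clonality,
    )


def classify_seeding_pattern_edges(
        migration_edges: list[tuple[str, str]],
        primary_site: str = "primary") -> tuple[SeedingPattern, dict[str, Clonality]]:
    """Seeding pattern and per-destination clonality from migration edges."""
    graph = nx.DiGraph()
    graph.add_nodes_from({s for e in migration_edges for s in e})
    graph.add_edges_from(set(migration_edges))

    in_edges: dict[str, int] = {}
    sources: dict[str, set[str]] = {}
    for src, dest in migration_edges:
        in_edges[dest] = in_edges.get(dest, 0) + 1
        sources.setdefault(dest, set()).add(src)

    if graph.number_of_nodes() and not nx.is_directed_acyclic_graph(graph):
        pattern = SeedingPattern.RESEEDING
    elif any(len(s) >= 2 for s in sources.values()):
        pattern = SeedingPattern.MULTI_SOURCE
    elif all(src == primary_site for src, _ in migration_edges):
        pattern = SeedingPattern.PARALLEL_SINGLE_SOURCE
    else:
        pattern = SeedingPattern.SINGLE_SOURCE

    clonality = {
        dest: (Clonality.POLYCLONAL if n >= 2 else Clonality.MONOCLONAL)
        for dest, n in in_edges.items()
    }
    return pattern, clonality


def classify_seeding_pattern(history: MigrationHistory,
                             primary_site: str = "primary"
                             ) -> tuple[SeedingPattern, dict[str, Clonality]]:
    """Re-derive pattern and clonality from a migration history."""
    return classify_seeding_pattern_edges(history.migration_edges, primary_site)


def inferred_sources(history: MigrationHistory) -> dict[str, set[str]]:
    """Map each seeded site to the set of sites that seeded it."""
    out: dict[str, set[str]] = {}
    for src, dest in history.migration_edges:
        out.setdefault(dest, set()).add(src)
    return out
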