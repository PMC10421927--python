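"""Shared builders for the test suite.

The helpers construct in-memory variant / normal / segment tables with
sensible passing defaults so each test only spells out the fields it is
probing.
"""

from __future__ import annotations

import pandas as pd
import pytest

PASSING_QUALITY = {"tlod": 30.0, "mmq": 65.0, "seqq": 50.0, "strandq": 40.0}


def make_variant(patient_id="P1", sample_id="S1", chrom="1", pos0=999,
                 ref="C", alt="T", gene="GENE1", effect="missense",
                 alt_count=30, depth=100, vaf=None, trinuc_context="ACA",
                 **quality):
    q = {**PASSING_QUALITY, **quality}
    if vaf is None:
        vaf = round(alt_count / depth, 6) if depth else 0.0
    return {
        "patient_id": patient_id, "sample_id": sample_id, "chrom": chrom,
        "pos0": pos0, "ref": ref, "alt": alt, "gene": gene, "effect": effect,
        "alt_count": alt_count, "depth": depth, "vaf": vaf,
        **q, "trinuc_context": trinuc_context,
    }


def make_normal(patient_id="P1", chrom="1", pos0=999, ref="C", alt="T",
                depth=30, alt_count=0):
    return {
        "patient_id": patient_id, "chrom": chrom, "pos0": pos0,
        "ref": ref, "alt": alt, "depth": depth, "alt_count": alt_count,
    }


def variants_frame(rows):
    return pd.DataFrame(rows)


def normals_frame(rows):
    return pd.DataFrame(rows)


def make_segment(sample_id="S1", chrom="1", start=0, end=1_000_000,
                 log2_ratio=0.0, total_cn=2, major_cn=1, minor_cn=1):
    return {
        "sample_id": sample_id, "chrom": chrom, "start": start, "end": end,
        "log2_ratio": log2_ratio, "total_cn": total_cn,
        "major_cn": major_cn, "minor_cn": minor_cn,
    }


def random_phylo_tree(rng, n_leaves, site_pool=None):
    """Random rooted tree (not necessarily binary) with labeled leaves.

    Returns (PhyloTree, leaf_sites). Internal nodes have 2-3 children;
    leaves are samples named ``s0..``, assigned random sites from
    ``site_pool`` when given.
    """
    from metroute.phylogeny import PhyloTree

    parent = {"root": None}
    leaf_sample = {}
    open_nodes = ["root"]
    counter = [0]
    made_leaves = 0
    internal = 0
    while made_leaves < n_leaves:
        node = open_nodes.pop(int(rng.integers(len(open_nodes)))) \
            if len(open_nodes) > 1 else open_nodes.pop()
        # decide children: leaves vs internals
        remaining = n_leaves - made_leaves
        n_children = int(rng.integers(2, 4))
        for _ in range(n_children):
            counter[0] += 1
            if remaining > 0 and (rng.random() < 0.6 or internal > 6
                                  or not open_nodes):
                nid = f"L{counter[0]}"
                parent[nid] = node
                leaf_sample[nid] = f"s{made_leaves}"
                made_leaves += 1
                remaining -= 1
            else:
                nid = f"I{counter[0]}"
                parent[nid] = node
                open_nodes.append(nid)
                internal += 1
        if not open_nodes and made_leaves < n_leaves:
            # reopen a random internal node by adding a leaf under root
            open_nodes.append("root")
    # any internal node left open with no children becomes a leaf
    children = {}
    for n, p in parent.items():
        if p is not None:
            children.setdefault(p, []).append(n)
    for n in list(parent):
        if n != "root" and n.startswith("I") and n not in children:
            leaf_sample[n] = f"s{made_leaves}"
            made_leaves += 1
    tree = PhyloTree(parent=parent, leaf_sample=leaf_sample, root="root")
    leaf_sites = None
    if site_pool is not None:
        leaf_sites = {s: str(rng.choice(site_pool))
                      for s in leaf_sample.values()}
    return tree, leaf_sites


@pytest.fixture()
def toy_arms():
    """Four tiny arms (two chromosomes, 100 bp each) for oracle tests."""
    return pd.DataFrame([
        {"chrom": "1", "arm": "p", "start": 0, "end": 100},
        {"chrom": "1", "arm": "q", "start": 100, "end": 200},
        {"chrom": "2", "arm": "p", "start": 0, "end": 100},
        {"chrom": "2", "arm": "q", "start": 100, "end": 200},
    ])
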