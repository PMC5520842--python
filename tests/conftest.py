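"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's own code paths: tree
splits and path lengths come from explicit graph traversal over networkx
graphs, topology identification from least-squares fits over every
unrooted topology, and codon counting from exhaustive mutant/pathway
enumeration using Biopython translation.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest
from Bio.Seq import Seq

BASES = "ACGT"


def translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


SENSE_CODONS = sorted(
    c for c in ("".join(t) for t in itertools.product(BASES, repeat=3))
    if translate_codon(c) != "*"
)


# ---------------------------------------------------------------- trees


def random_additive_tree(labels, rng, blen=(0.1, 1.0)):
    """A random unrooted binary tree as a networkx graph with edge lengths.

    Built by repeatedly attaching the next leaf to a uniformly chosen
    existing edge; all branch lengths are drawn uniformly, so the distance
    matrix is additive and generic (no zero internal branches).
    """
    g = nx.Graph()
    center = "_n0"
    for leaf in labels[:3]:
        g.add_edge(center, leaf, length=rng.uniform(*blen))
    counter = 1
    for leaf in labels[3:]:
        edges = list(g.edges(data=True))
        u, v, data = edges[rng.integers(0, len(edges))]
        w = f"_n{counter}"
        counter += 1
        split = rng.uniform(0.2, 0.8)
        g.remove_edge(u, v)
        g.add_edge(u, w, length=data["length"] * split)
        g.add_edge(w, v, length=data["length"] * (1 - split))
        g.add_edge(w, leaf, length=rng.uniform(*blen))
    return g


def graph_leaf_distances(g, labels):
    d = np.zeros((len(labels), len(labels)))
    paths = dict(nx.all_pairs_dijkstra_path_length(g, weight="length"))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            d[i, j] = paths[a][b]
    return d


def graph_splits(g, labels):
    """Nontrivial splits of a tree graph, each as the side without labels[0]."""
    ref = labels[0]
    splits = set()
    for u, v in list(g.edges()):
        g.remove_edge(u, v)
        comp = nx.node_connected_component(g, u)
        g.add_edge(u, v, length=0)  # length unused afterwards
        side = frozenset(l for l in labels if l in comp)
        if ref in side:
            side = frozenset(labels) - side
        if 1 < len(side) < len(labels) - 1:
            splits.add(side)
    return splits


def dendropy_splits(tree, labels):
    """Nontrivial splits of a dendropy tree, same normalization."""
    ref = labels[0]
    splits = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if ref in side:
            side = frozenset(labels) - side
        if 1 < len(side) < len(labels) - 1:
            splits.add(side)
    return splits


def enumerate_topologies(labels):
    """Every unrooted binary topology on the labels, as networkx graphs."""
    first = nx.Graph()
    first.add_edges_from([("_t0", l) for l in labels[:3]])
    trees = [(first, 1)]
    for leaf in labels[3:]:
        nxt = []
        for g, counter in trees:
            for u, v in list(g.edges()):
                h = g.copy()
                w = f"_t{counter}"
                h.remove_edge(u, v)
                h.add_edges_from([(u, w), (w, v), (w, leaf)])
                nxt.append((h, counter + 1))
        trees = nxt
    return [g for g, _ in trees]


def best_fit_topology(labels, d):
    """Identify the generating topology by exact least-squares fit.

    For each candidate topology, branch lengths are solved from the
    pair-path incidence system; an additive matrix fits its own topology
    with zero residual and no other (for generic branch lengths).
    """
    pairs = list(itertools.combinations(range(len(labels)), 2))
    best_splits, best_res = None, np.inf
    for g in enumerate_topologies(labels):
        edges = list(g.edges())
        a = np.zeros((len(pairs), len(edges)))
        for row, (i, j) in enumerate(pairs):
            path = nx.shortest_path(g, labels[i], labels[j])
            on_path = {frozenset(e) for e in zip(path, path[1:])}
            for col, e in enumerate(edges):
                if frozenset(e) in on_path:
                    a[row, col] = 1.0
        y = np.array([d[i, j] for i, j in pairs])
        sol, *_ = np.linalg.lstsq(a, y, rcond=None)
        res = float(np.sum((a @ sol - y) ** 2))
        if res < best_res:
            best_res = res
            best_splits = graph_splits(g, labels)
    return best_splits, best_res


# ---------------------------------------------------------------- codons


def oracle_syn_sites(codon: str) -> float:
    """Synonymous sites by explicit enumeration of all nine mutants."""
    total = 0.0
    aa = translate_codon(codon)
    for pos in range(3):
        syn = viable = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if translate_codon(mut) == "*":
                continue
            viable += 1
            syn += translate_codon(mut) == aa
        if viable:
            total += syn / viable
    return total


def oracle_pathways(ca: str, cb: str):
    """(Sd, Nd) by exhaustive recursion over minimal mutation pathways."""

    def walk(cur, remaining):
        if not remaining:
            return [(0, 0, False)]
        results = []
        for k, pos in enumerate(remaining):
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            stop = translate_codon(nxt) == "*"
            syn = translate_codon(nxt) == translate_codon(cur)
            for sd, nd, blocked in walk(nxt, remaining[:k] + remaining[k + 1 :]):
                results.append((sd + syn, nd + (not syn), blocked or stop))
        return results

    paths = walk(ca, tuple(i for i in range(3) if ca[i] != cb[i]))
    clean = [p for p in paths if not p[2]] or paths
    sd = sum(p[0] for p in clean) / len(clean)
    nd = sum(p[1] for p in clean) / len(clean)
    return sd, nd


def random_sense_neighbor(codon: str, rng, max_diffs: int = 2) -> str:
    """A sense codon differing from the input at ≤ max_diffs positions."""
    for _ in range(100):
        out = list(codon)
        k = int(rng.integers(0, max_diffs + 1))
        for pos in rng.choice(3, size=k, replace=False):
            out[pos] = BASES[rng.integers(0, 4)]
        cand = "".join(out)
        if translate_codon(cand) != "*":
            return cand
    return codon


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
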