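"""Neighbor-joining phylogeny on Poisson-corrected protein distances.

Pairwise amino-acid distances use the Poisson correction d = −ln(1 − p),
where p is the proportion of differing comparable sites.  Trees are built
by the Saitou–Nei neighbor-joining agglomeration with deterministic
tie-breaking, bootstrap support comes from column resampling, and
subfamily/section labels are assigned by rooted clade membership relative
to user-supplied reference exemplars (the split criterion between sections
is not derivable from the tree alone).

Trees are returned as :class:`dendropy.Tree` objects; all serialization is
of the unrooted tree (rooting happens only transiently for clade labeling).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np

log = logging.getLogger(__name__)

GAP = "-"


@dataclass
class Alignment:
    """An aligned set of gapped amino-acid sequences."""

    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon ids")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"unequal row lengths {sorted(lengths)}")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        from Bio import SeqIO

        taxa, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            taxa.append(rec.id)
            rows.append(str(rec.seq).upper())
        return cls(taxa=taxa, rows=rows)

    def subset_columns(self, indices: Sequence[int]) -> "Alignment":
        rows = ["".join(r[i] for i in indices) for r in self.rows]
        return Alignment(taxa=list(self.taxa), rows=rows)


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(self.d < 0):
            raise ValueError("negative distances")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("nonzero diagonal")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("non-finite distances")


class UndefinedDistanceError(ValueError):
    """Raised when p ≥ 1 makes the Poisson correction undefined."""


def poisson_distance(
    alignment: Alignment, gap_policy: str = "complete"
) -> DistanceMatrix:
    """Poisson-corrected distances d = −ln(1 − p) for every taxon pair.

    ``gap_policy`` is ``"complete"`` (columns containing any gap removed
    before comparison — the MEGA-style default) or ``"pairwise"`` (each
    pair compared over its own gap-free columns).
    """
    if alignment.n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if gap_policy not in ("complete", "pairwise"):
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    rows = alignment.rows
    n = alignment.n_taxa
    if gap_policy == "complete":
        keep = [
            c for c in range(alignment.n_columns)
            if all(r[c] != GAP for r in rows)
        ]
        rows = ["".join(r[c] for c in keep) for r in rows]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = rows[i], rows[j]
            if gap_policy == "pairwise":
                cols = [(x, y) for x, y in zip(a, b) if x != GAP and y != GAP]
            else:
                cols = list(zip(a, b))
            if not cols:
                raise UndefinedDistanceError(
                    f"no comparable columns for ({alignment.taxa[i]}, "
                    f"{alignment.taxa[j]})"
                )
            p = sum(x != y for x, y in cols) / len(cols)
            if p >= 1.0:
                raise UndefinedDistanceError(
                    f"p = 1 for ({alignment.taxa[i]}, {alignment.taxa[j]}): "
                    "Poisson correction undefined"
                )
            d[i, j] = d[j, i] = -np.log(1.0 - p)
    return DistanceMatrix(taxa=list(alignment.taxa), d=d)


def _nj_newick(taxa: list[str], d0: np.ndarray) -> str:
    """Saitou–Nei NJ; ties broken at the lowest active (row, column) pair."""
    d = d0.copy()
    # each active entry: newick fragment for the subtree rooted at that node
    nodes = [f"{t}" for t in taxa]
    active = list(range(len(taxa)))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best, best_q = None, np.inf
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * sub[i, j] - r[i] - r[j]
                if q < best_q - 1e-15:
                    best_q, best = q, (i, j)
        i, j = best
        dij = sub[i, j]
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            log.debug("clamping negative branch %.3g", li)
            lj += li
            li = 0.0
        if lj < 0:
            log.debug("clamping negative branch %.3g", lj)
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        gi, gj = active[i], active[j]
        new = f"({nodes[gi]}:{li:.12g},{nodes[gj]}:{lj:.12g})"
        # distances from the new node u to every other active node k
        new_row = np.zeros(d.shape[0] + 1)
        for k_local, gk in enumerate(active):
            if k_local in (i, j):
                continue
            new_row[gk] = (d[gi, gk] + d[gj, gk] - dij) / 2.0
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(new)
        active = [g for g in active if g not in (gi, gj)] + [len(nodes) - 1]
    ga, gb, gc = active
    dab, dac, dbc = d[ga, gb], d[ga, gc], d[gb, gc]
    la = max((dab + dac - dbc) / 2.0, 0.0)
    lb = max((dab + dbc - dac) / 2.0, 0.0)
    lc = max((dac + dbc - dab) / 2.0, 0.0)
    return (
        f"({nodes[ga]}:{la:.12g},{nodes[gb]}:{lb:.12g},{nodes[gc]}:{lc:.12g});"
    )


def nj_tree(
    dm: DistanceMatrix,
    taxon_namespace: dendropy.TaxonNamespace | None = None,
) -> dendropy.Tree:
    """Neighbor-joining tree from a distance matrix.

    On an additive matrix the leaf-to-leaf path lengths of the returned
    tree reproduce the input distances (up to floating error).
    """
    if len(dm.taxa) < 3:
        raise ValueError("need at least 3 taxa for a tree")
    newick = _nj_newick(dm.taxa, dm.d)
    tns = taxon_namespace or dendropy.TaxonNamespace()
    tree = dendropy.Tree.get(
        data=newick, schema="newick", taxon_namespace=tns,
        preserve_underscores=True,
    )
    tree.is_rooted = False
    return tree


def tree_path_distances(tree: dendropy.Tree) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf patristic distances keyed by sorted label pairs."""
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    taxa = list(tree.taxon_namespace)
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1 :]:
            key = tuple(sorted((t1.label, t2.label)))
            out[key] = pdm.patristic_distance(t1, t2)
    return out


def _nontrivial_splits(tree: dendropy.Tree) -> set[int]:
    tree.encode_bipartitions()
    return {
        b.split_bitmask
        for b in tree.bipartition_encoding
        if not b.is_trivial()
    }


def bootstrap_support(
    alignment: Alignment,
    replicates: int = 1000,
    seed: int | None = None,
    gap_policy: str = "complete",
) -> dendropy.Tree:
    """NJ tree with internal edges annotated by bootstrap percentages.

    Columns are resampled with replacement ``replicates`` times; each
    internal bipartition of the full-data tree is labeled with the
    percentage of replicate trees containing it.  Deterministic under a
    fixed seed.  Replicates whose resampled columns leave some pair
    saturated (p ≥ 1) are skipped with a warning and removed from the
    denominator.
    """
    if replicates < 1:
        raise ValueError("replicates must be ≥ 1")
    tns = dendropy.TaxonNamespace()
    full = nj_tree(poisson_distance(alignment, gap_policy), tns)
    if alignment.n_taxa < 4:
        log.warning("fewer than 4 taxa: no internal edges to support")
        return full
    rng = np.random.default_rng(seed)
    counts: dict[int, int] = {}
    n_ok = 0
    for _ in range(replicates):
        cols = rng.integers(0, alignment.n_columns, size=alignment.n_columns)
        try:
            rep_dm = poisson_distance(alignment.subset_columns(cols), gap_policy)
        except UndefinedDistanceError as err:
            log.warning("bootstrap replicate skipped: %s", err)
            continue
        n_ok += 1
        for s in _nontrivial_splits(nj_tree(rep_dm, tns)):
            counts[s] = counts.get(s, 0) + 1
    full.encode_bipartitions()
    for edge in full.preorder_edge_iter():
        head = edge.head_node
        if head.is_leaf() or edge.tail_node is None:
            continue
        if n_ok == 0:
            head.label = "0"
            continue
        pct = 100.0 * counts.get(edge.bipartition.split_bitmask, 0) / n_ok
        head.label = str(int(round(pct)))
    return full


def assign_clades(
    tree: dendropy.Tree,
    references: Mapping[str, str],
    outgroup: str,
) -> dict[str, str]:
    """Label each taxon with the group of the reference clade it nests in.

    The tree is rooted at the outgroup; each unlabeled taxon receives the
    group of the references in the smallest rooted clade that contains it
    and at least one reference.  If that clade mixes reference groups the
    taxon is labeled ``"ambiguous"`` rather than guessed.
    """
    work = tree.clone(depth=1)
    og_node = None
    for leaf in work.leaf_node_iter():
        if leaf.taxon.label == outgroup:
            og_node = leaf
            break
    if og_node is None:
        raise ValueError(f"outgroup {outgroup!r} not in tree")
    if not references:
        raise ValueError("need at least one reference exemplar")
    work.to_outgroup_position(og_node, update_bipartitions=False)
    labels: dict[str, str] = {}
    for leaf in work.leaf_node_iter():
        name = leaf.taxon.label
        if name == outgroup:
            continue
        if name in references:
            labels[name] = references[name]
            continue
        node = leaf.parent_node
        assigned = None
        while node is not None:
            clade_taxa = {l.taxon.label for l in node.leaf_iter()}
            groups = {
                references[t] for t in clade_taxa if t in references
            }
            if groups:
                assigned = groups.pop() if len(groups) == 1 else "ambiguous"
                break
            node = node.parent_node
        labels[name] = assigned if assigned is not None else "ambiguous"
    return labels
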