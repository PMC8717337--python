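"""Naive reference implementations of the community metrics.

These deliberately avoid the vectorized edge-incidence machinery the
production code uses: distances come from dendropy's own phylogenetic
distance matrix and every metric is an explicit loop over pairs or edge
sets.  They exist to cross-check the fast paths (in tests and in the
acceptance checks) and are far too slow for real pipelines.
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import dendropy
import numpy as np

from .trees import Phylogeny

__all__ = ["ref_cophenetic", "ref_pd", "ref_mpd", "ref_mntd", "ref_vpd",
           "ref_phylosor"]


def ref_cophenetic(tree: Phylogeny) -> dict[tuple[str, str], float]:
    """Pairwise patristic distances via dendropy's distance matrix."""
    pdm = tree.dendropy_tree.phylogenetic_distance_matrix()
    out: dict[tuple[str, str], float] = {}
    taxa = list(tree.dendropy_tree.taxon_namespace)
    for t1, t2 in combinations(taxa, 2):
        d = pdm.patristic_distance(t1, t2)
        out[(t1.label, t2.label)] = d
        out[(t2.label, t1.label)] = d
    for t in taxa:
        out[(t.label, t.label)] = 0.0
    return out


def _root_path_edges(tree: Phylogeny, label: str) -> list:
    dtree = tree.dendropy_tree
    node = next(lf for lf in dtree.leaf_node_iter()
                if lf.taxon is not None and lf.taxon.label == label)
    edges = []
    while node.parent_node is not None:
        edges.append(node.edge)
        node = node.parent_node
    return edges


def ref_pd(tree: Phylogeny, taxa: Sequence[str], include_root: bool = False) -> float:
    """Faith's PD by explicit union/intersection of root-to-tip edge sets."""
    taxa = list(taxa)
    paths = [set(id(e) for e in _root_path_edges(tree, t)) for t in taxa]
    lengths = {}
    for t in taxa:
        for e in _root_path_edges(tree, t):
            lengths[id(e)] = e.length
    union = set().union(*paths)
    if include_root:
        return sum(lengths[e] for e in union)
    if len(taxa) < 2:
        return float("nan")
    shared_by_all = set.intersection(*paths)  # root-to-MRCA path
    return sum(lengths[e] for e in union - shared_by_all)


def ref_mpd(tree: Phylogeny, taxa: Sequence[str]) -> float:
    if len(taxa) < 2:
        return float("nan")
    d = ref_cophenetic(tree)
    pairs = [d[(a, b)] for a, b in combinations(taxa, 2)]
    return sum(pairs) / len(pairs)


def ref_mntd(tree: Phylogeny, taxa: Sequence[str]) -> float:
    if len(taxa) < 2:
        return float("nan")
    d = ref_cophenetic(tree)
    mins = [min(d[(a, b)] for b in taxa if b != a) for a in taxa]
    return sum(mins) / len(mins)


def ref_vpd(tree: Phylogeny, taxa: Sequence[str]) -> float:
    if len(taxa) < 2:
        return float("nan")
    d = ref_cophenetic(tree)
    pairs = np.array([d[(a, b)] for a, b in combinations(taxa, 2)])
    return float(((pairs - pairs.mean()) ** 2).mean())


def ref_phylosor(tree: Phylogeny, taxa_a: Sequence[str],
                 taxa_b: Sequence[str]) -> float:
    """PhyloSor by explicit edge-set algebra under the pooled-MRCA rooting."""
    pooled = list(dict.fromkeys(list(taxa_a) + list(taxa_b)))
    paths = {t: set(id(e) for e in _root_path_edges(tree, t)) for t in pooled}
    lengths = {id(e): e.length for t in pooled for e in _root_path_edges(tree, t)}
    above_mrca = set.intersection(*paths.values()) if pooled else set()

    def bl(taxa: Sequence[str]) -> float:
        union = set().union(*(paths[t] for t in taxa)) - above_mrca
        return sum(lengths[e] for e in union)

    bl_a, bl_b, bl_union = bl(list(taxa_a)), bl(list(taxa_b)), bl(pooled)
    shared = bl_a + bl_b - bl_union
    return 1.0 - shared / (0.5 * (bl_a + bl_b))
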