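"""Rooted, branch-length-bearing phylogenies and posterior-like tree samples.

Trees are stored as :class:`Phylogeny` objects wrapping a dendropy tree plus a
cached edge-incidence structure: a boolean matrix ``M`` with one row per tip
and one column per non-root edge, ``M[i, e]`` true iff edge ``e`` lies on the
path from tip ``i`` to the root.  All patristic-distance and spanning-subtree
quantities used by the community metrics reduce to set algebra on the columns
of ``M`` weighted by edge lengths, which keeps the null-model pipelines fast
without re-traversing the tree.

Branch lengths are interpreted as time (Ma) throughout; the code never assumes
ultrametricity.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "TreeSample",
    "DistanceMatrix",
    "NewickError",
    "read_newick",
    "write_newick",
    "prune_to",
    "cophenetic",
    "subtree_length",
]


class NewickError(ValueError):
    """Raised for malformed Newick input or invariant violations."""


@dataclass(frozen=True)
class DistanceMatrix:
    """Square matrix of pairwise patristic distances with an explicit label order."""

    labels: tuple[str, ...]
    values: np.ndarray  # (n, n) float, symmetric, zero diagonal

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValueError("distance matrix shape does not match labels")
        object.__setattr__(self, "values", v)

    def index_of(self, labels: Iterable[str]) -> np.ndarray:
        pos = {lab: i for i, lab in enumerate(self.labels)}
        try:
            return np.array([pos[l] for l in labels], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"label not in distance matrix: {exc.args[0]!r}") from None

    def submatrix(self, labels: Sequence[str]) -> np.ndarray:
        idx = self.index_of(labels)
        return self.values[np.ix_(idx, idx)]


class Phylogeny:
    """A rooted tree with branch lengths on every non-root edge.

    Invariants enforced on construction: >= 2 tips, unique non-empty tip
    labels, finite non-negative lengths on all non-root edges (zero allowed --
    posterior draws may contain zero-length branches; negatives rejected).
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()
        self._edge_cache: tuple[np.ndarray, np.ndarray] | None = None
        leaves = [nd for nd in tree.leaf_node_iter()]
        self._tip_labels: tuple[str, ...] = tuple(_leaf_label(nd) for nd in leaves)
        self._tip_index = {lab: i for i, lab in enumerate(self._tip_labels)}

    # -- construction / validation -------------------------------------------------

    def _validate(self) -> None:
        tree = self._tree
        labels = []
        for leaf in tree.leaf_node_iter():
            lab = _leaf_label(leaf)
            if not lab:
                raise NewickError("empty tip label")
            labels.append(lab)
        if len(labels) < 2:
            raise NewickError(f"tree must have >= 2 tips, got {len(labels)}")
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise NewickError(f"duplicate tip label(s): {sorted(dupes)}")
        root = tree.seed_node
        for nd in tree.preorder_node_iter():
            if nd is root:
                continue
            el = nd.edge.length
            if el is None:
                raise NewickError(
                    f"missing branch length on edge above "
                    f"{_leaf_label(nd) if nd.is_leaf() else 'an internal node'}"
                )
            if not math.isfinite(el) or el < 0:
                raise NewickError(f"invalid branch length {el!r}")

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        return _parse_one(newick, line_no=None)

    # -- basic accessors -----------------------------------------------------------

    @property
    def tip_labels(self) -> tuple[str, ...]:
        return self._tip_labels

    @property
    def n_tips(self) -> int:
        return len(self._tip_labels)

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def total_branch_length(self) -> float:
        root = self._tree.seed_node
        return float(
            sum(nd.edge.length for nd in self._tree.preorder_node_iter() if nd is not root)
        )

    def as_newick(self) -> str:
        s = self._tree.as_string(schema="newick", suppress_rooting=True,
                                 unquoted_underscores=True)
        return s.strip()

    # -- edge-incidence structure ----------------------------------------------------

    def edge_structure(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(M, lengths)``: tip x edge boolean incidence and edge lengths.

        Row order follows :attr:`tip_labels`; column order is a fixed postorder.
        """
        if self._edge_cache is None:
            root = self._tree.seed_node
            nodes = [nd for nd in self._tree.postorder_node_iter() if nd is not root]
            n_tips, n_edges = self.n_tips, len(nodes)
            M = np.zeros((n_tips, n_edges), dtype=bool)
            lengths = np.empty(n_edges, dtype=float)
            below: dict[int, np.ndarray] = {}
            for e, nd in enumerate(nodes):
                lengths[e] = nd.edge.length
                if nd.is_leaf():
                    tips = np.array([self._tip_index[_leaf_label(nd)]], dtype=np.intp)
                else:
                    tips = np.concatenate([below[id(c)] for c in nd.child_nodes()])
                below[id(nd)] = tips
                M[tips, e] = True
            self._edge_cache = (M, lengths)
        return self._edge_cache

    def tip_indices(self, taxa: Iterable[str]) -> np.ndarray:
        missing = [t for t in taxa if t not in self._tip_index] if not isinstance(taxa, np.ndarray) else []
        if missing:
            raise KeyError(f"taxa not in tree: {sorted(missing)}")
        return np.array([self._tip_index[t] for t in taxa], dtype=np.intp)

    def relabeled(self, mapping: dict[str, str]) -> "Phylogeny":
        """Return a copy with tip labels replaced according to ``mapping``."""
        clone = self._tree.clone(depth=1)
        clone.taxon_namespace = dendropy.TaxonNamespace()
        for leaf in clone.leaf_node_iter():
            old = _leaf_label(leaf)
            leaf.taxon = clone.taxon_namespace.new_taxon(label=mapping.get(old, old))
        return Phylogeny(clone)


class TreeSample:
    """Ordered collection of trees over one shared tip-label set."""

    def __init__(self, trees: Sequence[Phylogeny]):
        if len(trees) < 1:
            raise NewickError("TreeSample needs at least one tree")
        ref = set(trees[0].tip_labels)
        for i, t in enumerate(trees[1:], start=2):
            other = set(t.tip_labels)
            if other != ref:
                diff = sorted(ref.symmetric_difference(other))
                raise NewickError(
                    f"tree {i} has a different tip set; symmetric difference: {diff}"
                )
        self._trees = list(trees)

    def __len__(self) -> int:
        return len(self._trees)

    def __getitem__(self, i: int) -> Phylogeny:
        return self._trees[i]

    def __iter__(self) -> Iterator[Phylogeny]:
        return iter(self._trees)

    @property
    def tip_labels(self) -> frozenset[str]:
        return frozenset(self._trees[0].tip_labels)


# ---------------------------------------------------------------------------------
# parsing / writing


def _leaf_label(node: dendropy.Node) -> str:
    lab = node.taxon.label if node.taxon is not None else (node.label or "")
    return lab.strip().strip("'\"").strip()


def _parse_one(newick: str, line_no: int | None) -> Phylogeny:
    where = f" (line {line_no})" if line_no is not None else ""
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            taxon_namespace=dendropy.TaxonNamespace(),
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"malformed Newick{where}: {exc}") from exc
    try:
        return Phylogeny(tree)
    except NewickError as exc:
        raise NewickError(f"{exc}{where}") from None


def read_newick(source: str | Path | io.TextIOBase) -> TreeSample:
    """Read one or more Newick trees (one per line or ';'-separated).

    Returns the trees in file order as a :class:`TreeSample`; every tree must
    carry branch lengths on all non-root edges and all trees must share one
    tip-label set.
    """
    if isinstance(source, io.TextIOBase):
        text = source.read()
    else:
        p = Path(source)
        if p.exists():
            text = p.read_text()
        elif isinstance(source, str) and ";" in source:
            text = source
        else:
            raise FileNotFoundError(source)

    trees: list[Phylogeny] = []
    buf = ""
    start_line = 1
    for ln, line in enumerate(text.splitlines() or [text], start=1):
        if not buf.strip():
            start_line = ln
        buf += line + "\n"
        while ";" in buf:
            chunk, buf = buf.split(";", 1)
            if chunk.strip():
                trees.append(_parse_one(chunk + ";", start_line))
            start_line = ln
    if buf.strip():
        raise NewickError(f"unterminated Newick string starting at line {start_line}")
    if not trees:
        raise NewickError("no Newick trees found in input")
    return TreeSample(trees)


def write_newick(trees: Phylogeny | TreeSample, path: str | Path) -> None:
    """Write trees one Newick string per line."""
    if isinstance(trees, Phylogeny):
        trees = TreeSample([trees])
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.as_newick())
            if not t.as_newick().endswith("\n"):
                fh.write("\n")


# ---------------------------------------------------------------------------------
# operations


def prune_to(tree: Phylogeny, taxa: Iterable[str]) -> Phylogeny:
    """Restrict ``tree`` to ``taxa``, preserving pairwise patristic distances.

    Unbranched internal nodes created by the pruning are merged with their
    branch lengths summed.
    """
    keep = sorted(set(taxa))
    unknown = [t for t in keep if t not in tree._tip_index]
    if unknown:
        raise KeyError(f"taxa not in tree: {unknown}")
    if len(keep) < 2:
        raise ValueError("prune_to requires at least two taxa")
    clone = tree.dendropy_tree.clone(depth=1)
    keep_set = set(keep)
    drop = [leaf.taxon for leaf in clone.leaf_node_iter()
            if _leaf_label(leaf) not in keep_set]
    clone.prune_taxa(drop, suppress_unifurcations=True)
    # a leftover root unifurcation leaves an uncounted stem edge; harmless for
    # patristic distances, but collapse it for a clean crown-rooted tree
    root = clone.seed_node
    while len(root.child_nodes()) == 1:
        child = root.child_nodes()[0]
        clone.seed_node = child
        child.parent_node = None
        child.edge.length = None
        root = child
    return Phylogeny(clone)


def cophenetic(tree: Phylogeny) -> DistanceMatrix:
    """Pairwise patristic distances between all tips (path sums of branch lengths)."""
    M, lengths = tree.edge_structure()
    W = M * lengths  # (tips, edges)
    depth = W.sum(axis=1)
    shared = W @ M.T
    D = depth[:, None] + depth[None, :] - 2.0 * shared
    np.fill_diagonal(D, 0.0)
    np.clip(D, 0.0, None, out=D)
    return DistanceMatrix(labels=tree.tip_labels, values=D)


def subtree_length(tree: Phylogeny, taxa: Iterable[str], include_root: bool = False) -> float:
    """Total branch length of the minimal subtree connecting ``taxa``.

    With ``include_root=False`` the subtree is rooted at the MRCA of ``taxa``
    (no edge above the MRCA counted); a single taxon then has no subtree and
    the result is NaN (undefined, never silently zero).  With
    ``include_root=True`` the path from the MRCA up to the tree root is
    counted as well.
    """
    taxa = list(taxa)
    if len(taxa) == 0:
        raise ValueError("subtree_length requires at least one taxon")
    idx = tree.tip_indices(taxa)
    M, lengths = tree.edge_structure()
    union = M[idx].any(axis=0)
    if include_root:
        return float(lengths[union].sum())
    if len(idx) < 2:
        return float("nan")
    mrca_path = M[idx].all(axis=0)  # edges shared by all root paths = root-to-MRCA
    return float(lengths[union & ~mrca_path].sum())
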