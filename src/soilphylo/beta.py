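"""Pairwise compositional turnover: Sorensen and PhyloSor dissimilarity.

PhyloSor here uses the pooled-pair rooting convention: for a pair of
communities A and B, each community's branch-length total BL_X is the length
of the minimal subtree connecting X to the MRCA of the pooled set A∪B.  The
shared branch length is then exactly BL_A + BL_B − BL_{A∪B} and is
non-negative, and single-species communities have a well-defined BL (their
tip-to-MRCA path).  This deliberately differs from the root-excluded Faith's
PD used for the alpha metrics, where each community is rooted at its own
MRCA.

On a star tree with equal tip branches PhyloSor reduces exactly to the
species-level Sorensen index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .community import CommunityMatrix
from .trees import Phylogeny, TreeSample

__all__ = ["BetaMatrix", "sorensen", "phylosor", "sorensen_matrix",
           "phylosor_matrix", "beta_over_trees"]


@dataclass(frozen=True)
class BetaMatrix:
    """Symmetric site x site dissimilarity matrix in [0, 1]."""

    sites: tuple[str, ...]
    values: np.ndarray
    metric: str  # "sorensen" | "phylosor"
    aggregation: str = "single-tree"  # or "median-of-<n>-trees" etc.

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.sites),) * 2:
            raise ValueError("beta matrix shape does not match site labels")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("beta matrix must be symmetric")
        object.__setattr__(self, "values", v)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.sites), columns=list(self.sites))

    def to_long(self) -> pd.DataFrame:
        rows = []
        n = len(self.sites)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append((self.sites[i], self.sites[j], self.values[i, j]))
        return pd.DataFrame(rows, columns=["site_i", "site_j", "value"])

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.sites), k=1)
        return self.values[iu]


def sorensen(a: Sequence[int], b: Sequence[int]) -> float:
    """Sorensen dissimilarity (b+c)/(2a+b+c) of two binary occurrence rows."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    shared = int((a & b).sum())
    only_a = int((a & ~b).sum())
    only_b = int((b & ~a).sum())
    denom = 2 * shared + only_a + only_b
    if denom == 0:
        return float("nan")
    return (only_a + only_b) / denom


def sorensen_matrix(community: CommunityMatrix) -> BetaMatrix:
    """All pairwise Sorensen dissimilarities (tree-independent)."""
    C = community.values.astype(np.int64)
    shared = C @ C.T
    S = np.diag(shared).astype(float)
    denom = S[:, None] + S[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (denom - 2 * shared) / denom
    np.fill_diagonal(out, np.where(S > 0, 0.0, np.nan))
    return BetaMatrix(community.sites, out, metric="sorensen",
                      aggregation="single-tree")


def _phylosor_values(C: np.ndarray, M: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """PhyloSor dissimilarity for all site pairs, vectorized over pairs.

    ``C``: binary sites x tips; ``M``/``lengths``: tip-edge incidence in the
    same tip order.  Returns a full symmetric matrix (NaN where a site is
    empty).
    """
    C = np.asarray(C, dtype=bool)
    n_sites = C.shape[0]
    Mi = M.astype(np.int64)
    counts = C.astype(np.int64) @ Mi              # per-site tip counts under each edge
    present = counts > 0
    out = np.full((n_sites, n_sites), np.nan)
    np.fill_diagonal(out, np.where(C.sum(axis=1) > 0, 0.0, np.nan))
    iu, ju = np.triu_indices(n_sites, k=1)
    pooled = counts[iu] + counts[ju] - (C[iu] & C[ju]).astype(np.int64) @ Mi
    S_pool = (C[iu] | C[ju]).sum(axis=1)
    ok = (C[iu].any(axis=1)) & (C[ju].any(axis=1))
    # edges on the root-to-pooled-MRCA path carry every pooled tip
    above = pooled == S_pool[:, None]
    bl_a = ((present[iu] & ~above) * lengths).sum(axis=1)
    bl_b = ((present[ju] & ~above) * lengths).sum(axis=1)
    bl_union = (((pooled > 0) & ~above) * lengths).sum(axis=1)
    shared = bl_a + bl_b - bl_union
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = shared / (0.5 * (bl_a + bl_b))
    dis = 1.0 - sim
    dis = np.where(ok, dis, np.nan)
    out[iu, ju] = dis
    out[ju, iu] = dis
    return out


def phylosor(tree: Phylogeny, taxa_a: Sequence[str], taxa_b: Sequence[str]) -> float:
    """PhyloSor dissimilarity between two taxon sets on one tree."""
    order = tree.tip_labels
    pos = {t: i for i, t in enumerate(order)}
    C = np.zeros((2, len(order)), dtype=bool)
    for row, taxa in ((0, taxa_a), (1, taxa_b)):
        for t in taxa:
            if t not in pos:
                raise KeyError(f"taxon not in tree: {t!r}")
            C[row, pos[t]] = True
    M, lengths = tree.edge_structure()
    return float(_phylosor_values(C, M, lengths)[0, 1])


def phylosor_matrix(community: CommunityMatrix, tree: Phylogeny) -> BetaMatrix:
    """All pairwise PhyloSor dissimilarities on one tree."""
    idx = tree.tip_indices(community.taxa)
    M, lengths = tree.edge_structure()
    vals = _phylosor_values(community.values.astype(bool), M[idx], lengths)
    return BetaMatrix(community.sites, vals, metric="phylosor",
                      aggregation="single-tree")


def beta_over_trees(community: CommunityMatrix, trees: TreeSample,
                    summary: str = "median") -> BetaMatrix:
    """PhyloSor summarized across a posterior-like tree sample.

    Computed per tree per pair, then reduced with the configured statistic
    (median by default, mirroring the cross-tree aggregation of the alpha
    SES metrics; mean available).
    """
    if summary not in ("median", "mean"):
        raise ValueError(f"summary must be 'median' or 'mean', got {summary!r}")
    stack = np.stack([phylosor_matrix(community, t).values for t in trees])
    reducer = np.nanmedian if summary == "median" else np.nanmean
    with np.errstate(invalid="ignore"):
        vals = reducer(stack, axis=0)
    return BetaMatrix(community.sites, vals, metric="phylosor",
                      aggregation=f"{summary}-of-{len(trees)}-trees")
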