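"""Per-community (per-site) alpha metrics: S, Faith's PD, MPD, MNTD, VPD.

Conventions, fixed across the pipeline:

* PD is root-excluded: the total branch length of the minimal subtree
  connecting the community's species, rooted at their MRCA, with no edge
  above the MRCA counted.  It is therefore undefined (NaN) for S < 2, as are
  MPD, MNTD and VPD.
* Distances are patristic (branch-length) distances in Ma, never node counts.
* VPD (Lambda+) is the population variance over the S(S-1)/2 unordered
  pairwise distances (denominator = number of pairs) and is reported raw:
  it is insensitive to sampling effort and is never standardized against a
  null model.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .community import CommunityMatrix
from .trees import DistanceMatrix, Phylogeny, cophenetic, subtree_length

__all__ = ["richness", "faith_pd", "mpd", "mntd", "vpd", "compute_alpha"]


def richness(row: Iterable[int]) -> int:
    """Species richness S of one community row."""
    return int(np.asarray(list(row)).sum())


def faith_pd(tree: Phylogeny, taxa: Sequence[str]) -> float:
    """Root-excluded Faith's PD; NaN for fewer than two taxa."""
    taxa = list(taxa)
    if len(taxa) < 2:
        return float("nan")
    return subtree_length(tree, taxa, include_root=False)


def _pair_distances(dist: DistanceMatrix, taxa: Sequence[str]) -> np.ndarray:
    sub = dist.submatrix(list(taxa))
    iu = np.triu_indices(sub.shape[0], k=1)
    return sub[iu]


def mpd(dist: DistanceMatrix, taxa: Sequence[str]) -> float:
    """Mean patristic distance over all unordered pairs of present taxa."""
    if len(taxa) < 2:
        return float("nan")
    return float(_pair_distances(dist, taxa).mean())


def mntd(dist: DistanceMatrix, taxa: Sequence[str]) -> float:
    """Mean distance from each present taxon to its nearest present neighbour."""
    if len(taxa) < 2:
        return float("nan")
    sub = dist.submatrix(list(taxa)).copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def vpd(dist: DistanceMatrix, taxa: Sequence[str]) -> float:
    """Variance of pairwise distances (Lambda+), averaged over pairs."""
    if len(taxa) < 2:
        return float("nan")
    d = _pair_distances(dist, taxa)
    return float(((d - d.mean()) ** 2).mean())


# ---------------------------------------------------------------------------
# vectorized internals shared with the null-model pipelines


def pd_rows(C: np.ndarray, M: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Root-excluded PD for every row of a binary matrix ``C`` (sites x tips).

    ``M``/``lengths`` are the tree's tip-edge incidence structure with tip
    rows ordered like the columns of ``C``.  Rows with S < 2 yield NaN.
    """
    C = np.asarray(C, dtype=bool)
    S = C.sum(axis=1)
    counts = C.astype(np.int64) @ M.astype(np.int64)  # tips under each edge, per site
    union = counts > 0
    on_mrca_path = counts == S[:, None]  # edges carrying every present tip
    out = ((union & ~on_mrca_path) * lengths).sum(axis=1)
    out[S < 2] = np.nan
    return out


def mpd_rows(C: np.ndarray, D: np.ndarray) -> np.ndarray:
    """MPD for every row of ``C`` given the full distance matrix ``D``."""
    C = np.asarray(C, dtype=float)
    S = C.sum(axis=1)
    total = np.einsum("ij,jk,ik->i", C, D, C)  # sums each ordered pair twice
    with np.errstate(invalid="ignore", divide="ignore"):
        out = total / (S * (S - 1.0))
    out[S < 2] = np.nan
    return out


def mntd_rows(C: np.ndarray, D: np.ndarray) -> np.ndarray:
    """MNTD for every row of ``C``."""
    C = np.asarray(C, dtype=bool)
    n_sites = C.shape[0]
    out = np.full(n_sites, np.nan)
    for i in range(n_sites):
        idx = np.flatnonzero(C[i])
        if idx.size < 2:
            continue
        sub = D[np.ix_(idx, idx)].copy()
        np.fill_diagonal(sub, np.inf)
        out[i] = sub.min(axis=1).mean()
    return out


def vpd_rows(C: np.ndarray, D: np.ndarray) -> np.ndarray:
    """VPD (Lambda+) for every row of ``C``: population variance over pairs."""
    C = np.asarray(C, dtype=float)
    S = C.sum(axis=1)
    n_pairs = S * (S - 1.0) / 2.0
    sum_d = np.einsum("ij,jk,ik->i", C, D, C) / 2.0
    sum_d2 = np.einsum("ij,jk,ik->i", C, D * D, C) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sum_d / n_pairs
        out = sum_d2 / n_pairs - mean**2
    out = np.where(np.isnan(out), out, np.maximum(out, 0.0))  # guard fp round-off
    out[S < 2] = np.nan
    return out


METRIC_ROW_FUNCS = {"MPD": mpd_rows, "MNTD": mntd_rows, "VPD": vpd_rows}


def compute_alpha(community: CommunityMatrix, tree: Phylogeny) -> pd.DataFrame:
    """All alpha metrics for every site of an aligned community matrix.

    The cophenetic matrix is computed once for the tree and reused.  Returns
    one row per site with columns S, PD, MPD, MNTD, VPD; metrics undefined at
    S < 2 are NaN.
    """
    order = list(community.taxa)
    idx = tree.tip_indices(order)
    D_full = cophenetic(tree).values[np.ix_(idx, idx)]
    M_full, lengths = tree.edge_structure()
    M = M_full[idx]
    C = community.values.astype(bool)
    return pd.DataFrame(
        {
            "site": list(community.sites),
            "S": C.sum(axis=1).astype(int),
            "PD": pd_rows(C, M, lengths),
            "MPD": mpd_rows(C, D_full),
            "MNTD": mntd_rows(C, D_full),
            "VPD": vpd_rows(C, D_full),
        }
    ).set_index("site", drop=False)
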