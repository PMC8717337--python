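"""Null models and standardized effect sizes (SES).

Two null models, matching their distinct uses:

* **independent swap** for the alpha metrics (PD, MPD, MNTD): repeatedly finds
  a random 2x2 checkerboard submatrix of the occurrence matrix and flips it,
  preserving every site's richness and every species' occupancy exactly.  The
  species pool is all taxa of the aligned matrix.
* **tip shuffle** for phylogenetic beta diversity (SES.PhyloSor): the
  community matrix stays fixed and the tip labels of each phylogeny are
  permuted uniformly at random, preserving topology and branch lengths.

SES = (observed - null mean) / null sd, with the null sd taken over the null
replicates (ddof=1).  Negative SES indicates phylogenetic clustering, positive
overdispersion.  With a posterior-like sample of trees, nulls are generated
independently per tree and per-site SES values are aggregated across trees by
the median (configurable).

Swap effort is counted in *successful* swaps (default 1000 per null matrix,
attempt cap 100 x cells) so mixing is comparable across matrix shapes; all
runs log their effort counters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

from . import alpha as _alpha
from .beta import BetaMatrix, _phylosor_values, beta_over_trees
from .community import CommunityMatrix
from .trees import Phylogeny, TreeSample, cophenetic

logger = logging.getLogger(__name__)

__all__ = [
    "NullConfig",
    "independent_swap",
    "tip_shuffle",
    "ses_alpha_pipeline",
    "ses_phylosor_pipeline",
    "summarize_ses_by_stratum",
    "SESAlphaResult",
    "SESBetaResult",
]

_SEED_MAX = 2**31 - 1


@dataclass
class NullConfig:
    """Configuration of a null-model run.

    n_null_per_tree defaults to 999 for the alpha pipeline (999 random
    communities per phylogeny) and should be set to 10 for the tip-shuffle
    beta pipeline (10 randomizations of each tree).
    """

    model: str = "independent_swap"  # or "tip_shuffle"
    n_null_per_tree: int = 999
    n_swaps: int = 1000              # successful swaps per null matrix
    max_attempts: int | None = None  # default 100 x (rows x cols)
    seed: int = 0
    summary: str = "median"          # cross-tree aggregation: median | mean
    share_nulls: bool = False        # reuse one null set across trees (speed-up)

    def __post_init__(self) -> None:
        if self.model not in ("independent_swap", "tip_shuffle"):
            raise ValueError(f"unknown null model {self.model!r}")
        if self.n_null_per_tree < 1:
            raise ValueError("n_null_per_tree must be >= 1")
        if self.summary not in ("median", "mean"):
            raise ValueError("summary must be 'median' or 'mean'")


@njit(cache=False)
def _swap_kernel(mat, n_target, max_attempts, seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    n_rows, n_cols = mat.shape
    successes = 0
    attempts = 0
    while successes < n_target and attempts < max_attempts:
        attempts += 1
        r1 = np.random.randint(0, n_rows)
        r2 = np.random.randint(0, n_rows)
        c1 = np.random.randint(0, n_cols)
        c2 = np.random.randint(0, n_cols)
        if r1 == r2 or c1 == c2:
            continue
        a = mat[r1, c1]
        d = mat[r2, c2]
        if a == d and mat[r1, c2] == mat[r2, c1] and a != mat[r1, c2]:
            mat[r1, c1] = 1 - a
            mat[r2, c2] = 1 - d
            mat[r1, c2] = a
            mat[r2, c1] = d
            successes += 1
    return successes, attempts


def _swap_array(C: np.ndarray, n_swaps: int, max_attempts: int,
                seed: int) -> tuple[np.ndarray, int, int]:
    out = C.astype(np.int8).copy()
    successes, attempts = _swap_kernel(out, n_swaps, max_attempts, seed)
    return out, int(successes), int(attempts)


def independent_swap(matrix: CommunityMatrix, n_swaps: int = 1000,
                     rng: np.random.Generator | int | None = None,
                     max_attempts: int | None = None) -> CommunityMatrix:
    """One independent-swap randomization of a binary matrix.

    Performs ``n_swaps`` successful checkerboard flips (capped at
    ``max_attempts`` attempts, default 100 x cells); row and column sums are
    preserved exactly.  A matrix with no checkerboard (e.g. perfectly nested)
    is returned unchanged with a logged warning.
    """
    rng = np.random.default_rng(rng)
    if max_attempts is None:
        max_attempts = 100 * matrix.values.size
    seed = int(rng.integers(0, _SEED_MAX))
    out, successes, attempts = _swap_array(matrix.values, n_swaps, max_attempts, seed)
    if successes == 0:
        logger.warning("no checkerboard found in %d attempts; matrix returned unchanged",
                       attempts)
    return CommunityMatrix(matrix.sites, matrix.taxa, out)


def tip_shuffle(tree: Phylogeny, rng: np.random.Generator | int | None = None) -> Phylogeny:
    """Permute tip labels uniformly at random; topology and lengths unchanged."""
    rng = np.random.default_rng(rng)
    labels = list(tree.tip_labels)
    perm = rng.permutation(len(labels))
    mapping = {labels[i]: labels[perm[i]] for i in range(len(labels))}
    return tree.relabeled(mapping)


# ---------------------------------------------------------------------------
# alpha SES pipeline


@dataclass
class SESAlphaResult:
    """Cross-tree summary plus per-tree SES values and effort counters."""

    summary: pd.DataFrame   # site, metric, observed_median, null_mean, null_sd, ses, ...
    per_tree: pd.DataFrame  # tree, site, metric, observed, null_mean, null_sd, ses, rank
    effort: dict


def ses_alpha_pipeline(
    community: CommunityMatrix,
    trees: TreeSample,
    metrics: Sequence[str] = ("PD", "MPD", "MNTD"),
    config: NullConfig | None = None,
) -> SESAlphaResult:
    """SES of PD/MPD/MNTD per site under the independent-swap null.

    For each tree: observed metrics are computed, ``n_null_per_tree``
    swap-randomized matrices are generated and measured, and per-site SES
    values are formed; the final per-site value is the configured cross-tree
    summary (median by default) of the SES values.  The raw observed metric's
    cross-tree median is reported alongside for median-of-raw analyses.
    """
    config = config or NullConfig()
    if config.model != "independent_swap":
        raise ValueError("alpha SES uses the independent_swap model")
    bad = set(metrics) - {"PD", "MPD", "MNTD"}
    if bad:
        raise ValueError(f"unsupported SES metrics: {sorted(bad)} (VPD is never standardized)")

    C = community.values.astype(np.int8)
    n_sites = len(community.sites)
    max_attempts = config.max_attempts or 100 * C.size
    ss = np.random.SeedSequence(config.seed)
    tree_seeds = ss.generate_state(len(trees) * config.n_null_per_tree) % _SEED_MAX
    tree_seeds = tree_seeds.reshape(len(trees), config.n_null_per_tree)

    shared_nulls: list[np.ndarray] | None = None
    if config.share_nulls:
        shared_nulls = [
            _swap_array(C, config.n_swaps, max_attempts, int(s))[0]
            for s in tree_seeds[0]
        ]

    records = []
    swap_successes = swap_attempts = total_nulls = 0
    for t_idx, tree in enumerate(trees):
        idx = tree.tip_indices(community.taxa)
        D = cophenetic(tree).values[np.ix_(idx, idx)]
        M_full, lengths = tree.edge_structure()
        M = M_full[idx]

        def metric_rows(mat: np.ndarray) -> dict[str, np.ndarray]:
            vals = {}
            for m in metrics:
                if m == "PD":
                    vals[m] = _alpha.pd_rows(mat, M, lengths)
                else:
                    vals[m] = _alpha.METRIC_ROW_FUNCS[m](mat, D)
            return vals

        obs = metric_rows(C)
        sums = {m: np.zeros(n_sites) for m in metrics}
        sq_sums = {m: np.zeros(n_sites) for m in metrics}
        below = {m: np.zeros(n_sites) for m in metrics}
        ties = {m: np.zeros(n_sites) for m in metrics}
        n_valid = {m: np.zeros(n_sites) for m in metrics}

        for k in range(config.n_null_per_tree):
            if shared_nulls is not None:
                null_C = shared_nulls[k]
            else:
                null_C, succ, att = _swap_array(C, config.n_swaps, max_attempts,
                                                int(tree_seeds[t_idx, k]))
                swap_successes += succ
                swap_attempts += att
            total_nulls += 1
            null_vals = metric_rows(null_C)
            for m in metrics:
                v = null_vals[m]
                ok = ~np.isnan(v)
                sums[m][ok] += v[ok]
                sq_sums[m][ok] += v[ok] ** 2
                below[m][ok] += (v[ok] < obs[m][ok])
                ties[m][ok] += (v[ok] == obs[m][ok])
                n_valid[m][ok] += 1

        for m in metrics:
            n = n_valid[m]
            with np.errstate(invalid="ignore", divide="ignore"):
                mean = sums[m] / n
                var = (sq_sums[m] - n * mean**2) / (n - 1)
                sd = np.sqrt(np.maximum(var, 0.0))
                ses = (obs[m] - mean) / sd
                rank = (below[m] + 0.5 * ties[m]) / n
            ses = np.where((sd > 0) & ~np.isnan(obs[m]), ses, np.nan)
            for s_idx, site in enumerate(community.sites):
                records.append((t_idx, site, m, obs[m][s_idx], mean[s_idx],
                                sd[s_idx], ses[s_idx], rank[s_idx], int(n[s_idx])))

    per_tree = pd.DataFrame(records, columns=[
        "tree", "site", "metric", "observed", "null_mean", "null_sd",
        "ses", "obs_quantile", "n_null"])
    agg = np.median if config.summary == "median" else np.mean

    def _summ(g: pd.DataFrame) -> pd.Series:
        return pd.Series({
            "observed_median": np.nanmedian(g["observed"]),
            "null_mean": np.nanmedian(g["null_mean"]),
            "null_sd": np.nanmedian(g["null_sd"]),
            "ses": agg(g["ses"].dropna()) if g["ses"].notna().any() else np.nan,
            "obs_quantile": np.nanmedian(g["obs_quantile"]),
            "n_trees": g["tree"].nunique(),
        })

    summary = (per_tree.groupby(["site", "metric"], sort=True)
               .apply(_summ, include_groups=False).reset_index())
    effort = {
        "model": "independent_swap",
        "n_trees": len(trees),
        "n_null_per_tree": config.n_null_per_tree,
        "total_null_matrices": total_nulls,
        "null_matrices_per_tree": total_nulls // len(trees),
        "n_swaps_target": config.n_swaps,
        "swap_successes_total": swap_successes,
        "swap_attempts_total": swap_attempts,
        "share_nulls": config.share_nulls,
        "summary": config.summary,
        "seed": config.seed,
    }
    return SESAlphaResult(summary=summary, per_tree=per_tree, effort=effort)


# ---------------------------------------------------------------------------
# beta SES pipeline (tip shuffle)


@dataclass
class SESBetaResult:
    """Per-pair SES.PhyloSor with formation-stratum tags and effort counters."""

    pairs: pd.DataFrame
    effort: dict


def ses_phylosor_pipeline(
    community: CommunityMatrix,
    trees: TreeSample,
    env: pd.DataFrame | None = None,
    config: NullConfig | None = None,
) -> SESBetaResult:
    """SES of PhyloSor dissimilarity under the tip-shuffle null.

    The observed value per pair is the cross-tree summary (median by default)
    of PhyloSor; the null distribution pools ``n_trees x n_null_per_tree``
    values, each from recomputing PhyloSor after permuting the tip labels of
    one tree (community matrix fixed).  Pairs are tagged with their
    geological-formation stratum when an environment table is given.
    """
    config = config or NullConfig(model="tip_shuffle", n_null_per_tree=10)
    if config.model != "tip_shuffle":
        raise ValueError("SES.PhyloSor uses the tip_shuffle model")

    observed = beta_over_trees(community, trees, summary=config.summary)
    obs = observed.condensed()
    n_pairs = obs.size
    C = community.values.astype(bool)

    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    sums = np.zeros(n_pairs)
    sq_sums = np.zeros(n_pairs)
    n_valid = np.zeros(n_pairs)
    total = 0
    iu, ju = np.triu_indices(len(community.sites), k=1)
    for tree in trees:
        idx = tree.tip_indices(community.taxa)
        M_full, lengths = tree.edge_structure()
        M = M_full[idx]
        for _ in range(config.n_null_per_tree):
            perm = rng.permutation(len(idx))
            vals = _phylosor_values(C, M[perm], lengths)[iu, ju]
            ok = ~np.isnan(vals)
            sums[ok] += vals[ok]
            sq_sums[ok] += vals[ok] ** 2
            n_valid[ok] += 1
            total += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sums / n_valid
        var = (sq_sums - n_valid * mean**2) / (n_valid - 1)
        sd = np.sqrt(np.maximum(var, 0.0))
        ses = (obs - mean) / sd
    ses = np.where((sd > 0) & ~np.isnan(obs), ses, np.nan)

    sites = community.sites
    df = pd.DataFrame({
        "site_i": [sites[i] for i in iu],
        "site_j": [sites[j] for j in ju],
        "observed": obs,
        "null_mean": mean,
        "null_sd": sd,
        "ses": ses,
        "n_null": n_valid.astype(int),
    })
    if env is not None:
        form = env.set_index("site")["formation"].astype(str)
        fi = df["site_i"].map(form)
        fj = df["site_j"].map(form)
        df["stratum"] = [
            f"{a}-{b}" if a <= b else f"{b}-{a}" for a, b in zip(fi, fj)
        ]
        df["within_formation"] = (fi == fj).to_numpy()

    effort = {
        "model": "tip_shuffle",
        "n_trees": len(trees),
        "n_null_per_tree": config.n_null_per_tree,
        "pooled_null_per_pair": int(total),
        "summary": config.summary,
        "seed": config.seed,
    }
    return SESBetaResult(pairs=df, effort=effort)


def summarize_ses_by_stratum(ses_beta: pd.DataFrame) -> pd.DataFrame:
    """Five-number summary of SES.PhyloSor per formation-pair stratum.

    Expects the ``pairs`` table of :func:`ses_phylosor_pipeline` with a
    ``stratum`` column; emits one tidy row per non-empty stratum (3 within +
    3 between for a three-formation design).
    """
    if "stratum" not in ses_beta.columns:
        raise ValueError("pairs table has no stratum tags; pass env to ses_phylosor_pipeline")
    rows = []
    for stratum, g in ses_beta.groupby("stratum", sort=True):
        vals = g["ses"].dropna().to_numpy()
        if vals.size == 0:
            logger.info("stratum %s has no defined SES values; omitted", stratum)
            continue
        q = np.percentile(vals, [0, 25, 50, 75, 100])
        rows.append((stratum, bool(g["within_formation"].iloc[0]), vals.size,
                     *q.tolist()))
    return pd.DataFrame(rows, columns=[
        "stratum", "within_formation", "n_pairs", "min", "q1", "median", "q3", "max"])
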