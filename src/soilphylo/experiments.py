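"""End-to-end validation experiments used by the test suite and the
acceptance checks: metric-oracle comparisons, null-model calibration, and
qualitative scenario-signature recovery.

Every experiment re-runs the pipeline from scratch at a stated (scaled-down)
problem size and returns plain dictionaries of measured quantities.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from . import reference
from .alpha import compute_alpha, faith_pd, mntd, mpd, vpd
from .community import CommunityMatrix
from .gradient import fit_gradient_models, pcoa
from .nulls import NullConfig, independent_swap, ses_alpha_pipeline
from .synthetic import assemble_communities, generate, simulate_tree
from .trees import cophenetic

__all__ = [
    "metric_oracle_error",
    "swap_calibration",
    "scenario_signatures",
    "pcoa_recovery",
]


def metric_oracle_error(n_trees: int = 50, max_tips: int = 8, seed: int = 0) -> dict:
    """Max relative error of PD/MPD/MNTD/VPD against naive reference
    implementations, over random Yule trees and every taxon subset of size >= 2.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    n_checked = 0
    for _ in range(n_trees):
        n_tips = int(rng.integers(4, max_tips + 1))
        tree = simulate_tree(n_tips, crown_age=float(rng.uniform(10, 200)), rng=rng)
        dist = cophenetic(tree)
        labels = tree.tip_labels
        ref_d = reference.ref_cophenetic(tree)  # computed once per tree
        for r in range(2, n_tips + 1):
            for taxa in combinations(labels, r):
                dpairs = [ref_d[(a, b)] for a, b in combinations(taxa, 2)]
                ref_mpd_v = sum(dpairs) / len(dpairs)
                ref_vpd_v = float(np.mean((np.array(dpairs) - ref_mpd_v) ** 2))
                ref_mntd_v = float(np.mean([
                    min(ref_d[(a, b)] for b in taxa if b != a) for a in taxa]))
                pairs = [
                    (faith_pd(tree, taxa), reference.ref_pd(tree, taxa)),
                    (mpd(dist, taxa), ref_mpd_v),
                    (mntd(dist, taxa), ref_mntd_v),
                    (vpd(dist, taxa), ref_vpd_v),
                ]
                for got, want in pairs:
                    scale = max(abs(want), 1.0)
                    worst = max(worst, abs(got - want) / scale)
                    n_checked += 1
    return {"max_rel_error": worst, "n_comparisons": n_checked, "n_trees": n_trees}


def _neutral_base_community(n_sites: int, n_taxa: int,
                            rng: np.random.Generator) -> CommunityMatrix:
    """A margin-heterogeneous binary matrix with no built-in structure."""
    p = rng.uniform(0.2, 0.6, size=n_taxa)
    C = (rng.random((n_sites, n_taxa)) < p[None, :]).astype(np.int8)
    # guarantee S >= 2 everywhere so MPD is defined
    for i in range(n_sites):
        while C[i].sum() < 2:
            C[i, rng.integers(0, n_taxa)] = 1
    sites = tuple(f"T{i + 1:02d}" for i in range(n_sites))
    taxa = tuple(f"sp{j + 1:03d}" for j in range(n_taxa))
    return CommunityMatrix(sites, taxa, C)


def swap_calibration(n_sites: int = 20, n_taxa: int = 30, n_null: int = 199,
                     n_replicates: int = 200, seed: int = 0) -> dict:
    """Type-I calibration of SES.MPD when the data are the null.

    Each replicate community is an independent-swap randomization of a fixed
    base matrix, so the swap null is the true generator; SES.MPD should be
    centred on zero with ~5% of |SES| exceeding 1.96.
    """
    rng = np.random.default_rng(seed)
    tree = simulate_tree(n_taxa, crown_age=100.0, rng=rng)
    base = _neutral_base_community(n_sites, n_taxa, rng)
    from .trees import TreeSample
    trees = TreeSample([tree])
    ses_values = []
    for rep in range(n_replicates):
        comm = independent_swap(base, n_swaps=1000, rng=rng)
        cfg = NullConfig(n_null_per_tree=n_null,
                         seed=int(rng.integers(0, 2**31 - 1)))
        res = ses_alpha_pipeline(comm, trees, metrics=("MPD",), config=cfg)
        ses_values.append(res.summary["ses"].to_numpy())
    ses = np.concatenate(ses_values)
    ses = ses[~np.isnan(ses)]
    return {
        "mean_ses": float(ses.mean()),
        "type1_rate": float((np.abs(ses) > 1.96).mean()),
        "n_values": int(ses.size),
        "n_replicates": n_replicates,
        "n_null": n_null,
    }


def scenario_signatures(seed: int = 1, n_trees: int = 10, n_null: int = 99) -> dict:
    """Direction-only recovery of the built-in scenario signatures.

    fern_like should give a significant positive richness ~ log10(cation)
    slope, palm_like a significant negative one; the clustered scenario a
    negative median SES.MPD on poor-soil (non-Solimoes) sites, more negative
    than the neutral scenario's.
    """
    out: dict = {"seed": seed, "n_trees": n_trees, "n_null": n_null}
    for scen in ("fern_like", "palm_like"):
        ds = generate(scen, seed=seed, n_trees=1)
        alpha = compute_alpha(ds.community, ds.trees[0])
        fit = fit_gradient_models(alpha, ds.env, ["S"]).iloc[0]
        out[f"{scen}_richness_slope"] = float(fit["linear_slope"])
        out[f"{scen}_richness_p"] = float(fit["linear_p"])

    for scen in ("clustered", "neutral"):
        ds = generate(scen, seed=seed, n_trees=n_trees)
        cfg = NullConfig(n_null_per_tree=n_null, seed=seed)
        res = ses_alpha_pipeline(ds.community, ds.trees, metrics=("MPD",),
                                 config=cfg)
        ses = res.summary.set_index("site")["ses"]
        poor = ds.env.loc[ds.env["formation"] != "Solimoes", "site"]
        rich = ds.env.loc[ds.env["formation"] == "Solimoes", "site"]
        out[f"{scen}_median_ses_mpd_poor"] = float(np.nanmedian(ses.loc[poor]))
        out[f"{scen}_median_ses_mpd_rich"] = float(np.nanmedian(ses.loc[rich]))
        out[f"{scen}_mean_ses_mpd"] = float(np.nanmean(ses))
    return out


def pcoa_recovery(n_points: int = 12, seed: int = 0) -> dict:
    """PCoA sanity: Euclidean-input recovery and the eigenvalue-trace identity."""
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n_points, 2))
    D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    ordn = pcoa(D, k=2)
    X = pts - pts.mean(axis=0)
    Y = ordn.scores
    # orthogonal Procrustes: residual after optimal rotation/reflection
    U, _, Vt = np.linalg.svd(X.T @ Y)
    R = U @ Vt
    resid = float(np.abs(X - Y @ R.T).max())
    A = -0.5 * D**2
    J = np.eye(n_points) - 1.0 / n_points
    trace = float(np.trace(J @ A @ J))
    return {
        "procrustes_residual": resid,
        "eigenvalue_sum_minus_trace": float(abs(ordn.eigenvalues.sum() - trace)),
        "n_points": n_points,
    }
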