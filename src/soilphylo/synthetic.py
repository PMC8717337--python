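"""Synthetic study designs: trees, soil gradients, and niche-filtered communities.

The generator emulates a 40-transect inventory design on three geological
strata (9 Solimoes, 12 Ica, 19 terrace sites).  Soil base-cation
concentrations are drawn per stratum from log-normals calibrated to the
field means — 7.59 cmol(+)/kg on Solimoes, 0.16 on Ica, 0.37 on terraces —
with the reported ranges treated as central 95% intervals.  Species carry
Gaussian edaphic niches on the log10-cation axis and communities assemble by
independent Bernoulli filtering:

    P(species s present at site j) = p_max_s * exp(-(x_j - mu_s)^2 / (2 tau_s^2))

Niche optima evolve on a simulated Yule phylogeny either by Brownian motion
(neutral phylogenetic signal) or by a biased two-state poor/rich
substrate-preference character (modelling asymmetric niche shifts between
poor and rich soils), so communities can be phylogenetically clustered by
construction.  Every dataset records its full truth (niche parameters,
states, seed) and regenerates byte-identically from (scenario, seed).

Scenario presets
----------------
fern_like   biased two-state with poor->rich shifts more frequent than the
            reverse, a majority rich-adapted pool and narrow tolerances:
            richness increases with cation concentration.
palm_like   majority poor-adapted pool with broader tolerances and higher
            occupancy: richness decreases with cation concentration.
clustered   a single clade (~30% of tips) is narrowly filtered to poor
            soils against a diffuse background: poor-soil communities are
            phylogenetically clustered (negative SES.MPD).
neutral     optima i.i.d. uniform on the gradient, very broad tolerances:
            no built-in gradient or phylogenetic effect.
"""

from __future__ import annotations

import json
import random
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .community import CommunityMatrix, read_environment, validate_environment
from .trees import Phylogeny, TreeSample, write_newick

__all__ = [
    "NicheModel",
    "SyntheticDataset",
    "STRATUM_CALIBRATION",
    "simulate_tree",
    "simulate_environment",
    "simulate_niche",
    "assemble_communities",
    "jitter_tree_sample",
    "generate",
    "write_dataset",
    "SCENARIOS",
]

# printed stratum statistics: arithmetic mean and range of base-cation
# concentration in cmol(+)/kg, used as (mean, low, high) for calibration
STRATUM_CALIBRATION: dict[str, tuple[float, float, float]] = {
    "Solimoes": (7.59, 2.56, 13.89),
    "Ica": (0.16, 0.11, 0.26),
    "Terrace": (0.37, 0.18, 0.60),
}
DEFAULT_STRATUM_COUNTS = (9, 12, 19)  # Solimoes, Ica, Terrace


@dataclass
class NicheModel:
    """Edaphic niche generator spec, plus the realized per-species table.

    ``table`` (after :func:`simulate_niche`) has one row per species with
    columns taxon, mu (optimum on the log10-cation axis), tau (> 0,
    tolerance), p_max (peak occupancy in (0, 1]) and, for state-based
    generators, state.
    """

    generator: str              # brownian | biased_two_state | clustered_clade | uniform
    params: dict = field(default_factory=dict)
    table: pd.DataFrame | None = None

    def validate_realized(self) -> None:
        t = self.table
        if t is None:
            raise ValueError("niche model is not realized; call simulate_niche")
        if not np.isfinite(t["mu"]).all():
            raise ValueError("non-finite niche optimum")
        if not (t["tau"] > 0).all():
            raise ValueError("niche tolerance must be > 0")
        if not ((t["p_max"] > 0) & (t["p_max"] <= 1)).all():
            raise ValueError("p_max must be in (0, 1]")


@dataclass
class SyntheticDataset:
    tree: Phylogeny
    trees: TreeSample
    community: CommunityMatrix
    env: pd.DataFrame
    niche: NicheModel
    truth: dict


# ---------------------------------------------------------------------------
# trees


def simulate_tree(n_tips: int, crown_age: float,
                  rng: np.random.Generator | int | None = None) -> Phylogeny:
    """Pure-birth (Yule) tree, ultrametric, rescaled so crown depth = crown_age."""
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = np.random.default_rng(rng)
    if n_tips == 2:  # crown tree of two tips is a cherry of depth crown_age
        from .trees import read_newick
        return read_newick(f"(sp001:{crown_age},sp002:{crown_age});")[0]
    pyrng = random.Random(int(rng.integers(0, 2**31 - 1)))
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_tips, rng=pyrng)
    tree.seed_node.edge.length = None
    # name tips deterministically in leaf-traversal order
    tree.taxon_namespace = dendropy.TaxonNamespace()
    width = max(3, len(str(n_tips)))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = tree.taxon_namespace.new_taxon(label=f"sp{i:0{width}d}")
    depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    scale = crown_age / depth
    for nd in tree.preorder_node_iter():
        if nd.edge.length is not None:
            nd.edge.length *= scale
    return Phylogeny(tree)


def jitter_tree_sample(tree: Phylogeny, n_trees: int, cv: float = 0.1,
                       rng: np.random.Generator | int | None = None) -> TreeSample:
    """Posterior-like sample: per-branch log-normal length noise, mean 1, fixed topology."""
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = np.random.default_rng(rng)
    if cv == 0:
        return TreeSample([tree] * n_trees)
    sigma = np.sqrt(np.log1p(cv**2))
    mu = -(sigma**2) / 2.0  # E[lognormal] = 1
    draws = []
    for _ in range(n_trees):
        clone = tree.dendropy_tree.clone(depth=1)
        for nd in clone.preorder_node_iter():
            if nd.edge.length is not None:
                nd.edge.length *= float(rng.lognormal(mu, sigma))
        draws.append(Phylogeny(clone))
    return TreeSample(draws)


# ---------------------------------------------------------------------------
# environment


def _lognormal_params(mean: float, low: float, high: float) -> tuple[float, float]:
    """(mu, sigma) of the underlying normal: sigma from the range as a central
    95% interval, mu so the arithmetic mean is exact."""
    sigma = np.log(high / low) / (2 * 1.959963984540054)
    mu = np.log(mean) - sigma**2 / 2.0
    return mu, sigma


def simulate_environment(
    counts: Sequence[int] = DEFAULT_STRATUM_COUNTS,
    rng: np.random.Generator | int | None = None,
    covariates: bool = True,
) -> pd.DataFrame:
    """Per-site soil table for (n_solimoes, n_ica, n_terrace) transects.

    Base-cation concentrations are log-normal per stratum (see module
    docstring).  Optional covariates phosphorus (mg/kg), aluminum
    (cmol(+)/kg) and pH are noisy monotone functions of the cation axis so
    ordination arrows are exercised; they carry no independent truth.
    """
    n_sol, n_ica, n_ter = counts
    rng = np.random.default_rng(rng)
    rows: list[tuple[str, float, str]] = []
    i = 0
    for formation, n in (("Solimoes", n_sol), ("Ica", n_ica), ("Terrace", n_ter)):
        mu, sigma = _lognormal_params(*STRATUM_CALIBRATION[formation])
        vals = rng.lognormal(mu, sigma, size=n)
        for v in vals:
            i += 1
            rows.append((f"T{i:02d}", float(v), formation))
    df = pd.DataFrame(rows, columns=["site", "base_cation", "formation"])
    if covariates and len(df):
        x = np.log10(df["base_cation"].to_numpy())
        df["phosphorus"] = 10 ** (0.75 + 0.25 * x + rng.normal(0, 0.10, len(df)))
        df["aluminum"] = np.exp(0.8 - 0.6 * x + rng.normal(0, 0.20, len(df)))
        df["pH"] = 4.5 + 0.7 * x + rng.normal(0, 0.15, len(df))
    return validate_environment(df) if len(df) else df.set_index("site", drop=False)


# ---------------------------------------------------------------------------
# niches


def _brownian_tip_values(tree: Phylogeny, sigma2: float, root_value: float,
                         rng: np.random.Generator) -> dict[str, float]:
    vals: dict[int, float] = {}
    tips: dict[str, float] = {}
    dtree = tree.dendropy_tree
    vals[id(dtree.seed_node)] = root_value
    for nd in dtree.preorder_node_iter():
        if nd is dtree.seed_node:
            continue
        parent = vals[id(nd.parent_node)]
        step = rng.normal(0.0, np.sqrt(sigma2 * nd.edge.length)) if sigma2 > 0 else 0.0
        vals[id(nd)] = parent + step
        if nd.is_leaf():
            tips[nd.taxon.label] = vals[id(nd)]
    return tips


def _two_state_tip_states(tree: Phylogeny, q_pr: float, q_rp: float,
                          root_state: str, rng: np.random.Generator) -> dict[str, str]:
    """Binary poor/rich character evolving by a CTMC along branches."""
    rates = {"poor": q_pr, "rich": q_rp}
    flip = {"poor": "rich", "rich": "poor"}
    states: dict[int, str] = {}
    tips: dict[str, str] = {}
    dtree = tree.dendropy_tree
    states[id(dtree.seed_node)] = root_state
    for nd in dtree.preorder_node_iter():
        if nd is dtree.seed_node:
            continue
        s = states[id(nd.parent_node)]
        t = 0.0
        length = nd.edge.length
        while True:
            rate = rates[s]
            if rate <= 0:
                break
            t += rng.exponential(1.0 / rate)
            if t >= length:
                break
            s = flip[s]
        states[id(nd)] = s
        if nd.is_leaf():
            tips[nd.taxon.label] = s
    return tips


def simulate_niche(tree: Phylogeny, model: NicheModel,
                   rng: np.random.Generator | int | None = None) -> NicheModel:
    """Realize per-species niche parameters on the tree.

    Generators:

    * ``brownian``: mu evolves by Brownian motion (params: sigma2,
      root_value, tau, p_max).
    * ``biased_two_state``: a poor/rich preference state evolves with rates
      q_pr (poor->rich) and q_rp; mu is drawn from the state-conditional
      normal (params also: root_state, mu_poor, mu_rich, sd_poor, sd_rich,
      tau or tau_poor/tau_rich, p_max).
    * ``clustered_clade``: the clade closest to ``clade_fraction`` of the
      tips gets a narrow poor-soil niche; the rest a diffuse one.
    * ``uniform``: mu i.i.d. uniform on (mu_low, mu_high), no phylogenetic
      structure.
    """
    rng = np.random.default_rng(rng)
    p = model.params
    labels = list(tree.tip_labels)
    if model.generator == "brownian":
        tips = _brownian_tip_values(tree, p["sigma2"], p.get("root_value", 0.0), rng)
        table = pd.DataFrame({
            "taxon": labels,
            "mu": [tips[l] for l in labels],
            "tau": p["tau"],
            "p_max": p["p_max"],
        })
    elif model.generator == "biased_two_state":
        states = _two_state_tip_states(tree, p["q_pr"], p["q_rp"],
                                       p.get("root_state", "poor"), rng)
        mu_of = {"poor": (p["mu_poor"], p.get("sd_poor", 0.2)),
                 "rich": (p["mu_rich"], p.get("sd_rich", 0.2))}
        tau_of = {"poor": p.get("tau_poor", p.get("tau", 0.5)),
                  "rich": p.get("tau_rich", p.get("tau", 0.5))}
        st = [states[l] for l in labels]
        table = pd.DataFrame({
            "taxon": labels,
            "mu": [rng.normal(*mu_of[s]) for s in st],
            "tau": [tau_of[s] for s in st],
            "p_max": p["p_max"],
            "state": st,
        })
    elif model.generator == "clustered_clade":
        frac = p.get("clade_fraction", 0.3)
        lo = max(2, round(0.85 * frac * len(labels)))
        hi = max(lo, round(1.3 * frac * len(labels)))
        # among clades in the size band, take the youngest (tightest-knit)
        # MRCA so its members are markedly closer than random taxon sets;
        # age is normalized by clade size so small clades are not favoured
        best, best_score = None, None
        dtree = tree.dendropy_tree
        for nd in dtree.preorder_internal_node_iter():
            if nd is dtree.seed_node:
                continue
            size = len(nd.leaf_nodes())
            if lo <= size <= hi:
                age = max(lf.distance_from_root() for lf in nd.leaf_nodes()) \
                    - nd.distance_from_root()
                score = age / np.log(size)  # Yule crown age grows ~ log(size)
                if best is None or score < best_score:
                    best, best_score = nd, score
        if best is None:  # no clade in band: fall back to closest size
            target = frac * len(labels)
            best = min((nd for nd in dtree.preorder_internal_node_iter()
                        if nd is not dtree.seed_node
                        and 2 <= len(nd.leaf_nodes()) < len(labels)),
                       key=lambda nd: abs(len(nd.leaf_nodes()) - target))
        clade = {lf.taxon.label for lf in best.leaf_nodes()}
        in_clade = np.array([l in clade for l in labels])
        table = pd.DataFrame({
            "taxon": labels,
            "mu": np.where(in_clade,
                           rng.normal(p["clade_mu"], p.get("clade_mu_sd", 0.1),
                                      len(labels)),
                           p.get("bg_mu", 0.0)),
            "tau": np.where(in_clade, p["clade_tau"], p["bg_tau"]),
            "p_max": np.where(in_clade, p["clade_p_max"], p["bg_p_max"]),
            "state": np.where(in_clade, "clade", "background"),
        })
    elif model.generator == "uniform":
        table = pd.DataFrame({
            "taxon": labels,
            "mu": rng.uniform(p.get("mu_low", -1.2), p.get("mu_high", 1.2),
                              len(labels)),
            "tau": p["tau"],
            "p_max": p["p_max"],
        })
    else:
        raise ValueError(f"unknown niche generator {model.generator!r}")
    realized = NicheModel(generator=model.generator, params=dict(p), table=table)
    realized.validate_realized()
    return realized


def assemble_communities(env: pd.DataFrame, niche: NicheModel,
                         rng: np.random.Generator | int | None = None) -> CommunityMatrix:
    """Niche-filtered assembly: independent Bernoulli presence per species x site.

    All-empty sites are retained (they carry missing metrics downstream).
    """
    niche.validate_realized()
    rng = np.random.default_rng(rng)
    x = np.log10(env["base_cation"].to_numpy(dtype=float))
    t = niche.table
    mu = t["mu"].to_numpy()
    tau = t["tau"].to_numpy(dtype=float)
    p_max = t["p_max"].to_numpy(dtype=float)
    P = p_max[None, :] * np.exp(-((x[:, None] - mu[None, :]) ** 2)
                                / (2.0 * tau[None, :] ** 2))
    draws = (rng.random(P.shape) < P).astype(np.int8)
    return CommunityMatrix(tuple(env["site"]), tuple(t["taxon"]), draws)


def presence_probabilities(env: pd.DataFrame, niche: NicheModel) -> np.ndarray:
    """Deterministic site x species presence probabilities (the assembly kernel)."""
    x = np.log10(env["base_cation"].to_numpy(dtype=float))
    t = niche.table
    return (t["p_max"].to_numpy()[None, :]
            * np.exp(-((x[:, None] - t["mu"].to_numpy()[None, :]) ** 2)
                     / (2.0 * t["tau"].to_numpy(dtype=float)[None, :] ** 2)))


# ---------------------------------------------------------------------------
# scenarios

SCENARIOS: dict[str, dict] = {
    "fern_like": dict(
        n_tips=140, crown_age=330.0,
        niche=NicheModel("biased_two_state", dict(
            q_pr=0.012, q_rp=0.003, root_state="poor",
            mu_poor=-0.7, sd_poor=0.20, mu_rich=0.9, sd_rich=0.15,
            tau=0.35, p_max=0.4)),
    ),
    "palm_like": dict(
        n_tips=60, crown_age=106.0,
        niche=NicheModel("biased_two_state", dict(
            q_pr=0.008, q_rp=0.05, root_state="poor",
            mu_poor=-0.6, sd_poor=0.25, mu_rich=0.8, sd_rich=0.20,
            tau=0.6, p_max=0.6)),
    ),
    "clustered": dict(
        n_tips=60, crown_age=100.0,
        niche=NicheModel("clustered_clade", dict(
            clade_fraction=0.3, clade_mu=-0.65, clade_mu_sd=0.10,
            clade_tau=0.3, clade_p_max=0.8,
            bg_mu=0.5, bg_tau=1.0, bg_p_max=0.3)),
    ),
    "neutral": dict(
        n_tips=60, crown_age=100.0,
        niche=NicheModel("uniform", dict(mu_low=-1.2, mu_high=1.2,
                                         tau=6.0, p_max=0.35)),
    ),
}


def generate(scenario: str, seed: int, n_trees: int = 100,
             branch_cv: float = 0.1,
             stratum_counts: Sequence[int] = DEFAULT_STRATUM_COUNTS) -> SyntheticDataset:
    """Build a fully aligned synthetic dataset for a named scenario.

    Deterministic in (scenario, seed): two calls regenerate byte-identical
    trees, occurrences, environment and truth.
    """
    if scenario not in SCENARIOS:
        raise ValueError(
            f"unknown scenario {scenario!r}; valid: {sorted(SCENARIOS)}")
    cfg = SCENARIOS[scenario]
    scen_key = zlib.crc32(scenario.encode()) % 2**31  # stable across processes
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(scen_key,))
    r_tree, r_env, r_niche, r_comm, r_jitter = (
        np.random.default_rng(s) for s in ss.spawn(5))
    tree = simulate_tree(cfg["n_tips"], cfg["crown_age"], r_tree)
    env = simulate_environment(stratum_counts, r_env)
    niche = simulate_niche(tree, cfg["niche"], r_niche)
    community = assemble_communities(env, niche, r_comm)
    trees = jitter_tree_sample(tree, n_trees, branch_cv, r_jitter)
    truth = {
        "scenario": scenario,
        "seed": int(seed),
        "n_trees": int(n_trees),
        "branch_cv": float(branch_cv),
        "stratum_counts": list(stratum_counts),
        "tree": {"n_tips": cfg["n_tips"], "crown_age": cfg["crown_age"]},
        "niche_generator": cfg["niche"].generator,
        "niche_params": cfg["niche"].params,
        "niche_table": niche.table.to_dict(orient="list"),
    }
    return SyntheticDataset(tree=tree, trees=trees, community=community,
                            env=env, niche=niche, truth=truth)


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> Path:
    """Write trees.nwk, community.csv, environment.csv, truth.json, manifest.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_newick(ds.trees, outdir / "trees.nwk")
    ds.community.to_frame().to_csv(outdir / "community.csv", index_label="site")
    ds.env.reset_index(drop=True).to_csv(outdir / "environment.csv", index=False)
    (outdir / "truth.json").write_text(json.dumps(ds.truth, indent=1))
    manifest = {k: ds.truth[k] for k in
                ("scenario", "seed", "n_trees", "branch_cv", "stratum_counts")}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir
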