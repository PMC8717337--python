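"""Synthetic-data generator: design fidelity, niche evolution, reproducibility."""

import json

import numpy as np
import pytest

from soilphylo import cophenetic
from soilphylo.synthetic import (NicheModel, SCENARIOS, assemble_communities,
                                 generate, jitter_tree_sample,
                                 presence_probabilities, simulate_environment,
                                 simulate_niche, simulate_tree, write_dataset)


class TestSimulateTree:
    def test_two_tip_cherry(self):
        tree = simulate_tree(2, crown_age=100.0, rng=0)
        d = cophenetic(tree)
        assert d.values[0, 1] == pytest.approx(200.0)

    @pytest.mark.parametrize("n,age", [(10, 50.0), (60, 106.0)])
    def test_crown_depth_exact(self, n, age):
        tree = simulate_tree(n, crown_age=age, rng=1)
        depths = [lf.distance_from_root()
                  for lf in tree.dendropy_tree.leaf_node_iter()]
        assert max(depths) == pytest.approx(age, abs=1e-9)
        assert min(depths) == pytest.approx(age, abs=1e-6)  # ultrametric

    def test_tip_count_and_unique_labels(self):
        tree = simulate_tree(60, crown_age=106.0, rng=2)
        assert tree.n_tips == 60
        assert len(set(tree.tip_labels)) == 60


class TestSimulateEnvironment:
    def test_default_design_counts(self):
        env = simulate_environment(rng=0)
        assert len(env) == 40
        counts = env["formation"].value_counts()
        assert counts["Solimoes"] == 9
        assert counts["Ica"] == 12
        assert counts["Terrace"] == 19

    def test_partial_design(self):
        env = simulate_environment((0, 0, 5), rng=1)
        assert len(env) == 5
        assert (env["formation"] == "Terrace").all()

    def test_solimoes_mean_converges(self):
        env = simulate_environment((10_000, 0, 0), rng=3)
        assert env["base_cation"].mean() == pytest.approx(7.59, abs=0.3)

    def test_ranges_roughly_central_95(self):
        env = simulate_environment((0, 10_000, 0), rng=4)
        inside = env["base_cation"].between(0.11, 0.26).mean()
        assert 0.85 < inside < 0.999


class TestNiche:
    def test_brownian_zero_rate_constant(self):
        tree = simulate_tree(10, crown_age=50.0, rng=0)
        model = NicheModel("brownian", dict(sigma2=0.0, root_value=0.3,
                                            tau=1.0, p_max=0.5))
        realized = simulate_niche(tree, model, rng=1)
        assert np.allclose(realized.table["mu"], 0.3)

    def test_brownian_signal_sisters_closer(self):
        """BM variance grows with independent path length: close relatives get
        closer optima on average than distant ones."""
        rng = np.random.default_rng(5)
        tree = simulate_tree(40, crown_age=100.0, rng=rng)
        model = NicheModel("brownian", dict(sigma2=0.01, root_value=0.0,
                                            tau=1.0, p_max=0.5))
        D = cophenetic(tree)
        diffs, dists = [], []
        for rep in range(20):
            realized = simulate_niche(tree, model, rng=rng)
            mu = realized.table.set_index("taxon")["mu"]
            labs = list(D.labels)
            for i in range(0, len(labs) - 1, 2):
                a, b = labs[i], labs[i + 1]
                diffs.append((mu[a] - mu[b]) ** 2)
                dists.append(D.values[i, i + 1])
        diffs, dists = np.array(diffs), np.array(dists)
        near = diffs[dists < np.median(dists)].mean()
        far = diffs[dists >= np.median(dists)].mean()
        assert near < far

    def test_biased_two_state_concentrates_poor_tips(self):
        """With rare rich->poor reversals from a poor root, poor tips cluster
        into few clades (checked against direct Markov-chain expectations)."""
        rng = np.random.default_rng(6)
        tree = simulate_tree(80, crown_age=300.0, rng=rng)
        model = NicheModel("biased_two_state", dict(
            q_pr=0.01, q_rp=0.0005, root_state="poor",
            mu_poor=-0.7, mu_rich=0.9, tau=0.4, p_max=0.5))
        realized = simulate_niche(tree, model, rng=rng)
        states = realized.table.set_index("taxon")["state"]
        assert (states == "rich").mean() > 0.5  # strong poor->rich bias
        # poor tips should be phylogenetically clumped: mean pairwise distance
        # among poor tips below that of random same-sized tip sets
        poor = [t for t, s in states.items() if s == "poor"]
        if len(poor) >= 3:
            D = cophenetic(tree)
            obs = D.submatrix(poor)[np.triu_indices(len(poor), 1)].mean()
            rand_means = []
            labs = list(tree.tip_labels)
            for _ in range(200):
                pick = rng.choice(labs, size=len(poor), replace=False)
                rand_means.append(
                    D.submatrix(list(pick))[np.triu_indices(len(poor), 1)].mean())
            assert obs < np.percentile(rand_means, 25)


class TestAssembly:
    def _setup(self):
        tree = simulate_tree(30, crown_age=100.0, rng=0)
        env = simulate_environment(rng=0)
        return tree, env

    def test_infinite_tolerance_gives_pmax_everywhere(self):
        tree, env = self._setup()
        model = NicheModel("uniform", dict(mu_low=-1, mu_high=1, tau=1e9,
                                           p_max=0.4))
        realized = simulate_niche(tree, model, rng=1)
        P = presence_probabilities(env, realized)
        assert np.allclose(P, 0.4)

    def test_probability_pmax_at_optimum(self):
        tree, env = self._setup()
        model = NicheModel("uniform", dict(mu_low=-1, mu_high=1, tau=0.5,
                                           p_max=0.7))
        realized = simulate_niche(tree, model, rng=2)
        realized.table.loc[0, "mu"] = np.log10(env["base_cation"].iloc[0])
        P = presence_probabilities(env, realized)
        assert P[0, 0] == pytest.approx(0.7)

    def test_observed_richness_matches_analytic_expectation(self):
        tree, env = self._setup()
        model = NicheModel("uniform", dict(mu_low=-1, mu_high=1, tau=0.6,
                                           p_max=0.5))
        realized = simulate_niche(tree, model, rng=3)
        P = presence_probabilities(env, realized)
        expected = P.sum(axis=1)
        rng = np.random.default_rng(4)
        reps = np.array([assemble_communities(env, realized, rng).richness
                         for _ in range(200)], dtype=float)
        se = np.sqrt((P * (1 - P)).sum(axis=1) / 200)
        assert (np.abs(reps.mean(axis=0) - expected) <= 3 * se + 1e-9).all()


class TestJitter:
    def test_cv_zero_identical_copies(self, toy5):
        sample = jitter_tree_sample(toy5, 4, cv=0.0, rng=0)
        assert len(sample) == 4
        assert all(t.total_branch_length() == toy5.total_branch_length()
                   for t in sample)

    def test_topology_preserved(self, toy5):
        sample = jitter_tree_sample(toy5, 5, cv=0.2, rng=1)
        for t in sample:
            # same bipartitions: pruning to any pair preserves relative order
            assert set(t.tip_labels) == set(toy5.tip_labels)
            assert t.dendropy_tree.as_string(schema="newick").count("(") == \
                toy5.dendropy_tree.as_string(schema="newick").count("(")

    def test_mean_branch_length_preserved(self, toy5):
        sample = jitter_tree_sample(toy5, 1000, cv=0.1, rng=2)
        totals = np.array([t.total_branch_length() for t in sample])
        assert totals.mean() == pytest.approx(toy5.total_branch_length(), rel=0.02)


class TestGenerate:
    def test_unknown_scenario_lists_valid_names(self):
        with pytest.raises(ValueError, match="fern_like"):
            generate("no_such_scenario", seed=0)

    def test_byte_identical_regeneration(self, tmp_path):
        d1 = write_dataset(generate("clustered", seed=9, n_trees=3), tmp_path / "a")
        d2 = write_dataset(generate("clustered", seed=9, n_trees=3), tmp_path / "b")
        for name in ("trees.nwk", "community.csv", "environment.csv", "truth.json"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_dataset_aligned_and_truth_sufficient(self):
        ds = generate("neutral", seed=2, n_trees=3)
        assert set(ds.community.taxa) == set(ds.tree.tip_labels)
        assert list(ds.community.sites) == list(ds.env["site"])
        assert ds.truth["scenario"] == "neutral"
        assert len(ds.truth["niche_table"]["mu"]) == len(ds.community.taxa)

    def test_single_formation_exclusivity_fern_exceeds_palm(self):
        """Narrow fern-like niches produce more single-formation specialists."""
        def exclusive_fraction(ds):
            occ = ds.community.to_frame()
            form = ds.env["formation"]
            per_form = occ.groupby(form, observed=True).any()
            observed = occ.any(axis=0)
            return (per_form.sum(axis=0)[observed] == 1).mean()
        fern = exclusive_fraction(generate("fern_like", seed=5, n_trees=1))
        palm = exclusive_fraction(generate("palm_like", seed=5, n_trees=1))
        assert fern > palm
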