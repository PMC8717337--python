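"""Null models: swap invariants, shuffle uniformity, SES pipelines, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from soilphylo import (CommunityMatrix, NullConfig, cophenetic,
                       independent_swap, ses_alpha_pipeline,
                       ses_phylosor_pipeline, summarize_ses_by_stratum,
                       tip_shuffle)
from soilphylo.synthetic import generate, simulate_tree
from soilphylo.trees import TreeSample


class TestIndependentSwap:
    def test_only_move_on_2x2_checkerboard(self):
        comm = CommunityMatrix(("r1", "r2"), ("c1", "c2"),
                               np.array([[1, 0], [0, 1]]))
        out = independent_swap(comm, n_swaps=1, rng=0)
        assert np.array_equal(out.values, np.array([[0, 1], [1, 0]]))

    @pytest.mark.parametrize("seed", range(5))
    def test_margins_preserved_exactly(self, seed, small_dataset):
        comm = small_dataset.community
        out = independent_swap(comm, n_swaps=500, rng=seed)
        assert np.array_equal(out.values.sum(axis=0), comm.values.sum(axis=0))
        assert np.array_equal(out.values.sum(axis=1), comm.values.sum(axis=1))

    def test_nested_matrix_returned_unchanged_with_warning(self, caplog):
        # perfectly nested: no 2x2 checkerboard exists
        nested = CommunityMatrix(("r1", "r2", "r3"), ("c1", "c2", "c3"),
                                 np.array([[1, 1, 1], [1, 1, 0], [1, 0, 0]]))
        with caplog.at_level("WARNING"):
            out = independent_swap(nested, n_swaps=10, rng=1, max_attempts=2000)
        assert np.array_equal(out.values, nested.values)
        assert any("no checkerboard" in r.message for r in caplog.records)

    def test_long_run_uniform_over_reachable_states(self):
        """On a small instance the swap chain visits reachable states uniformly.

        Successful-swap counts of mixed parity are used: with a fixed count
        the two-state chain would alternate deterministically.
        """
        start = np.array([[1, 0], [0, 1], [1, 1]], dtype=np.int8)
        comm = CommunityMatrix(("r1", "r2", "r3"), ("c1", "c2"), start)
        # enumerate the swap graph: binary 3x2 matrices with same margins
        from itertools import product
        margins_r, margins_c = start.sum(1), start.sum(0)
        states = [np.array(m, dtype=np.int8).reshape(3, 2)
                  for m in product([0, 1], repeat=6)
                  if (np.array(m).reshape(3, 2).sum(1) == margins_r).all()
                  and (np.array(m).reshape(3, 2).sum(0) == margins_c).all()]
        keys = {arr.tobytes() for arr in states}
        assert len(keys) == 2  # the two checkerboard states
        counts = {k: 0 for k in keys}
        rng = np.random.default_rng(42)
        n_draws = 3000
        for _ in range(n_draws):
            n_swaps = 10 + int(rng.random() < 0.5)
            out = independent_swap(comm, n_swaps=n_swaps, rng=rng)
            counts[out.values.tobytes()] += 1
        observed = np.array(list(counts.values()))
        assert (observed > 0).all()
        chi2 = stats.chisquare(observed).pvalue
        assert chi2 > 1e-4  # not grossly non-uniform


class TestTipShuffle:
    def test_distances_multiset_invariant(self, toy5):
        before = np.sort(cophenetic(toy5).values, axis=None)
        after = np.sort(cophenetic(tip_shuffle(toy5, rng=0)).values, axis=None)
        assert np.allclose(before, after)

    def test_topology_and_lengths_unchanged(self, toy5):
        shuffled = tip_shuffle(toy5, rng=1)
        assert shuffled.total_branch_length() == pytest.approx(
            toy5.total_branch_length())
        assert set(shuffled.tip_labels) == set(toy5.tip_labels)

    def test_permutations_approximately_uniform(self):
        tree = simulate_tree(3, crown_age=10.0, rng=0)
        counts: dict[tuple, int] = {}
        rng = np.random.default_rng(7)
        n = 6000
        for _ in range(n):
            labels = tuple(tip_shuffle(tree, rng=rng).tip_labels)
            counts[labels] = counts.get(labels, 0) + 1
        assert len(counts) == 6
        p = stats.chisquare(list(counts.values())).pvalue
        assert p > 1e-4


class TestSESAlpha:
    def test_single_tree_summary_equals_per_tree(self, small_dataset):
        ds = small_dataset
        trees = TreeSample([ds.trees[0]])
        cfg = NullConfig(n_null_per_tree=49, seed=5)
        res = ses_alpha_pipeline(ds.community, trees, metrics=("MPD",), config=cfg)
        merged = res.summary.merge(res.per_tree, on=["site", "metric"])
        ok = merged["ses_x"].notna()
        assert np.allclose(merged.loc[ok, "ses_x"], merged.loc[ok, "ses_y"])

    def test_effort_counters(self, small_dataset):
        ds = small_dataset
        cfg = NullConfig(n_null_per_tree=7, seed=2)
        trees = TreeSample([ds.trees[0], ds.trees[1]])
        res = ses_alpha_pipeline(ds.community, trees, metrics=("MPD",), config=cfg)
        assert res.effort["null_matrices_per_tree"] == 7
        assert res.effort["total_null_matrices"] == 14

    def test_null_generated_community_has_small_median_ses(self):
        """Communities produced by the swap null itself are calibrated: SES
        centred on zero (|median| < 0.2 at 199 nulls, 20 sites, pooled over
        10 replicate communities to average out site-level noise)."""
        rng = np.random.default_rng(11)
        tree = simulate_tree(25, crown_age=100.0, rng=rng)
        p = rng.uniform(0.2, 0.6, 25)
        C = (rng.random((20, 25)) < p).astype(np.int8)
        C[:, 0] = 1  # avoid S<2 rows
        C[:, 1] = 1
        base = CommunityMatrix(tuple(f"t{i}" for i in range(20)),
                               tree.tip_labels, C)
        pooled = []
        for rep in range(10):
            comm = independent_swap(base, n_swaps=2000, rng=rng)
            cfg = NullConfig(n_null_per_tree=199,
                             seed=int(rng.integers(0, 2**31 - 1)))
            res = ses_alpha_pipeline(comm, TreeSample([tree]), metrics=("MPD",),
                                     config=cfg)
            pooled.append(res.summary["ses"].to_numpy())
        assert abs(np.nanmedian(np.concatenate(pooled))) < 0.2

    def test_vpd_never_standardized(self, small_dataset):
        with pytest.raises(ValueError, match="VPD"):
            ses_alpha_pipeline(small_dataset.community, small_dataset.trees,
                               metrics=("VPD",))

    def test_deterministic_given_seed(self, small_dataset):
        ds = small_dataset
        trees = TreeSample([ds.trees[0]])
        cfg = NullConfig(n_null_per_tree=19, seed=21)
        r1 = ses_alpha_pipeline(ds.community, trees, metrics=("MPD", "PD"), config=cfg)
        r2 = ses_alpha_pipeline(ds.community, trees, metrics=("MPD", "PD"), config=cfg)
        pd.testing.assert_frame_equal(r1.summary, r2.summary)
        assert r1.summary.to_csv() == r2.summary.to_csv()  # byte-identical

    def test_clustered_more_negative_than_neutral(self):
        """Single-clade filtering yields clustering the neutral scenario lacks."""
        vals = {}
        for scen in ("clustered", "neutral"):
            ds = generate(scen, seed=3, n_trees=3)
            cfg = NullConfig(n_null_per_tree=49, seed=3)
            res = ses_alpha_pipeline(ds.community, ds.trees, metrics=("MPD",),
                                     config=cfg)
            ses = res.summary.set_index("site")["ses"]
            poor = ds.env.loc[ds.env["formation"] != "Solimoes", "site"]
            vals[scen] = float(np.nanmedian(ses.loc[poor]))
        assert vals["clustered"] < 0
        assert vals["clustered"] < vals["neutral"]


class TestSESPhylosor:
    def test_pooled_null_count(self, small_dataset):
        ds = small_dataset
        cfg = NullConfig(model="tip_shuffle", n_null_per_tree=4, seed=1)
        res = ses_phylosor_pipeline(ds.community, ds.trees, env=ds.env, config=cfg)
        assert res.effort["pooled_null_per_pair"] == 4 * len(ds.trees)
        assert (res.pairs["n_null"] == 4 * len(ds.trees)).all()

    def test_sister_replacement_pairs_get_negative_ses(self):
        """Two sites whose unshared species are each other's sisters share far
        more branch length than random labelings allow: strongly negative
        SES.PhyloSor.  Fully identical sites are degenerate (null sd 0, SES
        missing) since no relabeling can change a zero dissimilarity."""
        tree = simulate_tree(30, crown_age=100.0, rng=5)
        D = cophenetic(tree)
        vals = D.values.copy()
        np.fill_diagonal(vals, np.inf)
        nn = vals.argmin(axis=1)
        sisters = sorted({tuple(sorted((i, int(nn[i]))))
                          for i in range(30) if nn[int(nn[i])] == i})[:4]
        C = np.zeros((3, 30), dtype=np.int8)
        for i, j in sisters:
            C[0, i] = 1
            C[1, j] = 1
        C[2] = C[0]
        comm = CommunityMatrix(("a", "b", "c"), tree.tip_labels, C)
        cfg = NullConfig(model="tip_shuffle", n_null_per_tree=40, seed=9)
        res = ses_phylosor_pipeline(comm, TreeSample([tree] * 5), config=cfg)
        pairs = res.pairs.set_index(["site_i", "site_j"])
        near = pairs.loc[("a", "b")]
        assert near["observed"] < near["null_mean"]
        assert near["ses"] < -1.0
        identical = pairs.loc[("a", "c")]
        assert identical["observed"] == pytest.approx(0.0)
        assert np.isnan(identical["ses"])

    def test_stratum_summary_has_six_rows(self, small_dataset):
        ds = small_dataset
        cfg = NullConfig(model="tip_shuffle", n_null_per_tree=3, seed=2)
        res = ses_phylosor_pipeline(ds.community, ds.trees, env=ds.env, config=cfg)
        summ = summarize_ses_by_stratum(res.pairs)
        assert len(summ) == 6
        assert summ["within_formation"].sum() == 3

    def test_five_number_summary_order_statistics(self):
        pairs = pd.DataFrame({
            "site_i": list("abcde"), "site_j": list("fghij"),
            "ses": [-2.0, -1.0, 0.0, 1.0, 2.0],
            "stratum": ["Ica-Ica"] * 5, "within_formation": [True] * 5})
        row = summarize_ses_by_stratum(pairs).iloc[0]
        assert (row["min"], row["q1"], row["median"], row["q3"], row["max"]) \
            == (-2.0, -1.0, 0.0, 1.0, 2.0)
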