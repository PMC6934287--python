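from math import ceil

import numpy as np
import pandas as pd
import pytest

import convsearch as cs
from convsearch.simulate import broken_stick_variances


class TestBDTree:
    def test_pure_birth_is_ultrametric(self):
        rng = np.random.default_rng(0)
        tree = cs.simulate_bd_tree(0.5, 0.0, 30, rng)
        depths = tree.time_depth[: tree.ntips]
        assert np.ptp(depths) < 1e-9
        tree.validate()

    def test_death_produces_fossil_tips(self):
        found = False
        for seed in range(10):
            rng = np.random.default_rng(seed)
            tree = cs.simulate_bd_tree(0.5, 0.2, 30, rng)
            depths = tree.time_depth[: tree.ntips]
            if depths.min() < depths.max() - 1e-9:
                found = True
                break
        assert found

    def test_min_tips_and_validity(self):
        rng = np.random.default_rng(5)
        tree = cs.simulate_bd_tree(0.5, 0.2, 80, rng)
        assert tree.ntips >= 80
        tree.validate()

    def test_bad_rates(self):
        with pytest.raises(ValueError):
            cs.simulate_bd_tree(0.2, 0.5, 10, np.random.default_rng(0))


class TestBM:
    def test_small_sigma_collapses_to_root(self, bd_tree):
        phen = cs.simulate_bm(bd_tree, 2, 1e-18, np.random.default_rng(1))
        assert np.abs(phen.to_numpy()).max() < 1e-6

    def test_variance_law(self):
        tree = cs.from_newick_string("((A:1,B:1):1,(C:0.5,D:0.5):1.5);")
        vals = np.array([
            cs.simulate_bm(tree, 1, 2.0, np.random.default_rng(s))
            .loc["A", "v1"] for s in range(1500)])
        expected = 2.0 * 2.0  # sigma2 * root-to-tip depth
        assert vals.var() == pytest.approx(expected, rel=0.10)

    def test_covariance_law(self):
        tree = cs.from_newick_string("((A:1,B:1):1,(C:0.5,D:0.5):1.5);")
        ab = np.array([
            cs.simulate_bm(tree, 1, 1.0, np.random.default_rng(s))
            .loc[["A", "B"], "v1"].to_numpy() for s in range(1500)])
        shared = 1.0  # shared path length of A and B
        cov = np.cov(ab.T)[0, 1]
        assert cov == pytest.approx(shared, rel=0.15)


class TestRescale:
    def test_neutral_parameters_identity(self, bd_tree):
        for model, param in [("kappa", 1.0), ("delta", 1.0),
                             ("lambda", 1.0), ("trend", 0.0)]:
            out = cs.rescale_tree(bd_tree, model, param)
            assert np.allclose(out.length, bd_tree.length, atol=1e-12)

    def test_kappa_zero_speciational(self, bd_tree):
        out = cs.rescale_tree(bd_tree, "kappa", 0.0)
        mask = np.arange(bd_tree.nnodes) != bd_tree.root
        assert np.allclose(out.length[mask], 1.0)

    def test_lambda_covariance_definition(self):
        """lambda scales shared (off-diagonal) path lengths, preserving
        tip depths and total height — checked against the covariance
        transform on a 6-tip tree."""
        tree = cs.from_newick_string(
            "(((a:1,b:1):1,(c:1,d:1):1):1,(e:2,f:2):1);")
        lam = 0.5
        out = cs.rescale_tree(tree, "lambda", lam)
        c_old = tree.shared_path_matrix
        c_new = out.shared_path_matrix
        off = ~np.eye(tree.ntips, dtype=bool)
        assert np.allclose(c_new[off], lam * c_old[off], atol=1e-12)
        assert np.allclose(np.diag(c_new), np.diag(c_old), atol=1e-12)
        assert out.height == pytest.approx(tree.height)

    def test_delta_preserves_height(self, bd_tree):
        out = cs.rescale_tree(bd_tree, "delta", 2.0)
        assert out.height == pytest.approx(bd_tree.height, abs=1e-9)

    def test_out_of_range_warns(self, bd_tree):
        with pytest.warns(UserWarning, match="outside"):
            cs.rescale_tree(bd_tree, "kappa", 2.0)


class TestDrift:
    def test_ds_zero_equals_bm_same_seed(self, bd_tree):
        a = cs.simulate_drift(bd_tree, 3, 1.0, 0.0,
                              np.random.default_rng(2))
        b = cs.simulate_bm(bd_tree, 3, 1.0, np.random.default_rng(2))
        pd.testing.assert_frame_equal(a, b)

    def test_trend_in_mean(self):
        tree = cs.from_newick_string("((A:1,B:1):1,(C:0.5,D:0.5):1.5);")
        ds = 0.8
        vals = np.array([
            cs.simulate_drift(tree, 1, 1.0, ds, np.random.default_rng(s))
            .loc["A", "v1"] for s in range(1500)])
        assert vals.mean() == pytest.approx(ds * 2.0, rel=0.10)
        assert vals.var() == pytest.approx(2.0, rel=0.10)


class TestPlantClades:
    def _plant(self, seed=30, **kw):
        rng = np.random.default_rng(seed)
        tree = cs.simulate_bd_tree(0.5, 0.2, 80, rng)
        phen = cs.simulate_bm(tree, 3, 1.0, rng)
        spec = cs.CladePlantSpec(**kw)
        return tree, phen, cs.plant_convergent_clades(tree, phen, spec,
                                                      rng)

    def test_tip_bookkeeping(self):
        tree, phen, (tree2, phen2, truth) = self._plant()
        assert tree2.ntips == tree.ntips + len(truth.tips_b)
        assert len(truth.tips_b) == truth.log["source_size"] - 2
        tree2.validate()

    def test_planted_means_near_target(self):
        tree, phen, (tree2, phen2, truth) = self._plant()
        m = phen.to_numpy().max(axis=0)
        target = truth.f * m
        for tips in (truth.tips_a, truth.tips_b):
            got = phen2.loc[tips].to_numpy().mean(axis=0)
            # 2% multiplicative jitter: means land very close to f*m
            assert np.allclose(got, target, rtol=0.03, atol=1e-9)

    def test_graft_distance_contract(self):
        tree, phen, (tree2, phen2, truth) = self._plant()
        assert truth.log["graft_distance"] >= ceil(tree.ntips / 10)
        _, _, (t3, p3, truth3) = self._plant(seed=31,
                                             exact_graft_distance=3)
        assert truth3.log["graft_distance"] == 3

    def test_planted_pair_is_candidate(self):
        from convsearch.clades import enumerate_candidate_pairs
        tree, phen, (tree2, phen2, truth) = self._plant(seed=32)
        pairs = enumerate_candidate_pairs(tree2)
        keys = {frozenset((p.node_a, p.node_b)) for p in pairs}
        assert frozenset((truth.mrca_a, truth.mrca_b)) in keys

    def test_null_condition_regenerates_phenotype(self):
        tree, phen, _ = self._plant(seed=33)
        rng = np.random.default_rng(33)
        tree2, phen2, truth = cs.plant_convergent_clades(
            tree, phen, cs.CladePlantSpec(), rng, convergent=False)
        assert truth.f is None
        assert not truth.convergent
        assert sorted(phen2.index) == sorted(tree2.tip_labels)


class TestPlantStates:
    def test_contracts(self):
        rng = np.random.default_rng(34)
        tree = cs.simulate_bd_tree(0.5, 0.2, 80, rng)
        phen = cs.simulate_bm(tree, 3, 1.0, rng)
        phen2, states, truth = cs.plant_convergent_states(tree, phen, 2,
                                                          rng=rng)
        sizes = pd.Series(list(states.values())).value_counts()
        assert sizes.max() <= ceil(tree.ntips / 10)
        background = [t for t in tree.tip_labels if t not in states]
        pd.testing.assert_frame_equal(phen.loc[background],
                                      phen2.loc[background])

    def test_state2_double_spread(self):
        rng = np.random.default_rng(35)
        tree = cs.simulate_bd_tree(0.5, 0.0, 200, rng)
        phen = cs.simulate_bm(tree, 3, 1.0, rng)
        phen2, states, truth = cs.plant_convergent_states(tree, phen, 2,
                                                          rng=rng)
        s1 = phen2.loc[truth.tips_a].to_numpy().std(axis=0, ddof=1)
        s2 = phen2.loc[truth.tips_b].to_numpy().std(axis=0, ddof=1)
        ratio = (s2 / s1).mean()
        assert 1.3 < ratio < 2.7


class TestStayton:
    def test_broken_stick(self):
        v = broken_stick_variances(10)
        assert v.sum() == pytest.approx(1.0)
        assert np.all(np.diff(v) < 0)
        expected_first = sum(1.0 / j for j in range(1, 11)) / 10
        assert v[0] == pytest.approx(expected_first)

    def test_replicate_shapes_and_distances(self):
        tree, phen, tips, truth = cs.stayton_replicate(
            convergent=False, rng=np.random.default_rng(36))
        assert tree.ntips == 26
        assert 2 <= phen.shape[1] <= 10
        ids = tree.resolve_tips(tips)
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                assert tree.node_distance(a, b) >= 3
        assert not truth.convergent

    def test_strong_selection_reaches_optimum(self):
        """At alpha=50 the OU pull equilibrates: selected tips land within
        5% of the shared optimum (for traits whose optimum is not
        vanishingly small relative to the OU noise floor)."""
        checked = 0
        for seed in range(37, 42):
            tree, phen, tips, truth = cs.stayton_replicate(
                convergent=True, rng=np.random.default_rng(seed),
                alpha=50.0)
            theta = np.asarray(truth.log["theta"])
            vals = phen.loc[tips].to_numpy()
            meaningful = np.abs(theta) > 0.5
            # the pull acts since the lineages' common ancestor: the
            # equilibrium claim requires the decay to be complete
            ids = tree.resolve_tips(tips)
            anchor = tree.mrca(ids)
            dt = tree.time_depth[ids] - tree.time_depth[anchor]
            settled = np.exp(-50.0 * dt) < 1e-3
            if not (meaningful.any() and settled.any()):
                continue
            dev = np.abs(vals[np.ix_(settled, meaningful)]
                         - theta[meaningful])
            # allowance: 5% of the optimum plus the stationary OU noise
            noise = np.sqrt(
                broken_stick_variances(10)[truth.log["traits"]] / 100.0)
            bound = 0.05 * np.abs(theta[meaningful]) + 4 * noise[meaningful]
            assert np.all(dev <= bound)
            checked += 1
        assert checked >= 3


class TestSuite:
    def test_zero_replicates(self):
        out = cs.error_rate_suite("stayton-bm", 0, np.random.default_rng(0))
        assert out["records"].empty
        assert out["rates"] == {}

    def test_determinism_and_bounds(self):
        r1 = cs.error_rate_suite("stayton-bm", 10,
                                 np.random.default_rng(40), n_null=200)
        r2 = cs.error_rate_suite("stayton-bm", 10,
                                 np.random.default_rng(40), n_null=200)
        pd.testing.assert_frame_equal(r1["records"], r2["records"])
        assert 0.0 <= r1["rates"]["type_i"] <= 1.0
        lo, hi = r1["rates"]["type_i_ci"]
        assert 0.0 <= lo <= hi <= 1.0

    def test_unknown_design(self):
        with pytest.raises(ValueError, match="unknown design"):
            cs.error_rate_suite("nope", 1, np.random.default_rng(0))

    def test_clade_auto_smoke(self):
        out = cs.error_rate_suite("clade-auto", 2,
                                  np.random.default_rng(41), n_null=200,
                                  min_tips=50)
        df = out["records"]
        assert len(df) == 2
        assert {"any_significant", "hit_within2",
                "spec_both_significant"} <= set(df.columns)
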