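import math

import numpy as np
import pytest

from _oracles import enumeration_posteriors, random_tree_newick
from pheromat import synth  # noqa: F401  (tree generator used in stationary test)
from pheromat.asr import (
    Mk2Params,
    PhyloTree,
    marginal_posteriors,
    mcmc_rates,
    mk2_loglik,
    simulate_mk2,
)


class TestLoglik:
    def test_zero_branch_limit(self):
        tree = PhyloTree.from_newick("(a:0.0,b:0.0);")
        ll = mk2_loglik(tree, {"a": "1", "b": "1"}, Mk2Params(1.0, 1.0, (0.5, 0.5)))
        assert ll == pytest.approx(math.log(0.5))

    def test_stationary_long_branch_limit(self):
        tree = PhyloTree.from_newick("(a:1000.0,b:1000.0);")
        ll = mk2_loglik(tree, {"a": "1", "b": "1"}, Mk2Params(1.0, 1.0, (0.5, 0.5)))
        assert ll == pytest.approx(math.log(0.25), abs=1e-9)

    @pytest.mark.parametrize("mut", [0.1, 1.0, 10.0])
    def test_two_tip_closed_form(self, mut):
        """Symmetric two-state closed form for two tips in state 1."""
        tree = PhyloTree.from_newick("(a:1.0,b:1.0);")
        ll = mk2_loglik(tree, {"a": "1", "b": "1"}, Mk2Params(mut, mut, (0.5, 0.5)))
        e = math.exp(-2 * mut)
        closed = 0.5 * ((0.5 * (1 + e)) ** 2 + (0.5 * (1 - e)) ** 2)
        assert ll == pytest.approx(math.log(closed), abs=1e-12)

    def test_child_order_invariance(self):
        params = Mk2Params(0.8, 1.2)
        t1 = PhyloTree.from_newick("((a:0.1,b:0.2):0.3,(c:0.4,d:0.5):0.6);")
        t2 = PhyloTree.from_newick("((d:0.5,c:0.4):0.6,(b:0.2,a:0.1):0.3);")
        tips = {"a": "1", "b": "0", "c": "1", "d": "?"}
        assert mk2_loglik(t1, tips, params) == pytest.approx(mk2_loglik(t2, tips, params))

    def test_negative_branch_rejected(self):
        tree = PhyloTree.from_newick("(a:1.0,b:1.0);")
        tree.blen[1] = -0.5
        with pytest.raises(ValueError):
            mk2_loglik(tree, {"a": "1", "b": "1"}, Mk2Params())

    def test_missing_tip_state_rejected(self):
        tree = PhyloTree.from_newick("(a:1.0,b:1.0);")
        with pytest.raises(ValueError, match="missing"):
            mk2_loglik(tree, {"a": "1"}, Mk2Params())


class TestMarginalPosteriors:
    def test_consensus_limit(self):
        nwk = "(" + ",".join(f"t{i}:0.01" for i in range(10)) + ");"
        tree = PhyloTree.from_newick(nwk)
        post = marginal_posteriors(tree, {f"t{i}": "1" for i in range(10)}, Mk2Params(1, 1))
        assert post[tree.root][1] > 0.999

    def test_no_data_returns_prior(self):
        """With all tips unknown and the root prior at stationarity, every
        node's posterior equals that prior (the chain has nothing to update)."""
        tree = PhyloTree.from_newick("((a:0.3,b:0.2):0.1,c:0.4);")
        params = Mk2Params(0.7, 1.1)  # root prior defaults to stationary
        pi = params.stationary()
        post = marginal_posteriors(tree, {"a": "?", "b": "?", "c": "?"}, params)
        for v in post.values():
            assert v == pytest.approx(pi)
        # with a non-stationary prior the root itself still returns the prior
        params2 = Mk2Params(0.7, 1.1, (0.35, 0.65))
        post2 = marginal_posteriors(tree, {"a": "?", "b": "?", "c": "?"}, params2)
        assert post2[tree.root] == pytest.approx([0.35, 0.65])

    def test_posteriors_sum_to_one(self, rng):
        nwk = random_tree_newick(12, rng)
        tree = PhyloTree.from_newick(nwk)
        tips = {tree.labels[i]: str(rng.integers(2)) for i in tree.leaves}
        post = marginal_posteriors(tree, tips, Mk2Params(0.5, 1.5))
        for v in post.values():
            assert abs(v.sum() - 1.0) < 1e-9

    def test_enumeration_oracle_small_trees(self):
        """Up-down marginals equal exhaustive enumeration on trees of 2-6 tips."""
        rng = np.random.default_rng(77)
        for trial in range(12):
            n = int(rng.integers(2, 7))
            tree = PhyloTree.from_newick(random_tree_newick(n, rng))
            tips = {
                tree.labels[i]: rng.choice(["0", "1", "?"], p=[0.4, 0.4, 0.2])
                for i in tree.leaves
            }
            if all(s == "?" for s in tips.values()):
                tips[next(iter(tips))] = "1"
            params = Mk2Params(float(rng.uniform(0.1, 2)), float(rng.uniform(0.1, 2)))
            post = marginal_posteriors(tree, tips, params)
            expected, ll = enumeration_posteriors(tree, tips, params)
            assert mk2_loglik(tree, tips, params) == pytest.approx(ll)
            for i in range(tree.n_nodes):
                assert post[i] == pytest.approx(expected[i], abs=1e-10)


class TestSimulate:
    def test_zero_rates_clone_root(self):
        tree = PhyloTree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        tips, states = simulate_mk2(tree, Mk2Params(0.0, 0.0, (0.0, 1.0)), seed=1)
        assert set(tips.values()) == {"1"}

    def test_seed_determinism(self):
        tree = PhyloTree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        p = Mk2Params(0.8, 0.6)
        assert simulate_mk2(tree, p, seed=9) == simulate_mk2(tree, p, seed=9)

    def test_stationary_frequencies(self):
        """Long-branch tip frequencies approach the stationary distribution."""
        n = 400
        nwk = "(" + ",".join(f"t{i}:50.0" for i in range(n)) + ");"
        tree = PhyloTree.from_newick(nwk)
        params = Mk2Params(1.5, 0.5)  # pi1 = 0.75
        tips, _ = simulate_mk2(tree, params, seed=3)
        freq1 = sum(v == "1" for v in tips.values()) / n
        assert abs(freq1 - 0.75) < 3 * math.sqrt(0.75 * 0.25 / n)


class TestMcmc:
    def test_seed_reproducibility(self):
        tree = PhyloTree.from_newick("((a:0.3,b:0.2):0.1,(c:0.4,d:0.1):0.2);")
        tips = {"a": "1", "b": "1", "c": "0", "d": "?"}
        r1 = mcmc_rates(tree, tips, n_samples=50, seed=5)
        r2 = mcmc_rates(tree, tips, n_samples=50, seed=5)
        assert np.array_equal(r1.samples, r2.samples)

    def test_zero_samples_rejected(self):
        tree = PhyloTree.from_newick("(a:1,b:1);")
        with pytest.raises(ValueError):
            mcmc_rates(tree, {"a": "1", "b": "0"}, n_samples=0)

    def test_posterior_averaging_normalised(self):
        tree = PhyloTree.from_newick("((a:0.3,b:0.2):0.1,(c:0.4,d:0.1):0.2);")
        tips = {"a": "1", "b": "1", "c": "0", "d": "0"}
        res = mcmc_rates(tree, tips, n_samples=60, seed=2)
        for v in res.mean_posteriors.values():
            assert abs(v.sum() - 1.0) < 1e-9
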