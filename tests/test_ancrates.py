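import math

import numpy as np
import pytest
from scipy import stats

from thermevol.ancrates import (node_tip_shared_paths, paired_rate_test,
                                reconstruct_ancestors, tip_absolute_rates)
from thermevol.errors import ParameterError
from thermevol.models import fit_model
from thermevol.phylo import vcv
from thermevol.simulate import simulate_bm_branchwise, simulate_yule_tree

from conftest import star_tree


def _bm_fit(tree, x):
    return fit_model(tree, x, "BM")


class TestReconstruct:
    def test_two_tip_inverse_branch_weighting(self, two_tip_tree):
        x = {"A": 0.0, "B": 4.0}
        f = _bm_fit(two_tip_tree, x)
        anc = reconstruct_ancestors(two_tip_tree, x, f)
        assert anc[two_tip_tree.root] == pytest.approx(1.0)

    def test_constant_trait_everywhere(self):
        t = simulate_yule_tree(10, 1.0, 50)
        x = np.full(10, 7.5)
        f = fit_model(t, x, "BM")
        anc = reconstruct_ancestors(t, x, f)
        assert all(v == pytest.approx(7.5) for v in anc.values())

    @pytest.mark.parametrize("seed", range(5))
    def test_dense_conditional_mvn_oracle(self, seed):
        t = simulate_yule_tree(7, 1.0, 60 + seed)
        x = simulate_bm_branchwise(t, 1.5, 2.0, np.random.default_rng(seed))
        f = _bm_fit(t, x)
        anc = reconstruct_ancestors(t, x, f)
        C = vcv(t).matrix
        internal, M = node_tip_shared_paths(t)
        w = np.linalg.solve(C, x - f.root_state)
        expected = f.root_state + M @ w
        got = np.asarray([anc[int(k)] for k in internal])
        assert np.abs(got - expected).max() < 1e-8

    def test_shift_invariance(self, rng):
        t = simulate_yule_tree(12, 1.0, 70)
        x = simulate_bm_branchwise(t, 1.0, 0.0, rng)
        f0 = _bm_fit(t, x)
        f1 = _bm_fit(t, x + 42.0)
        a0 = reconstruct_ancestors(t, x, f0)
        a1 = reconstruct_ancestors(t, x + 42.0, f1)
        for k in a0:
            assert a1[k] == pytest.approx(a0[k] + 42.0, abs=1e-8)

    def test_lambda_one_equals_bm(self, rng):
        t = simulate_yule_tree(9, 1.0, 71)
        x = simulate_bm_branchwise(t, 1.0, 0.0, rng)
        fb = _bm_fit(t, x)
        fl = fit_model(t, x, "LA")
        anc_b = reconstruct_ancestors(t, x, fb)
        # force lambda to exactly 1 to compare the transform paths
        fl.lam = 1.0
        fl.root_state = fb.root_state
        anc_l = reconstruct_ancestors(t, x, fl)
        for k in anc_b:
            assert anc_l[k] == pytest.approx(anc_b[k], abs=1e-10)

    def test_star_tree_every_ancestor_is_gls_mean(self, rng):
        t = star_tree(8)
        x = rng.standard_normal(8)
        f = _bm_fit(t, x)
        anc = reconstruct_ancestors(t, x, f)
        assert anc[t.root] == pytest.approx(float(x.mean()))

    def test_size_mismatch_error(self, rng):
        t = simulate_yule_tree(8, 1.0, 72)
        t2 = simulate_yule_tree(9, 1.0, 73)
        x2 = simulate_bm_branchwise(t2, 1.0, 0.0, rng)
        f = _bm_fit(t2, x2)
        with pytest.raises(ParameterError):
            reconstruct_ancestors(t, x2[:8], f)


class TestTipRates:
    def test_two_tip_example(self, two_tip_tree):
        x = {"A": 0.0, "B": 4.0}
        f = _bm_fit(two_tip_tree, x)
        anc = reconstruct_ancestors(two_tip_tree, x, f)
        rates = {r.species: r.abs_rate
                 for r in tip_absolute_rates(two_tip_tree, x, anc)}
        assert rates["A"] == pytest.approx(1.0)
        assert rates["B"] == pytest.approx(1.0)

    def test_constant_trait_zero_rates(self):
        t = simulate_yule_tree(6, 1.0, 80)
        x = np.full(6, 3.0)
        f = fit_model(t, x, "BM")
        anc = reconstruct_ancestors(t, x, f)
        assert all(r.abs_rate == pytest.approx(0.0)
                   for r in tip_absolute_rates(t, x, anc))

    def test_shift_leaves_rates_unchanged(self, rng):
        t = simulate_yule_tree(20, 1.0, 81)
        x = simulate_bm_branchwise(t, 1.0, 0.0, rng)
        r0 = {r.species: r.abs_rate for r in tip_absolute_rates(
            t, x, reconstruct_ancestors(t, x, _bm_fit(t, x)))}
        x1 = x + 13.0
        r1 = {r.species: r.abs_rate for r in tip_absolute_rates(
            t, x1, reconstruct_ancestors(t, x1, _bm_fit(t, x1)))}
        for s in r0:
            assert r1[s] == pytest.approx(r0[s], abs=1e-8)

    def test_wn_uses_grand_mean_and_depth(self, rng):
        t = simulate_yule_tree(10, 1.0, 82)
        x = simulate_bm_branchwise(t, 1.0, 0.0, rng)
        f = fit_model(t, x, "WN")
        anc = reconstruct_ancestors(t, x, f)
        depths = dict(zip(t.tip_labels, vcv(t).matrix.diagonal()))
        for r in tip_absolute_rates(t, x, anc, model_used="WN"):
            assert r.branch_time == pytest.approx(depths[r.species])
            assert r.ancestor_estimate == pytest.approx(f.root_state)

    def test_depth_mode(self, rng):
        t = simulate_yule_tree(10, 1.0, 83)
        x = simulate_bm_branchwise(t, 1.0, 0.0, rng)
        anc = reconstruct_ancestors(t, x, _bm_fit(t, x))
        depths = dict(zip(t.tip_labels, vcv(t).matrix.diagonal()))
        for r in tip_absolute_rates(t, x, anc, time_mode="depth"):
            assert r.branch_time == pytest.approx(depths[r.species])

    def test_rate_decreases_with_branch_length(self):
        # ancestor-descendant contrasts: longer terminal branches damp the
        # per-time rate; Spearman correlation should be negative
        neg = 0
        reps = 60
        for rep in range(reps):
            t = simulate_yule_tree(256, 1.0, 900 + rep)
            x = simulate_bm_branchwise(t, 1.0, 0.0,
                                       np.random.default_rng(rep))
            anc = reconstruct_ancestors(t, x, _bm_fit(t, x))
            rr = tip_absolute_rates(t, x, anc)
            rho = stats.spearmanr([r.branch_time for r in rr],
                                  [r.abs_rate for r in rr]).statistic
            neg += rho < 0
        assert neg / reps > 0.9


class TestPairedRateTest:
    def test_equal_rates(self):
        rates = {f"s{i}": 1.0 + i for i in range(5)}
        res = paired_rate_test(rates, rates)
        assert res.t_statistic == 0.0
        assert res.p_value == 1.0

    def test_constant_ratio_degenerate(self):
        a = {f"s{i}": math.e * (1.0 + i) for i in range(5)}
        b = {f"s{i}": 1.0 + i for i in range(5)}
        res = paired_rate_test(a, b)
        assert res.degenerate
        assert res.p_value == 0.0
        assert res.mean_ln_rate_A - res.mean_ln_rate_B == pytest.approx(1.0)

    def test_zero_rates_excluded(self):
        a = {"s1": 1.0, "s2": 2.0, "s3": 3.0, "s4": 0.0}
        b = {"s1": 1.0, "s2": 1.0, "s3": 2.0, "s4": 5.0}
        res = paired_rate_test(a, b)
        assert res.m == 3
        assert res.n_excluded_zero == 1

    def test_too_few_pairs(self):
        with pytest.raises(ParameterError):
            paired_rate_test({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 1.0})

    def test_power_at_ratio_four(self):
        # traits with sigma^2 ratio 16 -> abs-rate ratio ~ 4 on the ln scale
        reps, hits = 100, 0
        t = simulate_yule_tree(200, 1.0, 91)
        for rep in range(reps):
            rng = np.random.default_rng(rep)
            xa = simulate_bm_branchwise(t, 16.0, 0.0, rng)
            xb = simulate_bm_branchwise(t, 1.0, 0.0, rng)
            ra = tip_absolute_rates(
                t, xa, reconstruct_ancestors(t, xa, _bm_fit(t, xa)))
            rb = tip_absolute_rates(
                t, xb, reconstruct_ancestors(t, xb, _bm_fit(t, xb)))
            res = paired_rate_test(ra, rb)
            hits += (res.p_value < 0.05
                     and res.mean_ln_rate_A > res.mean_ln_rate_B)
        assert hits / reps >= 0.9
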