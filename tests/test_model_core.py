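import numpy as np
import pytest
from scipy.integrate import quad

import mixtwice as mt
from mixtwice.model_core import (
    DegenerateDataError,
    SummaryStats,
    build_effect_grid,
    build_variance_grid,
    component_loglik,
    mixture_loglik,
    normal_component_logdensity,
    scaled_chisq_logdensity,
)


class TestSummaryStats:
    def test_valid(self):
        s = SummaryStats.from_arrays(x=[0.1, -0.2], s2=[1.0, 2.0], df=18)
        assert s.m == 2 and s.df == 18.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(x=[np.inf, 0.0], s2=[1.0, 1.0], df=18),
            dict(x=[0.0, 0.0], s2=[1.0, 0.0], df=18),
            dict(x=[0.0, 0.0], s2=[1.0, -1.0], df=18),
            dict(x=[0.0, 0.0], s2=[1.0, np.nan], df=18),
            dict(x=[0.0, 0.0], s2=[1.0, 1.0], df=0.5),
            dict(x=[0.0], s2=[1.0, 1.0], df=18),
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            SummaryStats.from_arrays(**kwargs)

    def test_per_unit_df_rejected(self):
        with pytest.raises(ValueError):
            SummaryStats.from_arrays(x=[0.0, 1.0], s2=[1.0, 1.0], df=[18, 20])


class TestEffectGrid:
    def test_half_width_rule(self):
        grid = build_effect_grid([-3.0, 1.0, 2.0], K=2, mode=0.0)
        np.testing.assert_allclose(grid.values, [-3.0, -1.5, 0.0, 1.5, 3.0])
        assert grid.mode_index == 2 and grid.values[2] == 0.0

    def test_degenerate_all_at_mode(self):
        with pytest.raises(DegenerateDataError):
            build_effect_grid([1.0], K=1, mode=1.0)

    def test_default_K_layout(self):
        grid = build_effect_grid([-0.5, 0.5], K=15, mode=0.0)
        assert grid.n_points == 31
        assert grid.spacing == pytest.approx(1.0 / 30.0, rel=1e-12)
        assert grid.values[15] == 0.0
        # every estimate inside the support
        assert grid.values[0] == -0.5 and grid.values[-1] == 0.5

    def test_nonzero_mode(self):
        grid = build_effect_grid([0.0, 4.0], K=2, mode=1.0)
        assert grid.values[grid.mode_index] == 1.0
        assert np.all(np.abs(np.array([0.0, 4.0]) - 1.0) <= 3.0 + 1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            build_effect_grid([0.0, np.nan], K=2)


class TestVarianceGrid:
    def test_span_rule(self):
        grid = build_variance_grid([1.0, 2.0, 5.0], L=3)
        np.testing.assert_allclose(grid.values, [1.0, 3.0, 5.0])

    def test_equal_inputs_padded(self):
        grid = build_variance_grid([2.0, 2.0], L=3)
        np.testing.assert_allclose(grid.values, [1.9, 2.0, 2.1])

    def test_single_point_is_midpoint(self):
        grid = build_variance_grid([1.0, 5.0], L=1)
        np.testing.assert_allclose(grid.values, [3.0])

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            build_variance_grid([1.0, 0.0], L=3)


class TestScaledChisq:
    def test_closed_forms(self):
        # nu=2: chi2 pdf f(y) = exp(-y/2)/2, times nu/b
        assert scaled_chisq_logdensity(1.0, 1.0, 2) == pytest.approx(-1.0, abs=1e-12)
        assert scaled_chisq_logdensity(2.0, 2.0, 2) == pytest.approx(
            -1.0 - np.log(2.0), abs=1e-12
        )

    @pytest.mark.parametrize("df", [2, 5, 18.0])
    def test_scale_equivariance(self, df):
        lhs = scaled_chisq_logdensity(2.0, 2.0, df)
        rhs = scaled_chisq_logdensity(1.0, 1.0, df) + np.log(0.5)
        assert lhs == pytest.approx(rhs, rel=1e-12)

    @pytest.mark.parametrize("b,df", [(1.0, 2), (2.0, 5), (0.5, 18)])
    def test_density_integrates_to_one(self, b, df):
        total, _ = quad(
            lambda s2: np.exp(scaled_chisq_logdensity(s2, b, df)), 0, np.inf
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_input_errors(self):
        with pytest.raises(ValueError):
            scaled_chisq_logdensity(-1.0, 1.0, 2)
        with pytest.raises(ValueError):
            scaled_chisq_logdensity(1.0, 0.0, 2)


class TestNormalComponent:
    @pytest.mark.parametrize(
        "x,a,b,expected",
        [
            (0.0, 0.0, 1.0, -0.9189385332046727),
            (1.0, 0.0, 1.0, -1.4189385332046727),
            (0.0, 0.0, 4.0, -0.5 * np.log(8 * np.pi)),
        ],
    )
    def test_closed_forms(self, x, a, b, expected):
        assert normal_component_logdensity(x, a, b) == pytest.approx(
            expected, abs=1e-12
        )

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            normal_component_logdensity(0.0, 0.0, -1.0)


class TestComponentLoglik:
    def make_single(self):
        stats = SummaryStats.from_arrays(x=[0.0], s2=[1.0], df=2)
        egrid = mt.EffectGrid(values=np.array([-1.0, 0.0, 1.0]), K=1)
        vgrid = mt.VarianceGrid(values=np.array([1.0]))
        return stats, egrid, vgrid

    def test_single_unit_value(self):
        stats, egrid, vgrid = self.make_single()
        comp = component_loglik(stats, egrid, vgrid)
        assert comp.entries[0, 1, 0] == pytest.approx(-1.9189385332046727, abs=1e-12)

    def test_cache_consistency(self):
        """entries = normal part + cached chisq part exactly."""
        spec = mt.make_scenario("near_normal", pi0=0.5, m=20, n_per_group=5)
        stats = mt.simulate_dataset(spec, seed=3).stats
        egrid = build_effect_grid(stats.x, K=3)
        vgrid = build_variance_grid(stats.s2, L=4)
        comp = component_loglik(stats, egrid, vgrid)
        normal = normal_component_logdensity(
            stats.x[:, None, None],
            egrid.values[None, :, None],
            vgrid.values[None, None, :],
        )
        np.testing.assert_array_equal(
            comp.entries, normal + comp.chisq_part[:, None, :]
        )
        assert np.all(np.isfinite(comp.entries) | (comp.entries == -np.inf))

    def test_maximized_at_nearest_grid_point(self):
        stats = SummaryStats.from_arrays(x=[0.6], s2=[1.0], df=4)
        egrid = mt.EffectGrid(values=np.array([-1.0, 0.0, 1.0]), K=1)
        vgrid = mt.VarianceGrid(values=np.array([0.5, 1.5]))
        comp = component_loglik(stats, egrid, vgrid)
        for l in range(2):
            assert np.argmax(comp.entries[0, :, l]) == 2  # a=1 nearest to 0.6

    def test_k_differences_independent_of_s2(self):
        egrid = mt.EffectGrid(values=np.array([-2.0, 0.0, 2.0]), K=1)
        vgrid = mt.VarianceGrid(values=np.array([0.5, 1.0]))
        s_a = SummaryStats.from_arrays(x=[0.3], s2=[0.4], df=6)
        s_b = SummaryStats.from_arrays(x=[0.3], s2=[2.5], df=6)
        d_a = component_loglik(s_a, egrid, vgrid).entries[0]
        d_b = component_loglik(s_b, egrid, vgrid).entries[0]
        np.testing.assert_allclose(
            d_a - d_a[1][None, :], d_b - d_b[1][None, :], rtol=1e-12
        )


class TestMixtureLoglik:
    def comp(self, m=25, K=3, L=3, seed=7):
        spec = mt.make_scenario("near_normal", pi0=0.5, m=m, n_per_group=5)
        stats = mt.simulate_dataset(spec, seed=seed).stats
        egrid = build_effect_grid(stats.x, K=K)
        vgrid = build_variance_grid(stats.s2, L=L)
        return component_loglik(stats, egrid, vgrid)

    def test_degenerate_mixture_equals_entry(self):
        stats = SummaryStats.from_arrays(x=[0.0], s2=[1.0], df=2)
        egrid = mt.EffectGrid(values=np.array([-1.0, 0.0, 1.0]), K=1)
        vgrid = mt.VarianceGrid(values=np.array([1.0]))
        comp = component_loglik(stats, egrid, vgrid)
        ll, _, _ = mixture_loglik(np.array([0.0, 1.0, 0.0]), np.array([1.0]), comp)
        assert ll == pytest.approx(-1.9189385332046727, abs=1e-10)

    def test_additivity_over_units(self):
        spec = mt.make_scenario("near_normal", pi0=0.5, m=15, n_per_group=5)
        stats = mt.simulate_dataset(spec, seed=9).stats
        doubled = SummaryStats.from_arrays(
            x=np.concatenate([stats.x, stats.x]),
            s2=np.concatenate([stats.s2, stats.s2]),
            df=stats.df,
        )
        egrid = build_effect_grid(stats.x, K=3)
        vgrid = build_variance_grid(stats.s2, L=3)
        rng = np.random.default_rng(0)
        g = rng.dirichlet(np.ones(7))
        h = rng.dirichlet(np.ones(3))
        ll1, _, _ = mixture_loglik(g, h, component_loglik(stats, egrid, vgrid))
        ll2, _, _ = mixture_loglik(g, h, component_loglik(doubled, egrid, vgrid))
        assert ll2 == pytest.approx(2 * ll1, rel=1e-12)

    def test_dimension_mismatch(self):
        comp = self.comp()
        with pytest.raises(ValueError):
            mixture_loglik(np.ones(4) / 4, np.ones(3) / 3, comp)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_gradients_match_finite_differences(self, seed):
        comp = self.comp(seed=seed)
        rng = np.random.default_rng(seed)
        g = rng.dirichlet(np.ones(7))
        h = rng.dirichlet(np.ones(3))
        _, grad_g, grad_h = mixture_loglik(g, h, comp)
        eps = 1e-6
        for vec, grad, which in ((g, grad_g, "g"), (h, grad_h, "h")):
            for j in range(len(vec)):
                up, dn = vec.copy(), vec.copy()
                up[j] += eps
                dn[j] -= eps
                if which == "g":
                    lp = mixture_loglik(up, h, comp, validate=False)[0]
                    lm = mixture_loglik(dn, h, comp, validate=False)[0]
                else:
                    lp = mixture_loglik(g, up, comp, validate=False)[0]
                    lm = mixture_loglik(g, dn, comp, validate=False)[0]
                fd = (lp - lm) / (2 * eps)
                assert fd == pytest.approx(grad[j], rel=1e-5, abs=1e-8)

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_convex_combination_bounds(self, seed):
        """Per-unit mixture density lies between the extreme components."""
        comp = self.comp(seed=seed)
        rng = np.random.default_rng(seed)
        g = rng.dirichlet(np.ones(7))
        h = rng.dirichlet(np.ones(3))
        w = np.einsum("k,l->kl", g, h).ravel()
        dens = np.exp(comp.entries.reshape(comp.m, -1))
        mixture = dens @ w
        assert np.all(mixture <= dens.max(axis=1) + 1e-15)
        assert np.all(mixture >= dens.min(axis=1) - 1e-15)

    def test_permutation_invariance(self):
        spec = mt.make_scenario("near_normal", pi0=0.5, m=40, n_per_group=5)
        stats = mt.simulate_dataset(spec, seed=13).stats
        perm = np.random.default_rng(1).permutation(stats.m)
        shuffled = SummaryStats.from_arrays(
            x=stats.x[perm], s2=stats.s2[perm], df=stats.df
        )
        egrid = build_effect_grid(stats.x, K=3)
        vgrid = build_variance_grid(stats.s2, L=3)
        g = np.ones(7) / 7
        h = np.ones(3) / 3
        ll1 = mixture_loglik(g, h, component_loglik(stats, egrid, vgrid))[0]
        ll2 = mixture_loglik(g, h, component_loglik(shuffled, egrid, vgrid))[0]
        assert ll1 == pytest.approx(ll2, rel=1e-13)

    def test_log_space_matches_direct(self):
        """On a well-scaled instance the stabilized value equals the naive
        non-log computation to near machine precision."""
        comp = self.comp(m=15, seed=21)
        rng = np.random.default_rng(2)
        g = rng.dirichlet(np.ones(7))
        h = rng.dirichlet(np.ones(3))
        ll, _, _ = mixture_loglik(g, h, comp)
        dens = np.exp(comp.entries)
        direct = float(np.sum(np.log(np.einsum("ikl,k,l->i", dens, g, h))))
        assert ll == pytest.approx(direct, rel=1e-10)
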