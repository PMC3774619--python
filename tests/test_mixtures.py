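import numpy as np
import pytest

import patchstat as ps
from patchstat.mixtures import ComponentCollapseError, fit_seeded_mixture


class TestSeededEM:
    def test_single_seed_closed_form(self):
        model = ps.fit_seeded_mixture([1.0, 2.0, 3.0], [(5.0, 2.0, 1.0)])
        (w, mu, sd), = model.components
        assert w == 1.0
        assert mu == pytest.approx(2.0)
        assert sd == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_two_component_recovery(self, rng):
        x = np.concatenate([rng.normal(0, 1, 1000), rng.normal(10, 1, 1000)])
        model = ps.fit_seeded_mixture(x, [(1.0, 2.0, 0.5), (8.0, 2.0, 0.5)])
        means = np.sort(model.means)
        assert abs(means[0] - 0.0) < 0.2
        assert abs(means[1] - 10.0) < 0.2
        assert np.all(np.abs(model.weights - 0.5) < 0.05)

    def test_loglik_nondecreasing(self, rng):
        x = np.concatenate([rng.normal(0, 1, 300), rng.normal(4, 2, 300)])
        _, trace = fit_seeded_mixture(
            x, [(-1.0, 1.5, 0.4), (5.0, 1.5, 0.6)], return_trace=True
        )
        assert len(trace) >= 2
        assert np.all(np.diff(trace) >= -1e-9)

    def test_matches_sklearn_em(self, rng):
        """Independent cross-check against sklearn's EM from the same start."""
        from sklearn.mixture import GaussianMixture

        x = np.concatenate([rng.normal(2, 1, 800), rng.normal(9, 2, 1200)])
        seeds = [(1.0, 1.5, 0.5), (8.0, 1.5, 0.5)]
        model = ps.fit_seeded_mixture(x, seeds)
        gm = GaussianMixture(
            n_components=2,
            weights_init=[0.5, 0.5],
            means_init=[[1.0], [8.0]],
            precisions_init=[[[1 / 1.5**2]], [[1 / 1.5**2]]],
            reg_covar=0.0,
            tol=1e-10,
            max_iter=2000,
        ).fit(x[:, None])
        np.testing.assert_allclose(
            np.sort(model.means), np.sort(gm.means_.ravel()), atol=1e-3
        )
        np.testing.assert_allclose(
            np.sort(model.sds), np.sort(np.sqrt(gm.covariances_.ravel())), atol=1e-3
        )

    def test_collapse_detected(self):
        x = np.array([1.0, 1.0, 1.0, 1.0, 5.0, 6.0])
        with pytest.raises((ComponentCollapseError, ValueError)):
            ps.fit_seeded_mixture(x, [(1.0, 0.01, 0.5), (5.5, 1.0, 0.5)])

    def test_invalid_seeds(self):
        with pytest.raises(ValueError):
            ps.fit_seeded_mixture([1.0, 2.0], [(0.0, -1.0, 1.0)])


class TestSimulation:
    def test_deterministic_and_sized(self):
        model = ps.MixtureModel(((0.3, 0.0, 1.0), (0.7, 10.0, 2.0)))
        a = ps.simulate_from_mixture(model, 500, seed=5)
        b = ps.simulate_from_mixture(model, 500, seed=5)
        np.testing.assert_array_equal(a, b)
        assert a.shape == (500,)

    def test_fixed_counts_exact(self):
        model = ps.MixtureModel(((0.3, 0.0, 0.5), (0.7, 100.0, 0.5)))
        x = ps.simulate_from_mixture(model, 10, seed=2, fixed_counts=True)
        assert np.sum(x < 50) == 3  # exactly round(0.3 * 10) draws from comp 1

    def test_component_weights_respected(self):
        model = ps.MixtureModel(((0.3, 0.0, 0.5), (0.7, 100.0, 0.5)))
        x = ps.simulate_from_mixture(model, 100_000, seed=1)
        assert np.mean(x < 50) == pytest.approx(0.3, abs=0.01)

    def test_degenerate_sd_limit(self):
        model = ps.MixtureModel(((1.0, 5.0, 1e-12),))
        x = ps.simulate_from_mixture(model, 100, seed=0)
        np.testing.assert_allclose(x, 5.0, atol=1e-9)

    def test_single_gaussian_on_skewed_areas_puts_mass_below_zero(self, rng):
        """The Gaussian model's negative-area mass betrays skewed area data."""
        areas = rng.lognormal(3.0, 1.0, size=400)
        model = ps.fit_seeded_mixture(areas, [(areas.mean(), areas.std(), 1.0)])
        assert model.mass_below(0.0) > 0.01


class TestKDE:
    def test_bandwidth_closed_form(self):
        # sample with unit sample sd and IQR/1.34 > 1; 32**(1/5) = 2
        c = np.sqrt(31.0 / 32.0)
        x = np.array([-c] * 16 + [c] * 16)
        res = ps.kde_with_bandwidth(x)
        assert res.bandwidth == pytest.approx(0.45)

    def test_density_integrates_to_one(self, rng):
        res = ps.kde_with_bandwidth(rng.normal(0, 1, 2000))
        mass = np.trapezoid(res.density, res.grid)
        assert mass == pytest.approx(1.0, abs=1e-3)

    def test_consistency_for_normal_sample(self):
        from scipy.stats import norm

        x = np.random.default_rng(3).normal(0, 1, 10_000)
        res = ps.kde_with_bandwidth(x)
        sup = np.max(np.abs(res.density - norm.pdf(res.grid)))
        assert sup < 0.05

    def test_bandwidth_scales_linearly(self, rng):
        x = rng.gamma(3, 2, 500)
        b1 = ps.kde_with_bandwidth(x).bandwidth
        b2 = ps.kde_with_bandwidth(7.5 * x).bandwidth
        assert b2 == pytest.approx(7.5 * b1)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            ps.kde_with_bandwidth([2.0, 2.0, 2.0])


class TestAreaEnvelope:
    def _model(self):
        return ps.MixtureModel(((1.0, 50.0, 10.0),))

    def test_alpha_is_two_over_nsim_plus_one(self, rng):
        res = ps.area_envelope_test(
            rng.normal(50, 10, 100), self._model(), n_sim=39, seed=1
        )
        assert res.alpha == pytest.approx(2.0 / 40.0)

    def test_containment_when_data_is_a_simulation(self):
        model = self._model()
        data = ps.simulate_from_mixture(model, 200, seed=77)
        # envelope built from sims including the data's own seed stream
        rng = np.random.default_rng(9)
        sims = [
            np.sort(ps.simulate_from_mixture(model, 200, int(rng.integers(2**31))))
            for _ in range(38)
        ] + [np.sort(data)]
        lo = np.min(sims, axis=0)
        hi = np.max(sims, axis=0)
        x = np.sort(data)
        assert np.sum((x < lo) | (x > hi)) == 0

    def test_planted_outliers_detected(self, rng):
        model = self._model()
        data = ps.simulate_from_mixture(model, 300, seed=4)
        data[:5] = 50.0 + 10.0 * 10 + np.arange(5) * 10  # far above mean + 10 sd
        res = ps.area_envelope_test(data, model, n_sim=39, seed=8)
        assert res.n_deviations >= 5
        assert res.pct_deviations == pytest.approx(100 * res.n_deviations / 300)

    def test_order_invariance(self, rng):
        model = self._model()
        data = rng.normal(50, 10, 150)
        r1 = ps.area_envelope_test(data, model, seed=3)
        r2 = ps.area_envelope_test(rng.permutation(data), model, seed=3)
        assert r1.n_deviations == r2.n_deviations
        np.testing.assert_array_equal(r1.rank_min, r2.rank_min)

    def test_invalid_nsim(self):
        with pytest.raises(ValueError):
            ps.area_envelope_test([1.0, 2.0], self._model(), n_sim=0)
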