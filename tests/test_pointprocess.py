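import numpy as np
import pytest
from scipy.spatial.distance import cdist, pdist

import patchstat as ps
from patchstat.pointprocess import (
    InvalidFitError,
    PointPattern,
    _bt_quadrature,
    isotropic_weight,
)


def brute_pair_count(points, r):
    pts = np.asarray(points)
    c = 0
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            if np.hypot(*(pts[i] - pts[j])) <= r:
                c += 1
    return c


def brute_k(pattern, r_grid, correction):
    pts = pattern.points
    n = pattern.n
    out = np.zeros(len(r_grid))
    for gi, r in enumerate(r_grid):
        acc = 0.0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                d = float(np.hypot(*(pts[i] - pts[j])))
                if d <= r:
                    w = 1.0 if correction == "none" else isotropic_weight(
                        pts[i], d, pattern.window
                    )
                    acc += w
        out[gi] = pattern.window_area / n**2 * acc
    return out


def quadrature_circle_fraction(point, d, window, n_theta=62832):
    """Arc-integration oracle for the inside-window circle fraction."""
    theta = (np.arange(n_theta) + 0.5) * (2 * np.pi / n_theta)
    x = point[0] + d * np.cos(theta)
    y = point[1] + d * np.sin(theta)
    inside = (x >= 0) & (x <= window[0]) & (y >= 0) & (y <= window[1])
    return inside.mean()


class TestPairCount:
    def test_two_points(self):
        pts = [(0.0, 0.0), (1.0, 0.0)]
        assert ps.pair_count(pts, 0.5) == 0
        assert ps.pair_count(pts, 2.0) == 1

    def test_matches_double_loop(self, rng):
        pts = rng.uniform(0, 10, size=(200, 2))
        for r in (0.5, 1.5, 4.0):
            assert ps.pair_count(pts, r) == brute_pair_count(pts, r)


class TestIsotropicWeight:
    def test_interior_point_full_circle(self):
        assert isotropic_weight((5, 5), 2.0, (10, 10)) == pytest.approx(1.0)

    def test_edge_midpoint_half_circle(self):
        assert isotropic_weight((5, 0), 2.0, (10, 10)) == pytest.approx(2.0)

    def test_corner_quarter_circle(self):
        assert isotropic_weight((0, 0), 2.0, (10, 10)) == pytest.approx(4.0)

    def test_matches_arc_quadrature(self, rng):
        window = (10.0, 7.0)
        for _ in range(40):
            p = (rng.uniform(0, 10), rng.uniform(0, 7))
            d = rng.uniform(0.1, 4.0)
            frac = quadrature_circle_fraction(p, d, window)
            if frac <= 0:
                continue
            assert 1.0 / isotropic_weight(p, d, window) == pytest.approx(
                frac, abs=1e-3
            )


class TestKandL:
    def test_two_point_hand_value(self):
        pat = PointPattern(np.array([[0.3, 0.5], [0.7, 0.5]]), (1.0, 1.0))
        k = ps.k_function(pat, [0.5], correction="none")
        # |W|/n^2 * (2 ordered pairs) = 1/4 * 2
        assert k[0] == pytest.approx(0.5)

    def test_matches_brute_force(self, rng):
        pts = rng.uniform(0, 20, size=(40, 2))
        pat = PointPattern(pts, (20.0, 20.0))
        grid = np.array([1.0, 3.0, 5.0])
        for corr in ("none", "isotropic"):
            np.testing.assert_allclose(
                ps.k_function(pat, grid, corr), brute_k(pat, grid, corr), rtol=1e-9
            )

    def test_nondecreasing(self, rng):
        pat = PointPattern(rng.uniform(0, 30, size=(80, 2)), (30.0, 30.0))
        grid = np.linspace(0.1, 10, 60)
        k = ps.k_function(pat, grid)
        assert np.all(np.diff(k) >= 0)

    def test_corrections_agree_for_interior_circles(self):
        # all points far from the border, radii smaller than the margin
        rng = np.random.default_rng(1)
        pts = rng.uniform(40, 60, size=(30, 2))
        pat = PointPattern(pts, (100.0, 100.0))
        grid = np.linspace(1, 5, 10)
        np.testing.assert_allclose(
            ps.k_function(pat, grid, "none"),
            ps.k_function(pat, grid, "isotropic"),
            rtol=1e-12,
        )

    def test_l_transform(self):
        assert ps.l_function([np.pi])[0] == pytest.approx(1.0)
        assert ps.l_function([0.0])[0] == 0.0
        with pytest.raises(ValueError):
            ps.l_function([-1.0])

    def test_csr_l_close_to_r(self):
        """Mean L-hat over Poisson simulations tracks the CSR line L = r."""
        rng = np.random.default_rng(5)
        grid = np.linspace(1, 25, 25)
        acc = np.zeros_like(grid)
        n_sim = 40
        for _ in range(n_sim):
            pts = np.column_stack([rng.uniform(0, 100, 150), rng.uniform(0, 100, 150)])
            pat = PointPattern(pts, (100.0, 100.0))
            acc += ps.l_function(ps.k_function(pat, grid, "isotropic"))
        mean_l = acc / n_sim
        assert np.max(np.abs(mean_l - grid)) < 0.03 * 100


class TestPseudolikelihood:
    def test_poisson_limit_maximised_at_intensity(self):
        pat = ps.simulate_strauss(80, 1.0, 3.0, (40, 40), seed=2)
        lam = pat.n / pat.window_area
        best = ps.strauss_log_pseudolikelihood(pat, lam, 1.0, 3.0)
        for b in (0.8 * lam, 1.25 * lam):
            assert ps.strauss_log_pseudolikelihood(pat, b, 1.0, 3.0) < best

    def test_matches_brute_force(self, rng):
        """Direct double-loop evaluation agrees to 1e-9 relative."""
        for _ in range(10):
            n = int(rng.integers(12, 50))
            pts = rng.uniform(0, 15, size=(n, 2))
            pat = PointPattern(pts, (15.0, 15.0))
            beta, gamma, r = rng.uniform(0.05, 0.5), rng.uniform(0.1, 1.5), 2.0
            mine = ps.strauss_log_pseudolikelihood(pat, beta, gamma, r)
            # brute force with the same quadrature
            dummy, wq, m = _bt_quadrature(pat, 4.0)
            qall = np.vstack([dummy, pts])
            acc = 0.0
            for i in range(n):
                t = sum(
                    1
                    for j in range(n)
                    if j != i and np.hypot(*(pts[i] - pts[j])) <= r
                )
                acc += np.log(beta) + t * np.log(gamma)
            for q in range(qall.shape[0]):
                t = sum(
                    1
                    for j in range(n)
                    if np.hypot(*(qall[q] - pts[j])) <= r
                    and not (q >= m and q - m == j)
                )
                acc -= wq[q] * beta * gamma**t
            assert mine == pytest.approx(acc, rel=1e-9)

    def test_quadrature_convergence(self):
        """Refining the dummy grid converges; doubling moves the value <1%.

        The integrand gamma^t(u) is piecewise constant with circular-arc
        discontinuities, so the midpoint rule converges at O(h); the default
        4x density is accurate to well under a percent and quadrupling the
        density shrinks the error further.
        """
        pat = ps.simulate_strauss(200, 0.5, 2.0, (60, 60), seed=9)
        vals = {
            f: ps.strauss_log_pseudolikelihood(pat, 0.06, 0.5, 2.0, quad_factor=f)
            for f in (4, 8, 64, 256)
        }
        ref = vals[256]
        assert abs(vals[8] - vals[4]) < 0.01 * abs(vals[4])
        assert abs(vals[64] - ref) < abs(vals[4] - ref)
        assert abs(vals[64] - ref) < 2e-3 * abs(ref)

    def test_hard_core_infinities(self):
        pat = ps.simulate_strauss(40, 0.0, 2.0, (40, 40), seed=3)
        finite = ps.strauss_log_pseudolikelihood(pat, 0.05, 0.0, 2.0)
        assert np.isfinite(finite)
        # plant an r-close pair
        pts = np.vstack([pat.points, pat.points[0] + [0.5, 0.0]])
        pat2 = PointPattern(pts, pat.window)
        assert ps.strauss_log_pseudolikelihood(pat2, 0.05, 0.0, 2.0) == -np.inf


class TestFitStrauss:
    def test_fit_value_consistent_with_direct_formula(self):
        pat = ps.simulate_strauss(100, 0.3, 3.0, (60, 60), seed=4)
        fit = ps.fit_strauss(pat, correction="none")
        direct = ps.strauss_log_pseudolikelihood(pat, fit.beta, fit.gamma, fit.r)
        assert fit.log_pseudolikelihood == pytest.approx(direct, rel=1e-6)

    def test_recovery_single_pattern(self):
        pat = ps.simulate_strauss(200, 0.2, 5.0, (100, 100), seed=1)
        fit = ps.fit_strauss(pat)
        assert abs(fit.r - 5.0) <= 1.0
        assert fit.gamma < 0.6
        assert fit.valid

    def test_clustered_pattern_rejected(self):
        """Parent-offspring clustering drives gamma above 1: model rejection."""
        rng = np.random.default_rng(0)
        parents = np.column_stack([rng.uniform(0, 80, 25), rng.uniform(0, 60, 25)])
        pts = np.concatenate([p + rng.normal(0, 1.5, (6, 2)) for p in parents])
        pts = pts[
            (pts[:, 0] >= 0) & (pts[:, 0] <= 80) & (pts[:, 1] >= 0) & (pts[:, 1] <= 60)
        ]
        fit = ps.fit_strauss(PointPattern(pts, (80.0, 60.0)))
        assert fit.gamma > 1.0
        assert not fit.valid

    def test_too_few_points_rejected(self, rng):
        pat = PointPattern(rng.uniform(0, 10, size=(5, 2)), (10.0, 10.0))
        with pytest.raises(ValueError):
            ps.fit_strauss(pat)


class TestSimulation:
    def test_fixed_count_and_determinism(self):
        a = ps.simulate_strauss(60, 0.5, 2.0, (30, 30), seed=11)
        b = ps.simulate_strauss(60, 0.5, 2.0, (30, 30), seed=11)
        assert a.n == 60
        np.testing.assert_array_equal(a.points, b.points)

    def test_hard_core_guarantee(self):
        pat = ps.simulate_strauss(80, 0.0, 2.5, (50, 50), seed=6)
        assert pdist(pat.points).min() >= 2.5

    def test_infeasible_packing_rejected(self):
        with pytest.raises(RuntimeError, match="pack"):
            ps.simulate_strauss(500, 0.0, 5.0, (20, 20), seed=0)

    def test_gamma_one_reduces_to_csr(self):
        """gamma = 1 simulations track the CSR line L = r."""
        grid = np.linspace(1, 12, 12)
        acc = np.zeros_like(grid)
        n_sim = 20
        for s in range(n_sim):
            pat = ps.simulate_strauss(120, 1.0, 3.0, (60, 60), seed=100 + s)
            acc += ps.l_function(ps.k_function(pat, grid, "isotropic"))
        assert np.max(np.abs(acc / n_sim - grid)) < 0.03 * 60

    def test_trace_stabilises(self):
        _, trace = ps.simulate_strauss(
            100, 0.3, 3.0, (60, 60), seed=5, return_trace=True
        )
        # late-chain s(x) fluctuates around a stable level well below the start
        late = trace[len(trace) // 2 :]
        assert late.std() <= trace[: len(trace) // 10].std() + 5


class TestLEnvelope:
    def test_containment_when_data_is_a_simulation(self):
        fitlike = ps.simulate_strauss(80, 0.3, 3.0, (50, 50), seed=21)
        fit = ps.fit_strauss(fitlike, correction="none")
        data = ps.simulate_strauss(
            fit.n, fit.gamma, fit.r, fit.window, seed=303,
            proposals_per_point=2000, burn_in_per_point=500,
        )
        rng = np.random.default_rng(9)
        grid = np.linspace(0.5, 12, 24)
        sims = [
            ps.l_function(
                ps.k_function(
                    ps.simulate_strauss(
                        fit.n, fit.gamma, fit.r, fit.window,
                        seed=int(rng.integers(2**31)),
                        proposals_per_point=2000, burn_in_per_point=500,
                    ),
                    grid,
                    "none",
                )
            )
            for _ in range(15)
        ] + [ps.l_function(ps.k_function(data, grid, "none"))]
        lo, hi = np.min(sims, axis=0), np.max(sims, axis=0)
        ldata = ps.l_function(ps.k_function(data, grid, "none"))
        assert not np.any((ldata < lo) | (ldata > hi))

    def test_refuses_invalid_fit(self):
        rng = np.random.default_rng(0)
        parents = np.column_stack([rng.uniform(0, 80, 25), rng.uniform(0, 60, 25)])
        pts = np.concatenate([p + rng.normal(0, 1.5, (6, 2)) for p in parents])
        pts = pts[
            (pts[:, 0] >= 0) & (pts[:, 0] <= 80) & (pts[:, 1] >= 0) & (pts[:, 1] <= 60)
        ]
        pat = PointPattern(pts, (80.0, 60.0))
        fit = ps.fit_strauss(pat)
        assert not fit.valid
        with pytest.raises(InvalidFitError):
            ps.l_envelope_test(pat, fit)

    def test_clustered_data_exits_hard_core_envelope(self):
        """Planted misfit: clustered data leave a repulsive model's band."""
        rng = np.random.default_rng(3)
        parents = np.column_stack([rng.uniform(5, 55, 12), rng.uniform(5, 45, 12)])
        pts = np.concatenate([p + rng.normal(0, 1.0, (8, 2)) for p in parents])
        pts = np.clip(pts, 0.01, None)
        pts[:, 0] = np.minimum(pts[:, 0], 59.99)
        pts[:, 1] = np.minimum(pts[:, 1], 49.99)
        pat = PointPattern(pts, (60.0, 50.0))
        hard_core_fit = ps.StraussFit(
            beta=pat.intensity, gamma=0.2, r=3.0,
            log_pseudolikelihood=0.0, correction="none", n=pat.n,
            window=pat.window, profile_r=np.array([3.0]),
            profile_pl=np.array([0.0]),
        )
        env = ps.l_envelope_test(
            pat, hard_core_fit, n_sim=19, seed=2,
            r_grid=np.linspace(0.5, 8, 16),
            proposals_per_point=2000, burn_in_per_point=500,
        )
        small_r = env.r_grid <= 4.0
        assert np.any(env.outside[small_r] & (env.l_data > env.env_hi)[small_r])
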