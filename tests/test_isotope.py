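import numpy as np
import pytest
from scipy import stats

from niche_coexist import isotope
from niche_coexist._errors import ContractError, DegenerateDataError, DomainError


def point_set(pts, group="sp"):
    return isotope.IsotopePointSet(group, np.asarray(pts, dtype=float))


@pytest.fixture
def gaussian_cloud():
    rng = np.random.default_rng(42)
    return point_set(rng.multivariate_normal(
        [-24.0, 9.0], [[2.0, 0.4], [0.4, 0.8]], size=50))


class TestLaymanMetrics:
    def test_collinear_worked_example(self):
        m = isotope.layman_metrics(point_set([(0, 0), (1, 0), (3, 0)]))
        assert m.CR == pytest.approx(3.0)
        assert m.NR == pytest.approx(0.0)
        assert m.CD == pytest.approx(1.1111, abs=1e-4)
        assert m.MNND == pytest.approx(1.3333, abs=1e-4)
        assert m.SDNND == pytest.approx(0.5774, abs=1e-4)
        assert m.hull_area == 0.0

    def test_equilateral_triangle_geometry(self):
        h = np.sqrt(3) / 2
        m = isotope.layman_metrics(point_set([(0, 0), (1, 0), (0.5, h)]))
        assert m.CD == pytest.approx(1 / np.sqrt(3), abs=1e-9)
        assert m.MNND == pytest.approx(1.0, abs=1e-9)
        assert m.SDNND == pytest.approx(0.0, abs=1e-9)
        assert m.hull_area == pytest.approx(h / 2, abs=1e-9)

    def test_repeated_single_point_all_zero(self):
        m = isotope.layman_metrics(point_set([(2.0, 3.0)] * 5))
        assert (m.CR, m.NR, m.CD, m.MNND, m.SDNND, m.hull_area) == \
            (0, 0, 0, 0, 0, 0)

    def test_single_point_rejected(self):
        with pytest.raises(DomainError):
            isotope.layman_metrics(point_set([(0, 0)]))

    def test_translation_invariance(self, gaussian_cloud):
        m1 = isotope.layman_metrics(gaussian_cloud)
        shifted = point_set(gaussian_cloud.points + np.array([5.0, -3.0]))
        m2 = isotope.layman_metrics(shifted)
        for field in ("CR", "NR", "CD", "MNND", "SDNND", "hull_area"):
            assert getattr(m1, field) == pytest.approx(
                getattr(m2, field), abs=1e-9)

    def test_cr_nr_not_rotation_invariant(self):
        pts = np.array([(0.0, 0.0), (4.0, 0.0), (2.0, 1.0)])
        theta = np.pi / 4
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        m1 = isotope.layman_metrics(point_set(pts))
        m2 = isotope.layman_metrics(point_set(pts @ rot.T))
        assert m1.CR != pytest.approx(m2.CR, abs=1e-6)


class TestStandardEllipse:
    def test_identity_covariance_gives_pi(self):
        s = np.sqrt(1.5)
        fit = isotope.fit_standard_ellipse(
            point_set([(s, 0), (-s, 0), (0, s), (0, -s)]))
        np.testing.assert_allclose(fit.cov, np.eye(2), atol=1e-12)
        assert fit.SEA == pytest.approx(np.pi, abs=1e-9)
        assert fit.SEAc == pytest.approx(1.5 * np.pi, abs=1e-9)  # n = 4

    def test_sea_rotation_invariant(self, gaussian_cloud):
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        f1 = isotope.fit_standard_ellipse(gaussian_cloud)
        f2 = isotope.fit_standard_ellipse(
            point_set(gaussian_cloud.points @ rot.T))
        assert f1.SEA == pytest.approx(f2.SEA, rel=1e-9)

    def test_seac_exceeds_sea_and_converges(self):
        rng = np.random.default_rng(0)
        pts = rng.multivariate_normal([0, 0], np.diag([4.0, 1.0]), size=10_000)
        fit = isotope.fit_standard_ellipse(point_set(pts))
        assert fit.SEAc > fit.SEA
        assert fit.SEAc == pytest.approx(2 * np.pi, rel=0.05)

    def test_singular_covariance_rejected(self):
        with pytest.raises(DegenerateDataError):
            isotope.fit_standard_ellipse(point_set([(0, 0), (1, 1), (2, 2)]))


class TestPosterior:
    def test_posterior_mean_concentrates(self):
        rng = np.random.default_rng(1)
        pts = rng.multivariate_normal([-20.0, 8.0], np.eye(2), size=10_000)
        post = isotope.posterior_mu_sigma(point_set(pts), n_draws=500, seed=2)
        mu_hat = post.mu.mean(axis=0)
        assert abs(mu_hat[0] + 20.0) < 0.05
        assert abs(mu_hat[1] - 8.0) < 0.05

    def test_same_seed_identical_draws(self, gaussian_cloud):
        p1 = isotope.posterior_mu_sigma(gaussian_cloud, n_draws=50, seed=3)
        p2 = isotope.posterior_mu_sigma(gaussian_cloud, n_draws=50, seed=3)
        np.testing.assert_array_equal(p1.mu, p2.mu)
        np.testing.assert_array_equal(p1.sigma, p2.sigma)

    def test_zero_draws_rejected(self, gaussian_cloud):
        with pytest.raises(ContractError):
            isotope.posterior_mu_sigma(gaussian_cloud, n_draws=0, seed=0)

    def test_sigma_draws_are_spd(self, gaussian_cloud):
        post = isotope.posterior_mu_sigma(gaussian_cloud, n_draws=200, seed=4)
        evals = np.linalg.eigvalsh(post.sigma)
        assert (evals > 0).all()


class TestSeaPosterior:
    def test_stubbed_identity_posterior_constant(self):
        post = isotope.PosteriorDraws.from_fixed([0, 0], np.eye(2),
                                                 n_draws=200)
        out = isotope.sea_posterior(post)
        np.testing.assert_allclose(out["draws"], np.pi, atol=1e-12)
        lo, hi = out["intervals"][0.95]
        assert lo == pytest.approx(np.pi) and hi == pytest.approx(np.pi)

    def test_doubling_sigma_doubles_sea(self):
        p1 = isotope.PosteriorDraws.from_fixed([0, 0], np.eye(2), 200)
        p2 = isotope.PosteriorDraws.from_fixed([0, 0], 2 * np.eye(2), 200)
        s1 = isotope.sea_posterior(p1)["draws"]
        s2 = isotope.sea_posterior(p2)["draws"]
        np.testing.assert_allclose(s2, 2 * s1, rtol=1e-12)

    def test_interval_covers_truth(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            pts = rng.multivariate_normal([0, 0], np.eye(2), size=500)
            post = isotope.posterior_mu_sigma(point_set(pts), n_draws=400,
                                              seed=seed)
            lo, hi = isotope.sea_posterior(post)["intervals"][0.95]
            hits += lo <= np.pi <= hi
        assert hits >= 8

    def test_needs_enough_draws(self):
        post = isotope.PosteriorDraws.from_fixed([0, 0], np.eye(2), 10)
        with pytest.raises(ContractError):
            isotope.sea_posterior(post)


class TestNicheRegion:
    def test_centre_is_member_at_any_level(self):
        for alpha in (0.05, 0.5, 0.95):
            region = isotope.niche_region([1.0, 2.0], np.eye(2), alpha)
            assert region.contains([1.0, 2.0])[0]

    def test_boundary_radius_is_chi2_quantile(self):
        region = isotope.niche_region([0, 0], np.eye(2), 0.95)
        assert region.q == pytest.approx(stats.chi2.ppf(0.95, 2), abs=1e-9)
        assert region.q == pytest.approx(-2 * np.log(0.05), abs=1e-9)
        r = np.sqrt(region.q)
        assert region.contains([r - 1e-9, 0.0])[0]
        assert not region.contains([r + 1e-9, 0.0])[0]

    def test_monte_carlo_membership_fraction(self):
        rng = np.random.default_rng(5)
        sigma = np.array([[2.0, 0.5], [0.5, 1.0]])
        mu = np.array([-24.0, 9.0])
        region = isotope.niche_region(mu, sigma, 0.95)
        z = rng.multivariate_normal(mu, sigma, size=100_000)
        frac = region.contains(z).mean()
        assert abs(frac - 0.95) < 3 * np.sqrt(0.95 * 0.05 / 100_000)

    def test_non_spd_sigma_rejected(self):
        with pytest.raises(DomainError):
            isotope.niche_region([0, 0], np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestOverlapProb:
    def test_distant_species_do_not_overlap(self):
        pa = isotope.PosteriorDraws.from_fixed([0, 0], np.eye(2), 5)
        pb = isotope.PosteriorDraws.from_fixed([100, 0], np.eye(2), 5)
        out = isotope.overlap_prob(pa, pb, n_mc=5000, seed=0)
        assert out.mean < 1e-4

    def test_containment_is_directional(self):
        pa = isotope.PosteriorDraws.from_fixed([0, 0], np.eye(2), 5)
        pb = isotope.PosteriorDraws.from_fixed([0, 0], 4 * np.eye(2), 5)
        ab = isotope.overlap_prob(pa, pb, n_mc=20_000, seed=1)
        ba = isotope.overlap_prob(pb, pa, n_mc=20_000, seed=1)
        assert ab.mean > ba.mean   # small niche sits inside the big one

    def test_draw_count_mismatch_rejected(self):
        pa = isotope.PosteriorDraws.from_fixed([0, 0], np.eye(2), 5)
        pb = isotope.PosteriorDraws.from_fixed([0, 0], np.eye(2), 6)
        with pytest.raises(ContractError):
            isotope.overlap_prob(pa, pb, n_mc=2000, seed=2)


class TestBootstrap:
    def test_identical_points_zero_spread(self):
        ps = point_set([(1.0, 2.0)] * 6)
        for metric in ("CR", "NR", "CD", "MNND", "SDNND"):
            est, sd, ci = isotope.bootstrap_metric(ps, metric, n_boot=200,
                                                   seed=0)
            assert est == 0.0 and sd == 0.0 and ci == (0.0, 0.0)

    def test_two_point_cr_support(self):
        # exhaustive enumeration: of the 4 equally likely resamples of two
        # points, half repeat one point (CR = 0), half keep both (CR = 3)
        ps = point_set([(0.0, 0.0), (3.0, 0.0)])
        est, sd, _ = isotope.bootstrap_metric(ps, "CR", n_boot=4000, seed=1)
        assert est == pytest.approx(3.0)
        # Bernoulli(0.5) scaled by 3: SD = 1.5, up to Monte-Carlo error
        assert sd == pytest.approx(1.5, abs=0.05)

    def test_same_seed_same_interval(self, gaussian_cloud):
        r1 = isotope.bootstrap_metric(gaussian_cloud, "SEAc", n_boot=300,
                                      seed=7)
        r2 = isotope.bootstrap_metric(gaussian_cloud, "SEAc", n_boot=300,
                                      seed=7)
        assert r1[2] == r2[2]

    def test_unknown_metric_rejected(self, gaussian_cloud):
        with pytest.raises(KeyError):
            isotope.bootstrap_metric(gaussian_cloud, "width", seed=0)
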