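import numpy as np
import pytest
from scipy import integrate, stats

from vergebayes import (
    DistancePosterior,
    VergenceNoiseModel,
    error_asymmetry,
    half_vergence_from_distance,
    sample_measured_angle,
    vergence_likelihood_pdf,
)


def _posterior(geom, distance_cm, sigma_deg, truncation="measured"):
    noise = VergenceNoiseModel.from_degrees(sigma_deg)
    theta = half_vergence_from_distance(geom, distance_cm)
    return DistancePosterior(theta, noise, geom, truncation=truncation)


class TestVergenceLikelihood:
    @pytest.mark.parametrize("sigma_deg", [0.25, 1.0, 1.75])
    @pytest.mark.parametrize("distance", [20.0, 60.0, 140.0])
    def test_matches_cdf_ratio_construction(self, geom, sigma_deg, distance):
        """The density must equal normal-pdf / (Phi(b) - Phi(a)) on the support."""
        sigma = np.deg2rad(sigma_deg)
        noise = VergenceNoiseModel(sigma)
        theta_f = half_vergence_from_distance(geom, distance)
        cand = np.linspace(1e-4, np.pi / 2 - 1e-4, 101)
        mass = stats.norm.cdf(np.pi / 2, theta_f, sigma) - stats.norm.cdf(
            0.0, theta_f, sigma
        )
        oracle = stats.norm.pdf(cand, theta_f, sigma) / mass
        np.testing.assert_allclose(
            vergence_likelihood_pdf(noise, theta_f, cand), oracle, atol=1e-10
        )

    @pytest.mark.parametrize("sigma_deg", [0.25, 1.0, 1.75])
    @pytest.mark.parametrize("distance", [20.0, 80.0, 140.0])
    def test_normalised_on_support(self, geom, sigma_deg, distance):
        noise = VergenceNoiseModel.from_degrees(sigma_deg)
        theta_f = half_vergence_from_distance(geom, distance)
        val, _ = integrate.quad(
            lambda t: vergence_likelihood_pdf(noise, theta_f, t),
            0.0,
            np.pi / 2,
            points=[theta_f],
            limit=200,
        )
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_mode_at_true_angle_when_truncation_negligible(self, geom):
        noise = VergenceNoiseModel.from_degrees(0.5)
        theta_f = half_vergence_from_distance(geom, 40.0)
        around = theta_f + np.deg2rad(np.linspace(-2, 2, 201))
        dens = vergence_likelihood_pdf(noise, theta_f, around)
        assert abs(around[np.argmax(dens)] - theta_f) < np.deg2rad(0.03)

    def test_zero_outside_support(self, geom):
        noise = VergenceNoiseModel.from_degrees(1.0)
        theta_f = half_vergence_from_distance(geom, 50.0)
        assert vergence_likelihood_pdf(noise, theta_f, -0.01) == 0.0
        assert vergence_likelihood_pdf(noise, theta_f, np.pi / 2 + 0.01) == 0.0

    def test_true_angle_outside_support_raises(self):
        noise = VergenceNoiseModel.from_degrees(1.0)
        with pytest.raises(ValueError):
            vergence_likelihood_pdf(noise, -0.1, 0.05)


class TestSampling:
    def test_moments_match_closed_form(self, geom):
        noise = VergenceNoiseModel.from_degrees(1.0)
        theta_f = half_vergence_from_distance(geom, 50.0)
        n = 50_000
        draws = sample_measured_angle(noise, theta_f, n, seed=11)
        frozen = noise.frozen(theta_f)
        se = frozen.std() / np.sqrt(n)
        assert abs(draws.mean() - frozen.mean()) < 3 * se

    def test_support_and_reproducibility(self, geom):
        noise = VergenceNoiseModel.from_degrees(1.75)
        theta_f = half_vergence_from_distance(geom, 140.0)
        a = sample_measured_angle(noise, theta_f, 20_000, seed=5)
        b = sample_measured_angle(noise, theta_f, 20_000, seed=5)
        c = sample_measured_angle(noise, theta_f, 20_000, seed=6)
        assert np.all((a > 0) & (a < np.pi / 2))
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)


class TestDistancePosterior:
    def test_pdf_cdf_consistency(self, geom):
        post = _posterior(geom, 50.0, 1.0)
        for d in np.linspace(25, 120, 20):
            num, _ = integrate.quad(post.pdf, 1e-3, d, limit=300)
            assert num == pytest.approx(post.cdf(d), abs=1e-6)

    def test_cdf_limits(self, geom):
        post = _posterior(geom, 50.0, 1.0)
        assert post.cdf(1e-6) < 1e-12
        assert post.cdf(1e7) == pytest.approx(1.0, abs=1e-6)

    def test_empirical_cdf_of_pushed_samples(self, geom):
        """Kolmogorov distance between pushed-forward draws and the analytic CDF."""
        post = _posterior(geom, 50.0, 1.0)
        theta = sample_measured_angle(post.noise, post.measured_angle, 100_000, seed=3)
        d = geom.half_interocular / np.tan(theta)
        ks = stats.kstest(d, post.cdf).statistic
        assert ks < 0.01

    @pytest.mark.parametrize("distance", [30.0, 60.0, 100.0, 140.0])
    def test_positive_skew_ordering(self, geom, distance):
        """mean > median > mode for the pushed-forward density over distance."""
        from vergebayes import posterior_mean, posterior_median, posterior_peak

        post = _posterior(geom, distance, 1.0)
        mean = posterior_mean(post)
        med = posterior_median(post)
        mode = posterior_peak(post)
        assert mean > med > mode

    def test_concentrates_as_noise_vanishes(self, geom):
        widths = []
        for sigma_deg in (0.1, 0.01, 0.001):
            post = _posterior(geom, 50.0, sigma_deg)
            widths.append(post.ppf(0.995) - post.ppf(0.005))
        assert np.all(np.diff(widths) < 0)
        assert widths[-1] < 0.1  # cm, around a 50 cm target

    def test_anchor_variants_coincide_when_truncation_negligible(self, geom):
        # at 30 cm the support boundary is >12 sigma away: both readings of the
        # truncation constant give the same density
        a = _posterior(geom, 30.0, 0.5, truncation="measured")
        b = _posterior(geom, 30.0, 0.5, truncation="candidate")
        d = np.linspace(25, 40, 31)
        np.testing.assert_allclose(a.pdf(d), b.pdf(d), rtol=1e-7)

    def test_candidate_anchor_is_normalised(self, geom):
        # integrate over the full distance domain via the angle substitution
        post = _posterior(geom, 60.0, 1.0, truncation="candidate")
        h = geom.half_interocular
        val, _ = integrate.quad(
            lambda t: post.pdf(h / np.tan(t)) * h / np.sin(t) ** 2,
            1e-9,
            np.pi / 2 - 1e-9,
            points=[post.measured_angle],
            limit=300,
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_domain_errors(self, geom):
        post = _posterior(geom, 50.0, 1.0)
        with pytest.raises(ValueError):
            post.pdf(0.0)
        with pytest.raises(ValueError):
            post.cdf(-3.0)


class TestErrorAsymmetry:
    def test_overestimation_exceeds_underestimation_on_grid(self, geom):
        for distance in np.arange(20.0, 141.0, 10.0):
            theta_f = half_vergence_from_distance(geom, distance)
            for delta_deg in np.arange(0.1, 1.76, 0.15):
                delta = np.deg2rad(delta_deg)
                if delta >= theta_f:
                    continue
                over, under = error_asymmetry(geom, distance, delta)
                assert over > under > 0

    def test_vanishing_delta_limit(self, geom):
        over, under = error_asymmetry(geom, 100.0, 1e-9)
        assert over == pytest.approx(0.0, abs=1e-4)
        assert under == pytest.approx(0.0, abs=1e-4)

    def test_matches_direct_evaluation(self, geom):
        delta = np.deg2rad(1.0)
        theta_f = half_vergence_from_distance(geom, 100.0)
        over, under = error_asymmetry(geom, 100.0, delta)
        h = geom.half_interocular
        assert over == pytest.approx(h / np.tan(theta_f - delta) - 100.0, rel=1e-12)
        assert under == pytest.approx(100.0 - h / np.tan(theta_f + delta), rel=1e-12)
        assert over > 0 and under > 0

    def test_delta_exceeding_angle_raises(self, geom):
        with pytest.raises(ValueError):
            error_asymmetry(geom, 140.0, np.deg2rad(2.0))
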