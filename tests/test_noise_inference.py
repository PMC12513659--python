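import numpy as np
import pandas as pd
import pytest

from vergebayes import (
    EstimateDataset,
    fit_surface,
    infer_sigma,
    peak_grid,
    peak_vs_distance_curve,
    prediction_interval,
)

SIGMAS = np.arange(0.25, 1.76, 0.25)
DISTANCES = np.arange(20.0, 101.0, 10.0)


def _quadratic_grid(coef, noise_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in SIGMAS:
        for d in DISTANCES:
            x = np.array([1.0, s, d, s * s, d * d, s * d])
            rows.append(
                {
                    "sigma_deg": s,
                    "distance_cm": d,
                    "peak_cm": float(x @ coef + noise_sd * rng.normal()),
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="module")
def analytic_surface():
    """Surface through the noise-free MAP curve: smooth, cheap, no Monte Carlo."""
    rows = []
    for s in SIGMAS:
        peaks = peak_vs_distance_curve(np.deg2rad(s), DISTANCES)
        rows.extend(
            {"sigma_deg": s, "distance_cm": d, "peak_cm": p}
            for d, p in zip(DISTANCES, peaks)
        )
    return fit_surface(pd.DataFrame(rows))


COEF = np.array([2.0, -3.0, 1.05, -0.8, -0.001, -0.15])


class TestFitSurface:
    def test_exact_quadratic_recovered(self):
        surf = fit_surface(_quadratic_grid(COEF))
        np.testing.assert_allclose(surf.coefficients, COEF, atol=1e-8)
        assert surf.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        grid = _quadratic_grid(COEF, noise_sd=2.0, seed=3)
        surf = fit_surface(grid)
        s = grid["sigma_deg"].to_numpy()
        d = grid["distance_cm"].to_numpy()
        x = np.column_stack([np.ones_like(s), s, d, s * s, d * d, s * d])
        y = grid["peak_cm"].to_numpy()
        beta = np.linalg.solve(x.T @ x, x.T @ y)
        np.testing.assert_allclose(surf.coefficients, beta, rtol=1e-8)

    def test_rank_deficient_design_is_named(self):
        grid = _quadratic_grid(COEF)
        only_two = grid[grid["sigma_deg"] < 0.6]
        with pytest.raises(ValueError, match="noise"):
            fit_surface(only_two)

    def test_surface_tracks_its_grid(self, analytic_surface):
        g = analytic_surface.grid
        pred = analytic_surface.predict(
            g["sigma_deg"].to_numpy(), g["distance_cm"].to_numpy()
        )
        assert np.corrcoef(pred, g["peak_cm"])[0, 1] > 0.99


class TestInferSigma:
    def test_data_on_a_slice_recovers_that_slice(self, analytic_surface):
        est = analytic_surface.predict(0.75, DISTANCES)
        res = infer_sigma(analytic_surface, EstimateDataset.from_arrays(DISTANCES, est))
        assert res.sigma_hat_deg == pytest.approx(0.75, abs=1e-4)
        assert res.sse < 1e-6
        assert res.r_squared_data > 0.9999
        assert not res.at_boundary

    def test_more_underestimation_implies_more_noise(self, analytic_surface):
        est = analytic_surface.predict(0.75, DISTANCES)
        base = infer_sigma(
            analytic_surface, EstimateDataset.from_arrays(DISTANCES, est)
        ).sigma_hat_deg
        shrunk = infer_sigma(
            analytic_surface, EstimateDataset.from_arrays(DISTANCES, 0.9 * est)
        ).sigma_hat_deg
        assert shrunk > base
        # grid-scan oracle for the shrunk data
        sse = lambda s: float(
            np.sum((0.9 * est - analytic_surface.predict(s, DISTANCES)) ** 2)
        )
        scan = np.linspace(0.25, 1.75, 601)
        oracle = scan[np.argmin([sse(s) for s in scan])]
        assert shrunk == pytest.approx(oracle, abs=0.005)

    def test_boundary_minimum_is_flagged(self, analytic_surface):
        # estimates far above any slice push the minimiser to the low-noise edge
        est = analytic_surface.predict(0.25, DISTANCES) + 20.0
        res = infer_sigma(analytic_surface, EstimateDataset.from_arrays(DISTANCES, est))
        assert res.at_boundary

    def test_out_of_span_distances_rejected(self, analytic_surface):
        data = EstimateDataset.from_arrays([150.0], [120.0])
        with pytest.raises(ValueError, match="span"):
            infer_sigma(analytic_surface, data)

    def test_interpolated_distances_are_fine(self, analytic_surface):
        # data need not sit on the simulated distance grid
        d = np.array([25.0, 47.0, 83.0])
        est = analytic_surface.predict(1.0, d)
        res = infer_sigma(analytic_surface, EstimateDataset.from_arrays(d, est))
        assert res.sigma_hat_deg == pytest.approx(1.0, abs=0.01)


class TestPredictionInterval:
    def test_interval_centred_on_surface(self, analytic_surface):
        pi = prediction_interval(analytic_surface, 1.0, DISTANCES)
        pred = analytic_surface.predict(1.0, DISTANCES)
        np.testing.assert_allclose(pi["predicted_cm"], pred, rtol=1e-10)
        assert np.all(pi["lower_cm"] < pi["predicted_cm"])
        assert np.all(pi["upper_cm"] > pi["predicted_cm"])

    def test_wider_at_grid_edges(self, analytic_surface):
        pi = prediction_interval(analytic_surface, 1.0, [20.0, 60.0, 100.0])
        width = (pi["upper_cm"] - pi["lower_cm"]).to_numpy()
        assert width[0] >= width[1]
        assert width[2] >= width[1]

    def test_coverage_of_held_out_peaks(self):
        """Fresh-seed simulated peaks should fall inside nominal 95% intervals."""
        grid = peak_grid([0.5, 1.0, 1.5], DISTANCES, n_trials=2000, seed=31)
        surf = fit_surface(grid)
        held = peak_grid([0.5, 1.0, 1.5], DISTANCES, n_trials=2000, seed=32)
        inside = 0
        for s in (0.5, 1.0, 1.5):
            pi = prediction_interval(surf, s, DISTANCES)
            obs = held[held["sigma_deg"] == s].sort_values("distance_cm")[
                "peak_cm"
            ].to_numpy()
            inside += int(np.sum((obs >= pi["lower_cm"]) & (obs <= pi["upper_cm"])))
        assert inside / 27 >= 0.9


class TestEstimateDatasetIO:
    def test_round_trip_with_provenance_header(self, tmp_path):
        ds = EstimateDataset.from_arrays([20.0, 30.0], [19.5, 28.8], [1.2, 2.0])
        path = tmp_path / "data.csv"
        ds.to_csv(path, header_comment="synthetic example\nseed=1")
        text = path.read_text()
        assert text.startswith("# synthetic example")
        back = EstimateDataset.from_csv(path)
        pd.testing.assert_frame_equal(back.table, ds.table)

    def test_validation(self):
        with pytest.raises(ValueError):
            EstimateDataset.from_arrays([20.0, -1.0], [19.0, 18.0])
        with pytest.raises(ValueError):
            EstimateDataset(pd.DataFrame({"distance_cm": [10.0]}))
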