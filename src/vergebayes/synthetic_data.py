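"""Synthetic behavioural datasets for a manual distance-matching experiment.

The generator emulates the design of classic distance-matching studies:
physical targets on a uniform grid of distances (default 20 to 100 cm in
10 cm steps), many matching trials per distance, and per-distance summary
rows of mean reported distance with its SD -- the form in which such data
are published.  Each simulated trial draws a noisy vergence measurement,
forms the trial's posterior over distance, and reports the posterior peak,
optionally corrupted by additive zero-mean Gaussian report noise truncated
at zero (off by default; response bias is outside the estimation model and
exists here only to stress-test inference robustness).

The per-trial peak is located by a dense grid scan of the posterior density
with parabolic refinement -- deliberately *not* the optimiser used by the
estimation pipeline, so that parameter recovery exercises two independent
routes that share only the geometry and measurement model.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .estimators import DEFAULT_BOUNDS, IntegrationBounds
from .geometry import DEFAULT_GEOMETRY, ViewingGeometry
from .likelihood import VergenceNoiseModel, sample_measured_angle
from .noise_inference import EstimateDataset

__all__ = [
    "ExperimentSpec",
    "generate_dataset",
    "fixture",
    "fixture_names",
    "FIXTURE_REGISTRY",
]


@dataclass(frozen=True)
class ExperimentSpec:
    """Design of one synthetic distance-matching experiment.

    ``sigma_true_deg`` is the vergence noise (degrees) the simulated observer
    actually has; the default 0.79 deg is the noise level a behavioural
    distance-matching dataset implies under this model.  ``report_noise_sd``
    (cm) adds truncated Gaussian report noise and defaults to zero.
    """

    distances: tuple = tuple(range(20, 101, 10))
    trials_per_distance: int = 1000
    sigma_true_deg: float = 0.79
    report_noise_sd: float = 0.0
    seed: int = 0
    summary: str = "mean"

    def __post_init__(self) -> None:
        if len(self.distances) == 0 or any(d <= 0 for d in self.distances):
            raise ValueError("distances must be a nonempty grid of positive lengths")
        if self.trials_per_distance < 1:
            raise ValueError("trials_per_distance must be >= 1")
        if not self.sigma_true_deg > 0:
            raise ValueError("sigma_true_deg must be > 0")
        if self.report_noise_sd < 0:
            raise ValueError("report_noise_sd must be >= 0")
        if self.summary not in ("mean", "peak"):
            raise ValueError(f"summary must be 'mean' or 'peak', got {self.summary!r}")


def _grid_peak_estimates(
    theta_hat: np.ndarray,
    sigma: float,
    geom: ViewingGeometry,
    bounds: IntegrationBounds,
    n_grid: int = 4000,
) -> np.ndarray:
    """Per-trial posterior peaks by dense grid argmax with parabolic refinement.

    Works in the angle domain, where the candidate-anchored log posterior is

        -(theta - theta_hat)^2 / (2 sigma^2) + 2 log sin(theta) - log Z(theta)

    and evaluates it on a shared grid for the whole batch of trials.
    """
    h = geom.half_interocular
    t_lo = np.arctan(h / bounds.upper)
    t_hi = np.arctan(h / bounds.lower)
    grid = np.linspace(t_lo, t_hi, n_grid)
    z = ndtr((np.pi / 2 - grid) / sigma) - ndtr(-grid / sigma)
    base = 2.0 * np.log(np.sin(grid)) - np.log(z)  # trial-independent part
    theta_star = np.empty_like(theta_hat)
    for start in range(0, theta_hat.size, 2000):  # bound the matrix size
        th = theta_hat[start : start + 2000]
        logf = base[None, :] - 0.5 * ((grid[None, :] - th[:, None]) / sigma) ** 2
        idx = np.clip(np.argmax(logf, axis=1), 1, n_grid - 2)
        rows = np.arange(th.size)
        y0, y1, y2 = logf[rows, idx - 1], logf[rows, idx], logf[rows, idx + 1]
        denom = y0 - 2 * y1 + y2
        shift = np.where(np.abs(denom) > 1e-300, 0.5 * (y0 - y2) / denom, 0.0)
        theta_star[start : start + 2000] = grid[idx] + np.clip(shift, -1, 1) * (
            grid[1] - grid[0]
        )
    return h / np.tan(theta_star)


def _kde_peak(values: np.ndarray) -> float:
    """Mode of a Silverman-bandwidth Gaussian KDE by grid argmax with refinement.

    Kept local to this module (plain scipy) so the generator does not share
    code with the response-simulation pipeline it is used to test.
    """
    from scipy.stats import gaussian_kde

    if np.ptp(values) == 0.0:
        return float(values[0])
    kde = gaussian_kde(values, bw_method="silverman")
    grid = np.linspace(values.min(), values.max(), 512)
    dens = kde(grid)
    i = int(np.argmax(dens))
    lo, hi = max(i - 1, 0), min(i + 1, len(grid) - 1)
    fine = np.linspace(grid[lo], grid[hi], 64)
    return float(fine[np.argmax(kde(fine))])


def generate_dataset(
    spec: ExperimentSpec,
    geom: ViewingGeometry = DEFAULT_GEOMETRY,
    bounds: IntegrationBounds = DEFAULT_BOUNDS,
    return_trials: bool = False,
):
    """Simulate one experiment and summarise it as an :class:`EstimateDataset`.

    With ``summary="mean"`` (default) rows are per-distance means of the
    per-trial reports with their SDs -- the mean +- SD form in which
    behavioural distance-matching data are published.  With
    ``summary="peak"`` rows carry the per-distance mode of a kernel density
    over the reports, i.e. the most likely single report, which is the
    quantity the peak surface used for noise inference predicts; because the
    per-trial reports are positively skewed, mean rows sit systematically
    above peak rows and noise inferred from them is correspondingly lower.
    With ``return_trials=True`` also returns the long per-trial table
    (``distance_cm``, ``trial``, ``estimate_cm``).
    """
    sigma = np.deg2rad(spec.sigma_true_deg)
    noise = VergenceNoiseModel(sigma)
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(len(spec.distances))
    rows = []
    trials = []
    for dist, child in zip(spec.distances, children):
        rng = np.random.default_rng(child)
        theta_f = np.arctan(geom.half_interocular / dist)
        theta_hat = sample_measured_angle(noise, theta_f, spec.trials_per_distance, rng)
        est = _grid_peak_estimates(np.asarray(theta_hat), sigma, geom, bounds)
        if spec.report_noise_sd > 0:
            # additive zero-mean Gaussian report noise, responses kept positive
            u = rng.uniform(size=est.size)
            lo_cdf = ndtr(-est / spec.report_noise_sd)
            z = ndtri(lo_cdf + u * (1.0 - lo_cdf))
            est = est + spec.report_noise_sd * z
        central = float(np.mean(est)) if spec.summary == "mean" else _kde_peak(est)
        rows.append(
            {
                "distance_cm": float(dist),
                "estimate_cm": central,
                "sd_cm": float(np.std(est, ddof=1)) if est.size > 1 else 0.0,
            }
        )
        if return_trials:
            trials.append(
                pd.DataFrame(
                    {
                        "distance_cm": float(dist),
                        "trial": np.arange(est.size),
                        "estimate_cm": est,
                    }
                )
            )
    dataset = EstimateDataset(pd.DataFrame(rows))
    if return_trials:
        return dataset, pd.concat(trials, ignore_index=True)
    return dataset


# --------------------------------------------------------------------------
# packaged fixtures

_FIXTURE_KW = dict(trials_per_distance=2000, summary="peak")

FIXTURE_REGISTRY: dict[str, ExperimentSpec] = {
    # the noise level a behavioural distance-matching dataset implies under
    # this model; peak-summarised so the rows carry the quantity the peak
    # surface predicts
    "viguier_like_sigma079": ExperimentSpec(sigma_true_deg=0.79, seed=79, **_FIXTURE_KW),
    "low_noise_sigma025": ExperimentSpec(sigma_true_deg=0.25, seed=25, **_FIXTURE_KW),
    "high_noise_sigma175": ExperimentSpec(sigma_true_deg=1.75, seed=175, **_FIXTURE_KW),
}


def fixture(name: str) -> EstimateDataset:
    """Load a packaged, seeded synthetic dataset by name.

    The files ship with the package (see :func:`regenerate_fixtures`) so a
    reload is byte-identical across runs.  Unknown names raise with the list
    of available fixtures.
    """
    if name not in FIXTURE_REGISTRY:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURE_REGISTRY)}"
        )
    path = resources.files("vergebayes").joinpath(f"data/{name}.csv")
    with resources.as_file(path) as p:
        return EstimateDataset.from_csv(p)


def fixture_names() -> list[str]:
    return sorted(FIXTURE_REGISTRY)


def regenerate_fixtures(out_dir) -> list[Path]:
    """Regenerate every registry fixture into ``out_dir`` (deterministic)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, spec in FIXTURE_REGISTRY.items():
        ds = generate_dataset(spec)
        path = out_dir / f"{name}.csv"
        header = (
            f"synthetic distance-matching dataset '{name}'\n"
            f"generator: vergebayes.synthetic_data.generate_dataset\n"
            f"sigma_true_deg={spec.sigma_true_deg} trials_per_distance="
            f"{spec.trials_per_distance} report_noise_sd={spec.report_noise_sd} "
            f"summary={spec.summary} seed={spec.seed}"
        )
        ds.to_csv(path, header_comment=header)
        written.append(path)
    return written
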