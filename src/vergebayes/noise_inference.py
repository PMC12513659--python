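"""Inference of the vergence noise level from behavioural distance estimates.

Simulated response-distribution peaks over a (noise, distance) grid are
summarised by an ordinary-least-squares quadratic surface in the noise level
``s`` (degrees) and the physical distance ``d`` (cm) -- terms 1, s, d, s^2,
d^2, sd.  The quadratic is a deliberately simple description of the peak
surface, not a model in its own right.  A behavioural dataset of
(distance, estimate) pairs is then positioned along the continuous noise axis
by minimising the sum of squared differences between the reported estimates
and the surface; the minimising ``s`` is the vergence noise the model needs
to reproduce the observed pattern of distance misestimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize

__all__ = [
    "PeakSurface",
    "EstimateDataset",
    "NoiseFitResult",
    "fit_surface",
    "infer_sigma",
    "prediction_interval",
]

_TERMS = ("const", "sigma", "distance", "sigma^2", "distance^2", "sigma*distance")


def _design(sigma_deg, distance_cm) -> np.ndarray:
    s = np.asarray(sigma_deg, dtype=float)
    d = np.asarray(distance_cm, dtype=float)
    s, d = np.broadcast_arrays(s, d)
    return np.column_stack(
        [np.ones_like(s), s, d, s * s, d * d, s * d]
    )


@dataclass(frozen=True)
class PeakSurface:
    """Quadratic surface fitted to simulated response-distribution peaks.

    ``coefficients`` are in the term order 1, s, d, s^2, d^2, sd with ``s``
    the noise level in degrees and ``d`` the distance in cm.
    """

    grid: pd.DataFrame = field(repr=False)
    coefficients: np.ndarray
    r_squared: float
    _results: object = field(repr=False, compare=False, default=None)

    @property
    def sigma_span(self) -> tuple[float, float]:
        s = self.grid["sigma_deg"]
        return float(s.min()), float(s.max())

    @property
    def distance_span(self) -> tuple[float, float]:
        d = self.grid["distance_cm"]
        return float(d.min()), float(d.max())

    def predict(self, sigma_deg, distance_cm):
        out = _design(sigma_deg, distance_cm) @ self.coefficients
        return out if (np.ndim(sigma_deg) or np.ndim(distance_cm)) else float(out[0])


def fit_surface(grid: pd.DataFrame) -> PeakSurface:
    """Ordinary-least-squares quadratic surface through a peak grid.

    ``grid`` needs columns ``sigma_deg``, ``distance_cm``, ``peak_cm`` and at
    least three distinct values on each axis; otherwise the quadratic design
    is rank-deficient and the offending axis is named in the error.
    """
    for col in ("sigma_deg", "distance_cm", "peak_cm"):
        if col not in grid.columns:
            raise ValueError(f"grid is missing column {col!r}")
    for col, label in (("sigma_deg", "noise"), ("distance_cm", "distance")):
        if grid[col].nunique() < 3:
            raise ValueError(
                f"need >= 3 distinct {label} values to identify the quadratic "
                f"surface, got {grid[col].nunique()}"
            )
    x = _design(grid["sigma_deg"].to_numpy(), grid["distance_cm"].to_numpy())
    y = grid["peak_cm"].to_numpy(dtype=float)
    results = sm.OLS(y, x).fit()
    return PeakSurface(
        grid=grid.reset_index(drop=True),
        coefficients=np.asarray(results.params, dtype=float),
        r_squared=float(results.rsquared),
        _results=results,
    )


@dataclass(frozen=True)
class EstimateDataset:
    """Rows of (true distance, reported estimate, optional SD), all in cm.

    The on-disk form is delimited text with header
    ``distance_cm,estimate_cm,sd_cm`` (``sd_cm`` optional) and ``#`` comment
    lines for provenance.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        for col in ("distance_cm", "estimate_cm"):
            if col not in t.columns:
                raise ValueError(f"dataset is missing column {col!r}")
            if np.any(t[col].to_numpy(dtype=float) <= 0):
                raise ValueError(f"all {col} values must be > 0")
        if "sd_cm" not in t.columns:
            object.__setattr__(self, "table", t.assign(sd_cm=np.nan))

    def __len__(self) -> int:
        return len(self.table)

    @property
    def distances(self) -> np.ndarray:
        return self.table["distance_cm"].to_numpy(dtype=float)

    @property
    def estimates(self) -> np.ndarray:
        return self.table["estimate_cm"].to_numpy(dtype=float)

    @classmethod
    def from_arrays(cls, distances, estimates, sds=None) -> "EstimateDataset":
        frame = pd.DataFrame(
            {
                "distance_cm": np.asarray(distances, dtype=float),
                "estimate_cm": np.asarray(estimates, dtype=float),
            }
        )
        frame["sd_cm"] = np.nan if sds is None else np.asarray(sds, dtype=float)
        return cls(frame)

    @classmethod
    def from_csv(cls, path) -> "EstimateDataset":
        frame = pd.read_csv(path, comment="#")
        return cls(frame)

    def to_csv(self, path, header_comment: str | None = None) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            if header_comment:
                for line in header_comment.splitlines():
                    fh.write(f"# {line}\n")
            self.table.to_csv(fh, index=False, float_format="%.6f")


@dataclass(frozen=True)
class NoiseFitResult:
    """Outcome of positioning a dataset on the noise axis of a peak surface."""

    sigma_hat_deg: float
    sse: float
    r_squared_data: float
    at_boundary: bool
    sigma_bounds: tuple[float, float]


def infer_sigma(
    surface: PeakSurface, data: EstimateDataset, weighted: bool = False
) -> NoiseFitResult:
    """Vergence noise minimising the data-to-surface sum of squared differences.

    The noise axis is treated as continuous within the simulated span; data
    distances are evaluated on the surface at their own values (per-datapoint
    interpolation).  By default the SSE is unweighted; ``weighted=True``
    weights rows by 1/sd^2 where SDs are available.  A minimum at the edge of
    the simulated noise span is flagged ``at_boundary``.
    """
    d_lo, d_hi = surface.distance_span
    if np.any(data.distances < d_lo) or np.any(data.distances > d_hi):
        raise ValueError(
            "data distances fall outside the surface's simulated distance span "
            f"[{d_lo}, {d_hi}] cm"
        )
    s_lo, s_hi = surface.sigma_span
    w = np.ones(len(data))
    if weighted:
        sd = data.table["sd_cm"].to_numpy(dtype=float)
        ok = np.isfinite(sd) & (sd > 0)
        w = np.where(ok, 1.0 / np.where(ok, sd, 1.0) ** 2, 1.0)

    def sse(s):
        resid = data.estimates - surface.predict(s, data.distances)
        return float(np.sum(w * resid * resid))

    res = optimize.minimize_scalar(
        sse, bounds=(s_lo, s_hi), method="bounded", options={"xatol": 1e-6}
    )
    sigma_hat = float(res.x)
    tol = 1e-3 * (s_hi - s_lo)
    at_boundary = sigma_hat - s_lo < tol or s_hi - sigma_hat < tol
    resid = data.estimates - surface.predict(sigma_hat, data.distances)
    ss_res = float(np.sum(resid * resid))
    ss_tot = float(np.sum((data.estimates - data.estimates.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return NoiseFitResult(
        sigma_hat_deg=sigma_hat,
        sse=float(res.fun),
        r_squared_data=r2,
        at_boundary=bool(at_boundary),
        sigma_bounds=(s_lo, s_hi),
    )


def prediction_interval(
    surface: PeakSurface, sigma_deg: float, distances, alpha: float = 0.05
) -> pd.DataFrame:
    """Single-prediction intervals along one noise slice of the surface.

    Standard OLS prediction intervals for a *new* observation (residual plus
    leverage variance), widening towards the edges of the fitted grid.
    Returns a DataFrame with columns ``distance_cm``, ``predicted_cm``,
    ``lower_cm``, ``upper_cm``.
    """
    if surface._results is None:
        raise ValueError("surface carries no fitted model; use fit_surface")
    d = np.atleast_1d(np.asarray(distances, dtype=float))
    exog = _design(np.full_like(d, float(sigma_deg)), d)
    pred = surface._results.get_prediction(exog).summary_frame(alpha=alpha)
    return pd.DataFrame(
        {
            "distance_cm": d,
            "predicted_cm": pred["mean"].to_numpy(),
            "lower_cm": pred["obs_ci_lower"].to_numpy(),
            "upper_cm": pred["obs_ci_upper"].to_numpy(),
        }
    )
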