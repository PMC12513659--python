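"""Noisy vergence measurement model and its push-forward over distance.

The measured half-vergence angle is modelled as an unbiased Gaussian-noise
corrupted reading of the true angle, truncated to the physically possible
range (0, pi/2):

    theta_hat ~ N(theta_F, sigma^2)  restricted to  0 < theta_hat < pi/2.

Because distance is a strictly decreasing nonlinear function of the angle,
``D = h / tan(theta)``, the induced density over distance is the
change-of-variables push-forward of the truncated normal, with Jacobian
``h / (h^2 + D^2)``.  The push-forward is positively skewed in distance: a
symmetric angular error corresponds to a larger overestimation than
underestimation error in centimetres.  Under a flat distance prior this
push-forward *is* the posterior over distance.

Two parameterisations of the truncation constant are exposed, because the
normalising constant of the truncated normal can be anchored either at the
distribution's centre (giving the exact push-forward density of
``h / tan(theta_hat)``, with a closed-form CDF) or at the candidate angle
being scanned (the form obtained when the truncated-normal formula is read
off with the candidate distance's own angle inside the constants).  The two
coincide wherever the truncation mass is negligible; both are retained so the
trial-level simulator can use the candidate-anchored form while estimators
use the closed-form CDF.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
from scipy import integrate
from scipy import stats
from scipy.special import ndtr

from .geometry import (
    DEFAULT_GEOMETRY,
    ViewingGeometry,
    distance_from_half_vergence,
    half_vergence_from_distance,
)

__all__ = [
    "VergenceNoiseModel",
    "DistancePosterior",
    "vergence_likelihood_pdf",
    "sample_measured_angle",
    "distance_posterior_pdf",
    "distance_posterior_cdf",
    "error_asymmetry",
]


@dataclass(frozen=True)
class VergenceNoiseModel:
    """Zero-mean Gaussian noise on the half-vergence angle, truncated to its support.

    Parameters
    ----------
    sigma
        Standard deviation of the angular noise, radians.  The behavioural
        literature quotes this in degrees; use :meth:`from_degrees` there.
    support
        Open interval of physically possible half-vergence angles, default
        (0, pi/2).
    """

    sigma: float
    support: tuple[float, float] = (0.0, np.pi / 2)

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        lo, hi = self.support
        if not lo < hi:
            raise ValueError(f"invalid support {self.support}")

    @classmethod
    def from_degrees(cls, sigma_deg: float, support=(0.0, np.pi / 2)) -> "VergenceNoiseModel":
        return cls(np.deg2rad(sigma_deg), support)

    @property
    def sigma_deg(self) -> float:
        return float(np.rad2deg(self.sigma))

    def frozen(self, center: float):
        """Frozen scipy truncated normal centred on ``center``."""
        lo, hi = self.support
        a = (lo - center) / self.sigma
        b = (hi - center) / self.sigma
        return stats.truncnorm(a, b, loc=center, scale=self.sigma)

    def truncation_mass(self, center: float) -> float:
        """Probability mass an untruncated normal at ``center`` would place outside the support."""
        lo, hi = self.support
        return float(
            ndtr((lo - center) / self.sigma) + 1.0 - ndtr((hi - center) / self.sigma)
        )


def vergence_likelihood_pdf(noise: VergenceNoiseModel, true_angle: float, candidate_angle):
    """Truncated-normal likelihood density of a measured angle given the true angle.

    Density per radian; zero outside the support.  ``true_angle`` must lie
    inside the support.
    """
    lo, hi = noise.support
    if not lo < true_angle < hi:
        raise ValueError(f"true_angle {true_angle} outside support {noise.support}")
    out = noise.frozen(true_angle).pdf(np.asarray(candidate_angle, dtype=float))
    return out if np.ndim(candidate_angle) else float(out)


def sample_measured_angle(noise: VergenceNoiseModel, true_angle: float, n: int, seed):
    """Draw ``n`` i.i.d. measured angles via inverse-CDF sampling.

    ``seed`` is required (an int, :class:`numpy.random.SeedSequence`, or
    :class:`numpy.random.Generator`); no global RNG state is used.  All draws
    lie strictly inside the support.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = noise.support
    if not lo < true_angle < hi:
        raise ValueError(f"true_angle {true_angle} outside support {noise.support}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.uniform(size=int(n))
    return noise.frozen(true_angle).ppf(u)


def _log_trunc_const(theta, sigma, support):
    """log of the truncated-normal normalising mass anchored at ``theta``."""
    lo, hi = support
    z = ndtr((hi - theta) / sigma) - ndtr((lo - theta) / sigma)
    return np.log(z)


@dataclass(frozen=True)
class DistancePosterior:
    """Density over fixation distance induced by one measured vergence angle.

    With a flat distance prior, the posterior over ``D`` is the truncated
    normal pushed through ``D = h / tan(theta)``:

        p(D) = TN(atan(h / D); centre, sigma) * h / (h^2 + D^2)

    ``truncation="measured"`` (default) anchors the truncation constant at the
    measured angle, giving the exact push-forward density of
    ``h / tan(theta_hat)`` with closed-form CDF and quantiles.
    ``truncation="candidate"`` anchors the constant at the candidate angle
    ``atan(h / D)``, the per-trial form used by the response simulator; its
    CDF is computed by quadrature on the (finite) angle domain.
    """

    measured_angle: float
    noise: VergenceNoiseModel
    geom: ViewingGeometry = DEFAULT_GEOMETRY
    truncation: str = "measured"

    def __post_init__(self) -> None:
        lo, hi = self.noise.support
        if not lo < self.measured_angle < hi:
            raise ValueError(
                f"measured_angle {self.measured_angle} outside support {self.noise.support}"
            )
        if self.truncation not in ("measured", "candidate"):
            raise ValueError(f"unknown truncation anchor {self.truncation!r}")

    # -- angle <-> distance -------------------------------------------------
    def angle_of(self, distance):
        return half_vergence_from_distance(self.geom, distance)

    @property
    def point_inverse(self) -> float:
        """Noise-free inversion ``h / tan(theta_hat)`` of the measured angle (cm)."""
        return distance_from_half_vergence(self.geom, self.measured_angle)

    # -- densities ----------------------------------------------------------
    def _theta_logpdf(self, theta):
        """Log density over the *angle* domain (per radian)."""
        sig = self.noise.sigma
        lo, hi = self.noise.support
        logphi = -0.5 * ((theta - self.measured_angle) / sig) ** 2 - np.log(
            sig * np.sqrt(2 * np.pi)
        )
        anchor = theta if self.truncation == "candidate" else self.measured_angle
        out = logphi - _log_trunc_const(anchor, sig, self.noise.support)
        return np.where((theta > lo) & (theta < hi), out, -np.inf)

    @cached_property
    def _norm(self) -> float:
        """Total mass of the (possibly unnormalised) angle density."""
        if self.truncation == "measured":
            return 1.0
        lo, hi = self.noise.support
        val, _ = integrate.quad(
            lambda t: np.exp(self._theta_logpdf(t)),
            lo,
            hi,
            points=[self.measured_angle],
            limit=200,
            epsabs=1e-12,
            epsrel=1e-10,
        )
        return float(val)

    def pdf(self, distance):
        """Posterior density over distance (per cm)."""
        d = np.asarray(distance, dtype=float)
        if np.any(d <= 0):
            raise ValueError("distance must be strictly positive")
        h = self.geom.half_interocular
        theta = np.arctan(h / d)
        jac = h / (h * h + d * d)
        out = np.exp(self._theta_logpdf(theta)) * jac / self._norm
        return out if out.ndim else float(out)

    def cdf(self, distance):
        """P(D <= distance).

        Distance decreases in angle, so the distance CDF is one minus the
        angle CDF evaluated at ``atan(h / D)``.
        """
        d = np.asarray(distance, dtype=float)
        if np.any(d <= 0):
            raise ValueError("distance must be strictly positive")
        theta = np.arctan(self.geom.half_interocular / d)
        if self.truncation == "measured":
            out = 1.0 - self.noise.frozen(self.measured_angle).cdf(theta)
        else:
            lo, hi = self.noise.support
            flat = np.atleast_1d(theta)
            vals = np.empty_like(flat)
            for i, t in enumerate(flat):
                v, _ = integrate.quad(
                    lambda x: np.exp(self._theta_logpdf(x)),
                    t,
                    hi,
                    points=[self.measured_angle] if lo < self.measured_angle < hi else None,
                    limit=200,
                    epsabs=1e-12,
                    epsrel=1e-10,
                )
                vals[i] = v / self._norm
            out = vals.reshape(np.shape(theta))
        return out if np.ndim(out) else float(out)

    def ppf(self, q):
        """Distance quantile function (closed form for the measured anchor)."""
        if self.truncation != "measured":
            raise NotImplementedError(
                "closed-form quantiles exist only for the measured anchor"
            )
        qq = np.asarray(q, dtype=float)
        theta = self.noise.frozen(self.measured_angle).ppf(1.0 - qq)
        out = self.geom.half_interocular / np.tan(theta)
        return out if out.ndim else float(out)


def distance_posterior_pdf(post: DistancePosterior, candidate_distance):
    return post.pdf(candidate_distance)


def distance_posterior_cdf(post: DistancePosterior, candidate_distance):
    return post.cdf(candidate_distance)


def error_asymmetry(geom: ViewingGeometry, true_distance: float, delta: float):
    """Distance errors produced by a symmetric angular error ``delta``.

    Returns ``(overestimation, underestimation)``:

        over  = h / tan(theta_F - delta) - D_F
        under = D_F - h / tan(theta_F + delta)

    The overestimation error is strictly the larger of the two for any
    ``0 < delta < theta_F``, which is why the push-forward density over
    distance is positively skewed.
    """
    theta_f = half_vergence_from_distance(geom, true_distance)
    if not 0 < delta < theta_f:
        raise ValueError(f"delta must satisfy 0 < delta < theta_F ({theta_f:.6f} rad)")
    h = geom.half_interocular
    over = h / np.tan(theta_f - delta) - true_distance
    under = true_distance - h / np.tan(theta_f + delta)
    return float(over), float(under)
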