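"""Prior transforms between world distances and vergence angles.

Three analyses live here, all downstream of the estimation model rather than
inside it (the posterior itself assumes a flat distance prior):

* converting an empirical sample of world distances into the corresponding
  "vergence prior" through ``theta = atan(h / D)``;
* the closed-form distance density that a *flat* vergence prior on an angle
  interval (a, b) implies, ``p(D) = h / ((b - a) (h^2 + D^2))`` -- monotone
  decreasing, peaked towards zero distance;
* the "internalised" prior: the distribution of *perceived* distances
  obtained by pushing world distances through the model's physical-to-
  perceived mapping, which compresses far distances toward near ones.

A simplified synthetic-scene sampler stands in for a scanned-object corpus:
spheres of random radius are placed without overlap on a square ground
plane, points are sampled on their surfaces, and only points visible to both
eyes (sphere-occlusion test from each eye position) contribute radial
distances from the cyclopean eye.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .estimators import DEFAULT_BOUNDS, IntegrationBounds, map_estimate
from .geometry import DEFAULT_GEOMETRY, ViewingGeometry

__all__ = [
    "DistanceSample",
    "FlatVergencePriorSpec",
    "SceneSpec",
    "vergence_prior_from_distances",
    "flat_vergence_distance_pdf",
    "sample_flat_vergence_distances",
    "internalised_prior",
    "synthetic_scene_distances",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DistanceSample:
    """A sample of radial distances (cm) from the cyclopean eye."""

    distances: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        object.__setattr__(self, "distances", d)
        if d.ndim != 1:
            raise ValueError("distances must be one-dimensional")
        if d.size and np.any(d <= 0):
            bad = int(np.flatnonzero(d <= 0)[0])
            raise ValueError(f"non-positive distance at row {bad}")

    def __len__(self) -> int:
        return self.distances.size


def vergence_prior_from_distances(sample, geom: ViewingGeometry = DEFAULT_GEOMETRY):
    """Half-vergence angles produced by fixating each distance in the sample.

    Elementwise ``atan(h / D)``; output lies in (0, pi/2) and reverses the
    ordering of the distances.
    """
    d = sample.distances if isinstance(sample, DistanceSample) else np.asarray(sample, float)
    if d.size == 0:
        raise ValueError("sample is empty")
    if np.any(d <= 0):
        bad = int(np.flatnonzero(d <= 0)[0])
        raise ValueError(f"non-positive distance at row {bad}")
    return np.arctan(geom.half_interocular / d)


@dataclass(frozen=True)
class FlatVergencePriorSpec:
    """A uniform prior over half-vergence angles on (a, b), with base length h (cm)."""

    a: float = 0.0
    b: float = np.pi / 2
    h: float = DEFAULT_GEOMETRY.half_interocular

    def __post_init__(self) -> None:
        if not (0 <= self.a < self.b <= np.pi / 2):
            raise ValueError(f"require 0 <= a < b <= pi/2, got a={self.a}, b={self.b}")
        if not self.h > 0:
            raise ValueError("h must be > 0")

    @property
    def distance_support(self) -> tuple[float, float]:
        """Image of (a, b) under ``D = h / tan(theta)`` (far bound may be inf)."""
        lo = self.h / np.tan(self.b) if self.b < np.pi / 2 else 0.0
        hi = self.h / np.tan(self.a) if self.a > 0 else np.inf
        return float(lo), float(hi)


def flat_vergence_distance_pdf(spec: FlatVergencePriorSpec, distance):
    """Distance density implied by a flat vergence prior on (a, b).

    ``p(D) = h / ((b - a) (h^2 + D^2))`` on the image of (a, b), zero
    outside.  For a = 0, b = pi/2 the support is (0, inf), the density
    integrates to one exactly, and it decreases strictly with distance, so
    near distances are a priori far more probable than far ones.
    """
    d = np.asarray(distance, dtype=float)
    lo, hi = spec.distance_support
    dens = spec.h / ((spec.b - spec.a) * (spec.h**2 + d**2))
    out = np.where((d > lo) & (d < hi), dens, 0.0)
    return out if out.ndim else float(out)


def sample_flat_vergence_distances(spec: FlatVergencePriorSpec, n: int, seed) -> DistanceSample:
    """Sample distances whose induced vergence angles are uniform on (a, b)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    theta = rng.uniform(spec.a, spec.b, size=int(n))
    # guard the closed endpoints (zero-probability draws)
    eps = np.finfo(float).tiny
    theta = np.clip(theta, eps, np.pi / 2 - 1e-15)
    return DistanceSample(spec.h / np.tan(theta))


def internalised_prior(
    sample: DistanceSample,
    sigma: float | None = None,
    mapping=None,
    geom: ViewingGeometry = DEFAULT_GEOMETRY,
    bounds: IntegrationBounds | None = None,
) -> DistanceSample:
    """World distances pushed through the physical-to-perceived mapping.

    By default the mapping is the noise-free MAP curve at vergence noise
    ``sigma``: each distance is replaced by the peak of the posterior whose
    measured angle is that distance's true angle.  Any callable mapping an
    array of distances to perceived distances may be supplied instead.
    Rows where the mapping is undefined (non-finite output) are dropped and
    the count logged.  Because the MAP underestimates far distances, the
    mapped sample's mean and upper quantiles contract toward near space.
    """
    if mapping is None:
        if sigma is None:
            raise ValueError("provide sigma for the default MAP mapping, or a mapping")
        b = bounds if bounds is not None else DEFAULT_BOUNDS

        def mapping(d):
            theta = np.arctan(geom.half_interocular / np.asarray(d, dtype=float))
            return map_estimate(theta, sigma, geom, b, truncation="measured")

    mapped = np.asarray(mapping(sample.distances), dtype=float)
    if mapped.shape != sample.distances.shape:
        raise ValueError("mapping must return one perceived distance per input distance")
    ok = np.isfinite(mapped) & (mapped > 0)
    dropped = int(np.sum(~ok))
    if dropped:
        log.warning("internalised_prior: dropped %d rows with undefined mapping", dropped)
    return DistanceSample(mapped[ok])


# --------------------------------------------------------------------------
# synthetic scene sampler


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of the sphere-scene stand-in for a scanned-object corpus.

    Spheres rest on a square ground plane (side ``plane_size`` cm, centred at
    the origin of the x-z floor plane, y up).  The observer's cyclopean eye
    sits at ``observer`` (cm) relative to the plane centre with the eyes
    displaced ``+-interocular/2`` along x.
    """

    n_objects: int = 14
    radius_range: tuple[float, float] = (1.5, 4.0)
    plane_size: float = 35.0
    n_scenes: int = 20
    points_per_object: int = 200
    observer: tuple[float, float, float] = (0.0, 8.0, 60.0)
    interocular: float = 6.5
    max_scene_attempts: int = 200
    max_place_attempts: int = 50

    def __post_init__(self) -> None:
        r_lo, r_hi = self.radius_range
        if not 0 < r_lo <= r_hi:
            raise ValueError("radius_range must satisfy 0 < lo <= hi")
        if 2 * r_hi > self.plane_size:
            raise ValueError("largest object cannot fit on the plane")
        if self.n_objects < 0:
            raise ValueError("n_objects must be >= 0")


def _place_spheres(spec: SceneSpec, rng: np.random.Generator):
    """Sequentially place non-overlapping bounding circles; None on failure."""
    half = spec.plane_size / 2.0
    centers = np.empty((spec.n_objects, 2))
    radii = np.empty(spec.n_objects)
    for i in range(spec.n_objects):
        r = rng.uniform(*spec.radius_range)
        placed = False
        for _ in range(spec.max_place_attempts):
            xy = rng.uniform(-(half - r), half - r, size=2)
            if i == 0 or np.all(
                np.hypot(*(centers[:i] - xy).T) >= radii[:i] + r
            ):
                centers[i] = xy
                radii[i] = r
                placed = True
                break
        if not placed:
            return None
    return centers, radii


def _segment_occluded(origins, points, sphere_centers, sphere_radii):
    """Whether the segment from an eye to each point is blocked by any sphere.

    Vectorised ray-sphere intersection; a hit strictly before the endpoint
    (including the point's own sphere, i.e. self-occlusion by the far side)
    counts as blocked.
    """
    u = points - origins  # (M, 3)
    seg_len = np.linalg.norm(u, axis=1, keepdims=True)
    u = u / seg_len
    o = np.broadcast_to(origins, points.shape)
    occluded = np.zeros(points.shape[0], dtype=bool)
    eps = 1e-6
    for c, r in zip(sphere_centers, sphere_radii):
        oc = o - c  # (M, 3)
        b = np.einsum("ij,ij->i", u, oc)
        q = np.einsum("ij,ij->i", oc, oc) - r * r
        disc = b * b - q
        hit = disc > 0
        sq = np.sqrt(np.where(hit, disc, 0.0))
        t1 = -b - sq
        t2 = -b + sq
        limit = seg_len[:, 0] - eps
        occluded |= hit & (
            ((t1 > eps) & (t1 < limit)) | ((t2 > eps) & (t2 < limit))
        )
    return occluded


def synthetic_scene_distances(spec: SceneSpec, seed) -> DistanceSample:
    """Radial distances of binocularly visible surface points in random scenes.

    For each scene, spheres are placed by sequential rejection (a scene where
    not all objects fit is discarded and redrawn); points are sampled
    uniformly on each sphere's surface; a point is kept only if the open
    segment to *each* eye is unobstructed by every sphere, its own included.
    Returns the distances from the cyclopean eye across all scenes.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if spec.n_objects == 0 or spec.n_scenes == 0:
        return DistanceSample(np.empty(0))
    h = spec.interocular / 2.0
    cyclopean = np.asarray(spec.observer, dtype=float)
    eyes = np.array([cyclopean + [-h, 0, 0], cyclopean + [h, 0, 0]])
    all_d = []
    for _ in range(spec.n_scenes):
        placement = None
        for _ in range(spec.max_scene_attempts):
            placement = _place_spheres(spec, rng)
            if placement is not None:
                break
        if placement is None:
            raise RuntimeError(
                "could not place all objects without overlap; reduce n_objects "
                "or the object radii"
            )
        centers_xz, radii = placement
        # sphere centres in 3D: resting on the floor plane (y = radius)
        centers = np.column_stack([centers_xz[:, 0], radii, centers_xz[:, 1]])
        # uniform points on each sphere surface
        m = spec.points_per_object
        normals = rng.normal(size=(spec.n_objects, m, 3))
        normals /= np.linalg.norm(normals, axis=2, keepdims=True)
        points = centers[:, None, :] + radii[:, None, None] * normals
        points = points.reshape(-1, 3)
        visible = np.ones(points.shape[0], dtype=bool)
        for eye in eyes:
            visible &= ~_segment_occluded(eye, points, centers, radii)
        vis_points = points[visible]
        if vis_points.size:
            all_d.append(np.linalg.norm(vis_points - cyclopean, axis=1))
    if not all_d:
        return DistanceSample(np.empty(0))
    return DistanceSample(np.concatenate(all_d))
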