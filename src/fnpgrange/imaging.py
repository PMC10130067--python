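"""Cone back-projection onto the beam-axis plane and list-mode MLEM.

Each event cone is discretised into equi-spaced surface rays; forward
ray-plane intersections are binned into an N x N pixel grid, with at most
one increment per cone and pixel (the cone's binary *footprint*, i.e. its
row of the sparse system matrix).  Simple back-projection sums footprints;
list-mode MLEM iterates the classic EM update with unit pixel
sensitivities, which conserves total intensity (the fixed point satisfies
sum(lambda) = number of events) and increases the list-mode log-likelihood
monotonically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .geometry import BeamGeometry, DetectorGeometry, Z_AXIS
from .kinematics import EventCone, cone_rays


class ImagingError(ValueError):
    pass


@dataclass(frozen=True)
class ImagePlane:
    """Back-projection plane containing the beam axis.

    ``origin`` is the world point at the grid center; ``u_hat`` (the beam
    direction, i.e. depth) and ``v_hat`` span the plane, ``normal``
    completes the frame.  Pixels are square, ``n_pixels`` per side.
    """

    origin: np.ndarray
    u_hat: np.ndarray
    v_hat: np.ndarray
    normal: np.ndarray
    n_pixels: int = 100
    pixel_mm: float = 2.0

    @property
    def half_extent(self) -> float:
        return self.n_pixels * self.pixel_mm / 2.0

    def to_plane_coords(self, points: np.ndarray) -> np.ndarray:
        rel = np.asarray(points, dtype=float) - self.origin
        return np.column_stack([rel @ self.u_hat, rel @ self.v_hat])

    def u_centers(self) -> np.ndarray:
        """World u-coordinates (depth, mm) of pixel-column centers."""
        edges = -self.half_extent + self.pixel_mm * np.arange(self.n_pixels + 1)
        centers = (edges[:-1] + edges[1:]) / 2.0
        return centers + float(self.origin @ self.u_hat)

    def u_edges(self) -> np.ndarray:
        edges = -self.half_extent + self.pixel_mm * np.arange(self.n_pixels + 1)
        return edges + float(self.origin @ self.u_hat)


@dataclass
class ReconstructedImage:
    """N x N non-negative pixel intensities with grid metadata."""

    values: np.ndarray  # shape (n_pixels, n_pixels), indexed [iv, iu]
    plane: ImagePlane
    n_iterations: int = 0
    log_likelihood: list = field(default_factory=list)
    n_dropped_empty: int = 0


def build_image_plane(beam: BeamGeometry, det: DetectorGeometry,
                      n_pixels: int = 100, pixel_mm: float = 2.0,
                      center_u: float | None = None) -> ImagePlane:
    """Plane through the beam axis, facing the detector.

    The normal is the component of the isocenter-to-detector direction
    perpendicular to the beam axis; for an anterior/posterior detector
    (theta = 0 or 180) this is degenerate and the x-z plane is used.  The
    grid is centered on the expected production region (mid-range depth)
    unless ``center_u`` overrides it.
    """
    if n_pixels < 8:
        raise ImagingError("n_pixels must be >= 8")
    los = det.face_center / np.linalg.norm(det.face_center)
    perp = los - np.dot(los, Z_AXIS) * Z_AXIS
    norm = np.linalg.norm(perp)
    normal = np.array([0.0, 1.0, 0.0]) if norm < 1e-9 else perp / norm
    u_hat = Z_AXIS.copy()
    v_hat = np.cross(normal, u_hat)
    if center_u is None:
        center_u = beam.surface_z + beam.nominal_range_r0 / 2.0
    origin = center_u * u_hat
    return ImagePlane(origin=origin, u_hat=u_hat, v_hat=v_hat, normal=normal,
                      n_pixels=n_pixels, pixel_mm=pixel_mm)


def ray_plane_intersection(apex: np.ndarray, direction: np.ndarray,
                           plane: ImagePlane) -> np.ndarray | None:
    """Forward intersection of one ray with the plane as (u, v), or None."""
    direction = np.asarray(direction, dtype=float)
    denom = float(direction @ plane.normal)
    if abs(denom) < 1e-12:
        return None
    t = float((plane.origin - np.asarray(apex, dtype=float)) @ plane.normal) / denom
    if t <= 0:
        return None
    point = np.asarray(apex, dtype=float) + t * direction
    return plane.to_plane_coords(point[None, :])[0]


def cone_footprint(cone: EventCone, plane: ImagePlane,
                   n_rays: int = 1000) -> np.ndarray:
    """Unique pixel indices (flattened iv * N + iu) hit by the cone's rays.

    Rays are traced as infinite half-lines; backward and parallel rays as
    well as intersections outside the grid window are discarded.  Each
    pixel appears at most once regardless of how many rays land in it.
    """
    rays = cone_rays(cone, n_rays)
    denom = rays @ plane.normal
    ok = np.abs(denom) >= 1e-12
    t = np.empty(len(rays))
    t[ok] = float((plane.origin - cone.apex) @ plane.normal) / denom[ok]
    ok &= t > 0
    if not np.any(ok):
        return np.empty(0, dtype=np.int64)
    points = cone.apex[None, :] + t[ok, None] * rays[ok]
    uv = plane.to_plane_coords(points)
    h = plane.half_extent
    iu = np.floor((uv[:, 0] + h) / plane.pixel_mm).astype(np.int64)
    iv = np.floor((uv[:, 1] + h) / plane.pixel_mm).astype(np.int64)
    n = plane.n_pixels
    inside = (iu >= 0) & (iu < n) & (iv >= 0) & (iv < n)
    if not np.any(inside):
        return np.empty(0, dtype=np.int64)
    return np.unique(iv[inside] * n + iu[inside])


def cone_footprints(cones, plane: ImagePlane, n_rays: int = 1000) -> list[np.ndarray]:
    return [cone_footprint(c, plane, n_rays) for c in cones]


def backproject(footprints, plane: ImagePlane) -> ReconstructedImage:
    """Sum binary footprints: pixel value = number of cones covering it."""
    n = plane.n_pixels
    img = np.zeros(n * n)
    for fp in footprints:
        img[fp] += 1.0
    return ReconstructedImage(values=img.reshape(n, n), plane=plane)


def _system_matrix(footprints, n_pix: int) -> tuple[sparse.csr_matrix, int]:
    rows, cols = [], []
    n_empty = 0
    i = 0
    for fp in footprints:
        if len(fp) == 0:
            n_empty += 1
            continue
        rows.append(np.full(len(fp), i, dtype=np.int64))
        cols.append(fp)
        i += 1
    if i == 0:
        raise ImagingError("no non-empty footprints to reconstruct from")
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    mat = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(i, n_pix))
    return mat, n_empty


def lmmlem(footprints, plane: ImagePlane, n_iter: int = 100,
           init: float = 1.0) -> ReconstructedImage:
    """List-mode MLEM with unit sensitivities, run for exactly ``n_iter`` steps.

    lambda_j <- lambda_j * sum_i t_ij / (sum_j' t_ij' lambda_j'), s_j = 1.
    Empty footprints are dropped and counted; events whose current forward
    projection is zero contribute nothing that iteration (guard).  The
    recorded trace is the full list-mode Poisson objective
    sum_i log(sum_j t_ij lambda_j) - sum_j s_j lambda_j, which the EM
    update increases monotonically (after the first update the total
    intensity is fixed at the event count, so the first term alone is
    monotone as well).
    """
    n_pix = plane.n_pixels ** 2
    mat, n_empty = _system_matrix(footprints, n_pix)
    lam = np.full(n_pix, float(init))
    loglik: list[float] = []
    for _ in range(n_iter):
        q = mat @ lam
        good = q > 0
        inv_q = np.zeros_like(q)
        inv_q[good] = 1.0 / q[good]
        loglik.append(float(np.sum(np.log(q[good])) - lam.sum()))
        lam = lam * (mat.T @ inv_q)
    return ReconstructedImage(values=lam.reshape(plane.n_pixels, plane.n_pixels),
                              plane=plane, n_iterations=n_iter,
                              log_likelihood=loglik, n_dropped_empty=n_empty)


def slice_profile(image: ReconstructedImage, beam: BeamGeometry,
                  half_width_pixels: int = 0):
    """1D depth profile: the pixel row containing the beam axis (+- extra rows).

    Returns a :class:`fnpgrange.range_stats.DepthProfile` over the grid's
    depth (u) bins.  Raises if the beam axis lies outside the grid window.
    """
    from .range_stats import DepthProfile  # local import to avoid a cycle

    plane = image.plane
    # the beam axis is the line (0,0,z); its v-coordinate is constant
    pv = float((np.zeros(3) - plane.origin) @ plane.v_hat)
    h = plane.half_extent
    iv = int(np.floor((pv + h) / plane.pixel_mm))
    if not 0 <= iv < plane.n_pixels:
        raise ImagingError("beam axis lies outside the image grid")
    lo = max(0, iv - half_width_pixels)
    hi = min(plane.n_pixels, iv + half_width_pixels + 1)
    counts = image.values[lo:hi, :].sum(axis=0)
    return DepthProfile(edges=plane.u_edges(), counts=counts, species="")
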