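"""Coordinate frames, the segmented bar-array detector, and ray queries.

World frame convention: the proton beam travels along +z, depth in the
patient is measured from the entrance plane ``z = surface_z`` (default 0),
and the treatment isocenter sits at the world origin.  The detector is a
rectangular array of optically segmented scintillator bars; its placement
is parameterised by the angle ``theta`` between the beam axis and the line
joining the isocenter to the center of the detector front face, and by the
distance ``D`` along that line.  ``theta`` is measured in the x-z plane, so
the detector center always has y = 0.

Detector-local frame: ``e1`` is the bar axis (the 300 mm dimension, chosen
parallel to the back-projection plane -- dual-ended readout resolves the
depth of interaction along this axis), ``e2`` is the second face axis, and
``e3`` is the line of sight pointing from the isocenter into the detector.
Bars are stacked on a regular grid across (e2, e3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

Z_AXIS = np.array([0.0, 0.0, 1.0])


class GeometryError(ValueError):
    """Raised for inconsistent geometry configuration."""


@dataclass(frozen=True)
class BeamGeometry:
    """Pencil-beam description.

    The beam axis is fixed to +z; ``nominal_range_r0`` is the nominal depth
    of the Bragg peak below the entrance plane, ``spot_fwhm`` the lateral
    Gaussian spot size at the entrance and ``divergence_mrad`` the angular
    divergence (kept for bookkeeping; its effect over a few cm of depth is
    far below the spot size and is not modelled).
    """

    nominal_range_r0: float = 60.0
    surface_z: float = 0.0
    spot_fwhm: float = 4.7
    divergence_mrad: float = 2.5
    energy_mev: float = 85.0
    axis_direction: np.ndarray = field(default_factory=lambda: Z_AXIS.copy())

    def __post_init__(self) -> None:
        if self.spot_fwhm <= 0:
            raise GeometryError("spot_fwhm must be > 0")
        if self.nominal_range_r0 <= 0:
            raise GeometryError("nominal_range_R0 must be > 0")


@dataclass(frozen=True)
class DetectorGeometry:
    """Segmented bar-array detector at orientation ``theta`` / distance ``D``.

    ``outer_dims`` is (bar-axis length, e2 extent, e3 depth) in mm.  The two
    stacking extents must be divisible by the bar cross section.
    """

    theta_deg: float = 90.0
    distance_mm: float = 300.0
    outer_dims: tuple[float, float, float] = (300.0, 200.0, 200.0)
    bar_mm: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta_deg <= 180.0:
            raise GeometryError(f"theta must lie in [0, 180] deg, got {self.theta_deg}")
        _, l2, l3 = self.outer_dims
        for extent in (l2, l3):
            n = extent / self.bar_mm
            if abs(n - round(n)) > 1e-9:
                raise GeometryError(
                    f"stacking extent {extent} mm not divisible by bar size {self.bar_mm} mm"
                )
        if self.distance_mm <= l3 / 2.0:
            raise GeometryError("isocenter distance must exceed half the detector depth")

    # --- derived quantities -------------------------------------------------

    @property
    def n_bars_e2(self) -> int:
        return round(self.outer_dims[1] / self.bar_mm)

    @property
    def n_bars_e3(self) -> int:
        return round(self.outer_dims[2] / self.bar_mm)

    @property
    def n_bars(self) -> int:
        return self.n_bars_e2 * self.n_bars_e3

    @property
    def half_dims(self) -> np.ndarray:
        return np.asarray(self.outer_dims) / 2.0

    @property
    def rotation(self) -> np.ndarray:
        """Columns are the local axes (e1, e2, e3) in world coordinates."""
        t = np.deg2rad(self.theta_deg)
        st, ct = np.sin(t), np.cos(t)
        e3 = np.array([st, 0.0, ct])
        if abs(st) < 1e-12:
            # line of sight parallel to the beam (theta = 0 or 180): bars along x
            e1 = np.array([1.0, 0.0, 0.0])
        else:
            # exact unit component of the beam axis perpendicular to e3
            e1 = np.array([-ct, 0.0, st])
        e2 = np.cross(e3, e1)
        return np.column_stack([e1, e2, e3])

    @property
    def face_center(self) -> np.ndarray:
        """World coordinates of the center of the front face."""
        return self.distance_mm * self.rotation[:, 2]

    @property
    def box_center(self) -> np.ndarray:
        return (self.distance_mm + self.outer_dims[2] / 2.0) * self.rotation[:, 2]

    # --- frame transforms ---------------------------------------------------

    def world_to_local(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.box_center) @ self.rotation

    def local_to_world(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.box_center


def build_geometry(config) -> tuple[BeamGeometry, DetectorGeometry]:
    """Build consistent geometry objects from a :class:`~fnpgrange.config.Config`."""
    g, b = config.geometry, config.beam
    beam = BeamGeometry(
        nominal_range_r0=b.range_mm,
        surface_z=b.surface_z_mm,
        spot_fwhm=b.fwhm_mm,
        divergence_mrad=b.divergence_mrad,
        energy_mev=b.energy_mev,
    )
    det = DetectorGeometry(
        theta_deg=g.theta_deg,
        distance_mm=g.distance_mm,
        outer_dims=tuple(g.dims_mm),
        bar_mm=g.bar_mm,
    )
    return beam, det


def _stack_index(u: float, half: float, pitch: float, n: int) -> int | None:
    """Index of the stacking cell containing coordinate ``u``.

    Boundary points are assigned to the lower-index cell (tie rule).
    """
    f = (u + half) / pitch
    if f < 0.0 or f > n:
        return None
    i = int(np.floor(f))
    if i == f and i > 0:  # exactly on an internal boundary -> lower cell
        i -= 1
    if i >= n:  # upper outer boundary
        i = n - 1
    return i


def locate_bar(point: np.ndarray, det: DetectorGeometry) -> int | None:
    """Return the id of the bar whose box contains ``point`` (world mm), else None."""
    u1, u2, u3 = det.world_to_local(np.asarray(point, dtype=float))
    h1, _, _ = det.half_dims
    if not -h1 <= u1 <= h1:
        return None
    i2 = _stack_index(u2, det.half_dims[1], det.bar_mm, det.n_bars_e2)
    i3 = _stack_index(u3, det.half_dims[2], det.bar_mm, det.n_bars_e3)
    if i2 is None or i3 is None:
        return None
    return i2 * det.n_bars_e3 + i3


def bar_center(bar_id: int, det: DetectorGeometry) -> np.ndarray:
    """World coordinates of the axis point at the center of a bar's box."""
    if not 0 <= bar_id < det.n_bars:
        raise GeometryError(f"bar id {bar_id} out of range")
    i2, i3 = divmod(bar_id, det.n_bars_e3)
    u2 = -det.half_dims[1] + (i2 + 0.5) * det.bar_mm
    u3 = -det.half_dims[2] + (i3 + 0.5) * det.bar_mm
    return det.local_to_world(np.array([0.0, u2, u3]))


def bar_transverse_center(bar_id: int, det: DetectorGeometry) -> tuple[float, float]:
    """Local (e2, e3) coordinates of a bar's cross-section center."""
    i2, i3 = divmod(bar_id, det.n_bars_e3)
    u2 = -det.half_dims[1] + (i2 + 0.5) * det.bar_mm
    u3 = -det.half_dims[2] + (i3 + 0.5) * det.bar_mm
    return u2, u3


def _slab_intersection(origin_l: np.ndarray, dir_l: np.ndarray, half: np.ndarray):
    """(t_enter, t_exit) of a ray with the local axis-aligned box, or None."""
    t0, t1 = -np.inf, np.inf
    for k in range(3):
        if abs(dir_l[k]) < 1e-15:
            if abs(origin_l[k]) > half[k]:
                return None
            continue
        ta = (-half[k] - origin_l[k]) / dir_l[k]
        tb = (half[k] - origin_l[k]) / dir_l[k]
        if ta > tb:
            ta, tb = tb, ta
        t0 = max(t0, ta)
        t1 = min(t1, tb)
    if t0 > t1:
        return None
    return t0, t1


def entrance_intersection(
    origin: np.ndarray, direction: np.ndarray, det: DetectorGeometry
) -> np.ndarray | None:
    """First intersection of the forward ray with the detector's outer box.

    Returns the entry point in world coordinates, or None if the ray misses.
    If the origin is already inside the box, the origin itself is returned
    (the ray starts inside by convention).
    """
    direction = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(direction) - 1.0) > 1e-9:
        raise GeometryError("direction must be a unit vector")
    origin = np.asarray(origin, dtype=float)
    origin_l = det.world_to_local(origin)
    dir_l = direction @ det.rotation
    hit = _slab_intersection(origin_l, dir_l, det.half_dims)
    if hit is None:
        return None
    t0, t1 = hit
    if t1 < 0:
        return None
    if t0 <= 0.0:
        return origin.copy()
    return origin + t0 * direction


def exit_distance(point: np.ndarray, direction: np.ndarray, det: DetectorGeometry) -> float:
    """Distance from an interior ``point`` to where the ray leaves the box."""
    point_l = det.world_to_local(np.asarray(point, dtype=float))
    dir_l = np.asarray(direction, dtype=float) @ det.rotation
    hit = _slab_intersection(point_l, dir_l, det.half_dims)
    if hit is None:
        return 0.0
    return max(hit[1], 0.0)


def batch_entrance(
    origins: np.ndarray, directions: np.ndarray, det: DetectorGeometry
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised :func:`entrance_intersection` over (n, 3) arrays.

    Returns ``(enters, entry_points)`` where rows of ``entry_points`` are
    valid only where ``enters`` is True.
    """
    origins_l = det.world_to_local(origins)
    dirs_l = np.asarray(directions, dtype=float) @ det.rotation
    half = det.half_dims
    with np.errstate(divide="ignore", invalid="ignore"):
        ta = (-half - origins_l) / dirs_l
        tb = (half - origins_l) / dirs_l
    lo = np.minimum(ta, tb)
    hi = np.maximum(ta, tb)
    parallel = np.abs(dirs_l) < 1e-15
    inside_slab = np.abs(origins_l) <= half
    lo = np.where(parallel, np.where(inside_slab, -np.inf, np.inf), lo)
    hi = np.where(parallel, np.where(inside_slab, np.inf, -np.inf), hi)
    t0 = lo.max(axis=1)
    t1 = hi.min(axis=1)
    enters = (t0 <= t1) & (t1 >= 0)
    t_entry = np.where(t0 > 0, t0, 0.0)
    points = np.asarray(origins, dtype=float) + t_entry[:, None] * np.asarray(directions)
    return enters, points
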