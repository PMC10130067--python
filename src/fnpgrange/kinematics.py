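"""Event-cone reconstruction from selected coincidences.

A detected particle's possible incidence directions form a cone: apex at
the first interaction, axis along the vector from the second interaction
back to the first (pointing towards the source region), and half-angle
fixed by scattering kinematics.  The azimuthal angle is unresolved by
construction.

Fast neutrons (double (n,p) scatter): the time-of-flight tau between the
two scatters and their separation d give the scattered-neutron energy
``E' = (1/2) m_n c^2 (d / (tau c))^2`` (non-relativistic), the incident
energy is ``E = E' + E_p`` with the recoil-proton energy from the first
scatter's light output, and the lab scattering angle satisfies
``theta = asin(sqrt(E_p / E))``.

Prompt gammas (triple Compton): the geometric scattering angle at the
second interaction together with the first two energy deposits determines
the incident photon energy in closed form, from which the first-scatter
angle follows via the Compton relation.  The third hit's energy is unused.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import C_MM_NS, FN, M_E_C2, M_N_C2, PG


class ConeRejection(Exception):
    """A coincidence that cannot yield a physical cone; ``reason`` is counted."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass(frozen=True)
class EventCone:
    """Reconstructed incidence cone of one detected FN or PG."""

    event_id: int
    species: str
    apex: np.ndarray  # world mm, first-scatter position
    axis: np.ndarray  # unit vector pointing back towards the source
    half_angle: float  # rad
    e_incident: float  # MeV
    beta: float | None = None  # v/c of the scattered neutron (FN only)


def reconstruct_fn_cone(hit1, hit2) -> EventCone:
    """FN cone from the first two (n,p) scatters (time-ordered).

    ``hit1``/``hit2`` expose ``position`` (3-vector mm), ``time`` (ns) and
    ``edep`` (MeV), e.g. rows of a selected-coincidence table.  Raises
    :class:`ConeRejection` for non-positive time-of-flight or superluminal
    separation (possible after smearing).
    """
    r1 = np.asarray(hit1.position, dtype=float)
    r2 = np.asarray(hit2.position, dtype=float)
    tau = float(hit2.time) - float(hit1.time)
    if tau <= 0:
        raise ConeRejection("nonpositive_tof")
    d = float(np.linalg.norm(r2 - r1))
    if d <= 0:
        raise ConeRejection("coincident_positions")
    beta = d / tau / C_MM_NS
    if beta >= 1.0:
        raise ConeRejection("superluminal")
    e_scattered = 0.5 * M_N_C2 * beta * beta
    e_p = float(hit1.edep)
    e_n = e_scattered + e_p
    ratio = e_p / e_n
    assert ratio <= 1.0  # E_n >= E_p by construction
    half_angle = math.asin(math.sqrt(ratio))
    if half_angle <= 0:
        raise ConeRejection("zero_angle")
    return EventCone(
        event_id=int(getattr(hit1, "event_id", -1)), species=FN,
        apex=r1, axis=(r1 - r2) / d, half_angle=half_angle,
        e_incident=e_n, beta=beta,
    )


def reconstruct_pg_cone(hit1, hit2, hit3) -> EventCone:
    """PG cone from the first three interactions (time-ordered).

    Uses the deposits of the first two hits and the geometric scattering
    angle at the second; rejects collinear geometries (the closed form
    divides by 1 - cos(theta_2)) and smeared events whose implied
    first-scatter angle is unphysical.
    """
    r1 = np.asarray(hit1.position, dtype=float)
    r2 = np.asarray(hit2.position, dtype=float)
    r3 = np.asarray(hit3.position, dtype=float)
    a = r2 - r1
    b = r3 - r2
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na <= 0 or nb <= 0:
        raise ConeRejection("coincident_positions")
    cos_t2 = float(np.dot(a, b) / (na * nb))
    cos_t2 = max(-1.0, min(1.0, cos_t2))
    if 1.0 - cos_t2 < 1e-12:
        raise ConeRejection("collinear")
    de1 = float(hit1.edep)
    de2 = float(hit2.edep)
    e_gamma = de1 + 0.5 * (de2 + math.sqrt(de2 * de2
                                           + 4.0 * de2 * M_E_C2 / (1.0 - cos_t2)))
    e_prime = e_gamma - de1
    cos_t1 = 1.0 + M_E_C2 * (1.0 / e_gamma - 1.0 / e_prime)
    if not -1.0 < cos_t1 < 1.0:
        raise ConeRejection("unphysical_angle")
    half_angle = math.acos(cos_t1)
    return EventCone(
        event_id=int(getattr(hit1, "event_id", -1)), species=PG,
        apex=r1, axis=a / -na, half_angle=half_angle, e_incident=e_gamma,
    )


def _orthonormal_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # tie-break: seed with the global axis least aligned with the cone axis
    k = int(np.argmin(np.abs(axis)))
    g = np.zeros(3)
    g[k] = 1.0
    e1 = g - np.dot(g, axis) * axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return e1, e2


def cone_rays(cone: EventCone, n_rays: int = 1000) -> np.ndarray:
    """Discretise a cone into ``n_rays`` equi-spaced surface rays.

    Rays are unit vectors at azimuths ``2*pi*k / n_rays`` around the axis,
    each making the cone's half-angle with it; the in-plane frame is chosen
    deterministically (global axis least aligned with the cone axis).
    """
    if n_rays < 3:
        raise ValueError("n_rays must be >= 3")
    e1, e2 = _orthonormal_frame(cone.axis)
    phi = 2.0 * np.pi * np.arange(n_rays) / n_rays
    ct, st = np.cos(cone.half_angle), np.sin(cone.half_angle)
    rays = (ct * cone.axis[None, :]
            + st * (np.cos(phi)[:, None] * e1[None, :]
                    + np.sin(phi)[:, None] * e2[None, :]))
    return rays / np.linalg.norm(rays, axis=1, keepdims=True)


@dataclass
class _Hit:
    event_id: int
    position: np.ndarray
    time: float
    edep: float


def reconstruct_cones(selected: pd.DataFrame, species: str,
                      ) -> tuple[list[EventCone], dict[str, int]]:
    """Reconstruct cones for a selected-coincidence table; tally rejections.

    ``selected`` is the output of
    :func:`fnpgrange.response.select_coincidences` (rows carry a ``rank``).
    Returns accepted cones and a counter of rejection reasons; accepted
    plus rejected equals the number of selected coincidences.
    """
    need = 2 if species == FN else 3
    cones: list[EventCone] = []
    tally: dict[str, int] = {}
    if len(selected) == 0:
        return cones, tally
    pos = selected[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    times = selected["t_ns"].to_numpy(dtype=float)
    edeps = selected["edep_MeV"].to_numpy(dtype=float)
    ids = selected["event_id"].to_numpy()
    for start in range(0, len(selected), need):
        hits = [_Hit(int(ids[start]), pos[start + k], float(times[start + k]),
                     float(edeps[start + k])) for k in range(need)]
        try:
            if species == FN:
                cones.append(reconstruct_fn_cone(*hits))
            else:
                cones.append(reconstruct_pg_cone(*hits))
        except ConeRejection as rej:
            tally[rej.reason] = tally.get(rej.reason, 0) + 1
    return cones, tally


def cones_to_frame(cones: list[EventCone]) -> pd.DataFrame:
    """Flatten cones into the canonical cone-table schema."""
    return pd.DataFrame({
        "event_id": [c.event_id for c in cones],
        "species": [c.species for c in cones],
        "apex_x_mm": [c.apex[0] for c in cones],
        "apex_y_mm": [c.apex[1] for c in cones],
        "apex_z_mm": [c.apex[2] for c in cones],
        "axis_x": [c.axis[0] for c in cones],
        "axis_y": [c.axis[1] for c in cones],
        "axis_z": [c.axis[2] for c in cones],
        "half_angle_rad": [c.half_angle for c in cones],
        "E_MeV": [c.e_incident for c in cones],
    })
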