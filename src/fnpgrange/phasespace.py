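"""Synthetic FN/PG phase space and detector interaction histories.

This module stands in for a full Monte-Carlo patient simulation.  It samples
fast-neutron (FN) and prompt-gamma (PG) production points tied to a nominal
proton range, applies controlled range shifts, transports the particles to
the detector and generates collision sequences that satisfy (n,p)-elastic
and Compton kinematics *exactly* (to machine precision).  Kinematic
exactness is the module's core contract: downstream cone reconstruction
must round-trip unsmeared histories perfectly.

The depth profiles emulate the qualitative structure of proton-induced
secondary production: FN emission is concentrated at shallow depths
(truncated exponential decay), while PG emission rises towards the end of
the proton range and falls off sharply (power-law rise times a logistic
distal edge).  A range shift translates both profiles rigidly along the
beam axis.  A negative shift (dilated patient surface) pushes production
upstream of the nominal entrance plane, so the translated support is only
clipped at a configurable floor ``clip_z_min`` well below zero.

Interaction sampling uses effective constant mean free paths rather than
energy-dependent cross sections: for a desk-scale study only the kinematic
correctness of the collision sequences matters, not absolute interaction
rates.  Neutron transport is non-relativistic, mirroring the cone
reconstruction; a warning counts generated neutrons with v/c > 0.1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import Config, EmissionSection, TransportSection
from .constants import C_MM_NS, FN, FWHM_OVER_SIGMA, M_E_C2, M_N_C2, PG
from .geometry import (
    BeamGeometry,
    DetectorGeometry,
    batch_entrance,
    entrance_intersection,
    exit_distance,
    locate_bar,
)

EVENT_COLUMNS = [
    "event_id", "species", "prod_x_mm", "prod_y_mm", "prod_z_mm",
    "E0_MeV", "dir_x", "dir_y", "dir_z", "t0_ns",
]
COLLISION_COLUMNS = [
    "event_id", "species", "hit_index", "bar_id",
    "x_mm", "y_mm", "z_mm", "t_ns", "edep_MeV", "kind",
]

NP_ELASTIC = "np_elastic"
COMPTON = "compton"
PHOTOABSORPTION = "photoabsorption"


@dataclass(frozen=True)
class PhaseSpaceEvent:
    """One emitted secondary particle."""

    event_id: int
    species: str
    position: np.ndarray  # production point, world mm
    energy: float  # MeV
    direction: np.ndarray  # unit vector
    time: float = 0.0  # ns


@dataclass(frozen=True)
class CollisionRecord:
    """One detector interaction of a transported particle."""

    event_id: int
    species: str
    hit_index: int
    bar_id: int
    position: np.ndarray  # world mm
    time: float  # ns
    edep: float  # MeV
    kind: str


@dataclass(frozen=True)
class EmissionModel:
    """Species-specific depth profiles, spectra, yields and the range shift."""

    r0: float = 60.0  # nominal proton range below the entrance plane, mm
    params: EmissionSection = field(default_factory=EmissionSection)
    delta_mm: float = 0.0  # applied range shift (translation of both profiles)

    @property
    def fn_support(self) -> tuple[float, float]:
        return (0.0, self.params.fn_cutoff_frac * self.r0)

    @property
    def pg_support(self) -> tuple[float, float]:
        return (0.0, self.r0 + 6.0 * self.params.pg_falloff_mm)

    def fn_pdf(self, z: np.ndarray) -> np.ndarray:
        """Unnormalised FN depth density on the *unshifted* support."""
        z = np.asarray(z, dtype=float)
        lo, hi = self.fn_support
        out = np.exp(-z / self.params.fn_decay_mm)
        return np.where((z >= lo) & (z <= hi), out, 0.0)

    def pg_pdf(self, z: np.ndarray) -> np.ndarray:
        """Unnormalised PG depth density: power-law rise with a logistic distal edge."""
        z = np.asarray(z, dtype=float)
        lo, hi = self.pg_support
        rise = np.power(np.clip(z / self.r0, 0.0, None), self.params.pg_rise_power)
        fall = 1.0 / (1.0 + np.exp((z - self.r0) / self.params.pg_falloff_mm))
        return np.where((z >= lo) & (z <= hi), rise * fall, 0.0)


def emission_model_from_config(config: Config) -> EmissionModel:
    return EmissionModel(r0=config.beam.range_mm, params=config.emission)


def apply_range_shift(model: EmissionModel, delta: float) -> EmissionModel:
    """Translate both depth profiles rigidly by ``delta`` mm (deeper is positive).

    The shift is stored as a model parameter and realised at sampling time,
    so shifts compose additively and invert exactly.
    """
    if abs(model.delta_mm + delta) > model.params.max_shift_mm:
        raise ValueError(
            f"cumulative shift {model.delta_mm + delta} mm exceeds "
            f"the configured bound {model.params.max_shift_mm} mm"
        )
    return replace(model, delta_mm=model.delta_mm + delta)


# --------------------------------------------------------------------------
# sampling primitives
# --------------------------------------------------------------------------

def _inverse_cdf_sample(pdf, support, uniforms, n_grid=4097) -> np.ndarray:
    """Numeric inverse-CDF sampling of a 1D density via a fine trapezoid grid."""
    z = np.linspace(support[0], support[1], n_grid)
    p = pdf(z)
    cdf = np.concatenate([[0.0], np.cumsum((p[1:] + p[:-1]) * 0.5 * np.diff(z))])
    if cdf[-1] <= 0:
        raise ValueError("depth profile integrates to zero on its support")
    cdf /= cdf[-1]
    # de-duplicate flat regions so np.interp stays monotone
    keep = np.concatenate([[True], np.diff(cdf) > 0])
    return np.interp(uniforms, cdf[keep], z[keep])


def sample_depths(model: EmissionModel, species: str, n: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Sample production depths for one species, including the range shift."""
    u = rng.random(n)
    if species == FN:
        base = _inverse_cdf_sample(model.fn_pdf, model.fn_support, u)
    elif species == PG:
        base = _inverse_cdf_sample(model.pg_pdf, model.pg_support, u)
    else:
        raise ValueError(f"unknown species {species!r}")
    return np.maximum(base + model.delta_mm, model.params.clip_z_min)


def sample_vmf_directions(kappa: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit vectors from a von Mises-Fisher density around +z; kappa=0 -> isotropic."""
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    u = rng.random(n)
    if kappa == 0:
        w = 2.0 * u - 1.0
    else:
        # inverse CDF of the vMF polar marginal
        w = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    s = np.sqrt(np.clip(1.0 - w * w, 0.0, None))
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), w])


def _sample_fn_energies(params: EmissionSection, n: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Truncated exponential continuum on [fn_e_min, fn_e_max]."""
    t = params.fn_e_temp
    a = np.exp(-params.fn_e_min / t)
    b = np.exp(-params.fn_e_max / t)
    u = rng.random(n)
    return -t * np.log(a - u * (a - b))


def _sample_pg_energies(params: EmissionSection, n: int,
                        rng: np.random.Generator) -> np.ndarray:
    w = np.asarray(params.pg_line_weights, dtype=float)
    w = w / w.sum()
    return rng.choice(np.asarray(params.pg_lines_mev), size=n, p=w)


def sample_klein_nishina(energy_mev: float, n: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Sample ``cos(theta)`` from the Klein-Nishina differential cross-section.

    Rejection sampling with the flat envelope f(cos=1) = 2, which bounds the
    (unnormalised) density r^3 + r - r^2 sin^2(theta), r = E'/E.
    """
    k = energy_mev / M_E_C2
    out = np.empty(n)
    filled = 0
    while filled < n:
        m = max(64, 2 * (n - filled))
        c = rng.uniform(-1.0, 1.0, m)
        r = 1.0 / (1.0 + k * (1.0 - c))
        f = r * r * (r + 1.0 / r - (1.0 - c * c))
        acc = c[rng.uniform(0.0, 2.0, m) < f]
        take = min(len(acc), n - filled)
        out[filled:filled + take] = acc[:take]
        filled += take
    return out


def klein_nishina_pdf(energy_mev: float, cos_theta: np.ndarray) -> np.ndarray:
    """Unnormalised Klein-Nishina density in cos(theta) (quadrature oracle)."""
    k = energy_mev / M_E_C2
    c = np.asarray(cos_theta, dtype=float)
    r = 1.0 / (1.0 + k * (1.0 - c))
    return r * r * (r + 1.0 / r - (1.0 - c * c))


def _orthonormal_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic (e1, e2) completing ``axis`` to a right-handed frame.

    The seed vector is the global axis least aligned with ``axis``; this is
    singularity-free and reproducible.
    """
    k = int(np.argmin(np.abs(axis)))
    g = np.zeros(3)
    g[k] = 1.0
    e1 = g - np.dot(g, axis) * axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return e1, e2


def _deflect(direction: np.ndarray, cos_theta: float, phi: float) -> np.ndarray:
    """Unit vector at polar angle arccos(cos_theta) from ``direction``."""
    e1, e2 = _orthonormal_frame(direction)
    sin_theta = np.sqrt(max(0.0, 1.0 - cos_theta * cos_theta))
    v = (cos_theta * direction
         + sin_theta * (np.cos(phi) * e1 + np.sin(phi) * e2))
    return v / np.linalg.norm(v)


def neutron_speed(energy_mev: float) -> float:
    """Non-relativistic neutron speed in mm/ns."""
    return C_MM_NS * np.sqrt(2.0 * energy_mev / M_N_C2)


# --------------------------------------------------------------------------
# emission
# --------------------------------------------------------------------------

def sample_emission(model: EmissionModel, beam: BeamGeometry, n_protons: int,
                    rng_seed: int | np.random.SeedSequence) -> pd.DataFrame:
    """Draw FN/PG phase-space events for a pencil-beam spot of ``n_protons``.

    Event counts are Poisson with means ``yield * n_protons`` per species;
    depths follow the species profile (with the model's range shift applied),
    transverse coordinates the beam's Gaussian spot.  FN directions follow
    the forward-biased von Mises-Fisher density, PG directions are isotropic.
    Sampling uses independent sub-streams per species, so results are
    reproducible under a fixed seed.
    """
    if n_protons < 0:
        raise ValueError("n_protons must be >= 0")
    ss = (rng_seed if isinstance(rng_seed, np.random.SeedSequence)
          else np.random.SeedSequence(rng_seed))
    seed_fn, seed_pg = ss.spawn(2)
    frames = []
    next_id = 0
    for species, seed in ((FN, seed_fn), (PG, seed_pg)):
        rng = np.random.default_rng(seed)
        mean = (model.params.fn_yield if species == FN else model.params.pg_yield)
        n = int(rng.poisson(mean * n_protons)) if n_protons > 0 else 0
        depth = sample_depths(model, species, n, rng)
        sigma = beam.spot_fwhm / FWHM_OVER_SIGMA
        x = rng.normal(0.0, sigma, n)
        y = rng.normal(0.0, sigma, n)
        if species == FN:
            dirs = sample_vmf_directions(model.params.kappa, n, rng)
            energy = _sample_fn_energies(model.params, n, rng)
        else:
            dirs = sample_vmf_directions(0.0, n, rng)
            energy = _sample_pg_energies(model.params, n, rng)
        frames.append(pd.DataFrame({
            "event_id": np.arange(next_id, next_id + n, dtype=np.int64),
            "species": species,
            "prod_x_mm": x,
            "prod_y_mm": y,
            "prod_z_mm": beam.surface_z + depth,
            "E0_MeV": energy,
            "dir_x": dirs[:, 0],
            "dir_y": dirs[:, 1],
            "dir_z": dirs[:, 2],
            "t0_ns": 0.0,
        }))
        next_id += n
    out = pd.concat(frames, ignore_index=True)
    # categorical species keeps multi-million-event tables compact
    out["species"] = out["species"].astype("category")
    return out[EVENT_COLUMNS]


def sample_aimed_emission(model: EmissionModel, beam: BeamGeometry,
                          det: DetectorGeometry, n_events: int,
                          rng_seed: int | np.random.SeedSequence,
                          species: str = FN) -> pd.DataFrame:
    """Like :func:`sample_emission` but aim directions at the detector face.

    A variance-reduction device for tests and small studies: production
    points and energies follow the emission model, while each direction
    points at a uniformly drawn point on the detector front face.  Kinematic
    properties of the resulting histories are unaffected by the aiming.
    """
    ss = (rng_seed if isinstance(rng_seed, np.random.SeedSequence)
          else np.random.SeedSequence(rng_seed))
    rng = np.random.default_rng(ss)
    depth = sample_depths(model, species, n_events, rng)
    sigma = beam.spot_fwhm / FWHM_OVER_SIGMA
    x = rng.normal(0.0, sigma, n_events)
    y = rng.normal(0.0, sigma, n_events)
    prod = np.column_stack([x, y, beam.surface_z + depth])
    rot = det.rotation
    h1, h2, _ = det.half_dims
    targets = (det.face_center[None, :]
               + rng.uniform(-h1, h1, n_events)[:, None] * rot[:, 0]
               + rng.uniform(-h2, h2, n_events)[:, None] * rot[:, 1])
    dirs = targets - prod
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    if species == FN:
        energy = _sample_fn_energies(model.params, n_events, rng)
    else:
        energy = _sample_pg_energies(model.params, n_events, rng)
    return pd.DataFrame({
        "event_id": np.arange(n_events, dtype=np.int64),
        "species": species,
        "prod_x_mm": prod[:, 0], "prod_y_mm": prod[:, 1], "prod_z_mm": prod[:, 2],
        "E0_MeV": energy,
        "dir_x": dirs[:, 0], "dir_y": dirs[:, 1], "dir_z": dirs[:, 2],
        "t0_ns": 0.0,
    })[EVENT_COLUMNS]


# --------------------------------------------------------------------------
# interaction histories
# --------------------------------------------------------------------------

def simulate_neutron_history(event: PhaseSpaceEvent, det: DetectorGeometry,
                             rng: np.random.Generator,
                             transport: TransportSection | None = None,
                             ) -> list[CollisionRecord]:
    """Sequence of (n,p) elastic scatters of one neutron inside the detector.

    Free paths are exponential with mean ``lambda_n_mm``; center-of-mass
    scattering is isotropic, so the recoil proton energy is uniform on
    (0, E) and the lab scattering angle satisfies sin^2(theta) = E_p / E
    exactly (equal-mass elastic kinematics).  Time advances with the
    non-relativistic speed of the *current* neutron energy.  The history
    terminates on exit, when the scattered energy falls below the
    termination threshold, or after ``max_scatters`` collisions.
    """
    tp = transport or TransportSection()
    entry = entrance_intersection(event.position, event.direction, det)
    if entry is None:
        return []
    records: list[CollisionRecord] = []
    pos = np.asarray(event.position, dtype=float)
    u = np.asarray(event.direction, dtype=float)
    energy = float(event.energy)
    t = float(event.time)
    pending = float(np.linalg.norm(entry - pos))  # flight before entering the box
    pos = entry
    for hit_index in range(tp.max_scatters):
        s = rng.exponential(tp.lambda_n_mm)
        if s >= exit_distance(pos, u, det):
            break
        t += (pending + s) / neutron_speed(energy)
        pending = 0.0
        pos = pos + s * u
        e_p = rng.uniform(0.0, energy)
        records.append(CollisionRecord(
            event_id=event.event_id, species=FN, hit_index=hit_index,
            bar_id=locate_bar(pos, det), position=pos, time=t,
            edep=e_p, kind=NP_ELASTIC,
        ))
        energy -= e_p
        if energy < tp.neutron_term_mev:
            break
        sin2 = e_p / (energy + e_p)
        cos_theta = np.sqrt(max(0.0, 1.0 - sin2))
        u = _deflect(u, cos_theta, rng.uniform(0.0, 2.0 * np.pi))
    return records


def simulate_gamma_history(event: PhaseSpaceEvent, det: DetectorGeometry,
                           rng: np.random.Generator,
                           transport: TransportSection | None = None,
                           ) -> list[CollisionRecord]:
    """Compton-scatter (plus optional terminal photoabsorption) history.

    Scattering angles are drawn from the Klein-Nishina cross-section at the
    current photon energy; the energy update follows the Compton relation
    exactly.  The photon travels at c throughout.
    """
    tp = transport or TransportSection()
    entry = entrance_intersection(event.position, event.direction, det)
    if entry is None:
        return []
    records: list[CollisionRecord] = []
    pos = np.asarray(event.position, dtype=float)
    u = np.asarray(event.direction, dtype=float)
    energy = float(event.energy)
    t = float(event.time) + float(np.linalg.norm(entry - pos)) / C_MM_NS
    pos = entry
    for hit_index in range(tp.max_scatters):
        s = rng.exponential(tp.lambda_g_mm)
        if s >= exit_distance(pos, u, det):
            break
        t += s / C_MM_NS
        pos = pos + s * u
        if rng.random() < tp.photoabsorption_prob:
            records.append(CollisionRecord(
                event_id=event.event_id, species=PG, hit_index=hit_index,
                bar_id=locate_bar(pos, det), position=pos, time=t,
                edep=energy, kind=PHOTOABSORPTION,
            ))
            break
        cos_theta = float(sample_klein_nishina(energy, 1, rng)[0])
        e_prime = energy / (1.0 + (energy / M_E_C2) * (1.0 - cos_theta))
        records.append(CollisionRecord(
            event_id=event.event_id, species=PG, hit_index=hit_index,
            bar_id=locate_bar(pos, det), position=pos, time=t,
            edep=energy - e_prime, kind=COMPTON,
        ))
        energy = e_prime
        u = _deflect(u, cos_theta, rng.uniform(0.0, 2.0 * np.pi))
    return records


def _kn_batch(energies: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Klein-Nishina cos(theta) for a vector of (possibly distinct) energies."""
    k = np.asarray(energies, dtype=float) / M_E_C2
    n = k.size
    out = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        c = rng.uniform(-1.0, 1.0, todo.size)
        r = 1.0 / (1.0 + k[todo] * (1.0 - c))
        f = r * r * (r + 1.0 / r - (1.0 - c * c))
        acc = rng.uniform(0.0, 2.0, todo.size) < f
        out[todo[acc]] = c[acc]
        todo = todo[~acc]
    return out


def _deflect_batch(dirs: np.ndarray, cos_theta: np.ndarray,
                   phi: np.ndarray) -> np.ndarray:
    """Vectorised :func:`_deflect` (same deterministic frame rule per row)."""
    n = len(dirs)
    k = np.argmin(np.abs(dirs), axis=1)
    g = np.zeros_like(dirs)
    g[np.arange(n), k] = 1.0
    e1 = g - np.sum(g * dirs, axis=1, keepdims=True) * dirs
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(dirs, e1)
    st = np.sqrt(np.clip(1.0 - cos_theta * cos_theta, 0.0, None))
    out = (cos_theta[:, None] * dirs
           + st[:, None] * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2))
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def _batch_exit_distance(pos: np.ndarray, dirs: np.ndarray,
                         det: DetectorGeometry) -> np.ndarray:
    """Distance to the box boundary for interior points, vectorised."""
    pos_l = det.world_to_local(pos)
    dir_l = dirs @ det.rotation
    half = det.half_dims
    with np.errstate(divide="ignore", invalid="ignore"):
        ta = (-half - pos_l) / dir_l
        tb = (half - pos_l) / dir_l
    hi = np.maximum(ta, tb)
    hi = np.where(np.abs(dir_l) < 1e-15, np.inf, hi)
    return np.clip(hi.min(axis=1), 0.0, None)


def _batch_locate_bars(pos: np.ndarray, det: DetectorGeometry) -> np.ndarray:
    """Bar ids for interior points (vectorised; no boundary tie handling
    needed for continuously sampled collision positions)."""
    local = det.world_to_local(pos)
    i2 = np.floor((local[:, 1] + det.half_dims[1]) / det.bar_mm).astype(np.int64)
    i3 = np.floor((local[:, 2] + det.half_dims[2]) / det.bar_mm).astype(np.int64)
    i2 = np.clip(i2, 0, det.n_bars_e2 - 1)
    i3 = np.clip(i3, 0, det.n_bars_e3 - 1)
    return i2 * det.n_bars_e3 + i3


def _batch_histories(event_ids: np.ndarray, entry: np.ndarray, origins: np.ndarray,
                     dirs: np.ndarray, energies: np.ndarray, times: np.ndarray,
                     species: str, det: DetectorGeometry,
                     rng: np.random.Generator, tp: TransportSection) -> dict:
    """Step-synchronous vectorised transport of entering events.

    Statistically identical to the per-event history functions (same
    kinematics and free-path model, different random-number ordering);
    used by :func:`simulate_histories` for throughput.
    """
    cols: dict[str, list] = {k: [] for k in COLLISION_COLUMNS}
    pos = entry.copy()
    u = dirs.copy()
    energy = energies.astype(float).copy()
    t = times.astype(float).copy()
    pending = np.linalg.norm(entry - origins, axis=1)
    ids = event_ids.copy()
    lam = tp.lambda_n_mm if species == FN else tp.lambda_g_mm
    for hit_index in range(tp.max_scatters):
        if ids.size == 0:
            break
        s = rng.exponential(lam, ids.size)
        stay = s < _batch_exit_distance(pos, u, det)
        ids, pos, u, energy, t, pending, s = (
            a[stay] for a in (ids, pos, u, energy, t, pending, s))
        if ids.size == 0:
            break
        if species == FN:
            speed = neutron_speed(energy)
        else:
            speed = C_MM_NS
        t = t + (pending + s) / speed
        pending = np.zeros_like(t)
        pos = pos + s[:, None] * u
        bars = _batch_locate_bars(pos, det)
        if species == FN:
            e_p = rng.uniform(0.0, energy)
            kinds = np.full(ids.size, NP_ELASTIC)
            edep = e_p
        else:
            absorbed = rng.random(ids.size) < tp.photoabsorption_prob
            cos_theta = _kn_batch(energy, rng)
            e_prime = energy / (1.0 + (energy / M_E_C2) * (1.0 - cos_theta))
            edep = np.where(absorbed, energy, energy - e_prime)
            kinds = np.where(absorbed, PHOTOABSORPTION, COMPTON)
        cols["event_id"].append(ids.copy())
        cols["species"].append(np.full(ids.size, species))
        cols["hit_index"].append(np.full(ids.size, hit_index, dtype=np.int64))
        cols["bar_id"].append(bars)
        cols["x_mm"].append(pos[:, 0].copy())
        cols["y_mm"].append(pos[:, 1].copy())
        cols["z_mm"].append(pos[:, 2].copy())
        cols["t_ns"].append(t.copy())
        cols["edep_MeV"].append(edep.copy())
        cols["kind"].append(kinds)
        if species == FN:
            energy = energy - e_p
            live = energy >= tp.neutron_term_mev
            sin2 = e_p / (energy + e_p)
            cos_theta = np.sqrt(np.clip(1.0 - sin2, 0.0, None))
            phi = rng.uniform(0.0, 2.0 * np.pi, ids.size)
            u = _deflect_batch(u, cos_theta, phi)
        else:
            live = ~absorbed
            energy = e_prime
            phi = rng.uniform(0.0, 2.0 * np.pi, ids.size)
            u = _deflect_batch(u, cos_theta, phi)
        ids, pos, u, energy, t, pending = (
            a[live] for a in (ids, pos, u, energy, t, pending))
    return {k: (np.concatenate(v) if v else np.empty(0)) for k, v in cols.items()}


def _records_to_frame(records: list[CollisionRecord]) -> pd.DataFrame:
    if not records:
        return pd.DataFrame(columns=COLLISION_COLUMNS)
    return pd.DataFrame({
        "event_id": np.array([r.event_id for r in records], dtype=np.int64),
        "species": [r.species for r in records],
        "hit_index": np.array([r.hit_index for r in records], dtype=np.int64),
        "bar_id": np.array([r.bar_id for r in records], dtype=np.int64),
        "x_mm": np.array([r.position[0] for r in records]),
        "y_mm": np.array([r.position[1] for r in records]),
        "z_mm": np.array([r.position[2] for r in records]),
        "t_ns": np.array([r.time for r in records]),
        "edep_MeV": np.array([r.edep for r in records]),
        "kind": [r.kind for r in records],
    })[COLLISION_COLUMNS]


def simulate_histories(events: pd.DataFrame, det: DetectorGeometry,
                       rng_seed: int | np.random.SeedSequence,
                       transport: TransportSection | None = None,
                       vectorized: bool = True) -> pd.DataFrame:
    """Transport a table of phase-space events and collect all collisions.

    Events whose straight-line ray misses the detector box produce no
    collisions and are skipped without consuming random numbers.
    Independent sub-streams are used per species.  The vectorised engine
    (default) transports all events of a species step-synchronously; the
    per-event functions remain available (``vectorized=False``) and are
    statistically equivalent.
    """
    tp = transport or TransportSection()
    ss = (rng_seed if isinstance(rng_seed, np.random.SeedSequence)
          else np.random.SeedSequence(rng_seed))
    seed_fn, seed_pg = ss.spawn(2)
    if len(events) == 0:
        return pd.DataFrame(columns=COLLISION_COLUMNS)
    origins = events[["prod_x_mm", "prod_y_mm", "prod_z_mm"]].to_numpy()
    dirs = events[["dir_x", "dir_y", "dir_z"]].to_numpy()
    enters, entry_points = batch_entrance(origins, dirs, det)
    species_arr = events["species"].to_numpy()
    energies = events["E0_MeV"].to_numpy(dtype=float)
    n_fast = int(np.sum(enters & (species_arr == FN)
                        & (neutron_speed(energies) / C_MM_NS > 0.1)))
    if n_fast:
        warnings.warn(
            f"{n_fast} neutrons generated with v/c > 0.1; the non-relativistic "
            "kinematics used throughout are an approximation for these",
            RuntimeWarning, stacklevel=2,
        )
    frames = []
    for species, seed, simulate in ((FN, seed_fn, simulate_neutron_history),
                                    (PG, seed_pg, simulate_gamma_history)):
        rng = np.random.default_rng(seed)
        mask = enters & (species_arr == species)
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            continue
        if vectorized:
            cols = _batch_histories(
                events["event_id"].to_numpy()[idx], entry_points[idx],
                origins[idx], dirs[idx], energies[idx],
                events["t0_ns"].to_numpy(dtype=float)[idx],
                species, det, rng, tp)
            if len(cols["event_id"]):
                frames.append(pd.DataFrame(cols))
        else:
            records: list[CollisionRecord] = []
            for i in idx:
                ev = PhaseSpaceEvent(
                    event_id=int(events["event_id"].iat[i]), species=species,
                    position=origins[i], energy=float(energies[i]),
                    direction=dirs[i], time=float(events["t0_ns"].iat[i]),
                )
                records.extend(simulate(ev, det, rng, tp))
            if records:
                frames.append(_records_to_frame(records))
    if not frames:
        return pd.DataFrame(columns=COLLISION_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["event_id", "hit_index"], kind="mergesort")
    out = out[COLLISION_COLUMNS].reset_index(drop=True)
    for col in ("species", "kind"):
        out[col] = out[col].astype("category")
    return out


def generate_dataset(model: EmissionModel, beam: BeamGeometry,
                     det: DetectorGeometry, n_protons: int,
                     rng_seed: int | np.random.SeedSequence,
                     transport: TransportSection | None = None,
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """End-to-end synthetic run: emission sampling plus interaction histories.

    Returns linked event and collision tables; the event table retains the
    true production coordinates for ground-truth analyses.
    """
    ss = (rng_seed if isinstance(rng_seed, np.random.SeedSequence)
          else np.random.SeedSequence(rng_seed))
    seed_emit, seed_hist = ss.spawn(2)
    events = sample_emission(model, beam, n_protons, seed_emit)
    collisions = simulate_histories(events, det, seed_hist, transport)
    return events, collisions
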