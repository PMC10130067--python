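"""End-to-end orchestration: simulate -> smear -> cones -> image -> detect.

The stages mirror the analysis workflow: a synthetic phase space is
generated for each range-shift scenario, detector response is applied,
event cones are reconstructed and imaged, 1D depth profiles are extracted,
and bootstrapped range-landmark distributions feed the Gaussian Naive
Bayes / AUROC detectability analysis over a grid of proton intensities.

A single global seed spawns independent sub-streams per scenario and
stage, so partial re-runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import Config
from .constants import FN, PG, SUM
from .detection import min_intensity_at_threshold, repeated_auroc
from .geometry import build_geometry
from .imaging import backproject, build_image_plane, cone_footprints, lmmlem, slice_profile
from .kinematics import reconstruct_cones
from .phasespace import apply_range_shift, emission_model_from_config, generate_dataset
from .range_stats import (
    DepthProfile,
    bin_ground_truth,
    bootstrap_rl_ground_truth,
    calibrate_shift,
    range_landmark,
)
from .response import apply_energy_cuts, select_coincidences, smear_collisions


@dataclass
class ScenarioResult:
    """Artifacts of one range-shift scenario."""

    shift_mm: float
    n_protons: int
    events: pd.DataFrame
    collisions: pd.DataFrame
    profiles: dict[str, DepthProfile]  # reconstructed 1D profiles per species
    ground_truth_z: dict[str, np.ndarray]  # production depths of imaged events
    n_cones: dict[str, int]
    tallies: dict[str, dict] = field(default_factory=dict)
    images: dict = field(default_factory=dict)  # per-species ReconstructedImage

    @property
    def efficiency(self) -> dict[str, float]:
        """Accepted cones per simulated proton, per species."""
        return {sp: n / self.n_protons for sp, n in self.n_cones.items()
                if sp != SUM}


def run_scenario(config: Config, shift_mm: float, n_protons: int,
                 rng_seed: int | np.random.SeedSequence,
                 smeared: bool = True,
                 chunk_protons: int = 20_000_000) -> ScenarioResult:
    """Simulate one scenario and reconstruct its FN/PG/SUM depth profiles.

    Smeared data are imaged by plain cone back-projection; unsmeared data
    use list-mode MLEM (the un-regularised iteration is reserved for
    noise-free cones, switchable via ``imaging.use_mlem_smeared``).

    Large spots are simulated in chunks of ``chunk_protons`` to bound peak
    memory; only events that produced at least one collision keep their
    phase-space (truth) row in the returned table.
    """
    ss = (rng_seed if isinstance(rng_seed, np.random.SeedSequence)
          else np.random.SeedSequence(rng_seed))
    seed_sim, seed_smear = ss.spawn(2)
    beam, det = build_geometry(config)
    model = apply_range_shift(emission_model_from_config(config), shift_mm)
    n_chunks = max(1, -(-n_protons // chunk_protons))
    chunk_sizes = [n_protons // n_chunks] * n_chunks
    chunk_sizes[-1] += n_protons - sum(chunk_sizes)
    ev_frames, col_frames = [], []
    for k, (n_chunk, seed) in enumerate(zip(chunk_sizes, seed_sim.spawn(n_chunks))):
        ev, col = generate_dataset(model, beam, det, n_chunk, seed,
                                   config.transport)
        offset = k * (1 << 33)  # keep event ids globally unique across chunks
        ev["event_id"] += offset
        col["event_id"] += offset
        ev_frames.append(ev[ev["event_id"].isin(col["event_id"])])
        col_frames.append(col)
    events = pd.concat(ev_frames, ignore_index=True)
    collisions = pd.concat(col_frames, ignore_index=True)
    collisions = apply_energy_cuts(collisions, config.resolution)
    if smeared and len(collisions):
        collisions = smear_collisions(collisions, det, config.resolution, seed_smear)
    plane = build_image_plane(beam, det, config.imaging.n_pixels,
                              config.imaging.pixel_mm)
    use_mlem = (not smeared) or config.imaging.use_mlem_smeared
    profiles: dict[str, DepthProfile] = {}
    gt_z: dict[str, np.ndarray] = {}
    n_cones: dict[str, int] = {}
    tallies: dict[str, dict] = {}
    images: dict = {}
    for species in (FN, PG):
        selected, tally = select_coincidences(collisions, species)
        cones, rejections = reconstruct_cones(selected, species)
        tallies[species] = {**tally.as_dict(), "cone_rejections": rejections}
        n_cones[species] = len(cones)
        imaged_ids = {c.event_id for c in cones}
        ev = events[events["species"] == species]
        gt_z[species] = ev[ev["event_id"].isin(imaged_ids)]["prod_z_mm"].to_numpy()
        footprints = cone_footprints(cones, plane, config.imaging.n_rays)
        if cones:
            image = (lmmlem(footprints, plane, config.imaging.mlem_iterations)
                     if use_mlem else backproject(footprints, plane))
            images[species] = image
            prof = slice_profile(image, beam, config.imaging.slice_half_width)
            profiles[species] = DepthProfile(edges=prof.edges, counts=prof.counts,
                                             species=species)
        else:
            plane_edges = plane.u_edges()
            profiles[species] = DepthProfile(edges=plane_edges,
                                             counts=np.zeros(len(plane_edges) - 1),
                                             species=species)
    profiles[SUM] = profiles[FN] + profiles[PG]
    gt_z[SUM] = np.concatenate([gt_z[FN], gt_z[PG]])
    n_cones[SUM] = n_cones[FN] + n_cones[PG]
    return ScenarioResult(shift_mm=shift_mm, n_protons=n_protons, events=events,
                          collisions=collisions, profiles=profiles,
                          ground_truth_z=gt_z, n_cones=n_cones, tallies=tallies,
                          images=images)


def detectability_study(config: Config, n_protons: int, shifts, intensities,
                        rng_seed: int, species=(FN, PG, SUM),
                        n_boot: int | None = None, n_repeats: int | None = None,
                        smeared: bool = True,
                        ) -> tuple[pd.DataFrame, dict[float, ScenarioResult]]:
    """AUROC grid over (species, shift, intensity) from reconstructed profiles.

    One scenario is simulated per shift (plus the no-shift reference); for
    every grid cell the no-shift and shifted profiles are Poisson-
    bootstrapped at the intensity-matched scale and the repeated-split GNB
    AUROC of the two RL sample sets is recorded.
    """
    n_boot = n_boot or config.analysis.bootstrap_iterations
    n_repeats = n_repeats or config.analysis.gnb_repeats
    ss = np.random.SeedSequence(rng_seed)
    shifts = list(shifts)
    seeds = ss.spawn(len(shifts) + 2)
    def slim(res: ScenarioResult) -> ScenarioResult:
        # keep only what the bootstrap/detection stages need (the full event
        # tables of a large run would otherwise dominate memory)
        res.events = res.events.iloc[0:0]
        res.collisions = res.collisions.iloc[0:0]
        return res

    scenarios: dict[float, ScenarioResult] = {
        0.0: slim(run_scenario(config, 0.0, n_protons, seeds[0], smeared))
    }
    for shift, seed in zip(shifts, seeds[1:-1]):
        scenarios[shift] = slim(run_scenario(config, shift, n_protons, seed, smeared))
    cell_ss = seeds[-1]
    rows = []
    from .range_stats import bootstrap_rl_reconstructed

    for sp in species:
        for shift in shifts:
            for intensity in intensities:
                s0, s1, s2 = cell_ss.spawn(3)
                scale = intensity / n_protons
                rl0 = bootstrap_rl_reconstructed(
                    scenarios[0.0].profiles[sp], scale, n_boot, s0, species=sp,
                    intensity=intensity)
                rl1 = bootstrap_rl_reconstructed(
                    scenarios[shift].profiles[sp], scale, n_boot, s1, species=sp,
                    intensity=intensity)
                mean, sd = repeated_auroc(rl0.samples, rl1.samples,
                                          n_repeats=n_repeats,
                                          test_frac=config.analysis.test_fraction,
                                          rng_seed=s2)
                rows.append({
                    "species": sp, "shift_mm": shift, "intensity": intensity,
                    "auroc_mean": mean, "auroc_sd": sd, "n_repeats": n_repeats,
                    "n_cones": scenarios[shift].n_cones[sp],
                })
    return pd.DataFrame(rows), scenarios


def intensity_thresholds(summary: pd.DataFrame, threshold: float = 0.9,
                         log_interp: bool = True) -> pd.DataFrame:
    """Interpolated minimum intensity at the AUROC threshold per (species, shift)."""
    rows = []
    for (sp, shift), grp in summary.groupby(["species", "shift_mm"]):
        grp = grp.sort_values("intensity")
        best, bounds = min_intensity_at_threshold(
            grp["intensity"].to_numpy(), grp["auroc_mean"].to_numpy(),
            grp["auroc_sd"].to_numpy(), threshold, log_interp)
        rows.append({
            "species": sp, "shift_mm": shift, "min_intensity": best,
            "min_intensity_lo": bounds[0] if bounds else None,
            "min_intensity_hi": bounds[1] if bounds else None,
        })
    return pd.DataFrame(rows)


def ground_truth_calibration(config: Config, shifts, n_samples: int,
                             rng_seed: int, species: str = FN,
                             ) -> tuple[float, float, float, pd.DataFrame]:
    """Delta-RL vs true-shift calibration on ground-truth emission depths.

    For each shift a fresh emission sample is drawn (independent seeds) and
    the RL of its binned depth profile is compared to the no-shift
    reference; an OLS fit quantifies the linear response.
    """
    from .phasespace import sample_depths

    model0 = emission_model_from_config(config)
    ss = (rng_seed if isinstance(rng_seed, np.random.SeedSequence)
          else np.random.SeedSequence(rng_seed))
    support = config.analysis.profile_support_mm
    bw = config.analysis.gt_bin_mm

    def rl_for(model, seed):
        rng = np.random.default_rng(seed)
        z = sample_depths(model, species, n_samples, rng)
        return range_landmark(bin_ground_truth(z, bw, support, species))

    shifts = list(shifts)
    seeds = ss.spawn(len(shifts) + 1)
    rl0 = rl_for(model0, seeds[0])
    records = []
    for shift, seed in zip(shifts, seeds[1:]):
        rl = rl_for(apply_range_shift(model0, shift), seed)
        records.append({"shift_mm": shift, "delta_rl": rl - rl0})
    frame = pd.DataFrame(records)
    slope, intercept, r2 = calibrate_shift(frame["shift_mm"], frame["delta_rl"])
    return slope, intercept, r2, frame


def ground_truth_rl_distribution(config: Config, production_z: np.ndarray,
                                 n_total: int, n_histories: float,
                                 intensity: float, rng_seed, species: str = ""):
    """Convenience wrapper: intensity-matched coordinate bootstrap."""
    from .range_stats import bootstrap_sample_size

    n = bootstrap_sample_size(n_total, n_histories, intensity)
    return bootstrap_rl_ground_truth(
        production_z, n, config.analysis.bootstrap_iterations, rng_seed,
        config.analysis.gt_bin_mm, config.analysis.profile_support_mm,
        config.analysis.use_bin_centers, species, intensity)
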