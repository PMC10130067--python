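# Methods

This note documents the models implemented in `fnpgrange`, the assumptions
behind them, the default parameters and why they were chosen, and the
numerical and statistical design decisions.  It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinate conventions and geometry

The proton beam travels along +z; depth in the patient is measured from
the entrance plane z = `surface_z` (default 0 mm).  The treatment
isocenter is the world origin.  The detector is a 300 × 200 × 200 mm³
array of 10 × 10 mm² organic scintillator bars (20 × 20 = 400 bars), with
dual-ended readout resolving the depth of interaction (DOI) along the
300 mm bar axis.  Its placement is set by the angle θ between the beam
axis and the isocenter-to-face-center line (θ measured in the x–z plane)
and the distance D along that line.  D is not dictated by the physics of
the method; the default of 300 mm is a plausible clinical standoff and is
configurable.  Bars run parallel to the back-projection plane, as implied
by the DOI readout; the stacking grid spans the other face axis and the
detector depth.

## Synthetic phase space

The generator emulates the statistical structure of a Monte-Carlo patient
simulation without modelling the patient:

* **Depth profiles.**  FN production falls gently along the proton track:
  a truncated exponential with decay length 30 mm on [0, R₀]
  (R₀ = 60 mm, an 85 MeV proton range in soft tissue).  PG production
  rises roughly linearly to a distal peak and falls off sharply:
  (z/R₀)¹ × logistic(−(z − R₀)/w) with w = 2 mm.  Both choices reproduce
  the qualitative structure of proton-induced secondary emission — FN
  dominant at shallow depths, PG dominant near the end of range — while
  keeping the two distributions broad and strongly overlapping, as they
  are in patient-scale simulations.  The overlap matters statistically:
  for the summed FN+PG landmark the per-sample variance decomposes as
  Var_sum = w·V_FN + (1−w)·V_PG + w(1−w)·D², with D the separation of the
  species' mean depths and w the FN count fraction.  Only when D stays
  below roughly 1.5× the per-species depth spread does the summed
  distribution inherit the 1/√N benefit of pooled counts — the mechanism
  behind the improved sensitivity of summed distributions.  Spiky,
  disjoint profiles would bury that benefit under composition noise and
  would misrepresent the system being emulated.
* **Range shifts.**  A shift Δ rigidly translates both profiles.  It is
  stored as a model parameter and applied at sampling time, so shifts
  compose additively and invert exactly.  A *negative* shift corresponds
  to added tissue upstream of the nominal entrance plane, so production at
  slightly negative depth is physical; the translated support is clipped
  only at `clip_z_min` = −10 mm and the analysis histograms span
  [−10, 110] mm.  Clipping at z = 0 would destroy the exact translation
  equivariance of the landmark for dilation-like shifts.
* **Yields and spectra.**  0.05 FN and 0.10 PG per proton (production, not
  detection, per 85 MeV proton on tissue — order-of-magnitude realistic);
  FN energies follow a truncated exponential (T = 8 MeV) on 0.5–60 MeV;
  PG energies are drawn from the discrete lines {2.2, 4.44, 5.2, 6.13} MeV
  with weights {0.15, 0.50, 0.15, 0.20} (carbon 4.44 MeV dominant).  FN
  directions are forward-peaked via a von Mises–Fisher density with
  κ = 2 (a qualitative choice — κ = 0 recovers isotropy); PG emission is
  isotropic.
* **Transport.**  Mean free paths are effective constants (λₙ = 50 mm,
  λ_γ = 150 mm), not cross-section driven: for this package only the
  *kinematic correctness* of the collision sequences matters.  Neutron
  (n,p) scattering is isotropic in the centre of mass, so the recoil
  energy is uniform on (0, E) and the lab angle obeys sin²θ = Eₚ/E
  exactly.  Photon scattering angles are sampled from the Klein–Nishina
  cross-section (flat-envelope rejection, bound f(cos θ = 1) = 2) with the
  exact Compton energy update; a 5% per-interaction photoabsorption
  terminates a history by depositing the full remaining energy.  Histories
  stop on exit, after 5 interactions, or (neutrons) below 0.1 MeV.
  Neutron transport is non-relativistic, matching the reconstruction; a
  warning counts generated neutrons with v/c > 0.1.
* **What is not modelled.**  No patient attenuation or in-patient scatter
  (an optional exponential attenuation hook exists), no energy-dependent
  DOI resolution, no light quenching function (the ×2 FN resolution
  scaling stands in for it), no pile-up, dead time or species
  misidentification.  Consequently, passing tests demonstrate the
  correctness and statistical behaviour of the *analysis chain*, not the
  absolute performance of a physical detector.

Two transport engines produce statistically identical histories: scalar
per-event functions (reference implementation, used by the kinematics
tests) and a step-synchronous vectorised engine used for throughput.
Events whose straight-line ray misses the detector box are skipped without
consuming random numbers.

## Detector response

Cuts of 100 keV (FN) and 10 keV (PG) are applied to the *true* deposits
before smearing.  The relative energy resolution
R(L) = √(α² + β²/L + γ²/L²) with α = 0.0497, β = 0, γ = 0.0349 is
interpreted as FWHM/centroid (σ = R·L/2.3548); the interpretation is
switchable (`resolution_is_fwhm`), as the convention is not fixed by the
parameter values themselves.  The same FWHM convention is applied to the
500 ps timing and the 11.775 mm DOI resolution.  Deposited energy in MeV
is identified with light output in MeVee; the FN ×2 scaling of R partially
accounts for quenching.  The two transverse hit coordinates are re-sampled
uniformly within ±2.5 mm of the segment centre (a 5 mm window inside a
10 mm segment, kept as specified).  Negative smeared energies are redrawn
(truncation).  Coincidence selection uses the smeared times, as an
experiment would: FN events need ≥2 (n,p) scatters with the first two in
distinct bars; PG events need ≥3 interactions (the third may be an
absorption) in pairwise-distinct bars.  The distinct-bar rule is stated
for PG readout and extended to FN here, since TOF between hits in a single
bar would not be resolvable.  All rejections are tallied, and tallies
balance against input counts.

## Cone reconstruction

FN: τ and d between the first two scatters give E′ₙ = ½ mₙc²(d/(τc))²
(evaluated via β = (d/τ)/c to avoid unit drift), Eₙ = E′ₙ + Eₚ, and
θ = sin⁻¹√(Eₚ/Eₙ); the apex is the first scatter, the axis points from the
second scatter to the first.  Rejections: non-positive τ, superluminal
separation (possible after smearing; rejection rather than capping),
Eₚ/Eₙ > 1 cannot occur by construction.  β > 0.1 is possible for the hard
end of the FN spectrum and is only counted, matching the non-relativistic
design.

PG: the second-scatter angle θ₂ comes from the hit geometry and, with the
first two deposits, determines E_γ in closed form; θ₁ then follows from
the Compton relation.  The third hit contributes only its position.
Collinear triples (division by 1 − cos θ₂) and smeared events with
|cos θ₁| > 1 are rejected and counted.

Cone rays: n equi-spaced azimuths (default 1000) around the axis, built on
a deterministic orthonormal frame seeded by the global axis least aligned
with the cone axis (singularity-free tie-break).

For unsmeared histories the reconstruction round-trips exactly: the
emission direction lies on the cone and the PG energy is recovered to
machine precision.  This is checked for every accepted cone in the
acceptance suite.  With energy cuts enabled, a removed sub-threshold hit
makes a selected coincidence non-consecutive and legitimately breaks the
closed form, so exactness checks run with negligible cuts.

## Imaging

The back-projection plane contains the beam axis; its normal is the
component of the line of sight perpendicular to the beam (x–z fallback for
the degenerate anterior case).  The default grid is 100 × 100 pixels of
2 mm, centred at mid-range depth.  Footprints are binary (one increment
per cone and pixel).  LM-MLEM runs exactly 100 iterations from a uniform
start with unit sensitivities; the recorded objective is the full
list-mode Poisson log-likelihood Σᵢ log(Σⱼ tᵢⱼλⱼ) − Σⱼλⱼ, which the EM
update increases monotonically; after the first update the total intensity
is fixed at the event count, making the first term monotone on its own.
MLEM is applied to unsmeared cones; smeared pipelines use plain
back-projection (the un-regularised iteration amplifies noise), with a
flag to override.

1D profiles are slices through the image along the beam axis.  The default
slice integrates ±2 pixel rows (±5 mm): the 4.7 mm FWHM beam spot spreads
production over about that window, and a single 2 mm row through a
list-mode MLEM image at desk-scale counts is dominated by reconstruction
speckle.  The width is configurable (`imaging.slice_half_width`).

## Range landmark and bootstraps

The RL is the count-weighted mean of bin-centre depths (1 mm bins for
ground truth, the 2 mm pixel grid for reconstructions).  A raw-coordinate
mean is available behind `use_bin_centers=False`.  The intensity-matched
bootstrap sample size is N = N_total/(N_hist/I).  Ground-truth bootstrap:
resample N coordinates with replacement, bin, take the RL (vectorised as
bin-centre mapping followed by resampled means, which is algebraically
identical).  Reconstructed bootstrap: rescale each profile bin by I/N_hist
and resample it from a Poisson distribution, once per iteration, on the
*single* reconstruction — no re-reconstruction per iteration.  Defaults:
10⁴ iterations.  All-zero resamples are redrawn and counted.  Bootstrap RL
distributions are Gaussian in the CLT regime; the normality check uses
Shapiro–Wilk on a seeded subsample of ≤2000 draws (the test is unreliable
for much larger samples, and at 10⁴ draws it would resolve the
O(skew/√N) finite-N departure that is irrelevant to the detection stage).

## Detection

A single-feature Gaussian Naive Bayes classifier (class means,
ML variances floored at 10⁻¹² mm², empirical priors, log-space posterior,
ties to "no shift") is re-fit on 1000 random unstratified 80/20 splits;
test samples are scored with the shift-class posterior and the AUROC uses
the rank-sum estimator with tie correction.  Splits that lose a class are
redrawn.  Posterior scores and raw RL values give identical AUROC whenever
the posterior is monotone in RL (verified in tests); the closed form
AUROC = Φ(d/(σ√2)) for equal-variance Gaussian classes is the reference
oracle.  Detectability thresholds interpolate the mean AUROC linearly in
log₁₀(intensity) against the 0.9 level (switchable to linear), with bounds
from the mean ± σ curves.

## Problem sizes

Desk-scale sizes are chosen by statistical power, not convenience:

* Kinematic round trips: ≥1000 accepted cones per species, generated with
  direction importance-aiming at the detector face (`sample_aimed_emission`);
  aiming changes only the acceptance rate, not the kinematics.
* Calibration: 11 shifts of −5…+5 mm, 2 × 10⁵ depths each, independent
  seeds; the RL sampling error (~0.04 mm) makes the OLS slope error ≪ 0.05.
* Detectability grid: shifts {0.5, 1, 2} mm × intensities {10⁶, 10⁷, 10⁸},
  unsmeared LM-MLEM route, 2000 bootstrap RLs per class, 1000 GNB repeats.
  The simulated spot (10⁸ protons in the acceptance script, 2 × 10⁸ in the
  acceptance test) is set so that the scenario-level landmark noise
  σ_depth/√N_cones (≈0.05–0.1 mm) sits well below the smallest shift gap
  of 0.5 mm; per-intensity bootstrap widths are invariant to the simulated
  spot size, since the rescaling factor I/N_hist cancels against the cone
  count.  Generation is chunked (2 × 10⁷ protons per chunk) to bound peak
  memory, and only events with detector collisions keep their truth rows.

## Known limitations

* The landmark responds to *any* change in the detected depth
  distribution, including acceptance changes, not only to true range
  shifts; the synthetic study isolates the shift response by construction.
* Back-projected (smeared-route) profiles carry broad arc backgrounds;
  their landmark response remains linear but noisier than the MLEM route,
  and substantially more cones are needed for the same power.
* Single-detector, single-spot geometry; no patient heterogeneity, so
  imaging artifacts from data incompleteness at oblique orientations are
  not reproduced quantitatively.
* The Poisson bootstrap treats reconstructed bin values as independent;
  MLEM induces inter-bin correlations that the bin-wise resampling
  procedure ignores.
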