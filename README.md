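# fnpgrange

Hybrid **fast-neutron (FN) / prompt-gamma (PG)** imaging for proton-range
verification, as a reusable simulation and analysis pipeline.

During proton therapy the beam stops inside the patient, so the beam range
must be monitored indirectly through secondary particles.  A compact array
of optically segmented organic scintillator bars can detect *both* fast
neutrons (via double (n,p) elastic scatter with time-of-flight) and prompt
gamma rays (via triple Compton scatter), reconstruct an event cone per
particle, and image the production distributions in the patient.  Because
FN production dominates at shallow depths while PG production peaks near
the end of the proton track, the two species carry complementary range
information, and pooling them improves the statistics available from a
single pencil-beam spot (10⁶–10⁸ protons).

`fnpgrange` implements this chain end to end with a synthetic phase-space
generator standing in for a full Monte-Carlo patient simulation:

1. **Phase space** — FN/PG production points tied to a nominal range R₀,
   with a controlled range shift Δ translating both depth profiles rigidly;
   detector interaction histories satisfy the scattering kinematics exactly.
2. **Detector response** — deposited-energy cuts (100 keV FN / 10 keV PG),
   the measured resolution model R(L) = √(α² + β²/L + γ²/L²)
   (α = 0.0497, β = 0, γ = 0.0349), 500 ps FWHM timing, 11.775 mm
   depth-of-interaction resolution and 5 mm uniform segment re-sampling.
3. **Cone reconstruction** — FN: E′ₙ = ½ mₙ(d/τ)², Eₙ = E′ₙ + Eₚ,
   θ = sin⁻¹√(Eₚ/Eₙ); PG: the closed-form Compton solution for E_γ from the
   first two deposits and the second-scatter angle, then
   cos θ₁ = 1 + mₑc²(1/E_γ − 1/E′_γ).
4. **Imaging** — each cone discretised into 1000 equi-spaced rays,
   intersected with a plane through the beam axis, binned once per cone
   into an N×N grid (binary footprints); list-mode MLEM
   λⱼ ← λⱼ Σᵢ tᵢⱼ / (Σⱼ′ tᵢⱼ′ λⱼ′) with unit sensitivities, 100 iterations
   (plain back-projection for resolution-smeared data).
5. **Range landmark (RL)** — the count-weighted mean depth of the 1D
   profile; ΔRL tracks the true range shift one-to-one.
6. **Detection** — intensity-matched bootstrap of RL distributions
   (coordinate resampling for ground truth, per-bin Poisson resampling for
   reconstructed profiles), a Gaussian Naive Bayes classifier over
   repeated random 80/20 splits, and the mean AUROC with an
   AUROC ≥ 0.9 detectability threshold.

## Worked example

```python
from fnpgrange.config import Config
from fnpgrange.pipeline import run_scenario
from fnpgrange.range_stats import range_landmark, bootstrap_rl_reconstructed, delta_rl
from fnpgrange.detection import repeated_auroc

cfg = Config()                               # reference settings
ref     = run_scenario(cfg, 0.0, 2_000_000, 11, smeared=False)
shifted = run_scenario(cfg, 2.0, 2_000_000, 12, smeared=False)
print("accepted cones (no shift):", ref.n_cones)
print(f"summed-profile range landmark: "
      f"{range_landmark(ref.profiles['SUM']):.2f} mm -> "
      f"{range_landmark(shifted.profiles['SUM']):.2f} mm")
b0 = bootstrap_rl_reconstructed(ref.profiles["SUM"],     1e7 / 2_000_000, 2000, 13)
b1 = bootstrap_rl_reconstructed(shifted.profiles["SUM"], 1e7 / 2_000_000, 2000, 14)
d, sd = delta_rl(b1, b0)
print(f"Delta RL at 1e7 protons/spot: {d:.2f} +/- {sd:.2f} mm")
auc, auc_sd = repeated_auroc(b0.samples, b1.samples, n_repeats=500, rng_seed=15)
print(f"mean AUROC (no shift vs 2 mm): {auc:.3f} +/- {auc_sd:.3f}")
```

Output:

```
accepted cones (no shift): {'FN': 1198, 'PG': 639, 'SUM': 1837}
summed-profile range landmark: 25.52 mm -> 28.19 mm
Delta RL at 1e7 protons/spot: 2.66 +/- 0.30 mm
mean AUROC (no shift vs 2 mm): 1.000 +/- 0.000
```

Two million simulated protons yield ~1800 imaged cones; the summed FN+PG
range landmark moves by ≈2.7 mm under a 2 mm applied shift (unit response
plus Monte-Carlo fluctuation of this small run), and at a spot intensity of
10⁷ protons the bootstrapped RL distributions of the two scenarios are
perfectly separable (AUROC ≈ 1), i.e. a 2 mm shift is comfortably
detectable at that intensity.

A command-line driver exposes the stages individually:

```sh
fnpgrange simulate  --n-protons 1000000 --shift 1.0 --out-dir out
fnpgrange calibrate --shift-grid -5,-4,-3,-2,-1,0,1,2,3,4,5 --out-dir out
fnpgrange detect    --n-protons 20000000 --shift-grid 0.5,1,2 \
                    --intensity-grid 1e6,1e7,1e8 --out-dir out
```

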