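# ipdtsim

Simulation of interstitial photodynamic therapy (iPDT) outcomes for
5-aminolevulinic-acid-induced protoporphyrin IX (ALA-PpIX) in brain
tissue: voxel Monte Carlo light transport from cylindrical fiber
diffusers, a photobleaching-corrected singlet-oxygen dose model, and
threshold-based cell-death segmentation with treated-volume metrics.

It is written for medical-physics and biomedical-optics researchers who
need a quantitative, reproducible way to explore how iPDT outcomes depend
on treatment variables — diffuser positions and spacing, delivered
fluence, photosensitizer concentration, and photobleaching — before (or
instead of) clinical measurement.

## Model

The pipeline has three stages:

1. **Light transport.**  Photon packets are launched from the lateral
   surface of cylindrical diffusers (default 1.1 mm diameter, 40 mm
   radiation length) and propagated through a voxelized tissue model by
   Monte Carlo (Henyey–Greenstein scattering, absorption weighting,
   Russian roulette), yielding the fluence-rate field φ(x,y,z) in mW/cm².
   Every run carries an exact energy-conservation ledger.

2. **Singlet-oxygen dose.**  The accumulated singlet-oxygen concentration
   after delivering fluence F = φT (J/cm²) to tissue with initial PpIX
   concentration C₀ is

       D_SO = A · Φ · C₀ · β · (1 − e^(−F/β)),
       A = 1000 · ε · ln10 · λ / (h c N_A) ≈ 61.3 (J/cm²)⁻¹,

   with ε = 5000 cm⁻¹M⁻¹, λ = 635 nm, singlet-oxygen quantum yield
   Φ = 0.77 and photobleaching fluence constant β (default 13.5 J/cm²).
   Photobleaching makes the dose saturate at A·Φ·C₀·β: beyond a few β of
   fluence, more light adds almost nothing.

3. **Outcome.**  Cell death is assumed where D_SO reaches the threshold
   D_SO(th) (default 0.56 mM); the treated volume TV (killed tumor),
   damaged volume DV (killed normal tissue) and tumor coverage
   TC = TV / tumor volume summarize the plan.

Closed-form inversions of stage 2 — required fluence for a threshold,
minimum treatable C₀, minimum bleaching coefficient — are first-class
functions.  See `docs/methods.md` for assumptions and numerical details.

## Worked example

```python
import math
import ipdtsim as ipdt

params = ipdt.PhotophysicalParams()  # ε=5000, 635 nm, Φ=0.77, β=13.5

# Fluence needed to reach the cell-death threshold at C0 = 5.8 uM:
for th_mM in (0.4, 0.56, 0.72):
    f = ipdt.required_fluence(th_mM * 1e-3, 5.8e-6, params)
    print(f"threshold {th_mM} mM -> required fluence {f:.2f} J/cm^2")

# Below this PpIX level no amount of light can treat a voxel:
c0_min = ipdt.min_initial_concentration(0.56e-3, math.inf, params)
print(f"minimum treatable C0: {c0_min * 1e6:.2f} uM")

# A small end-to-end run: uniform tumor phantom, one diffuser.
model = ipdt.build_uniform_phantom((64, 64, 64), (0.01, 0.01, 0.01))
diff = ipdt.DiffuserSpec(tip_position=(0.32, 0.32, 0.12),
                         radiation_length=0.4, linear_power_density=200.0)
fluence = ipdt.simulate_fluence(model, diff, n_photons=100_000, seed=1)
dose = ipdt.dose_map(fluence, 3600.0, model, params)
mask = ipdt.cell_death_mask(dose, 0.56e-3)
report = ipdt.volume_metrics(mask, model)
print(f"TV = {report.tv:.3f} cm^3, TC = {report.tc:.2f}")
```

Output:

```
threshold 0.4 mM -> required fluence 1.55 J/cm^2
threshold 0.56 mM -> required fluence 2.22 J/cm^2
threshold 0.72 mM -> required fluence 2.93 J/cm^2
minimum treatable C0: 0.88 uM
TV = 0.255 cm^3, TC = 0.97
```

The required fluences are strikingly small (a 200 mW/cm diffuser delivers
~580 mW/cm² at its surface, i.e. 2 J/cm² within seconds at the fiber);
the treatment margin is set by how fast fluence decays with distance, and
the minimum-C₀ line shows why regions of poor ALA-PpIX uptake stay
untreated no matter how long the irradiation runs.

The same pipeline is scriptable from the shell (`ipdtsim phantom`,
`fluence`, `dose`, `outcome`, `run`, `scan`); run `ipdtsim --help`.

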