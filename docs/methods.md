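# Methods

`ipdtsim` simulates the immediate outcome of interstitial photodynamic
therapy (iPDT) with 5-aminolevulinic-acid-induced protoporphyrin IX (PpIX)
in brain tissue.  The computation separates into three stages that mirror
the physics: light transport (Monte Carlo), photochemistry (singlet-oxygen
generation with photobleaching), and a threshold cell-death model with
volume metrics.

## Tissue models

A `TissueModel` is a regular voxel lattice (0-based indices; voxel
(i, j, k) occupies the half-open box `[origin + i·spacing,
origin + (i+1)·spacing)`, coordinates in cm) carrying a tissue label per
voxel (0 void, 1 normal/white matter, 2 tumor), a label → (μa, μs, g)
optical-property table, and an initial PpIX concentration field C0(x,y,z)
in mol/L.  Spacings are stored per axis and never assumed cubic.

Default optical properties at 635 nm: tumor μa = 1.7 cm⁻¹, μs = 365 cm⁻¹,
g = 0.9; white matter μa = 0.7 cm⁻¹, μs = 951 cm⁻¹, g = 0.9.

Two parametric generators stand in for patient imaging:

* **uniform phantom** — tumor-only block with uniform C0 (default 5.8 μM,
  the typical measured ALA-PpIX level in malignant brain tumor); the
  standard geometry for the photobleaching and sensitivity analyses;
* **ellipsoid phantom** — ellipsoidal tumor (voxel-center membership test)
  embedded in white matter, normal-tissue C0 = C0_tumor / TN with the
  tumor-to-normal uptake ratio TN (default 95; reported values for brain
  span ~12–95 depending on the reference tissue).

What these phantoms do **not** emulate: heterogeneous PpIX uptake,
irregular tumor boundaries, vasculature, edema, or any patient-specific
anatomy.  Tests passing on them validate the algorithms and the
bookkeeping, not clinical accuracy for a particular patient geometry.

## Monte Carlo light transport

Cylindrical fiber diffusers (defaults: outer diameter 0.11 cm, radiation
length 4 cm) are modeled as uniform lateral-surface emitters: launch
points are uniform in the axial coordinate and azimuth on the cylinder
surface; directions are isotropic over the outward hemisphere about the
local surface normal; end faces do not emit.  This is the simplest model
consistent with a "uniformly emitting radiation section" and with the
surface-fluence relation φ_sur = P_linear / (π·d).  Whether packets should
instead start inside the diffuser volume is an open modeling choice; the
surface launch was adopted and is isolated in one kernel function for
sensitivity checking.

Packet transport is the standard hop/drop/spin scheme on the voxel grid:
dimensionless step −ln ξ consumed across voxel boundaries with partial
geometric steps; at each interaction the packet deposits W·μa/μt in the
current voxel and scatters via Henyey–Greenstein with the local g; Russian
roulette below weight 1e-4 with survival probability 0.1.  Refractive
indices are matched everywhere (no Fresnel reflection); leaving the grid
or entering a void voxel terminates the packet into the escape tally; the
diffuser volume is ordinary tissue after launch.  Fluence rate is
estimated from absorbed weight, φ[v] = dep[v]·P_total/(n·μa[v]·V_voxel)
(mW/cm² for P in mW), with a track-length estimator in voxels where
μa = 0.

Numerical choices worth stating:

* **Energy ledger.**  `roulette_discarded_weight` is the *net* roulette
  weight (killed minus survivor boosts), so deposited + escaped +
  discarded equals the launched weight exactly (to float accumulation,
  ~1e-15 relative), giving a deterministic conservation assertion rather
  than an in-expectation one.
* **Reproducibility.**  The kernel is serial and seeded once; identical
  inputs and seed give bit-identical maps.  A global seed is expanded into
  per-diffuser substreams via `SeedSequence([seed, diffuser_index])`, so
  adding a diffuser to a plan never perturbs the streams of existing ones.
* **Boundary stepping** advances the voxel index on the axis that produced
  the nearest face (no epsilon nudging), which avoids stuck packets with
  grazing directions.
* `n_photons` defaults to 1e6 — adequate for fields within a few
  attenuation lengths of a fiber on desk hardware; increase for far-field
  statistics.

### Validation against the diffusion approximation

The independent oracle is the point-source diffusion closed form
φ(r) = P·exp(−μ_eff r)/(4πDr), D = 1/(3(μa+μs′)), μ_eff = √(3μa(μa+μs′)).
The P1 approximation is only trustworthy when μa ≪ μs′ and r is several
transport mean free paths; with the brain-tumor properties
(μa/μs′ ≈ 0.047) the closed form itself drifts from transport by ~16% at
r = 0.8 cm, which would test the oracle rather than the code.  The
cross-check therefore runs in a strongly diffusive validation medium
(μa = 0.3 cm⁻¹, μs = 40 cm⁻¹, g = 0: μa/μs′ ≈ 0.0075), where a
1e6-packet run from a near-point source (0.05 cm radiation section)
agrees with the closed form to ~1% over r = 0.3–0.8 cm (asserted at 15%).

## Singlet-oxygen dose model

Accumulated singlet-oxygen concentration for local fluence rate φ (W/cm²)
over time T:

    D_SO = A · Φ · C0 · β · (1 − exp(−φT/β))      [mol/L]
    A    = 1000 · ε · ln10 · λ / (h · c · N_A)    [(J/cm²)⁻¹]

with ε = 5000 cm⁻¹M⁻¹, λ = 635 nm, Φ = 0.77 (singlet-oxygen quantum
yield), β the photobleaching fluence constant (default 13.5 J/cm²;
literature range ~4.5–33).  A ≈ 61.3 (J/cm²)⁻¹ is the moles of photons
absorbed per liter per unit fluence per unit PpIX concentration; the 1000
converts cm³ to L.  Disabling bleaching gives the linear light-dose model
D_SO = A·Φ·C0·F.

Assumptions: ample tissue oxygenation (no oxygen depletion; Φ constant in
time and identical for tumor and normal tissue); photobleaching is a pure
fluence effect (C(t) = C0·exp(−φt/β)), making the dose a function of the
delivered fluence F = φT only (reciprocity).  The model deliberately
excludes oxygen-diffusion/consumption kinetics and triplet-state rate
equations.  Physical constants are stored at the rounded precision common
in this dosimetry literature (c = 3.0e10 cm/s, N_A = 6.0e23 mol⁻¹) rather
than CODATA values, so that derived quantities match the conventionally
printed numbers.

Derived quantities, all closed-form except the last:

* saturation dose `A·Φ·C0·β` — the F → ∞ limit under bleaching;
* required fluence `F = −β·ln(1 − D_th/(A·Φ·C0·β))`;
* minimum initial concentration `C0_min = D_th/(A·Φ·β·(1 − e^{−F/β}))`
  (at F = ∞: `D_th/(A·Φ·β)`);
* minimum bleaching coefficient: the root in β of
  `β(1 − e^{−F/β}) = D_th/(A·Φ·C0)`; the left side is monotone from 0 to
  F, so the root is unique and found by bracketed root-solving on
  [1e-6, 1e6] J/cm² to 1e-6 relative.

Infeasible inversions (threshold at or above saturation; threshold not
reachable even without bleaching) raise a dedicated
`UnreachableDoseError` instead of returning a number.

A trapezoidal time-stepped integral of the same integrand is kept as an
independent oracle; it converges to the closed form as O(dt²).

## Cell-death model and metrics

Cell death is assumed where D_SO reaches the threshold D_SO(th), default
0.56 mM; the same threshold applies to normal tissue (a conservative
choice — normal brain is likely more resistant).  The comparison is
inclusive (≥) so that a voxel driven exactly to threshold by the required
fluence counts as treated, keeping the inversion identity exact in
floating point; a strict mode is available.  Voxels are counted whole.

Metrics: TV (killed tumor volume), DV (killed normal volume),
TC = TV / tumor volume.  TC is reported as undefined (None/NaN) for
tumorless models rather than 0 or 1.

## Pipeline and scans

`run_pipeline` archives its config beside the outputs, so an output
directory regenerates itself bit-exactly from `config.yaml`.  Parameter
scans over photochemical quantities (C0, β, threshold) reuse one cached
fluence map — transport and photophysics separate exactly in this model —
while scans over transport parameters rerun the Monte Carlo stage.

## Problem sizes used in the shipped tests

Closed-form checks are instantaneous.  The Monte Carlo physics checks use
two shared 1e6-packet runs (a 64³ tumor phantom with a central diffuser
and the 60³ diffusive-medium point-source run, ~2–3 minutes each on one
core); all other transport tests use 5e3–2e5 packets on ≤64³ grids.  These
sizes were chosen as the smallest at which the statistical assertions
(5 relative standard errors for azimuthal symmetry, 15% for the diffusion
cross-check) are comfortably resolved.

## Known limitations

* No oxygen-depletion kinetics: in poorly perfused tissue the constant-Φ
  assumption overestimates dose.
* No thermal modeling; the 0.9 cm interfiber spacing convention is taken
  as an input constraint, not derived.
* Matched refractive indices everywhere; no Fresnel effects at the fiber
  or tissue boundaries.
* The threshold model ignores sublethal damage, repair, and immune
  response; it estimates the immediate photochemical outcome only.
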