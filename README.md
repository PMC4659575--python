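# atriomech

Multiscale simulation of human atrial electromechanics, built to study how
persistent atrial-fibrillation electrical remodeling (AFER) weakens atrial
contraction — the substrate of *atrial stunning* after cardioversion.

The package provides:

* **Coupled cell models** — the Courtemanche–Ramirez–Nattel human atrial
  action-potential model coupled to a Rice-type cross-bridge contraction
  model through Ca²⁺–troponin binding. The cytosolic Ca²⁺ balance is

  dCaᵢ/dt = b(Caᵢ)·[(2I_NaCa − I_CaL − I_bCa − I_pCa)/(2V_myo F)
  + (V_nsr(J_leak − J_up) + J_rel V_jsr)/V_myo − (dTropCa/dt)/1000],

  with b the instantaneous calmodulin buffering factor. A family of regional
  variants (crista terminalis, Bachmann's bundle, valve rings, appendages,
  septum, pulmonary veins, …) is generated by conductance scale factors, and
  an AF-remodeling profile (I_CaL −70%, I_Kur −50%, I_to −65%, I_K1 +100%,
  I_Ks +100%, I_NaCa +55%, SERCA +50%, RyR +300%, SR leak +25%) maps any
  variant to its chronic-AF counterpart.
* **Deformation-aware monodomain tissue** on 1D cables and 2D fibred sheets:
  C_m ∂V/∂t = −(I_ion + I_stim) + ∇·(D C⁻¹ ∇V), Strang splitting with
  Rush–Larsen reaction steps and Crank–Nicolson diffusion, a staggered 1 ms
  electromechanics loop exchanging active strain γ = (SL−SL₀)/SL₀ against
  the right Cauchy–Green tensor C, and cross-field S1–S2 re-entry induction.
* **Active-strain continuum kernels** — F = F_e F₀ with F₀ = I + γ f⊗f, the
  transversely isotropic Guccione energy W = C₁e^Q (C₁ = 0.831 kPa,
  C₂ = 14.31, C₃ = 4.49, C₄ = 10), its second Piola–Kirchhoff stress,
  homogeneous incompressible active contraction, and divergence-theorem
  cavity volumes on closed triangulated surfaces.

Intended users: cardiac-electrophysiology modellers who want a tested,
desk-scale (laptop-runnable) reference implementation of coupled atrial
electromechanics and of AFER's mechanical consequences.

## Worked example

Pace the baseline right-atrial cell to its 1 Hz steady state (1000 beats),
control vs AF-remodeled:

```bash
atriomech simulate-cell --region RA/PM --remodeling control --beats 1000 --out ra_control.csv
atriomech simulate-cell --region RA/PM --remodeling af      --beats 1000 --out ra_af.csv
```

prints

```
RA/PM/control: APD90=283.6 ms  Ca 0.106->1.605 uM  SL shortening 13.1%  peak force 0.243
RA/PM/af: APD90=136.9 ms  Ca 0.082->1.147 uM  SL shortening 5.8%  peak force 0.086
```

Reading: AF remodeling abbreviates the action potential, lowers the
diastolic→systolic Ca²⁺ transient (here −28% systolic), and consequently
collapses sarcomere shortening (13.1% → 5.8% of resting length) and peak
active force (−65%) — the cellular mechanism behind weak atrial contraction
in AF-remodeled tissue. The CSV holds the final-beat traces (t, V, Ca_i,
SR Ca, SL, γ, normalised force); a JSON manifest with config, versions and
output hashes is written alongside.

The same library surface exposes the regional sweep
(`atriomech sweep-regions`), cable/sheet tissue runs with conduction-velocity
measurement (`simulate-cable`, `simulate-sheet`, including `--s2-delay` for
cross-field re-entry induction on an AF sheet), cavity volumes
(`compute-volume`) and geometry fixtures (`make-fixture`). In Python:

```python
from atriomech.cell import PacingProtocol, run_pacing
trace = run_pacing("PV", "af", PacingProtocol(s1_count=1000))
print(trace.biomarkers)        # APD90, Ca levels, SL shortening, peak force
df = trace.to_frame()          # t, V, Ca_i, Ca_up, Ca_rel, SL, gamma, F_active
```

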