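# Methods

`atriomech` simulates human atrial electromechanics at three scales: the
single myocyte (biophysical action-potential model coupled to a cross-bridge
contraction model), desk-scale tissue (1D cables and 2D fibred sheets with a
deformation-aware monodomain equation), and the continuum kernels of the
active-strain elasticity framework (multiplicative deformation decomposition,
Guccione passive law, divergence-theorem cavity volume).

## The coupled cell model

**Electrophysiology.** The membrane model is the Courtemanche–Ramirez–Nattel
(CRN) human right-atrial myocyte: 12 Hodgkin–Huxley voltage gates, the
Ca²⁺-release gates (u, v, w) driven by the flux signal Fn, and five ionic
concentrations (Naᵢ, Kᵢ, Caᵢ, NSR and JSR Ca²⁺). All equations and parameters
are the published 1998 values; currents are whole-cell picoamperes on a 100 pF
cell. The published quiescent state is the initial condition, and the
regression tests verify rest-state stability (V stays at −81.2 mV for seconds
without stimulation) and that the fixed-step production integrator tracks an
adaptive stiff reference solve of an independently written right-hand side.

**Regional heterogeneity.** Conductance scale factors on G_Na, G_to, G_CaL,
G_Kr and G_Kur (applied exactly once, multiplicatively) produce the regional
AP family: crista terminalis and Bachmann's bundle (G_CaL ×1.67, CT epi/endo
sub-variants with reduced G_to), valve rings (G_CaL ×0.67 with G_Kr ×1.53
TVR / ×2.44 MVR), appendages, left atrium (G_Kr ×1.6), septum (G_Na ×1.5,
G_CaL ×0.25, G_Kur ×0.67). The right atrium / pectinate muscle profile is the
base model. The pulmonary-vein sleeve has no published factor row; its
profile (G_to ×0.75, G_CaL ×0.42, G_Kr ×3.0) follows the lineage pattern for
PV electrophysiology (reduced I_to and I_CaL, enhanced I_Kr) and was
calibrated once against the reported control PV APD₉₀ of 181 ms, then frozen;
it is overridable via `register_region`. The left-atrial limb of Bachmann's
bundle is mapped to the CT-upper-endo profile (the two are reported jointly).

**AF electrical remodeling (AFER).** Persistent-AF remodeling multiplies the
maximal activities: I_CaL ×0.30, I_Kur ×0.50, I_to ×0.35, I_K1 ×2, I_Ks ×2,
I_NaCa ×1.55, SERCA ×1.5, RyR ×4, SR leak ×1.25; I_Kr unchanged; the base
model carries no I_KACh so that entry is a recorded no-op. Factors act on
maximal scaling constants (conductances, i_NaCa_max, i_up_max, k_rel,
k_leak), never on instantaneous currents. Because the base model defines the
SR leak rate as I_up_max/Ca_up_max, the leak inherits the SERCA factor and
the +25% applies on top (net ×1.875); the decoupled alternative was evaluated
and reproduces the reported AF Ca-handling pattern much more poorly (see
Limitations).

**Myofilament mechanics.** Contraction is the Rice mean-field approximation
of cooperative thin-filament activation and cross-bridge cycling: Ca²⁺ binds
low- and high-affinity troponin sites; regulatory units switch
non-permissive/permissive with strong cooperativity (Hill-type permissivity,
n = 15); permissive units cycle through pre- and post-powerstroke
strongly-bound states whose mean distortions carry the normalised force;
sarcomere-overlap functions modulate attachment and force. Published base
rate constants are used at 37 °C (the Q10 corrections activate only below
that) with the rat/base species factor; both the temperature and species
scalings are configurable. In twitch ("cell") mode the sarcomere shortens
against the model's internal viscoelastic load with resting length
SL₀ = 1.9 µm; the isosarcometric mode is retained for steady-state
force–Ca²⁺ validation, where the closed-form steady state of the cycle is
checked against direct relaxation of the ODEs and yields a half-activation of
~2 µM and Hill slope ~5–7 at SL = 2.2 µm.

**Coupling.** The cytosolic Ca²⁺ balance replaces the electrophysiology
model's instantaneous troponin buffer with the myofilament model's dynamic
troponin binding:

    dCaᵢ/dt = b(Caᵢ) [ (2 I_NaCa − I_CaL − I_bCa − I_pCa)/(2 V_myo F)
                       + (V_nsr (J_leak − J_up) + J_rel V_jsr)/V_myo
                       − (dTropCa/dt)/1000 ]

with b the instantaneous calmodulin factor
1/(1 + CMDN_max·K_CMDN/(Caᵢ+K_CMDN)²), Caᵢ in mM and dTropCa/dt in µM/ms (the
1/1000 converts to mM). dTropCa/dt is the exact chain-rule derivative of the
troponin-bound Ca²⁺ (a function of troponin occupancies, sarcomere overlap and
the strongly-bound cross-bridge fraction), which makes the per-beat total-Ca
budget close to <0.1% of the cytosolic content swing (asserted at <0.5%).
The mechanical state feeds the tissue scale through the active strain
γ = (SL − SL₀)/SL₀.

**Integration.** The production integrator is fixed-step at Δt = 0.01 ms:
exact-exponential (Rush–Larsen) updates for every state that is linear in
itself at frozen inputs (the 12 voltage gates via 0.05 mV lookup tables of
steady state and exp(−Δt/τ), fca/u/v, and the cross-bridge mean distortions),
forward Euler for the remaining slow states. This choice replaces an adaptive
stiff sub-solver for the concentrations: at Δt = 0.01 ms the slow states are
integrated far inside their stability and accuracy limits, a dt-halving test
bounds the APD₉₀ sensitivity below 0.5 ms, and a one-beat comparison against
scipy's BDF at rtol 1e-8 stays under 1 mV outside the upstroke (the upstroke
itself carries a sub-ms phase shift). An adaptive reference path
(`cell_rhs_factory` + solve_ivp) is part of the package and serves as the
oracle in tests. Exponential gate updates keep gates in [0, 1] by
construction; concentrations carry defensive positivity floors that
physiological trajectories never touch.

**Stimulus and protocol.** Rectangular 2 ms current pulses; unless specified,
the amplitude is twice the diastolic threshold found by bisection per cell
variant (capture = sustained depolarisation 30 ms after the pulse). The
standard protocol is 1000 S1 beats at 1 Hz (the full-protocol steady state;
biomarkers are read from the final beat) with an optional premature S2. Tests
use shorter conditioning trains where only kinetics are at stake; the
residual approach-to-steady-state drift of the baseline control APD₉₀ between
beat 200 and beat 1000 is about −11 ms (294.5 → 283.6), and the last-10-beat
drift after 1000 beats is <0.05 ms.

**Biomarkers.** APD₉₀ is measured from the instant of maximal dV/dt to 90%
repolarisation of (V_max − V_diastolic), the diastolic reference sampled
immediately before the stimulus, with linear interpolation of the crossing;
Ca²⁺ diastolic/systolic and SL/force extrema are per-beat extrema; SR content
is the volume-weighted (NSR+JSR)/V_myo free Ca²⁺ at end of beat.
Unrepolarised or absent APs raise typed errors rather than returning numbers.

## Tissue scale

**Monodomain with deformation.** C_m dV/dt = −(I_ion+I_stim) + ∇·(D C⁻¹ ∇V),
with D built per node from the fibre direction and the longitudinal/
transverse conductivities 1.26 / 0.42 mm²/ms (3:1 ratio) and C the right
Cauchy–Green tensor of the tissue deformation (identity when undeformed).
The effective tensor D C⁻¹ is validated symmetric positive-definite.
Space: conservative finite-difference face fluxes on regular lattices
(dx = 0.25 mm default), no-flux boundaries, face-averaged cross differences
for rotated fibre fields. Time: Strang splitting — half reaction, full
Crank–Nicolson diffusion, half reaction — second-order in Δt; the long-run
driver fuses adjacent half reactions of consecutive steps (verified
equivalent within tolerance). Measured longitudinal conduction velocity is
1.77 mm/ms at dx = 0.25 with √3 ± 3% anisotropy, √2 scaling under
conductivity doubling, <1% change on a half-spaced grid, and CV×(1/λ)
rescaling under a prescribed fibre stretch C = diag(λ², 1), the analytically
expected behaviours.

**Electro-mechanical loop.** Every Δt_mech = 1 ms the electrophysiology
exports γ and receives C. The desk-scale mechanics surrogate is kinematic
fibre shortening, F = (1+γ) f⊗f + (1+γ)^(-1/2) (I − f⊗f) (volume-preserving),
optionally routed through a coarser mechanics lattice by linear grid-to-grid
projection; organ-scale finite-element elasticity is out of scope and the
continuum kernels are written as pure functions so an FEM layer can be added.
Contraction (γ<0) raises material-frame conduction speed through C⁻¹, the
direction the rescaling law dictates.

**Re-entry (AFER-AF analogue).** Functional re-entry is induced by a
cross-field S1–S2: planar S1 from the left edge, premature S2 over the lower
half-sheet so the S2 boundary crosses the S1 refractory band and the blocked
segment leaves a free wavefront end that curls into recovering tissue. Two
desk-scale accommodations, both documented as the package's own choices: the
sheet uses isotropic reduced coupling D = 0.063 mm²/ms (gap-junction
down-regulation accompanies AF structurally; isotropy keeps both lattice
directions above the discrete propagation threshold at dx = 0.5 mm), and the
S1 train is delivered at a 300 ms interval so rate adaptation shortens the
wavelength the 40 mm sheet must accommodate. Within a scanned S2 window
(~130–150 ms after the last S1) the AF-remodeled sheet sustains re-entry for
the full observation horizon (>1 s, cycle length ~160–190 ms); a late S2
(290 ms) produces a single ectopic beat; the control sheet shows no sustained
window at the same delays. Tissue runs at these scales use Δt = 0.02 ms (an
explicit, capped override of the 0.01 ms default; the dt-sensitivity tests
cover the accuracy cost).

## Continuum kernels

F = F_e F₀ with active part F₀ = I + γ f⊗f (det F₀ = 1+γ; γ ≤ −1 rejected);
elastic strain E_e = (F_eᵀF_e − I)/2. Passive energy W = C₁ exp(Q),
Q = C₂E₁₁² + C₃(E₂₂²+E₃₃²+E₂₃²) + 2C₄(E₁₂E₂₁+E₁₃E₃₁) in an orthonormal frame
with axis 1 = fibre (transverse axes chosen deterministically: the
least-aligned coordinate axis projected orthogonal to f); defaults
C₁ = 0.831 kPa, C₂ = 14.31, C₃ = 4.49, C₄ = 10. The second Piola–Kirchhoff
stress is the symmetric-tensor gradient ∂W/∂E_e − p C_e⁻¹ and is verified
against central finite differences of the energy to 1e−6 relative. The
homogeneous traction-free contraction problem is reduced by exact
incompressibility (λ_t = λ_f^(−1/2), the pressure eliminated algebraically)
to bounded scalar minimisation, cross-checked against dense grid search.
Cavity volume uses the divergence theorem on closed, consistently
outward-oriented triangulations, V = Σ det[a b c]/6, with orientation and
closedness validated edge-by-edge and the reference volume required positive;
icosphere refinement converges at second order.

## Synthetic fixtures

Cables (with regional segment maps), uniform or jitter-perturbed fibre
sheets, and icospheres are generated in code; the only stochastic element
(fibre jitter) requires an explicit seeded generator and records its seed.
These fixtures emulate idealised, homogeneous-by-construction tissue: they
carry none of the anatomical fibre disarray, wall-thickness variation or
boundary geometry of real atria, so tissue-level tests demonstrate solver
correctness and qualitative electromechanical mechanisms, not anatomical
prediction.

## Known limitations and honest discrepancies

* **AF action-potential duration.** With every published AF factor applied
  exactly to the base CRN equations, the baseline RA APD₉₀ at 1 Hz steady
  state is ~137 ms, not the reported 188 ms (~−31%); factor ablation shows
  the I_K1 doubling alone shortens pure-CRN APD₉₀ by ~100 ms. The reported
  AF value evidently depends on unprinted kinetic modifications of the
  source model lineage. Consequently the AF-side APD targets (baseline AF
  APD₉₀, the AF APD of regional variants, the abbreviation percentage) and
  the biomarkers that inherit the shortened AF plateau (diastolic-Ca and SR
  reductions, force reduction: measured −22.8%, −39.1%, −64.7% vs reported
  ~−50%, ~−50%, −82%) sit outside their reproduction bands, while the
  control-side values (274/283.6 ms, PV 181/181.2 ms, BBRA 325/310.7 ms) and
  the systolic-Ca and PV-force reductions reproduce within band. The
  directionality of every AF effect matches the reported findings.
* The printed coupled Ca-balance carries a 0.5·J_rel factor; implemented
  with the base model's full-release partition because the halved variant
  drains the SR, collapses the control force to ~0 (contradicting the
  reported control behaviour) and breaks Ca conservation. Both partition
  factors remain configurable in the kernel for sensitivity work.
* Single-cell rate dependence beyond 1 Hz, stretch-activated channels,
  temperature dependence away from 37 °C, and organ-scale FEM mechanics with
  endocardial pressure loading are out of scope.
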