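# Methods

## Model structure

The simulated unit is one gram of small-intestinal mucosa, reduced to
four compartments:

* **Lumen** — an infinite reservoir of fixed composition (`C_lum_glc`,
  `C_lum_Na`). All scenarios hold the luminal fluid constant, which
  matches perfused-segment experiments and removes luminal depletion
  from the problem.
* **Enterocyte cytosol** — solute amounts (µmol) and water volume (ml);
  concentrations are derived as amount/volume so that mass is conserved
  exactly while the cell swells or shrinks.
* **Interstitium** — same representation, plus a nonlinear
  pressure–volume relation `P_in = k·(exp((V−V₀)/V₀) − 1)` (clipped
  below at `pressure_floor`). Any strictly increasing convex law with
  P(V₀)=0 would serve; the exponential is the simplest with those
  properties.
* **Capillary** — a well-mixed compartment of fixed volume `V_cap`,
  flushed by perfusion `Q_cap·cap_flow` entering at arterial
  composition and leaving at the mean capillary composition. The single
  dial `Q_cap` multiplies both perfusion and the endothelial
  permeabilities, realizing "capillary clearance" as one knob.

Fluxes are positive in the absorptive direction (lumen→cell,
cell→interstitium, lumen→interstitium, interstitium→capillary). A
negative apical GLUT2 flux is glucose backflux into the lumen.

## Flux laws and their assumptions

* **GLUT2** (apical, titratable; basolateral, constitutive) and the
  **basolateral Na carrier** are symmetric two-site carriers,
  `J = Vmax·(g_o/(1+g_o) − g_i/(1+g_i))` with `g = C/Km` —
  antisymmetric, bounded by ±Vmax, zero only at equal concentrations.
  Km(GLUT2) = 17 mM, Km(Na) = 25 mM.
* **SGLT1** is modelled as an irreversible product of Michaelis terms
  in luminal glucose (Km 17.9 mM, the electrogenic value) and luminal
  Na (Km 30 mM), with strict 2 Na : 1 glucose coupling. Irreversibility
  reflects the export site's very low glucose affinity; saturation and
  polarization are the only SGLT1 properties the analysis depends on,
  so a full multi-state carrier cycle is deliberately not modelled.
* **Na pump**: `J = Vmax·Na_cyt/(Na_cyt+Km)`. The pump and the
  basolateral Na carrier act in parallel as independent cytosol exits.
* **Solute across water-swept barriers** (tight junction, capillary
  wall): the convective-diffusion law `J = J_w·(C_o+C_i)/2 + P·ΔC`.
  The same law serves both barriers; for the junction, `P` is the
  paracellular permeability (cm/s) times `pc_area_factor`.
* **Water**: osmotic flow `Lp·(RT·Δ(σ-weighted osmolarity) − ΔP)` with
  NaCl counted as two particles, glucose as one and
  RT = `osmotic_factor` = 19.3 mm Hg/mM (37 °C). Carrier glucose flux
  additionally drags `n_w_per_glc` = 210 water molecules per glucose
  across the apical and basolateral membranes. Water crosses the
  capillary wall driven by interstitial pressure alone: the fenestrated
  villus endothelium reflects small crystalloids hardly at all (σ≈0
  there), and the plasma oncotic offset is folded into the zero point
  of the compliance law. A small `lymph_coeff·max(P_in,0)` term stands
  in for lymphatic drainage.
* **Cytosolic impermeant osmolyte** `n_imp_cyt` (K⁺ salts, proteins,
  metabolites; σ = 1): without it the cell's water balance would be
  independent of cell volume and the steady-state volume indeterminate.
  Its value sets the resting volume near `V_cyt_ref` = 0.55 ml.

Electroneutrality is assumed; chloride follows Na implicitly (the
factor 2) and membrane potential is not modelled. GLUT5/fructose,
incretin signalling and carrier trafficking dynamics are out of scope.

## Units and the reference parameter set

Concentrations are mM, volumes ml/g tissue, time hours, pressure mm Hg.
Carrier Vmax values in configurations are in *model flux units* — the
published convention in which rates are normalized to the baseline
SGLT1 uptake (≈1 at 50 mM luminal glucose) and the apical GLUT2
titration runs from 0 to 2. Internally one model flux unit is
`flux_scale` = 60 µmol h⁻¹ g⁻¹; this absolute scale is what makes
0.5–0.6 ml pools turn over on the sub-hour timescales the inhibitor
experiments show, and it is broadly the magnitude of jejunal glucose
uptake per gram.

Constants with published values (Km's, boundary concentrations, the
0–2 GLUT2 range, the 0–0.02 cm/s paracellular range, clearance factors
1 and 10) are fixed at those values. The remaining magnitudes
(`Vmax_glut2_bl`, `Vmax_pump`, `Vmax_Na_bl`, `pc_area_factor`,
`P_cap_*`, `cap_flow`, `Lp_*`, compliance constants, `n_imp_cyt`,
`flux_scale`) are not published; they were chosen once, by analysis of
the steady-state balances, to satisfy two registration behaviours
simultaneously, and then frozen (`config/reference.yaml`, identical to
the dataclass defaults):

1. with `P_glc_pc` = 0.015 cm/s under high clearance, the luminal
   concentration at which paracellular glucose flux equals SGLT1 flux
   lies between 20 and 30 mM (the frozen set gives 22.1 mM);
2. under low apical GLUT2 (Vmax 0.5) and low clearance (Q_cap 1) with
   50 mM luminal glucose, steady-state cytosolic glucose exceeds the
   luminal concentration (the frozen set gives 80.5 mM), so the
   apical/basolateral pair acts as the double-membrane rectifier.

The reference configuration itself is the high-clearance condition
(`Q_cap` = 10, `Vmax_glut2_ap` = 2, 50 mM luminal glucose) used by the
titration and inhibitor scenarios; the factorial scenario overrides it
to its own low base. The crossover is only finite under high clearance
— at Q_cap = 1 the interstitium accumulates above the lumen and the
paracellular route is secretory at every luminal concentration.

## Inhibitor semantics

`ScaleSet` holds multiplicative factors in [0,1]. `sglt1_scale` and
`glut2_ap_scale` scale the respective Vmax. `pc_scale` scales the
**whole** paracellular solute flux — diffusion and solvent drag
together, since a junction whose glucose permeability is blocked passes
no glucose by either mechanism; this is also what makes the
total-blockade equilibration exact. The paracellular *water* path is
scaled separately (`pc_water_scale`); by default phloretin mode B
leaves it open (the blocked quantities are named as solute
permeabilities), and the `phloretin_blocks_water` flag closes it too.
Scenario events: phloridzin at 0.5 h (SGLT1 → 0), phloretin at 1.0 h
(apical GLUT2 → 0 in mode A; also the paracellular solute path in
mode B). Every time course starts from the steady state of its
pre-event configuration.

## Numerics

* **Integration**: LSODA, rtol 1e-8 / atol 1e-10, reporting grid
  0.005 h. Integration restarts exactly at each schedule event, so
  discontinuous scale changes never straddle a step; states are
  continuous across events, fluxes are not. Six auxiliary states
  accumulate the boundary fluxes so mass-balance residuals can be
  audited per run (they close to ~1e-15 relative; the suite asserts
  1e-6).
* **Guards**: a terminal event aborts any trajectory whose compartment
  volume reaches zero (`IntegrationError`, carrying the last valid
  state) — a hard error, not a clip. Within a step the right-hand side
  tolerates hair-below-zero probes by flooring amounts at 0.
* **Steady states**: damped root finding (scipy `hybr`) in log state
  space, so positivity is structural. Residuals are scaled by *fixed*
  characteristic pool sizes, not the current state — a relative
  |dy/y| measure would vanish spuriously on degenerate branches where a
  pool grows without bound. Accepted only if the scaled derivative norm
  is < 1e-8; otherwise the state is relaxed by integration (chunks up
  to 500 h) and re-polished. Agreement between the root and the
  integrate-to-convergence oracle is enforced at 0.1% on the reference
  configuration and 20 random ±50% parameter perturbations.
* **Crossover search**: coarse 5 mM scan of steady-state
  `J_pc_glc − J_sglt1` over (0.5, 200] mM, then bracketed root
  refinement to 0.05 mM. No sign change ⇒ no crossover (reported as
  `None`, e.g. at zero paracellular permeability).
* **Degenerate inputs**: negative concentrations, non-positive Km or
  volumes, unknown config keys, non-increasing event times and
  out-of-range scale factors are all hard validation errors naming the
  offending field.

## What the scenarios do and do not show

The scenario boundary values (50 or 30 mM luminal glucose in 150 mM
NaCl, 5 mM arterial glucose, clearance ×1/×10, GLUT2 0–2, paracellular
permeability 0–0.02 cm/s, events at 0.5/1.0 h) are the published
experimental conditions and are the package defaults, not tuning
dials. Directions, orderings and the registration crossover are the
reproducible content; absolute flux magnitudes depend on the
unpublished remainder of the original parameterization and are
explicitly not reproduced. The model also averages the whole villus
into one unit: axial redistribution along the intestine, villus
countercurrent gradients, membrane potential and regulatory trafficking
of GLUT2 are outside its scope, so quantitative agreement with tissue
experiments should not be inferred from the passing suite — the suite
establishes internal consistency (conservation, carrier laws, solver
cross-validation) and the qualitative flux-balance behaviours.

The transluminal-insensitivity check (net uptake nearly unchanged by
apical GLUT2) is asserted for luminal glucose ≥ 10 mM: below the
arterial level net flux passes through zero and a relative comparison
is not meaningful.

## Problem sizes

Default sweeps use 0–100 mM luminal glucose in 5 mM steps and nine
paracellular permeabilities in [0, 0.02] cm/s; time courses run 2 h at
0.005 h reporting resolution. The whole test suite and the acceptance
script each run in well under a minute on one CPU.
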