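# Methods

`cardioem` is a multiscale model of human left-ventricular
electromechanics in heart failure with preserved ejection fraction
(HFpEF).  This note documents the model chain, the choices made where
the design was genuinely open, and what the package's synthetic
protocols do and do not establish about real myocardium.

## Coupled electromechanical cell

**Electrophysiology.**  The cellular substrate is the published human
ventricular action-potential model with endo-, mid- and epicardial
conductance variants (fast and late Na⁺ currents, transient outward and
the three K⁺ rectifier currents, L-type Ca²⁺ current with
Ca²⁺/voltage-dependent inactivation and CaMKII-modulated rate
dependence, Na⁺/Ca²⁺ exchange split into myoplasmic and subspace
components, Na⁺/K⁺-ATPase, background and pump currents, and the
four-compartment Ca²⁺ cycling system with SERCA uptake, RyR release and
a network-SR leak).  Equations and constants are transcribed verbatim
from the published source formulation in `tables.py` (voltage-dependent
rates) and `_kernels.py` (fluxes, pumps, balances).

**Myofilament.**  Contraction comes from the approximate
crossbridge-cycling model: regulatory units with low/high-affinity
troponin sites and strongly cooperative permissiveness (n = 15),
a four-state crossbridge cycle (non-permissive, permissive,
pre-rotation, post-rotation) with mean-distortion dynamics,
filament-overlap geometry, exponential titin and collagen passive
elements, and unloaded sarcomere-length dynamics against a preload.
Metabolite sensitivity (MgATP, MgADP, Pi, pH) is carried as
multiplicative rate modifiers that are ≈1 at the normal defaults
(MgATP 5 mM, MgADP 36 µM, Pi 2 mM, pH 7.15); no protocol here departs
from those levels.  The crossbridge rate constants are scaled by the
species factor 0.2 (the model's slower-species value): the rat-scale
kinetics give 70 ms time-to-peak unloaded twitches, whereas human
myocardium at 37 °C relaxes over several hundred milliseconds.  The
scaling leaves every steady-state force identical and only slows the
kinetics.

**Coupling.**  The cytosolic Ca²⁺ balance is

&nbsp;&nbsp;d[Ca²⁺]ᵢ/dt = β_Cai · ( −(I_pCa + I_Cab − 2 I_NaCa,i)·A_cap/(2 F v_myo)
− J_up·v_nsr/v_myo + J_diff,Ca·v_ss/v_myo − J_Trop/1000 )

where β_Cai contains **only** the calmodulin buffer and J_Trop (µM/ms)
is the net troponin-binding flux computed by the myofilament model
(including the overlap- and crossbridge-weighted redistribution terms).
The EP model's intrinsic troponin buffer is removed from this equation
— the central coupling decision; keeping it would double-count troponin
and damp the Ca²⁺ transient.  Subspace and SR buffers are untouched.
One consequence worth knowing: the dynamic troponin kinetics buffer
less strongly than the original instantaneous buffer, so free Ca²⁺
transients are somewhat larger and APDs a few ms shorter than in the
uncoupled EP model.

**Integration.**  Fixed-step integration with the exponential
(Rush–Larsen) update for all 28 voltage-gated variables (steady states,
time constants and the per-step exponential factors are tabulated on a
0.02 mV grid and linearly interpolated), exact exponential updates for
the three linear-in-state variables whose time constants can collapse
(the two SR-release ramps and the ICaL mode fraction), and forward
Euler for potentials, concentrations and myofilament states.  Default
dt = 0.01 ms (tests use 0.02 ms, the stability edge; APD changes by
< 0.2 ms between the two).  A symmetrised second-order variant
(exponential gate half-steps around an explicit-midpoint core) is used
where a second-order reaction flow is required, and an adaptive stiff
reference (LSODA on the same right-hand side) serves as the
cross-validation oracle: peak-Ca²⁺ errors of the first-order scheme are
3.5/1.7/0.85 % at dt = 0.02/0.01/0.005 ms.

**Stimulus convention**: −80 µA/µF for 0.5 ms at beat start, carried on
the K⁺ balance.  **APD₉₀**: from the instant of maximum upstroke
velocity to 90 % repolarisation between the beat maximum and the
pre-stimulus diastolic potential, linearly interpolated at the
crossing.  **Steady pacing**: up to 1000 beats with early exit once
beat-to-beat APD₉₀ changes < 0.1 ms and diastolic Ca²⁺ < 0.5 % for
three consecutive beats (with a configurable floor, default 200 beats;
the heavy tests use 400).

## Heart-failure remodeling

CONTROL, HFPEF and HFREF are multiplicative factor maps over the
baseline cell.  Common failing-heart factors: I_NaL ×1.8, τ_hL ×1.8,
I_to ×0.4, I_K1 ×0.68, I_NaK ×0.7, CaMKa ×1.5 (applied wherever active
CaMKII enters flux/gate modulation), non-phosphorylated RyR release
target ×0.8, SR leak ×2.3.  The variants differ ionically **only** in
NCX (HFpEF ×0.70, HFrEF ×1.75) plus the passive myofilament rows
(HFpEF: titin ×2.0, collagen amplitude ×2.0 with exponent ×0.5; HFrEF:
titin ×1.0, collagen ×2.36 / ×0.42).  HFpEF tissue additionally scales
all conductivities by 0.8 (interstitial fibrosis).

Two rows of the remodeling table admit two readings and are exposed as
overrides:

* **SR leak "130 %"** — interpreted as a +130 % *change* (×2.3).  Under
  the alternative ×1.3 reading the HFpEF cell ends with a *higher* SR
  content, *higher* peak Ca²⁺/tension and only ~+45 % leak,
  contradicting the phenotype this variant is defined by (SR deficit,
  reduced systolic release, leak ≈ double control, diastolic Ca²⁺
  ≈ +75 %).  The ×2.3 reading reproduces all four at once and is the
  default; pass `{"I_leak": 1.3}` to explore the other.
* **I_Nab "100 %"** — no-op (×1.0) by default; part of the HF
  literature doubles the background Na⁺ conductance instead.  The
  difference is small either way (the current is tiny).

## Protocols

* **Post-rest contraction (PRC)**: condition 600 beats (10 min at
  1 Hz; reducible for tests, flagged in the result), rest 1/2/3/5/10 s,
  one stimulus.  Diastolic quantities (Ca²⁺ level, SR content, resting
  tension) are read at the end of the rest, immediately before the
  post-rest stimulus — the protocol probes what the SR retains during
  rest; systolic quantities and the per-beat leak integral come from
  the post-rest beat.  *Resting tension* is the residual active
  (crossbridge) force: in an unloaded cell the total force is pinned at
  the titin preload and carries no information.  At 2 Hz the protocol
  conditions at the test rate by default (configurable).
* **SR-leak biomarker**: the time integral of the NSR→myoplasm leak
  flux over one cycle (mM per beat).
* **SR-content biomarker**: volume-weighted mean of the network and
  junctional SR concentrations.
* **NCX sweep**: steady 1 Hz runs on the HFpEF background with NCX at
  0.70/1.00/1.50/1.75 of control; all other HFpEF factors fixed.
* **F–pCa**: clamped-Ca²⁺ isometric relaxation to a stationary force
  (relative change < 10⁻⁶/ms) per pCa point at SL 2.2 µm.

## Tissue electrophysiology

Monodomain reaction–diffusion with the anisotropic tensor
D = σ_f f⊗f + σ_s s⊗s + σ_n n⊗n and the printed weights
(3.0, 0.1, 0.31525; note σ_n > σ_s as printed).  The printed
conductivity units are dimensionally inconsistent for the monodomain
equation, so the weights are treated as relative anisotropy ratios and
one calibration constant (0.100 mm²/ms per unit weight) maps them to an
effective diffusivity such that a control strand conducts at the target
65 cm/s — the conduction velocity, not the raw constants, is treated as
authoritative.  Time stepping is Strang-split (half-step reaction,
Crank–Nicolson diffusion on P1 tetrahedra with lumped mass, half-step
reaction); with the symmetrised cell step the observed convergence
order on a 1D pulse is 2.0.  Conduction velocity is measured from a
linear fit of activation time (maximum dV/dt) vs position over the
central half of a ≥20 mm strand; dx ≤ 0.125 mm keeps the velocity
grid-independent to < 3 % (at dx = 0.25 mm the sharp upstroke is
under-resolved and conduction slows by ~6 %).

Transmural cell types tile the normalised wall depth 60 % ENDO /
30 % MCELL / 10 % EPI from the endocardium.  The paper's
patient-derived activation sites are unavailable; the default stimulus
is three endocardial patches (apical-septal, mid free-wall, basal) of
14 mm radius, sized so the coarse LV activates completely in ≈185 ms,
matching the study's ~200 ms full-activation milestone.  Both are
configurable.

## Left-ventricular mechanics

Truncated-ellipsoid meshes (endocardial equatorial radius 24 mm, long
half-axis 68 mm, truncated half-way up, cavity ≈133 mL) with the wall
offset outward by 9/12/15/18 mm — the cavity is identical at
end-diastole across the hypertrophy presets, so EF differences isolate
the wall-thickness effect.  Structured hexahedral grids are subdivided
into tetrahedra with the Kuhn scheme (face-diagonal compatible across
neighbours and the circumferential wrap; degenerate apex tetrahedra
dropped).  Fibers follow a linear transmural helix rule, +60° (endo) to
−60° (epi), about the local circumferential direction; the sheet
direction is transmural.

The active-strain decomposition F = F_e F₀ uses
F₀ = I + γ_f f⊗f + γ_s s⊗s + γ_n n⊗n with γ_n = K γ_f (K = 4) and
γ_s = 1/((1+γ_f)(1+γ_n)) − 1, so det F₀ = 1 identically.  γ_f =
(SL − SL₀)/SL₀ comes from the unloaded single-cell sarcomere trace
(SL₀ = 1.9 µm, the preload length).  The elastic response is the mixed
compressible neo-Hookean energy W = μ/2 (I:C_e − 3) − μ ln J_e +
p ln J_e − p²/(2λ) with μ = 2 kPa, λ/μ = 10³ (for a traction-free
active contraction only λ/μ matters; the printed model is isotropic —
anisotropy enters through F₀ only, as printed).  Equilibria are
solved with damped Newton on P2 displacements / P1 pressures
(degree-3 quadrature, analytic residuals, forward-difference consistent
tangents, incremental γ loading on failure) to a relative residual of
10⁻⁸.  Boundary conditions: basal plane fixed longitudinally, two
in-plane pins against the remaining rigid modes, zero traction
elsewhere; no cavity pressure is applied (the study itself used no
fluid coupling).

**Staggered loop**: every Δt_mech (default 10 ms here; the study used
1 ms at production resolution) the per-vertex γ_f is evaluated from the
local cell type's twitch table shifted by the node's activation time,
projected to the mechanics mesh, and an equilibrium is solved
(warm-started).  The activation map defaults to the calibrated
anisotropic shortest-path (eikonal-style) solution on the mesh edge
graph — on coarse meshes a full monodomain solve overestimates
conduction badly, and the map is within a few ms of the fine-mesh
monodomain answer; `ep_mode="monodomain"` runs the PDE instead.  There
is no stretch feedback from tissue to cell (the study's own stated
simplification).  EF = (EDV − ESV)/EDV from the divergence-theorem
cavity volume (endocardial surface closed by a basal-plane cap).
Stress maps report the von Mises norm of the Cauchy stress, strain maps
the Frobenius norm of the elastic Green–Lagrange tensor, at element
centroids.

## Problem sizes and known limitations

* Heavy protocols in the test suite run at dt = 0.02 ms with 300–400
  conditioning beats and coarse LV meshes (12×6×2 structured cells,
  ≈820 tetrahedra, Δt_mech = 10 ms); the acceptance script uses
  dt = 0.01 ms and the full 600-beat conditioning.  These sizes
  reproduce the cellular biomarkers to well within their tolerances;
  organ-level EF on such meshes is a scaled-down setting.
* The coupled cell reproduces the published baseline EP model's steady
  state closely (resting potential −87.9 mV, ENDO diastolic Ca²⁺
  78 nM, SR 1.6 mM, APD₉₀ 226/323/260 ms for EPI/MCELL/ENDO at 1 Hz).
  The study's printed APDs are systematically longer (233/357/274
  control); that offset originates upstream of the remodeling factors
  and is not reproducible from the published equations, so
  HFpEF-vs-control *differences* and orderings are the meaningful
  cellular outputs here, and the absolute-APD and EF acceptance checks
  are reported at face value.
* At 2 Hz the control cell's positive Ca²⁺ staircase loads its SR
  faster than the HFpEF cell leaks its own, so the relative SR-content
  deficit *shrinks* with rate in this implementation even though the
  diastolic-Ca²⁺ and resting-tension abnormalities grow.
* The single-beat γ drive holds its end-diastolic value after one cycle
  length; runs longer than one cycle therefore show the residual
  (incomplete-relaxation) state rather than repeated beats.
* All algorithms are deterministic — there is no random number anywhere
  — so identical configurations reproduce outputs byte for byte.
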