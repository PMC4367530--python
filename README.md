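# cardioem

Multiscale electromechanics of the human left ventricle in **heart
failure with preserved ejection fraction (HFpEF)** — from a coupled
ventricular cell (electrophysiology + crossbridge-cycling myofilament)
through heart-failure ion-channel remodeling and monodomain tissue
conduction to an active-strain finite-element ventricle with variable
concentric hypertrophy.

HFpEF accounts for roughly half of heart failure: the ventricle ejects
a normal fraction yet relaxes incompletely and stiffens.  `cardioem`
lets you ask *why* at each scale: at the cell, remodeled Ca²⁺ handling
(doubled SR leak, 30 % less Na⁺/Ca²⁺ exchange, reduced Na⁺/K⁺ pump …)
elevates diastolic [Ca²⁺]ᵢ and leaves a residual crossbridge force; at
the organ, a concentrically thickened wall converts the weakened
cellular shortening into a preserved — even supranormal — ejection
fraction.

The package is a library first: import it, build a variant, run a
protocol.  `examples/` holds one short script per capability, and a
thin `cardioem` CLI wraps the same functions for shell use.

## The model in brief

* **Cell.**  A human ventricular action-potential model (ENDO / MCELL /
  EPI variants) coupled to a cooperative crossbridge myofilament model
  through the cytosolic calcium balance
  `d[Ca²⁺]ᵢ/dt = β_Cai(−(I_pCa+I_Cab−2I_NaCa,i)·A_cap/(2Fv_myo) −
  J_up·v_nsr/v_myo + J_diff,Ca·v_ss/v_myo − J_Trop/1000)`,
  where `J_Trop` is the troponin-binding flux computed by the
  myofilament model and `β_Cai` keeps only the calmodulin buffer.
* **Remodeling.**  CONTROL / HFPEF / HFREF as multiplicative factor
  maps (I_NaL ×1.8, I_to ×0.4, I_K1 ×0.68, I_NaK ×0.7, SR leak ×2.3, …);
  the two failing variants differ ionically *only* in NCX (0.70 vs
  1.75) plus the titin/collagen passive rows.
* **Tissue.**  Monodomain propagation with
  `D = σ_f f⊗f + σ_s s⊗s + σ_n n⊗n`, calibrated to 65 cm/s fiber-
  direction conduction; Strang splitting (2nd order), 60/30/10
  transmural cell-type layering, 20 % conductivity loss in HFpEF.
* **Ventricle.**  Truncated-ellipsoid meshes at 9/12/15/18 mm wall
  thickness (fixed cavity), rule-based ±60° fiber helix, active-strain
  decomposition `F = F_e F₀`, `F₀ = I + γ_f f⊗f + γ_s s⊗s + γ_n n⊗n`
  with `γ_f = (SL−SL₀)/SL₀`, `γ_n = 4 γ_f`, det F₀ ≡ 1; mixed P2–P1
  neo-Hookean Newton solves; `EF = (EDV−ESV)/EDV` from the cavity
  volume.

See `docs/methods.md` for assumptions, parameter choices, numerical
schemes and limitations.

## Worked example

```python
from cardioem import pace, biomarkers_from_trace

for variant in ("CONTROL", "HFPEF"):
    tr = pace(variant, "EPI", cl=1000.0, dt=0.02, min_beats=400)
    b = biomarkers_from_trace(tr)
    print(variant, f"APD90={b.apd90:.1f} ms",
          f"dia Ca={1e6*b.dia_cai:.0f} nM",
          f"SR leak={b.sr_leak:.2f} mM/beat",
          f"resting force={b.resting_tension:.2e}")
```

prints (epicardial cell, 1 Hz steady state):

```
CONTROL APD90=225.7 ms dia Ca=70 nM SR leak=0.54 mM/beat resting force=1.21e-07
HFPEF APD90=229.4 ms dia Ca=134 nM SR leak=1.12 mM/beat resting force=7.17e-06
```

— the HFpEF cell roughly doubles its diastolic Ca²⁺ and SR leak and
keeps a residual diastolic crossbridge force ~60× control: incomplete
relaxation at the cellular level.  `examples/post_rest_contraction.py`
shows the corresponding post-rest protocol (diastolic Ca²⁺ ≈ +75–90 %
vs control at every rest interval), and
`examples/lv_ejection_fraction.py` the organ-level ejection fraction
rising with wall thickness.

## Command line

```bash
cardioem pace --variant HFPEF --cell EPI --cl 1000 --out out/
cardioem prc --variant HFPEF --rate 1
cardioem cv --dx 0.1
cardioem lv-em --preset SEVERE
cardioem fixtures lv-coarse --out fixtures/
```

Each run echoes its full configuration (`config.yaml`) next to its
outputs; all algorithms are deterministic, so a config reproduces its
outputs byte for byte.

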