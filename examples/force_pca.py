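"""Steady-state force-pCa relation at SL = 2.2 um, control vs HFpEF.

Each point clamps cytosolic Ca2+ and integrates the isometric
myofilament model to steady state.  The HFpEF curve sits above control
at every pCa because the titin passive element is doubled; the active
component is sigmoidal with a Hill coefficient > 1.
"""

from cardioem import MmParams, steady_fpca, build_variant

grid = [4.0, 4.5, 5.0, 5.25, 5.5, 5.75, 6.0, 6.5, 7.0]
ctrl = steady_fpca(grid, 2.2, MmParams())
hf = steady_fpca(grid, 2.2, build_variant("HFPEF")[1])

norm = max(p.total for p in ctrl)   # relative force, control max = 1
print(" pCa   control total  control passive    HFpEF total   HFpEF passive")
for pc, ph in zip(ctrl, hf):
    print(f"{pc.pca:4.2f} {pc.total / norm:14.4f} {pc.passive / norm:16.4f}"
          f" {ph.total / norm:14.4f} {ph.passive / norm:15.4f}")
print("\n(forces normalised to the control maximum)")
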