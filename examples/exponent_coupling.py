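"""Tumor-deformed signalling exponents (model 3).

Here the tumor does not touch the rate constants; it bends the
autocrine/paracrine exponents themselves via modifiers r_ij scaled by
D/sigma.  With the cross-paracrine terms switched off (g12 = g21 = 0) the
populations decouple and weak autocrine feedback (g11 = 0.005,
g22 = 0.20) yields an overdamped unit; the script prints the fixed point
for a few modifier choices, confirms each is an exact root of the
deformed equations, and reports the spectrum class.
"""

from osteodyn import (ModelSpec, RemodelingParams, TumorParams, Variant,
                      model3_steady_state, residual, stability_report)

params = RemodelingParams(g11=0.005, g22=0.20, g12=0.0, g21=0.0)
tumor = TumorParams(sigma=0.05)

for r in [(0.0, 0.0, 0.0, 0.0), (0.1, 0.2, 0.0, 0.05),
          (-0.2, 0.3, 0.0, -0.1)]:
    spec = ModelSpec(Variant.MODEL3, r11=r[0], r12=r[1], r21=r[2], r22=r[3])
    ss = model3_steady_state(params, tumor.sigma, *r)
    rep = stability_report(spec, params, tumor)
    print(f"r_ij={r}: fixed point ({ss.x1bar:.4f}, {ss.x2bar:.4f}), "
          f"residual {residual(spec, params, tumor, ss):.1e}, "
          f"class {rep.eig_class.value}")
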