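"""Closed-form steady states of the tumor-coupled remodeling variants.

Builds the canonical parameter set, evaluates the nontrivial fixed point
(x1bar osteoclasts, x2bar osteoblasts) of each model-1 scenario and two
model-2 couplings, and prints them.  The numbers quantify how each tumor
coupling shifts the cell balance of the remodeling unit away from the
tumor-free fixed point printed first.
"""

from osteodyn import (base_steady_state, default_params,
                      model1_steady_state, model2_steady_state)

params, _ = default_params()
base = base_steady_state(params)
print(f"tumor-free fixed point: x1bar={base.x1bar:.4f}  "
      f"x2bar={base.x2bar:.4f}")

print("\nmodel 1 (rate modulation), sigma = 0.05 and 0.40:")
for scenario in range(9):
    cells = [model1_steady_state(params, s, scenario) for s in (0.05, 0.40)]
    print(f"  scenario {scenario}: "
          + "   ".join(f"sigma={s}: ({ss.x1bar:9.4f}, {ss.x2bar:10.4f})"
                       for s, ss in zip((0.05, 0.40), cells)))

print("\nmodel 2 (tumor power-law factor), sigma = 0.05:")
for g31, g32 in [(-0.10, 0.0), (-0.05, 0.0), (-0.10, -0.01)]:
    ss = model2_steady_state(params, 0.05, g31, g32)
    print(f"  g31={g31:+.2f} g32={g32:+.2f}: "
          f"({ss.x1bar:.4f}, {ss.x2bar:.4f})   [{ss.source}]")
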