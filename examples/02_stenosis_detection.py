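"""Detect stenotic lesions on a centerline area profile.

A robust line fit estimates the healthy reference lumen; lesions are
connected regions of the severity profile 1 - A/A_ref above 0.25 that reach
at least 0.4 somewhere. The report carries the morphology (A_s, L_s, A, D)
that parameterizes the lumped pressure-drop element.
"""

import coro1d as c1

tree = c1.resample_tree(c1.make_synthetic(c1.SyntheticSpec(
    kind="stenotic_tube", base_area=0.1, length=5.0,
    severity=0.6, extent=1.0)), spacing=0.05)

branch = tree.branches["b0"]
ref = c1.reference_area(branch)
lesions = c1.detect_stenoses(branch, ref)

print(c1.lesion_report(lesions).to_string(index=False))
print()
l = lesions[0]
print(f"constructed minimum area: {0.1 * (1 - 0.6):.4f} cm^2, "
      f"detected A_s = {l.A_s:.4f} cm^2")
print(f"area stenosis degree A_s/A = {l.severity:.2f} "
      f"(0.40 means a 60% area reduction)")
print(f"viscous coefficient Kv0 = {c1.kv_reference(l.A_s, l.L_s, l.A):.1f}")
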