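"""Build synthetic coronary centerline trees and write them to disk.

The generator covers the three shapes used throughout the package: a
constant-area tube, a tube with a smooth (cosine) stenosis, and a symmetric
binary tree whose daughter areas follow a cube-law radius split.
"""

from pathlib import Path

import coro1d as c1

out = Path("scratch/examples")
out.mkdir(parents=True, exist_ok=True)

tube = c1.make_synthetic(c1.SyntheticSpec(kind="straight_tube",
                                          base_area=0.1, length=5.0))
sten = c1.make_synthetic(c1.SyntheticSpec(kind="stenotic_tube", base_area=0.1,
                                          length=5.0, severity=0.6, extent=1.0))
tree = c1.make_synthetic(c1.SyntheticSpec(kind="bifurcation_tree", depth=2,
                                          base_area=0.1, length=3.0))

for name, t in [("tube", tube), ("stenotic", sten), ("tree", tree)]:
    c1.write_centerline_tree(t, out / f"{name}.json")
    print(f"{name:9s} branches={len(t.branches)} junctions={len(t.junctions)} "
          f"outlets={len(t.outlet_branch_ids)} "
          f"min_area={min(b.area.min() for b in t.branches.values()):.4f} cm^2")

# The stenotic tube dips to base_area*(1-severity) = 0.04 cm^2 at its center;
# the tree's first daughters carry area 0.1 * 2^(-2/3) = 0.063 cm^2.
back = c1.read_centerline_tree(out / "tree.json")
print("round trip preserved", len(back.branches), "branches")
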