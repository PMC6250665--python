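"""Pulsatile finite-volume run over two cardiac cycles (~1 min of compute).

A raised-cosine aortic waveform (70-114 mmHg, 0.8 s period) drives a
straight tube; the outlet flow is held at its hyperemic value. The run
verifies the quasi-rigid regime (area excursions well under 1%) and that
time-averaged pressures match a steady solve at the mean aortic pressure.
"""

import numpy as np

import coro1d as c1

tree = c1.resample_tree(c1.make_synthetic(c1.SyntheticSpec(
    kind="straight_tube", base_area=0.1, length=3.0)), spacing=0.05)
wave = c1.aortic_waveform(dp_mmhg=70.0, sp_mmhg=114.0, period=0.8)
boundary = c1.BoundarySpec(Pao=wave, outlet_flows={"b0": 2.0})
wall = c1.WallLaw(beta=c1.calibrate_beta((60.0, 125.0)))
model = c1.NetworkModel(tree, wall=wall, boundary=boundary)

state = c1.solve_transient(model, n_cycles=2, cfl=0.9)
steady = c1.solve_steady(model)  # uses the waveform mean (78.8 mmHg)

print(f"steps = {state.meta['steps']}, simulated time = {state.meta['time']:.2f} s")
print(f"max |A - A0|/A0 over the final cycle = "
      f"{100 * state.meta['max_area_dev']:.3f}% (quasi-rigid bound: 1%)")
print(f"cycle-to-cycle periodicity residual = "
      f"{state.meta['cycle_residual_mmhg']:.2e} mmHg")
diff = np.max(np.abs(state.P["b0"] - steady.P["b0"])) / 1333.22
print(f"time-averaged vs mean-pressure steady field: max diff = {diff:.4f} mmHg")
print(f"FFR at the outlet (ratio of time averages) = {state.ffr('b0')[-1]:.4f}")
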