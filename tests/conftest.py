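"""Shared fixtures.

Heavy transient runs are session-scoped so the expensive finite-volume
integrations are performed once and inspected by several tests.
"""

from __future__ import annotations

import pytest

import coro1d as c1


@pytest.fixture(scope="session")
def wall():
    """Quasi-rigid wall calibrated for the 60-125 mmHg pressure range."""
    return c1.WallLaw(beta=c1.calibrate_beta((60.0, 125.0)))


@pytest.fixture(scope="session")
def straight_tube():
    tree = c1.make_synthetic(c1.SyntheticSpec(
        kind="straight_tube", base_area=0.1, length=5.0))
    return c1.resample_tree(tree, 0.05)


@pytest.fixture(scope="session")
def stenotic_tube():
    tree = c1.make_synthetic(c1.SyntheticSpec(
        kind="stenotic_tube", base_area=0.1, length=5.0,
        severity=0.6, extent=1.0))
    return c1.resample_tree(tree, 0.05)


@pytest.fixture(scope="session")
def lesion_tree():
    """2-level bifurcating tree with one lesion on the root branch."""
    tree = c1.make_synthetic(c1.SyntheticSpec(
        kind="bifurcation_tree", base_area=0.1, length=3.0, depth=2,
        length_ratio=0.7, severity=0.5, extent=0.8))
    return c1.resample_tree(tree, 0.05)


@pytest.fixture(scope="session")
def lesion_tree_model(lesion_tree, wall):
    lesions = [l for b in lesion_tree.branches.values()
               for l in c1.detect_stenoses(b)]
    boundary = c1.BoundarySpec(Pao=90.0, outlet_flows={
        o: 0.5 for o in lesion_tree.outlet_branch_ids})
    return c1.NetworkModel(
        lesion_tree, wall=wall, junction_model="S",
        stenoses=[c1.StenosisElement(l) for l in lesions], boundary=boundary)


@pytest.fixture(scope="session")
def lesion_tree_steady(lesion_tree_model):
    return c1.solve_steady(lesion_tree_model)


@pytest.fixture(scope="session")
def lesion_tree_transient(lesion_tree_model):
    return c1.solve_transient(lesion_tree_model, max_time=2.0,
                              steady_tol_mmhg=1e-3)


@pytest.fixture(scope="session")
def pulsatile_tube_run(wall):
    """Two cardiac cycles on a straight tube driven by a pulsatile aortic
    waveform (70-114 mmHg raised-cosine systole, 0.8 s period)."""
    tree = c1.resample_tree(c1.make_synthetic(c1.SyntheticSpec(
        kind="straight_tube", base_area=0.1, length=3.0)), 0.05)
    boundary = c1.BoundarySpec(Pao=c1.aortic_waveform(70.0, 114.0, period=0.8),
                               outlet_flows={"b0": 2.0})
    model = c1.NetworkModel(tree, wall=wall, boundary=boundary)
    state = c1.solve_transient(model, n_cycles=2, cfl=0.9)
    return model, state


@pytest.fixture(scope="session")
def poiseuille_transient(straight_tube, wall):
    """Constant-BC transient run on the straight tube, to convergence."""
    boundary = c1.BoundarySpec(Pao=90.0, outlet_flows={"b0": 1.0})
    model = c1.NetworkModel(straight_tube, wall=wall, boundary=boundary)
    state = c1.solve_transient(model, max_time=2.0, steady_tol_mmhg=1e-4)
    return model, state
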