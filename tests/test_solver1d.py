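"""1D solver core: tube law, stenosis element, junctions, steady and
transient solutions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import coro1d as c1
from coro1d.centerline import Branch, CenterlineTree
from coro1d.solver1d import JunctionFace, junction_solve
from coro1d.units import MMHG_TO_DYN


class TestTubeLaw:
    def test_reference_point(self):
        w = c1.WallLaw(beta=1e7, P0_mmhg=88.0)
        assert c1.tube_law(0.1, 0.1, w) == pytest.approx(88.0 * MMHG_TO_DYN)

    def test_quadruple_area_adds_beta(self):
        w = c1.WallLaw(beta=1e7)
        assert c1.tube_law(0.4, 0.1, w) == pytest.approx(w.P0 + 1e7)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(a=st.floats(0.01, 1.0), a0=st.floats(0.01, 1.0),
           beta=st.floats(1e5, 1e9))
    def test_inverse_roundtrip(self, a, a0, beta):
        w = c1.WallLaw(beta=beta)
        assert c1.tube_law_inverse(c1.tube_law(a, a0, w), a0, w) == \
            pytest.approx(a, rel=1e-10)


class TestCalibrateBeta:
    def test_deviation_below_one_percent(self):
        beta = c1.calibrate_beta((80.0, 120.0), P0_mmhg=88.0)
        w = c1.WallLaw(beta=beta)
        for p in (80.0, 120.0):
            a = c1.tube_law_inverse(p * MMHG_TO_DYN, 0.1, w)
            assert abs(a - 0.1) / 0.1 < 0.01

    def test_monotone_in_range_width(self):
        b1 = c1.calibrate_beta((80.0, 100.0))
        b2 = c1.calibrate_beta((40.0, 160.0))
        assert b2 >= b1

    def test_safety_factor_applied(self):
        assert c1.calibrate_beta((80.0, 120.0), safety=4.0) == \
            pytest.approx(2 * c1.calibrate_beta((80.0, 120.0), safety=2.0))


class TestKvReference:
    def test_reference_case(self):
        # direct arithmetic: 32*(0.83*0.5+3.28*0.2)/(2*sqrt(0.1))*(0.75*2.5+0.25)^2
        oracle = 32 * (0.83 * 0.5 + 3.28 * np.sqrt(0.04)) / (2 * np.sqrt(0.1)) \
            * (0.75 * 0.1 / 0.04 + 0.25) ** 2
        assert oracle == pytest.approx(244.7, abs=0.01)
        assert c1.kv_reference(0.04, 0.5, 0.1) == pytest.approx(oracle, rel=1e-12)

    def test_vanishing_lesion_limit(self):
        # A_s -> A, L_s -> 0: Kv -> 32*3.28/2 = 52.48
        val = c1.kv_reference(0.1 - 1e-12, 1e-12, 0.1)
        assert val == pytest.approx(52.48, rel=1e-5)

    def test_strictly_decreasing_in_as(self):
        vals = [c1.kv_reference(a_s, 0.5, 0.1) for a_s in np.linspace(0.01, 0.09, 9)]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            c1.kv_reference(0.1, 0.5, 0.1)
        with pytest.raises(ValueError):
            c1.kv_reference(0.04, 0.0, 0.1)


def _lesion(As=0.04, Ls=0.5, A=0.1):
    return c1.StenosisLesion(branch_id="b0", s_start=2.0, s_end=2.0 + Ls,
                             A_s=As, A=A)


class TestStenosisDp:
    def test_zero_velocity(self):
        dp, terms = c1.stenosis_dp(0.0, 0.0, c1.StenosisElement(_lesion()),
                                   c1.FluidProps())
        assert dp == 0.0 and terms == (0.0, 0.0, 0.0)

    def test_term_by_term_oracle(self):
        fluid = c1.FluidProps()
        e = c1.StenosisElement(_lesion(), f_K=1.0)
        U = 50.0
        dp, terms = c1.stenosis_dp(U, 0.0, e, fluid)
        D = 2 * np.sqrt(0.1 / np.pi)
        visc = 244.69625477441414 * 0.04 / D * U
        turb = 1.52 * 1.05 / 2 * (0.1 / 0.04 - 1) ** 2 * U ** 2
        assert terms[0] == pytest.approx(visc, rel=1e-12)
        assert terms[1] == pytest.approx(turb, rel=1e-12)
        assert dp == pytest.approx(visc + turb, rel=1e-12)

    def test_inertial_term(self):
        fluid = c1.FluidProps()
        e = c1.StenosisElement(_lesion())
        dp0, _ = c1.stenosis_dp(10.0, 0.0, e, fluid)
        dp1, terms = c1.stenosis_dp(10.0, 100.0, e, fluid)
        assert dp1 - dp0 == pytest.approx(1.0 * 1.05 * 0.5 * 100.0, rel=1e-12)
        assert terms[2] == pytest.approx(52.5, rel=1e-12)

    def test_fk_scales_viscous_term(self):
        fluid = c1.FluidProps()
        _, t1 = c1.stenosis_dp(20.0, 0.0, c1.StenosisElement(_lesion(), f_K=1.0), fluid)
        _, t2 = c1.stenosis_dp(20.0, 0.0, c1.StenosisElement(_lesion(), f_K=1.3), fluid)
        assert t2[0] == pytest.approx(1.3 * t1[0], rel=1e-12)
        assert t2[1] == t1[1]


class TestJunctionLossCoeffs:
    def test_unit_k_case(self):
        # u_i = u_1 and C_i = 0.5 -> K_i = 1, p_loss = rho u1^2/2.
        # C = 0.5 requires cos(0.75(pi-phi))/(lam psi) = 0.5: with lam=1,
        # psi=1 -> phi = pi - acos(0.5)/0.75
        phi = np.pi - np.arccos(0.5) / 0.75
        terms = c1.junction_loss_coeffs(
            {"a": 2.0, "b": 2.0}, {"a": 0.1, "b": 0.1}, {"b": phi}, "a", 1.05)
        assert terms.C["b"] == pytest.approx(0.5, rel=1e-12)
        assert terms.K["b"] == pytest.approx(1.0, rel=1e-12)
        assert terms.p_loss["b"] == pytest.approx(1.05 * 20.0 ** 2 / 2, rel=1e-12)

    def test_zero_branch_velocity(self):
        terms = c1.junction_loss_coeffs(
            {"a": 2.0, "b": 0.0}, {"a": 0.1, "b": 0.1}, {"b": 0.3}, "a", 1.05)
        assert terms.K["b"] == 0.0 and terms.p_loss["b"] == 0.0

    def test_large_lambda_psi_limit(self):
        terms = c1.junction_loss_coeffs(
            {"a": 1.0, "b": 1e9}, {"a": 1e5, "b": 1e-4}, {"b": 0.0}, "a", 1.05)
        assert terms.C["b"] == pytest.approx(1.0, abs=1e-6)

    def test_zero_supplier_velocity_convention(self):
        terms = c1.junction_loss_coeffs(
            {"a": 0.0, "b": 1.0}, {"a": 0.1, "b": 0.1}, {"b": 0.3}, "a", 1.05)
        assert terms.p_loss["b"] == 0.0

    def test_loss_clamped_nonnegative(self):
        # small velocity ratio with C < 0 would give K < 0; p_loss stays >= 0
        terms = c1.junction_loss_coeffs(
            {"a": 2.0, "b": 0.2}, {"a": 0.1, "b": 0.05}, {"b": np.pi / 2}, "a", 1.05)
        assert terms.p_loss["b"] >= 0.0


def _two_face_junction(A0=0.1, beta=2.56e7):
    return [JunctionFace("a", +1, A0, beta), JunctionFace("b", -1, A0, beta)]


def _three_face_junction(beta=2.56e7):
    return [JunctionFace("p", +1, 0.1, beta),
            JunctionFace("l", -1, 0.063, beta, angle=0.5),
            JunctionFace("r", -1, 0.063, beta, angle=0.5)]


class TestJunctionSolve:
    fluid = c1.FluidProps()
    P0 = 88.0 * MMHG_TO_DYN

    def test_collinear_equal_areas_continuous(self):
        faces = _two_face_junction()
        A, Q, info = junction_solve("S", faces, [0.1, 0.1], [1.0, 1.0],
                                    self.fluid, self.P0)
        assert A[0] == pytest.approx(A[1], rel=1e-12)
        assert Q[0] == pytest.approx(Q[1], rel=1e-12)
        assert Q[0] == pytest.approx(1.0, rel=1e-10)

    # interior states near tube-law equilibrium (small pressure offsets),
    # as the transient solver supplies them
    A_INT = [0.10002, 0.06297, 0.06302]
    Q_INT = [2.0, 0.9, 1.1]

    def test_mass_conservation(self):
        faces = _three_face_junction()
        A, Q, info = junction_solve("S", faces, self.A_INT, self.Q_INT,
                                    self.fluid, self.P0)
        assert abs(Q[0] - Q[1] - Q[2]) < 1e-10 * np.max(np.abs(Q))

    def test_s_model_total_pressure(self):
        faces = _three_face_junction()
        A, Q, _ = junction_solve("S", faces, self.A_INT, self.Q_INT,
                                 self.fluid, self.P0)
        beta = faces[0].beta
        tp = [self.P0 + beta * (np.sqrt(a / f.A0) - 1) + 0.525 * (q / a) ** 2
              for a, q, f in zip(A, Q, faces)]
        assert abs(tp[1] - tp[0]) / abs(tp[0]) < 1e-10
        assert abs(tp[2] - tp[0]) / abs(tp[0]) < 1e-10

    def test_d_model_residual_matches_loss_terms(self):
        faces = _three_face_junction()
        A, Q, info = junction_solve("D", faces, self.A_INT, self.Q_INT,
                                    self.fluid, self.P0)
        beta = faces[0].beta
        tp = [self.P0 + beta * (np.sqrt(a / f.A0) - 1) + 0.525 * (q / a) ** 2
              for a, q, f in zip(A, Q, faces)]
        # independent re-evaluation of the loss model on the solution
        terms = c1.junction_loss_coeffs(
            {f.branch_id: q for f, q in zip(faces, Q)},
            {f.branch_id: a for f, a in zip(faces, A)},
            {f.branch_id: f.angle for f in faces}, info["supplier"], self.fluid.rho)
        for i, f in enumerate(faces[1:], start=1):
            expected = tp[0] - terms.p_loss[f.branch_id]
            assert abs(tp[i] - expected) / abs(tp[0]) < 1e-10

    def test_d_with_zero_k_equals_s_exactly(self):
        faces = _three_face_junction()
        args = (self.A_INT, self.Q_INT, self.fluid, self.P0)
        A_s, Q_s, _ = junction_solve("S", faces, *args)
        A_d, Q_d, _ = junction_solve("D", faces, *args, k_override=0.0)
        assert np.array_equal(A_s, A_d)
        assert np.array_equal(Q_s, Q_d)

    def test_supplier_resolution_by_flow(self):
        faces = _three_face_junction()
        _, _, info = junction_solve("S", faces, self.A_INT, self.Q_INT,
                                    self.fluid, self.P0)
        assert info["supplier"] == "p"


def _tapered_branch(length=4.0, a0=0.1, a1=0.05, spacing=0.05):
    s = np.linspace(0.0, length, int(round(length / spacing)) + 1)
    area = a0 + (a1 - a0) * s / length
    return Branch("b0", s, np.outer(s, [1, 0, 0]), area)


def _tapered_tube_tree(**kw):
    b = _tapered_branch(**kw)
    return CenterlineTree({"b0": b}, [], "b0", ["b0"])


class TestSolveSteady:
    def test_poiseuille_closed_form(self):
        tree = c1.resample_tree(c1.make_synthetic(c1.SyntheticSpec(
            kind="straight_tube", base_area=0.1, length=10.0)), 0.05)
        model = c1.NetworkModel(tree, boundary=c1.BoundarySpec(
            Pao=90.0, outlet_flows={"b0": 1.0}))
        st_ = c1.solve_steady(model)
        dp = st_.P["b0"][0] - st_.P["b0"][-1]
        exact = 2 * 11 * np.pi * 0.04 * 10.0 * 1.0 / 0.1 ** 2  # 2764.6 dyn/cm^2
        assert dp == pytest.approx(exact, rel=1e-10)
        assert dp / MMHG_TO_DYN == pytest.approx(2.0736, abs=1e-3)

    def test_inviscid_taper_conserves_total_pressure(self):
        tree = _tapered_tube_tree()
        model = c1.NetworkModel(tree, fluid=c1.FluidProps(mu=0.0),
                                boundary=c1.BoundarySpec(Pao=90.0,
                                                         outlet_flows={"b0": 2.0}))
        st_ = c1.solve_steady(model)
        tp = st_.P["b0"] + 0.5 * 1.05 * st_.U("b0") ** 2
        np.testing.assert_allclose(tp, tp[0], rtol=1e-12)

    def test_tapered_friction_closed_form(self):
        # linear taper: friction integral has the closed form
        # 2 w pi mu Q / m * (1/A(0) - 1/A(s)) with m = dA/ds < 0
        tree = _tapered_tube_tree()
        q, m = 2.0, (0.05 - 0.1) / 4.0
        model = c1.NetworkModel(tree, boundary=c1.BoundarySpec(
            Pao=90.0, outlet_flows={"b0": q}))
        st_ = c1.solve_steady(model)
        s = st_.s["b0"]
        area = tree.branches["b0"].area
        fric = 2 * 11 * np.pi * 0.04 * q / m * (1 / 0.1 - 1 / area)
        bern = 0.525 * (q / 0.1) ** 2 - 0.525 * (q / area) ** 2
        exact = 90.0 * MMHG_TO_DYN + bern - fric
        np.testing.assert_allclose(st_.P["b0"], exact, rtol=1e-5)

    def test_stenotic_superposition(self, stenotic_tube, wall):
        lesions = c1.detect_stenoses(stenotic_tube.branches["b0"])
        assert len(lesions) == 1
        e = c1.StenosisElement(lesions[0])
        q = 2.0
        model = c1.NetworkModel(stenotic_tube, wall=wall, stenoses=[e],
                                boundary=c1.BoundarySpec(Pao=90.0,
                                                         outlet_flows={"b0": q}))
        st_ = c1.solve_steady(model)
        # element drop equals the independent scalar evaluation
        u = q / lesions[0].A
        dp_oracle, _ = c1.stenosis_dp(u, 0.0, e, model.fluid)
        assert st_.stenosis_records[0]["dp"] == pytest.approx(dp_oracle, rel=1e-12)
        # outlet pressure = inlet - friction outside spans - element drop
        br = stenotic_tube.branches["b0"]
        fric = 2 * 11 * np.pi * 0.04 * q / br.area ** 2
        before = br.s <= lesions[0].s_start + 1e-12
        after = br.s >= lesions[0].s_end - 1e-12
        fric_int = np.trapezoid(fric[before], br.s[before]) \
            + np.trapezoid(fric[after], br.s[after])
        expected = 90.0 * MMHG_TO_DYN - fric_int - dp_oracle
        assert st_.P["b0"][-1] == pytest.approx(expected, rel=1e-6)

    def test_junction_mass_and_flow_distribution(self, lesion_tree_steady,
                                                 lesion_tree_model):
        flows = lesion_tree_model.branch_flows()
        assert flows["b0"] == pytest.approx(2.0, rel=1e-12)
        assert flows["b0L"] == pytest.approx(1.0, rel=1e-12)
        total_out = sum(lesion_tree_model.boundary.outlet_flow_mean(o)
                        for o in lesion_tree_model.tree.outlet_branch_ids)
        assert flows["b0"] == pytest.approx(total_out, rel=1e-12)

    def test_d_model_distal_pressure_not_higher(self, lesion_tree, wall):
        boundary = c1.BoundarySpec(Pao=90.0, outlet_flows={
            o: 0.5 for o in lesion_tree.outlet_branch_ids})
        pS = c1.solve_steady(c1.NetworkModel(lesion_tree, wall=wall,
                                             junction_model="S", boundary=boundary))
        pD = c1.solve_steady(c1.NetworkModel(lesion_tree, wall=wall,
                                             junction_model="D", boundary=boundary))
        assert pD.P["b0LL"][-1] <= pS.P["b0LL"][-1] + 1e-9


class TestSolveTransient:
    def test_matches_steady_on_straight_tube(self, poiseuille_transient):
        model, tr = poiseuille_transient
        st_ = c1.solve_steady(model)
        rel = np.max(np.abs(tr.P["b0"] - st_.P["b0"]) / st_.P["b0"])
        assert rel < 0.005

    def test_poiseuille_drop(self, poiseuille_transient):
        _, tr = poiseuille_transient
        dp = tr.P["b0"][0] - tr.P["b0"][-1]
        exact = 2 * 11 * np.pi * 0.04 * 5.0 * 1.0 / 0.1 ** 2
        assert dp == pytest.approx(exact, rel=0.005)

    def test_tree_equivalence_with_steady(self, lesion_tree_steady,
                                          lesion_tree_transient):
        for bid in lesion_tree_steady.P:
            rel = np.max(np.abs(lesion_tree_transient.P[bid]
                                - lesion_tree_steady.P[bid])
                         / np.abs(lesion_tree_steady.P[bid]))
            assert rel < 0.005, bid

    def test_global_mass_balance(self, lesion_tree_transient, lesion_tree_model):
        q_in = lesion_tree_transient.Q["b0"][0]
        q_out = sum(lesion_tree_model.boundary.outlet_flow_mean(o)
                    for o in lesion_tree_model.tree.outlet_branch_ids)
        assert q_in == pytest.approx(q_out, rel=1e-3)

    def test_quasi_rigidity_pulsatile(self, pulsatile_tube_run):
        _, tr = pulsatile_tube_run
        assert tr.meta["max_area_dev"] < 0.01

    def test_pulsatile_mean_matches_mean_pressure_steady(self, pulsatile_tube_run):
        model, tr = pulsatile_tube_run
        st_ = c1.solve_steady(model)  # uses the waveform mean
        assert np.max(np.abs(tr.P["b0"] - st_.P["b0"])) / MMHG_TO_DYN < 0.05

    def test_periodicity_reached(self, pulsatile_tube_run):
        _, tr = pulsatile_tube_run
        assert tr.meta["cycle_residual_mmhg"] < 0.01

    def test_grid_convergence_first_order(self, wall):
        # transient pressure error vs the closed-form tapered solution
        # decreases at >= 1st order under refinement
        q, m = 2.0, (0.05 - 0.1) / 4.0
        errs = []
        for dx in (0.2, 0.1):
            tree = _tapered_tube_tree(spacing=dx)
            model = c1.NetworkModel(tree, wall=wall, boundary=c1.BoundarySpec(
                Pao=90.0, outlet_flows={"b0": q}))
            tr = c1.solve_transient(model, dx=dx, max_time=2.0,
                                    steady_tol_mmhg=1e-5)
            area = tree.branches["b0"].area
            fric = 2 * 11 * np.pi * 0.04 * q / m * (1 / 0.1 - 1 / area)
            bern = 0.525 * (q / 0.1) ** 2 - 0.525 * (q / area) ** 2
            exact = 90.0 * MMHG_TO_DYN + bern - fric
            errs.append(np.max(np.abs(tr.P["b0"] - exact)))
        assert errs[1] < errs[0] / 1.8

    def test_negative_area_aborts(self, straight_tube, wall):
        model = c1.NetworkModel(straight_tube, wall=wall,
                                boundary=c1.BoundarySpec(
                                    Pao=90.0, outlet_flows={"b0": 1e5}))
        with pytest.raises((c1.solver1d.SolverError, RuntimeError)):
            c1.solve_transient(model, max_time=0.05)
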