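"""1D hemodynamics core.

Governing equations (per branch, CGS units)::

    dA/dt + dQ/dx = 0
    dQ/dt + d(Q^2/A)/dx + (A/rho) dP/dx + 2*pi*omega*mu*U/rho = 0
    P = P0 + beta * (sqrt(A/A0) - 1)

with flow rate Q, lumen area A, mean velocity U = Q/A, velocity-profile
parameter omega, and an effective wall stiffness beta chosen large enough
that the vessel is quasi-rigid (|A - A0|/A0 < 1%), mimicking rigid-wall 3D
reference simulations.

Junctions impose mass conservation plus either conservation of total
pressure P + rho*U^2/2 (standard, S) or a dissipative loss model (D) with a
loss coefficient built from flow/area ratios and branching angles, closed by
outgoing Riemann invariants W = U +/- 4c of the hyperbolic system
(c = sqrt(beta/(2 rho)) (A/A0)^(1/4)).

Stenoses are excised from the 1D mesh and replaced by a lumped element
enforcing the pressure drop

    dP = Kv * mu/D * U + Kt * rho/2 * (A/A_s - 1)^2 * U^2 + Ku*rho*L_s*dU/dt

between its end faces (U, A, D of the unobstructed vessel).

Two solvers are provided: a steady differential-algebraic solver (exact
branch-wise momentum quadrature in the rigid limit) and a transient
second-order MUSCL/HLL finite-volume solver under a global CFL restriction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd

from .centerline import Branch, CenterlineTree, branch_angles
from .stenosis_detect import StenosisLesion
from .units import MMHG_TO_DYN, dyn_to_mmhg, mmhg_to_dyn


# ---------------------------------------------------------------------------
# physical parameter containers
# ---------------------------------------------------------------------------

@dataclass
class FluidProps:
    """Blood as a Newtonian fluid: density (g/cm^3) and viscosity (poise)."""

    rho: float = 1.05
    mu: float = 0.04

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.mu < 0:
            raise ValueError("rho must be positive and mu non-negative")


@dataclass
class WallLaw:
    """Tube-law stiffness beta (dyn/cm^2) and reference pressure P0 (mmHg)."""

    beta: float = 3.2e7
    P0_mmhg: float = 88.0

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")

    @property
    def P0(self) -> float:
        """Reference pressure in dyn/cm^2."""
        return mmhg_to_dyn(self.P0_mmhg)


@dataclass
class ProfileParam:
    """Velocity-profile parameter omega = f_omega * omega0 (omega0 = 11 for
    blunt hyperemic coronary profiles)."""

    omega0: float = 11.0
    f_omega: float = 1.0

    @property
    def omega(self) -> float:
        return self.f_omega * self.omega0


def tube_law(A, A0, wall: WallLaw):
    """Pressure (dyn/cm^2) from area via P = P0 + beta (sqrt(A/A0) - 1)."""
    return wall.P0 + wall.beta * (np.sqrt(np.asarray(A, float) / A0) - 1.0)


def tube_law_inverse(P, A0, wall: WallLaw):
    """Area from pressure (dyn/cm^2): the inverse of :func:`tube_law`."""
    return A0 * (1.0 + (np.asarray(P, float) - wall.P0) / wall.beta) ** 2


def calibrate_beta(
    pressure_range_mmhg: tuple[float, float],
    P0_mmhg: float = 88.0,
    tolerance: float = 0.01,
    safety: float = 2.0,
    beta_floor: float = 1e5,
) -> float:
    """Smallest beta on a factor-2 grid keeping |A - A0|/A0 below ``tolerance``
    over the given pressure range, times a safety factor.

    The quasi-rigid regime requires area deviations under 1% for any pressure
    the simulation will visit; with the square-root tube law the deviation at
    pressure P is (1 + (P - P0)/beta)^2 - 1.
    """
    pmin, pmax = (mmhg_to_dyn(p) for p in pressure_range_mmhg)
    p0 = mmhg_to_dyn(P0_mmhg)
    dev_max = max(abs(pmin - p0), abs(pmax - p0))

    def dev(beta: float) -> float:
        x = dev_max / beta
        return max(abs((1.0 + x) ** 2 - 1.0), abs((1.0 - x) ** 2 - 1.0))

    beta = beta_floor
    while dev(beta) >= tolerance:
        beta *= 2.0
        if beta > 1e15:  # pragma: no cover - unreachable for sane inputs
            raise RuntimeError("beta search diverged")
    return beta * safety


# ---------------------------------------------------------------------------
# stenosis element
# ---------------------------------------------------------------------------

def kv_reference(As: float, Ls: float, A: float) -> float:
    """Geometry-based viscous coefficient of the lumped stenosis model:

    Kv = 32 (0.83 L_s + 3.28 sqrt(A_s)) / (2 sqrt(A)) [0.75 A/A_s + 0.25]^2
    """
    if not 0 < As < A:
        raise ValueError(f"need 0 < A_s < A, got A_s={As}, A={A}")
    if Ls <= 0:
        raise ValueError("L_s must be positive")
    return 32.0 * (0.83 * Ls + 3.28 * np.sqrt(As)) / (2.0 * np.sqrt(A)) \
        * (0.75 * A / As + 0.25) ** 2


@dataclass
class StenosisElement:
    """Lumped pressure-drop element for one lesion.

    ``Kv = f_K * Kv0`` with Kv0 the geometry-based reference coefficient;
    Kt and Ku are the turbulent and inertial coefficients (one-fits-all
    defaults 1.52 and 1.0).
    """

    lesion: StenosisLesion
    f_K: float = 1.0
    Kt: float = 1.52
    Ku: float = 1.0

    def __post_init__(self) -> None:
        if self.f_K <= 0 or self.Kt <= 0 or self.Ku <= 0:
            raise ValueError("stenosis coefficients must be positive")

    @cached_property
    def Kv0(self) -> float:
        return kv_reference(self.lesion.A_s, self.lesion.L_s, self.lesion.A)

    @property
    def Kv(self) -> float:
        return self.f_K * self.Kv0


def stenosis_dp(U: float, dUdt: float, element: StenosisElement, fluid: FluidProps):
    """Pressure drop (dyn/cm^2) across the element and its three terms.

    ``U`` and ``dUdt`` are velocity and acceleration in the unobstructed
    vessel. Returns (dp, (viscous, turbulent, inertial)).
    """
    les = element.lesion
    viscous = element.Kv * fluid.mu / les.D * U
    turbulent = element.Kt * fluid.rho / 2.0 * (les.A / les.A_s - 1.0) ** 2 * U * abs(U)
    inertial = element.Ku * fluid.rho * les.L_s * dUdt
    return viscous + turbulent + inertial, (viscous, turbulent, inertial)


# ---------------------------------------------------------------------------
# junction loss model
# ---------------------------------------------------------------------------

@dataclass
class JunctionLossTerms:
    """Per-branch dissipative-junction quantities (non-supplier branches)."""

    supplier: str
    lambda_: dict[str, float]   # Q_i / Q_1
    psi: dict[str, float]       # A_1 / A_i
    phi: dict[str, float]       # geometric angle from the supplier (rad)
    C: dict[str, float]
    K: dict[str, float]
    p_loss: dict[str, float]    # dyn/cm^2, clamped at >= 0


def junction_loss_coeffs(
    flows: dict[str, float],
    areas: dict[str, float],
    angles: dict[str, float],
    supplier: str,
    rho: float,
) -> JunctionLossTerms:
    """Loss coefficients of the dissipative junction model.

    ``flows`` are inflow/outflow magnitudes (mL/s), ``areas`` the lumen areas
    at the junction faces, ``angles`` the geometric angles from the supplier.
    For each non-supplier branch i:

        C_i = 1 - cos(3/4 (pi - phi_i)) / (lambda_i psi_i)
        K_i = (2 C_i + u_i^2/u_1^2 - 1) u_i^2/u_1^2
        p_loss_i = max(K_i, 0) * rho u_1^2 / 2

    A zero supplier velocity yields zero losses by convention. The loss is
    clamped at >= 0: the model only ever dissipates energy.
    """
    q1, a1 = abs(flows[supplier]), areas[supplier]
    u1 = q1 / a1
    lam, psi, phi, C, K, ploss = {}, {}, {}, {}, {}, {}
    for bid in flows:
        if bid == supplier:
            continue
        qi, ai = abs(flows[bid]), areas[bid]
        ui = qi / ai
        if u1 == 0.0 or q1 == 0.0:
            lam[bid] = psi[bid] = phi[bid] = C[bid] = K[bid] = ploss[bid] = 0.0
            continue
        lam[bid] = qi / q1
        psi[bid] = a1 / ai
        phi[bid] = float(angles.get(bid, 0.0))
        if lam[bid] == 0.0:
            C[bid], K[bid], ploss[bid] = 0.0, 0.0, 0.0
            continue
        C[bid] = 1.0 - np.cos(0.75 * (np.pi - phi[bid])) / (lam[bid] * psi[bid])
        vr = (ui / u1) ** 2
        K[bid] = (2.0 * C[bid] + vr - 1.0) * vr
        ploss[bid] = max(K[bid], 0.0) * rho * u1 ** 2 / 2.0
    return JunctionLossTerms(supplier, lam, psi, phi, C, K, ploss)


# ---------------------------------------------------------------------------
# junction interface solve (Riemann-invariant coupling)
# ---------------------------------------------------------------------------

class JunctionSolveError(RuntimeError):
    """Newton iteration at a junction failed to converge."""


@dataclass
class JunctionFace:
    """One branch face at a junction.

    ``side`` is +1 when the branch's distal end meets the junction (flow
    arrives along +s) and -1 for a proximal end (flow leaves along +s).
    """

    branch_id: str
    side: int
    A0: float      # reference area at the face
    beta: float
    angle: float = 0.0


def junction_solve(
    model: str,
    faces: list[JunctionFace],
    A_int: np.ndarray,
    Q_int: np.ndarray,
    fluid: FluidProps,
    P0: float,
    x0: np.ndarray | None = None,
    k_override: float | None = None,
    tol: float = 1e-11,
    max_iter: int = 100,
):
    """Solve the nonlinear junction system for the interface states.

    Unknowns are (A_i, Q_i) at each face. Equations: mass conservation,
    N_j - 1 total-pressure relations (with the loss term for the D model,
    Picard-lagged inside the Newton iteration) and one outgoing Riemann
    invariant per face, evaluated from the adjacent interior states
    ``A_int, Q_int``. Returns (A_star, Q_star, info).

    ``k_override`` forces every loss coefficient K_i to the given value
    (0 makes the D model coincide with the S model exactly).
    """
    n = len(faces)
    rho = fluid.rho
    sides = np.array([f.side for f in faces], float)
    A0f = np.array([f.A0 for f in faces])
    betas = np.array([f.beta for f in faces])
    b = betas / np.sqrt(A0f)                    # so that P = P0 - beta + b sqrt(A)
    c0 = np.sqrt(b / (2.0 * rho))               # c(A) = c0 * A**0.25
    A_int = np.asarray(A_int, float)
    Q_int = np.asarray(Q_int, float)
    W = Q_int / A_int + sides * 4.0 * c0 * A_int ** 0.25

    # supplier: face with the largest inflow, ties broken by branch id
    inflow = sides * Q_int
    order = sorted(range(n), key=lambda i: (-inflow[i], faces[i].branch_id))
    sup = order[0]
    others = [i for i in range(n) if i != sup]

    qscale = max(np.max(np.abs(Q_int)), 1e-12)
    cscale = float(np.max(c0 * A_int ** 0.25))
    # total-pressure residual measured relative to the pressure magnitude
    pscale = max(abs(P0), rho / 2.0 * np.max((Q_int / A_int) ** 2), 1.0)

    x = np.concatenate([A_int, Q_int]) if x0 is None else x0.copy()

    def p_losses(A: np.ndarray, Q: np.ndarray) -> np.ndarray:
        out = np.zeros(n)
        if model == "S" and k_override is None:
            return out
        u1 = abs(Q[sup]) / A[sup]
        if k_override is not None:
            out[others] = max(k_override, 0.0) * rho * u1 ** 2 / 2.0
            return out
        flows = {f.branch_id: float(Q[i]) for i, f in enumerate(faces)}
        areas = {f.branch_id: float(A[i]) for i, f in enumerate(faces)}
        angles = {f.branch_id: f.angle for f in faces}
        terms = junction_loss_coeffs(flows, areas, angles, faces[sup].branch_id, rho)
        for i in others:
            out[i] = terms.p_loss[faces[i].branch_id]
        return out

    def residual(x: np.ndarray, loss: np.ndarray) -> np.ndarray:
        A, Q = x[:n], x[n:]
        U = Q / A
        r = np.empty(2 * n)
        r[0] = np.dot(sides, Q) / qscale
        r[1:n] = ((P_of(A[sup], sup) + rho / 2 * U[sup] ** 2)
                  - (P_of(A[others], others) + rho / 2 * U[others] ** 2)
                  - loss[others]) / pscale
        r[n:] = (U + sides * 4.0 * c0 * A ** 0.25 - W) / cscale
        return r

    def P_of(A, i):
        return P0 - betas[i] + b[i] * np.sqrt(A)

    def jacobian(x: np.ndarray) -> np.ndarray:
        A, Q = x[:n], x[n:]
        U = Q / A
        J = np.zeros((2 * n, 2 * n))
        J[0, n:] = sides / qscale
        dP_dA = b / (2.0 * np.sqrt(A))
        for row, i in enumerate(others, start=1):
            J[row, sup] = (dP_dA[sup] - rho * U[sup] ** 2 / A[sup]) / pscale
            J[row, n + sup] = rho * U[sup] / A[sup] / pscale
            J[row, i] = -(dP_dA[i] - rho * U[i] ** 2 / A[i]) / pscale
            J[row, n + i] = -rho * U[i] / A[i] / pscale
        c = c0 * A ** 0.25
        for i in range(n):
            J[n + i, i] = (-U[i] / A[i] + sides[i] * c[i] / A[i]) / cscale
            J[n + i, n + i] = 1.0 / A[i] / cscale
        return J

    loss = p_losses(x[:n], x[n:])
    r = residual(x, loss)
    stalls = 0
    for it in range(max_iter):
        rmax = np.max(np.abs(r))
        if rmax < tol or (stalls >= 3 and rmax < 1e-8):
            break
        dx = np.linalg.solve(jacobian(x), -r)
        lam_ls = 1.0
        x_new, r_new, loss_new = x, r, loss
        for _ in range(12):
            trial = x + lam_ls * dx
            if np.all(trial[:n] > 0):
                loss_t = p_losses(trial[:n], trial[n:])
                r_t = residual(trial, loss_t)
                x_new, r_new, loss_new = trial, r_t, loss_t
                if np.max(np.abs(r_t)) < rmax or lam_ls < 1e-3:
                    break
            lam_ls *= 0.5
        stalls = stalls + 1 if np.max(np.abs(r_new)) >= 0.5 * rmax else 0
        x, r, loss = x_new, r_new, loss_new
    else:
        # lagged-loss Newton stalled (strong loss nonlinearity far from
        # equilibrium): retry on the full residual with an FD Jacobian
        from scipy import optimize as _opt

        def full_residual(z):
            return residual(z, p_losses(z[:n], z[n:]))

        sol = _opt.root(full_residual, x, method="hybr")
        if sol.success and np.max(np.abs(sol.fun)) < 1e-9 and np.all(sol.x[:n] > 0):
            x, r = sol.x, sol.fun
            it = max_iter
        else:
            raise JunctionSolveError(
                f"junction Newton did not converge: max residual "
                f"{np.max(np.abs(r)):.3e}")
    info = {"iterations": it, "residual": float(np.max(np.abs(r))), "supplier": faces[sup].branch_id}
    return x[:n], x[n:], info


# ---------------------------------------------------------------------------
# boundary data
# ---------------------------------------------------------------------------

@dataclass
class Waveform:
    """Periodic tabulated waveform; linear interpolation, values repeat with
    ``period`` (s)."""

    t: np.ndarray
    v: np.ndarray
    period: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.v = np.asarray(self.v, float)

    def __call__(self, t):
        return np.interp(np.mod(t, self.period), self.t, self.v)

    @property
    def mean(self) -> float:
        tt = np.linspace(0.0, self.period, 512)
        return float(np.trapezoid(self(tt), tt) / self.period)


def aortic_waveform(dp_mmhg: float = 70.0, sp_mmhg: float = 114.0,
                    period: float = 0.8, systole_fraction: float = 0.4,
                    n: int = 200) -> Waveform:
    """Synthetic aortic pressure waveform (mmHg): a raised-cosine systolic
    pulse from diastolic ``dp`` to systolic ``sp`` over the stated fraction
    of the cycle."""
    t = np.linspace(0.0, period, n)
    ts = systole_fraction * period
    p = np.full(n, float(dp_mmhg))
    mask = t < ts
    p[mask] += (sp_mmhg - dp_mmhg) * 0.5 * (1.0 - np.cos(2.0 * np.pi * t[mask] / ts))
    return Waveform(t, p, period)


@dataclass
class BoundarySpec:
    """Inlet aortic pressure (mmHg; scalar or periodic waveform) and
    prescribed outlet flows (mL/s; scalars or waveforms), keyed by outlet
    branch id."""

    Pao: float | Waveform
    outlet_flows: dict

    @property
    def pulsatile(self) -> bool:
        return isinstance(self.Pao, Waveform) or any(
            isinstance(q, Waveform) for q in self.outlet_flows.values())

    @property
    def period(self) -> float:
        if isinstance(self.Pao, Waveform):
            return self.Pao.period
        for q in self.outlet_flows.values():
            if isinstance(q, Waveform):
                return q.period
        return 1.0

    def pao_dyn(self, t: float) -> float:
        p = self.Pao(t) if isinstance(self.Pao, Waveform) else self.Pao
        return float(mmhg_to_dyn(p))

    @property
    def pao_mean_dyn(self) -> float:
        p = self.Pao.mean if isinstance(self.Pao, Waveform) else self.Pao
        return float(mmhg_to_dyn(p))

    def outlet_flow(self, bid: str, t: float) -> float:
        q = self.outlet_flows[bid]
        return float(q(t)) if isinstance(q, Waveform) else float(q)

    def outlet_flow_mean(self, bid: str) -> float:
        q = self.outlet_flows[bid]
        return float(q.mean) if isinstance(q, Waveform) else float(q)


# ---------------------------------------------------------------------------
# network model
# ---------------------------------------------------------------------------

@dataclass
class NetworkModel:
    """A complete 1D network: geometry, wall, fluid, junction model choice,
    embedded stenosis elements and boundary data."""

    tree: CenterlineTree
    fluid: FluidProps = field(default_factory=FluidProps)
    wall: WallLaw = field(default_factory=WallLaw)
    profile: ProfileParam = field(default_factory=ProfileParam)
    junction_model: str = "S"
    stenoses: list[StenosisElement] = field(default_factory=list)
    boundary: BoundarySpec = None

    def __post_init__(self) -> None:
        if self.junction_model not in ("S", "D"):
            raise ValueError("junction_model must be 'S' or 'D'")
        by_branch: dict[str, list[StenosisElement]] = {}
        for e in self.stenoses:
            by_branch.setdefault(e.lesion.branch_id, []).append(e)
        for bid, els in by_branch.items():
            els.sort(key=lambda e: e.lesion.s_start)
            for a, bnext in zip(els, els[1:]):
                if bnext.lesion.s_start < a.lesion.s_end:
                    raise ValueError(f"overlapping stenosis spans on branch {bid!r}")
        # resolve junction angles once from the geometry
        for j in self.tree.junctions:
            if j.angles is None:
                j.angles = branch_angles(self.tree, j)

    def stenoses_on(self, branch_id: str) -> list[StenosisElement]:
        els = [e for e in self.stenoses if e.lesion.branch_id == branch_id]
        return sorted(els, key=lambda e: e.lesion.s_start)

    def branch_flows(self) -> dict[str, float]:
        """Steady branch flows (mL/s) from tree mass balance of the mean
        prescribed outlet flows."""
        flows: dict[str, float] = {}

        def q_of(bid: str) -> float:
            if bid in flows:
                return flows[bid]
            jid = self.tree.child_junction_of(bid)
            if jid is None:
                q = self.boundary.outlet_flow_mean(bid)
            else:
                j = self.tree.junction(jid)
                q = sum(q_of(d) for d in self.tree.downstream_branches(j))
            flows[bid] = q
            return q

        for bid in self.tree.branches:
            q_of(bid)
        return flows


# ---------------------------------------------------------------------------
# flow state
# ---------------------------------------------------------------------------

@dataclass
class FlowState:
    """A, Q, P, U fields over the network (steady values, or final-cycle
    time averages for transient runs), plus per-stenosis pressure drops."""

    s: dict[str, np.ndarray]
    A: dict[str, np.ndarray]
    Q: dict[str, np.ndarray]
    P: dict[str, np.ndarray]            # dyn/cm^2
    pao_dyn: float
    stenosis_records: list[dict] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def U(self, bid: str) -> np.ndarray:
        return self.Q[bid] / self.A[bid]

    def P_mmhg(self, bid: str) -> np.ndarray:
        return dyn_to_mmhg(self.P[bid])

    def ffr(self, bid: str) -> np.ndarray:
        return self.P[bid] / self.pao_dyn

    def to_frame(self) -> pd.DataFrame:
        rows = [pd.DataFrame({
            "branch_id": bid, "s": self.s[bid], "A": self.A[bid],
            "Q": self.Q[bid], "P_mmHg": self.P_mmhg(bid), "U": self.U(bid),
        }) for bid in self.s]
        return pd.concat(rows, ignore_index=True)

    def stenosis_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"branch_id": r["lesion"].branch_id,
             "s_start": r["lesion"].s_start, "s_end": r["lesion"].s_end,
             "dP_mmHg": dyn_to_mmhg(r["dp"]),
             "viscous_mmHg": dyn_to_mmhg(r["terms"][0]),
             "turbulent_mmHg": dyn_to_mmhg(r["terms"][1]),
             "inertial_mmHg": dyn_to_mmhg(r["terms"][2])}
            for r in self.stenosis_records
        ])


# ---------------------------------------------------------------------------
# steady solver (differential-algebraic system)
# ---------------------------------------------------------------------------

def solve_steady(model: NetworkModel) -> FlowState:
    """Steady rigid-limit solution.

    Branch flows follow exactly from tree mass balance of the prescribed
    outlet flows; A = A0; the pressure integrates the steady momentum balance

        dP/dx = -(rho/A) d(Q^2/A)/dx - 2*omega*pi*mu*Q/A^2

    branch-by-branch from the inlet (Bernoulli term exact, friction by
    trapezoidal quadrature at centerline resolution), inserting junction
    relations and stenosis pressure drops as algebraic jumps.
    """
    tree, fluid, prof = model.tree, model.fluid, model.profile
    flows = model.branch_flows()
    pao = model.boundary.pao_mean_dyn
    P: dict[str, np.ndarray] = {}
    state = FlowState(
        s={bid: b.s.copy() for bid, b in tree.branches.items()},
        A={bid: b.area.copy() for bid, b in tree.branches.items()},
        Q={bid: np.full(b.n_points, flows[bid]) for bid, b in tree.branches.items()},
        P=P, pao_dyn=pao,
    )
    start_p: dict[str, float] = {tree.inlet_branch_id: pao}
    stack = [tree.inlet_branch_id]
    coef = 2.0 * prof.omega * np.pi * fluid.mu
    while stack:
        bid = stack.pop()
        br = tree.branches[bid]
        q = flows[bid]
        A0 = br.area
        if np.any(A0 <= 0):
            raise ValueError(f"branch {bid!r}: zero or negative area point")
        U = q / A0
        fric = coef * q / A0 ** 2
        p = np.empty(br.n_points)
        p[0] = start_p[bid]
        # integrate between consecutive points; lesion spans handled as jumps
        els = model.stenoses_on(bid)
        starts = {}
        for e in els:
            i1 = int(np.searchsorted(br.s, e.lesion.s_start, "right")) - 1
            i2 = int(np.searchsorted(br.s, e.lesion.s_end, "left"))
            starts[i1] = (i2, e)
        ds = np.diff(br.s)
        dp_fric = 0.5 * (fric[:-1] + fric[1:]) * ds
        k = 0
        while k < br.n_points - 1:
            if k in starts:
                i2, e = starts[k]
                u_ref = q / e.lesion.A
                dp, terms = stenosis_dp(u_ref, 0.0, e, fluid)
                p[i2] = p[k] - dp
                if i2 - k > 1:  # fill excised points for reporting
                    p[k + 1:i2] = np.interp(br.s[k + 1:i2], [br.s[k], br.s[i2]],
                                            [p[k], p[i2]])
                state.stenosis_records.append(
                    {"lesion": e.lesion, "dp": dp, "terms": terms, "U": u_ref, "f_K": e.f_K})
                k = i2
            else:
                p[k + 1] = p[k] + fluid.rho / 2.0 * (U[k] ** 2 - U[k + 1] ** 2) - dp_fric[k]
                k += 1
        P[bid] = p
        jid = tree.child_junction_of(bid)
        if jid is None:
            continue
        jct = tree.junction(jid)
        children = tree.downstream_branches(jct)
        angles = jct.angles or {}
        a_faces = {bid: float(A0[-1])}
        q_faces = {bid: q}
        for ch in children:
            a_faces[ch] = float(tree.branches[ch].area[0])
            q_faces[ch] = flows[ch]
        if model.junction_model == "D":
            terms = junction_loss_coeffs(q_faces, a_faces, angles, bid, fluid.rho)
            losses = terms.p_loss
        else:
            losses = {ch: 0.0 for ch in children}
        tp_sup = p[-1] + fluid.rho / 2.0 * U[-1] ** 2
        for ch in children:
            u_ch = flows[ch] / a_faces[ch]
            start_p[ch] = tp_sup - fluid.rho / 2.0 * u_ch ** 2 - losses[ch]
            stack.append(ch)
    state.meta["mode"] = "steady"
    return state


# ---------------------------------------------------------------------------
# transient solver: mesh assembly
# ---------------------------------------------------------------------------

class _Segment:
    """A contiguous 1D finite-volume mesh piece of one branch."""

    def __init__(self, branch: Branch, s_lo: float, s_hi: float, dx: float):
        self.branch_id = branch.id
        self.s_lo, self.s_hi = s_lo, s_hi
        n = max(2, int(round((s_hi - s_lo) / dx)))
        self.n = n
        self.dx = (s_hi - s_lo) / n
        self.s_c = s_lo + (np.arange(n) + 0.5) * self.dx
        self.A0 = np.interp(self.s_c, branch.s, branch.area)
        s_f = s_lo + np.arange(n + 1) * self.dx
        self.A0_face = np.interp(s_f, branch.s, branch.area)
        self.sl = None  # global cell slice, set at assembly


class _Mesh:
    """Global cell arrays plus index maps for faces and couplers."""

    def __init__(self, model: NetworkModel, dx: float):
        tree = model.tree
        self.model = model
        self.segments: list[_Segment] = []
        self.by_branch: dict[str, list[_Segment]] = {}
        for bid, br in tree.branches.items():
            cuts = [br.s[0]]
            for e in model.stenoses_on(bid):
                cuts += [e.lesion.s_start, e.lesion.s_end]
            cuts.append(br.s[-1])
            segs = []
            for lo, hi in zip(cuts[0::2], cuts[1::2]):
                if hi - lo < 2 * dx:
                    raise ValueError(
                        f"branch {bid!r}: mesh piece [{lo:.3f},{hi:.3f}] shorter than 2 dx")
                segs.append(_Segment(br, lo, hi, dx))
            self.by_branch[bid] = segs
            self.segments += segs
        # global cell layout
        pos = 0
        for seg in self.segments:
            seg.sl = slice(pos, pos + seg.n)
            pos += seg.n
        self.n_cells = pos
        self.A0 = np.concatenate([s.A0 for s in self.segments])
        self.dx_c = np.concatenate([np.full(s.n, s.dx) for s in self.segments])
        # face layout: n+1 faces per segment, contiguous
        fpos = 0
        self.faceL = np.empty(pos, int)   # left face of each cell
        self.faceR = np.empty(pos, int)
        A0_face_parts = []
        int_iL, int_iR, int_f = [], [], []
        for seg in self.segments:
            cells = np.arange(seg.sl.start, seg.sl.stop)
            self.faceL[seg.sl] = fpos + np.arange(seg.n)
            self.faceR[seg.sl] = fpos + np.arange(1, seg.n + 1)
            A0_face_parts.append(seg.A0_face)
            int_f.append(fpos + np.arange(1, seg.n))
            int_iL.append(cells[:-1])
            int_iR.append(cells[1:])
            seg.face_lo, seg.face_hi = fpos, fpos + seg.n
            fpos += seg.n + 1
        self.n_faces = fpos
        self.A0_face = np.concatenate(A0_face_parts)
        self.int_f = np.concatenate(int_f)
        self.int_iL = np.concatenate(int_iL)
        self.int_iR = np.concatenate(int_iR)
        beta = model.wall.beta
        self.b_face = beta / np.sqrt(self.A0_face)
        self.b_cell = beta / np.sqrt(self.A0)
        # slope neighbor maps (clamped at segment boundaries -> zero slope)
        prev_idx = np.arange(pos)
        next_idx = np.arange(pos)
        for seg in self.segments:
            prev_idx[seg.sl.start + 1:seg.sl.stop] -= 1
            next_idx[seg.sl.start:seg.sl.stop - 1] += 1
        self.prev_idx, self.next_idx = prev_idx, next_idx


def _minmod(dl: np.ndarray, dr: np.ndarray) -> np.ndarray:
    out = np.where(dl * dr > 0.0, np.where(np.abs(dl) < np.abs(dr), dl, dr), 0.0)
    return out


# coupler classes -----------------------------------------------------------

class _InletBC:
    def __init__(self, mesh: _Mesh, seg: _Segment, model: NetworkModel):
        self.face = seg.face_lo
        self.cell = seg.sl.start
        self.model = model
        b = mesh.b_face[self.face]
        self.b = b
        self.A0f = mesh.A0_face[self.face]
        # interior state extrapolated to the face at constant eta = A/A0
        self.ratio = self.A0f / mesh.A0[self.cell]
        self.c0 = np.sqrt(b / (2.0 * model.fluid.rho))
        self.last = None

    def star(self, t, A, Q, dt):
        wall = self.model.wall
        p = self.model.boundary.pao_dyn(t)
        A_star = tube_law_inverse(p, self.A0f, wall)
        a_c, q_c = A[self.cell] * self.ratio, Q[self.cell]
        w_minus = q_c / a_c - 4.0 * self.c0 * a_c ** 0.25
        u_star = w_minus + 4.0 * self.c0 * A_star ** 0.25
        self.last = (float(A_star), float(u_star * A_star))
        return self.last


class _OutletBC:
    def __init__(self, mesh: _Mesh, seg: _Segment, bid: str, model: NetworkModel):
        self.face = seg.face_hi
        self.cell = seg.sl.stop - 1
        self.bid = bid
        self.model = model
        b = mesh.b_face[self.face]
        self.ratio = mesh.A0_face[self.face] / mesh.A0[self.cell]
        self.c0 = np.sqrt(b / (2.0 * model.fluid.rho))
        self.last = None

    def star(self, t, A, Q, dt):
        q_out = self.model.boundary.outlet_flow(self.bid, t)
        a_c, q_c = A[self.cell] * self.ratio, Q[self.cell]
        w_plus = q_c / a_c + 4.0 * self.c0 * a_c ** 0.25
        a = a_c
        for _ in range(50):
            f = q_out / a + 4.0 * self.c0 * a ** 0.25 - w_plus
            fp = -q_out / a ** 2 + self.c0 * a ** -0.75
            step = f / fp
            a_new = a - step
            if a_new <= 0:
                a_new = a / 2.0
            if abs(a_new - a) < 1e-14 * a:
                a = a_new
                break
            a = a_new
        self.last = (float(a), float(q_out))
        return self.last


class _JunctionCoupler:
    def __init__(self, mesh: _Mesh, jct, model: NetworkModel):
        tree = model.tree
        up = tree.upstream_branch(jct)
        self.faces: list[JunctionFace] = []
        self.cells: list[int] = []
        self.face_ids: list[int] = []
        angles = jct.angles or {}
        for bid in jct.branch_ids:
            if bid == up:
                seg = mesh.by_branch[bid][-1]
                self.cells.append(seg.sl.stop - 1)
                self.face_ids.append(seg.face_hi)
                side = +1
            else:
                seg = mesh.by_branch[bid][0]
                self.cells.append(seg.sl.start)
                self.face_ids.append(seg.face_lo)
                side = -1
            fid = self.face_ids[-1]
            self.faces.append(JunctionFace(
                bid, side, float(mesh.A0_face[fid]), model.wall.beta,
                float(angles.get(bid, 0.0))))
        self.ratios = np.array([mesh.A0_face[f] / mesh.A0[c]
                                for f, c in zip(self.face_ids, self.cells)])
        self.model = model
        self.x_prev: np.ndarray | None = None
        self.last_info = None
        self.last = None

    def star(self, t, A, Q, dt):
        A_int = A[self.cells] * self.ratios
        Q_int = Q[self.cells]
        A_s, Q_s, info = junction_solve(
            self.model.junction_model, self.faces, A_int, Q_int,
            self.model.fluid, self.model.wall.P0, x0=self.x_prev)
        self.x_prev = np.concatenate([A_s, Q_s])
        self.last_info = info
        self.last = (A_s, Q_s)
        return self.last


class _StenosisCoupler:
    def __init__(self, mesh: _Mesh, seg_l: _Segment, seg_r: _Segment,
                 element: StenosisElement, model: NetworkModel):
        self.element = element
        self.model = model
        self.cell_l = seg_l.sl.stop - 1
        self.cell_r = seg_r.sl.start
        self.face_l = seg_l.face_hi
        self.face_r = seg_r.face_lo
        rho = model.fluid.rho
        self.bL = mesh.b_face[self.face_l]
        self.bR = mesh.b_face[self.face_r]
        self.ratioL = mesh.A0_face[self.face_l] / mesh.A0[self.cell_l]
        self.ratioR = mesh.A0_face[self.face_r] / mesh.A0[self.cell_r]
        self.c0L = np.sqrt(self.bL / (2.0 * rho))
        self.c0R = np.sqrt(self.bR / (2.0 * rho))
        self.U_prev = 0.0
        self.x_prev = None
        self.last = None
        self.last_dp = 0.0

    def star(self, t, A, Q, dt):
        fluid = self.model.fluid
        e, les = self.element, self.element.lesion
        aL_c, qL_c = A[self.cell_l] * self.ratioL, Q[self.cell_l]
        aR_c, qR_c = A[self.cell_r] * self.ratioR, Q[self.cell_r]
        wL = qL_c / aL_c + 4.0 * self.c0L * aL_c ** 0.25
        wR = qR_c / aR_c - 4.0 * self.c0R * aR_c ** 0.25
        kv_mu_d = e.Kv * fluid.mu / les.D
        kt_fac = e.Kt * fluid.rho / 2.0 * (les.A / les.A_s - 1.0) ** 2
        ku_fac = e.Ku * fluid.rho * les.L_s / max(dt, 1e-30)
        if self.x_prev is None:
            x = np.array([aL_c, aR_c, 0.5 * (qL_c + qR_c)])
        else:
            x = self.x_prev.copy()
        for _ in range(60):
            aL, aR, q = x
            u = q / les.A
            dp = kv_mu_d * u + kt_fac * u * abs(u) + ku_fac * (u - self.U_prev)
            r = np.array([
                q / aL + 4.0 * self.c0L * aL ** 0.25 - wL,
                q / aR - 4.0 * self.c0R * aR ** 0.25 - wR,
                (self.bL * np.sqrt(aL) - self.bR * np.sqrt(aR)) - dp,
            ])
            ddp_dq = (kv_mu_d + 2.0 * kt_fac * abs(u) + ku_fac) / les.A
            J = np.array([
                [-q / aL ** 2 + self.c0L * aL ** -0.75, 0.0, 1.0 / aL],
                [0.0, -q / aR ** 2 - self.c0R * aR ** -0.75, 1.0 / aR],
                [self.bL / (2.0 * np.sqrt(aL)), -self.bR / (2.0 * np.sqrt(aR)), -ddp_dq],
            ])
            dxv = np.linalg.solve(J, -r)
            x_new = x + dxv
            while x_new[0] <= 0 or x_new[1] <= 0:
                dxv *= 0.5
                x_new = x + dxv
            x = x_new
            if np.max(np.abs(dxv) / np.maximum(np.abs(x), 1e-12)) < 1e-13:
                break
        self.x_prev = x
        aL, aR, q = x
        u = q / les.A
        self.last_dp = kv_mu_d * u + kt_fac * u * abs(u) + ku_fac * (u - self.U_prev)
        self.last_u = u
        self.last = ((float(aL), float(q)), (float(aR), float(q)))
        return self.last

    def commit(self) -> None:
        """Record the converged velocity for the backward-Euler dU/dt."""
        if self.x_prev is not None:
            self.U_prev = self.x_prev[2] / self.element.lesion.A


# ---------------------------------------------------------------------------
# transient solver
# ---------------------------------------------------------------------------

class SolverError(RuntimeError):
    pass


def solve_transient(
    model: NetworkModel,
    n_cycles: int = 3,
    cfl: float = 0.9,
    dx: float = 0.05,
    steady_tol_mmhg: float = 5e-3,
    max_time: float = 4.0,
    check_every: int = 400,
) -> FlowState:
    """Second-order finite-volume (MUSCL/HLL) transient solution.

    With pulsatile boundary data, ``n_cycles`` cardiac cycles are integrated
    and the final cycle's time averages are reported, together with the
    cycle-to-cycle periodicity residual. With constant boundary data the run
    stops once the pressure field is stationary to ``steady_tol_mmhg``
    (checked every ``check_every`` steps) or at ``max_time`` seconds.
    """
    mesh = _Mesh(model, dx)
    fluid, wall, prof, bc = model.fluid, model.wall, model.profile, model.boundary
    rho = fluid.rho
    fric_coef = 2.0 * prof.omega * np.pi * fluid.mu / rho

    # couplers
    couplers: list = []
    inlet_segs = mesh.by_branch[model.tree.inlet_branch_id]
    couplers.append(_InletBC(mesh, inlet_segs[0], model))
    for bid in model.tree.outlet_branch_ids:
        couplers.append(_OutletBC(mesh, mesh.by_branch[bid][-1], bid, model))
    for jct in model.tree.junctions:
        couplers.append(_JunctionCoupler(mesh, jct, model))
    sten_couplers: list[_StenosisCoupler] = []
    for bid, segs in mesh.by_branch.items():
        els = model.stenoses_on(bid)
        for k, e in enumerate(els):
            sc = _StenosisCoupler(mesh, segs[k], segs[k + 1], e, model)
            sten_couplers.append(sc)
            couplers.append(sc)

    # initial state: uniform pressure at Pao(0), branch flows from mass balance
    p_init = bc.pao_dyn(0.0)
    A = tube_law_inverse(p_init, mesh.A0, wall) + np.zeros(mesh.n_cells)
    flows0 = model.branch_flows()
    Q = np.empty(mesh.n_cells)
    for bid, segs in mesh.by_branch.items():
        for seg in segs:
            Q[seg.sl] = flows0[bid]
    for sc in sten_couplers:
        sc.U_prev = flows0[sc.element.lesion.branch_id] / sc.element.lesion.A

    b_face_int = mesh.b_face[mesh.int_f]
    inv3rho = 1.0 / (3.0 * rho)
    A0f_int = mesh.A0_face[mesh.int_f]
    c0_int = np.sqrt(b_face_int / (2.0 * rho))
    c0_cell = np.sqrt(mesh.b_cell / (2.0 * rho))
    # well-balanced geometric source: with S_geo = eta^1.5 * beta * dA0/(3 rho dx)
    # the flux divergence cancels exactly for spatially constant eta = A/A0
    # (uniform pressure, zero flow), which the stiff tube law requires.
    geo_coef = wall.beta * (mesh.A0_face[mesh.faceR] - mesh.A0_face[mesh.faceL]) \
        / (3.0 * rho * mesh.dx_c)

    Fm = np.zeros(mesh.n_faces)
    Fq = np.zeros(mesh.n_faces)

    def rhs(t, A, Q, dt):
        eta = A / mesh.A0
        dL_e = eta - eta[mesh.prev_idx]
        dR_e = eta[mesh.next_idx] - eta
        sl_e = _minmod(dL_e, dR_e)
        dL_q = Q - Q[mesh.prev_idx]
        dR_q = Q[mesh.next_idx] - Q
        sl_q = _minmod(dL_q, dR_q)
        iL, iR = mesh.int_iL, mesh.int_iR
        A_L = (eta[iL] + 0.5 * sl_e[iL]) * A0f_int
        A_R = (eta[iR] - 0.5 * sl_e[iR]) * A0f_int
        Q_L = Q[iL] + 0.5 * sl_q[iL]
        Q_R = Q[iR] - 0.5 * sl_q[iR]
        uL, uR = Q_L / A_L, Q_R / A_R
        cL = c0_int * A_L ** 0.25
        cR = c0_int * A_R ** 0.25
        S_L = np.minimum(uL - cL, uR - cR)
        S_R = np.maximum(uL + cL, uR + cR)
        FmL, FmR = Q_L, Q_R
        FqL = Q_L * uL + b_face_int * A_L ** 1.5 * inv3rho
        FqR = Q_R * uR + b_face_int * A_R ** 1.5 * inv3rho
        den = S_R - S_L
        fm = (S_R * FmL - S_L * FmR + S_L * S_R * (A_R - A_L)) / den
        fq = (S_R * FqL - S_L * FqR + S_L * S_R * (Q_R - Q_L)) / den
        fm = np.where(S_L >= 0, FmL, np.where(S_R <= 0, FmR, fm))
        fq = np.where(S_L >= 0, FqL, np.where(S_R <= 0, FqR, fq))
        Fm[mesh.int_f] = fm
        Fq[mesh.int_f] = fq
        for cp in couplers:
            st = cp.star(t, A, Q, dt)
            if isinstance(cp, _StenosisCoupler):
                for (a_s, q_s), fid, bq in ((st[0], cp.face_l, cp.bL),
                                            (st[1], cp.face_r, cp.bR)):
                    Fm[fid] = q_s
                    Fq[fid] = q_s ** 2 / a_s + bq * a_s ** 1.5 * inv3rho
            elif isinstance(cp, _JunctionCoupler):
                A_s, Q_s = st
                for a_s, q_s, fid, f in zip(A_s, Q_s, cp.face_ids, cp.faces):
                    bq = f.beta / np.sqrt(f.A0)
                    Fm[fid] = q_s
                    Fq[fid] = q_s ** 2 / a_s + bq * a_s ** 1.5 * inv3rho
            else:
                a_s, q_s = st
                bq = mesh.b_face[cp.face]
                Fm[cp.face] = q_s
                Fq[cp.face] = q_s ** 2 / a_s + bq * a_s ** 1.5 * inv3rho
        dA = -(Fm[mesh.faceR] - Fm[mesh.faceL]) / mesh.dx_c
        dQ = -(Fq[mesh.faceR] - Fq[mesh.faceL]) / mesh.dx_c \
            - fric_coef * Q / A + eta ** 1.5 * geo_coef
        return dA, dQ

    pulsatile = bc.pulsatile
    period = bc.period
    t_end = n_cycles * period if pulsatile else max_time
    t = 0.0
    step = 0
    t_rec0 = (n_cycles - 1) * period if pulsatile else None
    p_int = np.zeros(mesh.n_cells)
    pao_int = 0.0
    q_int = np.zeros(mesh.n_cells)
    rec_time = 0.0
    sten_dp_int = np.zeros(len(sten_couplers))
    sten_u_int = np.zeros(len(sten_couplers))
    max_area_dev = 0.0
    p_check = None
    steady_resid = np.inf
    cycle_snapshot = None
    cycle_resid = np.nan

    def pressure(A):
        return wall.P0 - wall.beta + mesh.b_cell * np.sqrt(A)

    while t < t_end - 1e-12:
        u = Q / A
        c = c0_cell * A ** 0.25
        dt = cfl * np.min(mesh.dx_c / (np.abs(u) + c))
        if pulsatile:  # land exactly on cycle boundaries
            next_bdry = (np.floor(t / period + 1e-12) + 1.0) * period
            dt = min(dt, next_bdry - t)
        dt = min(dt, t_end - t)
        dA1, dQ1 = rhs(t, A, Q, dt)
        A1 = A + dt * dA1
        Q1 = Q + dt * dQ1
        if np.any(A1 <= 0):
            raise SolverError(f"negative area at t={t:.5f}s")
        dA2, dQ2 = rhs(t + dt, A1, Q1, dt)
        A_new = 0.5 * (A + A1 + dt * dA2)
        Q_new = 0.5 * (Q + Q1 + dt * dQ2)
        if np.any(A_new <= 0):
            raise SolverError(f"negative area at t={t:.5f}s")
        A, Q = A_new, Q_new
        for sc in sten_couplers:
            sc.commit()
        t += dt
        step += 1
        recording = (t_rec0 is None) or (t > t_rec0)
        if recording:
            p_now = pressure(A)
            p_int += p_now * dt
            q_int += Q * dt
            pao_int += bc.pao_dyn(t) * dt
            rec_time += dt
            for k, sc in enumerate(sten_couplers):
                sten_dp_int[k] += sc.last_dp * dt
                sten_u_int[k] += sc.last_u * dt
            max_area_dev = max(max_area_dev, float(np.max(np.abs(A / mesh.A0 - 1.0))))
        if pulsatile and abs(t - (n_cycles - 1) * period) < 1e-9:
            cycle_snapshot = pressure(A).copy()
        if not pulsatile and step % check_every == 0:
            p_now = pressure(A)
            if p_check is not None:
                steady_resid = float(np.max(np.abs(p_now - p_check))) / MMHG_TO_DYN
                if steady_resid < steady_tol_mmhg:
                    break
            p_check = p_now.copy()

    if pulsatile:
        P_cells = p_int / rec_time
        Q_cells = q_int / rec_time
        pao_mean = pao_int / rec_time
        sten_dp = sten_dp_int / rec_time
        sten_u = sten_u_int / rec_time
        if cycle_snapshot is not None:
            cycle_resid = float(np.max(np.abs(pressure(A) - cycle_snapshot))) / MMHG_TO_DYN
    else:
        P_cells = pressure(A)
        Q_cells = Q.copy()
        pao_mean = bc.pao_dyn(t)
        sten_dp = np.array([sc.last_dp for sc in sten_couplers])
        sten_u = np.array([sc.last_u for sc in sten_couplers])
        max_area_dev = float(np.max(np.abs(A / mesh.A0 - 1.0)))

    # map cell data back to the branch point grids
    tree = model.tree
    s_out, A_out, Q_out, P_out = {}, {}, {}, {}
    def _with_faces(seg: _Segment, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Cell samples extended to the segment end faces by linear
        extrapolation (keeps end-to-end pressure drops second-order)."""
        yc = y[seg.sl]
        lo = 1.5 * yc[0] - 0.5 * yc[1]
        hi = 1.5 * yc[-1] - 0.5 * yc[-2]
        return (np.concatenate([[seg.s_lo], seg.s_c, [seg.s_hi]]),
                np.concatenate([[lo], yc, [hi]]))

    for bid, br in tree.branches.items():
        segs = mesh.by_branch[bid]
        parts = [( _with_faces(sg, P_cells), _with_faces(sg, Q_cells),
                   _with_faces(sg, A)) for sg in segs]
        s_all = np.concatenate([p[0][0] for p in parts])
        p_all = np.concatenate([p[0][1] for p in parts])
        q_all = np.concatenate([p[1][1] for p in parts])
        a_all = np.concatenate([p[2][1] for p in parts])
        s_out[bid] = br.s.copy()
        P_out[bid] = np.interp(br.s, s_all, p_all)
        Q_out[bid] = np.interp(br.s, s_all, q_all)
        A_out[bid] = np.interp(br.s, s_all, a_all)
    state = FlowState(s_out, A_out, Q_out, P_out, pao_dyn=float(pao_mean))
    for k, sc in enumerate(sten_couplers):
        e = sc.element
        u = float(sten_u[k])
        visc = e.Kv * fluid.mu / e.lesion.D * u
        turb = e.Kt * rho / 2.0 * (e.lesion.A / e.lesion.A_s - 1.0) ** 2 * u * abs(u)
        state.stenosis_records.append({
            "lesion": e.lesion, "dp": float(sten_dp[k]),
            "terms": (visc, turb, float(sten_dp[k]) - visc - turb),
            "U": u, "f_K": e.f_K})
    state.meta.update({
        "mode": "transient", "steps": step, "time": t,
        "junctions": {jct.id: cp.last_info for jct, cp in zip(
            model.tree.junctions,
            [c for c in couplers if isinstance(c, _JunctionCoupler)])},
        "max_area_dev": max_area_dev,
        "steady_residual_mmhg": steady_resid if not pulsatile else np.nan,
        "cycle_residual_mmhg": cycle_resid,
    })
    return state
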