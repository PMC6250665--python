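"""Parameter estimation against reference pressure data.

Two factors are estimated by deterministic bounded least squares, re-running
the 1D solver per iterate:

* ``f_K`` scales each stenosis element's viscous coefficient
  (Kv = f_K * Kv0) so the element's pressure drop matches a per-lesion
  target drop (typically lumped from a 3D reference simulation);
* ``f_omega`` scales the network's velocity-profile parameter
  (omega = f_omega * omega0) so outlet pressures match per-outlet targets.

Costs are time-averaged squared mismatches over one cardiac cycle (plain
squared mismatches for steady targets).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .solver1d import FlowState, NetworkModel, solve_steady, solve_transient

BOUNDS = (0.05, 20.0)


@dataclass
class CalibrationTargets:
    """Reference values the 1D model is tuned to.

    ``stenosis_dp_mmhg`` maps lesion index (order of ``model.stenoses``) to a
    target pressure drop; ``outlet_p_mmhg`` maps outlet branch id to a target
    pressure at the distal end. Values are steady scalars or time averages.
    """

    stenosis_dp_mmhg: dict[int, float] = field(default_factory=dict)
    outlet_p_mmhg: dict[str, float] = field(default_factory=dict)


@dataclass
class CalibrationResult:
    f_K: dict[int, float]
    f_omega: float
    cost: float
    iterations: int
    converged: bool


def _solve(model: NetworkModel, transient: bool, **kw) -> FlowState:
    return solve_transient(model, **kw) if transient else solve_steady(model)


def _stenosis_dps_mmhg(state: FlowState, model: NetworkModel) -> dict[int, float]:
    by_lesion = {id(r["lesion"]): r["dp"] / 1333.22 for r in state.stenosis_records}
    return {k: by_lesion[id(e.lesion)] for k, e in enumerate(model.stenoses)}


def _outlet_ps_mmhg(state: FlowState, model: NetworkModel) -> dict[str, float]:
    return {o: float(state.P_mmhg(o)[-1]) for o in model.tree.outlet_branch_ids}


def estimate_fk(
    model: NetworkModel,
    targets: CalibrationTargets,
    transient: bool = False,
    **solver_kw,
) -> CalibrationResult:
    """Estimate the stenosis factor f_K of every lesion (jointly).

    Minimizes the summed squared mismatch between each element's pressure
    drop and its target, with f_K bounded to [0.05, 20]. The model's
    elements are updated in place with the estimates.
    """
    idx = sorted(targets.stenosis_dp_mmhg)
    if not idx:
        raise ValueError("no stenosis targets given")
    missing = [k for k in idx if k >= len(model.stenoses)]
    if missing:
        raise ValueError(f"targets reference unknown lesions {missing}")
    tvec = np.array([targets.stenosis_dp_mmhg[k] for k in idx])
    n_ev = 0

    def residuals(f: np.ndarray) -> np.ndarray:
        nonlocal n_ev
        n_ev += 1
        for k, fk in zip(idx, f):
            model.stenoses[k].f_K = float(fk)
        dps = _stenosis_dps_mmhg(_solve(model, transient, **solver_kw), model)
        return np.array([dps[k] for k in idx]) - tvec

    x0 = np.array([model.stenoses[k].f_K for k in idx])
    res = optimize.least_squares(residuals, x0, bounds=BOUNDS, xtol=1e-10,
                                 ftol=1e-10, gtol=None, diff_step=1e-6)
    for k, fk in zip(idx, res.x):
        model.stenoses[k].f_K = float(fk)
    return CalibrationResult(
        f_K={k: float(v) for k, v in zip(idx, res.x)},
        f_omega=model.profile.f_omega,
        cost=float(np.sum(res.fun ** 2)), iterations=n_ev,
        converged=bool(res.success))


def estimate_fomega(
    model: NetworkModel,
    targets: CalibrationTargets,
    transient: bool = False,
    **solver_kw,
) -> CalibrationResult:
    """Estimate the network profile factor f_omega from outlet pressures."""
    outlets = sorted(targets.outlet_p_mmhg)
    if not outlets:
        raise ValueError("no outlet pressure targets given")
    tvec = np.array([targets.outlet_p_mmhg[o] for o in outlets])
    n_ev = 0

    def residuals(f: np.ndarray) -> np.ndarray:
        nonlocal n_ev
        n_ev += 1
        model.profile.f_omega = float(f[0])
        ps = _outlet_ps_mmhg(_solve(model, transient, **solver_kw), model)
        return np.array([ps[o] for o in outlets]) - tvec

    res = optimize.least_squares(residuals, np.array([model.profile.f_omega]),
                                 bounds=BOUNDS, xtol=1e-10, ftol=1e-10,
                                 gtol=None, diff_step=1e-6)
    model.profile.f_omega = float(res.x[0])
    return CalibrationResult(
        f_K={k: e.f_K for k, e in enumerate(model.stenoses)},
        f_omega=float(res.x[0]),
        cost=float(np.sum(res.fun ** 2)), iterations=n_ev,
        converged=bool(res.success))


def estimate_all(
    model: NetworkModel,
    targets: CalibrationTargets,
    n_sweeps: int = 2,
    transient: bool = False,
    **solver_kw,
) -> CalibrationResult:
    """Best-case calibration: f_K per lesion, then f_omega, alternated.

    Lesion drops depend mostly on their own Kv while outlet pressures fold in
    the distributed friction, so a couple of block-coordinate sweeps settle
    both factors.
    """
    res_k = res_w = None
    for _ in range(max(1, n_sweeps)):
        if targets.stenosis_dp_mmhg:
            res_k = estimate_fk(model, targets, transient, **solver_kw)
        if targets.outlet_p_mmhg:
            res_w = estimate_fomega(model, targets, transient, **solver_kw)
    last = res_w or res_k
    return CalibrationResult(
        f_K={k: e.f_K for k, e in enumerate(model.stenoses)},
        f_omega=model.profile.f_omega,
        cost=last.cost, iterations=last.iterations, converged=last.converged)
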