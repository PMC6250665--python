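"""FFR computation, scenario orchestration and comparison statistics.

Fractional Flow Reserve is the ratio of (time-averaged) distal coronary
pressure to (time-averaged) aortic pressure under hyperemia; values below
0.8 flag a functionally significant stenosis. Four physics scenarios are
supported, each combined with the S or D junction model:

* ``R`` (raw): no stenosis elements, the narrowing stays in the 1D mesh;
* ``P`` (practical): detected lesions become lumped elements with the
  one-fits-all coefficients (f_K = 1);
* ``I`` (intermediate): per-lesion f_K estimated against target drops;
* ``B`` (best-case): f_K and the network profile factor f_omega estimated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from .calibrate import CalibrationTargets, estimate_all
from .centerline import CenterlineTree
from .solver1d import (BoundarySpec, FlowState, FluidProps, NetworkModel,
                       ProfileParam, StenosisElement, WallLaw, solve_steady,
                       solve_transient)
from .stenosis_detect import DetectionConfig, detect_stenoses

FFR_CUTOFF = 0.8
MIN_DISTAL_GAP = 1.0  # cm: clinical margin distal to the target lesion


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

@dataclass
class ScenarioConfig:
    """One of the eight scenarios Y_X, Y in {R, P, I, B}, X in {S, D}."""

    physics: str = "P"
    junction: str = "D"
    targets: CalibrationTargets | None = None
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    transient: bool = False
    solver_options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.physics not in "RPIB" or len(self.physics) != 1:
            raise ValueError("physics must be one of R, P, I, B")
        if self.junction not in ("S", "D"):
            raise ValueError("junction must be S or D")
        if self.physics in "IB" and self.targets is None:
            raise ValueError(f"scenario {self.physics} requires calibration targets")

    @property
    def name(self) -> str:
        return f"{self.physics}_{self.junction}"


@dataclass
class FFRField:
    """Per-point FFR over the tree, with the flow state it came from."""

    tree: CenterlineTree
    state: FlowState
    lesions: list = field(default_factory=list)
    calibration: object = None

    def ffr(self, branch_id: str) -> np.ndarray:
        return self.state.ffr(branch_id)

    def to_frame(self) -> pd.DataFrame:
        rows = [pd.DataFrame({"branch_id": bid, "s": self.state.s[bid],
                              "FFR": self.ffr(bid)})
                for bid in self.state.s]
        return pd.concat(rows, ignore_index=True)

    # -- sampling along vessels --------------------------------------------
    def vessel_profile(self, vessel: str | list[str]) -> tuple[np.ndarray, np.ndarray]:
        """(arclength from ostium of the path, FFR) along a vessel.

        ``vessel`` is a distal branch id (the path from the inlet is
        resolved) or an explicit root-to-tip list of branch ids.
        """
        path = self.tree.path_to(vessel) if isinstance(vessel, str) else list(vessel)
        s_all, f_all, offset = [], [], 0.0
        for bid in path:
            s = self.state.s[bid]
            s_all.append(offset + (s - s[0]))
            f_all.append(self.ffr(bid))
            offset += float(s[-1] - s[0])
        return np.concatenate(s_all), np.concatenate(f_all)

    def ffr_at(self, vessel: str | list[str], locations) -> np.ndarray:
        """FFR at arclength locations (cm from the vessel ostium), linearly
        interpolated along the vessel path."""
        s, f = self.vessel_profile(vessel)
        locations = np.atleast_1d(np.asarray(locations, float))
        if np.any(locations < s[0] - 1e-9) or np.any(locations > s[-1] + 1e-9):
            raise ValueError(
                f"locations outside vessel [{s[0]:.3f}, {s[-1]:.3f}] cm")
        return np.interp(locations, s, f)


def ell_4p(vessel_length: float) -> np.ndarray:
    """The four standard comparison locations {l/4, l/2, 3l/4, l}."""
    return vessel_length * np.array([0.25, 0.5, 0.75, 1.0])


def place_ffr_location(vessel_length: float, lesion_s_end: float,
                       min_gap: float = MIN_DISTAL_GAP) -> float:
    """A clinically plausible interrogation point: at least ``min_gap`` cm
    (10 mm by routine practice) distal to the target lesion, warning when the
    vessel is too short to honor the margin."""
    loc = lesion_s_end + min_gap
    if loc > vessel_length:
        warnings.warn("vessel too short for the 10 mm distal margin; "
                      "placing the interrogation point at the vessel end")
        loc = vessel_length
    return loc


def run_scenario(
    tree: CenterlineTree,
    boundary: BoundarySpec,
    scenario: ScenarioConfig,
    fluid: FluidProps | None = None,
    wall: WallLaw | None = None,
    profile: ProfileParam | None = None,
) -> FFRField:
    """Execute one scenario end to end: lesion detection (skipped for R),
    optional calibration (I/B), the 1D solve, and FFR extraction."""
    fluid = fluid or FluidProps()
    wall = wall or WallLaw()
    profile = profile or ProfileParam()
    lesions = []
    if scenario.physics != "R":
        for b in tree.branches.values():
            lesions += detect_stenoses(b, config=scenario.detection)
    elements = [StenosisElement(l) for l in lesions]
    model = NetworkModel(tree, fluid, wall, profile,
                         junction_model=scenario.junction,
                         stenoses=elements, boundary=boundary)
    calib = None
    if scenario.physics in "IB":
        targets = scenario.targets
        if scenario.physics == "I":
            targets = CalibrationTargets(stenosis_dp_mmhg=targets.stenosis_dp_mmhg)
        calib = estimate_all(model, targets, transient=False)
    state = (solve_transient(model, **scenario.solver_options)
             if scenario.transient else solve_steady(model))
    return FFRField(tree, state, lesions=lesions, calibration=calib)


# ---------------------------------------------------------------------------
# comparison statistics
# ---------------------------------------------------------------------------

def bland_altman(x, y) -> tuple[float, float]:
    """Bland-Altman agreement: mean and SD (n-1) of the differences y - x."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = y - x
    return float(np.mean(d)), float(np.std(d, ddof=1))


def fit_and_correlate(x, y) -> tuple[float, float, float, float]:
    """OLS linear fit y = a*x + b plus Pearson r with its two-sided p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.var(x) == 0:
        raise ValueError("x has zero variance")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue), float(res.pvalue)


@dataclass
class ComparisonStats:
    """Agreement and diagnostic-classification summary of a test FFR field
    against a reference one at a functional cutoff."""

    n: int
    m_BA: float
    SD_BA: float
    a: float
    b: float
    r: float
    p_value: float
    cutoff: float
    Prev: float
    AUC: float
    Acc: float
    Sen: float
    Spe: float
    PPV: float
    NPV: float
    TP: int
    FP: int
    FN: int
    TN: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def classify(ffr_ref, ffr_test, cutoff: float = FFR_CUTOFF) -> dict:
    """Confusion-matrix indexes of ``ffr_test`` against reference labels.

    A positive is a functionally significant stenosis: FFR < cutoff. AUC is
    computed from the continuous test values (lower FFR = more positive)
    against the reference labels. Degenerate label sets (all positive or all
    negative) yield NaN for the undefined indexes with a warning.
    """
    ref = np.asarray(ffr_ref, float)
    test = np.asarray(ffr_test, float)
    if ref.shape != test.shape:
        raise ValueError("ffr_ref and ffr_test must have equal length")
    pos = ref < cutoff
    pred = test < cutoff
    tp = int(np.sum(pos & pred))
    fp = int(np.sum(~pos & pred))
    fn = int(np.sum(pos & ~pred))
    tn = int(np.sum(~pos & ~pred))
    n = ref.size

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    if pos.all() or (~pos).all():
        warnings.warn("reference labels are all one class; AUC and some "
                      "indexes are undefined")
        auc = float("nan")
    else:
        auc = float(roc_auc_score(pos, -test))
    return {
        "n": n, "TP": tp, "FP": fp, "FN": fn, "TN": tn,
        "Prev": ratio(tp + fn, n),
        "Acc": ratio(tp + tn, n),
        "Sen": ratio(tp, tp + fn),
        "Spe": ratio(tn, tn + fp),
        "PPV": ratio(tp, tp + fp),
        "NPV": ratio(tn, tn + fn),
        "AUC": auc,
    }


def compare_ffr(ffr_ref, ffr_test, cutoff: float = FFR_CUTOFF) -> ComparisonStats:
    """Full agreement + classification report (test vs reference)."""
    m, sd = bland_altman(ffr_ref, ffr_test)
    a, b, r, p = fit_and_correlate(ffr_ref, ffr_test)
    cls = classify(ffr_ref, ffr_test, cutoff)
    return ComparisonStats(n=cls["n"], m_BA=m, SD_BA=sd, a=a, b=b, r=r,
                           p_value=p, cutoff=cutoff, Prev=cls["Prev"],
                           AUC=cls["AUC"], Acc=cls["Acc"], Sen=cls["Sen"],
                           Spe=cls["Spe"], PPV=cls["PPV"], NPV=cls["NPV"],
                           TP=cls["TP"], FP=cls["FP"], FN=cls["FN"], TN=cls["TN"])


def paired_pressure_test(dp_ref, dp_test):
    """Wilcoxon signed-rank test on paired pressure drops (the conventional
    paired rank test for non-normal Delta-P samples). Returns (stat, p)."""
    res = sps.wilcoxon(np.asarray(dp_ref, float), np.asarray(dp_test, float))
    return float(res.statistic), float(res.pvalue)
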