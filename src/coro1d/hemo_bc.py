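"""Hyperemic coronary boundary data.

Total hyperemic coronary flow is derived from cardiac output
(RCBF = 0.045 * CO, HCBF = CFR * RCBF with a physiological CFR of 2.6),
apportioned to the major epicardial arteries by circulation dominance, and
split among a tree's outlets by Murray's law (flow proportional to outlet
radius cubed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .centerline import CenterlineTree

CFR_DEFAULT = 2.6
RCBF_FRACTION = 0.045

#: Percentage of the total hyperemic flow Q_T entering each major epicardial
#: artery, by circulation dominance, with and without a ramus intermedius.
INLET_PERCENTAGES: dict[bool, dict[str, dict[str, float]]] = {
    False: {  # RI not present
        "right": {"LAD": 60.0, "LCx": 22.0, "RCA": 18.0, "RI": 0.0},
        "left":  {"LAD": 60.0, "LCx": 30.0, "RCA": 10.0, "RI": 0.0},
        "co":    {"LAD": 60.0, "LCx": 24.0, "RCA": 16.0, "RI": 0.0},
    },
    True: {  # RI present
        "right": {"LAD": 57.0, "LCx": 10.0, "RCA": 18.0, "RI": 15.0},
        "left":  {"LAD": 60.0, "LCx": 15.0, "RCA": 10.0, "RI": 15.0},
        "co":    {"LAD": 59.0, "LCx": 10.0, "RCA": 16.0, "RI": 15.0},
    },
}


@dataclass
class HyperemicFlow:
    """Resting and hyperemic coronary flow derived from cardiac output."""

    CO: float    # cardiac output, mL/min
    CFR: float   # coronary flow reserve
    RCBF: float  # resting coronary blood flow, mL/min
    HCBF: float  # hyperemic coronary blood flow, mL/min

    @property
    def hcbf_mls(self) -> float:
        """Hyperemic flow in mL/s."""
        return self.HCBF / 60.0


def hyperemic_flow(CO: float, CFR: float = CFR_DEFAULT) -> HyperemicFlow:
    """Total hyperemic coronary blood flow from cardiac output (mL/min)."""
    if CO <= 0:
        raise ValueError(f"cardiac output must be positive, got {CO}")
    rcbf = RCBF_FRACTION * CO
    return HyperemicFlow(CO=CO, CFR=CFR, RCBF=rcbf, HCBF=CFR * rcbf)


def inlet_fraction(dominance: str, artery: str, ri_present: bool = False) -> float:
    """Fraction of Q_T entering ``artery`` for the given dominance."""
    try:
        table = INLET_PERCENTAGES[bool(ri_present)][dominance.lower()]
    except KeyError:
        raise ValueError(f"unknown dominance {dominance!r} (right|left|co)") from None
    try:
        return table[artery] / 100.0
    except KeyError:
        raise ValueError(f"unknown artery {artery!r} ({sorted(table)})") from None


def outlet_radius(tree: CenterlineTree, branch_id: str, tail: float = 0.25) -> float:
    """Outlet radius (cm) from the mean area over the distal ``tail`` cm,
    robust to endpoint noise."""
    b = tree.branches[branch_id]
    mask = b.s >= b.s[-1] - tail
    return float(np.sqrt(b.area[mask].mean() / np.pi))


class OutletFlowSet(dict):
    """Outlet flows (mL/s) keyed by outlet branch id; sums to the inlet flow."""

    @property
    def total(self) -> float:
        return float(sum(self.values()))


def murray_split(tree: CenterlineTree, inlet_flow: float, exponent: float = 3.0) -> OutletFlowSet:
    """Split ``inlet_flow`` (mL/s) among outlets by Murray's law.

    Each outlet receives flow proportional to its radius to the given power
    (classical Murray exponent 3), normalized so the flows sum exactly to the
    inlet flow (mass closure).
    """
    outlets = tree.outlet_branch_ids
    if not outlets:
        raise ValueError("tree has no outlets")
    r = np.array([outlet_radius(tree, o) for o in outlets])
    w = r ** exponent
    w = w / w.sum()
    return OutletFlowSet(zip(outlets, (inlet_flow * w).tolist()))


def coronary_outlet_flows(
    tree: CenterlineTree,
    CO: float | None = None,
    hcbf_ml_min: float | None = None,
    dominance: str = "right",
    artery: str = "LAD",
    ri_present: bool = False,
    cfr: float = CFR_DEFAULT,
    murray_exponent: float = 3.0,
) -> OutletFlowSet:
    """Outlet flows (mL/s) for one arterial tree under hyperemia.

    Either ``CO`` (cardiac output, mL/min) or ``hcbf_ml_min`` (total hyperemic
    coronary flow, mL/min) must be given; the tree's inlet flow is the Q_T
    fraction for its artery and dominance, split by Murray's law.
    """
    if (CO is None) == (hcbf_ml_min is None):
        raise ValueError("give exactly one of CO or hcbf_ml_min")
    hcbf = hyperemic_flow(CO, cfr).HCBF if CO is not None else hcbf_ml_min
    frac = inlet_fraction(dominance, artery, ri_present)
    if frac == 0.0:
        warnings.warn(f"artery {artery!r} receives no flow for dominance {dominance!r}")
    return murray_split(tree, hcbf * frac / 60.0, murray_exponent)
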