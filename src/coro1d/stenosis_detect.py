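"""Automatic stenosis detection on centerline area profiles.

A reference ("healthy") lumen area is fit per branch by a robust line fit
that iteratively excludes lumen-loss points, and lesions are extracted as
connected regions of the severity profile ``sigma(s) = 1 - A(s)/A_ref(s)``
exceeding an extent threshold, provided they contain at least one point above
a (stricter) trigger threshold. Each lesion yields the morphology
(A_s, L_s, reference area A, diameter D) consumed by the lumped stenosis
pressure-drop element.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .centerline import Branch

_AREA_FLOOR = 1e-6  # cm^2; keeps A_ref positive on pathological fits


@dataclass
class DetectionConfig:
    trigger_severity: float = 0.4
    extent_severity: float = 0.25
    min_gap: float = 0.5          # cm between lesions before merging
    mad_multiplier: float = 2.5   # k in the negative-residual exclusion rule
    max_iterations: int = 20


@dataclass
class ReferenceAreaModel:
    """Fitted healthy-lumen line A_ref(s) with fit diagnostics."""

    s: np.ndarray
    area_ref: np.ndarray
    inlier_mask: np.ndarray
    iterations: int
    slope: float
    intercept: float

    def __call__(self, s) -> np.ndarray:
        return np.maximum(self.intercept + self.slope * np.asarray(s, float), _AREA_FLOOR)


@dataclass
class StenosisLesion:
    """Morphology of one stenotic lesion on a branch."""

    branch_id: str
    s_start: float
    s_end: float
    A_s: float     # minimum lumen area in the region (cm^2)
    A: float       # reference (unobstructed) area at the minimum (cm^2)

    def __post_init__(self) -> None:
        if not self.s_end > self.s_start:
            raise ValueError("lesion must have positive extent")
        if not 0 < self.A_s < self.A:
            raise ValueError(f"lesion requires 0 < A_s < A, got A_s={self.A_s}, A={self.A}")

    @property
    def L_s(self) -> float:
        return self.s_end - self.s_start

    @property
    def D(self) -> float:
        """Reference diameter 2*sqrt(A/pi) (cm)."""
        return 2.0 * float(np.sqrt(self.A / np.pi))

    @property
    def severity(self) -> float:
        """Area stenosis degree A_s/A in (0, 1)."""
        return self.A_s / self.A


def reference_area(branch: Branch, config: DetectionConfig | None = None) -> ReferenceAreaModel:
    """Robust healthy-lumen line fit of area vs arclength.

    Ordinary least squares is refit after excluding points whose residual is
    negative beyond ``k * MAD`` (lumen loss only: positive outliers are kept),
    until the inlier set stabilizes or the iteration cap is reached.
    """
    cfg = config or DetectionConfig()
    s, a = branch.s, branch.area
    if s.size < 4:
        raise ValueError(f"branch {branch.id!r}: need >= 4 points for a reference fit")
    inliers = np.ones(s.size, dtype=bool)
    slope = intercept = 0.0
    it = 0
    for it in range(1, cfg.max_iterations + 1):
        slope, intercept = np.polyfit(s[inliers], a[inliers], 1)
        resid = a - (intercept + slope * s)
        mad = np.median(np.abs(resid[inliers] - np.median(resid[inliers])))
        cut = cfg.mad_multiplier * max(mad, 1e-12)
        new_inliers = resid >= -cut
        if new_inliers.sum() < 4:
            break
        if np.array_equal(new_inliers, inliers):
            inliers = new_inliers
            break
        inliers = new_inliers
    area_ref = np.maximum(intercept + slope * s, _AREA_FLOOR)
    return ReferenceAreaModel(s, area_ref, inliers, it, float(slope), float(intercept))


def severity_profile(branch: Branch, ref: ReferenceAreaModel) -> np.ndarray:
    """sigma(s) = 1 - A(s)/A_ref(s)."""
    return 1.0 - branch.area / ref.area_ref


def detect_stenoses(
    branch: Branch,
    ref: ReferenceAreaModel | None = None,
    config: DetectionConfig | None = None,
) -> list[StenosisLesion]:
    """Extract stenotic lesions from a branch's severity profile.

    A lesion is a maximal connected run of points with
    ``sigma > extent_severity`` containing at least one point with
    ``sigma >= trigger_severity``; runs separated by less than ``min_gap`` cm
    are merged before the trigger test. Deterministic: identical input gives
    an identical lesion list.
    """
    cfg = config or DetectionConfig()
    if ref is None:
        ref = reference_area(branch, cfg)
    sigma = severity_profile(branch, ref)
    above = sigma > cfg.extent_severity
    if not above.any():
        return []
    # connected runs of `above`
    idx = np.flatnonzero(np.diff(np.concatenate([[0], above.view(np.int8), [0]])))
    runs = list(zip(idx[0::2], idx[1::2] - 1))  # inclusive index ranges
    # merge runs separated by < min_gap
    merged = [list(runs[0])]
    for lo, hi in runs[1:]:
        if branch.s[lo] - branch.s[merged[-1][1]] < cfg.min_gap:
            merged[-1][1] = hi
        else:
            merged.append([lo, hi])
    lesions: list[StenosisLesion] = []
    for lo, hi in merged:
        seg = slice(lo, hi + 1)
        if np.max(sigma[seg]) < cfg.trigger_severity:
            continue
        k = lo + int(np.argmin(branch.area[seg]))
        lesions.append(StenosisLesion(
            branch_id=branch.id,
            s_start=float(branch.s[lo]),
            s_end=float(branch.s[hi]),
            A_s=float(branch.area[k]),
            A=float(ref.area_ref[k]),
        ))
    return lesions


def lesion_report(lesions: list[StenosisLesion]) -> pd.DataFrame:
    """Tabular lesion report (one row per lesion)."""
    return pd.DataFrame([
        {"branch_id": l.branch_id, "s_start": l.s_start, "s_end": l.s_end,
         "L_s": l.L_s, "A_s": l.A_s, "A": l.A, "D": l.D, "severity": l.severity}
        for l in lesions
    ])
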