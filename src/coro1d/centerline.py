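"""Coronary centerline trees.

A centerline tree is the 1D geometric substrate of the hemodynamic model:
branches of arclength-parameterized points carrying the lumen cross-sectional
area, joined at junctions, with a single inlet (the coronary ostium) and one
outlet per leaf. Units are CGS: cm for lengths, cm^2 for areas.

The native on-disk dialect is a small JSON schema::

    {"branches":  [{"id": ..., "points": [{"s":..., "xyz":[x,y,z], "area":...}]}],
     "junctions": [{"id": ..., "branch_ids": [...], "supplier_id": ...}],
     "inlet": branch_id, "outlets": [branch_id, ...]}

plus a flat CSV export with one row per point
(branch_id, s, x, y, z, area).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import networkx as nx
import numpy as np
import pandas as pd


class CenterlineError(ValueError):
    """Malformed centerline data (parse or validation failure)."""


class TopologyError(CenterlineError):
    """Branch/junction connectivity is not a rooted tree."""


class CenterlinePoint(NamedTuple):
    s: float
    xyz: tuple[float, float, float]
    area: float


@dataclass
class Branch:
    """An unbranched vessel segment, oriented proximal -> distal.

    ``s`` is the arclength coordinate (cm, strictly increasing, 0 at the
    proximal end by convention), ``xyz`` the 3D positions (n, 3) and ``area``
    the lumen cross-sectional area A0 (cm^2, positive).
    """

    id: str
    s: np.ndarray
    xyz: np.ndarray
    area: np.ndarray

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        self.area = np.asarray(self.area, dtype=float)
        if self.s.size < 2:
            raise CenterlineError(f"branch {self.id!r}: needs >= 2 points")
        if self.s.size != self.xyz.shape[0] or self.s.size != self.area.size:
            raise CenterlineError(f"branch {self.id!r}: field length mismatch")
        if np.any(np.diff(self.s) <= 0):
            raise CenterlineError(f"branch {self.id!r}: s must be strictly increasing")
        if np.any(self.area <= 0):
            raise CenterlineError(f"branch {self.id!r}: areas must be positive")

    @property
    def length(self) -> float:
        return float(self.s[-1] - self.s[0])

    @property
    def n_points(self) -> int:
        return int(self.s.size)

    @property
    def points(self) -> Iterator[CenterlinePoint]:
        for k in range(self.s.size):
            yield CenterlinePoint(float(self.s[k]), tuple(self.xyz[k]), float(self.area[k]))


@dataclass
class Junction:
    """A branching point joining ``N_j >= 2`` branches.

    ``angles`` maps branch id -> angle theta_i (radians) measured from the
    supplier branch (theta = 0 for the supplier itself). The supplier may be
    left unset and is then resolved at solve time from the flow field.
    """

    id: str
    branch_ids: list[str]
    supplier_id: str | None = None
    angles: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if len(self.branch_ids) < 2:
            raise CenterlineError(f"junction {self.id!r}: needs >= 2 branches")


@dataclass
class CenterlineTree:
    """A rooted, acyclic network of branches joined at junctions."""

    branches: dict[str, Branch]
    junctions: list[Junction]
    inlet_branch_id: str
    outlet_branch_ids: list[str]
    _parent_junction: dict[str, str] = field(default_factory=dict, repr=False)
    _child_junction: dict[str, str] = field(default_factory=dict, repr=False)
    _junction_parent_branch: dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- topology -----------------------------------------------------------
    def validate(self) -> None:
        if self.inlet_branch_id not in self.branches:
            raise TopologyError(f"inlet branch {self.inlet_branch_id!r} not found")
        for j in self.junctions:
            for b in j.branch_ids:
                if b not in self.branches:
                    raise TopologyError(f"junction {j.id!r} references unknown branch {b!r}")
        g = nx.Graph()
        g.add_nodes_from(("b", b) for b in self.branches)
        for j in self.junctions:
            g.add_node(("j", j.id))
            for b in j.branch_ids:
                g.add_edge(("j", j.id), ("b", b))
        if not nx.is_connected(g):
            raise TopologyError("centerline network is not connected")
        if g.number_of_edges() != g.number_of_nodes() - 1:
            raise TopologyError("centerline network contains a cycle")
        self._orient()
        leaves = {b for b in self.branches if b not in self._child_junction}
        if set(self.outlet_branch_ids) != leaves:
            raise TopologyError(
                f"outlets {sorted(self.outlet_branch_ids)} != leaf branches {sorted(leaves)}"
            )

    def _orient(self) -> None:
        """BFS from the inlet: assigns each junction its upstream branch."""
        self._parent_junction.clear()
        self._child_junction.clear()
        self._junction_parent_branch.clear()
        by_branch: dict[str, list[Junction]] = {b: [] for b in self.branches}
        for j in self.junctions:
            for b in j.branch_ids:
                by_branch[b].append(j)
        seen_j: set[str] = set()
        frontier = [self.inlet_branch_id]
        visited = {self.inlet_branch_id}
        while frontier:
            nxt: list[str] = []
            for b in frontier:
                for j in by_branch[b]:
                    if j.id in seen_j:
                        continue
                    seen_j.add(j.id)
                    self._child_junction[b] = j.id
                    self._junction_parent_branch[j.id] = b
                    for d in j.branch_ids:
                        if d not in visited:
                            visited.add(d)
                            self._parent_junction[d] = j.id
                            nxt.append(d)
            frontier = nxt

    def junction(self, junction_id: str) -> Junction:
        for j in self.junctions:
            if j.id == junction_id:
                return j
        raise KeyError(junction_id)

    def upstream_branch(self, junction: Junction) -> str:
        """The branch entering the junction from the inlet side."""
        return self._junction_parent_branch[junction.id]

    def downstream_branches(self, junction: Junction) -> list[str]:
        up = self.upstream_branch(junction)
        return [b for b in junction.branch_ids if b != up]

    def child_junction_of(self, branch_id: str) -> str | None:
        return self._child_junction.get(branch_id)

    def path_to(self, branch_id: str) -> list[str]:
        """Branch ids from the inlet down to (and including) ``branch_id``."""
        path = [branch_id]
        while path[0] in self._parent_junction:
            jid = self._parent_junction[path[0]]
            path.insert(0, self._junction_parent_branch[jid])
        if path[0] != self.inlet_branch_id:
            raise TopologyError(f"branch {branch_id!r} not reachable from inlet")
        return path


# -- arclength --------------------------------------------------------------

def arclength_from_xyz(xyz: np.ndarray) -> np.ndarray:
    """Cumulative chord length (cm), starting at 0."""
    d = np.linalg.norm(np.diff(np.asarray(xyz, float).reshape(-1, 3), axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(d)])


# -- I/O --------------------------------------------------------------------

def write_centerline_tree(tree: CenterlineTree, path) -> None:
    """Serialize a tree to the native JSON dialect."""
    doc = {
        "branches": [
            {
                "id": b.id,
                "points": [
                    {"s": float(s), "xyz": [float(x) for x in p], "area": float(a)}
                    for s, p, a in zip(b.s, b.xyz, b.area)
                ],
            }
            for b in tree.branches.values()
        ],
        "junctions": [
            {
                "id": j.id,
                "branch_ids": list(j.branch_ids),
                **({"supplier_id": j.supplier_id} if j.supplier_id else {}),
                **({"angles": {k: float(v) for k, v in j.angles.items()}} if j.angles else {}),
            }
            for j in tree.junctions
        ],
        "inlet": tree.inlet_branch_id,
        "outlets": list(tree.outlet_branch_ids),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_centerline_tree(path, dialect: str = "native_json") -> CenterlineTree:
    """Read and validate a centerline tree.

    Branch arclengths are recomputed from the xyz chord lengths (offset to the
    stored proximal s so coordinates survive a round trip).
    """
    if dialect != "native_json":
        raise ValueError(f"unsupported dialect {dialect!r} (native_json only)")
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise CenterlineError(f"{path}: not valid JSON: {exc}") from exc
    branches: dict[str, Branch] = {}
    for rec in doc.get("branches", []):
        try:
            bid = rec["id"]
            pts = rec["points"]
            xyz = np.array([p["xyz"] for p in pts], dtype=float)
            area = np.array([p["area"] for p in pts], dtype=float)
            s0 = float(pts[0].get("s", 0.0))
        except (KeyError, TypeError, IndexError) as exc:
            raise CenterlineError(f"{path}: malformed branch record {rec.get('id')!r}: {exc}") from exc
        s = s0 + arclength_from_xyz(xyz)
        branches[bid] = Branch(bid, s, xyz, area)
    junctions = [
        Junction(rec["id"], list(rec["branch_ids"]), rec.get("supplier_id"),
                 {k: float(v) for k, v in rec["angles"].items()} if rec.get("angles") else None)
        for rec in doc.get("junctions", [])
    ]
    return CenterlineTree(branches, junctions, doc["inlet"], list(doc["outlets"]))


def tree_to_frame(tree: CenterlineTree) -> pd.DataFrame:
    """Flat per-point table (branch_id, s, x, y, z, area)."""
    rows = []
    for b in tree.branches.values():
        rows.append(pd.DataFrame({
            "branch_id": b.id, "s": b.s,
            "x": b.xyz[:, 0], "y": b.xyz[:, 1], "z": b.xyz[:, 2],
            "area": b.area,
        }))
    return pd.concat(rows, ignore_index=True)


def write_centerline_csv(tree: CenterlineTree, path) -> None:
    tree_to_frame(tree).to_csv(path, index=False)


# -- resampling -------------------------------------------------------------

def resample_branch(branch: Branch, spacing: float = 0.05) -> Branch:
    """Resample to equal arclength spacing (cm).

    The last interval may be shorter so that both endpoints are preserved;
    positions and areas are interpolated linearly in arclength.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if spacing >= branch.length:
        raise ValueError(
            f"spacing {spacing} >= branch length {branch.length} of {branch.id!r}")
    s0, s1 = float(branch.s[0]), float(branch.s[-1])
    n_full = int(np.floor((s1 - s0) / spacing + 1e-9))
    s_new = s0 + spacing * np.arange(n_full + 1)
    if s1 - s_new[-1] > 1e-9 * spacing:
        s_new = np.append(s_new, s1)
    else:
        s_new[-1] = s1
    xyz = np.column_stack([np.interp(s_new, branch.s, branch.xyz[:, k]) for k in range(3)])
    area = np.interp(s_new, branch.s, branch.area)
    return Branch(branch.id, s_new, xyz, area)


def resample_tree(tree: CenterlineTree, spacing: float = 0.05) -> CenterlineTree:
    branches = {bid: resample_branch(b, spacing) for bid, b in tree.branches.items()}
    return CenterlineTree(branches, [Junction(j.id, list(j.branch_ids), j.supplier_id,
                                              dict(j.angles) if j.angles else None)
                                     for j in tree.junctions],
                          tree.inlet_branch_id, list(tree.outlet_branch_ids))


# -- junction angles --------------------------------------------------------

def _window_tangent(branch: Branch, end: str, window: float) -> np.ndarray:
    """Least-squares tangent (unit, oriented proximal->distal) near one end."""
    if end == "distal":
        mask = branch.s >= branch.s[-1] - window
    else:
        mask = branch.s <= branch.s[0] + window
    pts = branch.xyz[mask]
    if pts.shape[0] < 2:
        raise CenterlineError(f"branch {branch.id!r}: fewer than 2 points in angle window")
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    t = vt[0]
    norm = np.linalg.norm(t)
    chord = pts[-1] - pts[0]
    if norm == 0 or np.linalg.norm(chord) == 0:
        raise CenterlineError(f"branch {branch.id!r}: degenerate tangent at {end} end")
    if np.dot(t, chord) < 0:  # orient along increasing s
        t = -t
    return t / np.linalg.norm(t)


def branch_angles(tree: CenterlineTree, junction: Junction, window: float = 0.25) -> dict[str, float]:
    """Angles theta_i (radians) of each junction branch from the supplier.

    Tangents are least-squares line fits over ``window`` cm of centerline
    adjacent to the junction; the supplier's angle is 0 by definition. The
    geometric supplier is the upstream branch unless ``junction.supplier_id``
    overrides it.
    """
    supplier = junction.supplier_id or tree.upstream_branch(junction)
    tangents: dict[str, np.ndarray] = {}
    up = tree.upstream_branch(junction)
    for bid in junction.branch_ids:
        end = "distal" if bid == up else "proximal"
        tangents[bid] = _window_tangent(tree.branches[bid], end, window)
    t_sup = tangents[supplier]
    return {
        bid: 0.0 if bid == supplier
        else float(np.arccos(np.clip(np.dot(t_sup, t), -1.0, 1.0)))
        for bid, t in tangents.items()
    }


# -- synthetic geometry -----------------------------------------------------

@dataclass
class SyntheticSpec:
    """Parameters for the synthetic geometry generator.

    kinds: ``straight_tube`` (constant area), ``stenotic_tube`` (cosine area
    dip of given fractional ``severity`` and axial ``extent``) and
    ``bifurcation_tree`` (symmetric binary tree with cube-law daughter areas).
    ``noise`` adds multiplicative lognormal-ish area jitter, seeded.
    """

    kind: str = "straight_tube"
    base_area: float = 0.1
    length: float = 5.0
    point_spacing: float = 0.05
    severity: float = 0.0
    extent: float = 1.0
    center: float | None = None
    depth: int = 2
    branch_angle: float = np.pi / 6
    length_ratio: float = 0.7
    area_ratio: float | None = None
    noise: float = 0.0
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("straight_tube", "stenotic_tube", "bifurcation_tree"):
            raise ValueError(f"unknown synthetic kind {self.kind!r}")
        if not (0.0 <= self.severity < 1.0):
            raise ValueError("severity must be in [0, 1)")
        if self.point_spacing <= 0:
            raise ValueError("point_spacing must be positive")
        if self.base_area <= 0 or self.length <= 0:
            raise ValueError("base_area and length must be positive")


def cosine_dip(s: np.ndarray, severity: float, extent: float, center: float) -> np.ndarray:
    """Fractional area reduction profile: a raised-cosine bump of peak
    ``severity`` over ``extent`` cm centered at ``center``."""
    w = np.zeros_like(s)
    inside = np.abs(s - center) < extent / 2.0
    w[inside] = 0.5 * (1.0 + np.cos(2.0 * np.pi * (s[inside] - center) / extent))
    return severity * w


def _tube_points(length: float, spacing: float) -> np.ndarray:
    n = max(2, int(round(length / spacing)))
    return np.linspace(0.0, length, n + 1)


def make_synthetic(spec: SyntheticSpec) -> CenterlineTree:
    """Build a synthetic centerline tree; bit-reproducible for a fixed seed."""
    rng = np.random.default_rng(spec.random_seed)

    def jitter(area: np.ndarray) -> np.ndarray:
        if spec.noise > 0:
            area = area * (1.0 + spec.noise * rng.standard_normal(area.size))
            area = np.maximum(area, 0.05 * spec.base_area)
        return area

    if spec.kind in ("straight_tube", "stenotic_tube"):
        s = _tube_points(spec.length, spec.point_spacing)
        area = np.full_like(s, spec.base_area)
        if spec.kind == "stenotic_tube" and spec.severity > 0:
            center = spec.length / 2.0 if spec.center is None else spec.center
            area = spec.base_area * (1.0 - cosine_dip(s, spec.severity, spec.extent, center))
        xyz = np.column_stack([s, np.zeros_like(s), np.zeros_like(s)])
        b = Branch("b0", s, xyz, jitter(area))
        return CenterlineTree({"b0": b}, [], "b0", ["b0"])

    # bifurcation_tree
    area_ratio = spec.area_ratio if spec.area_ratio is not None else 2.0 ** (-2.0 / 3.0)
    branches: dict[str, Branch] = {}
    junctions: list[Junction] = []
    outlets: list[str] = []

    def grow(bid: str, origin: np.ndarray, direction: np.ndarray, length: float,
             area0: float, level: int, dip: bool) -> None:
        s = _tube_points(length, spec.point_spacing)
        xyz = origin + np.outer(s, direction)
        area = np.full_like(s, area0)
        if dip and spec.severity > 0:
            center = length / 2.0 if spec.center is None else spec.center
            area = area0 * (1.0 - cosine_dip(s, spec.severity, spec.extent, center))
        branches[bid] = Branch(bid, s, xyz, jitter(area))
        if level >= spec.depth:
            outlets.append(bid)
            return
        tip = xyz[-1]
        # rotate +/- branch_angle in the plane spanned by direction and y-axis
        phi = float(np.arctan2(direction[1], direction[0]))
        kids = []
        for sign, tag in ((+1, "L"), (-1, "R")):
            ang = phi + sign * spec.branch_angle
            d = np.array([np.cos(ang), np.sin(ang), 0.0])
            kid = f"{bid}{tag}"
            kids.append(kid)
            grow(kid, tip, d, length * spec.length_ratio, area0 * area_ratio,
                 level + 1, False)
        junctions.append(Junction(f"j_{bid}", [bid, *kids], supplier_id=bid))

    grow("b0", np.zeros(3), np.array([1.0, 0.0, 0.0]), spec.length,
         spec.base_area, 0, dip=spec.severity > 0)
    return CenterlineTree(branches, junctions, "b0", outlets)
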