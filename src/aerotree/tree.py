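"""Bifurcating airway-tree geometry.

The airway tree is a strict rooted binary tree: generation 1 is the
trachea with label ``"1"``; every non-terminal segment has exactly two
daughters whose labels append ``"1"`` (left) or ``"2"`` (right) to the
parent label.  Markov state indices enumerate labels breadth-first, so
the trachea is state 1, its daughters states 2 and 3, and so on; within
a generation, states are ordered by the label read as a binary code.

Geometry is fully 3-D: each segment carries start/end coordinates (m)
and a diameter, and the gravity direction is a property of the tree, so
body orientation is changed by rigidly rotating the branch vectors.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .physics import TubeSpec

__all__ = [
    "AirwaySegment",
    "AirwayTree",
    "TreeGeneratorParams",
    "label_to_state",
    "state_to_label",
    "gravity_angle",
    "rotation_matrix",
    "rotate_tree",
    "generate_synthetic_tree",
    "constrict_segment",
    "read_tree_csv",
    "write_tree_csv",
    "read_tree_json",
    "write_tree_json",
    "demo_tree",
    "main_bronchus_tube",
]

DEFAULT_GRAVITY = np.array([0.0, 0.0, -1.0])


def label_to_state(label: str) -> int:
    """Map an airway label ("1", "11", "12", "111", ...) to its state index.

    Breadth-first: generation g occupies states 2**(g-1) .. 2**g - 1,
    ordered by the daughter digits read as a binary code.
    """
    if not label or label[0] != "1" or any(c not in "12" for c in label[1:]):
        raise ValueError(f"malformed airway label: {label!r}")
    gen = len(label)
    offset = 0
    for c in label[1:]:
        offset = 2 * offset + (int(c) - 1)
    return 2 ** (gen - 1) + offset


def state_to_label(state: int) -> str:
    """Inverse of :func:`label_to_state`."""
    if state < 1:
        raise ValueError("state indices start at 1")
    gen = state.bit_length()
    offset = state - 2 ** (gen - 1)
    digits = []
    for _ in range(gen - 1):
        digits.append(str((offset & 1) + 1))
        offset >>= 1
    return "1" + "".join(reversed(digits))


@dataclass(frozen=True)
class AirwaySegment:
    """One cylindrical airway segment (a Markov state)."""

    state: int
    label: str
    parent: int | None
    generation: int
    start: np.ndarray  # (3,) m
    end: np.ndarray  # (3,) m
    diameter: float  # m

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", np.asarray(self.start, dtype=float))
        object.__setattr__(self, "end", np.asarray(self.end, dtype=float))
        if self.diameter <= 0:
            raise ValueError("segment diameter must be positive")
        if self.length <= 0:
            raise ValueError("segment must have distinct endpoints")
        if self.generation != len(self.label):
            raise ValueError("generation must equal label length")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.end - self.start))

    @property
    def direction(self) -> np.ndarray:
        """Unit vector along the flow direction."""
        d = self.end - self.start
        return d / np.linalg.norm(d)


@dataclass
class AirwayTree:
    """Airway segments keyed by Markov state index, plus gravity."""

    segments: dict[int, AirwaySegment]
    gravity: np.ndarray = field(default_factory=lambda: DEFAULT_GRAVITY.copy())
    #: original file ids -> remapped state indices (for trees read from file)
    id_map: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gravity = np.asarray(self.gravity, dtype=float)
        n = np.linalg.norm(self.gravity)
        if not math.isclose(n, 1.0, rel_tol=1e-9):
            if n == 0:
                raise ValueError("gravity vector must be nonzero")
            self.gravity = self.gravity / n
        self._daughters: dict[int, list[int]] = {s: [] for s in self.segments}
        roots = []
        for seg in self.segments.values():
            if seg.parent is None:
                roots.append(seg.state)
            else:
                if seg.parent not in self.segments:
                    raise ValueError(f"segment {seg.state} has unknown parent")
                self._daughters[seg.parent].append(seg.state)
        if len(roots) != 1:
            raise ValueError("tree must have exactly one root")
        self.root = roots[0]
        for s, ds in self._daughters.items():
            if len(ds) not in (0, 2):
                raise ValueError(
                    f"segment {s} has {len(ds)} daughters; airway bifurcations "
                    "require exactly 0 or 2")
            ds.sort()

    def daughters(self, state: int) -> list[int]:
        return self._daughters[state]

    @property
    def terminals(self) -> list[int]:
        return sorted(s for s, d in self._daughters.items() if not d)

    @property
    def n_generations(self) -> int:
        return max(seg.generation for seg in self.segments.values())

    def generation_states(self, g: int) -> list[int]:
        return sorted(s for s, seg in self.segments.items() if seg.generation == g)

    def path_to_root(self, state: int) -> list[int]:
        """States from the root down to ``state`` inclusive."""
        path = []
        s: int | None = state
        while s is not None:
            path.append(s)
            s = self.segments[s].parent
        return path[::-1]

    def paths(self) -> list[list[int]]:
        """All root-to-terminal paths, ordered by terminal state."""
        return [self.path_to_root(t) for t in self.terminals]

    def tube(self, state: int) -> TubeSpec:
        """Segment as a tube with its gravity angle."""
        seg = self.segments[state]
        return TubeSpec(length=seg.length, diameter=seg.diameter,
                        angle=gravity_angle(seg, self.gravity))


def gravity_angle(segment: AirwaySegment, gravity: np.ndarray) -> float:
    """Signed elevation of the segment axis above the horizontal plane.

    ``-pi/2`` when the flow direction is parallel to gravity (descending),
    ``0`` when horizontal, ``+pi/2`` when ascending against gravity.
    """
    g = np.asarray(gravity, dtype=float)
    g = g / np.linalg.norm(g)
    u = segment.direction
    return float(np.arcsin(np.clip(-np.dot(u, g), -1.0, 1.0)))


def rotation_matrix(axis, degrees: float) -> np.ndarray:
    """Rotation about ``axis`` ('x'/'y'/'z' or a 3-vector) by ``degrees``."""
    if isinstance(axis, str):
        axis = {"x": (1, 0, 0), "y": (0, 1, 0), "z": (0, 0, 1)}[axis.lower()]
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    t = math.radians(degrees)
    c, s = math.cos(t), math.sin(t)
    x, y, z = a
    K = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(a, a)


def rotate_tree(tree: AirwayTree, rotation: np.ndarray) -> AirwayTree:
    """Rigidly rotate all branches about the tree inlet.

    Topology, lengths, diameters and the gravity direction are unchanged;
    only orientations relative to gravity change.  The rotation origin is
    immaterial for deposition (only branch directions enter the kernels).
    """
    R = np.asarray(rotation, dtype=float)
    if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-9) \
            or not math.isclose(float(np.linalg.det(R)), 1.0, abs_tol=1e-9):
        raise ValueError("rotation must be a proper orthogonal 3x3 matrix")
    origin = tree.segments[tree.root].start
    segs = {
        s: replace(seg,
                   start=origin + R @ (seg.start - origin),
                   end=origin + R @ (seg.end - origin))
        for s, seg in tree.segments.items()
    }
    return AirwayTree(segs, gravity=tree.gravity.copy(), id_map=dict(tree.id_map))


def constrict_segment(tree: AirwayTree, state: int,
                      diameter_factor: float) -> AirwayTree:
    """Return a tree with one segment's diameter multiplied by the factor."""
    if state not in tree.segments:
        raise ValueError(f"unknown state {state}")
    if not 0 < diameter_factor <= 1:
        raise ValueError("diameter factor must lie in (0, 1]")
    segs = dict(tree.segments)
    seg = segs[state]
    segs[state] = replace(seg, diameter=seg.diameter * diameter_factor)
    return AirwayTree(segs, gravity=tree.gravity.copy(), id_map=dict(tree.id_map))


@dataclass(frozen=True)
class TreeGeneratorParams:
    """Parameters of the synthetic asymmetric airway-tree generator.

    Defaults mimic adult human conducting-airway morphometry: a 12 cm,
    18 mm trachea, daughter length/diameter ratios ~0.78 (major) and
    ~0.70 (minor), branching half-angles uniform in [20°, 50°] with
    uniform azimuth.
    """

    n_generations: int = 12
    root_length: float = 0.12  # m
    root_diameter: float = 0.018  # m
    length_ratio_major: float = 0.78
    length_ratio_minor: float = 0.70
    diameter_ratio_major: float = 0.78
    diameter_ratio_minor: float = 0.70
    branch_angle_range: tuple[float, float] = (math.radians(20), math.radians(50))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_generations < 1:
            raise ValueError("need at least one generation")
        for r in (self.length_ratio_major, self.length_ratio_minor,
                  self.diameter_ratio_major, self.diameter_ratio_minor):
            if not 0 < r <= 1:
                raise ValueError("scaling ratios must lie in (0, 1]")


def _orthonormal_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return e1, e2


def generate_synthetic_tree(params: TreeGeneratorParams) -> AirwayTree:
    """Seeded synthetic asymmetric 3-D airway tree.

    A full binary tree with ``2**n - 1`` segments.  The trachea descends
    along gravity from the origin.  At each bifurcation the major and
    minor daughters (randomly assigned left/right) scale the parent
    length/diameter by the major/minor ratios and branch off at random
    half-angles and azimuths, so branch orientations relative to gravity
    become broadly distributed after a few generations.
    """
    rng = np.random.default_rng(params.seed)
    segs: dict[int, AirwaySegment] = {}
    root_dir = np.array([0.0, 0.0, -1.0])
    segs[1] = AirwaySegment(
        state=1, label="1", parent=None, generation=1,
        start=np.zeros(3), end=root_dir * params.root_length,
        diameter=params.root_diameter)
    lo, hi = params.branch_angle_range
    for g in range(1, params.n_generations):
        for s in range(2 ** (g - 1), 2 ** g):
            parent = segs[s]
            u = parent.direction
            e1, e2 = _orthonormal_basis(u)
            psi = rng.uniform(0.0, 2.0 * math.pi)
            major_first = bool(rng.integers(0, 2))
            for j, daughter_state in enumerate((2 * s, 2 * s + 1)):
                is_major = (j == 0) == major_first
                lr = params.length_ratio_major if is_major else params.length_ratio_minor
                dr = params.diameter_ratio_major if is_major else params.diameter_ratio_minor
                phi = rng.uniform(lo, hi)
                azim = psi + (0.0 if j == 0 else math.pi)
                d = (math.cos(phi) * u
                     + math.sin(phi) * (math.cos(azim) * e1 + math.sin(azim) * e2))
                d /= np.linalg.norm(d)
                length = parent.length * lr
                segs[daughter_state] = AirwaySegment(
                    state=daughter_state,
                    label=state_to_label(daughter_state),
                    parent=s, generation=g + 1,
                    start=parent.end.copy(),
                    end=parent.end + d * length,
                    diameter=parent.diameter * dr)
    return AirwayTree(segs)


def demo_tree(n_generations: int = 3, root_length: float = 0.12,
              root_diameter: float = 0.018, ratio: float = 0.75) -> AirwayTree:
    """Small symmetric planar tree (the classic 7-state, 3-generation demo).

    Daughters branch at ±35° from the parent direction in the x–z plane,
    with both length and diameter scaled by ``ratio`` per generation.
    Deterministic; useful for worked examples and exact tests.
    """
    segs: dict[int, AirwaySegment] = {}
    segs[1] = AirwaySegment(
        state=1, label="1", parent=None, generation=1,
        start=np.zeros(3), end=np.array([0.0, 0.0, -root_length]),
        diameter=root_diameter)
    half = math.radians(35)
    for g in range(1, n_generations):
        for s in range(2 ** (g - 1), 2 ** g):
            parent = segs[s]
            u = parent.direction
            for j, ds in enumerate((2 * s, 2 * s + 1)):
                sign = -1.0 if j == 0 else 1.0
                c, sn = math.cos(sign * half), math.sin(sign * half)
                # rotate parent direction by ±35 degrees about the y axis
                d = np.array([c * u[0] + sn * u[2], u[1], -sn * u[0] + c * u[2]])
                length = parent.length * ratio
                segs[ds] = AirwaySegment(
                    state=ds, label=state_to_label(ds), parent=s,
                    generation=g + 1, start=parent.end.copy(),
                    end=parent.end + d * length,
                    diameter=parent.diameter * ratio)
    return AirwayTree(segs)


def main_bronchus_tube() -> TubeSpec:
    """The single-tube benchmark geometry: a third-generation bronchus,
    6.3 cm long, 1.35 cm in diameter, horizontal."""
    return TubeSpec(length=0.063, diameter=0.0135, angle=0.0)


# ---------------------------------------------------------------- file I/O

_CSV_COLUMNS = ["id", "parent_id", "x0", "y0", "z0", "x1", "y1", "z1",
                "diameter_m"]


def _segments_from_records(records: list[dict],
                           gravity=None) -> AirwayTree:
    """Build a tree from raw id/parent records, remapping ids breadth-first."""
    by_id: dict = {r["id"]: r for r in records}
    children: dict = {r["id"]: [] for r in records}
    roots = []
    for r in records:
        pid = r["parent_id"]
        if pid is None:
            roots.append(r["id"])
        else:
            if pid not in by_id:
                raise ValueError(f"segment {r['id']} references unknown parent {pid}")
            children[pid].append(r["id"])
    if len(roots) != 1:
        raise ValueError("tree file must contain exactly one root")
    for i, ch in children.items():
        if len(ch) not in (0, 2):
            raise ValueError(
                f"segment {i} has {len(ch)} daughters; 0 or 2 required")
    # breadth-first label assignment; daughters ordered by file id
    labels: dict = {roots[0]: "1"}
    queue = [roots[0]]
    while queue:
        i = queue.pop(0)
        for k, ch in enumerate(sorted(children[i])):
            labels[ch] = labels[i] + str(k + 1)
            queue.append(ch)
    id_map = {i: label_to_state(lab) for i, lab in labels.items()}
    segs = {}
    for r in records:
        s = id_map[r["id"]]
        pid = r["parent_id"]
        segs[s] = AirwaySegment(
            state=s, label=labels[r["id"]],
            parent=None if pid is None else id_map[pid],
            generation=len(labels[r["id"]]),
            start=np.array([r["x0"], r["y0"], r["z0"]], dtype=float),
            end=np.array([r["x1"], r["y1"], r["z1"]], dtype=float),
            diameter=float(r["diameter_m"]))
    g = DEFAULT_GRAVITY if gravity is None else np.asarray(gravity, float)
    return AirwayTree(segs, gravity=g, id_map=id_map)


def read_tree_csv(path) -> AirwayTree:
    """Read a tree from CSV with columns id,parent_id,x0..z1,diameter_m."""
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"tree CSV missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        pid = getattr(row, "parent_id")
        records.append({
            "id": getattr(row, "id"),
            "parent_id": None if pd.isna(pid) else type(getattr(row, "id"))(pid),
            **{c: getattr(row, c) for c in ("x0", "y0", "z0", "x1", "y1", "z1",
                                            "diameter_m")}})
    return _segments_from_records(records)


def write_tree_csv(tree: AirwayTree, path) -> None:
    rows = []
    for s in sorted(tree.segments):
        seg = tree.segments[s]
        rows.append({
            "id": s, "parent_id": seg.parent,
            "x0": seg.start[0], "y0": seg.start[1], "z0": seg.start[2],
            "x1": seg.end[0], "y1": seg.end[1], "z1": seg.end[2],
            "diameter_m": seg.diameter})
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False,
                                                    float_format="%.17g")


def read_tree_json(path) -> AirwayTree:
    """JSON dialect: {"segments": [...], "gravity": [gx, gy, gz]?}."""
    with open(path) as fh:
        doc = json.load(fh)
    records = [{
        "id": r["id"], "parent_id": r.get("parent_id"),
        "x0": r["x0"], "y0": r["y0"], "z0": r["z0"],
        "x1": r["x1"], "y1": r["y1"], "z1": r["z1"],
        "diameter_m": r["diameter_m"]} for r in doc["segments"]]
    return _segments_from_records(records, gravity=doc.get("gravity"))


def write_tree_json(tree: AirwayTree, path) -> None:
    doc = {
        "gravity": [float(v) for v in tree.gravity],
        "segments": [{
            "id": s, "parent_id": tree.segments[s].parent,
            "x0": tree.segments[s].start[0], "y0": tree.segments[s].start[1],
            "z0": tree.segments[s].start[2], "x1": tree.segments[s].end[0],
            "y1": tree.segments[s].end[1], "z1": tree.segments[s].end[2],
            "diameter_m": tree.segments[s].diameter}
            for s in sorted(tree.segments)],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
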