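"""Coronary tree container: centerline nodes, tapered segments, stenoses, outlets.

The tree is a rooted, directed, acyclic branching structure in physical
(mm) coordinates.  Segments connect a parent node to a child node and carry
a linearly tapered lumen radius; stenoses are focal diameter reductions
parameterised by their centre arc-length, length and percent diameter
stenosis.  Terminal nodes are labelled outlets (LAD / LCX / diagonal /
marginal) that later receive lumped microvascular resistances.

Serialisation is plain versioned JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

SCHEMA_VERSION = 1

BRANCH_LABELS = ("LAD", "LCX", "diagonal", "marginal")


@dataclass
class Node:
    id: int
    position: np.ndarray  # (3,) mm
    radius: float  # reference lumen radius, mm

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("node position must be a 3-vector (mm)")
        if not self.radius > 0:
            raise ValueError(f"node {self.id}: radius must be > 0")


@dataclass
class Segment:
    id: int
    parent: int  # node id
    child: int  # node id
    length: float  # mm
    radius_prox: float  # mm
    radius_dist: float  # mm

    def __post_init__(self) -> None:
        if not self.length > 0:
            raise ValueError(f"segment {self.id}: length must be > 0")
        if not (self.radius_prox > 0 and self.radius_dist > 0):
            raise ValueError(f"segment {self.id}: radii must be > 0")

    def radius_at(self, s: float) -> float:
        """Reference (unstenosed) radius at arc-length ``s`` from the proximal end."""
        t = np.clip(s / self.length, 0.0, 1.0)
        return self.radius_prox + (self.radius_dist - self.radius_prox) * t


@dataclass
class Stenosis:
    id: int
    segment: int  # segment id
    center: float  # arc-length of lesion centre from segment start, mm
    length: float  # lesion length, mm
    severity: float  # percent diameter reduction, in (0, 100)

    @property
    def start(self) -> float:
        return self.center - self.length / 2.0

    @property
    def end(self) -> float:
        return self.center + self.length / 2.0


@dataclass
class CoronaryTree:
    nodes: dict[int, Node]
    segments: list[Segment]
    stenoses: list[Stenosis]
    outlets: dict[int, str]  # terminal node id -> branch label
    inlet: int

    # derived adjacency, built lazily
    _children: dict[int, list[Segment]] = field(default_factory=dict, repr=False)
    _parent_seg: dict[int, Segment] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index()
        self.validate()

    def _index(self) -> None:
        self._children = {nid: [] for nid in self.nodes}
        self._parent_seg = {}
        for seg in self.segments:
            self._children[seg.parent].append(seg)
            if seg.child in self._parent_seg:
                raise ValueError(f"node {seg.child} has multiple parents")
            self._parent_seg[seg.child] = seg

    def validate(self) -> None:
        if self.inlet not in self.nodes:
            raise ValueError("inlet node missing from node table")
        if self.inlet in self._parent_seg:
            raise ValueError("inlet must have no parent")
        roots = [nid for nid in self.nodes if nid not in self._parent_seg]
        if roots != [self.inlet]:
            raise ValueError(f"tree must have exactly one root, found {roots}")
        # acyclicity + reachability: walk from the root
        seen: set[int] = set()
        stack = [self.inlet]
        while stack:
            nid = stack.pop()
            if nid in seen:
                raise ValueError("cycle detected")
            seen.add(nid)
            stack.extend(s.child for s in self._children[nid])
        if seen != set(self.nodes):
            raise ValueError("tree contains nodes unreachable from the inlet")
        terminals = {nid for nid in self.nodes if not self._children[nid] }
        if terminals != set(self.outlets):
            raise ValueError(
                f"terminal nodes {sorted(terminals)} must coincide with "
                f"labelled outlets {sorted(self.outlets)}"
            )
        for label in self.outlets.values():
            if label not in BRANCH_LABELS:
                raise ValueError(f"unknown branch label {label!r}")
        seg_ids = [s.id for s in self.segments]
        if len(set(seg_ids)) != len(seg_ids):
            raise ValueError("duplicate segment ids")
        by_id = {s.id: s for s in self.segments}
        for st in self.stenoses:
            seg = by_id.get(st.segment)
            if seg is None:
                raise ValueError(f"stenosis {st.id} references unknown segment")
            if not (0.0 < st.severity < 100.0):
                raise ValueError(f"stenosis {st.id}: severity must be in (0, 100)")
            if st.start < 0.0 or st.end > seg.length:
                raise ValueError(f"stenosis {st.id} extends outside its segment")

    # -- traversal helpers -------------------------------------------------

    def children_of(self, node_id: int) -> list[Segment]:
        return self._children[node_id]

    def parent_segment(self, node_id: int) -> Segment | None:
        return self._parent_seg.get(node_id)

    def segment_by_id(self, seg_id: int) -> Segment:
        for s in self.segments:
            if s.id == seg_id:
                return s
        raise KeyError(seg_id)

    def stenosis_by_id(self, sten_id: int) -> Stenosis:
        for st in self.stenoses:
            if st.id == sten_id:
                return st
        raise KeyError(sten_id)

    def stenoses_on(self, seg_id: int) -> list[Stenosis]:
        return sorted((s for s in self.stenoses if s.segment == seg_id),
                      key=lambda s: s.center)

    def path_segments(self, node_id: int) -> list[Segment]:
        """Segments from the inlet down to ``node_id``, proximal first."""
        path: list[Segment] = []
        while node_id != self.inlet:
            seg = self._parent_seg[node_id]
            path.append(seg)
            node_id = seg.parent
        return path[::-1]

    def main_continuation(self, seg: Segment) -> list[Segment]:
        """Downstream main-branch path starting with ``seg`` (largest-radius child
        at each bifurcation), used to place distal pressure-readout points."""
        path = [seg]
        while True:
            kids = self._children[path[-1].child]
            if not kids:
                return path
            path.append(max(kids, key=lambda s: s.radius_prox))

    def bifurcations(self) -> list[tuple[Segment, list[Segment]]]:
        out = []
        for nid, kids in self._children.items():
            if len(kids) >= 2 and nid in self._parent_seg:
                out.append((self._parent_seg[nid], kids))
        return out

    def murray_residuals(self) -> np.ndarray:
        """Relative Murray's-law residual |r_p^3 - sum r_c^3| / r_p^3 per bifurcation."""
        res = []
        for parent_seg, kids in self.bifurcations():
            rp3 = parent_seg.radius_dist ** 3
            rc3 = sum(k.radius_prox ** 3 for k in kids)
            res.append(abs(rp3 - rc3) / rp3)
        return np.asarray(res)

    def outlet_positions(self) -> tuple[list[int], np.ndarray]:
        """Outlet node ids (sorted) and their positions as an (n, 3) array."""
        ids = sorted(self.outlets)
        pos = np.array([self.nodes[i].position for i in ids], dtype=float)
        return ids, pos

    # -- JSON round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "inlet": self.inlet,
            "nodes": [
                {"id": n.id, "position": n.position.tolist(), "radius": n.radius}
                for n in sorted(self.nodes.values(), key=lambda n: n.id)
            ],
            "segments": [
                {
                    "id": s.id, "parent": s.parent, "child": s.child,
                    "length": s.length,
                    "radius_prox": s.radius_prox, "radius_dist": s.radius_dist,
                }
                for s in self.segments
            ],
            "stenoses": [
                {
                    "id": s.id, "segment": s.segment, "center": s.center,
                    "length": s.length, "severity": s.severity,
                }
                for s in self.stenoses
            ],
            "outlets": {str(k): v for k, v in self.outlets.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CoronaryTree":
        if d.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(f"unsupported tree schema version {d.get('schema_version')}")
        nodes = {n["id"]: Node(n["id"], np.array(n["position"]), n["radius"])
                 for n in d["nodes"]}
        segments = [Segment(**s) for s in d["segments"]]
        stenoses = [Stenosis(**s) for s in d["stenoses"]]
        outlets = {int(k): v for k, v in d["outlets"].items()}
        return cls(nodes, segments, stenoses, outlets, d["inlet"])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "CoronaryTree":
        return cls.from_dict(json.loads(Path(path).read_text()))
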