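"""Spatial graph of capillary centrelines and polyline utilities.

All coordinates are world coordinates in micrometres, ordered ``(x, y, z)``.
A :class:`CapillaryGraph` is the object every capillary metric is computed
from: nodes are junctions or free ends, edges carry an ordered polyline whose
first/last points coincide with the incident node coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError

__all__ = [
    "Edge",
    "CapillaryGraph",
    "polyline_length",
    "resample_polyline",
    "turning_angles",
    "segment_directions_lengths",
]


def polyline_length(points: np.ndarray) -> float:
    """Euclidean arc length of a polyline given as an (N, 3) array (µm)."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or len(points) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def resample_polyline(points: np.ndarray, step: float = 5.0) -> np.ndarray:
    """Resample a polyline by arc length into segments of ``step`` µm.

    Interior vertices are placed at multiples of ``step`` along the original
    curve; both endpoints are preserved, so the final segment may be shorter
    than ``step``. Chord lengths can only shrink, hence the resampled length
    never exceeds the original.

    Raises
    ------
    DegenerateGeometryError
        If the polyline has fewer than two points or zero total length.
    """
    points = np.asarray(points, dtype=float)
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    if points.ndim != 2 or len(points) < 2:
        raise DegenerateGeometryError("polyline needs at least two points")
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    total = float(seg.sum())
    if total == 0.0:
        raise DegenerateGeometryError("polyline has zero length (all points identical)")
    s = np.concatenate([[0.0], np.cumsum(seg)])
    # interior arc-length stations strictly between 0 and total
    n_interior = int(np.ceil(total / step)) - 1
    stations = np.concatenate([[0.0], (np.arange(1, n_interior + 1)) * step, [total]])
    stations = stations[stations <= total]
    if stations[-1] != total:
        stations = np.concatenate([stations, [total]])
    out = np.empty((len(stations), 3))
    for k in range(3):
        out[:, k] = np.interp(stations, s, points[:, k])
    out[0] = points[0]
    out[-1] = points[-1]
    return out


def turning_angles(points: np.ndarray) -> np.ndarray:
    """Exterior (turning) angles at the interior vertices of a polyline.

    The exterior angle at a vertex is the angle between the incoming and
    outgoing segment directions: 0 for collinear continuation, π for a full
    reversal. Zero-length segments contribute no angle.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 3:
        return np.zeros(0)
    d = np.diff(points, axis=0)
    norms = np.linalg.norm(d, axis=1)
    keep = norms > 0
    d = d[keep] / norms[keep][:, None]
    if len(d) < 2:
        return np.zeros(0)
    cosang = np.clip(np.einsum("ij,ij->i", d[:-1], d[1:]), -1.0, 1.0)
    return np.arccos(cosang)


def segment_directions_lengths(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit directions and lengths of the segments of a polyline."""
    d = np.diff(np.asarray(points, dtype=float), axis=0)
    lengths = np.linalg.norm(d, axis=1)
    keep = lengths > 0
    return d[keep] / lengths[keep][:, None], lengths[keep]


@dataclass
class Edge:
    """One capillary branch: an ordered polyline between two graph nodes."""

    u: int
    v: int
    points: np.ndarray  # (N, 3) world µm; points[0] at node u, points[-1] at node v

    @property
    def length(self) -> float:
        return polyline_length(self.points)


@dataclass
class CapillaryGraph:
    """Vectorised capillary network in world micrometres.

    Self-loops and parallel edges are allowed (anastomoses). Node coordinates
    and edge polyline endpoints must coincide; :meth:`validate` checks this.
    """

    nodes: dict[int, np.ndarray] = field(default_factory=dict)
    edges: list[Edge] = field(default_factory=list)

    def add_node(self, point) -> int:
        nid = (max(self.nodes) + 1) if self.nodes else 0
        self.nodes[nid] = np.asarray(point, dtype=float)
        return nid

    def add_edge(self, u: int, v: int, points) -> Edge:
        pts = np.asarray(points, dtype=float)
        e = Edge(u, v, pts)
        if e.length == 0.0:
            raise DegenerateGeometryError("zero-length edge")
        self.edges.append(e)
        return e

    def degrees(self) -> dict[int, int]:
        deg = {nid: 0 for nid in self.nodes}
        for e in self.edges:
            deg[e.u] += 1
            deg[e.v] += 1
        return deg

    def branch_point_count(self) -> int:
        return sum(1 for d in self.degrees().values() if d >= 3)

    def copy(self) -> "CapillaryGraph":
        return CapillaryGraph(
            nodes={k: v.copy() for k, v in self.nodes.items()},
            edges=[Edge(e.u, e.v, e.points.copy()) for e in self.edges],
        )

    def transform(self, func) -> "CapillaryGraph":
        """Return a copy with ``func`` applied to every (N, 3) coordinate array."""
        g = CapillaryGraph()
        g.nodes = {k: np.asarray(func(v[None, :]), dtype=float)[0] for k, v in self.nodes.items()}
        g.edges = [Edge(e.u, e.v, np.asarray(func(e.points), dtype=float)) for e in self.edges]
        return g

    def scale_z(self, factor: float) -> "CapillaryGraph":
        """Multiply all z world-coordinates by ``factor`` (axial calibration)."""
        if factor <= 0:
            raise ValueError(f"z scale factor must be positive, got {factor}")

        def f(p):
            q = np.array(p, dtype=float)
            q[:, 2] *= factor
            return q

        return self.transform(f)

    def resampled(self, step: float = 5.0) -> "CapillaryGraph":
        """Copy with every edge polyline arc-length resampled at ``step`` µm."""
        g = CapillaryGraph(nodes={k: v.copy() for k, v in self.nodes.items()})
        for e in self.edges:
            g.edges.append(Edge(e.u, e.v, resample_polyline(e.points, step)))
        return g

    def validate(self, atol: float = 1e-6) -> None:
        for e in self.edges:
            if e.u not in self.nodes or e.v not in self.nodes:
                raise ValueError(f"edge ({e.u}, {e.v}) references missing node")
            if not np.allclose(e.points[0], self.nodes[e.u], atol=atol) or not np.allclose(
                e.points[-1], self.nodes[e.v], atol=atol
            ):
                raise ValueError(f"edge ({e.u}, {e.v}) polyline does not end at its nodes")
            if e.length == 0.0:
                raise ValueError(f"edge ({e.u}, {e.v}) has zero length")

    # ------------------------------------------------------------------ I/O
    def to_dict(self) -> dict:
        return {
            "nodes": {str(k): list(map(float, v)) for k, v in self.nodes.items()},
            "edges": [
                {"u": e.u, "v": e.v, "points": np.asarray(e.points, float).tolist()}
                for e in self.edges
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CapillaryGraph":
        g = cls()
        g.nodes = {int(k): np.asarray(v, dtype=float) for k, v in d["nodes"].items()}
        g.edges = [Edge(int(e["u"]), int(e["v"]), np.asarray(e["points"], dtype=float)) for e in d["edges"]]
        return g

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_json(cls, path) -> "CapillaryGraph":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_swc(self, path, radius: float = 2.5) -> None:
        """Write an SWC-like text file (id, type, x, y, z, radius, parent).

        Polylines are emitted as chains; junction nodes are written once and
        referenced as parents where possible. Intended for visualisation only.
        """
        lines = []
        counter = 1
        node_swc: dict[int, int] = {}
        for e in self.edges:
            pts = np.asarray(e.points, float)
            prev = node_swc.get(e.u, -1)
            if prev == -1:
                lines.append(f"{counter} 0 {pts[0,0]:.3f} {pts[0,1]:.3f} {pts[0,2]:.3f} {radius:.3f} -1")
                node_swc[e.u] = counter
                prev = counter
                counter += 1
            for p in pts[1:-1]:
                lines.append(f"{counter} 0 {p[0]:.3f} {p[1]:.3f} {p[2]:.3f} {radius:.3f} {prev}")
                prev = counter
                counter += 1
            if e.v in node_swc:
                # close into existing node: emit a duplicate point referencing it
                lines.append(
                    f"{counter} 0 {pts[-1,0]:.3f} {pts[-1,1]:.3f} {pts[-1,2]:.3f} {radius:.3f} {prev}"
                )
                counter += 1
            else:
                lines.append(
                    f"{counter} 0 {pts[-1,0]:.3f} {pts[-1,1]:.3f} {pts[-1,2]:.3f} {radius:.3f} {prev}"
                )
                node_swc[e.v] = counter
                counter += 1
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
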