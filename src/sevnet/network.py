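"""Domain model for spatial road networks.

A network is a planar multigraph whose edges ("links") carry polyline
geometry.  A link runs between two adjacent junctions, or between a
junction and a dead end; nodes are the shared endpoints.  Links are the
unit of analysis throughout the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping

import numpy as np
from scipy.spatial import cKDTree

from . import geometry as geo

__all__ = ["Polyline", "Link", "Node", "SpatialNetwork", "ArealUnit", "build_network"]

#: default endpoint snap tolerance, meters (road-data vertex jitter scale)
DEFAULT_SNAP_TOLERANCE_M = 0.5


@dataclass(frozen=True)
class Polyline:
    """Ordered 2-D vertices in projected meters; consecutive vertices distinct."""

    points: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "points", geo.as_points(self.points))

    @property
    def length(self) -> float:
        return geo.arc_length(self.points)

    def point_at(self, s: float) -> np.ndarray:
        return geo.point_at_arc(self.points, s)


@dataclass(frozen=True)
class Link:
    """One network link with geometry and precomputed traversal costs.

    ``internal_angular_cost_deg`` is the total deflection at interior
    vertices — the degrees turned when driving the link end to end.
    ``weight`` is the analysis weight (1 per link by default: aggregation
    and betweenness count links, not meters).
    """

    id: Hashable
    geometry: Polyline
    node_a: int
    node_b: int
    length_m: float
    internal_angular_cost_deg: float
    weight: float = 1.0

    @property
    def is_loop(self) -> bool:
        return self.node_a == self.node_b


@dataclass(frozen=True)
class Node:
    id: int
    coordinate: np.ndarray
    incident_ends: tuple  # of (link id, end) with end in {"a", "b"}

    @property
    def degree(self) -> int:
        return len(self.incident_ends)


@dataclass
class SpatialNetwork:
    """Planar multigraph of polyline links meeting at shared-endpoint nodes."""

    links: dict
    nodes: dict
    snap_tolerance_m: float = DEFAULT_SNAP_TOLERANCE_M

    # -- basic accessors -------------------------------------------------
    @property
    def n_links(self) -> int:
        return len(self.links)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def link_ids(self) -> list:
        return sorted(self.links, key=str)

    def degree(self, node_id: int) -> int:
        return self.nodes[node_id].degree

    def junction_nodes(self) -> list[int]:
        """Nodes of degree >= 3 (dead ends and degree-2 vertices excluded)."""
        return [n for n, node in self.nodes.items() if node.degree >= 3]

    def total_length(self) -> float:
        return float(sum(l.length_m for l in self.links.values()))

    def bounds(self) -> tuple[float, float, float, float]:
        pts = np.vstack([l.geometry.points for l in self.links.values()])
        return (
            float(pts[:, 0].min()),
            float(pts[:, 1].min()),
            float(pts[:, 0].max()),
            float(pts[:, 1].max()),
        )

    def to_networkx(self):
        """Node-level MultiGraph with length-weighted edges (for inspection)."""
        import networkx as nx

        g = nx.MultiGraph()
        for nid, node in self.nodes.items():
            g.add_node(nid, coordinate=tuple(node.coordinate))
        for lid, link in self.links.items():
            g.add_edge(link.node_a, link.node_b, key=lid, length=link.length_m)
        return g

    def connected_components(self) -> list[set]:
        import networkx as nx

        return [set(c) for c in nx.connected_components(self.to_networkx())]

    def validate(self) -> None:
        """Check graph-consistency invariants; raise AssertionError on failure."""
        end_count = 0
        for node in self.nodes.values():
            for lid, end in node.incident_ends:
                link = self.links[lid]
                nid = link.node_a if end == "a" else link.node_b
                assert nid == node.id, f"incident end mismatch at node {node.id}"
                pt = link.geometry.points[0 if end == "a" else -1]
                assert (
                    np.linalg.norm(pt - node.coordinate) <= self.snap_tolerance_m + 1e-9
                ), f"endpoint of link {lid} off node {node.id}"
            end_count += node.degree
        assert end_count == 2 * self.n_links, "sum of degrees != 2 x links"


@dataclass
class ArealUnit:
    """One areal unit (e.g. an enumeration district) with its outcomes."""

    id: Hashable
    polygon: object  # shapely (Multi)Polygon
    attributes: dict = field(default_factory=dict)

    @property
    def cohesion(self):
        return self.attributes.get("cohesion")

    @property
    def deprivation(self):
        return self.attributes.get("deprivation")

    @property
    def urban(self):
        return self.attributes.get("urban")


def _snap_clusters(coords: np.ndarray, tol: float) -> np.ndarray:
    """Union-find over endpoint pairs within ``tol``; returns cluster labels."""
    n = len(coords)
    parent = np.arange(n)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    if tol > 0 and n > 1:
        tree = cKDTree(coords)
        for i, j in tree.query_pairs(tol):
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)
    return np.array([find(i) for i in range(n)])


def build_network(
    line_features: Iterable[tuple[Hashable, object]] | Mapping[Hashable, object],
    snap_tolerance_m: float = DEFAULT_SNAP_TOLERANCE_M,
    weights: Mapping[Hashable, float] | None = None,
) -> SpatialNetwork:
    """Assemble a :class:`SpatialNetwork` from ``(id, coordinates)`` features.

    Endpoints closer than ``snap_tolerance_m`` are merged into a single
    node (the node takes the coordinate of the first endpoint seen, so
    rebuilding an already-snapped network is a no-op).  Link lengths and
    internal angular costs are precomputed here.

    Raises
    ------
    ValueError
        For zero-length features (reported by id) or duplicate ids.
    """
    if isinstance(line_features, Mapping):
        items = list(line_features.items())
    else:
        items = list(line_features)
    ids = [fid for fid, _ in items]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate link ids in input features")

    polylines: dict[Hashable, Polyline] = {}
    for fid, coords in items:
        try:
            polylines[fid] = Polyline(coords)
        except ValueError as exc:
            raise ValueError(f"feature {fid!r}: {exc}") from exc

    all_pts = np.vstack([p.points for p in polylines.values()])
    if np.all(np.abs(all_pts) <= 180.0):
        warnings.warn(
            "all coordinates lie within +/-180: these look geographic "
            "(lon/lat); a projected metric CRS is required",
            stacklevel=2,
        )

    order = sorted(polylines, key=str)
    endpoints = np.array(
        [pt for fid in order for pt in (polylines[fid].points[0], polylines[fid].points[-1])]
    )
    labels = _snap_clusters(endpoints, snap_tolerance_m)

    node_of_label: dict[int, int] = {}
    node_coord: dict[int, np.ndarray] = {}
    node_ends: dict[int, list] = {}
    links: dict[Hashable, Link] = {}
    for k, fid in enumerate(order):
        pl = polylines[fid]
        ends = []
        for which, row in (("a", 2 * k), ("b", 2 * k + 1)):
            lab = labels[row]
            if lab not in node_of_label:
                nid = len(node_of_label)
                node_of_label[lab] = nid
                node_coord[nid] = endpoints[lab]  # first endpoint of the cluster
                node_ends[nid] = []
            nid = node_of_label[lab]
            node_ends[nid].append((fid, which))
            ends.append(nid)
        links[fid] = Link(
            id=fid,
            geometry=pl,
            node_a=ends[0],
            node_b=ends[1],
            length_m=pl.length,
            internal_angular_cost_deg=geo.internal_angular_cost(pl.points),
            weight=1.0 if weights is None else float(weights.get(fid, 1.0)),
        )
        if ends[0] == ends[1]:
            warnings.warn(f"link {fid!r} is a loop (both ends on one node)", stacklevel=2)

    nodes = {
        nid: Node(id=nid, coordinate=node_coord[nid], incident_ends=tuple(node_ends[nid]))
        for nid in node_coord
    }
    net = SpatialNetwork(links=links, nodes=nodes, snap_tolerance_m=snap_tolerance_m)
    net.validate()
    return net
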