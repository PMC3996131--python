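"""Radius-limited link metrics on spatial networks.

For each origin link, the surrounding network within a *network radius*
``r`` (meters along the network, measured from the origin link's center)
is delimited, and 16 descriptive statistics are computed on it.  Route
statistics use *angular* geodesics — paths minimizing the cumulative
degrees turned at polyline vertices and at junctions — while the radius
itself is Euclidean (meters along the network).

In *continuous space* mode, links crossing the radius boundary contribute
the exact portion that falls inside, weighted by the included fraction;
in discrete mode a link is either wholly in or out.

Metric columns (sDNA-style abbreviations):

=======  ===========================================================
Links    link count in radius (sum of included weight fractions)
Length   network length in radius, m
NQPDA    link count penalized by angular distance to each
TPDA     destination popularity under the two-phase trip model
MGLA     mean along-network length of angular geodesics, m
MCF      mean crow-flight length of angular geodesics, m
MAD      mean angular length of geodesics, degrees
DivA     mean diversion ratio (network length / crow flight) per route
BtA      angular betweenness (flow prediction, radius-limited)
TPBtA    two-phase angular betweenness (fixed trips per origin)
Jnc      junction count in radius (nodes of degree >= 3)
Con      connectivity: link ends joining in-radius junctions
HullA    area of convex hull of reached points, m^2
HullP    perimeter of convex hull, m
HullR    max crow-flight distance from origin point to a reached point, m
HullSI   hull shape index, perimeter / perimeter of equal-area circle
=======  ===========================================================
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint

from . import geometry as geo
from .network import Link, SpatialNetwork

__all__ = [
    "DEFAULT_RADII",
    "METRIC_NAMES",
    "METRIC_HYPOTHESES",
    "PartialLink",
    "RadialSubsystem",
    "Geodesic",
    "origin_point",
    "reachable_subsystem",
    "angular_geodesics",
    "angular_geodesic",
    "hull_stats",
    "link_metrics",
    "betweenness_family",
    "compute_link_metrics",
    "hullr_profile",
    "metric_column",
]

#: walking-scale analysis radii, meters
DEFAULT_RADII = (300, 600, 900, 1200, 1500)

METRIC_NAMES = (
    "Links", "Length", "NQPDA", "TPDA", "MGLA", "MCF", "MAD", "DivA",
    "BtA", "TPBtA", "Jnc", "Con", "HullA", "HullP", "HullR", "HullSI",
)

#: hypothesis-family tags carried as metadata: D density, DD density
#: distribution, T twistiness, F flow, L literature (junction density),
#: E efficiency, H homogeneity
METRIC_HYPOTHESES = {
    "Links": ("D",), "Length": ("D",), "NQPDA": ("D", "DD", "T"),
    "TPDA": ("D",), "MGLA": ("DD", "T"), "MCF": ("DD",), "MAD": ("DD", "T"),
    "DivA": ("T",), "BtA": ("F",), "TPBtA": ("F",), "Jnc": ("L",),
    "Con": ("L",), "HullA": ("E",), "HullP": ("E",), "HullR": ("E",),
    "HullSI": ("E", "H"),
}

#: floor (degrees) for the angular-distance denominator in NQPDA
DEFAULT_DELTA_DEG = 1.0

#: hulls below this area (a micron-scale sliver) are treated as collinear
DEGENERATE_HULL_AREA_M2 = 1e-6

_FRAC_EPS = 1e-9


def metric_column(metric: str, radius_m: float, continuous: bool = True) -> str:
    """Column name for an aggregated metric, e.g. ``HullR600c``."""
    return f"{metric}{int(round(radius_m))}{'c' if continuous else ''}"


# ---------------------------------------------------------------------------
# subsystem delimitation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PartialLink:
    """The portion ``[a, b]`` (arc-length fractions) of one link that is
    inside the radius; ``P`` is the included weight fraction."""

    link_id: Hashable
    a: float
    b: float
    P: float

    @property
    def full(self) -> bool:
        return self.a <= _FRAC_EPS and self.b >= 1.0 - _FRAC_EPS


@dataclass
class RadialSubsystem:
    origin_link: Hashable
    origin_s: float            # arc position of the analysis center, m
    origin_xy: np.ndarray
    radius_m: float
    continuous: bool
    members: list              # of PartialLink, deterministic order
    node_dist: dict            # node id -> network distance from origin point
    end_dist: dict             # link id -> (dist to end a, dist to end b)

    def member_map(self) -> dict:
        out: dict = {}
        for m in self.members:
            out.setdefault(m.link_id, []).append(m)
        return out


def origin_point(link: Link, mode: str = "euclidean") -> float:
    """Arc position (meters) of the link's analysis center.

    ``euclidean``: half the arc length.  ``angular``: the first arc
    position where the cumulative internal deflection reaches half the
    link's total (falling back to the Euclidean center on straight links).
    """
    if mode == "euclidean":
        return link.length_m / 2.0
    if mode == "angular":
        return geo.angular_center_arc(link.geometry.points)
    raise ValueError(f"unknown origin mode {mode!r}")


def _adjacency(net: SpatialNetwork) -> dict:
    """node -> [(neighbor node, length, link id)], cached on the network."""
    cache = getattr(net, "_sevnet_adjacency", None)
    if cache is not None:
        return cache
    adj: dict = {n: [] for n in net.nodes}
    for lid in net.link_ids():
        link = net.links[lid]
        adj[link.node_a].append((link.node_b, link.length_m, lid))
        if not link.is_loop:
            adj[link.node_b].append((link.node_a, link.length_m, lid))
    net._sevnet_adjacency = adj
    return adj


def _distance_field(
    net: SpatialNetwork, origin_link: Hashable, s0: float, r_max: float
) -> dict:
    """Dijkstra (Euclidean length) from the origin point, truncated at r_max."""
    link = net.links[origin_link]
    adj = _adjacency(net)
    dist: dict = {}
    heap = []
    counter = 0
    for nid, d0 in ((link.node_a, s0), (link.node_b, link.length_m - s0)):
        if d0 <= r_max:
            heapq.heappush(heap, (d0, counter, nid))
            counter += 1
    while heap:
        d, _, n = heapq.heappop(heap)
        if n in dist:
            continue
        dist[n] = d
        for m, w, _lid in adj[n]:
            nd = d + w
            if nd <= r_max and m not in dist:
                heapq.heappush(heap, (nd, counter, m))
                counter += 1
    return dist


def _merge_intervals(ivals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    ivals = sorted((lo, hi) for lo, hi in ivals if hi - lo > -_FRAC_EPS)
    out: list[tuple[float, float]] = []
    for lo, hi in ivals:
        if out and lo <= out[-1][1] + _FRAC_EPS:
            out[-1] = (out[-1][0], max(out[-1][1], hi))
        else:
            out.append((lo, hi))
    return out


def _included_intervals(
    length: float, dA: float, dB: float, r: float, s0: float | None = None
) -> list[tuple[float, float]]:
    """Arc intervals of one link within network distance ``r`` of the origin.

    Distance at arc position s is min(dA + s, dB + L - s), plus |s - s0|
    on the origin link itself.
    """
    ivals = []
    if r >= dA:
        ivals.append((0.0, min(length, r - dA)))
    if r >= dB:
        ivals.append((max(0.0, length - (r - dB)), length))
    if s0 is not None:
        ivals.append((max(0.0, s0 - r), min(length, s0 + r)))
    return _merge_intervals(ivals)


def reachable_subsystem(
    net: SpatialNetwork,
    origin_link: Hashable,
    r: float,
    continuous: bool = True,
    origin_mode: str = "euclidean",
    node_dist: dict | None = None,
) -> RadialSubsystem:
    """Delimit the network reachable within Euclidean network distance ``r``.

    Continuous mode includes the exact sub-intervals of boundary-crossing
    links (``P`` = included fraction x weight); discrete mode includes a
    link only when its entire geometry lies within ``r``.  The origin link
    is always a member.
    """
    if r < 0:
        raise ValueError("radius must be nonnegative")
    olink = net.links[origin_link]
    s0 = origin_point(olink, origin_mode)
    if node_dist is None:
        node_dist = _distance_field(net, origin_link, s0, r)
    origin_xy = olink.geometry.point_at(s0)

    members: list[PartialLink] = []
    end_dist: dict = {}
    inf = math.inf
    for lid in net.link_ids():
        link = net.links[lid]
        dA = node_dist.get(link.node_a, inf)
        dB = node_dist.get(link.node_b, inf)
        is_origin = lid == origin_link
        if not is_origin and min(dA, dB) > r:
            continue
        end_dist[lid] = (dA, dB)
        L = link.length_m
        ivals = _included_intervals(L, dA, dB, r, s0 if is_origin else None)
        if continuous:
            for lo, hi in ivals:
                members.append(
                    PartialLink(lid, lo / L, hi / L, (hi - lo) / L * link.weight)
                )
            if is_origin and not ivals:  # r == 0 degenerate
                members.append(PartialLink(lid, s0 / L, s0 / L, 0.0))
        else:
            covered = (
                len(ivals) == 1
                and ivals[0][0] <= _FRAC_EPS
                and ivals[0][1] >= L - _FRAC_EPS
            )
            if covered or is_origin:
                members.append(PartialLink(lid, 0.0, 1.0, link.weight))
    return RadialSubsystem(
        origin_link=origin_link,
        origin_s=s0,
        origin_xy=origin_xy,
        radius_m=float(r),
        continuous=continuous,
        members=members,
        node_dist=node_dist,
        end_dist=end_dist,
    )


# ---------------------------------------------------------------------------
# angular geodesics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Geodesic:
    dest: PartialLink
    angular_cost_deg: float
    network_length_m: float
    crow_flight_m: float
    path: tuple  # link ids from origin to destination inclusive


def _dir_arriving(link: Link, end: str) -> np.ndarray:
    """Travel direction when arriving at the given end of a link."""
    pts = link.geometry.points
    if end == "b":
        return geo.segment_direction(pts, len(pts) - 2)
    return -geo.segment_direction(pts, 0)


def _dir_departing(link: Link, end: str) -> np.ndarray:
    """Travel direction when departing a link from the given end."""
    pts = link.geometry.points
    if end == "a":
        return geo.segment_direction(pts, 0)
    return -geo.segment_direction(pts, len(pts) - 2)


def _rep_point(link: Link, part: PartialLink) -> tuple[float, np.ndarray]:
    """Representative point of a member: midpoint of its included interval."""
    s = (part.a + part.b) / 2.0 * link.length_m
    return s, link.geometry.point_at(s)


def _link_order(net: SpatialNetwork) -> tuple[list, dict]:
    """Links in lexicographic id order plus the id -> rank map (cached)."""
    cache = getattr(net, "_sevnet_link_order", None)
    if cache is not None:
        return cache
    ids = net.link_ids()
    cache = (ids, {lid: i for i, lid in enumerate(ids)})
    net._sevnet_link_order = cache
    return cache


def angular_geodesics(
    net: SpatialNetwork, sub: RadialSubsystem
) -> dict[int, Geodesic]:
    """Minimum-angular-cost routes from the origin point to every member.

    Routes are confined to the subsystem: only fully included links are
    traversable, and a partial destination is entered from the end its
    included interval is anchored to.  Ties in angular cost are broken by
    smaller network length, then by lexicographically smallest link-id
    path, so outputs are deterministic.  Members without a route (possible
    in discrete mode) are absent from the result.

    Returns a dict mapping member index (position in ``sub.members``) to
    its :class:`Geodesic`; the origin link maps to the trivial geodesic.
    """
    olink = net.links[sub.origin_link]
    s0 = sub.origin_s
    opts = olink.geometry.points
    member_by_link = sub.member_map()
    ids, rank = _link_order(net)

    # traversable links: fully included members
    traversable = {
        lid for lid, parts in member_by_link.items() if any(p.full for p in parts)
    }

    # Dijkstra over states (link id, arrival end); cost = (degrees, meters,
    # path ranks) compared lexicographically
    best: dict = {}
    heap: list = []
    origin_parts = member_by_link.get(sub.origin_link, [])
    opart = next(
        (
            p
            for p in origin_parts
            if p.a * olink.length_m - _FRAC_EPS <= s0 <= p.b * olink.length_m + _FRAC_EPS
        ),
        origin_parts[0] if origin_parts else None,
    )
    if opart is not None:
        for end, s_end, frac_ok in (
            ("a", 0.0, opart.a <= _FRAC_EPS),
            ("b", olink.length_m, opart.b >= 1.0 - _FRAC_EPS),
        ):
            if not frac_ok:
                continue
            theta = geo.angular_cost_between(opts, s0, s_end)
            heapq.heappush(
                heap,
                (theta, abs(s_end - s0), (rank[sub.origin_link],), (sub.origin_link, end)),
            )

    settled_at_node: dict = {}  # node id -> list of settled states
    while heap:
        theta, length, path, state = heapq.heappop(heap)
        if state in best:
            continue
        best[state] = (theta, length, path)
        lid, end = state
        link = net.links[lid]
        node = link.node_a if end == "a" else link.node_b
        settled_at_node.setdefault(node, []).append(state)
        v_in = _dir_arriving(link, end)
        for nlid, nend in net.nodes[node].incident_ends:
            if nlid not in traversable:
                continue
            nlink = net.links[nlid]
            other = "b" if nend == "a" else "a"
            nstate = (nlid, other)
            if nstate in best:
                continue
            turn = geo.turn_angle_deg(v_in, _dir_departing(nlink, nend))
            heapq.heappush(
                heap,
                (
                    theta + turn + nlink.internal_angular_cost_deg,
                    length + nlink.length_m,
                    path + (rank[nlid],),
                    nstate,
                ),
            )

    geos: dict[int, Geodesic] = {}
    for idx, part in enumerate(sub.members):
        if part.link_id == sub.origin_link:
            if part is opart:
                geos[idx] = Geodesic(part, 0.0, 0.0, 0.0, (sub.origin_link,))
            continue
        link = net.links[part.link_id]
        rep_s, rep_xy = _rep_point(link, part)
        entries = []
        if part.a <= _FRAC_EPS:
            entries.append(("a", link.node_a, 0.0))
        if part.b >= 1.0 - _FRAC_EPS:
            entries.append(("b", link.node_b, link.length_m))
        cands = []
        for entry_end, node, s_entry in entries:
            for state in settled_at_node.get(node, []):
                base_theta, base_len, base_path = best[state]
                turn = geo.turn_angle_deg(
                    _dir_arriving(net.links[state[0]], state[1]),
                    _dir_departing(link, entry_end),
                )
                theta = base_theta + turn + geo.angular_cost_between(
                    link.geometry.points, s_entry, rep_s
                )
                length = base_len + abs(rep_s - s_entry)
                cands.append((theta, length, base_path + (rank[part.link_id],)))
        if not cands:
            continue
        theta, length, path = min(cands)
        crow = float(np.linalg.norm(rep_xy - sub.origin_xy))
        geos[idx] = Geodesic(
            part, theta, length, crow, tuple(ids[i] for i in path)
        )
    return geos


def angular_geodesic(
    net: SpatialNetwork, sub: RadialSubsystem, dest: PartialLink
) -> Geodesic | None:
    """Geodesic to one member (None when unreachable inside the subsystem)."""
    idx = sub.members.index(dest)
    return angular_geodesics(net, sub).get(idx)


# ---------------------------------------------------------------------------
# hull statistics
# ---------------------------------------------------------------------------

def _interval_coords(pts: np.ndarray, arcs: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Vertices of the sub-polyline between arc positions lo..hi, with the
    interpolated cut points at both ends."""
    head = geo.point_at_arc(pts, lo)
    tail = geo.point_at_arc(pts, hi)
    inner = pts[(arcs > lo + geo.EPS_M) & (arcs < hi - geo.EPS_M)]
    return np.vstack([[head], inner, [tail]])


def reached_points(net: SpatialNetwork, sub: RadialSubsystem) -> np.ndarray:
    """All polyline vertices of included portions plus boundary cut points."""
    coords = [sub.origin_xy[None, :]]
    for part in sub.members:
        link = net.links[part.link_id]
        pts = link.geometry.points
        arcs = geo.cumulative_arcs(pts)
        L = link.length_m
        coords.append(_interval_coords(pts, arcs, part.a * L, part.b * L))
    return np.vstack(coords)


def hull_stats(net: SpatialNetwork, sub: RadialSubsystem) -> dict:
    """Convex-hull statistics of the reached points.

    HullR is the maximum crow-flight distance from the origin point to any
    reached point (never exceeding the network radius).  Degenerate
    collinear hulls have zero area, perimeter equal to twice the extent,
    and an undefined (NaN) shape index.
    """
    pts = reached_points(net, sub)
    hull_r = float(np.linalg.norm(pts - sub.origin_xy, axis=1).max())
    hull = MultiPoint(pts).convex_hull
    if hull.geom_type == "Polygon":
        area = float(hull.area)
        perim = float(hull.exterior.length)
        boundary = np.asarray(hull.exterior.coords)
    elif hull.geom_type == "LineString":
        area, perim = 0.0, 0.0
        boundary = np.asarray(hull.coords)
    else:  # single point
        return {"HullA": 0.0, "HullP": 0.0, "HullR": hull_r, "HullSI": float("nan")}
    if area < DEGENERATE_HULL_AREA_M2:
        # collinear within floating point: zero area, perimeter is twice
        # the extent (out and back along the line)
        diffs = boundary[:, None, :] - boundary[None, :, :]
        extent = float(np.sqrt((diffs**2).sum(-1)).max())
        return {"HullA": 0.0, "HullP": 2.0 * extent, "HullR": hull_r,
                "HullSI": float("nan")}
    si = perim / (2.0 * math.sqrt(math.pi * area))
    return {"HullA": area, "HullP": perim, "HullR": hull_r, "HullSI": si}


# ---------------------------------------------------------------------------
# per-link metrics and the betweenness family
# ---------------------------------------------------------------------------

def _sigma_weights(path: Sequence, origin, dest) -> dict:
    """Geodesic-membership weight of each link on a path.

    Endpoint convention: 1 for strictly intermediate links, 1/2 for the
    origin and destination links of a proper pair, 1/3 for the single link
    of a self pair.  Kept in one place so alternatives stay testable.
    """
    if origin == dest:
        return {origin: 1.0 / 3.0}
    out: dict = {}
    for lid in set(path):
        out[lid] = 0.5 if lid in (origin, dest) else 1.0
    return out


def _row_from_subsystem(
    net: SpatialNetwork,
    sub: RadialSubsystem,
    geos: dict[int, Geodesic],
    delta_deg: float = DEFAULT_DELTA_DEG,
) -> dict:
    """The non-betweenness metrics for one (origin link, radius) pair."""
    nan = float("nan")
    if sub.continuous:
        links = float(sum(p.P for p in sub.members))
    else:
        links = float(len(sub.members))
    length = float(
        sum((p.b - p.a) * net.links[p.link_id].length_m for p in sub.members)
    )

    # destination loop: members other than the origin link, with P > 0
    w_sum = 0.0
    nqpda = 0.0
    sums = {"MGLA": 0.0, "MCF": 0.0, "MAD": 0.0}
    div_sum = 0.0
    div_w = 0.0
    n_dest = 0
    n_dropped = 0
    for idx, part in enumerate(sub.members):
        if part.link_id == sub.origin_link or part.P <= 0.0:
            continue
        n_dest += 1
        g = geos.get(idx)
        if g is None:
            n_dropped += 1
            continue
        w = part.P
        w_sum += w
        nqpda += w / max(g.angular_cost_deg, delta_deg)
        sums["MGLA"] += w * g.network_length_m
        sums["MCF"] += w * g.crow_flight_m
        sums["MAD"] += w * g.angular_cost_deg
        if g.crow_flight_m > geo.EPS_M:
            div_sum += w * (g.network_length_m / g.crow_flight_m)
            div_w += w

    junctions = [
        n for n, d in sub.node_dist.items()
        if d <= sub.radius_m and net.nodes[n].degree >= 3
    ]
    row = {
        "Links": links,
        "Length": length,
        "NQPDA": nqpda,
        "MGLA": sums["MGLA"] / w_sum if w_sum > 0 else nan,
        "MCF": sums["MCF"] / w_sum if w_sum > 0 else nan,
        "MAD": sums["MAD"] / w_sum if w_sum > 0 else nan,
        "DivA": div_sum / div_w if div_w > 0 else nan,
        "Jnc": float(len(junctions)),
        "Con": float(sum(net.nodes[n].degree for n in junctions)),
        "n_destinations": n_dest,
        "n_dropped": n_dropped,
    }
    row.update(hull_stats(net, sub))
    return row


def link_metrics(
    net: SpatialNetwork,
    origin_link: Hashable,
    r: float,
    continuous: bool = True,
    origin_mode: str = "euclidean",
    delta_deg: float = DEFAULT_DELTA_DEG,
) -> dict:
    """All non-betweenness metrics for one (link, radius) pair.

    BtA/TPBtA/TPDA need contributions from every origin and are produced
    by :func:`betweenness_family` or :func:`compute_link_metrics`; here
    they are NaN placeholders.
    """
    sub = reachable_subsystem(net, origin_link, r, continuous, origin_mode)
    geos = angular_geodesics(net, sub)
    row = _row_from_subsystem(net, sub, geos, delta_deg)
    row.update({"link_id": origin_link, "radius_m": float(r)})
    row.setdefault("BtA", float("nan"))
    row.setdefault("TPBtA", float("nan"))
    row.setdefault("TPDA", float("nan"))
    return row


def _accumulate_betweenness(
    net: SpatialNetwork,
    sub: RadialSubsystem,
    geos: dict[int, Geodesic],
    bta: dict,
    tpbta: dict,
    tpda: dict,
) -> None:
    """Add one origin's pairwise ledger into the running betweenness sums."""
    W = net.links[sub.origin_link].weight
    p_total = sum(p.P for p in sub.members)
    if p_total <= 0.0:
        return
    for idx, part in enumerate(sub.members):
        share = W * part.P / p_total
        tpda[part.link_id] = tpda.get(part.link_id, 0.0) + share
        if part.link_id == sub.origin_link:
            # self pair: trivial geodesic on the origin link
            sig = 1.0 / 3.0
            bta[part.link_id] = bta.get(part.link_id, 0.0) + W * part.P * sig
            tpbta[part.link_id] = tpbta.get(part.link_id, 0.0) + share * sig
            continue
        g = geos.get(idx)
        if g is None:
            continue
        for lid, sig in _sigma_weights(g.path, sub.origin_link, part.link_id).items():
            bta[lid] = bta.get(lid, 0.0) + W * part.P * sig
            tpbta[lid] = tpbta.get(lid, 0.0) + share * sig


def betweenness_family(
    net: SpatialNetwork,
    r: float,
    continuous: bool = True,
    origin_mode: str = "euclidean",
) -> pd.DataFrame:
    """BtA, TPBtA and TPDA for every link at one radius."""
    bta: dict = {}
    tpbta: dict = {}
    tpda: dict = {}
    for lid in net.link_ids():
        sub = reachable_subsystem(net, lid, r, continuous, origin_mode)
        geos = angular_geodesics(net, sub)
        _accumulate_betweenness(net, sub, geos, bta, tpbta, tpda)
    ids = net.link_ids()
    return pd.DataFrame(
        {
            "link_id": ids,
            "radius_m": float(r),
            "BtA": [bta.get(i, 0.0) for i in ids],
            "TPBtA": [tpbta.get(i, 0.0) for i in ids],
            "TPDA": [tpda.get(i, 0.0) for i in ids],
        }
    )


def compute_link_metrics(
    net: SpatialNetwork,
    radii: Iterable[float] = DEFAULT_RADII,
    continuous: bool = True,
    origin_mode: str = "euclidean",
    delta_deg: float = DEFAULT_DELTA_DEG,
    progress: bool = False,
) -> pd.DataFrame:
    """The full 16-metric table for every (link, radius) pair.

    One Euclidean distance field is computed per origin and shared across
    radii; per-origin work is independent (embarrassingly parallelizable)
    but runs on one CPU here.
    """
    radii = sorted(float(r) for r in radii)
    if not radii:
        raise ValueError("at least one radius required")
    r_max = radii[-1]
    ids = net.link_ids()
    rows: list[dict] = []
    bt: dict[float, tuple[dict, dict, dict]] = {r: ({}, {}, {}) for r in radii}
    iterator = ids
    if progress:
        from tqdm import tqdm  # pragma: no cover

        iterator = tqdm(ids, desc="origins")  # pragma: no cover
    for lid in iterator:
        olink = net.links[lid]
        s0 = origin_point(olink, origin_mode)
        field_full = _distance_field(net, lid, s0, r_max)
        for r in radii:
            node_dist = {n: d for n, d in field_full.items() if d <= r}
            sub = reachable_subsystem(
                net, lid, r, continuous, origin_mode, node_dist=node_dist
            )
            geos = angular_geodesics(net, sub)
            row = _row_from_subsystem(net, sub, geos, delta_deg)
            row.update({"link_id": lid, "radius_m": r})
            rows.append(row)
            _accumulate_betweenness(net, sub, geos, *bt[r])
    df = pd.DataFrame(rows)
    for r in radii:
        bta, tpbta, tpda = bt[r]
        mask = df["radius_m"] == r
        df.loc[mask, "BtA"] = [bta.get(i, 0.0) for i in df.loc[mask, "link_id"]]
        df.loc[mask, "TPBtA"] = [tpbta.get(i, 0.0) for i in df.loc[mask, "link_id"]]
        df.loc[mask, "TPDA"] = [tpda.get(i, 0.0) for i in df.loc[mask, "link_id"]]
    cols = ["link_id", "radius_m", *METRIC_NAMES, "n_destinations", "n_dropped"]
    return df[cols].sort_values(["radius_m", "link_id"], key=lambda s: s.astype(str) if s.name == "link_id" else s).reset_index(drop=True)


# ---------------------------------------------------------------------------
# fast HullR-only profile (for dense radius sweeps)
# ---------------------------------------------------------------------------

def hullr_profile(
    net: SpatialNetwork,
    radii: Iterable[float],
    continuous: bool = True,
    origin_mode: str = "euclidean",
) -> pd.DataFrame:
    """HullR for every link at many radii, without path analysis.

    HullR needs only the reached points, so it is computed directly from
    per-origin distance fields with vectorized candidate-point scans; the
    result matches :func:`compute_link_metrics` exactly.  Continuous-space
    semantics only.
    """
    if not continuous:
        raise NotImplementedError("fast HullR profile is continuous-space only")
    radii = sorted(float(r) for r in radii)
    r_max = radii[-1]
    ids = net.link_ids()

    # global segment arrays
    seg_link: list[int] = []
    seg_s0: list[float] = []
    seg_p0: list[np.ndarray] = []
    seg_p1: list[np.ndarray] = []
    link_len = np.array([net.links[l].length_m for l in ids])
    node_index = {n: i for i, n in enumerate(sorted(net.nodes))}
    link_na = np.array([node_index[net.links[l].node_a] for l in ids])
    link_nb = np.array([node_index[net.links[l].node_b] for l in ids])
    for li, lid in enumerate(ids):
        pts = net.links[lid].geometry.points
        arcs = geo.cumulative_arcs(pts)
        for k in range(len(pts) - 1):
            seg_link.append(li)
            seg_s0.append(arcs[k])
            seg_p0.append(pts[k])
            seg_p1.append(pts[k + 1])
    seg_link = np.array(seg_link)
    seg_s0 = np.array(seg_s0)
    seg_p0 = np.array(seg_p0)
    seg_p1 = np.array(seg_p1)
    seg_len = np.linalg.norm(seg_p1 - seg_p0, axis=1)
    seg_s1 = seg_s0 + seg_len

    # all-pairs node distances, truncated at r_max (min over parallel edges)
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import dijkstra as cs_dijkstra

    n_nodes = len(node_index)
    pair_w: dict = {}
    for li, lid in enumerate(ids):
        a, b = link_na[li], link_nb[li]
        if a == b:
            continue
        key = (min(a, b), max(a, b))
        w = link_len[li]
        if key not in pair_w or w < pair_w[key]:
            pair_w[key] = w
    if pair_w:
        rows_, cols_ = zip(*pair_w)
        graph = coo_matrix(
            (np.array(list(pair_w.values())), (np.array(rows_), np.array(cols_))),
            shape=(n_nodes, n_nodes),
        ).tocsr()
    else:
        graph = coo_matrix((n_nodes, n_nodes)).tocsr()
    D = cs_dijkstra(graph, directed=False, limit=r_max + 1e-9)

    out = np.full((len(ids), len(radii)), np.nan)
    for oi, lid in enumerate(ids):
        olink = net.links[lid]
        s0 = origin_point(olink, origin_mode)
        oxy = olink.geometry.point_at(s0)
        dn = np.minimum(s0 + D[link_na[oi]], (link_len[oi] - s0) + D[link_nb[oi]])
        dA = dn[link_na][seg_link]
        dB = dn[link_nb][seg_link]
        L = link_len[seg_link]
        own = seg_link == oi

        def net_dist(s):
            d = np.minimum(dA + s, dB + (L - s))
            return np.where(own, np.minimum(d, np.abs(s - s0)), d)

        # candidate arc positions per segment: the segment ends, the
        # boundary cuts from each link end, and (origin link) s0 +/- r
        for ri, r in enumerate(radii):
            cands = [
                seg_s0,
                seg_s1,
                np.clip(r - dA, seg_s0, seg_s1),
                np.clip(L - (r - dB), seg_s0, seg_s1),
                np.clip(np.where(own, s0 - r, seg_s0), seg_s0, seg_s1),
                np.clip(np.where(own, s0 + r, seg_s0), seg_s0, seg_s1),
            ]
            best = 0.0
            for s in cands:
                ok = net_dist(s) <= r + 1e-9
                if not ok.any():
                    continue
                t = np.where(seg_len > 0, (s - seg_s0) / np.where(seg_len > 0, seg_len, 1.0), 0.0)
                xy = seg_p0 + t[:, None] * (seg_p1 - seg_p0)
                d_euc = np.linalg.norm(xy - oxy, axis=1)
                best = max(best, float(d_euc[ok].max()))
            out[oi, ri] = best
    recs = [
        {"link_id": ids[oi], "radius_m": r, "HullR": out[oi, ri]}
        for oi in range(len(ids))
        for ri, r in enumerate(radii)
    ]
    return pd.DataFrame(recs)
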