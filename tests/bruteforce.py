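"""Independent brute-force reference for the radial link metrics.

Node distances are recomputed by exhaustive simple-path enumeration on a
networkx multigraph, angular geodesics by exhaustive (branch-and-bound)
depth-first enumeration of state-simple paths, hulls via scipy's Qhull —
all independent of the engine's Dijkstra/shapely code paths.

The elementary *angle primitives* (turn angle between two directions,
deflection sum along a polyline) are shared with the package on purpose:
they are conventions, not algorithms, and routes that tie mathematically
(turns of one sign between fixed start and end directions sum to the
same total whatever the route) must evaluate to bit-identical costs in
both implementations for the documented tie-breaking to be comparable.
"""

from __future__ import annotations

import math
from itertools import combinations

import networkx as nx
import numpy as np
from scipy.spatial import ConvexHull, QhullError

from sevnet import geometry as geo

DELTA_DEG = 1.0
EPS = 1e-9


# ---------------------------------------------------------------------------
# geometry helpers (angle primitives shared with the package, see above)
# ---------------------------------------------------------------------------

def _cumarc(pts):
    pts = np.asarray(pts, float)
    return np.concatenate([[0.0], np.cumsum(np.hypot(*np.diff(pts, axis=0).T))])


def _interp(pts, s):
    arcs = _cumarc(pts)
    s = min(max(s, 0.0), arcs[-1])
    i = int(np.searchsorted(arcs, s, side="right")) - 1
    i = min(i, len(pts) - 2)
    seg = arcs[i + 1] - arcs[i]
    t = 0.0 if seg == 0 else (s - arcs[i]) / seg
    return np.asarray(pts[i]) + t * (np.asarray(pts[i + 1]) - np.asarray(pts[i]))


def _ang(v1, v2):
    """Absolute angle turned from direction v1 to v2, degrees."""
    return geo.turn_angle_deg(v1, v2)


def _internal_between(pts, s_lo, s_hi):
    """Degrees turned at vertices strictly between two arc positions."""
    return geo.angular_cost_between(np.asarray(pts, float), s_lo, s_hi)


def _dir_arrive(pts, end):
    pts = np.asarray(pts, float)
    if end == "b":
        return geo.segment_direction(pts, len(pts) - 2)
    return -geo.segment_direction(pts, 0)


def _dir_depart(pts, end):
    pts = np.asarray(pts, float)
    if end == "a":
        return geo.segment_direction(pts, 0)
    return -geo.segment_direction(pts, len(pts) - 2)


# ---------------------------------------------------------------------------
# distances by exhaustive path enumeration
# ---------------------------------------------------------------------------

def _multigraph(net):
    g = nx.MultiGraph()
    g.add_nodes_from(net.nodes)
    for lid, link in net.links.items():
        g.add_edge(link.node_a, link.node_b, key=lid,
                   length=_cumarc(link.geometry.points)[-1])
    return g


def _min_node_dist(g, u, v):
    """Min total length over all simple edge paths (exhaustive)."""
    if u == v:
        return 0.0
    best = math.inf
    for path in nx.all_simple_edge_paths(g, u, v):
        w = sum(g.edges[e]["length"] for e in path)
        best = min(best, w)
    return best


def ref_subsystem(net, origin, r, continuous=True, origin_mode="euclidean"):
    """Members [(lid, lo_m, hi_m, P)], node distances, origin point."""
    g = _multigraph(net)
    olink = net.links[origin]
    opts = olink.geometry.points
    L0 = _cumarc(opts)[-1]
    if origin_mode == "euclidean":
        s0 = L0 / 2.0
    else:
        raise NotImplementedError
    oxy = _interp(opts, s0)

    node_dist = {}
    for n in g.nodes:
        da = s0 + _min_node_dist(g, olink.node_a, n)
        db = (L0 - s0) + _min_node_dist(g, olink.node_b, n)
        d = min(da, db)
        if d <= r:
            node_dist[n] = d

    members = []
    for lid in sorted(net.links, key=str):
        link = net.links[lid]
        L = _cumarc(link.geometry.points)[-1]
        dA = node_dist.get(link.node_a, math.inf)
        dB = node_dist.get(link.node_b, math.inf)
        iv = []
        if r >= dA:
            iv.append((0.0, min(L, r - dA)))
        if r >= dB:
            iv.append((max(0.0, L - (r - dB)), L))
        if lid == origin:
            iv.append((max(0.0, s0 - r), min(L, s0 + r)))
        iv.sort()
        merged = []
        for lo, hi in iv:
            if merged and lo <= merged[-1][1] + EPS:
                merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
            else:
                merged.append((lo, hi))
        if continuous:
            for lo, hi in merged:
                members.append((lid, lo, hi, (hi - lo) / L * link.weight))
        else:
            full = len(merged) == 1 and merged[0][0] <= EPS and merged[0][1] >= L - EPS
            if full or lid == origin:
                members.append((lid, 0.0, L, link.weight))
    return {"origin": origin, "s0": s0, "oxy": oxy, "r": r,
            "members": members, "node_dist": node_dist,
            "continuous": continuous}


def ref_point_distance(net, origin, s0, lid, s):
    """Network distance from the origin point to an arbitrary on-link point."""
    g = _multigraph(net)
    olink, tlink = net.links[origin], net.links[lid]
    L0 = _cumarc(olink.geometry.points)[-1]
    Lt = _cumarc(tlink.geometry.points)[-1]
    best = abs(s - s0) if lid == origin else math.inf
    for eo, so in ((olink.node_a, s0), (olink.node_b, L0 - s0)):
        for et, st in ((tlink.node_a, s), (tlink.node_b, Lt - s)):
            best = min(best, so + _min_node_dist(g, eo, et) + st)
    return best


# ---------------------------------------------------------------------------
# angular geodesics by exhaustive state enumeration
# ---------------------------------------------------------------------------

def _rank_map(net):
    ids = sorted(net.links, key=str)
    return ids, {lid: i for i, lid in enumerate(ids)}


def ref_geodesic(net, sub, member):
    """Exhaustive min-(theta, length, lex path) route to one member.

    Enumerates every path through states (link, arrival end) without
    repeated states, confined to fully included links; destinations are
    entered from the end(s) their included interval is anchored to.
    Returns (theta, length, crow, path ids) or None if unreachable.
    """
    origin = sub["origin"]
    lid, lo, hi, P = member
    if lid == origin:
        return (0.0, 0.0, 0.0, (origin,))
    olink = net.links[origin]
    opts = olink.geometry.points
    L0 = _cumarc(opts)[-1]
    s0 = sub["s0"]
    ids, rank = _rank_map(net)

    by_link = {}
    for m in sub["members"]:
        by_link.setdefault(m[0], []).append(m)
    lengths = {k: _cumarc(net.links[k].geometry.points)[-1] for k in net.links}
    traversable = {
        k for k, parts in by_link.items()
        if any(p[1] <= EPS and p[2] >= lengths[k] - EPS for p in parts)
    }

    dlink = net.links[lid]
    dpts = dlink.geometry.points
    Ld = lengths[lid]
    rep_s = (lo + hi) / 2.0
    rep_xy = _interp(dpts, rep_s)
    crow = float(np.hypot(*(rep_xy - sub["oxy"])))
    entries = {}
    if lo <= EPS:
        entries[dlink.node_a] = ("a", 0.0)
    if hi >= Ld - EPS:
        entries[dlink.node_b] = ("b", Ld)

    # origin exits
    oparts = [m for m in by_link.get(origin, [])
              if m[1] - EPS <= s0 <= m[2] + EPS]
    starts = []
    if oparts:
        op = oparts[0]
        if op[1] <= EPS:
            starts.append(("a", 0.0))
        if op[2] >= L0 - EPS:
            starts.append(("b", L0))
    best = None
    stack = []
    for end, s_end in starts:
        theta0 = _internal_between(opts, s0, s_end)
        node = olink.node_a if end == "a" else olink.node_b
        stack.append((theta0, abs(s_end - s0), (rank[origin],),
                      (origin, end), node, frozenset({(origin, end)})))
    while stack:
        theta, length, path, state, node, seen = stack.pop()
        # branch and bound: extending a path never decreases (theta,
        # length), so strictly worse prefixes cannot yield the minimum
        if best is not None and (theta, length) > (best[0], best[1]):
            continue
        v_in = _dir_arrive(net.links[state[0]].geometry.points, state[1])
        if node in entries:
            e_end, s_entry = entries[node]
            turn = _ang(v_in, _dir_depart(dpts, e_end))
            cand = (theta + turn + _internal_between(dpts, s_entry, rep_s),
                    length + abs(rep_s - s_entry),
                    path + (rank[lid],))
            if best is None or cand < best:
                best = cand
        for nlid, nend in net.nodes[node].incident_ends:
            if nlid not in traversable:
                continue
            other = "b" if nend == "a" else "a"
            nstate = (nlid, other)
            if nstate in seen:
                continue
            npts = net.links[nlid].geometry.points
            turn = _ang(v_in, _dir_depart(npts, nend))
            internal = _internal_between(npts, 0.0, lengths[nlid])
            ntheta = theta + turn + internal
            nlength = length + lengths[nlid]
            if best is not None and (ntheta, nlength) > (best[0], best[1]):
                continue
            nnode = net.links[nlid].node_a if other == "a" else net.links[nlid].node_b
            stack.append((ntheta, nlength,
                          path + (rank[nlid],), nstate, nnode,
                          seen | {nstate}))
    if best is None:
        return None
    theta, length, path = best
    return theta, length, crow, tuple(ids[i] for i in path)


# ---------------------------------------------------------------------------
# hull and per-link metrics
# ---------------------------------------------------------------------------

def ref_reached_points(net, sub):
    pts_out = [np.asarray(sub["oxy"], float)]
    for lid, lo, hi, _P in sub["members"]:
        pts = np.asarray(net.links[lid].geometry.points, float)
        arcs = _cumarc(pts)
        pts_out.append(_interp(pts, lo))
        for k, a in enumerate(arcs):
            if lo + EPS < a < hi - EPS:
                pts_out.append(pts[k])
        pts_out.append(_interp(pts, hi))
    return np.array(pts_out)


def ref_hull(net, sub):
    pts = ref_reached_points(net, sub)
    oxy = np.asarray(sub["oxy"], float)
    hull_r = float(np.hypot(*(pts - oxy).T).max())
    uniq = np.unique(np.round(pts, 12), axis=0)
    area, perim = 0.0, 0.0
    if len(uniq) >= 3:
        try:
            h = ConvexHull(uniq)
            area, perim = float(h.volume), float(h.area)  # scipy 2-D naming
        except QhullError:
            pass
    if area < 1e-6:  # micron-scale sliver: collinear within floating point
        area = 0.0
    if area == 0.0:
        extent = max(
            (np.hypot(*(p - q)) for p, q in combinations(uniq, 2)), default=0.0
        )
        perim = 2.0 * float(extent)
    si = perim / (2.0 * math.sqrt(math.pi * area)) if area > 0 else float("nan")
    return {"HullA": area, "HullP": perim, "HullR": hull_r, "HullSI": si}


def ref_link_metrics(net, origin, r, continuous=True, delta=DELTA_DEG):
    """All non-betweenness metrics, by direct transliteration."""
    sub = ref_subsystem(net, origin, r, continuous)
    if continuous:
        links = sum(m[3] for m in sub["members"])
    else:
        links = float(len(sub["members"]))
    lengths = {k: _cumarc(net.links[k].geometry.points)[-1] for k in net.links}
    length = sum(m[2] - m[1] for m in sub["members"])

    w = mgla = mcf = mad = 0.0
    div_sum = div_w = 0.0
    nqpda = 0.0
    n_dropped = 0
    for m in sub["members"]:
        if m[0] == origin or m[3] <= 0:
            continue
        g = ref_geodesic(net, sub, m)
        if g is None:
            n_dropped += 1
            continue
        theta, netlen, crow, _path = g
        w += m[3]
        nqpda += m[3] / max(theta, delta)
        mgla += m[3] * netlen
        mcf += m[3] * crow
        mad += m[3] * theta
        if crow > EPS:
            div_sum += m[3] * netlen / crow
            div_w += m[3]
    nan = float("nan")
    junctions = [n for n, d in sub["node_dist"].items()
                 if d <= r and net.nodes[n].degree >= 3]
    out = {
        "Links": links, "Length": length, "NQPDA": nqpda,
        "MGLA": mgla / w if w else nan,
        "MCF": mcf / w if w else nan,
        "MAD": mad / w if w else nan,
        "DivA": div_sum / div_w if div_w else nan,
        "Jnc": float(len(junctions)),
        "Con": float(sum(net.nodes[n].degree for n in junctions)),
        "n_dropped": n_dropped,
    }
    out.update(ref_hull(net, sub))
    return out


# ---------------------------------------------------------------------------
# betweenness family with an explicit pairwise ledger
# ---------------------------------------------------------------------------

def ref_betweenness(net, r, continuous=True):
    """(BtA, TPBtA, TPDA dicts, ledger rows (origin, dest, path, trip))."""
    bta, tpbta, tpda = {}, {}, {}
    ledger = []
    for y in sorted(net.links, key=str):
        W = net.links[y].weight
        sub = ref_subsystem(net, y, r, continuous)
        p_total = sum(m[3] for m in sub["members"])
        if p_total <= 0:
            continue
        for m in sub["members"]:
            lid, lo, hi, P = m
            share = W * P / p_total
            tpda[lid] = tpda.get(lid, 0.0) + share
            if lid == y:
                bta[y] = bta.get(y, 0.0) + W * P / 3.0
                tpbta[y] = tpbta.get(y, 0.0) + share / 3.0
                ledger.append((y, y, (y,), share))
                continue
            g = ref_geodesic(net, sub, m)
            if g is None:
                continue
            path = g[3]
            for x in set(path):
                sig = 0.5 if x in (y, lid) else 1.0
                bta[x] = bta.get(x, 0.0) + W * P * sig
                tpbta[x] = tpbta.get(x, 0.0) + share * sig
            ledger.append((y, lid, path, share))
    return bta, tpbta, tpda, ledger


def ref_full_row(net, origin, r, continuous=True):
    """One complete 16-metric row (betweenness via ref_betweenness)."""
    row = ref_link_metrics(net, origin, r, continuous)
    bta, tpbta, tpda, _ = ref_betweenness(net, r, continuous)
    row["BtA"] = bta.get(origin, 0.0)
    row["TPBtA"] = tpbta.get(origin, 0.0)
    row["TPDA"] = tpda.get(origin, 0.0)
    return row
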