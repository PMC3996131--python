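"""Radial engine: origin points, subsystems, geodesics, hulls, metrics,
betweenness — each checked against closed forms or the brute-force
reference in ``bruteforce.py``."""

import math

import numpy as np
import pandas as pd
import pytest

from sevnet import build_network
from sevnet.radial import (
    angular_geodesics,
    betweenness_family,
    compute_link_metrics,
    hull_stats,
    hullr_profile,
    link_metrics,
    origin_point,
    reachable_subsystem,
)

import bruteforce as bf
from conftest import make_chain, make_grid, random_small_net


# ---------------------------------------------------------------------------
# origin points
# ---------------------------------------------------------------------------

def test_origin_point_straight_link_both_modes():
    net = build_network([("s", [(0, 0), (100, 0)])])
    link = net.links["s"]
    assert origin_point(link, "euclidean") == pytest.approx(50.0)
    assert origin_point(link, "angular") == pytest.approx(50.0)


def test_origin_point_L_shape_corner():
    net = build_network([("L", [(0, 0), (100, 0), (100, 100)])])
    link = net.links["L"]
    assert origin_point(link, "euclidean") == pytest.approx(100.0)
    # all angular cost is at the corner, so the angular center is there too
    assert origin_point(link, "angular") == pytest.approx(100.0)


# ---------------------------------------------------------------------------
# subsystems
# ---------------------------------------------------------------------------

def test_chain_symmetric_extent_continuous(chain21):
    # origin at chain center, r = 600: exactly 600 m included each way
    sub = reachable_subsystem(chain21, "c10", 600.0, continuous=True)
    total = sum(
        (p.b - p.a) * chain21.links[p.link_id].length_m for p in sub.members
    )
    assert total == pytest.approx(1200.0)


def test_chain_discrete_membership_matches_bruteforce(chain21):
    sub = reachable_subsystem(chain21, "c10", 600.0, continuous=False)
    got = sorted(p.link_id for p in sub.members)
    # brute force: a link is a member iff its farthest point is within r
    expect = []
    for lid, link in chain21.links.items():
        s0 = link.length_m / 2.0
        dmax = max(
            bf.ref_point_distance(chain21, "c10", 50.0, lid, s)
            for s in (0.0, link.length_m)
        )
        if dmax <= 600.0 or lid == "c10":
            expect.append(lid)
    assert got == sorted(expect)
    assert len(got) == 11  # five whole links each way plus the origin


@pytest.mark.parametrize("seed,r", [(0, 150.0), (1, 220.0), (2, 90.0)])
def test_continuous_interval_boundaries_lie_at_radius(seed, r):
    """Cut points of partial links sit at network distance exactly r."""
    net = random_small_net(seed)
    origin = net.link_ids()[0]
    s0 = net.links[origin].length_m / 2.0
    sub = reachable_subsystem(net, origin, r, continuous=True)
    checked = 0
    for p in sub.members:
        L = net.links[p.link_id].length_m
        for frac, interior in ((p.a, p.a > 1e-9), (p.b, p.b < 1 - 1e-9)):
            if interior:
                d = bf.ref_point_distance(net, origin, s0, p.link_id, frac * L)
                assert d == pytest.approx(r, abs=1e-6)
                checked += 1
    assert checked > 0


def test_zero_radius_subsystem_contains_only_origin_point(grid3):
    sub = reachable_subsystem(grid3, "h00", 0.0, continuous=True)
    assert [p.link_id for p in sub.members] == ["h00"]
    assert sub.members[0].P == 0.0


# ---------------------------------------------------------------------------
# angular geodesics
# ---------------------------------------------------------------------------

def test_collinear_destination_zero_angular_cost(chain21):
    sub = reachable_subsystem(chain21, "c10", 600.0, continuous=True)
    geos = angular_geodesics(chain21, sub)
    for g in geos.values():
        assert g.angular_cost_deg == pytest.approx(0.0, abs=1e-9)
        if g.crow_flight_m > 0:
            assert g.network_length_m == pytest.approx(g.crow_flight_m)


def test_grid_destination_one_right_turn(grid3):
    sub = reachable_subsystem(grid3, "h00", 150.0, continuous=True)
    geos = angular_geodesics(grid3, sub)
    by_dest = {g.dest.link_id: g for g in geos.values()}
    assert by_dest["v10"].angular_cost_deg == pytest.approx(90.0)
    assert by_dest["h10"].angular_cost_deg == pytest.approx(0.0)


def test_angular_geodesic_prefers_straight_bypass_over_zigzag():
    """The minimum-angle route can be longer in meters: a square bypass
    beats a zigzag in degrees turned, and matches the enumeration oracle."""
    # direct zigzag (two teeth, 8 x 90-degree turns) vs a 3-sided bypass
    # costing 4 x 90: the bypass wins on degrees despite more meters
    zig = [(0, 0), (25, 0), (25, 40), (60, 40), (60, 0), (95, 0), (95, 40),
           (130, 40), (130, 0), (150, 0)]
    feats = [
        ("dest", [(150, 0), (250, 0)]),
        ("orig", [(-100, 0), (0, 0)]),
        ("zig", zig),
        ("by1", [(0, 0), (0, -120)]),
        ("by2", [(0, -120), (150, -120)]),
        ("by3", [(150, -120), (150, 0)]),
    ]
    net = build_network(feats)
    sub = reachable_subsystem(net, "orig", 10_000.0, continuous=True)
    geos = angular_geodesics(net, sub)
    g = next(g for g in geos.values() if g.dest.link_id == "dest")
    ref = bf.ref_geodesic(
        net,
        bf.ref_subsystem(net, "orig", 10_000.0, True),
        next(m for m in bf.ref_subsystem(net, "orig", 10_000.0, True)["members"] if m[0] == "dest"),
    )
    assert g.path == ref[3]
    assert g.angular_cost_deg == pytest.approx(ref[0], rel=1e-12)
    assert "by1" in g.path  # the bypass, not the zigzag
    assert g.network_length_m > abs(250.0 / 2 + 150.0 - (-50.0))  # longer than direct


@pytest.mark.parametrize("seed,r", [(0, 200.0), (3, 260.0), (5, 150.0)])
def test_geodesics_match_enumeration_oracle(seed, r):
    net = random_small_net(seed)
    origin = net.link_ids()[2]
    sub = reachable_subsystem(net, origin, r, continuous=True)
    geos = angular_geodesics(net, sub)
    ref_sub = bf.ref_subsystem(net, origin, r, True)
    assert len(ref_sub["members"]) == len(sub.members)
    for idx, part in enumerate(sub.members):
        ref = bf.ref_geodesic(net, ref_sub, ref_sub["members"][idx])
        got = geos.get(idx)
        if ref is None:
            assert got is None
            continue
        assert got.angular_cost_deg == pytest.approx(ref[0], rel=1e-9, abs=1e-9)
        assert got.network_length_m == pytest.approx(ref[1], rel=1e-9, abs=1e-9)
        assert got.crow_flight_m == pytest.approx(ref[2], rel=1e-9, abs=1e-9)
        assert got.path == ref[3]


# ---------------------------------------------------------------------------
# hull statistics
# ---------------------------------------------------------------------------

def test_hull_straight_road_degenerate():
    net = build_network([("road", [(0.0, 0.0), (2000.0, 0.0)])])
    sub = reachable_subsystem(net, "road", 600.0, continuous=True)
    h = hull_stats(net, sub)
    assert h["HullR"] == pytest.approx(600.0)
    assert h["HullA"] == 0.0
    assert h["HullP"] == pytest.approx(2400.0)
    assert math.isnan(h["HullSI"])


def test_hull_staircase_closed_form(staircase):
    # 600 m of staircase each way from the central corner displaces
    # (300, 300): HullR = sqrt(2) * 300
    sub = reachable_subsystem(staircase, "stair", 600.0, continuous=True)
    h = hull_stats(staircase, sub)
    assert h["HullR"] == pytest.approx(math.sqrt(2) * 300.0, abs=0.01)


def test_hull_circular_loop_chord_formula(ring200):
    # arc 600 m on a rho=200 m circle: chord = 2 rho sin(arc / (2 rho))
    sub = reachable_subsystem(ring200, "ring_u", 600.0, continuous=True)
    h = hull_stats(ring200, sub)
    assert h["HullR"] == pytest.approx(400.0 * math.sin(1.5), abs=0.01)


# ---------------------------------------------------------------------------
# link metrics
# ---------------------------------------------------------------------------

def test_isolated_link_metrics():
    net = build_network([("iso", [(0, 0), (80, 0)])])
    row = link_metrics(net, "iso", 500.0, continuous=False)
    assert row["Links"] == 1.0
    assert math.isnan(row["MGLA"])
    assert math.isnan(row["MAD"])
    assert math.isnan(row["DivA"])
    assert row["Jnc"] == 0.0 and row["Con"] == 0.0


def test_chain_mad_zero_diva_one(chain21):
    row = link_metrics(chain21, "c10", 600.0, continuous=True)
    assert row["MAD"] == pytest.approx(0.0, abs=1e-9)
    assert row["DivA"] == pytest.approx(1.0)
    assert row["MCF"] <= row["MGLA"] + 1e-9


def test_grid_row_matches_bruteforce_reference(grid3):
    got = link_metrics(grid3, "h01", 300.0, continuous=False)
    ref = bf.ref_full_row(grid3, "h01", 300.0, continuous=False)
    bt = betweenness_family(grid3, 300.0, continuous=False).set_index("link_id")
    for key, val in ref.items():
        if key in ("n_dropped",):
            continue
        engine = bt.loc["h01", key] if key in ("BtA", "TPBtA", "TPDA") else got[key]
        if isinstance(val, float) and math.isnan(val):
            assert math.isnan(engine)
        else:
            assert engine == pytest.approx(val, rel=1e-9, abs=1e-12), key


# ---------------------------------------------------------------------------
# betweenness family
# ---------------------------------------------------------------------------

def test_three_link_path_betweenness_enumeration():
    net = make_chain(3)
    got = betweenness_family(net, 10_000.0, continuous=True).set_index("link_id")
    bta, tpbta, tpda, ledger = bf.ref_betweenness(net, 10_000.0, True)
    for lid in net.links:
        assert got.loc[lid, "BtA"] == pytest.approx(bta.get(lid, 0.0), rel=1e-12)
        assert got.loc[lid, "TPBtA"] == pytest.approx(tpbta.get(lid, 0.0), rel=1e-12)
        assert got.loc[lid, "TPDA"] == pytest.approx(tpda.get(lid, 0.0), rel=1e-12)
    # middle link carries the cross traffic
    assert got.loc["c01", "BtA"] > got.loc["c00", "BtA"]


def test_tpbta_per_origin_trip_conservation(grid3):
    # every origin distributes exactly its weight over destinations, so
    # the TPDA column sums to the number of origins
    got = betweenness_family(grid3, 250.0, continuous=True)
    assert got["TPDA"].sum() == pytest.approx(grid3.n_links, rel=1e-12)


def test_star_center_dominates_spokes():
    feats = [
        ("center", [(-50, 0), (50, 0)]),
        ("sp_e", [(50, 0), (250, 0)]),
        ("sp_n", [(50, 0), (50, 200)]),
        ("sp_w", [(-50, 0), (-250, 0)]),
        ("sp_s", [(-50, 0), (-50, -200)]),
    ]
    net = build_network(feats)
    got = betweenness_family(net, 10_000.0, continuous=True).set_index("link_id")
    bta, *_ = bf.ref_betweenness(net, 10_000.0, True)
    for lid in net.links:
        assert got.loc[lid, "BtA"] == pytest.approx(bta[lid], rel=1e-12)
    center = got.loc["center", "BtA"]
    for spoke in ("sp_e", "sp_n", "sp_w", "sp_s"):
        assert center > got.loc[spoke, "BtA"]


# ---------------------------------------------------------------------------
# fast HullR path and whole-table consistency
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", [0, 4])
def test_hullr_profile_matches_engine(seed):
    net = random_small_net(seed)
    radii = [100.0, 200.0, 350.0]
    fast = hullr_profile(net, radii).set_index(["link_id", "radius_m"])
    slow = compute_link_metrics(net, radii).set_index(["link_id", "radius_m"])
    for key in fast.index:
        assert fast.loc[key, "HullR"] == pytest.approx(
            slow.loc[key, "HullR"], rel=1e-9, abs=1e-9
        )


def test_continuous_equals_discrete_at_saturating_radius(grid3):
    r = 5000.0  # far beyond diameter + longest link
    cont = compute_link_metrics(grid3, [r], continuous=True)
    disc = compute_link_metrics(grid3, [r], continuous=False)
    pd.testing.assert_series_equal(cont["Links"], disc["Links"], atol=1e-9)
    pd.testing.assert_series_equal(cont["Length"], disc["Length"], atol=1e-9)
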