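"""Shared fixtures: canonical toy networks and session-scoped synthetic
boroughs (generated once; the expensive full metric table is reused by
the statistical calibration tests)."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from sevnet import (
    GeneratorSpec,
    build_network,
    build_unit_table,
    compute_link_metrics,
    gen_districts,
    gen_network,
)


# ---------------------------------------------------------------------------
# deterministic toy networks
# ---------------------------------------------------------------------------

def make_grid(nx: int = 3, ny: int = 3, spacing: float = 100.0):
    """nx x ny nodes joined by axis-aligned streets."""
    feats = []
    for i in range(nx):
        for j in range(ny):
            if i + 1 < nx:
                feats.append(
                    (f"h{i}{j}", [(i * spacing, j * spacing), ((i + 1) * spacing, j * spacing)])
                )
            if j + 1 < ny:
                feats.append(
                    (f"v{i}{j}", [(i * spacing, j * spacing), (i * spacing, (j + 1) * spacing)])
                )
    return build_network(feats)


def make_chain(n_links: int = 21, length: float = 100.0):
    """Straight east-west chain of equal links."""
    feats = [
        (f"c{k:02d}", [(k * length, 0.0), ((k + 1) * length, 0.0)])
        for k in range(n_links)
    ]
    return build_network(feats)


@pytest.fixture
def grid3():
    return make_grid(3, 3)


@pytest.fixture
def chain21():
    return make_chain(21)


@pytest.fixture
def staircase():
    """One 1200 m link turning 90 degrees every 100 m; center on a corner."""
    pts = [(0.0, 0.0)]
    for k in range(12):
        x, y = pts[-1]
        pts.append((x + 100.0, y) if k % 2 == 0 else (x, y + 100.0))
    return build_network([("stair", pts)])


@pytest.fixture
def ring200():
    """Circular loop of radius 200 m as two finely sampled semicircles."""
    rho = 200.0
    theta = np.linspace(0.0, np.pi, 601)
    upper = [(rho * np.cos(t), rho * np.sin(t)) for t in theta]
    lower = [(rho * np.cos(t), -rho * np.sin(t)) for t in theta]
    return build_network([("ring_u", upper), ("ring_l", lower)])


def random_small_net(seed: int):
    """Connected jittered partial grid, <= 12 links, some curved geometry.

    Spanning tree plus random extras on a 3x3 jittered node grid; about
    40% of links get an offset interior vertex so internal angular costs
    are exercised.
    """
    rng = np.random.default_rng(seed)
    nodes = {
        (i, j): np.array([i * 100.0, j * 100.0]) + rng.normal(0.0, 12.0, 2)
        for i in range(3)
        for j in range(3)
    }
    edges = [((i, j), (i + 1, j)) for i in range(2) for j in range(3)]
    edges += [((i, j), (i, j + 1)) for i in range(3) for j in range(2)]
    order = rng.permutation(len(edges))

    parent = {n: n for n in nodes}

    def find(n):
        while parent[n] != n:
            parent[n] = parent[parent[n]]
            n = parent[n]
        return n

    chosen = []
    extras = []
    for idx in order:
        a, b = edges[idx]
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            chosen.append(edges[idx])
        else:
            extras.append(edges[idx])
    for e in extras:
        if rng.random() < 0.5 and len(chosen) < 12:
            chosen.append(e)

    feats = []
    for k, (a, b) in enumerate(sorted(chosen, key=str)):
        p0, p1 = nodes[a], nodes[b]
        if rng.random() < 0.4:
            mid = (p0 + p1) / 2.0 + rng.normal(0.0, 18.0, 2)
            coords = [tuple(p0), tuple(mid), tuple(p1)]
        else:
            coords = [tuple(p0), tuple(p1)]
        feats.append((f"e{k:02d}", coords))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_network(feats)


# ---------------------------------------------------------------------------
# session-scoped synthetic boroughs
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def borough_spec():
    """Stated world for the statistical tests: composite borough with 325
    districts and the study-patterned outcome coefficients."""
    return GeneratorSpec(layout="composite", tiles_x=5, tiles_y=5,
                         k_districts=325, seed=0)


@pytest.fixture(scope="session")
def borough(borough_spec):
    net = gen_network(borough_spec)
    units = gen_districts(net, borough_spec.k_districts, seed=borough_spec.seed)
    return net, units


@pytest.fixture(scope="session")
def borough_unit_table(borough):
    """Full 16-metric x 5-radius table aggregated to the 325 districts.

    This is the one expensive fixture (about a minute); the calibration
    and recovery tests re-draw outcomes over it cheaply.
    """
    net, units = borough
    rows = compute_link_metrics(net, (300, 600, 900, 1200, 1500))
    for u in units:
        u.attributes.setdefault("cohesion", np.nan)
        u.attributes.setdefault("deprivation", np.nan)
        u.attributes.setdefault("urban", np.nan)
    return build_unit_table(units, net, rows)


@pytest.fixture(scope="session")
def big_borough():
    """~2,000-link composite borough with 325 districts (for the sweep)."""
    spec = GeneratorSpec(layout="composite", tiles_x=10, tiles_y=10,
                         k_districts=325, seed=0)
    net = gen_network(spec)
    units = gen_districts(net, spec.k_districts, seed=spec.seed)
    return spec, net, units
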