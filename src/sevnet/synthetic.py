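"""Synthetic street networks, districts and outcomes.

Nothing in the survey or road data this package was designed around is
redistributable, so every stage is exercised on generated stand-ins:

* street-network families with controllable straightness and severance
  (grids, zigzags, loops, cul-de-sac estates, linear settlements, and
  composite "boroughs" tiling several families),
* a Voronoi partition of the network's bounding region standing in for
  enumeration districts,
* a district-level cohesion outcome generated as a linear function of
  standardized deprivation, standardized HullR600c and urban status plus
  Gaussian noise calibrated to a target population r-squared.

Default coefficients (-0.42 deprivation, +0.26 HullR600c, -0.10 urban;
r-squared 0.249; 325 districts) mirror the magnitudes reported in the
study the pipeline is patterned on.  All randomness flows from one seed
through named substreams, so e.g. changing the district count never
perturbs the network geometry.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Point, box
from shapely.ops import voronoi_diagram
from shapely.strtree import STRtree

from .aggregation import DEFAULT_BUFFER_M, assign_links, build_unit_table
from .network import ArealUnit, SpatialNetwork, build_network
from .radial import hullr_profile, metric_column

__all__ = [
    "GeneratorSpec",
    "SimulatedWorld",
    "substream",
    "gen_network",
    "gen_districts",
    "gen_outcomes",
    "simulate",
]

LAYOUTS = (
    "grid",
    "perturbed_grid",
    "zigzag",
    "loop",
    "culdesac_estate",
    "linear_settlement",
    "composite",
)


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible substream of the run seed."""
    return np.random.default_rng([int(seed) % 2**31, zlib.crc32(name.encode())])


@dataclass(frozen=True)
class GeneratorSpec:
    """Stated world for the synthetic borough.

    Geometry defaults use a 100 m street spacing (a typical UK urban block
    scale); outcome defaults are the study-patterned coefficients above.
    """

    layout: str = "composite"
    spacing_m: float = 100.0
    segment_len_m: float = 100.0
    n_x: int = 4                      # node columns for grid layouts
    n_y: int = 4                      # node rows for grid layouts
    n_segments: int = 12              # zigzag / linear settlement segments
    loop_radius_m: float = 200.0
    perturbation_sd_m: float = 10.0   # vertex jitter for perturbed grids
    tiles_x: int = 10                 # composite meta-grid
    tiles_y: int = 10
    k_districts: int = 325
    beta_deprivation: float = -0.42
    beta_hullr: float = 0.26
    beta_urban: float = -0.10
    target_r2: float = 0.249
    noise_sd: float | None = None     # overrides the r2 calibration when set
    u_shape: bool = False             # U-shaped deprivation-HullR coupling
    tertile_hullr_betas: tuple | None = None  # (least, mid, most deprived)
    allow_disconnected: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.layout not in LAYOUTS:
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.spacing_m <= 0 or self.segment_len_m <= 0 or self.loop_radius_m <= 0:
            raise ValueError("all lengths must be positive")
        if self.k_districts < 1:
            raise ValueError("k_districts must be >= 1")
        if self.target_r2 >= 1:
            raise ValueError("target population r2 must be < 1")


# ---------------------------------------------------------------------------
# network families: each returns [(link id, coordinate list), ...]
# ---------------------------------------------------------------------------

def _grid(nx: int, ny: int, spacing: float, ox: float = 0.0, oy: float = 0.0,
          jitter: np.ndarray | None = None):
    nodes = {}
    for i in range(nx):
        for j in range(ny):
            dx, dy = (0.0, 0.0) if jitter is None else jitter[i * ny + j]
            nodes[(i, j)] = (ox + i * spacing + dx, oy + j * spacing + dy)
    feats = []
    for i in range(nx):
        for j in range(ny):
            if i + 1 < nx:
                feats.append((f"h{i}_{j}", [nodes[(i, j)], nodes[(i + 1, j)]]))
            if j + 1 < ny:
                feats.append((f"v{i}_{j}", [nodes[(i, j)], nodes[(i, j + 1)]]))
    return feats


def _zigzag(seg_len: float, n_segments: int, ox: float = 0.0, oy: float = 0.0):
    """One staircase link: alternating east/north segments, 90 deg turns."""
    pts = [(ox, oy)]
    for k in range(n_segments):
        x, y = pts[-1]
        pts.append((x + seg_len, y) if k % 2 == 0 else (x, y + seg_len))
    return [("zig0", pts)]


def _loop(radius: float, n_vertices: int = 128, ox: float = 0.0, oy: float = 0.0):
    """A circular loop approximated by two semicircular links."""
    cx, cy = ox + radius, oy
    theta = np.linspace(0.0, np.pi, n_vertices // 2 + 1)
    upper = [(cx + radius * np.cos(t), cy + radius * np.sin(t)) for t in theta]
    lower = [(cx + radius * np.cos(t), cy - radius * np.sin(t)) for t in theta]
    return [("loop_u", upper), ("loop_l", lower)]


def _culdesac_estate(spacing: float, n_spine: int, rng: np.random.Generator,
                     ox: float = 0.0, oy: float = 0.0):
    """A spine road with tree-like cul-de-sac interiors hanging off it.

    High severance by construction: most links are dead-end branches, so
    network distance buys little crow-flight displacement.
    """
    feats = []
    spine = [(ox + i * spacing, oy) for i in range(n_spine + 1)]
    for i in range(n_spine):
        feats.append((f"sp{i}", [spine[i], spine[i + 1]]))
    for i in range(1, n_spine):
        x, y = spine[i]
        for side in (+1, -1):
            # curved access stub then a T of two dead ends
            bend = float(rng.uniform(-0.3, 0.3)) * spacing
            sx, sy = x + bend, y + side * 0.7 * spacing
            feats.append((f"stub{i}_{side}", [(x, y), (x + bend / 2, y + side * 0.4 * spacing), (sx, sy)]))
            for arm, ddx in (("l", -0.45), ("r", +0.45)):
                ex = sx + ddx * spacing
                ey = sy + side * float(rng.uniform(0.2, 0.45)) * spacing
                feats.append((f"cul{i}_{side}{arm}", [(sx, sy), (ex, ey)]))
    return feats


def _linear_settlement(seg_len: float, n_segments: int, rng: np.random.Generator,
                       ox: float = 0.0, oy: float = 0.0):
    """One long near-straight road with short dead-end side stubs."""
    feats = []
    heading = 0.0
    pts = [(ox, oy)]
    for _ in range(n_segments):
        heading += float(rng.normal(0.0, np.radians(4.0)))
        x, y = pts[-1]
        pts.append((x + seg_len * np.cos(heading), y + seg_len * np.sin(heading)))
    for i in range(n_segments):
        feats.append((f"main{i}", [pts[i], pts[i + 1]]))
    for i in range(1, n_segments):
        x, y = pts[i]
        side = 1 if i % 2 == 0 else -1
        feats.append((f"side{i}", [(x, y), (x + side * 10.0, y + side * 0.5 * seg_len)]))
    return feats


_COMPOSITE_CYCLE = ("grid", "culdesac_estate", "linear_settlement", "perturbed_grid")


def _bounds(feats):
    pts = np.array([p for _, coords in feats for p in coords])
    return pts.min(axis=0), pts.max(axis=0)


def gen_network(spec: GeneratorSpec) -> SpatialNetwork:
    """Generate the network family requested by the spec (snapped, planar).

    The composite layout tiles the non-loop families over a
    ``tiles_x x tiles_y`` meta-grid and joins neighbouring tiles with
    straight connector links, yielding one connected borough-scale
    network with spatially heterogeneous severance.
    """
    rng = substream(spec.seed, "network")
    s = spec.spacing_m
    if spec.layout == "grid":
        feats = _grid(spec.n_x, spec.n_y, s)
    elif spec.layout == "perturbed_grid":
        jitter = rng.normal(0.0, spec.perturbation_sd_m, size=(spec.n_x * spec.n_y, 2))
        feats = _grid(spec.n_x, spec.n_y, s, jitter=jitter)
    elif spec.layout == "zigzag":
        feats = _zigzag(spec.segment_len_m, spec.n_segments)
    elif spec.layout == "loop":
        feats = _loop(spec.loop_radius_m)
    elif spec.layout == "culdesac_estate":
        feats = _culdesac_estate(s, max(3, spec.n_segments // 3), rng)
    elif spec.layout == "linear_settlement":
        feats = _linear_settlement(spec.segment_len_m, spec.n_segments, rng)
    else:  # composite
        feats = []
        tile_nodes = []  # endpoints per tile, for connectors
        cell = 5.0 * s
        for tj in range(spec.tiles_y):
            for ti in range(spec.tiles_x):
                fam = _COMPOSITE_CYCLE[int(rng.integers(len(_COMPOSITE_CYCLE)))]
                ox, oy = ti * cell, tj * cell
                if fam == "grid":
                    local = _grid(4, 4, s, ox, oy)
                elif fam == "perturbed_grid":
                    jit = rng.normal(0.0, spec.perturbation_sd_m, size=(16, 2))
                    local = _grid(4, 4, s, ox, oy, jitter=jit)
                elif fam == "culdesac_estate":
                    local = _culdesac_estate(s, 3, rng, ox, oy)
                else:
                    local = _linear_settlement(0.8 * s, 5, rng, ox, oy + 0.5 * s)
                prefix = f"t{ti}_{tj}_"
                local = [(prefix + lid, coords) for lid, coords in local]
                feats.extend(local)
                ends = np.array(
                    [coords[k] for _, coords in local for k in (0, -1)]
                )
                tile_nodes.append(((ti, tj), ends))
        # straight connectors between nearest endpoints of adjacent tiles
        by_tile = dict(tile_nodes)
        for (ti, tj), ends in tile_nodes:
            for dti, dtj in ((1, 0), (0, 1)):
                other = by_tile.get((ti + dti, tj + dtj))
                if other is None:
                    continue
                d = np.linalg.norm(ends[:, None, :] - other[None, :, :], axis=2)
                i, j = np.unravel_index(np.argmin(d), d.shape)
                a, b = ends[i], other[j]
                if np.linalg.norm(a - b) < 1e-6:
                    continue
                feats.append(
                    (f"conn{ti}_{tj}_{dti}{dtj}", [tuple(a), tuple(b)])
                )
    net = build_network(feats)
    comps = net.connected_components()
    if len(comps) > 1 and not spec.allow_disconnected:
        raise ValueError(
            f"generated network has {len(comps)} components; "
            "set allow_disconnected to accept"
        )
    return net


# ---------------------------------------------------------------------------
# districts
# ---------------------------------------------------------------------------

def gen_districts(net: SpatialNetwork, k: int, seed: int = 0) -> list[ArealUnit]:
    """Voronoi-style contiguous partition of the network's bounding region.

    Cells grow around ``k`` sampled link centers, so every district
    contains at least one link center and the cells tile the (slightly
    buffered) bounding box exactly.
    """
    ids = net.link_ids()
    if k > len(ids):
        raise ValueError(f"k={k} exceeds the {len(ids)} links available")
    rng = substream(seed, "districts")
    chosen = rng.choice(len(ids), size=k, replace=False)
    centers = []
    for i in sorted(chosen):
        link = net.links[ids[i]]
        centers.append(link.geometry.point_at(link.length_m / 2.0))
    centers = np.array(centers)
    # nudge exact duplicates so every seed gets its own cell
    for i in range(1, len(centers)):
        while np.any(np.all(np.abs(centers[:i] - centers[i]) < 1e-9, axis=1)):
            centers[i] = centers[i] + rng.normal(0.0, 1e-3, size=2)

    xmin, ymin, xmax, ymax = net.bounds()
    region = box(xmin - 50.0, ymin - 50.0, xmax + 50.0, ymax + 50.0)
    if k == 1:
        return [ArealUnit(id="d000", polygon=region)]
    mp = MultiPoint([Point(c) for c in centers])
    cells = voronoi_diagram(mp, envelope=region)
    tree = STRtree(list(cells.geoms))
    units = []
    for i, c in enumerate(centers):
        pt = Point(c)
        hits = tree.query(pt, predicate="intersects")
        cand = [cells.geoms[h] for h in hits if cells.geoms[h].distance(pt) < 1e-9]
        if not cand:
            raise RuntimeError("voronoi cell lookup failed")
        poly = cand[0].intersection(region)
        units.append(ArealUnit(id=f"d{i:03d}", polygon=poly))
    return units


# ---------------------------------------------------------------------------
# outcomes
# ---------------------------------------------------------------------------

def _safe_z(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    return np.zeros_like(x) if sd == 0 else (x - x.mean()) / sd


def gen_outcomes(
    units: list[ArealUnit],
    unit_table: pd.DataFrame,
    spec: GeneratorSpec,
    hullr_col: str = "HullR600c",
) -> pd.DataFrame:
    """Generate deprivation, urban status and cohesion for each district.

    cohesion = b_dep * z(deprivation) + b_hull * z(HullR600c)
             + b_urb * z(urban) + noise,

    with the noise SD calibrated from the empirical covariance of the
    generated predictors so the population r-squared equals the target
    (deprivation and HullR are correlated under the U-shape flag, so
    orthogonality is never assumed).  Urban status is the indicator of
    above-median link density (links per unit area).  With the optional
    U-shape, districts poorly connected for their size are pushed to
    either extreme of deprivation, mimicking the observed pattern that
    low-connectivity areas are either very poor or very rich.
    """
    rng = substream(spec.seed, "outcomes")
    table = unit_table.set_index("unit_id")
    order = [u.id for u in units]
    hull = table.loc[order, hullr_col].to_numpy(dtype=float)
    if not np.isfinite(hull).all():
        raise ValueError("HullR column has missing values; cannot generate outcomes")
    z_h = _safe_z(hull)
    n = len(order)

    if spec.u_shape:
        sign = rng.choice([-1.0, 1.0], size=n)
        dep = sign * 0.6 * (z_h - 2.0) ** 2 + rng.normal(0.0, 1.0, size=n)
    else:
        dep = rng.normal(0.0, 1.0, size=n)

    areas = np.array([u.polygon.area for u in units])
    n_links = table.loc[order, "n_links"].to_numpy(dtype=float)
    density = n_links / np.maximum(areas, 1.0)
    urban = (density > np.median(density)).astype(float)

    z_dep = _safe_z(dep)
    z_urb = _safe_z(urban)
    b_h = np.full(n, spec.beta_hullr)
    if spec.tertile_hullr_betas is not None:
        rank = pd.Series(dep, index=order).rank(method="first").to_numpy()
        tert = np.minimum((3 * (rank - 1) / n).astype(int), 2)
        b_h = np.asarray(spec.tertile_hullr_betas, dtype=float)[tert]
    signal = spec.beta_deprivation * z_dep + b_h * z_h + spec.beta_urban * z_urb

    var_signal = float(np.var(signal, ddof=1))
    if spec.noise_sd is not None:
        sigma = float(spec.noise_sd)
    elif var_signal == 0.0:
        sigma = 1.0
    elif spec.target_r2 <= 0.0:
        raise ValueError("target r2 must be positive when a signal is present")
    else:
        sigma = float(np.sqrt(var_signal * (1.0 - spec.target_r2) / spec.target_r2))
    cohesion = signal + rng.normal(0.0, sigma, size=n)
    return pd.DataFrame(
        {"unit_id": order, "cohesion": cohesion, "deprivation": dep, "urban": urban}
    )


# ---------------------------------------------------------------------------
# one-call world
# ---------------------------------------------------------------------------

@dataclass
class SimulatedWorld:
    spec: GeneratorSpec
    net: SpatialNetwork
    units: list
    unit_table: pd.DataFrame   # unit_id, n_links, HullR600c, outcomes
    outcomes: pd.DataFrame


def simulate(
    spec: GeneratorSpec,
    buffer_m: float = DEFAULT_BUFFER_M,
    hull_radius_m: float = 600.0,
) -> SimulatedWorld:
    """Generate network, districts, HullR600c aggregation and outcomes."""
    net = gen_network(spec)
    units = gen_districts(net, spec.k_districts, seed=spec.seed)
    rows = hullr_profile(net, [hull_radius_m])
    from .aggregation import aggregate

    mapping = assign_links(units, net, buffer_m)
    table = aggregate(mapping, rows, continuous=True)
    outcomes = gen_outcomes(units, table, spec,
                            hullr_col=metric_column("HullR", hull_radius_m, True))
    merged = table.merge(outcomes, on="unit_id")
    for u in units:
        row = outcomes.set_index("unit_id").loc[u.id]
        u.attributes.update(row.to_dict())
    return SimulatedWorld(spec=spec, net=net, units=units,
                          unit_table=merged, outcomes=outcomes)
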