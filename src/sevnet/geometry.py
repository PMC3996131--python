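"""Polyline primitives: arc length, interpolation, deflection angles.

All coordinates are 2-D and in projected meters.  Angles are in degrees;
the deflection at a vertex is 180 minus the interior angle between the two
adjoining segments, i.e. 0 for a straight continuation and approaching 180
for a hairpin.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "as_points",
    "arc_length",
    "cumulative_arcs",
    "point_at_arc",
    "deflection_angles",
    "internal_angular_cost",
    "segment_direction",
    "turn_angle_deg",
    "angular_cost_between",
    "angular_center_arc",
]

#: vertices closer than this (meters) are treated as coincident
EPS_M = 1e-9


def as_points(points) -> np.ndarray:
    """Coerce to an (n, 2) float array, dropping exactly repeated vertices."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("polyline needs an (n>=2, 2) coordinate array")
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > EPS_M
    pts = pts[keep]
    if len(pts) < 2:
        raise ValueError("polyline has zero length after dropping repeated vertices")
    return pts


def cumulative_arcs(pts: np.ndarray) -> np.ndarray:
    """Arc-length position of every vertex, starting at 0."""
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def arc_length(pts: np.ndarray) -> float:
    return float(cumulative_arcs(pts)[-1])


def point_at_arc(pts: np.ndarray, s: float) -> np.ndarray:
    """Coordinate at arc-length position ``s`` (clamped to the polyline)."""
    arcs = cumulative_arcs(pts)
    s = float(np.clip(s, 0.0, arcs[-1]))
    i = int(np.searchsorted(arcs, s, side="right")) - 1
    i = min(i, len(pts) - 2)
    seg = arcs[i + 1] - arcs[i]
    t = 0.0 if seg <= 0 else (s - arcs[i]) / seg
    return pts[i] + t * (pts[i + 1] - pts[i])


def segment_direction(pts: np.ndarray, index: int) -> np.ndarray:
    """Unit direction vector of segment ``index`` (from vertex i to i+1)."""
    d = pts[index + 1] - pts[index]
    n = np.linalg.norm(d)
    if n <= EPS_M:
        raise ValueError("degenerate segment")
    return d / n


def turn_angle_deg(v_in: np.ndarray, v_out: np.ndarray) -> float:
    """Absolute deflection in degrees between two travel directions."""
    dot = float(np.clip(np.dot(v_in, v_out), -1.0, 1.0))
    return float(np.degrees(np.arccos(dot)))


def deflection_angles(pts: np.ndarray) -> np.ndarray:
    """Deflection (degrees) at each interior vertex; empty for 2-point lines."""
    if len(pts) < 3:
        return np.zeros(0)
    d = np.diff(pts, axis=0)
    d = d / np.linalg.norm(d, axis=1, keepdims=True)
    dots = np.clip(np.einsum("ij,ij->i", d[:-1], d[1:]), -1.0, 1.0)
    return np.degrees(np.arccos(dots))


def internal_angular_cost(pts: np.ndarray) -> float:
    """Total degrees turned at interior vertices when traversing the polyline."""
    return float(deflection_angles(pts).sum())


def angular_cost_between(pts: np.ndarray, s_from: float, s_to: float) -> float:
    """Degrees turned at interior vertices strictly between two arc positions.

    A vertex lying exactly at either endpoint contributes nothing: the
    traveller starts (or stops) there and never turns through it.
    """
    lo, hi = sorted((float(s_from), float(s_to)))
    arcs = cumulative_arcs(pts)
    defl = deflection_angles(pts)
    inner = arcs[1:-1]
    mask = (inner > lo + EPS_M) & (inner < hi - EPS_M)
    return float(defl[mask].sum())


def angular_center_arc(pts: np.ndarray) -> float:
    """Arc position splitting the internal angular cost in half.

    Convention: the first arc position at which the cumulative deflection
    reaches half the total.  Links with no internal cost fall back to half
    the arc length (the Euclidean center).
    """
    defl = deflection_angles(pts)
    total = defl.sum()
    arcs = cumulative_arcs(pts)
    if total <= 0:
        return float(arcs[-1] / 2.0)
    cum = np.cumsum(defl)
    # tolerance so an exact half at a vertex is not skipped by fp noise
    idx = int(np.searchsorted(cum, total / 2.0 - 1e-9 * max(total, 1.0), side="left"))
    return float(arcs[1 + idx])
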