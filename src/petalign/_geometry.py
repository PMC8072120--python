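"""Polyline geometry helpers shared across modules.

Coordinate convention (package-wide): points are float ``(x, y)`` pairs in
pixel units, 0-based, x rightward, y downward, with a pixel's center at
integer coordinates.  Polylines are ``(N, 2)`` arrays.
"""
from __future__ import annotations

import numpy as np

from .errors import InputError

__all__ = [
    "as_points",
    "polyline_arclength",
    "resample_polyline",
    "point_polyline_distance",
    "project_point_to_polyline",
    "split_closed_polyline",
    "signed_area",
    "luma",
]


def as_points(pts) -> np.ndarray:
    a = np.asarray(pts, dtype=float)
    if a.ndim != 2 or a.shape[1] != 2:
        raise InputError(f"expected an (N, 2) point array, got shape {a.shape}")
    return a


def polyline_arclength(pts: np.ndarray, closed: bool = False) -> np.ndarray:
    """Cumulative arc length at each vertex (length N, or N+1 if closed)."""
    p = as_points(pts)
    if closed:
        p = np.vstack([p, p[:1]])
    seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_polyline(pts, n: int, closed: bool = False) -> np.ndarray:
    """Resample a polyline to ``n`` vertices uniform in arc length.

    Open polylines keep both endpoints.  Closed polylines are resampled over
    the full perimeter starting at the first vertex; the duplicate closing
    vertex is not repeated.
    """
    p = as_points(pts)
    if len(p) < 2:
        raise InputError("polyline needs at least 2 vertices to resample")
    if n < 2:
        raise InputError("need n >= 2 resampled points")
    s = polyline_arclength(p, closed=closed)
    total = s[-1]
    if total <= 0:
        # degenerate: all vertices coincide
        return np.repeat(p[:1], n, axis=0)
    if closed:
        t = np.linspace(0.0, total, n, endpoint=False)
        src = np.vstack([p, p[:1]])
    else:
        t = np.linspace(0.0, total, n)
        src = p
    x = np.interp(t, s, src[:, 0])
    y = np.interp(t, s, src[:, 1])
    return np.column_stack([x, y])


def _segment_projection(point, a, b):
    """Project ``point`` onto segment a→b; return (t in [0,1], foot, dist)."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return 0.0, a, float(np.linalg.norm(point - a))
    t = float(np.clip((point - a) @ ab / denom, 0.0, 1.0))
    foot = a + t * ab
    return t, foot, float(np.linalg.norm(point - foot))


def point_polyline_distance(point, pts, closed: bool = False) -> float:
    """Minimum Euclidean distance from a point to a polyline."""
    p = as_points(pts)
    q = np.asarray(point, dtype=float)
    if closed:
        p = np.vstack([p, p[:1]])
    # vectorized point-to-segment distance over all segments
    a, b = p[:-1], p[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom = np.where(denom == 0, 1.0, denom)
    t = np.clip(np.einsum("ij,ij->i", q - a, ab) / denom, 0.0, 1.0)
    foot = a + t[:, None] * ab
    return float(np.min(np.linalg.norm(q - foot, axis=1)))


def project_point_to_polyline(point, pts, closed: bool = False):
    """Nearest point on a polyline.

    Returns ``(s, foot)`` where ``s`` is the arc-length position of the foot
    along the polyline and ``foot`` its coordinates.
    """
    p = as_points(pts)
    q = np.asarray(point, dtype=float)
    ring = np.vstack([p, p[:1]]) if closed else p
    s_cum = polyline_arclength(p, closed=closed)
    best = (np.inf, 0.0, p[0])
    for i in range(len(ring) - 1):
        t, foot, d = _segment_projection(q, ring[i], ring[i + 1])
        if d < best[0]:
            seg_len = s_cum[i + 1] - s_cum[i]
            best = (d, s_cum[i] + t * seg_len, foot)
    return best[1], best[2]


def split_closed_polyline(contour, p0, p1):
    """Split a closed polyline at the feet of two points; return both arcs.

    The split points themselves are inserted, so each returned open arc starts
    at the foot of ``p0`` and ends at the foot of ``p1`` (first arc follows
    the stored vertex order; second arc is the complement, also p0→p1).
    """
    c = as_points(contour)
    s0, f0 = project_point_to_polyline(p0, c, closed=True)
    s1, f1 = project_point_to_polyline(p1, c, closed=True)
    if np.allclose(f0, f1):
        raise InputError("split points coincide on the contour")
    s = polyline_arclength(c, closed=True)
    total = s[-1]

    def _walk(sa, sb):
        """Vertices strictly between arc positions sa→sb (forward)."""
        if sb < sa:
            sb += total
        out = [_point_at(c, s, sa % total)]
        # vertex arc positions, unwrapped over two turns
        for k in range(len(c) * 2):
            sv = s[k % len(c)] + (k // len(c)) * total
            if sa < sv < sb:
                out.append(c[k % len(c)])
        out.append(_point_at(c, s, sb % total))
        return np.array(out)

    arc_fwd = _walk(s0, s1)
    arc_bwd = _walk(s1, s0)[::-1]  # reversed so it also runs p0→p1
    return arc_fwd, arc_bwd


def _point_at(c, s, target):
    """Point at arc-length ``target`` along closed polyline ``c``."""
    ring = np.vstack([c, c[:1]])
    idx = int(np.searchsorted(s, target, side="right")) - 1
    idx = min(max(idx, 0), len(ring) - 2)
    seg = s[idx + 1] - s[idx]
    t = 0.0 if seg == 0 else (target - s[idx]) / seg
    return ring[idx] + t * (ring[idx + 1] - ring[idx])


def signed_area(pts) -> float:
    """Shoelace area of a closed polyline in image coordinates (y down)."""
    p = as_points(pts)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def luma(rgb: np.ndarray) -> np.ndarray:
    """ITU-R BT.601 luminance of an (..., 3) RGB array, same scale as input."""
    a = np.asarray(rgb, dtype=float)
    return 0.299 * a[..., 0] + 0.587 * a[..., 1] + 0.114 * a[..., 2]
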