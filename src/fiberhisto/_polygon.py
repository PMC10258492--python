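"""Low-level polygon geometry on label rasters.

Pixels are unit squares: pixel (r, c) has its center at integer coordinates
(x=c, y=r) and corners on the half-integer grid. Outer contours are traced
along the "cracks" between foreground and background pixels, so the shoelace
area of a traced contour equals the pixel count of the (hole-filled) region.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "trace_outer_contour",
    "polygon_area",
    "convex_hull_vertices",
    "min_feret_px",
    "max_feret_px",
]


def _left(d: tuple[int, int]) -> tuple[int, int]:
    # left turn of an axis-aligned step (row-down screen coordinates)
    return (-d[1], d[0])


def _right(d: tuple[int, int]) -> tuple[int, int]:
    return (d[1], -d[0])


def trace_outer_contour(binary: np.ndarray) -> np.ndarray:
    """Trace the outer crack boundary of a single filled region.

    Parameters
    ----------
    binary
        2-D boolean array containing one connected, hole-free region.

    Returns
    -------
    (N, 2) float array of (x, y) vertices on the half-integer grid,
    forming a closed ring (first vertex not repeated). Empty array for an
    empty input.

    Notes
    -----
    Directed boundary edges are emitted with the region on a fixed side, then
    chained into a single closed walk. At corners where the boundary pinches
    (diagonally touching pixels of the same region) the walk prefers the
    sharpest left turn, which keeps 8-connected regions on one contour.
    """
    B = np.asarray(binary, dtype=bool)
    if B.ndim != 2:
        raise ValueError("binary image must be 2-D")
    if not B.any():
        return np.empty((0, 2), dtype=float)

    H, W = B.shape
    P = np.zeros((H + 2, W + 2), dtype=bool)
    P[1:-1, 1:-1] = B

    top = B & ~P[:-2, 1:-1]
    right = B & ~P[1:-1, 2:]
    bottom = B & ~P[2:, 1:-1]
    left = B & ~P[1:-1, :-2]

    # start corner -> list of end corners, clockwise orientation in
    # (row, col) corner-lattice coordinates
    edges: dict[tuple[int, int], list[tuple[int, int]]] = {}

    def _emit(sr, sc, er, ec):
        edges.setdefault((sr, sc), []).append((er, ec))

    for r, c in zip(*np.nonzero(top)):
        _emit(r, c, r, c + 1)
    for r, c in zip(*np.nonzero(right)):
        _emit(r, c + 1, r + 1, c + 1)
    for r, c in zip(*np.nonzero(bottom)):
        _emit(r + 1, c + 1, r + 1, c)
    for r, c in zip(*np.nonzero(left)):
        _emit(r + 1, c, r, c)

    # top-left-most corner of the region cannot be a pinch corner, so the
    # walk is unambiguous at its start
    start = min(k for k, v in edges.items() if v)
    ends = edges[start]
    cur = min(ends)
    ends.remove(cur)
    path = [start, cur]
    d = (cur[0] - start[0], cur[1] - start[1])

    while cur != start:
        outs = edges.get(cur, [])
        if len(outs) == 1:
            nxt = outs.pop()
        elif not outs:  # pragma: no cover - malformed input
            raise RuntimeError("open boundary while tracing contour")
        else:
            for pref in (_left(d), d, _right(d)):
                cand = (cur[0] + pref[0], cur[1] + pref[1])
                if cand in outs:
                    nxt = cand
                    outs.remove(cand)
                    break
            else:  # pragma: no cover - cannot happen for crack boundaries
                raise RuntimeError("no turn available while tracing contour")
        d = (nxt[0] - cur[0], nxt[1] - cur[1])
        path.append(nxt)
        cur = nxt

    verts = np.asarray(path[:-1], dtype=float)
    # corner lattice (r, c) -> pixel-centered (x, y) = (c - 0.5, r - 0.5)
    return np.column_stack([verts[:, 1] - 0.5, verts[:, 0] - 0.5])


def polygon_area(vertices: np.ndarray) -> float:
    """Shoelace area of a closed ring given as (N, 2) (x, y) vertices."""
    v = np.asarray(vertices, dtype=float)
    if len(v) < 3:
        return 0.0
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def convex_hull_vertices(points: np.ndarray) -> np.ndarray | None:
    """Hull vertices in counter-clockwise order, or None if degenerate."""
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if len(pts) < 3:
        return None
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return None  # collinear
    return pts[hull.vertices]


def min_feret_px(points: np.ndarray) -> float:
    """Minimum caliper (Feret) width of a point set, in the same units.

    The minimum width of a convex polygon is attained with one caliper jaw
    flush against a hull edge, so it suffices to take, for each hull edge,
    the largest vertex distance to the edge's supporting line, and minimise
    over edges.
    """
    hv = convex_hull_vertices(points)
    if hv is None:
        return 0.0
    edges = np.roll(hv, -1, axis=0) - hv
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    width = np.inf
    for a, e, L in zip(hv, edges, lengths):
        if L == 0:
            continue
        rel = hv - a
        d = np.abs(e[0] * rel[:, 1] - e[1] * rel[:, 0]) / L
        width = min(width, d.max())
    return float(width)


def max_feret_px(points: np.ndarray) -> float:
    """Maximum caliper (Feret) diameter: largest pairwise hull distance."""
    hv = convex_hull_vertices(points)
    if hv is None:
        pts = np.unique(np.asarray(points, dtype=float), axis=0)
        if len(pts) < 2:
            return 0.0
        hv = pts
    diff = hv[:, None, :] - hv[None, :, :]
    return float(np.sqrt((diff**2).sum(-1)).max())
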