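"""Independent brute-force oracles shared by the test modules."""

from collections import deque

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import Point, Polygon


def flood_fill_hull_oracle(mask):
    """Hole filling by border flood fill, then a point hull via shapely.

    Independent of the package's implementation: holes are removed by
    flood-filling the background from the image border, and the convex
    hull is rasterized by testing each pixel center against a shapely
    polygon of the hull vertices.
    """
    mask = np.asarray(mask) > 0
    h, w = mask.shape
    outside = np.zeros_like(mask, dtype=bool)
    queue = deque()
    for r in range(h):
        for c in (0, w - 1):
            if not mask[r, c] and not outside[r, c]:
                outside[r, c] = True
                queue.append((r, c))
    for c in range(w):
        for r in (0, h - 1):
            if not mask[r, c] and not outside[r, c]:
                outside[r, c] = True
                queue.append((r, c))
    while queue:
        r, c = queue.popleft()
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and not mask[rr, cc] \
                    and not outside[rr, cc]:
                outside[rr, cc] = True
                queue.append((rr, cc))
    filled = ~outside
    pts = np.argwhere(filled)
    if len(pts) < 3:
        return filled.astype(np.uint8)
    try:
        hull = ConvexHull(pts.astype(float))
    except QhullError:
        return filled.astype(np.uint8)
    poly = Polygon(pts[hull.vertices]).buffer(1e-9)
    out = np.zeros((h, w), dtype=np.uint8)
    for r in range(h):
        for c in range(w):
            if poly.covers(Point(r, c)):
                out[r, c] = 1
    return out
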