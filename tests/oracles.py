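"""Independent reference implementations used only by the tests.

These are deliberately separate code paths from the package: a per-cell
ray-marching viewshed oracle, an even-odd ray-cast point-in-polygon test,
and an exhaustive-enumeration CART split search.  They share only the
*published definitions* (sampling rule, strict-inequality blocking, the Gini
gain formula and tie rules) with the implementations they check.
"""

from __future__ import annotations

import math

import numpy as np

# ---------------------------------------------------------------------------
# viewshed
# ---------------------------------------------------------------------------


def oracle_bilinear(values: np.ndarray, fr: float, fc: float) -> float:
    """Bilinear interpolation, edge-clamped, blending rows before columns
    (the reverse blend order of the engine)."""
    n_rows, n_cols = values.shape
    r0 = math.floor(fr)
    c0 = math.floor(fc)
    tr, tc = fr - r0, fc - c0
    if r0 < 0:
        r0, tr = 0, 0.0
    if c0 < 0:
        c0, tc = 0, 0.0
    if r0 >= n_rows - 1:
        r0, tr = n_rows - 1, 0.0
    if c0 >= n_cols - 1:
        c0, tc = n_cols - 1, 0.0
    r1, c1 = min(r0 + 1, n_rows - 1), min(c0 + 1, n_cols - 1)
    left = values[r0, c0] * (1 - tr) + values[r1, c0] * tr
    right = values[r0, c1] * (1 - tr) + values[r1, c1] * tr
    return left * (1 - tc) + right * tc


def oracle_visible(
    values: np.ndarray,
    x0: float,
    y0: float,
    cs: float,
    ox: float,
    oy: float,
    oz: float,
    row: int,
    col: int,
    step: float,
) -> bool:
    """Ray-marching line-of-sight: sample the surface strictly between
    observer and target cell center; any sample strictly above the sight
    line blocks."""
    tx = x0 + (col + 0.5) * cs
    ty = y0 + (row + 0.5) * cs
    dist = math.hypot(tx - ox, ty - oy)
    orow = int((oy - y0) / cs)
    ocol = int((ox - x0) / cs)
    if (orow, ocol) == (row, col) or dist == 0.0:
        return True
    tz = values[row, col]
    s = step
    while s < dist:
        t = s / dist
        sx = ox + t * (tx - ox)
        sy = oy + t * (ty - oy)
        sz = oracle_bilinear(values, (sy - y0) / cs - 0.5, (sx - x0) / cs - 0.5)
        if sz > oz + t * (tz - oz):
            return False
        s += step
    return True


def oracle_viewshed_counts(
    values: np.ndarray,
    x0: float,
    y0: float,
    cs: float,
    observers: list[tuple[float, float, float]],
    max_distance: float,
    step: float,
) -> np.ndarray:
    n_rows, n_cols = values.shape
    counts = np.zeros((n_rows, n_cols), dtype=int)
    for row in range(n_rows):
        for col in range(n_cols):
            tx = x0 + (col + 0.5) * cs
            ty = y0 + (row + 0.5) * cs
            for ox, oy, oz in observers:
                if math.hypot(tx - ox, ty - oy) > max_distance:
                    continue
                if oracle_visible(values, x0, y0, cs, ox, oy, oz, row, col, step):
                    counts[row, col] += 1
    return counts


# ---------------------------------------------------------------------------
# point in polygon (even-odd ray cast)
# ---------------------------------------------------------------------------


def oracle_point_in_polygon(ring: list[tuple[float, float]], x: float, y: float) -> bool:
    """Even-odd rule with explicit on-edge detection (edges count inside)."""
    n = len(ring)
    inside = False
    for i in range(n - 1):
        (x1, y1), (x2, y2) = ring[i], ring[i + 1]
        # on-segment check
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        if abs(cross) < 1e-12:
            if min(x1, x2) - 1e-12 <= x <= max(x1, x2) + 1e-12 and min(y1, y2) - 1e-12 <= y <= max(y1, y2) + 1e-12:
                return True
        if (y1 > y) != (y2 > y):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xint:
                inside = not inside
    return inside


# ---------------------------------------------------------------------------
# exhaustive CART split search
# ---------------------------------------------------------------------------

MIN_GAIN = 1e-9


def _imp(a: int, b: int) -> float:
    n = a + b
    return n - (a * a + b * b) / n


def oracle_best_split(X: np.ndarray, y: np.ndarray, columns: list[str], min_leaf: int):
    """Enumerate every (variable, threshold) candidate; return the best rule
    as (col_index, threshold) or None.  Ties: earlier column, then smaller
    threshold; gains must exceed MIN_GAIN."""
    n = len(y)
    n1 = int(y.sum())
    parent = _imp(n - n1, n1)
    best = None
    best_gain = MIN_GAIN
    for j in range(len(columns)):
        vals = X[:, j]
        for thr_lo, thr_hi in zip(sorted(set(vals))[:-1], sorted(set(vals))[1:]):
            thr = (thr_lo + thr_hi) / 2.0
            left = vals < thr
            ln = int(left.sum())
            if ln < min_leaf or n - ln < min_leaf:
                continue
            l1 = int(y[left].sum())
            r1 = n1 - l1
            gain = parent - (_imp(ln - l1, l1) + _imp(n - ln - r1, r1))
            if gain > best_gain:
                best_gain = gain
                best = (j, thr)
    return best


def oracle_grow(X: np.ndarray, y: np.ndarray, columns: list[str], min_split: int, min_leaf: int, max_depth: int):
    """Recursive exhaustive-search tree; nodes as nested dicts."""
    n = len(y)
    n1 = int(y.sum())
    node = {"n": n, "counts": (n - n1, n1)}
    if max_depth <= 0 or n < min_split or n1 == 0 or n1 == n:
        return node
    found = oracle_best_split(X, y, columns, min_leaf)
    if found is None:
        return node
    j, thr = found
    node["variable"] = columns[j]
    node["threshold"] = thr
    left = X[:, j] < thr
    node["left"] = oracle_grow(X[left], y[left], columns, min_split, min_leaf, max_depth - 1)
    node["right"] = oracle_grow(X[~left], y[~left], columns, min_split, min_leaf, max_depth - 1)
    return node


def tree_to_dict(node):
    """Convert a package TreeNode to the oracle's nested-dict shape."""
    d = {"n": node.n, "counts": tuple(node.class_counts)}
    if node.children is not None:
        d["variable"] = node.split.variable
        d["threshold"] = node.split.threshold
        d["left"] = tree_to_dict(node.children[0])
        d["right"] = tree_to_dict(node.children[1])
    return d
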