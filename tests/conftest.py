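"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately use different formulations from the package
code (plain loops, plane-foot/edge-clamp geometry, textbook ANOVA sums) so
that agreement is a genuine cross-check, not a tautology.
"""

from __future__ import annotations

import numpy as np
import pytest

from bstmap.geometry import ProjectedMap, SurfaceMesh


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)


def make_projected_map(x, y, distances=None, flags=None, side="right"):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if distances is None:
        distances = np.full(len(x), 0.5)
    if flags is None:
        flags = np.full(len(x), "valid", dtype=object)
    return ProjectedMap(x=x, y=y, distances=np.asarray(distances, dtype=float),
                        flags=np.asarray(flags, dtype=object), side=side)


# ---------------------------------------------------------------------------
# geometry oracle: exhaustive per-triangle nearest point via plane foot /
# clamped edges, scalar loops throughout


def _segment_distance(p, a, b):
    ab = b - a
    denom = float(np.dot(ab, ab))
    t = 0.0 if denom == 0 else min(1.0, max(0.0, float(np.dot(p - a, ab)) / denom))
    return float(np.linalg.norm(p - (a + t * ab)))


def _triangle_distance(p, a, b, c):
    best = min(
        _segment_distance(p, a, b),
        _segment_distance(p, b, c),
        _segment_distance(p, c, a),
    )
    n = np.cross(b - a, c - a)
    norm = np.linalg.norm(n)
    if norm > 1e-14:
        n = n / norm
        foot = p - np.dot(p - a, n) * n
        basis = np.column_stack([b - a, c - a])
        st, *_ = np.linalg.lstsq(basis, foot - a, rcond=None)
        s, t = float(st[0]), float(st[1])
        if s >= -1e-12 and t >= -1e-12 and s + t <= 1 + 1e-12:
            best = min(best, float(np.linalg.norm(p - foot)))
    return best


def brute_force_surface_distance(points, mesh: SurfaceMesh):
    """Exhaustive minimum over every triangle, one pair at a time."""
    points = np.atleast_2d(points)
    tris = mesh.triangles
    out = np.empty(len(points))
    for i, p in enumerate(points):
        out[i] = min(_triangle_distance(p, *tri) for tri in tris)
    return out


# ---------------------------------------------------------------------------
# ICC oracle: textbook two-way ANOVA with explicit loops


def icc_a1_oracle(data):
    data = [list(map(float, row)) for row in np.asarray(data)]
    n = len(data)
    k = len(data[0])
    grand = sum(sum(row) for row in data) / (n * k)
    row_means = [sum(row) / k for row in data]
    col_means = [sum(data[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((m - grand) ** 2 for m in row_means)
    ss_cols = n * sum((m - grand) ** 2 for m in col_means)
    ss_err = sum(
        (data[i][j] - row_means[i] - col_means[j] + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


# ---------------------------------------------------------------------------
# BST oracle: plain 16-term re-summation


def tws_oracle(mean_distances, cyst_flags=None):
    """Independent re-summation of the 16 weighted squares (right-foot frame)."""
    offsets = [-0.375, -0.125, 0.125, 0.375]
    sx = sy = 0.0
    for row in range(4):
        for col in range(4):
            i = row * 4 + col
            if cyst_flags is not None and cyst_flags[i]:
                dmc = 1.0
            else:
                d = mean_distances[i]
                if not np.isfinite(d):
                    continue
                dmc = 1.0 - d
            sx += dmc * offsets[col]
            sy += dmc * offsets[row]
    return sx / 16, sy / 16
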