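"""Articular surface meshes and inter-surface distance maps.

The ankle joint-space analysis starts from two triangulated articular
surfaces: the talar dome (source) and the tibial plafond (target).  For every
articular vertex of the dome the *distance map* records the Euclidean
distance to the nearest point anywhere on the plafond surface (nearest point
on a triangle, not nearest vertex).  Vertices labelled ``cyst`` are kept as
holes in the map (they score maximally downstream); vertices labelled
``osteophyte`` are extra-articular and excluded from all analysis.

The map is then projected onto the axial plane in an anatomical frame with
+x = lateral and +y = anterior; left feet are mirrored at projection time so
the downstream grid scoring can use a single right-foot convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
from scipy.spatial import cKDTree

from .errors import ValidationError

logger = logging.getLogger(__name__)

REGION_LABELS = ("articular", "osteophyte", "cyst")
FLAG_VALID = "valid"
FLAG_CYST = "cyst"
FLAG_EXCLUDED = "excluded"


@dataclass
class SurfaceMesh:
    """A triangulated articular surface in millimetres.

    Parameters
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array
        Triangle vertex indices.
    region_labels : (n,) str array, optional
        Per-vertex region, one of ``articular`` (default), ``osteophyte``
        (extra-articular, excluded) or ``cyst`` (subchondral cyst hole).
    """

    vertices: np.ndarray
    faces: np.ndarray
    region_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValidationError("vertices must be an (n, 3) array")
        if not np.isfinite(self.vertices).all():
            raise ValidationError("vertex coordinates must be finite")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3 or len(self.faces) == 0:
            raise ValidationError("faces must be a non-empty (m, 3) index array")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise ValidationError("face indices reference non-existent vertices")
        if self.region_labels is None:
            self.region_labels = np.full(len(self.vertices), "articular", dtype=object)
        else:
            self.region_labels = np.asarray(self.region_labels, dtype=object)
            if self.region_labels.shape != (len(self.vertices),):
                raise ValidationError("region_labels must have one entry per vertex")
            bad = set(self.region_labels) - set(REGION_LABELS)
            if bad:
                raise ValidationError(f"unknown region labels: {sorted(bad)}")
        if not np.any(self.region_labels == "articular"):
            raise ValidationError("mesh has no articular vertices")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def triangles(self) -> np.ndarray:
        """(m, 3, 3) array of triangle corner coordinates."""
        return self.vertices[self.faces]


@dataclass
class DistanceMap:
    """Sampled talus→tibia distances at talar dome vertices.

    ``distances`` holds NaN wherever ``flags`` is not ``valid`` (cyst holes
    carry no distance; osteophyte vertices are excluded).
    """

    positions: np.ndarray  # (n, 3) mm
    distances: np.ndarray  # (n,) mm, NaN for non-valid samples
    flags: np.ndarray  # (n,) str in {valid, cyst, excluded}
    side: str = "right"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        self.flags = np.asarray(self.flags, dtype=object)
        if self.side not in ("left", "right"):
            raise ValidationError("side must be 'left' or 'right'")
        n = len(self.positions)
        if self.distances.shape != (n,) or self.flags.shape != (n,):
            raise ValidationError("positions, distances and flags must align")
        valid = self.flags == FLAG_VALID
        if np.any(self.distances[valid] < 0) or not np.isfinite(self.distances[valid]).all():
            raise ValidationError("valid samples must have finite distance >= 0")
        if not np.any(valid | (self.flags == FLAG_CYST)):
            raise ValidationError("distance map has no valid or cyst samples")


@dataclass
class ProjectedMap:
    """Axial-plane view of a :class:`DistanceMap`.

    Coordinates are anatomical: +x = lateral, +y = anterior, for both sides
    (left feet were mirrored during projection).
    """

    x: np.ndarray  # (n,) mm, + = lateral
    y: np.ndarray  # (n,) mm, + = anterior
    distances: np.ndarray  # (n,) mm, NaN for cyst samples
    flags: np.ndarray  # (n,) str
    projection_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    side: str = "right"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        self.flags = np.asarray(self.flags, dtype=object)
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValidationError("projected coordinates must be finite")


# ---------------------------------------------------------------------------
# mesh I/O


def load_surface(
    path: str | Path,
    fmt: str | None = None,
    labels_path: str | Path | None = None,
) -> SurfaceMesh:
    """Load a PLY/STL/OBJ surface, with optional sidecar region labels.

    The sidecar is a CSV with columns ``vertex_index,label`` next to the mesh
    (``<stem>.labels.csv``) or given explicitly via ``labels_path``.  Vertices
    not listed default to ``articular``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mesh file not found: {path}")
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in ("ply", "stl", "obj"):
        raise ValidationError(f"unsupported mesh format: {fmt!r}")
    try:
        loaded = trimesh.load(str(path), file_type=fmt, process=False, force="mesh")
    except Exception as exc:  # trimesh raises a zoo of parse errors
        raise IOError(f"could not read mesh file {path}: {exc}") from exc
    vertices = np.asarray(loaded.vertices, dtype=float)
    faces = np.asarray(loaded.faces, dtype=int)
    if len(faces) == 0:
        raise ValidationError(f"mesh {path} has no faces")

    labels = None
    if labels_path is None:
        candidate = path.with_suffix(".labels.csv")
        labels_path = candidate if candidate.exists() else None
    if labels_path is not None:
        table = pd.read_csv(labels_path)
        if not {"vertex_index", "label"}.issubset(table.columns):
            raise ValidationError(
                f"label sidecar {labels_path} must have columns vertex_index,label"
            )
        idx = table["vertex_index"].to_numpy(dtype=int)
        if idx.min() < 0 or idx.max() >= len(vertices):
            raise ValidationError(f"label sidecar {labels_path} indexes missing vertices")
        labels = np.full(len(vertices), "articular", dtype=object)
        labels[idx] = table["label"].astype(str).to_numpy()
    return SurfaceMesh(vertices=vertices, faces=faces, region_labels=labels)


def save_surface(mesh: SurfaceMesh, path: str | Path) -> None:
    """Write a surface as ASCII PLY/STL/OBJ plus a label sidecar if non-trivial."""
    path = Path(path)
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    fmt = path.suffix.lstrip(".").lower()
    file_type = {"stl": "stl_ascii"}.get(fmt, fmt)
    tm.export(str(path), file_type=file_type)
    if np.any(mesh.region_labels != "articular"):
        nontrivial = np.nonzero(mesh.region_labels != "articular")[0]
        pd.DataFrame(
            {"vertex_index": nontrivial, "label": mesh.region_labels[nontrivial]}
        ).to_csv(path.with_suffix(".labels.csv"), index=False)


# ---------------------------------------------------------------------------
# nearest point on triangle (Ericson's region method, vectorized)


def _closest_point_on_triangles(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on each triangle ``tri[i]`` to each point ``p[i]``.

    ``p`` is (n, 3); ``tri`` is (n, 3, 3).  Pairwise (not cross-product)
    evaluation; callers broadcast as needed.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    out = np.empty_like(p)
    remaining = np.ones(len(p), dtype=bool)

    def take(mask: np.ndarray, values: np.ndarray) -> None:
        nonlocal remaining
        sel = remaining & mask
        out[sel] = values[sel] if values.shape[0] == len(p) else values
        remaining &= ~mask

    # vertex regions
    take((d1 <= 0) & (d2 <= 0), a)
    take((d3 >= 0) & (d4 <= d3), b)
    # edge ab
    m = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    sel = remaining & m
    if sel.any():
        t = d1[sel] / (d1[sel] - d3[sel])
        out[sel] = a[sel] + t[:, None] * ab[sel]
        remaining &= ~m
    take((d6 >= 0) & (d5 <= d6), c)
    # edge ac
    m = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    sel = remaining & m
    if sel.any():
        t = d2[sel] / (d2[sel] - d6[sel])
        out[sel] = a[sel] + t[:, None] * ac[sel]
        remaining &= ~m
    # edge bc
    m = (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
    sel = remaining & m
    if sel.any():
        t = (d4[sel] - d3[sel]) / ((d4[sel] - d3[sel]) + (d5[sel] - d6[sel]))
        out[sel] = b[sel] + t[:, None] * (c[sel] - b[sel])
        remaining &= ~m
    # face interior
    if remaining.any():
        denom = va[remaining] + vb[remaining] + vc[remaining]
        v = vb[remaining] / denom
        w = vc[remaining] / denom
        out[remaining] = a[remaining] + v[:, None] * ab[remaining] + w[:, None] * ac[remaining]
    return out


def points_to_surface_distance(points: np.ndarray, target: SurfaceMesh) -> np.ndarray:
    """Exact distance from each point to the nearest point on the target surface.

    A KD-tree on triangle centroids prunes candidates without losing
    exactness: any triangle whose nearest point could beat the current upper
    bound ``ub`` must have its centroid within ``ub + r_max`` of the query,
    where ``r_max`` bounds the centroid-to-corner radius over all triangles.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tri = target.triangles
    centroids = tri.mean(axis=1)
    radii = np.linalg.norm(tri - centroids[:, None, :], axis=2).max(axis=1)
    r_max = radii.max()
    tree = cKDTree(centroids)

    k = min(8, len(tri))
    _, idx = tree.query(points, k=k)
    idx = np.atleast_2d(idx)
    rep = np.repeat(points, k, axis=0)
    cand = _closest_point_on_triangles(rep, tri[idx.reshape(-1)])
    ub = np.linalg.norm(rep - cand, axis=1).reshape(len(points), k).min(axis=1)

    groups = tree.query_ball_point(points, ub + r_max + 1e-12)
    counts = np.fromiter((len(g) for g in groups), dtype=int, count=len(groups))
    flat = np.concatenate([np.asarray(g, dtype=int) for g in groups])
    rep = np.repeat(points, counts, axis=0)
    closest = _closest_point_on_triangles(rep, tri[flat])
    d_all = np.linalg.norm(rep - closest, axis=1)
    offsets = np.concatenate(([0], np.cumsum(counts)[:-1]))
    return np.minimum.reduceat(d_all, offsets)


def compute_distance_map(source: SurfaceMesh, target: SurfaceMesh, side: str = "right") -> DistanceMap:
    """Distance map of the talar dome (source) against the tibial plafond (target).

    Distances are evaluated at articular source vertices; ``cyst`` vertices
    are flagged holes, ``osteophyte`` vertices are excluded.
    """
    if len(target.faces) == 0:
        raise ValidationError("target mesh has no faces")
    flags = np.full(source.n_vertices, FLAG_VALID, dtype=object)
    flags[source.region_labels == "cyst"] = FLAG_CYST
    flags[source.region_labels == "osteophyte"] = FLAG_EXCLUDED
    distances = np.full(source.n_vertices, np.nan)
    articular = flags == FLAG_VALID
    distances[articular] = points_to_surface_distance(source.vertices[articular], target)
    return DistanceMap(
        positions=source.vertices.copy(), distances=distances, flags=flags, side=side
    )


# ---------------------------------------------------------------------------
# axial projection


def project_axial(
    dm: DistanceMap,
    axis: np.ndarray = (0.0, 0.0, 1.0),
    ap_direction: np.ndarray = (0.0, 1.0, 0.0),
    side: str | None = None,
) -> ProjectedMap:
    """Project the distance map onto the plane normal to ``axis``.

    The in-plane frame has +y along the anterior direction and +x completing
    a right-handed frame with the axis; for left feet x is then mirrored so
    that +x is always the anatomically lateral direction.  Excluded
    (osteophyte) samples are dropped; distances are carried unchanged.
    """
    side = side or dm.side
    if side not in ("left", "right"):
        raise ValidationError("side must be 'left' or 'right'")
    axis = np.asarray(axis, dtype=float)
    ap = np.asarray(ap_direction, dtype=float)
    axis = axis / np.linalg.norm(axis)
    ap = ap / np.linalg.norm(ap)
    if np.linalg.norm(np.cross(axis, ap)) < 1e-9:
        raise ValidationError("projection axis and AP direction are parallel")
    y_dir = ap - np.dot(ap, axis) * axis
    y_dir /= np.linalg.norm(y_dir)
    x_dir = np.cross(y_dir, axis)  # x cross y = axis (right-handed)

    keep = dm.flags != FLAG_EXCLUDED
    pos = dm.positions[keep]
    x = pos @ x_dir
    y = pos @ y_dir
    if side == "left":
        x = -x
    return ProjectedMap(
        x=x,
        y=y,
        distances=dm.distances[keep],
        flags=dm.flags[keep],
        projection_axis=axis,
        side=side,
    )
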