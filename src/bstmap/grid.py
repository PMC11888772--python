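"""The Battleship technique: 16-square grid scoring of a talar dome distance map.

The projected dome is enclosed in its bounding rectangle, which is split into
a 4x4 grid of equal squares (rows run posterior→anterior, columns
medial→lateral).  Each square receives a distance mapping coefficient

    DMC = 1 − mean intraarticular distance (mm),

with cyst samples contributing distance 0 so a fully cystic square scores the
maximal DMC of exactly 1.  Each DMC is weighted by the square centre's
normalized coordinates (±0.125, ±0.375 in units of the rectangle size) and
the 16 weighted terms are summed and divided by 16:

    TWSx = Σ DMC_i·cx_i / 16,   TWSy = Σ DMC_i·cy_i / 16.

(TWSx, TWSy) is the distance-map weighted-sum point.  With +x = lateral and
+y = anterior, TWSx < 0 places the contact focus medially (varus pattern),
TWSx > 0 laterally (valgus); TWSy > 0 anteriorly, TWSy < 0 posteriorly; an
exactly zero component is neutral.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .geometry import FLAG_CYST, FLAG_EXCLUDED, ProjectedMap

logger = logging.getLogger(__name__)

#: normalized centre offsets of grid rows/columns (posterior→anterior /
#: medial→lateral), in units of the full rectangle extent.
CENTER_OFFSETS = np.array([-0.375, -0.125, 0.125, 0.375])

#: Σ cx² over the 16 squares; the lever arm of a unit linear gradient.
SUM_CX_SQUARED = 1.25

#: TWS response to a unit distance gradient along one axis: −Σcx²/16.
GRADIENT_GAIN = -SUM_CX_SQUARED / 16  # = -0.078125


@dataclass
class GridSquare:
    row: int  # 0..3, posterior → anterior
    col: int  # 0..3, medial → lateral
    quadrant: str  # AL | AM | PL | PM
    center_norm: tuple[float, float]  # (cx, cy) normalized units
    x_bounds: tuple[float, float]  # mm
    y_bounds: tuple[float, float]  # mm


@dataclass
class DomeGrid:
    """4x4 grid over the bounding rectangle of the projected dome."""

    center: tuple[float, float]  # anatomical centre, mm
    x_min: float
    x_max: float
    y_min: float
    y_max: float
    squares: list[GridSquare]

    @property
    def half_width_x(self) -> float:
        return (self.x_max - self.x_min) / 2

    @property
    def half_width_y(self) -> float:
        return (self.y_max - self.y_min) / 2


@dataclass
class SquareStat:
    """Per-square scoring record."""

    row: int
    col: int
    quadrant: str
    center_norm: tuple[float, float]
    n_samples: int
    mean_distance: float  # mm, NaN when empty
    cyst_fraction: float
    flag_empty: bool
    dmc: float = np.nan
    wsq_x: float = 0.0
    wsq_y: float = 0.0


@dataclass
class BSTResult:
    tws_x: float
    tws_y: float
    coronal_class: str  # varus | valgus | neutral
    sagittal_class: str  # anterior | posterior | neutral
    square_stats: list[SquareStat]
    side: str = "right"


def _nonexcluded(pm: ProjectedMap) -> np.ndarray:
    return pm.flags != FLAG_EXCLUDED


def find_anatomical_center(pm: ProjectedMap) -> tuple[float, float]:
    """Midpoint of the medio-lateral and antero-posterior extents.

    Mirrors the clinical construction: the articular surface is measured
    posterior→anterior and medial→lateral and the intersection of the two
    mid-measurements is the anatomical centre.  Osteophyte (excluded)
    samples do not participate.
    """
    keep = _nonexcluded(pm)
    if not keep.any():
        raise ValidationError("projected map has no non-excluded samples")
    x, y = pm.x[keep], pm.y[keep]
    return (float(x.min() + x.max()) / 2, float(y.min() + y.max()) / 2)


def build_grid(pm: ProjectedMap, center: tuple[float, float] | None = None) -> DomeGrid:
    """Build the 16-square grid on the bounding rectangle of the dome.

    The rectangle is always split into 4x4 *equal* squares; the anatomical
    centre only anchors the X/Y axes that define quadrant membership, which
    each square inherits from its own centre.
    """
    keep = _nonexcluded(pm)
    if not keep.any():
        raise ValidationError("projected map has no non-excluded samples")
    x, y = pm.x[keep], pm.y[keep]
    x_min, x_max = float(x.min()), float(x.max())
    y_min, y_max = float(y.min()), float(y.max())
    if x_max <= x_min or y_max <= y_min:
        raise ValidationError("bounding rectangle has zero area")
    if center is None:
        center = find_anatomical_center(pm)
    cx0, cy0 = center
    if not (x_min <= cx0 <= x_max and y_min <= cy0 <= y_max):
        raise ValidationError("anatomical centre lies outside the sample extents")

    width, depth = x_max - x_min, y_max - y_min
    squares = []
    for row in range(4):
        for col in range(4):
            sq_cx_mm = x_min + (col + 0.5) / 4 * width
            sq_cy_mm = y_min + (row + 0.5) / 4 * depth
            lat = sq_cx_mm > cx0  # lateral of the anatomical centre axis
            ant = sq_cy_mm > cy0
            quadrant = ("A" if ant else "P") + ("L" if lat else "M")
            squares.append(
                GridSquare(
                    row=row,
                    col=col,
                    quadrant=quadrant,
                    center_norm=(float(CENTER_OFFSETS[col]), float(CENTER_OFFSETS[row])),
                    x_bounds=(x_min + col / 4 * width, x_min + (col + 1) / 4 * width),
                    y_bounds=(y_min + row / 4 * depth, y_min + (row + 1) / 4 * depth),
                )
            )
    return DomeGrid(center=(cx0, cy0), x_min=x_min, x_max=x_max, y_min=y_min, y_max=y_max, squares=squares)


def square_mean_distances(pm: ProjectedMap, grid: DomeGrid) -> list[SquareStat]:
    """Assign samples to squares and average distances per square.

    Square bounds are half-open (a sample exactly on an interior boundary
    belongs to the square on the positive side); the last row/column is
    closed.  Cyst samples count as distance 0 and feed ``cyst_fraction``.
    Empty squares are flagged, not fatal.
    """
    keep = _nonexcluded(pm)
    x, y = pm.x[keep], pm.y[keep]
    d = pm.distances[keep]
    flags = pm.flags[keep]
    width = grid.x_max - grid.x_min
    depth = grid.y_max - grid.y_min
    col = np.clip(np.floor((x - grid.x_min) / width * 4).astype(int), 0, 3)
    row = np.clip(np.floor((y - grid.y_min) / depth * 4).astype(int), 0, 3)
    sq_index = row * 4 + col

    d_eff = np.where(flags == FLAG_CYST, 0.0, d)
    stats = []
    for sq in grid.squares:
        i = sq.row * 4 + sq.col
        in_sq = sq_index == i
        n = int(in_sq.sum())
        if n == 0:
            stats.append(
                SquareStat(
                    row=sq.row, col=sq.col, quadrant=sq.quadrant,
                    center_norm=sq.center_norm, n_samples=0,
                    mean_distance=np.nan, cyst_fraction=0.0, flag_empty=True,
                )
            )
            continue
        cyst_fraction = float((flags[in_sq] == FLAG_CYST).mean())
        stats.append(
            SquareStat(
                row=sq.row, col=sq.col, quadrant=sq.quadrant,
                center_norm=sq.center_norm, n_samples=n,
                mean_distance=float(d_eff[in_sq].mean()),
                cyst_fraction=cyst_fraction, flag_empty=False,
            )
        )
    return stats


def compute_dmc(mean_distance: float, cyst_fraction: float = 0.0, flag_empty: bool = False) -> float:
    """Distance mapping coefficient of a square: 1 − mean distance (mm).

    Cyst samples already enter the mean as distance 0, so a fully cystic
    square yields exactly 1, the maximal DMC.  Empty squares have no DMC
    (NaN) and contribute weight 0 downstream.  Distances above 1 mm give a
    negative DMC; that is the formula's intended extension.
    """
    if flag_empty:
        return float("nan")
    if not np.isfinite(mean_distance) or mean_distance < 0:
        raise ValidationError("mean distance must be finite and >= 0")
    if not 0.0 <= cyst_fraction <= 1.0:
        raise ValidationError("cyst_fraction must lie in [0, 1]")
    return 1.0 - mean_distance


def compute_weighted_sums(stats: list[SquareStat]) -> tuple[float, float]:
    """Fill per-square WSQ values and return (TWSx, TWSy).

    WSQx = DMC·cx, WSQy = DMC·cy; empty squares contribute 0 but the divisor
    stays 16 ("the total number of squares").
    """
    if len(stats) != 16:
        raise ValidationError(f"expected 16 square stats, got {len(stats)}")
    tws_x = tws_y = 0.0
    for s in stats:
        if s.flag_empty or not np.isfinite(s.dmc):
            s.wsq_x = s.wsq_y = 0.0
        else:
            s.wsq_x = s.dmc * s.center_norm[0]
            s.wsq_y = s.dmc * s.center_norm[1]
        tws_x += s.wsq_x
        tws_y += s.wsq_y
    return tws_x / 16, tws_y / 16


def classify(
    tws_x: float,
    tws_y: float,
    zero_tol: float = 0.0,
    decimals: int | None = 3,
) -> tuple[str, str]:
    """Assign coronal and sagittal contact-pattern classes from the TWS point.

    With +x = lateral, +y = anterior: a medial TWSx (negative) is varus, a
    lateral one valgus; an anterior TWSy is anterior, a posterior one
    posterior; a component of exactly 0 (after rounding to ``decimals``,
    default 3, and within ``zero_tol``) is neutral.
    """
    if not (np.isfinite(tws_x) and np.isfinite(tws_y)):
        raise ValidationError("TWS components must be finite")
    if zero_tol < 0:
        raise ValidationError("zero_tol must be >= 0")
    if decimals is not None:
        tws_x = round(tws_x, decimals)
        tws_y = round(tws_y, decimals)
    if tws_x < -zero_tol:
        coronal = "varus"
    elif tws_x > zero_tol:
        coronal = "valgus"
    else:
        coronal = "neutral"
    if tws_y > zero_tol:
        sagittal = "anterior"
    elif tws_y < -zero_tol:
        sagittal = "posterior"
    else:
        sagittal = "neutral"
    return coronal, sagittal


def _grid_square_stats(
    mean_distances: np.ndarray, cyst_flags: np.ndarray
) -> list[SquareStat]:
    """SquareStats for a mesh-free 16-value table (row-major, canonical frame)."""
    stats = []
    for row in range(4):
        for col in range(4):
            i = row * 4 + col
            cx = float(CENTER_OFFSETS[col])
            cy = float(CENTER_OFFSETS[row])
            quadrant = ("A" if cy > 0 else "P") + ("L" if cx > 0 else "M")
            cystic = bool(cyst_flags[i])
            d = mean_distances[i]
            empty = not cystic and not np.isfinite(d)
            stats.append(
                SquareStat(
                    row=row, col=col, quadrant=quadrant, center_norm=(cx, cy),
                    n_samples=0 if empty else 1,
                    mean_distance=0.0 if cystic else (np.nan if empty else float(d)),
                    cyst_fraction=1.0 if cystic else 0.0,
                    flag_empty=empty,
                )
            )
    return stats


def score_squares(stats: list[SquareStat], zero_tol: float = 0.0,
                  decimals: int | None = 3, side: str = "right") -> BSTResult:
    """DMC → weighted sums → classification for prepared square stats."""
    for s in stats:
        s.dmc = compute_dmc(s.mean_distance, s.cyst_fraction, s.flag_empty)
    tws_x, tws_y = compute_weighted_sums(stats)
    coronal, sagittal = classify(tws_x, tws_y, zero_tol=zero_tol, decimals=decimals)
    return BSTResult(
        tws_x=tws_x, tws_y=tws_y, coronal_class=coronal,
        sagittal_class=sagittal, square_stats=stats, side=side,
    )


def bst_from_grid(
    mean_distances,
    cyst_flags=None,
    side: str = "right",
    zero_tol: float = 0.0,
    decimals: int | None = 3,
) -> BSTResult:
    """Battleship score from a precomputed 16-square table (mesh-free entry).

    ``mean_distances`` is row-major: rows posterior→anterior, columns in the
    *image* frame, which for a right foot is medial→lateral.  Left-foot
    tables are column-mirrored first so that anatomically identical patterns
    yield identical results on either side.  NaN marks an empty square.
    """
    values = np.asarray(mean_distances, dtype=float)
    if values.shape != (16,):
        raise ValidationError("expected 16 mean distances in row-major order")
    if cyst_flags is None:
        cyst_flags = np.zeros(16, dtype=bool)
    cyst_flags = np.asarray(cyst_flags, dtype=bool)
    if cyst_flags.shape != (16,):
        raise ValidationError("expected 16 cyst flags")
    defined = np.isfinite(values) & ~cyst_flags
    if np.any(values[defined] < 0):
        raise ValidationError("mean distances must be >= 0")
    if side not in ("left", "right"):
        raise ValidationError("side must be 'left' or 'right'")
    if side == "left":
        values = values.reshape(4, 4)[:, ::-1].reshape(16)
        cyst_flags = cyst_flags.reshape(4, 4)[:, ::-1].reshape(16)
    stats = _grid_square_stats(values, cyst_flags)
    return score_squares(stats, zero_tol=zero_tol, decimals=decimals, side=side)


def bst_from_map(
    pm: ProjectedMap,
    center: tuple[float, float] | None = None,
    zero_tol: float = 0.0,
    decimals: int | None = 3,
) -> BSTResult:
    """Full grid pipeline on a projected distance map.

    Composes anatomical centre → grid → per-square means → DMC → weighted
    sums → classification.  The map must already be in the anatomical frame
    (+x lateral), as produced by :func:`bstmap.geometry.project_axial`.
    """
    grid = build_grid(pm, center=center)
    stats = square_mean_distances(pm, grid)
    return score_squares(stats, zero_tol=zero_tol, decimals=decimals, side=pm.side)
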