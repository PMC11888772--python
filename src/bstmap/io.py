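"""File-format plumbing: CSV/JSON schemas and heatmap export.

All tables are comma-separated UTF-8 with "." decimals and a header row.
Grid tables store the 16 squares row-major as ``mean_r{row}c{col}`` (mm) and
``cyst_r{row}c{col}`` (0/1) columns, rows posterior→anterior, columns in the
image frame (medial→lateral for right feet).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .geometry import FLAG_CYST, DistanceMap, ProjectedMap
from .grid import BSTResult
from .reliability import RATINGS_COLUMNS, StatsReport, validate_ratings

GRID_VALUE_COLUMNS = [f"mean_r{r}c{c}" for r in range(4) for c in range(4)]
GRID_CYST_COLUMNS = [f"cyst_r{r}c{c}" for r in range(4) for c in range(4)]
GRID_META_COLUMNS = ["patient_id", "rater_id", "reading", "side"]


# ---------------------------------------------------------------------------
# grid CSV


def write_grid_csv(path: str | Path, rows: list[dict]) -> None:
    """Write grid records: each dict has the meta fields plus ``mean_distances``
    (16 values) and ``cyst_flags`` (16 bools)."""
    records = []
    for row in rows:
        rec = {k: row.get(k, "") for k in GRID_META_COLUMNS}
        rec.update(dict(zip(GRID_VALUE_COLUMNS, np.asarray(row["mean_distances"], dtype=float))))
        rec.update(dict(zip(GRID_CYST_COLUMNS, np.asarray(row["cyst_flags"], dtype=int))))
        records.append(rec)
    pd.DataFrame(records).to_csv(path, index=False)


def read_grid_csv(path: str | Path) -> list[dict]:
    """Read grid records back as dicts with arrays, preserving meta fields."""
    try:
        table = pd.read_csv(path)
    except Exception as exc:
        raise ValidationError(f"could not parse grid CSV {path}: {exc}") from exc
    missing = set(GRID_VALUE_COLUMNS) - set(table.columns)
    if missing:
        raise ValidationError(f"grid CSV {path} missing columns: {sorted(missing)[:4]}...")
    out = []
    for i, row in table.iterrows():
        rec = {k: row[k] for k in GRID_META_COLUMNS if k in table.columns}
        rec["mean_distances"] = row[GRID_VALUE_COLUMNS].to_numpy(dtype=float)
        if set(GRID_CYST_COLUMNS).issubset(table.columns):
            rec["cyst_flags"] = row[GRID_CYST_COLUMNS].to_numpy(dtype=float).astype(bool)
        else:
            rec["cyst_flags"] = np.zeros(16, dtype=bool)
        rec["_row"] = int(i)
        out.append(rec)
    if not out:
        raise ValidationError(f"grid CSV {path} contains no rows")
    return out


# ---------------------------------------------------------------------------
# distance map CSV


def write_distance_map_csv(path: str | Path, dm: DistanceMap) -> None:
    pd.DataFrame({
        "x_mm": dm.positions[:, 0],
        "y_mm": dm.positions[:, 1],
        "z_mm": dm.positions[:, 2],
        "distance_mm": dm.distances,
        "flag": dm.flags,
    }).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# BST result JSON / CSV


def bst_result_to_dict(result: BSTResult) -> dict:
    return {
        "tws_x": result.tws_x,
        "tws_y": result.tws_y,
        "coronal_class": result.coronal_class,
        "sagittal_class": result.sagittal_class,
        "side": result.side,
        "squares": [
            {k: (None if isinstance(v, float) and not np.isfinite(v) else v)
             for k, v in dataclasses.asdict(s).items()}
            for s in result.square_stats
        ],
    }


def write_bst_result(result: BSTResult, json_path: str | Path,
                     csv_path: str | Path | None = None) -> None:
    Path(json_path).write_text(json.dumps(bst_result_to_dict(result), indent=2) + "\n")
    if csv_path is not None:
        pd.DataFrame([dataclasses.asdict(s) for s in result.square_stats]).to_csv(
            csv_path, index=False
        )


# ---------------------------------------------------------------------------
# ratings / cohort CSV


def read_ratings_csv(path: str | Path) -> pd.DataFrame:
    try:
        table = pd.read_csv(path)
    except Exception as exc:
        raise ValidationError(f"could not parse ratings CSV {path}: {exc}") from exc
    missing = set(RATINGS_COLUMNS) - set(table.columns)
    if missing:
        raise ValidationError(f"ratings CSV {path} missing columns: {sorted(missing)}")
    return validate_ratings(table)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    try:
        table = pd.read_csv(path)
    except Exception as exc:
        raise ValidationError(f"could not parse cohort CSV {path}: {exc}") from exc
    if len(table) == 0:
        raise ValidationError(f"cohort CSV {path} is empty")
    for i, row in table.iterrows():
        vals = row.drop(labels=[c for c in ("patient_id", "side", "coronal_class", "sagittal_class") if c in table.columns])
        if not np.isfinite(pd.to_numeric(vals, errors="coerce")).all():
            raise ValidationError(f"cohort CSV {path}: non-numeric value in row {i}")
    return table


def write_stats_report(report: StatsReport, json_path: str | Path,
                       md_path: str | Path | None = None) -> None:
    Path(json_path).write_text(json.dumps(report.to_dict(), indent=2) + "\n")
    if md_path is not None:
        Path(md_path).write_text(report.to_markdown())


def reliability_report_to_dict(report: dict) -> dict:
    out = {}
    for measure, entries in report.items():
        if measure == "pooled_mean_estimate":
            out[measure] = entries
            continue
        out[measure] = [
            {"measurement": e["measurement"], "label": e["label"], **e["icc"].to_dict()}
            for e in entries
        ]
    return out


# ---------------------------------------------------------------------------
# heatmap


def export_heatmap(pm: ProjectedMap, path: str | Path, grid=None,
                   result: BSTResult | None = None) -> None:
    """Distance-map heatmap in the clinical colour convention: red = minimal
    distance (contact), blue = maximal; cyst samples are left as gaps.

    When a :class:`~bstmap.grid.DomeGrid` is given, the 16-square grid is
    overlaid; when a result is given, the weighted-sum point is marked (its
    normalized coordinates mapped back to mm on the grid rectangle).
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5.5))
    valid = pm.flags != FLAG_CYST
    sc = ax.scatter(pm.x[valid], pm.y[valid], c=pm.distances[valid],
                    cmap="RdBu", s=8, linewidths=0)
    fig.colorbar(sc, ax=ax, label="distance (mm)")
    if grid is not None:
        for i in range(5):
            gx = grid.x_min + i / 4 * (grid.x_max - grid.x_min)
            gy = grid.y_min + i / 4 * (grid.y_max - grid.y_min)
            ax.axvline(gx, color="0.5", lw=0.6)
            ax.axhline(gy, color="0.5", lw=0.6)
        if result is not None:
            mid_x = (grid.x_min + grid.x_max) / 2
            mid_y = (grid.y_min + grid.y_max) / 2
            px = mid_x + result.tws_x * (grid.x_max - grid.x_min)
            py = mid_y + result.tws_y * (grid.y_max - grid.y_min)
            ax.plot([px], [py], marker="*", color="k", markersize=14,
                    label=f"TWS ({result.tws_x:.4f}, {result.tws_y:.4f})")
            ax.legend(loc="upper right", fontsize=8)
    ax.set_xlabel("x (mm, + lateral)")
    ax.set_ylabel("y (mm, + anterior)")
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
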