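"""Weekly activity-space estimation: kernel utilization distributions (KUD).

The utilization distribution for one individual x week x diel period is an
equal-weight mixture of isotropic bivariate Gaussian kernels with a fixed
bandwidth h (default 50 m, the conventional smoothing factor for this array
scale on projected coordinates), evaluated on a regular grid and normalized
to total mass 1. The activity-space size is the area of the 95% highest-
density region: grid cells sorted by probability, accumulated until the
isopleth mass is reached, counted, and converted to km².

A weekly KUD is only produced when the individual carries positions on more
than four distinct dates that week (>= 5 position-days), successive or not.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class KudConfig:
    bandwidth: float = 50.0        # kernel sd, meters
    isopleth: float = 0.95
    grid_resolution: float = 5.0   # meters per cell
    grid_buffer: float = 5.0       # multiples of bandwidth beyond the data bbox
    min_position_days: int = 5     # "> 4 position-days"

    def __post_init__(self) -> None:
        if not 0.0 < self.isopleth < 1.0:
            raise ValueError("isopleth must be in (0, 1)")
        if self.bandwidth <= 0 or self.grid_resolution <= 0:
            raise ValueError("bandwidth and grid resolution must be positive")


@dataclass
class UtilizationDistribution:
    x0: float                 # center of the first cell column
    y0: float
    resolution: float
    probs: np.ndarray         # shape (ny, nx), sums to 1
    key: tuple = ()           # (transmitter_id, iso_year, iso_week, diel)
    n_positions: int = 0
    n_position_days: int = 0

    def __post_init__(self) -> None:
        total = float(self.probs.sum())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"UD mass {total} not 1 within 1e-9")
        if (self.probs < 0).any():
            raise ValueError("negative cell probability")


def estimate_ud(
    x: np.ndarray, y: np.ndarray, config: KudConfig | None = None, key: tuple = ()
) -> UtilizationDistribution:
    """Gaussian-kernel UD on a regular grid covering the positions plus a
    ``grid_buffer * bandwidth`` margin. All positions identical is fine (the
    UD is then a single kernel)."""
    config = config or KudConfig()
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0:
        raise ValueError("no positions")
    h, res = config.bandwidth, config.grid_resolution
    pad = config.grid_buffer * h
    gx = np.arange(x.min() - pad, x.max() + pad + res, res)
    gy = np.arange(y.min() - pad, y.max() + pad + res, res)
    # isotropic kernels are separable: density = Ax^T . Ay with per-axis
    # Gaussian factor matrices (n_points x n_cells)
    ax = np.exp(-0.5 * ((gx[None, :] - x[:, None]) / h) ** 2)
    ay = np.exp(-0.5 * ((gy[None, :] - y[:, None]) / h) ** 2)
    dens = ay.T @ ax  # (ny, nx)
    total = dens.sum()
    if total <= 0:
        raise ValueError("degenerate UD: zero total density on grid")
    return UtilizationDistribution(
        x0=float(gx[0]),
        y0=float(gy[0]),
        resolution=res,
        probs=dens / total,
        key=key,
        n_positions=int(x.size),
    )


def isopleth_area(ud: UtilizationDistribution, p: float | None = None) -> float:
    """Area (km²) of the smallest set of grid cells holding mass >= p.

    Cells are ranked by probability; the crossing cell is included.
    """
    if p is None:
        p = 0.95
    if not 0.0 < p < 1.0:
        raise ValueError("isopleth probability must be in (0, 1)")
    flat = np.sort(ud.probs.ravel())[::-1]
    csum = np.cumsum(flat)
    n_cells = int(np.searchsorted(csum, p, side="left")) + 1
    return n_cells * ud.resolution**2 / 1e6


def isopleth_cells(ud: UtilizationDistribution, p: float = 0.95) -> np.ndarray:
    """Boolean mask of grid cells inside the p highest-density region."""
    flat = np.sort(ud.probs.ravel())[::-1]
    csum = np.cumsum(flat)
    thresh = flat[int(np.searchsorted(csum, p, side="left"))]
    return ud.probs >= thresh


def isopleth_geojson(ud: UtilizationDistribution, p: float = 0.95) -> dict:
    """GeoJSON MultiPolygon of the isopleth cells (one square per cell;
    planar 'coordinates' in meters). Deliberately simple: a cell dump, not a
    dissolved contour."""
    mask = isopleth_cells(ud, p)
    half = ud.resolution / 2.0
    polys = []
    ys, xs = np.nonzero(mask)
    for iy, ix in zip(ys.tolist(), xs.tolist()):
        cx = ud.x0 + ix * ud.resolution
        cy = ud.y0 + iy * ud.resolution
        polys.append([[
            [cx - half, cy - half], [cx + half, cy - half],
            [cx + half, cy + half], [cx - half, cy + half],
            [cx - half, cy - half],
        ]])
    return {
        "type": "Feature",
        "properties": {"key": list(ud.key), "isopleth": p},
        "geometry": {"type": "MultiPolygon", "coordinates": polys},
    }


def weekly_space_use(
    positions: pd.DataFrame,
    diel: pd.Series,
    config: KudConfig | None = None,
) -> pd.DataFrame:
    """95% KUD area per (individual, ISO year, ISO week, diel period).

    ``positions`` needs timestamp, transmitter_id, x_m, y_m; ``diel`` is the
    per-row day/night label. Groups with fewer distinct position dates than
    ``min_position_days`` are skipped (logged).
    """
    config = config or KudConfig()
    if positions.empty:
        return pd.DataFrame(columns=[
            "transmitter_id", "iso_year", "iso_week", "diel",
            "activity_space_km2", "n_positions", "n_position_days",
        ])
    iso = positions["timestamp"].dt.isocalendar()
    tbl = positions.assign(
        iso_year=iso["year"].astype(int),
        iso_week=iso["week"].astype(int),
        diel=diel.to_numpy(),
        date=positions["timestamp"].dt.date,
    )
    rows = []
    n_skipped = 0
    for key, grp in tbl.groupby(["transmitter_id", "iso_year", "iso_week", "diel"], sort=True):
        n_days = grp["date"].nunique()
        if n_days < config.min_position_days:
            n_skipped += 1
            continue
        ud = estimate_ud(grp["x_m"].to_numpy(), grp["y_m"].to_numpy(), config, key=key)
        ud.n_position_days = int(n_days)
        rows.append({
            "transmitter_id": key[0], "iso_year": key[1], "iso_week": key[2], "diel": key[3],
            "activity_space_km2": isopleth_area(ud, config.isopleth),
            "n_positions": len(grp), "n_position_days": n_days,
        })
    if n_skipped:
        log.info("skipped %d individual-week-diel groups with < %d position-days",
                 n_skipped, config.min_position_days)
    return pd.DataFrame(rows)


def build_model_table(
    activity_weekly: pd.DataFrame,
    space_weekly: pd.DataFrame,
    metadata: pd.DataFrame,
    labels: pd.DataFrame,
) -> pd.DataFrame:
    """Join weekly activity and weekly activity-space into model-ready rows.

    Inner join on (transmitter_id, iso_year, iso_week, diel); both responses
    log-transformed; disc length, sex, and philopatry label attached. Rows
    with a nonpositive response are dropped (logged); individuals missing
    from ``metadata`` raise an error listing the ids.
    """
    keys = ["transmitter_id", "iso_year", "iso_week", "diel"]
    merged = activity_weekly.merge(space_weekly, on=keys, how="inner", suffixes=("", "_sp"))
    if merged.empty:
        return pd.DataFrame(columns=keys + [
            "activity_mh", "activity_space_km2", "log_activity", "log_space",
            "disc_length", "sex", "philopatry",
        ])
    missing = set(merged["transmitter_id"]) - set(metadata["transmitter_id"])
    if missing:
        raise ValueError(f"individuals missing metadata: {sorted(missing)}")
    merged = merged.merge(
        metadata[["transmitter_id", "sex", "disc_length_cm"]], on="transmitter_id"
    ).rename(columns={"disc_length_cm": "disc_length"})
    merged = merged.merge(
        labels[["transmitter_id", "label"]].rename(columns={"label": "philopatry"}),
        on="transmitter_id", how="left",
    )
    ok = (merged["activity_mh"] > 0) & (merged["activity_space_km2"] > 0)
    if (~ok).any():
        log.info("dropping %d rows with nonpositive responses", int((~ok).sum()))
        merged = merged[ok]
    merged = merged.assign(
        log_activity=np.log(merged["activity_mh"]),
        log_space=np.log(merged["activity_space_km2"]),
    )
    cols = keys + ["activity_mh", "activity_space_km2", "log_activity", "log_space",
                   "disc_length", "sex", "philopatry"]
    extra = [c for c in merged.columns if c.startswith("n_")]
    return merged[cols + extra].reset_index(drop=True)
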