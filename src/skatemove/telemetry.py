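"""Telemetry ingest, spurious-detection removal, and position-error filtering.

CSV dialects
------------
detections.csv      timestamp (ISO-8601, UTC), receiver_id, transmitter_id, depth_m
positions.csv       timestamp, transmitter_id, x_m, y_m, error_metric, source
individuals.csv     transmitter_id, sex, disc_length_cm, tagging_date
exclusions.csv      transmitter_id, date, reason
reference_fixes.csv positions.csv columns + true_x_m, true_y_m

Positions carry a manufacturer error metric (HPE for VPS-style arrays, HDOP
for Pinpoint-style arrays) tagged by the ``source`` column; the two dialects
are calibrated and filtered independently because the metrics are not on a
common scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DETECTION_COLUMNS = ["timestamp", "receiver_id", "transmitter_id", "depth_m"]
POSITION_COLUMNS = ["timestamp", "transmitter_id", "x_m", "y_m", "error_metric", "source"]

FLOAT_FMT = "%.12g"  # deterministic CSV round-trip at 12 significant digits


class ConfigError(ValueError):
    """Invalid configuration or inconsistent input tables."""


# ---------------------------------------------------------------------------
# readers / writers


def read_detections(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    return df


def read_positions(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    if (df["error_metric"] < 0).any():
        raise ConfigError("negative error_metric in positions table")
    if not np.isfinite(df[["x_m", "y_m"]].to_numpy()).all():
        raise ConfigError("non-finite coordinates in positions table")
    return df


def read_individuals(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["tagging_date"] = pd.to_datetime(df["tagging_date"]).dt.date
    return df


def read_exclusions(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["date"] = pd.to_datetime(df["date"]).dt.date
    return df


def read_reference_fixes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    return df


def write_csv(df: pd.DataFrame, path) -> None:
    """Deterministic CSV writer (fixed float format, no index)."""
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%dT%H:%M:%S%z")
    out.to_csv(path, index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# filtering


def filter_single_detections(
    detections: pd.DataFrame, window: pd.Timedelta | str = "24h"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop detections isolated within a rolling +/- window per transmitter.

    A detection is retained iff at least one other detection of the same
    transmitter lies within ``window`` of it (before or after). Returns
    (retained, removed); both preserve the input row order.
    """
    if detections.empty:
        return detections.copy(), detections.iloc[0:0].copy()
    window = pd.Timedelta(window)
    df = detections.sort_values(["transmitter_id", "timestamp"], kind="mergesort")
    ts = df["timestamp"]
    same_prev = df["transmitter_id"].eq(df["transmitter_id"].shift())
    same_next = df["transmitter_id"].eq(df["transmitter_id"].shift(-1))
    near_prev = same_prev & (ts - ts.shift() <= window)
    near_next = same_next & (ts.shift(-1) - ts <= window)
    keep = (near_prev | near_next).reindex(detections.index)
    retained = detections[keep]
    removed = detections[~keep]
    if len(removed):
        log.info("filter_single_detections removed %d of %d records", len(removed), len(detections))
    return retained, removed


def _median_error_curve(metric: np.ndarray, error: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Candidate thresholds (unique metrics ascending) and the median measured
    error among fixes with metric <= threshold, for each candidate."""
    order = np.argsort(metric, kind="stable")
    metric_s, error_s = metric[order], error[order]
    cands = np.unique(metric_s)
    medians = np.empty(len(cands))
    for i, c in enumerate(cands):
        n = np.searchsorted(metric_s, c, side="right")
        medians[i] = np.median(error_s[:n])
    return cands, medians


@dataclass
class CutoffResult:
    source: str
    cutoff: float
    median_error: float
    retention: float  # fraction of reference fixes with metric <= cutoff
    achieved_target: bool


def calibrate_error_cutoff(
    reference: pd.DataFrame,
    target_median_error: float = 3.5,
    min_fixes: int = 20,
) -> dict[str, CutoffResult]:
    """Largest per-dialect error-metric threshold keeping the median measured
    error of retained reference fixes strictly below ``target_median_error``.

    ``reference`` needs columns x_m, y_m, true_x_m, true_y_m, error_metric,
    source. If no threshold achieves the target for a dialect, the smallest
    observed metric is returned with ``achieved_target=False``.
    """
    results: dict[str, CutoffResult] = {}
    for source, grp in reference.groupby("source", sort=True):
        if len(grp) < min_fixes:
            raise ConfigError(
                f"{len(grp)} reference fixes for dialect {source!r}; need >= {min_fixes}"
            )
        metric = grp["error_metric"].to_numpy(float)
        error = np.hypot(
            grp["x_m"].to_numpy(float) - grp["true_x_m"].to_numpy(float),
            grp["y_m"].to_numpy(float) - grp["true_y_m"].to_numpy(float),
        )
        if not np.isfinite(error).all():
            raise ConfigError(f"non-finite measured error for dialect {source!r}")
        cands, medians = _median_error_curve(metric, error)
        ok = medians < target_median_error
        if ok.any():
            idx = np.flatnonzero(ok)[-1]
            achieved = True
        else:
            idx = 0
            achieved = False
            log.warning(
                "dialect %s: no threshold reaches median error < %.3g; "
                "falling back to minimum metric %.3g",
                source, target_median_error, cands[0],
            )
        cutoff = float(cands[idx])
        results[source] = CutoffResult(
            source=source,
            cutoff=cutoff,
            median_error=float(medians[idx]),
            retention=float(np.mean(metric <= cutoff)),
            achieved_target=achieved,
        )
    return results


def filter_positions(
    fixes: pd.DataFrame, cutoffs: dict[str, float | CutoffResult]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Retain fixes with error_metric <= their dialect's cutoff.

    Returns (retained, summary); the summary has one row per dialect with
    retained counts and percentages. Fixes whose dialect has no cutoff are
    rejected with a logged warning and reported under ``unknown_dialect``.
    """
    cut = {k: (v.cutoff if isinstance(v, CutoffResult) else float(v)) for k, v in cutoffs.items()}
    if any(c < 0 for c in cut.values()):
        raise ConfigError("negative error-metric cutoff")
    known = fixes["source"].isin(cut)
    if (~known).any():
        for src in fixes.loc[~known, "source"].unique():
            log.warning("rejecting %d fixes with unknown dialect %r",
                        int((fixes["source"] == src).sum()), src)
    thresh = fixes["source"].map(cut)
    keep = known & (fixes["error_metric"] <= thresh)
    retained = fixes[keep]
    rows = []
    for src, grp in fixes.groupby("source", sort=True):
        n_kept = int(keep[grp.index].sum())
        rows.append({
            "source": src,
            "cutoff": cut.get(src, np.nan),
            "n_input": len(grp),
            "n_retained": n_kept,
            "pct_retained": 100.0 * n_kept / len(grp) if len(grp) else np.nan,
            "known_dialect": src in cut,
        })
    return retained, pd.DataFrame(rows)


WHOLE_INDIVIDUAL_REASONS = {"tag_failure", "post_tagging_death"}


def apply_exclusions(
    detections: pd.DataFrame,
    fixes: pd.DataFrame,
    exclusions: pd.DataFrame,
    individuals: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop records after a mortality date, or entirely for whole-individual
    exclusion reasons (tag failure, death within 24 h of tagging).

    ``exclusions`` columns: transmitter_id, date, reason. If ``individuals``
    is given, an exclusion date before the tagging date raises ConfigError.
    """
    if exclusions.empty:
        return detections.copy(), fixes.copy()
    bad = ~exclusions["reason"].isin(WHOLE_INDIVIDUAL_REASONS | {"mortality"})
    if bad.any():
        raise ConfigError(f"unknown exclusion reasons: {sorted(exclusions.loc[bad, 'reason'])}")
    if individuals is not None:
        merged = exclusions.merge(
            individuals[["transmitter_id", "tagging_date"]], on="transmitter_id", how="left"
        )
        early = merged["date"] < merged["tagging_date"]
        if early.any():
            ids = sorted(merged.loc[early, "transmitter_id"])
            raise ConfigError(f"exclusion date before tagging date for {ids}")

    drop_all = set(exclusions.loc[exclusions["reason"].isin(WHOLE_INDIVIDUAL_REASONS),
                                  "transmitter_id"])
    mort = exclusions[exclusions["reason"] == "mortality"]
    mort_date = dict(zip(mort["transmitter_id"], mort["date"]))

    def _apply(df: pd.DataFrame) -> pd.DataFrame:
        keep = ~df["transmitter_id"].isin(drop_all)
        if mort_date:
            cut = df["transmitter_id"].map(mort_date)
            has_cut = cut.notna()
            dates = df["timestamp"].dt.date
            keep &= ~(has_cut & (dates >= cut))
        return df[keep]

    return _apply(detections), _apply(fixes)


# ---------------------------------------------------------------------------
# optional helper: geographic -> planar


def lonlat_to_utm(lon: np.ndarray, lat: np.ndarray, zone: int | None = None):
    """Forward transverse-Mercator (UTM) projection, WGS84, northern hemisphere.

    Convenience for users whose positions arrive in geographic coordinates;
    the rest of the package works exclusively in planar meters. Krüger-series
    accuracy is well below positioning error (< 1 mm within a zone).
    """
    lon = np.asarray(lon, float)
    lat = np.asarray(lat, float)
    if zone is None:
        zone = int(np.floor((np.mean(lon) + 180) / 6) + 1)
    lon0 = np.deg2rad(zone * 6 - 183)
    a, f = 6378137.0, 1 / 298.257223563
    k0, e2 = 0.9996, f * (2 - f)
    ep2 = e2 / (1 - e2)
    phi, lam = np.deg2rad(lat), np.deg2rad(lon)
    n_rad = a / np.sqrt(1 - e2 * np.sin(phi) ** 2)
    t = np.tan(phi) ** 2
    c = ep2 * np.cos(phi) ** 2
    aa = (lam - lon0) * np.cos(phi)
    m = a * (
        (1 - e2 / 4 - 3 * e2**2 / 64 - 5 * e2**3 / 256) * phi
        - (3 * e2 / 8 + 3 * e2**2 / 32 + 45 * e2**3 / 1024) * np.sin(2 * phi)
        + (15 * e2**2 / 256 + 45 * e2**3 / 1024) * np.sin(4 * phi)
        - (35 * e2**3 / 3072) * np.sin(6 * phi)
    )
    x = k0 * n_rad * (
        aa + (1 - t + c) * aa**3 / 6 + (5 - 18 * t + t**2 + 72 * c - 58 * ep2) * aa**5 / 120
    ) + 500000.0
    y = k0 * (
        m + n_rad * np.tan(phi) * (
            aa**2 / 2 + (5 - t + 9 * c + 4 * c**2) * aa**4 / 24
            + (61 - 58 * t + t**2 + 600 * c - 330 * ep2) * aa**6 / 720
        )
    )
    return x, y, zone
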