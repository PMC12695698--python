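"""Daily presence series and philopatry-pattern classification.

Individuals are classified from daily presence/absence records into three
multi-year patterns:

* site fidelity (SF): at least one internal absence strictly longer than the
  threshold (default 90 days) followed by a return;
* continuous residency (CR): no over-threshold absence and a presence span
  longer than one year (365 days);
* seasonal residency (SR): no over-threshold absence, span of at most a year.

An internal absence between consecutive presence days d_k < d_{k+1} has
length (d_{k+1} - d_k - 1) empty days. The terminal absence after the last
detection never triggers SF: both residency patterns end with a permanent
emigration, and site fidelity requires the animal to come back. Spans are
measured from first to last presence day; the tagging date plays no role.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

LABELS = ("CR", "SR", "SF")


@dataclass
class PresenceSeries:
    """Ordered calendar dates on which an individual was detected."""

    transmitter_id: str
    presence_days: np.ndarray  # datetime64[D], strictly increasing
    study_window: tuple[date, date]

    def __post_init__(self) -> None:
        days = np.asarray(self.presence_days, dtype="datetime64[D]")
        if days.size == 0:
            raise ValueError(f"{self.transmitter_id}: empty presence series")
        if not (np.diff(days) > np.timedelta64(0, "D")).all():
            days = np.unique(days)
        start, end = self.study_window
        if days[0] < np.datetime64(start, "D") or days[-1] > np.datetime64(end, "D"):
            raise ValueError(f"{self.transmitter_id}: presence days outside study window")
        self.presence_days = days


@dataclass
class PhilopatryConfig:
    absence_threshold: int = 90   # days; absences strictly longer flag SF
    residency_span: int = 365     # days; spans strictly longer flag CR

    def __post_init__(self) -> None:
        if self.absence_threshold <= 0 or self.residency_span <= 0:
            raise ValueError("thresholds must be strictly positive")


@dataclass
class PhilopatryLabel:
    transmitter_id: str
    label: str
    max_internal_absence: int
    presence_span: int
    n_presence_days: int


def build_presence(
    detections: pd.DataFrame, study_window: tuple[date, date]
) -> list[PresenceSeries]:
    """One presence series per transmitter; a date is present iff it carries
    at least one detection (UTC calendar-date binning)."""
    out: list[PresenceSeries] = []
    if detections.empty:
        return out
    dates = detections["timestamp"].dt.tz_convert("UTC").dt.tz_localize(None).dt.normalize()
    tbl = pd.DataFrame({"transmitter_id": detections["transmitter_id"], "date": dates})
    for tid, grp in tbl.groupby("transmitter_id", sort=True):
        days = np.unique(grp["date"].to_numpy().astype("datetime64[D]"))
        out.append(PresenceSeries(str(tid), days, study_window))
    return out


def _gaps(days: np.ndarray) -> np.ndarray:
    """Internal absence lengths in empty days between consecutive presence days."""
    if days.size < 2:
        return np.empty(0, dtype=int)
    return np.diff(days).astype("timedelta64[D]").astype(int) - 1


def classify(series: PresenceSeries, config: PhilopatryConfig | None = None) -> PhilopatryLabel:
    """Classify one presence series as CR, SR, or SF (see module docstring)."""
    config = config or PhilopatryConfig()
    days = series.presence_days
    gaps = _gaps(days)
    max_abs = int(gaps.max()) if gaps.size else 0
    span = int((days[-1] - days[0]).astype("timedelta64[D]").astype(int))
    if max_abs > config.absence_threshold:
        label = "SF"
    elif span > config.residency_span:
        label = "CR"
    else:
        label = "SR"
    return PhilopatryLabel(
        transmitter_id=series.transmitter_id,
        label=label,
        max_internal_absence=max_abs,
        presence_span=span,
        n_presence_days=int(days.size),
    )


def classify_all(
    seriess: list[PresenceSeries], config: PhilopatryConfig | None = None
) -> pd.DataFrame:
    labels = [classify(s, config) for s in seriess]
    return pd.DataFrame(
        {
            "transmitter_id": [l.transmitter_id for l in labels],
            "label": [l.label for l in labels],
            "max_internal_absence_d": [l.max_internal_absence for l in labels],
            "presence_span_d": [l.presence_span for l in labels],
            "n_presence_days": [l.n_presence_days for l in labels],
        }
    )


@dataclass
class SensitivityResult:
    counts: pd.DataFrame        # rows: threshold; columns: CR, SR, SF, n_changed
    label_matrix: pd.DataFrame  # rows: transmitter_id; one column per threshold
    default_threshold: int


def sensitivity(
    seriess: list[PresenceSeries],
    thresholds: tuple[int, ...] = (60, 90, 120),
    default_threshold: int = 90,
    residency_span: int = 365,
) -> SensitivityResult:
    """Re-classify every series at each absence threshold and count label
    changes relative to the default threshold."""
    if not seriess:
        raise ValueError("no presence series supplied")
    if not thresholds:
        raise ValueError("empty threshold set")
    thresholds = tuple(sorted(set(thresholds) | {default_threshold}))
    cols = {}
    for th in thresholds:
        cfg = PhilopatryConfig(absence_threshold=th, residency_span=residency_span)
        cols[th] = pd.Series(
            {s.transmitter_id: classify(s, cfg).label for s in seriess}, name=th
        )
    matrix = pd.DataFrame(cols).rename_axis("transmitter_id")
    base = matrix[default_threshold]
    rows = []
    for th in thresholds:
        counts = matrix[th].value_counts()
        rows.append(
            {
                "threshold": th,
                **{lab: int(counts.get(lab, 0)) for lab in LABELS},
                "n_changed": int((matrix[th] != base).sum()),
            }
        )
    return SensitivityResult(
        counts=pd.DataFrame(rows).set_index("threshold"),
        label_matrix=matrix,
        default_threshold=default_threshold,
    )
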