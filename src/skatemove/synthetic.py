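"""Synthetic acoustic-telemetry cohorts with known ground truth.

Two fidelity levels are generated from one configuration and one seed:

* model-ready weekly behavior rows — draws from the exact bivariate mixed
  model the analysis fits (trait vector per individual-week-diel row equals
  fixed effects + individual random intercepts + correlated residual noise),
  used to test the Gibbs sampler without the geometry stack;
* raw telemetry — correlated-random-walk tracks inside the receiver array
  polygon, perturbed positions with a manufacturer-style error metric, and
  irregular detection streams (with optional injected isolated detections to
  exercise the 24-h filter).

Presence histories follow three philopatry archetypes: continuous residents
(CR) stay > 365 days with only short gaps, seasonal residents (SR) stay at
most a year and emigrate between September and January, and site-fidelity
individuals (SF) leave for one over-threshold absence starting in late
autumn and return in spring. Default archetype frequencies, the disc-length
range, and seasonal windows follow the observed cohort (24.3% CR, 59.3% SR,
16.4% SF; discs 24-59 cm); everything is overridable.

All randomness flows from a single integer seed through spawned
``numpy.random.Generator`` streams, so each sub-product is reproducible in
isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import Point, Polygon

from .telemetry import write_csv

log = logging.getLogger(__name__)

TRAITS = ("log_space", "log_activity")
ARCHETYPES = ("CR", "SR", "SF")


class SimConfigError(ValueError):
    pass


def _default_G() -> np.ndarray:
    # among-individual (co)variance of (log_space, log_activity)
    return np.array([[0.202, 0.087], [0.087, 0.285]])


def _default_R() -> np.ndarray:
    # residual (co)variance of (log_space, log_activity)
    return np.array([[0.706, 0.218], [0.218, 0.533]])


def _default_beta() -> dict[str, tuple[float, float]]:
    """Fixed effects as name -> (log_space coef, log_activity coef).

    Week terms apply to a scaled cubic basis t, t^2, t^3 with
    t = (week - 27) / 26; philopatry contrasts are null (the trait of
    interest downstream), day is lower than night for both traits.
    """
    return {
        "intercept": (-3.0, 5.0),
        "philopatry_SF": (0.0, 0.0),
        "philopatry_SR": (0.0, 0.0),
        "disc_length": (0.012, 0.005),
        "sex_male": (0.0, 0.0),
        "week1": (0.35, -0.30),
        "week2": (-0.20, 0.15),
        "week3": (0.25, 0.35),
        "diel_day": (-0.40, -0.30),
    }


def _default_polygon() -> Polygon:
    # ~0.9 km^2 rectangular array footprint, planar meters
    return Polygon([(0, 0), (950, 0), (950, 950), (0, 950)])


@dataclass
class ErrorModel:
    """Links the true positional perturbation to the reported error metric.

    Each fix is perturbed with isotropic Gaussian noise of sd sigma drawn
    from a lognormal; the reported metric is sigma times lognormal noise
    times a per-dialect scale, hence monotone in sigma in expectation.
    """

    sigma_log_mean: float = float(np.log(3.5))  # median true sd 3.5 m
    sigma_log_sd: float = 0.6
    metric_noise_sd: float = 0.3
    metric_scale: dict = field(default_factory=lambda: {"vps": 1.0, "pinpoint": 0.5})


@dataclass
class MovementModel:
    """Correlated random walk with a home-range tether.

    The kinematics are a modeling artifact: any generator respecting the
    per-individual mean speed (exp of the log-activity effect) and a
    per-individual home-range scale serves the downstream tests.
    """

    base_log_speed_mh: float = 5.0      # exp(5) ~ 148 m/h mean speed
    turn_sd: float = 0.8                # radians per step
    home_radius_m: float = 120.0        # scaled by exp(0.5 * log_space effect)
    interval_range_s: tuple = (40.0, 160.0)  # transmitter delay range
    hours_per_day: float = 24.0


@dataclass
class SimConfig:
    n_individuals: int = 177
    philopatry_probs: tuple = (0.243, 0.593, 0.164)  # (CR, SR, SF)
    study_start: date = date(2019, 5, 5)
    study_end: date = date(2023, 6, 4)
    G_true: np.ndarray = field(default_factory=_default_G)
    R_true: np.ndarray = field(default_factory=_default_R)
    beta_true: dict = field(default_factory=_default_beta)
    disc_length_range: tuple = (24.0, 59.0)
    sex_male_prob: float = 0.599
    array_polygon: Polygon = field(default_factory=_default_polygon)
    error_model: ErrorModel = field(default_factory=ErrorModel)
    movement: MovementModel = field(default_factory=MovementModel)
    # presence construction
    absence_threshold_days: int = 90       # archetype construction respects this
    short_gap_cap_days: int = 25           # CR/SR internal absences never exceed this
    bout_mean_days: float = 9.0
    short_gap_mean_days: float = 3.0
    sf_absence_mean_days: float = 150.0    # Nov/Dec departure, Mar/Apr return
    sf_absence_sd_days: float = 25.0
    singleton_rate: float = 0.0            # per-eligible-absence injection prob
    raw_days_per_individual: int | None = None  # cap on simulated track days
    background_detections_per_day: int = 3  # sparse stream on every presence day
    seed: int = 0

    def __post_init__(self) -> None:
        self.G_true = np.asarray(self.G_true, float)
        self.R_true = np.asarray(self.R_true, float)
        self.validate()

    def validate(self) -> None:
        p = np.asarray(self.philopatry_probs, float)
        if p.shape != (3,) or abs(p.sum() - 1.0) > 1e-12 or (p < 0).any():
            raise SimConfigError("philopatry_probs must be 3 nonnegative values summing to 1")
        for name, m in (("G_true", self.G_true), ("R_true", self.R_true)):
            if m.shape != (2, 2) or not np.allclose(m, m.T):
                raise SimConfigError(f"{name} must be symmetric 2x2")
            if np.linalg.eigvalsh(m).min() < -1e-12:
                raise SimConfigError(f"{name} must be positive semi-definite")
        if self.study_end <= self.study_start:
            raise SimConfigError("study_end must be after study_start")
        if self.array_polygon.area <= 0:
            raise SimConfigError("array polygon has zero area")
        lo, hi = self.disc_length_range
        if not lo < hi:
            raise SimConfigError("disc_length_range must be increasing")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["G_true"] = self.G_true.tolist()
        d["R_true"] = self.R_true.tolist()
        d["study_start"] = self.study_start.isoformat()
        d["study_end"] = self.study_end.isoformat()
        d["array_polygon"] = list(map(list, self.array_polygon.exterior.coords))
        d["beta_true"] = {k: list(v) for k, v in self.beta_true.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["study_start"] = date.fromisoformat(d["study_start"])
        d["study_end"] = date.fromisoformat(d["study_end"])
        d["array_polygon"] = Polygon(d["array_polygon"])
        d["G_true"] = np.asarray(d["G_true"], float)
        d["R_true"] = np.asarray(d["R_true"], float)
        d["beta_true"] = {k: tuple(v) for k, v in d["beta_true"].items()}
        d["philopatry_probs"] = tuple(d["philopatry_probs"])
        if isinstance(d.get("error_model"), dict):
            d["error_model"] = ErrorModel(**d["error_model"])
        if isinstance(d.get("movement"), dict):
            mv = dict(d["movement"])
            mv["interval_range_s"] = tuple(mv["interval_range_s"])
            d["movement"] = MovementModel(**mv)
        for key in ("disc_length_range",):
            d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class SyntheticIndividual:
    id: str
    sex: str                      # 'female' | 'male'
    disc_length: float            # cm
    archetype: str                # CR | SR | SF
    arrival_day: date
    emigration_day: date          # last presence day
    absence_windows: list         # [(start, end)] inclusive empty-day windows
    random_effect: np.ndarray     # (log_space dev, log_activity dev)
    presence_days: np.ndarray     # datetime64[D]

    @property
    def tagging_date(self) -> date:
        return self.arrival_day


# ---------------------------------------------------------------------------
# presence construction


def _bout_days(rng, start: date, end: date, cfg: SimConfig) -> list[date]:
    """Presence days from ``start`` to ``end`` as bouts separated by short
    gaps capped at ``short_gap_cap_days`` (< any classification threshold of
    interest). First and last days are always present."""
    days: list[date] = []
    cur = start
    while cur <= end:
        bout = 1 + rng.geometric(1.0 / cfg.bout_mean_days)
        for k in range(bout):
            d = cur + timedelta(days=k)
            if d > end:
                break
            days.append(d)
        gap = 1 + min(int(rng.geometric(1.0 / cfg.short_gap_mean_days)),
                      cfg.short_gap_cap_days - 1)
        cur = cur + timedelta(days=bout + gap)
    if days[-1] != end:
        days.append(end)
    return days


def _rand_date(rng, lo: date, hi: date) -> date:
    span = (hi - lo).days
    return lo + timedelta(days=int(rng.integers(0, max(span, 0) + 1)))


def _presence_for_archetype(rng, archetype: str, cfg: SimConfig):
    """Returns (arrival, emigration, long_absence_windows, presence_days)."""
    start, end = cfg.study_start, cfg.study_end
    window = (end - start).days
    if archetype == "CR":
        if window < 400:
            raise SimConfigError(
                "study window shorter than 400 days cannot host a continuous "
                "resident (> 365-day span); set philopatry_probs[0] = 0"
            )
        span = int(rng.integers(380, min(900, window - 1) + 1))
        arrival = _rand_date(rng, start, end - timedelta(days=span))
        emig = arrival + timedelta(days=span)
        days = _bout_days(rng, arrival, emig, cfg)
        return arrival, emig, [], days
    if archetype == "SR":
        # arrive Mar-Aug, permanently emigrate Sep-Jan
        year = int(rng.integers(start.year, max(end.year, start.year + 1)))
        arrival = _rand_date(rng, date(year, 3, 1), date(year, 8, 20))
        arrival = min(max(arrival, start), end - timedelta(days=40))
        exit_lo = date(year, 9, 10)
        exit_hi = date(year + 1, 1, 31)
        emig = _rand_date(rng, max(exit_lo, arrival + timedelta(days=30)), exit_hi)
        emig = min(emig, end, arrival + timedelta(days=365))
        days = _bout_days(rng, arrival, emig, cfg)
        return arrival, emig, [], days
    if archetype == "SF":
        # block 1 (spring-autumn), long winter absence, block 2 (return)
        year = int(rng.integers(start.year, max(end.year - 1, start.year + 1)))
        arrival = _rand_date(rng, date(year, 3, 1), date(year, 8, 31))
        arrival = min(max(arrival, start), date(year, 10, 1))
        b1_end = _rand_date(rng, date(year, 10, 15), date(year, 12, 15))
        b1_end = max(b1_end, arrival + timedelta(days=10))
        absence = int(np.clip(rng.normal(cfg.sf_absence_mean_days, cfg.sf_absence_sd_days),
                              cfg.absence_threshold_days + 5, 210))
        b2_start = b1_end + timedelta(days=absence + 1)
        b2_end = b2_start + timedelta(days=int(rng.integers(30, 181)))
        b2_end = min(b2_end, end)
        if b2_end <= b2_start:  # ran out of study window; pull the pattern earlier
            shift = (b2_start - end).days + 30
            arrival -= timedelta(days=shift)
            b1_end -= timedelta(days=shift)
            b2_start -= timedelta(days=shift)
            b2_end = min(b2_start + timedelta(days=60), end)
            arrival = max(arrival, start)
        days = _bout_days(rng, arrival, b1_end, cfg) + _bout_days(rng, b2_start, b2_end, cfg)
        absences = [(b1_end + timedelta(days=1), b2_start - timedelta(days=1))]
        return arrival, b2_end, absences, days
    raise SimConfigError(f"unknown archetype {archetype!r}")


def simulate_individuals(config: SimConfig) -> list[SyntheticIndividual]:
    """Draw the cohort: archetypes from ``philopatry_probs``, bivariate
    random effects from ``G_true``, archetype-consistent presence histories.
    Deterministic given ``config.seed``."""
    try:
        np.linalg.cholesky(config.G_true + 1e-12 * np.eye(2))
    except np.linalg.LinAlgError as exc:
        raise SimConfigError("G_true is not positive semi-definite") from exc
    ss = np.random.SeedSequence(config.seed)
    rng_arch, rng_traits, rng_presence = (np.random.default_rng(s) for s in ss.spawn(3))
    archetypes = rng_arch.choice(ARCHETYPES, size=config.n_individuals,
                                 p=np.asarray(config.philopatry_probs, float))
    effects = rng_traits.multivariate_normal(np.zeros(2), config.G_true,
                                             size=config.n_individuals,
                                             method="cholesky")
    lo, hi = config.disc_length_range
    discs = np.round(rng_traits.uniform(lo, hi, size=config.n_individuals), 1)
    sexes = np.where(rng_traits.random(config.n_individuals) < config.sex_male_prob,
                     "male", "female")
    out = []
    for i in range(config.n_individuals):
        arrival, emig, absences, days = _presence_for_archetype(
            rng_presence, archetypes[i], config
        )
        out.append(SyntheticIndividual(
            id=f"T{i + 1:04d}",
            sex=str(sexes[i]),
            disc_length=float(discs[i]),
            archetype=str(archetypes[i]),
            arrival_day=arrival,
            emigration_day=emig,
            absence_windows=absences,
            random_effect=effects[i],
            presence_days=np.array(sorted(set(days)), dtype="datetime64[D]"),
        ))
    return out


def individuals_frame(individuals: list[SyntheticIndividual]) -> pd.DataFrame:
    return pd.DataFrame({
        "transmitter_id": [i.id for i in individuals],
        "sex": [i.sex for i in individuals],
        "disc_length_cm": [i.disc_length for i in individuals],
        "tagging_date": [i.tagging_date.isoformat() for i in individuals],
        "archetype": [i.archetype for i in individuals],
    })


# ---------------------------------------------------------------------------
# model-ready weekly rows


def week_basis(week: np.ndarray) -> np.ndarray:
    """Scaled cubic basis used by the generator's seasonal effect:
    t, t^2, t^3 with t = (week - 27) / 26. The fitted model's orthogonal
    cubic spans the same function space."""
    t = (np.asarray(week, float) - 27.0) / 26.0
    return np.column_stack([t, t**2, t**3])


def _beta_matrix(beta: dict) -> tuple[list[str], np.ndarray]:
    names = list(beta)
    mat = np.array([beta[k] for k in names], float)  # (n_terms, 2)
    return names, mat


def true_row_mean(ind: SyntheticIndividual, week: np.ndarray, diel_day: np.ndarray,
                  beta: dict) -> np.ndarray:
    """Fixed-effect + random-intercept mean for rows of one individual;
    returns (n, 2) in TRAITS order."""
    names, mat = _beta_matrix(beta)
    wb = week_basis(week)
    n = len(week)
    cols = {
        "intercept": np.ones(n),
        "philopatry_SF": np.full(n, 1.0 if ind.archetype == "SF" else 0.0),
        "philopatry_SR": np.full(n, 1.0 if ind.archetype == "SR" else 0.0),
        "disc_length": np.full(n, ind.disc_length),
        "sex_male": np.full(n, 1.0 if ind.sex == "male" else 0.0),
        "week1": wb[:, 0],
        "week2": wb[:, 1],
        "week3": wb[:, 2],
        "diel_day": diel_day.astype(float),
    }
    X = np.column_stack([cols[k] for k in names])
    return X @ mat + ind.random_effect[None, :]


def simulate_weekly_rows(
    individuals: list[SyntheticIndividual], config: SimConfig
) -> pd.DataFrame:
    """One row per individual x present calendar week x diel period, drawn
    from the generating mixed model (responses on the log scale plus their
    exponentiated counterparts)."""
    ss = np.random.SeedSequence((config.seed, 1))
    rng = np.random.default_rng(ss)
    L = np.linalg.cholesky(config.R_true + 1e-15 * np.eye(2))
    frames = []
    for ind in individuals:
        iso = pd.DatetimeIndex(ind.presence_days).isocalendar()
        weeks = sorted(set(zip(iso["year"].astype(int), iso["week"].astype(int))))
        n_wk = len(weeks)
        week_no = np.repeat([w for _, w in weeks], 2)
        iso_year = np.repeat([y for y, _ in weeks], 2)
        diel_day = np.tile([0.0, 1.0], n_wk)  # night, day per week
        mean = true_row_mean(ind, week_no, diel_day, config.beta_true)
        noise = rng.standard_normal((2 * n_wk, 2)) @ L.T
        y = mean + noise
        frames.append(pd.DataFrame({
            "transmitter_id": ind.id,
            "iso_year": iso_year,
            "iso_week": week_no,
            "diel": np.where(diel_day > 0.5, "day", "night"),
            "log_space": y[:, 0],
            "log_activity": y[:, 1],
            "disc_length": ind.disc_length,
            "sex": ind.sex,
            "philopatry": ind.archetype,
        }))
    rows = pd.concat(frames, ignore_index=True)
    rows["activity_space_km2"] = np.exp(rows["log_space"])
    rows["activity_mh"] = np.exp(rows["log_activity"])
    return rows


def simulate_balanced_rows(
    config: SimConfig, n_weeks: int = 15
) -> pd.DataFrame:
    """Balanced model-ready cohort: every individual contributes the same
    ``n_weeks`` weeks spread over the season, day and night each (so
    2 * n_weeks rows per individual). The parameter-recovery design: the
    realized among-individual covariance is the only sampling noise between
    the generating values and a correct fit."""
    individuals = simulate_individuals(config)
    ss = np.random.SeedSequence((config.seed, 4))
    rng = np.random.default_rng(ss)
    L = np.linalg.cholesky(config.R_true + 1e-15 * np.eye(2))
    weeks = np.linspace(2, 52, n_weeks).round().astype(int)
    week_no = np.repeat(weeks, 2)
    diel_day = np.tile([0.0, 1.0], n_weeks)
    frames = []
    for ind in individuals:
        mean = true_row_mean(ind, week_no, diel_day, config.beta_true)
        y = mean + rng.standard_normal((2 * n_weeks, 2)) @ L.T
        frames.append(pd.DataFrame({
            "transmitter_id": ind.id,
            "iso_year": config.study_start.year,
            "iso_week": week_no,
            "diel": np.where(diel_day > 0.5, "day", "night"),
            "log_space": y[:, 0],
            "log_activity": y[:, 1],
            "disc_length": ind.disc_length,
            "sex": ind.sex,
            "philopatry": ind.archetype,
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# raw telemetry


def _receiver_grid(polygon: Polygon, n: int = 28) -> pd.DataFrame:
    minx, miny, maxx, maxy = polygon.bounds
    side = int(np.ceil(np.sqrt(n)))
    xs = np.linspace(minx + 75, maxx - 75, side)
    ys = np.linspace(miny + 75, maxy - 75, side)
    pts = [(x, y) for y in ys for x in xs][:n]
    return pd.DataFrame({
        "receiver_id": [f"R{k + 1:02d}" for k in range(len(pts))],
        "x_m": [p[0] for p in pts],
        "y_m": [p[1] for p in pts],
    })


def _simulate_track_day(rng, start_xy, heading, speed_ms, home_xy, radius,
                        polygon: Polygon, mv: MovementModel, day_start_s: float):
    """One day of a tethered correlated random walk. Returns (times_s, xy,
    heading, last_xy)."""
    times = []
    t = day_start_s + float(rng.uniform(*mv.interval_range_s))
    day_end = day_start_s + mv.hours_per_day * 3600.0
    while t < day_end:
        times.append(t)
        t += float(rng.uniform(*mv.interval_range_s))
    times = np.asarray(times)
    xy = np.empty((len(times), 2))
    pos = np.asarray(start_xy, float)
    prev_t = day_start_s
    for k, tk in enumerate(times):
        dt = tk - prev_t
        heading += float(rng.normal(0.0, mv.turn_sd))
        step = np.array([np.cos(heading), np.sin(heading)]) * speed_ms * dt
        cand = pos + step
        # home tether: beyond the individual's range, walk back toward home
        if np.hypot(*(cand - home_xy)) > radius or not polygon.contains(Point(cand)):
            heading = float(np.arctan2(home_xy[1] - pos[1], home_xy[0] - pos[0])
                            + rng.normal(0.0, 0.3))
            cand = pos + np.array([np.cos(heading), np.sin(heading)]) * speed_ms * dt
            if not polygon.contains(Point(cand)):
                cand = pos
        pos = cand
        xy[k] = pos
        prev_t = tk
    return times, xy, heading, pos


def simulate_positions(
    individuals: list[SyntheticIndividual], config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Raw-level telemetry for the cohort.

    Returns (positions, detections, info). Positions carry the perturbed
    coordinates, the noisy error metric, and the true coordinates
    (true_x_m/true_y_m, for tests; the CSV writer keeps them — a real
    ingest simply ignores unknown columns). Detections are emitted at the
    position instants at the nearest receiver; ``info['n_injected']`` counts
    injected isolated detections (one per eligible >= 3-day absence, rate
    ``config.singleton_rate``).
    """
    if config.array_polygon.area <= 0:
        raise SimConfigError("array polygon has zero area")
    ss = np.random.SeedSequence((config.seed, 2))
    receivers = _receiver_grid(config.array_polygon)
    rx = receivers[["x_m", "y_m"]].to_numpy()
    em, mv = config.error_model, config.movement
    pos_frames, det_frames = [], []
    n_injected = 0
    minx, miny, maxx, maxy = config.array_polygon.bounds
    for ind, seed in zip(individuals, ss.spawn(len(individuals))):
        rng = np.random.default_rng(seed)
        speed_mh = float(np.exp(mv.base_log_speed_mh + ind.random_effect[1]))
        speed_ms = speed_mh / 3600.0
        radius = mv.home_radius_m * float(np.exp(0.5 * ind.random_effect[0]))
        home = np.array([rng.uniform(minx + radius, maxx - radius),
                         rng.uniform(miny + radius, maxy - radius)])
        home = np.clip(home, [minx + 10, miny + 10], [maxx - 10, maxy - 10])
        source = "vps" if rng.random() < 0.9 else "pinpoint"
        days = ind.presence_days
        if config.raw_days_per_individual is not None:
            days = days[: config.raw_days_per_individual]
        pos = home.copy()
        heading = float(rng.uniform(0, 2 * np.pi))
        t_all, xy_all = [], []
        for d in days:
            day_start = (d - np.datetime64("1970-01-01")).astype("timedelta64[D]").astype(int) * 86400.0
            times, xy, heading, pos = _simulate_track_day(
                rng, pos, heading, speed_ms, home, radius, config.array_polygon, mv, day_start
            )
            t_all.append(times)
            xy_all.append(xy)
        if not t_all:
            continue
        t_all = np.concatenate(t_all)
        xy_all = np.vstack(xy_all)
        sigma = rng.lognormal(em.sigma_log_mean, em.sigma_log_sd, size=len(t_all))
        obs = xy_all + rng.standard_normal(xy_all.shape) * sigma[:, None]
        metric = sigma * np.exp(rng.normal(0.0, em.metric_noise_sd, size=len(t_all)))
        metric *= em.metric_scale[source]
        ts = pd.to_datetime(t_all * 1e9, utc=True)
        pos_frames.append(pd.DataFrame({
            "timestamp": ts,
            "transmitter_id": ind.id,
            "x_m": obs[:, 0],
            "y_m": obs[:, 1],
            "error_metric": metric,
            "source": source,
            "true_x_m": xy_all[:, 0],
            "true_y_m": xy_all[:, 1],
        }))
        near = np.argmin(
            (xy_all[:, 0][:, None] - rx[:, 0]) ** 2 + (xy_all[:, 1][:, None] - rx[:, 1]) ** 2,
            axis=1,
        )
        det = pd.DataFrame({
            "timestamp": ts,
            "receiver_id": receivers["receiver_id"].to_numpy()[near],
            "transmitter_id": ind.id,
            "depth_m": np.nan,
            "injected_singleton": False,
        })
        # sparse detection stream on every presence day (including days with
        # no position track), so the presence history survives a track cap
        k = config.background_detections_per_day
        if k > 0:
            all_days = ind.presence_days
            day_s = (all_days - np.datetime64("1970-01-01")).astype("timedelta64[D]"
                     ).astype(int) * 86400.0
            offs = rng.uniform(3600.0, 82800.0, size=(len(all_days), k))
            bg_t = np.sort((day_s[:, None] + offs).ravel())
            det = pd.concat([det, pd.DataFrame({
                "timestamp": pd.to_datetime(bg_t * 1e9, utc=True),
                "receiver_id": receivers["receiver_id"].to_numpy()[
                    rng.integers(0, len(receivers), size=len(bg_t))],
                "transmitter_id": ind.id,
                "depth_m": np.nan,
                "injected_singleton": False,
            })], ignore_index=True)
        # isolated detections inside long absences (>= 3 empty days keeps the
        # injected record > 24 h from any true detection)
        if config.singleton_rate > 0 and len(days) > 1:
            gaps = np.diff(days).astype(int)
            for gi in np.flatnonzero(gaps >= 4):
                if rng.random() < config.singleton_rate:
                    mid = days[gi] + np.timedelta64(int(gaps[gi] // 2), "D")
                    ts_mid = pd.Timestamp(mid.astype("datetime64[s]"), tz="UTC") + pd.Timedelta(hours=12)
                    det = pd.concat([det, pd.DataFrame({
                        "timestamp": [ts_mid],
                        "receiver_id": [receivers["receiver_id"].iloc[0]],
                        "transmitter_id": [ind.id],
                        "depth_m": [np.nan],
                        "injected_singleton": [True],
                    })], ignore_index=True)
                    n_injected += 1
        det_frames.append(det)
    positions = (pd.concat(pos_frames, ignore_index=True) if pos_frames
                 else pd.DataFrame(columns=["timestamp", "transmitter_id", "x_m", "y_m",
                                            "error_metric", "source", "true_x_m", "true_y_m"]))
    detections = (pd.concat(det_frames, ignore_index=True).sort_values(
        ["transmitter_id", "timestamp"], kind="mergesort").reset_index(drop=True)
        if det_frames else pd.DataFrame(columns=["timestamp", "receiver_id",
                                                 "transmitter_id", "depth_m",
                                                 "injected_singleton"]))
    return positions, detections, {"n_injected": n_injected, "receivers": receivers}


def simulate_reference_fixes(
    config: SimConfig, n_per_source: int = 400
) -> pd.DataFrame:
    """Stationary reference-transmitter fixes at known locations, sharing the
    cohort's error model; used to calibrate the error-metric cutoff."""
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 3)))
    em = config.error_model
    minx, miny, maxx, maxy = config.array_polygon.bounds
    frames = []
    for source, scale in sorted(em.metric_scale.items()):
        true = np.column_stack([
            rng.uniform(minx + 50, maxx - 50, n_per_source),
            rng.uniform(miny + 50, maxy - 50, n_per_source),
        ])
        sigma = rng.lognormal(em.sigma_log_mean, em.sigma_log_sd, size=n_per_source)
        obs = true + rng.standard_normal(true.shape) * sigma[:, None]
        metric = sigma * np.exp(rng.normal(0.0, em.metric_noise_sd, n_per_source)) * scale
        t0 = pd.Timestamp(config.study_start, tz="UTC")
        frames.append(pd.DataFrame({
            "timestamp": t0 + pd.to_timedelta(np.arange(n_per_source) * 600, unit="s"),
            "transmitter_id": f"REF-{source}",
            "x_m": obs[:, 0],
            "y_m": obs[:, 1],
            "error_metric": metric,
            "source": source,
            "true_x_m": true[:, 0],
            "true_y_m": true[:, 1],
        }))
    return pd.concat(frames, ignore_index=True)


def write_simulated(out_dir, config: SimConfig) -> dict:
    """Generate and write the full synthetic dataset as the CSV dialects the
    ingest module reads. Returns a manifest of written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    individuals = simulate_individuals(config)
    positions, detections, info = simulate_positions(individuals, config)
    weekly = simulate_weekly_rows(individuals, config)
    reference = simulate_reference_fixes(config)
    paths = {
        "individuals": out / "individuals.csv",
        "detections": out / "detections.csv",
        "positions": out / "positions.csv",
        "reference_fixes": out / "reference_fixes.csv",
        "weekly_true": out / "weekly_true.csv",
        "config": out / "sim_config.yaml",
    }
    write_csv(individuals_frame(individuals), paths["individuals"])
    write_csv(detections.drop(columns=["injected_singleton"]), paths["detections"])
    write_csv(positions, paths["positions"])
    write_csv(reference, paths["reference_fixes"])
    write_csv(weekly, paths["weekly_true"])
    config.to_yaml(paths["config"])
    return {k: str(v) for k, v in paths.items()}
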