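"""Weekly fine-scale activity from filtered positions.

Splits each individual's position series into sub-trajectories at gaps
over 30 min, interpolates every 80 s, computes per-step activity
(dist/dt * 3600, m/h), labels steps day/night from computed sunrise and
sunset at the array centroid, and averages per individual x ISO week x diel
period.
"""

from pathlib import Path

from skatemove.movement import activity_steps, aggregate_weekly
from skatemove.solar import DielCalendar
from skatemove.telemetry import read_positions, write_csv

RESULTS = Path(__file__).resolve().parents[1] / "results"
LAT, LON = 42.225, -8.9  # array centroid


def main() -> None:
    fixes = read_positions(RESULTS / "positions_filtered.csv")
    calendar = DielCalendar(LAT, LON)
    steps = activity_steps(fixes, calendar, step=80.0, max_gap=1800.0)
    weekly = aggregate_weekly(steps)
    write_csv(weekly, RESULTS / "activity_weekly.csv")
    print(f"{len(steps)} interpolated 80-s steps -> {len(weekly)} weekly rows")
    by_diel = weekly.groupby("diel")["activity_mh"].mean()
    print("mean weekly activity (m/h) by diel period:")
    print(by_diel.round(1).to_string())


if __name__ == "__main__":
    main()
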