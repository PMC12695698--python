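"""Generate the synthetic study cohorts.

Writes two datasets under results/:
* ``synthetic_cohort/`` — raw-level telemetry for a compact cohort (capped
  track days) used by the filtering/activity/space-use steps (02-05);
* ``model_cohort.csv`` — model-ready weekly behavior rows for the full-size
  cohort (177 individuals, multi-year presence histories) used by the
  classification summary (03) and the mixed-model fit (06).
"""

from datetime import date
from pathlib import Path

import pandas as pd

from skatemove.synthetic import (SimConfig, individuals_frame, simulate_individuals,
                                 simulate_weekly_rows, write_simulated)
from skatemove.telemetry import write_csv

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    RESULTS.mkdir(exist_ok=True)

    raw_cfg = SimConfig(
        n_individuals=20,
        study_start=date(2019, 5, 5),
        study_end=date(2021, 11, 1),
        raw_days_per_individual=30,
        singleton_rate=0.2,
        seed=SEED,
    )
    paths = write_simulated(RESULTS / "synthetic_cohort", raw_cfg)
    print("raw cohort written:")
    for k, v in paths.items():
        print(f"  {k}: {v}")

    full_cfg = SimConfig(n_individuals=177, seed=SEED)
    individuals = simulate_individuals(full_cfg)
    rows = simulate_weekly_rows(individuals, full_cfg)
    write_csv(individuals_frame(individuals), RESULTS / "model_cohort_individuals.csv")
    write_csv(rows, RESULTS / "model_cohort.csv")
    counts = pd.Series([i.archetype for i in individuals]).value_counts()
    print(f"\nfull cohort: {len(individuals)} individuals, {len(rows)} weekly rows")
    print(f"archetypes: {counts.to_dict()} "
          "(generating frequencies 24.3% CR / 59.3% SR / 16.4% SF)")


if __name__ == "__main__":
    main()
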