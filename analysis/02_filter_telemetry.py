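"""Filter the raw synthetic telemetry.

Removes detections isolated within a rolling 24 h window, calibrates the
per-dialect positional-error cutoff against the reference transmitters
(largest threshold keeping the median measured error below 3.5 m), and
filters positions. Prints the per-dialect retention the way retention is
conventionally reported (count and percentage per manufacturer dialect).
"""

from pathlib import Path

from skatemove import telemetry

RESULTS = Path(__file__).resolve().parents[1] / "results"
COHORT = RESULTS / "synthetic_cohort"


def main() -> None:
    det = telemetry.read_detections(COHORT / "detections.csv")
    kept_det, removed = telemetry.filter_single_detections(det)
    telemetry.write_csv(kept_det, RESULTS / "detections_filtered.csv")
    print(f"detections: {len(det)} -> {len(kept_det)} "
          f"({len(removed)} isolated detections removed)")

    ref = telemetry.read_reference_fixes(COHORT / "reference_fixes.csv")
    cutoffs = telemetry.calibrate_error_cutoff(ref, target_median_error=3.5)
    for src, res in cutoffs.items():
        print(f"cutoff[{src}]: metric <= {res.cutoff:.3f} "
              f"(median error {res.median_error:.2f} m, "
              f"reference retention {100 * res.retention:.1f}%)")

    fixes = telemetry.read_positions(COHORT / "positions.csv")
    kept_pos, summary = telemetry.filter_positions(fixes, cutoffs)
    telemetry.write_csv(kept_pos, RESULTS / "positions_filtered.csv")
    telemetry.write_csv(summary, RESULTS / "position_retention.csv")
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
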