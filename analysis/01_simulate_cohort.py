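#!/usr/bin/env python
"""Generate the 35-mouse reference cohort and export its tables.

Writes the schedule, weights, ground-truth composition and the per-day
metrics table under results/analysis/. The raw minute-resolution logs are
large and regenerable from the seed, so they are not exported here; use
``bottlechoice.io.write_drink_log`` if they are needed on disk.
"""

from bottlechoice.io import write_schedule, write_weights
from bottlechoice.simulate import DEFAULT_REFERENCE_SEED, reference_cohort

from _common import cohort_daily, outdir


def main() -> None:
    out = outdir()
    cohort = reference_cohort(DEFAULT_REFERENCE_SEED)

    write_schedule(cohort.schedule, out / "schedule.yaml")
    write_weights(cohort.records, out / "weights.csv")
    cohort.truth.to_csv(out / "cohort_truth.csv", index=False)

    daily = cohort_daily(cohort)
    daily.to_csv(out / "daily_metrics.csv", index=False, float_format="%.4f")

    comp = cohort.truth["archetype"].value_counts()
    print(f"Reference cohort: {len(cohort.logs)} mice, seed {DEFAULT_REFERENCE_SEED}")
    print(comp.to_string())
    n_av = (cohort.truth["true_label"] == "avoider").sum()
    print(f"ground truth: {n_av} avoiders / {len(cohort.logs)} mice")
    print(f"wrote schedule, weights, truth and {len(daily)} daily-metric rows to {out}")


if __name__ == "__main__":
    main()
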