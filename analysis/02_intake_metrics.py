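#!/usr/bin/env python
"""Population intake and percent-consumption profiles across concentrations.

Reproduces the group-level picture: daily nicotine intake rises with
concentration (titrating around ~10 mg/kg/day at the population level),
while percent consumption starts near 50% and falls at high concentrations.
Also tabulates each mouse's min/max consecutive-day intake difference — the
feature that separates the two phenotypes.
"""

import pandas as pd

from bottlechoice.metrics import intake_deltas
from bottlechoice.simulate import reference_cohort

from _common import cohort_daily, cohort_summaries, outdir


def main() -> None:
    out = outdir()
    cohort = reference_cohort()
    summaries = cohort_summaries(cohort)
    daily = cohort_daily(cohort)

    by_conc = (
        summaries.groupby("concentration")
        .agg(mean_intake=("mean_intake", "mean"), sem_intake=("mean_intake", "sem"),
             mean_pct=("mean_pct", "mean"), sem_pct=("mean_pct", "sem"),
             n=("mouse_id", "size"))
        .reset_index()
    )
    by_conc.to_csv(out / "population_by_concentration.csv", index=False,
                   float_format="%.3f")
    print("Population means by nicotine concentration (µg/ml):")
    print(by_conc.round(2).to_string(index=False))

    deltas = []
    for mouse_id, sub in daily.groupby("mouse_id"):
        d = intake_deltas(sub)
        deltas.append(dict(mouse_id=mouse_id, min_delta=d.min_delta,
                           max_delta=d.max_delta))
    delta_df = pd.DataFrame(deltas)
    delta_df.to_csv(out / "intake_delta_extremes.csv", index=False,
                    float_format="%.3f")
    big_drop = (delta_df["min_delta"] < -2.0).sum()
    steady = (delta_df["min_delta"] > -0.5).sum()
    print(f"\nconsecutive-day differences: {big_drop} mice show a large negative "
          f"minimum (abrupt intake reductions); {steady} never drop beyond the "
          f"0.5 mg/kg/day noise band (steady increasers / very low drinkers); "
          f"tables in {out}")


if __name__ == "__main__":
    main()
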