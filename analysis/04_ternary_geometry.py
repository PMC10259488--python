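#!/usr/bin/env python
"""Pseudo-ternary choice geometry of the reference cohort.

Maps each mouse × condition to the consumption-index / side-bias plane,
computes distances to the three apices (0% consumption, 100% consumption,
pure side bias), and contrasts the avoider and non-avoider trajectories:
only avoiders migrate toward the 0% apex as concentration rises. Writes the
point and distance tables and an SVG of the diagram.
"""

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from bottlechoice.phenotype import classify_cohort
from bottlechoice.simulate import reference_cohort
from bottlechoice.ternary import SIDE_SCALE, group_apex_distances, points_table

from _common import cohort_summaries, outdir


def main() -> None:
    out = outdir()
    cohort = reference_cohort()
    calls = classify_cohort(cohort.logs, cohort.schedule, cohort.records)
    summaries = cohort_summaries(cohort)

    pts = points_table(summaries).merge(calls[["mouse_id", "label"]], on="mouse_id")
    pts.to_csv(out / "ternary_points.csv", index=False, float_format="%.3f")

    dist = group_apex_distances(pts, group_col="label")
    dist.to_csv(out / "apex_distances.csv", index=False, float_format="%.3f")

    first, last = pts["condition_id"].iloc[0], pts["condition_id"].iloc[-1]
    print("Mean distance to the 0%-consumption apex, habituation vs 200 µg/ml:")
    for label in ("avoider", "non_avoider"):
        sub = dist[(dist["label"] == label) & (dist["apex"] == "zero")]
        d0 = float(sub.loc[sub["condition_id"] == first, "mean"].iloc[0])
        d1 = float(sub.loc[sub["condition_id"] == last, "mean"].iloc[0])
        print(f"  {label:12s}: {d0:6.1f} -> {d1:6.1f}")

    fig, ax = plt.subplots(figsize=(6, 5.5))
    tri_x = [0, 100, 50, 0]
    tri_y = [0, 0, 100 * SIDE_SCALE, 0]
    ax.plot(tri_x, tri_y, color="0.4", lw=1)
    for label, color in (("non_avoider", "tab:blue"), ("avoider", "tab:orange")):
        sub = pts[pts["label"] == label]
        hab = sub[sub["condition_id"] == first]
        top = sub[sub["condition_id"] == last]
        ax.scatter(hab["x"], hab["y"] * SIDE_SCALE, s=12, color=color, alpha=0.5)
        ax.scatter(top["x"], top["y"] * SIDE_SCALE, s=45, color=color, label=label)
    ax.annotate("0% nic.", (0, 0), textcoords="offset points", xytext=(-12, -14))
    ax.annotate("100% nic.", (100, 0), textcoords="offset points", xytext=(-18, -14))
    ax.annotate("side biased", (50, 100 * SIDE_SCALE), textcoords="offset points",
                xytext=(-28, 8))
    ax.set_xlabel("consumption index (%)")
    ax.set_ylabel("side-bias index (scaled)")
    ax.legend(frameon=False)
    ax.set_title("small dots: habituation; large dots: 200 µg/ml")
    fig.tight_layout()
    fig.savefig(out / "ternary_diagram.svg")
    print(f"\npoint/distance tables and ternary_diagram.svg written to {out}")


if __name__ == "__main__":
    main()
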