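"""Avoider / non-avoider phenotype classification.

The behavioral definitions are narrative in origin; they are made operational
with four explicit, config-exposed parameters:

* ``low_intake_ceiling`` (2 mg/kg/day) — a mouse whose daily intake never
  reaches this ceiling is an avoider with rule ``low_intake``.
* ``noise_band`` (0.5 mg/kg/day) — day-to-day intake changes within this band
  are treated as noise.
* ``quit_level`` (0.2) — after an abrupt drop, intake must stay below this
  fraction of the pre-drop mean for the remainder of the task (evaluated on
  per-condition means of the post-drop days) for the drop to count as
  durable avoidance.
* ``avoid_pct`` (20%) — a condition counts as avoided when its mean percent
  drug consumption is below this.

Rule precedence: the low-intake rule is checked before the abrupt-drop rule,
so a mouse that both stays low and drops is labelled ``low_intake``. An
abrupt drop only qualifies when it lands at, or within one day after, an
increase in drug concentration. Mice with a strong side bias during
habituation (preference <20% or >80%, strict inequalities) are excluded
before classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from bottlechoice.io import DrinkLog, MouseRecord, Schedule
from bottlechoice.metrics import (
    condition_summaries,
    daily_metrics,
    habituation_side_preference,
    intake_deltas,
)

__all__ = [
    "LABEL_AVOIDER",
    "LABEL_NON_AVOIDER",
    "LABEL_EXCLUDED",
    "PhenotypeParams",
    "PhenotypeCall",
    "exclude_side_bias",
    "classify_avoider",
    "aversion_threshold",
    "classify_cohort",
    "cohort_phenotype_table",
]

LABEL_AVOIDER = "avoider"
LABEL_NON_AVOIDER = "non_avoider"
LABEL_EXCLUDED = "excluded"

RULE_LOW_INTAKE = "low_intake"
RULE_ABRUPT_DROP = "abrupt_drop"
RULE_MONOTONE = "monotone_increase"
RULE_PLATEAU = "plateau"
RULE_SIDE_BIAS = "side_bias_exclusion"


@dataclass
class PhenotypeParams:
    low_intake_ceiling: float = 2.0  # mg/kg/day
    noise_band: float = 0.5  # mg/kg/day
    quit_level: float = 0.2  # fraction of pre-drop mean intake
    avoid_pct: float = 20.0  # % consumption counting as avoidance
    side_bias_low: float = 20.0  # habituation exclusion bounds, strict
    side_bias_high: float = 80.0


@dataclass
class PhenotypeCall:
    mouse_id: str
    label: str  # avoider | non_avoider | excluded
    rule_fired: str
    features: dict = field(default_factory=dict)
    aversion_threshold_conc: float | None = None


def exclude_side_bias(
    habituation_pct: float, params: PhenotypeParams | None = None
) -> tuple[bool, str]:
    """Apply the habituation side-bias exclusion.

    Returns ``(excluded, reason)``. Excluded iff the habituation side
    preference is strictly below 20% or strictly above 80%; the boundaries
    themselves are kept. An undefined preference (no habituation drinking)
    is excluded as unassessable.
    """
    params = params or PhenotypeParams()
    if not np.isfinite(habituation_pct):
        return True, "no habituation drinking"
    if habituation_pct < params.side_bias_low or habituation_pct > params.side_bias_high:
        return True, f"habituation side preference {habituation_pct:.1f}%"
    return False, ""


def _drug_condition_means(daily: pd.DataFrame) -> pd.DataFrame:
    drug = daily[(daily["concentration"] > 0) & ~daily["missing"]]
    return (
        drug.groupby("condition_id", sort=False)
        .agg(
            concentration=("concentration", "first"),
            mean_intake=("intake_mg_per_kg", "mean"),
            mean_pct=("pct_drug", "mean"),
            first_day=("day", "min"),
        )
        .reset_index()
        .sort_values("first_day")
    )


def _find_abrupt_drop(
    drug: pd.DataFrame, deltas, params: PhenotypeParams
) -> tuple[int, float] | None:
    """First durable transition-anchored drop; returns (drop_day, threshold_conc)."""
    intake = drug["intake_mg_per_kg"].to_numpy(float)
    days = drug["day"].to_numpy(int)
    conc = drug["concentration"].to_numpy(float)
    cond = drug["condition_id"].to_numpy(object)
    for j, (delta, at_step) in enumerate(zip(deltas.deltas, deltas.after_increase)):
        if delta >= -params.noise_band or not at_step:
            continue
        drop_idx = j + 1  # drop lands on this drug day
        pre = intake[:drop_idx]
        if len(pre) == 0:
            continue
        quit_ceiling = params.quit_level * float(pre.mean())
        post = pd.DataFrame(
            {"cond": cond[drop_idx:], "intake": intake[drop_idx:]}
        )
        if len(post) == 0:
            continue
        cond_means = post.groupby("cond", sort=False)["intake"].mean()
        if bool((cond_means < quit_ceiling).all()):
            return int(days[drop_idx]), float(conc[drop_idx])
    return None


def classify_avoider(
    daily: pd.DataFrame,
    sched: Schedule | None = None,
    params: PhenotypeParams | None = None,
) -> PhenotypeCall:
    """Classify one mouse from its daily metrics table (habituation included).

    Avoider rules: ``low_intake`` (daily intake never reaches the ceiling),
    else ``abrupt_drop`` (a > noise_band drop at/within 1 day of a
    concentration increase with intake staying below ``quit_level`` × the
    pre-drop mean for every later condition). Non-avoiders are ``plateau``
    when the last two condition means agree within the noise band (or when a
    non-durable drop exceeded it), else ``monotone_increase``.
    """
    params = params or PhenotypeParams()
    drug = daily[(daily["concentration"] > 0) & ~daily["missing"]].sort_values("day")
    if len(drug) < 2:
        raise ValueError("classification needs at least 2 covered drug days")
    deltas = intake_deltas(daily)
    cond_means = _drug_condition_means(daily)
    max_intake = float(drug["intake_mg_per_kg"].max())
    hab_pct = habituation_side_preference(daily)
    final_pct = float(cond_means["mean_pct"].iloc[-1])
    features = dict(
        min_delta=deltas.min_delta,
        max_delta=deltas.max_delta,
        max_intake=max_intake,
        final_pct=final_pct,
        habituation_pct=hab_pct,
    )

    if max_intake < params.low_intake_ceiling:
        label, rule = LABEL_AVOIDER, RULE_LOW_INTAKE
    else:
        drop = _find_abrupt_drop(drug, deltas, params)
        if drop is not None:
            label, rule = LABEL_AVOIDER, RULE_ABRUPT_DROP
            features["drop_day"] = drop[0]
        elif (
            len(cond_means) >= 2
            and abs(cond_means["mean_intake"].iloc[-1] - cond_means["mean_intake"].iloc[-2])
            <= params.noise_band
        ):
            label, rule = LABEL_NON_AVOIDER, RULE_PLATEAU
        elif deltas.min_delta > -params.noise_band:
            label, rule = LABEL_NON_AVOIDER, RULE_MONOTONE
        else:
            label, rule = LABEL_NON_AVOIDER, RULE_PLATEAU

    call = PhenotypeCall(
        mouse_id=str(drug["mouse_id"].iloc[0]),
        label=label,
        rule_fired=rule,
        features=features,
    )
    call.aversion_threshold_conc = aversion_threshold(daily, params=params, call=call)
    return call


def aversion_threshold(
    daily: pd.DataFrame,
    sched: Schedule | None = None,
    params: PhenotypeParams | None = None,
    call: PhenotypeCall | None = None,
) -> float | None:
    """Lowest concentration from which the mouse persistently avoids the drug.

    For avoiders: the lowest concentration whose condition-mean percent
    consumption is below ``avoid_pct`` with every later condition also below
    it; ``None`` for non-avoiders or when no such condition exists.
    """
    params = params or PhenotypeParams()
    if call is not None and call.label != LABEL_AVOIDER:
        return None
    cond_means = _drug_condition_means(daily)
    below = (cond_means["mean_pct"] < params.avoid_pct).to_numpy()
    if not below.any():
        return None
    # suffix scan: first condition from which all later ones are avoided
    suffix_ok = np.logical_and.accumulate(below[::-1])[::-1]
    idx = int(np.argmax(suffix_ok))
    if not suffix_ok[idx]:
        return None
    return float(cond_means["concentration"].iloc[idx])


def classify_cohort(
    logs: list[DrinkLog],
    sched: Schedule,
    records: list[MouseRecord],
    params: PhenotypeParams | None = None,
    *,
    day_offset_minutes: int = 0,
) -> pd.DataFrame:
    """Exclusion + classification for a whole cohort.

    Returns a tidy table with one row per mouse: label, rule, features and
    aversion threshold. Mice failing the habituation side-bias screen get
    ``label='excluded'`` and are not classified further.
    """
    params = params or PhenotypeParams()
    recs = {r.mouse_id: r for r in records}
    rows = []
    for log in logs:
        daily = daily_metrics(log, sched, recs[log.mouse_id],
                              day_offset_minutes=day_offset_minutes)
        hab_pct = habituation_side_preference(daily)
        excluded, reason = exclude_side_bias(hab_pct, params)
        if excluded:
            call = PhenotypeCall(log.mouse_id, LABEL_EXCLUDED, RULE_SIDE_BIAS,
                                 {"habituation_pct": hab_pct, "reason": reason})
        else:
            call = classify_avoider(daily, sched, params)
        rows.append(
            dict(
                mouse_id=call.mouse_id,
                label=call.label,
                rule_fired=call.rule_fired,
                aversion_threshold_conc=call.aversion_threshold_conc,
                **{k: v for k, v in call.features.items() if not isinstance(v, str)},
            )
        )
    return pd.DataFrame(rows)


def cohort_phenotype_table(
    calls: pd.DataFrame, group_col: str | None = None
) -> pd.DataFrame:
    """Counts and proportions of phenotype labels, optionally per group."""
    keys = [group_col] if group_col else []
    rows = []
    groups = calls.groupby(group_col, sort=False) if group_col else [(None, calls)]
    for key, sub in groups:
        counts = sub["label"].value_counts()
        n = len(sub)
        n_class = int(counts.get(LABEL_AVOIDER, 0) + counts.get(LABEL_NON_AVOIDER, 0))
        row = {group_col: key} if group_col else {}
        row.update(
            n_total=n,
            n_excluded=int(counts.get(LABEL_EXCLUDED, 0)),
            n_avoider=int(counts.get(LABEL_AVOIDER, 0)),
            n_non_avoider=int(counts.get(LABEL_NON_AVOIDER, 0)),
            prop_avoider=(counts.get(LABEL_AVOIDER, 0) / n_class) if n_class else float("nan"),
        )
        rows.append(row)
    return pd.DataFrame(rows)
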