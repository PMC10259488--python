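"""Daily and per-condition intake and percent-consumption metrics.

Definitions
-----------
* Daily drug-bottle volume is the increment of that bottle's cumulative
  volume over the calendar day (minutes ``[1440*(d-1), 1440*d)`` from
  experiment start, shiftable with ``day_offset_minutes``).
* Nicotine intake (mg/kg/day) = ``vol_drug_ml * concentration_ug_per_ml /
  weight_g`` (µg/ml × ml = µg; per g body weight this is exactly mg/kg).
* Percent drug consumption = ``100 * vol_drug / (vol_drug + vol_vehicle)``;
  undefined (NaN) when no fluid was consumed — never 0 or 50.
* A day with no log coverage at all is flagged ``missing`` and excluded from
  condition means (no imputation).

During habituation both bottles hold water, so intake is 0 and the "drug"
side is a virtual one: habituation days are assigned the same
alternate-every-other-day side pattern as the drug phase, which makes
water-vs-water percent-consumption (and hence ternary points) well defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from bottlechoice.io import (
    MINUTES_PER_DAY,
    SIDE_LEFT,
    SIDE_NONE,
    SIDE_RIGHT,
    DrinkLog,
    MouseRecord,
    Schedule,
    weight_on_day,
)

__all__ = [
    "DailyMetrics",
    "IntakeDeltas",
    "daily_metrics",
    "condition_summaries",
    "habituation_side_preference",
    "intake_deltas",
    "titration_response",
]

DailyMetrics = pd.DataFrame  # tidy per-day table; see daily_metrics() for columns


def _cumulative_before(minutes: np.ndarray, volume: np.ndarray, t: int) -> float:
    """Cumulative volume consumed strictly before minute ``t`` (0 before the log)."""
    i = int(np.searchsorted(minutes, t, side="left"))
    return float(volume[i - 1]) if i > 0 else 0.0


def _virtual_habituation_sides(sched: Schedule, swap_every: int = 2) -> dict[int, str]:
    # mirror the drug phase's alternation (starting on the same side as the
    # first drug day) so water-vs-water days have a well-defined
    # "to-be-drug" side and side relabeling stays a symmetry
    drug_sides = [d.drug_side for d in sched.days if d.drug_side != SIDE_NONE]
    first = drug_sides[0] if drug_sides else SIDE_LEFT
    other = SIDE_RIGHT if first == SIDE_LEFT else SIDE_LEFT
    return {
        d: (first if (i // swap_every) % 2 == 0 else other)
        for i, d in enumerate(sched.habituation_days())
    }


def daily_metrics(
    log: DrinkLog,
    sched: Schedule,
    rec: MouseRecord,
    *,
    day_offset_minutes: int = 0,
    habituation_virtual_sides: bool = True,
) -> pd.DataFrame:
    """Per-day metrics for one mouse.

    Returns a DataFrame with one row per schedule day and columns
    ``mouse_id, day, condition_id, concentration, drug_side, pct_side,
    is_habituation, vol_left_ml, vol_right_ml, vol_drug_ml, vol_vehicle_ml,
    vol_total_ml, weight_g, intake_mg_per_kg, pct_drug, missing``.

    ``pct_side`` is the side used for the percent-consumption numerator: the
    actual drug side on drug days, the virtual alternating side on
    habituation days (or ``none`` when disabled, leaving pct NaN).
    """
    virtual = _virtual_habituation_sides(sched) if habituation_virtual_sides else {}
    rows = []
    for sd in sched.days:
        start = MINUTES_PER_DAY * (sd.day - 1) + day_offset_minutes
        end = start + MINUTES_PER_DAY
        i0 = int(np.searchsorted(log.minutes, start, side="left"))
        i1 = int(np.searchsorted(log.minutes, end, side="left"))
        covered = i1 > i0
        is_hab = sd.concentration == 0
        pct_side = sd.drug_side if sd.drug_side != SIDE_NONE else virtual.get(sd.day, SIDE_NONE)
        w = weight_on_day(rec, sd.day)

        if not covered:
            rows.append(
                dict(
                    mouse_id=log.mouse_id, day=sd.day, condition_id=sd.condition_id,
                    concentration=sd.concentration, drug_side=sd.drug_side,
                    pct_side=pct_side, is_habituation=is_hab,
                    vol_left_ml=np.nan, vol_right_ml=np.nan, vol_drug_ml=np.nan,
                    vol_vehicle_ml=np.nan, vol_total_ml=np.nan, weight_g=w,
                    intake_mg_per_kg=np.nan, pct_drug=np.nan, missing=True,
                )
            )
            continue

        inc_l = _cumulative_before(log.minutes, log.vol_left, end) - _cumulative_before(
            log.minutes, log.vol_left, start
        )
        inc_r = _cumulative_before(log.minutes, log.vol_right, end) - _cumulative_before(
            log.minutes, log.vol_right, start
        )
        total = inc_l + inc_r
        if pct_side == SIDE_LEFT:
            vol_drug, vol_veh = inc_l, inc_r
        elif pct_side == SIDE_RIGHT:
            vol_drug, vol_veh = inc_r, inc_l
        else:
            vol_drug = vol_veh = np.nan
        pct = 100.0 * vol_drug / total if total > 0 and pct_side != SIDE_NONE else np.nan
        intake = 0.0 if is_hab else vol_drug * sd.concentration / w
        rows.append(
            dict(
                mouse_id=log.mouse_id, day=sd.day, condition_id=sd.condition_id,
                concentration=sd.concentration, drug_side=sd.drug_side,
                pct_side=pct_side, is_habituation=is_hab,
                vol_left_ml=inc_l, vol_right_ml=inc_r, vol_drug_ml=vol_drug,
                vol_vehicle_ml=vol_veh, vol_total_ml=total, weight_g=w,
                intake_mg_per_kg=intake, pct_drug=pct, missing=False,
            )
        )
    return pd.DataFrame(rows)


def condition_summaries(daily: pd.DataFrame, sched: Schedule | None = None) -> pd.DataFrame:
    """Per-condition means for one mouse's daily table.

    ``pct_c1``/``pct_c2`` are the percent drug consumption averaged over the
    days with the drug bottle on the left (c1) resp. right (c2) physical
    side; a side with no usable days yields NaN. Condition means are
    unweighted over non-missing days; ``n_days_used`` reports coverage.
    """
    rows = []
    for condition_id, sub in daily.groupby("condition_id", sort=False):
        ok = sub[~sub["missing"]]
        pct_ok = ok[ok["pct_drug"].notna()]
        c1 = pct_ok.loc[pct_ok["pct_side"] == SIDE_LEFT, "pct_drug"]
        c2 = pct_ok.loc[pct_ok["pct_side"] == SIDE_RIGHT, "pct_drug"]
        rows.append(
            dict(
                mouse_id=sub["mouse_id"].iloc[0],
                condition_id=condition_id,
                concentration=sub["concentration"].iloc[0],
                is_habituation=bool(sub["is_habituation"].iloc[0]),
                n_days=len(sub),
                n_days_used=len(ok),
                mean_intake=ok["intake_mg_per_kg"].mean(),
                mean_pct=pct_ok["pct_drug"].mean(),
                pct_c1=c1.mean() if len(c1) else np.nan,
                pct_c2=c2.mean() if len(c2) else np.nan,
            )
        )
    return pd.DataFrame(rows)


def habituation_side_preference(daily: pd.DataFrame) -> float:
    """Percent of total habituation fluid consumed from the left bottle.

    This is the side-preference figure the <20% / >80% exclusion rule is
    applied to. NaN when nothing was drunk during habituation.
    """
    hab = daily[daily["is_habituation"] & ~daily["missing"]]
    total = hab["vol_total_ml"].sum()
    if len(hab) == 0 or total <= 0:
        return float("nan")
    return float(100.0 * hab["vol_left_ml"].sum() / total)


@dataclass
class IntakeDeltas:
    """Consecutive-(drug-)day intake differences for one mouse.

    ``after_increase[j]`` marks deltas whose later day falls at, or within one
    day after, an increase in nicotine concentration — the transitions where
    an abrupt avoidance drop is expected to appear.
    """

    mouse_id: str
    days: np.ndarray  # drug days used, ordered
    deltas: np.ndarray  # intake[day j+1] - intake[day j]
    after_increase: np.ndarray  # bool per delta
    min_delta: float
    max_delta: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mouse_id": self.mouse_id,
                "day_from": self.days[:-1],
                "day_to": self.days[1:],
                "delta_intake": self.deltas,
                "after_concentration_increase": self.after_increase,
            }
        )


def intake_deltas(daily: pd.DataFrame) -> IntakeDeltas:
    """Differences in intake between consecutive drug days (habituation excluded)."""
    drug = daily[(daily["concentration"] > 0) & ~daily["missing"]].sort_values("day")
    if len(drug) < 2:
        raise ValueError("need at least 2 drug days with coverage to compute deltas")
    intake = drug["intake_mg_per_kg"].to_numpy(float)
    days = drug["day"].to_numpy(int)
    conc = drug["concentration"].to_numpy(float)
    deltas = np.diff(intake)
    # per-day flag: concentration rose entering this day (the first drug day
    # always follows the 0 µg/ml habituation step)
    stepped = np.concatenate(([True], conc[1:] > conc[:-1]))
    # delta j spans (day j -> day j+1); the drop lands on day j+1
    after = stepped[1:] | stepped[:-1]
    return IntakeDeltas(
        mouse_id=str(drug["mouse_id"].iloc[0]),
        days=days,
        deltas=deltas,
        after_increase=after,
        min_delta=float(deltas.min()),
        max_delta=float(deltas.max()),
    )


def titration_response(
    daily: pd.DataFrame,
    sched: Schedule,
    *,
    lag_days: int = 1,
    tolerance: float = 0.25,
) -> pd.DataFrame:
    """Per-transition intake adjustment around each concentration change.

    For each transition between consecutive drug conditions the table
    reports the pre-transition condition mean, the last pre-transition day,
    intake on each of the first ``lag_days`` days after the change, and a
    ``rapid`` flag set when intake on day ``lag_days`` is back within
    ``tolerance`` (relative) of the pre-transition condition mean — i.e. the
    mouse re-titrated its dose within a day.
    """
    conds = [c for c in sched.conditions() if c[1] > 0]
    if len(conds) < 2:
        return pd.DataFrame(
            columns=[
                "mouse_id", "cond_from", "cond_to", "conc_from", "conc_to",
                "pre_mean_intake", "last_pre_intake", "post_intake", "rapid",
            ]
        )
    by_day = daily.set_index("day")
    rows = []
    for (cid_a, conc_a, days_a), (cid_b, conc_b, days_b) in zip(conds[:-1], conds[1:]):
        pre = daily[(daily["condition_id"] == cid_a) & ~daily["missing"]]
        pre_mean = pre["intake_mg_per_kg"].mean()
        last_pre = by_day["intake_mg_per_kg"].get(days_a[-1], np.nan)
        post_day = days_b[min(lag_days, len(days_b)) - 1]
        post = by_day["intake_mg_per_kg"].get(post_day, np.nan)
        rapid = (
            bool(abs(post - pre_mean) <= tolerance * max(pre_mean, 1e-12))
            if np.isfinite(post) and np.isfinite(pre_mean)
            else False
        )
        rows.append(
            dict(
                mouse_id=daily["mouse_id"].iloc[0],
                cond_from=cid_a, cond_to=cid_b,
                conc_from=conc_a, conc_to=conc_b,
                pre_mean_intake=pre_mean, last_pre_intake=last_pre,
                post_intake=post, rapid=rapid,
            )
        )
    return pd.DataFrame(rows)
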