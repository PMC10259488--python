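"""Readers, writers and domain containers for two-bottle choice data.

On-disk dialects
----------------
* **Drink logs** — delimited text (CSV, or TSV when the extension is
  ``.tsv``/``.tab``) with columns ``mouse_id, minute, volume_left_ml,
  volume_right_ml``. Volumes are *cumulative* ml per bottle, recorded every
  minute by the acquisition system; gaps (missing minutes) are allowed and
  mean "no drinking recorded", duplicated minutes are an error.
* **Schedules** — YAML with a ``days`` list of ``{day, concentration,
  drug_side}`` records (concentration in µg/ml; ``drug_side`` one of
  ``left``/``right``/``none``) and an optional ``vehicle`` string.
* **Weights** — delimited text with columns ``mouse_id, day, weight_g``.
  Mice are weighed every other day, so lookups carry the nearest earlier
  weight forward (and the first weight backward before it).

All files are UTF-8; volumes are written to 3 decimals and weights to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

SIDE_LEFT = "left"
SIDE_RIGHT = "right"
SIDE_NONE = "none"
SIDES = (SIDE_LEFT, SIDE_RIGHT)

MINUTES_PER_DAY = 1440

_LOG_COLUMNS = ["mouse_id", "minute", "volume_left_ml", "volume_right_ml"]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


# ---------------------------------------------------------------------------
# Drink logs
# ---------------------------------------------------------------------------


@dataclass
class DrinkLog:
    """Minute-resolution cumulative drinking volumes for one mouse.

    ``minutes`` are minutes since experiment start (strictly increasing,
    gaps allowed); ``vol_left``/``vol_right`` are the cumulative ml consumed
    from each bottle at each timestamp (non-negative, non-decreasing).
    """

    mouse_id: str
    minutes: np.ndarray
    vol_left: np.ndarray
    vol_right: np.ndarray

    def __post_init__(self) -> None:
        self.minutes = np.asarray(self.minutes, dtype=np.int64)
        self.vol_left = np.asarray(self.vol_left, dtype=float)
        self.vol_right = np.asarray(self.vol_right, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = len(self.minutes)
        if len(self.vol_left) != n or len(self.vol_right) != n:
            raise ValueError(
                f"mouse {self.mouse_id}: bottle series lengths differ from timestamps"
            )
        if n == 0:
            raise ValueError(f"mouse {self.mouse_id}: empty drink log")
        dm = np.diff(self.minutes)
        if np.any(dm == 0):
            m = int(self.minutes[1:][dm == 0][0])
            raise ValueError(f"mouse {self.mouse_id}: duplicated minute {m}")
        if np.any(dm < 0):
            raise ValueError(f"mouse {self.mouse_id}: timestamps not increasing")
        for name, v in (("volume_left_ml", self.vol_left), ("volume_right_ml", self.vol_right)):
            if v[0] < 0:
                raise ValueError(f"mouse {self.mouse_id}: negative cumulative volume in {name}")
            dv = np.diff(v)
            if np.any(dv < -1e-9):
                m = int(self.minutes[1:][dv < -1e-9][0])
                raise ValueError(
                    f"mouse {self.mouse_id}: cumulative volume decreased in {name} at minute {m}"
                )

    def swapped(self) -> "DrinkLog":
        """Return a copy with the left/right bottle labels exchanged."""
        return DrinkLog(self.mouse_id, self.minutes.copy(),
                        self.vol_right.copy(), self.vol_left.copy())


def read_drink_log(path: str | Path) -> list[DrinkLog]:
    """Read a drinking-log table; one :class:`DrinkLog` per mouse, validated."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in _LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    logs = []
    for mouse_id, sub in df.groupby("mouse_id", sort=True):
        sub = sub.sort_values("minute")
        logs.append(
            DrinkLog(
                str(mouse_id),
                sub["minute"].to_numpy(),
                sub["volume_left_ml"].to_numpy(float),
                sub["volume_right_ml"].to_numpy(float),
            )
        )
    return logs


def write_drink_log(logs: Iterable[DrinkLog], path: str | Path) -> None:
    path = Path(path)
    frames = [
        pd.DataFrame(
            {
                "mouse_id": log.mouse_id,
                "minute": log.minutes,
                "volume_left_ml": np.round(log.vol_left, 3),
                "volume_right_ml": np.round(log.vol_right, 3),
            }
        )
        for log in logs
    ]
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep=_sep_for(path), index=False, float_format="%.3f"
    )


# ---------------------------------------------------------------------------
# Schedules
# ---------------------------------------------------------------------------


@dataclass
class ScheduleDay:
    day: int
    concentration: float  # µg/ml nicotine in the drug bottle; 0 during habituation
    drug_side: str  # left | right | none
    condition_id: str = ""


@dataclass
class Schedule:
    """Ordered per-day (concentration, drug side) assignments.

    Condition ids are derived as maximal runs of equal concentration and
    labelled ``cond{k}_{conc}ug`` in schedule order, so a re-exposure to a
    previously used concentration forms a new condition.
    """

    days: list[ScheduleDay]
    vehicle: str = "2% saccharine"

    def __post_init__(self) -> None:
        if not self.days:
            raise ValueError("schedule has no days")
        self.days = sorted(self.days, key=lambda d: d.day)
        for d in self.days:
            if d.concentration < 0:
                raise ValueError(f"day {d.day}: negative concentration")
            if d.concentration > 0 and d.drug_side not in SIDES:
                raise ValueError(
                    f"day {d.day}: drug_side missing for concentration {d.concentration:g}"
                )
        self._assign_condition_ids()

    def _assign_condition_ids(self) -> None:
        k = 0
        prev_conc: float | None = None
        for d in self.days:
            if prev_conc is None or d.concentration != prev_conc:
                k += 1
                prev_conc = d.concentration
            d.condition_id = f"cond{k:02d}_{d.concentration:g}ug"

    # -- convenience accessors -------------------------------------------------

    @property
    def n_days(self) -> int:
        return self.days[-1].day

    def day(self, day_index: int) -> ScheduleDay:
        for d in self.days:
            if d.day == day_index:
                return d
        raise KeyError(f"day {day_index} not in schedule")

    def conditions(self) -> list[tuple[str, float, list[int]]]:
        """``(condition_id, concentration, day_indices)`` in schedule order."""
        out: list[tuple[str, float, list[int]]] = []
        for d in self.days:
            if out and out[-1][0] == d.condition_id:
                out[-1][2].append(d.day)
            else:
                out.append((d.condition_id, d.concentration, [d.day]))
        return out

    def drug_days(self) -> list[int]:
        return [d.day for d in self.days if d.concentration > 0]

    def habituation_days(self) -> list[int]:
        return [d.day for d in self.days if d.concentration == 0]

    def swapped(self) -> "Schedule":
        """Return a copy with left/right drug sides exchanged."""
        flip = {SIDE_LEFT: SIDE_RIGHT, SIDE_RIGHT: SIDE_LEFT, SIDE_NONE: SIDE_NONE}
        return Schedule(
            [ScheduleDay(d.day, d.concentration, flip[d.drug_side]) for d in self.days],
            vehicle=self.vehicle,
        )


def read_schedule(path: str | Path) -> Schedule:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not data or "days" not in data or not data["days"]:
        raise ValueError(f"{path}: empty or day-less schedule file")
    days = [
        ScheduleDay(
            int(rec["day"]),
            float(rec["concentration"]),
            str(rec.get("drug_side", SIDE_NONE)),
        )
        for rec in data["days"]
    ]
    return Schedule(days, vehicle=str(data.get("vehicle", "2% saccharine")))


def write_schedule(sched: Schedule, path: str | Path) -> None:
    data = {
        "vehicle": sched.vehicle,
        "days": [
            {"day": d.day, "concentration": d.concentration, "drug_side": d.drug_side}
            for d in sched.days
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def _drug_side_pattern(i: int, first_side: str, swap_every: int) -> str:
    other = SIDE_RIGHT if first_side == SIDE_LEFT else SIDE_LEFT
    return first_side if (i // swap_every) % 2 == 0 else other


def standard_schedule(
    concentrations: Sequence[float] = (10.0, 50.0, 100.0, 200.0),
    days_per_condition: int = 4,
    habituation_days: int = 4,
    first_drug_side: str = SIDE_LEFT,
    swap_every: int = 2,
) -> Schedule:
    """The ascending-concentration protocol: habituation then 4 days per
    concentration with the drug bottle swapped every other day."""
    days = [ScheduleDay(d, 0.0, SIDE_NONE) for d in range(1, habituation_days + 1)]
    i = 0
    day = habituation_days + 1
    for conc in concentrations:
        for _ in range(days_per_condition):
            days.append(ScheduleDay(day, conc, _drug_side_pattern(i, first_drug_side, swap_every)))
            i += 1
            day += 1
    return Schedule(days)


def single_step_schedule(
    concentration: float = 100.0,
    drug_days: int = 4,
    habituation_days: int = 4,
    first_drug_side: str = SIDE_LEFT,
    swap_every: int = 2,
) -> Schedule:
    """Habituation followed by direct exposure to a single concentration."""
    return standard_schedule(
        concentrations=(concentration,),
        days_per_condition=drug_days,
        habituation_days=habituation_days,
        first_drug_side=first_drug_side,
        swap_every=swap_every,
    )


# ---------------------------------------------------------------------------
# Mouse records (weights & tags)
# ---------------------------------------------------------------------------


@dataclass
class MouseRecord:
    """Sparse per-mouse body weights (g) plus free-form genotype/treatment tags."""

    mouse_id: str
    weights: dict[int, float]
    tags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValueError(f"mouse {self.mouse_id}: no recorded weights")
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError(f"mouse {self.mouse_id}: non-positive weight")


def weight_on_day(rec: MouseRecord, day: int) -> float:
    """Recorded weight if present, else nearest earlier weight (carry-forward);
    before the first record, the first weight (carry-backward)."""
    days = sorted(rec.weights)
    earlier = [d for d in days if d <= day]
    return rec.weights[earlier[-1]] if earlier else rec.weights[days[0]]


def read_weights(path: str | Path) -> list[MouseRecord]:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    for col in ("mouse_id", "day", "weight_g"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col}")
    tag_cols = [c for c in df.columns if c not in ("mouse_id", "day", "weight_g")]
    records = []
    for mouse_id, sub in df.groupby("mouse_id", sort=True):
        weights = {int(r.day): float(r.weight_g) for r in sub.itertuples()}
        tags = {c: str(sub[c].iloc[0]) for c in tag_cols}
        records.append(MouseRecord(str(mouse_id), weights, tags))
    return records


def write_weights(records: Iterable[MouseRecord], path: str | Path) -> None:
    path = Path(path)
    rows = []
    for rec in records:
        for day, w in sorted(rec.weights.items()):
            rows.append({"mouse_id": rec.mouse_id, "day": day, "weight_g": round(w, 1), **rec.tags})
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False, float_format="%.1f")


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Free-form per-mouse (or per-neuron) covariate table."""
    path = Path(path)
    return pd.read_csv(path, sep=_sep_for(path))
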