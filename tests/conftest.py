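"""Shared fixtures and table builders for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from bottlechoice import (
    classify_cohort,
    condition_summaries,
    daily_metrics,
    reference_cohort,
)


@pytest.fixture(scope="session")
def ref_cohort():
    """The fixed-seed 35-mouse reference cohort (generated once per run)."""
    return reference_cohort()


@pytest.fixture(scope="session")
def ref_calls(ref_cohort):
    return classify_cohort(ref_cohort.logs, ref_cohort.schedule, ref_cohort.records)


@pytest.fixture(scope="session")
def ref_summaries(ref_cohort):
    """Per-mouse condition summaries for the reference cohort, concatenated."""
    recs = {r.mouse_id: r for r in ref_cohort.records}
    frames = []
    for log in ref_cohort.logs:
        daily = daily_metrics(log, ref_cohort.schedule, recs[log.mouse_id])
        frames.append(condition_summaries(daily))
    return pd.concat(frames, ignore_index=True)


def make_daily(
    intakes,
    concs,
    pcts=None,
    mouse_id: str = "t1",
    hab_days: int = 0,
    hab_left_frac: float = 0.5,
) -> pd.DataFrame:
    """Build a minimal daily-metrics table directly from per-day values.

    ``intakes``/``concs``/``pcts`` describe the drug days; ``hab_days``
    water-vs-water days are prepended with the given left-bottle share.
    Useful for exercising classification rules on hand-crafted series.
    """
    intakes = list(intakes)
    concs = list(concs)
    assert len(intakes) == len(concs)
    if pcts is None:
        pcts = [50.0] * len(intakes)
    pcts = list(pcts)

    rows = []
    day = 1
    for _ in range(hab_days):
        rows.append(
            dict(
                mouse_id=mouse_id, day=day, condition_id="cond01_0ug",
                concentration=0.0, drug_side="none",
                pct_side="left" if day % 2 else "right", is_habituation=True,
                vol_left_ml=4.0 * hab_left_frac, vol_right_ml=4.0 * (1 - hab_left_frac),
                vol_drug_ml=np.nan, vol_vehicle_ml=np.nan, vol_total_ml=4.0,
                weight_g=25.0, intake_mg_per_kg=0.0,
                pct_drug=100.0 * hab_left_frac, missing=False,
            )
        )
        day += 1
    cond_idx = 1 + (1 if hab_days else 0)
    prev = None
    for intake, conc, pct in zip(intakes, concs, pcts):
        if prev is not None and conc != prev:
            cond_idx += 1
        prev = conc
        rows.append(
            dict(
                mouse_id=mouse_id, day=day, condition_id=f"cond{cond_idx:02d}_{conc:g}ug",
                concentration=float(conc), drug_side="left" if day % 2 else "right",
                pct_side="left" if day % 2 else "right", is_habituation=False,
                vol_left_ml=2.0, vol_right_ml=2.0, vol_drug_ml=2.0,
                vol_vehicle_ml=2.0, vol_total_ml=4.0, weight_g=25.0,
                intake_mg_per_kg=float(intake), pct_drug=float(pct), missing=False,
            )
        )
        day += 1
    return pd.DataFrame(rows)
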