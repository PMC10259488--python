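"""Shared helpers for the numbered analysis drivers."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from bottlechoice.metrics import condition_summaries, daily_metrics
from bottlechoice.simulate import Cohort

RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"


def outdir() -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    return RESULTS


def cohort_daily(cohort: Cohort) -> pd.DataFrame:
    """Concatenated per-day metrics for every mouse in a cohort."""
    recs = {r.mouse_id: r for r in cohort.records}
    return pd.concat(
        [daily_metrics(log, cohort.schedule, recs[log.mouse_id]) for log in cohort.logs],
        ignore_index=True,
    )


def cohort_summaries(cohort: Cohort) -> pd.DataFrame:
    """Concatenated per-condition summaries for every mouse in a cohort."""
    recs = {r.mouse_id: r for r in cohort.records}
    frames = []
    for log in cohort.logs:
        daily = daily_metrics(log, cohort.schedule, recs[log.mouse_id])
        frames.append(condition_summaries(daily))
    return pd.concat(frames, ignore_index=True)
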