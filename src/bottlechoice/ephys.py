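"""Quantification of nicotine-evoked responses.

Two read-outs are supported:

* **Puff-evoked currents** (ex vivo voltage clamp, typically −60 mV): the
  baseline is the median current over the second before the puff; the
  response is the minimum of the lightly smoothed current within a window
  after the puff (3 s default, matching the transient's time course). The
  amplitude is reported as a positive magnitude in pA — the field's
  "−pA" convention for inward currents. Deviations that do not exceed
  ``sig_mult`` × the baseline noise are reported as no response.
* **Peri-injection firing-rate changes** (in vivo juxtacellular spike
  trains): baseline rate over the 5 min before the i.v. injection; the
  response is the binned post-injection rate (10 s bins over 180 s) that
  deviates most from baseline, expressed as % of variation from baseline.
  The direction (activated/inhibited) is only asserted when the deviation
  exceeds ``sig_mult`` standard deviations of the binned baseline rate.

A generic ordinary-least-squares helper covers the dose–current and
anatomical-covariate correlations, returning R², adjusted R², F and the
two-sided p exactly satisfying F = R²/(1−R²)·(n−2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CurrentTrace",
    "SpikeTrain",
    "EvokedResponse",
    "RegressionResult",
    "puff_current_amplitude",
    "firing_rate_change",
    "covariate_regression",
    "regression_from_f",
    "per_mouse_means",
]

DIR_ACTIVATED = "activated"
DIR_INHIBITED = "inhibited"
DIR_NONE = "none"


@dataclass
class CurrentTrace:
    """Voltage-clamp current samples (pA) around a local agonist puff."""

    neuron_id: str
    sample_rate: float  # Hz
    samples: np.ndarray  # pA
    puff_time: float  # s from trace start
    holding_mv: float = -60.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not (0 <= self.puff_time <= len(self.samples) / self.sample_rate):
            raise ValueError("puff_time outside trace span")


@dataclass
class SpikeTrain:
    """Sorted spike times (s) around an i.v. injection."""

    neuron_id: str
    spike_times: np.ndarray
    injection_time: float
    baseline_span: float = 300.0  # 5 min baseline precedes the injection

    def __post_init__(self) -> None:
        self.spike_times = np.sort(np.asarray(self.spike_times, dtype=float))
        if self.injection_time < self.baseline_span:
            raise ValueError("injection_time earlier than the required baseline span")


@dataclass
class EvokedResponse:
    neuron_id: str
    kind: str  # "current" | "rate"
    amplitude: float  # pA magnitude, or Δrate in % of baseline
    baseline: float  # pA or Hz
    direction: str  # activated | inhibited | none
    window: tuple[float, float]  # response window used, s
    defined: bool = True
    note: str = ""


def puff_current_amplitude(
    trace: CurrentTrace,
    *,
    window_s: float = 3.0,
    baseline_s: float = 1.0,
    smooth_s: float = 0.005,
    sig_mult: float = 3.0,
) -> EvokedResponse:
    """Peak inward current after the puff, as a positive pA magnitude.

    The trace is box-smoothed (5 ms default) before the peak search so that
    single-sample noise extremes do not inflate the amplitude. Adding a
    constant offset to the whole trace leaves the result unchanged.
    """
    fs = trace.sample_rate
    i_puff = int(round(trace.puff_time * fs))
    i0 = i_puff - int(round(baseline_s * fs))
    if i0 < 0:
        raise ValueError("insufficient pre-puff baseline in trace")
    i_end = i_puff + int(round(window_s * fs))
    if i_end > len(trace.samples):
        raise ValueError("response window exceeds trace")
    k = max(1, int(round(smooth_s * fs)))
    kernel = np.ones(k) / k
    smoothed = np.convolve(trace.samples, kernel, mode="same")
    baseline = float(np.median(trace.samples[i0:i_puff]))
    # raw (unsmoothed) baseline SD: a conservative noise reference, so the
    # smoothed-extreme search cannot fire on noise alone
    noise_sd = float(np.std(trace.samples[i0:i_puff]))
    seg = smoothed[i_puff + 1 : i_end]
    amplitude = baseline - float(seg.min())
    window = (trace.puff_time, trace.puff_time + window_s)
    if amplitude > sig_mult * noise_sd and amplitude > 0:
        return EvokedResponse(trace.neuron_id, "current", amplitude, baseline,
                              DIR_ACTIVATED, window)
    return EvokedResponse(trace.neuron_id, "current", 0.0, baseline, DIR_NONE, window)


def firing_rate_change(
    train: SpikeTrain,
    *,
    bin_s: float = 10.0,
    post_s: float = 180.0,
    sig_mult: float = 2.0,
    smooth_bins: int = 3,
) -> EvokedResponse:
    """Percent change of firing rate from baseline after the injection.

    Baseline rate = spike count over the pre-injection baseline span divided
    by its duration. The response rate is the extreme (up or down) of the
    smoothed post-injection rate — binned at ``bin_s`` and averaged over
    ``smooth_bins`` adjacent bins — and Δ% = 100·(response −
    baseline)/baseline. Smoothing matters: the raw extreme of skewed
    Poisson count bins is biased upward, whereas the smoothed estimator is
    centered on 0 for a rate-stable train. A silent baseline leaves Δ%
    undefined (flagged).
    """
    t0 = train.injection_time
    span = train.baseline_span
    times = train.spike_times
    n_base = int(np.count_nonzero((times >= t0 - span) & (times < t0)))
    base_rate = n_base / span
    window = (t0, t0 + post_s)
    if base_rate == 0:
        return EvokedResponse(train.neuron_id, "rate", float("nan"), 0.0,
                              DIR_NONE, window, defined=False,
                              note="silent baseline: % change undefined")
    k = max(1, int(smooth_bins))
    kernel = np.ones(k) / k

    base_edges = np.arange(t0 - span, t0 + bin_s / 2, bin_s)
    base_rates = np.histogram(times, bins=base_edges)[0] / bin_s
    if len(base_rates) >= k:
        base_rates = np.convolve(base_rates, kernel, mode="valid")
    sd_base = float(base_rates.std(ddof=1)) if len(base_rates) > 1 else 0.0

    n_bins = int(post_s // bin_s)
    edges = t0 + np.arange(n_bins + 1) * bin_s
    rates = np.histogram(times, bins=edges)[0] / bin_s
    if len(rates) >= k:
        rates = np.convolve(rates, kernel, mode="valid")
    up = float(rates.max() - base_rate)
    down = float(base_rate - rates.min())
    if up >= down:
        response, deviation, direction = float(rates.max()), up, DIR_ACTIVATED
    else:
        response, deviation, direction = float(rates.min()), down, DIR_INHIBITED
    if deviation <= sig_mult * sd_base:
        direction = DIR_NONE
    delta_pct = 100.0 * (response - base_rate) / base_rate
    return EvokedResponse(train.neuron_id, "rate", delta_pct, base_rate,
                          direction, window)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    adj_r2: float
    f: float
    df: tuple[int, int]
    p: float
    n: int
    log_x: bool = False


def covariate_regression(
    x: np.ndarray, y: np.ndarray, *, log_x: bool = False
) -> RegressionResult:
    """Ordinary least squares of ``y`` on ``x`` (optionally log10-transformed).

    Returns slope, intercept, R², adjusted R², F with (1, n−2) df and the
    two-sided p from the F distribution. Degenerate predictors (zero
    variance, n < 3) raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("regression needs n >= 3 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in regression inputs")
    if log_x:
        if np.any(x <= 0):
            raise ValueError("log_x requires strictly positive x")
        x = np.log10(x)
    n = len(x)
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise ValueError("zero variance in x")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    if r2 >= 1.0:
        f, p = float("inf"), 0.0
    else:
        f = r2 / (1.0 - r2) * (n - 2)
        p = float(sps.f.sf(f, 1, n - 2))
    return RegressionResult(slope, intercept, r2, adj_r2, f, (1, n - 2), p, n, log_x)


def regression_from_f(f: float, n: int) -> tuple[float, float]:
    """(R², adjusted R²) implied by a printed F(1, n−2) statistic.

    Useful to check published values: R² = F/(F + n − 2) and
    adj R² = 1 − (1 − R²)(n − 1)/(n − 2).
    """
    r2 = f / (f + (n - 2))
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return r2, adj


def per_mouse_means(
    table: pd.DataFrame, mouse_col: str = "mouse_id", value_col: str = "amplitude"
) -> pd.DataFrame:
    """Average per-neuron values within each mouse.

    Correlations against behavioral covariates are computed per mouse, not
    per neuron, so neuron-level tables are collapsed first; shuffling
    neurons within a mouse leaves the downstream regression unchanged.
    """
    return table.groupby(mouse_col, as_index=False)[value_col].mean()
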