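"""Synthetic cohorts with bout-structured drinking and known ground truth.

Behavioral model
----------------
Each bottle is an independent marked point process: bout onsets are Poisson
within each day at an archetype- and state-dependent rate, and bout volumes
are gamma distributed. Body weights evolve as a slow random walk around
25 g, recorded every other day. Four drinking archetypes are generated:

* ``tracker`` — follows the drug bottle across swaps with a fixed
  preference; drinking volume is concentration-independent, so intake rises
  with concentration.
* ``side_biased`` — drinks almost exclusively one physical side; consumes
  the drug passively on the days it sits there. Its habituation side split
  is kept moderate so the cohort passes the side-bias screen.
* ``plateau`` — a titrator: above a per-mouse knee concentration the
  drug-side bout rate scales as ``(knee/conc)**titration_exponent``, holding
  the daily dose constant.
* ``avoider_abrupt`` — tracker-like until the concentration first reaches
  its per-mouse aversion threshold; within one day the drug-side bout rate
  and bout size collapse and (with ``persistence``) stay collapsed, with
  drinking re-routed to the vehicle bottle.
* ``avoider_low`` — constitutively tiny drug-side drinking from the start.
* ``minipump_saline`` / ``minipump_nicotine`` — single-step protocol
  archetypes whose drug-bottle preference follows a per-day profile:
  pretreated-with-saline mice avoid the 100 µg/ml bottle abruptly, mice
  pretreated with nicotine reduce their preference only gradually.

The reference cohort (35 mice: 17 avoider archetypes, 18 non-avoiders) is
calibrated by analytic moment matching so that the condition-mean intake at
200 µg/ml is ≈2.6 mg/kg/day for avoiders and ≈16.9 mg/kg/day for
non-avoiders, and so that the habituation side preference of every mouse
stays inside the (20%, 80%) inclusion window.

Electrophysiology model
-----------------------
Puff-evoked currents are double-exponential transients (50 ms rise, 500 ms
decay) on a noisy holding current, with per-neuron peak amplitudes drawn
from a lognormal distribution calibrated to a group mean. Spike trains are
inhomogeneous Poisson with a smooth (alpha-shaped) post-injection rate
excursion of a programmed percent change.

All randomness flows from a single seeded :class:`numpy.random.Generator`,
so equal seeds give byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from bottlechoice.ephys import CurrentTrace, SpikeTrain
from bottlechoice.io import (
    MINUTES_PER_DAY,
    SIDE_LEFT,
    SIDE_RIGHT,
    DrinkLog,
    MouseRecord,
    Schedule,
    single_step_schedule,
    standard_schedule,
)

__all__ = [
    "DEFAULT_REFERENCE_SEED",
    "ArchetypeParams",
    "Cohort",
    "EphysGroupParams",
    "EPHYS_GROUPS",
    "simulate_mouse",
    "reference_cohort",
    "minipump_cohort",
    "simulate_current_trace",
    "simulate_ephys_group",
    "simulate_spike_train",
    "simulate_spike_group",
    "archetype_presets",
]

DEFAULT_REFERENCE_SEED = 20230530

ARCH_TRACKER = "tracker"
ARCH_SIDE_BIASED = "side_biased"
ARCH_PLATEAU = "plateau"
ARCH_AVOIDER_ABRUPT = "avoider_abrupt"
ARCH_AVOIDER_LOW = "avoider_low"
ARCH_MINIPUMP_SALINE = "minipump_saline"
ARCH_MINIPUMP_NICOTINE = "minipump_nicotine"

AVOIDER_ARCHETYPES = {ARCH_AVOIDER_ABRUPT, ARCH_AVOIDER_LOW}

# Single-step (minipump pretreatment) drug-phase preference profiles, one
# value per day at 100 µg/ml: saline-pretreated mice avoid abruptly, mice
# with a nicotine history reduce preference only gradually.
MINIPUMP_PROFILES = {
    ARCH_MINIPUMP_SALINE: (0.35, 0.22, 0.18, 0.17),  # mean 23.0%
    ARCH_MINIPUMP_NICOTINE: (0.50, 0.44, 0.38, 0.33),  # mean 41.25%
}


@dataclass
class ArchetypeParams:
    """Generative parameters for one simulated mouse."""

    archetype: str
    total_bout_rate: float = 180.0  # bouts/day, both bottles combined
    bout_volume_ml: float = 5.0 / 180.0  # mean bout volume (total ~5 ml/day)
    bout_shape: float = 8.0  # gamma shape of bout volumes
    drug_preference: float = 0.5  # fraction of bouts on the drug bottle
    preferred_side: str = SIDE_LEFT  # side_biased only
    side_strength: float = 0.95  # side_biased: fraction of bouts on that side
    hab_left_bias: float = 0.5  # habituation split toward the left bottle
    aversion_threshold: float | None = None  # µg/ml, avoider_abrupt
    persistence: bool = True  # keep the collapse for the rest of the task
    collapse_rate_factor: float = 0.015  # drug-side bout-rate factor after trigger
    collapse_bout_volume_ml: float = 0.008
    titration_knee: float | None = None  # µg/ml, plateau archetype
    titration_exponent: float = 1.0
    low_drug_bout_rate: float = 18.0  # avoider_low drug-side bouts/day
    low_drug_bout_volume_ml: float = 0.00487
    daily_pref_profile: tuple[float, ...] | None = None  # minipump archetypes
    weight_g: float = 25.0

    def is_avoider(self) -> bool:
        return self.archetype in AVOIDER_ARCHETYPES


def archetype_presets() -> dict[str, ArchetypeParams]:
    """Baseline parameter sets for each archetype (before per-mouse jitter)."""
    return {
        ARCH_TRACKER: ArchetypeParams(ARCH_TRACKER, drug_preference=0.62),
        ARCH_SIDE_BIASED: ArchetypeParams(
            ARCH_SIDE_BIASED, bout_volume_ml=4.5 / 180.0, hab_left_bias=0.68
        ),
        ARCH_PLATEAU: ArchetypeParams(
            ARCH_PLATEAU, drug_preference=0.55, titration_knee=90.0
        ),
        ARCH_AVOIDER_ABRUPT: ArchetypeParams(
            ARCH_AVOIDER_ABRUPT,
            drug_preference=0.55,
            bout_volume_ml=4.6 / 180.0,
            aversion_threshold=200.0,
        ),
        ARCH_AVOIDER_LOW: ArchetypeParams(ARCH_AVOIDER_LOW),
        ARCH_MINIPUMP_SALINE: ArchetypeParams(
            ARCH_MINIPUMP_SALINE, daily_pref_profile=MINIPUMP_PROFILES[ARCH_MINIPUMP_SALINE]
        ),
        ARCH_MINIPUMP_NICOTINE: ArchetypeParams(
            ARCH_MINIPUMP_NICOTINE,
            daily_pref_profile=MINIPUMP_PROFILES[ARCH_MINIPUMP_NICOTINE],
        ),
    }


def _day_bottle_params(
    params: ArchetypeParams,
    concentration: float,
    drug_side: str,
    day_in_condition: int,
    collapsed: bool,
) -> dict[str, tuple[float, float]]:
    """(bout rate, mean bout volume) per physical side for one day."""
    r_total = params.total_bout_rate
    v = params.bout_volume_ml
    if concentration == 0:
        left = params.hab_left_bias
        return {
            SIDE_LEFT: (r_total * left, v),
            SIDE_RIGHT: (r_total * (1.0 - left), v),
        }

    arch = params.archetype
    if arch == ARCH_SIDE_BIASED:
        on_pref = params.side_strength
        pref, other = (
            (SIDE_LEFT, SIDE_RIGHT)
            if params.preferred_side == SIDE_LEFT
            else (SIDE_RIGHT, SIDE_LEFT)
        )
        return {pref: (r_total * on_pref, v), other: (r_total * (1 - on_pref), v)}

    p = params.drug_preference
    if arch in MINIPUMP_PROFILES and params.daily_pref_profile is not None:
        profile = params.daily_pref_profile
        p = profile[min(day_in_condition, len(profile) - 1)]
        drug = (r_total * p, v)
        veh = (r_total * (1 - p), v)
    elif arch == ARCH_AVOIDER_LOW:
        drug = (params.low_drug_bout_rate, params.low_drug_bout_volume_ml)
        veh = (r_total - params.low_drug_bout_rate, v)
    elif arch == ARCH_AVOIDER_ABRUPT and collapsed:
        drug = (r_total * p * params.collapse_rate_factor, params.collapse_bout_volume_ml)
        # drinking re-routes to the vehicle bottle, keeping fluid intake up
        veh = (r_total * (1 - p) + 0.9 * r_total * p, v)
    elif arch == ARCH_PLATEAU and params.titration_knee is not None:
        m = min(1.0, (params.titration_knee / concentration) ** params.titration_exponent)
        drug = (r_total * p * m, v)
        veh = (r_total * (1 - p), v)
    else:  # tracker, or avoider_abrupt before its threshold
        drug = (r_total * p, v)
        veh = (r_total * (1 - p), v)

    if drug_side == SIDE_LEFT:
        return {SIDE_LEFT: drug, SIDE_RIGHT: veh}
    return {SIDE_LEFT: veh, SIDE_RIGHT: drug}


def simulate_mouse(
    params: ArchetypeParams,
    sched: Schedule,
    rng: np.random.Generator,
    mouse_id: str = "m01",
) -> tuple[DrinkLog, MouseRecord, dict]:
    """Simulate one mouse over a schedule.

    Returns the minute-resolution drink log (full coverage), the weight
    record, and a ground-truth dict (archetype, true label, threshold).
    """
    n_days = sched.n_days
    n_min = n_days * MINUTES_PER_DAY
    inc = {SIDE_LEFT: np.zeros(n_min), SIDE_RIGHT: np.zeros(n_min)}

    # weights: recorded every other day, slow random walk
    weights: dict[int, float] = {}
    w = params.weight_g
    for day in range(1, n_days + 1, 2):
        weights[day] = round(float(w), 1)
        w += rng.normal(0.0, 0.15)
        w = max(w, 15.0)

    day_in_cond: dict[int, int] = {}
    for _, _, days in sched.conditions():
        for i, d in enumerate(days):
            day_in_cond[d] = i

    triggered_from: int | None = None
    for sd in sched.days:
        conc = sd.concentration
        if (
            params.archetype == ARCH_AVOIDER_ABRUPT
            and params.aversion_threshold is not None
            and conc >= params.aversion_threshold
            and triggered_from is None
        ):
            triggered_from = sd.day + 1  # collapse within one day of the step
        collapsed = (
            triggered_from is not None
            and sd.day >= triggered_from
            and (params.persistence or conc >= (params.aversion_threshold or np.inf))
        )
        bottles = _day_bottle_params(
            params, conc, sd.drug_side, day_in_cond[sd.day], collapsed
        )
        offset = (sd.day - 1) * MINUTES_PER_DAY
        for side, (rate, vol_mean) in bottles.items():
            n_bouts = int(rng.poisson(max(rate, 0.0)))
            if n_bouts == 0:
                continue
            minutes = offset + rng.integers(0, MINUTES_PER_DAY, size=n_bouts)
            vols = rng.gamma(params.bout_shape, vol_mean / params.bout_shape, size=n_bouts)
            np.add.at(inc[side], minutes, vols)

    log = DrinkLog(
        mouse_id,
        np.arange(n_min, dtype=np.int64),
        np.cumsum(inc[SIDE_LEFT]),
        np.cumsum(inc[SIDE_RIGHT]),
    )
    rec = MouseRecord(mouse_id, weights, {"archetype": params.archetype})
    truth = {
        "mouse_id": mouse_id,
        "archetype": params.archetype,
        "true_label": "avoider" if params.is_avoider() else "non_avoider",
        "aversion_threshold": params.aversion_threshold,
    }
    return log, rec, truth


@dataclass
class Cohort:
    schedule: Schedule
    logs: list[DrinkLog]
    records: list[MouseRecord]
    truth: pd.DataFrame
    params: list[ArchetypeParams] = field(default_factory=list)


def _jittered(base: ArchetypeParams, rng: np.random.Generator, **overrides) -> ArchetypeParams:
    """Per-mouse variation around an archetype preset."""
    p = replace(base, **overrides)
    p = replace(
        p,
        drug_preference=float(np.clip(p.drug_preference + rng.normal(0, 0.015), 0.01, 0.99)),
        bout_volume_ml=float(p.bout_volume_ml * max(rng.normal(1.0, 0.02), 0.5)),
        hab_left_bias=float(np.clip(p.hab_left_bias + rng.normal(0, 0.03), 0.3, 0.78)),
        weight_g=float(max(rng.normal(25.0, 0.8), 18.0)),
    )
    if p.archetype == ARCH_SIDE_BIASED:
        p = replace(p, side_strength=float(np.clip(p.side_strength + rng.normal(0, 0.01), 0.9, 0.97)))
    if p.archetype == ARCH_PLATEAU and p.titration_knee is not None:
        p = replace(p, titration_knee=float(np.clip(rng.normal(p.titration_knee, 8.0), 60.0, 140.0)))
    return p


def _reference_param_list(rng: np.random.Generator) -> list[ArchetypeParams]:
    presets = archetype_presets()
    plan: list[tuple[ArchetypeParams, dict]] = []
    # 18 non-avoiders: 6 trackers, 5 side-biased, 7 plateau titrators
    plan += [(presets[ARCH_TRACKER], {}) for _ in range(6)]
    plan += [
        (presets[ARCH_SIDE_BIASED],
         {"preferred_side": SIDE_LEFT if i % 2 == 0 else SIDE_RIGHT})
        for i in range(5)
    ]
    plan += [(presets[ARCH_PLATEAU], {}) for _ in range(7)]
    # 17 avoiders: abrupt with per-mouse thresholds (mostly at the 100->200
    # step, some as low as 10 µg/ml) plus constitutively low drinkers
    thresholds = [200.0] * 8 + [100.0] * 2 + [50.0] * 2 + [10.0]
    plan += [(presets[ARCH_AVOIDER_ABRUPT], {"aversion_threshold": t}) for t in thresholds]
    plan += [(presets[ARCH_AVOIDER_LOW], {}) for _ in range(4)]
    out = []
    for base, overrides in plan:
        hab_override = {}
        if base.archetype == ARCH_SIDE_BIASED:
            # habituation bias leans toward the preferred side but stays
            # inside the (20, 80)% inclusion window
            side = overrides.get("preferred_side", SIDE_LEFT)
            hab_override["hab_left_bias"] = 0.68 if side == SIDE_LEFT else 0.32
        out.append(_jittered(base, rng, **{**overrides, **hab_override}))
    return out


def reference_cohort(seed: int = DEFAULT_REFERENCE_SEED) -> Cohort:
    """The fixed-composition 35-mouse cohort on the ascending schedule.

    17 avoider archetypes (13 abrupt with thresholds 10–200 µg/ml, 4 low
    intake) and 18 non-avoiders (6 trackers, 5 side-biased, 7 plateau
    titrators), calibrated so condition-mean intake at 200 µg/ml is
    ≈2.6 (avoiders) and ≈16.9 mg/kg/day (non-avoiders). Deterministic for a
    given seed; ground-truth labels are attached.
    """
    rng = np.random.default_rng(seed)
    sched = standard_schedule()
    param_list = _reference_param_list(rng)
    logs, records, truths = [], [], []
    for i, params in enumerate(param_list):
        mouse_id = f"m{i + 1:02d}"
        log, rec, truth = simulate_mouse(params, sched, rng, mouse_id)
        logs.append(log)
        records.append(rec)
        truths.append(truth)
    return Cohort(sched, logs, records, pd.DataFrame(truths), param_list)


def minipump_cohort(
    treatment: str = "saline",
    n: int | None = None,
    seed: int = 0,
    concentration: float = 100.0,
) -> Cohort:
    """Single-step protocol cohort after chronic minipump pretreatment.

    ``treatment`` is ``"saline"`` (n=23 default; abrupt avoidance of the
    100 µg/ml bottle, condition-mean percent consumption ≈23%) or
    ``"nicotine"`` (n=25 default; gradual decrease, ≈41%).
    """
    arch = ARCH_MINIPUMP_SALINE if treatment == "saline" else ARCH_MINIPUMP_NICOTINE
    if treatment not in ("saline", "nicotine"):
        raise ValueError("treatment must be 'saline' or 'nicotine'")
    if n is None:
        n = 23 if treatment == "saline" else 25
    rng = np.random.default_rng(seed)
    sched = single_step_schedule(concentration)
    base = archetype_presets()[arch]
    logs, records, truths, plist = [], [], [], []
    for i in range(n):
        profile = tuple(
            float(np.clip(v + rng.normal(0, 0.03), 0.02, 0.95))
            for v in base.daily_pref_profile
        )
        params = _jittered(base, rng, daily_pref_profile=profile)
        mouse_id = f"{treatment[:3]}{i + 1:02d}"
        log, rec, truth = simulate_mouse(params, sched, rng, mouse_id)
        truth["treatment"] = treatment
        logs.append(log)
        records.append(rec)
        truths.append(truth)
        plist.append(params)
    return Cohort(sched, logs, records, pd.DataFrame(truths), plist)


# ---------------------------------------------------------------------------
# Electrophysiology
# ---------------------------------------------------------------------------


@dataclass
class EphysGroupParams:
    """Calibration of one recorded group of neurons."""

    label: str
    mean_pa: float  # target mean peak amplitude (positive magnitude)
    sd_pa: float = 80.0  # lognormal spread across neurons
    n_neurons: int = 30
    noise_sd_pa: float = 5.0
    rise_s: float = 0.05
    decay_s: float = 0.5
    sample_rate: float = 2000.0
    duration_s: float = 5.0
    puff_time_s: float = 1.0
    holding_pa: float = -20.0


# Printed group means (pA magnitudes) and group sizes from the recorded
# cohorts; the spread is a generator design choice (see docs/methods.md).
EPHYS_GROUPS = {
    "avoider": EphysGroupParams("avoider", 254.64, n_neurons=57),
    "non_avoider": EphysGroupParams("non_avoider", 183.20, n_neurons=52),
    "minipump_saline": EphysGroupParams("minipump_saline", 401.0, n_neurons=24),
    "minipump_nicotine": EphysGroupParams("minipump_nicotine", 202.0, n_neurons=34),
    "naive_wt": EphysGroupParams("naive_wt", 370.0, n_neurons=32),
    "chrnb4_ko": EphysGroupParams("chrnb4_ko", 83.0, sd_pa=30.0, n_neurons=27),
}


def _double_exponential(t: np.ndarray, rise_s: float, decay_s: float) -> np.ndarray:
    """Unit-peak double-exponential transient, zero for t < 0."""
    s = np.where(t >= 0, np.exp(-t / decay_s) - np.exp(-t / rise_s), 0.0)
    t_peak = rise_s * decay_s / (decay_s - rise_s) * np.log(decay_s / rise_s)
    peak = np.exp(-t_peak / decay_s) - np.exp(-t_peak / rise_s)
    return s / peak


def simulate_current_trace(
    amplitude_pa: float,
    rng: np.random.Generator,
    *,
    neuron_id: str = "n01",
    params: EphysGroupParams | None = None,
) -> CurrentTrace:
    """One voltage-clamp trace with a programmed inward peak amplitude."""
    p = params or EphysGroupParams("single", amplitude_pa)
    n = int(p.duration_s * p.sample_rate)
    t = np.arange(n) / p.sample_rate
    signal = p.holding_pa - amplitude_pa * _double_exponential(
        t - p.puff_time_s, p.rise_s, p.decay_s
    )
    signal = signal + rng.normal(0.0, p.noise_sd_pa, size=n)
    return CurrentTrace(neuron_id, p.sample_rate, signal, p.puff_time_s)


def _lognormal_amplitudes(
    mean: float, sd: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=n)


def simulate_ephys_group(
    params: EphysGroupParams, seed: int | np.random.Generator = 0
) -> tuple[list[CurrentTrace], np.ndarray]:
    """Traces for one neuron group plus the ground-truth peak amplitudes."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    amps = _lognormal_amplitudes(params.mean_pa, params.sd_pa, params.n_neurons, rng)
    traces = [
        simulate_current_trace(
            float(a), rng, neuron_id=f"{params.label}_{i + 1:03d}", params=params
        )
        for i, a in enumerate(amps)
    ]
    return traces, amps


def simulate_spike_train(
    rng: np.random.Generator,
    *,
    base_hz: float = 5.0,
    delta_pct: float = 0.0,
    neuron_id: str = "u01",
    baseline_s: float = 300.0,
    post_s: float = 300.0,
    peak_s: float = 40.0,
) -> SpikeTrain:
    """Inhomogeneous Poisson train with an alpha-shaped post-injection excursion.

    The rate is ``base_hz`` before the injection and
    ``base_hz * (1 + delta_pct/100 * g(t))`` after it, where g rises to 1 at
    ``peak_s`` and relaxes back (floored at rate 0 for strong inhibition).
    Generated by thinning, so the realized train is exactly Poisson.
    """
    total = baseline_s + post_s
    r_max = base_hz * max(1.0, 1.0 + max(delta_pct, 0.0) / 100.0) + 1e-9
    n_cand = rng.poisson(r_max * total)
    t = np.sort(rng.uniform(0.0, total, size=n_cand))
    rel = (t - baseline_s) / peak_s
    g = np.where(t >= baseline_s, rel * np.exp(1.0 - rel), 0.0)
    rate = np.clip(base_hz * (1.0 + delta_pct / 100.0 * g), 0.0, None)
    keep = rng.uniform(0.0, r_max, size=n_cand) < rate
    return SpikeTrain(neuron_id, t[keep], injection_time=baseline_s,
                      baseline_span=baseline_s)


def simulate_spike_group(
    n_neurons: int,
    seed: int | np.random.Generator = 0,
    *,
    delta_mean_pct: float = 80.0,
    delta_sd_pct: float = 25.0,
    frac_inhibited: float = 0.2,
    base_hz_mean: float = 8.0,
    base_hz_sd: float = 3.0,
    label: str = "grp",
) -> tuple[list[SpikeTrain], pd.DataFrame]:
    """A group of spike trains with programmed rate changes and ground truth."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    trains, rows = [], []
    for i in range(n_neurons):
        base = float(max(rng.normal(base_hz_mean, base_hz_sd), 1.0))
        inhibited = bool(rng.uniform() < frac_inhibited)
        delta = float(rng.normal(delta_mean_pct, delta_sd_pct))
        delta = -abs(delta) * 0.6 if inhibited else abs(delta)
        delta = max(delta, -95.0)
        train = simulate_spike_train(
            rng, base_hz=base, delta_pct=delta, neuron_id=f"{label}_{i + 1:03d}"
        )
        trains.append(train)
        rows.append(dict(neuron_id=train.neuron_id, base_hz=base, true_delta_pct=delta))
    return trains, pd.DataFrame(rows)
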