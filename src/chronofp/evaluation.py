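"""Alarm scoring and seizure-time surrogate significance testing.

A seizure is correctly predicted when its onset occurs after an alarm plus
the prediction horizon (SPH) and within the following occurrence period
(SOP): alarm at time t covers onsets in (t+SPH, t+SPH+SOP]. Seizure
sensitivity is the fraction of seizures so covered; the false-positive rate
per hour divides the false alarms by the interictal duration minus the
refractory time they consume.

Statistical validation uses seizure-time surrogates: every onset is
relocated, uniformly and independently, into the interictal period (away
from real preictal/exclusion zones and from other surrogate onsets), the
fixed alarm series is re-scored, and the real sensitivity is compared to
the surrogate sample with the exchangeability rank p-value
p = (1 + #{surrogate SS >= real SS}) / (N + 1), one-sided at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ALPHA = 0.05
DEFAULT_N_SURROGATES = 30


@dataclass
class EvaluationResult:
    ss: float
    fpr_h: float
    per_seizure: np.ndarray  # bool, predicted flags
    n_false_alarms: int
    interictal_hours: float


@dataclass
class SurrogateResult:
    real_ss: float
    surrogate_ss: np.ndarray
    p_value: float
    validated: bool
    alpha: float = ALPHA


def _predicts(alarm_t: float, onset: float, sop_min: float, sph_min: float) -> bool:
    lo = alarm_t + sph_min * 60.0
    return lo < onset <= lo + sop_min * 60.0


def predicted_flags(alarm_times, onsets, sop_min: float,
                    sph_min: float) -> tuple[np.ndarray, np.ndarray]:
    """(per-seizure predicted flags, per-alarm true-alarm flags)."""
    alarm_times = np.asarray(alarm_times, float)
    onsets = np.asarray(onsets, float)
    seized = np.zeros(onsets.size, bool)
    true_alarm = np.zeros(alarm_times.size, bool)
    for j, t in enumerate(alarm_times):
        for i, o in enumerate(onsets):
            if _predicts(t, o, sop_min, sph_min):
                seized[i] = True
                true_alarm[j] = True
    return seized, true_alarm


def score_alarms(alarms, onsets, sop_min: float, sph_min: float,
                 interictal_hours: float) -> EvaluationResult:
    """Seizure sensitivity and refractory-corrected false-alarm rate."""
    alarm_times = getattr(alarms, "alarm_times", alarms)
    onsets = np.asarray(onsets, float)
    if onsets.size == 0:
        raise ValueError("no seizures to score")
    seized, true_alarm = predicted_flags(alarm_times, onsets, sop_min, sph_min)
    n_false = int((~true_alarm).sum())
    refractory_h = (sop_min + sph_min) / 60.0
    denom = interictal_hours - n_false * refractory_h
    if denom <= 0:
        raise ValueError(
            "degenerate record: refractory time of false alarms exceeds the "
            "interictal duration"
        )
    return EvaluationResult(
        ss=float(seized.mean()),
        fpr_h=n_false / denom,
        per_seizure=seized,
        n_false_alarms=n_false,
        interictal_hours=float(interictal_hours),
    )


def interictal_hours(t_start: float, t_end: float, onsets,
                     preictal_span_min: float,
                     exclusion_min: float = 10.0) -> float:
    """Interictal duration of [t_start, t_end): total span minus, for each
    onset, its preictal footprint (SPH included) and post-onset exclusion."""
    onsets = np.asarray(onsets, float)
    total = t_end - t_start
    for o in onsets:
        lo = max(o - preictal_span_min * 60.0, t_start)
        hi = min(o + exclusion_min * 60.0, t_end)
        total -= max(hi - lo, 0.0)
    if total <= 0:
        raise ValueError("no interictal time in the scoring interval")
    return total / 3600.0


def _draw_surrogate_onsets(rng: np.random.Generator, t_start: float,
                           t_end: float, real_onsets: np.ndarray,
                           sop_min: float, sph_min: float,
                           preictal_span_min: float, exclusion_min: float,
                           max_tries: int = 10_000) -> np.ndarray:
    """Relocate each onset uniformly into the interictal span.

    Candidates may not fall inside any real onset's preictal/exclusion
    footprint nor within SOP+SPH of an already placed surrogate.
    """
    forbidden = [(o - preictal_span_min * 60.0, o + exclusion_min * 60.0)
                 for o in real_onsets]
    min_sep = (sop_min + sph_min) * 60.0
    placed: list[float] = []
    for i in range(real_onsets.size):
        for _ in range(max_tries):
            cand = rng.uniform(t_start, t_end)
            if any(lo < cand <= hi for lo, hi in forbidden):
                continue
            if any(abs(cand - p) < min_sep for p in placed):
                continue
            placed.append(cand)
            break
        else:
            raise RuntimeError(
                f"cannot place a surrogate onset for seizure {i}: "
                "interictal span too crowded"
            )
    return np.array(sorted(placed))


def surrogate_test(alarms, onsets, t_start: float, t_end: float,
                   sop_min: float, sph_min: float,
                   preictal_span_min: float | None = None,
                   exclusion_min: float = 10.0,
                   n_surrogates: int = DEFAULT_N_SURROGATES,
                   seed: int = 0) -> SurrogateResult:
    """One-sided surrogate test of seizure sensitivity against chance.

    The alarm series is held fixed; each replicate relocates every onset
    into the interictal period and re-scores sensitivity. Validated means
    the real sensitivity beats the surrogate sample with rank p < alpha.
    """
    alarm_times = getattr(alarms, "alarm_times", alarms)
    onsets = np.asarray(onsets, float)
    if preictal_span_min is None:
        preictal_span_min = sop_min + sph_min
    rng = np.random.default_rng(seed)
    real_flags, _ = predicted_flags(alarm_times, onsets, sop_min, sph_min)
    real_ss = float(real_flags.mean())
    surr = np.empty(n_surrogates)
    for r in range(n_surrogates):
        s_onsets = _draw_surrogate_onsets(
            rng, t_start, t_end, onsets, sop_min, sph_min,
            preictal_span_min, exclusion_min)
        flags, _ = predicted_flags(alarm_times, s_onsets, sop_min, sph_min)
        surr[r] = flags.mean()
    p = (1.0 + np.sum(surr >= real_ss)) / (n_surrogates + 1.0)
    return SurrogateResult(
        real_ss=real_ss,
        surrogate_ss=surr,
        p_value=float(p),
        validated=bool(p < ALPHA),
    )
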