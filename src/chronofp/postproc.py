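"""Firing-power regularization and alarm generation.

The firing power fp[n] is the fraction of preictal-classified samples in a
trailing window of tau samples, tau being the event duration in windows —
a moving average that smooths the raw classifier output into [0, 1].

Three alarm strategies convert curves into alarms, all with a refractory
period of SOP + SPH between alarms:

* control — an alarm at every upward 0.5-crossing of the single curve;
* chronological — the three event curves must cross 0.5 in chronological
  order (event 1, then 2, then 3) within a span limit; the alarm fires at
  the event-3 occurrence;
* cumulative — the three curves are summed (range [0, 3]) and the sum must
  exceed 0.5, 1.0 and 1.5 sequentially within the span limit; the alarm
  fires at the 1.5-crossing.

A "crossing" is strictly above the threshold at n with a value at or below
it at n-1 (the sample before the record is an implicit 0). Simultaneous
multi-threshold crossings in a single step count as sequential: a
discrete-time curve can legitimately jump.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_THRESHOLD = 0.5
CUMULATIVE_THRESHOLDS = (0.5, 1.0, 1.5)
WINDOWS_PER_MINUTE = 12  # 5-s non-overlapping windows


@dataclass
class FiringPowerCurve:
    fp: np.ndarray
    times: np.ndarray
    tau: int
    range_max: float = 1.0

    def __post_init__(self) -> None:
        if self.fp.size != self.times.size:
            raise ValueError("curve and time axis lengths differ")
        if self.tau < 1:
            raise ValueError("tau must be >= 1")
        if self.fp.size and (self.fp.min() < -1e-12
                             or self.fp.max() > self.range_max + 1e-12):
            raise ValueError("firing power out of range")


@dataclass
class AlarmSeries:
    alarm_times: np.ndarray  # seconds
    refractory_min: float
    strategy: str

    def __post_init__(self) -> None:
        self.alarm_times = np.asarray(self.alarm_times, float)
        gaps = np.diff(self.alarm_times)
        if gaps.size and gaps.min() < self.refractory_min * 60.0 - 1e-9:
            raise ValueError("alarms closer than the refractory period")


def firing_power(O: np.ndarray, tau: int, times: np.ndarray | None = None,
                 warmup: str = "mean") -> FiringPowerCurve:
    """Trailing-window mean of a binary output stream.

    ``warmup='mean'`` averages over the available history for the first
    tau-1 samples; ``warmup='zero'`` emits 0 there instead.
    """
    O = np.asarray(O)
    if O.size == 0:
        raise ValueError("empty output stream")
    if not set(np.unique(O)) <= {0, 1}:
        raise ValueError("output stream must be binary")
    if tau < 1:
        raise ValueError("tau must be >= 1")
    c = np.concatenate([[0], np.cumsum(O)])
    n = np.arange(1, O.size + 1)
    trailing = c[n] - c[np.maximum(n - tau, 0)]
    if warmup == "mean":
        fp = trailing / np.minimum(n, tau)
    elif warmup == "zero":
        fp = np.where(n >= tau, trailing / tau, 0.0)
    else:
        raise ValueError(f"unknown warmup mode {warmup!r}")
    if times is None:
        times = np.arange(O.size, dtype=float)
    return FiringPowerCurve(fp=np.asarray(fp, float),
                            times=np.asarray(times, float), tau=tau)


def _upward_crossings(fp: np.ndarray, threshold: float) -> np.ndarray:
    prev = np.concatenate([[0.0], fp[:-1]])
    return (fp > threshold) & (prev <= threshold)


def alarms_control(curve: FiringPowerCurve,
                   threshold: float = DEFAULT_THRESHOLD,
                   refractory_min: float = 15.0) -> AlarmSeries:
    """Alarm at each upward threshold crossing outside refractory windows."""
    cross = _upward_crossings(curve.fp, threshold)
    alarms: list[float] = []
    refr_s = refractory_min * 60.0
    last = -np.inf
    for i in np.flatnonzero(cross):
        t = curve.times[i]
        if t - last >= refr_s:
            alarms.append(t)
            last = t
    return AlarmSeries(np.array(alarms), refractory_min, "control")


def alarms_chronological(curves: list[FiringPowerCurve],
                         threshold: float = DEFAULT_THRESHOLD,
                         span_limit_min: float = 30.0,
                         refractory_min: float = 15.0) -> AlarmSeries:
    """Alarm when events 1, 2, 3 occur in chronological order within the span.

    An event "occurs" at an upward threshold crossing of its curve. The most
    recent qualifying event-1/event-2 occurrences are retained; occurrences
    inside a refractory window are ignored; same-sample occurrences count as
    ordered (event 1 before 2 before 3 within one sample). The pending
    sequence is cleared on alarm.
    """
    if len(curves) != 3:
        raise ValueError("three event curves required")
    n = curves[0].fp.size
    if any(c.fp.size != n for c in curves):
        raise ValueError("event curves have unequal lengths")
    times = curves[0].times
    occ = [_upward_crossings(c.fp, threshold) for c in curves]

    span_s = span_limit_min * 60.0
    refr_s = refractory_min * 60.0
    alarms: list[float] = []
    last_alarm = -np.inf
    t1 = t2 = pair_t1 = None
    for i in range(n):
        t = times[i]
        if t - last_alarm < refr_s:
            continue
        if occ[0][i]:
            t1 = t
        if occ[1][i] and t1 is not None:
            t2, pair_t1 = t, t1
        if occ[2][i] and t2 is not None and t - pair_t1 <= span_s:
            alarms.append(t)
            last_alarm = t
            t1 = t2 = pair_t1 = None
    return AlarmSeries(np.array(alarms), refractory_min, "chronological")


def sum_curves(curves: list[FiringPowerCurve]) -> FiringPowerCurve:
    """Pointwise sum of the three event curves (range [0, 3])."""
    n = curves[0].fp.size
    if any(c.fp.size != n for c in curves):
        raise ValueError("event curves have unequal lengths")
    return FiringPowerCurve(
        fp=np.sum([c.fp for c in curves], axis=0),
        times=curves[0].times,
        tau=max(c.tau for c in curves),
        range_max=float(len(curves)),
    )


def alarms_cumulative(curves: list[FiringPowerCurve],
                      thresholds: tuple[float, float, float] = CUMULATIVE_THRESHOLDS,
                      span_limit_min: float = 30.0,
                      refractory_min: float = 15.0,
                      reset_on_drop: bool = False) -> AlarmSeries:
    """Alarm when the summed curve exceeds the three thresholds in order.

    Arming requires an upward crossing of the lowest threshold; the higher
    thresholds must then be exceeded within the span limit, and the alarm
    fires at the highest-threshold crossing. The sequence state resets on
    alarm and on span expiry (and, optionally, when the sum drops back
    below the lowest threshold).
    """
    if len(curves) != 3:
        raise ValueError("three event curves required")
    summed = sum_curves(curves)
    S, times = summed.fp, summed.times
    thr0, thr1, thr2 = thresholds
    span_s = span_limit_min * 60.0
    refr_s = refractory_min * 60.0

    alarms: list[float] = []
    last_alarm = -np.inf
    stage = 0
    t0 = 0.0
    prev = 0.0
    for i in range(S.size):
        t, v = times[i], S[i]
        if t - last_alarm < refr_s:
            prev = v
            stage = 0
            continue
        if stage > 0 and t - t0 > span_s:
            stage = 0
        if stage > 0 and reset_on_drop and v <= thr0:
            stage = 0
        if stage == 0 and v > thr0 and prev <= thr0:
            stage = 1
            t0 = t
        if stage == 1 and v > thr1:
            stage = 2
        if stage == 2 and v > thr2:
            alarms.append(t)
            last_alarm = t
            stage = 0
        prev = v
    return AlarmSeries(np.array(alarms), refractory_min, "cumulative")


def event_tau(scheme, event_index: int) -> int:
    """Moving-window length in samples: the event's duration in 5-s windows."""
    return int(round(scheme.event_duration_min(event_index) * WINDOWS_PER_MINUTE))
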