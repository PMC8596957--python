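"""Summaries of acclimation voltage cycles and chronoamperometry traces.

Acclimation in a microbial fuel cell proceeds in feed cycles: voltage rises
after each substrate spike and decays as the batch is exhausted; when it falls
below a refeed threshold the medium is partially replaced and a new cycle
begins.  Chronoamperometry at a fixed applied potential instead yields a
single current transient whose peak height/time characterise the biofilm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["CurrentPeak", "VoltageCycleSummary", "find_current_peak", "segment_cycles", "peak_ratio"]


@dataclass(frozen=True)
class CurrentPeak:
    peak_current: float  # A
    peak_time: float  # h


@dataclass(frozen=True)
class VoltageCycleSummary:
    cycle_index: int
    peak_voltage: float  # V
    peak_time: float  # h
    start_time: float  # h
    end_time: float  # h


def _as_trace(time_h: Sequence[float], values: Sequence[float]):
    t = np.asarray(time_h, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.size == 0 or v.shape != t.shape:
        raise ValueError("trace needs aligned non-empty time and value arrays")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return t, v


def find_current_peak(time_h: Sequence[float], current_a: Sequence[float]) -> CurrentPeak:
    """Global maximum of a current trace; ties broken by earliest time."""
    t, i = _as_trace(time_h, current_a)
    idx = int(np.argmax(i))  # argmax returns the first maximum
    return CurrentPeak(peak_current=float(i[idx]), peak_time=float(t[idx]))


def segment_cycles(
    time_h: Sequence[float],
    voltage_v: Sequence[float],
    refeed_threshold: float = 0.001,
) -> list[VoltageCycleSummary]:
    """Split a voltage trace into feed cycles at the refeed threshold.

    A cycle opens at the first sample above the threshold, and a new one at
    each upward crossing after the voltage has spent at least one sample below
    it (the one-sample dwell suppresses noise-induced splits).  A trace that
    never exceeds the threshold yields no cycles.
    """
    if refeed_threshold <= 0:
        raise ValueError("refeed_threshold must be positive")
    t, v = _as_trace(time_h, voltage_v)

    starts: list[int] = []
    below = True  # armed: the next sample above threshold opens a cycle
    for k in range(v.size):
        if v[k] > refeed_threshold and below:
            starts.append(k)
            below = False
        elif v[k] <= refeed_threshold:
            below = True
    if not starts:
        return []

    bounds = starts + [v.size]
    summaries = []
    for idx, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
        seg_t, seg_v = t[a:b], v[a:b]
        j = int(np.argmax(seg_v))
        summaries.append(
            VoltageCycleSummary(
                cycle_index=idx,
                peak_voltage=float(seg_v[j]),
                peak_time=float(seg_t[j]),
                start_time=float(seg_t[0]),
                end_time=float(seg_t[-1]),
            )
        )
    return summaries


def peak_ratio(
    summaries: Sequence[VoltageCycleSummary], cycle_a: int, cycle_b: int
) -> float:
    """Peak-voltage ratio of cycle_b over cycle_a (e.g. last over first)."""
    by_index = {s.cycle_index: s for s in summaries}
    try:
        a, b = by_index[cycle_a], by_index[cycle_b]
    except KeyError as exc:
        raise KeyError(f"cycle {exc.args[0]} not present") from None
    if a.peak_voltage == 0:
        raise ZeroDivisionError("reference cycle has zero peak voltage")
    return b.peak_voltage / a.peak_voltage
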