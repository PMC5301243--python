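"""Mitochondrial oxygen-consumption rates from oximetry traces.

Isolated-mitochondria respiration is recorded as percent O2 saturation
versus time in a closed chamber.  Succinate addition starts substrate-only
(state IV) respiration; subsequent ADP starts phosphorylating (state III)
respiration.  Each slope is taken over the 60-s window beginning 60 s after
the respective addition and converted to nmol O2/min/mg protein via

    rate = 199 (nmol) * Y / 20.9 * 1000 / M (ug)

with Y the consumption slope in %/min and M the protein load in ug; 199 nmol
is the chamber O2 content at air saturation (20.9%).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

CHAMBER_O2_NMOL = 199.0
AIR_PERCENT = 20.9
UG_PER_MG = 1000.0

EVENT_LABELS = ("mitochondria", "succinate", "adp")


@dataclass
class OxygenTrace:
    """Percent-O2 time series with substrate-addition events."""

    time_s: np.ndarray
    o2_percent: np.ndarray
    events: Sequence[tuple[float, str]]
    protein_ug: float

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.o2_percent = np.asarray(self.o2_percent, dtype=float)
        if self.time_s.size != self.o2_percent.size:
            raise ValueError("time and O2 arrays differ in length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time axis must be strictly increasing")
        if np.any(self.o2_percent < 0) or np.any(self.o2_percent > 110):
            raise ValueError("O2 percent outside [0, 110]")
        if self.protein_ug <= 0:
            raise ValueError("protein_ug must be > 0")
        times = [t for t, _ in self.events]
        if sorted(times) != list(times):
            raise ValueError("events must be time-ordered")

    def event_time(self, label: str) -> float:
        for t, lbl in self.events:
            if lbl == label:
                return t
        raise ValueError(f"event {label!r} not present in trace")


@dataclass
class OxygenRates:
    slope_stateIV: float   # %/min
    slope_stateIII: float  # %/min
    rate_stateIV: float    # nmol O2/min/mg protein
    rate_stateIII: float

    @property
    def respiratory_control_ratio(self) -> float:
        """State III / state IV; informational only."""
        return self.rate_stateIII / self.rate_stateIV if self.rate_stateIV else np.nan


def fit_slope(trace: OxygenTrace, window_start_s: float,
              window_len_s: float = 60.0) -> float:
    """Least-squares O2 slope over [start, start+len) as a positive
    consumption magnitude (-dO2/dt) in %/min."""
    t, y = trace.time_s, trace.o2_percent
    if window_start_s < t[0] or window_start_s + window_len_s > t[-1] + 1e-9:
        raise ValueError(
            f"window [{window_start_s}, {window_start_s + window_len_s}] s "
            f"outside trace range [{t[0]}, {t[-1]}] s"
        )
    m = (t >= window_start_s) & (t < window_start_s + window_len_s)
    if m.sum() < 3:
        raise ValueError("fewer than 3 samples in the slope window")
    slope_per_s = np.polyfit(t[m], y[m], 1)[0]
    return float(-slope_per_s * 60.0)


def o2_consumption_rate(Y: float, M: float) -> float:
    """The printed conversion: 199 * Y / 20.9 * 1000 / M."""
    if M <= 0:
        raise ValueError("protein mass M must be > 0")
    if Y < 0:
        raise ValueError("slope Y must be >= 0")
    return CHAMBER_O2_NMOL * Y / AIR_PERCENT * UG_PER_MG / M


def state_rates(trace: OxygenTrace, delay_s: float = 60.0,
                window_len_s: float = 60.0) -> OxygenRates:
    """State IV (post-succinate) and state III (post-ADP) rates.

    Each slope is measured 1 min after the addition, for 1 min, then
    converted with the trace's protein load.
    """
    t_succ = trace.event_time("succinate")
    t_adp = trace.event_time("adp")
    if t_adp <= t_succ:
        raise ValueError("ADP event must follow the succinate event")
    y4 = fit_slope(trace, t_succ + delay_s, window_len_s)
    y3 = fit_slope(trace, t_adp + delay_s, window_len_s)
    return OxygenRates(
        slope_stateIV=y4,
        slope_stateIII=y3,
        rate_stateIV=o2_consumption_rate(max(y4, 0.0), trace.protein_ug),
        rate_stateIII=o2_consumption_rate(max(y3, 0.0), trace.protein_ug),
    )
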