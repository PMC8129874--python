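"""Session-level MET labels from breath-by-breath VO2.

Raw VO2 is smoothed with a 30-second time-based running average, the first
two minutes (non-steady-state onset) are discarded, and the remaining
plateau mean is divided by the 3.5 mL·min⁻¹·kg⁻¹ resting convention to
yield one MET value per session. Traces too short to reach steady state are
excluded and counted rather than silently labeled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import REST_VO2, SessionVo2, Vo2Trace

logger = logging.getLogger(__name__)

DEFAULT_SMOOTH_HALF_WIDTH_S = 15.0  # 30-s full-width running average
DEFAULT_ONSET_S = 120.0
DEFAULT_MIN_BREATHS = 10


class SteadyStateError(ValueError):
    """Raised when a trace ends before steady state can be assessed."""


@dataclass(frozen=True)
class MetLabel:
    participant_id: str
    activity_name: str
    met_value: float
    steady_state_window: tuple[float, float]
    n_breaths_used: int

    def __post_init__(self):
        if self.met_value <= 0:
            raise ValueError("met_value must be positive")
        t0, t1 = self.steady_state_window
        if t0 < 0 or t1 <= t0:
            raise ValueError("invalid steady-state window")


def smooth_vo2(trace: Vo2Trace, half_width_s: float = DEFAULT_SMOOTH_HALF_WIDTH_S) -> Vo2Trace:
    """Time-based running average: each breath's value becomes the mean of raw
    values at breaths within ±``half_width_s`` seconds. Breath times are
    unchanged. Time-based (not breath-count) windows are used because breath
    intervals are irregular."""
    if trace.breath_times.size == 0:
        raise ValueError("empty trace")
    if half_width_s <= 0:
        raise ValueError("half_width_s must be > 0")
    t = trace.breath_times
    v = trace.vo2_values
    lo = np.searchsorted(t, t - half_width_s, side="left")
    hi = np.searchsorted(t, t + half_width_s, side="right")
    csum = np.concatenate([[0.0], np.cumsum(v)])
    smoothed = (csum[hi] - csum[lo]) / (hi - lo)
    return Vo2Trace(breath_times=t.copy(), vo2_values=smoothed)


def steady_state_met(
    trace: Vo2Trace,
    onset_s: float = DEFAULT_ONSET_S,
    *,
    participant_id: str = "",
    activity_name: str = "",
    half_width_s: float = DEFAULT_SMOOTH_HALF_WIDTH_S,
    min_breaths: int = DEFAULT_MIN_BREATHS,
    max_abs_slope: float | None = None,
) -> MetLabel:
    """Label one session: smoothed-VO2 mean over [onset_s, end] divided by 3.5.

    Raises :class:`SteadyStateError` when the trace ends at or before
    ``onset_s`` (no plateau reachable) or fewer than ``min_breaths`` breaths
    fall in the retained window. When ``max_abs_slope`` (mL·min⁻¹·kg⁻¹ per
    second) is set, a plateau whose fitted slope exceeds it is also rejected —
    a deterministic stand-in for manual plateau screening.
    """
    if trace.breath_times.size == 0 or trace.breath_times[-1] <= onset_s:
        raise SteadyStateError(
            f"trace ends at {trace.breath_times[-1] if trace.breath_times.size else 0:.0f} s "
            f"<= onset {onset_s:.0f} s; steady state not reached"
        )
    smoothed = smooth_vo2(trace, half_width_s)
    keep = smoothed.breath_times >= onset_s
    n_used = int(keep.sum())
    if n_used < min_breaths:
        raise SteadyStateError(
            f"only {n_used} breaths after onset (< {min_breaths})"
        )
    t_used = smoothed.breath_times[keep]
    v_used = smoothed.vo2_values[keep]
    if max_abs_slope is not None:
        slope = float(np.polyfit(t_used, v_used, 1)[0])
        if abs(slope) > max_abs_slope:
            raise SteadyStateError(
                f"plateau slope {slope:.4g} exceeds {max_abs_slope:.4g}"
            )
    return MetLabel(
        participant_id=participant_id,
        activity_name=activity_name,
        met_value=float(v_used.mean() / REST_VO2),
        steady_state_window=(float(onset_s), float(t_used[-1])),
        n_breaths_used=n_used,
    )


def label_cohort_vo2(
    traces: list[SessionVo2],
    onset_s: float = DEFAULT_ONSET_S,
    **kwargs,
) -> tuple[pd.DataFrame, int]:
    """Label every session trace; return (labels table, exclusion count).

    The table has columns participant_id, activity, met_value, t_start,
    t_end, n_breaths. Sessions failing the steady-state contract are
    excluded and counted.
    """
    rows = []
    n_excluded = 0
    for sv in traces:
        try:
            label = steady_state_met(
                sv.trace,
                onset_s,
                participant_id=sv.participant_id,
                activity_name=sv.activity_name,
                **kwargs,
            )
        except SteadyStateError as exc:
            logger.warning(
                "excluding %s/%s: %s", sv.participant_id, sv.activity_name, exc
            )
            n_excluded += 1
            continue
        rows.append(
            {
                "participant_id": label.participant_id,
                "activity": label.activity_name,
                "met_value": label.met_value,
                "t_start": label.steady_state_window[0],
                "t_end": label.steady_state_window[1],
                "n_breaths": label.n_breaths_used,
            }
        )
    columns = ["participant_id", "activity", "met_value", "t_start", "t_end", "n_breaths"]
    return pd.DataFrame(rows, columns=columns), n_excluded
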