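"""Spontaneous coiling and tactile-evoked C-bend quantification in embryos.

Young zebrafish embryos (~25 hpf) produce spontaneous trunk coils — single
contractions or short barrages of several contractions in quick succession.
Each isolated contraction or barrage counts as one motor event; the summary
statistics are the event rate (events/min) and the share of events with
more than one contraction.  Slightly older embryos (~51 hpf) respond to a
light touch with a C-bend, whose duration is read off a trunk-curvature
trace as the span from the first deviation from baseline until the return
to baseline; only complete (returned) bends contribute durations, and when
several contractions follow one stimulus only the first is scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CoilingEvent",
    "CoilingEventSeries",
    "CoilingSummary",
    "CurvatureTrace",
    "CBendMeasure",
    "group_contractions",
    "summarize_coiling",
    "measure_cbend",
]

GAP_THRESHOLD_S = 1.0  # contractions closer than this form one event


@dataclass(frozen=True)
class CoilingEvent:
    onset: float  # s
    n_contractions: int

    def __post_init__(self) -> None:
        if self.n_contractions < 1:
            raise ValueError("an event has at least one contraction")


@dataclass
class CoilingEventSeries:
    """Grouped contraction events over one embryo recording."""

    duration: float  # s
    events: list[CoilingEvent]

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        onsets = [e.onset for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")
        if onsets and (onsets[0] < 0 or onsets[-1] > self.duration):
            raise ValueError("event onsets must lie within the recording")


@dataclass
class CoilingSummary:
    events_per_min: float
    pct_multi: float | None  # None when there are no events
    has_any_multi: bool


@dataclass
class CurvatureTrace:
    """Uniformly sampled trunk-curvature (or trunk-angle) time series."""

    frame_rate: float
    values: np.ndarray
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be a 1-D array")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.frame_rate


@dataclass
class CBendMeasure:
    onset: float  # s
    duration_ms: float | None  # None for incomplete bends
    peak_amplitude: float
    complete: bool


def group_contractions(
    contraction_times,
    gap_threshold: float = GAP_THRESHOLD_S,
    duration: float | None = None,
) -> CoilingEventSeries:
    """Group individual contractions into motor events.

    Contractions separated by less than ``gap_threshold`` seconds belong to
    the same event; the event onset is its first contraction.  Input times
    must be sorted.
    """
    t = np.asarray(list(contraction_times), dtype=float)
    if t.size and np.any(np.diff(t) < 0):
        raise ValueError("contraction times must be sorted")
    if gap_threshold < 0:
        raise ValueError("gap_threshold must be non-negative")
    if duration is None:
        duration = float(t[-1]) + gap_threshold if t.size else 1.0
    events: list[CoilingEvent] = []
    i = 0
    while i < t.size:
        j = i + 1
        while j < t.size and t[j] - t[j - 1] < gap_threshold:
            j += 1
        events.append(CoilingEvent(onset=float(t[i]), n_contractions=j - i))
        i = j
    return CoilingEventSeries(duration=duration, events=events)


def summarize_coiling(series: CoilingEventSeries) -> CoilingSummary:
    """Event rate and multi-contraction share of a coiling recording."""
    n = len(series.events)
    events_per_min = n / (series.duration / 60.0)
    if n == 0:
        return CoilingSummary(events_per_min=0.0, pct_multi=None, has_any_multi=False)
    n_multi = sum(1 for e in series.events if e.n_contractions > 1)
    return CoilingSummary(
        events_per_min=events_per_min,
        pct_multi=100.0 * n_multi / n,
        has_any_multi=n_multi > 0,
    )


def measure_cbend(
    trace: CurvatureTrace,
    deviation_threshold: float | None = None,
    return_tolerance: float | None = None,
    stim_times=None,
    min_above: int = 2,
) -> list[CBendMeasure]:
    """Detect C-bends in a curvature trace and measure their durations.

    A bend starts at the first sample whose deviation from baseline exceeds
    ``deviation_threshold`` and ends at the first subsequent sample whose
    deviation is back within ``return_tolerance``; the duration is the time
    between those samples.  Bends that do not return before the trace ends
    are flagged incomplete and carry no duration.  Candidate bends with
    fewer than ``min_above`` consecutive supra-threshold samples are
    discarded as noise.  Detection uses the absolute deviation, so left and
    right coils score identically.

    When thresholds are omitted they are derived from the trace's robust
    noise level (1.4826 x MAD of the deviation): 3 sigma to call an onset,
    1 sigma to call a return.  When ``stim_times`` is given, only the first
    bend at or after each stimulus is reported (one response per stimulus).
    """
    dev = np.abs(trace.values - trace.baseline)
    if deviation_threshold is None or return_tolerance is None:
        # median(|noise|) = 0.6745 sigma for symmetric noise; robust to
        # pulses as long as they occupy under half of the trace
        sd = float(np.median(dev)) / 0.6745
        if sd == 0:
            sd = max(1e-12, 0.01 * float(dev.max(initial=0.0)))
        if deviation_threshold is None:
            deviation_threshold = 3.0 * sd
        if return_tolerance is None:
            return_tolerance = sd
    if deviation_threshold <= return_tolerance:
        raise ValueError("deviation_threshold must exceed return_tolerance")

    fr = trace.frame_rate
    events: list[CBendMeasure] = []
    n = dev.size
    i = 0
    while i < n:
        if dev[i] > deviation_threshold:
            start = i
            j = i + 1
            while j < n and dev[j] > return_tolerance:
                j += 1
            above = int(np.sum(dev[start:j] > deviation_threshold))
            if above >= min_above:
                complete = j < n
                peak = float(np.max(dev[start:j]))
                # inclusive frame count: onset is detected one sample late
                # (the trace must exceed the threshold) while the return is
                # detected immediately; counting both endpoints centers the
                # estimate on the true pulse width
                duration = (j - start + 1) / fr * 1000.0 if complete else None
                events.append(
                    CBendMeasure(
                        onset=start / fr,
                        duration_ms=duration,
                        peak_amplitude=peak,
                        complete=complete,
                    )
                )
            i = j
        else:
            i += 1

    if stim_times is not None:
        responses: list[CBendMeasure] = []
        for t0 in stim_times:
            after = [e for e in events if e.onset >= t0]
            if after:
                responses.append(after[0])
        return responses
    return events
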