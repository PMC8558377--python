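"""SPW-R detection: candidate epochs, cycle extraction, event features, bursts.

Candidate epochs are maximal intervals of z-scored ripple-band power above
threshold (default 3 SD), extended to the surrounding z > 0.5 envelope so the
first/last cycles are not truncated, and merged across gaps shorter than the
merge gap. Detections overlapping active-exploration segments are excluded.
Within each epoch, ripple cycles are the alternating extrema of the
ripple-bandpassed trace; a trough is accepted only if its interval from the
last accepted trough lies in [4, 10] ms — pairs outside the bounds are
skipped as false detections and the scan continues. Event start/end are the
first/last accepted troughs; the internal ripple frequency is the reciprocal
of the mean inter-trough interval over the five middle cycles (three for
ripples with fewer than six cycles).
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np

from .core import DetectionParams, RippleEvent, StateSegments, TimeSeries

__all__ = [
    "detect_candidate_epochs",
    "extract_ripple_cycles",
    "build_ripple_event",
    "group_burst_complexes",
    "detect_ripples",
]


def detect_candidate_epochs(ripple_z_power: TimeSeries, states: Optional[StateSegments],
                            params: DetectionParams,
                            edge_guard: float = 0.0) -> List[Tuple[float, float]]:
    """Supra-threshold ripple-power intervals during immobility.

    Returns half-open ``(start, end)`` intervals in seconds: maximal regions
    where z exceeds ``envelope_threshold`` that contain at least one sample
    above ``ripple_power_threshold``, merged across gaps shorter than
    ``merge_gap``, with intervals overlapping active segments removed.
    ``edge_guard`` seconds at either record boundary are excluded
    (filter-transient contamination).
    """
    z = ripple_z_power.values
    fs = ripple_z_power.sampling_rate
    core = z > params.ripple_power_threshold
    if not core.any():
        return []
    envelope = z > params.envelope_threshold
    # maximal envelope runs containing a core sample
    idx = np.flatnonzero(np.diff(envelope.astype(np.int8)))
    starts = np.concatenate([[0] if envelope[0] else [], idx[~envelope[idx]] + 1]).astype(int)
    ends = np.concatenate([idx[envelope[idx]] + 1, [z.size] if envelope[-1] else []]).astype(int)
    core_cum = np.concatenate([[0], np.cumsum(core)])
    keep = (core_cum[ends] - core_cum[starts]) > 0
    starts, ends = starts[keep], ends[keep]
    if starts.size == 0:
        return []
    # merge across short gaps
    merged = [[starts[0], ends[0]]]
    gap = params.merge_gap * fs
    for s, e in zip(starts[1:], ends[1:]):
        if s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    t0 = ripple_z_power.start_time
    out = []
    lo = t0 + edge_guard
    hi = ripple_z_power.end_time - edge_guard
    for s, e in merged:
        start, end = t0 + s / fs, t0 + e / fs
        if start < lo or end > hi:
            continue
        if states is not None and states.overlaps_active(start, end):
            continue
        out.append((start, end))
    return out


def _refined_extrema(x: np.ndarray, fs: float, t0: float,
                     kind: str) -> np.ndarray:
    """Local extrema times with parabolic sub-sample refinement.

    ``kind`` is ``"min"`` or ``"max"``. Discrete extrema come from sign
    changes of the first difference (ties break to the earlier sample); each
    is refined by the vertex of the parabola through its three neighbours.
    """
    d = np.diff(x)
    if kind == "min":
        idx = np.flatnonzero((d[:-1] < 0) & (d[1:] >= 0)) + 1
    else:
        idx = np.flatnonzero((d[:-1] > 0) & (d[1:] <= 0)) + 1
    idx = idx[(idx > 0) & (idx < x.size - 1)]
    if idx.size == 0:
        return np.array([])
    denom = x[idx - 1] - 2 * x[idx] + x[idx + 1]
    delta = np.zeros(idx.size)
    ok = np.abs(denom) > 1e-30
    delta[ok] = 0.5 * (x[idx - 1] - x[idx + 1])[ok] / denom[ok]
    delta = np.clip(delta, -0.5, 0.5)
    return t0 + (idx + delta) / fs


def extract_ripple_cycles(ripple_band_lfp: TimeSeries, epoch: Tuple[float, float],
                          params: DetectionParams) -> Tuple[np.ndarray, np.ndarray]:
    """Accepted trough and peak times within a candidate epoch.

    Troughs are scanned in time order; a trough is accepted when its interval
    from the last accepted trough lies within the cycle-period bounds. A
    too-short interval skips the candidate (noise blip); a too-long interval
    accepts the trough as the new reference but the spanning pair is excluded
    from frequency estimation downstream. Returns empty arrays when fewer
    than ``min_troughs`` troughs are accepted (epoch discarded, not fatal).
    """
    seg = ripple_band_lfp.slice(*epoch)
    troughs = _refined_extrema(seg.values, seg.sampling_rate, seg.start_time, "min")
    peaks = _refined_extrema(seg.values, seg.sampling_rate, seg.start_time, "max")
    if troughs.size == 0:
        return np.array([]), np.array([])
    cmin = params.cycle_period_min / 1000.0 - params.interval_tolerance
    cmax = params.cycle_period_max / 1000.0 + params.interval_tolerance
    accepted = [troughs[0]]
    n_valid_pairs = 0
    for t in troughs[1:]:
        dt = t - accepted[-1]
        if dt < cmin:
            continue  # false detection closer than the minimum cycle period
        if dt <= cmax:
            n_valid_pairs += 1
        # an over-long pair is excluded from frequency estimation downstream,
        # but the trough still becomes the new scan reference
        accepted.append(t)
    accepted = np.asarray(accepted)
    if accepted.size < params.min_troughs or n_valid_pairs < params.min_troughs - 1:
        return np.array([]), np.array([])
    peaks = peaks[(peaks > accepted[0]) & (peaks < accepted[-1])]
    return accepted, peaks


def build_ripple_event(trough_times: np.ndarray, peak_times: np.ndarray,
                       ripple_z_power: TimeSeries, spw_z_power: TimeSeries,
                       temperature: TimeSeries,
                       params: DetectionParams) -> Optional[RippleEvent]:
    """Assemble a :class:`RippleEvent` from accepted cycles.

    Frequency is ``1 / mean(inter-trough interval)`` over the five middle
    intervals (three when the ripple has fewer than six cycles); intervals
    outside the cycle-period bounds (gaps from excluded pairs) do not enter
    the mean. Power features are the mean and max of the z traces over
    ``[start, end]``. Returns ``None`` when fewer than three valid intervals
    remain (frequency not estimable).
    """
    trough_times = np.asarray(trough_times, dtype=float)
    if trough_times.size < params.min_troughs:
        return None
    intervals = np.diff(trough_times)
    cmin = params.cycle_period_min / 1000.0 - params.interval_tolerance
    cmax = params.cycle_period_max / 1000.0 + params.interval_tolerance
    valid = intervals[(intervals >= cmin) & (intervals <= cmax)]
    n = valid.size
    if n < 3:
        return None
    if trough_times[-1] - trough_times[0] < params.min_event_duration:
        return None  # shorter than any physiological ripple; noise transient
    if n >= 6:
        lo = (n - 5) // 2
        sel = valid[lo:lo + 5]
    else:
        lo = (n - 3) // 2
        sel = valid[lo:lo + 3]
    frequency = 1.0 / float(np.mean(sel))
    start, end = float(trough_times[0]), float(trough_times[-1])
    i0 = ripple_z_power.index_at(start)
    i1 = ripple_z_power.index_at(end)
    rip = ripple_z_power.values[i0:i1 + 1]
    j0 = spw_z_power.index_at(start)
    j1 = spw_z_power.index_at(end)
    spw = spw_z_power.values[j0:j1 + 1]
    return RippleEvent(
        start=start,
        end=end,
        trough_times=trough_times,
        peak_times=np.asarray(peak_times, dtype=float),
        frequency=frequency,
        ripple_power_avg=float(np.mean(rip)),
        ripple_power_max=float(np.max(rip)),
        spw_power_avg=float(np.mean(spw)),
        spw_power_max=float(np.max(spw)),
        temperature=temperature.value_at(start),
        burst_id=None,
    )


def group_burst_complexes(events: List[RippleEvent],
                          max_gap: float = 0.200) -> List[RippleEvent]:
    """Assign burst ids to chains of events with successive starts <= max_gap.

    Singleton events keep ``burst_id = None``. Events must be time-sorted.
    Mutates and returns the list.
    """
    starts = [e.start for e in events]
    if starts != sorted(starts):
        raise ValueError("events must be time-sorted")
    next_id = 0
    chain = [0] if events else []
    for i in range(1, len(events)):
        if events[i].start - events[i - 1].start <= max_gap:
            chain.append(i)
        else:
            next_id = _flush_chain(events, chain, next_id)
            chain = [i]
    _flush_chain(events, chain, next_id)
    return events


def _flush_chain(events, chain, next_id):
    if len(chain) >= 2:
        for i in chain:
            events[i].burst_id = next_id
        return next_id + 1
    return next_id


def detect_ripples(ripple_band_lfp: TimeSeries,
                   ripple_z_detect: TimeSeries,
                   ripple_z_power: TimeSeries,
                   spw_z_power: TimeSeries,
                   temperature: TimeSeries,
                   states: Optional[StateSegments],
                   params: DetectionParams,
                   edge_guard: float = 0.0) -> List[RippleEvent]:
    """Full SPW-R detection chain on precomputed traces.

    ``ripple_z_detect`` is the (smoothed) z trace used for thresholding;
    ``ripple_z_power``/``spw_z_power`` are the unsmoothed z traces used for
    the per-event power features.
    """
    epochs = detect_candidate_epochs(ripple_z_detect, states, params, edge_guard)
    events: List[RippleEvent] = []
    for epoch in epochs:
        troughs, peaks = extract_ripple_cycles(ripple_band_lfp, epoch, params)
        if troughs.size == 0:
            continue
        ev = build_ripple_event(troughs, peaks, ripple_z_power, spw_z_power,
                                temperature, params)
        if ev is not None:
            events.append(ev)
    events.sort(key=lambda e: e.start)
    group_burst_complexes(events, max_gap=params.burst_max_gap)
    return events
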