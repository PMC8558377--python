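"""Interictal discharge detection, myoclonus discrimination, artifact rules.

Candidate spikes are samples that are simultaneously high-amplitude
(|z| > 1 SD of the broadband LFP) and fast-rising (|z| > 5 SD of its first
derivative); candidates within a 100 ms dead time collapse to one event
aligned to the largest-|z| extremum. Thresholds are polarity-agnostic
because depth-electrode polarity varies with lamina. Myoclonic events are
separated from plain interictal spikes by the ratio of normalized EMG power
in the 100 ms after vs before the spike (> 2 means myoclonus). Artifacts are
flagged by rule: coincident supra-threshold deflections on >= 2 LFP channels
with sustained pre-existing EMG elevation, or occurrence inside an
active-exploration segment; a manual-override file takes precedence.
"""

from __future__ import annotations

import warnings
from dataclasses import replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import uniform_filter1d

from .core import (
    ACTIVE,
    DetectionParams,
    EpilepticEvent,
    StateSegments,
    TimeSeries,
)

__all__ = [
    "lfp_derivative",
    "detect_spike_candidates",
    "classify_myoclonic",
    "classify_events",
    "reject_artifacts",
    "locate_gtc",
    "gtc_extent",
    "peri_event_average",
]


def lfp_derivative(lfp: TimeSeries) -> TimeSeries:
    """First derivative estimated by central difference x sampling rate."""
    d = np.gradient(lfp.values) * lfp.sampling_rate
    return lfp.copy_with(d, units=f"{lfp.units}/s" if lfp.units else "",
                         label="lfp-derivative")


def detect_spike_candidates(lfp_z: TimeSeries, lfp_deriv_z: TimeSeries,
                            params: DetectionParams,
                            temperature: Optional[TimeSeries] = None,
                            edge_guard: float = 0.0) -> List[EpilepticEvent]:
    """Events where amplitude and derivative thresholds are exceeded together.

    Seed samples within ``spike_dead_time`` of each other collapse to a
    single event aligned to the extremum of ``|lfp_z|`` over the seed span.
    """
    if lfp_z.n != lfp_deriv_z.n:
        raise ValueError("amplitude and derivative traces must be aligned")
    a = lfp_z.values
    d = lfp_deriv_z.values
    fs = lfp_z.sampling_rate
    mask = (np.abs(a) > params.spike_amp_threshold) & \
           (np.abs(d) > params.spike_deriv_threshold)
    seeds = np.flatnonzero(mask)
    if seeds.size == 0:
        return []
    dead = params.spike_dead_time * fs
    groups = np.split(seeds, np.flatnonzero(np.diff(seeds) > dead) + 1)
    events: List[EpilepticEvent] = []
    lo = lfp_z.start_time + edge_guard
    hi = lfp_z.end_time - edge_guard
    for g in groups:
        i0, i1 = int(g[0]), int(g[-1])
        k = i0 + int(np.argmax(np.abs(a[i0:i1 + 1])))
        t = lfp_z.time_at(k)
        if t < lo or t > hi:
            continue
        events.append(EpilepticEvent(
            trough_time=t,
            event_class="interictal_spike",
            amplitude=float(a[k]),
            temperature=temperature.value_at(t) if temperature is not None
            else float("nan"),
        ))
    # enforce the dead time between the aligned event times as well
    pruned: List[EpilepticEvent] = []
    for ev in events:
        if pruned and ev.trough_time - pruned[-1].trough_time < params.spike_dead_time:
            if abs(ev.amplitude) > abs(pruned[-1].amplitude):
                pruned[-1] = ev
        else:
            pruned.append(ev)
    return pruned


def _recentered(mean_z: float) -> float:
    """Map a mean z-scored power back to a positive power-like scale.

    Instantaneous power of stationary Gaussian noise has mean ~= SD, so its
    z-score is bounded below by about -1; adding 1 restores a nonnegative
    scale. A 0.01 floor guards the ratio against division pathologies.
    """
    return max(mean_z + 1.0, 0.01)


def classify_myoclonic(event: EpilepticEvent, emg_z_power: TimeSeries,
                       params: DetectionParams) -> EpilepticEvent:
    """Classify one spike as myoclonic vs interictal by the EMG power ratio.

    Normalized EMG power is averaged over the ``emg_window`` (100 ms) before
    and after the spike time; a post/pre ratio strictly greater than
    ``emg_ratio_threshold`` is consistent with myoclonus. Events whose
    windows fall outside the record are left unclassified with a warning.
    Artifact/GTC events pass through unchanged.
    """
    if event.event_class in ("artifact", "gtc"):
        return event
    w = params.emg_window / 1000.0
    t = event.trough_time
    if t - w < emg_z_power.start_time or t + w > emg_z_power.end_time:
        warnings.warn(f"event at {t:.3f} s too close to record edge; left unclassified")
        return event
    pre = emg_z_power.slice(t - w, t).values
    post = emg_z_power.slice(t, t + w).values[1:]  # exclude the spike sample itself
    pre_mean = float(np.mean(pre))
    post_mean = float(np.mean(post))
    ratio = _recentered(post_mean) / _recentered(pre_mean)
    cls = "myoclonic" if ratio > params.emg_ratio_threshold else "interictal_spike"
    return replace(event, event_class=cls, emg_power_pre=pre_mean,
                   emg_power_post=post_mean, emg_ratio=ratio)


def classify_events(events: Sequence[EpilepticEvent], emg_z_power: TimeSeries,
                    params: DetectionParams) -> List[EpilepticEvent]:
    return [classify_myoclonic(e, emg_z_power, params) for e in events]


def _elevated_emg_runs(emg_z_power: TimeSeries, params: DetectionParams) -> list:
    # short smoothing: a myoclonic burst (EMG strictly after the spike) must
    # not bleed backward and mimic pre-existing movement
    w = max(1, int(round(params.artifact_emg_smoothing * emg_z_power.sampling_rate)))
    if w % 2 == 0:
        w += 1
    sm = np.sqrt(uniform_filter1d(emg_z_power.values ** 2, size=w, mode="nearest"))
    mask = sm > params.emg_state_threshold
    idx = np.flatnonzero(np.diff(mask.astype(np.int8)))
    starts = np.concatenate([[0] if mask[0] else [], idx[~mask[idx]] + 1]).astype(int)
    ends = np.concatenate([idx[mask[idx]] + 1, [mask.size] if mask[-1] else []]).astype(int)
    fs = emg_z_power.sampling_rate
    t0 = emg_z_power.start_time
    return [(t0 + s / fs, t0 + e / fs) for s, e in zip(starts, ends)]


def reject_artifacts(events: Sequence[EpilepticEvent],
                     lfp_z_channels: Sequence[TimeSeries],
                     emg_z_power: TimeSeries,
                     states: StateSegments,
                     params: DetectionParams,
                     overrides: Optional[Dict[float, str]] = None,
                     ripple_events: Optional[Sequence] = None,
                     ) -> List[EpilepticEvent]:
    """Assign the artifact class by rule, honoring manual overrides.

    The heuristic stands in for the study's manual review. An event becomes
    an artifact if (a) >= 2 LFP channels show a supra-threshold deflection
    within ``artifact_coincidence`` of the event AND the EMG is elevated for
    >= ``artifact_emg_sustain`` in a run that begins before the event and
    covers it (movement artifact), (b) the event lies in an
    active-exploration segment, (c) the event has ripple morphology: its
    trough lies inside a detected SPW-R and its amplitude is below
    ``ripple_morphology_amp`` (epileptiform spikes are several-fold larger
    than ripple cycles), or (d) unusual morphology: the extremum amplitude
    is below ``artifact_min_amplitude``, i.e. within the background range a
    reviewer would never call a discharge. ``overrides`` maps event times
    (matched within 50 ms) to verdicts ``"artifact"`` or ``"keep"``.
    """
    emg_runs = _elevated_emg_runs(emg_z_power, params)
    ripple_spans = [(r.start - 0.01, r.end + 0.01) for r in (ripple_events or [])]
    out: List[EpilepticEvent] = []
    for ev in events:
        t = ev.trough_time
        verdict = _override_for(overrides, t)
        if verdict is not None:
            is_artifact = verdict == "artifact"
        elif states is not None and states.label_at(t) == ACTIVE:
            is_artifact = True
        elif abs(ev.amplitude) < params.artifact_min_amplitude:
            is_artifact = True
        elif abs(ev.amplitude) < params.ripple_morphology_amp and \
                any(s <= t <= e for s, e in ripple_spans):
            is_artifact = True
        else:
            is_artifact = _multichannel_with_emg(t, lfp_z_channels, emg_runs, params)
        if is_artifact:
            out.append(replace(ev, event_class="artifact"))
        else:
            out.append(ev)
    return out


def _override_for(overrides, t, tol=0.050):
    if not overrides:
        return None
    times = np.array(sorted(overrides))
    i = int(np.argmin(np.abs(times - t)))
    if abs(times[i] - t) <= tol:
        return overrides[float(times[i])]
    return None


def _multichannel_with_emg(t, lfp_z_channels, emg_runs, params) -> bool:
    n_hit = 0
    for ch in lfp_z_channels:
        i0 = ch.index_at(t - params.artifact_coincidence)
        i1 = ch.index_at(t + params.artifact_coincidence)
        if np.max(np.abs(ch.values[i0:i1 + 1])) > params.spike_amp_threshold:
            n_hit += 1
    if n_hit < 2:
        return False
    for s, e in emg_runs:
        if s <= t - params.artifact_emg_lead and e >= t \
                and e - s >= params.artifact_emg_sustain:
            return True
    return False


def locate_gtc(annotations: Optional[dict],
               lfp_power_z: Optional[TimeSeries] = None,
               emg_power_z: Optional[TimeSeries] = None,
               params: Optional[DetectionParams] = None) -> Optional[float]:
    """GTC onset time: the annotation if present, else a sustained-power rule.

    Without an annotation, the onset is the first time where both the
    broadband LFP power z and EMG power z (each smoothed over
    ``gtc_smoothing``) exceed ``gtc_power_threshold`` for at least
    ``gtc_min_duration`` seconds. Returns ``None`` when no such epoch exists.
    """
    if annotations and "gtc_onset" in annotations:
        return float(annotations["gtc_onset"])
    if lfp_power_z is None or emg_power_z is None:
        return None
    ext = gtc_extent(lfp_power_z, emg_power_z, params or DetectionParams())
    return None if ext is None else ext[0]


def gtc_extent(lfp_power_z: TimeSeries, emg_power_z: TimeSeries,
               params: DetectionParams) -> Optional[Tuple[float, float]]:
    """(start, end) of the first sustained joint high-power epoch, or None."""
    fs = lfp_power_z.sampling_rate
    w = max(1, int(round(params.gtc_smoothing * fs)))
    lfp_sm = uniform_filter1d(lfp_power_z.values, size=w, mode="nearest")
    emg_sm = uniform_filter1d(emg_power_z.values, size=w, mode="nearest")
    mask = (lfp_sm > params.gtc_power_threshold) & \
           (emg_sm > params.gtc_power_threshold)
    idx = np.flatnonzero(np.diff(mask.astype(np.int8)))
    starts = np.concatenate([[0] if mask[0] else [], idx[~mask[idx]] + 1]).astype(int)
    ends = np.concatenate([idx[mask[idx]] + 1, [mask.size] if mask[-1] else []]).astype(int)
    min_len = params.gtc_min_duration * fs
    for s, e in zip(starts, ends):
        if e - s >= min_len:
            return (lfp_power_z.time_at(int(s)), lfp_power_z.time_at(int(e - 1)))
    return None


def peri_event_average(traces: Sequence[TimeSeries],
                       events: Sequence[EpilepticEvent],
                       window: float) -> List[TimeSeries]:
    """Mean of each trace in ``[-window, +window]`` around event times.

    Events whose window extends beyond a trace are skipped for that trace;
    zero usable events is an error.
    """
    out = []
    for trace in traces:
        fs = trace.sampling_rate
        half = int(round(window * fs))
        segs = []
        for ev in events:
            c = trace.index_at(ev.trough_time)
            if c - half < 0 or c + half >= trace.n:
                continue
            segs.append(trace.values[c - half:c + half + 1])
        if not segs:
            raise ValueError("no events with a full peri-event window")
        mean = np.mean(np.asarray(segs), axis=0)
        out.append(TimeSeries(mean, fs, start_time=-half / fs,
                              units=trace.units, label=f"{trace.label}-peri"))
    return out
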