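"""Temperature- and seizure-aligned aggregation of detected events.

Binning convention: bins are ``[center - w/2, center + w/2)`` with centers at
multiples of the bin width anchored at 36.0 degC. Event rates in a bin are
the event count divided by the dwell time (time the animal spent at
temperatures in the bin, within the analyzed restriction). Aggregation is
always per-subject first, then across subjects (grand average +- SEM);
events are never pooled across subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import optimize, signal, stats

from .core import (
    RIPPLE_BAND,
    BandDefinition,
    DetectionParams,
    EpilepticEvent,
    RippleEvent,
    StateSegments,
    TimeSeries,
    intersect_intervals,
)

__all__ = [
    "TemperatureBinSummary",
    "AlignedSeries",
    "SpectralPeak",
    "PairedResult",
    "SigmoidFit",
    "GroupTrend",
    "OnsetSummary",
    "temperature_bin_center",
    "dwell_and_rate",
    "feature_by_temperature",
    "spectral_peak_frequency",
    "align_to_anchor",
    "onset_temperatures",
    "peri_event_rate",
    "pre_post_rate_test",
    "spw_amplitude_split_test",
    "fit_sigmoid_trend",
    "pearson_trend",
    "grand_average",
    "trend_and_group_stats",
]

BIN_ANCHOR = 36.0


@dataclass
class TemperatureBinSummary:
    bin_center: float
    bin_width: float
    dwell_time: float = 0.0
    event_count: int = 0
    rate: float = float("nan")       # events/s; NaN when undefined
    mean_feature: float = float("nan")
    sem: float = float("nan")
    n: int = 0
    defined: bool = True


@dataclass
class AlignedSeries:
    anchor_type: str                 # "gtc" | "temperature_crossing"
    anchor_time: float
    relative_times: np.ndarray
    values: Optional[np.ndarray] = None


@dataclass
class SpectralPeak:
    bin_center: float
    frequency: float                 # Hz; NaN when flagged
    ok: bool
    n_seconds: float = 0.0


@dataclass
class PairedResult:
    statistic: float
    pvalue: float
    pre: np.ndarray
    post: np.ndarray
    n: int


@dataclass
class SigmoidFit:
    floor: float
    ceiling: float
    midpoint: float
    slope: float
    converged: bool
    degenerate: bool = False


@dataclass
class GroupTrend:
    r: float
    pvalue: float
    grand_mean: float
    sem: float
    n_subjects: int


@dataclass
class OnsetSummary:
    mean: float
    sem: float
    values: np.ndarray


def temperature_bin_center(temp: Union[float, np.ndarray], width: float) -> np.ndarray:
    """Center of the half-open bin containing ``temp``."""
    idx = np.floor((np.asarray(temp, dtype=float) - BIN_ANCHOR) / width + 0.5)
    return BIN_ANCHOR + idx * width


def _event_time(ev) -> float:
    if isinstance(ev, RippleEvent):
        return ev.start
    if isinstance(ev, EpilepticEvent):
        return ev.trough_time
    return float(ev)


def _in_intervals(t: float, intervals) -> bool:
    return any(s <= t < e for s, e in intervals)


def dwell_and_rate(events: Sequence, temperature: TimeSeries, bin_width: float = 0.5,
                   restrict: Optional[Sequence[Tuple[float, float]]] = None,
                   ) -> List[TemperatureBinSummary]:
    """Per-bin dwell time, event count, and rate = count / dwell.

    ``restrict`` limits both the dwell-time denominator and the counted
    events to the given intervals (e.g. pre-ictal immobility). Bins with
    events but zero dwell are flagged undefined rather than zero-filled.
    """
    times = temperature.times()
    temps = temperature.values
    if restrict is not None:
        mask = np.zeros(times.size, dtype=bool)
        for s, e in restrict:
            mask |= (times >= s) & (times < e)
        temps_r = temps[mask]
    else:
        temps_r = temps
    dwell_centers, dwell_counts = np.unique(
        temperature_bin_center(temps_r, bin_width), return_counts=True)
    dwell = dict(zip(dwell_centers, dwell_counts / temperature.sampling_rate))

    counts: dict = {}
    for ev in events:
        t = _event_time(ev)
        if restrict is not None and not _in_intervals(t, restrict):
            continue
        temp = getattr(ev, "temperature", None)
        if temp is None or (isinstance(temp, float) and np.isnan(temp)):
            temp = temperature.value_at(t)
        c = float(temperature_bin_center(temp, bin_width))
        counts[c] = counts.get(c, 0) + 1

    out = []
    for center in sorted(set(dwell) | set(counts)):
        d = dwell.get(center, 0.0)
        k = counts.get(center, 0)
        if d > 0:
            out.append(TemperatureBinSummary(center, bin_width, d, k, k / d, n=k))
        else:
            out.append(TemperatureBinSummary(center, bin_width, 0.0, k,
                                             float("nan"), n=k, defined=False))
    return out


def feature_by_temperature(events: Sequence, feature: Union[str, Callable],
                           bin_width: float = 0.25) -> List[TemperatureBinSummary]:
    """Per-bin mean and SEM of an event feature keyed by event temperature."""
    get = (lambda e: getattr(e, feature)) if isinstance(feature, str) else feature
    groups: dict = {}
    for ev in events:
        c = float(temperature_bin_center(ev.temperature, bin_width))
        groups.setdefault(c, []).append(get(ev))
    out = []
    for center in sorted(groups):
        vals = np.asarray(groups[center], dtype=float)
        n = vals.size
        sem = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        out.append(TemperatureBinSummary(center, bin_width, event_count=n,
                                         mean_feature=float(np.mean(vals)),
                                         sem=sem, n=n))
    return out


def _gauss_offset(f, amp, mu, sigma, offset):
    return amp * np.exp(-0.5 * ((f - mu) / sigma) ** 2) + offset


def spectral_peak_frequency(lfp: TimeSeries, temperature: TimeSeries,
                            states: Optional[StateSegments],
                            bin_width: float = 1.0,
                            band: BandDefinition = RIPPLE_BAND,
                            min_seconds: float = 4.0,
                            segment_seconds: float = 0.5,
                            ) -> List[SpectralPeak]:
    """Gaussian-fitted ripple-band spectral peak per temperature bin.

    Immobility LFP samples are concatenated by temperature bin; each bin with
    at least ``min_seconds`` of signal gets a Welch spectrum (Hanning
    segments of ``segment_seconds``, 50% overlap) and a Gaussian+offset fit
    over the band slice. Bins where the fitted amplitude is below twice the
    residual SD (no significant peak) or where the fit fails are flagged.
    """
    fs = lfp.sampling_rate
    t_lfp = lfp.times()
    temp_at_lfp = np.interp(t_lfp, temperature.times(), temperature.values)
    centers = temperature_bin_center(temp_at_lfp, bin_width)
    if states is not None:
        immobile = np.zeros(lfp.n, dtype=bool)
        for s, e in states.immobile_intervals():
            i0, i1 = lfp.index_at(s), lfp.index_at(e - 1e-9)
            immobile[i0:i1 + 1] = True
    else:
        immobile = np.ones(lfp.n, dtype=bool)

    nperseg = int(round(segment_seconds * fs))
    out = []
    for center in np.unique(centers):
        sel = (centers == center) & immobile
        n_sec = sel.sum() / fs
        if n_sec < min_seconds:
            continue
        x = lfp.values[sel]
        f, pxx = signal.welch(x, fs=fs, window="hann", nperseg=nperseg,
                              noverlap=nperseg // 2)
        sl = (f >= band.low) & (f <= band.high)
        fb, pb = f[sl], pxx[sl]
        peak = _fit_band_peak(fb, pb, band)
        out.append(SpectralPeak(float(center), peak if peak is not None
                                else float("nan"), peak is not None, n_sec))
    return out


def _fit_band_peak(fb, pb, band) -> Optional[float]:
    amp0 = float(pb.max() - pb.min())
    if amp0 <= 0:
        return None
    p0 = [amp0, float(fb[np.argmax(pb)]), 20.0, float(pb.min())]
    try:
        popt, _ = optimize.curve_fit(
            _gauss_offset, fb, pb, p0=p0,
            bounds=([0, band.low, 2.0, -np.inf],
                    [np.inf, band.high, band.high - band.low, np.inf]),
            maxfev=5000)
    except (RuntimeError, ValueError):
        return None
    resid = pb - _gauss_offset(fb, *popt)
    if popt[0] < 2.0 * np.std(resid):
        return None
    return float(popt[1])


def align_to_anchor(times: Union[np.ndarray, Sequence[float]],
                    temperature: TimeSeries,
                    params: DetectionParams,
                    gtc_time: Optional[float] = None,
                    values: Optional[np.ndarray] = None) -> AlignedSeries:
    """Times relative to the GTC onset, or to the first upward crossing of
    the alignment temperature (38.5 degC) when no GTC exists (WT sessions)."""
    if gtc_time is not None:
        anchor, kind = float(gtc_time), "gtc"
    else:
        tv = temperature.values
        at = params.alignment_temperature
        cross = np.flatnonzero((tv[:-1] < at) & (tv[1:] >= at))
        if cross.size == 0:
            raise ValueError("no anchor available: no GTC and the temperature "
                             f"never reaches {at} degC")
        anchor, kind = temperature.time_at(int(cross[0]) + 1), "temperature_crossing"
    rel = np.asarray(times, dtype=float) - anchor
    return AlignedSeries(anchor_type=kind, anchor_time=anchor, relative_times=rel,
                         values=None if values is None else np.asarray(values))


def onset_temperatures(per_session_events: Sequence[Sequence[EpilepticEvent]],
                       classes: Sequence[str] = ("interictal_spike", "myoclonic", "gtc"),
                       ) -> dict:
    """Temperature at the first event of each class per session, then the
    grand average +- SEM across sessions. Classes absent everywhere map to
    ``None``."""
    out = {}
    for cls in classes:
        firsts = []
        for events in per_session_events:
            of_cls = [e for e in events if e.event_class == cls]
            if of_cls:
                first = min(of_cls, key=lambda e: e.trough_time)
                firsts.append(first.temperature)
        if not firsts:
            out[cls] = None
            continue
        vals = np.asarray(firsts, dtype=float)
        sem = float(np.std(vals, ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
        out[cls] = OnsetSummary(mean=float(np.mean(vals)), sem=sem, values=vals)
    return out


def peri_event_rate(event_times: Sequence[float], trigger_times: Sequence[float],
                    bin_width: float = 0.25, window: float = 1.0,
                    duration: Optional[float] = None,
                    ) -> Tuple[np.ndarray, np.ndarray]:
    """Event rate (events/s) in relative-time bins around triggers.

    Returns ``(bin_centers, rates)`` with rates = counts / (bin_width x
    number of usable triggers). Triggers whose window overlaps a record edge
    are skipped when ``duration`` is given.
    """
    triggers = np.asarray(trigger_times, dtype=float)
    if duration is not None:
        triggers = triggers[(triggers >= window) & (triggers <= duration - window)]
    if triggers.size == 0:
        raise ValueError("no usable trigger events")
    events = np.sort(np.asarray(event_times, dtype=float))
    edges = np.arange(-window, window + bin_width / 2, bin_width)
    counts = np.zeros(edges.size - 1)
    for trig in triggers:
        rel = events[(events >= trig - window) & (events <= trig + window)] - trig
        counts += np.histogram(rel, bins=edges)[0]
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts / (bin_width * triggers.size)


def _window_rate(events: np.ndarray, triggers: np.ndarray,
                 lo: float, hi: float) -> float:
    total = 0
    for trig in triggers:
        total += int(np.sum((events >= trig + lo) & (events < trig + hi)))
    return total / ((hi - lo) * triggers.size)


def pre_post_rate_test(per_session: Sequence[Tuple[Sequence[float], Sequence[float], float]],
                       window: float = 1.0) -> PairedResult:
    """Paired t-test of per-session SPW-R rates 1 s before vs after triggers.

    ``per_session`` holds ``(spwr_times, trigger_times, duration)`` per
    session; rates are mean counts per second in ``[-window, 0)`` and
    ``(0, +window]`` around each trigger. Two-sided test.
    """
    pre, post = [], []
    for spwr, trig, duration in per_session:
        spwr = np.asarray(spwr, dtype=float)
        trig = np.asarray(trig, dtype=float)
        trig = trig[(trig >= window) & (trig <= duration - window)]
        if trig.size == 0:
            continue
        pre.append(_window_rate(spwr, trig, -window, 0.0))
        post.append(_window_rate(spwr, trig, 1e-12, window))
    if len(pre) < 2:
        raise ValueError("paired test needs at least 2 sessions with triggers")
    pre_a, post_a = np.asarray(pre), np.asarray(post)
    if np.allclose(pre_a, post_a):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_rel(pre_a, post_a)
    return PairedResult(float(t), float(p), pre_a, post_a, len(pre))


def spw_amplitude_split_test(per_session_ripples: Sequence[Sequence[RippleEvent]],
                             params: DetectionParams) -> PairedResult:
    """Paired t-test of per-session mean SPW power below vs >= 38 degC.

    Sessions lacking events on either side of the split are excluded with a
    warning.
    """
    split = params.spw_split_temperature
    below, above = [], []
    for events in per_session_ripples:
        lo = [e.spw_power_avg for e in events if e.temperature < split]
        hi = [e.spw_power_avg for e in events if e.temperature >= split]
        if not lo or not hi:
            warnings.warn("session with events on only one side of the split excluded")
            continue
        below.append(np.mean(lo))
        above.append(np.mean(hi))
    if len(below) < 2:
        raise ValueError("paired test needs at least 2 two-sided sessions")
    below_a, above_a = np.asarray(below), np.asarray(above)
    if np.allclose(below_a, above_a):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_rel(below_a, above_a)
    return PairedResult(float(t), float(p), below_a, above_a, len(below))


def _logistic(x, floor, ceiling, midpoint, slope):
    return floor + (ceiling - floor) / (1.0 + np.exp(-(x - midpoint) / slope))


def fit_sigmoid_trend(x: Sequence[float], y: Sequence[float]) -> SigmoidFit:
    """Least-squares 4-parameter logistic (floor, ceiling, midpoint, slope)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5:
        raise ValueError("sigmoid fit needs at least 5 points")
    span = float(np.ptp(y))
    scale = max(abs(float(np.mean(y))), span, 1e-12)
    if span < 1e-12 * scale:
        return SigmoidFit(float(y[0]), float(y[0]), float(np.median(x)),
                          float("nan"), converged=True, degenerate=True)
    p0 = [float(y.min()), float(y.max()), float(np.median(x)),
          max(float(np.ptp(x)) / 8.0, 1e-3)]
    try:
        popt, _ = optimize.curve_fit(_logistic, x, y, p0=p0, maxfev=20000)
    except (RuntimeError, ValueError):
        return SigmoidFit(*(float("nan"),) * 4, converged=False)
    fit = SigmoidFit(*map(float, popt), converged=True)
    if abs(fit.ceiling - fit.floor) < 1e-6 * scale:
        fit.degenerate = True
    return fit


def pearson_trend(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Pearson R with two-sided p; zero variance in either input is an error."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("correlation needs n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def grand_average(per_subject_values: Sequence[float]) -> Tuple[float, float]:
    """Grand mean of per-subject means and SEM = sd / sqrt(n_subjects)."""
    vals = np.asarray(per_subject_values, dtype=float)
    if vals.size == 0:
        raise ValueError("no subjects")
    sem = float(np.std(vals, ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
    return float(np.mean(vals)), sem


def trend_and_group_stats(x: Sequence[float], y: Sequence[float],
                          per_subject_values: Sequence[float]) -> GroupTrend:
    r, p = pearson_trend(x, y)
    mean, sem = grand_average(per_subject_values)
    return GroupTrend(r=r, pvalue=p, grand_mean=mean, sem=sem,
                      n_subjects=len(per_subject_values))
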