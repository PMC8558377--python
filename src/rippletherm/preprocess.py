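"""Filtering, envelope power, z-normalization, baseline and state labeling.

All bandpass filtering is zero-phase FIR (Hanning-window design applied
forward-backward), matching the zero-lag requirement: event timing must not
shift between bands. Instantaneous power is the squared magnitude of the
analytic (Hilbert) signal. Every power/amplitude trace is normalized to
z-units against statistics of a reference quiet (NREM-like) epoch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal
from scipy.fft import next_fast_len
from scipy.ndimage import uniform_filter1d

from .core import (
    ACTIVE,
    DELTA_BAND,
    IMMOBILE,
    BandDefinition,
    BaselineStats,
    DetectionParams,
    StateSegments,
    THETA_BAND,
    TimeSeries,
)

__all__ = [
    "FilterSpec",
    "default_taps",
    "ingest_resample",
    "bandpass_zero_phase",
    "instantaneous_power",
    "smooth_moving_average",
    "compute_baseline_stats",
    "zscore",
    "select_baseline_epoch",
    "classify_behavioral_state",
]

TARGET_RATE = 2048.0
ANTIALIAS_CUTOFF = 1024.0


@dataclass
class FilterSpec:
    """Zero-phase FIR bandpass specification (Hanning window design)."""

    band: BandDefinition
    taps: int
    window_shape: str = "hann"
    application: str = "zero-phase"

    def __post_init__(self) -> None:
        if self.taps % 2 == 0:
            raise ValueError("taps must be odd for a symmetric linear-phase FIR")


def default_taps(band: BandDefinition, sampling_rate: float) -> int:
    """Next odd integer >= 3 x rate / low-edge.

    Long enough for ~3 cycles of the slowest band component, giving >=40 dB
    stopband with the Hanning window.
    """
    n = int(math.ceil(3.0 * sampling_rate / band.low))
    return n if n % 2 == 1 else n + 1


def make_filter(band: BandDefinition, sampling_rate: float,
                taps: int = None) -> FilterSpec:
    band.validate_for_rate(sampling_rate)
    if taps is None:
        taps = default_taps(band, sampling_rate)
    return FilterSpec(band=band, taps=taps)


def _fir_kernel(spec: FilterSpec, sampling_rate: float) -> np.ndarray:
    return signal.firwin(spec.taps, [spec.band.low, spec.band.high],
                         pass_zero=False, window="hann", fs=sampling_rate)


def bandpass_zero_phase(series: TimeSeries, spec) -> TimeSeries:
    """Zero-phase bandpass: forward-backward application of a linear-phase FIR.

    ``spec`` may be a :class:`FilterSpec` or a :class:`BandDefinition`
    (default tap count is then derived from the band's low edge).
    """
    if isinstance(spec, BandDefinition):
        spec = make_filter(spec, series.sampling_rate)
    spec.band.validate_for_rate(series.sampling_rate)
    if series.n < 3 * spec.taps:
        raise ValueError(
            f"series too short for filtering: {series.n} samples < 3 x {spec.taps} taps")
    b = _fir_kernel(spec, series.sampling_rate)
    y = signal.filtfilt(b, [1.0], series.values)
    return series.copy_with(y, label=f"{spec.band.name}-band")


def instantaneous_power(series: TimeSeries) -> TimeSeries:
    """Squared analytic-signal magnitude (units of input squared)."""
    n = series.n
    analytic = signal.hilbert(series.values, N=next_fast_len(n))[:n]
    power = np.abs(analytic) ** 2
    label = f"{series.label}-power" if series.label else "power"
    units = f"({series.units})^2" if series.units else ""
    return series.copy_with(power, units=units, label=label)


def smooth_moving_average(series: TimeSeries, window_s: float) -> TimeSeries:
    """Centered moving average; window rounded to an odd sample count."""
    w = max(1, int(round(window_s * series.sampling_rate)))
    if w % 2 == 0:
        w += 1
    return series.copy_with(uniform_filter1d(series.values, size=w, mode="nearest"))


def ingest_resample(raw: TimeSeries, target_rate: float = TARGET_RATE) -> TimeSeries:
    """Anti-alias low-pass at 1,024 Hz and resample to 2048 Hz.

    Accepts rates that are integer multiples of the target, or any rate
    >= 2 x target for polyphase resampling. Upsampling is refused.
    """
    fs = raw.sampling_rate
    if abs(fs - target_rate) < 1e-9:
        return raw
    if fs < target_rate:
        raise ValueError(f"upsampling refused: input rate {fs} Hz < {target_rate} Hz")
    fs_int = int(round(fs))
    if abs(fs - fs_int) > 1e-6:
        raise ValueError("ingest_resample requires an integer input rate")
    if fs_int % int(target_rate) != 0 and fs < 2 * target_rate:
        raise ValueError(
            "input rate must be an integer multiple of the target, or >= twice "
            "the target for polyphase resampling")
    frac = Fraction(int(target_rate), fs_int)
    # resample_poly's Kaiser-windowed FIR cuts at min(fs)/2 = 1,024 Hz, i.e.
    # the anti-alias low-pass is applied before decimation.
    y = signal.resample_poly(raw.values, frac.numerator, frac.denominator)
    return TimeSeries(y, target_rate, start_time=raw.start_time,
                      units=raw.units, label=raw.label)


def compute_baseline_stats(quantity: TimeSeries, epoch: tuple, tag: str,
                           min_duration: float = 30.0) -> BaselineStats:
    """Mean/SD of ``quantity`` over ``epoch`` (half-open, seconds)."""
    start, end = epoch
    if end - start < min_duration:
        raise ValueError(f"baseline epoch shorter than {min_duration} s")
    if start < quantity.start_time - 1e-9 or end > quantity.end_time + 1e-9:
        raise ValueError("baseline epoch outside recording")
    seg = quantity.slice(start, min(end, quantity.end_time))
    mean = float(np.mean(seg.values))
    sd = float(np.std(seg.values))
    if sd <= 0:
        raise ValueError("baseline epoch is constant (sd = 0)")
    return BaselineStats(mean=mean, sd=sd, epoch=(start, end), quantity_tag=tag)


def zscore(quantity: TimeSeries, stats: BaselineStats) -> TimeSeries:
    """Pointwise ``(f(t) - mean) / sd`` against the baseline statistics."""
    if quantity.label and stats.quantity_tag and quantity.label != stats.quantity_tag:
        raise ValueError(
            f"tag mismatch: series {quantity.label!r} vs stats {stats.quantity_tag!r}")
    z = (quantity.values - stats.mean) / stats.sd
    return quantity.copy_with(z, units="z")


def select_baseline_epoch(emg_power: TimeSeries, lfp: TimeSeries,
                          min_duration: float = 60.0,
                          step: float = 1.0) -> tuple:
    """Quietest contiguous window usable as the NREM-like baseline.

    Returns the ``min_duration`` window minimizing mean EMG power, subject to
    a theta-dominance veto: windows with (6-10 Hz power)/(1-4 Hz power) >= 1
    in the LFP are rejected as likely exploratory theta. Ties break to the
    earliest window. Deterministic for fixed input.
    """
    if emg_power.duration < min_duration or lfp.duration < min_duration:
        raise ValueError("recording shorter than the minimum baseline duration")
    fs = emg_power.sampling_rate
    w = int(round(min_duration * fs))
    hop = max(1, int(round(step * fs)))
    x = emg_power.values
    csum = np.concatenate([[0.0], np.cumsum(x)])
    starts = np.arange(0, x.size - w + 1, hop)
    means = (csum[starts + w] - csum[starts]) / w
    # earliest window within 5% of the global minimum, then ascending order:
    # stationary quiet EMG makes many windows statistically equivalent, and
    # preferring the earliest anchors the baseline in the pre-induction rest
    near_min = np.flatnonzero(means <= 1.05 * means.min())
    rest = np.setdiff1d(np.argsort(means, kind="stable"), near_min,
                        assume_unique=False)
    order = np.concatenate([near_min, rest])
    fs_lfp = lfp.sampling_rate
    nperseg = min(int(2 * fs_lfp), int(min_duration * fs_lfp))
    for k in order:
        t0 = emg_power.time_at(int(starts[k]))
        t1 = t0 + min_duration
        seg = lfp.slice(t0, min(t1, lfp.end_time))
        f, pxx = signal.welch(seg.values, fs=fs_lfp, nperseg=nperseg)
        theta = pxx[(f >= THETA_BAND.low) & (f <= THETA_BAND.high)].sum()
        delta = pxx[(f >= DELTA_BAND.low) & (f <= DELTA_BAND.high)].sum()
        if delta > 0 and theta / delta < 1.0:
            return (t0, t1)
    raise ValueError(
        "no qualifying baseline window (theta veto everywhere); "
        "set a manual baseline epoch in the run configuration")


def _runs_from_mask(mask: np.ndarray) -> list:
    """Maximal runs of a boolean mask as (start_idx, end_idx, value)."""
    if mask.size == 0:
        return []
    change = np.flatnonzero(np.diff(mask.astype(np.int8))) + 1
    bounds = np.concatenate([[0], change, [mask.size]])
    return [(int(bounds[i]), int(bounds[i + 1]), bool(mask[bounds[i]]))
            for i in range(bounds.size - 1)]


def classify_behavioral_state(emg_z_power: TimeSeries,
                              params: DetectionParams) -> StateSegments:
    """Label samples active vs immobile/NREM from z-scored EMG power.

    The z trace is smoothed by a moving RMS (``state_smoothing`` window);
    samples above ``emg_state_threshold`` are active. Segments shorter than
    ``min_state_segment`` are merged into their neighbors (shortest first),
    so the output tiles the record with no sub-threshold-length segments.
    """
    fs = emg_z_power.sampling_rate
    w = max(1, int(round(params.state_smoothing * fs)))
    if w % 2 == 0:
        w += 1
    rms = np.sqrt(uniform_filter1d(emg_z_power.values ** 2, size=w, mode="nearest"))
    mask = rms > params.emg_state_threshold
    runs = [[s, e, v] for s, e, v in _runs_from_mask(mask)]
    min_len = int(round(params.min_state_segment * fs))
    while len(runs) > 1:
        lengths = [r[1] - r[0] for r in runs]
        i = int(np.argmin(lengths))
        if lengths[i] >= min_len:
            break
        # absorb the shortest run into its neighbors (flip its label)
        runs[i][2] = not runs[i][2]
        merged = []
        for r in runs:
            if merged and merged[-1][2] == r[2]:
                merged[-1][1] = r[1]
            else:
                merged.append(r)
        runs = merged
    t0 = emg_z_power.start_time
    intervals = [(t0 + s / fs, t0 + e / fs, ACTIVE if v else IMMOBILE)
                 for s, e, v in runs]
    return StateSegments(intervals=intervals)
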