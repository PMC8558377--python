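"""Domain types shared by all analysis stages.

Times are seconds from recording start (0-based). Segment intervals are
half-open ``[start, end)``; ripple start/end are the inclusive instants of
the first and last accepted troughs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "TimeSeries",
    "Recording",
    "BandDefinition",
    "BaselineStats",
    "DetectionParams",
    "RippleEvent",
    "EpilepticEvent",
    "StateSegments",
    "RIPPLE_BAND",
    "SPW_BAND",
    "EMG_BAND",
    "THETA_BAND",
    "DELTA_BAND",
    "LFP_RATE",
    "TEMPERATURE_RATE",
]

#: Electrophysiology sampling rate after preprocessing (Hz).
LFP_RATE = 2048.0
#: Core body temperature sampling rate (Hz).
TEMPERATURE_RATE = 10.0


@dataclass
class TimeSeries:
    """Uniformly sampled signal with declared units.

    Parameters
    ----------
    values : array-like
        Sample values (1-D).
    sampling_rate : float
        Samples per second; must be positive.
    start_time : float
        Time of the first sample in seconds from recording start.
    units : str
        Physical units, e.g. ``"uV"``, ``"degC"``, ``"z"``.
    label : str
        Quantity tag used to match a trace with its baseline statistics
        (e.g. ``"ripple-power"``). Empty means untagged.
    """

    values: np.ndarray
    sampling_rate: float
    start_time: float = 0.0
    units: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("TimeSeries values must be 1-D")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be > 0")

    # -- geometry -----------------------------------------------------
    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.n / self.sampling_rate

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n) / self.sampling_rate

    def index_at(self, t: float) -> int:
        """Index of the sample nearest to time ``t`` (clipped to range)."""
        i = int(round((t - self.start_time) * self.sampling_rate))
        return min(max(i, 0), self.n - 1)

    def time_at(self, i: int) -> float:
        return self.start_time + i / self.sampling_rate

    def value_at(self, t: float) -> float:
        """Value of the sample nearest to time ``t``."""
        return float(self.values[self.index_at(t)])

    def slice(self, start: float, end: float) -> "TimeSeries":
        """Samples in the half-open interval ``[start, end)``."""
        i0 = max(0, int(math.ceil((start - self.start_time) * self.sampling_rate - 1e-9)))
        i1 = min(self.n, int(math.ceil((end - self.start_time) * self.sampling_rate - 1e-9)))
        if i1 <= i0:
            raise ValueError(f"empty slice [{start}, {end}) for series of span "
                             f"[{self.start_time}, {self.end_time})")
        return TimeSeries(self.values[i0:i1], self.sampling_rate,
                          start_time=self.time_at(i0), units=self.units, label=self.label)

    def copy_with(self, values: np.ndarray, units: Optional[str] = None,
                  label: Optional[str] = None) -> "TimeSeries":
        return TimeSeries(values, self.sampling_rate, self.start_time,
                          units=self.units if units is None else units,
                          label=self.label if label is None else label)

    def assert_finite(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TimeSeries contains non-finite values")


@dataclass
class BandDefinition:
    """Frequency band with ``0 < low < high``."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(f"invalid band {self.name}: {self.low}-{self.high} Hz")

    def validate_for_rate(self, sampling_rate: float) -> None:
        if self.high >= sampling_rate / 2:
            raise ValueError(
                f"band {self.name} upper edge {self.high} Hz >= Nyquist "
                f"({sampling_rate / 2} Hz)")


RIPPLE_BAND = BandDefinition("ripple", 100.0, 260.0)
SPW_BAND = BandDefinition("spw", 10.0, 20.0)
EMG_BAND = BandDefinition("emg", 200.0, 700.0)
THETA_BAND = BandDefinition("theta", 6.0, 10.0)
DELTA_BAND = BandDefinition("delta", 1.0, 4.0)


@dataclass
class Recording:
    """One session: LFP and EMG channels, temperature trace, annotations."""

    lfp_channels: list
    emg_channels: list
    temperature: TimeSeries
    annotations: dict = field(default_factory=dict)
    subject_id: str = ""
    genotype: str = "WT"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.temperature is None:
            raise ValueError("temperature required")
        chans = list(self.lfp_channels) + list(self.emg_channels)
        if not chans:
            raise ValueError("recording has no electrophysiology channels")
        rate = chans[0].sampling_rate
        nsamp = chans[0].n
        for name, ch in self.iter_channels():
            if ch.sampling_rate != rate or ch.n != nsamp:
                raise ValueError(
                    f"channel-length mismatch: {name} has "
                    f"({ch.n} samples @ {ch.sampling_rate} Hz), expected "
                    f"({nsamp} @ {rate} Hz)")
        # temperature span must cover the electrophysiology span
        # (allow one temperature sample of slack at the tail)
        slack = 1.0 / self.temperature.sampling_rate + 1e-9
        if (self.temperature.start_time > chans[0].start_time + 1e-9
                or self.temperature.end_time + slack < chans[0].end_time):
            raise ValueError("temperature trace does not cover the recording span")
        if self.genotype not in ("WT", "DS"):
            raise ValueError(f"unknown genotype {self.genotype!r}")

    def iter_channels(self):
        for i, ch in enumerate(self.lfp_channels):
            yield f"lfp{i}", ch
        for i, ch in enumerate(self.emg_channels):
            yield f"emg{i}", ch

    @property
    def sampling_rate(self) -> float:
        return self.lfp_channels[0].sampling_rate

    @property
    def duration(self) -> float:
        return self.lfp_channels[0].duration


@dataclass
class BaselineStats:
    """Mean/SD of a quantity over a reference quiet (NREM-like) epoch.

    These anchor every z-scored trace: ``z(t) = (f(t) - mean) / sd``.
    """

    mean: float
    sd: float
    epoch: tuple
    quantity_tag: str

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError("baseline sd must be > 0 (constant epoch?)")
        if self.epoch[1] <= self.epoch[0]:
            raise ValueError("baseline epoch must have positive duration")


@dataclass
class DetectionParams:
    """Thresholds and windows for every detection stage.

    All z thresholds are in baseline-SD units; windows in the units noted.
    """

    ripple_power_threshold: float = 3.0      # z
    spike_amp_threshold: float = 1.0         # z
    spike_deriv_threshold: float = 5.0       # z
    emg_state_threshold: float = 1.5         # z, paper allows 1-2
    cycle_period_min: float = 4.0            # ms
    cycle_period_max: float = 10.0           # ms
    emg_window: float = 100.0                # ms
    emg_ratio_threshold: float = 2.0
    alignment_temperature: float = 38.5      # degC
    max_temperature: float = 40.0            # degC
    spw_split_temperature: float = 38.0      # degC

    # -- derived/implementation parameters --------------------------------
    envelope_threshold: float = 0.5          # z, candidate boundary extension
    merge_gap: float = 0.020                 # s, candidate merge gap
    power_smoothing: float = 0.020           # s, detection-power moving average
    min_troughs: int = 4                     # = 3 cycles
    min_event_duration: float = 0.030        # s, first-to-last trough span
    interval_tolerance: float = 2.5e-5       # s, guard on cycle bounds
    spike_dead_time: float = 0.100           # s
    state_smoothing: float = 0.200           # s, EMG moving RMS
    min_state_segment: float = 2.0           # s; exploration bouts last seconds,
                                             # myoclonic EMG bursts must not count
    baseline_min_duration: float = 60.0      # s
    burst_max_gap: float = 0.200             # s
    artifact_emg_sustain: float = 0.250      # s
    artifact_emg_lead: float = 0.100         # s, EMG run must begin this early
    artifact_emg_smoothing: float = 0.050    # s, EMG smoothing for the rule
    artifact_coincidence: float = 0.010      # s
    ripple_morphology_amp: float = 8.0       # z, spike-vs-ripple morphology split
    artifact_min_amplitude: float = 4.0      # z, morphology floor for true spikes
    gtc_power_threshold: float = 5.0         # z
    gtc_min_duration: float = 5.0            # s
    gtc_guard: float = 2.0                   # s excluded around GTC
    gtc_smoothing: float = 0.5               # s

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = [
            "ripple_power_threshold", "spike_amp_threshold",
            "spike_deriv_threshold", "emg_state_threshold",
            "cycle_period_min", "cycle_period_max", "emg_window",
            "emg_ratio_threshold", "alignment_temperature", "max_temperature",
            "spw_split_temperature",
        ]
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not self.cycle_period_min < self.cycle_period_max:
            raise ValueError("cycle_period_min must be < cycle_period_max")
        if not 1.0 <= self.emg_state_threshold <= 2.0:
            raise ValueError("emg_state_threshold must lie in [1, 2]")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "DetectionParams":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise ValueError(f"unknown DetectionParams keys: {sorted(unknown)}")
        return cls(**known)


@dataclass
class RippleEvent:
    """One detected SPW-R complex."""

    start: float                 # s, first trough
    end: float                   # s, last trough
    trough_times: np.ndarray
    peak_times: np.ndarray
    frequency: float             # Hz, internal ripple frequency
    ripple_power_avg: float      # z
    ripple_power_max: float      # z
    spw_power_avg: float         # z
    spw_power_max: float         # z
    temperature: float           # degC at event start
    burst_id: Optional[int] = None

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


EVENT_CLASSES = ("interictal_spike", "myoclonic", "artifact", "gtc")


@dataclass
class EpilepticEvent:
    """One detected epileptiform discharge."""

    trough_time: float           # s, aligned to the largest-|z| extremum
    event_class: str = "interictal_spike"
    amplitude: float = float("nan")        # z, signed
    emg_power_pre: Optional[float] = None  # z
    emg_power_post: Optional[float] = None # z
    emg_ratio: Optional[float] = None
    temperature: float = float("nan")      # degC

    def __post_init__(self) -> None:
        if self.event_class not in EVENT_CLASSES:
            raise ValueError(f"unknown event class {self.event_class!r}")


ACTIVE = "active"
IMMOBILE = "immobile_nrem"


@dataclass
class StateSegments:
    """Behavioral-state intervals tiling ``[0, duration)``.

    ``intervals`` is an ordered list of ``(start, end, label)`` with labels
    in ``{"active", "immobile_nrem"}``.
    """

    intervals: list

    def __post_init__(self) -> None:
        prev_end = None
        for start, end, label in self.intervals:
            if label not in (ACTIVE, IMMOBILE):
                raise ValueError(f"unknown state label {label!r}")
            if end <= start:
                raise ValueError("state segment with non-positive duration")
            if prev_end is not None and abs(start - prev_end) > 1e-9:
                raise ValueError("state segments must tile the record")
            prev_end = end

    def label_at(self, t: float) -> str:
        for start, end, label in self.intervals:
            if start <= t < end:
                return label
        # clamp to the final segment for t == duration
        return self.intervals[-1][2]

    def intervals_with(self, label: str) -> list:
        return [(s, e) for s, e, lab in self.intervals if lab == label]

    def active_intervals(self) -> list:
        return self.intervals_with(ACTIVE)

    def immobile_intervals(self) -> list:
        return self.intervals_with(IMMOBILE)

    def overlaps_active(self, start: float, end: float) -> bool:
        for s, e in self.active_intervals():
            if start < e and end > s:
                return True
        return False

    @property
    def duration(self) -> float:
        return self.intervals[-1][1]


def intersect_intervals(a: Sequence, b: Sequence) -> list:
    """Pairwise intersection of two ordered interval lists."""
    out = []
    for s1, e1 in a:
        for s2, e2 in b:
            s, e = max(s1, s2), min(e1, e2)
            if e > s:
                out.append((s, e))
    return sorted(out)


def replace_event(event, **kwargs):
    """dataclasses.replace re-exported for callers building modified events."""
    return replace(event, **kwargs)
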