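"""Ground-truth-annotated synthetic thermal-induction sessions.

The generator emulates the statistical structure the analysis assumes: pink
(1/f) background LFP, SPW-R complexes (a Gaussian-windowed 10-20 Hz sharp
wave with a superimposed Gaussian-enveloped ripple oscillation) whose rate
and internal frequency depend on core temperature, genotype presets (slower
DS ripples, a non-monotonic DS rate profile peaking at 37.5 degC, rising DS
SPW amplitude >= 38 degC), interictal spikes and myoclonic spikes with EMG
bursts above their onset temperatures, a terminal generalized tonic-clonic
event, post-event SPW-R suppression, and movement epochs with artifacts.

All randomness flows from a single session seed through a SeedSequence
spawn (temperature / schedule / render streams), so a fixed seed reproduces
a session bit-exactly. Free parameters that the study does not print (ramp
rate, SNR, burst-follower distribution, suppression multipliers, frequency
slope) carry defaults chosen so detection-recovery invariants hold; each is
marked "free" in its field comment.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.fft import irfft, rfft, rfftfreq
from scipy.ndimage import uniform_filter1d

from .core import (
    EMG_BAND,
    LFP_RATE,
    RIPPLE_BAND,
    TEMPERATURE_RATE,
    EpilepticEvent,
    Recording,
    RippleEvent,
    TimeSeries,
)
from .preprocess import bandpass_zero_phase

__all__ = [
    "GenotypePreset",
    "GroundTruth",
    "GroundTruthRecord",
    "EventSchedule",
    "DetectionScore",
    "wt_preset",
    "ds_preset",
    "generate_temperature_profile",
    "generate_constant_profile",
    "sample_event_times",
    "render_session",
    "simulate_session",
    "simulate_baseline",
    "simulate_cohort",
    "evaluate_detection",
]


@dataclass
class GenotypePreset:
    """Generator parameterization for one genotype.

    Temperature-dependent quantities are exposed as methods (``spwr_rate``,
    ``ripple_freq``, ...). Printed study values parameterize the defaults of
    :func:`wt_preset` / :func:`ds_preset`; everything else is a free
    parameter of the simulator.
    """

    label: str                                  # "WT" | "DS"
    ripple_freq_at_36c: float                   # Hz (WT 175, DS 135)
    ripple_freq_slope: float = 8.0              # Hz/degC (free)
    spwr_rate_36: float = 0.30                  # events/s at 36 degC (free)
    spwr_rate_peak: float = 0.75                # events/s at the DS peak (free)
    spwr_peak_temp: Optional[float] = None      # degC; None = monotone (WT)
    spwr_peak_sigma: float = 0.45               # degC, width of the DS bump (free)
    spwr_rate_slope: float = 0.10               # events/s/degC, WT monotone (free)
    spw_amp_step_temperature: Optional[float] = None  # degC (DS 38)
    spw_amp_step_gain: float = 2.0              # amplitude multiplier (free)
    spike_onset_temp: Optional[float] = None    # degC (DS 37.8)
    spike_rate: float = 0.40                    # events/s above onset (free)
    mc_onset_temp: Optional[float] = None       # degC (DS 38.8)
    mc_rate: float = 0.50                       # events/s above onset (free)
    gtc_temp: Optional[float] = None            # degC (DS 38.9)
    gtc_duration: float = 15.0                  # s (free, within 10-20 s)
    post_spike_suppression: Tuple[float, float] = (1.0, 0.2)   # (s, keep prob)
    post_gtc_suppression: Tuple[float, float] = (60.0, 0.05)   # (s, keep prob)
    emg_burst_amp: float = 8.0                  # x EMG background SD (free)
    emg_burst_duration: float = 0.150           # s (free)
    noise_exponent: float = 1.0                 # 1/f^a LFP background (free)
    noise_amplitude_uv: float = 50.0            # broadband 1/f SD, uV (free)
    noise_white_uv: float = 10.0                # wideband electrode noise SD (free)
    emg_noise_uv: float = 20.0                  # EMG background SD, uV (free)
    ripple_snr: float = 8.0                     # peak amp / ripple-band SD (free)
    ripple_env_sigma: float = 0.016             # s, ripple Gaussian envelope (free)
    spw_amp_uv: float = 160.0                   # uV, SPW deflection (free)
    spw_sigma: float = 0.020                    # s, SPW envelope (free)
    spike_amp_uv: float = 800.0                 # uV (free)
    spike_tau: float = 0.003                    # s, spike sharpness (free)
    freq_jitter_sd: float = 2.0                 # Hz, per-event (free)
    ramp_rate: float = 0.5 / 60.0               # degC/s (free; study says "slowly")
    baseline_duration: float = 180.0            # s at 36 degC (free)
    cooling_duration: float = 120.0             # s (free)
    max_temperature: float = 40.0               # degC cap (WT ramp end)
    follower_probs: Tuple[float, ...] = (0.4, 0.3, 0.2, 0.1)  # 0-3 followers (free)
    n_lfp_channels: int = 2
    contra_gain: float = 0.7                    # event gain on the 2nd channel

    def __post_init__(self) -> None:
        if self.label not in ("WT", "DS"):
            raise ValueError("label must be WT or DS")
        onsets = (self.spike_onset_temp, self.mc_onset_temp, self.gtc_temp)
        if self.label == "WT" and any(v is not None for v in onsets):
            raise ValueError("WT preset must have no spike/MC/GTC onsets")
        if self.label == "DS":
            s, m, g = onsets
            if None in onsets or not (s < m <= g):
                raise ValueError("DS onset ordering must be spike < MC <= GTC")
        for r in (self.spwr_rate_36, self.spwr_rate_peak, self.spike_rate, self.mc_rate):
            if r < 0:
                raise ValueError("rates must be >= 0")

    # -- temperature-dependent profiles ------------------------------------
    def spwr_rate(self, temp: Union[float, np.ndarray]) -> np.ndarray:
        temp = np.asarray(temp, dtype=float)
        if self.spwr_peak_temp is None:
            rate = self.spwr_rate_36 + self.spwr_rate_slope * (temp - 36.0)
        else:
            bump = self.spwr_rate_peak - self.spwr_rate_36
            rate = self.spwr_rate_36 + bump * np.exp(
                -0.5 * ((temp - self.spwr_peak_temp) / self.spwr_peak_sigma) ** 2)
        return np.maximum(rate, 0.0)

    def spike_rate_at(self, temp: Union[float, np.ndarray]) -> np.ndarray:
        temp = np.asarray(temp, dtype=float)
        if self.spike_onset_temp is None:
            return np.zeros_like(temp)
        return np.where(temp >= self.spike_onset_temp, self.spike_rate, 0.0)

    def mc_rate_at(self, temp: Union[float, np.ndarray]) -> np.ndarray:
        temp = np.asarray(temp, dtype=float)
        if self.mc_onset_temp is None:
            return np.zeros_like(temp)
        return np.where(temp >= self.mc_onset_temp, self.mc_rate, 0.0)

    def ripple_freq(self, temp: Union[float, np.ndarray]) -> np.ndarray:
        f = self.ripple_freq_at_36c + self.ripple_freq_slope * \
            (np.asarray(temp, dtype=float) - 36.0)
        return np.clip(f, 100.0, 250.0)

    def to_dict(self) -> dict:
        return asdict(self)


def wt_preset(**overrides) -> GenotypePreset:
    """Wildtype: 175 Hz ripples at 36 degC, monotone rate, no epileptic events."""
    return GenotypePreset(label="WT", ripple_freq_at_36c=175.0, **overrides)


def ds_preset(**overrides) -> GenotypePreset:
    """Dravet model: 135 Hz ripples at 36 degC, rate peak at 37.5 degC, SPW
    amplitude step >= 38 degC, onsets 37.8 (spikes) / 38.8 (MC) / 38.9 (GTC)."""
    defaults = dict(
        label="DS",
        ripple_freq_at_36c=135.0,
        spwr_peak_temp=37.5,
        spw_amp_step_temperature=38.0,
        spike_onset_temp=37.8,
        mc_onset_temp=38.8,
        gtc_temp=38.9,
    )
    defaults.update(overrides)
    return GenotypePreset(**defaults)


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthRecord:
    type: str                    # spwr | interictal_spike | myoclonic | gtc
    time: float                  # s (waveform center for ripples)
    frequency: float = float("nan")   # Hz, ripples only
    spw_amplitude: float = float("nan")  # uV, ripples only
    temperature: float = float("nan")    # degC at injection


@dataclass
class GroundTruth:
    records: List[GroundTruthRecord] = field(default_factory=list)

    def times_of(self, kind: str) -> np.ndarray:
        return np.array([r.time for r in self.records if r.type == kind])

    def of_type(self, kind: str) -> List[GroundTruthRecord]:
        return [r for r in self.records if r.type == kind]

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame([asdict(r) for r in self.records])

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")


@dataclass
class EventSchedule:
    """Injected-event schedule prior to waveform rendering."""

    ripples: List[Tuple[float, float, float]]   # (time, freq Hz, spw amp uV)
    spikes: List[float]
    mcs: List[float]
    gtc_onset: Optional[float]
    active_epochs: List[Tuple[float, float]]


# ---------------------------------------------------------------------------
# Temperature profiles
# ---------------------------------------------------------------------------

def _jitter(rng, n, amplitude=0.02, smooth=51):
    return amplitude * uniform_filter1d(rng.standard_normal(n), size=smooth,
                                        mode="nearest") * np.sqrt(smooth)


def generate_temperature_profile(preset: GenotypePreset, seed) -> TimeSeries:
    """Plateau at 36 degC, linear ramp to the terminal temperature (GTC
    temperature for DS, the 40 degC cap for WT), then exponential cooling."""
    rng = np.random.default_rng(seed)
    fs = TEMPERATURE_RATE
    end_temp = preset.gtc_temp if preset.gtc_temp is not None else preset.max_temperature
    # overshoot the nominal ramp so the jittered trace is guaranteed to cross
    # the terminal temperature; the ramp is truncated at the first crossing
    ramp_dur = (end_temp + 0.08 - 36.0) / preset.ramp_rate
    n_base = int(round(preset.baseline_duration * fs))
    n_ramp = int(round(ramp_dur * fs))
    n_cool = int(round(preset.cooling_duration * fs))
    base = np.full(n_base, 36.0)
    ramp = 36.0 + preset.ramp_rate * np.arange(1, n_ramp + 1) / fs
    body = np.concatenate([base, ramp]) + _jitter(rng, n_base + n_ramp)
    crossed = np.flatnonzero(body[n_base:] >= end_temp)
    cut = n_base + (int(crossed[0]) if crossed.size else n_ramp - 1)
    body = body[:cut + 1]
    peak = body[-1]
    cool = peak - (peak - 35.5) * (1 - np.exp(-np.arange(1, n_cool + 1) / fs / 180.0))
    cool = cool + _jitter(rng, n_cool)
    temp = np.concatenate([body, cool])
    return TimeSeries(temp, fs, units="degC", label="temperature")


def generate_constant_profile(temp_c: float, duration: float, seed) -> TimeSeries:
    """Constant-temperature plateau (baseline recordings)."""
    rng = np.random.default_rng(seed)
    n = int(round(duration * TEMPERATURE_RATE))
    values = np.full(n, float(temp_c)) + _jitter(rng, n)
    return TimeSeries(values, TEMPERATURE_RATE, units="degC", label="temperature")


# ---------------------------------------------------------------------------
# Event schedule
# ---------------------------------------------------------------------------

def _poisson_times(rng, rate_fn, temperature: TimeSeries, t_max: float) -> np.ndarray:
    """Inhomogeneous Poisson via thinning against the profile maximum."""
    rates = np.asarray(rate_fn(temperature.values), dtype=float)
    rmax = float(rates.max(initial=0.0))
    if rmax <= 0:
        return np.array([])
    n = rng.poisson(rmax * t_max)
    times = np.sort(rng.uniform(0.0, t_max, size=n))
    idx = np.minimum((times * temperature.sampling_rate).astype(int), rates.size - 1)
    keep = rng.uniform(size=n) < rates[idx] / rmax
    return times[keep]


def _enforce_min_gap(times: np.ndarray, gap: float) -> np.ndarray:
    out = []
    for t in times:
        if not out or t - out[-1] >= gap:
            out.append(t)
    return np.asarray(out)


def _mask_near(times: np.ndarray, centers: Sequence[float], before: float,
               after: float) -> np.ndarray:
    drop = np.zeros(times.size, dtype=bool)
    for c in centers:
        drop |= (times >= c - before) & (times <= c + after)
    return ~drop


def sample_event_times(preset: GenotypePreset, temperature: TimeSeries,
                       seed, include_movement: bool = True) -> EventSchedule:
    """Draw the injected-event schedule from the preset's rate profiles.

    SPW-R seed events follow an inhomogeneous Poisson process driven by the
    temperature-dependent rate; each seed spawns 0-3 burst followers at
    80-200 ms gaps. Spikes and myoclonic events are Poisson above their onset
    temperatures (pre-ictal only); the GTC sits at the first crossing of the
    preset's GTC temperature. SPW-R intensity is multiplicatively suppressed
    after spikes/MC and deeply after the GTC.
    """
    rng = np.random.default_rng(seed)
    duration = temperature.duration
    edge = 2.0

    # --- GTC ---------------------------------------------------------------
    gtc_onset = None
    if preset.gtc_temp is not None:
        above = np.flatnonzero(temperature.values >= preset.gtc_temp)
        if above.size:
            gtc_onset = temperature.time_at(int(above[0]))
    pre_ictal_end = gtc_onset - 1.0 if gtc_onset is not None else duration

    # --- movement/artifact epochs in the baseline plateau --------------------
    active_epochs: List[Tuple[float, float]] = []
    if include_movement and preset.baseline_duration >= 120.0:
        start = rng.uniform(20.0, 40.0)
        active_epochs.append((start, start + rng.uniform(15.0, 25.0)))
        start2 = rng.uniform(90.0, 110.0)
        active_epochs.append((start2, start2 + rng.uniform(10.0, 20.0)))

    # --- epileptic events ----------------------------------------------------
    spikes = _poisson_times(rng, preset.spike_rate_at, temperature, duration)
    mcs = _poisson_times(rng, preset.mc_rate_at, temperature, duration)
    spikes = spikes[(spikes > edge) & (spikes < pre_ictal_end)]
    mcs = mcs[(mcs > edge) & (mcs < pre_ictal_end)]
    merged = sorted([(t, "s") for t in spikes] + [(t, "m") for t in mcs])
    kept, last = [], -np.inf
    for t, kind in merged:
        if t - last >= 0.3:
            kept.append((t, kind))
            last = t
    spikes = np.array([t for t, k in kept if k == "s"])
    mcs = np.array([t for t, k in kept if k == "m"])
    epileptic_all = np.sort(np.concatenate([spikes, mcs]))

    # --- SPW-R seeds + burst followers ---------------------------------------
    mean_followers = float(np.dot(preset.follower_probs,
                                  np.arange(len(preset.follower_probs))))
    seeds = _poisson_times(
        rng, lambda T: preset.spwr_rate(T) / (1.0 + mean_followers),
        temperature, duration)
    seeds = _enforce_min_gap(seeds, 0.4)
    ripple_times = []
    for t in seeds:
        ripple_times.append(t)
        k = rng.choice(len(preset.follower_probs), p=preset.follower_probs)
        cur = t
        for _ in range(int(k)):
            cur = cur + rng.uniform(0.10, 0.20)
            ripple_times.append(cur)
    ripple_times = np.sort(np.asarray(ripple_times))
    ripple_times = ripple_times[(ripple_times > edge) & (ripple_times < duration - edge)]

    # suppression thinning around epileptic events
    if epileptic_all.size:
        sup_dur, keep_p = preset.post_spike_suppression
        hard = _mask_near(ripple_times, epileptic_all, before=0.15, after=0.15)
        in_sup = ~_mask_near(ripple_times, epileptic_all, before=-0.15, after=sup_dur)
        survive = hard & (~in_sup | (rng.uniform(size=ripple_times.size) < keep_p))
        ripple_times = ripple_times[survive]
    if gtc_onset is not None:
        sup_dur, keep_p = preset.post_gtc_suppression
        gtc_end = gtc_onset + preset.gtc_duration
        hard = _mask_near(ripple_times, [gtc_onset], before=1.0,
                          after=preset.gtc_duration + 1.0)
        in_sup = (ripple_times > gtc_end) & (ripple_times <= gtc_end + sup_dur)
        survive = hard & (~in_sup | (rng.uniform(size=ripple_times.size) < keep_p))
        ripple_times = ripple_times[survive]
    for s, e in active_epochs:
        ripple_times = ripple_times[(ripple_times < s - 0.5) | (ripple_times > e + 0.5)]

    # per-event frequency and SPW amplitude
    ripples = []
    for t in ripple_times:
        temp_here = temperature.value_at(t)
        freq = float(np.clip(preset.ripple_freq(temp_here)
                             + rng.normal(0.0, preset.freq_jitter_sd), 100.0, 250.0))
        amp = preset.spw_amp_uv * rng.lognormal(0.0, 0.15)
        if (preset.spw_amp_step_temperature is not None
                and temp_here >= preset.spw_amp_step_temperature):
            amp *= preset.spw_amp_step_gain
        ripples.append((float(t), freq, float(amp)))

    return EventSchedule(ripples=ripples, spikes=list(spikes), mcs=list(mcs),
                         gtc_onset=gtc_onset, active_epochs=active_epochs)


# ---------------------------------------------------------------------------
# Waveform rendering
# ---------------------------------------------------------------------------

def _pink_noise(rng, n: int, exponent: float, sd: float) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = rfft(white)
    freqs = rfftfreq(n, 1.0)
    shape = np.ones_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    shape[0] = 0.0
    x = irfft(spec * shape, n)
    return x * (sd / np.std(x))


def _add_wave(buf: np.ndarray, fs: float, center: float, wave: np.ndarray) -> None:
    half = wave.size // 2
    c = int(round(center * fs))
    i0, i1 = c - half, c - half + wave.size
    w0 = max(0, -i0)
    w1 = wave.size - max(0, i1 - buf.size)
    if w1 <= w0:
        return
    buf[max(i0, 0):min(i1, buf.size)] += wave[w0:w1]


def _ripple_wave(fs, freq, amp, env_sigma):
    tt = np.arange(-3 * env_sigma, 3 * env_sigma, 1.0 / fs)
    return -amp * np.exp(-0.5 * (tt / env_sigma) ** 2) * np.cos(2 * np.pi * freq * tt)


def _spw_wave(fs, amp, sigma):
    tt = np.arange(-3 * sigma, 3 * sigma, 1.0 / fs)
    return -amp * np.exp(-0.5 * (tt / sigma) ** 2) * np.cos(2 * np.pi * 15.0 * tt)


def _spike_wave(fs, amp, tau):
    tt = np.arange(-5 * tau, 5 * tau, 1.0 / fs)
    return -amp * (tt / tau) * np.exp(0.5 - 0.5 * (tt / tau) ** 2)


def render_session(schedule: EventSchedule, preset: GenotypePreset, seed,
                   temperature: TimeSeries,
                   annotate_gtc: bool = False) -> Tuple[Recording, GroundTruth]:
    """Render a schedule into LFP/EMG channels plus the ground-truth ledger."""
    rng = np.random.default_rng(seed)
    fs = LFP_RATE
    n = int(round(temperature.duration * fs))

    lfp = [_pink_noise(rng, n, preset.noise_exponent, preset.noise_amplitude_uv)
           + rng.standard_normal(n) * preset.noise_white_uv
           for _ in range(preset.n_lfp_channels)]
    emg = rng.standard_normal(n) * preset.emg_noise_uv

    # ripple amplitude calibrated against the ripple-band SD of the background
    probe = TimeSeries(lfp[0][:int(30 * fs)], fs, units="uV")
    band_sd = float(np.std(bandpass_zero_phase(probe, RIPPLE_BAND).values))
    ripple_amp = preset.ripple_snr * band_sd

    truth = GroundTruth()
    gains = [1.0 if i == 0 else preset.contra_gain
             for i in range(preset.n_lfp_channels)]

    for t, freq, spw_amp in schedule.ripples:
        rw = _ripple_wave(fs, freq, ripple_amp, preset.ripple_env_sigma)
        sw = _spw_wave(fs, spw_amp, preset.spw_sigma)
        for ch, g in zip(lfp, gains):
            _add_wave(ch, fs, t, g * rw)
            _add_wave(ch, fs, t, g * sw)
        truth.records.append(GroundTruthRecord(
            "spwr", t, frequency=freq, spw_amplitude=spw_amp,
            temperature=temperature.value_at(t)))

    spike = _spike_wave(fs, preset.spike_amp_uv, preset.spike_tau)
    for t in schedule.spikes:
        for ch, g in zip(lfp, gains):
            _add_wave(ch, fs, t, g * spike)
        truth.records.append(GroundTruthRecord(
            "interictal_spike", t, temperature=temperature.value_at(t)))

    burst_n = int(round(preset.emg_burst_duration * fs))
    for t in schedule.mcs:
        for ch, g in zip(lfp, gains):
            _add_wave(ch, fs, t, g * spike)
        burst = rng.standard_normal(burst_n) * preset.emg_noise_uv * \
            preset.emg_burst_amp * np.hanning(burst_n)
        _add_wave(emg, fs, t + preset.emg_burst_duration / 2, burst)
        truth.records.append(GroundTruthRecord(
            "myoclonic", t, temperature=temperature.value_at(t)))

    if schedule.gtc_onset is not None:
        _render_gtc(lfp, emg, fs, schedule.gtc_onset, preset, rng)
        truth.records.append(GroundTruthRecord(
            "gtc", schedule.gtc_onset,
            temperature=temperature.value_at(schedule.gtc_onset)))

    for s, e in schedule.active_epochs:
        _render_active_epoch(lfp, emg, fs, s, e, preset, rng)

    annotations = {}
    if annotate_gtc and schedule.gtc_onset is not None:
        annotations["gtc_onset"] = schedule.gtc_onset

    recording = Recording(
        lfp_channels=[TimeSeries(ch, fs, units="uV", label=f"lfp{i}")
                      for i, ch in enumerate(lfp)],
        emg_channels=[TimeSeries(emg, fs, units="uV", label="emg0")],
        temperature=temperature,
        annotations=annotations,
        subject_id=f"sim-{preset.label}-{seed}",
        genotype=preset.label,
    )
    truth.records.sort(key=lambda r: r.time)
    return recording, truth


def _render_gtc(lfp, emg, fs, onset, preset, rng):
    from scipy.signal.windows import tukey
    dur = preset.gtc_duration
    n_gtc = int(round(dur * fs))
    tt = np.arange(n_gtc) / fs
    env = tukey(n_gtc, 0.15)  # abrupt electrographic onset, brief tapers
    tonic = 600.0 * env * np.sin(2 * np.pi * 8.0 * tt)
    spike = _spike_wave(fs, 1200.0, preset.spike_tau)
    for ch in lfp:
        _add_wave(ch, fs, onset + dur / 2, tonic)
    t = onset + 0.2
    while t < onset + dur - 0.2:
        for ch in lfp:
            _add_wave(ch, fs, t, spike)
        t += rng.uniform(0.12, 0.20)
    emg_burst = rng.standard_normal(n_gtc) * preset.emg_noise_uv * 8.0 * env
    _add_wave(emg, fs, onset + dur / 2, emg_burst)


def _render_active_epoch(lfp, emg, fs, start, end, preset, rng):
    n_ep = int(round((end - start) * fs))
    tt = np.arange(n_ep) / fs
    ramp = min(1.0, n_ep / fs / 4)
    env = np.ones(n_ep)
    n_ramp = int(ramp * fs)
    if n_ramp > 0:
        env[:n_ramp] = np.linspace(0, 1, n_ramp)
        env[-n_ramp:] = np.linspace(1, 0, n_ramp)
    theta = 80.0 * env * np.sin(2 * np.pi * 7.0 * tt)
    for ch in lfp:
        _add_wave(ch, fs, (start + end) / 2, theta)
    emg_act = rng.standard_normal(n_ep) * preset.emg_noise_uv * 6.0 * env
    _add_wave(emg, fs, (start + end) / 2, emg_act)
    # movement artifacts: fast bilateral deflections inside the epoch
    artifact = _spike_wave(fs, 500.0, 0.005)
    for t in np.linspace(start + 3.0, end - 3.0, 2):
        for ch in lfp:
            _add_wave(ch, fs, t, artifact)


# ---------------------------------------------------------------------------
# Session-level wrappers
# ---------------------------------------------------------------------------

def _spawn(seed) -> list:
    return np.random.SeedSequence(seed).spawn(3)


def simulate_session(preset: GenotypePreset, seed,
                     annotate_gtc: bool = False) -> Tuple[Recording, GroundTruth]:
    """Full thermal-induction session: profile -> schedule -> waveforms."""
    ss_temp, ss_sched, ss_render = _spawn(seed)
    temperature = generate_temperature_profile(preset, ss_temp)
    schedule = sample_event_times(preset, temperature, ss_sched)
    return render_session(schedule, preset, ss_render, temperature,
                          annotate_gtc=annotate_gtc)


def simulate_baseline(preset: GenotypePreset, duration: float,
                      seed) -> Tuple[Recording, GroundTruth]:
    """Constant-36-degC session (no ramp, no epileptic events, no movement)."""
    ss_temp, ss_sched, ss_render = _spawn(seed)
    temperature = generate_constant_profile(36.0, duration, ss_temp)
    schedule = sample_event_times(preset, temperature, ss_sched,
                                  include_movement=False)
    return render_session(schedule, preset, ss_render, temperature)


def simulate_cohort(preset: GenotypePreset, n_sessions: int, base_seed: int,
                    annotate_gtc: bool = False) -> List[Tuple[Recording, GroundTruth]]:
    """n sessions seeded ``base_seed + index`` (reproducible cohorts)."""
    return [simulate_session(preset, base_seed + i, annotate_gtc=annotate_gtc)
            for i in range(n_sessions)]


# ---------------------------------------------------------------------------
# Detection scoring
# ---------------------------------------------------------------------------

@dataclass
class DetectionScore:
    precision: float
    recall: float
    n_truth: int
    n_detected: int
    n_matched: int
    freq_errors: np.ndarray


def _detected_time(ev) -> float:
    if isinstance(ev, RippleEvent):
        return ev.midpoint
    if isinstance(ev, EpilepticEvent):
        return ev.trough_time
    return float(ev)


def evaluate_detection(truth: GroundTruth, detected: Sequence,
                       tolerance: float = 0.025,
                       truth_type: str = "spwr") -> DetectionScore:
    """Greedy one-to-one matching of detections to injected events by time.

    Pairs within ``tolerance`` are matched closest-first. For ripples, the
    matched-pair frequency error distribution (detected - true) is returned.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    records = truth.of_type(truth_type)
    t_truth = np.array([r.time for r in records])
    t_det = np.array([_detected_time(e) for e in detected])
    pairs = []
    for i, tt in enumerate(t_truth):
        close = np.flatnonzero(np.abs(t_det - tt) <= tolerance)
        for j in close:
            pairs.append((abs(t_det[j] - tt), i, int(j)))
    pairs.sort()
    used_t, used_d = set(), set()
    matches = []
    for _, i, j in pairs:
        if i in used_t or j in used_d:
            continue
        used_t.add(i)
        used_d.add(j)
        matches.append((i, j))
    n_matched = len(matches)
    precision = n_matched / t_det.size if t_det.size else float("nan")
    recall = n_matched / t_truth.size if t_truth.size else float("nan")
    freq_errors = []
    for i, j in matches:
        det = detected[j]
        if isinstance(det, RippleEvent) and np.isfinite(records[i].frequency):
            freq_errors.append(det.frequency - records[i].frequency)
    return DetectionScore(precision=precision, recall=recall,
                          n_truth=t_truth.size, n_detected=t_det.size,
                          n_matched=n_matched,
                          freq_errors=np.asarray(freq_errors))
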