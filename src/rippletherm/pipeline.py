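"""End-to-end orchestration: preprocess -> detect -> thermal aggregation.

``analyze_recording`` runs the full single-session chain and returns every
intermediate needed by the aggregation stage; ``run_pipeline`` handles
multi-session cohorts, disk outputs (event tables, bin summaries, statistics
report, run manifest), and deterministic reruns: identical config + seed
produce byte-identical reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import __version__
from .core import (
    EMG_BAND,
    RIPPLE_BAND,
    SPW_BAND,
    DetectionParams,
    EpilepticEvent,
    Recording,
    RippleEvent,
    StateSegments,
    TimeSeries,
    intersect_intervals,
)
from .epileptic import (
    classify_events,
    detect_spike_candidates,
    gtc_extent,
    lfp_derivative,
    locate_gtc,
    reject_artifacts,
)
from .io import read_session, write_events
from .preprocess import (
    bandpass_zero_phase,
    classify_behavioral_state,
    compute_baseline_stats,
    default_taps,
    instantaneous_power,
    select_baseline_epoch,
    smooth_moving_average,
    zscore,
)
from .ripples import detect_ripples, group_burst_complexes
from .synth import ds_preset, simulate_session, wt_preset
from .thermal import (
    dwell_and_rate,
    feature_by_temperature,
    onset_temperatures,
    pearson_trend,
    pre_post_rate_test,
    spw_amplitude_split_test,
    grand_average,
)

logger = logging.getLogger("rippletherm")

__all__ = ["RunConfig", "SessionResult", "analyze_recording", "run_pipeline"]


@dataclass
class RunConfig:
    """Run configuration; JSON keys map 1:1 to these fields."""

    input_paths: List[str] = field(default_factory=list)
    preset: Optional[str] = None         # "WT" | "DS" when simulating
    n_sessions: int = 1
    seed: int = 1
    out_dir: str = "rippletherm-out"
    params: DetectionParams = field(default_factory=DetectionParams)
    baseline_epoch: Optional[Tuple[float, float]] = None
    annotate_gtc: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.preset is None and not self.input_paths:
            raise ValueError("config needs input_paths or a simulation preset")
        if self.preset is not None and self.preset not in ("WT", "DS"):
            raise ValueError("preset must be WT or DS")
        self.params.validate()

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = json.load(fh)
        if "params" in d:
            d["params"] = DetectionParams.from_dict(d["params"])
        if d.get("baseline_epoch") is not None:
            d["baseline_epoch"] = tuple(d["baseline_epoch"])
        return cls(**d)

    def to_dict(self) -> dict:
        return {
            "input_paths": list(self.input_paths),
            "preset": self.preset,
            "n_sessions": self.n_sessions,
            "seed": self.seed,
            "out_dir": self.out_dir,
            "params": self.params.to_dict(),
            "baseline_epoch": list(self.baseline_epoch) if self.baseline_epoch else None,
            "annotate_gtc": self.annotate_gtc,
            "log_level": self.log_level,
        }


@dataclass
class SessionResult:
    subject_id: str
    genotype: str
    duration: float
    baseline_epoch: Tuple[float, float]
    states: StateSegments
    ripple_events: List[RippleEvent]
    epileptic_events: List[EpilepticEvent]
    gtc_onset: Optional[float]
    gtc_span: Optional[Tuple[float, float]]
    temperature: TimeSeries

    @property
    def clean_epileptic(self) -> List[EpilepticEvent]:
        return [e for e in self.epileptic_events if e.event_class != "artifact"]

    def pre_ictal_immobility(self) -> List[Tuple[float, float]]:
        """Immobile intervals before the GTC (whole record when none)."""
        end = self.gtc_onset - 2.0 if self.gtc_onset is not None else self.duration
        if end <= 0:
            return []
        return intersect_intervals(self.states.immobile_intervals(), [(0.0, end)])


def analyze_recording(recording: Recording, params: Optional[DetectionParams] = None,
                      baseline_epoch: Optional[Tuple[float, float]] = None,
                      overrides=None) -> SessionResult:
    """Run the full detection chain on one session."""
    params = params or DetectionParams()
    lfp = recording.lfp_channels[0]
    emg = recording.emg_channels[0]
    fs = lfp.sampling_rate
    temp = recording.temperature

    # band traces and instantaneous powers
    ripple_band = bandpass_zero_phase(lfp, RIPPLE_BAND)
    spw_band = bandpass_zero_phase(lfp, SPW_BAND)
    emg_band = bandpass_zero_phase(emg, EMG_BAND)
    ripple_power = instantaneous_power(ripple_band)
    ripple_power_sm = smooth_moving_average(ripple_power, params.power_smoothing)
    ripple_power_sm.label = "ripple-power-smoothed"
    spw_power = instantaneous_power(spw_band)
    emg_power = instantaneous_power(emg_band)
    lfp_power = instantaneous_power(lfp)
    deriv = lfp_derivative(lfp)

    if baseline_epoch is None:
        baseline_epoch = select_baseline_epoch(emg_power, lfp,
                                               params.baseline_min_duration)
    logger.info("baseline epoch: %.1f-%.1f s", *baseline_epoch)

    def z_of(series, tag):
        series = series.copy_with(series.values, label=tag)
        stats = compute_baseline_stats(series, baseline_epoch, tag)
        return zscore(series, stats)

    ripple_z_detect = z_of(ripple_power_sm, "ripple-power-smoothed")
    ripple_z = z_of(ripple_power, "ripple-power")
    spw_z = z_of(spw_power, "spw-power")
    emg_z = z_of(emg_power, "emg-power")
    lfp_amp_z = z_of(lfp, "lfp-amplitude")
    deriv_z = z_of(deriv, "lfp-derivative")
    lfp_power_z = z_of(lfp_power, "lfp-power")

    states = classify_behavioral_state(emg_z, params)

    # edge guard: one SPW filter length (the longest kernel used)
    edge_guard = default_taps(SPW_BAND, fs) / fs

    gtc_onset = locate_gtc(recording.annotations, lfp_power_z, emg_z, params)
    gtc_span = None
    if gtc_onset is not None and "gtc_onset" not in recording.annotations:
        gtc_span = gtc_extent(lfp_power_z, emg_z, params)
    elif gtc_onset is not None:
        gtc_span = (gtc_onset, gtc_onset)

    ripple_events = detect_ripples(ripple_band, ripple_z_detect, ripple_z, spw_z,
                                   temp, states, params, edge_guard=edge_guard)
    spike_events = detect_spike_candidates(lfp_amp_z, deriv_z, params,
                                           temperature=temp, edge_guard=edge_guard)
    spike_events = classify_events(spike_events, emg_z, params)

    # secondary-channel z traces for the multi-channel artifact rule
    other_z = []
    for ch in recording.lfp_channels[1:]:
        ch_tagged = ch.copy_with(ch.values, label="lfp-amplitude")
        st = compute_baseline_stats(ch_tagged, baseline_epoch, "lfp-amplitude")
        other_z.append(zscore(ch_tagged, st))
    spike_events = reject_artifacts(spike_events, [lfp_amp_z] + other_z, emg_z,
                                    states, params, overrides=overrides,
                                    ripple_events=ripple_events)

    # a broadband discharge rings in the ripple band: drop SPW-R detections
    # whose span contains a retained epileptiform event
    spike_times = [e.trough_time for e in spike_events
                   if e.event_class in ("interictal_spike", "myoclonic")]
    if spike_times:
        ripple_events = [r for r in ripple_events
                         if not any(r.start - 0.05 <= t <= r.end + 0.05
                                    for t in spike_times)]
        for r in ripple_events:
            r.burst_id = None
        group_burst_complexes(ripple_events, max_gap=params.burst_max_gap)

    # GTC guard: exclude events within +-gtc_guard of the GTC span
    if gtc_span is not None:
        g0 = gtc_span[0] - params.gtc_guard
        g1 = gtc_span[1] + params.gtc_guard
        ripple_events = [e for e in ripple_events if e.end < g0 or e.start > g1]
        spike_events = [e for e in spike_events
                        if e.trough_time < g0 or e.trough_time > g1]

    return SessionResult(
        subject_id=recording.subject_id,
        genotype=recording.genotype,
        duration=recording.duration,
        baseline_epoch=tuple(baseline_epoch),
        states=states,
        ripple_events=ripple_events,
        epileptic_events=spike_events,
        gtc_onset=gtc_onset,
        gtc_span=gtc_span,
        temperature=temp,
    )


# ---------------------------------------------------------------------------
# Cohort aggregation and disk outputs
# ---------------------------------------------------------------------------

def _session_events_with_gtc(res: SessionResult) -> List[EpilepticEvent]:
    events = list(res.clean_epileptic)
    if res.gtc_onset is not None:
        events.append(EpilepticEvent(
            trough_time=res.gtc_onset, event_class="gtc",
            temperature=res.temperature.value_at(res.gtc_onset)))
    return events


def _round(x, nd=6):
    if x is None:
        return None
    if isinstance(x, float) and not np.isfinite(x):
        return None
    return round(float(x), nd)


def aggregate_cohort(results: Sequence[SessionResult],
                     params: DetectionParams) -> dict:
    """Per-subject then grand-average statistics for a cohort."""
    report: dict = {"n_sessions": len(results), "sessions": []}
    rate_bins_by_session = []
    for res in results:
        restrict = res.pre_ictal_immobility()
        bins = dwell_and_rate(res.ripple_events, res.temperature, 0.5,
                              restrict=restrict)
        rate_bins_by_session.append(bins)
        ev_temps = np.array([e.temperature for e in res.ripple_events])
        ev_freqs = np.array([e.frequency for e in res.ripple_events])
        corr = None
        if ev_temps.size >= 3 and np.std(ev_temps) > 0 and np.std(ev_freqs) > 0:
            r, p = pearson_trend(ev_temps, ev_freqs)
            corr = {"r": _round(r), "p": _round(p)}
        report["sessions"].append({
            "subject_id": res.subject_id,
            "genotype": res.genotype,
            "n_ripples": len(res.ripple_events),
            "n_spikes": sum(e.event_class == "interictal_spike"
                            for e in res.clean_epileptic),
            "n_myoclonic": sum(e.event_class == "myoclonic"
                               for e in res.clean_epileptic),
            "n_artifacts": sum(e.event_class == "artifact"
                               for e in res.epileptic_events),
            "gtc_onset": _round(res.gtc_onset),
            "mean_frequency": _round(np.mean(ev_freqs)) if ev_freqs.size else None,
            "freq_temp_pearson": corr,
            "rate_bins": [
                {"center": b.bin_center, "dwell_s": _round(b.dwell_time),
                 "count": b.event_count, "rate": _round(b.rate),
                 "defined": b.defined}
                for b in bins],
        })

    # genotype grand averages of per-subject mean frequencies
    by_geno: dict = {}
    for res in results:
        if res.ripple_events:
            by_geno.setdefault(res.genotype, []).append(
                float(np.mean([e.frequency for e in res.ripple_events])))
    report["genotype_mean_frequency"] = {
        g: dict(zip(("grand_mean", "sem"), map(_round, grand_average(v))))
        for g, v in by_geno.items()}

    # grand-average rate per bin + peak bin
    centers = sorted({b.bin_center for bins in rate_bins_by_session for b in bins
                      if b.defined})
    grand_bins = []
    for c in centers:
        vals = [b.rate for bins in rate_bins_by_session for b in bins
                if b.bin_center == c and b.defined]
        grand_bins.append({"center": c, "rate": _round(np.mean(vals)),
                           "n_sessions": len(vals)})
    report["grand_rate_bins"] = grand_bins
    defined = [g for g in grand_bins if g["rate"] is not None]
    report["rate_peak_bin"] = (max(defined, key=lambda g: g["rate"])["center"]
                               if defined else None)

    onsets = onset_temperatures([_session_events_with_gtc(r) for r in results])
    report["onset_temperatures"] = {
        cls: None if s is None else
        {"mean": _round(s.mean), "sem": _round(s.sem),
         "values": [_round(v) for v in s.values]}
        for cls, s in onsets.items()}

    # SPW-R suppression around spikes (paired pre/post rate)
    per_session = []
    for res in results:
        triggers = [e.trough_time for e in res.clean_epileptic
                    if e.event_class in ("interictal_spike", "myoclonic")]
        if triggers:
            per_session.append(([e.start for e in res.ripple_events], triggers,
                                res.duration))
    if len(per_session) >= 2:
        pp = pre_post_rate_test(per_session)
        report["pre_post_spike_test"] = {
            "t": _round(pp.statistic), "p": _round(pp.pvalue),
            "pre": [_round(v) for v in pp.pre],
            "post": [_round(v) for v in pp.post]}

    try:
        split = spw_amplitude_split_test([r.ripple_events for r in results], params)
        report["spw_split_test"] = {
            "t": _round(split.statistic), "p": _round(split.pvalue),
            "below": [_round(v) for v in split.pre],
            "above": [_round(v) for v in split.post]}
    except (ValueError,):
        report["spw_split_test"] = None
    return report


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured run and write outputs under ``out_dir``."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), "INFO"))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sessions: List[Tuple[Recording, Optional[object]]] = []
    if config.input_paths:
        for p in config.input_paths:
            sessions.append((read_session(p), None))
    else:
        preset = wt_preset() if config.preset == "WT" else ds_preset()
        for i in range(config.n_sessions):
            rec, truth = simulate_session(preset, config.seed + i,
                                          annotate_gtc=config.annotate_gtc)
            sessions.append((rec, truth))

    results = []
    for i, (rec, truth) in enumerate(sessions):
        try:
            res = analyze_recording(rec, config.params,
                                    baseline_epoch=config.baseline_epoch)
        except Exception as exc:  # propagate with stage context
            raise RuntimeError(f"analysis failed for session {i} "
                               f"({rec.subject_id}): {exc}") from exc
        results.append(res)
        write_events(res.ripple_events, out / f"session{i}_ripples.csv")
        if res.epileptic_events:
            write_events(res.epileptic_events, out / f"session{i}_epileptic.csv")
        if truth is not None:
            truth.write_csv(out / f"session{i}_truth.csv")

    report = aggregate_cohort(results, config.params)
    with open(out / "statistics.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    manifest = {"config": config.to_dict(), "version": __version__}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return report
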