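# Methods

This note documents the analysis model, the simulator it is validated
against, the parameters that matter, and the numerical choices made where
the design was genuinely open.

## Signal model and normalization

All electrophysiology is processed at 2048 Hz. Ingest of higher-rate data
applies a polyphase anti-alias low-pass at 1,024 Hz before decimation;
upsampling is refused. Three bands are used throughout: ripple 100–260 Hz,
sharp wave (SPW) 10–20 Hz, EMG 200–700 Hz. Bandpass filters are
Hanning-window FIR kernels of length `next odd ≥ 3 × rate / low-edge`
(~63 taps for the ripple band, ~615 for the SPW band at 2048 Hz), applied
forward–backward so the net phase is zero — event timing must not shift
between bands. Instantaneous power is the squared magnitude of the analytic
(Hilbert) signal.

Every power/amplitude trace is z-scored against the mean and SD of a
reference quiet epoch, which makes thresholds transferable across electrodes
and animals. The baseline epoch is selected automatically as the earliest
60-s window whose mean EMG power is within 5 % of the session minimum and
that passes a theta veto (6–10 Hz power < 1–4 Hz power in the LFP); a manual
epoch can be set in the run configuration. Preferring the earliest
near-minimal window anchors the baseline in pre-induction rest — quiet EMG
is statistically stationary, so pure minimization would land on an arbitrary
quiet window, occasionally mid-ramp where epileptiform events inflate the
baseline SDs. Each quantity (ripple power, SPW power, EMG power, LFP
amplitude, LFP derivative, broadband LFP power) gets its own baseline
statistics; whether amplitude statistics should be reused for the derivative
is an interpretation, and per-quantity statistics are the cleaner reading.

Behavioral state is classified from z-scored EMG power smoothed by a 200-ms
moving RMS: samples above 1.5 z (configurable within 1–2) are *active*,
everything else *immobile/NREM*. Segments shorter than 2 s are merged into
their neighbors, shortest first, so the segments tile the record. The 2-s
floor matters: exploration bouts last many seconds, while myoclonic EMG
bursts (~150 ms, sometimes in pairs) must not masquerade as exploration —
with a sub-second floor, clustered myoclonus becomes "active" and the
events inside it are mislabeled artifacts.

## SPW-R detection

Candidate epochs are maximal regions where the z-scored ripple power exceeds
0.5 that contain at least one sample above 3 SD, merged across gaps < 20 ms;
candidates overlapping active segments, or within one SPW-filter length of
the record edges, are excluded. The 0.5-z boundary extension exists because
events are delimited by their first/last troughs — thresholding alone would
truncate the outer cycles.

Two implementation details stabilize the 3-SD rule. First, the detection
trace is the instantaneous power smoothed by a 20-ms moving average
(feature powers reported per event use the unsmoothed z traces).
Instantaneous power of band-limited Gaussian noise is exponentially
distributed; an unsmoothed 3-SD rule would fire on a fixed fraction of
baseline samples. Second, events whose trough span is shorter than 30 ms are
discarded: no physiological ripple is that brief, and residual noise
crossings are. Even so, the rule's selectivity partly rests on the baseline
epoch containing ripples — they inflate the baseline SD and push the
threshold above the noise tail (the same reason quiet-sleep normalization is
used in the first place). Consequently detection degrades gracefully with
the generator's SNR: precision ≥ 0.97 for SNR ≥ 6, ≈ 0.9 at SNR 5 (SNR =
peak ripple amplitude / ripple-band background SD).

Within each candidate epoch, troughs and peaks of the ripple-bandpassed
trace are located by sign changes of the first difference (ties to the
earlier sample) and refined to sub-sample precision by parabolic
interpolation. Troughs are scanned in order: an inter-trough interval
shorter than 4 ms skips the candidate trough; one longer than 10 ms excludes
that pair from frequency estimation but the scan continues from the new
trough (so a single missed cycle does not discard the event). The interval
bounds carry a ±25 µs numerical guard (~5 % of one sample) so that an
exactly-10-ms spacing, measured on interpolated trough times, is never
rejected by floating-point noise. Events need ≥ 4 accepted troughs and ≥ 3
in-range intervals. Frequency is the reciprocal of the mean of the five
middle in-range intervals (indices ⌊(n−5)/2⌋ … ⌊(n−5)/2⌋+4; the middle
three when the ripple has fewer than six cycles); power features are the
mean and max of the ripple- and SPW-power z traces over [start, end];
the event temperature is the sample nearest the start. Events whose
successive starts are ≤ 200 ms apart are chained into burst complexes.

A known estimator property: under in-band noise the cycle rule is
asymmetric — spuriously inserted troughs create short *valid* intervals
while deletions create > 10 ms intervals that are excluded — so slow ripples
are biased slightly fast (≈ +2–3 Hz at 135 Hz, SNR 8; negligible at
175 Hz, which sits near the band-noise centroid). This is a faithful
consequence of the interval rule, not corrected for.

The 4-ms bound nominally corresponds to 250 Hz although the filter band
extends to 260 Hz; the millisecond bounds are applied literally and the band
is used for filtering only. Oscillations with sub-4-ms periods cannot form
accepted pairs (the skip rule can alias them onto harmonics, but in the full
chain the 100–260 Hz bandpass removes such content before extraction).

## Epileptiform events

Spike candidates are samples that are simultaneously high-amplitude
(|z| > 1) and fast-rising (|derivative z| > 5, derivative = central
difference × rate on the broadband LFP). Thresholds are applied to absolute
values because depth-electrode polarity varies with lamina; events are
aligned to the largest-|z| extremum, and candidates within a 100-ms dead
time collapse to one event.

Myoclonus discrimination: mean normalized EMG power over the 100 ms before
and after the spike; post/pre strictly greater than 2 means myoclonic. Since
z-scored power can be ≤ 0, both means are re-centered by +1 (instantaneous
power of stationary Gaussian noise has mean ≈ SD, so z ≥ −1 and z+1 restores
a nonnegative power-like scale) and floored at 0.01 to avoid division
pathologies. The ratio of normalized powers is invariant to global EMG gain.
Events whose windows cross the record edge are left unclassified with a
warning.

The study's manual review of candidates is replaced by a documented
heuristic (an override file of manual verdicts takes precedence):

1. events inside active-exploration segments are artifacts;
2. coincident supra-threshold deflections on ≥ 2 LFP channels *with* EMG
   elevated for ≥ 250 ms in a run beginning ≥ 100 ms before the event are
   movement artifacts (the lead requirement distinguishes them from
   myoclonus, whose EMG starts at the spike);
3. candidates with |amplitude z| < 4 are "unusual morphology" rejects — a
   deflection within the background range that no reviewer would call a
   discharge (it also removes the rare pure-noise coincidences of the two
   thresholds, which would otherwise corrupt first-event onset
   temperatures);
4. candidates with |amplitude z| < 8 whose trough lies inside a detected
   SPW-R are ripple cycles riding a large sharp wave, not discharges.

Separately, SPW-R detections whose span contains a retained discharge are
dropped: a broadband spike rings in the 100–260 Hz band and otherwise
produces one false ripple per spike.

GTC onset is the annotation when present, otherwise the first epoch where
broadband LFP power z and EMG power z (each smoothed over 0.5 s) jointly
exceed 5 for ≥ 5 s. Detected GTC spans ± 2 s are excluded from all SPW-R and
spike statistics.

## Temperature-resolved aggregation

Bins are `[center − w/2, center + w/2)` with centers at multiples of the
width anchored at 36.0 °C (widths 1, 0.5 and 0.25 °C are used for spectra,
rates and per-event frequencies respectively). Rates divide event counts by
dwell time (temperature samples in the bin / 10 Hz), restricted to pre-ictal
immobility; zero-dwell bins are flagged undefined, never zero-filled.
Spectral peak frequency per 1 °C bin is a Gaussian-plus-offset fit to the
100–260 Hz slice of a Welch spectrum (0.5-s Hanning segments, 50 % overlap)
of concatenated immobility signal (≥ 4 s per bin); "no peak" is declared
when the fitted amplitude is below twice the residual SD. The offset term is
an interpretation (the fit would otherwise chase the 1/f floor).
Concatenating discontiguous segments adds broadband leakage at the seams;
with 0.5-s windows this is negligible relative to the ripple peak.

Alignment uses the GTC onset when one exists, else the first upward crossing
of 38.5 °C. Onset temperature per class is the temperature at the first
event of that class per session, grand-averaged across sessions. Peri-event
SPW-R rate histograms use 250-ms bins normalized by bin width × trigger
count; triggers whose window crosses a record edge are skipped. The
suppression test compares per-session mean rates in [−1, 0) vs (0, +1] s
around discharges with a two-sided paired t-test; the SPW split test
compares per-session mean SPW power below vs ≥ 38 °C the same way. Sigmoid
trends are 4-parameter logistics fitted by least squares, with degenerate
(flat) and non-converged fits flagged rather than fabricated. Pearson R with
α = 0.05 (two-sided) is used for continuous trends; no multiple-testing
correction is applied anywhere. All group statistics are per-subject first,
then grand average ± SEM = sd/√n_subjects.

## Synthetic sessions

The generator emulates the study's recording conditions; all stochastic
draws derive from one session seed via SeedSequence streams (temperature /
schedule / render), so a fixed seed reproduces a session bit-exactly, and
cohorts use seed + index.

**Temperature** (10 Hz): 180 s plateau at 36 °C, linear ramp at 0.5 °C/min
(a free parameter; the protocol is only described as slow), truncated at the
first crossing of the terminal temperature — the GTC temperature for DS
(38.9 °C), the 40 °C cap for WT — then exponential passive cooling, with
±0.02 °C smoothed jitter.

**Events.** SPW-R seeds follow an inhomogeneous Poisson process with the
genotype rate profile — WT: 0.30 events/s at 36 °C rising 0.10 /s/°C;
DS: 0.30 events/s plus a Gaussian bump peaking at 0.75 /s at 37.5 °C
(σ 0.45 °C) — each seed spawning 0–3 burst followers (probabilities
0.4/0.3/0.2/0.1) at 100–200 ms gaps. Interictal spikes and myoclonic events
are Poisson at 0.4 /s and 0.5 /s above their onset temperatures (DS: 37.8
and 38.8 °C; WT has none), pre-ictal only. SPW-R intensity is multiplied by
0.2 for 1 s after each discharge and by 0.05 for 60 s after the GTC, and
ripples are blanked within ±150 ms of discharges and during movement epochs.

**Waveforms** (2048 Hz, 2 LFP channels at gains 1.0/0.7 plus one EMG):
background is 1/f LFP noise (50 µV SD) plus a 10 µV white electrode-noise
floor — the white floor sets a realistic derivative variance, without which
ordinary SPW-R would exceed the 5-SD derivative threshold. A ripple is a
Gaussian-enveloped (σ 16 ms) sinusoid at
`f(T) = f₃₆ + 8 Hz/°C × (T − 36)` clipped to [100, 250] Hz (f₃₆ = 175 Hz WT,
135 Hz DS; the slope is free, chosen so the pre-ictal rise spans ~20 Hz)
with ±2 Hz per-event jitter, at amplitude 8 × the ripple-band background SD
(the SNR definition). The SPW is a Gaussian-windowed 15 Hz deflection
(160 µV lognormal, doubled at ≥ 38 °C in DS). Spikes are derivative-of-
Gaussian transients (800 µV, τ 3 ms); myoclonic spikes add a 150-ms EMG
burst at 8 × EMG background SD starting at the spike peak; the GTC is 15 s
of large 8 Hz tonic oscillation plus polyspikes with sustained EMG; movement
epochs add theta, elevated EMG and bilateral artifacts during the plateau.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: spatially structured multi-unit activity and true
1/f^χ spectral mixtures, ripple-frequency chirp within events, state
transitions other than a binary active/immobile split, REM (absent in the
emulated protocol), electrode drift, and genuine artifact morphology beyond
stereotyped bilateral transients. Recovery results certify the pipeline's
correctness under the stated statistical structure, not detector performance
on arbitrary recordings.

## Problem sizes and verification

The test suite and the acceptance script simulate 900-s baseline recordings
(~250 SPW-R each) for frequency recovery, a 6-session DS cohort (~650 s per
session) for onset/rate/suppression recovery, and 3 WT sessions for the
no-seizure controls; these sizes give per-quantity sampling error well
inside the recovery tolerances while keeping a full run in tens of seconds.
Detection scoring matches events greedily one-to-one within 25 ms
(ripple truth times are envelope centers, compared to detected event
midpoints). Every recovery quantity reported by `scripts/acceptance.py` is
recomputed from fresh simulations at run time.

## Known limitations

- The 3-SD detection rule inherits its selectivity from ripple contamination
  of the baseline epoch; on recordings with very sparse ripples (or SNR ≲ 5)
  precision drops and the ripple-power threshold should be raised or the
  baseline epoch set manually.
- The cycle rule biases slow ripples a few Hz fast under in-band noise (see
  above).
- Artifact review is a heuristic stand-in for expert judgment; the override
  file is the escape hatch.
- `TemperatureBinSummary.rate` assumes the temperature trace samples dwell
  time uniformly (true at a constant 10 Hz).
- EDF ingest trusts channel labels to separate EMG from LFP.
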