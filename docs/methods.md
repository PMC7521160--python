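# Methods

`swripple` implements a complete analysis chain for sharp wave-ripple
(SWR) activity in NREM-sleep intracranial EEG: two bipolar channels
(hippocampus, HPC; amygdala, AMY), sampled nominally at 1 kHz, carrying
sleep-stage annotations in 20-s epochs.  Because clinical recordings of
this kind cannot be redistributed, the package ships a synthetic LFP
generator with full ground truth; every statistical stage is validated
against that ground truth or against analytic null distributions.

## Preprocessing

Channels are high-pass filtered at 0.3 Hz (2nd-order Butterworth) and
notch filtered at 50 Hz and harmonics up to 300 Hz (2nd-order IIR
notches, Q ≈ 35), all zero-phase (forward–backward).  Artifacts are
flagged per channel where the |z| of the first difference (signal
gradient) or of the >250-Hz Hilbert envelope exceeds 6; z statistics
are computed over the whole recording, giving one channel-specific
threshold.  Flags are dilated by 250 ms per side so filter ringing
cannot leak into clean data.  Analysis "trials" are maximal
artifact-free runs of ≥3 s inside contiguous same-stage (N2/N3) epoch
spans.  For cross-channel analyses a sample counts as clean only if it
is clean on both channels (joint mask), which keeps the two channels'
trial grids identical and every cross-site comparison time-aligned.
Artifact rejection runs on the filtered signals.

## Spectra and 1/f adjustment

Power spectral densities use Welch's method per trial (3-s Hann
windows, 80% overlap, zero-padded to 4096 samples at 1 kHz → 0.244-Hz
bins; windows never cross a trial boundary) and are averaged across
trials weighted by trial duration.  To expose narrowband peaks, the
notch-filtered regions (50/100/150/200 ± 5 Hz) are bridged with
modified-Akima interpolation, a power law a·f^b is fitted by ordinary
least squares of log10 power on log10 frequency over 4–175 Hz, and the
fit is subtracted.  The residual is resampled to 200 log-spaced bins
(0.5–200 Hz) and smoothed three times with a centred 5-bin moving
average whose window shrinks at the edges.  The fit range avoids the
low-frequency flattening below ~4 Hz and the interpolated 200-Hz
region; the 200-bin count for the log grid is a package choice (the
resampling itself is part of the procedure, the count is not critical).

## Time–frequency decomposition

Complex Morlet wavelets are parametrized by their temporal FWHM h:
w(t) = exp(i2πft)·exp(−4 ln2 t²/h²), with 50 log-spaced centre
frequencies in [0.5, 200] Hz and h log-spaced from 3 s (0.5 Hz) to
0.025 s (200 Hz).  The spectral FWHM is 4 ln2/(πh): 0.294 Hz and
35.3 Hz at the extremes.  Kernels are truncated where the envelope
falls below 10⁻⁴ of its peak and normalized to unit energy —
normalization cancels in every z-scored quantity downstream.  Trials
are reflection-padded by 5 s per side (tiling the reflection when a
trial is shorter than the pad), convolved via FFT, trimmed, and
downsampled by keeping every 4th sample (the wavelet itself band-limits
magnitude and phase, so no extra anti-alias filter is applied).
Decomposed trials are concatenated in temporal order with a
column→recording-sample map; per stage, the concatenation is cut into
60-s segments (15 000 columns at 250 Hz), discarding the trailing
remainder.  Segments are the unit of connectivity and PAC statistics;
the column map serves the ripple-locked analyses.

## Connectivity

Per 60-s segment and centre frequency, AEC is the Spearman correlation
(tie-corrected ranks) of the two channels' magnitude series, and PLV is
|mean over time of exp(iΔφ)|.  Both are z-scored against n = 100
surrogates obtained by circularly shifting one channel's magnitude or
phase series by a uniform random 1–59 s (one shift per iteration,
applied jointly to all frequencies, preserving the null's
cross-frequency structure; circular shifts preserve the series'
spectrum exactly).  The per-recording summary is the mean z across
segments.

## Phase–amplitude coupling

Coupling between a modulating frequency f1 and a modulated frequency
f2 (admissible when f2 > 2·f1, strict, on centre frequencies) uses the
debiased mean vector length: dPAC = |mean amp_f2·(exp(iφ_f1) − B)|
with B = mean exp(iφ_f1).  Subtracting B removes the spurious coupling
that a nonuniform phase distribution would otherwise produce; the
statistic reduces to the classic mean vector length when phases are
uniform.  Amplitude is the magnitude (not squared power) of the
convolution result.  Same-site grids take phase and amplitude from one
channel; cross-site grids take phase from one structure and amplitude
from the other.  Per segment and pair, dPAC is z-scored against 100
circular time-shifts (1–59 s) of the phase series relative to the
amplitude series (matrix form: one complex matmul per shift).
Significance across segments uses the one-sample cluster-based
permutation test below.  A ripple-band modulation profile summarizes
each grid as the mean dPAC_Z over f2 ∈ [75, 110] Hz per f1 ≤ 85 Hz.

## Ripple detection and surrogates

Channel data are zero-phase FIR band-pass filtered 70–110 Hz with 5-Hz
transition zones (Hamming-window design, ~0.66-s kernel at 1 kHz,
applied forward–backward; linear phase is mandatory before the Hilbert
transform).  The envelope is the magnitude of the analytic signal,
z-scored over the concatenated clean trial samples of the channel.  An
event is seeded wherever z exceeds 2.5 and extended to the surrounding
crossings of 2.0; runs sharing samples merge.  Events must last ≥35 ms
(~3 cycles at 70 Hz) and have 0.76 s of clean same-trial data on each
side of the envelope peak, guaranteeing that the 1.5-s analysis window
and the full 377-column locked TF map fit inside clean data.  Event
properties: duration between the lower-threshold crossings; amplitude
= max |band-passed signal| in the event; main frequency = argmax of the
8× zero-padded FFT of the band-passed event; density = events per clean
minute.  No envelope smoothing is applied: smoothing (10–20 ms was
evaluated) lengthens noise excursions past the 35-ms rule and raises
the false-positive rate more than it helps recall.

For the event-locked null, 1000 surrogate event sets are drawn, each
with as many time points as detected ripples, uniformly from eligible
samples: a full margin inside one trial and ≥1.5 s from every true
ripple peak (no 1.5-s window overlap with real events; surrogate
windows may overlap each other).

At the detector's prescribed operating point, an event whose
band-passed amplitude is exactly 3× the background ripple-band SD has
an expected peak envelope of √(9+2)·σ ≈ 3.3σ against a threshold of
~2.88σ with Rayleigh fluctuation 0.65σ, so roughly a quarter of such
events fall below threshold no matter how the detector is coded;
≥90% recall is reached from about 5× upward.  On Gaussian 1/f
background the intrinsic false-positive rate is ~1.5–2.5 events/min
(a scale-free property of the z-scored envelope).  Both facts are
visible in the acceptance measurements.

## Co-occurrence

A ripple in one channel co-occurs with the other channel when its peak
lies within ±window/2 (closed interval; windows 1500, 500, 100 ms) of
any peak there; rates are the percentage of the first channel's events
with a partner.  Counting is per event of the first channel (several
events may share a partner).  Significance is the proportion of the
1000 surrogate-set rates that reach the observed rate (ties count; a
rate above all surrogates is reported as P < 0.001).  For 100-ms
co-occurrences, signed lags (first channel minus nearest partner, ms)
are tested against zero with a one-sample t-test.

## Ripple-locked analyses

All locked analyses use a 1.5-s window centred on the ripple peak and
share one set of 1000 surrogate event sets per channel, so ERP, power
and ITPC panels rest on the same null.  The ERP averages mean-centred
snippets; its band is the pointwise 2.5–97.5 percentile across
surrogate ERPs.  ERP spectra use Welch with 1.25-s Hann windows at 95%
overlap (hop floored to 63 samples; all full windows averaged),
zero-padded to 2048 samples (0.488-Hz bins), and are z-scored per bin
against the surrogate ERP spectra.  TF power (squared magnitude) is
first z-scored per frequency over all NREM columns of the channel
(pooling N2 and N3), averaged over event-centred windows of ±188
columns (377 columns at 250 Hz; 50 × 377 = 18 850 bins), and z-scored
against the 1000 mean surrogate responses.  ITPC is |mean over events
of the unit phasor| per bin, normalized identically.  Because z values
can be extreme, cluster outlines are drawn at up to 5 evenly spaced
integer z levels between the lowest Z ≥ 3 whose clusters do not span
all frequency rows and the highest Z ≤ 25 still producing a valid
cluster; clusters are 4-connected, sign-homogeneous, and must span ≥2
frequency bins and ≥10 time bins (36 ms).  Cross-site analyses use one
channel's events with the other channel's signal and TF data through
the identical code path.

## Cluster-based permutation test

dPAC_Z grids are compared to zero across segments with one-tailed
one-sample t-tests per pair; bins with p < 0.1 (clusteralpha) form
4-connected clusters of bounding extent ≥2×2; cluster mass is the sum
of t.  The null records the maximum cluster mass under each of 1000
random sign flips of whole segments (exact under a symmetric null);
clusters with mass above the 95th percentile are significant
(one-tailed P < 0.05).  Type-I error of the machinery is verified on
200 null simulations of 30 N(0, 1) 12×12 grids (300 permutations per
run, a problem-size choice for the calibration only).

## Synthetic data generator

The generator emulates what the analyses need to be exercised, not a
biophysical cortex:

- **Background**: Gaussian noise shaped in the frequency domain to an
  exact a·f^b density (default a = 500 µV²/Hz at 1 Hz, b = −2),
  putting the 70–110-Hz band SD near 1.6 µV so that default ripple
  amplitudes sit at a realistic ~4–7× band SD and genuine ripples do
  not trip the gradient-artifact criterion.
- **Ripples**: Hann-enveloped bursts at 80 Hz, rate 5.5/min (HPC) and
  2.6/min (AMY), envelope FWHM 50 ± 8 ms, amplitudes 12 and 6 µV
  defined as the peak of the 70–110-Hz filtered waveform (the filter's
  attenuation of the short burst is pre-compensated) — matching how a
  dual-threshold detector measures duration and amplitude.  Event times
  are Poisson, thinned to ≥200 ms separation.
- **Sharp waves**: each ripple rides one Gaussian-windowed cycle at a
  frequency drawn uniformly from 2–8 Hz, amplitude 50 µV, with the SPW
  phase at the ripple peak fixed by `spw_ripple_phase` (polarity is a
  free parameter, as bipolar referencing makes it arbitrary).
- **Spindles**: waxing–waning 13-Hz bursts, 1 s, 20 µV, 2/min.
- **Co-occurrence**: each HPC ripple spawns an AMY partner with
  probability `cooccurrence_prob` (default 0.2) at a Gaussian lag
  (SD 20 ms); the pairing map is recorded.
- **PAC**: when `pac_depth` > 0 a narrowband stochastic delta
  oscillation (4 Hz centre, 2-Hz spectral FWHM, 25 µV mean envelope) is
  added to both channels and ripple amplitudes are scaled by
  (1 + depth·cos φ_delta).  The modulator is deliberately *not* a pure
  sinusoid: a coherent oscillator's phase survives circular time shifts
  up to a constant rotation, which would make the time-shift surrogate
  null blind to the coupling; a drifting narrowband phase decorrelates
  over ~1/bandwidth ≈ 0.5 s, well inside the ≥1-s shifts.
- **Artifacts**: alternating 2000-µV triangular spikes and 200-ms
  500-µV steps.

All randomness flows through one seeded generator with named
sub-streams, so identical configurations give bit-identical signals
and ground truth.  What the generator does **not** model: nonstationary
sleep depth, epileptiform discharges beyond simple spikes,
multi-channel volume conduction, realistic spindle–SO nesting, or
1/f-knee spectra.  Passing tests therefore demonstrate the
correctness and calibration of the machinery, not clinical
performance on real iEEG.

## Problem sizes

Default test syntheses are 5–6 min (the statistics scale to full
nights without change); null calibrations use 200 runs of 60-s
segment pairs at 500 Hz with a 25×25 subsampled PAC grid; the
acceptance script's null calibration uses 50 runs.  These sizes keep
each property estimable while the whole suite stays desk-scale.

## Known limitations

- Detector recall below ~5× band-SD amplitude is intrinsically limited
  by the prescribed thresholds (see above); no retuning is attempted.
- The 1/f fit assumes a pure power law; spectra with a knee would bias
  a and b.
- The EDF writer covers continuous 2-channel µV recordings with 1-s
  records only.
- Surrogate-normalized statistics assume segments are long relative to
  the signal's autocorrelation; for frequencies below ~0.5 Hz a 60-s
  segment holds few effective samples and z values are noisy.
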