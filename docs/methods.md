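# Methods

This note documents the models, parameters and design choices behind
`lateroflux`: what each stage computes, why its defaults are what they are,
what the synthetic generator does and does not emulate, and where the
numerical edges are.

## Study design and windowing

The package targets bilateral lower-extremity LDF protocols: a baseline of
at least 15 min, a stimulus (here: ingesting 500 mL of saline at 4, 10 or
30 °C over ~5 min), and at least 30 min of post-stimulus recording, with
both legs recorded simultaneously at 64 Hz in arbitrary perfusion units
(PU). Analysis uses four 10-min windows: `Pre` is the last 600 s before the
stimulus (when the baseline is longer than 15 min, the window nearest the
intervention is the conventional choice), and `Post1`–`Post3` tile
[stimulus, stimulus + 1800 s] exactly, with trailing partial samples
truncated so every segment has `600·fs` samples. HRV and EGG endpoints are
computed on the unsegmented 15-min pre and 30-min post records, and so are
the laterality values used in the correlation stage.

The stimulus time is session metadata (a YAML sidecar per subject), not
parsed from the signal: LDF exports carry no standardized in-band event
marker, and declaring it explicitly is robust across vendors. For the same
reason the text reader accepts any tab/comma/semicolon-delimited file with a
declared column layout rather than guessing one vendor dialect; the
canonical dialect the package writes is tab-separated with a header line and
time in seconds at full float precision (so write→read round-trips exactly).

## Laterality index

For each post window,

    LI = mean(|Post_L − Post_R|) / mean(|Pre_L − Pre_R|) × 100.

The index is unsigned — it measures whether the left–right asymmetry grew
(LI > 100) or shrank (LI < 100), not which side drove it. It is scale
invariant (calibration drifts common to both probes cancel) and symmetric
under swapping side labels.

In band mode the index is applied to scalar band-component values, so the
"mean" collapses to a single absolute difference per window; a config option
(`band_statistic="series"`) instead differences the band-averaged amplitude
time series sample-wise before averaging, restricted to cone-of-influence-
free samples. The scalar form is the default because band components are
already time averages; the two variants agree in direction on all synthetic
checks.

A zero denominator (identical sides before the stimulus) yields a flagged
undefined value, not an exception: real LDF noise makes this practically
impossible, but degenerate synthetic inputs must not abort a batch run.
Undefined values are excluded listwise per test family, with counts logged.

In the group ANOVA the within factor has four levels: `Pre`, entered as a
definitional reference level (the baseline window differenced against itself
gives exactly 100), then `Post1`–`Post3`. Without the reference level a
constant post-stimulus asymmetry change would load entirely on the group
main effect and the group × window interaction would be structurally null;
with it, the interaction captures exactly "groups diverge from baseline
differently", which is the scientific question. With 60 subjects in 3
groups this gives the familiar df shapes (2,57), (3,171) and (6,171). The
`Pre` level has zero variance by construction; on null synthetic cohorts the
uncorrected interaction test still rejects at the nominal rate (the pipeline
verifies ~5% over 200 replicates), because all pairwise contrast variances
remain equal (the shared `Pre`-window denominator restores the
Huynh–Feldt condition).

## Wavelet band decomposition

Six conventional microvascular frequency bands are used (Hz, half-open so
contiguous bands stay disjoint on the grid):

| band            | interval        | attribution                  |
|-----------------|-----------------|------------------------------|
| endo_no_indep   | [0.005, 0.0095) | endothelial, NO-independent  |
| endo_no_dep     | [0.0095, 0.02)  | endothelial, NO-dependent    |
| neurogenic      | [0.02, 0.06)    | sympathetic nerve activity   |
| myogenic        | [0.06, 0.15)    | vascular smooth muscle       |
| respiratory     | [0.15, 0.4)     | respiration                  |
| cardiac         | [0.4, 1.6)      | heart beat                   |

The registry's lower bound is 0.005 Hz so that the NO-independent
endothelial band is representable; it is immutable by default and
config-overridable.

The transform is an analytic Morlet filterbank computed in the frequency
domain: the signal is mean-removed, zero-padded to at least twice the next
power of two, its spectrum restricted to positive frequencies (doubled, i.e.
the analytic signal), and multiplied per grid frequency `f_c` by a Gaussian
kernel `exp(−ω₀²/2 · (ω/ω_c − 1)²)` with unit peak gain, ω₀ = 6. This is
the L1-normalized Morlet CWT up to a single amplitude calibration chosen so
a unit-amplitude sinusoid at a grid frequency produces ridge amplitude 1.0
(verified to ±2% against the analytic response and to ±10% against a
periodogram amplitude oracle). ω₀ = 6 is the field-standard compromise
between time and frequency resolution for microvascular LDF work and is
config-exposed.

The frequency grid is log-spaced at 16 voices per octave over the registry
span (~134 points over 0.005–1.6 Hz): uniform relative resolution across
four decades, which a linear grid cannot give.

Edge handling is zero padding plus a cone of influence: at scale
`s = ω₀/(2πf)` samples closer than `√2·s` (the wavelet's e-folding time) to
either edge are excluded from all averages. A band component is the mean
over in-band grid frequencies of the COI-free time-averaged amplitude. A
600-s window holds only ~3–6 cycles of the slowest band and its COI covers
most of the window; those components are still computed (the protocol
applies the analysis there anyway) but carried with `reliable=False`
whenever the COI-free span covers less than one cycle of the band's lower
edge. Consumers must propagate, not drop, this flag.

Because every band lies below 1.6 Hz, `decompose_bands` decimates 64-Hz
input to a 16-Hz working rate first (polyphase FIR, mean-padded so the DC
offset causes no edge roll-off). The decimated path matches the native-rate
path to within 2% and makes a 4-window bilateral session ~16× cheaper.

## HRV

Input is an RR-interval series in ms (R-peak detection from raw ECG is out
of scope; deposited data reach RR via standard HRV software, and the
synthetic generator emits RR directly). Processing per phase (pre = first
15 min, post = next 30 min):

1. **Artifact correction** ("medium" preset): a beat deviating more than
   0.25 s from the 11-beat local median is replaced by cubic-spline
   interpolation over accepted beats. Threshold and window are
   config-exposed; runs with >5% corrected beats carry a quality warning.
2. **Detrending** by smoothness priors: trend = `(I + λ²D₂ᵀD₂)⁻¹ z` with D₂
   the second-difference operator and λ = 500 (a time-varying high-pass
   with cutoff well below the vagal band at normal heart rates); the
   detrended series is `z − trend`. Implemented as a sparse pentadiagonal
   solve, matching the dense closed form to 1e-8.
3. **Metrics**: mean RR from the corrected (un-detrended) series — the
   detrended series is zero-mean, so its mean is meaningless; RMSSD from
   the detrended series, matching common software behavior (a
   `detrend_for_rmssd=False` switch restores the raw-series variant, since
   protocols differ on this point). For iid Gaussian jitter of sd σ the
   population RMSSD is σ√2, which the recovery study verifies to within
   10% per subject at ≥900 beats.
4. **Change rates**: `Post/Pre × 100` for both metrics; a zero pre value
   flags the rate undefined.

## EGG dominant frequency

Each of the 8 abdominal channels is downsampled to a 10-Hz working rate
(cascaded polyphase decimation; spectra below 0.25 Hz unchanged within 1%),
band-passed 0.01–0.25 Hz (2nd-order zero-phase Butterworth — the corners
are declared config, not ground truth, since only the taper and DF band are
protocol-fixed), mean-removed and Hann-tapered, then a single periodogram is
taken. With 15-min records the resolution is ~0.0011 Hz, comfortably finer
than the 0.005-Hz contract over the slow-wave range; records shorter than
300 s trigger a resolution warning.

Per channel the maximum power in 0.033–0.066 Hz (2–4 cpm) is found; the
subject's DF is the frequency of the largest of the eight peaks, ties broken
toward the lower frequency. The peak must clear a noise floor of 3× an
out-of-band reference power or the DF is flagged undefined. The reference
is the pooled out-of-band power (within the passband, 0.01–0.2 Hz, so the
floor is not deflated by filtered-out regions) at the quantile matching the
in-band max statistic — the subject peak is a maximum over
(in-band bins × 8 channels) draws, so pure noise lands near floor/3 and is
rejected, while a slow wave at SNR 3 exceeds the floor by orders of
magnitude. Factor and comparison range are config.

## Statistics

- **Paired pre/post**: two-sided paired t, df = n−1; zero-variance
  difference vectors are flagged degenerate instead of producing spurious
  p values.
- **Mixed RM-ANOVA** (pingouin backend, verified against a from-scratch
  sums-of-squares decomposition to 1e-8 on balanced toys): temperature group
  between subjects, window within. Headline F/df are the
  sphericity-assumed decomposition — (g−1, N−g), (w−1, (N−g)(w−1)),
  ((g−1)(w−1), (N−g)(w−1)) — the scale on which such designs are
  conventionally reported; Greenhouse–Geisser ε is available from the
  backend. Subjects with incomplete window sets are dropped listwise and
  logged.
- **Post-hoc**: pairwise Welch t per post window, FDR-corrected as one
  family. (The exact post-hoc behind per-window group annotations in such
  studies is rarely named; Welch avoids the equal-variance assumption.)
- **Spearman**: mid-rank Pearson on ranks; exact permutation p for n ≤ 9,
  t approximation above.
- **FDR**: Benjamini–Hochberg adjusted p per family is the default — it is
  deterministic and well behaved at small family sizes. A Storey-type
  tail-area estimator (π₀ at λ = 0.5, capped, floored at 1/m) is available
  behind the same interface for comparison with tail-area/local-fdr tools;
  corrected p values from those tools will not match BH numerically, so
  cross-study comparisons should use raw statistics.
- **Shapiro–Wilk** is computed and reported as advisory only; it never
  gates the pipeline.

The orchestrator excludes any subject failing a stage, logs the reason, and
aborts only if fewer than half survive (threshold config).

## Synthetic cohorts

The generator emulates the study conditions: 20 subjects per group
(4 °C/10 °C/30 °C), 64-Hz bilateral LDF spanning 15-min baseline + 30-min
post, RR series, and 8-channel EGG.

- **LDF**: per side, a 20-PU baseline offset plus one sinusoidal oscillator
  per band — frequency drawn uniformly within the band per subject, phase
  per side — plus white Gaussian noise (sd 0.3 PU). Left amplitudes are
  0.5/0.5/0.8/1.0/1.2/2.0 PU from slowest to cardiac; right amplitudes are
  0.9× left, giving a stable nonzero baseline asymmetry so the laterality
  denominator is never degenerate. Single tones rather than 1/f vasomotion
  are deliberate: band power is then analytically known, which is what
  parameter-recovery tests require. Group effects are per-band, per-side
  amplitude multipliers that switch on at the stimulus; the default
  scenario doubles the left cardiac amplitude in the 30 °C group only. The
  published group effect sizes are shown only graphically in this
  literature, so the multiplier is a free parameter chosen to be a
  moderate, unambiguous effect; it is not calibrated to any reported value.
- **RR**: mean 800 ms, iid Gaussian jitter sd 25 ms, optional slow
  sinusoidal trend, and optional artifact beats replaced by ±250–400 ms
  excursions — a simplification of real ectopy taxonomies down to what the
  median-filter correction must catch.
- **EGG**: one slow wave near 0.05 Hz (±0.01 Hz per subject) shared by all
  8 channels with per-channel phase, two harmonics at halved amplitudes,
  white noise. Synthesized at a 10-Hz rate: all content sits below
  0.25 Hz, and the analysis path downsamples to 10 Hz regardless, so
  synthesizing at an acquisition-like kHz rate would only inflate files.

Determinism: a cohort is generated from one `SeedSequence` root, one spawn
per subject, sub-spawned per modality — identical spec + seed gives a
byte-identical dataset, and subject k's signals do not change when the
cohort grows.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: 1/f and nonstationary vasomotion, movement
artifacts, probe repositioning, respiratory–cardiac coupling, real ectopic
beat morphology, gastric slow-wave frequency drift and propagation, or
inter-subject variance in effect sizes. Recovery results on this test bed
demonstrate the estimators are correct and calibrated, not that real
effects of this size exist.

## Problem sizes in the validation studies

The studies module fixes these sizes as its study conditions: the
asymmetry-recovery cohort uses 60 subjects (20/group); the RMSSD and DF
recovery studies use 100 seeded subjects each; the type-I calibration uses
200 null cohorts of 60 subjects with oscillators disabled (pure noise around
the offset), which leaves the raw laterality statistic's null distribution
intact while keeping generation cheap.

## Known limitations

- The slowest endothelial band in 10-min windows is structurally
  unreliable (few cycles, COI covers most of the window); it is reported
  with a flag rather than suppressed, mirroring field practice.
- The laterality index is unsigned; directional questions need a different
  statistic, which is deliberately out of scope.
- Band-mode laterality on near-silent bands is a ratio of two small noisy
  numbers and has heavy tails; group statistics on such channels are valid
  but low-powered, and the undefined-value flagging exists for the exact
  degenerate limit.
- EDF support writes 16-bit quantized samples (standard EDF); round-trips
  are exact only to the quantization step of the channel's physical range.
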