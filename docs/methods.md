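# Methods

`qrsbench` evaluates QRS (R-peak) detectors along three axes at once:
the temporal tolerance allowed when pairing detections with reference
annotations, the level of muscular noise mixed into the signal, and the
beat morphology class. This note records the models, the parameter
choices that matter, and the design decisions taken where the
underlying methods left them open.

## Matching and metrics

A detection `d` may be paired with an annotation `a` when
`|d - a| <= DTT`, the *detector temporal tolerance*, a two-sided
inclusive bound in samples ("8.33 ms (3 samples)" therefore means
±3 samples at 360 Hz). The pairing is maximum-cardinality one-to-one,
computed by a sorted two-pointer sweep; for interval constraints on a
line this greedy sweep is optimal, and the test suite verifies it
against exhaustive bipartite matching on all random instances up to
12×12. Ties are broken toward the earlier detection. Unmatched
annotations are FN, unmatched detections FP, and
`Se = TP/(TP+FN)`, `PPV = TP/(TP+FP)`, `F1 = 2·PPV·Se/(Se+PPV)`,
`DER = (FN+FP)/TB`, with TP/TB as the headline accuracy ratio.

Raising the tolerance can only convert FN/FP pairs into TPs, never the
reverse, so TP is nondecreasing in DTT; this monotonicity is asserted
as a property on every benchmark run. The default sweep grid is
{3, 17, 31, 45, 59} samples, i.e. 8.33–163.89 ms at 360 Hz.

Stratification by morphology (N, L, R, V, P, A; everything else OTHER)
only filters the tally: the matching itself is always computed against
the *full* annotation set, so a detection near an excluded beat cannot
be silently re-credited to a nearby stratum. Summary tables report the
mean and *population* standard deviation of record-pooled TP/TB
percentages across the summarized axes (morphology × noise, DTT ×
noise, or morphology × DTT); strata with TB = 0 are excluded, mirroring
the per-record tables that omit records without beats of the class.
Whether such statistics should pool over records before averaging is a
genuine convention choice; pooled-first is the default and the tidy
per-record grid is always written so either view can be recomputed.

## Noise mixing

Signal and noise "power factors" are first-difference powers,
`P = 1/(N-1) · Σ (x[i+1]-x[i])²`, which emphasizes exactly the
high-frequency band where muscular artifact competes with the QRS.
The relative SNR between an ECG record (`Ps`) and the noise record
(`Pn`) and the noise scaling factor `k` (the mixture is
`ECG_test = ECG_orig + k·MA`, point by point) are each offered in two
conventions, because the conventions in circulation are not mutually
consistent: a 20·log10 factor applied to the power ratio together with
`k = sqrt(tSNR/eSNR)` — a square root of a ratio of *dB values*, which
is dimensionally irregular and undefined for non-positive dB — versus
the physically consistent solution of `relative_snr(Ps, k²·Pn) = tSNR`,
i.e. `k = 10^((eSNR−tSNR)/40)` under the 20·log convention. The
"printed" forms are the package default for fidelity; the "power"
convention is what the benchmark fixture uses, and it reproduces the
target SNR exactly (the suite checks < 0.01 dB). Neither is asserted
to be the intended reading; both are exposed.

No resampling is performed (a noise/record sampling-rate mismatch is an
error); noise shorter than a record is tiled, longer noise truncated
from sample 0.

## The four detectors

All detectors are deterministic, emit strictly increasing R-peak sample
indices, and enforce a 200 ms refractory period. The detected position
is the argmax of each algorithm's own decision signal; **no group-delay
compensation is applied anywhere**, because the systematic temporal
offset of a detector's fiducial point is precisely what the DTT sweep
is designed to measure. Adaptive thresholds are initialized from the
opening 2 s of the record and detection then runs from sample 0
(offline-benchmark initialization): initializing and *starting* after
the learning window would unconditionally forfeit its beats, while a
silent lead-in would cold-start the thresholds at noise level.

**1 — decaying threshold** (`mwa_window_ms=40`, `search_window_ms=260`,
`refractory_ms=200`, `decay_tau_ms=200`, `threshold_coeff=0.5`).
Feature: square(MWA(first difference)) — in that order. The causal
moving average of the first difference is proportional to
`x[n]−x[n−W]`, so the squared feature has a mirror lobe exactly W
samples after the apex; W is sized to a QRS upstroke (40 ms) so both
lobes stay inside the complex (a W much wider than the upstroke puts
the mirror lobe ~W after the apex and the marked peak intermittently
with it). Three states: threshold crossing opens a fixed 260 ms window
whose feature argmax is the R-peak; a 200 ms wait; then the threshold
restarts at `c ×` (mean feature amplitude at all previous R-peaks) and
decays exponentially (τ = 200 ms) until the feature reaches it.

**2 — dual moving average** (`n_short=28`, `n_long=110` samples,
`alpha=0.7`, `beta=0.3`, `peak_fraction=0.5`). Two rectified high-pass
paths, `u = |x − MA_short(x)|` and `y = |x − MA_long(x)|`; `u` triggers
a 200 ms search window, the R-peak is the argmax of `y` inside it.
Because `x[n]` itself enters both paths undelayed, this detector's
fiducial sits essentially on the apex — the source of its strength at
tight tolerances. The threshold update is the convex combination
`thr ← α·thr + β·(peak_fraction·y_peak)`; the fraction is required
because a threshold converging to the full `y` peak would exceed the
`u` path's peak (u ≤ y pointwise at the apex) and stop triggering. The
whole chain is scale-invariant: doubling the signal amplitude leaves
detection positions bit-identical.

**3 — level crossing** (`resolution_bits M=8`, `hysteresis_levels
k_l=4`, `min_run_levels=64`, `max_run_ms=120`, 11-bit event timer).
The record's amplitude range is divided into `2^M − 1` uniform interior
levels. An event is emitted when the signal crosses the next level in
the running direction, or `k_l` levels against it (asymmetric
hysteresis); the latter flags a direction reversal — a local peak. The
beat detector accepts a reversal whose preceding monotonic event run
spans ≥ 64 levels within ≤ 120 ms: a QRS deflection sweeps most of the
amplitude range in tens of milliseconds, while P/T waves span a few
percent of it. The span threshold must scale with the level grid — at
M = 8 a span of a few levels would flag P waves and Q troughs, whose
accepted detections then refractory-block the true R reversal. Event
timing is exposed as an 11-bit counter readout (ticks mod 2048);
absolute sample indices are retained for evaluation only. A sample
landing exactly on a level counts as crossed upward (ties are
measure-zero for floating-point inputs).

**4 — Pan–Tompkins adaptation** (Butterworth band-pass 5–15 Hz, order
2 per edge, five-point derivative, squaring, 150 ms moving-window
integral; SPK/NPK updates 0.125/0.875, `T1 = NPK + 0.25(SPK−NPK)`,
searchback at 1.66× the average RR with half threshold, threshold
halving when the last RR leaves 92–116 % of the regular-RR average; the
parallel second threshold on the band-passed signal is not applied).
The R-peak is the *first* strict local maximum of the integrated
feature above the threshold. The causal band-pass plus the 150 ms
integration window give this detector an inherent, morphology-dependent
fiducial delay of roughly 15–150 ms, and which shoulder ripple of the
integrated bump first exceeds the threshold depends on the adaptive
threshold level — so its accuracy at tight tolerances is poor and
becomes excellent only at 125–164 ms tolerances. This is a property of
the method, reproduced deliberately, not compensated. The band-pass
filter state is initialized at the signal's first value so a DC offset
does not inject a spurious onset transient.

## Synthetic data

The generator emulates the *structure* of an annotated arrhythmia
database record: a uniformly sampled channel (default 360 Hz), beats at
RR-jittered positions (default 5 % multiplicative jitter), a per-beat
morphology label stream, and mild sinusoidal baseline wander
(0.05 mV at 0.33 Hz). Beats are sums of Gaussian bumps whose
amplitude/width/polarity encode the morphology: ventricular beats are
wide (σ = 28 ms vs 11 ms for normal), large, P-wave-free, with
discordant T; paced beats are a 4 ms spike plus a wide evoked complex;
bundle-branch-block types widen the QRS. Each annotation is the argmax
of the *composite* written waveform within ±40 ms of the nominal apex,
so ground truth is exact by construction. Identical seeds give
bitwise-identical output.

Muscle noise is Gaussian noise band-limited to 20–120 Hz (chosen to
overlap QRS spectral content — the property that makes muscular
artifact hard), zero-mean, normalized to unit first-difference power.

What the generator does *not* emulate: physiological heart-rate
variability, respiration modulation, real artifact nonstationarity,
electrode motion, or the spectrum of any particular recorded noise
channel. Passing the fixture suite therefore demonstrates the internal
consistency of the pipeline and the detectors' idealized behavior, not
clinical-grade accuracy on real recordings.

The benchmark fixture is three 30 s records (normal-only; normal with
ventricular and block beats; normal with atrial, block and paced
beats), one synthetic noise channel, and mixed variants at 15/7/3 dB in
the power-consistent convention. 30 s at 60 bpm keeps the full
4-detector × 5-DTT × 4-noise × 6-morphology sweep under a few seconds
of CPU while leaving ~30 beats per record for stable ratios.

## File formats

WFDB headers, signal formats 212 (read; the 12-bit packed dialect of
the classic arrhythmia databases) and 16 (read/write), and MIT-format
beat annotations (read/write, including SKIP-encoded long gaps) are
implemented in-package. Amplitudes convert via `(adc − baseline)/gain`;
the default write gain uses most of the int16 range, bounding
round-trip error by one ADC step. Only beat annotation codes are kept
when reading annotations; rhythm/quality/boundary codes are discarded,
and beat symbols outside the six classes map to OTHER (beat counting
utilities count the full beat alphabet and report OTHER separately).

## Numerical and degenerate-input choices

- Zero-denominator metrics return an undefined marker (`None`), not an
  exception; TB = 0 strata are excluded from aggregation.
- A constant record yields an empty level-crossing event stream (not an
  error); an all-zero record yields zero detections from every
  algorithm.
- Logarithms are base-10 throughout dB arithmetic.
- Detections, grid CSVs and manifests are byte-reproducible across
  reruns of the same configuration.

## Known limitations

- Detector parameter defaults for algorithms 1–3 are this package's
  concretization of compactly described methods; published reference
  implementations could differ in unpublished constants, so absolute
  TP/TB values on real databases are not expected to match any single
  published row, while the ordinal structure (tolerance sensitivity,
  noise robustness ranking, morphology difficulty) is.
- Computational-complexity profiling and true-R-peak estimation from
  vectorcardiography are out of scope.
- Only muscular-artifact-type noise is modeled; baseline-wander and
  electrode-motion stress tests are not included.
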