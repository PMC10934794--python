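# qrsbench

Multidimensional benchmarking of QRS (R-peak) detection algorithms for
ECG signal processing.

Most QRS-detector comparisons report a single sensitivity/precision
number that silently depends on an arbitrary choice: how far a
detection may sit from the reference annotation and still count as
correct. `qrsbench` makes that choice — the **detector temporal
tolerance (DTT)** — an explicit experimental axis, and crosses it with
two more: **SNR-controlled muscular-noise contamination** and **QRS
beat morphology**. The result is a grid of true-positive-to-total-beat
ratios

    TP/TB  indexed by  (algorithm, DTT, noise level, morphology, record)

that shows not just *whether* a detector finds beats, but how precisely
it places them, how gracefully it degrades in noise, and which beat
shapes it struggles with. The toolkit is aimed at developers of
wearable/mobile ECG firmware and of ECG interpretive software who must
choose a detector for a given downstream use (HRV analysis needs tight
temporal precision; rhythm surveillance does not).

## What is inside

- **Four QRS detectors** (`qrsbench.detectors`), deterministic, with a
  200 ms refractory period:
  1. a low-complexity *decaying-threshold* detector
     (differentiate → moving-window average → square, three-state
     exponential-decay thresholding);
  2. a *dual moving-average* detector (two rectified high-pass paths
     `u = |x − MA_short(x)|`, `y = |x − MA_long(x)|`; `u` triggers a
     200 ms search window, `y`'s argmax is the beat);
  3. a *level-crossing* detector (event-based sampling on a
     `2^M − 1`-level grid with asymmetric hysteresis `k_l`, then
     peak/beat detection on the event stream — no filters at all);
  4. a *Pan–Tompkins adaptation* (Butterworth band-pass 5–15 Hz,
     derivative, squaring, 150 ms integration; adaptive SPK/NPK
     thresholds, searchback, no second threshold).
- **Tolerance-aware evaluation** (`qrsbench.evaluation`): optimal
  one-to-one matching under `|detection − annotation| ≤ DTT`
  (two-pointer sweep, verified against exhaustive bipartite matching),
  Se/PPV/F1/DER/TP-TB metrics, morphology-stratified tallies, pooled
  mean±std summary tables and per-record noise-delta reports.
- **Noise stress testing** (`qrsbench.noise`): first-difference power
  factors, relative SNR, scaling factor `k`, and point-by-point mixing
  `ECG_test = ECG_orig + k·MA`, in both the literal ("printed") and the
  physically consistent ("power") convention (see `docs/methods.md`).
- **WFDB file support** (`qrsbench.wfdb_io`): headers, signal formats
  212 (read) and 16 (read/write), MIT-format beat annotations
  (read/write), beat-count utilities, detections CSV import/export.
- **Synthetic data with exact ground truth** (`qrsbench.synthetic`):
  Gaussian-bump beat templates for the six morphology classes
  (N, L, R, V, paced, atrial-premature), band-limited muscle noise, and
  a one-call on-disk mini-database fixture.
- **Orchestration** (`qrsbench.pipeline`) and a thin CLI (`qrsbench`
  with verbs `synth`, `mix`, `detect`, `evaluate`, `sweep`).

## Worked example

```sh
python examples/detect_synthetic_ecg.py
```

```
record: 30 s at 360 Hz, 30 true beats

algorithm 1 ( decaying threshold): 30 detections, TP/TB = 100.0% at DTT=17, offsets 13..14 samples
algorithm 2 (dual moving average): 30 detections, TP/TB = 100.0% at DTT=17, offsets -1..0 samples
algorithm 3 (     level crossing): 30 detections, TP/TB = 100.0% at DTT=17, offsets 1..2 samples
algorithm 4 (       Pan-Tompkins): 30 detections, TP/TB =  86.7% at DTT=17, offsets 5..6 samples
```

Every detector finds all 30 beats, but their fiducial points differ:
the dual moving-average detector sits on the apex itself (offset
−1..0 samples), the decaying-threshold detector lags by ~14 samples
(39 ms) — inside a 17-sample tolerance but hopeless at a 3-sample one —
and the Pan–Tompkins chain's integration delay already costs it beats
at 47 ms tolerance. `examples/full_benchmark_sweep.py` runs the full
grid and prints the mean±std TP/TB per tolerance; with the default
fixture the four detectors climb from (17 %, 100 %, 97 %, 0 %) at
8.33 ms to (100 %, 100 %, 100 %, 100 %) at 163.89 ms — the growth rate
*is* the temporal-precision ranking. `examples/noise_stress_mixing.py`
shows the SNR-controlled mixing round trip, and `examples/wfdb_files.py`
the WFDB/annotation round trip.

To benchmark real WFDB data, point the sweep at a database directory
and a noise record:

```sh
qrsbench sweep --db data/mitdb --noise data/nstdb/ma --out results/mitdb \
    --target-snr 15,7,3 --dtt-samples 3,17,31,45,59
```

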