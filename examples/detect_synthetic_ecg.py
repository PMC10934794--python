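"""Generate a synthetic ECG and run all four QRS detectors on it.

Prints, per detector, the number of detections and the TP/TB ratio at a
47 ms temporal tolerance (17 samples at 360 Hz): the fraction of true
beats whose detection lands within that distance of the annotated apex.
"""

from qrsbench import SynthSpec, detect, generate_ecg, match

rec, truth = generate_ecg(SynthSpec(duration_s=30.0, heart_rate_bpm=60.0, seed=42))
print(f"record: {rec.duration_s:.0f} s at {rec.fs:.0f} Hz, {len(truth)} true beats\n")

for alg, name in [
    (1, "decaying threshold"),
    (2, "dual moving average"),
    (3, "level crossing"),
    (4, "Pan-Tompkins"),
]:
    det = detect(rec, alg)
    m = match(det, truth, 17)
    offsets = [o for *_, o in m.pairs]
    spread = f"offsets {min(offsets)}..{max(offsets)} samples" if offsets else "-"
    print(
        f"algorithm {alg} ({name:>19}): {len(det):2d} detections, "
        f"TP/TB = {100 * m.tp / len(truth):5.1f}% at DTT=17, {spread}"
    )

print(
    "\nTP/TB is the fraction of annotated beats matched one-to-one within the"
    "\ntolerance; the offset range shows each detector's systematic fiducial"
    "\ndelay, which is what a tolerance sweep exposes."
)
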