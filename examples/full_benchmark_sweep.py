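"""The full multidimensional benchmark on a synthetic mini-database.

Writes a 3-record fixture (clean + noise-mixed variants at 15/7/3 dB),
runs all four detectors over the 5-point tolerance grid, and prints the
mean/std TP/TB summary per tolerance — the layout that exposes how fast
each detector degrades as the allowed detection-to-annotation distance
shrinks.
"""

import tempfile
from pathlib import Path

from qrsbench import aggregate, make_benchmark_fixture, samples_to_ms
from qrsbench.pipeline import RunConfig, run_sweep

with tempfile.TemporaryDirectory() as td:
    make_benchmark_fixture(td, seed=7)
    config = RunConfig(
        db_dir=td, noise_path=str(Path(td) / "ma_synth.hea"), convention="power"
    )
    grid = run_sweep(config)

summary = aggregate(grid, ["algorithm", "dtt_samples"], ["morphology", "noise"])
print("mean/std of pooled TP/TB (%) over 6 morphologies x 4 noise levels:\n")
print(f"{'DTT ms (samples)':>18} | " + " | ".join(f"alg {a}: mean  std " for a in (1, 2, 3, 4)))
for dtt in sorted(summary.dtt_samples.unique()):
    row = f"{samples_to_ms(dtt, 360):7.2f} ({dtt:2d})     | "
    for alg in (1, 2, 3, 4):
        cell = summary[(summary.algorithm == alg) & (summary.dtt_samples == dtt)].iloc[0]
        row += f"{cell['mean']:11.2f} {cell['std']:5.2f} | "
    print(row)

print(
    "\nEvery column grows toward 100% as the tolerance widens; the growth"
    "\nrate ranks the detectors' temporal precision."
)
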