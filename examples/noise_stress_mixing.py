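"""SNR-controlled mixing of muscular noise into an ECG record.

Builds a synthetic ECG and a band-limited muscle-artifact noise channel,
computes the existing SNR from first-difference powers, scales the noise
to hit targets of 15/7/3 dB, and verifies the achieved SNR.
"""

from qrsbench import SynthSpec, difference_power, generate_ecg, mix, relative_snr, scaling_factor
from qrsbench.synthetic import generate_muscle_noise

ecg, _ = generate_ecg(SynthSpec(duration_s=30.0, seed=5))
noise = generate_muscle_noise(duration_s=30.0, seed=6)

ps = difference_power(ecg.samples)
pn = difference_power(noise.samples)
esnr = relative_snr(ps, pn)
print(f"signal power factor Ps = {ps:.4e}, noise Pn = {pn:.4e}")
print(f"existing SNR (eSNR)    = {esnr:.2f} dB\n")

for target in (15.0, 7.0, 3.0):
    spec = scaling_factor(esnr, target, convention="power")
    mixed = mix(ecg, noise, spec.k)
    achieved = relative_snr(ps, difference_power(spec.k * noise.samples))
    print(
        f"target {target:4.0f} dB: k = {spec.k:.4f}, achieved SNR = "
        f"{achieved:.4f} dB, mixed record peak = {mixed.samples.max():.2f} mV"
    )

print(
    "\nk scales the noise channel before point-by-point addition; in the"
    "\npower-consistent convention the achieved SNR hits the target exactly."
)
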