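"""From admittance change to detected I/Q response.

Pushes a small conductance/susceptance change through the
comparator-based amplifier (0.5 V drive, 200 kOhm || 100 pF feedback),
synthesizes the output waveform at the 1 MHz sampling rate, and
recovers the phasor by coherent detection.  Also shows that the phase
mismatch bias cancels under water-referenced normalization.
"""

from admitsense import (
    AdmittanceDelta,
    ComplexAdmittance,
    DriveConfig,
    FeedbackConfig,
    amplifier_output,
    coherent_detect,
    synthesize_waveform,
)

y0 = ComplexAdmittance(g=1e-5, b=0.0, frequency=5000.0)
fb = FeedbackConfig()  # 200 kOhm || 100 pF
delta = AdmittanceDelta(dg=2e-6, db=1e-6)  # sample vs balance point

for theta in (0.0, 0.05):
    drive = DriveConfig(u=0.5, frequency=5000.0, theta=theta)
    out = amplifier_output(delta, y0, drive, fb)
    ref = amplifier_output(AdmittanceDelta(0.0, 0.0), y0, drive, fb)
    w = synthesize_waveform(out, 5000.0, 1e6, 100)
    i, q = coherent_detect(w, 5000.0, 1e6)
    print(f"theta = {theta:4.2f} rad:")
    print(f"  raw output phasor      I = {i:+.4f} V, Q = {q:+.4f} V")
    n = out - ref
    print(f"  water-normalized       I = {n.real:+.4f} V, Q = {n.imag:+.4f} V")

print(
    "\nThe raw phasor shifts with the mismatch theta, but the normalized"
    "\nresponse (sample minus deionized-water reference) is identical:"
    "\nthe fixed biases Y0*theta^2/2 and Y0*theta cancel exactly."
)
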