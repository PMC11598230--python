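"""Estimating mixed NaCl/KCl concentrations from normalized responses.

Takes the four normalized responses of one sample (two frequencies x
two channels), initializes from the closed-form solve of the linear
quadrature models, refines with Gauss-Newton on the quadratic
surfaces, and prints the full audit trail.
"""

from admitsense import Channel, estimate, reference_calibration

quadratic = reference_calibration("quadratic")
linear = reference_calibration("linear")

truth = (1.0, 2.0)  # mM NaCl, KCl
measurement = {
    (f, c): quadratic.model(f, c).predict(*truth)
    for f in quadratic.frequencies
    for c in Channel
}
print("normalized responses (V):")
for (f, c), v in sorted(measurement.items(), key=lambda kv: (kv[0][0], kv[0][1].value)):
    print(f"  {f / 1e3:3.0f} kHz {c.value:10s} {v:+.4f}")

res = estimate(measurement, quadratic=quadratic, linear=linear)
print(f"\nlinear-stage initial estimate : ({res.x1_init:+.3f}, {res.x2_init:+.3f}) mM")
print(f"ill-conditioning warning      : {res.condition_warning}")
print(f"refined estimate              : ({res.x1_hat:.6f}, {res.x2_hat:.6f}) mM")
print(f"iterations = {res.iterations}, residual norm = {res.residual_norm:.2e}")

print(
    "\nThe linear initialization is rough — the two quadrature slope rows"
    "\nare nearly collinear (condition number ~147) — but the Gauss-Newton"
    "\nstage recovers the true (1, 2) mM mixture to machine-level accuracy"
    "\non noise-free responses."
)
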