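# Methods

This note records the models implemented in `admitsense`, the defaults
and why they were chosen, the numerical choices, and what the synthetic
studies do and do not demonstrate.

## Equivalent circuit

An electrolyte sample between two identical insulated electrodes is
modelled as two series polarization impedances `Zp = Rp + 1/(jωCp)`
(electrical double layer at each electrode) around a parallel bulk
`Zs = Rs/(1 + jωRsCs)`. The branch admittance is `Y = 1/(2Zp + Zs)`;
the factor 2 encodes the two identical electrodes. The model assumes
balanced, stable polarization and frequency-independent lumped values
(no constant-phase-element or Warburg refinement, no Rs dispersion).

No numeric circuit values are part of any calibration: `Rp, Cp, Rs, Cs`
are free simulation parameters, and the calibration/estimation layers
operate purely on normalized responses. Limit cases use an explicit
`INFINITE_CAPACITANCE` sentinel rather than `inf` floats so the
analytic limits (`Zp → Rp`, `Zs → 0`) are taken exactly. Following the
intended limit behaviour, `Rp = 0` and `Cs = 0` are admissible even
though all values are normally positive.

The reduction `(GT, CT) = (G, B/ω)` is evaluated per frequency; nothing
assumes a single `(GT, CT)` pair is valid at both working frequencies.

## Analog front end

Phasor convention: for `P = I + jQ` the waveform is
`s(t) = I·sin(ωt) + Q·cos(ωt)`; I is in phase with the non-inverted
drive. This makes the mapping "in-phase ↔ ΔG, quadrature ↔ ΔB"
literal in the amplifier equation

    Uout = −[ΔY + Y0(θ²/2 + jθ)]·U/Yf,

which is implemented in its general complex-`Y0` form (the common
real-`Y0` presentation is the special case). Key consequences, each
verified by test: the phase-shift network gain `(jωR₂C−1)/(jωR₂C+1)`
has unit magnitude at every frequency; `Uout` is linear in ΔY at fixed
θ; and subtracting a reference (deionized-water) measurement removes
the θ-biases exactly, which is the entire justification for working in
water-normalized response units. Mismatch is restricted to
`|θ| < 0.2 rad`, the regime where the second-order phase expansion
behind the bias terms is meaningful.

Defaults mirror the prototype operating point: `U = 0.5 V`,
`Rf = 200 kΩ`, `Cf = 100 pF`, working frequencies 5 and 10 kHz,
sampling at 1 MHz. Coherent detection integrates over 100 cycles by
default (no integration time is prescribed by the design; 100 cycles
keeps records short while the sin/cos correlators stay exactly
orthogonal). Records must span whole cycles — fractional spans are
detected and flagged as spectral leakage rather than silently biasing
I/Q. Op-amp non-idealities, ADC quantization and oscillator phase noise
are out of scope.

## Response surfaces

Per (frequency, channel) the normalized response is modelled as
`V = α0 + α1x1 + α2x1² + α3x2 + α4x2²` (mM concentrations; linear form
sets α2 = α4 = 0). There is no x1·x2 interaction term in the default
design, matching the additive surface family the device calibration
uses; an `include_interaction` flag exists for exploration and defaults
off. Fitting is ordinary least squares — no weighting, since no
heteroscedasticity treatment is part of the calibration — with
rank-deficiency reported by naming the deficient design columns. The
fit diagnostic `R` is the Pearson correlation between fitted and
observed responses: it is 1 for perfect fits and matches the reported
"correlation coefficient" usage; it is left unset when the response is
constant (undefined correlation). Intercepts are retained as fitted —
water-normalized responses need not pass through zero because the
surfaces are least-squares fits, not constrained interpolants.

The shipped reference coefficient sets (quadratic and linear, 5 and
10 kHz) are the published calibration of the prototype device and serve
as the default ground truth of the synthetic generator, so downstream
tests are anchored to realistic surface shapes.

## Inversion

Stage 1 solves the 2×2 linear system of the two linear quadrature
surfaces in closed form. The slope matrix built from the reference
calibration has determinant ≈ 6.2·10⁻³ against entries ≈ 0.5
(condition number ≈ 147): NaCl and KCl move every response almost
proportionally, so this solve loses about two decimal digits. The
ill-conditioning threshold is therefore set at condition number 100 —
chosen so the reference calibration itself is flagged — raising
`condition_warning` and, when linear in-phase models are available,
augmenting to a 4×2 least-squares solve.

Stage 2 is projected Gauss–Newton on the stacked residuals
`r_k(x) = V_k(x) − y_k` with the analytic Jacobian
`∂V/∂x_i = α_{1|3} + 2α_{2|4}x_i`. With exactly two equations
(quadrature-only mode) this is classical Newton–Raphson; the default
uses all four quadratic surfaces, and a mixed mode (linear quadrature +
quadratic in-phase) is provided as well. Steps are solved by least
squares (tolerant of a rank-deficient Jacobian) with halving
backtracking; iterates are projected onto the admissible box, default
[0, 8] mM (twice the calibrated range — negative concentrations are
unphysical, extrapolation warns rather than fails). Tolerances:
step-norm 10⁻¹⁰ mM, residual 10⁻⁸, 50 iterations maximum. `converged`
keys on the step-norm (or exact-residual) criterion; for noisy
measurements the least-squares residual floors at the noise level, so
a residual-based convergence notion would be vacuous. Non-convergence
is reported in the result, never raised.

Because the linear and quadratic calibrations are *independent fits*,
the stage-1 estimate can land far from the truth on quadratic-generated
data (ill-conditioning amplifies the inter-model mismatch), and the
residual surface has a second shallow minimum along the nearly-collinear
valley. The estimator therefore globalizes: if refinement from the
linear init does not reach an exact root, it enumerates candidate roots
algebraically — two surfaces without interaction terms intersect where
a quartic in x1 vanishes (eliminating x2² leaves x2 linear in x1) —
and refines from the best-ranked candidates, keeping the lowest-residual
result. On noise-free forward data this recovers every concentration in
[0, 4]² (0.25 mM steps) to better than 10⁻⁶ mM.

Single-frequency, single-channel inversion reduces to a quadratic in
one unknown and can have two admissible roots (the in-phase surfaces
bend over near 6–8 mM); `admissible_roots` exposes the enumeration, and
the two-frequency estimator resolves the ambiguity. Of note, even the
two-frequency *quadrature-only* pair admits a second exact intersection
for some mixtures; the four-surface default disambiguates.

## Synthetic studies

The generator emulates the mixed-design study: concentration levels
{0, 0.5, 1, 2, 3, 4} mM per analyte (the calibrated 0.5–4 mM range plus
the water reference), full Cartesian grid (the measured subset of
combinations is not prescribed, so the full product is used), two
frequencies, both channels, 5 replicates per condition — the replicate
count of the emulated protocol. Noise is additive, Gaussian, and
homoscedastic per observation with default σ = 0.02 response units; no
noise magnitude is prescribed by the design (only error bars are
shown), so σ is a config knob, with 0.02 small against the ≈ 0.25 V
response step between adjacent single-salt levels. Single-electrolyte
modes hold the other analyte at zero. A fixed seed reproduces datasets
byte-identically.

A second generation path maps each response through the amplifier
equation to an admittance delta, synthesizes the output waveform, and
recovers responses by coherent detection plus reference subtraction.
The two paths agree to detection tolerance, and the waveform path
demonstrates the θ-bias cancellation end to end.

What passing tests do **not** show about real data: the generator's
noise is idealized (no drift, no temperature/humidity dependence, no
electrode fouling, no heteroscedasticity), the truth surfaces are the
published coefficient sets rather than a physical model, and replicates
are exchangeable. Conclusions about the real device's absolute accuracy
or its reported fit correlations cannot be drawn from these synthetics.

## Resolution limits (known limitation)

The four reference surfaces are nearly collinear in (x1, x2): the
Gauss–Newton Jacobian has condition number ≈ 60–150 across the grid,
with smallest singular value ≈ 0.016 response units per mM at
mid-grid. Consequences, all measured by the test suite and the
acceptance study at the default σ = 0.02:

- the **total** concentration x1 + x2 is resolved to ≈ 0.05 mM;
- the **split** between NaCl and KCl carries per-axis RMSE of
  ≈ 0.9–1.1 mM per single measurement, so nearest-level assignment on a
  0.5 mM mixed grid fails for a substantial fraction of samples — the
  finest fully-resolved mixed-grid spacing under these conditions is
  4 mM;
- the estimator carries a small-σ bias of a few hundredths of a mM
  (nonlinear least squares is biased at O(σ²/curvature), amplified
  here by the valley geometry); it shrinks as σ → 0 but is ≈ 0.06 mM
  at σ = 0.01 at mid-grid.

These are properties of the printed surface geometry, not of the
solver: the same pipeline recovers concentrations to 10⁻⁶ mM without
noise. Sub-0.5 mM mixed-salt resolution would require either lower
per-measurement noise (≈ an order of magnitude), replicate averaging,
or surfaces with more contrast between the two analytes (additional
frequencies or channels with different Na/K sensitivity ratios).

## Problem sizes

The default test suite and the acceptance study use the study-scale
designs throughout: 6×6 (or 8×8) grids, 5 replicates, 100-cycle
detection records, Monte-Carlo loops of 150–500 draws, and 20 noise
realizations for the resolution figure — sizes chosen to hold
Monte-Carlo standard errors comfortably below the tolerances they are
compared against.
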