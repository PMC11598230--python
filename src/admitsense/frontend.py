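"""Analog front end: drive generation, phase-shift networks, the
comparator-based differential amplifier, and coherent I/Q detection.

The sensing chain drives the target admittance ``Y0 + ΔY`` with
``U·sin(ωt)`` and the reference admittance ``Y1`` with the inverted
signal ``aU·sin(ωt + π − θ)``, where ``θ`` is the residual phase
mismatch left after trimming the phase-shift (PS) networks.  With the
balance condition ``Y0 = a·Y1`` and feedback admittance ``Yf``, the
amplifier output phasor is

    Uout = −[ΔY + Y0(θ²/2 + jθ)]·U / Yf

so the in-phase component of ``Uout`` carries the conductance change
``ΔG`` and the quadrature component the susceptance change ``ΔB``, both
amplified by ``U/Yf``.  The fixed mismatch biases ``Y0θ²/2`` and
``Y0θ`` are common to every measurement and cancel exactly when
responses are normalized against a reference (deionized-water)
measurement.

Phasor convention: for a phasor ``P = I + jQ`` the time-domain signal
is ``s(t) = I·sin(ωt) + Q·cos(ωt)``, i.e. I is the component in phase
with the non-inverted drive and Q leads it by 90 degrees.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .circuit import ComplexAdmittance

__all__ = [
    "DriveConfig",
    "PSNetworkConfig",
    "FeedbackConfig",
    "AdmittanceDelta",
    "ps_gain",
    "amplifier_output",
    "bias_terms",
    "synthesize_waveform",
    "coherent_detect",
]

#: Small-mismatch bound assumed by the second-order phase expansion.
MAX_PHASE_MISMATCH = 0.2


@dataclass(frozen=True)
class DriveConfig:
    """Two-phase drive: ``U·sin(ωt)`` and ``aU·sin(ωt + π − θ)``.

    ``amplitude_trim`` stands in for the variable resistor that sets the
    inverted-drive amplitude on the physical board; it multiplies ``a``.
    """

    u: float = 0.5
    frequency: float = 5_000.0
    a: float = 1.0
    theta: float = 0.0
    amplitude_trim: float = 1.0

    def __post_init__(self) -> None:
        if self.u <= 0:
            raise ValueError("drive amplitude u must be positive")
        if self.a <= 0 or self.amplitude_trim <= 0:
            raise ValueError("amplitude ratio and trim must be positive")
        if self.frequency <= 0:
            raise ValueError("working frequency must be positive")
        if abs(self.theta) >= MAX_PHASE_MISMATCH:
            raise ValueError(
                f"|theta| must stay below {MAX_PHASE_MISMATCH} rad for the "
                "small-mismatch expansion to hold"
            )

    @property
    def omega(self) -> float:
        return 2.0 * math.pi * self.frequency


@dataclass(frozen=True)
class PSNetworkConfig:
    """First-order all-pass phase-shift network: trim resistor R2, capacitor C."""

    r2: float
    c: float

    def __post_init__(self) -> None:
        if self.r2 <= 0 or self.c <= 0:
            raise ValueError("PS network R2 and C must be positive")


@dataclass(frozen=True)
class FeedbackConfig:
    """Feedback branch of the amplifier: Rf in parallel with Cf.

    Defaults mirror the prototype board: 200 kΩ ∥ 100 pF.
    """

    rf: float = 200e3
    cf: float = 100e-12

    def __post_init__(self) -> None:
        if self.rf <= 0:
            raise ValueError("feedback resistance rf must be positive")
        if self.cf < 0:
            raise ValueError("feedback capacitance cf must be non-negative")

    def admittance(self, omega: float) -> complex:
        """``Yf = 1/Rf + jωCf`` at angular frequency ``omega``."""
        if omega <= 0:
            raise ValueError("omega must be positive")
        return complex(1.0 / self.rf, omega * self.cf)


@dataclass(frozen=True)
class AdmittanceDelta:
    """Admittance change ``ΔY = ΔG + jΔB`` of the target vs the balance point."""

    dg: float
    db: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.dg) and math.isfinite(self.db)):
            raise ValueError("admittance delta components must be finite")

    @property
    def as_complex(self) -> complex:
        return complex(self.dg, self.db)


def ps_gain(cfg: PSNetworkConfig, omega: float) -> complex:
    """Phasor voltage gain ``(jωR2C − 1)/(jωR2C + 1)`` of the PS network.

    A first-order all-pass: unit magnitude at every frequency, phase
    sweeping from π (ωR2C → 0) to 0 (ωR2C → ∞), which is what lets R2
    null the drive-path phase mismatch without touching amplitude.
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    jwrc = 1j * omega * cfg.r2 * cfg.c
    return (jwrc - 1.0) / (jwrc + 1.0)


def amplifier_output(
    delta: AdmittanceDelta,
    y0: ComplexAdmittance,
    drive: DriveConfig,
    fb: FeedbackConfig,
) -> complex:
    """Output phasor ``−[ΔY + Y0(θ²/2 + jθ)]·U/Yf`` of the amplifier.

    Implements the general complex-``Y0`` form; the familiar split into
    ``ΔG + Y0θ²/2`` (in-phase) and ``ΔB + Y0θ`` (quadrature) is its
    real-``Y0`` special case.  Output is linear in ``ΔY`` at fixed θ.
    """
    yf = fb.admittance(drive.omega)
    if yf == 0:
        raise ZeroDivisionError("feedback admittance is zero; gain is singular")
    theta = drive.theta
    bias = y0.as_complex * (theta * theta / 2.0 + 1j * theta)
    return -(delta.as_complex + bias) * drive.u / yf


def bias_terms(y0: ComplexAdmittance, theta: float) -> AdmittanceDelta:
    """Fixed mismatch bias ``Y0(θ²/2 + jθ)`` expressed as an admittance delta.

    This is the additive term a reference (deionized-water) measurement
    carries identically, so normalization subtracts it exactly.  Zero
    when θ = 0; the in-phase part is even in θ, the quadrature part odd.
    """
    bias = y0.as_complex * (theta * theta / 2.0 + 1j * theta)
    return AdmittanceDelta(dg=bias.real, db=bias.imag)


def synthesize_waveform(
    phasor: complex,
    frequency: float,
    sampling_rate: float = 1e6,
    n_cycles: int = 100,
) -> np.ndarray:
    """Sample ``s(t) = Re(P)·sin(ωt) + Im(P)·cos(ωt)`` over whole cycles.

    Returns exactly ``round(n_cycles · fs / f)`` samples starting at
    t = 0.  Requires ``fs >= 20·f`` (comfortably above Nyquist so the
    quadrature correlators are well conditioned) and an integer number
    of samples per record.
    """
    if frequency <= 0 or sampling_rate <= 0:
        raise ValueError("frequency and sampling_rate must be positive")
    if n_cycles < 1 or int(n_cycles) != n_cycles:
        raise ValueError("n_cycles must be a positive integer")
    if sampling_rate < 20.0 * frequency:
        raise ValueError(
            "sampling_rate must be at least 20x the working frequency "
            f"(got fs/f = {sampling_rate / frequency:.2f})"
        )
    n_exact = n_cycles * sampling_rate / frequency
    n = int(round(n_exact))
    if abs(n_exact - n) > 1e-9:
        raise ValueError(
            "record length is not an integer number of samples; choose "
            "fs, f, n_cycles with integer fs·n_cycles/f"
        )
    t = np.arange(n) / sampling_rate
    wt = 2.0 * math.pi * frequency * t
    return phasor.real * np.sin(wt) + phasor.imag * np.cos(wt)


def coherent_detect(
    waveform: np.ndarray,
    frequency: float,
    sampling_rate: float = 1e6,
) -> tuple[float, float]:
    """Lock-in detection: correlate against sin/cos references.

    ``I = (2/N)·Σ s[n]·sin(ωtₙ)`` and ``Q = (2/N)·Σ s[n]·cos(ωtₙ)``.
    For a clean sinusoid spanning an integer number of periods this
    returns the phasor's rectangular components exactly; otherwise a
    warning is issued and the result carries spectral-leakage bias of
    order 1/N per fractional cycle.
    """
    if frequency <= 0 or sampling_rate <= 0:
        raise ValueError("frequency and sampling_rate must be positive")
    s = np.asarray(waveform, dtype=float)
    n = s.size
    if n == 0:
        raise ValueError("waveform is empty")
    cycles = n * frequency / sampling_rate
    if abs(cycles - round(cycles)) > 1e-9:
        warnings.warn(
            f"waveform spans {cycles:.6f} cycles (non-integer); I/Q estimates "
            "carry spectral-leakage bias",
            stacklevel=2,
        )
    t = np.arange(n) / sampling_rate
    wt = 2.0 * math.pi * frequency * t
    i = 2.0 / n * float(np.dot(s, np.sin(wt)))
    q = 2.0 / n * float(np.dot(s, np.cos(wt)))
    return i, q
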