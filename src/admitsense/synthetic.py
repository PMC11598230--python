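"""Synthetic measurement generator emulating the mixed-electrolyte study design.

The emulated experiment: NaCl/KCl solutions on a concentration grid
spanning 0.5–4 mM (plus deionized water as the normalization
reference), measured at two working frequencies (5 and 10 kHz) on both
detection channels, five replicates each.  Responses are drawn from a
ground-truth set of response surfaces (by default the published
quadratic calibration of the prototype device) with additive
homoscedastic Gaussian noise per observation.

Two generation paths exist and agree in expectation:

- the *phasor* path (:func:`generate`) samples the surfaces directly;
- the *waveform* path (:func:`generate_waveform_dataset`) maps each
  response through the amplifier equation to an admittance delta,
  synthesizes the amplifier output waveform, and leaves coherent
  detection plus reference subtraction to recover the responses —
  exercising the whole analog chain, including the exact cancellation
  of the phase-mismatch biases under water-referenced normalization.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .circuit import ComplexAdmittance
from .frontend import (
    AdmittanceDelta,
    DriveConfig,
    FeedbackConfig,
    amplifier_output,
    coherent_detect,
    synthesize_waveform,
)
from .regression import (
    WORKING_FREQUENCIES,
    CalibrationSet,
    Channel,
    MeasurementRecord,
    reference_calibration,
)

__all__ = [
    "GeneratorMode",
    "GeneratorConfig",
    "generate",
    "ChainConfig",
    "WaveformRecord",
    "WaveformDataset",
    "generate_waveform_dataset",
    "detect_dataset",
]


class GeneratorMode(str, enum.Enum):
    MIXED = "mixed"
    SINGLE_NACL = "single_NaCl"
    SINGLE_KCL = "single_KCl"


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design knobs for the synthetic generator.

    Defaults mirror the emulated experiment: levels {0, 0.5, 1, 2, 3, 4}
    mM per analyte, 5 replicates per condition, homoscedastic Gaussian
    noise of 0.02 response units per observation.  ``mode`` selects the
    mixed Cartesian design or a single-electrolyte series (the other
    analyte held at zero).  A fixed seed makes the output byte-identical
    across runs.
    """

    grid: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 3.0, 4.0)
    replicates: int = 5
    noise_sigma: float = 0.02
    seed: int = 0
    truth: CalibrationSet | None = None
    mode: GeneratorMode = GeneratorMode.MIXED

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid", tuple(float(g) for g in self.grid))
        object.__setattr__(self, "mode", GeneratorMode(self.mode))
        if any(g < 0 for g in self.grid) or not self.grid:
            raise ValueError("grid levels must be non-negative and non-empty")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    def resolve_truth(self) -> CalibrationSet:
        return self.truth if self.truth is not None else reference_calibration()

    def design_points(self) -> list[tuple[float, float]]:
        """Concentration pairs of the design, reference (0, 0) always first."""
        if self.mode is GeneratorMode.MIXED:
            pts = [(x1, x2) for x1 in self.grid for x2 in self.grid]
        elif self.mode is GeneratorMode.SINGLE_NACL:
            pts = [(x, 0.0) for x in self.grid]
        else:
            pts = [(0.0, x) for x in self.grid]
        if (0.0, 0.0) not in pts:
            pts.insert(0, (0.0, 0.0))
        else:
            pts = [(0.0, 0.0)] + [p for p in pts if p != (0.0, 0.0)]
        return pts


def generate(cfg: GeneratorConfig) -> list[MeasurementRecord]:
    """Phasor-level synthetic dataset.

    For every design point × frequency × channel × replicate the
    response is the truth-surface value plus ``N(0, σ²)`` noise.  The
    deionized-water point (0, 0) is always present as the normalization
    reference.  Iteration order (and hence the noise stream) is fixed,
    so a fixed seed reproduces the dataset exactly.
    """
    truth = cfg.resolve_truth()
    rng = np.random.default_rng(cfg.seed)
    records: list[MeasurementRecord] = []
    for x1, x2 in cfg.design_points():
        for freq in truth.frequencies:
            for channel in (Channel.IN_PHASE, Channel.QUADRATURE):
                clean = truth.model(freq, channel).predict(x1, x2)
                noise = rng.normal(0.0, cfg.noise_sigma, size=cfg.replicates)
                for rep in range(cfg.replicates):
                    records.append(
                        MeasurementRecord(
                            x1=x1,
                            x2=x2,
                            frequency=freq,
                            channel=channel,
                            response=clean + noise[rep],
                            replicate=rep,
                        )
                    )
    return records


# ---------------------------------------------------------------------
# Waveform-level path


@dataclass(frozen=True)
class ChainConfig:
    """Analog-chain parameters for the waveform generation path.

    ``y0`` is the balanced baseline admittance (the reference sample as
    seen by the amplifier); the phase mismatch ``theta`` applies the
    fixed biases that water-referenced normalization must cancel.
    """

    u: float = 0.5
    theta: float = 0.0
    feedback: FeedbackConfig = field(default_factory=FeedbackConfig)
    sampling_rate: float = 1e6
    n_cycles: int = 100
    y0: complex = 1e-5 + 0j

    def drive(self, frequency: float) -> DriveConfig:
        return DriveConfig(u=self.u, frequency=frequency, theta=self.theta)


@dataclass(frozen=True)
class WaveformRecord:
    """One sampled amplifier-output record for a design point."""

    x1: float
    x2: float
    frequency: float
    replicate: int
    samples: np.ndarray


@dataclass(frozen=True)
class WaveformDataset:
    """Waveform records plus per-frequency reference (water) records."""

    records: list[WaveformRecord]
    references: dict[float, np.ndarray]
    chain: ChainConfig
    config: GeneratorConfig


def _response_to_delta(
    v_inphase: float, v_quadrature: float, chain: ChainConfig, frequency: float
) -> AdmittanceDelta:
    """Invert the zero-mismatch amplifier equation: ΔY = −V·Yf/U.

    The normalized response phasor V = V_I + j·V_Q is what the detector
    reports after reference subtraction; the admittance change that
    produces it (at θ = 0) is ΔY = −V·Yf/U.
    """
    yf = chain.feedback.admittance(2.0 * np.pi * frequency)
    dy = -complex(v_inphase, v_quadrature) * yf / chain.u
    return AdmittanceDelta(dg=dy.real, db=dy.imag)


def generate_waveform_dataset(
    cfg: GeneratorConfig, chain: ChainConfig = ChainConfig()
) -> WaveformDataset:
    """Time-domain synthetic dataset through the full analog chain.

    Each design point's truth response (plus noise at the response
    level) is mapped to an admittance delta, pushed through the
    amplifier equation — including the θ-dependent bias terms — and
    synthesized as a sampled waveform.  Per-frequency water references
    (ΔY = 0, same biases) are included so :func:`detect_dataset` can
    normalize exactly as the instrument does.
    """
    truth = cfg.resolve_truth()
    rng = np.random.default_rng(cfg.seed)
    records: list[WaveformRecord] = []
    references: dict[float, np.ndarray] = {}
    for freq in truth.frequencies:
        drive = chain.drive(freq)
        y0 = ComplexAdmittance.from_complex(chain.y0, frequency=freq)
        ref_phasor = amplifier_output(AdmittanceDelta(0.0, 0.0), y0, drive, chain.feedback)
        references[freq] = synthesize_waveform(
            ref_phasor, freq, chain.sampling_rate, chain.n_cycles
        )
    for x1, x2 in cfg.design_points():
        for freq in truth.frequencies:
            drive = chain.drive(freq)
            y0 = ComplexAdmittance.from_complex(chain.y0, frequency=freq)
            v_i = truth.model(freq, Channel.IN_PHASE).predict(x1, x2)
            v_q = truth.model(freq, Channel.QUADRATURE).predict(x1, x2)
            noise = rng.normal(0.0, cfg.noise_sigma, size=(cfg.replicates, 2))
            for rep in range(cfg.replicates):
                delta = _response_to_delta(
                    v_i + noise[rep, 0], v_q + noise[rep, 1], chain, freq
                )
                phasor = amplifier_output(delta, y0, drive, chain.feedback)
                samples = synthesize_waveform(
                    phasor, freq, chain.sampling_rate, chain.n_cycles
                )
                records.append(
                    WaveformRecord(
                        x1=x1, x2=x2, frequency=freq, replicate=rep, samples=samples
                    )
                )
    return WaveformDataset(records=records, references=references, chain=chain, config=cfg)


def detect_dataset(dataset: WaveformDataset) -> list[MeasurementRecord]:
    """Coherently detect every waveform and normalize against the reference.

    Recovers the normalized response dataset from the time-domain
    records: detect I/Q of each record and of the per-frequency water
    reference and subtract — the normalized response *is* the
    reference-subtracted amplifier output phasor, in volts.  With a
    noise-free, zero-mismatch chain this reproduces :func:`generate`'s
    responses to detection tolerance; with θ ≠ 0 the mismatch biases
    cancel exactly in the subtraction.
    """
    chain = dataset.chain
    ref_iq: dict[float, complex] = {}
    for freq, samples in dataset.references.items():
        i, q = coherent_detect(samples, freq, chain.sampling_rate)
        ref_iq[freq] = complex(i, q)
    out: list[MeasurementRecord] = []
    for rec in dataset.records:
        i, q = coherent_detect(rec.samples, rec.frequency, chain.sampling_rate)
        # bias terms sit in both target and reference; the difference is
        # -ΔY·U/Yf, which the forward map defined to equal the response
        v = complex(i, q) - ref_iq[rec.frequency]
        for channel, value in (
            (Channel.IN_PHASE, v.real),
            (Channel.QUADRATURE, v.imag),
        ):
            out.append(
                MeasurementRecord(
                    x1=rec.x1,
                    x2=rec.x2,
                    frequency=rec.frequency,
                    channel=channel,
                    response=value,
                    replicate=rec.replicate,
                )
            )
    return out
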