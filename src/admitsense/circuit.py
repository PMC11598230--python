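"""Lumped equivalent-circuit model of an electrolyte sample between two
polarized electrodes.

When an AC voltage is applied across a pair of identical coplanar
electrodes in contact with an electrolyte, ions accumulate at each
electrode surface and form an electrical double layer.  Each electrode's
polarization is modelled as a series RC pair ``Zp = Rp + 1/(jωCp)``; the
bulk sample between the electrodes is a parallel RC pair
``Zs = Rs ∥ Cs``.  The two (identical) polarization impedances sit in
series with the sample, and the whole branch reduces to one equivalent
admittance ``Y = G + jB``, conventionally quoted as a conductance ``GT``
and capacitance ``CT = B/ω``.

None of the circuit values are fixed by calibration — they are free
simulation parameters.  The calibration and inversion layers operate on
normalized responses only and never consume these parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

__all__ = [
    "INFINITE_CAPACITANCE",
    "Capacitance",
    "CircuitParams",
    "ComplexAdmittance",
    "polarization_impedance",
    "sample_impedance",
    "total_admittance",
    "simplify_to_gc",
]


class _InfiniteCapacitance:
    """Sentinel for a capacitance so large its reactance vanishes.

    An explicit marker (rather than ``math.inf``) so that limit cases are
    taken analytically instead of through floating-point division.
    """

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "INFINITE_CAPACITANCE"


INFINITE_CAPACITANCE = _InfiniteCapacitance()

#: A capacitance in farads, or the infinite-capacitance sentinel.
Capacitance = Union[float, _InfiniteCapacitance]


def _check_positive(name: str, value: float, *, allow_zero: bool = False) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    if value < 0 or (value == 0 and not allow_zero):
        bound = "non-negative" if allow_zero else "strictly positive"
        raise ValueError(f"{name} must be {bound}, got {value!r}")


@dataclass(frozen=True)
class CircuitParams:
    """Lumped circuit values for one electrode/sample/electrode branch.

    Parameters
    ----------
    rp : float
        Polarization resistance of one electrode, ohms (>= 0).
    cp : float or INFINITE_CAPACITANCE
        Polarization (double-layer) capacitance of one electrode, farads.
        The sentinel means negligible polarization reactance.
    rs : float
        Bulk sample resistance, ohms (> 0); falls as ion concentration rises.
    cs : float or INFINITE_CAPACITANCE
        Bulk sample capacitance, farads (>= 0, or the sentinel).
    """

    rp: float
    cp: Capacitance
    rs: float
    cs: Capacitance

    def __post_init__(self) -> None:
        _check_positive("rp", self.rp, allow_zero=True)
        if not isinstance(self.cp, _InfiniteCapacitance):
            _check_positive("cp", self.cp)
        _check_positive("rs", self.rs)
        if not isinstance(self.cs, _InfiniteCapacitance):
            _check_positive("cs", self.cs, allow_zero=True)


@dataclass(frozen=True)
class ComplexAdmittance:
    """Admittance ``Y = G + jB`` siemens at one probing frequency.

    ``g`` is the conductance (real part), ``b`` the susceptance
    (imaginary part); for a capacitive element ``b = ωC``.
    """

    g: float
    b: float
    frequency: float

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError(f"frequency must be positive, got {self.frequency!r}")

    @property
    def omega(self) -> float:
        return 2.0 * math.pi * self.frequency

    @property
    def as_complex(self) -> complex:
        return complex(self.g, self.b)

    @classmethod
    def from_complex(cls, y: complex, frequency: float) -> "ComplexAdmittance":
        return cls(g=y.real, b=y.imag, frequency=frequency)


def _check_omega(omega: float) -> None:
    if omega <= 0 or not math.isfinite(omega):
        raise ValueError(f"angular frequency must be positive and finite, got {omega!r}")


def polarization_impedance(params: CircuitParams, omega: float) -> complex:
    """Series-RC impedance ``Zp = Rp + 1/(jωCp)`` of one electrode.

    With the infinite-capacitance sentinel the reactance vanishes and
    ``Zp = Rp`` exactly.  The imaginary part is strictly negative for any
    finite ``Cp`` (capacitive).
    """
    _check_omega(omega)
    if isinstance(params.cp, _InfiniteCapacitance):
        return complex(params.rp, 0.0)
    return params.rp + 1.0 / (1j * omega * params.cp)


def sample_impedance(params: CircuitParams, omega: float) -> complex:
    """Parallel-RC impedance ``Zs = Rs/(1 + jωRsCs)`` of the bulk sample.

    ``Cs = 0`` gives the open-capacitor limit ``Zs = Rs``; the
    infinite-capacitance sentinel gives a short (``Zs = 0``).
    """
    _check_omega(omega)
    if isinstance(params.cs, _InfiniteCapacitance):
        return 0j
    return params.rs / (1.0 + 1j * omega * params.rs * params.cs)


def total_admittance(params: CircuitParams, omega: float) -> ComplexAdmittance:
    """Equivalent admittance ``Y = 1/(2·Zp + Zs)`` of the full branch.

    The factor 2 reflects the two identical electrodes whose polarization
    impedances are in series with the sample.  Passivity guarantees
    ``G >= 0`` for any admissible :class:`CircuitParams`.
    """
    _check_omega(omega)
    z_total = 2.0 * polarization_impedance(params, omega) + sample_impedance(params, omega)
    if z_total == 0:
        raise ZeroDivisionError("total branch impedance is zero; admittance is singular")
    y = 1.0 / z_total
    return ComplexAdmittance.from_complex(y, frequency=omega / (2.0 * math.pi))


def simplify_to_gc(y: ComplexAdmittance) -> tuple[float, float]:
    """Reduce an admittance to the conventional ``(GT, CT)`` pair.

    ``GT = G`` and ``CT = B/ω``; at the same frequency the pair
    round-trips to the original admittance.
    """
    return y.g, y.b / y.omega


def admittance_from_gc(gt: float, ct: float, frequency: float) -> ComplexAdmittance:
    """Inverse of :func:`simplify_to_gc` at the given frequency."""
    omega = 2.0 * math.pi * frequency
    return ComplexAdmittance(g=gt, b=omega * ct, frequency=frequency)
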