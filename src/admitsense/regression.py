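"""Quadratic / linear response-surface calibration.

Each (working frequency, detection channel) pair has its own surface
mapping the mixed concentrations to the normalized response

    V(x1, x2) = α0 + α1·x1 + α2·x1² + α3·x2 + α4·x2²

with ``x1`` the NaCl and ``x2`` the KCl concentration in mM, and the
response in deionized-water-referenced volts.  The linear form is the
special case ``α2 = α4 = 0``.  There is deliberately no interaction
term ``x1·x2`` in the default design (the surfaces are additive in the
two analytes); an opt-in flag adds one for exploration.

Fitting is ordinary (unweighted) least squares; the fit diagnostic ``R``
is the Pearson correlation between fitted and observed responses, which
is 1 for a perfect fit.

The package ships the published calibration of the prototype
coplanar-electrode device (quadratic and linear coefficient sets at
5 and 10 kHz) as JSON resources; :func:`reference_calibration` loads
them.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "Channel",
    "ModelForm",
    "RegressionModel",
    "MeasurementRecord",
    "CalibrationSet",
    "predict",
    "fit",
    "correlation",
    "reference_calibration",
]

WORKING_FREQUENCIES = (5_000.0, 10_000.0)


class Channel(str, enum.Enum):
    """Detection channel: in-phase tracks ΔG, quadrature tracks ΔB."""

    IN_PHASE = "in_phase"
    QUADRATURE = "quadrature"


class ModelForm(str, enum.Enum):
    QUADRATIC = "quadratic"
    LINEAR = "linear"


@dataclass(frozen=True)
class RegressionModel:
    """One calibrated response surface.

    ``alpha`` holds (α0, α1, α2, α3, α4); a linear-form model has
    α2 = α4 = 0 exactly.  ``r`` is the Pearson fit diagnostic when the
    model came from :func:`fit`, None for externally supplied
    coefficients.  ``alpha_interaction`` is the optional x1·x2
    coefficient (0 unless fitted with ``include_interaction=True``).
    """

    alpha: tuple[float, float, float, float, float]
    frequency: float
    channel: Channel
    form: ModelForm = ModelForm.QUADRATIC
    r: float | None = None
    alpha_interaction: float = 0.0

    def __post_init__(self) -> None:
        if len(self.alpha) != 5:
            raise ValueError("alpha must hold exactly five coefficients")
        object.__setattr__(self, "alpha", tuple(float(a) for a in self.alpha))
        object.__setattr__(self, "channel", Channel(self.channel))
        object.__setattr__(self, "form", ModelForm(self.form))
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.form is ModelForm.LINEAR and (self.alpha[2] != 0.0 or self.alpha[4] != 0.0):
            raise ValueError("linear-form model requires alpha2 = alpha4 = 0")
        if self.r is not None and not -1.0 <= self.r <= 1.0:
            raise ValueError("fit diagnostic r must lie in [-1, 1]")

    # -- evaluation ---------------------------------------------------
    def predict(self, x1, x2):
        """Surface value at concentrations (x1, x2) mM; vectorized."""
        x1 = np.asarray(x1, dtype=float)
        x2 = np.asarray(x2, dtype=float)
        if np.any(x1 < 0) or np.any(x2 < 0):
            raise ValueError("concentrations must be non-negative")
        a0, a1, a2, a3, a4 = self.alpha
        out = a0 + a1 * x1 + a2 * x1**2 + a3 * x2 + a4 * x2**2
        out = out + self.alpha_interaction * x1 * x2
        return float(out) if out.ndim == 0 else out

    def gradient(self, x1: float, x2: float) -> tuple[float, float]:
        """Analytic (∂V/∂x1, ∂V/∂x2) = (α1 + 2α2·x1, α3 + 2α4·x2)."""
        _, a1, a2, a3, a4 = self.alpha
        return (
            a1 + 2.0 * a2 * x1 + self.alpha_interaction * x2,
            a3 + 2.0 * a4 * x2 + self.alpha_interaction * x1,
        )


def predict(model: RegressionModel, x1, x2):
    """Functional alias for :meth:`RegressionModel.predict`."""
    return model.predict(x1, x2)


@dataclass(frozen=True)
class MeasurementRecord:
    """One normalized response observation at known concentrations."""

    x1: float
    x2: float
    frequency: float
    channel: Channel
    response: float
    replicate: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "channel", Channel(self.channel))
        for name in ("x1", "x2", "frequency", "response"):
            object.__setattr__(self, name, float(getattr(self, name)))
        object.__setattr__(self, "replicate", int(self.replicate))
        if self.x1 < 0 or self.x2 < 0:
            raise ValueError("concentrations must be non-negative")
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")


_COLUMN_NAMES = {
    ModelForm.QUADRATIC: ("1", "x1", "x1^2", "x2", "x2^2"),
    ModelForm.LINEAR: ("1", "x1", "x2"),
}


def _design_matrix(
    x1: np.ndarray, x2: np.ndarray, form: ModelForm, include_interaction: bool
) -> tuple[np.ndarray, tuple[str, ...]]:
    cols = [np.ones_like(x1), x1, x1**2, x2, x2**2]
    names = list(_COLUMN_NAMES[ModelForm.QUADRATIC])
    if form is ModelForm.LINEAR:
        cols = [cols[0], cols[1], cols[3]]
        names = list(_COLUMN_NAMES[ModelForm.LINEAR])
    if include_interaction:
        cols.append(x1 * x2)
        names.append("x1*x2")
    return np.column_stack(cols), tuple(names)


def fit(
    records: Iterable[MeasurementRecord],
    frequency: float,
    channel: Channel,
    form: ModelForm = ModelForm.QUADRATIC,
    *,
    include_interaction: bool = False,
) -> RegressionModel:
    """Ordinary least-squares fit of one response surface.

    Selects the records matching ``(frequency, channel)`` and solves the
    normal system over the design ``[1, x1, x1², x2, x2²]`` (quadratic
    columns dropped for the linear form).  Requires enough distinct
    concentration levels for the design to be full rank; a
    rank-deficient design raises with the offending column names.
    """
    channel = Channel(channel)
    form = ModelForm(form)
    sel = [r for r in records if r.frequency == frequency and r.channel == channel]
    n_min = 6 if include_interaction else (5 if form is ModelForm.QUADRATIC else 3)
    levels_min = 3 if form is ModelForm.QUADRATIC else 2
    x1 = np.array([r.x1 for r in sel], dtype=float)
    x2 = np.array([r.x2 for r in sel], dtype=float)
    y = np.array([r.response for r in sel], dtype=float)
    if len(sel) < n_min:
        raise ValueError(
            f"need at least {n_min} records for a {form.value} fit, got {len(sel)} "
            f"matching ({frequency} Hz, {channel.value})"
        )
    for name, x in (("x1", x1), ("x2", x2)):
        if np.unique(x).size < levels_min:
            raise ValueError(
                f"need at least {levels_min} distinct {name} levels for a "
                f"{form.value} fit, got {np.unique(x).size}"
            )
    design, names = _design_matrix(x1, x2, form, include_interaction)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        deficient = _deficient_columns(design, names)
        raise ValueError(
            "rank-deficient design (rank "
            f"{rank} < {design.shape[1]}); deficient column(s): {', '.join(deficient)}"
        )
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    if form is ModelForm.LINEAR:
        alpha = (beta[0], beta[1], 0.0, beta[2], 0.0)
        inter = beta[3] if include_interaction else 0.0
    else:
        alpha = tuple(beta[:5])
        inter = beta[5] if include_interaction else 0.0
    model = RegressionModel(
        alpha=alpha,
        frequency=frequency,
        channel=channel,
        form=form,
        alpha_interaction=float(inter),
    )
    try:
        return replace(model, r=correlation(model, sel))
    except ValueError:
        # constant response (or prediction): R undefined, keep it unset
        return model


def _deficient_columns(design: np.ndarray, names: Sequence[str]) -> list[str]:
    """Name the columns whose removal restores full rank."""
    out = []
    full = np.linalg.matrix_rank(design)
    for j, name in enumerate(names):
        reduced = np.delete(design, j, axis=1)
        if np.linalg.matrix_rank(reduced) == full:
            out.append(name)
    return out or list(names)


def correlation(model: RegressionModel, records: Iterable[MeasurementRecord]) -> float:
    """Pearson correlation R between model predictions and observations."""
    sel = list(records)
    if len(sel) < 3:
        raise ValueError("need at least 3 records to compute R")
    pred = np.array([model.predict(r.x1, r.x2) for r in sel])
    obs = np.array([r.response for r in sel])
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        raise ValueError("R is undefined: zero variance in predictions or observations")
    return float(stats.pearsonr(pred, obs).statistic)


# ---------------------------------------------------------------------
# Calibration sets


@dataclass(frozen=True)
class CalibrationSet:
    """Response-surface models keyed by (frequency Hz, channel)."""

    models: Mapping[tuple[float, Channel], RegressionModel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "models",
            {(float(f), Channel(c)): m for (f, c), m in dict(self.models).items()},
        )

    @classmethod
    def from_models(cls, models: Iterable[RegressionModel]) -> "CalibrationSet":
        return cls({(m.frequency, m.channel): m for m in models})

    def model(self, frequency: float, channel: Channel) -> RegressionModel:
        key = (float(frequency), Channel(channel))
        if key not in self.models:
            raise KeyError(
                f"no model calibrated for ({key[0]:g} Hz, {key[1].value}); "
                f"available: {sorted((f, c.value) for f, c in self.models)}"
            )
        return self.models[key]

    @property
    def frequencies(self) -> tuple[float, ...]:
        return tuple(sorted({f for f, _ in self.models}))

    def channel_models(self, channel: Channel) -> list[RegressionModel]:
        """Models for one channel, ordered by ascending frequency."""
        channel = Channel(channel)
        return [self.model(f, channel) for f in self.frequencies if (f, channel) in self.models]

    def __iter__(self):
        return iter(self.models.values())

    def __len__(self) -> int:
        return len(self.models)


def reference_calibration(form: ModelForm | str = ModelForm.QUADRATIC) -> CalibrationSet:
    """Published calibration of the prototype device (5 and 10 kHz).

    These coefficient sets were fitted by the device authors on real
    mixed NaCl/KCl measurements over 0.5–4 mM; they serve as the default
    ground truth for simulation and as a working calibration for the
    estimator examples.
    """
    form = ModelForm(form)
    name = f"calibration_{form.value}.json"
    payload = json.loads(resources.files("admitsense.data").joinpath(name).read_text())
    models = [
        RegressionModel(
            alpha=tuple(entry["alpha"]),
            frequency=entry["frequency_hz"],
            channel=Channel(entry["channel"]),
            form=form,
            r=entry.get("r"),
        )
        for entry in payload["models"]
    ]
    return CalibrationSet.from_models(models)
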