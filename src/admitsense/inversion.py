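"""Two-frequency inversion of the calibrated response surfaces.

Given normalized responses measured at both working frequencies, the
mixed concentrations (x1, x2) are estimated in two stages:

1. ``linear_init`` — the two linear *quadrature* surfaces form a 2×2
   linear system whose closed-form solution is a direct concentration
   estimate.  The printed slopes are nearly collinear (NaCl and KCl
   move the responses almost proportionally), so the solve is
   ill-conditioned; when the condition number exceeds a threshold a
   warning flag is raised and, if linear in-phase models are supplied,
   the system is augmented to a 4×2 least-squares solve.
2. ``newton_refine`` — Gauss–Newton iteration on the stacked residuals
   against the quadratic surfaces, started from the linear estimate,
   with the analytic Jacobian.  With exactly two equations this is the
   classical Newton–Raphson root find; with all four surfaces it is the
   natural least-squares generalization.

Single-frequency inversion can admit two admissible roots (the
quadratic surfaces are not injective over the admissible box); using
both frequencies restores uniqueness.  :func:`admissible_roots`
exposes the one-unknown root enumeration used to demonstrate this.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .regression import CalibrationSet, Channel, ModelForm, RegressionModel

__all__ = [
    "EstimationResult",
    "LinearInitResult",
    "linear_init",
    "newton_refine",
    "estimate",
    "admissible_roots",
]

#: Admissible concentration box, mM (2x the calibrated range; negative
#: concentrations are unphysical).
DEFAULT_BOX = (0.0, 8.0)
#: Condition number above which linear_init flags ill-conditioning
#: (~two decimal digits of precision lost in the 2x2 solve; the
#: published quadrature slope matrix sits at ~147).
DEFAULT_COND_THRESHOLD = 100.0

STEP_TOL = 1e-10
RESIDUAL_TOL = 1e-8
MAX_ITER = 50


@dataclass(frozen=True)
class LinearInitResult:
    """Closed-form initial estimate from the linear quadrature models."""

    x1: float
    x2: float
    condition_number: float
    condition_warning: bool
    augmented: bool


@dataclass(frozen=True)
class EstimationResult:
    """Refined concentration estimate with audit diagnostics.

    ``residual_norm`` is the 2-norm of the response residuals at the
    final iterate; for noisy measurements it floors at the noise level,
    so ``converged`` keys on the step-norm criterion (the iterate has
    stopped moving), not on the residual.
    """

    x1_hat: float
    x2_hat: float
    iterations: int
    converged: bool
    residual_norm: float
    condition_warning: bool = False
    x1_init: float | None = None
    x2_init: float | None = None

    @property
    def estimate(self) -> tuple[float, float]:
        return (self.x1_hat, self.x2_hat)


def _slope_matrix(models: Sequence[RegressionModel]) -> tuple[np.ndarray, np.ndarray]:
    m = np.array([[mod.alpha[1], mod.alpha[3]] for mod in models], dtype=float)
    b = np.array([mod.alpha[0] for mod in models], dtype=float)
    return m, b


def linear_init(
    models: Sequence[RegressionModel],
    responses: Sequence[float],
    *,
    inphase_models: Sequence[RegressionModel] | None = None,
    inphase_responses: Sequence[float] | None = None,
    cond_threshold: float = DEFAULT_COND_THRESHOLD,
) -> LinearInitResult:
    """Closed-form (x1, x2) from two linear quadrature surfaces.

    Solves ``[α1 α3]·x = y − α0`` exactly.  If the slope matrix's
    condition number exceeds ``cond_threshold`` the result carries
    ``condition_warning=True`` and, when linear in-phase models (with
    their responses) are supplied, the system is augmented to a 4×2
    least-squares solve to stabilize the estimate.  A singular slope
    matrix raises, pointing the caller at the augmented path.
    """
    if len(models) != 2 or len(responses) != 2:
        raise ValueError("linear_init needs exactly two quadrature models and responses")
    for mod in models:
        if mod.form is not ModelForm.LINEAR:
            raise ValueError("linear_init requires linear-form models")
    m, b = _slope_matrix(models)
    y = np.asarray(responses, dtype=float) - b
    det = float(np.linalg.det(m))
    if det == 0.0 or not math.isfinite(det):
        raise np.linalg.LinAlgError(
            "quadrature slope matrix is singular; supply linear in-phase models "
            "for the augmented least-squares path"
        )
    cond = float(np.linalg.cond(m))
    warning = cond > cond_threshold
    augmented = False
    if warning and inphase_models is not None:
        if inphase_responses is None or len(inphase_models) != len(inphase_responses):
            raise ValueError("inphase_models and inphase_responses must pair up")
        m_i, b_i = _slope_matrix(list(inphase_models))
        m = np.vstack([m, m_i])
        y = np.concatenate([y, np.asarray(inphase_responses, dtype=float) - b_i])
        x, *_ = np.linalg.lstsq(m, y, rcond=None)
        augmented = True
    else:
        x = np.linalg.solve(m, y)
    return LinearInitResult(
        x1=float(x[0]),
        x2=float(x[1]),
        condition_number=cond,
        condition_warning=warning,
        augmented=augmented,
    )


def _residuals(
    models: Sequence[RegressionModel], responses: np.ndarray, x: np.ndarray
) -> np.ndarray:
    return np.array([m.predict(x[0], x[1]) for m in models]) - responses


def _jacobian(models: Sequence[RegressionModel], x: np.ndarray) -> np.ndarray:
    return np.array([m.gradient(x[0], x[1]) for m in models])


def newton_refine(
    models: Sequence[RegressionModel],
    responses: Sequence[float],
    init: tuple[float, float],
    *,
    box: tuple[float, float] = DEFAULT_BOX,
    step_tol: float = STEP_TOL,
    residual_tol: float = RESIDUAL_TOL,
    max_iter: int = MAX_ITER,
) -> EstimationResult:
    """Projected Gauss–Newton refinement of (x1, x2).

    Minimizes ``Σ_k (V_k(x) − y_k)²`` over the admissible box using the
    analytic Jacobian ``∂V/∂x_i = α_{1|3} + 2α_{2|4}·x_i``.  Steps are
    solved by least squares (which tolerates a rank-deficient Jacobian)
    and damped by halving while they fail to reduce the residual.
    Non-convergence is reported in the result, never raised.
    """
    if len(models) < 2:
        raise ValueError("need at least two response surfaces to determine two unknowns")
    if len(models) != len(responses):
        raise ValueError("models and responses must pair up")
    lo, hi = box
    y = np.asarray(responses, dtype=float)
    x = np.clip(np.asarray(init, dtype=float), lo, hi)
    if not np.all(np.isfinite(x)):
        raise ValueError("initial point must be finite")
    r = _residuals(models, y, x)
    converged = bool(np.linalg.norm(r) < residual_tol)
    iterations = 0
    for iterations in range(1, max_iter + 1) if not converged else range(0):
        jac = _jacobian(models, x)
        step, *_ = np.linalg.lstsq(jac, -r, rcond=None)
        # backtracking: halve the step while it fails to reduce ||r||
        scale = 1.0
        norm_r = np.linalg.norm(r)
        for _ in range(20):
            x_new = np.clip(x + scale * step, lo, hi)
            r_new = _residuals(models, y, x_new)
            if np.linalg.norm(r_new) <= norm_r or np.allclose(x_new, x):
                break
            scale *= 0.5
        step_taken = x_new - x
        x, r = x_new, r_new
        if np.linalg.norm(step_taken) < step_tol or np.linalg.norm(r) < residual_tol:
            converged = True
            break
    return EstimationResult(
        x1_hat=float(x[0]),
        x2_hat=float(x[1]),
        iterations=iterations,
        converged=converged,
        residual_norm=float(np.linalg.norm(r)),
    )


def _conic_pair_roots(
    ma: RegressionModel,
    ya: float,
    mb: RegressionModel,
    yb: float,
    box: tuple[float, float],
    slack: float = 0.5,
) -> list[tuple[float, float]]:
    """All intersections of two response conics inside the (padded) box.

    Each surface equation ``V(x1, x2) = y`` is a conic with no x1·x2
    cross term, so eliminating the x2² term between two of them leaves
    x2 *linear* in x1; back-substitution gives a quartic in x1 whose
    real roots enumerate every simultaneous solution of the pair.  This
    is the exhaustive counterpart of a single Newton run: it can see
    roots in different basins of the nearly-collinear residual valley.
    """
    a0, a1, a2, a3, a4 = ma.alpha
    b0, b1, b2, b3, b4 = mb.alpha
    ca, cb = a0 - ya, b0 - yb
    d = a3 * b4 - b3 * a4
    scale = max(abs(a3), abs(a4), abs(b3), abs(b4), 1e-30)
    if abs(d) < 1e-12 * scale * scale:
        return []
    # x2 as a quadratic polynomial in x1 (coefficients lowest-first)
    z = -np.array(
        [ca * b4 - cb * a4, a1 * b4 - b1 * a4, a2 * b4 - b2 * a4], dtype=float
    ) / d
    poly = np.zeros(5)
    poly[:3] += np.array([ca, a1, a2])
    poly[:3] += a3 * z
    zz = np.convolve(z, z)
    poly += a4 * zz
    # trim negligible high-order coefficients so polyroots is stable
    top = np.max(np.abs(poly)) or 1.0
    deg = len(poly) - 1
    while deg > 0 and abs(poly[deg]) < 1e-14 * top:
        deg -= 1
    if deg == 0:
        return []
    roots = np.polynomial.polynomial.polyroots(poly[: deg + 1])
    lo, hi = box[0] - slack, box[1] + slack
    out = []
    for r in roots:
        if abs(r.imag) > 1e-8:
            continue
        x1 = float(r.real)
        x2 = float(np.polynomial.polynomial.polyval(x1, z))
        if lo <= x1 <= hi and lo <= x2 <= hi:
            out.append((min(max(x1, box[0]), box[1]), min(max(x2, box[0]), box[1])))
    return out


def candidate_starts(
    models: Sequence[RegressionModel],
    responses: Sequence[float],
    box: tuple[float, float] = DEFAULT_BOX,
) -> list[tuple[float, float]]:
    """Candidate (x1, x2) roots from same-channel cross-frequency pairs.

    Pairs the surfaces that share a channel across the two working
    frequencies and enumerates their conic intersections, ranked by the
    full stacked residual.  Used to globalize the Gauss–Newton
    refinement when the linear initialization lands in the wrong basin.
    """
    y = np.asarray(responses, dtype=float)
    by_channel: dict = {}
    for model, yk in zip(models, y):
        by_channel.setdefault(model.channel, []).append((model, float(yk)))
    cands: list[tuple[float, float]] = []
    for pairs in by_channel.values():
        for i in range(len(pairs)):
            for j in range(i + 1, len(pairs)):
                (ma, ya), (mb, yb) = pairs[i], pairs[j]
                cands.extend(_conic_pair_roots(ma, ya, mb, yb, box))
    if not cands:
        return []

    def stacked_sq(p):
        return float(sum((m.predict(*p) - yk) ** 2 for m, yk in zip(models, y)))

    return sorted(set(cands), key=stacked_sq)


_MODES = ("quadratic", "quadrature_only", "mixed")


def estimate(
    measurements: Mapping[tuple[float, Channel | str], float],
    *,
    quadratic: CalibrationSet,
    linear: CalibrationSet,
    mode: str = "quadratic",
    box: tuple[float, float] = DEFAULT_BOX,
    cond_threshold: float = DEFAULT_COND_THRESHOLD,
    **refine_kwargs,
) -> EstimationResult:
    """Full two-frequency estimation pipeline.

    ``measurements`` maps ``(frequency_hz, channel)`` to the normalized
    response; all four (two frequencies × two channels) must be
    present.  The linear quadrature models give the closed-form initial
    point; ``mode`` selects the surfaces the refinement stage fits:

    - ``"quadratic"`` (default): all four quadratic surfaces,
    - ``"quadrature_only"``: the two quadratic quadrature surfaces
      (exactly determined — classical Newton–Raphson),
    - ``"mixed"``: linear quadrature + quadratic in-phase surfaces.

    The result carries the initial estimate and the conditioning flag
    of the linear stage for audit.
    """
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}, got {mode!r}")
    meas = {(float(f), Channel(c)): float(v) for (f, c), v in measurements.items()}
    freqs = quadratic.frequencies
    if len(freqs) < 2:
        raise ValueError(
            "two-frequency estimation needs calibrations at two working "
            f"frequencies; calibration covers {freqs}"
        )
    missing = [
        (f, c.value)
        for f in freqs
        for c in (Channel.IN_PHASE, Channel.QUADRATURE)
        if (f, c) not in meas
    ]
    if missing:
        raise ValueError(
            "single-frequency or partial input is not supported (single-frequency "
            "inversion can be non-unique); missing (frequency, channel) pairs: "
            f"{missing}"
        )

    lin_q = linear.channel_models(Channel.QUADRATURE)
    lin_i = linear.channel_models(Channel.IN_PHASE)
    y_q = [meas[(m.frequency, Channel.QUADRATURE)] for m in lin_q]
    y_i = [meas[(m.frequency, Channel.IN_PHASE)] for m in lin_i]
    init = linear_init(
        lin_q,
        y_q,
        inphase_models=lin_i or None,
        inphase_responses=y_i or None,
        cond_threshold=cond_threshold,
    )

    if mode == "quadrature_only":
        models = quadratic.channel_models(Channel.QUADRATURE)
    elif mode == "mixed":
        models = lin_q + quadratic.channel_models(Channel.IN_PHASE)
    else:
        models = [
            quadratic.model(f, c)
            for f in freqs
            for c in (Channel.IN_PHASE, Channel.QUADRATURE)
        ]
    responses = [meas[(m.frequency, m.channel)] for m in models]
    result = newton_refine(models, responses, (init.x1, init.x2), box=box, **refine_kwargs)
    # The linear and quadratic calibrations are independent fits, so under
    # ill-conditioning the linear init can land in the wrong basin of the
    # nearly-collinear residual valley.  If the refinement did not reach
    # an exact root, retry from the algebraically enumerated candidate
    # roots and keep the best fit.
    residual_tol = refine_kwargs.get("residual_tol", RESIDUAL_TOL)
    if result.residual_norm > residual_tol:
        for start in candidate_starts(models, responses, box)[:3]:
            retry = newton_refine(models, responses, start, box=box, **refine_kwargs)
            if retry.residual_norm < result.residual_norm:
                result = retry
            if result.residual_norm < residual_tol:
                break
    return EstimationResult(
        x1_hat=result.x1_hat,
        x2_hat=result.x2_hat,
        iterations=result.iterations,
        converged=result.converged,
        residual_norm=result.residual_norm,
        condition_warning=init.condition_warning,
        x1_init=init.x1,
        x2_init=init.x2,
    )


def admissible_roots(
    model: RegressionModel,
    response: float,
    *,
    fixed_x2: float = 0.0,
    box: tuple[float, float] = DEFAULT_BOX,
    atol: float = 1e-9,
) -> list[float]:
    """All x1 roots of ``V(x1, fixed_x2) = response`` inside the box.

    With one frequency and one channel the inversion reduces to a
    quadratic in one unknown, which can have two admissible roots —
    the non-uniqueness that motivates the two-frequency procedure.
    """
    a0, a1, a2, a3, a4 = model.alpha
    c = a0 + a3 * fixed_x2 + a4 * fixed_x2**2 - response
    roots = np.roots([a2, a1, c]) if a2 != 0.0 else (
        np.array([-c / a1]) if a1 != 0.0 else np.array([])
    )
    out = [
        float(r.real)
        for r in np.atleast_1d(roots)
        if abs(r.imag) < atol and box[0] - atol <= r.real <= box[1] + atol
    ]
    return sorted(out)
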