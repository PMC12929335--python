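"""Phase-specific correction of post-contrast liver attenuation.

Iodinated contrast raises liver attenuation by an amount that depends on the
acquisition phase (arterial, portal venous, delayed).  Each phase is mapped
back to a non-contrast-equivalent value with an increasing, saturating
exponential

    corrected L = alpha + beta * (1 - exp(-L' * kappa))

where ``L'`` is the measured post-contrast mean liver attenuation in
Hounsfield units (HU).  The curve is strictly increasing in ``L'`` and
bounded above by ``alpha + beta``; its exact algebraic inverse is used by the
cohort simulator.  Coefficients are estimated from paired scans by
unweighted nonlinear least squares (Levenberg--Marquardt with the analytic
Jacobian and deterministic multi-start over the rate constant).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from types import MappingProxyType
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "CorrectionModel",
    "FitResult",
    "PUBLISHED_MODELS",
    "POST_CONTRAST_PHASES",
    "correct",
    "invert",
    "fit_correction",
    "rmse",
    "load_models",
    "dump_models",
]

POST_CONTRAST_PHASES = ("arterial", "venous", "delayed")


@dataclass(frozen=True)
class CorrectionModel:
    """Saturating exponential map from post-contrast to non-contrast HU.

    Parameters
    ----------
    phase : str
        Contrast phase the model applies to (arterial, venous or delayed).
    alpha : float
        Offset in HU; the curve's value at ``L' = 0``.
    beta : float
        Amplitude in HU; the curve saturates at ``alpha + beta``.
    kappa : float
        Rate constant in 1/HU controlling how quickly saturation is reached.
    """

    phase: str
    alpha: float
    beta: float
    kappa: float

    def __post_init__(self) -> None:
        if self.phase not in POST_CONTRAST_PHASES:
            raise ValueError(
                f"phase must be one of {POST_CONTRAST_PHASES}, got {self.phase!r}"
            )
        if not (self.beta > 0 and self.kappa > 0):
            raise ValueError("beta and kappa must be positive (increasing, saturating form)")

    @property
    def saturation(self) -> float:
        """Upper bound ``alpha + beta`` of the corrected value (HU)."""
        return self.alpha + self.beta


#: Published coefficient triples for the three post-contrast phases.
PUBLISHED_MODELS: Mapping[str, CorrectionModel] = MappingProxyType(
    {
        "arterial": CorrectionModel("arterial", -31.478, 114.8, 0.022),
        "venous": CorrectionModel("venous", -33.488, 109.094, 0.015),
        "delayed": CorrectionModel("delayed", -25.431, 96.961, 0.02),
    }
)

#: Residual noise (HU) of each correction equation on its derivation data,
#: used as the default phase-specific noise level in the cohort simulator.
DERIVATION_RMSE_HU: Mapping[str, float] = MappingProxyType(
    {"arterial": 4.7, "venous": 7.4, "delayed": 4.9}
)


def correct(l_post, model: CorrectionModel):
    """Convert post-contrast liver attenuation to a non-contrast equivalent.

    Accepts a scalar or array of HU values; defined for all finite reals.
    """
    l_post = np.asarray(l_post, dtype=float)
    out = model.alpha + model.beta * (1.0 - np.exp(-l_post * model.kappa))
    return float(out) if out.ndim == 0 else out


def invert(l_nc, model: CorrectionModel):
    """Exact inverse of :func:`correct`.

    Only defined on the open interval ``(alpha, alpha + beta)``; the curve
    saturates at ``alpha + beta`` so values at or beyond the bound have no
    finite pre-image.
    """
    arr = np.asarray(l_nc, dtype=float)
    if np.any(arr <= model.alpha) or np.any(arr >= model.saturation):
        raise ValueError(
            f"non-contrast value out of the invertible open interval "
            f"({model.alpha}, {model.saturation}) for phase {model.phase!r}"
        )
    out = -np.log(1.0 - (arr - model.alpha) / model.beta) / model.kappa
    return float(out) if out.ndim == 0 else out


def rmse(l_post, l_nc, model: CorrectionModel) -> float:
    """Root mean squared residual of ``l_nc - correct(l_post)`` (divisor n)."""
    l_post = np.asarray(l_post, dtype=float)
    l_nc = np.asarray(l_nc, dtype=float)
    if l_post.size == 0:
        raise ValueError("need at least one pair")
    resid = l_nc - correct(l_post, model)
    return float(np.sqrt(np.mean(resid**2)))


@dataclass(frozen=True)
class FitResult:
    """Outcome of a nonlinear least-squares fit of the correction curve."""

    model: CorrectionModel
    rmse: float
    n: int
    converged: bool
    iterations: int


def _model_and_jacobian(x: np.ndarray, theta: np.ndarray):
    alpha, beta, kappa = theta
    e = np.exp(-x * kappa)
    f = alpha + beta * (1.0 - e)
    jac = np.column_stack([np.ones_like(x), 1.0 - e, beta * x * e])
    return f, jac


def _levenberg_marquardt(
    x: np.ndarray,
    y: np.ndarray,
    theta0: np.ndarray,
    max_iter: int,
    tol: float,
):
    """Classic LM on the saturating exponential; rejects steps leaving beta,kappa>0."""
    theta = theta0.copy()
    f, jac = _model_and_jacobian(x, theta)
    r = y - f
    sse = float(r @ r)
    lam = 1e-3
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        a = jac.T @ jac
        g = jac.T @ r
        stepped = False
        for _ in range(50):
            damped = a + lam * np.diag(np.diag(a))
            try:
                delta = np.linalg.solve(damped, g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            trial = theta + delta
            if trial[1] <= 0 or trial[2] <= 0:
                lam *= 10.0
                continue
            f_t, jac_t = _model_and_jacobian(x, trial)
            r_t = y - f_t
            sse_t = float(r_t @ r_t)
            if np.isfinite(sse_t) and sse_t <= sse:
                improvement = sse - sse_t
                theta, f, jac, r, sse = trial, f_t, jac_t, r_t, sse_t
                lam = max(lam / 10.0, 1e-14)
                stepped = True
                if improvement <= tol * max(sse, 1e-30):
                    converged = True
                break
            lam *= 10.0
        if not stepped:
            converged = True  # no admissible step improves: at a (local) optimum
            break
        if converged:
            break
    return theta, sse, converged, it


def fit_correction(
    l_post: Iterable[float],
    l_nc: Iterable[float],
    phase: str,
    *,
    max_iter: int = 200,
    tol: float = 1e-10,
    kappa_starts: tuple[float, ...] = (0.005, 0.01, 0.02, 0.04),
) -> FitResult:
    """Fit ``(alpha, beta, kappa)`` to paired (post-contrast, non-contrast) HU.

    Unweighted least squares minimising ``sum (l_nc - f(l_post))^2``.
    Deterministic multi-start over ``kappa_starts`` guards against the rate
    constant's sensitivity to initialisation; the start with the lowest SSE
    wins.  RMSE uses divisor ``n``.
    """
    x = np.asarray(list(l_post), dtype=float)
    y = np.asarray(list(l_nc), dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("l_post and l_nc must be 1-D sequences of equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 pairs to fit 3 coefficients, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate input: l_post values are constant")

    alpha0 = float(np.min(y)) - 5.0
    beta0 = float(np.ptp(y)) + 10.0
    best = None
    for k0 in kappa_starts:
        theta0 = np.array([alpha0, beta0, k0], dtype=float)
        theta, sse, converged, iters = _levenberg_marquardt(x, y, theta0, max_iter, tol)
        if best is None or sse < best[1]:
            best = (theta, sse, converged, iters)
    theta, sse, converged, iters = best
    model = CorrectionModel(phase, float(theta[0]), float(theta[1]), float(theta[2]))
    return FitResult(
        model=model,
        rmse=float(math.sqrt(sse / x.size)),
        n=int(x.size),
        converged=converged,
        iterations=iters,
    )


def dump_models(models: Mapping[str, CorrectionModel], path) -> None:
    """Serialize a model registry to JSON (phase, alpha, beta, kappa)."""
    payload = [
        {"phase": m.phase, "alpha": m.alpha, "beta": m.beta, "kappa": m.kappa}
        for m in models.values()
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_models(path) -> dict[str, CorrectionModel]:
    """Load a model registry from JSON written by :func:`dump_models`."""
    with open(path) as fh:
        payload = json.load(fh)
    return {
        entry["phase"]: CorrectionModel(
            entry["phase"], entry["alpha"], entry["beta"], entry["kappa"]
        )
        for entry in payload
    }
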