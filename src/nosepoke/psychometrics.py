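"""Weibull psychometric function and threshold fitting.

Performance versus concentration is modelled with the Weibull psychometric
function

    psi(x) = g + (A - g) * (1 - exp(-(x / a)^b))

where ``A`` is the maximum performance, ``b`` the steepness, ``a`` the
threshold concentration and ``g`` the false-alarm floor.  ``g`` is a
property of the paradigm and is held fixed during fitting: 0.5 (chance) in
go/no-go success rates, 0 in habituation/dis-habituation dis-habituation
scores.  The remaining parameters (A, b, a) are estimated by nonlinear
least squares; the threshold estimate is the fitted ``a`` itself.

Concentrations are typically log-spaced over several decades; the fit is
carried out with ``b`` and ``a`` in log-space, which makes it exactly
equivariant under rescaling of the concentration axis.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = ["PsychometricParams", "PsychometricFit", "weibull", "fit_psychometric"]


@dataclass(frozen=True)
class PsychometricParams:
    """Weibull psychometric parameters (A, b, a, g)."""

    A: float  # maximum performance
    b: float  # steepness (> 0)
    a: float  # threshold concentration (> 0)
    g: float = 0.0  # false-alarm / floor rate

    def __post_init__(self):
        if not self.b > 0:
            raise ValueError(f"steepness b must be > 0, got {self.b}")
        if not self.a > 0:
            raise ValueError(f"threshold a must be > 0, got {self.a}")
        if self.A < self.g:
            raise ValueError(f"maximum A ({self.A}) must be >= floor g ({self.g})")

    def __call__(self, x):
        return weibull(x, self)


def weibull(x, params: PsychometricParams):
    """Evaluate the Weibull psychometric function; monotone non-decreasing in x."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("concentration x must be >= 0")
    out = params.g + (params.A - params.g) * (-np.expm1(-((x / params.a) ** params.b)))
    return float(out) if out.ndim == 0 else out


@dataclass
class PsychometricFit:
    """Result of a psychometric fit: parameters, fit quality, honesty flag."""

    params: PsychometricParams
    rss: float
    n_points: int
    converged: bool
    g_fixed: float
    message: str = ""

    @property
    def threshold(self) -> float:
        """The threshold concentration (the fitted ``a``)."""
        return self.params.a

    def to_json(self) -> str:
        return json.dumps(
            {
                "params": {
                    "A": self.params.A,
                    "b": self.params.b,
                    "a": self.params.a,
                    "g": self.params.g,
                },
                "rss": self.rss,
                "n_points": self.n_points,
                "converged": self.converged,
                "g_fixed": self.g_fixed,
                "message": self.message,
            },
            indent=1,
        )


def _initial_guess(xs: np.ndarray, ys: np.ndarray, g: float) -> tuple[float, float, float]:
    """A0 = max(y), b0 = 1, a0 = concentration at half-rise (log interpolation)."""
    a_max = float(np.max(ys))
    half = g + 0.5 * (a_max - g)
    logx = np.log(xs)
    # first crossing of the half-rise level, interpolated on the log axis
    a0 = math.exp(float(np.interp(half, ys, logx))) if a_max > g else float(
        math.exp(np.mean(logx))
    )
    return a_max, 1.0, a0


def fit_psychometric(
    xs,
    ys,
    g_fixed: float,
    init_strategy: str = "multi",
    sigma=None,
) -> PsychometricFit:
    """Fit (A, b, a) by nonlinear least squares with ``g`` held fixed.

    Parameters
    ----------
    xs, ys
        Ascending positive concentrations and the measured responses
        (success rates or dis-habituation scores).
    g_fixed
        The paradigm's floor: 0.5 for go/no-go, 0.0 for dis-habituation.
    init_strategy
        ``"multi"`` (default) refines from three jittered starting points
        and keeps the best optimum; ``"single"`` uses one start.
    sigma
        Optional per-point uncertainties (e.g. across-animal standard
        errors); residuals are divided by them, so noisier points carry
        less weight.

    A flat response profile leaves the threshold unidentifiable; the fit
    is then returned with ``converged=False`` rather than a silent guess.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.ndim != 1 or xs.shape != ys.shape:
        raise ValueError("xs and ys must be 1-D arrays of equal length")
    if sigma is not None:
        sigma = np.asarray(sigma, dtype=float)
        if sigma.shape != ys.shape or np.any(sigma < 0):
            raise ValueError("sigma must be non-negative and match ys in shape")
    if len(xs) < 3:
        raise ValueError(f"need at least 3 points to fit 3 parameters, got {len(xs)}")
    if np.any(xs <= 0):
        raise ValueError("concentrations must be > 0")
    if np.any(np.diff(xs) <= 0):
        raise ValueError("concentrations must be strictly ascending")

    scale = max(float(np.max(np.abs(ys))), abs(g_fixed), 1e-300)
    if float(np.ptp(ys)) <= 1e-9 * scale:
        # flat data: a is unidentifiable
        A0, _, a0 = _initial_guess(xs, ys, g_fixed)
        params = PsychometricParams(max(A0, g_fixed), 1.0, a0, g_fixed)
        rss = float(np.sum((ys - weibull(xs, params)) ** 2))
        return PsychometricFit(params, rss, len(xs), False, g_fixed, "flat response profile")

    A0, b0, a0 = _initial_guess(xs, ys, g_fixed)
    if sigma is None:
        weights = np.ones_like(ys)
    else:
        # floor tiny/zero sigmas so no point gets effectively infinite weight
        floor = 1e-6 * scale
        weights = 1.0 / np.maximum(sigma, floor)

    def residuals(theta):
        A, log_b, log_a = theta
        with np.errstate(over="ignore"):  # (x/a)^b -> inf is a valid saturation
            p = g_fixed + (A - g_fixed) * (
                -np.expm1(-((xs / math.exp(log_a)) ** math.exp(log_b)))
            )
        return (p - ys) * weights

    # deterministic multi-start: the half-rise heuristic plus a coarse grid
    # over slope and threshold, guarding against local minima on the b-a ridge
    starts = [(math.log(b0), math.log(a0))]
    if init_strategy == "multi":
        for b_init in (0.75, 1.5, 3.0):
            for a_init in xs[::2]:
                starts.append((math.log(b_init), math.log(a_init)))
    best = None
    for lb0, la0 in starts:
        try:
            res = least_squares(
                residuals,
                x0=[A0, lb0, la0],
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                max_nfev=4_000,
            )
        except Exception:  # pragma: no cover - optimizer failure path
            continue
        if best is None or res.cost < best.cost:
            best = res

    if best is None:  # pragma: no cover
        params = PsychometricParams(A0, b0, a0, g_fixed)
        return PsychometricFit(
            params, float("nan"), len(xs), False, g_fixed, "optimizer failed"
        )

    A, log_b, log_a = best.x
    a_hat, b_hat = math.exp(log_a), math.exp(log_b)
    # honesty checks: a threshold far outside the sampled range is not a
    # measurement, and A <= g means no response above floor was found
    in_range = xs[0] / 1e3 <= a_hat <= xs[-1] * 1e3
    identifiable = A > g_fixed and in_range and np.isfinite([A, b_hat, a_hat]).all()
    params = PsychometricParams(max(A, g_fixed), b_hat, a_hat, g_fixed)
    rss = float(np.sum((ys - weibull(xs, params)) ** 2))
    message = "" if (best.success and identifiable) else (
        "threshold outside sampled range" if not in_range else "degenerate fit"
    )
    return PsychometricFit(
        params, rss, len(xs), bool(best.success and identifiable), g_fixed, message
    )
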