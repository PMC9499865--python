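"""Five-parameter logistic (5PL) standard curves for bead-based immunoassays.

Multiplex cytokine panels quantify analytes by interpolating median
fluorescence against a standard curve fitted with a 5PL model,

    y = d + (a - d) / (1 + (x/c)^b)^g

with ``a`` the signal at zero dose, ``d`` the signal at infinite dose,
``c`` the inflection concentration (pg/ml), ``b`` the slope and ``g`` the
asymmetry.  Concentrations interpolated below the assay's lower limit of
detection are floored to 0, matching how the cohort tables encode
below-LLOD measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import BelowRangeError, FitError, ParameterError, SaturationError

__all__ = [
    "FivePLParams",
    "five_pl_forward",
    "five_pl_invert",
    "fit_standard_curve",
]


@dataclass(frozen=True)
class FivePLParams:
    a: float  # asymptote at zero dose (assay units)
    d: float  # asymptote at infinite dose
    c: float  # inflection concentration, pg/ml
    b: float  # slope
    g: float  # asymmetry

    def __post_init__(self):
        vals = (self.a, self.d, self.c, self.b, self.g)
        if not all(math.isfinite(v) for v in vals):
            raise ParameterError("5PL parameters must be finite")
        if self.c <= 0:
            raise ParameterError("inflection concentration c must be positive")
        if self.b == 0:
            raise ParameterError("slope b must be nonzero")
        if self.g <= 0:
            raise ParameterError("asymmetry g must be positive")
        if self.a == self.d:
            raise ParameterError("asymptotes a and d must differ")


def five_pl_forward(x, params: FivePLParams):
    """Signal at concentration ``x`` (pg/ml); monotone in x for b, g > 0."""
    xv = np.asarray(x, dtype=float)
    if np.any(xv < 0):
        raise ParameterError("concentration must be non-negative")
    with np.errstate(divide="ignore"):
        y = params.d + (params.a - params.d) / (
            1.0 + (xv / params.c) ** params.b
        ) ** params.g
    return float(y) if np.isscalar(x) else y


def five_pl_invert(y: float, params: FivePLParams, llod_pg_ml: float | None = None) -> float:
    """Concentration at signal ``y``; inverse of :func:`five_pl_forward`.

    ``y`` must lie strictly between the asymptotes.  A signal at or beyond
    the zero-dose asymptote means the analyte is below the detectable range:
    with ``llod_pg_ml`` set the flooring rule applies and 0 is returned,
    otherwise :class:`BelowRangeError` is raised.  A signal at or beyond the
    infinite-dose asymptote raises :class:`SaturationError`.  Interpolated
    concentrations below ``llod_pg_ml`` are also floored to 0.
    """
    a, d = params.a, params.d
    increasing = d > a
    if (increasing and y >= d) or (not increasing and y <= d):
        raise SaturationError(f"signal {y} at or beyond the high-dose asymptote {d}")
    if (increasing and y <= a) or (not increasing and y >= a):
        if y == a:
            x = 0.0
        elif llod_pg_ml is not None:
            return 0.0
        else:
            raise BelowRangeError(f"signal {y} at or below the zero-dose asymptote {a}")
    else:
        ratio = (a - d) / (y - d)  # > 1 inside the open signal range
        x = params.c * (ratio ** (1.0 / params.g) - 1.0) ** (1.0 / params.b)
    if llod_pg_ml is not None and x < llod_pg_ml:
        return 0.0
    return float(x)


def _forward_vec(x, a, d, c, b, g):
    return d + (a - d) / (1.0 + (x / c) ** b) ** g


def fit_standard_curve(standards, max_iterations: int = 20000) -> FivePLParams:
    """Least-squares 5PL fit to (known concentration, observed signal) pairs.

    Requires at least 6 standards spanning the dynamic range, including a
    zero/blank.  On noiseless standards generated from known parameters the
    fit recovers each parameter to well under 1% relative error.
    """
    pts = [(float(x), float(y)) for x, y in standards]
    if len(pts) < 6:
        raise FitError(f"need >= 6 standards, got {len(pts)}")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.any(x < 0):
        raise ParameterError("standard concentrations must be non-negative")
    if len(np.unique(x)) < 5:
        raise FitError("standards are rank deficient: need >= 5 distinct concentrations")

    order = np.argsort(x)
    a0 = y[order[0]]
    d0 = y[order[-1]]
    positive = x[x > 0]
    c0 = float(np.exp(np.mean(np.log(positive))))
    p0 = [a0, d0, c0, 1.0, 1.0]
    bounds = (
        [-np.inf, -np.inf, 1e-9, 1e-3, 1e-3],
        [np.inf, np.inf, np.inf, 50.0, 50.0],
    )
    try:
        popt, _ = curve_fit(
            _forward_vec, x, y, p0=p0, bounds=bounds, maxfev=max_iterations
        )
    except RuntimeError as exc:
        residuals = y - _forward_vec(x, *p0)
        raise FitError(f"5PL fit did not converge: {exc}", residuals=residuals) from exc
    params = FivePLParams(a=popt[0], d=popt[1], c=popt[2], b=popt[3], g=popt[4])
    residuals = y - _forward_vec(x, *popt)
    rel = np.abs(residuals) / np.maximum(np.abs(y), 1e-12)
    if np.max(rel) > 0.5:
        raise FitError("5PL fit converged to a poor solution", residuals=residuals)
    return params
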