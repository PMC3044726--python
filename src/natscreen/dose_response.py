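"""Four-parameter-logistic (4PL) dose-response fitting and IC50/pIC50
reporting.

The model is the log10-based sigmoid used by standard dose-response
software:

    y = bottom + (top - bottom) / (1 + 10^((log_ic50 - x) * hill))

with x the log10 molar concentration.  Least-squares fitting is done on
the pooled replicates with a documented deterministic initialization
(top/bottom from the data extremes, hill = 1, log_ic50 at the dose whose
mean response is nearest half-range) and the Hill slope bounded to
[0.1, 10].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

HILL_BOUNDS = (0.1, 10.0)


@dataclass(frozen=True)
class DoseResponsePoint:
    concentration: float  # molar
    response: float
    replicate: int = 0

    def __post_init__(self) -> None:
        if not self.concentration > 0:
            raise ValueError("concentration must be positive")

    @property
    def log_concentration(self) -> float:
        return math.log10(self.concentration)


@dataclass
class FourPLFit:
    top: float
    bottom: float
    hill: float
    log_ic50: float
    ic50: float
    pic50: float
    residual_sse: float
    converged: bool
    message: str = ""


def four_pl(x, top: float, bottom: float, hill: float, log_ic50: float):
    """4PL response at log10 molar concentration x."""
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ic50 - x) * hill))


def pic50(ic50: float) -> float:
    """pIC50 = -log10(IC50 in molar)."""
    if not ic50 > 0:
        raise ValueError("IC50 must be positive")
    return -math.log10(ic50)


def _initial_guess(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    top = float(y.max())
    bottom = float(y.min())
    half = (top + bottom) / 2.0
    # dose whose mean response is nearest half-range
    means: dict[float, float] = {}
    for xi, yi in zip(x, y):
        means.setdefault(xi, 0.0)
    for xi in means:
        means[xi] = float(np.mean(y[x == xi]))
    x0 = min(means, key=lambda xi: abs(means[xi] - half))
    return top, bottom, 1.0, float(x0)


def fit_ic50(points: list[DoseResponsePoint]) -> FourPLFit:
    """Pooled least-squares 4PL fit; deterministic given the data.

    Non-convergence is reported through ``converged=False`` with a
    diagnostic message rather than an exception.
    """
    x = np.array([p.log_concentration for p in points])
    y = np.array([p.response for p in points])
    if len(np.unique(x)) < 4:
        raise ValueError("need at least 4 distinct concentrations")
    # canonical order so the fit is invariant under data shuffling
    order = np.lexsort((y, x))
    x, y = x[order], y[order]
    p0 = _initial_guess(x, y)
    span = max(y.max() - y.min(), 1.0)
    lower = [y.min() - 2 * span, y.min() - 2 * span, HILL_BOUNDS[0], x.min() - 6.0]
    upper = [y.max() + 2 * span, y.max() + 2 * span, HILL_BOUNDS[1], x.max() + 6.0]
    p0 = np.clip(p0, lower, upper)
    try:
        popt, _ = curve_fit(
            four_pl, x, y, p0=p0, bounds=(lower, upper), maxfev=20000
        )
        converged = bool(np.all(np.isfinite(popt)))
        message = "" if converged else "non-finite parameters"
    except RuntimeError as exc:
        popt = np.array(p0, dtype=float)
        converged = False
        message = str(exc)
    top, bottom, hill, log_ic50 = (float(v) for v in popt)
    resid = y - four_pl(x, *popt)
    return FourPLFit(
        top=top,
        bottom=bottom,
        hill=hill,
        log_ic50=log_ic50,
        ic50=10.0**log_ic50,
        pic50=-log_ic50,
        residual_sse=float(np.sum(resid**2)),
        converged=converged,
        message=message,
    )
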