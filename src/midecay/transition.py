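"""Exponential-to-power-law transition points of composite decay fits.

A composite curve f(x) = a exp(-bx) + c x^d is exponential-dominated at
short distances and power-law-dominated at long ones. In log-log space
(g(u) = log10 f(10^u)) a pure power law is affine and a pure exponential is
concave, so the switch shows up as a dip in the second derivative g''(u).
The minimand of g'' marks the last distance where comparisons still fall
mostly within one subroutine; flooring it to an integer distance gives the
reported transition point, an estimate of subroutine length.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .corpus import CorpusSummary
from .decay import DecayModelFit, evaluate_model

__all__ = [
    "TransitionPoint",
    "log_space_curvature",
    "curvature_analytic",
    "transition_point",
    "compare_to_per_nut_length",
]

LN10 = math.log(10.0)


def _check_composite(fit: DecayModelFit):
    if fit.family != "composite":
        raise ValueError("transition analysis is defined for composite fits only")
    if fit.params["a"] <= 0 or fit.params["c"] <= 0:
        raise ValueError("both composite components must have positive amplitude")


@dataclass
class TransitionPoint:
    """Estimated switch from exponential- to power-law-dominated decay."""

    transition_distance: int
    continuous_distance: float
    u_grid: np.ndarray
    curvature: np.ndarray
    on_boundary: bool
    fit: DecayModelFit

    @property
    def reliable(self) -> bool:
        return not self.on_boundary


def log_space_curvature(fit: DecayModelFit, d_max: float, n_grid: int = 2000):
    """Second derivative of log10 f(10^u) on a uniform u-grid over [0, log10 D].

    Computed by central differences; :func:`curvature_analytic` provides the
    closed form for cross-checking. Raises if the curve is non-positive
    anywhere on the grid (not log-transformable).
    """
    _check_composite(fit)
    if d_max <= 1:
        raise ValueError("domain maximum must exceed 1")
    u = np.linspace(0.0, math.log10(d_max), n_grid)
    x = 10.0**u
    f = fit.predict(x)
    if (f <= 0).any():
        raise ValueError("composite curve is non-positive on the domain; cannot take logs")
    g = np.log10(f)
    h = u[1] - u[0]
    g2 = np.empty_like(g)
    g2[1:-1] = (g[2:] - 2 * g[1:-1] + g[:-2]) / h**2
    g2[0] = g2[1]
    g2[-1] = g2[-2]
    return u, g2


def curvature_analytic(fit: DecayModelFit, u) -> np.ndarray:
    """Closed-form g''(u) for the composite model.

    With x = 10^u, g'(u) = x f'(x)/f(x) and
    g''(u) = ln(10) * x * d/dx [x f'(x)/f(x)].
    """
    _check_composite(fit)
    a, b = fit.params["a"], fit.params["b"]
    c, d = fit.params["c"], fit.params["d"]
    x = 10.0 ** np.asarray(u, dtype=float)
    e = np.exp(-b * x)
    f = a * e + c * x**d
    f1 = -a * b * e + c * d * x ** (d - 1)
    f2 = a * b**2 * e + c * d * (d - 1) * x ** (d - 2)
    h1 = (f1 + x * f2) / f - x * f1**2 / f**2
    return LN10 * x * h1


def transition_point(fit: DecayModelFit, d_max: float, n_grid: int = 2000,
                     integer_mode: str = "floor") -> TransitionPoint:
    """Locate the curvature minimand and map it back to an element distance.

    The continuous minimand is floored ("the point immediately prior" to the
    switch); ``integer_mode="nearest"`` rounds instead. Ties break toward
    the smaller distance. A minimand on the grid boundary is flagged
    unreliable.
    """
    u, g2 = log_space_curvature(fit, d_max, n_grid)
    # endpoints carry copied curvature values; search the interior and flag
    # a minimand on its edge as a boundary solution
    i = int(np.argmin(g2[1:-1])) + 1
    on_boundary = i in (1, len(u) - 2)
    if on_boundary:
        warnings.warn("curvature minimand lies on the domain boundary; transition unreliable")
    x_star = 10.0 ** u[i]
    if integer_mode == "floor":
        dist = max(1, math.floor(x_star))
    elif integer_mode == "nearest":
        dist = max(1, round(x_star))
    else:
        raise ValueError(f"unknown integer_mode {integer_mode!r}")
    return TransitionPoint(
        transition_distance=dist,
        continuous_distance=x_star,
        u_grid=u,
        curvature=g2,
        on_boundary=on_boundary,
        fit=fit,
    )


def compare_to_per_nut_length(transition: TransitionPoint, summary: CorpusSummary) -> dict:
    """Compare a transition point with the mean per-nut action-sequence length.

    Emits a z-style margin (mean - transition)/SE and raises a flag when the
    transition is not clearly shorter than the per-nut mean (i.e. when
    transition >= mean - 2 SE).
    """
    if not summary.per_nut_available:
        return {
            "individual": summary.individual_id,
            "transition": transition.transition_distance,
            "per_nut_mean": None,
            "per_nut_se": None,
            "margin": None,
            "flag": None,
            "status": "per-nut statistics unavailable; comparison skipped",
        }
    mean = summary.mean_per_nut_length
    se = summary.se_per_nut_length
    t = transition.transition_distance
    margin = (mean - t) / se if se > 0 else math.inf
    return {
        "individual": summary.individual_id,
        "transition": t,
        "per_nut_mean": mean,
        "per_nut_se": se,
        "margin": margin,
        "flag": t >= mean - 2 * se,
        "status": "ok",
    }
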