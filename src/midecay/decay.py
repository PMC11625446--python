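"""Decay-model fitting and AICc model selection for MI decay curves.

Three candidate families describe how adjusted MI falls off with
inter-element distance x >= 1:

    exponential:  a * exp(-b x)          (Markovian chaining)
    power law:    a * x**b,  b <= 0      (fully nested hierarchy)
    composite:    a * exp(-b x) + c * x**d
                  (Markov subroutines arranged hierarchically)

All models are fitted without an additive constant — the chains estimated
from the data are irreducible and aperiodic, so MI must decay towards
zero — by Levenberg-Marquardt least squares in linear space over a
deterministic multi-start grid. Fits are compared by small-sample AICc with
the Gaussian log-likelihood implied by the residual sum of squares; the
error variance counts as a parameter, so K = n_coefficients + 1.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lmfit import Parameters, minimize
from sklearn.base import BaseEstimator

__all__ = [
    "FAMILIES",
    "DecayModelFit",
    "ModelComparison",
    "FitInfeasibleError",
    "fit_decay_model",
    "gaussian_ll_and_aicc",
    "compare_models",
    "akaike_weights",
    "DecayModelSelector",
    "evaluate_model",
]

FAMILIES = ("exponential", "power_law", "composite")


class FitInfeasibleError(RuntimeError):
    """Raised when a family cannot be fitted (too few points / no convergence)."""

    def __init__(self, family: str, message: str):
        self.family = family
        super().__init__(f"{family}: {message}")


def evaluate_model(family: str, params: dict, x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if family == "exponential":
        return params["a"] * np.exp(-x * params["b"])
    if family == "power_law":
        return params["a"] * np.power(x, params["b"])
    if family == "composite":
        return params["a"] * np.exp(-x * params["b"]) + params["c"] * np.power(x, params["d"])
    raise ValueError(f"unknown family {family!r}")


@dataclass
class DecayModelFit:
    """A fitted decay model with its Gaussian likelihood and AICc."""

    family: str
    params: dict
    rss: float
    n_points: int
    converged: bool
    n_restarts: int
    ll: Optional[float] = None
    k: Optional[int] = None
    aicc: Optional[float] = None

    @property
    def n_coefficients(self) -> int:
        return len(self.params)

    def predict(self, x) -> np.ndarray:
        return evaluate_model(self.family, self.params, x)


def _param_grid(family: str, y_max: float):
    amps = (0.1, 1.0, max(y_max, 1e-3))
    rates = (0.05, 0.3, 1.0)
    powers = (-0.1, -0.5, -1.5)
    if family == "exponential":
        for a, b in itertools.product(amps, rates):
            yield {"a": a, "b": b}
    elif family == "power_law":
        for a, b in itertools.product(amps, powers):
            yield {"a": a, "b": b}
    else:
        for a, b, c, d in itertools.product(amps, rates, amps, powers):
            yield {"a": a, "b": b, "c": c, "d": d}


def _make_params(family: str, start: dict) -> Parameters:
    p = Parameters()
    if family == "exponential":
        p.add("a", value=start["a"], min=0.0)
        p.add("b", value=start["b"], min=0.0)
    elif family == "power_law":
        p.add("a", value=start["a"], min=0.0)
        p.add("b", value=start["b"], max=0.0)
    else:
        p.add("a", value=start["a"], min=0.0)
        p.add("b", value=start["b"], min=0.0)
        p.add("c", value=start["c"], min=0.0)
        p.add("d", value=start["d"], max=0.0)
    return p


def fit_decay_model(x, y, family: str, compute_aicc: bool = True) -> DecayModelFit:
    """Least-squares fit of one decay family over the deterministic start grid.

    Negative y values (noise-floor fluctuations of adjusted MI) are retained.
    Raises :class:`FitInfeasibleError` when there are too few points for the
    family or no start converges.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if (x < 1).any():
        raise ValueError("decay models are defined for distances >= 1")
    if not np.isfinite(y).all():
        raise ValueError("y contains non-finite values")
    n_coef = 4 if family == "composite" else 2
    k = n_coef + 1
    if len(x) < k + 2:
        raise FitInfeasibleError(family, f"{len(x)} points < required {k + 2}")

    def residual(pars):
        vals = {name: pars[name].value for name in pars}
        return evaluate_model(family, vals, x) - y

    best = None
    n_starts = 0
    for start in _param_grid(family, float(np.max(y))):
        n_starts += 1
        try:
            res = minimize(residual, _make_params(family, start), method="leastsq")
        except Exception:
            continue
        rss = float(np.sum(res.residual**2))
        if res.success and (best is None or rss < best[0]):
            best = (rss, {name: float(res.params[name].value) for name in res.params})
    if best is None:
        raise FitInfeasibleError(family, "no start converged")
    fit = DecayModelFit(
        family=family,
        params=best[1],
        rss=best[0],
        n_points=len(x),
        converged=True,
        n_restarts=n_starts,
    )
    if compute_aicc:
        gaussian_ll_and_aicc(fit)
    return fit


def gaussian_ll_and_aicc(fit: DecayModelFit) -> DecayModelFit:
    """Attach the Gaussian log-likelihood, K, and AICc to a converged fit.

    LL = -(n/2) [ln(2 pi) + ln(RSS/n) + 1]; K counts the coefficients plus
    the error variance; AICc = 2K - 2LL + 2K(K+1)/(n - K - 1).
    """
    if not fit.converged:
        raise ValueError("AICc requires a converged fit")
    n = fit.n_points
    k = fit.n_coefficients + 1
    if n <= k + 1:
        raise FitInfeasibleError(fit.family, f"AICc undefined for n={n}, K={k}")
    rss = max(fit.rss, np.finfo(float).tiny)
    ll = -(n / 2.0) * (math.log(2 * math.pi) + math.log(rss / n) + 1.0)
    fit.ll = ll
    fit.k = k
    fit.aicc = 2 * k - 2 * ll + (2 * k * (k + 1)) / (n - k - 1)
    return fit


def akaike_weights(delta: Sequence[float]) -> np.ndarray:
    """Akaike weights w_i = exp(-delta_i / 2) / sum_j exp(-delta_j / 2)."""
    d = np.asarray(delta, dtype=float)
    w = np.exp(-d / 2.0)
    return w / w.sum()


@dataclass
class ModelComparison:
    """AICc ranking of candidate families with Akaike weights."""

    table: pd.DataFrame
    tie_threshold: float
    best_set: list = field(init=False)
    sole_best: Optional[str] = field(init=False)

    def __post_init__(self):
        under = self.table.loc[self.table["dAICc"] < self.tie_threshold, "family"]
        self.best_set = list(under)
        self.sole_best = self.best_set[0] if len(self.best_set) == 1 else None


def compare_models(fits: Sequence[DecayModelFit], tie_threshold: float = 2.0) -> ModelComparison:
    """Rank fitted families by AICc.

    dAICc is relative to the minimum; families with dAICc below
    ``tie_threshold`` are "competing" — a sole best model exists only when
    exactly one family sits under the threshold.
    """
    fits = [f for f in fits if f.converged and f.aicc is not None]
    if not fits:
        raise FitInfeasibleError("comparison", "no converged fits to compare")
    rows = sorted(fits, key=lambda f: f.aicc)
    aicc = np.array([f.aicc for f in rows])
    delta = aicc - aicc[0]
    w = akaike_weights(delta)
    table = pd.DataFrame(
        {
            "family": [f.family for f in rows],
            "K": [f.k for f in rows],
            "AICc": aicc,
            "dAICc": delta,
            "AICc_wt": w,
            "cum_wt": np.cumsum(w),
            "LL": [f.ll for f in rows],
        }
    )
    return ModelComparison(table=table, tie_threshold=tie_threshold)


class DecayModelSelector(BaseEstimator):
    """Fit all three decay families to (distance, MI_adj) data and rank them.

    Parameters
    ----------
    families : tuple of str
        Candidate families to fit.
    tie_threshold : float
        dAICc below which models are treated as competing.

    Attributes
    ----------
    fits_ : dict family -> DecayModelFit (converged families only)
    failures_ : dict family -> str (reason a family could not be fitted)
    comparison_ : ModelComparison
    best_family_ : str or None
        The sole best family, or None when models compete.
    """

    def __init__(self, families=FAMILIES, tie_threshold: float = 2.0):
        self.families = families
        self.tie_threshold = tie_threshold

    def fit(self, X, y):
        self.fits_ = {}
        self.failures_ = {}
        for family in self.families:
            try:
                self.fits_[family] = fit_decay_model(X, y, family)
            except FitInfeasibleError as exc:
                self.failures_[family] = str(exc)
        if not self.fits_:
            raise FitInfeasibleError("all", "no family could be fitted")
        self.comparison_ = compare_models(list(self.fits_.values()), self.tie_threshold)
        self.best_family_ = self.comparison_.sole_best
        return self

    def predict(self, X, family: Optional[str] = None) -> np.ndarray:
        """Evaluate the best (or a named) fitted family at distances X."""
        if family is None:
            family = self.best_family_ or self.comparison_.table["family"].iloc[0]
        return self.fits_[family].predict(X)
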