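"""Mutual-information decay curves for categorical sequences.

For a concatenated action stream, MI between elements a distance d apart is

    MI_hat(d) = S_hat(X) + S_hat(Y) - S_hat(X, Y)

with X the first members and Y the second members of all ordered pairs
(s_i, s_{i+d}), each entropy Grassberger-corrected on the paired subsample.
A chance floor MI_sh(d) is built by uniformly permuting the whole stream
(one shuffle per replicate, reused across distances) and recomputing the
joint entropy against the observed marginals. MI_adj = MI_hat - mean MI_sh,
and the maximum dependency distance is the last distance before
MI_hat - upper-95%-CI(MI_sh) first drops below zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .corpus import Corpus, TokenStream
from .entropy import LN2, grassberger_entropy, npsi_table, plugin_entropy

__all__ = [
    "DistancePairTable",
    "MIDecayCurve",
    "MIDecayEstimator",
    "pairs_at_distance",
    "mi_at_distance",
    "estimate_decay_curve",
    "max_dependency_distance",
]


@dataclass
class DistancePairTable:
    """Joint and marginal counts of symbol pairs at one inter-element distance."""

    distance: int
    x_counts: dict
    y_counts: dict
    joint: dict
    n_pairs: int


def pairs_at_distance(stream: TokenStream, d: int) -> DistancePairTable:
    """Enumerate ordered pairs (s_i, s_{i+d}) and tabulate counts.

    At d=0 each element pairs with itself, so the joint table is diagonal.
    """
    N = stream.N
    if not 0 <= d < N:
        raise ValueError(f"distance {d} out of range for stream of length {N}")
    syms = stream.symbols
    first = syms[: N - d]
    second = syms[d:]
    joint: dict = {}
    xc: dict = {}
    yc: dict = {}
    for a, b in zip(first, second):
        joint[(a, b)] = joint.get((a, b), 0) + 1
        xc[a] = xc.get(a, 0) + 1
        yc[b] = yc.get(b, 0) + 1
    return DistancePairTable(distance=d, x_counts=xc, y_counts=yc, joint=joint, n_pairs=N - d)


def mi_at_distance(table: DistancePairTable, corrected: bool = True) -> float:
    """MI_hat (bits) from a pair table: S(X) + S(Y) - S(X, Y)."""
    est = grassberger_entropy if corrected else plugin_entropy
    sx = est(list(table.x_counts.values())).value
    sy = est(list(table.y_counts.values())).value
    sxy = est(list(table.joint.values())).value
    return sx + sy - sxy


@dataclass
class MIDecayCurve:
    """Per-distance MI estimates with their permutation chance floor."""

    distances: np.ndarray
    mi_hat: np.ndarray
    mi_sh_mean: np.ndarray
    mi_sh_lo: np.ndarray
    mi_sh_hi: np.ndarray
    n_permutations: int
    N: int
    seed: Optional[int] = None
    mi_adj: np.ndarray = field(init=False)
    margin: np.ndarray = field(init=False)

    def __post_init__(self):
        lengths = {len(self.distances), len(self.mi_hat), len(self.mi_sh_mean),
                   len(self.mi_sh_lo), len(self.mi_sh_hi)}
        if len(lengths) != 1:
            raise ValueError("curve arrays must share one length")
        self.mi_adj = self.mi_hat - self.mi_sh_mean
        self.margin = self.mi_hat - self.mi_sh_hi

    @property
    def d_max(self) -> int:
        return int(self.distances[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "d": self.distances,
                "mi_hat": self.mi_hat,
                "mi_sh_mean": self.mi_sh_mean,
                "mi_sh_lo": self.mi_sh_lo,
                "mi_sh_hi": self.mi_sh_hi,
                "mi_adj": self.mi_adj,
                "margin": self.margin,
            }
        )

    def fit_points(self, max_distance: int, drop_last_point: bool = False):
        """(x, y) arrays over distances 1..max_distance for decay fitting.

        Distance 0 measures entropy rather than decay and is always
        excluded; ``drop_last_point`` trims the final distance, the
        convention under which reported AICc tables back-solve.
        """
        hi = max_distance - 1 if drop_last_point else max_distance
        mask = (self.distances >= 1) & (self.distances <= hi)
        return self.distances[mask].astype(float), self.mi_adj[mask]


def max_dependency_distance(curve: MIDecayCurve):
    """Maximum distance with MI significantly above chance.

    Returns ``(distance, censored)``: the distance immediately before the
    first d >= 1 where MI_hat falls below the permutation upper 95% CI, or
    (d_max, True) if the margin never goes negative within the window.
    """
    d = curve.distances
    margin = curve.margin
    for i in range(len(d)):
        if d[i] >= 1 and margin[i] < 0:
            return int(d[i]) - 1, False
    return curve.d_max, True


class MIDecayEstimator(BaseEstimator):
    """Estimate an MI decay curve with a permutation chance floor.

    Parameters
    ----------
    d_max : int
        Largest inter-element distance examined (window 0..d_max).
    n_perm : int
        Number of whole-stream permutations for the chance floor; each
        replicate is shuffled once and reused across all distances.
    ci : tuple of float
        Percentiles of the permutation MI_sh distribution used as the
        95% interval.
    corrected : bool
        Grassberger-corrected entropies (True) or plug-in (False).
    strict_literal : bool
        Evaluate the mixed-base printed form of the Grassberger estimator.
    exclude_cross_boundary_pairs : bool
        Skip pairs spanning two source sequences (requires fitting on a
        :class:`~midecay.corpus.Corpus`). Default False: the concatenated
        stream carries no boundary markers.
    random_state : int or None
        Seed for the permutation generator.

    Attributes
    ----------
    curve_ : MIDecayCurve
    max_distance_ : int
        Maximum significant dependency distance.
    censored_ : bool
        True when the margin never fell below zero within the window.
    """

    def __init__(self, d_max: int = 100, n_perm: int = 1000, ci=(2.5, 97.5),
                 corrected: bool = True, strict_literal: bool = False,
                 exclude_cross_boundary_pairs: bool = False, random_state=None):
        self.d_max = d_max
        self.n_perm = n_perm
        self.ci = ci
        self.corrected = corrected
        self.strict_literal = strict_literal
        self.exclude_cross_boundary_pairs = exclude_cross_boundary_pairs
        self.random_state = random_state

    # -- internals -----------------------------------------------------
    def _entropy_fn(self, N_total):
        if self.corrected:
            tab = npsi_table(N_total)
            if self.strict_literal:
                def H(counts, Np):
                    return math.log2(Np) - float(tab[counts].sum()) / Np
            else:
                def H(counts, Np):
                    return (math.log(Np) - float(tab[counts].sum()) / Np) / LN2
        else:
            def H(counts, Np):
                c = counts[counts > 0]
                p = c / Np
                return float(-np.sum(p * np.log2(p)))
        return H

    def fit(self, X, y=None):
        """Compute the decay curve for a TokenStream or Corpus."""
        labels = None
        if isinstance(X, Corpus):
            if self.exclude_cross_boundary_pairs:
                labels = X.sequence_labels
            X = X.concatenated
        if not isinstance(X, TokenStream):
            X = TokenStream(tuple(X))
        if X.N < 2:
            raise ValueError("stream must contain at least 2 symbols")
        if self.n_perm < 2:
            raise ValueError("n_perm must be at least 2")

        codes, alphabet = X.codes()
        N = len(codes)
        K = len(alphabet)
        d_max = self.d_max
        if d_max >= N:
            warnings.warn(
                f"d_max={d_max} >= stream length {N}; truncating window to {N - 1}"
            )
            d_max = N - 1

        H = self._entropy_fn(N)
        n_d = d_max + 1
        mi_hat = np.empty(n_d)
        s_marg = np.empty((n_d, 2))
        masks = [None] * n_d
        for d in range(n_d):
            x = codes[: N - d] if d else codes
            yv = codes[d:] if d else codes
            if labels is not None and d:
                m = labels[: N - d] == labels[d:]
                masks[d] = m
                x, yv = x[m], yv[m]
            Np = len(x)
            if Np == 0:
                mi_hat[d] = np.nan
                s_marg[d] = np.nan
                continue
            sx = H(np.bincount(x, minlength=K), Np)
            sy = H(np.bincount(yv, minlength=K), Np)
            sxy = H(np.bincount(x * K + yv, minlength=K * K), Np)
            mi_hat[d] = sx + sy - sxy
            s_marg[d] = (sx, sy)

        rng = np.random.default_rng(self.random_state)
        mi_sh = np.empty((self.n_perm, n_d))
        for p in range(self.n_perm):
            perm = rng.permutation(codes)
            for d in range(n_d):
                x = perm[: N - d] if d else perm
                yv = perm[d:] if d else perm
                if masks[d] is not None:
                    x, yv = x[masks[d]], yv[masks[d]]
                Np = len(x)
                if Np == 0:
                    mi_sh[p, d] = np.nan
                    continue
                sxy = H(np.bincount(x * K + yv, minlength=K * K), Np)
                mi_sh[p, d] = s_marg[d, 0] + s_marg[d, 1] - sxy

        lo, hi = np.percentile(mi_sh, self.ci, axis=0)
        self.curve_ = MIDecayCurve(
            distances=np.arange(n_d),
            mi_hat=mi_hat,
            mi_sh_mean=mi_sh.mean(axis=0),
            mi_sh_lo=lo,
            mi_sh_hi=hi,
            n_permutations=self.n_perm,
            N=N,
            seed=self.random_state,
        )
        self.max_distance_, self.censored_ = max_dependency_distance(self.curve_)
        return self

    def transform(self, X=None) -> pd.DataFrame:
        """Return the fitted curve as a tidy per-distance frame."""
        if not hasattr(self, "curve_"):
            raise AttributeError("estimator is not fitted")
        return self.curve_.to_frame()


def estimate_decay_curve(stream, d_max: int = 100, n_perm: int = 1000,
                         seed=None, **kwargs) -> MIDecayCurve:
    """Functional wrapper over :class:`MIDecayEstimator`."""
    est = MIDecayEstimator(d_max=d_max, n_perm=n_perm, random_state=seed, **kwargs)
    est.fit(stream)
    return est.curve_
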