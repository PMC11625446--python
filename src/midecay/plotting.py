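"""Optional matplotlib figures (MI decay curves with overlaid fits)."""

from __future__ import annotations

import numpy as np

from .decay import DecayModelFit

STYLES = {
    "exponential": dict(color="tab:green", linestyle="-."),
    "power_law": dict(color="tab:red", linestyle="--"),
    "composite": dict(color="tab:blue", linestyle="-"),
}


def plot_decay_curve(curve, fits=None, max_distance=None, ax=None, title=None):
    """MI_adj vs distance with the permutation CI band and fitted models.

    ``fits`` maps family name -> :class:`DecayModelFit`. Returns the axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    d = curve.distances
    ax.fill_between(d, curve.mi_sh_lo - curve.mi_sh_mean, curve.mi_sh_hi - curve.mi_sh_mean,
                    alpha=0.25, color="grey", label="permutation 95% CI")
    ax.plot(d, curve.mi_adj, "o", ms=3, color="purple", label="MI_adj")
    if fits:
        hi = max_distance or curve.d_max
        x = np.linspace(1, hi, 300)
        for family, fit in fits.items():
            ax.plot(x, fit.predict(x), label=family, **STYLES.get(family, {}))
    if max_distance is not None:
        ax.axvline(max_distance, color="k", lw=0.8, alpha=0.5)
    ax.set_xlabel("inter-element distance")
    ax.set_ylabel("adjusted MI (bits)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    return ax
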