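"""Diagnostic plots: multistart waterfalls and profile-likelihood curves."""

from __future__ import annotations

import numpy as np

from .estimation import MultistartResult
from .profile_likelihood import ProfileResult


def waterfall_plot(result: MultistartResult, ax=None):
    """Sorted log-likelihoods of all converged starts; a plateau at the top
    marks the basin of the (putative) global optimum."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ll = result.waterfall()
    ax.plot(np.arange(1, len(ll) + 1), ll, "o-", ms=3)
    ax.axhline(ll[0] - result.threshold / 2.0, color="grey", ls="--", lw=1,
               label="joint 95% threshold")
    ax.set_xlabel("start (sorted)")
    ax.set_ylabel("log-likelihood")
    ax.legend()
    return ax


def profile_plot(prof: ProfileResult, ax=None):
    """One profile with its optimum, bounds and the CI threshold line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ok = np.isfinite(prof.pl)
    ax.plot(prof.grid[ok], prof.pl[ok], "o-", ms=3)
    ax.axhline(prof.threshold, color="grey", ls="--", lw=1,
               label=f"{prof.alpha:.0%} threshold")
    ax.axvline(prof.z_hat_value, color="k", lw=0.8)
    for b in (prof.lb, prof.ub):
        ax.axvline(b, color="red", lw=0.8, alpha=0.4)
    ax.set_xlabel(f"log10 {prof.name}")
    ax.set_ylabel("profile log-likelihood")
    ax.legend()
    return ax
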