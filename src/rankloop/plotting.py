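"""Simple figures: rank-aggression profiles and chain statistics with bands."""

from __future__ import annotations

import numpy as np

from .model import WindowResult

__all__ = ["plot_profile", "plot_chain_statistics"]


def plot_profile(w: WindowResult, ax=None, per_1000_min: bool = True):
    """Observed (smoothed) R(Delta) with the null band for one window."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    scale = 1000.0 if per_1000_min else 1.0
    d = w.profile.deltas
    ax.plot(d, w.profile_smoothed.values * scale, "-", color="firebrick",
            label="observed (+-1 rank avg)")
    if w.null_profile_mean is not None:
        m, s = w.null_profile_mean * scale, w.null_profile_sd * scale
        ax.plot(d, m, "--", color="steelblue", label="null mean")
        ax.fill_between(d, m - s, m + s, color="steelblue", alpha=0.3,
                        label="null 1 sigma")
    if w.boot_profile_sd is not None:
        r = w.profile.values * scale
        s = w.boot_profile_sd * scale
        ax.fill_between(d, r - s, r + s, color="firebrick", alpha=0.2)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel(r"rank difference $\Delta$ (positive = down the hierarchy)")
    unit = "acts / individual / 1000 min" if per_1000_min else "acts / individual / min"
    ax.set_ylabel(rf"$R(\Delta)$ [{unit}]")
    ax.set_title(f"window {w.label}")
    ax.legend(fontsize=8)
    return ax


def plot_chain_statistics(w: WindowResult, statistic: str = "W", ax=None):
    """W(n) or T(n) vs chain length with the null band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ns = [c.n for c in w.chains if statistic == "W" or c.n >= 2]
    obs = [getattr(c, statistic) for c in w.chains if statistic == "W" or c.n >= 2]
    mu = [getattr(c, f"{statistic}_null_mean") for c in w.chains
          if statistic == "W" or c.n >= 2]
    sd = [getattr(c, f"{statistic}_null_sd") for c in w.chains
          if statistic == "W" or c.n >= 2]
    ax.plot(ns, obs, "o-", color="firebrick", label="observed")
    mu, sd = np.asarray(mu), np.asarray(sd)
    if np.all(np.isfinite(mu)):
        ax.plot(ns, mu, "--", color="steelblue", label="null mean")
        ax.fill_between(ns, mu - sd, mu + sd, color="steelblue", alpha=0.3)
    if statistic == "T":
        ax.axhline(0, color="grey", lw=0.5)
    ax.set_xlabel("chain length n (edges)")
    ax.set_ylabel(f"{statistic}(n)")
    ax.set_title(f"window {w.label}")
    ax.legend(fontsize=8)
    return ax
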