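"""Thin matplotlib helpers: banded p-value histograms and joint
(cos(theta), v) densities.  Visualization only — no statistics are decided
here."""

from __future__ import annotations

import numpy as np

from .reference import BandedHistogram


def plot_banded_histogram(band: BandedHistogram, ax=None):
    """Observed p-value histogram on top of the reference confidence band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    centers = 0.5 * (band.edges[:-1] + band.edges[1:])
    width = band.edges[1] - band.edges[0]
    ax.bar(centers, band.hi - band.lo, bottom=band.lo, width=width,
           color="0.8", label="reference band")
    if band.q_obs is not None:
        ax.step(band.edges, np.r_[band.q_obs, band.q_obs[-1]], where="post",
                color="tab:orange", label="observed")
    ax.set_xlabel(r"$\hat{p}$")
    ax.set_ylabel("probability per bin")
    ax.set_xlim(0, 1)
    ax.legend()
    return ax


def plot_momentary_density(cos_theta, speed, ax=None, gridsize=120):
    """Kernel-density map of the joint (cos(theta), v) distribution.

    Gaussian product kernel with scipy's rule-of-thumb bandwidth; intended
    as a qualitative overview of the available movement steps.
    """
    import matplotlib.pyplot as plt
    from scipy.stats import gaussian_kde

    cos_theta = np.asarray(cos_theta, float)
    speed = np.asarray(speed, float)
    if ax is None:
        _, ax = plt.subplots()
    kde = gaussian_kde(np.vstack([cos_theta, speed]))
    xg = np.linspace(-1, 1, gridsize)
    yg = np.linspace(0, max(speed.max(), 1e-9), gridsize)
    xx, yy = np.meshgrid(xg, yg)
    zz = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(xx.shape)
    ax.pcolormesh(xx, yy, zz, shading="auto", cmap="viridis")
    ax.set_xlabel(r"$\cos(\theta)$")
    ax.set_ylabel("speed (µm/min)")
    return ax
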