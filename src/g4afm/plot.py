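"""Quick-look plotting helpers (matplotlib, Agg-safe)."""

from __future__ import annotations

import numpy as np

from .height_classes import MaskedHistogram, MixtureFit
from .profile_stats import GaussianFit, PeakSet
from .topograph import Topograph
from .trace import HeightProfile


def plot_topograph(topo: Topograph, ax=None, zrange_nm=None, cmap="afmhot"):
    """Render a height map with a nm colour scale and nm axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    w, h = topo.extent_nm
    vmin, vmax = zrange_nm if zrange_nm else (None, None)
    im = ax.imshow(topo.heights, extent=(0, w, h, 0), cmap=cmap,
                   vmin=vmin, vmax=vmax)
    ax.set_xlabel("x (nm)")
    ax.set_ylabel("y (nm)")
    ax.figure.colorbar(im, ax=ax, label="height (nm)")
    return ax


def plot_profile(profile: HeightProfile, peaks: PeakSet | None = None, ax=None):
    """Height profile along a trace, optionally with identified peaks."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(profile.arc_positions_nm, profile.heights_nm, lw=1)
    if peaks is not None and len(peaks):
        ax.plot(peaks.positions_nm, profile.heights_nm[peaks.indices], "x", ms=6)
    ax.set_xlabel("position along trace (nm)")
    ax.set_ylabel("height (nm)")
    return ax


def plot_separation_histogram(values, fit: GaussianFit, ax=None):
    """Peak-peak separation histogram with its Gaussian fit."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    width = (fit.domain[1] - fit.domain[0]) / 20
    edges = np.arange(fit.domain[0], fit.domain[1] + width, width)
    ax.hist(values, bins=edges, alpha=0.6)
    x = np.linspace(*fit.domain, 200)
    ax.plot(x, fit.amplitude * np.exp(-0.5 * ((x - fit.mean) / fit.sd) ** 2))
    ax.set_xlabel("peak-peak separation (nm)")
    ax.set_ylabel("count")
    return ax


def plot_height_classes(hist: MaskedHistogram, mix: MixtureFit | None = None, ax=None):
    """Masked pixel-height distribution with the two-component fit."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.bar(hist.bin_centers_nm, hist.counts, width=hist.bin_width_nm, alpha=0.6)
    if mix is not None:
        x = np.linspace(hist.bin_centers_nm[0], hist.bin_centers_nm[-1], 400)
        for comp in mix.components:
            ax.plot(x, comp.amplitude * np.exp(-0.5 * ((x - comp.mean) / comp.sd) ** 2))
    ax.set_xlabel("pixel height (nm)")
    ax.set_ylabel("count")
    return ax
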