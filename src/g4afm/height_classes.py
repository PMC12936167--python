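"""Masked pixel-height distributions and two-class height classification.

On surfaces carrying both tall filaments (G4) and thin polymeric chains, the
histogram of structure-pixel heights (background subtracted by flattening,
background pixels excluded by the grain mask) is bimodal.  A least-squares
sum of two Gaussians fitted to that histogram resolves the two classes;
individual structures are then labelled by the nearest component mean of
their mean apex height.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from scipy.optimize import curve_fit

from .profile_stats import GaussianFit, StructureStats
from .topograph import Topograph

__all__ = [
    "MaskedHistogram",
    "MixtureFit",
    "build_histogram_mask",
    "masked_height_distribution",
    "fit_two_gaussians",
    "classify_structure",
]

DEFAULT_HEIGHT_BIN_NM = 0.1


@dataclass
class MaskedHistogram:
    """Histogram of structure-pixel heights (uniform bins)."""

    bin_centers_nm: np.ndarray
    counts: np.ndarray
    bin_width_nm: float
    n_pixels: int
    mask_provenance: dict

    def __post_init__(self) -> None:
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


@dataclass
class MixtureFit:
    """Two Gaussian components sorted by mean (low = RNA_like, high = G4)."""

    low: GaussianFit
    high: GaussianFit
    degenerate: bool = False

    @property
    def components(self) -> tuple[GaussianFit, GaussianFit]:
        return (self.low, self.high)


def build_histogram_mask(
    labels: np.ndarray, dilate_px: int = 1, erode_px: int = 4
) -> np.ndarray:
    """Pixel mask used for the height histogram.

    The grain mask is dilated by ``dilate_px`` (to recover the full structure
    extent lost to thresholding) and then eroded by ``erode_px``.  The net
    trim (default 3 px ~ 1.5 nm) matches the width of the tip-broadened edge
    band: edge-slope pixels report tip geometry rather than structure height,
    and a shallower trim leaves enough of them to drag the fitted component
    means visibly below the apex populations.
    """
    mask = labels > 0
    if dilate_px > 0:
        mask = ndimage.binary_dilation(mask, iterations=dilate_px)
    if erode_px > 0:
        eroded = ndimage.binary_erosion(mask, iterations=erode_px)
        # do not let small grains vanish entirely
        mask = eroded if eroded.any() else mask
    return mask


def masked_height_distribution(
    topo: Topograph,
    labels: np.ndarray,
    bin_width_nm: float = DEFAULT_HEIGHT_BIN_NM,
    domain: tuple[float, float] | None = None,
    dilate_px: int = 1,
    erode_px: int = 4,
) -> MaskedHistogram:
    """Histogram the heights of structure pixels only.

    ``labels`` is a grain label image (0 = background) or a boolean mask.
    ``domain`` fixes the bin range so histograms from several images can be
    summed bin-by-bin; by default it spans the masked data.
    """
    mask = build_histogram_mask(np.asarray(labels), dilate_px, erode_px)
    if not mask.any():
        raise ValueError("empty mask: no structure pixels to histogram")
    vals = topo.heights[mask]
    if domain is None:
        domain = (float(np.floor(vals.min() / bin_width_nm) * bin_width_nm),
                  float(vals.max() + bin_width_nm))
    edges = np.arange(domain[0], domain[1] + bin_width_nm / 2, bin_width_nm)
    counts, edges = np.histogram(vals, bins=edges)
    clipped = int(len(vals) - counts.sum())
    return MaskedHistogram(
        bin_centers_nm=0.5 * (edges[:-1] + edges[1:]),
        counts=counts,
        bin_width_nm=bin_width_nm,
        n_pixels=int(len(vals) - clipped),
        mask_provenance={
            "dilate_px": dilate_px,
            "erode_px": erode_px,
            "n_masked_pixels": int(len(vals)),
            "n_outside_domain": clipped,
        },
    )


def sum_histograms(hists: list[MaskedHistogram]) -> MaskedHistogram:
    """Pool histograms computed on identical bins (e.g. several images)."""
    first = hists[0]
    for h in hists[1:]:
        if h.bin_centers_nm.shape != first.bin_centers_nm.shape or not np.allclose(
            h.bin_centers_nm, first.bin_centers_nm
        ):
            raise ValueError("histograms must share bins to be pooled")
    counts = np.sum([h.counts for h in hists], axis=0)
    return MaskedHistogram(
        bin_centers_nm=first.bin_centers_nm.copy(),
        counts=counts,
        bin_width_nm=first.bin_width_nm,
        n_pixels=int(sum(h.n_pixels for h in hists)),
        mask_provenance={"pooled_from": len(hists)},
    )


def _two_gauss(x, a1, m1, s1, a2, m2, s2):
    return a1 * np.exp(-0.5 * ((x - m1) / s1) ** 2) + a2 * np.exp(
        -0.5 * ((x - m2) / s2) ** 2
    )


def _initial_means(hist: MaskedHistogram) -> np.ndarray:
    counts = hist.counts.astype(float)
    min_dist = max(1, int(round(0.3 / hist.bin_width_nm)))
    idx, props = signal.find_peaks(
        counts, prominence=0.05 * counts.max(), distance=min_dist
    )
    if len(idx) < 2:
        raise ValueError(
            "histogram has fewer than 2 local modes; supply init_means explicitly"
        )
    order = np.argsort(counts[idx])[::-1]
    chosen = np.sort(idx[order[:2]])
    return hist.bin_centers_nm[chosen]


def fit_two_gaussians(
    hist: MaskedHistogram, init_means: tuple[float, float] | None = None
) -> MixtureFit:
    """Least-squares fit of a sum of two Gaussians to the histogram counts.

    Initial means come from the two most prominent histogram modes unless
    supplied.  Components are returned sorted by mean, so the result does not
    depend on initialisation order.  A fit whose means collapse to within one
    bin width is flagged ``degenerate``.
    """
    x = hist.bin_centers_nm
    y = hist.counts.astype(float)
    if init_means is None:
        m1, m2 = _initial_means(hist)
    else:
        m1, m2 = sorted(init_means)
    a0 = float(y.max())
    s0 = max(3 * hist.bin_width_nm, 0.1)
    p0 = (a0, float(m1), s0, a0, float(m2), s0)
    lo, hi = float(x.min()), float(x.max())
    try:
        popt, pcov = curve_fit(
            _two_gauss, x, y, p0=p0,
            bounds=([0, lo, 1e-4, 0, lo, 1e-4], [np.inf, hi, hi - lo, np.inf, hi, hi - lo]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise ValueError(f"two-Gaussian fit did not converge (p0={p0})") from exc
    perr = np.sqrt(np.diag(pcov))
    comps = []
    for k in (0, 3):
        comps.append(
            GaussianFit(
                mean=float(popt[k + 1]), sd=float(abs(popt[k + 2])),
                amplitude=float(popt[k]),
                domain=(lo, hi),
                stderr_mean=float(perr[k + 1]), stderr_sd=float(perr[k + 2]),
                n=hist.n_pixels, method="histogram",
            )
        )
    comps.sort(key=lambda c: c.mean)
    # unresolvable fits: means closer than a bin or than the narrower
    # component's width (two Gaussians splitting one population), a component
    # narrower than a bin (fitting a single noisy bin), or one whose
    # amplitude is negligible next to the other
    sep = abs(comps[1].mean - comps[0].mean)
    amps = sorted(c.amplitude for c in comps)
    degenerate = (
        sep < max(hist.bin_width_nm, min(comps[0].sd, comps[1].sd))
        or min(comps[0].sd, comps[1].sd) < 0.75 * hist.bin_width_nm
        or (amps[1] > 0 and amps[0] / amps[1] < 0.1)
    )
    return MixtureFit(low=comps[0], high=comps[1], degenerate=degenerate)


def classify_structure(stats: StructureStats, mix: MixtureFit) -> str:
    """Label a structure by the nearest mixture-component mean.

    Returns ``"RNA_like"`` (low component), ``"G4"`` (high component) or
    ``"ambiguous"`` when the structure's mean apex height lies within one
    component SD of *both* means.
    """
    m = stats.mean_height_nm
    d_low = abs(m - mix.low.mean)
    d_high = abs(m - mix.high.mean)
    if d_low <= mix.low.sd and d_high <= mix.high.sd:
        return "ambiguous"
    return "RNA_like" if d_low <= d_high else "G4"
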