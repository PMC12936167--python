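"""Per-structure statistics on height profiles.

The quantities reported for each traced structure: prominence-selected peaks
and their consecutive separations, a single-Gaussian fit to the pooled
separation histogram, RMS roughness about the profile mean, mean trace
(apex) height, and contour length in the Freeman convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.optimize import curve_fit
from scipy.stats import norm

from .trace import SQRT2, HeightProfile, Trace

__all__ = [
    "PeakSet",
    "GaussianFit",
    "StructureStats",
    "find_peaks_by_prominence",
    "peak_separations",
    "fit_gaussian",
    "rms_roughness",
    "mean_trace_height",
    "contour_length",
    "structure_stats",
    "stats_table",
]

DEFAULT_MIN_PROMINENCE_NM = 0.15  # ~2x the default pixel noise
DEFAULT_SEPARATION_BIN_NM = 1.0
DEFAULT_SEPARATION_DOMAIN = (0.0, 20.0)


@dataclass
class PeakSet:
    """Prominence-selected local maxima of one height profile."""

    positions_nm: np.ndarray
    indices: np.ndarray
    prominences_nm: np.ndarray
    min_prominence_nm: float

    def __len__(self) -> int:
        return len(self.positions_nm)


@dataclass
class GaussianFit:
    """Single Gaussian fitted to a histogram (or by ML to raw values)."""

    mean: float
    sd: float
    amplitude: float
    domain: tuple[float, float]
    stderr_mean: float
    stderr_sd: float
    n: int
    method: str = "histogram"
    r_squared: float = float("nan")


@dataclass
class StructureStats:
    """Summary statistics for one traced structure."""

    structure_id: int
    mean_height_nm: float
    rms_roughness_nm: float
    contour_length_nm: float
    separations_nm: list[float] = field(default_factory=list)
    n_peaks: int = 0
    class_label: str | None = None
    centroid_nm: tuple[float, float] | None = None


def find_peaks_by_prominence(
    profile: HeightProfile, min_prominence_nm: float = DEFAULT_MIN_PROMINENCE_NM
) -> PeakSet:
    """Local maxima with topographic prominence >= ``min_prominence_nm``.

    Prominence is measured against the lower of the two flanking minima
    bounded by higher peaks or the profile ends (the scipy definition).
    Profiles shorter than 3 samples return an empty set.
    """
    h = profile.heights_nm
    if len(h) < 3:
        return PeakSet(np.empty(0), np.empty(0, dtype=int), np.empty(0),
                       min_prominence_nm)
    idx, props = signal.find_peaks(h, prominence=min_prominence_nm)
    return PeakSet(
        positions_nm=profile.arc_positions_nm[idx],
        indices=idx,
        prominences_nm=props["prominences"],
        min_prominence_nm=min_prominence_nm,
    )


def peak_separations(peaks: PeakSet) -> list[float]:
    """Consecutive differences of peak arc positions (empty if < 2 peaks)."""
    if len(peaks) < 2:
        return []
    return np.diff(peaks.positions_nm).tolist()


def _gauss(x: np.ndarray, amp: float, mu: float, sd: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((x - mu) / sd) ** 2)


def fit_gaussian(
    values: np.ndarray,
    bin_width_nm: float = DEFAULT_SEPARATION_BIN_NM,
    domain: tuple[float, float] | None = None,
    method: str = "histogram",
) -> GaussianFit:
    """Fit a single Gaussian to a sample of values.

    ``method="histogram"`` (default, mirroring how separation distributions
    are usually plotted and fitted) bins the values at ``bin_width_nm`` and
    least-squares fits ``A exp(-(x-mu)^2 / 2 sd^2)`` to the bin counts;
    parameter standard errors come from the scaled covariance of the fit.
    ``method="mle"`` uses the sample mean/SD directly with textbook standard
    errors.  Requires at least 10 values; all-equal input is rejected.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 10:
        raise ValueError(f"need at least 10 values to fit, got {len(values)}")
    if np.ptp(values) == 0:
        raise ValueError("degenerate input: all values are equal")
    if domain is None:
        lo = min(0.0, values.min())
        domain = (lo, float(values.max()) + bin_width_nm)
    n = len(values)
    if method == "mle":
        mu, sd = norm.fit(values)
        return GaussianFit(
            mean=float(mu), sd=float(sd), amplitude=float("nan"), domain=domain,
            stderr_mean=float(sd / np.sqrt(n)),
            stderr_sd=float(sd / np.sqrt(2 * n)),
            n=n, method="mle",
        )
    if method != "histogram":
        raise ValueError("method must be 'histogram' or 'mle'")

    edges = np.arange(domain[0], domain[1] + bin_width_nm, bin_width_nm)
    counts, edges = np.histogram(values, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    p0 = (float(counts.max()), float(values.mean()), max(float(values.std()), bin_width_nm / 4))
    try:
        popt, pcov = curve_fit(
            _gauss, centers, counts, p0=p0,
            bounds=([0.0, domain[0], 1e-6], [np.inf, domain[1], np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise ValueError(
            f"Gaussian fit did not converge (initial guesses {p0})"
        ) from exc
    perr = np.sqrt(np.diag(pcov))
    resid = counts - _gauss(centers, *popt)
    ss_tot = float(((counts - counts.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else float("nan")
    sd = float(abs(popt[2]))
    # a near-perfect histogram fit can report a vanishing covariance; the mean
    # of n samples is never determined better than the sampling floor sd/sqrt(n)
    se_mean = max(float(perr[1]), sd / np.sqrt(n))
    return GaussianFit(
        mean=float(popt[1]), sd=sd, amplitude=float(popt[0]),
        domain=domain,
        stderr_mean=se_mean, stderr_sd=float(perr[2]),
        n=n, method="histogram", r_squared=r2,
    )


def rms_roughness(profile: HeightProfile) -> float:
    """sqrt(mean((h - mean(h))^2)) over the profile heights."""
    h = profile.heights_nm
    if len(h) < 2:
        raise ValueError("profile must have at least 2 samples")
    return float(np.sqrt(np.mean((h - h.mean()) ** 2)))


def mean_trace_height(profile: HeightProfile) -> float:
    """Arithmetic mean of the profile heights.

    This is the mean *apex* height along the trace, not an average over all
    grain pixels (which would be pulled down by the slopes at the structure
    edges and by tip broadening).
    """
    if len(profile) == 0:
        raise ValueError("empty profile")
    return float(profile.heights_nm.mean())


def contour_length(trace: Trace, pixel_size_nm: float) -> float:
    """Freeman contour length: steps of 1 or sqrt(2) pixels, scaled to nm."""
    poly = trace.polyline_px
    if len(poly) < 2:
        return 0.0
    d = np.abs(np.diff(poly, axis=0))
    steps = np.where(d.sum(axis=1) == 2, SQRT2, 1.0)
    return float(steps.sum() * pixel_size_nm)


def structure_stats(
    trace: Trace,
    profile: HeightProfile,
    pixel_size_nm: float,
    min_prominence_nm: float = DEFAULT_MIN_PROMINENCE_NM,
) -> StructureStats:
    """Assemble the per-structure summary used throughout the pipeline."""
    peaks = find_peaks_by_prominence(profile, min_prominence_nm)
    seps = peak_separations(peaks)
    cx, cy = trace.centroid_nm(pixel_size_nm)
    return StructureStats(
        structure_id=trace.grain_id,
        mean_height_nm=mean_trace_height(profile),
        rms_roughness_nm=rms_roughness(profile),
        contour_length_nm=contour_length(trace, pixel_size_nm),
        separations_nm=seps,
        n_peaks=len(peaks),
        centroid_nm=(float(cx), float(cy)),
    )


def stats_table(stats: list[StructureStats]) -> pd.DataFrame:
    """Tabulate per-structure statistics (one row per structure)."""
    return pd.DataFrame(
        {
            "structure_id": [s.structure_id for s in stats],
            "mean_height_nm": [s.mean_height_nm for s in stats],
            "rms_roughness_nm": [s.rms_roughness_nm for s in stats],
            "contour_length_nm": [s.contour_length_nm for s in stats],
            "n_peaks": [s.n_peaks for s in stats],
            "class_label": [s.class_label for s in stats],
        }
    )
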