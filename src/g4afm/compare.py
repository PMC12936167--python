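"""Paired same-field analysis of before/after ionic-exchange images.

When the imaging solution is exchanged (e.g. KCl -> NiCl2) the same surface
location is re-imaged.  This module registers the two images by integer-pixel
normalized cross-correlation, matches structures across them, quantifies
persistence/fragmentation, and measures the bead morphometry of contracted
chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .profile_stats import find_peaks_by_prominence
from .topograph import Topograph
from .trace import HeightProfile, Trace

__all__ = [
    "PairedField",
    "MatchResult",
    "PersistenceReport",
    "BeadReport",
    "register_images",
    "match_structures",
    "persistence_stats",
    "bead_stats",
]

DEFAULT_MATCH_TOL_NM = 20.0
DEFAULT_BEAD_PROMINENCE_NM = 0.5


@dataclass
class PairedField:
    """Registered before/after image pair."""

    before: Topograph
    after: Topograph
    offset_px: tuple[int, int]  # (row, col): after = before shifted by offset
    confidence: float  # normalized correlation peak in [-1, 1]


@dataclass
class MatchResult:
    """Structure correspondences between the two images."""

    pairs: list[tuple[int, int]]  # (before_id, after_id)
    fragments: dict[int, list[int]]  # before_id -> extra after fragments
    unmatched_before: list[int]
    unmatched_after: list[int]
    tol_nm: float = DEFAULT_MATCH_TOL_NM


@dataclass
class PersistenceReport:
    """Per-structure persistence across the solution exchange."""

    table: pd.DataFrame  # columns: before_id, matched, retained_fraction, n_fragments
    removed_fraction: float
    mean_retained_fraction: float
    n_structures: int
    warnings: list[str] = field(default_factory=list)


@dataclass
class BeadReport:
    """Bead morphometry of one contracted chain profile."""

    positions_nm: np.ndarray
    heights_nm: np.ndarray
    spacings_nm: np.ndarray
    mean_spacing_nm: float
    sd_spacing_nm: float
    mean_height_nm: float


# ---------------------------------------------------------------------------
# registration


def _ncc_surface(a: np.ndarray, b: np.ndarray, max_shift: int) -> np.ndarray:
    """Normalized cross-correlation of ``b`` against ``a`` for every integer
    shift within ``max_shift``, computed with FFT convolutions and integral
    sums over the overlap region (exact Pearson r per shift)."""
    a = a.astype(float)
    b = b.astype(float)
    ones = np.ones_like(a)
    # full-correlation surfaces; index (dy+H-1, dx+W-1) = shift (dy, dx)
    num_ab = fftconvolve(a, b[::-1, ::-1], mode="full")
    sum_a = fftconvolve(a, ones[::-1, ::-1], mode="full")
    sum_b = fftconvolve(ones, b[::-1, ::-1], mode="full")
    sum_a2 = fftconvolve(a * a, ones[::-1, ::-1], mode="full")
    sum_b2 = fftconvolve(ones, (b * b)[::-1, ::-1], mode="full")
    n_ov = fftconvolve(ones, ones[::-1, ::-1], mode="full")

    H, W = a.shape
    c0, c1 = H - 1, W - 1
    sl = (slice(c0 - max_shift, c0 + max_shift + 1),
          slice(c1 - max_shift, c1 + max_shift + 1))
    n = n_ov[sl]
    cov = num_ab[sl] - sum_a[sl] * sum_b[sl] / n
    var_a = sum_a2[sl] - sum_a[sl] ** 2 / n
    var_b = sum_b2[sl] - sum_b[sl] ** 2 / n
    denom = np.sqrt(np.maximum(var_a, 0.0) * np.maximum(var_b, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, cov / denom, -np.inf)
    return r


def register_images(
    before: Topograph,
    after: Topograph,
    max_shift_px: int = 32,
    min_confidence: float = 0.2,
) -> PairedField:
    """Find the integer-pixel offset maximizing normalized cross-correlation.

    The returned ``offset_px`` is the (row, col) shift that maps before-frame
    coordinates to after-frame coordinates.  Registration of uncorrelated
    images fails with an explanatory error suggesting a manual offset.
    """
    if before.shape != after.shape:
        raise ValueError("images must share shape")
    if before.pixel_size_nm != after.pixel_size_nm:
        raise ValueError("images must share pixel size")
    if max_shift_px >= min(before.shape) // 2:
        raise ValueError("max_shift_px must be below half the image size")
    r = _ncc_surface(before.heights, after.heights, max_shift_px)
    idx = np.unravel_index(np.argmax(r), r.shape)
    confidence = float(r[idx])
    # convolution index -> shift of `after` relative to `before`
    offset = (int(max_shift_px - idx[0]), int(max_shift_px - idx[1]))
    if confidence < min_confidence:
        raise ValueError(
            f"registration confidence {confidence:.3f} below floor "
            f"{min_confidence}; the fields may not overlap — supply a manual offset"
        )
    return PairedField(before, after, offset, confidence)


# ---------------------------------------------------------------------------
# structure matching


def _point_to_polyline_nm(point: np.ndarray, poly_nm: np.ndarray) -> float:
    """Min distance from a point to a polyline's segments (all nm)."""
    if len(poly_nm) == 1:
        return float(np.hypot(*(point - poly_nm[0])))
    p0 = poly_nm[:-1]
    seg = poly_nm[1:] - p0
    seg_len2 = (seg**2).sum(axis=1)
    seg_len2[seg_len2 == 0] = 1e-12
    t = np.clip(((point - p0) * seg).sum(axis=1) / seg_len2, 0.0, 1.0)
    proj = p0 + t[:, None] * seg
    return float(np.min(np.hypot(*(point - proj).T)))


def _trace_poly_nm(trace: Trace, px: float) -> np.ndarray:
    return np.column_stack(
        [trace.polyline_px[:, 1] * px, trace.polyline_px[:, 0] * px]
    )


def match_structures(
    traces_before: dict[int, Trace],
    traces_after: dict[int, Trace],
    field_pair: PairedField,
    tol_nm: float = DEFAULT_MATCH_TOL_NM,
) -> MatchResult:
    """Greedy nearest-centroid matching after offset correction.

    Each after-structure matches at most one before-structure.  Remaining
    after-structures whose centroid lies within ``tol_nm`` of a matched
    before-trace polyline are grouped as that structure's fragments.
    """
    px = field_pair.before.pixel_size_nm
    off_nm = np.array([field_pair.offset_px[1] * px, field_pair.offset_px[0] * px])
    cents_b = {i: t.centroid_nm(px) for i, t in traces_before.items()}
    cents_a = {i: t.centroid_nm(px) - off_nm for i, t in traces_after.items()}

    available = set(cents_a)
    pairs: list[tuple[int, int]] = []
    # candidate distances, greedy by closeness (deterministic tie-break on ids)
    cand = sorted(
        (float(np.hypot(*(cb - cents_a[ai]))), bi, ai)
        for bi, cb in cents_b.items()
        for ai in cents_a
    )
    matched_b: set[int] = set()
    for d, bi, ai in cand:
        if d > tol_nm:
            break
        if bi in matched_b or ai not in available:
            continue
        pairs.append((bi, ai))
        matched_b.add(bi)
        available.discard(ai)

    fragments: dict[int, list[int]] = {bi: [] for bi, _ in pairs}
    polys_b = {bi: _trace_poly_nm(traces_before[bi], px) for bi in cents_b}
    still_unmatched = []
    for ai in sorted(available):
        best_bi, best_d = None, np.inf
        for bi in cents_b:
            d = _point_to_polyline_nm(cents_a[ai], polys_b[bi])
            if d < best_d:
                best_bi, best_d = bi, d
        if best_bi is not None and best_d <= tol_nm:
            fragments.setdefault(best_bi, []).append(ai)
        else:
            still_unmatched.append(ai)

    matched_or_fragmented = matched_b | {b for b, f in fragments.items() if f}
    unmatched_before = sorted(set(cents_b) - matched_or_fragmented)
    return MatchResult(
        pairs=pairs,
        fragments=fragments,
        unmatched_before=unmatched_before,
        unmatched_after=still_unmatched,
        tol_nm=tol_nm,
    )


def persistence_stats(
    match: MatchResult,
    traces_before: dict[int, Trace],
    traces_after: dict[int, Trace],
    pixel_size_nm: float,
) -> PersistenceReport:
    """Retained-length fractions and fragment counts per before-structure.

    Retained fraction = (sum of after contour over the match and its
    fragments) / before contour, clipped to [0, 1.05] with a warning above 1
    (tracing jitter can slightly exceed unity for unchanged structures).
    """
    from .profile_stats import contour_length

    matched_after: dict[int, list[int]] = {}
    for bi, ai in match.pairs:
        matched_after.setdefault(bi, []).append(ai)
    for bi, frags in match.fragments.items():
        matched_after.setdefault(bi, []).extend(frags)

    rows = []
    warns: list[str] = []
    for bi in sorted(traces_before):
        before_len = contour_length(traces_before[bi], pixel_size_nm)
        after_ids = matched_after.get(bi, [])
        after_len = sum(
            contour_length(traces_after[ai], pixel_size_nm) for ai in after_ids
        )
        frac = after_len / before_len if before_len > 0 else 0.0
        if frac > 1.05:
            warns.append(
                f"structure {bi}: retained fraction {frac:.2f} > 1.05, clipped"
            )
        frac = min(frac, 1.05)
        rows.append(
            {
                "before_id": bi,
                "matched": bool(after_ids),
                "retained_fraction": frac,
                "n_fragments": len(after_ids),
            }
        )
    table = pd.DataFrame(rows)
    n = len(table)
    removed = float((~table["matched"]).mean()) if n else 0.0
    mean_ret = float(table["retained_fraction"].mean()) if n else 0.0
    return PersistenceReport(
        table=table,
        removed_fraction=removed,
        mean_retained_fraction=mean_ret,
        n_structures=n,
        warnings=warns,
    )


# ---------------------------------------------------------------------------
# bead morphometry


def bead_stats(
    profile: HeightProfile,
    min_prominence_nm: float = DEFAULT_BEAD_PROMINENCE_NM,
) -> BeadReport:
    """Bead positions, heights and spacings along a contracted-chain profile.

    Beads are prominence peaks (default floor 0.5 nm — beads stand ~1.8 nm
    above the inter-bead baseline, so this rejects noise wiggles while
    keeping every real bead).  Fewer than two beads yield empty spacings.
    """
    peaks = find_peaks_by_prominence(profile, min_prominence_nm)
    spacings = np.diff(peaks.positions_nm) if len(peaks) >= 2 else np.empty(0)
    heights = profile.heights_nm[peaks.indices] if len(peaks) else np.empty(0)
    return BeadReport(
        positions_nm=peaks.positions_nm,
        heights_nm=heights,
        spacings_nm=spacings,
        mean_spacing_nm=float(spacings.mean()) if len(spacings) else float("nan"),
        sd_spacing_nm=float(spacings.std(ddof=1)) if len(spacings) > 1 else float("nan"),
        mean_height_nm=float(heights.mean()) if len(heights) else float("nan"),
    )
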