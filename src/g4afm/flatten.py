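"""Topograph flattening: scan-line alignment and background tilt removal.

AFM raw images carry per-scan-line offsets and a global tilt that must be
removed before any height is meaningful.  The scheme here is the standard
two-pass one: a coarse full-image plane fit identifies candidate background
(substrate) pixels, per-row *median* background offsets are subtracted
(medians are robust to residual foreground pixels), and a final least-squares
polynomial surface (order 1 or 2) is fitted to the background and removed.
After flattening the background median is zero, so structure heights read
directly in nm above the substrate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .topograph import Topograph

__all__ = [
    "FlattenResult",
    "estimate_background",
    "align_rows",
    "remove_tilt",
    "flatten",
]

MIN_BACKGROUND_FRACTION = 0.2
DEFAULT_EXCLUSION_QUANTILE = 0.7


@dataclass
class FlattenResult:
    """Outcome of a flattening pass."""

    corrected: Topograph
    row_offsets: np.ndarray
    plane: np.ndarray  # fitted polynomial coefficients (order-dependent length)
    background_mask: np.ndarray
    order: int = 1
    warnings: list[str] = field(default_factory=list)


def _design_matrix(rows: np.ndarray, cols: np.ndarray, px: float, order: int) -> np.ndarray:
    x = cols * px
    y = rows * px
    if order == 1:
        return np.column_stack([x, y, np.ones_like(x)])
    if order == 2:
        return np.column_stack([x, y, np.ones_like(x), x * x, x * y, y * y])
    raise ValueError("order must be 1 or 2")


def _fit_surface(
    heights: np.ndarray, mask: np.ndarray, px: float, order: int
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares polynomial surface on masked pixels.

    Returns ``(coefficients, fitted_surface)``; raises on rank deficiency
    (e.g. a mask confined to a single row).
    """
    rows, cols = np.nonzero(mask)
    A = _design_matrix(rows.astype(float), cols.astype(float), px, order)
    z = heights[rows, cols]
    coeffs, _, rank, _ = np.linalg.lstsq(A, z, rcond=None)
    if rank < A.shape[1]:
        raise ValueError(
            f"rank-deficient surface fit (rank {rank} < {A.shape[1]}): "
            "background mask does not span the image plane"
        )
    nrows, ncols = heights.shape
    rr, cc = np.meshgrid(np.arange(nrows, dtype=float), np.arange(ncols, dtype=float),
                         indexing="ij")
    surface = (_design_matrix(rr.ravel(), cc.ravel(), px, order) @ coeffs).reshape(
        heights.shape
    )
    return coeffs, surface


def estimate_background(
    topo: Topograph, exclusion_quantile: float = DEFAULT_EXCLUSION_QUANTILE
) -> np.ndarray:
    """Boolean mask of substrate pixels.

    A coarse order-1 plane is fitted to the whole image and removed, then
    pixels at or below the ``exclusion_quantile`` height quantile are
    declared background.  Fails if fewer than 20% of pixels qualify, or if
    the image is a uniform tall plateau (constant and clearly above zero —
    no substrate level is identifiable; a constant image *at* zero is by
    convention all background).
    """
    if not 0.0 < exclusion_quantile < 1.0:
        raise ValueError("exclusion_quantile must be in (0, 1)")
    if np.ptp(topo.heights) < 1e-9:
        if abs(float(np.median(topo.heights))) < 0.2:
            return np.ones(topo.shape, dtype=bool)
        raise ValueError(
            "no identifiable background: the image is a uniform plateau well "
            "above zero"
        )
    _, coarse = _fit_surface(
        topo.heights, np.ones(topo.shape, dtype=bool), topo.pixel_size_nm, order=1
    )
    residual = topo.heights - coarse
    cutoff = np.quantile(residual, exclusion_quantile)
    mask = residual <= cutoff
    if mask.mean() < MIN_BACKGROUND_FRACTION:
        raise ValueError(
            "no identifiable background: fewer than 20% of pixels fall below "
            f"the {exclusion_quantile:.2f} height quantile (degenerate image)"
        )
    return mask


def align_rows(
    topo: Topograph, background_mask: np.ndarray, min_pixels: int = 3
) -> FlattenResult:
    """Subtract the per-row median of background pixels from every row.

    Rows with fewer than ``min_pixels`` background pixels get their offset
    interpolated from neighbouring rows and a warning is recorded.
    """
    h = topo.heights
    nrows = h.shape[0]
    offsets = np.full(nrows, np.nan)
    counts = background_mask.sum(axis=1)
    for r in range(nrows):
        if counts[r] >= min_pixels:
            offsets[r] = np.median(h[r, background_mask[r]])
    warns: list[str] = []
    bad = np.isnan(offsets)
    if bad.any():
        good = ~bad
        if not good.any():
            raise ValueError("no row has enough background pixels to align")
        offsets[bad] = np.interp(
            np.flatnonzero(bad), np.flatnonzero(good), offsets[good]
        )
        msg = f"{bad.sum()} row(s) lacked background pixels; offsets interpolated"
        warns.append(msg)
        warnings.warn(msg, stacklevel=2)
    corrected = topo.with_heights(h - offsets[:, None])
    return FlattenResult(
        corrected=corrected,
        row_offsets=offsets,
        plane=np.zeros(3),
        background_mask=background_mask,
        warnings=warns,
    )


def remove_tilt(
    topo: Topograph, background_mask: np.ndarray, order: int = 1
) -> FlattenResult:
    """Fit a polynomial surface (order 1 or 2) to background pixels and
    subtract it, re-zeroing on the background median."""
    coeffs, surface = _fit_surface(
        topo.heights, background_mask, topo.pixel_size_nm, order
    )
    h = topo.heights - surface
    h -= np.median(h[background_mask])
    return FlattenResult(
        corrected=topo.with_heights(h),
        row_offsets=np.zeros(topo.shape[0]),
        plane=coeffs,
        background_mask=background_mask,
        order=order,
    )


def flatten(
    topo: Topograph,
    order: int = 1,
    exclusion_quantile: float = DEFAULT_EXCLUSION_QUANTILE,
) -> FlattenResult:
    """Full flattening: pre-align rows -> coarse mask -> row align -> refit.

    A first per-row median over *all* pixels removes the bulk of the scan-line
    offsets (otherwise an offset row sits bodily above the background quantile
    and escapes the mask entirely), then the background mask is estimated, row
    offsets are refined on background pixels only, and the final polynomial
    surface is fitted and removed.  Returns a :class:`FlattenResult` whose
    ``corrected`` topograph has background median ~0; ``row_offsets`` and
    ``plane`` record what was removed for audit.
    """
    pre_offsets = np.median(topo.heights, axis=1)
    pre = topo.with_heights(topo.heights - pre_offsets[:, None])
    mask = estimate_background(pre, exclusion_quantile)
    rows = align_rows(pre, mask)
    # refine the mask on the row-aligned image before the final surface fit
    mask2 = estimate_background(rows.corrected, exclusion_quantile)
    tilt = remove_tilt(rows.corrected, mask2, order=order)
    return FlattenResult(
        corrected=tilt.corrected,
        row_offsets=pre_offsets + rows.row_offsets,
        plane=tilt.plane,
        background_mask=mask2,
        order=order,
        warnings=rows.warnings,
    )
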