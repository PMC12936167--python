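"""Synthetic AFM topograph generator: single-structure primitives.

This module renders the three structure classes seen on mica in the study
system — tall filamentous G-quadruplexes (G4) with axial periodic bumps, thin
uniform RNA-like chains, and contracted beaded chains — together with the
instrument artifacts (row offsets, plane tilt, pixel noise, finite-tip
dilation) that the analysis pipeline must undo.  Backbones follow a 2-D
worm-like chain; ridges have Gaussian cross-sections; overlapping structures
compose by pointwise max because AFM reports the topmost surface.

Scene-level composition (placing many structures, paired before/after fields)
lives in :mod:`g4afm.scenes`.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .topograph import Topograph

__all__ = [
    "BackboneModel",
    "FilamentSpec",
    "BeadSpec",
    "ArtifactSpec",
    "GroundTruthRecord",
    "generate_backbone",
    "render_filament",
    "render_beaded_chain",
    "apply_tip_convolution",
    "add_instrument_artifacts",
    "wlc_mean_square_end_to_end",
    "amplitude_for_rms",
    "smoothing_gain",
    "DIGITIZED_STEP_FACTOR",
    "FWHM_TO_SIGMA",
    "ground_truth_to_json",
    "ground_truth_from_json",
]

#: Conversion from full width at half maximum to the Gaussian sigma.
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

#: Arc spacing (nm) at which backbones are resampled for painting; must be
#: well below the axial sigma of the sweep so the crest stays scallop-free.
PAINT_SPACING_NM = 0.1

#: Along-tangent sigma of the swept cross-section (see ``_paint_ridge``).
DEFAULT_AXIAL_SIGMA_NM = 1.0

#: Expected true arc spacing, in pixels, between consecutive samples of an
#: 8-connected digitised path at uniform random orientation:
#: E[sec theta] over theta in [0, 45 deg] = ln(1+sqrt(2)) / (pi/4).
DIGITIZED_STEP_FACTOR = math.log(1.0 + math.sqrt(2.0)) / (math.pi / 4.0)


# ---------------------------------------------------------------------------
# specs


@dataclass
class BackboneModel:
    """Worm-like-chain geometry of one filament backbone.

    ``persistence_length_nm`` controls stiffness: tangent angles random-walk
    with per-step variance ``step_nm / persistence_length_nm``, which gives the
    standard 2-D tangent correlation ``exp(-s / (2 lp))``.
    """

    contour_length_nm: float
    persistence_length_nm: float
    step_nm: float = 0.25

    def __post_init__(self) -> None:
        if not self.contour_length_nm > 0:
            raise ValueError("contour_length_nm must be > 0")
        if not self.persistence_length_nm > 0:
            raise ValueError("persistence_length_nm must be > 0")
        if not self.step_nm > 0:
            raise ValueError("step_nm must be > 0")


@dataclass
class FilamentSpec:
    """Rendering parameters for a ridge-like structure.

    ``class_label`` encodes the structure class: ``"G4"`` (tall filament,
    baseline apex near 3.4 nm with periodic bumps), ``"RNA_like"`` (thin
    uniform chain near 0.9 nm) or ``"beaded"`` (rendered via
    :class:`BeadSpec`, see :func:`render_beaded_chain`).
    """

    baseline_height_nm: float
    bump_period_nm: float = 0.0
    bump_amplitude_nm: float = 0.0
    apparent_width_nm: float = 5.0
    class_label: str = "G4"
    waveform: str = "sine"  # "sine" or "stacked"
    phase: float | None = None

    def __post_init__(self) -> None:
        if not self.baseline_height_nm > 0:
            raise ValueError("baseline_height_nm must be > 0")
        if self.bump_amplitude_nm > 0 and not self.bump_period_nm > 0:
            raise ValueError("bump_period_nm must be > 0 when amplitude > 0")
        if not self.apparent_width_nm > 0:
            raise ValueError("apparent_width_nm must be > 0")
        if self.waveform not in {"sine", "stacked"}:
            raise ValueError("waveform must be 'sine' or 'stacked'")


@dataclass
class BeadSpec:
    """Bead geometry of a contracted chain (the divalent-cation morphology)."""

    bead_height_nm: float = 2.0
    bead_spacing_mean_nm: float = 11.0
    bead_spacing_sd_nm: float = 4.0
    interbead_height_nm: float = 0.2
    bead_width_nm: float = 4.0
    chain_width_nm: float = 3.0

    def __post_init__(self) -> None:
        if not self.bead_spacing_mean_nm > 0:
            raise ValueError("bead_spacing_mean_nm must be > 0")
        if self.interbead_height_nm < 0:
            raise ValueError("interbead_height_nm must be >= 0")
        if not self.bead_height_nm > self.interbead_height_nm:
            raise ValueError("bead_height_nm must exceed interbead_height_nm")


@dataclass
class ArtifactSpec:
    """Instrument artifacts added to a rendered scene.

    The defaults model a well-tuned liquid-cell instrument with a
    high-resolution probe: per-scan-line offsets of 0.1 nm SD, no deliberate
    tilt, 0.05 nm pixel noise and a 1 nm tip radius — small relative to the
    0.9 nm chains that must stay resolvable, and sharp enough not to fill
    the troughs between axial bumps ~5 nm apart.
    """

    row_offset_sd_nm: float = 0.1
    tilt: tuple[float, float, float] = (0.0, 0.0, 0.0)  # a*x + b*y + c, nm
    noise_sd_nm: float = 0.05
    tip_radius_nm: float = 1.0

    def __post_init__(self) -> None:
        if self.row_offset_sd_nm < 0 or self.noise_sd_nm < 0:
            raise ValueError("artifact SDs must be >= 0")
        if self.tip_radius_nm < 0:
            raise ValueError("tip_radius_nm must be >= 0 (0 = ideal tip)")


@dataclass
class GroundTruthRecord:
    """Generator-side truth for one rendered structure."""

    structure_id: int
    class_label: str
    polyline_nm: np.ndarray  # (N, 2) columns (x, y) in nm
    contour_length_nm: float
    mean_apex_height_nm: float
    bump_period_nm: float | None = None
    params: dict = field(default_factory=dict)
    bead_arc_nm: np.ndarray | None = None

    @property
    def centroid_nm(self) -> np.ndarray:
        return self.polyline_nm.mean(axis=0)


# ---------------------------------------------------------------------------
# backbone geometry


def generate_backbone(
    model: BackboneModel, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Sample a 2-D worm-like-chain backbone polyline.

    Returns an ``(N, 2)`` array of ``(x, y)`` positions in nm, starting at the
    origin with a uniformly random initial heading.  Angular increments are
    drawn i.i.d. normal with variance ``step / persistence_length`` so the
    ensemble obeys the closed-form 2-D WLC mean-square end-to-end distance
    (see :func:`wlc_mean_square_end_to_end`).
    """
    rng = np.random.default_rng(rng)
    n_steps = max(1, int(round(model.contour_length_nm / model.step_nm)))
    sigma = math.sqrt(model.step_nm / model.persistence_length_nm)
    theta0 = rng.uniform(0.0, 2.0 * math.pi)
    dtheta = rng.normal(0.0, sigma, size=n_steps)
    dtheta[0] = 0.0
    theta = theta0 + np.cumsum(dtheta)
    steps = model.step_nm * np.column_stack([np.cos(theta), np.sin(theta)])
    poly = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    return poly


def wlc_mean_square_end_to_end(contour_nm: float, persistence_nm: float) -> float:
    """Closed-form 2-D WLC ``<R^2>`` for tangent correlation exp(-s/(2 lp)).

    ``<R^2> = 4 lp L [1 - (2 lp / L)(1 - exp(-L / (2 lp)))]``
    """
    L, lp = contour_nm, persistence_nm
    return 4.0 * lp * L * (1.0 - (2.0 * lp / L) * (1.0 - math.exp(-L / (2.0 * lp))))


def polyline_arc_length(poly: np.ndarray) -> float:
    return float(np.hypot(*np.diff(poly, axis=0).T).sum())


def resample_polyline(poly: np.ndarray, spacing_nm: float) -> np.ndarray:
    """Resample a polyline at uniform arc spacing (endpoint included)."""
    seg = np.hypot(*np.diff(poly, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        return poly[:1].copy()
    n = max(2, int(math.ceil(total / spacing_nm)) + 1)
    snew = np.linspace(0.0, total, n)
    x = np.interp(snew, s, poly[:, 0])
    y = np.interp(snew, s, poly[:, 1])
    return np.column_stack([x, y])


# ---------------------------------------------------------------------------
# rendering


def _check_inside(topo: Topograph, poly_nm: np.ndarray) -> None:
    w, h = topo.extent_nm
    if (
        poly_nm[:, 0].min() < 0
        or poly_nm[:, 1].min() < 0
        or poly_nm[:, 0].max() > w
        or poly_nm[:, 1].max() > h
    ):
        raise ValueError("backbone polyline lies outside the image bounds")


def _paint_ridge(
    heights: np.ndarray,
    pixel_size_nm: float,
    samples_nm: np.ndarray,
    apex_nm: np.ndarray,
    width_nm: float,
    axial_sigma_nm: float | None = None,
    profile: str = "plateau",
) -> None:
    """Max-compose a ridge onto ``heights``.

    The ridge is a *sweep* of a cross-section along the backbone: each
    sample deposits a patch that is narrow along the local tangent
    (``axial_sigma_nm``, default 1 nm — well below the axial repeats being
    emulated, but wide enough that densely spaced samples leave no scallop
    between them), so the crest reproduces the apex profile instead of being
    axially smeared by wide radial footprints.

    The perpendicular cross-section (FWHM = ``width_nm``) models a solid
    object imaged by a sharp tip: ``"plateau"`` (default) is a flat top of
    half the width with Gaussian shoulders — the imaged edges of these
    assemblies are tip-limited and steep, which is what keeps the
    pixel-height distribution tightly peaked at the apex value; a pure
    ``"gaussian"`` fall-off is available for comparison.
    """
    px = pixel_size_nm
    if axial_sigma_nm is None:
        axial_sigma_nm = DEFAULT_AXIAL_SIGMA_NM
    if profile == "plateau":
        top_half = width_nm / 4.0
        edge_sigma = (width_nm / 2.0 - top_half) / math.sqrt(2.0 * math.log(2.0))
    elif profile == "gaussian":
        top_half = 0.0
        edge_sigma = width_nm * FWHM_TO_SIGMA
    else:
        raise ValueError("profile must be 'plateau' or 'gaussian'")
    reach = top_half + 3.5 * edge_sigma
    win = max(1, int(math.ceil(max(reach, 3.5 * axial_sigma_nm) / px)))
    nrows, ncols = heights.shape
    inv_perp = 1.0 / (2.0 * edge_sigma * edge_sigma)
    inv_par = 1.0 / (2.0 * axial_sigma_nm * axial_sigma_nm)

    # unit tangents from finite differences along the sample chain
    if len(samples_nm) > 1:
        tang = np.gradient(samples_nm, axis=0)
    else:
        tang = np.array([[1.0, 0.0]])
    norms = np.hypot(tang[:, 0], tang[:, 1])
    norms[norms == 0] = 1.0
    tang = tang / norms[:, None]

    for (x, y), h, (tx, ty) in zip(samples_nm, apex_nm, tang):
        c0 = int(round(x / px))
        r0 = int(round(y / px))
        r_lo, r_hi = max(0, r0 - win), min(nrows, r0 + win + 1)
        c_lo, c_hi = max(0, c0 - win), min(ncols, c0 + win + 1)
        if r_lo >= r_hi or c_lo >= c_hi:
            continue
        ys = np.arange(r_lo, r_hi) * px - y
        xs = np.arange(c_lo, c_hi) * px - x
        dx = xs[None, :]
        dy = ys[:, None]
        d_par = dx * tx + dy * ty
        d_perp = np.maximum(np.abs(-dx * ty + dy * tx) - top_half, 0.0)
        patch = h * np.exp(-(d_par**2) * inv_par - (d_perp**2) * inv_perp)
        np.maximum(heights[r_lo:r_hi, c_lo:c_hi], patch, out=heights[r_lo:r_hi, c_lo:c_hi])


def _stacked_offsets(
    arcs: np.ndarray,
    period_nm: float,
    amplitude_nm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Piecewise-constant axial modulation: stacked units of random length.

    Unit lengths are drawn N(period, 0.2*period) truncated positive; each unit
    carries a uniform offset chosen so the axial RMS matches ``amplitude/sqrt(2)``
    (same RMS as a sinusoid of the given amplitude).
    """
    total = arcs[-1]
    bounds = [0.0]
    while bounds[-1] < total:
        step = rng.normal(period_nm, 0.2 * period_nm)
        while step <= 0.2 * period_nm:
            step = rng.normal(period_nm, 0.2 * period_nm)
        bounds.append(bounds[-1] + step)
    half_range = amplitude_nm * math.sqrt(1.5)  # uniform RMS c/sqrt(3) = a/sqrt(2)
    offsets = rng.uniform(-half_range, half_range, size=len(bounds))
    idx = np.searchsorted(bounds, arcs, side="right") - 1
    return offsets[idx]


def render_filament(
    topo: Topograph,
    polyline_nm: np.ndarray,
    spec: FilamentSpec,
    rng: np.random.Generator | int | None = None,
    structure_id: int = 0,
) -> GroundTruthRecord:
    """Render a filament ridge onto ``topo`` (in place) and return its truth.

    The along-backbone apex height is ``baseline + modulation(arc)`` — a
    sinusoid by default, or piecewise-constant stacked units emulating bulky
    irregular variations.  Heights compose with the existing surface by
    pointwise max.
    """
    _check_inside(topo, polyline_nm)
    rng = np.random.default_rng(rng)
    samples = resample_polyline(polyline_nm, PAINT_SPACING_NM)
    seg = np.hypot(*np.diff(samples, axis=0).T)
    arcs = np.concatenate([[0.0], np.cumsum(seg)])

    if spec.bump_amplitude_nm > 0:
        if spec.waveform == "sine":
            phase = spec.phase if spec.phase is not None else rng.uniform(0, 2 * math.pi)
            modulation = spec.bump_amplitude_nm * np.sin(
                2.0 * math.pi * arcs / spec.bump_period_nm + phase
            )
        else:
            modulation = _stacked_offsets(
                arcs, spec.bump_period_nm, spec.bump_amplitude_nm, rng
            )
    else:
        modulation = np.zeros_like(arcs)

    apex = spec.baseline_height_nm + modulation
    _paint_ridge(topo.heights, topo.pixel_size_nm, samples, apex,
                 spec.apparent_width_nm)

    return GroundTruthRecord(
        structure_id=structure_id,
        class_label=spec.class_label,
        polyline_nm=polyline_nm.copy(),
        contour_length_nm=polyline_arc_length(polyline_nm),
        mean_apex_height_nm=float(apex.mean()),
        bump_period_nm=spec.bump_period_nm if spec.bump_amplitude_nm > 0 else None,
        params=asdict(spec),
    )


def render_beaded_chain(
    topo: Topograph,
    polyline_nm: np.ndarray,
    bead: BeadSpec,
    rng: np.random.Generator | int | None = None,
    structure_id: int = 0,
) -> GroundTruthRecord:
    """Render a contracted beaded chain onto ``topo`` (in place).

    A thin ridge at the inter-bead baseline follows the backbone; Gaussian
    bumps of ``bead_height_nm`` are placed along it at arc spacings drawn from
    N(mean, sd) truncated positive (deterministic ``floor(L/s)+1`` placement
    when sd = 0).
    """
    _check_inside(topo, polyline_nm)
    rng = np.random.default_rng(rng)
    samples = resample_polyline(polyline_nm, PAINT_SPACING_NM)
    total = polyline_arc_length(polyline_nm)

    # inter-bead baseline ridge
    if bead.interbead_height_nm > 0:
        _paint_ridge(
            topo.heights,
            topo.pixel_size_nm,
            samples,
            np.full(len(samples), bead.interbead_height_nm),
            bead.chain_width_nm,
        )

    # bead centres along the arc
    bead_arcs = [0.0]
    while True:
        if bead.bead_spacing_sd_nm > 0:
            step = rng.normal(bead.bead_spacing_mean_nm, bead.bead_spacing_sd_nm)
            while step <= 0:
                step = rng.normal(bead.bead_spacing_mean_nm, bead.bead_spacing_sd_nm)
        else:
            step = bead.bead_spacing_mean_nm
        nxt = bead_arcs[-1] + step
        if nxt > total + 1e-9:
            break
        bead_arcs.append(nxt)
    bead_arcs = np.asarray(bead_arcs)

    seg = np.hypot(*np.diff(samples, axis=0).T)
    arcs = np.concatenate([[0.0], np.cumsum(seg)])
    bx = np.interp(bead_arcs, arcs, samples[:, 0])
    by = np.interp(bead_arcs, arcs, samples[:, 1])
    bead_sigma = bead.bead_width_nm * FWHM_TO_SIGMA
    _paint_ridge(
        topo.heights,
        topo.pixel_size_nm,
        np.column_stack([bx, by]),
        np.full(len(bead_arcs), bead.bead_height_nm),
        bead.bead_width_nm,
        axial_sigma_nm=bead_sigma,  # beads are isotropic blobs
        profile="gaussian",
    )

    return GroundTruthRecord(
        structure_id=structure_id,
        class_label="beaded",
        polyline_nm=polyline_nm.copy(),
        contour_length_nm=total,
        mean_apex_height_nm=bead.bead_height_nm,
        bump_period_nm=bead.bead_spacing_mean_nm,
        params=asdict(bead),
        bead_arc_nm=bead_arcs,
    )


# ---------------------------------------------------------------------------
# instrument artifacts


def apply_tip_convolution(topo: Topograph, tip_radius_nm: float) -> Topograph:
    """Dilate the surface with a spherical-cap tip (radius in nm).

    Grayscale dilation with the structuring function
    ``t(v) = sqrt(r^2 - |v|^2) - r``; the output is pointwise >= the input and
    isolated apex heights are preserved.  ``tip_radius_nm = 0`` is the
    identity (ideal tip).
    """
    if tip_radius_nm < 0:
        raise ValueError("tip_radius_nm must be >= 0")
    px = topo.pixel_size_nm
    r_px = int(math.floor(tip_radius_nm / px))
    if tip_radius_nm == 0 or r_px == 0:
        return topo.copy()
    offs = np.arange(-r_px, r_px + 1) * px
    d2 = offs[:, None] ** 2 + offs[None, :] ** 2
    footprint = d2 <= tip_radius_nm**2
    structure = np.where(
        footprint, np.sqrt(np.maximum(tip_radius_nm**2 - d2, 0.0)) - tip_radius_nm, 0.0
    )
    dilated = ndimage.grey_dilation(
        topo.heights, footprint=footprint, structure=structure
    )
    return topo.with_heights(dilated, tip_radius_nm=tip_radius_nm)


def add_instrument_artifacts(
    topo: Topograph,
    art: ArtifactSpec,
    seed: np.random.Generator | int | None = None,
) -> Topograph:
    """Add row offsets, a global plane and i.i.d. pixel noise (seeded).

    The same seed always produces bit-identical output.  The all-zero
    :class:`ArtifactSpec` (with ``tip_radius_nm`` ignored here — tip dilation
    is a separate operation) is the identity.
    """
    rng = np.random.default_rng(seed)
    nrows, ncols = topo.shape
    px = topo.pixel_size_nm
    h = topo.heights.copy()
    row_offsets = np.zeros(nrows)
    if art.row_offset_sd_nm > 0:
        row_offsets = rng.normal(0.0, art.row_offset_sd_nm, size=nrows)
        h += row_offsets[:, None]
    a, b, c = art.tilt
    if any(v != 0 for v in (a, b, c)):
        x = np.arange(ncols) * px
        y = np.arange(nrows) * px
        h += a * x[None, :] + b * y[:, None] + c
    if art.noise_sd_nm > 0:
        h += rng.normal(0.0, art.noise_sd_nm, size=h.shape)
    out = topo.with_heights(h, artifacts=asdict(art))
    out.meta["true_row_offsets"] = row_offsets
    return out


# ---------------------------------------------------------------------------
# calibration helpers


def smoothing_gain(period_nm: float, sample_spacing_nm: float, window: int = 3) -> float:
    """Amplitude gain of a centred ``window``-sample moving average applied to
    a sinusoid of the given period sampled at ``sample_spacing_nm``."""
    if window != 3:
        # general closed form: Dirichlet kernel
        k = np.arange(-(window // 2), window // 2 + 1)
        return float(np.mean(np.cos(2 * math.pi * k * sample_spacing_nm / period_nm)))
    return (1.0 + 2.0 * math.cos(2.0 * math.pi * sample_spacing_nm / period_nm)) / 3.0


def amplitude_for_rms(
    target_rms_nm: float,
    period_nm: float,
    pixel_size_nm: float,
    smooth_window: int = 3,
) -> float:
    """Sinusoid amplitude whose *measured* axial RMS equals ``target_rms_nm``.

    Inverts the analytic sinusoid relation RMS = a/sqrt(2), corrected for the
    profile pipeline's 3-sample rolling-average gain at the expected digitised
    sample spacing (``DIGITIZED_STEP_FACTOR`` pixels of true arc per sample).
    """
    spacing = DIGITIZED_STEP_FACTOR * pixel_size_nm
    g = smoothing_gain(period_nm, spacing, smooth_window)
    if g < 0.1:
        raise ValueError(
            "period too short relative to pixel size: smoothing would erase it"
        )
    return target_rms_nm * math.sqrt(2.0) / g


# ---------------------------------------------------------------------------
# ground-truth serialisation


def ground_truth_to_json(records: Sequence[GroundTruthRecord], path: str | Path) -> Path:
    path = Path(path)
    payload = []
    for r in records:
        entry = {
            "structure_id": r.structure_id,
            "class_label": r.class_label,
            "polyline_nm": np.round(r.polyline_nm, 3).tolist(),
            "contour_length_nm": round(r.contour_length_nm, 4),
            "mean_apex_height_nm": round(r.mean_apex_height_nm, 4),
            "bump_period_nm": r.bump_period_nm,
            "params": {k: (v if not isinstance(v, np.ndarray) else v.tolist())
                       for k, v in r.params.items()},
        }
        if r.bead_arc_nm is not None:
            entry["bead_arc_nm"] = np.round(r.bead_arc_nm, 3).tolist()
        payload.append(entry)
    path.write_text(json.dumps(payload, indent=1))
    return path


def ground_truth_from_json(path: str | Path) -> list[GroundTruthRecord]:
    payload = json.loads(Path(path).read_text())
    records = []
    for entry in payload:
        records.append(
            GroundTruthRecord(
                structure_id=entry["structure_id"],
                class_label=entry["class_label"],
                polyline_nm=np.asarray(entry["polyline_nm"], dtype=float),
                contour_length_nm=entry["contour_length_nm"],
                mean_apex_height_nm=entry["mean_apex_height_nm"],
                bump_period_nm=entry.get("bump_period_nm"),
                params=entry.get("params", {}),
                bead_arc_nm=(
                    np.asarray(entry["bead_arc_nm"], dtype=float)
                    if "bead_arc_nm" in entry
                    else None
                ),
            )
        )
    return records
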