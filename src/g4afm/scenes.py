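"""Scene-level synthetic topograph generation.

A *scene* is a set of AFM fields populated with structures drawn from
configured classes, rendered with instrument artifacts and accompanied by
per-structure ground truth.  Presets reproduce the study conditions:

``g4_scene``
    Self-assembled G4 filaments before wet/dry cycling: apex heights drawn
    N(3.4, 0.2) nm across molecules, sinusoidal axial bumps with a 5.4 nm
    repeat, per-structure roughness targets N(0.21, 0.07) nm, N = 33.
``post_cycling_scene``
    The smoother post-cycling filaments: heights N(2.6, 0.1) nm, repeat
    5.1 nm, roughness targets N(0.07, 0.02) nm, N = 15.
``mixed_scene``
    Tall filaments (apex 2.5 nm) mixed with thin uniform chains (0.9 nm,
    contour 50-100 nm) for the bimodal height-classification analysis.
``ionic_exchange_scene``
    A paired before/after field: in the "after" image most G4s are removed
    or fragmented and the thin chains are re-rendered as contracted beaded
    chains (beads ~2 nm high, spacing N(11, 4) nm, inter-bead 0.2 nm).

Pixel size defaults to 0.5 nm/px (2 px/nm); structures are placed without
mutual overlap, since the analysis chain does not disentangle crossing
filaments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy import ndimage

from .synth import (
    ArtifactSpec,
    BackboneModel,
    BeadSpec,
    FilamentSpec,
    GroundTruthRecord,
    add_instrument_artifacts,
    amplitude_for_rms,
    apply_tip_convolution,
    ground_truth_to_json,
    generate_backbone,
    render_beaded_chain,
    render_filament,
)
from .topograph import Topograph, save_txt

__all__ = [
    "StructureGroup",
    "PairedOptions",
    "SceneConfig",
    "SceneField",
    "generate_scene",
    "g4_scene",
    "post_cycling_scene",
    "mixed_scene",
    "ionic_exchange_scene",
    "scene_from_yaml",
    "save_scene",
]


@dataclass
class StructureGroup:
    """A class of structures to scatter across the scene."""

    class_label: str  # "G4" or "RNA_like"
    count: int
    length_range_nm: tuple[float, float]
    persistence_length_nm: float
    height_mean_nm: float
    height_sd_nm: float = 0.0
    period_nm: float | None = None
    rms_mean_nm: float | None = None  # per-structure roughness targets ...
    rms_sd_nm: float = 0.0            # ... converted to sinusoid amplitudes
    amplitude_nm: float | None = None  # overrides rms targets when set
    apparent_width_nm: float = 5.0
    waveform: str = "sine"


@dataclass
class PairedOptions:
    """How the "after solution exchange" field differs from the "before"."""

    g4_remove_fraction: float = 0.8
    g4_retained_fraction: float = 0.5  # contour fraction kept when fragmented
    g4_max_fragments: int = 3
    rna_to_beads: bool = True
    bead: BeadSpec = field(default_factory=BeadSpec)
    shift_px: tuple[int, int] = (0, 0)  # (row, col) shift of the after field


@dataclass
class SceneConfig:
    image_px: int = 512
    pixel_size_nm: float = 0.5
    n_images: int = 1
    groups: list[StructureGroup] = field(default_factory=list)
    artifacts: ArtifactSpec = field(default_factory=ArtifactSpec)
    margin_nm: float = 10.0
    min_separation_nm: float = 6.0
    max_attempts: int = 400
    backbone_step_nm: float = 0.25
    paired: PairedOptions | None = None


@dataclass
class SceneField:
    """One rendered image with its ground truth (and optional paired image)."""

    topo: Topograph
    records: list[GroundTruthRecord]
    pristine: Topograph | None = None  # tip-convolved, artifact-free surface
    after_topo: Topograph | None = None
    after_records: list[GroundTruthRecord] | None = None
    after_pristine: Topograph | None = None


# ---------------------------------------------------------------------------
# placement


class _Placer:
    """Rejection-samples backbone placements without mutual overlap."""

    def __init__(self, image_px: int, pixel_size_nm: float, margin_nm: float):
        self.n = image_px
        self.px = pixel_size_nm
        self.margin = margin_nm
        self.occupied = np.zeros((image_px, image_px), dtype=bool)
        self._dist = None  # lazily recomputed distance-to-occupied (px)

    def _distance_map(self) -> np.ndarray:
        if self._dist is None:
            if self.occupied.any():
                self._dist = ndimage.distance_transform_edt(~self.occupied)
            else:
                self._dist = np.full(self.occupied.shape, np.inf)
        return self._dist

    def try_place(
        self, shape: np.ndarray, clearance_nm: float, rng: np.random.Generator
    ) -> np.ndarray | None:
        """Translate a backbone shape to a random clear position, or None."""
        extent = self.px * (self.n - 1)
        lo_x = self.margin - shape[:, 0].min()
        hi_x = extent - self.margin - shape[:, 0].max()
        lo_y = self.margin - shape[:, 1].min()
        hi_y = extent - self.margin - shape[:, 1].max()
        if hi_x <= lo_x or hi_y <= lo_y:
            return None  # shape too large for the field
        shift = np.array([rng.uniform(lo_x, hi_x), rng.uniform(lo_y, hi_y)])
        poly = shape + shift
        cols = np.clip(np.rint(poly[:, 0] / self.px).astype(int), 0, self.n - 1)
        rows = np.clip(np.rint(poly[:, 1] / self.px).astype(int), 0, self.n - 1)
        dist = self._distance_map()
        if (dist[rows, cols] * self.px < clearance_nm).any():
            return None
        self.occupied[rows, cols] = True
        self._dist = None
        return poly


# ---------------------------------------------------------------------------
# generation


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, low: float
) -> float:
    if sd == 0:
        return mean
    val = rng.normal(mean, sd)
    while val <= low:
        val = rng.normal(mean, sd)
    return float(val)


def _filament_spec(
    group: StructureGroup, cfg: SceneConfig, rng: np.random.Generator
) -> FilamentSpec:
    height = _truncated_normal(rng, group.height_mean_nm, group.height_sd_nm, 0.05)
    if group.amplitude_nm is not None:
        amp = group.amplitude_nm
    elif group.rms_mean_nm is not None and group.period_nm:
        rms = _truncated_normal(rng, group.rms_mean_nm, group.rms_sd_nm, 0.005)
        amp = amplitude_for_rms(rms, group.period_nm, cfg.pixel_size_nm)
    else:
        amp = 0.0
    return FilamentSpec(
        baseline_height_nm=height,
        bump_period_nm=group.period_nm or 0.0,
        bump_amplitude_nm=amp,
        apparent_width_nm=group.apparent_width_nm,
        class_label=group.class_label,
        waveform=group.waveform,
    )


def _render_after(
    field_records: list[GroundTruthRecord],
    cfg: SceneConfig,
    rng: np.random.Generator,
) -> tuple[Topograph, list[GroundTruthRecord]]:
    """Re-render the same field after a simulated solution exchange."""
    opts = cfg.paired
    assert opts is not None
    blank = Topograph(
        np.zeros((cfg.image_px, cfg.image_px)), cfg.pixel_size_nm,
        meta={"paired": "after"},
    )
    shift_nm = np.array(
        [opts.shift_px[1] * cfg.pixel_size_nm, opts.shift_px[0] * cfg.pixel_size_nm]
    )
    out_records: list[GroundTruthRecord] = []
    next_id = 0
    for rec in field_records:
        poly = rec.polyline_nm + shift_nm
        extent = cfg.pixel_size_nm * (cfg.image_px - 1)
        poly = np.clip(poly, 0.0, extent)  # small shifts stay inside margins
        if rec.class_label == "G4":
            if rng.uniform() < opts.g4_remove_fraction:
                continue
            # fragment: keep `retained_fraction` of the contour in 1..max pieces
            n_frag = int(rng.integers(1, opts.g4_max_fragments + 1))
            seg = np.hypot(*np.diff(poly, axis=0).T)
            arcs = np.concatenate([[0.0], np.cumsum(seg)])
            total = arcs[-1]
            keep_len = opts.g4_retained_fraction * total / n_frag
            starts = np.sort(rng.uniform(0, total - keep_len, size=n_frag))
            spec = FilamentSpec(
                baseline_height_nm=rec.params.get("baseline_height_nm", 2.6),
                bump_period_nm=rec.params.get("bump_period_nm", 0.0),
                bump_amplitude_nm=rec.params.get("bump_amplitude_nm", 0.0),
                apparent_width_nm=rec.params.get("apparent_width_nm", 5.0),
                class_label="G4",
                waveform=rec.params.get("waveform", "sine"),
            )
            for s0 in starts:
                sel = (arcs >= s0) & (arcs <= s0 + keep_len)
                if sel.sum() < 2:
                    continue
                frag = poly[sel]
                out_records.append(
                    render_filament(blank, frag, spec, rng, structure_id=next_id)
                )
                next_id += 1
        elif rec.class_label == "RNA_like" and opts.rna_to_beads:
            out_records.append(
                render_beaded_chain(blank, poly, opts.bead, rng, structure_id=next_id)
            )
            next_id += 1
        else:
            spec = FilamentSpec(
                baseline_height_nm=rec.params.get("baseline_height_nm", 0.9),
                apparent_width_nm=rec.params.get("apparent_width_nm", 4.0),
                class_label=rec.class_label,
            )
            out_records.append(
                render_filament(blank, poly, spec, rng, structure_id=next_id)
            )
            next_id += 1
    return blank, out_records


def generate_scene(cfg: SceneConfig, seed: int) -> list[SceneField]:
    """Generate the scene: deterministic for identical ``(cfg, seed)``.

    Structures are distributed round-robin across ``n_images`` fields and
    placed by rejection sampling with a clearance of
    ``apparent_width + min_separation``; a field that cannot accommodate its
    structures within ``max_attempts`` tries per structure raises.
    """
    root = np.random.SeedSequence(seed)
    image_seeds = root.spawn(cfg.n_images)

    # round-robin assignment of structure requests to images
    requests: list[list[StructureGroup]] = [[] for _ in range(cfg.n_images)]
    slot = 0
    for group in cfg.groups:
        for _ in range(group.count):
            requests[slot % cfg.n_images].append(group)
            slot += 1

    fields: list[SceneField] = []
    sid = 0
    for img_idx, (img_seed, reqs) in enumerate(zip(image_seeds, requests)):
        rng = np.random.default_rng(img_seed)
        topo = Topograph(
            np.zeros((cfg.image_px, cfg.image_px)),
            cfg.pixel_size_nm,
            meta={"scene_image": img_idx, "seed": seed},
        )
        placer = _Placer(cfg.image_px, cfg.pixel_size_nm, cfg.margin_nm)
        records: list[GroundTruthRecord] = []
        for group in reqs:
            placed = None
            for _ in range(cfg.max_attempts):
                L = rng.uniform(*group.length_range_nm)
                shape = generate_backbone(
                    BackboneModel(L, group.persistence_length_nm, cfg.backbone_step_nm),
                    rng,
                )
                clearance = group.apparent_width_nm + cfg.min_separation_nm
                placed = placer.try_place(shape, clearance, rng)
                if placed is not None:
                    break
            if placed is None:
                raise RuntimeError(
                    f"could not place a {group.class_label} structure after "
                    f"{cfg.max_attempts} attempts: the scene is overcrowded"
                )
            spec = _filament_spec(group, cfg, rng)
            records.append(
                render_filament(topo, placed, spec, rng, structure_id=sid)
            )
            sid += 1

        pristine = apply_tip_convolution(topo, cfg.artifacts.tip_radius_nm)
        noisy = add_instrument_artifacts(pristine, cfg.artifacts, rng)
        field_out = SceneField(topo=noisy, records=records, pristine=pristine)

        if cfg.paired is not None:
            after_rng = np.random.default_rng(img_seed.spawn(1)[0])
            after_topo, after_records = _render_after(records, cfg, after_rng)
            after_pristine = apply_tip_convolution(
                after_topo, cfg.artifacts.tip_radius_nm
            )
            after_noisy = add_instrument_artifacts(
                after_pristine, cfg.artifacts, after_rng
            )
            field_out.after_topo = after_noisy
            field_out.after_records = after_records
            field_out.after_pristine = after_pristine
        fields.append(field_out)
    return fields


# ---------------------------------------------------------------------------
# presets (the study conditions)


def g4_scene(n_structures: int = 33, n_images: int = 7) -> SceneConfig:
    """Pre-cycling G4 filaments: 3.4 +/- 0.2 nm apex, 5.4 nm axial repeat,
    per-molecule roughness targets 0.21 +/- 0.07 nm."""
    return SceneConfig(
        n_images=n_images,
        groups=[
            StructureGroup(
                class_label="G4",
                count=n_structures,
                length_range_nm=(120.0, 200.0),
                persistence_length_nm=250.0,
                height_mean_nm=3.4,
                height_sd_nm=0.2,
                period_nm=5.4,
                rms_mean_nm=0.21,
                rms_sd_nm=0.07,
                apparent_width_nm=5.0,
            )
        ],
    )


def post_cycling_scene(n_structures: int = 15, n_images: int = 4) -> SceneConfig:
    """Post-cycling G4 filaments: smoother (0.07 +/- 0.02 nm roughness) and
    lower (2.6 +/- 0.1 nm), repeat 5.1 nm."""
    return SceneConfig(
        n_images=n_images,
        groups=[
            StructureGroup(
                class_label="G4",
                count=n_structures,
                length_range_nm=(120.0, 200.0),
                persistence_length_nm=250.0,
                height_mean_nm=2.6,
                height_sd_nm=0.1,
                period_nm=5.1,
                rms_mean_nm=0.07,
                rms_sd_nm=0.02,
                apparent_width_nm=5.0,
            )
        ],
    )


def mixed_scene(
    n_g4: int = 16, n_rna: int = 32, n_images: int = 4
) -> SceneConfig:
    """Two-class field: tall filaments (2.5 nm apex) and thin uniform chains
    (0.9 nm, 50-100 nm contour) for bimodal height classification."""
    return SceneConfig(
        n_images=n_images,
        groups=[
            StructureGroup(
                class_label="G4",
                count=n_g4,
                length_range_nm=(80.0, 180.0),
                persistence_length_nm=250.0,
                height_mean_nm=2.5,
                height_sd_nm=0.1,
                period_nm=5.1,
                rms_mean_nm=0.07,
                rms_sd_nm=0.02,
                apparent_width_nm=5.0,
            ),
            StructureGroup(
                class_label="RNA_like",
                count=n_rna,
                length_range_nm=(50.0, 100.0),
                persistence_length_nm=18.0,
                height_mean_nm=0.9,
                height_sd_nm=0.1,
                apparent_width_nm=4.0,
            ),
        ],
    )


def ionic_exchange_scene(
    n_rna: int = 33,
    n_g4: int = 10,
    n_images: int = 5,
    g4_remove_fraction: float = 0.8,
    shift_px: tuple[int, int] = (0, 0),
) -> SceneConfig:
    """Paired before/after field: thin chains contract into beaded chains
    (beads ~2 nm, spacing 11 +/- 4 nm, inter-bead 0.2 nm) and most tall
    filaments are removed or fragmented."""
    return SceneConfig(
        n_images=n_images,
        groups=[
            StructureGroup(
                class_label="RNA_like",
                count=n_rna,
                length_range_nm=(60.0, 120.0),
                persistence_length_nm=25.0,
                height_mean_nm=0.9,
                height_sd_nm=0.1,
                apparent_width_nm=4.0,
            ),
            StructureGroup(
                class_label="G4",
                count=n_g4,
                length_range_nm=(80.0, 160.0),
                persistence_length_nm=250.0,
                height_mean_nm=2.6,
                height_sd_nm=0.1,
                period_nm=5.1,
                rms_mean_nm=0.07,
                rms_sd_nm=0.02,
                apparent_width_nm=5.0,
            ),
        ],
        paired=PairedOptions(
            g4_remove_fraction=g4_remove_fraction,
            shift_px=shift_px,
        ),
    )


_PRESETS = {
    "g4": g4_scene,
    "post_cycling": post_cycling_scene,
    "mixed": mixed_scene,
    "ionic_exchange": ionic_exchange_scene,
}


def scene_from_yaml(path: str | Path) -> SceneConfig:
    """Build a :class:`SceneConfig` from a YAML file.

    The file either names a ``preset`` (with optional keyword overrides) or
    spells out the full config with a ``groups`` list.
    """
    data = yaml.safe_load(Path(path).read_text()) or {}
    if "preset" in data:
        name = data.pop("preset")
        if name not in _PRESETS:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
        preset_kwargs = data.pop("preset_args", {})
        cfg = _PRESETS[name](**preset_kwargs)
        if data:
            cfg = replace(cfg, **data)
        return cfg
    groups = [StructureGroup(**g) for g in data.pop("groups", [])]
    artifacts = ArtifactSpec(**data.pop("artifacts", {}))
    paired = data.pop("paired", None)
    if paired is not None:
        bead = BeadSpec(**paired.pop("bead", {}))
        paired = PairedOptions(bead=bead, **paired)
    return SceneConfig(groups=groups, artifacts=artifacts, paired=paired, **data)


def save_scene(fields: Sequence[SceneField], outdir: str | Path) -> Path:
    """Write every field as text matrix + sidecar, with ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, f in enumerate(fields):
        save_txt(f.topo, outdir / f"field_{i:02d}.txt")
        ground_truth_to_json(f.records, outdir / f"field_{i:02d}_truth.json")
        if f.after_topo is not None:
            save_txt(f.after_topo, outdir / f"field_{i:02d}_after.txt")
            ground_truth_to_json(
                f.after_records or [], outdir / f"field_{i:02d}_after_truth.json"
            )
    return outdir
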