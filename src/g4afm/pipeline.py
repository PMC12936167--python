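"""End-to-end orchestration and the synthetic parameter-recovery benchmark.

``analyze_topograph`` composes flatten -> grain detection -> tracing ->
profile statistics for one image; ``analyze_fields`` pools several images
the way population statistics are reported (per-molecule values gathered
from multiple AFM images, mean +/- SD with N).

``run_synthetic_benchmark`` generates the canonical scenes at the study
conditions, runs the full pipeline on them, and compares every recovered
quantity against its generator value with a 3-standard-error criterion —
a check that the tracing/peak/fit chain is unbiased at the reported
parameter values.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import compare as cmp_mod
from . import height_classes as hc
from . import interpret
from . import profile_stats as ps
from .flatten import FlattenResult, flatten
from .scenes import (
    g4_scene,
    generate_scene,
    ionic_exchange_scene,
    mixed_scene,
    post_cycling_scene,
)
from .topograph import Topograph
from .trace import GrainMask, HeightProfile, Trace, trace_topograph

__all__ = [
    "PipelineConfig",
    "FieldAnalysis",
    "analyze_topograph",
    "pooled_separation_fit",
    "run_synthetic_benchmark",
    "RecoveryEntry",
]


@dataclass
class PipelineConfig:
    """Tunable parameters of the analysis chain (defaults per module)."""

    flatten_order: int = 1
    exclusion_quantile: float = 0.7
    height_threshold_nm: float = 0.4
    min_size_px: int = 20
    exclude_border: bool = True
    detect_smooth_sigma_px: float = 1.0
    dilation_px: int = 3
    smooth_window_px: int = 3
    min_prominence_nm: float = ps.DEFAULT_MIN_PROMINENCE_NM
    separation_bin_nm: float = ps.DEFAULT_SEPARATION_BIN_NM
    height_bin_nm: float = hc.DEFAULT_HEIGHT_BIN_NM
    quartet_spacing_nm: float = interpret.QUARTET_SPACING_NM


@dataclass
class FieldAnalysis:
    """All per-image pipeline products."""

    flatten_result: FlattenResult
    grains: GrainMask
    traces: dict[int, Trace]
    profiles: dict[int, HeightProfile]
    stats: list[ps.StructureStats]

    @property
    def topo(self) -> Topograph:
        return self.flatten_result.corrected


def analyze_topograph(topo: Topograph, cfg: PipelineConfig | None = None) -> FieldAnalysis:
    """Flatten one raw topograph and measure every traceable structure."""
    cfg = cfg or PipelineConfig()
    flat = flatten(topo, order=cfg.flatten_order,
                   exclusion_quantile=cfg.exclusion_quantile)
    grains, traces, profiles = trace_topograph(
        flat.corrected,
        height_threshold_nm=cfg.height_threshold_nm,
        min_size_px=cfg.min_size_px,
        exclude_border=cfg.exclude_border,
        dilation_px=cfg.dilation_px,
        smooth_window_px=cfg.smooth_window_px,
        detect_smooth_sigma_px=cfg.detect_smooth_sigma_px,
    )
    stats = [
        ps.structure_stats(traces[g], profiles[g], topo.pixel_size_nm,
                           cfg.min_prominence_nm)
        for g in sorted(traces)
    ]
    return FieldAnalysis(flat, grains, traces, profiles, stats)


def analyze_fields(
    topos: Sequence[Topograph], cfg: PipelineConfig | None = None
) -> list[FieldAnalysis]:
    return [analyze_topograph(t, cfg) for t in topos]


def pooled_separation_fit(
    analyses: Sequence[FieldAnalysis], cfg: PipelineConfig | None = None
) -> tuple[ps.GaussianFit, np.ndarray]:
    """Pool peak separations from all structures and fit one Gaussian."""
    cfg = cfg or PipelineConfig()
    seps = np.concatenate(
        [np.asarray(s.separations_nm) for a in analyses for s in a.stats]
        or [np.empty(0)]
    )
    fit = ps.fit_gaussian(seps, bin_width_nm=cfg.separation_bin_nm,
                          domain=ps.DEFAULT_SEPARATION_DOMAIN)
    return fit, seps


# ---------------------------------------------------------------------------
# ground-truth matching (for recovery scoring)


def match_to_ground_truth(
    analysis: FieldAnalysis,
    records,
    pixel_size_nm: float,
    tol_nm: float = 15.0,
) -> dict[int, int]:
    """Map grain id -> ground-truth structure_id by nearest centroid."""
    out: dict[int, int] = {}
    for s in analysis.stats:
        if s.centroid_nm is None:
            continue
        c = np.asarray(s.centroid_nm)
        best, best_d = None, np.inf
        for rec in records:
            d = float(np.hypot(*(rec.centroid_nm - c)))
            if d < best_d:
                best, best_d = rec.structure_id, d
        if best is not None and best_d <= tol_nm:
            out[s.structure_id] = best
    return out


# ---------------------------------------------------------------------------
# benchmark


@dataclass
class RecoveryEntry:
    """One recovered-vs-generator comparison."""

    name: str
    value: float
    expected: float
    se: float
    n: int
    passed: bool
    note: str = ""

    @staticmethod
    def from_values(name, value, expected, se, n, note="") -> "RecoveryEntry":
        ok = bool(abs(value - expected) <= 3.0 * se) if se > 0 else False
        return RecoveryEntry(name, float(value), float(expected), float(se),
                             int(n), ok, note)


def _population(values: np.ndarray) -> tuple[float, float, int]:
    v = np.asarray(values, dtype=float)
    n = len(v)
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0, n


def _sub_seeds(seed: int, k: int) -> list[int]:
    # independent 31-bit child seeds
    return [int(s) & 0x7FFFFFFF for s in np.random.SeedSequence(seed).generate_state(k)]


def benchmark_g4_recovery(seed: int, cfg: PipelineConfig | None = None) -> dict:
    """Pre-cycling scene: periodicity, mean trace height, RMS roughness."""
    cfg = cfg or PipelineConfig()
    scene = g4_scene()
    fields = generate_scene(scene, seed)
    analyses = analyze_fields([f.topo for f in fields], cfg)

    fit, seps = pooled_separation_fit(analyses, cfg)
    heights = np.array([s.mean_height_nm for a in analyses for s in a.stats])
    rms = np.array([s.rms_roughness_nm for a in analyses for s in a.stats])
    h_mean, h_se, h_n = _population(heights)
    r_mean, r_se, r_n = _population(rms)
    group = scene.groups[0]
    quartets = interpret.quartet_count(fit.mean, fit.sd, cfg.quartet_spacing_nm)
    return {
        "periodicity": RecoveryEntry.from_values(
            "periodicity", fit.mean, group.period_nm, fit.stderr_mean, len(seps),
            note="Gaussian fit to pooled peak-peak separations",
        ),
        "height_pre": RecoveryEntry.from_values(
            "height_pre", h_mean, group.height_mean_nm, h_se, h_n,
            note="population mean trace height",
        ),
        "rms_pre": RecoveryEntry.from_values(
            "rms_pre", r_mean, group.rms_mean_nm, r_se, r_n,
            note="population mean per-structure RMS roughness",
        ),
        "quartets": {
            "n": quartets.n_quartets,
            "uncertainty": quartets.n_uncertainty,
            "from_separation_nm": fit.mean,
        },
        "n_structures": h_n,
    }


def benchmark_post_cycling(seed: int, cfg: PipelineConfig | None = None) -> dict:
    """Post-cycling scene: lower mean height, much lower roughness."""
    cfg = cfg or PipelineConfig()
    scene = post_cycling_scene()
    fields = generate_scene(scene, seed)
    analyses = analyze_fields([f.topo for f in fields], cfg)
    heights = np.array([s.mean_height_nm for a in analyses for s in a.stats])
    rms = np.array([s.rms_roughness_nm for a in analyses for s in a.stats])
    h_mean, h_se, h_n = _population(heights)
    r_mean, r_se, r_n = _population(rms)
    group = scene.groups[0]
    return {
        "height_post": RecoveryEntry.from_values(
            "height_post", h_mean, group.height_mean_nm, h_se, h_n,
            note="population mean trace height after cycling",
        ),
        "rms_post": RecoveryEntry.from_values(
            "rms_post", r_mean, group.rms_mean_nm, r_se, r_n,
            note="population mean RMS roughness after cycling",
        ),
        "n_structures": h_n,
    }


def benchmark_two_class(seed: int, cfg: PipelineConfig | None = None) -> dict:
    """Mixed scene: bimodal masked height distribution + classification."""
    cfg = cfg or PipelineConfig()
    scene = mixed_scene()
    fields = generate_scene(scene, seed)
    analyses = analyze_fields([f.topo for f in fields], cfg)

    hists = [
        hc.masked_height_distribution(
            a.topo, a.grains.labels, bin_width_nm=cfg.height_bin_nm,
            domain=(0.0, 4.0),
        )
        for a in analyses
    ]
    pooled = hc.sum_histograms(hists)
    mix = hc.fit_two_gaussians(pooled)

    # classification accuracy vs ground truth
    n_correct = 0
    n_total = 0
    for a, f in zip(analyses, fields):
        gt = {r.structure_id: r.class_label for r in f.records}
        mapping = match_to_ground_truth(a, f.records, f.topo.pixel_size_nm)
        for s in a.stats:
            truth = gt.get(mapping.get(s.structure_id))
            if truth is None:
                continue
            label = hc.classify_structure(s, mix)
            s.class_label = label
            n_total += 1
            if label == truth:
                n_correct += 1
    accuracy = n_correct / n_total if n_total else float("nan")
    g4_group = next(g for g in scene.groups if g.class_label == "G4")
    rna_group = next(g for g in scene.groups if g.class_label == "RNA_like")
    # the comparison is against the *nominal* generator mean, so the finite-N
    # sampling of per-structure apex heights contributes to the uncertainty
    se_high = float(np.hypot(mix.high.stderr_mean,
                             g4_group.height_sd_nm / np.sqrt(g4_group.count)))
    se_low = float(np.hypot(mix.low.stderr_mean,
                            rna_group.height_sd_nm / np.sqrt(rna_group.count)))
    return {
        "class_high": RecoveryEntry.from_values(
            "class_high", mix.high.mean, g4_group.height_mean_nm,
            se_high, pooled.n_pixels,
            note="higher Gaussian component of the masked pixel-height histogram",
        ),
        "class_low": RecoveryEntry.from_values(
            "class_low", mix.low.mean, rna_group.height_mean_nm,
            se_low, pooled.n_pixels,
            note="lower Gaussian component of the masked pixel-height histogram",
        ),
        "classification_accuracy": accuracy,
        "n_classified": n_total,
        "degenerate": mix.degenerate,
    }


def benchmark_beads(seed: int, cfg: PipelineConfig | None = None) -> dict:
    """Paired ionic-exchange scene: bead spacing + persistence statistics."""
    cfg = cfg or PipelineConfig()
    scene = ionic_exchange_scene()
    fields = generate_scene(scene, seed)

    bead_cfg = PipelineConfig(
        height_threshold_nm=0.1,  # below the 0.2 nm inter-bead baseline
        min_size_px=cfg.min_size_px,
    )
    spacings: list[np.ndarray] = []
    n_chains = 0
    removed_obs: list[float] = []
    for f in fields:
        before = analyze_topograph(f.topo, cfg)
        after = analyze_topograph(f.after_topo, bead_cfg)
        # bead morphometry on after-image chains classed as beaded by truth
        truth_after = {r.structure_id: r for r in (f.after_records or [])}
        mapping = match_to_ground_truth(after, f.after_records or [],
                                        f.after_topo.pixel_size_nm)
        for gid, profile in after.profiles.items():
            rec = truth_after.get(mapping.get(gid))
            if rec is None or rec.class_label != "beaded":
                continue
            report = cmp_mod.bead_stats(profile)
            if len(report.spacings_nm):
                spacings.append(report.spacings_nm)
                n_chains += 1
        # persistence of tall filaments across the exchange
        pair = cmp_mod.register_images(f.topo, f.after_topo, max_shift_px=16,
                                       min_confidence=0.05)
        g4_before = {
            s.structure_id: before.traces[s.structure_id]
            for s in before.stats
            if s.mean_height_nm > 1.8 and s.structure_id in before.traces
        }
        if g4_before:
            match = cmp_mod.match_structures(g4_before, after.traces, pair)
            rep = cmp_mod.persistence_stats(match, g4_before, after.traces,
                                            f.topo.pixel_size_nm)
            removed_obs.append(rep.removed_fraction)
    all_sp = np.concatenate(spacings) if spacings else np.empty(0)
    bead = scene.paired.bead
    se = float(all_sp.std(ddof=1) / np.sqrt(len(all_sp))) if len(all_sp) > 1 else 0.0
    return {
        "bead_spacing": RecoveryEntry.from_values(
            "bead_spacing", all_sp.mean() if len(all_sp) else float("nan"),
            bead.bead_spacing_mean_nm, se, len(all_sp),
            note=f"pooled bead-to-bead spacings from {n_chains} chains",
        ),
        "n_chains": n_chains,
        "g4_removed_fraction_observed": float(np.mean(removed_obs))
        if removed_obs else float("nan"),
        "g4_remove_fraction_configured": scene.paired.g4_remove_fraction,
    }


def run_synthetic_benchmark(seed: int, cfg: PipelineConfig | None = None) -> dict:
    """Run all canonical scenes and gather recovered-vs-generator entries."""
    s_g4, s_post, s_mix, s_bead = _sub_seeds(seed, 4)
    out: dict = {"seed": seed}
    out.update(benchmark_g4_recovery(s_g4, cfg))
    out.update(benchmark_post_cycling(s_post, cfg))
    out.update(benchmark_two_class(s_mix, cfg))
    out.update(benchmark_beads(s_bead, cfg))
    rms_pre = out["rms_pre"].value
    rms_post = out["rms_post"].value
    out["roughness_drop"] = {
        "pre": rms_pre,
        "post": rms_post,
        "post_below_pre": bool(rms_post < rms_pre),
    }
    return out


def benchmark_to_json(report: dict, path: str | Path) -> Path:
    path = Path(path)

    def enc(obj):
        if isinstance(obj, RecoveryEntry):
            return asdict(obj)
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(type(obj).__name__)

    path.write_text(json.dumps(report, default=enc, indent=1))
    return path
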