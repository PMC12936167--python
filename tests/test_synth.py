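"""Generator tests: WLC geometry, rendering, artifacts, tip convolution."""

import numpy as np
import pytest

from g4afm import (
    ArtifactSpec,
    BackboneModel,
    BeadSpec,
    FilamentSpec,
    Topograph,
    add_instrument_artifacts,
    apply_tip_convolution,
    generate_backbone,
    render_beaded_chain,
    render_filament,
    wlc_mean_square_end_to_end,
)
from g4afm.scenes import (
    SceneConfig,
    StructureGroup,
    generate_scene,
    ionic_exchange_scene,
)
from g4afm.synth import polyline_arc_length, resample_polyline

from conftest import small_g4_scene


class TestBackbone:
    def test_rigid_rod_limit(self):
        """Very stiff chain: end-to-end distance equals the contour length."""
        poly = generate_backbone(BackboneModel(100.0, 1e9), 0)
        r = np.hypot(*(poly[-1] - poly[0]))
        assert r == pytest.approx(100.0, abs=BackboneModel(100.0, 1e9).step_nm)

    def test_arc_length_matches_contour(self):
        model = BackboneModel(137.0, 20.0)
        poly = generate_backbone(model, 3)
        assert polyline_arc_length(poly) == pytest.approx(137.0, abs=model.step_nm)

    def test_wlc_ensemble_matches_closed_form(self):
        """<R^2> over 500 seeds agrees with the 2-D WLC formula (3 SEM)."""
        L, lp = 100.0, 10.0
        r2 = np.array(
            [
                ((p := generate_backbone(BackboneModel(L, lp), s))[-1] - p[0]) ** 2
                for s in range(500)
            ]
        ).sum(axis=1)
        expected = wlc_mean_square_end_to_end(L, lp)
        sem = r2.std(ddof=1) / np.sqrt(len(r2))
        assert abs(r2.mean() - expected) < 3 * sem

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            BackboneModel(-1.0, 10.0)
        with pytest.raises(ValueError):
            BackboneModel(10.0, 0.0)

    def test_rna_like_default_lengths_span_50_100nm(self):
        """The thin-chain preset draws contours in the 50-100 nm range."""
        cfg = ionic_exchange_scene()
        rna = next(g for g in cfg.groups if g.class_label == "RNA_like")
        lo, hi = rna.length_range_nm
        assert lo >= 50.0 and hi <= 120.0
        from g4afm.scenes import mixed_scene

        rna2 = next(g for g in mixed_scene().groups if g.class_label == "RNA_like")
        assert rna2.length_range_nm == (50.0, 100.0)


class TestRenderFilament:
    def test_constant_ridge(self, straight_ridge):
        """Amplitude 0 -> apex height 3.4 nm everywhere along the crest."""
        topo, rec = straight_ridge
        crest = topo.heights[32, 30:210]
        assert crest == pytest.approx(3.4, abs=1e-6)
        assert rec.mean_apex_height_nm == pytest.approx(3.4, abs=1e-9)

    def test_sinusoid_axial_rms(self, sine_ridge):
        """Axial apex RMS about its mean = amplitude / sqrt(2) (analytic)."""
        topo, rec, spec = sine_ridge
        crest = topo.heights[32, 40:200]  # away from the ends
        rms = np.sqrt(np.mean((crest - crest.mean()) ** 2))
        assert rms == pytest.approx(spec.bump_amplitude_nm / np.sqrt(2), rel=0.05)

    def test_rendered_peaks_separated_by_period(self, sine_ridge):
        """Crest maxima sit one bump period apart."""
        from scipy.signal import find_peaks

        topo, rec, spec = sine_ridge
        crest = topo.heights[32]
        idx, _ = find_peaks(crest, prominence=0.2)
        seps = np.diff(idx) * topo.pixel_size_nm
        assert np.mean(seps) == pytest.approx(spec.bump_period_nm, rel=0.05)

    def test_backbone_outside_image_rejected(self, blank_topo):
        poly = np.array([[0.0, 0.0], [500.0, 500.0]])
        with pytest.raises(ValueError, match="outside"):
            render_filament(blank_topo, poly, FilamentSpec(3.4), 0)

    def test_overlap_composes_by_max(self):
        """Crossing ridges: the junction keeps the taller surface, not the sum."""
        topo = Topograph(np.zeros((64, 64)), 0.5)
        h = np.column_stack([np.linspace(4, 27, 200), np.full(200, 16.0)])
        v = np.column_stack([np.full(200, 16.0), np.linspace(4, 27, 200)])
        render_filament(topo, h, FilamentSpec(3.4), 0)
        render_filament(topo, v, FilamentSpec(0.9, apparent_width_nm=4.0), 0)
        assert topo.heights.max() == pytest.approx(3.4, abs=1e-6)
        assert topo.heights[32, 32] == pytest.approx(3.4, abs=1e-6)


class TestBeadedChain:
    def test_deterministic_placement_sd_zero(self):
        """sd 0, spacing s, contour L -> floor(L/s) + 1 beads."""
        topo = Topograph(np.zeros((64, 256)), 0.5)
        poly = np.column_stack([np.linspace(5, 110, 400), np.full(400, 16.0)])
        bead = BeadSpec(bead_spacing_sd_nm=0.0, bead_spacing_mean_nm=11.0)
        rec = render_beaded_chain(topo, poly, bead, 0)
        L = polyline_arc_length(poly)
        assert len(rec.bead_arc_nm) == int(L // 11.0) + 1

    def test_profile_min_max_span(self):
        """Bead height 2 nm over 0.2 nm baseline -> crest spans ~0.2-2.0 nm."""
        topo = Topograph(np.zeros((64, 256)), 0.5)
        poly = np.column_stack([np.linspace(5, 110, 400), np.full(400, 16.0)])
        render_beaded_chain(topo, poly, BeadSpec(bead_spacing_sd_nm=0.0), 0)
        crest = topo.heights[32, 20:210]
        assert crest.max() == pytest.approx(2.0, abs=0.05)
        assert crest.min() == pytest.approx(0.2, abs=0.05)

    def test_spacing_draws_match_generator(self):
        """Generator spacings follow the censored truncated-normal renewal.

        Finite chains drop the last interval when it overshoots the contour,
        which biases retained spacings low (inspection paradox); the oracle
        is an independent numpy simulation of the same renewal process.
        """
        rng = np.random.default_rng(7)
        spacings = []
        for k in range(60):
            topo = Topograph(np.zeros((64, 512)), 0.5)
            poly = np.column_stack([np.linspace(5, 240, 900), np.full(900, 16.0)])
            rec = render_beaded_chain(topo, poly, BeadSpec(), rng)
            spacings.extend(np.diff(rec.bead_arc_nm))
        spacings = np.asarray(spacings)

        oracle_rng = np.random.default_rng(99)
        L = 235.0
        oracle = []
        for _ in range(800):
            pos = 0.0
            while True:
                step = oracle_rng.normal(11.0, 4.0)
                if step <= 0:
                    continue
                if pos + step > L:
                    break
                oracle.append(step)
                pos += step
        oracle = np.asarray(oracle)
        sem = np.hypot(
            spacings.std(ddof=1) / np.sqrt(len(spacings)),
            oracle.std(ddof=1) / np.sqrt(len(oracle)),
        )
        assert abs(spacings.mean() - oracle.mean()) < 3 * sem

    def test_nonpositive_spacing_rejected(self):
        with pytest.raises(ValueError):
            BeadSpec(bead_spacing_mean_nm=0.0)


def _brute_force_dilation(h, tip_radius, px):
    """Direct max-over-footprint spherical-cap dilation (independent oracle)."""
    n, m = h.shape
    out = np.full_like(h, -np.inf)
    r_px = int(np.floor(tip_radius / px))
    for i in range(n):
        for j in range(m):
            best = -np.inf
            for di in range(-r_px, r_px + 1):
                for dj in range(-r_px, r_px + 1):
                    d2 = (di * px) ** 2 + (dj * px) ** 2
                    if d2 > tip_radius**2:
                        continue
                    ii, jj = i + di, j + dj
                    if 0 <= ii < n and 0 <= jj < m:
                        cap = np.sqrt(tip_radius**2 - d2) - tip_radius
                        best = max(best, h[ii, jj] + cap)
            out[i, j] = best
    return out


class TestTipConvolution:
    def test_zero_radius_is_identity(self, rng):
        t = Topograph(rng.normal(size=(32, 32)), 0.5)
        out = apply_tip_convolution(t, 0.0)
        assert np.array_equal(out.heights, t.heights)

    def test_spike_against_brute_force(self):
        """Single spike: matches the direct dilation oracle on a 9x9 grid."""
        h = np.zeros((16, 16))
        h[8, 8] = 3.0
        t = Topograph(h, 0.5)
        out = apply_tip_convolution(t, 2.0)
        oracle = _brute_force_dilation(h, 2.0, 0.5)
        assert np.allclose(out.heights, oracle)
        assert out.heights[8, 8] == pytest.approx(3.0)  # apex preserved
        assert (out.heights > 0.1).sum() > 1  # spike becomes a plateau

    def test_ridge_widens_apex_unchanged(self, straight_ridge):
        topo, _ = straight_ridge
        out = apply_tip_convolution(topo, 2.0)
        w_before = (topo.heights[:, 100] > 1.7).sum()
        w_after = (out.heights[:, 100] > 1.7).sum()
        assert w_after > w_before
        assert out.heights[32, 100] == pytest.approx(3.4, abs=1e-6)
        oracle = _brute_force_dilation(topo.heights[16:48, 86:114], 2.0, 0.5)
        assert np.allclose(out.heights[21:43, 91:109], oracle[5:-5, 5:-5])

    def test_extensive(self, rng):
        """Dilation never lowers any pixel."""
        t = Topograph(rng.normal(scale=0.5, size=(32, 32)), 0.5)
        out = apply_tip_convolution(t, 1.5)
        assert (out.heights >= t.heights - 1e-12).all()


class TestArtifacts:
    def test_all_zero_spec_is_identity(self, rng):
        t = Topograph(rng.normal(size=(32, 32)), 0.5)
        spec = ArtifactSpec(row_offset_sd_nm=0, noise_sd_nm=0, tip_radius_nm=0)
        out = add_instrument_artifacts(t, spec, 0)
        assert np.array_equal(out.heights, t.heights)

    def test_same_seed_bit_identical(self, rng):
        t = Topograph(np.zeros((32, 32)), 0.5)
        a = add_instrument_artifacts(t, ArtifactSpec(), 42)
        b = add_instrument_artifacts(t, ArtifactSpec(), 42)
        assert np.array_equal(a.heights, b.heights)

    def test_plane_recoverable_by_least_squares(self):
        """Tilt (a, b, c) on a flat image: closed-form plane fit recovers it."""
        t = Topograph(np.zeros((64, 64)), 0.5)
        spec = ArtifactSpec(row_offset_sd_nm=0, noise_sd_nm=0,
                            tilt=(0.02, -0.015, 0.3), tip_radius_nm=0)
        out = add_instrument_artifacts(t, spec, 0)
        rr, cc = np.meshgrid(np.arange(64.0), np.arange(64.0), indexing="ij")
        A = np.column_stack([cc.ravel() * 0.5, rr.ravel() * 0.5,
                             np.ones(64 * 64)])
        coef, *_ = np.linalg.lstsq(A, out.heights.ravel(), rcond=None)
        assert coef == pytest.approx([0.02, -0.015, 0.3], abs=1e-10)


class TestScenes:
    def test_empty_scene(self):
        cfg = SceneConfig(groups=[], n_images=1)
        fields = generate_scene(cfg, 0)
        assert len(fields) == 1
        assert fields[0].records == []
        # flat plus artifacts only: nothing above 1 nm
        assert fields[0].topo.heights.max() < 1.0

    def test_determinism(self):
        cfg = small_g4_scene(n=3, n_images=1)
        a = generate_scene(cfg, 5)
        b = generate_scene(cfg, 5)
        assert np.array_equal(a[0].topo.heights, b[0].topo.heights)
        assert len(a[0].records) == len(b[0].records)
        for ra, rb in zip(a[0].records, b[0].records):
            assert np.array_equal(ra.polyline_nm, rb.polyline_nm)

    def test_ground_truth_contour_matches_polyline(self, g4_fields):
        for f in g4_fields:
            for rec in f.records:
                assert rec.contour_length_nm == pytest.approx(
                    polyline_arc_length(rec.polyline_nm), abs=0.26
                )

    def test_polylines_inside_bounds(self, g4_fields):
        for f in g4_fields:
            w, h = f.topo.extent_nm
            for rec in f.records:
                assert rec.polyline_nm.min() >= 0
                assert rec.polyline_nm[:, 0].max() <= w
                assert rec.polyline_nm[:, 1].max() <= h

    def test_paired_dissolve_fraction_one_removes_all_g4(self):
        cfg = ionic_exchange_scene(n_rna=4, n_g4=3, n_images=1,
                                   g4_remove_fraction=1.0)
        fields = generate_scene(cfg, 1)
        after = fields[0].after_records
        assert after is not None
        assert all(r.class_label != "G4" for r in after)

    def test_overcrowded_scene_fails_with_message(self):
        cfg = SceneConfig(
            image_px=128,
            n_images=1,
            max_attempts=5,
            groups=[
                StructureGroup("G4", 40, (55.0, 60.0), 250.0, 3.4)
            ],
        )
        with pytest.raises(RuntimeError, match="overcrowded"):
            generate_scene(cfg, 0)


def test_resample_polyline_preserves_length():
    poly = np.array([[0.0, 0.0], [3.0, 4.0], [6.0, 4.0]])
    res = resample_polyline(poly, 0.1)
    assert polyline_arc_length(res) == pytest.approx(8.0, abs=0.05)
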