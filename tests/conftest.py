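"""Shared fixtures: small rendered structures and scenes, generated fresh."""

from __future__ import annotations

import numpy as np
import pytest

from g4afm import (
    ArtifactSpec,
    FilamentSpec,
    Topograph,
    render_filament,
)
from g4afm.scenes import SceneConfig, StructureGroup, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def blank_topo():
    return Topograph(np.zeros((128, 256)), 0.5)


@pytest.fixture
def straight_ridge(blank_topo):
    """A clean horizontal constant-height ridge (apex 3.4 nm)."""
    poly = np.column_stack([np.linspace(10, 118, 600), np.full(600, 16.0)])
    rec = render_filament(
        blank_topo, poly, FilamentSpec(3.4, apparent_width_nm=5.0), 1
    )
    return blank_topo, rec


@pytest.fixture
def sine_ridge():
    """A clean horizontal ridge with sinusoidal axial bumps."""
    topo = Topograph(np.zeros((128, 256)), 0.5)
    poly = np.column_stack([np.linspace(10, 118, 600), np.full(600, 16.0)])
    spec = FilamentSpec(3.4, 5.4, 0.34, 5.0, phase=0.3)
    rec = render_filament(topo, poly, spec, 1)
    return topo, rec, spec


def small_g4_scene(n=6, n_images=2, artifacts=None):
    """A compact tall-filament scene used across tests."""
    return SceneConfig(
        n_images=n_images,
        groups=[
            StructureGroup(
                class_label="G4",
                count=n,
                length_range_nm=(100.0, 160.0),
                persistence_length_nm=250.0,
                height_mean_nm=3.4,
                height_sd_nm=0.2,
                period_nm=5.4,
                rms_mean_nm=0.21,
                rms_sd_nm=0.07,
            )
        ],
        artifacts=artifacts or ArtifactSpec(),
    )


@pytest.fixture(scope="session")
def g4_fields():
    """One small rendered scene reused by read-only tests."""
    return generate_scene(small_g4_scene(), seed=99)
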