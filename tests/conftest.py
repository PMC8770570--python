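"""Shared fixtures: synthetic scenes at reduced size for fast unit tests."""

from __future__ import annotations

import dataclasses

import pytest

from marrowquant import bone_geometry, corrections, synthetic_data as sd


def small_preset(**overrides) -> sd.ScenePreset:
    """A compact scene: thinner bone so the marrow keeps enough depth."""
    base = sd.get_preset("bm_baseline",
                         shape=(28, 64, 64),
                         bone_thickness_range=(15.0, 33.0))
    return dataclasses.replace(base, **overrides) if overrides else base


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free small scene at the 10 s reference time (no distortion
    beyond crosstalk + attenuation)."""
    preset = small_preset(noise=sd.NO_NOISE, t_acquired=10.0)
    stack, truth = sd.generate_calvaria(preset, seed=11)
    return preset, stack, truth


@pytest.fixture(scope="session")
def noisy_scene():
    """Default-noise small scene (the study conditions, reduced size)."""
    preset = small_preset()
    stack, truth = sd.generate_calvaria(preset, seed=7)
    return preset, stack, truth


@pytest.fixture(scope="session")
def clean_maps(clean_scene):
    _, stack, _ = clean_scene
    s1 = corrections.subtract_background(stack)
    return s1, bone_geometry.compute_bone_maps(s1)


@pytest.fixture(scope="session")
def noisy_maps(noisy_scene):
    _, stack, _ = noisy_scene
    s1 = corrections.subtract_background(stack)
    return s1, bone_geometry.compute_bone_maps(s1)
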