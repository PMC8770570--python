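"""Correction chain: background, depth, crosstalk, clearance, registration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from marrowquant import bone_geometry as bg, corrections as co, synthetic_data as sd
from marrowquant.stack import VoxelStack

from conftest import small_preset


def _stack(channels, **kw):
    return VoxelStack(channels=channels, **kw)


# ---------------------------------------------------------------------------
# background
# ---------------------------------------------------------------------------

def test_background_subtraction_examples():
    s = _stack({"red": np.full((2, 3, 3), 25.0), "green": np.full((2, 3, 3), 25.0)})
    out = co.subtract_background(s, 10.0)
    np.testing.assert_allclose(out["red"], 15.0)
    out2 = co.subtract_background(s, {"red": 25.0, "green": 0.0})
    np.testing.assert_allclose(out2["red"], 0.0)
    np.testing.assert_allclose(out2["green"], 25.0)
    assert "background_subtracted" in out.stages


def test_background_shape_mismatch_fails():
    s = _stack({"red": np.zeros((2, 3, 3))})
    with pytest.raises(ValueError):
        co.subtract_background(s, {"red": np.zeros((1, 3, 3))})


def test_background_recovers_offsets_exactly(clean_scene):
    preset, _, _ = clean_scene
    p = small_preset(noise=sd.NoiseParams(photon_scale=0.0, read_sd=0.0,
                                          background_offset=40.0),
                     t_acquired=10.0)
    stack, truth = sd.generate_calvaria(p, seed=13)
    out = co.subtract_background(stack)
    ref, _ = sd.generate_calvaria(small_preset(noise=sd.NO_NOISE,
                                               t_acquired=10.0), seed=13)
    for ch in ("red", "green", "shg"):
        np.testing.assert_allclose(out[ch], ref[ch], atol=1e-9)


# ---------------------------------------------------------------------------
# attenuation fits (noise-free exactness + noisy tolerance)
# ---------------------------------------------------------------------------

def test_noise_free_coefficient_recovery(clean_scene, clean_maps):
    preset, _, truth = clean_scene
    s1, maps = clean_maps
    c1g = co.fit_bone_green_attenuation(s1, maps)
    assert c1g == pytest.approx(truth.attenuation.c1_green, abs=1e-6)
    vessels = truth.mask(sd.VESSEL)
    c1r = co.fit_bone_red_attenuation(s1, maps, vessels, c1g)
    assert c1r == pytest.approx(truth.attenuation.c1_red, abs=1e-5)
    thick = co.apply_depth_correction(
        s1, co.AttenuationModel(c1_green=c1g, c1_red=c1r), maps)
    c2r, c2g = co.fit_marrow_attenuation(thick, vessels, maps)
    assert c2g == pytest.approx(truth.attenuation.c2_green, abs=1e-5)
    assert c2r == pytest.approx(truth.attenuation.c2_red, abs=1e-5)


def test_zero_attenuation_scene_gives_zero_coefficients():
    p = small_preset(
        noise=sd.NO_NOISE, t_acquired=10.0,
        attenuation=dict(c1_green=0.0, c1_red=0.0, c2_green=0.0, c2_red=0.0))
    stack, truth = sd.generate_calvaria(p, seed=14)
    s1 = co.subtract_background(stack)
    maps = bg.compute_bone_maps(s1)
    assert co.fit_bone_green_attenuation(s1, maps) == pytest.approx(0.0, abs=1e-9)
    c1r = co.fit_bone_red_attenuation(s1, maps, truth.mask(sd.VESSEL), 0.0)
    assert c1r == pytest.approx(0.0, abs=1e-9)


def test_noisy_coefficient_recovery_within_ten_percent(noisy_scene, noisy_maps):
    from marrowquant import segmentation as seg
    _, _, truth = noisy_scene
    s1, maps = noisy_maps
    m = seg.segment_stack(s1, maps, snr_floor=(15, 15))
    c1g = co.fit_bone_green_attenuation(s1, maps)
    c1r = co.fit_bone_red_attenuation(s1, maps, m.vessels, c1g,
                                      intensity_floor=15)
    assert c1g == pytest.approx(truth.attenuation.c1_green, rel=0.10)
    assert c1r == pytest.approx(truth.attenuation.c1_red, rel=0.10)


def test_degenerate_endosteal_geometry_fails():
    p = small_preset(bone_thickness_range=(24.0, 24.0), noise=sd.NO_NOISE,
                     t_acquired=10.0)
    stack, truth = sd.generate_calvaria(p, seed=15)
    s1 = co.subtract_background(stack)
    maps = bg.compute_bone_maps(s1)
    with pytest.raises(ValueError, match="identical bone thickness"):
        co.fit_bone_red_attenuation(s1, maps, truth.mask(sd.VESSEL), 1 / 30)


def test_depth_constant_intensity_gives_zero_c2(clean_maps):
    s1, maps = clean_maps
    flat = s1.with_channels({"red": np.full(s1.shape, 500.0),
                             "green": np.full(s1.shape, 400.0)})
    vessels = maps.depth_map > 0
    c2r, c2g = co.fit_marrow_attenuation(flat, vessels, maps, erosion_um=0.0)
    assert c2r == pytest.approx(0.0, abs=1e-12)
    assert c2g == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------------
# applying the depth correction
# ---------------------------------------------------------------------------

def test_depth_correction_closed_forms():
    mask = np.zeros((6, 2, 2), dtype=bool)
    mask[:2] = True  # 2 bone planes a 3 um -> Z1 = 6... use z_step=15 for 30
    maps = bg.BoneMaps(mask=mask,
                       thickness_map=np.full((2, 2), 30.0),
                       depth_map=np.where(
                           np.arange(6)[:, None, None] >= 2,
                           (np.arange(6)[:, None, None] - 1) * 15.0, 0.0),
                       endosteum_z=np.full((2, 2), 1),
                       valid_columns=np.ones((2, 2), dtype=bool),
                       partial_thickness=np.minimum(np.arange(6), 2)[
                           :, None, None] * 15.0,
                       z_step=15.0)
    inten = np.ones((6, 2, 2))
    s = _stack({"red": inten, "green": inten}, z_step=15.0)
    att = co.AttenuationModel(c1_green=1 / 30, c1_red=1 / 30)
    out = co.apply_depth_correction(s, att, maps)
    # marrow voxel under 30 um of bone with c1 = 1/30 and c2 = 0: factor e
    np.testing.assert_allclose(out["red"][2:], math.e, rtol=1e-12)
    # bone-top voxel: zero overlying bone -> unchanged
    np.testing.assert_allclose(out["red"][0], 1.0, rtol=1e-12)


def test_correction_factor_cap_flags():
    mask = np.zeros((3, 1, 1), dtype=bool)
    mask[0] = True
    maps = bg.BoneMaps(mask=mask, thickness_map=np.full((1, 1), 1000.0),
                       depth_map=np.zeros((3, 1, 1)),
                       endosteum_z=np.zeros((1, 1), dtype=int),
                       valid_columns=np.ones((1, 1), dtype=bool),
                       partial_thickness=np.zeros((3, 1, 1)), z_step=3.0)
    s = _stack({"red": np.ones((3, 1, 1)), "green": np.ones((3, 1, 1))})
    out = co.apply_depth_correction(
        s, co.AttenuationModel(c1_green=0.05, c1_red=0.05), maps)
    assert out["red"].max() <= math.exp(co.CORRECTION_CAP_LOG) + 1e-9
    assert any(t.startswith("depth_correction_capped") for t in out.stages)


# ---------------------------------------------------------------------------
# crosstalk
# ---------------------------------------------------------------------------

def test_unmix_pure_red_emitter():
    red, green = co.unmix_crosstalk(np.array([1.0]), np.array([0.12]),
                                    co.CrosstalkMatrix(0.12, 0.0))
    assert red[0] == pytest.approx(1.0, abs=1e-12)
    assert green[0] == pytest.approx(0.0, abs=1e-12)


def test_unmix_identity():
    r = np.array([3.0, 4.0])
    g = np.array([1.0, 2.0])
    ru, gu = co.unmix_crosstalk(r, g, co.CrosstalkMatrix(0.0, 0.0))
    np.testing.assert_array_equal(ru, r)
    np.testing.assert_array_equal(gu, g)


@settings(max_examples=50, deadline=None)
@given(st.floats(0.0, 0.5), st.floats(0.0, 0.5), st.integers(0, 2 ** 31 - 1))
def test_mix_unmix_roundtrip(a, b, seed):
    rng = np.random.default_rng(seed)
    red = rng.random(20) * 100
    green = rng.random(20) * 100
    xt = co.CrosstalkMatrix(red_into_green=a, green_into_red=b)
    g_m = green + a * red
    r_m = red + b * green
    r_u, g_u = co.unmix_crosstalk(r_m, g_m, xt)
    np.testing.assert_allclose(r_u, red, atol=1e-9)
    np.testing.assert_allclose(g_u, green, atol=1e-9)


def test_singular_crosstalk_rejected():
    with pytest.raises(ValueError):
        co.CrosstalkMatrix(red_into_green=1.0, green_into_red=0.5)


# ---------------------------------------------------------------------------
# registration + clearance
# ---------------------------------------------------------------------------

def test_rigid_registration_recovers_injected_shift():
    p = small_preset(noise=sd.NO_NOISE)
    s1, s2, truth = sd.generate_timepoint_pair(p, seed=16, dt=60.0,
                                               rigid_offset=(3, 2, 1))
    assert co.register_rigid(s1, s2) == (3, 2, 1)


def test_registration_identity_for_identical_stacks(noisy_scene):
    _, stack, _ = noisy_scene
    assert co.register_rigid(stack, stack) == (0, 0, 0)


def test_registration_robust_at_default_noise():
    s1, s2, truth = sd.generate_timepoint_pair(small_preset(), seed=17,
                                               dt=60.0, rigid_offset=(1, 4, 2))
    rec = co.register_rigid(s1, s2)
    assert max(abs(r - t) for r, t in zip(rec, (1, 4, 2))) <= 1


def test_clearance_two_point_closed_form():
    s1 = _stack({"red": np.full((1, 20, 20), 100.0)}, t_acquired=10.0)
    s2 = _stack({"red": np.full((1, 20, 20), 50.0)}, t_acquired=310.0)
    field = co.fit_clearance(s1, s2, channels=("red",))
    np.testing.assert_allclose(field.rates["red"], math.log(2) / 300,
                               rtol=1e-12)
    s3 = _stack({"red": np.full((1, 20, 20), 100.0)}, t_acquired=400.0)
    field2 = co.fit_clearance(s1, s3, channels=("red",))
    np.testing.assert_allclose(field2.rates["red"], 0.0, atol=1e-15)


def test_clearance_time_order_enforced():
    s1 = _stack({"red": np.ones((1, 4, 4))}, t_acquired=100.0)
    s2 = _stack({"red": np.ones((1, 4, 4))}, t_acquired=50.0)
    with pytest.raises(ValueError):
        co.fit_clearance(s1, s2)


def test_clearance_per_subregion_recovery_noise_free():
    """Depth correction and crosstalk removal run first (pipeline order):
    the 12% red bleed-through in the green channel decays at the red rate
    and would otherwise bias the green rates."""
    p = small_preset(noise=sd.NO_NOISE)
    s1, s2, truth = sd.generate_timepoint_pair(p, seed=18, dt=300.0)
    maps = bg.compute_bone_maps(s1)
    def correct(s):
        return co.unmix_crosstalk(
            co.apply_depth_correction(s, truth.attenuation, maps),
            xtalk=truth.crosstalk)
    exclude = (truth.labels == sd.BONE) | truth.af_cell_mask
    field = co.fit_clearance(correct(s1), correct(s2), exclude_mask=exclude,
                             min_intensity=1e-3)
    for ch in ("red", "green"):
        fitted, true = field.rates[ch], truth.clearance_rates[ch]
        ok = ~field.flagged[ch]
        assert ok.mean() > 0.9
        np.testing.assert_allclose(fitted[ok], true[ok], rtol=0.05)


def test_apply_clearance_correction_examples():
    k = math.log(2) / 600.0
    field = co.ClearanceField(rates={"red": np.full((1, 1), k)},
                              subregion_px=4)
    s = _stack({"red": np.full((1, 4, 4), 10.0)}, t_acquired=610.0)
    out = co.apply_clearance_correction(s, field)
    np.testing.assert_allclose(out["red"], 20.0, rtol=1e-12)
    s_ref = _stack({"red": np.full((1, 4, 4), 10.0)}, t_acquired=10.0)
    out_ref = co.apply_clearance_correction(s_ref, field)
    np.testing.assert_allclose(out_ref["red"], 10.0, rtol=1e-12)


def test_corrected_timepoints_agree():
    """After clearance correction to the common reference time, the two
    stacks agree voxelwise in the dye compartments (noise-free)."""
    p = small_preset(noise=sd.NO_NOISE)
    s1, s2, truth = sd.generate_timepoint_pair(p, seed=19, dt=300.0)
    exclude = (truth.labels == sd.BONE) | truth.af_cell_mask
    field = co.fit_clearance(s1, s2, exclude_mask=exclude, min_intensity=1e-3)
    c1 = co.apply_clearance_correction(s1, field)
    c2 = co.apply_clearance_correction(s2, field)
    dye = np.isfinite(truth.true_ratio)
    rel = np.abs(c1["red"][dye] - c2["red"][dye]) / np.maximum(
        c1["red"][dye], 1e-12)
    assert np.median(rel) <= 0.02
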