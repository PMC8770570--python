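"""Forward optical simulator of calvarial bone-marrow z-stacks.

Builds scenes with known ground truth so every downstream stage is testable
by parameter recovery: a cortical bone plate of smoothly varying thickness
(SHG + green autofluorescence), a marrow cavity with tubular vessels
(~25% of marrow volume), densely packed dark cells separated by ~1 um
dye-filled interstitial gaps, endosteal osteoid patches, and ground-truth
pH / [Ca2+] fields per compartment.  The forward model converts the ion
fields to red/green emission through the inverse calibration maps, then
distorts the stack with dye clearance, spectral crosstalk, two-layer
exponential attenuation exp(-(C1*Z1 + C2*Z2)), bone autofluorescence
(attenuated by overlying bone only) and shot + read noise, in that order --
the exact inverse of the correction chain.

Scene presets encode the study conditions: serum pH 7.3 and [Ca2+] 1.0 mM
intravascularly; interstitial pH 7.1 with a 0.30-unit 10-90% span;
interstitial calcium 1.0 +/- 0.54 mM at baseline, 0.7 mM in
deposition-dominated (D-type) cavities, 1.3 mM in aged mixed-activity
cavities, and 1.5 +/- 0.57 mM hotspots around marked stem-cell positions;
attenuation lengths 30 um (green) / 40 um (red) in bone and 20 um (green)
in marrow with C2G - C2R = ln(1.2)/50 per um; crosstalk 12% / 1.3%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from marrowquant.calibration import (
    CaCalibration,
    PHCalibration,
    ratio_from_ca,
    ratio_from_ph,
)
from marrowquant.corrections import AttenuationModel, CrosstalkMatrix, REFERENCE_TIME_S
from marrowquant.stack import (
    CH_BLUE,
    CH_GREEN,
    CH_RED,
    CH_SHG,
    DEFAULT_VOXEL_XY,
    DEFAULT_Z_STEP,
    VoxelStack,
)

# compartment labels
BONE, VESSEL, CELL, INTERSTITIUM, OSTEOID = 0, 1, 2, 3, 4
LABEL_NAMES = {BONE: "bone", VESSEL: "vessel", CELL: "cell",
               INTERSTITIUM: "interstitium", OSTEOID: "osteoid"}
DYE_LABELS = (VESSEL, INTERSTITIUM, OSTEOID)


class PackingError(RuntimeError):
    """Vessel packing could not reach the requested volume fraction."""

    def __init__(self, target: float, achieved: float):
        super().__init__(
            f"vessel volume fraction {target:.3f} unreachable; "
            f"achieved {achieved:.3f}")
        self.target = target
        self.achieved = achieved


@dataclass(frozen=True)
class FieldSpec:
    """Distribution spec for a spatially correlated scalar field."""

    mean: float
    sd: float = 0.0
    correlation_um: float = 10.0
    distribution: str = "normal"       # "normal" | "lognormal"


@dataclass(frozen=True)
class NoiseParams:
    """Photon (Poisson) + additive Gaussian read noise, plus offset."""

    photon_scale: float = 1.0   # 0 disables shot noise
    read_sd: float = 3.0        # counts; 0 disables read noise
    background_offset: float = 10.0


NO_NOISE = NoiseParams(photon_scale=0.0, read_sd=0.0, background_offset=0.0)

DEFAULT_ATTENUATION = dict(
    c1_green=1.0 / 30.0, c1_red=1.0 / 40.0,
    c2_green=1.0 / 20.0, c2_red=1.0 / 20.0 - math.log(1.2) / 50.0)


def default_attenuation() -> AttenuationModel:
    return AttenuationModel(**DEFAULT_ATTENUATION)


@dataclass(frozen=True)
class HotspotSpec:
    """Elevated-calcium patches around marked (stem-cell) positions."""

    mean: float = 1.5           # mM
    sd: float = 0.57            # mM
    radius_um: float = 18.0
    n_cells: int = 5
    max_bone_distance_um: float = 15.0


@dataclass(frozen=True)
class ScenePreset:
    """Everything that defines a synthetic scene (the study conditions)."""

    name: str
    modality: str = "ca"                         # "ca" | "ph"
    shape: tuple[int, int, int] = (40, 128, 128)  # (nz, ny, nx)
    voxel_size_xy: float = DEFAULT_VOXEL_XY
    z_step: float = DEFAULT_Z_STEP
    bone_thickness_range: tuple[float, float] = (20.0, 60.0)
    vessel_volume_fraction: float = 0.25
    vessel_diameter_um: float = 10.0
    vessel_style: str = "tube"                   # "tube" | "column"
    cell_diameter: float = 7.0
    interstitial_gap: float = 1.0
    ph_vessel: FieldSpec = FieldSpec(mean=7.3)
    ca_vessel: FieldSpec = FieldSpec(mean=1.0)
    ph_interstitial: FieldSpec = FieldSpec(mean=7.1, sd=0.117)
    ca_interstitial: FieldSpec = FieldSpec(mean=1.0, sd=0.54,
                                           distribution="lognormal")
    osteoid_ca: float = 5.0                      # mM
    osteoid_fraction: float = 0.01               # of endosteal columns
    osteoid_green_gain: float = 3.0              # dye accumulation in osteoid
    attenuation: dict = field(
        default_factory=lambda: dict(DEFAULT_ATTENUATION))
    crosstalk: CrosstalkMatrix = CrosstalkMatrix()
    clearance_halflife: dict = field(
        default_factory=lambda: {CH_GREEN: 900.0, CH_RED: 600.0})  # s
    clearance_spatial_sd: float = 0.10           # lognormal sd of tile factor
    clearance_subregion_px: int = 20
    noise: NoiseParams = NoiseParams()
    autofluorescence_level: float = 0.25         # of vessel green reference
    autofluorescent_cell_fraction: float = 0.02
    green_reference: dict = field(
        default_factory=lambda: {VESSEL: 2000.0, INTERSTITIUM: 1200.0,
                                 OSTEOID: 1200.0})
    af_cell_green: float = 600.0
    shg_intensity: float = 1500.0
    # SHG is strongly forward-directed and detected near 470 nm; its
    # effective attenuation through bone is much weaker than the dye bands
    shg_attenuation_per_um: float = 1.0 / 60.0
    t_acquired: float = 120.0                    # s after injection
    hotspot: HotspotSpec | None = None
    ph_cal: PHCalibration = PHCalibration()
    ca_cal: CaCalibration = CaCalibration()

    def __post_init__(self) -> None:
        if not (0.0 < self.vessel_volume_fraction < 1.0):
            raise ValueError("vessel_volume_fraction must be in (0, 1)")
        lo, hi = self.bone_thickness_range
        if lo <= 0 or hi < lo:
            raise ValueError("bone thickness range must be positive and ordered")
        if not (4.0 <= self.ph_interstitial.mean <= 10.0):
            raise ValueError("interstitial pH preset outside physical range")
        if self.ca_interstitial.mean < 0:
            raise ValueError("calcium must be non-negative")

    @property
    def attenuation_model(self) -> AttenuationModel:
        return AttenuationModel(**self.attenuation)


def _preset_registry() -> dict:
    base = ScenePreset(name="bm_baseline")
    return {
        "bm_baseline": base,
        "bm_baseline_ph": replace(base, name="bm_baseline_ph", modality="ph",
                                  osteoid_fraction=0.0),
        "d_type": replace(base, name="d_type",
                          ca_interstitial=FieldSpec(mean=0.7, sd=0.38,
                                                    distribution="lognormal"),
                          osteoid_fraction=0.02),
        "m_aged": replace(base, name="m_aged",
                          ca_interstitial=FieldSpec(mean=1.3, sd=0.54,
                                                    distribution="lognormal")),
        "hsc_hotspot": replace(base, name="hsc_hotspot", hotspot=HotspotSpec()),
        "depth_probe": replace(base, name="depth_probe",
                               bone_thickness_range=(30.0, 30.0),
                               vessel_style="column",
                               vessel_volume_fraction=0.35,
                               ca_interstitial=FieldSpec(mean=1.0, sd=0.0),
                               osteoid_fraction=0.0,
                               autofluorescent_cell_fraction=0.0,
                               noise=NO_NOISE, t_acquired=REFERENCE_TIME_S),
    }


PRESETS = _preset_registry()


def get_preset(name: str, **overrides) -> ScenePreset:
    """Look up a named preset, optionally overriding fields."""
    preset = PRESETS[name]
    return replace(preset, **overrides) if overrides else preset


@dataclass
class GroundTruth:
    """Everything the generator knows; the oracle for parameter recovery."""

    labels: np.ndarray                   # int8 compartment per voxel
    ph: np.ndarray                       # NaN where not dye-accessible
    ca: np.ndarray                       # mM, NaN where not dye-accessible
    true_ratio: np.ndarray               # undistorted R/G, NaN where dark
    z1_map: np.ndarray                   # 2D, discrete bone thickness (um)
    z1_analytic: np.ndarray              # 2D, continuous thickness field (um)
    z2_map: np.ndarray                   # 3D, depth below endosteum (um)
    partial_z1: np.ndarray               # 3D, bone overlying each voxel (um)
    attenuation: AttenuationModel
    crosstalk: CrosstalkMatrix
    clearance_rates: dict                # channel -> (nty, ntx) rates, s^-1
    clearance_subregion_px: int
    vessel_fraction_realized: float
    af_cell_mask: np.ndarray
    cell_positions: np.ndarray | None = None   # (n, 3) voxel coords (z, y, x)
    rigid_offset: tuple | None = None
    background_offset: float = 0.0

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label


# ---------------------------------------------------------------------------
# field + geometry helpers
# ---------------------------------------------------------------------------

def _correlated_field(rng: np.random.Generator, shape, corr_um: float,
                      voxel_xy: float, z_step: float) -> np.ndarray:
    """Standard-normal field with ~corr_um spatial correlation length."""
    white = rng.standard_normal(shape)
    if corr_um <= 0:
        return white
    if len(shape) == 3:
        sigma = (corr_um / z_step, corr_um / voxel_xy, corr_um / voxel_xy)
    else:
        sigma = (corr_um / voxel_xy,) * len(shape)
    f = ndimage.gaussian_filter(white, sigma=sigma, mode="reflect")
    f -= f.mean()  # heavy smoothing leaves a dominant residual mean
    sd = f.std()
    return f / sd if sd > 0 else np.zeros(shape)


def _draw_field(rng, spec: FieldSpec, shape, voxel_xy, z_step) -> np.ndarray:
    """Materialise a FieldSpec as a correlated random field."""
    if spec.sd == 0:
        return np.full(shape, float(spec.mean))
    g = _correlated_field(rng, shape, spec.correlation_um, voxel_xy, z_step)
    if spec.distribution == "lognormal":
        s2 = math.log(1.0 + (spec.sd / spec.mean) ** 2)
        mu = math.log(spec.mean) - s2 / 2.0
        return np.exp(mu + math.sqrt(s2) * g)
    return spec.mean + spec.sd * g


def _ball_offsets(radius_um: float, voxel_xy: float, z_step: float):
    dz = int(math.ceil(radius_um / z_step))
    dxy = int(math.ceil(radius_um / voxel_xy))
    zz, yy, xx = np.mgrid[-dz:dz + 1, -dxy:dxy + 1, -dxy:dxy + 1]
    keep = ((zz * z_step) ** 2 + (yy * voxel_xy) ** 2
            + (xx * voxel_xy) ** 2) <= radius_um ** 2
    return np.stack([zz[keep], yy[keep], xx[keep]], axis=1)


def _draw_centerline(line_mask: np.ndarray, p0_um, direction, length_um,
                     voxel_xy: float, z_step: float) -> None:
    """Rasterise a straight centerline (physical coords, um) into a volume."""
    step = 0.5 * voxel_xy
    n = max(int(length_um / step), 2)
    t = np.arange(n)[:, None] * step
    pts = np.asarray(p0_um)[None, :] + np.asarray(direction)[None, :] * t
    idx = np.round(pts / np.array([z_step, voxel_xy, voxel_xy])).astype(int)
    nz, ny, nx = line_mask.shape
    ok = ((idx[:, 0] >= 0) & (idx[:, 0] < nz)
          & (idx[:, 1] >= 0) & (idx[:, 1] < ny)
          & (idx[:, 2] >= 0) & (idx[:, 2] < nx))
    idx = idx[ok]
    line_mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True


def _build_vessels(rng, preset: ScenePreset, marrow: np.ndarray,
                   n_bone: np.ndarray) -> np.ndarray:
    """Pack tubes (or vertical columns) to the target marrow volume fraction."""
    nz, ny, nx = marrow.shape
    vox, zs = preset.voxel_size_xy, preset.z_step
    radius = preset.vessel_diameter_um / 2.0
    target = preset.vessel_volume_fraction
    marrow_vox = int(marrow.sum())
    sampling = (zs, vox, vox)
    lines = np.zeros(marrow.shape, dtype=bool)

    ext_um = np.array([nz * zs, ny * vox, nx * vox])

    def realized(mask_lines):
        dist = ndimage.distance_transform_edt(~mask_lines, sampling=sampling)
        vessels = (dist <= radius) & marrow
        return vessels, vessels.sum() / marrow_vox

    if preset.vessel_style == "column":
        # vertical cylinders spanning the marrow, on a coarse grid
        pitch = max(int(round(2.2 * radius / vox)), 4)
        for y in range(pitch // 2, ny, pitch):
            for x in range(pitch // 2, nx, pitch):
                zs_top = int(n_bone[y, x])
                lines[zs_top:, y, x] = True
        vessels, frac = realized(lines)
        return vessels

    def add_tube(length, endosteal=False):
        theta = rng.uniform(0, 2 * math.pi)
        if endosteal:
            # sinusoid hugging the endosteal surface: the centerline follows
            # the local bone interface at one vessel radius below it, so the
            # tube top touches the endosteum under varying bone thickness
            p0 = np.array([0.0, rng.uniform(0, ext_um[1]),
                           rng.uniform(0, ext_um[2])])
            direction = np.array([0.0, math.sin(theta), math.cos(theta)])
            p0 -= direction * length / 2.0
            step = 0.5 * vox
            n = max(int(length / step), 2)
            t = np.arange(n)[:, None] * step
            pts = p0[None, :] + direction[None, :] * t
            iy = np.clip(np.round(pts[:, 1] / vox).astype(int), 0, ny - 1)
            ix = np.clip(np.round(pts[:, 2] / vox).astype(int), 0, nx - 1)
            pts[:, 0] = n_bone[iy, ix] * zs + 0.8 * radius
            idx = np.round(pts / np.array([zs, vox, vox])).astype(int)
            ok = ((idx[:, 1] >= 0) & (idx[:, 1] < ny)
                  & (idx[:, 2] >= 0) & (idx[:, 2] < nx)
                  & (idx[:, 0] >= 0) & (idx[:, 0] < nz))
            idx = idx[ok]
            lines[idx[:, 0], idx[:, 1], idx[:, 2]] = True
            return
        # mostly horizontal tube through a random marrow point
        zfrac = rng.uniform(0.15, 0.85)
        p0 = np.array([
            (n_bone.mean() * zs) + zfrac * (ext_um[0] - n_bone.mean() * zs),
            rng.uniform(0, ext_um[1]),
            rng.uniform(0, ext_um[2])])
        dz = rng.uniform(-0.15, 0.15)
        direction = np.array([dz, math.sin(theta), math.cos(theta)])
        direction /= np.linalg.norm(direction)
        p0 -= direction * length / 2.0
        _draw_centerline(lines, p0, direction, length, vox, zs)

    # add tubes in batches sized from the current volume deficit so only a
    # handful of distance transforms are needed
    per_um = math.pi * radius ** 2 / (vox * vox * zs)  # voxels per um of tube
    full_len = 1.2 * ext_um[1]
    frac = 0.0
    vessels = np.zeros_like(marrow)
    # a few vessels always run right along the endosteum (they anchor the
    # bone-thickness correction, as in real calvarial marrow)
    for _ in range(2):
        add_tube(full_len, endosteal=True)
    n_added = 2
    for _ in range(12):
        if frac >= target - 0.005:
            break
        deficit_vox = (target - frac) * marrow_vox
        n_new = int(deficit_vox / (per_um * 0.8 * full_len))
        if n_new >= 1:
            for _ in range(n_new):
                add_tube(full_len)
                n_added += 1
        else:  # fine-tuning: one short tube sized to the deficit
            add_tube(float(np.clip(deficit_vox / per_um, 5.0, full_len)))
            n_added += 1
        if n_added > 200:
            break
        vessels, frac = realized(lines)
    if frac < target - 0.02:
        raise PackingError(target, frac)
    return vessels


def _build_cells(rng, preset: ScenePreset, marrow: np.ndarray,
                 vessels: np.ndarray):
    """Voronoi-style dense cell packing leaving ~gap-wide interstitial sheets.

    Cell seeds sit on a jittered grid with spacing cell_diameter + gap; the
    interstitium is the sheet of voxels within gap/2 of a Voronoi boundary
    or within gap of a vessel surface, everything else in the marrow being
    dark cell bodies.
    """
    nz, ny, nx = marrow.shape
    vox, zs = preset.voxel_size_xy, preset.z_step
    sampling = (zs, vox, vox)
    spacing = preset.cell_diameter + preset.interstitial_gap
    gap = preset.interstitial_gap

    seeds = np.zeros(marrow.shape, dtype=bool)
    jitter = gap / 2.0
    zs_pts = np.arange(spacing / 2, nz * zs, spacing)
    ys_pts = np.arange(spacing / 2, ny * vox, spacing)
    xs_pts = np.arange(spacing / 2, nx * vox, spacing)
    for z_um in zs_pts:
        for y_um in ys_pts:
            for x_um in xs_pts:
                p = np.array([z_um, y_um, x_um]) + rng.uniform(-jitter, jitter, 3)
                iz, iy, ix = np.round(p / np.array([zs, vox, vox])).astype(int)
                if 0 <= iz < nz and 0 <= iy < ny and 0 <= ix < nx:
                    seeds[iz, iy, ix] = True

    _, (iz, iy, ix) = ndimage.distance_transform_edt(
        ~seeds, sampling=sampling, return_indices=True)
    seed_label = (iz * ny + iy) * nx + ix  # nearest-seed id per voxel

    # in-plane Voronoi boundaries only: at a 3 um z step the ~1 um
    # horizontal gap sheets between stacked cells are below the axial
    # resolution, so only the lateral gap network is generated
    boundary = np.zeros(marrow.shape, dtype=bool)
    boundary[:, :-1] |= seed_label[:, :-1] != seed_label[:, 1:]
    boundary[:, :, :-1] |= seed_label[:, :, :-1] != seed_label[:, :, 1:]

    near_boundary = ndimage.distance_transform_edt(
        ~boundary, sampling=sampling) <= gap / 2.0
    near_vessel = ndimage.distance_transform_edt(
        ~vessels, sampling=sampling) <= gap

    cells = marrow & ~vessels & ~near_boundary & ~near_vessel
    return cells, seed_label


# ---------------------------------------------------------------------------
# scene assembly
# ---------------------------------------------------------------------------

@dataclass
class _Scene:
    """Internal: geometry + truth fields, before rendering."""

    preset: ScenePreset
    labels: np.ndarray
    ph: np.ndarray
    ca: np.ndarray
    true_ratio: np.ndarray
    z1_map: np.ndarray
    z1_analytic: np.ndarray
    z2_map: np.ndarray
    partial_z1: np.ndarray
    clearance_rates: dict
    af_cell_mask: np.ndarray
    vessel_fraction: float
    cell_positions: np.ndarray | None


def _build_scene(preset: ScenePreset, seed: int) -> _Scene:
    rng = np.random.default_rng(seed)
    nz, ny, nx = preset.shape
    vox, zs = preset.voxel_size_xy, preset.z_step

    # --- bone plate of smoothly varying thickness -------------------------
    lo, hi = preset.bone_thickness_range
    g = _correlated_field(rng, (ny, nx), corr_um=15.0, voxel_xy=vox, z_step=zs)
    from scipy.stats import norm
    t_analytic = lo + (hi - lo) * norm.cdf(g) if hi > lo else np.full((ny, nx), lo)
    n_bone = np.clip(np.round(t_analytic / zs).astype(int), 1, nz - 12)
    zidx = np.arange(nz).reshape(-1, 1, 1)
    bone = zidx < n_bone
    marrow = ~bone

    z1_map = n_bone.astype(float) * zs
    endo = n_bone - 1  # deepest bone voxel index
    z2_map = np.where(marrow, (zidx - endo) * zs, 0.0).astype(float)
    partial_z1 = np.minimum(zidx, n_bone).astype(float) * zs

    # --- compartments -----------------------------------------------------
    vessels = _build_vessels(rng, preset, marrow, n_bone)
    cells, seed_label = _build_cells(rng, preset, marrow, vessels)
    interstitium = marrow & ~vessels & ~cells

    labels = np.full(preset.shape, CELL, dtype=np.int8)
    labels[bone] = BONE
    labels[vessels] = VESSEL
    labels[interstitium] = INTERSTITIUM
    labels[cells] = CELL

    # osteoid: endosteal patches relabelled from marrow compartments
    if preset.osteoid_fraction > 0:
        n_patch = max(int(round(preset.osteoid_fraction * ny * nx / 60.0)), 2)
        rad_px = int(round(2.5 / vox))
        for _ in range(n_patch):
            cy, cx = rng.integers(0, ny), rng.integers(0, nx)
            zp = int(n_bone[cy, cx])
            if zp >= nz:
                continue
            y0, y1 = max(cy - rad_px, 0), min(cy + rad_px + 1, ny)
            x0, x1 = max(cx - rad_px, 0), min(cx + rad_px + 1, nx)
            yy, xx = np.mgrid[y0:y1, x0:x1]
            disk = ((yy - cy) ** 2 + (xx - cx) ** 2) <= rad_px ** 2
            patch = np.zeros((ny, nx), dtype=bool)
            patch[y0:y1, x0:x1] = disk
            sel = patch & (labels[zp] != BONE) & (labels[zp] != VESSEL)
            labels[zp][sel] = OSTEOID

    # autofluorescent cells: a fraction of cell instances, green-only
    af_cell_mask = np.zeros(preset.shape, dtype=bool)
    if preset.autofluorescent_cell_fraction > 0:
        cell_ids = np.unique(seed_label[labels == CELL])
        n_af = int(round(preset.autofluorescent_cell_fraction * len(cell_ids)))
        if n_af:
            chosen = rng.choice(cell_ids, size=n_af, replace=False)
            af_cell_mask = np.isin(seed_label, chosen) & (labels == CELL)

    # --- ground-truth ion fields ------------------------------------------
    vessel_m = labels == VESSEL
    interst_m = labels == INTERSTITIUM
    osteoid_m = labels == OSTEOID
    dye_m = vessel_m | interst_m | osteoid_m

    ph = np.full(preset.shape, np.nan)
    ca = np.full(preset.shape, np.nan)
    ph_i = _draw_field(rng, preset.ph_interstitial, preset.shape, vox, zs)
    ca_i = _draw_field(rng, preset.ca_interstitial, preset.shape, vox, zs)
    ph_v = _draw_field(rng, preset.ph_vessel, preset.shape, vox, zs)
    ca_v = _draw_field(rng, preset.ca_vessel, preset.shape, vox, zs)
    ph[interst_m | osteoid_m] = ph_i[interst_m | osteoid_m]
    ca[interst_m] = ca_i[interst_m]
    ph[vessel_m] = ph_v[vessel_m]
    ca[vessel_m] = ca_v[vessel_m]
    ca[osteoid_m] = preset.osteoid_ca

    # hotspots: elevated calcium around marked cell positions near the bone
    cell_positions = None
    if preset.hotspot is not None:
        hs = preset.hotspot
        candidates = np.argwhere(interst_m & (z2_map > 0)
                                 & (z2_map <= hs.max_bone_distance_um))
        if len(candidates) < hs.n_cells:
            raise RuntimeError("not enough endosteal interstitium for hotspots")
        picks = []
        min_sep = 8.0  # um between marked cells
        order = rng.permutation(len(candidates))
        scale = np.array([zs, vox, vox])
        for i in order:
            p = candidates[i]
            if all(np.linalg.norm((p - q) * scale) >= min_sep for q in picks):
                picks.append(p)
            if len(picks) == hs.n_cells:
                break
        cell_positions = np.asarray(picks)
        pos_mask = np.zeros(preset.shape, dtype=bool)
        pos_mask[tuple(cell_positions.T)] = True
        dist = ndimage.distance_transform_edt(~pos_mask, sampling=(zs, vox, vox))
        hot = dist <= hs.radius_um
        hot_field = _draw_field(
            rng, FieldSpec(mean=hs.mean, sd=hs.sd,
                           distribution="lognormal"), preset.shape, vox, zs)
        sel = hot & interst_m
        ca[sel] = hot_field[sel]

    # --- true emission ratio ----------------------------------------------
    true_ratio = np.full(preset.shape, np.nan)
    if preset.modality == "ph":
        true_ratio[dye_m] = np.asarray(ratio_from_ph(ph[dye_m], preset.ph_cal))
    else:
        true_ratio[dye_m] = np.asarray(ratio_from_ca(ca[dye_m], preset.ca_cal))

    # --- per-subregion clearance rates -------------------------------------
    sub = preset.clearance_subregion_px
    nty, ntx = int(np.ceil(ny / sub)), int(np.ceil(nx / sub))
    rates = {}
    for ch in (CH_GREEN, CH_RED):
        k0 = math.log(2.0) / preset.clearance_halflife[ch]
        if preset.clearance_spatial_sd > 0:
            s2 = math.log(1.0 + preset.clearance_spatial_sd ** 2)
            factor = np.exp(rng.normal(-s2 / 2.0, math.sqrt(s2), (nty, ntx)))
        else:
            factor = np.ones((nty, ntx))
        rates[ch] = k0 * factor

    return _Scene(preset=preset, labels=labels, ph=ph, ca=ca,
                  true_ratio=true_ratio, z1_map=z1_map, z1_analytic=t_analytic,
                  z2_map=z2_map, partial_z1=partial_z1, clearance_rates=rates,
                  af_cell_mask=af_cell_mask,
                  vessel_fraction=float(vessels.sum() / marrow.sum()),
                  cell_positions=cell_positions)


def _expand_tiles(tiles: np.ndarray, sub: int, ny: int, nx: int) -> np.ndarray:
    full = np.repeat(np.repeat(tiles, sub, axis=0), sub, axis=1)
    return full[:ny, :nx]


def _render(scene: _Scene, t_acquired: float, rng: np.random.Generator
            ) -> VoxelStack:
    """Forward model: emission -> clearance -> crosstalk -> attenuation ->
    bone autofluorescence -> noise + background."""
    p = scene.preset
    nz, ny, nx = p.shape
    labels = scene.labels
    att = p.attenuation_model

    green_em = np.zeros(p.shape)
    for lab, ref in p.green_reference.items():
        green_em[labels == lab] = ref
    green_em[labels == OSTEOID] *= p.osteoid_green_gain
    red_em = np.where(np.isfinite(scene.true_ratio),
                      scene.true_ratio * green_em, 0.0)

    # dye clearance since the 10 s reference (tile-wise rates)
    clear = {}
    for ch, kt in scene.clearance_rates.items():
        k_px = _expand_tiles(kt, p.clearance_subregion_px, ny, nx)
        clear[ch] = np.exp(-k_px * (t_acquired - REFERENCE_TIME_S))[None, :, :]
    green_d = green_em * clear[CH_GREEN]
    red_d = red_em * clear[CH_RED]

    # autofluorescent cells emit green only and do not clear
    green_d = green_d + np.where(scene.af_cell_mask, p.af_cell_green, 0.0)

    # spectral crosstalk (detection-side mixing)
    a, b = p.crosstalk.red_into_green, p.crosstalk.green_into_red
    green_mix = green_d + a * red_d
    red_mix = red_d + b * green_d

    # two-layer attenuation along the vertical collection path
    in_bone = labels == BONE
    z1_path = np.where(in_bone, scene.partial_z1,
                       np.broadcast_to(scene.z1_map, p.shape))
    z2_path = np.where(in_bone, 0.0, scene.z2_map)
    att_g = np.exp(-(att.c1_green * z1_path + att.c2_green * z2_path))
    att_r = np.exp(-(att.c1_red * z1_path + att.c2_red * z2_path))
    green_i = green_mix * att_g
    red_i = red_mix * att_r

    # bone autofluorescence: green, attenuated by overlying bone only
    af = p.autofluorescence_level * p.green_reference[VESSEL]
    green_i = green_i + np.where(
        in_bone, af * np.exp(-att.c1_green * scene.partial_z1), 0.0)

    shg = np.where(
        in_bone,
        p.shg_intensity * np.exp(-p.shg_attenuation_per_um * scene.partial_z1),
        0.0)

    channels = {CH_SHG: shg, CH_GREEN: green_i, CH_RED: red_i}
    noisy = {}
    for ch, arr in channels.items():
        out = arr
        if p.noise.photon_scale > 0:
            lam = np.maximum(arr, 0.0) * p.noise.photon_scale
            out = rng.poisson(lam).astype(np.float64) / p.noise.photon_scale
        if p.noise.read_sd > 0:
            out = out + rng.normal(0.0, p.noise.read_sd, arr.shape)
        noisy[ch] = np.maximum(out + p.noise.background_offset, 0.0)

    return VoxelStack(channels=noisy, voxel_size_xy=p.voxel_size_xy,
                      z_step=p.z_step, t_acquired=t_acquired,
                      background_offset=p.noise.background_offset,
                      stages=("simulated",))


def _truth_from_scene(scene: _Scene, rigid_offset=None) -> GroundTruth:
    p = scene.preset
    return GroundTruth(
        labels=scene.labels, ph=scene.ph, ca=scene.ca,
        true_ratio=scene.true_ratio, z1_map=scene.z1_map,
        z1_analytic=scene.z1_analytic, z2_map=scene.z2_map,
        partial_z1=scene.partial_z1, attenuation=p.attenuation_model,
        crosstalk=p.crosstalk, clearance_rates=scene.clearance_rates,
        clearance_subregion_px=p.clearance_subregion_px,
        vessel_fraction_realized=scene.vessel_fraction,
        af_cell_mask=scene.af_cell_mask,
        cell_positions=scene.cell_positions, rigid_offset=rigid_offset,
        background_offset=p.noise.background_offset)


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------

def generate_calvaria(preset: ScenePreset | str, seed: int
                      ) -> tuple[VoxelStack, GroundTruth]:
    """Generate one distorted stack plus its full ground truth."""
    if isinstance(preset, str):
        preset = get_preset(preset)
    scene = _build_scene(preset, seed)
    rng = np.random.default_rng((seed, 1))
    stack = _render(scene, preset.t_acquired, rng)
    return stack, _truth_from_scene(scene)


def generate_timepoint_pair(preset: ScenePreset | str, seed: int, dt: float,
                            rigid_offset: tuple[int, int, int] | None = None
                            ) -> tuple[VoxelStack, VoxelStack, GroundTruth]:
    """Two stacks of the identical scene separated by ``dt`` seconds.

    The second stack differs only by additional dye clearance, a fresh noise
    draw and (optionally) a known rigid voxel offset for registration tests.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if isinstance(preset, str):
        preset = get_preset(preset)
    scene = _build_scene(preset, seed)
    rng = np.random.default_rng((seed, 1))
    s1 = _render(scene, preset.t_acquired, rng)
    s2 = _render(scene, preset.t_acquired + dt, rng)
    if rigid_offset is not None:
        shifted = {ch: np.roll(arr, rigid_offset, axis=(0, 1, 2))
                   for ch, arr in s2.channels.items()}
        s2 = s2.with_channels(shifted, stage=f"offset:{tuple(rigid_offset)}")
    return s1, s2, _truth_from_scene(scene, rigid_offset=rigid_offset)


def generate_calibration_series(kind: str, levels=None, cal=None,
                                noise_sd: float = 0.02, replicates: int = 3,
                                seed: int = 0) -> pd.DataFrame:
    """In vitro calibration series: (level, replicate, ratio) table.

    Ratios come from the forward calibration map with multiplicative
    Gaussian noise (``noise_sd`` relative SD, 3 replicates by default).
    """
    rng = np.random.default_rng(seed)
    if kind == "ph":
        cal = cal or PHCalibration()
        if levels is None:
            levels = np.arange(5.6, 9.01, 0.4)
        fwd = lambda x: ratio_from_ph(x, cal)  # noqa: E731
    elif kind == "ca":
        cal = cal or CaCalibration()
        if levels is None:
            levels = np.array([0.0, 0.1, 0.25, 0.5, 1.0, 2.0, 5.0, 10.0, 15.0])
        fwd = lambda x: ratio_from_ca(x, cal)  # noqa: E731
    else:
        raise ValueError("kind must be 'ph' or 'ca'")
    rows = []
    for lev in np.asarray(levels, dtype=float):
        r0 = float(fwd(lev))
        for rep in range(replicates):
            noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            rows.append({"level": lev, "replicate": rep,
                         "ratio": r0 * (1.0 + noise)})
    return pd.DataFrame(rows)


def generate_bonefront_scene(remaining_fraction: float, seed: int,
                             shape: tuple[int, int, int] = (24, 96, 96),
                             intensity: float = 1000.0,
                             noise: NoiseParams = NO_NOISE
                             ) -> tuple[VoxelStack, float]:
    """Bone-remodelling scene: Dye 2 labels the full endosteal front, Dye 1
    a connected subset covering ``remaining_fraction`` of it.

    Returns a stack with blue (Dye 1, old front) and red (Dye 2, new front)
    channels plus the realised overlap fraction.
    """
    if not (0.0 <= remaining_fraction <= 1.0):
        raise ValueError("remaining_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    vox, zs = DEFAULT_VOXEL_XY, DEFAULT_Z_STEP
    g = _correlated_field(rng, (ny, nx), corr_um=12.0, voxel_xy=vox, z_step=zs)
    from scipy.stats import norm
    t = 20.0 + 25.0 * norm.cdf(g)
    n_bone = np.clip(np.round(t / zs).astype(int), 1, nz - 4)
    endo = n_bone - 1

    # endosteal front: one surface voxel per column
    front_cols = np.ones((ny, nx), dtype=bool)
    total = int(front_cols.sum())
    n_keep = int(round(remaining_fraction * total))

    keep = np.zeros((ny, nx), dtype=bool)
    if n_keep > 0:
        # connected growth (BFS) over the column grid from a random start
        start = (int(rng.integers(0, ny)), int(rng.integers(0, nx)))
        from collections import deque
        q = deque([start])
        seen = {start}
        count = 0
        while q and count < n_keep:
            y, x = q.popleft()
            keep[y, x] = True
            count += 1
            for dy, dx in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                p = (y + dy, x + dx)
                if (0 <= p[0] < ny and 0 <= p[1] < nx and p not in seen):
                    seen.add(p)
                    q.append(p)

    cols_y, cols_x = np.nonzero(front_cols)
    blue = np.zeros(shape)
    red = np.zeros(shape)
    red[endo[cols_y, cols_x], cols_y, cols_x] = intensity
    ky, kx = np.nonzero(keep)
    blue[endo[ky, kx], ky, kx] = intensity
    shg = np.where(np.arange(nz).reshape(-1, 1, 1) < n_bone, 1200.0, 0.0)

    channels = {CH_BLUE: blue, CH_RED: red, CH_SHG: shg}
    if noise.read_sd > 0 or noise.photon_scale > 0:
        out = {}
        for ch, arr in channels.items():
            v = arr
            if noise.photon_scale > 0:
                v = rng.poisson(np.maximum(v, 0) * noise.photon_scale
                                ).astype(float) / noise.photon_scale
            if noise.read_sd > 0:
                v = v + rng.normal(0, noise.read_sd, arr.shape)
            out[ch] = np.maximum(v + noise.background_offset, 0)
        channels = out
    stack = VoxelStack(channels=channels, voxel_size_xy=vox, z_step=zs,
                       stages=("simulated_bonefront",))
    return stack, keep.sum() / total
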