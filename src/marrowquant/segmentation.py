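"""Compartment segmentation from the red dye channel.

The cell-impermeable dye pair fills vessels and the ~1 um interstitial gaps
between marrow cells, which appear dark; segmentation therefore runs on the
red channel in a fixed order: contrast enhancement by histogram
equalization with a 10% saturated fraction, per-plane white top-hat
filtering to remove uneven illumination, local adaptive thresholding with a
Gaussian-weighted mean, a morphological-opening split of thick tubular
vessels from thin interstitial sheets, and finally osteoid detection
(bright endosteal patches) plus exclusion of low-SNR and green-only
(autofluorescent) voxels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_local
from skimage.morphology import disk, remove_small_holes, white_tophat

from marrowquant.bone_geometry import BoneMaps
from marrowquant.stack import CH_GREEN, CH_RED, VoxelStack


@dataclass
class CompartmentMasks:
    """Binary 3D masks for the dye-labelled compartments.

    ``vessels`` and ``interstitium`` are disjoint; ``osteoid`` sits on the
    endosteal shell; ``excluded`` collects low-SNR and autofluorescent
    voxels that must never enter ratiometric statistics.
    """

    vessels: np.ndarray
    interstitium: np.ndarray
    osteoid: np.ndarray = None
    excluded: np.ndarray = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.osteoid is None:
            self.osteoid = np.zeros(self.vessels.shape, dtype=bool)
        if self.excluded is None:
            self.excluded = np.zeros(self.vessels.shape, dtype=bool)
        if (self.vessels & self.interstitium).any():
            raise ValueError("vessel and interstitium masks overlap")


def enhance_contrast(image: np.ndarray, saturated_fraction: float = 0.10
                     ) -> np.ndarray:
    """Histogram equalization with a fixed saturated fraction.

    A monotone non-decreasing remapping of intensities to [0, 1] such that
    the top ``saturated_fraction`` of voxels map to the output maximum
    (1.0); with fraction 0 this is plain histogram equalization.  A
    constant image cannot be equalized and is returned unchanged (scaled
    copy) with a warning.
    """
    image = np.asarray(image, dtype=float)
    if not (0.0 <= saturated_fraction < 1.0):
        raise ValueError("saturated_fraction must be in [0, 1)")
    if np.ptp(image) == 0:
        warnings.warn("constant image; contrast enhancement is the identity")
        return np.zeros_like(image)
    flat = image.ravel()
    if saturated_fraction > 0:
        cut = np.quantile(flat, 1.0 - saturated_fraction)
    else:
        cut = flat.max()
    clipped = np.minimum(image, cut)
    # CDF-based equalization of the clipped data
    values, counts = np.unique(clipped.ravel(), return_counts=True)
    cdf = np.cumsum(counts).astype(float)
    cdf /= cdf[-1]
    lo = cdf[0]
    eq = (cdf - lo) / (1.0 - lo) if lo < 1.0 else cdf
    out = np.interp(clipped.ravel(), values, eq).reshape(image.shape)
    return out


def tophat_per_plane(image: np.ndarray, radius_um: float,
                     voxel_size_xy: float) -> np.ndarray:
    """White top-hat with a disk footprint, applied independently per plane.

    Removes structures larger than the footprint (slowly varying
    illumination) while preserving dye-filled gaps and vessels.
    """
    if radius_um <= voxel_size_xy:
        raise ValueError("top-hat radius must exceed the voxel size")
    r = int(round(radius_um / voxel_size_xy))
    # decomposed footprint: a sequence of small erosions/dilations that
    # approximates the disk but scales to large radii
    footprint = disk(r, decomposition="sequence") if r > 8 else disk(r)
    out = np.empty_like(image, dtype=float)
    for z in range(image.shape[0]):
        out[z] = white_tophat(np.asarray(image[z], dtype=float),
                              footprint=footprint)
    return out


def adaptive_threshold(image: np.ndarray, window_um: float,
                       voxel_size_xy: float, offset: float = 0.0
                       ) -> np.ndarray:
    """Per-plane local adaptive threshold with a Gaussian-weighted mean.

    A voxel is foreground iff its intensity exceeds the Gaussian-weighted
    local mean by more than ``offset`` (so a constant image yields an empty
    mask for any offset >= 0).
    """
    block = int(round(window_um / voxel_size_xy))
    if block < 3:
        raise ValueError("adaptive window must span at least 3 voxels")
    if block % 2 == 0:
        block += 1
    out = np.zeros(image.shape, dtype=bool)
    for z in range(image.shape[0]):
        plane = np.asarray(image[z], dtype=float)
        local_mean = threshold_local(plane, block_size=block, method="gaussian",
                                     offset=0.0)
        out[z] = plane > local_mean + offset
    return out


def _anisotropic_ball(radius_um: float, voxel_size_xy: float, z_step: float
                      ) -> np.ndarray:
    dz = int(radius_um // z_step)
    dxy = max(int(round(radius_um / voxel_size_xy)), 1)
    zz, yy, xx = np.mgrid[-dz:dz + 1, -dxy:dxy + 1, -dxy:dxy + 1]
    return ((zz * z_step) ** 2 + (yy * voxel_size_xy) ** 2
            + (xx * voxel_size_xy) ** 2) <= radius_um ** 2


def split_vessels_interstitium(dye_mask: np.ndarray, voxel_size_xy: float,
                               z_step: float, opening_radius_um: float = 2.0,
                               min_component_voxels: int = 30,
                               perivascular_trim_um: float = 1.0
                               ) -> CompartmentMasks:
    """Separate thick tubular vessels from thin interstitial sheets.

    Morphological opening with a ball of ``opening_radius_um`` keeps only
    structures thicker than twice the radius (the vessels, ~10 um across);
    the remaining foreground is interstitium.  Shot-noise holes inside
    vessel lumens are filled per plane before the opening so they cannot
    shatter tube cores.  Components smaller than ``min_component_voxels``
    are dropped to the excluded mask.
    """
    dye_mask = np.asarray(dye_mask, dtype=bool)
    excluded = np.zeros(dye_mask.shape, dtype=bool)
    if not dye_mask.any():
        return CompartmentMasks(vessels=np.zeros_like(dye_mask),
                                interstitium=np.zeros_like(dye_mask),
                                excluded=excluded,
                                provenance={"opening_radius_um": opening_radius_um})
    # fill only holes much smaller than a cell cross-section (~240 voxels
    # at 0.4 um/pixel), so dark cells are preserved
    hole_area = max(int(3.0 / voxel_size_xy) ** 2, 4)
    filled = np.stack([remove_small_holes(dye_mask[z], max_size=hole_area)
                       for z in range(dye_mask.shape[0])])
    ball = _anisotropic_ball(opening_radius_um, voxel_size_xy, z_step)
    vessels = ndimage.binary_opening(filled, structure=ball)
    if perivascular_trim_um > 0:
        # the opened tube includes the ~1 um dye-filled perivascular sheet;
        # trim it back so that sheet counts as interstitium
        r = int(round(perivascular_trim_um / voxel_size_xy))
        if r > 0:
            yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
            fp = ((yy ** 2 + xx ** 2) <= r ** 2)[None, :, :]
            vessels = ndimage.binary_erosion(vessels, structure=fp)
    interstitium = dye_mask & ~vessels
    # drop speckle components
    for name, mask in (("vessels", vessels), ("interstitium", interstitium)):
        lab, n = ndimage.label(mask)
        if n:
            sizes = np.bincount(lab.ravel())
            small = np.isin(lab, np.nonzero(sizes < min_component_voxels)[0])
            small &= mask
            mask &= ~small
            excluded |= small
    return CompartmentMasks(vessels=vessels, interstitium=interstitium,
                            excluded=excluded,
                            provenance={"opening_radius_um": opening_radius_um,
                                        "min_component_voxels": min_component_voxels})


def detect_osteoid_and_exclusions(red: np.ndarray, green: np.ndarray,
                                  bone_maps: BoneMaps,
                                  masks: CompartmentMasks,
                                  d_osteo_um: float = 5.0,
                                  osteoid_factor: float = 3.0,
                                  snr_floor: tuple[float, float] = (0.0, 0.0)
                                  ) -> CompartmentMasks:
    """Identify osteoids and build the exclusion mask.

    Osteoid: foreground voxels within ``d_osteo_um`` of the bone whose red
    intensity exceeds ``osteoid_factor`` times the interstitial median of
    the endosteal shell under comparable bone thickness (the reference is
    computed per thickness bin, so overlying-bone attenuation is not
    mistaken for dimness).  Excluded: voxels below the SNR floor in both
    channels, plus green-only objects (cell autofluorescence shows in green
    with no red dye signal).
    """
    red = np.asarray(red, dtype=float)
    green = np.asarray(green, dtype=float)
    fg = masks.vessels | masks.interstitium
    near_bone = (bone_maps.depth_map > 0) & (bone_maps.depth_map <= d_osteo_um)

    inter_shell = masks.interstitium & near_bone
    if not inter_shell.any():
        inter_shell = masks.interstitium
    osteoid = np.zeros(red.shape, dtype=bool)
    if inter_shell.any():
        thick3d = np.broadcast_to(bone_maps.thickness_map, red.shape)
        edges = np.quantile(thick3d[inter_shell], np.linspace(0, 1, 7))
        edges = np.unique(edges)
        global_ref = np.median(red[inter_shell])
        cand = fg & near_bone
        for lo, hi in zip(edges[:-1], edges[1:]):
            in_bin = (thick3d >= lo) & (thick3d <= hi)
            ref_sel = inter_shell & in_bin
            ref = np.median(red[ref_sel]) if ref_sel.sum() >= 20 else global_ref
            osteoid |= cand & in_bin & (red > osteoid_factor * ref)

    low_red, low_green = snr_floor
    both_low = (red <= low_red) & (green <= low_green)
    green_only = (green > low_green) & (red <= low_red) & ~bone_maps.mask
    excluded = masks.excluded | both_low | green_only

    vessels = masks.vessels & ~osteoid & ~excluded
    interstitium = masks.interstitium & ~osteoid & ~excluded
    osteoid = osteoid & ~excluded
    prov = dict(masks.provenance)
    prov.update({"d_osteo_um": d_osteo_um, "osteoid_factor": osteoid_factor,
                 "snr_floor": snr_floor})
    return CompartmentMasks(vessels=vessels, interstitium=interstitium,
                            osteoid=osteoid, excluded=excluded, provenance=prov)


def segment_stack(stack: VoxelStack, bone_maps: BoneMaps,
                  tophat_um: float = 20.0, window_um: float = 25.0,
                  offset: float = 0.0, opening_radius_um: float = 2.0,
                  min_component_voxels: int = 30, d_osteo_um: float = 5.0,
                  osteoid_factor: float = 3.0,
                  snr_floor: tuple[float, float] = (0.0, 0.0),
                  channel: str = CH_RED) -> CompartmentMasks:
    """Full segmentation pipeline on the dye channel, in the fixed order
    enhance -> top-hat -> adaptive threshold -> vessel/interstitium split ->
    osteoid + exclusions.  Bone voxels are removed from all dye masks."""
    img = np.asarray(stack[channel], dtype=float)
    enhanced = enhance_contrast(img, saturated_fraction=0.10)
    flattened = tophat_per_plane(enhanced, tophat_um, stack.voxel_size_xy)
    fg = adaptive_threshold(flattened, window_um, stack.voxel_size_xy,
                            offset=offset)
    fg &= ~bone_maps.mask & (bone_maps.depth_map > 0)
    masks = split_vessels_interstitium(
        fg, stack.voxel_size_xy, stack.z_step,
        opening_radius_um=opening_radius_um,
        min_component_voxels=min_component_voxels)
    masks = detect_osteoid_and_exclusions(
        img, np.asarray(stack[CH_GREEN], dtype=float), bone_maps, masks,
        d_osteo_um=d_osteo_um, osteoid_factor=osteoid_factor,
        snr_floor=snr_floor)
    masks.provenance.update({"tophat_um": tophat_um, "window_um": window_um,
                             "offset": offset, "channel": channel})
    return masks
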