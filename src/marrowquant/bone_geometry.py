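"""Bone mask, thickness map (Z1) and depth-from-endosteum map (Z2).

The cortical bone is delineated from the second-harmonic-generation (SHG)
channel by global Otsu thresholding.  From the binary mask two geometric
maps drive the depth correction:

* the 2D thickness map gives, per x-y column, the amount of bone material a
  vertically travelling photon must traverse (Z1 = bone-voxel count x z
  step; bone may be porous, so this is material, not top-to-bottom extent);
* the 3D depth map gives, per marrow voxel, the distance to the endosteum
  (Z2), the deepest bone voxel of the same column, measured along z.

Columns containing no bone (field-of-view edges) are flagged and excluded
from attenuation fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from marrowquant.stack import CH_SHG, VoxelStack


@dataclass
class BoneMaps:
    """Bone geometry derived from the SHG channel.

    Attributes
    ----------
    mask : (nz, ny, nx) bool
        Bone voxels.
    thickness_map : (ny, nx) float
        Z1 in micrometres per column.
    depth_map : (nz, ny, nx) float
        Z2 in micrometres; 0 inside/above bone, increases by one z step per
        marrow plane below the endosteum.
    endosteum_z : (ny, nx) int
        z index of the deepest bone voxel per column; -1 where no bone.
    valid_columns : (ny, nx) bool
        Columns that contain bone and are usable for attenuation fitting.
    partial_thickness : (nz, ny, nx) float
        Bone material overlying each voxel (micrometres); for a bone voxel
        this is the bone above it inside the plate, for a marrow voxel it
        equals the full column thickness.
    """

    mask: np.ndarray
    thickness_map: np.ndarray
    depth_map: np.ndarray
    endosteum_z: np.ndarray
    valid_columns: np.ndarray
    partial_thickness: np.ndarray
    z_step: float


def bone_mask(shg: np.ndarray, closing_radius: int = 1) -> np.ndarray:
    """Binary bone mask by global Otsu thresholding of the SHG stack.

    A 3D morphological closing (radius ``closing_radius`` voxels) bridges
    speckle holes left by thresholding noisy SHG.  A flat or single-valued
    histogram cannot be thresholded; a warning is raised and an empty mask
    returned.
    """
    shg = np.asarray(shg)
    if shg.size == 0:
        raise ValueError("empty SHG channel")
    if np.ptp(shg) == 0:
        warnings.warn("SHG histogram is degenerate (constant image); "
                      "returning empty bone mask")
        return np.zeros(shg.shape, dtype=bool)
    thr = threshold_otsu(shg)
    mask = shg > thr
    if closing_radius > 0 and mask.any():
        # 6-connected closing bridges speckle holes without filling genuine
        # staircase concavities of the endosteal surface
        struct = ndimage.generate_binary_structure(3, 1)
        # pad by edge replication so the closing is border-neutral
        r = closing_radius
        padded = np.pad(mask, r, mode="edge")
        padded = ndimage.binary_closing(padded, structure=struct, iterations=r)
        mask = padded[r:-r, r:-r, r:-r]
    return mask


def thickness_map(mask: np.ndarray, z_step: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-column bone thickness Z1 (micrometres) and a valid-column flag.

    Thickness counts bone voxels (attenuating material traversed
    vertically), so porous bone contributes only its solid part.
    """
    counts = mask.sum(axis=0)
    valid = counts > 0
    if not valid.any():
        warnings.warn("bone mask is empty; thickness map is all zero")
    return counts.astype(np.float64) * z_step, valid


def depth_map(mask: np.ndarray, z_step: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel distance to the endosteum Z2 and the endosteal z index.

    The endosteum of a column is its deepest bone voxel; marrow voxels below
    it get Z2 = (z - endosteum_z) * z_step, voxels at or above get 0.
    Columns without bone get Z2 = 0 and endosteum_z = -1.
    """
    nz = mask.shape[0]
    any_bone = mask.any(axis=0)
    # deepest bone voxel index per column
    endo = np.where(any_bone, nz - 1 - np.argmax(mask[::-1], axis=0), -1)
    zidx = np.arange(nz).reshape(-1, 1, 1)
    below = (zidx > endo) & any_bone
    depth = np.where(below, (zidx - endo) * z_step, 0.0)
    return depth.astype(np.float64), endo.astype(np.int64)


def partial_thickness(mask: np.ndarray, z_step: float) -> np.ndarray:
    """Bone material strictly above each voxel, per column, in micrometres.

    Inside the bone plate this is the attenuating path of bone
    autofluorescence emitted at that voxel; below the plate it saturates at
    the full column thickness.
    """
    above = np.cumsum(mask, axis=0) - mask  # bone voxels with smaller z
    return above.astype(np.float64) * z_step


def compute_bone_maps(stack: VoxelStack, closing_radius: int = 1,
                      shg_channel: str = CH_SHG) -> BoneMaps:
    """Run the full bone-geometry derivation on a stack's SHG channel."""
    mask = bone_mask(stack[shg_channel], closing_radius=closing_radius)
    thick, valid = thickness_map(mask, stack.z_step)
    depth, endo = depth_map(mask, stack.z_step)
    part = partial_thickness(mask, stack.z_step)
    return BoneMaps(mask=mask, thickness_map=thick, depth_map=depth,
                    endosteum_z=endo, valid_columns=valid,
                    partial_thickness=part, z_step=stack.z_step)
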