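"""The correction chain: background, two-step depth correction, crosstalk,
clearance.

Measured fluorescence follows I = I0 * exp(-(C1*Z1 + C2*Z2)) per channel,
where C1 and C2 are the attenuation coefficients of cortical bone and
marrow, Z1 the local bone thickness and Z2 the depth below the endosteum.
The chain runs in the fixed order

    (i) background subtraction -> (ii) depth correction ->
    (iii) crosstalk unmixing  -> (iv) clearance correction

and each stage tags the stack's provenance.  Coefficient estimation:

* C1 (green) from the exponential decay of bone autofluorescence with depth
  into the bone plate;
* C1 (red) by minimising, over candidate coefficients, the variance of
  thickness-corrected intravascular log ratios across endosteal-vessel
  voxels under differing bone thickness (the intravascular ratio is
  systemically constant, so residual spread is attenuation mismatch);
* C2 (both channels) from the decay of mean intravascular intensity with
  depth in the thickness-corrected stack, equivalently by minimising the
  spread of depth-corrected means across depth bins.

Dye clearance between timepoints is fitted per 20x20-pixel subregion with a
one-component exponential and intensities are referenced back to 10 s after
injection.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.ndimage import binary_erosion as ndi_binary_erosion
from skimage.registration import phase_cross_correlation

from marrowquant.bone_geometry import BoneMaps
from marrowquant.stack import CH_GREEN, CH_RED, DYE_CHANNELS, VoxelStack

#: per-voxel correction factors are capped here so deep low-signal voxels do
#: not amplify noise unboundedly; capped voxels are flagged in diagnostics
CORRECTION_CAP_LOG = 6.0

REFERENCE_TIME_S = 10.0


@dataclass
class AttenuationModel:
    """Bone (C1) and marrow (C2) attenuation coefficients, per channel, 1/um."""

    c1_green: float
    c1_red: float
    c2_green: float = 0.0
    c2_red: float = 0.0
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("c1_green", "c1_red", "c2_green", "c2_red"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")

    def coeffs(self, channel: str) -> tuple[float, float]:
        if channel == CH_GREEN:
            return self.c1_green, self.c2_green
        if channel == CH_RED:
            return self.c1_red, self.c2_red
        raise KeyError(f"no attenuation coefficients for channel {channel!r}")


@dataclass(frozen=True)
class CrosstalkMatrix:
    """Spectral bleed-through fractions between the two collection channels."""

    red_into_green: float = 0.12
    green_into_red: float = 0.013

    def __post_init__(self) -> None:
        a, b = self.red_into_green, self.green_into_red
        if not (0 <= a < 1 and 0 <= b < 1):
            raise ValueError("crosstalk fractions must lie in [0, 1)")
        if a * b >= 1:
            raise ValueError("mixing matrix is singular")

    def as_matrix(self) -> np.ndarray:
        """Mixing matrix M with (G_meas, R_meas) = M @ (G, R)."""
        return np.array([[1.0, self.red_into_green],
                         [self.green_into_red, 1.0]])


@dataclass
class ClearanceField:
    """Per-subregion exponential decay rates for each dye channel."""

    rates: dict[str, np.ndarray]        # s^-1, shape (ny_tiles, nx_tiles)
    subregion_px: int = 20
    reference_time: float = REFERENCE_TIME_S
    flagged: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ch, k in self.rates.items():
            if not np.all(np.isfinite(k)):
                raise ValueError(f"non-finite clearance rates in channel {ch}")


# ---------------------------------------------------------------------------
# (i) background subtraction
# ---------------------------------------------------------------------------

def subtract_background(stack: VoxelStack, background=None) -> VoxelStack:
    """Subtract a pre-injection background from every channel, clamped at 0.

    ``background`` may be a scalar, a per-channel dict of scalars or arrays,
    or None to use the stack's recorded ``background_offset``.
    """
    if background is None:
        background = stack.background_offset
    new = {}
    for ch, arr in stack.channels.items():
        bg = background.get(ch, 0.0) if isinstance(background, dict) else background
        bg = np.asarray(bg, dtype=np.float32)
        if bg.ndim and bg.shape != arr.shape:
            raise ValueError(
                f"background shape {bg.shape} does not match stack {arr.shape}")
        new[ch] = np.maximum(arr - bg, 0.0)
    out = stack.with_channels(new, stage="background_subtracted")
    out.background_offset = 0.0
    return out


# ---------------------------------------------------------------------------
# (ii) depth correction: coefficient fits and application
# ---------------------------------------------------------------------------

def fit_bone_green_attenuation(stack: VoxelStack, bone_maps: BoneMaps,
                               min_bins: int = 3) -> float:
    """C1 (green) from bone-autofluorescence decay with depth into bone.

    Bone voxels are binned by the bone material overlying them; the slope of
    log(mean green) against that depth gives the coefficient.
    """
    mask = bone_maps.mask
    if not mask.any():
        raise ValueError("bone mask is empty; supply C1 manually")
    depth_in_bone = bone_maps.partial_thickness[mask]
    green = np.asarray(stack[CH_GREEN])[mask]
    bins = np.unique(depth_in_bone)
    means = np.array([green[depth_in_bone == b].mean() for b in bins])
    ok = means > 0
    if ok.sum() < min_bins:
        raise ValueError(
            f"only {int(ok.sum())} usable depth bins inside bone "
            f"(need >= {min_bins}); supply C1 manually")
    res = stats.linregress(bins[ok], np.log(means[ok]))
    return max(-float(res.slope), 0.0)


def fit_bone_red_attenuation(stack: VoxelStack, bone_maps: BoneMaps,
                             vessel_mask: np.ndarray, c1_green: float,
                             z2_max: float | None = None,
                             intensity_floor: float = 0.0,
                             erosion_um: float = 1.2,
                             c2_diff: float | None = None) -> float:
    """C1 (red) by converging thickness-corrected endosteal-vessel ratios.

    Vessel voxels immediately below the endosteum (Z2 <= ``z2_max``; default
    one z step, so the marrow term is a constant offset) see distortion only
    from the overlying bone.  They are grouped into ROIs by overlying bone
    thickness; since the intravascular ratio is systemically constant, the
    weighted variance across thickness groups of

        log(mean R / mean G) + (c - C1G) * Z1

    vanishes at the true red coefficient, and its minimiser is the weighted
    least-squares slope in Z1 (group means keep low-SNR voxels from
    dominating the objective).

    With ``c2_diff`` = C2R - C2G supplied (a refinement pass once the
    marrow coefficients are known), deeper endosteal planes can be used:
    the marrow term is compensated per voxel instead of being held constant
    by the single-plane restriction.
    """
    if z2_max is None:
        z2_max = bone_maps.z_step
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    if erosion_um > 0:
        # in-plane erosion keeps only vessel cores, so stray interstitial
        # voxels in the mask cannot bias the convergence objective
        r = int(round(erosion_um / stack.voxel_size_xy))
        if r > 0:
            yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
            footprint = ((yy ** 2 + xx ** 2) <= r ** 2)[None, :, :]
            eroded = ndi_binary_erosion(vessel_mask, structure=footprint)
            if eroded.any():
                vessel_mask = eroded
    sel = (vessel_mask
           & (bone_maps.depth_map > 0) & (bone_maps.depth_map <= z2_max)
           & bone_maps.valid_columns[None, :, :])
    red = np.asarray(stack[CH_RED])
    green = np.asarray(stack[CH_GREEN])
    sel &= (red > intensity_floor) & (green > intensity_floor)
    if sel.sum() < 3:
        raise ValueError("fewer than 3 endosteal-vessel voxels available")
    z1 = np.broadcast_to(bone_maps.thickness_map, sel.shape)[sel]
    red_s, green_s = red[sel], green[sel]
    if c2_diff is not None:
        # remove the marrow-depth term so mixed-Z2 selections stay unbiased
        z2_s = bone_maps.depth_map[sel]
        red_s = red_s * np.exp(c2_diff * z2_s)
    groups = np.unique(z1)
    z1_b, x_b, w_b = [], [], []
    for gz in groups:
        g_sel = z1 == gz
        n = int(g_sel.sum())
        if n < 1:
            continue
        z1_b.append(gz)
        x_b.append(math.log(red_s[g_sel].mean() / green_s[g_sel].mean()))
        w_b.append(n)
    z1_b = np.asarray(z1_b)
    x_b = np.asarray(x_b)
    w_b = np.asarray(w_b, dtype=float)
    if len(z1_b) < 2 or np.ptp(z1_b) == 0:
        raise ValueError("endosteal vessels all lie under identical bone "
                         "thickness; C1 (red) is unidentifiable")
    # argmin_c sum_b w_b (x_b + (c - c1g) z1_b - const)^2
    zm = np.average(z1_b, weights=w_b)
    xm = np.average(x_b, weights=w_b)
    cov = np.average((z1_b - zm) * (x_b - xm), weights=w_b)
    var = np.average((z1_b - zm) ** 2, weights=w_b)
    return max(c1_green - float(cov / var), 0.0)


def fit_marrow_attenuation(stack: VoxelStack, vessel_mask: np.ndarray,
                           bone_maps: BoneMaps, min_bins: int = 3,
                           intensity_floor: float = 0.0,
                           min_voxels_per_bin: int = 20,
                           erosion_um: float = 1.2
                           ) -> tuple[float, float]:
    """C2 (red, green) from intravascular intensity decay with marrow depth.

    Operates on the thickness-corrected stack: per channel, mean
    intravascular intensity per Z2 bin is fitted with an exponential decay
    (log-linear least squares), which is the minimiser of the spread of
    depth-corrected bin means.  The vessel mask is eroded in-plane by
    ``erosion_um`` first: stray non-vascular voxels carry a different dye
    concentration and would otherwise bend the depth profile.  Returns
    (c2_red, c2_green).
    """
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    if erosion_um > 0:
        r = int(round(erosion_um / stack.voxel_size_xy))
        if r > 0:
            yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
            footprint = ((yy ** 2 + xx ** 2) <= r ** 2)[None, :, :]
            eroded = ndi_binary_erosion(vessel_mask, structure=footprint)
            if eroded.any():
                vessel_mask = eroded
    sel = (vessel_mask & (bone_maps.depth_map > 0)
           & bone_maps.valid_columns[None, :, :])
    if not sel.any():
        raise ValueError("no intravascular voxels below the endosteum")
    z2 = bone_maps.depth_map[sel]
    out = {}
    for ch in (CH_RED, CH_GREEN):
        inten = np.asarray(stack[ch])[sel]
        ok_vox = inten > intensity_floor
        bins = np.unique(z2[ok_vox])
        means, used = [], []
        for b in bins:
            vals = inten[ok_vox & (z2 == b)]
            if len(vals) >= min_voxels_per_bin and vals.mean() > 0:
                means.append(vals.mean())
                used.append(b)
        if len(used) < min_bins:
            raise ValueError(
                f"vasculature spans only {len(used)} usable depth bins in "
                f"channel {ch} (need >= {min_bins})")
        used, means = np.asarray(used), np.asarray(means)
        res = stats.linregress(used, np.log(means))
        out[ch] = max(-float(res.slope), 0.0)
    return out[CH_RED], out[CH_GREEN]


def apply_depth_correction(stack: VoxelStack, attenuation: AttenuationModel,
                           bone_maps: BoneMaps,
                           cap_log: float = CORRECTION_CAP_LOG,
                           channels: tuple[str, ...] = DYE_CHANNELS
                           ) -> VoxelStack:
    """Undo the two-layer exponential attenuation voxelwise.

    Marrow voxels are multiplied by exp(C1*Z1 + C2*Z2) with the full column
    thickness; voxels inside bone use only the bone material above them
    (partial Z1, Z2 = 0), which keeps the bone-autofluorescence fit
    self-consistent.  The log correction factor is capped at ``cap_log`` and
    capped voxels are counted in the returned stack's provenance.
    """
    in_bone = bone_maps.mask
    z1_path = np.where(in_bone, bone_maps.partial_thickness,
                       np.broadcast_to(bone_maps.thickness_map, in_bone.shape))
    z2_path = np.where(in_bone, 0.0, bone_maps.depth_map)
    new, n_capped = {}, 0
    for ch in channels:
        c1, c2 = attenuation.coeffs(ch)
        log_factor = c1 * z1_path + c2 * z2_path
        capped = log_factor > cap_log
        n_capped += int(capped.sum())
        factor = np.exp(np.minimum(log_factor, cap_log))
        new[ch] = np.asarray(stack[ch]) * factor
    out = stack.with_channels(new, stage="depth_corrected")
    if n_capped:
        out = out.tagged(f"depth_correction_capped:{n_capped}")
    return out


# ---------------------------------------------------------------------------
# (iii) crosstalk
# ---------------------------------------------------------------------------

def unmix_crosstalk(stack_or_red, green=None,
                    xtalk: CrosstalkMatrix = CrosstalkMatrix()):
    """Invert the 2x2 spectral mixing system exactly.

    Accepts either a VoxelStack (returns a new stack) or (red, green) arrays
    (returns unmixed (red, green)).  Solves

        G_meas = G + a R,   R_meas = R + b G

    with a = red_into_green, b = green_into_red; unmixed negatives are
    clamped to zero (and counted in provenance for the stack form).
    """
    a, b = xtalk.red_into_green, xtalk.green_into_red
    det = 1.0 - a * b

    def solve(red_m, green_m):
        red_u = (red_m - b * green_m) / det
        green_u = (green_m - a * red_m) / det
        return red_u, green_u

    if isinstance(stack_or_red, VoxelStack):
        stack = stack_or_red
        red_u, green_u = solve(np.asarray(stack[CH_RED], dtype=np.float64),
                               np.asarray(stack[CH_GREEN], dtype=np.float64))
        n_neg = int((red_u < 0).sum() + (green_u < 0).sum())
        out = stack.with_channels(
            {CH_RED: np.maximum(red_u, 0.0), CH_GREEN: np.maximum(green_u, 0.0)},
            stage="crosstalk_unmixed")
        if n_neg:
            out = out.tagged(f"crosstalk_negatives_clamped:{n_neg}")
        return out
    red_u, green_u = solve(np.asarray(stack_or_red, dtype=np.float64),
                           np.asarray(green, dtype=np.float64))
    return red_u, green_u


# ---------------------------------------------------------------------------
# (iv) clearance
# ---------------------------------------------------------------------------

def register_rigid(stack_t1: VoxelStack, stack_t2: VoxelStack,
                   channel: str = CH_RED, min_correlation: float = 0.05
                   ) -> tuple[int, int, int]:
    """Integer (dz, dy, dx) shift of t2 relative to t1 maximising the
    normalised cross-correlation of one channel.

    A weak correlation peak triggers a warning and an identity shift.
    """
    ref = np.asarray(stack_t1[channel], dtype=np.float64)
    mov = np.asarray(stack_t2[channel], dtype=np.float64)
    raw, _, _ = phase_cross_correlation(ref, mov, upsample_factor=1,
                                        normalization=None)
    correction = tuple(int(round(s)) for s in raw)  # roll(mov, correction) -> ref
    aligned = np.roll(mov, correction, axis=(0, 1, 2))
    peak = float(np.corrcoef(ref.ravel(), aligned.ravel())[0, 1])
    if not np.isfinite(peak) or peak < min_correlation:
        warnings.warn("registration correlation peak below floor; "
                      "returning identity shift")
        return (0, 0, 0)
    return tuple(-c for c in correction)


def apply_shift(stack: VoxelStack, shift: tuple[int, int, int]) -> VoxelStack:
    """Apply an integer voxel shift (circularly) to all channels."""
    new = {ch: np.roll(arr, shift, axis=(0, 1, 2))
           for ch, arr in stack.channels.items()}
    return stack.with_channels(new, stage=f"registered:{shift}")


def _tile_means(arr: np.ndarray, sub: int, use: np.ndarray) -> np.ndarray:
    """Mean of usable voxels per x-y tile (NaN where none)."""
    nz, ny, nx = arr.shape
    nty, ntx = int(np.ceil(ny / sub)), int(np.ceil(nx / sub))
    means = np.full((nty, ntx), np.nan)
    for ty in range(nty):
        for tx in range(ntx):
            block = arr[:, ty * sub:(ty + 1) * sub, tx * sub:(tx + 1) * sub]
            ublock = use[:, ty * sub:(ty + 1) * sub, tx * sub:(tx + 1) * sub]
            if ublock.any():
                means[ty, tx] = block[ublock].mean()
    return means


def _fill_from_neighbors(values: np.ndarray, invalid: np.ndarray) -> np.ndarray:
    """Iteratively replace invalid tiles by the mean of valid neighbours."""
    out = values.copy()
    bad = invalid.copy()
    while bad.any():
        filled_any = False
        for ty, tx in zip(*np.nonzero(bad)):
            neigh = []
            for dy, dx in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                y, x = ty + dy, tx + dx
                if 0 <= y < out.shape[0] and 0 <= x < out.shape[1] and not bad[y, x]:
                    neigh.append(out[y, x])
            if neigh:
                out[ty, tx] = float(np.mean(neigh))
                bad[ty, tx] = False
                filled_any = True
        if not filled_any:  # no valid tile anywhere
            out[bad] = 0.0
            break
    return out


def fit_clearance(stack_t1: VoxelStack, stack_t2: VoxelStack,
                  times: tuple[float, float] | None = None,
                  subregion: int = 20,
                  channels: tuple[str, ...] = DYE_CHANNELS,
                  exclude_mask: np.ndarray | None = None,
                  min_intensity: float = 0.0) -> ClearanceField:
    """Per-subregion one-component exponential decay rates between two stacks.

    Each dye channel is divided into ``subregion`` x ``subregion`` pixel
    tiles; each tile is assigned the mean of its usable voxels and the decay
    rate is the exact two-point solution k = ln(I1/I2) / (t2 - t1).  Tiles
    where the rate is undefined (non-positive means, e.g. perfusion still
    rising) are flagged and filled from neighbouring tiles.

    ``exclude_mask`` removes voxels (e.g. bone, whose autofluorescence does
    not clear) from the tile means.
    """
    if times is None:
        times = (stack_t1.t_acquired, stack_t2.t_acquired)
    t1, t2 = times
    if t2 <= t1:
        raise ValueError(f"need t2 > t1, got {times}")
    dt = t2 - t1
    rates, flagged = {}, {}
    for ch in channels:
        a1 = np.asarray(stack_t1[ch])
        a2 = np.asarray(stack_t2[ch])
        # one joint voxel selection for both timepoints, so the dimmer
        # stack does not lose its faintest voxels and bias the rate
        use = (a1 > min_intensity) & (a2 > min_intensity)
        if exclude_mask is not None:
            use &= ~np.asarray(exclude_mask, dtype=bool)
        m1 = _tile_means(a1, subregion, use)
        m2 = _tile_means(a2, subregion, use)
        with np.errstate(invalid="ignore", divide="ignore"):
            k = np.log(m1 / m2) / dt
        bad = ~np.isfinite(k)
        if bad.all():
            raise ValueError(f"no usable subregions in channel {ch}")
        rates[ch] = _fill_from_neighbors(np.where(bad, 0.0, k), bad)
        flagged[ch] = bad
    return ClearanceField(rates=rates, subregion_px=subregion, flagged=flagged)


def apply_clearance_correction(stack: VoxelStack, fieldv: ClearanceField,
                               t_acquired: float | None = None) -> VoxelStack:
    """Reference dye intensities back to ``reference_time`` (10 s default).

    Each tile is multiplied by exp(k * (t_acquired - t_ref)).
    """
    if t_acquired is None:
        t_acquired = stack.t_acquired
    if t_acquired is None or not np.isfinite(t_acquired):
        raise ValueError("stack has no acquisition time; cannot correct clearance")
    sub = fieldv.subregion_px
    _, ny, nx = stack.shape
    new = {}
    for ch, k in fieldv.rates.items():
        factor_tiles = np.exp(k * (t_acquired - fieldv.reference_time))
        factor = np.repeat(np.repeat(factor_tiles, sub, axis=0), sub, axis=1)
        factor = factor[:ny, :nx]
        new[ch] = np.asarray(stack[ch]) * factor[None, :, :]
    out = stack.with_channels(new, stage="clearance_corrected")
    out.t_acquired = fieldv.reference_time
    return out
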