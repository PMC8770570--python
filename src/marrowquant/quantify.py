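"""Readouts: masked ratio maps, ROI sampling, depth profiles, D/M/R cavity
classification, marked-cell neighbourhood statistics and group comparisons.

Ratiometric values are only meaningful inside dye-labelled compartments, so
every statistic here is restricted by the segmentation masks and by a
per-channel SNR floor; ROI subregions mirror the manual sampling used in
the field (~5x5 um intravascular, ~20x20 um interstitial patches, 10-25 per
cavity), with saturation avoidance automated as exclusion of
detector-ceiling voxels.  Group differences use the unpaired two-sided
Mann-Whitney U test, exact by exhaustive enumeration for small samples.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage, stats


@dataclass
class ROISample:
    """One sampled subregion and its summary values."""

    center: tuple[int, int, int]      # (z, y, x) voxel coords
    size_um: float
    compartment: str
    mean_ratio: float
    n_voxels: int
    depth_um: float = np.nan
    value: float = np.nan             # calibrated pH or [Ca2+]


@dataclass
class CavityRecord:
    """Bone-remodelling classification of one marrow cavity."""

    cavity_id: int
    dye1_dye2_fraction: float
    cavity_class: str                 # "D" | "M" | "R"
    stats: dict = field(default_factory=dict)


@dataclass
class GroupSummary:
    """Distribution summary matching box-and-whisker reporting."""

    median: float
    q1: float
    q3: float
    p10: float
    p90: float
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        seq = (self.p10, self.q1, self.median, self.q3, self.p90)
        if not all(a <= b or np.isnan(a) or np.isnan(b)
                   for a, b in zip(seq, seq[1:])):
            raise ValueError("percentiles are not monotone")


def summarize(values) -> GroupSummary:
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        raise ValueError("no finite values to summarize")
    p10, q1, med, q3, p90 = np.percentile(v, [10, 25, 50, 75, 90])
    return GroupSummary(median=float(med), q1=float(q1), q3=float(q3),
                        p10=float(p10), p90=float(p90), mean=float(v.mean()),
                        sd=float(v.std(ddof=1)) if len(v) > 1 else 0.0,
                        n=len(v))


# ---------------------------------------------------------------------------
# ratio maps and ROI sampling
# ---------------------------------------------------------------------------

def ratio_map(red: np.ndarray, green: np.ndarray,
              include_mask: np.ndarray | None = None,
              floor: tuple[float, float] = (0.0, 0.0),
              ceiling: float | None = None) -> np.ndarray:
    """Voxelwise red/green ratio, NaN wherever the ratio is not meaningful.

    Voxels outside ``include_mask``, below the per-channel SNR ``floor``
    (red, green) or at/above the detector ``ceiling`` in either channel are
    undefined and never averaged downstream.
    """
    red = np.asarray(red, dtype=float)
    green = np.asarray(green, dtype=float)
    ok = (red > floor[0]) & (green > floor[1])
    if include_mask is not None:
        ok &= np.asarray(include_mask, dtype=bool)
    if ceiling is not None:
        ok &= (red < ceiling) & (green < ceiling)
    out = np.full(red.shape, np.nan)
    np.divide(red, green, out=out, where=ok)
    return out


def sample_rois(ratio_volume: np.ndarray, mask: np.ndarray, n: int,
                size_um: float, voxel_size_xy: float, compartment: str,
                seed: int, depth_map: np.ndarray | None = None,
                min_coverage: float = 0.5, min_voxels: int = 10,
                max_tries: int = 2000,
                convert: Callable[[np.ndarray], np.ndarray] | None = None,
                red: np.ndarray | None = None,
                green: np.ndarray | None = None,
                subpatch_um: float = 2.0) -> list[ROISample]:
    """Seeded random placement of square in-plane ROIs inside a compartment.

    An ROI is accepted when at least ``min_coverage`` of its voxels (and at
    least ``min_voxels``) are finite ratio values inside the compartment
    mask.  With ``red``/``green`` supplied the subregion ratio is the ratio
    of summed intensities over those voxels — the standard ratiometric
    estimator, insensitive to the upward bias of single-voxel ratios at low
    SNR — otherwise the mean of voxel ratios is used.  ``convert``
    calibrates the subregion ratio to a pH or [Ca2+] value.  Returns fewer
    than ``n`` ROIs with a warning if placement fails.  For sheet-like
    compartments (interstitium) ``min_coverage`` must be well below the 0.5
    suitable for vessels.

    Calibration of a nonlinear response over a spatially varying field is
    done at ``subpatch_um`` tiles inside the ROI (small against the field's
    correlation length, large enough to average out voxel noise) and the
    calibrated values are averaged; converting one ROI-wide ratio instead
    would understate the mean wherever the response curve is concave.
    """
    rng = np.random.default_rng(seed)
    mask = np.asarray(mask, dtype=bool)
    half = max(int(round(size_um / voxel_size_xy / 2)), 1)
    cand = np.argwhere(mask & np.isfinite(ratio_volume))
    samples: list[ROISample] = []
    if len(cand) == 0:
        warnings.warn(f"no usable voxels for {compartment} ROIs")
        return samples
    taken: list[np.ndarray] = []
    tries = 0
    while len(samples) < n and tries < max_tries:
        tries += 1
        z, y, x = cand[rng.integers(len(cand))]
        y0, y1 = y - half, y + half + 1
        x0, x1 = x - half, x + half + 1
        if y0 < 0 or x0 < 0 or y1 > mask.shape[1] or x1 > mask.shape[2]:
            continue
        patch_ratio = ratio_volume[z, y0:y1, x0:x1]
        patch_mask = mask[z, y0:y1, x0:x1] & np.isfinite(patch_ratio)
        if patch_mask.mean() < min_coverage or patch_mask.sum() < min_voxels:
            continue
        c = np.array([z, y, x])
        if any(np.all(np.abs(c - t) < (1, half, half)) for t in taken):
            continue  # avoid duplicate placements
        if red is not None and green is not None:
            patch_red = red[z, y0:y1, x0:x1]
            patch_green = green[z, y0:y1, x0:x1]
            gsum = float(patch_green[patch_mask].sum())
            if gsum <= 0:
                continue
            mean_ratio = float(patch_red[patch_mask].sum()) / gsum
        else:
            patch_red = patch_green = None
            mean_ratio = float(patch_ratio[patch_mask].mean())
        value = np.nan
        if convert is not None:
            sub_ratios = []
            if patch_red is not None and subpatch_um > 0:
                step = max(int(round(subpatch_um / voxel_size_xy)), 1)
                for sy in range(0, patch_mask.shape[0], step):
                    for sx in range(0, patch_mask.shape[1], step):
                        sm = patch_mask[sy:sy + step, sx:sx + step]
                        if sm.sum() < max(step * step // 4, 2):
                            continue
                        gs = float(patch_green[sy:sy + step, sx:sx + step][sm].sum())
                        if gs > 0:
                            sub_ratios.append(
                                float(patch_red[sy:sy + step, sx:sx + step][sm].sum()) / gs)
            if not sub_ratios:
                sub_ratios = [mean_ratio]
            conv = np.asarray(convert(np.asarray(sub_ratios)), dtype=float)
            conv = conv[np.isfinite(conv)]
            if len(conv):
                value = float(conv.mean())
        depth = float(depth_map[z, y, x]) if depth_map is not None else np.nan
        samples.append(ROISample(center=(int(z), int(y), int(x)),
                                 size_um=size_um, compartment=compartment,
                                 mean_ratio=mean_ratio,
                                 n_voxels=int(patch_mask.sum()),
                                 depth_um=depth, value=value))
        taken.append(c)
    if len(samples) < n:
        warnings.warn(f"placed only {len(samples)}/{n} {compartment} ROIs")
    return samples


def depth_profile(values: Sequence[float], depths: Sequence[float],
                  bin_um: float = 10.0):
    """Bin values by depth and fit a linear trend.

    Returns (table, fit): ``table`` is a list of dicts (bin centre, n, mean,
    sd) and ``fit`` has the regression slope with a 95% CI.
    """
    values = np.asarray(values, dtype=float)
    depths = np.asarray(depths, dtype=float)
    ok = np.isfinite(values) & np.isfinite(depths)
    values, depths = values[ok], depths[ok]
    if len(values) == 0:
        raise ValueError("no finite (value, depth) pairs")
    edges = np.arange(0.0, depths.max() + bin_um, bin_um)
    if len(edges) < 2:
        edges = np.array([0.0, max(depths.max(), bin_um)])
    table = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (depths >= lo) & (depths < hi)
        if sel.any():
            table.append({"depth_bin": (lo + hi) / 2, "n": int(sel.sum()),
                          "mean": float(values[sel].mean()),
                          "sd": float(values[sel].std(ddof=0))})
    if len(np.unique(depths)) > 1:
        res = stats.linregress(depths, values)
        ci = 1.96 * res.stderr if res.stderr is not None else np.nan
        fit = {"slope": float(res.slope), "intercept": float(res.intercept),
               "slope_ci95": (float(res.slope - ci), float(res.slope + ci))}
    else:
        fit = {"slope": 0.0, "intercept": float(values.mean()),
               "slope_ci95": (np.nan, np.nan)}
    return table, fit


# ---------------------------------------------------------------------------
# bone-remodelling cavity classification
# ---------------------------------------------------------------------------

def classify_cavity(dye1_mask: np.ndarray, dye2_mask: np.ndarray,
                    cavity_id: int = 0) -> CavityRecord:
    """D/M/R classification from the retained old-bone-front fraction.

    fraction = |dye1 on the dye2 front| / |dye2 front|; > 0.75 is
    deposition (D), < 0.25 resorption (R), the closed interval [0.25, 0.75]
    mixed (M).  Scale-free: depends only on the masks.
    """
    d1 = np.asarray(dye1_mask, dtype=bool)
    d2 = np.asarray(dye2_mask, dtype=bool)
    n2 = int(d2.sum())
    if n2 == 0:
        raise ValueError("dye-2 bone front is empty; cannot classify cavity")
    frac = float((d1 & d2).sum() / n2)
    if frac > 0.75:
        cls = "D"
    elif frac < 0.25:
        cls = "R"
    else:
        cls = "M"
    return CavityRecord(cavity_id=cavity_id, dye1_dye2_fraction=frac,
                        cavity_class=cls)


# ---------------------------------------------------------------------------
# marked-cell neighbourhood statistics
# ---------------------------------------------------------------------------

def neighborhood_stats(cell_positions: np.ndarray, ratio_volume: np.ndarray,
                       interstitium_mask: np.ndarray,
                       vessel_mask: np.ndarray | None,
                       voxel_size_xy: float, z_step: float,
                       radius_um: float = 15.0, n_patches: int = 5,
                       patch_um: float = 3.0, seed: int = 0,
                       convert: Callable | None = None,
                       red: np.ndarray | None = None,
                       green: np.ndarray | None = None) -> list[dict]:
    """Local interstitial values in a neighbourhood around each marked cell.

    For each cell, ``n_patches`` small interstitial patches are drawn
    (seeded) within ``radius_um`` of the cell, excluding intravascular
    voxels; the per-cell record reports the mean ratio, the calibrated
    local mean (via ``convert``) and a flag when no interstitial voxel lies
    within reach.  The default radius (15 um, roughly a few cell diameters)
    is configurable.
    """
    rng = np.random.default_rng(seed)
    inter = np.asarray(interstitium_mask, dtype=bool)
    if vessel_mask is not None:
        inter = inter & ~np.asarray(vessel_mask, dtype=bool)
    usable = inter & np.isfinite(ratio_volume)
    scale = np.array([z_step, voxel_size_xy, voxel_size_xy])
    half = max(int(round(patch_um / voxel_size_xy / 2)), 1)
    records = []
    coords = np.argwhere(usable)
    for i, pos in enumerate(np.asarray(cell_positions)):
        d = np.linalg.norm((coords - pos) * scale, axis=1)
        near = coords[d <= radius_um]
        if len(near) == 0:
            records.append({"cell": i, "flagged": True, "mean_ratio": np.nan,
                            "value": np.nan, "n_patches": 0})
            continue
        patch_means, patch_vals = [], []
        for _ in range(n_patches):
            z, y, x = near[rng.integers(len(near))]
            y0, y1 = max(y - half, 0), min(y + half + 1, usable.shape[1])
            x0, x1 = max(x - half, 0), min(x + half + 1, usable.shape[2])
            pmask = usable[z, y0:y1, x0:x1]
            if not pmask.any():
                continue
            if red is not None and green is not None:
                gsum = float(green[z, y0:y1, x0:x1][pmask].sum())
                if gsum <= 0:
                    continue
                pm = float(red[z, y0:y1, x0:x1][pmask].sum()) / gsum
            else:
                pm = float(ratio_volume[z, y0:y1, x0:x1][pmask].mean())
            patch_means.append(pm)
            if convert is not None:
                v = float(np.asarray(convert(np.array([pm])))[0])
                if np.isfinite(v):
                    patch_vals.append(v)
        if not patch_means:
            records.append({"cell": i, "flagged": True, "mean_ratio": np.nan,
                            "value": np.nan, "n_patches": 0})
            continue
        records.append({
            "cell": i, "flagged": False,
            "mean_ratio": float(np.mean(patch_means)),
            "value": float(np.mean(patch_vals)) if patch_vals else np.nan,
            "n_patches": len(patch_means)})
    return records


# ---------------------------------------------------------------------------
# group comparison (Mann-Whitney U)
# ---------------------------------------------------------------------------

def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample a, with 0.5 credit for ties."""
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mannwhitney_u(a, b, exact_max_total: int = 16) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    For pooled sample sizes up to ``exact_max_total`` the p-value is exact:
    every partition of the pooled values is enumerated and the two-sided
    p-value is the probability of a U at least as far from its null mean
    n_a*n_b/2 as observed.  Larger samples use the normal approximation
    with tie correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 1 or nb < 1:
        raise ValueError("both groups must be non-empty")
    u_obs = _u_statistic(a, b)
    mu = na * nb / 2.0

    if na + nb <= exact_max_total:
        pooled = np.concatenate([a, b])
        idx = range(na + nb)
        count = 0
        total = math.comb(na + nb, na)
        dev = abs(u_obs - mu)
        for comb in combinations(idx, na):
            sel = np.zeros(na + nb, dtype=bool)
            sel[list(comb)] = True
            u = _u_statistic(pooled[sel], pooled[~sel])
            if abs(u - mu) >= dev - 1e-12:
                count += 1
        return u_obs, count / total

    # normal approximation with tie correction
    pooled = np.concatenate([a, b])
    n = na + nb
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts ** 3 - counts).sum()) / (n * (n - 1))
    sigma2 = na * nb / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return u_obs, 1.0
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(sigma2)  # continuity corrected
    p = 2.0 * stats.norm.sf(max(z, 0.0))
    return u_obs, min(p, 1.0)


def compare_groups(a, b) -> dict:
    """Summaries of both groups plus the Mann-Whitney comparison."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need n >= 3 per group")
    u, p = mannwhitney_u(a, b)
    return {"a": summarize(a), "b": summarize(b), "u": u, "p": p,
            "test": "two-sided Mann-Whitney U"}
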