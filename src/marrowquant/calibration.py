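"""Ratio <-> ion-concentration calibration.

The red/green emission ratio R of the SNARF-type pH probe follows a
sigmoidal titration curve

    pH = pKa + log10((R - R0) / (RM - R)) + log10(S_basic / S_acid)

with R0 the ratio at the acidic plateau (pH 5.6), RM the ratio at the basic
plateau (pH 9.0) and S_basic/S_acid the ratio of red emission at the two
plateaus.  The Rhod-5N/AF488 pair reports extracellular calcium through

    [Ca2+] = Keff * ((R - R0) / (RM - R)) ** (1 / h)

where Keff is the effective dissociation constant, RM the fitted maximum
ratio at saturating calcium and h the Hill slope (h = 1 recovers the simple
single-site isotherm).  A day-to-day reference adjustment rescales measured
ratios by a standard sample of known calcium concentration imaged with each
dye preparation:

    R_adj = R * (Rref1 / Rref2) * (Kd^-1 + Ca_ref1^-1) / (Kd^-1 + Ca_ref2^-1)

All fits are ordinary nonlinear least squares (scipy); confidence intervals
for the calcium fit come from a seeded parametric bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy import optimize


class RatioDomainError(ValueError):
    """Measured ratio outside the invertible domain of a calibration curve.

    Attributes
    ----------
    boundary : str
        Which boundary was crossed ("low" for R <= R0, "high" for R >= RM).
    """

    def __init__(self, msg: str, boundary: str):
        super().__init__(msg)
        self.boundary = boundary


@dataclass(frozen=True)
class PHCalibration:
    """Parameters of the sigmoidal pH titration curve."""

    pka: float = 7.5
    r0: float = 0.2          # ratio at the acidic plateau (pH 5.6)
    rm: float = 2.0          # ratio at the basic plateau (pH 9.0)
    s_basic_over_s_acid: float = 1.0
    residual_sd: float | None = None

    def __post_init__(self) -> None:
        if not (self.rm > self.r0 > 0):
            raise ValueError(f"need RM > R0 > 0, got R0={self.r0}, RM={self.rm}")
        if self.s_basic_over_s_acid <= 0:
            raise ValueError("S ratio must be positive")


@dataclass(frozen=True)
class CaCalibration:
    """Parameters of the calcium response curve (Hill-generalised isotherm)."""

    keff: float = 0.85       # mM
    r0: float = 0.2          # ratio at 0 mM calcium
    rm: float = 2.0          # fitted maximum ratio
    hill_slope: float = 1.0
    ci90: dict[str, tuple[float, float]] | None = None
    residual_sd: float | None = None

    def __post_init__(self) -> None:
        if not (self.rm > self.r0):
            raise ValueError(f"need RM > R0, got R0={self.r0}, RM={self.rm}")
        if self.keff <= 0 or self.hill_slope <= 0:
            raise ValueError("keff and hill_slope must be positive")


@dataclass(frozen=True)
class DayReference:
    """A standard-sample reading used for day-to-day ratio adjustment."""

    ratio_ref: float
    ca_ref: float            # mM, known concentration of the standard
    kd: float = 0.85         # mM, probe dissociation constant

    def __post_init__(self) -> None:
        if min(self.ratio_ref, self.ca_ref, self.kd) <= 0:
            raise ValueError("reference quantities must all be positive")


OutOfRange = Literal["raise", "nan", "clamp"]

_CLAMP_EPS = 1e-9


def _prepare_ratio(r, r0: float, rm: float, out_of_range: OutOfRange,
                   low_closed: bool):
    """Validate/clamp ratios against the open interval (r0, rm)."""
    r = np.asarray(r, dtype=float)
    low = (r < r0) if low_closed else (r <= r0)
    high = r >= rm
    if out_of_range == "raise":
        if np.any(low):
            raise RatioDomainError(
                f"ratio below calibration floor R0={r0}", boundary="low")
        if np.any(high):
            raise RatioDomainError(
                f"ratio at or above calibration ceiling RM={rm}", boundary="high")
    elif out_of_range == "clamp":
        span = rm - r0
        r = np.clip(r, r0 + _CLAMP_EPS * span if not low_closed else r0,
                    rm - _CLAMP_EPS * span)
    elif out_of_range == "nan":
        r = np.where(low | high, np.nan, r)
    else:  # pragma: no cover - guarded by Literal
        raise ValueError(f"unknown out_of_range mode {out_of_range!r}")
    return r


def ph_from_ratio(r, cal: PHCalibration, out_of_range: OutOfRange = "raise"):
    """Convert red/green ratio(s) to pH.  Requires R strictly in (R0, RM)."""
    r = _prepare_ratio(r, cal.r0, cal.rm, out_of_range, low_closed=False)
    with np.errstate(invalid="ignore", divide="ignore"):
        ph = (cal.pka
              + np.log10((r - cal.r0) / (cal.rm - r))
              + np.log10(cal.s_basic_over_s_acid))
    return ph if ph.ndim else float(ph)


def ratio_from_ph(ph, cal: PHCalibration):
    """Inverse of :func:`ph_from_ratio` (algebraic solution)."""
    ph = np.asarray(ph, dtype=float)
    q = 10.0 ** (ph - cal.pka - np.log10(cal.s_basic_over_s_acid))
    r = (cal.r0 + cal.rm * q) / (1.0 + q)
    return r if r.ndim else float(r)


def ca_from_ratio(r, cal: CaCalibration, out_of_range: OutOfRange = "raise"):
    """Convert red/green ratio(s) to [Ca2+] in mM.

    Strictly increasing on [R0, RM); diverges as R approaches RM (probe
    saturation).  R = R0 maps to 0 mM.
    """
    r = _prepare_ratio(r, cal.r0, cal.rm, out_of_range, low_closed=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        q = (r - cal.r0) / (cal.rm - r)
        ca = cal.keff * q ** (1.0 / cal.hill_slope)
    return ca if ca.ndim else float(ca)


def ratio_from_ca(ca, cal: CaCalibration):
    """Inverse of :func:`ca_from_ratio`."""
    ca = np.asarray(ca, dtype=float)
    if np.any(ca < 0):
        raise ValueError("calcium concentration must be non-negative")
    u = (ca / cal.keff) ** cal.hill_slope
    r = (cal.r0 + cal.rm * u) / (1.0 + u)
    return r if r.ndim else float(r)


def day_adjust_ratio(ratio_m, ref1: DayReference, ref2: DayReference):
    """Adjust a measured ratio for day-to-day dye-preparation drift.

    With identical references the adjustment is the identity.
    """
    factor = (ref1.ratio_ref / ref2.ratio_ref) * (
        (1.0 / ref1.kd + 1.0 / ref1.ca_ref)
        / (1.0 / ref2.kd + 1.0 / ref2.ca_ref)
    )
    return ratio_m * factor


# ---------------------------------------------------------------------------
# curve fitting
# ---------------------------------------------------------------------------

def _as_level_ratio(table) -> tuple[np.ndarray, np.ndarray]:
    """Accept a DataFrame with (level|ph|ca, ratio) columns or two arrays."""
    if isinstance(table, pd.DataFrame):
        level_col = next(c for c in ("level", "ph", "ca") if c in table.columns)
        return (table[level_col].to_numpy(dtype=float),
                table["ratio"].to_numpy(dtype=float))
    level, ratio = table
    return np.asarray(level, dtype=float), np.asarray(ratio, dtype=float)


def fit_ph_calibration(table, s_basic_over_s_acid: float = 1.0) -> PHCalibration:
    """Fit the pH titration curve to (pH, ratio) replicates.

    The spectral term log10(S_basic/S_acid) is perfectly confounded with pKa
    in the titration model, so the S ratio is taken as a known constant
    (measured separately from the plateau emissions) and pKa, R0, RM are
    fitted.  Requires ratios at >= 4 distinct pH levels spanning the sigmoid.
    """
    ph, ratio = _as_level_ratio(table)
    if len(np.unique(ph)) < 4:
        raise ValueError("need >= 4 distinct pH levels to fit the sigmoid")

    def model(x, pka, r0, rm):
        cal = PHCalibration(pka=pka, r0=r0, rm=rm,
                            s_basic_over_s_acid=s_basic_over_s_acid)
        return np.asarray(ratio_from_ph(x, cal))

    rmin, rmax = ratio.min(), ratio.max()
    span = max(rmax - rmin, 1e-6)
    p0 = (float(np.median(ph)), max(rmin - 0.05 * span, 1e-6), rmax + 0.05 * span)
    try:
        popt, _ = optimize.curve_fit(
            model, ph, ratio, p0=p0,
            bounds=([0.0, 1e-9, 1e-9], [14.0, np.inf, np.inf]), maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"pH calibration fit did not converge: {exc}") from exc
    resid = ratio - model(ph, *popt)
    return PHCalibration(pka=float(popt[0]), r0=float(popt[1]), rm=float(popt[2]),
                         s_basic_over_s_acid=s_basic_over_s_acid,
                         residual_sd=float(np.std(resid)))


def _fit_ca_once(ca: np.ndarray, ratio: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    def model(x, keff, r0, rm, hill):
        cal = CaCalibration(keff=keff, r0=r0, rm=max(rm, r0 + 1e-9),
                            hill_slope=hill)
        return np.asarray(ratio_from_ca(x, cal))

    rmin, rmax = ratio.min(), ratio.max()
    span = max(rmax - rmin, 1e-6)
    p0 = (max(float(np.median(ca[ca > 0])), 1e-3),
          max(rmin, 1e-6), rmax + 0.1 * span, 1.0)
    popt, _ = optimize.curve_fit(
        model, ca, ratio, p0=p0,
        bounds=([1e-6, 1e-9, 1e-9, 0.05], [1e3, np.inf, np.inf, 20.0]),
        maxfev=40000)
    resid = ratio - model(ca, *popt)
    return popt, resid


def fit_ca_calibration(table, ph_labels=None, joint: bool = True,
                       n_boot: int = 200, seed: int = 0,
                       ci: bool = True) -> CaCalibration | dict:
    """Fit the calcium response curve, with Hill slope, to ([Ca2+], ratio) data.

    Parameters
    ----------
    table
        DataFrame with columns (level|ca, ratio) or a (ca, ratio) array pair.
        Needs >= 5 distinct concentration levels including 0 mM and a
        near-saturating level.
    ph_labels
        Optional per-row pH labels.  With ``joint=True`` (default, matching
        the pooled dashed-line calibration) all labels are fitted together;
        otherwise a dict of per-label fits is returned.
    n_boot, seed, ci
        Parametric-bootstrap settings for the 90% confidence intervals.
    """
    ca, ratio = _as_level_ratio(table)
    if ph_labels is not None and not joint:
        labels = np.asarray(ph_labels)
        return {lab: fit_ca_calibration((ca[labels == lab], ratio[labels == lab]),
                                        n_boot=n_boot, seed=seed, ci=ci)
                for lab in np.unique(labels)}

    levels = np.unique(ca)
    if len(levels) < 5:
        raise ValueError("need >= 5 distinct calcium levels")
    if levels.min() > 0:
        raise ValueError("calibration series must include the 0 mM level")

    try:
        popt, resid = _fit_ca_once(ca, ratio)
    except RuntimeError as exc:
        raise RuntimeError(f"calcium calibration fit did not converge: {exc}") from exc
    residual_sd = float(np.std(resid))

    ci90 = None
    if ci and residual_sd > 0 and n_boot > 0:
        rng = np.random.default_rng(seed)
        cal_hat = CaCalibration(keff=popt[0], r0=popt[1], rm=popt[2],
                                hill_slope=popt[3])
        fitted = np.asarray(ratio_from_ca(ca, cal_hat))
        draws = []
        for _ in range(n_boot):
            sim = fitted + rng.normal(0.0, residual_sd, size=fitted.shape)
            try:
                p, _ = _fit_ca_once(ca, sim)
                draws.append(p)
            except RuntimeError:
                continue
        if len(draws) >= max(20, n_boot // 4):
            draws = np.asarray(draws)
            names = ("keff", "r0", "rm", "hill_slope")
            ci90 = {n: (float(np.percentile(draws[:, i], 5)),
                        float(np.percentile(draws[:, i], 95)))
                    for i, n in enumerate(names)}
        else:
            warnings.warn("bootstrap mostly failed to converge; CI omitted")

    return CaCalibration(keff=float(popt[0]), r0=float(popt[1]),
                         rm=float(popt[2]), hill_slope=float(popt[3]),
                         ci90=ci90, residual_sd=residual_sd)


def propagate_ratio_uncertainty(r: float, sd_r: float, cal: CaCalibration
                                ) -> dict[str, float | bool]:
    """Map a ratio +/- one SD through the calcium conversion.

    Because the conversion is convex (steeply so near RM), the interval is
    asymmetric about the point estimate except in the near-linear low-calcium
    regime.  If the upper ratio bound reaches RM the interval is one-sided.
    """
    if sd_r < 0:
        raise ValueError("sd_r must be non-negative")
    point = ca_from_ratio(r, cal)
    lo = ca_from_ratio(max(r - sd_r, cal.r0), cal)
    one_sided = (r + sd_r) >= cal.rm
    hi = np.inf if one_sided else ca_from_ratio(r + sd_r, cal)
    return {"low": float(lo), "point": float(point), "high": float(hi),
            "one_sided": bool(one_sided)}
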