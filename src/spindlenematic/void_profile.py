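"""Axial density inversion and average void shape from retardance.

For a spindle whose long axis lies in the image plane, the time-averaged
retardance column at axial position x_i is the Abel-type projection of a
(locally uniform) cross-sectional density through a disk of radius R(x_i):

    r_pred(x_i, y) = 2 * A0 * rho_x(x_i) * sqrt(R(x_i)^2 - y^2)

Fitting each column yields the relative density profile rho_x(x) (the
local spindle radius R(x) comes along for free and doubles as a cross
check of the boundary fit).  Attributing all density missing from the
central spindle to n_chr identical, in-phase voids converts 1 - rho_x(x)
into an average per-void width profile, which is then fitted by a circle
arc of chord beta, giving the equivalent waist diameter (the geometric
mean sqrt(a*b) of an elliptical cross section).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .synthetic_data import circle_arc_width

__all__ = ["DensityProfile", "VoidShape", "fit_cross_sections",
           "void_fractions", "void_width_profile"]

_UNIT = 1e-3  # nm^2 * um^-2 * um -> nm


@dataclass
class DensityProfile:
    """Relative cross-sectional density vs axial position."""

    x: np.ndarray             # um, spindle frame
    rho: np.ndarray           # normalized to [0, 1], 1 = void-free
    rho_raw: np.ndarray       # um^-2, before normalization
    radius: np.ndarray        # fitted R(x), um
    resid: np.ndarray         # per-column rms fit residual, nm
    skipped: np.ndarray       # columns dropped (too few valid pixels)
    meta: dict = field(default_factory=dict)


@dataclass
class VoidShape:
    """Average void profile summary."""

    waist: float              # equivalent diameter at the plate, um
    beta: float               # circle-arc chord length, um
    x: np.ndarray             # sample positions, um
    d_void: np.ndarray        # measured per-void width profile, um
    d_fit: np.ndarray         # fitted circle-arc profile, um


def _semicircle(y, amp, radius):
    return amp * np.sqrt(np.clip(radius**2 - y**2, 0.0, None))


def _fit_column_free(yy, rr, pixel_size):
    """Unconstrained least-squares fit of one column: both the amplitude
    and the radius free (the straightforward reading of the projected-
    disk form).  The radius couples to interior density structure: a
    central deficit flattens the profile and inflates R."""
    r_init = max((yy.max() - yy.min()) / 2, pixel_size)
    popt, _ = curve_fit(_semicircle, yy, rr,
                        p0=[rr.max() / r_init, 1.05 * r_init],
                        bounds=([0, 0.3 * r_init], [np.inf, 3.0 * r_init]),
                        maxfev=2000)
    return float(popt[0]), float(popt[1])


def _fit_column_support(col, y, *, smooth_px=1.2, thr_frac=0.10):
    """Support-based column fit: the radius from the (sub-pixel) edge of
    the suprathreshold region — unaffected by where inside the cross
    section the density is missing — and the amplitude from the column
    integral, which recovers the *mean* cross-sectional density exactly
    for any void arrangement.  The sqrt-shaped edge makes the threshold
    crossing sit slightly inside R; a two-pass correction removes it."""
    from scipy import ndimage

    sm = ndimage.gaussian_filter1d(col, smooth_px)
    thr = thr_frac * sm.max()
    ipk = int(np.argmax(sm))
    above = sm > thr
    lo = ipk
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = ipk
    while hi < len(sm) - 1 and above[hi + 1]:
        hi += 1

    def crossing(i, d):
        j = i + d
        if not (0 <= j < len(sm)) or sm[i] == sm[j]:
            return y[i]
        return y[i] + (y[j] - y[i]) * (sm[i] - thr) / (sm[i] - sm[j])

    half = (crossing(hi, 1) - crossing(lo, -1)) / 2.0
    if half <= 0:
        raise RuntimeError("degenerate column support")
    integ = float(np.trapezoid(np.clip(col, 0, None), y))
    radius = half
    for _ in range(3):
        amp = integ / ((np.pi / 2.0) * radius**2)
        radius = half + (thr / amp) ** 2 / (2.0 * half)
    amp = integ / ((np.pi / 2.0) * radius**2)
    return float(amp), float(radius)


def fit_cross_sections(mean_ret, pixel_size, *, a0=7.5, center=None,
                       x_range=None, min_pixels=5, rel_threshold=0.05,
                       radius_mode="support"):
    """Fit every retardance column to the projected-disk form.

    Parameters
    ----------
    mean_ret : 2D time-averaged retardance (nm), registered, spindle
        horizontal.
    pixel_size : um.
    a0 : per-microtubule retardance constant (nm^2).
    center : (cx, cy) um relative to the image center; default (0, 0).
    x_range : optional (lo, hi) um restricting the fitted columns, e.g.
        to exclude the annular pole-cap region where the filled-disk
        projection no longer applies.
    min_pixels : columns with fewer valid (suprathreshold) pixels are
        skipped and flagged.
    radius_mode : 'support' (default) estimates R from the column's
        suprathreshold extent and the density from the column integral,
        which is unbiased for any interior void arrangement; 'free'
        fits (amplitude, R) jointly by least squares, the naive reading
        of the model, whose R inflates slightly over density deficits.

    Returns a :class:`DensityProfile` with rho normalized by the mean of
    its top decile (the near-pole plateau), then clipped to [0, 1].
    """
    img = np.asarray(mean_ret, float)
    h, w = img.shape
    cx, cy = center if center is not None else (0.0, 0.0)
    x = (np.arange(w) + 0.5 - w / 2) * pixel_size - cx
    y = (np.arange(h) + 0.5 - h / 2) * pixel_size - cy
    gmax = img.max()
    cols, rhos, radii, resids, skipped = [], [], [], [], []
    for j in range(w):
        if x_range is not None and not (x_range[0] <= x[j] <= x_range[1]):
            continue
        col = img[:, j]
        valid = col > rel_threshold * gmax
        if valid.sum() < min_pixels:
            if col.max() > rel_threshold * gmax:
                skipped.append(x[j])
            continue
        yy, rr = y[valid], col[valid]
        try:
            if radius_mode == "support":
                amp, radius = _fit_column_support(col, y)
            else:
                amp, radius = _fit_column_free(yy, rr, pixel_size)
        except RuntimeError:
            skipped.append(x[j])
            continue
        cols.append(x[j])
        rhos.append(amp / (2.0 * a0 * _UNIT))
        radii.append(radius)
        resids.append(float(np.sqrt(np.mean(
            (rr - _semicircle(yy, amp, radius)) ** 2))))
    if not cols:
        raise ValueError("no fittable columns")
    xs = np.asarray(cols)
    rho_raw = np.asarray(rhos)
    k = max(1, len(rho_raw) // 10)
    ref = np.sort(rho_raw)[-k:].mean()
    rho = np.clip(rho_raw / ref, 0.0, 1.0)
    return DensityProfile(xs, rho, rho_raw, np.asarray(radii),
                          np.asarray(resids), np.asarray(skipped),
                          meta={"a0": a0, "norm_ref": float(ref)})


def void_fractions(profile):
    """(volume fraction, plate-area fraction) taken up by voids.

    Plate-area fraction is the missing density at the metaphase plate,
    1 - rho_x(0); the volume fraction attributes all missing density to
    voids: 1 - sum rho_x pi R^2 / sum pi R^2 over the profiled columns.
    """
    if profile.rho.max() > 1.0 + 1e-9:
        raise ValueError("profile is not normalized")
    i0 = int(np.argmin(np.abs(profile.x)))
    plate = float(1.0 - profile.rho[i0])
    w = np.pi * profile.radius**2
    volume = float(1.0 - np.sum(profile.rho * w) / np.sum(w))
    return volume, plate


def void_width_profile(profile, n_chr=20):
    """Average void shape from the missing-density attribution.

    The per-void missing area at x is [1 - rho_x(x)] pi R(x)^2 / n_chr;
    its effective diameter d_void(x) = 2 sqrt(A_void / pi) is fitted to
    the width profile of a circle arc of chord beta, yielding the waist
    (diameter at x = 0) and beta.
    """
    missing = (1.0 - profile.rho) * np.pi * profile.radius**2 / n_chr
    if np.any(missing < -1e-9):
        warnings.warn("negative missing area clipped to zero")
    missing = np.clip(missing, 0.0, None)
    d = 2.0 * np.sqrt(missing / np.pi)
    x = profile.x
    # fit over the contiguous positive region around the plate
    pos = d > 0.02 * d.max()
    i0 = int(np.argmin(np.abs(x)))
    lo = i0
    while lo > 0 and pos[lo - 1]:
        lo -= 1
    hi = i0
    while hi < len(d) - 1 and pos[hi + 1]:
        hi += 1
    xs, ds = x[lo:hi + 1], d[lo:hi + 1]
    if len(xs) < 5:
        raise ValueError("void region too small to fit")
    w0 = float(d[i0])
    b0 = float(xs[-1] - xs[0])
    popt, _ = curve_fit(lambda xi, w, b: circle_arc_width(xi, w, b), xs, ds,
                        p0=[w0, max(b0, 4 * w0)],
                        bounds=([0.2 * w0, 2 * w0], [5 * w0, np.inf]),
                        maxfev=5000)
    waist, beta = float(popt[0]), float(popt[1])
    return VoidShape(waist, beta, xs, ds, circle_arc_width(xs, waist, beta))
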