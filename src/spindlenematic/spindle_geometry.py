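"""Pole-indented tactoid geometry: construction, boundary extraction, fitting.

The MII-oocyte spindle silhouette is modelled as a *pole-indented tactoid*:
the lens bounded by two convex circle arcs that intersect at the virtual
poles (+-l0, 0) and reach apex height r_belt at x = 0, with a concave
spherical "bite" of radius r_cap carved out around each virtual pole.  The
planar boundary therefore consists of four circle arcs; revolving it about
the long axis gives the 3D body used for rendering and volume bookkeeping.

Conventions
-----------
l0      virtual-pole half-spacing (um)        [the paper-style L0]
r_belt  belt half-width / apex height (um)    [R0]
r_cap   polar-cap (indentation) radius (um)   [r0]

The convex ("belt") circle has center (0, c) with
c = (r_belt**2 - l0**2) / (2 r_belt) and radius R_c = sqrt(l0**2 + c**2);
the cap circles have radius r_cap and centers (+-l0, 0).  The curve is
mirror symmetric about both axes, passes through (0, +-r_belt) and through
the pole tips (+-(l0 - r_cap), 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .exceptions import FitFailureError, InvalidGeometryError, LowContrastError

__all__ = [
    "BoundaryCurve",
    "PoleIndentedTactoid",
    "belt_circle",
    "tactoid_junction",
    "tactoid_cap_angle",
    "tactoid_boundary_radius",
    "tactoid_cross_section",
    "extract_boundary",
    "fit_tactoid",
    "pool_tactoids",
]


# ---------------------------------------------------------------- geometry

def belt_circle(l0, r_belt):
    """Center height c and radius R_c of the convex belt circle."""
    if l0 <= 0 or r_belt <= 0:
        raise InvalidGeometryError("l0 and r_belt must be positive")
    c = (r_belt**2 - l0**2) / (2.0 * r_belt)
    return c, np.hypot(l0, c)


def tactoid_junction(l0, r_belt, r_cap):
    """Intersection (x*, y*) of the belt circle with the +x cap circle.

    Raises :class:`InvalidGeometryError` when the arcs do not intersect
    in the upper half plane (no valid pole-indented tactoid).
    """
    if not (0 < r_cap < l0):
        raise InvalidGeometryError("need 0 < r_cap < l0")
    c, rc = belt_circle(l0, r_belt)
    disc = 4.0 * rc**2 - r_cap**2
    if disc <= 0:
        raise InvalidGeometryError("cap circle does not intersect the belt arc")
    y = (c * r_cap**2 + r_cap * l0 * np.sqrt(disc)) / (2.0 * rc**2)
    if y <= 0:
        raise InvalidGeometryError("cap/belt junction not in the upper half plane")
    x = (2.0 * l0**2 - r_cap**2 + 2.0 * c * y) / (2.0 * l0)
    if not (0 < x < l0):
        raise InvalidGeometryError("cap swallows the belt arc")
    return float(x), float(y)


def tactoid_cap_angle(l0, r_belt, r_cap):
    """Polar angle of the cap/belt junction seen from the origin."""
    xj, yj = tactoid_junction(l0, r_belt, r_cap)
    return float(np.arctan2(yj, xj))


def tactoid_boundary_radius(phi, l0, r_belt, r_cap):
    """Boundary radius b(phi) of the pole-indented tactoid (star-shaped
    about the origin for all admissible parameters)."""
    phi = np.asarray(phi, dtype=float)
    c, _ = belt_circle(l0, r_belt)
    phi_j = tactoid_cap_angle(l0, r_belt, r_cap)
    # fold into [0, pi/2] using the double mirror symmetry
    psi = np.abs(np.arctan2(np.sin(phi), np.cos(phi)))
    psi = np.where(psi > np.pi / 2, np.pi - psi, psi)
    cosp, sinp = np.cos(psi), np.sin(psi)
    with np.errstate(invalid="ignore"):
        b_cap = l0 * cosp - np.sqrt(l0**2 * cosp**2 - l0**2 + r_cap**2)
    b_conv = c * sinp + np.sqrt(c**2 * sinp**2 + l0**2)
    out = np.where(psi < phi_j, b_cap, b_conv)
    return out if out.ndim else float(out)


def tactoid_cross_section(x, l0, r_belt, r_cap):
    """Outer and inner radii of the revolved body at axial position x.

    The 3D spindle is the revolved belt lens minus balls of radius r_cap
    at the virtual poles, so near the poles cross-sections are annuli.
    Returns ``(outer, inner)`` arrays (um); the solid part is
    inner < sqrt(y^2+z^2) < outer, empty where outer <= inner.
    """
    x = np.asarray(x, dtype=float)
    c, rc = belt_circle(l0, r_belt)
    with np.errstate(invalid="ignore"):
        outer = np.sqrt(np.clip(rc**2 - x**2, 0.0, None)) + c
    outer = np.clip(outer, 0.0, None)
    outer = np.where(np.abs(x) > l0, 0.0, outer)
    inner = np.sqrt(np.clip(r_cap**2 - (np.abs(x) - l0) ** 2, 0.0, None))
    return outer, inner


# ------------------------------------------------------------- data types

@dataclass
class BoundaryCurve:
    """Polar samples of an extracted spindle boundary.

    phi are polar angles (rad) about ``center`` (um, image frame);
    radius are boundary radii (um).  Bins where no gradient maximum was
    found are absent.
    """

    phi: np.ndarray
    radius: np.ndarray
    center: tuple[float, float] = (0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        if np.any(self.radius <= 0):
            raise ValueError("boundary radii must be positive")


@dataclass
class PoleIndentedTactoid:
    """Fitted pole-indented tactoid parameters (um)."""

    l0: float
    r_belt: float
    r_cap: float
    rms: float = np.nan
    degenerate: bool = False

    def boundary_radius(self, phi):
        return tactoid_boundary_radius(phi, self.l0, self.r_belt, self.r_cap)


# ------------------------------------------------- boundary extraction

def extract_boundary(mean_retardance, pixel_size, *, blur_um=1.0, n_phi=360,
                     max_fail_frac=0.10):
    """Locate the spindle boundary on a time-averaged retardance image.

    The background (median of the four 5x5-pixel corners) is subtracted,
    the image Gaussian-filtered (radius ``blur_um``), and for each polar
    angle bin the boundary radius is the radial position of the maximum
    gradient magnitude along the ray from the spindle center.

    Raises :class:`LowContrastError` if more than ``max_fail_frac`` of the
    bins have no gradient maximum above the noise floor.
    """
    img = np.asarray(mean_retardance, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D image")
    corners = np.concatenate([
        img[:5, :5].ravel(), img[:5, -5:].ravel(),
        img[-5:, :5].ravel(), img[-5:, -5:].ravel(),
    ])
    img = img - np.median(corners)
    sigma = blur_um / pixel_size
    sm = ndimage.gaussian_filter(img, sigma)
    gy, gx = np.gradient(sm)
    grad = np.hypot(gx, gy)

    # intensity-weighted center of the bright half-maximum region
    mask = sm > 0.5 * sm.max()
    if not np.any(mask):
        raise LowContrastError("no pixels above half maximum")
    ii, jj = np.nonzero(mask)
    w = sm[mask]
    ci = float(np.sum(ii * w) / np.sum(w))
    cj = float(np.sum(jj * w) / np.sum(w))

    gcorners = np.concatenate([
        grad[:8, :8].ravel(), grad[:8, -8:].ravel(),
        grad[-8:, :8].ravel(), grad[-8:, -8:].ravel(),
    ])
    floor = max(float(gcorners.mean() + 5.0 * gcorners.std()), 1e-12)

    h, wid = grad.shape
    r_max = np.hypot(h, wid) / 2
    rs = np.arange(1.0, r_max, 0.5)
    phis = np.linspace(-np.pi, np.pi, n_phi, endpoint=False) + np.pi / n_phi
    ok_phi, ok_r = [], []
    for phi in phis:
        pi_ = ci + rs * np.sin(phi)
        pj_ = cj + rs * np.cos(phi)
        prof = ndimage.map_coordinates(grad, [pi_, pj_], order=1,
                                       mode="constant", cval=0.0)
        k = int(np.argmax(prof))
        if prof[k] <= floor or k == 0 or k == len(rs) - 1:
            continue
        # parabolic sub-sample refinement of the gradient maximum
        y0, y1, y2 = prof[k - 1], prof[k], prof[k + 1]
        denom = y0 - 2 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        ok_phi.append(phi)
        ok_r.append((rs[k] + np.clip(delta, -1, 1) * 0.5) * pixel_size)
    if len(ok_phi) < n_phi * (1.0 - max_fail_frac):
        raise LowContrastError(
            f"boundary found in only {len(ok_phi)}/{n_phi} angle bins"
        )
    return BoundaryCurve(np.asarray(ok_phi), np.asarray(ok_r),
                         center=(cj * pixel_size, ci * pixel_size),
                         meta={"blur_um": blur_um, "pixel_size": pixel_size})


# ------------------------------------------------------------ tactoid fit

def _assign_and_fit(xa, ya, phi_fold, l0, cap_init_deg=25.0, max_iter=50):
    """Iterated sector assignment + algebraic circle fits at fixed l0.

    Points are folded into the first quadrant (xa, ya >= 0).  Returns
    (sse, c, r_cap, cap_mask) or None when a class empties / no
    convergence.
    """
    cap = phi_fold < np.deg2rad(cap_init_deg)
    for _ in range(max_iter):
        conv = ~cap
        if cap.sum() < 2 or conv.sum() < 3:
            return None
        # belt circle through (+-l0, 0), center (0, c):  x^2+y^2-2cy = l0^2
        yc, rr = ya[conv], xa[conv] ** 2 + ya[conv] ** 2
        denom = 2.0 * np.sum(yc**2)
        if denom <= 0:
            return None
        c = float(np.sum(yc * (rr - l0**2)) / denom)
        r_cap = float(np.mean(np.hypot(xa[cap] - l0, ya[cap])))
        rc = np.hypot(l0, c)
        res_conv = np.abs(np.hypot(xa, ya - c) - rc)
        res_cap = np.abs(np.hypot(xa - l0, ya) - r_cap)
        new_cap = res_cap < res_conv
        if np.array_equal(new_cap, cap):
            sse = float(np.sum(np.minimum(res_conv, res_cap) ** 2))
            return sse, c, r_cap, cap
        cap = new_cap
    raise FitFailureError("sector assignment did not converge")


def fit_tactoid(boundary, *, symmetric=True):
    """Fit a pole-indented tactoid to a polar boundary curve.

    Mirror symmetry about both axes is enforced: all samples are folded
    into the first quadrant, the belt circle is constrained to pass
    through (+-l0, 0) with its center on the y-axis, and the caps are
    circles of radius r_cap centered at (+-l0, 0).  The fit is nested:
    algebraic circle fits with iterated convex/cap sector assignment
    inside, a deterministic 1D search over l0 outside.

    Returns a :class:`PoleIndentedTactoid`; ``degenerate`` is set (with a
    warning) when the fitted caps collapse (r_cap/l0 outside [0.05, 0.95]),
    as happens for cap-free shapes such as circles or ellipses.
    """
    phi = np.asarray(boundary.phi, dtype=float)
    b = np.asarray(boundary.radius, dtype=float)
    x, y = b * np.cos(phi), b * np.sin(phi)
    xa, ya = np.abs(x), np.abs(y)
    phi_fold = np.arctan2(ya, xa)  # in [0, pi/2]
    if not symmetric:
        warnings.warn("asymmetric fitting not implemented; folding anyway")

    b_max = float(b.max())

    def solve(l0):
        """Best converged assignment over several cap-seed widths: thin
        polar caps need a narrow seed, fat caps a wide one."""
        best = None
        for init_deg in (5.0, 15.0, 25.0, 45.0):
            try:
                out = _assign_and_fit(xa, ya, phi_fold, l0, init_deg)
            except FitFailureError:
                continue
            if out is not None and (best is None or out[0] < best[0]):
                best = out
        return best

    def objective(l0):
        out = solve(l0)
        return np.inf if out is None else out[0]

    l0_grid = np.linspace(1.02 * b_max, 4.0 * b_max, 80)
    sse_grid = np.array([objective(l0) for l0 in l0_grid])
    if not np.any(np.isfinite(sse_grid)):
        raise FitFailureError("no admissible l0 found")
    k = int(np.argmin(sse_grid))
    lo = l0_grid[max(k - 1, 0)]
    hi = l0_grid[min(k + 1, len(l0_grid) - 1)]
    res = optimize.minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-4 * b_max})
    l0 = float(res.x)
    if objective(l0) > sse_grid[k]:
        l0 = float(l0_grid[k])
    out = solve(l0)
    if out is None:
        raise FitFailureError("fit collapsed at optimal l0")
    sse, c, r_cap, _ = out
    r_belt = float(np.hypot(l0, c) + c)
    rms = float(np.sqrt(sse / len(b)))
    # a boundary that a plain circle fits as well as the four-arc model
    # has no resolvable polar caps (circles/ellipses are the r_cap -> 0
    # degeneration of the model family)
    circle_rms = float(np.std(b))
    degenerate = (not (0.05 * l0 < r_cap < 0.95 * l0) or r_belt <= 0
                  or circle_rms <= max(2.0 * rms, 1e-9 * b_max))
    if degenerate:
        warnings.warn(
            "tactoid fit degenerate (caps collapsed); boundary is probably "
            "not pole-indented", stacklevel=2)
        return PoleIndentedTactoid(l0, r_belt, r_cap, rms, degenerate=True)
    try:
        tactoid_junction(l0, r_belt, r_cap)
    except InvalidGeometryError as exc:
        raise FitFailureError(f"fitted arcs do not intersect: {exc}") from exc
    return PoleIndentedTactoid(l0, r_belt, r_cap, rms)


# ---------------------------------------------------------------- pooling

@dataclass
class NormalizedTactoid:
    """Population-average tactoid in l0 = 1 units."""

    r_belt_ratio: float
    r_cap_ratio: float
    r_belt_se: float
    r_cap_se: float
    n: int


def pool_tactoids(fits):
    """Rescale each fit by its own l0 and average over spindles.

    Returns a :class:`NormalizedTactoid` with the mean and standard error
    of r_belt/l0 and r_cap/l0 (l0 = 1 by construction).  With a single
    fit the ratios pass through and the SEs are NaN.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to pool")
    rb = np.array([f.r_belt / f.l0 for f in fits])
    rc = np.array([f.r_cap / f.l0 for f in fits])
    n = len(fits)
    if n == 1:
        return NormalizedTactoid(float(rb[0]), float(rc[0]), np.nan, np.nan, 1)
    return NormalizedTactoid(
        float(rb.mean()), float(rc.mean()),
        float(rb.std(ddof=1) / np.sqrt(n)), float(rc.std(ddof=1) / np.sqrt(n)), n,
    )
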