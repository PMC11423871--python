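"""Circle-arc nematic director model of the spindle interior.

In a tactoid-shaped nematic droplet with strong (tangential on the convex
surface, normal on the polar caps) anchoring, the director inside the
droplet lies tangent to the unique family of circle arcs through the two
virtual poles at (+-L0, 0).  This module provides that model field, the
anchoring-angle prediction on the fitted boundary, nematically correct
angle averaging, the odd-symmetric quadrant fold used when pooling
spindles, and rms model-vs-data residuals.

All angles are nematic: theta and theta + pi are the same state.  Angle
arithmetic therefore happens in the doubled-angle representation
exp(2i*theta); the nematic distance between two angles is
d(t1, t2) = |arg exp(2i(t1 - t2))| / 2, which lies in [0, pi/2].
"""

from __future__ import annotations

import numpy as np

from .exceptions import DegenerateAverageError, GridError, SingularPointError

__all__ = [
    "wrap_nematic",
    "nematic_distance",
    "theta_arcs",
    "anchoring_angle",
    "nematic_mean",
    "symmetrize_quadrant",
    "model_residual",
    "rescaled_profile",
]


def wrap_nematic(theta):
    """Reduce angles to the principal nematic branch [-pi/2, pi/2)."""
    return np.mod(np.asarray(theta, dtype=float) + np.pi / 2, np.pi) - np.pi / 2


def nematic_distance(t1, t2):
    """Nematic angular distance |arg e^{2i(t1-t2)}|/2, in [0, pi/2]."""
    d = np.angle(np.exp(2j * (np.asarray(t1, float) - np.asarray(t2, float))))
    return np.abs(d) / 2


def theta_arcs(x, y, l0, *, pole_tol=1e-9):
    """Nematic angle of the circle-arc director field at (x, y).

    The unique circle through (x, y), (l0, 0) and (-l0, 0) has its center
    at (0, c) with c = (x^2 + y^2 - l0^2) / (2 y); the director is the
    tangent of that circle.  On the axis (y = 0) the limit is theta = 0.

    Parameters
    ----------
    x, y : array_like
        Coordinates in the spindle frame (um or any common unit).
    l0 : float
        Virtual-pole half-spacing (> 0).

    Raises
    ------
    SingularPointError
        If any query point coincides with a virtual pole (+-l0, 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if l0 <= 0:
        raise ValueError("l0 must be positive")
    at_pole = (np.abs(np.abs(x) - l0) < pole_tol) & (np.abs(y) < pole_tol)
    if np.any(at_pole):
        raise SingularPointError("director field is singular at the virtual poles")
    on_axis = np.abs(y) < pole_tol
    y_safe = np.where(on_axis, 1.0, y)
    c = (x**2 + y**2 - l0**2) / (2.0 * y_safe)
    # tangent direction (y - c, -x), perpendicular to the radius vector
    theta = np.arctan2(-x, y - c)
    theta = np.where(on_axis, 0.0, theta)
    return wrap_nematic(theta)


def anchoring_angle(phi, tactoid):
    """Predicted boundary angle eta(phi) of a pole-indented tactoid.

    On the convex sectors the director is tangent to the boundary; on the
    concave polar caps it is normal to it (i.e. radial from the cap
    center at (+-l0, 0)).  Both are nematic angles.

    Parameters
    ----------
    phi : array_like
        Polar angle(s) about the spindle center, any real value.
    tactoid : object
        Anything exposing ``l0, r0, rr0`` tactoid attributes, e.g.
        :class:`spindlenematic.spindle_geometry.PoleIndentedTactoid` or
        a plain namespace with ``l0``, ``r0_cap``, ``r0_belt``.
    """
    from .spindle_geometry import tactoid_boundary_radius, tactoid_cap_angle

    phi = np.asarray(phi, dtype=float)
    l0, r_belt, r_cap = _tactoid_params(tactoid)
    b = tactoid_boundary_radius(phi, l0, r_belt, r_cap)
    px = b * np.cos(phi)
    py = b * np.sin(phi)
    phi_j = tactoid_cap_angle(l0, r_belt, r_cap)
    folded = np.abs(wrap_pi(phi))
    on_cap = (folded < phi_j) | (folded > np.pi - phi_j)
    pole_sign = np.where(np.cos(phi) >= 0, 1.0, -1.0)
    # cap: normal passes through the cap center (sign*l0, 0)
    eta_cap = np.arctan2(py, px - pole_sign * l0)
    # convex: tangent of the belt circle (center (0, c))
    c = (r_belt**2 - l0**2) / (2.0 * r_belt)
    eta_conv = np.arctan2(-px, py - c)
    return wrap_nematic(np.where(on_cap, eta_cap, eta_conv))


def wrap_pi(angle):
    """Reduce angles to (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(angle, float), 2 * np.pi)


def _tactoid_params(tactoid):
    return float(tactoid.l0), float(tactoid.r_belt), float(tactoid.r_cap)


def nematic_mean(angles, *, tol=1e-9):
    """Nematic average (1/2) arg sum_j exp(2 i theta_j).

    Respects the theta ~ theta + pi equivalence: the mean of {0, pi} is 0,
    not pi/2.  Raises :class:`DegenerateAverageError` when the doubled-angle
    resultant is numerically zero (e.g. {pi/4, 3pi/4}).
    """
    angles = np.asarray(angles, dtype=float).ravel()
    if angles.size == 0:
        raise ValueError("need at least one angle")
    z = np.exp(2j * angles).sum()
    if np.abs(z) / angles.size < tol:
        raise DegenerateAverageError(
            "doubled-angle resultant is zero; nematic mean undefined"
        )
    return float(wrap_nematic(0.5 * np.angle(z)))


def symmetrize_quadrant(field):
    """Fold a centered angle field into its first quadrant using the
    odd symmetry theta(-x, y) = theta(x, -y) = -theta(x, y).

    For a grid point (x1, y1) in the first quadrant the returned value is

        [theta(x1, y1) - theta(x1, -y1) - theta(-x1, y1) + theta(-x1, -y1)] / 4

    The grid must have even dimensions with the symmetry center between
    the four central pixels (pixel-center convention), so each pixel has
    exact mirror partners.

    Returns the first-quadrant array with shape (H//2, W//2), row index
    increasing with y and column index increasing with x.
    """
    f = np.asarray(field, dtype=float)
    if f.ndim != 2 or f.shape[0] % 2 or f.shape[1] % 2:
        raise GridError("field must be 2D with even dimensions")
    h2, w2 = f.shape[0] // 2, f.shape[1] // 2
    ne = f[h2:, w2:]                      # (+x, +y)
    se = f[:h2, w2:][::-1, :]             # (+x, -y), flipped to match NE order
    nw = f[h2:, :w2][:, ::-1]             # (-x, +y)
    sw = f[:h2, :w2][::-1, ::-1]          # (-x, -y)
    return (ne - se - nw + sw) / 4.0


def model_residual(measured_theta, l0, x, y, mask=None):
    """Root-mean-square nematic deviation between a measured time-averaged
    angle field and the circle-arc model with the given l0.

    Parameters
    ----------
    measured_theta : 2D array (rad)
    l0 : float
    x, y : 1D coordinate axes (um) of the field columns / rows
    mask : optional 2D bool array restricting the comparison (e.g. the
        spindle interior).  Empty overlap raises ``ValueError``.
    """
    xx, yy = np.meshgrid(np.asarray(x, float), np.asarray(y, float))
    # exclude the poles themselves
    ok = ~(((np.abs(np.abs(xx) - l0) < 1e-6) & (np.abs(yy) < 1e-6)))
    if mask is not None:
        ok &= np.asarray(mask, bool)
    if not np.any(ok):
        raise ValueError("empty overlap region between field and mask")
    model = theta_arcs(xx[ok], yy[ok], l0)
    d = nematic_distance(np.asarray(measured_theta, float)[ok], model)
    return float(np.sqrt(np.mean(d**2)))


def rescaled_profile(fields, l0s, xs, ys, *, axis="y", coord=0.25, band=0.06,
                     bins=24, lim=1.0):
    """Pooled line profile of angle fields after r -> r / l0 rescaling.

    Each spindle's field is rescaled by its own l0, folded into the first
    quadrant with :func:`symmetrize_quadrant`, and the values in a band
    around the requested line are binned against the along-line
    coordinate.  With ``axis='y'`` the profile runs along y at fixed
    x = coord (all in l0 units); with ``axis='x'`` along x at fixed y.

    Returns ``(centers, mean, se)`` arrays; empty bins are NaN.
    """
    acc = [[] for _ in range(bins)]
    edges = np.linspace(0.0, lim, bins + 1)
    for f, l0, x, y in zip(fields, l0s, xs, ys):
        q = symmetrize_quadrant(np.asarray(f, float))
        h2, w2 = q.shape
        xq = np.asarray(x, float)[w2:] / l0
        yq = np.asarray(y, float)[h2:] / l0
        xx, yy = np.meshgrid(xq, yq)
        if axis == "y":
            along, across = yy, xx
        else:
            along, across = xx, yy
        sel = np.abs(across - coord) <= band
        idx = np.digitize(along[sel], edges) - 1
        vals = q[sel]
        for i, v in zip(idx, vals):
            if 0 <= i < bins:
                acc[i].append(v)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mean = np.full(bins, np.nan)
    se = np.full(bins, np.nan)
    for i, a in enumerate(acc):
        if a:
            a = np.asarray(a)
            mean[i] = a.mean()
            se[i] = a.std(ddof=1) / np.sqrt(len(a)) if len(a) > 1 else 0.0
    return centers, mean, se
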