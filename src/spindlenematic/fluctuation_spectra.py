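"""Orientational fluctuation analysis: spectra and density coupling.

Near the spindle center the time-averaged director is nearly horizontal,
so the transverse director fluctuation is, to lowest order, the angle
deviation itself: delta_n_y ~ theta(r, t) - theta_arcs(r).  This module
extracts that fluctuation stack from a registered movie, computes the
spatiotemporal correlation function

    c_nn(q, w) = |delta_n_y~(q, w)|^2 / (tau0 * lambda0^2)

and its equal-time reduction s_nn(q) = (1/2pi) integral c_nn dw, with
mirror padding in all dimensions before the Fourier transforms and a
diffraction cutoff discarding modes with |q| > 2pi / lambda_im.  The
fixed-q_x slice s_nn(q0, q_y) with q0 = 2pi/lambda0 is the standard
diagnostic: a homogeneous active nematic decays as q_y^-2; regularly
spaced high-fluctuation voids add a peak at q_y ~ 2pi / spacing.

Real-space coupling between fluctuations and microtubule density is
quantified by a linear fit of <|delta_theta|>_t against <r>_t and by the
ratio of mean fluctuation in low- vs high-density regions of the locally
binarized retardance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .director_model import nematic_mean, theta_arcs, wrap_nematic

__all__ = [
    "FluctuationStack", "Spectrum", "compute_fluctuations", "spectrum",
    "slice_qy", "find_peak", "local_binarize", "density_fluctuation_coupling",
]


@dataclass
class FluctuationStack:
    """delta_n_y(x, y, t) over a centered analysis box."""

    dny: np.ndarray           # (T, h, w), rad
    pixel_size: float         # um
    frame_interval: float     # s
    box_um: float             # lambda0, side length of the box
    origin: tuple = (0.0, 0.0)

    @property
    def duration(self):
        """tau0, total duration (s)."""
        return self.dny.shape[0] * self.frame_interval


@dataclass
class Spectrum:
    """Correlation spectra with axis metadata (fftshifted, ascending)."""

    qx: np.ndarray            # rad/um
    qy: np.ndarray
    omega: np.ndarray         # rad/s
    s_nn: np.ndarray          # (len(qy), len(qx)); NaN beyond the cutoff
    c_nn: np.ndarray          # (len(omega), len(qy), len(qx))
    lambda_im: float
    meta: dict = field(default_factory=dict)


def compute_fluctuations(movie, l0, *, box_um=8.0, center=None,
                         max_mean_deg=15.0):
    """Extract delta_n_y over a box of side ``box_um`` at the spindle
    center of a registered movie, subtracting the circle-arc reference
    field for the given l0.

    Warns when the time-averaged angle exceeds ``max_mean_deg`` anywhere
    in the box (the small-angle identification delta_n_y ~ delta_theta
    then degrades beyond the ~1% level).
    """
    x, y = movie.frame_coords()
    cx, cy = center if center is not None else (0.0, 0.0)
    jj = np.nonzero(np.abs(x - cx) <= box_um / 2)[0]
    ii = np.nonzero(np.abs(y - cy) <= box_um / 2)[0]
    if len(ii) < 2 or len(jj) < 2:
        raise ValueError("analysis box smaller than 2 pixels")
    xx, yy = np.meshgrid(x[jj], y[ii])
    ref = theta_arcs(xx, yy, l0)
    sub = movie.slow_axis[:, ii[0]:ii[-1] + 1, jj[0]:jj[-1] + 1]
    tmean = _nematic_time_mean(sub)
    if np.any(np.abs(tmean) > np.deg2rad(max_mean_deg)):
        warnings.warn("time-mean angle exceeds 15 deg in the analysis box; "
                      "small-angle identification degrades")
    dny = wrap_nematic(sub - ref[None])
    return FluctuationStack(dny, movie.pixel_size, movie.frame_interval,
                            box_um, origin=(float(cx), float(cy)))


def _nematic_time_mean(stack):
    z = np.exp(2j * stack).mean(axis=0)
    return 0.5 * np.angle(z)


def spectrum(fluct, *, lambda_im=0.530, pad_factor=1):
    """(2+1)D correlation spectra of a fluctuation stack.

    Mirror padding extends every dimension by ``pad_factor`` times its
    length (default: doubled) before the FFT; transforms use the
    physical (integral) normalization so that
    sum_q s_nn(q) (dq/2pi)^2 equals the time-averaged spatial variance.
    Modes with |q| > 2pi/lambda_im are set to NaN in ``s_nn``.
    """
    d = fluct.dny
    if d.shape[1] < 2 or d.shape[2] < 2:
        raise ValueError("box smaller than 2 pixels")
    pad = np.pad(d, [(0, pad_factor * s) for s in d.shape], mode="symmetric")
    nt, ny, nx = pad.shape
    dt, dx = fluct.frame_interval, fluct.pixel_size
    f = np.fft.fftn(pad) * (dt * dx * dx)
    tau0 = nt * dt
    area = (ny * dx) * (nx * dx)
    c_nn = np.abs(f) ** 2 / (tau0 * area)
    omega = 2 * np.pi * np.fft.fftfreq(nt, d=dt)
    qy = 2 * np.pi * np.fft.fftfreq(ny, d=dx)
    qx = 2 * np.pi * np.fft.fftfreq(nx, d=dx)
    c_nn = np.fft.fftshift(c_nn)
    omega = np.fft.fftshift(omega)
    qy_s = np.fft.fftshift(qy)
    qx_s = np.fft.fftshift(qx)
    s_nn = np.trapezoid(c_nn, omega, axis=0) / (2 * np.pi)
    # periodic endpoint: trapezoid drops half a bin at each omega end;
    # add it back so Parseval bookkeeping holds
    dom = omega[1] - omega[0]
    s_nn = s_nn + 0.5 * dom * (c_nn[0] + c_nn[-1]) / (2 * np.pi)
    # wider-than-doubling symmetric extension tiles the box coherently:
    # power at box-commensurate modes grows with the square of the copy
    # count while the mode spacing only shrinks linearly; rescale to the
    # doubled-padding reference so s_nn is padding-width invariant
    copies = (1 + pad_factor) / 2.0
    s_nn = s_nn / copies**2
    qmag = np.hypot(qy_s[:, None], qx_s[None, :])
    s_nn = np.where(qmag > 2 * np.pi / lambda_im, np.nan, s_nn)
    return Spectrum(qx_s, qy_s, omega, s_nn, c_nn, lambda_im,
                    meta={"padding": "mirror", "box_um": fluct.box_um})


def slice_qy(spec, lambda0):
    """The s_nn(q0, q_y) slice at q0 = 2pi/lambda0, symmetrized over the
    +-q0 columns and +-q_y; returns (q_y > 0 array, values).

    Only modes commensurate with the *unpadded* box (multiples of
    2pi/lambda0) are returned: mirror padding halves the mode spacing,
    but the interleaved half-modes are interpolates of the data and
    carry a systematic even/odd alternation, not independent structure.
    """
    q0 = 2 * np.pi / lambda0
    cols = [int(np.argmin(np.abs(spec.qx - q0))),
            int(np.argmin(np.abs(spec.qx + q0)))]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        s = np.nanmean(spec.s_nn[:, cols], axis=1)
    ratio = spec.qy / q0
    pos = (spec.qy > 1e-12) & (np.abs(ratio - np.round(ratio)) < 1e-6)
    qy_pos = spec.qy[pos]
    s_pos = s[pos]
    # fold the negative branch onto the positive one
    for i, q in enumerate(qy_pos):
        j = int(np.argmin(np.abs(spec.qy + q)))
        if np.isfinite(s[j]):
            s_pos[i] = np.nanmean([s_pos[i], s[j]])
    ok = np.isfinite(s_pos)
    return qy_pos[ok], s_pos[ok]


def find_peak(qy, s, *, n_anchor=3, mad_factor=4.0, q0=None):
    """Locate a spectral peak above the inverse-square background.

    The background is the fixed-q_x slice of an isotropic inverse-square
    spectrum, C / (q0^2 + q_y^2) — which decays as q_y^-2 at large q_y —
    with C fitted (log-log) to the ``n_anchor`` lowest and highest q_y
    points; q0 defaults to the first slice mode.  The peak is the
    largest local maximum of the relative residual s/background - 1 that
    is *also* a local maximum of the slice itself — a monotonically
    decaying slice never yields a peak, whatever the residual shape —
    and is accepted when the relative residual exceeds ``mad_factor``
    times its MAD.  Returns ``(qy_star, lambda_star)`` or ``None`` — no
    peak is a valid outcome for homogeneous fields.
    """
    qy = np.asarray(qy, float)
    s = np.asarray(s, float)
    if len(qy) < 2 * n_anchor + 3:
        return None
    if q0 is None:
        q0 = qy[0]
    anchor = np.r_[np.arange(n_anchor), np.arange(len(qy) - n_anchor, len(qy))]
    logc = np.mean(np.log(s[anchor]) + np.log(q0**2 + qy[anchor] ** 2))
    bg = np.exp(logc) / (q0**2 + qy**2)
    # spectral estimates have multiplicative noise, so work with the
    # relative residual (uniform variance across q)
    resid = s / bg - 1.0
    mad = np.median(np.abs(resid - np.median(resid)))
    interior = np.arange(1, len(qy) - 1)
    local_max = interior[(resid[interior] > resid[interior - 1])
                         & (resid[interior] >= resid[interior + 1])
                         & (s[interior] > s[interior - 1])
                         & (s[interior] >= s[interior + 1])]
    if len(local_max) == 0:
        return None
    k = local_max[np.argmax(resid[local_max])]
    if resid[k] <= mad_factor * max(mad, 1e-300):
        return None
    qstar = float(qy[k])
    return qstar, 2 * np.pi / qstar


def local_binarize(image, pixel_size, radius_um=2.0):
    """Local adaptive binarization: pixel -> 1 iff its value is >= the
    mean over the disk of ``radius_um`` around it (edge disks are
    clipped to the image)."""
    r_px = radius_um / pixel_size
    if r_px < 1:
        raise ValueError("radius must be at least 1 pixel")
    n = int(np.ceil(r_px))
    ii, jj = np.mgrid[-n:n + 1, -n:n + 1]
    disk = (ii**2 + jj**2 <= r_px**2).astype(float)
    img = np.asarray(image, float)
    num = ndimage.convolve(img, disk, mode="constant", cval=0.0)
    den = ndimage.convolve(np.ones_like(img), disk, mode="constant", cval=0.0)
    return (img >= num / den).astype(np.uint8)


def density_fluctuation_coupling(mean_ret, mean_absdtheta, mask):
    """Couple fluctuation magnitude to microtubule density.

    Returns ``(slope, ratio)``: the least-squares slope (rad/nm) of
    <|delta_theta|>_t against <r>_t over the box pixels, and the ratio of
    mean |delta_theta| in low-density (mask == 0) vs high-density
    (mask == 1) regions of the binarized retardance.
    """
    r = np.asarray(mean_ret, float).ravel()
    f = np.asarray(mean_absdtheta, float).ravel()
    m = np.asarray(mask).ravel().astype(bool)
    if r.shape != f.shape or r.shape != m.shape:
        raise ValueError("inputs must share a shape")
    if not m.any() or m.all():
        raise ValueError("empty low- or high-density class")
    slope = float(np.polyfit(r, f, 1)[0])
    ratio = float(f[~m].mean() / f[m].mean())
    return slope, ratio
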