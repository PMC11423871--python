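"""Rigid registration of LC-PolScope movies into the spindle rest frame.

A PolScope movie is a paired retardance (nm) and slow-axis (rad, nematic)
time series.  Analysis of spindle structure requires the spindle to sit
motionless, centered and horizontal; live spindles instead translate and
rotate by several micrometers/degrees over a recording.  Registration
proceeds in four steps:

1. optional ROI crop (a manual acquisition-time step; pass ``roi``);
2. per-frame translation from the center of brightness of the largest
   bright component of the Gaussian-blurred, thresholded retardance;
3. a single rotation making the movie-wide nematic-mean slow axis
   horizontal — slow-axis *values* are rotated along with the raster;
4. per-frame refinement that aligns gradient-magnitude images to a
   moving-average reference by cross-correlation with sub-pixel
   (parabolic/upsampled) refinement.

Step 4 may fail on pathological frames; it then falls back to the step-2
estimate with a warning (omitting it does not substantially alter
downstream statistics).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .director_model import nematic_mean, wrap_nematic
from .exceptions import DegenerateAverageError, EmptyFrameError

__all__ = ["PolScopeMovie", "RigidTrack", "register_movie",
           "worst_case_tilt_error"]


def worst_case_tilt_error(out_of_plane_max=0.1, n_grid=10001):
    """Worst-case relative retardance error from residual spindle tilt.

    Acquisition keeps the out-of-plane component c of the spindle axis
    below ``out_of_plane_max``; the measured retardance scales with the
    intrinsic one as (1 - c^2) (the squared-cosine projection law), so
    the relative deviation is c^2.  The maximum over all admissible
    tilts is returned in percent.
    """
    c = np.linspace(0.0, float(out_of_plane_max), n_grid)
    rel_err = np.abs(1.0 - (1.0 - c**2))
    return float(rel_err.max() * 100.0)


@dataclass
class PolScopeMovie:
    """Paired retardance / slow-axis time series.

    retardance : (T, H, W) float array, nm, >= 0
    slow_axis  : (T, H, W) float array, rad, nematic (mod pi)
    pixel_size : um per pixel
    frame_interval : s between frames
    """

    retardance: np.ndarray
    slow_axis: np.ndarray
    pixel_size: float
    frame_interval: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.retardance = np.asarray(self.retardance, dtype=float)
        self.slow_axis = wrap_nematic(np.asarray(self.slow_axis, dtype=float))
        if self.retardance.shape != self.slow_axis.shape:
            raise ValueError("retardance and slow_axis shapes differ")
        if self.retardance.ndim != 3:
            raise ValueError("expected (T, H, W) arrays")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")
        self.retardance = np.clip(self.retardance, 0.0, None)

    @property
    def n_frames(self):
        return self.retardance.shape[0]

    def frame_coords(self):
        """Physical pixel-center coordinates (x_um, y_um) relative to the
        image center (1D arrays for columns and rows)."""
        t, h, w = self.retardance.shape
        x = (np.arange(w) + 0.5 - w / 2) * self.pixel_size
        y = (np.arange(h) + 0.5 - h / 2) * self.pixel_size
        return x, y


@dataclass
class RigidTrack:
    """Per-frame rigid transform mapping the raw frame into the spindle
    frame: first translate by (dx_um, dy_um), then rotate by rot_rad
    about the image center."""

    dx_um: np.ndarray
    dy_um: np.ndarray
    rot_rad: np.ndarray

    def __post_init__(self):
        self.dx_um = np.asarray(self.dx_um, float)
        self.dy_um = np.asarray(self.dy_um, float)
        self.rot_rad = np.pi - np.mod(np.pi - np.asarray(self.rot_rad, float),
                                      2 * np.pi)
        if not (np.all(np.isfinite(self.dx_um)) and np.all(np.isfinite(self.dy_um))
                and np.all(np.isfinite(self.rot_rad))):
            raise ValueError("track values must be finite")

    def to_frame(self):
        return pd.DataFrame({
            "frame": np.arange(len(self.dx_um)),
            "dx_um": self.dx_um, "dy_um": self.dy_um, "rot_rad": self.rot_rad,
        })


def _brightness_center(frame, sigma_px, threshold_pct=99.9):
    """Step-2 primitive: center of brightness (row, col, in px) of the
    largest component above half the (robust) maximum."""
    sm = ndimage.gaussian_filter(frame, sigma_px)
    thr = 0.5 * np.percentile(sm, threshold_pct)
    mask = sm > thr
    if not mask.any():
        raise EmptyFrameError("no pixels above threshold")
    lab, n = ndimage.label(mask)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    big = lab == (1 + int(np.argmax(sizes)))
    w = sm * big
    tot = w.sum()
    ii, jj = np.mgrid[0:frame.shape[0], 0:frame.shape[1]]
    return float((ii * w).sum() / tot), float((jj * w).sum() / tot), big


def _resample_movie(movie, dx_px, dy_px, rot):
    """Resample both channels with per-frame translation + global rotation.

    Output pixel o (image frame, spindle-centered, axis horizontal) samples
    the input at p = R(rot) (o - C) + C + d_t, with C the image center.
    Retardance is interpolated bilinearly; the slow axis through its
    doubled-angle components, after which the values are rotated by -rot.
    """
    t, h, w = movie.retardance.shape
    ci, cj = h / 2 - 0.5, w / 2 - 0.5
    oi, oj = np.mgrid[0:h, 0:w].astype(float)
    cosr, sinr = np.cos(rot), np.sin(rot)
    # image row index grows with +y here (coords consistent throughout)
    rel_i, rel_j = oi - ci, oj - cj
    base_i = ci + sinr * rel_j + cosr * rel_i
    base_j = cj + cosr * rel_j - sinr * rel_i
    ret = np.empty_like(movie.retardance)
    ang = np.empty_like(movie.slow_axis)
    for k in range(t):
        coords = [base_i + dy_px[k], base_j + dx_px[k]]
        ret[k] = ndimage.map_coordinates(movie.retardance[k], coords, order=1,
                                         mode="nearest")
        c2 = ndimage.map_coordinates(np.cos(2 * movie.slow_axis[k]), coords,
                                     order=1, mode="nearest")
        s2 = ndimage.map_coordinates(np.sin(2 * movie.slow_axis[k]), coords,
                                     order=1, mode="nearest")
        ang[k] = wrap_nematic(0.5 * np.arctan2(s2, c2) - rot)
    return ret, ang


def register_movie(movie, *, blur_um=3.0, ref_window=10, roi=None,
                   max_refine_px=5.0):
    """Register a PolScope movie into the spindle rest frame.

    Parameters
    ----------
    movie : PolScopeMovie
    blur_um : Gaussian blur radius (um) for the brightness-center step;
        the Gaussian sigma is half this radius.
    ref_window : width (frames) of the moving-average reference for the
        final alignment step.
    roi : optional pair of slices cropping both channels first.
    max_refine_px : refinement shifts larger than this are treated as
        divergent; the frame falls back to the step-2 estimate.

    Returns
    -------
    (registered : PolScopeMovie, track : RigidTrack)
    """
    if movie.n_frames < 2:
        raise ValueError("need at least 2 frames")
    if roi is not None:
        movie = PolScopeMovie(movie.retardance[(slice(None),) + tuple(roi)],
                              movie.slow_axis[(slice(None),) + tuple(roi)],
                              movie.pixel_size, movie.frame_interval,
                              dict(movie.meta))
    t, h, w = movie.retardance.shape
    sigma_px = (blur_um / 2.0) / movie.pixel_size
    ci, cj = h / 2 - 0.5, w / 2 - 0.5

    # step 2: per-frame translation from center of brightness
    dy_px = np.zeros(t)
    dx_px = np.zeros(t)
    angles = []
    for k in range(t):
        bi, bj, comp = _brightness_center(movie.retardance[k], sigma_px)
        dy_px[k] = bi - ci
        dx_px[k] = bj - cj
        angles.append(movie.slow_axis[k][comp])

    # step 3: single rotation from the movie-wide nematic mean
    try:
        rot = nematic_mean(np.concatenate(angles))
    except DegenerateAverageError:
        rot = 0.0
        warnings.warn("degenerate mean orientation; skipping rotation step")

    # preliminary resample for the step-4 refinement
    ret_pre, _ = _resample_movie(movie, dx_px, dy_px, rot)
    grad = np.hypot(*np.gradient(ret_pre, axis=(1, 2)))
    ref = ndimage.uniform_filter1d(grad, size=min(ref_window, t), axis=0,
                                   mode="nearest")
    cosr, sinr = np.cos(rot), np.sin(rot)
    for k in range(t):
        shift, _, _ = phase_cross_correlation(ref[k], grad[k],
                                              upsample_factor=20)
        if np.hypot(*shift) > max_refine_px:
            warnings.warn(f"frame {k}: refinement diverged; keeping step-2 "
                          "estimate")
            continue
        # shifting the registered frame by `shift` equals sampling the raw
        # frame at d_t - R(rot) shift
        si, sj = float(shift[0]), float(shift[1])
        dy_px[k] -= sinr * sj + cosr * si
        dx_px[k] -= cosr * sj - sinr * si

    ret, ang = _resample_movie(movie, dx_px, dy_px, rot)
    registered = PolScopeMovie(ret, ang, movie.pixel_size,
                               movie.frame_interval,
                               {**movie.meta, "registered": True})
    track = RigidTrack(-dx_px * movie.pixel_size, -dy_px * movie.pixel_size,
                       np.full(t, -rot))
    return registered, track
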