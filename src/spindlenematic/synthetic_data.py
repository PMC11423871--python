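"""Ground-truth spindle, movie and metaphase-plate generators.

Every downstream stage of the pipeline (registration, geometry fitting,
director comparison, fluctuation spectra, void inversion, plate
statistics) is exercised on data produced here, with known ground truth:

* a pole-indented tactoid body of revolution with microtubule density
  rho0, rendered to retardance via the projection law
  r = A0 * integral of rho along the optical axis  (A0 in nm^2, rho in
  um^-2, path in um; 1 nm^2 um^-2 um = 1e-3 nm);
* tactoid-like voids: a circle-arc width profile of chord beta revolved
  about the spindle axis and scaled anisotropically so the metaphase-
  plate cross section is an (a, b) ellipse;
* a slow-axis channel equal to the circle-arc director field plus an
  orientational fluctuation field with a power-law equal-time spectrum
  (|q|^exponent, default -2) and Ornstein-Uhlenbeck temporal decay,
  boosted by a constant factor inside voids;
* per-frame rigid drift, additive Gaussian retardance noise and wrapped
  angular jitter on the slow axis.

Pixel (i, j) is centered at ((j+0.5)*px, (i+0.5)*px) in a 0-based,
row-major raster; spindle-frame coordinates are relative to the image
center.  All physical lengths in um, retardance in nm, angles in rad.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .director_model import theta_arcs, wrap_nematic
from .exceptions import InvalidGeometryError
from .movie_registration import PolScopeMovie
from .spindle_geometry import tactoid_boundary_radius, tactoid_cross_section

__all__ = [
    "FluctParams", "VoidTruth", "SpindleGroundTruth", "PlateGroundTruth",
    "make_tactoid_boundary", "circle_arc_width", "default_voids",
    "sample_fluctuation_field", "render_polscope_movie", "analytic_volume",
    "make_plate_truth", "render_plate_image", "render_confocal_stack",
    "save_movie", "load_movie",
]


# ------------------------------------------------------------- parameters

@dataclass
class FluctParams:
    """Orientational fluctuation statistics.

    amplitude : rms fluctuation angle (rad) outside voids
    spectral_exponent : power-law exponent of the equal-time spatial
        spectrum (default -2, the active-nematic scaling)
    void_boost : multiplicative enhancement inside voids (default 1.07)
    correlation_time : OU temporal correlation time (s)
    """

    amplitude: float = 0.05
    spectral_exponent: float = -2.0
    void_boost: float = 1.07
    correlation_time: float = 10.0
    void_edge_um: float = 0.25  # smoothing of the boost envelope edge

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.void_boost < 1:
            raise ValueError("void_boost must be >= 1")


@dataclass
class VoidTruth:
    """One tactoid-like void.

    center : (x, y, z) um in the spindle frame
    beta   : void length along the spindle axis (um)
    a, b   : metaphase-plate cross-section semi-axes (um), a >= b
    psi    : in-plane (y-z) orientation of the a-axis (rad)
    """

    center: tuple
    beta: float
    a: float
    b: float
    psi: float = 0.0

    def __post_init__(self):
        self.center = tuple(float(v) for v in self.center)
        if len(self.center) != 3:
            raise ValueError("center must be 3D")
        if not (self.a >= self.b > 0):
            raise ValueError("need a >= b > 0")
        if self.beta <= 0:
            raise ValueError("beta must be positive")

    @property
    def waist(self):
        """Equivalent (geometric-mean) waist diameter 2*sqrt(ab)... the
        diameter of the circle with the same cross-sectional area."""
        return 2.0 * np.sqrt(self.a * self.b)


@dataclass
class SpindleGroundTruth:
    """Full specification of a synthetic PolScope recording."""

    l0: float = 15.2          # virtual-pole half-spacing (um)
    r_belt: float = 8.0       # belt half-width (um)
    r_cap: float = 4.0        # polar-cap radius (um)
    rho0: float = 50.0        # microtubule density away from voids (um^-2)
    a0: float = 7.5           # per-microtubule retardance constant (nm^2)
    voids: list = field(default_factory=list)
    fluct: FluctParams = field(default_factory=FluctParams)
    n_frames: int = 60
    pixel_size: float = 0.25  # um
    frame_interval: float = 3.6  # s
    drift: np.ndarray | None = None   # (n_frames, 3): dx_um, dy_um, rot_rad
    noise_sd: float = 0.1     # additive retardance noise (nm)
    angle_jitter_sd: float = 0.0  # wrapped angular jitter on slow axis (rad)
    seed: int = 0
    shape: tuple | None = None  # (H, W); default fits spindle + margin

    def __post_init__(self):
        if not (0 < self.r_cap < self.l0) or self.r_belt <= 0:
            raise InvalidGeometryError("need 0 < r_cap < l0 and r_belt > 0")
        if self.rho0 <= 0 or self.pixel_size <= 0:
            raise ValueError("rho0 and pixel_size must be positive")
        if self.drift is not None:
            self.drift = np.asarray(self.drift, dtype=float)
            if self.drift.shape != (self.n_frames, 3):
                raise ValueError("drift must have shape (n_frames, 3)")

    def image_shape(self):
        if self.shape is not None:
            return tuple(self.shape)
        half_x = 1.25 * self.l0
        half_y = 1.4 * self.r_belt
        w = 2 * int(np.ceil(half_x / self.pixel_size))
        h = 2 * int(np.ceil(half_y / self.pixel_size))
        return h, w


# ----------------------------------------------------- geometric helpers

def make_tactoid_boundary(l0, r_belt, r_cap, n_points=360):
    """Closed 2D pole-indented-tactoid boundary curve, (n_points, 2) um.

    Sampled at uniform polar angles starting at phi = 0, so the pole tips
    (+-(l0 - r_cap), 0) are always on the curve and, for n_points
    divisible by 4, so are the apexes (0, +-r_belt).  The curve is
    invariant under both mirror symmetries by construction.
    """
    if n_points < 16:
        raise ValueError("n_points must be >= 16")
    phi = np.linspace(0.0, 2 * np.pi, n_points, endpoint=False)
    b = tactoid_boundary_radius(phi, l0, r_belt, r_cap)
    return np.column_stack([b * np.cos(phi), b * np.sin(phi)])


def circle_arc_width(xi, waist, beta):
    """Width profile d(xi) of a circle arc of chord beta and maximal
    width ``waist``: d = 2 (sqrt(rho_c^2 - xi^2) - (rho_c - waist/2)),
    rho_c = beta^2/(4 waist) + waist/4, clipped at 0 outside |xi|<beta/2."""
    xi = np.asarray(xi, dtype=float)
    rho_c = beta**2 / (4.0 * waist) + waist / 4.0
    with np.errstate(invalid="ignore"):
        d = 2.0 * (np.sqrt(np.clip(rho_c**2 - xi**2, 0.0, None))
                   - (rho_c - waist / 2.0))
    return np.clip(d, 0.0, None)


def _void_profile_factor(xi, void):
    """Scale factor f(xi) in [0, 1] of a void's cross section at axial
    offset xi: the circle-arc profile of its equal-area revolved twin."""
    return circle_arc_width(xi, void.waist, void.beta) / void.waist


def _void_chord(xs, ys, void):
    """Optical-axis (z) chord length through one void at spindle-frame
    pixel coordinates (xs, ys).  Vectorized over arrays."""
    cx, cy, _cz = void.center
    xi = xs - cx
    f = _void_profile_factor(xi, void)
    eta = ys - cy
    aa = void.a * f
    bb = void.b * f
    out = np.zeros_like(np.broadcast_arrays(xs, ys)[0], dtype=float)
    ok = (aa > 0) & (bb > 0)
    if not np.any(ok):
        return out
    c0, s0 = np.cos(void.psi), np.sin(void.psi)
    with np.errstate(divide="ignore", invalid="ignore"):
        ia2 = 1.0 / aa**2
        ib2 = 1.0 / bb**2
        alpha = s0**2 * ia2 + c0**2 * ib2
        blin = 2.0 * eta * c0 * s0 * (ia2 - ib2)
        gam = eta**2 * (c0**2 * ia2 + s0**2 * ib2) - 1.0
        disc = blin**2 - 4.0 * alpha * gam
        chord = np.where(ok & (disc > 0), np.sqrt(np.clip(disc, 0, None)) / alpha,
                         0.0)
    return np.nan_to_num(chord)


def _body_half_chords(xs, ys, truth):
    """Half chord length through the revolved pole-indented tactoid."""
    outer, inner = tactoid_cross_section(xs, truth.l0, truth.r_belt, truth.r_cap)
    ho = np.sqrt(np.clip(outer**2 - ys**2, 0.0, None))
    hb = np.sqrt(np.clip(inner**2 - ys**2, 0.0, None))
    return np.clip(ho - np.minimum(hb, ho), 0.0, None)


def _validate_voids(truth, n_xi=25, n_tau=24):
    """Every void must lie strictly inside the spindle body."""
    for void in truth.voids:
        cx, cy, cz = void.center
        xi = np.linspace(-0.49 * void.beta, 0.49 * void.beta, n_xi)
        tau = np.linspace(0, 2 * np.pi, n_tau, endpoint=False)
        f = _void_profile_factor(xi, void)[:, None]
        c0, s0 = np.cos(void.psi), np.sin(void.psi)
        uy = void.a * f * np.cos(tau)[None, :]
        uz = void.b * f * np.sin(tau)[None, :]
        y = cy + c0 * uy - s0 * uz
        z = cz + s0 * uy + c0 * uz
        x = cx + np.broadcast_to(xi[:, None], y.shape)
        rad = np.hypot(y, z)
        outer, inner = tactoid_cross_section(x, truth.l0, truth.r_belt,
                                             truth.r_cap)
        if np.any(rad >= outer) or np.any(rad <= inner):
            raise InvalidGeometryError("void extends outside the spindle body")


def default_voids(n_chr=20, beta=11.0, waist=1.0, aspect=2.5, plate_radius=5.0,
                  seed=0):
    """A realistic void population: n_chr voids of length beta whose
    metaphase-plate cross sections are (a, b) ellipses with a/b = aspect
    and geometric-mean diameter ``waist``, placed without overlap inside
    a disk of ``plate_radius`` in the y-z plane (steric random placement).
    """
    from .chromosome_mc import random_placement

    b = waist / (2.0 * np.sqrt(aspect))
    a = aspect * b
    cfg = random_placement(n_chr, a, b, plate_radius, seed=seed)
    return [VoidTruth((0.0, float(y), float(z)), beta, a, b, float(ang))
            for y, z, ang in zip(cfg.x, cfg.y, cfg.angle)]


# ------------------------------------------------------------ fluctuations

def sample_fluctuation_field(fluct, shape, pixel_size, n_frames,
                             frame_interval, seed, void_mask=None,
                             regularize=False):
    """Sample a (T, H, W) orientational fluctuation field delta_theta.

    Spatial structure by spectral filtering of white noise with
    |q|^(exponent/2); temporal structure by an AR(1) (discretized
    Ornstein-Uhlenbeck) recursion with the requested correlation time.
    The marginal spatial rms equals ``fluct.amplitude``; values inside
    ``void_mask`` are multiplied by ``fluct.void_boost``.

    A non-negative exponent is refused (the spectrum does not decay)
    unless ``regularize=True`` accepts the implicit grid cutoff.
    """
    h, w = shape
    if fluct.amplitude == 0:
        return np.zeros((n_frames, h, w))
    if fluct.spectral_exponent >= 0 and not regularize:
        raise ValueError("non-negative spectral exponent needs regularize=True")
    rng = np.random.default_rng(seed)
    qy = 2 * np.pi * np.fft.fftfreq(h, d=pixel_size)
    qx = 2 * np.pi * np.fft.fftfreq(w, d=pixel_size)
    q = np.hypot(qy[:, None], qx[None, :])
    with np.errstate(divide="ignore"):
        filt = np.where(q > 0, q ** (fluct.spectral_exponent / 2.0), 0.0)
    # filtering unit white noise gives field variance mean(filt^2)
    filt = filt / np.sqrt(np.mean(filt**2)) * fluct.amplitude

    def draw_field():
        wn = rng.standard_normal((h, w))
        return np.fft.ifft2(np.fft.fft2(wn) * filt).real

    phi = np.exp(-frame_interval / fluct.correlation_time) \
        if fluct.correlation_time > 0 else 0.0
    out = np.empty((n_frames, h, w))
    cur = draw_field()
    out[0] = cur
    for t in range(1, n_frames):
        cur = phi * cur + np.sqrt(1 - phi**2) * draw_field()
        out[t] = cur
    if void_mask is not None:
        # multiplicative boost through a smooth envelope: sharp mask
        # edges would inject broadband high-q power that real (smooth)
        # void enhancements do not have
        env = np.asarray(void_mask, bool).astype(float)
        if fluct.void_edge_um > 0:
            env = ndimage.gaussian_filter(env, fluct.void_edge_um / pixel_size)
        out = out * (1.0 + (fluct.void_boost - 1.0) * env)[None, :, :]
    return out


# ------------------------------------------------------------- rendering

def void_projection_mask(truth, xs, ys):
    """2D mask of pixels whose optical-axis ray crosses any void."""
    m = np.zeros_like(xs, dtype=bool)
    for void in truth.voids:
        m |= _void_chord(xs, ys, void) > 0
    return m


def render_polscope_movie(truth):
    """Render a :class:`PolScopeMovie` from ground truth.

    Per pixel and frame, retardance (nm) is A0 times the line integral of
    microtubule density along the optical axis through the revolved
    tactoid minus void interiors; the slow axis is the circle-arc
    director angle plus the sampled fluctuation field.  Rigid drift moves
    the spindle (rendered analytically, no resampling error), then
    additive Gaussian noise and angular jitter are applied.
    """
    _validate_voids(truth)
    h, w = truth.image_shape()
    px = truth.pixel_size
    x = (np.arange(w) + 0.5 - w / 2) * px
    y = (np.arange(h) + 0.5 - h / 2) * px
    xx, yy = np.meshgrid(x, y)
    rng = np.random.default_rng(truth.seed)

    base_mask = void_projection_mask(truth, xx, yy)
    dtheta = sample_fluctuation_field(
        truth.fluct, (h, w), px, truth.n_frames, truth.frame_interval,
        seed=rng.integers(2**31), void_mask=base_mask)

    drift = truth.drift if truth.drift is not None \
        else np.zeros((truth.n_frames, 3))
    ret = np.empty((truth.n_frames, h, w))
    ang = np.empty((truth.n_frames, h, w))
    scale = truth.a0 * truth.rho0 * 1e-3  # nm per um of chord
    for t in range(truth.n_frames):
        dx, dy, rot = drift[t]
        cosr, sinr = np.cos(rot), np.sin(rot)
        # inverse rigid map: pixel -> spindle frame
        ux, uy = xx - dx, yy - dy
        xs = cosr * ux + sinr * uy
        ys = -sinr * ux + cosr * uy
        chord = _body_half_chords(xs, ys, truth) * 2.0
        for void in truth.voids:
            chord = chord - _void_chord(xs, ys, void)
        r = scale * np.clip(chord, 0.0, None)
        if truth.noise_sd > 0:
            r = r + rng.normal(0.0, truth.noise_sd, size=r.shape)
        ret[t] = np.clip(r, 0.0, None)

        # director + fluctuations, expressed in the image frame
        ys_safe = np.where((np.abs(np.abs(xs) - truth.l0) < 1e-9)
                           & (np.abs(ys) < 1e-9), 1e-6, ys)
        th = theta_arcs(xs, ys_safe, truth.l0)
        ii = ys / px + h / 2 - 0.5
        jj = xs / px + w / 2 - 0.5
        dth = ndimage.map_coordinates(dtheta[t], [ii, jj], order=1,
                                      mode="nearest")
        a = th + dth + rot
        if truth.angle_jitter_sd > 0:
            a = a + rng.normal(0.0, truth.angle_jitter_sd, size=a.shape)
        ang[t] = wrap_nematic(a)

    meta = {"truth": truth_to_dict(truth)}
    return PolScopeMovie(ret, ang, px, truth.frame_interval, meta)


def analytic_volume(truth, n_x=4001):
    """Spindle body volume minus void volumes (um^3), by fine quadrature
    of the cross-section areas; the independent reference for projected-
    density bookkeeping."""
    x = np.linspace(-truth.l0, truth.l0, n_x)
    outer, inner = tactoid_cross_section(x, truth.l0, truth.r_belt,
                                         truth.r_cap)
    area = np.pi * np.clip(outer**2 - inner**2, 0.0, None)
    v = np.trapezoid(area, x)
    for void in truth.voids:
        xi = np.linspace(-void.beta / 2, void.beta / 2, 2001)
        f = _void_profile_factor(xi, void)
        v -= np.trapezoid(np.pi * void.a * void.b * f**2, xi)
    return float(v)


# --------------------------------------------------------------- plates

@dataclass
class PlateGroundTruth:
    """Ground truth for a rendered metaphase plate."""

    boundary_radius: float
    ellipses: list            # (cx, cy, a_semi?, ...) see fields below
    a: float                  # full long axis (um)
    b: float                  # full short axis (um)
    potential_name: str = "none"
    potential_params: dict = field(default_factory=dict)
    seed: int = 0

    def boundary_curve(self, n=256):
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        return np.column_stack([self.boundary_radius * np.cos(t),
                                self.boundary_radius * np.sin(t)])


def make_plate_truth(n_chr=20, a=2.1, b=0.8, boundary_radius=6.5,
                     potential_name="none", potential_params=None, seed=0):
    """Place n_chr (a, b) ellipses in a disk; steric-only placement for
    ``potential_name='none'``, annealed Metropolis placement otherwise.
    ``a`` and ``b`` are full axes (Fig.-style), placement uses semi-axes.
    """
    from . import chromosome_mc as mc

    if n_chr < 1:
        raise ValueError("n_chr must be >= 1")
    potential_params = dict(potential_params or {})
    if potential_name == "none":
        cfg = mc.random_placement(n_chr, a / 2, b / 2, boundary_radius,
                                  seed=seed)
    else:
        params = mc.MCParams(potential_name=potential_name, seed=seed,
                             **potential_params)
        cfg = mc.anneal(n_chr, a / 2, b / 2, boundary_radius, params)
    ellipses = [(float(x), float(y), float(t))
                for x, y, t in zip(cfg.x, cfg.y, cfg.angle)]
    return PlateGroundTruth(boundary_radius, ellipses, a, b, potential_name,
                            potential_params, seed)


def _ellipse_union_mask(truth, xx, yy):
    m = np.zeros_like(xx, dtype=bool)
    sa, sb = truth.a / 2, truth.b / 2
    for cx, cy, th in truth.ellipses:
        c0, s0 = np.cos(th), np.sin(th)
        u = (xx - cx) * c0 + (yy - cy) * s0
        v = -(xx - cx) * s0 + (yy - cy) * c0
        m |= (u / sa) ** 2 + (v / sb) ** 2 <= 1.0
    return m


def render_plate_image(truth, pixel_size=0.1, psf_sd=0.15, noise=0.0,
                       dilate_um=0.3, margin_um=1.5, seed=0):
    """Render a two-channel metaphase-plate image.

    Channel 0 (microtubule): blurred indicator of the plate disk minus
    the dilated ellipse union (voids hug chromosomes).  Channel 1
    (chromosome): blurred indicator of the ellipse union.  Returns
    ``(image (2, H, W), pixel_size)``.
    """
    r = truth.boundary_radius + margin_um
    n = 2 * int(np.ceil(r / pixel_size))
    x = (np.arange(n) + 0.5 - n / 2) * pixel_size
    xx, yy = np.meshgrid(x, x)
    chrom = _ellipse_union_mask(truth, xx, yy)
    disk = np.hypot(xx, yy) <= truth.boundary_radius
    dil = ndimage.binary_dilation(
        chrom, iterations=max(1, int(round(dilate_um / pixel_size))))
    mt = disk & ~dil
    sig = psf_sd / pixel_size
    img = np.stack([
        ndimage.gaussian_filter(mt.astype(float), sig),
        ndimage.gaussian_filter(chrom.astype(float), sig),
    ])
    if noise > 0:
        rng = np.random.default_rng(seed)
        img = np.clip(img + rng.normal(0, noise, img.shape), 0, None)
    return img, pixel_size


def render_confocal_stack(truth, tilt_deg=0.0, voxel=(0.4, 0.15, 0.15),
                          chrom_halfwidth=0.5, spindle_halflength=12.0,
                          spindle_radius=None):
    """Synthetic two-channel 3D confocal stack with the metaphase plate
    tilted by ``tilt_deg`` about the y axis (plate normal rotated away
    from the stack x axis).  Returns ``(stack (2, X, Y, Z), voxel)``
    with voxel = (dx, dy, dz) um.  Intended for reslicing tests.
    """
    rad = spindle_radius or truth.boundary_radius + 1.0
    dx, dyv, dzv = voxel
    nx = 2 * int(np.ceil((chrom_halfwidth * 6 + abs(
        np.sin(np.deg2rad(tilt_deg))) * rad + 1.0) / dx))
    ny = 2 * int(np.ceil((rad + 1.0) / dyv))
    nz = 2 * int(np.ceil((rad + 1.0) / dzv))
    xs = (np.arange(nx) + 0.5 - nx / 2) * dx
    ys = (np.arange(ny) + 0.5 - ny / 2) * dyv
    zs = (np.arange(nz) + 0.5 - nz / 2) * dzv
    xg, yg, zg = np.meshgrid(xs, ys, zs, indexing="ij")
    t = np.deg2rad(tilt_deg)
    # rotate about y: plate coordinates (xp normal, yp, zp in-plane)
    xp = np.cos(t) * xg + np.sin(t) * zg
    zp = -np.sin(t) * xg + np.cos(t) * zg
    inplane = _ellipse_union_mask(truth, yg, zp)
    chrom = np.exp(-0.5 * (xp / chrom_halfwidth) ** 2) * inplane
    mt = (np.exp(-0.5 * (xp / spindle_halflength) ** 2)
          * (np.hypot(yg, zp) <= rad) * (~inplane))
    return np.stack([mt, chrom]), voxel


# ------------------------------------------------------------------- I/O

def truth_to_dict(truth):
    def conv(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return {k: conv(v) for k, v in dataclasses.asdict(o).items()}
        if isinstance(o, (list, tuple)):
            return [conv(v) for v in o]
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return o
    return conv(truth)


def save_movie(movie, prefix):
    """Write a movie as paired multi-page float32 TIFFs plus a JSON
    sidecar (ground truth / metadata) and a CSV drift table if present."""
    import tifffile

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(f"{prefix}_retardance.tif",
                     movie.retardance.astype(np.float32),
                     photometric="minisblack")
    tifffile.imwrite(f"{prefix}_slowaxis.tif",
                     movie.slow_axis.astype(np.float32),
                     photometric="minisblack")
    side = {"pixel_size_um": movie.pixel_size,
            "frame_interval_s": movie.frame_interval,
            "retardance_units": "nm", "slow_axis_units": "rad"}
    side.update({k: v for k, v in movie.meta.items() if k != "drift"})
    with open(f"{prefix}_truth.json", "w") as fh:
        json.dump(side, fh, indent=1, default=str)
    truth = movie.meta.get("truth")
    if isinstance(truth, dict) and truth.get("drift") is not None:
        import pandas as pd

        d = np.asarray(truth["drift"], float)
        pd.DataFrame(d, columns=["dx_um", "dy_um", "rot_rad"]).to_csv(
            f"{prefix}_drift.csv", index_label="frame")


def load_movie(prefix):
    import tifffile

    with open(f"{prefix}_truth.json") as fh:
        side = json.load(fh)
    ret = tifffile.imread(f"{prefix}_retardance.tif").astype(float)
    ang = tifffile.imread(f"{prefix}_slowaxis.tif").astype(float)
    meta = {k: v for k, v in side.items()
            if k not in ("pixel_size_um", "frame_interval_s")}
    return PolScopeMovie(ret, ang, side["pixel_size_um"],
                         side["frame_interval_s"], meta)
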