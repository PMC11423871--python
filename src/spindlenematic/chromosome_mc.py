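"""Metropolis Monte Carlo of metaphase-plate chromosome configurations.

Chromosome sections are hard ellipses (no overlap, confined to a disk
boundary) that optionally interact through a long-ranged repulsive pair
potential acting between centers:

    none           U = 0                 (steric-only null model)
    inv5           U = A s^-5            (far-field 3D quadrupole analogue)
    inv3           U = A s^-3
    yukawa         U = A e^{-s/lam} / s
    quadrupole_2d  the 2D defect-quadrupole curve, log-log interpolated

Two samplers are provided: *random sequential placement* (uniform
position/orientation, rejecting overlap — the steric null of the
experimental comparison) and *annealed Metropolis placement* (single-
ellipse translation+rotation moves, hard constraints rejected outright,
geometric temperature schedule).  The hot inner loop is numba-compiled;
ellipse-ellipse overlap uses an exact algebraic test (affine map to a
unit circle plus a point-to-ellipse Lagrange root), not a polygonal
approximation, so the ~0.1 um scales that set the pair-correlation
minimum are not resolution limited.

Unless stated otherwise lengths are um, angles rad, energies in units of
the (final) temperature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .exceptions import PackingInfeasibleError, StepSizeError

__all__ = [
    "MCParams", "Configuration", "potential", "random_placement",
    "random_placement_sections", "anneal", "run_mc", "render_mask",
    "simulate_ensemble", "ellipses_overlap", "ellipse_inside_disk",
]


# ----------------------------------------------------- geometry kernels

@njit(cache=True)
def _eig2(m00, m01, m11):
    tr = m00 + m11
    det = m00 * m11 - m01 * m01
    disc = math.sqrt(max(tr * tr / 4.0 - det, 0.0))
    l1 = tr / 2.0 + disc
    l2 = tr / 2.0 - disc
    if abs(m01) > 1e-300:
        vx, vy = l1 - m11, m01
    elif m00 >= m11:
        vx, vy = 1.0, 0.0
    else:
        vx, vy = 0.0, 1.0
    n = math.hypot(vx, vy)
    return l1, l2, vx / n, vy / n


@njit(cache=True)
def _ellipse_f(t, e1, e2, u1, u2):
    a = e1 * u1 / (t + e1 * e1)
    b = e2 * u2 / (t + e2 * e2)
    return a * a + b * b - 1.0


@njit(cache=True)
def _dist_outside(e1, e2, u1, u2):
    """Distance from an exterior point (u1, u2) to the ellipse with semi
    axes (e1, e2); Lagrange root on t > 0 by bisection."""
    u1 = abs(u1)
    u2 = abs(u2)
    t_lo = 0.0
    t_hi = e1 * math.hypot(u1, u2) + e1 * e1
    while _ellipse_f(t_hi, e1, e2, u1, u2) > 0.0:
        t_hi *= 2.0
    for _ in range(90):
        t = 0.5 * (t_lo + t_hi)
        if _ellipse_f(t, e1, e2, u1, u2) > 0.0:
            t_lo = t
        else:
            t_hi = t
    t = 0.5 * (t_lo + t_hi)
    a = t * u1 / (t + e1 * e1)
    b = t * u2 / (t + e2 * e2)
    return math.hypot(a, b)


@njit(cache=True)
def _overlap(x1, y1, t1, x2, y2, t2, sa, sb):
    dx = x2 - x1
    dy = y2 - y1
    d2 = dx * dx + dy * dy
    if d2 >= 4.0 * sa * sa:
        return False
    if d2 <= 4.0 * sb * sb:
        return True
    c1, s1 = math.cos(t1), math.sin(t1)
    u = c1 * dx + s1 * dy
    v = -s1 * dx + c1 * dy
    phi = t2 - t1
    cp, sp = math.cos(phi), math.sin(phi)
    # affine map sending ellipse 1 to the unit circle; ellipse 2 becomes
    # the image of the unit circle under M around center q
    m00, m01 = cp, -sp * sb / sa
    m10, m11 = sp * sa / sb, cp
    a00 = m00 * m00 + m01 * m01
    a01 = m00 * m10 + m01 * m11
    a11 = m10 * m10 + m11 * m11
    l1, l2, vx, vy = _eig2(a00, a01, a11)
    e1 = math.sqrt(max(l1, 1e-300))
    e2 = math.sqrt(max(l2, 1e-300))
    qx = u / sa
    qy = v / sb
    w1 = vx * (-qx) + vy * (-qy)
    w2 = -vy * (-qx) + vx * (-qy)
    if (w1 / e1) ** 2 + (w2 / e2) ** 2 <= 1.0:
        return True
    return _dist_outside(e1, e2, w1, w2) < 1.0


@njit(cache=True)
def _inside_disk(x, y, th, sa, sb, rb):
    """True iff the whole ellipse lies inside the disk of radius rb at
    the origin (farthest boundary point test)."""
    d = math.hypot(x, y)
    if d + sa <= rb:
        return True
    if d + sb > rb and d + sa > rb and d >= rb:
        return False
    c, s = math.cos(th), math.sin(th)
    u1 = abs(c * (-x) + s * (-y))
    u2 = abs(-s * (-x) + c * (-y))
    if u1 < 1e-12 and u2 < 1e-12:
        return sa <= rb
    if u1 < 1e-12:
        far2 = max(sa * sa + u2 * u2, (sb + u2) * (sb + u2))
        return math.sqrt(far2) <= rb
    nu = math.hypot(u1, u2)
    t_lo = -sa * sa - 2.0 * sa * nu - sb
    t_hi = -sa * sa - 1e-14 * sa * sa - 1e-300
    for _ in range(90):
        t = 0.5 * (t_lo + t_hi)
        if _ellipse_f(t, sa, sb, u1, u2) > 0.0:
            t_hi = t
        else:
            t_lo = t
    t = 0.5 * (t_lo + t_hi)
    fa = t * u1 / (t + sa * sa)
    fb = t * u2 / (t + sb * sb)
    return math.hypot(fa, fb) <= rb


def ellipses_overlap(pose1, pose2, sa, sb):
    """Exact overlap test for two congruent (sa, sb) ellipses given
    poses (x, y, angle)."""
    return bool(_overlap(pose1[0], pose1[1], pose1[2],
                         pose2[0], pose2[1], pose2[2], sa, sb))


def ellipse_inside_disk(pose, sa, sb, boundary_radius):
    return bool(_inside_disk(pose[0], pose[1], pose[2], sa, sb,
                             boundary_radius))


# -------------------------------------------------------------- potentials

_PIDS = {"none": 0, "inv5": 1, "inv3": 2, "yukawa": 3, "quadrupole_2d": 4}


@njit(cache=True)
def _pair_u(s, pid, amp, lam, tx, ty):
    if pid == 0:
        return 0.0
    if pid == 1:
        return amp / s**5
    if pid == 2:
        return amp / s**3
    if pid == 3:
        return amp * math.exp(-s / lam) / s
    ls = math.log(s)
    n = tx.shape[0]
    if ls <= tx[0]:
        return amp * math.exp(ty[0] + (ls - tx[0]) * (ty[1] - ty[0])
                              / (tx[1] - tx[0]))
    if ls >= tx[n - 1]:
        return amp * math.exp(ty[n - 1] - 4.0 * (ls - tx[n - 1]))
    lo, hi = 0, n - 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if tx[mid] <= ls:
            lo = mid
        else:
            hi = mid
    f = (ls - tx[lo]) / (tx[hi] - tx[lo])
    return amp * math.exp(ty[lo] * (1.0 - f) + ty[hi] * f)


@njit(cache=True)
def _total_energy(xs, ys, pid, amp, lam, tx, ty):
    n = xs.shape[0]
    e = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            s = math.hypot(xs[i] - xs[j], ys[i] - ys[j])
            e += _pair_u(s, pid, amp, lam, tx, ty)
    return e


@dataclass
class Potential:
    """Pair potential with both a Python callable and the encoded form
    consumed by the compiled kernel."""

    name: str
    pid: int
    amplitude: float
    lambda_b: float
    table_logs: np.ndarray
    table_logu: np.ndarray

    def __call__(self, s):
        s = np.asarray(s, float)
        if np.any(s <= 0):
            raise ValueError("separation must be positive")
        out = np.array([_pair_u(float(v), self.pid, self.amplitude,
                                self.lambda_b, self.table_logs,
                                self.table_logu) for v in np.atleast_1d(s)])
        return out if np.ndim(s) else float(out[0])


_EMPTY = np.zeros(2)


def potential(name, *, amplitude=1.0, lambda_b=1.0, beta=11.0, D=1.0,
              n_table=200):
    """Build a named pair potential.

    For ``quadrupole_2d`` the defect-quadrupole interaction curve for
    (beta, D) is computed once and interpolated log-log; beyond the
    table it continues with the exact d^-4 far-field slope.  ``amplitude``
    multiplies the base shape for every potential.
    """
    if name not in _PIDS:
        raise ValueError(f"unknown potential {name!r}")
    pid = _PIDS[name]
    tx, ty = _EMPTY, _EMPTY
    if pid == 4:
        from .nematic_quadrupole import interaction_potential, solve_geometry

        quad = solve_geometry(beta, D)
        d = np.geomspace(1.02 * D, 60.0 * beta, n_table)
        curve = interaction_potential(quad, d)
        ok = curve.u > 0
        tx = np.log(curve.d[ok])
        ty = np.log(curve.u[ok])
    return Potential(name, pid, float(amplitude), float(lambda_b), tx, ty)


@dataclass
class MCParams:
    """Annealing parameters.

    ``amplitude=None`` applies the default calibration: the pair energy
    equals the final temperature at s = 2b, twice the chromosome minor
    axis — just beyond side-by-side contact.  That makes the repulsion
    decisive (several kT) at contact range, a weakening bias out to the
    coordination shell, and negligible beyond.  Much stronger coupling
    freezes an expanded lattice whose correlations overshoot the
    observed neighbor spacing; much weaker coupling degenerates into
    bare packing texture.
    """

    potential_name: str = "inv5"
    amplitude: float | None = None
    lambda_b: float = 1.0
    t_initial: float = 100.0
    t_final: float = 1.0
    sweeps: int = 400
    moves_per_sweep: int | None = None
    step_xy: float = 0.4
    step_ang: float = 0.5
    max_attempts: int = 200000
    seed: int = 0
    record_every: int = 0
    quad_beta: float = 11.0
    quad_D: float = 1.0
    calib_s: float = 1.6      # 2b for the default (2.1, 0.8) ellipse

    def build_potential(self, calib_s=None):
        base = potential(self.potential_name, amplitude=1.0,
                         lambda_b=self.lambda_b, beta=self.quad_beta,
                         D=self.quad_D)
        if self.amplitude is not None:
            amp = float(self.amplitude)
        elif base.pid == 0:
            amp = 0.0
        else:
            amp = self.t_final / base(calib_s or self.calib_s)
        return Potential(base.name, base.pid, amp, base.lambda_b,
                         base.table_logs, base.table_logu)


@dataclass
class Configuration:
    """Ellipse poses plus bookkeeping."""

    x: np.ndarray
    y: np.ndarray
    angle: np.ndarray
    sa: float                 # semi-major axis (um)
    sb: float                 # semi-minor axis (um)
    boundary_radius: float
    energy: float = 0.0
    trace: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def n(self):
        return len(self.x)

    def audit_hard_core(self):
        """Exact validity audit: no overlaps, everything inside."""
        for i in range(self.n):
            if not _inside_disk(self.x[i], self.y[i], self.angle[i],
                                self.sa, self.sb, self.boundary_radius):
                return False
            for j in range(i + 1, self.n):
                if _overlap(self.x[i], self.y[i], self.angle[i],
                            self.x[j], self.y[j], self.angle[j],
                            self.sa, self.sb):
                    return False
        return True


# --------------------------------------------------------------- samplers

def random_placement(n, sa, sb, boundary_radius, *, seed=0,
                     max_attempts=200000):
    """Random sequential insertion of n hard ellipses in a disk: uniform
    center and orientation, rejecting overlap and boundary violation."""
    if sa < sb or sb <= 0:
        raise ValueError("need sa >= sb > 0")
    rng = np.random.default_rng(seed)
    xs = np.empty(n)
    ys = np.empty(n)
    ts = np.empty(n)
    placed = 0
    for _ in range(max_attempts):
        if placed == n:
            break
        r = boundary_radius * math.sqrt(rng.random())
        a = 2 * math.pi * rng.random()
        x, y = r * math.cos(a), r * math.sin(a)
        th = math.pi * rng.random()
        if not _inside_disk(x, y, th, sa, sb, boundary_radius):
            continue
        ok = True
        for j in range(placed):
            if _overlap(x, y, th, xs[j], ys[j], ts[j], sa, sb):
                ok = False
                break
        if ok:
            xs[placed] = x
            ys[placed] = y
            ts[placed] = th
            placed += 1
    if placed < n:
        raise PackingInfeasibleError(
            f"placed {placed}/{n} ellipses in {max_attempts} attempts")
    return Configuration(xs, ys, ts, sa, sb, boundary_radius)


def random_placement_sections(sections, boundary_mask, *, seed=0,
                              max_attempts=5000):
    """Steric random re-arrangement of arbitrary pixelated sections (the
    form used with experimentally binarized chromosomes).

    sections : list of small 2D bool arrays
    boundary_mask : 2D bool array, admissible region

    Returns a labelled int image (0 background, i for section i).
    """
    from scipy import ndimage as ndi

    rng = np.random.default_rng(seed)
    boundary = np.asarray(boundary_mask, bool)
    occ = np.zeros_like(boundary)
    lab = np.zeros(boundary.shape, dtype=np.int32)
    h, w = boundary.shape
    for idx, sec in enumerate(sections, start=1):
        sec = np.asarray(sec, bool)
        done = False
        for _ in range(max_attempts):
            ang = rng.random() * 360.0
            rot = ndi.rotate(sec.astype(np.uint8), ang, order=0, reshape=True
                             ).astype(bool)
            sh, sw = rot.shape
            if sh >= h or sw >= w:
                continue
            i0 = rng.integers(0, h - sh)
            j0 = rng.integers(0, w - sw)
            sl = (slice(i0, i0 + sh), slice(j0, j0 + sw))
            if np.any(rot & ~boundary[sl]) or np.any(rot & occ[sl]):
                continue
            occ[sl] |= rot
            lab[sl][rot] = idx
            done = True
            break
        if not done:
            raise PackingInfeasibleError(f"could not place section {idx}")
    return lab


@njit(cache=True)
def _mc_kernel(xs, ys, ts, sa, sb, rb, pid, amp, lam, tx, ty, sweeps,
               moves, t0, tf, step_xy, step_ang, seed, record_every,
               rec):
    np.random.seed(seed)
    n = xs.shape[0]
    gamma = (tf / t0) ** (1.0 / max(sweeps - 1, 1))
    temp = t0
    trace = np.empty(sweeps)
    acc_first = 0
    irec = 0
    for sweep in range(sweeps):
        for _ in range(moves):
            i = np.random.randint(0, n)
            nx = xs[i] + step_xy * (2.0 * np.random.random() - 1.0)
            ny = ys[i] + step_xy * (2.0 * np.random.random() - 1.0)
            nt = ts[i] + step_ang * (2.0 * np.random.random() - 1.0)
            if not _inside_disk(nx, ny, nt, sa, sb, rb):
                continue
            ok = True
            for j in range(n):
                if j != i and _overlap(nx, ny, nt, xs[j], ys[j], ts[j],
                                       sa, sb):
                    ok = False
                    break
            if not ok:
                continue
            du = 0.0
            if pid != 0:
                for j in range(n):
                    if j == i:
                        continue
                    s_new = math.hypot(nx - xs[j], ny - ys[j])
                    s_old = math.hypot(xs[i] - xs[j], ys[i] - ys[j])
                    du += (_pair_u(s_new, pid, amp, lam, tx, ty)
                           - _pair_u(s_old, pid, amp, lam, tx, ty))
            if du <= 0.0 or np.random.random() < math.exp(-du / temp):
                xs[i] = nx
                ys[i] = ny
                ts[i] = nt
                if sweep == 0:
                    acc_first += 1
        trace[sweep] = _total_energy(xs, ys, pid, amp, lam, tx, ty)
        if record_every > 0 and (sweep + 1) % record_every == 0 \
                and irec < rec.shape[0]:
            for i in range(n):
                rec[irec, i, 0] = xs[i]
                rec[irec, i, 1] = ys[i]
                rec[irec, i, 2] = ts[i]
            irec += 1
        temp *= gamma
    return trace, acc_first, irec


def run_mc(config, params):
    """Run the Metropolis kernel from an existing configuration.

    Returns ``(final Configuration, records)`` where records is a
    (n_recorded, n, 3) pose array when ``params.record_every > 0``.
    Raises :class:`StepSizeError` on zero acceptance in the first sweep.
    """
    pot = params.build_potential(calib_s=4.0 * config.sb)
    xs = config.x.copy()
    ys = config.y.copy()
    ts = config.angle.copy()
    moves = params.moves_per_sweep or config.n
    nrec = params.sweeps // params.record_every if params.record_every else 0
    rec = np.empty((nrec, config.n, 3))
    trace, acc_first, irec = _mc_kernel(
        xs, ys, ts, config.sa, config.sb, config.boundary_radius,
        pot.pid, pot.amplitude, pot.lambda_b, pot.table_logs, pot.table_logu,
        params.sweeps, moves, params.t_initial, params.t_final,
        params.step_xy, params.step_ang, int(params.seed) % 2**31,
        params.record_every, rec)
    if acc_first == 0:
        raise StepSizeError("zero acceptance over the first sweep; reduce "
                            "step_xy / step_ang")
    out = Configuration(xs, ys, ts, config.sa, config.sb,
                        config.boundary_radius, energy=float(trace[-1]),
                        trace=trace)
    return out, rec[:irec]


def anneal(n, sa, sb, boundary_radius, params):
    """Random initialization followed by annealed Metropolis placement."""
    init = random_placement(n, sa, sb, boundary_radius, seed=params.seed,
                            max_attempts=params.max_attempts)
    out, _ = run_mc(init, params)
    return out


# ---------------------------------------------------- rendering, ensembles

def render_mask(config, pixel_size=0.1, margin_um=0.6):
    """Rasterize a configuration: returns ``(chromosome mask, boundary
    mask, pixel_size)`` on a grid covering the disk plus margin."""
    r = config.boundary_radius + margin_um
    n = 2 * int(np.ceil(r / pixel_size))
    c = (np.arange(n) + 0.5 - n / 2) * pixel_size
    xx, yy = np.meshgrid(c, c)
    mask = np.zeros((n, n), bool)
    for x, y, th in zip(config.x, config.y, config.angle):
        c0, s0 = np.cos(th), np.sin(th)
        u = (xx - x) * c0 + (yy - y) * s0
        v = -(xx - x) * s0 + (yy - y) * c0
        mask |= (u / config.sa) ** 2 + (v / config.sb) ** 2 <= 1.0
    boundary = np.hypot(xx, yy) <= config.boundary_radius
    return mask, boundary, pixel_size


def uniform_placement_reference(sa, sb, boundary_radius, *, pixel_size=0.1,
                                margin_um=0.6, n_samples=1500, seed=0):
    """Expected single-ellipse coverage map under uniform steric
    placement in the disk — the inhomogeneous null reference for
    ensemble pair correlations.

    Uniform placement cannot put centers within an ellipse-size margin
    of the boundary, so even interaction-free configurations are denser
    centrally; normalizing pair counts with this map removes exactly
    that admissible-region trend (and nothing else).
    """
    rng = np.random.default_rng(seed)
    acc = None
    k = 0
    attempts = 0
    while k < n_samples and attempts < 50 * n_samples:
        attempts += 1
        r = boundary_radius * math.sqrt(rng.random())
        a = 2 * math.pi * rng.random()
        x, y = r * math.cos(a), r * math.sin(a)
        th = math.pi * rng.random()
        if not _inside_disk(x, y, th, sa, sb, boundary_radius):
            continue
        cfg = Configuration(np.array([x]), np.array([y]), np.array([th]),
                            sa, sb, boundary_radius)
        m, _, _ = render_mask(cfg, pixel_size, margin_um)
        acc = m.astype(np.float64) if acc is None else acc + m
        k += 1
    if k == 0:
        raise PackingInfeasibleError("no admissible placement found")
    acc /= k
    # the disk is rotationally symmetric, so radially average the Monte
    # Carlo map to remove its sampling noise
    n = acc.shape[0]
    c = (np.arange(n) + 0.5 - n / 2) * pixel_size
    rr = np.hypot(c[:, None], c[None, :])
    nbin = int(np.ceil(rr.max() / pixel_size)) + 1
    idx = np.minimum((rr / pixel_size).astype(int), nbin - 1)
    sums = np.bincount(idx.ravel(), weights=acc.ravel(), minlength=nbin)
    counts = np.bincount(idx.ravel(), minlength=nbin)
    prof = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return prof[idx]


@dataclass
class EnsembleResult:
    s: np.ndarray             # bin centers (um)
    curves: np.ndarray        # (n_replicates, n_bins)
    mean: np.ndarray
    extrema: object           # plate_analysis.GiiExtrema
    configs: list


def simulate_ensemble(*, n_chr=20, a=2.1, b=0.8, boundary_radius=6.5,
                      params=None, n_replicates=200, pixel_size=0.1,
                      bin_um=0.1, s_max=8.0, n_boot=1000, seed=0,
                      steric_only=False, inhomogeneity_correction=True):
    """Replicate MC configurations, rasterize them at the analysis pixel
    size and push them through the same pair-correlation code path as
    experimental plates.  ``a`` and ``b`` are full axes (um).

    With ``steric_only=True`` (or potential 'none') configurations come
    from random sequential placement — the Fig.-4C-style null.

    ``inhomogeneity_correction`` selects the pair-count reference:
    ``False`` (default) is the flat plate-boundary normalization used
    for experimental plates; ``"uniform"`` normalizes against the
    uniform-placement coverage map (:func:`uniform_placement_reference`);
    ``"ensemble"`` normalizes against the replicate-mean mask — the
    standard inhomogeneous estimator, which removes every one-point
    (radial) density trend and leaves pure pair structure.  The
    corrected modes also apply the canonical finite-N factor
    n/(n-1) — with exactly n sections the cross-section pair density is
    (n-1)/n of the squared mean — so a structureless ensemble reads 1
    at all separations.
    """
    from .plate_analysis import gii_extrema, pair_correlation

    params = params or MCParams()
    rng = np.random.default_rng(seed)
    mode = {True: "uniform", False: "flat"}.get(inhomogeneity_correction,
                                                inhomogeneity_correction)
    reference = None
    if mode == "uniform":
        reference = uniform_placement_reference(
            a / 2, b / 2, boundary_radius, pixel_size=pixel_size,
            seed=int(rng.integers(2**31)))
    masks = []
    configs = []
    bnd = px = None
    for k in range(n_replicates):
        rep_seed = int(rng.integers(2**31))
        if steric_only or params.potential_name == "none":
            cfg = random_placement(n_chr, a / 2, b / 2, boundary_radius,
                                   seed=rep_seed)
        else:
            import dataclasses as _dc

            cfg = anneal(n_chr, a / 2, b / 2, boundary_radius,
                         _dc.replace(params, seed=rep_seed))
        mask, bnd, px = render_mask(cfg, pixel_size)
        masks.append(mask)
        configs.append(cfg)
    if mode == "ensemble":
        reference = np.mean(masks, axis=0)
    curves = []
    s_ref = None
    for mask in masks:
        ref = reference if reference is not None else bnd
        pc = pair_correlation(mask, ref, px, bin_um=bin_um, s_max=s_max)
        curves.append(pc.g)
        s_ref = pc.s
    curves = np.asarray(curves)
    if mode in ("uniform", "ensemble"):
        curves = curves * (n_chr / max(n_chr - 1, 1))
    ext = gii_extrema(s_ref, curves, n_boot=n_boot,
                      seed=int(rng.integers(2**31)))
    return EnsembleResult(s_ref, curves, curves.mean(axis=0), ext, configs)
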