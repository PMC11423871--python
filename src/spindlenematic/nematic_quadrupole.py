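"""2D defect-quadrupole model of a void and the void-void repulsion.

A tactoid-like void embedded in a 2D nematic with far-field director
along x can be represented by the simplest charge-neutral defect
arrangement that reproduces its deformation field: two -1/2 defects at
the void tips (+-beta/2, 0) and two +1/2 defects at (+-p, 0) inside.
In the one-constant Frank approximation each defect contributes a
harmonic angle field k_i * arg(z - z_i), so the superposition

    theta(z) = theta_inf + sum_i k_i arg(z - z_i)

solves the bulk Euler-Lagrange equation; the void boundary is *emergent*,
defined as the separatrix streamlines of the director through the -1/2
defects.  The inner spacing p is solved from the requested void width D
(the lens width is monotone decreasing in p, so bisection is exact).

For two such quadrupoles offset by d perpendicular to the far-field
director, charge neutrality makes the cross-pair logarithmic sum

    U_int(d) / k = -2 pi * sum_{i in A, j in B} k_i k_j ln |r_i - r_j|

well defined and system-size independent; it is exactly the cross term
of the Frank energy.  U_int is repulsive and decays as d^-4 in the far
field, the aligned-quadrupole law of 2D electrostatics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import (GeometryInfeasibleError, OverlapError,
                         SingularPointError, TracingError)

__all__ = [
    "DefectSet", "DefectQuadrupole", "InteractionCurve",
    "director_from_defects", "solve_geometry", "trace_void_boundary",
    "interaction_potential", "numeric_interaction",
]


@dataclass
class DefectSet:
    """Point defects (position, half-integer charge) plus far-field angle."""

    positions: np.ndarray     # (n, 2)
    charges: np.ndarray       # (n,)
    far_field: float = 0.0

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        self.charges = np.asarray(self.charges, float)
        if len(self.positions) != len(self.charges):
            raise ValueError("positions/charges length mismatch")
        if np.any(np.abs(2 * self.charges - np.round(2 * self.charges)) > 1e-9):
            raise ValueError("charges must be half-integer multiples")
        d = self.positions[:, None, :] - self.positions[None, :, :]
        r = np.hypot(d[..., 0], d[..., 1])
        np.fill_diagonal(r, np.inf)
        if np.any(r < 1e-12):
            raise ValueError("defect positions must be distinct")


def director_from_defects(defects, x, y, *, core_tol=1e-9):
    """Director angle theta(x, y) of a defect superposition (rad, not
    reduced mod pi so windings are visible to the caller)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    theta = np.full(np.broadcast_shapes(x.shape, y.shape), defects.far_field,
                    dtype=float)
    for (px, py), k in zip(defects.positions, defects.charges):
        dx, dy = x - px, y - py
        if np.any(np.hypot(dx, dy) < core_tol):
            raise SingularPointError("evaluation at a defect core")
        theta = theta + k * np.arctan2(dy, dx)
    return theta


@dataclass
class DefectQuadrupole:
    """One void: -1/2 defects at (+-beta/2, 0), +1/2 at (+-p, 0)."""

    beta: float
    D: float
    p: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0 < self.p < self.beta / 2):
            raise ValueError("need 0 < p < beta/2")

    def defect_set(self, offset=(0.0, 0.0)):
        ox, oy = offset
        pos = np.array([[-self.beta / 2 + ox, oy], [-self.p + ox, oy],
                        [self.p + ox, oy], [self.beta / 2 + ox, oy]])
        return DefectSet(pos, np.array([-0.5, 0.5, 0.5, -0.5]))


def _trace_separatrix(defects, beta, *, launch_angle=2 * np.pi / 3,
                      step=None, max_steps=20000):
    """Integrate the director streamline leaving the -1/2 defect at
    (beta/2, 0) along its upper-left separatrix (at 120 deg, by the local
    three-fold structure with theta_reg = 0) across the lens.  Fixed-step
    RK4 on the unit director with sign continuity; the trace ends when
    the path returns to the axis (y <= 0) or passes the opposite defect
    (x <= -beta/2), whichever comes first, with the crossing
    interpolated.

    Returns the (n, 2) path.
    """
    if step is None:
        step = beta / 400.0
    px = defects.positions[:, 0].copy()
    py = defects.positions[:, 1].copy()
    ks = defects.charges.copy()
    far = defects.far_field

    def unit_dir(p, prev):
        th = far + np.sum(ks * np.arctan2(p[1] - py, p[0] - px))
        u = np.array([np.cos(th), np.sin(th)])
        return u if np.dot(u, prev) >= 0 else -u

    start = np.array([beta / 2, 0.0])
    direction = np.array([np.cos(launch_angle), np.sin(launch_angle)])
    pos = start + 2.0 * step * direction
    prev = direction
    path = [pos.copy()]
    for _ in range(max_steps):
        k1 = unit_dir(pos, prev)
        k2 = unit_dir(pos + 0.5 * step * k1, k1)
        k3 = unit_dir(pos + 0.5 * step * k2, k2)
        k4 = unit_dir(pos + step * k3, k3)
        newpos = pos + step / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        if newpos[1] <= 0.0 or newpos[0] <= -beta / 2:
            if newpos[1] <= 0.0:
                t = pos[1] / (pos[1] - newpos[1])
            else:
                t = (pos[0] + beta / 2) / (pos[0] - newpos[0])
            path.append(pos + t * (newpos - pos))
            return np.asarray(path)
        prev = unit_dir(newpos, k4)
        pos = newpos
        path.append(pos.copy())
    raise TracingError("streamline did not return to the axis")


def solve_geometry(beta, D, *, tol=None):
    """Solve the inner defect spacing p reproducing void width D.

    The separatrix lens width is monotone decreasing in p on
    (0, beta/2): p -> beta/2 annihilates each +-1/2 pair and the width
    vanishes, p -> 0 gives the widest lens.  Bisection on p is therefore
    exact.  Raises :class:`GeometryInfeasibleError` when D is out of the
    attainable range.
    """
    if not (0 < D < beta):
        raise ValueError("need 0 < D < beta")
    tol = tol or 1e-4 * beta

    def width(p):
        q = DefectQuadrupole(beta, D, p) if 0 < p < beta / 2 else None
        path = _trace_separatrix(q.defect_set(), beta)
        return 2.0 * path[:, 1].max(), path

    lo, hi = 1e-3 * beta, beta / 2 * (1 - 1e-3)
    w_lo, _ = width(lo)
    w_hi, _ = width(hi)
    if not (w_hi <= D <= w_lo):
        raise GeometryInfeasibleError(
            f"width D={D} outside attainable range [{w_hi:.3g}, {w_lo:.3g}]")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        w_mid, path = width(mid)
        if abs(w_mid - D) < 1e-6 * beta or hi - lo < tol:
            break
        if w_mid > D:
            lo = mid
        else:
            hi = mid
    return DefectQuadrupole(beta, D, mid, meta={"achieved_width": w_mid})


def trace_void_boundary(quad, *, closure_tol=None):
    """Closed void boundary: the separatrix through the -1/2 defects,
    mirrored into the lower half plane.  Raises :class:`TracingError`
    when the streamline misses the opposite defect by more than the
    closure tolerance (beta/100 by default)."""
    closure_tol = closure_tol or quad.beta / 100.0
    path = _trace_separatrix(quad.defect_set(), quad.beta)
    end = path[-1]
    if abs(end[0] - (-quad.beta / 2)) > closure_tol or abs(end[1]) > closure_tol:
        raise TracingError(f"streamline closed at {end}, expected "
                           f"({-quad.beta / 2}, 0)")
    upper = np.vstack([[quad.beta / 2, 0.0], path])
    lower = upper[::-1].copy()
    lower[:, 1] *= -1
    return np.vstack([upper, lower[1:]])


def interaction_potential(quad, d_values):
    """Deformation-induced interaction of two parallel, director-aligned
    voids with centers separated by d perpendicular to the far-field
    director.  Returns an :class:`InteractionCurve` with U_int/k.

    Requires d > D (non-overlapping void boundaries)."""
    d_values = np.atleast_1d(np.asarray(d_values, float))
    if np.any(d_values <= quad.D):
        raise OverlapError("void boundaries overlap for d <= D")
    a = quad.defect_set()
    u = np.array([_cross_pair_sum(a, quad.defect_set(offset=(0.0, d)))
                  for d in d_values])
    return InteractionCurve(d_values, u)


def _cross_pair_sum(set_a, set_b):
    d = set_a.positions[:, None, :] - set_b.positions[None, :, :]
    r = np.hypot(d[..., 0], d[..., 1])
    kk = set_a.charges[:, None] * set_b.charges[None, :]
    return float(-2 * np.pi * np.sum(kk * np.log(r)))


@dataclass
class InteractionCurve:
    """Samples of U_int(d)/k (dimensionless, k = Frank constant)."""

    d: np.ndarray
    u: np.ndarray

    def loglog_slope(self, d_min, d_max):
        sel = (self.d >= d_min) & (self.d <= d_max) & (self.u > 0)
        if sel.sum() < 2:
            raise ValueError("too few points in range")
        return float(np.polyfit(np.log(self.d[sel]), np.log(self.u[sel]), 1)[0])


def numeric_interaction(quad, d, *, box=None, n=2400):
    """Brute-force oracle: the interaction energy as the numerically
    integrated Frank cross term  integral grad(theta_A) . grad(theta_B)
    over a large box.  Samples closer to a defect core than half a grid
    step are excised: the 1/r singularity is integrable and its angular
    average against the locally smooth partner gradient vanishes, but a
    sample landing arbitrarily close to a core would otherwise inject an
    unbounded quadrature error.  (A larger excision is not harmless: the
    disk's second-order contribution against the partner's gradient
    scales with its area and matters at the percent level.)"""
    box = box or 25.0 * quad.beta
    xs = np.linspace(-box, box, n)
    h = xs[1] - xs[0]
    xx, yy = np.meshgrid(xs, xs)
    gax = np.zeros_like(xx)
    gay = np.zeros_like(xx)
    gbx = np.zeros_like(xx)
    gby = np.zeros_like(xx)
    keep = np.ones_like(xx, dtype=bool)
    r_excise = 0.45 * h
    for (px, py), k in zip(quad.defect_set().positions,
                           quad.defect_set().charges):
        dx, dy = xx - px, yy - py
        r2 = np.maximum(dx**2 + dy**2, 1e-300)
        keep &= r2 > r_excise**2
        gax += k * (-dy) / r2
        gay += k * dx / r2
    for (px, py), k in zip(quad.defect_set(offset=(0.0, d)).positions,
                           quad.defect_set(offset=(0.0, d)).charges):
        dx, dy = xx - px, yy - py
        r2 = np.maximum(dx**2 + dy**2, 1e-300)
        keep &= r2 > r_excise**2
        gbx += k * (-dy) / r2
        gby += k * dx / r2
    return float(np.sum((gax * gbx + gay * gby) * keep) * h * h)
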